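"""Shared fixtures: phantom pipelines run once per session."""

import numpy as np
import pytest

from cortmap.phantom import PhantomSpec, medial_lateral_thickness
from cortmap.pipeline import PipelineConfig, run_pipeline


@pytest.fixture(scope="session")
def pipeline_bundle(tmp_path_factory):
    """Full default-phantom pipeline: volume, mesh, map, frame, regions, angles."""
    outdir = tmp_path_factory.mktemp("pipeline")
    cfg = PipelineConfig(outdir=str(outdir), seed=11, varus_angle=7.0)
    bundle = run_pipeline(cfg)
    bundle["outdir"] = outdir
    return bundle


@pytest.fixture(scope="session")
def ml_phantom_bundle():
    """Phantom with 6 mm medial / 4 mm lateral cortex, mapped in the proximal band."""
    from cortmap.cbt import FitConfig, estimate_thickness_map, extract_surface

    spec = PhantomSpec(
        thickness_field=medial_lateral_thickness(6.0, 4.0, side="right"),
        noise_sd=15.0, seed=5)
    from cortmap.phantom import generate_tibia_phantom
    volume, gt = generate_tibia_phantom(spec)
    mesh = extract_surface(volume, points_per_ring=40, ring_step=3)
    zfrac = mesh.vertices[:, 2] / spec.tibial_length
    mask = (zfrac >= 0.60) & (zfrac <= 0.72)
    tmap = estimate_thickness_map(volume, mesh, FitConfig(), vertex_mask=mask)
    return {"spec": spec, "volume": volume, "ground_truth": gt, "mesh": mesh,
            "thickness_map": tmap, "mask": mask}


@pytest.fixture(scope="session")
def noiseless_phantom():
    """Noise-free default phantom with its extracted surface (for frame geometry)."""
    from cortmap.cbt import extract_surface
    from cortmap.phantom import generate_tibia_phantom

    spec = PhantomSpec(noise_sd=0.0, seed=0)
    volume, gt = generate_tibia_phantom(spec)
    mesh = extract_surface(volume, points_per_ring=48, ring_step=2)
    return {"spec": spec, "volume": volume, "ground_truth": gt, "mesh": mesh}


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
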