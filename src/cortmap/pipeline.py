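"""End-to-end pipeline over the phantom: config, stages, artifact bundle.

Each stage writes CSV/JSON (and optionally NIfTI/PLY) outputs into an output
directory together with a log line naming the configuration hash, so a run is
reproducible from its config and seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .anatomy import build_tibial_cs
from .cbt import FitConfig, estimate_thickness_map, extract_surface
from .cohort import CohortSpec, generate_cohort
from .morphometry import (compute_fta, compute_section_centroids,
                          fit_anatomical_axis, fit_mct_plane, mct_coronal_angle)
from .phantom import (PhantomSpec, generate_alignment_meshes,
                      generate_mct_points, generate_tibia_phantom)
from .regions import aggregate_regions
from .stats import (PowerSpec, compare_areas_within_group, compare_groups,
                    correlate, sample_size_for_correlation)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Serializable stage parameters; the hash of this config tags every output."""

    outdir: str = "results"
    seed: int = 0
    side: str = "right"
    # phantom
    tibial_length: float = 330.0
    noise_sd: float = 15.0
    varus_angle: float = 7.0
    # surface / map
    points_per_ring: int = 40
    ring_step: int = 3
    half_length: float = 9.0
    profile_spacing: float = 0.3
    filter_radius: float = 0.0
    band: tuple = (0.28, 0.72)   # height-fraction window mapped for estimation
    # plateau digitization
    mct_noise_sd: float = 0.0
    # cohort
    cohort_seed: int = 0

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), sort_keys=True)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]

    @classmethod
    def from_json(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            d = json.load(fh)
        if "band" in d:
            d["band"] = tuple(d["band"])
        return cls(**d)


def _log(cfg: PipelineConfig, outdir: Path, stage: str, message: str) -> None:
    with open(outdir / "pipeline.log", "a") as fh:
        fh.write(f"cortmap {__version__} config={cfg.config_hash} "
                 f"seed={cfg.seed} [{stage}] {message}\n")


def _phantom_spec(cfg: PipelineConfig) -> PhantomSpec:
    return PhantomSpec(tibial_length=cfg.tibial_length, noise_sd=cfg.noise_sd,
                       varus_angle=cfg.varus_angle, side=cfg.side, seed=cfg.seed)


def run_pipeline(cfg: PipelineConfig, stages=("phantom", "estimate", "frame",
                                              "regions", "morphometry",
                                              "cohort", "stats"),
                 save_volume: bool = False) -> dict:
    """Run the requested stages in order; returns the in-memory artifact bundle.

    Stage failures raise with the stage name; outputs written before the
    failure are retained.
    """
    unknown = [s for s in stages if s not in _STAGES]
    if unknown:
        raise ValueError(f"unknown pipeline stage(s): {unknown}")
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    (outdir / "config.json").write_text(cfg.to_json())
    bundle: dict = {"config": cfg}
    for stage in stages:
        try:
            _STAGES[stage](cfg, outdir, bundle, save_volume=save_volume)
            _log(cfg, outdir, stage, "ok")
        except Exception as exc:
            _log(cfg, outdir, stage, f"FAILED: {exc}")
            raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc
    return bundle


def _stage_phantom(cfg, outdir, bundle, save_volume=False):
    volume, gt = generate_tibia_phantom(_phantom_spec(cfg))
    bundle["volume"], bundle["ground_truth"] = volume, gt
    gt.landmarks.to_json(str(outdir / "landmarks.json"))
    if save_volume:
        volume.save(str(outdir / "phantom.nii.gz"))


def _stage_estimate(cfg, outdir, bundle, **_):
    volume, gt = bundle["volume"], bundle["ground_truth"]
    mesh = extract_surface(volume, points_per_ring=cfg.points_per_ring,
                           ring_step=cfg.ring_step)
    L = gt.spec.tibial_length
    zfrac = mesh.vertices[:, 2] / L
    mask = (zfrac >= cfg.band[0]) & (zfrac <= cfg.band[1])
    fit_cfg = FitConfig(half_length=cfg.half_length, spacing=cfg.profile_spacing,
                        filter_radius=cfg.filter_radius)
    tmap = estimate_thickness_map(volume, mesh, fit_cfg, vertex_mask=mask)
    bundle["mesh"], bundle["thickness_map"] = mesh, tmap
    df = tmap.to_dataframe(mesh)
    df["config_hash"] = cfg.config_hash
    df.to_csv(outdir / "thickness_map.csv", index=False)


def _stage_frame(cfg, outdir, bundle, **_):
    gt = bundle["ground_truth"]
    cs = build_tibial_cs(bundle["mesh"], gt.landmarks)
    bundle["tibial_cs"] = cs
    cs.to_json(str(outdir / "tibial_cs.json"))


def _stage_regions(cfg, outdir, bundle, **_):
    gt = bundle["ground_truth"]
    reg = aggregate_regions(bundle["thickness_map"], bundle["mesh"],
                            bundle["tibial_cs"], gt.landmarks, side=cfg.side)
    bundle["regional"] = reg
    for name, df in (("regional_cbt.csv", reg.table), ("ratios.csv", reg.ratios)):
        df = df.copy()
        df["config_hash"] = cfg.config_hash
        df.to_csv(outdir / name, index=False)


def _stage_morphometry(cfg, outdir, bundle, **_):
    gt = bundle["ground_truth"]
    spec = _phantom_spec(cfg)
    femur, tibia, femoral_frame = generate_alignment_meshes(spec)
    fem_axis = fit_anatomical_axis(
        compute_section_centroids(femur, femoral_frame, "femur"))
    tib_axis = fit_anatomical_axis(
        compute_section_centroids(tibia, femoral_frame, "tibia"))
    fta = compute_fta(fem_axis, tib_axis, femoral_frame, side=cfg.side)
    pts = generate_mct_points(spec.mct_coronal_slope, noise_sd=cfg.mct_noise_sd,
                              seed=cfg.seed, side=cfg.side)
    plane = fit_mct_plane(pts)
    mct = mct_coronal_angle(plane, bundle.get("tibial_cs", gt.true_tibial_cs))
    bundle["fta"], bundle["mct_angle"] = fta, mct
    with open(outdir / "morphometry.json", "w") as fh:
        json.dump({"fta_deg": fta.fta, "varus_deviation_deg": fta.varus_deviation,
                   "mct_coronal_angle_deg": mct,
                   "true_fta_deg": gt.true_fta,
                   "true_mct_angle_deg": gt.true_mct_angle,
                   "config_hash": cfg.config_hash}, fh, indent=1)


def _stage_cohort(cfg, outdir, bundle, **_):
    cohort = generate_cohort(CohortSpec(seed=cfg.cohort_seed))
    bundle["cohort"] = cohort
    out = cohort.copy()
    out["config_hash"] = cfg.config_hash
    out.to_csv(outdir / "cohort.csv", index=False)


def _stage_stats(cfg, outdir, bundle, **_):
    cohort = bundle["cohort"]
    rows = []
    for group, sub in cohort.groupby("group"):
        areas = np.column_stack([sub[f"cbt_most_proximal_{s}"]
                                 for s in ("medial", "anterior", "lateral",
                                           "posterior")])
        rep = compare_areas_within_group(areas)
        rows.append({"analysis": "areas_most_proximal", "group": group,
                     "test": rep.test_name, "p": rep.p_value,
                     "directions": "; ".join(rep.directions)})
        rep = correlate(sub["mct"], sub["cbt_most_proximal_medial"])
        rows.append({"analysis": "mct_vs_most_proximal_medial", "group": group,
                     "test": rep.test_name, "p": rep.p_value,
                     "directions": f"cc={rep.statistic:.3f}"})
    rep = compare_groups({g: sub["cbt_most_proximal_medial"].to_numpy()
                          for g, sub in cohort.groupby("group")})
    rows.append({"analysis": "groups_most_proximal_medial", "group": "all",
                 "test": rep.test_name, "p": rep.p_value,
                 "directions": "; ".join(rep.directions)})
    import pandas as pd
    df = pd.DataFrame(rows)
    df["config_hash"] = cfg.config_hash
    df.to_csv(outdir / "stats.csv", index=False)
    bundle["stats"] = df
    n_m = sample_size_for_correlation(PowerSpec(rho=0.594))
    n_f = sample_size_for_correlation(PowerSpec(rho=0.554))
    with open(outdir / "sample_size.json", "w") as fh:
        json.dump({"oa_male_rho": 0.594, "oa_male_n": n_m,
                   "oa_female_rho": 0.554, "oa_female_n": n_f,
                   "alpha": 0.05, "power": 0.80,
                   "config_hash": cfg.config_hash}, fh, indent=1)
    bundle["sample_size"] = {"oa_male": n_m, "oa_female": n_f}


_STAGES = {
    "phantom": _stage_phantom,
    "estimate": _stage_estimate,
    "frame": _stage_frame,
    "regions": _stage_regions,
    "morphometry": _stage_morphometry,
    "cohort": _stage_cohort,
    "stats": _stage_stats,
}
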