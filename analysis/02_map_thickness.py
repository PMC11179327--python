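#!/usr/bin/env python
"""Extract the cortical surface and estimate the per-vertex thickness map.

Runs the two-pass model fit (free cortical density, global pooling, fixed
density refit) along every surface normal in the diaphysis and reports the
recovered global density and map accuracy against the 5 mm ground truth.
"""
from pathlib import Path

import numpy as np

from cortmap.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parents[1] / "results" / "analysis"

def main():
    cfg = PipelineConfig(outdir=str(OUT), seed=11, varus_angle=7.0)
    bundle = run_pipeline(cfg, stages=("phantom", "estimate"))
    tmap = bundle["thickness_map"]
    est = [f is not None for f in tmap.fits]
    print(f"vertices fitted: {int(np.sum(est))}  converged: {tmap.n_converged}")
    print(f"global cortical density: {tmap.global_cortical_density:.0f} HU "
          f"(truth 1200)")
    print(f"mean thickness: {np.nanmean(tmap.thickness):.3f} mm (truth 5.000)")
    print(f"thickness map -> {OUT/'thickness_map.csv'}")

if __name__ == "__main__":
    main()
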