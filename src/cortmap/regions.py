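"""Standardized regional CBT: 6 height bands x 4 axial sectors = 24 regions.

Heights are fractions of tibial length (eminence midpoint to talar-dome
midpoint); the diaphysis is the 30-70% band split into six sub-bands.  Sectors
are 90-degree wedges of the axial (xy) plane of the tibial frame centred on
the medial, anterior, lateral and posterior directions.  Regional values are
arithmetic means of converged per-vertex thickness; standardized values divide
by tibial length and are reported on a x10^-3 scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .anatomy import Landmarks, TibialCS
from .cbt import SurfaceMesh, ThicknessMap

__all__ = [
    "HEIGHT_BANDS",
    "SECTORS",
    "RegionalCBT",
    "compute_tibial_length",
    "assign_height_band",
    "assign_sector",
    "standardize",
    "aggregate_regions",
]

# (name, lower fraction, upper fraction); bands are half-open [lo, hi) with the
# uppermost band closed at 0.70
HEIGHT_BANDS = (
    ("most_distal", 0.30, 0.37),
    ("distal", 0.37, 0.43),
    ("central_distal", 0.43, 0.50),
    ("central_proximal", 0.50, 0.57),
    ("proximal", 0.57, 0.63),
    ("most_proximal", 0.63, 0.70),
)

SECTORS = ("medial", "anterior", "lateral", "posterior")

LOW_COUNT = 20  # fewer points than ever observed per region; flag, don't drop


@dataclass
class RegionalCBT:
    """24-region table of actual and standardized thickness plus M/L, A/P ratios."""

    table: pd.DataFrame       # 24 rows: height_band, sector, n_points, means
    ratios: pd.DataFrame      # per height band + total: ml_ratio, ap_ratio
    tibial_length: float


def compute_tibial_length(landmarks: Landmarks) -> float:
    """Distance from the eminence midpoint to the talar-dome midpoint (mm)."""
    L = float(np.linalg.norm(landmarks.eminence_midpoint - landmarks.talar_midpoint))
    if L == 0:
        raise ValueError("eminence and talar midpoints coincide")
    return L


def assign_height_band(z_fraction: float) -> str | None:
    """Band name for a height fraction, or None outside the 30-70% diaphysis."""
    for name, lo, hi in HEIGHT_BANDS:
        if lo <= z_fraction < hi:
            return name
    if z_fraction == HEIGHT_BANDS[-1][2]:
        return HEIGHT_BANDS[-1][0]
    return None


def assign_sector(x: float, y: float, side: str = "right") -> str:
    """Axial sector of a point in the tibial frame.

    Azimuth is measured from the medial direction (x_eff = -x for a right
    tibia, +x for a left one); wedges are half-open counterclockwise, so a
    point exactly on the 45-degree medial/anterior boundary is anterior.
    """
    if x == 0 and y == 0:
        raise ValueError("sector undefined at the axis origin")
    x_eff = -x if side == "right" else x
    theta = np.arctan2(y, x_eff)
    k = int(np.floor((theta + np.pi / 4) / (np.pi / 2)))
    return {0: "medial", 1: "anterior", 2: "lateral", -2: "lateral",
            -1: "posterior"}[k]


def standardize(actual_mm: float, tibial_length_mm: float) -> float:
    """Thickness / tibial length on the x10^-3 scale."""
    if tibial_length_mm <= 0:
        raise ValueError("tibial length must be positive")
    return actual_mm / tibial_length_mm * 1e3


def aggregate_regions(tmap: ThicknessMap, mesh: SurfaceMesh, cs: TibialCS,
                      landmarks: Landmarks, side: str = "right") -> RegionalCBT:
    """Mean converged thickness per region, standardized values and ratios.

    Height fractions are measured along the frame z-axis from the projected
    talar-dome midpoint.  Empty regions are reported with ``n_points = 0`` and
    NaN means; regions below the low-count threshold are flagged.
    """
    L = compute_tibial_length(landmarks)
    local = cs.to_local(mesh.vertices)
    z_ref = cs.to_local(landmarks.talar_midpoint)[2]
    zfrac = (local[:, 2] - z_ref) / L

    rows = []
    values: dict[tuple[str, str], np.ndarray] = {}
    ok = tmap.converged & np.isfinite(tmap.thickness)
    band_names = [assign_height_band(f) for f in zfrac]
    sector_names = [assign_sector(px, py, side) if (px, py) != (0, 0) else None
                    for px, py in zip(local[:, 0], local[:, 1])]
    for band, lo, hi in HEIGHT_BANDS:
        for sector in SECTORS:
            sel = ok & np.array([b == band and s == sector
                                 for b, s in zip(band_names, sector_names)])
            vals = tmap.thickness[sel]
            values[(band, sector)] = vals
            mean_actual = float(np.mean(vals)) if len(vals) else np.nan
            rows.append({
                "height_band": band,
                "sector": sector,
                "n_points": int(len(vals)),
                "mean_actual_mm": mean_actual,
                "mean_standardized": (standardize(mean_actual, L)
                                      if len(vals) else np.nan),
                "low_count": bool(len(vals) < LOW_COUNT),
            })
    table = pd.DataFrame(rows)

    ratio_rows = []
    for band, _, _ in HEIGHT_BANDS:
        ratio_rows.append(_ratio_row(band, {s: values[(band, s)] for s in SECTORS}))
    totals = {s: np.concatenate([values[(b, s)] for b, _, _ in HEIGHT_BANDS])
              for s in SECTORS}
    ratio_rows.append(_ratio_row("total", totals))
    ratios = pd.DataFrame(ratio_rows)
    return RegionalCBT(table=table, ratios=ratios, tibial_length=L)


def _ratio_row(label: str, sector_values: dict) -> dict:
    def mean(s):
        v = sector_values[s]
        return float(np.mean(v)) if len(v) else np.nan
    m, l = mean("medial"), mean("lateral")
    a, p = mean("anterior"), mean("posterior")
    return {
        "height_band": label,
        "ml_ratio": m / l if l and np.isfinite(l) and l != 0 else np.nan,
        "ap_ratio": a / p if p and np.isfinite(p) and p != 0 else np.nan,
    }
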