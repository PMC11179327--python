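"""Synthetic cohort generator with a configurable MCT-CBT correlation.

Each subject draws demographics, alignment angles and 24 regional standardized
CBT values from group-specific normal marginals (truncated to physical
ranges).  The MCT coronal angle and the most proximal-medial standardized CBT
are drawn jointly Gaussian with the group's correlation ``rho`` (a Gaussian
copula with normal marginals); all other regions are independent given the
group.  Group defaults follow the published cohort tables housed in
``reference_tables``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import reference_tables as ref
from .regions import HEIGHT_BANDS, SECTORS

__all__ = ["GroupSpec", "CohortSpec", "generate_cohort"]

# truncation keeps marginals physical; bounds are far (>~3 SD) from every
# group mean so sample moments still converge to the spec values
TRUNCATION = {
    "age": (30.0, 105.0), "height": (120.0, 200.0), "weight": (25.0, 130.0),
    "bmi": (12.0, 45.0), "fta": (150.0, 215.0), "mct": (0.0, 35.0),
    "cbt": (2.0, 60.0),
}

CORRELATED_REGION = ("most_proximal", "medial")


def _region_cols():
    bands = [b for b, _, _ in HEIGHT_BANDS]
    return [f"cbt_{b}_{s}" for b in bands for s in SECTORS]


@dataclass
class GroupSpec:
    """Per-group marginal moments and the MCT-CBT link."""

    name: str
    sex: str
    diagnosis: str
    n: int
    demographics: dict          # var -> (mean, sd)
    regional: dict              # (band, sector) -> (mean, sd), standardized
    rho: float                  # MCT vs most proximal-medial CBT

    def validate(self) -> None:
        if self.n < 0:
            raise ValueError(f"group {self.name}: n must be >= 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"group {self.name}: |rho| must be <= 1")
        for var, (m, sd) in self.demographics.items():
            if sd < 0:
                raise ValueError(f"group {self.name}: negative SD for {var}")
        for key, (m, sd) in self.regional.items():
            if sd < 0:
                raise ValueError(f"group {self.name}: negative SD for region {key}")


@dataclass
class CohortSpec:
    """Full cohort description; defaults reproduce the published group moments."""

    groups: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            self.groups = default_groups()

    def validate(self) -> None:
        for g in self.groups:
            g.validate()


def default_groups(n_override: dict | None = None) -> list:
    reg = ref.regional_reference()
    reg = reg[reg["height_band"] != "total"]
    groups = []
    for name, n in ref.GROUP_N.items():
        if n_override and name in n_override:
            n = n_override[name]
        sub = reg[reg["group"] == name]
        regional = {(r.height_band, r.sector): (r.mean, r.sd)
                    for r in sub.itertuples()}
        groups.append(GroupSpec(
            name=name,
            sex="male" if name.endswith("male") and not name.endswith("female")
                else "female",
            diagnosis="oa" if name.startswith("oa") else "healthy",
            n=n,
            demographics=dict(ref.DEMOGRAPHICS[name]),
            regional=regional,
            rho=ref.MCT_CBT_CORRELATION[name],
        ))
    return groups


def _truncated_normal(rng, mean, sd, bounds, size):
    """Normal draws re-sampled into bounds (bounds are several SD out)."""
    if sd == 0:
        return np.full(size, mean)
    out = rng.normal(mean, sd, size)
    bad = (out < bounds[0]) | (out > bounds[1])
    while np.any(bad):
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < bounds[0]) | (out > bounds[1])
    return out


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """One row per subject: group, sex, demographics, FTA, MCT, 24 regional CBTs."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    cols = (["subject", "group", "sex", "diagnosis", "age", "height", "weight",
             "bmi", "fta", "mct"] + _region_cols())
    rows = []
    sid = 0
    for g in spec.groups:
        if g.n == 0:
            continue
        demo = {var: _truncated_normal(rng, m, sd, TRUNCATION[var], g.n)
                for var, (m, sd) in g.demographics.items()
                if var not in ("mct",)}
        # joint draw: MCT and the correlated region share a Gaussian copula
        mu_m, sd_m = g.demographics["mct"]
        mu_c, sd_c = g.regional[CORRELATED_REGION]
        cov = np.array([[1.0, g.rho], [g.rho, 1.0]])
        z = rng.multivariate_normal([0.0, 0.0], cov, size=g.n,
                                    method="cholesky")
        mct = np.clip(mu_m + sd_m * z[:, 0], *TRUNCATION["mct"])
        cbt_link = np.clip(mu_c + sd_c * z[:, 1], *TRUNCATION["cbt"])
        regional = {}
        for (band, sector), (m, sd) in g.regional.items():
            key = f"cbt_{band}_{sector}"
            if (band, sector) == CORRELATED_REGION:
                regional[key] = cbt_link
            else:
                regional[key] = _truncated_normal(rng, m, sd, TRUNCATION["cbt"], g.n)
        for i in range(g.n):
            row = {"subject": sid, "group": g.name, "sex": g.sex,
                   "diagnosis": g.diagnosis,
                   "age": demo["age"][i], "height": demo["height"][i],
                   "weight": demo["weight"][i], "bmi": demo["bmi"][i],
                   "fta": demo["fta"][i], "mct": mct[i]}
            row.update({k: v[i] for k, v in regional.items()})
            rows.append(row)
            sid += 1
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)
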