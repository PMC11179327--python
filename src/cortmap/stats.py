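"""Normality-gated statistics, reliability and exact-power sample size.

Every comparison first applies a Shapiro-Wilk gate at the 0.05 level and then
selects the parametric or rank-based test: repeated-measures ANOVA vs
Friedman for within-group area comparisons, one-way ANOVA vs Kruskal-Wallis
between groups, Pearson vs Spearman for correlations.  The gate decision is
recorded in every report so a run is fully reproducible.

The sample-size calculation for a correlation uses the exact sampling
distribution of the Pearson correlation under bivariate normality (the
hypergeometric-function density), integrating it over the two-sided rejection
region of the level-alpha t-test of zero correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import integrate, special
from scipy import stats as sps

__all__ = [
    "TestReport",
    "PowerSpec",
    "compare_areas_within_group",
    "compare_groups",
    "correlate",
    "icc",
    "exact_power_correlation",
    "fisher_z_power_correlation",
    "sample_size_for_correlation",
]

GATE_ALPHA = 0.05


@dataclass
class TestReport:
    """Outcome of one gated test with its normality decision and summaries."""

    test_name: str
    statistic: float
    p_value: float
    gate: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    posthoc: pd.DataFrame | None = None
    directions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")


def _group_summary(values: np.ndarray) -> dict:
    v = np.asarray(values, dtype=float)
    m, sd = float(np.mean(v)), float(np.std(v, ddof=1))
    half = sps.t.ppf(0.975, len(v) - 1) * sd / np.sqrt(len(v))
    return {"n": len(v), "mean": m, "sd": sd, "ci95": (m - half, m + half)}


def _shapiro_normal(x: np.ndarray, alpha: float = GATE_ALPHA) -> tuple[bool, float]:
    p = float(sps.shapiro(np.asarray(x, dtype=float)).pvalue)
    return p >= alpha, p


# ---------------------------------------------------------------------------
# within-group area comparison (repeated measures)
# ---------------------------------------------------------------------------

def _rm_anova(data: np.ndarray) -> tuple[float, float]:
    """Two-way within-subject (subjects x conditions) F-test, closed form."""
    n, k = data.shape
    grand = data.mean()
    subj = data.mean(axis=1)
    cond = data.mean(axis=0)
    ss_cond = n * np.sum((cond - grand) ** 2)
    ss_subj = k * np.sum((subj - grand) ** 2)
    ss_tot = np.sum((data - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    ms_cond = ss_cond / df_cond
    ms_err = ss_err / df_err
    if ms_err <= 0:
        raise ValueError("degenerate repeated-measures data (zero error variance)")
    F = ms_cond / ms_err
    return float(F), float(sps.f.sf(F, df_cond, df_err))


def compare_areas_within_group(values: np.ndarray, labels=("medial", "anterior",
                                                           "lateral", "posterior"),
                               posthoc: bool = True) -> TestReport:
    """Compare repeated area measurements within one group of subjects.

    ``values`` is subjects x areas.  Normal residuals select repeated-measures
    ANOVA (post hoc: paired t with Holm); otherwise Friedman (post hoc:
    pairwise Wilcoxon with Holm).  Directional summaries report the
    medial-lateral and anterior-posterior contrasts.
    """
    data = np.asarray(values, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need >= 2 subjects with repeated area measurements")
    n, k = data.shape
    resid = data - data.mean(axis=1, keepdims=True) - data.mean(axis=0) + data.mean()
    if np.allclose(resid, 0):
        normal, p_gate = True, 1.0  # identical columns: trivially null
        F, p = 0.0, 1.0
        name = "rm_anova"
    else:
        normal, p_gate = _shapiro_normal(resid.ravel())
        if normal:
            name = "rm_anova"
            F, p = _rm_anova(data)
        else:
            name = "friedman"
            F, p = sps.friedmanchisquare(*data.T)
            F, p = float(F), float(p)
    report = TestReport(
        test_name=name, statistic=F, p_value=p,
        gate={"residual_normal": normal, "shapiro_p": p_gate},
        summary={lab: _group_summary(data[:, j]) for j, lab in enumerate(labels)},
    )
    if posthoc:
        rows = []
        for i, j in combinations(range(k), 2):
            a, b = data[:, i], data[:, j]
            if np.allclose(a, b):
                stat_ij, p_ij = 0.0, 1.0
            elif normal:
                stat_ij, p_ij = sps.ttest_rel(a, b)
            else:
                stat_ij, p_ij = sps.wilcoxon(a, b)
            rows.append({"a": labels[i], "b": labels[j], "stat": float(stat_ij),
                         "p_raw": float(p_ij),
                         "direction": f"{labels[i]} > {labels[j]}"
                         if a.mean() > b.mean() else f"{labels[i]} < {labels[j]}"})
        ph = pd.DataFrame(rows)
        ph["p_holm"] = _holm(ph["p_raw"].to_numpy())
        report.posthoc = ph
        report.directions = [
            f"{r.direction} (p={r.p_holm:.4g})"
            for r in ph.itertuples()
            if r.p_holm < 0.05 and {r.a, r.b} in ({"medial", "lateral"},
                                                  {"anterior", "posterior"})]
    return report


# ---------------------------------------------------------------------------
# between-group comparison
# ---------------------------------------------------------------------------

def compare_groups(groups: dict, posthoc: bool = True) -> TestReport:
    """Gated one-way ANOVA (+Tukey) or Kruskal-Wallis (+Dunn-Holm).

    ``groups`` maps group label to a 1D array of observations.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[g], dtype=float) for g in labels]
    if len(arrays) < 2 or any(len(a) < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 observations each")
    if all(np.ptp(a) == 0 for a in arrays):
        raise ValueError("constant data in all groups; comparison degenerate")
    gate = {}
    normal = True
    for g, a in zip(labels, arrays):
        ok, p = _shapiro_normal(a)
        gate[g] = p
        normal = normal and ok
    if normal:
        name = "one_way_anova"
        stat, p = sps.f_oneway(*arrays)
    else:
        name = "kruskal_wallis"
        stat, p = sps.kruskal(*arrays)
    report = TestReport(
        test_name=name, statistic=float(stat), p_value=float(p),
        gate={"all_normal": normal, "shapiro_p": gate},
        summary={g: _group_summary(a) for g, a in zip(labels, arrays)},
    )
    if posthoc:
        if normal:
            from statsmodels.stats.multicomp import pairwise_tukeyhsd
            flat = np.concatenate(arrays)
            tags = np.concatenate([[g] * len(a) for g, a in zip(labels, arrays)])
            tk = pairwise_tukeyhsd(flat, tags)
            ph = pd.DataFrame(tk.summary().data[1:], columns=tk.summary().data[0])
            ph = ph.rename(columns={"group1": "a", "group2": "b",
                                    "p-adj": "p_adj"})
        else:
            ph = _dunn_holm(arrays, labels)
        report.posthoc = ph
        means = {g: float(np.mean(a)) for g, a in zip(labels, arrays)}
        report.directions = [
            f"{r.a} {'>' if means[r.a] > means[r.b] else '<'} {r.b}"
            for r in ph.itertuples() if float(r.p_adj) < 0.05]
    return report


def _holm(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (m - rank) * p[idx])
        adj[idx] = min(running, 1.0)
    return adj


def _dunn_holm(arrays, labels) -> pd.DataFrame:
    """Dunn's rank-based pairwise test after Kruskal-Wallis, Holm-adjusted."""
    flat = np.concatenate(arrays)
    ranks = sps.rankdata(flat)
    N = len(flat)
    # tie correction
    _, counts = np.unique(flat, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    splits = np.cumsum([len(a) for a in arrays])[:-1]
    rank_groups = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in rank_groups]
    rows = []
    for i, j in combinations(range(len(arrays)), 2):
        ni, nj = len(arrays[i]), len(arrays[j])
        se = np.sqrt(tie * N * (N + 1) / 12.0 * (1.0 / ni + 1.0 / nj))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append({"a": labels[i], "b": labels[j], "stat": float(z),
                     "p_raw": float(2 * sps.norm.sf(abs(z)))})
    ph = pd.DataFrame(rows)
    ph["p_adj"] = _holm(ph["p_raw"].to_numpy())
    return ph


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def correlate(x, y) -> TestReport:
    """Pearson if both margins pass the Shapiro gate, Spearman otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant margin: correlation undefined")
    okx, px = _shapiro_normal(x)
    oky, py = _shapiro_normal(y)
    if okx and oky:
        name = "pearson"
        r, p = sps.pearsonr(x, y)
    else:
        name = "spearman"
        r, p = sps.spearmanr(x, y)
    return TestReport(test_name=name, statistic=float(r), p_value=float(p),
                      gate={"x_normal": okx, "y_normal": oky,
                            "shapiro_p": (px, py)},
                      summary={"n": len(x)})


# ---------------------------------------------------------------------------
# reliability
# ---------------------------------------------------------------------------

def icc(measurements: np.ndarray, mode: str = "intra") -> float:
    """Variance-components intraclass correlation for subjects x measurements.

    ``intra``: two-way mixed, consistency, single measures (ICC3,1) — repeats
    of one rater.  ``inter``: two-way random, absolute agreement, single
    measures (ICC2,1) — different raters.
    """
    data = np.asarray(measurements, dtype=float)
    if data.ndim != 2 or data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 measurement columns")
    if np.ptp(data) == 0:
        raise ValueError("zero total variance; ICC undefined")
    if mode not in ("intra", "inter"):
        raise ValueError("mode must be 'intra' or 'inter'")
    import pingouin as pg
    n, k = data.shape
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(n), k),
        "rater": np.tile(np.arange(k), n),
        "score": data.ravel(),
    })
    res = pg.intraclass_corr(long, targets="subject", raters="rater",
                             ratings="score")
    # pingouin labels: ICC(C,1) = two-way consistency single (ICC3,1),
    # ICC(A,1) = two-way absolute agreement single (ICC2,1)
    wanted = "ICC(C,1)" if mode == "intra" else "ICC(A,1)"
    sel = res.loc[res["Type"].isin([wanted, "ICC3" if mode == "intra" else "ICC2"])]
    return float(sel["ICC"].iloc[0])


# ---------------------------------------------------------------------------
# exact power / sample size for a correlation
# ---------------------------------------------------------------------------

@dataclass
class PowerSpec:
    rho: float
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must be in (0, 1)")
        if not -1 < self.rho < 1 or self.rho == 0:
            raise ValueError("rho must be in (-1, 1) and non-zero")


def _r_density(r, rho, n):
    """Exact density of the sample correlation under bivariate normality."""
    logc = (np.log(n - 2) + special.gammaln(n - 1)
            + (n - 1) / 2 * np.log1p(-rho**2)
            + (n - 4) / 2 * np.log1p(-r**2)
            - 0.5 * np.log(2 * np.pi) - special.gammaln(n - 0.5)
            - (n - 1.5) * np.log1p(-rho * r))
    return np.exp(logc) * special.hyp2f1(0.5, 0.5, n - 0.5, (rho * r + 1) / 2)


def _r_critical(n: int, alpha: float) -> float:
    tcrit = sps.t.ppf(1 - alpha / 2, n - 2)
    return tcrit / np.sqrt(n - 2 + tcrit**2)


def exact_power_correlation(rho: float, n: int, alpha: float = 0.05) -> float:
    """Power of the two-sided level-alpha test of zero correlation at true rho."""
    if n < 4:
        raise ValueError("n must be >= 4")
    rc = _r_critical(n, alpha)
    lo, _ = integrate.quad(_r_density, -1, -rc, args=(rho, n))
    hi, _ = integrate.quad(_r_density, rc, 1, args=(rho, n))
    return float(lo + hi)


def fisher_z_power_correlation(rho: float, n: int, alpha: float = 0.05) -> float:
    """Fisher-z approximation of the same power (cross-check evaluator)."""
    if n < 4:
        raise ValueError("n must be >= 4")
    za = sps.norm.ppf(1 - alpha / 2)
    delta = np.arctanh(rho) * np.sqrt(n - 3)
    return float(sps.norm.sf(za - delta) + sps.norm.cdf(-za - delta))


def sample_size_for_correlation(spec: PowerSpec, method: str = "exact",
                                n_max: int = 10000) -> int:
    """Smallest n >= 4 whose test of zero correlation reaches the target power."""
    evaluator = {"exact": exact_power_correlation,
                 "fisher_z": fisher_z_power_correlation}[method]
    for n in range(4, n_max + 1):
        if evaluator(spec.rho, n, spec.alpha) >= spec.power:
            return n
    raise ValueError(f"power {spec.power} not reached by n = {n_max}")
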