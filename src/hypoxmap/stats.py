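"""Descriptive statistics and the nonparametric test battery for per-patient records.

Conventions
-----------
* Quartiles use linear interpolation between order statistics at positions
  0.25(n-1) and 0.75(n-1) (numpy's default, R type 7).
* Standard deviations are sample SDs (n-1 denominator); a single observation
  reports SD 0 by convention (logged).
* Wilcoxon signed-rank: zero differences dropped, ties mid-ranked; exact
  two-sided p by enumeration of sign assignments for n <= 15, normal
  approximation with continuity and tie correction otherwise.
* Wilcoxon rank-sum (Mann-Whitney): exact null distribution (dynamic-
  programming enumeration of rank subsets) when min(n) <= 8 and there are no
  ties, normal approximation with tie correction otherwise.
* Friedman test: within-row mid-ranking, chi-square with k-1 df (scipy).
* Bonferroni: p_adj = min(1, m * p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "SummaryStats",
    "TestResult",
    "summarize",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "friedman",
    "bonferroni",
    "cohort_table",
    "load_table3",
    "records_from_frame",
    "round_half_away",
]

TABLE_COLUMNS = [
    "fdg_suv_max",
    "mtv_cm3",
    "tlg",
    "fmiso_suv_max",
    "hsv_fdg_cm3",
    "hsv_mri_cm3",
    "hsv_union_cm3",
    "mri_volume_cm3",
]


@dataclass
class PatientRecord:
    """One row of the per-patient metrics table."""

    patient: str
    fdg_suv_max: float
    mtv_cm3: float
    tlg: float
    fmiso_suv_max: float
    hsv_fdg_cm3: float
    hsv_mri_cm3: float
    hsv_union_cm3: float
    mri_volume_cm3: float

    def __post_init__(self) -> None:
        for name in ("mtv_cm3", "hsv_fdg_cm3", "hsv_mri_cm3", "hsv_union_cm3", "mri_volume_cm3"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        tol = 0.02  # printed values are rounded to 2 decimals
        if self.hsv_union_cm3 < max(self.hsv_fdg_cm3, self.hsv_mri_cm3) - tol:
            raise ValueError("union hypoxic volume cannot be below its components")

    @property
    def hypoxic(self) -> bool:
        return self.hsv_union_cm3 > 0


@dataclass
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float


@dataclass
class TestResult:
    statistic: float
    p_value: float
    p_adjusted: float
    method: str
    n: tuple

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 and 0.0 <= self.p_adjusted <= 1.0):
            raise ValueError("p-values must lie in [0, 1]")
        if self.p_adjusted + 1e-12 < self.p_value:
            raise ValueError("adjusted p cannot be below the raw p")


def round_half_away(x: float, decimals: int = 1) -> float:
    """Round half away from zero (display convention for summary tables)."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean/SD/median/quartiles/min/max with the conventions above."""
    v = np.asarray(list(values), dtype=float)
    if v.size == 0:
        raise ValueError("summarize requires at least one value")
    if v.size == 1:
        logger.info("summarize: single observation, SD reported as 0 by convention")
        sd = 0.0
    else:
        sd = float(v.std(ddof=1))
    return SummaryStats(
        n=int(v.size),
        mean=float(v.mean()),
        sd=sd,
        median=float(np.quantile(v, 0.5)),
        q1=float(np.quantile(v, 0.25)),
        q3=float(np.quantile(v, 0.75)),
        min=float(v.min()),
        max=float(v.max()),
    )


def _signed_rank_exact_p(w: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the positive-rank sum by enumerating sign vectors.

    Mid-ranks may be half-integers; doubling makes them integers so the null
    distribution is a polynomial convolution."""
    r2 = np.round(ranks * 2).astype(int)
    total = r2.sum()
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(round(w * 2))
    p_le = dist[: w2 + 1].sum()
    p_ge = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(
    x: Sequence[float], y: Sequence[float], m_comparisons: int = 1
) -> TestResult:
    """Two-sided paired Wilcoxon signed-rank test."""
    x = np.asarray(list(x), dtype=float)
    y = np.asarray(list(y), dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("paired samples of equal length n >= 2 required")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all paired differences are zero")
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    n = d.size
    if n <= 15:
        p = _signed_rank_exact_p(w_pos, ranks)
        method = "wilcoxon-signed-rank-exact"
    else:
        mean = n * (n + 1) / 4.0
        tie_counts = np.unique(ranks, return_counts=True)[1]
        var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
        cc = 0.5 * np.sign(w_pos - mean)
        z = (w_pos - mean - cc) / np.sqrt(var)
        p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "wilcoxon-signed-rank-normal"
    return TestResult(w_pos, p, bonferroni([p], m_comparisons)[0], method, (n,))


def _rank_sum_null_counts(n1: int, n2: int) -> np.ndarray:
    """counts[w] = number of n1-subsets of ranks 1..n1+n2 with rank sum w."""
    N = n1 + n2
    max_w = n1 * N
    # dp[k][w]: ways to pick k ranks summing to w
    dp = np.zeros((n1 + 1, max_w + 1))
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(r, n1), 0, -1):
            dp[k, r:] += dp[k - 1, : max_w + 1 - r]
    return dp[n1]


def wilcoxon_rank_sum(
    a: Sequence[float], b: Sequence[float], m_comparisons: int = 1
) -> TestResult:
    """Two-sided Mann-Whitney / Wilcoxon rank-sum test for independent samples."""
    a = np.asarray(list(a), dtype=float)
    b = np.asarray(list(b), dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    w = float(ranks[:n1].sum())
    u = w - n1 * (n1 + 1) / 2.0
    ties = np.unique(combined).size < combined.size
    if min(n1, n2) <= 8 and not ties:
        counts = _rank_sum_null_counts(n1, n2)
        total = counts.sum()
        wi = int(round(w))
        p_le = counts[: wi + 1].sum() / total
        p_ge = counts[wi:].sum() / total
        p = float(min(1.0, 2.0 * min(p_le, p_ge)))
        method = "wilcoxon-rank-sum-exact"
    else:
        mean = n1 * n2 / 2.0
        N = n1 + n2
        tie_counts = np.unique(combined, return_counts=True)[1]
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (N * (N - 1.0)) if N > 1 else 0.0
        var = n1 * n2 / 12.0 * (N + 1.0 - tie_term)
        if var <= 0:
            p = 1.0
        else:
            cc = 0.5 * np.sign(u - mean)
            z = (u - mean - cc) / np.sqrt(var)
            p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
        method = "wilcoxon-rank-sum-normal"
    return TestResult(u, p, bonferroni([p], m_comparisons)[0], method, (n1, n2))


def friedman(matrix: np.ndarray, m_comparisons: int = 1) -> TestResult:
    """Friedman chi-square test over a patients x conditions table."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] < 2 or m.shape[1] < 2:
        raise ValueError("need >= 2 complete rows and >= 2 conditions")
    if not np.all(np.isfinite(m)):
        raise ValueError("incomplete rows are not supported")
    n, k = m.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, m)  # within-row mid-ranks
    col_sums = ranks.sum(axis=0)
    chi2 = 12.0 / (n * k * (k + 1)) * (col_sums**2).sum() - 3.0 * n * (k + 1)
    # tie correction (as in the standard tie-adjusted Friedman statistic)
    ties = 0.0
    for i in range(n):
        _, counts = np.unique(m[i], return_counts=True)
        ties += float((counts**3 - counts).sum())
    c = 1.0 - ties / (n * (k**3 - k))
    if c <= 0:
        # every row fully tied: no evidence of any difference
        return TestResult(0.0, 1.0, 1.0, "friedman", (n, k))
    chi2 /= c
    p = float(min(1.0, sps.chi2.sf(chi2, k - 1)))
    return TestResult(float(chi2), p, bonferroni([p], m_comparisons)[0], "friedman", (n, k))


def bonferroni(p_values: Sequence[float], m: int) -> list[float]:
    """Bonferroni adjustment: min(1, m * p) for each p."""
    if m < 1:
        raise ValueError("m must be >= 1")
    if m < len(list(p_values)):
        raise ValueError("m must be at least the number of p-values")
    return [float(min(1.0, m * p)) for p in p_values]


DIRECTION_PARAMS = {
    "adc": "mean",
    "t1": "max",
    "t2": "max",
    "ktrans": "mean",
    "kep": "mean",
    "ve": "mean",
    "vp": "mean",
}


def compare_hypoxic_normoxic(
    region_stats: pd.DataFrame,
    params: Optional[dict] = None,
    hsv_mask: str = "hsv_union",
    nsv_mask: str = "nsv_union",
) -> dict:
    """Paired Wilcoxon tests of hypoxic vs normoxic subvolume statistics.

    ``region_stats`` is the long table produced by the cohort simulator
    (columns patient / mask / map / mean / max).  For each parameter the
    configured statistic (mean, or max for T1/T2) is compared between the
    hypoxic and normoxic subvolume across patients with a measurable hypoxic
    volume; p-values are Bonferroni-adjusted for the number of parameters.
    """
    params = params or DIRECTION_PARAMS
    m = len(params)
    out = {}
    for p, stat in params.items():
        sub = region_stats[region_stats["map"] == p]
        h = sub[sub["mask"] == hsv_mask].set_index("patient")[stat]
        n_ = sub[sub["mask"] == nsv_mask].set_index("patient")[stat]
        common = h.dropna().index.intersection(n_.dropna().index)
        out[p] = wilcoxon_signed_rank(h.loc[common], n_.loc[common], m_comparisons=m)
    return out


def direction_outcomes(region_stats: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter adjusted p-value and median hypoxic-minus-normoxic
    difference for one simulated cohort (see :func:`compare_hypoxic_normoxic`)."""
    tests = compare_hypoxic_normoxic(region_stats)
    rows = {}
    for p, stat in DIRECTION_PARAMS.items():
        sub = region_stats[region_stats["map"] == p]
        h = sub[sub["mask"] == "hsv_union"].set_index("patient")[stat]
        n_ = sub[sub["mask"] == "nsv_union"].set_index("patient")[stat]
        common = h.dropna().index.intersection(n_.dropna().index)
        diff = (h.loc[common] - n_.loc[common]).median()
        rows[p] = dict(
            p_value=tests[p].p_value,
            p_adjusted=tests[p].p_adjusted,
            median_diff=float(diff),
            n=len(common),
        )
    return pd.DataFrame(rows).T


def load_table3() -> pd.DataFrame:
    """The packaged per-patient cohort metrics table."""
    with resources.files("hypoxmap.data").joinpath("table3.csv").open() as fh:
        return pd.read_csv(fh)


def records_from_frame(df: pd.DataFrame) -> list[PatientRecord]:
    return [
        PatientRecord(
            patient=str(row["patient"]),
            **{c: float(row[c]) for c in TABLE_COLUMNS},
        )
        for _, row in df.iterrows()
    ]


def cohort_table(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Summary rows (n, mean, sd, median, q1, q3, min, max) for every metric,
    plus the count of hypoxic patients (hsv_union_cm3 > 0) as an attribute.

    Full precision is retained; display rounding is the caller's concern
    (:func:`round_half_away`)."""
    if len(records) == 0:
        raise ValueError("cohort_table requires at least one record")
    data = {c: [getattr(r, c) for r in records] for c in TABLE_COLUMNS}
    rows = {}
    for col, vals in data.items():
        s = summarize(vals)
        rows[col] = dict(
            n=s.n, mean=s.mean, sd=s.sd, median=s.median, q1=s.q1, q3=s.q3,
            min=s.min, max=s.max,
        )
    out = pd.DataFrame(rows).T
    out.attrs["n_hypoxic"] = int(sum(r.hypoxic for r in records))
    return out
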