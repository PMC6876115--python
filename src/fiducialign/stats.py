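"""Rank-based statistics and summary tables for paired RMSE comparisons.

Exact tests are computed by enumeration of the permutation null: the
signed-rank null over sign assignments (via an equivalent integer
dynamic-programming convolution) and the rank-sum null over all group
assignments of the pooled ranks. Ties get average ranks; the normal
approximation applies tie-corrected variance and a continuity correction.
Two-sided p-values double the smaller tail, capped at 1.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .deviation import round_half_up
from .errors import InvalidParameterError, UndefinedTestError

DROP = "drop"  # classic Wilcoxon: discard zero differences
PRATT = "pratt"  # rank zeros, then discard their ranks


@dataclass
class PairedSamples:
    """Labelled paired vectors of per-participant RMSE values [mm]."""

    a: np.ndarray
    b: np.ndarray
    label_a: str = "sphere"
    label_b: str = "cross"
    paired: bool = True

    def __post_init__(self):
        self.a = np.asarray(self.a, dtype=np.float64).ravel()
        self.b = np.asarray(self.b, dtype=np.float64).ravel()
        if self.paired and len(self.a) != len(self.b):
            raise InvalidParameterError("paired samples require equal lengths")
        if np.any(self.a < 0) or np.any(self.b < 0):
            raise InvalidParameterError("RMSE values must be >= 0")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, col_a: str = "rmse_sphere", col_b: str = "rmse_cross"):
        return cls(df[col_a].to_numpy(), df[col_b].to_numpy(), col_a, col_b)


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    variance: float
    min: float
    max: float
    n: int

    def mean_range_str(self, ndigits: int = 2) -> str:
        """Table-style 'mean (min-max)' with half-up rounding."""
        from .deviation import format_mm

        return (
            f"{format_mm(self.mean, ndigits)} "
            f"({format_mm(self.min, ndigits)}–{format_mm(self.max, ndigits)})"
        )


def summarize(values) -> SummaryStats:
    """Exact mean, sample sd (n-1), variance, min, max of a value vector."""
    v = np.asarray(values, dtype=np.float64).ravel()
    if len(v) == 0:
        raise InvalidParameterError("summarize needs at least one value")
    sd = float(np.std(v, ddof=1)) if len(v) > 1 else 0.0
    return SummaryStats(
        mean=float(np.mean(v)),
        sd=sd,
        variance=sd**2,
        min=float(np.min(v)),
        max=float(np.max(v)),
        n=len(v),
    )


def repetition_analysis(rmse_values) -> SummaryStats:
    """Summary of replicate-RMSE vectors (workflow repetition variance)."""
    v = np.asarray(rmse_values, dtype=np.float64).ravel()
    if len(v) < 2:
        raise InvalidParameterError("repetition analysis needs n >= 2 replicates")
    return summarize(v)


# -- signed-rank test ---------------------------------------------------


def _signed_rank_setup(samples: PairedSamples, zero_policy: str):
    d = samples.a - samples.b
    if np.all(d == 0):
        raise UndefinedTestError("all paired differences are zero")
    if zero_policy == DROP:
        nz = d[d != 0]
        ranks = rankdata(np.abs(nz))
        w_plus = float(ranks[nz > 0].sum())
        return ranks, w_plus
    if zero_policy == PRATT:
        ranks_all = rankdata(np.abs(d))
        nz_mask = d != 0
        ranks = ranks_all[nz_mask]
        w_plus = float(ranks_all[(d > 0)].sum())
        return ranks, w_plus
    raise InvalidParameterError(f"unknown zero_policy: {zero_policy!r}")


def _exact_signed_rank_p(ranks: np.ndarray, w_plus: float) -> float:
    """Exact two-sided p over all 2^n sign assignments.

    Implemented as an integer DP convolution on doubled ranks (average
    ranks are half-integers); identical to the full enumeration.
    """
    r2 = np.rint(2.0 * np.asarray(ranks)).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1, dtype=np.float64)
    dist[0] = 1.0
    for r in r2:
        shifted = np.zeros_like(dist)
        shifted[r:] = dist[: total + 1 - r]
        dist = dist + shifted
    dist /= dist.sum()
    w2 = int(np.rint(2.0 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def _normal_signed_rank_p(ranks: np.ndarray, w_plus: float, zero_policy: str) -> float:
    n = len(ranks)
    mean_w = float(np.sum(ranks)) / 2.0
    # variance = sum(r_i^2) / 4 exactly (handles ties and Pratt zeros' removal)
    var_w = float(np.sum(np.asarray(ranks) ** 2)) / 4.0
    if var_w == 0:
        raise UndefinedTestError("zero variance in signed-rank statistic")
    diff = w_plus - mean_w
    cc = min(0.5, abs(diff))  # continuity correction toward the mean
    z = (abs(diff) - cc) / np.sqrt(var_w)
    from scipy.stats import norm

    return float(min(1.0, 2.0 * norm.sf(z)))


def wilcoxon_signed_rank(
    samples: PairedSamples, zero_policy: str = DROP, mode: str = "auto"
) -> tuple[float, float]:
    """Wilcoxon signed-rank test; returns (W_plus, two-sided p).

    W_plus is the sum of ranks of positive differences (average ranks for
    tied |d|). ``mode``: "exact" enumerates the sign-assignment null (the
    enumeration handles ties correctly), "normal_approx" uses the
    tie-corrected normal approximation with continuity correction, "auto"
    picks exact for n <= 20 after zero handling.
    """
    if not samples.paired:
        raise InvalidParameterError("signed-rank test requires paired samples")
    ranks, w_plus = _signed_rank_setup(samples, zero_policy)
    if len(ranks) == 0:
        raise UndefinedTestError("no non-zero differences remain")
    if mode == "auto":
        mode = "exact" if len(ranks) <= 20 else "normal_approx"
    if mode == "exact":
        p = _exact_signed_rank_p(ranks, w_plus)
    elif mode == "normal_approx":
        p = _normal_signed_rank_p(ranks, w_plus, zero_policy)
    else:
        raise InvalidParameterError(f"unknown mode: {mode!r}")
    return w_plus, p


# -- rank-sum (Mann-Whitney) test ---------------------------------------


def mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exact two-sample Mann-Whitney test; returns (U_a, two-sided p).

    U_a is the U statistic of sample ``a`` with average ranks for ties.
    The p-value enumerates all C(n_a + n_b, n_a) assignments of the pooled
    (tied) ranks to group a, so ties are handled by construction. Exact
    enumeration is limited to n_a + n_b <= 20.
    """
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if len(a) == 0 or len(b) == 0:
        raise InvalidParameterError("both samples must be non-empty")
    n_a, n_b = len(a), len(b)
    if n_a + n_b > 20:
        raise InvalidParameterError(
            "exact enumeration limited to n_a + n_b <= 20; no approximation requested"
        )
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    r_a = float(ranks[:n_a].sum())
    u_a = r_a - n_a * (n_a + 1) / 2.0

    idx = np.arange(n_a + n_b)
    u_values = np.empty(0)
    combos = list(itertools.combinations(idx, n_a))
    u_values = np.fromiter(
        (ranks[list(c)].sum() for c in combos), dtype=np.float64, count=len(combos)
    ) - n_a * (n_a + 1) / 2.0
    eps = 1e-9
    lower = np.mean(u_values <= u_a + eps)
    upper = np.mean(u_values >= u_a - eps)
    p = float(min(1.0, 2.0 * min(lower, upper)))
    return u_a, p


# -- packaged table fixtures --------------------------------------------


def load_table(which: int) -> pd.DataFrame:
    """Load the packaged per-participant RMSE fixture (1 or 2)."""
    if which not in (1, 2):
        raise InvalidParameterError("table must be 1 or 2")
    with resources.files("fiducialign.data").joinpath(f"table{which}.csv").open() as fh:
        return pd.read_csv(fh)


def table_summary(which: int) -> dict:
    """Mean (range) rows and the exact tests for a packaged fixture table."""
    df = load_table(which)
    samples = PairedSamples.from_frame(df)
    sphere = summarize(samples.a)
    cross = summarize(samples.b)
    w_plus, p_signed = wilcoxon_signed_rank(samples)
    _, p_ranksum = mann_whitney_exact(samples.a, samples.b)
    return {
        "table": which,
        "sphere": sphere,
        "cross": cross,
        "sphere_mean_range": sphere.mean_range_str(),
        "cross_mean_range": cross.mean_range_str(),
        "w_plus": w_plus,
        "p_signed_rank": p_signed,
        "p_rank_sum": p_ranksum,
    }
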