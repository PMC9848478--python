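"""Effect-size statistics: Wilcoxon r, chi-square goodness-of-fit w (Cohen),
Pearson r, and the classical chi-square count test.

Effect-size levels follow the convention: no practical difference (n) for
r < 0.2, * for 0.2 <= r < 0.3, ** for 0.3 <= r < 0.5, *** for r >= 0.5.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

LEVEL_BINS = ((0.2, "n"), (0.3, "*"), (0.5, "**"))


def effect_level(r: float) -> str:
    for upper, label in LEVEL_BINS:
        if r < upper:
            return label
    return "***"


@dataclass(frozen=True)
class EffectSize:
    statistic: str  # wilcoxon_r | cohen_w | pearson_r
    value: float
    n: int
    level: str

    @classmethod
    def from_r(cls, statistic: str, value: float, n: int) -> "EffectSize":
        return cls(statistic, value, n, effect_level(abs(value)))


def _rank_with_ties(pooled: np.ndarray):
    ranks = stats.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    return ranks, tie_counts


def wilcoxon_effect_size(
    x: Sequence[float],
    y: Sequence[float],
    paired: bool = False,
    continuity_correction: bool = False,
) -> EffectSize:
    """r = |Z| / sqrt(N) from the tie-corrected normal approximation.

    Unpaired mode uses the rank-sum (Mann-Whitney) Z; paired mode the
    signed-rank Z with zero differences dropped. N is the total number of
    observations across both samples. The tie-corrected variance is the exact
    variance of the rank statistic under the null, so without the continuity
    correction Z agrees exactly with exhaustive-enumeration moments at any n;
    the correction is available but off by default.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n_total = len(x) + len(y)
    if paired:
        if len(x) != len(y):
            raise ValueError("paired samples must have equal length")
        z = _signed_rank_z(x, y, continuity_correction)
    else:
        if len(x) == 0 or len(y) == 0:
            raise ValueError("both samples must be non-empty")
        z = _rank_sum_z(x, y, continuity_correction)
    if z is None:
        logger.warning("wilcoxon_effect_size: degenerate all-tied data, r = 0")
        return EffectSize.from_r("wilcoxon_r", 0.0, n_total)
    r = abs(z) / math.sqrt(n_total)
    return EffectSize.from_r("wilcoxon_r", min(r, 1.0), n_total)


def _continuity(diff: float, apply: bool) -> float:
    if not apply or diff == 0:
        return 0.0
    return -0.5 if diff > 0 else 0.5


def _rank_sum_z(x: np.ndarray, y: np.ndarray, continuity: bool) -> Optional[float]:
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks, tie_counts = _rank_with_ties(pooled)
    w = ranks[:n1].sum()
    mean_w = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var_w = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_w <= 0:
        return None
    diff = w - mean_w
    return (diff + _continuity(diff, continuity)) / math.sqrt(var_w)


def _signed_rank_z(x: np.ndarray, y: np.ndarray, continuity: bool) -> Optional[float]:
    d = x - y
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return None
    ranks = stats.rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    mean_w = n * (n + 1) / 4.0
    _, tie_counts = np.unique(np.abs(d), return_counts=True)
    var_w = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts**3 - tie_counts).sum() / 48.0
    if var_w <= 0:
        return None
    diff = w_plus - mean_w
    return (diff + _continuity(diff, continuity)) / math.sqrt(var_w)


def chisq_gof_effect_size(
    observed: Sequence[float], expected: Sequence[float]
) -> EffectSize:
    """Cohen's w = sqrt(chi2 / N) for an observed-vs-expected count table."""
    observed = np.asarray(observed, dtype=float)
    expected = np.asarray(expected, dtype=float)
    if observed.shape != expected.shape:
        raise ValueError("observed and expected must have equal length")
    if np.any(expected <= 0):
        raise ValueError("expected counts must all be positive")
    if not math.isclose(observed.sum(), expected.sum(), rel_tol=1e-6, abs_tol=0.5):
        raise ValueError("observed and expected totals differ beyond rounding")
    chi2 = float(((observed - expected) ** 2 / expected).sum())
    n = float(observed.sum())
    w = math.sqrt(chi2 / n)
    return EffectSize.from_r("cohen_w", w, int(round(n)))


def chisq_count_test(observed: Sequence[float], expected_proportions: Sequence[float]):
    """Classical chi-square goodness-of-fit test; returns (statistic, p)."""
    observed = np.asarray(observed, dtype=float)
    props = np.asarray(expected_proportions, dtype=float)
    if len(observed) != len(props):
        raise ValueError("observed and proportions must have equal length")
    if len(observed) < 2:
        raise ValueError("need >= 2 categories (0 degrees of freedom otherwise)")
    if not math.isclose(props.sum(), 1.0, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError("expected proportions must sum to 1")
    expected = observed.sum() * props
    if np.any(expected < 1):
        logger.warning("chisq_count_test: expected count < 1 in some cell")
    statistic, p = stats.chisquare(observed, expected)
    return float(statistic), float(p)


def pearson(x: Sequence[float], y: Sequence[float]) -> EffectSize:
    """Product-moment correlation as an EffectSize (level on |r|)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 3:
        raise ValueError("need n >= 3 for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for constant input")
    r = float(np.corrcoef(x, y)[0, 1])
    return EffectSize.from_r("pearson_r", r, len(x))
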