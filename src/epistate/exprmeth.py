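"""Expression quantification scale, category thresholds, the threshold DE
rule, and region-level CpG methylation averaging."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

MIN_CPG_COVERAGE = 5  # strictly more than 5x required


@dataclass(frozen=True)
class CategoryThresholds:
    """Boundaries on the log2(RPKM+1) scale separating not/lowly/expressed."""

    kind: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("low threshold must be below high threshold")

    @classmethod
    def te(cls) -> "CategoryThresholds":
        return cls("te", 0.4, 1.4)

    @classmethod
    def gene(cls) -> "CategoryThresholds":
        return cls("gene", 1.5, 5.0)


@dataclass
class DiffCall:
    region_id: str
    delta: float  # B - A on the log2(RPKM+1) scale
    higher_value: float
    de: bool
    direction: str  # up / down / none


@dataclass
class RegionMeth:
    region_id: str
    mean: Optional[float]
    n_cpgs_used: int

    @property
    def defined(self) -> bool:
        return self.n_cpgs_used >= 1


def rpkm_log_transform(count: float, t_pc: float, length_bp: float) -> float:
    """log2(RPKM + 1) where the per-million total is protein-coding-mapped
    reads and the per-kilobase length is the region length."""
    if count < 0:
        raise ValueError("count must be non-negative")
    if t_pc <= 0 or length_bp <= 0:
        raise ValueError("t_pc and length must be positive")
    rpkm = count / (t_pc / 1e6) / (length_bp / 1000.0)
    return float(np.log2(rpkm + 1.0))


def categorize_expression(value: float, thresholds: CategoryThresholds) -> str:
    """<=low: not_expressed; >low and <=high: lowly_expressed; >high: expressed."""
    if value <= thresholds.low:
        return "not_expressed"
    if value <= thresholds.high:
        return "lowly_expressed"
    return "expressed"


def call_de(
    value_a: float,
    value_b: float,
    thresholds: CategoryThresholds,
    region_id: str = "",
    external_significant: Optional[bool] = None,
) -> DiffCall:
    """Threshold DE rule: |delta| >= 2 (>= 4-fold) and the higher of the two
    values above the low-expression floor.

    ``external_significant``, when provided (e.g. from an external
    dispersion-model test), is AND-combined with the threshold rule.
    """
    delta = value_b - value_a
    higher = max(value_a, value_b)
    de = abs(delta) >= 2.0 and higher > thresholds.low
    if external_significant is not None:
        de = de and external_significant
    direction = "none" if not de else ("up" if delta > 0 else "down")
    return DiffCall(region_id=region_id, delta=delta, higher_value=higher, de=de, direction=direction)


def region_methylation(
    cpgs: Sequence[Tuple[int, int]], region_id: str = ""
) -> RegionMeth:
    """Unweighted mean of per-CpG methylation fractions over CpGs covered
    more than 5x; undefined when no CpG qualifies."""
    fractions = []
    for meth, total in cpgs:
        if not (0 <= meth <= total):
            raise ValueError("require 0 <= meth_reads <= total_reads")
        if total > MIN_CPG_COVERAGE:
            fractions.append(meth / total)
    if not fractions:
        return RegionMeth(region_id=region_id, mean=None, n_cpgs_used=0)
    return RegionMeth(
        region_id=region_id,
        mean=float(np.mean(fractions)),
        n_cpgs_used=len(fractions),
    )


def region_methylation_table(cpg_table: pd.DataFrame) -> list:
    """Vector version over a bedGraph-like CpG frame with columns
    region_id, meth_reads, total_reads."""
    out = []
    for region_id, group in cpg_table.groupby("region_id", sort=True):
        pairs = list(zip(group["meth_reads"].astype(int), group["total_reads"].astype(int)))
        out.append(region_methylation(pairs, region_id=str(region_id)))
    return out


def de_calls_to_frame(calls: Sequence[DiffCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [c.region_id for c in calls],
            "delta": [c.delta for c in calls],
            "higher_value": [c.higher_value for c in calls],
            "de": [int(c.de) for c in calls],
            "direction": [c.direction for c in calls],
        }
    )
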