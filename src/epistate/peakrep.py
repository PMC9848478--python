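"""Pseudoreplicates, a minimal Poisson window peak caller, and the
replicated-peak retention and FDR rules.

The minimal caller exists so synthetic pipelines are self-contained; it is a
simple one-sided Poisson test per window with Benjamini-Hochberg q-values,
not a re-implementation of any external caller.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING, Optional, Sequence

import numpy as np
from scipy import stats

if TYPE_CHECKING:  # pragma: no cover
    from .spikenorm import WindowProfile

logger = logging.getLogger(__name__)

Q_THRESHOLDS = {"histone": 1e-3, "atac": 1e-4}


@dataclass
class PeakCall:
    chrom: str
    start: int
    end: int
    name: str = "."
    score: float = 0.0
    p: Optional[float] = None
    q: Optional[float] = None
    summit: Optional[int] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.name}: start must be < end")
        for label, v in (("p", self.p), ("q", self.q)):
            if v is not None and not (0.0 < v <= 1.0):
                raise ValueError(f"peak {self.name}: {label} outside (0, 1]")

    def overlaps(self, other: "PeakCall") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class ReplicatedPeakSet:
    pooled: list
    overlaps_rep1: list
    overlaps_rep2: list
    overlaps_psr1: list
    overlaps_psr2: list

    @property
    def retained_flags(self) -> list:
        return [
            (r1 and r2) or (p1 and p2)
            for r1, r2, p1, p2 in zip(
                self.overlaps_rep1, self.overlaps_rep2,
                self.overlaps_psr1, self.overlaps_psr2,
            )
        ]

    @property
    def retained(self) -> list:
        return [pk for pk, keep in zip(self.pooled, self.retained_flags) if keep]


def split_pseudoreplicates(fragments: Sequence, seed: int):
    """Randomly partition fragments into two halves of sizes n//2 and n - n//2.

    The split is without replacement: the halves are disjoint and their union
    is the input. Deterministic for a fixed seed.
    """
    n = len(fragments)
    if n < 2:
        raise ValueError("need at least 2 fragments to pseudoreplicate")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    half = n // 2
    first = [fragments[i] for i in sorted(order[:half])]
    second = [fragments[i] for i in sorted(order[half:])]
    return first, second


def call_broad_peaks_minimal(
    profile: "WindowProfile",
    background_rate: float,
    p_threshold: float = 0.05,
    merge_gap: int = 0,
) -> list:
    """Call enriched windows against a flat Poisson background and merge.

    A window with count c is significant when P(Poisson(background_rate) >= c)
    < p_threshold. Adjacent/nearby significant windows (gap <= merge_gap bp)
    merge into one peak whose p is the minimum window p; q is the BH-adjusted
    q of that window over all tested windows.
    """
    if background_rate <= 0:
        raise ValueError("background_rate must be positive")
    if p_threshold <= 0:
        raise ValueError("p_threshold must be positive")

    # one-sided upper tail, inclusive of the observed count
    all_p = []
    window_records = []  # (chrom, start, end, count, p-index)
    for chrom in profile.starts:
        starts, ends = profile.window_bounds(chrom)
        counts = profile.values[chrom]
        pvals = stats.poisson.sf(np.ceil(counts) - 1, background_rate)
        for s, e, c, p in zip(starts, ends, counts, pvals):
            window_records.append((chrom, int(s), int(e), float(c), len(all_p)))
            all_p.append(float(p))
    if not window_records:
        return []

    qvals = _benjamini_hochberg(np.asarray(all_p))

    peaks = []
    counter = 0
    for chrom in profile.starts:
        chrom_windows = [w for w in window_records if w[0] == chrom]
        current = None  # [start, end, min_p, min_q, max_count]
        for _, s, e, c, idx in chrom_windows:
            p, q = all_p[idx], float(qvals[idx])
            if p >= p_threshold:
                continue
            if current is not None and s - current[1] <= merge_gap:
                current[1] = max(current[1], e)
                current[2] = min(current[2], p)
                current[3] = min(current[3], q)
                current[4] = max(current[4], c)
            else:
                if current is not None:
                    counter += 1
                    peaks.append(_make_peak(chrom, current, counter))
                current = [s, e, p, q, c]
        if current is not None:
            counter += 1
            peaks.append(_make_peak(chrom, current, counter))
    return peaks


def _make_peak(chrom: str, rec, counter: int) -> PeakCall:
    start, end, p, q, count = rec
    return PeakCall(
        chrom=chrom,
        start=start,
        end=end,
        name=f"peak_{counter}",
        score=count,
        p=max(p, np.nextafter(0, 1)),
        q=max(min(q, 1.0), np.nextafter(0, 1)),
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = len(p)
    order = np.argsort(p)
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(ranked, 1.0)
    return q


def _overlaps_any(peak: PeakCall, others: Sequence[PeakCall]) -> bool:
    return any(peak.overlaps(o) for o in others)


def retain_reproducible(
    pooled: Sequence[PeakCall],
    rep1: Sequence[PeakCall],
    rep2: Sequence[PeakCall],
    psr1: Sequence[PeakCall],
    psr2: Sequence[PeakCall],
) -> ReplicatedPeakSet:
    """Keep pooled peaks overlapping both replicates or both pseudoreplicates.

    Overlap means >= 1 bp of intersection. Only pooled peaks ever appear in
    the output; replicate peaks act purely as evidence.
    """
    by_chrom = {}
    for label, peak_list in (("r1", rep1), ("r2", rep2), ("p1", psr1), ("p2", psr2)):
        for pk in peak_list:
            by_chrom.setdefault((label, pk.chrom), []).append(pk)

    flags = {"r1": [], "r2": [], "p1": [], "p2": []}
    for pk in pooled:
        for label in flags:
            flags[label].append(_overlaps_any(pk, by_chrom.get((label, pk.chrom), ())))
    return ReplicatedPeakSet(
        pooled=list(pooled),
        overlaps_rep1=flags["r1"],
        overlaps_rep2=flags["r2"],
        overlaps_psr1=flags["p1"],
        overlaps_psr2=flags["p2"],
    )


def filter_q(peaks: Sequence[PeakCall], assay: str) -> list:
    """FDR filter: q < 1e-3 for histone marks, q < 1e-4 for ATAC."""
    if assay not in Q_THRESHOLDS:
        raise ValueError(f"assay must be one of {sorted(Q_THRESHOLDS)}")
    threshold = Q_THRESHOLDS[assay]
    kept, dropped_undefined = [], 0
    for pk in peaks:
        if pk.q is None:
            dropped_undefined += 1
            continue
        if pk.q < threshold:
            kept.append(pk)
    if dropped_undefined:
        logger.warning("filter_q: dropped %d peaks with undefined q", dropped_undefined)
    return kept
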