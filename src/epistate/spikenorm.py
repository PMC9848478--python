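"""Spike-in normalization factors, normalized region signal, window profiles.

The normalized count for region r in IP sample s is

    NC[r, s] = f_s * (ip[r, s] + eps) / (input_hat[r, s] + eps) / (L_r / 1000)

where f_s is the spike-in factor (geometric-mean reference over the antibody
group), input_hat is the paired input count depth-scaled to the IP sample's
mapped-read total, and L_r the region length in bp. eps defaults to 0.5 on
both numerator and denominator so all-zero rows stay finite.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .regionio import Region

logger = logging.getLogger(__name__)


@dataclass
class SampleRecord:
    sample_id: str
    antibody: str
    cell_type: str
    sex: str = "F"
    week: int = 0
    role: str = "IP"  # IP or input
    replicate: int = 1
    target_mapped_reads: int = 0
    spike_mapped_reads: int = 0

    def __post_init__(self) -> None:
        if self.role not in ("IP", "input"):
            raise ValueError(f"sample {self.sample_id}: role must be IP or input")
        if self.target_mapped_reads <= 0:
            raise ValueError(f"sample {self.sample_id}: target_mapped_reads must be > 0")
        if self.spike_mapped_reads < 0:
            raise ValueError(f"sample {self.sample_id}: negative spike_mapped_reads")


@dataclass(frozen=True)
class NormalizationFactor:
    sample_id: str
    antibody_group: str
    factor: float

    def __post_init__(self) -> None:
        if not self.factor > 0:
            raise ValueError("normalization factor must be positive")


@dataclass
class SignalMatrix:
    """Regions x IP-samples matrix of normalized counts."""

    regions: list
    samples: list  # SampleRecord list (IP only)
    values: pd.DataFrame  # index = region ids, columns = sample ids
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        arr = self.values.to_numpy()
        if not np.all(np.isfinite(arr)) or np.any(arr < 0):
            raise ValueError("signal values must be finite and non-negative")
        if self.values.shape != (len(self.regions), len(self.samples)):
            raise ValueError("values shape does not match regions x samples")

    def replicate_mean(self) -> pd.Series:
        """Mean NC across the held samples, per region."""
        return self.values.mean(axis=1)


def spike_factors(
    samples: Sequence[SampleRecord], antibody: str
) -> list:
    """Per-sample spike factors for one antibody group.

    f_s = G / spike_reads_s with G the geometric mean of the group's spike
    totals, so the factors themselves have geometric mean exactly 1.
    """
    group = [s for s in samples if s.antibody == antibody and s.role == "IP"]
    if not group:
        raise ValueError(f"no IP samples for antibody {antibody!r}")
    for s in group:
        if s.spike_mapped_reads <= 0:
            raise ValueError(
                f"sample {s.sample_id}: zero spike-in reads, factor undefined"
            )
    spike = np.array([s.spike_mapped_reads for s in group], dtype=float)
    gmean = float(np.exp(np.mean(np.log(spike))))
    return [
        NormalizationFactor(s.sample_id, antibody, gmean / s.spike_mapped_reads)
        for s in group
    ]


def pair_inputs(
    ip_samples: Sequence[SampleRecord], input_samples: Sequence[SampleRecord]
) -> dict:
    """Map each IP sample id to its input sample (same cell type)."""
    by_cell: dict = {}
    for s in input_samples:
        if s.role == "input":
            by_cell.setdefault(s.cell_type, s)
    pairing = {}
    for s in ip_samples:
        if s.cell_type not in by_cell:
            raise ValueError(f"IP sample {s.sample_id}: no input sample for cell type {s.cell_type}")
        pairing[s.sample_id] = by_cell[s.cell_type]
    return pairing


def normalize_signal(
    ip_counts: pd.DataFrame,
    input_counts: pd.DataFrame,
    factors: Iterable[NormalizationFactor],
    regions: Sequence[Region],
    ip_samples: Sequence[SampleRecord],
    input_samples: Sequence[SampleRecord],
    epsilon: float = 0.5,
) -> SignalMatrix:
    """Spike-, input- and length-normalize IP counts into a SignalMatrix.

    ``ip_counts`` columns are IP sample ids, ``input_counts`` columns input
    sample ids; rows are region ids in ``regions`` order.
    """
    if epsilon < 0:
        raise ValueError("epsilon must be non-negative")
    factor_by_id = {f.sample_id: f.factor for f in factors}
    pairing = pair_inputs(ip_samples, input_samples)
    ip_by_id = {s.sample_id: s for s in ip_samples}
    region_ids = [r.id for r in regions]
    lengths_kb = np.array([r.length for r in regions], dtype=float) / 1000.0

    columns = {}
    for sample_id in ip_counts.columns:
        if sample_id not in factor_by_id:
            raise ValueError(f"no spike factor for IP sample {sample_id}")
        ip = ip_counts.loc[region_ids, sample_id].to_numpy(dtype=float)
        inp_sample = pairing[sample_id]
        inp = input_counts.loc[region_ids, inp_sample.sample_id].to_numpy(dtype=float)
        depth_scale = ip_by_id[sample_id].target_mapped_reads / inp_sample.target_mapped_reads
        input_hat = inp * depth_scale
        nc = factor_by_id[sample_id] * (ip + epsilon) / (input_hat + epsilon) / lengths_kb
        columns[sample_id] = nc

    values = pd.DataFrame(columns, index=region_ids)
    return SignalMatrix(
        regions=list(regions),
        samples=[ip_by_id[c] for c in values.columns],
        values=values,
        pseudocount=epsilon,
    )


@dataclass
class WindowProfile:
    """Fixed-width sliding-window signal per chromosome.

    ``values[chrom]`` aligns with ``starts[chrom]``; window i covers
    [starts[i], starts[i] + window_size) clipped at the chromosome end.
    """

    window_size: int
    step: int
    chrom_lengths: dict
    starts: dict = field(default_factory=dict)
    values: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.step > self.window_size:
            raise ValueError("step > window_size would leave unscanned gaps")

    def window_bounds(self, chrom: str):
        starts = self.starts[chrom]
        ends = np.minimum(starts + self.window_size, self.chrom_lengths[chrom])
        return starts, ends


def window_profile(
    fragments: dict,
    chrom_lengths: dict,
    window_size: int = 50,
    step: int = 25,
    factor: float = 1.0,
) -> WindowProfile:
    """Count fragments overlapping each sliding window, scaled by ``factor``.

    ``fragments`` maps chrom -> iterable of (start, end) half-open intervals.
    Defaults give the 50-nt / 25-nt-offset profile; pass window_size == step
    for non-overlapping genome bins (5 kb ChIP / 1 kb ATAC comparisons).
    """
    if window_size <= 0 or step <= 0:
        raise ValueError("window_size and step must be positive")
    profile = WindowProfile(window_size=window_size, step=step, chrom_lengths=dict(chrom_lengths))
    for chrom, length in chrom_lengths.items():
        starts = np.arange(0, max(length - 1, 1), step, dtype=np.int64)
        counts = np.zeros(len(starts), dtype=float)
        for frag_start, frag_end in fragments.get(chrom, ()):
            if frag_end <= frag_start:
                continue
            # window w overlaps iff w*step < frag_end and w*step+window > frag_start
            first = max(0, int(np.ceil((frag_start - window_size + 1) / step)))
            last = min(len(starts) - 1, (frag_end - 1) // step)
            if first <= last:
                counts[first : last + 1] += 1.0
        profile.starts[chrom] = starts
        profile.values[chrom] = counts * factor
    return profile


def write_bedgraph(profile: WindowProfile, path) -> None:
    with open(path, "w", encoding="utf-8") as handle:
        for chrom in sorted(profile.starts):
            starts, ends = profile.window_bounds(chrom)
            for s, e, v in zip(starts, ends, profile.values[chrom]):
                handle.write(f"{chrom}\t{s}\t{e}\t{v:.6g}\n")


SAMPLE_SHEET_COLUMNS = (
    "sample_id",
    "antibody",
    "cell_type",
    "sex",
    "week",
    "role",
    "replicate",
    "target_mapped_reads",
    "spike_mapped_reads",
)


def read_sample_sheet(path) -> list:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in SAMPLE_SHEET_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: sample sheet missing columns {missing}")
    records = []
    for _, row in frame.iterrows():
        records.append(
            SampleRecord(
                sample_id=row["sample_id"],
                antibody=row["antibody"],
                cell_type=row["cell_type"],
                sex=row["sex"],
                week=int(row["week"]),
                role=row["role"],
                replicate=int(row["replicate"]),
                target_mapped_reads=int(row["target_mapped_reads"]),
                spike_mapped_reads=int(row["spike_mapped_reads"]),
            )
        )
    return records


def write_sample_sheet(samples: Sequence[SampleRecord], path) -> None:
    rows = [
        {c: getattr(s, c) for c in SAMPLE_SHEET_COLUMNS}
        for s in samples
    ]
    pd.DataFrame(rows, columns=list(SAMPLE_SHEET_COLUMNS)).to_csv(path, sep="\t", index=False)
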