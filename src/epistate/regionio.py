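"""Genomic region model and interval/table readers and writers.

All coordinates are 0-based half-open throughout the package. BED input is
native; anything 1-based must be converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

logger = logging.getLogger(__name__)

STRANDS = ("+", "-", ".")


@dataclass
class Region:
    """A genomic interval with identity and metadata.

    ``start``/``end`` are 0-based half-open; ``kind`` distinguishes promoter
    windows from transposable-element copies; ``attrs`` carries free-form
    string metadata (``gene_id``, ``te_family``, ``te_class``,
    ``te_subfamily``, ``tss`` ...).
    """

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "."
    kind: str = "te"
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"unknown strand symbol {self.strand!r}")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"region {self.id}: require 0 <= start < end, got "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        """Interval width in bp (half-open, so simply end - start)."""
        return self.end - self.start

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0

    def overlaps(self, other: "Region") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class PromoterWindowSpec:
    """Promoter window extent around a TSS, in bp."""

    upstream: int = 2000
    downstream: int = 500

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("window extents must be non-negative")
        if self.upstream + self.downstream <= 0:
            raise ValueError("window must have positive total width")

    @property
    def width(self) -> int:
        return self.upstream + self.downstream


@dataclass
class GenomeAnnotation:
    """Chromosome sizes plus the promoter and TE region sets."""

    chromosomes: dict
    promoters: list
    tes: list

    def __post_init__(self) -> None:
        seen: set = set()
        for region in self.all_regions():
            if region.chrom not in self.chromosomes:
                raise ValueError(f"region {region.id} on undeclared chromosome {region.chrom}")
            if region.end > self.chromosomes[region.chrom]:
                raise ValueError(f"region {region.id} extends past end of {region.chrom}")
            if region.id in seen:
                raise ValueError(f"duplicate region id {region.id}")
            seen.add(region.id)

    def all_regions(self) -> Iterable[Region]:
        yield from self.promoters
        yield from self.tes


def promoter_from_tss(
    tss_chrom: str,
    tss_pos: int,
    strand: str,
    spec: PromoterWindowSpec = PromoterWindowSpec(),
    chrom_length: Optional[int] = None,
    region_id: Optional[str] = None,
    attrs: Optional[dict] = None,
) -> Region:
    """Build a strand-oriented promoter window around a TSS.

    On ``+`` the window is [tss - upstream, tss + downstream); on ``-`` it is
    mirrored to [tss - downstream, tss + upstream). Clipped at 0 and, when
    ``chrom_length`` is given, at the chromosome end.
    """
    if strand not in ("+", "-"):
        raise ValueError(f"unknown strand symbol {strand!r}")
    if tss_pos < 0:
        raise ValueError("tss_pos must be non-negative")
    if strand == "+":
        start, end = tss_pos - spec.upstream, tss_pos + spec.downstream
    else:
        start, end = tss_pos - spec.downstream, tss_pos + spec.upstream
    start = max(start, 0)
    if chrom_length is not None:
        end = min(end, chrom_length)
    all_attrs = {"tss": str(tss_pos)}
    if attrs:
        all_attrs.update(attrs)
    return Region(
        id=region_id or f"{tss_chrom}:{tss_pos}:{strand}",
        chrom=tss_chrom,
        start=start,
        end=end,
        strand=strand,
        kind="promoter",
        attrs=all_attrs,
    )


# ---------------------------------------------------------------------------
# readers / writers

_REGION_TABLE_COLUMNS = ("id", "chrom", "start", "end", "strand", "kind")


def read_regions(path, format: str = "bed", kind: str = "te") -> list:
    """Read regions from BED3+ / BED6+ or a headered region table (TSV).

    Zero-width or inverted records are rejected with a logged diagnostic;
    structurally malformed lines raise, naming the line number.
    """
    if format == "bed":
        return _read_bed(path, kind)
    if format == "region-table":
        return _read_region_table(path)
    raise ValueError(f"unknown region format {format!r}")


def _read_bed(path, kind: str) -> list:
    regions = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}: line {lineno}: expected >=3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer coordinate") from exc
            if start >= end or start < 0:
                logger.warning("%s: line %d: rejected interval [%d, %d)", path, lineno, start, end)
                continue
            name = fields[3] if len(fields) > 3 and fields[3] != "." else f"region_{lineno}"
            strand = fields[5] if len(fields) > 5 and fields[5] in STRANDS else "."
            attrs = {}
            # extra columns beyond BED6 become key=value attrs when tagged,
            # positional attr_N otherwise
            for i, extra in enumerate(fields[6:]):
                if "=" in extra:
                    key, _, value = extra.partition("=")
                    attrs[key] = value
                else:
                    attrs[f"attr_{i}"] = extra
            regions.append(Region(name, chrom, start, end, strand, kind, attrs))
    return regions


def _read_region_table(path) -> list:
    import csv

    regions = []
    with open(path, encoding="utf-8", newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            return regions
        missing = [c for c in _REGION_TABLE_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise ValueError(f"{path}: region table missing columns {missing}")
        for lineno, row in enumerate(reader, start=2):
            start, end = int(row["start"]), int(row["end"])
            if start >= end or start < 0:
                logger.warning("%s: line %d: rejected interval [%d, %d)", path, lineno, start, end)
                continue
            attrs = {
                k: v
                for k, v in row.items()
                if k not in _REGION_TABLE_COLUMNS and v not in (None, "")
            }
            regions.append(
                Region(row["id"], row["chrom"], start, end, row["strand"], row["kind"], attrs)
            )
    return regions


def write_regions(regions: Iterable[Region], path, format: str = "region-table") -> None:
    """Write regions as a headered TSV table or as BED6+ (attrs as key=value)."""
    with open(path, "w", encoding="utf-8") as handle:
        if format == "region-table":
            keys = sorted({k for r in regions for k in r.attrs})
            handle.write("\t".join(_REGION_TABLE_COLUMNS + tuple(keys)) + "\n")
            for r in regions:
                row = [r.id, r.chrom, str(r.start), str(r.end), r.strand, r.kind]
                row += [r.attrs.get(k, "") for k in keys]
                handle.write("\t".join(row) + "\n")
        elif format == "bed":
            for r in regions:
                row = [r.chrom, str(r.start), str(r.end), r.id, "0", r.strand]
                row += [f"{k}={v}" for k, v in sorted(r.attrs.items())]
                handle.write("\t".join(row) + "\n")
        else:
            raise ValueError(f"unknown region format {format!r}")


def read_peaks(path, format: str = "broadPeak") -> list:
    """Read ENCODE broadPeak (9 col) / narrowPeak (10 col) files.

    The -log10 p/q columns are mapped back to linear probabilities; the
    ENCODE missing-value sentinel -1 maps to None (undefined).
    """
    from .peakrep import PeakCall

    expected = {"broadPeak": 9, "narrowPeak": 10}.get(format)
    if expected is None:
        raise ValueError(f"unknown peak format {format!r}")
    peaks = []
    with open(path, encoding="utf-8") as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != expected:
                raise ValueError(
                    f"{path}: line {lineno}: expected {expected} {format} columns, "
                    f"got {len(fields)}"
                )
            log_p, log_q = float(fields[7]), float(fields[8])
            peaks.append(
                PeakCall(
                    chrom=fields[0],
                    start=int(fields[1]),
                    end=int(fields[2]),
                    name=fields[3],
                    score=float(fields[4]),
                    p=None if log_p == -1 else 10.0 ** (-log_p),
                    q=None if log_q == -1 else 10.0 ** (-log_q),
                    summit=int(fields[9]) if format == "narrowPeak" else None,
                )
            )
    return peaks


def write_peaks(peaks, path, format: str = "broadPeak") -> None:
    import math

    def neglog10(v):
        return -1.0 if v is None else (-math.log10(v) if v > 0 else 999.0)

    with open(path, "w", encoding="utf-8") as handle:
        for peak in peaks:
            row = [
                peak.chrom,
                str(peak.start),
                str(peak.end),
                peak.name,
                str(int(round(peak.score))),
                ".",
                "0.0",
                f"{neglog10(peak.p):.6g}",
                f"{neglog10(peak.q):.6g}",
            ]
            if format == "narrowPeak":
                row.append(str(-1 if peak.summit is None else peak.summit))
            handle.write("\t".join(row) + "\n")
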