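"""TE-to-promoter assignment by nearest TSS, distance-resolved correlation of
TE and gene differential expression, and regulatory-TE classification."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .chromstate import StateVector
from .effstats import pearson
from .regionio import PromoterWindowSpec, Region

MAX_LINK_DISTANCE = 100_000


@dataclass
class TEGeneLink:
    te_id: str
    gene_id: str
    distance: int  # signed bp, negative = upstream of TSS in gene orientation

    @property
    def within_window(self) -> bool:
        return abs(self.distance) < MAX_LINK_DISTANCE

    @property
    def upstream(self) -> bool:
        return self.distance < 0


@dataclass
class RegulatoryTECall:
    te_id: str
    upstream: bool
    has_active_mark_or_atac: bool

    @property
    def putative_regulatory(self) -> bool:
        return self.upstream and self.has_active_mark_or_atac


def promoter_tss(promoter: Region, spec: PromoterWindowSpec = PromoterWindowSpec()) -> int:
    """TSS position of a promoter region: the stored ``tss`` attr when
    present, otherwise derived from the window geometry and strand."""
    if "tss" in promoter.attrs:
        return int(promoter.attrs["tss"])
    if promoter.strand == "+":
        return promoter.start + spec.upstream
    if promoter.strand == "-":
        return promoter.end - spec.upstream
    raise ValueError(f"promoter {promoter.id} without tss attr needs a gene strand")


def _gene_id(promoter: Region) -> str:
    return promoter.attrs.get("gene_id", promoter.id)


def signed_distance(te: Region, promoter: Region, tss: int) -> float:
    """TE midpoint to TSS, negative when the TE lies 5' of the TSS in gene
    orientation."""
    raw = te.midpoint - tss
    return raw if promoter.strand != "-" else -raw


def assign_nearest_promoter(
    tes: Sequence[Region],
    promoters: Sequence[Region],
    max_dist: int = MAX_LINK_DISTANCE,
    spec: PromoterWindowSpec = PromoterWindowSpec(),
) -> list:
    """Link each TE to its nearest same-chromosome TSS strictly closer than
    ``max_dist``; TEs with no TSS in range are omitted. Ties break to the
    lexicographically smallest gene id."""
    by_chrom: Dict[str, list] = {}
    for p in promoters:
        by_chrom.setdefault(p.chrom, []).append((promoter_tss(p, spec), p))
    links = []
    for te in tes:
        best = None  # (abs_dist, gene_id, signed_dist)
        for tss, prom in by_chrom.get(te.chrom, ()):
            d = signed_distance(te, prom, tss)
            key = (abs(d), _gene_id(prom))
            if best is None or key < (best[0], best[1]):
                best = (abs(d), _gene_id(prom), d)
        if best is not None and best[0] < max_dist:
            links.append(TEGeneLink(te_id=te.id, gene_id=best[1], distance=int(round(best[2]))))
    return links


def link_correlation(
    links: Sequence[TEGeneLink],
    te_delta: Mapping[str, float],
    gene_delta: Mapping[str, float],
):
    """Pearson correlation between linked TE and gene deltas.

    Returns (r, n); r is None when fewer than 3 links carry both deltas.
    """
    xs, ys = [], []
    for link in links:
        if link.te_id in te_delta and link.gene_id in gene_delta:
            xs.append(te_delta[link.te_id])
            ys.append(gene_delta[link.gene_id])
    n = len(xs)
    if n < 3:
        return None, n
    return pearson(xs, ys).value, n


@dataclass
class DistanceCorrelationProfile:
    bin_edges: np.ndarray  # signed bp, len = n_bins + 1
    correlations: list  # per-bin r or None
    counts: list  # per-bin n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "r": [np.nan if r is None else r for r in self.correlations],
                "n": self.counts,
            }
        )


def distance_binned_correlation(
    links: Sequence[TEGeneLink],
    te_delta: Mapping[str, float],
    gene_delta: Mapping[str, float],
    bin_width: int = 10_000,
) -> DistanceCorrelationProfile:
    """Per-distance-bin link correlation over [-100 kb, +100 kb)."""
    span = 2 * MAX_LINK_DISTANCE
    if span % bin_width != 0:
        raise ValueError("bin_width must divide 200 kb")
    edges = np.arange(-MAX_LINK_DISTANCE, MAX_LINK_DISTANCE + 1, bin_width)
    binned: Dict[int, list] = {i: [] for i in range(len(edges) - 1)}
    for link in links:
        if not link.within_window:
            continue
        idx = int((link.distance + MAX_LINK_DISTANCE) // bin_width)
        idx = min(idx, len(edges) - 2)
        binned[idx].append(link)
    correlations, counts = [], []
    for i in range(len(edges) - 1):
        r, n = link_correlation(binned[i], te_delta, gene_delta)
        correlations.append(r)
        counts.append(n)
    return DistanceCorrelationProfile(bin_edges=edges, correlations=correlations, counts=counts)


def classify_regulatory_te(
    links: Sequence[TEGeneLink],
    de_up_in_target: Mapping[str, bool],
    states: Sequence[StateVector],
    atac: Optional[Mapping[str, bool]] = None,
) -> list:
    """Flag upregulated linked TEs that sit upstream of their gene's TSS and
    carry an active mark or ATAC signal as putatively regulatory."""
    state_by_id = {s.region_id: s for s in states}
    atac = atac or {}
    calls = []
    for link in links:
        if not de_up_in_target.get(link.te_id, False):
            continue
        if link.te_id not in state_by_id:
            raise ValueError(f"no state vector for linked TE {link.te_id}")
        state = state_by_id[link.te_id]
        active = bool(state.active) or bool(atac.get(link.te_id, False))
        calls.append(
            RegulatoryTECall(
                te_id=link.te_id,
                upstream=link.upstream,
                has_active_mark_or_atac=active,
            )
        )
    return calls


def links_to_frame(links: Sequence[TEGeneLink]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "te_id": [l.te_id for l in links],
            "gene_id": [l.gene_id for l in links],
            "distance": [l.distance for l in links],
            "within_window": [int(l.within_window) for l in links],
        }
    )
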