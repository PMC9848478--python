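"""Binary occupancy calls, combinatorial state assignment, cell-type
specificity, signature transition tables, and TE-family enrichment."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .effstats import chisq_gof_effect_size
from .peakrep import PeakCall
from .regionio import Region

MARKS = ("5mC", "H3K9me3", "H3K27me3", "H2aK119ub", "H3K4me3", "H3K4me1", "H3K27ac", "ATAC")
REPRESSIVE_MARKS = ("5mC", "H3K9me3", "H3K27me3", "H2aK119ub")
ACTIVE_MARKS = ("H3K4me3", "H3K27ac")

NO_SIGNATURE = "none"


def signature_label(marks: Iterable[str]) -> str:
    mark_set = set(marks)
    ordered = [m for m in MARKS if m in mark_set]
    return "+".join(ordered) if ordered else NO_SIGNATURE


@dataclass
class StateVector:
    region_id: str
    repressive: frozenset
    active: frozenset
    h3k4me1: bool
    category: str

    @property
    def repressive_signature(self) -> str:
        return signature_label(self.repressive)


def _region_overlaps_peaks(region: Region, peaks: Sequence[PeakCall]) -> bool:
    return any(
        region.chrom == pk.chrom and region.start < pk.end and pk.start < region.end
        for pk in peaks
    )


def call_occupancy(
    signal: pd.Series,
    retained_peaks: Sequence[PeakCall],
    regions: Sequence[Region],
    negative_regions: Sequence[Region],
) -> pd.Series:
    """Binary occupancy for one mark in one cell type.

    A region is occupied iff it overlaps at least one retained peak AND its
    normalized signal exceeds the mean signal over the negative regions.
    ``signal`` is the replicate-mean NC indexed by region id and must cover
    both region sets.
    """
    if len(negative_regions) == 0:
        raise ValueError("negative region set is empty; occupancy threshold undefined")
    missing = [r.id for r in list(regions) + list(negative_regions) if r.id not in signal.index]
    if missing:
        raise ValueError(f"signal does not cover regions: {missing[:5]}...")
    threshold = float(signal.loc[[r.id for r in negative_regions]].mean())
    by_chrom: Dict[str, list] = {}
    for pk in retained_peaks:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    occupied = {}
    for r in regions:
        has_peak = _region_overlaps_peaks(r, by_chrom.get(r.chrom, ()))
        occupied[r.id] = bool(has_peak and signal.loc[r.id] > threshold)
    return pd.Series(occupied, name="occupied")


def default_negative_regions(
    regions: Sequence[Region], retained_peaks: Sequence[PeakCall]
) -> list:
    """Regions of the analyzed set overlapping no retained peak (default
    background for the occupancy threshold)."""
    by_chrom: Dict[str, list] = {}
    for pk in retained_peaks:
        by_chrom.setdefault(pk.chrom, []).append(pk)
    return [r for r in regions if not _region_overlaps_peaks(r, by_chrom.get(r.chrom, ()))]


def call_meth_occupancy(region_meth: Iterable, threshold: float = 0.5) -> pd.Series:
    """5mC occupancy: mean region methylation >= threshold.

    Regions with undefined methylation (no qualifying CpG) are unoccupied.
    ``region_meth`` is an iterable of exprmeth.RegionMeth.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    out = {}
    for rm in region_meth:
        out[rm.region_id] = bool(rm.defined and rm.mean >= threshold)
    return pd.Series(out, name="5mC")


def build_occupancy_matrix(per_mark: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Assemble per-mark occupancy Series into a region x mark boolean frame."""
    frame = pd.DataFrame({m: per_mark[m] for m in MARKS if m in per_mark})
    if frame.isna().any().any():
        raise ValueError("occupancy matrix has missing region/mark entries")
    return frame.astype(bool)


def assign_state(occ_row: Mapping[str, bool], region_id: str = "") -> StateVector:
    """Classify a region from its per-mark occupancy row.

    Categories: repressive (>=1 repressive mark, no active mark), active
    (>=1 active mark, no repressive), bivalent (both), neutral (neither
    repressive nor active; H3K4me1 or ATAC alone stay neutral).
    """
    repressive = frozenset(m for m in REPRESSIVE_MARKS if occ_row.get(m, False))
    active = frozenset(m for m in ACTIVE_MARKS if occ_row.get(m, False))
    if repressive and active:
        category = "bivalent"
    elif repressive:
        category = "repressive"
    elif active:
        category = "active"
    else:
        category = "neutral"
    return StateVector(
        region_id=region_id,
        repressive=repressive,
        active=active,
        h3k4me1=bool(occ_row.get("H3K4me1", False)),
        category=category,
    )


def assign_states(occupancy: pd.DataFrame) -> list:
    return [assign_state(row, region_id=rid) for rid, row in occupancy.iterrows()]


SPECIFICITY_LABELS = ("A-specific", "B-specific", "shared", "neither")


def specificity(occ_a: pd.DataFrame, occ_b: pd.DataFrame) -> pd.DataFrame:
    """Per region x mark label comparing occupancy between two cell types."""
    if set(occ_a.index) != set(occ_b.index) or list(occ_a.columns) != list(occ_b.columns):
        raise ValueError("occupancy matrices must share regions and marks")
    occ_b = occ_b.loc[occ_a.index]
    labels = np.where(
        occ_a & occ_b, "shared",
        np.where(occ_a & ~occ_b, "A-specific",
                 np.where(~occ_a & occ_b, "B-specific", "neither")),
    )
    return pd.DataFrame(labels, index=occ_a.index, columns=occ_a.columns)


@dataclass
class TransitionTable:
    """Counts of regions moving between repressive signatures A -> B."""

    counts: pd.DataFrame  # index = signature in A, columns = signature in B
    n_regions: int

    def de_novo_count(self) -> int:
        """Regions with no repressive mark in A but some in B."""
        if NO_SIGNATURE not in self.counts.index:
            return 0
        row = self.counts.loc[NO_SIGNATURE]
        return int(row.drop(labels=[NO_SIGNATURE], errors="ignore").sum())

    def to_long(self) -> pd.DataFrame:
        long = self.counts.stack().reset_index()
        long.columns = ["signature_a", "signature_b", "count"]
        return long


def transitions(states_a: Sequence[StateVector], states_b: Sequence[StateVector]) -> TransitionTable:
    """Cross-tabulate repressive signatures between matched region sets."""
    a_by_id = {s.region_id: s for s in states_a}
    b_by_id = {s.region_id: s for s in states_b}
    if set(a_by_id) != set(b_by_id):
        raise ValueError("state vectors must cover identical region ids")
    pairs = [(a_by_id[rid].repressive_signature, b_by_id[rid].repressive_signature) for rid in a_by_id]
    frame = pd.DataFrame(pairs, columns=["a", "b"])
    counts = pd.crosstab(frame["a"], frame["b"])
    counts.index.name = "signature_a"
    counts.columns.name = "signature_b"
    return TransitionTable(counts=counts, n_regions=len(pairs))


@dataclass
class FamilyEnrichment:
    family: str
    observed: int
    expected: float
    enrichment_rate: float


def family_enrichment(
    subgroup: Sequence[Region],
    background: Sequence[Region],
    family_attr: str = "te_family",
):
    """Observed/expected TE family composition of a subgroup vs background.

    Expected counts follow background family proportions scaled to the
    subgroup size; Cohen's w over the family table quantifies the distortion.
    Returns (FamilyEnrichment list, EffectSize).
    """
    if not subgroup or not background:
        raise ValueError("subgroup and background must be non-empty")
    bg_ids = {r.id for r in background}
    stray = [r.id for r in subgroup if r.id not in bg_ids]
    if stray:
        raise ValueError(f"subgroup regions missing from background: {stray[:5]}")

    def family_of(r: Region) -> str:
        return r.attrs.get(family_attr, "unknown")

    bg_counts: Dict[str, int] = {}
    for r in background:
        bg_counts[family_of(r)] = bg_counts.get(family_of(r), 0) + 1
    obs_counts: Dict[str, int] = {f: 0 for f in bg_counts}
    for r in subgroup:
        obs_counts[family_of(r)] += 1

    n_sub, n_bg = len(subgroup), len(background)
    families = sorted(bg_counts)
    results = []
    for fam in families:
        expected = n_sub * bg_counts[fam] / n_bg
        observed = obs_counts[fam]
        rate = observed / expected if expected > 0 else float("nan")
        results.append(FamilyEnrichment(fam, observed, expected, rate))
    effect = chisq_gof_effect_size(
        [obs_counts[f] for f in families],
        [n_sub * bg_counts[f] / n_bg for f in families],
    )
    return results, effect


# ---------------------------------------------------------------------------
# tabular export

def occupancy_to_tsv(occupancy: pd.DataFrame, path) -> None:
    out = occupancy.astype(int)
    out.index.name = "region_id"
    out.to_csv(path, sep="\t")


def states_to_frame(states: Sequence[StateVector]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "region_id": [s.region_id for s in states],
            "repressive_signature": [s.repressive_signature for s in states],
            "active_marks": [signature_label(s.active) for s in states],
            "h3k4me1": [int(s.h3k4me1) for s in states],
            "category": [s.category for s in states],
        }
    )
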