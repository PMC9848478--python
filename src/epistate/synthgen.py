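"""Ground-truth-bearing synthetic data generator.

Emulates the statistical structure the pipeline assumes: negative-binomial
IP/input counts with a fixed spike-in admixture, mark x cell-type global
abundance multipliers, per-region mark states with configurable cross-cell
persistence, state-coupled bimodal expression with planted DE and linked
TE-gene deltas, and binomial CpG methylation with variable coverage.

One RNG stream per output type, all spawned from the master seed, so adding
an output never perturbs the others.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import telink
from .chromstate import MARKS
from .regionio import GenomeAnnotation, PromoterWindowSpec, Region, promoter_from_tss
from .spikenorm import SampleRecord

PEAK_MARKS = tuple(m for m in MARKS if m != "5mC")  # 5mC occupancy comes from BS-seq


def _stable_key(*parts: str) -> int:
    """Process-independent integer key for RNG substreams (built-in hash is
    salted per interpreter run)."""
    import zlib

    return zlib.crc32("|".join(parts).encode("utf-8"))

TE_CLASS_OF_FAMILY = {
    "SVA": "Retroposon",
    "L1HS": "LINE",
    "ERVK": "LTR",
    "DNA:hAT": "DNA",
    "L2": "LINE",
}


def _default_family_proportions() -> Dict[str, float]:
    return {"SVA": 0.10, "L1HS": 0.10, "ERVK": 0.10, "DNA:hAT": 0.35, "L2": 0.35}


def _default_state_probs() -> Dict[str, float]:
    return {
        "5mC": 0.30,
        "H3K9me3": 0.25,
        "H3K27me3": 0.25,
        "H2aK119ub": 0.20,
        "H3K4me3": 0.30,
        "H3K4me1": 0.25,
        "H3K27ac": 0.25,
        "ATAC": 0.30,
    }


@dataclass
class SyntheticConfig:
    seed: int = 0
    chromosomes: Dict[str, int] = field(default_factory=lambda: {"chr1": 1_200_000, "chr2": 800_000})
    n_promoters: int = 120
    n_tes: int = 240
    te_length_range: Tuple[int, int] = (300, 3000)
    # regions are kept disjoint with this margin so a peak called over one
    # region cannot bleed into a neighbour (fragment + window extent)
    te_placement_margin: int = 300
    te_family_proportions: Dict[str, float] = field(default_factory=_default_family_proportions)
    promoter_spec: PromoterWindowSpec = field(default_factory=PromoterWindowSpec)
    cell_types: Tuple[str, str] = ("GSC", "PGC")

    # region state model
    state_probs: Dict[str, float] = field(default_factory=_default_state_probs)
    state_persistence: float = 0.7  # prob. cell B inherits cell A's call per mark

    # ChIP / ATAC count model
    global_abundance_multiplier: Dict[Tuple[str, str], float] = field(default_factory=dict)
    nb_mean_occupied: float = 200.0  # per kb of region, at multiplier 1
    nb_mean_unoccupied: float = 4.0
    nb_dispersion: float = 25.0  # NB size; -> infinity recovers Poisson
    input_nb_dispersion: float = 200.0  # inputs are genome-wide and far less bursty
    sequencing_depth: int = 400_000
    input_depth: int = 300_000
    n_replicates: int = 2
    spike_cell_fraction: float = 1.0 / 20.0
    # spike chromatin / baseline target chromatin in sequenced reads; small
    # relative to target so the spike admixture barely distorts target shares
    spike_relative_abundance: float = 0.02

    # fragment model (for the minimal peak caller)
    fragments_per_kb_occupied: float = 60.0
    fragment_background_per_kb: float = 1.0
    fragment_length: int = 150

    # expression model
    te_expr_modes: Tuple[float, float] = (0.1, 3.0)  # not-expressed / expressed modes
    gene_expr_modes: Tuple[float, float] = (0.5, 6.5)
    expr_noise_sd: float = 0.1
    de_fraction: float = 0.2
    de_delta_range_te: Tuple[float, float] = (2.5, 2.9)
    de_delta_range_gene: Tuple[float, float] = (2.5, 4.0)
    null_delta_max: float = 1.0
    te_gene_rho: float = 0.5

    # methylation model
    meth_mean_occupied: float = 0.85
    meth_mean_unoccupied: float = 0.10
    meth_beta_concentration: float = 40.0
    cpgs_per_kb: float = 8.0
    coverage_mean: float = 30.0
    coverage_fixed: Optional[int] = None  # degenerate coverage instead of Poisson

    def __post_init__(self) -> None:
        total = sum(self.te_family_proportions.values())
        if not np.isclose(total, 1.0):
            raise ValueError("te_family_proportions must sum to 1")
        if not -1.0 <= self.te_gene_rho <= 1.0:
            raise ValueError("te_gene_rho must lie in [-1, 1]")
        if any(v <= 0 for v in self.global_abundance_multiplier.values()):
            raise ValueError("abundance multipliers must be positive")

    def multiplier(self, mark: str, cell_type: str) -> float:
        return self.global_abundance_multiplier.get((mark, cell_type), 1.0)

    def rng_for(self, stream: str) -> np.random.Generator:
        root = np.random.SeedSequence(self.seed)
        streams = ("annotation", "states", "chip", "fragments", "expression", "methylation", "misc")
        idx = streams.index(stream)
        return np.random.default_rng(root.spawn(len(streams))[idx])


@dataclass
class SyntheticTruth:
    states: Dict[str, pd.DataFrame]  # cell type -> region x mark booleans
    multipliers: Dict[Tuple[str, str], float]
    de_regions: Dict[str, float]  # region id -> planted delta (B - A)
    links: list  # telink.TEGeneLink
    rho: float
    meth_means: Dict[str, Dict[str, float]]  # cell type -> region id -> true mean


# ---------------------------------------------------------------------------
# annotation


def simulate_annotation(config: SyntheticConfig) -> GenomeAnnotation:
    """Non-overlapping promoters on a jittered lattice plus uniformly placed
    TE copies with family labels. Deterministic per seed."""
    rng = config.rng_for("annotation")
    chroms = list(config.chromosomes.items())
    total_len = sum(l for _, l in chroms)
    width = config.promoter_spec.width
    margin = config.te_placement_margin

    promoters = []
    remaining = config.n_promoters
    for i, (chrom, length) in enumerate(chroms):
        n_here = remaining if i == len(chroms) - 1 else int(round(config.n_promoters * length / total_len))
        n_here = min(n_here, remaining)
        remaining -= n_here
        if n_here == 0:
            continue
        spacing = length / n_here
        if spacing < width + margin + 2:
            raise ValueError(f"cannot pack {n_here} promoters of width {width} on {chrom}")
        for j in range(n_here):
            strand = "+" if rng.random() < 0.5 else "-"
            jitter = rng.integers(0, max(int(spacing - width - margin), 1))
            slot = int(j * spacing) + jitter
            # keep the full window inside the slot
            tss = slot + (config.promoter_spec.upstream if strand == "+" else config.promoter_spec.downstream)
            gene_id = f"gene{len(promoters):04d}"
            promoters.append(
                promoter_from_tss(
                    chrom,
                    tss,
                    strand,
                    config.promoter_spec,
                    chrom_length=length,
                    region_id=f"prom_{gene_id}",
                    attrs={"gene_id": gene_id},
                )
            )

    families = sorted(config.te_family_proportions)
    probs = np.array([config.te_family_proportions[f] for f in families])
    tes = []
    chrom_names = [c for c, _ in chroms]
    chrom_probs = np.array([l for _, l in chroms], dtype=float) / total_len
    margin = config.te_placement_margin
    occupied: Dict[str, list] = {c: [] for c, _ in chroms}
    for p in promoters:
        occupied[p.chrom].append((p.start, p.end))
    for i in range(config.n_tes):
        te_len = int(rng.integers(config.te_length_range[0], config.te_length_range[1]))
        placed = False
        for _ in range(200):
            chrom = chrom_names[rng.choice(len(chrom_names), p=chrom_probs)]
            length = config.chromosomes[chrom]
            if length - te_len <= 1:
                continue
            start = int(rng.integers(0, length - te_len))
            end = start + te_len
            if any(start - margin < e and s < end + margin for s, e in occupied[chrom]):
                continue
            occupied[chrom].append((start, end))
            placed = True
            break
        if not placed:
            raise ValueError(
                f"cannot pack {config.n_tes} TEs without overlap; enlarge the genome"
            )
        family = families[rng.choice(len(families), p=probs)]
        tes.append(
            Region(
                id=f"te{i:05d}",
                chrom=chrom,
                start=start,
                end=end,
                strand="+" if rng.random() < 0.5 else "-",
                kind="te",
                attrs={"te_family": family, "te_class": TE_CLASS_OF_FAMILY[family]},
            )
        )
    return GenomeAnnotation(chromosomes=dict(config.chromosomes), promoters=promoters, tes=tes)


# ---------------------------------------------------------------------------
# states


def draw_states(config: SyntheticConfig, annotation: GenomeAnnotation) -> Dict[str, pd.DataFrame]:
    """Per-region boolean mark states for both cell types.

    Cell A marks are independent Bernoulli; cell B inherits each call with
    probability ``state_persistence`` and redraws otherwise.
    """
    rng = config.rng_for("states")
    region_ids = [r.id for r in annotation.all_regions()]
    n = len(region_ids)
    cell_a, cell_b = config.cell_types
    a = {}
    b = {}
    for mark in MARKS:
        p = config.state_probs.get(mark, 0.25)
        occ_a = rng.random(n) < p
        inherit = rng.random(n) < config.state_persistence
        redraw = rng.random(n) < p
        occ_b = np.where(inherit, occ_a, redraw)
        a[mark] = occ_a
        b[mark] = occ_b
    return {
        cell_a: pd.DataFrame(a, index=region_ids).astype(bool),
        cell_b: pd.DataFrame(b, index=region_ids).astype(bool),
    }


def make_truth(config: SyntheticConfig, annotation: GenomeAnnotation) -> SyntheticTruth:
    states = draw_states(config, annotation)
    links = telink.assign_nearest_promoter(annotation.tes, annotation.promoters, spec=config.promoter_spec)
    return SyntheticTruth(
        states=states,
        multipliers=dict(config.global_abundance_multiplier),
        de_regions={},
        links=links,
        rho=config.te_gene_rho,
        meth_means={},
    )


# ---------------------------------------------------------------------------
# ChIP / ATAC counts and fragments


@dataclass
class ChipSimulation:
    mark: str
    cell_type: str
    ip_counts: pd.DataFrame  # region x IP replicate
    input_counts: pd.DataFrame  # region x 1 input sample
    ip_samples: list
    input_sample: SampleRecord
    fragments: Dict[str, Dict[str, list]]  # replicate id -> chrom -> [(start, end)]


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.maximum(mean, 1e-9)
    p = dispersion / (dispersion + mean)
    return rng.negative_binomial(dispersion, p)


def simulate_chip(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    annotation: GenomeAnnotation,
    mark: str,
    cell_type: str,
    regions: Optional[Sequence[Region]] = None,
) -> ChipSimulation:
    """NB IP and input counts plus fragment lists for one mark in one cell.

    Per-region target chromatin abundance is length-proportional, boosted at
    truly occupied regions, and globally scaled by the mark x cell multiplier.
    Spike chromatin is constant across cell types for the same mark, so the
    multiplier is recoverable after spike normalization but cancels under
    depth-only normalization.
    """
    # deterministic per (mark, cell) substream, independent of call order
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _stable_key("chip", mark, cell_type))))

    if regions is None:
        regions = list(annotation.all_regions())
    region_ids = [r.id for r in regions]
    lengths_kb = np.array([r.length for r in regions], dtype=float) / 1000.0
    occupied = truth.states[cell_type].loc[region_ids, mark].to_numpy()
    mult = config.multiplier(mark, cell_type)

    per_kb = np.where(occupied, config.nb_mean_occupied, config.nb_mean_unoccupied)
    abundance = per_kb * lengths_kb * mult
    total_abundance = abundance.sum()
    # spike chromatin is a fixed external quantity: identical for every cell
    # type assayed with the same antibody (expected baseline, not the cell's
    # own occupancy draw)
    p_occ = config.state_probs.get(mark, 0.25)
    expected_per_kb = p_occ * config.nb_mean_occupied + (1.0 - p_occ) * config.nb_mean_unoccupied
    spike_abundance = config.spike_relative_abundance * expected_per_kb * lengths_kb.sum()

    ip_cols, ip_samples = {}, []
    for rep in range(1, config.n_replicates + 1):
        # fixed nominal depth: the NC form keeps 1/depth through the spike
        # factor, so depth jitter would masquerade as abundance change
        depth = float(config.sequencing_depth)
        expected = depth * abundance / (total_abundance + spike_abundance)
        counts = _nb_draw(rng, expected, config.nb_dispersion)
        spike_reads = int(rng.poisson(depth * spike_abundance / (total_abundance + spike_abundance)))
        sample_id = f"{mark}_{cell_type}_rep{rep}"
        ip_cols[sample_id] = counts
        ip_samples.append(
            SampleRecord(
                sample_id=sample_id,
                antibody=mark,
                cell_type=cell_type,
                role="IP",
                replicate=rep,
                target_mapped_reads=max(int(counts.sum()), 1),
                spike_mapped_reads=max(spike_reads, 1),
            )
        )

    input_expected = config.input_depth * lengths_kb / lengths_kb.sum()
    input_counts = _nb_draw(rng, input_expected, config.input_nb_dispersion)
    input_sample = SampleRecord(
        sample_id=f"input_{cell_type}",
        antibody="input",
        cell_type=cell_type,
        role="input",
        replicate=1,
        target_mapped_reads=max(int(input_counts.sum()), 1),
        spike_mapped_reads=0,
    )

    fragments = {}
    frag_rng = np.random.default_rng(np.random.SeedSequence((config.seed, _stable_key("frag", mark, cell_type))))
    for sample in ip_samples:
        frags: Dict[str, list] = {c: [] for c in annotation.chromosomes}
        for r, occ in zip(regions, occupied):
            if not occ:
                continue
            n_frags = frag_rng.poisson(config.fragments_per_kb_occupied * r.length / 1000.0 * mult)
            if n_frags == 0:
                continue
            starts = frag_rng.integers(r.start, max(r.end - config.fragment_length, r.start + 1), size=n_frags)
            frags[r.chrom].extend(
                (int(s), int(min(s + config.fragment_length, annotation.chromosomes[r.chrom])))
                for s in starts
            )
        for chrom, length in annotation.chromosomes.items():
            n_bg = frag_rng.poisson(config.fragment_background_per_kb * length / 1000.0)
            starts = frag_rng.integers(0, max(length - config.fragment_length, 1), size=n_bg)
            frags[chrom].extend((int(s), int(s) + config.fragment_length) for s in starts)
        for chrom in frags:
            frags[chrom].sort()
        fragments[sample.sample_id] = frags

    return ChipSimulation(
        mark=mark,
        cell_type=cell_type,
        ip_counts=pd.DataFrame(ip_cols, index=region_ids),
        input_counts=pd.DataFrame({input_sample.sample_id: input_counts}, index=region_ids),
        ip_samples=ip_samples,
        input_sample=input_sample,
        fragments=fragments,
    )


def recovered_abundance_ratio(config: SyntheticConfig, mark: str):
    """Simulate both cell types for ``mark`` and measure the between-cell
    normalized-signal ratio (second cell over first) across regions truly
    occupied in both.

    Returns (spike_ratio, depth_only_ratio): with spike factors applied the
    configured global multiplier is recoverable; under depth-only
    normalization (unit factors) global abundance changes cancel and the
    ratio sits near 1.
    """
    from .spikenorm import NormalizationFactor, normalize_signal, spike_factors

    annotation = simulate_annotation(config)
    truth = make_truth(config, annotation)
    regions = list(annotation.all_regions())
    cell_a, cell_b = config.cell_types
    shared = truth.states[cell_a][mark] & truth.states[cell_b][mark]
    shared_ids = shared[shared].index
    sims = {c: simulate_chip(config, truth, annotation, mark, c) for c in (cell_a, cell_b)}
    factors = spike_factors(sims[cell_a].ip_samples + sims[cell_b].ip_samples, mark)
    totals: Dict[str, float] = {}
    totals_depth: Dict[str, float] = {}
    for cell, sim in sims.items():
        unit = [NormalizationFactor(s.sample_id, mark, 1.0) for s in sim.ip_samples]
        for label, used, sink in (("spike", factors, totals), ("depth", unit, totals_depth)):
            signal = normalize_signal(
                sim.ip_counts, sim.input_counts, used, regions, sim.ip_samples, [sim.input_sample]
            )
            sink[cell] = float(signal.values.loc[shared_ids].mean(axis=1).sum())
    return totals[cell_b] / totals[cell_a], totals_depth[cell_b] / totals_depth[cell_a]


# ---------------------------------------------------------------------------
# expression


def simulate_linked_deltas(
    n_links: int, rho: float, seed: int, scale: float = 1.5
):
    """Bivariate-normal (gene, TE) differential-expression deltas at
    correlation rho over synthetic one-to-one links.

    Returns (links, te_delta, gene_delta) with ids te00000.../gene0000...
    """
    rng = np.random.default_rng(seed)
    z_gene = rng.standard_normal(n_links)
    z_te = rho * z_gene + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal(n_links)
    links = [
        telink.TEGeneLink(te_id=f"te{i:05d}", gene_id=f"gene{i:04d}", distance=int(rng.integers(-90_000, 90_000)))
        for i in range(n_links)
    ]
    te_delta = {l.te_id: float(z_te[i] * scale) for i, l in enumerate(links)}
    gene_delta = {l.gene_id: float(z_gene[i] * scale) for i, l in enumerate(links)}
    return links, te_delta, gene_delta


def simulate_expression(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    annotation: GenomeAnnotation,
) -> pd.DataFrame:
    """State-coupled bimodal expression with planted DE deltas.

    Baseline (cell A) values sit at the expressed mode when the region's cell
    A state carries an active mark, else at the not-expressed mode. Each
    region carries a latent z; linked TEs share their gene's latent at
    correlation ``te_gene_rho``. The planted delta is a deterministic odd
    monotone function of z: small (|delta| <= null_delta_max) inside the
    central quantile, jumping into the configured DE range in the tails so
    that a ``de_fraction`` of regions is differentially expressed in
    expectation. Monotonicity makes rho = 1 with zero noise yield exactly
    correlated deltas. DE baselines are re-anchored so values stay
    non-negative. Planted DE deltas are recorded in ``truth.de_regions``.

    Output columns: <cell>_rep1/2 per cell type; rows indexed by region id,
    values on the log2(RPKM+1) scale.
    """
    from scipy.stats import norm

    rng = config.rng_for("expression")
    cell_a, cell_b = config.cell_types
    regions = list(annotation.all_regions())

    gene_latent = {}
    for prom in annotation.promoters:
        gene_latent[prom.attrs.get("gene_id", prom.id)] = rng.standard_normal()
    te_gene = {l.te_id: l.gene_id for l in truth.links}

    def latent_for(region: Region) -> float:
        if region.kind == "promoter":
            return gene_latent[region.attrs.get("gene_id", region.id)]
        gid = te_gene.get(region.id)
        base = gene_latent[gid] if gid is not None else rng.standard_normal()
        rho = config.te_gene_rho
        return rho * base + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.standard_normal()

    z_cut = float(norm.ppf(1.0 - config.de_fraction / 2.0)) if config.de_fraction > 0 else np.inf
    null_scale = config.null_delta_max / max(z_cut, 1e-9)

    def planted_delta(z: float, delta_range) -> tuple:
        """(delta, is_de): odd monotone in z, DE in the |z| > z_cut tails."""
        if abs(z) <= z_cut:
            return float(np.clip(z * null_scale, -config.null_delta_max, config.null_delta_max)), False
        low, high = delta_range
        magnitude = min(low + 0.2 * (abs(z) - z_cut), high)
        return float(np.sign(z) * magnitude), True

    n = len(regions)
    values_a = np.zeros(n)
    values_b = np.zeros(n)
    truth.de_regions = {}
    for i, region in enumerate(regions):
        low, high = config.te_expr_modes if region.kind == "te" else config.gene_expr_modes
        delta_range = (
            config.de_delta_range_te if region.kind == "te" else config.de_delta_range_gene
        )
        z = latent_for(region)
        delta, is_de = planted_delta(z, delta_range)
        state = truth.states[cell_a].loc[region.id]
        base = high if (state["H3K4me3"] or state["H3K27ac"]) else low
        if is_de:
            # anchor so the higher endpoint clears the expressed range
            a = low if delta > 0 else high
            values_a[i], values_b[i] = a, max(a + delta, 0.0)
            truth.de_regions[region.id] = delta
        else:
            values_a[i] = base
            values_b[i] = max(base + delta, 0.0)
    columns = {}
    for cell, values in ((cell_a, values_a), (cell_b, values_b)):
        for rep in (1, 2):
            noise = rng.normal(0.0, config.expr_noise_sd, size=n)
            columns[f"{cell}_rep{rep}"] = np.maximum(values + noise, 0.0)
    return pd.DataFrame(columns, index=[r.id for r in regions])


# ---------------------------------------------------------------------------
# methylation


def simulate_methylation(
    config: SyntheticConfig,
    truth: SyntheticTruth,
    annotation: GenomeAnnotation,
    cell_type: str,
) -> pd.DataFrame:
    """Per-CpG methylation table (chrom, pos0, pos1, meth, total, region_id).

    Region true means are Beta-distributed around the occupied or unoccupied
    mode according to the region's true 5mC state; per-CpG coverage is
    Poisson and methylated reads Binomial(coverage, true mean).
    """
    rng = np.random.default_rng(np.random.SeedSequence((config.seed, _stable_key("meth", cell_type))))
    rows = []
    truth.meth_means.setdefault(cell_type, {})
    kappa = config.meth_beta_concentration
    for region in annotation.all_regions():
        occupied = bool(truth.states[cell_type].loc[region.id, "5mC"])
        mu = config.meth_mean_occupied if occupied else config.meth_mean_unoccupied
        true_mean = float(rng.beta(mu * kappa, (1.0 - mu) * kappa))
        truth.meth_means[cell_type][region.id] = true_mean
        n_cpgs = max(int(round(region.length / 1000.0 * config.cpgs_per_kb)), 1)
        positions = np.sort(rng.integers(region.start, region.end, size=n_cpgs))
        if config.coverage_fixed is not None:
            coverage = np.full(n_cpgs, config.coverage_fixed, dtype=int)
        else:
            coverage = rng.poisson(config.coverage_mean, size=n_cpgs)
        meth = rng.binomial(coverage, true_mean)
        for pos, cov, m in zip(positions, coverage, meth):
            rows.append((region.chrom, int(pos), int(pos) + 1, int(m), int(cov), region.id))
    return pd.DataFrame(
        rows, columns=["chrom", "pos0", "pos1", "meth_reads", "total_reads", "region_id"]
    )


# ---------------------------------------------------------------------------
# full emission


def simulate_all(config: SyntheticConfig, outdir) -> SyntheticTruth:
    """Generate and write every synthetic input the pipeline consumes.

    Emits region tables, a sample sheet, IP/input count matrices, fragment
    tables, expression values, CpG tables, and truth.json under ``outdir``.
    """
    from .regionio import write_regions
    from .spikenorm import write_sample_sheet

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    annotation = simulate_annotation(config)
    truth = make_truth(config, annotation)

    write_regions(annotation.promoters, outdir / "promoters.tsv")
    write_regions(annotation.tes, outdir / "tes.tsv")
    with open(outdir / "chromosomes.tsv", "w", encoding="utf-8") as handle:
        handle.write("chrom\tlength\n")
        for chrom, length in config.chromosomes.items():
            handle.write(f"{chrom}\t{length}\n")

    all_samples = []
    cell_a, cell_b = config.cell_types
    for mark in PEAK_MARKS:
        for cell in (cell_a, cell_b):
            sim = simulate_chip(config, truth, annotation, mark, cell)
            sim.ip_counts.rename_axis("region_id").to_csv(
                outdir / f"ip_counts_{mark}_{cell}.tsv", sep="\t"
            )
            sim.input_counts.rename_axis("region_id").to_csv(
                outdir / f"input_counts_{cell}_{mark}.tsv", sep="\t"
            )
            all_samples.extend(sim.ip_samples)
            all_samples.append(sim.input_sample)
            frag_rows = []
            for sample_id, per_chrom in sim.fragments.items():
                for chrom, frags in per_chrom.items():
                    frag_rows.extend((sample_id, chrom, s, e) for s, e in frags)
            pd.DataFrame(frag_rows, columns=["sample_id", "chrom", "start", "end"]).to_csv(
                outdir / f"fragments_{mark}_{cell}.tsv", sep="\t", index=False
            )
    # one input record per cell type is enough downstream; drop duplicates
    seen = set()
    unique_samples = []
    for s in all_samples:
        if s.sample_id not in seen:
            unique_samples.append(s)
            seen.add(s.sample_id)
    write_sample_sheet(unique_samples, outdir / "samples.tsv")

    expr = simulate_expression(config, truth, annotation)
    expr.rename_axis("region_id").to_csv(outdir / "expression.tsv", sep="\t")

    for cell in (cell_a, cell_b):
        meth = simulate_methylation(config, truth, annotation, cell)
        meth.to_csv(outdir / f"cpg_{cell}.tsv", sep="\t", index=False)

    truth_json = {
        "seed": config.seed,
        "cell_types": list(config.cell_types),
        "rho": truth.rho,
        "multipliers": {f"{m}|{c}": v for (m, c), v in truth.multipliers.items()},
        "de_regions": truth.de_regions,
        "links": [
            {"te_id": l.te_id, "gene_id": l.gene_id, "distance": l.distance} for l in truth.links
        ],
        "states": {
            cell: {mark: frame[mark].astype(int).to_dict() for mark in frame.columns}
            for cell, frame in truth.states.items()
        },
        "meth_means": truth.meth_means,
    }
    with open(outdir / "truth.json", "w", encoding="utf-8") as handle:
        json.dump(truth_json, handle, indent=1)
    return truth
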