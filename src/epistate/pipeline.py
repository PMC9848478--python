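"""Stage orchestration: configuration, dependency checking, manifests, and
the end-to-end synthetic run."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict

import numpy as np
import pandas as pd
import yaml

from . import chromstate, effstats, exprmeth, peakrep, somgrid, spikenorm, synthgen, telink
from .regionio import read_regions, write_peaks
from .synthgen import PEAK_MARKS, SyntheticConfig

logger = logging.getLogger(__name__)

__version__ = "0.1.0"

STAGES = (
    "simulate",
    "normalize",
    "peaks",
    "occupancy",
    "states",
    "transitions",
    "express",
    "link",
    "som",
    "stats",
)

STAGE_DEPENDENCIES = {
    "simulate": (),
    "normalize": ("simulate",),
    "peaks": ("simulate",),
    "occupancy": ("normalize", "peaks"),
    "states": ("occupancy",),
    "transitions": ("states",),
    "express": ("simulate",),
    "link": ("simulate", "express"),
    "som": ("normalize", "express"),
    "stats": ("states", "transitions", "express", "link", "som"),
}


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    synthetic: dict = field(default_factory=dict)
    epsilon: float = 0.5
    meth_threshold: float = 0.5
    peak_window_size: int = 200
    peak_window_step: int = 100
    peak_p_threshold: float = 0.05
    peak_merge_gap: int = 200
    link_bin_width: int = 10_000
    som: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "outdir" not in raw:
            raise ValueError("config must declare an outdir")
        raw["outdir"] = Path(raw["outdir"])
        return cls(**raw)

    def synthetic_config(self) -> SyntheticConfig:
        params = dict(self.synthetic)
        mults = params.pop("global_abundance_multiplier", None)
        cfg = SyntheticConfig(seed=self.seed, **params)
        if mults:
            cfg.global_abundance_multiplier = {
                tuple(key.split("|")): float(v) for key, v in mults.items()
            }
        return cfg

    @property
    def simdir(self) -> Path:
        return self.outdir / "sim"


def _sha256(path: Path) -> str:
    digest = hashlib.sha256()
    with open(path, "rb") as handle:
        for chunk in iter(lambda: handle.read(65536), b""):
            digest.update(chunk)
    return digest.hexdigest()


class Manifest:
    """Per-run record of stage inputs, outputs, parameters, and hashes."""

    def __init__(self, outdir: Path):
        self.path = outdir / "manifest.json"
        self.data: Dict[str, dict] = {}
        if self.path.exists():
            with open(self.path, encoding="utf-8") as handle:
                self.data = json.load(handle)

    def record(self, stage: str, inputs, outputs, params: dict, seed: int) -> None:
        self.data[stage] = {
            "inputs": {str(p): _sha256(Path(p)) for p in inputs},
            "outputs": {str(p): _sha256(Path(p)) for p in outputs},
            "params": params,
            "seed": seed,
            "version": __version__,
        }
        with open(self.path, "w", encoding="utf-8") as handle:
            json.dump(self.data, handle, indent=1)

    def up_to_date(self, stage: str, inputs) -> bool:
        entry = self.data.get(stage)
        if entry is None:
            return False
        recorded = entry["inputs"]
        current = {str(p): _sha256(Path(p)) for p in inputs if Path(p).exists()}
        if set(recorded) != set(current) or any(recorded[k] != current[k] for k in recorded):
            return False
        return all(Path(p).exists() for p in entry["outputs"])


class StageError(RuntimeError):
    pass


def run_stage(name: str, config: PipelineConfig, force: bool = False) -> bool:
    """Run one stage; returns True if work was done, False if up to date.

    Raises StageError naming the missing upstream stage when dependencies
    have not produced their outputs yet.
    """
    if name not in STAGES:
        raise ValueError(f"unknown stage {name!r}; expected one of {STAGES}")
    config.outdir.mkdir(parents=True, exist_ok=True)
    manifest = Manifest(config.outdir)
    for dep in STAGE_DEPENDENCIES[name]:
        if dep not in manifest.data:
            raise StageError(f"stage {name!r} requires stage {dep!r}; run that first")

    runner = _STAGE_RUNNERS[name]
    inputs = runner.inputs(config)
    if not force and manifest.up_to_date(name, inputs):
        logger.info("stage %s: up to date", name)
        return False
    outputs, params = runner.run(config)
    manifest.record(name, inputs, outputs, params, config.seed)
    return True


def run_all(config: PipelineConfig, force: bool = False) -> dict:
    """Execute every stage in dependency order and return the final report."""
    for name in STAGES:
        run_stage(name, config, force=force)
    with open(config.outdir / "report.json", encoding="utf-8") as handle:
        return json.load(handle)


# ---------------------------------------------------------------------------
# stage implementations


class _Stage:
    def __init__(self, inputs, run):
        self.inputs = inputs
        self.run = run


def _sim_inputs(config: PipelineConfig):
    return []


def _sim_run(config: PipelineConfig):
    synthgen.simulate_all(config.synthetic_config(), config.simdir)
    outputs = sorted(config.simdir.glob("*.tsv")) + [config.simdir / "truth.json"]
    return outputs, {"synthetic": config.synthetic}


def _load_annotation(config: PipelineConfig):
    promoters = read_regions(config.simdir / "promoters.tsv", format="region-table")
    tes = read_regions(config.simdir / "tes.tsv", format="region-table")
    chroms = pd.read_csv(config.simdir / "chromosomes.tsv", sep="\t")
    chrom_lengths = dict(zip(chroms["chrom"], chroms["length"].astype(int)))
    return promoters, tes, chrom_lengths


def _cells(config: PipelineConfig):
    return tuple(config.synthetic.get("cell_types", ("GSC", "PGC")))


def _norm_inputs(config: PipelineConfig):
    return sorted(config.simdir.glob("ip_counts_*.tsv")) + [config.simdir / "samples.tsv"]


def _norm_run(config: PipelineConfig):
    promoters, tes, _ = _load_annotation(config)
    regions = promoters + tes
    samples = spikenorm.read_sample_sheet(config.simdir / "samples.tsv")
    sigdir = config.outdir / "signal"
    sigdir.mkdir(exist_ok=True)
    outputs = []
    for mark in PEAK_MARKS:
        group = [s for s in samples if s.antibody == mark and s.role == "IP"]
        factors = spikenorm.spike_factors(group, mark)
        for cell in _cells(config):
            ip = pd.read_csv(config.simdir / f"ip_counts_{mark}_{cell}.tsv", sep="\t", index_col="region_id")
            inp = pd.read_csv(config.simdir / f"input_counts_{cell}_{mark}.tsv", sep="\t", index_col="region_id")
            cell_ips = [s for s in group if s.cell_type == cell]
            cell_inputs = [s for s in samples if s.role == "input" and s.cell_type == cell]
            signal = spikenorm.normalize_signal(
                ip[[s.sample_id for s in cell_ips]], inp, factors, regions,
                cell_ips, cell_inputs, epsilon=config.epsilon,
            )
            out = sigdir / f"nc_{mark}_{cell}.tsv"
            signal.values.rename_axis("region_id").to_csv(out, sep="\t")
            outputs.append(out)
    return outputs, {"epsilon": config.epsilon}


def _fragments_by_sample(path: Path):
    table = pd.read_csv(path, sep="\t")
    out: Dict[str, Dict[str, list]] = {}
    for (sample_id, chrom), group in table.groupby(["sample_id", "chrom"]):
        out.setdefault(sample_id, {})[chrom] = list(zip(group["start"], group["end"]))
    return out


def _peaks_inputs(config: PipelineConfig):
    return sorted(config.simdir.glob("fragments_*.tsv"))


def _profile_and_call(frag_map, chrom_lengths, config: PipelineConfig):
    profile = spikenorm.window_profile(
        frag_map, chrom_lengths, window_size=config.peak_window_size, step=config.peak_window_step
    )
    values = np.concatenate([profile.values[c] for c in profile.values]) if profile.values else np.array([0.0])
    background = max(float(values.mean()), 1e-6)
    return peakrep.call_broad_peaks_minimal(
        profile, background, p_threshold=config.peak_p_threshold, merge_gap=config.peak_merge_gap
    )


def _peaks_run(config: PipelineConfig):
    _, _, chrom_lengths = _load_annotation(config)
    peakdir = config.outdir / "peaks"
    peakdir.mkdir(exist_ok=True)
    outputs = []
    for mark in PEAK_MARKS:
        for cell in _cells(config):
            frag_by_sample = _fragments_by_sample(config.simdir / f"fragments_{mark}_{cell}.tsv")
            rep_ids = sorted(frag_by_sample)
            rep_frag_lists = []
            for rid in rep_ids:
                flat = [
                    (chrom, s, e)
                    for chrom, frags in frag_by_sample[rid].items()
                    for s, e in frags
                ]
                rep_frag_lists.append(flat)
            pooled_flat = [f for flat in rep_frag_lists for f in flat]
            psr1_flat, psr2_flat = peakrep.split_pseudoreplicates(pooled_flat, seed=config.seed)

            def to_map(flat):
                frag_map: Dict[str, list] = {}
                for chrom, s, e in flat:
                    frag_map.setdefault(chrom, []).append((s, e))
                return frag_map

            pooled = _profile_and_call(to_map(pooled_flat), chrom_lengths, config)
            reps = [_profile_and_call(to_map(flat), chrom_lengths, config) for flat in rep_frag_lists]
            psrs = [
                _profile_and_call(to_map(psr1_flat), chrom_lengths, config),
                _profile_and_call(to_map(psr2_flat), chrom_lengths, config),
            ]
            replicated = peakrep.retain_reproducible(pooled, reps[0], reps[1], psrs[0], psrs[1])
            assay = "atac" if mark == "ATAC" else "histone"
            final = peakrep.filter_q(replicated.retained, assay)
            out = peakdir / f"{mark}_{cell}.broadPeak"
            write_peaks(final, out)
            outputs.append(out)
    return outputs, {
        "window": [config.peak_window_size, config.peak_window_step],
        "p_threshold": config.peak_p_threshold,
        "merge_gap": config.peak_merge_gap,
    }


def _occ_inputs(config: PipelineConfig):
    return sorted((config.outdir / "signal").glob("nc_*.tsv")) + sorted(
        (config.outdir / "peaks").glob("*.broadPeak")
    ) + sorted(config.simdir.glob("cpg_*.tsv"))


def _occ_run(config: PipelineConfig):
    from .regionio import read_peaks

    promoters, tes, _ = _load_annotation(config)
    outputs = []
    for cell in _cells(config):
        per_mark = {}
        for mark in PEAK_MARKS:
            nc = pd.read_csv(config.outdir / "signal" / f"nc_{mark}_{cell}.tsv", sep="\t", index_col="region_id")
            signal = nc.mean(axis=1)
            peaks = read_peaks(config.outdir / "peaks" / f"{mark}_{cell}.broadPeak")
            calls = []
            for regions in (promoters, tes):
                negatives = chromstate.default_negative_regions(regions, peaks)
                if not negatives:
                    negatives = regions  # degenerate: everything peaked
                calls.append(chromstate.call_occupancy(signal, peaks, regions, negatives))
            per_mark[mark] = pd.concat(calls)
        cpg = pd.read_csv(config.simdir / f"cpg_{cell}.tsv", sep="\t")
        meths = exprmeth.region_methylation_table(cpg)
        meth_occ = chromstate.call_meth_occupancy(meths, threshold=config.meth_threshold)
        all_ids = [r.id for r in promoters + tes]
        per_mark["5mC"] = meth_occ.reindex(all_ids).fillna(False).astype(bool)
        occupancy = chromstate.build_occupancy_matrix(per_mark).loc[all_ids]
        out = config.outdir / f"occupancy_{cell}.tsv"
        chromstate.occupancy_to_tsv(occupancy, out)
        outputs.append(out)
    return outputs, {"meth_threshold": config.meth_threshold}


def _read_occupancy(path: Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="region_id").astype(bool)


def _states_inputs(config: PipelineConfig):
    return [config.outdir / f"occupancy_{c}.tsv" for c in _cells(config)]


def _states_run(config: PipelineConfig):
    outputs = []
    for cell in _cells(config):
        occupancy = _read_occupancy(config.outdir / f"occupancy_{cell}.tsv")
        states = chromstate.assign_states(occupancy)
        out = config.outdir / f"states_{cell}.tsv"
        chromstate.states_to_frame(states).to_csv(out, sep="\t", index=False)
        outputs.append(out)
    return outputs, {}


def _trans_inputs(config: PipelineConfig):
    return [config.outdir / f"occupancy_{c}.tsv" for c in _cells(config)]


def _trans_run(config: PipelineConfig):
    cell_a, cell_b = _cells(config)
    occ_a = _read_occupancy(config.outdir / f"occupancy_{cell_a}.tsv")
    occ_b = _read_occupancy(config.outdir / f"occupancy_{cell_b}.tsv")
    table = chromstate.transitions(chromstate.assign_states(occ_a), chromstate.assign_states(occ_b))
    out = config.outdir / "transitions.tsv"
    table.to_long().to_csv(out, sep="\t", index=False)
    spec = chromstate.specificity(occ_a, occ_b)
    spec_out = config.outdir / "specificity.tsv"
    spec.rename_axis("region_id").to_csv(spec_out, sep="\t")
    return [out, spec_out], {"cells": [cell_a, cell_b]}


def _expr_inputs(config: PipelineConfig):
    return [config.simdir / "expression.tsv", config.simdir / "promoters.tsv", config.simdir / "tes.tsv"]


def _expr_run(config: PipelineConfig):
    promoters, tes, _ = _load_annotation(config)
    kind_of = {r.id: r.kind for r in promoters + tes}
    expr = pd.read_csv(config.simdir / "expression.tsv", sep="\t", index_col="region_id")
    cell_a, cell_b = _cells(config)
    mean_a = expr[[c for c in expr.columns if c.startswith(cell_a)]].mean(axis=1)
    mean_b = expr[[c for c in expr.columns if c.startswith(cell_b)]].mean(axis=1)
    te_thr, gene_thr = exprmeth.CategoryThresholds.te(), exprmeth.CategoryThresholds.gene()
    rows, calls = [], []
    for rid in expr.index:
        thr = te_thr if kind_of.get(rid) == "te" else gene_thr
        rows.append(
            {
                "region_id": rid,
                "kind": kind_of.get(rid, "gene"),
                f"value_{cell_a}": mean_a[rid],
                f"value_{cell_b}": mean_b[rid],
                f"category_{cell_a}": exprmeth.categorize_expression(mean_a[rid], thr),
                f"category_{cell_b}": exprmeth.categorize_expression(mean_b[rid], thr),
            }
        )
        calls.append(exprmeth.call_de(mean_a[rid], mean_b[rid], thr, region_id=rid))
    cat_out = config.outdir / "expression_categories.tsv"
    pd.DataFrame(rows).to_csv(cat_out, sep="\t", index=False)
    de_out = config.outdir / "de_calls.tsv"
    exprmeth.de_calls_to_frame(calls).to_csv(de_out, sep="\t", index=False)
    return [cat_out, de_out], {"thresholds": {"te": [0.4, 1.4], "gene": [1.5, 5.0]}}


def _link_inputs(config: PipelineConfig):
    return [config.simdir / "promoters.tsv", config.simdir / "tes.tsv", config.outdir / "de_calls.tsv"]


def _link_run(config: PipelineConfig):
    promoters, tes, _ = _load_annotation(config)
    links = telink.assign_nearest_promoter(tes, promoters)
    de = pd.read_csv(config.outdir / "de_calls.tsv", sep="\t", index_col="region_id")
    gene_of_prom = {p.id: p.attrs.get("gene_id", p.id) for p in promoters}
    te_delta = {rid: float(de.loc[rid, "delta"]) for rid in de.index if rid.startswith("te")}
    gene_delta = {
        gene_of_prom[rid]: float(de.loc[rid, "delta"]) for rid in de.index if rid in gene_of_prom
    }
    links_out = config.outdir / "links.tsv"
    telink.links_to_frame(links).to_csv(links_out, sep="\t", index=False)
    profile = telink.distance_binned_correlation(links, te_delta, gene_delta, bin_width=config.link_bin_width)
    prof_out = config.outdir / "link_correlation.tsv"
    profile.to_frame().to_csv(prof_out, sep="\t", index=False)
    r, n = telink.link_correlation(links, te_delta, gene_delta)
    summary_out = config.outdir / "link_summary.json"
    with open(summary_out, "w", encoding="utf-8") as handle:
        json.dump({"r": r, "n": n, "n_links": len(links)}, handle)
    return [links_out, prof_out, summary_out], {"bin_width": config.link_bin_width}


def _som_inputs(config: PipelineConfig):
    return sorted((config.outdir / "signal").glob("nc_*.tsv")) + [
        config.simdir / "expression.tsv"
    ] + sorted(config.simdir.glob("cpg_*.tsv"))


def _som_run(config: PipelineConfig):
    promoters, tes, _ = _load_annotation(config)
    prom_ids = [r.id for r in promoters]
    datasets = {}
    for mark in PEAK_MARKS:
        for cell in _cells(config):
            nc = pd.read_csv(config.outdir / "signal" / f"nc_{mark}_{cell}.tsv", sep="\t", index_col="region_id")
            datasets[f"{mark}_{cell}"] = nc.mean(axis=1).loc[prom_ids]
    expr = pd.read_csv(config.simdir / "expression.tsv", sep="\t", index_col="region_id")
    for cell in _cells(config):
        cols = [c for c in expr.columns if c.startswith(cell)]
        datasets[f"RNA_{cell}"] = expr[cols].mean(axis=1).loc[prom_ids]
    meth_tracks = {}
    for cell in _cells(config):
        cpg = pd.read_csv(config.simdir / f"cpg_{cell}.tsv", sep="\t")
        meths = [m for m in exprmeth.region_methylation_table(cpg) if m.region_id in set(prom_ids)]
        meth_tracks[f"5mC_{cell}"] = meths
    features = somgrid.prepare_features(datasets, meth_tracks)
    som_cfg = somgrid.SOMConfig(seed=config.seed, **config.som)
    fit = somgrid.train_som(features, som_cfg)
    codebook_out = config.outdir / "som_codebook.tsv"
    pd.DataFrame(fit.codebook, columns=fit.feature_names).rename_axis("node").to_csv(codebook_out, sep="\t")
    assign_out = config.outdir / "som_assignment.tsv"
    fit.assignment.rename_axis("region_id").to_csv(assign_out, sep="\t")
    qe_out = config.outdir / "som_qe.tsv"
    pd.DataFrame(fit.qe_trajectory, columns=["cycle", "qe"]).to_csv(qe_out, sep="\t", index=False)
    return [codebook_out, assign_out, qe_out], {"som": config.som}


def _stats_inputs(config: PipelineConfig):
    cells = _cells(config)
    return [
        config.outdir / f"occupancy_{cells[0]}.tsv",
        config.outdir / f"occupancy_{cells[1]}.tsv",
        config.outdir / "transitions.tsv",
        config.outdir / "expression_categories.tsv",
        config.outdir / "de_calls.tsv",
        config.outdir / "link_summary.json",
        config.outdir / "som_assignment.tsv",
        config.outdir / "som_codebook.tsv",
        config.outdir / "som_qe.tsv",
    ]


def _stats_run(config: PipelineConfig):
    cell_a, cell_b = _cells(config)
    occ = {c: _read_occupancy(config.outdir / f"occupancy_{c}.tsv") for c in (cell_a, cell_b)}
    categories = pd.read_csv(config.outdir / "expression_categories.tsv", sep="\t")
    de = pd.read_csv(config.outdir / "de_calls.tsv", sep="\t")
    transitions_long = pd.read_csv(config.outdir / "transitions.tsv", sep="\t")
    with open(config.outdir / "link_summary.json", encoding="utf-8") as handle:
        link_summary = json.load(handle)
    som_assign = pd.read_csv(config.outdir / "som_assignment.tsv", sep="\t")
    codebook = pd.read_csv(config.outdir / "som_codebook.tsv", sep="\t", index_col="node")
    qe = pd.read_csv(config.outdir / "som_qe.tsv", sep="\t")

    state_counts = {}
    for cell in (cell_a, cell_b):
        states = chromstate.assign_states(occ[cell])
        counts = pd.Series([s.category for s in states]).value_counts().to_dict()
        state_counts[cell] = counts

    expr_effect = effstats.wilcoxon_effect_size(
        categories[f"value_{cell_a}"], categories[f"value_{cell_b}"]
    )

    report = {
        "n_regions": int(len(occ[cell_a])),
        "occupied_counts": {
            cell: {m: int(occ[cell][m].sum()) for m in occ[cell].columns} for cell in occ
        },
        "state_categories": state_counts,
        "transition_total": int(transitions_long["count"].sum()),
        "de_summary": {
            "n_de": int(de["de"].sum()),
            "n_up": int((de["direction"] == "up").sum()),
            "n_down": int((de["direction"] == "down").sum()),
        },
        "link_summary": link_summary,
        "som": {
            "n_nodes": int(len(codebook)),
            "n_assigned": int(len(som_assign)),
            "qe_initial": float(qe["qe"].iloc[0]),
            "qe_final": float(qe["qe"].iloc[-1]),
        },
        "expression_effect": {
            "statistic": expr_effect.statistic,
            "value": expr_effect.value,
            "n": expr_effect.n,
            "level": expr_effect.level,
        },
    }
    out = config.outdir / "report.json"
    with open(out, "w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=1)
    return [out], {}


_STAGE_RUNNERS = {
    "simulate": _Stage(_sim_inputs, _sim_run),
    "normalize": _Stage(_norm_inputs, _norm_run),
    "peaks": _Stage(_peaks_inputs, _peaks_run),
    "occupancy": _Stage(_occ_inputs, _occ_run),
    "states": _Stage(_states_inputs, _states_run),
    "transitions": _Stage(_trans_inputs, _trans_run),
    "express": _Stage(_expr_inputs, _expr_run),
    "link": _Stage(_link_inputs, _link_run),
    "som": _Stage(_som_inputs, _som_run),
    "stats": _Stage(_stats_inputs, _stats_run),
}
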