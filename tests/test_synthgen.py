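import json

import numpy as np
import pandas as pd
import pytest

from epistate import synthgen, telink
from epistate.regionio import read_regions
from epistate.synthgen import SyntheticConfig


class TestSimulateAnnotation:
    def test_counts_and_promoter_width(self, small_synth_config, small_annotation):
        assert len(small_annotation.promoters) == small_synth_config.n_promoters
        assert all(p.length == 2500 for p in small_annotation.promoters)
        assert len(small_annotation.tes) == small_synth_config.n_tes

    def test_deterministic(self, small_synth_config):
        again = synthgen.simulate_annotation(small_synth_config)
        for a, b in zip(again.all_regions(), synthgen.simulate_annotation(small_synth_config).all_regions()):
            assert (a.id, a.chrom, a.start, a.end, a.strand) == (b.id, b.chrom, b.start, b.end, b.strand)

    def test_single_family(self):
        config = SyntheticConfig(seed=1, n_promoters=10, n_tes=30, te_family_proportions={"SVA": 1.0})
        annotation = synthgen.simulate_annotation(config)
        assert all(t.attrs["te_family"] == "SVA" for t in annotation.tes)

    def test_infeasible_packing_rejected(self):
        config = SyntheticConfig(seed=1, chromosomes={"chr1": 10_000}, n_promoters=50, n_tes=1)
        with pytest.raises(ValueError, match="pack"):
            synthgen.simulate_annotation(config)

    def test_promoters_within_chromosomes(self, small_annotation, small_synth_config):
        for r in small_annotation.all_regions():
            assert 0 <= r.start < r.end <= small_synth_config.chromosomes[r.chrom]


class TestDrawStates:
    def test_persistence_one_copies_states(self, small_annotation):
        config = SyntheticConfig(seed=2, n_promoters=60, n_tes=120,
                                 chromosomes={"chr1": 700_000, "chr2": 500_000},
                                 state_persistence=1.0)
        states = synthgen.draw_states(config, small_annotation)
        assert states["GSC"].equals(states["PGC"])

    def test_occupancy_probability_approx(self, small_annotation):
        config = SyntheticConfig(seed=3, state_probs={m: 0.5 for m in synthgen.MARKS})
        states = synthgen.draw_states(config, small_annotation)
        frac = states["GSC"].to_numpy().mean()
        assert abs(frac - 0.5) < 0.1


class TestSimulateChip:
    def test_occupied_unoccupied_mean_ratio(self, small_synth_config, small_annotation, small_truth):
        sim = synthgen.simulate_chip(small_synth_config, small_truth, small_annotation, "H3K9me3", "GSC")
        occ = small_truth.states["GSC"]["H3K9me3"]
        lengths = pd.Series({r.id: r.length for r in small_annotation.all_regions()})
        per_kb = sim.ip_counts.mean(axis=1) / (lengths / 1000)
        ratio = per_kb[occ].mean() / per_kb[~occ].mean()
        expected = small_synth_config.nb_mean_occupied / small_synth_config.nb_mean_unoccupied
        assert 0.5 * expected < ratio < 1.5 * expected

    def test_poisson_limit(self):
        config = SyntheticConfig(
            seed=4, n_promoters=10, n_tes=400, te_length_range=(1000, 1001),
            chromosomes={"chr1": 600_000, "chr2": 400_000},
            nb_dispersion=1e9, state_probs={m: 0.0 for m in synthgen.MARKS},
        )
        annotation = synthgen.simulate_annotation(config)
        truth = synthgen.make_truth(config, annotation)
        sim = synthgen.simulate_chip(config, truth, annotation, "H3K9me3", "GSC")
        te_counts = sim.ip_counts.loc[[t.id for t in annotation.tes]].to_numpy().ravel()
        ratio = te_counts.var() / te_counts.mean()
        assert 0.8 < ratio < 1.25  # Poisson limit: variance ~= mean

    def test_overdispersed_at_small_size(self):
        config = SyntheticConfig(
            seed=4, n_promoters=10, n_tes=400, te_length_range=(1000, 1001),
            chromosomes={"chr1": 600_000, "chr2": 400_000},
            nb_dispersion=3.0, state_probs={m: 0.0 for m in synthgen.MARKS},
        )
        annotation = synthgen.simulate_annotation(config)
        truth = synthgen.make_truth(config, annotation)
        sim = synthgen.simulate_chip(config, truth, annotation, "H3K9me3", "GSC")
        te_counts = sim.ip_counts.loc[[t.id for t in annotation.tes]].to_numpy().ravel()
        assert te_counts.var() / te_counts.mean() > 2.0

    def test_deterministic(self, small_synth_config, small_annotation, small_truth):
        sim1 = synthgen.simulate_chip(small_synth_config, small_truth, small_annotation, "ATAC", "PGC")
        sim2 = synthgen.simulate_chip(small_synth_config, small_truth, small_annotation, "ATAC", "PGC")
        assert sim1.ip_counts.equals(sim2.ip_counts)
        assert sim1.fragments == sim2.fragments

    def test_multiplier_recovery(self):
        """Planted global 0.5 multiplier recovered through spike
        normalization within +-10% (3 seeds; the acceptance suite runs 10)."""
        for seed in range(3):
            config = SyntheticConfig(seed=seed, global_abundance_multiplier={("H3K27me3", "PGC"): 0.5})
            spike_ratio, depth_ratio = synthgen.recovered_abundance_ratio(config, "H3K27me3")
            assert abs(spike_ratio - 0.5) <= 0.05
            assert depth_ratio > 0.75  # depth-only normalization hides the loss


class TestSimulateExpression:
    def test_rho_one_no_noise_perfect_correlation(self):
        config = SyntheticConfig(seed=6, n_promoters=80, n_tes=160, te_gene_rho=1.0, expr_noise_sd=0.0)
        annotation = synthgen.simulate_annotation(config)
        truth = synthgen.make_truth(config, annotation)
        synthgen.simulate_expression(config, truth, annotation)
        # planted deltas for linked TEs equal a monotone map of the shared
        # latent; with rho=1 all delta pairs are perfectly rank-correlated
        gene_of = {p.id: p.attrs["gene_id"] for p in annotation.promoters}
        prom_of_gene = {g: p for p, g in gene_of.items()}
        expr = synthgen.simulate_expression(config, truth, annotation)
        mean = {c: expr[[f"{c}_rep1", f"{c}_rep2"]].mean(axis=1) for c in config.cell_types}
        delta = mean[config.cell_types[1]] - mean[config.cell_types[0]]
        te_delta = {l.te_id: float(delta[l.te_id]) for l in truth.links}
        gene_delta = {g: float(delta[p]) for g, p in prom_of_gene.items()}
        r, n = telink.link_correlation(truth.links, te_delta, gene_delta)
        assert n >= 3
        assert r > 0.95

    def test_planted_de_separation(self):
        config = SyntheticConfig(seed=7, n_promoters=100, n_tes=200, expr_noise_sd=0.0)
        annotation = synthgen.simulate_annotation(config)
        truth = synthgen.make_truth(config, annotation)
        synthgen.simulate_expression(config, truth, annotation)
        assert truth.de_regions
        for delta in truth.de_regions.values():
            assert abs(delta) >= 2.5

    def test_bimodal_with_sparse_middle(self):
        config = SyntheticConfig(seed=8, n_promoters=200, n_tes=400,
                                 chromosomes={"chr1": 1_800_000, "chr2": 1_200_000})
        annotation = synthgen.simulate_annotation(config)
        truth = synthgen.make_truth(config, annotation)
        expr = synthgen.simulate_expression(config, truth, annotation)
        te_ids = [t.id for t in annotation.tes]
        values = expr.loc[te_ids].to_numpy().ravel()
        low = (values <= 0.8).mean()
        high = (values > 2.0).mean()
        middle = ((values > 0.8) & (values <= 2.0)).mean()
        assert low > 0.2 and high > 0.2
        assert middle < max(low, high)


class TestSimulateMethylation:
    def test_degenerate_coverage_four_all_undefined(self, small_annotation, small_truth):
        from epistate.exprmeth import region_methylation_table

        config = SyntheticConfig(seed=9, coverage_fixed=4)
        table = synthgen.simulate_methylation(config, small_truth, small_annotation, "GSC")
        results = region_methylation_table(table)
        assert results and all(not r.defined for r in results)

    def test_estimate_concentrates_on_true_mean(self):
        config = SyntheticConfig(
            seed=10, n_promoters=4, n_tes=4, te_length_range=(10_000, 10_001),
            chromosomes={"chr1": 200_000, "chr2": 100_000},
            coverage_fixed=50, cpgs_per_kb=10.0, meth_beta_concentration=1e7,
            meth_mean_occupied=0.9, meth_mean_unoccupied=0.1,
        )
        from epistate.exprmeth import region_methylation_table

        annotation = synthgen.simulate_annotation(config)
        truth = synthgen.make_truth(config, annotation)
        table = synthgen.simulate_methylation(config, truth, annotation, "GSC")
        for result in region_methylation_table(table):
            if result.region_id.startswith("te"):
                assert result.n_cpgs_used >= 90
                true_mean = truth.meth_means["GSC"][result.region_id]
                assert abs(result.mean - true_mean) < 0.05

    def test_deterministic(self, small_synth_config, small_annotation, small_truth):
        t1 = synthgen.simulate_methylation(small_synth_config, small_truth, small_annotation, "PGC")
        t2 = synthgen.simulate_methylation(small_synth_config, small_truth, small_annotation, "PGC")
        assert t1.equals(t2)


class TestSimulateAll:
    def test_emits_round_trippable_files(self, tmp_path, small_synth_config):
        truth = synthgen.simulate_all(small_synth_config, tmp_path)
        promoters = read_regions(tmp_path / "promoters.tsv", format="region-table")
        tes = read_regions(tmp_path / "tes.tsv", format="region-table")
        annotation = synthgen.simulate_annotation(small_synth_config)
        assert [p.id for p in promoters] == [p.id for p in annotation.promoters]
        for a, b in zip(tes, annotation.tes):
            assert (a.start, a.end, a.attrs["te_family"]) == (b.start, b.end, b.attrs["te_family"])
        with open(tmp_path / "truth.json", encoding="utf-8") as handle:
            payload = json.load(handle)
        assert payload["rho"] == small_synth_config.te_gene_rho
        assert set(payload["states"]) == {"GSC", "PGC"}
        assert (tmp_path / "samples.tsv").exists()
        assert (tmp_path / "expression.tsv").exists()

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(te_family_proportions={"SVA": 0.5})
        with pytest.raises(ValueError):
            SyntheticConfig(te_gene_rho=1.5)
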