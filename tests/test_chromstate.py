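import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from epistate import chromstate
from epistate.chromstate import (
    MARKS,
    assign_state,
    assign_states,
    build_occupancy_matrix,
    call_meth_occupancy,
    call_occupancy,
    default_negative_regions,
    family_enrichment,
    signature_label,
    specificity,
    transitions,
)
from epistate.exprmeth import RegionMeth
from epistate.peakrep import PeakCall
from epistate.regionio import Region


def peak(chrom, start, end):
    return PeakCall(chrom, start, end, q=1e-6, p=1e-6)


class TestCallOccupancy:
    def setup_method(self):
        self.regions = [Region(f"r{i}", "chr1", i * 1000, i * 1000 + 500) for i in range(4)]
        self.negatives = [Region(f"n{i}", "chr1", 50_000 + i * 1000, 50_000 + i * 1000 + 500) for i in range(2)]

    def _signal(self, values, neg_values=(2.0, 2.0)):
        ids = [r.id for r in self.regions] + [r.id for r in self.negatives]
        return pd.Series(list(values) + list(neg_values), index=ids)

    def test_peak_and_signal_required(self):
        signal = self._signal([5.0, 1.0, 10.0, 5.0])
        peaks = [peak("chr1", 0, 600), peak("chr1", 1000, 1600), peak("chr1", 3000, 3600)]
        occ = call_occupancy(signal, peaks, self.regions, self.negatives)
        assert occ["r0"]  # peak + signal above negative mean 2.0
        assert not occ["r1"]  # peak but signal 1.0 below threshold
        assert not occ["r2"]  # signal 10 but no peak overlap
        assert occ["r3"]

    def test_empty_negative_set_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            call_occupancy(self._signal([1, 1, 1, 1]), [], self.regions, [])

    def test_brute_force_oracle(self, rng):
        from conftest import random_regions

        regions = random_regions(rng, 800, kind="promoter", prefix="p")
        negatives = random_regions(rng, 200, kind="promoter", prefix="neg")
        peaks = [
            peak(str(rng.choice(["chr1", "chr2"])), int(s), int(s) + int(rng.integers(100, 3000)))
            for s in rng.integers(0, 99_000, size=120)
        ]
        signal = pd.Series(
            rng.gamma(2.0, 2.0, size=1000),
            index=[r.id for r in regions] + [r.id for r in negatives],
        )
        occ = call_occupancy(signal, peaks, regions, negatives)
        threshold = signal.loc[[r.id for r in negatives]].mean()
        for r in regions:
            has_peak = any(
                r.chrom == pk.chrom and r.start < pk.end and pk.start < r.end for pk in peaks
            )
            assert occ[r.id] == (has_peak and signal[r.id] > threshold)

    def test_default_negative_regions(self):
        peaks = [peak("chr1", 0, 600)]
        negatives = default_negative_regions(self.regions, peaks)
        assert [r.id for r in negatives] == ["r1", "r2", "r3"]


class TestMethOccupancy:
    def test_above_threshold(self):
        occ = call_meth_occupancy([RegionMeth("a", 0.8, 5)], threshold=0.5)
        assert occ["a"]

    def test_boundary_is_occupied(self):
        occ = call_meth_occupancy([RegionMeth("a", 0.5, 3)], threshold=0.5)
        assert occ["a"]

    def test_undefined_not_occupied(self):
        occ = call_meth_occupancy([RegionMeth("a", None, 0)])
        assert not occ["a"]

    def test_threshold_validation(self):
        with pytest.raises(ValueError):
            call_meth_occupancy([], threshold=1.5)


class TestAssignState:
    def test_repressive_signature_reported_exactly(self):
        state = assign_state({"H3K9me3": True, "5mC": True}, "r")
        assert state.category == "repressive"
        assert state.repressive == frozenset({"H3K9me3", "5mC"})
        assert state.repressive_signature == "5mC+H3K9me3"

    def test_bivalent(self):
        state = assign_state({"H3K27me3": True, "H3K4me3": True}, "r")
        assert state.category == "bivalent"

    def test_all_false_neutral(self):
        state = assign_state({}, "r")
        assert state.category == "neutral"
        assert state.repressive_signature == "none"

    def test_h3k4me1_alone_stays_neutral(self):
        state = assign_state({"H3K4me1": True}, "r")
        assert state.category == "neutral"
        assert state.h3k4me1

    def test_active(self):
        assert assign_state({"H3K27ac": True}, "r").category == "active"

    @given(st.lists(st.booleans(), min_size=8, max_size=8))
    def test_categories_partition(self, row):
        occ = dict(zip(MARKS, row))
        state = assign_state(occ, "r")
        assert state.category in {"repressive", "bivalent", "active", "neutral"}
        assert (state.category == "bivalent") == (bool(state.repressive) and bool(state.active))
        if not state.repressive and not state.active:
            assert state.category == "neutral"


class TestSpecificity:
    def _occ(self, rows):
        return pd.DataFrame(rows, index=[f"r{i}" for i in range(len(rows))], columns=["H3K9me3"])

    def test_labels(self):
        occ_a = self._occ([[True], [False], [True], [False]])
        occ_b = self._occ([[False], [True], [True], [False]])
        labels = specificity(occ_a, occ_b)["H3K9me3"]
        assert list(labels) == ["A-specific", "B-specific", "shared", "neither"]

    def test_partition_counts(self, rng):
        occ_a = pd.DataFrame(rng.random((100, 3)) < 0.4, columns=["a", "b", "c"])
        occ_b = pd.DataFrame(rng.random((100, 3)) < 0.4, columns=["a", "b", "c"])
        labels = specificity(occ_a, occ_b)
        for mark in labels.columns:
            assert labels[mark].value_counts().sum() == 100

    def test_mismatched_regions_rejected(self):
        occ_a = self._occ([[True]])
        occ_b = pd.DataFrame([[True]], index=["other"], columns=["H3K9me3"])
        with pytest.raises(ValueError):
            specificity(occ_a, occ_b)


class TestTransitions:
    def _states(self, spec):
        occ = pd.DataFrame(
            {m: [m in marks for marks in spec.values()] for m in MARKS},
            index=list(spec),
        )
        return assign_states(occ)

    def test_single_flow(self):
        ids = [f"r{i}" for i in range(10)]
        states_a = self._states({i: {"5mC"} for i in ids})
        states_b = self._states({i: set() for i in ids})
        table = transitions(states_a, states_b)
        assert table.counts.loc["5mC", "none"] == 10
        assert table.n_regions == 10

    def test_total_conservation(self, rng):
        ids = [f"r{i}" for i in range(200)]
        marks = ["5mC", "H3K9me3", "H3K27me3"]
        spec_a = {i: {m for m in marks if rng.random() < 0.4} for i in ids}
        spec_b = {i: {m for m in marks if rng.random() < 0.4} for i in ids}
        table = transitions(self._states(spec_a), self._states(spec_b))
        assert table.counts.to_numpy().sum() == 200

    def test_dictionary_counting_oracle(self, rng):
        ids = [f"r{i}" for i in range(150)]
        choices = [set(), {"5mC"}, {"H3K9me3"}, {"5mC", "H3K9me3"}]
        spec_a = {i: choices[rng.integers(0, 4)] for i in ids}
        spec_b = {i: choices[rng.integers(0, 4)] for i in ids}
        table = transitions(self._states(spec_a), self._states(spec_b))
        expected = {}
        for i in ids:
            key = (signature_label(spec_a[i]), signature_label(spec_b[i]))
            expected[key] = expected.get(key, 0) + 1
        for (sig_a, sig_b), count in expected.items():
            assert table.counts.loc[sig_a, sig_b] == count

    def test_de_novo_count(self):
        states_a = self._states({"r1": set(), "r2": set(), "r3": {"5mC"}})
        states_b = self._states({"r1": {"H3K9me3"}, "r2": set(), "r3": {"5mC"}})
        assert transitions(states_a, states_b).de_novo_count() == 1

    def test_id_mismatch_rejected(self):
        states_a = self._states({"r1": set()})
        states_b = self._states({"r2": set()})
        with pytest.raises(ValueError):
            transitions(states_a, states_b)


def te(i, family):
    return Region(f"te{i}", "chr1", i * 100, i * 100 + 50, kind="te", attrs={"te_family": family})


class TestFamilyEnrichment:
    def test_five_fold(self):
        background = [te(i, "SVA") for i in range(10)] + [te(100 + i, "L2") for i in range(90)]
        subgroup = [te(i, "SVA") for i in range(10)] + [te(100 + i, "L2") for i in range(10)]
        results, effect = family_enrichment(subgroup, background)
        by_family = {r.family: r for r in results}
        assert math.isclose(by_family["SVA"].enrichment_rate, 5.0)

    def test_identity(self):
        background = [te(i, "SVA") for i in range(5)] + [te(10 + i, "L2") for i in range(5)]
        results, effect = family_enrichment(background, background)
        assert all(math.isclose(r.enrichment_rate, 1.0) for r in results)
        assert effect.value == 0.0

    def test_two_family_hand_computation(self):
        background = [te(i, "SVA") for i in range(20)] + [te(100 + i, "L2") for i in range(80)]
        subgroup = [te(i, "SVA") for i in range(15)] + [te(100 + i, "L2") for i in range(15)]
        results, effect = family_enrichment(subgroup, background)
        by_family = {r.family: r for r in results}
        # expected SVA = 30 * 20/100 = 6; rate = 15/6 = 2.5
        assert math.isclose(by_family["SVA"].expected, 6.0)
        assert math.isclose(by_family["SVA"].enrichment_rate, 2.5)
        # chi2 = (15-6)^2/6 + (15-24)^2/24 = 13.5 + 3.375; w = sqrt(chi2/30)
        assert math.isclose(effect.value, math.sqrt((13.5 + 3.375) / 30))

    def test_subgroup_must_be_subset(self):
        background = [te(0, "SVA")]
        with pytest.raises(ValueError):
            family_enrichment([te(99, "L2")], background)


class TestOccupancyMatrix:
    def test_build_and_assign(self, rng):
        per_mark = {
            m: pd.Series(rng.random(50) < 0.3, index=[f"r{i}" for i in range(50)]) for m in MARKS
        }
        occ = build_occupancy_matrix(per_mark)
        states = assign_states(occ)
        counts = pd.Series([s.category for s in states]).value_counts()
        assert counts.sum() == 50
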