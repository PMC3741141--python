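import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phenoarc import (
    DataValueError,
    PhenoDataset,
    ProminenceProfile,
    ThresholdSpec,
    UnknownEntityError,
    build_mask,
    derive_cooccurrence,
    derive_prominence,
    derive_transitions,
    filter_connections,
    pair_specific_genes,
    quartile_thresholds,
)
from phenoarc.events import Connection, ConnectionSet, EventMask

import oracles
from conftest import random_dataset, random_mask


class TestBuildMask:
    def test_default_thresholds_pass_everything_observed(self, tiny_dataset):
        mask = build_mask(tiny_dataset)
        assert mask.array.all()

    def test_interval_inclusive_both_ends(self):
        ds = PhenoDataset(
            ["g"], ["A"], 2, {("g", "A"): np.array([0.4, 0.6])}
        )
        mask = build_mask(ds, ThresholdSpec({"A": (0.5, 1.0)}))
        assert mask.array[0, 0].tolist() == [False, True]
        # boundary values pass
        edge = build_mask(ds, ThresholdSpec({"A": (0.4, 0.6)}))
        assert edge.array.all()

    def test_missing_never_passes(self):
        ds = PhenoDataset(["g"], ["A"], 2, {("g", "A"): np.array([np.nan, 1.0])})
        assert build_mask(ds).array[0, 0].tolist() == [False, True]

    def test_unknown_phenotype_threshold(self, tiny_dataset):
        with pytest.raises(UnknownEntityError):
            build_mask(tiny_dataset, ThresholdSpec({"Z": (0, 1)}))

    def test_inverted_interval_rejected(self):
        with pytest.raises(DataValueError):
            ThresholdSpec({"A": (1.0, 0.0)})


class TestQuartileThresholds:
    def test_lower_q1_of_1_to_8(self):
        # sort-based oracle: rank 0.25 * 7 = 1.75 -> 2 + 0.75 * 1 = 2.75
        ds = PhenoDataset(
            ["g1", "g2"],
            ["A"],
            4,
            {
                ("g1", "A"): np.array([1.0, 2.0, 3.0, 4.0]),
                ("g2", "A"): np.array([5.0, 6.0, 7.0, 8.0]),
            },
        )
        spec = quartile_thresholds(ds, "lower")
        lo, hi = spec.interval("A")
        assert lo == -np.inf
        assert hi == pytest.approx(2.75)
        assert hi == pytest.approx(oracles.quartile(range(1, 9), 0.25))

    def test_constant_values_admit_everything_both_sides(self):
        ds = PhenoDataset(["g"], ["A"], 3, {("g", "A"): np.full(3, 2.5)})
        for side in ("lower", "upper"):
            mask = build_mask(ds, quartile_thresholds(ds, side))
            assert mask.array.all()

    def test_single_observation_boundary(self):
        ds = PhenoDataset(
            ["g"], ["A"], 2, {("g", "A"): np.array([3.0, np.nan])}
        )
        assert quartile_thresholds(ds, "lower").interval("A")[1] == 3.0
        assert quartile_thresholds(ds, "upper").interval("A")[0] == 3.0

    def test_no_observations_rejected(self):
        ds = PhenoDataset(["g"], ["A"], 2, {("g", "A"): np.array([np.nan] * 2)})
        with pytest.raises(DataValueError):
            quartile_thresholds(ds, "lower")

    def test_bad_side(self, tiny_dataset):
        with pytest.raises(DataValueError):
            quartile_thresholds(tiny_dataset, "middle")

    @pytest.mark.parametrize("seed", range(10))
    def test_lower_pass_fraction_minimal_above_quarter(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_genes=8, n_phenotypes=2, n_timepoints=5)
        spec = quartile_thresholds(ds, "lower")
        arr = ds.to_array()
        for j, p in enumerate(ds.phenotypes):
            pooled = np.sort(arr[:, j, :].ravel())
            hi = spec.interval(p)[1]
            frac = np.mean(pooled <= hi)
            assert frac >= 0.25
            # minimal among observed cutoffs admitting >= 25%
            admissible = [v for v in pooled if np.mean(pooled <= v) >= 0.25]
            assert np.sum(pooled <= hi) <= np.sum(pooled <= min(admissible))


class TestCooccurrence:
    def test_single_gene_lag1(self):
        arr = np.zeros((1, 2, 3), dtype=bool)
        arr[0, 0, 1] = True  # A at t=1
        arr[0, 1, 2] = True  # B at t=2
        mask = EventMask(["g"], ["A", "B"], arr)
        conns = derive_cooccurrence(mask, {1})
        assert len(conns) == 1
        rec = conns.records[0]
        assert (rec.source, rec.target, rec.t_source, rec.t_target) == ("A", "B", 1, 2)
        assert rec.genes == {"g"} and rec.weight == 1 and rec.directed

    def test_three_genes_aggregate_weight(self):
        arr = np.zeros((3, 2, 3), dtype=bool)
        arr[:, 0, 1] = True
        arr[:, 1, 2] = True
        mask = EventMask(["g1", "g2", "g3"], ["A", "B"], arr)
        conns = derive_cooccurrence(mask, {1})
        assert len(conns) == 1
        assert conns.records[0].weight == 3

    def test_all_true_mask_full_interconnection(self):
        # gating off => every unordered pair at every time (lag 0)
        n_t, P = 4, 3
        mask = EventMask(
            ["g"], [f"P{i}" for i in range(P)], np.ones((1, P, n_t), dtype=bool)
        )
        conns = derive_cooccurrence(mask, {0})
        assert len(conns) == n_t * P * (P - 1) // 2
        assert all(not r.directed and r.source < r.target for r in conns)

    def test_lag_out_of_range(self):
        mask = EventMask(["g"], ["A", "B"], np.ones((1, 2, 3), dtype=bool))
        with pytest.raises(DataValueError):
            derive_cooccurrence(mask, {3})

    @pytest.mark.parametrize("seed", range(5))
    def test_weights_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        mask = random_mask(rng)
        conns = derive_cooccurrence(mask, {0, 1, 3})
        expected = oracles.cooccurrence_counts(mask.array, {0, 1, 3})
        got = {
            (
                mask.phenotypes.index(r.source),
                mask.phenotypes.index(r.target),
                r.t_source,
                r.t_target,
            ): {mask.genes.index(g) for g in r.genes}
            for r in conns
        }
        assert got == expected

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_tightening_thresholds_never_raises_weights(self, seed):
        rng = np.random.default_rng(seed)
        ds = random_dataset(rng, n_genes=5, n_phenotypes=3, n_timepoints=4)
        wide = ThresholdSpec({p: (-1.0, 1.0) for p in ds.phenotypes})
        tight = ThresholdSpec({p: (-0.5, 0.5) for p in ds.phenotypes})
        w_wide = {
            (r.source, r.target, r.t_source, r.t_target): r.weight
            for r in derive_cooccurrence(build_mask(ds, wide), {0, 1})
        }
        for r in derive_cooccurrence(build_mask(ds, tight), {0, 1}):
            key = (r.source, r.target, r.t_source, r.t_target)
            assert r.weight <= w_wide.get(key, 0)


class TestProminence:
    def test_argmax(self, tiny_dataset):
        prof = derive_prominence(tiny_dataset)
        assert prof.entries["g1"] == ("A", "A", "B")
        assert prof.entries["g2"] == ("A", "B", "B")

    def test_tie_broken_by_input_order(self):
        ds = PhenoDataset(
            ["g"], ["A", "B"], 1,
            {("g", "A"): np.array([0.5]), ("g", "B"): np.array([0.5])},
        )
        assert derive_prominence(ds).entries["g"] == ("A",)

    def test_none_when_nothing_passes(self):
        ds = PhenoDataset(
            ["g"], ["A", "B"], 1,
            {("g", "A"): np.array([0.1]), ("g", "B"): np.array([0.2])},
        )
        spec = ThresholdSpec({"A": (0.5, 1.0), "B": (0.5, 1.0)})
        assert derive_prominence(ds, spec).entries["g"] == (None,)

    def test_all_missing_gives_none(self):
        ds = PhenoDataset(["g"], ["A"], 1, {("g", "A"): np.array([np.nan])})
        assert derive_prominence(ds).entries["g"] == (None,)


class TestTransitions:
    def _profile(self, entries):
        phen = sorted({p for seq in entries.values() for p in seq if p})
        return ProminenceProfile(list(entries), phen, entries)

    def test_simple_switch(self):
        conns = derive_transitions(self._profile({"g": ("A", "A", "B")}))
        assert [(r.source, r.target, r.t_source, r.t_target) for r in conns] == [
            ("A", "B", 1, 2)
        ]
        assert conns.records[0].directed

    def test_gap_breaks_chain(self):
        conns = derive_transitions(self._profile({"g": ("A", None, "B")}))
        assert len(conns) == 0

    def test_no_self_transitions_by_default(self):
        conns = derive_transitions(self._profile({"g": ("A", "A", "A")}))
        assert len(conns) == 0
        with_self = derive_transitions(
            self._profile({"g": ("A", "A", "A")}), include_self=True
        )
        assert len(with_self) == 2

    def test_five_synchronized_genes_weight_five(self):
        entries = {f"g{i}": ("A", "A", "A", "A", "B") for i in range(5)}
        conns = derive_transitions(self._profile(entries))
        assert len(conns) == 1
        assert conns.records[0].weight == 5
        assert (conns.records[0].t_source, conns.records[0].t_target) == (3, 4)

    def test_only_consecutive_unit_lags(self):
        entries = {"g": ("A", "B", "C", "A")}
        for r in derive_transitions(self._profile(entries)):
            assert r.t_target - r.t_source == 1
            assert r.source != r.target


class TestFilterConnections:
    @pytest.fixture
    def conns(self):
        return ConnectionSet(
            [
                Connection("A", "B", 0, 1, frozenset({"g1", "g2"}), True),
                Connection("B", "C", 1, 3, frozenset({"g2"}), True),
                Connection("A", "C", 2, 2, frozenset({"g3"}), False),
            ],
            ["A", "B", "C"],
            4,
            genes_universe=frozenset({"g1", "g2", "g3"}),
        )

    def test_phenotype_touch_semantics(self, conns):
        kept = filter_connections(conns, phenotype_subset={"C"})
        assert {(r.source, r.target) for r in kept} == {("B", "C"), ("A", "C")}

    def test_disjoint_gene_subset_empties(self, conns):
        assert len(filter_connections(conns, gene_subset={"g3"})) == 1

    def test_gene_subset_intersects(self, conns):
        kept = filter_connections(conns, gene_subset={"g1"})
        assert len(kept) == 1 and kept.records[0].genes == {"g1"}

    def test_max_lag(self, conns):
        kept = filter_connections(conns, max_lag=1)
        assert all(r.lag <= 1 for r in kept) and len(kept) == 2

    def test_time_window(self, conns):
        kept = filter_connections(conns, time_window=(1, 3))
        assert {(r.t_source, r.t_target) for r in kept} == {(1, 3), (2, 2)}

    def test_unknown_entities_rejected(self, conns):
        with pytest.raises(UnknownEntityError):
            filter_connections(conns, gene_subset={"nope"})
        with pytest.raises(UnknownEntityError):
            filter_connections(conns, phenotype_subset={"Z"})


class TestPairSpecificGenes:
    def _set(self, mapping):
        records = [
            Connection(*sorted(pair), 0, 0, frozenset(genes), False)
            for pair, genes in mapping.items()
        ]
        phen = sorted({p for pair in mapping for p in pair})
        return ConnectionSet(records, phen, 1)

    def test_set_difference(self):
        spec = pair_specific_genes(
            self._set({("A", "B"): {"g1", "g2"}, ("A", "C"): {"g2"}})
        )
        assert spec[("A", "B")] == {"g1"}
        assert spec[("A", "C")] == set()

    def test_single_pair_all_specific(self):
        spec = pair_specific_genes(self._set({("A", "B"): {"g1", "g2"}}))
        assert spec[("A", "B")] == {"g1", "g2"}

    def test_identical_sets_nothing_specific(self):
        spec = pair_specific_genes(
            self._set({("A", "B"): {"g1"}, ("A", "C"): {"g1"}})
        )
        assert spec[("A", "B")] == set() == spec[("A", "C")]
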