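import copy
import math

import numpy as np
import pytest

from admeseq.chem_data import (
    AggregatedDataset,
    EndpointSpec,
    MoleculeRecord,
    SmilesParseError,
    aggregate_endpoints,
    canonicalize_key,
    fit_and_apply_normalization,
    hash_kfold,
    read_dataset,
    stratified_kfold,
    write_dataset,
)


class TestCanonicalize:
    def test_same_molecule_same_key(self):
        assert canonicalize_key("OCC") == canonicalize_key("CCO")

    def test_idempotent(self):
        key = canonicalize_key("c1ccccc1O")
        assert canonicalize_key(key) == key

    @pytest.mark.parametrize("bad", ["not_a_smiles", "C(((", ""])
    def test_parse_error(self, bad):
        with pytest.raises(SmilesParseError):
            canonicalize_key(bad)

    def test_opaque_mode_passes_through(self):
        assert canonicalize_key("not_a_smiles", opaque=True) == "not_a_smiles"


class TestAggregate:
    def test_two_endpoint_merge(self, toy_specs):
        tables = {"e1": [("CCO", 1.0), ("CCN", 0.0)], "e2": [("CCO", 2.5)]}
        ds = aggregate_endpoints(tables, toy_specs)
        assert len(ds.records) == 2
        by_key = {r.key: r for r in ds.records}
        cco, ccn = by_key[canonicalize_key("CCO")], by_key[canonicalize_key("CCN")]
        assert cco.mask == {"e1": True, "e2": True}
        assert cco.labels == {"e1": 1.0, "e2": 2.5}
        assert ccn.mask == {"e1": True, "e2": False}
        assert "e2" not in ccn.labels

    def test_disjoint_sets_are_additive(self, toy_specs):
        tables = {
            "e1": [("CCO", 1.0), ("CCN", 0.0), ("CCC", 1.0)],
            "e2": [("CCCl", 0.5), ("CCBr", 1.5)],
        }
        ds = aggregate_endpoints(tables, toy_specs)
        assert len(ds.records) == 5

    def test_same_canonical_key_merges(self, toy_specs):
        ds = aggregate_endpoints({"e1": [("CCO", 1.0), ("OCC", 1.0)]}, toy_specs[:1])
        assert len(ds.records) == 1
        assert ds.records[0].labels["e1"] == 1.0

    def test_classification_majority_vote_and_tie_drop(self, toy_specs):
        tables = {"e1": [("CCO", 1.0), ("OCC", 1.0), ("CCO", 0.0),
                         ("CCN", 1.0), ("NCC", 0.0)]}
        ds = aggregate_endpoints(tables, toy_specs[:1])
        by_key = {r.key: r for r in ds.records}
        assert by_key[canonicalize_key("CCO")].labels["e1"] == 1.0  # 2-1 vote
        tied = by_key[canonicalize_key("CCN")]
        assert tied.mask["e1"] is False and "e1" not in tied.labels

    def test_regression_duplicates_averaged(self, toy_specs):
        ds = aggregate_endpoints(
            {"e2": [("CCO", 1.0), ("OCC", 2.0)]}, [toy_specs[1]]
        )
        assert ds.records[0].labels["e2"] == pytest.approx(1.5)

    def test_strict_mode_raises_on_conflict(self, toy_specs):
        with pytest.raises(ValueError, match="conflicting"):
            aggregate_endpoints(
                {"e2": [("CCO", 1.0), ("OCC", 2.0)]},
                [toy_specs[1]],
                duplicate_policy="strict",
            )

    def test_empty_tables_error(self, toy_specs):
        with pytest.raises(ValueError, match="empty"):
            aggregate_endpoints({}, toy_specs)

    def test_parse_error_names_row(self, toy_specs):
        with pytest.raises(SmilesParseError, match="e1.*row 1"):
            aggregate_endpoints({"e1": [("CCO", 1.0), ("xxx(", 0.0)]}, toy_specs)

    def test_aggregation_conserves_observed_entries(self, toy_specs):
        # without duplicates, observed cells == input rows; no mask without value
        rng = np.random.default_rng(0)
        mols = ["C" * (i + 1) for i in range(20)]
        tables = {
            "e1": [(m, float(rng.integers(2))) for m in mols[:15]],
            "e2": [(m, float(rng.normal())) for m in mols[5:]],
        }
        ds = aggregate_endpoints(tables, toy_specs)
        observed = sum(sum(r.mask.values()) for r in ds.records)
        assert observed == 15 + 15
        for r in ds.records:
            assert set(r.labels) == {e for e, on in r.mask.items() if on}


class TestNormalization:
    def _dataset(self, values, keys=None):
        keys = keys or [f"k{i}" for i in range(len(values))]
        spec = EndpointSpec(name="r", category="A", task_type="regression")
        records = [
            MoleculeRecord(key=k, labels={"r": v}, mask={"r": True})
            for k, v in zip(keys, values)
        ]
        return AggregatedDataset(records=records, endpoints=[spec])

    def test_three_point_population_zscore(self):
        ds = self._dataset([1.0, 2.0, 3.0])
        out = fit_and_apply_normalization(ds, {"k0", "k1", "k2"})
        got = [r.labels["r"] for r in out.records]
        expected = math.sqrt(3.0 / 2.0)  # population sd of {1,2,3} is sqrt(2/3)
        assert got == pytest.approx([-expected, 0.0, expected], abs=1e-12)
        assert np.mean(got) == pytest.approx(0.0, abs=1e-9)
        assert np.std(got) == pytest.approx(1.0, abs=1e-9)

    def test_already_standardized_is_fixed_point(self):
        vals = [-math.sqrt(1.5), 0.0, math.sqrt(1.5)]
        out = fit_and_apply_normalization(self._dataset(vals), {"k0", "k1", "k2"})
        assert [r.labels["r"] for r in out.records] == pytest.approx(vals, abs=1e-12)

    def test_held_out_at_train_mean_maps_to_zero(self):
        ds = self._dataset([1.0, 3.0, 2.0], keys=["a", "b", "held"])
        out = fit_and_apply_normalization(ds, {"a", "b"})
        held = next(r for r in out.records if r.key == "held")
        assert held.labels["r"] == pytest.approx(0.0, abs=1e-12)

    def test_zero_spread_names_endpoint(self):
        with pytest.raises(ValueError, match="'r'.*zero spread|zero spread"):
            fit_and_apply_normalization(self._dataset([2.0, 2.0]), {"k0", "k1"})

    def test_fit_never_reads_held_out_values(self):
        ds = self._dataset([1.0, 2.0, 3.0, 5.0], keys=["a", "b", "c", "h"])
        poisoned = copy.deepcopy(ds)
        poisoned.records[3].labels["r"] = 1e9
        stats = fit_and_apply_normalization(ds, {"a", "b", "c"}).endpoints[0]
        stats_p = fit_and_apply_normalization(poisoned, {"a", "b", "c"}).endpoints[0]
        assert (stats.norm_mean, stats.norm_sd) == (stats_p.norm_mean, stats_p.norm_sd)

    def test_input_not_mutated(self):
        ds = self._dataset([1.0, 2.0, 3.0])
        fit_and_apply_normalization(ds, {"k0", "k1", "k2"})
        assert [r.labels["r"] for r in ds.records] == [1.0, 2.0, 3.0]


class TestFolds:
    def _binary_dataset(self, n, n_pos):
        spec = EndpointSpec(name="y", category="A", task_type="classification")
        records = [
            MoleculeRecord(
                key=f"k{i}", labels={"y": float(i < n_pos)}, mask={"y": True}
            )
            for i in range(n)
        ]
        return AggregatedDataset(records=records, endpoints=[spec])

    def test_small_stratified_split(self):
        ds = self._binary_dataset(10, 2)
        folds = stratified_kfold(ds, 2, "y", seed=0)
        assert set(folds.values()) == {0, 1}
        for f in (0, 1):
            members = [k for k, v in folds.items() if v == f]
            positives = sum(1 for k in members if int(k[1:]) < 2)
            assert len(members) == 5 and positives == 1

    @pytest.mark.parametrize("n,n_pos,k", [(40, 12, 5), (33, 5, 3), (50, 25, 5)])
    def test_positive_counts_near_proportional(self, n, n_pos, k):
        ds = self._binary_dataset(n, n_pos)
        folds = stratified_kfold(ds, k, "y", seed=3)
        share = n_pos / k
        for f in range(k):
            pos = sum(1 for key, v in folds.items() if v == f and int(key[1:]) < n_pos)
            assert abs(pos - share) < 1.0

    def test_deterministic_under_seed(self):
        ds = self._binary_dataset(30, 10)
        assert stratified_kfold(ds, 5, "y", 7) == stratified_kfold(ds, 5, "y", 7)
        assert stratified_kfold(ds, 5, "y", 7) != stratified_kfold(ds, 5, "y", 8)

    def test_single_class_falls_back_to_plain_kfold(self):
        ds = self._binary_dataset(12, 12)
        folds = stratified_kfold(ds, 4, "y", seed=0)
        sizes = [list(folds.values()).count(f) for f in range(4)]
        assert sizes == [3, 3, 3, 3]

    def test_k_exceeding_minority_count_errors(self):
        with pytest.raises(ValueError, match="minority"):
            stratified_kfold(self._binary_dataset(10, 2), 5, "y", seed=0)

    def test_hash_kfold_deterministic_and_total(self):
        ds = self._binary_dataset(50, 20)
        folds = hash_kfold(ds, 5, seed=1)
        assert folds == hash_kfold(ds, 5, seed=1)
        assert set(folds) == set(ds.keys)
        assert set(folds.values()) <= set(range(5))


class TestRoundTrip:
    def test_write_read_write_is_exact_and_byte_stable(self, tmp_path, toy_specs):
        tables = {
            "e1": [("CCO", 1.0), ("CCN", 0.0), ("CCC", 1.0)],
            "e2": [("CCO", 2.5), ("CCC", -0.1234567890123456)],
        }
        ds = aggregate_endpoints(tables, toy_specs)
        ds = fit_and_apply_normalization(ds, set(ds.keys))
        ds.folds = hash_kfold(ds, 3, seed=0)
        t1, m1 = tmp_path / "t1.csv", tmp_path / "m1.yaml"
        write_dataset(ds, t1, m1)
        back = read_dataset(t1, m1)
        assert back.folds == ds.folds
        assert [r.key for r in back.records] == [r.key for r in ds.records]
        for a, b in zip(ds.records, back.records):
            assert a.labels == b.labels and a.mask == b.mask
        t2, m2 = tmp_path / "t2.csv", tmp_path / "m2.yaml"
        write_dataset(back, t2, m2)
        assert t1.read_bytes() == t2.read_bytes()
        assert m1.read_bytes() == m2.read_bytes()
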