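import copy
import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admeseq.chem_data import EndpointSpec
from admeseq.encoders import EncoderModel, params_hash
from admeseq.presets import SMALL_ENCODER
from admeseq.seq_mtl import (
    LossLedger,
    TrainConfig,
    masked_losses,
    pcgrad_project,
    single_category_config,
    train_naive,
    train_sequential,
    validation_split,
)

FAST = dict(epochs_max=3, batch_size=64, learning_rate=1e-3)


class TestMaskedLosses:
    SPECS = [
        EndpointSpec(name="c", category="A", task_type="classification"),
        EndpointSpec(name="r", category="D", task_type="regression"),
    ]

    def test_perfect_classification_near_zero(self):
        per, total = masked_losses(
            {"c": np.array([1.0, 0.0, 1.0])},
            {"c": np.array([1.0, 0.0, 1.0])},
            {"c": np.ones(3, dtype=bool)},
            self.SPECS,
        )
        assert per["c"] == pytest.approx(0.0, abs=1e-6)
        assert total == per["c"]

    def test_masked_flip_leaves_loss_bit_identical(self):
        preds = {"c": np.array([0.7, 0.3, 0.9])}
        mask = {"c": np.array([True, False, True])}
        base = masked_losses(preds, {"c": np.array([1.0, 0.0, 1.0])}, mask, self.SPECS)
        flipped = masked_losses(preds, {"c": np.array([1.0, 1.0, 1.0])}, mask, self.SPECS)
        assert base == flipped

    def test_two_squared_errors_mean(self):
        per, _ = masked_losses(
            {"r": np.array([0.5, -0.5])},
            {"r": np.array([0.0, 0.0])},
            {"r": np.ones(2, dtype=bool)},
            self.SPECS,
        )
        assert per["r"] == pytest.approx(0.25)

    def test_total_is_unweighted_mean_over_contributing_endpoints(self):
        per, total = masked_losses(
            {"c": np.array([0.5]), "r": np.array([1.0])},
            {"c": np.array([1.0]), "r": np.array([0.0])},
            {"c": np.array([True]), "r": np.array([True])},
            self.SPECS,
        )
        assert total == pytest.approx((per["c"] + per["r"]) / 2)

    def test_all_masked_is_flagged_noop(self):
        per, total = masked_losses(
            {"c": np.array([0.5])},
            {"c": np.array([1.0])},
            {"c": np.array([False])},
            self.SPECS,
        )
        assert per == {} and total is None


class TestPCGrad:
    def test_worked_conflicting_pair(self):
        g1, g2 = np.array([1.0, 0.0]), np.array([-1.0, 1.0])
        # g1 projected onto g2's normal plane: (0.5, 0.5); g2 has no conflict
        # partner left raw, so the sum is (0.5,0.5) + g2' where g2' is g2
        # projected against raw g1: g2 - (-1/1) g1 = (0,1); total (0.5, 1.5)
        out = pcgrad_project([g1, g2], seed=0)
        proj_g1 = g1 - (g1 @ g2) / (g2 @ g2) * g2
        np.testing.assert_allclose(proj_g1, [0.5, 0.5])
        assert abs(proj_g1 @ g2) < 1e-12
        proj_g2 = g2 - (g2 @ g1) / (g1 @ g1) * g1
        np.testing.assert_allclose(out, proj_g1 + proj_g2)

    def test_no_conflict_is_exact_sum(self):
        g1, g2 = np.array([1.0, 0.0]), np.array([0.0, 1.0])
        np.testing.assert_array_equal(pcgrad_project([g1, g2], seed=0), [1.0, 1.0])

    def test_single_gradient_identity(self):
        g = np.array([0.3, -0.2, 7.0])
        np.testing.assert_array_equal(pcgrad_project([g], seed=0), g)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_two_vector_orthogonality_property(self, seed):
        rng = np.random.default_rng(seed)
        g1, g2 = rng.normal(size=5), rng.normal(size=5)
        if g1 @ g2 >= 0:
            g2 = -g2 - g1 * 1e-3  # force a conflict
        if g1 @ g2 >= 0:
            return
        proj = g1 - (g1 @ g2) / (g2 @ g2) * g2
        assert abs(proj @ g2) < 1e-6 * np.linalg.norm(proj) * np.linalg.norm(g2) + 1e-9

    def test_zero_norm_partner_skipped(self):
        g1, g2 = np.array([1.0, 0.0]), np.array([0.0, 0.0])
        out = pcgrad_project([g1, g2], seed=0)
        np.testing.assert_array_equal(out, g1)

    def test_mismatched_lengths_error(self):
        with pytest.raises(ValueError):
            pcgrad_project([np.ones(2), np.ones(3)], seed=0)


class TestValidationSplit:
    def test_deterministic_and_disjoint(self):
        keys = [f"k{i}" for i in range(200)]
        tr1, va1 = validation_split(keys, seed=4)
        tr2, va2 = validation_split(keys, seed=4)
        np.testing.assert_array_equal(tr1, tr2)
        np.testing.assert_array_equal(va1, va2)
        assert set(tr1).isdisjoint(va1)
        assert len(tr1) + len(va1) == 200
        assert 0.03 < len(va1) / 200 < 0.2


def _fresh_model(dataset, seed=3):
    return EncoderModel(dataset.endpoints, SMALL_ENCODER, seed=seed)


class TestTraining:
    def test_seed_determinism(self, synth_small):
        dataset, _ = synth_small
        cfg = TrainConfig(mode="sequential", seed=9, **FAST)
        _, ledger1 = train_sequential(_fresh_model(dataset), dataset, cfg)
        _, ledger2 = train_sequential(_fresh_model(dataset), dataset, cfg)
        assert ledger1 == ledger2

    def test_reduction_sequential_one_category_equals_naive(self, synth_small):
        dataset, _ = synth_small
        seq_cfg = TrainConfig(
            mode="sequential", order=("M",), pcgrad=False, seed=5, **FAST
        )
        m1, l1 = train_sequential(_fresh_model(dataset), dataset, seq_cfg)
        naive_cfg = single_category_config(TrainConfig(seed=5, **FAST), "M")
        m2, l2 = train_naive(_fresh_model(dataset), dataset, naive_cfg)
        assert l1 == l2
        assert params_hash(m1) == params_hash(m2)

    def test_masked_label_invariance_through_training(self, synth_small):
        dataset, _ = synth_small
        poisoned = copy.deepcopy(dataset)
        n_poisoned = 0
        for rec in poisoned.records:
            for name, observed in rec.mask.items():
                if not observed:
                    rec.labels[name] = 1e6  # placeholder must be ignored
                    n_poisoned += 1
        assert n_poisoned > 0
        cfg = TrainConfig(mode="sequential", seed=2, epochs_max=1, batch_size=64)
        m1, l1 = train_sequential(_fresh_model(dataset), dataset, cfg)
        m2, l2 = train_sequential(_fresh_model(poisoned), poisoned, cfg)
        assert l1 == l2
        assert params_hash(m1) == params_hash(m2)

    def test_ledger_total_is_mean_of_endpoint_val_losses(self, synth_small):
        dataset, _ = synth_small
        cfg = TrainConfig(mode="naive", seed=1, **FAST)
        _, ledger = train_naive(_fresh_model(dataset), dataset, cfg)
        for epoch, total in ledger.total_val.items():
            vals = list(ledger.val_at(epoch).values())
            assert total == pytest.approx(np.mean(vals), abs=1e-9)

    def test_reverse_order_changes_visit_sequence(self, synth_small):
        dataset, _ = synth_small
        fwd = TrainConfig(mode="sequential", order=tuple("ADME"), seed=1, **FAST)
        rev = TrainConfig(mode="sequential", order=tuple("EMDA"), seed=1, **FAST)
        _, lf = train_sequential(_fresh_model(dataset), dataset, fwd)
        _, lr = train_sequential(_fresh_model(dataset), dataset, rev)
        groups_f = {g for (_, g, _) in lf.train}
        groups_r = {g for (_, g, _) in lr.train}
        assert groups_f == groups_r == set("ADME")
        assert lf != lr  # different visit order leaves a different ledger

    def test_subset_single_category_is_stl_source(self, synth_small):
        dataset, _ = synth_small
        cfg = TrainConfig(
            mode="subset", subset_categories=frozenset({"A"}), seed=1, **FAST
        )
        _, ledger = train_naive(_fresh_model(dataset), dataset, cfg)
        assert {ep for (_, _, ep) in ledger.train} == {
            s.name for s in dataset.endpoints if s.category == "A"
        }

    def test_empty_subset_rejected(self):
        with pytest.raises(ValueError, match="subset"):
            TrainConfig(mode="subset", subset_categories=frozenset())

    def test_category_without_data_errors(self, synth_small):
        dataset, _ = synth_small
        stripped = copy.deepcopy(dataset)
        for rec in stripped.records:
            for s in stripped.endpoints:
                if s.category == "E":
                    rec.mask[s.name] = False
                    rec.labels.pop(s.name, None)
        cfg = TrainConfig(mode="sequential", seed=0, **FAST)
        with pytest.raises(ValueError, match="E"):
            train_sequential(_fresh_model(stripped), stripped, cfg)

    def test_wrong_mode_rejected(self, synth_small):
        dataset, _ = synth_small
        with pytest.raises(ValueError):
            train_sequential(
                _fresh_model(dataset), dataset, TrainConfig(mode="naive", **FAST)
            )
        with pytest.raises(ValueError):
            train_naive(
                _fresh_model(dataset), dataset, TrainConfig(mode="sequential", **FAST)
            )


class TestLedger:
    def test_best_epoch_prefers_lowest_then_earliest(self):
        ledger = LossLedger(total_val={0: 0.5, 1: 0.3, 2: 0.3, 3: 0.4})
        assert ledger.best_epoch() == 1

    def test_equality_semantics(self):
        a = LossLedger(total_val={0: 0.5})
        b = LossLedger(total_val={0: 0.5})
        assert a == b
        b.total_val[0] = 0.5000001
        assert a != b


def test_order_must_be_permutation():
    with pytest.raises(ValueError):
        TrainConfig(order=("A", "A", "D"))
    cfg = dataclasses.replace(TrainConfig(), order=tuple("EMDA"))
    assert cfg.order == ("E", "M", "D", "A")
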