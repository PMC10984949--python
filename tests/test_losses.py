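"""Loss components against closed forms and brute-force pair enumeration."""

import math

import numpy as np
import pytest

from molfewshot import autodiff as ad
from molfewshot.losses import (
    LossConfig,
    TrainingClock,
    combined_loss,
    contrastive_dynamic,
    contrastive_loss_tensor,
    contrastive_static,
    hard_fraction,
    pair_label_matrix,
    pairwise_distances,
    prepare_battery,
    select_hard_negatives,
    supervised_loss,
)


def brute_force_contrastive(emb, labels, m, fraction=None):
    """Independent oracle: explicit double loop + explicit sorting."""
    n = len(emb)
    pairs = []
    for i in range(n):
        for j in range(i + 1, n):
            d = math.dist(emb[i], emb[j])
            pairs.append((i, j, d, labels[i] == labels[j]))
    if fraction is None:
        keep = {(i, j) for i, j, _, _ in pairs}
    else:
        negs = sorted([(d, i, j) for i, j, d, same in pairs if not same])
        n_hard = math.ceil(fraction * len(negs))
        keep = {(i, j) for i, j, _, same in pairs if same}
        keep |= {(i, j) for _, i, j in negs[:n_hard]}
    total = 0.0
    for i, j, d, same in pairs:
        if (i, j) not in keep:
            continue
        total += d ** 2 if same else max(0.0, m - d ** 2)
    return total


class TestSupervisedLoss:
    def test_uniform_prediction_gives_log2(self):
        logits = np.zeros((2, 2))
        assert supervised_loss(logits, np.array([0, 1])) == pytest.approx(math.log(2))

    def test_confident_correct_prediction_vanishes(self):
        logits = np.array([[50.0, -50.0], [-50.0, 50.0]])
        assert supervised_loss(logits, np.array([0, 1])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_per_sample_enumeration(self, rng):
        logits = rng.normal(size=(4, 2))
        labels = np.array([0, 1, 1, 0])
        expected = 0.0
        for row, y in zip(logits, labels):
            p = np.exp(row) / np.exp(row).sum()
            expected -= math.log(p[y])
        expected /= 4
        assert supervised_loss(logits, labels) == pytest.approx(expected)

    def test_rejects_bad_labels(self):
        with pytest.raises(ValueError):
            supervised_loss(np.zeros((2, 2)), np.array([0, 2]))


class TestPairwiseDistances:
    def test_identical_rows_give_zero(self):
        D = pairwise_distances(np.ones((3, 4)))
        assert np.allclose(D, 0.0)

    def test_one_dimensional_closed_form(self):
        D = pairwise_distances(np.array([[0.0], [3.0]]))
        assert D[0, 1] == pytest.approx(3.0)

    def test_matches_per_pair_norms(self, rng):
        X = rng.normal(size=(5, 3))
        D = pairwise_distances(X)
        for i in range(5):
            for j in range(5):
                assert D[i, j] == pytest.approx(np.linalg.norm(X[i] - X[j]))
        assert np.allclose(D, D.T)
        assert np.allclose(np.diag(D), 0.0)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pairwise_distances(np.array([[0.0, np.inf], [1.0, 2.0]]))


class TestContrastiveStatic:
    def test_same_class_at_zero_distance(self):
        battery = prepare_battery(np.ones((2, 3)), np.array([1, 1]), 1.0)
        assert contrastive_static(battery, 1.0) == pytest.approx(0.0)

    def test_margin_satisfied_pair_contributes_nothing(self):
        emb = np.array([[0.0], [5.0]])
        battery = prepare_battery(emb, np.array([0, 1]), 1.0)
        assert contrastive_static(battery, 4.0) == pytest.approx(0.0)

    def test_three_point_hand_enumeration(self):
        # pairs: (1,2) same class D2=1 -> 1; (1,3) D2=9 -> 0; (2,3) D2=4 -> 0
        emb = np.array([[0.0], [1.0], [3.0]])
        labels = np.array([1, 1, 0])
        battery = prepare_battery(emb, labels, 1.0)
        assert contrastive_static(battery, 4.0) == pytest.approx(1.0)

    def test_rejects_non_positive_margin(self):
        battery = prepare_battery(np.eye(3), np.array([0, 1, 1]), 1.0)
        with pytest.raises(ValueError):
            contrastive_static(battery, 0.0)


class TestHardFraction:
    def test_reference_settings_at_zero(self):
        cfg = LossConfig(alpha_start=1.0, alpha_end=0.2, beta=0.01)
        out = hard_fraction(TrainingClock(0), cfg)
        assert out.raw == pytest.approx(1.2)
        assert out.fraction == pytest.approx(1.0)

    def test_decay_limit_is_alpha_end(self):
        cfg = LossConfig(alpha_start=1.0, alpha_end=0.2, beta=0.01)
        assert hard_fraction(TrainingClock(10 ** 7), cfg).raw == pytest.approx(0.2)

    def test_closed_form_at_t_100(self):
        cfg = LossConfig(alpha_start=1.0, alpha_end=0.2, beta=0.01)
        assert hard_fraction(TrainingClock(100), cfg).raw == pytest.approx(
            math.exp(-1) + 0.2
        )

    def test_strictly_decreasing_for_positive_beta(self):
        cfg = LossConfig(alpha_start=1.0, alpha_end=0.2, beta=0.05)
        vals = [hard_fraction(TrainingClock(t), cfg).raw for t in range(0, 200, 10)]
        assert all(a > b for a, b in zip(vals, vals[1:]))
        assert vals[0] == pytest.approx(cfg.alpha_start + cfg.alpha_end)


class TestHardNegativeSelection:
    def test_full_fraction_selects_every_negative_pair(self, rng):
        emb = rng.normal(size=(6, 2))
        labels = np.array([0, 0, 0, 1, 1, 1])
        battery = prepare_battery(emb, labels, 1.0)
        assert battery.hard_pair_count == battery.negative_pair_count == 9
        assert contrastive_dynamic(battery, 2.0) == pytest.approx(
            contrastive_static(battery, 2.0)
        )

    def test_zero_fraction_keeps_only_attraction(self):
        emb = np.array([[0.0], [1.0], [3.0]])
        battery = prepare_battery(emb, np.array([1, 1, 0]), 0.0)
        assert battery.hard_pair_count == 0
        assert contrastive_dynamic(battery, 4.0) == pytest.approx(1.0)

    def test_smallest_distance_pair_selected_first(self):
        # negative-pair distances 0.5, 2.0, 3.0; fraction 1/3 keeps only 0.5
        emb = np.array([[0.0], [0.5], [2.0], [3.0]])
        labels = np.array([0, 1, 1, 1])
        D = pairwise_distances(emb)
        battery = select_hard_negatives(D, pair_label_matrix(labels), 1.0 / 3.0)
        assert battery.indicator[0, 1] == 1
        assert battery.indicator[0, 2] == 0 and battery.indicator[0, 3] == 0

    def test_no_negative_pairs_warns(self):
        emb = np.array([[0.0], [1.0]])
        D = pairwise_distances(emb)
        with pytest.warns(UserWarning):
            battery = select_hard_negatives(D, pair_label_matrix(np.array([1, 1])), 0.5)
        assert battery.hard_pair_count == 0
        assert battery.indicator[0, 1] == 1  # attraction pair survives


class TestContrastiveDynamic:
    def test_fraction_half_matches_brute_force(self, rng):
        emb = rng.normal(size=(10, 4))
        labels = rng.integers(0, 2, 10)
        battery = prepare_battery(emb, labels, 0.5)
        expected = brute_force_contrastive(emb, labels, 2.5, fraction=0.5)
        assert contrastive_dynamic(battery, 2.5) == pytest.approx(expected, rel=1e-6)

    @pytest.mark.parametrize("case", range(20))
    def test_oracle_equivalence_random_batteries(self, case):
        rng = np.random.default_rng(1000 + case)
        n = int(rng.integers(3, 17))
        d = int(rng.integers(1, 9))
        emb = rng.normal(size=(n, d)) * rng.uniform(0.5, 3)
        labels = rng.integers(0, 2, n)
        frac = float(rng.uniform(0, 1))
        m = float(rng.uniform(0.5, 5))
        battery = prepare_battery(emb, labels, frac)
        assert contrastive_dynamic(battery, m) == pytest.approx(
            brute_force_contrastive(emb, labels, m, fraction=frac), rel=1e-6
        )
        assert contrastive_static(battery, m) == pytest.approx(
            brute_force_contrastive(emb, labels, m), rel=1e-6
        )

    def test_permutation_invariance(self, rng):
        emb = rng.normal(size=(8, 3))
        labels = rng.integers(0, 2, 8)
        perm = rng.permutation(8)
        a = contrastive_dynamic(prepare_battery(emb, labels, 0.4), 2.0)
        b = contrastive_dynamic(prepare_battery(emb[perm], labels[perm], 0.4), 2.0)
        assert a == pytest.approx(b, rel=1e-9)


class TestCombinedLoss:
    def test_zero_weight_reduces_to_supervised(self):
        cfg = LossConfig(weight_w=0.0)
        assert combined_loss(0.7, 123.0, cfg) == pytest.approx(0.7)

    def test_weighted_sum(self):
        cfg = LossConfig(weight_w=1.0)
        assert combined_loss(0.5, 2.0, cfg) == pytest.approx(2.5)

    @pytest.mark.parametrize("w", [0.1, 1.0, 10.0])
    def test_weight_grid_accepted(self, w):
        assert LossConfig(weight_w=w).weight_w == w

    def test_contrastive_disabled_drops_term(self):
        cfg = LossConfig(contrastive_enabled=False, dynamic_enabled=False)
        assert combined_loss(0.5, 99.0, cfg) == pytest.approx(0.5)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError):
            LossConfig(weight_w=-0.1)

    def test_dynamic_requires_contrastive(self):
        with pytest.raises(ValueError):
            LossConfig(dynamic_enabled=True, contrastive_enabled=False)


class TestGradientDirection:
    def test_same_class_pair_attracts(self):
        emb = ad.parameter(np.array([[0.0, 0.0], [1.0, 0.5]]))
        loss, _ = contrastive_loss_tensor(emb, np.array([1, 1]),
                                          LossConfig(dynamic_enabled=False))
        loss.backward()
        before = np.linalg.norm(emb.data[0] - emb.data[1])
        stepped = emb.data - 0.01 * emb.grad
        after = np.linalg.norm(stepped[0] - stepped[1])
        assert after < before

    def test_different_class_pair_inside_margin_repels(self):
        emb = ad.parameter(np.array([[0.0, 0.0], [0.5, 0.0]]))
        loss, _ = contrastive_loss_tensor(emb, np.array([0, 1]),
                                          LossConfig(margin_m=4.0, dynamic_enabled=False))
        loss.backward()
        before = np.linalg.norm(emb.data[0] - emb.data[1])
        stepped = emb.data - 0.01 * emb.grad
        after = np.linalg.norm(stepped[0] - stepped[1])
        assert after > before

    def test_tensor_loss_matches_numpy_path(self, rng):
        emb = rng.normal(size=(9, 5))
        labels = rng.integers(0, 2, 9)
        cfg = LossConfig(margin_m=3.0)
        loss, battery = contrastive_loss_tensor(ad.parameter(emb), labels, cfg, 0.6)
        assert float(loss.data) == pytest.approx(
            contrastive_dynamic(prepare_battery(emb, labels, 0.6), 3.0), rel=1e-9
        )
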