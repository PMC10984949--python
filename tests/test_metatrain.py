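"""Training loop, AUC protocol and ablation variants."""

import numpy as np
import pytest

from molfewshot import (
    EncoderConfig,
    EvalReport,
    FewShotGraphModel,
    LossConfig,
    MetaConfig,
    TrainingClock,
    ablation_variant,
    auc_score,
    episode_stream,
    meta_train,
)


def brute_force_auc(scores, labels):
    """Concordant-pair count with half credit for ties."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestAUC:
    def test_perfect_ranking(self):
        assert auc_score(np.array([0.9, 0.8, 0.2, 0.1]),
                         np.array([1, 1, 0, 0])) == 1.0

    def test_constant_scores_give_half(self):
        assert auc_score(np.full(6, 0.3),
                         np.array([1, 0, 1, 0, 1, 0])) == pytest.approx(0.5)

    def test_hand_worked_example(self):
        # pos {0.9, 0.4}, neg {0.6, 0.1}: 3 of 4 pairs concordant
        assert auc_score(np.array([0.9, 0.4, 0.6, 0.1]),
                         np.array([1, 1, 0, 0])) == pytest.approx(0.75)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(4, 30))
            scores = np.round(rng.normal(size=n), 1)  # rounding forces ties
            labels = rng.integers(0, 2, n)
            if len(np.unique(labels)) < 2:
                continue
            assert auc_score(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels)
            )

    def test_single_class_is_nan_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isnan(auc_score(np.array([0.1, 0.2]), np.array([1, 1])))

    def test_nan_aucs_excluded_from_aggregate(self):
        report = EvalReport(per_task_auc={"a": [0.8, float("nan")], "b": [0.6]},
                            runs=2).finalize()
        assert report.mean_auc == pytest.approx(0.7)


class TestAblationVariants:
    def test_wc_disables_contrastive(self):
        cfg = ablation_variant("wc")
        assert not cfg.contrastive_enabled and not cfg.dynamic_enabled

    def test_wd_is_static_contrastive(self):
        cfg = ablation_variant("wd")
        assert cfg.contrastive_enabled and not cfg.dynamic_enabled

    def test_full_is_dynamic(self):
        cfg = ablation_variant("full")
        assert cfg.contrastive_enabled and cfg.dynamic_enabled

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ablation_variant("nope")

    def test_base_hyperparameters_propagate(self):
        base = LossConfig(margin_m=7.0, weight_w=3.0)
        assert ablation_variant("wd", base=base).margin_m == 7.0
        assert ablation_variant("full", base=base).weight_w == 3.0


class TestMetaTraining:
    def test_clock_and_metrics_follow_outer_steps(self, small_family):
        fam = small_family
        model = FewShotGraphModel(
            fam.table, fam.split, k_shot=2,
            encoder_config=EncoderConfig(hidden_dim=8, n_layers=2),
            meta_config=MetaConfig(meta_train_iterations=15, runs=1),
        )
        res = model.fit(seed=0)
        assert res.clock.t == 15
        assert len(res.metrics) == 15
        assert res.metrics[0]["f_raw"] == pytest.approx(1.2)
        assert res.metrics[0]["f_clipped"] == 1.0
        fs = [row["f_raw"] for row in res.metrics]
        assert all(a > b for a, b in zip(fs, fs[1:]))

    def test_supervised_only_training_reduces_query_loss(self, small_family):
        fam = small_family
        model = FewShotGraphModel(
            fam.table, fam.split, k_shot=3,
            encoder_config=EncoderConfig(hidden_dim=16, n_layers=3),
            loss_config=ablation_variant("wc"),
            meta_config=MetaConfig(meta_train_iterations=50, inner_steps=0, runs=1),
        )
        res = model.fit(seed=1)
        losses = [row["loss_sup"] for row in res.metrics]
        assert np.mean(losses[-10:]) < np.mean(losses[:10])

    def test_seeded_determinism_of_final_parameters(self, small_family):
        fam = small_family
        def run():
            model = FewShotGraphModel(
                fam.table, fam.split, k_shot=2,
                encoder_config=EncoderConfig(hidden_dim=8, n_layers=2),
                meta_config=MetaConfig(meta_train_iterations=8, runs=1),
            )
            return model.fit(seed=5)
        a, b = run(), run()
        for k in a.params.params:
            assert np.array_equal(a.params.params[k].data, b.params.params[k].data), k

    def test_meta_test_preserves_base_parameters(self, tiny_trained):
        model, res = tiny_trained
        before = res.params.copy_state()
        report = res.evaluate(runs=2)
        after = res.params.copy_state()
        assert all(np.array_equal(before[k], after[k]) for k in before)
        assert report.runs == 2
        for aucs in report.per_task_auc.values():
            assert len(aucs) == 2
            for a in aucs:
                assert np.isnan(a) or 0.0 <= a <= 1.0

    def test_stream_shorter_than_iterations_errors(self, small_family):
        fam = small_family
        model = FewShotGraphModel(
            fam.table, fam.split, k_shot=2,
            encoder_config=EncoderConfig(hidden_dim=8, n_layers=2),
            meta_config=MetaConfig(meta_train_iterations=5, runs=1),
        )
        short = episode_stream(fam.table, fam.split, "meta_train", 2, seed=0,
                               n_episodes=2, query_size=8)
        with pytest.raises(StopIteration):
            meta_train(model.encoder, model.init_params(0), short,
                       model.loss_config, model.meta_config, TrainingClock())

    def test_second_order_variant_not_available(self):
        with pytest.raises(NotImplementedError):
            MetaConfig(first_order=False)
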