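"""Episodic meta-training and the AUC-based meta-test protocol.

Training follows a first-order MAML-style loop. For each outer step a
meta-batch of episodes is drawn; per episode the encoder parameters are
cloned, adapted for ``inner_steps`` plain-gradient steps on the support-set
combined loss, and the query-set combined loss is evaluated under the
adapted parameters. The query gradients (taken at the adapted point — the
first-order approximation) are averaged across the meta-batch and applied
to the base parameters with Adam. The training clock t counts completed
outer steps and drives the hard-negative fraction f(t).

Contrastive pairs during meta-training span support ∪ query (both labelled
in this phase); at meta-test time adaptation sees the support set only, and
the query set is scored — never trained on. Evaluation runs the protocol
``runs`` times with distinct seeds and reports the mean and standard
deviation of the per-task query AUCs.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_auc_score

from . import autodiff as ad
from .chem_io import TaskSplit, TaskTable
from .encoder import GINEncoder, ParameterSet, collate
from .episodes import Episode, episode_stream
from .losses import (
    LossConfig,
    TrainingClock,
    contrastive_loss_tensor,
    hard_fraction,
    supervised_loss,
)


@dataclass
class MetaConfig:
    inner_steps: int = 1
    inner_lr: float = 0.01
    outer_lr: float = 0.001
    meta_batch_tasks: int = 1
    meta_train_iterations: int = 300
    first_order: bool = True
    runs: int = 10
    finetune_steps_at_test: int = 80
    finetune_lr: float = 0.02
    # contrastive pair sums are not normalised by pair count, so gradients can
    # be large early on; a global-norm clip keeps every update bounded
    max_grad_norm: float = 5.0

    def __post_init__(self):
        if self.inner_lr <= 0 or self.outer_lr <= 0 or self.finetune_lr <= 0:
            raise ValueError("learning rates must be positive")
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.inner_steps < 0:
            raise ValueError("inner_steps must be non-negative")
        if not self.first_order:
            raise NotImplementedError(
                "only the first-order meta-gradient variant is implemented"
            )


@dataclass
class EvalReport:
    """Per-task query AUCs across runs plus their aggregate mean ± std.

    Undefined AUCs (single-class query sets) are stored as NaN, warned
    about, and excluded from the aggregate.
    """

    per_task_auc: dict = field(default_factory=dict)
    mean_auc: float = float("nan")
    std_auc: float = float("nan")
    runs: int = 0

    def finalize(self) -> "EvalReport":
        vals = [a for aucs in self.per_task_auc.values() for a in aucs
                if np.isfinite(a)]
        self.mean_auc = float(np.mean(vals)) if vals else float("nan")
        self.std_auc = float(np.std(vals)) if vals else float("nan")
        return self

    def to_json(self) -> str:
        return json.dumps(
            {
                "per_task_auc": {t: list(v) for t, v in self.per_task_auc.items()},
                "mean_auc": self.mean_auc,
                "std_auc": self.std_auc,
                "runs": self.runs,
                "single_run": self.runs == 1,
            },
            indent=2,
        )


def auc_score(scores: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based ROC AUC (Mann–Whitney, ties half-credit); NaN if one class."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        warnings.warn("query set contains a single class; AUC undefined")
        return float("nan")
    return float(roc_auc_score(labels, scores))


def ablation_variant(name: str, base: LossConfig | None = None) -> LossConfig:
    """Loss configuration for the named ablation.

    ``full``: dynamic contrastive on. ``wc``: no contrastive term (pure
    cross-entropy). ``wd``: contrastive on but static (no hard-negative
    schedule).
    """
    base = base or LossConfig()
    common = dict(margin_m=base.margin_m, weight_w=base.weight_w,
                  alpha_start=base.alpha_start, alpha_end=base.alpha_end,
                  beta=base.beta, hinge=base.hinge)
    if name == "full":
        return LossConfig(dynamic_enabled=True, contrastive_enabled=True, **common)
    if name == "wc":
        return LossConfig(dynamic_enabled=False, contrastive_enabled=False, **common)
    if name == "wd":
        return LossConfig(dynamic_enabled=False, contrastive_enabled=True, **common)
    raise ValueError(f"unknown ablation variant {name!r}; use full/wc/wd")


def _clip_gradients(grads: dict, max_norm: float) -> dict:
    """Scale the gradient dict so its global L2 norm is at most max_norm."""
    if max_norm <= 0:
        return grads
    total = np.sqrt(sum(float((g * g).sum()) for g in grads.values() if g is not None))
    if total > max_norm:
        scale = max_norm / total
        grads = {k: (g * scale if g is not None else None) for k, g in grads.items()}
    return grads


def _clip_param_grads(params: dict, max_norm: float) -> None:
    clipped = _clip_gradients({k: p.grad for k, p in params.items()}, max_norm)
    for k, p in params.items():
        p.grad = clipped[k]


def _episode_loss(
    encoder: GINEncoder,
    pset: ParameterSet,
    graphs: list,
    labels: np.ndarray,
    loss_cfg: LossConfig,
    fraction: float,
    query_slice: slice | None = None,
    rng: np.random.Generator | None = None,
):
    """Combined loss on a batch; CE over `query_slice` rows (all if None)."""
    emb, logits = encoder.forward(pset, collate(graphs), training=True, rng=rng)
    if query_slice is not None:
        idx = np.arange(len(graphs))[query_slice]
        sup_logits = logits.gather_rows(idx)
        sup_labels = labels[query_slice]
    else:
        sup_logits, sup_labels = logits, labels
    l_sup = supervised_loss(sup_logits, sup_labels)
    stats = {"loss_sup": float(l_sup.data), "loss_contra": 0.0,
             "n_neg_pairs": 0, "n_hard_pairs": 0}
    if loss_cfg.contrastive_enabled and loss_cfg.weight_w > 0:
        l_con, battery = contrastive_loss_tensor(emb, labels, loss_cfg, fraction)
        total = l_sup + ad.constant(loss_cfg.weight_w) * l_con
        stats.update(loss_contra=float(l_con.data),
                     n_neg_pairs=battery.negative_pair_count,
                     n_hard_pairs=battery.hard_pair_count)
    else:
        total = l_sup
    stats["loss_total"] = float(total.data)
    return total, stats


def meta_train(
    encoder: GINEncoder,
    pset: ParameterSet,
    stream,
    loss_cfg: LossConfig,
    meta_cfg: MetaConfig,
    clock: TrainingClock,
    seed: int = 0,
) -> tuple[ParameterSet, list]:
    """Run the outer loop; returns the updated parameters and a metrics log.

    One metrics dict is appended per outer step: the clock value, component
    losses, the raw and clipped f(t), and the negative/hard pair counts.
    """
    stream = iter(stream)
    outer_opt = ad.Adam(pset.params, lr=meta_cfg.outer_lr)
    rng = np.random.default_rng([seed, 17])
    metrics: list = []
    for step in range(meta_cfg.meta_train_iterations):
        sched = hard_fraction(clock, loss_cfg)
        grad_accum = {k: np.zeros_like(p.data) for k, p in pset.params.items()}
        step_stats = None
        for _ in range(meta_cfg.meta_batch_tasks):
            episode = next(stream)
            adapted = pset.clone()
            inner_opt = ad.SGD(adapted.params, lr=meta_cfg.inner_lr)
            sup_graphs = [g for g, _ in episode.support]
            sup_labels = episode.support_labels()
            for _ in range(meta_cfg.inner_steps):
                loss, _ = _episode_loss(encoder, adapted, sup_graphs, sup_labels,
                                        loss_cfg, sched.fraction, rng=rng)
                inner_opt.zero_grad()
                loss.backward()
                _clip_param_grads(adapted.params, meta_cfg.max_grad_norm)
                inner_opt.step()
            all_graphs = sup_graphs + [g for g, _ in episode.query]
            all_labels = np.concatenate([sup_labels, episode.query_labels()])
            loss, stats = _episode_loss(
                encoder, adapted, all_graphs, all_labels, loss_cfg,
                sched.fraction, query_slice=slice(len(sup_graphs), None), rng=rng,
            )
            if not np.isfinite(stats["loss_total"]):
                raise RuntimeError(
                    f"non-finite loss at step {step}, task {episode.task_name!r}: {stats}"
                )
            for p in adapted.params.values():
                p.grad = None
            loss.backward()
            for k, p in adapted.params.items():
                if p.grad is not None:
                    grad_accum[k] += p.grad / meta_cfg.meta_batch_tasks
            pset.buffers = adapted.buffers  # carry running statistics forward
            step_stats = stats
        outer_opt.step(grads=_clip_gradients(grad_accum, meta_cfg.max_grad_norm))
        t = clock.tick()
        metrics.append({"step": step, "t": t, "f_raw": sched.raw,
                        "f_clipped": sched.fraction, **step_stats})
    return pset, metrics


def finetune_and_score(
    encoder: GINEncoder,
    pset: ParameterSet,
    episode: Episode,
    loss_cfg: LossConfig,
    meta_cfg: MetaConfig,
    fraction: float,
    seed: int = 0,
) -> tuple[float, ParameterSet]:
    """Adapt a parameter clone on the support set, score the query set.

    Fine-tuning uses Adam (scale-robust against the unnormalised contrastive
    sums); the query batch is scored with its own batch statistics
    (transductive normalisation, standard in the MAML lineage). Returns the
    query AUC (NaN when undefined) and the adapted clone; the base
    parameters are never touched.
    """
    adapted = pset.clone()
    opt = ad.Adam(adapted.params, lr=meta_cfg.finetune_lr)
    rng = np.random.default_rng([seed, 23])
    sup_graphs = [g for g, _ in episode.support]
    sup_labels = episode.support_labels()
    for _ in range(meta_cfg.finetune_steps_at_test):
        loss, stats = _episode_loss(encoder, adapted, sup_graphs, sup_labels,
                                    loss_cfg, fraction, rng=rng)
        if not np.isfinite(stats["loss_total"]):
            raise RuntimeError(f"non-finite fine-tuning loss: {stats}")
        opt.zero_grad()
        loss.backward()
        _clip_param_grads(adapted.params, meta_cfg.max_grad_norm)
        opt.step()
    _, logits = encoder.forward(adapted, collate([g for g, _ in episode.query]),
                                training=True, rng=rng)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    prob_pos = np.exp(z[:, 1]) / np.exp(z).sum(axis=1)
    return auc_score(prob_pos, episode.query_labels()), adapted


def meta_test(
    encoder: GINEncoder,
    pset: ParameterSet,
    table: TaskTable,
    split: TaskSplit,
    k_shot: int,
    loss_cfg: LossConfig,
    meta_cfg: MetaConfig,
    seed: int = 0,
) -> EvalReport:
    """Evaluate on every test task over ``meta_cfg.runs`` seeded runs."""
    before = pset.copy_state()
    fraction = min(1.0, loss_cfg.alpha_end) if loss_cfg.dynamic_enabled else 1.0
    report = EvalReport(per_task_auc={t: [] for t in split.test_tasks},
                        runs=meta_cfg.runs)
    for run in range(meta_cfg.runs):
        run_seed = (seed + 1000003 * run) % (2 ** 31)
        for episode in episode_stream(table, split, "meta_test", k_shot, run_seed):
            auc, _ = finetune_and_score(encoder, pset, episode, loss_cfg,
                                        meta_cfg, fraction, seed=run_seed)
            report.per_task_auc[episode.task_name].append(auc)
    after = pset.copy_state()
    assert all(np.array_equal(before[k], after[k]) for k in before), \
        "meta_test must not mutate the base parameters"
    return report.finalize()
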