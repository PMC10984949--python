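"""The bifurcated training objective: cross-entropy + dynamic contrastive loss.

The total loss is

    L = L_label + w * L_contra

where ``L_label`` is the mean cross-entropy over the batch and ``L_contra``
is a margin-based contrastive loss over unordered sample pairs (i < j,
self-pairs excluded):

    L_contra = sum_{i<j} [ y_ij * D(i,j)^2
                           + (1 - y_ij) * max(0, m - D(i,j)^2) ] * I(i,j)

with y_ij = 1 iff the two samples share a class, D the Euclidean embedding
distance, and m the margin. In the *static* form the indicator I is 1
everywhere. In the *dynamic* form, I stays 1 on all same-class (attraction)
pairs but restricts repulsion to the hardest fraction f(t) of the
different-class pairs — "hard" meaning closest in embedding space, i.e. the
pairs violating or nearly violating the margin. The fraction follows an
exponential decay over training steps t:

    f(t) = alpha_start * exp(-beta * t) + alpha_end

so training emphasises the hardest negatives early (f clipped to 1 means
"use all negatives") and relaxes toward a stable floor alpha_end. Defaults
alpha_start=1, alpha_end=0.2, beta=0.01 follow the reference configuration;
the raw f(t) (which exceeds 1 at t=0) is reported alongside the clipped
selection fraction.

The repulsion hinge acts on the *squared* distance, max(0, m - D^2); the
classical Hadsell-style hinge max(0, m - D)^2 is available via
``hinge="classical"`` for experimentation. Pair sums are not normalised by
pair count — the weight w absorbs overall scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import NamedTuple, Union

import numpy as np
from scipy.spatial.distance import squareform, pdist

from . import autodiff as ad
from .autodiff import Tensor

ArrayOrTensor = Union[np.ndarray, Tensor]


@dataclass
class LossConfig:
    margin_m: float = 1.0
    weight_w: float = 1.0
    alpha_start: float = 1.0
    alpha_end: float = 0.2
    beta: float = 0.01
    dynamic_enabled: bool = True
    contrastive_enabled: bool = True
    hinge: str = "squared_distance"  # or "classical"

    def __post_init__(self):
        if self.margin_m <= 0:
            raise ValueError("margin_m must be positive")
        if self.weight_w < 0:
            raise ValueError("weight_w must be non-negative")
        if min(self.alpha_start, self.alpha_end, self.beta) < 0:
            raise ValueError("alpha_start, alpha_end and beta must be non-negative")
        if self.dynamic_enabled and not self.contrastive_enabled:
            raise ValueError("dynamic selection requires the contrastive term")
        if self.hinge not in ("squared_distance", "classical"):
            raise ValueError("hinge must be 'squared_distance' or 'classical'")


class TrainingClock:
    """Counts completed outer optimisation steps; drives the decay schedule."""

    def __init__(self, t: int = 0):
        if t < 0:
            raise ValueError("t must be non-negative")
        self.t = int(t)

    def tick(self) -> int:
        self.t += 1
        return self.t


class HardFraction(NamedTuple):
    raw: float       # f(t) as the formula gives it (may exceed 1)
    fraction: float  # clipped to [0, 1], usable as a selection fraction


def hard_fraction(clock: TrainingClock, config: LossConfig) -> HardFraction:
    """Evaluate the decay schedule f(t) = a_start * exp(-beta t) + a_end."""
    raw = config.alpha_start * math.exp(-config.beta * clock.t) + config.alpha_end
    return HardFraction(raw=raw, fraction=min(max(raw, 0.0), 1.0))


@dataclass
class PairwiseBattery:
    """Pairwise distances, pair labels and the hard-negative indicator.

    All matrices are (n, n); only the upper triangle (i < j) enters loss
    sums. ``indicator`` is 1 on every same-class pair and on the selected
    hard different-class pairs.
    """

    distances: np.ndarray
    pair_labels: np.ndarray
    indicator: np.ndarray
    negative_pair_count: int
    hard_pair_count: int

    def __post_init__(self):
        if not np.allclose(self.distances, self.distances.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.abs(np.diag(self.distances)) > 1e-12):
            raise ValueError("distance matrix must have zero diagonal")
        if self.hard_pair_count > self.negative_pair_count:
            raise ValueError("hard pairs cannot outnumber negative pairs")


def pairwise_distances(embeddings: np.ndarray) -> np.ndarray:
    """Euclidean distance matrix D(i,j) = ||e_i - e_j||_2."""
    embeddings = np.asarray(embeddings, dtype=np.float64)
    if embeddings.ndim != 2 or embeddings.shape[0] < 2:
        raise ValueError("need a (n >= 2, d) embedding matrix")
    if not np.all(np.isfinite(embeddings)):
        raise ValueError("non-finite embeddings")
    return squareform(pdist(embeddings, metric="euclidean"))


def pair_label_matrix(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    return (labels[:, None] == labels[None, :]).astype(np.int64)


def select_hard_negatives(
    distances: np.ndarray,
    pair_labels: np.ndarray,
    fraction: float,
) -> PairwiseBattery:
    """Mark the closest ``fraction`` of different-class pairs as hard.

    Among the |K| unordered different-class pairs, the ceil(fraction * |K|)
    smallest-distance pairs receive indicator 1 (hardest = closest, i.e.
    margin-violating first); every same-class pair keeps indicator 1 so the
    attraction term always survives. Ties break lexicographically by (i, j).
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must lie in [0, 1]")
    n = distances.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    neg_mask = pair_labels[iu, ju] == 0
    neg_i, neg_j = iu[neg_mask], ju[neg_mask]
    n_neg = int(neg_mask.sum())

    indicator = np.zeros((n, n), dtype=np.int64)
    same = pair_labels.astype(bool).copy()
    np.fill_diagonal(same, False)
    indicator[same] = 1

    if n_neg == 0:
        warnings.warn("no different-class pairs in batch; repulsion term is empty")
        n_hard = 0
    else:
        n_hard = int(math.ceil(fraction * n_neg))
        if n_hard > 0:
            d = distances[neg_i, neg_j]
            order = np.lexsort((neg_j, neg_i, d))  # distance, then (i, j)
            take = order[:n_hard]
            indicator[neg_i[take], neg_j[take]] = 1
            indicator[neg_j[take], neg_i[take]] = 1
    return PairwiseBattery(
        distances=distances,
        pair_labels=np.asarray(pair_labels),
        indicator=indicator,
        negative_pair_count=n_neg,
        hard_pair_count=n_hard,
    )


def _pair_terms(battery: PairwiseBattery, margin_m: float, hinge: str) -> np.ndarray:
    if margin_m <= 0:
        raise ValueError("margin must be positive")
    D = battery.distances
    y = battery.pair_labels
    attract = y * D ** 2
    if hinge == "classical":
        repel = (1 - y) * np.maximum(0.0, margin_m - D) ** 2
    else:
        repel = (1 - y) * np.maximum(0.0, margin_m - D ** 2)
    return attract + repel


def contrastive_static(
    battery: PairwiseBattery, margin_m: float, hinge: str = "squared_distance"
) -> float:
    """Static contrastive loss: all unordered pairs, no hard-negative gating."""
    terms = _pair_terms(battery, margin_m, hinge)
    iu, ju = np.triu_indices(battery.distances.shape[0], k=1)
    return float(terms[iu, ju].sum())


def contrastive_dynamic(
    battery: PairwiseBattery, margin_m: float, hinge: str = "squared_distance"
) -> float:
    """Dynamic contrastive loss: pair terms gated by the hard indicator."""
    terms = _pair_terms(battery, margin_m, hinge) * battery.indicator
    iu, ju = np.triu_indices(battery.distances.shape[0], k=1)
    return float(terms[iu, ju].sum())


def supervised_loss(logits: ArrayOrTensor, labels: np.ndarray) -> ArrayOrTensor:
    """Mean cross-entropy from logits via a stable log-softmax.

    Accepts a plain array (returns a float) or an autodiff Tensor (returns a
    scalar Tensor wired into the tape).
    """
    labels = np.asarray(labels, dtype=np.int64)
    if labels.size == 0:
        raise ValueError("empty batch")
    if np.any((labels != 0) & (labels != 1)):
        raise ValueError("labels must lie in {0, 1}")
    is_tensor = isinstance(logits, Tensor)
    lg = logits if is_tensor else ad.constant(np.asarray(logits, dtype=np.float64))
    logp = ad.log_softmax(lg)
    picked = logp * ad.constant(np.eye(2)[labels])
    loss = -(picked.sum()) / float(labels.size)
    return loss if is_tensor else float(loss.data)


def contrastive_loss_tensor(
    embeddings: Tensor,
    labels: np.ndarray,
    config: LossConfig,
    fraction: float = 1.0,
) -> tuple[Tensor, PairwiseBattery]:
    """Differentiable contrastive term for training.

    The hard-negative selection runs on *detached* distances (selection is a
    discrete choice and carries no gradient); the returned Tensor
    differentiates the gated pair terms w.r.t. the embeddings. With
    ``config.dynamic_enabled`` false the indicator is all-ones (static form,
    the "wd" ablation) and ``fraction`` is ignored.
    """
    n = embeddings.shape[0]
    if n < 2:
        raise ValueError("contrastive loss needs at least two samples")
    eff_fraction = fraction if config.dynamic_enabled else 1.0
    battery = prepare_battery(embeddings.data, labels, eff_fraction)

    sq = (embeddings * embeddings).sum(axis=1, keepdims=True)  # (n, 1)
    d2 = ad.relu(sq + sq.reshape(1, n) - 2.0 * (embeddings @ embeddings.T))
    y = ad.constant(battery.pair_labels.astype(np.float64))
    if config.hinge == "classical":
        dist = (d2 + 1e-12).sqrt()
        repel = ad.relu(ad.constant(config.margin_m) - dist) ** 2
    else:
        repel = ad.relu(ad.constant(config.margin_m) - d2)
    terms = y * d2 + (1.0 - y) * repel
    mask = np.triu(np.ones((n, n)), k=1) * battery.indicator
    loss = (terms * ad.constant(mask)).sum()
    return loss, battery


def prepare_battery(
    embeddings: np.ndarray, labels: np.ndarray, fraction: float
) -> PairwiseBattery:
    """Distances + pair labels + hard-negative indicator in one call."""
    D = pairwise_distances(embeddings)
    return select_hard_negatives(D, pair_label_matrix(labels), fraction)


def combined_loss(supervised: float, contrastive: float, config: LossConfig) -> float:
    """Total objective L = L_label + w * L_contra, honouring ablation flags."""
    for v in (supervised, contrastive):
        if not np.isfinite(v):
            raise ValueError("loss components must be finite")
    if not config.contrastive_enabled:
        return float(supervised)
    return float(supervised + config.weight_w * contrastive)
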