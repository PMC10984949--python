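"""Few-shot episode construction (support/query sampling) over task pools.

An episode is one task instance: a class-balanced support set with exactly
k molecules per class (so "10-shot" = 10 positives + 10 negatives) and a
disjoint query set. The sampler, not the pool, controls support balance —
on a 1%-positive pool the support is still (k, k) and the imbalance shows
up in the query set, which is the faithful evaluation target.

Meta-training draws tasks uniformly with replacement from the training
split; meta-testing enumerates each held-out task exactly once per run.
Everything is seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Union

import numpy as np

from .chem_io import TaskSplit, TaskTable, task_dataset


@dataclass
class Episode:
    task_name: str
    support: list  # (MolecularGraph, label), exactly k per class
    query: list    # (MolecularGraph, label), disjoint from support
    k_shot: int

    def support_labels(self) -> np.ndarray:
        return np.array([y for _, y in self.support], dtype=np.int64)

    def query_labels(self) -> np.ndarray:
        return np.array([y for _, y in self.query], dtype=np.int64)


def sample_episode(
    pool: list,
    k_shot: int,
    query_size: Union[int, str],
    rng_seed: int,
    task_name: str = "",
) -> Episode:
    """Draw a support/query episode from a labelled pool, without replacement.

    ``query_size`` is an integer (stratified draw, capped by availability)
    or ``"rest"`` (everything not in the support). With an integer size the
    query keeps at least one sample of each class when the remainder allows.
    """
    if k_shot < 1:
        raise ValueError("k_shot must be positive")
    rng = np.random.default_rng(rng_seed)
    pos_idx = [i for i, (_, y) in enumerate(pool) if y == 1]
    neg_idx = [i for i, (_, y) in enumerate(pool) if y == 0]
    for name, idx in (("positives", pos_idx), ("negatives", neg_idx)):
        if len(idx) < k_shot + 1:
            raise ValueError(
                f"pool has {len(idx)} {name}; need at least {k_shot + 1} "
                f"(k_shot={k_shot} support + >=1 query)"
            )
    sup_pos = rng.choice(pos_idx, size=k_shot, replace=False)
    sup_neg = rng.choice(neg_idx, size=k_shot, replace=False)
    support_ids = set(map(int, sup_pos)) | set(map(int, sup_neg))
    rest = [i for i in range(len(pool)) if i not in support_ids]
    if query_size == "rest":
        query_ids = rest
    else:
        q = int(query_size)
        rest_pos = [i for i in rest if pool[i][1] == 1]
        rest_neg = [i for i in rest if pool[i][1] == 0]
        # stratified: aim for the pool's residual class ratio, >=1 per class
        n_pos = max(1, min(len(rest_pos), round(q * len(rest_pos) / max(len(rest), 1))))
        n_neg = min(len(rest_neg), q - n_pos)
        query_ids = list(rng.choice(rest_pos, size=n_pos, replace=False)) + \
            list(rng.choice(rest_neg, size=n_neg, replace=False))
    support = [pool[int(i)] for i in list(sup_pos) + list(sup_neg)]
    query = [pool[int(i)] for i in query_ids]
    return Episode(task_name=task_name, support=support, query=query, k_shot=k_shot)


def episode_stream(
    table: TaskTable,
    split: TaskSplit,
    phase: str,
    k_shot: int,
    seed: int,
    n_episodes: int | None = None,
    query_size: Union[int, str] = 32,
) -> Iterator[Episode]:
    """Yield episodes for a phase; reproducible for a fixed (seed, phase).

    ``meta_train`` yields ``n_episodes`` episodes over tasks drawn uniformly
    with replacement; ``meta_test`` enumerates every test task once with
    ``query_size="rest"``.
    """
    if phase not in ("meta_train", "meta_test"):
        raise ValueError("phase must be 'meta_train' or 'meta_test'")
    split.validate(table)
    tasks = split.train_tasks if phase == "meta_train" else split.test_tasks
    if not tasks:
        raise ValueError(f"no tasks in split for phase {phase}")
    pools = {t: task_dataset(table, t) for t in tasks}
    rng = np.random.default_rng([seed, 0 if phase == "meta_train" else 1])
    if phase == "meta_test":
        for t in tasks:
            yield sample_episode(pools[t], k_shot, "rest",
                                 int(rng.integers(2 ** 31)), task_name=t)
        return
    if n_episodes is None:
        raise ValueError("meta_train stream needs n_episodes")
    for _ in range(n_episodes):
        t = tasks[int(rng.integers(len(tasks)))]
        yield sample_episode(pools[t], k_shot, query_size,
                             int(rng.integers(2 ** 31)), task_name=t)
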