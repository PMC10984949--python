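# molfewshot

Few-shot molecular property prediction with a dynamic contrastive loss.

Early-stage assay panels pose a double problem for structure-based
prediction: each new task (an assay, a toxicity endpoint) comes with only a
handful of labelled molecules, and the labels are often heavily imbalanced
— actives can be 1% of the panel. `molfewshot` addresses this by
meta-training a graph isomorphism network (GIN) encoder across many related
tasks so that it adapts to an unseen task from k labelled molecules per
class, and by shaping the embedding space with a contrastive objective
whose emphasis on *hard negatives* decays over training.

## The objective

For a batch of molecules with embeddings e_i and binary labels y_i, the
training loss is

```
L = L_label + w · L_contra

L_label  = (1/k) Σ_i CrossEntropy(y_i, ŷ_i)
L_contra = Σ_{i<j} [ y_ij · D(i,j)² + (1 − y_ij) · max(0, m − D(i,j)²) ] · I(i,j, f(t))
```

where D(i,j) = ‖e_i − e_j‖₂, y_ij = 1 iff the two molecules share a class,
and m is a margin enforced between classes. The indicator I keeps every
same-class (attraction) pair and, among the different-class pairs, selects
the hardest fraction f(t) — the closest pairs, those violating or nearly
violating the margin — according to an exponential decay over training
steps:

```
f(t) = α_start · e^(−β·t) + α_end        (defaults 1, 0.2, 0.01)
```

so training focuses on every negative early (f clipped to 1) and relaxes
toward a stable floor α_end. Episodic training follows a first-order
MAML-style loop: adapt a clone on the support set, update the shared
parameters from the query-set loss. Evaluation reports the mean ± std of
rank-based ROC AUC over held-out tasks and seeded runs.

The encoder is a 5-layer GIN with jumping-knowledge sum pooling and a
linear head; the contrastive loss acts on the pre-head graph embedding.
Everything runs on a compact NumPy autodiff engine bundled with the
package — no GPU framework needed.

A synthetic task-family generator makes the whole pipeline testable with no
downloads: tasks over a shared atom vocabulary whose positive label is the
presence of a task-specific structural motif, with controllable class
imbalance (1%–60% positives), emitted as valid SMILES and verifiable by
independent subgraph search.

## Worked example

```python
from molfewshot import (FewShotGraphModel, MetaConfig, SyntheticSpec,
                        generate_task_family, reference_loss_config)

table, split = generate_task_family(
    SyntheticSpec(n_tasks=8, n_molecules_per_task=80,
                  positive_fraction=0.2, seed=1))
model = FewShotGraphModel(
    table, split, k_shot=5,
    loss_config=reference_loss_config(),
    meta_config=MetaConfig(meta_train_iterations=100, runs=3))
results = model.fit(seed=1)
report = results.evaluate()
print(results.summary())
```

prints

```
            Few-shot molecular property prediction
==============================================================
Tasks (train/test):           6 / 2
Molecules:                    640
k-shot:                       5
Encoder:                      5-layer GIN, dim 32, JK sum
Loss:                         CE + 1.0 x contrastive (m=5000.0)
Hard-negative schedule:       1.0*exp(-0.01 t) + 0.2
Outer steps (t):              100   (Adam, lr 0.001)
Inner adaptation:             1 step(s), SGD lr 0.01
--------------------------------------------------------------
Combined loss (first/last):   3499487.0510 / 1264481.3623
f(t) raw (first/last):        1.2000 / 0.5716
--------------------------------------------------------------
Meta-test AUC (mean ± std):   0.7798 ± 0.2273   (3 runs)
  task_006                    0.9730
  task_007                    0.5865
==============================================================
```

Reading the output: the raw schedule value starts at α_start + α_end = 1.2
(clipped to 1 for selection — every negative pair is used early) and has
decayed to 0.57 after 100 steps. The combined loss is dominated by the
unnormalised contrastive pair sum; what matters is its downward trend. The
two held-out tasks are scored by adapting a clone of the encoder on 5+5
support molecules and ranking the remaining ~70 molecules; an AUC of 0.97
means near-perfect recovery of that task's hidden motif rule, while 0.59 on
the other task shows how noisy 5-shot adaptation on an 80-molecule task can
be — the reference studies below average ten seeded runs on larger families
for that reason.

## Command line

```
molfewshot simulate --config config.yaml [--preset imbalanced|balanced]
molfewshot train    --config config.yaml
molfewshot eval     --config config.yaml --checkpoint runs/encoder.npz
molfewshot ablate   --config config.yaml          # full vs wc vs wd
molfewshot project  --config config.yaml --checkpoint runs/encoder.npz
```

The YAML config has sections `data`, `encoder`, `loss`, `episodes`, `meta`,
`eval`, `synthetic` plus a global `seed` and `output_dir`; see
`tests/test_model_cli.py` for a complete minimal example. Training writes a
JSON-lines metrics log (one line per outer step with component losses and
the raw and clipped f(t)) and an `.npz` checkpoint; evaluation emits the
AUC report as JSON.

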