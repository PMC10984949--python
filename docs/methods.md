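# Methods

## Problem setting

The package targets binary molecular property prediction when each
prediction task has only a handful of labelled molecules per class and the
classes can be heavily imbalanced — the situation typical of early-stage
bioactivity and toxicity panels, where a assay may have thousands of
screened compounds but very few actives. The approach treats each assay
(task) as an episode source: a *support set* with k labelled molecules per
class is used to adapt a shared encoder, and a disjoint *query set*
measures how well the adapted model ranks unseen molecules (ROC AUC).

## Model

Molecules are parsed from SMILES into attributed graphs (implicit
hydrogens). Each atom carries two categorical codes — atomic number and
chirality tag — and each bond carries bond type and bond direction. This
minimal vocabulary matches the attribute-masking GIN pretraining lineage,
so externally pretrained trunks can be loaded through the checkpoint
contract.

The encoder is a graph isomorphism network (GIN): at layer *l* each node is
updated as

    h_v ← MLP_l( (1 + ε_l) · h_v + Σ_{u∈N(v)} (h_u + e_uv) )

with a learnable ε_l, a two-layer ReLU MLP (hidden width 2d), batch
normalisation after each layer, and learned embedding tables for all
categorical codes. Node states are sum-pooled per graph at every layer and
the per-layer readouts are combined by a jumping-knowledge (JK) sum into
the graph embedding (dimension d; `last`, `max` and `concat` modes are also
available). A linear head maps the embedding to two class logits. The
default configuration is 5 layers at d=32. The *pre-head* embedding is the
representation used by the contrastive objective: the head is task-specific
while the contrastive loss shapes the shared space.

## Objective

The training loss is

    L = L_label + w · L_contra,

with `L_label` the mean cross-entropy of the logits and `L_contra` a
margin-based contrastive loss over unordered sample pairs (i < j,
self-pairs excluded):

    L_contra = Σ_{i<j} [ y_ij D(i,j)² + (1 − y_ij) max(0, m − D(i,j)²) ] · I(i,j)

where y_ij = 1 iff samples i and j share a class, D is the Euclidean
distance between their embeddings and m the margin. The repulsion hinge
acts on the *squared* distance; the classical Hadsell-style hinge
max(0, m − D)² is available behind `hinge="classical"` for experimentation
(a small ε=1e-12 guards the √ at coincident points). Pair sums are not
normalised by pair count; the weight w absorbs overall scale.

In the **dynamic** form the indicator I(i,j) equals 1 on every same-class
pair — the attraction component always survives — and on different-class
pairs it selects only the hardest fraction f(t): among the |K| unordered
different-class pairs, the ⌈f(t)·|K|⌉ with the smallest distance (hardest =
closest, i.e. violating or nearly violating the margin) receive indicator
1; ties break lexicographically by pair index. The fraction follows an
exponential decay over completed outer optimisation steps t:

    f(t) = α_start · e^{−β t} + α_end,

defaults α_start = 1, α_end = 0.2, β = 0.01. At t = 0 the raw value is 1.2;
it is clipped to [0,1] for selection ("use every negative early") while the
raw value is logged so the schedule remains auditable. Selection operates
on detached distances — it is a discrete choice and carries no gradient;
all gradients come from reverse-mode automatic differentiation (the package
ships a compact tape-based engine on NumPy; no GPU framework is required).

Ablation variants: `wc` drops the contrastive term entirely (pure
cross-entropy) and `wd` keeps the contrastive term but disables the
schedule (static, all pairs).

### Choosing the margin

The margin must be commensurate with the embedding distance scale,
otherwise the hinge is either always or never active. With sum readout over
8–16-atom molecules, batch-normalised node states and a 5-layer JK-sum at
d=32, the median pairwise squared distance at initialisation is ≈5·10³
(measured on a probe batch). The reference studies therefore use
m = 5000 (`molfewshot.reference_loss_config()`), which makes the repulsion
hinge active from the start. The `LossConfig` default of m = 1.0 is only
appropriate for unit-scale embeddings. With a margin far below the distance
scale the contrastive term degenerates to pure within-class attraction,
which in pilot runs destabilised test-time adaptation.

## Episodic training

Meta-training uses a first-order MAML-style loop. Per outer step, for each
episode in the meta-batch (default 1): clone the parameters, take
`inner_steps` (default 1) plain-gradient steps on the support-set combined
loss, then evaluate the combined loss on the episode under the adapted
parameters — cross-entropy on the query set, contrastive pairs over
support ∪ query (both are labelled during meta-training). The query
gradient at the adapted point approximates the meta-gradient (first order;
differentiating through the inner updates is not implemented) and is
averaged over the meta-batch, clipped to a global L2 norm of 5, and applied
to the base parameters with Adam (lr 1e-3). The clock t increments once per
outer step and drives f(t). Gradient clipping is required because the
unnormalised pair sums produce very large early gradients.

Support sets are class-balanced by construction — exactly k per class
regardless of pool imbalance ("10-shot" = 10 + 10); the imbalance expresses
itself in the query set. Meta-training queries are fixed-size (32,
stratified to the residual pool ratio) to bound step cost; meta-testing
queries are the entire remainder of the task pool.

## Meta-testing

For each run (distinct seed) and each held-out task: draw a support set,
fine-tune a parameter clone for `finetune_steps_at_test` (default 80) Adam
steps (lr 0.02) on the support-set combined loss — Adam because it is
robust to the contrastive term's scale — then score the query set with the
positive-class probability. Contrastive pairs at test time use the support
set only; query labels are never touched. Scoring uses the query batch's
own normalisation statistics (transductive batch norm, standard in the MAML
lineage); the dynamic fraction at test time is the schedule's terminal
value α_end. AUC is rank-based (Mann–Whitney, ties half-credit). Query sets
containing a single class yield an undefined AUC, which is warned about and
excluded from aggregation rather than imputed. The report aggregates mean ±
standard deviation over all (task, run) AUCs; base parameters are verified
unchanged after evaluation.

## Synthetic task families

The generator emulates a multi-task bioactivity panel without external
data. Each task carries a secret connected labelled subgraph (motif,
default 3 atoms) over a shared vocabulary {C, N, O, S}; a molecule is
positive iff it contains the motif. Background molecules are random
valence-legal trees of 8–16 heavy atoms (carbon-rich element draw, 30%
chance of one ring closure), assembled with RDKit and emitted as valid
SMILES so synthetic data traverses the same parsing path as real data.
Positives are grown around an embedded motif copy; negatives are
rejection-sampled against a substructure match, making the labels exact by
construction (and independently verifiable by subgraph isomorphism). The
positive fraction per task is exact (round(fraction · n)); presets
"imbalanced" (1–20% positives) and "balanced" (30–60%) reproduce the two
imbalance regimes of real panels.

What this emulates: many related tasks over a shared chemistry whose labels
are structure-determined — the premise that makes transfer measurable. What
it does not emulate: realistic medicinal-chemistry distributions, bond-order
or stereochemical diversity, label noise, and activity cliffs
(near-identical graphs with opposite labels). Passing the synthetic studies
therefore demonstrates that the machinery learns structure-determined
labels under imbalance; it does not certify benchmark-level performance on
real assay panels.

## Reference studies and sizes

The stock studies (`molfewshot.studies`) fix the following sizes, chosen to
exercise the full pipeline at desk scale:

* **recovery** — 25 tasks (20 meta-train / 5 meta-test), 150 molecules per
  task at 20% positives; 300 outer steps; evaluated at k=10 and k=1 over
  seeded runs. Typical mean 10-shot meta-test AUC is ≈0.84 (chance 0.5),
  with 1-shot clearly lower — more shots help.
* **ablation** — same layout with 200 molecules per task at 5% positives,
  k=3 (a low shot count keeps adaptation signal scarce, the regime the
  contrastive term targets); full objective vs `wc`, two support draws per
  task per run to reduce protocol noise.
* **separation** — silhouette of the 2-D PCA projection (components by
  eigen-decomposition of the covariance, signs fixed by the
  largest-magnitude loading) of a held-out task's query embeddings, trained
  encoder vs random initialisation under the identical adaptation protocol.

## Numerical choices

* Batch norm: ε = 1e-5, momentum 0.1; training mode uses batch statistics
  (population update with Bessel correction), evaluation mode running
  statistics, except query scoring which is transductive (above). Batches
  of one sample fall back to running statistics.
* Gradient clipping: global L2 norm 5 on inner, outer and fine-tuning
  updates.
* Hard-pair ties broken lexicographically by (i, j); selection size
  ⌈fraction·|K|⌉.
* Xavier-uniform initialisation everywhere; ε_l initialised to 0.
* Episode sampling, parameter initialisation and dropout are all driven by
  seeded NumPy generators; single-threaded runs are bit-reproducible.

## Known limitations

* Second-order meta-gradients are not implemented (`first_order=False`
  raises).
* The contrastive pair sums grow quadratically with episode size; episodes
  beyond a few hundred samples become slow on the bundled NumPy engine.
* The generator's chemistry is deliberately narrow (four elements, single
  bonds, small rings); it is a testbed, not a benchmark.
* The full-vs-wc ablation margin on synthetic families is small relative to
  seed noise; the reference study averages ten runs to resolve it.
* The PCA-silhouette diagnostic does not show a training benefit on these
  synthetic families: motif labels correlate with element composition,
  which a randomly initialised sum-pooling GIN already exposes as its
  dominant embedding variance, so the random baseline's top-2-PCA
  silhouette matches or exceeds the trained encoder's even though the
  trained encoder adapts to far higher query AUC. The separation study
  reports this contrast honestly; on real assay panels, where labels are
  not composition-determined, the diagnostic may behave differently.
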