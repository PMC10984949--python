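"""Synthetic motif-labelled molecular task families.

Emulates the structure of multi-task bioactivity benchmarks without any
external data: a family of binary tasks over small organic molecules built
from a shared atom vocabulary. Each task carries a secret structural motif
(a connected labelled subgraph, by default a 3-atom pattern); a molecule is
*positive* for the task iff it contains that motif as a subgraph. Background
molecules are random valence-legal trees (with occasional ring closures)
over the same vocabulary, so tasks are related — the premise that makes
meta-learning transfer measurable — yet each requires recognising its own
substructure.

The positive-class proportion is controllable per task, covering the range
seen in real property-prediction collections: near-balanced tasks down to
heavily imbalanced ones where positives are rare. Presets ``"imbalanced"``
(fractions in [0.01, 0.2]) and ``"balanced"`` (fractions in [0.3, 0.6])
reproduce those two regimes.

Every emitted molecule is assembled with RDKit and written as a valid
SMILES string, so the downstream pipeline consumes synthetic data through
exactly the same parsing path as real data. Construction guarantees the
label: positives are grown around an embedded copy of the motif, negatives
are rejection-sampled against an RDKit substructure match.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from rdkit import Chem

from .chem_io import MISSING, TaskSplit, TaskTable

# Maximum single-bond connections per element in generated molecules.
_VALENCE = {"C": 4, "N": 3, "O": 2, "S": 2}
# Background element draw; carbon-rich like real organic chemistry.
_ELEMENT_WEIGHTS = {"C": 0.6, "N": 0.2, "O": 0.15, "S": 0.05}

_MAX_NEGATIVE_TRIES = 500


@dataclass
class SyntheticSpec:
    """Parameters of a synthetic task family."""

    n_tasks: int = 25
    n_molecules_per_task: int = 150
    positive_fraction: float = 0.2
    atom_vocabulary: list = field(default_factory=lambda: ["C", "N", "O", "S"])
    motif_size: int = 3
    seed: int = 0
    min_atoms: int = 8
    max_atoms: int = 16
    ring_prob: float = 0.3
    # optional per-task override of positive_fraction (len == n_tasks)
    positive_fractions: Optional[list] = None

    def __post_init__(self):
        if self.n_tasks < 1 or self.n_molecules_per_task < 2:
            raise ValueError("need >=1 task and >=2 molecules per task")
        if self.motif_size < 2:
            raise ValueError("motif_size must be >= 2")
        if not all(e in _VALENCE for e in self.atom_vocabulary):
            raise ValueError(f"vocabulary limited to {sorted(_VALENCE)}")
        if self.min_atoms < self.motif_size or self.max_atoms < self.min_atoms:
            raise ValueError("need motif_size <= min_atoms <= max_atoms")
        fracs = self.positive_fractions or [self.positive_fraction] * self.n_tasks
        if len(fracs) != self.n_tasks:
            raise ValueError("positive_fractions must have one entry per task")
        for f in fracs:
            n_pos = round(f * self.n_molecules_per_task)
            if not 0 < f < 1 or n_pos < 1 or n_pos > self.n_molecules_per_task - 1:
                raise ValueError(
                    f"positive fraction {f} infeasible at "
                    f"{self.n_molecules_per_task} molecules/task"
                )

    def task_fractions(self) -> list:
        return list(self.positive_fractions or
                    [self.positive_fraction] * self.n_tasks)


@dataclass
class SyntheticFamily:
    """A generated family plus its per-task ground-truth motifs."""

    table: TaskTable
    split: TaskSplit
    motifs: dict  # task name -> motif SMILES


def preset_spec(name: str, seed: int = 0, **overrides) -> SyntheticSpec:
    """Stock imbalance profiles: 'imbalanced' (1–20% positives) or 'balanced'."""
    rng = np.random.default_rng([seed, 97])
    n_tasks = overrides.pop("n_tasks", 25)
    n_mol = overrides.pop("n_molecules_per_task", 150)
    if name == "imbalanced":
        lo, hi = 0.01, 0.2
    elif name == "balanced":
        lo, hi = 0.3, 0.6
    else:
        raise ValueError(f"unknown preset {name!r}; use 'imbalanced' or 'balanced'")
    fracs = []
    for _ in range(n_tasks):
        f = float(rng.uniform(lo, hi))
        f = max(f, 1.5 / n_mol)  # keep at least one positive per task
        fracs.append(f)
    return SyntheticSpec(n_tasks=n_tasks, n_molecules_per_task=n_mol,
                         positive_fraction=float(np.mean(fracs)),
                         positive_fractions=fracs, seed=seed, **overrides)


# -- molecule construction ---------------------------------------------------

def _free_valence(mol: Chem.RWMol, idx: int) -> int:
    atom = mol.GetAtomWithIdx(idx)
    return _VALENCE[atom.GetSymbol()] - atom.GetDegree()


def _grow_tree(mol: Chem.RWMol, rng: np.random.Generator, vocab: list,
               weights: np.ndarray, target_atoms: int) -> None:
    """Attach weighted-random atoms with single bonds until target size."""
    while mol.GetNumAtoms() < target_atoms:
        anchors = [i for i in range(mol.GetNumAtoms()) if _free_valence(mol, i) > 0]
        if not anchors:
            break
        anchor = int(rng.choice(anchors))
        sym = vocab[int(rng.choice(len(vocab), p=weights))]
        new_idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(anchor, new_idx, Chem.BondType.SINGLE)


def _maybe_close_ring(mol: Chem.RWMol, rng: np.random.Generator,
                      ring_prob: float) -> None:
    if rng.random() >= ring_prob:
        return
    n = mol.GetNumAtoms()
    candidates = [
        (i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if mol.GetBondBetweenAtoms(i, j) is None
        and _free_valence(mol, i) > 0
        and _free_valence(mol, j) > 0
    ]
    if candidates:
        i, j = candidates[int(rng.choice(len(candidates)))]
        mol.AddBond(i, j, Chem.BondType.SINGLE)


def _finish(mol: Chem.RWMol) -> str:
    out = mol.GetMol()
    Chem.SanitizeMol(out)
    return Chem.MolToSmiles(out)


def _random_motif(rng: np.random.Generator, vocab: list, size: int) -> str:
    """A random connected labelled tree of `size` atoms (single bonds)."""
    mol = Chem.RWMol()
    mol.AddAtom(Chem.Atom(vocab[int(rng.choice(len(vocab)))]))
    while mol.GetNumAtoms() < size:
        anchors = [i for i in range(mol.GetNumAtoms()) if _free_valence(mol, i) > 0]
        anchor = int(rng.choice(anchors))
        sym = vocab[int(rng.choice(len(vocab)))]
        idx = mol.AddAtom(Chem.Atom(sym))
        mol.AddBond(anchor, idx, Chem.BondType.SINGLE)
    return _finish(mol)


def _sample_molecule(rng: np.random.Generator, spec: SyntheticSpec,
                     weights: np.ndarray, motif: Optional[Chem.Mol]) -> str:
    """One random molecule; grown around an embedded motif copy if given."""
    mol = Chem.RWMol()
    if motif is not None:
        mol.InsertMol(motif)
    else:
        sym = spec.atom_vocabulary[int(rng.choice(len(spec.atom_vocabulary),
                                                  p=weights))]
        mol.AddAtom(Chem.Atom(sym))
    target = int(rng.integers(spec.min_atoms, spec.max_atoms + 1))
    _grow_tree(mol, rng, spec.atom_vocabulary, weights, target)
    _maybe_close_ring(mol, rng, spec.ring_prob)
    return _finish(mol)


def contains_motif(smiles: str, motif_smiles: str) -> bool:
    """Substructure containment of the motif pattern in a molecule."""
    mol = Chem.MolFromSmiles(smiles)
    patt = Chem.MolFromSmiles(motif_smiles)
    return mol.HasSubstructMatch(patt)


def generate_family(spec: SyntheticSpec) -> SyntheticFamily:
    """Generate the full family: table, train/test split and motif registry.

    Each molecule is labelled for exactly one task (cells for other tasks
    stay missing, as in sparse multi-task benchmark tables). The number of
    positives per task is exact: round(fraction * n_molecules). The final
    ceil(25%) of tasks form the meta-test split.
    """
    rng = np.random.default_rng(spec.seed)
    weights = np.array([_ELEMENT_WEIGHTS[e] for e in spec.atom_vocabulary])
    weights = weights / weights.sum()

    motifs: dict = {}
    seen_motifs: set = set()
    task_names = [f"task_{i:03d}" for i in range(spec.n_tasks)]
    for name in task_names:
        for _ in range(1000):
            m = _random_motif(rng, spec.atom_vocabulary, spec.motif_size)
            if m not in seen_motifs:
                seen_motifs.add(m)
                motifs[name] = m
                break
        else:
            raise ValueError(
                f"cannot draw {spec.n_tasks} distinct motifs of size "
                f"{spec.motif_size} over {spec.atom_vocabulary}"
            )

    records = []
    for name, frac in zip(task_names, spec.task_fractions()):
        patt = Chem.MolFromSmiles(motifs[name])
        n_pos = round(frac * spec.n_molecules_per_task)
        n_neg = spec.n_molecules_per_task - n_pos
        task_rows = []
        for _ in range(n_pos):
            smiles = _sample_molecule(rng, spec, weights, motif=patt)
            task_rows.append((smiles, 1))
        for _ in range(n_neg):
            for _try in range(_MAX_NEGATIVE_TRIES):
                smiles = _sample_molecule(rng, spec, weights, motif=None)
                if not contains_motif(smiles, motifs[name]):
                    task_rows.append((smiles, 0))
                    break
            else:
                raise ValueError(
                    f"cannot sample a motif-free molecule for {name} "
                    f"(motif {motifs[name]!r} too common)"
                )
        for smiles, y in task_rows:
            labels = {t: MISSING for t in task_names}
            labels[name] = y
            records.append((smiles, labels))

    table = TaskTable(records=records, task_names=task_names)
    n_test = int(np.ceil(0.25 * spec.n_tasks))
    split = TaskSplit(train_tasks=task_names[:-n_test] if n_test else task_names,
                      test_tasks=task_names[-n_test:] if n_test else [])
    return SyntheticFamily(table=table, split=split, motifs=motifs)


def generate_task_family(spec: SyntheticSpec) -> tuple:
    """(TaskTable, TaskSplit) view of :func:`generate_family`."""
    fam = generate_family(spec)
    return fam.table, fam.split


def fixture_smiles() -> list:
    """Hand-curated (smiles, heavy-atom count, bond count) triples.

    Small named molecules with independently verifiable counts; hydrogens
    are implicit, so they appear in neither count.
    """
    return [
        ("C", 1, 0),                            # methane
        ("CCO", 3, 2),                          # ethanol
        ("c1ccccc1", 6, 6),                     # benzene
        ("c1ccncc1", 6, 6),                     # pyridine
        ("CC(=O)O", 4, 3),                      # acetic acid
        ("C1CCCCC1", 6, 6),                     # cyclohexane
        ("Cc1ccccc1", 7, 7),                    # toluene
        ("CC#N", 3, 2),                         # acetonitrile
        ("C=O", 2, 1),                          # formaldehyde
        ("CC(C)C", 4, 3),                       # isobutane
        ("CC(=O)Oc1ccccc1C(=O)O", 13, 13),      # aspirin
        ("Cn1cnc2c1c(=O)n(C)c(=O)n2C", 14, 15), # caffeine
    ]
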