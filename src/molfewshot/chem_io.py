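"""SMILES parsing into attributed molecular graphs and multi-task table IO.

Molecules enter the pipeline as SMILES strings and are converted with RDKit
into :class:`MolecularGraph` objects holding categorical atom and bond codes.
The feature vocabulary is deliberately minimal — per atom the atomic number
and chirality tag, per bond the bond type and bond direction — which is the
feature set used by the attribute-masking GIN pretraining lineage, so that
externally produced encoder checkpoints remain interchangeable.

Label tables follow the MoleculeNet layout: a CSV with one ``smiles`` column
and one column per binary task, cells in {1, 0, empty}; empty means the
compound is unlabeled for that task and is never coerced to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")  # parse errors are raised, not printed

# Vocabulary sizes for the categorical codes (atomic number capped at 118).
NUM_ATOM_TYPES = 119
NUM_CHIRALITY_TAGS = 4
NUM_BOND_TYPES = 4
NUM_BOND_DIRECTIONS = 3

_CHIRALITY = {
    Chem.rdchem.ChiralType.CHI_UNSPECIFIED: 0,
    Chem.rdchem.ChiralType.CHI_TETRAHEDRAL_CW: 1,
    Chem.rdchem.ChiralType.CHI_TETRAHEDRAL_CCW: 2,
    Chem.rdchem.ChiralType.CHI_OTHER: 3,
}
_BOND_TYPE = {
    Chem.rdchem.BondType.SINGLE: 0,
    Chem.rdchem.BondType.DOUBLE: 1,
    Chem.rdchem.BondType.TRIPLE: 2,
    Chem.rdchem.BondType.AROMATIC: 3,
}
_BOND_DIR = {
    Chem.rdchem.BondDir.NONE: 0,
    Chem.rdchem.BondDir.ENDUPRIGHT: 1,
    Chem.rdchem.BondDir.ENDDOWNRIGHT: 2,
}

MISSING = None  # sentinel for an unlabeled cell


class SmilesParseError(ValueError):
    """Raised when a SMILES string cannot be parsed into a molecule."""


@dataclass
class MolecularGraph:
    """Attributed molecular graph (hydrogens implicit).

    ``node_features``: (n_atoms, 2) int codes [atomic number, chirality tag].
    ``edge_index``: (2, n_edges) int; every bond stored in both directions.
    ``edge_features``: (n_edges, 2) int codes [bond type, bond direction].
    """

    node_features: np.ndarray
    edge_index: np.ndarray
    edge_features: np.ndarray
    smiles: str

    @property
    def n_atoms(self) -> int:
        return self.node_features.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edge_index.shape[1]

    def validate(self) -> None:
        if self.n_atoms < 1:
            raise ValueError("graph must contain at least one atom")
        if self.n_edges and self.edge_index.max() >= self.n_atoms:
            raise ValueError("edge endpoint out of range")
        # symmetry: the set of directed edges is closed under reversal
        fwd = {(int(a), int(b)) for a, b in self.edge_index.T}
        if {(b, a) for a, b in fwd} != fwd:
            raise ValueError("edge list is not symmetric")


def parse_smiles(smiles: str) -> MolecularGraph:
    """Convert a SMILES string to a :class:`MolecularGraph`.

    Raises :class:`SmilesParseError` naming the offending string on invalid
    input; never skips silently. Deterministic: identical strings produce
    identical graphs.
    """
    if not smiles:
        raise SmilesParseError("empty SMILES string")
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    nf = np.array(
        [[a.GetAtomicNum(), _CHIRALITY.get(a.GetChiralTag(), 3)] for a in mol.GetAtoms()],
        dtype=np.int64,
    ).reshape(-1, 2)
    src, dst, ef = [], [], []
    for bond in mol.GetBonds():
        i, j = bond.GetBeginAtomIdx(), bond.GetEndAtomIdx()
        code = [_BOND_TYPE[bond.GetBondType()], _BOND_DIR.get(bond.GetBondDir(), 0)]
        src += [i, j]
        dst += [j, i]
        ef += [code, code]
    return MolecularGraph(
        node_features=nf,
        edge_index=np.array([src, dst], dtype=np.int64).reshape(2, -1),
        edge_features=np.array(ef, dtype=np.int64).reshape(-1, 2),
        smiles=smiles,
    )


def canonical_smiles(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesParseError(f"cannot parse SMILES: {smiles!r}")
    return Chem.MolToSmiles(mol)


@dataclass
class TaskTable:
    """Multi-task binary label table over a shared compound list."""

    records: list  # list of (smiles, {task -> 0/1/None})
    task_names: list = field(default_factory=list)

    def __post_init__(self):
        if not self.task_names:
            raise ValueError("task_names must be non-empty")
        if len(set(self.task_names)) != len(self.task_names):
            raise ValueError("task names must be unique")

    def __len__(self):
        return len(self.records)


@dataclass
class TaskSplit:
    """Which task columns are used for meta-training vs meta-testing."""

    train_tasks: list
    test_tasks: list

    def validate(self, table: TaskTable) -> None:
        if set(self.train_tasks) & set(self.test_tasks):
            raise ValueError("train and test task sets overlap")
        unknown = (set(self.train_tasks) | set(self.test_tasks)) - set(table.task_names)
        if unknown:
            raise ValueError(f"split references unknown tasks: {sorted(unknown)}")


def read_task_table(path) -> TaskTable:
    """Read a MoleculeNet-style CSV: `smiles` column + one column per task.

    Label cells must be "1", "0" or empty; anything else is an error. Empty
    cells stay missing (None). Row order is preserved.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if df.empty and df.columns.empty:
        raise ValueError(f"empty task table: {path}")
    if "smiles" not in df.columns:
        raise ValueError(f"no 'smiles' column in {path}")
    task_names = [c for c in df.columns if c != "smiles"]
    if not task_names:
        raise ValueError(f"no task columns in {path}")
    records = []
    for idx, row in df.iterrows():
        labels = {}
        for t in task_names:
            cell = row[t].strip()
            if cell == "":
                labels[t] = MISSING
            elif cell in ("0", "1"):
                labels[t] = int(cell)
            else:
                raise ValueError(
                    f"row {idx}, task {t!r}: label {cell!r} not in {{0, 1, empty}}"
                )
        if all(v is MISSING for v in labels.values()):
            raise ValueError(f"row {idx} ({row['smiles']!r}) has no label for any task")
        records.append((row["smiles"], labels))
    return TaskTable(records=records, task_names=task_names)


def write_task_table(table: TaskTable, path) -> None:
    rows = []
    for smiles, labels in table.records:
        row = {"smiles": smiles}
        for t in table.task_names:
            v = labels.get(t, MISSING)
            row[t] = "" if v is MISSING else str(int(v))
        rows.append(row)
    pd.DataFrame(rows, columns=["smiles"] + list(table.task_names)).to_csv(
        path, index=False
    )


def read_task_split(path) -> TaskSplit:
    with open(path) as fh:
        data = json.load(fh)
    return TaskSplit(train_tasks=list(data["train_tasks"]),
                     test_tasks=list(data["test_tasks"]))


def write_task_split(split: TaskSplit, path) -> None:
    Path(path).write_text(
        json.dumps({"train_tasks": split.train_tasks, "test_tasks": split.test_tasks},
                   indent=2)
    )


def task_dataset(table: TaskTable, task: str) -> list:
    """Graph/label pairs for one task; rows missing that task's label drop out.

    Raises if the task ends up with zero positives or zero negatives —
    few-shot episodes would be impossible.
    """
    if task not in table.task_names:
        raise KeyError(f"unknown task {task!r}")
    pairs = []
    for smiles, labels in table.records:
        y = labels.get(task, MISSING)
        if y is MISSING:
            continue
        pairs.append((parse_smiles(smiles), int(y)))
    n_pos = sum(1 for _, y in pairs if y == 1)
    n_neg = len(pairs) - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError(
            f"task {task!r} has {n_pos} positives / {n_neg} negatives; "
            "both classes are required"
        )
    return pairs
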