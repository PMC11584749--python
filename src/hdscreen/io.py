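"""Dataset ingestion, evaluation splits, and result files.

Molecule tables are delimited text (CSV/TSV) with configurable column
names for id, SMILES and binary activity label.  Feature matrices
(precomputed per-molecule embeddings) are dense delimited text with one
row per molecule, row order contractually matching the molecule table.

Two split strategies are provided:

* **scaffold split** — molecules are grouped by Bemis–Murcko scaffold
  and whole scaffold groups are assigned greedily (largest group
  first) to train, then validation, then test, so no scaffold spans
  partitions; this tests generalisation to novel chemotypes.
* **stratified split** — random split preserving the class ratio
  (default 75% train / 25% test), the usual control split for skewed
  screening decks.

External precomputed splits are accepted as plain id-list files.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.model_selection import train_test_split

from .am import RankedScreen

logger = logging.getLogger("hdscreen")

__all__ = [
    "MoleculeTable",
    "DatasetSplit",
    "read_molecule_table",
    "read_feature_matrix",
    "scaffold_split",
    "stratified_split",
    "write_screen_results",
    "read_screen_results",
    "write_split",
    "read_split",
]


@dataclass
class MoleculeTable:
    """Validated molecule records in file order.

    ``ids`` are unique strings, ``smiles`` parseable SMILES, ``labels``
    optional binary {0,1} activities.  ``n_skipped`` counts rows
    dropped for unparseable SMILES.
    """

    ids: list[str]
    smiles: list[str]
    labels: np.ndarray | None = None
    n_skipped: int = 0

    def __len__(self) -> int:
        return len(self.ids)


@dataclass
class DatasetSplit:
    """Disjoint id sets for train / optional validation / test."""

    train_ids: list[str]
    test_ids: list[str]
    valid_ids: list[str] = field(default_factory=list)
    method: str = "external"
    seed: int = 0

    def __post_init__(self) -> None:
        parts = [set(self.train_ids), set(self.valid_ids), set(self.test_ids)]
        total = sum(len(p) for p in parts)
        if len(parts[0] | parts[1] | parts[2]) != total:
            raise ValueError("split partitions must be disjoint")
        if not self.train_ids or not self.test_ids:
            raise ValueError("train and test partitions must be non-empty")


def read_molecule_table(
    path,
    smiles_col: str = "smiles",
    label_col: str | None = "label",
    id_col: str | None = None,
    sep: str | None = None,
) -> MoleculeTable:
    """Read a delimited molecule table into a validated :class:`MoleculeTable`.

    Rows whose SMILES fails to parse are skipped with a logged count
    (the skip policy for dataset-level ingestion; single-molecule APIs
    raise instead).  Duplicate ids and missing columns are hard errors.
    When ``id_col`` is None, ids are the 0-based row indices as strings.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype=str)
    if df.empty:
        raise ValueError(f"molecule table {path} is empty")
    for col in filter(None, (smiles_col, label_col, id_col)):
        if col not in df.columns:
            raise ValueError(
                f"column {col!r} not found in {path}; columns: {list(df.columns)}"
            )
    ids = (
        df[id_col].astype(str).tolist()
        if id_col
        else [str(i) for i in range(len(df))]
    )
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})[:5]
        raise ValueError(f"duplicate molecule ids in {path}: {dupes}")

    keep_ids: list[str] = []
    keep_smiles: list[str] = []
    keep_rows: list[int] = []
    n_skipped = 0
    for row, (mid, smi) in enumerate(zip(ids, df[smiles_col].astype(str))):
        if not smi or Chem.MolFromSmiles(smi) is None:
            n_skipped += 1
            logger.warning("skipping unparseable SMILES at row %d: %r", row, smi)
            continue
        keep_ids.append(mid)
        keep_smiles.append(smi)
        keep_rows.append(row)
    if n_skipped:
        logger.info("skipped %d unparseable SMILES in %s", n_skipped, path)
    if not keep_ids:
        raise ValueError(f"no valid SMILES rows in {path}")

    labels = None
    if label_col:
        raw = df[label_col].iloc[keep_rows].tolist()
        try:
            labels = np.array([int(v) for v in raw], dtype=np.int64)
        except (TypeError, ValueError):
            raise ValueError(f"labels in {path} must be integers 0 or 1")
        if not np.isin(labels, (0, 1)).all():
            bad = sorted(set(labels.tolist()) - {0, 1})
            raise ValueError(f"labels must be binary {{0,1}}; found {bad}")
    return MoleculeTable(ids=keep_ids, smiles=keep_smiles, labels=labels, n_skipped=n_skipped)


def read_feature_matrix(path, n_expected: int | None = None, sep: str | None = None) -> np.ndarray:
    """Read a dense per-molecule embedding matrix from delimited text.

    One row per molecule, in the same order as the molecule table.  A
    row-count mismatch against ``n_expected`` is a hard error (never a
    truncation); non-finite entries are rejected.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    mat = np.loadtxt(path, delimiter=sep, ndmin=2)
    if n_expected is not None and mat.shape[0] != n_expected:
        raise ValueError(
            f"feature matrix {path} has {mat.shape[0]} rows; molecule table has "
            f"{n_expected} — row orders must match exactly"
        )
    if not np.all(np.isfinite(mat)):
        raise ValueError(f"feature matrix {path} contains non-finite entries")
    return mat


def _murcko_scaffold(smiles: str) -> str:
    mol = Chem.MolFromSmiles(smiles)
    return MurckoScaffold.MurckoScaffoldSmiles(mol=mol) if mol is not None else ""


def scaffold_split(
    table: MoleculeTable,
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
) -> DatasetSplit:
    """Bemis–Murcko scaffold split with greedy largest-group-first assignment.

    ``fractions`` are (train, valid, test) and must sum to 1; a zero
    validation fraction yields a two-way split.  Each scaffold group
    goes entirely to the currently least-filled-relative-to-target
    partition, largest groups first (ties in group size broken by a
    seeded shuffle, then deterministically by scaffold string), so no
    scaffold spans partitions.  Partition sizes land within one
    largest-group size of the requested fractions.
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    if any(f < 0 for f in fractions):
        raise ValueError(f"fractions must be non-negative, got {fractions}")
    groups: dict[str, list[str]] = {}
    for mid, smi in zip(table.ids, table.smiles):
        groups.setdefault(_murcko_scaffold(smi), []).append(mid)

    n_active_parts = sum(1 for f in fractions if f > 0)
    if len(groups) < n_active_parts:
        raise ValueError(
            f"only {len(groups)} distinct scaffolds for {n_active_parts} partitions; "
            "consider a stratified split instead"
        )
    rng = np.random.default_rng(seed)
    keys = sorted(groups)
    rng.shuffle(keys)
    keys.sort(key=lambda k: -len(groups[k]))  # stable: keeps shuffled order within size ties

    n_total = len(table)
    targets = [f * n_total for f in fractions]
    parts: list[list[str]] = [[], [], []]
    for key in keys:
        members = groups[key]
        # fill deficit-first among partitions with a positive target
        deficits = [
            (targets[j] - len(parts[j]), j) for j in range(3) if fractions[j] > 0
        ]
        j = max(deficits, key=lambda t: (t[0], -t[1]))[1]
        parts[j].extend(members)
    train, valid, test = parts
    if not train or not test:
        raise ValueError(
            "scaffold split left train or test empty; consider a stratified split"
        )
    return DatasetSplit(
        train_ids=train, valid_ids=valid, test_ids=test, method="scaffold", seed=seed
    )


def stratified_split(
    table: MoleculeTable, train_fraction: float = 0.75, seed: int = 0
) -> DatasetSplit:
    """Random class-stratified train/test split (default 75%/25%)."""
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0, 1), got {train_fraction}")
    if table.labels is None:
        raise ValueError("stratified split requires activity labels")
    classes, counts = np.unique(table.labels, return_counts=True)
    if classes.size < 2:
        raise ValueError("stratified split requires both classes present")
    if counts.min() < 2:
        raise ValueError(
            "each class needs at least 2 members for a stratified split"
        )
    train_ids, test_ids = train_test_split(
        table.ids,
        train_size=train_fraction,
        stratify=table.labels,
        random_state=seed,
    )
    return DatasetSplit(
        train_ids=list(train_ids), test_ids=list(test_ids),
        method="stratified", seed=seed,
    )


def write_split(split: DatasetSplit, path) -> None:
    """Write a split as a two-column CSV: id, partition."""
    rows = (
        [(i, "train") for i in split.train_ids]
        + [(i, "valid") for i in split.valid_ids]
        + [(i, "test") for i in split.test_ids]
    )
    pd.DataFrame(rows, columns=["id", "partition"]).to_csv(path, index=False)


def read_split(path) -> DatasetSplit:
    """Read an id-list split file (columns id, partition)."""
    df = pd.read_csv(path, dtype=str)
    for col in ("id", "partition"):
        if col not in df.columns:
            raise ValueError(f"split file {path} missing column {col!r}")
    by_part = {p: df.loc[df["partition"] == p, "id"].tolist() for p in ("train", "valid", "test")}
    return DatasetSplit(
        train_ids=by_part["train"], valid_ids=by_part["valid"], test_ids=by_part["test"],
        method="external",
    )


def write_screen_results(screen: RankedScreen, path) -> None:
    """Write a ranked screen as delimited text: id, eta, (label,) rank.

    Scores round-trip at 12 significant digits, enough to preserve the
    ranking exactly on re-read.
    """
    if len(screen) == 0:
        raise ValueError("cannot write an empty screen")
    ids = screen.ids if screen.ids is not None else np.arange(len(screen))
    cols: dict[str, object] = {
        "id": ids,
        "eta": [f"{s:.12g}" for s in screen.scores],
    }
    if screen.labels is not None:
        cols["label"] = screen.labels
    cols["rank"] = np.arange(1, len(screen) + 1)
    pd.DataFrame(cols).to_csv(path, index=False)


def read_screen_results(path) -> RankedScreen:
    """Round-trip reader for :func:`write_screen_results` output."""
    df = pd.read_csv(path, dtype={"id": str})
    labels = df["label"].to_numpy(dtype=np.int64) if "label" in df.columns else None
    return RankedScreen(
        scores=df["eta"].to_numpy(dtype=np.float64),
        ids=df["id"].to_numpy(),
        labels=labels,
    )
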