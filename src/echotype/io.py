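"""Signal/manifest I/O and stratified cross-validation fold assignment.

Signals live in newline-delimited decimal text files; a UTF-8 CSV manifest
(columns ``id,path,label[,material,diameter_um,seed]``) indexes them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.model_selection import StratifiedKFold


@dataclass
class SignalRecord:
    id: str
    samples: np.ndarray
    label: str
    metadata: dict = field(default_factory=dict)


@dataclass
class LabeledSignalSet:
    """Uniform-length labeled signals plus an optional train/test role tag.

    ``positive_label`` names the class mapped to 1 when labels are binarized
    (precision/recall are reported for this class); by default the first
    class in alphabetical order.
    """

    records: list[SignalRecord]
    positive_label: str | None = None
    role: str | None = None  # "train" | "test" | None

    def __post_init__(self):
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate record ids in dataset")
        lengths = {len(r.samples) for r in self.records}
        if len(lengths) > 1:
            raise ValueError(f"signals have inconsistent lengths: {sorted(lengths)}")
        if self.positive_label is None and self.records:
            self.positive_label = sorted({r.label for r in self.records})[0]

    def __len__(self):
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    @property
    def labels(self) -> list[str]:
        return [r.label for r in self.records]

    @property
    def classes(self) -> list[str]:
        return sorted({r.label for r in self.records})

    def binary_labels(self) -> np.ndarray:
        """0/1 vector with 1 for the positive class; requires 2 classes."""
        if len(self.classes) != 2:
            raise ValueError(f"binary task needs exactly 2 classes, found {self.classes}")
        if self.positive_label not in self.classes:
            raise ValueError(f"positive label {self.positive_label!r} not among {self.classes}")
        return np.array([1 if r.label == self.positive_label else 0 for r in self.records])

    def signal_matrix(self) -> np.ndarray:
        return np.stack([r.samples for r in self.records])

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def subset(self, ids, role: str | None = None) -> "LabeledSignalSet":
        wanted = set(ids)
        missing = wanted - set(self.ids)
        if missing:
            raise KeyError(f"unknown ids: {sorted(missing)}")
        recs = [r for r in self.records if r.id in wanted]
        return LabeledSignalSet(recs, positive_label=self.positive_label, role=role)


def read_signal_file(path) -> np.ndarray:
    """Read one sample per line; reports the 1-based line of any bad value."""
    path = Path(path)
    values = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            text = line.strip()
            if not text:
                continue
            try:
                values.append(float(text))
            except ValueError as exc:
                raise ValueError(f"{path}: non-numeric value at line {lineno}: {text!r}") from exc
    if not values:
        raise ValueError(f"{path}: empty signal file")
    return np.asarray(values, dtype=float)


def write_signal_file(samples, path) -> None:
    samples = np.asarray(samples, dtype=float)
    if samples.size == 0:
        raise ValueError("refusing to write an empty signal")
    if not np.all(np.isfinite(samples)):
        raise ValueError("signal contains non-finite samples")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for v in samples:
            fh.write(f"{float(v)!r}\n")


_MANIFEST_EXTRAS = ("material", "diameter_um", "seed")


def write_dataset(sset: LabeledSignalSet, out_dir) -> Path:
    """Write per-signal text files plus ``manifest.csv``; returns its path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.csv"
    with manifest.open("w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "path", "label", *_MANIFEST_EXTRAS])
        for rec in sset.records:
            rel = f"{rec.id}.txt"
            write_signal_file(rec.samples, out_dir / rel)
            writer.writerow([rec.id, rel, rec.label] + [rec.metadata.get(k, "") for k in _MANIFEST_EXTRAS])
    return manifest


def load_manifest(path, positive_label: str | None = None) -> LabeledSignalSet:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"manifest not found: {path}")
    records = []
    with path.open("r", encoding="utf-8", newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"id", "path", "label"}
        missing = required - set(reader.fieldnames or [])
        if missing:
            raise ValueError(f"manifest missing columns: {sorted(missing)}")
        for row in reader:
            sig_path = Path(row["path"])
            if not sig_path.is_absolute():
                sig_path = path.parent / sig_path
            if not sig_path.exists():
                raise FileNotFoundError(f"signal file for id {row['id']!r} not found: {sig_path}")
            meta = {k: row[k] for k in _MANIFEST_EXTRAS if k in row and row[k] not in (None, "")}
            records.append(SignalRecord(row["id"], read_signal_file(sig_path), row["label"], meta))
    return LabeledSignalSet(records, positive_label=positive_label)


@dataclass
class FoldAssignment:
    k: int
    fold_of: dict[str, int]

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.fold_of.items() if f == fold]

    def train_test_ids(self, fold: int) -> tuple[list[str], list[str]]:
        test = self.fold_ids(fold)
        train = [i for i, f in self.fold_of.items() if f != fold]
        return train, test


def stratified_kfold(sset: LabeledSignalSet, k: int, seed: int = 0) -> FoldAssignment:
    """Label-stratified partition into k folds (per-class counts differ <= 1).

    Every signal lands in exactly one test fold, so each is used for testing
    once across the k validation runs.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    counts = sset.class_counts()
    small = {c: n for c, n in counts.items() if n < k}
    if small:
        raise ValueError(f"classes smaller than k={k}: {small}")
    ids = np.array(sset.ids)
    labels = np.array(sset.labels)
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    fold_of: dict[str, int] = {}
    for fold, (_, test_idx) in enumerate(splitter.split(ids, labels)):
        for i in test_idx:
            fold_of[str(ids[i])] = fold
    return FoldAssignment(k=k, fold_of=fold_of)
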