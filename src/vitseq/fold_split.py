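"""Stratified 10-fold cross-validation splits at the subject level.

The split is specified as an explicit algorithm rather than a library call
so behaviour is reproducible independent of library versions: subjects are
shuffled per class with the seed and dealt round-robin into ``n_folds`` test
buckets (so test sets partition the cohort and class proportions are
preserved to within one subject), and for each fold the remaining subjects
are divided per class into train/validation with validation fraction
``val_frac`` (the conventional 80/20 division by default).

Splitting is always at subject level — a subject's slices never appear in
two subsets of the same fold.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .errors import DataError, ParameterError, StratificationError
from .vit_features import CLASS_NAMES, FeatureSequence

SUBSET_NAMES = ("train", "valid", "test")
#: fold-file basenames: <prefix>data_Fold<i>.npy / <prefix>lbl_Fold<i>.npy
_FILE_PREFIXES = {"train": "train", "valid": "valid", "test": "test"}


@dataclass(frozen=True)
class FoldSplit:
    """Disjoint train/validation/test subject-id sets for one fold (1-based)."""

    fold_index: int
    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        sets = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        total = sum(len(s) for s in sets)
        if len(set().union(*sets)) != total:
            raise DataError(
                f"fold {self.fold_index}: train/validation/test sets overlap"
            )

    def subset(self, name: str) -> tuple[str, ...]:
        return {"train": self.train_ids, "valid": self.val_ids, "test": self.test_ids}[name]

    @property
    def all_ids(self) -> set[str]:
        return set(self.train_ids) | set(self.val_ids) | set(self.test_ids)


def make_folds(
    sequences: list[FeatureSequence],
    n_folds: int = 10,
    val_frac: float = 0.2,
    seed: int = 0,
) -> list[FoldSplit]:
    """Build ``n_folds`` stratified subject-level splits.

    Per class, subjects are shuffled once with the seed and dealt round-robin
    into test buckets; for each fold the non-test subjects of each class are
    split into train/validation with ``round(val_frac * n)`` validation
    members (at least 1 when two or more remain, and always leaving at least
    one training subject). Identical seeds give identical folds.
    """
    if n_folds < 2:
        raise ParameterError(f"n_folds must be >= 2, got {n_folds}")
    if not (0.0 < val_frac < 1.0):
        raise ParameterError(f"val_frac must be in (0, 1), got {val_frac}")
    by_class: dict[str, list[str]] = {}
    for seq in sequences:
        by_class.setdefault(seq.label, []).append(seq.subject_id)
    if len(set(sid for ids in by_class.values() for sid in ids)) != len(sequences):
        raise DataError("duplicate subject ids in the dataset")
    for label, ids in by_class.items():
        if len(ids) < n_folds:
            raise StratificationError(
                f"class {label!r} has {len(ids)} subjects, fewer than "
                f"n_folds={n_folds}"
            )
    rng = np.random.default_rng(seed)
    # one permutation per class, in fixed class order for determinism
    permuted = {
        label: [by_class[label][i] for i in rng.permutation(len(by_class[label]))]
        for label in CLASS_NAMES
        if label in by_class
    }
    test_buckets: list[list[str]] = [[] for _ in range(n_folds)]
    for label, ids in permuted.items():
        for m, sid in enumerate(ids):
            test_buckets[m % n_folds].append(sid)
    folds = []
    for i in range(n_folds):
        test = set(test_buckets[i])
        train: list[str] = []
        val: list[str] = []
        for label, ids in permuted.items():
            remainder = [sid for sid in ids if sid not in test]
            n_val = int(round(val_frac * len(remainder)))
            if len(remainder) >= 2:
                n_val = max(1, n_val)
            n_val = min(n_val, max(len(remainder) - 1, 0))
            val.extend(remainder[:n_val])
            train.extend(remainder[n_val:])
        folds.append(
            FoldSplit(
                fold_index=i + 1,
                train_ids=tuple(sorted(train)),
                val_ids=tuple(sorted(val)),
                test_ids=tuple(sorted(test)),
            )
        )
    return folds


def write_fold_files(
    folds: list[FoldSplit],
    sequences: list[FeatureSequence],
    out_dir: str | Path,
    seed: int | None = None,
) -> dict:
    """Emit the six-files-per-fold layout plus a JSON manifest.

    For fold ``i`` the files are ``traindata_Fold<i>.npy`` /
    ``trainlbl_Fold<i>.npy`` and likewise for valid/test. Data files are 3D
    arrays (n_subjects x seq_len x feature_dim); row order matches the
    manifest's per-fold subject-id lists and the label files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    seq_map = {s.subject_id: s for s in sequences}
    manifest: dict = {"n_folds": len(folds), "seed": seed, "folds": []}
    for fold in folds:
        entry: dict = {"fold": fold.fold_index}
        for name in SUBSET_NAMES:
            ids = fold.subset(name)
            missing = [sid for sid in ids if sid not in seq_map]
            if missing:
                raise DataError(
                    f"fold {fold.fold_index} {name}: no stored features for "
                    f"subjects {missing}"
                )
            data = np.stack([seq_map[sid].features for sid in ids])
            labels = np.array([seq_map[sid].label_code for sid in ids], dtype=np.int64)
            prefix = _FILE_PREFIXES[name]
            np.save(out_dir / f"{prefix}data_Fold{fold.fold_index}.npy", data)
            np.save(out_dir / f"{prefix}lbl_Fold{fold.fold_index}.npy", labels)
            entry[name] = list(ids)
        manifest["folds"].append(entry)
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def load_fold(fold_dir: str | Path, fold_index: int) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Load one fold's (data, labels) arrays keyed by subset name."""
    fold_dir = Path(fold_dir)
    out = {}
    for name in SUBSET_NAMES:
        prefix = _FILE_PREFIXES[name]
        data_path = fold_dir / f"{prefix}data_Fold{fold_index}.npy"
        lbl_path = fold_dir / f"{prefix}lbl_Fold{fold_index}.npy"
        if not data_path.exists() or not lbl_path.exists():
            raise DataError(f"missing fold files for fold {fold_index} in {fold_dir}")
        out[name] = (np.load(data_path), np.load(lbl_path))
    return out
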