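"""Compound-disjoint (out-of-sample) data splitting.

The viscosity dataset has repeated compounds at multiple temperatures, so
random row splits leak test compounds into training and flatter the
apparent accuracy. All splits here move *whole compounds*: shuffled
compounds are accumulated into the training side until it first reaches
the target row fraction, and grouped k-fold CV partitions training
compounds into row-balanced folds.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .curation import CuratedDataset


@dataclass
class SplitPlan:
    """Row-index partition of a dataset with compound-disjoint sides."""

    train_row_indices: np.ndarray
    test_row_indices: np.ndarray
    seed: int
    achieved_train_fraction: float

    def __post_init__(self) -> None:
        self.train_row_indices = np.asarray(self.train_row_indices, dtype=int)
        self.test_row_indices = np.asarray(self.test_row_indices, dtype=int)
        overlap = set(self.train_row_indices) & set(self.test_row_indices)
        if overlap:
            raise ValueError(f"train/test rows overlap: {sorted(overlap)[:5]}")

    def to_json(self) -> str:
        return json.dumps(
            {
                "seed": self.seed,
                "train_row_indices": self.train_row_indices.tolist(),
                "test_row_indices": self.test_row_indices.tolist(),
                "achieved_train_fraction": self.achieved_train_fraction,
            }
        )


def _rows_by_compound(compound_ids: list[str]) -> dict[str, list[int]]:
    groups: dict[str, list[int]] = {}
    for i, cid in enumerate(compound_ids):
        groups.setdefault(cid, []).append(i)
    return groups


def out_of_sample_split(
    dataset: CuratedDataset | list[str],
    train_fraction: float = 0.8,
    seed: int = 0,
) -> SplitPlan:
    """Compound-disjoint train/test split.

    Compounds are shuffled by ``seed``; whole compounds enter training
    until the training row count first reaches ``train_fraction`` of all
    rows (slight overshoot allowed), the remainder is the test set.
    Accepts a curated dataset or a bare compound-id-per-row list.
    """
    ids = dataset.compound_ids if isinstance(dataset, CuratedDataset) else list(dataset)
    n = len(ids)
    groups = _rows_by_compound(ids)
    if len(groups) < 2:
        raise ValueError("need >= 2 unique compounds to split")
    rng = np.random.default_rng(seed)
    compounds = list(groups)
    rng.shuffle(compounds)
    target = train_fraction * n
    train_rows: list[int] = []
    test_rows: list[int] = []
    for c in compounds:
        if len(train_rows) < target:
            train_rows.extend(groups[c])
        else:
            test_rows.extend(groups[c])
    if not test_rows:
        # ensure a non-empty test side: move the last-added compound over
        last = compounds[-1]
        train_rows = [i for i in train_rows if ids[i] != last]
        test_rows = groups[last]
    return SplitPlan(
        np.sort(train_rows),
        np.sort(test_rows),
        seed=seed,
        achieved_train_fraction=len(train_rows) / n,
    )


def grouped_kfold(
    train_row_indices: np.ndarray,
    compound_ids: list[str],
    k: int = 5,
    seed: int = 0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Compound-disjoint k-fold plans over the training rows.

    Compounds are shuffled by ``seed`` and assigned greedily largest-first
    to the currently smallest fold (balancing by row count). Returns k
    (fit_rows, validation_rows) pairs; every training row is validated
    exactly once.
    """
    train_row_indices = np.asarray(train_row_indices, dtype=int)
    groups = _rows_by_compound([compound_ids[i] for i in train_row_indices])
    if len(groups) < k:
        raise ValueError(f"need >= {k} unique compounds for {k}-fold CV")
    rng = np.random.default_rng(seed)
    compounds = list(groups)
    rng.shuffle(compounds)
    # stable sort keeps the shuffled order among equal-sized compounds
    compounds.sort(key=lambda c: -len(groups[c]))
    fold_rows: list[list[int]] = [[] for _ in range(k)]
    for c in compounds:
        smallest = min(range(k), key=lambda f: (len(fold_rows[f]), f))
        fold_rows[smallest].extend(train_row_indices[i] for i in groups[c])
    plans = []
    for f in range(k):
        val = np.sort(fold_rows[f])
        fit = np.sort(np.concatenate([fold_rows[g] for g in range(k) if g != f]))
        plans.append((fit, val))
    return plans
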