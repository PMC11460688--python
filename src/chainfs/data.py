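"""Tabular input/output and synthetic benchmark generation.

The pipeline consumes a plain sample x feature matrix with a categorical
label column.  Real applications read CSV/TSV; for offline testing a seeded
generator plants class-conditional Gaussian structure with known feature
roles (informative / redundant / noise) so that every downstream stage can
be checked against ground truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureTable",
    "SyntheticSpec",
    "read_table",
    "write_table",
    "make_synthetic",
    "worked_fixtures",
]


@dataclass
class FeatureTable:
    """A rectangular sample x feature matrix with named columns.

    ``values`` may contain NaN (missing cells) until :func:`chainfs.chain.preprocess`
    has run; all supervised operations require a complete matrix.
    """

    values: np.ndarray  # (n_samples, n_features), float
    feature_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("feature matrix must be 2-dimensional")
        if not self.feature_ids:
            self.feature_ids = [f"f{i}" for i in range(self.values.shape[1])]
        if len(self.feature_ids) != self.values.shape[1]:
            raise ValueError("feature_ids length must match number of columns")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("feature_ids must be unique")
        if self.values.shape[0] < 2:
            raise ValueError("need at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset(self, indices: Sequence[int]) -> "FeatureTable":
        """Column-subset view preserving names (copy)."""
        idx = list(indices)
        return FeatureTable(self.values[:, idx].copy(),
                            [self.feature_ids[i] for i in idx])


def check_labels(labels: np.ndarray, n_samples: int, *, min_classes: int = 2) -> np.ndarray:
    """Validate a label vector against a table and return it as an array."""
    labels = np.asarray(labels)
    if labels.ndim != 1 or len(labels) != n_samples:
        raise ValueError(
            f"labels must be a vector of length {n_samples}, got shape {labels.shape}")
    if len(np.unique(labels)) < min_classes:
        raise ValueError(f"need at least {min_classes} distinct classes")
    return labels


def encode_labels(labels: np.ndarray) -> np.ndarray:
    """Encode class labels as integers 0..n_classes-1 in sorted label order.

    For more than two classes this imposes an ordinal reading of the label,
    which rank-correlation relevance inherits (documented limitation).
    """
    classes, encoded = np.unique(np.asarray(labels), return_inverse=True)
    del classes
    return encoded.astype(int)


# ---------------------------------------------------------------------------
# File IO
# ---------------------------------------------------------------------------

def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


def read_table(path: str | Path, label_column: str | int,
               missing_token: str | None = None) -> tuple[FeatureTable, np.ndarray]:
    """Read a CSV/TSV with a header row into a table and label vector.

    Parameters
    ----------
    label_column
        Column name, or integer position within the header.
    missing_token
        Extra token (e.g. ``"?"``) mapped to a missing cell in addition to
        empty fields; missing cells surface as NaN for later imputation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    na_values = [missing_token] if missing_token is not None else None
    df = pd.read_csv(path, sep=_sep_for(path), na_values=na_values,
                     keep_default_na=True)
    if isinstance(label_column, int):
        if not 0 <= label_column < df.shape[1]:
            raise ValueError(f"label column index {label_column} out of range")
        label_name = df.columns[label_column]
    else:
        if label_column not in df.columns:
            raise ValueError(f"label column {label_column!r} not found in header")
        label_name = label_column
    labels = df[label_name].to_numpy()
    if pd.isna(labels).any():
        raise ValueError("label column contains missing values")
    feats = df.drop(columns=[label_name])
    try:
        values = feats.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric feature cell: {exc}") from exc
    return FeatureTable(values, [str(c) for c in feats.columns]), labels


def write_table(path: str | Path, table: FeatureTable, labels: np.ndarray,
                label_column: str = "label") -> None:
    """Write table + labels as CSV/TSV (delimiter chosen by extension)."""
    path = Path(path)
    df = pd.DataFrame(table.values, columns=table.feature_ids)
    df[label_column] = np.asarray(labels)
    df.to_csv(path, sep=_sep_for(path), index=False)


# ---------------------------------------------------------------------------
# Synthetic benchmark generator
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    """Recipe for a planted-structure classification dataset.

    Informative features carry a class-conditional mean shift of
    ``class_separation`` (in units of the within-class standard deviation,
    which is 1).  Each redundant feature is a designated informative parent
    plus Gaussian noise of sd ``redundancy_noise_sd``.  Noise features are
    class-independent standard normals.  ``missing_rate`` cells are blanked
    uniformly at random (missing completely at random) to exercise
    preprocessing.
    """

    n_samples: int = 200
    n_informative: int = 5
    n_redundant: int = 5
    n_noise: int = 50
    n_classes: int = 2
    class_separation: float = 3.0
    redundancy_noise_sd: float = 0.1
    missing_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least one informative feature")
        if min(self.n_redundant, self.n_noise) < 0:
            raise ValueError("feature counts must be nonnegative")
        if self.n_classes < 2:
            raise ValueError("need at least 2 classes")
        if self.n_samples < 2 * self.n_classes:
            raise ValueError("need at least 2 samples per class")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.class_separation < 0 or self.redundancy_noise_sd < 0:
            raise ValueError("separation and noise sd must be nonnegative")

    @property
    def n_features(self) -> int:
        return self.n_informative + self.n_redundant + self.n_noise


def make_synthetic(spec: SyntheticSpec) -> tuple[FeatureTable, np.ndarray, list[str]]:
    """Generate a dataset from ``spec``; returns (table, labels, roles).

    Roles are per-feature strings: ``"informative"``, ``"redundant:<parent>"``
    (parent = column index of the informative feature copied) or ``"noise"``.
    Deterministic for a fixed spec (seeded generator).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, d = spec.n_samples, spec.n_features

    # balanced classes, remainder spread over the first classes
    labels = np.repeat(np.arange(spec.n_classes), n // spec.n_classes)
    labels = np.concatenate([labels, np.arange(n - len(labels))])
    rng.shuffle(labels)

    X = np.empty((n, d))
    roles: list[str] = []

    # class-conditional means on a simplex-ish layout: class c shifts feature j
    # by sep * (+1 if (c + j) even else -1) / 2 so every informative feature
    # separates at least one pair of classes.
    sep = spec.class_separation
    for j in range(spec.n_informative):
        signs = np.where((labels + j) % 2 == 0, 0.5, -0.5)
        X[:, j] = sep * signs + rng.standard_normal(n)
        roles.append("informative")

    for j in range(spec.n_redundant):
        parent = j % spec.n_informative
        X[:, spec.n_informative + j] = (
            X[:, parent] + spec.redundancy_noise_sd * rng.standard_normal(n))
        roles.append(f"redundant:{parent}")

    start = spec.n_informative + spec.n_redundant
    X[:, start:] = rng.standard_normal((n, spec.n_noise))
    roles.extend(["noise"] * spec.n_noise)

    if spec.missing_rate > 0:
        mask = rng.random((n, d)) < spec.missing_rate
        # keep at least one observed value per column so imputation is defined
        for j in np.flatnonzero(mask.all(axis=0)):
            mask[rng.integers(n), j] = False
        X = X.copy()
        X[mask] = np.nan

    ids = [f"f{j}" for j in range(d)]
    return FeatureTable(X, ids), labels, roles


def write_roles(path: str | Path, roles: list[str], feature_ids: list[str]) -> None:
    """JSON sidecar mapping feature id -> planted role."""
    Path(path).write_text(json.dumps(dict(zip(feature_ids, roles)), indent=2))


def worked_fixtures() -> dict[str, object]:
    """Small canonical inputs used across the unit tests.

    ``features1``/``features2`` are the observed/expected count sets of the
    worked chi-square example; ``identity_table`` is a 4-sample, 2-feature
    table whose first column equals the label vector, for rank-correlation
    edge cases.
    """
    table = FeatureTable(
        np.array([[0.0, 5.0], [1.0, 3.0], [2.0, 8.0], [3.0, 1.0]]),
        ["equals_label", "scrambled"],
    )
    return {
        "features1": (10.0, 20.0, 30.0, 40.0),
        "features2": (15.0, 25.0, 35.0, 45.0),
        "identity_table": table,
        "identity_labels": np.array([0, 1, 2, 3]),
    }
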