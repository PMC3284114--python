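"""Sample and pool containers.

A :class:`Pool` is an ordered collection of samples, each carrying a fixed
-dimension feature vector and a hidden true label.  The label encodes the
two-class convention used throughout the package:

* ``1`` — the minority (target) class, e.g. cancer regions;
* ``0`` — the majority (non-target) class.

Learners never read ``y`` directly; labels are revealed one sample at a
time through the annotation oracle, which meters cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ValidationError

MINORITY = 1  #: label of the minority / target class
MAJORITY = 0  #: label of the majority / non-target class


@dataclass(frozen=True)
class Sample:
    """A single pool member: id, feature vector, hidden true label."""

    id: str
    features: np.ndarray
    true_label: int

    def __post_init__(self):
        if self.true_label not in (MINORITY, MAJORITY):
            raise ValidationError(f"true_label must be 0 or 1, got {self.true_label}")


@dataclass
class Pool:
    """Ordered sample collection with unique ids.

    Parameters
    ----------
    ids : array of str
        Unique sample identifiers.
    X : ndarray, shape (n, d)
        Feature matrix; one row per sample.
    y : ndarray of {0, 1}
        Hidden true labels (1 = minority class).  Only the annotation
        oracle should consult these.
    role : {"train", "test"}
    """

    ids: np.ndarray
    X: np.ndarray
    y: np.ndarray
    role: str = "train"
    feature_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.ids = np.asarray(self.ids, dtype=object)
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=np.int8)
        if self.X.ndim != 2:
            raise ValidationError("X must be 2-D (n_samples, n_features)")
        n = len(self.ids)
        if self.X.shape[0] != n or self.y.shape[0] != n:
            raise ValidationError("ids, X and y must have the same length")
        if len(np.unique(self.ids)) != n:
            raise ValidationError("sample ids must be unique")
        if self.role not in ("train", "test"):
            raise ValidationError(f"role must be 'train' or 'test', got {self.role!r}")
        if not self.feature_names:
            self.feature_names = [f"f{i + 1}" for i in range(self.X.shape[1])]

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def dim(self) -> int:
        return self.X.shape[1]

    @property
    def n_minority(self) -> int:
        return int((self.y == MINORITY).sum())

    def sample(self, i: int) -> Sample:
        return Sample(id=self.ids[i], features=self.X[i], true_label=int(self.y[i]))

    def subset(self, indices, role: str | None = None) -> "Pool":
        indices = np.asarray(indices, dtype=np.intp) if np.asarray(indices).dtype != bool else np.asarray(indices)
        return Pool(
            ids=self.ids[indices],
            X=self.X[indices],
            y=self.y[indices],
            role=role or self.role,
            feature_names=list(self.feature_names),
        )

    # ---- delimited-text round trip ------------------------------------
    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.X, columns=self.feature_names)
        df.insert(0, "id", self.ids)
        df["label"] = self.y
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, role: str = "train") -> "Pool":
        if "id" not in df.columns or "label" not in df.columns:
            raise ValidationError("feature table must have 'id' and 'label' columns")
        feat_cols = [c for c in df.columns if c not in ("id", "label")]
        return cls(
            ids=df["id"].astype(str).to_numpy(),
            X=df[feat_cols].to_numpy(dtype=float),
            y=df["label"].to_numpy(),
            role=role,
            feature_names=feat_cols,
        )

    @classmethod
    def from_csv(cls, path, role: str = "train") -> "Pool":
        return cls.from_frame(pd.read_csv(path), role=role)


@dataclass
class LabeledSet:
    """A growing annotated training set (ids, features, revealed labels)."""

    ids: list = field(default_factory=list)
    X_rows: list = field(default_factory=list)
    y_list: list = field(default_factory=list)

    def add(self, sample_id, features, label) -> None:
        self.ids.append(sample_id)
        self.X_rows.append(np.asarray(features, dtype=float))
        self.y_list.append(int(label))

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def X(self) -> np.ndarray:
        return np.vstack(self.X_rows) if self.X_rows else np.empty((0, 0))

    @property
    def y(self) -> np.ndarray:
        return np.asarray(self.y_list, dtype=np.int8)

    @property
    def n_minority(self) -> int:
        return int(sum(1 for v in self.y_list if v == MINORITY))

    @property
    def n_majority(self) -> int:
        return len(self.y_list) - self.n_minority

    def has_both_classes(self) -> bool:
        return 0 < self.n_minority < len(self)
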