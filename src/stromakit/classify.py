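"""Reference-based morphometric subtype classification.

Individual cells are assigned to one of two reference-like morphometric
subgroups (e.g. spindle-shaped multipotent "Y201-like" vs flat/spread
nullipotent "Y202-like" stromal phenotypes) or left unclassified, from
reference population measurements alone.

The feature space is (log aspect ratio, log area) — both are right-skewed
positive quantities, so logs symmetrise them.  Each reference population
is summarised by its feature mean vector and covariance; a query cell is
assigned to the nearer reference by Mahalanobis distance iff the distance
margin |d1 - d2| exceeds ``margin`` and the nearer distance is at most
``d_max``; otherwise it is "unclassified" (cells between categories).

The estimator follows the scikit-learn protocol (fit/predict/get_params)
and composes with sklearn model selection; :func:`fit_reference_profiles`
and :func:`classify_population` are thin functional wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .qpi import CellObject

__all__ = [
    "ReferenceProfile",
    "ClassificationReport",
    "MorphotypeClassifier",
    "fit_reference_profiles",
    "classify_population",
    "cells_to_features",
]

UNCLASSIFIED = "unclassified"


@dataclass
class ReferenceProfile:
    """Gaussian summary of one reference population in feature space."""

    label: str
    mean: np.ndarray          # (2,) mean of (log aspect_ratio, log area)
    covariance: np.ndarray    # (2, 2), positive definite
    n_reference: int

    def __post_init__(self) -> None:
        self.mean = np.asarray(self.mean, dtype=float).reshape(2)
        self.covariance = np.asarray(self.covariance, dtype=float).reshape(2, 2)
        evals = np.linalg.eigvalsh(self.covariance)
        if evals.min() <= 0:
            raise ValueError(f"covariance of {self.label!r} is singular")
        if self.n_reference < 30:
            raise ValueError("reference profiles need n >= 30 cells")


@dataclass
class ClassificationReport:
    """Per-class fractions, counts and per-cell assignments."""

    fractions: dict[str, float]
    counts: dict[str, int]
    assignments: pd.Series  # cell index -> class label

    def __post_init__(self) -> None:
        total = sum(self.fractions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class fractions must sum to 1")


def cells_to_features(cells: list[CellObject] | pd.DataFrame) -> np.ndarray:
    """(n, 2) array of (log aspect_ratio, log area) from cells or a table."""
    if isinstance(cells, pd.DataFrame):
        ar = cells["aspect_ratio"].to_numpy(dtype=float)
        area = (
            cells["area_um2"] if "area_um2" in cells else cells["area"]
        ).to_numpy(dtype=float)
    else:
        ar = np.array([c.aspect_ratio for c in cells], dtype=float)
        area = np.array([c.area for c in cells], dtype=float)
    if len(ar) == 0:
        raise ValueError("no cells supplied")
    return np.column_stack([np.log(ar), np.log(area)])


class MorphotypeClassifier(ClassifierMixin, BaseEstimator):
    """Mahalanobis-gated nearest-reference classifier with rejection.

    Parameters
    ----------
    margin : minimum Mahalanobis-distance margin |d1 - d2| required to
        commit to the nearer class; smaller margins are "between
        categories" and rejected.
    d_max : maximum distance to the nearer reference; cells further than
        this from both references are rejected.

    Attributes (after fit)
    ----------------------
    classes_ : the two reference labels, in first-seen order.
    profiles_ : dict label -> :class:`ReferenceProfile`.

    ``predict`` returns the winning label or ``"unclassified"``.
    """

    def __init__(self, margin: float = 1.0, d_max: float = 3.0):
        self.margin = margin
        self.d_max = d_max

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n, 2): (log aspect_ratio, log area)")
        labels = list(dict.fromkeys(y.tolist()))
        if len(labels) != 2:
            raise ValueError("exactly two reference classes are required")
        self.classes_ = np.asarray(labels)
        self.profiles_ = {}
        for lab in labels:
            sub = X[y == lab]
            cov = np.cov(sub, rowvar=False)
            self.profiles_[lab] = ReferenceProfile(
                label=str(lab), mean=sub.mean(axis=0), covariance=cov,
                n_reference=len(sub),
            )
        self._inv_cov = {
            lab: np.linalg.inv(p.covariance) for lab, p in self.profiles_.items()
        }
        return self

    def mahalanobis(self, X) -> np.ndarray:
        """(n, 2) distances to each reference, column order = classes_."""
        check_is_fitted(self, "profiles_")
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), 2))
        for j, lab in enumerate(self.classes_):
            d = X - self.profiles_[lab].mean
            out[:, j] = np.sqrt(np.einsum("ij,jk,ik->i", d, self._inv_cov[lab], d))
        return out

    def predict(self, X) -> np.ndarray:
        d = self.mahalanobis(X)
        nearer = d.argmin(axis=1)
        d_near = d.min(axis=1)
        gap = np.abs(d[:, 0] - d[:, 1])
        labels = self.classes_[nearer].astype(object)
        reject = (gap < self.margin) | (d_near > self.d_max)
        labels[reject] = UNCLASSIFIED
        return labels

    def report(self, X, index=None) -> ClassificationReport:
        """Classify and summarise fractions/counts over a population."""
        X = np.asarray(X, dtype=float)
        if len(X) == 0:
            raise ValueError("empty query population")
        pred = self.predict(X)
        classes = [str(c) for c in self.classes_] + [UNCLASSIFIED]
        counts = {c: int((pred == c).sum()) for c in classes}
        n = len(pred)
        fractions = {c: counts[c] / n for c in classes}
        if index is None:
            index = pd.RangeIndex(n)
        return ClassificationReport(
            fractions=fractions, counts=counts,
            assignments=pd.Series(pred, index=index, name="class"),
        )


def fit_reference_profiles(
    ref1: list[CellObject] | pd.DataFrame,
    ref2: list[CellObject] | pd.DataFrame,
    labels: tuple[str, str] = ("ref1", "ref2"),
) -> tuple[ReferenceProfile, ReferenceProfile]:
    """Fit Gaussian feature profiles for two reference populations."""
    X1, X2 = cells_to_features(ref1), cells_to_features(ref2)
    X = np.vstack([X1, X2])
    y = np.array([labels[0]] * len(X1) + [labels[1]] * len(X2))
    clf = MorphotypeClassifier().fit(X, y)
    return clf.profiles_[labels[0]], clf.profiles_[labels[1]]


def classify_population(
    cells: list[CellObject] | pd.DataFrame,
    profiles: tuple[ReferenceProfile, ReferenceProfile],
    margin: float = 1.0,
    d_max: float = 3.0,
) -> ClassificationReport:
    """Assign each cell to a reference-like class or leave it unclassified."""
    p1, p2 = profiles
    clf = MorphotypeClassifier(margin=margin, d_max=d_max)
    clf.classes_ = np.asarray([p1.label, p2.label])
    clf.profiles_ = {p1.label: p1, p2.label: p2}
    clf._inv_cov = {
        p.label: np.linalg.inv(p.covariance) for p in (p1, p2)
    }
    X = cells_to_features(cells)
    index = cells.index if isinstance(cells, pd.DataFrame) else None
    return clf.report(X, index=index)
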