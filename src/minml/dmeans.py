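"""Class-mean-difference attribute ranking (*dMeans*) for two-class tables.

A two-class feature table is scored attribute by attribute: for every
attribute the per-class arithmetic means ``M1`` and ``M2`` are computed and
their difference ``d = M1 - M2`` is taken as the attribute's relevance.
Sorting all attributes by ``d`` from high to low yields the *relevance
permutation* — the order in which the classifier in :mod:`minml.mml` grows
its attribute subset.

Two ranking modes are offered.  ``signed`` is the literal rule (sort by
``M1 - M2``); ``absolute`` sorts by ``|M1 - M2|``, which treats attributes
whose second-class mean exceeds the first as equally relevant.  Attribute
positions are reported 1-based throughout, matching the convention of
tabulated gene/pixel indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeatureDataset",
    "RelevancePermutation",
    "class_attribute_means",
    "relevance_permutation",
]

#: Ranking modes accepted everywhere a permutation is built.
MODES = ("signed", "absolute")


@dataclass(eq=False)
class FeatureDataset:
    """An ``m x n`` numeric pattern matrix with binary class labels.

    Parameters
    ----------
    patterns
        Two-dimensional array-like of finite reals, one row per pattern.
    labels
        Length-``m`` sequence with exactly two distinct class identifiers.

    The two class identifiers are ordered canonically: ``C1`` is the
    lexicographically (or numerically) smaller label, ``C2`` the larger.
    This fixes the sign of the dMeans difference ``M1 - M2``.
    """

    patterns: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.patterns = np.asarray(self.patterns, dtype=float)
        if self.patterns.ndim != 2:
            raise ValueError("patterns must be a 2-D matrix")
        m, n = self.patterns.shape
        if m < 2 or n < 2:
            raise ValueError(f"need at least 2 patterns and 2 attributes, got {m}x{n}")
        if not np.all(np.isfinite(self.patterns)):
            raise ValueError("patterns contain missing or non-finite values")
        self.labels = np.asarray(self.labels)
        if self.labels.shape != (m,):
            raise ValueError("labels must be a length-m sequence")
        distinct = sorted(set(self.labels.tolist()))
        if len(distinct) != 2:
            raise ValueError(
                f"exactly two distinct class labels required, got {distinct!r}"
            )
        self._classes = tuple(distinct)

    # -- basic geometry ---------------------------------------------------
    @property
    def m(self) -> int:
        return self.patterns.shape[0]

    @property
    def n(self) -> int:
        return self.patterns.shape[1]

    @property
    def classes(self) -> tuple:
        """The two class labels as ``(C1, C2)``, C1 being the smaller."""
        return self._classes

    def class_mask(self, label) -> np.ndarray:
        if label not in self._classes:
            raise ValueError(f"unknown class label {label!r}")
        return self.labels == label

    def subset(self, index) -> "FeatureDataset":
        """Row subset as a new dataset; raises if a class is emptied."""
        sub_p = self.patterns[index]
        sub_l = self.labels[index]
        if len(set(sub_l.tolist())) != 2:
            raise ValueError("subset empties one of the two classes")
        return FeatureDataset(sub_p, sub_l)


@dataclass(frozen=True)
class RelevancePermutation:
    """Ordering of all attribute positions by dMeans relevance.

    ``order`` is a permutation of ``1..n`` (1-based positions) and ``d``
    holds the corresponding differences, non-increasing under the chosen
    ``mode``.  Ties are broken by ascending original position.
    """

    order: np.ndarray
    d: np.ndarray
    mode: str
    classes: tuple = field(default=())

    def __post_init__(self) -> None:
        object.__setattr__(self, "order", np.asarray(self.order, dtype=int))
        object.__setattr__(self, "d", np.asarray(self.d, dtype=float))

    @property
    def n(self) -> int:
        return self.order.size

    def top(self, k: int) -> np.ndarray:
        """The first ``k`` (most relevant) attribute positions."""
        return self.order[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, self.n + 1),
                "position": self.order,
                "d": self.d,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def class_attribute_means(ds: FeatureDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-class column means ``(M1, M2)`` of a two-class table.

    ``M1[i]`` is the mean of attribute ``i`` over all patterns of the
    smaller-labelled class ``C1``; ``M2[i]`` over ``C2``.
    """
    c1, c2 = ds.classes
    m1_rows = ds.patterns[ds.class_mask(c1)]
    m2_rows = ds.patterns[ds.class_mask(c2)]
    if m1_rows.shape[0] == 0 or m2_rows.shape[0] == 0:
        raise ValueError("empty class: both classes need at least one pattern")
    return m1_rows.mean(axis=0), m2_rows.mean(axis=0)


def relevance_permutation(ds: FeatureDataset, mode: str = "signed") -> RelevancePermutation:
    """Rank all attributes by the class-mean difference.

    Parameters
    ----------
    ds
        Two-class feature table.
    mode
        ``"signed"`` sorts by ``M1 - M2`` (the literal rule); ``"absolute"``
        sorts by ``|M1 - M2|``.

    Returns
    -------
    RelevancePermutation
        All ``n`` positions sorted by descending relevance, ties broken by
        ascending position.  Deterministic.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    m1, m2 = class_attribute_means(ds)
    d = m1 - m2
    key = np.abs(d) if mode == "absolute" else d
    # Stable argsort of the negated key: descending, ties by ascending index.
    idx = np.argsort(-key, kind="stable")
    return RelevancePermutation(
        order=idx + 1, d=key[idx], mode=mode, classes=ds.classes
    )
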