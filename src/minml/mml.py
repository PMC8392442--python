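"""The minimalist classifier: (std, mean) projection and hypothesis line.

Each pattern, restricted to a selected subset of attributes, is collapsed
to two statistics: the sample standard deviation (x-axis) and the
arithmetic mean (y-axis) of the selected values.  Training grows the
attribute subset along the dMeans relevance permutation, one prefix length
``k`` at a time; at each ``k`` the class whose projected means lie lower is
the *minor* class, the other the *major* class, and the decision boundary
is the horizontal line

    h = (max(minor-class means) + min(major-class means)) / 2.

A pattern is assigned the below-side class when its projected mean is
below ``h`` and the above-side class when above; the standard-deviation
coordinate never influences the decision.  The search stops at the first
``k`` that separates the training classes completely, otherwise the
smallest ``k`` maximizing training accuracy is kept.

Standard deviation is the *sample* one (divisor ``k - 1``): for two values
``a, b`` it equals ``|a - b| / sqrt(2)``, e.g. ``std(67.9, 81.6) = 9.6874``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dmeans import MODES, FeatureDataset, RelevancePermutation, relevance_permutation

__all__ = [
    "ProjectedPoint",
    "MMLModel",
    "SeparationProfile",
    "project_pattern",
    "hypothesis_value",
    "assign_class",
    "train",
    "predict_set",
    "render_projection",
]

TIE_POLICIES = ("below", "above")


@dataclass(frozen=True)
class ProjectedPoint:
    """A pattern collapsed to (sample std, mean) of its selected values."""

    x: float  # sample standard deviation, >= 0
    y: float  # arithmetic mean


@dataclass(frozen=True)
class MMLModel:
    """Trained minimalist classifier.

    Attributes
    ----------
    positions
        First ``k_star`` attribute positions (1-based) of the relevance
        permutation computed on the training set.
    hypothesis
        The horizontal decision boundary ``h``, in attribute-value units.
    side_map
        ``{"below": label, "above": label}`` — which class lies on each
        side of ``h``.
    tie_policy
        Side assigned when a pattern's mean equals ``h`` exactly.
    """

    positions: tuple
    hypothesis: float
    side_map: dict
    tie_policy: str = "below"
    training_accuracy: float = float("nan")
    permutation_mode: str = "signed"

    def __post_init__(self):
        object.__setattr__(self, "positions", tuple(int(p) for p in self.positions))
        if len(self.positions) < 2:
            raise ValueError("a model needs at least 2 selected attributes")
        if self.tie_policy not in TIE_POLICIES:
            raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
        if set(self.side_map) != {"below", "above"}:
            raise ValueError("side_map must have exactly the keys 'below' and 'above'")
        if not np.isfinite(self.hypothesis):
            raise ValueError("hypothesis must be finite")

    @property
    def k_star(self) -> int:
        return len(self.positions)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "k_star": self.k_star,
            "positions": list(self.positions),
            "hypothesis": self.hypothesis,
            "side_map": {k: str(v) for k, v in self.side_map.items()},
            "tie_policy": self.tie_policy,
            "training_accuracy": self.training_accuracy,
            "permutation_mode": self.permutation_mode,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, payload: dict) -> "MMLModel":
        return cls(
            positions=payload["positions"],
            hypothesis=payload["hypothesis"],
            side_map=dict(payload["side_map"]),
            tie_policy=payload.get("tie_policy", "below"),
            training_accuracy=payload.get("training_accuracy", float("nan")),
            permutation_mode=payload.get("permutation_mode", "signed"),
        )

    @classmethod
    def load(cls, path) -> "MMLModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass(frozen=True)
class SeparationProfile:
    """Per-``k`` trace of the attribute-growth search (inspection aid)."""

    k: np.ndarray
    hypothesis: np.ndarray
    accuracy: np.ndarray
    fully_separated: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "k": self.k,
                "hypothesis": self.hypothesis,
                "accuracy": self.accuracy,
                "fully_separated": self.fully_separated,
            }
        )


def project_pattern(p: Sequence[float], positions: Iterable[int]) -> ProjectedPoint:
    """Collapse pattern ``p`` to (sample std, mean) over ``positions``.

    ``positions`` are 1-based attribute indices; at least two are required
    (the sample standard deviation is undefined for a single value).
    """
    p = np.asarray(p, dtype=float)
    pos = np.asarray(list(positions), dtype=int)
    if pos.size < 2:
        raise ValueError("at least 2 attribute positions are required")
    if pos.min() < 1 or pos.max() > p.size:
        raise ValueError(
            f"positions must lie in [1, {p.size}] for this pattern"
        )
    values = p[pos - 1]
    return ProjectedPoint(x=float(np.std(values, ddof=1)), y=float(values.mean()))


def hypothesis_value(minor_means: Sequence[float], major_means: Sequence[float]) -> float:
    """Midpoint between the minor class's highest and the major class's
    lowest projected mean.  Defined regardless of overlap."""
    minor = np.asarray(list(minor_means), dtype=float)
    major = np.asarray(list(major_means), dtype=float)
    if minor.size == 0 or major.size == 0:
        raise ValueError("both classes need at least one projected mean")
    return float((minor.max() + major.min()) / 2.0)


def assign_class(model: MMLModel, p: Sequence[float]):
    """Classify one pattern: below/above the hypothesis line by its mean."""
    point = project_pattern(p, model.positions)
    if point.y < model.hypothesis:
        return model.side_map["below"]
    if point.y > model.hypothesis:
        return model.side_map["above"]
    return model.side_map[model.tie_policy]


def _sweep(tr: FeatureDataset, perm: RelevancePermutation, ks: np.ndarray, tie_policy: str):
    """Vectorized evaluation of every prefix length in ``ks``.

    Returns per-k arrays (hypothesis, correct counts, fully_separated,
    minor_is_c1) computed from the training patterns only.
    """
    X = tr.patterns[:, perm.order - 1]  # columns in relevance order
    csum = np.cumsum(X, axis=1)
    means = csum[:, ks - 1] / ks  # (m, K) projected means at each k

    c1, c2 = tr.classes
    m1 = tr.class_mask(c1)
    m2 = tr.class_mask(c2)
    avg1 = means[m1].mean(axis=0)
    avg2 = means[m2].mean(axis=0)
    # Minor = the class whose average projected mean is lower; ties -> C1.
    minor_is_c1 = avg1 <= avg2

    max1, min1 = means[m1].max(axis=0), means[m1].min(axis=0)
    max2, min2 = means[m2].max(axis=0), means[m2].min(axis=0)
    max_minor = np.where(minor_is_c1, max1, max2)
    min_major = np.where(minor_is_c1, min2, min1)
    h = (max_minor + min_major) / 2.0

    below = means < h
    if tie_policy == "below":
        pred_minor = means <= h
    else:
        pred_minor = below
    true_is_minor = m1[:, None] == minor_is_c1[None, :]
    correct = (pred_minor == true_is_minor).sum(axis=0)
    fully_separated = max_minor < min_major
    return h, correct, fully_separated, minor_is_c1


def train(
    tr: FeatureDataset,
    *,
    mode: str = "signed",
    k_schedule: Sequence[int] | None = None,
    tie_policy: str = "below",
) -> tuple[MMLModel, SeparationProfile]:
    """Learn an :class:`MMLModel` by growing attributes along the permutation.

    Parameters
    ----------
    tr
        Training set (two classes).
    mode
        Relevance-permutation mode, ``"signed"`` or ``"absolute"``.
    k_schedule
        Prefix lengths to examine, each in ``[2, n]``.  Default: the full
        sweep ``2..n``.  A coarse grid (e.g. ``[3, 5, 10, 100, 1000, n]``)
        is useful for very wide tables.
    tie_policy
        Class side assigned when a projected mean equals ``h``.

    Returns
    -------
    (MMLModel, SeparationProfile)
        The search stops early at the first ``k`` reaching training
        accuracy 1.0; otherwise the smallest ``k`` maximizing training
        accuracy is selected.  Fully deterministic.
    """
    if tie_policy not in TIE_POLICIES:
        raise ValueError(f"tie_policy must be one of {TIE_POLICIES}")
    perm = relevance_permutation(tr, mode=mode)
    n = tr.n
    if k_schedule is None:
        ks = np.arange(2, n + 1)
    else:
        ks = np.asarray(list(k_schedule), dtype=int)
        if ks.size == 0:
            raise ValueError("k_schedule must not be empty")
        if ks.min() < 2 or ks.max() > n:
            raise ValueError(f"k_schedule entries must lie in [2, {n}]")

    h, correct, fully_separated, minor_is_c1 = _sweep(tr, perm, ks, tie_policy)
    m = tr.m
    accuracy = correct / m

    perfect = np.flatnonzero(correct == m)
    if perfect.size:
        sel = perfect[0]  # earliest k in schedule order reaching 1.0
    else:
        best = correct.max()
        candidates = np.flatnonzero(correct == best)
        sel = candidates[np.argmin(ks[candidates])]  # smallest k among ties

    k_star = int(ks[sel])
    c1, c2 = tr.classes
    minor, major = (c1, c2) if minor_is_c1[sel] else (c2, c1)
    model = MMLModel(
        positions=tuple(perm.top(k_star)),
        hypothesis=float(h[sel]),
        side_map={"below": minor, "above": major},
        tie_policy=tie_policy,
        training_accuracy=float(accuracy[sel]),
        permutation_mode=mode,
    )
    profile = SeparationProfile(
        k=ks, hypothesis=h, accuracy=accuracy, fully_separated=fully_separated
    )
    return model, profile


def predict_set(model: MMLModel, te) -> tuple[np.ndarray, list[ProjectedPoint]]:
    """Classify every pattern of a test set.

    ``te`` may be a :class:`FeatureDataset` or a plain 2-D matrix (test
    sets need not carry labels).  Returns the predicted labels and the
    projected points (for plotting).
    """
    patterns = te.patterns if isinstance(te, FeatureDataset) else np.asarray(te, dtype=float)
    if patterns.ndim != 2:
        raise ValueError("test patterns must form a 2-D matrix")
    labels = []
    points = []
    for row in patterns:
        points.append(project_pattern(row, model.positions))
        labels.append(assign_class(model, row))
    return np.asarray(labels, dtype=object), points


def render_projection(
    points_by_class: dict,
    hypothesis: float,
    test_points: Sequence[ProjectedPoint] | None = None,
    *,
    path=None,
    title: str | None = None,
    ax=None,
):
    """Plot the 2-D projection: per-class curves sorted by std, the
    horizontal hypothesis line, and optional test points (black squares).

    Parameters
    ----------
    points_by_class
        Mapping from class label to a sequence of :class:`ProjectedPoint`.
    hypothesis
        y-value of the decision line.
    test_points
        Optional held-out patterns to mark distinctly.
    path
        If given, the figure is written there (PNG) and closed.

    Returns the matplotlib ``Axes`` used.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    for label, pts in points_by_class.items():
        pts = sorted(pts, key=lambda q: q.x)  # ascending std along x
        xs = [q.x for q in pts]
        ys = [q.y for q in pts]
        ax.plot(xs, ys, marker="o", markersize=3, linewidth=1, label=str(label))
    ax.axhline(hypothesis, color="magenta", linewidth=1.5, label="hypothesis")
    if test_points:
        ax.scatter(
            [q.x for q in test_points],
            [q.y for q in test_points],
            marker="s",
            color="black",
            zorder=5,
            label="test",
        )
    ax.set_xlabel("standard deviation")
    ax.set_ylabel("mean")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
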