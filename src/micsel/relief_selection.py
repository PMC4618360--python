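"""Relieff feature weighting and IterRelCen iterative channel selection.

Relieff scores each feature by how well it separates samples from their
nearest neighbors: for a target sample R, the weight of feature f is decreased
by its mean range-normalized difference to the k nearest same-class samples
(near hits H_j) and increased by the prior-weighted mean difference to the k
nearest samples of every other class (near misses M_j(C)):

    W(f) <- W(f) - sum_j d(f, R, H_j) / (m k)
                 + sum_{C != class(R)} [ p(C) / (1 - p(class(R))) ]
                   * sum_j d(f, R, M_j(C)) / (m k)

with d(f, R, Ro) = |value(f,R) - value(f,Ro)| / (max(f) - min(f)) and m the
number of target samples. On two classes this reduces to classic Relief.

IterRelCen hardens Relieff against noisy, high-dimensional EEG features in two
ways. First, target samples are not drawn at random: within each class,
samples are taken in order of distance to the class center (per-feature mean),
since central samples characterize their class more reliably than outliers.
Second, weighting is embedded in an elimination loop: each iteration recomputes
the weights from scratch on the surviving features only, removes the N
lowest-weighted features, and hands the surviving set to an evaluator
(typically cross-validated SVM accuracy), until no features remain. As noisy
features disappear, the distances driving neighbor search become increasingly
faithful, so the surviving weights sharpen from one iteration to the next.

Everything here is deterministic apart from Relieff's optional random target
draw: ties in distances, weights and orderings always break by ascending
index.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .core_data import FeatureMatrix, ValidationError

__all__ = [
    "ReliefConfig",
    "WeightVector",
    "IterationRecord",
    "SelectionTrace",
    "feature_diff",
    "nearest_neighbors",
    "relieff_weights",
    "class_center_order",
    "iterrelcen",
    "features_to_channels",
]


@dataclass
class ReliefConfig:
    """Parameters shared by Relieff and IterRelCen.

    k: number of near hits/misses per target; must be smaller than the
    smallest class. m: number of target samples (None = every sample; in
    IterRelCen each class contributes round(m x class share) center-ordered
    targets). seed drives Relieff's random target draw only — IterRelCen
    contains no randomness. distance: aggregate sample metric over the
    current features; only range-normalized Manhattan is provided, matching
    the per-feature diff that the weights themselves use.
    """

    k: int = 10
    m: int | None = None
    seed: int = 0
    distance: str = "manhattan"

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValidationError("k must be at least 1")
        if self.m is not None and self.m < 1:
            raise ValidationError("m must be at least 1 (or None for all samples)")
        if self.distance != "manhattan":
            raise ValidationError(
                f"unsupported distance {self.distance!r}; only 'manhattan' is provided"
            )


@dataclass
class WeightVector:
    """Relieff weights over a (possibly surviving-subset) feature set."""

    weights: np.ndarray
    feature_ids: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.feature_ids = np.asarray(self.feature_ids, dtype=int)
        if self.weights.shape != self.feature_ids.shape:
            raise ValidationError("weights and feature_ids must align")


@dataclass
class IterationRecord:
    """One IterRelCen iteration: the feature set the weights were computed on,
    those weights, what was removed, what survived, and the evaluator's
    accuracy on the surviving set (None once the set is empty)."""

    features: np.ndarray
    weights: WeightVector
    removed: np.ndarray
    survivors: np.ndarray
    accuracy: float | None


@dataclass
class SelectionTrace:
    """Full record of an IterRelCen run.

    ``surviving_sizes()`` starts at the full feature count and ends at 0;
    consecutive sizes differ by exactly ``removal_size`` except possibly the
    last step.
    """

    initial_features: np.ndarray
    initial_accuracy: float | None
    iterations: list[IterationRecord] = field(default_factory=list)
    removal_size: int = 0

    def surviving_sizes(self) -> list[int]:
        return [int(self.initial_features.size)] + [
            int(rec.survivors.size) for rec in self.iterations
        ]

    def steps(self) -> list[tuple[np.ndarray, float | None]]:
        """(surviving feature ids, accuracy) per evaluated set, the full set
        first, excluding the final empty set."""
        out: list[tuple[np.ndarray, float | None]] = [
            (self.initial_features, self.initial_accuracy)
        ]
        out.extend(
            (rec.survivors, rec.accuracy)
            for rec in self.iterations
            if rec.survivors.size
        )
        return out


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------


def feature_diff(
    f: int,
    r: np.ndarray,
    ro: np.ndarray,
    frange: tuple[float, float],
) -> float:
    """Range-normalized absolute difference of feature ``f`` between two
    samples; lies in [0, 1] when the range covers the training data. A
    degenerate range (max == min) yields 0 with a warning."""
    lo, hi = frange
    if hi <= lo:
        warnings.warn(f"feature {f} has a degenerate range; diff defined as 0",
                      stacklevel=2)
        return 0.0
    return float(abs(r[f] - ro[f]) / (hi - lo))


def _scaled(X: np.ndarray, ranges: np.ndarray | None = None) -> np.ndarray:
    """Divide each feature by its (max - min); constant features contribute 0
    to every distance."""
    if ranges is None:
        ranges = X.max(axis=0) - X.min(axis=0)
    safe = np.where(ranges > 0, ranges, 1.0)
    Xs = X / safe
    Xs[:, ranges <= 0] = 0.0
    return Xs


def nearest_neighbors(
    target: np.ndarray,
    pool: np.ndarray,
    k: int,
    ranges: np.ndarray | None = None,
) -> np.ndarray:
    """Indices (into ``pool``) of the k samples nearest to ``target`` under
    the aggregate range-normalized Manhattan distance; ties break by ascending
    pool index. ``pool`` must exclude the target itself."""
    pool = np.atleast_2d(np.asarray(pool, dtype=float))
    target = np.asarray(target, dtype=float)
    if pool.shape[0] < k:
        raise ValidationError(f"pool of {pool.shape[0]} samples cannot supply k={k}")
    if ranges is None:
        stacked = np.vstack([target[None, :], pool])
        ranges = stacked.max(axis=0) - stacked.min(axis=0)
    safe = np.where(ranges > 0, ranges, np.inf)
    d = np.abs(pool - target[None, :]) / safe[None, :]
    dist = d.sum(axis=1)
    order = np.argsort(dist, kind="stable")
    return order[:k]


def class_center_order(fm: FeatureMatrix | np.ndarray, cls: int,
                       labels: np.ndarray | None = None) -> np.ndarray:
    """Sample indices of class ``cls`` ordered by ascending distance to the
    class center (per-feature mean over the class), ties by ascending index.

    Accepts either a FeatureMatrix or a raw (X, labels) pair.
    """
    if isinstance(fm, FeatureMatrix):
        X, y = fm.values, fm.labels
    else:
        if labels is None:
            raise ValidationError("labels required when passing a raw array")
        X, y = np.asarray(fm, dtype=float), np.asarray(labels, dtype=int)
    members = np.flatnonzero(y == cls)
    if members.size == 0:
        raise ValidationError(f"class {cls} has no samples")
    Xs = _scaled(X)
    center = Xs[members].mean(axis=0)
    dist = np.abs(Xs[members] - center[None, :]).sum(axis=1)
    return members[np.argsort(dist, kind="stable")]


# ---------------------------------------------------------------------------
# Relieff
# ---------------------------------------------------------------------------


def _relieff_core(
    X: np.ndarray,
    y: np.ndarray,
    k: int,
    targets: np.ndarray,
) -> np.ndarray:
    """Eq.-style Relieff update over explicit targets; m = len(targets)."""
    n, n_feat = X.shape
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValidationError("Relieff needs at least 2 classes")
    too_small = classes[counts < k + 1]
    if too_small.size:
        raise ValidationError(
            f"classes {too_small.tolist()} have fewer than k+1={k + 1} samples"
        )
    priors = {c: cnt / n for c, cnt in zip(classes, counts)}
    ranges = X.max(axis=0) - X.min(axis=0)
    if np.any(ranges <= 0):
        warnings.warn(
            f"{int((ranges <= 0).sum())} constant feature(s): their diffs are 0",
            stacklevel=3,
        )
    Xs = _scaled(X, ranges)
    # full pairwise scaled-Manhattan distances; n is at most a few hundred
    D = cdist(Xs, Xs, metric="cityblock")
    m = len(targets)
    W = np.zeros(n_feat)
    members = {c: np.flatnonzero(y == c) for c in classes}
    for t in targets:
        ct = y[t]
        for c in classes:
            pool = members[c]
            if c == ct:
                pool = pool[pool != t]
            order = pool[np.argsort(D[t, pool], kind="stable")[:k]]
            diffs = np.abs(Xs[order] - Xs[t][None, :]).sum(axis=0)
            if c == ct:
                W -= diffs / (m * k)
            else:
                W += (priors[c] / (1.0 - priors[ct])) * diffs / (m * k)
    return W


def relieff_weights(
    fm: FeatureMatrix,
    cfg: ReliefConfig,
    targets: Sequence[int] | np.ndarray | None = None,
) -> WeightVector:
    """Relieff weights for every feature of ``fm``.

    If ``targets`` is omitted, ``cfg.m`` targets are drawn uniformly without
    replacement using ``cfg.seed`` (all samples when ``cfg.m`` is None). On
    two classes the update coincides with classic Relief. On min-max
    normalized input every weight lies in [-1, 1].
    """
    X, y = fm.values, fm.labels
    n = X.shape[0]
    if targets is None:
        m = n if cfg.m is None else cfg.m
        if m > n:
            raise ValidationError(f"m={m} exceeds the {n} available samples")
        rng = np.random.default_rng(cfg.seed)
        targets = np.sort(rng.choice(n, size=m, replace=False))
    else:
        targets = np.asarray(targets, dtype=int)
        if targets.size == 0:
            raise ValidationError("explicit target list is empty")
        if targets.min() < 0 or targets.max() >= n:
            raise ValidationError("target index out of range")
    W = _relieff_core(X, y, cfg.k, np.asarray(targets, dtype=int))
    return WeightVector(weights=W, feature_ids=np.arange(X.shape[1]))


# ---------------------------------------------------------------------------
# IterRelCen
# ---------------------------------------------------------------------------


def _center_targets(X: np.ndarray, y: np.ndarray, m: int | None) -> np.ndarray:
    """Per class, the round(m x class share) samples closest to the class
    center, in center order; classes visited in ascending label order."""
    n = X.shape[0]
    m_total = n if m is None else m
    targets: list[np.ndarray] = []
    for c in np.unique(y):
        n_c = int((y == c).sum())
        m_c = int(round(m_total * n_c / n))
        if m_c == 0:
            continue
        order = class_center_order(X, int(c), labels=y)
        targets.append(order[:m_c])
    if not targets:
        raise ValidationError("no targets selected; increase m")
    return np.concatenate(targets)


def iterrelcen(
    fm: FeatureMatrix,
    cfg: ReliefConfig,
    N: int,
    evaluator: Callable[[np.ndarray], float] | None = None,
    targets: Sequence[int] | np.ndarray | None = None,
) -> SelectionTrace:
    """Run the iterative center-targeted Relieff elimination loop.

    Per iteration: (a) targets are the center-ordered per-class samples
    (deterministic; or the fixed ``targets`` override), (b) Relieff weights
    are recomputed from scratch on the surviving features, (c) the ``N``
    smallest-weight features are removed (ties by ascending feature index),
    (d) the evaluator is called on the surviving set while nonempty. The
    initial full set is evaluated once before any removal. The loop ends when
    the feature set is empty, after ceil(n_features / N) weight passes.
    """
    X, y = fm.values, fm.labels
    n_features = X.shape[1]
    if not (1 <= N <= n_features):
        raise ValidationError(f"N must lie in [1, {n_features}], got {N}")
    fixed_targets = None if targets is None else np.asarray(targets, dtype=int)

    def _eval(ids: np.ndarray, context: str) -> float | None:
        if evaluator is None:
            return None
        try:
            return float(evaluator(ids))
        except Exception as exc:  # noqa: BLE001 - re-raise with loop context
            raise RuntimeError(f"evaluator failed at {context}") from exc

    surviving = np.arange(n_features)
    trace = SelectionTrace(
        initial_features=surviving.copy(),
        initial_accuracy=_eval(surviving, "initial full set"),
        removal_size=N,
    )
    iteration = 0
    while surviving.size:
        iteration += 1
        Xs = X[:, surviving]
        tgt = fixed_targets if fixed_targets is not None else _center_targets(Xs, y, cfg.m)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # constant-feature diffs are defined as 0
            w = _relieff_core(Xs, y, cfg.k, tgt)
        n_rm = min(N, surviving.size)
        removed_local = np.sort(np.argsort(w, kind="stable")[:n_rm])
        removed = surviving[removed_local]
        survivors = np.delete(surviving, removed_local)
        acc = _eval(survivors, f"iteration {iteration}") if survivors.size else None
        trace.iterations.append(
            IterationRecord(
                features=surviving.copy(),
                weights=WeightVector(weights=w, feature_ids=surviving.copy()),
                removed=removed,
                survivors=survivors.copy(),
                accuracy=acc,
            )
        )
        surviving = survivors
    assert len(trace.iterations) == math.ceil(n_features / N)
    return trace


def features_to_channels(
    feature_ids: Sequence[int] | np.ndarray, n_bands: int = 13
) -> np.ndarray:
    """Channels holding at least one of the given features (sorted, unique).

    Feature ``i`` belongs to channel ``i // n_bands`` under the channel-major
    concatenation order.
    """
    ids = np.asarray(list(feature_ids), dtype=int)
    if ids.size == 0:
        return np.array([], dtype=int)
    if ids.min() < 0:
        raise ValidationError("negative feature index")
    return np.unique(ids // n_bands)
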