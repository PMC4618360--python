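"""Cross-validated evaluation of channel selection.

The selection protocol is nested: a stratified tenfold outer cross-validation
estimates generalization accuracy, and within each outer training fold the
iterative selection (IterRelCen) is run with an inner stratified 5-fold SVM
accuracy as its evaluator. Min-max normalization parameters are always fit on
the training fold and applied to the test fold, so neither normalization nor
selection ever sees test labels or test feature statistics.

The reported accuracy is Acc = (1/k) * sum_i acc_i, the arithmetic mean of the
per-fold test accuracies; "optimal" channels are the smallest channel set
among the elimination steps whose mean accuracy is maximal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .core_data import FeatureMap, FeatureMatrix, ValidationError
from .feature_bank import minmax_normalize
from .relief_selection import (
    ReliefConfig,
    SelectionTrace,
    WeightVector,
    features_to_channels,
    iterrelcen,
)

__all__ = [
    "SVMConfig",
    "CVResult",
    "ChannelCurve",
    "StepwiseCVResult",
    "OptimalSelection",
    "stratified_folds",
    "train_eval_svm",
    "cv_accuracy",
    "run_selection_cv",
    "select_optimal",
    "optimal_channels",
    "channel_weight_map",
    "accuracy_vs_channels",
    "band_usage_counts",
]


@dataclass
class SVMConfig:
    """RBF-kernel soft-margin SVM settings.

    gamma="auto" means 1 / n_features (of the feature subset in use). For K
    classes the underlying model trains K(K-1)/2 pairwise classifiers
    (one-against-one).
    """

    C: float = 1.0
    gamma: float | str = "auto"
    kernel: str = "rbf"

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ValidationError("C must be positive")
        if isinstance(self.gamma, (int, float)) and self.gamma <= 0:
            raise ValidationError("gamma must be positive")

    def make(self) -> SVC:
        return SVC(
            C=self.C,
            gamma=self.gamma,
            kernel=self.kernel,
            decision_function_shape="ovo",
        )


@dataclass
class CVResult:
    """Per-fold test accuracies and their exact arithmetic mean."""

    fold_accuracies: np.ndarray
    fold_assignments: np.ndarray
    selected_features: list[np.ndarray] | None = None

    def __post_init__(self) -> None:
        self.fold_accuracies = np.asarray(self.fold_accuracies, dtype=float)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


@dataclass
class ChannelCurve:
    """Mean/sd CV accuracy as channels are added in descending-weight order."""

    n_channels_used: np.ndarray
    mean_accuracy: np.ndarray
    sd_accuracy: np.ndarray
    channel_order: np.ndarray

    def peak(self) -> tuple[int, float]:
        """(number of channels, accuracy) at the curve's maximum; among ties,
        the fewest channels."""
        i = int(np.argmax(self.mean_accuracy))
        best = self.mean_accuracy[i]
        ties = np.flatnonzero(self.mean_accuracy >= best - 1e-12)
        i = int(ties[0])
        return int(self.n_channels_used[i]), float(self.mean_accuracy[i])


@dataclass
class StepwiseCVResult:
    """Outer-CV accuracies along the elimination schedule.

    ``accuracies[s, f]`` is the outer test accuracy of fold ``f`` at step
    ``s`` (step 0 = full feature set); ``mean_accuracy`` averages over folds.
    """

    step_sizes: np.ndarray
    accuracies: np.ndarray
    fold_assignments: np.ndarray
    traces: list[SelectionTrace] = field(default_factory=list)

    @property
    def mean_accuracy(self) -> np.ndarray:
        return self.accuracies.mean(axis=1)

    @property
    def sd_accuracy(self) -> np.ndarray:
        return self.accuracies.std(axis=1, ddof=1)


@dataclass
class OptimalSelection:
    """The chosen operating point: smallest channel set at peak accuracy."""

    step_index: int
    mean_accuracy: float
    feature_ids: np.ndarray
    channels: np.ndarray
    bands_per_channel: dict[int, np.ndarray]
    weights: WeightVector | None = None


# ---------------------------------------------------------------------------
# Folds and SVM
# ---------------------------------------------------------------------------


def stratified_folds(labels: np.ndarray, k: int = 10, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (one integer in [0, k) per
    trial); per-fold class counts differ by at most 1 from proportionality."""
    labels = np.asarray(labels, dtype=int)
    classes, counts = np.unique(labels, return_counts=True)
    small = classes[counts < k]
    if small.size:
        raise ValidationError(
            f"classes {small.tolist()} have fewer than k={k} members"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(labels.size, dtype=int)
    for fold, (_, test_idx) in enumerate(skf.split(np.zeros(labels.size), labels)):
        assignment[test_idx] = fold
    return assignment


def train_eval_svm(
    train: FeatureMatrix, test: FeatureMatrix, cfg: SVMConfig
) -> float:
    """Fit the SVM on ``train`` and return its accuracy on ``test``."""
    if train.map != test.map:
        raise ValidationError("train and test must share a FeatureMap")
    if np.unique(train.labels).size < 2:
        raise ValidationError("training fold contains a single class")
    clf = cfg.make()
    clf.fit(train.values, train.labels)
    return float(np.mean(clf.predict(test.values) == test.labels))


def _subset_accuracy(
    X_train: np.ndarray,
    y_train: np.ndarray,
    X_test: np.ndarray,
    y_test: np.ndarray,
    cfg: SVMConfig,
) -> float:
    if np.unique(y_train).size < 2:
        raise ValidationError("training fold contains a single class")
    clf = cfg.make()
    clf.fit(X_train, y_train)
    return float(np.mean(clf.predict(X_test) == y_test))


def cv_accuracy(
    fm: FeatureMatrix,
    feature_ids: np.ndarray | None = None,
    svm_cfg: SVMConfig | None = None,
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Stratified k-fold CV accuracy on a feature subset of raw features.

    Normalization is fit on each training fold and applied to its test fold.
    """
    svm_cfg = svm_cfg or SVMConfig()
    ids = (
        np.arange(fm.n_features)
        if feature_ids is None
        else np.asarray(feature_ids, dtype=int)
    )
    assignment = stratified_folds(fm.labels, k=k, seed=seed)
    accs = []
    for fold in range(k):
        tr = assignment != fold
        te = ~tr
        Xtr, Xte = _normalized_split(fm.values[:, ids], tr, te)
        accs.append(_subset_accuracy(Xtr, fm.labels[tr], Xte, fm.labels[te], svm_cfg))
    return CVResult(fold_accuracies=np.array(accs), fold_assignments=assignment)


def _normalized_split(
    X: np.ndarray, tr: np.ndarray, te: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Min-max normalize train/test columns with train-fit parameters."""
    mn = X[tr].min(axis=0)
    mx = X[tr].max(axis=0)
    span = mx - mn
    safe = np.where(span > 0, span, 1.0)
    Xtr = 2.0 * (X[tr] - mn) / safe - 1.0
    Xte = 2.0 * (X[te] - mn) / safe - 1.0
    Xtr[:, span <= 0] = 0.0
    Xte[:, span <= 0] = 0.0
    return Xtr, Xte


# ---------------------------------------------------------------------------
# Nested selection CV
# ---------------------------------------------------------------------------


def _elimination_sizes(n_features: int, N: int) -> np.ndarray:
    """Surviving-set sizes that get evaluated: n, n-N, n-2N, ... (> 0)."""
    sizes = [n_features]
    s = n_features
    while s > 0:
        s -= min(N, s)
        if s > 0:
            sizes.append(s)
    return np.array(sizes, dtype=int)


def run_selection_cv(
    fm: FeatureMatrix,
    relief_cfg: ReliefConfig | None = None,
    svm_cfg: SVMConfig | None = None,
    N: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    inner_folds: int = 5,
) -> StepwiseCVResult:
    """Nested selection CV: per outer fold, IterRelCen on the training data
    (inner evaluator = ``inner_folds``-fold CV on the training fold; 0 skips
    the inner evaluation), then outer test accuracy at every step of the
    elimination schedule. ``fm`` holds raw (unnormalized) features.
    """
    relief_cfg = relief_cfg or ReliefConfig()
    svm_cfg = svm_cfg or SVMConfig()
    assignment = stratified_folds(fm.labels, k=n_folds, seed=seed)
    sizes = _elimination_sizes(fm.n_features, N)
    accuracies = np.empty((sizes.size, n_folds))
    traces: list[SelectionTrace] = []

    for fold in range(n_folds):
        tr = assignment != fold
        te = ~tr
        ytr = fm.labels[tr]
        Xtr, Xte = _normalized_split(fm.values, tr, te)
        yte = fm.labels[te]
        train_fm = FeatureMatrix(values=Xtr, labels=ytr, map=fm.map)

        if inner_folds > 0:
            inner_assign = stratified_folds(ytr, k=inner_folds, seed=seed + 1)

            def inner_eval(ids: np.ndarray) -> float:
                accs = []
                for f in range(inner_folds):
                    itr = inner_assign != f
                    ite = ~itr
                    accs.append(
                        _subset_accuracy(
                            Xtr[np.ix_(itr, ids)], ytr[itr],
                            Xtr[np.ix_(ite, ids)], ytr[ite], svm_cfg,
                        )
                    )
                return float(np.mean(accs))

            evaluator = inner_eval
        else:
            evaluator = None

        trace = iterrelcen(train_fm, relief_cfg, N, evaluator=evaluator)
        traces.append(trace)
        for s, (ids, _) in enumerate(trace.steps()):
            accuracies[s, fold] = _subset_accuracy(
                Xtr[:, ids], ytr, Xte[:, ids], yte, svm_cfg
            )

    return StepwiseCVResult(
        step_sizes=sizes,
        accuracies=accuracies,
        fold_assignments=assignment,
        traces=traces,
    )


def select_optimal(
    steps: list[tuple[np.ndarray, float]], n_bands: int = 13
) -> int:
    """Index of the optimal step: maximal accuracy (ties within 1e-12), and
    among those the smallest channel set, then the smallest feature set."""
    if not steps:
        raise ValidationError("no steps to choose from")
    accs = np.array([a for _, a in steps], dtype=float)
    best = accs.max()
    candidates = np.flatnonzero(accs >= best - 1e-12)
    key = [
        (features_to_channels(steps[i][0], n_bands).size, len(steps[i][0]), i)
        for i in candidates
    ]
    return int(min(key)[2])


def optimal_channels(
    fm: FeatureMatrix,
    relief_cfg: ReliefConfig | None = None,
    svm_cfg: SVMConfig | None = None,
    N: int = 10,
    n_folds: int = 10,
    seed: int = 0,
    inner_folds: int = 5,
    stepwise: StepwiseCVResult | None = None,
) -> OptimalSelection:
    """End-to-end optimal channel determination.

    The operating step is chosen by mean outer-fold accuracy (smallest channel
    set among ties). Because the outer folds generally disagree on feature
    identities, the reported channel set is a point estimate from one final
    IterRelCen pass over the full data at the chosen step size; the accuracy
    attached to it remains the cross-validated one.
    """
    relief_cfg = relief_cfg or ReliefConfig()
    svm_cfg = svm_cfg or SVMConfig()
    if stepwise is None:
        stepwise = run_selection_cv(
            fm, relief_cfg, svm_cfg, N=N, n_folds=n_folds, seed=seed,
            inner_folds=inner_folds,
        )
    full_fm = minmax_normalize(fm)
    full_trace = iterrelcen(full_fm, relief_cfg, N, evaluator=None)
    full_steps = [ids for ids, _ in full_trace.steps()]
    mean_acc = stepwise.mean_accuracy
    chosen = select_optimal(
        [(full_steps[s], mean_acc[s]) for s in range(len(full_steps))],
        n_bands=fm.map.n_bands,
    )
    ids = full_steps[chosen]
    channels = features_to_channels(ids, fm.map.n_bands)
    bands = {
        int(c): np.sort(fm.map.band_of(ids[fm.map.channel_of(ids) == c]))
        for c in channels
    }
    # weights of the surviving features, from the pass that produced this step
    weights = None
    if chosen > 0:
        rec = full_trace.iterations[chosen - 1]
        keep = np.isin(rec.weights.feature_ids, ids)
        weights = WeightVector(
            weights=rec.weights.weights[keep], feature_ids=rec.weights.feature_ids[keep]
        )
    return OptimalSelection(
        step_index=chosen,
        mean_accuracy=float(mean_acc[chosen]),
        feature_ids=ids,
        channels=channels,
        bands_per_channel=bands,
        weights=weights,
    )


# ---------------------------------------------------------------------------
# Reporting arithmetic
# ---------------------------------------------------------------------------


def channel_weight_map(weights: WeightVector, fmap: FeatureMap) -> np.ndarray:
    """Per-channel weight: the sum of a channel's surviving feature weights;
    channels with no surviving feature get 0."""
    out = np.zeros(fmap.n_channels)
    np.add.at(out, fmap.channel_of(weights.feature_ids), weights.weights)
    return out


def accuracy_vs_channels(
    fm: FeatureMatrix,
    channel_weights: np.ndarray,
    svm_cfg: SVMConfig | None = None,
    n_folds: int = 10,
    seed: int = 0,
) -> ChannelCurve:
    """CV accuracy as channels are added one by one in descending weight
    order (ties by ascending channel index), using all bands of each added
    channel. The last point equals plain all-channel CV accuracy."""
    svm_cfg = svm_cfg or SVMConfig()
    channel_weights = np.asarray(channel_weights, dtype=float)
    n_ch = fm.map.n_channels
    if channel_weights.shape != (n_ch,):
        raise ValidationError("one weight per channel required")
    order = np.lexsort((np.arange(n_ch), -channel_weights))
    assignment = stratified_folds(fm.labels, k=n_folds, seed=seed)
    means, sds = [], []
    for c in range(1, n_ch + 1):
        chans = order[:c]
        ids = np.sort(
            np.concatenate(
                [np.arange(ch * fm.map.n_bands, (ch + 1) * fm.map.n_bands) for ch in chans]
            )
        )
        accs = []
        for fold in range(n_folds):
            tr = assignment != fold
            te = ~tr
            Xtr, Xte = _normalized_split(fm.values[:, ids], tr, te)
            accs.append(
                _subset_accuracy(Xtr, fm.labels[tr], Xte, fm.labels[te], svm_cfg)
            )
        means.append(float(np.mean(accs)))
        sds.append(float(np.std(accs, ddof=1)))
    return ChannelCurve(
        n_channels_used=np.arange(1, n_ch + 1),
        mean_accuracy=np.array(means),
        sd_accuracy=np.array(sds),
        channel_order=order,
    )


def band_usage_counts(
    feature_ids: np.ndarray, fmap: FeatureMap
) -> np.ndarray:
    """Per band, the number of distinct channels that kept that band."""
    ids = np.asarray(feature_ids, dtype=int)
    counts = np.zeros(fmap.n_bands, dtype=int)
    if ids.size == 0:
        return counts
    pairs = np.unique(np.stack([fmap.channel_of(ids), fmap.band_of(ids)]), axis=1)
    for b in pairs[1]:
        counts[b] += 1
    return counts
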