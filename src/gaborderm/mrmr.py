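"""Minimum-redundancy maximum-relevance feature selection via mutual information.

Continuous deep features are discretized to three states at mu +/- sigma
(thresholds fit on training rows only), the convention of the original
mRMR literature.  Mutual information is the plug-in histogram estimate
in bits,

    I(X;Y) = sum_xy p(x,y) log2( p(x,y) / (p(x) p(y)) ),    0*log 0 := 0.

Relevance of a feature set F for the class C is the mean I(f; C) over F;
redundancy is the normalised double sum of pairwise I(f_i; f_j) over F —
self-pairs included and normalisation by |F|, exactly as the criterion is
printed in the reference protocol (the conventional 1/|F|^2 variant is
available via ``pair_normalization='squared'``).  Greedy selection picks
first the single most relevant feature, then repeatedly the candidate
maximising

    I(X_i; C) - (1/|S|) * sum_{X_j in S} I(X_i; X_j)

with ties broken toward the lowest column index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "DiscretizationRule",
    "JointHistogram",
    "SelectionResult",
    "AblationCurve",
    "fit_discretization",
    "discretize",
    "joint_histogram",
    "mutual_information",
    "entropy",
    "relevance",
    "redundancy",
    "mrmr_select",
    "ablation_sweep",
]


@dataclass
class DiscretizationRule:
    """Per-feature (mu - sigma, mu + sigma) thresholds, fit on train rows.

    States are 0 (low), 1 (mid), 2 (high); constant columns map to all-mid
    and are flagged in ``constant_columns``.
    """

    lower: np.ndarray
    upper: np.ndarray
    constant_columns: np.ndarray

    def __post_init__(self):
        if np.any(self.lower > self.upper):
            raise ValueError("discretization thresholds must be ordered")


@dataclass
class JointHistogram:
    """Joint and marginal plug-in probabilities of a discrete pair."""

    counts: np.ndarray
    n: int

    @property
    def joint(self) -> np.ndarray:
        return self.counts / self.n

    @property
    def px(self) -> np.ndarray:
        return self.joint.sum(axis=1)

    @property
    def py(self) -> np.ndarray:
        return self.joint.sum(axis=0)


@dataclass
class SelectionResult:
    """Greedy mRMR output: pick order with per-step score traces."""

    order: list
    relevance_trace: list
    criterion_trace: list

    @property
    def k(self) -> int:
        return len(self.order)


@dataclass
class AblationCurve:
    """Test accuracy versus selected-feature count, per SVM kernel."""

    ks: list
    accuracy: dict = field(default_factory=dict)  # kernel -> [acc per k]

    def __post_init__(self):
        if list(self.ks) != sorted(set(self.ks)):
            raise ValueError("k values must be strictly increasing")

    def best_k(self, kernel: str) -> tuple:
        accs = self.accuracy[kernel]
        i = int(np.argmax(accs))
        return self.ks[i], accs[i]


def fit_discretization(values: np.ndarray) -> DiscretizationRule:
    """Fit mu +/- sigma thresholds per column on training rows."""
    values = np.asarray(values, dtype=float)
    mu = values.mean(axis=0)
    sigma = values.std(axis=0)
    constant = sigma == 0
    return DiscretizationRule(
        lower=mu - sigma, upper=mu + sigma, constant_columns=constant
    )


def discretize(values: np.ndarray, rule: DiscretizationRule) -> np.ndarray:
    """Map columns to 3-state integer codes using the fitted thresholds."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    states = np.ones(values.shape, dtype=np.int64)
    states[values < rule.lower] = 0
    states[values > rule.upper] = 2
    states[:, rule.constant_columns] = 1
    return states


def joint_histogram(x: np.ndarray, y: np.ndarray) -> JointHistogram:
    x = np.asarray(x).ravel()
    y = np.asarray(y).ravel()
    if len(x) != len(y):
        raise ValueError(
            f"length mismatch: x has {len(x)} samples, y has {len(y)}"
        )
    if len(x) == 0:
        raise ValueError("need at least one sample")
    _, xi = np.unique(x, return_inverse=True)
    _, yi = np.unique(y, return_inverse=True)
    counts = np.zeros((xi.max() + 1, yi.max() + 1))
    np.add.at(counts, (xi, yi), 1.0)
    return JointHistogram(counts=counts, n=len(x))


def mutual_information(x: np.ndarray, y: np.ndarray) -> float:
    """Plug-in mutual information in bits; non-negative, symmetric."""
    h = joint_histogram(x, y)
    pxy = h.joint
    outer = np.outer(h.px, h.py)
    nz = pxy > 0
    mi = float(np.sum(pxy[nz] * np.log2(pxy[nz] / outer[nz])))
    return max(mi, 0.0)  # clip the tiny negative round-off


def entropy(x: np.ndarray) -> float:
    """Plug-in Shannon entropy in bits."""
    _, counts = np.unique(np.asarray(x).ravel(), return_counts=True)
    p = counts / counts.sum()
    return float(-np.sum(p * np.log2(p)))


def relevance(states: np.ndarray, labels: np.ndarray) -> float:
    """Mean mutual information between each column and the class labels."""
    states = np.atleast_2d(states)
    if states.shape[1] == 0:
        return 0.0
    return float(
        np.mean([
            mutual_information(states[:, j], labels)
            for j in range(states.shape[1])
        ])
    )


def redundancy(states: np.ndarray, pair_normalization: str = "printed") -> float:
    """Normalised double-sum of pairwise MI over the feature subset.

    ``'printed'`` divides the full double sum (self-pairs included) by
    |F| as the reference criterion is printed; ``'squared'`` divides by
    |F|^2, the convention of the wider mRMR literature.
    """
    states = np.atleast_2d(states)
    d = states.shape[1]
    if d == 0:
        return 0.0
    total = 0.0
    for i in range(d):
        for j in range(d):
            total += mutual_information(states[:, i], states[:, j])
    if pair_normalization == "printed":
        return total / d
    if pair_normalization == "squared":
        return total / d**2
    raise ValueError(f"unknown pair_normalization {pair_normalization!r}")


def mrmr_select(
    states: np.ndarray, labels: np.ndarray, k: int
) -> SelectionResult:
    """Greedy mRMR selection of k features from discretized columns.

    The first pick maximises I(X; C); each later pick maximises
    I(X_i; C) - (1/|S|) * sum_{X_j in S} I(X_i; X_j).  Ties break toward
    the lowest column index.  ``states`` must already be discretized with
    a rule fit on the same training rows as ``labels``.
    """
    states = np.atleast_2d(np.asarray(states))
    labels = np.asarray(labels).ravel()
    n, d = states.shape
    if not 1 <= k <= d:
        raise ValueError(f"k must be in [1, {d}], got {k}")
    if n != len(labels):
        raise ValueError("states and labels disagree on the sample count")

    rel = np.array([
        mutual_information(states[:, j], labels) for j in range(d)
    ])
    # pairwise feature MI, computed lazily
    pair_cache: dict = {}

    def pair_mi(i: int, j: int) -> float:
        key = (min(i, j), max(i, j))
        if key not in pair_cache:
            pair_cache[key] = mutual_information(states[:, i], states[:, j])
        return pair_cache[key]

    order: list = []
    relevance_trace: list = []
    criterion_trace: list = []
    remaining = list(range(d))

    first = int(np.argmax(rel))  # argmax takes the lowest index on ties
    order.append(first)
    relevance_trace.append(float(rel[first]))
    criterion_trace.append(float(rel[first]))
    remaining.remove(first)

    while len(order) < k:
        scores = np.array([
            rel[i] - np.mean([pair_mi(i, j) for j in order])
            for i in remaining
        ])
        pick = remaining[int(np.argmax(scores))]
        order.append(pick)
        relevance_trace.append(float(rel[pick]))
        criterion_trace.append(float(scores.max()))
        remaining.remove(pick)

    return SelectionResult(
        order=order,
        relevance_trace=relevance_trace,
        criterion_trace=criterion_trace,
    )


def ablation_sweep(
    train_features,
    train_labels,
    test_features,
    test_labels,
    ks,
    kernels=("linear", "quadratic", "gaussian"),
    svm_seed: int = 0,
) -> AblationCurve:
    """Test accuracy of top-k mRMR features for each k and SVM kernel.

    Selection (discretization rule, label MI, greedy order) uses training
    rows only; the nested greedy order is computed once at max(ks) and
    prefixes are reused.  ``train_features``/``test_features`` are
    FeatureMatrix objects or plain arrays.
    """
    from gaborderm.classify import SVMSpec, train_classifier

    ks = list(ks)
    if not ks:
        raise ValueError("ks must be non-empty")
    if list(ks) != sorted(set(ks)):
        raise ValueError("ks must be strictly increasing")

    xtr = getattr(train_features, "values", np.asarray(train_features))
    xte = getattr(test_features, "values", np.asarray(test_features))
    ytr = np.asarray(train_labels)
    yte = np.asarray(test_labels)
    if ks[-1] > xtr.shape[1]:
        raise ValueError(
            f"largest k={ks[-1]} exceeds feature count {xtr.shape[1]}"
        )

    rule = fit_discretization(xtr)
    states = discretize(xtr, rule)
    selection = mrmr_select(states, ytr, ks[-1])

    curve = AblationCurve(ks=ks, accuracy={kern: [] for kern in kernels})
    for kern in kernels:
        for k in ks:
            cols = selection.order[:k]
            model = train_classifier(
                xtr[:, cols], ytr, SVMSpec(kernel=kern), seed=svm_seed
            )
            acc = float(np.mean(model.predict(xte[:, cols]) == yte))
            curve.accuracy[kern].append(acc)
    return curve
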