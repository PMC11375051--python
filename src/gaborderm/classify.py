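"""SVM classification with linear, quadratic and Gaussian kernels.

The quadratic kernel is the inhomogeneous polynomial of degree 2; the
Gaussian kernel scale defaults to 1/(d * var(X)) (scikit-learn 'scale').
Features are standardized with training-set statistics; the multiclass
scheme is one-vs-one with per-class real-valued scores exposed for ROC
analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = ["SVMSpec", "SVMModel", "train_classifier"]

_KERNELS = ("linear", "quadratic", "gaussian")


@dataclass(frozen=True)
class SVMSpec:
    kernel: str = "linear"
    box_constraint: float = 1.0
    kernel_scale: float | str = "auto"
    standardize: bool = True
    multiclass_scheme: str = "one-vs-one"

    def __post_init__(self):
        if self.kernel not in _KERNELS:
            raise ValueError(
                f"unknown kernel {self.kernel!r}; expected one of {_KERNELS}"
            )
        if self.box_constraint <= 0:
            raise ValueError("box_constraint must be positive")


class SVMModel:
    """A fitted SVM with per-class decision scores."""

    def __init__(self, pipeline: Pipeline, classes: np.ndarray):
        self._pipeline = pipeline
        self.classes_ = classes

    def predict(self, X) -> np.ndarray:
        return self._pipeline.predict(np.asarray(X))

    def decision_scores(self, X) -> np.ndarray:
        """n x n_classes real-valued scores (one-vs-rest shaped)."""
        scores = self._pipeline.decision_function(np.asarray(X))
        if scores.ndim == 1:  # binary: expand to two columns
            scores = np.column_stack([-scores, scores])
        return scores


def train_classifier(X, y, spec: SVMSpec = SVMSpec(), seed: int = 0) -> SVMModel:
    """Fit an SVM per the spec; standardization parameters fit on X only."""
    X = getattr(X, "values", X)
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError(
            f"training labels contain a single class {classes.tolist()}; "
            "at least two are required"
        )
    if len(y) < len(classes):
        raise ValueError("need at least as many rows as classes")

    gamma = spec.kernel_scale
    if gamma == "auto":
        gamma = "scale"  # 1 / (d * var(X))
    if spec.kernel == "linear":
        svc = SVC(kernel="linear", C=spec.box_constraint,
                  decision_function_shape="ovr", random_state=seed)
    elif spec.kernel == "quadratic":
        svc = SVC(kernel="poly", degree=2, coef0=1.0, gamma=gamma,
                  C=spec.box_constraint,
                  decision_function_shape="ovr", random_state=seed)
    else:
        svc = SVC(kernel="rbf", gamma=gamma, C=spec.box_constraint,
                  decision_function_shape="ovr", random_state=seed)

    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", svc))
    pipeline = Pipeline(steps)
    pipeline.fit(X, y)
    return SVMModel(pipeline=pipeline, classes=classes)
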