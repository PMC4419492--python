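"""Soft-margin kernel SVMs: the standard C-SVM and the biased (per-class
penalty) variant.

The C-SVM solves the usual dual quadratic programme

    min_a  1/2 sum_ij a_i a_j y_i y_j K(x_i, x_j) - sum_i a_i
    s.t.   sum_i y_i a_i = 0,   0 <= a_i <= C,

and classifies by ``sign(sum_i a_i y_i K(x, x_i) + b)``.  The biased SVM
replaces the single box constraint with class-specific penalties
``0 <= a_i <= C+`` for positive samples and ``0 <= a_i <= C-`` for negative
samples, so that misclassifying the rare (nodule) class costs more.  The
penalty for the majority class is conventionally derived from the class
ratio: ``C- = round(C+ / round(N_ratio))`` (floored at 1).

The QP itself is delegated to libsvm's SMO solver (scikit-learn ``SVC``);
per-class penalties enter through sample-class weights, which scale the box
constraint exactly as above.  The trained model is extracted into a
self-contained :class:`SVMModel` whose prediction path is an explicit
kernel expansion over the stored support coefficients.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.metrics.pairwise import linear_kernel, polynomial_kernel, rbf_kernel
from sklearn.svm import SVC

from .datasets import LabeledDataset

__all__ = ["KernelSpec", "SVMModel", "train_csvm", "train_biased_svm",
           "biased_penalty_from_ratio", "predict"]

SOLVER_TOL = 1e-4
MAX_ITER = 1_000_000


@dataclass(frozen=True)
class KernelSpec:
    """Kernel family and parameters.

    ``gamma`` may be the string ``"scale"`` (resolved at training time to
    ``1 / (d * var(X))`` on the possibly-standardized training features) or
    a positive number.
    """

    name: str = "rbf"
    gamma: float | str = "scale"
    degree: int = 3
    coef0: float = 0.0

    def __post_init__(self) -> None:
        if self.name not in ("rbf", "linear", "poly"):
            raise ValueError(f"unsupported kernel: {self.name}")


def _kernel_matrix(spec: KernelSpec, gamma: float, X: np.ndarray,
                   Y: np.ndarray) -> np.ndarray:
    if spec.name == "rbf":
        return rbf_kernel(X, Y, gamma=gamma)
    if spec.name == "linear":
        return linear_kernel(X, Y)
    return polynomial_kernel(X, Y, degree=spec.degree, gamma=gamma,
                             coef0=spec.coef0)


@dataclass
class SVMModel:
    """A trained soft-margin kernel SVM in dual form.

    ``dual_coef`` holds ``alpha_i * y_i`` for the support vectors, so
    ``alphas = |dual_coef|`` and the decision function is
    ``K(x, SV) @ dual_coef + offset``.  ``scaler_mean``/``scaler_scale``
    hold the training-fold standardization (None when disabled).
    """

    support_vectors: np.ndarray
    dual_coef: np.ndarray
    offset: float
    kernel: KernelSpec
    gamma_value: float
    class_penalties: tuple[float, float]        # (C+, C-)
    support_indices: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    support_labels: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    scaler_mean: np.ndarray | None = None
    scaler_scale: np.ndarray | None = None
    feature_names: tuple[str, ...] = ()
    version: str = "rusmote-svm-1"

    @property
    def alphas(self) -> np.ndarray:
        return np.abs(self.dual_coef)

    def _transform(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if self.scaler_mean is not None:
            X = (X - self.scaler_mean) / self.scaler_scale
        return X

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.support_vectors.shape[1]:
            if not (X.ndim == 2 and X.shape[0] == 0):
                raise ValueError(
                    f"expected {self.support_vectors.shape[1]} feature columns, "
                    f"got shape {X.shape}")
        if X.shape[0] == 0:
            return np.empty(0)
        K = _kernel_matrix(self.kernel, self.gamma_value,
                           self._transform(X), self.support_vectors)
        return K @ self.dual_coef + self.offset

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Labels in {+1, -1}; a decision value of exactly 0 maps to +1."""
        f = self.decision_function(X)
        return np.where(f >= 0, 1, -1)

    # -- serialization ---------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "version": self.version,
            "kernel": {"name": self.kernel.name, "gamma": self.kernel.gamma,
                       "degree": self.kernel.degree, "coef0": self.kernel.coef0},
            "gamma_value": self.gamma_value,
            "class_penalties": list(self.class_penalties),
            "support_vectors": self.support_vectors.tolist(),
            "dual_coef": self.dual_coef.tolist(),
            "offset": self.offset,
            "support_indices": self.support_indices.tolist(),
            "support_labels": self.support_labels.tolist(),
            "scaler_mean": None if self.scaler_mean is None else self.scaler_mean.tolist(),
            "scaler_scale": None if self.scaler_scale is None else self.scaler_scale.tolist(),
            "feature_names": list(self.feature_names),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SVMModel":
        payload = json.loads(Path(path).read_text())
        kern = payload["kernel"]
        return cls(
            support_vectors=np.array(payload["support_vectors"], dtype=float),
            dual_coef=np.array(payload["dual_coef"], dtype=float),
            offset=float(payload["offset"]),
            kernel=KernelSpec(kern["name"], kern["gamma"], kern["degree"],
                              kern["coef0"]),
            gamma_value=float(payload["gamma_value"]),
            class_penalties=tuple(payload["class_penalties"]),
            support_indices=np.array(payload["support_indices"], dtype=int),
            support_labels=np.array(payload["support_labels"], dtype=int),
            scaler_mean=(None if payload["scaler_mean"] is None
                         else np.array(payload["scaler_mean"])),
            scaler_scale=(None if payload["scaler_scale"] is None
                          else np.array(payload["scaler_scale"])),
            feature_names=tuple(payload["feature_names"]),
            version=payload["version"],
        )


def _resolve_gamma(spec: KernelSpec, X: np.ndarray) -> float:
    if spec.name == "linear":
        return 0.0
    if isinstance(spec.gamma, str):
        if spec.gamma != "scale":
            raise ValueError(f"unknown gamma spec: {spec.gamma!r}")
        var = float(X.var())
        return 1.0 / (X.shape[1] * var) if var > 0 else 1.0
    return float(spec.gamma)


def train_biased_svm(train: LabeledDataset, c_plus: float, c_minus: float,
                     kernel: KernelSpec | str = KernelSpec(),
                     standardize: bool = True) -> SVMModel:
    """Train the per-class-penalty soft-margin SVM.

    The box constraint is ``0 <= alpha_i <= C+`` on positive-class samples
    and ``0 <= alpha_i <= C-`` on negative-class samples.
    """
    if isinstance(kernel, str):
        kernel = KernelSpec(kernel)
    if c_plus <= 0 or c_minus <= 0:
        raise ValueError("penalties must be positive")
    classes = np.unique(train.labels)
    if len(classes) < 2:
        raise ValueError("training data must contain both classes")
    if not np.all(np.isfinite(train.features)):
        raise ValueError("non-finite features in training data")

    X = train.features.astype(float)
    mean = scale = None
    if standardize:
        mean = X.mean(axis=0)
        scale = X.std(axis=0)
        scale[scale == 0] = 1.0
        X = (X - mean) / scale
    y = train.labels
    gamma = _resolve_gamma(kernel, X)

    # class_weight scales C per class: effective box constraint C * w[y_i]
    est = SVC(C=1.0, kernel=kernel.name,
              gamma=(gamma if kernel.name != "linear" else "scale"),
              degree=kernel.degree, coef0=kernel.coef0,
              class_weight={1: c_plus, -1: c_minus},
              tol=SOLVER_TOL, max_iter=MAX_ITER, cache_size=200)
    with warnings.catch_warnings():
        warnings.simplefilter("always")
        est.fit(X, y)
    if est.fit_status_ != 0:
        warnings.warn("SVM solver did not converge within the iteration cap",
                      stacklevel=2)

    support = est.support_
    return SVMModel(
        support_vectors=X[support],
        dual_coef=est.dual_coef_[0].copy(),
        offset=float(est.intercept_[0]),
        kernel=kernel,
        gamma_value=gamma,
        class_penalties=(float(c_plus), float(c_minus)),
        support_indices=support.copy(),
        support_labels=y[support].copy(),
        scaler_mean=mean,
        scaler_scale=scale,
        feature_names=train.feature_names,
    )


def train_csvm(train: LabeledDataset, C: float,
               kernel: KernelSpec | str = KernelSpec(),
               standardize: bool = True) -> SVMModel:
    """Train the standard C-SVM (single penalty C on both classes)."""
    return train_biased_svm(train, C, C, kernel=kernel, standardize=standardize)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def biased_penalty_from_ratio(c_plus: float, n_ratio: float) -> float:
    """Majority-class penalty from the class ratio.

    ``C- = max(1, round(C+ / round(N_ratio)))`` with round = half away from
    zero.  E.g. C+ = 10 at a ratio of 454/75 (~6) gives C- = 2.
    """
    if n_ratio < 1:
        raise ValueError("n_ratio must be >= 1")
    return float(max(1, _round_half_away(c_plus / _round_half_away(n_ratio))))


def predict(model: SVMModel, X: np.ndarray) -> np.ndarray:
    """Labels in {+1, -1} from the model's kernel-expansion decision rule."""
    return model.predict(X)
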