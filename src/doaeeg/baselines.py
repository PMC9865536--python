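"""Conventional feature-based PSI regressors used as comparisons:
RBF-kernel support vector regression, a 300-tree random forest, and a
14-64-16-1 multilayer perceptron, all fit on the standardized 14-feature
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

N_FEATURES = 14
KINDS = ("svr", "rf", "ann")


@dataclass
class BaselineSpec:
    kind: str = "rf"
    svr: dict = field(default_factory=lambda: {"C": 1.0, "epsilon": 0.1, "gamma": "scale"})
    rf_n_trees: int = 300
    ann_hidden: tuple[int, int] = (64, 16)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"kind must be one of {KINDS}")


@dataclass
class FittedBaseline:
    spec: BaselineSpec
    estimator: object


def fit_baseline(spec: BaselineSpec, features: np.ndarray, psi: np.ndarray) -> FittedBaseline:
    """Fit one baseline on column-standardized 14-feature vectors."""
    features = np.asarray(features, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if features.ndim != 2 or features.shape[1] != N_FEATURES:
        raise ValueError(f"features must be (n, {N_FEATURES}), got {features.shape}")
    if np.any(psi < 0) or np.any(psi > 100):
        raise ValueError("PSI labels must lie in [0, 100]")
    if spec.kind == "svr":
        est = SVR(kernel="rbf", **spec.svr)
    elif spec.kind == "rf":
        est = RandomForestRegressor(n_estimators=spec.rf_n_trees, random_state=spec.seed)
    else:
        est = MLPRegressor(
            hidden_layer_sizes=spec.ann_hidden,
            activation="relu",
            solver="adam",
            learning_rate_init=0.005,
            batch_size=min(64, len(features)),
            max_iter=256,
            alpha=1e-4,
            random_state=spec.seed,
        )
    est.fit(features, psi)
    return FittedBaseline(spec=spec, estimator=est)


def predict_baseline(model: FittedBaseline, features: np.ndarray) -> np.ndarray:
    """Predict PSI, clipped to [0, 100] for parity with the bounded DRSN head."""
    features = np.asarray(features, dtype=float)
    if features.ndim != 2 or features.shape[1] != N_FEATURES:
        raise ValueError(f"features must be (n, {N_FEATURES}), got {features.shape}")
    if not hasattr(model.estimator, "predict"):
        raise ValueError("model is not fitted")
    return np.clip(model.estimator.predict(features), 0.0, 100.0)
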