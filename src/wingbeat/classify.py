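"""One-vs-all binary classification methods.

Three representations of the same event feed three methods:

* ``wbf`` — the scalar dominant-frequency estimate alone;
* ``features`` — the canonical 12-feature vector, classified by a
  Random Forest;
* ``nn`` — the 2048-point spectral vector, classified by a 3-hidden-layer
  ReLU network (2000/1500/1000 nodes, dropout 0.5 on the last hidden
  layer, Adam, cross-entropy).

By default the WBF method uses the identical tree-ensemble machinery
restricted to the single WBF feature, so differences between ``wbf`` and
``features`` reflect the representation rather than the learner; a 1-D
Gaussian class-conditional classifier is available as an alternative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from ._mlp import BinaryMLP
from .features import FEATURE_NAMES
from .spectral import POINTS_PER_CHANNEL

__all__ = ["METHODS", "NNConfig", "ForestConfig", "BinaryClassifier", "fit",
           "predict_proba", "input_width"]

METHODS = ("wbf", "features", "nn")

_WIDTHS = {"wbf": 1, "features": len(FEATURE_NAMES), "nn": 4 * POINTS_PER_CHANNEL}


def input_width(method: str) -> int:
    """Expected input dimensionality for a method."""
    try:
        return _WIDTHS[method]
    except KeyError:
        raise ValueError(f"unknown method: {method!r}") from None


@dataclass(frozen=True)
class NNConfig:
    """Architecture and training schedule of the neural-network method.

    The default three hidden layers (2000, 1500, 1000) with a single
    probabilistic output define the reference architecture; training
    hyperparameters default to learning rate 1e-3, 30 epochs, batch 32.
    Smaller ``layer_sizes`` scale the network down for cheap experiment
    grids without changing its form.
    """

    layer_sizes: tuple = (2000, 1500, 1000)
    dropout_last: float = 0.5
    learning_rate: float = 1e-3
    epochs: int = 30
    batch_size: int = 32

    def __post_init__(self) -> None:
        if len(self.layer_sizes) != 3:
            raise ValueError("exactly 3 hidden layers are required")


@dataclass(frozen=True)
class ForestConfig:
    """Random Forest settings shared by the wbf and features methods."""

    n_estimators: int = 500
    max_features: str = "sqrt"
    wbf_mode: str = "forest"  # or "gaussian"


class _Gaussian1D:
    """Class-conditional univariate Gaussian alternative for the WBF
    method: posterior of 'target' under two fitted normals with
    empirical priors."""

    def fit(self, X: np.ndarray, y: np.ndarray) -> "_Gaussian1D":
        x = X.reshape(-1)
        self.params = {}
        for cls in (False, True):
            xs = x[y == cls]
            self.params[cls] = (xs.mean(), max(xs.std(), 1e-9), xs.size / x.size)
        return self

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        from scipy.stats import norm

        x = X.reshape(-1)
        like = {}
        for cls, (mu, sd, prior) in self.params.items():
            like[cls] = prior * norm.pdf(x, mu, sd)
        denom = like[True] + like[False]
        denom[denom == 0] = 1.0
        return like[True] / denom


@dataclass
class BinaryClassifier:
    """A fitted one-vs-all classifier for one target species."""

    method: str
    target_species: Optional[str]
    model: object
    decision_threshold: float = 0.5
    seed: int = 0

    def predict_proba(self, X) -> np.ndarray:
        return predict_proba(self, X)

    def predict(self, X) -> np.ndarray:
        return self.predict_proba(X) >= self.decision_threshold


def _validate(method: str, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=np.float64)
    if X.ndim == 1:
        X = X[:, None]
    width = input_width(method)
    if X.ndim != 2 or X.shape[1] != width:
        raise ValueError(
            f"method {method!r} expects inputs of width {width}, got {X.shape}"
        )
    return X


def fit(
    method: str,
    train_inputs,
    train_labels,
    config=None,
    seed: int = 0,
    target_species: Optional[str] = None,
) -> BinaryClassifier:
    """Train a one-vs-all classifier.

    ``train_labels`` is boolean (True = target).  Deterministic given
    ``seed``.  Raises on a single-class training set or an input width
    that does not match the method.
    """
    X = _validate(method, train_inputs)
    y = np.asarray(train_labels, dtype=bool)
    if y.shape[0] != X.shape[0]:
        raise ValueError("inputs and labels must have equal length")
    if y.all() or not y.any():
        raise ValueError("training set must contain both classes")

    if method == "nn":
        cfg = config or NNConfig()
        model = BinaryMLP(
            n_inputs=X.shape[1],
            hidden=cfg.layer_sizes,
            dropout_last=cfg.dropout_last,
            learning_rate=cfg.learning_rate,
            epochs=cfg.epochs,
            batch_size=cfg.batch_size,
            seed=seed,
        ).fit(X, y)
    else:
        cfg = config or ForestConfig()
        if method == "wbf" and cfg.wbf_mode == "gaussian":
            model = _Gaussian1D().fit(X, y)
        else:
            model = RandomForestClassifier(
                n_estimators=cfg.n_estimators,
                max_features=cfg.max_features,
                random_state=seed,
                n_jobs=1,
            ).fit(X, y)
    return BinaryClassifier(
        method=method, target_species=target_species, model=model, seed=seed
    )


def predict_proba(classifier: BinaryClassifier, inputs) -> np.ndarray:
    """Probability of the target class for each event, in [0, 1]."""
    X = _validate(classifier.method, inputs)
    model = classifier.model
    if isinstance(model, RandomForestClassifier):
        proba = model.predict_proba(X)
        target_col = list(model.classes_).index(True)
        return proba[:, target_col]
    return np.asarray(model.predict_proba(X), dtype=np.float64)
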