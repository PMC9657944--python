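"""Gradient-boosted classification stage on molecular features.

One regularized gradient-boosted tree ensemble per protein target,
trained on extracted molecular features (GNN embeddings or Morgan
fingerprints) against the logistic objective with per-tree L1/L2
penalties. The boosting itself is delegated to xgboost; this module
owns the contract: configuration, thresholding, determinism, and the
training report.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import xgboost as xgb


class BoosterError(ValueError):
    pass


@dataclass(frozen=True)
class BoosterConfig:
    n_trees: int = 200
    max_depth: int = 6
    learning_rate: float = 0.1
    reg_lambda: float = 1.0
    reg_alpha: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_trees < 1:
            raise BoosterError("n_trees must be ≥ 1")
        if self.learning_rate <= 0:
            raise BoosterError("learning_rate must be > 0")


@dataclass
class TargetClassifier:
    """A trained per-target booster with its decision threshold."""

    target_id: str
    booster: xgb.Booster
    decision_threshold: float = 0.5
    training_report: dict = field(default_factory=dict)

    @property
    def n_features(self) -> int:
        return self.booster.num_features()

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        features = np.asarray(features, dtype=np.float64)
        if features.ndim != 2 or features.shape[1] != self.n_features:
            raise BoosterError(
                f"feature dimension mismatch: got {features.shape}, "
                f"model expects (*, {self.n_features})"
            )
        return self.booster.predict(xgb.DMatrix(features)).astype(np.float64)

    def predict(self, features: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """(probabilities, binary calls); call = proba ≥ threshold."""
        proba = self.predict_proba(features)
        return proba, (proba >= self.decision_threshold).astype(np.int64)

    def save(self, path) -> None:
        self.booster.save_model(str(path))

    @classmethod
    def load(cls, path, target_id: str, decision_threshold: float = 0.5) -> "TargetClassifier":
        booster = xgb.Booster()
        booster.load_model(str(path))
        return cls(target_id, booster, decision_threshold)


def train_booster(
    features: np.ndarray,
    labels: np.ndarray,
    config: BoosterConfig = BoosterConfig(),
    target_id: str = "",
    decision_threshold: float = 0.5,
) -> TargetClassifier:
    """Fit the regularized boosted ensemble on extracted features.

    Deterministic given ``config.seed`` (single-threaded histogram
    trees). Raises on single-class labels, NaNs, or length mismatch.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels).ravel().astype(np.int64)
    if features.shape[0] != labels.shape[0]:
        raise BoosterError(
            f"{features.shape[0]} feature rows vs {labels.shape[0]} labels"
        )
    if np.isnan(features).any():
        raise BoosterError("features contain NaN")
    classes = np.unique(labels)
    if len(classes) < 2:
        raise BoosterError(f"labels contain a single class ({classes.tolist()})")
    dtrain = xgb.DMatrix(features, label=labels)
    booster = xgb.train(
        {
            "objective": "binary:logistic",
            "max_depth": config.max_depth,
            "eta": config.learning_rate,
            "lambda": config.reg_lambda,
            "alpha": config.reg_alpha,
            "seed": config.seed,
            "nthread": 1,
            "tree_method": "hist",
        },
        dtrain,
        num_boost_round=config.n_trees,
    )
    report = {
        "n_active": int((labels == 1).sum()),
        "n_inactive": int((labels == 0).sum()),
        "config": asdict(config),
    }
    return TargetClassifier(target_id, booster, decision_threshold, report)


def training_logloss(classifier: TargetClassifier,
                     features: np.ndarray, labels: np.ndarray) -> float:
    """Mean logistic loss of the fitted model on its training data."""
    p = np.clip(classifier.predict_proba(features), 1e-12, 1 - 1e-12)
    y = np.asarray(labels, dtype=np.float64).ravel()
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())
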