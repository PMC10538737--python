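"""Risk estimators: pi-hat(x) = Pr(Y=1 | X=x) behind one shared contract.

Four learner families are provided: a feed-forward neural network (single,
and as a bagged + performance-filtered "stable" ensemble), random forest,
SVM with probability calibration, and plain logistic regression.  Every
fitted learner is a :class:`RiskEstimator` whose ``predict_prob`` is
deterministic and clipped away from {0, 1} so downstream log-ratio
importance scores stay finite.

The stable ensemble trains one network per bootstrap resample, scores each
network by binary cross-entropy on its own out-of-bag rows, discards the
networks whose OOB loss exceeds the ensemble mean ("many could be better
than all"), and averages the survivors' probabilities.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, asdict
from typing import Callable, Sequence

import numpy as np
from sklearn.calibration import CalibratedClassifierCV
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import GridSearchCV
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from .cohort import CohortTable

logger = logging.getLogger(__name__)

__all__ = [
    "RiskEstimator",
    "DnnEnsembleConfig",
    "fit_single_dnn",
    "fit_stable_dnn",
    "fit_rf",
    "fit_svm",
    "fit_logistic",
    "fit_learner",
    "predict_risk",
    "DEFAULT_CLIP",
]

DEFAULT_CLIP = 1e-6


class ColumnMismatchError(ValueError):
    """Prediction matrix does not match the training encoding."""


@dataclass
class RiskEstimator:
    """A fitted conditional-probability estimator.

    ``predict_prob`` maps an (n, p) matrix in the training encoding to a
    length-n vector of class-1 probabilities, clipped to [eps, 1-eps].
    """

    _predict: Callable[[np.ndarray], np.ndarray]
    learner_kind: str
    n_features: int
    fit_metadata: dict = field(default_factory=dict)
    clip: float = DEFAULT_CLIP

    def predict_prob(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_features:
            raise ColumnMismatchError(
                f"{self.learner_kind}: expected {self.n_features} encoded columns, "
                f"got {X.shape[1]}"
            )
        p = np.asarray(self._predict(X), dtype=float).reshape(-1)
        return np.clip(p, self.clip, 1.0 - self.clip)


class _ContinuousScaler:
    """Center/scale only the continuous encoded columns by training stats."""

    def __init__(self, cols: Sequence[int], X: np.ndarray):
        self.cols = list(cols)
        self.mean = X[:, self.cols].mean(axis=0) if self.cols else np.empty(0)
        sd = X[:, self.cols].std(axis=0) if self.cols else np.empty(0)
        self.sd = np.where(sd > 0, sd, 1.0)

    def __call__(self, X: np.ndarray) -> np.ndarray:
        if not self.cols:
            return X
        X = X.copy()
        X[:, self.cols] = (X[:, self.cols] - self.mean) / self.sd
        return X


@dataclass
class DnnEnsembleConfig:
    """Hyperparameters of the (stable) neural-network learner.

    Defaults follow the analysis configuration: 4 hidden layers of
    50/40/30/20 ReLU units trained by Adam on binary cross-entropy.  The
    bag count and filtering rule belong to the ensemble wrapper.
    """

    hidden_layers: tuple = (50, 40, 30, 20)
    n_bags: int = 100
    keep_rule: str = "below_mean"   # or "top_k:<fraction>"
    epochs: int = 100
    batch_size: int = 32
    learning_rate: float = 1e-3
    l2_penalty: float = 1e-4
    seed: int = 0

    def __post_init__(self):
        if self.n_bags < 1:
            raise ValueError("n_bags must be >= 1")


def _check_trainable(train: CohortTable):
    if not train.has_both_classes():
        raise ValueError("training data must contain both outcome classes")


def _fit_mlp(X: np.ndarray, y: np.ndarray, config: DnnEnsembleConfig, seed: int):
    net = MLPClassifier(
        hidden_layer_sizes=tuple(config.hidden_layers),
        activation="relu",
        solver="adam",
        alpha=config.l2_penalty,
        batch_size=min(config.batch_size, X.shape[0]),
        learning_rate_init=config.learning_rate,
        max_iter=config.epochs,
        random_state=int(seed),
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*Maximum iterations.*")
        net.fit(X, y)
    if not np.isfinite(net.loss_):
        raise RuntimeError(
            f"non-finite training loss ({net.loss_}); lower the learning rate"
        )
    return net


def fit_single_dnn(
    train: CohortTable, config: DnnEnsembleConfig | None = None, seed: int | None = None
) -> RiskEstimator:
    """Fit one feed-forward network on the whole training table."""
    _check_trainable(train)
    config = config or DnnEnsembleConfig()
    seed = config.seed if seed is None else seed
    scaler = _ContinuousScaler(train.continuous_columns, train.X)
    net = _fit_mlp(scaler(train.X), train.Y, config, seed)
    return RiskEstimator(
        _predict=lambda X: net.predict_proba(scaler(X))[:, 1],
        learner_kind="dnn",
        n_features=train.X.shape[1],
        fit_metadata={"config": asdict(config), "seed": seed, "loss": float(net.loss_)},
    )


def _bce(y: np.ndarray, p: np.ndarray, eps: float = DEFAULT_CLIP) -> float:
    p = np.clip(p, eps, 1 - eps)
    return float(-(y * np.log(p) + (1 - y) * np.log(1 - p)).mean())


def fit_stable_dnn(train: CohortTable, config: DnnEnsembleConfig | None = None) -> RiskEstimator:
    """Bagged, performance-filtered network ensemble.

    Each of ``n_bags`` networks is trained on a bootstrap resample and scored
    by binary cross-entropy on its out-of-bag rows; networks scoring worse
    than the ensemble's mean OOB loss are dropped and the survivors'
    probabilities are averaged.
    """
    _check_trainable(train)
    config = config or DnnEnsembleConfig()
    rng = np.random.default_rng(config.seed)
    scaler = _ContinuousScaler(train.continuous_columns, train.X)
    Xs, y, n = scaler(train.X), train.Y, train.n

    nets, oob_losses = [], []
    for b in range(config.n_bags):
        # resample until both classes and a non-empty OOB set are present
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), idx)
            if 0 < y[idx].sum() < n and oob.size > 0:
                break
        net = _fit_mlp(Xs[idx], y[idx], config, seed=rng.integers(2**31))
        nets.append(net)
        oob_losses.append(_bce(y[oob], net.predict_proba(Xs[oob])[:, 1]))

    oob_losses = np.asarray(oob_losses)
    if config.keep_rule.startswith("top_k:"):
        frac = float(config.keep_rule.split(":", 1)[1])
        k = max(1, int(round(frac * len(nets))))
        keep = np.argsort(oob_losses)[:k]
    else:
        keep = np.flatnonzero(oob_losses <= oob_losses.mean())
    if keep.size == 0:   # unreachable for below_mean; guard for custom rules
        logger.warning("all networks filtered; keeping the single best")
        keep = np.array([int(np.argmin(oob_losses))])
    assert oob_losses[keep].mean() <= oob_losses.mean() + 1e-12
    kept = [nets[i] for i in keep]

    def _predict(X: np.ndarray) -> np.ndarray:
        Xs_ = scaler(X)
        return np.mean([m.predict_proba(Xs_)[:, 1] for m in kept], axis=0)

    logger.info(
        "stable DNN: kept %d/%d networks (mean OOB loss %.4f -> %.4f)",
        keep.size, config.n_bags, oob_losses.mean(), oob_losses[keep].mean(),
    )
    return RiskEstimator(
        _predict=_predict,
        learner_kind="dnn_ensemble",
        n_features=train.X.shape[1],
        fit_metadata={
            "config": asdict(config),
            "oob_losses": oob_losses.tolist(),
            "kept": keep.tolist(),
        },
    )


DEFAULT_RF_GRID = {"max_features": ["sqrt", 0.5], "min_samples_leaf": [1, 5]}
DEFAULT_SVM_GRID = {"C": [0.1, 1.0, 10.0], "gamma": ["scale"]}


def fit_rf(
    train: CohortTable,
    n_trees: int = 1000,
    grid: dict | None = None,
    cv: int = 3,
    seed: int = 0,
) -> RiskEstimator:
    """Random forest with a cross-validated grid search over a small grid."""
    _check_trainable(train)
    grid = DEFAULT_RF_GRID if grid is None else grid
    base = RandomForestClassifier(n_estimators=n_trees, random_state=seed, n_jobs=1)
    if grid:
        search = GridSearchCV(base, grid, cv=cv, scoring="neg_log_loss")
        search.fit(train.X, train.Y)
        model, best = search.best_estimator_, search.best_params_
    else:
        model, best = base.fit(train.X, train.Y), {}
    return RiskEstimator(
        _predict=lambda X: model.predict_proba(X)[:, 1],
        learner_kind="rf",
        n_features=train.X.shape[1],
        fit_metadata={"n_trees": n_trees, "best_params": best, "seed": seed},
    )


def fit_svm(
    train: CohortTable,
    kernel: str = "rbf",
    grid: dict | None = None,
    cv: int = 3,
    seed: int = 0,
) -> RiskEstimator:
    """RBF-kernel SVM; probabilities from a sigmoid calibration on CV folds."""
    _check_trainable(train)
    grid = DEFAULT_SVM_GRID if grid is None else grid
    scaler = _ContinuousScaler(train.continuous_columns, train.X)
    Xs = scaler(train.X)
    base = SVC(kernel=kernel, random_state=seed)
    if grid:
        search = GridSearchCV(base, grid, cv=cv, scoring="accuracy")
        search.fit(Xs, train.Y)
        best = search.best_params_
        base = SVC(kernel=kernel, random_state=seed, **best)
    else:
        best = {}
    model = CalibratedClassifierCV(base, method="sigmoid", cv=cv)
    model.fit(Xs, train.Y)
    return RiskEstimator(
        _predict=lambda X: model.predict_proba(scaler(X))[:, 1],
        learner_kind="svm",
        n_features=train.X.shape[1],
        fit_metadata={"kernel": kernel, "best_params": best, "seed": seed},
    )


def fit_logistic(train: CohortTable, seed: int = 0) -> RiskEstimator:
    """Maximum-likelihood logistic regression; ridge fallback when singular."""
    _check_trainable(train)
    scaler = _ContinuousScaler(train.continuous_columns, train.X)
    Xs = scaler(train.X)
    ridged = False
    design = np.column_stack([np.ones(train.n), Xs])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        logger.warning("singular design; fitting ridge-stabilized logistic model")
        ridged = True
    model = LogisticRegression(
        C=1.0 if ridged else np.inf,
        max_iter=5000,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*onverge.*")
        model.fit(Xs, train.Y)
    return RiskEstimator(
        _predict=lambda X: model.predict_proba(scaler(X))[:, 1],
        learner_kind="logistic",
        n_features=train.X.shape[1],
        fit_metadata={
            "ridged": ridged,
            "coef": model.coef_.ravel().tolist(),
            "intercept": float(model.intercept_[0]),
        },
    )


def fit_learner(
    train: CohortTable,
    learner_kind: str,
    configs: dict | None = None,
    seed: int = 0,
) -> RiskEstimator:
    """Dispatch on learner kind: dnn | dnn_ensemble | rf | svm | logistic."""
    configs = configs or {}
    if learner_kind in ("dnn_ensemble", "stable_dnn"):
        cfg = configs.get("dnn") or DnnEnsembleConfig(seed=seed)
        return fit_stable_dnn(train, cfg)
    if learner_kind == "dnn":
        cfg = configs.get("dnn") or DnnEnsembleConfig(seed=seed)
        return fit_single_dnn(train, cfg, seed=seed)
    if learner_kind == "rf":
        return fit_rf(train, seed=seed, **configs.get("rf", {}))
    if learner_kind == "svm":
        return fit_svm(train, seed=seed, **configs.get("svm", {}))
    if learner_kind == "logistic":
        return fit_logistic(train, seed=seed)
    raise ValueError(f"unknown learner kind {learner_kind!r}")


def predict_risk(estimator: RiskEstimator, X: np.ndarray) -> np.ndarray:
    """Functional alias for ``estimator.predict_prob``."""
    return estimator.predict_prob(X)
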