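"""Bagged regression ensembles over eight algorithm families.

Families: multilayer perceptron (mlp), RBF-kernel support vector
regression (svr), random forest (rf), gradient boosting (gbr), LightGBM
(lgbm), XGBoost (xgb), L1-regularized linear regression (lasso), and
partial least squares (pls).

Each final model is a bag of ``n_estimators`` (default 20) members, each
trained on a seeded with-replacement resample of the training rows of the
same size as the training set. The bag's mean is the prediction; the
spread of member predictions yields a percentile confidence interval
(default 90%: 5th/95th percentiles, linear interpolation).

Hyperparameter tuning picks the grid point with the best pooled left-out
R^2 across grouped CV folds, using single (un-bagged) fits per point;
bagging is reserved for the final refit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from lightgbm import LGBMRegressor
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.linear_model import Lasso
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR
from xgboost import XGBRegressor

ALGORITHM_FAMILIES = ("mlp", "svr", "rf", "gbr", "lgbm", "xgb", "lasso", "pls")

#: Small default grids per family (1-3 key knobs, 1-4 values); user grids
#: via tune_hyperparameters(grid=...) override these entirely.
DEFAULT_GRIDS: dict[str, list[dict]] = {
    "mlp": [
        {"hidden_layer_sizes": (64,), "alpha": 1e-3},
        {"hidden_layer_sizes": (64, 64), "alpha": 1e-3},
    ],
    "svr": [{"C": 1.0, "epsilon": 0.05}, {"C": 10.0, "epsilon": 0.05}],
    "rf": [{"n_estimators": 100, "max_features": 0.3}],
    "gbr": [{"n_estimators": 100, "learning_rate": 0.1, "max_depth": 3}],
    "lgbm": [
        {"n_estimators": 300, "num_leaves": 31, "learning_rate": 0.05,
         "colsample_bytree": 0.6},
        {"n_estimators": 600, "num_leaves": 63, "learning_rate": 0.04,
         "colsample_bytree": 0.4},
    ],
    "xgb": [{"n_estimators": 200, "max_depth": 6, "learning_rate": 0.1}],
    "lasso": [{"alpha": 1e-3}, {"alpha": 1e-2}, {"alpha": 1e-1}],
    "pls": [{"n_components": 5}, {"n_components": 10}],
}

#: Families whose fits are bit-reproducible given a fixed seed and thread
#: count (all of them here: single-threaded deterministic configurations).
DETERMINISTIC_FAMILIES = frozenset(ALGORITHM_FAMILIES)

_TREE_FAMILIES = frozenset({"rf", "gbr", "lgbm", "xgb"})


@dataclass(frozen=True)
class AlgorithmSpec:
    """One algorithm family plus its hyperparameters."""

    family: str
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.family not in ALGORITHM_FAMILIES:
            raise ValueError(
                f"unknown family {self.family!r}; choose from {ALGORITHM_FAMILIES}"
            )

    @property
    def is_tree_family(self) -> bool:
        return self.family in _TREE_FAMILIES


def make_estimator(spec: AlgorithmSpec, seed: int = 0):
    """Instantiate one unfitted estimator for a spec.

    ``seed`` fixes every stochastic element (MLP init, tree subsampling);
    thread counts are pinned to 1 so replays are bit-stable.
    """
    hp = dict(spec.hyperparameters)
    if spec.family == "mlp":
        hp.setdefault("max_iter", 500)
        return MLPRegressor(random_state=seed, **hp)
    if spec.family == "svr":
        return SVR(kernel=hp.pop("kernel", "rbf"), **hp)
    if spec.family == "rf":
        return RandomForestRegressor(random_state=seed, n_jobs=1, **hp)
    if spec.family == "gbr":
        return GradientBoostingRegressor(random_state=seed, **hp)
    if spec.family == "lgbm":
        hp.setdefault("n_jobs", 1)
        hp.setdefault("verbose", -1)
        return LGBMRegressor(random_state=seed, **hp)
    if spec.family == "xgb":
        hp.setdefault("n_jobs", 1)
        hp.setdefault("verbosity", 0)
        return XGBRegressor(random_state=seed, **hp)
    if spec.family == "lasso":
        hp.setdefault("max_iter", 5000)
        return Lasso(**hp)
    if spec.family == "pls":
        return PLSRegression(**hp)
    raise AssertionError(spec.family)


def _fit_predictor(spec: AlgorithmSpec, X, y, seed: int):
    est = make_estimator(spec, seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(X, y)
    return est


def _predict(est, X) -> np.ndarray:
    return np.asarray(est.predict(X), dtype=float).reshape(len(X))


@dataclass
class PredictionInterval:
    """Bagged mean with percentile confidence bounds (log10-cP units)."""

    mean: float
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (self.lower <= self.upper):
            raise ValueError("interval bounds out of order")


@dataclass
class BaggedModel:
    """A bag of independently bootstrapped estimators of one family."""

    estimators: list
    bootstrap_seeds: list[int]
    algorithm: AlgorithmSpec
    master_seed: int

    @property
    def n_estimators(self) -> int:
        return len(self.estimators)

    def member_predictions(self, X) -> np.ndarray:
        """(n_estimators, n_rows) matrix of per-member predictions."""
        return np.vstack([_predict(e, X) for e in self.estimators])

    def predict(self, X) -> np.ndarray:
        return self.member_predictions(X).mean(axis=0)


def bootstrap_indices(n_rows: int, n_estimators: int, seed: int) -> np.ndarray:
    """(n_estimators, n_rows) with-replacement row resamples, seeded."""
    rng = np.random.default_rng(seed)
    return rng.integers(0, n_rows, size=(n_estimators, n_rows))


def fit_bagged_ensemble(
    spec: AlgorithmSpec,
    X: np.ndarray,
    y: np.ndarray,
    n_estimators: int = 20,
    seed: int = 0,
) -> BaggedModel:
    """Train ``n_estimators`` members on seeded bootstrap resamples."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(X) != len(y) or len(y) < 2:
        raise ValueError("X rows must equal y length and be >= 2")
    idx = bootstrap_indices(len(y), n_estimators, seed)
    member_seeds = np.random.default_rng(seed).integers(
        0, 2**31 - 1, size=n_estimators
    )
    estimators = []
    for m in range(n_estimators):
        try:
            estimators.append(
                _fit_predictor(spec, X[idx[m]], y[idx[m]], int(member_seeds[m]))
            )
        except Exception as exc:
            raise RuntimeError(f"estimator {m} failed to train: {exc}") from exc
    return BaggedModel(estimators, member_seeds.tolist(), spec, seed)


def predict_with_uncertainty(
    model: BaggedModel, X: np.ndarray, ci_level: float = 0.90
) -> list[PredictionInterval]:
    """Bagged mean plus percentile interval of the member predictions."""
    preds = model.member_predictions(np.asarray(X, dtype=float))
    lo_q = 100 * (1 - ci_level) / 2
    hi_q = 100 - lo_q
    means = preds.mean(axis=0)
    lowers = np.percentile(preds, lo_q, axis=0)
    uppers = np.percentile(preds, hi_q, axis=0)
    return [
        PredictionInterval(float(m), float(lo), float(hi))
        for m, lo, hi in zip(means, lowers, uppers)
    ]


def tune_hyperparameters(
    family: str,
    X: np.ndarray,
    y: np.ndarray,
    fold_plans: list[tuple[np.ndarray, np.ndarray]],
    grid: list[dict] | None = None,
    seed: int = 0,
) -> tuple[AlgorithmSpec, dict]:
    """Grid search by pooled left-out R^2 over grouped CV folds.

    For each grid point a single (un-bagged) estimator is fit per fold
    and scored on the left-out rows; predictions are pooled across folds
    before computing R^2/RMSE. Ties go to lower RMSE, then first-in-grid.

    Returns the winning spec and its pooled CV diagnostics
    ``{"r2_cv", "rmse_cv", "cv_predictions", "cv_row_indices"}``.
    """
    from .evaluation import r_squared, rmse  # local import to avoid a cycle

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    grid = grid if grid is not None else DEFAULT_GRIDS[family]
    if not grid:
        raise ValueError("empty hyperparameter grid")
    # fold plans may carry global row indices; map them into X's rows
    best = None
    for g, hp in enumerate(grid):
        spec = AlgorithmSpec(family, dict(hp))
        pooled_pred, pooled_true, pooled_rows = [], [], []
        try:
            for fit_rows, val_rows in fold_plans:
                est = _fit_predictor(spec, X[fit_rows], y[fit_rows], seed)
                pooled_pred.append(_predict(est, X[val_rows]))
                pooled_true.append(y[val_rows])
                pooled_rows.append(np.asarray(val_rows))
        except Exception as exc:
            warnings.warn(f"grid point {hp} failed: {exc}; skipping")
            continue
        yhat = np.concatenate(pooled_pred)
        ytrue = np.concatenate(pooled_true)
        r2 = r_squared(ytrue, yhat)
        err = rmse(ytrue, yhat)
        key = (-r2, err, g)
        if best is None or key < best[0]:
            best = (
                key,
                spec,
                {
                    "r2_cv": r2,
                    "rmse_cv": err,
                    "cv_predictions": yhat,
                    "cv_row_indices": np.concatenate(pooled_rows),
                },
            )
    if best is None:
        raise RuntimeError("every grid point failed to fit")
    return best[1], best[2]
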