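"""Metrics, model scoring, and the benchmarking protocols.

The model-selection statistic rewards accuracy with a small
generalization gap:

    Score_M = R2_test * (1 - |R2_5CV - R2_test|)

where R2_5CV is computed on the pooled left-out predictions of grouped
five-fold cross-validation on the training split (not a mean of per-fold
R2), and R2_test on a compound-disjoint held-out test set. The benchmark
repeats the whole protocol over several split seeds and ranks algorithm
families by mean Score_M.

The learning-curve experiment fixes a 20% compound-disjoint test set per
split and re-trains on nested compound-wise training subsets of
increasing size, contrasting featurizations (e.g. 2D-only vs 2D plus MD
descriptors) to locate where external physics-based features pay off.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .curation import CuratedDataset
from .features import (
    FeatureConfig,
    FeatureMatrix,
    apply_preprocessor,
    assemble_feature_matrix,
    fit_preprocessor,
)
from .models import (
    DEFAULT_GRIDS,
    AlgorithmSpec,
    fit_bagged_ensemble,
    tune_hyperparameters,
)
from .splitting import grouped_kfold, out_of_sample_split


def r_squared(y_true, y_pred) -> float:
    """Coefficient of determination, 1 - SS_res/SS_tot."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if len(y_true) < 2:
        raise ValueError("need >= 2 observations")
    ss_tot = np.sum((y_true - y_true.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("R^2 undefined for constant y_true")
    return float(1.0 - np.sum((y_true - y_pred) ** 2) / ss_tot)


def rmse(y_true, y_pred) -> float:
    """Root-mean-square error (log10-cP units throughout this package)."""
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape:
        raise ValueError("length mismatch")
    if len(y_true) == 0:
        raise ValueError("need >= 1 observation")
    return float(np.sqrt(np.mean((y_true - y_pred) ** 2)))


def model_score(r2_cv: float, r2_test: float) -> float:
    """Score_M = R2_test * (1 - |R2_cv - R2_test|); inputs may be negative."""
    return float(r2_test * (1.0 - abs(r2_cv - r2_test)))


def subset_rows(matrix: FeatureMatrix, rows) -> FeatureMatrix:
    rows = np.asarray(rows, dtype=int)
    return FeatureMatrix(
        matrix.values[rows],
        list(matrix.feature_names),
        list(matrix.block_tags),
        [matrix.row_keys[i] for i in rows],
    )


@dataclass
class BenchmarkResult:
    """Per-(algorithm, seed) metrics plus seed-aggregated leaderboard."""

    per_run: pd.DataFrame
    models: dict = field(default_factory=dict)  # (algorithm, seed) -> BaggedModel

    def aggregates(self) -> pd.DataFrame:
        agg = self.per_run.groupby("algorithm").agg(
            {
                c: ["mean", "std"]
                for c in (
                    "r2_cv",
                    "rmse_cv",
                    "r2_train",
                    "rmse_train",
                    "r2_test",
                    "rmse_test",
                    "score_m",
                )
            }
        )
        agg.columns = ["_".join(c) for c in agg.columns]
        agg = agg.sort_values("score_m_mean", ascending=False)
        agg["rank"] = np.arange(1, len(agg) + 1)
        return agg

    def leaderboard(self) -> str:
        agg = self.aggregates()
        lines = ["rank  algorithm  Score_M(mean±std)  R2_test  RMSE_test"]
        for name, row in agg.iterrows():
            std = row["score_m_std"] if np.isfinite(row["score_m_std"]) else 0.0
            lines.append(
                f"{int(row['rank']):>4}  {name:<9}  "
                f"{row['score_m_mean']:.4f}±{std:.4f}  "
                f"{row['r2_test_mean']:.4f}  {row['rmse_test_mean']:.4f}"
            )
        return "\n".join(lines)


def run_benchmark(
    dataset: CuratedDataset,
    algorithms: list[str],
    feature_config: FeatureConfig | None = None,
    external_blocks: pd.DataFrame | None = None,
    seeds=(0, 1, 2, 3, 4),
    n_estimators: int = 20,
    k: int = 5,
    grids: dict[str, list[dict]] | None = None,
    train_fraction: float = 0.8,
    correlation_cutoff: float = 0.90,
    keep_models: bool = False,
) -> BenchmarkResult:
    """Five-seed compound-disjoint benchmark of algorithm families.

    Per seed: 80:20 out-of-sample split -> preprocessing fit on train ->
    grouped 5-CV hyperparameter tuning (pooled left-out metrics) ->
    bagged refit on the full training split -> test prediction. Score_M
    and the rank ordering come from the seed-averaged metrics.
    """
    if not algorithms:
        raise ValueError("need at least one algorithm")
    feature_config = feature_config or FeatureConfig()
    matrix = assemble_feature_matrix(dataset, external_blocks, feature_config)
    y = dataset.log_viscosity
    rows = []
    models = {}
    for seed in seeds:
        plan = out_of_sample_split(dataset, train_fraction, seed)
        tr, te = plan.train_row_indices, plan.test_row_indices
        pre = fit_preprocessor(subset_rows(matrix, tr), correlation_cutoff)
        Xtr = apply_preprocessor(pre, subset_rows(matrix, tr)).values
        Xte = apply_preprocessor(pre, subset_rows(matrix, te)).values
        ytr, yte = y[tr], y[te]
        train_cids = [dataset.compound_ids[i] for i in tr]
        fold_plans = grouped_kfold(np.arange(len(tr)), train_cids, k=k, seed=seed)
        for algo in algorithms:
            grid = (grids or {}).get(algo, DEFAULT_GRIDS[algo])
            spec, cv = tune_hyperparameters(
                algo, Xtr, ytr, fold_plans, grid=grid, seed=seed
            )
            model = fit_bagged_ensemble(spec, Xtr, ytr, n_estimators, seed)
            yhat_tr = model.predict(Xtr)
            yhat_te = model.predict(Xte)
            r2_test = r_squared(yte, yhat_te)
            rows.append(
                {
                    "algorithm": algo,
                    "seed": seed,
                    "r2_cv": cv["r2_cv"],
                    "rmse_cv": cv["rmse_cv"],
                    "r2_train": r_squared(ytr, yhat_tr),
                    "rmse_train": rmse(ytr, yhat_tr),
                    "r2_test": r2_test,
                    "rmse_test": rmse(yte, yhat_te),
                    "score_m": model_score(cv["r2_cv"], r2_test),
                    "n_train": len(tr),
                    "n_test": len(te),
                }
            )
            if keep_models:
                models[(algo, seed)] = (model, pre)
    return BenchmarkResult(pd.DataFrame(rows), models)


def _nested_subsets(
    train_rows: np.ndarray,
    compound_ids: list[str],
    sizes: list[int],
    seed: int,
) -> dict[int, np.ndarray]:
    """Nested compound-wise training subsets, one per requested row count."""
    rng = np.random.default_rng(seed)
    groups: dict[str, list[int]] = {}
    for i in train_rows:
        groups.setdefault(compound_ids[i], []).append(int(i))
    compounds = list(groups)
    rng.shuffle(compounds)
    subsets: dict[int, np.ndarray] = {}
    for size in sorted(sizes):
        if size > len(train_rows):
            raise ValueError(
                f"requested train size {size} exceeds {len(train_rows)} rows"
            )
        acc: list[int] = []
        for c in compounds:
            if len(acc) >= size:
                break
            acc.extend(groups[c])
        subsets[size] = np.sort(acc)
    return subsets


def run_learning_curve(
    dataset: CuratedDataset,
    feature_configs: dict[str, dict],
    train_sizes: list[int],
    seeds=tuple(range(20)),
    spec: AlgorithmSpec | None = None,
    n_estimators: int = 20,
    correlation_cutoff: float = 0.90,
) -> pd.DataFrame:
    """Test RMSE vs training-set size for competing featurizations.

    ``feature_configs`` maps a label (e.g. "2D", "2D+MD") to
    ``{"config": FeatureConfig, "external": DataFrame-or-None}``. Per
    split seed a fixed 20% compound-disjoint test set is held out and
    nested compound-wise subsets of each size are trained with the same
    (default LGBM) bagged model. Returns a long-form table
    (config, size, seed, rmse_test) plus per-(config, size) aggregates
    available via groupby.
    """
    spec = spec or AlgorithmSpec("lgbm", DEFAULT_GRIDS["lgbm"][0])
    matrices = {
        name: assemble_feature_matrix(
            dataset, cfg.get("external"), cfg.get("config") or FeatureConfig()
        )
        for name, cfg in feature_configs.items()
    }
    y = dataset.log_viscosity
    records = []
    for seed in seeds:
        plan = out_of_sample_split(dataset, 0.8, seed)
        subsets = _nested_subsets(
            plan.train_row_indices, dataset.compound_ids, train_sizes, seed
        )
        te = plan.test_row_indices
        for name, matrix in matrices.items():
            for size, rows in subsets.items():
                pre = fit_preprocessor(subset_rows(matrix, rows), correlation_cutoff)
                Xtr = apply_preprocessor(pre, subset_rows(matrix, rows)).values
                Xte = apply_preprocessor(pre, subset_rows(matrix, te)).values
                model = fit_bagged_ensemble(spec, Xtr, y[rows], n_estimators, seed)
                records.append(
                    {
                        "config": name,
                        "size": size,
                        "actual_size": len(rows),
                        "seed": seed,
                        "rmse_test": rmse(y[te], model.predict(Xte)),
                    }
                )
    return pd.DataFrame(records)


def learning_curve_summary(curve: pd.DataFrame) -> pd.DataFrame:
    """Mean±std test RMSE per (config, size) and percent change between
    configs at each size (relative to the first config label)."""
    agg = (
        curve.groupby(["config", "size"])["rmse_test"]
        .agg(["mean", "std"])
        .reset_index()
    )
    base = agg["config"].iloc[0]
    base_means = agg[agg["config"] == base].set_index("size")["mean"]
    agg["pct_change_vs_" + base] = [
        100.0 * (m - base_means[s]) / base_means[s]
        for m, s in zip(agg["mean"], agg["size"])
    ]
    return agg
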