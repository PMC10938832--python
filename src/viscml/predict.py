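"""Model bundles and the temperature-sweep prediction workflow.

A bundle packages a fitted bagged model with its frozen preprocessing
transform, feature configuration and training metadata (seeds, library
versions, training temperature range) so that any prediction is exactly
replayable. The temperature sweep predicts log10 viscosity with a 90%
confidence band over a temperature grid for a list of structures — the
screening mode used e.g. for candidate battery-electrolyte solvents —
flagging extrapolation beyond the training temperature range and warning
when a predicted curve is not non-increasing in temperature (bulk
liquids thin with heat; a violation signals an untrustworthy region).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .curation import CuratedDataset, ViscosityRecord
from .features import (
    FeatureConfig,
    PreprocessTransform,
    apply_preprocessor,
    assemble_feature_matrix,
    fit_preprocessor,
)
from .models import (
    AlgorithmSpec,
    BaggedModel,
    fit_bagged_ensemble,
    predict_with_uncertainty,
)


@dataclass
class ModelBundle:
    """A trained bagged model plus everything needed to featurize for it."""

    model: BaggedModel
    preprocessor: PreprocessTransform
    feature_config: FeatureConfig
    train_T_range: tuple[float, float]
    uses_external: bool
    external_columns: list[str]

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        import lightgbm
        import sklearn
        import xgboost

        manifest = {
            "algorithm": {
                "family": self.model.algorithm.family,
                "hyperparameters": self.model.algorithm.hyperparameters,
            },
            "master_seed": self.model.master_seed,
            "bootstrap_seeds": self.model.bootstrap_seeds,
            "n_estimators": self.model.n_estimators,
            "feature_config": vars(self.feature_config),
            "train_T_range": list(self.train_T_range),
            "uses_external": self.uses_external,
            "external_columns": self.external_columns,
            "versions": {
                "sklearn": sklearn.__version__,
                "lightgbm": lightgbm.__version__,
                "xgboost": xgboost.__version__,
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
        (directory / "preprocessor.json").write_text(
            json.dumps(self.preprocessor.to_dict())
        )
        joblib.dump(self.model.estimators, directory / "estimators.joblib")

    @classmethod
    def load(cls, directory) -> "ModelBundle":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        pre = PreprocessTransform.from_dict(
            json.loads((directory / "preprocessor.json").read_text())
        )
        estimators = joblib.load(directory / "estimators.joblib")
        spec = AlgorithmSpec(
            manifest["algorithm"]["family"],
            dict(manifest["algorithm"]["hyperparameters"]),
        )
        model = BaggedModel(
            estimators, manifest["bootstrap_seeds"], spec, manifest["master_seed"]
        )
        return cls(
            model=model,
            preprocessor=pre,
            feature_config=FeatureConfig(**manifest["feature_config"]),
            train_T_range=tuple(manifest["train_T_range"]),
            uses_external=manifest["uses_external"],
            external_columns=list(manifest["external_columns"]),
        )


def fit_bundle(
    dataset: CuratedDataset,
    family: str = "lgbm",
    hyperparameters: dict | None = None,
    feature_config: FeatureConfig | None = None,
    external_blocks: pd.DataFrame | None = None,
    n_estimators: int = 20,
    seed: int = 0,
    correlation_cutoff: float = 0.90,
) -> ModelBundle:
    """Train a bagged model on a whole curated dataset and bundle it."""
    from .models import DEFAULT_GRIDS

    feature_config = feature_config or FeatureConfig()
    matrix = assemble_feature_matrix(dataset, external_blocks, feature_config)
    pre = fit_preprocessor(matrix, correlation_cutoff)
    X = apply_preprocessor(pre, matrix).values
    spec = AlgorithmSpec(
        family, dict(hyperparameters or DEFAULT_GRIDS[family][0])
    )
    model = fit_bagged_ensemble(spec, X, dataset.log_viscosity, n_estimators, seed)
    temps = dataset.temperatures
    return ModelBundle(
        model=model,
        preprocessor=pre,
        feature_config=feature_config,
        train_T_range=(float(temps.min()), float(temps.max())),
        uses_external=external_blocks is not None,
        external_columns=(
            [str(c) for c in external_blocks.columns]
            if external_blocks is not None
            else []
        ),
    )


def predict_temperature_sweep(
    bundle: ModelBundle,
    structures: list[str],
    T_grid: list[float],
    external: pd.DataFrame | None = None,
    ci_level: float = 0.90,
) -> pd.DataFrame:
    """Predicted viscosity curves with confidence bands.

    Returns one row per (structure, T): mean/lower/upper log10 viscosity,
    the cP-scale mean, an ``extrapolated`` flag for temperatures outside
    the bundle's training range, and a per-structure
    ``monotonic_violation`` flag raised when predicted log viscosity ever
    increases with temperature (also emitted as a warning).
    """
    if bundle.uses_external and external is None:
        raise ValueError(
            "model was trained with external descriptor columns; supply them"
        )
    from .curation import canonical_smiles

    records, cids = [], []
    for smi in structures:
        canon = canonical_smiles(smi)
        if canon is None:
            raise ValueError(f"unparseable SMILES: {smi!r}")
        for T in T_grid:
            records.append(ViscosityRecord(canon, float(T), 1.0, "sweep"))
            cids.append(canon)
    sweep_ds = CuratedDataset(records, np.zeros(len(records)), cids)
    matrix = assemble_feature_matrix(sweep_ds, external, bundle.feature_config)
    X = apply_preprocessor(bundle.preprocessor, matrix).values
    intervals = predict_with_uncertainty(bundle.model, X, ci_level)

    t_lo, t_hi = bundle.train_T_range
    rows = []
    for (cid, rec), iv in zip(zip(cids, records), intervals):
        rows.append(
            {
                "structure": cid,
                "temperature_K": rec.temperature,
                "log10_viscosity_pred": iv.mean,
                "log10_viscosity_lower": iv.lower,
                "log10_viscosity_upper": iv.upper,
                "viscosity_cP_pred": 10.0**iv.mean,
                "extrapolated": not (t_lo <= rec.temperature <= t_hi),
            }
        )
    out = pd.DataFrame(rows)
    flags = {}
    for cid, grp in out.groupby("structure"):
        curve = grp.sort_values("temperature_K")["log10_viscosity_pred"].to_numpy()
        violated = bool(np.any(np.diff(curve) > 1e-12))
        flags[cid] = violated
        if violated:
            warnings.warn(
                f"predicted log-viscosity of {cid} is not non-increasing in T"
            )
    out["monotonic_violation"] = out["structure"].map(flags)
    return out
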