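"""Physics-informed feature construction for viscosity QSPR.

Each molecule is described by three structural blocks — a 2D
physicochemical/topological descriptor block (RDKit), a hashed circular
(Morgan) fingerprint block, and an element-composition statistics block —
plus inverse temperature as an external column (the Vogel law makes
log10(viscosity) roughly linear in 1/T). Optional external blocks, such as
MD-trajectory descriptors, are joined by (compound, temperature).

Preprocessing follows a fixed recipe fit on training rows only: drop
features with |Pearson r| >= 0.90 to an earlier kept feature (greedy,
keep-first in column order), drop zero-variance features, then standardize
to zero mean and unit variance. The fitted transform is frozen: applying
it never refits, which is what keeps test folds leakage-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Descriptors, rdFingerprintGenerator

from ._elements import ELEMENT_PROPERTIES, PROPERTY_NAMES
from .curation import CuratedDataset

_COMP_STATS = ("mean", "min", "max", "range", "std")
# atomic_number/period/group duplicate mass & radius trends; keep the
# physically distinct subset for composition statistics
_COMP_PROPERTIES = (
    "atomic_mass",
    "electronegativity",
    "covalent_radius",
    "vdw_radius",
    "ionization_energy",
    "electron_affinity",
    "valence_electrons",
)


@dataclass
class FeatureConfig:
    """Featurization knobs.

    fingerprint_radius/bits control the circular fingerprint; the three
    ``use_*`` switches enable blocks; ``impute`` is ``"fail"`` (default:
    any missing descriptor aborts assembly) or ``"median"``.
    """

    fingerprint_radius: int = 2
    fingerprint_bits: int = 1000
    use_2d: bool = True
    use_fp: bool = True
    use_comp: bool = True
    correlation_cutoff: float = 0.90
    impute: str = "fail"


@dataclass
class FeatureMatrix:
    """n x p numeric matrix with named, block-tagged columns.

    ``block_tags`` entries come from {"2D", "FP", "COMP", "EXT", "MD"};
    ``row_keys`` are (compound_id, temperature) pairs aligned with rows.
    """

    values: np.ndarray
    feature_names: list[str]
    block_tags: list[str]
    row_keys: list[tuple[str, float]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if len(self.feature_names) != p or len(self.block_tags) != p:
            raise ValueError("feature_names/block_tags must match column count")
        if len(self.row_keys) != n:
            raise ValueError("row_keys must match row count")
        if len(set(self.feature_names)) != p:
            raise ValueError("feature names must be unique")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.feature_names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names)


def inverse_temperature(T: float | np.ndarray) -> float | np.ndarray:
    """Reciprocal absolute temperature, the Vogel-motivated input feature."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    out = 1.0 / T
    return float(out) if out.ndim == 0 else out


def _composition_features(mol) -> tuple[list[float], list[str]]:
    molh = Chem.AddHs(mol)
    symbols = [a.GetSymbol() for a in molh.GetAtoms()]
    values: list[float] = []
    names: list[str] = []
    for prop in _COMP_PROPERTIES:
        idx = PROPERTY_NAMES.index(prop)
        vals = np.array([ELEMENT_PROPERTIES[s][idx] for s in symbols], dtype=float)
        stats = {
            "mean": vals.mean(),
            "min": vals.min(),
            "max": vals.max(),
            "range": vals.max() - vals.min(),
            "std": vals.std(),
        }
        for stat in _COMP_STATS:
            values.append(float(stats[stat]))
            names.append(f"COMP_{prop}_{stat}")
    n = len(symbols)
    for el in sorted(ELEMENT_PROPERTIES):
        values.append(symbols.count(el) / n)
        names.append(f"COMP_frac_{el}")
    values.append(float(n))
    names.append("COMP_n_atoms")
    values.append(float(mol.GetNumHeavyAtoms()))
    names.append("COMP_n_heavy")
    return values, names


def compute_structure_features(
    structure: str, config: FeatureConfig | None = None
) -> tuple[np.ndarray, list[str], list[str]]:
    """Structural feature vector for one SMILES.

    Returns (values, names, block_tags). Deterministic per structure;
    individual 2D descriptors that fail to evaluate become NaN and are
    resolved by the assembly-time ``impute`` policy.
    """
    config = config or FeatureConfig()
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {structure!r}")
    if len(Chem.GetMolFrags(mol)) > 1:
        raise ValueError(f"multi-fragment structure not supported: {structure!r}")

    values: list[float] = []
    names: list[str] = []
    tags: list[str] = []
    if config.use_2d:
        for name, fn in Descriptors.descList:
            try:
                v = float(fn(mol))
                if not np.isfinite(v):
                    v = float("nan")
            except Exception:
                v = float("nan")
            values.append(v)
            names.append(f"RD_{name}")
            tags.append("2D")
    if config.use_fp:
        gen = rdFingerprintGenerator.GetMorganGenerator(
            radius=config.fingerprint_radius, fpSize=config.fingerprint_bits
        )
        bits = gen.GetFingerprint(mol)
        arr = np.zeros(config.fingerprint_bits)
        for b in bits.GetOnBits():
            arr[b] = 1.0
        values.extend(arr.tolist())
        names.extend(f"FP_{i:04d}" for i in range(config.fingerprint_bits))
        tags.extend(["FP"] * config.fingerprint_bits)
    if config.use_comp:
        cvals, cnames = _composition_features(mol)
        values.extend(cvals)
        names.extend(cnames)
        tags.extend(["COMP"] * len(cvals))
    return np.array(values), names, tags


def assemble_feature_matrix(
    dataset: CuratedDataset,
    external_blocks: pd.DataFrame | None = None,
    config: FeatureConfig | None = None,
    external_tag: str = "MD",
) -> FeatureMatrix:
    """One feature row per curated record.

    Structural blocks are computed once per unique compound and broadcast
    to all its rows; inverse temperature is always appended as an EXT
    column. ``external_blocks``, if given, is a DataFrame indexed by
    (compound_id, temperature) whose columns are joined per row (strict:
    a missing key is an error).
    """
    config = config or FeatureConfig()
    cache: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
    rows: list[np.ndarray] = []
    names: list[str] | None = None
    tags: list[str] | None = None
    row_keys: list[tuple[str, float]] = []
    for rec, cid in zip(dataset.records, dataset.compound_ids):
        if cid not in cache:
            cache[cid] = compute_structure_features(cid, config)
        svals, snames, stags = cache[cid]
        row = np.append(svals, inverse_temperature(rec.temperature))
        if external_blocks is not None:
            key = (cid, rec.temperature)
            try:
                ext = external_blocks.loc[key]
            except KeyError:
                raise KeyError(
                    f"external block missing row for {key} (strict policy)"
                )
            row = np.append(row, np.asarray(ext, dtype=float))
        rows.append(row)
        row_keys.append((cid, rec.temperature))
        if names is None:
            names = list(snames) + ["Inv_Temp"]
            tags = list(stags) + ["EXT"]
            if external_blocks is not None:
                names += [str(c) for c in external_blocks.columns]
                tags += [external_tag] * external_blocks.shape[1]
    if not rows:
        raise ValueError("empty dataset")
    X = np.vstack(rows)

    if np.isnan(X).any():
        bad = [names[j] for j in np.where(np.isnan(X).any(axis=0))[0]]
        if config.impute == "median":
            med = np.nanmedian(X, axis=0)
            idx = np.where(np.isnan(X))
            X[idx] = np.take(med, idx[1])
        else:
            raise ValueError(
                f"missing values in features {bad[:5]}... "
                "(set config.impute='median' to fill)"
            )
    return FeatureMatrix(X, names, tags, row_keys)


@dataclass
class PreprocessTransform:
    """Frozen train-fitted preprocessing: column selection + standardization."""

    kept_feature_names: list[str]
    means: np.ndarray
    stds: np.ndarray
    correlation_cutoff: float
    dropped_correlated: list[str] = field(default_factory=list)
    dropped_constant: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.stds = np.asarray(self.stds, dtype=float)
        if np.any(self.stds <= 0):
            raise ValueError("kept-feature stds must be positive")

    def to_dict(self) -> dict:
        return {
            "kept_feature_names": self.kept_feature_names,
            "means": self.means.tolist(),
            "stds": self.stds.tolist(),
            "correlation_cutoff": self.correlation_cutoff,
            "dropped_correlated": self.dropped_correlated,
            "dropped_constant": self.dropped_constant,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PreprocessTransform":
        return cls(
            kept_feature_names=list(d["kept_feature_names"]),
            means=np.array(d["means"]),
            stds=np.array(d["stds"]),
            correlation_cutoff=float(d["correlation_cutoff"]),
            dropped_correlated=list(d.get("dropped_correlated", [])),
            dropped_constant=list(d.get("dropped_constant", [])),
        )


def fit_preprocessor(
    train: FeatureMatrix, correlation_cutoff: float = 0.90
) -> PreprocessTransform:
    """Fit the correlation/variance/standardization transform on training rows.

    Correlation removal is a greedy keep-first scan in column order: a
    feature is dropped when its |Pearson r| with any earlier *kept*
    feature reaches the cutoff. Constant features (undefined r) survive
    the scan and are removed by the zero-variance rule.
    """
    X = train.values
    n, p = X.shape
    if n < 2:
        raise ValueError("need >= 2 training rows to fit the preprocessor")
    std = X.std(axis=0)
    # roundoff can leave a constant column with std ~ 1e-16; treat
    # variance below float precision of the column scale as zero
    tiny = 1e-12 * np.maximum(1.0, np.abs(X).max(axis=0))
    std = np.where(std <= tiny, 0.0, std)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X, rowvar=False)
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)

    kept: list[int] = []
    dropped_corr: list[str] = []
    for j in range(p):
        if kept and np.any(np.abs(corr[j, kept]) >= correlation_cutoff):
            dropped_corr.append(train.feature_names[j])
        else:
            kept.append(j)
    dropped_const = [train.feature_names[j] for j in kept if std[j] == 0]
    kept = [j for j in kept if std[j] > 0]
    if not kept:
        raise ValueError("all features dropped by preprocessing")
    return PreprocessTransform(
        kept_feature_names=[train.feature_names[j] for j in kept],
        means=X[:, kept].mean(axis=0),
        stds=std[kept],
        correlation_cutoff=correlation_cutoff,
        dropped_correlated=dropped_corr,
        dropped_constant=dropped_const,
    )


def apply_preprocessor(
    transform: PreprocessTransform, matrix: FeatureMatrix
) -> FeatureMatrix:
    """Subset to kept features and standardize with frozen training stats.

    Never refits; not idempotent (a second application rescales by the
    training statistics again).
    """
    name_to_idx = {n: i for i, n in enumerate(matrix.feature_names)}
    try:
        idx = [name_to_idx[n] for n in transform.kept_feature_names]
    except KeyError as exc:
        raise KeyError(f"matrix lacks kept feature {exc}")
    Z = (matrix.values[:, idx] - transform.means) / transform.stds
    return FeatureMatrix(
        Z,
        list(transform.kept_feature_names),
        [matrix.block_tags[i] for i in idx],
        list(matrix.row_keys),
    )
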