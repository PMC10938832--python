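"""Synthetic viscosity data with the statistical structure the pipeline assumes.

Each synthetic compound follows a Vogel curve in log10 form,

    log10 mu(T) = A + B / (T - C),

with parameters tied to simple structure summaries (heavy-atom count,
hydrogen-bond donors) so that 2D descriptors carry genuine signal:
bigger and more hydrogen-bonding molecules are more viscous. Temperatures
are drawn right-skewed inside 227-404 K and viscosities clip to
0.10-26.52 cP, mirroring the value ranges of curated experimental data;
log-scale Gaussian noise (default sd 0.02) models measurement scatter.

The generator can also inject labeled curation violations (disallowed
elements, gross range outliers, positive viscosity-temperature
deviations), emit surrogate "MD-like" external descriptor columns with a
controllable informativeness, and produce toy trajectories whose
descriptor values are analytically known.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Lipinski

from .curation import CuratedDataset, ViscosityRecord, canonical_smiles
from .md import SystemTopology, Trajectory, TrajectoryFrame

# six battery-electrolyte solvents used for temperature-sweep demos
BATTERY_SOLVENTS = {
    "MA": "CC(=O)OC",  # methyl acetate
    "EA": "CC(=O)OCC",  # ethyl acetate
    "MB": "CCCC(=O)OC",  # methyl butyrate
    "MP": "CCC(=O)OC",  # methyl propionate
    "DMC": "COC(=O)OC",  # dimethyl carbonate
    "EMC": "CCOC(=O)OC",  # ethyl methyl carbonate
}

_ALKYL = (
    "C",
    "CC",
    "CCC",
    "CCCC",
    "CCCCC",
    "CCCCCC",
    "CCCCCCC",
    "CCCCCCCC",
    "CC(C)C",
    "CC(C)CC",
    "CCC(C)C",
    "CC(C)(C)C",
    "CCCC(C)C",
    "CC(C)CCC",
)


@dataclass(frozen=True)
class VogelParams:
    """log10 mu(T) = A + B/(T - C); A in log10 cP, B and C in kelvin."""

    A: float
    B: float
    C: float

    def __post_init__(self) -> None:
        if self.B < 0:
            raise ValueError("B must be non-negative")

    def log10_viscosity(self, T: float | np.ndarray) -> float | np.ndarray:
        return self.A + self.B / (np.asarray(T, dtype=float) - self.C)


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults are the package's study conditions."""

    n_compounds: int = 200
    temperatures_per_compound: int = 5
    noise_sd: float = 0.02  # log10-cP
    n_element_outliers: int = 0
    n_range_outliers: int = 0
    n_deviation_outliers: int = 0
    viscosity_range_cP: tuple[float, float] = (0.10, 26.52)
    temperature_range_K: tuple[float, float] = (227.0, 404.0)
    seed: int = 0
    # fixture overrides: explicit compounds, frozen Vogel parameters and an
    # evenly spaced temperature window instead of skewed random sampling
    compounds: list[str] | None = None
    fixed_params: dict[str, "VogelParams"] | None = None
    temperature_grid_K: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if (
            min(
                self.n_compounds,
                self.temperatures_per_compound,
                self.n_element_outliers,
                self.n_range_outliers,
                self.n_deviation_outliers,
            )
            < 0
        ):
            raise ValueError("counts must be non-negative")
        if (
            self.viscosity_range_cP[0] >= self.viscosity_range_cP[1]
            or self.temperature_range_K[0] >= self.temperature_range_K[1]
        ):
            raise ValueError("ranges must be ordered")

    @classmethod
    def curation_fixture(cls, seed: int = 0) -> "SyntheticConfig":
        """Noise-free fixture with labeled violations for filter tests.

        2 compounds x 5 clean rows plus 2 element / 1 range / 1 deviation
        injections. Vogel parameters are frozen and temperatures evenly
        spaced so that, for every seed, each injected row trips exactly
        its own filter and no clean row sits near an IQR fence.
        """
        ma, ea = BATTERY_SOLVENTS["MA"], BATTERY_SOLVENTS["EA"]
        return cls(
            n_compounds=2,
            temperatures_per_compound=5,
            noise_sd=0.0,
            n_element_outliers=2,
            n_range_outliers=1,
            n_deviation_outliers=1,
            seed=seed,
            compounds=[ma, ea],
            fixed_params={
                ma: VogelParams(-1.30, 355.0, 100.0),
                ea: VogelParams(-1.28, 365.0, 105.0),
            },
            temperature_grid_K=(280.0, 302.0),
        )


def generate_compound_library(
    n: int, seed: int = 0, preset: str | None = None
) -> list[str]:
    """n distinct single-fragment organic SMILES from a fragment grammar.

    Chemotypes: esters, carbonates, ethers, alcohols and alkanes built
    from linear/branched alkyl groups. ``preset="battery"`` returns the
    six battery-electrolyte solvents (n must be 6).
    """
    if preset == "battery":
        if n != 6:
            raise ValueError("battery preset has exactly 6 compounds")
        return list(BATTERY_SOLVENTS.values())
    if n < 1:
        raise ValueError("n must be >= 1")
    candidates: list[str] = []
    for r1 in _ALKYL:
        for r2 in _ALKYL:
            candidates.append(f"{r1}C(=O)O{r2}")  # esters
            candidates.append(f"{r1}OC(=O)O{r2}")  # carbonates
            candidates.append(f"{r1}O{r2}")  # ethers
    candidates += [f"{r}O" for r in _ALKYL]  # alcohols
    candidates += list(_ALKYL)  # alkanes
    seen: set[str] = set()
    library: list[str] = []
    for smi in candidates:
        canon = canonical_smiles(smi)
        if canon is not None and canon not in seen:
            seen.add(canon)
            library.append(canon)
    if n > len(library):
        raise ValueError(
            f"grammar capacity is {len(library)} compounds; requested {n}"
        )
    rng = np.random.default_rng(seed)
    rng.shuffle(library)
    return library[:n]


def assign_vogel_parameters(smiles: str, seed: int = 0) -> VogelParams:
    """Structure-linked Vogel parameters, deterministic per (smiles, seed).

    Both B and the divergence temperature C shift upward with molecular
    size through a smooth crossover centred near 12 heavy atoms —
    emulating the regime change from small-molecule flow to the more
    cooperative dynamics of larger liquids — and B grows with
    hydrogen-bond donor count. The structure-independent jitters (A sd
    0.05, B sd 10 K, C sd 6 K) model compound-level idiosyncrasy while
    staying small relative to the structural signal, so descriptors can
    in principle explain most of the variance.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"unparseable SMILES: {smiles!r}")
    canon = Chem.MolToSmiles(mol)
    sub = zlib.crc32(canon.encode())
    rng = np.random.default_rng([seed, sub])
    heavy = mol.GetNumHeavyAtoms()
    donors = Lipinski.NumHDonors(mol)
    size_crossover = 1.0 / (1.0 + np.exp(-1.5 * (heavy - 12)))
    A = rng.normal(-1.4, 0.05)
    B = max(
        0.0,
        130.0
        + 6.0 * (heavy - 3)
        + 80.0 * donors
        + 90.0 * size_crossover
        + rng.normal(0, 10.0),
    )
    C = float(np.clip(rng.normal(75.0 + 45.0 * size_crossover, 6.0), 50.0, 160.0))
    return VogelParams(float(A), float(B), C)


_ELEMENT_VIOLATIONS = (
    "[Na+].[Cl-]",  # two fragments, disallowed metal
    "O",  # no carbon
    "CC[Sn](CC)CC",  # disallowed metal
    "CCB(O)O",  # boron
    "C[Se]C",  # selenium
    "[K+].[I-]",  # two fragments
)


def generate_dataset(
    config: SyntheticConfig,
) -> tuple[list[ViscosityRecord], pd.DataFrame]:
    """Synthetic viscosity records plus a ground-truth table.

    Clean rows follow per-compound Vogel curves with log-scale noise and
    clipping to the configured cP range; requested numbers of
    element-violating, range-outlier and positive-deviation rows are
    appended with labels. The ground truth carries the generating
    parameters, noiseless log-viscosities, clipping flags and the
    injection label of every record, aligned with the returned list.
    """
    rng = np.random.default_rng(config.seed)
    t_lo, t_hi = config.temperature_range_K
    v_lo, v_hi = config.viscosity_range_cP
    if config.compounds is not None:
        library = [canonical_smiles(s) for s in config.compounds]
        if len(library) != config.n_compounds:
            raise ValueError("compounds list must match n_compounds")
    else:
        library = generate_compound_library(config.n_compounds, config.seed)
    fixed = {
        canonical_smiles(k): v for k, v in (config.fixed_params or {}).items()
    }

    records: list[ViscosityRecord] = []
    truth_rows: list[dict] = []

    def _emit(smiles, cid, T, visc, label, params=None, clean_log=np.nan, clipped=False):
        records.append(ViscosityRecord(smiles, float(T), float(visc), "synthetic"))
        truth_rows.append(
            {
                "structure": smiles,
                "compound_id": cid,
                "temperature_K": float(T),
                "viscosity_cP": float(visc),
                "log10_viscosity_clean": clean_log,
                "A": params.A if params else np.nan,
                "B": params.B if params else np.nan,
                "C": params.C if params else np.nan,
                "clipped": clipped,
                "label": label,
            }
        )

    per_compound: dict[str, list[tuple[float, float]]] = {}
    for smi in library:
        params = fixed.get(smi) or assign_vogel_parameters(smi, config.seed)
        if config.temperature_grid_K is not None:
            g_lo, g_hi = config.temperature_grid_K
            temps = np.linspace(g_lo, g_hi, config.temperatures_per_compound)
        else:
            temps = np.sort(
                t_lo
                + (t_hi - t_lo)
                * rng.beta(2.0, 4.0, config.temperatures_per_compound)
            )
        kept: list[tuple[float, float]] = []
        for T in temps:
            clean_log = float(params.log10_viscosity(T))
            noisy = clean_log + rng.normal(0.0, config.noise_sd)
            visc = float(np.clip(10.0**noisy, v_lo, v_hi))
            clipped = not (v_lo < 10.0**noisy < v_hi)
            _emit(smi, smi, T, visc, "clean", params, clean_log, clipped)
            kept.append((float(T), visc))
        per_compound[smi] = kept

    # --- injected violations -------------------------------------------
    # injections sit at typical clean values in the untargeted variable so
    # each row trips exactly its own filter
    clean_T = np.array([t for curve in per_compound.values() for t, _ in curve])
    clean_V = np.array([v for curve in per_compound.values() for _, v in curve])
    inj_T = float(np.median(clean_T))
    typical_V = float(np.median(clean_V))
    for j in range(config.n_element_outliers):
        smi = _ELEMENT_VIOLATIONS[j % len(_ELEMENT_VIOLATIONS)]
        _emit(smi, smi, inj_T + 0.1 * (j + 1), typical_V, "element_outlier")
    hosts = [c for c in library if len(per_compound[c]) >= 2] or library
    for j in range(config.n_range_outliers):
        host = hosts[(j + 1) % len(hosts)]
        _emit(
            host, host, inj_T - 0.1 * (j + 1), rng.uniform(300.0, 1500.0),
            "range_outlier",
        )
    for j in range(config.n_deviation_outliers):
        host = hosts[j % len(hosts)]
        curve = per_compound[host]
        (t1, v1), (t2, _) = curve[0], curve[1]
        t_new = 0.5 * (t1 + t2)
        bump = rng.uniform(0.05, 0.5)
        _emit(host, host, t_new, v1 + bump, "deviation_outlier")

    return records, pd.DataFrame(truth_rows)


def records_to_csv(records: list[ViscosityRecord], path) -> None:
    """Write records in the CSV dialect the curation reader expects."""
    pd.DataFrame(
        {
            "structure": [r.structure for r in records],
            "temperature_K": [r.temperature for r in records],
            "viscosity_cP": [r.viscosity for r in records],
            "source": [r.source for r in records],
        }
    ).to_csv(path, index=False)


# monotone signal transforms per surrogate column; MD_FV and MD_RMSD are
# negatively related to log-viscosity (more free volume / mobility in
# thinner liquids)
_SURROGATE_TRANSFORMS = {
    "MD_density": lambda s: s + 0.1 * s**2,
    "MD_FV": lambda s: -s,
    "MD_Rg": lambda s: s**3 + s,
    "MD_SP": lambda s: np.exp(s / 2.0),
    "MD_SP_E": lambda s: 0.8 * s,
    "MD_SP_V": lambda s: s + 0.5 * np.abs(s),
    "MD_HV": lambda s: s,
    "MD_RMSD": lambda s: -np.exp(s / 3.0),
}


def generate_surrogate_external_descriptors(
    dataset: CuratedDataset,
    ground_truth: pd.DataFrame,
    informativeness: float = 0.9,
    seed: int = 0,
) -> pd.DataFrame:
    """Eight surrogate MD-like descriptor columns keyed by (compound, T).

    Each column blends a monotone function of the row's noiseless
    log-viscosity with seeded Gaussian noise:
    ``alpha * z(g(signal)) + (1 - alpha) * eps``, standardized. At
    informativeness 0 the columns are pure noise; at 1 they are noiseless
    monotone transforms of the target.
    """
    if not 0.0 <= informativeness <= 1.0:
        raise ValueError("informativeness must lie in [0, 1]")
    truth = ground_truth.set_index(["compound_id", "temperature_K"])[
        "log10_viscosity_clean"
    ]
    signal = np.array(
        [
            truth.loc[(cid, rec.temperature)]
            for cid, rec in zip(dataset.compound_ids, dataset.records)
        ]
    )
    rng = np.random.default_rng(seed)
    cols = {}
    for name, g in _SURROGATE_TRANSFORMS.items():
        raw = g(signal)
        z = (raw - raw.mean()) / raw.std() if raw.std() > 0 else raw * 0.0
        mixed = informativeness * z + (1.0 - informativeness) * rng.normal(
            size=len(z)
        )
        std = mixed.std()
        cols[name] = (mixed - mixed.mean()) / std if std > 0 else mixed
    index = pd.MultiIndex.from_tuples(
        [(cid, rec.temperature) for cid, rec in zip(dataset.compound_ids, dataset.records)],
        names=["compound_id", "temperature_K"],
    )
    return pd.DataFrame(cols, index=index)


def generate_toy_trajectory(
    case: str, **params
) -> tuple[Trajectory, SystemTopology, dict]:
    """Analytic trajectory fixtures with expected descriptor metadata.

    Cases: ``single-sphere`` (radius r, box L), ``dimer`` (separation d),
    ``square`` (side a), ``lattice`` (m per axis, radius r, box L),
    ``translate`` (delta Å/frame, n_frames), ``constant-energy``
    (e_inter/e_elec/e_vdw, box L, n_molecules).
    """
    L = float(params.get("box", 10.0))
    box = np.array([L, L, L])

    def topo(n_atoms, mass=12.011, radius=1.7, membership=None, n_mol=None):
        membership = (
            np.asarray(membership)
            if membership is not None
            else np.zeros(n_atoms, dtype=int)
        )
        return SystemTopology(
            np.full(n_atoms, mass),
            np.full(n_atoms, radius),
            membership,
            n_mol if n_mol is not None else int(membership.max()) + 1,
        )

    if case == "single-sphere":
        r = float(params.get("radius", 1.7))
        coords = np.array([[L / 2, L / 2, L / 2]])
        frames = [
            TrajectoryFrame(coords, box, 100.0 * k) for k in range(4)
        ]
        expected = {
            "MD_FV": 100.0 * (1.0 - 4.0 / 3.0 * np.pi * r**3 / L**3),
            "MD_Rg": 0.0,
        }
        return Trajectory(frames, ["C"]), topo(1, radius=r), expected

    if case == "dimer":
        d = float(params.get("d", 2.0))
        coords = np.array(
            [[L / 2 - d / 2, L / 2, L / 2], [L / 2 + d / 2, L / 2, L / 2]]
        )
        frames = [
            TrajectoryFrame(coords, box, 100.0 * k) for k in range(4)
        ]
        return Trajectory(frames, ["C", "C"]), topo(2), {"MD_Rg": d / 2.0}

    if case == "square":
        a = float(params.get("a", 2.0))
        c = L / 2
        coords = np.array(
            [
                [c - a / 2, c - a / 2, c],
                [c + a / 2, c - a / 2, c],
                [c + a / 2, c + a / 2, c],
                [c - a / 2, c + a / 2, c],
            ]
        )
        frames = [
            TrajectoryFrame(coords, box, 100.0 * k) for k in range(4)
        ]
        return Trajectory(frames, ["C"] * 4), topo(4), {"MD_Rg": a / np.sqrt(2.0)}

    if case == "lattice":
        m = int(params.get("m", 3))
        r = float(params.get("radius", 1.0))
        spacing = L / m
        if r > spacing / 2:
            raise ValueError("spheres would overlap; shrink radius")
        pts = [(spacing * (i + 0.5), spacing * (j + 0.5), spacing * (k + 0.5))
               for i in range(m) for j in range(m) for k in range(m)]
        coords = np.array(pts)
        frames = [
            TrajectoryFrame(coords, box, 100.0 * k) for k in range(4)
        ]
        n = m**3
        expected = {"MD_FV": 100.0 * (1.0 - n * 4.0 / 3.0 * np.pi * r**3 / L**3)}
        return (
            Trajectory(frames, ["C"] * n),
            topo(n, radius=r, membership=np.arange(n)),
            expected,
        )

    if case == "translate":
        delta = np.asarray(params.get("delta", (1.0, 0.0, 0.0)), dtype=float)
        n_frames = int(params.get("n_frames", 3))
        base = np.array([[2.0, 2.0, 2.0], [4.0, 4.0, 4.0]])
        frames = [
            TrajectoryFrame(base + k * delta, box, 100.0 * k)
            for k in range(n_frames)
        ]
        expected = {
            "rmsd_per_frame": [
                float(k * np.linalg.norm(delta)) for k in range(n_frames)
            ]
        }
        return Trajectory(frames, ["C", "C"]), topo(2, membership=[0, 1], n_mol=2), expected

    if case == "constant-energy":
        e_inter = float(params.get("e_inter", -1000.0))
        n_mol = int(params.get("n_molecules", 10))
        coords = np.array([[L / 2, L / 2, L / 2]] * n_mol)
        energies = {
            "e_inter": e_inter,
            "e_elec": float(params.get("e_elec", 0.4 * e_inter)),
            "e_vdw": float(params.get("e_vdw", 0.6 * e_inter)),
        }
        frames = [
            TrajectoryFrame(coords, box, 100.0 * k, dict(energies))
            for k in range(4)
        ]
        from .md import KCAL_PER_MOL_A3_TO_MPA

        ced = -e_inter / L**3 * KCAL_PER_MOL_A3_TO_MPA
        expected = {"CED": ced, "MD_SP": float(np.sqrt(max(ced, 0.0)))}
        return (
            Trajectory(frames, ["C"] * n_mol),
            topo(n_mol, membership=np.arange(n_mol)),
            expected,
        )

    raise ValueError(f"unknown toy-trajectory case {case!r}")
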