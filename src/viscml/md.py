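"""Trajectory-derived descriptors for viscosity modeling.

Eight descriptors are extracted from equilibrium MD trajectories of a
liquid cell, one set per (compound, temperature): packing density
(g/cm^3), percentage free volume, mean molecular radius of gyration (Å),
Hansen-type solubility parameter and its electrostatic / van-der-Waals
components (MPa^1/2), heat of vaporization (kcal/mol), and root-mean-
square displacement (Å). Ensemble averaging uses the trailing portion of
the production run (default: the last half), where the system is assumed
equilibrated.

Trajectories are read from an extended-XYZ dialect whose comment line
carries ``key=value`` metadata: ``box="lx ly lz"`` (Å, orthorhombic),
``time`` (ps) and optional per-frame energies ``e_total``, ``e_inter``,
``e_elec``, ``e_vdw`` (kcal/mol of simulation cell). Topology (masses,
vdW radii, molecule membership) comes from a JSON sidecar; masses and
radii default to the bundled element table when omitted.

Internal units are Å / ps / u / kcal·mol⁻¹; conversions to g/cm^3 and
MPa happen only at the reporting boundary.
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from ._elements import atomic_mass, vdw_radius

U_TO_G = 1.66053906660e-24
A3_TO_CM3 = 1e-24
#: 1 kcal/mol per Å^3 expressed in MPa
KCAL_PER_MOL_A3_TO_MPA = 4184.0 / 6.02214076e23 / 1e-30 / 1e6
#: gas constant in kcal/(mol K)
R_KCAL_MOL_K = 1.98720425864083e-3

ENERGY_KEYS = ("e_total", "e_inter", "e_elec", "e_vdw")


@dataclass
class TrajectoryFrame:
    """One saved frame: coordinates, box, time, optional energy split."""

    coordinates: np.ndarray  # (N, 3) Å
    box_lengths: np.ndarray  # (3,) Å, orthorhombic
    time: float  # ps
    energies: dict | None = None  # kcal/mol per simulation cell

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.box_lengths = np.asarray(self.box_lengths, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must be (N, 3)")
        if np.any(self.box_lengths <= 0):
            raise ValueError("box lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return len(self.coordinates)

    @property
    def volume(self) -> float:
        return float(np.prod(self.box_lengths))


@dataclass
class Trajectory:
    frames: list[TrajectoryFrame]
    elements: list[str] | None = None

    def __post_init__(self) -> None:
        if not self.frames:
            raise ValueError("empty trajectory")
        n = self.frames[0].n_atoms
        if any(f.n_atoms != n for f in self.frames):
            raise ValueError("atom count varies across frames")
        times = [f.time for f in self.frames]
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frames)


@dataclass
class SystemTopology:
    """Per-atom constants the descriptor formulas need."""

    atom_masses: np.ndarray  # u
    vdw_radii: np.ndarray  # Å
    molecule_membership: np.ndarray  # molecule index per atom
    n_molecules: int

    def __post_init__(self) -> None:
        self.atom_masses = np.asarray(self.atom_masses, dtype=float)
        self.vdw_radii = np.asarray(self.vdw_radii, dtype=float)
        self.molecule_membership = np.asarray(self.molecule_membership, dtype=int)
        if len(self.atom_masses) == 0:
            raise ValueError("empty topology")
        if not (
            len(self.atom_masses)
            == len(self.vdw_radii)
            == len(self.molecule_membership)
        ):
            raise ValueError("per-atom arrays must have equal length")
        if np.any(self.atom_masses <= 0):
            raise ValueError("masses must be positive")
        seen = np.unique(self.molecule_membership)
        if not np.array_equal(seen, np.arange(self.n_molecules)):
            raise ValueError("molecule indices must be contiguous 0..n_molecules-1")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_masses)


@dataclass
class MDDescriptorSet:
    """The eight trajectory descriptors for one (compound, temperature)."""

    MD_density: float  # g/cm^3
    MD_FV: float  # percent
    MD_Rg: float  # Å
    MD_SP: float  # MPa^1/2
    MD_SP_E: float  # MPa^1/2
    MD_SP_V: float  # MPa^1/2
    MD_HV: float  # kcal/mol
    MD_RMSD: float  # Å

    def __post_init__(self) -> None:
        if self.MD_density <= 0:
            raise ValueError("density must be positive")
        if not 0 <= self.MD_FV <= 100:
            raise ValueError("free volume is a percentage")
        if self.MD_Rg < 0 or self.MD_RMSD < 0:
            raise ValueError("Rg and RMSD are non-negative")

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in DESCRIPTOR_NAMES}


DESCRIPTOR_NAMES = (
    "MD_density",
    "MD_FV",
    "MD_Rg",
    "MD_SP",
    "MD_SP_E",
    "MD_SP_V",
    "MD_HV",
    "MD_RMSD",
)

_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def _parse_comment(line: str) -> dict:
    out = {}
    for key, quoted, bare in _KV_RE.findall(line):
        out[key] = quoted if quoted else bare
    return out


def read_trajectory(path, topology_path=None) -> tuple[Trajectory, SystemTopology | None]:
    """Read an extended-XYZ trajectory (and optional JSON topology)."""
    frames: list[TrajectoryFrame] = []
    elements: list[str] | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        n = int(lines[i])
        meta = _parse_comment(lines[i + 1])
        if "box" not in meta:
            raise ValueError(f"frame at line {i + 1} lacks box= metadata")
        box = np.array([float(x) for x in meta["box"].split()])
        time = float(meta.get("time", len(frames)))
        energies = {k: float(meta[k]) for k in ENERGY_KEYS if k in meta} or None
        syms, coords = [], []
        for row in lines[i + 2 : i + 2 + n]:
            parts = row.split()
            syms.append(parts[0])
            coords.append([float(x) for x in parts[1:4]])
        if len(coords) != n:
            raise ValueError(f"frame at line {i} truncated")
        if elements is None:
            elements = syms
        elif syms != elements:
            raise ValueError("atom ordering/types vary across frames")
        frames.append(TrajectoryFrame(np.array(coords), box, time, energies))
        i += 2 + n
    traj = Trajectory(frames, elements)

    topology = None
    if topology_path is not None:
        with open(topology_path) as fh:
            d = json.load(fh)
        membership = np.asarray(d["molecule_membership"], dtype=int)
        masses = d.get("atom_masses") or [atomic_mass(s) for s in elements]
        radii = d.get("vdw_radii") or [vdw_radius(s) for s in elements]
        topology = SystemTopology(
            np.asarray(masses, dtype=float),
            np.asarray(radii, dtype=float),
            membership,
            int(d.get("n_molecules", membership.max() + 1)),
        )
        if topology.n_atoms != traj.frames[0].n_atoms:
            raise ValueError(
                f"topology has {topology.n_atoms} atoms, frames have "
                f"{traj.frames[0].n_atoms}"
            )
    return traj, topology


def write_trajectory(path, trajectory: Trajectory) -> None:
    """Write the extended-XYZ dialect (round-trips with read_trajectory)."""
    elements = trajectory.elements or ["X"] * trajectory.frames[0].n_atoms
    with open(path, "w") as fh:
        for frame in trajectory.frames:
            fh.write(f"{frame.n_atoms}\n")
            box = " ".join(f"{b:.8g}" for b in frame.box_lengths)
            meta = f'box="{box}" time={frame.time:.8g}'
            if frame.energies:
                meta += "".join(
                    f" {k}={v:.10g}" for k, v in frame.energies.items()
                )
            fh.write(meta + "\n")
            for sym, xyz in zip(elements, frame.coordinates):
                fh.write(f"{sym} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}\n")


def _min_image(delta: np.ndarray, box: np.ndarray) -> np.ndarray:
    return delta - box * np.round(delta / box)


def mass_density(frame: TrajectoryFrame, topology: SystemTopology) -> float:
    """Packing density in g/cm^3."""
    if frame.volume <= 0:
        raise ValueError("zero box volume")
    grams = topology.atom_masses.sum() * U_TO_G
    return grams / (frame.volume * A3_TO_CM3)


def radius_of_gyration(frame: TrajectoryFrame, topology: SystemTopology) -> float:
    """Mean mass-weighted molecular Rg (Å), molecules unwrapped via
    minimum-image displacements from each molecule's first atom."""
    values = []
    for m in range(topology.n_molecules):
        sel = topology.molecule_membership == m
        coords = frame.coordinates[sel]
        masses = topology.atom_masses[sel]
        anchor = coords[0]
        unwrapped = anchor + _min_image(coords - anchor, frame.box_lengths)
        com = np.average(unwrapped, axis=0, weights=masses)
        sq = np.sum((unwrapped - com) ** 2, axis=1)
        values.append(math.sqrt(np.average(sq, weights=masses)))
    return float(np.mean(values))


def unwrap_trajectory(trajectory: Trajectory) -> list[np.ndarray]:
    """Continuous coordinates: frame-to-frame displacements min-imaged."""
    out = [trajectory.frames[0].coordinates.copy()]
    for prev, cur in zip(trajectory.frames, trajectory.frames[1:]):
        step = _min_image(cur.coordinates - prev.coordinates, cur.box_lengths)
        out.append(out[-1] + step)
    return out


def rms_displacement(
    trajectory: Trajectory,
    topology: SystemTopology | None = None,
    reference_index: int = 0,
) -> np.ndarray:
    """Per-frame RMS displacement (Å) from a reference frame.

    Mobility measure: unwrapped coordinates, no rotational or
    translational superposition.
    """
    if len(trajectory) < 2:
        raise ValueError("need >= 2 frames")
    if not 0 <= reference_index < len(trajectory):
        raise IndexError(f"reference index {reference_index} out of range")
    unwrapped = unwrap_trajectory(trajectory)
    ref = unwrapped[reference_index]
    return np.array(
        [math.sqrt(np.mean(np.sum((u - ref) ** 2, axis=1))) for u in unwrapped]
    )


def percent_free_volume(
    frame: TrajectoryFrame,
    topology: SystemTopology,
    probe_radius: float = 0.0,
    grid_spacing: float = 0.5,
) -> float:
    """Percent of box volume outside every atom's vdW sphere.

    Grid estimate: points on a regular lattice are occupied when within
    (vdW radius + probe) of any atom under periodic minimum image.
    """
    if grid_spacing <= 0:
        raise ValueError("grid_spacing must be positive")
    box = frame.box_lengths
    counts = np.maximum(np.round(box / grid_spacing).astype(int), 1)
    axes = [(np.arange(c) + 0.5) * b / c for c, b in zip(counts, box)]
    gx, gy, gz = np.meshgrid(*axes, indexing="ij")
    points = np.column_stack([gx.ravel(), gy.ravel(), gz.ravel()])
    if topology.n_atoms == 0:
        return 100.0
    tree = cKDTree(points, boxsize=box)
    wrapped = np.mod(frame.coordinates, box)
    occupied = np.zeros(len(points), dtype=bool)
    for r in np.unique(topology.vdw_radii):
        sel = topology.vdw_radii == r
        hits = tree.query_ball_point(wrapped[sel], r + probe_radius)
        for h in hits:
            occupied[h] = True
    return 100.0 * (1.0 - occupied.mean())


def _mean_energy(frames: list[TrajectoryFrame], key: str) -> float:
    vals = [f.energies[key] for f in frames if f.energies and key in f.energies]
    if not vals:
        raise ValueError(f"no frames carry energy component {key!r}")
    return float(np.mean(vals))


def cohesive_energy_and_solubility(
    frames: list[TrajectoryFrame], topology: SystemTopology
) -> dict[str, float]:
    """Cohesive energy density (MPa) and Hansen-type solubility parameters.

    CED = -<E_inter>/<V>; MD_SP = sqrt(CED); electrostatic and vdW
    components analogously from their energy shares. A non-cohesive
    (positive) mean energy clamps the component to zero with a warning.
    """
    vol = float(np.mean([f.volume for f in frames]))

    def _ced(key: str) -> float:
        try:
            e = _mean_energy(frames, key)
        except ValueError:
            if key == "e_inter":
                raise
            return float("nan")
        ced = -e / vol * KCAL_PER_MOL_A3_TO_MPA
        if ced < 0:
            warnings.warn(f"positive mean {key}: clamping CED component to 0")
            return 0.0
        return ced

    ced = _ced("e_inter")
    ced_e = _ced("e_elec")
    ced_v = _ced("e_vdw")
    return {
        "CED": ced,
        "MD_SP": math.sqrt(ced),
        "MD_SP_E": math.sqrt(ced_e) if not math.isnan(ced_e) else float("nan"),
        "MD_SP_V": math.sqrt(ced_v) if not math.isnan(ced_v) else float("nan"),
    }


def heat_of_vaporization(
    frames: list[TrajectoryFrame], topology: SystemTopology, T: float
) -> float:
    """HV = -<E_inter>/n_molecules + R*T (kcal/mol), ideal-vapor limit."""
    if topology.n_molecules < 1:
        raise ValueError("need at least one molecule")
    e_inter = _mean_energy(frames, "e_inter")
    return -e_inter / topology.n_molecules + R_KCAL_MOL_K * T


def ensemble_descriptors(
    trajectory: Trajectory,
    topology: SystemTopology,
    T: float,
    trailing_fraction: float = 0.5,
    probe_radius: float = 0.0,
    grid_spacing: float = 0.5,
) -> MDDescriptorSet:
    """Ensemble-averaged descriptor set over the trailing window.

    The window is the last ``trailing_fraction`` of frames (default half,
    mirroring averaging over the back end of a production run). MD_RMSD
    is the mean displacement of the window's frames from the window's
    first frame.
    """
    n = len(trajectory)
    start = int(math.floor(n * (1.0 - trailing_fraction)))
    window = trajectory.frames[start:]
    if len(window) < 2:
        raise ValueError("trailing window must contain >= 2 frames")
    dens = float(np.mean([mass_density(f, topology) for f in window]))
    fv = float(
        np.mean(
            [
                percent_free_volume(f, topology, probe_radius, grid_spacing)
                for f in window
            ]
        )
    )
    rg = float(np.mean([radius_of_gyration(f, topology) for f in window]))
    sp = cohesive_energy_and_solubility(window, topology)
    hv = heat_of_vaporization(window, topology, T)
    sub = Trajectory(window, trajectory.elements)
    disp = rms_displacement(sub, topology, reference_index=0)
    rmsd = float(np.mean(disp[1:]))
    return MDDescriptorSet(
        MD_density=dens,
        MD_FV=fv,
        MD_Rg=rg,
        MD_SP=sp["MD_SP"],
        MD_SP_E=sp["MD_SP_E"],
        MD_SP_V=sp["MD_SP_V"],
        MD_HV=hv,
        MD_RMSD=rmsd,
    )
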