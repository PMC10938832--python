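"""Viscosity dataset curation.

Raw (SMILES, temperature, viscosity) records pass through a three-stage
filtration before modeling:

1. structure filter — keep single-fragment organic molecules built only
   from {H, C, N, O, F, Si, P, S, Cl, Br, I};
2. range filter — box-and-whisker outlier removal: a record is dropped if
   its viscosity or its temperature falls outside 1.5x the interquartile
   range of the respective variable;
3. positive-deviation filter — bulk-liquid viscosity decreases with
   temperature, so within each compound any point whose viscosity exceeds
   the previous retained (lower-temperature) point by more than 0.02 cP is
   removed.

Viscosities are then carried on the log10 scale, which de-skews the raw
distribution. Every removal is accounted for in a :class:`CurationReport`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

#: Elements admitted by the structure filter.
ALLOWED_ELEMENTS = frozenset(
    {"H", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)

#: Positive-deviation threshold in centipoise (strict inequality).
DEVIATION_THRESHOLD_CP = 0.02

#: Box-whisker fence multiplier.
IQR_FENCE_MULTIPLIER = 1.5


@dataclass(frozen=True)
class ViscosityRecord:
    """One experimental observation.

    Parameters
    ----------
    structure : str
        SMILES string of the molecule.
    temperature : float
        Temperature in kelvin; must be positive.
    viscosity : float
        Dynamic viscosity in centipoise; must be positive.
    source : str
        Free-text provenance tag.
    """

    structure: str
    temperature: float
    viscosity: float
    source: str = ""

    def __post_init__(self) -> None:
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0 K, got {self.temperature}")
        if not self.viscosity > 0:
            raise ValueError(f"viscosity must be > 0 cP, got {self.viscosity}")


@dataclass
class Removal:
    """A filtered-out record together with the reason it was dropped."""

    record: ViscosityRecord
    reason: str


@dataclass
class CuratedDataset:
    """Filtered records with log-scale viscosities and compound identities.

    ``compound_ids`` are canonical SMILES; two records share an id iff
    their structures canonicalize identically.
    """

    records: list[ViscosityRecord]
    log_viscosity: np.ndarray
    compound_ids: list[str]

    def __post_init__(self) -> None:
        self.log_viscosity = np.asarray(self.log_viscosity, dtype=float)
        if not (
            len(self.records) == len(self.log_viscosity) == len(self.compound_ids)
        ):
            raise ValueError("records, log_viscosity and compound_ids must align")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def temperatures(self) -> np.ndarray:
        return np.array([r.temperature for r in self.records], dtype=float)

    @property
    def viscosities(self) -> np.ndarray:
        return np.array([r.viscosity for r in self.records], dtype=float)

    def to_frame(self) -> pd.DataFrame:
        """Curated dataset as a DataFrame (the CSV export schema)."""
        return pd.DataFrame(
            {
                "structure": [r.structure for r in self.records],
                "temperature_K": self.temperatures,
                "viscosity_cP": self.viscosities,
                "log10_viscosity": self.log_viscosity,
                "compound_id": self.compound_ids,
            }
        )


@dataclass
class CurationReport:
    """Bookkeeping of how many records each filtration stage removed."""

    counts_in: int = 0
    removed_by_structure_filter: int = 0
    removed_by_range_filter: int = 0
    removed_by_deviation_filter: int = 0
    counts_out: int = 0
    removals: list[Removal] = field(default_factory=list)

    def reconciles(self) -> bool:
        removed = (
            self.removed_by_structure_filter
            + self.removed_by_range_filter
            + self.removed_by_deviation_filter
        )
        return self.counts_in - removed == self.counts_out

    def to_dict(self) -> dict:
        return {
            "counts_in": self.counts_in,
            "removed_by_structure_filter": self.removed_by_structure_filter,
            "removed_by_range_filter": self.removed_by_range_filter,
            "removed_by_deviation_filter": self.removed_by_deviation_filter,
            "counts_out": self.counts_out,
        }


@dataclass
class ParseReport:
    """Rows that could not be turned into records, with line numbers."""

    skipped: list[tuple[int, str]] = field(default_factory=list)


_DEFAULT_COLUMN_MAP = {
    "structure": "structure",
    "temperature": "temperature_K",
    "viscosity": "viscosity_cP",
    "source": "source",
    "temperature_unit": "K",
}


def read_records(
    path, column_map: dict | None = None
) -> tuple[list[ViscosityRecord], ParseReport]:
    """Read viscosity records from a delimited text file.

    ``column_map`` maps the roles ``structure``, ``temperature``,
    ``viscosity`` (and optionally ``source``) to column names, and may set
    ``temperature_unit`` to ``"C"`` for Celsius input (converted to kelvin
    at this boundary; all downstream code works in K and cP).

    Unparseable rows are skipped and listed in the returned
    :class:`ParseReport` with their (0-based) row numbers.
    """
    cmap = dict(_DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    sep = "\t" if str(path).endswith((".tsv", ".tab")) else ","
    df = pd.read_csv(path, sep=sep)
    for role in ("structure", "temperature", "viscosity"):
        if cmap[role] not in df.columns:
            raise KeyError(
                f"column {cmap[role]!r} (role {role!r}) not found in {path}"
            )
    offset = 273.15 if str(cmap.get("temperature_unit", "K")).upper() == "C" else 0.0
    has_source = cmap.get("source") in df.columns

    records: list[ViscosityRecord] = []
    report = ParseReport()
    for i, row in df.iterrows():
        try:
            t = float(row[cmap["temperature"]]) + offset
            v = float(row[cmap["viscosity"]])
            s = str(row[cmap["structure"]])
            src = str(row[cmap["source"]]) if has_source else ""
            records.append(ViscosityRecord(s, t, v, src))
        except (ValueError, TypeError) as exc:
            report.skipped.append((int(i), str(exc)))
    if not records:
        raise ValueError(f"no parseable rows in {path}")
    return records, report


def canonical_smiles(structure: str) -> str | None:
    """Canonical SMILES, or None when the structure does not parse."""
    mol = Chem.MolFromSmiles(structure)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def filter_structures(
    records: list[ViscosityRecord],
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS,
) -> tuple[list[ViscosityRecord], list[Removal]]:
    """Keep single-fragment organic molecules over the allowed element set.

    "Organic" is operationalized as containing at least one carbon atom,
    "single" as one connected fragment after SMILES parsing. Unparseable
    SMILES are removed with reason ``parse_failure``.
    """
    kept: list[ViscosityRecord] = []
    removed: list[Removal] = []
    for rec in records:
        mol = Chem.MolFromSmiles(rec.structure)
        if mol is None:
            removed.append(Removal(rec, "parse_failure"))
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            removed.append(Removal(rec, "multiple_fragments"))
            continue
        symbols = {a.GetSymbol() for a in mol.GetAtoms()}
        bad = symbols - allowed_elements
        if bad:
            removed.append(Removal(rec, f"disallowed_elements:{sorted(bad)}"))
            continue
        if "C" not in symbols:
            removed.append(Removal(rec, "no_carbon"))
            continue
        kept.append(rec)
    return kept, removed


def _iqr_fences(values: np.ndarray, k: float) -> tuple[float, float]:
    # linear-interpolation quantile convention, fixed across the package
    q1, q3 = np.quantile(values, [0.25, 0.75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def filter_range_outliers(
    records: list[ViscosityRecord], k: float = IQR_FENCE_MULTIPLIER
) -> tuple[list[ViscosityRecord], list[Removal]]:
    """Box-and-whisker outlier removal on viscosity and temperature.

    A record is removed iff its viscosity OR temperature lies outside
    [Q1 - k*IQR, Q3 + k*IQR] of that variable. Fences come from the
    pre-filter distribution: single pass, not iterated.
    """
    if not records:
        return [], []
    visc = np.array([r.viscosity for r in records])
    temp = np.array([r.temperature for r in records])
    v_lo, v_hi = _iqr_fences(visc, k)
    t_lo, t_hi = _iqr_fences(temp, k)
    kept, removed = [], []
    for rec in records:
        if not (v_lo <= rec.viscosity <= v_hi):
            removed.append(Removal(rec, "viscosity_out_of_range"))
        elif not (t_lo <= rec.temperature <= t_hi):
            removed.append(Removal(rec, "temperature_out_of_range"))
        else:
            kept.append(rec)
    return kept, removed


def filter_positive_temperature_deviation(
    records: list[ViscosityRecord],
    threshold: float = DEVIATION_THRESHOLD_CP,
) -> tuple[list[ViscosityRecord], list[Removal]]:
    """Remove points that break the inverse viscosity-temperature trend.

    Within each compound (canonical-SMILES identity), records are sorted
    by ascending temperature. Scanning upward, a point whose viscosity
    exceeds that of the last retained point by strictly more than
    ``threshold`` cP is removed; comparison is always against the last
    retained point, so the lowest-temperature anchor of each curve is
    always preserved and a single forward pass converges.
    """
    by_compound: dict[str, list[tuple[int, ViscosityRecord]]] = {}
    order: dict[int, ViscosityRecord] = {}
    parse_failures: list[int] = []
    for i, rec in enumerate(records):
        order[i] = rec
        canon = canonical_smiles(rec.structure)
        if canon is None:
            parse_failures.append(i)
            continue
        by_compound.setdefault(canon, []).append((i, rec))

    removed_idx: set[int] = set()
    for group in by_compound.values():
        group_sorted = sorted(group, key=lambda ir: ir[1].temperature)
        last_visc: float | None = None
        for i, rec in group_sorted:
            # strict inequality; epsilon guards float artifacts at the
            # exact-threshold boundary (e.g. 1.02 - 1.00 vs 0.02)
            if last_visc is not None and rec.viscosity - last_visc > threshold + 1e-12:
                removed_idx.add(i)
            else:
                last_visc = rec.viscosity
    kept = [order[i] for i in sorted(order) if i not in removed_idx and i not in parse_failures]
    removed = [
        Removal(order[i], "positive_temperature_deviation") for i in sorted(removed_idx)
    ]
    removed += [Removal(order[i], "parse_failure") for i in parse_failures]
    return kept, removed


def log_transform_viscosity(records: list[ViscosityRecord]) -> CuratedDataset:
    """Attach log10 viscosities and canonical compound ids."""
    logs = []
    ids = []
    cache: dict[str, str] = {}
    for rec in records:
        if not rec.viscosity > 0:
            raise ValueError("viscosity must be positive for log transform")
        logs.append(math.log10(rec.viscosity))
        if rec.structure not in cache:
            canon = canonical_smiles(rec.structure)
            if canon is None:
                raise ValueError(f"unparseable SMILES: {rec.structure!r}")
            cache[rec.structure] = canon
        ids.append(cache[rec.structure])
    return CuratedDataset(list(records), np.array(logs), ids)


def load_curated_csv(path) -> CuratedDataset:
    """Reload a curated dataset written by ``CuratedDataset.to_frame``.

    Trusts the stored compound ids and log values; does not re-filter.
    """
    df = pd.read_csv(path)
    records = [
        ViscosityRecord(s, t, v, "curated")
        for s, t, v in zip(df["structure"], df["temperature_K"], df["viscosity_cP"])
    ]
    return CuratedDataset(
        records, df["log10_viscosity"].to_numpy(), df["compound_id"].tolist()
    )


def curate(
    records: list[ViscosityRecord],
    allowed_elements: frozenset[str] = ALLOWED_ELEMENTS,
    fence_multiplier: float = IQR_FENCE_MULTIPLIER,
    deviation_threshold: float = DEVIATION_THRESHOLD_CP,
) -> tuple[CuratedDataset, CurationReport]:
    """Full curation: structure -> range -> deviation filters, then log10.

    Returns the curated dataset and a report whose counts reconcile
    exactly (counts_in - removals = counts_out).
    """
    report = CurationReport(counts_in=len(records))
    kept, rm = filter_structures(records, allowed_elements)
    report.removed_by_structure_filter = len(rm)
    report.removals.extend(rm)
    kept, rm = filter_range_outliers(kept, fence_multiplier)
    report.removed_by_range_filter = len(rm)
    report.removals.extend(rm)
    kept, rm = filter_positive_temperature_deviation(kept, deviation_threshold)
    report.removed_by_deviation_filter = len(rm)
    report.removals.extend(rm)
    report.counts_out = len(kept)
    if kept:
        dataset = log_transform_viscosity(kept)
    else:
        dataset = CuratedDataset([], np.array([]), [])
    return dataset, report
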