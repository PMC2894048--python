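"""Curated-database schema: entry types, TSV round-tripping and dummy coding.

The database is a literature meta-dataset of aggregation-kinetics experiments:
one row per (protein, GAG, condition) experiment, with the observed aggregation
half-times in the absence and presence of the glycosaminoglycan and the derived
acceleration statistic ``G = ln(t_half_no_gag / t_half_with_gag)``.

The on-disk dialect is UTF-8, tab-separated, one header row, decimal points.
Optional fields are empty cells and are carried as ``None``; analyses that need
them exclude such entries pairwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DegenerateEncodingError,
    EmptyInputError,
    EntryValidationError,
    ParseError,
    SchemaError,
)

__all__ = [
    "GagDescriptor",
    "ProteinDescriptor",
    "ExperimentalCondition",
    "DatasetEntry",
    "load_dataset",
    "load_schema",
    "save_dataset",
    "entries_to_frame",
    "encode_dummies",
    "dataset_summary",
    "COLUMNS",
    "REFERENCE_LEVELS",
    "G_RECOMPUTE_TOL",
]

#: absolute tolerance when checking a stored G against ln(t0/tg)
G_RECOMPUTE_TOL = 1e-6

#: relative tolerance for protein:GAG molar-ratio consistency
RATIO_REL_TOL = 0.05

URONIC_LEVELS = ("glucuronic", "iduronic", "none")
SULFATION_POSITIONS = ("N", "O", "mixed", "none")
FOLDING_LEVELS = ("globular", "natively_unfolded")

#: reference (dropped) level per dichotomous variable used in the dummy coding
REFERENCE_LEVELS = {
    "uronic_acid": "glucuronic",
    "sulfation_position": "O",
    "folding_status": "globular",
    "disease_related": "False",
}


@dataclass
class GagDescriptor:
    """Chemical descriptors of a glycosaminoglycan, counted per disaccharide unit."""

    name: str
    sulfates_per_disaccharide: float
    charges_per_disaccharide: float
    uronic_acid: str
    sulfation_position: str
    molecular_weight: float | None = None

    def validate(self) -> None:
        if self.sulfates_per_disaccharide < 0:
            raise EntryValidationError(
                f"GAG {self.name!r}: sulfates_per_disaccharide < 0"
            )
        # each sulfate carries one negative charge; the carboxylate can add ~1 more
        if self.charges_per_disaccharide < self.sulfates_per_disaccharide - 1e-9:
            raise EntryValidationError(
                f"GAG {self.name!r}: charges ({self.charges_per_disaccharide}) fewer "
                f"than sulfates ({self.sulfates_per_disaccharide})"
            )
        if self.uronic_acid not in URONIC_LEVELS:
            raise EntryValidationError(
                f"GAG {self.name!r}: unknown uronic_acid {self.uronic_acid!r}"
            )
        if self.sulfation_position not in SULFATION_POSITIONS:
            raise EntryValidationError(
                f"GAG {self.name!r}: unknown sulfation_position {self.sulfation_position!r}"
            )
        no_sulfates = self.sulfates_per_disaccharide == 0
        if no_sulfates != (self.sulfation_position == "none"):
            raise EntryValidationError(
                f"GAG {self.name!r}: sulfation_position 'none' must coincide with "
                f"zero sulfates per disaccharide"
            )
        if self.molecular_weight is not None and self.molecular_weight <= 0:
            raise EntryValidationError(f"GAG {self.name!r}: molecular_weight <= 0")


@dataclass
class ProteinDescriptor:
    """Descriptors of the aggregating polypeptide (net charge at pH 7.5)."""

    name: str
    length: int
    net_charge: float
    lys_arg_count: int
    folding_status: str
    disease_related: bool

    def validate(self) -> None:
        if self.length <= 0:
            raise EntryValidationError(f"protein {self.name!r}: length <= 0")
        if not 0 <= self.lys_arg_count <= self.length:
            raise EntryValidationError(
                f"protein {self.name!r}: lys_arg_count outside [0, length]"
            )
        if self.folding_status not in FOLDING_LEVELS:
            raise EntryValidationError(
                f"protein {self.name!r}: unknown folding_status {self.folding_status!r}"
            )


@dataclass
class ExperimentalCondition:
    """Solution conditions of one experiment; molarity in mM, concentrations in µM."""

    solute_molarity: float
    protein_conc: float | None = None
    gag_conc: float | None = None
    protein_gag_molar_ratio: float | None = None
    pH: float | None = None
    temperature: float | None = None
    buffer_text: str = ""

    def validate(self) -> None:
        if self.solute_molarity < 0:
            raise EntryValidationError("solute_molarity < 0")
        for name in ("protein_conc", "gag_conc", "protein_gag_molar_ratio"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise EntryValidationError(f"{name} must be positive, got {v}")
        if (
            self.protein_conc is not None
            and self.gag_conc is not None
            and self.protein_gag_molar_ratio is not None
        ):
            implied = self.protein_conc / self.gag_conc
            if not math.isclose(
                implied, self.protein_gag_molar_ratio, rel_tol=RATIO_REL_TOL
            ):
                raise EntryValidationError(
                    f"protein_gag_molar_ratio {self.protein_gag_molar_ratio} "
                    f"inconsistent with protein_conc/gag_conc = {implied:.4g} "
                    f"(>{RATIO_REL_TOL:.0%} relative)"
                )


@dataclass
class DatasetEntry:
    """One curated literature experiment with its observed kinetic outcome."""

    protein: ProteinDescriptor
    gag: GagDescriptor
    condition: ExperimentalCondition
    t_half_no_gag: float | None
    t_half_with_gag: float | None
    G: float
    time_unit: str = "h"
    source: str = ""

    def validate(self) -> None:
        self.protein.validate()
        self.gag.validate()
        self.condition.validate()
        have_pair = self.t_half_no_gag is not None and self.t_half_with_gag is not None
        if have_pair:
            if self.t_half_no_gag <= 0 or self.t_half_with_gag <= 0:
                raise EntryValidationError("t_half values must be positive")
            recomputed = math.log(self.t_half_no_gag / self.t_half_with_gag)
            if abs(recomputed - self.G) > G_RECOMPUTE_TOL:
                raise EntryValidationError(
                    f"stored G = {self.G} does not match "
                    f"ln(t_half_no_gag/t_half_with_gag) = {recomputed:.8g}"
                )
        if not self.time_unit:
            raise EntryValidationError("time_unit must be non-empty (both t_half share it)")


# ---------------------------------------------------------------------------
# TSV round-tripping
# ---------------------------------------------------------------------------

#: canonical column order of the entry table
COLUMNS = [
    "protein",
    "protein_length",
    "protein_net_charge",
    "protein_lys_arg",
    "folding_status",
    "disease_related",
    "gag",
    "sulfates_per_disaccharide",
    "charges_per_disaccharide",
    "uronic_acid",
    "sulfation_position",
    "gag_molecular_weight",
    "solute_molarity",
    "protein_conc",
    "gag_conc",
    "protein_gag_molar_ratio",
    "pH",
    "temperature",
    "buffer",
    "t_half_no_gag",
    "t_half_with_gag",
    "time_unit",
    "G",
    "source",
]

_REQUIRED = [
    "protein",
    "protein_length",
    "protein_net_charge",
    "protein_lys_arg",
    "folding_status",
    "disease_related",
    "gag",
    "sulfates_per_disaccharide",
    "charges_per_disaccharide",
    "uronic_acid",
    "sulfation_position",
    "solute_molarity",
    "G",
]

_NUMERIC = {
    "protein_length",
    "protein_net_charge",
    "protein_lys_arg",
    "sulfates_per_disaccharide",
    "charges_per_disaccharide",
    "gag_molecular_weight",
    "solute_molarity",
    "protein_conc",
    "gag_conc",
    "protein_gag_molar_ratio",
    "pH",
    "temperature",
    "t_half_no_gag",
    "t_half_with_gag",
    "G",
}

#: factors to convert a recognised time unit to hours
_TIME_TO_HOURS = {"s": 1 / 3600, "sec": 1 / 3600, "min": 1 / 60, "h": 1.0, "hr": 1.0, "d": 24.0, "day": 24.0}


def _opt_float(value, row: int, column: str) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise ParseError(
            f"row {row}, column {column!r}: cannot parse {value!r} as a number",
            row=row,
            column=column,
        ) from None


def _parse_bool(value, row: int, column: str) -> bool:
    s = str(value).strip().lower()
    if s in {"true", "1", "yes"}:
        return True
    if s in {"false", "0", "no"}:
        return False
    raise ParseError(
        f"row {row}, column {column!r}: cannot parse {value!r} as a boolean",
        row=row,
        column=column,
    )


def load_schema(path: str | Path) -> dict[str, str]:
    """Read a YAML column map (file column -> canonical column) for load_dataset.

    The bundled ``data/schema.yaml`` is the identity map with documentation;
    edit the keys to ingest tables with different headers.
    """
    import yaml

    mapping = yaml.safe_load(Path(path).read_text())
    if not isinstance(mapping, dict) or not all(
        isinstance(k, str) and isinstance(v, str) for k, v in mapping.items()
    ):
        raise SchemaError(f"{path}: expected a flat string-to-string column map")
    unknown = sorted(set(mapping.values()) - set(COLUMNS))
    if unknown:
        raise SchemaError(f"{path}: maps to unknown canonical columns {unknown}")
    return mapping


def load_dataset(
    path: str | Path,
    schema: dict[str, str] | None = None,
    normalize_time: bool = True,
    strict: bool = True,
) -> list[DatasetEntry]:
    """Read an entry table from tab-separated text and validate every row.

    Parameters
    ----------
    path
        TSV file with a single header row.
    schema
        Optional map from file column names to canonical names in
        :data:`COLUMNS` (e.g. loaded from ``schema.yaml``). Identity by default.
    normalize_time
        Convert recognised time units to hours at load. ``G`` depends only on
        the ratio of the two half-times, so this is cosmetic for the analysis.
    strict
        If True (default), raise on the first invalid row; otherwise drop
        invalid rows and attach the diagnostics to the returned list as the
        ``rejected`` attribute is not used — diagnostics are raised instead.

    Returns
    -------
    list of :class:`DatasetEntry`
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        frame = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise EmptyInputError(f"{path}: file is empty") from None
    if schema:
        missing_src = [c for c in schema if c not in frame.columns]
        if missing_src:
            raise SchemaError(f"{path}: schema maps absent columns {missing_src}")
        frame = frame.rename(columns=schema)
    missing = [c for c in _REQUIRED if c not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")
    if len(frame) == 0:
        raise EmptyInputError(f"{path}: no data rows")

    entries: list[DatasetEntry] = []
    problems: list[str] = []
    for i, rec in enumerate(frame.to_dict("records")):
        row = i + 2  # 1-based line number including header
        try:
            entries.append(_entry_from_record(rec, row, normalize_time))
        except (ParseError, EntryValidationError) as exc:
            if strict:
                raise
            problems.append(f"row {row}: {exc}")
    if not entries:
        raise EmptyInputError(f"{path}: every row was rejected: {problems}")
    return entries


def _entry_from_record(rec: dict, row: int, normalize_time: bool) -> DatasetEntry:
    def opt(col):
        return _opt_float(rec.get(col, ""), row, col)

    def req(col):
        v = opt(col)
        if v is None:
            raise ParseError(f"row {row}: required numeric column {col!r} is empty",
                             row=row, column=col)
        return v

    protein = ProteinDescriptor(
        name=str(rec["protein"]),
        length=int(req("protein_length")),
        net_charge=req("protein_net_charge"),
        lys_arg_count=int(req("protein_lys_arg")),
        folding_status=str(rec["folding_status"]),
        disease_related=_parse_bool(rec["disease_related"], row, "disease_related"),
    )
    gag = GagDescriptor(
        name=str(rec["gag"]),
        sulfates_per_disaccharide=req("sulfates_per_disaccharide"),
        charges_per_disaccharide=req("charges_per_disaccharide"),
        uronic_acid=str(rec["uronic_acid"]),
        sulfation_position=str(rec["sulfation_position"]),
        molecular_weight=opt("gag_molecular_weight"),
    )
    condition = ExperimentalCondition(
        solute_molarity=req("solute_molarity"),
        protein_conc=opt("protein_conc"),
        gag_conc=opt("gag_conc"),
        protein_gag_molar_ratio=opt("protein_gag_molar_ratio"),
        pH=opt("pH"),
        temperature=opt("temperature"),
        buffer_text=str(rec.get("buffer", "")),
    )
    t0 = opt("t_half_no_gag")
    tg = opt("t_half_with_gag")
    unit = str(rec.get("time_unit", "") or "h")
    if normalize_time and unit in _TIME_TO_HOURS and unit not in ("h", "hr"):
        k = _TIME_TO_HOURS[unit]
        t0 = None if t0 is None else t0 * k
        tg = None if tg is None else tg * k
        unit = "h"
    entry = DatasetEntry(
        protein=protein,
        gag=gag,
        condition=condition,
        t_half_no_gag=t0,
        t_half_with_gag=tg,
        G=req("G"),
        time_unit=unit,
        source=str(rec.get("source", "")),
    )
    try:
        entry.validate()
    except EntryValidationError as exc:
        raise EntryValidationError(f"row {row}: {exc}", row=row) from None
    return entry


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(value)
    if isinstance(value, float):
        return repr(value)  # shortest exact decimal -> bit-identical round trip
    return str(value)


def entries_to_frame(entries: Sequence[DatasetEntry]) -> pd.DataFrame:
    """Flatten entries to a DataFrame with the canonical :data:`COLUMNS`."""
    rows = []
    for e in entries:
        rows.append(
            {
                "protein": e.protein.name,
                "protein_length": e.protein.length,
                "protein_net_charge": e.protein.net_charge,
                "protein_lys_arg": e.protein.lys_arg_count,
                "folding_status": e.protein.folding_status,
                "disease_related": e.protein.disease_related,
                "gag": e.gag.name,
                "sulfates_per_disaccharide": e.gag.sulfates_per_disaccharide,
                "charges_per_disaccharide": e.gag.charges_per_disaccharide,
                "uronic_acid": e.gag.uronic_acid,
                "sulfation_position": e.gag.sulfation_position,
                "gag_molecular_weight": e.gag.molecular_weight,
                "solute_molarity": e.condition.solute_molarity,
                "protein_conc": e.condition.protein_conc,
                "gag_conc": e.condition.gag_conc,
                "protein_gag_molar_ratio": e.condition.protein_gag_molar_ratio,
                "pH": e.condition.pH,
                "temperature": e.condition.temperature,
                "buffer": e.condition.buffer_text,
                "t_half_no_gag": e.t_half_no_gag,
                "t_half_with_gag": e.t_half_with_gag,
                "time_unit": e.time_unit,
                "G": e.G,
                "source": e.source,
            }
        )
    return pd.DataFrame(rows, columns=COLUMNS)


def save_dataset(entries: Sequence[DatasetEntry], path: str | Path) -> None:
    """Write entries as tab-separated text re-loadable by :func:`load_dataset`.

    Floats are written with ``repr`` (shortest exact decimal), so a
    save→load round trip reproduces the values bit-identically. Entries are
    validated first; an invariant violation refuses the write.
    """
    for i, e in enumerate(entries):
        try:
            e.validate()
        except EntryValidationError as exc:
            raise EntryValidationError(f"entry {i}: {exc}", row=i) from None
    frame = entries_to_frame(entries)
    path = Path(path)
    with path.open("w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(COLUMNS) + "\n")
        for rec in frame.to_dict("records"):
            fh.write("\t".join(_fmt(rec[c]) for c in COLUMNS) + "\n")


# ---------------------------------------------------------------------------
# Dummy coding
# ---------------------------------------------------------------------------

def encode_dummies(
    entries: Sequence[DatasetEntry] | pd.DataFrame,
    variables: Iterable[str],
) -> pd.DataFrame:
    """Recode categorical descriptors into 0/1 dummy columns.

    One reference level per variable is dropped (see :data:`REFERENCE_LEVELS`;
    for variables without a registered reference the alphabetically first
    observed level is dropped). Column names are deterministic:
    ``"<variable>=<level>"`` with levels in alphabetical order.
    """
    frame = entries if isinstance(entries, pd.DataFrame) else entries_to_frame(entries)
    out = {}
    for var in variables:
        if var not in frame.columns:
            raise SchemaError(f"unknown categorical variable {var!r}")
        values = frame[var].astype(str)
        levels = sorted(values.unique())
        if len(levels) < 2:
            raise DegenerateEncodingError(
                f"variable {var!r} has a single observed level {levels!r}"
            )
        reference = REFERENCE_LEVELS.get(var, levels[0])
        if reference not in levels:
            reference = levels[0]
        for level in levels:
            if level == reference:
                continue
            out[f"{var}={level}"] = (values == level).astype(int).to_numpy()
    return pd.DataFrame(out, index=frame.index)


def dataset_summary(entries: Sequence[DatasetEntry]) -> dict:
    """Counts and ranges used by ``gagfib db summary`` and sanity checks."""
    frame = entries_to_frame(entries)
    numeric = frame.select_dtypes(include=[np.number])
    return {
        "n_entries": len(entries),
        "n_proteins": frame["protein"].nunique(),
        "n_gags": frame["gag"].nunique(),
        "G_range": (float(frame["G"].min()), float(frame["G"].max())),
        "ranges": {
            c: (float(numeric[c].min()), float(numeric[c].max()))
            for c in numeric.columns
            if numeric[c].notna().any()
        },
    }
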