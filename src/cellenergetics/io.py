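"""Tabular I/O: species trait tables, lipid composition tables, flat configs.

All tables are tab-delimited UTF-8 text with '.' decimals.  Species tables
allow missing cells (empty fields), which are loaded as NaN and flagged;
cells that contain unparseable text reject the whole row with a
row-numbered message.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .cost_models import LipidSpecies, MembraneComposition
from .errors import SchemaError

__all__ = [
    "SPECIES_TABLE_COLUMNS",
    "SpeciesTable",
    "read_species_table",
    "write_species_table",
    "read_lipid_composition",
    "read_config",
    "write_json_report",
]

#: Canonical species-table schema; only the first two are mandatory.
SPECIES_TABLE_COLUMNS = (
    "species",
    "group",
    "cell_volume_um3",
    "division_time_h",
    "plasma_area_um2",
    "mito_outer_um2",
    "mito_inner_um2",
    "ribosomes_per_cell",
    "atp_synthase_per_cell",
)
_MANDATORY = ("species", "cell_volume_um3")
_NUMERIC = tuple(c for c in SPECIES_TABLE_COLUMNS if c not in ("species", "group"))


@dataclass
class SpeciesTable:
    """A typed cross-species trait table plus load diagnostics."""

    frame: pd.DataFrame
    rejected: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.frame)

    def missing_cells(self) -> list[tuple[str, str]]:
        """(species, column) pairs whose value is missing."""
        out = []
        for col in self.frame.columns:
            if col in ("species", "group"):
                continue
            for sp in self.frame.loc[self.frame[col].isna(), "species"]:
                out.append((sp, col))
        return out


def read_species_table(path: Union[str, Path]) -> SpeciesTable:
    """Load a tab-delimited species table.

    Mandatory columns: ``species`` and ``cell_volume_um3``.  Empty numeric
    cells load as missing; rows with text where a number is expected, or
    with negative values, are dropped with a row-numbered message collected
    in ``rejected`` (and emitted as a warning).  Duplicate species labels
    are a schema error.
    """
    path = Path(path)
    try:
        raw = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: file is empty or has no header") from exc
    missing = [c for c in _MANDATORY if c not in raw.columns]
    if missing:
        raise SchemaError(f"{path}: missing mandatory columns {missing}")

    rejected: list[str] = []
    keep = np.ones(len(raw), dtype=bool)
    numeric_cols = [c for c in raw.columns if c in _NUMERIC]
    parsed = {}
    for col in numeric_cols:
        values = pd.to_numeric(raw[col], errors="coerce")
        bad = values.isna() & raw[col].notna() & (raw[col].str.strip() != "")
        neg = values < 0
        for idx in raw.index[bad]:
            # +2: header line plus 1-based numbering.
            rejected.append(f"row {idx + 2}: unparseable value {raw.at[idx, col]!r} in column {col!r}")
        for idx in raw.index[neg]:
            rejected.append(f"row {idx + 2}: negative value {values[idx]!r} in column {col!r}")
        keep &= ~(bad.to_numpy() | neg.to_numpy())
        parsed[col] = values
    frame = raw.copy()
    for col, values in parsed.items():
        frame[col] = values
    frame = frame.loc[keep].reset_index(drop=True)
    if rejected:
        warnings.warn(f"{path}: rejected {len(rejected)} cell(s): " + "; ".join(rejected))
    dup = frame["species"][frame["species"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"{path}: duplicate species labels {sorted(set(dup))}")
    return SpeciesTable(frame=frame, rejected=rejected)


def write_species_table(table: Union[SpeciesTable, pd.DataFrame], path: Union[str, Path]) -> None:
    frame = table.frame if isinstance(table, SpeciesTable) else table
    frame.to_csv(path, sep="\t", index=False)


def read_lipid_composition(path: Union[str, Path]) -> MembraneComposition:
    """Load a membrane composition TSV.

    Columns: name, domain, chain_length, unsaturations, fraction, and
    optional total_cost_override / reduced_cost_override (blank = none).
    """
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    required = {"name", "domain", "chain_length", "unsaturations", "fraction"}
    missing = required - set(frame.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    components = []
    for _, row in frame.iterrows():
        overrides = {}
        for col in ("total_cost_override", "reduced_cost_override"):
            if col in frame.columns and pd.notna(row[col]):
                overrides[col] = float(row[col])
        sp = LipidSpecies(
            name=str(row["name"]),
            domain=str(row["domain"]),
            chain_length=float(row["chain_length"]),
            unsaturations=float(row["unsaturations"]),
            **overrides,
        )
        components.append((sp, float(row["fraction"])))
    return MembraneComposition(components)


def read_config(path: Union[str, Path]) -> dict:
    """Parse a flat ``key = value`` config file.

    Lines starting with '#' are comments; values are coerced to int, then
    float, then kept as strings.
    """
    out: dict = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise SchemaError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, _, value = line.partition("=")
        key, value = key.strip(), value.strip()
        for cast in (int, float):
            try:
                out[key] = cast(value)
                break
            except ValueError:
                continue
        else:
            out[key] = value
    return out


def write_json_report(obj, path: Union[str, Path]) -> None:
    """Write a JSON mirror of a report with stable key order."""
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
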