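"""Bioenergetic complex counts, membrane occupancy, and required turnover.

Proteomic copy numbers per cell, divided by the stoichiometry of each
subunit within a complex, give independent estimates of how many assembled
complexes a cell can hold.  Multiplying a complex count by its physical
membrane footprint and dividing by membrane area gives the fraction of the
membrane the complexes occupy.  Dividing the ATP share of the lifetime
energy budget by (division time × complex count) gives the ATP turnover
each complex must sustain, comparable against measured maximal rates of
F0F1 ATP synthase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "Subunit",
    "ComplexCensus",
    "ComplexCountEstimate",
    "FootprintModel",
    "DEFAULT_FOOTPRINTS",
    "complexes_per_cell",
    "occupancy_fraction",
    "required_turnover",
    "ECOLI_ATP_SYNTHASE_COMPLEXES",
    "ECOLI_SURFACE_AREA_UM2",
    "BACTERIAL_MEAN_SYNTHASE_OCCUPANCY",
    "ETC_TO_SYNTHASE_FOOTPRINT_FACTOR",
    "MAX_TURNOVER_PER_S",
    "DEFAULT_ATP_SHARE",
]


@dataclass(frozen=True)
class Subunit:
    """One protein subunit: copies per cell and copies per assembled complex."""

    name: str
    copies_per_cell: float
    stoichiometry_per_complex: int = 1

    def __post_init__(self) -> None:
        if self.copies_per_cell < 0:
            raise InvalidInputError("copies_per_cell must be >= 0")
        if self.stoichiometry_per_complex < 1:
            raise InvalidInputError("stoichiometry_per_complex must be >= 1")


@dataclass(frozen=True)
class ComplexCensus:
    """Per-subunit copy numbers for one membrane complex."""

    subunits: Sequence[Subunit]
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "subunits", tuple(self.subunits))


@dataclass(frozen=True)
class ComplexCountEstimate:
    """Independent per-subunit complex-count estimates and their summary.

    The mean assumes every copy is assembled; the minimum is the
    conservative assembled-complex limit (the scarcest subunit caps the
    number of complete complexes).
    """

    per_subunit: dict[str, float]
    mean: float
    min: float
    max: float


def complexes_per_cell(census: ComplexCensus) -> ComplexCountEstimate:
    """Estimate assembled complexes per cell from subunit copy numbers.

    Each subunit with copies > 0 yields copies / stoichiometry; the summary
    is the arithmetic mean of those estimates, with min and max reported so
    callers can apply the conservative limit.
    """
    estimates = {
        s.name: s.copies_per_cell / s.stoichiometry_per_complex
        for s in census.subunits
        if s.copies_per_cell > 0
    }
    if not estimates:
        raise InsufficientDataError(
            "census has no subunit with positive copy number"
        )
    vals = list(estimates.values())
    return ComplexCountEstimate(
        per_subunit=estimates,
        mean=sum(vals) / len(vals),
        min=min(vals),
        max=max(vals),
    )


@dataclass(frozen=True)
class FootprintModel:
    """Membrane footprint of one complex, nm²."""

    footprint_nm2: float
    name: str = ""

    def __post_init__(self) -> None:
        if self.footprint_nm2 <= 0:
            raise InvalidInputError("footprint must be > 0")


#: Membrane footprints: bacterial F0F1 from its widest (F1) diameter;
#: eukaryotic synthases are slightly larger; an ETC unit is larger still.
DEFAULT_FOOTPRINTS = {
    "atp_synthase_bacteria": FootprintModel(64.0, "bacterial F0F1 ATP synthase"),
    "atp_synthase_eukaryote": FootprintModel(110.0, "eukaryotic F0F1 ATP synthase"),
    "etc_unit": FootprintModel(570.0, "electron transport chain unit"),
}

#: Reference complex count for E. coli (from subunit proteomics).
ECOLI_ATP_SYNTHASE_COMPLEXES = 3018
#: E. coli cell surface area, μm².
ECOLI_SURFACE_AREA_UM2 = 15.8
#: Mean ATP synthase membrane occupancy across five bacterial species.
BACTERIAL_MEAN_SYNTHASE_OCCUPANCY = 0.011
#: The ETC footprint is treated as ~5× the synthase footprint where the
#: occupancy arguments scale bacterial synthase occupancy up to the ETC.
ETC_TO_SYNTHASE_FOOTPRINT_FACTOR = 5.0
#: Measured maximal ATP synthase turnover rates (per second, liposome assays).
MAX_TURNOVER_PER_S = {
    "bacteria_mean": 195.0,
    "soybean_plastid": 295.0,
    "S_cerevisiae": 120.0,
    "bovine_heart": 440.0,
}
#: Share of biosynthetic energy flowing through ATP hydrolysis (the rest is
#: redox); used to discount budgets before computing required turnover.
DEFAULT_ATP_SHARE = 0.15


def occupancy_fraction(
    n_complexes: float, footprint_nm2: float, membrane_area_um2: float
) -> float:
    """Fraction of a membrane occupied by ``n_complexes`` of given footprint.

    Pure area ratio (1 μm² = 1e6 nm²); no steric packing limit is imposed,
    but fractions above 1 trigger a warning since they are physically
    impossible.
    """
    if n_complexes < 0 or footprint_nm2 < 0:
        raise InvalidInputError("counts and footprints must be >= 0")
    if membrane_area_um2 <= 0:
        raise InvalidInputError("membrane_area_um2 must be > 0")
    frac = n_complexes * footprint_nm2 / (membrane_area_um2 * 1e6)
    if frac > 1:
        warnings.warn(
            f"occupancy fraction {frac:.3g} exceeds 1; inputs are inconsistent "
            "with the available membrane area"
        )
    return frac


def required_turnover(
    total_budget_atp: float,
    atp_share: float,
    division_time_h: float,
    n_complexes: float,
) -> float:
    """ATP produced per complex per second to meet the cell's budget.

    total_budget × atp_share / (division_time × 3600 × n_complexes).
    ``atp_share`` discounts the budget to the portion actually delivered as
    ATP hydrolysis (default elsewhere 0.15, i.e. an 85% discount).
    """
    if total_budget_atp <= 0:
        raise InvalidInputError("total_budget_atp must be > 0")
    if not 0 < atp_share <= 1:
        raise InvalidInputError("atp_share must lie in (0, 1]")
    if division_time_h <= 0 or n_complexes <= 0:
        raise InvalidInputError("division_time_h and n_complexes must be > 0")
    return total_budget_atp * atp_share / (division_time_h * 3600.0 * n_complexes)
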