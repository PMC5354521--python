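"""Cell and organelle membrane geometry and growth-budget apportionment.

Covers closed-form surface areas and volumes for the cell shapes that occur
in morphometric surveys (spheres, spherocylindrical rods, triaxial
ellipsoids), conversion of outer mitochondrial membrane area to total
(inner + outer) area via the cristae-inclusive inner:outer ratio, and a
Table-1-style report splitting a cell's membrane lipid cost across
compartments and expressing it as a fraction of the growth budget.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

from scipy.special import ellipeinc, ellipkinc

import pandas as pd

from . import energy_budget
from .cost_models import MEAN_DIRECT_COST_EUKARYOTE
from .errors import InvalidInputError

__all__ = [
    "Sphere",
    "Spherocylinder",
    "Ellipsoid",
    "CellGeometry",
    "surface_area",
    "cell_volume",
    "MitochondrialMorphology",
    "DEFAULT_INNER_OUTER_RATIO",
    "OBSERVED_INNER_OUTER_RATIOS",
    "mean_observed_inner_outer_ratio",
    "total_mito_area",
    "MembraneInventory",
    "MembraneBudgetReport",
    "membrane_budget_table",
    "apportionment_from_shares",
    "table1",
]


@dataclass(frozen=True)
class Sphere:
    radius: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidInputError("radius must be > 0")

    def surface_area(self) -> float:
        return 4.0 * math.pi * self.radius**2

    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.radius**3


@dataclass(frozen=True)
class Spherocylinder:
    """A cylinder of length ``cylinder_length`` capped by two hemispheres."""

    radius: float
    cylinder_length: float

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise InvalidInputError("radius must be > 0")
        if self.cylinder_length < 0:
            raise InvalidInputError("cylinder_length must be >= 0")

    def surface_area(self) -> float:
        return 2.0 * math.pi * self.radius * self.cylinder_length + 4.0 * math.pi * self.radius**2

    def volume(self) -> float:
        return (
            math.pi * self.radius**2 * self.cylinder_length
            + 4.0 / 3.0 * math.pi * self.radius**3
        )


@dataclass(frozen=True)
class Ellipsoid:
    """Triaxial ellipsoid with semi-axes a, b, c (μm), in any order."""

    a: float
    b: float
    c: float

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c) <= 0:
            raise InvalidInputError("all semi-axes must be > 0")

    def volume(self) -> float:
        return 4.0 / 3.0 * math.pi * self.a * self.b * self.c

    def surface_area(self) -> float:
        # Exact Legendre form for a >= b >= c; spheroid and sphere limits
        # handled separately because the general expression degenerates.
        a, b, c = sorted((self.a, self.b, self.c), reverse=True)
        rel = 1e-12 * a
        if a - c <= rel:  # sphere
            return 4.0 * math.pi * a * a
        if a - b <= rel:  # oblate spheroid (a = b > c)
            e = math.sqrt(1.0 - (c / a) ** 2)
            return 2.0 * math.pi * a * a + math.pi * c * c / e * math.log((1 + e) / (1 - e))
        if b - c <= rel:  # prolate spheroid (a > b = c)
            e = math.sqrt(1.0 - (b / a) ** 2)
            return 2.0 * math.pi * b * b * (1.0 + a / (b * e) * math.asin(e))
        phi = math.acos(c / a)
        m = (a * a * (b * b - c * c)) / (b * b * (a * a - c * c))
        F = ellipkinc(phi, m)
        E = ellipeinc(phi, m)
        s = math.sin(phi)
        return (
            2.0 * math.pi * c * c
            + 2.0 * math.pi * a * b / s * (E * s * s + F * (1.0 - s * s))
        )


CellGeometry = Union[Sphere, Spherocylinder, Ellipsoid]


def surface_area(geometry: CellGeometry) -> float:
    """Surface area (μm²) of a cell shape."""
    return geometry.surface_area()


def cell_volume(geometry: CellGeometry) -> float:
    """Volume (μm³) of a cell shape."""
    return geometry.volume()


#: Cristae-inclusive inner:outer membrane area ratio used to extrapolate
#: total mitochondrial area from outer-membrane measurements alone.
DEFAULT_INNER_OUTER_RATIO = 4.6
#: Individual observed ratios (mammals, Ochromonas, Rhus, Tetrahymena);
#: their arithmetic mean (3.775) is lower than the 4.6 default and is
#: provided for sensitivity analyses.
OBSERVED_INNER_OUTER_RATIOS = (5.0, 2.4, 2.5, 5.2)


def mean_observed_inner_outer_ratio() -> float:
    """Arithmetic mean of the individually observed inner:outer ratios."""
    return sum(OBSERVED_INNER_OUTER_RATIOS) / len(OBSERVED_INNER_OUTER_RATIOS)


@dataclass(frozen=True)
class MitochondrialMorphology:
    """Summed outer membrane area of all mitochondria in one cell (μm²)."""

    outer_area: float
    inner_to_outer_ratio: float = DEFAULT_INNER_OUTER_RATIO

    def __post_init__(self) -> None:
        if self.outer_area < 0:
            raise InvalidInputError("outer_area must be >= 0")
        if self.inner_to_outer_ratio < 1:
            raise InvalidInputError("inner:outer ratio must be >= 1 (cristae add area)")


def total_mito_area(morphology: MitochondrialMorphology) -> float:
    """Total (inner + outer) mitochondrial membrane area, μm².

    Extrapolates from the outer area as outer × (1 + inner:outer ratio).
    When inner membranes were measured directly, pass inner + outer
    downstream and skip this extrapolation.
    """
    return morphology.outer_area * (1.0 + morphology.inner_to_outer_ratio)


_COMPARTMENTS = ("plasma", "mitochondria", "nucleus", "er_golgi", "vesicles")


@dataclass(frozen=True)
class MembraneInventory:
    """Per-compartment membrane areas (μm²) for one cell.

    ``mitochondria`` is the inner + outer total; ``er_golgi`` pools the
    endoplasmic reticulum and Golgi; ``vesicles`` pools vesicles and
    vacuoles.  Plastid membranes are excluded by convention in algae.
    """

    plasma: float = 0.0
    mitochondria: float = 0.0
    nucleus: float = 0.0
    er_golgi: float = 0.0
    vesicles: float = 0.0

    def __post_init__(self) -> None:
        for name in _COMPARTMENTS:
            if getattr(self, name) < 0:
                raise InvalidInputError(f"membrane area {name} must be >= 0")

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in _COMPARTMENTS}

    def total_area(self) -> float:
        return sum(self.as_dict().values())


@dataclass(frozen=True)
class MembraneBudgetReport:
    """Apportionment of membrane costs across compartments.

    ``shares`` are normalized to sum to one over compartments with membrane;
    ``total_fraction`` is total membrane cost over the growth budget;
    ``internal_share`` = 1 − plasma share; ``internal_fraction_of_total`` =
    total_fraction × internal_share.
    """

    costs_atp: dict[str, float]
    shares: dict[str, float]
    total_membrane_cost: float
    growth_budget: float
    total_fraction: float
    internal_share: float
    internal_fraction_of_total: float
    generic_costs: bool = False

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"compartment": k, "cost_atp": self.costs_atp[k], "share": self.shares[k]}
            for k in self.costs_atp
        ]
        return pd.DataFrame(rows)


def membrane_budget_table(
    inventory: MembraneInventory,
    mean_lipid_cost: Union[float, Mapping[str, float]] = MEAN_DIRECT_COST_EUKARYOTE,
    volume: float = 1.0,
    head_group_area: float = energy_budget.HEAD_GROUP_AREA_UM2,
) -> MembraneBudgetReport:
    """Split the membrane lipid cost of a cell across compartments.

    ``mean_lipid_cost`` may be one ATP/molecule value for all compartments
    or a per-compartment mapping.  When the single eukaryotic mean reduced
    cost is used the report is flagged ``generic_costs`` (a "generic-cost
    approximation"): species-specific compositions shift per-compartment
    costs by tens of percent.
    """
    areas = inventory.as_dict()
    if isinstance(mean_lipid_cost, Mapping):
        costs_per_lipid = {k: float(mean_lipid_cost.get(k, MEAN_DIRECT_COST_EUKARYOTE)) for k in areas}
        generic = False
    else:
        costs_per_lipid = {k: float(mean_lipid_cost) for k in areas}
        generic = True
    if any(c <= 0 for c in costs_per_lipid.values()):
        raise InvalidInputError("per-lipid costs must be > 0")

    total_area = inventory.total_area()
    if total_area == 0:
        warnings.warn("inventory has zero total membrane area; report is all zeros")
        zeros = {k: 0.0 for k in areas}
        return MembraneBudgetReport(zeros, zeros, 0.0, energy_budget.growth_cost(volume),
                                    0.0, 0.0, 0.0, generic)

    costs = {
        k: energy_budget.membrane_lipid_cost(areas[k], costs_per_lipid[k], head_group_area)
        for k in areas
    }
    total_cost = sum(costs.values())
    shares = {k: costs[k] / total_cost for k in costs}
    cg = energy_budget.growth_cost(volume)
    total_fraction = total_cost / cg
    internal_share = 1.0 - shares["plasma"]
    return MembraneBudgetReport(
        costs_atp=costs,
        shares=shares,
        total_membrane_cost=total_cost,
        growth_budget=cg,
        total_fraction=total_fraction,
        internal_share=internal_share,
        internal_fraction_of_total=total_fraction * internal_share,
        generic_costs=generic,
    )


def apportionment_from_shares(
    total_fraction: float, plasma_share: float
) -> dict[str, float]:
    """Internal-membrane arithmetic from published apportionment numbers.

    Given the fraction of the growth budget spent on all membranes and the
    plasma membrane's share of that spend, returns the internal share
    (1 − plasma) and the internal fraction of the whole budget.
    """
    if not 0 <= plasma_share <= 1:
        raise InvalidInputError("plasma_share must lie in [0, 1]")
    if total_fraction < 0:
        raise InvalidInputError("total_fraction must be >= 0")
    internal = 1.0 - plasma_share
    return {
        "internal_share": internal,
        "internal_fraction_of_total": total_fraction * internal,
    }


#: Published per-species membrane accounting: Ostreococcus tauri (Ot),
#: Saccharomyces cerevisiae (Sc), Dunaliella salina (Ds), and a Sus scrofa
#: pancreas cell (Ss).  Areas exclude plastid membranes in the algae.
_TABLE1 = {
    "Ot": {"cell_volume_um3": 1.0, "total_membranes_um2": 15.0,
           "budget_fraction": 0.324, "plasma": 0.556, "mitochondria": 0.243,
           "nucleus": 0.113, "er_golgi": 0.034, "vesicles": 0.055},
    "Sc": {"cell_volume_um3": 44.0, "total_membranes_um2": 204.0,
           "budget_fraction": 0.096, "plasma": 0.328, "mitochondria": 0.359,
           "nucleus": 0.085, "er_golgi": 0.111, "vesicles": 0.114},
    "Ds": {"cell_volume_um3": 591.0, "total_membranes_um2": 2299.0,
           "budget_fraction": 0.094, "plasma": 0.134, "mitochondria": 0.197,
           "nucleus": 0.034, "er_golgi": 0.318, "vesicles": 0.316},
    "Ss": {"cell_volume_um3": 1060.0, "total_membranes_um2": 12952.0,
           "budget_fraction": 0.302, "plasma": 0.044, "mitochondria": 0.223,
           "nucleus": 0.008, "er_golgi": 0.706, "vesicles": 0.019},
}


def table1() -> pd.DataFrame:
    """Published membrane cost apportionment for four reference cells.

    Columns are species codes; rows are cell volume, total membrane area,
    the membrane fraction of the growth budget, and the five compartment
    shares of that membrane spend.
    """
    return pd.DataFrame(_TABLE1)
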