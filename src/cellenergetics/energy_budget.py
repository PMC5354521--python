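"""Cell energy budgets versus volume, membrane lipid costs, and selection calculus.

All budgets are in raw ATP counts (not units of 1e9) to avoid unit drift;
report formatting scales for display.  The two empirical budget laws are
power laws in cell volume ``V`` (μm³), normalized to 20 °C:

* maintenance rate  ``C_M = 0.39e9 · V^0.88``  ATP/cell/hour,
* growth cost       ``C_G = 27e9  · V^0.97``  ATP/cell,

and the lifetime budget of one division of duration ``t`` hours is
``C_T = C_G + t·C_M``.  A membrane of area ``A`` μm² costs
``(2/a_h)·c̄_L·A`` ATP, with ``a_h`` the lipid head-group area (default
6.5e-7 μm², giving the familiar 3.1e6 lipids/μm² bilayer coefficient) and
``c̄_L`` the mean per-lipid cost.  A trait's relative cost ``s_c`` (its ATP
cost over the cell's budget) acts as a selection coefficient against the
trait and is effective only when the net advantage exceeds the drift
threshold 1/N_e (haploid) or 1/(2N_e) (diploid).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

from .errors import InvalidInputError

__all__ = [
    "MAINTENANCE_COEF",
    "MAINTENANCE_EXPONENT",
    "GROWTH_COEF",
    "GROWTH_EXPONENT",
    "HEAD_GROUP_AREA_UM2",
    "MITO_AREA_COEF",
    "MITO_AREA_EXPONENT",
    "CellSpec",
    "EnergyBudget",
    "Ploidy",
    "SelectionContext",
    "SelectionOutcome",
    "maintenance_rate",
    "growth_cost",
    "total_cost",
    "cell_budget",
    "lipids_per_area",
    "membrane_lipid_cost",
    "mito_membrane_relative_cost",
    "mito_membrane_relative_cost_approx",
    "relative_cost",
    "selection_outcome",
]

#: C_M coefficient, ATP/cell/hour at V = 1 μm³ (0.39e9, 20 °C-normalized).
MAINTENANCE_COEF = 0.39e9
MAINTENANCE_EXPONENT = 0.88
#: C_G coefficient, ATP/cell at V = 1 μm³ (27e9).
GROWTH_COEF = 27e9
GROWTH_EXPONENT = 0.97
#: Membrane area per lipid head group, μm² (one leaflet).
HEAD_GROUP_AREA_UM2 = 6.5e-7
#: Total mitochondrial membrane area law A = 3.0·V^0.99 (μm² vs μm³).
MITO_AREA_COEF = 3.0
MITO_AREA_EXPONENT = 0.99
#: Mean total cost of a mitochondrial lipid, ATP/molecule.
MITO_MEAN_LIPID_COST = 440.0


def _require_positive(name: str, value: float) -> None:
    if not value > 0:
        raise InvalidInputError(f"{name} must be > 0, got {value!r}")


def maintenance_rate(
    volume: float,
    coefficient: float = MAINTENANCE_COEF,
    exponent: float = MAINTENANCE_EXPONENT,
) -> float:
    """Basal maintenance cost C_M in ATP/cell/hour for a cell of ``volume`` μm³."""
    _require_positive("volume", volume)
    return coefficient * volume**exponent


def growth_cost(
    volume: float,
    coefficient: float = GROWTH_COEF,
    exponent: float = GROWTH_EXPONENT,
) -> float:
    """One-time cost C_G (ATP) of building a daughter cell of ``volume`` μm³."""
    _require_positive("volume", volume)
    return coefficient * volume**exponent


def total_cost(volume: float, division_time: float) -> float:
    """Lifetime budget C_T = C_G + t·C_M of one division lasting ``division_time`` h."""
    _require_positive("volume", volume)
    if division_time < 0:
        raise InvalidInputError(f"division_time must be >= 0, got {division_time!r}")
    return growth_cost(volume) + division_time * maintenance_rate(volume)


@dataclass(frozen=True)
class CellSpec:
    """A cell described by volume (μm³), division time (hours), and group."""

    volume: float
    division_time: float
    group: str = "bacteria"

    def __post_init__(self) -> None:
        _require_positive("volume", self.volume)
        _require_positive("division_time", self.division_time)


@dataclass(frozen=True)
class EnergyBudget:
    """Maintenance rate (ATP/h), growth cost (ATP), and lifetime total (ATP)."""

    maintenance_rate: float
    growth_cost: float
    total_cost: float
    division_time: float


def cell_budget(cell: CellSpec) -> EnergyBudget:
    """Evaluate the full energy budget of ``cell``."""
    cm = maintenance_rate(cell.volume)
    cg = growth_cost(cell.volume)
    return EnergyBudget(
        maintenance_rate=cm,
        growth_cost=cg,
        total_cost=cg + cell.division_time * cm,
        division_time=cell.division_time,
    )


def lipids_per_area(
    head_group_area: float = HEAD_GROUP_AREA_UM2,
    protein_area_fraction: float = 0.0,
) -> float:
    """Lipid molecules per μm² of bilayer: 2/a_h, optionally discounted for
    the membrane fraction occupied by protein (at most 0.5)."""
    _require_positive("head_group_area", head_group_area)
    if not 0.0 <= protein_area_fraction <= 0.5:
        raise InvalidInputError(
            "protein_area_fraction must lie in [0, 0.5]; membranes are never "
            f"more than half protein (got {protein_area_fraction!r})"
        )
    return 2.0 / head_group_area * (1.0 - protein_area_fraction)


def membrane_lipid_cost(
    area: float,
    mean_lipid_cost: float,
    head_group_area: float = HEAD_GROUP_AREA_UM2,
    protein_area_fraction: float = 0.0,
) -> float:
    """ATP cost C_L of building a bilayer of ``area`` μm².

    C_L = (2/a_h)·c̄_L·A; with the default head-group area the leading
    coefficient is ≈3.1e6 lipids/μm².
    """
    if area < 0:
        raise InvalidInputError(f"area must be >= 0, got {area!r}")
    _require_positive("mean_lipid_cost", mean_lipid_cost)
    return lipids_per_area(head_group_area, protein_area_fraction) * mean_lipid_cost * area


def mito_membrane_relative_cost(
    volume: float,
    area_coefficient: float = MITO_AREA_COEF,
    area_exponent: float = MITO_AREA_EXPONENT,
    mean_lipid_cost: float = MITO_MEAN_LIPID_COST,
    head_group_area: float = HEAD_GROUP_AREA_UM2,
) -> float:
    """Mitochondrial membrane lipid cost as a fraction of the growth budget.

    Composes the membrane cost of the total mitochondrial area law
    A = 3.0·V^0.99 (inner + outer, all mitochondria) at c̄_L = 440 ATP with
    the growth law C_G = 27e9·V^0.97.  Numerically ≈ 0.15·V^0.02 — about
    15% of the growth budget of a 1 μm³ cell and nearly size-independent.
    """
    _require_positive("volume", volume)
    area = area_coefficient * volume**area_exponent
    return membrane_lipid_cost(area, mean_lipid_cost, head_group_area) / growth_cost(volume)


def mito_membrane_relative_cost_approx(volume: float) -> float:
    """The printed 0.15·V^0.02 shortcut; the explicit composition is ground truth."""
    _require_positive("volume", volume)
    return 0.15 * volume**0.02


def relative_cost(component_cost: float, total_cost: float) -> float:
    """Relative cost s_c of a trait: its ATP cost over the cell's total budget."""
    if component_cost < 0:
        raise InvalidInputError("component_cost must be >= 0")
    if not total_cost > 0:
        raise InvalidInputError("total_cost must be > 0")
    return component_cost / total_cost


class Ploidy(str, Enum):
    HAPLOID = "haploid"
    DIPLOID = "diploid"


@dataclass(frozen=True)
class SelectionContext:
    """Inputs of the selection-versus-drift comparison for one trait."""

    trait_cost_fraction: float  # s_c
    trait_benefit: float  # s_a
    effective_population_size: float  # N_e
    ploidy: Ploidy = Ploidy.HAPLOID

    def __post_init__(self) -> None:
        if self.trait_cost_fraction < 0:
            raise InvalidInputError("trait_cost_fraction (s_c) must be >= 0")
        if self.effective_population_size < 1:
            raise InvalidInputError("effective_population_size must be >= 1")
        object.__setattr__(self, "ploidy", Ploidy(self.ploidy))


@dataclass(frozen=True)
class SelectionOutcome:
    net_selection: float  # s_n = s_a - s_c
    drift_threshold: float  # 1/N_e or 1/(2 N_e)
    effective: bool  # |s_n| exceeds the drift threshold


def selection_outcome(ctx: SelectionContext) -> SelectionOutcome:
    """Net selection s_n = s_a − s_c versus the drift threshold.

    Selection perceives the trait only if |s_n| exceeds 1/N_e in a haploid
    or 1/(2N_e) in a diploid; below that the trait is effectively neutral.
    """
    sn = ctx.trait_benefit - ctx.trait_cost_fraction
    denom = ctx.effective_population_size
    if ctx.ploidy is Ploidy.DIPLOID:
        denom *= 2.0
    threshold = 1.0 / denom
    return SelectionOutcome(
        net_selection=sn,
        drift_threshold=threshold,
        effective=abs(sn) > threshold,
    )
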