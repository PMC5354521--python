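"""ATP-denominated biosynthetic costs of lipids and membrane compositions.

Glycerophospholipid costs are modelled as affine functions of the mean
fatty-acid chain length ``N_L`` (carbons per chain) and the mean number of
unsaturated carbons per chain ``N_U``.  Two cost conventions are supported:

* the *total* (evolutionary) cost ``c_L`` — direct ATP hydrolyses in the
  biosynthetic pathway plus the ATP-generating potential lost by diverting
  metabolic precursors; and
* the *reduced* (direct) cost ``c_L'`` — the direct ATP expenditure only.

Bacteria and eukaryotes carry different constants because eukaryotic fatty
acid synthesis pays an extra toll for exporting oxaloacetate from the
mitochondrion to generate cytosolic acetyl-CoA.

The module also carries the redox-versus-ATP share arithmetic: most of the
energy of monomer biosynthesis flows through NADH/NADPH oxidations rather
than ATP hydrolysis, and each oxidation is conventionally worth ~3 ATP.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

from .errors import DomainValidityError, InvalidInputError, ExtrapolationWarning

__all__ = [
    "Domain",
    "LipidSpecies",
    "MembraneComposition",
    "MonomerCostTable",
    "CARDIOLIPIN",
    "MITO_MEAN_TOTAL_LIPID_COST",
    "MEAN_DIRECT_COST_BACTERIA",
    "MEAN_DIRECT_COST_EUKARYOTE",
    "MEAN_DIRECT_COST_MITOCHONDRIA",
    "lipid_cost_total",
    "lipid_cost_reduced",
    "species_cost",
    "mean_membrane_cost",
    "atp_hydrolysis_share",
]


class Domain(str, Enum):
    """Phylogenetic domain selecting the lipid cost constants."""

    BACTERIA = "bacteria"
    EUKARYOTE = "eukaryote"


#: (base cost at N_L=16, ATP per extra chain carbon) for the total cost.
_TOTAL_CONSTANTS = {Domain.BACTERIA: (320.0, 38.0), Domain.EUKARYOTE: (340.0, 40.0)}
#: same for the reduced (direct-ATP-only) cost.
_REDUCED_CONSTANTS = {Domain.BACTERIA: (110.0, 7.0), Domain.EUKARYOTE: (120.0, 9.0)}
#: ATP per unsaturated carbon, shared by all four formulas.
_UNSATURATION_COST = 6.0
#: chain lengths below this are outside the lipid chemistry the model covers.
_MIN_CALIBRATED_CHAIN_LENGTH = 10.0

#: Average total cost of a mitochondrial membrane lipid (ATP/molecule).
MITO_MEAN_TOTAL_LIPID_COST = 440.0
#: Average direct (reduced) cost per plasma-membrane lipid, bacteria.
MEAN_DIRECT_COST_BACTERIA = 123.0
#: Average direct cost per lipid, eukaryotes (whole cell and plasma membrane).
MEAN_DIRECT_COST_EUKARYOTE = 143.0
#: Average direct cost per mitochondrial lipid (the most expensive class).
MEAN_DIRECT_COST_MITOCHONDRIA = 155.0


def _coerce_domain(domain: "Domain | str") -> Domain:
    try:
        return Domain(domain)
    except ValueError as exc:
        raise InvalidInputError(f"unknown domain {domain!r}") from exc


def _check_chain(chain_length: float, unsaturations: float) -> None:
    if chain_length is None or chain_length < 1:
        raise InvalidInputError(
            f"chain_length must be >= 1 carbon, got {chain_length!r}"
        )
    if unsaturations < 0:
        raise InvalidInputError(
            f"unsaturations must be >= 0, got {unsaturations!r}"
        )
    if chain_length < _MIN_CALIBRATED_CHAIN_LENGTH:
        warnings.warn(
            f"chain_length={chain_length} is below the calibrated range "
            f"(N_L >= {_MIN_CALIBRATED_CHAIN_LENGTH:g}); cost is an extrapolation",
            ExtrapolationWarning,
            stacklevel=3,
        )


def _affine_cost(chain_length, unsaturations, base, per_carbon) -> float:
    cost = base + per_carbon * (chain_length - 16.0) + _UNSATURATION_COST * unsaturations
    if cost <= 0:
        raise DomainValidityError(
            f"cost model yields non-positive cost ({cost:g} ATP) at "
            f"N_L={chain_length}, N_U={unsaturations}; outside domain of validity"
        )
    return cost


def lipid_cost_total(
    chain_length: float, unsaturations: float, domain: "Domain | str"
) -> float:
    """Total (evolutionary) cost of one glycerophospholipid, in ATP.

    ``320 + 38(N_L - 16) + 6 N_U`` for bacteria and
    ``340 + 40(N_L - 16) + 6 N_U`` for eukaryotes, where ``N_L`` is the mean
    fatty-acid chain length and ``N_U`` the mean unsaturated carbons per chain.
    """
    _check_chain(chain_length, unsaturations)
    base, per_carbon = _TOTAL_CONSTANTS[_coerce_domain(domain)]
    return _affine_cost(chain_length, unsaturations, base, per_carbon)


def lipid_cost_reduced(
    chain_length: float, unsaturations: float, domain: "Domain | str"
) -> float:
    """Reduced (direct) cost of one glycerophospholipid, in ATP.

    Ignores the ATP-generating potential lost by diverting precursors:
    ``110 + 7(N_L - 16) + 6 N_U`` (bacteria), ``120 + 9(N_L - 16) + 6 N_U``
    (eukaryotes).
    """
    _check_chain(chain_length, unsaturations)
    base, per_carbon = _REDUCED_CONSTANTS[_coerce_domain(domain)]
    return _affine_cost(chain_length, unsaturations, base, per_carbon)


@dataclass(frozen=True)
class LipidSpecies:
    """One lipid class with its cost parameters.

    ``total_cost_override`` / ``reduced_cost_override`` short-circuit the
    chain-length formulas; they exist for lipids whose structure the
    two-chain glycerophospholipid model cannot represent (cardiolipin, with
    four acyl chains, is the shipped example).
    """

    name: str
    domain: Domain = Domain.BACTERIA
    chain_length: float = 16.0
    unsaturations: float = 0.0
    total_cost_override: Optional[float] = None
    reduced_cost_override: Optional[float] = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "domain", _coerce_domain(self.domain))
        if self.chain_length < 1:
            raise InvalidInputError("chain_length must be >= 1 carbon")
        if self.unsaturations < 0:
            raise InvalidInputError("unsaturations must be >= 0")
        for label, val in (
            ("total_cost_override", self.total_cost_override),
            ("reduced_cost_override", self.reduced_cost_override),
        ):
            if val is not None and val <= 0:
                raise InvalidInputError(f"{label} must be positive, got {val!r}")
        if (
            self.total_cost_override is not None
            and self.reduced_cost_override is not None
            and self.reduced_cost_override > self.total_cost_override
        ):
            raise InvalidInputError("reduced cost override exceeds total cost override")


#: Cardiolipin: four acyl chains, not representable by the two-chain formula,
#: so its published per-molecule costs are carried as explicit overrides.
CARDIOLIPIN = LipidSpecies(
    name="cardiolipin",
    domain=Domain.EUKARYOTE,
    chain_length=18.0,
    unsaturations=2.0,
    total_cost_override=640.0,
    reduced_cost_override=240.0,
)


def species_cost(lipid: LipidSpecies, reduced: bool = False) -> float:
    """Cost of one molecule of ``lipid``: the override when set, else the formula."""
    override = lipid.reduced_cost_override if reduced else lipid.total_cost_override
    if override is not None:
        return float(override)
    fn = lipid_cost_reduced if reduced else lipid_cost_total
    return fn(lipid.chain_length, lipid.unsaturations, lipid.domain)


@dataclass(frozen=True)
class MembraneComposition:
    """A membrane as (lipid species, mole fraction) pairs summing to one."""

    components: Sequence[tuple[LipidSpecies, float]] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        object.__setattr__(self, "components", tuple(self.components))
        fracs = [f for _, f in self.components]
        if any(f < 0 for f in fracs):
            raise InvalidInputError("mole fractions must be non-negative")
        if self.components and abs(sum(fracs) - 1.0) > 1e-9:
            raise InvalidInputError(
                f"mole fractions must sum to 1 (got {sum(fracs)!r})"
            )


def mean_membrane_cost(composition: MembraneComposition, reduced: bool = False) -> float:
    """Mole-fraction-weighted mean lipid cost of a membrane, in ATP/molecule."""
    if not composition.components:
        raise InvalidInputError("cannot average an empty membrane composition")
    return sum(f * species_cost(sp, reduced=reduced) for sp, f in composition.components)


@dataclass(frozen=True)
class MonomerCostTable:
    """Biosynthetic costs of the monomeric building blocks, in ATP equivalents."""

    amino_acid_cost: float = 30.0
    nucleotide_cost: float = 50.0
    atp_equiv_per_redox: float = 3.0

    def __post_init__(self) -> None:
        if min(self.amino_acid_cost, self.nucleotide_cost, self.atp_equiv_per_redox) <= 0:
            raise InvalidInputError("all monomer cost entries must be positive")


def atp_hydrolysis_share(redox_per_atp: float, atp_equiv_per_redox: float = 3.0) -> float:
    """Fraction of a biosynthetic energy budget paid directly by ATP hydrolysis.

    If a pathway performs ``redox_per_atp`` NADH/NADPH oxidations per ATP
    hydrolysis, and each oxidation is worth ``atp_equiv_per_redox`` ATP, the
    direct-ATP share of the total energy is
    ``1 / (1 + redox_per_atp * atp_equiv_per_redox)``.

    Amino-acid biosynthesis (~1.5 oxidations per hydrolysis) gives ~18%;
    lipid biosynthesis (~2.0) gives ~14%.
    """
    if redox_per_atp < 0:
        raise InvalidInputError("redox_per_atp must be >= 0")
    if atp_equiv_per_redox <= 0:
        raise InvalidInputError("atp_equiv_per_redox must be > 0")
    return 1.0 / (1.0 + redox_per_atp * atp_equiv_per_redox)
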