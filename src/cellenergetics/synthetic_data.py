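"""Synthetic cross-species trait tables with power-law structure.

Real cross-species compilations of cell volume, division time, membrane
areas, and molecular-machine counts follow allometric power laws with
multiplicative scatter.  This module generates pseudo-species tables with
exactly that structure — y = c·x^b with lognormal noise (Gaussian on the
log10 scale) and log-uniformly sampled volumes spanning several orders of
magnitude — so that the fitting and budget pipelines can be exercised and
calibrated without any external downloads.  Seeds are mandatory: every
generated dataset is reproducible by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InvalidInputError
from .scaling_fit import ScalingDataset

__all__ = [
    "PowerLawRelation",
    "GeneratorConfig",
    "DEFAULT_RELATIONS",
    "default_relations",
    "generate_power_law",
    "generate_species_table",
]


@dataclass(frozen=True)
class PowerLawRelation:
    """One trait's scaling law: trait = coefficient · V^exponent, with
    lognormal scatter of ``sd_log10`` decades."""

    trait: str
    coefficient: float
    exponent: float
    sd_log10: float = 0.2

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise InvalidInputError("coefficient must be > 0")
        if self.sd_log10 < 0:
            raise InvalidInputError("sd_log10 must be >= 0")


# Default generating relations, keyed by group.  Exponents and coefficients
# mirror published cross-species fits where one exists (mitochondrial area
# 3.0·V^0.99, ribosomes 7586·V^0.82, ATP synthases 113·S^1.26, division-time
# exponents −0.17 bacteria / +0.13 eukaryotes); division-time coefficients
# (1 h and 3 h at V = 1 μm³) are representative round numbers since only the
# exponents are published.  Plasma area derives from a sphere of equal
# volume, S = (36π)^(1/3)·V^(2/3).
_SPHERE_AREA_COEF = (36.0 * math.pi) ** (1.0 / 3.0)

DEFAULT_RELATIONS: dict[str, tuple[PowerLawRelation, ...]] = {
    "bacteria": (
        PowerLawRelation("division_time_h", 1.0, -0.17),
        PowerLawRelation("plasma_area_um2", _SPHERE_AREA_COEF, 2.0 / 3.0),
        PowerLawRelation("ribosomes_per_cell", 7586.0, 0.82),
    ),
    "eukaryote": (
        PowerLawRelation("division_time_h", 3.0, 0.13),
        PowerLawRelation("plasma_area_um2", _SPHERE_AREA_COEF, 2.0 / 3.0),
        PowerLawRelation("mito_total_um2", 3.0, 0.99),
        PowerLawRelation("ribosomes_per_cell", 7586.0, 0.82),
    ),
}

#: ATP synthase count scales with cell *surface area*, not volume.
ATP_SYNTHASE_VS_SURFACE = PowerLawRelation("atp_synthase_per_cell", 113.0, 1.26)

#: Volume spans (μm³) typical of each group's surveyed species.
DEFAULT_VOLUME_RANGES = {"bacteria": (0.03, 10.0), "eukaryote": (0.2, 2000.0)}

_EUKARYOTE_ONLY_TRAITS = {"mito_total_um2", "mito_outer_um2", "mito_inner_um2"}
#: inner:outer split used when emitting separate mitochondrial columns.
_INNER_OUTER_RATIO = 4.6


def default_relations(group: str) -> tuple[PowerLawRelation, ...]:
    try:
        return DEFAULT_RELATIONS[group]
    except KeyError as exc:
        raise ConfigurationError(f"unknown group {group!r}") from exc


@dataclass(frozen=True)
class GeneratorConfig:
    """Configuration of one synthetic species table.

    ``seed`` has no default on purpose: reproducibility is not optional.
    """

    seed: int
    group: str = "eukaryote"
    n_species: int = 50
    volume_range: Optional[tuple[float, float]] = None
    relations: Optional[Sequence[PowerLawRelation]] = None
    sd_log10: float = 0.2
    include_atp_synthase: bool = True

    def __post_init__(self) -> None:
        if self.group not in DEFAULT_RELATIONS:
            raise ConfigurationError(f"unknown group {self.group!r}")
        if self.n_species < 3:
            raise ConfigurationError("n_species must be >= 3")
        if self.sd_log10 < 0:
            raise ConfigurationError("sd_log10 must be >= 0")
        vr = self.volume_range or DEFAULT_VOLUME_RANGES[self.group]
        if not (vr[0] > 0 and vr[0] < vr[1]):
            raise ConfigurationError(f"invalid volume_range {vr!r}")
        object.__setattr__(self, "volume_range", (float(vr[0]), float(vr[1])))
        rels = tuple(self.relations) if self.relations is not None else default_relations(self.group)
        if self.group == "bacteria":
            offending = {r.trait for r in rels} & _EUKARYOTE_ONLY_TRAITS
            if offending:
                raise ConfigurationError(
                    f"eukaryote-only traits {sorted(offending)} requested for bacteria"
                )
        object.__setattr__(self, "relations", rels)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return 10.0 ** rng.uniform(math.log10(lo), math.log10(hi), size=n)


def generate_power_law(
    coefficient: float,
    exponent: float,
    sd_log10: float,
    n: int,
    x_range: tuple[float, float] = (0.1, 1000.0),
    seed: Optional[int] = None,
    name: str = "synthetic",
) -> ScalingDataset:
    """Simulate one allometric relation y = coefficient·x^exponent·10^ε.

    x is sampled log-uniformly on ``x_range`` and ε ~ Normal(0, sd_log10).
    A seed is required; the same seed always yields the same dataset.
    """
    if coefficient <= 0:
        raise InvalidInputError("coefficient must be > 0")
    if sd_log10 < 0:
        raise InvalidInputError("sd_log10 must be >= 0")
    if n < 3:
        raise InvalidInputError("n must be >= 3")
    if not (x_range[0] > 0 and x_range[0] < x_range[1]):
        raise InvalidInputError(f"invalid x_range {x_range!r}")
    if seed is None:
        raise InvalidInputError("a seed is required for reproducibility")
    rng = np.random.default_rng(seed)
    x = _log_uniform(rng, x_range[0], x_range[1], n)
    eps = rng.normal(0.0, sd_log10, size=n) if sd_log10 > 0 else np.zeros(n)
    y = coefficient * x**exponent * 10.0**eps
    return ScalingDataset(x=x, y=y, name=name)


def generate_species_table(config: GeneratorConfig) -> pd.DataFrame:
    """Generate a pseudo-species trait table.

    One row per species with columns ``species``, ``group``,
    ``cell_volume_um3``, plus one column per configured relation, all
    generated from the relation's power law in volume with multiplicative
    lognormal noise of ``config.sd_log10`` decades (a relation's own
    ``sd_log10`` is overridden by the config-level value only if the
    relation uses the class default).  ATP synthase counts scale with the
    generated plasma membrane area rather than with volume.  For
    eukaryotes the total mitochondrial area is also split into outer and
    inner columns using the default inner:outer ratio.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_species
    volumes = _log_uniform(rng, *config.volume_range, n)
    table = pd.DataFrame(
        {
            "species": [f"{config.group[:3]}_{i:03d}" for i in range(n)],
            "group": config.group,
            "cell_volume_um3": volumes,
        }
    )
    for rel in config.relations:
        sd = config.sd_log10
        eps = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        table[rel.trait] = rel.coefficient * volumes**rel.exponent * 10.0**eps
    if config.include_atp_synthase:
        if "plasma_area_um2" not in table:
            raise ConfigurationError(
                "atp_synthase_per_cell requires a plasma_area_um2 relation"
            )
        sd = config.sd_log10
        eps = rng.normal(0.0, sd, size=n) if sd > 0 else np.zeros(n)
        rel = ATP_SYNTHASE_VS_SURFACE
        table["atp_synthase_per_cell"] = (
            rel.coefficient * table["plasma_area_um2"] ** rel.exponent * 10.0**eps
        )
    if "mito_total_um2" in table:
        table["mito_outer_um2"] = table["mito_total_um2"] / (1.0 + _INNER_OUTER_RATIO)
        table["mito_inner_um2"] = table["mito_total_um2"] - table["mito_outer_um2"]
    return table
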