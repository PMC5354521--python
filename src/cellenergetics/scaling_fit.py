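"""Power-law fitting on log-log axes and algebra on fitted exponents.

Allometric relations y = c·x^b are fitted as ordinary least squares of
log10(y) on log10(x); the coefficient is 10^intercept and standard errors
are the usual OLS ones on the log10 scale.  Ratios and products of
power-law quantities compose by adding/subtracting exponents, with the
composite SE taken in quadrature under an independence assumption.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Optional, Sequence, Union

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import InsufficientDataError, InvalidInputError

__all__ = [
    "ScalingDataset",
    "PowerLawFit",
    "CombinedExponent",
    "fit_power_law",
    "fit_power_law_grouped",
    "combine_exponents",
    "predict",
]


@dataclass(frozen=True)
class ScalingDataset:
    """Paired positive measurements (x, y) with optional labels and groups."""

    x: np.ndarray
    y: np.ndarray
    labels: Optional[Sequence[str]] = None
    groups: Optional[Sequence[str]] = None
    name: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float))
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float))
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise InvalidInputError("x and y must be 1-D arrays of equal length")
        for attr in ("labels", "groups"):
            vals = getattr(self, attr)
            if vals is not None and len(vals) != len(self.x):
                raise InvalidInputError(f"{attr} length does not match data length")

    def __len__(self) -> int:
        return len(self.x)

    def label_of(self, i: int) -> str:
        return self.labels[i] if self.labels is not None else f"record {i}"

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        x: str,
        y: str,
        label: Optional[str] = None,
        group: Optional[str] = None,
        name: str = "",
    ) -> "ScalingDataset":
        sub = frame.dropna(subset=[x, y])
        return cls(
            x=sub[x].to_numpy(float),
            y=sub[y].to_numpy(float),
            labels=sub[label].tolist() if label else None,
            groups=sub[group].tolist() if group else None,
            name=name,
        )


@dataclass(frozen=True)
class PowerLawFit:
    """A fitted power law y = coefficient · x^exponent.

    Standard errors refer to the log10-scale regression: ``se_log_coefficient``
    is the SE of the intercept (log10 of the coefficient), ``se_exponent`` the
    SE of the slope.
    """

    coefficient: float
    exponent: float
    se_log_coefficient: float = 0.0
    se_exponent: float = 0.0
    r_squared: float = 1.0
    n: int = 0
    group_offsets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.coefficient <= 0:
            raise InvalidInputError("coefficient must be positive")
        if self.se_log_coefficient < 0 or self.se_exponent < 0:
            raise InvalidInputError("standard errors must be >= 0")

    def predict(self, x) -> "np.ndarray | float":
        return predict(self, x)

    def as_dict(self) -> dict:
        return {
            "coefficient": self.coefficient,
            "exponent": self.exponent,
            "se_log_coefficient": self.se_log_coefficient,
            "se_exponent": self.se_exponent,
            "r_squared": self.r_squared,
            "n": self.n,
        }


def _validated_logs(dataset: ScalingDataset) -> tuple[np.ndarray, np.ndarray]:
    bad = np.flatnonzero(~((dataset.x > 0) & (dataset.y > 0) &
                           np.isfinite(dataset.x) & np.isfinite(dataset.y)))
    if bad.size:
        names = ", ".join(dataset.label_of(int(i)) for i in bad[:10])
        raise InvalidInputError(
            f"power-law fitting requires positive finite x and y; offending: {names}"
        )
    if len(dataset) < 3:
        raise InsufficientDataError(
            f"need at least 3 observations to fit a power law, got {len(dataset)}"
        )
    return np.log10(dataset.x), np.log10(dataset.y)


def _as_dataset(data, y=None) -> ScalingDataset:
    if isinstance(data, ScalingDataset):
        return data
    if y is not None:
        return ScalingDataset(np.asarray(data, float), np.asarray(y, float))
    raise InvalidInputError("pass a ScalingDataset or two arrays (x, y)")


def fit_power_law(data, y=None) -> PowerLawFit:
    """Fit y = c·x^b by OLS of log10(y) on log10(x).

    Accepts a :class:`ScalingDataset` or two positional arrays.  Returns the
    coefficient on the natural scale (10^intercept), the exponent, both
    log10-scale standard errors, r² of the log-log regression, and n.
    """
    dataset = _as_dataset(data, y)
    lx, ly = _validated_logs(dataset)
    res = sm.OLS(ly, sm.add_constant(lx)).fit()
    intercept, slope = res.params
    se_int, se_slope = res.bse
    # Noiseless data: residual variance underflows and bse can be nan.
    if not np.isfinite(se_int):
        se_int = 0.0
    if not np.isfinite(se_slope):
        se_slope = 0.0
    r2 = float(res.rsquared)
    if not np.isfinite(r2):
        r2 = 1.0
    return PowerLawFit(
        coefficient=float(10.0**intercept),
        exponent=float(slope),
        se_log_coefficient=float(se_int),
        se_exponent=float(se_slope),
        r_squared=min(max(r2, 0.0), 1.0),
        n=len(dataset),
    )


def fit_power_law_grouped(dataset: ScalingDataset) -> PowerLawFit:
    """Common-exponent fit with per-group multiplicative offsets.

    Convenience for eyeballing prokaryote/eukaryote continuity: a shared
    slope with group-specific intercepts (returned as multiplicative factors
    relative to the first group, sorted alphabetically).  No test statistic
    is attached.
    """
    if dataset.groups is None:
        raise InvalidInputError("grouped fit requires dataset.groups")
    lx, ly = _validated_logs(dataset)
    groups = pd.Categorical(list(dataset.groups))
    dummies = pd.get_dummies(groups, drop_first=True, dtype=float)
    X = sm.add_constant(np.column_stack([lx, dummies.to_numpy()]))
    res = sm.OLS(ly, X).fit()
    offsets = {
        str(level): float(10.0 ** res.params[2 + i])
        for i, level in enumerate(dummies.columns)
    }
    base = str(groups.categories[0])
    offsets[base] = 1.0
    se = res.bse
    return PowerLawFit(
        coefficient=float(10.0 ** res.params[0]),
        exponent=float(res.params[1]),
        se_log_coefficient=float(se[0]) if np.isfinite(se[0]) else 0.0,
        se_exponent=float(se[1]) if np.isfinite(se[1]) else 0.0,
        r_squared=min(max(float(res.rsquared), 0.0), 1.0),
        n=len(dataset),
        group_offsets=offsets,
    )


class CombinedExponent(NamedTuple):
    exponent: float
    se: float


ExponentLike = Union[PowerLawFit, CombinedExponent, tuple, float, int]


def _exp_se(value: ExponentLike) -> tuple[float, float]:
    if isinstance(value, PowerLawFit):
        return value.exponent, value.se_exponent
    if isinstance(value, (tuple, list)) and len(value) == 2:
        exp, se = float(value[0]), float(value[1])
    else:
        exp, se = float(value), 0.0
    if se < 0:
        raise InvalidInputError("standard errors must be >= 0")
    return exp, se


def combine_exponents(
    a: ExponentLike, operation: str, b: ExponentLike
) -> CombinedExponent:
    """Exponent of a product or ratio of two power-law quantities.

    If y1 ∝ x^b1 and y2 ∝ x^b2 then y1·y2 ∝ x^(b1+b2) and y1/y2 ∝ x^(b1−b2).
    The SE of the composite exponent combines in quadrature,
    sqrt(se1² + se2²), assuming the two estimates are independent — e.g.
    growth cost ∝ V^0.97 over a division time ∝ V^−0.17 gives a per-cell
    biomass-rate exponent of 1.14 with SE sqrt(0.04² + 0.11²) ≈ 0.12.
    """
    ea, sa = _exp_se(a)
    eb, sb = _exp_se(b)
    if operation in ("multiply", "*"):
        exp = ea + eb
    elif operation in ("divide", "/"):
        exp = ea - eb
    else:
        raise InvalidInputError(f"operation must be 'multiply' or 'divide', got {operation!r}")
    return CombinedExponent(exp, float(np.hypot(sa, sb)))


def predict(fit: PowerLawFit, x) -> "np.ndarray | float":
    """Evaluate the fitted power law at ``x`` (> 0)."""
    arr = np.asarray(x, dtype=float)
    if np.any(~(arr > 0)):
        raise InvalidInputError("prediction requires x > 0")
    out = fit.coefficient * arr**fit.exponent
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out
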