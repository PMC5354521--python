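"""Budget laws, membrane costs, Eq-style compositions, and selection calculus."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellenergetics import energy_budget as eb
from cellenergetics.errors import InvalidInputError


def test_maintenance_rate_values():
    assert eb.maintenance_rate(1.0) == pytest.approx(0.39e9)
    assert eb.maintenance_rate(10.0) == pytest.approx(0.39e9 * 10**0.88, rel=1e-12)
    with pytest.raises(InvalidInputError):
        eb.maintenance_rate(0.0)


def test_growth_cost_values():
    assert eb.growth_cost(1.0) == pytest.approx(27e9)
    # independent log-space evaluation of 27e9 * 100^0.97
    expected = 10 ** (np.log10(27e9) + 0.97 * 2.0)
    assert eb.growth_cost(100.0) == pytest.approx(expected, rel=1e-12)
    assert expected == pytest.approx(2.35e12, rel=0.01)


@settings(derandomize=True, max_examples=40)
@given(v=st.floats(min_value=1e-2, max_value=1e4))
def test_growth_cost_homogeneity(v):
    assert eb.growth_cost(8 * v) / eb.growth_cost(v) == pytest.approx(8**0.97, rel=1e-10)


def test_total_cost_additive_and_linear_in_time():
    assert eb.total_cost(1.0, 0.0) == pytest.approx(27e9)
    assert eb.total_cost(1.0, 1.0) == pytest.approx(27.39e9)
    assert eb.total_cost(1.0, 10.0) == pytest.approx(30.9e9)
    # linearity: C_T(t1+t2) - C_T(t1) == t2 * C_M
    v = 3.7
    assert eb.total_cost(v, 5.0) - eb.total_cost(v, 2.0) == pytest.approx(
        3.0 * eb.maintenance_rate(v), rel=1e-12
    )
    with pytest.raises(InvalidInputError):
        eb.total_cost(1.0, -1.0)


def test_cell_budget_consistency():
    b = eb.cell_budget(eb.CellSpec(volume=2.0, division_time=4.0))
    assert b.total_cost == pytest.approx(b.growth_cost + 4.0 * b.maintenance_rate)


def test_membrane_lipid_cost_coefficient():
    # 2 / 6.5e-7 = 3.0769e6 lipids per um^2 of bilayer, printed as 3.1e6
    assert eb.membrane_lipid_cost(1.0, 1.0) == pytest.approx(2 / 6.5e-7)
    assert float(f"{eb.lipids_per_area():.2g}") == pytest.approx(3.1e6)


def test_membrane_lipid_cost_values():
    assert eb.membrane_lipid_cost(3.0, 440.0) == pytest.approx(4.0615e9, rel=1e-3)
    assert eb.membrane_lipid_cost(0.0, 440.0) == 0.0
    with pytest.raises(InvalidInputError):
        eb.membrane_lipid_cost(-1.0, 440.0)


def test_protein_area_fraction_discounts_lipids():
    full = eb.membrane_lipid_cost(2.0, 143.0)
    half = eb.membrane_lipid_cost(2.0, 143.0, protein_area_fraction=0.5)
    assert half == pytest.approx(0.5 * full)
    with pytest.raises(InvalidInputError):
        eb.lipids_per_area(protein_area_fraction=0.6)


def test_mito_relative_cost_at_unit_volume():
    val = eb.mito_membrane_relative_cost(1.0)
    assert val == pytest.approx(0.152, abs=0.002)  # reported as ~15%


def test_mito_relative_cost_scales_weakly():
    assert eb.mito_membrane_relative_cost(100.0) == pytest.approx(
        0.152 * 100**0.02, abs=0.003
    )
    # nearly flat: three decades of volume change the fraction by < 15%
    lo, hi = eb.mito_membrane_relative_cost(1.0), eb.mito_membrane_relative_cost(1000.0)
    assert abs(hi - lo) / lo < 0.15


@settings(derandomize=True, max_examples=40)
@given(v=st.floats(min_value=0.2, max_value=1e4))
def test_mito_relative_cost_is_the_explicit_composition(v):
    explicit = eb.membrane_lipid_cost(3.0 * v**0.99, 440.0) / eb.growth_cost(v)
    assert eb.mito_membrane_relative_cost(v) == pytest.approx(explicit, rel=1e-12)


@settings(derandomize=True, max_examples=40)
@given(v=st.floats(min_value=0.2, max_value=1e4))
def test_printed_shortcut_tracks_composition_within_one_percent(v):
    # 0.15 is a rounding of (3.0769e6*440*3.0)/27e9 = 0.1504
    assert eb.mito_membrane_relative_cost_approx(v) == pytest.approx(
        eb.mito_membrane_relative_cost(v), rel=0.01
    )


def test_relative_cost():
    assert eb.relative_cost(0.0, 5.0) == 0.0
    assert eb.relative_cost(5.0, 5.0) == 1.0
    assert eb.relative_cost(4.06e9, 27e9) == pytest.approx(0.150, abs=0.001)
    with pytest.raises(InvalidInputError):
        eb.relative_cost(1.0, 0.0)


@settings(derandomize=True, max_examples=50)
@given(
    total=st.floats(min_value=1e6, max_value=1e15),
    frac=st.floats(min_value=0, max_value=1),
)
def test_relative_cost_bounded_when_component_within_budget(total, frac):
    assert 0 <= eb.relative_cost(frac * total, total) <= 1


@pytest.mark.parametrize(
    "sa, sc, ne, ploidy, sn, thr, effective",
    [
        (0.02, 0.01, 1000, "haploid", 0.01, 1e-3, True),
        (0.01, 0.01, 1000, "haploid", 0.0, 1e-3, False),
        (0.0, 0.0004, 1000, "diploid", -0.0004, 5e-4, False),
    ],
)
def test_selection_outcome(sa, sc, ne, ploidy, sn, thr, effective):
    out = eb.selection_outcome(
        eb.SelectionContext(
            trait_cost_fraction=sc,
            trait_benefit=sa,
            effective_population_size=ne,
            ploidy=ploidy,
        )
    )
    assert out.net_selection == pytest.approx(sn)
    assert out.drift_threshold == pytest.approx(thr)
    assert out.effective is effective
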