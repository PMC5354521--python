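"""Lipid cost formulas, overrides, composition averaging, and redox shares."""

import itertools

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cellenergetics import cost_models as cm
from cellenergetics.errors import (
    DomainValidityError,
    ExtrapolationWarning,
    InvalidInputError,
)


@pytest.mark.parametrize(
    "nl, nu, domain, expected",
    [
        (16, 0, "bacteria", 320.0),
        (16, 0, "eukaryote", 340.0),
        (18, 1, "bacteria", 402.0),
        (14, 0, "bacteria", 244.0),
        (22, 6, "eukaryote", 616.0),
    ],
)
def test_total_cost_examples(nl, nu, domain, expected):
    assert cm.lipid_cost_total(nl, nu, domain) == pytest.approx(expected)


@pytest.mark.parametrize(
    "nl, nu, domain, expected",
    [
        (16, 0, "bacteria", 110.0),
        (16, 0, "eukaryote", 120.0),
        (22, 6, "eukaryote", 210.0),
    ],
)
def test_reduced_cost_examples(nl, nu, domain, expected):
    assert cm.lipid_cost_reduced(nl, nu, domain) == pytest.approx(expected)


def test_chain_length_validation():
    with pytest.raises(InvalidInputError):
        cm.lipid_cost_total(0, 0, "bacteria")
    with pytest.raises(InvalidInputError):
        cm.lipid_cost_total(16, -1, "bacteria")
    with pytest.raises(InvalidInputError):
        cm.lipid_cost_total(16, 0, "archaea")


def test_short_chains_warn_then_leave_validity_domain():
    with pytest.warns(ExtrapolationWarning):
        cm.lipid_cost_reduced(9, 0, "bacteria")
    with pytest.warns(ExtrapolationWarning):
        with pytest.raises(DomainValidityError):
            cm.lipid_cost_total(2, 0, "bacteria")


_GRID = list(itertools.product(range(14, 23), range(0, 7)))


def test_grid_properties_by_enumeration():
    """Over the biological (N_L, N_U) grid: reduced < total, eukaryote >=
    bacteria, and total costs stay inside the 244-616 ATP envelope."""
    totals = []
    for nl, nu in _GRID:
        for domain in ("bacteria", "eukaryote"):
            total = cm.lipid_cost_total(nl, nu, domain)
            reduced = cm.lipid_cost_reduced(nl, nu, domain)
            assert reduced < total
            totals.append(total)
        assert cm.lipid_cost_total(nl, nu, "eukaryote") >= cm.lipid_cost_total(nl, nu, "bacteria")
        assert cm.lipid_cost_reduced(nl, nu, "eukaryote") >= cm.lipid_cost_reduced(nl, nu, "bacteria")
    assert min(totals) == pytest.approx(244.0)
    assert max(totals) == pytest.approx(616.0)


@settings(derandomize=True, max_examples=60)
@given(
    nl=st.floats(min_value=10, max_value=26),
    nu=st.floats(min_value=0, max_value=6),
    dnl=st.floats(min_value=0.1, max_value=4),
    domain=st.sampled_from(["bacteria", "eukaryote"]),
)
def test_costs_strictly_increase_in_chain_length_and_unsaturation(nl, nu, dnl, domain):
    for fn in (cm.lipid_cost_total, cm.lipid_cost_reduced):
        assert fn(nl + dnl, nu, domain) > fn(nl, nu, domain)
        assert fn(nl, nu + 1, domain) > fn(nl, nu, domain)


def test_cardiolipin_overrides():
    assert cm.species_cost(cm.CARDIOLIPIN, reduced=False) == 640.0
    assert cm.species_cost(cm.CARDIOLIPIN, reduced=True) == 240.0


def test_species_cost_falls_through_to_formula():
    plain = cm.LipidSpecies("palmitoyl-PG", "bacteria", 16, 0)
    assert cm.species_cost(plain) == pytest.approx(320.0)
    assert cm.species_cost(plain, reduced=True) == pytest.approx(110.0)


def test_species_override_invariants():
    with pytest.raises(InvalidInputError):
        cm.LipidSpecies("bad", "bacteria", 16, 0, total_cost_override=-5)
    with pytest.raises(InvalidInputError):
        cm.LipidSpecies("bad", "bacteria", 16, 0,
                        total_cost_override=100, reduced_cost_override=200)


def test_mean_membrane_cost():
    sp = lambda c: cm.LipidSpecies(f"c{c}", "bacteria", 16, 0, total_cost_override=c)
    single = cm.MembraneComposition([(sp(440.0), 1.0)])
    assert cm.mean_membrane_cost(single) == pytest.approx(440.0)
    mix = cm.MembraneComposition([(sp(320.0), 0.5), (sp(400.0), 0.5)])
    assert cm.mean_membrane_cost(mix) == pytest.approx(360.0)
    with pytest.raises(InvalidInputError):
        cm.mean_membrane_cost(cm.MembraneComposition([]))


def test_composition_fraction_invariants():
    sp = cm.LipidSpecies("x", "bacteria", 16, 0)
    with pytest.raises(InvalidInputError):
        cm.MembraneComposition([(sp, 0.5), (sp, 0.6)])
    with pytest.raises(InvalidInputError):
        cm.MembraneComposition([(sp, -0.1), (sp, 1.1)])


def test_mitochondrial_reference_cost_constant():
    assert cm.MITO_MEAN_TOTAL_LIPID_COST == 440.0


@pytest.mark.parametrize(
    "redox, expected",
    [(1.5, 1 / 5.5), (2.0, 1 / 7.0), (0.0, 1.0)],
)
def test_atp_hydrolysis_share_examples(redox, expected):
    assert cm.atp_hydrolysis_share(redox, 3.0) == pytest.approx(expected)


@settings(derandomize=True, max_examples=50)
@given(
    r=st.floats(min_value=0, max_value=50),
    dr=st.floats(min_value=0.01, max_value=5),
    k=st.floats(min_value=0.1, max_value=10),
)
def test_atp_share_bounded_and_decreasing(r, dr, k):
    s = cm.atp_hydrolysis_share(r, k)
    assert 0 < s <= 1
    assert cm.atp_hydrolysis_share(r + dr, k) < s


def test_atp_share_rejects_negative_inputs():
    with pytest.raises(InvalidInputError):
        cm.atp_hydrolysis_share(-1, 3)
    with pytest.raises(InvalidInputError):
        cm.atp_hydrolysis_share(1.5, 0)
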