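"""Reaction kinetics: force, resistance, flux, and their invariants."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tkm import Modifier, Reaction, ResistanceSpec
from tkm.kinetics import flux, force, resistance

CAPS = {"a": 2e-3, "b": 5e-4, "c": 1e-3, "m": 1e-4}


def rxn(stoich, x=3, modifiers=()):
    kind = "regulated" if modifiers else "constant"
    return Reaction(
        id="R",
        stoich=stoich,
        resistance_spec=ResistanceSpec(kind, x, tuple(modifiers)),
    )


def test_force_simple():
    r = rxn({"a": -1, "b": 1})
    assert force(r, {"a": 2.0, "b": 0.5}) == pytest.approx(1.5)
    assert force(r, {"a": 1.0, "b": 1.0}) == 0.0
    # stoichiometric multiplicity enters as the exponent
    r2 = rxn({"a": -2, "b": 1})
    assert force(r2, {"a": 3.0, "b": 1.0}) == pytest.approx(8.0)


def test_force_rejects_negative_potential():
    r = rxn({"a": -1, "b": 1})
    with pytest.raises(ValueError):
        force(r, {"a": -0.1, "b": 1.0})


def test_resistance_value():
    r = rxn({"a": -1, "b": 1}, x=3)
    # R = 10^-x * C_a^-1, independent of potentials without modifiers
    assert resistance(r, {}, CAPS) == pytest.approx(1e-3 / CAPS["a"])
    r2 = rxn({"a": -2, "c": -1, "b": 1}, x=2)
    assert resistance(r2, {}, CAPS) == pytest.approx(
        1e-2 * CAPS["a"] ** -2 * CAPS["c"] ** -1
    )


def test_modifier_factors():
    inh = Modifier("m", "inhibitor", 0.5)
    act = Modifier("m", "activator", 0.5)
    assert inh.factor(0.5) == pytest.approx(2.0)
    assert act.factor(0.5) == pytest.approx(0.5)
    assert inh.factor(0.0) == 1.0 == act.factor(0.0)
    r_inh = rxn({"a": -1, "b": 1}, modifiers=[inh])
    r_act = rxn({"a": -1, "b": 1}, modifiers=[act])
    base = resistance(rxn({"a": -1, "b": 1}), {}, CAPS)
    assert resistance(r_inh, {"m": 1.0}, CAPS) == pytest.approx(3.0 * base)
    assert resistance(r_act, {"m": 1.0}, CAPS) == pytest.approx(base / 3.0)


def test_flux_sign_and_zero_enzyme():
    r = rxn({"a": -1, "b": 1})
    xi = {"a": 2.0, "b": 0.5}
    assert flux(r, xi, 1.0, CAPS) > 0
    assert flux(r, {"a": 0.5, "b": 2.0}, 1.0, CAPS) < 0
    assert flux(r, xi, 0.0, CAPS) == 0.0
    with pytest.raises(ValueError):
        flux(r, xi, -1.0, CAPS)


def test_enforced_flux_is_clamped():
    r = Reaction(id="D", stoich={"a": -1}, enforced_flux=2.5, exchange=True)
    assert r.is_enforced
    assert flux(r, {"a": 1e-9}, 0.0, CAPS) == 2.5


def test_quasi_equilibrium_has_no_resistance():
    r = Reaction(id="Q", stoich={"a": -1, "b": 1}, resistance_spec=ResistanceSpec("zero"))
    assert r.is_quasi_equilibrium
    with pytest.raises(ValueError):
        resistance(r, {}, CAPS)


@given(
    xi=st.lists(
        st.floats(min_value=1e-6, max_value=1e3), min_size=4, max_size=4
    ),
    stoich_a=st.integers(min_value=1, max_value=3),
    stoich_b=st.integers(min_value=1, max_value=3),
)
@settings(max_examples=200, deadline=None)
def test_flux_sign_matches_force_sign(xi, stoich_a, stoich_b):
    """Thermodynamic consistency: sign(J) = sign(F) for any potentials."""
    xa, xb, xc, xm = xi
    r = rxn(
        {"a": -stoich_a, "b": stoich_b},
        modifiers=[Modifier("m", "inhibitor", 0.3)],
    )
    pots = {"a": xa, "b": xb, "c": xc, "m": xm}
    f = force(r, pots)
    j = flux(r, pots, 1.0, CAPS)
    assert math.copysign(1.0, j) == math.copysign(1.0, f) or (j == 0.0 and f == 0.0)
    assert j * f >= 0.0
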