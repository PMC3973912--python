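"""Thermokinetic state primitives: capacities, potentials, corrections."""

import math

import pytest

from tkm import CapacityRangeError, ThermoContext, capacity, ionic_strength_correction
from tkm.thermo import concentration_of, potential_of


@pytest.fixture(scope="module")
def ctx():
    return ThermoContext()


def test_capacity_exponential_form(ctx):
    base = capacity(0.0, 0, 0.0, ctx)
    assert capacity(ctx.RT, 0, 0.0, ctx) == pytest.approx(base * math.exp(-1.0))
    assert capacity(-ctx.RT, 0, 0.0, ctx) == pytest.approx(base * math.exp(1.0))


def test_capacity_charge_and_potential(ctx):
    # positive charge moving into a negative-inside compartment is favored
    base = capacity(0.0, 0, -0.15, ctx)
    cation = capacity(0.0, 1, -0.15, ctx)
    anion = capacity(0.0, -1, -0.15, ctx)
    assert cation > base > anion
    # z*F*phi enters additively with mu0'
    assert cation == pytest.approx(capacity(ctx.F_const * (-0.15), 0, 0.0, ctx), rel=1e-12)


def test_capacity_range_error(ctx):
    with pytest.raises(CapacityRangeError):
        capacity(1e9, 0, 0.0, ctx)
    with pytest.raises(CapacityRangeError):
        capacity(-1e9, 0, 0.0, ctx)


def test_potential_concentration_roundtrip(ctx):
    C = capacity(-20000.0, -2, -0.15, ctx)
    for c in (1e-6, 1e-3, 0.5 * C, 2.0 * C):
        xi = potential_of(c, C)
        assert concentration_of(xi, C) == pytest.approx(c, rel=1e-14)
    assert potential_of(C, C) == pytest.approx(1.0)


def test_ionic_strength_correction(ctx):
    assert ionic_strength_correction(0, 0.25, ctx) == 0.0
    assert ionic_strength_correction(3, 0.0, ctx) == 0.0
    # negative shift (stabilization), quadratic in z
    one = ionic_strength_correction(1, 0.25, ctx)
    two = ionic_strength_correction(2, 0.25, ctx)
    assert one < 0
    assert two == pytest.approx(4.0 * one, rel=1e-12)
    with pytest.raises(ValueError):
        ionic_strength_correction(1, -0.1, ctx)
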