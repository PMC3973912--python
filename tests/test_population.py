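"""Growth law, maintenance, chemostat balances, moiety/quinone pools."""

import math

import pytest

from tkm import (
    ChemostatEnv,
    GrowthParams,
    MaintenanceParams,
    MoietyPolicy,
    QuinonePool,
    growth_rate,
    maintenance_rate,
    ramp,
)
from tkm.population import BiomassStoichiometry, chemostat_rhs, quinone_totals


def test_ramp_shape():
    assert ramp(0.5, 1.0, 3.0) == 0.0
    assert ramp(2.0, 1.0, 3.0) == pytest.approx(0.5)
    assert ramp(3.0, 1.0, 3.0) == 1.0
    assert ramp(10.0, 1.0, 3.0) == 1.0
    # smoothing keeps the value inside [0, 1] and close to the sharp ramp
    assert 0.0 <= ramp(1.0, 1.0, 3.0, eps=0.1) <= 0.1


def test_growth_rate_zero_below_ratio_window():
    bp = BiomassStoichiometry(nu={"a": 1.0})
    gp = GrowthParams(k_a=0.01, k_b=100.0, k_lo=1.0, k_hi=3.0)
    assert growth_rate({"a": 1e-3}, 0.5, bp, gp) == 0.0
    mid = growth_rate({"a": 1e-3}, 2.0, bp, gp)
    top = growth_rate({"a": 1e-3}, 5.0, bp, gp)
    assert 0 < mid < top
    assert top == pytest.approx(0.01 * (100.0 + math.log(1e-3)))


def test_growth_rate_increases_with_precursor():
    bp = BiomassStoichiometry(nu={"a": 2.0})
    gp = GrowthParams(k_a=0.01, k_b=100.0, k_lo=1.0, k_hi=3.0)
    lo = growth_rate({"a": 1e-4}, 5.0, bp, gp)
    hi = growth_rate({"a": 1e-3}, 5.0, bp, gp)
    assert hi > lo > 0


def test_maintenance_saturates_without_overdrive():
    mp = MaintenanceParams(max_rate=6.0, k_lo=0.3, k_hi=1.5)
    assert maintenance_rate(0.1, mp) == 0.0
    assert maintenance_rate(1.5, mp) == pytest.approx(6.0)
    assert maintenance_rate(50.0, mp) == pytest.approx(6.0)


def test_maintenance_overdrive_strictly_increasing_above_window():
    mp = MaintenanceParams(max_rate=6.0, k_lo=0.3, k_hi=1.5, overdrive=0.05)
    ratios = [1.5, 2.0, 5.0, 20.0, 100.0]
    vals = [maintenance_rate(r, mp) for r in ratios]
    assert vals == sorted(vals)
    assert all(b > a for a, b in zip(vals, vals[1:]))
    # overdrive slope is 5% of the in-window slope
    slope_in = (maintenance_rate(1.0, mp) - maintenance_rate(0.9, mp)) / 0.1
    slope_out = (maintenance_rate(10.1, mp) - maintenance_rate(10.0, mp)) / 0.1
    assert slope_out == pytest.approx(0.05 * slope_in, rel=1e-9)
    with pytest.raises(ValueError):
        MaintenanceParams(max_rate=6.0, k_lo=0.3, k_hi=1.5, overdrive=-0.1)


def test_chemostat_rhs_balances():
    env = ChemostatEnv(D=0.2, c_in={"s": 0.01}, k_out={"o2": 300.0},
                       aerobiosis=50.0, o2_id="o2", k_in_100=1e-2)
    dcx, dc = chemostat_rhs(
        c_X=0.5, mu=0.2, c={"s": 0.002, "o2": 1e-6},
        J={"s": -10.0, "o2": -5.0}, env=env, gas={"o2"},
    )
    assert dcx == 0.0  # mu = D
    # dissolved: D*(c_in - c) + J*c_X/1000
    assert dc["s"] == pytest.approx(0.2 * (0.01 - 0.002) - 10.0 * 0.5e-3)
    # gas: supply scales with aerobiosis fraction of k_in_100
    assert dc["o2"] == pytest.approx(
        -5.0 * 0.5e-3 + 0.5 * 1e-2 - 300.0 * 1e-6
    )


def test_quinone_totals_ramp_and_clamp():
    mp = MoietyPolicy(quinones=(
        QuinonePool("ubiquinone", "q8", "q8h2", 1e-4, 4e-6, dead_ox=1e-4),
        QuinonePool("menaquinone", "mqn8", "mql8", 4e-4, -3e-6, dead_ox=1e-4),
    ))
    t0 = quinone_totals(0.0, mp)
    t50 = quinone_totals(50.0, mp)
    t100 = quinone_totals(100.0, mp)
    t150 = quinone_totals(150.0, mp)
    # ubiquinone rises linearly with aerobiosis, menaquinone falls
    assert t0["ubiquinone"] == pytest.approx(1e-4)
    assert t50["ubiquinone"] == pytest.approx(1e-4 + 50 * 4e-6)
    assert t0["menaquinone"] > t50["menaquinone"] > t100["menaquinone"]
    # clamped beyond 100%
    assert t150 == t100
    assert min(t100.values()) > 0
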