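"""Comparison scaling, overlays, and production-curve bookkeeping."""

import numpy as np
import pandas as pd
import pytest

from tkm import limiting_precursor, overlay, scaling_factor
from tkm.assess import ProductionCurve


def test_scaling_factor_examples():
    xs = np.array([1.0, 2.0, 3.0])
    assert scaling_factor(xs, xs) == pytest.approx(1.0)
    assert scaling_factor(xs, 2.0 * xs) == pytest.approx(0.5)
    assert scaling_factor([1.0, 2.0], [2.0, 2.0]) == pytest.approx(5.0 / 6.0)


def test_scaling_factor_orthogonal_raises():
    with pytest.raises(ValueError):
        scaling_factor([1.0, 0.0], [0.0, 1.0])
    with pytest.raises(ValueError):
        scaling_factor([1.0, 2.0], [1.0, 2.0, 3.0])


def test_overlay_scales_relative_but_not_absolute():
    grid = [0.0, 50.0, 100.0]
    sim = pd.DataFrame({"a": grid, "c_x": [1.0, 2.0, 3.0], "J_v": [5.0, 4.0, 3.0]})
    data = pd.DataFrame({"a": grid, "c_x": [2.0, 4.0, 6.0], "J_v": [5.5, 4.5, 3.5]})
    rep = overlay(sim, data, on="a")
    per = rep.per_variable.set_index("variable")
    # relative variable: f = 0.5 makes the overlay exact
    assert per.loc["c_x", "f"] == pytest.approx(0.5)
    assert per.loc["c_x", "residual_norm"] == pytest.approx(0.0, abs=1e-12)
    # flux column compared directly
    assert per.loc["J_v", "f"] == 1.0
    assert not per.loc["J_v", "scaled"]
    np.testing.assert_allclose(rep.scaled_data["c_x"], sim["c_x"])


def test_overlay_reports_unmatched_grid_points():
    sim = pd.DataFrame({"a": [0.0, 50.0], "c_x": [1.0, 2.0]})
    data = pd.DataFrame({"a": [50.0, 75.0], "c_x": [2.0, 3.0]})
    rep = overlay(sim, data, on="a")
    assert rep.unmatched == [0.0, 75.0]
    assert list(rep.scaled_data["a"]) == [50.0]


def _curve(relative: dict[str, list[float]], species) -> ProductionCurve:
    n = len(next(iter(relative.values())))
    demand = np.linspace(0.0, 3.0, n)
    c_X = np.full(n, 0.25)
    return ProductionCurve(
        drain=" + ".join(species) + " ->",
        species=tuple(species),
        aerobic=False,
        demand=demand,
        productivity=demand * c_X,
        mu=np.full(n, 0.2),
        c_X=c_X,
        relative=pd.DataFrame(relative),
        outcomes=["steady"] * n,
    )


def test_limiting_precursor_picks_strongest_drop():
    curve = _curve({"a": [1.0, 0.9, 0.8], "b": [1.0, 0.5, 0.1]}, ("a", "b"))
    diag = limiting_precursor(curve)
    assert diag.limiting == ("b",)
    assert diag.drops["b"] == pytest.approx(0.1)
    assert diag.at_demand == pytest.approx(3.0)


def test_limiting_precursor_reports_ties():
    curve = _curve({"a": [1.0, 0.6, 0.2], "b": [1.0, 0.4, 0.2]}, ("a", "b"))
    diag = limiting_precursor(curve)
    assert set(diag.limiting) == {"a", "b"}


def test_curve_table_bookkeeping():
    curve = _curve({"a": [1.0, 0.9, 0.8]}, ("a",))
    df = curve.table()
    assert df["q_prod"].iloc[0] == 0.0
    np.testing.assert_allclose(df["q_prod"], df["J_prod"] * df["c_X"])
    assert df["rel_a"].iloc[0] == 1.0
    assert curve.q_max == pytest.approx(3.0 * 0.25)
    assert curve.demand_at_max == pytest.approx(3.0)
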