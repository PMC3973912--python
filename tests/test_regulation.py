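"""Transcription-factor activities, expression modifiers, enzyme balance."""

import pytest

from tkm import Gene, Regulator, TranscriptionFactor, tf_activity
from tkm.exprs import SignalExpression
from tkm.regulation import enzyme_rhs, expression_modifier, synthesis_rate


def tf(k=1e-6, n=2.0):
    return TranscriptionFactor("t", SignalExpression("s"), k_half=k, hill_n=n)


def test_tf_activity_half_point():
    assert tf_activity(1e-6, tf()) == pytest.approx(0.5)
    assert tf_activity(1e-6, tf(n=-4.0)) == pytest.approx(0.5)


def test_tf_activity_monotone_and_bounded():
    t_up, t_dn = tf(n=2.0), tf(n=-2.0)
    xs = [1e-9, 1e-7, 1e-6, 1e-5, 1e-3]
    up = [tf_activity(x, t_up) for x in xs]
    dn = [tf_activity(x, t_dn) for x in xs]
    assert all(0 < a < 1 for a in up + dn)
    assert up == sorted(up)
    assert dn == sorted(dn, reverse=True)


def test_tf_activity_no_overflow_at_extreme_signals():
    a = tf_activity(1e-300, tf(n=-8.0))
    assert 0 < a <= 1
    with pytest.raises(ValueError):
        tf_activity(0.0, tf())


def test_expression_modifier_closed_forms():
    for k in range(0, 6):
        assert expression_modifier(k, 0.0) == pytest.approx(2.0**-k)
        assert expression_modifier(k, 1.0) == 1.0
    assert expression_modifier(3, 0.0) == pytest.approx(0.125)
    with pytest.raises(ValueError):
        expression_modifier(2, 1.5)


def test_synthesis_rate_composition():
    g = Gene(
        id="g",
        basal_rate=0.2,
        regulators=(
            Regulator("act", "activator", 2),
            Regulator("inh", "inhibitor", 1),
        ),
    )
    # activator at a, inhibitor contributes with 1 - a
    rate = synthesis_rate(g, {"act": 1.0, "inh": 0.0})
    assert rate == pytest.approx(0.2)
    rate = synthesis_rate(g, {"act": 0.0, "inh": 0.0})
    assert rate == pytest.approx(0.2 * 0.25)
    rate = synthesis_rate(g, {"act": 1.0, "inh": 1.0})
    assert rate == pytest.approx(0.2 * 0.5)
    with pytest.raises(KeyError):
        synthesis_rate(g, {"act": 1.0})


def test_enzyme_steady_state_is_jsyn_over_mu():
    # dc_E/dt = J_syn - mu*c_E vanishes exactly at c_E = J_syn/mu
    J_syn, mu = 0.35, 0.2
    assert enzyme_rhs(J_syn / mu, J_syn, mu) == pytest.approx(0.0, abs=1e-15)
    assert enzyme_rhs(0.0, J_syn, mu) == pytest.approx(J_syn)
    with pytest.raises(ValueError):
        enzyme_rhs(-1.0, J_syn, mu)


def test_signal_expression_arithmetic():
    e = SignalExpression("(a+b)/(a+b+c)")
    assert e({"a": 1.0, "b": 1.0, "c": 2.0}) == pytest.approx(0.5)
    with pytest.raises(ValueError):
        SignalExpression("__import__('os')")
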