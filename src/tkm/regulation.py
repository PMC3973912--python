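"""Transcription-factor activities and gene-expression dynamics.

Transcription factor activity follows a phenomenological Hill law on a
metabolic signal x (a concentration or an arithmetic expression over
concentrations, e.g. the pep/pyr ratio for CRP or the quinol fraction for
ArcA):

    a_TF = x^n / (x^n + k^n),  a in (0, 1)

with n > 0 for activation by the signal and n < 0 for inhibition.  Each
regulator scales the synthesis rate of its target gene by

    s(k, a) = 2^-k + (1 - 2^-k) * a

so a single regulator spans a factor of 2^k between a = 0 and a = 1;
regulators combine multiplicatively, inhibitors enter with 1 - a.  Enzyme
concentrations follow synthesis minus growth dilution:

    dc_E/dt = J_syn - mu * c_E.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

from .exprs import SignalExpression

__all__ = [
    "TranscriptionFactor",
    "Regulator",
    "Gene",
    "EnzymeState",
    "tf_activity",
    "expression_modifier",
    "synthesis_rate",
    "enzyme_rhs",
]


@dataclass(frozen=True)
class TranscriptionFactor:
    """A transcription factor driven by one metabolic signal.

    ``signal`` is an arithmetic expression over metabolite concentrations
    (mol/l); ``k_half`` is the half-activation signal value in the same
    units; ``hill_n`` the (possibly negative) Hill exponent.
    """

    id: str
    signal: SignalExpression
    k_half: float
    hill_n: float

    def __post_init__(self) -> None:
        if self.k_half <= 0:
            raise ValueError(f"TF {self.id!r}: k_half must be positive")
        if self.hill_n == 0:
            raise ValueError(f"TF {self.id!r}: hill_n must be nonzero")

    def activity(self, concentrations: Mapping[str, float]) -> float:
        return tf_activity(self.signal(concentrations), self)


@dataclass(frozen=True)
class Regulator:
    """(transcription factor, mode, integer strength k) acting on a gene."""

    tf_id: str
    mode: Literal["activator", "inhibitor"]
    strength: int

    def __post_init__(self) -> None:
        if not isinstance(self.strength, int) or self.strength < 1:
            raise ValueError(
                f"regulation strength must be a positive integer, got {self.strength!r}"
            )
        if self.mode not in ("activator", "inhibitor"):
            raise ValueError(f"unknown regulator mode {self.mode!r}")


@dataclass(frozen=True)
class Gene:
    """A gene with a maximal synthesis rate and its regulators.

    ``basal_rate`` is J_syn,max in enzyme-concentration units per hour; the
    default of D (the dilution rate) for unregulated genes makes their
    steady-state enzyme concentration equal one.
    """

    id: str
    basal_rate: float
    regulators: tuple[Regulator, ...] = ()

    def __post_init__(self) -> None:
        if self.basal_rate <= 0:
            raise ValueError(f"gene {self.id!r}: basal_rate must be positive")


class EnzymeState(dict):
    """Mapping gene-id -> enzyme concentration (model units, >= 0)."""

    def __setitem__(self, key: str, value: float) -> None:
        if value < 0:
            raise ValueError(f"enzyme concentration for {key!r} negative: {value}")
        super().__setitem__(key, value)


def tf_activity(x: float, tf: TranscriptionFactor) -> float:
    """Hill activity a = x^n / (x^n + k^n), strictly inside (0, 1).

    Evaluated in log space so strongly negative exponents with small
    signals cannot overflow.
    """
    if x <= 0:
        raise ValueError(f"TF {tf.id!r}: signal must be positive, got {x}")
    import math

    # a = 1 / (1 + (k/x)^n) = logistic(n * log(x/k))
    t = tf.hill_n * (math.log(x) - math.log(tf.k_half))
    if t > 500:
        return 1.0 - 1e-16
    if t < -500:
        return 1e-16
    return 1.0 / (1.0 + math.exp(-t))


def expression_modifier(k: int, a: float) -> float:
    """Expression factor s(k, a) = 2^-k + (1 - 2^-k) * a."""
    if not 0 <= a <= 1:
        raise ValueError(f"activity must be in [0, 1], got {a}")
    w = 2.0**-k
    return w + (1.0 - w) * a


def synthesis_rate(gene: Gene, activities: Mapping[str, float]) -> float:
    """J_syn = basal_rate * prod_r s(k_r, a_r), inhibitors with 1 - a."""
    rate = gene.basal_rate
    for reg in gene.regulators:
        try:
            a = activities[reg.tf_id]
        except KeyError:
            raise KeyError(
                f"gene {gene.id!r}: unknown transcription factor {reg.tf_id!r}"
            ) from None
        if reg.mode == "inhibitor":
            a = 1.0 - a
        rate *= expression_modifier(reg.strength, a)
    return rate


def enzyme_rhs(c_E: float, J_syn: float, mu: float) -> float:
    """dc_E/dt = J_syn - mu * c_E (synthesis minus growth dilution)."""
    if c_E < 0:
        raise ValueError(f"enzyme concentration must be non-negative, got {c_E}")
    if mu < 0:
        raise ValueError(f"growth rate must be non-negative, got {mu}")
    return J_syn - mu * c_E
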