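"""Reactions, thermokinetic forces, resistances and fluxes.

A reaction with stoichiometry ``sum_i nu_ij * X_i`` (reactants negative)
carries the thermokinetic force

    F_j = prod_{reactants} xi_i^{|nu_ij|} - prod_{products} xi_i^{|nu_ij|}

and, for a finite resistance ``R_j`` and enzyme concentration ``c_E``, the
flux ``J_j = c_E * F_j / R_j``.  The resistance is tied to the forward rate
constant ``k_+j = 10^x`` (integer x) and the capacities of the reactant set
``E_j`` via ``R_j = k_+j^-1 * prod_{i in E_j} C_i^{-|nu_ij|}``; with this
parametrization the thermokinetic rate law is algebraically identical to
reversible mass action with forward constant ``c_E * k_+j`` and the
equilibrium constant implied by the formation energies.  A vanishing
resistance (kind ``zero``) declares the reaction quasi-equilibrium and is
handled as an algebraic constraint by the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Mapping

__all__ = [
    "Modifier",
    "ResistanceSpec",
    "Reaction",
    "FluxVector",
    "force",
    "resistance",
    "flux",
]


@dataclass(frozen=True)
class Modifier:
    """Multiplicative resistance modifier (1 + xi_m/theta)^(+1|-1).

    Activators (exponent -1) lower the resistance as the effector potential
    rises; inhibitors (exponent +1) raise it.  ``theta`` is the half-effect
    threshold in potential units.
    """

    metabolite: str
    role: Literal["activator", "inhibitor"]
    theta: float

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError(f"modifier threshold must be positive, got {self.theta}")
        if self.role not in ("activator", "inhibitor"):
            raise ValueError(f"unknown modifier role {self.role!r}")

    def factor(self, xi_m: float) -> float:
        base = 1.0 + xi_m / self.theta
        return base if self.role == "inhibitor" else 1.0 / base


@dataclass(frozen=True)
class ResistanceSpec:
    """Resistance specification of a reaction.

    kind
        ``constant``: R from ``log10_k_plus`` and reactant capacities.
        ``regulated``: same base value times the modifier terms.
        ``zero``: quasi-equilibrium; no finite resistance exists.
    log10_k_plus
        Integer exponent x with k_+ = 10^x (search-space restriction of the
        free kinetic parameters to decades).
    """

    kind: Literal["constant", "regulated", "zero"]
    log10_k_plus: int | None = None
    modifiers: tuple[Modifier, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("constant", "regulated", "zero"):
            raise ValueError(f"unknown resistance kind {self.kind!r}")
        if self.kind == "zero":
            if self.modifiers:
                raise ValueError("quasi-equilibrium reactions take no modifiers")
        else:
            if self.log10_k_plus is None:
                raise ValueError(f"{self.kind} resistance requires log10_k_plus")
            if not isinstance(self.log10_k_plus, int):
                raise ValueError(
                    f"log10_k_plus must be an integer, got {self.log10_k_plus!r}"
                )
        if self.kind == "constant" and self.modifiers:
            raise ValueError("constant resistance cannot carry modifiers")


@dataclass
class Reaction:
    """Stoichiometry over metabolites plus a resistance specification.

    ``stoich`` maps metabolite id to the signed coefficient nu_ij
    (reactants negative, products positive).  ``enforced_flux`` marks a
    drain/exchange reaction whose flux is clamped to a given value
    regardless of the potentials (used for production-capability
    assessment); such reactions have no resistance.
    """

    id: str
    stoich: dict[str, float]
    resistance_spec: ResistanceSpec | None = None
    enzyme_id: str | None = None
    enforced_flux: float | None = None
    exchange: bool = False

    def __post_init__(self) -> None:
        if any(v == 0 for v in self.stoich.values()):
            raise ValueError(f"reaction {self.id!r}: zero stoichiometric coefficient")
        if not self.stoich:
            raise ValueError(f"reaction {self.id!r}: empty stoichiometry")
        if self.enforced_flux is None and self.resistance_spec is None:
            raise ValueError(
                f"reaction {self.id!r}: needs a resistance spec or an enforced flux"
            )
        if not self.exchange and self.enforced_flux is None:
            if not self.reactants or not self.products:
                raise ValueError(
                    f"reaction {self.id!r}: needs at least one reactant and one "
                    "product (flag exchange reactions explicitly)"
                )

    @property
    def reactants(self) -> dict[str, float]:
        """Reactant set E_j with positive multiplicities |nu_ij|."""
        return {m: -v for m, v in self.stoich.items() if v < 0}

    @property
    def products(self) -> dict[str, float]:
        return {m: v for m, v in self.stoich.items() if v > 0}

    @property
    def is_quasi_equilibrium(self) -> bool:
        return self.resistance_spec is not None and self.resistance_spec.kind == "zero"

    @property
    def is_enforced(self) -> bool:
        return self.enforced_flux is not None


class FluxVector(dict):
    """Mapping reaction-id -> biomass-specific flux (mmol/gDCW/h)."""

    def __setitem__(self, key: str, value: float) -> None:
        if not math.isfinite(value):
            raise ValueError(f"flux for {key!r} must be finite, got {value}")
        super().__setitem__(key, value)


def _side_product(rxn: Reaction, side: Mapping[str, float], xi: Mapping[str, float]) -> float:
    out = 1.0
    for met, mult in side.items():
        try:
            x = xi[met]
        except KeyError:
            raise KeyError(
                f"reaction {rxn.id!r}: potential for metabolite {met!r} missing"
            ) from None
        if x < 0:
            raise ValueError(
                f"reaction {rxn.id!r}: negative potential for {met!r}: {x}"
            )
        out *= x**mult
    return out


def force(rxn: Reaction, xi: Mapping[str, float]) -> float:
    """Thermokinetic force F_j = prod xi_reactants - prod xi_products."""
    return _side_product(rxn, rxn.reactants, xi) - _side_product(rxn, rxn.products, xi)


def resistance(
    rxn: Reaction,
    xi: Mapping[str, float],
    capacities: Mapping[str, float],
) -> float:
    """Resistance R_j = k_+j^-1 * prod_{E_j} C_i^{-|nu|} * modifiers(xi)."""
    spec = rxn.resistance_spec
    if spec is None or spec.kind == "zero":
        raise ValueError(
            f"reaction {rxn.id!r}: quasi-equilibrium reaction has no finite resistance"
        )
    value = 10.0 ** (-spec.log10_k_plus)
    for met, mult in rxn.reactants.items():
        value *= capacities[met] ** (-mult)
    for mod in spec.modifiers:
        try:
            xi_m = xi[mod.metabolite]
        except KeyError:
            raise KeyError(
                f"reaction {rxn.id!r}: modifier metabolite {mod.metabolite!r} missing"
            ) from None
        value *= mod.factor(xi_m)
    if value <= 0 or not math.isfinite(value):
        raise ValueError(f"reaction {rxn.id!r}: resistance evaluated to {value}")
    return value


def flux(
    rxn: Reaction,
    xi: Mapping[str, float],
    c_E: float,
    capacities: Mapping[str, float],
) -> float:
    """Flux J_j = c_E * F_j / R_j in mmol/gDCW/h.

    Zero enzyme carries no flux; the sign of the flux equals the sign of
    the force (thermodynamic consistency).
    """
    if c_E < 0:
        raise ValueError(f"reaction {rxn.id!r}: negative enzyme concentration {c_E}")
    if rxn.is_enforced:
        return rxn.enforced_flux  # clamped drain, independent of xi
    f = force(rxn, xi)
    if c_E == 0.0:
        return 0.0
    return c_E * f / resistance(rxn, xi, capacities)
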