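"""Solution conditions, thermokinetic capacities and potentials.

The thermokinetic formalism replaces concentrations by dimensionless
potentials.  For metabolite ``i`` with transformed standard Gibbs formation
energy ``mu0_prime`` (J/mol), charge number ``z`` and compartment electrical
potential ``phi`` (V), the thermokinetic capacity is

    C_i = c_ref * exp(-(mu0_prime + z * F * phi) / (R * T))

and concentration and potential are related by ``c_i = C_i * xi_i``.  The
potential is the exponential of the chemical potential in units of ``R*T``,
so products/ratios of potentials directly encode reaction Gibbs energies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

__all__ = [
    "GAS_CONSTANT",
    "FARADAY",
    "ThermoContext",
    "Compartment",
    "Metabolite",
    "PotentialVector",
    "CapacityRangeError",
    "capacity",
    "ionic_strength_correction",
    "concentration_of",
    "potential_of",
]

#: Ideal gas constant R* (J/mol/K).
GAS_CONSTANT = 8.31446261815324

#: Faraday constant F (C/mol).
FARADAY = 96485.33212

#: Debye-Hueckel coefficient alpha at 298.15 K (kg^1/2 mol^-1/2), Alberty's
#: extended form with ion-size term 1.6 kg^1/2 mol^-1/2.
DEBYE_HUECKEL_ALPHA = 1.17582
DEBYE_HUECKEL_B = 1.6

#: Exponent bound beyond which exp() is treated as out of numeric range.
_EXP_LIMIT = 500.0


class CapacityRangeError(ValueError):
    """Raised when a capacity exponent leaves the representable range."""


@dataclass(frozen=True)
class ThermoContext:
    """Global physical constants and solution conditions.

    Parameters
    ----------
    T : float
        Temperature in K (constant).
    p : float
        Pressure in Pa; informational only, all energies are transformed.
    pH : float
        Cytoplasmic pH; the Legendre transform to constant pH is assumed to
        be folded into the supplied formation energies.
    I : float
        Ionic strength in mol/kg.
    a_H2O : float
        Water activity (dimensionless), likewise folded into the energies.
    c_ref : float
        Reference concentration c° in mol/l.
    """

    T: float = 310.15
    p: float = 101325.0
    pH: float = 7.0
    I: float = 0.25
    a_H2O: float = 1.0
    c_ref: float = 1.0
    R_star: float = GAS_CONSTANT
    F_const: float = FARADAY
    #: specific cytoplasmic volume (l per gDCW); converts biomass-specific
    #: fluxes (mmol/gDCW/h) into intracellular concentration changes.
    v_cell: float = 0.002

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError(f"temperature must be positive, got {self.T}")
        if self.c_ref <= 0:
            raise ValueError(f"reference concentration must be positive, got {self.c_ref}")
        if self.I < 0:
            raise ValueError(f"ionic strength must be non-negative, got {self.I}")

    @property
    def RT(self) -> float:
        """R* * T in J/mol."""
        return self.R_star * self.T


@dataclass(frozen=True)
class Compartment:
    """Named compartment with an electrical potential ``phi`` (V)."""

    name: str
    phi: float = 0.0


def ionic_strength_correction(z: int, I: float, ctx: ThermoContext) -> float:
    """Additive Debye-Hueckel correction to ``mu0_prime`` in J/mol.

    Uses Alberty's extended form ``RT*ln(gamma) = -RT*alpha*z^2*sqrt(I) /
    (1 + 1.6*sqrt(I))`` with ``alpha`` evaluated at 298.15 K.  Zero for
    uncharged species or zero ionic strength.
    """
    if I < 0:
        raise ValueError(f"ionic strength must be non-negative, got {I}")
    if z == 0 or I == 0:
        return 0.0
    sqrt_i = math.sqrt(I)
    return -ctx.RT * DEBYE_HUECKEL_ALPHA * z * z * sqrt_i / (1.0 + DEBYE_HUECKEL_B * sqrt_i)


def capacity(mu0_prime: float, z: int, phi: float, ctx: ThermoContext) -> float:
    """Thermokinetic capacity C = c_ref * exp(-(mu0' + z*F*phi)/(R*T)) in mol/l.

    Raises
    ------
    CapacityRangeError
        If the exponent magnitude exceeds the representable range.
    """
    exponent = -(mu0_prime + z * ctx.F_const * phi) / ctx.RT
    if abs(exponent) > _EXP_LIMIT:
        raise CapacityRangeError(
            f"capacity out of numeric range (exponent {exponent:.1f})"
        )
    return ctx.c_ref * math.exp(exponent)


def concentration_of(xi: float, C: float) -> float:
    """Concentration c = C * xi (mol/l) from a potential and a capacity."""
    if xi < 0:
        raise ValueError(f"thermokinetic potential must be non-negative, got {xi}")
    return C * xi


def potential_of(c: float, C: float) -> float:
    """Potential xi = c / C from a concentration and a capacity."""
    if c < 0:
        raise ValueError(f"concentration must be non-negative, got {c}")
    return c / C


@dataclass
class Metabolite:
    """A chemical species in a compartment.

    ``mu0_prime`` is the transformed standard Gibbs formation energy in
    J/mol at the context's conditions (constant T, pH, water activity,
    corrected for ionic strength).  ``z`` is the charge number of the
    dominant protonation state at pH 7.

    Flags
    -----
    external
        Species lives in the reactor medium and follows chemostat balances.
    gas
        External species exchanged via the gas phase (O2, CO2).
    fixed
        Clamped boundary species (e.g. protons at constant pH); excluded
        from all balances, concentration pinned to ``fixed_conc``.
    """

    id: str
    mu0_prime: float
    z: int = 0
    compartment: Compartment = field(default_factory=lambda: Compartment("cytoplasm"))
    external: bool = False
    gas: bool = False
    fixed: bool = False
    fixed_conc: float | None = None
    #: transferable carbon atoms of the skeleton (acyl carbons for thioesters;
    #: cofactor ring carbons are not counted because cofactor pools are kept
    #: by de-novo synthesis outside the carbon bookkeeping).
    carbons: int = 0
    #: typical physiological concentration (mol/l), used only as the
    #: solver's initial guess; None falls back to the capacity.
    guess: float | None = None

    def capacity(self, ctx: ThermoContext) -> float:
        """Thermokinetic capacity, recomputed from the current fields."""
        try:
            return capacity(self.mu0_prime, self.z, self.compartment.phi, ctx)
        except CapacityRangeError as exc:
            raise CapacityRangeError(f"metabolite {self.id!r}: {exc}") from exc

    def concentration(self, xi: float, ctx: ThermoContext) -> float:
        return concentration_of(xi, self.capacity(ctx))

    def potential(self, c: float, ctx: ThermoContext) -> float:
        return potential_of(c, self.capacity(ctx))


class PotentialVector(dict):
    """Mapping metabolite-id -> thermokinetic potential (dimensionless, >= 0).

    A thin ``dict`` subclass that validates entries on insertion.
    """

    def __setitem__(self, key: str, value: float) -> None:
        if not math.isfinite(value) or value < 0:
            raise ValueError(
                f"potential for {key!r} must be finite and non-negative, got {value}"
            )
        super().__setitem__(key, value)

    @classmethod
    def from_concentrations(
        cls, conc: dict[str, float], capacities: dict[str, float]
    ) -> "PotentialVector":
        out = cls()
        for met, c in conc.items():
            out[met] = potential_of(c, capacities[met])
        return out
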