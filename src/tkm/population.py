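"""Biomass formation, maintenance, conserved moieties and the chemostat.

Growth converts a fixed stoichiometric bundle of twelve-precursor-level
metabolites plus ATP, NADPH and NAD into one gram of dry cell weight.  The
specific growth rate follows linlog kinetics in the reactant
concentrations, gated by a ramp in the ATP/ADP ratio (no growth below a
threshold energy charge, saturation above a second threshold).
Maintenance is an uncoupled ATP->ADP hydrolysis with its own ramp.

Conserved-moiety pools (adenylates, NAD(H), NADP(H), CoA) are held at a
constant total concentration by a de-novo synthesis flux mu*total into the
least-phosphorylated / most-oxidized member, exactly offsetting growth
dilution.  Quinone pool totals are affine functions of the aerobiosis
value, clamped above 100%; a constant non-reactive pool of oxidized
quinones accounts for the observation that part of the pool stays oxidized
even anaerobically.

The chemostat supplies medium at dilution rate D; gases exchange with the
head space via a supply rate k_in (for oxygen proportional to aerobiosis)
and an outgassing constant k_out.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

__all__ = [
    "ramp",
    "BiomassStoichiometry",
    "GrowthParams",
    "MaintenanceParams",
    "ChemostatEnv",
    "QuinonePool",
    "MoietyPool",
    "MoietyPolicy",
    "growth_rate",
    "maintenance_rate",
    "chemostat_rhs",
    "quinone_totals",
    "moiety_synthesis_flux",
]


def ramp(x: float, lo: float, hi: float, eps: float = 0.0) -> float:
    """Piecewise-linear ramp: 0 below lo, linear on [lo, hi], 1 above hi.

    ``eps`` > 0 applies a C1 smoothstep of that half-width (in x units) at
    both kinks, for use by continuation solvers; the default is the exact
    piecewise-linear form.
    """
    if hi <= lo:
        raise ValueError(f"ramp needs lo < hi, got [{lo}, {hi}]")
    t = (x - lo) / (hi - lo)
    if eps > 0.0:
        e = eps / (hi - lo)
        # smooth max(0, min(1, t)) with quadratic blends of half-width e
        t = _smooth_clip(t, e)
        return t
    return min(1.0, max(0.0, t))


def _smooth_clip(t: float, e: float) -> float:
    """C1 approximation of clip(t, 0, 1) with quadratic blending."""
    if t <= -e:
        low = 0.0
    elif t >= e:
        low = t
    else:
        low = (t + e) ** 2 / (4.0 * e)
    t = low
    u = 1.0 - t
    if u <= -e:
        return 1.0 - 0.0
    if u >= e:
        return 1.0 - u
    return 1.0 - (u + e) ** 2 / (4.0 * e)


@dataclass(frozen=True)
class GrowthParams:
    """Linlog growth with an ATP/ADP ramp.

    mu = ramp(atp/adp; k_lo, k_hi) * max(0, k_a * (k_b + sum_i nu_i ln c_i))

    k_a in 1/h sets the rate scale, k_b the dimensionless linlog offset,
    and [k_lo, k_hi] the adenylate-ratio window between no growth and
    saturation.
    """

    k_a: float
    k_b: float
    k_lo: float
    k_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.k_lo < self.k_hi:
            raise ValueError(f"need 0 < k_lo < k_hi, got {self.k_lo}, {self.k_hi}")
        if self.k_a <= 0:
            raise ValueError(f"k_a must be positive, got {self.k_a}")


@dataclass(frozen=True)
class MaintenanceParams:
    """Non-growth ATP hydrolysis: rate = max_rate * ramp(atp/adp).

    ``overdrive`` > 0 lets the rate keep rising above the ramp's
    saturation point at that fraction of the in-window slope, modeling
    futile ATP cycling that grows with the energy charge.  This keeps
    the hydrolysis a strictly increasing function of the adenylate
    ratio, so an ATP surplus always finds a finite steady ratio instead
    of running away once the ramp clamps.
    """

    max_rate: float  # mmol ATP/gDCW/h at ramp saturation
    k_lo: float
    k_hi: float
    overdrive: float = 0.0

    def __post_init__(self) -> None:
        if not 0 < self.k_lo < self.k_hi:
            raise ValueError(f"need 0 < k_lo < k_hi, got {self.k_lo}, {self.k_hi}")
        if self.max_rate < 0:
            raise ValueError(f"max_rate must be non-negative, got {self.max_rate}")
        if self.overdrive < 0:
            raise ValueError(f"overdrive must be non-negative, got {self.overdrive}")


@dataclass
class BiomassStoichiometry:
    """Precursor demands and byproduct releases per gram dry cell weight.

    ``nu`` maps precursor id -> mmol consumed per gDCW; ``byproducts``
    maps product id -> mmol released per gDCW.  Moiety closure (CoA
    release equals the acyl-CoA demand, ADP release equals the ATP demand,
    and so on) is checked against the model's pool definitions at load
    time rather than against hard-coded ids.
    """

    nu: dict[str, float]
    byproducts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for met, v in {**self.nu, **self.byproducts}.items():
            if v < 0:
                raise ValueError(f"biomass coefficient for {met!r} negative: {v}")

    @property
    def stoich(self) -> dict[str, float]:
        """Signed stoichiometry (mmol/gDCW): reactants negative."""
        out = {m: -v for m, v in self.nu.items() if v != 0}
        for m, v in self.byproducts.items():
            if v != 0:
                out[m] = out.get(m, 0.0) + v
        return out

    def carbon_per_gram(self, carbons: Mapping[str, int]) -> float:
        """Net mmol skeleton carbon fixed into 1 gDCW."""
        c = sum(v * carbons.get(m, 0) for m, v in self.nu.items())
        c -= sum(v * carbons.get(m, 0) for m, v in self.byproducts.items())
        return c


@dataclass
class ChemostatEnv:
    """Dilution rate, inflow medium and gas exchange.

    ``k_in_100`` holds the calibrated oxygen supply rate (mol/l/h) at 100%
    aerobiosis; the actual supply is affine in the aerobiosis value,
    ``k_in_O2 = aerobiosis/100 * k_in_100``.  Other gases may carry a
    constant ``k_in``.
    """

    D: float
    c_in: dict[str, float] = field(default_factory=dict)  # mol/l
    k_out: dict[str, float] = field(default_factory=dict)  # 1/h per gas
    k_in: dict[str, float] = field(default_factory=dict)  # mol/l/h per gas
    aerobiosis: float = 0.0
    o2_id: str | None = None
    k_in_100: float | None = None

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"dilution rate must be positive, got {self.D}")
        for gas, k in self.k_out.items():
            if k <= 0:
                raise ValueError(f"outgassing constant for {gas!r} must be positive")
        if self.aerobiosis < 0:
            raise ValueError(f"aerobiosis must be non-negative, got {self.aerobiosis}")

    def gas_supply(self, gas: str) -> float:
        """k_in for a gas species (mol/l/h) at the current aerobiosis."""
        if gas == self.o2_id:
            base = self.k_in.get(gas, 0.0)
            if self.k_in_100 is None:
                return base
            return base + self.aerobiosis / 100.0 * self.k_in_100
        return self.k_in.get(gas, 0.0)


@dataclass(frozen=True)
class QuinonePool:
    """Aerobiosis-dependent quinone pool (oxidized + reduced member).

    total(a) = intercept + slope * min(a, 100), constant above 100%
    aerobiosis.  ``dead_ox`` is a constant non-reactive oxidized pool that
    is reported in totals and redox states but takes part in no reaction.
    """

    name: str
    ox: str
    red: str
    intercept: float  # mol/l at 0% aerobiosis
    slope: float  # mol/l per aerobiosis %
    dead_ox: float = 0.0

    def __post_init__(self) -> None:
        if self.dead_ox < 0:
            raise ValueError(f"pool {self.name!r}: dead pool must be non-negative")
        for a in (0.0, 100.0):
            if self.intercept + self.slope * a < 0:
                raise ValueError(
                    f"pool {self.name!r}: negative total at {a}% aerobiosis"
                )

    def total(self, aerobiosis: float) -> float:
        if aerobiosis < 0:
            raise ValueError(f"aerobiosis must be non-negative, got {aerobiosis}")
        return self.intercept + self.slope * min(aerobiosis, 100.0)


@dataclass(frozen=True)
class MoietyPool:
    """A conserved pool held at a fixed total concentration.

    De-novo synthesis injects mu*total into ``inject`` (the
    least-phosphorylated / most-oxidized member), balancing dilution.
    """

    name: str
    members: tuple[str, ...]
    total: float  # mol/l
    inject: str

    def __post_init__(self) -> None:
        if self.total <= 0:
            raise ValueError(f"pool {self.name!r}: total must be positive")
        if self.inject not in self.members:
            raise ValueError(
                f"pool {self.name!r}: injection species {self.inject!r} not a member"
            )


@dataclass
class MoietyPolicy:
    """All conserved-moiety and quinone-pool definitions of a model."""

    pools: tuple[MoietyPool, ...] = ()
    quinones: tuple[QuinonePool, ...] = ()

    def pool_of(self, met: str) -> MoietyPool | None:
        for p in self.pools:
            if met in p.members:
                return p
        return None


def growth_rate(
    c: Mapping[str, float],
    ratio: float,
    bp: BiomassStoichiometry,
    gp: GrowthParams,
    eps: float = 0.0,
) -> float:
    """Specific growth rate mu (1/h) from precursor concentrations (mol/l)
    and the ATP/ADP ratio."""
    s = gp.k_b
    for met, nu in bp.nu.items():
        ci = c[met]
        if ci <= 0:
            raise ValueError(f"biomass reactant {met!r} has nonpositive concentration")
        s += nu * math.log(ci)
    lin = gp.k_a * s
    if eps > 0.0:
        # smooth max(0, lin) so continuation solvers keep a gradient at
        # the growth shut-off; exact outside a half-width of eps (1/h)
        if lin <= -eps:
            lin = 0.0
        elif lin < eps:
            lin = (lin + eps) ** 2 / (4.0 * eps)
    else:
        lin = max(0.0, lin)
    return ramp(ratio, gp.k_lo, gp.k_hi, eps) * lin


def maintenance_rate(ratio: float, mp: MaintenanceParams, eps: float = 0.0) -> float:
    """Maintenance ATP hydrolysis rate (mmol ATP/gDCW/h)."""
    if ratio < 0:
        raise ValueError(f"ATP/ADP ratio must be non-negative, got {ratio}")
    rate = ramp(ratio, mp.k_lo, mp.k_hi, eps)
    if mp.overdrive > 0.0:
        t = (ratio - mp.k_hi) / (mp.k_hi - mp.k_lo)
        e = eps / (mp.k_hi - mp.k_lo) if eps > 0.0 else 0.0
        if e > 0.0 and -e < t < e:
            t = (t + e) ** 2 / (4.0 * e)  # C1 hinge, matches ramp smoothing
        rate += mp.overdrive * max(0.0, t)
    return mp.max_rate * rate


def chemostat_rhs(
    c_X: float,
    mu: float,
    c: Mapping[str, float],
    J: Mapping[str, float],
    env: ChemostatEnv,
    gas: frozenset[str] | set[str] = frozenset(),
) -> tuple[float, dict[str, float]]:
    """Chemostat balances.

    Returns (dc_X/dt, {species: dc/dt}) with concentrations in mol/l and
    specific exchange rates J in mmol/gDCW/h (positive = production by the
    biomass).  Dissolved species flow in and out with the medium; gas
    species are exchanged with the head space instead.
    """
    dcx = (mu - env.D) * c_X
    out: dict[str, float] = {}
    for met, ci in c.items():
        prod = J.get(met, 0.0) * c_X * 1e-3  # mmol/l/h -> mol/l/h
        if met in gas:
            out[met] = prod + env.gas_supply(met) - env.k_out[met] * ci
        else:
            out[met] = prod + env.D * (env.c_in.get(met, 0.0) - ci)
    return dcx, out


def quinone_totals(aerobiosis: float, mp: MoietyPolicy) -> dict[str, float]:
    """Reactive pool totals (mol/l) of all quinone pools at an aerobiosis value."""
    return {q.name: q.total(aerobiosis) for q in mp.quinones}


def moiety_synthesis_flux(mu: float, total: float) -> float:
    """De-novo synthesis flux mu * total balancing growth dilution.

    Units follow the ``total`` argument: a pool size in mmol/gDCW yields a
    biomass-specific flux in mmol/gDCW/h; a concentration total (mol/l)
    yields a concentration rate (mol/l/h).
    """
    if mu < 0:
        raise ValueError(f"growth rate must be non-negative, got {mu}")
    return mu * total
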