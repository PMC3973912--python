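"""Production-capability assessment and comparison with relative data.

A production demand is imposed as an enforced drain reaction (arbitrary
stoichiometry, e.g. ``2 accoa + 4 nadh -> 2 coa + 4 nad`` for a lumped
butanol pathway); the chemostat is re-solved at each demand level J_prod
and the volumetric productivity q_prod = J_prod * c_X is recorded.  The
assessment sweeps the demand upward with continuation until the culture
can no longer sustain it, refining the grid near the collapse point, and
reports the maximum productivity together with the drained species whose
relative depletion is largest (the limiting precursor).

Aeration during an assessment is frozen in absolute terms: the aerobic
regime uses a fixed oxygen supply (by default 1.6x the calibrated 100%
supply of the undisturbed culture, so the undisturbed case sits at 160%
aerobiosis), because the aerobiosis of the perturbed culture shifts as
the biomass concentration changes.

Comparison with relative measurement data (e.g. relative metabolite
levels) uses one positive scaling factor per variable, chosen to minimise
||(1/f) x_s - x_m||^2; the closed form is f = (x_s.x_s)/(x_m.x_s).
Absolute variables (fluxes, biomass, yields) are compared directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modelfile import ModelDocument, add_drain_reaction, parse_stoichiometry
from .simulate import dc_replace_env
from .solve import solve_steady_state
from .system import SteadyState, assemble

__all__ = [
    "scaling_factor",
    "overlay",
    "OverlayReport",
    "ProductionCurve",
    "production_assessment",
    "limiting_precursor",
    "LimitingPrecursor",
    "assessment_table",
]


def scaling_factor(x_sim, x_meas) -> float:
    """Least-squares factor f minimising ||(1/f) x_sim - x_meas||^2.

    The optimum over g = 1/f is g = (x_s . x_m)/(x_s . x_s), hence
    f = (x_s . x_s)/(x_m . x_s).  f is positive whenever the vectors are
    positively correlated; an exactly orthogonal pair has no optimum and
    raises.
    """
    xs = np.asarray(x_sim, dtype=float)
    xm = np.asarray(x_meas, dtype=float)
    if xs.shape != xm.shape or xs.ndim != 1 or xs.size < 1:
        raise ValueError("inputs must be equal-length vectors")
    denom = float(xs @ xm)
    if denom == 0.0:
        raise ValueError("vectors are orthogonal; no scaling factor exists")
    return float(xs @ xs) / denom


@dataclass
class OverlayReport:
    """Result of overlaying measured data onto a simulated table.

    ``per_variable`` has one row per compared variable (its factor f,
    whether it was scaled, and the residual norm against the simulation);
    ``scaled_data`` holds the measured values multiplied by their f, ready
    to plot on the simulation's absolute axes; ``unmatched`` lists grid
    points present in only one of the two tables (excluded from the
    comparison).
    """

    per_variable: pd.DataFrame
    scaled_data: pd.DataFrame
    unmatched: list


def overlay(
    sim: pd.DataFrame,
    data: pd.DataFrame,
    on: str,
    absolute: tuple[str, ...] = ("J_", "c_X", "mu", "yield"),
) -> OverlayReport:
    """Compare a measured table against a simulated one.

    Both tables must share the grid column ``on``; every other common
    column is a compared variable.  Relative variables (typically
    metabolite levels) get their own scaling factor; variables whose name
    starts with one of the ``absolute`` prefixes are compared directly
    (f = 1).  Grid points present in only one table are excluded and
    reported, never silently dropped.
    """
    if on not in sim.columns or on not in data.columns:
        raise ValueError(f"both tables need the grid column {on!r}")
    common_grid = sorted(set(sim[on]) & set(data[on]))
    unmatched = sorted(set(sim[on]).symmetric_difference(set(data[on])))
    variables = [c for c in data.columns if c != on and c in sim.columns]
    if not variables:
        return OverlayReport(
            pd.DataFrame(columns=["variable", "f", "scaled", "residual_norm"]),
            pd.DataFrame({on: common_grid}),
            unmatched,
        )
    s = sim[sim[on].isin(common_grid)].sort_values(on)
    m = data[data[on].isin(common_grid)].sort_values(on)
    rows = []
    out = {on: np.asarray(common_grid, dtype=float)}
    for var in variables:
        xs = s[var].to_numpy(dtype=float)
        xm = m[var].to_numpy(dtype=float)
        is_abs = any(var.startswith(p) for p in absolute)
        if is_abs:
            f, flagged = 1.0, False
        else:
            try:
                f, flagged = scaling_factor(xs, xm), False
            except ValueError:
                f, flagged = 1.0, True
        scaled = f * xm
        rows.append(
            {
                "variable": var,
                "f": f,
                "scaled": not is_abs and not flagged,
                "orthogonal": flagged,
                "residual_norm": float(np.linalg.norm(xs - scaled)),
            }
        )
        out[var] = scaled
    return OverlayReport(pd.DataFrame(rows), pd.DataFrame(out), unmatched)


@dataclass
class ProductionCurve:
    """Result of a production-capability assessment.

    ``demand`` is the grid of enforced specific production fluxes J_prod
    (mmol/gDCW/h); ``productivity`` the volumetric q_prod = J_prod * c_X
    (mmol/l/h).  ``relative`` holds the tracked species' concentrations
    normalised to the undisturbed (J_prod = 0) state, so every curve
    starts at 1.
    """

    drain: str
    species: tuple[str, ...]  # drained (consumed) species
    aerobic: bool
    demand: np.ndarray
    productivity: np.ndarray
    mu: np.ndarray
    c_X: np.ndarray
    relative: pd.DataFrame
    outcomes: list[str]
    states: list[SteadyState] = field(repr=False, default_factory=list)

    @property
    def q_max(self) -> float:
        ok = [q for q, o in zip(self.productivity, self.outcomes) if o == "steady"]
        return float(max(ok)) if ok else float("nan")

    @property
    def demand_at_max(self) -> float:
        best, arg = -np.inf, float("nan")
        for d, q, o in zip(self.demand, self.productivity, self.outcomes):
            if o == "steady" and q > best:
                best, arg = q, float(d)
        return arg

    def table(self) -> pd.DataFrame:
        """One row per grid point: J_prod, c_X, q_prod, relative species."""
        base = self.c_X[0] if len(self.c_X) and self.c_X[0] > 0 else np.nan
        df = pd.DataFrame(
            {
                "J_prod": self.demand,
                "c_X": self.c_X,
                "c_X_rel": self.c_X / base,
                "q_prod": self.productivity,
                "mu": self.mu,
                "outcome": self.outcomes,
            }
        )
        for met in self.relative.columns:
            df[f"rel_{met}"] = self.relative[met].to_numpy()
        return df


def _walk_oxygen(sys, env, tol: float, depth_max: int = 8) -> SteadyState:
    """Continuation in absolute O2 supply from the anaerobic state of the
    same system up to the supply encoded in ``env``."""
    k_target = env.aerobiosis / 100.0 * (env.k_in_100 or 0.0)
    env0 = dc_replace_env(env, "aerobiosis", 0.0)
    state = solve_steady_state(sys, env=env0, tol=tol)
    if state.outcome != "steady":
        return state

    def walk(k_from: float, st: SteadyState, k_to: float, depth: int):
        e = dc_replace_env(env, "aerobiosis", 100.0)
        e.k_in_100 = k_to
        nxt = solve_steady_state(sys, env=e, guess=st, tol=tol)
        if nxt.outcome == "steady" or depth >= depth_max:
            return nxt
        mid = 0.5 * (k_from + k_to)
        sm = walk(k_from, st, mid, depth + 1)
        if sm.outcome != "steady":
            return sm
        return walk(mid, sm, k_to, depth + 1)

    return walk(0.0, state, k_target, 0)


def _aerobic_env(doc: ModelDocument, factor: float = 1.6):
    """Frozen fully-aerobic condition: absolute O2 supply ``factor`` times
    the calibrated 100% supply of the undisturbed culture."""
    if not doc.chemostat.k_in_100:
        raise ValueError("model oxygen supply is not calibrated (k_in_100 unset)")
    env = dc_replace_env(doc.chemostat, "aerobiosis", 100.0)
    env.k_in_100 = factor * doc.chemostat.k_in_100
    return env


def production_assessment(
    doc: ModelDocument,
    drain: str,
    aerobic: bool = False,
    demand_max: float = 8.0,
    n_points: int = 9,
    refine_rounds: int = 3,
    aeration_factor: float = 1.6,
    track: tuple[str, ...] = (),
    # near-equilibrium reactions carry gross one-way fluxes up to ~100x
    # the net flux; their floating-point cancellation puts the residual
    # noise floor near 1e-9, so assessments accept 1e-8
    tol: float = 1e-8,
) -> ProductionCurve:
    """Sweep an enforced drain and map the production capability.

    ``drain`` is a stoichiometry string written with ``->`` whose flux is
    clamped to each grid value in turn.  The demand grid starts at
    [0, demand_max] and is extended upward (doubling) while the culture
    still sustains the highest demand, then refined by bisection between
    the last sustained and the first failed demand for ``refine_rounds``
    rounds.  The undisturbed (J_prod = 0) point must converge; its
    concentrations normalise all reported relative values.

    ``track`` adds species to the reported relative-concentration table on
    top of the drained ones.
    """
    stoich, arrow = parse_stoichiometry(drain)
    if arrow != "->":
        raise ValueError(f"drain must be written with '->', got {arrow!r}")
    drained = tuple(m for m, v in stoich.items() if v < 0)
    tracked = drained + tuple(m for m in track if m not in drained)
    env = _aerobic_env(doc, aeration_factor) if aerobic else dc_replace_env(
        doc.chemostat, "aerobiosis", 0.0
    )

    results: dict[float, SteadyState] = {}

    def solve_at(demand: float, guess):
        model = add_drain_reaction(doc, drain, demand)
        sys = assemble(model)
        st = solve_steady_state(sys, env=env, guess=guess, tol=tol)
        if st.outcome != "steady" and guess is None and aerobic:
            # cold start at high aeration: walk the oxygen supply up
            # from the anaerobic state by continuation
            st = _walk_oxygen(sys, env, tol)
        return st

    grid = list(np.linspace(0.0, demand_max, n_points))
    prev = None
    for d in grid:
        st = solve_at(d, prev)
        results[d] = st
        if st.outcome == "steady":
            prev = st
        else:
            break
    if results[0.0].outcome != "steady":
        raise RuntimeError("undisturbed (zero-demand) steady state did not converge")
    # extend upward while everything is sustained
    sustained = [d for d, s in results.items() if s.outcome == "steady"]
    extensions = 0
    while sustained and max(sustained) == max(results) and extensions < 6:
        d = 2.0 * max(results)
        st = solve_at(d, results[max(sustained)])
        results[d] = st
        extensions += 1
        if st.outcome == "steady":
            sustained.append(d)
        else:
            break
    # refine the collapse edge
    for _ in range(refine_rounds):
        ok = sorted(d for d, s in results.items() if s.outcome == "steady")
        bad = sorted(d for d, s in results.items() if s.outcome != "steady")
        edge_bad = [b for b in bad if ok and b > ok[-1]]
        if not ok or not edge_bad:
            break
        mid = 0.5 * (ok[-1] + edge_bad[0])
        results[mid] = solve_at(mid, results[ok[-1]])

    demands = sorted(results)
    states = [results[d] for d in demands]
    base = results[0.0]
    rel = pd.DataFrame(
        {
            met: [
                s.concentrations.get(met, np.nan) / base.concentrations[met]
                if s.outcome == "steady"
                else np.nan
                for s in states
            ]
            for met in tracked
        }
    )
    return ProductionCurve(
        drain=drain,
        species=drained,
        aerobic=aerobic,
        demand=np.array(demands),
        productivity=np.array(
            [d * s.c_X if s.c_X > 0 else 0.0 for d, s in zip(demands, states)]
        ),
        mu=np.array([s.mu for s in states]),
        c_X=np.array([s.c_X for s in states]),
        relative=rel,
        outcomes=[s.outcome for s in states],
        states=states,
    )


@dataclass(frozen=True)
class LimitingPrecursor:
    """Diagnosis of a production curve's limiting precursor.

    ``limiting`` lists every drained species whose relative drop ties for
    the largest (usually one; ties are reported explicitly rather than
    broken arbitrarily).  ``drops`` maps each drained species to its
    concentration at the last converged point relative to the undisturbed
    state (small = strongly depleted).
    """

    limiting: tuple[str, ...]
    drops: dict[str, float]
    at_demand: float


def limiting_precursor(curve: ProductionCurve) -> LimitingPrecursor:
    """Drained species with the largest relative concentration drop at the
    last converged point of the curve."""
    idx = [i for i, o in enumerate(curve.outcomes) if o == "steady"]
    if not idx:
        raise ValueError("curve contains no converged states")
    last = idx[-1]
    drops = {
        met: float(curve.relative[met].iloc[last]) for met in curve.species
    }
    if not drops:
        raise ValueError("drain consumes no species; nothing can be limiting")
    worst = min(drops.values())
    limiting = tuple(
        m for m, r in drops.items() if np.isclose(r, worst, rtol=1e-9, atol=0.0)
    )
    return LimitingPrecursor(limiting, drops, float(curve.demand[last]))


def assessment_table(curves: list[ProductionCurve]) -> pd.DataFrame:
    """Summary table across assessed drains and aeration regimes."""
    rows = []
    for c in curves:
        diag = limiting_precursor(c)
        rows.append(
            {
                "drain": c.drain,
                "regime": "aerobic" if c.aerobic else "anaerobic",
                "q_max": c.q_max,
                "demand_at_max": c.demand_at_max,
                "limiting": "+".join(diag.limiting),
                "n_points": len(c.demand),
            }
        )
    return pd.DataFrame(rows)
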