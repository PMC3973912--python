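"""Assembly of the reduced differential-algebraic system.

The full model couples fast metabolic reactions with slow gene expression
and reactor dynamics.  Reactions declared with zero resistance are treated
as quasi-equilibrium: their flux becomes an algebraic unknown and the
force balance ``F_j(xi) = 0`` (kept in log form, ``sum_i nu_ij ln xi_i =
0``, where it is linear in the solver variables) replaces the kinetic rate
law.  This is the standard index reduction for the formalism: the raw
system has index 2, the reduced one index 1.

State layout (chemostat mode)
-----------------------------
``u``      log potentials of balanced intracellular species
``w``      log concentrations of extracellular (liquid + gas) species
``J_qe``   fluxes of quasi-equilibrium reactions (mmol/gDCW/h)
``c_X``    biomass concentration (g/l)
``c_E``    enzyme concentrations (dynamic problems only; the steady-state
           problem substitutes c_E = J_syn / D analytically)

Residual units are chosen so all rows are O(1): intracellular balances in
mmol/gDCW/h, extracellular balances in mmol/l/h, quasi-equilibrium
constraints dimensionless, and the growth condition as (mu - D)/D.

Closed mode (no chemostat section) solves ``S J = 0`` for a reaction
network with optional clamped boundary species; balance rows made
redundant by conservation relations are replaced by the corresponding
pool-total constraints.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .kinetics import Reaction
from .modelfile import ModelDocument, ModelError
from .population import (
    ChemostatEnv,
    maintenance_rate,
    ramp,
)
from .regulation import synthesis_rate

__all__ = ["DAESystem", "SteadyState", "assemble"]


@dataclass
class SteadyState:
    """A solved steady state of the full model."""

    xi: dict[str, float]
    concentrations: dict[str, float]  # mol/l
    c_E: dict[str, float]
    a_TF: dict[str, float]
    J: dict[str, float]  # mmol/gDCW/h, incl. quasi-equilibrium fluxes
    mu: float
    c_X: float
    residual_norm: float
    outcome: str = "steady"  # steady | washout | failed
    diagnostics: dict = field(default_factory=dict)

    @property
    def converged(self) -> bool:
        return self.outcome in ("steady", "washout")

    def summary(self) -> str:
        lines = [
            f"outcome: {self.outcome}",
            f"mu = {self.mu:.6g} 1/h, c_X = {self.c_X:.6g} g/l",
            f"residual norm = {self.residual_norm:.3g}",
        ]
        return "\n".join(lines)


class DAESystem:
    """Vectorized residual evaluator for one model document."""

    def __init__(self, doc: ModelDocument):
        doc.validate()
        self.doc = doc
        self.mode = "chemostat" if doc.chemostat is not None else "closed"
        ctx = doc.context

        mets = list(doc.metabolites.values())
        self.met_ids = [m.id for m in mets]
        self.met_index = {m: i for i, m in enumerate(self.met_ids)}
        self.n_met = len(mets)
        self.capacity = np.array([m.capacity(ctx) for m in mets])
        self.log_capacity = np.log(self.capacity)
        self.carbons = np.array([float(m.carbons) for m in mets])

        self.fixed_mask = np.array([m.fixed for m in mets])
        self.fixed_conc = np.array(
            [m.fixed_conc if m.fixed else 0.0 for m in mets]
        )
        self.int_idx = np.array(
            [i for i, m in enumerate(mets) if not m.fixed and not m.external],
            dtype=int,
        )
        self.ext_idx = np.array(
            [i for i, m in enumerate(mets) if not m.fixed and m.external], dtype=int
        )
        self.gas_mask_ext = np.array(
            [mets[i].gas for i in self.ext_idx], dtype=bool
        )
        self.n_int = len(self.int_idx)
        self.n_ext = len(self.ext_idx)

        # reaction classification: kinetic / quasi-equilibrium / enforced
        rxns = list(doc.reactions.values())
        self.kin: list[Reaction] = [
            r for r in rxns if not r.is_quasi_equilibrium and not r.is_enforced
        ]
        self.qe: list[Reaction] = [r for r in rxns if r.is_quasi_equilibrium]
        self.enf: list[Reaction] = [r for r in rxns if r.is_enforced]
        self.rxn_order = [r.id for r in self.kin + self.qe + self.enf]
        self.n_kin, self.n_qe, self.n_enf = len(self.kin), len(self.qe), len(self.enf)
        n_rxn = self.n_kin + self.n_qe + self.n_enf

        # stoichiometric matrix (n_met x n_rxn)
        self.S = np.zeros((self.n_met, n_rxn))
        for j, r in enumerate(self.kin + self.qe + self.enf):
            for met, v in r.stoich.items():
                self.S[self.met_index[met], j] = v

        # reactant/product multiplicity matrices for kinetic + qe reactions
        self.R_mat = np.zeros((self.n_kin + self.n_qe, self.n_met))
        self.P_mat = np.zeros((self.n_kin + self.n_qe, self.n_met))
        for j, r in enumerate(self.kin + self.qe):
            for met, mult in r.reactants.items():
                self.R_mat[j, self.met_index[met]] = mult
            for met, mult in r.products.items():
                self.P_mat[j, self.met_index[met]] = mult

        # base resistances of kinetic reactions (modifier-free part)
        self.base_resistance = np.empty(self.n_kin)
        for j, r in enumerate(self.kin):
            spec = r.resistance_spec
            val = 10.0 ** (-spec.log10_k_plus)
            for met, mult in r.reactants.items():
                val *= self.capacity[self.met_index[met]] ** (-mult)
            self.base_resistance[j] = val
        self.modifiers = [
            [
                (self.met_index[m.metabolite], m.role, m.theta)
                for m in (r.resistance_spec.modifiers or ())
            ]
            for r in self.kin
        ]

        # genes / enzymes
        self.genes = list(doc.genes.values())
        self.gene_index = {g.id: i for i, g in enumerate(self.genes)}
        self.n_genes = len(self.genes)
        self.rxn_gene = np.array(
            [
                self.gene_index[r.enzyme_id] if r.enzyme_id is not None else -1
                for r in self.kin
            ],
            dtype=int,
        )
        self.tfs = list(doc.transcription_factors.values())

        # biomass stoichiometry vector over species (mmol/gDCW per gram grown)
        self.bio_vec = np.zeros(self.n_met)
        if doc.biomass is not None:
            for met, v in doc.biomass.stoich.items():
                self.bio_vec[self.met_index[met]] = v
        self.energy_couple = doc.energy_couple
        if self.energy_couple is not None:
            self.i_num = self.met_index[self.energy_couple[0]]
            self.i_den = self.met_index[self.energy_couple[1]]

        # maintenance stoichiometry: hydrolysis of the energy couple
        self.maint_vec = np.zeros(self.n_met)
        if doc.maintenance is not None and self.energy_couple is not None:
            self.maint_vec[self.i_num] = -1.0
            self.maint_vec[self.i_den] = +1.0

        # moiety de-novo synthesis: per pool, injection index and total(conc)
        self.pool_inject: list[tuple[int, float]] = [
            (self.met_index[p.inject], p.total) for p in doc.moieties.pools
        ]
        self.quinone_pools = list(doc.moieties.quinones)
        self.quinone_inject = [self.met_index[q.ox] for q in self.quinone_pools]

        self.v_cell = ctx.v_cell
        self._check_structure()

        # closed-mode conservation handling
        if self.mode == "closed":
            self._setup_conservation()

        self.n_state = (
            self.n_int + self.n_ext + self.n_qe + (1 if self.mode == "chemostat" else 0)
        )

    # ------------------------------------------------------------------
    def _check_structure(self) -> None:
        """The reduced system must be structurally solvable."""
        if self.n_qe:
            sub = self.S[np.concatenate([self.int_idx, self.ext_idx]), :][
                :, self.n_kin : self.n_kin + self.n_qe
            ]
            if np.linalg.matrix_rank(sub) < self.n_qe:
                names = ", ".join(r.id for r in self.qe)
                raise ModelError(
                    "structurally singular quasi-equilibrium reduction; dependent "
                    f"constraints among reactions: {names}"
                )
        if self.mode == "chemostat":
            doc = self.doc
            if doc.biomass is None or doc.growth is None:
                raise ModelError("chemostat mode requires a biomass section")
            if self.energy_couple is None:
                raise ModelError("growth ramp requires an energy couple (ratio line)")

    def _setup_conservation(self) -> None:
        """Replace redundant closed-system balances by pool constraints."""
        bal_idx = np.concatenate([self.int_idx, self.ext_idx]).astype(int)
        S_bal = self.S[bal_idx, : self.n_kin + self.n_qe]
        # left null space of the balanced stoichiometry
        u_svd, s_svd, _ = np.linalg.svd(S_bal)
        tol = max(S_bal.shape) * (s_svd[0] if len(s_svd) else 1.0) * 1e-12
        rank = int((s_svd > tol).sum())
        null_dim = S_bal.shape[0] - rank
        W = u_svd[:, rank:]  # (n_bal x null_dim)
        self.conservation = W.T  # rows: conserved combinations over bal_idx
        # each conservation row replaces the balance of its largest component
        replaced: list[int] = []
        for row in self.conservation:
            order = np.argsort(-np.abs(row))
            for k in order:
                if k not in replaced:
                    replaced.append(int(k))
                    break
        self.replaced_rows = np.array(replaced, dtype=int)
        self.bal_idx = bal_idx
        if null_dim and len(set(replaced)) < null_dim:
            raise ModelError("could not assign conservation constraints to balances")

    # ------------------------------------------------------------------
    # state packing helpers

    def pack(self, ln_xi_int, ln_c_ext, J_qe, c_X=None) -> np.ndarray:
        parts = [ln_xi_int, ln_c_ext, J_qe]
        if self.mode == "chemostat":
            parts.append([c_X])
        return np.concatenate([np.asarray(p, dtype=float) for p in parts])

    def unpack(self, y: np.ndarray):
        n_i, n_e, n_q = self.n_int, self.n_ext, self.n_qe
        u = y[:n_i]
        w = y[n_i : n_i + n_e]
        J_qe = y[n_i + n_e : n_i + n_e + n_q]
        c_X = y[n_i + n_e + n_q] if self.mode == "chemostat" else None
        return u, w, J_qe, c_X

    def log_xi_full(self, u: np.ndarray, w: np.ndarray) -> np.ndarray:
        """Log potentials of all species from the packed state."""
        ln_xi = np.zeros(self.n_met)
        ln_xi[self.int_idx] = u
        if self.n_ext:
            ln_xi[self.ext_idx] = w - self.log_capacity[self.ext_idx]
        if self.fixed_mask.any():
            ln_xi[self.fixed_mask] = (
                np.log(self.fixed_conc[self.fixed_mask])
                - self.log_capacity[self.fixed_mask]
            )
        return ln_xi

    # ------------------------------------------------------------------
    # physics

    def fluxes(
        self, ln_xi: np.ndarray, c_E: np.ndarray, J_qe: np.ndarray
    ) -> np.ndarray:
        """All reaction fluxes in declaration order [kinetic, qe, enforced]."""
        n_fq = self.n_kin + self.n_qe
        # clip the exponent so wild line-search trial points yield large
        # finite fluxes instead of overflow
        prod_r = np.exp(np.minimum(self.R_mat @ ln_xi, 600.0))
        prod_p = np.exp(np.minimum(self.P_mat @ ln_xi, 600.0))
        F = prod_r - prod_p
        J = np.empty(self.n_kin + self.n_qe + self.n_enf)
        if self.n_kin:
            R = self.base_resistance.copy()
            xi = np.exp(np.minimum(ln_xi, 600.0))
            for j, mods in enumerate(self.modifiers):
                for idx, role, theta in mods:
                    base = 1.0 + xi[idx] / theta
                    R[j] *= base if role == "inhibitor" else 1.0 / base
            if c_E is None or len(c_E) == 0:
                cE = np.ones(self.n_kin)
            else:
                cE = np.where(
                    self.rxn_gene >= 0, c_E[np.maximum(self.rxn_gene, 0)], 1.0
                )
            J[: self.n_kin] = cE * F[: self.n_kin] / R
        J[self.n_kin : n_fq] = J_qe
        for j, r in enumerate(self.enf):
            J[n_fq + j] = r.enforced_flux
        return J

    def qe_residual(self, ln_xi: np.ndarray) -> np.ndarray:
        """Quasi-equilibrium constraints sum_i nu_ij ln xi_i = 0 (log form)."""
        if not self.n_qe:
            return np.zeros(0)
        sub = self.P_mat[self.n_kin :] - self.R_mat[self.n_kin :]
        return sub @ ln_xi

    def concentrations(self, ln_xi: np.ndarray) -> np.ndarray:
        return np.exp(np.minimum(ln_xi + self.log_capacity, 600.0))

    def conc_mapping(self, c: np.ndarray) -> dict[str, float]:
        return dict(zip(self.met_ids, c.tolist()))

    def activities(self, c: np.ndarray) -> np.ndarray:
        env = self.conc_mapping(c)
        return np.array([tf.activity(env) for tf in self.tfs])

    def enzyme_synthesis(self, a: np.ndarray) -> np.ndarray:
        acts = {tf.id: ai for tf, ai in zip(self.tfs, a)}
        return np.array([synthesis_rate(g, acts) for g in self.genes])

    def growth_mu(self, c: np.ndarray, eps: float) -> float:
        doc = self.doc
        if doc.growth is None:
            return 0.0
        gp = doc.growth
        s = gp.k_b
        for met, nu in doc.biomass.nu.items():
            ci = c[self.met_index[met]]
            if ci <= 0:
                return 0.0
            s += nu * math.log(ci)
        ratio = c[self.i_num] / c[self.i_den]
        return ramp(ratio, gp.k_lo, gp.k_hi, eps) * max(0.0, gp.k_a * s)

    def maintenance(self, c: np.ndarray, eps: float) -> float:
        if self.doc.maintenance is None:
            return 0.0
        ratio = c[self.i_num] / c[self.i_den]
        return maintenance_rate(ratio, self.doc.maintenance, eps)

    def synthesis_injection(self, mu: float, aerobiosis: float) -> np.ndarray:
        """De-novo moiety synthesis as specific fluxes (mmol/gDCW/h)."""
        inj = np.zeros(self.n_met)
        scale = self.v_cell * 1e3  # conc (mol/l) -> specific pool (mmol/gDCW)
        for idx, total in self.pool_inject:
            inj[idx] += mu * total * scale
        for q, idx in zip(self.quinone_pools, self.quinone_inject):
            inj[idx] += mu * q.total(aerobiosis) * scale
        return inj

    # ------------------------------------------------------------------
    # steady-state residual

    def steady_residual(
        self,
        y: np.ndarray,
        env: ChemostatEnv | None = None,
        eps: float = 0.0,
        c0: np.ndarray | None = None,
        washout: bool = False,
    ) -> np.ndarray:
        if self.mode == "chemostat":
            return self._steady_chemostat(y, env or self.doc.chemostat, eps, washout)
        return self._steady_closed(y, c0)

    def _steady_chemostat(self, y, env, eps, washout):
        u, w, J_qe, c_X = self.unpack(y)
        ln_xi = self.log_xi_full(u, w)
        c = self.concentrations(ln_xi)
        a = self.activities(c)
        mu = self.growth_mu(c, eps)
        if washout:
            mu_dil = max(mu, 1e-6)
            c_X = 0.0
        else:
            mu_dil = env.D
        c_E = self.enzyme_synthesis(a) / mu_dil
        J = self.fluxes(ln_xi, c_E, J_qe)
        m = self.maintenance(c, eps)
        net = self.S @ J + self.bio_vec * mu + self.maint_vec * m
        net += self.synthesis_injection(mu, env.aerobiosis)
        # growth dilution of intracellular material, in specific-flux units
        dilution = mu * c * (self.v_cell * 1e3)
        r_int = net[self.int_idx] - dilution[self.int_idx]
        r_qe = self.qe_residual(ln_xi)
        # extracellular balances in mmol/l/h
        ce = c[self.ext_idx]
        je = net[self.ext_idx]  # biomass byproducts included
        r_ext = np.empty(self.n_ext)
        for k, i_ext in enumerate(self.ext_idx):
            met = self.met_ids[i_ext]
            if self.gas_mask_ext[k]:
                r_ext[k] = je[k] * c_X + 1e3 * (
                    env.gas_supply(met) - env.k_out[met] * ce[k]
                )
            else:
                r_ext[k] = je[k] * c_X + 1e3 * env.D * (
                    env.c_in.get(met, 0.0) - ce[k]
                )
        if washout:
            return np.concatenate([r_int, r_qe, r_ext])
        r_mu = np.array([(mu - env.D) / env.D])
        return np.concatenate([r_int, r_qe, r_ext, r_mu])

    def _steady_closed(self, y, c0):
        u, w, J_qe, _ = self.unpack(y)
        ln_xi = self.log_xi_full(u, w)
        c = self.concentrations(ln_xi)
        c_E = np.ones(self.n_genes)
        J = self.fluxes(ln_xi, c_E, J_qe)
        net = (self.S @ J)[self.bal_idx]
        if self.conservation.shape[0]:
            if c0 is None:
                raise ValueError("closed-mode solve requires initial concentrations c0")
            cons = self.conservation @ (c[self.bal_idx] - c0[self.bal_idx])
            # conservation rows are O(c); rescale to O(1)
            scale = np.abs(self.conservation) @ np.maximum(c0[self.bal_idx], 1e-300)
            net[self.replaced_rows] = cons / np.maximum(scale, 1e-300)
        return np.concatenate([net, self.qe_residual(ln_xi)])

    # ------------------------------------------------------------------
    # dynamic residual (index-1 DAE, used by the implicit-Euler fallback)

    def dynamic_state_size(self) -> int:
        n = self.n_int + self.n_ext + self.n_qe
        if self.mode == "chemostat":
            n += 1 + self.n_genes
        return n

    def pack_dynamic(self, y_steady: np.ndarray, c_E: np.ndarray) -> np.ndarray:
        if self.mode == "chemostat":
            return np.concatenate([y_steady, c_E])
        return y_steady

    def dynamic_residual(
        self, y: np.ndarray, y_prev: np.ndarray, h: float, env: ChemostatEnv | None,
        eps: float = 1e-3, c0: np.ndarray | None = None,
    ) -> np.ndarray:
        """Implicit-Euler residual over a step of length h (hours)."""
        if self.mode == "closed":
            u, w, J_qe, _ = self.unpack(y)
            up, wp, _, _ = self.unpack(y_prev)
            ln_xi = self.log_xi_full(u, w)
            c = self.concentrations(ln_xi)
            cp = self.concentrations(self.log_xi_full(up, wp))
            J = self.fluxes(ln_xi, np.ones(self.n_genes), J_qe)
            net = (self.S @ J)[self.bal_idx]
            dc = (c[self.bal_idx] - cp[self.bal_idx]) / h
            scale = np.maximum(np.abs(net), 1.0)
            rows = (dc - net) / scale
            return np.concatenate([rows, self.qe_residual(ln_xi)])

        env = env or self.doc.chemostat
        n_s = self.n_int + self.n_ext + self.n_qe + 1
        u, w, J_qe, c_X = self.unpack(y[:n_s])
        c_E = y[n_s:]
        up, wp, _, c_Xp = self.unpack(y_prev[:n_s])
        c_Ep = y_prev[n_s:]
        ln_xi = self.log_xi_full(u, w)
        c = self.concentrations(ln_xi)
        cp = self.concentrations(self.log_xi_full(up, wp))
        a = self.activities(c)
        mu = self.growth_mu(c, eps)
        J = self.fluxes(ln_xi, c_E, J_qe)
        m = self.maintenance(c, eps)
        net = self.S @ J + self.bio_vec * mu + self.maint_vec * m
        net += self.synthesis_injection(mu, env.aerobiosis)
        dilution = mu * c * (self.v_cell * 1e3)
        # intracellular: v_cell*1e3 * dc/dt = net - dilution   (mmol/g/h)
        dc_int = (c[self.int_idx] - cp[self.int_idx]) / h
        r_int = self.v_cell * 1e3 * dc_int - (net[self.int_idx] - dilution[self.int_idx])
        r_qe = self.qe_residual(ln_xi)
        r_ext = np.empty(self.n_ext)
        for k, i_ext in enumerate(self.ext_idx):
            met = self.met_ids[i_ext]
            dc = (c[i_ext] - cp[i_ext]) / h
            if self.gas_mask_ext[k]:
                rhs = net[i_ext] * c_X + 1e3 * (
                    env.gas_supply(met) - env.k_out[met] * c[i_ext]
                )
            else:
                rhs = net[i_ext] * c_X + 1e3 * env.D * (
                    env.c_in.get(met, 0.0) - c[i_ext]
                )
            r_ext[k] = 1e3 * dc - rhs
        r_x = np.array([(c_X - c_Xp) / h - (mu - env.D) * c_X])
        J_syn = self.enzyme_synthesis(a)
        r_E = (c_E - c_Ep) / h - (J_syn - mu * c_E)
        return np.concatenate([r_int, r_qe, r_ext, r_x, r_E])

    # ------------------------------------------------------------------
    # reporting

    def build_state(
        self,
        y: np.ndarray,
        env: ChemostatEnv | None,
        residual_norm: float,
        outcome: str = "steady",
        eps: float = 0.0,
        washout: bool = False,
        diagnostics: dict | None = None,
    ) -> SteadyState:
        u, w, J_qe, c_X = self.unpack(y)
        ln_xi = self.log_xi_full(u, w)
        c = self.concentrations(ln_xi)
        a = self.activities(c)
        mu = self.growth_mu(c, eps)
        if self.mode == "chemostat":
            env = env or self.doc.chemostat
            denom = env.D if not washout else max(mu, 1e-6)
            c_E = self.enzyme_synthesis(a) / denom
            if washout:
                c_X = 0.0
        else:
            c_E = np.ones(self.n_genes)
            c_X = 0.0
        J = self.fluxes(ln_xi, c_E, J_qe)
        flux_map = dict(zip(self.rxn_order, J.tolist()))
        m = self.maintenance(c, eps)
        if self.doc.maintenance is not None:
            flux_map["MAINTENANCE"] = m
        if self.doc.biomass is not None:
            flux_map["BIOMASS"] = mu
        return SteadyState(
            xi=dict(zip(self.met_ids, np.exp(ln_xi).tolist())),
            concentrations=self.conc_mapping(c),
            c_E={g.id: v for g, v in zip(self.genes, c_E.tolist())},
            a_TF={tf.id: v for tf, v in zip(self.tfs, a.tolist())},
            J=flux_map,
            mu=mu,
            c_X=float(c_X) if c_X is not None else 0.0,
            residual_norm=residual_norm,
            outcome=outcome,
            diagnostics=diagnostics or {},
        )


def assemble(doc: ModelDocument) -> DAESystem:
    """Validate a document and build its reduced DAE system."""
    return DAESystem(doc)
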