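"""Assembled DAE system: structural and steady-state invariants."""

import math

import numpy as np
import pytest
from scipy.linalg import null_space

from tkm import assemble, build_fixture, solve_closed, solve_steady_state


def test_assemble_core(core_doc):
    sys = assemble(core_doc)
    assert sys.mode == "chemostat"
    assert sys.n_met == len(core_doc.metabolites)
    assert sys.n_qe > 0 and sys.n_kin > 0


def test_wegscheider_cycle_consistency(core_doc):
    """Equilibrium constants derived from capacities are cycle-free.

    For every internal flux mode y (S y = 0 over balanced species),
    sum_j y_j ln K_j = 0: thermodynamic consistency is structural, not a
    tuned property.
    """
    caps = core_doc.capacities()
    mets = core_doc.balanced_metabolites
    idx = {m: i for i, m in enumerate(mets)}
    rxns = [r for r in core_doc.reactions.values() if not r.exchange]
    S = np.zeros((len(mets), len(rxns)))
    lnK = np.zeros(len(rxns))
    for j, r in enumerate(rxns):
        for met, nu in r.stoich.items():
            if met in idx:
                S[idx[met], j] = nu
            lnK[j] += nu * math.log(caps[met])
    cycles = null_space(S)
    assert cycles.shape[1] > 0  # the network does contain cycles
    assert np.max(np.abs(cycles.T @ lnK)) < 1e-8


def test_carbon_conserved_per_reaction(core_doc):
    carbons = {m.id: m.carbons for m in core_doc.metabolites.values()}
    for r in core_doc.reactions.values():
        if r.exchange:
            continue
        dc = sum(nu * carbons.get(met, 0) for met, nu in r.stoich.items())
        assert dc == 0, f"reaction {r.id} changes carbon by {dc}"


def test_anaerobic_steady_state(anaerobic_state, core_doc):
    st = anaerobic_state
    assert st.outcome == "steady"
    assert st.mu == pytest.approx(core_doc.chemostat.D, rel=1e-6)
    assert st.c_X > 0.1
    assert all(c > 0 for c in st.concentrations.values())
    # quasi-equilibrium constraints hold in log-potential space
    for r in core_doc.reactions.values():
        if r.resistance_spec is not None and r.resistance_spec.kind == "zero":
            res = sum(nu * math.log(st.xi[m]) for m, nu in r.stoich.items())
            assert abs(res) < 1e-10, f"QE constraint {r.id} violated: {res}"


def test_thermodynamic_consistency_at_steady_state(anaerobic_state, core_doc):
    from tkm.kinetics import force

    st = anaerobic_state
    for r in core_doc.reactions.values():
        if r.enforced_flux is not None or r.resistance_spec.kind == "zero":
            continue
        f = force(r, st.xi)
        assert st.J[r.id] * f >= 0.0, f"{r.id}: J*F < 0"


def test_moiety_pools_at_steady_state(anaerobic_state, core_doc):
    for pool in core_doc.moieties.pools:
        total = sum(anaerobic_state.concentrations[m] for m in pool.members)
        assert total == pytest.approx(pool.total, rel=1e-8)


def test_no_etc_variant_solves(core_doc):
    doc = build_fixture("core", include_etc=False)
    assert not doc.transcription_factors
    st = solve_steady_state(doc)
    assert st.outcome == "steady"
    assert st.mu == pytest.approx(0.2, rel=1e-6)


def test_solve_closed_toy(toy_doc):
    c0 = {m: 0.5 * c for m, c in toy_doc.capacities().items()}
    st = solve_closed(toy_doc, c0)
    assert st.outcome == "steady"
    # adenylate pool conserved from the initial condition
    pool = toy_doc.moieties.pools[0]
    total0 = sum(c0[m] for m in pool.members)
    total = sum(st.concentrations[m] for m in pool.members)
    assert total == pytest.approx(total0, rel=1e-9)
    # clamped boundary species sustain a throughput mode; internal
    # balances then tie the fluxes together exactly
    J = st.J
    assert J["UPT"] == pytest.approx(J["GLY"], rel=1e-6)  # g6p balance
    assert J["EXC"] == pytest.approx(2.0 * J["GLY"], rel=1e-6)  # pyr balance
    atp_balance = -J["UPT"] + 3.0 * J["GLY"] + J["EXC"] - J["ATPASE"]
    assert abs(atp_balance) < 1e-8
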