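"""Packaged model fixtures: a toy chain and a core central-metabolism model.

The core fixture is a deliberately small but closed model of E. coli
glucose metabolism under varying oxygen availability: PTS uptake,
glycolysis (rapid steps as quasi-equilibria), an oxidative
pentose-phosphate lump for NADPH and C5 precursors, the fermentation
branches (PFL/PDH, acetate, ethanol, formate), a TCA cycle that can run
branched (fumarate reductase on menaquinone) or cyclic (succinate
dehydrogenase on ubiquinone), an electron transport chain with two NADH
dehydrogenases and two terminal oxidases of different proton
stoichiometry, ATP synthase, transhydrogenase, explicit adenylate /
NAD(H) / NADP(H) / CoA pools and aerobiosis-dependent quinone pools, and
FNR/ArcA regulation of the fermentative and respiratory genes.

Transformed formation energies are not copied from tables; they are
assembled by least squares so that every reaction's standard Gibbs energy
matches a target value taken from standard biochemical data, with a weak
prior pulling each capacity towards a typical physiological
concentration.  This keeps all capacities in a numerically benign range,
makes the default initial guess (all potentials one) meaningful, and
guarantees Wegscheider consistency because all equilibrium constants
derive from one potential per species.  Proton species are clamped at
fixed concentrations on both sides of the membrane and carry the proton
motive force explicitly; translocation stoichiometries follow the
conventional H+/2e- numbers (4 for NADH dehydrogenase I and cytochrome
bo3, 2 for cytochrome bd, 4 H+ per ATP at the synthase).

Fixture generation is deterministic: no randomness anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import math

import numpy as np

from .exprs import SignalExpression
from .kinetics import Modifier, Reaction, ResistanceSpec
from .modelfile import ModelDocument, parse_stoichiometry
from .population import (
    BiomassStoichiometry,
    ChemostatEnv,
    GrowthParams,
    MaintenanceParams,
    MoietyPolicy,
    MoietyPool,
    QuinonePool,
)
from .regulation import Gene, Regulator, TranscriptionFactor
from .thermo import Compartment, Metabolite, ThermoContext

__all__ = ["FixtureSpec", "build_fixture"]


@dataclass(frozen=True)
class FixtureSpec:
    """What to generate: toy (4 reactions) or core (~34 reactions)."""

    scale: Literal["toy", "core"] = "core"
    include_regulation: bool = True
    include_etc: bool = True


# ---------------------------------------------------------------------------
# species tables: id -> (z, compartment, carbons, typical conc mol/l, flags)
# flags: "" cytoplasmic, "e" external, "g" external gas, "f" clamped

_PHI_CYT = -0.15  # V, cytoplasmic side vs. medium
_PH_CYT = 7.6
_PH_EXT = 7.0

_CORE_SPECIES = [
    # glycolysis / PPP
    ("g6p", -2, "c", 6, 2e-3, ""),
    ("f6p", -2, "c", 6, 5e-4, ""),
    ("fdp", -4, "c", 6, 3e-3, ""),
    ("dhap", -2, "c", 3, 1e-3, ""),
    ("g3p", -2, "c", 3, 1e-4, ""),
    ("3pg", -3, "c", 3, 1.5e-3, ""),
    ("pep", -3, "c", 3, 2e-4, ""),
    ("pyr", -1, "c", 3, 5e-4, ""),
    ("r5p", -2, "c", 5, 5e-4, ""),
    # acetyl-CoA node and fermentation
    ("accoa", -4, "c", 2, 5e-4, ""),
    ("coa", -4, "c", 0, 5e-4, ""),
    ("for", -1, "c", 1, 1e-2, ""),
    ("ac", -1, "c", 2, 1e-2, ""),
    # TCA
    ("cit", -3, "c", 6, 1e-3, ""),
    ("icit", -3, "c", 6, 1e-4, ""),
    ("akg", -2, "c", 5, 5e-4, ""),
    ("succoa", -5, "c", 4, 1e-4, ""),
    ("succ", -2, "c", 4, 5e-4, ""),
    ("fum", -2, "c", 4, 3e-4, ""),
    ("mal", -2, "c", 4, 1e-3, ""),
    ("oaa", -2, "c", 4, 1e-6, ""),
    # energy and redox carriers
    ("atp", -4, "c", 0, 3e-3, ""),
    ("adp", -3, "c", 0, 1e-3, ""),
    ("amp", -2, "c", 0, 3e-4, ""),
    ("nad", -1, "c", 0, 2e-3, ""),
    ("nadh", -2, "c", 0, 1e-4, ""),
    ("nadp", -3, "c", 0, 2e-4, ""),
    ("nadph", -4, "c", 0, 1e-4, ""),
    ("q8", 0, "c", 0, 1e-4, ""),
    ("q8h2", 0, "c", 0, 1e-4, ""),
    ("mqn8", 0, "c", 0, 1e-4, ""),
    ("mql8", 0, "c", 0, 1e-4, ""),
    # medium
    ("glc_e", 0, "e", 6, 1e-5, "e"),
    ("ac_e", -1, "e", 2, 5e-3, "e"),
    ("etoh_e", 0, "e", 2, 5e-3, "e"),
    ("for_e", -1, "e", 1, 5e-3, "e"),
    ("succ_e", -2, "e", 4, 1e-3, "e"),
    ("o2", 0, "e", 0, 1e-5, "g"),
    ("co2", 0, "e", 1, 3e-5, "g"),
    # protons: cytoplasmic pH is clamped (buffering), the periplasmic
    # pool is balanced so the proton motive force emerges from the
    # pump/consumer balance instead of acting as an infinite energy bath
    ("h_c", 1, "c", 0, 10.0**-_PH_CYT, "f"),
    ("h_e", 1, "e", 0, 4e-9, "p"),
]

# reactions: (id, stoichiometry, dG0' target kJ/mol, x, enzyme, modifiers)
# arrow "=" marks quasi-equilibrium (no x / enzyme / target needed beyond dG).
_CORE_REACTIONS = [
    ("PTS", "glc_e + pep <-> g6p + pyr", -45.0, 10, "pts", []),
    ("PGI", "g6p = f6p", 2.5, None, None, []),
    ("PFK", "f6p + atp <-> fdp + adp", -16.0, 7, "pfk",
     [("adp", "activator", 0.3)]),
    ("FBA", "fdp = dhap + g3p", 21.0, None, None, []),
    ("TPI", "dhap = g3p", 5.5, None, None, []),
    # kinetic, not quasi-equilibrium: a QE GAPD locks the NAD/NADH ratio
    # algebraically to the glycolytic intermediates, which lets a redox
    # excursion stall all of glycolysis instantaneously
    ("GAPD", "g3p + nad + adp <-> 3pg + atp + nadh", -10.0, 11, "gap", []),
    ("ENO", "3pg = pep", 5.0, None, None, []),
    ("PYK", "pep + adp <-> pyr + atp", -30.0, 8, "pyk", []),
    ("PPC", "pep + co2 <-> oaa", -35.0, 9, "ppc", []),
    ("GND", "g6p + 2 nadp <-> r5p + co2 + 2 nadph", -15.0, 10, "gnd", []),
    # lumped non-oxidative pentose phosphate pathway (transketolase +
    # transaldolase), NADP-independent so r5p supply survives a reduced
    # NADPH pool
    ("TKT", "2 f6p + g3p = 3 r5p", 5.0, None, None, []),
    ("PDH", "pyr + coa + nad <-> accoa + co2 + nadh", -35.0, 10, "pdh",
     [("nadh", "inhibitor", 0.5)]),
    ("PFL", "pyr + coa <-> accoa + for", -16.0, 8, "pfl", []),
    ("PTACK", "accoa + adp <-> ac + atp + coa", -5.0, 8, "ptack", []),
    ("ACt", "ac <-> ac_e", 0.0, 4, "act", []),
    ("ADHEr", "accoa + 2 nadh <-> etoh_e + 2 nad + coa", -25.0, 11, "adhe", []),
    ("FORt", "for <-> for_e", 0.0, 4, "fort", []),
    ("CS", "accoa + oaa <-> cit + coa", -35.0, 12, "glta", []),
    ("ACONT", "cit = icit", 8.5, None, None, []),
    ("ICDHyr", "icit + nadp <-> akg + co2 + nadph", -5.0, 10, "icd", []),
    ("AKGDH", "akg + coa + nad <-> succoa + co2 + nadh", -30.0, 12, "sucab", []),
    ("SUCOAS", "succoa + adp <-> succ + atp + coa", -3.0, 9, "succd", []),
    ("SUCDH", "succ + q8 <-> fum + q8h2", -13.5, 10, "sdh", []),
    ("FRD", "fum + mql8 <-> succ + mqn8", -20.0, 8, "frd", []),
    ("FUM", "fum = mal", -3.4, None, None, []),
    # large capacity: MDH operates near equilibrium in vivo and must carry
    # the full oxidative TCA flux against its uphill standard Gibbs energy
    ("MDH", "mal + nad <-> oaa + nadh", 28.0, 9, "mdh", []),
    ("SUCCt", "succ <-> succ_e", 0.0, 4, "succt", []),
    ("ADK", "atp + amp = 2 adp", 0.0, None, None, []),
    # electron transport chain; targets are the redox chemistry only, the
    # clamped protons add the pmf term at run time
    ("NADHIq8", "nadh + q8 + 4 h_c <-> nad + q8h2 + 4 h_e", -81.0, 39, "nuo", []),
    ("NADHImq", "nadh + mqn8 <-> nad + mql8", -47.5, 7, "nuo", []),
    ("NADHII", "nadh + q8 <-> nad + q8h2", -81.0, 8, "ndh", []),
    ("CYTBO3", "2 q8h2 + o2 + 8 h_c <-> 2 q8 + 8 h_e", -278.0, 75, "cyo", []),
    ("CYTBD", "2 q8h2 + o2 + 4 h_c <-> 2 q8 + 4 h_e", -278.0, 43, "cyd", []),
    ("ATPS", "adp + 4 h_e <-> atp + 4 h_c", 37.0, 38, "atps", []),
    ("THD", "nadh + nadp + 2 h_e <-> nad + nadph + 2 h_c", 1.0, 25, "pnt", []),
    # soluble transhydrogenase (SthA/UdhA): energy-independent overflow
    # valve that re-oxidizes excess NADPH so the NADP pool cannot jam
    # fully reduced and throttle isocitrate dehydrogenase
    ("STHA", "nadph + nad <-> nadp + nadh", -1.0, 8, "stha", []),
    # passive proton leak dissipating the pmf
    ("HLEAK", "h_e <-> h_c", 0.0, 8, None, []),
]

_ETC_REACTIONS = {
    "NADHIq8", "NADHImq", "NADHII", "CYTBO3", "CYTBD", "ATPS", "THD",
    "SUCDH", "FRD", "SUCCt", "HLEAK",
}
_ETC_SPECIES = {"q8", "q8h2", "mqn8", "mql8", "o2", "succ_e", "h_c", "h_e"}

# gene -> regulators (tf, +activator/-inhibitor, strength)
_CORE_REGULATION = {
    "pfl": [("fnr", "+", 2), ("arca", "+", 2)],
    "adhe": [("fnr", "+", 1), ("arca", "+", 1)],
    "pdh": [("arca", "-", 1)],
    "glta": [("arca", "-", 1)],
    "sucab": [("arca", "-", 2), ("fnr", "-", 1)],
    "sdh": [("arca", "-", 2)],
    "frd": [("fnr", "+", 2)],
    "nuo": [("arca", "-", 1)],
    "ndh": [("fnr", "-", 1)],
    "cyo": [("arca", "-", 2), ("fnr", "-", 1)],
    "cyd": [("arca", "+", 2), ("fnr", "-", 1)],
}

# Neidhardt-style precursor demands (mmol/gDCW) at the precursor level,
# plus energy and redox requirements.
_CORE_BIOMASS_NU = {
    "g6p": 0.205,
    "f6p": 0.071,
    "fdp": 0.0,
    "dhap": 0.129,
    "3pg": 1.496,
    "pep": 0.519,
    "pyr": 2.833,
    "accoa": 3.748,
    "succoa": 0.1,
    "akg": 1.079,
    "oaa": 1.787,
    "r5p": 0.898,
    "atp": 60.0,
    "nadph": 18.2,
    "nad": 3.5,
}
_CORE_BIOMASS_BY = {"coa": 3.848, "adp": 60.0, "nadh": 3.5, "nadp": 18.2}

_MU_MAX = 0.3  # 1/h, saturated linlog growth rate at typical concentrations


def _solve_mu0(
    species: list[tuple],
    reactions: list[tuple],
    ctx: ThermoContext,
    phi: dict[str, float],
) -> dict[str, float]:
    """Assemble formation energies (J/mol) from reaction dG targets.

    Solves a weighted least-squares problem: strong rows enforce
    sum_i nu_ij mu0_i = dG_target_j - sum_i nu_ij z_i F phi_i over the
    non-clamped species, weak prior rows pull each mu0 towards the value
    that makes the capacity equal the species' typical concentration.
    Clamped species (protons) keep mu0 = 0 so their chemical potential is
    purely concentration + electrical (the pmf).
    """
    # clamped protons and the balanced periplasmic proton pool keep
    # mu0 = 0 so their chemical potentials stay physical (pmf bookkeeping)
    free = [s for s in species if s[5] not in ("f", "p")]
    index = {s[0]: i for i, s in enumerate(free)}
    info = {s[0]: s for s in species}
    n = len(free)
    rows, rhs = [], []
    w_rxn = 1e3
    for _rid, stoich_txt, dg, _x, _enz, _mods in reactions:
        stoich, _ = parse_stoichiometry(stoich_txt)
        row = np.zeros(n)
        adj = 0.0
        for met, nu in stoich.items():
            z, comp = info[met][1], info[met][2]
            if met in index:
                row[index[met]] = nu
                adj += nu * z * ctx.F_const * phi[comp]
        rows.append(w_rxn * row)
        rhs.append(w_rxn * (dg * 1e3 - adj))
    for sid, z, comp, _cbn, c_typ, _flag in free:
        row = np.zeros(n)
        row[index[sid]] = 1.0
        # capacity == typical concentration  <=>  mu0 = -RT ln(c/c0) - zF phi
        target = -ctx.RT * math.log(c_typ / ctx.c_ref) - z * ctx.F_const * phi[comp]
        rows.append(row)
        rhs.append(target)
    sol, *_ = np.linalg.lstsq(np.array(rows), np.array(rhs), rcond=None)
    return {sid: float(v) for sid, v in zip(index, sol)}


def _build_document(
    species: list[tuple],
    reactions: list[tuple],
    regulation: dict,
    with_regulation: bool,
) -> ModelDocument:
    ctx = ThermoContext(T=310.15, pH=_PH_EXT, I=0.25, v_cell=0.002)
    doc = ModelDocument(context=ctx)
    doc.provenance = [
        "# generated by tkm.fixtures.build_fixture -- do not edit by hand",
    ]
    doc.compartments = {
        "cytoplasm": Compartment("cytoplasm", _PHI_CYT),
        "external": Compartment("external", 0.0),
    }
    phi = {"c": _PHI_CYT, "e": 0.0}
    mu0 = _solve_mu0(species, reactions, ctx, phi)
    for sid, z, comp, cbn, c_typ, flag in species:
        doc.metabolites[sid] = Metabolite(
            id=sid,
            mu0_prime=mu0.get(sid, 0.0),
            z=z,
            compartment=doc.compartments["cytoplasm" if comp == "c" else "external"],
            external=comp == "e" and flag != "p",
            gas=flag == "g",
            fixed=flag == "f",
            fixed_conc=c_typ if flag == "f" else None,
            carbons=cbn,
            guess=None if flag == "f" else c_typ,
        )
    genes: set[str] = set()
    for rid, stoich_txt, _dg, x, enzyme, mods in reactions:
        stoich, arrow = parse_stoichiometry(stoich_txt)
        if arrow == "=":
            doc.reactions[rid] = Reaction(
                id=rid, stoich=stoich, resistance_spec=ResistanceSpec("zero")
            )
            continue
        modifiers = tuple(Modifier(m, role, theta) for m, role, theta in mods)
        kind = "regulated" if modifiers else "constant"
        exchange = len({v > 0 for v in stoich.values()}) < 2
        doc.reactions[rid] = Reaction(
            id=rid,
            stoich=stoich,
            resistance_spec=ResistanceSpec(kind, x, modifiers),
            enzyme_id=enzyme,
            exchange=exchange,
        )
        if enzyme:
            genes.add(enzyme)
    if with_regulation:
        doc.transcription_factors["fnr"] = TranscriptionFactor(
            "fnr", SignalExpression("o2"), k_half=5e-7, hill_n=-4.0
        )
        doc.transcription_factors["arca"] = TranscriptionFactor(
            "arca",
            SignalExpression("(q8h2+mql8)/(q8+q8h2+mqn8+mql8)"),
            k_half=0.65,
            hill_n=4.0,
        )
    for gid in sorted(genes):
        regs = []
        if with_regulation:
            for tf, sign, k in regulation.get(gid, []):
                if tf in doc.transcription_factors:
                    mode = "activator" if sign == "+" else "inhibitor"
                    regs.append(Regulator(tf, mode, k))
        doc.genes[gid] = Gene(id=gid, basal_rate=0.2, regulators=tuple(regs))
    return doc


def build_fixture(spec: FixtureSpec | str = "core", **kwargs) -> ModelDocument:
    """Generate a packaged model fixture; deterministic by construction."""
    if isinstance(spec, str):
        spec = FixtureSpec(scale=spec, **kwargs)
    if spec.scale == "toy":
        return _build_toy()
    if spec.scale != "core":
        raise ValueError(f"unknown fixture scale {spec.scale!r}")
    species = list(_CORE_SPECIES)
    reactions = list(_CORE_REACTIONS)
    if not spec.include_etc:
        species = [s for s in species if s[0] not in _ETC_SPECIES]
        reactions = [r for r in reactions if r[0] not in _ETC_REACTIONS]
    doc = _build_document(
        species, reactions, _CORE_REGULATION, spec.include_regulation
    )
    if not spec.include_etc:
        # both TF signals sense oxygen / quinone redox, gone without the ETC
        doc.transcription_factors.clear()
        for gid, gene in list(doc.genes.items()):
            doc.genes[gid] = Gene(gid, gene.basal_rate, ())

    doc.biomass = BiomassStoichiometry(
        nu={k: v for k, v in _CORE_BIOMASS_NU.items() if v > 0},
        byproducts=dict(_CORE_BIOMASS_BY),
    )
    doc.energy_couple = ("atp", "adp")
    typicals = {s[0]: s[4] for s in _CORE_SPECIES}
    # shallow linlog slope: growth rate control rests mainly on the
    # ATP/ADP ramp, precursor availability modulates it gently
    k_a = 0.003
    s_typ = sum(v * math.log(typicals[m]) for m, v in doc.biomass.nu.items())
    doc.growth = GrowthParams(
        k_a=k_a, k_b=_MU_MAX / k_a - s_typ, k_lo=1.0, k_hi=3.0
    )
    doc.maintenance = MaintenanceParams(
        max_rate=6.0, k_lo=0.3, k_hi=1.5, overdrive=0.05
    )
    pools = [
        MoietyPool("adenylates", ("atp", "adp", "amp"), 4.3e-3, "amp"),
        MoietyPool("nicotinamide", ("nad", "nadh"), 2.1e-3, "nad"),
        MoietyPool("nadp_pool", ("nadp", "nadph"), 3e-4, "nadp"),
        MoietyPool("coa_pool", ("coa", "accoa", "succoa"), 1.2e-3, "coa"),
    ]
    quinones = []
    if spec.include_etc:
        quinones = [
            QuinonePool("ubiquinone", "q8", "q8h2", 1e-4, 4e-6, dead_ox=1e-4),
            QuinonePool("menaquinone", "mqn8", "mql8", 4e-4, -3e-6, dead_ox=1e-4),
        ]
    doc.moieties = MoietyPolicy(pools=tuple(pools), quinones=tuple(quinones))
    k_out = {"co2": 300.0}
    if spec.include_etc:
        k_out["o2"] = 300.0
    doc.chemostat = ChemostatEnv(
        D=0.2,
        c_in={"glc_e": 0.015},
        k_out=k_out,
        # CO2 sparging keeps dissolved CO2 available for anaplerosis even
        # under fermentative conditions (bicarbonate-buffered medium)
        k_in={"co2": 1e-3},
        aerobiosis=0.0,
        o2_id="o2" if spec.include_etc else None,
        k_in_100=0.0 if spec.include_etc else None,
    )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# toy fixture: glc -> g6p -> pyr -> ac with explicit ATP stoichiometry


_TOY_SPECIES = [
    ("glc_e", 0, "e", 6, 1e-2, "f"),
    ("g6p", -2, "c", 6, 1e-3, ""),
    ("pyr", -1, "c", 3, 5e-4, ""),
    ("ac_e", -1, "e", 2, 1e-3, "f"),
    ("for_e", -1, "e", 1, 1e-3, "f"),
    ("atp", -4, "c", 0, 3e-3, ""),
    ("adp", -3, "c", 0, 1e-3, ""),
]

_TOY_REACTIONS = [
    ("UPT", "glc_e + atp <-> g6p + adp", -20.0, 6, None, []),
    ("GLY", "g6p + 3 adp <-> 2 pyr + 3 atp", -50.0, 6, None, []),
    ("EXC", "pyr + adp <-> ac_e + for_e + atp", -30.0, 5, None, []),
    ("ATPASE", "atp <-> adp", -50.0, 3, None, []),
]


def _build_toy() -> ModelDocument:
    doc = _build_document(_TOY_SPECIES, _TOY_REACTIONS, {}, with_regulation=False)
    doc.moieties = MoietyPolicy(
        pools=(MoietyPool("adenylates", ("atp", "adp"), 4e-3, "adp"),)
    )
    doc.validate()
    return doc
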