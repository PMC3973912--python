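"""The ``.tkm`` declarative model format.

A sectioned, line-oriented plain-text format.  ``#`` starts a comment
(outside quoted strings); lines before the first section header are kept
as a free-text provenance header.  Sections::

    [context]                 key = value (T, p, pH, I, a_H2O, c_ref, v_cell)
    [compartments]            name phi=<V>
    [metabolites]             id mu0=<kJ/mol> [z=<int>] [compartment=<name>]
                              [carbons=<int>] [guess=<mol/l>] [external] [gas]
                              [fixed conc=<mol/l>]
    [reactions]               ID: a + 2 b <-> c | x=<int> enzyme=<gene>
                              arrows: "<->" finite resistance, "=" quasi-
                              equilibrium (R=0), "->" enforced flux (J=<value>)
                              modifiers: activator=<met>:<theta> inhibitor=...
    [transcription_factors]   id signal="<expr>" k=<float> n=<float>
    [genes]                   id basal=<float> [regulators=tf:+k,tf:-k]
    [biomass]                 precursor <met> <mmol/gDCW> / byproduct <met> <...>
                              plus k_a, k_b, k_lo, k_hi
    [maintenance]             max, k_lo, k_hi, optional overdrive
    [moieties]                pool <name> members=a,b,c total=<mol/l> inject=<id>
                              quinone <name> ox=<id> red=<id> intercept=<mol/l>
                              slope=<mol/l per %> [dead=<mol/l>]
    [chemostat]               D, aerobiosis; inflow <met> <mol/l>;
                              gas <met> k_out=<1/h> [k_in=<mol/l/h>] [k_in_100=<mol/l/h>]

Formation energies are written in kJ/mol in the file and converted to
J/mol internally; all unit conversions live in this module.
"""

from __future__ import annotations

import copy
import math
import re
import shlex
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .exprs import SignalExpression
from .kinetics import Modifier, Reaction, ResistanceSpec
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

__all__ = [
    "ModelDocument",
    "ParseError",
    "ModelError",
    "parse_model",
    "serialize_model",
    "load_model",
    "save_model",
    "parse_stoichiometry",
    "add_drain_reaction",
]

_SECTIONS = (
    "context",
    "compartments",
    "metabolites",
    "reactions",
    "transcription_factors",
    "genes",
    "biomass",
    "maintenance",
    "moieties",
    "chemostat",
)


class ParseError(ValueError):
    """Malformed model file; carries the offending line number."""

    def __init__(self, message: str, lineno: int | None = None, line: str = ""):
        loc = f"line {lineno}: " if lineno is not None else ""
        super().__init__(f"{loc}{message}" + (f"  [{line.strip()}]" if line else ""))
        self.lineno = lineno


class ModelError(ValueError):
    """Structurally invalid model (dangling references, singular reductions...)."""


@dataclass
class ModelDocument:
    """A fully cross-referenced model definition."""

    context: ThermoContext = field(default_factory=ThermoContext)
    compartments: dict[str, Compartment] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    transcription_factors: dict[str, TranscriptionFactor] = field(default_factory=dict)
    genes: dict[str, Gene] = field(default_factory=dict)
    biomass: BiomassStoichiometry | None = None
    growth: GrowthParams | None = None
    #: (numerator, denominator) ids of the energy-charge ratio driving the
    #: growth and maintenance ramps, e.g. ("atp", "adp")
    energy_couple: tuple[str, str] | None = None
    maintenance: MaintenanceParams | None = None
    moieties: MoietyPolicy = field(default_factory=MoietyPolicy)
    chemostat: ChemostatEnv | None = None
    provenance: list[str] = field(default_factory=list)

    # -- derived views ---------------------------------------------------

    def capacities(self) -> dict[str, float]:
        return {m.id: m.capacity(self.context) for m in self.metabolites.values()}

    @property
    def balanced_metabolites(self) -> list[str]:
        """Species carrying a balance equation (i.e. not clamped)."""
        return [m.id for m in self.metabolites.values() if not m.fixed]

    @property
    def intracellular(self) -> list[str]:
        return [
            m.id
            for m in self.metabolites.values()
            if not m.fixed and not m.external
        ]

    @property
    def extracellular(self) -> list[str]:
        return [m.id for m in self.metabolites.values() if not m.fixed and m.external]

    @property
    def gas_species(self) -> frozenset[str]:
        return frozenset(m.id for m in self.metabolites.values() if m.gas)

    def copy(self) -> "ModelDocument":
        return copy.deepcopy(self)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        """Cross-reference and structural checks; raises ModelError."""
        mets = self.metabolites
        for rxn in self.reactions.values():
            for met in rxn.stoich:
                if met not in mets:
                    raise ModelError(
                        f"reaction {rxn.id!r}: unknown metabolite {met!r}"
                    )
            if rxn.resistance_spec is not None:
                for mod in rxn.resistance_spec.modifiers:
                    if mod.metabolite not in mets:
                        raise ModelError(
                            f"reaction {rxn.id!r}: unknown modifier metabolite "
                            f"{mod.metabolite!r}"
                        )
            if rxn.enzyme_id is not None and rxn.enzyme_id not in self.genes:
                raise ModelError(
                    f"reaction {rxn.id!r}: unknown enzyme gene {rxn.enzyme_id!r}"
                )
            if not rxn.is_enforced:
                for met, v in rxn.stoich.items():
                    if v != int(v):
                        raise ModelError(
                            f"reaction {rxn.id!r}: non-integer stoichiometry for "
                            f"{met!r} is only allowed in drains and biomass"
                        )
        for tf in self.transcription_factors.values():
            for name in tf.signal.names:
                if name not in mets:
                    raise ModelError(
                        f"transcription factor {tf.id!r}: unknown metabolite "
                        f"{name!r} in signal"
                    )
        for gene in self.genes.values():
            for reg in gene.regulators:
                if reg.tf_id not in self.transcription_factors:
                    raise ModelError(
                        f"gene {gene.id!r}: unknown transcription factor "
                        f"{reg.tf_id!r}"
                    )
        if self.biomass is not None:
            for met in {**self.biomass.nu, **self.biomass.byproducts}:
                if met not in mets:
                    raise ModelError(f"biomass: unknown metabolite {met!r}")
        if self.energy_couple is not None:
            for met in self.energy_couple:
                if met not in mets:
                    raise ModelError(f"energy-ratio couple: unknown metabolite {met!r}")
        for pool in self.moieties.pools:
            for met in pool.members:
                if met not in mets:
                    raise ModelError(f"moiety pool {pool.name!r}: unknown {met!r}")
        for q in self.moieties.quinones:
            for met in (q.ox, q.red):
                if met not in mets:
                    raise ModelError(f"quinone pool {q.name!r}: unknown {met!r}")
        if self.chemostat is not None:
            env = self.chemostat
            for met in env.c_in:
                if met not in mets or not mets[met].external:
                    raise ModelError(f"chemostat inflow of non-external {met!r}")
            for met in env.k_out:
                if met not in mets or not mets[met].gas:
                    raise ModelError(f"gas exchange declared for non-gas {met!r}")
            for m in mets.values():
                if m.gas and m.id not in env.k_out:
                    raise ModelError(f"gas species {m.id!r} lacks a k_out")
        for m in mets.values():
            if m.fixed and (m.fixed_conc is None or m.fixed_conc <= 0):
                raise ModelError(
                    f"fixed metabolite {m.id!r} needs a positive clamped concentration"
                )
            if m.gas and not m.external:
                raise ModelError(f"gas species {m.id!r} must be external")
        self._check_qe_independence()
        self._check_pool_conservation()

    def _check_qe_independence(self) -> None:
        """Quasi-equilibrium constraints must be linearly independent."""
        qe = [r for r in self.reactions.values() if r.is_quasi_equilibrium]
        if not qe:
            return
        ids = {m: i for i, m in enumerate(self.metabolites)}
        mat = np.zeros((len(qe), len(ids)))
        for i, r in enumerate(qe):
            for met, v in r.stoich.items():
                mat[i, ids[met]] = v
        if np.linalg.matrix_rank(mat) < len(qe):
            names = ", ".join(r.id for r in qe)
            raise ModelError(
                "quasi-equilibrium reactions form a dependent cycle that "
                f"over-determines the reduced system (among: {names})"
            )

    def _check_pool_conservation(self) -> None:
        """Every reaction and the biomass must conserve each moiety pool;
        kinetic reactions must conserve skeleton carbon."""
        pools = [(p.name, set(p.members)) for p in self.moieties.pools]
        pools += [(q.name, {q.ox, q.red}) for q in self.moieties.quinones]
        carbons = {m.id: m.carbons for m in self.metabolites.values()}
        for rxn in self.reactions.values():
            for name, members in pools:
                s = sum(v for met, v in rxn.stoich.items() if met in members)
                if abs(s) > 1e-9:
                    raise ModelError(
                        f"reaction {rxn.id!r} does not conserve moiety pool {name!r}"
                    )
            if not rxn.is_enforced:
                dc = sum(v * carbons.get(met, 0) for met, v in rxn.stoich.items())
                if abs(dc) > 1e-9:
                    raise ModelError(
                        f"reaction {rxn.id!r} does not conserve carbon ({dc:+g})"
                    )
        if self.biomass is not None:
            stoich = self.biomass.stoich
            for name, members in pools:
                s = sum(v for met, v in stoich.items() if met in members)
                if abs(s) > 1e-9:
                    raise ModelError(
                        f"biomass reaction does not conserve moiety pool {name!r}"
                    )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ModelDocument):
            return NotImplemented
        return serialize_model(self) == serialize_model(other)


# ---------------------------------------------------------------------------
# stoichiometry grammar


_ARROWS = ("<->", "->", "=")


def parse_stoichiometry(text: str) -> tuple[dict[str, float], str]:
    """Parse ``a + 2 b -> c`` into ({a: -1, b: -2, c: +1}, arrow).

    Arrows: ``<->`` reversible with finite resistance, ``=`` quasi-
    equilibrium, ``->`` enforced/irreversible exchange.  Either side of an
    enforced reaction may be empty.
    """
    arrow = None
    for a in _ARROWS:
        if a in text:
            arrow = a
            break
    if arrow is None:
        raise ValueError(f"no reaction arrow in {text!r}")
    left, right = text.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split("+"):
            parts = term.split()
            if len(parts) == 1:
                coeff, met = 1.0, parts[0]
            elif len(parts) == 2:
                try:
                    coeff = float(parts[0])
                except ValueError:
                    raise ValueError(f"malformed stoichiometry term {term.strip()!r}")
                met = parts[1]
            else:
                raise ValueError(f"malformed stoichiometry term {term.strip()!r}")
            # ids may start with a digit (3pg) but must contain a letter
            if not re.fullmatch(r"(?=.*[A-Za-z_])[A-Za-z0-9_]+", met):
                raise ValueError(f"invalid metabolite id {met!r}")
            if coeff <= 0:
                raise ValueError(f"non-positive coefficient in {term.strip()!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coeff
    add_side(left, -1.0)
    add_side(right, +1.0)
    stoich = {m: v for m, v in stoich.items() if v != 0}
    if not stoich:
        raise ValueError(f"empty stoichiometry {text!r}")
    return stoich, arrow


def format_stoichiometry(stoich: dict[str, float], arrow: str) -> str:
    def fmt(items: Iterable[tuple[str, float]]) -> str:
        terms = []
        for met, v in items:
            terms.append(met if v == 1 else f"{_num(v)} {met}")
        return " + ".join(terms)

    left = fmt((m, -v) for m, v in stoich.items() if v < 0)
    right = fmt((m, v) for m, v in stoich.items() if v > 0)
    return f"{left} {arrow} {right}".strip()


def _num(x: float) -> str:
    """Shortest exact decimal representation."""
    if x == int(x) and abs(x) < 1e15:
        return str(int(x))
    return repr(x)


# ---------------------------------------------------------------------------
# parsing


def _strip_comment(line: str) -> str:
    out = []
    in_quote = False
    for ch in line:
        if ch == '"':
            in_quote = not in_quote
        if ch == "#" and not in_quote:
            break
        out.append(ch)
    return "".join(out)


def _attrs(tokens: list[str], lineno: int, line: str) -> tuple[dict[str, str], list[str]]:
    """Split shlex tokens into key=value attrs and bare flags."""
    kv: dict[str, str] = {}
    flags: list[str] = []
    for tok in tokens:
        if "=" in tok:
            k, v = tok.split("=", 1)
            if k in kv:
                raise ParseError(f"duplicate attribute {k!r}", lineno, line)
            kv[k] = v
        else:
            flags.append(tok)
    return kv, flags


def _float(kv: dict[str, str], key: str, lineno: int, line: str, default=None) -> float:
    if key not in kv:
        if default is not None:
            return default
        raise ParseError(f"missing attribute {key!r}", lineno, line)
    try:
        return float(kv[key])
    except ValueError:
        raise ParseError(f"attribute {key!r} is not a number", lineno, line)


def _int(kv: dict[str, str], key: str, lineno: int, line: str, default=None) -> int:
    if key not in kv:
        if default is not None:
            return default
        raise ParseError(f"missing attribute {key!r}", lineno, line)
    v = kv[key]
    try:
        as_float = float(v)
    except ValueError:
        raise ParseError(f"attribute {key!r} is not a number", lineno, line)
    if as_float != int(as_float):
        raise ParseError(f"attribute {key!r} must be an integer, got {v}", lineno, line)
    return int(as_float)


def parse_model(text: str) -> ModelDocument:
    """Parse ``.tkm`` content into a validated :class:`ModelDocument`."""
    doc = ModelDocument()
    doc.compartments = {}
    section: str | None = None
    ctx_kv: dict[str, float] = {}
    bio_nu: dict[str, float] = {}
    bio_by: dict[str, float] = {}
    bio_kv: dict[str, float] = {}
    maint_kv: dict[str, float] = {}
    chem_kv: dict[str, float] = {}
    chem_inflow: dict[str, float] = {}
    chem_gas: dict[str, dict[str, float]] = {}
    pools: list[MoietyPool] = []
    quinones: list[QuinonePool] = []
    seen_header = False

    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = _strip_comment(raw)
        stripped = line.strip()
        if not stripped:
            # provenance header: keep leading comment lines verbatim
            if not seen_header and raw.strip():
                doc.provenance.append(raw.rstrip())
            continue
        if stripped.startswith("[") and stripped.endswith("]"):
            name = stripped[1:-1].strip()
            if name not in _SECTIONS:
                raise ParseError(f"unknown section {name!r}", lineno, raw)
            section = name
            seen_header = True
            continue
        if not seen_header:
            # provenance header: keep original comment lines verbatim
            doc.provenance.append(raw.rstrip())
            continue
        if section is None:
            raise ParseError("content before any section", lineno, raw)
        try:
            tokens = shlex.split(stripped)
        except ValueError as exc:
            raise ParseError(str(exc), lineno, raw)

        if section == "context":
            if len(tokens) >= 3 and tokens[1] == "=":
                key, val = tokens[0], tokens[2]
            else:
                raise ParseError("expected 'key = value'", lineno, raw)
            try:
                ctx_kv[key] = float(val)
            except ValueError:
                raise ParseError(f"context value for {key!r} not a number", lineno, raw)

        elif section == "compartments":
            name = tokens[0]
            kv, _ = _attrs(tokens[1:], lineno, raw)
            if name in doc.compartments:
                raise ParseError(f"duplicate compartment {name!r}", lineno, raw)
            doc.compartments[name] = Compartment(name, _float(kv, "phi", lineno, raw, 0.0))

        elif section == "metabolites":
            mid = tokens[0]
            if mid in doc.metabolites:
                raise ParseError(f"duplicate metabolite {mid!r}", lineno, raw)
            kv, flags = _attrs(tokens[1:], lineno, raw)
            bad = set(flags) - {"external", "gas", "fixed"}
            if bad:
                raise ParseError(f"unknown flags {sorted(bad)}", lineno, raw)
            comp_name = kv.get("compartment", "cytoplasm")
            if comp_name not in doc.compartments:
                raise ParseError(f"unknown compartment {comp_name!r}", lineno, raw)
            doc.metabolites[mid] = Metabolite(
                id=mid,
                mu0_prime=_float(kv, "mu0", lineno, raw, 0.0) * 1e3,  # kJ -> J
                z=_int(kv, "z", lineno, raw, 0),
                compartment=doc.compartments[comp_name],
                external="external" in flags,
                gas="gas" in flags,
                fixed="fixed" in flags,
                fixed_conc=_float(kv, "conc", lineno, raw) if "conc" in kv else None,
                carbons=_int(kv, "carbons", lineno, raw, 0),
                guess=_float(kv, "guess", lineno, raw) if "guess" in kv else None,
            )

        elif section == "reactions":
            if ":" not in stripped:
                raise ParseError("expected 'ID: stoichiometry | attrs'", lineno, raw)
            rid, rest = stripped.split(":", 1)
            rid = rid.strip()
            if rid in doc.reactions:
                raise ParseError(f"duplicate reaction {rid!r}", lineno, raw)
            if "|" in rest:
                stoich_txt, attr_txt = rest.split("|", 1)
            else:
                stoich_txt, attr_txt = rest, ""
            try:
                stoich, arrow = parse_stoichiometry(stoich_txt)
            except ValueError as exc:
                raise ParseError(str(exc), lineno, raw)
            kv, flags = _attrs(shlex.split(attr_txt), lineno, raw)
            mods: list[Modifier] = []
            for role in ("activator", "inhibitor"):
                if role in kv:
                    for part in kv[role].split(","):
                        try:
                            met, theta = part.split(":")
                            mods.append(Modifier(met, role, float(theta)))
                        except ValueError:
                            raise ParseError(
                                f"malformed {role} spec {part!r} (want met:theta)",
                                lineno,
                                raw,
                            )
            try:
                if arrow == "->":
                    rxn = Reaction(
                        id=rid,
                        stoich=stoich,
                        enforced_flux=_float(kv, "J", lineno, raw, 0.0),
                        exchange=True,
                    )
                elif arrow == "=":
                    if "x" in kv or mods:
                        raise ParseError(
                            "quasi-equilibrium reactions take no kinetic attributes",
                            lineno,
                            raw,
                        )
                    rxn = Reaction(
                        id=rid,
                        stoich=stoich,
                        resistance_spec=ResistanceSpec("zero"),
                        exchange="exchange" in flags,
                    )
                else:
                    kind = "regulated" if mods else "constant"
                    rxn = Reaction(
                        id=rid,
                        stoich=stoich,
                        resistance_spec=ResistanceSpec(
                            kind, _int(kv, "x", lineno, raw), tuple(mods)
                        ),
                        enzyme_id=kv.get("enzyme"),
                        exchange="exchange" in flags,
                    )
            except ValueError as exc:
                raise ParseError(str(exc), lineno, raw)
            doc.reactions[rid] = rxn

        elif section == "transcription_factors":
            tid = tokens[0]
            if tid in doc.transcription_factors:
                raise ParseError(f"duplicate transcription factor {tid!r}", lineno, raw)
            kv, _ = _attrs(tokens[1:], lineno, raw)
            if "signal" not in kv:
                raise ParseError("transcription factor needs a signal", lineno, raw)
            try:
                doc.transcription_factors[tid] = TranscriptionFactor(
                    id=tid,
                    signal=SignalExpression(kv["signal"]),
                    k_half=_float(kv, "k", lineno, raw),
                    hill_n=_float(kv, "n", lineno, raw),
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno, raw)

        elif section == "genes":
            gid = tokens[0]
            if gid in doc.genes:
                raise ParseError(f"duplicate gene {gid!r}", lineno, raw)
            kv, _ = _attrs(tokens[1:], lineno, raw)
            regs: list[Regulator] = []
            if "regulators" in kv:
                for part in kv["regulators"].split(","):
                    m = re.fullmatch(r"([A-Za-z_][A-Za-z0-9_]*):([+-])(\d+)", part)
                    if not m:
                        raise ParseError(
                            f"malformed regulator {part!r} (want tf:+k or tf:-k "
                            "with integer k)",
                            lineno,
                            raw,
                        )
                    mode = "activator" if m.group(2) == "+" else "inhibitor"
                    regs.append(Regulator(m.group(1), mode, int(m.group(3))))
            try:
                doc.genes[gid] = Gene(
                    id=gid,
                    basal_rate=_float(kv, "basal", lineno, raw),
                    regulators=tuple(regs),
                )
            except ValueError as exc:
                raise ParseError(str(exc), lineno, raw)

        elif section == "biomass":
            if tokens[0] == "ratio":
                if len(tokens) != 3:
                    raise ParseError("expected 'ratio <num> <den>'", lineno, raw)
                doc.energy_couple = (tokens[1], tokens[2])
            elif tokens[0] in ("precursor", "byproduct"):
                if len(tokens) != 3:
                    raise ParseError("expected 'precursor <met> <value>'", lineno, raw)
                target = bio_nu if tokens[0] == "precursor" else bio_by
                if tokens[1] in target:
                    raise ParseError(f"duplicate biomass entry {tokens[1]!r}", lineno, raw)
                try:
                    target[tokens[1]] = float(tokens[2])
                except ValueError:
                    raise ParseError("biomass coefficient not a number", lineno, raw)
            elif len(tokens) >= 3 and tokens[1] == "=":
                try:
                    bio_kv[tokens[0]] = float(tokens[2])
                except ValueError:
                    raise ParseError("biomass parameter not a number", lineno, raw)
            else:
                raise ParseError("malformed biomass line", lineno, raw)

        elif section == "maintenance":
            if len(tokens) >= 3 and tokens[1] == "=":
                try:
                    maint_kv[tokens[0]] = float(tokens[2])
                except ValueError:
                    raise ParseError("maintenance parameter not a number", lineno, raw)
            else:
                raise ParseError("expected 'key = value'", lineno, raw)

        elif section == "moieties":
            kind = tokens[0]
            kv, _ = _attrs(tokens[2:], lineno, raw)
            if len(tokens) < 2:
                raise ParseError("malformed moiety line", lineno, raw)
            name = tokens[1]
            try:
                if kind == "pool":
                    pools.append(
                        MoietyPool(
                            name=name,
                            members=tuple(kv["members"].split(",")),
                            total=_float(kv, "total", lineno, raw),
                            inject=kv["inject"],
                        )
                    )
                elif kind == "quinone":
                    quinones.append(
                        QuinonePool(
                            name=name,
                            ox=kv["ox"],
                            red=kv["red"],
                            intercept=_float(kv, "intercept", lineno, raw),
                            slope=_float(kv, "slope", lineno, raw),
                            dead_ox=_float(kv, "dead", lineno, raw, 0.0),
                        )
                    )
                else:
                    raise ParseError(f"unknown moiety kind {kind!r}", lineno, raw)
            except KeyError as exc:
                raise ParseError(f"missing attribute {exc.args[0]!r}", lineno, raw)
            except ValueError as exc:
                raise ParseError(str(exc), lineno, raw)

        elif section == "chemostat":
            if tokens[0] == "inflow":
                if len(tokens) != 3:
                    raise ParseError("expected 'inflow <met> <mol/l>'", lineno, raw)
                try:
                    chem_inflow[tokens[1]] = float(tokens[2])
                except ValueError:
                    raise ParseError("inflow concentration not a number", lineno, raw)
            elif tokens[0] == "gas":
                if len(tokens) < 2:
                    raise ParseError("expected 'gas <met> k_out=...'", lineno, raw)
                kv, _ = _attrs(tokens[2:], lineno, raw)
                entry = {"k_out": _float(kv, "k_out", lineno, raw)}
                if "k_in" in kv:
                    entry["k_in"] = _float(kv, "k_in", lineno, raw)
                if "k_in_100" in kv:
                    entry["k_in_100"] = _float(kv, "k_in_100", lineno, raw)
                chem_gas[tokens[1]] = entry
            elif len(tokens) >= 3 and tokens[1] == "=":
                try:
                    chem_kv[tokens[0]] = float(tokens[2])
                except ValueError:
                    raise ParseError("chemostat parameter not a number", lineno, raw)
            else:
                raise ParseError("malformed chemostat line", lineno, raw)

    # -- assemble composite sections -------------------------------------
    known_ctx = {"T", "p", "pH", "I", "a_H2O", "c_ref", "v_cell"}
    bad = set(ctx_kv) - known_ctx
    if bad:
        raise ParseError(f"unknown context keys {sorted(bad)}")
    doc.context = ThermoContext(**ctx_kv)

    if bio_nu or bio_kv:
        doc.biomass = BiomassStoichiometry(nu=bio_nu, byproducts=bio_by)
        try:
            doc.growth = GrowthParams(
                k_a=bio_kv["k_a"], k_b=bio_kv["k_b"],
                k_lo=bio_kv["k_lo"], k_hi=bio_kv["k_hi"],
            )
        except KeyError as exc:
            raise ParseError(f"biomass section missing parameter {exc.args[0]!r}")
    if maint_kv:
        try:
            doc.maintenance = MaintenanceParams(
                max_rate=maint_kv["max"], k_lo=maint_kv["k_lo"],
                k_hi=maint_kv["k_hi"],
                overdrive=maint_kv.get("overdrive", 0.0),
            )
        except KeyError as exc:
            raise ParseError(f"maintenance section missing parameter {exc.args[0]!r}")
    doc.moieties = MoietyPolicy(pools=tuple(pools), quinones=tuple(quinones))
    if chem_kv or chem_inflow or chem_gas:
        if "D" not in chem_kv:
            raise ParseError("chemostat section missing dilution rate D")
        o2_id = None
        k_in_100 = None
        for gas, entry in chem_gas.items():
            if "k_in_100" in entry:
                if o2_id is not None:
                    raise ParseError("only one gas may carry k_in_100")
                o2_id, k_in_100 = gas, entry["k_in_100"]
        doc.chemostat = ChemostatEnv(
            D=chem_kv["D"],
            c_in=chem_inflow,
            k_out={g: e["k_out"] for g, e in chem_gas.items()},
            k_in={g: e["k_in"] for g, e in chem_gas.items() if "k_in" in e},
            aerobiosis=chem_kv.get("aerobiosis", 0.0),
            o2_id=o2_id,
            k_in_100=k_in_100,
        )
    doc.validate()
    return doc


# ---------------------------------------------------------------------------
# serialization


def serialize_model(doc: ModelDocument) -> str:
    """Deterministic text form; ``parse_model(serialize_model(doc)) == doc``."""
    out: list[str] = []
    out.extend(doc.provenance)
    if doc.provenance:
        out.append("")

    ctx = doc.context
    out.append("[context]")
    for key in ("T", "p", "pH", "I", "a_H2O", "c_ref", "v_cell"):
        out.append(f"{key} = {_num(getattr(ctx, key))}")
    out.append("")

    out.append("[compartments]")
    for comp in doc.compartments.values():
        out.append(f"{comp.name} phi={_num(comp.phi)}")
    out.append("")

    out.append("[metabolites]")
    for m in doc.metabolites.values():
        parts = [m.id, f"mu0={_num(m.mu0_prime / 1e3)}"]
        if m.z:
            parts.append(f"z={m.z}")
        parts.append(f"compartment={m.compartment.name}")
        if m.carbons:
            parts.append(f"carbons={m.carbons}")
        if m.guess is not None:
            parts.append(f"guess={_num(m.guess)}")
        if m.external:
            parts.append("external")
        if m.gas:
            parts.append("gas")
        if m.fixed:
            parts.append(f"fixed conc={_num(m.fixed_conc)}")
        out.append(" ".join(parts))
    out.append("")

    if doc.reactions:
        out.append("[reactions]")
        for r in doc.reactions.values():
            if r.is_enforced:
                arrow = "->"
            elif r.is_quasi_equilibrium:
                arrow = "="
            else:
                arrow = "<->"
            line = f"{r.id}: {format_stoichiometry(r.stoich, arrow)}"
            attrs = []
            spec = r.resistance_spec
            if spec is not None and spec.kind != "zero":
                attrs.append(f"x={spec.log10_k_plus}")
                for mod in spec.modifiers:
                    attrs.append(f"{mod.role}={mod.metabolite}:{_num(mod.theta)}")
            if r.enzyme_id:
                attrs.append(f"enzyme={r.enzyme_id}")
            if r.is_enforced:
                attrs.append(f"J={_num(r.enforced_flux)}")
            if r.exchange and not r.is_enforced:
                attrs.append("exchange")
            if attrs:
                line += " | " + " ".join(attrs)
            out.append(line)
        out.append("")

    if doc.transcription_factors:
        out.append("[transcription_factors]")
        for tf in doc.transcription_factors.values():
            out.append(
                f'{tf.id} signal="{tf.signal.text}" k={_num(tf.k_half)} n={_num(tf.hill_n)}'
            )
        out.append("")

    if doc.genes:
        out.append("[genes]")
        for g in doc.genes.values():
            line = f"{g.id} basal={_num(g.basal_rate)}"
            if g.regulators:
                regs = ",".join(
                    f"{r.tf_id}:{'+' if r.mode == 'activator' else '-'}{r.strength}"
                    for r in g.regulators
                )
                line += f" regulators={regs}"
            out.append(line)
        out.append("")

    if doc.biomass is not None:
        out.append("[biomass]")
        if doc.energy_couple is not None:
            out.append(f"ratio {doc.energy_couple[0]} {doc.energy_couple[1]}")
        for met, v in doc.biomass.nu.items():
            out.append(f"precursor {met} {_num(v)}")
        for met, v in doc.biomass.byproducts.items():
            out.append(f"byproduct {met} {_num(v)}")
        gp = doc.growth
        for key, v in (("k_a", gp.k_a), ("k_b", gp.k_b), ("k_lo", gp.k_lo), ("k_hi", gp.k_hi)):
            out.append(f"{key} = {_num(v)}")
        out.append("")

    if doc.maintenance is not None:
        mp = doc.maintenance
        out.append("[maintenance]")
        out.append(f"max = {_num(mp.max_rate)}")
        out.append(f"k_lo = {_num(mp.k_lo)}")
        out.append(f"k_hi = {_num(mp.k_hi)}")
        if mp.overdrive:
            out.append(f"overdrive = {_num(mp.overdrive)}")
        out.append("")

    if doc.moieties.pools or doc.moieties.quinones:
        out.append("[moieties]")
        for p in doc.moieties.pools:
            out.append(
                f"pool {p.name} members={','.join(p.members)} "
                f"total={_num(p.total)} inject={p.inject}"
            )
        for q in doc.moieties.quinones:
            line = (
                f"quinone {q.name} ox={q.ox} red={q.red} "
                f"intercept={_num(q.intercept)} slope={_num(q.slope)}"
            )
            if q.dead_ox:
                line += f" dead={_num(q.dead_ox)}"
            out.append(line)
        out.append("")

    if doc.chemostat is not None:
        env = doc.chemostat
        out.append("[chemostat]")
        out.append(f"D = {_num(env.D)}")
        out.append(f"aerobiosis = {_num(env.aerobiosis)}")
        for met, v in env.c_in.items():
            out.append(f"inflow {met} {_num(v)}")
        for gas, k in env.k_out.items():
            line = f"gas {gas} k_out={_num(k)}"
            if gas in env.k_in:
                line += f" k_in={_num(env.k_in[gas])}"
            if gas == env.o2_id and env.k_in_100 is not None:
                line += f" k_in_100={_num(env.k_in_100)}"
            out.append(line)
        out.append("")

    return "\n".join(out).rstrip() + "\n"


def load_model(path) -> ModelDocument:
    with open(path, encoding="utf-8") as fh:
        return parse_model(fh.read())


def save_model(doc: ModelDocument, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(serialize_model(doc))


# ---------------------------------------------------------------------------
# drains


def add_drain_reaction(
    doc: ModelDocument,
    drain: str,
    J_prod: float = 0.0,
    rxn_id: str = "DRAIN",
) -> ModelDocument:
    """Return a copy of ``doc`` with an enforced production drain added.

    ``drain`` is a stoichiometry string like ``2 accoa + 4 nadh -> 2 coa +
    4 nad`` (the butanol pathway's overall precursor demand); the flux is
    clamped to ``J_prod`` (mmol/gDCW/h) regardless of the potentials.
    """
    if J_prod < 0:
        raise ValueError(f"enforced production flux must be non-negative, got {J_prod}")
    stoich, arrow = parse_stoichiometry(drain)
    if arrow != "->":
        raise ValueError(f"drain must be written with '->', got {arrow!r}")
    for met in stoich:
        if met not in doc.metabolites:
            raise ModelError(f"drain references unknown metabolite {met!r}")
    new = doc.copy()
    if rxn_id in new.reactions:
        raise ModelError(f"reaction id {rxn_id!r} already exists")
    new.reactions[rxn_id] = Reaction(
        id=rxn_id, stoich=stoich, enforced_flux=float(J_prod), exchange=True
    )
    new.validate()
    return new
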