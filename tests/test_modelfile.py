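""".tkm model format: parsing, serialization, validation, drains."""

import pytest

from tkm import (
    FixtureSpec,
    ModelError,
    ParseError,
    add_drain_reaction,
    build_fixture,
    parse_model,
    parse_stoichiometry,
    serialize_model,
)
from tkm.modelfile import format_stoichiometry


@pytest.mark.parametrize(
    "spec",
    [
        FixtureSpec(scale="toy"),
        FixtureSpec(scale="core"),
        FixtureSpec(scale="core", include_regulation=False),
        FixtureSpec(scale="core", include_etc=False),
    ],
    ids=["toy", "core", "core-noreg", "core-noetc"],
)
def test_serialize_parse_roundtrip(spec):
    doc = build_fixture(spec)
    text = serialize_model(doc)
    doc2 = parse_model(text)
    assert doc2 == doc
    # serialization is a fixed point
    assert serialize_model(doc2) == text


def test_core_fixture_text_is_compact(core_doc):
    text = serialize_model(core_doc)
    assert len(text.encode()) <= 64 * 1024


def test_parse_stoichiometry():
    stoich, arrow = parse_stoichiometry("2 a + b <-> 3 c")
    assert stoich == {"a": -2.0, "b": -1.0, "c": 3.0}
    assert arrow == "<->"
    stoich, arrow = parse_stoichiometry("pyr + nadh -> etoh_e + co2 + nad")
    assert arrow == "->"
    assert stoich["pyr"] == -1.0 and stoich["nad"] == 1.0
    out = format_stoichiometry({"a": -2.0, "b": -1.0, "c": 3.0}, "<->")
    assert parse_stoichiometry(out) == ({"a": -2.0, "b": -1.0, "c": 3.0}, "<->")


def test_parse_errors_carry_line_numbers():
    with pytest.raises(ParseError) as exc:
        parse_model("[metabolites]\nfoo mu0=not_a_number\n")
    assert exc.value.lineno == 2


def test_validation_rejects_unknown_metabolite(core_doc):
    doc = core_doc.copy()
    bad = doc.reactions["PYK"]
    doc.reactions["BAD"] = type(bad)(
        id="BAD", stoich={"nosuch": -1.0, "pyr": 1.0},
        resistance_spec=bad.resistance_spec,
    )
    with pytest.raises(ModelError):
        doc.validate()


def test_add_drain_reaction(core_doc):
    new = add_drain_reaction(core_doc, "g6p ->", J_prod=1.5)
    assert "DRAIN" in new.reactions
    assert new.reactions["DRAIN"].enforced_flux == 1.5
    assert "DRAIN" not in core_doc.reactions  # original untouched
    with pytest.raises(ValueError):
        add_drain_reaction(core_doc, "g6p <-> ", J_prod=1.0)
    with pytest.raises(ModelError):
        add_drain_reaction(core_doc, "nosuch ->", J_prod=1.0)


def test_drain_must_conserve_moiety_pools(core_doc):
    # a drain consuming NADH without returning NAD would destroy the
    # nicotinamide pool; validation rejects it
    with pytest.raises(ModelError):
        add_drain_reaction(core_doc, "pyr + nadh -> etoh_e + co2", J_prod=0.0)
    # the redox-closed form passes
    new = add_drain_reaction(core_doc, "pyr + nadh -> etoh_e + co2 + nad")
    assert new.reactions["DRAIN"].enforced_flux == 0.0
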