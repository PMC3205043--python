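"""Convention discovery, scoping semantics and the built-in handlers."""

import random

import pytest
from lxml import etree

from cmlcheck import (
    Severity,
    discover_conventions,
    parse,
    run_conventions,
    validate_document,
)
from cmlcheck import conventions as conv
from cmlcheck.conventions import ConventionBinding, validate_simpleunit
from cmlcheck.document import CML_NS, CONVENTION_NS
from conftest import non_valid_findings

CML = f'xmlns:cml="{CML_NS}"'
CONV = f'xmlns:conventions="{CONVENTION_NS}"'
SU = 'convention="conventions:simpleUnit"'


def _severities(findings):
    return [f.severity for f in findings]


class TestDiscovery:
    def test_two_sibling_declarations(self, corpus_by_id):
        root = parse(corpus_by_id["appendixB-valid-vi"].document)
        bindings, findings = discover_conventions(root)
        assert len(bindings) == 2
        assert {b.convention_uri for b in bindings} == {conv.SIMPLEUNIT_URI}
        assert findings == []

    def test_no_declarations_warns(self):
        root = parse(f"<cml:molecule {CML}/>".encode())
        bindings, findings = discover_conventions(root)
        assert bindings == []
        assert _severities(findings) == [Severity.WARNING]

    def test_unbound_prefix_is_an_error(self):
        root = parse(f'<cml:unitList convention="nosuch:thing" {CML}/>'.encode())
        bindings, findings = discover_conventions(root)
        assert bindings == []
        assert _severities(findings) == [Severity.ERROR]


class TestTraversal:
    def test_scope_under_foreign_root(self, corpus_by_id):
        root = parse(corpus_by_id["appendixB-valid-ii"].document)
        assert run_conventions(root) == []

    def test_cml_element_out_of_scope_is_silent(self, corpus_by_id):
        # a cml:module wrapper above the declaration draws no findings
        root = parse(corpus_by_id["appendixB-valid-iii"].document)
        assert run_conventions(root) == []

    def test_mode_persists_through_foreign_elements(self, corpus_by_id):
        root = parse(corpus_by_id["appendixB-info-iv"].document)
        findings = run_conventions(root)
        assert _severities(findings) == [Severity.INFO]
        assert "bond" in findings[0].message

    def test_unknown_convention_is_informational(self):
        doc = (
            f'<cml:molecule convention="conventions:mystery" {CML} {CONV}>'
            "<cml:atom/></cml:molecule>"
        )
        findings = run_conventions(parse(doc.encode()))
        assert _severities(findings) == [Severity.INFO]
        # subtree traversed out of mode: the atom draws nothing
        assert "mystery" in findings[0].message

    def test_declaration_on_foreign_element_is_ignored(self):
        doc = (
            f'<w:wrap xmlns:w="http://w/" {SU} {CML} {CONV}>'
            "<cml:molecule/></w:wrap>"
        )
        assert run_conventions(parse(doc.encode())) == []


class TestSimpleUnit:
    @pytest.mark.parametrize(
        "rid,message",
        [
            ("iii", conv.MSG_UNITLIST_NEEDS_UNIT),
            ("vi", conv.MSG_UNITLIST_NEEDS_UNIT),
            ("vii", conv.MSG_UNITLIST_NEEDS_UNIT),
        ],
    )
    def test_unitlist_needs_direct_unit_child(self, corpus_by_id, rid, message):
        root = parse(corpus_by_id[f"appendixB-invalid-{rid}"].document)
        findings = run_conventions(root)
        assert [f.message for f in findings] == [message]

    def test_declaration_on_molecule_is_one_error_at_the_attribute(self, corpus_by_id):
        root = parse(corpus_by_id["appendixB-invalid-i"].document)
        findings = run_conventions(root)
        assert len(findings) == 1
        assert findings[0].severity is Severity.ERROR
        assert findings[0].location.endswith(
            "@*[local-name() = 'convention' and namespace-uri() = '']"
        )

    def test_multiple_units_allowed(self, corpus_by_id):
        root = parse(corpus_by_id["appendixB-valid-xi"].document)
        assert run_conventions(root) == []

    def test_non_member_cml_element_draws_info(self, corpus_by_id):
        root = parse(corpus_by_id["appendixB-info-ii"].document)
        findings = run_conventions(root)
        assert _severities(findings) == [Severity.INFO]
        assert findings[0].message.startswith("atom is not a part of")

    def test_single_scope_entry_point(self, corpus_by_id):
        root = parse(corpus_by_id["appendixB-valid-i"].document)
        binding = ConventionBinding(root, conv.SIMPLEUNIT_URI)
        assert validate_simpleunit(binding) == []


def _run(doc: str):
    return run_conventions(parse(doc.encode()))


class TestMolecular:
    MOL = 'convention="conventions:molecular"'

    def test_name_child_satisfies_required_set(self):
        doc = f"<cml:molecule {self.MOL} {CML} {CONV}><cml:name>w</cml:name></cml:molecule>"
        assert _run(doc) == []

    def test_molecule_and_atomarray_exclusive(self):
        doc = (
            f"<cml:molecule {self.MOL} {CML} {CONV}>"
            '<cml:molecule><cml:atomArray><cml:atom id="a1"/></cml:atomArray></cml:molecule>'
            '<cml:atomArray><cml:atom id="a2"/></cml:atomArray>'
            "</cml:molecule>"
        )
        messages = [f.message for f in _run(doc)]
        assert messages == [conv.MSG_MOLECULE_EXCLUSIVE_CHILDREN]

    def test_atom_id_unique_within_eldest_molecule(self):
        doc = (
            f"<cml:molecule {self.MOL} {CML} {CONV}>"
            '<cml:molecule><cml:atomArray><cml:atom id="a1"/></cml:atomArray></cml:molecule>'
            '<cml:molecule><cml:atomArray><cml:atom id="a1"/></cml:atomArray></cml:molecule>'
            "</cml:molecule>"
        )
        messages = [f.message for f in _run(doc)]
        assert messages == [conv.msg_atom_id_not_unique("a1")]

    def test_partial_coordinates_error(self):
        doc = (
            f"<cml:molecule {self.MOL} {CML} {CONV}>"
            '<cml:atomArray><cml:atom id="a1" x3="1.0"/></cml:atomArray>'
            "</cml:molecule>"
        )
        messages = [f.message for f in _run(doc)]
        assert messages == [conv.MSG_ATOM_COORDS_TOGETHER]

    def test_self_bond_error(self):
        doc = (
            f"<cml:molecule {self.MOL} {CML} {CONV}>"
            '<cml:atomArray><cml:atom id="a1"/><cml:atom id="a2"/></cml:atomArray>'
            '<cml:bondArray><cml:bond atomRefs2="a1 a1"/></cml:bondArray>'
            "</cml:molecule>"
        )
        messages = [f.message for f in _run(doc)]
        assert messages == [conv.MSG_BOND_DISTINCT_ATOMS]


class TestCompchem:
    def test_base_fixture_is_clean(self, corpus_by_id):
        root = parse(corpus_by_id["compchem-base"].document)
        assert run_conventions(root) == []

    @pytest.mark.parametrize(
        "rule,message",
        [
            ("compchem.initialization-module", conv.MSG_INIT_MODULE_REQUIRED),
            ("compchem.single-molecule", conv.MSG_INIT_ONE_MOLECULE),
            ("compchem.molecular-declared", conv.MSG_DECLARE_MOLECULAR),
            ("compchem.atomarray", conv.MSG_INIT_NEEDS_ATOMARRAY),
            ("compchem.atom-coordinates", conv.MSG_INIT_ATOMS_3D),
        ],
    )
    def test_each_rule_fails_alone(self, corpus_by_id, rule, message):
        from cmlcheck import mutate_fixture

        mutant = mutate_fixture(corpus_by_id["compchem-base"], rule)
        findings = run_conventions(parse(mutant.document))
        assert [f.message for f in findings] == [message]

    def test_nested_molecular_scope_is_engaged(self, corpus_by_id):
        # breaking a molecular rule inside the compchem document surfaces
        # the molecular error, proving the nested handler runs
        tree = etree.fromstring(corpus_by_id["compchem-base"].document)
        atom = tree.find(".//{%s}atom" % CML_NS)
        del atom.attrib["id"]
        findings = run_conventions(parse(etree.tostring(tree)))
        assert conv.MSG_ATOM_NEEDS_ID in [f.message for f in findings]


class TestUnitDictionary:
    def test_base_fixture_is_clean(self, corpus_by_id):
        root = parse(corpus_by_id["unitdict-base"].document)
        assert run_conventions(root) == []

    def test_entry_with_definition_and_one_description_passes(self, corpus_by_id):
        root = parse(corpus_by_id["unitdict-base"].document)
        assert run_conventions(root) == []

    @pytest.mark.parametrize(
        "rule,message,severity",
        [
            ("unitdict.unit-id", conv.MSG_UNIT_NEEDS_ID, Severity.ERROR),
            ("unitdict.entry-definition", conv.MSG_ENTRY_NEEDS_DEFINITION, Severity.ERROR),
            ("unitdict.entry-description", conv.MSG_ENTRY_ONE_DESCRIPTION, Severity.ERROR),
            ("unitdict.dictionary-title", conv.MSG_DICTIONARY_NEEDS_TITLE, Severity.WARNING),
        ],
    )
    def test_each_rule_fails_alone(self, corpus_by_id, rule, message, severity):
        from cmlcheck import mutate_fixture

        mutant = mutate_fixture(corpus_by_id["unitdict-base"], rule)
        findings = run_conventions(parse(mutant.document))
        assert [(f.severity, f.message) for f in findings] == [(severity, message)]

    def test_non_member_element_draws_info(self):
        doc = (
            f'<cml:dictionary convention="conventions:unit-dictionary" '
            f'title="t" {CML} {CONV}><cml:molecule/></cml:dictionary>'
        )
        findings = _run(doc)
        assert _severities(findings) == [Severity.INFO]
        assert findings[0].message.startswith("molecule is not a part of")


class TestScopeProperties:
    def test_wrapping_in_foreign_ancestors_never_changes_findings(self, corpus):
        """Scope isolation: random foreign / no-namespace ancestor chains
        around any valid simpleUnit document leave its findings unchanged."""
        rng = random.Random(20110)
        valid_docs = [f for f in corpus if f.provenance == "appendixB-valid"]
        for fixture in valid_docs:
            baseline = [
                (f.severity, f.message)
                for f in non_valid_findings(validate_document(fixture.document))
            ]
            inner = etree.fromstring(fixture.document)
            for depth in range(rng.randint(1, 3)):
                if rng.random() < 0.5:
                    wrapper = etree.Element("{http://example.org/wrap}w%d" % depth)
                else:
                    wrapper = etree.Element("no-namespace-wrapper")
                wrapper.append(inner)
                inner = wrapper
            wrapped = etree.tostring(inner)
            observed = [
                (f.severity, f.message)
                for f in non_valid_findings(validate_document(wrapped))
            ]
            assert observed == baseline, fixture.id

    def test_disjoint_sibling_scopes_validate_independently(self, corpus_by_id):
        """Findings for the two-scope document equal the union of findings
        for two copies of the single-scope document."""
        single = run_conventions(parse(corpus_by_id["appendixB-valid-i"].document))
        double = run_conventions(parse(corpus_by_id["appendixB-valid-vi"].document))
        assert [f.message for f in double] == 2 * [f.message for f in single]

    def test_disjoint_scopes_each_contribute_their_infos(self):
        one = (
            f'<cml:unitList {SU}><cml:unit/><cml:molecule/></cml:unitList>'
        )
        doc = f'<w:r xmlns:w="http://w/" {CML} {CONV}>{one}{one}</w:r>'
        findings = _run(doc)
        assert _severities(findings) == [Severity.INFO, Severity.INFO]

    def test_info_findings_never_demote_valid(self, corpus):
        from cmlcheck import ValidationResult

        for fixture in corpus:
            if fixture.provenance != "appendixB-info":
                continue
            report = validate_document(fixture.document)
            assert report.result is ValidationResult.VALID, fixture.id
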