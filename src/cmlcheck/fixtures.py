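"""The validator-test corpus.

Every document the validator's behaviour is pinned against, generated
programmatically: the 23 simpleUnit documents (11 valid, 5 valid-with-info,
7 invalid), the four schema tests exercising namespace wildcards, the
5-atom reference molecule used by the chemistry operations, synthetic
documents exercising every molecular / compchem / unit-dictionary rule on
its passing side, and mutation-derived documents that each break exactly
one rule.
"""

from __future__ import annotations

import copy
import re
from dataclasses import dataclass
from typing import Callable, List, Optional, Tuple

from lxml import etree

from . import conventions as conv
from .chemistry import AtomView, MoleculeView
from .document import CML_NS, CONVENTION_NS
from .report import Severity, ValidationResult

XHTML_NS = "http://www.w3.org/1999/xhtml"

# namespace declaration snippets shared by the document templates
_CML = f'xmlns:cml="{CML_NS}"'
_CONV = f'xmlns:conventions="{CONVENTION_NS}"'
_X = f'xmlns:x="{XHTML_NS}"'
_SU = 'convention="conventions:simpleUnit"'


def _el_step(local: str, ns: str = CML_NS, index: int = 1) -> str:
    return f"/*[local-name() = '{local}' and namespace-uri() = '{ns}'][{index}]"


def _attr_step(local: str, ns: str = "") -> str:
    return f"@*[local-name() = '{local}' and namespace-uri() = '{ns}']"


def _ignored_message(name: str, uri: str = conv.SIMPLEUNIT_URI) -> str:
    return conv.IGNORED_TEMPLATE.format(name=name, uri=uri)


@dataclass(frozen=True)
class ExpectedFinding:
    """A finding the validator must produce: severity, message (regex,
    full-matched) and optionally the exact location path."""

    severity: Severity
    message_pattern: str
    location: Optional[str] = None

    def matches(self, finding) -> bool:
        if finding.severity is not self.severity:
            return False
        if not re.fullmatch(self.message_pattern, finding.message, re.DOTALL):
            return False
        if self.location is not None and finding.location != self.location:
            return False
        return True


def expect(severity: Severity, message: str, location: Optional[str] = None,
           pattern: bool = False) -> ExpectedFinding:
    return ExpectedFinding(
        severity, message if pattern else re.escape(message), location
    )


@dataclass(frozen=True)
class Fixture:
    """A document with its expected validation outcome.

    ``stage`` is ``"full"`` for whole-workflow expectations or ``"schema"``
    for documents judged on the structural stage alone (the schema tests
    declare no conventions, so the full workflow would add the
    no-convention warning on top of their structural verdict).
    """

    id: str
    document: bytes
    expected_result: ValidationResult
    expected_findings: Tuple[ExpectedFinding, ...] = ()
    provenance: str = "synthetic"
    stage: str = "full"

    def consistent(self) -> bool:
        """expected_findings must aggregate to expected_result."""
        worst = Severity.VALID
        for f in self.expected_findings:
            if f.severity > worst:
                worst = f.severity
        derived = {
            Severity.ERROR: ValidationResult.INVALID,
            Severity.WARNING: ValidationResult.VALID_WITH_WARNINGS,
        }.get(worst, ValidationResult.VALID)
        return derived == self.expected_result


def _fx(fid, doc, result, findings=(), provenance="synthetic", stage="full"):
    if isinstance(doc, str):
        doc = doc.encode("utf-8")
    return Fixture(fid, doc, result, tuple(findings), provenance, stage)


# --------------------------------------------------------------------------
# simpleUnit corpus: valid documents (no info findings expected)
# --------------------------------------------------------------------------

_VALID_DOCS = {
    "i": f'<cml:unitList {_SU} {_CML} {_CONV}><cml:unit/></cml:unitList>',
    "ii": (
        f'<x:p {_X} {_CML} {_CONV}>'
        f'<cml:unitList {_SU}><cml:unit/></cml:unitList>'
        '</x:p>'
    ),
    "iii": (
        f'<cml:module {_CML} {_CONV}>'
        f'<cml:unitList {_SU}><cml:unit/></cml:unitList>'
        '</cml:module>'
    ),
    "iv": (
        f'<element-in-default-namespace {_CML} {_CONV}>'
        f'<cml:unitList {_SU}><cml:unit/></cml:unitList>'
        '</element-in-default-namespace>'
    ),
    "v": (
        f'<x:p {_X} {_CML} {_CONV}>'
        'the unitList need not be the root element'
        f'<cml:unitList {_SU}><cml:unit/></cml:unitList>'
        '</x:p>'
    ),
    "vi": (
        f'<x:p {_X} {_CML} {_CONV}>'
        'there are multiple instances of the simpleUnit convention in this document'
        f'<cml:unitList {_SU}><cml:unit/></cml:unitList>'
        f'<cml:unitList {_SU}><cml:unit/></cml:unitList>'
        '</x:p>'
    ),
    "vii": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<cml:unit/>'
        f'<x:p {_X}>non cml child-this is fine</x:p>'
        '</cml:unitList>'
    ),
    "viii": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<element-in-default-namespace/>'
        '<cml:unit/>'
        '</cml:unitList>'
    ),
    "ix": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<cml:unit>'
        f'<x:p {_X}>non cml child-this is fine</x:p>'
        '</cml:unit>'
        '</cml:unitList>'
    ),
    "x": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<cml:unit><element-in-default-namespace/></cml:unit>'
        '</cml:unitList>'
    ),
    "xi": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<cml:unit/>'
        '<cml:unit>'
        f'<x:p {_X}>multiple cml:unit elements are allowed</x:p>'
        '</cml:unit>'
        '</cml:unitList>'
    ),
}

# --------------------------------------------------------------------------
# simpleUnit corpus: valid documents expecting exactly one info finding
# --------------------------------------------------------------------------

_INFO_DOCS = {
    "i": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<cml:unit/><cml:molecule/>'
        '</cml:unitList>',
        "molecule",
        _el_step("unitList") + _el_step("molecule"),
    ),
    "ii": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<cml:unit><cml:atom/></cml:unit>'
        '</cml:unitList>',
        "atom",
        _el_step("unitList") + _el_step("unit") + _el_step("atom"),
    ),
    "iii": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<cml:unit/>'
        '<cml:unit><cml:bond/></cml:unit>'
        '</cml:unitList>',
        "bond",
        _el_step("unitList") + _el_step("unit", index=2) + _el_step("bond"),
    ),
    "iv": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<cml:unit>'
        f'<x:p {_X}>this is still going to be processed in unitList mode.'
        '<cml:bond/></x:p>'
        '</cml:unit>'
        '</cml:unitList>',
        "bond",
        _el_step("unitList") + _el_step("unit") + _el_step("p", XHTML_NS)
        + _el_step("bond"),
    ),
    "v": (
        f'<x:p {_X} {_CML} {_CONV}>'
        'the unitList need not be the root element'
        f'<cml:unitList {_SU}><cml:molecule/><cml:unit/></cml:unitList>'
        '</x:p>',
        "molecule",
        _el_step("p", XHTML_NS) + _el_step("unitList") + _el_step("molecule"),
    ),
}

# --------------------------------------------------------------------------
# simpleUnit corpus: invalid documents expecting exactly one error
# --------------------------------------------------------------------------

_DECLARING_ERROR = conv.MSG_DECLARING_TEMPLATE.format(
    name="simpleUnit", element="unitList"
)

_INVALID_DOCS = {
    "i": (
        f'<cml:molecule {_SU} {_CML} {_CONV}>'
        '<cml:unitList><cml:unit/></cml:unitList>'
        '</cml:molecule>',
        _DECLARING_ERROR,
        _el_step("molecule") + _attr_step("convention"),
    ),
    "ii": (
        f'<x:p {_X} {_CML} {_CONV}>'
        f'<cml:molecule {_SU}>'
        '<cml:unitList><cml:unit/></cml:unitList>'
        '</cml:molecule>'
        '</x:p>',
        _DECLARING_ERROR,
        None,
    ),
    "iii": (
        f'<cml:unitList {_SU} {_CML} {_CONV}/>',
        conv.MSG_UNITLIST_NEEDS_UNIT,
        None,
    ),
    "iv": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<!-- not valid, a unitList must have at least one unit child -->'
        '</cml:unitList>',
        conv.MSG_UNITLIST_NEEDS_UNIT,
        None,
    ),
    "v": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        f'<x:p {_X}>no unit child of unitList</x:p>'
        '</cml:unitList>',
        conv.MSG_UNITLIST_NEEDS_UNIT,
        None,
    ),
    "vi": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        f'<x:p {_X}><cml:unit/>'
        'This unit is not a direct child of unitList and therefore should '
        'cause an error.</x:p>'
        '</cml:unitList>',
        conv.MSG_UNITLIST_NEEDS_UNIT,
        None,
    ),
    "vii": (
        f'<cml:unitList {_SU} {_CML} {_CONV}>'
        '<cml:unitList>'
        '<cml:unit>'
        f'<x:p {_X}>the outer unitList does not have at least one unit child</x:p>'
        '</cml:unit>'
        '</cml:unitList>'
        '</cml:unitList>',
        conv.MSG_UNITLIST_NEEDS_UNIT,
        None,
    ),
}

# --------------------------------------------------------------------------
# schema tests: namespace wildcards of the relaxed content model
# --------------------------------------------------------------------------

_SCHEMA_DOCS = {
    "i": (
        f'<cml:molecule {_CML}>'
        '<element-in-default-namespace>'
        'This is fine. The null prefix is not bound to anything and therefore '
        'is associated with the default namespace'
        '</element-in-default-namespace>'
        '</cml:molecule>',
        True,
    ),
    "ii": (
        f'<molecule xmlns="{CML_NS}" xmlns:other="http://www.example.net">'
        '<other:foreign-element>'
        'This is fine. The null prefix is bound to the CML namespace and the '
        '"other" prefix is bound to a non-CML namespace'
        '</other:foreign-element>'
        '</molecule>',
        True,
    ),
    "iii": (
        f'<molecule xmlns="{CML_NS}">'
        '<non-cml-element>'
        'This is invalid. The null prefix is bound to the CML namespace and '
        'the element "non-cml-element" is not part of this'
        '</non-cml-element>'
        '</molecule>',
        False,
    ),
    "iv": (
        f'<cml:molecule {_CML}>'
        '<cml:non-cml-element>'
        'This is invalid. The cml prefix is bound to the CML namespace and '
        'the element "non-cml-element" does not form part of this'
        '</cml:non-cml-element>'
        '</cml:molecule>',
        False,
    ),
}

_VOCAB_ERROR = 'the element "non-cml-element" is not part of the CML schema'

# --------------------------------------------------------------------------
# the 5-atom reference molecule for the chemistry operations
# --------------------------------------------------------------------------

MOL5_DOCUMENT = (
    f'<cml:molecule id="mol5" {_CML}>'
    '<cml:atomArray>'
    '<cml:atom id="a1" elementType="C" x3="0.0" y3="0.0" z3="0.0"/>'
    '<cml:atom id="a2" elementType="N" x3="0.0" y3="1.3" z3="0.0"/>'
    '<cml:atom id="a3" elementType="O" x3="1.0" y3="2.2" z3="0.0"/>'
    '<cml:atom id="a4" elementType="H" x3="0.85" y3="-0.54" z3="0.5"/>'
    '<cml:atom id="a5" elementType="H" x3="-0.85" y3="-0.54" z3="0.5"/>'
    '</cml:atomArray>'
    '</cml:molecule>'
).encode("utf-8")

# --------------------------------------------------------------------------
# synthetic convention bases (every rule passing)
# --------------------------------------------------------------------------

_MOLECULAR = 'convention="conventions:molecular"'
_COMPCHEM = 'convention="conventions:compchem"'
_UNITDICT = 'convention="conventions:unit-dictionary"'
_COMPCHEM_DICT = f'xmlns:compchem="{conv.COMPCHEM_DICT_NS}"'

_SYNTHETIC_BASES = {
    "molecular-flat": (
        f'<cml:molecule {_MOLECULAR} {_CML} {_CONV}>'
        '<cml:atomArray>'
        '<cml:atom id="a1" elementType="C" x3="0.0" y3="0.0" z3="0.0"/>'
        '<cml:atom id="a2" elementType="O" x3="1.2" y3="0.0" z3="0.0"/>'
        '</cml:atomArray>'
        '<cml:bondArray>'
        '<cml:bond atomRefs2="a1 a2" order="D"/>'
        '</cml:bondArray>'
        '</cml:molecule>'
    ),
    "molecular-simple": (
        f'<cml:molecule {_MOLECULAR} {_CML} {_CONV}>'
        '<cml:atomArray>'
        '<cml:atom id="a1" elementType="C"/>'
        '<cml:atom id="a2" elementType="O"/>'
        '</cml:atomArray>'
        '</cml:molecule>'
    ),
    "molecular-name": (
        f'<cml:molecule {_MOLECULAR} {_CML} {_CONV}>'
        '<cml:name>water</cml:name>'
        '</cml:molecule>'
    ),
    "molecular-nested": (
        f'<cml:molecule {_MOLECULAR} {_CML} {_CONV}>'
        '<cml:molecule>'
        '<cml:atomArray><cml:atom id="b1" elementType="N"/></cml:atomArray>'
        '</cml:molecule>'
        '<cml:molecule>'
        '<cml:atomArray><cml:atom id="b2" elementType="O"/></cml:atomArray>'
        '</cml:molecule>'
        '</cml:molecule>'
    ),
    "compchem-base": (
        f'<cml:module {_COMPCHEM} {_CML} {_CONV} {_COMPCHEM_DICT}>'
        '<cml:module dictRef="compchem:initialization">'
        f'<cml:molecule {_MOLECULAR}>'
        '<cml:atomArray>'
        '<cml:atom id="a1" elementType="C" x3="0.0" y3="0.0" z3="0.0"/>'
        '<cml:atom id="a2" elementType="H" x3="1.1" y3="0.0" z3="0.0"/>'
        '</cml:atomArray>'
        '</cml:molecule>'
        '</cml:module>'
        '</cml:module>'
    ),
    "unitdict-base": (
        f'<cml:dictionary {_UNITDICT} title="SI units" {_CML} {_CONV}>'
        '<cml:unitList>'
        '<cml:unit id="u1"/>'
        '</cml:unitList>'
        '<cml:entry id="e1">'
        '<cml:definition>the SI unit of length</cml:definition>'
        '<cml:description>base unit, symbol m</cml:description>'
        '</cml:entry>'
        '</cml:dictionary>'
    ),
}

# --------------------------------------------------------------------------
# mutations: rule_id -> (base id, tree edit, expected finding, result)
# --------------------------------------------------------------------------


def _q(local: str) -> str:
    return "{%s}%s" % (CML_NS, local)


def _find(tree, local: str, which: int = 0):
    hits = tree.findall(".//" + _q(local))
    if tree.tag == _q(local):
        hits = [tree] + hits
    if which >= len(hits):
        raise ValueError(f"base document has no {local}[{which}]")
    return hits[which]


def _remove(element) -> None:
    element.getparent().remove(element)


def _mut_remove_units(tree):
    for unit in tree.findall(_q("unit")):
        _remove(unit)


def _mut_rename_root_molecule(tree):
    tree.tag = _q("molecule")


def _mut_remove_name(tree):
    _remove(_find(tree, "name"))


def _mut_add_atomarray_to_outer(tree):
    array = etree.SubElement(tree, _q("atomArray"))
    etree.SubElement(array, _q("atom"), {"id": "c1", "elementType": "C"})


def _mut_remove_atoms(tree):
    for atom in tree.findall(".//" + _q("atom")):
        _remove(atom)


def _mut_remove_bond(tree):
    _remove(_find(tree, "bond"))


def _mut_add_bondarray(tree):
    array = etree.SubElement(tree, _q("bondArray"))
    etree.SubElement(array, _q("bond"), {"atomRefs2": "a1 a2", "order": "S"})


def _mut_drop_atom_id(tree):
    del _find(tree, "atom", 1).attrib["id"]


def _mut_duplicate_atom_id(tree):
    _find(tree, "atom", 1).set("id", "a1")


def _mut_drop_z3(tree):
    del _find(tree, "atom").attrib["z3"]


def _mut_bond_self_reference(tree):
    _find(tree, "bond").set("atomRefs2", "a1 a1")


def _mut_bond_missing_atom(tree):
    _find(tree, "bond").set("atomRefs2", "a1 a9")


def _mut_retarget_dictref(tree):
    _find(tree, "module", 1).set("dictRef", "compchem:calculation")


def _mut_duplicate_molecule(tree):
    molecule = _find(tree, "molecule")
    molecule.getparent().append(copy.deepcopy(molecule))


def _mut_drop_molecular_declaration(tree):
    del _find(tree, "molecule").attrib["convention"]


def _mut_replace_atomarray_with_name(tree):
    molecule = _find(tree, "molecule")
    _remove(_find(tree, "atomArray"))
    name = etree.SubElement(molecule, _q("name"))
    name.text = "methane fragment"


def _mut_strip_coordinates(tree):
    atom = _find(tree, "atom")
    for coord in ("x3", "y3", "z3"):
        del atom.attrib[coord]


def _mut_drop_unit_id(tree):
    del _find(tree, "unit").attrib["id"]


def _mut_remove_definition(tree):
    _remove(_find(tree, "definition"))


def _mut_add_description(tree):
    entry = _find(tree, "entry")
    extra = etree.SubElement(entry, _q("description"))
    extra.text = "a second description"


def _mut_drop_dictionary_title(tree):
    del tree.attrib["title"]


@dataclass(frozen=True)
class _MutationRule:
    base_id: str
    edit: Callable
    finding: Optional[ExpectedFinding]
    result: ValidationResult


def _err(message: str) -> ExpectedFinding:
    return expect(Severity.ERROR, message)


MUTATION_RULES = {
    "none": None,
    "simpleunit.unit-child": _MutationRule(
        "appendixB-valid-i", _mut_remove_units,
        _err(conv.MSG_UNITLIST_NEEDS_UNIT), ValidationResult.INVALID),
    "simpleunit.declaring-element": _MutationRule(
        "appendixB-valid-i", _mut_rename_root_molecule,
        _err(_DECLARING_ERROR), ValidationResult.INVALID),
    "molecular.required-children": _MutationRule(
        "molecular-name", _mut_remove_name,
        _err(conv.MSG_MOLECULE_REQUIRED_CHILDREN), ValidationResult.INVALID),
    "molecular.molecule-atomarray-exclusive": _MutationRule(
        "molecular-nested", _mut_add_atomarray_to_outer,
        _err(conv.MSG_MOLECULE_EXCLUSIVE_CHILDREN), ValidationResult.INVALID),
    "molecular.atomarray-atom": _MutationRule(
        "molecular-simple", _mut_remove_atoms,
        _err(conv.MSG_ATOMARRAY_NEEDS_ATOM), ValidationResult.INVALID),
    "molecular.bondarray-bond": _MutationRule(
        "molecular-flat", _mut_remove_bond,
        _err(conv.MSG_BONDARRAY_NEEDS_BOND), ValidationResult.INVALID),
    "molecular.bondarray-single": _MutationRule(
        "molecular-flat", _mut_add_bondarray,
        _err(conv.MSG_SINGLE_BONDARRAY), ValidationResult.INVALID),
    "molecular.atom-id": _MutationRule(
        "molecular-simple", _mut_drop_atom_id,
        _err(conv.MSG_ATOM_NEEDS_ID), ValidationResult.INVALID),
    "molecular.atom-id-unique": _MutationRule(
        "molecular-simple", _mut_duplicate_atom_id,
        _err(conv.msg_atom_id_not_unique("a1")), ValidationResult.INVALID),
    "molecular.coordinates": _MutationRule(
        "molecular-flat", _mut_drop_z3,
        _err(conv.MSG_ATOM_COORDS_TOGETHER), ValidationResult.INVALID),
    "molecular.bond-distinct-atoms": _MutationRule(
        "molecular-flat", _mut_bond_self_reference,
        _err(conv.MSG_BOND_DISTINCT_ATOMS), ValidationResult.INVALID),
    "molecular.bond-atoms-exist": _MutationRule(
        "molecular-flat", _mut_bond_missing_atom,
        _err(conv.msg_bond_atom_missing("a9")), ValidationResult.INVALID),
    "compchem.initialization-module": _MutationRule(
        "compchem-base", _mut_retarget_dictref,
        _err(conv.MSG_INIT_MODULE_REQUIRED), ValidationResult.INVALID),
    "compchem.single-molecule": _MutationRule(
        "compchem-base", _mut_duplicate_molecule,
        _err(conv.MSG_INIT_ONE_MOLECULE), ValidationResult.INVALID),
    "compchem.molecular-declared": _MutationRule(
        "compchem-base", _mut_drop_molecular_declaration,
        _err(conv.MSG_DECLARE_MOLECULAR), ValidationResult.INVALID),
    "compchem.atomarray": _MutationRule(
        "compchem-base", _mut_replace_atomarray_with_name,
        _err(conv.MSG_INIT_NEEDS_ATOMARRAY), ValidationResult.INVALID),
    "compchem.atom-coordinates": _MutationRule(
        "compchem-base", _mut_strip_coordinates,
        _err(conv.MSG_INIT_ATOMS_3D), ValidationResult.INVALID),
    "unitdict.unit-id": _MutationRule(
        "unitdict-base", _mut_drop_unit_id,
        _err(conv.MSG_UNIT_NEEDS_ID), ValidationResult.INVALID),
    "unitdict.entry-definition": _MutationRule(
        "unitdict-base", _mut_remove_definition,
        _err(conv.MSG_ENTRY_NEEDS_DEFINITION), ValidationResult.INVALID),
    "unitdict.entry-description": _MutationRule(
        "unitdict-base", _mut_add_description,
        _err(conv.MSG_ENTRY_ONE_DESCRIPTION), ValidationResult.INVALID),
    "unitdict.dictionary-title": _MutationRule(
        "unitdict-base", _mut_drop_dictionary_title,
        ExpectedFinding(Severity.WARNING, re.escape(conv.MSG_DICTIONARY_NEEDS_TITLE)),
        ValidationResult.VALID_WITH_WARNINGS),
}

#: which handler rules a fixture exercises on the passing side; used by the
#: coverage tests to pair every failing mutant with a passing document
RULE_BASES = {
    rule_id: rule.base_id
    for rule_id, rule in MUTATION_RULES.items()
    if rule is not None
}


def generate_fixture_corpus() -> List[Fixture]:
    """Build the complete corpus (appendix documents, schema tests, the
    reference molecule, synthetic bases and all mutation-derived mutants)."""
    fixtures: List[Fixture] = []
    for rid, doc in _VALID_DOCS.items():
        fixtures.append(
            _fx(f"appendixB-valid-{rid}", doc, ValidationResult.VALID,
                provenance="appendixB-valid")
        )
    for rid, (doc, name, location) in _INFO_DOCS.items():
        fixtures.append(
            _fx(
                f"appendixB-info-{rid}", doc, ValidationResult.VALID,
                [expect(Severity.INFO, _ignored_message(name), location)],
                provenance="appendixB-info",
            )
        )
    for rid, (doc, message, location) in _INVALID_DOCS.items():
        fixtures.append(
            _fx(
                f"appendixB-invalid-{rid}", doc, ValidationResult.INVALID,
                [expect(Severity.ERROR, message, location)],
                provenance="appendixB-invalid",
            )
        )
    for rid, (doc, is_valid) in _SCHEMA_DOCS.items():
        if is_valid:
            fixtures.append(
                _fx(f"schema-test-{rid}", doc, ValidationResult.VALID,
                    provenance="schema-test", stage="schema")
            )
        else:
            fixtures.append(
                _fx(
                    f"schema-test-{rid}", doc, ValidationResult.INVALID,
                    [expect(Severity.ERROR, _VOCAB_ERROR)],
                    provenance="schema-test", stage="schema",
                )
            )
    fixtures.append(
        _fx(
            "mol5", MOL5_DOCUMENT, ValidationResult.VALID_WITH_WARNINGS,
            [expect(Severity.WARNING, conv.MSG_NO_CONVENTIONS)],
        )
    )
    for base_id, doc in _SYNTHETIC_BASES.items():
        fixtures.append(_fx(base_id, doc, ValidationResult.VALID))
    by_id = {f.id: f for f in fixtures}
    for rule_id, rule in MUTATION_RULES.items():
        if rule is None:
            continue
        fixtures.append(mutate_fixture(by_id[rule.base_id], rule_id))
    return fixtures


def write_corpus(directory) -> "pathlib.Path":
    """Write the corpus to *directory* as ``.cml`` files plus a YAML
    manifest (id, provenance, stage, expected result and findings)."""
    import pathlib

    import yaml

    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = []
    for fixture in generate_fixture_corpus():
        (directory / f"{fixture.id}.cml").write_bytes(fixture.document)
        manifest.append(
            {
                "id": fixture.id,
                "file": f"{fixture.id}.cml",
                "provenance": fixture.provenance,
                "stage": fixture.stage,
                "expected_result": fixture.expected_result.value,
                "expected_findings": [
                    {
                        "severity": f.severity.tag,
                        "message_pattern": f.message_pattern,
                        "location": f.location,
                    }
                    for f in fixture.expected_findings
                ],
            }
        )
    manifest_path = directory / "manifest.yaml"
    manifest_path.write_text(yaml.safe_dump(manifest, sort_keys=False))
    return manifest_path


def random_molecule_tree(rng, max_depth: int = 4) -> MoleculeView:
    """A random nested molecule tree for charge-aggregation properties.

    Depth at most *max_depth*; formal charges drawn from [-3, 3] (and left
    unset about half the time), counts from {1, 2, 3}, unit occupancy, so
    the aggregate charge is always integral.
    """
    charge = rng.randint(-3, 3) if rng.random() < 0.5 else None
    mol = MoleculeView(
        formal_charge=charge,
        count=float(rng.choice((1, 2, 3))),
    )
    for i in range(rng.randint(0, 3)):
        atom_charge = rng.randint(-3, 3) if rng.random() < 0.7 else None
        mol.atoms.append(
            AtomView(
                id=f"a{i}",
                element_type=rng.choice(("C", "N", "O", "H")),
                formal_charge=atom_charge,
                count=float(rng.choice((1, 2, 3))),
            )
        )
    if max_depth > 1:
        for _ in range(rng.randint(0, 2)):
            mol.child_molecules.append(random_molecule_tree(rng, max_depth - 1))
    return mol


def mutate_fixture(base: Fixture, rule_id: str) -> Fixture:
    """Minimally edit *base* so that it violates exactly the named rule.

    ``rule_id`` ``"none"`` is the identity; unknown rule ids raise
    ``KeyError``.  The base must be a VALID fixture containing the
    constructs the rule speaks about.
    """
    rule = MUTATION_RULES[rule_id]
    if rule is None:
        return base
    if base.expected_result is not ValidationResult.VALID:
        raise ValueError("mutation bases must be VALID fixtures")
    if base.id != rule.base_id:
        raise ValueError(
            f"rule {rule_id!r} mutates fixture {rule.base_id!r}, got {base.id!r}"
        )
    tree = etree.fromstring(base.document)
    rule.edit(tree)
    return Fixture(
        id=f"mutant-{rule_id}",
        document=etree.tostring(tree),
        expected_result=rule.result,
        expected_findings=(rule.finding,),
        provenance="synthetic",
        stage="full",
    )
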