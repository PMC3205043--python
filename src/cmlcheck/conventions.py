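"""Convention discovery, scoping and the built-in convention handlers.

A convention is declared by a ``convention`` attribute whose QName value
expands to the convention's URI; its scope is the declaring element and
all descendants.  Traversal mirrors the template/mode style of rule
engines: outside any scope the walker descends silently; inside a scope
the active handler examines every CML element it meets (foreign and
no-namespace elements are passed through without findings); a nested
declaration switches handlers for the inner subtree.

Built-in handlers: simpleUnit (unit lists), molecular (small molecules),
compchem (computational-chemistry jobs) and unit-dictionary
(unit/entry dictionaries).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

from .document import (
    CML_NS,
    CONVENTION_NS,
    DocNode,
    UnboundPrefixError,
    XmlName,
    expand_qname,
    location_path,
)
from .report import Finding, error, info, warning

SIMPLEUNIT_URI = CONVENTION_NS + "simpleUnit"
MOLECULAR_URI = CONVENTION_NS + "molecular"
COMPCHEM_URI = CONVENTION_NS + "compchem"
UNIT_DICTIONARY_URI = CONVENTION_NS + "unit-dictionary"

#: dictionary namespace used by compchem dictRef values (note: no "www")
COMPCHEM_DICT_NS = "http://xml-cml.org/dictionary/compchem/"

MSG_UNITLIST_NEEDS_UNIT = "A unit list MUST contain child cml:unit elements"
MSG_NO_CONVENTIONS = "no conventions are declared in the document"

MSG_DECLARING_TEMPLATE = (
    "the only valid cml element that can specify the {name} convention "
    'is "{element}"'
)
MSG_MOLECULE_REQUIRED_CHILDREN = (
    "A molecule MUST contain at least one of the following elements: "
    "molecule, atomArray, name, label, formula"
)
MSG_MOLECULE_EXCLUSIVE_CHILDREN = (
    "A molecule MUST NOT contain both a child molecule and a child atomArray"
)
MSG_SINGLE_BONDARRAY = "A molecule MAY contain at most one bondArray child"
MSG_ATOMARRAY_NEEDS_ATOM = "An atomArray MUST contain at least one atom"
MSG_BONDARRAY_NEEDS_BOND = "A bondArray MUST contain at least one bond"
MSG_ATOM_NEEDS_ID = "An atom MUST have an id attribute"
MSG_ATOM_COORDS_TOGETHER = (
    "an atom with an x3 coordinate MUST also have y3 and z3 "
    "(3-D coordinates occur together)"
)
MSG_BOND_DISTINCT_ATOMS = "A bond MUST contain references to two distinct atoms"
MSG_INIT_MODULE_REQUIRED = (
    "There MUST be an initialization module (a module whose dictRef resolves "
    'to the compchem dictionary entry "initialization")'
)
MSG_INIT_ONE_MOLECULE = (
    "The initialization module MUST contain exactly one molecule"
)
MSG_DECLARE_MOLECULAR = (
    "molecules MUST declare that they conform to the molecular convention "
    '(convention = "conventions:molecular")'
)
MSG_INIT_NEEDS_ATOMARRAY = (
    "The molecule in the initialization module is REQUIRED to have an "
    "atomArray child"
)
MSG_INIT_ATOMS_3D = (
    "All the atoms in the molecule in the initialization module MUST have "
    "three dimensional coordinates"
)
MSG_UNIT_NEEDS_ID = "A unit MUST have an id attribute"
MSG_ENTRY_NEEDS_DEFINITION = "An entry MUST contain a definition child"
MSG_ENTRY_ONE_DESCRIPTION = "An entry MAY contain at most one description"
MSG_DICTIONARY_NEEDS_TITLE = "A dictionary SHOULD have a title attribute"


def msg_atom_id_not_unique(atom_id: str) -> str:
    return (
        f'the atom id "{atom_id}" is not unique within the eldest containing '
        "molecule"
    )


def msg_bond_atom_missing(atom_id: str) -> str:
    return (
        f'bond references atom "{atom_id}" which does not exist in the eldest '
        "containing molecule"
    )

IGNORED_TEMPLATE = (
    "{name} is not a part of the {uri} convention and may be "
    "ignored by some processors."
)


def _ignored(node: DocNode, uri: str) -> Finding:
    return info(
        IGNORED_TEMPLATE.format(name=node.name.local_name, uri=uri),
        location_path(node),
    )


def _declaring_element_error(handler: "ConventionHandler", attr: DocNode) -> Finding:
    allowed = next(iter(handler.admissible_declaring_elements))
    return error(
        MSG_DECLARING_TEMPLATE.format(name=handler.name, element=allowed),
        location_path(attr),
    )


def _direct_cml_children(node: DocNode, local_name: str) -> list:
    return [c for c in node.element_children() if c.is_cml(local_name)]


def eldest_containing_molecule(node: DocNode) -> Optional[DocNode]:
    """The outermost ancestor-or-self ``cml:molecule`` of *node*."""
    eldest = None
    cur: Optional[DocNode] = node
    while cur is not None:
        if cur.is_cml("molecule"):
            eldest = cur
        cur = cur.parent
    return eldest


@dataclass(frozen=True)
class ConventionBinding:
    """An element together with the expanded URI of the convention it declares."""

    element: DocNode
    convention_uri: str


class ConventionHandler:
    """Base class: per-node rules plus scope-entry rules for one convention.

    ``admissible_declaring_elements`` restricts which CML element may carry
    the declaration (None means any); ``member_elements`` are the CML
    elements the convention speaks about — other CML elements inside the
    scope draw an informational "may be ignored" finding when
    ``inform_on_non_members`` is set.
    """

    uri: str = ""
    name: str = ""
    admissible_declaring_elements: Optional[frozenset] = None
    member_elements: frozenset = frozenset()
    inform_on_non_members: bool = True

    def enter_scope(self, scope_root: DocNode) -> List[Finding]:
        """Scope-level checks run once when the declaration is encountered."""
        return []

    def visit_node(self, node: DocNode) -> List[Finding]:
        """Per-element checks; called for every element in the scope."""
        if not node.is_cml():
            return []
        if node.name.local_name in self.member_elements:
            return self.visit_member(node)
        if self.inform_on_non_members:
            return [_ignored(node, self.uri)]
        return []

    def visit_member(self, node: DocNode) -> List[Finding]:
        return []


class SimpleUnitHandler(ConventionHandler):
    """unitList elements must have at least one direct cml:unit child."""

    uri = SIMPLEUNIT_URI
    name = "simpleUnit"
    admissible_declaring_elements = frozenset({"unitList"})
    member_elements = frozenset({"unitList", "unit"})

    def visit_member(self, node: DocNode) -> List[Finding]:
        if node.name.local_name == "unitList":
            if not _direct_cml_children(node, "unit"):
                return [error(MSG_UNITLIST_NEEDS_UNIT, location_path(node))]
        return []


class MolecularHandler(ConventionHandler):
    """Small-molecule rules: required children, atom ids, coordinates, bonds."""

    uri = MOLECULAR_URI
    name = "molecular"
    admissible_declaring_elements = frozenset({"molecule"})
    member_elements = frozenset(
        {"molecule", "atomArray", "atom", "bondArray", "bond", "name", "label", "formula"}
    )

    REQUIRED_CHILD_SET = ("molecule", "atomArray", "name", "label", "formula")

    def visit_member(self, node: DocNode) -> List[Finding]:
        local = node.name.local_name
        if local == "molecule":
            return self._check_molecule(node)
        if local == "atomArray":
            if not _direct_cml_children(node, "atom"):
                return [error(MSG_ATOMARRAY_NEEDS_ATOM, location_path(node))]
        if local == "bondArray":
            if not _direct_cml_children(node, "bond"):
                return [error(MSG_BONDARRAY_NEEDS_BOND, location_path(node))]
        if local == "atom":
            return self._check_atom(node)
        if local == "bond":
            return self._check_bond(node)
        return []

    def _check_molecule(self, node: DocNode) -> List[Finding]:
        findings = []
        if not any(
            c for c in node.element_children()
            if c.is_cml() and c.name.local_name in self.REQUIRED_CHILD_SET
        ):
            findings.append(
                error(MSG_MOLECULE_REQUIRED_CHILDREN, location_path(node))
            )
        if _direct_cml_children(node, "molecule") and _direct_cml_children(node, "atomArray"):
            findings.append(
                error(MSG_MOLECULE_EXCLUSIVE_CHILDREN, location_path(node))
            )
        if len(_direct_cml_children(node, "bondArray")) > 1:
            findings.append(error(MSG_SINGLE_BONDARRAY, location_path(node)))
        return findings

    def _check_atom(self, node: DocNode) -> List[Finding]:
        findings = []
        atom_id = node.attribute_value("id")
        if atom_id is None:
            findings.append(error(MSG_ATOM_NEEDS_ID, location_path(node)))
        else:
            eldest = eldest_containing_molecule(node)
            if eldest is not None:
                first = next(
                    a
                    for a in eldest.iter_elements()
                    if a.is_cml("atom") and a.attribute_value("id") == atom_id
                )
                if first is not node:
                    findings.append(
                        error(msg_atom_id_not_unique(atom_id), location_path(node))
                    )
        present = [c for c in ("x3", "y3", "z3") if node.attribute(c) is not None]
        if present and len(present) < 3:
            findings.append(
                error(MSG_ATOM_COORDS_TOGETHER, location_path(node))
            )
        return findings

    def _check_bond(self, node: DocNode) -> List[Finding]:
        refs = node.attribute_value("atomRefs2")
        tokens = refs.split() if refs is not None else []
        if len(tokens) != 2 or tokens[0] == tokens[1]:
            return [error(MSG_BOND_DISTINCT_ATOMS, location_path(node))]
        eldest = eldest_containing_molecule(node)
        known = set()
        if eldest is not None:
            known = {
                a.attribute_value("id")
                for a in eldest.iter_elements()
                if a.is_cml("atom")
            }
        missing = [t for t in tokens if t not in known]
        if missing:
            return [error(msg_bond_atom_missing(missing[0]), location_path(node))]
        return []


class CompchemHandler(ConventionHandler):
    """Computational-chemistry job rules, layered over molecular.

    Requires an initialization module (a module whose dictRef expands to the
    compchem dictionary's "initialization" entry) holding exactly one
    molecule that itself declares the molecular convention, has an atomArray
    and whose atoms all carry 3-D coordinates.  The molecule's own molecular
    declaration engages the molecular handler as a nested scope.
    """

    uri = COMPCHEM_URI
    name = "compchem"
    admissible_declaring_elements = None
    inform_on_non_members = False

    _INIT_ENTRY = XmlName(COMPCHEM_DICT_NS, "initialization")

    def _is_initialization_module(self, node: DocNode) -> bool:
        if not node.is_cml("module"):
            return False
        dict_ref = node.attribute_value("dictRef")
        if dict_ref is None:
            return False
        try:
            return expand_qname(dict_ref, node) == self._INIT_ENTRY
        except UnboundPrefixError:
            return False

    def enter_scope(self, scope_root: DocNode) -> List[Finding]:
        findings = []
        init_modules = [
            n for n in scope_root.iter_elements() if self._is_initialization_module(n)
        ]
        if not init_modules:
            findings.append(
                error(MSG_INIT_MODULE_REQUIRED, location_path(scope_root))
            )
        for module in init_modules:
            molecules = _direct_cml_children(module, "molecule")
            if len(molecules) != 1:
                findings.append(
                    error(MSG_INIT_ONE_MOLECULE, location_path(module))
                )
                continue
            findings.extend(self._check_molecule(molecules[0]))
        return findings

    def _check_molecule(self, molecule: DocNode) -> List[Finding]:
        findings = []
        declared = molecule.attribute_value("convention")
        ok = False
        if declared is not None:
            try:
                name = expand_qname(declared, molecule)
                ok = name.namespace_uri + name.local_name == MOLECULAR_URI
            except UnboundPrefixError:
                ok = False
        if not ok:
            findings.append(error(MSG_DECLARE_MOLECULAR, location_path(molecule)))
        if not _direct_cml_children(molecule, "atomArray"):
            findings.append(
                error(MSG_INIT_NEEDS_ATOMARRAY, location_path(molecule))
            )
        for atom in molecule.iter_elements():
            if not atom.is_cml("atom"):
                continue
            if any(atom.attribute(c) is None for c in ("x3", "y3", "z3")):
                findings.append(error(MSG_INIT_ATOMS_3D, location_path(atom)))
        return findings


class UnitDictionaryHandler(ConventionHandler):
    """Dictionary rules: entries need definitions, units need ids."""

    uri = UNIT_DICTIONARY_URI
    name = "unit-dictionary"
    admissible_declaring_elements = frozenset({"dictionary"})
    member_elements = frozenset(
        {"dictionary", "entry", "definition", "description", "unit", "unitList", "unitType"}
    )

    def visit_member(self, node: DocNode) -> List[Finding]:
        local = node.name.local_name
        findings = []
        if local == "entry":
            if not _direct_cml_children(node, "definition"):
                findings.append(
                    error(MSG_ENTRY_NEEDS_DEFINITION, location_path(node))
                )
            if len(_direct_cml_children(node, "description")) > 1:
                findings.append(
                    error(MSG_ENTRY_ONE_DESCRIPTION, location_path(node))
                )
        elif local == "unit":
            if node.attribute("id") is None:
                findings.append(error(MSG_UNIT_NEEDS_ID, location_path(node)))
        elif local == "dictionary":
            if node.attribute("title") is None:
                findings.append(
                    warning(MSG_DICTIONARY_NEEDS_TITLE, location_path(node))
                )
        return findings


class ConventionRegistry:
    """URI -> handler mapping; unknown URIs draw an info, not an error."""

    def __init__(self, handlers=()):
        self._handlers = {}
        for handler in handlers:
            self.register(handler)

    def register(self, handler: ConventionHandler) -> None:
        self._handlers[handler.uri] = handler

    def get(self, uri: str) -> Optional[ConventionHandler]:
        return self._handlers.get(uri)

    def __contains__(self, uri: str) -> bool:
        return uri in self._handlers


def default_registry() -> ConventionRegistry:
    return ConventionRegistry(
        [
            SimpleUnitHandler(),
            MolecularHandler(),
            CompchemHandler(),
            UnitDictionaryHandler(),
        ]
    )


def _expanded_convention_uri(attr_value: str, node: DocNode) -> str:
    name = expand_qname(attr_value, node)
    return name.namespace_uri + name.local_name


def discover_conventions(root: DocNode) -> Tuple[List[ConventionBinding], List[Finding]]:
    """All convention declarations in document order.

    Zero declarations draw a warning; a declaration whose prefix is unbound
    (or that expands to no namespace) draws an error and yields no binding.
    """
    bindings: List[ConventionBinding] = []
    findings: List[Finding] = []
    declared = False
    for node in root.iter_elements():
        attr = node.attribute("convention")
        if attr is None:
            continue
        declared = True
        try:
            name = expand_qname(attr.value, node)
        except UnboundPrefixError as exc:
            findings.append(error(str(exc), location_path(attr)))
            continue
        if not name.namespace_uri:
            findings.append(
                error(
                    f"convention value {attr.value!r} does not expand to a "
                    "namespaced URI",
                    location_path(attr),
                )
            )
            continue
        bindings.append(ConventionBinding(node, name.namespace_uri + name.local_name))
    if not declared:
        findings.append(warning(MSG_NO_CONVENTIONS))
    return bindings, findings


def run_conventions(
    root: DocNode, registry: Optional[ConventionRegistry] = None
) -> List[Finding]:
    """Traverse the document, engaging handlers at their declarations.

    Declarations whose QName cannot be expanded are skipped silently here
    (:func:`discover_conventions` owns that error); declarations of unknown
    conventions draw an info and their subtree is traversed out of mode;
    declarations on an inadmissible element draw an error at the convention
    attribute and are likewise traversed out of mode.  Declarations on
    non-CML elements are ignored, as a CML-aware rule engine never matches
    them.
    """
    registry = registry or default_registry()
    findings: List[Finding] = []

    def walk(node: DocNode, handler: Optional[ConventionHandler], at_root: bool) -> None:
        attr = node.attribute("convention")
        if attr is not None and not at_root and node.is_cml():
            declare(node, attr)
            return
        if handler is not None:
            findings.extend(handler.visit_node(node))
        for child in node.element_children():
            walk(child, handler, False)

    def declare(node: DocNode, attr: DocNode) -> None:
        try:
            uri = _expanded_convention_uri(attr.value, node)
        except (UnboundPrefixError, ValueError):
            walk_children_out_of_mode(node)
            return
        handler = registry.get(uri)
        if handler is None:
            findings.append(
                info(
                    f"the convention {uri} is not known to this validator and "
                    "its rules were not checked",
                    location_path(attr),
                )
            )
            walk_children_out_of_mode(node)
            return
        admissible = handler.admissible_declaring_elements
        if admissible is not None and node.name.local_name not in admissible:
            findings.append(_declaring_element_error(handler, attr))
            walk_children_out_of_mode(node)
            return
        findings.extend(handler.enter_scope(node))
        walk(node, handler, True)

    def walk_children_out_of_mode(node: DocNode) -> None:
        for child in node.element_children():
            walk(child, None, False)

    walk(root, None, False)
    return findings


# -- single-scope entry points (one per built-in convention) -----------------


def _run_single(binding: ConventionBinding, expected_uri: str) -> List[Finding]:
    if binding.convention_uri != expected_uri:
        raise ValueError(
            f"binding declares {binding.convention_uri}, expected {expected_uri}"
        )
    registry = default_registry()
    handler = registry.get(expected_uri)
    findings: List[Finding] = []
    attr = binding.element.attribute("convention")
    admissible = handler.admissible_declaring_elements
    if admissible is not None and (
        not binding.element.is_cml()
        or binding.element.name.local_name not in admissible
    ):
        return [_declaring_element_error(handler, attr or binding.element)]
    findings.extend(handler.enter_scope(binding.element))

    def walk(node: DocNode, at_root: bool) -> None:
        if not at_root and node.attribute("convention") is not None and node.is_cml():
            # nested declaration: defer to the full engine's semantics
            findings.extend(run_conventions(node))
            return
        findings.extend(handler.visit_node(node))
        for child in node.element_children():
            walk(child, False)

    walk(binding.element, True)
    return findings


def validate_simpleunit(scope: ConventionBinding) -> List[Finding]:
    """Apply the simpleUnit rules to one declared scope."""
    return _run_single(scope, SIMPLEUNIT_URI)


def validate_molecular(scope: ConventionBinding) -> List[Finding]:
    """Apply the molecular rules to one declared scope."""
    return _run_single(scope, MOLECULAR_URI)


def validate_compchem(scope: ConventionBinding) -> List[Finding]:
    """Apply the compchem rules to one declared scope."""
    return _run_single(scope, COMPCHEM_URI)


def validate_unit_dictionary(scope: ConventionBinding) -> List[Finding]:
    """Apply the unit-dictionary rules to one declared scope."""
    return _run_single(scope, UNIT_DICTIONARY_URI)
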