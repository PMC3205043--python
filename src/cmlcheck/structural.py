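"""Schema-level structural checks.

Four independent, side-effect-free passes over a parsed tree: CML
vocabulary membership, the relaxed no-mixed-content model, attribute
admissibility/datatypes, and deprecated constructs (numeric bond orders).
Foreign-namespace and no-namespace elements are never constrained.
"""

from __future__ import annotations

from typing import Iterable, List

from .document import CML_NS, DocNode, location_path
from .report import Finding, error, warning
from .vocabulary import ANY_CML, TEXT_ONLY, VocabularyTable, default_vocabulary

#: bond order tokens tolerated structurally but deprecated
DEPRECATED_BOND_ORDERS = ("1", "2", "3")


def _cml_elements(root: DocNode) -> Iterable[DocNode]:
    return (n for n in root.iter_elements() if n.name.namespace_uri == CML_NS)


def check_vocabulary(root: DocNode, vocab: VocabularyTable | None = None) -> List[Finding]:
    """One error per CML-namespace element absent from the vocabulary."""
    vocab = vocab or default_vocabulary()
    findings = []
    for node in _cml_elements(root):
        if node.name.local_name not in vocab:
            findings.append(
                error(
                    f'the element "{node.name.local_name}" is not part of the '
                    "CML schema",
                    location_path(node),
                )
            )
    return findings


def check_content_model(root: DocNode, vocab: VocabularyTable | None = None) -> List[Finding]:
    """Enforce no mixed content on CML elements; text-only elements may not
    hold element children.  Elements failing the vocabulary check are skipped."""
    vocab = vocab or default_vocabulary()
    findings = []
    for node in _cml_elements(root):
        spec = vocab.spec_for(node.name.local_name)
        if spec is None:
            continue
        has_elements = any(True for _ in node.element_children())
        has_text = any(
            c.kind == "text" and c.value.strip() for c in node.children
        )
        if spec.content == ANY_CML and has_elements and has_text:
            findings.append(
                error(
                    f'the element "{node.name.local_name}" has mixed content '
                    "(text and element children), which CML does not allow",
                    location_path(node),
                )
            )
        elif spec.content == TEXT_ONLY and has_elements:
            findings.append(
                error(
                    f'the element "{node.name.local_name}" has text-only '
                    "content and may not contain element children",
                    location_path(node),
                )
            )
    return findings


def check_attribute_types(root: DocNode, vocab: VocabularyTable | None = None) -> List[Finding]:
    """Check every no-namespace attribute on known CML elements against its
    spec; unknown attributes and datatype/enumeration violations are errors.
    Foreign-namespaced attributes are unconstrained (##other)."""
    vocab = vocab or default_vocabulary()
    findings = []
    for node in _cml_elements(root):
        spec = vocab.spec_for(node.name.local_name)
        if spec is None:
            continue
        for attr in node.attributes:
            if attr.name.namespace_uri:
                continue
            attr_spec = spec.attributes.get(attr.name.local_name)
            if attr_spec is None:
                findings.append(
                    error(
                        f'attribute "{attr.name.local_name}" is not allowed on '
                        f'element "{node.name.local_name}"',
                        location_path(attr),
                    )
                )
                continue
            problem = attr_spec.check_value(attr.value)
            if problem is not None:
                findings.append(error(problem, location_path(attr)))
            if attr_spec.datatype == "real-requiring-pair-group":
                missing = [
                    p for p in attr_spec.peers if node.attribute(p) is None
                ]
                if missing:
                    names = ", ".join(f'"{p}"' for p in missing)
                    findings.append(
                        error(
                            f'attribute "{attr.name.local_name}" requires the '
                            f"companion attribute(s) {names}",
                            location_path(attr),
                        )
                    )
    return findings


def check_deprecated(root: DocNode) -> List[Finding]:
    """Warnings for deprecated constructs: numeric bond orders '1'/'2'/'3'
    (aliases of 'S'/'D'/'T')."""
    findings = []
    for node in _cml_elements(root):
        if node.name.local_name != "bond":
            continue
        order = node.attribute("order")
        if order is not None and order.value in DEPRECATED_BOND_ORDERS:
            findings.append(
                warning(
                    f'numeric bond orders are deprecated: order = "{order.value}"',
                    location_path(order),
                )
            )
    return findings
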