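"""Namespace-aware document model for CML validation.

Parses XML into a navigable tree of :class:`DocNode` objects that carry
parent links, in-scope namespace bindings and same-name sibling positions —
everything the validators downstream need to expand QNames and to cite
error locations in the report's path dialect.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Optional, Union

from lxml import etree

#: The Chemical Markup Language namespace.
CML_NS = "http://www.xml-cml.org/schema"
#: Root of the built-in convention URIs.
CONVENTION_NS = "http://www.xml-cml.org/convention/"
#: Namespace of the validation report vocabulary.
REPORT_NS = "http://www.xml-cml.org/report/"

_QNAME_RE = re.compile(r"^(?:(?P<prefix>[^\s:]+):)?(?P<local>[^\s:]+)$")


class UnboundPrefixError(ValueError):
    """A QName token uses a prefix with no in-scope namespace binding."""

    def __init__(self, prefix: str, token: str):
        self.prefix = prefix
        self.token = token
        super().__init__(
            f"prefix {prefix!r} in {token!r} is not bound to a namespace"
        )


@dataclass(frozen=True)
class XmlName:
    """Expanded name: namespace URI (may be empty) plus local name."""

    namespace_uri: str
    local_name: str

    def __post_init__(self) -> None:
        if not self.local_name:
            raise ValueError("local_name must be non-empty")

    def __str__(self) -> str:  # pragma: no cover - debugging aid
        if self.namespace_uri:
            return "{%s}%s" % (self.namespace_uri, self.local_name)
        return self.local_name


@dataclass(frozen=True)
class WellFormednessFailure:
    """Returned by :func:`parse` when the input is not well-formed XML."""

    message: str


# prefix ("" for default) -> namespace URI
NamespaceContext = dict


@dataclass
class DocNode:
    """One node of the parsed document.

    ``kind`` is ``"element"``, ``"attribute"`` or ``"text"``.  Elements carry
    ordered ``children`` (elements and text nodes) and ``attributes``;
    ``same_name_index`` is 1 + the number of preceding siblings with the
    same expanded name, which is the positional predicate used in location
    paths.
    """

    kind: str
    name: Optional[XmlName] = None
    value: str = ""
    attributes: list["DocNode"] = field(default_factory=list)
    children: list["DocNode"] = field(default_factory=list)
    parent: Optional["DocNode"] = field(default=None, repr=False)
    same_name_index: int = 1
    # prefix -> URI bindings in scope at this element
    nsmap: NamespaceContext = field(default_factory=dict, repr=False)
    # backing lxml element, kept for serialization / XPath oracles
    backing: object = field(default=None, repr=False, compare=False)

    # -- convenience accessors -------------------------------------------------

    def is_element(self) -> bool:
        return self.kind == "element"

    def element_children(self) -> Iterator["DocNode"]:
        return (c for c in self.children if c.kind == "element")

    def attribute(self, local_name: str, namespace_uri: str = "") -> Optional["DocNode"]:
        """Return the attribute node with the given expanded name, if present."""
        for a in self.attributes:
            if a.name.local_name == local_name and a.name.namespace_uri == namespace_uri:
                return a
        return None

    def attribute_value(self, local_name: str, namespace_uri: str = "") -> Optional[str]:
        a = self.attribute(local_name, namespace_uri)
        return None if a is None else a.value

    def text_content(self) -> str:
        """Concatenated direct text-node content (not recursive)."""
        return "".join(c.value for c in self.children if c.kind == "text")

    def iter_elements(self) -> Iterator["DocNode"]:
        """Depth-first iterator over this element and all element descendants."""
        if self.kind == "element":
            yield self
        for child in self.children:
            if child.kind == "element":
                yield from child.iter_elements()

    def is_cml(self, local_name: Optional[str] = None) -> bool:
        if self.kind != "element" or self.name.namespace_uri != CML_NS:
            return False
        return local_name is None or self.name.local_name == local_name


def _split_tag(tag: str) -> XmlName:
    if tag.startswith("{"):
        uri, _, local = tag[1:].partition("}")
        return XmlName(uri, local)
    return XmlName("", tag)


def _build(elem: etree._Element, parent: Optional[DocNode]) -> DocNode:
    nsmap = {("" if k is None else k): v for k, v in elem.nsmap.items()}
    node = DocNode(
        kind="element",
        name=_split_tag(elem.tag),
        parent=parent,
        nsmap=nsmap,
        backing=elem,
    )
    for raw_name, raw_value in elem.attrib.items():
        node.attributes.append(
            DocNode(
                kind="attribute",
                name=_split_tag(raw_name),
                value=raw_value,
                parent=node,
                nsmap=nsmap,
            )
        )
    if elem.text:
        node.children.append(
            DocNode(kind="text", value=elem.text, parent=node, nsmap=nsmap)
        )
    seen: dict[XmlName, int] = {}
    for child in elem:
        if isinstance(child.tag, str):  # skip comments / processing instructions
            child_node = _build(child, node)
            seen[child_node.name] = seen.get(child_node.name, 0) + 1
            child_node.same_name_index = seen[child_node.name]
            node.children.append(child_node)
        if child.tail:
            node.children.append(
                DocNode(kind="text", value=child.tail, parent=node, nsmap=nsmap)
            )
    return node


def _parser() -> etree.XMLParser:
    # hardened: no entity expansion, no DTD fetching, no network
    return etree.XMLParser(
        resolve_entities=False, no_network=True, load_dtd=False, huge_tree=False
    )


def parse(document_bytes: Union[bytes, str]) -> Union[DocNode, WellFormednessFailure]:
    """Parse XML bytes into a :class:`DocNode` tree.

    Returns a :class:`WellFormednessFailure` (never raises) for anything
    that is not well-formed XML, including empty input.
    """
    if isinstance(document_bytes, str):
        document_bytes = document_bytes.encode("utf-8")
    try:
        root = etree.fromstring(document_bytes, parser=_parser())
    except etree.XMLSyntaxError as exc:
        return WellFormednessFailure(str(exc))
    return _build(root, None)


def serialize(root: DocNode) -> bytes:
    """Serialize a parsed tree back to XML bytes."""
    if root.backing is None:
        raise ValueError("node does not originate from a parsed document")
    return etree.tostring(root.backing)


def in_scope_namespaces(node: DocNode) -> NamespaceContext:
    """All prefix -> URI bindings visible at *node* (inherited included)."""
    if node.kind not in ("element", "attribute"):
        raise ValueError("namespace context is defined for elements and attributes")
    return dict(node.nsmap)


def expand_qname(token: str, node: DocNode) -> XmlName:
    """Expand a ``prefix:local`` (or bare ``local``) token at *node*.

    A bare token takes the default-namespace binding; with neither a prefix
    binding nor a default namespace the result is in no namespace.  A bound
    prefix that is missing raises :class:`UnboundPrefixError`.
    """
    m = _QNAME_RE.match(token.strip())
    if m is None:
        raise ValueError(f"{token!r} is not a QName")
    prefix = m.group("prefix") or ""
    bindings = in_scope_namespaces(node)
    if prefix:
        if prefix not in bindings:
            raise UnboundPrefixError(prefix, token)
        return XmlName(bindings[prefix], m.group("local"))
    return XmlName(bindings.get("", ""), m.group("local"))


def _element_step(node: DocNode) -> str:
    return (
        "/*[local-name() = '%s' and namespace-uri() = '%s'][%d]"
        % (node.name.local_name, node.name.namespace_uri, node.same_name_index)
    )


def location_path(node: DocNode) -> str:
    """Absolute location path in the report dialect.

    Element steps read ``/*[local-name() = 'N' and namespace-uri() = 'U'][k]``
    with ``k`` counting preceding same-named siblings; an attribute node
    appends ``@*[local-name() = 'N' and namespace-uri() = 'U']`` directly to
    its owner's path.
    """
    if node.kind == "attribute":
        owner = location_path(node.parent)
        return owner + (
            "@*[local-name() = '%s' and namespace-uri() = '%s']"
            % (node.name.local_name, node.name.namespace_uri)
        )
    if node.kind != "element":
        raise ValueError("only elements and attributes have locations")
    steps = []
    cur: Optional[DocNode] = node
    while cur is not None:
        steps.append(_element_step(cur))
        cur = cur.parent
    return "".join(reversed(steps))
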