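"""Declarative vocabulary for the schema3-subset structural model.

The relaxed third-generation CML content model gives almost every element
"any" content — any CML, foreign-namespace or no-namespace children in any
order and cardinality, but no mixed content.  What remains to check
structurally is vocabulary membership, attribute admissibility and
attribute datatypes.  The table below covers the elements the built-in
conventions use; communities can extend it from a YAML file without code
changes (see :func:`load_vocabulary`).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

import yaml

ANY_CML = "any-cml-plus-foreign"
TEXT_ONLY = "text-only"

_QNAME_TOKEN_RE = re.compile(r"^(?:[^\s:]+:)?[^\s:]+$")
_INT_RE = re.compile(r"^[+-]?\d+$")


@dataclass(frozen=True)
class AttributeSpec:
    """One attribute with its datatype.

    ``datatype`` is one of ``string``, ``integer``, ``real``,
    ``real-requiring-pair-group`` (a real whose presence requires the named
    peer attributes), ``token-list(n)``, ``qname-ref`` or
    ``enumeration(values)``.
    """

    name: str
    datatype: str = "string"
    values: tuple = ()  # closed set for enumeration
    list_length: Optional[int] = None  # for token-list
    peers: tuple = ()  # for real-requiring-pair-group

    def check_value(self, value: str) -> Optional[str]:
        """Return an error message for a bad value, or None when acceptable."""
        if self.datatype == "string":
            return None
        if self.datatype == "integer":
            if not _INT_RE.match(value.strip()):
                return f'attribute "{self.name}" requires an integer, got "{value}"'
            return None
        if self.datatype in ("real", "real-requiring-pair-group"):
            try:
                float(value)
            except ValueError:
                return f'attribute "{self.name}" requires a real number, got "{value}"'
            return None
        if self.datatype == "token-list":
            tokens = value.split()
            if self.list_length is not None and len(tokens) != self.list_length:
                return (
                    f'attribute "{self.name}" requires {self.list_length} '
                    f'whitespace-separated tokens, got "{value}"'
                )
            return None
        if self.datatype == "qname-ref":
            if not _QNAME_TOKEN_RE.match(value.strip()):
                return f'attribute "{self.name}" requires a QName, got "{value}"'
            return None
        if self.datatype == "enumeration":
            if value not in self.values:
                allowed = " ".join(f'"{v}"' for v in self.values)
                return (
                    f'attribute "{self.name}" value "{value}" is not one of '
                    f"the allowed values {allowed}"
                )
            return None
        raise ValueError(f"unknown datatype {self.datatype!r}")


@dataclass(frozen=True)
class ElementSpec:
    name: str
    attributes: dict = field(default_factory=dict)  # local name -> AttributeSpec
    content: str = ANY_CML


@dataclass
class VocabularyTable:
    elements: dict  # local name -> ElementSpec
    obsoleted: frozenset = frozenset({"annotation", "appinfo", "documentation", "relatedEntry"})

    def __contains__(self, local_name: str) -> bool:
        return local_name in self.elements

    def spec_for(self, local_name: str) -> Optional[ElementSpec]:
        return self.elements.get(local_name)


def _attr(name, datatype="string", **kw) -> AttributeSpec:
    return AttributeSpec(name, datatype, **kw)


# attributes admitted on every CML element (generic per schema3: id, title,
# dictRef, convention)
COMMON_ATTRIBUTES = {
    "id": _attr("id"),
    "title": _attr("title"),
    "dictRef": _attr("dictRef", "qname-ref"),
    "convention": _attr("convention", "qname-ref"),
}

_ELEMENT_ATTRS = {
    "molecule": {
        "formalCharge": _attr("formalCharge", "integer"),
        "count": _attr("count", "real"),
        "spinMultiplicity": _attr("spinMultiplicity", "integer"),
    },
    "atom": {
        "elementType": _attr("elementType"),
        "x3": _attr("x3", "real"),
        "y3": _attr("y3", "real"),
        "z3": _attr("z3", "real"),
        "formalCharge": _attr("formalCharge", "integer"),
        "count": _attr("count", "real"),
        "occupancy": _attr("occupancy", "real"),
    },
    "bond": {
        "atomRefs2": _attr("atomRefs2", "token-list", list_length=2),
        "order": _attr(
            "order", "enumeration", values=("S", "D", "T", "A", "1", "2", "3")
        ),
    },
    "unit": {
        "unitType": _attr("unitType", "qname-ref"),
        "symbol": _attr("symbol"),
        "multiplierToSI": _attr("multiplierToSI", "real"),
    },
    "entry": {"term": _attr("term")},
    "dictionary": {"namespace": _attr("namespace")},
    "scalar": {
        "dataType": _attr("dataType"),
        "units": _attr("units", "qname-ref"),
    },
    "property": {},
    "parameter": {},
    # `type` enumerations for the elements carrying a typed attribute group;
    # list keeps type as a free string
    "cellParameter": {
        "type": _attr("type", "enumeration", values=("length", "angle"))
    },
    "peakStructure": {
        "type": _attr(
            "type", "enumeration", values=("coupling", "splitting", "other")
        )
    },
    "reaction": {
        "type": _attr(
            "type",
            "enumeration",
            values=("chainReaction", "initiation", "termination", "reversible", "other"),
        )
    },
    "spectrum": {
        "type": _attr(
            "type",
            "enumeration",
            values=("infrared", "massSpectrum", "NMR", "UV/VIS", "other"),
        )
    },
    "list": {"type": _attr("type")},
}

_ELEMENT_NAMES = (
    "molecule", "atomArray", "atom", "bondArray", "bond",
    "unitList", "unit", "unitType",
    "dictionary", "entry", "definition", "description",
    "module", "property", "parameter", "scalar", "list",
    "name", "label", "formula",
    "spectrum", "cellParameter", "crystal", "reaction", "peakStructure",
)

_TEXT_ONLY = frozenset({"scalar"})


def default_vocabulary() -> VocabularyTable:
    elements = {}
    for name in _ELEMENT_NAMES:
        attrs = dict(COMMON_ATTRIBUTES)
        attrs.update(_ELEMENT_ATTRS.get(name, {}))
        content = TEXT_ONLY if name in _TEXT_ONLY else ANY_CML
        elements[name] = ElementSpec(name, attrs, content)
    return VocabularyTable(elements)


def _spec_from_config(name: str, entry: dict) -> ElementSpec:
    attrs = dict(COMMON_ATTRIBUTES)
    for attr_name, attr_cfg in (entry.get("attributes") or {}).items():
        if isinstance(attr_cfg, str):
            attrs[attr_name] = AttributeSpec(attr_name, attr_cfg)
        else:
            attrs[attr_name] = AttributeSpec(
                attr_name,
                attr_cfg.get("datatype", "string"),
                values=tuple(attr_cfg.get("values", ())),
                list_length=attr_cfg.get("list_length"),
                peers=tuple(attr_cfg.get("peers", ())),
            )
    return ElementSpec(name, attrs, entry.get("content", ANY_CML))


def load_vocabulary(path) -> VocabularyTable:
    """Load vocabulary extensions from YAML, layered over the defaults.

    The file maps element names to ``{content, attributes}`` entries where
    each attribute is either a datatype string or a mapping with keys
    ``datatype``, ``values``, ``list_length``, ``peers``.
    """
    with open(path, "r", encoding="utf-8") as fh:
        config = yaml.safe_load(fh) or {}
    table = default_vocabulary()
    for name, entry in (config.get("elements") or {}).items():
        table.elements[name] = _spec_from_config(name, entry or {})
    return table
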