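"""Ordered validation workflow.

Checks run in a fixed order — well-formedness, schema-level structure
(plus deprecation warnings), conventions, QName/URI resolvability.
Malformed input stops everything; a schema error stops the convention and
URI checks; a convention error still lets the URI check run (the verdict
is already INVALID either way).  Sections never reached are omitted from
the report.
"""

from __future__ import annotations

import re
import urllib.request
from dataclasses import dataclass
from typing import List, Optional, Union

from .conventions import (
    ConventionRegistry,
    default_registry,
    discover_conventions,
    run_conventions,
)
from .document import (
    DocNode,
    UnboundPrefixError,
    WellFormednessFailure,
    expand_qname,
    location_path,
    parse,
)
from .report import (
    MSG_CONVENTIONS_VALID,
    MSG_DICTREFS_RESOLVABLE,
    MSG_SCHEMA_VALID,
    MSG_URIS_REACHABLE,
    MSG_WELL_FORMED,
    TestSection,
    ValidationReport,
    error,
    warning,
)
from .structural import (
    check_attribute_types,
    check_content_model,
    check_deprecated,
    check_vocabulary,
)
from .vocabulary import VocabularyTable, default_vocabulary, load_vocabulary

_ABSOLUTE_URI_RE = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:")


class OfflineResolver:
    """Treats every syntactically absolute URI as reachable; no network."""

    mode = "offline"

    def resolve(self, uri: str) -> bool:
        return bool(_ABSOLUTE_URI_RE.match(uri))


class OnlineResolver:
    """HEAD-requests each URI once (results cached per instance)."""

    mode = "online"

    def __init__(self, timeout: float = 5.0):
        self.timeout = timeout
        self._cache: dict = {}

    def resolve(self, uri: str) -> bool:
        if not _ABSOLUTE_URI_RE.match(uri):
            return False
        if uri not in self._cache:
            request = urllib.request.Request(uri, method="HEAD")
            try:
                with urllib.request.urlopen(request, timeout=self.timeout) as resp:
                    self._cache[uri] = resp.status < 400
            except Exception:
                self._cache[uri] = False
        return self._cache[uri]


@dataclass
class WorkflowConfig:
    """Validator configuration; the defaults run offline with no external files."""

    resolver_mode: str = "offline"
    vocabulary_path: Optional[str] = None
    radius_table_path: Optional[str] = None
    report_format: str = "xml"
    resolver: object = None
    registry: Optional[ConventionRegistry] = None

    def make_resolver(self):
        if self.resolver is not None:
            return self.resolver
        return OnlineResolver() if self.resolver_mode == "online" else OfflineResolver()

    def make_vocabulary(self) -> VocabularyTable:
        if self.vocabulary_path:
            return load_vocabulary(self.vocabulary_path)
        return default_vocabulary()


def _qname_attributes(root: DocNode, vocab: VocabularyTable):
    """All attributes on CML elements whose declared datatype is qname-ref."""
    for node in root.iter_elements():
        if not node.is_cml():
            continue
        spec = vocab.spec_for(node.name.local_name)
        if spec is None:
            continue
        for attr in node.attributes:
            if attr.name.namespace_uri:
                continue
            attr_spec = spec.attributes.get(attr.name.local_name)
            if attr_spec is not None and attr_spec.datatype == "qname-ref":
                yield node, attr


def check_uri_resolvability(
    root: DocNode,
    resolver=None,
    vocab: Optional[VocabularyTable] = None,
) -> List:
    """Expand every QName-valued attribute and query its URI.

    An unbound prefix is an error; a bound prefix whose expanded URI the
    resolver cannot reach is a warning (an offline dictionary should not
    invalidate a document).
    """
    resolver = resolver or OfflineResolver()
    vocab = vocab or default_vocabulary()
    findings = []
    for node, attr in _qname_attributes(root, vocab):
        try:
            name = expand_qname(attr.value, node)
        except UnboundPrefixError as exc:
            findings.append(error(str(exc), location_path(attr)))
            continue
        if not name.namespace_uri:
            findings.append(
                error(
                    f'the QName "{attr.value}" in attribute '
                    f'"{attr.name.local_name}" is not bound to a namespace',
                    location_path(attr),
                )
            )
            continue
        uri = name.namespace_uri + name.local_name
        if not resolver.resolve(uri):
            findings.append(
                warning(f"the URI {uri} was not reachable", location_path(attr))
            )
    return findings


def validate_document(
    document: Union[bytes, str, DocNode],
    config: Optional[WorkflowConfig] = None,
) -> ValidationReport:
    """Run the full ordered validation workflow and return the report.

    Accepts raw bytes (checked for well-formedness) or an already-parsed
    tree (necessarily well-formed; the report is identical either way).
    """
    config = config or WorkflowConfig()
    vocab = config.make_vocabulary()
    report = ValidationReport()

    wf_section = report.add(TestSection("well-formed-test"))
    if isinstance(document, DocNode):
        root = document
    else:
        parsed = parse(document)
        if isinstance(parsed, WellFormednessFailure):
            wf_section.record(error(f"xml is not well formed: {parsed.message}"))
            return report
        root = parsed
    wf_section.close(MSG_WELL_FORMED)

    schema_section = report.add(TestSection("schema-validation-test"))
    schema_section.record_all(check_vocabulary(root, vocab))
    schema_section.record_all(check_content_model(root, vocab))
    schema_section.record_all(check_attribute_types(root, vocab))
    schema_section.record_all(check_deprecated(root))
    schema_section.close(MSG_SCHEMA_VALID)
    if schema_section.has_errors():
        return report

    convention_section = report.add(TestSection("convention-validation-test"))
    _, discovery_findings = discover_conventions(root)
    convention_section.record_all(discovery_findings)
    convention_section.record_all(
        run_conventions(root, config.registry or default_registry())
    )
    convention_section.close(MSG_CONVENTIONS_VALID)

    # A convention error does not suppress the URI check: the reference
    # reports print the uris-reachable-test section alongside convention
    # errors, and the aggregate verdict is already INVALID.
    uri_section = report.add(TestSection("uris-reachable-test"))
    uri_section.record_all(
        check_uri_resolvability(root, config.make_resolver(), vocab)
    )
    uri_section.close(MSG_URIS_REACHABLE, MSG_DICTREFS_RESOLVABLE)
    return report
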