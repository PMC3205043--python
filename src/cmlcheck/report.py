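"""Validation report language.

A report is an ordered list of test sections (well-formedness, schema,
conventions, URI reachability); each section holds findings of severity
``valid``, ``info``, ``warning`` or ``error``.  A section may only be marked
valid when it holds no warning and no error; info findings are purely
informational and never demote the aggregate verdict.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional

from lxml import etree

from .document import REPORT_NS

SECTION_NAMES = (
    "well-formed-test",
    "schema-validation-test",
    "convention-validation-test",
    "uris-reachable-test",
)

# canonical valid-finding messages
MSG_WELL_FORMED = "xml is well formed"
MSG_SCHEMA_VALID = "document conforms to the schema"
MSG_CONVENTIONS_VALID = "document conforms to all the conventions specified"
MSG_URIS_REACHABLE = "All appropriate URIs were reachable"
MSG_DICTREFS_RESOLVABLE = "all dictRefs are resolvable"


class Severity(enum.IntEnum):
    """Finding severities, ordered for aggregation."""

    VALID = 0
    INFO = 1
    WARNING = 2
    ERROR = 3

    @property
    def tag(self) -> str:
        return self.name.lower()


class ValidationResult(enum.Enum):
    VALID = "VALID"
    VALID_WITH_WARNINGS = "VALID_WITH_WARNINGS"
    INVALID = "INVALID"


class ReportContractError(RuntimeError):
    """A section was marked valid while holding a warning or error."""


@dataclass(frozen=True)
class Finding:
    severity: Severity
    message: str
    location: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.message.strip():
            raise ValueError("finding message must be non-empty")


def valid(message: str) -> Finding:
    return Finding(Severity.VALID, message)


def info(message: str, location: Optional[str] = None) -> Finding:
    return Finding(Severity.INFO, message, location)


def warning(message: str, location: Optional[str] = None) -> Finding:
    return Finding(Severity.WARNING, message, location)


def error(message: str, location: Optional[str] = None) -> Finding:
    return Finding(Severity.ERROR, message, location)


@dataclass
class TestSection:
    name: str
    findings: list[Finding] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.name not in SECTION_NAMES:
            raise ValueError(f"unknown test section {self.name!r}")

    def record(self, finding: Finding) -> "TestSection":
        """Append *finding*; a valid finding may not join warnings/errors."""
        if finding.severity is Severity.VALID and self.has_problems():
            raise ReportContractError(
                f"section {self.name!r} holds a warning or error and "
                "cannot be marked valid"
            )
        if finding.severity in (Severity.WARNING, Severity.ERROR) and any(
            f.severity is Severity.VALID for f in self.findings
        ):
            raise ReportContractError(
                f"section {self.name!r} is already marked valid"
            )
        self.findings.append(finding)
        return self

    def record_all(self, findings) -> "TestSection":
        for f in findings:
            self.record(f)
        return self

    def has_problems(self) -> bool:
        return any(
            f.severity in (Severity.WARNING, Severity.ERROR) for f in self.findings
        )

    def has_errors(self) -> bool:
        return any(f.severity is Severity.ERROR for f in self.findings)

    def close(self, *valid_messages: str) -> "TestSection":
        """Mark the section valid (with the given messages) if it is clean."""
        if not self.has_problems():
            for msg in valid_messages:
                self.record(valid(msg))
        return self


@dataclass
class ValidationReport:
    sections: list[TestSection] = field(default_factory=list)

    def add(self, section: TestSection) -> TestSection:
        self.sections.append(section)
        return section

    def section(self, name: str) -> Optional[TestSection]:
        for s in self.sections:
            if s.name == name:
                return s
        return None

    def findings(self):
        for s in self.sections:
            yield from s.findings

    @property
    def result(self) -> ValidationResult:
        return aggregate_result(self)


def record_finding(section: TestSection, finding: Finding) -> TestSection:
    return section.record(finding)


def aggregate_result(report: ValidationReport) -> ValidationResult:
    """Errors give INVALID, else warnings give VALID_WITH_WARNINGS, else VALID."""
    worst = Severity.VALID
    for f in report.findings():
        if f.severity > worst:
            worst = f.severity
    if worst is Severity.ERROR:
        return ValidationResult.INVALID
    if worst is Severity.WARNING:
        return ValidationResult.VALID_WITH_WARNINGS
    return ValidationResult.VALID


def serialize_report(report: ValidationReport) -> bytes:
    """Serialize to the report XML vocabulary (default namespace, 2-space indent)."""
    root = etree.Element("{%s}report" % REPORT_NS, nsmap={None: REPORT_NS})
    for section in report.sections:
        sec_el = etree.SubElement(root, "{%s}%s" % (REPORT_NS, section.name))
        for f in section.findings:
            f_el = etree.SubElement(sec_el, "{%s}%s" % (REPORT_NS, f.severity.tag))
            f_el.text = f.message
            if f.location is not None:
                f_el.set("location", f.location)
    etree.indent(root, space="  ")
    return etree.tostring(root, xml_declaration=True, encoding="UTF-8") + b"\n"


def parse_report(data: bytes) -> ValidationReport:
    """Inverse of :func:`serialize_report` (whitespace-insensitive)."""
    root = etree.fromstring(data)
    if root.tag != "{%s}report" % REPORT_NS:
        raise ValueError("not a validation report")
    report = ValidationReport()
    for sec_el in root:
        if not isinstance(sec_el.tag, str):
            continue
        section = TestSection(etree.QName(sec_el).localname)
        for f_el in sec_el:
            severity = Severity[etree.QName(f_el).localname.upper()]
            message = (f_el.text or "").strip()
            section.findings.append(
                Finding(severity, message, f_el.get("location"))
            )
        report.sections.append(section)
    return report


def format_text(report: ValidationReport) -> str:
    """Plain-text digest of a report (one line per finding)."""
    lines = []
    for section in report.sections:
        lines.append(section.name)
        for f in section.findings:
            loc = f"  [{f.location}]" if f.location else ""
            lines.append(f"  {f.severity.tag.upper()}: {f.message}{loc}")
    lines.append(f"RESULT: {report.result.value}")
    return "\n".join(lines) + "\n"
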