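import pytest

from cmlcheck import Severity, parse, validate_document
from cmlcheck.fixtures import generate_fixture_corpus
from cmlcheck.structural import (
    check_attribute_types,
    check_content_model,
    check_deprecated,
    check_vocabulary,
)


@pytest.fixture(scope="session")
def corpus():
    return generate_fixture_corpus()


@pytest.fixture(scope="session")
def corpus_by_id(corpus):
    return {f.id: f for f in corpus}


def non_valid_findings(report):
    """All findings except the valid markers."""
    return [f for f in report.findings() if f.severity is not Severity.VALID]


def schema_stage_findings(document):
    """Findings of the structural stage alone (no conventions, no URIs)."""
    root = parse(document)
    return (
        check_vocabulary(root)
        + check_content_model(root)
        + check_attribute_types(root)
        + check_deprecated(root)
    )


def outcome(fixture):
    """(result, non-valid findings) for a fixture at its declared stage."""
    if fixture.stage == "schema":
        findings = schema_stage_findings(fixture.document)
        from cmlcheck import ValidationResult

        if any(f.severity is Severity.ERROR for f in findings):
            result = ValidationResult.INVALID
        elif any(f.severity is Severity.WARNING for f in findings):
            result = ValidationResult.VALID_WITH_WARNINGS
        else:
            result = ValidationResult.VALID
        return result, findings
    report = validate_document(fixture.document)
    return report.result, non_valid_findings(report)
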