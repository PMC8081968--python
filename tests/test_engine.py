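"""Validator engine: execution order, failure isolation, reports."""

import pytest

from neuroqc.engine import (
    SchemaError, TestResult, TestSpec, ValidationReport, ValidatorSpec,
    report_to_markdown, run_test, run_validator, self_check,
)
from neuroqc.model import Scan, Session


def _spec(test_id, outcome=True, level="session", raise_=False, doc=None):
    def run(target, project):
        if raise_:
            raise RuntimeError("synthetic breakage")
        return TestResult(test_id, outcome, [f"{test_id} detail"])
    return TestSpec(test_id, doc or f"Docstring of {test_id}.", run, level=level)


def _session(n_scans=3):
    scans = [Scan(f"{i:03d}", {"PatientID": "ALFA00001"}) for i in range(n_scans)]
    return Session("S1", "ALFA00001", "MR", scans=scans)


def test_docstring_must_be_non_empty():
    with pytest.raises(ValueError):
        TestSpec("T", "", lambda s, p: TestResult("T", True))


def test_scan_level_conjunction_all_pass():
    session = _session(3)
    result = run_test(_spec("T", level="scan"), session)
    assert result.has_passed
    assert len(result.data) == 3  # one entry per scan


def test_scan_level_conjunction_one_fails():
    session = _session(3)

    def run(scan, project):
        return TestResult("T", scan.scan_id != "001", [])

    result = run_test(TestSpec("T", "doc", run, level="scan"), session)
    assert not result.has_passed
    assert [e["has_passed"] for e in result.data] == [True, False, True]


def test_exception_inside_test_becomes_failure():
    result = run_test(_spec("T", raise_=True), _session())
    assert not result.has_passed
    assert any("synthetic breakage" in str(item) for item in result.data)


def test_failing_scan_test_downgrades_flags():
    session = _session(2)

    def run(scan, project):
        return TestResult("T", scan.scan_id == "000", [])

    spec = TestSpec("T", "doc", run, level="scan", on_fail_flag="questionable")
    run_test(spec, session)
    assert session.scans[0].quality_flag == "usable"
    assert session.scans[1].quality_flag == "questionable"


def test_validator_runs_all_tests_despite_failures():
    # failure isolation: a test that blows up at position k leaves k+1..n
    specs = [_spec("T1"), _spec("T2", raise_=True), _spec("T3", outcome=False),
             _spec("T4")]
    report = run_validator(ValidatorSpec("V", specs), _session(), persist=False)
    assert [s.test_id for s, _ in report.results] == ["T1", "T2", "T3", "T4"]
    assert [r.has_passed for _, r in report.results] == [True, False, False, True]
    assert report.summary == {"passed": 2, "failed": 2}


def test_empty_validator_gives_empty_report():
    report = run_validator(ValidatorSpec("V", []), _session(), persist=False)
    assert report.results == []
    assert report.summary == {"passed": 0, "failed": 0}


def test_duplicate_test_ids_rejected():
    with pytest.raises(ValueError):
        ValidatorSpec("V", [_spec("T"), _spec("T")])


def test_markdown_has_one_section_per_test_with_docstring_verbatim():
    specs = [_spec(f"T{i}", doc=f"Human-readable spec number {i}.")
             for i in range(9)]
    report = run_validator(ValidatorSpec("V", specs), _session(), persist=False)
    text = report_to_markdown(report)
    assert text.count("\n## ") == 9
    for spec in specs:
        assert spec.docstring in text  # verbatim containment
    # header carries provenance
    assert report.code_sha in text
    assert report.generated in text


def test_markdown_of_empty_report_is_header_only():
    report = run_validator(ValidatorSpec("V", []), _session(), persist=False)
    assert "## " not in report_to_markdown(report)


def test_json_round_trip_is_identity():
    specs = [_spec("T1"), _spec("T2", outcome=False)]
    report = run_validator(ValidatorSpec("V", specs), _session(), persist=False,
                           timestamp="2024-06-01T00:00:00+00:00")
    clone = ValidationReport.from_json(report.to_json())
    assert clone.to_json() == report.to_json()
    assert clone.summary == report.summary


def test_json_missing_field_is_schema_error():
    report = run_validator(ValidatorSpec("V", [_spec("T1")]), _session(),
                           persist=False)
    import json
    record = json.loads(report.to_json())
    del record["tests"][0]["has_passed"]
    with pytest.raises(SchemaError, match="has_passed"):
        ValidationReport.from_json(json.dumps(record))


def test_json_inconsistent_summary_is_schema_error():
    report = run_validator(ValidatorSpec("V", [_spec("T1")]), _session(),
                           persist=False)
    import json
    record = json.loads(report.to_json())
    record["summary"] = {"passed": 0, "failed": 1}
    with pytest.raises(SchemaError, match="summary"):
        ValidationReport.from_json(json.dumps(record))


def test_persisted_report_lands_as_session_resource(tmp_path):
    from neuroqc.fixtures import make_session
    from neuroqc.model import load_session

    make_session(tmp_path, "MR", "ALFA00009", seed=9)
    session = load_session(tmp_path / "ALFA00009" / "ALFA00009_MR01")
    run_validator(ValidatorSpec("DemoValidator", [_spec("T1")]), session)
    out = tmp_path / "ALFA00009" / "ALFA00009_MR01" / "resources" / "DemoValidator"
    assert (out / "report.json").exists()
    assert (out / "report.md").exists()
    assert (out / "report.pdf").exists()
    session2 = load_session(session.path)
    assert "DemoValidator" in session2.resources


def test_self_check_empty_registry_is_empty_table(selfcheck_project):
    assert self_check([], selfcheck_project) == []


def test_self_check_flags_broken_failing_fixture(selfcheck_project, registry):
    # a test whose failing fixture passes must yield row (true, false)
    from neuroqc.engine import FixtureRef
    from neuroqc.fixtures import passing_session_relpath

    pet = registry["PetSessionValidator"]
    good = pet.test("IsSubjectIdCorrect")
    clean_mr = FixtureRef(passing_session_relpath("ASHSValidator"))
    broken = TestSpec(good.test_id, good.docstring, good.run,
                      passing=good.passing, failing=clean_mr)
    rows = self_check([("PetSessionValidator", broken)], selfcheck_project)
    assert rows[0]["passed_on_passing"] is True
    assert rows[0]["failed_on_failing"] is False
    assert rows[0]["ok"] is False


def test_self_check_is_a_fixed_point(selfcheck_project, registry):
    # fixtures are read-only: two runs over one validator are identical
    tests = [("ASHSValidator", t) for t in registry["ASHSValidator"].tests]
    first = self_check(tests, selfcheck_project)
    second = self_check(tests, selfcheck_project)
    assert first == second
    assert all(r["ok"] for r in first)
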