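"""Test/Validator execution core.

A *Test* is one checkpoint over a session (or each of its scans): it has a
human-readable docstring, a ``run`` callable returning a
:class:`TestResult` (``has_passed`` boolean + ``data`` detail list), and a
pair of fixture references — one session on which it must pass and one on
which it must fail — that make the whole registry self-testing
(:func:`self_check`).

A *Validator* is an ordered list of Tests.  :func:`run_validator` executes
them all sequentially (failures never short-circuit: a report is a complete
checklist), optionally persists the resulting
:class:`ValidationReport` as a resource of the session (JSON + Markdown +
PDF), and downgrades scan quality flags when a failing test declares an
``on_fail_flag``.
"""

from __future__ import annotations

import datetime
import json
import traceback
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

from .model import Project, Scan, Session, set_quality_flag

__all__ = [
    "TestSpec",
    "TestResult",
    "ValidatorSpec",
    "ValidationReport",
    "FixtureRef",
    "SchemaError",
    "run_test",
    "run_validator",
    "self_check",
    "report_to_markdown",
    "report_to_pdf",
    "code_sha",
]


class SchemaError(ValueError):
    """A serialized report violates the report JSON schema."""


@dataclass(frozen=True)
class FixtureRef:
    """Reference to a fixture session inside the self-check project.

    ``session`` is a project-relative path (``<subject>/<session>``);
    ``scan_id`` optionally narrows the reference to one scan.
    """

    session: str
    scan_id: Optional[str] = None


@dataclass
class TestResult:
    __test__ = False  # not a pytest collectable despite the name

    test_id: str
    has_passed: bool
    data: list = field(default_factory=list)

    def __post_init__(self):
        if self.data is None:
            self.data = []
        if not isinstance(self.data, list):
            self.data = [self.data]


@dataclass
class TestSpec:
    """One checkpoint: identity, specification text, level and fixtures.

    ``run`` takes ``(session, project)`` for session-level tests and
    ``(scan, project)`` for scan-level ones, and returns a
    :class:`TestResult`.  ``passing``/``failing`` point at the fixture
    sessions used by :func:`self_check`.
    """

    __test__ = False  # not a pytest collectable despite the name

    test_id: str
    docstring: str
    run: Callable
    level: str = "session"  # "session" | "scan"
    passing: Optional[FixtureRef] = None
    failing: Optional[FixtureRef] = None
    on_fail_flag: Optional[str] = None

    def __post_init__(self):
        if not self.docstring:
            raise ValueError(f"test {self.test_id}: docstring must be non-empty")
        if self.level not in ("session", "scan"):
            raise ValueError(f"test {self.test_id}: invalid level {self.level!r}")
        if self.passing is not None and self.passing == self.failing:
            raise ValueError(f"test {self.test_id}: passing and failing fixtures equal")


@dataclass
class ValidatorSpec:
    name: str
    tests: list

    def __post_init__(self):
        ids = [t.test_id for t in self.tests]
        if len(ids) != len(set(ids)):
            raise ValueError(f"validator {self.name}: duplicate test ids")

    def test(self, test_id: str) -> TestSpec:
        for t in self.tests:
            if t.test_id == test_id:
                return t
        raise KeyError(test_id)


@dataclass
class ValidationReport:
    validator: str
    session_id: str
    subject_id: str
    generated: str  # ISO-8601 timestamp
    code_sha: str
    results: list  # ordered list of (TestSpec, TestResult)

    @property
    def summary(self) -> dict:
        passed = sum(1 for _, r in self.results if r.has_passed)
        return {"passed": passed, "failed": len(self.results) - passed}

    # -- serialization (schema is normative) --------------------------------
    def to_json(self) -> str:
        record = {
            "validator": self.validator,
            "session_id": self.session_id,
            "subject_id": self.subject_id,
            "generated": self.generated,
            "code_sha": self.code_sha,
            "tests": [
                {
                    "id": spec.test_id,
                    "docstring": spec.docstring,
                    "has_passed": result.has_passed,
                    "data": result.data,
                }
                for spec, result in self.results
            ],
            "summary": self.summary,
        }
        return json.dumps(record, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ValidationReport":
        record = json.loads(text)
        for key in ("validator", "session_id", "subject_id", "generated",
                    "code_sha", "tests", "summary"):
            if key not in record:
                raise SchemaError(f"report JSON missing field {key!r}")
        results = []
        for i, entry in enumerate(record["tests"]):
            for key in ("id", "docstring", "has_passed", "data"):
                if key not in entry:
                    raise SchemaError(f"tests[{i}] missing field {key!r}")
            spec = TestSpec(
                test_id=entry["id"],
                docstring=entry["docstring"],
                run=_unavailable_run,
            )
            results.append(
                (spec, TestResult(entry["id"], entry["has_passed"], entry["data"]))
            )
        report = cls(
            validator=record["validator"],
            session_id=record["session_id"],
            subject_id=record["subject_id"],
            generated=record["generated"],
            code_sha=record["code_sha"],
            results=results,
        )
        stored = record["summary"]
        if stored != report.summary:
            raise SchemaError(
                f"summary {stored} inconsistent with results {report.summary}"
            )
        return report


def _unavailable_run(*args, **kwargs):  # placeholder for deserialized specs
    raise RuntimeError("test deserialized from JSON cannot be re-run")


def code_sha() -> str:
    """Version-control identifier recorded in every report.

    Read from build metadata shipped with the installed package
    (``BUILD_SHA`` next to this module); "unknown" when absent, so reports
    remain reproducible outside a checkout.
    """
    marker = Path(__file__).with_name("BUILD_SHA")
    if marker.exists():
        sha = marker.read_text().strip()
        if sha:
            return sha
    return "unknown"


def run_test(test: TestSpec, session: Session,
             project: Optional[Project] = None,
             mutate_flags: bool = True) -> TestResult:
    """Execute one test over a session.

    Scan-level tests run once per scan; the overall outcome is the
    conjunction and ``data`` carries one entry per scan.  An exception
    inside a test becomes a failing result carrying the error description —
    it never aborts the validator.  When a failing test declares
    ``on_fail_flag``, the implicated scans are downgraded via
    :func:`neuroqc.model.set_quality_flag`.
    """
    try:
        if test.level == "scan":
            per_scan = []
            failed_scans = []
            for scan in session.scans:
                try:
                    res = test.run(scan, project)
                except Exception as exc:  # noqa: BLE001 - isolation contract
                    res = TestResult(test.test_id, False,
                                     [f"error: {exc.__class__.__name__}: {exc}"])
                per_scan.append(
                    {"scan_id": scan.scan_id, "has_passed": res.has_passed,
                     "data": res.data}
                )
                if not res.has_passed:
                    failed_scans.append(scan)
            result = TestResult(test.test_id, all(e["has_passed"] for e in per_scan),
                                per_scan)
            implicated = failed_scans
        else:
            result = test.run(session, project)
            if not isinstance(result, TestResult):
                raise TypeError(
                    f"test {test.test_id} returned {type(result).__name__}, "
                    "expected TestResult"
                )
            result.test_id = test.test_id
            implicated = session.scans
    except Exception as exc:  # noqa: BLE001 - isolation contract
        return TestResult(test.test_id, False,
                          [f"error: {exc.__class__.__name__}: {exc}",
                           traceback.format_exc(limit=2)])
    if mutate_flags and not result.has_passed and test.on_fail_flag is not None:
        for scan in implicated:
            set_quality_flag(scan, test.on_fail_flag)
    return result


def run_validator(validator: ValidatorSpec, session: Session,
                  project: Optional[Project] = None, persist: bool = True,
                  timestamp: Optional[str] = None) -> ValidationReport:
    """Run every test of a validator, in declared order, over a session.

    All tests always run regardless of earlier failures.  When ``persist``
    is true the report is written as a resource of the session
    (``resources/<ValidatorName>/report.{json,md,pdf}``), mirroring how
    validation outputs live next to the data they validate.
    """
    generated = timestamp or datetime.datetime.now(datetime.timezone.utc).isoformat(
        timespec="seconds")
    results = [(t, run_test(t, session, project)) for t in validator.tests]
    report = ValidationReport(
        validator=validator.name,
        session_id=session.session_id,
        subject_id=session.subject_id,
        generated=generated,
        code_sha=code_sha(),
        results=results,
    )
    if persist:
        if session.path is None:
            raise IOError("cannot persist report: session has no backing directory")
        out_dir = Path(session.path) / "resources" / validator.name
        out_dir.mkdir(parents=True, exist_ok=True)
        (out_dir / "report.json").write_text(report.to_json())
        (out_dir / "report.md").write_text(report_to_markdown(report))
        try:
            report_to_pdf(report, out_dir / "report.pdf")
        except Exception as exc:  # PDF is a convenience artifact, never fatal
            (out_dir / "report.pdf.err").write_text(str(exc))
    return report


def report_to_markdown(report: ValidationReport) -> str:
    """Render a report as Markdown: header plus one section per test.

    Every section quotes the test's docstring verbatim (the checkpoint's
    human-readable specification), then the outcome and the detail payload.
    """
    lines = [
        f"# {report.validator} — {report.session_id}",
        "",
        f"- subject: {report.subject_id}",
        f"- generated: {report.generated}",
        f"- code sha: {report.code_sha}",
        f"- summary: {report.summary['passed']} passed, "
        f"{report.summary['failed']} failed",
        "",
    ]
    for spec, result in report.results:
        outcome = "PASSED" if result.has_passed else "FAILED"
        lines += [f"## {spec.test_id}", "", spec.docstring, "",
                  f"**{outcome}**", ""]
        for item in result.data:
            if isinstance(item, dict) and "snapshot" in item:
                lines.append(f"![snapshot]({item['snapshot']})")
            else:
                lines.append(f"- {json.dumps(item) if isinstance(item, (dict, list)) else item}")
        if result.data:
            lines.append("")
    return "\n".join(lines) + "\n"


def report_to_pdf(report: ValidationReport, out_path) -> Path:
    """Write the report as a simple paginated text PDF (matplotlib backend).

    The Markdown file is the primary human-readable artifact; the PDF is a
    portable rendering of the same content.
    """
    import matplotlib
    matplotlib.use("Agg")
    from matplotlib.backends.backend_pdf import PdfPages

    text = report_to_markdown(report)
    lines = text.splitlines()
    per_page = 52
    out_path = Path(out_path)
    with PdfPages(out_path) as pdf:
        for start in range(0, max(len(lines), 1), per_page):
            import matplotlib.pyplot as plt
            fig = plt.figure(figsize=(8.27, 11.69))  # A4
            fig.text(0.06, 0.97, "\n".join(lines[start:start + per_page]),
                     va="top", ha="left", family="monospace", fontsize=8)
            pdf.savefig(fig)
            plt.close(fig)
    return out_path


def self_check(tests, project: Project):
    """Re-execute every test against its declared passing and failing fixture.

    Returns a list of rows ``{"validator", "test_id", "passed_on_passing",
    "failed_on_failing", "ok"}``; on a correct build every row has
    ``ok=True``.  An unresolvable fixture flags the row as failed.
    ``tests`` is an iterable of (validator_name, TestSpec).
    """
    rows = []
    cache: dict = {}

    def resolve(ref: FixtureRef) -> Session:
        if ref.session not in cache:
            from .model import load_session
            cache[ref.session] = load_session(Path(project.root) / ref.session)
        return cache[ref.session]

    for validator_name, test in tests:
        row = {"validator": validator_name, "test_id": test.test_id,
               "passed_on_passing": False, "failed_on_failing": False}
        try:
            if test.passing is None or test.failing is None:
                raise ValueError("fixtures not declared")
            passing = resolve(test.passing)
            failing = resolve(test.failing)
            row["passed_on_passing"] = run_test(
                test, passing, project, mutate_flags=False).has_passed
            row["failed_on_failing"] = not run_test(
                test, failing, project, mutate_flags=False).has_passed
        except Exception as exc:  # noqa: BLE001
            row["error"] = f"{exc.__class__.__name__}: {exc}"
        row["ok"] = row["passed_on_passing"] and row["failed_on_failing"]
        rows.append(row)
    return rows
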