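"""Acquisition-time checks on DICOM-derived session metadata.

Four generic primitives (key present-and-allowed, key within interval,
key consistent across scans, subject-id pattern match) plus two
project-level lookups (usable T1 availability, quantification
runnability).  All string comparisons trim whitespace and are
case-insensitive; raw values are echoed in the result payload so failing
reports are self-explanatory.
"""

from __future__ import annotations

import re
from typing import Optional

from ..config import CheckConfig, IntervalSpec
from ..engine import TestResult
from ..model import Project, Scan, Session

__all__ = [
    "metadata_present_and_allowed",
    "metadata_in_interval",
    "metadata_consistent_across_scans",
    "id_matches_pattern",
    "has_usable_t1",
    "quantification_runnable",
    "scan_has_nifti",
]


def _norm(value) -> str:
    return str(value).strip().upper()


def metadata_present_and_allowed(session: Session, key: str, allowed) -> TestResult:
    """Pass iff every scan carries ``key`` and its value is in ``allowed``."""
    allowed_norm = {_norm(v) for v in allowed}
    offenders = []
    for scan in session.scans:
        if key not in scan.metadata or scan.metadata[key] in (None, ""):
            offenders.append({"scan_id": scan.scan_id, "missing_key": key})
        elif _norm(scan.metadata[key]) not in allowed_norm:
            offenders.append({"scan_id": scan.scan_id, key: scan.metadata[key]})
    if not session.scans:
        offenders.append({"error": "session has no scans"})
    return TestResult(key, not offenders, offenders)


def metadata_in_interval(session: Session, spec: IntervalSpec) -> TestResult:
    """Pass iff ``spec.key`` is present, numeric and inside the closed interval
    on every scan."""
    data, ok = [], True
    for scan in session.scans:
        raw = scan.metadata.get(spec.key)
        entry = {"scan_id": scan.scan_id, spec.key: raw}
        if raw in (None, ""):
            entry["note"] = "missing"
            ok = False
        else:
            try:
                value = float(raw)
            except (TypeError, ValueError):
                entry["note"] = f"not numeric: {raw!r}"
                ok = False
            else:
                if not spec.contains(value):
                    entry["note"] = f"outside [{spec.lower}, {spec.upper}]"
                    ok = False
        data.append(entry)
    if not session.scans:
        data, ok = [{"error": "session has no scans"}], False
    return TestResult(spec.key, ok, data)


def metadata_consistent_across_scans(session: Session, keys) -> TestResult:
    """Pass iff each key takes a single value across all scans of the session.

    Vacuously true for a single-scan session.  Divergent keys are reported
    with the full set of observed values.
    """
    divergent = []
    for key in sorted(keys):
        values = {str(scan.metadata.get(key)) for scan in session.scans}
        if len(values) > 1:
            divergent.append({key: sorted(values)})
    return TestResult("consistency", not divergent, divergent)


def id_matches_pattern(session: Session, pattern: str) -> TestResult:
    """Pass iff the session's subject id and every scan's PatientID fully
    match ``pattern``."""
    try:
        regex = re.compile(pattern)
    except re.error as exc:
        raise ValueError(f"invalid subject-id pattern {pattern!r}: {exc}") from None
    offenders = []
    if not regex.fullmatch(session.subject_id or ""):
        offenders.append({"subject_id": session.subject_id})
    for scan in session.scans:
        pid = scan.metadata.get("PatientID", "")
        if not regex.fullmatch(str(pid)):
            offenders.append({"scan_id": scan.scan_id, "PatientID": pid})
    return TestResult("subject_id", not offenders, offenders)


def _find_usable_t1(project: Project, subject_id: str,
                    config: CheckConfig) -> Optional[tuple]:
    designations = tuple(d.upper() for d in config.t1_designations)
    for mr in project.sessions_of(subject_id, modality="MR"):
        for scan in mr.scans:
            desc = _norm(scan.metadata.get("SeriesDescription", ""))
            if any(d in desc for d in designations) and scan.quality_flag == "usable":
                return mr.session_id, scan.scan_id
    return None


def has_usable_t1(session: Session, project: Optional[Project],
                  config: CheckConfig) -> TestResult:
    """Pass iff some MR session of the same subject holds a T1-weighted scan
    flagged usable."""
    if project is None:
        return TestResult("HasUsableT1", False,
                          ["project context required to look up MR sessions"])
    found = _find_usable_t1(project, session.subject_id, config)
    if found is None:
        return TestResult("HasUsableT1", False,
                          [f"no usable T1 for subject {session.subject_id}"])
    return TestResult("HasUsableT1", True,
                      [{"session": found[0], "scan": found[1]}])


#: tracer expected by each quantification pipeline
PIPELINE_TRACERS = {"centiloid": "FLUTEMETAMOL", "fdg": "FDG"}


def quantification_runnable(session: Session, project: Optional[Project],
                            pipeline: str, config: CheckConfig) -> TestResult:
    """Check whether the session satisfies a quantification pipeline's
    preconditions: matching tracer, PET NIfTI present, usable T1 available.

    A tracer mismatch (including a missing tracer) makes the pipeline
    inapplicable: the result is pass-with-note, so a clean session is
    all-green and tracer registration itself stays the tracer check's job.
    """
    expected_tracer = PIPELINE_TRACERS[pipeline]
    tracers = {_norm(s.metadata.get("Radiopharmaceutical", "")) for s in session.scans}
    if expected_tracer not in tracers:
        return TestResult(pipeline, True,
                          [f"not applicable: tracer is not {expected_tracer}"])
    failures = []
    if not any(scan.nifti_files() for scan in session.scans):
        failures.append("no PET NIfTI volume in session")
    if project is None or _find_usable_t1(project, session.subject_id, config) is None:
        failures.append(f"no usable T1 for subject {session.subject_id}")
    return TestResult(pipeline, not failures,
                      failures or [f"{pipeline} preconditions satisfied"])


def scan_has_nifti(scan: Scan, _project=None) -> TestResult:
    """Scan-level: pass iff the scan holds at least one readable NIfTI volume."""
    import nibabel as nib

    candidates = scan.nifti_files()
    if not candidates:
        return TestResult("HasNifti", False,
                          [f"scan {scan.scan_id}: no NIfTI file"])
    for rel in candidates:
        try:
            img = nib.load(str(scan.path / rel))
            import numpy as np
            np.asanyarray(img.dataobj)  # force payload read: catches truncation
            return TestResult("HasNifti", True, [rel])
        except Exception as exc:  # noqa: BLE001 - corrupt volume is a failure
            last = f"{rel}: unreadable ({exc.__class__.__name__}: {exc})"
    return TestResult("HasNifti", False, [last])
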