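"""Project-wide bulk collection of measurements, test outcomes and files.

One command collects, across every session of a project, what would
otherwise require many manual operations: all FreeSurfer structure
volumes into a single spreadsheet, all validator outcomes into a
pass/fail table, all files of a named resource into per-session folders,
or all report snapshots into one flat folder with a manifest feeding the
visual-review gallery.  All outputs are plain CSV/folders and all
collection is idempotent (copy, never move).
"""

from __future__ import annotations

import json
import shutil
from pathlib import Path
from typing import Optional

import pandas as pd

from .checks.derivatives import parse_aseg_stats
from .model import Project

__all__ = ["aggregate_aseg", "aggregate_tests", "collect_files",
           "collect_snapshots"]


def aggregate_aseg(project: Project, resource_name: str = "FREESURFER6"):
    """All structure volumes, one row per session, one column per structure.

    Cells are Volume_mm3 taken verbatim from each session's ``aseg.stats``;
    sessions lacking the resource (or with an unparseable table) are
    skipped with a note.  Returns ``(DataFrame, notes)``.
    """
    rows, notes = {}, []
    for session in sorted(project.sessions, key=lambda s: s.session_id):
        resource = session.resources.get(resource_name)
        if resource is None:
            notes.append(f"{session.session_id}: no {resource_name} resource")
            continue
        stats = None
        for rel in resource.file_paths():
            if rel.endswith("aseg.stats"):
                stats = Path(resource.path) / rel
                break
        if stats is None:
            notes.append(f"{session.session_id}: no aseg.stats in "
                         f"{resource_name}")
            continue
        try:
            rows[session.session_id] = parse_aseg_stats(stats)
        except (ValueError, OSError) as exc:
            notes.append(f"{session.session_id}: unparseable aseg.stats "
                         f"({exc})")
    table = pd.DataFrame.from_dict(rows, orient="index")
    table = table.reindex(sorted(table.columns), axis=1)
    table.index.name = "session_id"
    return table, notes


def _load_report(session, validator_name: str) -> Optional[dict]:
    if session.path is None:
        return None
    path = Path(session.path) / "resources" / validator_name / "report.json"
    if not path.exists():
        return None
    with open(path) as fh:
        return json.load(fh)


#: which sessions each shipped validator applies to
_VALIDATOR_TARGETS = {
    "PetSessionValidator": ("modality", "PET"),
    "ArchivingValidator": ("modality", "MR"),
    "ASHSValidator": ("resource", "ASHS"),
    "SPM12Validator": ("resource", "SPM12"),
    "FreeSurfer6Validator": ("resource", "FREESURFER6"),
    "DTIFITValidator": ("resource", "DTIFIT"),
    "ANTSValidator": ("resource", "ANTS"),
}


def _applicable(session, validator_name: str) -> bool:
    kind, value = _VALIDATOR_TARGETS.get(validator_name, (None, None))
    if kind == "modality":
        return session.modality == value
    if kind == "resource":
        return value in session.resources
    return True  # unknown validator: any session with a report qualifies


def aggregate_tests(project: Project, validator_name: str):
    """Pass/fail table from persisted validation reports.

    One row per applicable session (PET sessions for the PET validator, MR
    sessions for archiving, resource-bearing sessions for derivative
    validators), one column per test id in validator declaration order;
    cells hold booleans.  Applicable sessions without a persisted report
    get a row of empty cells plus a note.  Returns ``(DataFrame, notes)``.
    """
    try:
        from .checks.registry import get_validator
        columns = [t.test_id for t in get_validator(validator_name).tests]
    except KeyError:
        columns = None
    rows, notes = {}, []
    for session in sorted(project.sessions, key=lambda s: s.session_id):
        record = _load_report(session, validator_name)
        if record is None:
            if _applicable(session, validator_name):
                rows[session.session_id] = {}
                notes.append(f"{session.session_id}: no {validator_name} report")
            continue
        if columns is None:
            columns = [t["id"] for t in record["tests"]]
        rows[session.session_id] = {t["id"]: bool(t["has_passed"])
                                    for t in record["tests"]}
    table = pd.DataFrame(
        [pd.Series(v, dtype=object) for v in rows.values()], index=list(rows))
    if columns:
        table = table.reindex(columns=columns)
    table.index.name = "session_id"
    return table, notes


def collect_files(project: Project, resource_name: str, dest_dir):
    """Copy every session's named resource into
    ``<dest>/<subject>_<session>/``; returns the list of created folders."""
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    created, notes = [], []
    for session in sorted(project.sessions, key=lambda s: s.session_id):
        resource = session.resources.get(resource_name)
        if resource is None:
            continue
        target = dest_dir / f"{session.subject_id}_{session.session_id}"
        for rel in resource.file_paths():
            src = Path(resource.path) / rel
            out = target / rel
            out.parent.mkdir(parents=True, exist_ok=True)
            shutil.copyfile(src, out)
        created.append(target)
    if not created:
        notes.append(f"resource {resource_name} absent from every session")
    return created, notes


def collect_snapshots(project: Project, validator_name: str, dest_dir):
    """Extract every snapshot referenced by a validator's reports into one
    flat folder, plus a manifest joining each snapshot to its session and
    per-test outcomes (the input of the review gallery).

    Returns ``(manifest DataFrame, notes)``; also writes
    ``manifest.csv`` into ``dest_dir``.
    """
    dest_dir = Path(dest_dir)
    dest_dir.mkdir(parents=True, exist_ok=True)
    entries, notes = [], []
    for session in sorted(project.sessions, key=lambda s: s.session_id):
        record = _load_report(session, validator_name)
        if record is None:
            continue
        outcomes = {t["id"]: bool(t["has_passed"]) for t in record["tests"]}
        for test in record["tests"]:
            for item in test["data"]:
                if not (isinstance(item, dict) and "snapshot" in item):
                    continue
                src = Path(session.path) / item["snapshot"]
                if not src.exists():
                    notes.append(f"{session.session_id}: missing snapshot "
                                 f"{item['snapshot']}")
                    continue
                snapshot_id = (f"{session.subject_id}_{session.session_id}"
                               f"_{test['id']}{src.suffix}")
                shutil.copyfile(src, dest_dir / snapshot_id)
                entries.append({"snapshot_id": snapshot_id,
                                "session_id": session.session_id,
                                "subject_id": session.subject_id,
                                **outcomes})
    manifest = pd.DataFrame(entries)
    if not manifest.empty:
        manifest = manifest.sort_values("snapshot_id").reset_index(drop=True)
    manifest.to_csv(dest_dir / "manifest.csv", index=False)
    return manifest, notes
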