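"""Filesystem-backed imaging project model.

An imaging *project* is a directory tree mirroring the classic
Project -> Subject -> Session -> Scan/Resource hierarchy of imaging
databases::

    <root>/<subject>/<session>/session.json
    <root>/<subject>/<session>/scans/<scan_id>/{image.nii.gz, image.json, ...}
    <root>/<subject>/<session>/resources/<NAME>/...

``session.json`` is the session descriptor (``session_id``, ``subject_id``,
``modality``).  Each scan directory may hold a NIfTI-1 volume plus a JSON
metadata sidecar with DICOM-derived keys (BIDS-style naming), and an
optional ``quality.json`` recording the scan quality flag.  A *resource* is
a named bundle of derivative files (pipeline outputs, validation reports)
with an optional ``provenance.json``.
"""

from __future__ import annotations

import json
import math
import os
import shutil
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

__all__ = [
    "QUALITY_FLAGS",
    "MODALITIES",
    "NUMERIC_METADATA_KEYS",
    "Scan",
    "Resource",
    "Session",
    "Project",
    "QualityFlagError",
    "SessionFormatError",
    "load_project",
    "load_session",
    "set_quality_flag",
    "write_session",
]

#: Ordered from best to worst; transitions to the right are downgrades.
QUALITY_FLAGS = ("usable", "questionable", "unusable")

MODALITIES = ("MR", "PET")

#: DICOM-derived sidecar keys that must parse as finite non-negative numbers.
NUMERIC_METADATA_KEYS = ("PatientWeight", "RadionuclideTotalDose")

SESSION_DESCRIPTOR = "session.json"
SCAN_QUALITY_FILE = "quality.json"
PROVENANCE_FILE = "provenance.json"


class SessionFormatError(ValueError):
    """A session directory or one of its sidecars is malformed."""


class QualityFlagError(ValueError):
    """An invalid quality flag or a forbidden flag transition."""


@dataclass
class Scan:
    """One acquisition within a session."""

    scan_id: str
    metadata: dict
    quality_flag: str = "usable"
    files: list = field(default_factory=list)  # paths relative to scan dir
    path: Optional[Path] = None

    def nifti_files(self) -> list:
        return [f for f in self.files if str(f).endswith((".nii", ".nii.gz"))]


@dataclass
class Resource:
    """A named bundle of derivative files attached to a session."""

    name: str
    path: Optional[Path] = None
    files: list = field(default_factory=list)  # (relative path, size in bytes)
    provenance: Optional[dict] = None

    def file_paths(self) -> list:
        return [f for f, _ in self.files]


@dataclass
class Session:
    """One imaging visit (MR or PET): ordered scans plus derivative resources."""

    session_id: str
    subject_id: str
    modality: str
    scans: list = field(default_factory=list)
    resources: dict = field(default_factory=dict)
    path: Optional[Path] = None

    def scan(self, scan_id: str) -> Scan:
        for s in self.scans:
            if s.scan_id == scan_id:
                return s
        raise KeyError(scan_id)


@dataclass
class Project:
    """A directory-backed imaging project."""

    root: Path
    sessions: list = field(default_factory=list)
    warnings: list = field(default_factory=list)

    @property
    def subjects(self) -> set:
        return {s.subject_id for s in self.sessions}

    def session(self, session_id: str) -> Session:
        for s in self.sessions:
            if s.session_id == session_id:
                return s
        raise KeyError(session_id)

    def sessions_of(self, subject_id: str, modality: Optional[str] = None) -> list:
        out = [s for s in self.sessions if s.subject_id == subject_id]
        if modality is not None:
            out = [s for s in out if s.modality == modality]
        return out


def _validate_metadata(meta: dict, source: Path) -> None:
    for key in NUMERIC_METADATA_KEYS:
        if key not in meta or meta[key] is None:
            continue
        try:
            value = float(meta[key])
        except (TypeError, ValueError):
            raise SessionFormatError(
                f"{source}: metadata key {key!r} must be numeric, "
                f"got {meta[key]!r}"
            ) from None
        if not math.isfinite(value) or value < 0:
            raise SessionFormatError(
                f"{source}: metadata key {key!r} must be a finite "
                f"non-negative number, got {meta[key]!r}"
            )


def _load_scan(scan_dir: Path) -> Scan:
    metadata: dict = {}
    for sidecar in sorted(scan_dir.glob("*.json")):
        if sidecar.name == SCAN_QUALITY_FILE:
            continue
        try:
            with open(sidecar) as fh:
                metadata.update(json.load(fh))
        except json.JSONDecodeError as exc:
            raise SessionFormatError(f"unparseable sidecar {sidecar}: {exc}") from None
    _validate_metadata(metadata, scan_dir)

    flag = "usable"
    quality_file = scan_dir / SCAN_QUALITY_FILE
    if quality_file.exists():
        with open(quality_file) as fh:
            flag = json.load(fh).get("quality_flag", "usable")
        if flag not in QUALITY_FLAGS:
            raise SessionFormatError(f"{quality_file}: invalid quality flag {flag!r}")

    files = sorted(
        str(p.relative_to(scan_dir))
        for p in scan_dir.rglob("*")
        if p.is_file() and p.name != SCAN_QUALITY_FILE
    )
    return Scan(
        scan_id=scan_dir.name,
        metadata=metadata,
        quality_flag=flag,
        files=files,
        path=scan_dir,
    )


def _load_resource(res_dir: Path) -> Resource:
    provenance = None
    prov_file = res_dir / PROVENANCE_FILE
    if prov_file.exists():
        with open(prov_file) as fh:
            provenance = json.load(fh)
    files = sorted(
        (str(p.relative_to(res_dir)), p.stat().st_size)
        for p in res_dir.rglob("*")
        if p.is_file() and p.name != PROVENANCE_FILE
    )
    return Resource(name=res_dir.name, path=res_dir, files=files, provenance=provenance)


def load_session(path) -> Session:
    """Load one session directory.

    Scans are ordered lexicographically by scan id so that reports are
    deterministic.  An unparseable sidecar raises
    :class:`SessionFormatError` naming the offending file.
    """
    path = Path(path)
    descriptor = path / SESSION_DESCRIPTOR
    if not descriptor.exists():
        raise SessionFormatError(f"no {SESSION_DESCRIPTOR} in {path}")
    with open(descriptor) as fh:
        try:
            desc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SessionFormatError(f"unparseable descriptor {descriptor}: {exc}") from None
    for key in ("session_id", "subject_id", "modality"):
        if key not in desc:
            raise SessionFormatError(f"{descriptor}: missing field {key!r}")
    if desc["modality"] not in MODALITIES:
        raise SessionFormatError(f"{descriptor}: unknown modality {desc['modality']!r}")

    scans = []
    scans_dir = path / "scans"
    if scans_dir.is_dir():
        for scan_dir in sorted(scans_dir.iterdir()):
            if scan_dir.is_dir():
                scans.append(_load_scan(scan_dir))

    resources: dict = {}
    res_root = path / "resources"
    if res_root.is_dir():
        for res_dir in sorted(res_root.iterdir()):
            if res_dir.is_dir():
                resources[res_dir.name] = _load_resource(res_dir)

    return Session(
        session_id=desc["session_id"],
        subject_id=desc["subject_id"],
        modality=desc["modality"],
        scans=scans,
        resources=resources,
        path=path,
    )


def load_project(root) -> Project:
    """Enumerate all sessions under ``root``.

    A directory is a session iff it contains ``session.json``.  Malformed
    sessions and stray non-session folders are collected as warnings on the
    returned :class:`Project`, never silently dropped.
    """
    root = Path(root)
    if not root.is_dir():
        raise FileNotFoundError(f"project root {root} does not exist")
    project = Project(root=root)
    for subject_dir in sorted(p for p in root.iterdir() if p.is_dir()):
        entries = sorted(p for p in subject_dir.iterdir() if p.is_dir())
        if not entries:
            project.warnings.append(f"{subject_dir}: no session directories")
            continue
        for session_dir in entries:
            if not (session_dir / SESSION_DESCRIPTOR).exists():
                project.warnings.append(
                    f"{session_dir}: not a session (no {SESSION_DESCRIPTOR})"
                )
                continue
            try:
                project.sessions.append(load_session(session_dir))
            except SessionFormatError as exc:
                project.warnings.append(f"{session_dir}: skipped ({exc})")
    seen: dict = {}
    for s in project.sessions:
        if s.session_id in seen:
            project.warnings.append(
                f"duplicate session id {s.session_id!r} "
                f"({seen[s.session_id]} and {s.path})"
            )
        seen[s.session_id] = s.path
    return project


def set_quality_flag(scan: Scan, new_flag: str, force: bool = False,
                     persist: bool = True) -> Scan:
    """Change a scan's quality flag.

    Engine-initiated transitions may only *downgrade*
    (usable -> questionable -> unusable); an upgrade attempt is rejected
    with a warning and leaves the scan untouched.  ``force=True`` is the
    manual override and allows any transition.
    """
    if new_flag not in QUALITY_FLAGS:
        raise QualityFlagError(f"invalid quality flag {new_flag!r}")
    old_rank = QUALITY_FLAGS.index(scan.quality_flag)
    new_rank = QUALITY_FLAGS.index(new_flag)
    if new_rank < old_rank and not force:
        warnings.warn(
            f"rejected upgrade {scan.quality_flag} -> {new_flag} on scan "
            f"{scan.scan_id} (use force=True to override)",
            stacklevel=2,
        )
        return scan
    scan.quality_flag = new_flag
    if persist and scan.path is not None:
        with open(scan.path / SCAN_QUALITY_FILE, "w") as fh:
            json.dump({"quality_flag": new_flag}, fh)
    return scan


def write_session(session: Session, root) -> Path:
    """Materialize a session under ``root/<subject>/<session>``.

    Copies scan and resource payloads from the session's backing
    directories when present; used by the fixture generator and by the
    round-trip contract (``load_session(write_session(s)) == s`` on
    metadata, file lists and flags).
    """
    root = Path(root)
    dest = root / session.subject_id / session.session_id
    dest.mkdir(parents=True, exist_ok=True)
    with open(dest / SESSION_DESCRIPTOR, "w") as fh:
        json.dump(
            {
                "session_id": session.session_id,
                "subject_id": session.subject_id,
                "modality": session.modality,
            },
            fh,
            indent=1,
        )
    for scan in session.scans:
        scan_dir = dest / "scans" / scan.scan_id
        scan_dir.mkdir(parents=True, exist_ok=True)
        if scan.path is not None and Path(scan.path) != scan_dir:
            for rel in scan.files:
                src = Path(scan.path) / rel
                if src.exists():
                    (scan_dir / rel).parent.mkdir(parents=True, exist_ok=True)
                    shutil.copyfile(src, scan_dir / rel)
        sidecar = scan_dir / "image.json"
        with open(sidecar, "w") as fh:
            json.dump(scan.metadata, fh, indent=1, sort_keys=True)
        with open(scan_dir / SCAN_QUALITY_FILE, "w") as fh:
            json.dump({"quality_flag": scan.quality_flag}, fh)
    for resource in session.resources.values():
        res_dir = dest / "resources" / resource.name
        res_dir.mkdir(parents=True, exist_ok=True)
        if resource.path is not None and Path(resource.path) != res_dir:
            for rel in resource.file_paths():
                src = Path(resource.path) / rel
                if src.exists():
                    (res_dir / rel).parent.mkdir(parents=True, exist_ok=True)
                    shutil.copyfile(src, res_dir / rel)
        if resource.provenance is not None:
            with open(res_dir / PROVENANCE_FILE, "w") as fh:
                json.dump(resource.provenance, fh, indent=1, sort_keys=True)
    return dest
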