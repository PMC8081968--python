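"""Checks over pipeline outputs attached to a session as resources.

Covers file-manifest completeness, software-version and execution-time
provenance, label completeness and volume safety intervals of
segmentation label maps, and the two volume readers that feed them:
voxel-count label volumes from NIfTI label maps and structure volumes
from FreeSurfer ``aseg.stats`` tables.
"""

from __future__ import annotations

import datetime
import fnmatch
from pathlib import Path
from typing import Optional

import numpy as np

from ..config import IntervalSpec
from ..engine import TestResult
from ..model import Resource, Session

__all__ = [
    "has_correct_items",
    "has_correct_version",
    "execution_time_within",
    "compute_label_volumes",
    "has_all_subfields",
    "volumes_within_intervals",
    "parse_aseg_stats",
    "load_labelmap",
]


def has_correct_items(resource: Optional[Resource], expected) -> TestResult:
    """Pass iff every expected entry (glob patterns allowed) matches at
    least one file of the resource.

    Unexpected extra files are reported but do not fail: pipelines add
    logs freely.
    """
    if resource is None:
        return TestResult("HasCorrectItems", False, ["resource absent"])
    present = resource.file_paths()
    missing = [pat for pat in expected
               if not any(fnmatch.fnmatch(f, pat) for f in present)]
    unexpected = [f for f in present
                  if not any(fnmatch.fnmatch(f, pat) for pat in expected)]
    data = []
    if missing:
        data.append({"missing": missing})
    if unexpected:
        data.append({"unexpected (not failing)": unexpected})
    return TestResult("HasCorrectItems", not missing, data)


def has_correct_version(resource: Optional[Resource], expected: str) -> TestResult:
    """Pass iff the resource's provenance records exactly the expected
    software version."""
    if resource is None or not resource.provenance:
        return TestResult("HasCorrectVersion", False, ["provenance absent"])
    actual = resource.provenance.get("software_version")
    ok = actual == expected
    return TestResult("HasCorrectVersion", ok,
                      [{"expected": expected, "actual": actual}] if not ok
                      else [actual])


def _parse_ts(value: str) -> datetime.datetime:
    return datetime.datetime.fromisoformat(value)


def execution_time_within(resource: Optional[Resource],
                          max_seconds: float) -> TestResult:
    """Pass iff the pipeline's elapsed wall time (finished - started, from
    provenance timestamps) does not exceed ``max_seconds``."""
    if resource is None or not resource.provenance:
        return TestResult("ExecutionTime", False, ["provenance absent"])
    prov = resource.provenance
    if not prov.get("started") or not prov.get("finished"):
        return TestResult("ExecutionTime", False,
                          ["started/finished timestamps absent"])
    elapsed = (_parse_ts(prov["finished"]) - _parse_ts(prov["started"])).total_seconds()
    return TestResult("ExecutionTime", elapsed <= max_seconds,
                      [{"elapsed_seconds": elapsed, "max_seconds": max_seconds}])


def load_labelmap(path):
    """Load an integer label map; error on non-integer voxel data."""
    import nibabel as nib

    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise ValueError(f"{path}: label map has non-integer voxel values")
        data = np.round(data).astype(np.int32)
    return img, data


def compute_label_volumes(labelmap, labels=None) -> dict:
    """Volume per label: voxel count times voxel volume from the header.

    ``labelmap`` is a loaded NIfTI image (or a path).  Background (label 0)
    is excluded.  Volumes are in mm^3; anisotropic voxels are supported via
    the header zooms, no affine resampling is applied.
    """
    import nibabel as nib

    if isinstance(labelmap, (str, Path)):
        img, data = load_labelmap(labelmap)
    else:
        img = labelmap
        data = np.asanyarray(img.dataobj)
        if not np.issubdtype(data.dtype, np.integer):
            raise ValueError("label map has non-integer voxel values")
    voxel_mm3 = float(np.prod(img.header.get_zooms()[:3]))
    values, counts = np.unique(data, return_counts=True)
    table = {int(v): float(c) * voxel_mm3
             for v, c in zip(values, counts) if int(v) != 0}
    if labels is not None:
        table = {l: vol for l, vol in table.items() if l in set(labels)}
    return table


def has_all_subfields(labelmap, expected_labels) -> TestResult:
    """Pass iff every expected label occupies at least one voxel."""
    if isinstance(labelmap, (str, Path)):
        _, data = load_labelmap(labelmap)
    else:
        data = np.asanyarray(labelmap.dataobj)
    present = set(int(v) for v in np.unique(data))
    absent = sorted(set(int(l) for l in expected_labels) - present)
    return TestResult("HasAllSubfields", not absent,
                      [{"absent_labels": absent}] if absent else [])


def volumes_within_intervals(volumes: dict, intervals: dict) -> TestResult:
    """Pass iff every region with a configured interval has a measured
    volume inside it (inclusive bounds).

    Regions without an interval are ignored; a region keyed in
    ``intervals`` but absent from ``volumes`` fails (unmeasured).
    ``intervals`` values may be :class:`IntervalSpec` or (lower, upper)
    pairs.
    """
    failures = []
    for region, spec in intervals.items():
        if not isinstance(spec, IntervalSpec):
            spec = IntervalSpec(str(region), float(spec[0]), float(spec[1]))
        key = region
        if key not in volumes:
            # interval keys read from JSON config are strings
            try:
                key = int(region)
            except (TypeError, ValueError):
                pass
        if key not in volumes:
            failures.append({"region": region, "volume": None,
                             "interval": [spec.lower, spec.upper],
                             "note": "absent"})
        elif not spec.contains(volumes[key]):
            failures.append({"region": region, "volume": volumes[key],
                             "interval": [spec.lower, spec.upper]})
    return TestResult("VolumesWithinIntervals", not failures, failures)


def parse_aseg_stats(path) -> dict:
    """Parse a FreeSurfer ``aseg.stats`` table into {StructName: Volume_mm3}.

    The format is comment header lines starting with '#' (including a
    ``# ColHeaders`` line naming the columns) followed by a
    whitespace-delimited table.  Raises ``ValueError`` when the
    Volume_mm3 or StructName column cannot be located.
    """
    colheaders = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("ColHeaders"):
                    colheaders = stripped.split()[1:]
                continue
            rows.append(line.split())
    if colheaders is None:
        # Standard aseg.stats column order as a fallback for stripped files.
        colheaders = ["Index", "SegId", "NVoxels", "Volume_mm3", "StructName",
                      "normMean", "normStdDev", "normMin", "normMax", "normRange"]
    try:
        vol_idx = colheaders.index("Volume_mm3")
        name_idx = colheaders.index("StructName")
    except ValueError:
        raise ValueError(f"{path}: no Volume_mm3/StructName column "
                         f"in {colheaders}") from None
    table = {}
    for row in rows:
        if len(row) <= max(vol_idx, name_idx):
            raise ValueError(f"{path}: truncated row {row}")
        table[row[name_idx]] = float(row[vol_idx])
    return table


def resource_file(resource: Resource, pattern: str) -> Optional[Path]:
    """First file of the resource matching a glob pattern, or None."""
    for rel in resource.file_paths():
        if fnmatch.fnmatch(rel, pattern):
            return Path(resource.path) / rel
    return None


def session_resource(session: Session, name: str) -> Optional[Resource]:
    return session.resources.get(name)
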