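"""Site configuration: thresholds, patterns and string expectations.

All tunable expectations used by the shipped checks live in one place and
can be overridden from a single JSON config file.  The shipped defaults
match a single-site PET/MR cohort setup: FDG and flutemetamol tracers, a
Siemens PET camera and a Philips MR scanner, weight and injected-dose
acceptance windows of [40, 150] kg and [1.5e8, 3.5e8] Bq (inclusive — a
physical reading exactly at the bound is acceptable).

Derivative-pipeline expectations (file manifests, software versions,
execution-time ceilings, volume safety intervals) are deliberately broad
defaults and must be site-calibrated; they are placeholders, not
published reference ranges.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, asdict
from pathlib import Path

__all__ = ["IntervalSpec", "CheckConfig", "load_config", "DEFAULT_CONFIG"]


@dataclass(frozen=True)
class IntervalSpec:
    """A closed acceptance interval on a numeric metadata key or volume."""

    key: str
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower <= self.upper:
            raise ValueError(f"invalid interval [{self.lower}, {self.upper}]")

    def contains(self, value: float) -> bool:
        return self.lower <= value <= self.upper


def _default_pipelines() -> dict:
    # Per-pipeline derivative expectations. Manifests are glob patterns
    # relative to the resource directory. Volume intervals are in mm^3 and
    # intentionally generous: site-calibrate before production use.
    return {
        "ASHS": {
            "version": "ASHS 1.0.0",
            "manifest": ["*seg*.nii.gz", "volumes.csv"],
            "labelmap": "*seg*.nii.gz",
            "expected_labels": [1, 2, 3, 4, 5],
            "volume_intervals": {
                "1": [50.0, 5000.0],   # CA1
                "2": [20.0, 3000.0],   # CA2/3
                "3": [20.0, 3000.0],   # DG
                "4": [20.0, 3000.0],   # SUB
                "5": [20.0, 3000.0],   # ERC
            },
        },
        "SPM12": {
            "version": "SPM12 r7771",
            "manifest": ["*seg*.nii.gz", "pipeline.log"],
            "labelmap": "*seg*.nii.gz",
            "max_seconds": 3600,
            "volume_intervals": {
                "1": [500.0, 2.0e6],   # gray matter
                "2": [400.0, 1.5e6],   # white matter
            },
        },
        "FREESURFER6": {
            "version": "freesurfer-6.0.0",
            "manifest": ["stats/aseg.stats", "mri/aseg*.nii.gz"],
            "labelmap": "mri/aseg*.nii.gz",
        },
        "DTIFIT": {
            "version": "FSL 6.0.1",
            "manifest": ["*_FA.nii.gz", "*_MD.nii.gz"],
        },
        "ANTS": {
            "version": "ANTs 2.3.1",
            "manifest": ["*Warped.nii.gz", "*.mat"],
        },
    }


@dataclass
class CheckConfig:
    """Every threshold, pattern and string expectation used by the checks."""

    allowed_tracers: tuple = ("FDG", "FLUTEMETAMOL")
    expected_pet_scanner: str = "SIEMENS Biograph64 VG51C"
    expected_mr_scanner: str = "Philips Ingenia CX"
    subject_id_pattern: str = r"^[A-Z]+[0-9]{5}$"
    consistency_keys: tuple = ("PatientID", "StudyDate", "Manufacturer",
                               "ManufacturerModelName")
    weight_interval: IntervalSpec = field(
        default_factory=lambda: IntervalSpec("PatientWeight", 40.0, 150.0))
    dose_interval: IntervalSpec = field(
        default_factory=lambda: IntervalSpec("RadionuclideTotalDose", 1.5e8, 3.5e8))
    t1_designations: tuple = ("T1",)  # SeriesDescription substrings, case-insensitive
    pipelines: dict = field(default_factory=_default_pipelines)

    def __post_init__(self):
        re.compile(self.subject_id_pattern)  # fail fast on a broken pattern

    def pipeline(self, name: str) -> dict:
        return self.pipelines[name]


DEFAULT_CONFIG = CheckConfig()


def load_config(path=None) -> CheckConfig:
    """Load a site config JSON, overriding shipped defaults key by key."""
    if path is None:
        return CheckConfig()
    with open(path) as fh:
        overrides = json.load(fh)
    base = asdict(CheckConfig())
    for key, value in overrides.items():
        if key not in base:
            raise KeyError(f"unknown config key {key!r}")
        base[key] = value
    for key in ("weight_interval", "dose_interval"):
        if isinstance(base[key], dict):
            base[key] = IntervalSpec(**base[key])
    for key in ("allowed_tracers", "consistency_keys", "t1_designations"):
        base[key] = tuple(base[key])
    return CheckConfig(**base)
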