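"""The shipped validator registry.

Assembles the concrete validators from the generic acquisition and
derivative primitives:

* **PetSessionValidator** — nine acquisition checks on every new PET
  session (tracer, metadata consistency, scanner model, weight and dose
  windows, subject-id format, usable-T1 availability, and runnability of
  the Centiloid and FDG quantification pipelines), in that order.
* **ArchivingValidator** — run at MR archiving time: NIfTI conversion
  (scan-level), subject-id format, MR scanner model, metadata consistency.
* **ASHSValidator / SPM12Validator / FreeSurfer6Validator /
  DTIFITValidator / ANTSValidator** — derivative checks (label
  completeness, software version, file manifest, volume safety intervals,
  execution time, snapshot generation) over the corresponding pipeline
  resources.

Each test declares a passing and a failing fixture session inside the
self-check project (:mod:`neuroqc.fixtures`), making the registry fully
self-testing.
"""

from __future__ import annotations

from typing import Optional

from .. import fixtures
from ..config import CheckConfig, DEFAULT_CONFIG, IntervalSpec
from ..engine import FixtureRef, TestResult, TestSpec, ValidatorSpec
from . import acquisition as acq
from . import derivatives as der

__all__ = ["build_registry", "get_validator", "iter_tests"]


def _refs(validator: str, defect_id: str) -> dict:
    return {
        "passing": FixtureRef(fixtures.passing_session_relpath(validator)),
        "failing": FixtureRef(fixtures.failing_session_relpath(defect_id)),
    }


# -- derivative test runners -----------------------------------------------

def _resource_test(session, project, name: str, op):
    return op(session.resources.get(name))


def _labelmap_volumes(session, config: CheckConfig, pipeline: str):
    resource = session.resources.get(pipeline)
    if resource is None:
        raise FileNotFoundError(f"resource {pipeline} absent")
    pattern = config.pipeline(pipeline)["labelmap"]
    path = der.resource_file(resource, pattern)
    if path is None:
        raise FileNotFoundError(f"{pipeline}: no label map matching {pattern!r}")
    return der.compute_label_volumes(path)


def _run_subfields(session, project, config: CheckConfig, pipeline: str):
    resource = session.resources.get(pipeline)
    if resource is None:
        return TestResult("HasAllSubfields", False, ["resource absent"])
    pattern = config.pipeline(pipeline)["labelmap"]
    path = der.resource_file(resource, pattern)
    if path is None:
        return TestResult("HasAllSubfields", False,
                          [f"no label map matching {pattern!r}"])
    return der.has_all_subfields(path, config.pipeline(pipeline)["expected_labels"])


def _run_volume_intervals(session, project, config: CheckConfig, pipeline: str):
    volumes = _labelmap_volumes(session, config, pipeline)
    return der.volumes_within_intervals(
        volumes, config.pipeline(pipeline)["volume_intervals"])


def _run_snapshot(session, project, config: CheckConfig, pipeline: str,
                  test_id: str):
    """Render the pipeline's segmentation over the subject's T1 (when on the
    same voxel grid) and pass iff a non-empty snapshot file is produced."""
    from ..snapshot import SnapshotSpec, plot_segment

    resource = session.resources.get(pipeline)
    if resource is None:
        return TestResult(test_id, False, ["resource absent"])
    pattern = config.pipeline(pipeline)["labelmap"]
    seg_path = der.resource_file(resource, pattern)
    if seg_path is None:
        return TestResult(test_id, False, [f"no label map matching {pattern!r}"])
    out_dir = session.path / "resources" / "SNAPSHOTS"
    spec = SnapshotSpec(planes=("axial",), n_slices=4, rowsize=2)
    out = plot_segment(seg_path, bg_path=None, spec=spec,
                       out_path=out_dir / f"{test_id}.png")
    ok = out.exists() and out.stat().st_size > 0
    rel = f"resources/SNAPSHOTS/{test_id}.png"
    return TestResult(test_id, ok, [{"snapshot": rel}])


# -- registry construction -------------------------------------------------

def build_registry(config: Optional[CheckConfig] = None) -> dict:
    """Build the shipped validators. ``config`` overrides site expectations."""
    return _build(config or DEFAULT_CONFIG)


def _build(config: CheckConfig) -> dict:
    c = config

    def pet_scanner(session, project):
        return acq.metadata_present_and_allowed(
            session, "ManufacturerModelName", {c.expected_pet_scanner})

    def mr_scanner(session, project):
        return acq.metadata_present_and_allowed(
            session, "ManufacturerModelName", {c.expected_mr_scanner})

    pet = ValidatorSpec("PetSessionValidator", [
        TestSpec(
            "IsTracerCorrect",
            "Checks that the radiopharmaceutical (tracer) is registered in "
            "the DICOM-derived metadata of every scan and belongs to the "
            f"allowed set {sorted(c.allowed_tracers)}.",
            lambda s, p: acq.metadata_present_and_allowed(
                s, "Radiopharmaceutical", c.allowed_tracers),
            **_refs("PetSessionValidator", "missing_tracer")),
        TestSpec(
            "IsSeriesDescriptionConsistent",
            "Checks that session-level metadata "
            f"({', '.join(c.consistency_keys)}) are consistent across all "
            "scans of the session.",
            lambda s, p: acq.metadata_consistent_across_scans(
                s, c.consistency_keys),
            **_refs("PetSessionValidator", "inconsistent_metadata")),
        TestSpec(
            "IsScannerVersionCorrect",
            "Checks that the scanner model registered in the DICOM-derived "
            f"metadata matches '{c.expected_pet_scanner}'.",
            pet_scanner,
            **_refs("PetSessionValidator", "bad_scanner")),
        TestSpec(
            "IsSubjectWeightConsistent",
            "Checks that the registered subject weight lies between "
            f"{c.weight_interval.lower:g} and {c.weight_interval.upper:g} kg "
            "(inclusive).",
            lambda s, p: acq.metadata_in_interval(s, c.weight_interval),
            **_refs("PetSessionValidator", "weight_low")),
        TestSpec(
            "IsTracerDoseConsistent",
            "Checks that the registered tracer dose lies between "
            f"{c.dose_interval.lower:.1e} and {c.dose_interval.upper:.1e} Bq "
            "(inclusive).",
            lambda s, p: acq.metadata_in_interval(s, c.dose_interval),
            **_refs("PetSessionValidator", "dose_low")),
        TestSpec(
            "IsSubjectIdCorrect",
            "Checks that the subject identifier has the right format "
            f"(pattern {c.subject_id_pattern}).",
            lambda s, p: acq.id_matches_pattern(s, c.subject_id_pattern),
            **_refs("PetSessionValidator", "bad_subject_id")),
        TestSpec(
            "HasUsableT1",
            "Checks that the subject has a valid T1-weighted image: some MR "
            "session of the same subject contains a T1 scan flagged usable.",
            lambda s, p: acq.has_usable_t1(s, p, c),
            **_refs("PetSessionValidator", "no_usable_t1")),
        TestSpec(
            "IsCentiloidRunnable",
            "Checks that the data are suited for the Centiloid amyloid "
            "quantification pipeline: flutemetamol tracer, PET NIfTI "
            "present, usable T1 available.",
            lambda s, p: acq.quantification_runnable(s, p, "centiloid", c),
            **_refs("PetSessionValidator", "no_usable_t1_flute")),
        TestSpec(
            "IsFDGQuantificationRunnable",
            "Checks that the data are suited for the FDG quantification "
            "pipeline: FDG tracer, PET NIfTI present, usable T1 available.",
            lambda s, p: acq.quantification_runnable(s, p, "fdg", c),
            **_refs("PetSessionValidator", "no_usable_t1")),
    ])

    archiving = ValidatorSpec("ArchivingValidator", [
        TestSpec(
            "HasNifti",
            "Checks, for every scan, that the DICOM files have been "
            "converted to a readable NIfTI volume.",
            acq.scan_has_nifti, level="scan", on_fail_flag="questionable",
            **_refs("ArchivingValidator", "missing_nifti")),
        TestSpec(
            "IsSubjectIdCorrect",
            "Checks that the subject identifier has the right format "
            f"(pattern {c.subject_id_pattern}).",
            lambda s, p: acq.id_matches_pattern(s, c.subject_id_pattern),
            **_refs("ArchivingValidator", "bad_subject_id_mr")),
        TestSpec(
            "IsScannerVersionCorrect",
            "Checks that the MR scanner model registered in the "
            f"DICOM-derived metadata matches '{c.expected_mr_scanner}'.",
            mr_scanner,
            **_refs("ArchivingValidator", "bad_scanner_mr")),
        TestSpec(
            "IsSeriesDescriptionConsistent",
            "Checks that session-level metadata "
            f"({', '.join(c.consistency_keys)}) are consistent across all "
            "scans of the session.",
            lambda s, p: acq.metadata_consistent_across_scans(
                s, c.consistency_keys),
            **_refs("ArchivingValidator", "inconsistent_metadata_mr")),
    ])

    def manifest_test(pipeline):
        return lambda s, p: der.has_correct_items(
            s.resources.get(pipeline), c.pipeline(pipeline)["manifest"])

    def version_test(pipeline):
        return lambda s, p: der.has_correct_version(
            s.resources.get(pipeline), c.pipeline(pipeline)["version"])

    ashs = ValidatorSpec("ASHSValidator", [
        TestSpec(
            "HasAllSubfields",
            "Checks that all expected hippocampal subfield labels "
            f"({c.pipeline('ASHS')['expected_labels']}) appear in the final "
            "segmentation with at least one voxel each.",
            lambda s, p: _run_subfields(s, p, c, "ASHS"),
            **_refs("ASHSValidator", "missing_subfield")),
        TestSpec(
            "HasCorrectASHSVersion",
            "Checks that the segmentation was produced by the expected "
            f"software version ('{c.pipeline('ASHS')['version']}').",
            version_test("ASHS"),
            **_refs("ASHSValidator", "wrong_version")),
        TestSpec(
            "HasCorrectItems",
            "Checks that the list of generated files matches the expected "
            f"manifest {c.pipeline('ASHS')['manifest']}.",
            manifest_test("ASHS"),
            **_refs("ASHSValidator", "missing_manifest_file")),
        TestSpec(
            "HasNormalSubfieldVolumes",
            "Checks that the resulting subfield volumes fall inside "
            "configured safety intervals (mm^3; site-calibrate the shipped "
            "defaults).",
            lambda s, p: _run_volume_intervals(s, p, c, "ASHS"),
            **_refs("ASHSValidator", "abnormal_volume")),
        TestSpec(
            "ASHSSnapshot",
            "Generates a snapshot of the final subfield segmentation for "
            "visual review; passes iff the snapshot file is produced and "
            "non-empty.",
            lambda s, p: _run_snapshot(s, p, c, "ASHS", "ASHSSnapshot"),
            **_refs("ASHSValidator", "empty_labelmap")),
    ])

    spm = ValidatorSpec("SPM12Validator", [
        TestSpec(
            "HasNormalVolumes",
            "Checks that global gray/white matter volumes fall inside "
            "predefined target intervals (mm^3; site-calibrate the shipped "
            "defaults).",
            lambda s, p: _run_volume_intervals(s, p, c, "SPM12"),
            **_refs("SPM12Validator", "abnormal_volume_spm12")),
        TestSpec(
            "SPM12SegmentExecutionTime",
            "Checks that the segmentation pipeline did not take longer than "
            f"{c.pipeline('SPM12')['max_seconds']} seconds; elapsed time is "
            "recorded in the result data.",
            lambda s, p: der.execution_time_within(
                s.resources.get("SPM12"), c.pipeline("SPM12")["max_seconds"]),
            **_refs("SPM12Validator", "overlong_execution")),
        TestSpec(
            "HasCorrectItems",
            "Checks that the list of generated files matches the expected "
            f"manifest {c.pipeline('SPM12')['manifest']}.",
            manifest_test("SPM12"),
            **_refs("SPM12Validator", "missing_manifest_file_spm12")),
        TestSpec(
            "HasCorrectSPM12Version",
            "Checks that the segmentation was produced by the expected "
            f"software version ('{c.pipeline('SPM12')['version']}').",
            version_test("SPM12"),
            **_refs("SPM12Validator", "wrong_version_spm12")),
        TestSpec(
            "SPM12Snapshot",
            "Generates a snapshot of the tissue segmentation for visual "
            "review; passes iff the snapshot file is produced and non-empty.",
            lambda s, p: _run_snapshot(s, p, c, "SPM12", "SPM12Snapshot"),
            **_refs("SPM12Validator", "empty_labelmap_spm12")),
    ])

    freesurfer = ValidatorSpec("FreeSurfer6Validator", [
        TestSpec(
            "HasCorrectItems",
            "Checks that the FreeSurfer output contains the expected files "
            f"({c.pipeline('FREESURFER6')['manifest']}), including the "
            "aseg.stats table.",
            manifest_test("FREESURFER6"),
            **_refs("FreeSurfer6Validator", "missing_manifest_file_fs6")),
        TestSpec(
            "HasCorrectFreeSurfer6Version",
            "Checks that recon-all was run with the expected software "
            f"version ('{c.pipeline('FREESURFER6')['version']}').",
            version_test("FREESURFER6"),
            **_refs("FreeSurfer6Validator", "wrong_version_fs6")),
        TestSpec(
            "FreeSurfer6Snapshot",
            "Generates a snapshot of the subcortical segmentation for "
            "visual review; passes iff the snapshot file is produced and "
            "non-empty.",
            lambda s, p: _run_snapshot(s, p, c, "FREESURFER6",
                                       "FreeSurfer6Snapshot"),
            **_refs("FreeSurfer6Validator", "empty_labelmap_fs6")),
    ])

    dtifit = ValidatorSpec("DTIFITValidator", [
        TestSpec(
            "HasCorrectItems",
            "Checks that the DTIFIT output contains the expected diffusion "
            f"maps ({c.pipeline('DTIFIT')['manifest']}).",
            manifest_test("DTIFIT"),
            **_refs("DTIFITValidator", "missing_manifest_file_dtifit")),
        TestSpec(
            "HasCorrectDTIFITVersion",
            "Checks that DTIFIT was run with the expected software version "
            f"('{c.pipeline('DTIFIT')['version']}').",
            version_test("DTIFIT"),
            **_refs("DTIFITValidator", "wrong_version_dtifit")),
    ])

    ants = ValidatorSpec("ANTSValidator", [
        TestSpec(
            "HasCorrectItems",
            "Checks that the ANTs registration output contains the expected "
            f"files ({c.pipeline('ANTS')['manifest']}).",
            manifest_test("ANTS"),
            **_refs("ANTSValidator", "missing_manifest_file_ants")),
        TestSpec(
            "HasCorrectANTSVersion",
            "Checks that the registration was run with the expected "
            f"software version ('{c.pipeline('ANTS')['version']}').",
            version_test("ANTS"),
            **_refs("ANTSValidator", "wrong_version_ants")),
    ])

    return {v.name: v for v in
            (pet, archiving, ashs, spm, freesurfer, dtifit, ants)}


def get_validator(name: str, config: Optional[CheckConfig] = None) -> ValidatorSpec:
    registry = build_registry(config)
    if name not in registry:
        raise KeyError(
            f"unknown validator {name!r}; available: {sorted(registry)}")
    return registry[name]


def iter_tests(config: Optional[CheckConfig] = None):
    """Yield (validator_name, TestSpec) over every shipped test."""
    for validator in build_registry(config).values():
        for test in validator.tests:
            yield validator.name, test
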