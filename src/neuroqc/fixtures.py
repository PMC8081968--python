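"""Synthetic imaging projects with controllable defects.

Generates complete filesystem-backed projects — MR/PET sessions with
NIfTI volumes, DICOM-derived JSON sidecars, and derivative resources
(segmentation label maps, FreeSurfer-style ``aseg.stats`` tables, file
manifests, provenance records) — entirely from a seed.  A clean session
passes its validator fully; each :data:`DEFECTS` entry injects one
deliberate flaw that flips its targeted test to fail, which is what makes
the whole check registry self-testing (every test ships a passing and a
failing fixture).

Everything is a pure function of (parameters, seed): per-session seeds
are derived from the global seed, so identical calls produce
byte-identical trees.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import Session, Scan, load_session

__all__ = [
    "DefectSpec", "DEFECTS", "make_phantom", "make_labelmap",
    "make_session", "make_project", "make_selfcheck_project",
    "passing_session_relpath", "failing_session_relpath",
]

# Metadata defaults for a clean synthetic session (study conditions).
PET_DEFAULTS = {
    "PatientWeight": 75.0,
    "RadionuclideTotalDose": 2.0e8,
    "Radiopharmaceutical": "FDG",
    "Manufacturer": "SIEMENS",
    "ManufacturerModelName": "SIEMENS Biograph64 VG51C",
    "SeriesDescription": "PET AC 3D",
    "StudyDate": "20240101",
    "Modality": "PT",
}
MR_DEFAULTS = {
    "Manufacturer": "Philips",
    "ManufacturerModelName": "Philips Ingenia CX",
    "SeriesDescription": "T1 MPRAGE",
    "StudyDate": "20240101",
    "Modality": "MR",
}

PHANTOM_SHAPE = (16, 16, 16)
LABELMAP_SHAPE = (24, 24, 24)

ASHS_COUNTS = {1: 300, 2: 120, 3: 80, 4: 150, 5: 100}
SPM_COUNTS = {1: 4000, 2: 3000}
ASEG_COUNTS = {17: 400, 53: 380}  # Left/Right-Hippocampus SegIds

#: Structures written into synthetic aseg.stats tables (name, base mm3).
ASEG_STRUCTURES = [
    ("Left-Lateral-Ventricle", 7500.0),
    ("Left-Hippocampus", 4250.0),
    ("Right-Hippocampus", 4380.0),
    ("Left-Amygdala", 1750.0),
    ("Right-Amygdala", 1820.0),
    ("Brain-Stem", 21500.0),
]


@dataclass(frozen=True)
class DefectSpec:
    """One deliberate flaw: which validator/test it targets, which other
    tests necessarily break with it, and how to inject it."""

    defect_id: str
    validator: str
    targeted_test: str
    expected_fails: tuple  # full fail set incl. precondition collateral
    kind: str              # "PET" | "MR" | derivative resource name
    params: dict = field(default_factory=dict)


def _d(defect_id, validator, targeted, expected, kind, **params):
    return DefectSpec(defect_id, validator, targeted, tuple(expected), kind, params)


DEFECTS = {d.defect_id: d for d in [
    # --- PET acquisition (PetSessionValidator) -----------------------------
    _d("weight_low", "PetSessionValidator", "IsSubjectWeightConsistent",
       ["IsSubjectWeightConsistent"], "PET", PatientWeight=30.0),
    _d("weight_high", "PetSessionValidator", "IsSubjectWeightConsistent",
       ["IsSubjectWeightConsistent"], "PET", PatientWeight=200.0),
    _d("dose_low", "PetSessionValidator", "IsTracerDoseConsistent",
       ["IsTracerDoseConsistent"], "PET", RadionuclideTotalDose=1.0e8),
    _d("dose_high", "PetSessionValidator", "IsTracerDoseConsistent",
       ["IsTracerDoseConsistent"], "PET", RadionuclideTotalDose=5.0e8),
    _d("bad_scanner", "PetSessionValidator", "IsScannerVersionCorrect",
       ["IsScannerVersionCorrect"], "PET",
       ManufacturerModelName="SIEMENS Biograph TruePoint"),
    _d("missing_tracer", "PetSessionValidator", "IsTracerCorrect",
       ["IsTracerCorrect"], "PET", Radiopharmaceutical=None),
    _d("bad_subject_id", "PetSessionValidator", "IsSubjectIdCorrect",
       ["IsSubjectIdCorrect"], "PET", subject_id="alfa_9x"),
    _d("inconsistent_metadata", "PetSessionValidator",
       "IsSeriesDescriptionConsistent", ["IsSeriesDescriptionConsistent"],
       "PET", second_scan_overrides={"StudyDate": "20240202"}),
    _d("no_usable_t1", "PetSessionValidator", "HasUsableT1",
       ["HasUsableT1", "IsFDGQuantificationRunnable"], "PET",
       t1_flag="unusable"),
    _d("no_usable_t1_flute", "PetSessionValidator", "IsCentiloidRunnable",
       ["HasUsableT1", "IsCentiloidRunnable"], "PET",
       t1_flag="unusable", Radiopharmaceutical="FLUTEMETAMOL"),
    # --- MR archiving (ArchivingValidator) ---------------------------------
    _d("missing_nifti", "ArchivingValidator", "HasNifti",
       ["HasNifti"], "MR", drop_nifti=True),
    _d("bad_scanner_mr", "ArchivingValidator", "IsScannerVersionCorrect",
       ["IsScannerVersionCorrect"], "MR",
       ManufacturerModelName="GE Discovery MR750"),
    _d("bad_subject_id_mr", "ArchivingValidator", "IsSubjectIdCorrect",
       ["IsSubjectIdCorrect"], "MR", subject_id="mr_bad_1"),
    _d("inconsistent_metadata_mr", "ArchivingValidator",
       "IsSeriesDescriptionConsistent", ["IsSeriesDescriptionConsistent"],
       "MR", second_scan_overrides={"StudyDate": "20240303"}),
    # --- ASHS derivative (ASHSValidator) -----------------------------------
    _d("missing_subfield", "ASHSValidator", "HasAllSubfields",
       ["HasAllSubfields", "HasNormalSubfieldVolumes"], "ASHS",
       label_counts={**ASHS_COUNTS, 3: 0}),
    _d("wrong_version", "ASHSValidator", "HasCorrectASHSVersion",
       ["HasCorrectASHSVersion"], "ASHS", software_version="ASHS 0.9"),
    _d("missing_manifest_file", "ASHSValidator", "HasCorrectItems",
       ["HasCorrectItems"], "ASHS", drop_file="volumes.csv"),
    _d("abnormal_volume", "ASHSValidator", "HasNormalSubfieldVolumes",
       ["HasNormalSubfieldVolumes"], "ASHS",
       label_counts={**ASHS_COUNTS, 1: 5}),
    _d("empty_labelmap", "ASHSValidator", "ASHSSnapshot",
       ["ASHSSnapshot", "HasAllSubfields", "HasNormalSubfieldVolumes"],
       "ASHS", label_counts={k: 0 for k in ASHS_COUNTS}),
    # --- SPM12 derivative (SPM12Validator) ---------------------------------
    _d("abnormal_volume_spm12", "SPM12Validator", "HasNormalVolumes",
       ["HasNormalVolumes"], "SPM12", label_counts={1: 100, 2: 3000}),
    _d("overlong_execution", "SPM12Validator", "SPM12SegmentExecutionTime",
       ["SPM12SegmentExecutionTime"], "SPM12", elapsed_seconds=7200),
    _d("missing_manifest_file_spm12", "SPM12Validator", "HasCorrectItems",
       ["HasCorrectItems"], "SPM12", drop_file="pipeline.log"),
    _d("wrong_version_spm12", "SPM12Validator", "HasCorrectSPM12Version",
       ["HasCorrectSPM12Version"], "SPM12", software_version="SPM12 r6906"),
    _d("empty_labelmap_spm12", "SPM12Validator", "SPM12Snapshot",
       ["SPM12Snapshot", "HasNormalVolumes"], "SPM12",
       label_counts={k: 0 for k in SPM_COUNTS}),
    # --- FreeSurfer6 derivative --------------------------------------------
    _d("missing_manifest_file_fs6", "FreeSurfer6Validator", "HasCorrectItems",
       ["HasCorrectItems"], "FREESURFER6", drop_file="stats/aseg.stats"),
    _d("wrong_version_fs6", "FreeSurfer6Validator",
       "HasCorrectFreeSurfer6Version", ["HasCorrectFreeSurfer6Version"],
       "FREESURFER6", software_version="freesurfer-5.3.0"),
    _d("empty_labelmap_fs6", "FreeSurfer6Validator", "FreeSurfer6Snapshot",
       ["FreeSurfer6Snapshot"], "FREESURFER6",
       label_counts={k: 0 for k in ASEG_COUNTS}),
    # --- DTIFIT / ANTS derivatives -----------------------------------------
    _d("missing_manifest_file_dtifit", "DTIFITValidator", "HasCorrectItems",
       ["HasCorrectItems"], "DTIFIT", drop_file="dti_MD.nii.gz"),
    _d("wrong_version_dtifit", "DTIFITValidator", "HasCorrectDTIFITVersion",
       ["HasCorrectDTIFITVersion"], "DTIFIT", software_version="FSL 5.0.11"),
    _d("missing_manifest_file_ants", "ANTSValidator", "HasCorrectItems",
       ["HasCorrectItems"], "ANTS", drop_file="transform.mat"),
    _d("wrong_version_ants", "ANTSValidator", "HasCorrectANTSVersion",
       ["HasCorrectANTSVersion"], "ANTS", software_version="ANTs 2.1.0"),
]}

#: PET-session defects usable in :func:`make_project` defect plans.
PET_DEFECT_IDS = tuple(d.defect_id for d in DEFECTS.values() if d.kind == "PET")

# Deterministic fixture layout of the self-check project -------------------
_CLEAN_PET_SUBJECT = "ALFA10000"
_CLEAN_DERIV_SUBJECT = "ALFA20000"


def _defect_subject(defect_id: str) -> str:
    index = list(DEFECTS).index(defect_id)
    return f"ALFA{30000 + index:05d}"


def passing_session_relpath(validator: str) -> str:
    """Project-relative path of the clean session a validator's tests pass on."""
    if validator == "PetSessionValidator":
        return f"{_CLEAN_PET_SUBJECT}/{_CLEAN_PET_SUBJECT}_PET01"
    if validator == "ArchivingValidator":
        return f"{_CLEAN_PET_SUBJECT}/{_CLEAN_PET_SUBJECT}_MR01"
    return f"{_CLEAN_DERIV_SUBJECT}/{_CLEAN_DERIV_SUBJECT}_MR01"


def failing_session_relpath(defect_id: str) -> str:
    """Project-relative path of the single-defect session that fails the
    defect's targeted test."""
    defect = DEFECTS[defect_id]
    subject = defect.params.get("subject_id", _defect_subject(defect_id))
    suffix = "PET01" if defect.kind == "PET" else "MR01"
    return f"{subject}/{subject}_{suffix}"


# --------------------------------------------------------------------------
# NIfTI generators
# --------------------------------------------------------------------------

def make_phantom(shape=PHANTOM_SHAPE, seed=0):
    """Ellipsoidal two-shell "head" phantom with seeded Gaussian noise.

    1 mm isotropic header; deterministic per seed.
    """
    import nibabel as nib

    rng = np.random.default_rng(seed)
    grid = np.indices(shape).astype(np.float64)
    center = [(s - 1) / 2.0 for s in shape]
    semi = [s * 0.42 for s in shape]
    r2 = sum(((grid[i] - center[i]) / semi[i]) ** 2 for i in range(3))
    vol = np.zeros(shape)
    vol[r2 <= 1.0] = 40.0    # outer shell ("skull/scalp")
    vol[r2 <= 0.55] = 100.0  # inner tissue
    vol += rng.normal(0.0, 2.0, size=shape)
    img = nib.Nifti1Image(vol.astype(np.float32), np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0))
    return img


def make_labelmap(shape=LABELMAP_SHAPE, label_counts=None, seed=0, zooms=(1.0, 1.0, 1.0)):
    """Label map where each label occupies *exactly* its requested voxel
    count as a connected blob (grown by seeded breadth-first flooding).

    ``compute_label_volumes`` recovers ``count * voxel_volume`` exactly.
    """
    import nibabel as nib

    label_counts = dict(label_counts or {})
    total = int(np.prod(shape))
    if sum(label_counts.values()) > total:
        raise ValueError(
            f"requested {sum(label_counts.values())} voxels > volume {total}")
    rng = np.random.default_rng(seed)
    data = np.zeros(shape, dtype=np.int16)
    for label in sorted(label_counts):
        count = int(label_counts[label])
        if count <= 0:
            continue
        free = np.argwhere(data == 0)
        start = tuple(free[rng.integers(len(free))])
        frontier = [start]
        taken = 0
        seen = {start}
        while frontier and taken < count:
            voxel = frontier.pop(0)
            if data[voxel] != 0:
                continue
            data[voxel] = label
            taken += 1
            for delta in ((1, 0, 0), (-1, 0, 0), (0, 1, 0),
                          (0, -1, 0), (0, 0, 1), (0, 0, -1)):
                nxt = tuple(np.add(voxel, delta))
                if all(0 <= nxt[i] < shape[i] for i in range(3)) \
                        and nxt not in seen and data[nxt] == 0:
                    seen.add(nxt)
                    frontier.append(nxt)
        if taken < count:  # blob got enclosed: top up from remaining space
            for voxel in map(tuple, np.argwhere(data == 0)):
                data[voxel] = label
                taken += 1
                if taken == count:
                    break
    affine = np.diag(list(zooms) + [1.0])
    img = nib.Nifti1Image(data, affine)
    img.header.set_zooms(zooms)
    return img


# --------------------------------------------------------------------------
# Session and resource writers
# --------------------------------------------------------------------------

def _write_json(path: Path, payload: dict) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def _write_scan(session_dir: Path, scan_id: str, metadata: dict, seed: int,
                with_nifti: bool = True, quality_flag: str = "usable") -> None:
    scan_dir = session_dir / "scans" / scan_id
    scan_dir.mkdir(parents=True, exist_ok=True)
    if with_nifti:
        make_phantom(seed=seed).to_filename(str(scan_dir / "image.nii.gz"))
    _write_json(scan_dir / "image.json",
                {k: v for k, v in metadata.items() if v is not None})
    _write_json(scan_dir / "quality.json", {"quality_flag": quality_flag})


def _aseg_stats_text(volumes: list) -> str:
    """Genuine FreeSurfer aseg.stats dialect (comment header + ColHeaders)."""
    lines = [
        "# Title Segmentation Statistics",
        "# generating_program mri_segstats",
        "# anatomy_type volume",
        "# SegVolFile mri/aseg.mgz",
        "# NTableCols 10",
        "# TableCol  1 ColHeader Index",
        "# TableCol  2 ColHeader SegId",
        "# TableCol  3 ColHeader NVoxels",
        "# TableCol  4 ColHeader Volume_mm3",
        "# TableCol  5 ColHeader StructName",
        "# ColHeaders  Index SegId NVoxels Volume_mm3 StructName "
        "normMean normStdDev normMin normMax normRange",
    ]
    for i, (seg_id, name, vol) in enumerate(volumes, start=1):
        nvox = int(round(vol))
        lines.append(
            f"{i:3d} {seg_id:4d} {nvox:8d} {vol:10.1f}  {name:<30s}"
            f" {85.0:8.4f} {7.5:8.4f} {40.0:8.4f} {110.0:8.4f} {70.0:8.4f}"
        )
    return "\n".join(lines) + "\n"


def synthesize_aseg_volumes(seed: int) -> list:
    """(SegId, StructName, Volume_mm3) rows with seeded biological jitter."""
    rng = np.random.default_rng(seed)
    rows = []
    for i, (name, base) in enumerate(ASEG_STRUCTURES):
        vol = round(base * float(rng.uniform(0.9, 1.1)), 1)
        rows.append((i + 2, name, vol))
    return rows


def _write_resource(session_dir: Path, name: str, seed: int,
                    defect: dict | None = None) -> None:
    """Write one derivative resource with optional defect overrides."""
    defect = defect or {}
    res_dir = session_dir / "resources" / name
    res_dir.mkdir(parents=True, exist_ok=True)
    drop = defect.get("drop_file")
    version_defaults = {
        "ASHS": "ASHS 1.0.0", "SPM12": "SPM12 r7771",
        "FREESURFER6": "freesurfer-6.0.0", "DTIFIT": "FSL 6.0.1",
        "ANTS": "ANTs 2.3.1",
    }
    elapsed = int(defect.get("elapsed_seconds", 600))
    provenance = {
        "software_version": defect.get("software_version", version_defaults[name]),
        "started": "2024-01-02T08:00:00",
        "finished": f"2024-01-02T{8 + elapsed // 3600:02d}:"
                    f"{(elapsed % 3600) // 60:02d}:{elapsed % 60:02d}",
    }
    _write_json(res_dir / "provenance.json", provenance)

    def put_labelmap(fname: str, counts: dict) -> None:
        if drop != fname:
            (res_dir / fname).parent.mkdir(parents=True, exist_ok=True)
            make_labelmap(LABELMAP_SHAPE, defect.get("label_counts", counts),
                          seed=seed).to_filename(str(res_dir / fname))

    if name == "ASHS":
        put_labelmap("ashs_seg_left.nii.gz", ASHS_COUNTS)
        if drop != "volumes.csv":
            (res_dir / "volumes.csv").write_text(
                "label,volume_mm3\n" + "".join(
                    f"{l},{c:.1f}\n" for l, c in
                    sorted(defect.get("label_counts", ASHS_COUNTS).items())))
    elif name == "SPM12":
        put_labelmap("spm_seg8_labels.nii.gz", SPM_COUNTS)
        if drop != "pipeline.log":
            (res_dir / "pipeline.log").write_text("SPM12: segmentation done\n")
    elif name == "FREESURFER6":
        put_labelmap("mri/aseg.nii.gz", ASEG_COUNTS)
        if drop != "stats/aseg.stats":
            (res_dir / "stats").mkdir(exist_ok=True)
            (res_dir / "stats" / "aseg.stats").write_text(
                _aseg_stats_text(synthesize_aseg_volumes(seed)))
    elif name == "DTIFIT":
        for fname in ("dti_FA.nii.gz", "dti_MD.nii.gz"):
            if drop != fname:
                make_phantom(seed=seed).to_filename(str(res_dir / fname))
    elif name == "ANTS":
        if drop != "t1Warped.nii.gz":
            make_phantom(seed=seed).to_filename(str(res_dir / "t1Warped.nii.gz"))
        if drop != "transform.mat":
            (res_dir / "transform.mat").write_text(
                "AffineTransform_double_3_3\n1 0 0 0 1 0 0 0 1 0 0 0\n")
    else:
        raise ValueError(f"unknown resource kind {name!r}")


def make_session(root, kind: str, subject_id: str, defects=(), seed: int = 0,
                 resources=(), session_suffix: str | None = None) -> Path:
    """Write one session directory (plus metadata/defect injection).

    ``kind`` is "MR" or "PET".  ``defects`` is a list of defect ids from
    :data:`DEFECTS` applying to this session's own metadata/files (PET/MR
    kinds) or its derivative resources.  Returns the session path.
    """
    root = Path(root)
    suffix = session_suffix or ("PET01" if kind == "PET" else "MR01")
    session_id = f"{subject_id}_{suffix}"
    session_dir = root / subject_id / session_id
    session_dir.mkdir(parents=True, exist_ok=True)
    _write_json(session_dir / "session.json",
                {"session_id": session_id, "subject_id": subject_id,
                 "modality": kind})

    overrides: dict = {}
    second_scan = None
    drop_nifti = False
    for defect_id in defects:
        defect = DEFECTS[defect_id]
        if defect.kind != kind:
            continue
        params = dict(defect.params)
        params.pop("subject_id", None)
        params.pop("t1_flag", None)
        second_scan = params.pop("second_scan_overrides", second_scan)
        drop_nifti = params.pop("drop_nifti", drop_nifti)
        overrides.update(params)

    defaults = PET_DEFAULTS if kind == "PET" else MR_DEFAULTS
    metadata = {**defaults, "PatientID": subject_id, **overrides}
    _write_scan(session_dir, "001", metadata, seed=seed, with_nifti=not drop_nifti)
    if second_scan is not None:
        _write_scan(session_dir, "002", {**metadata, **second_scan},
                    seed=seed + 1, with_nifti=not drop_nifti)

    for res_name in resources:
        res_defect = None
        for defect_id in defects:
            if DEFECTS[defect_id].kind == res_name:
                res_defect = dict(DEFECTS[defect_id].params)
        _write_resource(session_dir, res_name, seed=seed + 7, defect=res_defect)
    return session_dir


def _make_subject(root: Path, subject_id: str, seed: int, defects=(),
                  pet: bool = True, resources=()) -> Path:
    """One subject: an MR session providing a usable T1 (unless the defect
    plan says otherwise) and optionally a PET session."""
    t1_flag = "usable"
    for defect_id in defects:
        flag = DEFECTS[defect_id].params.get("t1_flag")
        if flag:
            t1_flag = flag
    mr_defects = [d for d in defects if DEFECTS[d].kind == "MR"]
    res_defects = [d for d in defects
                   if DEFECTS[d].kind not in ("MR", "PET")]
    mr_dir = make_session(root, "MR", subject_id, defects=mr_defects + res_defects,
                          seed=seed, resources=resources)
    if t1_flag != "usable":
        _write_json(mr_dir / "scans" / "001" / "quality.json",
                    {"quality_flag": t1_flag})
    if pet:
        pet_defects = [d for d in defects if DEFECTS[d].kind == "PET"]
        make_session(root, "PET", subject_id, defects=pet_defects, seed=seed + 3)
    return root / subject_id


def make_selfcheck_project(root, seed: int = 0) -> Path:
    """The self-check project: one clean PET subject, one clean derivative
    subject, and one single-defect subject per :data:`DEFECTS` entry, at
    the deterministic paths the shipped registry's fixture references use."""
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    all_resources = ("ASHS", "SPM12", "FREESURFER6", "DTIFIT", "ANTS")
    _make_subject(root, _CLEAN_PET_SUBJECT, seed=seed, pet=True)
    _make_subject(root, _CLEAN_DERIV_SUBJECT, seed=seed + 100, pet=False,
                  resources=all_resources)
    for i, defect in enumerate(DEFECTS.values()):
        subject = defect.params.get("subject_id", _defect_subject(defect.defect_id))
        resources = () if defect.kind in ("PET", "MR") else (defect.kind,)
        _make_subject(root, subject, seed=seed + 1000 + i * 17,
                      defects=[defect.defect_id],
                      pet=defect.kind == "PET", resources=resources)
    return root


def make_project(root, n_sessions: int = 10, defect_plan=None,
                 seed: int = 0) -> Path:
    """A project of ``n_sessions`` PET subjects (each with an MR sibling
    carrying a FreeSurfer resource with a synthetic ``aseg.stats``).

    ``defect_plan`` maps session index -> list of PET defect ids injected
    into that subject's PET session.  Reproducible per seed.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    defect_plan = defect_plan or {}
    for index in range(n_sessions):
        subject = f"ALFA{index + 1:05d}"
        defects = list(defect_plan.get(index, []))
        _make_subject(root, subject, seed=seed + index * 29, defects=defects,
                      pet=True, resources=("FREESURFER6",))
    return root
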