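"""Acquisition metadata checks: primitives, gates and lookups."""

import pytest
from hypothesis import given, settings, strategies as st

from neuroqc.checks import acquisition as acq
from neuroqc.config import DEFAULT_CONFIG, IntervalSpec
from neuroqc.model import Project, Scan, Session


def _pet_session(n_scans=1, **overrides):
    base = {
        "PatientID": "ALFA00001", "PatientWeight": 75.0,
        "RadionuclideTotalDose": 2.0e8, "Radiopharmaceutical": "FDG",
        "ManufacturerModelName": "SIEMENS Biograph64 VG51C",
        "StudyDate": "20240101",
    }
    base.update(overrides)
    scans = [Scan(f"{i:03d}", dict(base)) for i in range(n_scans)]
    return Session("S1", "ALFA00001", "PET", scans=scans)


# -- metadata_present_and_allowed ------------------------------------------

@pytest.mark.parametrize("value,allowed,expected", [
    ("FDG", {"FDG", "FLUTEMETAMOL"}, True),
    ("flutemetamol", {"FDG", "FLUTEMETAMOL"}, True),      # case-insensitive
    ("  FDG  ", {"FDG", "FLUTEMETAMOL"}, True),           # trimmed
    ("PIB", {"FDG", "FLUTEMETAMOL"}, False),
    ("SIEMENS Biograph64 VG51C", {"SIEMENS Biograph64 VG51C"}, True),
])
def test_present_and_allowed(value, allowed, expected):
    session = _pet_session(Radiopharmaceutical=value)
    result = acq.metadata_present_and_allowed(session, "Radiopharmaceutical",
                                              allowed)
    assert result.has_passed is expected


def test_absent_key_fails_and_is_named():
    session = _pet_session()
    del session.scans[0].metadata["Radiopharmaceutical"]
    result = acq.metadata_present_and_allowed(session, "Radiopharmaceutical",
                                              {"FDG"})
    assert not result.has_passed
    assert any("Radiopharmaceutical" in str(item) for item in result.data)


# -- metadata_in_interval ---------------------------------------------------

WEIGHT = DEFAULT_CONFIG.weight_interval
DOSE = DEFAULT_CONFIG.dose_interval


@pytest.mark.parametrize("value,spec,expected", [
    (80.0, WEIGHT, True),
    (40.0, WEIGHT, True),     # inclusive lower bound
    (150.0, WEIGHT, True),    # inclusive upper bound
    (39.9, WEIGHT, False),
    (200.0, WEIGHT, False),
    (2.0e8, DOSE, True),
    (1.0e8, DOSE, False),
    (1.5e8, DOSE, True),
])
def test_interval_gate(value, spec, expected):
    session = _pet_session(**{spec.key: value})
    assert acq.metadata_in_interval(session, spec).has_passed is expected


def test_weight_boundary_sweep_recovers_interval_exactly():
    # brute-force sweep oracle: passing integer weights == [40, 150]
    passing = [w for w in range(0, 300)
               if acq.metadata_in_interval(_pet_session(PatientWeight=float(w)),
                                           WEIGHT).has_passed]
    assert passing == list(range(40, 151))


def test_non_numeric_value_fails_with_parse_note():
    result = acq.metadata_in_interval(_pet_session(PatientWeight="heavy"),
                                      WEIGHT)
    assert not result.has_passed
    assert any("not numeric" in str(item) for item in result.data)


@settings(max_examples=60, derandomize=True)
@given(value=st.floats(0, 400, allow_nan=False),
       lo=st.floats(0, 200, allow_nan=False),
       widen=st.floats(0, 200, allow_nan=False))
def test_interval_check_is_monotone_in_the_interval(value, lo, widen):
    # enlarging the interval never converts a pass into a fail
    session = _pet_session(PatientWeight=value)
    narrow = IntervalSpec("PatientWeight", lo, lo + 50.0)
    wide = IntervalSpec("PatientWeight", max(lo - widen, 0.0),
                        lo + 50.0 + widen)
    if acq.metadata_in_interval(session, narrow).has_passed:
        assert acq.metadata_in_interval(session, wide).has_passed


# -- metadata_consistent_across_scans --------------------------------------

def test_single_scan_session_is_vacuously_consistent():
    result = acq.metadata_consistent_across_scans(_pet_session(1),
                                                  {"StudyDate"})
    assert result.has_passed


def test_consistent_keys_across_three_scans():
    session = _pet_session(3)
    result = acq.metadata_consistent_across_scans(session,
                                                  {"StudyDate", "PatientID"})
    # oracle: per-key value-set cardinality is 1
    for key in ("StudyDate", "PatientID"):
        assert len({s.metadata[key] for s in session.scans}) == 1
    assert result.has_passed


def test_divergent_key_reported_with_value_set():
    session = _pet_session(2)
    session.scans[1].metadata["PatientID"] = "ALFA00002"
    result = acq.metadata_consistent_across_scans(session, {"PatientID"})
    assert not result.has_passed
    assert result.data == [{"PatientID": ["ALFA00001", "ALFA00002"]}]


# -- id_matches_pattern -----------------------------------------------------

@pytest.mark.parametrize("subject_id,expected", [
    ("ALFA12345", True),
    ("", False),
    ("ALFA 1234", False),      # interior whitespace
    ("alfa12345", False),
    ("ALFA1234", False),       # too few digits
])
def test_subject_id_pattern(subject_id, expected):
    session = _pet_session(PatientID=subject_id)
    session.subject_id = subject_id
    result = acq.id_matches_pattern(session, DEFAULT_CONFIG.subject_id_pattern)
    assert result.has_passed is expected


def test_invalid_pattern_is_a_configuration_error():
    with pytest.raises(ValueError, match="pattern"):
        acq.id_matches_pattern(_pet_session(), "([unclosed")


# -- has_usable_t1 / quantification_runnable --------------------------------

def _project_with_t1(flag="usable", series="T1 MPRAGE"):
    t1 = Scan("001", {"SeriesDescription": series, "PatientID": "ALFA00001"},
              quality_flag=flag)
    mr = Session("S_MR", "ALFA00001", "MR", scans=[t1])
    pet = _pet_session()
    pet.scans[0].files = ["image.nii.gz"]
    project = Project(root=None, sessions=[mr, pet])
    return project, pet


def test_usable_t1_found():
    project, pet = _project_with_t1()
    result = acq.has_usable_t1(pet, project, DEFAULT_CONFIG)
    assert result.has_passed
    assert result.data == [{"session": "S_MR", "scan": "001"}]


@pytest.mark.parametrize("flag,series,expected", [
    ("unusable", "T1 MPRAGE", False),   # flag semantics
    ("usable", "T2 FLAIR", False),      # not a T1
    ("usable", "t1 mprage", True),      # designation is case-insensitive
])
def test_usable_t1_flag_and_designation(flag, series, expected):
    project, pet = _project_with_t1(flag=flag, series=series)
    assert acq.has_usable_t1(pet, project, DEFAULT_CONFIG).has_passed is expected


def test_no_mr_session_means_no_t1():
    pet = _pet_session()
    project = Project(root=None, sessions=[pet])
    assert not acq.has_usable_t1(pet, project, DEFAULT_CONFIG).has_passed


def test_runnability_precondition_conjunction():
    project, pet = _project_with_t1()
    assert acq.quantification_runnable(pet, project, "fdg",
                                       DEFAULT_CONFIG).has_passed
    # drop the T1: fdg quantification no longer runnable
    project.sessions[0].scans[0].quality_flag = "unusable"
    result = acq.quantification_runnable(pet, project, "fdg", DEFAULT_CONFIG)
    assert not result.has_passed
    assert any("T1" in str(item) for item in result.data)


def test_tracer_mismatch_is_pass_with_note():
    project, pet = _project_with_t1()
    result = acq.quantification_runnable(pet, project, "centiloid",
                                         DEFAULT_CONFIG)
    assert result.has_passed
    assert any("not applicable" in str(item) for item in result.data)


def test_missing_pet_nifti_blocks_quantification():
    project, pet = _project_with_t1()
    pet.scans[0].files = []
    result = acq.quantification_runnable(pet, project, "fdg", DEFAULT_CONFIG)
    assert not result.has_passed


# -- scan_has_nifti ---------------------------------------------------------

def test_scan_nifti_readable(tmp_path):
    from neuroqc.fixtures import make_phantom

    make_phantom(seed=1).to_filename(str(tmp_path / "image.nii.gz"))
    scan = Scan("001", {}, files=["image.nii.gz"], path=tmp_path)
    assert acq.scan_has_nifti(scan).has_passed


def test_scan_without_nifti_fails(tmp_path):
    scan = Scan("001", {}, files=["image.json"], path=tmp_path)
    assert not acq.scan_has_nifti(scan).has_passed


def test_truncated_nifti_fails_with_read_error(tmp_path):
    from neuroqc.fixtures import make_phantom

    path = tmp_path / "image.nii.gz"
    make_phantom(seed=1).to_filename(str(path))
    path.write_bytes(path.read_bytes()[:40])
    scan = Scan("001", {}, files=["image.nii.gz"], path=tmp_path)
    result = acq.scan_has_nifti(scan)
    assert not result.has_passed
    assert any("unreadable" in str(item) for item in result.data)
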