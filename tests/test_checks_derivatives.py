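"""Derivative checks: manifests, provenance, label volumes, aseg parsing."""

import numpy as np
import pytest

from neuroqc.checks import derivatives as der
from neuroqc.config import IntervalSpec
from neuroqc.fixtures import make_labelmap
from neuroqc.model import Resource


def _resource(tmp_path, files=(), provenance=None):
    for rel in files:
        path = tmp_path / rel
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text("x")
    return Resource("R", path=tmp_path,
                    files=[(f, 1) for f in files], provenance=provenance)


# -- has_correct_items ------------------------------------------------------

@pytest.mark.parametrize("expected,present,ok,missing", [
    (["a", "b"], ["a", "b"], True, []),
    (["a", "b"], ["a"], False, ["b"]),
    (["stats/aseg.stats"], ["stats/aseg.stats"], True, []),
    (["*seg*.nii.gz"], ["left_seg_corr.nii.gz"], True, []),
])
def test_manifest_matching(tmp_path, expected, present, ok, missing):
    result = der.has_correct_items(_resource(tmp_path, present), expected)
    assert result.has_passed is ok
    if missing:
        assert result.data[0]["missing"] == missing


def test_unexpected_files_warn_but_do_not_fail(tmp_path):
    result = der.has_correct_items(_resource(tmp_path, ["a", "stray.log"]),
                                   ["a"])
    assert result.has_passed
    assert "stray.log" in str(result.data)


def test_absent_resource_fails_manifest():
    assert not der.has_correct_items(None, ["a"]).has_passed


# -- has_correct_version ----------------------------------------------------

@pytest.mark.parametrize("actual,expected,ok", [
    ("ASHS 1.0.0", "ASHS 1.0.0", True),
    ("ASHS 0.9", "ASHS 1.0.0", False),
    (None, "ASHS 1.0.0", False),
])
def test_version_check(tmp_path, actual, expected, ok):
    prov = {"software_version": actual} if actual else None
    result = der.has_correct_version(_resource(tmp_path, provenance=prov),
                                     expected)
    assert result.has_passed is ok


# -- execution_time_within --------------------------------------------------

@pytest.mark.parametrize("elapsed,max_s,ok", [(600, 3600, True),
                                              (7200, 3600, False),
                                              (3600, 3600, True)])
def test_execution_time(tmp_path, elapsed, max_s, ok):
    prov = {"software_version": "x", "started": "2024-01-02T08:00:00",
            "finished": f"2024-01-02T{8 + elapsed // 3600:02d}:"
                        f"{(elapsed % 3600) // 60:02d}:00"}
    result = der.execution_time_within(_resource(tmp_path, provenance=prov),
                                       max_s)
    assert result.has_passed is ok
    assert result.data[0]["elapsed_seconds"] == elapsed


def test_missing_timestamps_fail_with_note(tmp_path):
    resource = _resource(tmp_path, provenance={"software_version": "x"})
    result = der.execution_time_within(resource, 10)
    assert not result.has_passed
    assert "absent" in str(result.data)


# -- compute_label_volumes --------------------------------------------------

def _brute_force_volumes(data, zooms):
    # independent triple-loop voxel counter
    counts = {}
    for i in range(data.shape[0]):
        for j in range(data.shape[1]):
            for k in range(data.shape[2]):
                label = int(data[i, j, k])
                if label != 0:
                    counts[label] = counts.get(label, 0) + 1
    voxel = zooms[0] * zooms[1] * zooms[2]
    return {l: c * voxel for l, c in counts.items()}


def test_unit_voxel_volumes():
    img = make_labelmap((8, 8, 8), {1: 10}, seed=1)
    assert der.compute_label_volumes(img) == {1: 10.0}


def test_anisotropic_voxel_volumes():
    img = make_labelmap((8, 8, 8), {1: 10}, seed=1, zooms=(2.0, 2.0, 2.0))
    assert der.compute_label_volumes(img) == {1: 80.0}


def test_empty_labelmap_gives_empty_table():
    img = make_labelmap((8, 8, 8), {}, seed=1)
    assert der.compute_label_volumes(img) == {}


def test_non_integer_labelmap_is_an_error(tmp_path):
    import nibabel as nib

    img = nib.Nifti1Image(np.full((4, 4, 4), 0.5, dtype=np.float32), np.eye(4))
    path = tmp_path / "bad.nii.gz"
    img.to_filename(str(path))
    with pytest.raises(ValueError, match="non-integer"):
        der.compute_label_volumes(path)


def test_volumes_match_brute_force_counter_on_random_maps():
    rng = np.random.default_rng(42)
    import nibabel as nib

    for trial in range(20):
        data = rng.integers(0, 5, size=(16, 16, 16)).astype(np.int16)
        zooms = tuple(float(z) for z in rng.choice([0.5, 1.0, 2.0], size=3))
        img = nib.Nifti1Image(data, np.diag(list(zooms) + [1.0]))
        img.header.set_zooms(zooms)
        assert der.compute_label_volumes(img) == _brute_force_volumes(data, zooms)


def test_volume_conservation():
    # labels + background account exactly for the image volume
    img = make_labelmap((16, 16, 16), {1: 101, 2: 57, 3: 13}, seed=3)
    volumes = der.compute_label_volumes(img)
    data = np.asanyarray(img.dataobj)
    background = float((data == 0).sum())
    assert sum(volumes.values()) + background == 16 ** 3


# -- has_all_subfields / volumes_within_intervals ---------------------------

def test_all_subfields_present():
    img = make_labelmap((16, 16, 16), {l: 10 for l in range(1, 6)}, seed=4)
    assert der.has_all_subfields(img, {1, 2, 3, 4, 5}).has_passed


def test_missing_subfield_reported():
    img = make_labelmap((16, 16, 16), {1: 10, 2: 10, 4: 10, 5: 10}, seed=4)
    result = der.has_all_subfields(img, {1, 2, 3, 4, 5})
    assert not result.has_passed
    assert result.data == [{"absent_labels": [3]}]


def test_empty_expectation_is_vacuous():
    img = make_labelmap((8, 8, 8), {}, seed=1)
    assert der.has_all_subfields(img, set()).has_passed


@pytest.mark.parametrize("volumes,intervals,ok", [
    ({1: 100.0}, {1: (50, 500)}, True),
    ({1: 10.0}, {1: (50, 500)}, False),            # below lower bound
    ({1: 100.0, 9: 1.0}, {1: (50, 500)}, True),    # un-keyed region ignored
    ({1: 100.0}, {}, True),                        # vacuous
    ({}, {1: (50, 500)}, False),                   # keyed region unmeasured
    ({1: 50.0}, {1: (50, 500)}, True),             # inclusive bound
])
def test_volume_safety_intervals(volumes, intervals, ok):
    assert der.volumes_within_intervals(volumes, intervals).has_passed is ok


def test_interval_spec_values_accepted():
    intervals = {1: IntervalSpec("1", 50, 500)}
    assert der.volumes_within_intervals({1: 100.0}, intervals).has_passed


# -- parse_aseg_stats -------------------------------------------------------

ASEG_FIXTURE = """\
# Title Segmentation Statistics
# ColHeaders  Index SegId NVoxels Volume_mm3 StructName normMean normStdDev normMin normMax normRange
  1   4      7500     7512.3  Left-Lateral-Ventricle    25.0 10.0 0.0 90.0 90.0
  2  17      4250     4249.8  Left-Hippocampus          80.0  7.0 40.0 110.0 70.0
  3  53      4380     4381.1  Right-Hippocampus         81.0  7.1 41.0 111.0 70.0
"""


def test_parse_aseg_fixture(tmp_path):
    path = tmp_path / "aseg.stats"
    path.write_text(ASEG_FIXTURE)
    table = der.parse_aseg_stats(path)
    # hand-parsed expectations
    assert table == {"Left-Lateral-Ventricle": 7512.3,
                     "Left-Hippocampus": 4249.8,
                     "Right-Hippocampus": 4381.1}
    # row count preserved exactly (line-count oracle)
    n_rows = sum(1 for line in ASEG_FIXTURE.splitlines()
                 if line.strip() and not line.startswith("#"))
    assert len(table) == n_rows


def test_header_only_file_gives_empty_table(tmp_path):
    path = tmp_path / "aseg.stats"
    path.write_text("# Title Segmentation Statistics\n# ColHeaders Index "
                    "SegId NVoxels Volume_mm3 StructName\n")
    assert der.parse_aseg_stats(path) == {}


def test_missing_volume_column_is_an_error(tmp_path):
    path = tmp_path / "aseg.stats"
    path.write_text("# ColHeaders Index SegId NVoxels StructName\n"
                    "1 4 7500 Left-Lateral-Ventricle\n")
    with pytest.raises(ValueError, match="Volume_mm3"):
        der.parse_aseg_stats(path)


def test_generated_aseg_fixture_parses_in_real_dialect(tmp_path):
    # the shipped generator writes the genuine aseg.stats dialect
    from neuroqc.fixtures import _aseg_stats_text, synthesize_aseg_volumes

    rows = synthesize_aseg_volumes(seed=11)
    path = tmp_path / "aseg.stats"
    path.write_text(_aseg_stats_text(rows))
    table = der.parse_aseg_stats(path)
    assert table == {name: vol for _, name, vol in rows}
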