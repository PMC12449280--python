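import json

import numpy as np
import pytest

from invertseg.backends import (BackendError, ClassWindow, default_windows,
                                external_segment, load_windows, window_segment)
from invertseg.evaluation import ClassMapping, evaluate_case
from invertseg.volume_io import write_volume

SOFT_TISSUE = [ClassWindow(class_name="soft", lo=20, hi=60)]


def test_air_volume_yields_empty_labelmap(volume_factory):
    v = volume_factory(np.full((10, 10, 10), -1000.0))
    out = window_segment(v, SOFT_TISSUE)
    assert not out.data.any()


def test_cube_in_air_labeled_exactly(volume_factory):
    data = np.full((20, 20, 20), -1000.0)
    data[5:15, 5:15, 5:15] = 40.0
    v = volume_factory(data)
    out = window_segment(v, SOFT_TISSUE)
    np.testing.assert_array_equal(out.data == 1, data == 40.0)
    assert out.vocabulary == {1: "soft"}


def test_deterministic(volume_factory, rng):
    v = volume_factory(rng.uniform(-1000, 1000, (16, 16, 16)))
    a = window_segment(v, default_windows())
    b = window_segment(v, default_windows())
    np.testing.assert_array_equal(a.data, b.data)


def test_component_filter_monotone(volume_factory, rng):
    """Lowering min_component_mm3 never removes labeled voxels."""
    v = volume_factory((rng.random((24, 24, 24)) < 0.08) * 40.0 - (1 - 0) * 0.0)
    big = window_segment(v, [ClassWindow(class_name="soft", lo=20, hi=60,
                                         min_component_mm3=20)])
    small = window_segment(v, [ClassWindow(class_name="soft", lo=20, hi=60,
                                           min_component_mm3=2)])
    assert np.all(small.data[big.data == 1] == 1)
    assert (small.data == 1).sum() >= (big.data == 1).sum()


def test_component_filter_drops_small_components(volume_factory):
    data = np.zeros((20, 20, 20))
    data[2:8, 2:8, 2:8] = 40.0       # 216 voxels
    data[15, 15, 15] = 40.0          # isolated voxel
    v = volume_factory(data)  # 1 mm voxels
    out = window_segment(v, [ClassWindow(class_name="soft", lo=20, hi=60,
                                         min_component_mm3=10.0)])
    assert out.data[4, 4, 4] == 1
    assert out.data[15, 15, 15] == 0


def test_side_constraints_respected(volume_factory, rng):
    v = volume_factory(rng.uniform(30, 50, (16, 16, 16)))
    left = window_segment(v, [ClassWindow(class_name="l", lo=20, hi=60,
                                          side_constraint="left_of_midline")])
    right = window_segment(v, [ClassWindow(class_name="r", lo=20, hi=60,
                                           side_constraint="right_of_midline")])
    assert not left.data[8:].any() and left.data[:8].all()
    assert not right.data[:8].any() and right.data[8:].all()


def test_priority_resolves_overlaps(volume_factory):
    v = volume_factory(np.full((6, 6, 6), 40.0))
    wins = [ClassWindow(class_name="lo_pri", lo=0, hi=100, priority=1),
            ClassWindow(class_name="hi_pri", lo=20, hi=60, priority=5)]
    out = window_segment(v, wins)
    assert np.all(out.data == 2)  # ids follow table order; hi_pri claims first
    assert out.vocabulary[2] == "hi_pri"


def test_empty_window_table_rejected(volume_factory):
    v = volume_factory(np.zeros((4, 4, 4)))
    with pytest.raises(ValueError):
        window_segment(v, [])


def test_window_validation():
    with pytest.raises(ValueError):
        ClassWindow(class_name="bad", lo=10, hi=10)
    with pytest.raises(ValueError):
        ClassWindow(class_name="bad", lo=0, hi=1, min_component_mm3=-1)
    with pytest.raises(ValueError):
        ClassWindow(class_name="bad", lo=0, hi=1, side_constraint="above")


def test_load_windows_roundtrip(tmp_path):
    path = tmp_path / "w.json"
    path.write_text(json.dumps([{"class_name": "soft", "lo": 20, "hi": 60,
                                 "priority": 2}]))
    wins = load_windows(path)
    assert wins == [ClassWindow(class_name="soft", lo=20, hi=60, priority=2)]


def test_default_windows_on_ct_phantom(default_case):
    """CT intensity priors recover every organ >= 10 cm3 with DSC >= 0.8."""
    pred = window_segment(default_case.ct, default_windows())
    mapping = ClassMapping.identity(default_case.truth.vocabulary.values())
    records = evaluate_case(pred, default_case.truth, mapping)
    for r in records:
        if r.ref_volume_cm3 >= 10.0:
            assert r.dsc >= 0.8, f"{r.class_name}: {r.dsc:.3f}"


class TestExternalAdapter:
    def _small_labelmap_file(self, tmp_path, volume_factory):
        data = np.zeros((6, 6, 6), dtype=np.int16)
        data[2:4, 2:4, 2:4] = 1
        from invertseg.volume_io import LabelMap
        lm = LabelMap(data=data, spacing=np.ones(3), affine=np.eye(4),
                      vocabulary={1: "organ"})
        ref = tmp_path / "fixed_labels.nii.gz"
        write_volume(lm, ref)
        return lm, ref

    def test_stub_command_roundtrip(self, tmp_path, volume_factory):
        lm, ref = self._small_labelmap_file(tmp_path, volume_factory)
        v = volume_factory(np.zeros((6, 6, 6), dtype=np.float32))
        out = external_segment(f"cp {ref} {{output}} && test -f {{input}}",
                               v, tmp_path / "work")
        np.testing.assert_array_equal(out.data, lm.data)

    def test_nonzero_exit_raises_backend_error(self, tmp_path, volume_factory):
        v = volume_factory(np.zeros((4, 4, 4), dtype=np.float32))
        with pytest.raises(BackendError, match="status 1"):
            external_segment("test -f {input} && cp {input} {output} && false",
                             v, tmp_path / "work")
        assert not (tmp_path / "work" / "output.nii.gz").exists()

    def test_missing_placeholder_rejected(self, tmp_path, volume_factory):
        v = volume_factory(np.zeros((4, 4, 4), dtype=np.float32))
        with pytest.raises(ValueError, match="placeholder"):
            external_segment("echo {input}", v, tmp_path / "work")

    def test_missing_output_raises(self, tmp_path, volume_factory):
        v = volume_factory(np.zeros((4, 4, 4), dtype=np.float32))
        with pytest.raises(BackendError, match="no output"):
            external_segment("echo {input} {output}", v, tmp_path / "work")

    def test_multifile_merge_by_class_map(self, tmp_path, volume_factory):
        from invertseg.volume_io import LabelMap
        work = tmp_path / "work"
        outdir = tmp_path / "parts"
        outdir.mkdir()
        for name, corner in (("kidney", 0), ("tumor", 3)):
            data = np.zeros((6, 6, 6), dtype=np.int16)
            data[corner:corner + 2, :2, :2] = 1
            write_volume(LabelMap(data=data, spacing=np.ones(3), affine=np.eye(4),
                                  vocabulary={1: name}), outdir / f"{name}.nii.gz")
        v = volume_factory(np.zeros((6, 6, 6), dtype=np.float32))
        out = external_segment(
            f"test -f {{input}} && cp -r {outdir} {{output}}", v, work,
            class_map={"kidney": 4, "tumor": 9})
        assert out.vocabulary == {4: "kidney", 9: "tumor"}
        assert (out.data == 4).sum() == 8 and (out.data == 9).sum() == 8
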