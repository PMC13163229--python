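"""Series filtering, slice loading, preprocessing, augmentation, splitting."""

import numpy as np
import pytest

from dsanet.data_io import (
    IMAGENET_MEANS,
    SliceRecord,
    SplitSpec,
    apply_augment,
    augment,
    filter_t2_series,
    load_slice,
    preprocess,
    read_manifest,
    split_dataset,
)
from dsanet.synthetic import generate_phantom, write_dicom_fixture


def _records(n, labels, patients):
    return [
        SliceRecord(patient_id=patients[i], pixels=np.zeros((2, 2)), label=labels[i], metadata={"idx": i})
        for i in range(n)
    ]


# -- series filtering ------------------------------------------------------


def test_filter_keeps_only_t2_transverse_protocols():
    sel = filter_t2_series(["t2_FS-TRA", "dwi_tra", "t1_tse_sag"])
    assert len(sel.kept) == 1 and len(sel.rejected) == 2
    assert sel.tallies["t2_FS-TRA"] == 1


def test_filter_is_case_insensitive():
    sel = filter_t2_series(["T2_TSE_TRA"])
    assert sel.kept == ["T2_TSE_TRA"]
    assert sel.tallies["t2_tse_TRA"] == 1


def test_filter_empty_input():
    sel = filter_t2_series([])
    assert sel.kept == [] and sel.rejected == []
    assert sum(sel.tallies.values()) == 0


def test_filter_orientation_gate_and_tally_sum():
    series = [("t2_TRA", "transverse"), ("t2_TRA", "sagittal"), ("t2_haste_TRA", "AX"), ("foo", "axial")]
    sel = filter_t2_series(series)
    assert len(sel.kept) == 2
    assert sum(sel.tallies.values()) == len(sel.kept)


# -- loading ---------------------------------------------------------------


def test_dicom_roundtrip(tmp_path):
    rec = generate_phantom(1, seed=3)
    path = tmp_path / "slice.dcm"
    write_dicom_fixture(rec, path)
    loaded = load_slice(path, label=1)
    assert loaded.pixels.shape == rec.pixels.shape
    assert np.allclose(loaded.pixels, np.clip(rec.pixels, 0, 65535).astype(np.uint16))
    assert loaded.series_description == rec.series_description


def test_png_roundtrip(tmp_path):
    from PIL import Image

    arr = (np.arange(224 * 224).reshape(224, 224) % 251).astype(np.uint8)
    path = tmp_path / "img.png"
    Image.fromarray(arr).save(path)
    rec = load_slice(path, label=0, patient_id="PAT_0001")
    assert rec.pixels.shape == (224, 224)
    assert np.allclose(rec.pixels, arr)


def test_nifti_middle_slice(tmp_path):
    import nibabel as nib

    vol = np.arange(4 * 5 * 3, dtype=np.float32).reshape(4, 5, 3)
    path = tmp_path / "vol.nii.gz"
    nib.save(nib.Nifti1Image(vol, np.eye(4)), str(path))
    rec = load_slice(path)
    assert np.allclose(rec.pixels, vol[:, :, 1])
    assert np.allclose(load_slice(path, slice_index=2).pixels, vol[:, :, 2])


def test_truncated_file_errors_with_path(tmp_path):
    path = tmp_path / "broken.dcm"
    path.write_bytes(b"\x00" * 40)
    with pytest.raises(IOError, match="broken.dcm"):
        load_slice(path)
    with pytest.raises(IOError, match="does not exist"):
        load_slice(tmp_path / "missing.png")


def test_manifest_roundtrip(tmp_path):
    from dsanet.synthetic import generate_cohort, write_cohort

    records = generate_cohort(3, 2, 0.5, seed=1)
    write_cohort(records, tmp_path / "cohort")
    loaded = read_manifest(tmp_path / "cohort" / "manifest.csv")
    assert len(loaded) == 6
    assert [r.patient_id for r in loaded] == [r.patient_id for r in records]
    assert [r.label for r in loaded] == [r.label for r in records]


# -- preprocessing ---------------------------------------------------------


def test_preprocess_constant_slice_maps_to_negative_means():
    out = preprocess(np.full((50, 60), 7.0), size=32)
    assert out.shape == (32, 32, 3)
    assert np.allclose(out, -np.asarray(IMAGENET_MEANS))


def test_preprocess_identity_when_already_sized_and_scaled():
    rng = np.random.default_rng(0)
    img = rng.uniform(0, 255, size=(64, 64))
    img.flat[0], img.flat[1] = 0.0, 255.0
    out = preprocess(img, size=64)
    assert np.allclose(out, np.repeat(img[:, :, None], 3, axis=2) - np.asarray(IMAGENET_MEANS))


def test_preprocess_keeps_disc_centered_after_downsampling():
    yy, xx = np.mgrid[0:128, 0:128]
    disc = (((yy - 63.5) ** 2 + (xx - 63.5) ** 2) <= 30**2).astype(float) * 255.0
    out = preprocess(disc, size=64)
    gray = out[:, :, 0] + np.asarray(IMAGENET_MEANS)[0]
    mass = gray > 127
    cy, cx = np.argwhere(mass).mean(axis=0)
    assert abs(cy - 31.5) < 1.0 and abs(cx - 31.5) < 1.0


def test_preprocess_rejects_bad_input():
    with pytest.raises(ValueError, match="2-D"):
        preprocess(np.zeros((4, 4, 2)))


@pytest.mark.parametrize("shape", [(10, 10), (100, 37), (224, 224)])
def test_preprocess_output_shape_is_invariant(shape):
    assert preprocess(np.random.default_rng(0).normal(size=shape), size=48).shape == (48, 48, 3)


# -- augmentation ----------------------------------------------------------


def test_augment_deterministic_for_fixed_seed():
    img = np.random.default_rng(0).uniform(size=(32, 32))
    a = augment(img, seed=5)
    b = augment(img, seed=5)
    assert np.array_equal(a, b)
    assert a.shape == img.shape


def test_augment_identity_draw():
    img = np.random.default_rng(1).uniform(size=(16, 16))
    assert np.array_equal(apply_augment(img, flip=False, angle=0.0, zoom=1.0), img)


def test_augment_forced_flip_mirrors():
    img = np.zeros((8, 8))
    img[:, :4] = 1.0  # left-right asymmetric
    flipped = apply_augment(img, flip=True, angle=0.0, zoom=1.0)
    assert np.array_equal(flipped, img[:, ::-1])


# -- splitting -------------------------------------------------------------


def test_slice_level_split_reproduces_reported_sizes():
    n = 3850
    labels = [1 if i < 2002 else 0 for i in range(n)]  # ~52% high risk
    patients = [f"PAT_{i % 75:04d}" for i in range(n)]
    records = _records(n, labels, patients)
    spec = SplitSpec(fractions=(0.6982, 0.1496, 0.1522), group_by_patient=False, seed=0)
    train, val, test = split_dataset(records, spec)
    assert (len(train), len(val), len(test)) == (2688, 576, 586)
    # exhaustive, disjoint partition
    ids = sorted(r.metadata["idx"] for part in (train, val, test) for r in part)
    assert ids == list(range(n))
    # per-label counts within one sample of the stratified target
    for part, frac in zip((train, val, test), spec.fractions):
        for lab, lab_total in ((1, 2002), (0, 1848)):
            got = sum(1 for r in part if r.label == lab)
            assert abs(got - frac * lab_total) <= 1.0


def test_split_seed_contract():
    records = _records(40, [i % 2 for i in range(40)], [f"P{i}" for i in range(40)])
    spec_a = SplitSpec(group_by_patient=False, seed=1)
    spec_b = SplitSpec(group_by_patient=False, seed=2)
    ids = lambda parts: [[r.metadata["idx"] for r in p] for p in parts]
    assert ids(split_dataset(records, spec_a)) == ids(split_dataset(records, spec_a))
    assert ids(split_dataset(records, spec_a)) != ids(split_dataset(records, spec_b))


def test_patient_grouping_prevents_leakage():
    labels = [i % 2 for i in range(60)]
    patients = [f"PAT_{i // 5:04d}" for i in range(60)]  # 12 patients x 5 slices
    # one label per patient, as in a real cohort
    labels = [(i // 5) % 2 for i in range(60)]
    records = _records(60, labels, patients)
    train, val, test = split_dataset(records, SplitSpec(seed=3))
    seen = {}
    for name, part in (("train", train), ("val", val), ("test", test)):
        for r in part:
            assert seen.setdefault(r.patient_id, name) == name
    assert len(train) + len(val) + len(test) == 60
    assert min(len(train), len(val), len(test)) > 0


def test_single_patient_grouping_is_an_error():
    records = _records(10, [i % 2 for i in range(10)], ["PAT_0000"] * 10)
    with pytest.raises(ValueError, match="patient"):
        split_dataset(records, SplitSpec(seed=0))


def test_split_spec_validation():
    with pytest.raises(ValueError, match="sum to 1"):
        SplitSpec(fractions=(0.5, 0.3, 0.3))
    with pytest.raises(ValueError, match="in \\(0,1\\)"):
        SplitSpec(fractions=(1.0, 0.0, 0.0))
    with pytest.raises(ValueError, match="at least 3"):
        split_dataset(_records(2, [0, 1], ["A", "B"]), SplitSpec())
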