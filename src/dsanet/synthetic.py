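"""Synthetic T2-like phantom slices with patient grouping.

The generator emulates the structure of a transverse prostate T2 slice at
the level a slice classifier sees: a smooth elliptical "gland" on a dark
background, a long-wavelength intensity texture (standing in for coil
inhomogeneity), per-pixel Gaussian noise, and — for the high-suspicion
class — a focal hypointense blob placed inside the gland whose intensity
offset is ``lesion_contrast`` and whose interior carries its own
fine-grained texture. All randomness derives from (spec, seed), so every
phantom is reproducible; the lesion mask is kept in the record metadata as
ground truth for localization checks.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .data_io import SliceRecord, T2_PROTOCOLS, records_to_manifest

__all__ = ["PhantomSpec", "generate_phantom", "generate_cohort", "write_cohort", "write_dicom_fixture"]


@dataclass
class PhantomSpec:
    image_size: int = 224
    gland_radius_range: tuple[float, float] = (0.22, 0.32)
    lesion_radius_range: tuple[float, float] = (0.05, 0.10)
    lesion_contrast: float = -60.0
    texture_scale: float = 0.15
    noise_sd: float = 8.0
    background_level: float = 40.0
    gland_level: float = 150.0
    texture_sd: float = 12.0

    def __post_init__(self):
        for lo, hi in (self.gland_radius_range, self.lesion_radius_range):
            if not (0.0 < lo <= hi < 0.5):
                raise ValueError("radius ranges must satisfy 0 < lo <= hi < 0.5")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.image_size < 8:
            raise ValueError("image_size must be at least 8")


def _ellipse_mask(size, cy, cx, ry, rx, theta):
    yy, xx = np.mgrid[0:size, 0:size]
    y, x = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (x * ct + y * st) / rx
    v = (-x * st + y * ct) / ry
    return u * u + v * v <= 1.0


def generate_phantom(label: int, spec: PhantomSpec = None, seed: int = 0) -> SliceRecord:
    """One phantom slice; class 1 adds a focal blob inside the gland.

    The record's metadata carries ``gland_mask`` and ``lesion_mask`` (class 0
    gets an all-false lesion mask). With ``lesion_contrast=0`` and
    ``noise_sd=0`` a class-1 image is pixelwise identical to the class-0
    image of the same seed, because lesion geometry draws come from a
    dedicated random stream.
    """
    if label not in (0, 1):
        raise ValueError(f"label must be 0 or 1, got {label}")
    spec = spec or PhantomSpec()
    n = spec.image_size
    ss = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0x9E37])
    rng_gland, rng_texture, rng_lesion, rng_noise = (np.random.default_rng(s) for s in ss.spawn(4))

    ry = n * rng_gland.uniform(*spec.gland_radius_range)
    rx = n * rng_gland.uniform(*spec.gland_radius_range)
    cy = n / 2 + rng_gland.uniform(-0.05, 0.05) * n
    cx = n / 2 + rng_gland.uniform(-0.05, 0.05) * n
    theta = rng_gland.uniform(0, np.pi)
    gland = _ellipse_mask(n, cy, cx, ry, rx, theta)

    image = np.full((n, n), spec.background_level)
    image[gland] = spec.gland_level
    image = gaussian_filter(image, sigma=2.0)  # soft gland boundary

    texture = gaussian_filter(rng_texture.normal(size=(n, n)), sigma=spec.texture_scale * n)
    sd = texture.std()
    if sd > 0:
        image += texture * (spec.texture_sd / sd)

    lesion_mask = np.zeros((n, n), dtype=bool)
    if label == 1:
        r_lesion = n * rng_lesion.uniform(*spec.lesion_radius_range)
        if r_lesion >= min(ry, rx):
            raise ValueError(f"lesion radius {r_lesion:.1f}px does not fit inside the gland (radii {ry:.1f}, {rx:.1f})")
        margin = r_lesion + 6.0  # keep the lesion clear of the smoothed gland boundary
        for _ in range(200):
            ly = cy + rng_lesion.uniform(-1, 1) * ry
            lx = cx + rng_lesion.uniform(-1, 1) * rx
            if _ellipse_mask(n, cy, cx, max(ry - margin, 1), max(rx - margin, 1), theta)[
                int(np.clip(ly, 0, n - 1)), int(np.clip(lx, 0, n - 1))
            ]:
                break
        lesion_mask = _ellipse_mask(n, ly, lx, r_lesion, r_lesion, 0.0)
        if spec.lesion_contrast != 0.0:
            image[lesion_mask] += spec.lesion_contrast
            fine = gaussian_filter(rng_lesion.normal(size=(n, n)), sigma=1.0)
            fsd = fine.std()
            if fsd > 0:
                image[lesion_mask] += fine[lesion_mask] * (0.05 * abs(spec.lesion_contrast) / fsd)

    if spec.noise_sd > 0:
        image += rng_noise.normal(0.0, spec.noise_sd, size=(n, n))
    image = np.clip(image, 0.0, 255.0)

    from scipy.ndimage import binary_erosion

    # interior of the gland untouched by the boundary smoothing, for oracle use
    gland_core = binary_erosion(gland, iterations=6)
    return SliceRecord(
        patient_id="PAT_SYNTH",
        pixels=image,
        label=label,
        series_description="t2_tse_TRA",
        metadata={"gland_mask": gland, "gland_core_mask": gland_core, "lesion_mask": lesion_mask, "seed": int(seed)},
    )


def generate_cohort(
    n_patients: int,
    slices_per_patient: int,
    class_balance: float = 0.52,
    spec: PhantomSpec = None,
    seed: int = 0,
) -> list[SliceRecord]:
    """Patient-grouped phantom cohort; one label per synthetic patient.

    ``class_balance`` is the fraction of high-suspicion patients (rounded to
    the nearest count). Patient ids follow the PAT_NNNN pattern and every
    slice of a patient shares the patient's label.
    """
    if n_patients < 2:
        raise ValueError("need at least 2 patients")
    if slices_per_patient < 1:
        raise ValueError("need at least 1 slice per patient")
    if not 0.0 < class_balance < 1.0:
        raise ValueError(f"class_balance must be in (0,1), got {class_balance}")
    spec = spec or PhantomSpec()
    n_pos = int(round(class_balance * n_patients))
    n_pos = min(max(n_pos, 1), n_patients - 1)
    rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 0xC0]))
    labels = rng.permutation(np.array([1] * n_pos + [0] * (n_patients - n_pos)))
    protocols = rng.choice(len(T2_PROTOCOLS), size=n_patients)
    records = []
    for p in range(n_patients):
        pid = f"PAT_{p:04d}"
        for s in range(slices_per_patient):
            slice_seed = (int(seed) * 1_000_003 + p * 1009 + s) & 0x7FFFFFFF
            rec = generate_phantom(int(labels[p]), spec, seed=slice_seed)
            rec.patient_id = pid
            rec.series_description = T2_PROTOCOLS[protocols[p]]
            records.append(rec)
    return records


def write_cohort(records, directory) -> "pd.DataFrame":  # noqa: F821
    """Write slices as 8-bit PNGs plus a CSV manifest usable by data_io."""
    from PIL import Image

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, rec in enumerate(records):
        path = directory / f"{rec.patient_id}_slice{i:04d}.png"
        Image.fromarray(np.clip(rec.pixels, 0, 255).astype(np.uint8)).save(path)
        rec.path = str(path)
    return records_to_manifest(records, directory / "manifest.csv")


def write_dicom_fixture(record: SliceRecord, path) -> None:
    """Write a minimal 16-bit Part-10 DICOM file for I/O round-trip tests."""
    import pydicom
    from pydicom.dataset import FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, SecondaryCaptureImageStorage, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = SecondaryCaptureImageStorage
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientID = record.patient_id
    ds.SeriesDescription = record.series_description
    ds.Modality = "MR"
    pixels = np.clip(record.pixels, 0, 65535).astype(np.uint16)
    ds.Rows, ds.Columns = pixels.shape
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.RescaleSlope = 1.0
    ds.RescaleIntercept = 0.0
    ds.PixelData = pixels.tobytes()
    ds.save_as(str(path), enforce_file_format=True)
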