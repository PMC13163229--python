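"""Slice loading, T2 series filtering, preprocessing, augmentation, splits.

Series selection follows the clinical acquisition-protocol allowlist of
transverse T2-weighted sequences (fat-suppressed, turbo spin echo and HASTE
variants); matching is case-insensitive and exact against the protocol name.
Preprocessing rescales each slice to [0, 255], resizes bilinearly to the
network input size, replicates grayscale to three channels and subtracts the
ImageNet channel means (additive-offset semantics).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.transform import AffineTransform, resize, rotate, warp

__all__ = [
    "SliceRecord",
    "SplitSpec",
    "SeriesSelection",
    "T2_PROTOCOLS",
    "IMAGENET_MEANS",
    "filter_t2_series",
    "load_slice",
    "preprocess",
    "augment",
    "split_dataset",
    "records_to_manifest",
    "read_manifest",
]

#: Accepted transverse T2-weighted acquisition protocol names.
T2_PROTOCOLS = (
    "t2_FS-TRA",
    "t2_tse_TRA",
    "t2_TRA",
    "t2_haste_tra_",
    "t2_tse_TRA-rectum",
    "t2_haste_TRA",
    "t2_FS_TRA",
)

#: RGB channel means subtracted after grayscale replication.
IMAGENET_MEANS = (123.68, 116.779, 103.939)

_TRANSVERSE = {"transverse", "axial", "tra", "ax", "axl"}


@dataclass
class SliceRecord:
    """One image slice with its patient id, series metadata and binary label
    (0 = PI-RADS 2-3 low suspicion, 1 = PI-RADS 4-5 high suspicion)."""

    patient_id: str
    pixels: np.ndarray
    label: int | None = None
    series_description: str = ""
    path: str | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2-D, got shape {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain non-finite values")
        if self.label is not None and self.label not in (0, 1):
            raise ValueError(f"label must be 0 or 1, got {self.label}")


@dataclass
class SplitSpec:
    fractions: tuple[float, float, float] = (0.6982, 0.1496, 0.1522)
    stratify_by_label: bool = True
    group_by_patient: bool = True
    seed: int = 0

    def __post_init__(self):
        if len(self.fractions) != 3 or any(not 0 < f < 1 for f in self.fractions):
            raise ValueError(f"fractions must be three values in (0,1), got {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1, got {sum(self.fractions)}")


@dataclass
class SeriesSelection:
    kept: list
    rejected: list
    tallies: dict[str, int]


def filter_t2_series(series, allowlist=T2_PROTOCOLS) -> SeriesSelection:
    """Keep transverse series whose description matches the protocol allowlist.

    ``series`` is an iterable of descriptions or of ``(description,
    orientation)`` pairs; when the orientation is omitted or ``None`` it is
    taken from the protocol name (all allowlisted protocols are transverse).
    Unmatched series are reported in ``rejected``, never raised.
    """
    lookup = {name.lower(): name for name in allowlist}
    tallies = {name: 0 for name in allowlist}
    kept, rejected = [], []
    for item in series:
        if isinstance(item, str):
            description, orientation = item, None
        else:
            description, orientation = item
        proto = lookup.get(str(description).strip().lower())
        transverse = orientation is None or str(orientation).strip().lower() in _TRANSVERSE
        if proto is not None and transverse:
            kept.append(item)
            tallies[proto] += 1
        else:
            rejected.append(item)
    return SeriesSelection(kept=kept, rejected=rejected, tallies=tallies)


def load_slice(source, label=None, patient_id=None, slice_index=None) -> SliceRecord:
    """Read one slice from a DICOM, PNG or NIfTI file.

    DICOM rescale slope/intercept are applied when present; NIfTI volumes
    yield the middle slice along the last axis unless ``slice_index`` is
    given. Unreadable files raise with the offending path.
    """
    path = Path(source)
    if not path.exists():
        raise IOError(f"cannot read slice: {path} does not exist")
    suffix = "".join(path.suffixes).lower()
    try:
        if suffix.endswith((".dcm", ".dicom")) or suffix == "":
            import pydicom

            ds = pydicom.dcmread(path)
            pixels = ds.pixel_array.astype(float)
            slope = float(getattr(ds, "RescaleSlope", 1.0))
            intercept = float(getattr(ds, "RescaleIntercept", 0.0))
            pixels = pixels * slope + intercept
            return SliceRecord(
                patient_id=patient_id or str(getattr(ds, "PatientID", "")),
                pixels=pixels,
                label=label,
                series_description=str(getattr(ds, "SeriesDescription", "")),
                path=str(path),
            )
        if suffix.endswith((".nii", ".nii.gz")):
            import nibabel as nib

            vol = np.asanyarray(nib.load(str(path)).dataobj).astype(float)
            if vol.ndim == 2:
                pixels = vol
            else:
                idx = vol.shape[-1] // 2 if slice_index is None else slice_index
                pixels = vol[..., idx]
            return SliceRecord(patient_id=patient_id or path.stem, pixels=pixels, label=label, path=str(path))
        if suffix.endswith((".png", ".jpg", ".jpeg", ".tif", ".tiff")):
            from PIL import Image

            with Image.open(path) as img:
                pixels = np.asarray(img.convert("F"), dtype=float)
            return SliceRecord(patient_id=patient_id or path.stem, pixels=pixels, label=label, path=str(path))
    except Exception as exc:  # noqa: BLE001 - re-raise with path context
        raise IOError(f"failed to read slice from {path}: {exc}") from exc
    raise IOError(f"unsupported slice format: {path}")


def preprocess(record, size: int = 224) -> np.ndarray:
    """SliceRecord (or 2-D array) → network-ready (size, size, 3) array.

    Per-slice min-max rescale to [0, 255] (a constant slice maps to zeros),
    bilinear resize, grayscale replication, ImageNet mean subtraction.
    """
    pixels = record.pixels if isinstance(record, SliceRecord) else np.asarray(record, dtype=float)
    if pixels.ndim != 2 or pixels.size == 0:
        raise ValueError(f"expected a non-empty 2-D slice, got shape {pixels.shape}")
    lo, hi = pixels.min(), pixels.max()
    scaled = np.zeros_like(pixels) if hi == lo else (pixels - lo) * (255.0 / (hi - lo))
    if scaled.shape != (size, size):
        scaled = resize(scaled, (size, size), order=1, mode="edge", anti_aliasing=False, preserve_range=True)
    rgb = np.repeat(scaled[:, :, None], 3, axis=2)
    return rgb - np.asarray(IMAGENET_MEANS)


def apply_augment(image: np.ndarray, flip: bool, angle: float, zoom: float) -> np.ndarray:
    """Deterministic augmentation core: horizontal flip, then rotation by
    ``angle`` degrees, then central zoom by factor ``zoom``; shape preserved."""
    out = np.asarray(image, dtype=float)
    if flip:
        out = out[:, ::-1, ...].copy()
    if angle != 0.0:
        out = _warp_channels(out, lambda ch: rotate(ch, angle, order=1, mode="constant", cval=0.0, preserve_range=True))
    if zoom != 1.0:
        h, w = out.shape[:2]
        center = np.array([(w - 1) / 2.0, (h - 1) / 2.0])  # (x, y) order
        # warp() wants the output->input map: p -> center + (p - center)/zoom
        tf = AffineTransform(scale=1.0 / zoom, translation=center * (1.0 - 1.0 / zoom))
        out = _warp_channels(out, lambda ch: warp(ch, tf, order=1, mode="constant", cval=0.0, preserve_range=True))
    return out


def _warp_channels(image, fn):
    if image.ndim == 2:
        return fn(image)
    return np.stack([fn(image[..., c]) for c in range(image.shape[-1])], axis=-1)


def augment(image: np.ndarray, seed) -> np.ndarray:
    """Training-time augmentation: random horizontal flip (p = 0.5), rotation
    uniform in ±15°, zoom uniform in ±10%, applied in that order.
    Deterministic for a fixed seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    flip = rng.random() < 0.5
    angle = rng.uniform(-15.0, 15.0)
    zoom = 1.0 + rng.uniform(-0.10, 0.10)
    return apply_augment(image, flip, angle, zoom)


# -- splitting -------------------------------------------------------------


def _largest_remainder(total: int, fractions) -> list[int]:
    raw = [f * total for f in fractions]
    sizes = [int(np.floor(r)) for r in raw]
    for i in sorted(range(len(raw)), key=lambda i: raw[i] - sizes[i], reverse=True)[: total - sum(sizes)]:
        sizes[i] += 1
    return sizes


def split_dataset(records: list[SliceRecord], spec: SplitSpec):
    """Stratified three-way partition into (train, validation, test).

    Slice-level mode reproduces exact global subset sizes (largest-remainder
    rounding) with per-label counts within one sample of the stratified
    target. Patient-grouped mode (the default spec) assigns whole patients,
    trading exact sizes for leakage safety.
    """
    if len(records) < 3:
        raise ValueError("need at least 3 records to split")
    labels = np.array([r.label for r in records])
    if spec.stratify_by_label and len(np.unique(labels)) < 2:
        raise ValueError("stratified split requires both classes present")
    rng = np.random.default_rng(spec.seed)
    if spec.group_by_patient:
        return _split_by_patient(records, labels, spec, rng)
    return _split_by_slice(records, labels, spec, rng)


def _split_by_slice(records, labels, spec, rng):
    n = len(records)
    global_sizes = _largest_remainder(n, spec.fractions)
    deficits = list(global_sizes)
    groups = [np.flatnonzero(labels == v) for v in np.unique(labels)] if spec.stratify_by_label else [np.arange(n)]
    subsets = [[], [], []]
    for idx in groups:
        idx = rng.permutation(idx)
        sizes = [int(np.floor(f * len(idx))) for f in spec.fractions]
        leftover = len(idx) - sum(sizes)
        # hand each leftover slot to a distinct subset with the largest deficit
        for s in sorted(range(3), key=lambda s: deficits[s] - sizes[s], reverse=True)[:leftover]:
            sizes[s] += 1
        lo = 0
        for s in range(3):
            subsets[s].extend(idx[lo : lo + sizes[s]])
            deficits[s] -= sizes[s]
            lo += sizes[s]
    out = []
    for s in range(3):
        order = np.sort(np.array(subsets[s], dtype=int))
        out.append([records[i] for i in order])
    return tuple(out)


def _split_by_patient(records, labels, spec, rng):
    patients: dict[str, dict] = {}
    for i, r in enumerate(records):
        patients.setdefault(r.patient_id, {"indices": [], "label": r.label})["indices"].append(i)
    if len(patients) < 3:
        raise ValueError(f"patient-grouped split impossible with {len(patients)} patient(s); need at least 3")
    by_label: dict[int, list[str]] = {}
    for pid, info in patients.items():
        by_label.setdefault(info["label"], []).append(pid)
    subsets = [[], [], []]
    groups = sorted(by_label) if spec.stratify_by_label else [None]
    for g in groups:
        pids = by_label[g] if g is not None else sorted(patients)
        n_group = sum(len(patients[p]["indices"]) for p in pids)
        # per-label quotas so every subset sees every label when possible
        targets = [max(f * n_group, 1e-9) for f in spec.fractions]
        assigned = [0.0, 0.0, 0.0]
        for pid in rng.permutation(sorted(pids)):
            # place the patient where the relative shortfall is largest
            s = int(np.argmax([(targets[s] - assigned[s]) / targets[s] for s in range(3)]))
            subsets[s].extend(patients[pid]["indices"])
            assigned[s] += len(patients[pid]["indices"])
    out = []
    for s in range(3):
        order = np.sort(np.array(subsets[s], dtype=int))
        out.append([records[i] for i in order])
    return tuple(out)


# -- manifests -------------------------------------------------------------


def records_to_manifest(records, path=None) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {
                "patient_id": r.patient_id,
                "path": r.path,
                "series_description": r.series_description,
                "label": r.label,
            }
            for r in records
        ]
    )
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_manifest(path) -> list[SliceRecord]:
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        rec = load_slice(row.path, label=int(row.label), patient_id=str(row.patient_id))
        rec.series_description = str(row.series_description) if not pd.isna(row.series_description) else ""
        records.append(rec)
    return records
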