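"""Volume containers, NIfTI/DICOM I/O, and deterministic preprocessing.

Arrays are indexed ``(slice, row, col)``, 0-based; spacing is reported
``(dz, dy, dx)`` in millimetres.  A case is a :class:`DualVolume` (co-registered
fat- and water-sequence channels) plus a :class:`LabelMask` sharing its
geometry.  Preprocessing follows the slice-wise convention of a 2D model:
per-channel Z-score normalization over the whole volume, in-plane resampling
to a target spacing (third-order spline for images, nearest neighbour for
masks; the slice axis is left at native thickness), and a centred crop/pad to
the network's in-plane size with invertible bookkeeping.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
from skimage.transform import resize as _sk_resize

from .schema import LabelSchema, get_schema

Spacing3 = Tuple[float, float, float]


@dataclass
class DualVolume:
    """Co-registered fat and water voxel grids with spacing metadata."""

    fat: np.ndarray
    water: np.ndarray
    spacing: Spacing3

    def __post_init__(self) -> None:
        self.fat = np.asarray(self.fat, dtype=np.float32)
        self.water = np.asarray(self.water, dtype=np.float32)
        if self.fat.shape != self.water.shape:
            raise ValueError("fat and water channels must share shape")
        if self.fat.ndim != 3:
            raise ValueError("expected 3D (slice, row, col) arrays")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.fat.shape

    def channels(self) -> np.ndarray:
        """Stack as (2, slices, rows, cols): fat first, water second."""
        return np.stack([self.fat, self.water])


@dataclass
class LabelMask:
    """Integer compartment mask sharing DualVolume geometry; 0 = background."""

    labels: np.ndarray
    schema: LabelSchema
    spacing: Spacing3

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("label array must be integer")
        if self.labels.ndim != 3:
            raise ValueError("expected 3D (slice, row, col) mask")
        if self.labels.min() < 0:
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.labels)) - {0}
        if not present <= set(self.schema.label_ids):
            raise ValueError(f"mask contains ids outside schema: {sorted(present)}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be positive")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.labels.shape


def _check_geometry(volume: DualVolume, mask: LabelMask) -> None:
    if volume.shape != mask.shape:
        raise ValueError(f"geometry mismatch: {volume.shape} vs {mask.shape}")
    if not np.allclose(volume.spacing, mask.spacing):
        raise ValueError("spacing mismatch between volume and mask")


# ---------------------------------------------------------------------------
# normalization


def _znorm_channel(a: np.ndarray) -> np.ndarray:
    sd = float(a.std())
    if sd == 0.0:
        return np.zeros_like(a, dtype=np.float32)
    return ((a - a.mean()) / sd).astype(np.float32)


def znormalize(volume: DualVolume) -> DualVolume:
    """Independently Z-score each channel over all voxels of the volume.

    A constant channel maps to all zeros rather than dividing by zero.
    """
    if volume.fat.size < 2:
        raise ValueError("need at least 2 voxels per channel to normalize")
    return replace(volume, fat=_znorm_channel(volume.fat), water=_znorm_channel(volume.water))


# ---------------------------------------------------------------------------
# resampling


def _target_dim(old_dim: int, old_sp: float, new_sp: float) -> int:
    # round-half-up of physical extent / target spacing
    return int(np.floor(old_dim * old_sp / new_sp + 0.5))


def resample_pair(
    volume: DualVolume,
    mask: LabelMask,
    target_inplane: Tuple[float, float],
) -> Tuple[DualVolume, LabelMask]:
    """Resample in-plane to ``(dy, dx)`` mm; slice axis untouched.

    Images use third-order spline interpolation; masks use nearest neighbour,
    so the resampled value set is a subset of the original label set.
    """
    _check_geometry(volume, mask)
    dz, dy, dx = volume.spacing
    ty, tx = float(target_inplane[0]), float(target_inplane[1])
    if ty <= 0 or tx <= 0:
        raise ValueError("target spacing must be positive")
    if ty == dy and tx == dx:
        return volume, mask
    ns, nr, nc = volume.shape
    out_r = _target_dim(nr, dy, ty)
    out_c = _target_dim(nc, dx, tx)

    def _res_img(ch: np.ndarray) -> np.ndarray:
        out = np.empty((ns, out_r, out_c), dtype=np.float32)
        for k in range(ns):
            out[k] = _sk_resize(
                ch[k].astype(np.float64), (out_r, out_c), order=3,
                mode="edge", anti_aliasing=False, preserve_range=True,
            )
        return out

    lab_out = np.empty((ns, out_r, out_c), dtype=mask.labels.dtype)
    for k in range(ns):
        lab_out[k] = _sk_resize(
            mask.labels[k], (out_r, out_c), order=0,
            mode="edge", anti_aliasing=False, preserve_range=True,
        ).astype(mask.labels.dtype)

    new_spacing = (dz, ty, tx)
    vol = DualVolume(_res_img(volume.fat), _res_img(volume.water), new_spacing)
    return vol, LabelMask(lab_out, mask.schema, new_spacing)


# ---------------------------------------------------------------------------
# crop / pad


@dataclass(frozen=True)
class CropPadTransform:
    """Bookkeeping to map a cropped/padded array back to original geometry."""

    original_inplane: Tuple[int, int]
    target_inplane: Tuple[int, int]
    crop_offset: Tuple[int, int]   # top-left of the crop in original coords
    pad_before: Tuple[int, int]    # zero/background padding in target coords

    def invert_mask(self, labels: np.ndarray) -> np.ndarray:
        """Map a (slices, rows, cols) label array back to original in-plane size."""
        ns = labels.shape[0]
        pr, pc = self.pad_before
        tr, tc = self.target_inplane
        orr, orc = self.original_inplane
        core = labels[:, pr:pr + min(orr, tr), pc:pc + min(orc, tc)]
        out = np.zeros((ns, orr, orc), dtype=labels.dtype)
        r0, c0 = self.crop_offset
        out[:, r0:r0 + core.shape[1], c0:c0 + core.shape[2]] = core
        return out


def _crop_pad_axis(n: int, target: int) -> Tuple[int, int]:
    """Return (crop_offset, pad_before) for one axis."""
    if n >= target:
        return ((n - target) // 2, 0)
    return (0, (target - n) // 2)


def crop_pad(
    volume: DualVolume,
    mask: LabelMask,
    size: Tuple[int, int],
) -> Tuple[DualVolume, LabelMask, CropPadTransform]:
    """Centred crop (when larger) / symmetric zero-pad (when smaller) in-plane.

    Masks pad with background (0).  The returned transform maps predictions
    made on the cropped grid back onto the original geometry.
    """
    _check_geometry(volume, mask)
    tr, tc = int(size[0]), int(size[1])
    if tr <= 0 or tc <= 0:
        raise ValueError("target size must be positive")
    ns, nr, nc = volume.shape
    ro, rp = _crop_pad_axis(nr, tr)
    co, cp = _crop_pad_axis(nc, tc)

    def _one(a: np.ndarray) -> np.ndarray:
        core = a[:, ro:ro + min(nr, tr), co:co + min(nc, tc)]
        out = np.zeros((ns, tr, tc), dtype=a.dtype)
        out[:, rp:rp + core.shape[1], cp:cp + core.shape[2]] = core
        return out

    tf = CropPadTransform((nr, nc), (tr, tc), (ro, co), (rp, cp))
    vol = DualVolume(_one(volume.fat), _one(volume.water), volume.spacing)
    msk = LabelMask(_one(mask.labels), mask.schema, mask.spacing)
    return vol, msk, tf


# ---------------------------------------------------------------------------
# NIfTI I/O

def _affine(spacing: Spacing3) -> np.ndarray:
    dz, dy, dx = spacing
    # array axes (slice, row, col) map to world steps (dz, dy, dx)
    return np.diag([dz, dy, dx, 1.0])


def write_dual_volume(volume: DualVolume, stem: Path) -> Tuple[Path, Path]:
    """Write ``<stem>_fat.nii.gz`` and ``<stem>_water.nii.gz``."""
    stem = Path(stem)
    paths = (stem.parent / f"{stem.name}_fat.nii.gz",
             stem.parent / f"{stem.name}_water.nii.gz")
    for p, arr in zip(paths, (volume.fat, volume.water)):
        img = nib.Nifti1Image(np.asarray(arr, dtype=np.float32), _affine(volume.spacing))
        img.header.set_zooms(volume.spacing)
        nib.save(img, p)
    return paths


def read_dual_volume(fat_path: Path, water_path: Path) -> DualVolume:
    fimg, wimg = nib.load(str(fat_path)), nib.load(str(water_path))
    spacing = tuple(float(z) for z in fimg.header.get_zooms()[:3])
    return DualVolume(
        np.asanyarray(fimg.dataobj, dtype=np.float32),
        np.asanyarray(wimg.dataobj, dtype=np.float32),
        spacing,
    )


def write_mask(mask: LabelMask, path: Path) -> Path:
    img = nib.Nifti1Image(mask.labels.astype(np.int16), _affine(mask.spacing))
    img.header.set_zooms(mask.spacing)
    nib.save(img, path)
    return Path(path)


def read_mask(path: Path, schema: LabelSchema | str) -> LabelMask:
    if isinstance(schema, str):
        schema = get_schema(schema)
    img = nib.load(str(path))
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMask(np.asanyarray(img.dataobj).astype(np.int32), schema, spacing)


def write_sidecar(path: Path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True))


# ---------------------------------------------------------------------------
# DICOM series (optional input path)


def read_dicom_series(directory: Path) -> Tuple[np.ndarray, Spacing3]:
    """Collapse a single-series DICOM directory to (volume, spacing).

    Slices are ordered by ImagePositionPatient z when present, otherwise by
    InstanceNumber.  Returns a float32 (slice, row, col) array.
    """
    import pydicom

    files = sorted(Path(directory).glob("*.dcm"))
    if not files:
        raise FileNotFoundError(f"no .dcm files in {directory}")
    dsets = [pydicom.dcmread(str(f)) for f in files]

    def sort_key(ds):
        if hasattr(ds, "ImagePositionPatient"):
            return float(ds.ImagePositionPatient[2])
        return int(getattr(ds, "InstanceNumber", 0))

    dsets.sort(key=sort_key)
    arr = np.stack([ds.pixel_array.astype(np.float32) for ds in dsets])
    ds0 = dsets[0]
    py, px = (float(v) for v in getattr(ds0, "PixelSpacing", [1.0, 1.0]))
    if len(dsets) > 1 and hasattr(ds0, "ImagePositionPatient"):
        dz = abs(float(dsets[1].ImagePositionPatient[2]) - float(ds0.ImagePositionPatient[2]))
    else:
        dz = float(getattr(ds0, "SliceThickness", 1.0))
    return arr, (dz or 1.0, py, px)
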