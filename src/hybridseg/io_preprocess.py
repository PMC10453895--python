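"""Volume / mask I/O, intensity normalization, and per-slice extraction.

Input is assumed BraTS-style preprocessed: co-registered, skull-stripped
multi-modal NIfTI volumes (T1, T1c, T2, FLAIR) with integer label masks in
{0,1,2,3}.  Registration, skull stripping and bias-field correction are
upstream concerns and are not implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

MODALITIES = ("t1", "t1c", "t2", "flair")
MANIFEST_COLUMNS = ("case_id", "t1", "t1c", "t2", "flair", "mask")


@dataclass
class MultiModalVolume:
    """A 4-channel volume, channel-major (modality, slice, row, col)."""

    voxels: np.ndarray
    modality_order: tuple[str, ...] = MODALITIES
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=np.float64)
        if self.voxels.ndim != 4 or self.voxels.shape[0] != 4:
            raise ValueError("volume must have exactly 4 modality channels")


@dataclass
class MultiModalSlice:
    """One axial slice as a 4-channel (modality, row, col) grid in [0,1]."""

    pixels: np.ndarray
    source_index: int = 0

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 3 or self.pixels.shape[0] != 4:
            raise ValueError("slice must have exactly 4 modality channels")


@dataclass
class SegmentationMask:
    """Integer label grid; values in {0 background, 1, 2, 3}."""

    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("mask labels must be integers")
        if not np.isin(np.unique(self.labels), [0, 1, 2, 3]).all():
            raise ValueError("mask labels must lie in {0,1,2,3}")


# ---------------------------------------------------------------------------
# I/O


def _load_nifti(path) -> tuple[np.ndarray, tuple[float, ...]]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=np.float64), img.header.get_zooms()[:3]


def read_volume(paths) -> MultiModalVolume:
    """Read a case from 4 single-modality NIfTI files or one 4-channel file.

    ``paths`` is a mapping modality-name -> path (keys t1, t1c, t2, flair),
    a sequence of 4 paths in that order, or a single path to a 4-channel
    NIfTI (4th axis = modality).  Raw intensities are left untouched.
    """
    if isinstance(paths, (str, Path)):
        data, spacing = _load_nifti(paths)
        if data.ndim != 4 or data.shape[-1] != 4:
            raise ValueError("incomplete case: single file must be 4-channel")
        # x,y,z,m -> m,z,y,x so axis 1 walks axial slices
        voxels = np.transpose(data, (3, 2, 1, 0))
        return MultiModalVolume(voxels=voxels, voxel_spacing=tuple(spacing))
    if isinstance(paths, dict):
        missing = [m for m in MODALITIES if m not in paths]
        if missing:
            raise ValueError(f"incomplete case: missing modalities {missing}")
        ordered = [paths[m] for m in MODALITIES]
    else:
        ordered = list(paths)
        if len(ordered) != 4:
            raise ValueError(
                f"incomplete case: expected 4 modality files, got {len(ordered)}"
            )
    arrays, spacing = [], None
    for p in ordered:
        data, sp = _load_nifti(p)
        spacing = spacing or sp
        arrays.append(np.transpose(data, (2, 1, 0)))
    shapes = {a.shape for a in arrays}
    if len(shapes) != 1:
        raise ValueError("unaligned modalities: shapes differ")
    return MultiModalVolume(voxels=np.stack(arrays), voxel_spacing=tuple(spacing))


def write_volume(volume: MultiModalVolume, path) -> None:
    """Write a volume as one 4-channel NIfTI (x, y, z, modality)."""
    data = np.transpose(volume.voxels, (3, 2, 1, 0)).astype(np.float32)
    affine = np.diag(list(volume.voxel_spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def write_mask(mask: SegmentationMask, path, spacing=(1.0, 1.0, 1.0)) -> None:
    """Write a mask as an unsigned 8-bit NIfTI."""
    labels = mask.labels
    if labels.ndim == 2:
        labels = labels[None]
    data = np.transpose(labels, (2, 1, 0)).astype(np.uint8)
    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(data, affine), str(path))


def read_mask(path) -> SegmentationMask:
    data, _ = _load_nifti(path)
    return SegmentationMask(labels=np.transpose(data, (2, 1, 0)).astype(np.uint8))


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"manifest missing columns {missing}")
    return df


def write_manifest(rows, path) -> pd.DataFrame:
    df = pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))
    df.to_csv(path, index=False)
    return df


# ---------------------------------------------------------------------------
# preprocessing


def normalize_intensity(volume: MultiModalVolume) -> MultiModalVolume:
    """Min-max normalize each modality to [0, 1] over brain (nonzero) voxels.

    The brain mask is taken as "nonzero in any modality"; background voxels
    stay 0.  A constant-valued modality maps to all zeros (0/0 guard).
    """
    if not np.isfinite(volume.voxels).all():
        raise ValueError("invalid intensities: non-finite values")
    voxels = volume.voxels.copy()
    brain = np.any(voxels != 0, axis=0)
    for m in range(voxels.shape[0]):
        vals = voxels[m][brain]
        if vals.size == 0:
            continue
        lo, hi = vals.min(), vals.max()
        if hi > lo:
            voxels[m][brain] = (vals - lo) / (hi - lo)
        else:
            voxels[m][brain] = 0.0
    return MultiModalVolume(
        voxels=voxels,
        modality_order=volume.modality_order,
        voxel_spacing=volume.voxel_spacing,
    )


def pad_to(image: np.ndarray, target: int, axes=(-2, -1)) -> np.ndarray:
    """Zero-pad the trailing spatial axes symmetrically to ``target``."""
    pads = [(0, 0)] * image.ndim
    for ax in axes:
        size = image.shape[ax]
        if size > target:
            raise ValueError(f"cannot pad down: {size} > {target}")
        before = (target - size) // 2
        pads[ax % image.ndim] = (before, target - size - before)
    return np.pad(image, pads)


def crop_center(image: np.ndarray, size: int, axes=(-2, -1)) -> np.ndarray:
    """Inverse of :func:`pad_to`: crop the centered ``size`` x ``size`` region."""
    slices = [slice(None)] * image.ndim
    for ax in axes:
        before = (image.shape[ax] - size) // 2
        slices[ax % image.ndim] = slice(before, before + size)
    return image[tuple(slices)]


def slice_dataset(
    volume: MultiModalVolume,
    mask: SegmentationMask,
    target_size: int = 256,
    keep_empty: bool = False,
) -> list[tuple[MultiModalSlice, SegmentationMask]]:
    """Cut a volume into padded per-slice training pairs.

    Axial slices are zero-padded symmetrically to ``target_size`` (mask
    padded with label 0).  Slices whose mask is entirely background are
    dropped unless ``keep_empty``.
    """
    labels = mask.labels
    if labels.ndim == 2:
        labels = labels[None]
    if labels.shape != volume.voxels.shape[1:]:
        raise ValueError("unaligned masks: mask incongruent with volume")
    pairs = []
    for i in range(volume.voxels.shape[1]):
        sl = labels[i]
        if not keep_empty and not sl.any():
            continue
        img = pad_to(volume.voxels[:, i], target_size)
        lab = pad_to(sl, target_size)
        pairs.append(
            (
                MultiModalSlice(pixels=img, source_index=i),
                SegmentationMask(labels=lab),
            )
        )
    return pairs
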