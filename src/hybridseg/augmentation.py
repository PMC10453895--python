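"""Stochastic training-time augmentations, applied jointly to image and mask.

The recipe: random rotation (±15°), scaling (0.8–1.2), horizontal flip
(p = 0.5), random elastic deformation (displacement field = Gaussian-filtered
white noise, σ = 4.0), additive intensity shift (−0.1 to 0.1, then clipped
to [0,1]) and contrast normalization by histogram equalization.  Geometric
transforms use bilinear interpolation for intensities and nearest-neighbour
for labels, so no interpolation-invented labels appear.  A single seeded
generator drives all draws for one pair; fixed order geometric → intensity
shift → contrast normalization.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage import exposure

from .io_preprocess import MultiModalSlice, SegmentationMask


@dataclass
class AugmentationConfig:
    rotation_deg: float = 15.0
    scale_range: tuple[float, float] = (0.8, 1.2)
    hflip_prob: float = 0.5
    elastic_sigma: float = 4.0
    elastic_alpha: float = 10.0  # max displacement, pixels
    elastic_prob: float = 0.5
    intensity_shift_range: tuple[float, float] = (-0.1, 0.1)
    contrast_norm: bool = True
    contrast_prob: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if self.scale_range[0] > self.scale_range[1]:
            raise ValueError("invalid augmentation config: scale range unordered")
        if self.intensity_shift_range[0] > self.intensity_shift_range[1]:
            raise ValueError("invalid augmentation config: shift range unordered")
        for p in (self.hflip_prob, self.elastic_prob, self.contrast_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("invalid augmentation config: probability not in [0,1]")
        if self.rotation_deg < 0 or self.elastic_alpha < 0:
            raise ValueError("invalid augmentation config: negative amplitude")


def _affine_pair(pixels, labels, angle_deg, scale):
    """Rotate+scale about the image center; bilinear image, nearest mask."""
    h, w = labels.shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    a = np.deg2rad(angle_deg)
    # backward map: output coord -> input coord (inverse rotation / scale)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    matrix = rot / scale
    offset = center - matrix @ center
    out_px = np.stack(
        [
            ndimage.affine_transform(c, matrix, offset=offset, order=1, mode="constant")
            for c in pixels
        ]
    )
    out_lab = ndimage.affine_transform(
        labels, matrix, offset=offset, order=0, mode="constant", cval=0
    )
    return out_px, out_lab


def elastic_deformation(
    slice_: MultiModalSlice,
    mask: SegmentationMask,
    sigma: float = 4.0,
    alpha: float = 10.0,
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
):
    """Warp image and mask by a smoothed random displacement field.

    The field is white noise filtered with a Gaussian of ``sigma`` and
    rescaled so its largest displacement is ``alpha`` pixels; both inputs
    are backward-warped with the same field.  ``alpha = 0`` is the identity.
    """
    if sigma <= 0:
        raise ValueError("invalid filter scale: sigma must be > 0")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")
    rng = rng if rng is not None else np.random.default_rng(seed)
    h, w = mask.labels.shape
    # always consume the draws so seeds stay aligned across alpha settings
    dy = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
    dx = ndimage.gaussian_filter(rng.standard_normal((h, w)), sigma)
    if alpha == 0:
        return slice_, mask
    peak = max(np.abs(dy).max(), np.abs(dx).max())
    if peak > 0:
        dy *= alpha / peak
        dx *= alpha / peak
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    coords = [yy + dy, xx + dx]
    pixels = np.stack(
        [
            ndimage.map_coordinates(c, coords, order=1, mode="constant")
            for c in slice_.pixels
        ]
    )
    labels = ndimage.map_coordinates(
        mask.labels, coords, order=0, mode="constant", cval=0
    )
    return (
        MultiModalSlice(pixels=pixels, source_index=slice_.source_index),
        SegmentationMask(labels=labels.astype(mask.labels.dtype)),
    )


def augment_pair(
    slice_: MultiModalSlice,
    mask: SegmentationMask,
    config: AugmentationConfig | None = None,
    seed: int | None = None,
):
    """Apply one random draw of the augmentation recipe to a slice/mask pair.

    Deterministic given the seed.  With every stochastic component disabled
    (zero rotation, unit scale, zero flip probability, zero shift, zero
    elastic amplitude, contrast off) the output is bit-identical to the input.
    """
    config = config or AugmentationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed if seed is None else seed)

    # draw everything up front, in fixed order, so determinism is easy to reason about
    angle = rng.uniform(-config.rotation_deg, config.rotation_deg)
    scale = rng.uniform(*config.scale_range)
    flip = rng.random() < config.hflip_prob
    do_elastic = rng.random() < config.elastic_prob
    shift = rng.uniform(*config.intensity_shift_range)
    do_contrast = config.contrast_norm and rng.random() < config.contrast_prob

    pixels = slice_.pixels
    labels = mask.labels

    if angle != 0.0 or scale != 1.0:
        pixels, labels = _affine_pair(pixels, labels, angle, scale)
    if flip:
        pixels = pixels[:, :, ::-1].copy()
        labels = labels[:, ::-1].copy()
    out_slice = MultiModalSlice(pixels=pixels, source_index=slice_.source_index)
    out_mask = SegmentationMask(labels=np.ascontiguousarray(labels))
    if config.elastic_alpha > 0 and do_elastic:
        out_slice, out_mask = elastic_deformation(
            out_slice, out_mask, config.elastic_sigma, config.elastic_alpha, rng=rng
        )
    if shift != 0.0:
        out_slice = MultiModalSlice(
            pixels=np.clip(out_slice.pixels + shift, 0.0, 1.0),
            source_index=out_slice.source_index,
        )
    if do_contrast:
        eq = np.stack([exposure.equalize_hist(c) for c in out_slice.pixels])
        out_slice = MultiModalSlice(pixels=eq, source_index=out_slice.source_index)
    return out_slice, out_mask


def identity_config() -> AugmentationConfig:
    """A configuration with every stochastic component disabled."""
    return AugmentationConfig(
        rotation_deg=0.0,
        scale_range=(1.0, 1.0),
        hflip_prob=0.0,
        elastic_alpha=0.0,
        elastic_prob=0.0,
        intensity_shift_range=(0.0, 0.0),
        contrast_norm=False,
    )
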