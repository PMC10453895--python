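"""Multi-modal phantom slices with nested tumor sub-region labels.

Each phantom emulates one skull-stripped, intensity-normalized axial slice:
an elliptical "brain" carrying a smooth random texture field, with a
randomly placed, randomly deformed tumor made of three nested sub-regions —
an enhancing rim (label 3) on the boundary of a core disc (label 2),
surrounded by an edema annulus (label 1).  The nesting ET ⊆ TC ⊆ WT matches
the BraTS evaluation convention.  Four modality channels (T1, T1c, T2,
FLAIR) receive per-region additive contrast offsets plus Gaussian noise and
are clipped to [0, 1].  Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io_preprocess import MODALITIES, MultiModalSlice, SegmentationMask

# additive offsets per modality for (edema, core, enhancing rim): rough
# qualitative mimicry of glioma contrast (FLAIR/T2 bright edema, T1 dark
# tumor, T1c bright enhancing rim)
DEFAULT_CONTRASTS = {
    "t1": (-0.10, -0.15, -0.05),
    "t1c": (0.00, -0.05, 0.40),
    "t2": (0.25, 0.20, 0.15),
    "flair": (0.35, 0.25, 0.30),
}

_BASE_INTENSITY = {"t1": 0.45, "t1c": 0.45, "t2": 0.40, "flair": 0.40}


@dataclass
class PhantomSpec:
    """Geometry, contrast and noise settings for one phantom slice."""

    image_size: int = 64
    tumor_radius_range: tuple[float, float] | None = None  # default size/8..size/4
    ring_thickness: float = 2.0
    edema_thickness: float | None = None  # default half the tumor radius
    modality_contrasts: dict = field(default_factory=lambda: dict(DEFAULT_CONTRASTS))
    noise_sd: float = 0.05
    background_texture_scale: float = 4.0
    seed: int = 0

    def radius_range(self) -> tuple[float, float]:
        if self.tumor_radius_range is not None:
            return self.tumor_radius_range
        return (self.image_size / 8.0, self.image_size / 4.0)

    def validate(self) -> None:
        lo, hi = self.radius_range()
        if not (0 < lo <= hi):
            raise ValueError("invalid phantom spec: bad tumor_radius_range")
        if hi * 2 >= self.image_size:
            raise ValueError("invalid phantom spec: tumor does not fit in image")
        if self.noise_sd < 0:
            raise ValueError("invalid phantom spec: noise_sd must be >= 0")
        if self.ring_thickness < 0:
            raise ValueError("invalid phantom spec: ring_thickness must be >= 0")


def _smooth_field(rng, size: int, scale: float) -> np.ndarray:
    """Zero-mean, unit-ish amplitude Gaussian-filtered white noise."""
    f = ndimage.gaussian_filter(rng.standard_normal((size, size)), scale)
    peak = np.abs(f).max()
    return f / peak if peak > 0 else f


def generate_phantom_slice(
    spec: PhantomSpec, seed: int | None = None
) -> tuple[MultiModalSlice, SegmentationMask]:
    """Generate one 4-channel phantom slice and its nested label mask."""
    spec.validate()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n = spec.image_size
    yy, xx = np.mgrid[0:n, 0:n].astype(float)
    cy = cx = (n - 1) / 2.0

    # brain: centered ellipse with mildly random axes
    ay = n * rng.uniform(0.38, 0.46)
    ax = n * rng.uniform(0.34, 0.44)
    brain = ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    # tumor geometry: deformed disc placed inside the brain
    lo, hi = spec.radius_range()
    radius = rng.uniform(lo, hi)
    edema = spec.edema_thickness if spec.edema_thickness is not None else radius / 2.0
    margin = radius + edema + 2.0
    ty = cy + rng.uniform(-1, 1) * max(ay - margin, 0.0) * 0.7
    tx = cx + rng.uniform(-1, 1) * max(ax - margin, 0.0) * 0.7
    # radial deformation: low-order angular harmonics
    theta = np.arctan2(yy - ty, xx - tx)
    deform = np.zeros_like(theta)
    for harmonic in (2, 3):
        deform += rng.uniform(0.0, 0.12) * np.cos(
            harmonic * theta + rng.uniform(0, 2 * np.pi)
        )
    dist = np.hypot(yy - ty, xx - tx) / (1.0 + deform)

    core_disc = dist <= radius
    rim = core_disc & (dist > radius - spec.ring_thickness)
    edema_annulus = (dist <= radius + edema) & ~core_disc

    labels = np.zeros((n, n), dtype=np.uint8)
    labels[edema_annulus & brain] = 1
    labels[core_disc & brain] = 2
    labels[rim & brain] = 3

    # intensities per modality
    pixels = np.zeros((4, n, n), dtype=np.float64)
    texture = _smooth_field(rng, n, spec.background_texture_scale)
    for m, name in enumerate(MODALITIES):
        offsets = spec.modality_contrasts.get(name, (0.0, 0.0, 0.0))
        img = np.zeros((n, n))
        img[brain] = _BASE_INTENSITY[name] + 0.10 * texture[brain]
        for lab, off in zip((1, 2, 3), offsets):
            img[labels == lab] += off
        if spec.noise_sd > 0:
            img[brain] += rng.normal(0.0, spec.noise_sd, size=int(brain.sum()))
        pixels[m] = np.clip(img, 0.0, 1.0)

    return (
        MultiModalSlice(pixels=pixels, source_index=0),
        SegmentationMask(labels=labels),
    )


def generate_phantom_dataset(
    spec: PhantomSpec, n: int, seed: int = 0
) -> list[tuple[MultiModalSlice, SegmentationMask]]:
    """Generate ``n`` independent phantom pairs.

    Per-item seeds derive from ``SeedSequence([seed, index])``, so the
    dataset is order-independent and any item can be regenerated alone.
    """
    if n < 1:
        raise ValueError("empty dataset request: n must be >= 1")
    out = []
    for i in range(n):
        item_seed = np.random.SeedSequence([seed, i])
        pair = generate_phantom_slice(spec, seed=item_seed)
        pair[0].source_index = i
        out.append(pair)
    return out
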