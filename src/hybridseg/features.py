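"""Handcrafted descriptors: dense SURF, HOG, and intensity/texture maps.

Dense SURF (DSURF) replaces interest-point detection with a regular grid of
keypoints; each keypoint gets the classic 64-dimensional SURF descriptor —
for each of 4x4 sub-regions of the support window, the tuple
(sum dx, sum dy, sum |dx|, sum |dy|) of Gaussian first-derivative responses,
L2-normalized.  HOG accumulates gradient magnitude into per-cell angular
histograms with block L2 normalization.  Texture maps provide sliding-window
statistics, GLCM contrast/homogeneity/energy, and an 8-neighbour LBP code
map.  All outputs can be assembled into an image-aligned ``FeatureStack``
whose channels feed the fusion pathways of the hybrid network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

__all__ = [
    "GridKeypoint",
    "HessianResponse",
    "DSURFDescriptor",
    "HOGParams",
    "HOGResult",
    "GradientField",
    "FeatureStack",
    "dense_grid",
    "hessian_responses",
    "dsurf_descriptors",
    "image_gradients",
    "hog_features",
    "glcm_matrix",
    "glcm_window_maps",
    "lbp_map",
    "texture_intensity_maps",
    "dsurf_to_channels",
    "feature_stack",
    "compute_feature_stack",
]


@dataclass
class GridKeypoint:
    x: int
    y: int
    scale: float = 1.6


@dataclass
class HessianResponse:
    """Second-order Gaussian-derivative responses at one point."""

    Lxx: float
    Lxy: float
    Lyy: float
    sigma: float

    @property
    def determinant(self) -> float:
        return self.Lxx * self.Lyy - self.Lxy**2


@dataclass
class DSURFDescriptor:
    keypoint: GridKeypoint
    orientation: float  # radians
    vector: np.ndarray  # 64 values: 4x4 sub-regions x (Sdx, Sdy, S|dx|, S|dy|)


@dataclass
class HOGParams:
    cell_size: int = 8
    block_size: int = 2  # in cells
    n_bins: int = 9
    signed: bool = False
    block_norm: str = "l2"
    epsilon: float = 1e-6

    def validate(self) -> None:
        if self.n_bins < 2:
            raise ValueError("invalid histogram: n_bins must be >= 2")
        if self.cell_size < 1 or self.block_size < 1:
            raise ValueError("invalid HOG geometry")


@dataclass
class HOGResult:
    cell_histograms: np.ndarray  # (n_cells_y, n_cells_x, n_bins)
    block_vector: np.ndarray  # flattened block-normalized descriptor
    pixel_maps: np.ndarray  # (n_bins, H, W)
    params: HOGParams


@dataclass
class GradientField:
    Gx: np.ndarray
    Gy: np.ndarray


@dataclass
class FeatureStack:
    """Named 2-D feature channels aligned to an image."""

    channels: np.ndarray  # (C, H, W)
    names: list = field(default_factory=list)
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.channels = np.asarray(self.channels, dtype=np.float64)
        if self.channels.ndim != 3:
            raise ValueError("unaligned features: channels must be (C, H, W)")
        if not np.isfinite(self.channels).all():
            raise ValueError("feature channels must be finite")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]


# ---------------------------------------------------------------------------
# dense grid + DSURF


def dense_grid(width: int, height: int, step: int, margin: int = 0, scale: float = 1.6):
    """Keypoints at (margin + i*step, margin + j*step), row-major.

    Points within ``margin`` of the right/bottom edge are excluded so the
    descriptor support fits; an over-large margin yields an empty list.
    """
    if step < 1:
        raise ValueError("step must be >= 1")
    points = []
    for y in range(margin, height - margin):
        if (y - margin) % step:
            continue
        for x in range(margin, width - margin):
            if (x - margin) % step:
                continue
            points.append(GridKeypoint(x=x, y=y, scale=scale))
    return points


def _gaussian_derivatives(image: np.ndarray, sigma: float):
    lx = ndimage.gaussian_filter(image, sigma, order=(0, 1), mode="reflect")
    ly = ndimage.gaussian_filter(image, sigma, order=(1, 0), mode="reflect")
    return lx, ly


def hessian_responses(image: np.ndarray, points, sigma: float = 1.6):
    """Second-order Gaussian-derivative (Hessian) responses at keypoints.

    Available for diagnostics; the dense grid makes detection unnecessary.
    """
    lxx = ndimage.gaussian_filter(image, sigma, order=(0, 2), mode="reflect")
    lyy = ndimage.gaussian_filter(image, sigma, order=(2, 0), mode="reflect")
    lxy = ndimage.gaussian_filter(image, sigma, order=(1, 1), mode="reflect")
    return [
        HessianResponse(
            Lxx=float(lxx[p.y, p.x]),
            Lxy=float(lxy[p.y, p.x]),
            Lyy=float(lyy[p.y, p.x]),
            sigma=sigma,
        )
        for p in points
    ]


def dsurf_descriptors(
    image: np.ndarray,
    step: int = 8,
    sigma: float = 1.6,
    window: int = 16,
    oriented: bool = False,
):
    """64-dimensional dense SURF descriptors on a regular keypoint grid.

    For every grid keypoint the ``window`` x ``window`` support is cut from
    the Gaussian first-derivative responses (Lx, Ly), optionally rotated to
    the dominant orientation theta = arctan2(sum W*Lx, sum W*Ly) with a
    Gaussian weight W, partitioned into 4x4 sub-regions, and summarized as
    (sum dx, sum dy, sum |dx|, sum |dy|) per sub-region, L2-normalized.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError("dsurf_descriptors expects a single-channel image")
    if window % 4:
        raise ValueError("window must be divisible by 4")
    h, w = image.shape
    half = window // 2
    lx, ly = _gaussian_derivatives(image, sigma)

    yy, xx = np.mgrid[0:window, 0:window] - (half - 0.5)
    weight = np.exp(-(xx**2 + yy**2) / (2 * (window / 3.0) ** 2))

    sub = window // 4
    descriptors, skipped = [], 0
    for p in dense_grid(w, h, step, margin=0, scale=sigma):
        y0, x0 = p.y - half, p.x - half
        if y0 < 0 or x0 < 0 or y0 + window > h or x0 + window > w:
            skipped += 1
            continue
        if oriented:
            wx = lx[y0 : y0 + window, x0 : x0 + window]
            wy = ly[y0 : y0 + window, x0 : x0 + window]
            theta = float(np.arctan2((weight * wx).sum(), (weight * wy).sum()))
            ct, st = np.cos(theta), np.sin(theta)
            ry = p.y + (xx * st + yy * ct)
            rx = p.x + (xx * ct - yy * st)
            slx = ndimage.map_coordinates(lx, [ry, rx], order=1, mode="nearest")
            sly = ndimage.map_coordinates(ly, [ry, rx], order=1, mode="nearest")
            dx = ct * slx + st * sly
            dy = -st * slx + ct * sly
        else:
            theta = 0.0
            dx = lx[y0 : y0 + window, x0 : x0 + window]
            dy = ly[y0 : y0 + window, x0 : x0 + window]
        vec = np.empty(64)
        i = 0
        for sy in range(4):
            for sx in range(4):
                bx = dx[sy * sub : (sy + 1) * sub, sx * sub : (sx + 1) * sub]
                by = dy[sy * sub : (sy + 1) * sub, sx * sub : (sx + 1) * sub]
                vec[i : i + 4] = (
                    bx.sum(),
                    by.sum(),
                    np.abs(bx).sum(),
                    np.abs(by).sum(),
                )
                i += 4
        norm = np.linalg.norm(vec)
        if norm > 0:
            vec /= norm
        descriptors.append(
            DSURFDescriptor(
                keypoint=GridKeypoint(p.x, p.y, sigma),
                orientation=theta,
                vector=vec,
            )
        )
    if skipped:
        logger.info("dsurf: skipped %d keypoints without full support", skipped)
    return descriptors


# ---------------------------------------------------------------------------
# HOG


def image_gradients(image: np.ndarray) -> GradientField:
    """Central-difference gradients, (f(x+1)-f(x-1))/2, edge-replicated."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2 or min(image.shape) < 3:
        raise ValueError("degenerate image: need at least 3x3")
    padded = np.pad(image, 1, mode="edge")
    gx = (padded[1:-1, 2:] - padded[1:-1, :-2]) / 2.0
    gy = (padded[2:, 1:-1] - padded[:-2, 1:-1]) / 2.0
    return GradientField(Gx=gx, Gy=gy)


def hog_features(image: np.ndarray, params: HOGParams | None = None) -> HOGResult:
    """Per-cell orientation histograms, block-normalized vector, pixel maps.

    Gradient magnitude is hard-assigned to the angular bin of its cell
    (angles folded to [0, 180) when unsigned); blocks of cells are
    L2-normalized with an epsilon guard.  The per-pixel channel maps
    broadcast each cell's raw histogram to its pixels.
    """
    params = params or HOGParams()
    params.validate()
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    cell, bs, nb = params.cell_size, params.block_size, params.n_bins
    if h < cell * bs or w < cell * bs:
        raise ValueError("image smaller than one block")

    g = image_gradients(image)
    mag = np.hypot(g.Gx, g.Gy)
    ang = np.degrees(np.arctan2(g.Gy, g.Gx))
    span = 360.0 if params.signed else 180.0
    ang = np.mod(ang, span)
    bins = np.minimum((ang / (span / nb)).astype(int), nb - 1)

    nyc, nxc = h // cell, w // cell
    hists = np.zeros((nyc, nxc, nb))
    ys, xs = np.mgrid[0 : nyc * cell, 0 : nxc * cell]
    flat = (
        (ys // cell) * (nxc * nb)
        + (xs // cell) * nb
        + bins[: nyc * cell, : nxc * cell]
    ).ravel()
    np.add.at(hists.reshape(-1), flat, mag[: nyc * cell, : nxc * cell].ravel())

    blocks = []
    for by in range(nyc - bs + 1):
        for bx in range(nxc - bs + 1):
            v = hists[by : by + bs, bx : bx + bs].ravel()
            blocks.append(v / np.sqrt((v**2).sum() + params.epsilon**2))
    block_vector = np.concatenate(blocks) if blocks else np.zeros(0)

    iy = np.minimum(np.arange(h) // cell, nyc - 1)
    ix = np.minimum(np.arange(w) // cell, nxc - 1)
    pixel_maps = hists[np.ix_(iy, ix)].transpose(2, 0, 1)

    return HOGResult(
        cell_histograms=hists,
        block_vector=block_vector,
        pixel_maps=pixel_maps,
        params=params,
    )


# ---------------------------------------------------------------------------
# texture / intensity maps


def _quantize(image: np.ndarray, levels: int) -> np.ndarray:
    """Equal-width quantization of [0, 1] intensities to ``levels`` levels."""
    return np.minimum((np.asarray(image, dtype=np.float64) * levels).astype(int),
                      levels - 1)


def glcm_matrix(
    image: np.ndarray,
    levels: int = 8,
    offsets=((0, 1),),
    symmetric: bool = True,
    normalized: bool = True,
) -> np.ndarray:
    """Gray-level co-occurrence matrix over the whole image.

    ``offsets`` are (dy, dx) pixel displacements; counts from all offsets
    are pooled.  Symmetric mode counts each pair in both directions.
    """
    if levels < 2:
        raise ValueError("invalid quantization: levels must be >= 2")
    q = _quantize(image, levels)
    mat = np.zeros((levels, levels))
    for dy, dx in offsets:
        a = q[max(0, -dy) : q.shape[0] - max(0, dy),
              max(0, -dx) : q.shape[1] - max(0, dx)]
        b = q[max(0, dy) :, max(0, dx) :][: a.shape[0], : a.shape[1]]
        np.add.at(mat, (a.ravel(), b.ravel()), 1.0)
    if symmetric:
        mat = mat + mat.T
    if normalized and mat.sum() > 0:
        mat = mat / mat.sum()
    return mat


def glcm_window_maps(
    image: np.ndarray,
    window: int = 7,
    levels: int = 8,
    offsets=((0, 1),),
) -> dict:
    """Sliding-window GLCM contrast / homogeneity / energy maps.

    Per pixel, a symmetric normalized co-occurrence matrix is built from
    the pairs whose first pixel lies in the centered window; features are
    averaged over offsets.
    """
    if levels < 2:
        raise ValueError("invalid quantization: levels must be >= 2")
    q = _quantize(image, levels)
    h, w = q.shape
    ii, jj = np.mgrid[0:levels, 0:levels]
    weights = {
        "glcm_contrast": (ii - jj) ** 2,
        "glcm_homogeneity": 1.0 / (1.0 + (ii - jj) ** 2),
    }
    out = {k: np.zeros((h, w)) for k in (*weights, "glcm_energy")}
    for dy, dx in offsets:
        a = q[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
        b = q[max(0, dy) :, max(0, dx) :][: a.shape[0], : a.shape[1]]
        valid = np.zeros((h, w))
        valid[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)] = 1.0
        total = ndimage.uniform_filter(valid, window, mode="constant")
        counts = np.empty((levels, levels, h, w))
        for i in range(levels):
            for j in range(levels):
                ind = np.zeros((h, w))
                ind[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)] = (
                    (a == i) & (b == j)
                ).astype(float)
                counts[i, j] = ndimage.uniform_filter(ind, window, mode="constant")
        sym = counts + counts.transpose(1, 0, 2, 3)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(total > 0, sym / (2.0 * total), 0.0)
        for name, wmat in weights.items():
            out[name] += (p * wmat[:, :, None, None]).sum(axis=(0, 1))
        out["glcm_energy"] += np.sqrt((p**2).sum(axis=(0, 1)))
    n_off = len(tuple(offsets))
    return {k: v / n_off for k, v in out.items()}


def lbp_map(image: np.ndarray, radius: int = 1) -> np.ndarray:
    """8-neighbour local binary pattern codes (neighbor >= center sets a bit).

    Neighbors are the 8 compass points at ``radius``; borders are
    edge-replicated.  A constant image codes to 255 everywhere.
    """
    image = np.asarray(image, dtype=np.float64)
    padded = np.pad(image, radius, mode="edge")
    h, w = image.shape
    offsets = [(0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1), (1, 0), (1, 1)]
    code = np.zeros((h, w), dtype=np.uint8)
    for bit, (dy, dx) in enumerate(offsets):
        nb = padded[
            radius + dy * radius : radius + dy * radius + h,
            radius + dx * radius : radius + dx * radius + w,
        ]
        code |= ((nb >= image) << bit).astype(np.uint8)
    return code


def texture_intensity_maps(
    image: np.ndarray,
    window: int = 7,
    glcm_levels: int = 8,
    glcm_offsets=((0, 1),),
    lbp_radius: int = 1,
) -> FeatureStack:
    """Sliding-window intensity statistics, GLCM features, and LBP codes.

    Channels: local mean, median, standard deviation (window x window,
    edge-replicated); GLCM contrast / homogeneity / energy; LBP code map
    scaled to [0, 1].
    """
    if window % 2 == 0:
        raise ValueError("window must be odd")
    image = np.asarray(image, dtype=np.float64)
    mean = ndimage.uniform_filter(image, window, mode="nearest")
    median = ndimage.median_filter(image, window, mode="nearest")
    sqmean = ndimage.uniform_filter(image**2, window, mode="nearest")
    sd = np.sqrt(np.maximum(sqmean - mean**2, 0.0))
    glcm = glcm_window_maps(image, window, glcm_levels, glcm_offsets)
    lbp = lbp_map(image, lbp_radius).astype(np.float64) / 255.0
    names = [
        "local_mean",
        "local_median",
        "local_sd",
        "glcm_contrast",
        "glcm_homogeneity",
        "glcm_energy",
        "lbp",
    ]
    channels = np.stack(
        [mean, median, sd, glcm["glcm_contrast"], glcm["glcm_homogeneity"],
         glcm["glcm_energy"], lbp]
    )
    prov = [
        {"descriptor": "texture", "channel": n, "window": window,
         "glcm_levels": glcm_levels, "lbp_radius": lbp_radius}
        for n in names
    ]
    return FeatureStack(channels=channels, names=names, provenance=prov)


# ---------------------------------------------------------------------------
# assembly


def dsurf_to_channels(
    descriptors, image_shape, step: int, window: int = 16
) -> FeatureStack:
    """Scatter grid descriptors to channels, nearest-neighbour upsampled.

    Each pixel takes the 64-vector of its nearest keypoint, giving 64
    piecewise-constant channels at full resolution.
    """
    if not descriptors:
        raise ValueError("unaligned features: no descriptors")
    h, w = image_shape
    xs = sorted({d.keypoint.x for d in descriptors})
    ys = sorted({d.keypoint.y for d in descriptors})
    xi = {x: i for i, x in enumerate(xs)}
    yi = {y: i for i, y in enumerate(ys)}
    grid = np.zeros((len(ys), len(xs), 64))
    for d in descriptors:
        grid[yi[d.keypoint.y], xi[d.keypoint.x]] = d.vector
    # nearest keypoint along each axis
    ix = np.argmin(np.abs(np.arange(w)[:, None] - np.asarray(xs)[None, :]), axis=1)
    iy = np.argmin(np.abs(np.arange(h)[:, None] - np.asarray(ys)[None, :]), axis=1)
    channels = grid[np.ix_(iy, ix)].transpose(2, 0, 1)
    prov = [
        {"descriptor": "dsurf", "component": i, "step": step, "window": window}
        for i in range(64)
    ]
    names = [f"dsurf_{i}" for i in range(64)]
    return FeatureStack(channels=channels, names=names, provenance=prov)


def hog_to_stack(result: HOGResult) -> FeatureStack:
    names = [f"hog_bin_{i}" for i in range(result.params.n_bins)]
    prov = [
        {"descriptor": "hog", "bin": i, "cell_size": result.params.cell_size,
         "n_bins": result.params.n_bins, "signed": result.params.signed}
        for i in range(result.params.n_bins)
    ]
    return FeatureStack(channels=result.pixel_maps, names=names, provenance=prov)


def feature_stack(image_shape, *stacks: FeatureStack) -> FeatureStack:
    """Concatenate descriptor outputs into one image-aligned stack."""
    if not stacks:
        raise ValueError("unaligned features: no descriptor outputs")
    for s in stacks:
        if s.channels.shape[1:] != tuple(image_shape):
            raise ValueError(
                f"unaligned features: {s.channels.shape[1:]} vs {tuple(image_shape)}"
            )
    return FeatureStack(
        channels=np.concatenate([s.channels for s in stacks]),
        names=[n for s in stacks for n in s.names],
        provenance=[p for s in stacks for p in s.provenance],
    )


def compute_feature_stack(
    pixels: np.ndarray,
    features=("hog",),
    source_channel: int = 3,
    hog_params: HOGParams | None = None,
    dsurf_step: int = 8,
    dsurf_window: int = 16,
    texture_window: int = 7,
) -> FeatureStack:
    """Extract the named feature groups from one multi-modal slice.

    Features are computed on a single source modality (default FLAIR,
    channel 3, where tumor regions are most conspicuous).
    """
    image = np.asarray(pixels)[source_channel]
    parts = []
    for name in features:
        if name == "hog":
            parts.append(hog_to_stack(hog_features(image, hog_params)))
        elif name == "dsurf":
            desc = dsurf_descriptors(image, step=dsurf_step, window=dsurf_window)
            parts.append(
                dsurf_to_channels(desc, image.shape, dsurf_step, dsurf_window)
            )
        elif name == "texture":
            parts.append(texture_intensity_maps(image, window=texture_window))
        else:
            raise ValueError(f"unknown feature group {name!r}")
    return feature_stack(image.shape, *parts)
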