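"""Fusion engine: low- and high-frequency rules and the end-to-end pipeline.

Two co-registered images are decomposed into a shift-invariant subband
pyramid.  The low-frequency approximations are fused by pixelwise convex
weights built from two activity measures — regional standard deviation and
a normalized local entropy of squared coefficients.  The high-frequency
directional bands are fused by binary weight maps: each band's
coefficients are first emphasized according to their statistical
dependencies (Jensen-Shannon divergences between generalized-Gaussian
models fitted on local blocks, split into a same-scale "horizontal" and an
across-scale "vertical" component), a saliency map is computed from the
emphasized coefficients by Gaussian smoothing of their magnitude, and at
every pixel the source with the larger saliency contributes its original
coefficient.

The dependency update rescales a coefficient by ``1 + h^2 + v^2`` with
``h + v in {0, 1}``, so the multiplier stays in ``[1, 2]``.  The update
feeds only the saliency comparison; the fused band selects unmodified
transform coefficients, which keeps fusion of an image with itself exactly
the identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import ndimage
from skimage.color import rgb2ycbcr, ycbcr2rgb

from .ggd_stats import DegenerateSampleError, GGDParams, fit_ggd_ml, jsd_ggd
from .nsct import SubbandPyramid, decompose, reconstruct

__all__ = [
    "FusionConfig",
    "DependencyField",
    "WeightMap",
    "GGDGrid",
    "regional_std",
    "local_entropy",
    "fuse_low",
    "fit_band_ggds",
    "fit_block_ggds",
    "horizontal_dependency",
    "vertical_dependency",
    "normalize_dependencies",
    "update_coefficients",
    "saliency_map",
    "weight_maps",
    "fuse_high",
    "fuse_images",
    "fuse_gray_color",
]

logger = logging.getLogger(__name__)

_TINY = 1e-300


@dataclass(frozen=True)
class FusionConfig:
    """All tunables of the pipeline.

    ``levels`` / ``directions``: pyramid depth and per-scale direction
    exponents, coarsest first.  ``window``: odd side of the square window
    for the low-frequency activity measures.  ``sharpness``: exponent on
    the regional standard deviation in the low-frequency weight (higher
    values sharpen the contrast competition).  ``saliency_radius`` /
    ``saliency_sigma``: the saliency filter is a normalized Gaussian of
    size ``(2 r + 1) x (2 r + 1)`` with that standard deviation.
    ``block_size``: side of the square tiles on which subband GGDs are
    fitted (auto-shrunk so each subband dimension holds at least 4 tiles).
    """

    levels: int = 4
    directions: tuple[int, ...] = (2, 2, 3, 3)
    window: int = 3
    sharpness: float = 1.2
    saliency_radius: int = 5
    saliency_sigma: float = 5.0
    block_size: int = 32
    eps: float = 1e-12
    seed: int = 0
    ties_to_first: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "directions", tuple(self.directions))
        if len(self.directions) != self.levels:
            raise ValueError(
                f"directions {self.directions} must list one exponent per "
                f"level (levels={self.levels})"
            )
        if self.window < 3 or self.window % 2 == 0:
            raise ValueError("window must be odd and >= 3")
        if self.block_size < 8:
            raise ValueError("block_size must be >= 8")


@dataclass
class DependencyField:
    """Normalized per-pixel horizontal/vertical dependency maps of one subband.

    Wherever either map is nonzero, ``jsd_h + jsd_v == 1``; both are zero
    where no dependency information exists.
    """

    jsd_h: np.ndarray
    jsd_v: np.ndarray


@dataclass
class WeightMap:
    """Binary per-pixel winner maps; ``w_a + w_b == 1`` everywhere."""

    w_a: np.ndarray
    w_b: np.ndarray


@dataclass
class GGDGrid:
    """GGD parameters fitted on non-overlapping tiles of one subband."""

    alpha: np.ndarray  # (gy, gx)
    beta: np.ndarray  # (gy, gx)
    y_bounds: np.ndarray  # (gy + 1,) tile edges in pixels
    x_bounds: np.ndarray  # (gx + 1,)
    shape: tuple[int, int]  # source subband shape

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.alpha.shape

    def params_at(self, iy: int, ix: int) -> GGDParams:
        return GGDParams(float(self.alpha[iy, ix]), float(self.beta[iy, ix]))

    def broadcast(self, tile_values: np.ndarray) -> np.ndarray:
        """Expand a (gy, gx) array of tile values to a full-size pixel map."""
        out = np.empty(self.shape, dtype=float)
        for iy in range(self.alpha.shape[0]):
            y0, y1 = self.y_bounds[iy], self.y_bounds[iy + 1]
            for ix in range(self.alpha.shape[1]):
                x0, x1 = self.x_bounds[ix], self.x_bounds[ix + 1]
                out[y0:y1, x0:x1] = tile_values[iy, ix]
        return out


# --------------------------------------------------------------------------
# low-frequency rule
# --------------------------------------------------------------------------


def regional_std(band: np.ndarray, window: int = 3) -> np.ndarray:
    """Local standard deviation over a uniform odd window, symmetric borders.

    Equals sqrt(mean(C^2) - mean(C)^2) over each window, i.e. the RMS
    deviation from the same-window local mean.
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd")
    arr = np.asarray(band, dtype=float)
    m = ndimage.uniform_filter(arr, size=window, mode="reflect")
    m2 = ndimage.uniform_filter(arr * arr, size=window, mode="reflect")
    return np.sqrt(np.maximum(m2 - m * m, 0.0))


def local_entropy(band: np.ndarray, window: int = 3, eps: float = 1e-12) -> np.ndarray:
    """Normalized Shannon entropy of squared coefficients in each window.

    Within each ``window x window`` neighbourhood the squared coefficients
    are normalized to a probability vector; the entropy is divided by
    ``log(window**2)`` so the result lies in [0, 1] (0: one dominant
    coefficient, 1: equal-magnitude coefficients).
    """
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be odd")
    arr = np.asarray(band, dtype=float)
    pad = window // 2
    padded = np.pad(arr, pad, mode="symmetric")
    windows = sliding_window_view(padded, (window, window))
    sq = windows * windows
    total = sq.sum(axis=(-1, -2)) + eps
    p = sq / total[..., None, None]
    ent = -(p * np.log(np.maximum(p, _TINY))).sum(axis=(-1, -2))
    return ent / np.log(window * window)


def fuse_low(low_a: np.ndarray, low_b: np.ndarray, cfg: FusionConfig) -> np.ndarray:
    """Fuse the approximation bands with activity-driven convex weights.

    Per pixel: ``delta = D^p / (D_A^p + D_B^p)`` from the regional standard
    deviation (``p`` = ``cfg.sharpness``) and ``xi = E / (E_A + E_B)`` from
    the local entropy; the fused coefficient is
    ``sum_s ((delta_s + xi_s) / 2) * C_s`` so the weights are convex and
    fusing identical inputs is the identity.  Where an activity denominator
    vanishes both sources get 0.5.
    """
    a = np.asarray(low_a, dtype=float)
    b = np.asarray(low_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    w = cfg.window
    p = cfg.sharpness
    da = regional_std(a, w) ** p
    db = regional_std(b, w) ** p
    ea = local_entropy(a, w, cfg.eps)
    eb = local_entropy(b, w, cfg.eps)

    d_sum = da + db
    e_sum = ea + eb
    delta_a = np.where(d_sum >= cfg.eps, da / np.maximum(d_sum, _TINY), 0.5)
    delta_b = 1.0 - delta_a
    xi_a = np.where(e_sum >= cfg.eps, ea / np.maximum(e_sum, _TINY), 0.5)
    xi_b = 1.0 - xi_a
    return 0.5 * (delta_a + xi_a) * a + 0.5 * (delta_b + xi_b) * b


# --------------------------------------------------------------------------
# block GGD fits and dependency maps
# --------------------------------------------------------------------------


def _tile_bounds(extent: int, block: int) -> np.ndarray:
    """Tile edges covering [0, extent); a short trailing tile is merged."""
    bounds = list(range(0, extent, block))
    bounds.append(extent)
    if len(bounds) > 2 and bounds[-1] - bounds[-2] < block:
        del bounds[-2]
    return np.asarray(bounds)


def effective_block_size(shape: tuple[int, int], block: int) -> int:
    """Shrink the block so each subband dimension holds at least 4 tiles."""
    b = block
    while b > 8 and min(shape) // b < 4:
        b //= 2
    return max(b, 8)


def fit_band_ggds(band: np.ndarray, block: int, eps: float = 1e-12) -> GGDGrid:
    """One ML GGD fit per non-overlapping tile of a subband.

    Tiles whose coefficients are (nearly) constant carry no distribution to
    fit and fall back to ``(alpha=eps, beta=2)``.
    """
    arr = np.asarray(band, dtype=float)
    b = effective_block_size(arr.shape, block)
    yb = _tile_bounds(arr.shape[0], b)
    xb = _tile_bounds(arr.shape[1], b)
    gy, gx = len(yb) - 1, len(xb) - 1
    alpha = np.empty((gy, gx))
    beta = np.empty((gy, gx))
    for iy in range(gy):
        for ix in range(gx):
            tile = arr[yb[iy] : yb[iy + 1], xb[ix] : xb[ix + 1]].ravel()
            if tile.std() < eps:
                alpha[iy, ix], beta[iy, ix] = eps, 2.0
                continue
            try:
                fit = fit_ggd_ml(tile)
            except DegenerateSampleError:
                fit = GGDParams(eps, 2.0)
            alpha[iy, ix], beta[iy, ix] = fit
    return GGDGrid(alpha=alpha, beta=beta, y_bounds=yb, x_bounds=xb, shape=arr.shape)


def fit_block_ggds(pyr: SubbandPyramid, block: int, eps: float = 1e-12) -> list[list[GGDGrid]]:
    """Fit tile GGDs for every directional subband of a pyramid."""
    return [[fit_band_ggds(band, block, eps) for band in scale] for scale in pyr.scales]


@lru_cache(maxsize=1 << 17)
def _jsd_cached(a1: float, b1: float, a2: float, b2: float) -> float:
    return jsd_ggd(GGDParams(a1, b1), GGDParams(a2, b2))


def _tile_jsd(g1: GGDGrid, g2: GGDGrid) -> np.ndarray:
    """Tile-wise JSD between two subbands' fitted GGD grids.

    The JSD is symmetric, so parameter pairs are canonically ordered before
    the cache lookup; identical fits short-circuit to zero.
    """
    if g1.grid_shape != g2.grid_shape:
        raise ValueError("GGD grids are not tile-aligned")
    out = np.zeros(g1.grid_shape)
    for iy in range(out.shape[0]):
        for ix in range(out.shape[1]):
            p = (float(g1.alpha[iy, ix]), float(g1.beta[iy, ix]))
            q = (float(g2.alpha[iy, ix]), float(g2.beta[iy, ix]))
            if p == q:
                continue
            if q < p:
                p, q = q, p
            out[iy, ix] = _jsd_cached(p[0], p[1], q[0], q[1])
    return out


def horizontal_dependency(scale_fits: Sequence[GGDGrid], i: int) -> np.ndarray:
    """Same-scale ("cousin") dependency of subband ``i``.

    Per tile, the sum of JSDs between subband ``i`` and every other
    directional subband of its scale, broadcast to pixel resolution.  A
    single-band scale has no cousins and yields a zero map.
    """
    grid_i = scale_fits[i]
    total = np.zeros(grid_i.grid_shape)
    for j, grid_j in enumerate(scale_fits):
        if j == i:
            continue
        total += _tile_jsd(grid_i, grid_j)
    return grid_i.broadcast(total)


def vertical_dependency(
    all_fits: Sequence[Sequence[GGDGrid]], l: int, i: int
) -> np.ndarray:
    """Across-scale (parent/child) dependency of subband ``i`` at scale ``l``.

    Per tile, the sum of JSDs against every subband at the adjacent coarser
    scale (parents, ``l - 1``) and finer scale (children, ``l + 1``).
    Tiles align across scales because all subbands share the image size.
    Missing neighbour scales contribute nothing; a single-scale pyramid
    yields a zero map.
    """
    if not 0 <= l < len(all_fits):
        raise ValueError(f"scale index {l} out of range")
    grid_i = all_fits[l][i]
    total = np.zeros(grid_i.grid_shape)
    for neighbor in (l - 1, l + 1):
        if 0 <= neighbor < len(all_fits):
            for grid_j in all_fits[neighbor]:
                total += _tile_jsd(grid_i, grid_j)
    return grid_i.broadcast(total)


def normalize_dependencies(
    h: np.ndarray, v: np.ndarray, eps: float = 1e-12
) -> DependencyField:
    """Normalize the two dependency components to sum to one.

    Where ``h + v`` is below ``eps`` both components are set to zero, so
    the subsequent coefficient update leaves those pixels unchanged.
    """
    h = np.asarray(h, dtype=float)
    v = np.asarray(v, dtype=float)
    if h.shape != v.shape:
        raise ValueError("dependency maps must share a shape")
    total = h + v
    ok = total >= eps
    safe = np.maximum(total, _TINY)
    return DependencyField(
        jsd_h=np.where(ok, h / safe, 0.0), jsd_v=np.where(ok, v / safe, 0.0)
    )


def update_coefficients(band: np.ndarray, dep: DependencyField) -> np.ndarray:
    """Emphasize coefficients by their dependency: ``C * (1 + h^2 + v^2)``.

    Since the normalized components sum to 0 or 1, the multiplier lies in
    ``[1, 2]``.
    """
    arr = np.asarray(band, dtype=float)
    if arr.shape != dep.jsd_h.shape:
        raise ValueError("band and dependency field shapes differ")
    return arr * (1.0 + dep.jsd_h**2 + dep.jsd_v**2)


# --------------------------------------------------------------------------
# high-frequency rule
# --------------------------------------------------------------------------


def _gaussian_kernel(radius: int, sigma: float) -> np.ndarray:
    ax = np.arange(-radius, radius + 1, dtype=float)
    k1 = np.exp(-(ax**2) / (2.0 * sigma**2))
    k = np.outer(k1, k1)
    return k / k.sum()


def saliency_map(band: np.ndarray, radius: int = 5, sigma: float = 5.0) -> np.ndarray:
    """Local average of coefficient magnitude under a normalized Gaussian.

    The kernel has size ``(2 * radius + 1) ** 2``; borders are
    symmetric-padded.  Nonnegative and homogeneous of degree one in the
    band amplitude.
    """
    if radius < 1:
        raise ValueError("radius must be >= 1")
    arr = np.abs(np.asarray(band, dtype=float))
    return ndimage.correlate(arr, _gaussian_kernel(radius, sigma), mode="reflect")


def weight_maps(s_a: np.ndarray, s_b: np.ndarray, ties_to_first: bool = True) -> WeightMap:
    """Binary winner maps from saliency comparison; ties go to the first image."""
    s_a = np.asarray(s_a, dtype=float)
    s_b = np.asarray(s_b, dtype=float)
    if s_a.shape != s_b.shape:
        raise ValueError("saliency maps must share a shape")
    if ties_to_first:
        w_a = (s_a >= s_b).astype(float)
    else:
        w_a = (s_a > s_b).astype(float)
    return WeightMap(w_a=w_a, w_b=1.0 - w_a)


def fuse_high(c_a: np.ndarray, c_b: np.ndarray, w: WeightMap) -> np.ndarray:
    """Weighted (here: selective) combination ``W_A * C_A + W_B * C_B``."""
    a = np.asarray(c_a, dtype=float)
    b = np.asarray(c_b, dtype=float)
    if a.shape != b.shape or a.shape != w.w_a.shape:
        raise ValueError("coefficient bands and weight maps must share a shape")
    return w.w_a * a + w.w_b * b


# --------------------------------------------------------------------------
# end-to-end pipeline
# --------------------------------------------------------------------------


def fuse_images(a: np.ndarray, b: np.ndarray, cfg: FusionConfig | None = None) -> np.ndarray:
    """Fuse two co-registered grayscale images.

    Both images are decomposed; the approximations are fused by the
    activity-weighted low-frequency rule; each pair of directional bands is
    fused by saliency comparison of dependency-emphasized coefficients;
    the fused pyramid is inverted.  Deterministic: two runs agree bitwise.
    """
    cfg = cfg or FusionConfig()
    img_a = np.asarray(a, dtype=float)
    img_b = np.asarray(b, dtype=float)
    if img_a.shape != img_b.shape:
        raise ValueError(f"shape mismatch: {img_a.shape} vs {img_b.shape}")
    if not (np.all(np.isfinite(img_a)) and np.all(np.isfinite(img_b))):
        raise ValueError("inputs contain non-finite pixels")

    logger.info("decomposing inputs (%d levels, directions %s)", cfg.levels, cfg.directions)
    pyr_a = decompose(img_a, cfg)
    pyr_b = decompose(img_b, cfg)

    logger.info("fusing low-frequency bands")
    fused_low = fuse_low(pyr_a.low, pyr_b.low, cfg)

    logger.info("fitting block GGDs (block size %d)", cfg.block_size)
    fits_a = fit_block_ggds(pyr_a, cfg.block_size, cfg.eps)
    fits_b = fit_block_ggds(pyr_b, cfg.block_size, cfg.eps)

    fused_scales: list[list[np.ndarray]] = []
    for l, (bands_a, bands_b) in enumerate(zip(pyr_a.scales, pyr_b.scales)):
        fused_bands: list[np.ndarray] = []
        for i, (band_a, band_b) in enumerate(zip(bands_a, bands_b)):
            dep_a = normalize_dependencies(
                horizontal_dependency(fits_a[l], i),
                vertical_dependency(fits_a, l, i),
                cfg.eps,
            )
            dep_b = normalize_dependencies(
                horizontal_dependency(fits_b[l], i),
                vertical_dependency(fits_b, l, i),
                cfg.eps,
            )
            sal_a = saliency_map(
                update_coefficients(band_a, dep_a), cfg.saliency_radius, cfg.saliency_sigma
            )
            sal_b = saliency_map(
                update_coefficients(band_b, dep_b), cfg.saliency_radius, cfg.saliency_sigma
            )
            w = weight_maps(sal_a, sal_b, cfg.ties_to_first)
            fused_bands.append(fuse_high(band_a, band_b, w))
        fused_scales.append(fused_bands)
        logger.info("fused scale %d (%d directions)", l, len(fused_bands))

    fused = SubbandPyramid(
        low=fused_low,
        scales=fused_scales,
        directions_per_scale=list(cfg.directions),
    )
    return reconstruct(fused)


def fuse_gray_color(
    gray: np.ndarray, color_rgb: np.ndarray, cfg: FusionConfig | None = None
) -> np.ndarray:
    """Fuse a grayscale anatomical image with an RGB functional image.

    The color image is converted to YCbCr; its luminance is fused with the
    grayscale image by :func:`fuse_images`, the chrominance channels pass
    through unchanged, and the result is converted back to RGB and clipped
    to [0, 1].
    """
    g = np.asarray(gray, dtype=float)
    c = np.asarray(color_rgb, dtype=float)
    if c.ndim != 3 or c.shape[-1] != 3:
        raise ValueError(f"color image must have 3 channels, got shape {c.shape}")
    if c.shape[:2] != g.shape:
        raise ValueError("gray and color images must share spatial dimensions")
    ycbcr = rgb2ycbcr(np.clip(c, 0.0, 1.0))
    # skimage's YCbCr luma spans [16, 235] for unit-range RGB
    luma = (ycbcr[..., 0] - 16.0) / 219.0
    fused_luma = fuse_images(g, luma, cfg)
    ycbcr[..., 0] = np.clip(fused_luma, 0.0, 1.0) * 219.0 + 16.0
    return np.clip(ycbcr2rgb(ycbcr), 0.0, 1.0)
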