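"""Shift-invariant multiscale, multidirectional image decomposition.

The decomposition mirrors the structure of the nonsubsampled contourlet
transform (NSCT): a nonsubsampled pyramid (NSP) splits the image into one
low-frequency approximation plus one detail band per level, and a
nonsubsampled directional filter bank (NSDFB) splits each detail band into
``2**l`` same-size directional subbands.  Both stages keep every band at
the input resolution, so the transform is redundant and fully
shift-invariant.

Two construction choices make the transform exactly invertible and exactly
shift-invariant under circular shifts:

* The NSP is an additive ("à trous") pyramid.  The level-``j`` lowpass is a
  separable binomial kernel with ``2**(j-1) - 1`` zeros inserted between
  taps, applied by circular (FFT) convolution; the detail band is the
  residual ``input - lowpass``, so ``low + sum(details)`` reproduces the
  input identically.
* The NSDFB is realized as frequency-domain angular wedge windows with
  raised-cosine transitions.  The ``2**l`` wedges tile the orientation
  half-circle and form an exact partition of unity, so the directional
  bands of a detail band sum back to that band.

Direction index increases counter-clockwise starting from the horizontal
frequency axis.  Scales are stored coarsest first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DecompositionError",
    "SubbandPyramid",
    "FilterBank",
    "build_filter_bank",
    "nsp_decompose",
    "nsdfb_decompose",
    "decompose",
    "reconstruct",
]

#: separable binomial lowpass, the base kernel of the à-trous pyramid
_BINOMIAL = np.array([1.0, 4.0, 6.0, 4.0, 1.0]) / 16.0


class DecompositionError(ValueError):
    """Raised when an image cannot be decomposed as requested."""


@dataclass
class SubbandPyramid:
    """One low-frequency band plus per-scale lists of directional bands.

    ``scales[0]`` is the coarsest scale; every band has the shape of the
    source image.  ``directions_per_scale[j]`` is the direction exponent
    ``l_j`` so scale ``j`` holds ``2**l_j`` bands.
    """

    low: np.ndarray
    scales: list[list[np.ndarray]]
    directions_per_scale: list[int]

    @property
    def shape(self) -> tuple[int, int]:
        return self.low.shape

    @property
    def n_high_bands(self) -> int:
        return sum(len(s) for s in self.scales)

    def validate(self) -> None:
        shape = self.low.shape
        if len(self.scales) != len(self.directions_per_scale):
            raise ValueError("scales and directions_per_scale length mismatch")
        for j, (bands, l) in enumerate(zip(self.scales, self.directions_per_scale)):
            if len(bands) != 2**l:
                raise ValueError(
                    f"scale {j}: expected {2**l} directional bands, got {len(bands)}"
                )
            for band in bands:
                if band.shape != shape:
                    raise ValueError(
                        f"scale {j}: band shape {band.shape} != low shape {shape}"
                    )


@dataclass
class FilterBank:
    """Frequency-domain filters of the decomposition for a fixed image shape.

    ``lowpass[j]`` is the full-grid frequency response of the pyramid
    lowpass at level ``j+1``; ``wedges[j]`` the list of angular wedge masks
    used at scale ``j`` (coarsest first).
    """

    shape: tuple[int, int]
    lowpass: list[np.ndarray]
    wedges: list[list[np.ndarray]] = field(default_factory=list)

    def partition_residual(self) -> float:
        """Worst deviation from the per-level partition of unity.

        At each level the lowpass response plus the highpass response split
        across that level's wedges must reproduce the identity:
        ``L_j + (1 - L_j) * sum(wedges) == 1`` at every frequency sample.
        """
        worst = 0.0
        for j, L in enumerate(self.lowpass):
            wsum = (
                np.sum(self.wedges[j], axis=0)
                if j < len(self.wedges) and self.wedges[j]
                else np.ones_like(L)
            )
            total = L + (1.0 - L) * wsum
            worst = max(worst, float(np.abs(total - 1.0).max()))
        return worst


def _as_image(image: np.ndarray) -> np.ndarray:
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise DecompositionError(f"expected a 2-D image, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise DecompositionError("image contains non-finite values")
    return arr


def _lowpass_response(shape: tuple[int, int], level: int) -> np.ndarray:
    """Full-FFT-grid response of the level-`level` à-trous binomial lowpass."""
    dilation = 2 ** (level - 1)
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]

    def h1d(f: np.ndarray) -> np.ndarray:
        # DTFT of the centered symmetric kernel [1,4,6,4,1]/16
        w = 2.0 * np.pi * f * dilation
        return (6.0 + 8.0 * np.cos(w) + 2.0 * np.cos(2.0 * w)) / 16.0

    return h1d(fy) * h1d(fx)


def _wedge_masks(shape: tuple[int, int], l: int) -> list[np.ndarray]:
    """Angular wedge windows forming a partition of unity over 2**l sectors.

    Orientation is taken modulo pi so each mask is symmetric under frequency
    negation and directional bands of real images stay real.  Adjacent
    wedges overlap over a raised-cosine transition of half-width a quarter
    sector, where the two windows sum exactly to one.
    """
    if l == 0:
        return [np.ones(shape)]
    n = 2**l
    fy = np.fft.fftfreq(shape[0])[:, None]
    fx = np.fft.fftfreq(shape[1])[None, :]
    theta = np.mod(np.arctan2(fy, fx), np.pi)
    delta = np.pi / n
    t = delta / 4.0  # transition half-width
    masks = []
    for i in range(n):
        center = (i + 0.5) * delta
        # signed angular distance to the sector center, periodic over pi
        d = np.abs(((theta - center + np.pi / 2.0) % np.pi) - np.pi / 2.0)
        m = np.zeros(shape)
        m[d <= delta / 2.0 - t] = 1.0
        ramp = (d > delta / 2.0 - t) & (d < delta / 2.0 + t)
        m[ramp] = 0.5 * (1.0 + np.cos(np.pi * (d[ramp] - (delta / 2.0 - t)) / (2.0 * t)))
        masks.append(m)
    return masks


def build_filter_bank(
    shape: tuple[int, int], levels: int, directions: Sequence[int]
) -> FilterBank:
    """Precompute the frequency-domain filters for a given image shape."""
    if len(directions) != levels:
        raise ValueError("directions must list one exponent per level")
    lowpass = [_lowpass_response(shape, j + 1) for j in range(levels)]
    # directions are given coarsest first, but NSP level 1 is the finest
    wedges = [_wedge_masks(shape, l) for l in directions]
    return FilterBank(shape=tuple(shape), lowpass=lowpass, wedges=wedges)


def nsp_decompose(image: np.ndarray, k: int) -> tuple[np.ndarray, list[np.ndarray]]:
    """Additive pyramid: one lowpass band plus ``k`` detail bands.

    Returns ``(low, highs)`` with ``highs[0]`` the finest level.  The
    decomposition is additive: ``low + sum(highs)`` equals the input to
    machine precision.
    """
    img = _as_image(image)
    if k < 1:
        raise DecompositionError("level count k must be >= 1")
    min_size = 2**k
    if min(img.shape) < min_size:
        raise DecompositionError(
            f"image of shape {img.shape} is too small for {k} levels; "
            f"each dimension must be at least {min_size} pixels"
        )
    spectrum = np.fft.fft2(img)
    highs: list[np.ndarray] = []
    current = spectrum
    for level in range(1, k + 1):
        response = _lowpass_response(img.shape, level)
        low_spec = current * response
        highs.append(np.fft.ifft2(current - low_spec).real)
        current = low_spec
    low = np.fft.ifft2(current).real
    return low, highs


def nsdfb_decompose(band: np.ndarray, l: int) -> list[np.ndarray]:
    """Split a band into ``2**l`` same-size directional subbands.

    The wedge windows tile orientation space and sum to one, so the
    returned bands sum back to the input.  ``l == 0`` returns the band
    unchanged in a singleton list.
    """
    arr = _as_image(band)
    if l < 0:
        raise DecompositionError("direction exponent l must be >= 0")
    if l == 0:
        return [arr.copy()]
    spectrum = np.fft.fft2(arr)
    return [np.fft.ifft2(spectrum * m).real for m in _wedge_masks(arr.shape, l)]


def decompose(image: np.ndarray, cfg) -> SubbandPyramid:
    """Full decomposition: pyramid stage, then a directional split per scale.

    ``cfg`` needs ``levels`` and ``directions`` (coarsest scale first, as in
    the default ``(2, 2, 3, 3)``: 4 + 4 + 8 + 8 = 24 directional bands).
    """
    levels = cfg.levels
    directions = list(cfg.directions)
    if len(directions) != levels:
        raise DecompositionError("config: len(directions) must equal levels")
    low, highs = nsp_decompose(image, levels)
    # highs are finest-first; store scales coarsest-first to match directions
    scales = [
        nsdfb_decompose(band, l)
        for band, l in zip(reversed(highs), directions)
    ]
    pyr = SubbandPyramid(low=low, scales=scales, directions_per_scale=directions)
    pyr.validate()
    return pyr


def reconstruct(pyr: SubbandPyramid) -> np.ndarray:
    """Invert :func:`decompose` by additive synthesis.

    Because both stages are additive with partition-of-unity filters, the
    inverse is the plain sum of the low band and every directional band.
    """
    pyr.validate()
    out = pyr.low.copy()
    for bands in pyr.scales:
        for band in bands:
            out += band
    return out
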