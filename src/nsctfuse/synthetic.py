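"""Synthetic phantom generators for exercising every fusion stage.

Real multimodal pairs (CT/MRI, MRI/PET, MRI/SPECT) are clinical data; the
generators here produce co-registered pairs with the same *complementary*
structure: a "CT-like" image of high-contrast piecewise-constant anatomy
(bright outer ring, dense blobs) and an "MRI-like" image of smooth tissue
gradients carrying fine oriented texture.  Named binary masks record which
structures exist in only one modality, which is what feature-preservation
checks need.  A companion generator produces a smooth pseudo-colored
functional image for the grayscale + color fusion path.

All generators are pure functions of their arguments; the same seed yields
bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ggd_stats import GGDParams, sample_ggd

__all__ = ["PhantomPair", "make_phantom_pair", "make_functional_phantom", "make_ggd_band"]

#: additive Gaussian pixel noise applied to both phantoms
_NOISE_SIGMA = 0.01


@dataclass
class PhantomPair:
    """Two co-registered phantoms plus masks of modality-exclusive features.

    ``masks["ring"]`` marks the bright ring present only in ``a``;
    ``masks["texture"]`` the oriented texture patch present only in ``b``.
    """

    a: np.ndarray
    b: np.ndarray
    masks: dict[str, np.ndarray]


def _square_size(size) -> tuple[int, int]:
    if np.isscalar(size):
        return int(size), int(size)
    h, w = size
    return int(h), int(w)


def make_phantom_pair(size=256, seed: int = 0) -> PhantomPair:
    """Generate a complementary "CT-like" / "MRI-like" phantom pair.

    The CT-like image ``a`` holds a bright outer ring (absent from ``b``)
    and high-contrast piecewise-constant blobs; the MRI-like image ``b``
    holds smooth intensity gradients plus a fine 30-degree sinusoidal
    texture disk (absent from ``a``).  Both get additive Gaussian noise of
    standard deviation 0.01 and are clipped to [0, 1].
    """
    h, w = _square_size(size)
    if min(h, w) < 64:
        raise ValueError("phantom size must be at least 64x64")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx) / (min(h, w) / 2.0)

    # CT-like: dark background, bright skull-like ring, dense blobs
    a = np.full((h, w), 0.05)
    ring = (r >= 0.80) & (r <= 0.92)
    a[ring] = 0.95
    rect = (
        (yy >= 0.28 * h) & (yy <= 0.44 * h) & (xx >= 0.22 * w) & (xx <= 0.42 * w)
    )
    a[rect] = 0.65
    blob = np.hypot(yy - 0.66 * h, xx - 0.36 * w) <= 0.09 * min(h, w)
    a[blob] = 0.80

    # MRI-like: smooth tissue gradients inside the head outline
    b = 0.25 + 0.30 * np.sin(np.pi * xx / w) * np.sin(np.pi * yy / h)
    b += 0.10 * np.cos(2.0 * np.pi * r)
    # fine oriented texture patch, placed away from a's blobs
    tex = np.hypot(yy - 0.45 * h, xx - 0.68 * w) <= 0.14 * min(h, w)
    phase = (xx * np.cos(np.pi / 6.0) + yy * np.sin(np.pi / 6.0)) / 3.0
    b = np.where(tex, b + 0.22 * np.sin(2.0 * np.pi * phase), b)

    a = np.clip(a + rng.normal(0.0, _NOISE_SIGMA, (h, w)), 0.0, 1.0)
    b = np.clip(b + rng.normal(0.0, _NOISE_SIGMA, (h, w)), 0.0, 1.0)
    return PhantomPair(a=a, b=b, masks={"ring": ring, "texture": tex})


def _hot_palette(activity: np.ndarray) -> np.ndarray:
    """Map [0, 1] activity through a hot-metal (black-red-yellow-white) ramp."""
    rgb = np.empty(activity.shape + (3,))
    rgb[..., 0] = np.clip(3.0 * activity, 0.0, 1.0)
    rgb[..., 1] = np.clip(3.0 * activity - 1.0, 0.0, 1.0)
    rgb[..., 2] = np.clip(3.0 * activity - 2.0, 0.0, 1.0)
    return rgb


def make_functional_phantom(size=256, seed: int = 0) -> np.ndarray:
    """Smooth pseudo-colored activity map co-registered to the phantom pair.

    Emulates the low spatial resolution of functional (PET/SPECT-like)
    data: a handful of broad Gaussian activity blobs inside the head
    outline, rendered through a hot-metal palette.  Channel values lie in
    [0, 1] and the luminance varies much more slowly than the structural
    phantom's texture.
    """
    h, w = _square_size(size)
    if min(h, w) < 64:
        raise ValueError("phantom size must be at least 64x64")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    activity = np.zeros((h, w))
    # broad blobs with deterministic jitter from the seed
    centers = np.array([[0.38, 0.35], [0.55, 0.65], [0.68, 0.42]])
    centers = centers + rng.uniform(-0.03, 0.03, centers.shape)
    widths = np.array([0.16, 0.12, 0.10]) * min(h, w)
    amps = np.array([0.9, 0.7, 0.8])
    for (fy, fx), s, amp in zip(centers, widths, amps):
        d2 = (yy - fy * h) ** 2 + (xx - fx * w) ** 2
        activity += amp * np.exp(-d2 / (2.0 * s**2))
    activity = np.clip(activity / activity.max(), 0.0, 1.0)
    return _hot_palette(activity)


def make_ggd_band(size, params: GGDParams, seed: int = 0) -> np.ndarray:
    """An i.i.d. generalized-Gaussian coefficient field.

    Reproduces the sparse, heavy-tailed statistics of directional subband
    coefficients (shape below 2 gives kurtosis well above the Gaussian 3).
    """
    h, w = _square_size(size)
    return sample_ggd(params, h * w, seed).reshape(h, w)
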