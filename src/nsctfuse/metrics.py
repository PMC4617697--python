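"""Fusion quality metrics: MI, EN, SF and the gradient-based Q^AB/F.

All histogram-based metrics quantize images to 256 gray levels by min-max
scaling and use base-2 logarithms, so the entropy of an 8-bit image is
bounded by 8 bits.  ``Q^AB/F`` is the Xydeas-Petrovic edge-preservation
score: Sobel gradient strength and orientation are compared between each
source and the fused image through sigmoid preservation curves, and the
per-source scores are averaged with gradient-strength weights.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import ndimage

__all__ = [
    "MetricsReport",
    "QabfConstants",
    "entropy_metric",
    "mutual_information_metric",
    "spatial_frequency",
    "q_abf",
    "evaluate_fusion",
]

_N_LEVELS = 256


@dataclass(frozen=True)
class QabfConstants:
    """Sigmoid constants of the edge-preservation score (standard values)."""

    gamma_g: float = 0.9994
    kappa_g: float = -15.0
    sigma_g: float = 0.5
    gamma_a: float = 0.9879
    kappa_a: float = -22.0
    sigma_a: float = 0.8


@dataclass
class MetricsReport:
    """Scores of one fusion result against its two sources."""

    mi: float
    en: float
    sf: float
    q_abf: float
    uid: None = None  # not implemented; reported as null

    def as_dict(self) -> dict:
        return asdict(self)


def _quantize(img: np.ndarray) -> np.ndarray:
    """Min-max scale to the integer range [0, 255]."""
    arr = np.asarray(img, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi - lo <= 0.0:
        return np.zeros(arr.shape, dtype=np.intp)
    scaled = (arr - lo) / (hi - lo) * (_N_LEVELS - 1)
    return np.rint(scaled).astype(np.intp)


def entropy_metric(f: np.ndarray) -> float:
    """Shannon entropy (bits) of the 256-bin gray-level histogram."""
    q = _quantize(f)
    counts = np.bincount(q.ravel(), minlength=_N_LEVELS)
    p = counts / counts.sum()
    p = p[p > 0]
    return float(-np.sum(p * np.log2(p)))


def _mi_pair(x: np.ndarray, y: np.ndarray) -> float:
    joint = np.zeros((_N_LEVELS, _N_LEVELS))
    np.add.at(joint, (x.ravel(), y.ravel()), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    outer = px[:, None] * py[None, :]
    return float(np.sum(joint[nz] * np.log2(joint[nz] / outer[nz])))


def mutual_information_metric(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> float:
    """Summed mutual information MI(A, F) + MI(B, F), in bits."""
    if not (np.shape(a) == np.shape(b) == np.shape(f)):
        raise ValueError("all images must share a shape")
    qa, qb, qf = _quantize(a), _quantize(b), _quantize(f)
    return _mi_pair(qa, qf) + _mi_pair(qb, qf)


def spatial_frequency(f: np.ndarray) -> float:
    """RMS of first differences: sqrt(RF^2 + CF^2).

    ``RF`` is the row (horizontal-difference) frequency, ``CF`` the column
    frequency.  On the usual convention the image is scaled to [0, 255]
    first, so values are comparable across bit depths.
    """
    arr = np.asarray(f, dtype=float)
    if arr.ndim != 2 or min(arr.shape) < 2:
        raise ValueError("need a 2-D image with at least 2 pixels per side")
    arr = _quantize(arr).astype(float)
    rf = np.sqrt(np.mean(np.diff(arr, axis=1) ** 2))
    cf = np.sqrt(np.mean(np.diff(arr, axis=0) ** 2))
    return float(np.hypot(rf, cf))


def _gradients(img: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    sx = ndimage.sobel(img, axis=1, mode="reflect")
    sy = ndimage.sobel(img, axis=0, mode="reflect")
    return np.hypot(sx, sy), np.arctan2(sy, sx)


def _edge_preservation(
    g_src: np.ndarray,
    a_src: np.ndarray,
    g_fus: np.ndarray,
    a_fus: np.ndarray,
    k: QabfConstants,
) -> np.ndarray:
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(
            g_src > g_fus,
            np.divide(g_fus, g_src, out=np.zeros_like(g_fus), where=g_src > 0),
            np.divide(g_src, g_fus, out=np.zeros_like(g_src), where=g_fus > 0),
        )
    ratio = np.where((g_src == 0) & (g_fus == 0), 1.0, ratio)
    # edge orientation is modulo pi; fold the difference into [0, pi/2]
    diff = np.abs(a_src - a_fus) % np.pi
    diff = np.minimum(diff, np.pi - diff)
    orient = 1.0 - diff / (np.pi / 2.0)
    q_g = k.gamma_g / (1.0 + np.exp(k.kappa_g * (ratio - k.sigma_g)))
    q_a = k.gamma_a / (1.0 + np.exp(k.kappa_a * (orient - k.sigma_a)))
    return q_g * q_a


def q_abf(
    a: np.ndarray,
    b: np.ndarray,
    f: np.ndarray,
    constants: QabfConstants | None = None,
) -> float:
    """Edge-transfer score in [0, 1]; 1 would be lossless edge preservation.

    Note the sigmoid curves cap the attainable score slightly below one:
    even ``q_abf(A, A, A)`` evaluates to about 0.975 with the standard
    constants.
    """
    if not (np.shape(a) == np.shape(b) == np.shape(f)):
        raise ValueError("all images must share a shape")
    k = constants or QabfConstants()
    ga, aa = _gradients(np.asarray(a, dtype=float))
    gb, ab = _gradients(np.asarray(b, dtype=float))
    gf, af = _gradients(np.asarray(f, dtype=float))
    q_af = _edge_preservation(ga, aa, gf, af, k)
    q_bf = _edge_preservation(gb, ab, gf, af, k)
    denom = float(np.sum(ga + gb))
    if denom <= 0.0:
        return 0.0
    return float(np.sum(q_af * ga + q_bf * gb) / denom)


def evaluate_fusion(a: np.ndarray, b: np.ndarray, f: np.ndarray) -> MetricsReport:
    """Compute the full metric report for a fused image and its sources."""
    return MetricsReport(
        mi=mutual_information_metric(a, b, f),
        en=entropy_metric(f),
        sf=spatial_frequency(f),
        q_abf=q_abf(a, b, f),
    )
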