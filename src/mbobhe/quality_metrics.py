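"""Raw image-quality metrics comparing an input image with its enhanced output.

The three metrics the Beta scoring layer consumes are

* RBD — relative brightness difference, ``exp(-|mu_y - mu_x| / (mu_x + c))``;
  1 when the mean brightness is perfectly preserved, decaying towards 0 as
  the brightness error grows.
* RCD — relative contrast difference, ``1 - exp(-|sigma_y - sigma_x| /
  (sigma_x + c))``; 0 at no contrast change, saturating towards 1.
* ASD — average structural difference: the fraction of pixels that keep
  their side-of-mean relation, i.e. whose ``(x - mu_x)(y - mu_y) >= 0``;
  1 when the bright/dark structure relative to the mean is fully preserved.

plus AMBE (``|mu_y - mu_x|``) and Shannon entropy of a histogram, used when
benchmarking the equalization family.  All statistics are taken on the
normalized ``[0, 1]`` intensity view with the population (1/MN) variance, so
the stability constant ``c`` is scale-free.

Functions accept either a :class:`~mbobhe.image_io.GrayImage` or an
already-normalized float array.  For ``GrayImage`` inputs the moments are
accumulated as exact integer sums of ``v`` and ``v**2`` before the single
final division, so any two code paths that see the same pixels (in any
order, or summarized through a histogram) produce bit-identical values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hist_core import Histogram
from .image_io import GrayImage

__all__ = [
    "MetricConfig",
    "mean_brightness",
    "nrms_contrast",
    "rbd",
    "rcd",
    "asd",
    "ambe",
    "entropy",
]


@dataclass(frozen=True)
class MetricConfig:
    """Metric tuning knobs.

    c : stability constant added to the denominator of RBD/RCD so a black
        (``mu_x = 0``) or constant (``sigma_x = 0``) input stays finite;
        lives on the normalized intensity scale.
    signed_rbd : use the raw signed exponent ``exp((mu_y - mu_x)/(mu_x + c))``
        instead of the bounded absolute-value form.  Unbounded above; kept
        for comparison only.
    """

    c: float = 1e-6
    signed_rbd: bool = False

    def __post_init__(self) -> None:
        if self.c <= 0:
            raise ValueError("c must be > 0")


def _as_norm(img) -> np.ndarray:
    if isinstance(img, GrayImage):
        return img.pixels / (img.levels - 1)
    return np.asarray(img, dtype=np.float64)


def mean_brightness(img) -> float:
    """Mean normalized intensity, in [0, 1]."""
    if isinstance(img, GrayImage):
        s1 = int(img.pixels.sum(dtype=np.int64))
        return s1 / (img.size * (img.levels - 1))
    arr = _as_norm(img)
    return float(arr.sum() / arr.size)


def nrms_contrast(img) -> float:
    """Population standard deviation of normalized intensity (NRMS contrast).

    Bounded by 0.5, attained by a half-black/half-white image.
    """
    if isinstance(img, GrayImage):
        d = img.levels - 1
        s1 = int(img.pixels.sum(dtype=np.int64))
        s2 = int((img.pixels * img.pixels).sum(dtype=np.int64))
        mu = s1 / (img.size * d)
        var = s2 / (img.size * d * d) - mu * mu
        return float(np.sqrt(max(var, 0.0)))
    arr = _as_norm(img)
    mu = arr.sum() / arr.size
    var = (arr * arr).sum() / arr.size - mu * mu
    return float(np.sqrt(max(var, 0.0)))


def _check_pair(x, y) -> None:
    sx = x.shape if isinstance(x, GrayImage) else np.asarray(x).shape
    sy = y.shape if isinstance(y, GrayImage) else np.asarray(y).shape
    if sx != sy:
        raise ValueError(f"image shapes differ: {sx} vs {sy}")


def rbd(x, y, cfg: MetricConfig = MetricConfig()) -> float:
    """Relative brightness difference; 1 iff means are equal."""
    _check_pair(x, y)
    mu_x = mean_brightness(x)
    mu_y = mean_brightness(y)
    if cfg.signed_rbd:
        return float(np.exp((mu_y - mu_x) / (mu_x + cfg.c)))
    return float(np.exp(-abs(mu_y - mu_x) / (mu_x + cfg.c)))


def rcd(x, y, cfg: MetricConfig = MetricConfig()) -> float:
    """Relative contrast difference; 0 iff NRMS contrasts are equal."""
    _check_pair(x, y)
    s_x = nrms_contrast(x)
    s_y = nrms_contrast(y)
    return float(1.0 - np.exp(-abs(s_y - s_x) / (s_x + cfg.c)))


def asd(x, y) -> float:
    """Average structural difference: fraction of pixels preserving their
    side-of-mean sign relation ``(x - mu_x)(y - mu_y) >= 0``."""
    _check_pair(x, y)
    mu_x = mean_brightness(x)
    mu_y = mean_brightness(y)
    xn = _as_norm(x)
    yn = _as_norm(y)
    d = (xn - mu_x) * (yn - mu_y)
    return float(np.count_nonzero(d >= 0) / d.size)


def ambe(x, y) -> float:
    """Absolute mean brightness error ``|mu_y - mu_x|`` (normalized scale)."""
    _check_pair(x, y)
    return abs(mean_brightness(y) - mean_brightness(x))


def entropy(hist: Histogram) -> float:
    """Shannon entropy of the gray-level distribution, in bits."""
    if hist.total <= 0:
        raise ValueError("histogram is empty")
    p = hist.counts[hist.counts > 0] / hist.total
    return float(-(p * np.log2(p)).sum())
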