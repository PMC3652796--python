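"""Deterministic generators of radiograph-like and degenerate test images.

Hand radiographs around ossification sites are characteristically
low-contrast and narrow in dynamic range: a smooth background luminance
gradient, brighter elliptical bone structures, and thin high-intensity edge
lines (the thickened white lines at epiphyseal borders).  :func:`make_phantom`
emulates exactly these features; :func:`make_ramp` and :func:`make_bimodal`
provide analytically transparent histograms for exercising the split rules.

All generators are pure functions of their spec: randomness comes from
``numpy.random.default_rng`` (the PCG64 generator) seeded from the spec, so
a fixed spec yields a bit-identical image on every call and platform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .image_io import GrayImage

logger = logging.getLogger(__name__)

__all__ = ["PhantomSpec", "make_phantom", "make_ramp", "make_bimodal"]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for a hand-radiograph-like phantom.

    Defaults describe the regime the enhancement targets: a narrow
    ([90, 140] of 256 levels) background sweep, a few bright "bones" about
    30 levels above their local background with +40-level rims, and mild
    sensor noise.
    """

    seed: int = 0
    size: tuple[int, int] = (128, 128)
    background: tuple[int, int] = (90, 140)
    bones: int = 4
    edge_gain: int = 40
    noise_sigma: float = 2.0
    levels: int = 256

    def __post_init__(self) -> None:
        low, high = self.background
        if not (0 <= low <= high <= self.levels - 1):
            raise ValueError(f"background range ({low}, {high}) invalid for L={self.levels}")
        if self.bones < 0 or self.noise_sigma < 0:
            raise ValueError("bones and noise_sigma must be non-negative")


_BONE_LIFT = 30  # interior brightness above local background, in gray levels


def make_phantom(spec: PhantomSpec) -> GrayImage:
    """Render the phantom described by ``spec``.

    A left-to-right linear gradient from ``background[0]`` to
    ``background[1]``; ``spec.bones`` filled ellipses (interiors +30 levels)
    with 1–2 px elliptical rims at ``+edge_gain``; additive seeded Gaussian
    noise; everything clipped into ``[0, L-1]``.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.size
    low, high = spec.background
    cols = np.linspace(low, high, n)
    img = np.tile(cols, (m, 1)).astype(np.float64)

    rr, cc = np.mgrid[0:m, 0:n]
    interior = np.zeros((m, n), dtype=bool)
    rim = np.zeros((m, n), dtype=bool)
    for _ in range(spec.bones):
        cy = rng.uniform(0.15 * m, 0.85 * m)
        cx = rng.uniform(0.15 * n, 0.85 * n)
        ry = rng.uniform(0.06 * m, 0.16 * m)
        rx = rng.uniform(0.06 * n, 0.16 * n)
        if cy - ry < 0 or cy + ry > m or cx - rx < 0 or cx + rx > n:
            logger.info("phantom ellipse clipped at the border")
        # normalized elliptical distance: 1 on the ellipse boundary
        dist = np.sqrt(((rr - cy) / ry) ** 2 + ((cc - cx) / rx) ** 2)
        interior |= dist <= 1.0
        rim_width = 1.5 / min(rx, ry)  # ~1-2 px band outside the boundary
        rim |= (dist > 1.0) & (dist <= 1.0 + rim_width)
    # overlapping structures do not stack: each pixel gets one lift at most
    rim &= ~interior
    img[interior] += _BONE_LIFT
    img[rim] += spec.edge_gain

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)

    img = np.clip(np.floor(img + 0.5), 0, spec.levels - 1).astype(np.int64)
    return GrayImage(img, spec.levels)


def make_ramp(m: int, n: int, levels: int = 256) -> GrayImage:
    """Row-major ramp cycling 0..L-1: as uniform a histogram as M*N allows."""
    vals = np.arange(m * n, dtype=np.int64) % levels
    return GrayImage(vals.reshape(m, n), levels)


def make_bimodal(
    m: int,
    n: int,
    lo_level: int,
    hi_level: int,
    fraction_lo: float,
    seed: int = 0,
    levels: int = 256,
) -> GrayImage:
    """Two-level image: exactly ``round(fraction_lo * M * N)`` pixels at
    ``lo_level``, the rest at ``hi_level``, in a seeded random arrangement."""
    if not (lo_level < hi_level):
        raise ValueError("lo_level must be < hi_level")
    if not (0.0 < fraction_lo < 1.0):
        raise ValueError("fraction_lo must be in (0, 1)")
    total = m * n
    n_lo = int(np.floor(fraction_lo * total + 0.5))
    flat = np.full(total, hi_level, dtype=np.int64)
    rng = np.random.default_rng(seed)
    flat[rng.permutation(total)[:n_lo]] = lo_level
    return GrayImage(flat.reshape(m, n), levels)
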