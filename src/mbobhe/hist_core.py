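"""Histogram/CDF computation and range-restricted histogram equalization.

Every histogram-equalization variant in this package is assembled from the
same primitive: equalize a closed level range ``[lo, hi]`` against the
cumulative distribution of the histogram mass inside that range, so a level
is never mapped outside its own segment.

Quantization uses round-half-up on the affine-scaled CDF.  Segments holding
zero or one occupied level map identity — this makes constant images a fixed
point of every method instead of saturating them to white.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image_io import GrayImage

__all__ = [
    "Histogram",
    "LutFragment",
    "TransformLUT",
    "compute_histogram",
    "segment_cdf",
    "equalize_segment",
    "assemble_lut",
    "apply_lut",
]


@dataclass(frozen=True)
class Histogram:
    """Per-level pixel counts over ``levels`` gray levels."""

    counts: np.ndarray = field(repr=False)
    total: int = 0

    def __post_init__(self) -> None:
        counts = np.ascontiguousarray(self.counts, dtype=np.int64)
        if counts.ndim != 1 or len(counts) < 2:
            raise ValueError("counts must be 1-D with length >= 2")
        if counts.min() < 0:
            raise ValueError("counts must be non-negative")
        if int(counts.sum()) != self.total:
            raise ValueError(f"sum(counts)={int(counts.sum())} != total={self.total}")
        object.__setattr__(self, "counts", counts)

    @property
    def levels(self) -> int:
        return len(self.counts)


@dataclass(frozen=True)
class LutFragment:
    """The mapping of one closed segment ``[lo, hi]`` of the level range."""

    lo: int
    hi: int
    mapping: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        mapping = np.ascontiguousarray(self.mapping, dtype=np.int64)
        if self.lo > self.hi or self.lo < 0:
            raise ValueError(f"invalid segment [{self.lo}, {self.hi}]")
        if len(mapping) != self.hi - self.lo + 1:
            raise ValueError("mapping length must equal segment width")
        if mapping.min() < self.lo or mapping.max() > self.hi:
            raise ValueError("mapping escapes its segment")
        if np.any(np.diff(mapping) < 0):
            raise ValueError("mapping must be non-decreasing")
        object.__setattr__(self, "mapping", mapping)


@dataclass(frozen=True)
class TransformLUT:
    """A full length-``L`` level→level mapping plus the segments it came from."""

    mapping: np.ndarray = field(repr=False)
    segments: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "mapping", np.ascontiguousarray(self.mapping, dtype=np.int64)
        )

    @property
    def levels(self) -> int:
        return len(self.mapping)


def compute_histogram(img: GrayImage) -> Histogram:
    counts = np.bincount(img.pixels.ravel(), minlength=img.levels)
    return Histogram(counts, img.size)


def segment_cdf(hist: Histogram, lo: int, hi: int) -> np.ndarray | None:
    """Cumulative distribution of the mass inside ``[lo, hi]``.

    Returns ``None`` for an empty segment (the degenerate marker; consumers
    map identity).  ``cdf[hi - lo] == 1`` exactly for non-empty segments.
    """
    if not (0 <= lo <= hi <= hist.levels - 1):
        raise ValueError(f"segment [{lo}, {hi}] outside [0, {hist.levels - 1}]")
    seg = hist.counts[lo : hi + 1]
    mass = int(seg.sum())
    if mass == 0:
        return None
    return np.cumsum(seg) / mass


def equalize_segment(
    hist: Histogram, lo: int, hi: int, *, cdf_min_shift: bool = False
) -> LutFragment:
    """Equalize the sub-histogram on ``[lo, hi]`` into a LUT fragment.

    ``mapping[k] = lo + round_half_up((hi - lo) * cdf[k])``.  With
    ``cdf_min_shift=True`` the alternative dialect
    ``(cdf - cdf_min) / (1 - cdf_min)`` is used instead of the plain CDF.
    Segments with at most one occupied level map identity.
    """
    cdf = segment_cdf(hist, lo, hi)
    width = hi - lo + 1
    identity = np.arange(lo, hi + 1, dtype=np.int64)
    if cdf is None:
        return LutFragment(lo, hi, identity)
    occupied = int(np.count_nonzero(hist.counts[lo : hi + 1]))
    if occupied <= 1:
        return LutFragment(lo, hi, identity)
    if cdf_min_shift:
        cdf_min = cdf[np.argmax(hist.counts[lo : hi + 1] > 0)]
        if cdf_min < 1.0:
            cdf = (cdf - cdf_min) / (1.0 - cdf_min)
    mapping = lo + np.floor((width - 1) * cdf + 0.5).astype(np.int64)
    np.clip(mapping, lo, hi, out=mapping)
    return LutFragment(lo, hi, mapping)


def assemble_lut(fragments: list[LutFragment]) -> TransformLUT:
    """Concatenate fragments whose segments partition ``[0, L-1]``."""
    if not fragments:
        raise ValueError("no fragments")
    frags = sorted(fragments, key=lambda f: f.lo)
    expect = 0
    for f in frags:
        if f.lo != expect:
            raise ValueError(
                f"fragments do not partition the range: gap/overlap at level {expect} "
                f"(next fragment starts at {f.lo})"
            )
        expect = f.hi + 1
    mapping = np.concatenate([f.mapping for f in frags])
    return TransformLUT(mapping, tuple((f.lo, f.hi) for f in frags))


def apply_lut(img: GrayImage, lut: TransformLUT) -> GrayImage:
    if lut.levels != img.levels:
        raise ValueError(f"LUT length {lut.levels} != image levels {img.levels}")
    return GrayImage(lut.mapping[img.pixels], img.levels)
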