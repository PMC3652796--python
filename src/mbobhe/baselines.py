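"""The classical histogram-equalization family used for comparison.

* GHE   — global HE over the full level range.
* BBHE  — bi-HE split at the image mean; each half equalized in place.
* DSIHE — bi-HE split at the image median.
* MMBEBHE — bi-HE whose split is chosen by exhaustive search to minimize
  AMBE, the absolute mean brightness error.
* RMSHE / RSIHE — recursive mean-/median-split HE giving up to 2**r
  segments at depth r; r=1 reduces to BBHE/DSIHE and r=0 to GHE.

The split level always belongs to the lower segment: a split at ``x_s``
induces the closed segments ``[0, x_s]`` and ``[x_s + 1, L - 1]``.  Ties in
MMBEBHE break toward the smallest candidate level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hist_core import (
    Histogram,
    TransformLUT,
    apply_lut,
    assemble_lut,
    compute_histogram,
    equalize_segment,
)
from .image_io import GrayImage

__all__ = [
    "SplitSpec",
    "ghe",
    "bbhe",
    "dsihe",
    "mmbebhe",
    "rmshe",
    "rsihe",
    "mean_split_level",
    "median_split_level",
    "recursive_split",
    "bi_he_lut",
    "METHODS",
]


@dataclass(frozen=True)
class SplitSpec:
    """Ordered separating levels and the closed segments they induce."""

    points: tuple[int, ...]
    levels: int

    def __post_init__(self) -> None:
        pts = tuple(int(p) for p in self.points)
        if list(pts) != sorted(set(pts)):
            raise ValueError("points must be strictly increasing")
        if pts and not (0 <= pts[0] and pts[-1] <= self.levels - 2):
            raise ValueError(f"points must lie in [0, {self.levels - 2}]")
        object.__setattr__(self, "points", pts)

    @property
    def segments(self) -> tuple[tuple[int, int], ...]:
        bounds = (0,) + tuple(p + 1 for p in self.points)
        highs = tuple(self.points) + (self.levels - 1,)
        return tuple(zip(bounds, highs))


def _equalize_segments(img: GrayImage, segments, *, cdf_min_shift: bool = False) -> TransformLUT:
    hist = compute_histogram(img)
    frags = [
        equalize_segment(hist, lo, hi, cdf_min_shift=cdf_min_shift)
        for lo, hi in segments
    ]
    return assemble_lut(frags)


def mean_split_level(img: GrayImage) -> int:
    """Floor of the mean raw level, clamped into [0, L-2]."""
    mu = img.pixels.sum(dtype=np.int64) / img.size
    return int(min(max(int(np.floor(mu)), 0), img.levels - 2))


def median_split_level(img: GrayImage) -> int:
    """Smallest level m with CDF(m) >= 1/2, clamped into [0, L-2]."""
    hist = compute_histogram(img)
    cdf = np.cumsum(hist.counts)
    m = int(np.argmax(2 * cdf >= hist.total))
    return min(m, img.levels - 2)


def _segment_mean_split(counts: np.ndarray, lo: int, hi: int) -> int:
    k = np.arange(lo, hi + 1)
    seg = counts[lo : hi + 1]
    mu = (seg * k).sum() / seg.sum()
    return int(min(max(int(np.floor(mu)), lo), hi - 1))


def _segment_median_split(counts: np.ndarray, lo: int, hi: int) -> int:
    seg = counts[lo : hi + 1]
    cdf = np.cumsum(seg)
    m = lo + int(np.argmax(2 * cdf >= cdf[-1]))
    return min(m, hi - 1)


def recursive_split(img: GrayImage, r: int, rule: str = "mean") -> SplitSpec:
    """Split the level range r times recursively by segment-local mean/median.

    Segments with fewer than two occupied levels or of width one stop
    recursing, so the result has at most ``2**r`` segments.
    """
    if r < 0:
        raise ValueError("recursion depth r must be >= 0")
    if rule not in ("mean", "median"):
        raise ValueError(f"rule must be 'mean' or 'median', got {rule!r}")
    counts = compute_histogram(img).counts
    splitter = _segment_mean_split if rule == "mean" else _segment_median_split
    points: list[int] = []

    def recurse(lo: int, hi: int, depth: int) -> None:
        if depth == 0 or hi - lo < 1:
            return
        if np.count_nonzero(counts[lo : hi + 1]) < 2:
            return
        s = splitter(counts, lo, hi)
        points.append(s)
        recurse(lo, s, depth - 1)
        recurse(s + 1, hi, depth - 1)

    recurse(0, img.levels - 1, r)
    return SplitSpec(tuple(sorted(points)), img.levels)


def ghe(img: GrayImage, *, cdf_min_shift: bool = False) -> GrayImage:
    """Global histogram equalization over the full range."""
    lut = _equalize_segments(img, [(0, img.levels - 1)], cdf_min_shift=cdf_min_shift)
    return apply_lut(img, lut)


def bi_he_lut(img: GrayImage, split: int, *, cdf_min_shift: bool = False) -> TransformLUT:
    """The bi-histogram-equalization LUT for an arbitrary separating point."""
    if not (0 <= split <= img.levels - 2):
        raise ValueError(f"split must lie in [0, {img.levels - 2}]")
    return _equalize_segments(
        img, [(0, split), (split + 1, img.levels - 1)], cdf_min_shift=cdf_min_shift
    )


def bbhe(img: GrayImage, *, cdf_min_shift: bool = False) -> GrayImage:
    """Brightness-preserving bi-HE: split at the image mean."""
    return apply_lut(img, bi_he_lut(img, mean_split_level(img), cdf_min_shift=cdf_min_shift))


def dsihe(img: GrayImage, *, cdf_min_shift: bool = False) -> GrayImage:
    """Dualistic sub-image HE: split at the image median."""
    return apply_lut(img, bi_he_lut(img, median_split_level(img), cdf_min_shift=cdf_min_shift))


def candidate_splits(hist: Histogram) -> np.ndarray:
    """All levels x_s for which both [0, x_s] and [x_s+1, L-1] hold mass."""
    cum = np.cumsum(hist.counts)
    xs = np.arange(hist.levels - 1)
    ok = (cum[:-1] > 0) & (cum[:-1] < hist.total)
    return xs[ok]


def mmbebhe(
    img: GrayImage, *, cdf_min_shift: bool = False
) -> tuple[GrayImage, int | None]:
    """Minimum-mean-brightness-error bi-HE.

    Scans every separating point with both segments non-empty, computes the
    would-be output mean directly from the histogram and the candidate LUT
    (``sum(counts[k] * mapping[k]) / total``, exact in integer arithmetic),
    and applies the bi-HE at the AMBE-minimizing split.  Returns
    ``(input, None)`` for degenerate (single-occupied-level) images.
    """
    hist = compute_histogram(img)
    cands = candidate_splits(hist)
    if len(cands) == 0:
        return img, None
    denom = img.size * (img.levels - 1)
    mu_x = int(img.pixels.sum(dtype=np.int64)) / denom
    best_xs: int | None = None
    best_ambe = np.inf
    for xs in cands:
        lut = bi_he_lut(img, int(xs), cdf_min_shift=cdf_min_shift)
        mu_y = int((hist.counts * lut.mapping).sum()) / denom
        a = abs(mu_y - mu_x)
        if a < best_ambe:
            best_ambe = a
            best_xs = int(xs)
    assert best_xs is not None
    return apply_lut(img, bi_he_lut(img, best_xs, cdf_min_shift=cdf_min_shift)), best_xs


def rmshe(img: GrayImage, r: int, *, cdf_min_shift: bool = False) -> GrayImage:
    """Recursive mean-separate HE at depth r (r=0 is GHE, r=1 is BBHE)."""
    spec = recursive_split(img, r, "mean")
    return apply_lut(img, _equalize_segments(img, spec.segments, cdf_min_shift=cdf_min_shift))


def rsihe(img: GrayImage, r: int, *, cdf_min_shift: bool = False) -> GrayImage:
    """Recursive sub-image (median-split) HE at depth r (r=1 is DSIHE)."""
    spec = recursive_split(img, r, "median")
    return apply_lut(img, _equalize_segments(img, spec.segments, cdf_min_shift=cdf_min_shift))


METHODS = ("ghe", "bbhe", "dsihe", "mmbebhe", "rmshe", "rsihe", "mbobhe")
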