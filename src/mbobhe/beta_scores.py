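"""Beta-density scoring: map raw metrics to normalized quality scores.

A raw metric value t in [0, 1] (RBD, RCD or ASD) is pushed through a Beta
density and divided by the density at the Beta mode, giving a score in
[0, 1] that peaks at 1 wherever the chosen shape parameters place the mode.
This relocates the "best" metric value away from the extremes: perfect
brightness preservation (RBD = 1) or zero contrast change (RCD = 0) means no
visible enhancement, so an interior optimum is scored highest.

Shapes with a < 1 or b < 1 put unbounded density at an endpoint and are
rejected — the max-normalization would be meaningless.  Densities are
evaluated in log space for stability at large shapes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import betaln

__all__ = [
    "BetaParams",
    "ScoreTriple",
    "beta_pdf",
    "beta_mode",
    "normalized_score",
    "score_triple",
    "DEFAULT_BPS",
    "DEFAULT_OCS",
    "DEFAULT_DPS",
]


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of a Beta distribution (both > 0)."""

    a: float
    b: float

    def __post_init__(self) -> None:
        if not (self.a > 0 and self.b > 0):
            raise ValueError(f"Beta shapes must be positive, got a={self.a}, b={self.b}")


# Package defaults (fully configurable; see docs/methods.md for rationale):
# brightness and detail scores peak near — but not at — perfect preservation,
# the contrast score peaks at a moderate contrast change.
DEFAULT_BPS = BetaParams(8.0, 2.0)  # mode 0.875
DEFAULT_OCS = BetaParams(2.0, 5.0)  # mode 0.2
DEFAULT_DPS = BetaParams(8.0, 2.0)  # mode 0.875


@dataclass(frozen=True)
class ScoreTriple:
    """Normalized (brightness, contrast, detail) scores, each in [0, 1]."""

    nbps: float
    nocs: float
    ndps: float

    def __iter__(self):
        yield from (self.nbps, self.nocs, self.ndps)


def _check_t(t: float) -> float:
    t = float(t)
    if not (0.0 <= t <= 1.0):
        raise ValueError(f"metric value must lie in [0, 1], got {t}")
    return t


def beta_pdf(t: float, params: BetaParams) -> float:
    """Beta(a, b) density at t, with 0**0 := 1 at the endpoints."""
    t = _check_t(t)
    a, b = params.a, params.b
    # endpoint handling: zero density when the exponent is positive,
    # finite limit when it is zero, unbounded (inf) when negative
    if t == 0.0:
        if a > 1:
            return 0.0
        if a == 1:
            return float(np.exp(-betaln(a, b)))
        return float("inf")
    if t == 1.0:
        if b > 1:
            return 0.0
        if b == 1:
            return float(np.exp(-betaln(a, b)))
        return float("inf")
    log_pdf = (a - 1.0) * np.log(t) + (b - 1.0) * np.log1p(-t) - betaln(a, b)
    return float(np.exp(log_pdf))


def beta_mode(params: BetaParams) -> float:
    """Argmax of the Beta(a, b) density on [0, 1]; requires a, b >= 1."""
    a, b = params.a, params.b
    if a < 1 or b < 1:
        raise ValueError(
            f"Beta({a}, {b}) has unbounded density at an endpoint; "
            "shapes must satisfy a >= 1 and b >= 1"
        )
    if a == 1 and b == 1:
        return 0.5  # flat density: any point; fixed for determinism
    if a == 1:
        return 0.0
    if b == 1:
        return 1.0
    return (a - 1.0) / (a + b - 2.0)


def normalized_score(t: float, params: BetaParams) -> float:
    """Beta density at t divided by the density at the mode; 1 at the mode.

    Computed as ``exp(logpdf(t) - logpdf(mode))`` so the Beta normalizer
    cancels exactly and the score is stable for large shapes.
    """
    t = _check_t(t)
    a, b = params.a, params.b
    mode = beta_mode(params)
    if a == 1 and b == 1:
        return 1.0
    if t == mode:
        return 1.0
    # log t and log(1-t); score 0 at an endpoint whose exponent is positive
    def _log_terms(v: float) -> float:
        out = 0.0
        if a != 1:
            if v == 0.0:
                return -np.inf
            out += (a - 1.0) * np.log(v)
        if b != 1:
            if v == 1.0:
                return -np.inf
            out += (b - 1.0) * np.log1p(-v)
        return out

    score = float(np.exp(_log_terms(t) - _log_terms(mode)))
    return min(score, 1.0)


def score_triple(
    rbd_value: float,
    rcd_value: float,
    asd_value: float,
    bps: BetaParams = DEFAULT_BPS,
    ocs: BetaParams = DEFAULT_OCS,
    dps: BetaParams = DEFAULT_DPS,
) -> ScoreTriple:
    """Map the raw metric triple (RBD, RCD, ASD) to (NBPS, NOCS, NDPS)."""
    return ScoreTriple(
        nbps=normalized_score(rbd_value, bps),
        nocs=normalized_score(rcd_value, ocs),
        ndps=normalized_score(asd_value, dps),
    )
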