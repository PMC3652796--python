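"""Batch comparison across the equalization family, and observer-study
table aggregation.

:func:`compare` runs any subset of the seven methods over a list of images
and tabulates the full metric panel per (image, method) — the quantitative
counterpart of putting the enhanced radiographs side by side.

:func:`aggregate_observer_table` reproduces the arithmetic of a manual
bone-age-assessment observer study summary: per image set (original / GHE /
MBOBHE), the mean over observers of the carpal and RUS (radius-ulna-short
bones) columns, their total, and the percentage change between two sets.
Means are rounded half-up to 2 decimals BEFORE totals and percentages are
formed — the convention under which every published summary cell of this
kind of table is self-consistent.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from . import baselines
from .beta_scores import DEFAULT_BPS, DEFAULT_DPS, DEFAULT_OCS, BetaParams, score_triple
from .core import ObjectiveWeights, mbobhe, objective
from .hist_core import compute_histogram
from .image_io import GrayImage
from .quality_metrics import MetricConfig, ambe, asd, entropy, rbd, rcd

__all__ = ["compare", "aggregate_observer_table", "percentage_change", "run_method"]


def run_method(
    img: GrayImage,
    method: str,
    r: int = 2,
    cfg: MetricConfig = MetricConfig(),
    bps: BetaParams = DEFAULT_BPS,
    ocs: BetaParams = DEFAULT_OCS,
    dps: BetaParams = DEFAULT_DPS,
    w: ObjectiveWeights = ObjectiveWeights(),
) -> GrayImage:
    """Dispatch a method name to its implementation and return the output."""
    if method == "ghe":
        return baselines.ghe(img)
    if method == "bbhe":
        return baselines.bbhe(img)
    if method == "dsihe":
        return baselines.dsihe(img)
    if method == "mmbebhe":
        return baselines.mmbebhe(img)[0]
    if method == "rmshe":
        return baselines.rmshe(img, r)
    if method == "rsihe":
        return baselines.rsihe(img, r)
    if method == "mbobhe":
        return mbobhe(img, cfg, bps, ocs, dps, w).output
    raise ValueError(f"unknown method {method!r}; choose from {baselines.METHODS}")


def compare(
    images: list[GrayImage],
    methods: list[str] = list(baselines.METHODS),
    r: int = 2,
    cfg: MetricConfig = MetricConfig(),
    bps: BetaParams = DEFAULT_BPS,
    ocs: BetaParams = DEFAULT_OCS,
    dps: BetaParams = DEFAULT_DPS,
    w: ObjectiveWeights = ObjectiveWeights(),
    labels: list[str] | None = None,
) -> pd.DataFrame:
    """One row per (image, method) with the full metric and score panel."""
    if not images:
        raise ValueError("need at least one image")
    if not methods:
        raise ValueError("need at least one method")
    for mname in methods:
        if mname not in baselines.METHODS:
            raise ValueError(f"unknown method {mname!r}; choose from {baselines.METHODS}")
    if labels is None:
        labels = [f"image{i}" for i in range(len(images))]
    rows = []
    for label, img in zip(labels, images):
        for mname in methods:
            out = run_method(img, mname, r, cfg, bps, ocs, dps, w)
            scores = score_triple(rbd(img, out, cfg), rcd(img, out, cfg),
                                  asd(img, out), bps, ocs, dps)
            rows.append({
                "image": label,
                "method": mname,
                "r": r if mname in ("rmshe", "rsihe") else pd.NA,
                "ambe": ambe(img, out),
                "entropy": entropy(compute_histogram(out)),
                "rbd": rbd(img, out, cfg),
                "rcd": rcd(img, out, cfg),
                "asd": asd(img, out),
                "nbps": scores.nbps,
                "nocs": scores.nocs,
                "ndps": scores.ndps,
                "nobj": objective(scores, w),
            })
    return pd.DataFrame(rows)


def _round2(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


def _round1(x: float) -> float:
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def aggregate_observer_table(table: pd.DataFrame) -> pd.DataFrame:
    """Summarize a per-observer table with columns set, observer, carpal, rus.

    Returns one row per set with ``carpal_mean``, ``rus_mean`` (means over
    observers, rounded half-up to 2 decimals) and ``total`` (sum of the two
    rounded means).  Every set must have the same observer count.
    """
    required = {"set", "observer", "carpal", "rus"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if (table[["carpal", "rus"]] < 0).any().any():
        raise ValueError("carpal/rus values must be non-negative")
    counts = table.groupby("set")["observer"].nunique()
    if counts.nunique() != 1 or len(table) != counts.sum():
        raise ValueError("every set must have the same (unique) observers")
    out = []
    for set_label, grp in table.groupby("set", sort=False):
        cm = _round2(grp["carpal"].mean())
        rm = _round2(grp["rus"].mean())
        out.append({
            "set": set_label,
            "carpal_mean": cm,
            "rus_mean": rm,
            "total": _round2(cm + rm),
        })
    return pd.DataFrame(out)


def percentage_change(summary: pd.DataFrame, set_from, set_to) -> dict[str, float]:
    """Percent decrease from ``set_from`` to ``set_to`` per summary column,
    computed from the 2-decimal rounded means and reported to 1 decimal."""
    a = summary.set_index("set").loc[set_from]
    b = summary.set_index("set").loc[set_to]
    return {
        col: _round1((a[col] - b[col]) / a[col] * 100.0)
        for col in ("carpal_mean", "rus_mean", "total")
    }
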