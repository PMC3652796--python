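# Methods

## The equalization primitive

Every method in the package is assembled from one primitive: equalize a
closed gray-level segment `[lo, hi]` against the cumulative distribution of
the histogram mass inside it,

    mapping[k] = lo + round_half_up((hi − lo) · cdf[k]),   k ∈ [lo, hi],

so a level can never leave its segment (range confinement) and the mapping
is non-decreasing. Quantization is round-half-up; this is a convention the
original method description leaves open, fixed here so outputs are
bit-reproducible. Two CDF dialects exist in the literature — the plain CDF
and the min-shifted `(cdf − cdf_min)/(1 − cdf_min)` form; the plain CDF is
the default and the shifted form is available via `cdf_min_shift=True`
everywhere (and `--cdf-min-shift` on the CLI).

Segments holding zero or one occupied level map identity. This replaces the
classic artifact in which a constant image equalizes to full white; with
this rule constant images are fixed points of all seven methods, and the
degenerate sub-histograms that bi-HE frequently creates (e.g. a two-level
image split between its levels) are left untouched rather than saturated.

A split at level `x_s` assigns `x_s` to the lower segment: `[0, x_s]` and
`[x_s+1, L−1]`. Recursive splitting (RMSHE/RSIHE) uses the segment-local
mean or median at every depth, stops on segments of width one or with fewer
than two occupied levels, and is defined at r=0 as plain GHE so the family
is closed: GHE ≡ RMSHE(0) ≡ RSIHE(0), BBHE ≡ RMSHE(1), DSIHE ≡ RSIHE(1),
all bit-exact by construction and verified bit-exact in the tests.

Split-level conventions: the mean split is `floor(mean)`; the median split
is the smallest level with CDF ≥ ½; both clamp into `[0, L−2]`. All
tie-breaks (MMBEBHE and the MBOBHE argmax) go to the smallest level.

## Metrics

All statistics are computed on the normalized intensity view `v/(L−1)` with
the population (1/MN) variance, so the stability constant `c` (default
1e−6) is scale-free. The three raw metrics are

    RBD = exp(−|μ_y − μ_x| / (μ_x + c))        ∈ (0, 1], 1 ⇔ means equal
    RCD = 1 − exp(−|σ_y − σ_x| / (σ_x + c))    ∈ [0, 1), 0 ⇔ contrasts equal
    ASD = #{(i,j) : (x_ij − μ_x)(y_ij − μ_y) ≥ 0} / MN   ∈ [0, 1]

Orientation conventions worth stating explicitly, because the published
formulations of this metric family are typographically ambiguous or
self-contradictory and an implementation has to pick one axis per metric:

* RBD uses the absolute brightness error in the exponent; the raw signed
  variant (unbounded above when the output brightens) is available behind
  `MetricConfig(signed_rbd=True)` but is not used by any method here.
* RCD is 0 at no contrast change and saturates toward 1; the Beta scoring
  layer relocates the optimum anyway, so this choice only fixes which way
  the axis points.
* ASD counts *preserved* side-of-mean relations (1 = structure intact);
  pixels exactly at the mean (product 0) count as preserved.

In double precision the open interval ends are reachable by saturation of
`exp`: exponents beyond ≈36 collapse `1 − exp(−t)` to exactly 1.0 and
beyond ≈745 `exp(−t)` underflows to exactly 0.0. The property tests assert
the bounds together with this saturation condition rather than pretending
the strict inequalities survive floating point.

### Exact-moment accumulation

Metric functions accept either a `GrayImage` or a float array. For
`GrayImage` inputs, μ and σ are formed from the exact integer sums Σv and
Σv² with a single final division. Consequently any two routes to the same
pixel multiset give bit-identical metrics — in particular the MBOBHE fast
path, which reads Σ counts[k]·mapping[k] and Σ counts[k]·mapping[k]² off
the histogram, is bit-identical to materializing each candidate image and
measuring it. The test suite exploits this: the naive O(L·MN)
materialize-and-measure rescan must reproduce the candidate table
*bit-for-bit*, which is a much sharper oracle than a tolerance comparison.

## Beta scoring

A raw metric t ∈ [0, 1] is scored as the Beta(a, b) density at t divided by
the density at the mode `(a−1)/(a+b−2)`, evaluated as
`exp(logpdf(t) − logpdf(mode))` so the Beta normalizer cancels exactly and
large shapes stay stable. Shapes with a < 1 or b < 1 place unbounded
density at an endpoint and are rejected; Beta(1, 1) scores 1 everywhere
(flat scoring, useful for switching a criterion off); a = 1 or b = 1 gives
monotone power-law scores with the mode at an endpoint.

Default shapes (`bps.m, bps.n, ocs.p, ocs.q, dps.u, dps.v` on the CLI):

| score | shape      | mode  | reading                                       |
|-------|-----------|-------|-----------------------------------------------|
| NBPS  | Beta(8, 2) | 0.875 | near-full brightness preservation preferred; a perfectly unchanged mean is mildly penalized |
| NOCS  | Beta(2, 5) | 0.2   | moderate contrast change preferred over none or extreme |
| NDPS  | Beta(8, 2) | 0.875 | high but not total structural preservation    |

These defaults are this package's own: the original tuning was done by
mean-opinion-score sessions with radiologists against TW3 stage criteria
and the resulting shape values were never published, so figure-level
reproduction of that study is impossible and not attempted. The defaults
were chosen once to encode the qualitative intent (interior optima,
brightness/detail weighted near preservation, contrast pushed away from
zero change) and all six numbers are plain keyword arguments / CLI flags.

Objective weights default to α = β = φ = 1 (also unreported in the original
study; equal weighting is the neutral choice).

## The MBOBHE search

Candidates are all `x_s ∈ [0, L−2]` with mass on both sides; images with a
single occupied level have no candidates and are returned unchanged with
`split=None`. The search evaluates every candidate (no pruning — the
candidate table is the certificate), costs O(L) per candidate after one
O(MN) histogram pass, and breaks objective ties toward the smallest level.
A useful structural check, verified on every fixture: with weights (1, 0, 0)
and the monotone shape Beta(5, 1) for NBPS, maximizing the objective is
equivalent to minimizing AMBE, and the chosen split coincides with
MMBEBHE's exactly.

The method operates on whole images; enhancing cropped ossification-site
regions of interest is the caller's choice via ordinary cropping before the
call.

## Synthetic phantoms

`make_phantom` emulates the regime the method targets, not hand anatomy: a
linear background gradient inside a narrow band (default levels 90–140 of
256), a few elliptical "bones" 30 levels above their local background with
1–2-pixel rims at +`edge_gain` (the thickened-white-line analogue at
epiphyseal borders, default +40), and additive Gaussian noise (default
σ = 2 levels), clipped to range. Overlapping structures do not stack, so
the histogram support stays inside the analytically known band — a tested
invariant. Randomness comes exclusively from `numpy.random.default_rng`
(PCG64) seeded from the spec, making every fixture a pure function of its
spec. `make_ramp` and `make_bimodal` give analytically transparent
histograms for exercising the split rules (the bimodal generator is the
standard case where mean and median splits diverge).

What the phantoms do not model: anatomy-shaped structures, spatially
correlated (quantum) noise, scatter, or detector response. Passing tests
therefore certify the algorithmic contracts — oracle equivalence,
identities, conservation, scoring behavior — not clinical image quality on
real radiographs.

## Observer-table aggregation

`aggregate_observer_table` reproduces the arithmetic of the published
three-observer bone-age study summary: per set, the mean over observers of
the carpal and RUS columns rounded half-up to 2 decimals, and the total
formed from the *rounded* means (the convention was reverse-engineered from
the printed tables: the unrounded Set 3 discrepancy means sum to 1.0867,
which only prints as the published 1.08 if rounding precedes the sum).
Percentage changes between sets are computed from the rounded means and
reported to 1 decimal. One published cell (the GHE set's RUS discrepancy
mean) is not derivable from its own per-observer values under any rounding;
the package computes and reports the consistent value.

## Problem sizes and runtime

The property-oracle suite runs on 50 seeded fixtures of 64×64 and 128×128
pixels at L = 256 — large enough that every histogram regime of interest
(narrow support, two-level, noisy) appears, small enough that the naive
O(L·MN) rescans used as oracles stay cheap. The full test suite and the
acceptance script each complete in well under a minute on one CPU.

## Known limitations

* Multi-point (more than two segments) or recursive MBOBHE is out of scope.
* No clipping/plateau-limit, histogram-weighting or dynamic gray-level
  allocation variants.
* 8-bit I/O only (internal level count is configurable); no DICOM and no
  16-bit windowing.
* The observer study itself (humans rating 160 radiographs) is inherently
  not computable; only its table arithmetic is implemented.
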