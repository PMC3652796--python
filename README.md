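# mbobhe

Contrast enhancement for low-contrast, narrow-dynamic-range grayscale
images by **Multipurpose Beta Optimized Bi-Histogram Equalization
(MBOBHE)**, together with the classical histogram-equalization family it is
usually compared against and the quality-metric panel needed to do the
comparison.

The motivating application is hand radiographs inspected for bone age
assessment: the ossification centers and epiphyseal plates that a TW3 or
Greulich–Pyle reading depends on sit in a narrow band of gray levels over a
smoothly varying background, and plain histogram equalization routinely
over-enhances them, shifts the overall brightness, or washes out the thin
bright edge lines that carry the diagnostic signal.

## The method

Bi-histogram equalization picks a separating gray level `x_s`, splits the
histogram into `[0, x_s]` and `[x_s+1, L−1]`, and equalizes each part within
its own range. The family differs only in how `x_s` is chosen: the image
mean (BBHE), the median (DSIHE), the level minimizing the absolute mean
brightness error AMBE = |μ_y − μ_x| (MMBEBHE), or recursively (RMSHE,
RSIHE, up to 2^r segments).

MBOBHE instead scores **every** candidate `x_s` on three axes and keeps the
one maximizing a weighted-sum objective:

- RBD = exp(−|μ_y − μ_x| / (μ_x + c)) — relative brightness difference;
- RCD = 1 − exp(−|σ_y − σ_x| / (σ_x + c)) — relative contrast difference
  (σ is the population standard deviation of normalized intensity);
- ASD — the fraction of pixels keeping their side-of-mean relation,
  sign((x − μ_x)(y − μ_y)) ≥ 0.

Each raw metric t is remapped through a Beta density normalized by its mode,
`N(t) = Beta_pdf(t; a, b) / Beta_pdf(mode)`, so that the *best* score sits at
an interior optimum rather than at an extreme — no brightness change and no
contrast change mean no visible enhancement, so they should not win. The
objective is

    Nobj = (α·NBPS + β·NOCS + φ·NDPS) / (α + β + φ)

maximized exhaustively over all L−1 separating points. The search is O(L²):
per-candidate moments and sign tallies come from the histogram and the
candidate lookup table alone, bit-identical to materializing each candidate
image but without the O(L·MN) cost.

## Worked example

No data download is needed; the `synthetic` module generates
radiograph-like phantoms (narrow-band background gradient, bright
elliptical "bones" with thin high-intensity rims, mild noise):

```python
import mbobhe as mb

img = mb.make_phantom(mb.PhantomSpec(seed=42, size=(128, 128)))
res = mb.mbobhe(img)
print(f"chosen split x_s = {res.split}")
print(f"objective Nobj  = {res.objective:.4f}")
table = mb.compare([img], ["ghe", "bbhe", "mmbebhe", "mbobhe"])
print(table[["method", "ambe", "rcd", "asd", "nobj"]].round(4).to_string(index=False))
```

prints

```
chosen split x_s = 108
objective Nobj  = 0.5608
 method   ambe    rcd    asd   nobj
    ghe 0.0268 0.9010 0.9847 0.3434
   bbhe 0.0082 0.9017 1.0000 0.1026
mmbebhe 0.0026 0.9018 0.9845 0.1307
 mbobhe 0.0648 0.8939 0.9532 0.5608
```

Read the rows as trade-offs: MMBEBHE minimizes the brightness error (`ambe`
0.0026) and BBHE leaves the side-of-mean structure perfectly intact (`asd`
1.0000), but both land at score extremes the Beta shapes deliberately
penalize; the searched split accepts a small brightness shift and a little
structural change and scores a much higher combined objective (`nobj`,
computed here with the package's default shapes and equal weights).
`res.candidates` holds the full per-split table `(xs, rbd, rcd, asd, nbps,
nocs, ndps, nobj)` — the optimality certificate.

The same operations are available from a shell:

```bash
mbobhe synth phantom.png --seed 42 --size 128 128
mbobhe enhance phantom.png enhanced.png --method mbobhe --dump-candidates table.csv
mbobhe compare phantom.png --methods ghe,bbhe,mbobhe
```

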