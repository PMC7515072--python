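# Methods

## Ordinal patterns and the tie rule

A window of `m` values taken with delay `τ` is reduced to the permutation of
its positions sorted by ascending value. Ties are broken by ascending
position, implemented as a single stable argsort by value — so a constant
window maps to the identity permutation and any strictly increasing
transformation of the series leaves every pattern (hence every plain
entropy) unchanged. Patterns are stored as the positions-by-value
permutation; `OrdinalPattern.rank_vector()` converts to the inverse (rank)
convention used by some other ordinal-analysis libraries, because the two
conventions are easy to confuse silently. Internally each pattern is
encoded by its lexicographic (Lehmer) rank in `0..m!−1`, which makes
counting a `bincount` and fixes a deterministic iteration order.

RR data in seconds essentially never ties; the tie rule matters only for
heavily quantised inputs.

## Entropies

All entropies are normalized by `log(m!)` and therefore live in `[0, 1]`
and are independent of logarithm base; this includes the weighted variant,
since the weighted frequencies are themselves a distribution over at most
`m!` symbols. Zero-probability patterns are omitted from `Σ p^α`
(`0^α = 0` for `α > 0`), which also keeps `α < 1` well-defined when not all
patterns occur.

Numerical choices:

* `Σ p^α` is evaluated in the log domain (`logsumexp(α·log p)`), so large
  orders (the min-entropy regime, e.g. `α = 10⁴`) do not underflow.
* `|α − 1| < 1e-6` dispatches to the Shannon form to avoid the `1/(1−α)`
  cancellation; the two branches agree to well below `1e-3` at `α = 1 ± 1e-4`.
* Results are clamped to `[0, 1]` to absorb last-bit round-off.

Window weights use the population (divide-by-`m`) variance. Constant
windows are forced to weight exactly zero (block-mean round-off otherwise
leaves a ~1e−32 residue), preserving "zero weight iff all values equal";
a series whose windows *all* have zero weight raises a distinct
degenerate-series error, since weighted frequencies would be 0/0.

## Multiscale evaluation

Coarse-graining at scale `s` takes non-overlapping block means; the trailing
`T mod s` values are dropped, so the length is exactly `⌊T/s⌋`. The
recommended sample-size rule `T > 5·m!` is surfaced as a structured warning,
not an error, because deep coarse-graining legitimately approaches it.

`entropy_surfaces` sweeps the `(s, τ)` grid with the coarse series computed
once per scale and the window sort and pattern counts shared across every
requested `(α, weighted)` surface — scanning both study orders `α = 1/2, 2`
plus the weighted variant costs little more than one surface. Grid cells
whose length precondition fails (or with zero total weight on a weighted
surface) are stored as missing (NaN) rather than raising, so full-range
scans run on short inputs; single-point `mrpe`/`wmrpe` calls still raise.
The single-cell path and the grid path share one entropy kernel, so
`mrpe(series, 1, α, m, τ)` equals the plain RPE of the raw series
bit-for-bit.

Group surfaces are the cell-wise arithmetic mean of per-subject normalized
entropies (missing if missing for any subject), not the entropy of pooled
series.

## Differentiation criterion

Per group and parameter point, subjects span the closed interval
`[min, max]` of their entropies. Three groups are differentiated when the
three intervals are pairwise disjoint; closed intervals touching at an
endpoint are *not* disjoint, so every gap must be strictly positive. The
difference is `min(lo_upper − hi_lower)` over the two adjacent pairs in the
induced descending order — equivalently the minimum distance between any
two cross-group values. The scan skips (and counts) cells where any subject
is missing, reports results in ascending `(s, τ)` order, and on ties in the
maximum difference reports the first maximiser while listing all of them.
The criterion is descriptive: with five subjects per group no significance
test is meaningful, and none is attached.

## Synthetic regimes

The generator provides test cohorts with the qualitative entropy contrast
of the three clinical groups; parameters are fixed once:

* `iid_like` (AF-like): i.i.d. gamma intervals, mean 0.44 s, sd ≈ 0.10 s.
  Exchangeable windows make all `m!` patterns equiprobable, so normalized
  entropy is ≈ 1 at every scale (≥ 0.99 at `T = 10⁵`).
* `correlated` (healthy-like): AR(1) with φ = 0.9 (stationary sd 0.04 s)
  smoothed by a 3-beat moving average, plus a 0.03 s sinusoid of period 250
  beats around 0.85 s. The short smoothing correlates consecutive
  increments, giving mid-range ordinal complexity (≈ 0.72 at
  `m = 3, τ = 1, α = 2`) that relaxes toward 1 as `τ` or `s` grows.
* `low_variability` (CHF-like): white noise convolved with a Gaussian
  kernel of sd 8 beats, rescaled to sd 0.012 s around 0.55 s. The smooth
  trajectories produce long monotone runs and low entropy (≈ 0.44 at
  `m = 3, τ = 1`) throughout the small-`(s, τ)` region.

A plain AR(1) is deliberately *not* used for the low-complexity regime:
its consecutive increments decorrelate as φ → 1, so its ordinal entropy
stays high no matter how strong the autocorrelation — genuine smoothness
(positively correlated increments) is what lowers pattern entropy.

Seeds are explicit everywhere; per-subject seeds are derived from the cohort
seed and stay below 2³¹. What the surrogates do **not** emulate: absolute
physiological rate distributions, ectopic beats and artefacts,
non-stationarity over 24 h, and long-range (1/f) correlations. Passing
tests therefore demonstrate the machinery and the qualitative group
contrast, not clinical performance. In particular, the regime ordering
iid_like > correlated > low_variability holds on the small-`(s, τ)`
interior of the grid where the regimes are distinguishable; at large delays
all smooth surrogates revert to entropy ≈ 1, and the mean over the *full*
default grid can place `correlated` below `low_variability` — real RR data,
with its long-range structure, decays differently.

## Problem sizes

The test suite works at desk scale (series of 10²–10⁴ intervals, sub-grids
of the default ranges; one cohort fixture of three subjects at
`T = 20 000`). The acceptance study uses five subjects per group at
`T = 50 000` over the full 20 × 100 grid for `m ∈ {3, 4, 5}` and
`α ∈ {1/2, 2}` — half the challenge recordings' length, which halves
runtime while leaving pattern-frequency standard errors (∝ `T^{−1/2}`)
far below the inter-regime gaps. The full-length clinical analysis is
available via `scripts/reproduce_physionet.py` once the challenge files are
downloaded.

## Known limitations

* The scan treats entropies as exact; subject-level sampling variability is
  not propagated into the disjointness verdict.
* Weighted entropy is not invariant under nonlinear monotone
  transformations of the series (window variances change non-uniformly);
  a test documents a counterexample.
* Only non-overlapping block-mean coarse-graining is implemented — no
  composite or refined multiscale variants.
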