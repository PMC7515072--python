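# mrpe — multiscale Rényi permutation entropy for heartbeat series

Ordinal-pattern complexity analysis of RR-interval (inter-beat) time series.
Heart-rate variability differs between atrial fibrillation (AF), healthy (H)
and congestive heart failure (CHF) subjects, but a single entropy number
rarely separates the groups. This package evaluates the ordinal complexity
of an RR series over a *four*-parameter family — coarse-graining scale `s`,
embedding delay `τ`, embedding dimension `m` and Rényi order `α` — and scans
that parameter grid for the points where three subject groups separate
completely.

## The measures

A window `(x_j, x_{j+τ}, …, x_{j+(m−1)τ})` is mapped to the permutation
`π ∈ S_m` of its positions sorted by ascending value (ties broken by
position — the standard Bandt–Pompe rule). Over all `T − (m−1)τ` windows
this gives relative frequencies `p_τ(π)`, or variance-weighted frequencies
`p_ωτ(π)` in which each window counts with weight
`ω(j) = (1/m) Σ_i (x_{j+(i−1)τ} − x̄_j)²`, so amplitude structure contributes
alongside pure order. The normalized Rényi permutation entropy is

    RPE(α, m, τ) = log( Σ_π p_τ(π)^α ) / (1 − α) / log(m!)  ∈ [0, 1],

with the Shannon permutation entropy as the α → 1 limit and min-entropy as
α → ∞. Coarse-graining at scale `s` replaces the series by its
non-overlapping block means of length `s`; MRPE/WMRPE is RPE/WRPE of the
coarse series, so `s = 1` recovers the plain measures.

**Group differentiation.** For fixed `(s, τ, m, α)` each group of subjects
spans the closed interval between its minimum and maximum entropy. Three
groups are *differentiated* at that parameter point when the three intervals
are pairwise disjoint (which forces an order, e.g. AF > H > CHF); the
*difference* is the smaller of the two adjacent gaps. The scan evaluates
this verdict over the default grid `1 ≤ s ≤ 20`, `1 ≤ τ ≤ 100`.

## Worked example

No download is needed: `synth_rr`/`synth_group` generate surrogate cohorts
in three regimes whose ordinal complexity contrasts like the clinical
groups' (`iid_like` ≈ AF, `correlated` ≈ H, `low_variability` ≈ CHF).

```python
import mrpe

af  = mrpe.synth_group("iid_like",        3, 20_000, seed=1, group="AF")
h   = mrpe.synth_group("correlated",      3, 20_000, seed=1, group="H")
chf = mrpe.synth_group("low_variability", 3, 20_000, seed=1, group="CHF")

print("MRPE(s=2, alpha=2, m=3, tau=1):")
for cohort in (af, h, chf):
    values = [mrpe.mrpe(s, 2, 2.0, 3, 1).value for s in cohort]
    print(f"  {cohort[0].group:>3}: " + " ".join(f"{v:.4f}" for v in values))

grids = {
    g[0].group: [mrpe.entropy_grid(s, 3, 2.0, False, range(1, 6), range(1, 11))
                 for s in g]
    for g in (af, h, chf)
}
results, summary = mrpe.scan_differentiation(grids)
print(f"differentiated points: {summary.n_differentiated}/{summary.n_evaluated}")
print(f"max difference {summary.max_difference:.4f} at (s, tau) = {summary.argmax}, "
      f"ordering {' > '.join(summary.ordering_at_max)}")
```

prints

```
MRPE(s=2, alpha=2, m=3, tau=1):
   AF: 0.9997 1.0000 0.9999
    H: 0.8210 0.8166 0.8237
  CHF: 0.4977 0.4985 0.4957
differentiated points: 37/50
max difference 0.2735 at (s, tau) = (1, 1), ordering AF > H > CHF
```

The near-i.i.d. cohort sits at the entropy ceiling with tiny spread, the two
structured regimes fall below it, and at 37 of the 50 grid points the three
per-group intervals are pairwise disjoint — the separation is largest
(0.27, the gap between the H and CHF intervals) at `s = 1, τ = 1`.

## Command line

```sh
mrpe simulate --regime correlated --length 100000 --seed 7 --out h1.txt
mrpe entropy  --input h1.txt --m 3 --alpha 0.5,2 --s-range 1:20 --tau-range 1:100 --out grids/
mrpe scan     --group AF=a1.txt,a2.txt --group H=n1.txt,n2.txt \
              --group CHF=c1.txt,c2.txt --m 3 --alpha 2 --out scan/
```

Input files are plain text, one RR interval in seconds per line (`#`
comments and blank lines ignored; two-column `time interval` exports are
auto-detected). Exit codes: 0 ok, 1 usage error, 2 data error.

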