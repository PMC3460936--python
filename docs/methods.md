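# Methods

## The model

`regionrisk` operationalizes a rank-based composite index for
prioritizing small geographic areas by cancer-mortality risk. The
method makes deliberately weak assumptions: factor values are only used
through their regional *ordering* (quartile membership), so it is
insensitive to units, skew and outliers, at the cost of discarding
within-quartile variation. It assumes regions are exchangeable units —
no spatial smoothing, adjacency weighting or population-size shrinkage
is applied — and that the configured risk directions are correct
(a direct factor's larger values mean higher risk; inverse factors,
income and education, are reversed).

### Quartile assignment

Two binning rules are exposed because published small-area tables are
ambiguous about which was used, and the two differ exactly when data
are tied or skewed:

* **`cutpoint`** (default): empirical 25/50/75th percentiles with
  linear interpolation between order statistics; a region's bin depends
  only on its value (`value ≤ Q1 → 1, ≤ median → 2, ≤ Q3 → 3, else 4`),
  so tied values always share a bin and bins can be very unbalanced —
  mortality tables in which over half the ZIP codes sit in quartile 4
  can only arise this way. That behaviour, plus rank being a pure
  function of value, makes it the safer default.
* **`equal_count`**: sort ascending, split into four contiguous blocks
  with sizes as equal as possible, remainders allocated to the *lowest*
  bins first (n = 11 → 3/3/3/2); regions with exactly equal values
  collapse to the lower of their blocks' bins. This reproduces the
  narrative convention "the three regions with the lowest rates form
  quartile 1".

Inverse factors are reranked `q → 5 − q` *after* binning, so quartile 4
of median income spans the lowest dollar range.

### Integrated quartile score

`S = Σ_f w_f q_f` with positive integer weights. The default
configurations weight incidence and mortality double at both geographic
levels. (At the ZIP level one published caption mentions doubling only
mortality, but 22 of the 23 published ZIP scores reproduce only when
*both* incidence and mortality are doubled, and the accompanying text
states both; arithmetic consistency won.) One published ZIP row
(37209, printed 27) is inconsistent with its own printed ranks under
every weighting consistent with the other 22 rows (they sum to 26); it
is treated as a source-table arithmetic slip — documented and excluded
from exact checks, not "corrected".

Priority ranking is competition-style on descending `S` (ties share
the minimum rank); row order among ties is made byte-reproducible by
descending mortality rank, then region id.

Scoring **requires complete values** for every configured factor.
Published score tables sometimes include regions whose raw values are
marked "not determined" in the same report (evidently sourced
elsewhere); silently imputing a quartile rank would fabricate data, so
the package errors instead and users drop the factor or region, or
supply the value, explicitly in configuration.

## Correlation analysis

Group sizes are tiny (3–30 units), so small-sample conventions are
load-bearing:

* Pearson `r` with a **Fisher-z interval**,
  `tanh(atanh r ± z_{1−α/2}/√(n−3))`. At `n = 3` the variance
  `1/(n−3)` is undefined and the interval is reported as `[−1, 1]`
  rather than failing — three-unit groups legitimately occur. `|r| = 1`
  is reported with `p = 0` and the degenerate interval `[r, r]`; values
  within 1e−12 of ±1 are snapped (indistinguishable from perfect
  linearity at double precision).
* Two-sided p from `t = r √((n−2)/(1−r²))` on `n − 2` df.
* **Spearman** = Pearson on mid-ranks (the standard tie correction
  follows automatically). For `n ≤ 8` the p-value is *exact*: full
  enumeration of all `n!` permutations of one mid-rank vector, counting
  `|ρ| ≥ |ρ_obs| − 1e−12` (the tolerance absorbs roundoff at ties).
  The t-approximation is used for `n > 8`.
* Groups with fewer than 3 complete cases are reported as *skipped*
  with a reason, never errored — small groups are a fact of ZIP-level
  data, not a user mistake.
* p-values are two-sided throughout and **unadjusted** by default
  (matching practice in this analysis style, where the tables are
  descriptive); `adjust="bonferroni"` is available.

## Synthetic data generator

`generate_regions` draws region tables from a **Gaussian copula**: a
latent multivariate normal with correlation `2 sin(π ρ_S / 6)` — the
exact conversion making the observed-scale Spearman correlation equal
the target `ρ_S` — is mapped through the standard-normal CDF and each
factor's quantile function. Marginal families: uniform, truncated
normal, lognormal. The generator uses NumPy's seeded PCG64, so a given
spec and seed reproduce byte-identical tables across runs and
platforms.

Default marginals sit on the scales real small-area breast-cancer
tables show — mortality ≈ truncated normal (25.5, 3.5) on [15, 40] per
100,000 women, incidence ≈ (96, 5) on [75, 115], percentages uniform
over their observed ranges (e.g. uninsured 6.1–18.3%), income lognormal
with median ≈ \$52,000 — chosen once to bracket the published quartile
ranges of the middle-Tennessee tables. The `paper-like` dependence
preset sets mortality's rank correlation to +0.4 with non-screening
and uninsurance and −0.4/−0.3 with income/education; the **signs**
follow the qualitative trends such analyses report, the **magnitudes
are illustrative**, not estimated (the raw per-region vectors behind
the published correlations were never released).

What the generator does *not* emulate: spatial autocorrelation between
adjacent regions, population-size-driven sampling noise on rates
(rates are drawn directly, not as Poisson counts over populations),
and missingness. Passing tests therefore demonstrate correctness of
the scoring and correlation machinery under known dependence — not
that the illustrative dependence magnitudes describe any real
population.

## Reference fixtures

`reference_fixture("county"|"zip")` returns the published quartile-rank
matrices (11 counties × 9 factors; 23 ZIPs × 7 factors) with the
default weighting. These are *ranks*, not raw values; they provide
exact ground truth for the integrated-score and priority stages, and
no ground truth at all for the correlation stage (hence the
property-based testing of that stage instead).

## Numerical and design choices

* Percentages are stored 0–100 as printed; region ids are opaque
  strings (ZIP codes keep leading zeros); no geocoding.
* Number parsing strips currency symbols and comma thousands
  separators ("$13,523" → 13523), locale-independent decimal point.
* Tied raw values always share the lower applicable bin in both
  methods, keeping rank a pure function of value.
* Non-PSD dependence matrices are rejected with the offending
  eigenvalue (tolerance −1e−10 on the smallest eigenvalue of the
  converted latent matrix; tiny negative eigenvalues from roundoff are
  clipped to zero in the factorization).
* The GeoJSON join annotates feature properties only and never touches
  geometry; unmatched regions and features are reported, not dropped.

## Problem sizes used in the test suite

Exact score checks run at the published sizes (11 and 23 regions).
Copula-fidelity checks use n = 10,000 regions (empirical Spearman
within ±0.02 of target, Kolmogorov distance ≤ 0.02 per marginal);
Fisher-interval coverage uses 2,000 bivariate-normal replicates at
ρ = 0.5, n = 30 (nominal 95%, accepted band 93–97%); scoring
invariants are checked on 500 randomly generated tables of 4–15
regions. These sizes give sampling error comfortably inside each
acceptance band while keeping a full suite run under half a minute.

## Known limitations

* Quartile scoring discards within-quartile variation; two regions at
  opposite ends of quartile 4 score identically.
* Equal weights (with the double weighting of incidence and mortality)
  encode a judgment, not an estimate; no data-driven weighting is
  offered, by design.
* No spatial statistics (Moran's I, cluster scans) or regression
  modeling; the method is descriptive prioritization.
* The exact Spearman p-value enumerates `n!` permutations and is
  limited to `n ≤ 8`; larger groups get the t-approximation.
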