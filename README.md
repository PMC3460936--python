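# regionrisk

Quartile-based small-area risk scoring and correlation analysis for
regional cancer-mortality disparities.

Community health programs — cancer coalitions, health departments,
philanthropic affiliates — must decide where to place screening vans,
patient navigators and education outreach with nothing finer-grained
than county- or ZIP-level census and registry extracts. `regionrisk`
implements a simple, auditable prioritization method for exactly that
setting: each small geographic unit is ranked into quartiles on every
risk factor, the quartile ranks are combined into a weighted integrated
score, and the regions with the highest scores — together with the
specific factors sitting in their worst quartile — identify both *where*
to intervene and *what kind* of resource would help.

## The method

For each risk factor $f$ (breast-cancer incidence and mortality per
100,000 women, % female population over 50, % Stage IV diagnoses, %
diagnosed without prior screening, % uninsured females, median household
income, educational attainment, % non-white population), each region is
assigned a quartile score $q_f \in \{1,2,3,4\}$, with 4 always the
**highest-risk** quartile. Factors where a *larger* value means *lower*
risk (income, education) are coded with `direction: inverse`, which
reverses the quartile numbering ($q \mapsto 5-q$). Two binning rules are
supported: `cutpoint` (empirical 25/50/75th-percentile cut-points; ties
always share a bin) and `equal_count` (contiguous blocks as equal as
possible, remainders to the lowest bins; 11 regions split 3/3/3/2).

The **integrated quartile score** of a region is

$$S = \sum_f w_f \, q_f,$$

with integer weights $w_f \ge 1$; the default configuration weights
incidence and mortality double ($w=2$) and everything else single, so
$S$ ranges over $[\Sigma w, 4\Sigma w]$ — 11–44 for the nine-factor
county layout, 9–36 for the seven-factor ZIP layout. Regions are ranked
by descending $S$ (ties share the best rank).

Around the score, the package provides:

* **Correlation analysis** — Pearson $r$ with a Fisher-$z$ 95% CI
  ($\operatorname{atanh} r \pm z_{0.975}/\sqrt{n-3}$; the full $[-1,1]$
  at $n=3$) and Spearman $\rho$ on mid-ranks with an *exact*
  permutation p-value for $n \le 8$ — between mortality and each factor,
  pooled and within geographic groups (ZIPs within a county). Group
  sizes in this setting are tiny, so the small-$n$ conventions matter.
* **Synthetic data** — a Gaussian-copula generator producing region
  tables with specified marginals (on realistic scales) and a target
  Spearman correlation matrix, via the latent-normal conversion
  $\rho_P = 2\sin(\pi\rho_S/6)$, for end-to-end testing with known
  ground truth.
* **Reference fixtures** — the published quartile-rank matrices of the
  middle-Tennessee community-profile analysis this package
  operationalizes (11 counties × 9 factors; 23 Davidson County ZIP
  codes × 7 factors), usable as exact ground truth for the scoring
  stage.
* **Reporting** — a priority report flagging each region's quartile-4
  ("modifiable target") factors, and a GeoJSON property join for
  choropleth mapping in any GIS tool.

## Worked example

Score the published county rank matrix and read off the priorities:

```python
import regionrisk as rr

ranks, specs = rr.reference_fixture("county")
table = rr.score_from_ranks(ranks, specs)
for row in table.rows[:4]:
    print(row.region_id, row.integrated_score, row.priority_rank)
```

```
Trousdale 42 1
Maury 34 2
Davidson 33 3
Dickson 29 4
```

Trousdale — quartile 4 on eight of nine factors — has the maximum
possible mortality/incidence contribution and tops the priority list
with 42 of a possible 44; Rutherford sits last at 20. A correlation on
five small-area rate pairs shows the small-sample behaviour:

```python
res = rr.pearson_with_ci([84.9, 93.5, 97.8, 99.8, 103.7],
                         [19.1, 25.6, 22.1, 27.3, 34.4])
print(f"r={res.estimate:.3f} CI=({res.ci_low:.3f}, {res.ci_high:.3f}) "
      f"p={res.p_value:.3f} n={res.n}")
```

```
r=0.840 CI=(-0.163, 0.989) p=0.075 n=5
```

A strong point estimate whose Fisher interval still spans zero at
$n=5$ — the reason the package reports intervals, not just estimates.

The same operations are available from the shell:

```sh
regionrisk simulate --seed 17 --n-regions 12 --n-groups 3 --out synth.csv
regionrisk score --input synth.csv --factors factors.yaml --out scores.csv
regionrisk correlate --input synth.csv --factors factors.yaml \
    --pairs mortality_rate:median_income --out corr.csv
regionrisk fixture --level zip --out zip_ranks.csv
regionrisk report --input synth.csv --factors factors.yaml --out-dir out/
regionrisk join-geo --scores scores.csv --geo regions.geojson --out map.geojson
```

`factors.yaml` is a list of `{name, direction, weight, units}` entries;
see `docs/methods.md` for the default configurations.

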