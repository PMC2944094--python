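# rifkit

Small-area environmental epidemiology in Python: standardized rates and
risks, distance-band risk analysis around putative pollution sources, and
Bayesian disease mapping — the analytical core of a "rapid inquiry"
workflow for health departments and registry analysts who need to answer
*"is disease risk elevated around this site / in these wards?"* from
routinely collected, aggregated health and population data.

## What it computes

**Indirect standardization.** Reference-population stratum rates r_s
(sex × age band, optionally year and a deprivation quintile) are projected
onto the study population's person-years n_s to give expected counts
E = Σ_s n_s r_s; the SIR/SMR is O/E with a 95% CI from Byar's cube-root
approximation to the exact Poisson interval (exact chi-square inversion
available). Directly standardized rates use study stratum rates weighted by
a standard population, with Fay–Feuer gamma CIs. Area-level socioeconomic
adjustment via a Carstairs-style deprivation index (z-score sum of male
unemployment, lack of car access, low social class, overcrowding) in
quintiles.

**Risk analysis.** Half-open distance bands [d_(k−1), d_k) around one or
more sources (points, lines, or polygons; distance to the *nearest*
source); areas join a band by geometric or population-weighted centroid.
Per-band SIRs plus a chi-square homogeneity test (df = K−1) and a Poisson
score test for log-linear trend in risk with distance.

**Disease mapping.** Per-area relative risks smoothed two ways:
empirical Bayes under a Poisson-gamma model (shrinkage toward the global
mean, prior fitted by negative-binomial marginal likelihood) and a fully
Bayesian Besag–York–Mollié model log RR_i = μ + u_i + v_i with an ICAR
spatial effect u and unstructured effect v, fitted by a seeded
Metropolis-within-Gibbs sampler (shrinkage toward the local mean).
Posterior exceedance probabilities Pr[RR_i > 1 | data] classify areas as
*elevated* (mean RR > 1 and exceedance > 0.8), *lowered* (RR < 1 and
exceedance < 0.2), or *uncertain*.

A synthetic-study generator (lattice geographies, stratified person-years,
Poisson counts under known RR surfaces) makes the whole pipeline testable
without any registry data.

## Worked example

```python
import numpy as np
from rifkit import standardize, riskanalysis

# Published-style two-band refinery analysis: observed and expected
# non-Hodgkin lymphoma counts, males, by distance band (outer, inner).
outer = standardize.indirect_ratio(148, 118.23)
print(outer.rounded())          # (1.25, 1.06, 1.47)

tests = {
    "homogeneity": riskanalysis.homogeneity_test([148, 184], [118.23, 165.75]),
    "trend": riskanalysis.trend_test([148, 184], [118.23, 165.75], [3.75, 1.25]),
}
for name, t in tests.items():
    print(name, round(t.statistic, 3), round(t.p_value, 4))
# homogeneity 1.185 0.2763
# trend 1.089 0.2763
```

The SIR 1.25 (95% CI 1.06–1.47) says male NHL incidence in that band ran
25% above what state reference rates predict. The homogeneity and trend
statistics (X² = z², two bands) do not reject constant risk across bands at
the 5% level.

End-to-end on synthetic data, from the shell:

```sh
rif synth --seed 7 --out fixture/           # geography + counts + truth
rif bands --counts fixture/counts.csv --population fixture/population.csv \
    --reference fixture/reference_rates.csv --areas fixture/areas.geojson \
    --sources sources.geojson --breaks 2500,5000 --out bands_out/
rif map --counts fixture/counts.csv --population fixture/population.csv \
    --reference fixture/reference_rates.csv --areas fixture/areas.geojson \
    --adjacency fixture/adjacency.txt --seed 1 --out map_out/
```

`rif map` writes a per-area CSV (raw, EB, and full-Bayes RR, exceedance,
classification) and a GeoJSON carrying the same properties for choropleth
rendering.

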