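# Methods

## Data model

Health events and person-years are aggregated tables keyed by
(area, sex, age band, year, optional covariate quintile). The age-band
structure is declared by the caller at load time rather than hard-coded,
because routine registries band populations differently; fixtures use
eighteen 5-year bands 0–4 … 85+. Disease latency is handled by the caller
shifting the year filter (e.g. restricting events to ≥5 years after
exposure onset), not by a dedicated mechanism — latency assumptions are
study-specific and belong in study design, not in the table plumbing.

Intercensal populations are interpolated cellwise and linearly between
census tables with identical stratum structure; interpolation is exact at a
census year and refuses to extrapolate beyond the census hull unless
explicitly allowed (linear extension of the nearest segment, clipped at
zero). Covariate quintiles sit at the 20/40/60/80th percentiles of the
area-value distribution; a value exactly on a boundary goes to the lower
quintile (a documented tie-break — the convention is arbitrary but must be
deterministic).

ICD code filters expand inclusive ranges at the three-character category
level ("C82–C85" → C82, C83, C84, C85) within one coding system; ICD-10
ranges may not cross letter chapters. Expansion is sorted and deduplicated,
hence idempotent and order-invariant.

## Geography

All geometry is planar with metric units. Geographic (lon/lat) input is
refused: buffering in degrees is meaningless, and rather than carry a
projection engine the package requires reprojection upstream (any GIS or
pyproj one-liner). Geometries travel as GeoJSON; adjacency as neighbour-list
text (`area_id n nbr1 …`).

Distance bands around one or more sources are half-open annuli
[d_(k−1), d_k) of distance to the *nearest* source (equivalently, buffer
rings of the source union). Area selection is by centroid: geometric
centroids are recomputed from the polygons, population-weighted centroids
are supplied as data (they cannot be derived from boundaries alone).
Selection uses the exact centroid-to-source distance rather than
point-in-polygon on buffered rings, so the half-open tie-break (a centroid
exactly at a break belongs to the outer band) holds exactly and assignment
is always a partition. Unassigned areas are excluded from band analyses but
retained in mapping analyses.

Contiguity adjacency: queen = any shared boundary point, rook = shared edge
of positive length. Isolated areas are allowed and flagged.

## Standardization

Expected counts are E = Σ_s n_s r_s over the adjustment strata; the
indirect ratio is O/E. The default 95% CI is Byar's cube-root approximation,

    lower = O (1 − 1/(9O) − z/(3√O))³ / E        (0 when O = 0)
    upper = (O+1) (1 − 1/(9(O+1)) + z/(3√(O+1)))³ / E,

which agrees with the exact (Garwood) interval to well under 0.01 on the
ratio scale for O ≥ 20; the exact chi-square inversion is available via
`method="exact_poisson"`. Report tables round half-even to 2 dp; internal
values are never rounded. When reference rates are built from raw
reference tables, the whole-region reference *includes* the study areas by
default (as when a state's own rates are the comparison for districts
within it); `exclude_areas` removes them.

Directly standardized rates are per × Σ_s w_s (o_s/n_s) with normalized
standard-population weights; the CI is the Fay–Feuer gamma interval, whose
upper bound stays honest at small counts where the normal approximation
fails.

The Carstairs-style deprivation index is the unweighted sum of area-level
z-scores of four census proportions (male unemployment, lack of car access,
low social class, overcrowding), the index's conventional construction; a
zero-variance component carries no ranking information and is dropped with
a warning rather than poisoning the sum with 0/0.

## Band tests

Both tests condition on the overall ratio θ̂ = ΣO/ΣE, matching standard
SMR heterogeneity practice, with no continuity correction. Homogeneity:
X² = Σ (O_k − θ̂E_k)²/(θ̂E_k) on K−1 df. Trend: Poisson score test with
U = Σx_kO_k − θ̂Σx_kE_k, V = θ̂[Σx_k²E_k − (Σx_kE_k)²/ΣE_k], z = U/√V.
With K = 2 the two coincide (X² = z²), a useful internal consistency check.
Default trend scores are band midpoint distances in km; band rank is
available when distances are not meaningful scores. Bands with E_k = 0 are
dropped from both tests with a warning.

Simulation checks in the test suite: at K = 3 with E = (50, 100, 200) and
5,000 null replicates, both tests reject 3–7% at nominal 5%; under a
monotone gradient (1.5, 1.2, 1.0) the trend test is the more powerful, as
a one-degree-of-freedom directional test should be.

## Empirical Bayes (Poisson-gamma)

RR_i ~ Gamma(α, ν) a priori gives the negative-binomial marginal
O_i ~ NB(α, ν/(ν+E_i)). (α, ν) maximize the marginal likelihood by
L-BFGS-B over (log α, log ν) (bounds e±12, tolerance 1e-8), started from
moment estimates (prior mean ΣO/ΣE; prior variance the E-weighted SMR
variance minus the Poisson component, floored at 1e-4). If the optimizer
fails the moment estimates are used and flagged. The EB estimate is the
conjugate posterior mean (O_i + α)/(E_i + ν): strictly between the raw SIR
and the prior mean α/ν, with shrinkage vanishing as E_i → ∞. Areas with
E_i = 0 are excluded and reported as missing — their risk is not estimable,
and RR 0 would be a fabrication.

## Full Bayes (BYM)

O_i ~ Poisson(E_i e^{μ + u_i + v_i}) with u ~ ICAR(τ_u) (each u_i
conditionally normal about its neighbours' mean with precision τ_u d_i),
v_i ~ N(0, 1/τ_v), flat prior on μ, and Gamma(0.5, 0.0005) hyperpriors on
both precisions — a conventional vague choice, configurable.

The sampler is Metropolis-within-Gibbs:

- random-walk Metropolis for μ and for each u_i and v_i against the Poisson
  likelihood; the v updates are run for all areas simultaneously (their
  full conditionals are independent), and the u updates in graph-colour
  classes (no two adjacent areas in a class), which keeps vectorized
  simultaneous updates exactly equivalent to single-site scans;
- conjugate Gibbs draws for τ_u (shape augmented by half the ICAR rank,
  n minus the number of connected components; rate by half the pairwise
  difference quadratic form u'(D−A)u) and τ_v;
- sum-to-zero recentring of u per connected component after each sweep
  (the standard identifiability treatment for the improper ICAR); isolated
  areas have u_i fixed at 0 and are smoothed only through v.

Proposal scales adapt every 50 sweeps during burn-in toward 30–50%
acceptance and are frozen afterwards, so retained draws come from a fixed
kernel. Defaults are 11,000 sweeps, 1,000 burn-in, thin 5 (2,000 retained
draws); the seed is mandatory and chains are bitwise-reproducible. The test
suite uses 700–12,000-sweep chains sized to each check — the checks
(exceedance of a strong anomaly, null calibration, conjugate moments) are
insensitive to chain length beyond these sizes, and the defaults remain the
recommendation for real analyses.

Correctness is checked three ways: a conjugate harness replaces the Poisson
likelihood with a normal one (edge-free graph, fixed μ and precisions) so
the posterior is available in closed form and the identical kernel must
reproduce its moments; a null field (O = E everywhere) must yield posterior
means near 1 and indecisive exceedance everywhere; and a block anomaly
(true RR 3, E = 50) must be flagged elevated with exceedance > 0.95 in
every block cell. On a spatially correlated truth the BYM posterior means
track the neighbourhood-averaged truth better than EB does — the local-
versus-global smoothing contrast the two models are meant to exhibit. Note
that in a null *region* of an otherwise non-null map, individual areas with
genuinely high observed counts can still earn high exceedance; calibration
claims are therefore about the field, not about every cell.

Exceedance is the fraction of retained draws with RR_i above the threshold
(≥100 draws required); classification uses strict inequalities — an area
with exceedance exactly 0.8 is uncertain.

## Synthetic studies

The generator emulates ward-level registry extracts: an n×n lattice of
square areas (default 20×20, 1 km cells) with queen adjacency; two sexes ×
eighteen 5-year age bands; baseline rates rising log-linearly from 2×10⁻⁵
to 2×10⁻³ per person-year across bands (the age gradient of adult cancers)
with male rates 1.3× female; area person-years log-normal around a median
of 2,000 per stratum cell (σ = 0.5 on the log scale), so sparse areas
exercise the shrinkage machinery the way small wards do. Counts are
Poisson(person-years × baseline × RR_area) under a chosen RR surface:
constant, banded steps around a point source, an ICAR draw (precision 10,
ridge 1e-4 to make it proper, exponentiated and mean-normalized to 1 — a
spatially correlated surface that gives the FB-vs-EB contrast a detectable
signal), or a rectangular block anomaly. The returned reference rates are
the baselines themselves, so expected counts computed downstream equal
person-years × rate exactly and the truth is recoverable.

What the generator does *not* emulate: migration between areas, temporal
rate trends, registration artifacts (local screening, boundary effects,
ICD revision changes), and non-Poisson overdispersion beyond what the RR
surface induces. Passing tests therefore demonstrate the statistical
machinery under clean stratified-Poisson sampling, not robustness to the
data pathologies of real registries.

## Known limitations

- No projection engine: coordinates must arrive in a projected metric CRS;
  shapefile input is not supported (GeoJSON only).
- Exposure is proximity: no plume or dispersion modelling (externally
  modelled exposure surfaces can enter as polygon "bands").
- Ecological analyses only; nothing here supports individual-level
  inference, and the modifiable areal unit problem applies to any chosen
  geography.
- The naive Monte-Carlo SE reported by the BYM fit ignores autocorrelation;
  for publication-grade uncertainty on posterior summaries, thin harder or
  compute an effective sample size from the retained draws.
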