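# Methods

## Model and procedure

`treeassoc` treats each species' stems in a rectangular plot as a marked
point pattern: locations in metres (origin at the plot's lower-left
corner), DBH in centimetres as a continuous mark and a surrogate for
developmental stage. Two second-order summaries are computed per species
pair on a distance grid:

* **Intertype L, `lrs_hat`** — an edge-corrected, intensity-normalised
  cumulative count of inter-type pairs within distance *d*, implemented
  exactly as the normalisation
  `1/((λ_r+λ_s)(n_r+n_s)π) · (S_rs/n_r + S_sr/n_s)` with directional
  edge-weighted pair sums `S`. No square-root (variance-stabilising)
  transform is applied; the statistic is compared against its own Monte
  Carlo null band, so only ranks matter and the transform would not change
  any decision.
* **Intertype mark correlation, `kmm_hat`** — the edge-weighted mean over
  ordered inter-type pairs within *d* of the product of per-species
  standardised marks. Marks are standardised per species *per plot* with the
  sample standard deviation (ddof=1); the statistic is therefore invariant
  under positive affine transforms of either species' marks and flips sign
  if one species' marks are negated. Lags with no inter-type pair are
  *undefined* (NaN), never zero.

Both statistics use a closed ball (`d_ij ≤ d`) and are symmetric in their
arguments (the two directional sums swap).

### Edge correction

Ripley's isotropic correction for a rectangular window is the default: each
pair's indicator is divided by the fraction of the circle of radius `d_ij`
centred on the focal stem that lies inside the window. The fraction is
computed in closed form by inclusion–exclusion over the four edge
half-planes and four corners; the formula is exact while a circle cannot
reach two opposite edges at once, which holds whenever the maximum analysis
distance is at most the shorter window side (the default 50 m cap in a
100 m window is half that bound). A pure-indicator mode (`corr="none"`) is
also provided; the estimator is then monotone in *d* but biased low near the
boundary, and its small-*d* CSR expectation is `d²/(n_r+n_s)`.

### Null models and envelopes

* Spatial independence (for L): **toroidal shift** — one pattern is rigidly
  translated by a uniform random vector with the window treated as a torus.
  This preserves each marginal pattern's internal (toroidal) second-order
  structure exactly. The species with fewer stems is shifted; the choice is
  recorded in the envelope metadata and is irrelevant to the statistic's
  symmetry.
* Mark independence (for Kmm): **random marking** — stem positions fixed,
  marks permuted uniformly within each species. Permuting within (not
  across) species preserves each species' mark distribution, which the
  per-species standardisation presumes.

Envelopes are pointwise rank quantiles over `n_sim` simulations (default
399): with α = 0.05 the bounds are the k-th lowest/highest simulated values,
`k = floor(α/2 · (n_sim+1))` — the 10th of 399, the 1st of 19. The nominal
pointwise two-sided error is `2k/(n_sim+1)`: exactly 5% at 399 simulations,
4% (slightly conservative) at 99. Simulated mark-correlation curves
undefined at a lag are excluded from that lag's bounds.

The **quasi p-value** at a lag is the Monte Carlo rank p on the side of the
empirical deviation from the null median:
`p = (1 + #{sims as or more extreme})/(n_sim + 1)`, bounded below by
`1/(n_sim+1)`. The acceptance threshold (default 0.01) is applied pointwise
at the representative distance; no simultaneous (global) envelope test is
implemented.

### Replication and pooling

Each plot's curves are standardised by the affine map sending that plot's
null band to [−1, 1] (`b = 2/(N_sup − N_inf)`, `a = 1 − b·N_sup`); lags with
a degenerate band are carried as missing. The pooled curve is the per-lag
mean over replicates with a defined value — generalising the three-plot
average to however many plots remain usable after the abundance filter.
Associations are runs of lags where the pooled curve leaves [−1, 1]; the
**strict coincidence rule** (default for replicated runs) additionally
requires every usable replicate to deviate on the same side at the lag,
suppressing one-plot flukes. The relaxed pooled-only rule is available.

The **representative distance** of an association is the in-run lag with the
largest exceedance `|F̂_st| − 1`; because the standardised scale divides the
raw deviation by the local half-width of the acceptance band, this is the
"most significant" point weighted by the null band's local extent. Ties
break toward the smallest distance. Each pair contributes at most one
record per statistic.

For replicated pairs the quasi-p at the representative distance is the rank
of the pooled standardised empirical value within the **pooled standardised
null ensemble**: each plot's simulated curves are standardised by that
plot's own band and averaged across plots simulation-by-simulation (plots
are independent, so the pairing of simulation indices is arbitrary). With a
single plot the standardisation is a monotone per-lag transform, so this
reduces exactly to the pointwise rank p. The alternative of taking the
maximum per-plot p was rejected: its floor is still `1/(n_sim+1)` but it is
reached only when every plot's empirical value beats all of its own
simulations simultaneously — with 99 simulations per plot that makes a 0.01
threshold effectively unattainable — and it double-counts the coincidence
requirement, which the strict rule already enforces.

### Abundance filter

A species enters the analysis only with strictly more than 60 stems
(configurable) in a plot; with replicated plots it must clear the threshold
in at least 2 plots (configurable), and deficient plots are dropped from
that species' replicate set. Each census row is treated as one individual;
multi-stemmed plants are not collapsed.

## Synthetic stands

The generator emulates replicated 1-ha censuses of clustered tropical tree
species:

* **Point processes**: CSR, or a Thomas process — Poisson parents (default
  mean 20/ha placed uniformly), Gaussian offspring dispersal (default
  σ = 5 m), offspring wrapped toroidally so intensity is preserved; stem
  counts are fixed per species, not Poisson.
* **Planted interactions**: `linked_clusters` shares one parent set between
  two species (each marginal remains an ordinary Thomas pattern);
  `repulsion_hardcore` resamples one species' stems until none lies within
  the hardcore distance of the other (error if infeasible after 200 rounds).
* **Marks**: lognormal DBH (defaults μ = 2.3, σ = 0.6 on the log-cm scale,
  i.e. a ~10 cm median with a realistic right skew). `cohort` /
  `nursery` structures drive log-DBH with a smooth stationary Gaussian
  random field (random Fourier features, squared-exponential covariance,
  default 10 m length-scale) shared between the two species, with the
  nursery species taking the negated field; heights follow a noisy
  allometry on DBH and carry no signal.

What the generator does **not** emulate: habitat or terrain covariates and
the induced intensity inhomogeneity, species interactions of more than two
species, measurement error in coordinates or DBH, and multi-stemmed
individuals. Passing recovery tests therefore demonstrate correctness of
the estimators, null models and decision rules under stationary clustered
patterns — not robustness to habitat confounding, which the toroidal-shift
null does not claim to remove.

## Numerical choices

* Distance grid: 100 lags of 0.5 m up to 50 m (configurable); the 50 m cap
  is half the shorter side of a 1-ha plot.
* Estimator implementation sorts the flattened inter-type distance matrix
  once and reads cumulative weighted sums per lag; random-marking envelopes
  reuse the pair geometry and permute standardised marks only. Equality with
  a naive O(n²) double loop is enforced to 1e-10 in tests.
* Edge-weight denominators are floored at 1e-12; with the 50 m cap the
  circle fraction never actually approaches zero.
* Per-pair RNG substreams derive from the run seed plus a CRC of
  (species pair, plot, statistic), so any pair re-runs bit-identically in
  isolation and results are invariant to scheduling and to census row order
  (stems are canonically sorted before analysis).
* Degenerate inputs: empty patterns and constant marks raise errors naming
  the species; envelope bounds at all-undefined lags are NaN and excluded
  from detection.

## Problem sizes in the shipped checks

The test suite and `scripts/acceptance.py` use sizes chosen to give stable
Monte Carlo estimates on a single CPU: 500 independent CSR datasets
(n = 100 per species, 99 simulations) for envelope calibration; 100 seeded
stands (n = 150 per species) for each recovery experiment; 300–1000 random
small patterns for oracle equivalence. Recovery is scored on envelope
excursions of the correct sign, matching how the detection rules operate.

## Known limitations

* The toroidal shift conflates habitat-driven co-aggregation with direct
  association; with a single unreplicated plot, significant excursions
  should be read as "spatial dependence", not mechanism.
* The pointwise 0.01 rule at a data-chosen distance is anti-conservative in
  the usual multiple-comparison sense; the expected false-positive count
  (α × number of pairs) is reported in every manifest for exactly that
  reason, and no further multiplicity correction is applied.
* The printed-form L statistic (no square root) has variance increasing
  with *d*; envelope width grows accordingly, which the standardisation
  absorbs but plots of raw curves should keep in mind.
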