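# treeassoc

Pairwise spatial-association analysis for stem-mapped forest censuses.

In species-rich forests, pairs of tree species can be spatially attracted
(growing together more than chance allows), repelled, or independent — and
those relationships can differ between life stages, with large stems of one
species sheltering small stems of another. `treeassoc` detects both kinds of
structure from a standard stem map (one row per free-standing woody plant:
plot, x/y coordinates, species, DBH, height) using second-order point-pattern
statistics, Monte Carlo null models and simulation envelopes, with support
for replicated plots.

## The statistics

For two species *r* and *s* with `n_r`, `n_s` stems and intensities
`λ_r = n_r/A`, `λ_s = n_s/A` in a plot of area *A*, the **intertype L
function** is

```
L̂_rs(d) = 1 / ((λ_r + λ_s)(n_r + n_s)π) · ( Σ_i Σ_j ω_ij(d)/n_r + Σ_i Σ_j ω_ji(d)/n_s )
```

where `ω_ij(d)` indicates inter-type pairs closer than *d*, optionally
divided by Ripley's isotropic edge-correction factor (the fraction of the
circle through the pair, centred on the focal stem, lying inside the plot).
For independent patterns its expectation is `d²/(n_r + n_s)`; excursions
above/below a null band indicate attraction/repulsion.

The **intertype mark-correlation function** `K̂mm_rs(d)` is the
edge-weighted mean, over inter-type stem pairs within *d*, of the product of
per-species standardised DBH marks `(m_i − m̄_r)/s_r · (m_j − m̄_s)/s_s`.
Positive values: similarly sized (same-stage) stems of the two species
co-occur. Negative values: large stems of one species sit among small stems
of the other (a nursery-like pattern).

Null models: **toroidal shift** (one pattern rigidly translated on the
torus; tests spatial independence for L̂_rs) and **random marking** (marks
permuted within species, positions fixed; tests mark independence for
K̂mm_rs). Envelopes are pointwise rank quantiles of 399 simulations by
default; significance at the representative distance uses the Monte Carlo
rank quasi-p `(1 + #{sims as extreme})/(n_sim + 1)`.

For replicated plots, each plot's empirical curve is mapped by the affine
transform that sends that plot's null band to exactly [−1, 1]
(`F̂_st = a(d) + b(d)F̂`, `b = 2/(N_sup − N_inf)`, `a = 1 − b·N_sup`), and
the per-plot curves are averaged. An association is reported where the
pooled curve leaves [−1, 1] — under the strict coincidence rule, only where
every usable plot deviates on the same side.

## Worked example

Simulate three replicate 1-ha plots with three clustered species, a planted
attraction between *cecropia* and *miconia* (shared cluster parents) plus a
planted nursery mark structure (large *cecropia* among small *miconia*),
then analyse them:

```
$ assoc simulate --config sim.yaml --out syn
wrote 1260 stems over 3 plots to syn/

$ assoc run --config run.yaml        # n_sim: 99, seed: 42, rule: strict
species analysed: 3
lrs: 1 associations (1 positive, 0 negative)
kmm: 1 associations (0 positive, 1 negative)
expected false positives per statistic: 0.2

$ assoc pair --config run.yaml --a cecropia --b miconia
lrs: + at 2.5 m (interval 1.5-18.0 m, quasi-p 0.0100)
kmm: - at 13.5 m (interval 1.5-30.0 m, quasi-p 0.0100)
```

The run recovers exactly the planted structure and nothing else: the linked
pair is spatially attracted (positive L̂_rs excursion, strongest at 2.5 m,
inside the 5 m planted cluster scale), and its marks are anti-correlated
(negative K̂mm_rs — the nursery signal), each at the smallest quasi-p
attainable with 99 simulations. `ocotea`, generated independently, shows no
association. The reported expected false-positive count (α × number of
pairs) is the bookkeeping to hold against small association counts.

The same flow works on real data: `assoc ingest --census file.csv` validates
a stem map and reports the abundance filter (by default a species is
analysed only where it has more than 60 stems per plot), and
`assoc run` accepts trait and species–habitat tables to produce guild
cross-tabulations and habitat-concordance counts.

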