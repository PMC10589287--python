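# Methods

## Score and model

The Metabolite Exchange Score of a metabolite in one sample is the
harmonic mean of its producer count P (species with an export flux
above tolerance) and consumer count C (import above tolerance):
MES = 2·P·C/(P+C), defined as 0 when either count is 0. The harmonic
mean is deliberate: it is dominated by the smaller of the two counts,
so a metabolite produced by forty species but consumed by one scores
barely above one. Counts, not fluxes, enter the score — MES measures
the *redundancy* of an exchange, not its magnitude; flux magnitudes are
used downstream in the attribution analyses.

Fluxes are taken as given from community metabolic modelling (units
mmol·gDW⁻¹·h⁻¹); nothing here runs or checks a flux-balance solver.
A species with both an export and an import record above tolerance for
the same metabolite counts once in P and once in C; dual-role species
are common in community models and no exclusivity rule is imposed.

### Calling tolerance

A flux qualifies a species as producer/consumer when it exceeds
1 × 10⁻⁶ mmol·gDW⁻¹·h⁻¹ (`--tolerance`). Solver outputs carry numerical
noise near zero; results should be reported alongside the tolerance
used. Raising the tolerance can only shrink P and C (tested property).

## Cohort comparisons

Per disease, metabolites are screened before testing: exchanged
(MES > 0) in ≥ 50 individuals of the pooled healthy+disease samples,
≥ 15 of them diseased; water (`h2o`) and oxygen (`o2`) are excluded as
trivially universal. Each surviving metabolite gets a two-group
Kruskal–Wallis test (df = 1) of per-sample MES, healthy vs disease,
with the Bonferroni threshold alpha / (number of metabolites in that
disease's family). A "one-sided" reading is realized by gating:
a result counts as a significant loss only if p < threshold *and* the
disease mean is lower (`--one-sided-mode gate`); halving the two-sided
p in the observed direction is available (`halve`). Direction uses
cohort means to match the delta used for ranking (`--direction-stat
median` switches both to medians). Ranked losses keep significant
reductions only, sorted by delta (healthy − disease mean MES)
descending, top 5 per disease, lexicographic tie-break.

Samples in which a screened metabolite has no entry score MES 0 there
(an unexchanged metabolite's defined score) rather than being dropped;
`zero_fill=False` gives the drop behaviour. The choice matters only for
metabolites absent from many samples, which the ≥ 50-individual screen
already disfavours.

Alpha diversity: richness S = taxa with abundance > 0; Shannon
H′ = −Σ aᵢ ln aᵢ in nats (the log base is a reporting convention; rank
tests are unaffected). Cohort comparisons use two-sided Wilcoxon
rank-sum with Holm adjustment within each index's family of diseases.

## Richness slopes

Each (sample, metabolite) pair contributes two observations — producer
count and consumer count — and OLS fits
`count ~ richness * category` per metabolite (≥ 50 distinct samples
required). The two-sided t-test p of the interaction term, against
alpha / (metabolites fitted), classifies metabolites as
consumer-steeper, producer-steeper, or no-difference. OLS with
homoskedastic errors is the default although counts would suggest a
GLM; fidelity to the standard `lm` practice for this analysis wins, and
the interaction contrast is robust to the variance misspecification at
these sample sizes. `--log-link` switches to a Poisson GLM with log
link (slopes then live on the log scale). Pairs where the metabolite is not exchanged
contribute no observations by default (`include_zeros` is deliberately
not offered: a P=C=0 pair is indistinguishable from "not modelled").

## Flux attribution

For one focal metabolite: per-sample production = Σ export flux ×
relative abundance over taxa, consumption likewise over imports;
excess = production − consumption (net export to the medium, may be
negative). Ratios P/C and production/consumption are NaN-flagged when
the denominator is zero and excluded from ratio tests. Totals are
log₂-transformed for testing; a zero total is replaced by half the
smallest nonzero total of that quantity (the transform needs a
pseudo-count and the data give no natural one — the choice is flagged
in output and only affects samples with literally no qualifying flux).

Cohort comparisons of these quantities reuse the gated Kruskal–Wallis
machinery. Where cohort sizes differ, the larger cohort is down-sampled
without replacement to the smaller one's size with a seeded generator
before weighted sums are compared (`--no-balance` to skip). Key-species
ranking: per taxon and role, the weighted flux sum within each balanced
cohort and their difference (delta); producers are ranked by increase
in disease, consumers by decrease. A taxon absent from a cohort simply
contributes 0 there, so cohort-exclusive species rank naturally.
Swapping the cohort order negates every delta exactly (tested).

The diversity-confounder model is OLS of a response (count or
log-flux) on a disease indicator plus richness, restricted to samples
with ≥ 99 species — nesting the comparison inside the richness range
where the relationship is near-linear — reporting the disease
coefficient and its two-sided t-test p.

## Gene association

Per sample a gene is summarized by prevalence (number of present taxa
carrying ≥ 1 copy) or abundance (Σ copies × relative abundance). Each
gene passing the filters (samples with ≥ 100 species; gene observed in
≥ 10 retained samples) is tested by OLS of log(value + 0.1) on disease
plus richness, Bonferroni-corrected over the genes tested in that mode.
The 0.1 offset keeps zeros finite under the log; natural log is used
(the base rescales coefficients, not p-values).

A caveat found during validation: the log transform is concave, so when
a planted effect shifts the two cohorts' richness *ranges* apart, a
linear richness covariate cannot fully absorb a purely
richness-mediated gene signal, and false positives can exceed the
nominal rate. The null-control benchmark therefore plants carriage
independent of cohort with no community effect; users comparing cohorts
with very different richness distributions should interpret borderline
gene hits cautiously.

## Synthetic communities

The generator emulates the statistical layout of community-FBA outputs,
not metabolism: no mass balance, no growth coupling, no correlation
structure between metabolites beyond shared richness.

Defaults: a pool of 150 species × 60 metabolites; per metabolite a
species is producer-only with probability 0.15, consumer-only 0.2,
dual-role 0.05 (each may be set per metabolite; every metabolite is
redrawn until it has ≥ 1 potential producer and consumer). Community
size (richness) is uniform over 34–236 — the span observed in modelled
gut communities — clipped to the pool size, since a sample cannot hold
more species than exist. Flux magnitudes are lognormal(μ = 0, σ = 1)
(median 1 mmol·gDW⁻¹·h⁻¹, right-skewed like pFBA exchange magnitudes);
raw abundances lognormal(0, 1.5), renormalized per sample — heavy-
tailed, so a single taxon can dominate a sample, as in real gut data.

Planted effects are species-level: a "lost" consumer loses that
capability in every disease sample, mimicking disease-associated
extinction of a cross-feeding partner, with optional full removal of
the species from disease communities (`remove_lost_species`, needed
when a species-linked signal such as gene carriage should shift too)
and per-role or per-species flux scaling. The identity effect
reproduces the null byte-for-byte. Every planted truth — realized
capabilities, removed species, per-sample P/C pre/post effect, flux
factors — is written to a ground-truth manifest that brute-force
recounts of the generated files must match exactly (tested).

What passing recovery tests shows: the pipeline detects the planted
effect classes at the stated sizes under this noise model. What it does
not show: performance under real-world complications the generator
omits — compositional correlations between metabolites, study batch
effects, model-reconstruction error, strain-level variation.

## Validation benchmarks and problem sizes

`mescore.benchmarks` (backing both `tests/test_acceptance.py` and
`scripts/acceptance.py`) uses these study conditions:

- **Formula exactness** — every (P, C) in 0..100², against exact
  rational arithmetic.
- **Matrix oracle** — 200 samples × 20 metabolites; pipeline scores vs
  an independent per-record recount; agreement must be exact.
- **Planted consumer loss** — 30 metabolites, 40 vs 40 samples, half
  the target's consumer species lost, 20 seeds; success = ranks #1 by
  delta and clears Bonferroni. Under the default uniform richness model
  the per-sample MES spread is dominated by richness (MES ≈ 0.22 × S),
  a 50% consumer loss cuts MES by only ~31%, and the rank-test AUC is
  ≈ 0.74, giving per-seed power around 0.6–0.75: the measured rate sits
  near 0.5, and the ranking component alone is essentially always
  correct. A loss fraction ≈ 0.7 (halving MES) is detected in ≥ 90% of
  seeds (module test).
- **Null family-wise error** — 300 metabolites, no effect, 20 seeds;
  fraction of families with any significant metabolite, expected ≤ 0.05
  within binomial error.
- **Slope recovery** — planted producer density 0.05 vs consumer 0.15
  per richness unit (counts are binomial in richness, so densities are
  slopes), 240-species pool, richness 34–236, 200 samples, 20 seeds;
  plus exact recovery on noiseless data.
- **Key species** — 46 vs 38 samples balanced to 38/38; the consumer
  with the largest weighted flux sum over the balanced healthy subset
  gets a 5× flux deficit in disease and must top the consumer delta
  ranking. Selection on the balanced subset matters because the
  heavy-tailed abundances let a single excluded sample carry most of a
  taxon's sum.
- **Gene recovery** — gene linked to the target's consumers (carriage
  0.9 vs 0.1 background), half those consumers removed from disease
  communities; must test enriched-in-healthy and significant. The
  richness filter is set to the simulated range's minimum (34) so the
  filter machinery runs without discarding the cohort.
- **CLI determinism** — all six subcommands run twice with identical
  arguments; every output file must be byte-identical.

All randomness in a benchmark derives from one master seed via child
seeds below 2³¹.

## Known limitations

- MES counts species, so it inherits MAG/model reconstruction biases;
  absent genomes are absent partners.
- Studies are pooled within cohorts; no batch/random-effect modelling.
- The confounder and gene models are linear in richness; strongly
  nonlinear diversity effects will leak into the disease term (see the
  gene-association caveat above).
- The simulator's fluxes are statistical stand-ins; recovery rates are
  statements about the analysis machinery, not about metabolic-model
  accuracy.
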