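# Methods

## Scope and data model

The pipeline analyzes marker-gene read-count tables (taxa × samples) from
a survey design pairing predator gut samples with ambient water samples at
each station and campaign. One dataset holds one marker (16S rRNA for
phototrophic prokaryotes and plastids, or 18S rRNA for eukaryotes); every
count column is tied to a sample record (gut vs water, predator species,
station, campaign, replicate) and every row to a six-rank lineage
(domain → genus). Counts are strictly non-negative integers on input;
relative abundances are always derived, never stored alongside counts.
Missing lineage ranks are empty strings, and a taxon displayed at a rank
it lacks becomes `Unclassified_<nearest named parent>`.

All validation is total and typed: malformed input raises a
`DataModelError` subclass naming the offending row/column; nothing is
silently coerced.

## Cleaning stages

The fixed stage order is **exclusion → aggregation → (optional station
merging) → quality filter → normalization**. Exclusion and aggregation are
integer-exact (per-sample totals are conserved by construction), so the
order of the first two stages is interchangeable when rules address the
aggregation rank; running exclusion first keeps the audit log at ASV
resolution.

**Exclusion** removes read classes that are not diet: the predator's own
reads (crustacean lineages in 18S data, where gut DNA inevitably contains
the consumer), heterotrophic bacteria in 16S data (indistinguishable from
gut symbionts without further work), and epibiont lineages such as
Euglenozoa. Rules are exact label matches at a named rank, optionally
scoped to one marker, so a single rule list serves mixed studies.

**Aggregation** follows the usual display conventions: 16S at class
level; 18S at order level with photoautotrophic classes routed to class
level via override rules. A taxon matched by two overrides is a
configuration error, not a tie to be broken silently.

**Quality filter.** For each (predator, station, campaign) group of gut
replicates, a prey is retained iff

- it appears (≥ 1 read) in at least `min_prevalence` (default **0.40**)
  of the group's replicates, and
- its reads pooled across the group's replicates are at least
  `min_pooled_abundance` (default **0.05**) of the group's pooled total.

Both comparisons are inclusive ("at least") and prevalence is an exact
fraction — no rounding of replicate counts. The abundance condition is
evaluated on pooled reads by default; an alternative reading (mean of
per-replicate proportions, which down-weights deep libraries) is available
as `mode="per_replicate_mean"` and differs exactly when library sizes are
skewed. Water samples are never subject to this filter; it exists to
remove rare, likely spurious prey assignments from diet summaries.

## Selectivity

The standardized forage ratio for prey *i* in gut sample *j* is

    S_ij = (R_ij / Rw_i) / Σ_k (R_kj / Rw_k)

with the sum over the included prey universe. S lies in [0, 1] and sums
to 1; it is invariant to rescaling of either the gut or the water vector,
so raw counts and proportions give identical results. 1/k is the
no-selection reference point.

Zero handling is explicit rather than inferred:

- Prey undetected in the water (Rw_i = 0) have an undefined ratio and are
  **excluded** from the index, reported with a reason. No pseudocount is
  added by default because a pseudocount fabricates electivity for taxa
  with no measured availability; an optional `pseudocount` ε on the water
  vector is available when retaining such prey matters more than that
  distortion.
- Prey absent from the gut but present in the water are kept with S = 0:
  they contribute nothing to the denominator and keeping them gives all
  replicates of a group a common index set.

The water reference for a station/campaign combines the (typically three)
water replicates. The default, `mean_proportions`, averages per-replicate
relative abundances, weighting replicates equally; `pooled_counts` sums
reads first, weighting by sequencing depth. The two coincide exactly when
replicates are identical and differ little when depths are balanced; the
choice is exposed in configuration because neither is canonical.
Selectivity (and diet overlap) are computed on 16S data by convention —
18S read counts are less quantitative across taxa spanning single cells to
multicellular organisms — and the pipeline skips these stages for 18S
datasets.

## Diet overlap

Pairwise diet similarity is (1 − Bray–Curtis) × 100 on relative
abundances, computed between gut replicates (not station means, so
within-station pairs exist and between-station similarity can be compared
to the within-station baseline). Bray–Curtis is a semimetric — symmetric,
zero iff compositions are equal, bounded in [0, 1]; the triangle
inequality is not guaranteed and is not asserted anywhere. Summaries
report the overall mean, the within-group mean and the between-group mean
(group = station × campaign) plus the full per-pair table, since a single
overall mean conflates diet stability across space with replicate
repeatability.

## PERMANOVA

The one-factor pseudo-F is computed directly from squared distances:

    SS_T = (1/N) Σ_{i<j} d_ij²
    SS_W = Σ_g (1/n_g) Σ_{i<j∈g} d_ij²
    F    = ((SS_T−SS_W)/(a−1)) / (SS_W/(N−a)),   R² = (SS_T−SS_W)/SS_T

Significance uses unrestricted label permutation (the appropriate scheme
for a single factor) with the add-one estimator p = (1 + #{F* ≥ F_obs}) /
(1 + n_perm), which is never exactly zero and is bounded below by
1/(n_perm+1). Ties at machine precision (|F*−F_obs| ≤ 1e-12) count as
exceedances, the conservative convention. If SS_W = 0 while groups
differ, F is +∞ with a warning (perfectly separated clusters); an
all-zero distance matrix is an error, not a p-value. Permutations are
vectorized (one einsum per group over the stacked permutation matrix), so
999 permutations on tens of samples cost milliseconds.

Pairwise tests run the same procedure per unordered group pair with
Benjamini–Hochberg adjustment across pairs (the correction is
configurable; BH is the default because no single convention dominates
for pairwise distance-based tests). Each pair's permutation stream is an
independent substream spawned from the root seed, so results are
independent of pair evaluation order.

**Station merging.** Before diet statistics, the pipeline can test
whether stations' water communities are distinguishable (pairwise
PERMANOVA per campaign on Bray–Curtis distances of water replicates) and
pool stations whose adjusted p exceeds `merge_alpha` (default 0.05) in
every campaign. Note the power limit: with three water replicates per
station, the smallest achievable two-group permutation p is ≈ 0.1, so at
that replication the test can only ever justify pooling — which is the
honest state of evidence at n = 3, not a defect of the test.

## Synthetic survey generator

The generator exists so that every stage can be tested against known
ground truth without sequencing data. It emulates:

- **Water communities:** each station has a mean composition; the
  realized community w for a station/campaign is drawn from a Dirichlet
  with concentration `water_concentration × base` (default concentration
  200, giving a few-percent coefficient of variation). Water replicates
  are multinomial reads of w at `water_library_size` (default 50 000
  reads, matching realistic MiSeq per-sample depth).
- **Consumption (Chesson mixing):** a predator with selectivity vector α
  on the simplex has gut composition p_i = α_i w_i / Σ_k α_k w_k. Under
  this model the standardized forage ratio is the exact inverse of the
  generator — S(p(α, w), w) = α in closed form — which yields the
  package's sharpest test: noise-free recovery to 1e-12, and stochastic
  recovery whose error must match an independent Monte-Carlo estimate of
  the estimator's own sampling distribution.
- **Replicate structure:** five gut replicates per predator-station
  (each representing a pool of five individuals) and three water
  replicates, the design the defaults encode.
- **Contaminants:** extra taxa appended to gut columns with lineages that
  the standard exclusion rules match exactly — predator (crustacean)
  reads, heterotrophic (gammaproteobacterial) reads, an euglenozoan
  epibiont. Defaults resolve per marker: 18S gets a 0.72 predator-read
  share (the residual consumer-DNA load a nested-PCR protocol leaves);
  16S gets 0.15 heterotrophic bacteria + 0.02 epibiont, a realistic load
  for universal-primer plastid data. Contaminant reads are added **on
  top** of the prey library as a deterministic top-up
  round(L·f/(1−f_total)), so the expected contaminant share equals f and
  — importantly for testing — a contaminated simulation and its clean
  same-seed twin have byte-identical prey counts. Exclusion therefore
  restores the clean dataset exactly, and downstream results agree to
  1e-12.
- **Randomness:** one root seed; every sample's reads come from a
  substream keyed by (seed, kind, station, campaign, predator,
  replicate) via CRC-hashed SeedSequence keys, so extending the design
  (adding a station or predator) never perturbs existing samples.
- **Overdispersion:** optionally, each replicate's composition is
  redrawn from Dirichlet(overdispersion × p) before multinomial
  sampling, giving Dirichlet-multinomial reads for biological
  between-replicate variability beyond counting noise.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: PCR and primer amplification
bias (read proportions are taken as unbiased estimates of template
proportions), taxonomic misassignment, chimeras, copy-number variation
between taxa, cross-sample contamination, and correlated replicate
structure beyond the Dirichlet overdispersion. On real surveys the
selectivity index inherits all of these upstream distortions.

## Problem sizes and numerical choices

Tests and the acceptance script run the generator at 6–12 taxa, 1–3
stations and 5 000–50 000 reads — sizes where the statistical behavior
under test (estimator bias and variance scaling, permutation calibration)
is already expressed, chosen as the package's own verification design.
Compositions must sum to 1 within 1e-9; exact identities (aggregation
totals, closed-form inversion, oracle agreement) are asserted at 1e-12;
TSV round-trips write floats at 17 significant digits so reload matches
to better than 1e-12. The permutation-test calibration check uses 200
null datasets × 999 permutations, for which the expected rejection rate
at p ≤ 0.05 lies in [0.03, 0.08] up to binomial noise.

## Known limitations

- One-factor PERMANOVA only; no stratified permutation, multi-factor
  designs, or dispersion (PERMDISP) testing — a significant PERMANOVA can
  reflect dispersion as well as location differences.
- No uncertainty intervals on S; replicate spread is the only variance
  indication reported.
- No compositional transforms (CLR/ALR), rarefaction or decontamination
  modeling; the quality filter and exclusion rules are the only
  denoising.
- Electivity indices other than the standardized forage ratio (Ivlev,
  Jacobs) are not provided.
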