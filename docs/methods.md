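# Methods

This note documents the models and procedures the package implements, the
parameter choices that matter, and what the synthetic-data generator does
and does not emulate.

## The catalogue as the frame of reference

All statistics are defined relative to a taxonomic checklist: the set of
accepted species binomials, each species' country-level distribution, a
medical-importance flag, and a map from countries to the seven
biogeographic realms (Afrotropical, Australian, Nearctic, Neotropical,
Oceanian, Oriental, Palearctic). Names flagged as synonyms must not appear;
matching of record names against the checklist is exact (whitespace- and
case-normalised) string equality — fuzzy matching and synonym resolution
are deliberately out of scope, because silently "rescuing" misspelled names
would bias coverage upward.

**Endemism** is defined operationally as a single-country catalogue
distribution. This is the only computable reading when the checklist is the
sole distribution source; an override list can be supplied where finer
knowledge exists.

**Gazetteer.** Country validation is membership (case-insensitive, after
whitespace normalisation) in a gazetteer that defaults to the catalogue's
own country set. Checklist "countries" include sub-national and island
localities that no ISO gazetteer carries, so the catalogue itself is the
most faithful authority; a custom list can be passed where needed.

## Curation chain

Five stages, applied in a fixed order:

1. keep only rows of the requested marker (e.g. `COI-5P`);
2. drop rows without a sequence (gap characters are stripped on ingest and
   sequences validated against the IUPAC alphabet);
3. drop rows whose country is absent or fails the gazetteer lookup —
   coordinates are never used to rescue a missing country, since
   coordinates on such rows are typically the least reliable field;
4. drop rows whose species name has no exact catalogue match;
5. drop **all** rows of any species whose distinct surviving country count
   exceeds its catalogue country count (a species reported from more
   countries than its known range is suspect wholesale, not row by row).

Stage 5 is species-atomic and count-based; it runs after country
validation, so the comparison uses only verifiable countries. Its removal
guarantees the post-curation invariant `n_db_countries ≤ n_cat_countries`
per species, which in turn bounds geographic coverage at 1 and taxonomic
coverage at 100 %. The chain is idempotent and its per-stage accounting
(rows in = removed + out, chained across stages) is validated on
construction.

Cross-repository reconciliation keys on accession with the version suffix
stripped (`AB123456.1 ≡ AB123456`), since the two repositories version
independently and versioned duplicates would otherwise break the
shared/unique partition. BOLD-style records carrying a GenBank accession
absent from the GenBank set are flagged "mined from GenBank".

## Coverage statistics

Taxonomic coverage of a unit (country or region) is
`100 · n_db_species / n_cat_species`, undefined (an error, not ∞) when the
catalogue holds no species there. Region rows aggregate member countries by
**set union** — a species recorded in two countries of one region counts
once. Reported percentages are rounded half-up to two decimals. Geographic
coverage of a species is `n_db_countries / n_cat_countries`.

## Identity search and the barcode gap

The identity engine computes the best local alignment of each pair over
both strands under affine-gap scoring, by dynamic programming (biotite's
optimal aligner with a custom substitution matrix). Defaults — match +2,
mismatch −3, gap open −5, gap extend −2 — approximate megablast and are
configurable. `pident` follows the BLAST convention: identical columns over
alignment length with gap columns in the denominator, and only exact A/C/G/T
equality counts as identity (`N` never matches). On a strand score tie the
plus strand is reported.

Each sequence is queried against the full set including itself; per query
the top-*k* hits (default 100) are retained, ranked by pident descending,
then alignment length descending, then subject id — the length key stops
trivially short perfect local matches from outranking full-length ones, and
the ordering makes output deterministic under input permutation and
relabelling.

Per species, `min_intra` is the minimum pident over conspecific hits and
`max_inter` the maximum over heterospecific hits; the gap is present iff
`min_intra − max_inter > 0`. Keeping self-hits makes the singleton rule
emerge without a special case: a species with one sequence has
`min_intra = 100`, so its gap is absent exactly when some heterospecific
identity reaches 100 (a total match) and present otherwise. Two
conventions the data cannot decide are explicit and configurable: self-hits
can be excluded (`include_self_hits=False`, falling back to the
total-match rule), and a species with no heterospecific hit in the
retained table is called gap-present with a `no_inter_hit` flag — nothing
in its searched neighbourhood is confusable with it. Top-*k* truncation can
only discard the *lowest* conspecific identities, so `min_intra` may be
overestimated for species with more than *k* close conspecific sequences;
affected species trigger a logged warning rather than silent bias.

## Binomial models

Country-level coverage is modelled as binomial counts — of `n_cat` species
in a country, `y` are covered — with a logit link; this is the only trials
structure that uses the catalogue richness. The species-level gap analysis
is Bernoulli. Count predictors are transformed `log(x+1)` then z-scored by
`PredictorTransform` (recorded in the fit); on that scale odds ratios are
per-SD-of-log-count and comparable across predictors. Because the original
analyses' exact predictor scaling is not recoverable, coefficient
*magnitudes* are not meaningful targets — only `OR = exp(β)` consistency
and sign/significance structure.

The GLM is fitted by IRLS (statsmodels, gradient tolerance 1e−8, 100
iterations max) with Wald SEs from the inverse Fisher information;
suspected quasi-separation marks the fit non-converged but still returns
it. The random-intercept GLMM is fitted by Laplace-approximated maximum
likelihood: per group the integral over the intercept is approximated at
its mode (inner 1-D Newton, tolerance 1e−10), and the marginal
log-likelihood is maximised over `(β, σ)` by L-BFGS-B with `σ ≥ 0`;
`σ̂ < 1e−4` sets a boundary flag. Fixed-effect SEs come from the numerical
Hessian of the Laplace log-likelihood (central differences); the σ row is
dropped from the covariance at the boundary. The intercept SD counts as
one parameter in `AIC = −2ℓ + 2k`. On a 20-group × 100-observation
Bernoulli test problem this implementation agrees with a reference mixed-
model fit to four decimals in coefficients, SEs, σ̂ and AIC.

VIF screening uses the closed form `1/(1−R²_j)` with exact collinearity
reported as +∞ plus a warning; the exclusion threshold default is 5.
All-subsets selection enumerates every additive predictor subset
(intercept-only included, capped at 12 predictors), ranks by AIC with ties
broken toward the smaller model, and flags ΔAIC < 2 as equally plausible.
Non-converged subsets keep their row but cannot be "best". Wald CIs are
symmetric on the log-odds scale, so reproduction of published
likelihood-based CIs is approximate by construction.

## Synthetic data

The generator's defaults mirror the audited system's scale: 3570 species
over 317 countries in 7 regions, endemic fraction 0.5, 128/3570 medically
important, 658-bp barcodes, and per-species sequence counts geometric with
mean 11 — which puts ≈ 62 % of species in the 1–10 sequence band. The
geometric tail is far lighter than real repositories' (a handful of vector
species carry thousands of sequences); analyses sensitive to that extreme
tail should not rely on the generator's count distribution.

Sequences evolve under Jukes–Cantor (site-independent, equal base
frequencies, no indels) on a star topology: root → species centroid → tip.
`intra_divergence` and `inter_divergence` are the **expected pairwise**
substitutions/site between conspecific and heterospecific sequences (tip
branch `intra/2`, centroid branch `(inter − intra)/2`). This
parameterisation makes the two regimes of interest exact: `intra ≪ inter`
separates the identity distributions (a universal barcode gap), and
`intra == inter` collapses all centroids onto the root so conspecific and
heterospecific identities are exchangeable and the gap all but vanishes.
The star topology was chosen over a coalescent precisely because it gives
direct, independent control of the two quantities the gap statistic
consumes; realism beyond identity structure (rate variation, indels,
pseudogenes, introgression) is out of scope, so passing gap tests show the
pipeline's decision logic is correct, not that real libraries are this
well behaved.

Record tables draw each catalogue (species, country) pair with probability
`logit⁻¹(β₀ + x_c·β + u_region)`, `u_region ~ N(0, σ²)`, with
standard-normal country covariates — a recoverable ground truth for the
coverage GLMM. Injected defects (wrong marker, missing sequence, missing
country, unmatched name) are *appended corrupted copies*, so curation must
remove exactly the injected rows and the clean bookkeeping is invariant.
The country-inflation defect is opt-in: because the sanity stage compares
counts, the generator injects enough out-of-range countries to push the
species past its catalogue count, which necessarily sacrifices all of that
species' rows; ground truth records the sacrificed species.

All outputs are deterministic functions of the configuration seed
(sub-streams are spawned per component, so catalogue, barcodes and records
are independently reproducible).

## Problem sizes used in the checks

Desk-scale runs keep the full pipeline exercised at sizes where the
all-vs-all aligner (the dominant cost, ~30 ms per 658-bp pair over both
strands) finishes in minutes: gap-prevalence regimes use 20 species × 5
sequences of 658 bp; oracle-equivalence uses 50 × 300 bp; GLM recovery uses
n = 2000, GLMM recovery 20 groups × 100, and subset selection 100
replicates of n = 1000. The curation, coverage and odds-ratio checks are
instantaneous.

## Known limitations

* The identity engine is exact dynamic programming, not a seeded heuristic;
  on identical inputs a heuristic tool may report slightly different
  pident for diverged pairs (it may miss the optimal local alignment).
  Prevalence comparisons against heuristic-based analyses should allow a
  couple of percentage points of slack.
* ITS2 handling is name-based filtering only; extracting the spacer from
  its conserved flanks (5.8S/28S) requires an HMM-based boundary tool and
  is out of scope.
* No NUMT detection, BIN clustering, or distance-model (e.g. K2P)
  alternatives to identity.
* The GLMM supports a single random intercept; crossed or nested random
  effects are not implemented.
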