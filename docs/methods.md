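# Methods

This note records the models implemented in `mirgoimpute`, the defaults and
why they were chosen, what the synthetic benchmark does and does not show,
and the numerical conventions a user relying on exact reproducibility
should know.

## Term-level semantic similarity

The default backend is the semantic-contribution method used by G-SESAME
and GOSemSim.  For a term *t*, every ancestor *a* (via `is_a` / `part_of`
edges, restricted by default to the molecular-function namespace) receives
an S-value: `S_t(t) = 1`, and walking child → parent each ancestor keeps
the best weighted contribution over its children on paths from *t*,
`S_t(a) = max_c w_rel(c→a) · S_t(c)`.  The pair score is

    sim(t1, t2) = Σ_{a ∈ anc(t1) ∩ anc(t2)} (S_t1(a) + S_t2(a)) / (SV(t1) + SV(t2)),

with `SV(t) = Σ_a S_t(a)`.  Contribution factors default to the published
values `w_is_a = 0.8`, `w_part_of = 0.6`; both are configurable
(`TermSimilarityModel.contribution_weights`) because annotation pipelines
differ on whether `part_of` edges should count at all.  The score is
symmetric, 1 on the diagonal, and bounded in [0, 1]; the test suite checks
it against an independent all-paths enumeration oracle on small random
DAGs.

An information-content backend is provided as an alternative:
`IC(x) = −ln(|G_x| / |G_root|)` with `G_x` the genes associated with *x*
or any descendant (natural log — the base only rescales IC, and nothing
downstream consumes absolute IC values).  Pair similarity under this
backend is the most-informative-common-ancestor score normalised to
[0, 1], `2·IC(mica) / (IC(t1) + IC(t2))`.  It requires an annotation map
and is not used by the default pipeline.

## From terms to genes to miRNAs

A gene's term set and a miRNA's target-gene set are compared with set
strategies applied to the rectangular matrix of constituent similarities:
`max`, `avg`, `rcmax` (the larger of the two directional best-match
averages) and `bma` (best-match average, the default at both levels —
`max` saturates on a single shared term, and `avg` scores identical sets
below 1).  Two design points:

* **Empty sets score 0, not an error.**  A miRNA without usable targets
  (or a gene whose terms were all filtered out) gets zero similarity
  everywhere off-diagonal; through `C = (1 − H)^α · D` its neighbour
  ranking then falls back to pure expression distance, which keeps every
  miRNA imputable.
* **A one-step `pooled` variant** (all targets' terms merged into one
  redundant set per miRNA, compared directly at term level) is available
  as an alternative to the default two-step lift; redundant frequent terms
  weigh more under pooling, which is sometimes wanted.

The gene-level and miRNA-level strategies may differ; both default to BMA.
Similarity matrices are computed densely with per-pair memoisation — at
miRNA-array scale (hundreds of rows) this costs seconds.

## Distance, combination, imputation

Expression distance is pairwise-complete Euclidean, **averaged over the
shared valid sample count n before the square root**, so pairs with
different amounts of missingness stay on one scale.  A pair with no shared
valid sample has an undefined distance and is excluded from neighbour
candidacy; any finite penalty value would be arbitrary.

`C_ij = (1 − H_ij)^α D_ij` with α ≥ 0; α = 0 reproduces D exactly
(including at H = 1, since `0^0 = 1` under IEEE semantics, which is the
intended limit).  C is monotone non-increasing in α wherever H < 1, so α
directly dials how much the functional signal overrides expression
distance.  α is best chosen by `select_alpha`, which simulates masks on a
complete matrix and scores each grid point on the same mask sequence
(default grid {0, 0.25, 0.5, 1, 2, 4}; ties go to the smaller α).

Imputation fills each missing cell (i, t) from the K candidates nearest
under C that are **observed at t** and have a defined distance — the
standard KNNimpute convention, which also avoids cascading estimates; ties
break by (distance, row index).  Weighted-KNN uses `w_j ∝ 1/C_ij`; if any
selected neighbour sits at distance exactly 0, the weight mass is split
equally among the zero-distance neighbours.  LLS regresses row i on the K
neighbour rows over the samples where all K + 1 rows are simultaneously
valid (simpler and better-posed than per-neighbour pairwise deletion),
solves rank-deficient systems by the minimum-norm solution, and applies
the coefficients to the neighbours' values at t; with zero shared samples
the cell falls back to the KNN estimate.  A cell with no admissible
neighbour falls back to the row mean of observed values; all fallbacks are
recorded in `ImputationResult.fallback_cells`.  Imputation is single-pass:
estimates never feed back into later estimates.  Default K = 5 — on miRNA
arrays the optimum sits around 4–5, far below typical mRNA settings,
because the profiles are smaller and flatter.

Estimates come from observed values only, observed cells pass through
bit-for-bit, and KNN estimates are convex combinations of neighbour values
(all property-tested).

## Missing-value simulation

Real array missingness concentrates in a subset of probes, so masks follow
a partial-random model rather than uniform sampling: `select_fraction`
(default 0.5) of the rows are chosen without replacement; each selected
row draws a rate r uniformly from the integers {1..p} (p = "maximum
missing rate", percent) and masks `max(1, floor(r% · n_samples))` cells.
The floor-then-clamp honours "at least one missing cell per selected row";
reading r as a uniform *integer* makes the expected overall rate
`select_fraction · mean_r(max(1, floor(r% · S))) / S` — ≈ 4.96 % at
p = 20 and ≈ 9.94 % at p = 40 with 60 samples (the idealised values
without flooring are (1+p)/4 = 5.25 % and 10.25 %).  With 120 samples and
p = 40 a selected row carries between 1 and 48 missing cells.  One integer
seed drives row selection and cell placement through a single generator
stream, so benchmark tables replay exactly.

## The synthetic benchmark generator

`synthetic_dataset` builds, from one seed: a toy molecular-function
ontology with one branch per cluster (binary tree of depth 3 under the
cluster root); per-cluster genes annotated with 2 terms drawn from their
branch; miRNAs targeting 3 private genes of their cluster; and a complete
expression matrix `row = sqrt(rho) · L_c + noise_sd · ε` where `L_c` is
the cluster's latent profile and ε is iid standard normal.  Functional
similarity and expression correlation therefore coincide by construction
— the regime the method assumes.

Defaults: 4 clusters × 10 miRNAs, 30 samples,
`within_cluster_correlation` rho = 0.5, `noise_sd` = 0.8.  These were
fixed so that imputation is non-trivial but not hopeless: expected
within- and between-cluster squared distances are 1.28 vs 2.28, close
enough (relative to the sampling noise of pairwise distances estimated on
≤ 30 shared samples) that expression-only neighbour ranking makes
mistakes functional similarity can correct, while expression-only KNN
still achieves NRMSE ≈ 0.9 (clearly better than guessing the mean).

What the generator does **not** emulate: intensity-dependent (MNAR)
missingness, platform artefacts, heterogeneous per-row dynamic range,
overlapping or hierarchical functional clusters, incomplete or wrong
annotation, and prediction noise in target lists.  Passing benchmarks
here show the machinery is correct and that the GO signal is exploited
when it is real; they do not quantify the gain on any particular real
array.

## Small-sample behaviour of LLS

At the benchmark scale (30 samples, K = 5, up to 40 % of a row masked)
unregularised least squares occasionally fits on only ~5–10 shared
samples, and those repetitions produce arbitrarily large NRMSE; the mean
over repetitions is then dominated by these outliers (visible as sd values
of several units in the reports).  GO-selected neighbour sets, being
same-cluster rows that differ only by noise, are *more* collinear and can
be hit harder.  Consequently, at this scale the LLS comparison between
expression-only and GO-based selection is unstable in both magnitude and
sign from one dataset realisation to the next, whereas the KNN comparison
is consistently in favour of GO-based selection.  Users imputing small
matrices with LLS should lower K below the shared-sample count they can
afford; the package deliberately keeps the estimator unregularised rather
than silently shrinking coefficients.

## Evaluation conventions

NRMSE divides the RMS error by the **population** standard deviation of
the true values, both taken **over the artificially masked cells only**
(default).  A whole-matrix variant sits behind `scope="full"`, but it
dilutes the score by the missing fraction and makes results depend on
matrix size, so masked-only is the default.  Zero masked cells or zero
variance of the true masked values raise errors rather than returning 0/0.
`benchmark` reuses the same mask within a repetition across every method ×
K × mode combination, so comparisons are paired; `expression_only` rows
never read H, and α = 0 GO-based runs equal them to the last bit.

Problem sizes used by the shipped tests and `scripts/acceptance.py`:
mask-model expectations on 200 × 60 matrices over 1000 masks; benchmark on
40 × 30 matrices, 100 repetitions (the acceptance script additionally
averages five independent dataset realisations, since one 40 × 30 draw is
itself noisy).

## Known limitations

* Target lists and annotations are consumed as given (an optional score
  column with keep-threshold supports pre-filtered prediction tools);
  no identifier reconciliation across database versions is attempted.
* Only `is_a` and `part_of` relations are traversed; `regulates`-type
  edges are ignored.
* The α search is a grid scan on simulated masks of a complete matrix; no
  automatic K selection is provided.
* LLS at small sample counts is heavy-tailed (see above).
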