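# mirgoimpute

GO-knowledge-aided missing-value imputation for miRNA expression matrices.

miRNA microarray profiles routinely contain missing values (low intensities,
spot artefacts, preprocessing), and the standard fixes — KNNimpute,
local-least-squares (LLS) imputation — choose the neighbours that drive each
estimate from expression distance alone.  For protein-coding genes,
functional annotation is known to sharpen that choice; miRNAs, however,
carry no direct Gene Ontology annotation.  `mirgoimpute` closes the loop
through their **target genes**: a miRNA inherits the GO terms of the genes
it regulates, functionally similar miRNAs get a high similarity score, and
that score steers neighbour selection during imputation.

## Method

1. **Term similarity.**  On the molecular-function DAG, two terms are scored
   by the semantic-contribution (G-SESAME / Wang) method: every ancestor *a*
   of a term *t* gets an S-value `S_t(t) = 1`,
   `S_t(a) = max_(c child of a on a path to t) w_rel · S_t(c)` with
   contribution factors `w_is_a = 0.8`, `w_part_of = 0.6`, and

       sim(t1, t2) = Σ_(a ∈ anc(t1) ∩ anc(t2)) [S_t1(a) + S_t2(a)] / (SV(t1) + SV(t2)).

   An annotation-frequency backend (`IC(x) = −ln |G_x| / |G_root|`) is
   available as an alternative.
2. **Gene and miRNA similarity.**  A gene is its set of GO terms; a miRNA is
   its set of target genes.  Each level is collapsed by the best-match
   average (BMA) over the rectangular constituent-similarity matrix,

       sim_BMA = (Σ_i max_j s_ij + Σ_j max_i s_ij) / (k + s),

   (strategies `max`, `avg`, `rcmax` and a one-step `pooled` variant are also
   provided), giving the miRNA functional-similarity matrix **H**.
3. **Combined measure.**  With **D** the pairwise-complete Euclidean
   expression distance `d_ij = sqrt(Σ_shared (G_is − G_js)² / n)`,

       C_ij = (1 − H_ij)^α · D_ij,    α ≥ 0,

   so functionally similar miRNAs are pulled closer; `α = 0` recovers plain
   expression distance.
4. **Imputation.**  A missing cell (i, t) is filled from the K rows nearest
   to i under C that are observed at t — weighted-KNN
   (`w_j ∝ 1/C_ij`, default K = 5) or LLS (regress row i on the neighbours
   over their shared observed samples, apply the coefficients at t).
5. **Evaluation.**  Artificial missingness follows a partial-random model
   (half the miRNAs get missing values; each draws its own rate uniformly
   from {1..p} percent) and accuracy is NRMSE
   `= sqrt(mean (G_est − G_true)²) / σ(G_true)` over the masked cells.

## Worked example

Everything below is reproducible with the `mirgoimpute` console script on a
synthetic dataset whose functional clusters and expression clusters
coincide by construction:

```bash
mirgoimpute synth --seed 7 --out-dir data
mirgoimpute similarity --obo data/ontology.obo --annotations data/annotations.tsv \
    --targets data/targets.tsv --out H.tsv
mirgoimpute simulate --expr data/expression.tsv -p 40 --reps 1 --seed 7 --out-dir masks
mirgoimpute impute --expr masks/masked_000.tsv --similarity H.tsv \
    --method knn -K 5 --alpha 1.0 --out completed.tsv
mirgoimpute benchmark --expr data/expression.tsv --similarity H.tsv \
    -K 5 -p 40 --reps 100 --seed 7 --out report.tsv
```

which prints

```text
wrote synthetic dataset (40 miRNAs x 30 samples, seed=7) to data
wrote 40x40 similarity matrix to H.tsv
wrote 1 masked cop(ies) to masks (seed=7)
imputed 124 cell(s) (0 by fallback) -> completed.tsv
method            mode  K  p  alpha  mean_nrmse  sd_nrmse  reps  seed
   knn expression_only  5 40    0.0    0.966237  0.052478   100     7
   knn        go_based  5 40    1.0    0.928755  0.050329   100     7
   lls expression_only  5 40    0.0    2.916573  8.866082   100     7
   lls        go_based  5 40    1.0    1.597923  1.809165   100     7
```

Reading the report: over 100 paired mask repetitions at maximum missing
rate p = 40 %, GO-aided neighbour selection lowers the KNN error from 0.97
to 0.93 NRMSE.  The LLS rows illustrate a known small-sample caveat: with
30 samples and K = 5 unregularised regressors, LLS occasionally overfits
badly (note the sd of 8.9), so its mean is dominated by rare catastrophic
repetitions — see `docs/methods.md`.

The same pipeline is available as sklearn-style estimators:

```python
from mirgoimpute import GOKNNImputer
completed = GOKNNImputer(n_neighbors=5, alpha=1.0,
                         functional_similarity=H).fit_transform(expr)
```

where `expr` is a miRNA × sample DataFrame with NaN for missing entries and
`H` a miRNA × miRNA similarity DataFrame (from
`mirgoimpute.functional_similarity` or `mirgoimpute similarity`).

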