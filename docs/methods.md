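# Methods

## Model and assumptions

The unit of inference is a TF-motif prediction: one transcription factor
with a set of predicted target genes. Under the null hypothesis the TF is
unrelated to the motif, so its cofitness with the predicted targets follows
the same distribution as with a random sample of genes. Under the
alternative, disrupting the TF phenocopies (activator) or mirrors
(repressor) disruption of at least one target, producing an extreme
positive or negative cofitness. The test is deliberately built on the **top**
target only: a TF's fitness pattern is typically driven by a small subset
of its regulon, so requiring signal from every target would destroy power.

Two complementary statistics are combined per direction:

- **Rank test.** If the *T* targets were random, the best rank *R* among
  *N*−1 partners satisfies `P(best ≤ R) = 1 − (1 − R/(N−1))^T` (draws with
  replacement; for *T* ≪ *N* this is indistinguishable from sampling
  without replacement). The factor 2 corrects for testing both directions.
  The rank is scale-free: it automatically adapts to TFs whose global
  cofitness distribution is wide or narrow.
- **Correlation test.** The rank alone can be significant even when the
  correlation is biologically negligible, so the extreme cofitness *r*
  must itself be significant: `z = √(M−3)·atanh(r)` is treated as standard
  normal, with a `2·T` Bonferroni factor (both signs, *T* targets).

Both p-values are computed for each direction and combined as the maximum;
requiring both tests simultaneously makes the combination conservative (the
observed null rate at the 0.01 level is ≈ 0.4%, see the calibration test).
Because the two tests are strongly correlated, the false-discovery rate is
reported as the single-test plug-in estimate `α·tested/validated` rather
than layering a further multiple-testing correction.

A TF is only tested at all when it has a *significant phenotype*
(|fitness| > 0.5 and |t| > 4, strictly, in at least one experiment): without
a phenotype the fitness profile is noise and a high rank would be
meaningless. The thresholds are fixed; per-organism recalibration of the
phenotype threshold against an experiment-replication model is out of scope
and flagged in the result metadata only through the fixed defaults.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| α (validation threshold) | 0.01 | — | stringent single-TF level; FDR is reported on top |
| phenotype gate | 0.5 / 4 | log₂ / t | standard strong-phenotype cut for RB-TnSeq fitness |
| close / far distance classes | ≤ 20 kb, ≥ 50 kb | bp | bias estimation contrast classes |
| pairs sampled per class | 1000 | pairs | stabilizes the medians to ≈ ±0.005 |
| min shared experiments | 10 | experiments | guards against spurious ±1 correlations from tiny overlap |
| operon gap | < 250 | bp | intergenic-distance heuristic for co-transcription |
| upstream window | 250 | bp | promoter-proximal motif search region |
| RBH thresholds | E ≤ 1e−5, id ≥ 50%, cov ≥ 80% | — | ortholog acceptance, applied in both directions |
| motif p threshold | 0.01 | — | empirical genome-wide fraction |
| discovery cutoffs | 0.6 / rank ≤ 10 / 0.8 | — | conserved and strong cofitness bars |

## Numerical and design choices

- **Distance** between genes is midpoint distance; infinite across
  scaffolds. Operon gaps, by contrast, use intergenic distance
  (`next begin − prev end − 1`, clamped at 0 for overlaps), the standard
  operon heuristic; the two roles are deliberately different.
- **Bias correction** subtracts the genome's bias estimate only from
  *positively* cofit partners within 20 kb of the focal gene, before
  ranking, and applies to all partners (not just annotated targets) since
  ranks are defined against the whole genome. The estimate is clamped at 0;
  pair sampling is uniform with replacement over eligible pairs, seeded.
- **Ranks** are competition ("min") ranks: tied partners share the smallest
  rank. This is the anti-conservative tie-break for the rank test, which is
  why the null calibration stresses it explicitly.
- **M in the Fisher test** is the shared-experiment count of the specific
  top pair, the defensible generalization of "number of fitness values" to
  tables with missing entries.
- **p-values are capped at 1** after every Bonferroni multiplication and
  floored at the smallest positive double, so they live in (0, 1].
- The rank formula is evaluated through `expm1`/`log1p` to avoid
  cancellation at small `R/(N−1)`.
- **Association-matrix mode** (e.g. coexpression) reuses the identical test
  with caller-supplied *M*, no bias correction and no phenotype gate; an
  exclusion list (typically same-operon targets) removes partners from both
  the target list and the ranking.
- **Alignment backend**: Smith-Waterman via Biopython's `PairwiseAligner`
  (BLOSUM62, gap open 11 / extend 1) with Karlin-Altschul gapped parameters
  λ = 0.267, K = 0.041 for bit scores and E-values. The backend sits behind
  `AlignParams` so an external aligner's hits could substitute. Coverage is
  measured on the query of each direction and both directions must pass.
  RBH ties break lexicographically on locus id and are logged.
- **Upstream windows**: one window per sub-series of the target's maximal
  run (the target's own window plus one per member 5′ of it), each the
  250 bp immediately 5′ of that member's strand-aware start, truncated at
  scaffold edges.
- **Empirical motif p**: every gene's best upstream hit is scored the same
  way; `p = (# genes scoring ≥ target) / (# genes scored)`, excluding the
  target's operon mates from numerator and denominator — but not the target
  itself, which ties itself, so the attainable minimum is 1/G and never 0.
  Score comparisons use a 1e−6 tolerance because forward- and
  reverse-strand sums order floating-point additions differently.
- **Discovery**: the "conserved cofitness rank ≤ 10" is evaluated in the
  focal organism's profile; candidates are searched in descending cofitness
  so the first qualifying gene is the answer, and the scan stops at 0.6,
  below which neither criterion can fire.

## The synthetic-data generator

The generator plants, with known ground truth, exactly the structures the
method exploits, using shared latent factors so every implied covariance is
positive-semidefinite:

- TF rows are `sign·c·(primary target row) + λ·(operon member row) + noise`,
  normalized to unit variance, so realized TF-target cofitness ≈ the
  configured coupling *c* and polar leakage ≈ λ (always positive, as a
  transcriptional artifact would be).
- Chromosomal proximity bias is a positional Gaussian-process factor
  (squared-exponential kernel, 40 kb length scale, amplitude √b), giving
  pairs ≤ 20 kb a correlation ≈ *b* and pairs ≥ 50 kb ≈ 0 — the contrast
  the bias estimator measures.
- Operons are geometric-length runs (capped at 8) with intra-run gaps of
  20-200 bp and inter-run gaps of 300-800 bp; strands are random per run.
- Motif sites are the PWM consensus planted at a random offset and strand
  in the 250-bp window upstream of chosen targets (or scrambled in place,
  preserving composition, for negative controls). The bundled synthetic PWM
  has deliberately heterogeneous per-position probabilities; a homogeneous
  matrix would put all scan scores on a lattice of match counts and create
  pathological ties in the empirical p.
- t statistics are `fitness·√(pseudo-replicates)/noise_sd` with 4
  pseudo-replicates, so the phenotype gate (|f| > 0.5, |t| > 4) passes for
  essentially every gene with ≥ 100 experiments — the real phenotype-FDR
  machinery of fitness pipelines is not modeled.

What the generator does **not** emulate: the barcode-counting noise model,
condition-correlated experiment blocks, genuine pathway co-regulation
(beyond the planted couplings), genome-scale proteome divergence, or
realistic promoter sequence composition. Passing tests therefore show the
statistics behave as designed under the stated correlation structures, not
that real compendia satisfy those structures.

## Problem sizes used in the test suite

Simulated studies are scaled to desk size as the package's own test
conditions: genomes of 600-6,000 genes, 10-200 experiments, 200 simulation
replicates for sign recovery, 2,000 randomized-target cases for type-I
error, 20 seeds for null bias, 10 for the polar control, and 50-400
orthologous pairs for propagation rates. The statistical assertions
(≤ 1.5% type-I at the 0.01 level, ≥ 90% sign recovery, bias recovery
±0.02, propagated fraction ±0.05, ~1% scrambled-site floor) are computed at
those sizes; real-compendium scale (25 organisms, ~500 tested TFs) is not
reproduced here.

## Known limitations

- The fixed phenotype thresholds slightly over-admit TFs in organisms
  where 0.5/4 would need upward adjustment to control phenotype FDR.
- Validation supports the TF-motif association, not each individual
  TF-target pair, and a validated sign can be wrong when polar effects
  create the top cofitness (flagged, not removed).
- All-vs-all Smith-Waterman orthology is quadratic; genome-scale proteome
  pairs should supply a precomputed ortholog map (`propagate` accepts one)
  or an external aligner's RBH output.
- "Dual" regulators are only ever labelled ambiguous; no attempt is made to
  separate condition-dependent activation and repression.
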