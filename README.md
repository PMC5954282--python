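# uipseq

Development toolkit for an RNA-seq diagnostic classifier that calls the
**usual interstitial pneumonia (UIP)** histopathologic pattern — the
hallmark of idiopathic pulmonary fibrosis — from transbronchial biopsy
(TBB) samples, so that a UIP/non-UIP determination can be made without
surgical lung biopsy.

The package is aimed at computational biologists building (or stress
testing) clinical transcriptomic classifiers under the constraints that
make this setting hard: few patients, several small biopsies per patient,
a heterogeneous "negative" class made of many distinct diseases, assay
batch effects, and a deployment mode (one pooled sequencing run per
patient) that differs from the training mode (individual biopsies).  It
implements the full development workflow as reusable, tested stages:

1. **Synthetic cohorts** (`uipseq.cohort`) — a negative-binomial
   generator with the study's structure: up to 5 TBBs per patient
   (typically 2 upper + 3 lower lobe), ~59% UIP prevalence, molecularly
   distinct non-UIP subtypes on disjoint gene sets, sentinel samples
   replicated across processing batches, in-vitro patient-level pools,
   and the lobe-to-patient label rules (any lobe with a UIP subtype ⇒
   UIP; otherwise any non-UIP condition ⇒ non-UIP; only non-diagnostic /
   unclassifiable-fibrosis lobes ⇒ no reference label).
2. **Frozen normalization** (`uipseq.normalization`) — median-of-ratios
   size factors `s_i = median_j K_ij / (∏_v K_vj)^(1/m)` and a
   closed-form variance-stabilizing transform for the trend
   `v(μ) = μ(1+α_e) + α_t μ²`,
   `vst(q) = log2[(1 + α_e + 2α_t q + 2√(α_t q (1+α_e+α_t q))) / 4α_t]`,
   asymptotically `log2 q`.  The per-gene geometric-mean reference and
   `(α_t, α_e)` are frozen on the training set and reapplied verbatim to
   any future sample.
3. **Gene filtering** (`uipseq.filtering`) — annotation filter
   (off-panel genes, pseudogenes, rRNA, TR/IG exon features), a
   low-expression filter, and a batch-sensitivity filter from per-gene
   mixed models on sentinel replicates,
   `g_ij = μ + β·sample_ij + batch_i + e_ij` (sample fixed, batch
   random), excluding the top 5% of genes by `σ²_batch + σ²_e`.
4. **In-silico mixing** (`uipseq.mixing`) — patient-level pseudo-pools
   `K^p_j = (1/n_p) Σ_{i∈I(p)} K_ij / s_i`, frozen-VST transformed, plus
   Gaussian technical-noise replicates with per-gene SD
   `τ_j = √(σ²_batch + σ²_e)`.
5. **Classification** (`uipseq.classifier`) — elastic-net penalized
   logistic regression (`ElasticNetLogit(...).fit()` →
   results object with `summary()`), minimizing
   `(1/n) Σ log(1+e^{-y(b+x'w)}) + λ(mixing‖w‖₁ + (1−mixing)/2 ‖w‖₂²)`
   by a deterministic FISTA proximal-gradient solver; patient-stratified
   folds (LOPO or k-fold) where all samples of a patient travel
   together; nested random-search tuning with the one-standard-error
   rule on inner-CV binomial deviance; `run_lopo` scores each held-out
   patient's individual samples *and* 100 noise replicates of their
   in-silico mix.  Scores are linear predictors (log-odds), not
   probabilities.
6. **Decision boundary** (`uipseq.boundary`) — prospectively locked from
   the replicated in-silico LOPO scores: among grid candidates with mean
   specificity > 0.90 and mean sensitivity ≥ 0.65, take the most
   specific (then most sensitive, then smallest).  Calls are strict:
   score above the boundary ⇒ UIP, at-or-below ⇒ non-UIP.
7. **Robustness monitoring** (`uipseq.monitoring`) — score-level variance
   components (pool fixed, run random) from replicated pools across
   runs, classifier ranking by SD as % of the 5–95% score range, a
   monitoring threshold σ_sv (largest score-noise SD that moves mean
   sensitivity/specificity by ≤ 2 points), and per-batch control gating.
8. **Evaluation** (`uipseq.evaluation`) — midrank Mann–Whitney AUC with
   DeLong CIs, Clopper–Pearson CIs for sensitivity/specificity,
   fold-mean vs pooled cvAUC, and `validate()`, which only accepts a
   locked artifact and audits train/test patient overlap.

## Worked example

```python
import pandas as pd
import uipseq as u
from uipseq.filtering import GeneSet

cfg = u.CohortConfig(n_patients=30, n_genes=600, seed=11)
cohort = u.generate_sentinels(u.generate_cohort(cfg), 8, 8, seed=12)
bio = cohort.counts.subset_samples(list(cohort.biopsy_samples()))
frozen = u.FrozenNormalization.fit(bio)

universe = GeneSet(list(cohort.counts.genes), "universe")
genes = u.filter_low_expression(bio, u.filter_by_annotation(universe, cohort.annotation))
expr_all = u.apply_vst(cohort.counts, frozen)
sent = cohort.sample_meta.index[cohort.sample_meta.role == "sentinel"]
sent_meta = pd.DataFrame({"source": cohort.sample_meta.loc[sent, "patient"],
                          "batch": cohort.sample_meta.loc[sent, "batch"]})
models = u.fit_gene_batch_model(expr_all[sent].loc[list(genes)], sent_meta)
genes = u.filter_batch_sensitive(models, genes)

labels = cohort.sample_labels(list(cohort.biopsy_samples()))
pm = cohort.sample_meta.loc[labels.index, "patient"]
expr = expr_all.loc[list(genes), labels.index]
noise = u.NoiseModel(tau=models.technical_sd().reindex(expr.index),
                     n_replicates=100, seed=13)

cv = u.run_lopo(expr, bio, labels, pm, frozen, noise, hyper=(0.02, 0.5), seed=14)
print(cv.summary())
```

```
Leave-one-patient-out cross-validation
  folds                     : 30
  samples scored            : 126
  patients (in-silico reps) : 30
  pooled sample-level AUC   : 1.000
  pooled patient-level AUC  : 1.000
```

Every score was produced by a model that never saw the scored patient
(30 folds, all of a patient's biopsies held out together); the
patient-level line aggregates 100 noise replicates of each held-out
patient's in-silico mix.  On this small, strongly separated synthetic
cohort both AUCs are 1.0.  Locking a boundary and validating on an
independent pooled test cohort:

```python
wide, pat_labels = cv.replicate_matrix()
sel = u.select_boundary(cv.replicate_scores, pat_labels,
                        spec_min=0.90, sens_floor=0.65)
final = u.train_penalized_logistic(expr, labels, 0.02, 0.5,
        metadata={"train_patients": sorted(pm.unique())})
final.lock_boundary(sel.boundary)

val = u.generate_validation_cohort(cohort, n_patients=20, seed=15)
vlab = (val.patient_truth["label"] == "UIP").astype(int)
vlab.index = ["POOL_" + x for x in vlab.index]
print(u.validate(final, val.counts, frozen, vlab,
                 train_patients=final.metadata["train_patients"],
                 patient_map=val.sample_meta["patient"]).summary())
```

```
Independent validation of locked classifier
  model hash      : 2c4db3f3a3eabc1d
  dataset hash    : 636dafee9e0fded1
  boundary        : -2.365
  AUC             : 1.000 [1.000-1.000]
  sensitivity     : 1.000 [0.631-1.000] (8/8)
  specificity     : 1.000 [0.735-1.000] (12/12)
  confusion       : {'tp': 8, 'fp': 0, 'tn': 12, 'fn': 0}
  overlap audit   : pass
```

The boundary (−2.365 on the log-odds scale) was chosen from training
replicates only; validation normalizes the 20 pooled test samples with
the frozen training artifact, scores them with the locked model, and
reports exact-binomial CIs.  The bracketed intervals are wide because the
test cohort is small — the point of the workflow is that they are honest.

A command-line interface mirrors the stages:
`uipseq simulate | normalize | filter-genes | mix | train |
select-boundary | monitor | evaluate` (see `uipseq --help`).

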