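# Methods

## The problem setting

A UIP/non-UIP classifier for interstitial lung disease has to be trained
under constraints that break most textbook workflows: tens of patients
rather than thousands; several small transbronchial biopsies (TBBs) per
patient whose histology can disagree across lobes; a non-UIP class that
is a union of many molecularly distinct diseases; visible reagent/run
batch effects; and a commercial deployment in which each future patient
is a *single pooled* sequencing run, while training data are individual
biopsies.  `uipseq` implements the development workflow end to end and
pairs it with a synthetic-cohort generator so every stage can be
exercised, audited and regression-tested without access to protected
patient data.

## Synthetic cohort model

Latent expression is additive on log2 scale.  For gene g in sample i of
patient p:

    log2 q_gi = baseline_g
              + class_effect_g            (informative genes, UIP patients)
              + subtype_shift_g[s(p)]     (non-UIP patients, subtype s(p))
              + lobe_gi                   ~ N(0, lobe_effect_sd²)
              + batch_g[b(i)]             ~ N(0, batch_sd²)

Counts are negative-binomial via the gamma–Poisson mixture with mean
`L_i · q_gi / Σ_g q_gi` (L_i = library size) and dispersion trend
`α(μ) = α_t + α_e/μ`, the same trend form the VST stage assumes.  Each
non-UIP subtype shifts its own disjoint random gene set, so subtypes are
molecularly distinct and no common "non-UIP signature" exists — the
structural reason differential-expression gene lists transfer poorly
between subtypes, which the generator reproduces by construction.

Defaults (one value per study condition, fixed):

| parameter | default | meaning / rationale |
|---|---|---|
| `n_patients` | 90 | training-cohort scale |
| `samples_per_patient_range` | 3–5 | TBBs per patient; lobe pattern "2 upper + 3 lower" truncated for smaller counts |
| `frac_uip` | 0.59 | training prevalence (validation cohorts use 0.47) |
| `n_genes` | 2000 | desk-scale universe; the pipeline is linear in genes |
| `frac_informative_genes` | 0.05 | planted class-informative fraction |
| `effect_size_sd` | 1.0 log2 | SD of class effects — a strong-signal cohort; cross-validated AUCs saturate near 1, above the real assay's ~0.9 |
| `lobe_effect_sd` | 0.25 log2 | within-patient biological variability; gives biological-replicate expression concordance r² ≈ 0.94, matching the assay's reported biological-replicate level |
| `batch_sd` | 0.15 log2 | per-(gene, batch) random shift, 8 batches |
| `dispersion_params` | (0.005, 2.0) | assay-level (technical) NB dispersion; biological variability is carried *explicitly* by the lobe/subtype/class terms, so α_t is calibrated to the assay's technical-replicate concordance (r² ≈ 0.98), not to biological-replicate dispersion — using a biological-scale α_t here would double-count noise |
| `library_size_range` | 3×10⁵–1.5×10⁶ | expected total counts per sample |
| `discordant_lobe_rate` | 3/90 | patients with one UIP and one non-UIP lobe; the label rules still assign UIP |
| `nondiagnostic_sample_rate` | 0.05 | biopsies with no sample-level histology; they inherit the patient label for training (the rate is not reported for the real cohort, hence a parameter) |
| `unlabelable_rate` | 0.0 | patients whose lobes are all non-diagnostic/CIF-NOC; excluded from all training and evaluation sets when present |

Sentinels are fresh patient-like biological sources re-counted in each of
n_batches new batches with a shared per-batch gene-level effect — the
design that identifies per-gene batch variance.  In-vitro pools mix a
patient's sample-level latent abundances with equal mass (linear-scale
mean of relative abundances) and re-count them with fresh technical noise
in a new batch.  Validation cohorts reuse the training gene truth
(baselines and class effects) but draw new patients, new subtype gene
sets, and one pooled sample per patient.

What the generator does **not** emulate: realistic transcript annotation
beyond a biotype column, correlated gene–gene co-expression modules, GC/
length biases, sample degradation or read-level artifacts.  Passing
tests therefore demonstrate that the *workflow machinery* is correct and
calibrated under the assumed variance structure — not that the real
assay achieves any particular performance.

## Normalization

Size factors are standard median-of-ratios: per-gene geometric means
over the reference samples (genes with any zero drop out of the
reference), then each sample's factor is the median ratio over usable
genes.  The dispersion trend `d ≈ α_t + α_e/mean` is fitted to per-gene
method-of-moments dispersions on normalized counts by iterated least
squares with residual trimming beyond 2 MADs (≤ 10 iterations); a
negative α_e triggers a refit with α_e pinned to 0, and a non-positive
α_t is floored at 10⁻⁸ (Poisson-like data).  The VST is the closed-form
antiderivative of 1/√v(μ) rescaled to base 2 (`README` formula); it is
strictly increasing and asymptotically log2.

Freezing: the reference geometric means and (α_t, α_e) are serialized
(JSON) at training time.  Applying them to a new sample uses only that
sample's counts and the frozen artifact, so normalized expression is
independent of whatever else is in the batch — asserted by a regression
test.  Genes missing from a new matrix are a hard error; a locked
clinical model must see its exact feature space, never an imputed one.

## Batch-sensitivity filtering

Per gene, sentinel expression is decomposed as
`g_ij = μ + β·sample_ij + batch_i + e_ij` with the biological source
fixed and the batch random.  Balanced designs use closed-form ANOVA
method of moments, vectorized over genes (batch mean square minus
residual mean square over sources-per-batch, truncated at zero);
unbalanced designs fall back to per-gene REML (statsmodels MixedLM),
with a Henderson-style method-of-moments rescue when the REML fit is
numerically singular.  "Total variation" is `σ²_batch + σ²_e`,
*excluding* the fixed source effects: differences between sentinel
donors are biology, not technical sensitivity (a `residual_only` switch
exists where the composition matters).  The top 5% of genes by total
variation are removed; ties at the cut break by gene ID so the filter is
deterministic.

## In-silico mixing

Mixed counts are the arithmetic mean of the patient's depth-normalized
counts; the frozen VST is applied to the mixed values directly, without
re-estimating a size factor for the mixed column — the C values are
already on the common normalized scale.  Technical-noise replicates add
independent `N(0, τ_j²)` on the VST scale with
`τ_j = √(σ²_batch + σ²_e)` from the sentinel model (the decomposition
of the original noise estimate is not documented, hence the
residual-only switch).  Mixing across patients or sample types is
deliberately unsupported: samples with very different read depths or
duplication profiles would dominate a naive average.

## Classifier

Elastic-net penalized logistic regression on VST expression,

    min  (1/n) Σ log(1+exp(−y(b + x'w))) + λ(mixing‖w‖₁ + (1−mixing)/2‖w‖₂²),

optimized by FISTA (accelerated proximal gradient) with soft-threshold
prox, step 1/L from the design's spectral norm (power iteration), and
monotonicity restarts every 10 iterations.  Convergence is a maximum
absolute coefficient change below `tol` (default 10⁻⁷ for exported fits,
10⁻⁴ inside hyper-parameter search); non-convergence raises.  Features
are standardized internally and the standardization is folded back into
the exported weights, so the serialized artifact scores raw expression.
The solver is cross-checked in the tests against two independent
optimizers (a split-variable L-BFGS-B formulation and scikit-learn's
saga) to 10⁻⁴.

The elastic-net penalty (rather than pure L1 or L2) is a design choice:
a sparse final gene list requires an L1 component, while the L2 share
stabilizes selection among correlated genes; pure ridge remains
available at `mixing=0`.  Scores are linear predictors: a probability
scale would compress exactly the region around the operating point where
the boundary is chosen.

Cross-validation treats the patient as the atomic unit.  Nested tuning
draws hyper-parameters at random (log-uniform λ, uniform mixing),
evaluates inner patient-stratified k-fold binomial deviance (deviance,
not AUC — its fold-wise SE is well defined at small fold counts), and
applies the one-standard-error rule: the most regularized candidate
(largest λ, then largest mixing) within one SE of the minimum.
`run_lopo` records, for every score, which patients trained the scoring
model; `audit_no_leakage()` re-checks the provenance.  The final model
repeats the tuning on the full training set and fits once.

A generic score-combining interface (`ensemble_score`, weighted mean of
training-standardized component scores) supports ensembles of external
learners; the learners themselves are out of scope here.

## Decision boundary

Candidates on a grid (step 0.01 on the score scale, finer than any
boundary we would report) spanning [min−step, max+step] of the
replicated in-silico patient-level LOPO scores.  For each candidate the
per-patient call probability `P(score > b)` is averaged over replicates
first, then across patients — identical in expectation to per-replicate
averaging, and invariant to duplicating a patient's replicates.
Admissible candidates need mean specificity strictly above 0.90 and mean
sensitivity at least 0.65; selection maximizes specificity, then
sensitivity, then takes the smallest admissible boundary (exact-equality
ties by default; a tolerance option widens the tie set).  If nothing is
admissible the best boundary under the sensitivity floor alone is
returned flagged `criteria_met=False` — never silently.  Calls use the
strict rule: above ⇒ UIP, at-or-below ⇒ non-UIP.

## Robustness monitoring

Score tables from replicated pools across runs are decomposed with pool
fixed and run random — the score-level mirror of the sentinel gene
model — by balanced ANOVA method of moments (REML when unbalanced).
`sd_total = √(sd²_between + sd²_intra)` holds exactly by construction.
Because different classifiers live on different score scales, each SD is
also reported as a percentage of the 5–95% inter-quantile range of
reference scores, and classifiers are ranked on that percentage.

σ_sv is *derived*, not copied: bisection (30 steps) finds the largest
noise SD whose injection into the patient-level replicate scores (common
random numbers across candidate SDs, 200 Monte-Carlo draws) shifts mean
sensitivity and specificity at the locked boundary by at most the
tolerance (default 0.02).  The procedure is a reconstruction of a
threshold-setting simulation whose original details are not public; it
is fully specified here and makes no claim to reproduce any particular
published threshold value.  Batch gating is strict: a new batch passes
only while the pooled across-batch control-score SD is *below* σ_sv.

## Evaluation

AUC is the midrank Mann–Whitney statistic (ties worth ½), with a DeLong
asymptotic CI; sensitivity/specificity use two-sided 95% Clopper–Pearson
intervals (the exact-binomial choice is consistent with CI widths at
test-set-sized denominators).  `cv_auc` returns both the fold-mean AUC
(the cvAUC of k-fold experiments) and the pooled-score AUC used for
LOPO, where single-patient folds have no per-fold AUC; the two disagree
on imbalanced folds and the tests pin a worked example of the
difference.  `validate()` structurally enforces prospective validation:
it only accepts an artifact with a locked boundary, normalizes test
counts with the frozen training parameters, embeds the model and dataset
hashes in the report, and flags any train/test patient overlap.

## Problem sizes and determinism

The default verification cohort is 60 patients × 2000 genes with 8
sentinels × 8 batches and 100 in-silico replicates per LOPO fold; the
repeated-seed boundary-calibration check runs at 28 patients × 400 genes
with fixed hyper-parameters, since it repeats the whole pipeline ten
times and its subject is the calibration property, not the search.
Parameter-recovery checks use 2000 genes (8×8 sentinel design) and
2000 × 200 counts for the dispersion trend.  Every stochastic step takes
an explicit seed or generator; identical seeds give byte-identical
cohorts, fits, and reports.

## Known limitations

- The generator's independence of genes (no co-expression) makes feature
  selection easier than on real data; planted-signal recovery rates are
  optimistic.
- Balanced-design variance components use method of moments; with very
  few runs (e.g. 3) the between-run component has 2 degrees of freedom
  and individual estimates are extremely noisy — recovery claims are
  made on the estimator's mean over repeated designs.
- The one-SE rule is applied over a modest random-search budget in the
  default pipeline; a larger budget changes the selected (λ, mixing) but
  rarely the downstream operating characteristics on strong-signal
  cohorts.
- `derive_sv_threshold` assumes additive Gaussian score noise; real
  batch shifts can rotate or compress score distributions in ways a
  single SD does not capture (per-gene monitoring in the filtering stage
  is the complementary control).
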