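# Methods

## The estimation problem

Bulk tumor DNA is a mixture: neoplastic cells, infiltrating immune cells and
other stromal components all contribute to the methylation signal measured on
450K-style arrays. At a CpG where tumor and non-tumor cells disagree, the
measured beta value of a sample with tumor purity `p` is approximately the
convex combination

    beta = p * beta_tumor + (1 - p) * beta_stroma,

so admixture produces *intermediate* methylation. `purityforest` exploits
this: it learns a regression from beta values to purity using gold-standard
labels (copy-number-derived ABSOLUTE-style scores or expression-derived
ESTIMATE-style scores) and can then score any new methylation cohort without
matched normal tissue and without knowing the tumor entity.

## Pipeline

1. **Partition.** Labeled samples are split 70/30 into training and test
   sets, stratified on the entity label when one is given, otherwise on
   outcome quintile bins. The split is reproducible from the seed; strata
   with a single sample trigger a pooled fallback that is flagged on the
   result.
2. **Dip screening (training partition only).** Hartigan's dip statistic is
   computed per probe over the training samples and the top 20% of probes by
   dip are kept. The dip of a sample is the smallest sup-norm distance
   between its empirical CDF and any unimodal CDF, computed by the greatest-
   convex-minorant / least-concave-majorant iteration on the sorted sample;
   values lie in [1/(2n), 1/4]. Multimodal probes — those segregating into
   methylation states across the cohort, with admixture smearing each state —
   score high; unimodal noise probes score near the lower bound. A standard-
   deviation screen is available as a comparator (`rank_probes_by_sd`).
3. **Importance ranking.** A 500-tree random-forest regression of purity on
   the screened probes ranks probes by impurity-decrease importance
   (permutation importance by flag). Regression forests use `max_features =
   1/3`, the classical regression-forest default for the number of candidate
   predictors per split.
4. **Candidate sweep with OOB selection.** For fractions 0.1%, 1%, 5% and
   10% *of the screened set* (`ceil` rounding; on a 20%-screened 450K array,
   85,600 probes, the 1% candidate has 856 probes), a forest is fitted on
   the top-ranked probes and its out-of-bag mean squared error recorded: each
   training sample is predicted only by trees whose bootstrap excluded it.
   The candidate minimizing OOB error wins; ties resolve to the smallest
   probe count. Fractions that collide to the same count on small screened
   sets are deduplicated.
5. **Final model.** A forest refitted on the chosen probe set, stored with
   the full sweep record, the partition, per-probe training medians (for
   imputation at prediction time) and the resolved configuration.

Prediction averages tree outputs and truncates into [0, 1]; model probes
missing from the queried matrix are imputed with the stored training medians
and the per-sample imputed fraction is reported alongside.

### Leakage and determinism

Screening, importance ranking, candidate selection and the final fit consume
only the training partition, so held-out samples cannot influence the probe
set. `train_purity_model` also accepts an explicit partition; re-running it
on the training samples alone with an all-train partition reproduces the
screening result, the final probe set and the archive bit for bit. All
randomness derives from a single seed through named seed sequences, one per
pipeline stage, so a stage's stream does not depend on cohort size or on the
other stages.

### Missing values

Probes with any missing value across the training samples are dropped before
screening (forests need a complete design; per-probe deletion would let
different probes see different samples during screening). At prediction
time, missing cells and absent probes are median-imputed from training.

## Dip statistic: numerics

The implementation follows the published iteration: prefix pointer arrays
encode the convex minorant fitted below the lower ECDF steps (counts `i-1`)
and the concave majorant above the upper steps (counts `i`); the candidate
modal interval shrinks toward the largest minorant–majorant gap while tail
deviations accumulate; the result is `max / (2n)` with a floor of `1/(2n)`.
Ties are retained (the beta scale quantizes); flat ECDF steps are handled by
zero-width segment guards. The test suite checks the implementation to 1e-9
against an independent linear-programming oracle that minimizes the sup
distance over unimodal CDFs directly (enumerating every "mode at a data
point, atom allowed" placement — interior-gap modes are dominated by gap
endpoints because convexity/concavity force minimum slopes through the gap),
and to 1e-12 for the analytic pin-downs: dip = 1/4 for two distinct points
and for balanced two-point masses, dip = 1/(2n) for uniform spacings and
constant samples, invariance under positive affine maps and reflection.

## The synthetic cohort generator

The generator replaces TCGA-scale training data at desk scale. Reference
study conditions (the defaults): 3 entities x 100 samples, 20,000 probes,
600 informative probes, purity ~ Beta(8, 2) per entity (mean 0.8 — the
high-purity regime of resected tumors), measurement noise on the logit scale
with sd 0.3, ABSOLUTE-like labels = truth + N(0, 0.15) logit noise,
ESTIMATE-like labels with an additional +0.25 logit offset, no missing
cells by default, 500 entity-perturbed probes (logit shift sd 0.8), a
44-probe immune-marker panel.

* **Baseline probes** draw one value per probe from Beta(0.5, 0.5) (most
  probes near 0 or 1, as on real arrays), shared between tumor and stroma:
  unimodal across the cohort regardless of noise.
* **Informative probes** have a mid-methylated stromal reference
  (U(0.42, 0.58): a mixed stromal cell population averages to intermediate
  methylation) and a per-entity tumor reference on an extreme side at least
  0.4 away from stroma, with the side varying across entities (the side
  vector is redrawn until non-constant). Across the cohort these probes are
  genuinely bimodal; within an entity the beta value is linear in purity.
  This entity-wise design is deliberate: purity itself is unimodal and the
  dip statistic is affine invariant, so a single shared tumor/stroma pair
  per probe yields *unimodal* beta distributions that no multimodality
  screen can find — in real pan-cancer cohorts, too, the bimodality that
  the dip test keys on comes from entity-wise differences in tumor
  methylomes at admixture-relevant sites.
* **Entity-specific probes** shift the tumor reference per entity on the
  logit scale without a tumor–stroma contrast: multimodal but only weakly
  purity-informative, the realistic competitors of the planted set in the
  screening step.
* **LUMP panel probes** are hypomethylated in stroma (U(0.05, 0.15)) and
  methylated in tumor in every entity (U(0.75, 0.95)). At these probes the
  stromal compartment is itself a mixture of an immune fraction
  (per sample U(0.4, 1.0)) and a methylated non-immune remainder, which is
  what keeps the LUMP-style score (mean panel beta / 0.85, capped at 1) an
  imperfect proxy of purity, as observed in real cohorts.
* **Mixing and noise.** `beta = logistic(logit(p*t + (1-p)*s) + eps)`,
  `eps ~ N(0, 0.3)`, with boundary-safe clipping at 1e-6; with noise off the
  transform is skipped entirely, so noise-free betas are exactly the convex
  combination. Logit-scale noise preserves [0, 1] and mimics the
  heteroscedastic error of beta values (small near the rails, large in the
  middle).

What the generator does **not** emulate: Infinium I/II probe-type chemistry,
copy-number effects on methylation intensity, batch effects, correlated
probe blocks (CpG islands moving together), or realistic entity proportions.
Passing tests therefore demonstrate that the pipeline recovers a planted
admixture signal under realistic noise — not that a model trained on these
cohorts transfers to real arrays.

## Parameter choices left open by the protocol

* `label_noise_sd = 0.15` logits: keeps the truth–label correlation around
  0.98, comfortably inside the >= 0.95 regime in which gold-standard
  regression is well-posed.
* `missing_rate = 0` by default: the training policy drops probes with any
  missing training value, so even a few percent missingness at 210 training
  samples would discard nearly every probe; missingness is exercised
  explicitly in the I/O and prediction paths instead.
* `n_entity_probes = 500`, shift sd 0.8: enough entity structure to compete
  with the planted probes in screening without swamping the 20% screen.
* Candidate fractions are fractions of the *screened* set: percentages of
  the full array could not produce an 856-probe model from {0.1, 1, 5, 10}%,
  while 1% of a 20% screen of a 428k-probe array does.
* `n_trees = 500` at every forest stage (the protocol fixes 500 only for the
  importance stage); symmetric and configurable.
* Predictions are truncated into [0, 1]: tree averaging cannot leave the
  label range, but imputation edge cases are guarded, and purity is a
  proportion.
* Quantile tables use linear interpolation between order statistics (the
  common default), recorded so the tables are reproducible.
* "Promoter" means TSS200 or TSS1500 in the manifest's gene-region relation;
  whether 5'UTR/1stExon should count is genuinely open, and the narrower
  convention is used here.
* Gene-symbol matching for tumor-suppressor overlap is case-sensitive exact
  match after whitespace trimming; aliases are out of scope.

## Known limitations

* The dip iteration is quadratic in the worst case over pathological tie
  structures; on cohort-sized samples (hundreds of values) it runs in well
  under a millisecond per probe, and a 20,000-probe screen takes seconds.
* OOB model selection prefers small models when informative probes are
  individually strong and redundant; on real arrays, where single-probe
  signal is weaker, the selected models are larger (hundreds of probes).
* The LUMP panel of the published score is not redistributable here; the
  generator ships a synthetic stand-in panel, and real panels can be passed
  as a plain probe-list file.
* Test-scale problem sizes: the acceptance suite runs the reference
  20,000-probe, 300-sample conditions; the 450K-scale behavior is covered
  only by the count arithmetic (85,600-probe screened set), not by a full
  450K fit.
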