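# endotype

Molecular profiling of the anti-proliferative response to aromatase
inhibitors (AIs) in ER+HER2− breast cancer.

In the presurgical setting, response to two weeks of AI is read out as the
proportional change in the Ki67 proliferation index,
`pc = 100·(Ki67_2wk − Ki67_baseline)/Ki67_baseline`. Poor responders (PR)
are the eligible patients in the worst 15% of `pc`; good responders (GR)
are drawn from the best 50% and matched to PRs on baseline-Ki67 categories
(10–20%, 20–30%, ≥30%) so both groups carry similar baseline
proliferation. PRs are further split at log2-normalized *ESR1* counts of
12 into ESR1-high and ESR1-low strata. The package implements this design
end to end for researchers studying endocrine-therapy resistance:

* **Responder selection** — eligibility (ER+, HER2−, baseline Ki67 > 10%,
  paired measurements), quantile selection, seeded category matching,
  ESR1 stratification, TILs categories, and the demographics-style group
  summary (Fisher exact / Mann–Whitney per covariate).
* **Calibrated intrinsic subtyping** — nearest-centroid PAM50-style calls
  (LumA, LumB, HER2e, Basal) by Spearman correlation to 50-gene centroids.
  Because study cohorts are luminal-skewed and sit on a different platform
  than the centroid training data, whole-cohort median centering is
  biased; the calibration search instead repeatedly draws k ∈ [5, 15]
  study samples carrying independent reference subtype calls, draws a
  composition-matched subset of a balanced training set, uses the
  difference of per-gene means as a candidate cross-platform centering
  vector, and keeps the vector maximizing concordance with the reference
  calls. Exposed both functionally (`calibration_search`,
  `assign_subtypes`) and as a scikit-learn estimator
  (`CalibratedSubtypeClassifier.fit/predict`).
* **Signature scoring** — single-sample GSEA (rank-weighted ECDF running
  sum), preranked GSEA with a gene-permutation null and NES, the
  *HOXB13*/*IL17BR* (H/I) log-ratio, score–score and covariate–score
  Spearman correlation with BH FDR (including the plasma-estradiol
  exclusion rule at 130 pmol/L).
* **Differential expression** — median-of-ratios size factors, an
  expressed-gene filter, and a simplified negative-binomial Wald test
  (Cox–Reid profile dispersion shrunk to an `a0 + a1/mean` trend),
  validated by simulation calibration rather than identity to any
  external tool.
* **Genomic comparisons** — somatic filters (VAF ≥ 5%, ≥ 5 alt reads,
  high/moderate consequence, population AF < 1e−5), tumour mutation
  burden, per-gene and per-3-Mbp-bin Fisher group comparisons,
  chromosomal instability (fraction of covered genome gained/lost), and
  compound TP53 status (mutation plus copy-number loss at the locus).
* **Synthetic cohorts** — a seeded generator producing clinical tables,
  NB counts with bimodal *ESR1* and platform-shifted PAM genes, MAF-like
  mutations and SEG segments, with full ground truth, so the entire
  pipeline is testable although the original patient-level data are
  access-controlled.

## Worked example

```python
import endotype as et

cfg = et.SimConfig(n_patients=400, seed=7)
clinical, counts, mutations, segments, truth = et.generate_cohort(cfg)
norm = et.log2_normalized(counts)

assignment = et.select_responder_groups(clinical, et.AnalysisConfig(match_seed=7))
assignment = et.stratify_by_esr1(norm, assignment)
print(assignment["response_class"].value_counts().to_dict())
# {'unassigned': 235, 'GR': 51, 'PR': 51}
print(assignment.loc[assignment.response_class == "PR", "esr1_stratum"]
      .value_counts().to_dict())
# {'HIGH': 37, 'LOW': 14}

training, labels = et.generate_training_set(cfg, 30)
reference = et.generate_reference_calls(truth, 59, error_rate=0.03, seed=8)
calibration = et.calibration_search(
    norm.values, reference, training, labels, truth.centroids,
    n_iter=50_000, seed=7,
)
print(f"concordance {calibration.best_concordance:.3f} "
      f"at k={calibration.best_k} {calibration.best_composition}")
# concordance 0.983 at k=14 {'LumA': 3, 'LumB': 8, 'HER2e': 3}
calls = et.assign_subtypes(norm.values, calibration, truth.centroids)
true_subtype = truth.samples.set_index("patient_id")["subtype"]
print(f"accuracy vs truth: {(calls['label'] == true_subtype).mean():.3f}")
# accuracy vs truth: 1.000
```

Reading the output: of 400 simulated patients, 51 fall in the worst-15%
tail of proportional Ki67 change (PR) and 51 category-matched good
responders are selected; 14 of the 51 PRs sit below the ESR1 threshold
(the ESR1-low stratum concentrates almost entirely in poor responders —
only 2 of the 51 GRs are low). The calibration search recovers a
centering vector whose calls agree with 58/59 noisy reference calls
(0.983; the reference itself carries 3% label error) and matches the true
subtype of every sample in the cohort.

Scoring and covariate correlation work the same way:

```python
scores = et.score_matrix(norm, truth.gene_sets)
corr = et.covariate_score_correlation(
    clinical.set_index("patient_id")["estradiol"], scores,
    exclusion_threshold=130.0,
)
print(corr.round(3))
#                      rho  p_value    n    fdr
# set
# IMMUNE_PROGRAM    -0.171    0.001  373  0.001
# ESTROGEN_RESPONSE  0.959    0.000  373  0.000
```

Plasma estradiol correlates strongly with the oestrogen-response program
(the generator couples them) and weakly negatively with the immune
program (resistant tumours are immune-hot and estradiol-low), after
excluding values above 130 pmol/L as not plausibly postmenopausal.

A `click` CLI mirrors the library: `endotype simulate | normalize |
respond | de | subtype | score | genomics | report` (see `--help`).

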