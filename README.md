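# monomark

Cross-platform consensus discovery of cell-population-specific marker
transcripts, and subtype-aware evaluation of a candidate marker's prognostic
value in tumor cohorts.

## The problem

Distinguishing closely related immune cell populations — for example
bone-marrow-derived monocytes infiltrating a brain tumor versus resident
microglia — requires marker transcripts that are robust to the quirks of any
single expression platform or analysis pipeline. And once a candidate marker
is in hand, its clinical value has to be judged against the strong survival
structure already explained by a tumor's molecular subtype.

`monomark` implements both halves as a tested, seedable pipeline for
computational biologists:

1. **Consensus marker discovery.** Expression from two cell populations is
   analyzed by four complementary differential-expression channels — two on
   the count (sequencing) platform, two on the log2-intensity (array)
   platform. Each channel *c* emits a per-gene fold change and a
   Benjamini–Hochberg q-value; within each enrichment direction, genes are
   ranked by |log2FC| and merged by the **mean fold-change rank**

   r̄(g) = (1/4) Σ_c r_c(g),

   with a gene admitted to the high-confidence catalog only when
   **q_c < 0.05 in at least 3 of the 4 channels**. An expression filter
   (value > 1 in ≥ 1 sample) and an unsupervised clustering separation check
   (average linkage on 1 − Pearson r) guard the input.

2. **Prognostic evaluation.** Tumor samples are assigned to transcriptional
   subtypes (Classical / Mesenchymal / Neural / Proneural by default) by
   Entrez-ID signature matching and **10-nearest-neighbor** classification
   against a labeled reference. The marker is **dichotomized at the cohort
   median**, compared by Kaplan–Meier curves and the log-rank test, and fed
   to Cox proportional-hazards models — univariate, and multivariate with
   subtype dummy-coded against a reference level — reporting HR = exp(β)
   with Wald 95% CIs and a joint Wald χ² for the subtype block.

A synthetic-data module generates every input with known ground truth
(marker identities and effect sizes; subtype memberships; the true marker
hazard ratio), so each stage is exercisable and testable without downloads.

## Worked example

`examples/03_marker_prognosis.py` simulates a 159-sample cohort whose
marker, when above the cohort median, multiplies the hazard by a true factor
of 1.57 on top of subtype-specific hazards, then re-analyzes it:

```
n = 159, events = 127
  High: median survival time 2.22
  Low: median survival time 4.68
log-rank: chi2 = 4.908, p = 0.0267

univariate Cox (High vs Low): HR = 1.49 (1.04-2.12), p = 0.0277

subtype-adjusted Cox model (reference subtype: Mesenchymal):
                                p      hr  ci_low  ci_high
variable
marker: High vs. Low       0.0176  1.5608  1.0807   2.2541
subtype (overall)          0.3705     NaN     NaN      NaN
Classical vs. Mesenchymal  0.4583  0.8405  0.5310   1.3303
Neural vs. Mesenchymal     0.3966  1.2821  0.7218   2.2773
Proneural vs. Mesenchymal  0.2786  0.7769  0.4921   1.2265
```

High-marker patients die roughly twice as fast (median 2.2 vs 4.7 time
units); the adjusted marker HR of 1.56 (CI 1.08–2.25) recovers the
generating value of 1.57 and stays significant after accounting for
subtype. The other examples cover marker discovery
(`01_discover_markers.py`: sensitivity 1.000, FDP 0.000 on a 2,000-gene
fixture), subtype assignment (`02_assign_subtypes.py`: accuracy 1.000 at
the default noise level) and the auxiliary statistics
(`04_group_statistics.py`).

There is also a thin CLI over the same pipeline:

```bash
monomark simulate --out run1 --seed 3
monomark de --out run1 && monomark consensus --out run1
monomark subtype --out run1 && monomark survival --out run1
monomark report --out run1    # single JSON: consensus top-N + survival block
```

External data enter through plain TSV matrices, a clinical TSV
(sample/time/event/subtype) and, for convenience, the GEO series-matrix
text format (`monomark.io.read_series_matrix`).

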