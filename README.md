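# phenodose

Predicting the need for a **drug dose reduction at first prescription**
from the phenotypes already recorded in a patient's Electronic Health
Record (EHR).

Many drugs — in particular substrates of cytochrome P450 enzymes — show
strong inter-individual variability in response. A dose reduction shortly
after a prescription is a useful proxy for an inappropriate (often
adverse) drug response, and a dose increase for a lack of response.
`phenodose` implements the full analysis pipeline for this problem, for
pharmacoepidemiologists and clinical-informatics researchers working with
longitudinal prescription and event logs:

1. **Interval extraction** — a *dose interval* is a pair of consecutive
   same-ingredient prescriptions (d₁ at t₁, d₂ at t₂) with identical route
   and unit and t₂ − t₁ ≤ 20 days, labelled *reduction*, *increase* or
   *continuation* from the move in quantity and frequency (opposite moves
   resolve on the daily dose, quantity × frequency). Outliers are trimmed
   (all intervals < 6 h, then the longest up to 10% of the pool) and
   continuations are kept only for patients who never had a dose change
   for that ingredient.
2. **Feature construction** — three binary feature streams observed
   strictly before t₁: diagnosis codes, note-derived condition mentions
   and lab-test orders; diagnosis and condition features are expanded with
   all is-a ancestors of their vocabularies, labs are not.
3. **Phenotype profiles** — per drug (or drug set) and outcome, each
   feature's 2×2 interval table (a, b; c, d) is scored with the
   one-sided hypergeometric tail p, the risk ratio
   RR = (a/(a+b)) / (c/(c+d)) and the information content
   IC = −log₂(corpus frequency). The profile keeps features with
   p < 0.05, RR ∉ (0.5, 2), IC inside the per-type inter-quartile band,
   p < α/m after Bonferroni correction, and surviving *elim* pruning
   (an ancestor is dropped when a descendant is at least as significant).
   Under-represented features display with a `NO ` prefix.
4. **Prediction** — balanced (undersampled) binary feature matrices over
   the profile features feed a random forest (100 trees, unlimited depth,
   int(log₂ m + 1) features per split), evaluated by stratified 10-fold
   cross-validation with the **entire feature selection recomputed inside
   each training fold**, and by hold-last-year-out temporal validation.
5. **Synthetic EHR generator** — seeded corpora with planted
   feature-outcome associations, DAG vocabularies and dose-change
   trajectories, so every stage can be tested against a known truth.

## Worked example

```python
from phenodose import (AnalysisConfig, build_profile, cross_validate_10fold,
                       simulate_cohort, recovery_corpus_config, prepare_study)

cohort = simulate_cohort(recovery_corpus_config(seed=42))
config = AnalysisConfig()
intervals, feature_sets = prepare_study(cohort, config)
print(intervals["label"].value_counts().to_dict())

case = list(intervals.loc[intervals.label == "reduction", "interval_id"])
control = list(intervals.loc[intervals.label == "continuation", "interval_id"])
profile = build_profile(case, control, feature_sets, cohort.ontologies,
                        config, subject="DRUG_A", outcome="reduction")
print(profile.step_counts)
print(profile.display_frame()[["feature_type", "display_label", "rr",
                               "p_value", "ic"]].head(6).to_string(index=False))

study = intervals[intervals["label"].isin(["reduction", "continuation"])]
result = cross_validate_10fold(study, feature_sets, cohort.ontologies,
                               config, seed=42, subject="DRUG_A")
print(f"AUC-ROC {result.auc_roc:.2f}  F {result.f_measure:.2f} "
      f"(P {result.precision:.2f}; R {result.recall:.2f})")
```

Output:

```text
{'reduction': 1095, 'continuation': 1030, 'increase': 536}
feature_type  condition  diagnosis  lab
step
tested              243        243  201
p_screen             14         17   15
rr_filter             5          7    2
ic_filter             2          3    1
bonferroni            2          2    1
elim                  2          2    1
feature_type display_label       rr      p_value       ic
   diagnosis          DX43 6.780441 1.131743e-29 3.431195
   condition          CN43 4.365531 1.368280e-23 3.271887
   diagnosis          DX44 3.693730 3.323859e-18 3.395036
   condition          CN44 3.075167 5.416905e-16 3.258831
         lab      LAB_0000 2.474605 3.176985e-12 3.170604
AUC-ROC 0.71  F 0.69 (P 0.70; R 0.69)
```

The generator planted five features (two diagnosis leaves, two condition
leaves, one lab code) at prevalence 0.16 in pre-reduction histories vs
0.04 before continuations (true RR 4). The cascade (step counts above,
one column per feature type) recovers exactly those five features and
nothing else; the empirical risk ratios scatter around 4 with the
expected sampling noise, the information contents sit mid-band, and a
ten-fold cross-validated forest on those five one-bit features reaches
the discrimination that generative structure supports. The profile is
orderable for display (strongest |log RR| first) and exportable as JSON
via `phenodose.export_profile_json`.

The same pipeline runs from the shell — `phenodose simulate`,
`phenodose extract-intervals`, `phenodose build-features`,
`phenodose build-profiles`, `phenodose evaluate`, `phenodose report` —
on plain CSV/JSON/YAML inputs (see `phenodose --help`).

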