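# Methods

## Problem and unit of analysis

The pipeline asks whether the phenotypes recorded in a patient's EHR
*before* a drug is prescribed predict that the dose will subsequently be
reduced. The unit of analysis throughout is the **dose interval**, not the
patient: a pair of consecutive prescriptions of the same ingredient for
one patient, with the same route of administration and the same dose
unit, separated by at most 20 days. The second prescription labels the
interval:

* **reduction** — quantity drops and frequency does not rise, or
  frequency drops and quantity does not rise;
* **increase** — the mirror image;
* **continuation** — quantity and frequency both unchanged;
* opposite moves (one up, one down) are resolved on the daily dose
  (quantity × frequency); an exact daily-dose tie counts as continuation,
  since neither direction is evidenced.

Dose values are prescribed (entered) numbers, not measurements, so dose
comparisons use exact numeric equality with no tolerance. Timestamps are
ISO-8601 in input files and held at second resolution internally; all
temporal comparisons are strict unless stated (history is *strictly*
before t₁; the ADR counting window is closed [t₁, t₂]).

Two cleaning rules follow interval labelling. First, outlier trimming:
every interval shorter than 6 h is removed (same-day corrections rather
than genuine dosing episodes), then the longest intervals are removed
until 10% of the pool is gone; if the short arm alone reaches 10%, no
long trimming happens. Trimming operates within each ingredient's pool by
default (the analysis is per drug; `trim_scope: global` pools
everything), and long-side ties break deterministically by (duration
descending, patient, t₁). Second, continuations are retained only for
(patient, ingredient) pairs with no reduction or increase anywhere in the
record, so the control arm reflects stable dosing; dose changes
themselves are always kept. The never-changed rule is scoped per
ingredient by default (`continuation_scope: patient` widens it): a
patient's unrelated drugs remain usable as controls.

## Features

Three binary feature streams are observed strictly before each
interval's first prescription: diagnosis codes, condition mentions
extracted from clinical notes (assumed pre-annotated; an optional
semantic-type allow-list can be applied at load time when a concept →
semantic-type map is supplied), and laboratory test orders (orders, not
results — proxies for a suspected condition). Presence is binary; repeat
mentions do not count extra, and the temporal order of history events is
deliberately not encoded. The lookback window is the whole available
record by default (`max_lookback_days` restricts it).

Diagnosis and condition features are **expanded** with every is-a
ancestor of their vocabulary DAG: an interval associated with a specific
concept is automatically associated with all more general ones. Lab
orders carry no usable hierarchy and are never expanded. Feature ids
present in events but absent from the ontology are treated as isolated
leaves (logged once per id), so a partial ontology degrades gracefully.

## Phenotype profiles

For one subject (a drug or a named drug set) and one outcome, every
feature observed in case (dose-change) or control (continuation)
intervals gets a 2×2 table — a/b case intervals with/without the feature,
c/d controls — and three statistics:

* **p** — the one-sided hypergeometric tail in the direction of the
  observed association (population N = a+b+c+d, successes K = a+c, draws
  n = a+b; upper tail P(X ≥ a) when RR ≥ 1, lower tail P(X ≤ a)
  otherwise). The directional tail is what makes *negative* associations
  (features over-represented before continuations, displayed with a
  `NO ` prefix) first-class citizens.
* **RR** — (a/(a+b)) / (c/(c+d)). When a or c is zero the
  Haldane–Anscombe correction adds 0.5 to every cell first, keeping the
  ratio finite and non-zero.
* **IC** — −log₂ of the feature's frequency over the interval corpus
  (intervals with empty feature sets count in the denominator). The IC
  screen drops features too common to be informative and too rare to be
  estimated.

The filter cascade, in order, with per-step survivor counts retained per
feature type:

1. p < 0.05 (uncorrected screen; `p_screen`);
2. drop 0.5 < RR < 2 (`rr_low`, `rr_high`) — association too weak in
   either direction;
3. keep IC strictly inside the per-type band. The band is the
   inter-quartile interval of the IC distribution of **all features
   tested** for that type — not of the step-2 survivors, whose quartiles
   would mechanically discard half of any signal however strong — with an
   optional fixed per-type override (`ic_fixed_bands`, e.g.
   4.25 < IC < 12.75 for condition vocabularies of realistic size);
4. Bonferroni: keep p < α/m. By default m is the number of features
   **tested** for this subject × outcome (`bonferroni_scope: tested`).
   Correcting instead by the post-filter survivor count
   (`bonferroni_scope: surviving`) is offered but is anti-conservative:
   the screens are data-dependent, so the shrunken m forfeits the
   family-wise guarantee (in null simulations it yields a non-empty
   profile in the majority of corpora, vs ≤ 5% for `tested`);
5. **elim** pruning per hierarchical type: a feature is removed iff some
   feature in the list has it among its strict ancestors with an equal or
   smaller p — a more general concept only survives when it beats every
   more specific one. Decisions are single-pass against the original
   p-values (no iterative re-testing). Labs, having no hierarchy, are
   untouched.

A profile may legitimately end up empty: no recorded phenotype
distinguishes the patients who needed the change. For the compact
variant, the k = 100 smallest-p features per type are kept (ties: larger
|log RR|, then feature id); display order is |log RR| descending.

## Classifier and evaluation

Eligibility per subject: at least 150 case and 150 control intervals, a
non-empty profile, and at most 55,000 prescriptions of the drug overall
(a volume cap against dominant, routinely-adjusted drugs). Training sets
are balanced by seeded undersampling of the majority class. The feature
matrix is binary over exactly the profile's features; a profile feature
absent from the known feature universe is a fatal error (leakage guard).

The forest: 100 trees, unlimited depth, int(log₂ m + 1) candidate
features per split for m profile features, class-probability outputs.

Two protocols:

* **Stratified 10-fold cross-validation** with per-fold feature
  selection: the entire cascade plus top-k runs on the nine training
  folds only, so a test interval never contributes to the contingency
  counts that select its fold's features. Balancing happens once before
  splitting by default (`balance_mode: per-fold` re-balances each
  training fold). If a training fold's profile is empty the fold scores
  0.5 across the board — no features, no information. Reported metrics
  are fold means; AUC-ROC from case probabilities, precision and recall
  macro-averaged over the two classes (equivalent to weighted on
  balanced sets), F the harmonic mean of the aggregated precision and
  recall. Instance counts are training-fold sizes.
* **Hold-last-year-out**: intervals are assigned to sides by the
  calendar year of t₁ (t₁ anchors the interval's decision point); the
  profile and forest are built strictly before the cutoff year (default
  2014) and scored on the cutoff year, both sides balanced
  independently. An empty training-side profile skips the subject with a
  recorded reason. This is the stringent protocol: it mirrors deployment
  on genuinely future data and pays for it with a smaller training set.

## ADR disproportionality

As a face-validity check that dose reductions track adverse responses,
mentions of conditions from a user-supplied ADR code list are counted
inside intervals (closed window [t₁, t₂], mention-level, not distinct
conditions) and the per-interval mention rates of the reduction and
continuation arms form a risk ratio, Haldane-corrected on zero counts.
The ADR code list is always an input, never hard-coded.

## Synthetic corpora

The generator produces what the pipeline consumes — prescription chains,
three event streams, two vocabulary DAGs — with a recoverable planted
truth. Key choices:

* **Signal is planted at interval level**: for each prescription pair,
  planted features are drawn with `prev_case` when the pair carries the
  target label and `prev_control` otherwise, and their events are placed
  strictly inside the history segment preceding that pair. The default
  chain length is 2 (one interval per patient × ingredient): with longer
  chains the cumulative history mixes draws made for earlier pairs into
  later intervals and dilutes the per-interval contrast, so the exact
  planted truth holds at chain length 2 and longer chains are for
  structural tests only.
* **Gaps** between prescriptions are lognormal, moment-matched to mean
  3.64 days and SD 4.41 days — the regime of short adjustment intervals
  the 20-day cap targets. About 2% of generated pairs fall outside the
  [6 h, 20 d] window and are dropped by extraction, on top of the 10%
  outlier trim.
* **Doses** move on a discrete grid (quantity halves or doubles,
  frequency fixed), so planted labels are unambiguous and recoverable.
* **Noise features** (200 per type by default) have label-independent
  prevalences drawn log-uniformly on [0.005, 0.5], giving an IC spread of
  roughly [1, 7.6] bits and a quartile band of about (2.7, 6.0) against
  which planted features are placed mid-band: the default five planted
  features (two diagnosis, two condition, one lab) use prevalence 0.16 vs
  0.04 — true RR 4, corpus IC ≈ 3.4.
* **Trap features** are planted with strong label dependence but
  timestamps at or after t₁ (half exactly at t₁ to pin the boundary).
  They must never appear in any history feature set; any lookback bug
  surfaces them immediately.
* **ADR mentions** are Poisson within intervals at per-arm rates
  (defaults 0.10 vs 0.05, true ratio 2).
* Outcome mix for the reference studies: 40% reductions, 20% increases,
  40% continuations, so case and control arms come out near-equal.

`truth_report` derives, from the configuration alone, each planted
feature's true RR, expected corpus IC and a detectability flag (RR
outside (0.5, 2) and IC inside the expected noise band).

Reference corpora (`phenodose.studies`): a **null corpus** (no planted
features, ~500 intervals/arm) for family-wise type-I control; a
**recovery corpus** (five RR-4 features, ~1,000 intervals/arm); and a
**classifier corpus** with ten planted RR-6 features (prevalence 0.24 vs
0.04; 4 diagnosis / 4 condition / 2 lab). The exact Bayes-optimal AUC of
the classifier corpus — computable from the two Binomial(10, p) count
distributions — is 0.907, chosen so that a 0.85 sanity bound tests the
implementation rather than the information content: with five features at
0.30 vs 0.05 the Bayes bound is 0.848, and no correct classifier can be
asked to clear 0.85 on it.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: feature correlations and comorbidity structure,
disease progression and seasonality (the generator is stationary, which
is exactly why CV and temporal holdout should agree on it), informative
missingness, coded-vocabulary idiosyncrasies, co-medication, and any
text-processing noise in condition mentions.

## Numerical and degenerate-input choices

* Hypergeometric tails come from `scipy.stats.hypergeom` (sf/cdf); the
  test suite pins them to an exact integer-arithmetic enumeration to
  1e-9 absolute over every table with N ≤ 60.
* The IC quartile band uses strict inequalities (matching the fixed-band
  convention); quartiles are linear-interpolation sample quantiles.
* Ties: long-trim order, top-k selection and display order all have
  total deterministic tie-breaks (documented above), so equal inputs
  reproduce byte-identical outputs.
* Empty case or control groups are fatal for a subject; an empty profile
  is a valid, flagged result. Unknown ontology nodes are isolated leaves.
  A cycle in an is-a edge list is fatal and names a cycle member.
* All randomness (generator, balancing, fold shuffling, forest) flows
  from explicit integer seeds; derived seeds stay below 2³¹.
* Reference-study sizes (100 null corpora, 20 recovery corpora, 10
  classifier seeds; 1,400–3,000 patients each) keep the full property
  suite in the low minutes on one CPU while leaving the binomial noise on
  each checked quantity well inside its asserted margin.

## Known limitations

Drug discontinuation and drug switches are not detected; co-administered
drugs are not features; lab *results* (as opposed to orders) are unused;
history encoding discards temporal order; the Bonferroni correction is
deliberately stringent (a Holm step-down would be more sensitive; a
config hook exists but only plain Bonferroni is implemented). Dose-
increase prediction is structurally supported (`outcome="increase"`)
but, as the reduction-focused design suggests, increases are harder to
phenotype: an absent response leaves fewer traces in the record than an
adverse one.
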