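# Methods

`cogtype` implements a screening pipeline for mild cognitive impairment
(MCI) built on two unobtrusive digital-biomarker streams: keystroke
dynamics from routine touchscreen typing, and linguistic features of
spontaneous written speech. This note documents the models, the parameter
choices, the synthetic data the package ships for validation, and the known
limitations.

## Keystroke dynamics

A typing session is a sequence of key press/release timestamp pairs
(integer milliseconds; no character content). Two series are derived:

* hold time `HT_n = t_n^r − t_n^p` for each of the `N` key events,
* flight time `FT_n = t_{n+1}^p − t_n^r` for `n = 1..N−1`.

Sessions with 40 or fewer key presses are dropped (strict "more than 40"
quality rule). Hold times are kept when strictly below 0.7 s and flight
times when strictly below 3 s, removing long pauses; both cut-offs are
strict upper bounds and are configurable. The hold-time bound is 700 ms: a
microsecond-scale bound would be physically impossible for key holds
(typical holds are ~100 ms), so the threshold is interpreted on the
millisecond scale standard in the keystroke-dynamics literature. Negative
flight times (rollover typing, where the next key is pressed before the
previous is released) pass the filter — only an upper bound is applied.
Filtered series are zero-padded at the tail to a common dimensionality of
100; longer sessions keep their first 100 values (the earliest,
least-fatigued typing — a deliberate choice where splitting would be the
alternative).

## Linguistic features

Input is dependency-parsed text in CoNLL-U. Nine per-document features are
computed, with word tokens defined as non-`PUNCT` tokens and the vocabulary
as case-folded surface forms (both conventions configurable; the worked
eight-word example in the test-suite, with 7 dependency links for 8 words,
is only consistent with word-only counting):

* `dvrst = V/W` — type/token ratio;
* `BI = W^(V^−0.165)` — Brunet index, lower for richer language;
* `HS = 100·ln(W)/(1 − hap/V)` — Honoré statistic with hapax count `hap`,
  higher for richer language; natural logarithm (the classical form);
* `wrd_sent` — mean word tokens per sentence;
* `nonstop` — fraction of vocabulary not in a configurable stopword list
  (plain text, one word per line);
* `NnVrb = nn/vrb`, `Nn = nn/(vrb+nn)`, `Prn = prn/(nn+prn)` — ratios over
  `NOUN`/`VERB`/`PRON` counts (`PROPN` is not counted as a noun by default;
  configurable, since tagset conventions differ across languages);
* `MDD` — mean dependency distance: per sentence, the sum of
  `|position(head) − position(dependent)|` over word-token positions for
  every non-root word token, divided by `N − 1`; the document value is the
  mean over sentences. Distances are accumulated during a pre-order
  traversal of the tree and are provably equal to the direct per-token sum,
  which the tests assert on random trees.

Undefined values (zero verb count, `hap == V`, no nouns and pronouns) are
NaN sentinels, not exceptions: one degenerate text must not abort a
subject. Per-user aggregation is the field-wise mean over the user's texts
with sentinel masking; a field undefined everywhere stays undefined.

## Fine-motor-impairment (FMI) severity models

Padded HT and FT sequences enter a 1-D convolutional autoencoder as two
channels of one length-100 input (a two-branch layout is an alternative the
architecture admits; the two-channel form is the default). The encoder is
two convolutional layers, kernel 5, 16 filters each, same padding, no
pooling; the decoder mirrors the encoder back to 2×100 with a linear output
layer. Pretraining is unsupervised reconstruction: mean squared error,
RMSprop at learning rate 1e-3, 50 epochs, mini-batches of 64, 80/20
train/validation split.

For severity regression the decoder is replaced by a flatten + 50-unit
ReLU hidden layer + linear scalar output, one model per symptom — rigidity
(R), bradykinesia (B), alternate finger tapping (AFT) — each targeting a
clinician-style 0–4 item score. The whole network is fine-tuned end-to-end
(the encoder is not frozen) for 50 epochs with mini-batches of 32.
Generalisation is measured by leave-one-subject-out (LOSO) cross-validation
with Spearman correlation between out-of-fold predictions and true scores;
predictions are clipped (not squashed) to [0, 4]. Subject-level features
for classification are the mean per-symptom index over the subject's
sessions (the distribution over sessions could carry extra signal; the mean
is the default and other summaries are easy to add on top of the
per-session API).

The network substrate is a compact, fully deterministic numpy
implementation (explicit backpropagation, RMSprop with ρ = 0.9, ε = 1e-8,
He initialisation, seeded shuffling; single-precision arithmetic). Fixed
seeds give bit-identical training runs on one machine; across platforms,
losses agree to well within 1e-6 per epoch. The default architecture has
2,930 autoencoder parameters and ~80k regressor parameters (dominated by
the flatten→50 dense layer); the parameter count is reported by
`Sequential.n_parameters()` rather than assumed.

Training sizes: severity fine-tuning is validated on a synthetic cohort of
30 subjects × 20 sessions (600 sessions), which one CPU handles in a few
minutes; the same code scales to larger cohorts unchanged.

## Classification experiments

All experiments are subject-level binary classification (MCI = 1) with
leave-one-subject-out cross-validation. Per fold, a standard scaler (zero
mean, unit variance) is fit on the training subjects only, then the
classifier; the held-out subject receives an out-of-fold probability.
Classifier families: logistic regression (L2, C = 1.0), random forest (100
trees, seeded), k-nearest-neighbours with k = 7 (k is capped at the
training-fold size for very small cohorts). Hyperparameters beyond k = 7
are defaults, exposed in `make_classifier`.

Two measures guard against a subtle but severe artifact of pooling
leave-one-out scores: holding out a subject depletes the training fold of
exactly one member of *their* class, so with weak or null features the
fold-dependent class composition alone pushes every held-out prediction
away from the subject's true class. On pure-noise data the pooled
out-of-fold scores become systematically anti-ordered — in the worst case
(intercept-only logistic regression) the AUC collapses to 0 rather than
0.5, and k-NN retains a persistent negative bias at any cohort size.
First, logistic regression and the random forest use class-balanced
weighting, cancelling the prior shift inside the loss. Second, folds are
*composition-matched*: for each held-out subject one randomly chosen
subject of the opposite class is also dropped from the training fold
(seeded, reproducible), so the fold's class composition is identical for
every subject and carries no information about the held-out label. Each
prediction remains strictly out-of-fold. With both measures, null features
score at chance for all three classifier families (verified on iid noise
and on full null cohorts); informative features are unaffected apart from
the loss of one training subject per fold. Plain folds are available via
``paired=False``.

Univariate feature selection ranks features by the one-way ANOVA F
statistic against the label (for a binary label this is the squared
two-sample t statistic); constant features score 0 and rank last. The
documented optimal presets are `exp1 = [nonstop, dvrst, HS, MDD]` and
`exp2 = [B, R]`.

The fused designs are cascades: first-stage models `just_nlp` (logistic
regression on nonstop, dvrst, MDD) and `just_keys` (7-NN on B, R) produce
probabilities that feed a second-stage classifier — design A: random forest
on P(just_nlp) + B; design B: 7-NN on P(just_keys) + dvrst, nonstop, MDD;
design C: random forest on both probabilities. Inside each outer training
fold the first-stage probabilities are produced by an *inner* LOSO, so no
subject's label ever reaches a model that predicts it. The deliberately
leaky alternative (stage models fit once on the full table, in-sample
probabilities reused) is implemented behind `nested=False` solely so the
regression test can demonstrate the inflation it causes on null data.

Evaluation: the AUC is bootstrapped by resampling subjects with
replacement (1,000 resamples by default; one-class resamples are redrawn),
reporting the mean and the 2.5/97.5 percentile CI. The operating point is
the cut-off maximising the Youden index J = sensitivity + specificity − 1
over all distinct score thresholds (a subject is called MCI at
`score ≥ cutoff`); ties prefer the higher specificity, matching the
screening use-case where false alarms are costly. Accuracy is computed at
that cut-off on the pooled out-of-fold predictions. Correlations with
clinical scales (MMSE-like and functional scores) are Pearson r with
two-sided p; zero-variance inputs are flagged undefined.

## Synthetic cohort generator

The generator exists so the entire pipeline is testable without any
private clinical data. What it emulates and what it does not:

* **Typing**: log-normal hold times (median 100 ms, log-sd 0.3) and
  inter-key gaps (median 250 ms, log-sd 0.5), session lengths log-normal
  around 60 keys (support crossing the 40-press QC threshold), long pauses
  (3–10 s) at rate 0.03 and rollover gaps at rate 0.02. Timestamps are
  assembled so the HT/FT definitions recover the drawn quantized values
  exactly (asserted). Not modelled: diurnal drift, fatigue within a
  session, key-position effects.
* **Severity data**: subjects cycle through severities 0–4; severity adds
  0.12 to the HT log-mean, 0.04 to the HT log-sd and 0.10 to the FT
  log-mean per unit — a monotone mapping — and the three item scores are
  the latent severity plus small rounding noise (inter-item r > 0.8).
* **Texts**: Zipf vocabulary (exponent 1.1 over 300 types), stopword
  insertions at rate 0.35 from a 25-word synthetic stopword list, content
  POS tags from a NOUN/VERB/PRON/ADJ/ADV multinomial, and random
  projective dependency trees in which every token attaches toward the
  root at a geometric distance (parameter 0.5), so one dial controls MDD
  and the adjacency limit gives MDD = 1 exactly. No real morphology,
  syntax or semantics is modelled — passing tests show the *measurement
  machinery* and *statistical pipeline* are correct, not that the features
  separate real clinical groups.
* **Group effects**: each effect dial is a standardized shift `d` of a
  subject-level parameter (in units of its between-subject SD), applied in
  the impairment direction: longer/more variable holds, slower
  transitions, steeper Zipf exponent, fewer stopwords, fewer nouns, more
  pronouns, shorter dependency distances. The calibration of the dial is
  asserted: the measured standardized group difference in session-mean HT
  is within 20% of the requested `d` at 200 subjects. Clinical scores are
  generated with MMSE-like values declining in the impairment latent and
  functional scores rising, so correlation analyses are exercisable.
* **Cohort defaults** mirror the study composition (11 MCI, 12 HC) with
  scaled-down volumes: 20 sessions and 4 texts per subject (the texts
  match the study; sessions are a tractable stand-in for the >100 per
  subject a live deployment accumulates).

Everything is driven by one `numpy.random.Generator` seed; the same spec
writes byte-identical artifact files, and the manifest records the spec and
all base distribution parameters.

## Numerical and degenerate-input choices

* Strict inequalities at both timing cut-offs; sessions emptied by
  filtering are flagged unusable and dropped with a warning.
* Single-token sentences are skipped in MDD (no defined link distance);
  documents with no usable sentence raise a feature-level error.
* Sentences without exactly one root, or with out-of-range head indices,
  are rejected at parse with a warning rather than poisoning the document.
* Bootstrap resamples containing a single class are redrawn, keeping the
  effective resample count at the requested 1,000.
* k-NN probability ties and the coarse probability grid (multiples of 1/7)
  are handled by the Youden tie rule (higher specificity, then higher
  cut-off).
* Neural-network training aborts with diagnostics on non-finite loss.

## Limitations

* The linguistic generator's independence assumptions (token forms
  independent of tags and of tree structure) make the nine features easier
  to separate than in real text; synthetic AUCs say nothing about clinical
  effect sizes.
* The per-subject aggregation of session indices (mean) discards
  within-subject variability that may itself be informative.
* CoNLL-U enhanced dependencies, empty nodes and multiword-token ranges
  are ignored (only the basic tree is used).
* The leakage experiment demonstrates inflation for in-sample stacking on
  one construction; it is a regression guard, not a general audit of
  stacking schemes.
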