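# cogtype

Digital-biomarker screening for mild cognitive impairment (MCI) from two
unobtrusive data streams people already produce on their phones: **how**
they type (keystroke dynamics) and **what** they write (spontaneous written
speech). The package is aimed at researchers in digital phenotyping and
computational neuropsychology who want a reproducible, privacy-aware
pipeline from raw timestamp/text records to bootstrapped classification
results — plus a synthetic cohort generator so every stage can be validated
without access to clinical data.

## What it computes

**Keystroke dynamics.** From press/release timestamp pairs of a typing
session, hold times HTₙ = tₙʳ − tₙᵖ and flight times FTₙ = tₙ₊₁ᵖ − tₙʳ;
sessions with ≤ 40 presses are dropped, HT ≥ 0.7 s and FT ≥ 3 s are
filtered out as pauses, and series are zero-padded to length 100. No
character content is ever represented.

**Fine-motor-impairment (FMI) indices.** A 1-D convolutional autoencoder
(two conv layers, kernel 5, 16 filters, no pooling) is pretrained to
reconstruct the padded HT/FT sequences; a two-layer head (50 hidden units)
is then fine-tuned end-to-end, one regressor per symptom — rigidity (R),
bradykinesia (B), alternate finger tapping (AFT) — against 0–4 item
scores, evaluated with leave-one-subject-out (LOSO) cross-validation.

**Linguistic biomarkers.** Nine features per dependency-parsed (CoNLL-U)
text, averaged per subject: type/token ratio `dvrst = V/W`, Brunet index
`BI = W^(V^−0.165)`, Honoré statistic `HS = 100·ln W / (1 − hap/V)`, mean
words per sentence, non-stopword vocabulary fraction, noun/verb ratio,
noun ratio, pronoun ratio, and mean dependency distance
`MDD = (1/(N−1)) Σ|DDᵢ|` averaged over sentences.

**Cohort experiments.** Per-subject feature tables feed LOSO-validated
classifiers (logistic regression, random forest, 7-NN) with fold-internal
standardization, univariate feature selection, cascaded fusion designs
(A/B/C, with nested inner LOSO for the first-stage probabilities so
stacking cannot leak labels), bootstrap ROC (1,000 resamples, 95%
percentile CI), Youden-index operating points, and Pearson correlation
against clinical scales.

## Worked example

```python
from cogtype import classify as cl, pipeline, simulate as sim

spec = sim.CohortSpec(n_mci=10, n_hc=7, sessions_per_subject=10,
                      texts_per_subject=4, seed=42)   # moderate effects, d = 1
cohort = sim.simulate_cohort_data(spec)
table = pipeline.cohort_feature_table(cohort)          # one row per subject
res = cl.run_experiment(table, "logistic_regression",
                        cl.FEATURE_PRESETS["exp1"], seed=1)
print(round(res.mean_auc, 3),
      tuple(round(x, 3) for x in res.auc_ci),
      round(res.accuracy, 3))
```

prints

```
0.752 (0.472, 0.971) 0.765
```

i.e. with 17 subjects and moderate group effects the linguistic screen
(nonstop, dvrst, HS, MDD with logistic regression) reaches a mean
bootstrap AUC of 0.75 whose 95% CI (0.47–0.97) is still too wide to
exclude chance — exactly the small-cohort uncertainty the bootstrap is
there to expose. Raising the effect sizes or the cohort size (see
`CohortSpec`) drives the AUC toward 1 and narrows the CI; setting all
effects to 0 centres it on 0.5.

The same pipeline is available from the shell:

```sh
cogtype simulate --seed 42 --out data/
cogtype extract-keys --input data/sessions.jsonl --out dynamics.npz
cogtype extract-nlp --conllu data/conllu --stopwords data/stopwords.txt --out nlp.csv
cogtype train-fmi --out models/
cogtype infer-fmi --models models/ --input data/sessions.jsonl --out indices.csv
```

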