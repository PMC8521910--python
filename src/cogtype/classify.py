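"""Cohort classification: LOSO cross-validation, cascaded fusion models,
bootstrap ROC evaluation, Youden cut-offs and clinical-score correlations.

The screening task is binary (MCI = 1, healthy control = 0) on a per-subject
feature table.  Three experiment families mirror the study design:

* EXP1 — linguistic features only (optimal preset: nonstop, dvrst, HS, MDD),
* EXP2 — keystroke-derived severity indices (B and R),
* EXP3 — fused designs on subjects with both modalities: first-stage models
  ``just_nlp`` (logistic regression on nonstop, dvrst, MDD) and ``just_keys``
  (7-NN on B, R), and cascades A (RF on P(just_nlp) + B), B (7-NN on
  P(just_keys) + dvrst, nonstop, MDD) and C (RF on both probabilities).

Every pipeline standardises features *inside* the training fold (zero mean,
unit variance) before fitting the classifier, so the held-out subject never
leaks into the scaler.  Cascade first-stage probabilities are produced by a
nested inner LOSO within each outer training fold, the standard guard
against stacking leakage; a deliberately leaky mode exists purely to
demonstrate the inflation it causes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import pearsonr
from sklearn.feature_selection import f_classif
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.metrics import roc_auc_score

logger = logging.getLogger(__name__)

LABEL_COL = "label"

#: Documented optimal feature presets per experiment.
FEATURE_PRESETS = {
    "exp1": ["nonstop", "dvrst", "HS", "MDD"],
    "exp2": ["B", "R"],
    "just_nlp": ["nonstop", "dvrst", "MDD"],
    "just_keys": ["B", "R"],
}

#: Extra (raw) features each cascade design appends to the first-stage
#: probabilities, and its second-stage classifier.
CASCADE_DESIGNS = {
    "just_nlp": {"stages": [], "extra": FEATURE_PRESETS["just_nlp"],
                 "classifier": "logistic_regression"},
    "just_keys": {"stages": [], "extra": FEATURE_PRESETS["just_keys"],
                  "classifier": "knn"},
    "A": {"stages": ["just_nlp"], "extra": ["B"],
          "classifier": "random_forest"},
    "B": {"stages": ["just_keys"], "extra": ["dvrst", "nonstop", "MDD"],
          "classifier": "knn"},
    "C": {"stages": ["just_nlp", "just_keys"], "extra": [],
          "classifier": "random_forest"},
}


@dataclass(frozen=True)
class CVPredictions:
    """Out-of-fold predicted MCI probabilities: one per subject."""

    subject_ids: list[str]
    scores: np.ndarray   # predicted P(MCI)
    labels: np.ndarray   # true labels, 0/1
    fold_ids: list[str]

    def __post_init__(self):
        n = len(self.subject_ids)
        if len(set(self.subject_ids)) != n:
            raise ValueError("duplicate subject in predictions")
        if not (len(self.scores) == len(self.labels) == len(self.fold_ids) == n):
            raise ValueError("prediction fields must have equal length")


@dataclass(frozen=True)
class ExperimentResult:
    """Bootstrap ROC summary at the Youden-optimal operating point."""

    mean_auc: float
    auc_ci: tuple[float, float]
    accuracy: float
    specificity: float
    sensitivity: float
    cutoff: float
    n_bootstraps: int
    classifier: str
    feature_set: list[str]

    def to_dict(self) -> dict:
        return {
            "mean_auc": self.mean_auc,
            "auc_ci_low": self.auc_ci[0], "auc_ci_high": self.auc_ci[1],
            "accuracy": self.accuracy, "specificity": self.specificity,
            "sensitivity": self.sensitivity, "cutoff": self.cutoff,
            "n_bootstraps": self.n_bootstraps, "classifier": self.classifier,
            "feature_set": list(self.feature_set),
        }


def _validate_table(table: pd.DataFrame) -> None:
    if table.index.has_duplicates:
        raise ValueError("feature table has duplicate subjects")
    if LABEL_COL not in table.columns:
        raise ValueError(f"feature table needs a '{LABEL_COL}' column")
    labels = set(table[LABEL_COL].unique())
    if not labels <= {0, 1}:
        raise ValueError(f"labels must be binary 0/1, got {labels}")


def make_classifier(name: str, seed: int = 0):
    """The three classifier families (k = 7 for the nearest-neighbour one).

    Logistic regression and the random forest use class-balanced weighting:
    under LOSO every training fold is depleted by exactly one member of the
    held-out subject's class, and with weak features that prior shift alone
    orders predictions *against* the true labels (anti-correlated
    out-of-fold probabilities, AUC far below 0.5 on null data).  Balancing
    the class weights cancels the fold-induced prior so chance-level
    features score at chance.
    """
    if name == "logistic_regression":
        return LogisticRegression(C=1.0, max_iter=1000,
                                  class_weight="balanced")
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed,
                                      class_weight="balanced")
    if name == "knn":
        return KNeighborsClassifier(n_neighbors=7)
    raise ValueError(f"unknown classifier {name!r}")


def select_features(table: pd.DataFrame, k: int) -> list[tuple[str, float]]:
    """Rank features by univariate association with the label; return top-k.

    The score is the one-way ANOVA F statistic of feature vs label (for a
    binary label, equivalent to the squared two-sample t statistic); constant
    features score 0 and rank last.
    """
    _validate_table(table)
    feats = [c for c in table.columns if c != LABEL_COL]
    if len(feats) < 2:
        raise ValueError("need at least two features to select from")
    X = table[feats].to_numpy(dtype=float)
    y = table[LABEL_COL].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    with np.errstate(divide="ignore", invalid="ignore"):
        scores, _ = f_classif(X, y)
    scores = np.nan_to_num(scores, nan=0.0, posinf=np.finfo(float).max)
    order = np.argsort(-scores, kind="stable")
    ranked = [(feats[i], float(scores[i])) for i in order]
    return ranked[:k]


def _knn_k_for(n_train: int, classifier: str) -> int:
    # 7-NN needs >= 7 training subjects; smaller folds degrade gracefully
    return min(7, n_train)


def _fold_mask(y: np.ndarray, i: int, rng: np.random.Generator,
               paired: bool) -> np.ndarray:
    """Training mask for the fold holding out subject ``i``.

    With ``paired=True`` (the default) one randomly chosen subject of the
    *opposite* class is dropped as well, so every training fold has the
    same class composition regardless of the held-out subject's label.
    Plain leave-one-out depletes the held-out subject's own class by one,
    and that composition shift alone anti-orders the pooled out-of-fold
    scores on uninformative features (AUC well below 0.5 on null data, for
    every classifier family); matching the composition removes the
    artifact while each prediction remains strictly out-of-fold.
    """
    train = np.ones(len(y), dtype=bool)
    train[i] = False
    if paired:
        opposite = np.flatnonzero((y != y[i]) & train)
        if len(opposite):
            train[rng.choice(opposite)] = False
    return train


def loso_predict(
    table: pd.DataFrame,
    classifier: str = "logistic_regression",
    features: list[str] | None = None,
    seed: int = 0,
    paired: bool = True,
) -> CVPredictions:
    """Leave-one-subject-out out-of-fold probabilities.

    Per fold: fit a StandardScaler on the training subjects, then the
    classifier, then predict the held-out subject's P(MCI).  Folds are
    composition-matched by default (see :func:`_fold_mask`).
    """
    _validate_table(table)
    feats = features or [c for c in table.columns if c != LABEL_COL]
    missing = [f for f in feats if f not in table.columns]
    if missing:
        raise KeyError(f"feature column(s) missing from table: {missing}")
    y = table[LABEL_COL].to_numpy()
    if min((y == 0).sum(), (y == 1).sum()) < 3:
        raise ValueError("need >= 3 subjects per class for LOSO")
    X = table[feats].to_numpy(dtype=float)

    fold_rng = np.random.default_rng(seed)
    scores = np.empty(len(table))
    for i in range(len(table)):
        train = _fold_mask(y, i, fold_rng, paired)
        clf = make_classifier(classifier, seed)
        if classifier == "knn":
            clf.set_params(n_neighbors=_knn_k_for(int(train.sum()), classifier))
        pipe = make_pipeline(StandardScaler(), clf)
        pipe.fit(X[train], y[train])
        scores[i] = pipe.predict_proba(X[i:i + 1])[0, 1]
    subjects = [str(s) for s in table.index]
    return CVPredictions(
        subject_ids=subjects, scores=scores, labels=y.copy(), fold_ids=subjects
    )


def _inner_loso_scores(X, y, classifier, seed, paired=True):
    """Out-of-fold probabilities within a training fold (nested LOSO)."""
    out = np.empty(len(X))
    fold_rng = np.random.default_rng(seed + 104729)
    for i in range(len(X)):
        train = _fold_mask(y, i, fold_rng, paired)
        if len(np.unique(y[train])) < 2:
            out[i] = 0.5
            continue
        clf = make_classifier(classifier, seed)
        if classifier == "knn":
            clf.set_params(n_neighbors=_knn_k_for(int(train.sum()), classifier))
        pipe = make_pipeline(StandardScaler(), clf)
        pipe.fit(X[train], y[train])
        out[i] = pipe.predict_proba(X[i:i + 1])[0, 1]
    return out


def cascade_predict(
    table: pd.DataFrame,
    design: str,
    seed: int = 0,
    nested: bool = True,
    paired: bool = True,
) -> CVPredictions:
    """Outer-LOSO predictions for one fused design (or a single-stage model).

    With ``nested=True`` (the default and the only defensible setting) the
    first-stage probabilities fed to the second-stage classifier are produced
    by an inner LOSO within each outer training fold, so no subject's label
    ever reaches a model that predicts it.  ``nested=False`` reproduces the
    classic stacking mistake — first-stage models fit once on the full table
    and their in-sample probabilities reused everywhere — and exists only for
    the leakage regression experiment.
    """
    _validate_table(table)
    if design not in CASCADE_DESIGNS:
        raise ValueError(f"unknown design {design!r}; one of {sorted(CASCADE_DESIGNS)}")
    d = CASCADE_DESIGNS[design]
    needed = set(d["extra"])
    for st in d["stages"]:
        needed |= set(CASCADE_DESIGNS[st]["extra"])
    missing = sorted(needed - set(table.columns))
    if missing:
        raise KeyError(f"design {design!r} needs missing feature column(s): {missing}")

    if not d["stages"]:
        return loso_predict(table, d["classifier"], d["extra"], seed,
                            paired=paired)

    y = table[LABEL_COL].to_numpy()
    X_extra = table[d["extra"]].to_numpy(dtype=float) if d["extra"] else \
        np.empty((len(table), 0))
    stage_X = {
        st: table[CASCADE_DESIGNS[st]["extra"]].to_numpy(dtype=float)
        for st in d["stages"]
    }

    leaky_probs = None
    if not nested:
        leaky_probs = {}
        for st in d["stages"]:
            clf = make_classifier(CASCADE_DESIGNS[st]["classifier"], seed)
            pipe = make_pipeline(StandardScaler(), clf)
            pipe.fit(stage_X[st], y)   # fit on everyone, score in-sample: leaks
            leaky_probs[st] = pipe.predict_proba(stage_X[st])[:, 1]

    fold_rng = np.random.default_rng(seed)
    scores = np.empty(len(table))
    for i in range(len(table)):
        train = _fold_mask(y, i, fold_rng, paired)
        cols_train, cols_test = [], []
        for st in d["stages"]:
            st_clf_name = CASCADE_DESIGNS[st]["classifier"]
            if nested:
                p_train = _inner_loso_scores(
                    stage_X[st][train], y[train], st_clf_name, seed,
                    paired=paired,
                )
                clf = make_classifier(st_clf_name, seed)
                if st_clf_name == "knn":
                    clf.set_params(
                        n_neighbors=_knn_k_for(int(train.sum()), st_clf_name))
                pipe = make_pipeline(StandardScaler(), clf)
                pipe.fit(stage_X[st][train], y[train])
                p_test = pipe.predict_proba(stage_X[st][i:i + 1])[0, 1]
            else:
                p_train = leaky_probs[st][train]
                p_test = leaky_probs[st][i]
            cols_train.append(p_train)
            cols_test.append(p_test)
        Z_train = np.column_stack(cols_train + [X_extra[train]]) if d["extra"] \
            else np.column_stack(cols_train)
        Z_test = np.concatenate([np.array(cols_test), X_extra[i]])[None] if d["extra"] \
            else np.array(cols_test)[None]
        clf2 = make_classifier(d["classifier"], seed)
        if d["classifier"] == "knn":
            clf2.set_params(n_neighbors=_knn_k_for(int(train.sum()), "knn"))
        pipe2 = make_pipeline(StandardScaler(), clf2)
        pipe2.fit(Z_train, y[train])
        scores[i] = pipe2.predict_proba(Z_test)[0, 1]

    subjects = [str(s) for s in table.index]
    return CVPredictions(
        subject_ids=subjects, scores=scores, labels=y.copy(), fold_ids=subjects
    )


def youden_cutoff(preds: CVPredictions) -> tuple[float, float, float]:
    """Cut-off maximising J = sensitivity + specificity − 1.

    A subject is called MCI when ``score >= cutoff``.  All distinct scores
    (plus +inf, i.e. call nobody) are enumerated; ties favour the higher
    specificity, then the higher cut-off.
    """
    y, s = preds.labels, preds.scores
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    pos, neg = (y == 1), (y == 0)
    best = None
    for t in np.concatenate([np.unique(s), [np.inf]]):
        call = s >= t
        se = float(call[pos].mean())
        sp = float((~call[neg]).mean())
        j = se + sp - 1.0
        key = (j, sp, t if np.isfinite(t) else np.inf)
        if best is None or key > best[0]:
            best = (key, (float(t), sp, se))
    return best[1]


def bootstrap_roc(
    preds: CVPredictions,
    n_boot: int = 1000,
    seed: int = 0,
    classifier: str = "",
    feature_set: list[str] | None = None,
) -> ExperimentResult:
    """Subject-level bootstrap of the ROC AUC plus the Youden operating point.

    Subjects are resampled with replacement ``n_boot`` times; one-class
    resamples are redrawn.  Reported are the mean AUC, the 2.5/97.5
    percentile CI, and accuracy/specificity/sensitivity at the Youden-optimal
    cut-off on the pooled out-of-fold predictions.
    """
    y, s = preds.labels, preds.scores
    if min((y == 0).sum(), (y == 1).sum()) < 2:
        raise ValueError("need >= 2 subjects per class for bootstrap ROC")
    rng = np.random.default_rng(seed)
    n = len(y)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if len(np.unique(y[idx])) == 2:
                break
        aucs[b] = roc_auc_score(y[idx], s[idx])
    cutoff, sp, se = youden_cutoff(preds)
    call = s >= cutoff
    accuracy = float((call == (y == 1)).mean())
    return ExperimentResult(
        mean_auc=float(aucs.mean()),
        auc_ci=(float(np.percentile(aucs, 2.5)), float(np.percentile(aucs, 97.5))),
        accuracy=accuracy, specificity=sp, sensitivity=se, cutoff=cutoff,
        n_bootstraps=n_boot, classifier=classifier,
        feature_set=feature_set or [],
    )


def clinical_correlation(values, scores) -> tuple[float, float]:
    """Pearson r and two-sided p between model output and a clinical scale."""
    x = np.asarray(values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("zero variance in correlation input; result undefined")
        return (float("nan"), float("nan"))
    r, p = pearsonr(x, y)
    return float(r), float(p)


def run_experiment(
    table: pd.DataFrame,
    design_or_classifier: str,
    features: list[str] | None = None,
    n_boot: int = 1000,
    seed: int = 0,
) -> ExperimentResult:
    """One end-to-end experiment: LOSO (or cascade) then bootstrap ROC."""
    if design_or_classifier in CASCADE_DESIGNS:
        preds = cascade_predict(table, design_or_classifier, seed=seed)
        name = design_or_classifier
        feats = features or CASCADE_DESIGNS[design_or_classifier]["extra"]
    else:
        preds = loso_predict(table, design_or_classifier, features, seed=seed)
        name = design_or_classifier
        feats = features or [c for c in table.columns if c != LABEL_COL]
    return bootstrap_roc(preds, n_boot=n_boot, seed=seed,
                         classifier=name, feature_set=feats)
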