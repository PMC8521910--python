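"""Glue between the feature extractors and the classification experiments:
per-subject feature tables from raw sessions/documents."""

from __future__ import annotations

from collections import defaultdict

import pandas as pd

from . import fmi, keystroke, linguistic
from .classify import LABEL_COL


def nlp_feature_table(
    documents, stopwords: set[str] = frozenset()
) -> pd.DataFrame:
    """One row per subject: the nine linguistic features, averaged over texts."""
    by_subject = defaultdict(list)
    for doc in documents:
        by_subject[doc.subject_id].append(
            linguistic.extract_features(doc, stopwords)
        )
    rows = {
        subj: vars(linguistic.aggregate_user_features(vecs))
        for subj, vecs in sorted(by_subject.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def fmi_feature_table(
    sessions,
    models,
    min_presses: int = keystroke.MIN_PRESSES,
) -> pd.DataFrame:
    """One row per subject: mean R/B/AFT indices over their usable sessions."""
    dynamics = keystroke.dynamics_pipeline(sessions, min_presses=min_presses)
    indices = fmi.predict_indices_batch(models, dynamics)
    by_subject = defaultdict(list)
    for ix in indices:
        by_subject[ix.subject_id].append(ix)
    rows = {
        subj: fmi.aggregate_subject_indices(ixs)
        for subj, ixs in sorted(by_subject.items())
    }
    return pd.DataFrame.from_dict(rows, orient="index")


def cohort_feature_table(
    cohort,
    models=None,
    stopwords: set[str] | None = None,
    min_presses: int = keystroke.MIN_PRESSES,
) -> pd.DataFrame:
    """Fused per-subject table: NLP features, FMI indices (when models are
    given) and the MCI/HC label."""
    from .simulate import STOPWORDS

    stop = set(STOPWORDS) if stopwords is None else stopwords
    table = nlp_feature_table(cohort.documents, stop)
    if models is not None:
        keys = fmi_feature_table(cohort.sessions, models, min_presses)
        table = table.join(keys.drop(columns=["n_sessions"]), how="inner")
    labels = pd.Series(
        {p.subject_id: p.label for p in cohort.subjects}, name=LABEL_COL
    )
    table = table.join(labels, how="inner")
    table.index.name = "subject_id"
    return table
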