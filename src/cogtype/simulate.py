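"""Synthetic cohort generation: typing sessions, severity-labelled training
data, and dependency-parsed documents with controllable group effects.

The generators emulate the structure of the study data — smartphone typing
sessions (press/release timestamp sequences) and short free-writing texts
stored as CoNLL-U — without any linguistic or behavioural realism beyond the
distributional features the pipeline measures:

* key hold times and inter-key gaps are log-normal (the standard model for
  keystroke latencies), with occasional long pauses (> 3 s) and rollover
  (negative gap) events so the filtering rules are exercised;
* word forms are drawn from a Zipf vocabulary, so the lexical-richness
  features respond to the Zipf exponent; POS tags come from a multinomial
  over NOUN/VERB/PRON/ADJ/ADV for content words;
* dependency trees are random projective trees built by attaching every
  token toward the root at a geometric distance, so the mean dependency
  distance is controlled by one attachment parameter and pre-order traversal
  is always well-defined.

Group (MCI vs HC) effects are standardized shifts ``d`` applied to
subject-level parameters, in the clinically observed directions: impaired
subjects type with longer and more variable hold times and slower
transitions, use a steeper Zipf exponent (poorer vocabulary), fewer
stopwords, fewer nouns, more pronouns, and shorter dependency distances.
Each ``d`` is in units of the between-subject standard deviation of that
parameter, so ``d = 0`` is an exact null and ``d = 2`` a large effect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .keystroke import TypingSession, compute_dynamics, filter_dynamics, pad_series
from .linguistic import ParsedDocument, Token
from .fmi import SeveritySample

#: Synthetic stopword inventory (also what the shipped stopword file holds).
STOPWORDS = tuple(f"s{i:02d}" for i in range(1, 26))

_FUNCTION_TAGS = ("ADP", "DET", "CCONJ")
_CONTENT_TAGS = ("NOUN", "VERB", "PRON", "ADJ", "ADV")


# ---------------------------------------------------------------------------
# Parameter containers


@dataclass(frozen=True)
class TypingParams:
    """Subject-level typing-session parameters (times in seconds)."""

    ht_log_mean: float = np.log(0.10)   # median hold time 100 ms
    ht_log_sd: float = 0.30
    ft_log_mean: float = np.log(0.25)   # median inter-key gap 250 ms
    ft_log_sd: float = 0.50
    n_keys_log_mean: float = np.log(60.0)
    n_keys_log_sd: float = 0.45
    long_pause_rate: float = 0.03       # gaps of 3-10 s, removed by the filter
    rollover_rate: float = 0.02         # negative flight times


@dataclass(frozen=True)
class DocParams:
    """Subject-level text-generation parameters."""

    zipf_exponent: float = 1.10
    vocab_size: int = 300
    stop_rate: float = 0.35
    noun_rate: float = 0.32             # multinomial over content tags
    verb_rate: float = 0.26
    pron_rate: float = 0.12
    attach_p: float = 0.50              # geometric head-distance parameter
    n_sents_mean: float = 5.0
    words_per_sent_mean: float = 9.0


#: Between-subject standard deviations of the group-shifted parameters.
SUBJECT_SD = {
    "ht_log_mean": 0.15,
    "ht_log_sd": 0.05,
    "ft_log_mean": 0.12,
    "zipf_exponent": 0.06,
    "stop_rate": 0.02,
    "noun_rate": 0.012,
    "pron_rate": 0.008,
    "attach_p": 0.04,
}


@dataclass(frozen=True)
class CohortSpec:
    """Cohort composition and standardized group effect sizes.

    Subject counts default to the study cohort (11 MCI, 12 HC); session and
    text counts are scaled-down defaults stated in the methods note.  Effect
    sizes are magnitudes; the generator applies each in the impairment
    direction.
    """

    n_mci: int = 11
    n_hc: int = 12
    sessions_per_subject: int = 20
    texts_per_subject: int = 4
    d_ht_loc: float = 1.0
    d_ht_scale: float = 1.0
    d_ft_loc: float = 1.0
    d_zipf: float = 1.0
    d_stopword: float = 1.0
    d_noun: float = 1.0
    d_pron: float = 1.0
    d_mdd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mci, self.n_hc, self.sessions_per_subject,
               self.texts_per_subject) < 1:
            raise ValueError("cohort counts must be positive")
        for name, val in asdict(self).items():
            if name.startswith("d_") and not np.isfinite(val):
                raise ValueError(f"effect size {name} must be finite")


@dataclass(frozen=True)
class SeverityGeneratorSpec:
    """Severity-labelled training data for the FMI regressors.

    Severity ``s`` in 0..4 shifts the hold-time log-mean and log-sd and the
    flight-time log-mean monotonically; the three item scores (rigidity,
    bradykinesia, alternate finger tapping) are the latent severity plus
    small independent perturbations, giving a high inter-item correlation.
    """

    n_subjects: int = 30
    sessions_per_subject: int = 20
    ht_loc_per_severity: float = 0.12   # log-scale increment per severity unit
    ht_scale_per_severity: float = 0.04
    ft_loc_per_severity: float = 0.10
    item_noise_sd: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if min(self.ht_loc_per_severity, self.ht_scale_per_severity,
               self.ft_loc_per_severity) < 0:
            raise ValueError("severity mapping must be monotone non-decreasing")


@dataclass
class SubjectProfile:
    subject_id: str
    label: int                      # MCI = 1, HC = 0
    typing: TypingParams
    doc: DocParams
    impairment: float               # latent, drives clinical scores


@dataclass
class CohortData:
    spec: CohortSpec
    subjects: list[SubjectProfile]
    sessions: list[TypingSession]
    documents: list[ParsedDocument]
    clinical: "dict[str, dict[str, float]]"   # subject -> scale -> score


# ---------------------------------------------------------------------------
# Typing sessions


def simulate_typing_session(
    params: TypingParams,
    rng: np.random.Generator,
    subject_id: str = "s0",
    session_id: str = "sess0",
    return_truth: bool = False,
):
    """One synthetic typing session.

    Hold times and inter-key gaps are drawn log-normal, quantized to integer
    milliseconds, and assembled into press/release timestamps such that the
    HT/FT definitions recover the drawn (quantized) values exactly.  With
    stated rates, long pauses (3–10 s) and rollover gaps are injected.
    """
    n = max(2, int(round(rng.lognormal(params.n_keys_log_mean,
                                       params.n_keys_log_sd))))
    ht_ms = np.round(
        rng.lognormal(params.ht_log_mean, params.ht_log_sd, size=n) * 1000
    ).astype(np.int64)
    ht_ms = np.maximum(ht_ms, 1)
    gap_ms = np.round(
        rng.lognormal(params.ft_log_mean, params.ft_log_sd, size=n - 1) * 1000
    ).astype(np.int64)
    long_pause = rng.random(n - 1) < params.long_pause_rate
    gap_ms[long_pause] = np.round(rng.uniform(3000, 10000, long_pause.sum()))
    rollover = (rng.random(n - 1) < params.rollover_rate) & ~long_pause
    # rollover: next press precedes this release, but stays after this press
    gap_ms[rollover] = -np.minimum(30, ht_ms[:-1][rollover] // 2)

    start = 1_600_000_000_000 + int(rng.integers(0, 10**9))
    press = np.empty(n, dtype=np.int64)
    release = np.empty(n, dtype=np.int64)
    press[0] = start
    for i in range(n):
        release[i] = press[i] + ht_ms[i]
        if i + 1 < n:
            press[i + 1] = release[i] + gap_ms[i]
    session = TypingSession(
        session_id=session_id, subject_id=subject_id,
        press_times=press, release_times=release,
    )
    if return_truth:
        return session, ht_ms / 1000.0, gap_ms / 1000.0
    return session


# ---------------------------------------------------------------------------
# Documents


def _random_projective_tree(n: int, attach_p: float, rng: np.random.Generator):
    """Heads for tokens 1..n: each non-root attaches toward the root at a
    geometric distance, guaranteeing a single-rooted projective tree."""
    heads = np.zeros(n, dtype=int)
    root = int(rng.integers(0, n))
    for i in range(n):
        if i == root:
            continue
        g = int(rng.geometric(attach_p))
        step = min(g, abs(i - root))
        heads[i] = (i - step if i > root else i + step) + 1  # 1-based
    return heads, root


def simulate_document(
    params: DocParams,
    rng: np.random.Generator,
    doc_id: str = "d0",
    subject_id: str = "s0",
) -> ParsedDocument:
    """One synthetic parsed document (paragraph-scale)."""
    ranks = np.arange(1, params.vocab_size + 1)
    zipf_p = ranks ** (-params.zipf_exponent)
    zipf_p /= zipf_p.sum()
    other = max(1e-9, 1.0 - params.noun_rate - params.verb_rate - params.pron_rate)
    tag_p = np.array([params.noun_rate, params.verb_rate, params.pron_rate,
                      other * 0.6, other * 0.4])
    tag_p /= tag_p.sum()

    n_sents = 1 + rng.poisson(max(params.n_sents_mean - 1, 0.0))
    sentences = []
    for _ in range(n_sents):
        n = 2 + rng.poisson(max(params.words_per_sent_mean - 2, 0.0))
        heads, _root = _random_projective_tree(n, params.attach_p, rng)
        tokens = []
        for i in range(n):
            if rng.random() < params.stop_rate:
                form = STOPWORDS[rng.integers(len(STOPWORDS))]
                upos = _FUNCTION_TAGS[rng.integers(len(_FUNCTION_TAGS))]
            else:
                form = f"w{1 + rng.choice(params.vocab_size, p=zipf_p):03d}"
                upos = _CONTENT_TAGS[rng.choice(len(tag_p), p=tag_p)]
            tokens.append(Token(id=i + 1, form=form, upos=upos, head=int(heads[i])))
        sentences.append(tokens)
    return ParsedDocument(doc_id=doc_id, subject_id=subject_id, sentences=sentences)


def document_to_conllu(doc: ParsedDocument) -> str:
    """Serialize a document to standard 10-column CoNLL-U."""
    lines = [f"# newdoc id = {doc.doc_id}", f"# subject_id = {doc.subject_id}"]
    for k, sent in enumerate(doc.sentences, start=1):
        lines.append(f"# sent_id = {doc.doc_id}-{k}")
        for tok in sent:
            deprel = "root" if tok.head == 0 else "dep"
            lines.append("\t".join([
                str(tok.id), tok.form, tok.form, tok.upos, "_", "_",
                str(tok.head), deprel, "_", "_",
            ]))
        lines.append("")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Severity dataset


def simulate_severity_dataset(
    spec: SeverityGeneratorSpec = SeverityGeneratorSpec(),
) -> list[SeveritySample]:
    """Severity-labelled typing sessions for fine-tuning the FMI regressors.

    Subjects cycle through severities 0..4; each subject's sessions are drawn
    with the monotone severity-to-timing mapping, filtered and padded exactly
    as the production pipeline does, and labelled with three correlated item
    scores.
    """
    rng = np.random.default_rng(spec.seed)
    base = TypingParams()
    samples: list[SeveritySample] = []
    for s_idx in range(spec.n_subjects):
        severity = s_idx % 5
        sid = f"sev{s_idx:03d}"
        scores = tuple(
            int(np.clip(round(severity + rng.normal(0, spec.item_noise_sd)), 0, 4))
            for _ in range(3)
        )
        params = TypingParams(
            ht_log_mean=base.ht_log_mean + spec.ht_loc_per_severity * severity,
            ht_log_sd=base.ht_log_sd + spec.ht_scale_per_severity * severity,
            ft_log_mean=base.ft_log_mean + spec.ft_loc_per_severity * severity,
            long_pause_rate=base.long_pause_rate,
            rollover_rate=base.rollover_rate,
        )
        for k in range(spec.sessions_per_subject):
            sess = simulate_typing_session(
                params, rng, subject_id=sid, session_id=f"{sid}-{k:03d}"
            )
            dyn = pad_series(filter_dynamics(compute_dynamics(sess)))
            samples.append(
                SeveritySample(dynamics=dyn, subject_id=sid, scores=scores)
            )
    return samples


# ---------------------------------------------------------------------------
# Full cohort


def _subject_profile(
    label: int, spec: CohortSpec, rng: np.random.Generator, subject_id: str
) -> SubjectProfile:
    sd = SUBJECT_SD

    def draw(base, key, d_effect, direction):
        shift = direction * d_effect * sd[key] * label
        return base + shift + rng.normal(0, sd[key])

    t0, d0 = TypingParams(), DocParams()
    typing = TypingParams(
        ht_log_mean=draw(t0.ht_log_mean, "ht_log_mean", spec.d_ht_loc, +1),
        ht_log_sd=max(0.05, draw(t0.ht_log_sd, "ht_log_sd", spec.d_ht_scale, +1)),
        ft_log_mean=draw(t0.ft_log_mean, "ft_log_mean", spec.d_ft_loc, +1),
    )
    doc = DocParams(
        zipf_exponent=max(0.5, draw(d0.zipf_exponent, "zipf_exponent",
                                    spec.d_zipf, +1)),
        stop_rate=float(np.clip(draw(d0.stop_rate, "stop_rate",
                                     spec.d_stopword, -1), 0.05, 0.8)),
        noun_rate=float(np.clip(draw(d0.noun_rate, "noun_rate",
                                     spec.d_noun, -1), 0.05, 0.6)),
        pron_rate=float(np.clip(draw(d0.pron_rate, "pron_rate",
                                     spec.d_pron, +1), 0.01, 0.4)),
        attach_p=float(np.clip(draw(d0.attach_p, "attach_p",
                                    spec.d_mdd, +1), 0.15, 0.95)),
    )
    # impairment latent: standardized typing-speed deviation from the base
    impairment = (typing.ht_log_mean - t0.ht_log_mean) / sd["ht_log_mean"]
    return SubjectProfile(subject_id=subject_id, label=label,
                          typing=typing, doc=doc, impairment=impairment)


def simulate_cohort_data(spec: CohortSpec = CohortSpec()) -> CohortData:
    """Generate the full cohort in memory (sessions, documents, clinical)."""
    rng = np.random.default_rng(spec.seed)
    subjects = []
    for i in range(spec.n_mci):
        subjects.append(_subject_profile(1, spec, rng, f"mci{i:03d}"))
    for i in range(spec.n_hc):
        subjects.append(_subject_profile(0, spec, rng, f"hc{i:03d}"))

    sessions, documents, clinical = [], [], {}
    for prof in subjects:
        for k in range(spec.sessions_per_subject):
            sessions.append(simulate_typing_session(
                prof.typing, rng, subject_id=prof.subject_id,
                session_id=f"{prof.subject_id}-k{k:03d}",
            ))
        for k in range(spec.texts_per_subject):
            documents.append(simulate_document(
                prof.doc, rng, doc_id=f"{prof.subject_id}-t{k:02d}",
                subject_id=prof.subject_id,
            ))
        # MMSE-like scale declines with impairment; the functional scales rise
        clinical[prof.subject_id] = {
            "MMSE": float(28.0 - 1.2 * prof.impairment + rng.normal(0, 0.8)),
            "FUCAS": float(45.0 + 3.0 * prof.impairment + rng.normal(0, 2.0)),
            "FRSSD": float(4.0 + 1.5 * prof.impairment + rng.normal(0, 1.0)),
        }
    return CohortData(spec=spec, subjects=subjects, sessions=sessions,
                      documents=documents, clinical=clinical)


def simulate_cohort(
    spec: CohortSpec, out_dir, force: bool = False
) -> CohortData:
    """Generate a cohort and write every artifact the other modules read.

    Produces ``sessions.jsonl``, ``conllu/<doc>.conllu``, ``labels.csv``,
    ``clinical.csv``, ``stopwords.txt`` and ``manifest.json`` under
    ``out_dir``.  Deterministic: the same spec (including seed) writes
    byte-identical files.
    """
    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"{out} is not empty (use force=True)")
    (out / "conllu").mkdir(parents=True, exist_ok=True)
    data = simulate_cohort_data(spec)

    with open(out / "sessions.jsonl", "w", encoding="utf-8") as fh:
        for s in data.sessions:
            fh.write(json.dumps({
                "session_id": s.session_id, "subject_id": s.subject_id,
                "press": s.press_times.tolist(),
                "release": s.release_times.tolist(),
            }) + "\n")
    for doc in data.documents:
        (out / "conllu" / f"{doc.doc_id}.conllu").write_text(
            document_to_conllu(doc), encoding="utf-8"
        )
    with open(out / "labels.csv", "w", encoding="utf-8") as fh:
        fh.write("subject_id,label\n")
        for prof in data.subjects:
            fh.write(f"{prof.subject_id},{prof.label}\n")
    with open(out / "clinical.csv", "w", encoding="utf-8") as fh:
        fh.write("subject_id,MMSE,FUCAS,FRSSD\n")
        for prof in data.subjects:
            c = data.clinical[prof.subject_id]
            fh.write(f"{prof.subject_id},{c['MMSE']:.3f},{c['FUCAS']:.3f},"
                     f"{c['FRSSD']:.3f}\n")
    (out / "stopwords.txt").write_text(
        "\n".join(STOPWORDS) + "\n", encoding="utf-8"
    )
    (out / "manifest.json").write_text(
        json.dumps({"spec": asdict(spec), "subject_sd": SUBJECT_SD,
                    "typing_base": asdict(TypingParams()),
                    "doc_base": asdict(DocParams())}, indent=2) + "\n",
        encoding="utf-8",
    )
    return data
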