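"""Nine written-speech biomarkers from dependency-parsed documents.

Inputs are CoNLL-U documents (already POS-tagged and dependency-parsed).
Per document the features are:

* ``dvrst = V / W`` — type/token ratio (W word tokens, V distinct forms),
* ``BI = W ** (V ** -0.165)`` — Brunet index; richer language gives *lower*
  values, roughly independent of text length,
* ``HS = 100 * ln(W) / (1 - hap / V)`` — Honoré statistic with ``hap`` the
  hapax-legomena count; richer language gives *higher* values,
* ``wrd_sent`` — mean word-token count per sentence,
* ``nonstop`` — fraction of the vocabulary that is not a stopword,
* ``NnVrb = nn / vrb``, ``Nn = nn / (vrb + nn)``, ``Prn = prn / (nn + prn)``
  — word-class ratios over NOUN/VERB/PRON counts,
* ``MDD`` — mean dependency distance: per sentence the mean absolute
  positional distance of every non-root word token to its head, then the
  mean over sentences.

Word tokens are the non-punctuation tokens; vocabulary is over case-folded
surface forms.  Undefined features (zero denominator, hap == V) are returned
as NaN sentinels and masked during per-user aggregation, so a single
degenerate text cannot abort a subject.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

FEATURE_NAMES = (
    "dvrst", "BI", "HS", "wrd_sent", "nonstop", "NnVrb", "Nn", "Prn", "MDD",
)


@dataclass(frozen=True)
class Token:
    """One syntactic word: 1-based position, surface form, UPOS tag, head id.

    ``head == 0`` marks the sentence root.
    """

    id: int
    form: str
    upos: str
    head: int

    @property
    def is_word(self) -> bool:
        return self.upos != "PUNCT"


@dataclass(frozen=True)
class ParsedDocument:
    """A CoNLL-U-backed document: list of sentences, each a list of Tokens."""

    doc_id: str
    subject_id: str
    sentences: list[list[Token]]

    def word_tokens(self):
        for sent in self.sentences:
            for tok in sent:
                if tok.is_word:
                    yield tok


@dataclass
class NLPFeatureVector:
    """The nine per-document features; NaN marks an undefined component."""

    dvrst: float
    BI: float
    HS: float
    wrd_sent: float
    nonstop: float
    NnVrb: float
    Nn: float
    Prn: float
    MDD: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, f.name) for f in fields(self)])


# ---------------------------------------------------------------------------
# CoNLL-U reading


def _parse_sentence(lines: list[str], where: str) -> list[Token] | None:
    tokens: list[Token] = []
    for line in lines:
        cols = line.split("\t")
        if len(cols) != 10:
            raise ValueError(f"{where}: expected 10 columns, got {len(cols)}")
        tok_id = cols[0]
        # multiword-token ranges (1-2) and empty nodes (1.1) carry no tree link
        if "-" in tok_id or "." in tok_id:
            continue
        tokens.append(
            Token(id=int(tok_id), form=cols[1], upos=cols[3], head=int(cols[6]))
        )
    n = len(tokens)
    roots = [t for t in tokens if t.head == 0]
    if len(roots) != 1:
        logger.warning("%s: sentence with %d roots rejected", where, len(roots))
        return None
    for t in tokens:
        if not (1 <= t.id <= n) or not (0 <= t.head <= n) or t.head == t.id:
            logger.warning("%s: token id/head out of range, sentence rejected", where)
            return None
    return tokens


def parse_conllu(text: str, doc_id: str = "", subject_id: str = "") -> ParsedDocument | None:
    """Parse one CoNLL-U document from a string; None when it has no sentences.

    Comment lines are honoured for metadata (``# subject_id = ...`` overrides
    the argument); sentences violating the single-root invariant are dropped
    with a warning.
    """
    sentences: list[list[Token]] = []
    current: list[str] = []
    n_sent = 0
    for raw in text.splitlines() + [""]:
        line = raw.rstrip("\n")
        if line.startswith("#"):
            body = line[1:].strip()
            if body.startswith("subject_id"):
                _, _, val = body.partition("=")
                subject_id = val.strip() or subject_id
            continue
        if line.strip() == "":
            if current:
                n_sent += 1
                sent = _parse_sentence(current, f"{doc_id} sentence {n_sent}")
                if sent is not None:
                    sentences.append(sent)
                current = []
            continue
        current.append(line)
    if not sentences:
        return None
    return ParsedDocument(doc_id=doc_id, subject_id=subject_id, sentences=sentences)


def read_conllu(path) -> list[ParsedDocument]:
    """Read CoNLL-U documents from a file or a directory of ``.conllu`` files."""
    p = Path(path)
    paths = sorted(p.glob("*.conllu")) if p.is_dir() else [p]
    docs = []
    for fp in paths:
        doc = parse_conllu(fp.read_text(encoding="utf-8"), doc_id=fp.stem)
        if doc is not None:
            docs.append(doc)
    return docs


def read_stopwords(path) -> set[str]:
    """Load a stopword list: UTF-8 text, one word per line, case-folded."""
    words = set()
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        w = line.strip().casefold()
        if w:
            words.add(w)
    return words


# ---------------------------------------------------------------------------
# Feature computations


def _vocab_counts(doc: ParsedDocument) -> dict[str, int]:
    counts: dict[str, int] = {}
    for tok in doc.word_tokens():
        key = tok.form.casefold()
        counts[key] = counts.get(key, 0) + 1
    return counts


def lexical_features(doc: ParsedDocument) -> tuple[float, float, float]:
    """Type/token ratio, Brunet index and Honoré statistic for one document."""
    counts = _vocab_counts(doc)
    W = sum(counts.values())
    if W == 0:
        raise ValueError(f"document {doc.doc_id}: no word tokens")
    V = len(counts)
    hap = sum(1 for c in counts.values() if c == 1)
    dvrst = V / W
    BI = W ** (V ** -0.165)
    HS = 100.0 * math.log(W) / (1.0 - hap / V) if hap < V else math.nan
    return dvrst, BI, HS


def structure_features(
    doc: ParsedDocument, stopwords: set[str]
) -> tuple[float, float]:
    """Mean words per sentence and the non-stopword vocabulary fraction."""
    w_sents = [sum(t.is_word for t in sent) for sent in doc.sentences]
    w_sents = [n for n in w_sents if n > 0]
    if not w_sents:
        raise ValueError(f"document {doc.doc_id}: no sentence with word tokens")
    wrd_sent = sum(w_sents) / len(w_sents)
    vocab = set(_vocab_counts(doc))
    content = vocab - stopwords
    nonstop = len(content) / len(vocab)
    return wrd_sent, nonstop


def word_class_features(
    doc: ParsedDocument, noun_tags: frozenset[str] = frozenset({"NOUN"})
) -> tuple[float, float, float]:
    """Noun/verb, noun and pronoun ratios from the UPOS tags.

    ``noun_tags`` is configurable (e.g. to include PROPN); zero denominators
    yield NaN.
    """
    nn = vrb = prn = 0
    for tok in doc.word_tokens():
        if tok.upos in noun_tags:
            nn += 1
        elif tok.upos == "VERB":
            vrb += 1
        elif tok.upos == "PRON":
            prn += 1
    NnVrb = nn / vrb if vrb else math.nan
    Nn = nn / (vrb + nn) if (vrb + nn) else math.nan
    Prn = prn / (nn + prn) if (nn + prn) else math.nan
    return NnVrb, Nn, Prn


def _preorder(sent: list[Token]) -> list[Token]:
    """Pre-order traversal (root, then subtrees left-to-right) of word tokens."""
    words = [t for t in sent if t.is_word]
    children: dict[int, list[Token]] = {t.id: [] for t in words}
    root = None
    for t in words:
        if t.head == 0:
            root = t
        elif t.head in children:
            children[t.head].append(t)
    order: list[Token] = []
    if root is None:
        return order
    stack = [root]
    while stack:
        node = stack.pop()
        order.append(node)
        stack.extend(sorted(children[node.id], key=lambda t: -t.id))
    return order


def compute_mdd(doc: ParsedDocument) -> float:
    """Document mean dependency distance.

    Per sentence: distances ``|position(head) - position(dependent)|`` over
    word-token positions for every non-root word token, summed and divided by
    ``N - 1`` (N word tokens; the root contributes no link).  The document
    value is the mean over sentences.  Distances are accumulated during a
    pre-order tree traversal; sentences with fewer than two word tokens are
    skipped with a warning.
    """
    sent_mdds = []
    for i, sent in enumerate(doc.sentences):
        words = [t for t in sent if t.is_word]
        n = len(words)
        if n < 2:
            logger.warning(
                "document %s sentence %d: <2 word tokens, skipped", doc.doc_id, i + 1
            )
            continue
        pos = {t.id: rank for rank, t in enumerate(words, start=1)}
        total = 0
        visited = 0
        for tok in _preorder(sent):
            visited += 1
            if tok.head != 0:
                if tok.head not in pos:
                    logger.warning(
                        "document %s sentence %d: head of %r is punctuation, "
                        "link skipped", doc.doc_id, i + 1, tok.form,
                    )
                    continue
                total += abs(pos[tok.head] - pos[tok.id])
        if visited < n:
            logger.warning(
                "document %s sentence %d: %d token(s) unreachable from root",
                doc.doc_id, i + 1, n - visited,
            )
        sent_mdds.append(total / (n - 1))
    if not sent_mdds:
        raise ValueError(f"document {doc.doc_id}: no sentence usable for MDD")
    return float(np.mean(sent_mdds))


def extract_features(
    doc: ParsedDocument,
    stopwords: set[str] = frozenset(),
    noun_tags: frozenset[str] = frozenset({"NOUN"}),
) -> NLPFeatureVector:
    """All nine features for one document (NaN where undefined)."""
    dvrst, BI, HS = lexical_features(doc)
    wrd_sent, nonstop = structure_features(doc, set(stopwords))
    NnVrb, Nn, Prn = word_class_features(doc, noun_tags)
    mdd = compute_mdd(doc)
    return NLPFeatureVector(
        dvrst=dvrst, BI=BI, HS=HS, wrd_sent=wrd_sent, nonstop=nonstop,
        NnVrb=NnVrb, Nn=Nn, Prn=Prn, MDD=mdd,
    )


def aggregate_user_features(vectors: list[NLPFeatureVector]) -> NLPFeatureVector:
    """Field-wise mean over a user's texts, masking NaN components.

    A field undefined in every text stays NaN in the aggregate.
    """
    if not vectors:
        raise ValueError("cannot aggregate an empty list of feature vectors")
    arr = np.stack([v.as_array() for v in vectors])
    with np.errstate(invalid="ignore"):
        means = np.where(
            np.all(np.isnan(arr), axis=0), np.nan, np.nanmean(arr, axis=0)
        )
    return NLPFeatureVector(**dict(zip(FEATURE_NAMES, means.tolist())))
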