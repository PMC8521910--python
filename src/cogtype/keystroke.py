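"""Keystroke dynamics: hold-time / flight-time extraction from typing sessions.

A *typing session* is the sequence of key press/release timestamps recorded
between a virtual keyboard appearing and disappearing.  Two timing variables
are derived per session:

* hold time  ``HT_n = t_n^r - t_n^p``  (press-to-release of key *n*),
* flight time ``FT_n = t_{n+1}^p - t_n^r``  (release of key *n* to press of
  key *n+1*; negative under rollover typing, where the next key is pressed
  before the previous one is released).

Sessions are quality-controlled on key count, the derived series are filtered
against upper bounds that remove long pauses, and zero-padded to a fixed
length so they can feed a fixed-input-size neural network.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace

import numpy as np

logger = logging.getLogger(__name__)

#: Hold times at or above this bound (seconds) are treated as pauses/noise.
DEFAULT_HT_MAX = 0.700
#: Flight times at or above this bound (seconds) are treated as pauses.
DEFAULT_FT_MAX = 3.0
#: Target fixed dimensionality of the padded HT/FT vectors.
PAD_LENGTH = 100
#: Sessions need strictly more than this many key presses to be usable.
MIN_PRESSES = 40


@dataclass(frozen=True)
class TypingSession:
    """Raw press/release timestamp sequences for one keyboard session.

    Timestamps are integer milliseconds since epoch; ``press_times`` and
    ``release_times`` are paired index-wise (event *i* is one key tap).
    """

    session_id: str
    subject_id: str
    press_times: np.ndarray
    release_times: np.ndarray

    def __post_init__(self) -> None:
        press = np.asarray(self.press_times, dtype=np.int64)
        release = np.asarray(self.release_times, dtype=np.int64)
        object.__setattr__(self, "press_times", press)
        object.__setattr__(self, "release_times", release)
        if press.ndim != 1 or release.ndim != 1:
            raise ValueError("timestamp sequences must be one-dimensional")
        if len(press) != len(release):
            raise ValueError(
                f"session {self.session_id}: {len(press)} presses vs "
                f"{len(release)} releases"
            )
        if len(press) < 1:
            raise ValueError(f"session {self.session_id}: no key events")
        if np.any(np.diff(press) < 0):
            raise ValueError(f"session {self.session_id}: press times not sorted")
        if np.any(release < press):
            raise ValueError(
                f"session {self.session_id}: release before press"
            )

    @property
    def n_keys(self) -> int:
        return len(self.press_times)


@dataclass(frozen=True)
class DynamicsSeries:
    """Derived hold-time/flight-time sequences for one session (seconds).

    ``padded_ht``/``padded_ft`` are ``None`` until :func:`pad_series` runs;
    ``unusable`` is set when filtering empties the series.
    """

    session_id: str
    subject_id: str
    ht: np.ndarray
    ft: np.ndarray
    n_raw: int
    filtered: bool = False
    unusable: bool = False
    n_removed_ht: int = 0
    n_removed_ft: int = 0
    padded_ht: np.ndarray | None = field(default=None)
    padded_ft: np.ndarray | None = field(default=None)


def read_sessions(path) -> list[TypingSession]:
    """Read typing sessions from a JSON Lines file.

    Each line is one object ``{"session_id", "subject_id", "press", "release"}``
    with timestamps in integer milliseconds.  Malformed records (bad JSON,
    missing keys, mismatched press/release lengths, unsorted or inverted
    timestamps) are skipped with a logged warning; an unreadable file is fatal.
    """
    sessions: list[TypingSession] = []
    n_rejected = 0
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                rec = json.loads(line)
                sessions.append(
                    TypingSession(
                        session_id=str(rec["session_id"]),
                        subject_id=str(rec["subject_id"]),
                        press_times=rec["press"],
                        release_times=rec["release"],
                    )
                )
            except (json.JSONDecodeError, KeyError, TypeError, ValueError) as exc:
                n_rejected += 1
                logger.warning("%s line %d: rejected record (%s)", path, lineno, exc)
    if n_rejected:
        logger.warning("%s: %d record(s) rejected", path, n_rejected)
    read_sessions.last_rejected = n_rejected  # type: ignore[attr-defined]
    return sessions


def qc_sessions(
    sessions: list[TypingSession], min_presses: int = MIN_PRESSES
) -> list[TypingSession]:
    """Keep sessions with strictly more than ``min_presses`` key presses."""
    return [s for s in sessions if s.n_keys > min_presses]


def compute_dynamics(session: TypingSession) -> DynamicsSeries:
    """Derive hold and flight times (seconds) from one session.

    For ``N`` key events the hold-time series has length ``N`` and the
    flight-time series length ``N - 1``.  Negative flight times (rollover)
    are retained.
    """
    press = session.press_times.astype(np.float64)
    release = session.release_times.astype(np.float64)
    ht = (release - press) / 1000.0
    ft = (press[1:] - release[:-1]) / 1000.0
    return DynamicsSeries(
        session_id=session.session_id,
        subject_id=session.subject_id,
        ht=ht,
        ft=ft,
        n_raw=session.n_keys,
    )


def filter_dynamics(
    series: DynamicsSeries,
    ht_max: float = DEFAULT_HT_MAX,
    ft_max: float = DEFAULT_FT_MAX,
) -> DynamicsSeries:
    """Drop hold times >= ``ht_max`` and flight times >= ``ft_max``.

    Both bounds are strict upper bounds ("smaller than"); only an upper bound
    is applied, so rollover (negative) flight times pass.  Order is preserved.
    A series left empty in both components is flagged unusable.
    """
    keep_ht = series.ht < ht_max
    keep_ft = series.ft < ft_max
    ht = series.ht[keep_ht]
    ft = series.ft[keep_ft]
    return replace(
        series,
        ht=ht,
        ft=ft,
        filtered=True,
        unusable=(len(ht) == 0 and len(ft) == 0),
        n_removed_ht=series.n_removed_ht + int((~keep_ht).sum()),
        n_removed_ft=series.n_removed_ft + int((~keep_ft).sum()),
    )


def pad_series(series: DynamicsSeries, length: int = PAD_LENGTH) -> DynamicsSeries:
    """Zero-pad (or truncate) HT/FT to a common fixed dimensionality.

    Shorter sequences get trailing zeros; longer ones keep their first
    ``length`` values (the earliest, least-fatigued typing).
    """
    if length <= 0:
        raise ValueError(f"pad length must be positive, got {length}")

    def _fit(x: np.ndarray) -> np.ndarray:
        out = np.zeros(length, dtype=np.float64)
        n = min(len(x), length)
        out[:n] = x[:n]
        return out

    return replace(series, padded_ht=_fit(series.ht), padded_ft=_fit(series.ft))


def dynamics_pipeline(
    sessions: list[TypingSession],
    min_presses: int = MIN_PRESSES,
    ht_max: float = DEFAULT_HT_MAX,
    ft_max: float = DEFAULT_FT_MAX,
    length: int = PAD_LENGTH,
) -> list[DynamicsSeries]:
    """QC -> compute -> filter -> pad; unusable series are dropped."""
    out = []
    for s in qc_sessions(sessions, min_presses):
        d = filter_dynamics(compute_dynamics(s), ht_max, ft_max)
        if d.unusable:
            logger.warning("session %s unusable after filtering", s.session_id)
            continue
        out.append(pad_series(d, length))
    return out


def stack_padded(series: list[DynamicsSeries]) -> np.ndarray:
    """Stack padded series to an (n_sessions, 2, length) array (HT, FT)."""
    if not series:
        raise ValueError("no series to stack")
    if any(s.padded_ht is None for s in series):
        raise ValueError("series must be padded first")
    return np.stack([np.stack([s.padded_ht, s.padded_ft]) for s in series])
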