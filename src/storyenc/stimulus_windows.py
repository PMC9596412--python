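"""Timed transcripts and sliding context windows.

A transcript is an onset-ordered sequence of tokens with durations, word
flags, and lexical frequencies.  For every target token and window size
W (15–90 s in 15 s steps), the context is the set of earlier tokens whose
onset falls in the half-open interval [target_onset - W, target_onset).
Early targets whose window extends before the narrative start keep
whatever context is available and are flagged ``is_full = False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from storyenc.errors import StoryEncError
from storyenc.lm_adapter import Vocab

__all__ = [
    "DEFAULT_WINDOWS",
    "TimedToken",
    "Transcript",
    "ContextWindow",
    "read_transcript",
    "write_transcript",
    "build_window",
    "window_stats",
]

DEFAULT_WINDOWS: tuple[int, ...] = (15, 30, 45, 60, 75, 90)

_COLUMNS = ["token", "onset_s", "duration_s", "is_word", "lex_freq"]


@dataclass(frozen=True)
class TimedToken:
    """One transcript unit (word or sub-word) with its timing.

    ``lex_freq`` is lexical frequency in occurrences per million (word
    tokens only; NaN for non-words).
    """

    text: str
    token_id: int
    onset: float
    duration: float
    is_word: bool
    lex_freq: float = float("nan")


@dataclass(frozen=True)
class Transcript:
    tokens: tuple[TimedToken, ...]
    total_duration: float
    condition_tag: str = "FW"

    def __post_init__(self):
        if len(self.tokens) < 1:
            raise StoryEncError("empty-transcript", "transcript needs >= 1 token")
        onsets = [t.onset for t in self.tokens]
        if any(b < a for a, b in zip(onsets, onsets[1:])):
            raise StoryEncError("unsorted-transcript", "token onsets must be non-decreasing")
        last = self.tokens[-1]
        if self.total_duration < last.onset + last.duration:
            raise StoryEncError(
                "bad-duration", "total_duration must cover the last token"
            )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def onsets(self) -> np.ndarray:
        return np.array([t.onset for t in self.tokens])

    @property
    def token_ids(self) -> np.ndarray:
        return np.array([t.token_id for t in self.tokens], dtype=np.int64)


@dataclass(frozen=True)
class ContextWindow:
    """The target token plus its time-bounded left context.

    ``is_full`` is True when the window lies entirely inside the
    narrative, i.e. the target's onset is at least W seconds in.
    """

    target_index: int
    context_indices: tuple[int, ...]
    window_seconds: float
    is_full: bool


def read_transcript(
    path: str | Path,
    vocab: Vocab,
    *,
    condition_tag: str = "FW",
    unknown_policy: str = "error",
) -> Transcript:
    """Read a transcript TSV (columns token, onset_s, duration_s, is_word, lex_freq).

    ``unknown_policy``: "error" rejects out-of-vocabulary tokens;
    "reserve" maps them all to the last vocabulary id.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise StoryEncError("bad-schema", f"transcript TSV missing columns: {missing}")
    if (df["onset_s"].diff().dropna() < 0).any():
        raise StoryEncError("unsorted-transcript", "onset_s must be non-decreasing")
    lookup = {t: i for i, t in enumerate(vocab.tokens)}
    tokens = []
    for row in df.itertuples(index=False):
        tid = lookup.get(row.token)
        if tid is None:
            if unknown_policy == "reserve":
                tid = vocab.size - 1
            else:
                raise StoryEncError("oov-token", f"unknown token {row.token!r}")
        tokens.append(
            TimedToken(
                text=str(row.token),
                token_id=tid,
                onset=float(row.onset_s),
                duration=float(row.duration_s),
                is_word=bool(row.is_word),
                lex_freq=float(row.lex_freq),
            )
        )
    last = tokens[-1]
    return Transcript(
        tokens=tuple(tokens),
        total_duration=last.onset + last.duration,
        condition_tag=condition_tag,
    )


def write_transcript(transcript: Transcript, path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "token": [t.text for t in transcript.tokens],
            "onset_s": [t.onset for t in transcript.tokens],
            "duration_s": [t.duration for t in transcript.tokens],
            "is_word": [int(t.is_word) for t in transcript.tokens],
            "lex_freq": [t.lex_freq for t in transcript.tokens],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def build_window(
    transcript: Transcript,
    target_index: int,
    window_seconds: float,
    *,
    empty_context_policy: str = "truncate",
) -> ContextWindow:
    """Assemble the left context of a target token for one window size.

    Membership uses token onsets and the half-open interval
    [target_onset - W, target_onset); the target itself is excluded.
    """
    n = len(transcript)
    if not 0 <= target_index < n:
        raise StoryEncError("bad-index", f"target index {target_index} outside transcript")
    onsets = transcript.onsets
    t0 = onsets[target_index]
    lo = t0 - window_seconds
    idx = np.nonzero((onsets >= lo) & (onsets < t0))[0]
    idx = idx[idx < target_index]
    if idx.size == 0 and empty_context_policy == "error":
        raise StoryEncError("no-context", f"target {target_index} has empty context")
    return ContextWindow(
        target_index=target_index,
        context_indices=tuple(int(i) for i in idx),
        window_seconds=float(window_seconds),
        is_full=bool(t0 >= window_seconds),
    )


def window_stats(transcript: Transcript, window_seconds: float) -> dict:
    """Mean +/- sd of context length, in tokens and in words, over all targets."""
    n_tokens, n_words = [], []
    is_word = np.array([t.is_word for t in transcript.tokens])
    for i in range(len(transcript)):
        win = build_window(transcript, i, window_seconds)
        ctx = np.array(win.context_indices, dtype=np.int64)
        n_tokens.append(ctx.size)
        n_words.append(int(is_word[ctx].sum()) if ctx.size else 0)
    return {
        "window_seconds": float(window_seconds),
        "mean_tokens": float(np.mean(n_tokens)),
        "sd_tokens": float(np.std(n_tokens, ddof=1)) if len(n_tokens) > 1 else 0.0,
        "mean_words": float(np.mean(n_words)),
        "sd_words": float(np.std(n_words, ddof=1)) if len(n_words) > 1 else 0.0,
    }
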