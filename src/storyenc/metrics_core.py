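"""Per-token surprisal and GradientXInput saliency.

Surprisal of a token is the negative base-10 log of its conditional
probability given its left context,

    surprisal(token) = -log10 P(token | context tokens),

so a perfectly predicted token has surprisal 0 and a uniform guess over
V alternatives has surprisal log10(V).

Saliency assigns each context token a nonnegative importance weight for
the prediction of the target: the L2 norm of the elementwise product of
the context token's embedding with the gradient of the target's score
with respect to that embedding (GradientXInput), then normalized to sum
to one.  A per-token "received saliency" series aggregates these
per-prediction vectors into a single predictor value per token.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from storyenc.errors import StoryEncError
from storyenc.lm_adapter import LanguageModelAdapter
from storyenc.stimulus_windows import ContextWindow, Transcript, build_window

__all__ = [
    "SaliencyVector",
    "surprisal",
    "saliency_vector",
    "compute_all_metrics",
    "aggregate_received_saliency",
    "tokens_vs_surprisal_correlation",
]

PROB_FLOOR = 1e-12  # clamp before log; softmax outputs are strictly positive anyway

AGGREGATION_MODES = ("mean_received", "last_prediction", "sum_received")


@dataclass(frozen=True)
class SaliencyVector:
    """Normalized per-context-token weights for one prediction event."""

    weights: np.ndarray
    target_index: int
    context_indices: tuple[int, ...]
    window_seconds: float
    is_full: bool


def surprisal(probs: np.ndarray, target_id: int, *, floor: float = PROB_FLOOR) -> float:
    """-log10 of the target token's probability; p=1 gives 0."""
    probs = np.asarray(probs, dtype=float)
    if not 0 <= target_id < probs.size:
        raise StoryEncError("oov-token", f"target id {target_id} outside distribution")
    return float(-np.log10(max(float(probs[target_id]), floor)))


def saliency_vector(
    grads: np.ndarray,
    embeds: np.ndarray,
    *,
    degenerate_policy: str = "uniform",
) -> np.ndarray:
    """Per-context-token GradientXInput weights, sum-normalized.

    Weight of context token j is ||grad_row_j * embed_row_j||_2.  An
    all-zero raw vector signals a degenerate gradient; policy "uniform"
    (default) returns equal weights, "error" raises.
    """
    grads = np.asarray(grads, dtype=float)
    embeds = np.asarray(embeds, dtype=float)
    if grads.shape != embeds.shape:
        raise StoryEncError("shape-mismatch", "gradient and embedding shapes differ")
    if grads.shape[0] < 1:
        raise StoryEncError("empty-context", "need at least one context token")
    raw = np.linalg.norm(grads * embeds, axis=1)
    total = raw.sum()
    if total <= 0.0:
        if degenerate_policy == "error":
            raise StoryEncError("degenerate-gradient", "all-zero saliency vector")
        return np.full(raw.size, 1.0 / raw.size)
    return raw / total


def compute_all_metrics(
    transcript: Transcript,
    lm: LanguageModelAdapter,
    window_seconds: float,
    *,
    words_only_saliency: bool = False,
) -> tuple[np.ndarray, list[SaliencyVector]]:
    """Surprisal for every token and a saliency vector for every prediction.

    Returns a per-token surprisal array (NaN for the first token, which
    has no context) and one :class:`SaliencyVector` per target with a
    non-empty context.  Early targets use their truncated context.
    """
    ids = transcript.token_ids
    n = len(transcript)
    surp = np.full(n, np.nan)
    vectors: list[SaliencyVector] = []
    for i in range(n):
        win = build_window(transcript, i, window_seconds)
        ctx = np.array(win.context_indices, dtype=np.int64)
        if words_only_saliency and not transcript.tokens[i].is_word:
            ctx_for_sal = None
        else:
            ctx_for_sal = ctx
        if ctx.size == 0:
            continue
        context_ids = ids[ctx]
        probs = lm.next_token_distribution(context_ids)
        surp[i] = surprisal(probs, int(ids[i]))
        if ctx_for_sal is not None:
            grads = lm.class_score_gradient(context_ids, int(ids[i]))
            embeds = lm.context_embeddings(context_ids)
            vectors.append(
                SaliencyVector(
                    weights=saliency_vector(grads, embeds),
                    target_index=i,
                    context_indices=win.context_indices,
                    window_seconds=window_seconds,
                    is_full=win.is_full,
                )
            )
    return surp, vectors


def aggregate_received_saliency(
    vectors: list[SaliencyVector],
    transcript: Transcript,
    window_seconds: float,
    mode: str = "mean_received",
) -> np.ndarray:
    """Collapse per-prediction saliency vectors into one value per token.

    Only predictions with a full window contribute (early truncated
    contexts are dropped).  Modes:

    - ``mean_received``: a token's value is the mean, over the
      full-window predictions whose context contains it, of the weight
      it received.
    - ``sum_received``: the sum of received weights (mass-conserving:
      the series total equals the number of full-window predictions).
    - ``last_prediction``: the single most recent full-window vector
      mapped onto its context positions.

    Tokens appearing in no contributing context are NaN.
    """
    if mode not in AGGREGATION_MODES:
        raise StoryEncError("bad-mode", f"unknown aggregation mode {mode!r}")
    n = len(transcript)
    full = [v for v in vectors if v.is_full and v.window_seconds == window_seconds]
    totals = np.zeros(n)
    counts = np.zeros(n)
    if mode == "last_prediction":
        if full:
            v = full[-1]
            for pos, w in zip(v.context_indices, v.weights):
                totals[pos] += w
                counts[pos] += 1
    else:
        for v in full:
            for pos, w in zip(v.context_indices, v.weights):
                totals[pos] += w
                counts[pos] += 1
    out = np.full(n, np.nan)
    seen = counts > 0
    if mode == "mean_received":
        out[seen] = totals[seen] / counts[seen]
    else:
        out[seen] = totals[seen]
    return out


def tokens_vs_surprisal_correlation(
    mean_context_tokens: np.ndarray, mean_surprisals: np.ndarray
) -> float:
    """Pearson r between per-window mean context length and mean surprisal."""
    x = np.asarray(mean_context_tokens, dtype=float)
    y = np.asarray(mean_surprisals, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StoryEncError("bad-input", "need >= 3 paired values")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise StoryEncError("degenerate-correlation", "zero variance input")
    return float(stats.pearsonr(x, y).statistic)
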