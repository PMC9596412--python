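"""Language-model adapter contract and a built-in analytic toy model.

Any autoregressive LM can drive the pipeline if it exposes three entry
points: a next-token probability distribution given a context, the input
embeddings of the context, and the gradient of a target token's score
with respect to those embeddings.  The :class:`ToyDecayLM` implements the
contract in closed form so that every downstream stage is testable with
no pretrained weights: it pools context embeddings with an exponential
recency decay (a stand-in for attention) and scores tokens linearly,

    g = sum_j  gamma^(n-j) * X_j,        logits = U @ g,

which makes the score gradient with respect to context row ``j`` exactly
``gamma^(n-j) * U[c]``.  A central finite-difference gradient is provided
as an independent numerical oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, Sequence, runtime_checkable

import numpy as np
from scipy.special import log_softmax, softmax

from storyenc.errors import StoryEncError

__all__ = [
    "Vocab",
    "LanguageModelAdapter",
    "ToyDecayLM",
    "finite_difference_gradient",
]


@dataclass(frozen=True)
class Vocab:
    """Ordered token inventory; token ids index into it."""

    tokens: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.tokens)) != len(self.tokens):
            raise StoryEncError("duplicate-token", "vocabulary tokens must be unique")

    @property
    def size(self) -> int:
        return len(self.tokens)

    def id_of(self, token: str) -> int:
        try:
            return self.tokens.index(token)
        except ValueError:
            raise StoryEncError("oov-token", f"token {token!r} not in vocabulary") from None


@runtime_checkable
class LanguageModelAdapter(Protocol):
    """Contract an autoregressive LM must satisfy for this pipeline."""

    vocab: Vocab

    def next_token_distribution(self, context_ids: Sequence[int]) -> np.ndarray: ...

    def context_embeddings(self, context_ids: Sequence[int]) -> np.ndarray: ...

    def class_score_gradient(self, context_ids: Sequence[int], target_id: int) -> np.ndarray: ...


def _check_context(context_ids: Sequence[int], V: int) -> np.ndarray:
    ids = np.asarray(context_ids, dtype=np.int64)
    if ids.size == 0:
        raise StoryEncError("empty-context", "context must contain at least one token")
    if ids.min() < 0 or ids.max() >= V:
        raise StoryEncError("oov-token", f"token id outside vocabulary of size {V}")
    return ids


@dataclass
class ToyDecayLM:
    """Deterministic, fully differentiable toy autoregressive LM.

    Parameters
    ----------
    E
        Embedding table, shape (V, d).
    U
        Output (unembedding) matrix, shape (V, d); row ``c`` scores class c.
    gamma
        Recency decay in [0, 1]: context token at distance k from the last
        token is weighted ``gamma**k`` in the pooled representation.
    score
        Which scalar the saliency gradient targets: ``"logit"`` (default,
        the pre-softmax score, the common GradientXInput convention) or
        ``"log_prob"`` (the log-softmax score).
    """

    E: np.ndarray
    U: np.ndarray
    gamma: float
    score: str = "logit"
    vocab: Vocab = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.E = np.asarray(self.E, dtype=float)
        self.U = np.asarray(self.U, dtype=float)
        if self.E.shape != self.U.shape:
            raise StoryEncError("shape-mismatch", "E and U must share shape (V, d)")
        if not 0.0 <= self.gamma <= 1.0:
            raise StoryEncError("bad-gamma", "gamma must lie in [0, 1]")
        if self.score not in ("logit", "log_prob"):
            raise StoryEncError("bad-score", f"unknown score {self.score!r}")
        if self.vocab is None:
            self.vocab = Vocab(tuple(f"tok{i}" for i in range(self.E.shape[0])))
        if self.vocab.size != self.E.shape[0]:
            raise StoryEncError("shape-mismatch", "vocab size must match embedding rows")

    # -- sizes -------------------------------------------------------------
    @property
    def V(self) -> int:
        return self.E.shape[0]

    @property
    def d(self) -> int:
        return self.E.shape[1]

    def _decay_weights(self, n: int) -> np.ndarray:
        # weight gamma^(n-1-j) for 0-indexed position j; last token weight 1
        return self.gamma ** np.arange(n - 1, -1, -1, dtype=float)

    # -- adapter contract --------------------------------------------------
    def context_embeddings(self, context_ids: Sequence[int]) -> np.ndarray:
        ids = _check_context(context_ids, self.V)
        return self.E[ids]

    def logits_from_embeddings(self, X: np.ndarray) -> np.ndarray:
        """Pre-softmax scores over the vocabulary for a context matrix X (n, d)."""
        w = self._decay_weights(X.shape[0])
        g = w @ X
        return self.U @ g

    def score_from_embeddings(self, X: np.ndarray, target_id: int) -> float:
        """Scalar score of ``target_id`` as a function of the embeddings.

        This is the function whose gradient GradientXInput needs; it is
        exposed so a finite-difference oracle can perturb X directly.
        """
        z = self.logits_from_embeddings(X)
        if self.score == "logit":
            return float(z[target_id])
        return float(log_softmax(z)[target_id])

    def next_token_distribution(self, context_ids: Sequence[int]) -> np.ndarray:
        ids = _check_context(context_ids, self.V)
        return softmax(self.logits_from_embeddings(self.E[ids]))

    def class_score_gradient(self, context_ids: Sequence[int], target_id: int) -> np.ndarray:
        """Gradient of the target token's score w.r.t. each context embedding row.

        Closed form for the logit score: row j is ``gamma^(n-1-j) * U[c]``.
        For the log-probability score the softmax Jacobian enters:
        row j is ``gamma^(n-1-j) * (U[c] - p @ U)``.
        """
        ids = _check_context(context_ids, self.V)
        if not 0 <= target_id < self.V:
            raise StoryEncError("oov-token", f"target id {target_id} outside vocabulary")
        w = self._decay_weights(ids.size)
        if self.score == "logit":
            direction = self.U[target_id]
        else:
            p = softmax(self.logits_from_embeddings(self.E[ids]))
            direction = self.U[target_id] - p @ self.U
        return np.outer(w, direction)

    # -- (de)serialization -------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        payload = {
            "E": self.E.tolist(),
            "U": self.U.tolist(),
            "gamma": self.gamma,
            "score": self.score,
            "vocab": list(self.vocab.tokens),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "ToyDecayLM":
        payload = json.loads(Path(path).read_text())
        return cls(
            E=np.asarray(payload["E"], dtype=float),
            U=np.asarray(payload["U"], dtype=float),
            gamma=float(payload["gamma"]),
            score=payload.get("score", "logit"),
            vocab=Vocab(tuple(payload["vocab"])),
        )

    @classmethod
    def random(cls, V: int, d: int, gamma: float, seed: int, scale: float = 1.0,
               score: str = "logit") -> "ToyDecayLM":
        rng = np.random.default_rng(seed)
        return cls(
            E=rng.normal(scale=scale, size=(V, d)),
            U=rng.normal(scale=scale, size=(V, d)),
            gamma=gamma,
            score=score,
        )


def finite_difference_gradient(
    lm: ToyDecayLM,
    context_ids: Sequence[int],
    target_id: int,
    step: float = 1e-5,
) -> np.ndarray:
    """Central-difference estimate of :meth:`ToyDecayLM.class_score_gradient`.

    Perturbs one embedding coordinate at a time; O(n*d) score evaluations.
    Serves as the independent numerical oracle for the analytic gradient.
    """
    if step <= 0:
        raise StoryEncError("bad-step", "finite-difference step must be positive")
    ids = _check_context(context_ids, lm.V)
    X0 = lm.E[ids].copy()
    grad = np.empty_like(X0)
    for j in range(X0.shape[0]):
        for k in range(X0.shape[1]):
            Xp = X0.copy()
            Xp[j, k] += step
            Xm = X0.copy()
            Xm[j, k] -= step
            grad[j, k] = (
                lm.score_from_embeddings(Xp, target_id)
                - lm.score_from_embeddings(Xm, target_id)
            ) / (2.0 * step)
    return grad
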