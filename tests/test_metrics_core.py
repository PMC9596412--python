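"""Surprisal, GradientXInput saliency, and predictor aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from storyenc import metrics_core
from storyenc.errors import StoryEncError
from storyenc.lm_adapter import ToyDecayLM
from storyenc.metrics_core import (
    aggregate_received_saliency,
    compute_all_metrics,
    saliency_vector,
    surprisal,
    tokens_vs_surprisal_correlation,
)
from storyenc.stimulus_windows import TimedToken, Transcript
from storyenc.tables import STUDY_WINDOW_SUMMARY


@pytest.mark.parametrize(
    "probs,target,expected",
    [
        (np.array([1.0, 0.0]), 0, 0.0),                  # certainty -> no surprise
        (np.array([0.1, 0.9]), 0, 1.0),                  # -log10(0.1)
        (np.full(1000, 1e-3), 5, 3.0),                   # uniform over 1000
    ],
)
def test_surprisal_unit_cases(probs, target, expected):
    assert surprisal(probs, target) == pytest.approx(expected, abs=1e-12)


def test_surprisal_zero_probability_clamped():
    val = surprisal(np.array([0.0, 1.0]), 0)
    assert val == pytest.approx(12.0)  # -log10(1e-12)


def test_saliency_gamma_zero_concentrates_on_last_token():
    lm = ToyDecayLM.random(10, 4, gamma=0.0, seed=2)
    ctx = [1, 2, 3]
    s = saliency_vector(lm.class_score_gradient(ctx, 5), lm.context_embeddings(ctx))
    np.testing.assert_allclose(s, [0.0, 0.0, 1.0], atol=1e-12)


def test_saliency_closed_form_identical_embeddings():
    # gamma=0.5, n=2, identical embeddings -> weights proportional to (0.5, 1)
    d = 3
    E = np.tile(np.array([1.0, -2.0, 0.5]), (4, 1))
    U = np.random.default_rng(0).normal(size=(4, d))
    lm = ToyDecayLM(E=E, U=U, gamma=0.5)
    ctx = [0, 1]
    s = saliency_vector(lm.class_score_gradient(ctx, 2), lm.context_embeddings(ctx))
    np.testing.assert_allclose(s, [1 / 3, 2 / 3], atol=1e-12)


def test_saliency_matches_analytic_decay_form():
    rng = np.random.default_rng(7)
    lm = ToyDecayLM.random(12, 5, gamma=0.6, seed=7)
    ctx = rng.integers(0, 12, size=6).tolist()
    tgt = 3
    s = saliency_vector(lm.class_score_gradient(ctx, tgt), lm.context_embeddings(ctx))
    n = len(ctx)
    raw = np.array([
        lm.gamma ** (n - 1 - j) * np.linalg.norm(lm.U[tgt] * lm.E[ctx[j]])
        for j in range(n)
    ])
    np.testing.assert_allclose(s, raw / raw.sum(), atol=1e-10)


def test_degenerate_saliency_policies():
    grads = np.zeros((3, 2))
    embeds = np.ones((3, 2))
    np.testing.assert_allclose(saliency_vector(grads, embeds), np.full(3, 1 / 3))
    with pytest.raises(StoryEncError) as e:
        saliency_vector(grads, embeds, degenerate_policy="error")
    assert e.value.code == "degenerate-gradient"


@settings(deadline=None, max_examples=60)
@given(st.integers(0, 2**31 - 1), st.integers(1, 15), st.floats(0.05, 1.0))
def test_saliency_is_probability_vector(seed, n, gamma):
    rng = np.random.default_rng(seed)
    lm = ToyDecayLM.random(10, 4, gamma=gamma, seed=seed)
    ctx = rng.integers(0, 10, size=n).tolist()
    s = saliency_vector(lm.class_score_gradient(ctx, int(rng.integers(0, 10))),
                        lm.context_embeddings(ctx))
    assert (s >= 0).all()
    assert abs(s.sum() - 1.0) < 1e-9


def test_compute_all_metrics_matches_scalar_recomputation(small_transcript, toy_lm):
    """Independent step-by-step oracle: per-target window, softmax, log10."""
    surp, vectors = compute_all_metrics(small_transcript, toy_lm, 15.0)
    assert np.isnan(surp[0])  # no context for the first token
    ids = small_transcript.token_ids
    onsets = small_transcript.onsets
    for i in range(1, len(small_transcript)):
        ctx = [j for j in range(i) if onsets[i] - 15.0 <= onsets[j] < onsets[i]]
        w = toy_lm.gamma ** np.arange(len(ctx) - 1, -1, -1)
        g = w @ toy_lm.E[ids[ctx]]
        z = toy_lm.U @ g
        p = np.exp(z - z.max())
        p /= p.sum()
        assert surp[i] == pytest.approx(-np.log10(p[ids[i]]), abs=1e-10)
    # one saliency vector per target with non-empty context
    assert [v.target_index for v in vectors] == list(range(1, len(small_transcript)))


def test_deterministic_transitions_give_zero_surprisal(small_transcript):
    # huge logit mass on the actual next token makes every prediction certain
    V, d = 10, 10
    E = np.eye(V, d)
    U = np.zeros((V, d))
    ids = small_transcript.token_ids
    # with gamma=0 the pooled vector is the last context embedding
    for prev, nxt in zip(ids[:-1], ids[1:]):
        U[nxt, prev] = 50.0
    lm = ToyDecayLM(E=E, U=U, gamma=0.0)
    surp, _ = compute_all_metrics(small_transcript, lm, 90.0)
    np.testing.assert_allclose(surp[1:], 0.0, atol=1e-6)


def test_received_saliency_mean_mode_brute_force(small_transcript, toy_lm):
    _, vectors = compute_all_metrics(small_transcript, toy_lm, 15.0)
    got = aggregate_received_saliency(vectors, small_transcript, 15.0, "mean_received")
    # brute-force accumulation over full-window predictions only
    acc = {i: [] for i in range(len(small_transcript))}
    for v in vectors:
        if v.is_full:
            for pos, w in zip(v.context_indices, v.weights):
                acc[pos].append(w)
    for i in range(len(small_transcript)):
        if acc[i]:
            assert got[i] == pytest.approx(np.mean(acc[i]), abs=1e-12)
        else:
            assert np.isnan(got[i])


def test_received_saliency_sum_mode_conserves_mass(tiny_config):
    from storyenc import synthetic_data
    transcript = synthetic_data.simulate_transcript(tiny_config)
    lm = synthetic_data.make_toy_lm(tiny_config)
    _, vectors = compute_all_metrics(transcript, lm, 30.0)
    total = np.nansum(
        aggregate_received_saliency(vectors, transcript, 30.0, "sum_received"))
    n_full = sum(1 for v in vectors if v.is_full)
    assert total == pytest.approx(n_full, rel=1e-9)


def test_last_prediction_mode_maps_single_vector(small_transcript, toy_lm):
    _, vectors = compute_all_metrics(small_transcript, toy_lm, 15.0)
    got = aggregate_received_saliency(vectors, small_transcript, 15.0,
                                      "last_prediction")
    last = [v for v in vectors if v.is_full][-1]
    for pos, w in zip(last.context_indices, last.weights):
        assert got[pos] == pytest.approx(w)
    with pytest.raises(StoryEncError) as e:
        aggregate_received_saliency(vectors, small_transcript, 15.0, "median")
    assert e.value.code == "bad-mode"


def test_study_table_correlation_reproduced():
    r = tokens_vs_surprisal_correlation(
        STUDY_WINDOW_SUMMARY["mean_tokens"].to_numpy(),
        STUDY_WINDOW_SUMMARY["mean_surprisal"].to_numpy(),
    )
    assert round(r, 2) == 0.93


@pytest.mark.parametrize("slope,expected", [(2.0, 1.0), (-0.5, -1.0)])
def test_correlation_linear_cases(slope, expected):
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert tokens_vs_surprisal_correlation(x, slope * x + 1) == pytest.approx(expected)


def test_correlation_degenerate_input():
    with pytest.raises(StoryEncError) as e:
        tokens_vs_surprisal_correlation(np.ones(4), np.arange(4.0))
    assert e.value.code == "degenerate-correlation"
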