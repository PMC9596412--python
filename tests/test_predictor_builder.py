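"""HRF kernel, event series, convolution/resampling, masks, designs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from storyenc.errors import StoryEncError
from storyenc.predictor_builder import (
    HrfSpec,
    PredictorSeries,
    build_design,
    convolve_resample,
    event_series,
    hrf_kernel,
    metric_to_predictor,
    read_predictor,
    valid_timepoint_mask,
    write_predictor,
)
from storyenc.stimulus_windows import TimedToken, Transcript


def test_hrf_peaks_at_peak_delay():
    dt = 0.1
    k = hrf_kernel(HrfSpec(), dt)
    assert np.argmax(k) * dt == pytest.approx(6.0, abs=0.1)
    assert k.max() == pytest.approx(1.0)
    assert k.sum() * dt > 0  # net positive response


def test_hrf_bad_dt():
    with pytest.raises(StoryEncError) as e:
        hrf_kernel(HrfSpec(), dt=0.0)
    assert e.value.code == "bad-dt"


def _one_token_transcript(onset, duration=0.3, total=60.0):
    return Transcript(
        tokens=(TimedToken("a", 0, onset, duration, True, 10.0),),
        total_duration=total,
    )


def test_event_series_single_impulse():
    tr = _one_token_transcript(10.0)
    s = event_series(tr, np.array([2.5]), dt=0.1)
    assert s[100] == 2.5
    assert np.count_nonzero(s) == 1


def test_event_series_nan_contributes_zero():
    tr = _one_token_transcript(10.0)
    s = event_series(tr, np.array([np.nan]), dt=0.1)
    assert not s.any()


def test_event_series_same_bin_amplitudes_sum():
    tokens = (
        TimedToken("a", 0, 5.01, 0.1, True, 1.0),
        TimedToken("b", 1, 5.04, 0.1, True, 1.0),
    )
    tr = Transcript(tokens=tokens, total_duration=30.0)
    s = event_series(tr, np.array([1.0, 2.0]), dt=0.1)
    assert s[50] == 3.0


def test_event_out_of_range():
    tr = _one_token_transcript(10.0, total=60.0)
    with pytest.raises(StoryEncError) as e:
        event_series(tr, np.array([1.0]), dt=0.1, duration_s=5.0)
    assert e.value.code == "event-out-of-range"


def test_convolution_of_impulse_returns_scaled_kernel():
    dt = 0.1
    kernel = hrf_kernel(HrfSpec(), dt)
    series = np.zeros(1000)
    series[0] = 2.0
    out = convolve_resample(series, kernel, tr=1.0, T=30, dt=dt)
    expect = 2.0 * kernel[np.arange(30) * 10]
    np.testing.assert_allclose(out, expect, atol=1e-12)


def test_convolution_linearity_and_length(rng):
    dt = 0.1
    kernel = hrf_kernel(HrfSpec(), dt)
    a = rng.normal(size=7200)
    b = rng.normal(size=7200)
    oa = convolve_resample(a, kernel, 1.0, 709, dt)
    ob = convolve_resample(b, kernel, 1.0, 709, dt)
    oab = convolve_resample(a + b, kernel, 1.0, 709, dt)
    assert oa.size == 709
    assert np.abs(oab - (oa + ob)).max() < 1e-10


@settings(deadline=None, max_examples=30)
@given(st.integers(0, 2**31 - 1), st.floats(0.1, 10.0))
def test_convolution_scaling_linearity(seed, c):
    rng = np.random.default_rng(seed)
    dt = 0.2
    kernel = hrf_kernel(HrfSpec(), dt)
    s = rng.normal(size=500)
    o1 = convolve_resample(s, kernel, 1.0, 50, dt)
    oc = convolve_resample(c * s, kernel, 1.0, 50, dt)
    np.testing.assert_allclose(oc, c * o1, rtol=1e-10, atol=1e-10)


def test_valid_counts_match_study_bookkeeping():
    counts = [
        int(valid_timepoint_mask(W, 1.0, 709, 11.0).sum())
        for W in (15, 30, 45, 60, 75, 90)
    ]
    assert counts == [683, 668, 653, 638, 623, 608]
    assert np.diff(counts).tolist() == [-15] * 5


def test_mask_degenerate_cases():
    assert valid_timepoint_mask(0, 1.0, 709, 0.0).all()
    with pytest.raises(StoryEncError) as e:
        valid_timepoint_mask(200, 1.0, 150, 11.0)
    assert e.value.code == "empty-mask"


def _interest(T=40, seed=0, name="interest"):
    rng = np.random.default_rng(seed)
    return PredictorSeries(values=rng.normal(size=T),
                           valid_mask=np.ones(T, dtype=bool), tr=1.0, name=name)


def test_design_standardized_columns(rng):
    interest = _interest()
    nuis = {"wd": rng.normal(size=40), "ws": rng.normal(size=40)}
    design = build_design(interest, nuis)
    X = design.masked
    for j in range(1, X.shape[1]):
        assert abs(X[:, j].mean()) < 1e-9
        assert abs(X[:, j].std() - 1.0) < 1e-9
    assert design.names == ("intercept", "interest", "wd", "ws")


def test_design_collinear_and_empty_errors():
    interest = _interest()
    with pytest.raises(StoryEncError) as e:
        build_design(interest, {"dup": interest.values.copy()})
    assert e.value.code == "collinear-design"
    empty = PredictorSeries(values=np.zeros(40),
                            valid_mask=np.ones(40, dtype=bool), tr=1.0, name="x")
    with pytest.raises(StoryEncError) as e:
        build_design(empty, {})
    assert e.value.code == "empty-predictor"


def test_predictor_tsv_round_trip(tmp_path):
    series = metric_to_predictor(
        _one_token_transcript(3.0), np.array([1.3]), name="m",
        tr=1.0, T=50, window_seconds=15, buffer_s=2)
    path = tmp_path / "pred.tsv"
    write_predictor(series, path)
    back = read_predictor(path, "m")
    np.testing.assert_allclose(back.values, series.values, atol=1e-12)
    np.testing.assert_array_equal(back.valid_mask, series.valid_mask)
    assert back.tr == series.tr
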