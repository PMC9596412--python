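"""From token-level metric series to fMRI-grid regressors.

Token metrics become amplitude-modulated impulses at token onsets on a
fine time grid, are convolved with a canonical double-gamma hemodynamic
response function, and are sampled at the scanner's TR to give a
length-T regressor.  A validity mask drops the initial time points whose
windows extend before the narrative start (relevant for the saliency
analysis, where only full-window predictions count).  Design matrices
combine the predictor of interest with nuisance regressors: word
duration (WD), lexical frequency (LF, log10 occurrences-per-million),
and word sound (WS, an audio-envelope series supplied on its own grid).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import gamma as gamma_dist

from storyenc.errors import StoryEncError
from storyenc.stimulus_windows import Transcript

__all__ = [
    "HrfSpec",
    "PredictorSeries",
    "DesignMatrix",
    "hrf_kernel",
    "event_series",
    "convolve_resample",
    "valid_timepoint_mask",
    "resample_envelope",
    "build_design",
    "metric_to_predictor",
    "write_predictor",
    "read_predictor",
]


@dataclass(frozen=True)
class HrfSpec:
    """Double-gamma HRF parameters (seconds), canonical defaults."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    kernel_length: float = 32.0


@dataclass(frozen=True)
class PredictorSeries:
    """A regressor on the fMRI grid with a validity mask."""

    values: np.ndarray
    valid_mask: np.ndarray
    tr: float
    name: str

    def __post_init__(self):
        if self.values.shape != self.valid_mask.shape:
            raise StoryEncError("shape-mismatch", "values and mask lengths differ")

    @property
    def T(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class DesignMatrix:
    """Named T x p design; first column is the intercept."""

    matrix: np.ndarray
    names: tuple[str, ...]
    valid_mask: np.ndarray
    tr: float

    @property
    def masked(self) -> np.ndarray:
        return self.matrix[self.valid_mask]

    def column(self, name: str) -> int:
        try:
            return self.names.index(name)
        except ValueError:
            raise StoryEncError("bad-column", f"no design column {name!r}") from None


def hrf_kernel(spec: HrfSpec = HrfSpec(), dt: float = 0.1) -> np.ndarray:
    """Sampled double-gamma difference, normalized to unit peak.

    h(t) = Gamma(peak/disp, disp).pdf(t) - ratio * Gamma(us/us_disp, us_disp).pdf(t)
    """
    if dt <= 0 or dt > 1:
        raise StoryEncError("bad-dt", "dt must lie in (0, 1]")
    t = np.arange(0.0, spec.kernel_length + dt / 2, dt)
    # shape = delay/dispersion + 1 puts the gamma mode exactly at the delay
    peak = gamma_dist.pdf(t, spec.peak_delay / spec.dispersion + 1.0,
                          scale=spec.dispersion)
    under = gamma_dist.pdf(
        t, spec.undershoot_delay / spec.undershoot_dispersion + 1.0,
        scale=spec.undershoot_dispersion,
    )
    h = peak - spec.undershoot_ratio * under
    return h / h.max()


def event_series(
    transcript: Transcript,
    values: np.ndarray,
    dt: float,
    duration_s: float | None = None,
) -> np.ndarray:
    """Impulse train on a dt grid: amplitude = token metric value at its onset bin.

    NaN values (null-flagged tokens) contribute zero.  Two tokens falling
    in the same bin have their amplitudes summed.
    """
    if dt <= 0:
        raise StoryEncError("bad-dt", "dt must be positive")
    values = np.asarray(values, dtype=float)
    if values.size != len(transcript):
        raise StoryEncError("shape-mismatch", "one value per token required")
    if duration_s is None:
        duration_s = transcript.total_duration
    n_bins = int(math.ceil(duration_s / dt)) + 1
    series = np.zeros(n_bins)
    for tok, v in zip(transcript.tokens, values):
        if np.isnan(v):
            continue
        b = int(round(tok.onset / dt))
        if b >= n_bins:
            raise StoryEncError(
                "event-out-of-range",
                f"token onset {tok.onset:.3f}s beyond series span {duration_s:.3f}s",
            )
        series[b] += v
    return series


def convolve_resample(
    series: np.ndarray, kernel: np.ndarray, tr: float, T: int, dt: float
) -> np.ndarray:
    """Convolve on the dt grid and sample at t = k*tr, k = 0..T-1.

    The tail is zero-padded if the scan outlasts the stimulus plus the
    kernel.
    """
    if tr <= 0:
        raise StoryEncError("bad-tr", "tr must be positive")
    if T < 1:
        raise StoryEncError("bad-T", "T must be >= 1")
    conv = np.convolve(series, kernel)[: series.size]
    out = np.zeros(T)
    for k in range(T):
        b = int(round(k * tr / dt))
        if b < conv.size:
            out[k] = conv[b]
    return out


def valid_timepoint_mask(
    window_seconds: float, tr: float, T: int, buffer_s: float
) -> np.ndarray:
    """Boolean mask marking invalid the first ceil((W + buffer)/tr) points."""
    if window_seconds < 0 or buffer_s < 0:
        raise StoryEncError("bad-input", "window and buffer must be non-negative")
    n_invalid = int(math.ceil((window_seconds + buffer_s) / tr))
    if n_invalid >= T:
        raise StoryEncError("empty-mask", "mask removes every time point")
    mask = np.ones(T, dtype=bool)
    mask[:n_invalid] = False
    return mask


def resample_envelope(
    time_s: np.ndarray, values: np.ndarray, tr: float, T: int
) -> np.ndarray:
    """Linear-interpolate an audio-envelope series onto the fMRI grid."""
    grid = np.arange(T) * tr
    return np.interp(grid, np.asarray(time_s, float), np.asarray(values, float))


def metric_to_predictor(
    transcript: Transcript,
    values: np.ndarray,
    *,
    name: str,
    tr: float,
    T: int,
    dt: float = 0.1,
    hrf: HrfSpec = HrfSpec(),
    window_seconds: float = 0.0,
    buffer_s: float = 0.0,
    mask: np.ndarray | None = None,
) -> PredictorSeries:
    """Full event -> HRF -> resample path for one token-metric series."""
    series = event_series(transcript, values, dt, duration_s=max(transcript.total_duration, T * tr))
    kernel = hrf_kernel(hrf, dt)
    sampled = convolve_resample(series, kernel, tr, T, dt)
    if mask is None:
        if window_seconds > 0 or buffer_s > 0:
            mask = valid_timepoint_mask(window_seconds, tr, T, buffer_s)
        else:
            mask = np.ones(T, dtype=bool)
    return PredictorSeries(values=sampled, valid_mask=mask, tr=tr, name=name)


def build_design(
    interest: PredictorSeries,
    nuisance: dict[str, np.ndarray],
    *,
    standardize: bool = True,
) -> DesignMatrix:
    """Intercept + interest + nuisance columns, z-scored within the valid mask."""
    T = interest.T
    if np.all(np.isnan(interest.values)) or np.all(interest.values == 0):
        raise StoryEncError("empty-predictor", "predictor of interest carries no signal")
    cols = [np.ones(T)]
    names = ["intercept", interest.name]
    cols.append(np.asarray(interest.values, float))
    for nm, v in nuisance.items():
        v = np.asarray(v, dtype=float)
        if v.size != T:
            raise StoryEncError("shape-mismatch", f"nuisance {nm!r} length != T")
        cols.append(v)
        names.append(nm)
    if len(set(names)) != len(names):
        raise StoryEncError("bad-column", "duplicate design column names")
    X = np.column_stack(cols)
    mask = interest.valid_mask
    if standardize:
        for j in range(1, X.shape[1]):
            mu = X[mask, j].mean()
            sd = X[mask, j].std()
            if sd == 0.0:
                raise StoryEncError("collinear-design", f"constant column {names[j]!r}")
            X[:, j] = (X[:, j] - mu) / sd
    if np.linalg.matrix_rank(X[mask]) < X.shape[1]:
        raise StoryEncError("collinear-design", "design matrix rank-deficient after masking")
    return DesignMatrix(matrix=X, names=tuple(names), valid_mask=mask, tr=interest.tr)


def write_predictor(series: PredictorSeries, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": np.arange(series.T) * series.tr,
            "value": series.values,
            "valid": series.valid_mask.astype(int),
        }
    ).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_predictor(path: str | Path, name: str) -> PredictorSeries:
    df = pd.read_csv(path, sep="\t")
    t = df["time_s"].to_numpy()
    tr = float(t[1] - t[0]) if t.size > 1 else 1.0
    return PredictorSeries(
        values=df["value"].to_numpy(float),
        valid_mask=df["valid"].to_numpy() > 0,
        tr=tr,
        name=name,
    )
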