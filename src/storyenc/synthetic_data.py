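"""Synthetic inputs for every pipeline stage.

Emulates the study conditions end to end with no downloads: a ~12-min
timed transcript (~2,500 tokens, ~63% full words) generated as a
jittered point process with Zipf-distributed token identities, a seeded
toy LM, a word-sound (audio-envelope) nuisance series, and multi-subject
two-condition ROI BOLD with AR(1) noise and effects planted in
designated ROIs.  The forward (FW) run carries the planted
linguistic-predictor effects; the backward (BW) run shares only the
auditory word-sound effect, mirroring a time-reversed control that
preserves acoustics but removes meaning.

Every artifact is a pure function of :class:`SimConfig` (including its
seed).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from storyenc.errors import StoryEncError
from storyenc.lm_adapter import ToyDecayLM
from storyenc.stimulus_windows import TimedToken, Transcript, write_transcript
from storyenc.encoding_glm import RoiSignalSet

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_transcript",
    "make_toy_lm",
    "simulate_envelope",
    "simulate_brain",
    "make_fixture_suite",
    "PROFILES",
]


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the generator; defaults reproduce the study scale.

    27 subjects, 709 volumes at TR = 1 s, 2,512 tokens over a ~12-min
    narrative (rate ≈ 3.54 tokens/s), word fraction 1589/2512 ≈ 0.63.
    R defaults to 100 ROIs for desk-scale runs; the "paper-scale"
    profile raises it to 1000.
    """

    seed: int = 0
    V: int = 250
    d: int = 12
    gamma: float = 0.8
    n_tokens: int = 2512
    narrative_duration: float = 709.0
    speech_rate_mean: float = 3.54   # tokens / s
    speech_rate_sd: float = 3.54     # controls interval jitter (CV = sd/mean)
    word_fraction: float = 1589 / 2512
    zipf_exponent: float = 1.1
    S: int = 27
    R: int = 100
    T: int = 709
    tr: float = 1.0
    effect_rois: tuple[int, ...] = (0, 1, 2, 3, 4)
    beta_surprisal: float = 1.0
    beta_saliency: float = 1.0
    beta_ws: float = 0.5
    noise_sd: float = 1.0
    ar1_coefficient: float = 0.3

    def __post_init__(self):
        for name in ("V", "d", "n_tokens", "S", "R", "T"):
            if getattr(self, name) <= 0:
                raise StoryEncError("bad-config", f"{name} must be positive")
        if not 0.0 <= self.ar1_coefficient < 1.0:
            raise StoryEncError("bad-ar1", "AR(1) coefficient must lie in [0, 1)")
        if any(r < 0 or r >= self.R for r in self.effect_rois):
            raise StoryEncError("bad-config", "effect ROI index outside 0..R-1")


PROFILES: dict[str, dict] = {
    "tiny": dict(S=5, R=20, T=150, n_tokens=500, narrative_duration=150.0,
                 V=80, d=8, effect_rois=(0, 1, 2)),
    "default": {},
    "paper-scale": dict(R=1000),
}


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects, kept alongside outputs for recovery scoring."""

    effect_rois: tuple[int, ...]
    planted_betas: dict      # predictor name -> beta in effect ROIs (FW run)
    beta_ws: float           # word-sound beta, both runs, all ROIs (BW) / effect design


def _zipf_probs(V: int, a: float) -> np.ndarray:
    p = 1.0 / np.arange(1, V + 1, dtype=float) ** a
    return p / p.sum()


def simulate_transcript(config: SimConfig, rng: np.random.Generator | None = None) -> Transcript:
    """Timed transcript: jittered-point-process onsets, Zipf token identities.

    Inter-onset intervals are gamma-distributed with mean 1/rate and
    coefficient of variation speech_rate_sd / speech_rate_mean, then the
    onset axis is rescaled so the narrative fits its stated duration.
    lex_freq is the Zipf probability expressed per million (words only).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_tokens
    rate = config.speech_rate_mean
    if rate * config.narrative_duration < 2:
        raise StoryEncError("too-sparse", "rate too low for the narrative duration")
    cv = config.speech_rate_sd / config.speech_rate_mean
    shape = 1.0 / cv**2
    intervals = rng.gamma(shape, scale=1.0 / (rate * shape), size=n)
    onsets = np.cumsum(intervals) - intervals[0]
    # fit the narrative inside its duration, leaving a short silent tail
    onsets *= (config.narrative_duration - 1.5) / max(onsets[-1], 1e-9)
    probs = _zipf_probs(config.V, config.zipf_exponent)
    ids = rng.choice(config.V, size=n, p=probs)
    is_word = rng.random(n) < config.word_fraction
    gaps = np.diff(np.append(onsets, config.narrative_duration))
    durations = np.minimum(0.8 * gaps, 1.5)
    tokens = tuple(
        TimedToken(
            text=f"tok{ids[i]}",
            token_id=int(ids[i]),
            onset=float(onsets[i]),
            duration=float(durations[i]),
            is_word=bool(is_word[i]),
            lex_freq=float(probs[ids[i]] * 1e6) if is_word[i] else float("nan"),
        )
        for i in range(n)
    )
    return Transcript(tokens=tokens, total_duration=config.narrative_duration)


def make_toy_lm(config: SimConfig) -> ToyDecayLM:
    """Seeded toy decay LM sized to the simulated vocabulary."""
    return ToyDecayLM.random(config.V, config.d, config.gamma, seed=config.seed + 1,
                             scale=0.3)


def simulate_envelope(config: SimConfig, rng: np.random.Generator | None = None,
                      dt: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Smooth positive word-sound (audio envelope) series on a dt grid."""
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    t = np.arange(0.0, config.narrative_duration + dt / 2, dt)
    raw = rng.normal(size=t.size)
    kernel = np.exp(-0.5 * (np.arange(-8, 9) / 3.0) ** 2)
    smooth = np.convolve(raw, kernel / kernel.sum(), mode="same")
    env = smooth - smooth.min() + 0.05
    return t, env


def _ar1_noise(rng: np.random.Generator, phi: float, sd: float,
               shape: tuple[int, ...], axis_time: int = -2) -> np.ndarray:
    """Stationary AR(1) Gaussian noise with sd ``sd`` and lag-1 corr ``phi``."""
    burn = 100
    sh = list(shape)
    sh[axis_time] += burn
    e = rng.normal(scale=sd * np.sqrt(1.0 - phi**2), size=sh)
    x = lfilter([1.0], [1.0, -phi], e, axis=axis_time)
    sl = [slice(None)] * len(sh)
    sl[axis_time] = slice(burn, None)
    return x[tuple(sl)]


def simulate_brain(
    config: SimConfig,
    planted: dict[str, np.ndarray],
    ws: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[RoiSignalSet, GroundTruth]:
    """Two-condition multi-subject ROI BOLD with planted effects.

    ``planted`` maps predictor name -> length-T series; each is z-scored
    and added with its configured beta to the FW signal of every effect
    ROI.  Non-effect FW ROIs are AR(1) noise only.  The BW run carries
    only the word-sound effect (beta_ws * z-scored ``ws``) in all ROIs
    plus independent noise: the control shares acoustics, not language.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 3)
    T, R, S = config.T, config.R, config.S

    def z(v: np.ndarray) -> np.ndarray:
        v = np.asarray(v, float)
        sd = v.std()
        if sd == 0:
            raise StoryEncError("bad-config", "constant planted predictor")
        return (v - v.mean()) / sd

    betas = {
        "surprisal": config.beta_surprisal,
        "saliency": config.beta_saliency,
    }
    fw_effect = np.zeros(T)
    planted_record = {}
    for name, series in planted.items():
        b = betas.get(name, 1.0)
        fw_effect += b * z(series)
        planted_record[name] = b
    bw_effect = config.beta_ws * z(ws)

    noise = _ar1_noise(rng, config.ar1_coefficient, config.noise_sd,
                       (S, 2, T, R), axis_time=2)
    signals = {}
    effect = np.array(config.effect_rois, dtype=int)
    for s in range(S):
        fw = noise[s, 0].copy()
        if planted:
            fw[:, effect] += fw_effect[:, None]
        bw = noise[s, 1] + bw_effect[:, None]
        signals[(s, "FW")] = fw
        signals[(s, "BW")] = bw
    labels = tuple(f"roi{j:04d}" for j in range(R))
    truth = GroundTruth(effect_rois=tuple(int(r) for r in config.effect_rois),
                        planted_betas=planted_record, beta_ws=config.beta_ws)
    return RoiSignalSet(signals=signals, roi_labels=labels), truth


def config_hash(config: SimConfig) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=list)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def make_fixture_suite(config: SimConfig, outdir: str | Path,
                       planted: dict[str, np.ndarray] | None = None) -> dict:
    """Write every pipeline input to ``outdir``; returns the manifest.

    Files: transcript.tsv, toy_lm.json, ws_envelope.tsv, per-subject
    per-condition ROI TSVs, roi_labels.tsv, ground_truth.json,
    manifest.json.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    transcript = simulate_transcript(config)
    write_transcript(transcript, outdir / "transcript.tsv")
    lm = make_toy_lm(config)
    lm.to_json(outdir / "toy_lm.json")
    t_env, env = simulate_envelope(config)
    pd.DataFrame({"time_s": t_env, "value": env}).to_csv(
        outdir / "ws_envelope.tsv", sep="\t", index=False, float_format="%.6f")
    grid = np.arange(config.T) * config.tr
    ws_grid = np.interp(grid, t_env, env)
    signals, truth = simulate_brain(config, planted or {}, ws_grid)
    labels = list(signals.roi_labels)
    for (s, cond), mat in signals.signals.items():
        pd.DataFrame(mat, columns=labels).to_csv(
            outdir / f"sub-{s:02d}_{cond}_bold.tsv", sep="\t", index=False,
            float_format="%.6f")
    pd.DataFrame({
        "roi_id": range(config.R),
        "label": labels,
        "network": ["synthetic"] * config.R,
        "hemisphere": ["NA"] * config.R,
    }).to_csv(outdir / "roi_labels.tsv", sep="\t", index=False)
    (outdir / "ground_truth.json").write_text(json.dumps({
        "effect_rois": list(truth.effect_rois),
        "planted_betas": truth.planted_betas,
        "beta_ws": truth.beta_ws,
    }, indent=2))
    manifest = {
        "config": asdict(config),
        "config_hash": config_hash(config),
        "files": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    checksums = {}
    for name in manifest["files"]:
        checksums[name] = hashlib.sha256((outdir / name).read_bytes()).hexdigest()[:16]
    manifest["checksums"] = checksums
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=list))
    return manifest


def profile_config(profile: str, seed: int = 0, **overrides) -> SimConfig:
    if profile not in PROFILES:
        raise StoryEncError("bad-config", f"unknown profile {profile!r}")
    kwargs = dict(PROFILES[profile])
    kwargs.update(overrides)
    return SimConfig(seed=seed, **kwargs)
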