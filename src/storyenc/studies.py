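"""Monte-Carlo studies closing the loop on the synthetic pipeline.

Two canned experiments used by the test suite and the acceptance
script:

- :func:`fwer_study` — family-wise error rate of the Bonferroni-corrected
  group contrast under the global null (no planted effect), across
  seeded replicates of the full simulate -> fit -> contrast -> test path.
- :func:`power_study` — sensitivity (fraction of planted ROIs flagged)
  when effects are planted on the surprisal predictor in a small set of
  ROIs.

Both reuse one stimulus (transcript + toy LM + predictors) across
replicates and redraw only the BOLD noise, which is the quantity under
study.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from storyenc import metrics_core, predictor_builder, synthetic_data
from storyenc.encoding_glm import (
    GroupResult,
    RoiSignalSet,
    contrast_fw_bw,
    fit_subject,
    group_test,
)
from storyenc.predictor_builder import DesignMatrix, HrfSpec, PredictorSeries

__all__ = [
    "build_encoding_inputs",
    "analyze_signals",
    "fwer_study",
    "power_study",
]


def build_encoding_inputs(
    config: synthetic_data.SimConfig,
    window_seconds: float = 15.0,
    metric: str = "surprisal",
    *,
    hrf: HrfSpec = HrfSpec(),
    dt: float = 0.1,
    buffer_s: float = 11.0,
) -> tuple[PredictorSeries, dict[str, np.ndarray], DesignMatrix]:
    """Simulate the stimulus once and build the design for one (metric, window).

    Returns the interest predictor, the nuisance series (WD, LF, WS on
    the fMRI grid), and the assembled design matrix.
    """
    transcript = synthetic_data.simulate_transcript(config)
    lm = synthetic_data.make_toy_lm(config)
    surp, vectors = metrics_core.compute_all_metrics(transcript, lm, window_seconds)
    if metric == "surprisal":
        values = surp
        mask = np.ones(config.T, dtype=bool)
    elif metric == "saliency":
        values = metrics_core.aggregate_received_saliency(
            vectors, transcript, window_seconds)
        mask = predictor_builder.valid_timepoint_mask(
            window_seconds, config.tr, config.T, buffer_s)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    interest = predictor_builder.metric_to_predictor(
        transcript, values, name=metric, tr=config.tr, T=config.T, dt=dt,
        hrf=hrf, mask=mask)

    wd = np.array([t.duration for t in transcript.tokens])
    lf = np.array([
        np.log10(t.lex_freq) if t.is_word and t.lex_freq > 0 else np.nan
        for t in transcript.tokens
    ])
    wd_pred = predictor_builder.metric_to_predictor(
        transcript, wd, name="wd", tr=config.tr, T=config.T, dt=dt, hrf=hrf)
    lf_pred = predictor_builder.metric_to_predictor(
        transcript, lf, name="lf", tr=config.tr, T=config.T, dt=dt, hrf=hrf)
    t_env, env = synthetic_data.simulate_envelope(config)
    ws = predictor_builder.resample_envelope(t_env, env, config.tr, config.T)
    nuisance = {"wd": wd_pred.values, "lf": lf_pred.values, "ws": ws}
    design = predictor_builder.build_design(interest, nuisance)
    return interest, nuisance, design


def analyze_signals(
    signals: RoiSignalSet,
    design: DesignMatrix,
    interest: str,
    *,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    sided: str = "one",
) -> GroupResult:
    """Per-subject FW/BW fits, contrast matrix, and the group t-test."""
    S = signals.n_subjects
    contrasts = []
    for s in range(S):
        fit_fw = fit_subject(signals.signals[(s, "FW")], design, signals.roi_labels)
        fit_bw = fit_subject(signals.signals[(s, "BW")], design, signals.roi_labels)
        contrasts.append(contrast_fw_bw(fit_fw, fit_bw, interest))
    return group_test(
        np.vstack(contrasts), roi_labels=signals.roi_labels,
        alpha=alpha, n_comparisons=n_comparisons, sided=sided)


def fwer_study(
    config: synthetic_data.SimConfig,
    n_reps: int = 200,
    seed: int = 0,
    *,
    alpha: float = 0.05,
) -> dict:
    """Family-wise error rate under the global null across replicates.

    No effect is planted (all betas zero); a replicate counts as a
    family-wise error when any ROI is flagged after Bonferroni.
    """
    null_cfg = replace(config, beta_surprisal=0.0, beta_saliency=0.0, effect_rois=())
    _, _, design = build_encoding_inputs(null_cfg)
    t_env, env = synthetic_data.simulate_envelope(null_cfg)
    ws = predictor_builder.resample_envelope(t_env, env, null_cfg.tr, null_cfg.T)
    rng = np.random.default_rng(seed)
    errors = 0
    for _ in range(n_reps):
        signals, _ = synthetic_data.simulate_brain(null_cfg, {}, ws, rng=rng)
        res = analyze_signals(signals, design, "surprisal", alpha=alpha)
        errors += int(res.significant.any())
    fwer = errors / n_reps
    mc_se = float(np.sqrt(alpha * (1 - alpha) / n_reps))
    return {"fwer": fwer, "n_reps": n_reps, "alpha": alpha, "mc_se": mc_se}


def power_study(
    config: synthetic_data.SimConfig,
    n_reps: int = 10,
    seed: int = 0,
    *,
    alpha: float = 0.05,
) -> dict:
    """Sensitivity of the full pipeline with surprisal effects planted.

    Each replicate plants ``beta_surprisal`` on the z-scored surprisal
    predictor in ``config.effect_rois``, redraws the BOLD noise, runs
    the two-level analysis, and scores the fraction of planted ROIs
    recovered (and any false positives outside them).
    """
    interest, _, design = build_encoding_inputs(config)
    t_env, env = synthetic_data.simulate_envelope(config)
    ws = predictor_builder.resample_envelope(t_env, env, config.tr, config.T)
    planted = {"surprisal": interest.values}
    rng = np.random.default_rng(seed)
    effect = set(config.effect_rois)
    sens, fps = [], []
    for _ in range(n_reps):
        signals, _ = synthetic_data.simulate_brain(config, planted, ws, rng=rng)
        res = analyze_signals(signals, design, "surprisal", alpha=alpha)
        flagged = {j for j, s in enumerate(res.significant) if s}
        sens.append(len(flagged & effect) / len(effect))
        fps.append(len(flagged - effect))
    return {
        "sensitivity": float(np.mean(sens)),
        "mean_false_positives": float(np.mean(fps)),
        "n_reps": n_reps,
    }
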