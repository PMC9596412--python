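"""Two-level ROI encoding GLM with a forward-vs-backward contrast.

First level: per subject and per condition, ordinary least squares of
every ROI-averaged BOLD time series on the design matrix (valid time
points only).  The predictor-of-interest betas from the forward (FW)
and backward (BW) runs are differenced per ROI.  Second level
(summary-statistics "mixed-effects" group analysis): a one-sample
t-test across subjects on those contrasts, one-sided positive (FW > BW)
by default, with Bonferroni correction over the number of ROIs tested
(overridable, e.g. to a fixed atlas size of 1000).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from storyenc.errors import StoryEncError
from storyenc.predictor_builder import DesignMatrix

__all__ = [
    "RoiSignalSet",
    "SubjectFit",
    "GroupResult",
    "fit_subject",
    "contrast_fw_bw",
    "group_test",
    "summarize_across_windows",
]


@dataclass(frozen=True)
class RoiSignalSet:
    """Per-subject, per-condition T x R ROI-averaged BOLD matrices."""

    signals: dict  # (subject_index, condition) -> np.ndarray (T, R)
    roi_labels: tuple[str, ...]

    @property
    def n_subjects(self) -> int:
        return len({s for s, _ in self.signals})

    @property
    def conditions(self) -> tuple[str, ...]:
        return tuple(sorted({c for _, c in self.signals}))


@dataclass(frozen=True)
class SubjectFit:
    betas: np.ndarray          # p x R
    design_names: tuple[str, ...]
    roi_labels: tuple[str, ...]
    residual_variance: np.ndarray  # R
    dof: int

    def beta(self, name: str) -> np.ndarray:
        return self.betas[self.design_names.index(name)]


@dataclass(frozen=True)
class GroupResult:
    roi_labels: tuple[str, ...]
    contrast_mean: np.ndarray
    t: np.ndarray
    dof: int
    p: np.ndarray
    p_bonferroni: np.ndarray
    significant: np.ndarray
    alpha: float
    n_comparisons: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "roi": self.roi_labels,
                "contrast": self.contrast_mean,
                "t": self.t,
                "p": self.p,
                "p_bonf": self.p_bonferroni,
                "sig": self.significant.astype(int),
            }
        )


def fit_subject(roi_matrix: np.ndarray, design: DesignMatrix,
                roi_labels: tuple[str, ...] | None = None) -> SubjectFit:
    """OLS of every ROI column on the masked design; exact normal-equations solution."""
    Y = np.asarray(roi_matrix, dtype=float)
    if Y.ndim != 2 or Y.shape[0] != design.matrix.shape[0]:
        raise StoryEncError("shape-mismatch", "ROI matrix rows must equal design T")
    mask = design.valid_mask
    X = design.matrix[mask]
    Ym = Y[mask]
    n, p = X.shape
    dof = n - p
    if dof <= 0:
        raise StoryEncError("insufficient-dof", f"{n} valid points for {p} regressors")
    betas, _, rank, _ = np.linalg.lstsq(X, Ym, rcond=None)
    if rank < p:
        raise StoryEncError("collinear-design", "design not full rank on valid points")
    resid = Ym - X @ betas
    if roi_labels is None:
        roi_labels = tuple(f"roi{j}" for j in range(Y.shape[1]))
    return SubjectFit(
        betas=betas,
        design_names=design.names,
        roi_labels=tuple(roi_labels),
        residual_variance=(resid**2).sum(axis=0) / dof,
        dof=dof,
    )


def contrast_fw_bw(fit_fw: SubjectFit, fit_bw: SubjectFit, interest: str) -> np.ndarray:
    """Per-ROI interest-beta difference, forward minus backward."""
    if fit_fw.roi_labels != fit_bw.roi_labels:
        raise StoryEncError("roi-mismatch", "ROI labels differ between conditions")
    if fit_fw.design_names != fit_bw.design_names:
        raise StoryEncError("roi-mismatch", "design columns differ between conditions")
    return fit_fw.beta(interest) - fit_bw.beta(interest)


def group_test(
    contrasts: np.ndarray,
    *,
    roi_labels: tuple[str, ...] | None = None,
    alpha: float = 0.05,
    n_comparisons: int | None = None,
    sided: str = "one",
) -> GroupResult:
    """One-sample t per ROI on the S x R subject-contrast matrix.

    dof = S - 1.  ``sided``: "one" tests FW > BW (positive effects),
    "two" is symmetric.  Bonferroni: p multiplied by ``n_comparisons``
    (defaults to the number of ROIs tested) and clipped at 1.
    """
    C = np.asarray(contrasts, dtype=float)
    if C.ndim != 2:
        raise StoryEncError("shape-mismatch", "contrasts must be S x R")
    S, R = C.shape
    if S < 3:
        raise StoryEncError("bad-input", "need at least 3 subjects")
    if sided not in ("one", "two"):
        raise StoryEncError("bad-input", f"unknown sidedness {sided!r}")
    if n_comparisons is None:
        n_comparisons = R
    mean = C.mean(axis=0)
    sd = C.std(axis=0, ddof=1)
    dof = S - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(S))
    zero_var = sd == 0.0
    t[zero_var & (mean > 0)] = np.inf
    t[zero_var & (mean < 0)] = -np.inf
    t[zero_var & (mean == 0)] = 0.0
    if sided == "one":
        p = stats.t.sf(t, dof)
    else:
        p = 2.0 * stats.t.sf(np.abs(t), dof)
    p_bonf = np.minimum(1.0, p * n_comparisons)
    if roi_labels is None:
        roi_labels = tuple(f"roi{j}" for j in range(R))
    return GroupResult(
        roi_labels=tuple(roi_labels),
        contrast_mean=mean,
        t=t,
        dof=dof,
        p=p,
        p_bonferroni=p_bonf,
        significant=p_bonf < alpha,
        alpha=alpha,
        n_comparisons=n_comparisons,
    )


def summarize_across_windows(results: dict[float, GroupResult]) -> dict:
    """Overlap bookkeeping of significant ROIs across window sizes."""
    if not results:
        raise StoryEncError("bad-input", "need at least one window result")
    windows = sorted(results)
    first = results[windows[0]]
    sig_sets = {}
    for w in windows:
        r = results[w]
        if r.roi_labels != first.roi_labels:
            raise StoryEncError("roi-mismatch", "ROI labels differ across windows")
        sig_sets[w] = {lab for lab, s in zip(r.roi_labels, r.significant) if s}
    union = set.union(*sig_sets.values())
    intersection = set.intersection(*sig_sets.values())
    return {
        "per_window_counts": {w: len(sig_sets[w]) for w in windows},
        "n_any_window": len(union),
        "n_all_windows": len(intersection),
        "union": sorted(union),
        "intersection": sorted(intersection),
    }
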