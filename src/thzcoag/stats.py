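"""Cohort statistics: group tests, correlations, normalized change spectra.

Mirrors the analysis applied to the measured absorption constants:

* pooled-variance two-tailed unpaired t-tests per frequency with a 95% CI
  of the group mean difference, with the significance-star bins
  ``* 0.01 < p < 0.05``, ``** 0.001 < p < 0.01``, ``*** p < 0.001``
  implemented exactly as printed (open intervals; boundary p-values are
  labelled on the less-significant side and flagged);
* bivariate Pearson correlations against hematology covariates, a
  correlation being declared only when p < 0.05;
* hematology filters (RBC strictly above the lower bound and at most the
  upper, i.e. "4 < RBC <= 5 M/uL"; PLT in the closed normal range);
* normalized absorption change spectra delta-alpha/alpha_blood with the
  transparency frequency taken from the zero crossing of a least-squares
  line fit over the analysis band, and the platelet-stratified red shift
  of that frequency.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

STAR_LABELS = ("ns", "*", "**", "***")


def assign_stars(p_value: float) -> tuple[str, bool]:
    """Significance label from the printed open-interval bins.

    Returns (label, boundary_flag); the flag marks p-values falling exactly
    on a bin edge, which are assigned the less-significant label.
    """
    if np.isnan(p_value):
        return "ns", False
    if p_value in (0.05, 0.01, 0.001):
        # boundary: conservative (less significant) side
        label = {0.05: "ns", 0.01: "*", 0.001: "**"}[p_value]
        return label, True
    if p_value < 0.001:
        return "***", False
    if p_value < 0.01:
        return "**", False
    if p_value < 0.05:
        return "*", False
    return "ns", False


@dataclass
class GroupComparison:
    freq_thz: Optional[float]
    mean_a: float
    mean_b: float
    t_statistic: float
    p_value: float
    ci_low: float
    ci_high: float
    n_a: int
    n_b: int
    stars: str
    boundary_flag: bool = False
    degenerate: bool = False


@dataclass
class CorrelationResult:
    freq_thz: Optional[float]
    covariate: str
    r: float
    p_value: float
    n: int
    significant: bool
    degenerate: bool = False


@dataclass
class DeltaSpectrum:
    """delta-alpha/alpha_blood spectrum with its fitted zero crossing."""

    freqs_thz: np.ndarray
    delta_over_alpha: np.ndarray
    fit_slope: float            # per THz
    fit_intercept: float
    transparency_freq_thz: Optional[float]
    n_state: int = 0
    n_blood: int = 0

    def excess_defect(self, freq_thz) -> np.ndarray:
        """'excess' above the transparency frequency, 'defect' below."""
        if self.transparency_freq_thz is None:
            raise ValueError("transparency frequency undefined (flat spectrum)")
        return np.where(np.asarray(freq_thz) >= self.transparency_freq_thz,
                        "excess", "defect")


def minute_average_alpha(alphas: Sequence[np.ndarray]) -> np.ndarray:
    """Per-frequency arithmetic mean of absorption spectra for one minute."""
    if len(alphas) == 0:
        raise ValueError("no spectra to average")
    stack = np.asarray(alphas, dtype=float)
    if stack.ndim != 2:
        raise ValueError("spectra must share one frequency grid")
    return stack.mean(axis=0)


def filter_subjects(records: pd.DataFrame, rbc_range=(4.0, 5.0),
                    plt_range=(100.0, 300.0)) -> pd.DataFrame:
    """Hematology window: lower < RBC <= upper, PLT in the closed range."""
    if rbc_range[0] >= rbc_range[1] or plt_range[0] >= plt_range[1]:
        raise ValueError("filter ranges must be well ordered")
    rbc = records["rbc_M_per_uL"]
    plt = records["plt_K_per_uL"]
    mask = (rbc > rbc_range[0]) & (rbc <= rbc_range[1]) \
        & (plt >= plt_range[0]) & (plt <= plt_range[1])
    return records[mask]


def unpaired_ttest(alphas_a, alphas_b, freq_thz: Optional[float] = None) -> GroupComparison:
    """Two-tailed pooled-variance two-sample t-test with 95% CI.

    Reproduces the default semantics of the classic equal-variance
    ``ttest2``: t from the pooled standard deviation, p two-tailed, CI on
    the difference of means (a minus b).
    """
    a = np.asarray(alphas_a, dtype=float)
    b = np.asarray(alphas_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least two observations")
    mean_a, mean_b = float(a.mean()), float(b.mean())
    pooled = ((a.size - 1) * a.var(ddof=1) + (b.size - 1) * b.var(ddof=1))
    degenerate = False
    if pooled == 0.0:
        diff = mean_a - mean_b
        degenerate = True
        if diff == 0.0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat, p = np.inf if diff > 0 else -np.inf, 0.0
        ci = (diff, diff)
    else:
        res = sps.ttest_ind(a, b, equal_var=True)
        t_stat, p = float(res.statistic), float(res.pvalue)
        interval = res.confidence_interval(0.95)
        ci = (float(interval.low), float(interval.high))
    stars, boundary = assign_stars(p)
    return GroupComparison(freq_thz=freq_thz, mean_a=mean_a, mean_b=mean_b,
                           t_statistic=t_stat, p_value=p, ci_low=ci[0],
                           ci_high=ci[1], n_a=a.size, n_b=b.size, stars=stars,
                           boundary_flag=boundary, degenerate=degenerate)


def pearson_correlation(alphas, covariate, name: str = "",
                        freq_thz: Optional[float] = None) -> CorrelationResult:
    """Pearson r with the two-sided p of the no-correlation hypothesis."""
    x = np.asarray(alphas, dtype=float)
    y = np.asarray(covariate, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.var(x) == 0.0 or np.var(y) == 0.0:
        return CorrelationResult(freq_thz, name, np.nan, np.nan, x.size,
                                 significant=False, degenerate=True)
    res = sps.pearsonr(x, y)
    r, p = float(res.statistic), float(res.pvalue)
    return CorrelationResult(freq_thz, name, r, p, x.size, significant=p < 0.05)


def delta_spectrum(alpha_state, alpha_blood, freqs_thz, band=(0.13, 1.02),
                   slope_threshold: float = 1.0e-3,
                   n_state: int = 0, n_blood: int = 0) -> DeltaSpectrum:
    """Normalized change spectrum and its fitted transparency frequency.

    delta-alpha/alpha_blood = (alpha_state - alpha_blood)/alpha_blood per
    frequency; a straight line is fit over ``band`` and the transparency
    frequency is its zero crossing -intercept/slope.  If the fitted slope
    magnitude is below ``slope_threshold`` (per THz) the crossing is
    undefined and reported as None.
    """
    freqs = np.asarray(freqs_thz, dtype=float)
    a_state = np.asarray(alpha_state, dtype=float)
    a_blood = np.asarray(alpha_blood, dtype=float)
    mask = (freqs >= band[0]) & (freqs <= band[1])
    if not np.any(mask):
        raise ValueError("band outside the frequency grid")
    if np.any(a_blood[mask] <= 0):
        raise ValueError("alpha_blood must be positive on the band")
    delta = a_state / a_blood - 1.0
    slope, intercept = np.polyfit(freqs[mask], delta[mask], 1)
    f_t = None if abs(slope) < slope_threshold else float(-intercept / slope)
    return DeltaSpectrum(freqs[mask], delta[mask], fit_slope=float(slope),
                         fit_intercept=float(intercept),
                         transparency_freq_thz=f_t,
                         n_state=n_state, n_blood=n_blood)


def plt_stratified_shift(records: pd.DataFrame, alpha_matrix: np.ndarray,
                         freqs_thz, alpha_blood,
                         bins=((100.0, 200.0), (200.0, 300.0)),
                         band=(0.13, 1.02)) -> dict:
    """Per-PLT-bin mean change spectra and the between-bin red shift.

    ``records`` (already filtered) and ``alpha_matrix`` rows must be
    aligned.  Bins are [low, high) except the last, which is closed.
    Returns {"bins": [(lo, hi, DeltaSpectrum|None), ...],
    "shift_thz": f_t(last bin) - f_t(first bin) or None}.
    """
    import warnings

    plt = np.asarray(records["plt_K_per_uL"], dtype=float)
    out = []
    for i, (lo, hi) in enumerate(bins):
        upper = plt <= hi if i == len(bins) - 1 else plt < hi
        sel = (plt >= lo) & upper
        if not np.any(sel):
            warnings.warn(f"PLT bin [{lo}, {hi}] is empty; skipped")
            out.append((lo, hi, None))
            continue
        mean_alpha = minute_average_alpha(alpha_matrix[sel])
        out.append((lo, hi, delta_spectrum(mean_alpha, alpha_blood, freqs_thz,
                                           band=band, n_state=int(sel.sum()))))
    shift = None
    first, last = out[0][2], out[-1][2]
    if first is not None and last is not None and \
            first.transparency_freq_thz is not None and last.transparency_freq_thz is not None:
        shift = last.transparency_freq_thz - first.transparency_freq_thz
    return {"bins": out, "shift_thz": shift}
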