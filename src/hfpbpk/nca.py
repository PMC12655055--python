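"""Non-compartmental exposure metrics and model-vs-observation statistics.

AUC uses the linear-up/log-down trapezoid; the terminal slope (lambda_z) is
fitted by log-linear regression on a sliding terminal window chosen by
adjusted R-squared (ties broken toward more points). Exposure ratios between
heart-failure and healthy summaries are dose-normalized; prediction accuracy
is expressed as observed/predicted fold errors against the conventional
0.5-2.0 acceptance window and the stricter 0.8-1.25 bioequivalence-style
window.

Units: time h, concentration ng/mL, AUC reported in ug*h/mL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

NG_H_PER_ML_TO_UG_H_PER_ML = 1e-3


@dataclass
class ConcentrationProfile:
    """A sampled plasma concentration-time course for one dose."""

    times: np.ndarray          # h, strictly increasing
    concentrations: np.ndarray  # ng/mL, >= 0
    dose: float = 1.0          # mg
    label: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.concentrations = np.asarray(self.concentrations, dtype=float)
        if self.times.ndim != 1 or len(self.times) != len(self.concentrations):
            raise ValueError("times and concentrations must align")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.concentrations < 0):
            raise ValueError("concentrations must be >= 0")


@dataclass
class ExposureSummary:
    """NCA summary of one profile."""

    auc_0_t: float              # ug*h/mL
    auc_inf: float | None       # ug*h/mL; None if lambda_z not estimable
    cmax: float                 # ng/mL
    cmin: float                 # ng/mL (trough over the sampled span)
    tmax: float                 # h
    lambda_z: float | None      # 1/h
    dose: float                 # mg
    profile: ConcentrationProfile | None = None

    def time_above(self, threshold: float) -> float:
        """Hours the (piecewise-linear) profile spends above a threshold."""
        if self.profile is None:
            raise ValueError("summary carries no profile")
        return time_above(self.profile, threshold)


def _auc_linear_up_log_down(t: np.ndarray, c: np.ndarray) -> float:
    """AUC in ng*h/mL over the sampled span."""
    auc = 0.0
    for i in range(len(t) - 1):
        dt = t[i + 1] - t[i]
        c1, c2 = c[i], c[i + 1]
        if c2 < c1 and c2 > 0:
            auc += dt * (c1 - c2) / np.log(c1 / c2)
        else:
            auc += dt * (c1 + c2) / 2.0
    return auc


def _fit_lambda_z(t: np.ndarray, c: np.ndarray):
    """Terminal log-linear fit; returns (lambda_z, window size) or None.

    Candidate windows are the last k >= 3 positive-concentration points
    strictly after Tmax; the window with the best adjusted R-squared wins,
    ties going to the larger window.
    """
    pos = c > 0
    i_tmax = int(np.argmax(c))
    candidates = []
    idx = np.nonzero(pos)[0]
    idx = idx[idx > i_tmax]
    for k in range(3, len(idx) + 1):
        sel = idx[-k:]
        ts, ys = t[sel], np.log(c[sel])
        slope, intercept = np.polyfit(ts, ys, 1)
        if slope >= 0:
            continue
        resid = ys - (slope * ts + intercept)
        ss_res = float(resid @ resid)
        ss_tot = float(((ys - ys.mean()) ** 2).sum())
        if ss_tot == 0:
            continue
        r2 = 1.0 - ss_res / ss_tot
        r2_adj = 1.0 - (1.0 - r2) * (k - 1) / (k - 2)
        candidates.append((round(r2_adj, 10), k, -slope))
    if not candidates:
        return None
    candidates.sort()
    _, k, lz = candidates[-1]
    return lz, k


def nca(profile: ConcentrationProfile) -> ExposureSummary:
    """Non-compartmental analysis of a concentration profile."""
    t, c = profile.times, profile.concentrations
    if len(t) < 3:
        raise ValueError("NCA requires at least 3 points")
    auc_t = _auc_linear_up_log_down(t, c) * NG_H_PER_ML_TO_UG_H_PER_ML
    fit = _fit_lambda_z(t, c)
    if fit is None:
        lambda_z, auc_inf = None, None
    else:
        lambda_z, _ = fit
        c_last = c[np.nonzero(c > 0)[0][-1]]
        auc_inf = auc_t + c_last / lambda_z * NG_H_PER_ML_TO_UG_H_PER_ML
    return ExposureSummary(
        auc_0_t=auc_t, auc_inf=auc_inf,
        cmax=float(c.max()), cmin=float(c.min()),
        tmax=float(t[np.argmax(c)]), lambda_z=lambda_z,
        dose=profile.dose, profile=profile)


def time_above(profile: ConcentrationProfile, threshold: float) -> float:
    """Total hours above a threshold, by linear interpolation of crossings."""
    t, c = profile.times, profile.concentrations
    total = 0.0
    for i in range(len(t) - 1):
        t1, t2, c1, c2 = t[i], t[i + 1], c[i], c[i + 1]
        dt = t2 - t1
        above1, above2 = c1 > threshold, c2 > threshold
        if above1 and above2:
            total += dt
        elif above1 != above2:
            frac = (threshold - c1) / (c2 - c1)
            total += dt * (1.0 - frac) if above1 else dt * frac
    return total


def exposure_ratio(hf: ExposureSummary, healthy: ExposureSummary,
                   dose_hf: float | None = None,
                   dose_h: float | None = None) -> dict:
    """Dose-normalized HF:healthy AUC and Cmax ratios (AUCR, CmaxR)."""
    dose_hf = hf.dose if dose_hf is None else dose_hf
    dose_h = healthy.dose if dose_h is None else dose_h
    if dose_hf <= 0 or dose_h <= 0:
        raise ValueError("doses must be > 0")
    if healthy.auc_0_t == 0 or healthy.cmax == 0:
        raise ZeroDivisionError("healthy summary has zero exposure")
    return {
        "aucr": (hf.auc_0_t / dose_hf) / (healthy.auc_0_t / dose_h),
        "cmaxr": (hf.cmax / dose_hf) / (healthy.cmax / dose_h),
    }


def fold_error(observed: float, predicted: float) -> dict:
    """Observed/predicted ratio with the two conventional windows."""
    if observed <= 0 or predicted <= 0:
        raise ValueError("fold_error requires positive inputs")
    ratio = observed / predicted
    return {
        "ratio": ratio,
        "within_2fold": 0.5 <= ratio <= 2.0,
        "within_bioeq": 0.8 <= ratio <= 1.25,
    }


def band_coverage(observed: ConcentrationProfile, band_times: np.ndarray,
                  band_lo: np.ndarray, band_hi: np.ndarray) -> float:
    """Fraction of observed points inside a 5th-95th percentile band.

    Band percentiles are interpolated linearly onto the observation times;
    observation times must be covered by the band grid.
    """
    if len(observed.times) == 0:
        raise ValueError("empty profile")
    if (observed.times.min() < band_times.min() - 1e-9
            or observed.times.max() > band_times.max() + 1e-9):
        raise ValueError("band grid does not cover observation times")
    lo = np.interp(observed.times, band_times, band_lo)
    hi = np.interp(observed.times, band_times, band_hi)
    inside = ((observed.concentrations >= lo)
              & (observed.concentrations <= hi))
    return float(inside.mean())


def summary_table(rows: list[dict]) -> pd.DataFrame:
    """Obs/Pre comparison table (one row per profile and metric)."""
    return pd.DataFrame(rows, columns=["drug", "group", "metric", "obs",
                                       "pre", "obs_over_pre", "within_2fold",
                                       "within_bioeq"])
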