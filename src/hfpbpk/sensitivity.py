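"""Local (one-at-a-time) and Sobol global sensitivity of exposure metrics.

Local scans rescale one parameter over a fold range on a log-spaced grid
(always including fold 1.0) and report the steady-state metric at each
point; blood-flow parameters rescale a single tissue's flow with the
pulmonary flow recomputed so the circulation stays closed. The Sobol
analysis uses Saltelli-style quasi-random sampling and the first-order /
total-order variance estimators provided by ``scipy.stats.sobol_indices``,
over the same fold bounds interpreted as uniform multiplier distributions.

Default fold ranges follow the local-scan conventions: two-fold for the
intrinsic clearances and hepatic/renal flows, three-fold for permeability
and the muscle/skin/adipose flows, and 0.7-1.3 for the unbound blood
fraction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .model import PBPKModel, Regimen, steady_state
from .nca import NG_H_PER_ML_TO_UG_H_PER_ML

FLOW_PARAMS = {
    "q_liver": "liver",
    "q_kidney": "kidney",
    "q_muscle": "muscle",
    "q_skin": "skin",
    "q_adipose": "adipose",
}
DRUG_PARAMS = ("cl_liver_int", "cl_kidney_int", "peff", "fu_b")
SCANNABLE = DRUG_PARAMS + tuple(FLOW_PARAMS)

#: Default fold ranges, [low, high] multipliers of baseline.
DEFAULT_FOLD_RANGES = {
    "cl_liver_int": (0.5, 2.0),
    "cl_kidney_int": (0.5, 2.0),
    "peff": (1.0 / 3.0, 3.0),
    "fu_b": (0.7, 1.3),
    "q_liver": (0.5, 2.0),
    "q_kidney": (0.5, 2.0),
    "q_muscle": (1.0 / 3.0, 3.0),
    "q_skin": (1.0 / 3.0, 3.0),
    "q_adipose": (1.0 / 3.0, 3.0),
}


@dataclass
class ScanSpec:
    """One-at-a-time scan of a single parameter."""

    parameter: str
    fold_range: tuple | None = None
    n_points: int = 7
    metric: str = "auc"

    def __post_init__(self) -> None:
        if self.parameter not in SCANNABLE:
            raise ValueError(f"unknown parameter {self.parameter!r}")
        if self.fold_range is None:
            self.fold_range = DEFAULT_FOLD_RANGES[self.parameter]
        low, high = self.fold_range
        if not 0 < low <= 1 <= high:
            raise ValueError("fold range must satisfy 0 < low <= 1 <= high")
        if self.metric not in ("auc", "cmax"):
            raise ValueError("metric must be 'auc' or 'cmax'")


@dataclass
class SobolSpec:
    """Variance-based global sensitivity over fold multipliers."""

    parameters: dict = field(
        default_factory=lambda: dict(DEFAULT_FOLD_RANGES))
    n_base_samples: int = 256
    seed: int = 0
    metric: str = "auc"

    def __post_init__(self) -> None:
        for p in self.parameters:
            if p not in SCANNABLE:
                raise ValueError(f"unknown parameter {p!r}")
        if self.metric not in ("auc", "cmax"):
            raise ValueError("metric must be 'auc' or 'cmax'")


@dataclass
class SensitivityReport:
    """Per-parameter sensitivity results as a tidy table."""

    table: pd.DataFrame
    kind: str               # "local" or "sobol"
    metadata: dict = field(default_factory=dict)


def apply_fold(model: PBPKModel, parameter: str, fold: float) -> PBPKModel:
    """Return a model copy with one parameter rescaled by ``fold``."""
    if fold <= 0:
        raise ValueError("fold must be > 0")
    if parameter in FLOW_PARAMS:
        phys = model.physiology.with_scaled_flow(FLOW_PARAMS[parameter],
                                                 fold)
        return model.with_physiology(phys)
    if parameter == "fu_b":
        fu_p = model.drug.fu_p * fold
        if fu_p > 1.0:
            raise ValueError("fu_b fold pushes fu_p above 1")
        return model.replace_drug(model.drug.replace(fu_p=fu_p))
    value = getattr(model.drug, parameter) * fold
    return model.replace_drug(model.drug.replace(**{parameter: value}))


def steady_state_metric(model: PBPKModel, regimen: Regimen,
                        metric: str = "auc") -> float:
    """Steady-state interval AUC (ug*h/mL) or Cmax (ng/mL)."""
    res = steady_state(model, regimen)
    conc = res.plasma_conc_ng_ml
    if metric == "cmax":
        return float(conc.max())
    return float(np.trapezoid(conc, res.times_h)) * NG_H_PER_ML_TO_UG_H_PER_ML


def local_scan(model: PBPKModel, regimen: Regimen,
               spec: ScanSpec) -> SensitivityReport:
    """Evaluate the metric on a log-spaced fold grid for one parameter."""
    low, high = spec.fold_range
    folds = np.geomspace(low, high, spec.n_points)
    if not np.any(np.isclose(folds, 1.0)):
        folds = np.sort(np.append(folds, 1.0))
    baseline = steady_state_metric(model, regimen, spec.metric)
    rows = []
    for f in folds:
        value = (baseline if np.isclose(f, 1.0)
                 else steady_state_metric(apply_fold(model, spec.parameter,
                                                     float(f)),
                                          regimen, spec.metric))
        rows.append({"parameter": spec.parameter, "fold": float(f),
                     "metric": spec.metric, "value": value,
                     "fold_change": value / baseline})
    return SensitivityReport(table=pd.DataFrame(rows), kind="local",
                             metadata={"baseline": baseline})


def sobol_indices_for_function(func, bounds: list, n_base: int,
                               seed: int) -> pd.DataFrame:
    """First/total Sobol indices of ``func`` over uniform boxes.

    ``func`` maps an array of shape (d, n) to n outputs; ``bounds`` is a
    list of (low, high). Deterministic for a fixed seed.
    """
    dists = [stats.uniform(loc=lo, scale=hi - lo) for lo, hi in bounds]
    rng = np.random.default_rng(seed)
    res = stats.sobol_indices(func=func, n=n_base, dists=dists, rng=rng)
    return pd.DataFrame({
        "s_i": np.atleast_1d(res.first_order),
        "s_ti": np.atleast_1d(res.total_order),
    })


def sobol_gsa(model: PBPKModel, regimen: Regimen,
              spec: SobolSpec) -> SensitivityReport:
    """Sobol GSA of the steady-state exposure metric over fold multipliers."""
    names = list(spec.parameters)
    bounds = [spec.parameters[p] for p in names]
    n_eval = {"count": 0}

    def func(x: np.ndarray) -> np.ndarray:
        out = np.empty(x.shape[1])
        for j in range(x.shape[1]):
            m = model
            try:
                for name, fold in zip(names, x[:, j]):
                    m = apply_fold(m, name, float(fold))
                out[j] = steady_state_metric(m, regimen, spec.metric)
            except Exception as exc:
                raise RuntimeError(
                    f"metric evaluation failed at sample {j}: {exc}") from exc
            n_eval["count"] += 1
        return out

    table = sobol_indices_for_function(func, bounds, spec.n_base_samples,
                                       spec.seed)
    table.insert(0, "parameter", names)
    table["rank"] = table["s_ti"].rank(ascending=False).astype(int)
    table = table.sort_values("rank").reset_index(drop=True)
    return SensitivityReport(table=table, kind="sobol",
                             metadata={"n_base_samples": spec.n_base_samples,
                                       "n_evaluations": n_eval["count"],
                                       "seed": spec.seed,
                                       "metric": spec.metric,
                                       "bounds": dict(spec.parameters)})
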