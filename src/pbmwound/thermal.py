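"""Irradiative heating kinetics and radiant-exposure dosimetry.

During a therapy session the wound surface warms both from the animal's own
internal heat transport (present in sham-treated controls) and from the light
source. The irradiative component is isolated by subtracting the control
group's mean warming ("zero-external-heating" reference) and fitting the
saturating exponential

    dT(t) = Ts * [1 - exp(-k * t)]

through the origin, where ``Ts`` (°C) is the long-term steady-state rise and
``k`` (per s) the rate constant. Confidence intervals on ``Ts`` are Wald-type
Student-t intervals from the least-squares covariance at ``n - 2`` df.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DataError, DomainError, FitConvergenceError, InsufficientDataError

__all__ = [
    "ThermalFit",
    "heating_model",
    "control_correct",
    "fit_heating",
    "detect_onset",
    "radiant_exposure",
    "core_temperature_change",
    "ONSET_NOT_DETECTED",
]

logger = logging.getLogger(__name__)

#: sentinel returned by :func:`detect_onset` when the control never deviates
ONSET_NOT_DETECTED = math.inf


def heating_model(t, ts: float, k: float):
    """Saturating irradiative heating ``Ts * (1 - exp(-k*t))`` (through origin)."""
    t = np.asarray(t, dtype=float)
    return ts * (1.0 - np.exp(-k * t))


@dataclass(frozen=True)
class ThermalFit:
    """Fitted steady-state temperature rise with its confidence interval."""

    ts: float        # °C steady-state rise
    k: float         # per s
    ci_low: float    # °C
    ci_high: float   # °C
    level: float     # confidence level of the interval
    n: int
    residual_ss: float
    negative_ts: bool = False  # flagged when the fitted rise is below zero

    def predict(self, t):
        return heating_model(t, self.ts, self.k)


def _baseline_deltas(sessions: pd.DataFrame) -> pd.DataFrame:
    """Per-animal change from the session's first reading."""
    out = sessions.copy()
    deltas = np.empty(len(out), dtype=float)
    for animal, idx in out.groupby("animal_id", sort=False).groups.items():
        sub = out.loc[idx].sort_values("t_s")
        t0 = sub.loc[sub["t_s"] == sub["t_s"].min(), "surface_C"].iloc[0]
        deltas[out.index.get_indexer(idx)] = out.loc[idx, "surface_C"] - t0
    out["delta_C"] = deltas
    return out


def control_correct(treated: pd.DataFrame, control: pd.DataFrame) -> pd.DataFrame:
    """Control-corrected warming of treated animals.

    For each treated reading, ``dT(t)`` is the animal's own rise over its t=0
    reading minus the control-group mean rise at the same time point, so the
    sham arm defines zero external heating and ``dT(0) = 0`` exactly. Both
    tables need ``animal_id, t_s, surface_C`` columns on a shared time grid.
    """
    if control.empty:
        raise DataError("control group is empty")
    if treated.empty:
        raise DataError("treated group is empty")
    ctrl = _baseline_deltas(control)
    ctrl_mean = ctrl.groupby("t_s")["delta_C"].mean()
    trt = _baseline_deltas(treated)
    missing = set(np.unique(trt["t_s"])) - set(ctrl_mean.index)
    if missing:
        raise DataError(
            f"control grid lacks {len(missing)} treated time points (e.g. {sorted(missing)[:3]})"
        )
    trt["delta_T_C"] = trt["delta_C"] - ctrl_mean.reindex(trt["t_s"]).to_numpy()
    return trt.drop(columns=["delta_C"])


def fit_heating(corrected: pd.DataFrame, level: float = 0.95) -> ThermalFit:
    """Least-squares fit of ``Ts*(1-exp(-k*t))`` to corrected dT readings.

    ``corrected`` needs ``t_s`` and ``delta_T_C`` columns (pooled over animals
    is fine). The CI on ``Ts`` uses the t quantile at ``n - 2`` df; a negative
    fitted ``Ts`` is permitted and flagged.
    """
    t = corrected["t_s"].to_numpy(dtype=float)
    y = corrected["delta_T_C"].to_numpy(dtype=float)
    if len(np.unique(t)) < 4:
        raise InsufficientDataError(
            f"need at least 4 time points, got {len(np.unique(t))}"
        )
    tmax = float(t.max())
    y_late = float(np.mean(y[t >= 0.75 * tmax])) if tmax > 0 else 0.0
    ts0 = y_late if abs(y_late) > 1e-12 else 1e-3
    k0 = 3.0 / tmax if tmax > 0 else 0.01
    try:
        popt, pcov = optimize.curve_fit(
            heating_model, t, y, p0=(ts0, k0),
            bounds=([-np.inf, 1e-8], [np.inf, np.inf]), maxfev=10000,
        )
    except RuntimeError as exc:  # pragma: no cover
        raise FitConvergenceError(str(exc)) from exc
    ts, k = float(popt[0]), float(popt[1])
    resid = y - heating_model(t, ts, k)
    rss = float(resid @ resid)
    n = len(t)
    se_ts = float(np.sqrt(max(pcov[0, 0], 0.0))) if np.isfinite(pcov[0, 0]) else 0.0
    tq = stats.t.ppf(0.5 + level / 2.0, max(n - 2, 1))
    return ThermalFit(
        ts=ts, k=k, ci_low=ts - tq * se_ts, ci_high=ts + tq * se_ts,
        level=level, n=n, residual_ss=rss, negative_ts=ts < 0,
    )


def detect_onset(control: pd.DataFrame, tolerance: float = 0.05) -> float:
    """Duration of the control group's flat phase (its internal-heating onset).

    Returns the last grid time at which the control-group mean surface
    temperature is still within ``tolerance`` (°C) of its t=0 mean — i.e. the
    grid point immediately preceding the first exceedance, so a control that
    is unchanged for the first 140 s reports 140. Returns
    :data:`ONSET_NOT_DETECTED` (infinity) when the mean never deviates. With
    ``tolerance=0`` on noisy data this degenerates to the first grid point
    (t=0), since every later reading deviates. Needs >= 2 control animals.
    """
    if control["animal_id"].nunique() < 2:
        raise InsufficientDataError("need at least 2 control animals")
    mean = control.groupby("t_s")["surface_C"].mean().sort_index()
    baseline = float(mean.iloc[0])
    dev = (mean - baseline).abs().to_numpy()
    times = mean.index.to_numpy(dtype=float)
    exceed = np.nonzero(dev > tolerance)[0]
    if exceed.size == 0:
        return ONSET_NOT_DETECTED
    return float(times[max(exceed[0] - 1, 0)])


def radiant_exposure(
    irradiance: float, duration: float, duty_factor: float | None = None
) -> float:
    """Radiant exposure (J/cm²) from irradiance (mW/cm²) and duration (s).

    ``irradiance/1000 * duration``, optionally scaled by a pulsing duty
    factor. The default (no duty factor) matches the usual dosimetry
    convention of quoting the time-averaged target irradiance, so 40 mW/cm²
    over 360 s gives 14.4 J/cm².
    """
    if irradiance < 0:
        raise DomainError(f"irradiance must be >= 0, got {irradiance}")
    if duration < 0:
        raise DomainError(f"duration must be >= 0, got {duration}")
    factor = 1.0
    if duty_factor is not None:
        if not 0 < duty_factor <= 1:
            raise DomainError(f"duty_factor must lie in (0, 1], got {duty_factor}")
        factor = duty_factor
    return irradiance / 1000.0 * duration * factor


def core_temperature_change(sessions: pd.DataFrame) -> pd.DataFrame:
    """Per-animal post−pre core-temperature change and the group summary.

    ``sessions`` needs one row per animal with ``core_pre_C`` and
    ``core_post_C`` (typically the t=0 row of a session table); animals with a
    missing reading are skipped with a logged warning. Returns a one-row
    DataFrame per group with ``n, mean_delta_C, sd_delta_C`` plus the
    per-animal deltas attached as ``deltas``.
    """
    rows = []
    for group, sub in sessions.groupby("group", sort=False):
        per_animal = sub.dropna(subset=["core_pre_C", "core_post_C"]) if {
            "core_pre_C",
            "core_post_C",
        } <= set(sub.columns) else sub.iloc[0:0]
        skipped = sub["animal_id"].nunique() - per_animal["animal_id"].nunique()
        if skipped:
            logger.warning(
                "group %s: skipping %d animal(s) with missing core readings",
                group, skipped,
            )
        deltas = (
            per_animal.groupby("animal_id", sort=False)
            .first()
            .eval("core_post_C - core_pre_C")
            .to_numpy(dtype=float)
        )
        rows.append(
            {
                "group": group,
                "n": len(deltas),
                "mean_delta_C": float(np.mean(deltas)) if len(deltas) else np.nan,
                "sd_delta_C": float(np.std(deltas, ddof=1)) if len(deltas) > 1 else 0.0,
                "deltas": deltas,
            }
        )
    return pd.DataFrame(rows)
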