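"""Whole-body clearance from external probe count-rate series.

After administration the whole-body retention of the radioligand is
monitored with a NaI probe at a fixed geometry; under monoexponential
clearance the log count rate falls linearly with time and the slope gives
the effective whole-body half-life T_eff.  The pooled fit shares one
decay constant across patients while letting each patient keep their own
intercept (different administered activities and geometries); an
alternative mode averages independent per-patient fits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .decay import LN2, decay_factor


class InsufficientDataError(ValueError):
    """Too few time points to constrain a fit."""


@dataclass(frozen=True)
class ProbeMeasurement:
    """One whole-body probe acquisition (net rate, fixed >1 m geometry)."""

    patient_id: str
    time_h: float
    net_rate_cps: float
    duration_s: float = 60.0
    geometry: str = "fixed_gt_1m"

    def __post_init__(self) -> None:
        if self.time_h < 0:
            raise ValueError("measurement time must be non-negative")
        if self.net_rate_cps < 0:
            raise ValueError("net count rate must be non-negative")


@dataclass
class ClearanceFit:
    """Fitted effective whole-body half-life with a 95% CI.

    ``amplitudes`` holds the back-extrapolated t=0 rate per patient (the
    normalisation constant: rate / amplitude is the retained fraction of
    administered activity).  ``scope`` is ``"pooled"`` (shared slope) or
    ``"per_patient"`` (mean of independent fits).
    """

    effective_half_life_h: float
    ci95_h: tuple[float, float]
    amplitudes: dict[str, float]
    scope: str
    residual_sd: float
    n_points: int

    def __post_init__(self) -> None:
        lo, hi = self.ci95_h
        if not (lo < self.effective_half_life_h < hi):
            raise ValueError("CI must bracket the point estimate")


def _as_frame(series: list[ProbeMeasurement]) -> pd.DataFrame:
    if not series:
        raise ValueError("empty probe series")
    df = pd.DataFrame(
        {
            "patient_id": [m.patient_id for m in series],
            "time_h": [m.time_h for m in series],
            "net_rate_cps": [m.net_rate_cps for m in series],
        }
    )
    if (df["net_rate_cps"] <= 0).any():
        raise ValueError("count rates must be positive for log-linear fitting")
    return df


def _fit_loglinear(t: np.ndarray, logr: np.ndarray, groups: np.ndarray):
    """Shared-slope, per-group-intercept OLS of log rate on time.

    Returns (slope, slope_se, dof, intercepts, residual_sd).
    """
    labels = pd.unique(groups)
    X = np.zeros((len(t), len(labels) + 1))
    X[:, 0] = t
    for k, lab in enumerate(labels):
        X[groups == lab, k + 1] = 1.0
    if len(t) <= len(labels) + 1:
        raise InsufficientDataError("need more time points than fitted parameters")
    res = sm.OLS(logr, X).fit()
    slope = res.params[0]
    intercepts = {lab: res.params[k + 1] for k, lab in enumerate(labels)}
    return slope, res.bse[0], res.df_resid, intercepts, math.sqrt(res.scale)


def fit_monoexponential(
    series: list[ProbeMeasurement], scope: str = "pooled"
) -> ClearanceFit:
    """Fit a monoexponential clearance model to probe series.

    Unweighted least squares on log rates.  ``scope="pooled"`` shares one
    decay constant across patients (per-patient intercepts) and derives
    the 95% CI from the t-distribution of the slope, transformed
    monotonically to the half-life scale.  ``scope="per_patient"``
    averages independent per-patient half-lives, with a t-interval over
    the patient means.
    """
    df = _as_frame(series)
    for pid, sub in df.groupby("patient_id"):
        if sub["time_h"].nunique() < 2:
            raise InsufficientDataError(
                f"patient {pid}: at least 2 distinct time points required"
            )

    t = df["time_h"].to_numpy()
    logr = np.log(df["net_rate_cps"].to_numpy())
    groups = df["patient_id"].to_numpy()

    if scope == "pooled":
        slope, se, dof, intercepts, resid_sd = _fit_loglinear(t, logr, groups)
        if slope >= 0:
            raise ValueError("fitted slope is non-negative: no clearance signal")
        tcrit = stats.t.ppf(0.975, dof)
        # monotone (decreasing) transform slope -> T_eff = -ln2/slope
        lo_slope, hi_slope = slope - tcrit * se, slope + tcrit * se
        t_eff = float(-LN2 / slope)
        ci = (float(-LN2 / lo_slope), float(-LN2 / hi_slope)) if hi_slope < 0 else (
            float(-LN2 / lo_slope),
            math.inf,
        )
        amplitudes = {pid: math.exp(a) for pid, a in intercepts.items()}
        return ClearanceFit(t_eff, ci, amplitudes, "pooled", resid_sd, len(df))

    if scope == "per_patient":
        per: dict[str, float] = {}
        amplitudes: dict[str, float] = {}
        resid = []
        for pid, sub in df.groupby("patient_id"):
            tt = sub["time_h"].to_numpy()
            ll = np.log(sub["net_rate_cps"].to_numpy())
            slope, a0 = np.polyfit(tt, ll, 1)
            if slope >= 0:
                raise ValueError(f"patient {pid}: non-negative fitted slope")
            per[pid] = -LN2 / slope
            amplitudes[pid] = math.exp(a0)
            resid.append(ll - (a0 + slope * tt))
        vals = np.array(list(per.values()))
        mean = float(vals.mean())
        if len(vals) > 1:
            half = stats.t.ppf(0.975, len(vals) - 1) * vals.std(ddof=1) / math.sqrt(
                len(vals)
            )
            half = max(half, 1e-12)
            ci = (mean - half, mean + half)
        else:
            ci = (mean - math.inf, mean + math.inf)
        resid_sd = float(np.concatenate(resid).std(ddof=0))
        return ClearanceFit(mean, ci, amplitudes, "per_patient", resid_sd, len(df))

    raise ValueError(f"unknown fit scope {scope!r}")


def normalize_series(
    series: list[ProbeMeasurement], administered_MBq: float
) -> pd.DataFrame:
    """Rescale probe rates to the retained fraction of administered activity.

    Each patient's rates are divided by the back-extrapolated t=0 rate of
    their own log-linear fit, so the fitted curve starts at 1.0.  The
    first measurement must lie within 0.5 h of injection so the
    extrapolation is anchored.  Returns a tidy frame with a
    ``fraction_of_administered`` column and the implied ``activity_MBq``.
    """
    if administered_MBq <= 0:
        raise ValueError("administered activity must be positive")
    df = _as_frame(series)
    if df["time_h"].min() > 0.5:
        raise ValueError("first probe measurement must be within 0.5 h of injection")
    out = []
    for pid, sub in df.groupby("patient_id"):
        slope, a0 = np.polyfit(
            sub["time_h"].to_numpy(), np.log(sub["net_rate_cps"].to_numpy()), 1
        )
        frac = sub["net_rate_cps"].to_numpy() / math.exp(a0)
        block = sub.copy()
        block["fraction_of_administered"] = frac
        block["activity_MBq"] = frac * administered_MBq
        out.append(block)
    return pd.concat(out, ignore_index=True)


def predict_retention(administered_MBq: float, t: float, t_eff: float) -> float:
    """Retained whole-body activity ``administered · 2^(−t/T_eff)`` in MBq."""
    if administered_MBq <= 0:
        raise ValueError("administered activity must be positive")
    return administered_MBq * decay_factor(t_eff, t)


def plan_imaging_schedule(
    t_eff: float, fractions: list[float] | None = None
) -> list[float]:
    """Imaging time points as multiples of the effective half-life.

    The default fractions 1/3, 2/3, 1.5, 3 and 5 bracket the clearance
    curve from early distribution to ~97% cleared; times are reported to
    0.1 h.  An empty fraction list yields an empty schedule.
    """
    if t_eff <= 0:
        raise ValueError("effective half-life must be positive")
    if fractions is None:
        fractions = [1.0 / 3.0, 2.0 / 3.0, 1.5, 3.0, 5.0]
    if any(f <= 0 for f in fractions):
        raise ValueError("fractions must be positive")
    if list(fractions) != sorted(fractions):
        raise ValueError("fractions must be ascending")
    return [round(t_eff * f, 1) for f in fractions]


def read_probe_csv(path) -> list[ProbeMeasurement]:
    """Read a probe series CSV (patient_id,time_h,net_rate_cps[,duration_s])."""
    df = pd.read_csv(path)
    required = {"patient_id", "time_h", "net_rate_cps"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"probe CSV missing columns: {sorted(missing)}")
    return [
        ProbeMeasurement(
            str(r.patient_id),
            float(r.time_h),
            float(r.net_rate_cps),
            float(getattr(r, "duration_s", 60.0)),
        )
        for r in df.itertuples(index=False)
    ]
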