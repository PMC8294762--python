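"""Rate estimation for turbidity and in vitro translation assays.

A condition's phase-separation propensity is the early-phase turbidity slope
(Δ absorbance/min over 0–5 min by default); translation activity is the
least-squares slope of end-point luminescence versus time. Normalization to a
buffer control and an apparent saturation concentration (Csat) from the
rate-vs-concentration profile round out the module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ribodrop.containers import KineticSeries
from ribodrop.errors import FittingError, NormalizationError

TURBIDITY_WINDOW = (0.0, 5.0)


@dataclass
class RateResult:
    """Least-squares slope of signal vs time over a window."""

    rate: float
    intercept: float
    r_squared: float
    window_min: tuple[float, float]
    n_points: int


@dataclass
class CsatEstimate:
    """Apparent saturation concentration from rates vs concentration.

    ``csat`` is the x-intercept of a line fitted to concentrations whose rate
    exceeds the noise floor; ``extrapolated`` flags estimates outside the
    tested concentration range.
    """

    csat: float
    slope_above: float
    fit_points: int
    extrapolated: bool


def fit_rate(series: KineticSeries, window_min: tuple[float, float] | None = None) -> RateResult:
    """Ordinary least-squares slope over the points inside the time window.

    For turbidity the conventional window is the first 5 min; pass ``None``
    to fit the full series (the convention for end-point luminescence, whose
    first read already sits at the end of the initial incubation).
    """
    t, s = series.time_min, series.signal
    if window_min is None:
        lo, hi = float(t[0]), float(t[-1])
    else:
        lo, hi = float(window_min[0]), float(window_min[1])
    keep = (t >= lo) & (t <= hi)
    if keep.sum() < 2:
        raise FittingError(f"fewer than 2 points in window [{lo}, {hi}] min")
    fit = stats.linregress(t[keep], s[keep])
    return RateResult(
        rate=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2) if np.isfinite(fit.rvalue) else 0.0,
        window_min=(lo, hi),
        n_points=int(keep.sum()),
    )


def estimate_csat(
    concentrations,
    rates,
    noise_floor: float | None = None,
) -> CsatEstimate:
    """Apparent Csat as the x-intercept of the supra-threshold rate line.

    Points with rate above the noise floor are fitted linearly in
    (concentration, rate); Csat is ``-intercept / slope``. The default noise
    floor is 3 standard deviations of the replicate rates at the lowest
    tested concentration (0 when that concentration has a single replicate).
    """
    c = np.asarray(concentrations, dtype=float)
    r = np.asarray(rates, dtype=float)
    if c.size != r.size:
        raise FittingError("concentrations and rates must have equal length")
    if c.size < 3:
        raise FittingError("need at least 3 concentrations")
    if (r < 0).any():
        raise FittingError("rates must be non-negative")

    if noise_floor is None:
        lowest = r[c == c.min()]
        noise_floor = 3.0 * float(np.std(lowest, ddof=1)) if lowest.size > 1 else 0.0

    above = r > noise_floor
    if above.sum() < 2:
        raise FittingError("no phase-separation transition: too few rates above the noise floor")
    fit = stats.linregress(c[above], r[above])
    if fit.slope <= 0:
        raise FittingError("non-positive slope above the noise floor; cannot form an x-intercept")
    csat = -fit.intercept / fit.slope
    csat = max(float(csat), 0.0)
    extrapolated = not (float(c.min()) <= csat <= float(c.max()))
    return CsatEstimate(
        csat=csat,
        slope_above=float(fit.slope),
        fit_points=int(above.sum()),
        extrapolated=extrapolated,
    )


def normalize_rates(rates: pd.DataFrame, control: str = "buffer") -> pd.DataFrame:
    """Normalize per-replicate rates to the mean rate of a control condition.

    ``rates`` is a long-format table with columns ``condition`` and ``rate``.
    Each rate is divided by the control's mean rate, so the control condition
    normalizes to 1 on average. Returns a summary with per-condition mean,
    SEM and replicate count of the normalized rates.
    """
    if control not in set(rates["condition"]):
        raise NormalizationError(f"control condition {control!r} not present")
    control_mean = float(rates.loc[rates["condition"] == control, "rate"].mean())
    if control_mean <= 0:
        raise NormalizationError("control mean rate must be positive")
    out = rates.copy()
    out["normalized"] = out["rate"] / control_mean
    summary = (
        out.groupby("condition", sort=False)["normalized"]
        .agg(mean="mean", sem=lambda v: v.sem(ddof=1) if len(v) > 1 else 0.0, n="count")
        .reset_index()
    )
    summary.attrs["control_mean_rate"] = control_mean
    return summary


def fit_plate(
    table: pd.DataFrame,
    mode: str = "turbidity",
    window_min: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Fit one rate per (condition, replicate) from a long-format plate table.

    ``table`` columns: ``condition, replicate, time_min, signal``. Turbidity
    mode defaults to the 0–5 min window; translation mode fits the full
    end-point series.
    """
    if mode not in {"turbidity", "translation"}:
        raise FittingError(f"unknown mode {mode!r}")
    if window_min is None and mode == "turbidity":
        window_min = TURBIDITY_WINDOW
    rows = []
    for (condition, replicate), sub in table.groupby(["condition", "replicate"], sort=False):
        sub = sub.sort_values("time_min")
        series = KineticSeries(
            time_min=sub["time_min"].to_numpy(),
            signal=sub["signal"].to_numpy(),
            condition=str(condition),
            assay="turbidity" if mode == "turbidity" else "luminescence",
        )
        res = fit_rate(series, window_min)
        rows.append(
            {"condition": condition, "replicate": replicate, "rate": res.rate,
             "intercept": res.intercept, "r_squared": res.r_squared,
             "n_points": res.n_points}
        )
    return pd.DataFrame(rows)
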