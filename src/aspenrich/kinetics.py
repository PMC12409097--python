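"""Sigmoidal fitting of molar positional 13C time courses.

A three-parameter logistic

    y(t) = y_max / (1 + exp(-k (t - t_mid)))

is fitted to each position's molar 13C time course by least squares over a
deterministic multi-start grid.  The maximum labelling slope k*y_max/4 is
the maximum carbon assimilation rate (pmol OD750^-1 mL^-1 min^-1) and the
sigmoid midpoint t_mid is the half-max time at which it is reached.  A fit
only classifies as ``sigmoidal`` when the fitted intensity at t = 0 is
essentially zero, the final observation reaches a threshold fraction of the
fitted plateau, and the sigmoid improves on a flat model by a set AIC
margin; otherwise the series is ``ambiguous`` (or ``no_signal`` when there
is nothing above the signal floor).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.optimize

__all__ = ["TimeCourse", "SigmoidalFit", "fit_sigmoid", "rate_table", "logistic"]


def logistic(t, y_max, k, t_mid):
    with np.errstate(over="ignore"):  # exp overflow -> y = 0, numerically fine
        return y_max / (1.0 + np.exp(-k * (np.asarray(t, float) - t_mid)))


@dataclass
class TimeCourse:
    """Molar 13C at one carbon position over time after the label pulse."""

    times_min: np.ndarray
    values: np.ndarray
    replicate_id: str = ""

    def __post_init__(self) -> None:
        self.times_min = np.asarray(self.times_min, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.times_min) != len(self.values):
            raise ValueError("times and values differ in length")
        if np.any(self.times_min < 0):
            raise ValueError("times must be non-negative")
        if np.any(np.diff(self.times_min) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.times_min[0] != 0:
            raise ValueError("time course must include t = 0")


@dataclass
class SigmoidalFit:
    y_max: float
    k: float
    t_mid: float
    max_slope: float
    half_max_time: float
    classification: str  # sigmoidal | ambiguous | no_signal
    aic_delta: float
    rss: float = float("nan")

    @property
    def is_sigmoidal(self) -> bool:
        return self.classification == "sigmoidal"


def _aic(rss: float, n: int, n_params: int) -> float:
    # Gaussian log-likelihood AIC up to a constant; floor rss to avoid
    # log(0) on noise-free data
    return n * np.log(max(rss, 1e-300) / n) + 2 * n_params


def fit_sigmoid(
    tc: TimeCourse,
    threshold_ratio: float = 0.75,
    max_t0_intensity: float = 0.0,
    threshold_aic: float = -10.0,
    t0_tolerance: float = 0.05,
    signal_floor: float = 0.0,
) -> SigmoidalFit:
    """Fit the logistic model to a labelling time course.

    Parameters
    ----------
    threshold_ratio
        The final observed value must reach this fraction of the fitted
        plateau, else the series is classified ``ambiguous``.
    max_t0_intensity, t0_tolerance
        The fitted y(0)/y_max must not exceed ``max_t0_intensity`` by more
        than ``t0_tolerance`` (label is absent before the pulse).
    threshold_aic
        Required AIC improvement of the sigmoid over a flat (constant)
        model; the fit is ``ambiguous`` when AIC_sigmoid - AIC_flat exceeds
        this (negative) threshold.
    signal_floor
        Series whose maximum stays at or below this value are ``no_signal``
        with zero rate.
    """
    if len(tc.times_min) < 5:
        raise ValueError("need at least 5 timepoints")
    t, y = tc.times_min, tc.values
    if np.nanmax(np.abs(y), initial=0.0) <= signal_floor:
        return SigmoidalFit(0.0, 0.0, 0.0, 0.0, 0.0, "no_signal", 0.0, 0.0)

    t_max = t[-1]
    y_max0 = max(float(np.nanmax(y)), 1e-12)
    bounds = ([1e-12, 1e-4, -t_max], [10 * y_max0, 10.0, 2 * t_max])
    # deterministic multi-start grid over curvature and midpoint
    starts = [
        (y_max0, k0, tm0)
        for k0 in (0.01, 0.05, 0.2, 1.0)
        for tm0 in np.quantile(t, (0.25, 0.5, 0.75))
    ]
    best = None
    for p0 in starts:
        try:
            popt, _ = scipy.optimize.curve_fit(
                logistic, t, y, p0=p0, bounds=bounds, maxfev=10000
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(np.sum((logistic(t, *popt) - y) ** 2))
        if best is None or rss < best[1]:
            best = (popt, rss)
    if best is None:
        return SigmoidalFit(
            0.0, 0.0, 0.0, 0.0, 0.0, "ambiguous", float("nan"), float("nan")
        )
    (y_max, k, t_mid), rss = best

    rss_flat = float(np.sum((y - y.mean()) ** 2))
    aic_delta = _aic(rss, len(y), 3) - _aic(rss_flat, len(y), 1)

    classification = "sigmoidal"
    if logistic(0.0, y_max, k, t_mid) / y_max > max_t0_intensity + t0_tolerance:
        classification = "ambiguous"
    elif y[-1] < threshold_ratio * y_max:
        classification = "ambiguous"
    elif aic_delta > threshold_aic:
        classification = "ambiguous"

    return SigmoidalFit(
        y_max=float(y_max),
        k=float(k),
        t_mid=float(t_mid),
        max_slope=float(k * y_max / 4.0),
        half_max_time=float(t_mid),
        classification=classification,
        aic_delta=float(aic_delta),
        rss=rss,
    )


def rate_table(fits: dict[tuple[str, str], list[SigmoidalFit]]):
    """Summarize assimilation rates per (position, condition).

    ``fits`` maps (position label, condition label) to replicate fits.  A
    cell is reported when at least half the replicates classify sigmoidal
    (mean over those replicates); otherwise it is ND (NaN).
    """
    import pandas as pd

    rows = []
    for (position, condition), replicate_fits in sorted(fits.items()):
        good = [f for f in replicate_fits if f.is_sigmoidal]
        detected = replicate_fits and len(good) * 2 >= len(replicate_fits)
        rows.append(
            {
                "position": position,
                "condition": condition,
                "n_replicates": len(replicate_fits),
                "n_sigmoidal": len(good),
                "max_slope": np.mean([f.max_slope for f in good])
                if detected
                else np.nan,
                "half_max_time": np.mean([f.half_max_time for f in good])
                if detected
                else np.nan,
                "detected": bool(detected),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "position", "condition", "n_replicates", "n_sigmoidal",
            "max_slope", "half_max_time", "detected",
        ],
    )
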