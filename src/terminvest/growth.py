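"""Doubling-time estimation from optical-density growth curves.

The maximum specific growth rate of a well is estimated by sliding a
fixed-width window across the log-transformed OD time series, fitting a
regression line in every window, and keeping the window with the largest
slope.  The doubling time is ln(2) divided by that slope, which on the
window endpoints is identical to

    D_t = dt * ln(2) / (ln(N*) - ln(N0))

with N0 and N* the densities at the start and end of the detected
exponential phase and dt its duration.

Plate-reader noise is approximately additive on OD, so after the log
transform its variance blows up as 1/OD^2 at low density: an unweighted
fit lets near-baseline readings dominate, and picking the *maximum*
slope across hundreds of overlapping windows then systematically selects
upward noise excursions.  Three numerical safeguards keep the estimator
honest on noisy plates while reducing exactly to plain max-slope OLS on
clean data:

* the per-window regression is inverse-variance weighted (weight
  proportional to OD^2, the delta-method variance of ln(OD) under
  additive noise), with the noise sd estimated robustly from second
  differences of the OD series;
* windows whose weighted mean OD sits below a multiple of that noise sd
  (an adaptive detection limit) are not eligible as the exponential
  phase;
* among eligible windows the winner maximises the lower confidence
  bound slope - z * se(slope) rather than the raw slope, which removes
  the selection bias toward noise-inflated windows.

On a noiseless curve the estimated noise is zero, every window is
eligible, all standard errors vanish, and the procedure is exactly
"largest slope wins".

Because OD is a biomass proxy, shrinking cells depress OD relative to cell
count and bias the estimated division rate downward.
:func:`od_bias_experiment` quantifies that bias on known count series; no
correction is applied when fitting plates, so count-based growth-rate
increases of shrinking cells are under- rather than over-estimated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import (
    DomainError,
    InsufficientDataError,
    LengthMismatchError,
    MalformedTableError,
    ZeroGrowthError,
)

__all__ = [
    "GrowthCurve",
    "ExponentialFit",
    "ODBiasResult",
    "doubling_time",
    "estimate_od_noise_sd",
    "max_slope_window",
    "fit_plate",
    "od_bias_experiment",
    "DEFAULT_WINDOW_FRAC",
    "MIN_WINDOW_POINTS",
    "DEFAULT_OD_FLOOR",
    "DEFAULT_SELECTION_Z",
    "DEFAULT_DETECTION_K",
]

#: Default window width as a fraction of the usable points of a curve.
DEFAULT_WINDOW_FRAC = 0.125
#: Smallest admissible window, in points.
MIN_WINDOW_POINTS = 5
#: Selection penalty: windows compete on slope - z * se(slope).
DEFAULT_SELECTION_Z = 2.0
#: Windows whose weighted mean OD is below this multiple of the estimated
#: noise sd are not eligible as the exponential phase.
DEFAULT_DETECTION_K = 15.0
#: OD readings at or below this floor are excluded from the log fit.
DEFAULT_OD_FLOOR = 1e-4
#: Slopes whose magnitude is below this (per hour) are treated as zero
#: growth; keeps rounding noise on flat curves from producing absurd
#: finite doubling times.
ZERO_SLOPE_TOL = 1e-12


@dataclass
class GrowthCurve:
    """One well's OD time series with its experimental metadata.

    ``times`` are hours and must be strictly increasing; ``od`` are OD650
    readings of the same length.  At least three points are required.
    """

    well: str
    times: np.ndarray
    od: np.ndarray
    day: int = 0
    treatment: str = ""
    replicate: int = 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.od = np.asarray(self.od, dtype=float)
        if self.times.ndim != 1 or self.od.ndim != 1:
            raise MalformedTableError(f"well {self.well!r}: times and od must be 1-d")
        if len(self.times) != len(self.od):
            raise LengthMismatchError(
                f"well {self.well!r}: {len(self.times)} times vs {len(self.od)} od values"
            )
        if len(self.times) < 3:
            raise InsufficientDataError(f"well {self.well!r}: fewer than 3 points")
        if not np.all(np.diff(self.times) > 0):
            raise MalformedTableError(f"well {self.well!r}: times not strictly increasing")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.od)):
            raise MalformedTableError(f"well {self.well!r}: non-finite values")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class ExponentialFit:
    """The max-slope window of a curve and the doubling time derived from it.

    ``slope`` is the fitted slope of ln(OD) on time (per hour), so it
    equals the specific growth rate over the window.  ``doubling_time`` is
    ln(2)/slope for positive slopes and NaN otherwise (flagged, never
    negative).  Window indices refer to the original curve arrays and are
    inclusive.
    """

    window_start_index: int
    window_end_index: int
    slope: float
    intercept: float
    r_squared: float
    delta_t: float
    n0: float
    n_star: float
    doubling_time: float = field(default=math.nan)

    @property
    def defined(self) -> bool:
        """Whether the doubling time is defined (positive slope)."""
        return math.isfinite(self.doubling_time)


def doubling_time(delta_t: float, n0: float, n_star: float) -> float:
    """Doubling time from densities at the ends of the exponential phase.

    Parameters
    ----------
    delta_t : duration of the exponential phase, hours (> 0).
    n0, n_star : biomass (OD) at the start and end of the phase (> 0).

    Returns
    -------
    ``delta_t * ln(2) / (ln(n_star) - ln(n0))`` in hours; positive iff the
    culture grew (``n_star > n0``).

    Raises
    ------
    ZeroGrowthError
        If ``n_star == n0`` (no net growth, the ratio is undefined).
    DomainError
        If any argument is non-positive.
    """
    if delta_t <= 0:
        raise DomainError(f"delta_t must be > 0, got {delta_t}")
    if n0 <= 0 or n_star <= 0:
        raise DomainError(f"densities must be > 0, got n0={n0}, n_star={n_star}")
    if n_star == n0:
        raise ZeroGrowthError("n_star equals n0: doubling time undefined")
    return delta_t * math.log(2.0) / (math.log(n_star) - math.log(n0))


def estimate_od_noise_sd(od: np.ndarray) -> float:
    """Robust estimate of the additive OD read-noise sd.

    Second differences cancel any locally linear trend, leaving
    ~N(0, 6 sd^2) noise plus a curvature term that is negligible on
    plate-reader grids; the median absolute value scaled by
    1.4826/sqrt(6) is then a robust sd estimate that returns exactly 0
    for noiseless piecewise-flat/linear stretches.
    """
    if len(od) < 3:
        return 0.0
    d2 = od[2:] - 2.0 * od[1:-1] + od[:-2]
    return float(1.4826 * np.median(np.abs(d2)) / math.sqrt(6.0))


def _windowed_wls(times: np.ndarray, od: np.ndarray, width: int, sd_od: float):
    """Weighted regression of ln(OD) on time for every contiguous window.

    Weights are the delta-method inverse variances od^2 / sd^2; with
    sd = 0 the weights are uniform and this is ordinary least squares.
    Returns per-window slope, intercept, weighted R^2, model-based
    se(slope) and weighted mean OD, indexed by window start.
    """
    y = np.log(od)
    sig = sd_od / od if sd_od > 0 else np.full_like(od, 1.0)
    w = 1.0 / sig**2
    tw = np.lib.stride_tricks.sliding_window_view(times, width)
    yw = np.lib.stride_tricks.sliding_window_view(y, width)
    ww = np.lib.stride_tricks.sliding_window_view(w, width)
    ow = np.lib.stride_tricks.sliding_window_view(od, width)
    wsum = ww.sum(axis=1)
    wn = ww / wsum[:, None]
    tbar = np.einsum("ij,ij->i", wn, tw)
    ybar = np.einsum("ij,ij->i", wn, yw)
    tc = tw - tbar[:, None]
    yc = yw - ybar[:, None]
    stt = np.einsum("ij,ij,ij->i", ww, tc, tc)
    sty = np.einsum("ij,ij,ij->i", ww, tc, yc)
    syy = np.einsum("ij,ij,ij->i", ww, yc, yc)
    slopes = sty / stt
    intercepts = ybar - slopes * tbar
    ss_res = np.maximum(syy - slopes * sty, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, 1.0 - ss_res / syy, 1.0)
    # exact sampling sd of the WLS slope when weights are true inverse
    # variances; identically 0 in the noiseless limit
    se = (1.0 / np.sqrt(stt)) if sd_od > 0 else np.zeros_like(slopes)
    mean_od = np.einsum("ij,ij->i", wn, ow)
    return slopes, intercepts, np.clip(r2, 0.0, 1.0), se, mean_od


def max_slope_window(
    curve: GrowthCurve,
    window_points: int,
    floor: float = 0.0,
    selection_z: float = DEFAULT_SELECTION_Z,
    detection_k: float = DEFAULT_DETECTION_K,
) -> ExponentialFit:
    """Detect the exponential phase as the window of maximal log-OD slope.

    OD values at or below ``floor`` (and never above zero readings) are
    excluded before the log transform; windows slide over the remaining
    points.  Windows whose weighted mean OD falls below ``detection_k``
    times the estimated read noise are not eligible (adaptive detection
    limit; if no window qualifies, all compete), and among eligible
    windows the one maximising ``slope - selection_z * se`` wins.  On
    noiseless data every window is eligible with zero se, so the winner
    is simply the largest slope; ties are broken by the earliest window
    start so the result is deterministic.

    Raises
    ------
    InsufficientDataError
        If fewer usable points remain than ``window_points``.
    DomainError
        If ``window_points`` < 3.
    """
    if window_points < 3:
        raise DomainError(f"window_points must be >= 3, got {window_points}")
    usable = np.flatnonzero(curve.od > max(floor, 0.0))
    if len(usable) < window_points:
        raise InsufficientDataError(
            f"well {curve.well!r}: {len(usable)} usable points < window of {window_points}"
        )
    t = curve.times[usable]
    od = curve.od[usable]
    sd_od = estimate_od_noise_sd(od)
    slopes, intercepts, r2, se, mean_od = _windowed_wls(t, od, window_points, sd_od)
    criterion = slopes - selection_z * se
    eligible = mean_od >= detection_k * sd_od
    if eligible.any():
        criterion = np.where(eligible, criterion, -np.inf)
    # earliest window within rounding tolerance of the maximum: exact-tie
    # plateaus (e.g. a noiseless exponential) resolve deterministically
    crit_max = criterion.max()
    tol = 1e-9 * max(1.0, abs(crit_max))
    best = int(np.argmax(criterion >= crit_max - tol))
    start = int(usable[best])
    end = int(usable[best + window_points - 1])
    slope = float(slopes[best])
    dt = math.log(2.0) / slope if slope > ZERO_SLOPE_TOL else math.nan
    return ExponentialFit(
        window_start_index=start,
        window_end_index=end,
        slope=slope,
        intercept=float(intercepts[best]),
        r_squared=float(r2[best]),
        delta_t=float(curve.times[end] - curve.times[start]),
        n0=float(curve.od[start]),
        n_star=float(curve.od[end]),
        doubling_time=dt,
    )


_GROWTH_COLUMNS = ["well", "day", "treatment", "replicate", "time_h", "od650"]


def curves_from_table(table: pd.DataFrame) -> list[GrowthCurve]:
    """Split a long-format growth table into :class:`GrowthCurve` objects."""
    missing = [c for c in _GROWTH_COLUMNS if c not in table.columns]
    if missing:
        raise MalformedTableError(f"growth table missing columns: {missing}")
    if table[["time_h", "od650"]].isna().any().any():
        bad = table.loc[table[["time_h", "od650"]].isna().any(axis=1), "well"].unique()
        raise MalformedTableError(f"missing values in wells: {sorted(map(str, bad))}")
    curves = []
    for (well, day, treatment, rep), grp in table.groupby(
        ["well", "day", "treatment", "replicate"], sort=True
    ):
        grp = grp.sort_values("time_h")
        curves.append(
            GrowthCurve(
                well=str(well),
                times=grp["time_h"].to_numpy(float),
                od=grp["od650"].to_numpy(float),
                day=int(day),
                treatment=str(treatment),
                replicate=int(rep),
            )
        )
    return curves


def fit_plate(
    table: pd.DataFrame,
    window_points: int | None = None,
    window_frac: float = DEFAULT_WINDOW_FRAC,
    floor: float = DEFAULT_OD_FLOOR,
) -> tuple[pd.DataFrame, list[dict]]:
    """Fit every curve of a plate and tabulate doubling times.

    Parameters
    ----------
    table : long-format growth table with columns
        ``well, day, treatment, replicate, time_h, od650``.
    window_points : window width in points; when None, 10% of each curve's
        usable points with a minimum of 5.
    floor : OD values at or below this are excluded from the log fit.

    Returns
    -------
    (dt_table, diagnostics)
        ``dt_table`` has columns ``Day, Phages, dt`` (one row per curve, in
        well order; undefined doubling times are NaN, flagged in the
        diagnostics, never dropped).  ``diagnostics`` is a list of per-curve
        dicts with the well id, window indices, slope, r_squared and a
        ``flagged`` boolean.
    """
    curves = curves_from_table(table)
    rows = []
    diagnostics = []
    for curve in curves:
        usable = int(np.count_nonzero(curve.od > max(floor, 0.0)))
        width = window_points or max(MIN_WINDOW_POINTS, round(window_frac * usable))
        diag = {
            "well": curve.well,
            "day": curve.day,
            "treatment": curve.treatment,
            "replicate": curve.replicate,
            "window_points": width,
        }
        try:
            fit = max_slope_window(curve, width, floor=floor)
        except InsufficientDataError as exc:
            # e.g. an empty/all-baseline well: flag the row, keep the rest
            rows.append({"Day": curve.day, "Phages": curve.treatment, "dt": math.nan})
            diagnostics.append({**diag, "flagged": True, "reason": str(exc)})
            continue
        rows.append({"Day": curve.day, "Phages": curve.treatment, "dt": fit.doubling_time})
        diagnostics.append(
            {
                **diag,
                "window_start_index": fit.window_start_index,
                "window_end_index": fit.window_end_index,
                "slope": fit.slope,
                "r_squared": fit.r_squared,
                "doubling_time": fit.doubling_time,
                "flagged": not fit.defined,
            }
        )
    return pd.DataFrame(rows, columns=["Day", "Phages", "dt"]), diagnostics


@dataclass
class ODBiasResult:
    """Outcome of the OD-vs-cell-size bias diagnostic."""

    observed_od: np.ndarray
    fit_true: ExponentialFit
    fit_observed: ExponentialFit

    @property
    def dt_true(self) -> float:
        return self.fit_true.doubling_time

    @property
    def dt_observed(self) -> float:
        return self.fit_observed.doubling_time


def od_bias_experiment(
    times: Sequence[float],
    true_counts: Sequence[float],
    size_scale: Sequence[float],
    window_points: int | None = None,
) -> ODBiasResult:
    """Quantify how shrinking cells bias OD-based doubling times.

    OD is proportional to cell count times mean optical cross-section, so
    the observed series is ``count * size_scale`` (unit proportionality
    constant).  Both the count series and the observed OD series are run
    through the same max-slope estimator; for any strictly decreasing
    ``size_scale`` the observed doubling time is at least the true one —
    the count (and hence division rate) of shrinking cells is
    underestimated.

    Raises
    ------
    LengthMismatchError
        If the three sequences differ in length.
    DomainError
        If counts or scale factors are not all positive.
    """
    times = np.asarray(times, dtype=float)
    counts = np.asarray(true_counts, dtype=float)
    scale = np.asarray(size_scale, dtype=float)
    if not (len(times) == len(counts) == len(scale)):
        raise LengthMismatchError(
            f"lengths differ: times {len(times)}, counts {len(counts)}, scale {len(scale)}"
        )
    if np.any(counts <= 0) or np.any(scale <= 0):
        raise DomainError("counts and size_scale must be positive")
    observed = counts * scale
    width = window_points or max(MIN_WINDOW_POINTS, round(DEFAULT_WINDOW_FRAC * len(times)))
    fit_true = max_slope_window(GrowthCurve("counts", times, counts), width)
    # constant observed series has slope 0 -> doubling time flagged undefined
    fit_obs = max_slope_window(GrowthCurve("observed", times, observed), width)
    return ODBiasResult(observed_od=observed, fit_true=fit_true, fit_observed=fit_obs)
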