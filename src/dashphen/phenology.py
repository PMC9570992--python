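"""Greenness time series smoothing and transition-date estimation.

A season of per-frame GCC values is a gappy daily series: one value per
captured day, with days lost to capture failure simply absent. The series is
smoothed with a centred calendar-window rolling mean and the start of the
leaf-on season (green-up) is estimated either by the amplitude-threshold
convention of the fixed-phenocam literature -- the first sustained crossing
of baseline + 10% of the seasonal amplitude -- or by a logistic fit.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "GCCSeries",
    "PhenologyEstimate",
    "DateComparison",
    "NoSeasonalSignalError",
    "rolling_mean",
    "estimate_green_up",
    "compare_dates",
]


class NoSeasonalSignalError(ValueError):
    """The series' seasonal amplitude is below the detection floor."""


@dataclass
class GCCSeries:
    """Date-indexed GCC observations for one tree.

    Dates are strictly increasing and unique; calendar gaps are allowed.
    NaN values mark dates that are present but masked (e.g. smoothed values
    supported by too few observations).
    """

    tree_id: str
    data: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        s = pd.Series(self.data, dtype=float)
        s.index = pd.DatetimeIndex(s.index)
        if s.index.has_duplicates:
            raise ValueError("duplicate dates in series")
        if not s.index.is_monotonic_increasing:
            s = s.sort_index()
        vals = s.dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError("gcc values must lie in [0, 1]")
        self.data = s

    @classmethod
    def from_observations(
        cls, tree_id: str, observations: list[tuple[dt.date, float]]
    ) -> "GCCSeries":
        dates, values = zip(*observations) if observations else ((), ())
        return cls(tree_id, pd.Series(list(values), index=pd.DatetimeIndex(dates)))

    def valid(self) -> pd.Series:
        """Observations with a value (NaN-masked dates dropped)."""
        return self.data.dropna()

    def __len__(self) -> int:
        return len(self.data)


@dataclass(frozen=True)
class PhenologyEstimate:
    """Green-up (and optionally plateau) date for one tree.

    ``baseline`` and ``amplitude`` are on the GCC scale of the input series;
    ``t0`` and ``rate`` are populated by the logistic method only.
    """

    tree_id: str
    green_up_date: dt.date
    plateau_date: dt.date | None
    baseline: float
    amplitude: float
    method: str
    threshold_fraction: float
    t0: float | None = None
    rate: float | None = None


@dataclass(frozen=True)
class DateComparison:
    """Per-tree signed date differences (estimated - reference) in whole days."""

    per_tree: pd.DataFrame
    max_abs_days: int


def rolling_mean(
    series: GCCSeries, window_days: int = 3, min_obs: int = 2
) -> GCCSeries:
    """Centred calendar-window rolling mean of a gappy daily series.

    Each output date ``d`` carries the mean of the observations whose dates
    fall in the calendar window ``[d - (w-1)//2, d + w//2]`` (for the default
    window of 3 days: ``[d-1, d+1]``). Calendar gaps widen the effective
    sample -- missing days contribute nothing and are never imputed. Output
    covers every calendar day from the first to the last observation; days
    supported by fewer than ``min_obs`` observations are emitted as NaN.
    """
    if window_days < 1:
        raise ValueError(f"window_days must be >= 1, got {window_days}")
    if min_obs < 1:
        raise ValueError(f"min_obs must be >= 1, got {min_obs}")
    obs = series.valid()
    if obs.empty:
        raise ValueError("empty series")
    full = pd.date_range(obs.index.min(), obs.index.max(), freq="D")
    back = (window_days - 1) // 2
    fwd = window_days // 2
    values = np.full(len(full), np.nan)
    for i, d in enumerate(full):
        window = obs[(obs.index >= d - pd.Timedelta(days=back)) & (obs.index <= d + pd.Timedelta(days=fwd))]
        if len(window) >= min_obs:
            values[i] = window.mean()
    return GCCSeries(series.tree_id, pd.Series(values, index=full))


def _first_sustained_crossing(
    obs: pd.Series, level: float, persistence: int
) -> dt.date | None:
    """First date whose value exceeds ``level`` with the next ``persistence - 1``
    valid observations also above it."""
    vals = obs.to_numpy()
    above = vals > level
    for i in range(len(vals)):
        if above[i] and i + persistence <= len(vals) and above[i : i + persistence].all():
            return obs.index[i].date()
    return None


def _logistic(t, baseline, amplitude, k, t0):
    return baseline + amplitude / (1.0 + np.exp(-k * (t - t0)))


def estimate_green_up(
    series: GCCSeries,
    method: str = "threshold",
    threshold_fraction: float = 0.10,
    baseline_days: int = 5,
    persistence: int = 3,
    plateau_fraction: float = 0.90,
    amplitude_floor: float = 0.02,
) -> PhenologyEstimate:
    """Estimate the start of the leaf-on season from a smoothed GCC series.

    Threshold method (default): the baseline is the mean of the first
    ``baseline_days`` valid values, the ceiling the 95th percentile of all
    valid values, and green-up the first date exceeding
    ``baseline + threshold_fraction * amplitude`` that is followed by at
    least ``persistence - 1`` further consecutive valid observations above
    the same level. The persistence guard prevents a single bright-morning
    spike from triggering green-up. The plateau date is the analogous
    sustained crossing at ``plateau_fraction`` of the amplitude, or ``None``
    when greenness is still rising at the end of the series.

    Logistic method: least-squares fit of
    ``baseline + amplitude / (1 + exp(-k (t - t0)))``; the green-up date is
    the analytic crossing ``t0 - ln((1-f)/f)/k`` with
    ``f = threshold_fraction``. A fit that fails to converge falls back to
    the threshold method with a warning.

    The input is expected to be smoothed already (see :func:`rolling_mean`).
    """
    obs = series.valid()
    if len(obs) < 10:
        raise ValueError(f"need >= 10 valid observations, got {len(obs)}")
    span = (obs.index.max() - obs.index.min()).days
    if span < 20:
        raise ValueError(f"series must span >= 20 days, got {span}")
    if not 0.0 < threshold_fraction < 1.0:
        raise ValueError("threshold_fraction must be in (0, 1)")

    if method == "logistic":
        t = (obs.index - obs.index.min()).days.to_numpy(dtype=float)
        y = obs.to_numpy()
        ymin, ymax = float(y.min()), float(y.max())
        half = ymin + 0.5 * (ymax - ymin)
        t0_guess = float(t[np.argmin(np.abs(y - half))])
        p0 = [ymin, max(ymax - ymin, 1e-3), 0.2, t0_guess]
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                popt, _ = curve_fit(
                    _logistic,
                    t,
                    y,
                    p0=p0,
                    bounds=([0.0, 0.0, 1e-4, t.min() - 60], [1.0, 1.0, 5.0, t.max() + 60]),
                    maxfev=20000,
                )
        except (RuntimeError, ValueError):
            warnings.warn("logistic fit did not converge; falling back to threshold method")
            return estimate_green_up(
                series,
                method="threshold",
                threshold_fraction=threshold_fraction,
                baseline_days=baseline_days,
                persistence=persistence,
                plateau_fraction=plateau_fraction,
                amplitude_floor=amplitude_floor,
            )
        baseline, amplitude, k, t0 = (float(v) for v in popt)
        if amplitude < amplitude_floor:
            raise NoSeasonalSignalError(
                f"fitted amplitude {amplitude:.4f} below floor {amplitude_floor}"
            )
        f = threshold_fraction
        t_cross = t0 - math.log((1 - f) / f) / k
        green_up = (obs.index.min() + pd.Timedelta(days=round(t_cross))).date()
        g = plateau_fraction
        t_plat = t0 - math.log((1 - g) / g) / k
        plateau: dt.date | None = (obs.index.min() + pd.Timedelta(days=round(t_plat))).date()
        first, last = obs.index.min().date(), obs.index.max().date()
        if not first <= green_up <= last:
            raise NoSeasonalSignalError(
                f"fitted green-up {green_up} falls outside the observed season"
            )
        if plateau is not None and not first <= plateau <= last:
            plateau = None
        return PhenologyEstimate(
            tree_id=series.tree_id,
            green_up_date=green_up,
            plateau_date=plateau,
            baseline=baseline,
            amplitude=amplitude,
            method="logistic",
            threshold_fraction=threshold_fraction,
            t0=t0,
            rate=k,
        )

    if method != "threshold":
        raise ValueError(f"method must be 'threshold' or 'logistic', got {method!r}")

    baseline = float(obs.iloc[:baseline_days].mean())
    ceiling = float(np.percentile(obs.to_numpy(), 95))
    amplitude = ceiling - baseline
    if amplitude < amplitude_floor:
        raise NoSeasonalSignalError(
            f"seasonal amplitude {amplitude:.4f} below floor {amplitude_floor}: no signal"
        )
    level = baseline + threshold_fraction * amplitude
    green_up = _first_sustained_crossing(obs, level, persistence)
    if green_up is None:
        raise NoSeasonalSignalError("no sustained crossing of the green-up threshold")
    plateau = _first_sustained_crossing(obs, baseline + plateau_fraction * amplitude, persistence)
    return PhenologyEstimate(
        tree_id=series.tree_id,
        green_up_date=green_up,
        plateau_date=plateau,
        baseline=baseline,
        amplitude=amplitude,
        method="threshold",
        threshold_fraction=threshold_fraction,
    )


def compare_dates(
    estimates: list,
    references: list[tuple[str, dt.date]],
) -> DateComparison:
    """Signed per-tree differences between estimated and reference dates.

    ``estimates`` may be :class:`PhenologyEstimate` objects or plain
    ``(tree_id, date)`` pairs. The difference is estimated minus reference in
    whole days; the maximum absolute difference is reported alongside.
    """
    est_map: dict[str, dt.date] = {}
    for e in estimates:
        if isinstance(e, PhenologyEstimate):
            est_map[e.tree_id] = e.green_up_date
        else:
            tree_id, date = e
            est_map[tree_id] = date
    ref_map = dict(references)
    missing = sorted(set(ref_map) ^ set(est_map))
    if missing:
        raise ValueError(f"unmatched tree_id(s): {', '.join(missing)}")
    rows = []
    for tree_id in ref_map:
        diff = (est_map[tree_id] - ref_map[tree_id]).days
        rows.append(
            {
                "tree_id": tree_id,
                "estimated": est_map[tree_id],
                "reference": ref_map[tree_id],
                "difference_days": diff,
            }
        )
    df = pd.DataFrame(rows)
    return DateComparison(per_tree=df, max_abs_days=int(df["difference_days"].abs().max()))
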