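"""Thermally "potential" activity from preference and operative temperature.

The chain implemented here mirrors how thermal-constraint activity models
are built for ectotherms:

1. fit the selected body temperature (T_b) preference with a
   Pearson-system density (:func:`dieloverlap.pearson.fit_pearson`);
2. rescale that density to a 0-1 *activity probability* as a function of
   temperature (:func:`activity_probability`);
3. average the operative temperature (T_o) loggers into 288 five-minute
   time-of-day bins (:func:`aggregate_to`);
4. resample bin midpoints with replacement, weighting each bin by the
   activity probability at its mean T_o (:func:`potential_activity`).

The resampled times form the *potential* activity distribution: when the
animal could be out, based on thermal suitability alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circular import CircularSample, hours_to_angle
from .errors import EstimationError, InputError
from .pearson import ThermalPreferenceFit

__all__ = [
    "OperativeTempSeries",
    "ActivityProbabilityCurve",
    "activity_probability",
    "aggregate_to",
    "potential_activity",
    "N_BINS",
    "BIN_MINUTES",
]

BIN_MINUTES = 5
N_BINS = 24 * 60 // BIN_MINUTES  # 288


@dataclass(frozen=True)
class OperativeTempSeries:
    """Mean operative temperature per 5-min time-of-day bin.

    ``mean_to[i]`` is the mean over all records (all loggers, all days,
    selected micro-environments) whose clock time falls in the half-open
    bin ``[5i, 5(i+1))`` minutes after midnight; NaN marks an empty bin.
    """

    mean_to: np.ndarray
    n_records: np.ndarray
    microenvs_included: tuple[str, ...] = ()

    def __post_init__(self):
        m = np.asarray(self.mean_to, dtype=float)
        n = np.asarray(self.n_records, dtype=int)
        if m.shape != (N_BINS,) or n.shape != (N_BINS,):
            raise InputError(f"series must have exactly {N_BINS} bins")
        if np.any((n == 0) != np.isnan(m)):
            raise InputError("bins with no records must be NaN and vice versa")
        object.__setattr__(self, "mean_to", m)
        object.__setattr__(self, "n_records", n)
        object.__setattr__(self, "microenvs_included", tuple(self.microenvs_included))

    @property
    def bin_mid_hours(self) -> np.ndarray:
        return (np.arange(N_BINS) + 0.5) * BIN_MINUTES / 60.0


@dataclass(frozen=True)
class ActivityProbabilityCurve:
    """Thermal activity probability: fitted T_b density rescaled to max 1."""

    temps: np.ndarray
    prob: np.ndarray
    peak_temp: float = field(default=np.nan)

    def __post_init__(self):
        t = np.asarray(self.temps, dtype=float)
        p = np.asarray(self.prob, dtype=float)
        if t.shape != p.shape or t.ndim != 1 or t.size < 2:
            raise InputError("temps and prob must be matching 1-d arrays")
        if np.any(p < 0) or not np.isclose(p.max(), 1.0, atol=1e-9):
            raise InputError("prob must be nonnegative with maximum exactly 1")
        object.__setattr__(self, "temps", t)
        object.__setattr__(self, "prob", p)
        if np.isnan(self.peak_temp):
            object.__setattr__(self, "peak_temp", float(t[np.argmax(p)]))

    def at(self, temps) -> np.ndarray:
        """Probability interpolated at arbitrary temperatures.

        Temperatures outside the tabulated range get probability zero, so
        operative temperatures far from the preferred range never acquire
        spurious edge weight.
        """
        return np.interp(
            np.asarray(temps, dtype=float), self.temps, self.prob,
            left=0.0, right=0.0,
        )


def activity_probability(
    fit: ThermalPreferenceFit, temp_grid
) -> ActivityProbabilityCurve:
    """Rescale a fitted preference density to a 0-1 activity probability."""
    grid = np.asarray(temp_grid, dtype=float)
    dens = fit.pdf(grid)
    peak = dens.max()
    if peak <= 0:
        raise EstimationError(
            "fitted density is zero on the whole temperature grid: "
            "grid and support do not intersect"
        )
    return ActivityProbabilityCurve(temps=grid, prob=dens / peak)


def aggregate_to(records: pd.DataFrame, microenvs=None) -> OperativeTempSeries:
    """Pool raw logger records into per-5-min-bin mean operative temperature.

    Parameters
    ----------
    records : DataFrame
        Columns ``timestamp`` (datetime-like) and ``temp_c``; a
        ``microenv`` column is required when ``microenvs`` is given.
    microenvs : iterable of str, optional
        Restrict pooling to these micro-environments (default: all).
    """
    if records is None or len(records) == 0:
        raise InputError("no operative-temperature records supplied")
    df = records.copy()
    if microenvs is not None:
        sel = list(microenvs)
        df = df[df["microenv"].isin(sel)]
        if len(df) == 0:
            raise InputError(f"no records in micro-environments {sel}")
        included = tuple(sorted(set(sel) & set(records["microenv"].unique())))
    else:
        included = tuple(sorted(df["microenv"].unique())) if "microenv" in df else ()
    ts = pd.to_datetime(df["timestamp"])
    minutes = ts.dt.hour * 60 + ts.dt.minute + ts.dt.second / 60.0
    bins = (minutes // BIN_MINUTES).astype(int).clip(0, N_BINS - 1)
    temps = pd.to_numeric(df["temp_c"])
    if not np.all(np.isfinite(temps)):
        raise InputError("non-finite operative temperatures in input")
    grouped = temps.groupby(bins.values)
    mean_to = np.full(N_BINS, np.nan)
    n_records = np.zeros(N_BINS, dtype=int)
    mean_to[grouped.mean().index] = grouped.mean().values
    n_records[grouped.count().index] = grouped.count().values
    return OperativeTempSeries(
        mean_to=mean_to, n_records=n_records, microenvs_included=included
    )


def potential_activity(
    series: OperativeTempSeries,
    curve: ActivityProbabilityCurve,
    n_out: int,
    seed: int | None = None,
    site: str = "",
    jitter: bool = False,
) -> CircularSample:
    """Resample times of day weighted by thermal activity probability.

    Each 5-min bin's weight is the activity probability at the bin's mean
    operative temperature (zero for bins with no records); ``n_out`` bin
    midpoints are drawn with replacement proportionally to these weights.
    With ``jitter=True`` a uniform within-bin offset is added.
    """
    if n_out < 1:
        raise InputError("n_out must be >= 1")
    weights = np.where(
        np.isnan(series.mean_to), 0.0, curve.at(np.nan_to_num(series.mean_to))
    )
    total = weights.sum()
    if total <= 0:
        raise EstimationError(
            "all bin weights are zero: operative temperatures never reach "
            "the preferred range (thermal mismatch)"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(N_BINS, size=n_out, replace=True, p=weights / total)
    hours = series.bin_mid_hours[idx]
    if jitter:
        hours = hours + rng.uniform(-0.5, 0.5, size=n_out) * (BIN_MINUTES / 60.0)
    return CircularSample(hours_to_angle(hours), site=site, role="potential")
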