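"""Piecewise-constant aqueous exposure schedules.

An :class:`ExposureSchedule` is the forcing function of the one-compartment
model: the exposure duration is divided into renewal intervals, and the
dissolved metal concentration is held constant within each interval
``[T_j, T_{j+1})``.  Intervals are half-open on the right; an evaluation
exactly at a renewal time belongs to the interval that starts there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import BiodynError

__all__ = ["ExposureSchedule"]


@dataclass(frozen=True)
class ExposureSchedule:
    """Renewal times and per-interval dissolved concentrations.

    Parameters
    ----------
    renewal_times : array-like of float
        Start time of each interval, in days, strictly increasing.  The
        first entry is the start of the exposure (``T_0``).
    interval_concentrations : array-like of float
        Dissolved water concentration (ug/L) held constant over each
        interval; one value per renewal time.
    horizon : float
        End of the exposure (days); closes the last interval.
    """

    renewal_times: np.ndarray
    interval_concentrations: np.ndarray
    horizon: float

    def __init__(self, renewal_times, interval_concentrations, horizon):
        times = np.asarray(renewal_times, dtype=float)
        concs = np.asarray(interval_concentrations, dtype=float)
        if times.ndim != 1 or times.size == 0:
            raise BiodynError("renewal_times must be a non-empty 1-d sequence")
        if np.any(np.diff(times) <= 0):
            raise BiodynError("renewal_times must be strictly increasing")
        if concs.shape != times.shape:
            raise BiodynError(
                "need exactly one concentration per interval: "
                f"{concs.size} concentrations for {times.size} intervals"
            )
        if np.any(concs < 0):
            raise BiodynError("interval concentrations must be >= 0")
        horizon = float(horizon)
        if horizon < times[-1]:
            raise BiodynError("horizon must be >= the last renewal time")
        times.setflags(write=False)
        concs.setflags(write=False)
        object.__setattr__(self, "renewal_times", times)
        object.__setattr__(self, "interval_concentrations", concs)
        object.__setattr__(self, "horizon", horizon)

    # -- construction helpers -------------------------------------------------

    @classmethod
    def regular(cls, n_days: float, renewal_every: float, concentrations) -> "ExposureSchedule":
        """Schedule with equally spaced renewals starting at t=0."""
        starts = np.arange(0.0, n_days, renewal_every)
        return cls(starts, concentrations, n_days)

    @classmethod
    def constant(cls, cw: float, n_days: float) -> "ExposureSchedule":
        """Single-interval schedule at a fixed concentration."""
        return cls([0.0], [cw], n_days)

    # -- interval arithmetic --------------------------------------------------

    @property
    def n_intervals(self) -> int:
        return self.renewal_times.size

    @property
    def start(self) -> float:
        return float(self.renewal_times[0])

    @property
    def interval_edges(self) -> np.ndarray:
        """All interval boundaries, including the horizon."""
        return np.append(self.renewal_times, self.horizon)

    def interval_index(self, t) -> np.ndarray:
        """Index of the interval containing each time (half-open on the right).

        ``t == horizon`` is mapped to the final interval so that the terminal
        concentration is evaluable.
        """
        t = np.asarray(t, dtype=float)
        if np.any(t < self.start) or np.any(t > self.horizon):
            raise BiodynError(
                f"evaluation times must lie within [{self.start}, {self.horizon}]"
            )
        idx = np.searchsorted(self.renewal_times, t, side="right") - 1
        return idx

    def concentration_at(self, t) -> np.ndarray:
        """Dissolved concentration (ug/L) at each time."""
        return self.interval_concentrations[self.interval_index(t)]

    def refined(self, factor: int) -> "ExposureSchedule":
        """Split every interval into `factor` equal sub-intervals.

        The forcing function is unchanged; only the grid is finer.  Used to
        study convergence of piecewise approximations.
        """
        if factor < 1:
            raise BiodynError("refinement factor must be >= 1")
        edges = self.interval_edges
        starts, concs = [], []
        for j in range(self.n_intervals):
            sub = np.linspace(edges[j], edges[j + 1], factor, endpoint=False)
            starts.extend(sub)
            concs.extend([self.interval_concentrations[j]] * factor)
        return ExposureSchedule(starts, concs, self.horizon)

    # -- I/O ------------------------------------------------------------------

    @classmethod
    def from_csv(cls, path, convention: str = "mean") -> "ExposureSchedule":
        """Read a renewal table (columns ``time_d``, ``cw_before_ugL``,
        ``cw_after_ugL``; either concentration column may be absent).

        Each row is a renewal event; the final row closes the exposure
        (its ``cw_after_ugL`` is ignored if present).  When both pre- and
        post-renewal measurements are available, the per-interval value is
        their arithmetic mean (``convention="mean"``, the default) or the
        post-renewal value alone (``convention="post"``).
        """
        df = pd.read_csv(path, comment="#")
        return cls.from_renewal_table(df, convention=convention)

    @classmethod
    def from_renewal_table(cls, df: pd.DataFrame, convention: str = "mean") -> "ExposureSchedule":
        if "time_d" not in df.columns:
            raise BiodynError("exposure table needs a time_d column")
        has_before = "cw_before_ugL" in df.columns
        has_after = "cw_after_ugL" in df.columns
        if not (has_before or has_after):
            raise BiodynError("exposure table needs cw_before_ugL and/or cw_after_ugL")
        times = df["time_d"].to_numpy(dtype=float)
        if times.size < 2:
            raise BiodynError("exposure table needs at least two rows (start and end)")
        starts, horizon = times[:-1], times[-1]
        if has_after and has_before:
            post = df["cw_after_ugL"].to_numpy(dtype=float)[:-1]
            pre_next = df["cw_before_ugL"].to_numpy(dtype=float)[1:]
            if convention == "mean":
                concs = np.where(np.isnan(pre_next), post, 0.5 * (post + pre_next))
            elif convention == "post":
                concs = post
            else:
                raise BiodynError(f"unknown forcing convention {convention!r}")
        elif has_after:
            concs = df["cw_after_ugL"].to_numpy(dtype=float)[:-1]
        else:
            # only pre-renewal measurements: the value measured at T_{j+1}
            # characterises interval j
            concs = df["cw_before_ugL"].to_numpy(dtype=float)[1:]
        return cls(starts, concs, horizon)

    def to_frame(self) -> pd.DataFrame:
        """Renewal table with post-renewal concentrations only."""
        times = self.interval_edges
        after = np.append(self.interval_concentrations, np.nan)
        return pd.DataFrame({"time_d": times, "cw_after_ugL": after})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)
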