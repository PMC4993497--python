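"""Calibration of growth and uptake rate constants from time series.

Model classes follow the fit()/Results convention: a model object is built
from data, ``fit()`` returns a results object carrying the estimate, its
residuals and a ``summary()`` string.

* :class:`GrowthModel` — relative growth rate ``g`` of the discrete growth
  law ``W_t = W_0 (1+g)^t`` by least squares on weight series.
* :class:`ParasiteUptakeModel` — parasite uptake rate constant ``kp`` from
  parasite concentration observations under a known piecewise host-derived
  forcing.  The predicted series is linear in ``kp``, so the least-squares
  estimate is closed form.
* :class:`UptakeKineticsModel` — joint (ku, ke) calibration of the
  uninfected host model against observed concentration series.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from .errors import BiodynError, InsufficientDataError
from .exposure import ExposureSchedule
from .kinetics import (FishState, KineticParams, _piecewise_eval,
                       _validate_eval_times)

__all__ = [
    "WeightSeries",
    "CalibrationSeries",
    "project_weight",
    "whole_fish_from_muscle",
    "GrowthModel",
    "GrowthResults",
    "fit_growth_rate",
    "ParasiteUptakeModel",
    "ParasiteUptakeResults",
    "fit_parasite_uptake_rate",
    "UptakeKineticsModel",
    "UptakeKineticsResults",
]

# fixed deterministic bracket for the growth-rate search (1/d)
_G_BOUNDS = (-0.5, 1.0)


def project_weight(w0: float, g_rate: float, t) -> np.ndarray | float:
    """Discrete growth law ``W_t = W_0 (1+g)^t`` (t in days)."""
    if w0 <= 0:
        raise BiodynError("initial weight must be > 0")
    if 1.0 + g_rate <= 0:
        raise BiodynError("1 + g must be > 0")
    return w0 * (1.0 + g_rate) ** np.asarray(t, dtype=float) if np.ndim(t) \
        else w0 * (1.0 + g_rate) ** float(t)


def whole_fish_from_muscle(muscle_conc, slope: float, intercept: float):
    """Linear muscle-to-whole-fish concentration conversion.

    Coefficients come from user-supplied tissue regressions; none are
    built in.
    """
    if not np.isfinite(slope):
        raise BiodynError("slope must be finite")
    return slope * np.asarray(muscle_conc, dtype=float) + intercept \
        if np.ndim(muscle_conc) else slope * float(muscle_conc) + intercept


# ---------------------------------------------------------------------------
# growth
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WeightSeries:
    """Observed weights over time for one subject kind."""

    times: np.ndarray
    weights: np.ndarray
    kind: str = "fish"  # or "parasite"

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        w = np.asarray(self.weights, dtype=float)
        if t.shape != w.shape or t.ndim != 1:
            raise BiodynError("times and weights must be equal-length 1-d arrays")
        if t.size and np.any(np.diff(t) <= 0):
            raise BiodynError("times must be strictly increasing")
        if np.any(w <= 0):
            raise BiodynError("weights must be > 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_csv(cls, path, kind: str = "fish") -> "WeightSeries":
        df = pd.read_csv(path, comment="#")
        return cls(df["time_d"].to_numpy(), df["weight_g"].to_numpy(), kind=kind)


@dataclass(frozen=True)
class GrowthResults:
    g: float
    w0: float
    residuals: np.ndarray
    objective: float
    n: int
    settings: dict

    def summary(self) -> str:
        return (f"relative growth rate g = {self.g:.6g} /d  "
                f"(W0 = {self.w0:.6g} g, n = {self.n}, "
                f"SSR = {self.objective:.6g})")

    def to_dict(self) -> dict:
        return {"estimate": self.g, "w0": self.w0,
                "objective": self.objective, "n": self.n,
                "residuals": list(map(float, self.residuals)),
                "settings": self.settings}


class GrowthModel:
    """Least-squares fit of the relative growth rate constant.

    Parameters
    ----------
    series : WeightSeries
    fit_w0 : bool
        If False (default) W0 is fixed to the first observation; if True it
        is profiled out analytically at each candidate g.
    scale : {"linear", "log"}
        Objective scale.  On the log scale the model is linear in
        ``log(1+g)`` and solved in closed form.
    """

    def __init__(self, series: WeightSeries, fit_w0: bool = False,
                 scale: str = "linear"):
        if series.times.size < 2:
            raise InsufficientDataError("growth fit needs >= 2 time points")
        if scale not in ("linear", "log"):
            raise BiodynError(f"unknown scale {scale!r}")
        self.series = series
        self.fit_w0 = fit_w0
        self.scale = scale

    def _w0_for(self, g: float) -> float:
        t, w = self.series.times, self.series.weights
        f = (1.0 + g) ** (t - t[0])
        if self.fit_w0:
            return float(np.dot(w, f) / np.dot(f, f))
        return float(w[0])

    def _ssr(self, g: float) -> float:
        t, w = self.series.times, self.series.weights
        pred = self._w0_for(g) * (1.0 + g) ** (t - t[0])
        return float(np.sum((w - pred) ** 2))

    def fit(self) -> GrowthResults:
        t, w = self.series.times, self.series.weights
        if self.scale == "log":
            # log W = log W0 + t*log(1+g): simple linear regression
            x = t - t[0]
            y = np.log(w)
            if self.fit_w0:
                slope, icpt = np.polyfit(x, y, 1)
                w0 = float(np.exp(icpt))
            else:
                w0 = float(w[0])
                slope = float(np.dot(x, y - np.log(w0)) / np.dot(x, x))
            g = float(np.expm1(slope))
        else:
            res = optimize.minimize_scalar(self._ssr, bounds=_G_BOUNDS,
                                           method="bounded",
                                           options={"xatol": 1e-12})
            g = float(res.x)
            w0 = self._w0_for(g)
        pred = w0 * (1.0 + g) ** (t - t[0])
        resid = w - pred
        return GrowthResults(g=g, w0=w0, residuals=resid,
                             objective=float(np.sum(resid ** 2)), n=t.size,
                             settings={"fit_w0": self.fit_w0, "scale": self.scale,
                                       "bounds": list(_G_BOUNDS)})


def fit_growth_rate(series: WeightSeries, **kw) -> GrowthResults:
    """Convenience wrapper: ``GrowthModel(series, **kw).fit()``."""
    return GrowthModel(series, **kw).fit()


# ---------------------------------------------------------------------------
# parasite uptake
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationSeries:
    """Parasite concentration observations plus the per-interval host source.

    `interval_starts` / `horizon` define the forcing grid on which `cf`
    (the host-derived source Ct*W/Wp, ug/g) is piecewise constant.
    """

    times: np.ndarray            # observation times (d)
    parasite_conc: np.ndarray    # observed Cp (ug/g ww)
    interval_starts: np.ndarray  # forcing grid (d)
    cf: np.ndarray               # host source per interval (ug/g ww)
    horizon: float
    n_parasites: int
    gp: float

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        cp = np.asarray(self.parasite_conc, dtype=float)
        starts = np.asarray(self.interval_starts, dtype=float)
        cf = np.asarray(self.cf, dtype=float)
        if t.shape != cp.shape:
            raise BiodynError("times and parasite_conc must align")
        if starts.shape != cf.shape:
            raise BiodynError("interval_starts and cf must align")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "parasite_conc", cp)
        object.__setattr__(self, "interval_starts", starts)
        object.__setattr__(self, "cf", cf)


@dataclass(frozen=True)
class ParasiteUptakeResults:
    kp: float
    residuals: np.ndarray
    objective: float
    n: int
    clipped: bool
    settings: dict

    def summary(self) -> str:
        note = "  (clipped to 0)" if self.clipped else ""
        return f"parasite uptake rate kp = {self.kp:.6g} /d  (n = {self.n}){note}"

    def to_dict(self) -> dict:
        return {"estimate": self.kp, "objective": self.objective,
                "n": self.n, "clipped": self.clipped,
                "residuals": list(map(float, self.residuals)),
                "settings": self.settings}


class ParasiteUptakeModel:
    """Closed-form least-squares estimate of kp.

    The parasite solution separates as ``Cp(t) = Cp0*exp(-lam_p (t-T0)) +
    kp*S(t)`` where ``S`` is the unit-gain response to the piecewise
    forcing, so the least-squares kp over the observations is a ratio of
    inner products.  A negative estimate is clipped to zero with a warning
    (a negative parasite uptake has no meaning in this model).

    mode : {"all", "endpoint"}
        Use every observation, or the final one only (single-ratio
        inversion).
    """

    def __init__(self, series: CalibrationSeries, cp0: float = 0.0,
                 mode: str = "all", parasite_loss: str = "np_gp"):
        if series.times.size < 1:
            raise InsufficientDataError("need at least one observation")
        if mode not in ("all", "endpoint"):
            raise BiodynError(f"unknown mode {mode!r}")
        self.series = series
        self.cp0 = float(cp0)
        self.mode = mode
        lam = (series.n_parasites if parasite_loss == "np_gp" else 1.0) * series.gp
        if lam <= 0:
            raise BiodynError("np * gp must be > 0")
        self.lam_p = lam

    def fit(self) -> ParasiteUptakeResults:
        s = self.series
        t = s.times
        edges = np.append(s.interval_starts, s.horizon)
        # unit-gain basis response and the free decay of the initial condition
        basis = _piecewise_eval(s.interval_starts, edges, s.cf, self.lam_p,
                                1.0, 0.0, t)
        decay = self.cp0 * np.exp(-self.lam_p * (t - s.interval_starts[0]))
        obs = s.parasite_conc - decay
        if self.mode == "endpoint":
            basis, obs, t_used = basis[-1:], obs[-1:], t[-1:]
        denom = float(np.dot(basis, basis))
        if denom == 0.0:
            if np.any(np.abs(obs) > 0):
                warnings.warn("forcing is identically zero but parasites "
                              "accumulated: kp is unidentifiable", UserWarning)
            kp = 0.0
        else:
            kp = float(np.dot(basis, obs) / denom)
        clipped = kp < 0.0
        if clipped:
            warnings.warn(f"negative kp estimate ({kp:.3g}) clipped to 0",
                          UserWarning)
            kp = 0.0
        pred = decay + kp * _piecewise_eval(s.interval_starts, edges, s.cf,
                                            self.lam_p, 1.0, 0.0, t)
        resid = s.parasite_conc - pred
        return ParasiteUptakeResults(kp=kp, residuals=resid,
                                     objective=float(np.sum(resid ** 2)),
                                     n=t.size, clipped=clipped,
                                     settings={"mode": self.mode,
                                               "cp0": self.cp0,
                                               "lam_p": self.lam_p})


def fit_parasite_uptake_rate(series: CalibrationSeries, cp0: float = 0.0,
                             **kw) -> ParasiteUptakeResults:
    return ParasiteUptakeModel(series, cp0=cp0, **kw).fit()


# ---------------------------------------------------------------------------
# joint (ku, ke) host calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class UptakeKineticsResults:
    ku: float
    ke: float
    residuals: np.ndarray
    objective: float
    n: int
    settings: dict

    def summary(self) -> str:
        return (f"ku = {self.ku:.6g} L/g/d  ke = {self.ke:.6g} /d  "
                f"(n = {self.n}, SSR = {self.objective:.6g})")


class UptakeKineticsModel:
    """Joint least-squares calibration of (ku, ke) for the uninfected host.

    Built from observed whole-fish concentrations under a known exposure
    schedule and growth rate; fit() minimises the sum of squared residuals
    of the analytical piecewise solution.
    """

    def __init__(self, schedule: ExposureSchedule, times, concentrations,
                 g: float = 0.0, c0: float = 0.0):
        self.schedule = schedule
        self.times = np.asarray(times, dtype=float)
        self.obs = np.asarray(concentrations, dtype=float)
        if self.times.shape != self.obs.shape:
            raise BiodynError("times and concentrations must align")
        if self.times.size < 2:
            raise InsufficientDataError("need >= 2 observations")
        self.g = float(g)
        self.c0 = float(c0)
        _validate_eval_times(schedule, self.times)

    def _predict(self, ku: float, ke: float) -> np.ndarray:
        sched = self.schedule
        return _piecewise_eval(sched.renewal_times, sched.interval_edges,
                               sched.interval_concentrations, ke + self.g,
                               ku, self.c0, self.times)

    def fit(self, x0: Optional[Sequence[float]] = None) -> UptakeKineticsResults:
        if x0 is None:
            # crude moment start: terminal slope ratio
            cw = float(np.mean(self.schedule.interval_concentrations))
            c_end = max(float(self.obs[-1]), 1e-12)
            ke0 = 0.05
            ku0 = max(c_end * (ke0 + self.g) / max(cw, 1e-12), 1e-8)
            x0 = [ku0, ke0]

        def resid(x):
            ku, ke = x
            return self._predict(ku, ke) - self.obs

        sol = optimize.least_squares(resid, x0=np.asarray(x0, dtype=float),
                                     bounds=([0.0, 0.0], [np.inf, np.inf]),
                                     xtol=1e-14, ftol=1e-14, gtol=1e-14)
        ku, ke = map(float, sol.x)
        r = self._predict(ku, ke) - self.obs
        return UptakeKineticsResults(ku=ku, ke=ke, residuals=r,
                                     objective=float(np.sum(r ** 2)),
                                     n=self.times.size,
                                     settings={"g": self.g, "c0": self.c0,
                                               "x0": list(map(float, x0))})
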