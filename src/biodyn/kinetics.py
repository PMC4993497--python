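"""One-compartment mass-balance engines for fish and fish-parasite systems.

The host model is the linear balance

    dCt/dt = ku * Cw(t) - (ke + g + kp) * Ct,

with ``Cw(t)`` piecewise constant over renewal intervals.  Parasite uptake
is treated as a host efflux (rate constant ``kp``), and the parasite
compartment is driven by the host concentration rescaled by the
host-to-parasite weight ratio,

    dCp/dt = kp * Ct * W/Wp - np * gp * Cp.

Both compartments admit exact per-interval solutions; the analytical
engines evaluate the interval recurrence

    C(T_{j+1}) = C(T_j) * exp(-lam*D_j) + (gain*F_j/lam) * (1 - exp(-lam*D_j))

with ``lam`` the total loss rate and ``F_j`` the per-interval forcing.
For the host the forcing is exact (water concentration is constant within
an interval); for the parasite the host-derived source is approximated as
constant within each interval, which introduces a first-order error in the
interval length.  A fixed-step 4th-order Runge-Kutta integrator of the
differential forms serves as the independent numerical oracle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BiodynError, DegenerateLossError
from .exposure import ExposureSchedule

__all__ = [
    "RateProvenance",
    "KineticParams",
    "FishState",
    "ParasiteLoad",
    "HostParasiteSystem",
    "PredictionSeries",
    "simulate_uninfected",
    "simulate_infected",
    "host_source_concentration",
    "ode_oracle",
    "steady_state",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RateProvenance:
    """How a rate-constant bundle was derived from weight and covalent index."""

    p: float                  # absorption efficiency, fraction in (0, 1)
    vr: float                 # ventilation rate, L/g/d
    ke0: float                # weight-corrected elimination rate, 1/d
    covalent_index: float     # dimensionless QSAR descriptor
    weight_g: float           # fish wet weight used in the allometry, g

    def __post_init__(self):
        if not (0.0 < self.p < 1.0):
            raise BiodynError(f"absorption efficiency must be in (0,1), got {self.p}")
        if self.weight_g <= 0:
            raise BiodynError("weight must be > 0")


@dataclass(frozen=True)
class KineticParams:
    """Rate-constant bundle for one compartmental run.

    ku : dissolved uptake rate constant (L/g/d)
    ke : elimination rate constant (1/d)
    g  : host relative growth rate constant (1/d), enters as growth dilution
    kp : parasite uptake rate constant (1/d); 0 for uninfected fish
    """

    ku: float
    ke: float
    g: float = 0.0
    kp: float = 0.0
    derived_from: Optional[RateProvenance] = None

    def __post_init__(self):
        if self.ku < 0 or self.ke < 0 or self.kp < 0:
            raise BiodynError("rate constants ku, ke, kp must be >= 0")
        if self.derived_from is not None:
            prov = self.derived_from
            if not np.isclose(self.ku, prov.p * prov.vr, rtol=1e-8, atol=1e-15):
                raise BiodynError("provenance inconsistent: ku != p * VR")

    @property
    def total_loss(self) -> float:
        """ke + g + kp, the loss rate in the host exponential."""
        return self.ke + self.g + self.kp

    def replace(self, **kw) -> "KineticParams":
        return dataclasses.replace(self, **kw)


@dataclass(frozen=True)
class FishState:
    """Initial whole-fish concentration (ug/g ww) and wet weight (g)."""

    C0: float
    W0: float

    def __post_init__(self):
        if self.C0 < 0:
            raise BiodynError("initial concentration must be >= 0")
        if self.W0 <= 0:
            raise BiodynError("fish weight must be > 0")


@dataclass(frozen=True)
class ParasiteLoad:
    """Parasite infrapopulation of one host.

    n_parasites : number of individuals
    Wp0 : total initial parasite wet weight (g)
    gp  : relative growth rate constant of an individual parasite (1/d)
    Cp0 : initial parasite concentration (ug/g ww)
    """

    n_parasites: int
    Wp0: float
    gp: float
    Cp0: float = 0.0

    def __post_init__(self):
        if self.n_parasites < 1:
            raise BiodynError("infected systems need at least one parasite")
        if self.Wp0 <= 0:
            raise BiodynError("parasite weight must be > 0")
        if self.Cp0 < 0:
            raise BiodynError("initial parasite concentration must be >= 0")


@dataclass(frozen=True)
class HostParasiteSystem:
    """A fish host with an optional parasite load."""

    fish: FishState
    load: Optional[ParasiteLoad] = None

    @property
    def infected(self) -> bool:
        return self.load is not None


@dataclass(frozen=True)
class PredictionSeries:
    """Time-stamped predicted concentrations (ug/g ww)."""

    times: np.ndarray
    host_conc: np.ndarray
    parasite_conc: Optional[np.ndarray] = None

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        host = np.asarray(self.host_conc, dtype=float)
        if times.shape != host.shape:
            raise BiodynError("times and host_conc must have equal length")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "host_conc", host)
        if self.parasite_conc is not None:
            par = np.asarray(self.parasite_conc, dtype=float)
            if par.shape != times.shape:
                raise BiodynError("parasite_conc length mismatch")
            object.__setattr__(self, "parasite_conc", par)

    def to_frame(self) -> pd.DataFrame:
        data = {"time_d": self.times, "host_conc_ugg": self.host_conc}
        if self.parasite_conc is not None:
            data["parasite_conc_ugg"] = self.parasite_conc
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# analytical piecewise-constant solver
# ---------------------------------------------------------------------------

def _check_loss(lam: float, what: str) -> None:
    if lam <= 0:
        raise DegenerateLossError(f"total loss rate for {what} must be > 0, got {lam}")


def _piecewise_states(starts: np.ndarray, edges: np.ndarray, forcing: np.ndarray,
                      lam: float, gain: float, c0: float) -> np.ndarray:
    """Concentration at every interval start, by the exact recurrence."""
    n = starts.size
    states = np.empty(n)
    states[0] = c0
    widths = np.diff(edges)
    decay = np.exp(-lam * widths)
    inflow = (gain * forcing / lam) * (1.0 - decay)
    for j in range(n - 1):
        states[j + 1] = states[j] * decay[j] + inflow[j]
    return states


def _piecewise_eval(schedule_starts: np.ndarray, edges: np.ndarray,
                    forcing: np.ndarray, lam: float, gain: float, c0: float,
                    eval_times: np.ndarray) -> np.ndarray:
    """Exact solution of dC/dt = gain*F_j - lam*C at arbitrary times."""
    states = _piecewise_states(schedule_starts, edges, forcing, lam, gain, c0)
    idx = np.searchsorted(schedule_starts, eval_times, side="right") - 1
    tau = eval_times - schedule_starts[idx]
    decay = np.exp(-lam * tau)
    return states[idx] * decay + (gain * forcing[idx] / lam) * (1.0 - decay)


def _expanded_eval(schedule: ExposureSchedule, lam: float, gain: float,
                   c0: float, eval_times: np.ndarray) -> np.ndarray:
    """Expanded-sum form of the piecewise solution.

    Algebraic expansion of the interval recurrence: a sum over completed
    intervals plus the current-interval term.  Kept as an independent code
    path for identity testing against the recurrence.
    """
    starts = schedule.renewal_times
    edges = schedule.interval_edges
    concs = schedule.interval_concentrations
    out = np.empty_like(eval_times)
    for i, t in enumerate(eval_times):
        k = int(np.searchsorted(starts, t, side="right") - 1)
        total = c0 * np.exp(-lam * (t - starts[0]))
        acc = 0.0
        for j in range(k):
            acc += concs[j] * (np.exp(-lam * (t - edges[j + 1])) - np.exp(-lam * (t - edges[j])))
        acc += concs[k] * (1.0 - np.exp(-lam * (t - starts[k])))
        out[i] = total + (gain / lam) * acc
    return out


def _validate_eval_times(schedule: ExposureSchedule, eval_times) -> np.ndarray:
    t = np.atleast_1d(np.asarray(eval_times, dtype=float))
    if np.any(t < schedule.start) or np.any(t > schedule.horizon):
        raise BiodynError(
            f"evaluation times must lie within [{schedule.start}, {schedule.horizon}]"
        )
    return t


def simulate_uninfected(schedule: ExposureSchedule, params: KineticParams,
                        fish: FishState, eval_times,
                        _method: str = "recurrence") -> PredictionSeries:
    """Whole-fish concentration of an uninfected fish under fluctuating exposure.

    Solves the exact per-interval recurrence of the one-compartment balance
    with loss rate ``ke + g``.  ``_method="expanded"`` selects the
    algebraically expanded sum instead (identity-testing hook).
    """
    if params.kp != 0:
        raise BiodynError("uninfected simulation requires kp == 0")
    lam = params.ke + params.g
    _check_loss(lam, "the uninfected fish")
    t = _validate_eval_times(schedule, eval_times)
    if _method == "recurrence":
        host = _piecewise_eval(schedule.renewal_times, schedule.interval_edges,
                               schedule.interval_concentrations, lam, params.ku,
                               fish.C0, t)
    elif _method == "expanded":
        host = _expanded_eval(schedule, lam, params.ku, fish.C0, t)
    else:
        raise BiodynError(f"unknown method {_method!r}")
    return PredictionSeries(times=t, host_conc=host)


def host_source_concentration(ct, w: float, wp: float):
    """Metal source seen by the parasites: the host concentration rescaled
    by the host-to-parasite weight ratio, ``Cf = Ct * W / Wp`` (ug/g ww)."""
    if w <= 0 or wp <= 0:
        raise BiodynError("weights must be > 0")
    return np.asarray(ct) * (w / wp)


def _interval_host_stats(schedule: ExposureSchedule, lam: float, gain: float,
                         c0: float, sampling: str) -> np.ndarray:
    """Representative host concentration for each renewal interval."""
    starts = schedule.renewal_times
    edges = schedule.interval_edges
    concs = schedule.interval_concentrations
    states = _piecewise_states(starts, edges, concs, lam, gain, c0)
    if sampling == "start":
        return states
    widths = np.diff(edges)
    css = gain * concs / lam  # within-interval asymptote
    if sampling == "midpoint":
        d = np.exp(-lam * widths / 2.0)
        return states * d + css * (1.0 - d)
    if sampling == "mean":
        # time-average of states*exp(-lam*tau) + css*(1-exp(-lam*tau))
        frac = (1.0 - np.exp(-lam * widths)) / (lam * widths)
        return css + (states - css) * frac
    raise BiodynError(f"unknown parasite forcing sampling {sampling!r}")


def simulate_infected(schedule: ExposureSchedule, params: KineticParams,
                      system: HostParasiteSystem, eval_times,
                      cf_sampling: str = "start",
                      weight_dynamics: str = "static",
                      parasite_loss: str = "np_gp") -> PredictionSeries:
    """Concentrations in an infected fish and its parasites.

    The host compartment is solved exactly as in :func:`simulate_uninfected`
    with the augmented loss rate ``ke + g + kp`` (parasite uptake acts as a
    host efflux).  The parasite compartment is then solved by the same
    recurrence with loss rate ``np * gp`` (growth dilution of the
    infrapopulation) and per-interval forcing ``Cf_j = Ct * W / Wp``
    sampled from the host series.

    Parameters
    ----------
    cf_sampling : {"start", "midpoint", "mean"}
        Where within each interval the host-derived source is sampled.
    weight_dynamics : {"static", "projected"}
        "static" holds the weight ratio at its initial value; "projected"
        recomputes W and Wp per interval from the discrete growth law
        ``W_t = W_0 * (1+g)^t``.
    parasite_loss : {"np_gp", "gp"}
        Loss rate of the parasite compartment: the printed form multiplies
        the individual growth-rate constant by the number of parasites.
    """
    if not system.infected:
        raise BiodynError("simulate_infected needs a parasite load; "
                          "use simulate_uninfected for uninfected fish")
    load = system.load
    fish = system.fish
    lam_host = params.total_loss
    _check_loss(lam_host, "the infected fish")
    if parasite_loss == "np_gp":
        lam_par = load.n_parasites * load.gp
    elif parasite_loss == "gp":
        lam_par = load.gp
    else:
        raise BiodynError(f"unknown parasite_loss {parasite_loss!r}")
    _check_loss(lam_par, "the parasites")
    t = _validate_eval_times(schedule, eval_times)

    host = _piecewise_eval(schedule.renewal_times, schedule.interval_edges,
                           schedule.interval_concentrations, lam_host,
                           params.ku, fish.C0, t)

    # per-interval host source for the parasites
    host_rep = _interval_host_stats(schedule, lam_host, params.ku, fish.C0,
                                    cf_sampling)
    if weight_dynamics == "static":
        ratio = fish.W0 / load.Wp0
        cf = host_rep * ratio
    elif weight_dynamics == "projected":
        starts = schedule.renewal_times
        w = fish.W0 * (1.0 + params.g) ** (starts - starts[0])
        wp = load.Wp0 * (1.0 + load.gp) ** (starts - starts[0])
        cf = host_rep * w / wp
    else:
        raise BiodynError(f"unknown weight_dynamics {weight_dynamics!r}")

    par = _piecewise_eval(schedule.renewal_times, schedule.interval_edges,
                          cf, lam_par, params.kp, load.Cp0, t)
    return PredictionSeries(times=t, host_conc=host, parasite_conc=par)


def steady_state(params: KineticParams, cw: float) -> float:
    """Equilibrium host concentration at constant exposure: ku*Cw/(ke+g+kp)."""
    lam = params.total_loss
    _check_loss(lam, "the host")
    return params.ku * cw / lam


# ---------------------------------------------------------------------------
# fixed-step RK4 oracle
# ---------------------------------------------------------------------------

def _rk4_linear_interval(c, lam, source, h, n_steps):
    """n_steps of classical RK4 for dC/dt = source - lam*C (vectorised).

    `c`, `lam`, `source` broadcast together; `source` is constant over the
    interval.
    """
    for _ in range(n_steps):
        k1 = source - lam * c
        k2 = source - lam * (c + 0.5 * h * k1)
        k3 = source - lam * (c + 0.5 * h * k2)
        k4 = source - lam * (c + h * k3)
        c = c + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return c


def _rk4_coupled_interval(ct, cp, lam_host, influx, kp_ratio, lam_par, h, n_steps):
    """RK4 for the coupled host/parasite system over one interval.

    dCt/dt = influx - lam_host*Ct ;  dCp/dt = kp_ratio*Ct - lam_par*Cp,
    with kp_ratio = kp * W / Wp.
    """
    for _ in range(n_steps):
        a1 = influx - lam_host * ct
        b1 = kp_ratio * ct - lam_par * cp
        ct2 = ct + 0.5 * h * a1
        cp2 = cp + 0.5 * h * b1
        a2 = influx - lam_host * ct2
        b2 = kp_ratio * ct2 - lam_par * cp2
        ct3 = ct + 0.5 * h * a2
        cp3 = cp + 0.5 * h * b2
        a3 = influx - lam_host * ct3
        b3 = kp_ratio * ct3 - lam_par * cp3
        ct4 = ct + h * a3
        cp4 = cp + h * b3
        a4 = influx - lam_host * ct4
        b4 = kp_ratio * ct4 - lam_par * cp4
        ct = ct + (h / 6.0) * (a1 + 2 * a2 + 2 * a3 + a4)
        cp = cp + (h / 6.0) * (b1 + 2 * b2 + 2 * b3 + b4)
    return ct, cp


def _segment_plan(schedule: ExposureSchedule, eval_times: np.ndarray):
    """Breakpoints merging interval edges and evaluation times."""
    pts = np.unique(np.concatenate([schedule.interval_edges, eval_times]))
    return pts


def ode_oracle(schedule: ExposureSchedule, params: KineticParams,
               system: HostParasiteSystem, eval_times, step: float = 1e-3,
               parasite_loss: str = "np_gp") -> PredictionSeries:
    """Fixed-step 4th-order integration of the differential mass balances.

    Independent numerical oracle for the analytical engines.  The host ODE
    uses the same piecewise-constant water forcing; the parasite ODE is
    driven by the *continuous* host solution (the coupled system), so the
    analytical parasite series converges to this oracle only as the renewal
    grid is refined.

    `step` is the nominal step (days); within each segment the step is
    shrunk to divide the segment exactly.
    """
    if step <= 0:
        raise BiodynError("step must be > 0")
    widths = np.diff(schedule.interval_edges)
    if step > widths.min():
        raise BiodynError("step must not exceed the shortest interval")
    t = _validate_eval_times(schedule, eval_times)
    infected = system.infected
    fish = system.fish
    lam_host = params.total_loss
    _check_loss(lam_host, "the host")
    if infected:
        load = system.load
        lam_par = (load.n_parasites if parasite_loss == "np_gp" else 1.0) * load.gp
        _check_loss(lam_par, "the parasites")
        kp_ratio = params.kp * fish.W0 / load.Wp0
        cp = load.Cp0
    ct = fish.C0

    pts = _segment_plan(schedule, t)
    out_host = {}
    out_par = {}
    for te in t[t == schedule.start]:
        out_host[te] = ct
        if infected:
            out_par[te] = cp
    eval_set = set(t.tolist())
    for a, b in zip(pts[:-1], pts[1:]):
        seg = b - a
        n_steps = max(1, int(np.ceil(seg / step - 1e-12)))
        h = seg / n_steps
        influx = params.ku * schedule.concentration_at(a)
        if infected:
            ct, cp = _rk4_coupled_interval(ct, cp, lam_host, influx,
                                           kp_ratio, lam_par, h, n_steps)
        else:
            ct = _rk4_linear_interval(ct, lam_host, influx, h, n_steps)
        if b in eval_set:
            out_host[b] = ct
            if infected:
                out_par[b] = cp
    host = np.array([out_host[te] for te in t])
    if infected:
        return PredictionSeries(times=t, host_conc=host,
                                parasite_conc=np.array([out_par[te] for te in t]))
    return PredictionSeries(times=t, host_conc=host)


def ode_oracle_batch(schedule: ExposureSchedule, concs: np.ndarray,
                     ku: np.ndarray, lam: np.ndarray, c0: np.ndarray,
                     eval_time: float, step: float = 1e-3) -> np.ndarray:
    """Vectorised RK4 oracle for many uninfected configurations at once.

    All configurations share the renewal grid of `schedule`; `concs` has
    shape (batch, n_intervals) and `ku`, `lam`, `c0` shape (batch,).
    Returns the host concentration of every configuration at `eval_time`.
    """
    if step <= 0:
        raise BiodynError("step must be > 0")
    concs = np.asarray(concs, dtype=float)
    c = np.asarray(c0, dtype=float).copy()
    edges = schedule.interval_edges
    t_end = float(eval_time)
    for j in range(schedule.n_intervals):
        a, b = edges[j], min(edges[j + 1], t_end)
        if b <= a:
            break
        seg = b - a
        n_steps = max(1, int(np.ceil(seg / step - 1e-12)))
        h = seg / n_steps
        c = _rk4_linear_interval(c, lam, ku * concs[:, j], h, n_steps)
        if b >= t_end:
            break
    return c
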