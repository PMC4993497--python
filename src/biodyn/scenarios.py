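"""Scenario grid for the uncertainty / sensitivity analysis.

Ten named scenarios perturb the uninfected fish's absorption efficiency
and elimination rate by factors of two, each combined with one of two
infection-effect assumptions borrowed from cadmium and cobalt kinetics in
a cyprinid-tapeworm system:

* Cd-like: the infected fish takes up metal twice as fast and eliminates
  it 1.7 times more slowly than the uninfected fish.
* Co-like: uptake twice as slow, elimination 1.7 times faster.

"n times lower" is implemented as division by n.  The uptake multipliers
act on the absorption-efficiency fraction (ventilation is assumed
unaffected by parasitism); a modified efficiency >= 1 is capped just
below 1 with a warning.  The parasite uptake rate kp is held fixed across
scenarios.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import BiodynError
from .exposure import ExposureSchedule
from .kinetics import (HostParasiteSystem, KineticParams, PredictionSeries,
                       RateProvenance, simulate_infected, simulate_uninfected)

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "SweepSummary",
    "infection_modifiers",
    "build_scenario_table",
    "apply_scenario",
    "run_sweep",
]

_P_CAP = 1.0 - 1e-6

#: infection-effect multipliers (uptake_factor, elimination_factor)
_INFECTION_MODES = {
    "cd_like": (2.0, 1.0 / 1.7),
    "co_like": (0.5, 1.7),
}


def infection_modifiers(mode: str) -> tuple[float, float]:
    """(uptake multiplier, elimination multiplier) applied to the infected
    fish on top of the uninfected parameters."""
    try:
        return _INFECTION_MODES[mode]
    except KeyError:
        raise BiodynError(f"unknown infection mode {mode!r}; "
                          f"expected one of {sorted(_INFECTION_MODES)}") from None


@dataclass(frozen=True)
class ScenarioSpec:
    """One scenario: multipliers on the uninfected fish plus an infection mode."""

    name: str
    p_factor: float = 1.0
    ke_factor: float = 1.0
    infection_mode: str = "cd_like"

    def __post_init__(self):
        if self.p_factor <= 0 or self.ke_factor <= 0:
            raise BiodynError("scenario factors must be > 0")
        infection_modifiers(self.infection_mode)  # validates the mode

    @property
    def group(self) -> str:
        """S (standard), absorption (A/B) or elimination (C/D)."""
        if self.p_factor != 1.0:
            return "absorption"
        if self.ke_factor != 1.0:
            return "elimination"
        return "standard"


def build_scenario_table() -> List[ScenarioSpec]:
    """The ten named scenarios of the sensitivity design.

    S1/S2 leave the uninfected parameters at their defaults; A and B halve
    and double the absorption efficiency; C and D halve and double the
    elimination rate.  Odd-numbered scenarios use the Cd-like infection
    effect, even-numbered the Co-like one.
    """
    blocks = [("S", 1.0, 1.0), ("A", 0.5, 1.0), ("B", 2.0, 1.0),
              ("C", 1.0, 0.5), ("D", 1.0, 2.0)]
    specs = []
    for prefix, p_factor, ke_factor in blocks:
        for idx, mode in ((1, "cd_like"), (2, "co_like")):
            specs.append(ScenarioSpec(name=f"{prefix}{idx}", p_factor=p_factor,
                                      ke_factor=ke_factor, infection_mode=mode))
    return specs


def _scale_uptake_via_p(base: KineticParams, factor: float) -> tuple[float, Optional[RateProvenance]]:
    """New ku after multiplying the absorption efficiency by `factor`."""
    if factor == 1.0:
        return base.ku, base.derived_from
    prov = base.derived_from
    if prov is None:
        raise BiodynError(
            "an uptake multiplier needs provenance (p, VR) on the base "
            "parameters; build them with derive_params")
    p_new = prov.p * factor
    if p_new >= 1.0:
        warnings.warn(f"modified absorption efficiency {p_new:.3g} >= 1; "
                      f"capped at {_P_CAP}", UserWarning)
        p_new = _P_CAP
    new_prov = RateProvenance(p=p_new, vr=prov.vr, ke0=prov.ke0,
                              covalent_index=prov.covalent_index,
                              weight_g=prov.weight_g)
    return p_new * prov.vr, new_prov


def apply_scenario(base: KineticParams, spec: ScenarioSpec) -> tuple[KineticParams, KineticParams]:
    """Derive (uninfected, infected) parameter bundles for one scenario.

    The uninfected bundle gets the scenario's p and ke multipliers and
    kp = 0; the infected bundle additionally carries the infection-mode
    multipliers and the base kp (held fixed across scenarios).
    """
    ku_unf, prov_unf = _scale_uptake_via_p(base, spec.p_factor)
    ke_unf = base.ke * spec.ke_factor
    uninfected = KineticParams(ku=ku_unf, ke=ke_unf, g=base.g, kp=0.0,
                               derived_from=prov_unf)
    up_f, el_f = infection_modifiers(spec.infection_mode)
    ku_inf, prov_inf = _scale_uptake_via_p(
        KineticParams(ku=ku_unf, ke=ke_unf, g=base.g, kp=0.0,
                      derived_from=prov_unf), up_f)
    infected = KineticParams(ku=ku_inf, ke=ke_unf * el_f, g=base.g,
                             kp=base.kp, derived_from=prov_inf)
    return uninfected, infected


@dataclass(frozen=True)
class ScenarioResult:
    """Simulation outputs of one scenario."""

    spec: ScenarioSpec
    uninfected_params: KineticParams
    infected_params: KineticParams
    uninfected: PredictionSeries
    infected: PredictionSeries

    @property
    def name(self) -> str:
        return self.spec.name


@dataclass(frozen=True)
class SweepSummary:
    """Max/min spread of predictions across scenario groups.

    `table` is tidy: one row per (group, compartment, time) with the
    maximum, minimum and their ratio across the scenarios of that group.
    """

    table: pd.DataFrame

    def spread_ratio(self, group: str, compartment: str,
                     time: Optional[float] = None) -> float:
        sub = self.table[(self.table["group"] == group)
                         & (self.table["compartment"] == compartment)]
        if time is None:
            time = sub["time_d"].max()
        row = sub[sub["time_d"] == time]
        if row.empty:
            raise BiodynError(f"no summary row for {group}/{compartment}/t={time}")
        return float(row["max_min_ratio"].iloc[0])


def run_sweep(schedule: ExposureSchedule, base_params: KineticParams,
              system: HostParasiteSystem, specs: Sequence[ScenarioSpec],
              eval_times, **sim_kwargs) -> tuple[List[ScenarioResult], SweepSummary]:
    """Run uninfected and infected simulations for every scenario.

    Returns the per-scenario results and a tidy spread summary (per
    scenario group, compartment and evaluation time).
    """
    if not system.infected:
        raise BiodynError("the sweep needs an infected system description")
    eval_times = np.atleast_1d(np.asarray(eval_times, dtype=float))
    results = []
    for spec in specs:
        p_unf, p_inf = apply_scenario(base_params, spec)
        unf = simulate_uninfected(schedule, p_unf, system.fish, eval_times)
        inf = simulate_infected(schedule, p_inf, system, eval_times, **sim_kwargs)
        results.append(ScenarioResult(spec=spec, uninfected_params=p_unf,
                                      infected_params=p_inf, uninfected=unf,
                                      infected=inf))

    rows = []
    groups: Dict[str, List[ScenarioResult]] = {}
    for res in results:
        groups.setdefault(res.spec.group, []).append(res)
    compartments = {
        "uninfected_host": lambda r: r.uninfected.host_conc,
        "infected_host": lambda r: r.infected.host_conc,
        "parasite": lambda r: r.infected.parasite_conc,
    }
    for gname, members in groups.items():
        for comp, getter in compartments.items():
            stack = np.vstack([getter(r) for r in members])
            hi = stack.max(axis=0)
            lo = stack.min(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(lo > 0, hi / lo, np.inf)
                ratio = np.where(hi == 0, 1.0, ratio)
            for k, t in enumerate(eval_times):
                rows.append({"group": gname, "compartment": comp,
                             "time_d": float(t), "max": float(hi[k]),
                             "min": float(lo[k]),
                             "max_min_ratio": float(ratio[k])})
    return results, SweepSummary(table=pd.DataFrame(rows))


def results_to_frame(results: Sequence[ScenarioResult]) -> pd.DataFrame:
    """Tidy output: one row per scenario x compartment x time."""
    rows = []
    for r in results:
        for comp, series, col in (
                ("uninfected_host", r.uninfected, "host_conc"),
                ("infected_host", r.infected, "host_conc"),
                ("parasite", r.infected, "parasite_conc")):
            vals = getattr(series, col)
            for t, v in zip(series.times, vals):
                rows.append({"scenario": r.name, "compartment": comp,
                             "time_d": float(t), "conc_ugg": float(v)})
    return pd.DataFrame(rows)
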