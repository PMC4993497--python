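"""Allometric and covalent-index parameterisation of the rate constants.

The dissolved uptake rate constant is the product of a metal-specific
absorption efficiency ``p`` and a size-dependent ventilation rate ``VR``:

    ku = p * VR
    VR = Q_liver * VRmax / (Q_liver + VRmax)          (liver limitation)
    VRmax = 254.4e-3 * (1e-3 * W)^(-1/4)              (W in g)

``p`` follows a logit QSAR on the covalent index (chi = Xm^2 * r):

    log10(p / (1 - p)) = 0.18 * chi - 2.31

Elimination scales with a quarter-power allometry of the wet weight in
grams, with the weight-corrected rate itself a covalent-index QSAR:

    ke = ke0 * W^(-1/4),   log10(ke0) = 0.25 * chi - 1.78

Note the deliberate unit asymmetry: the ventilation allometry converts W to
kg through the printed 1e-3 factor, while the elimination allometry uses W
in grams directly.  Both conventions are kept verbatim.

All model constants live in :class:`ModelConstants` so that refitted
coefficients (from :class:`AbsorptionRegression` / :class:`EliminationRegression`)
can replace the published ones without touching call sites.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BiodynError, InsufficientDataError
from .kinetics import KineticParams, RateProvenance

__all__ = [
    "ModelConstants",
    "DEFAULT_CONSTANTS",
    "MetalDescriptor",
    "RateRecord",
    "RegressionFit",
    "vr_max",
    "ventilation_rate",
    "absorption_efficiency",
    "uptake_rate_constant",
    "weight_corrected_elimination",
    "elimination_rate_constant",
    "derive_params",
    "AbsorptionRegression",
    "EliminationRegression",
    "fit_absorption_regression",
    "fit_elimination_regression",
]


@dataclass(frozen=True)
class ModelConstants:
    """Versioned table of the model's fixed constants (units in comments)."""

    q_liver: float = 99.14e-3           # liver blood flow, L/g/d
    vrmax_coeff: float = 254.4e-3       # maximal ventilation coefficient, L/g/d
    allometric_exponent: float = -0.25  # quarter-power scaling, dimensionless
    absorption_slope: float = 0.18      # logit(p) per covalent-index unit
    absorption_intercept: float = -2.31
    elimination_slope: float = 0.25     # log(ke0) per covalent-index unit
    elimination_intercept: float = -1.78
    log_base: float = 10.0              # base of the QSAR logarithms

    def replace(self, **kw) -> "ModelConstants":
        return dataclasses.replace(self, **kw)


DEFAULT_CONSTANTS = ModelConstants()


@dataclass(frozen=True)
class MetalDescriptor:
    """A metal and its covalent index (electronegativity^2 x ionic radius)."""

    name: str
    covalent_index: float
    essential: bool = False

    def __post_init__(self):
        if not np.isfinite(self.covalent_index):
            raise BiodynError("covalent index must be finite")


@dataclass(frozen=True)
class RateRecord:
    """One literature rate observation used for refitting the QSARs."""

    species: str
    weight_g: float
    metal: MetalDescriptor
    rate_kind: str          # "uptake" (L/g/d) or "elimination" (1/d)
    rate_value: float

    def __post_init__(self):
        if self.weight_g <= 0:
            raise BiodynError("weight must be > 0")
        if self.rate_value <= 0:
            raise BiodynError("rate value must be > 0")
        if self.rate_kind not in ("uptake", "elimination"):
            raise BiodynError(f"unknown rate kind {self.rate_kind!r}")


@dataclass(frozen=True)
class RegressionFit:
    """Least-squares line on the QSAR scale with its usual diagnostics."""

    slope: float
    intercept: float
    r2: float
    p_value: float
    n: int
    excluded: int = 0

    def __post_init__(self):
        if self.n < 3:
            raise BiodynError("a regression fit needs n >= 3")

    def summary(self) -> str:
        return (
            f"slope={self.slope:.6g}  intercept={self.intercept:.6g}  "
            f"r2={self.r2:.4f}  p={self.p_value:.3g}  n={self.n}"
            + (f"  (excluded {self.excluded})" if self.excluded else "")
        )


# ---------------------------------------------------------------------------
# forward parameterisation
# ---------------------------------------------------------------------------

def vr_max(weight: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Maximal ventilation rate (L/g/d) from the quarter-power allometry."""
    if weight <= 0:
        raise BiodynError("weight must be > 0")
    return constants.vrmax_coeff * (1e-3 * weight) ** constants.allometric_exponent


def ventilation_rate(weight: float, constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Effective ventilation rate (L/g/d), liver-blood-flow limited
    (Michaelis-Menten combination of Q_liver and VRmax)."""
    vrm = vr_max(weight, constants)
    return constants.q_liver * vrm / (constants.q_liver + vrm)


def absorption_efficiency(covalent_index: float,
                          constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Absorption efficiency p in (0,1) from the covalent-index logit QSAR."""
    if not np.isfinite(covalent_index):
        raise BiodynError("covalent index must be finite")
    y = constants.absorption_slope * covalent_index + constants.absorption_intercept
    q = constants.log_base ** y
    return q / (1.0 + q)


def uptake_rate_constant(weight: float, covalent_index: float,
                         constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Dissolved uptake rate constant ku = p * VR (L/g/d)."""
    return absorption_efficiency(covalent_index, constants) * ventilation_rate(weight, constants)


def weight_corrected_elimination(covalent_index: float,
                                 constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Weight-corrected elimination rate ke0 (1/d) from the covalent index."""
    if not np.isfinite(covalent_index):
        raise BiodynError("covalent index must be finite")
    y = constants.elimination_slope * covalent_index + constants.elimination_intercept
    return constants.log_base ** y


def elimination_rate_constant(weight: float, covalent_index: float,
                              constants: ModelConstants = DEFAULT_CONSTANTS) -> float:
    """Elimination rate constant ke = ke0 * W^(-1/4), W in grams."""
    if weight <= 0:
        raise BiodynError("weight must be > 0")
    return weight_corrected_elimination(covalent_index, constants) * \
        weight ** constants.allometric_exponent


def derive_params(weight: float, covalent_index: float, g: float = 0.0,
                  kp: float = 0.0,
                  constants: ModelConstants = DEFAULT_CONSTANTS) -> KineticParams:
    """Full rate-constant bundle for a fish of given weight and metal,
    with provenance recorded."""
    p = absorption_efficiency(covalent_index, constants)
    vr = ventilation_rate(weight, constants)
    ke0 = weight_corrected_elimination(covalent_index, constants)
    prov = RateProvenance(p=p, vr=vr, ke0=ke0, covalent_index=covalent_index,
                          weight_g=weight)
    return KineticParams(ku=p * vr,
                         ke=ke0 * weight ** constants.allometric_exponent,
                         g=g, kp=kp, derived_from=prov)


# ---------------------------------------------------------------------------
# regression refits from literature rate tables
# ---------------------------------------------------------------------------

def _log(x: np.ndarray, base: float) -> np.ndarray:
    return np.log(x) / np.log(base)


class _QsarRegression:
    """Shared machinery: transform records to (chi, response), run OLS."""

    rate_kind: str = ""

    def __init__(self, records: Sequence[RateRecord],
                 constants: ModelConstants = DEFAULT_CONSTANTS):
        bad_kind = [r for r in records if r.rate_kind != self.rate_kind]
        if bad_kind:
            raise BiodynError(
                f"expected only {self.rate_kind!r} records, got {bad_kind[0].rate_kind!r}")
        self.records = list(records)
        self.constants = constants

    def _responses(self):  # -> (chi, response, n_excluded)
        raise NotImplementedError

    def fit(self) -> RegressionFit:
        chi, y, excluded = self._responses()
        if chi.size < 3:
            raise InsufficientDataError(
                f"need >= 3 usable records, have {chi.size}")
        if np.unique(chi).size < 2:
            raise InsufficientDataError(
                "all records share one covalent index; no regression possible")
        res = stats.linregress(chi, y)
        return RegressionFit(slope=float(res.slope), intercept=float(res.intercept),
                             r2=float(res.rvalue ** 2), p_value=float(res.pvalue),
                             n=int(chi.size), excluded=excluded)


class AbsorptionRegression(_QsarRegression):
    """Refit of the absorption-efficiency logit QSAR from uptake records.

    For each record the absorption efficiency is back-calculated as
    ``p_i = ku_i / VR(W_i)`` with the package's ventilation model; records
    with p outside (0,1) are excluded with a warning; the logit of p is then
    regressed on the covalent index by ordinary least squares.
    """

    rate_kind = "uptake"

    def _responses(self):
        ku = np.array([r.rate_value for r in self.records])
        w = np.array([r.weight_g for r in self.records])
        chi = np.array([r.metal.covalent_index for r in self.records])
        vr = np.array([ventilation_rate(wi, self.constants) for wi in w])
        p = ku / vr
        ok = (p > 0.0) & (p < 1.0)
        if not np.all(ok):
            warnings.warn(
                f"excluded {int((~ok).sum())} record(s) with absorption "
                "efficiency outside (0,1)", UserWarning)
        y = _log(p[ok] / (1.0 - p[ok]), self.constants.log_base)
        return chi[ok], y, int((~ok).sum())


class EliminationRegression(_QsarRegression):
    """Refit of the weight-corrected elimination QSAR from elimination records.

    ``ke0_i = ke_i * W_i^{1/4}`` (undoing the quarter-power allometry, W in
    grams), then OLS of log(ke0) on the covalent index.
    """

    rate_kind = "elimination"

    def _responses(self):
        ke = np.array([r.rate_value for r in self.records])
        w = np.array([r.weight_g for r in self.records])
        chi = np.array([r.metal.covalent_index for r in self.records])
        ke0 = ke * w ** (-self.constants.allometric_exponent)
        y = _log(ke0, self.constants.log_base)
        return chi, y, 0


def fit_absorption_regression(records: Sequence[RateRecord],
                              constants: ModelConstants = DEFAULT_CONSTANTS) -> RegressionFit:
    return AbsorptionRegression(records, constants).fit()


def fit_elimination_regression(records: Sequence[RateRecord],
                               constants: ModelConstants = DEFAULT_CONSTANTS) -> RegressionFit:
    return EliminationRegression(records, constants).fit()


# ---------------------------------------------------------------------------
# rate-table I/O
# ---------------------------------------------------------------------------

def rate_records_from_frame(df: pd.DataFrame) -> List[RateRecord]:
    """Build rate records from a table with columns species, weight_g, metal,
    covalent_index, rate_kind, rate_value."""
    needed = {"species", "weight_g", "metal", "covalent_index", "rate_kind", "rate_value"}
    missing = needed - set(df.columns)
    if missing:
        raise BiodynError(f"rate table missing columns: {sorted(missing)}")
    out = []
    for _, row in df.iterrows():
        metal = MetalDescriptor(name=str(row["metal"]),
                                covalent_index=float(row["covalent_index"]))
        out.append(RateRecord(species=str(row["species"]),
                              weight_g=float(row["weight_g"]), metal=metal,
                              rate_kind=str(row["rate_kind"]),
                              rate_value=float(row["rate_value"])))
    return out


def rate_records_from_csv(path) -> List[RateRecord]:
    return rate_records_from_frame(pd.read_csv(path, comment="#"))
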