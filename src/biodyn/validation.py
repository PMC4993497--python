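"""Model-performance metrics and bioconcentration factors.

Predictions are judged against measurements by the coefficient of
determination and p-value of the least-squares regression of measured on
predicted concentrations, together with the mean absolute error and root
mean square error on the arithmetic concentration scale.  The
host-parasite partitioning is summarised by the bioconcentration factor,
the per-subject ratio of parasite to host concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import BiodynError, UndefinedMetricError

__all__ = [
    "PairedObservations",
    "performance_metrics",
    "bioconcentration_factor",
]


@dataclass(frozen=True)
class PairedObservations:
    """Predicted/measured concentration pairs with per-point labels."""

    predicted: np.ndarray
    measured: np.ndarray
    labels: Optional[Sequence[str]] = None
    measured_sd: Optional[np.ndarray] = None

    def __post_init__(self):
        pred = np.asarray(self.predicted, dtype=float)
        meas = np.asarray(self.measured, dtype=float)
        if pred.shape != meas.shape or pred.ndim != 1:
            raise BiodynError("predicted and measured must be equal-length 1-d arrays")
        if pred.size < 1:
            raise BiodynError("need at least one pair")
        object.__setattr__(self, "predicted", pred)
        object.__setattr__(self, "measured", meas)
        if self.measured_sd is not None:
            sd = np.asarray(self.measured_sd, dtype=float)
            if sd.shape != pred.shape:
                raise BiodynError("measured_sd length mismatch")
            object.__setattr__(self, "measured_sd", sd)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "PairedObservations":
        labels = None
        label_cols = [c for c in ("compartment", "metal", "group") if c in df.columns]
        if label_cols:
            labels = df[label_cols].astype(str).agg("/".join, axis=1).tolist()
        sd = df["measured_sd"].to_numpy() if "measured_sd" in df.columns else None
        return cls(predicted=df["predicted"].to_numpy(),
                   measured=df["measured"].to_numpy(), labels=labels,
                   measured_sd=sd)


def performance_metrics(pairs: PairedObservations) -> dict:
    """r2, regression p, MAE and RMSE of predictions against measurements.

    r2 and p come from the simple least-squares regression of measured on
    predicted (both are symmetric in direction for simple regression).
    MAE and RMSE are on the arithmetic concentration scale.  With fewer
    than 3 pairs, or zero variance in the predictions, r2 and p are
    returned as NaN with a warning; MAE/RMSE are always computed.
    """
    pred, meas = pairs.predicted, pairs.measured
    err = pred - meas
    out = {
        "mae": float(np.mean(np.abs(err))),
        "rmse": float(np.sqrt(np.mean(err ** 2))),
        "n": int(pred.size),
    }
    if pred.size < 3:
        warnings.warn("r2/p need at least 3 pairs; returning NaN", UserWarning)
        out["r2"] = out["p"] = float("nan")
        return out
    if np.ptp(pred) == 0.0:
        warnings.warn("zero variance in predictions: r2 undefined", UserWarning)
        out["r2"] = out["p"] = float("nan")
        return out
    res = stats.linregress(pred, meas)
    out["r2"] = float(res.rvalue ** 2)
    out["p"] = float(res.pvalue)
    return out


def bioconcentration_factor(parasite_conc, host_conc) -> dict:
    """Mean and sample SD (n-1 denominator) of per-subject Cp/Ct ratios.

    Subjects with non-positive host concentration are excluded with a
    warning; with a single usable subject the SD is NaN.
    """
    cp = np.asarray(parasite_conc, dtype=float)
    ct = np.asarray(host_conc, dtype=float)
    if cp.shape != ct.shape or cp.ndim != 1:
        raise BiodynError("parasite and host concentrations must align")
    ok = ct > 0
    n_excluded = int((~ok).sum())
    if n_excluded:
        warnings.warn(f"excluded {n_excluded} subject(s) with non-positive "
                      "host concentration", UserWarning)
    if not np.any(ok):
        raise UndefinedMetricError("no subject with positive host concentration")
    ratios = cp[ok] / ct[ok]
    n = int(ratios.size)
    sd = float(np.std(ratios, ddof=1)) if n > 1 else float("nan")
    if n == 1:
        warnings.warn("single subject: SD undefined", UserWarning)
    return {"mean": float(np.mean(ratios)), "sd": sd, "n": n,
            "n_excluded": n_excluded}


def metrics_report(df: pd.DataFrame, by: Sequence[str] = ("compartment",)) -> pd.DataFrame:
    """Per-group metric table from a tidy paired CSV (one row per point)."""
    rows = []
    for keys, sub in df.groupby(list(by)):
        keys = keys if isinstance(keys, tuple) else (keys,)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = performance_metrics(PairedObservations.from_frame(sub))
        rows.append({**dict(zip(by, keys)), **m})
    return pd.DataFrame(rows)
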