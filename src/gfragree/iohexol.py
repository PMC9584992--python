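"""Measured GFR from iohexol plasma clearance (slope-intercept, one-pool corrected).

After a single iohexol injection, plasma concentration in the late elimination
phase decays mono-exponentially, C(t) = c0·exp(−k·t).  The slope-intercept
clearance is CL1 = dose·k/c0 (= dose/AUC with AUC = c0/k of the terminal
phase).  Because the fast distribution phase is not sampled, CL1 overestimates
true clearance; the Bröchner-Mortensen one-pool quadratic

    CL = 0.990778·CL1 − 0.001218·CL1²

compensates, and CL is taken as the measured GFR (mGFR, ml/min).  The
coefficients are a documented convention and swappable per call.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "IohexolSample",
    "ClearanceResult",
    "fit_monoexponential",
    "slope_intercept_clearance",
    "one_pool_correction",
    "one_pool_inverse",
    "clearance_from_samples",
    "mgfr_table",
    "BM_COEFFS",
]

#: Bröchner-Mortensen one-pool coefficients (b1, b2): CL = b1·CL1 − b2·CL1²
BM_COEFFS: Tuple[float, float] = (0.990778, 0.001218)

#: slope-intercept clearance beyond which the quadratic is outside its
#: calibrated range (and past its vertex b1/(2·b2) ≈ 406.8 it would decrease)
BM_VALID_MAX = 400.0

#: log-linear fits below this R² are flagged as poor-quality decay curves
R2_QC_THRESHOLD = 0.97


@dataclass(frozen=True)
class IohexolSample:
    """One timed plasma (dried-blood-spot) sample: minutes post injection, mg/L."""

    t: float
    conc: float

    def __post_init__(self) -> None:
        if self.t <= 0:
            raise ValueError(f"sample time must be positive, got {self.t}")
        if self.conc <= 0:
            raise ValueError(f"concentration must be positive, got {self.conc}")


@dataclass(frozen=True)
class ClearanceResult:
    """Fitted mono-exponential parameters and corrected clearance for one subject."""

    c0: float  # extrapolated intercept, mg/L
    k: float  # elimination rate, 1/min
    cl_slope_intercept: float  # ml/min
    cl_corrected: float  # the mGFR, ml/min
    r_squared: float
    qc_pass: bool


def _as_arrays(samples) -> Tuple[np.ndarray, np.ndarray]:
    if isinstance(samples, tuple) and len(samples) == 2:
        t, conc = (np.asarray(a, dtype=float) for a in samples)
    else:
        seq = list(samples)
        t = np.array([s.t for s in seq], dtype=float)
        conc = np.array([s.conc for s in seq], dtype=float)
    return t, conc


def fit_monoexponential(samples) -> Tuple[float, float]:
    """Fit C(t) = c0·exp(−k·t) by ordinary least squares on ln(conc) vs t.

    ``samples`` is a sequence of :class:`IohexolSample` or a ``(t, conc)`` pair
    of arrays.  Returns ``(c0, k)`` with k > 0; raises ``ValueError`` on fewer
    than two distinct times, non-positive concentrations, or non-decaying data
    (fitted k ≤ 0).
    """
    t, conc = _as_arrays(samples)
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 samples at distinct times")
    if np.any(conc <= 0):
        raise ValueError("all concentrations must be positive")
    slope, intercept = np.polyfit(t, np.log(conc), 1)
    k = -slope
    if k <= 0:
        raise ValueError(f"fitted elimination rate k = {k:.3g} <= 0: data do not decay")
    return float(np.exp(intercept)), float(k)


def _log_r_squared(t: np.ndarray, conc: np.ndarray, c0: float, k: float) -> float:
    y = np.log(conc)
    resid = y - (np.log(c0) - k * t)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return 1.0
    return 1.0 - float(np.sum(resid**2)) / ss_tot


def slope_intercept_clearance(dose: float, c0: float, k: float) -> float:
    """One-compartment clearance CL1 = dose·k/c0, in ml/min.

    dose in mg, c0 in mg/L, k in 1/min; dose·k/c0 has units L/min, returned
    as ml/min.
    """
    if dose <= 0 or c0 <= 0 or k <= 0:
        raise ValueError("dose, c0 and k must all be positive")
    return dose * k / c0 * 1000.0


def one_pool_correction(cl1: float, coeffs: Tuple[float, float] = BM_COEFFS) -> float:
    """Correct a slope-intercept clearance for the missed distribution phase.

    ``CL = b1·CL1 − b2·CL1²`` (Bröchner-Mortensen one-pool quadratic by
    default).  Values outside [0, 400] ml/min raise a warning: the quadratic
    was calibrated on physiological clearances.
    """
    if cl1 < 0 or cl1 > BM_VALID_MAX:
        warnings.warn(
            f"slope-intercept clearance {cl1:.1f} ml/min outside the corrected"
            f" range [0, {BM_VALID_MAX:.0f}]",
            stacklevel=2,
        )
    b1, b2 = coeffs
    return b1 * cl1 - b2 * cl1**2


def one_pool_inverse(cl: float, coeffs: Tuple[float, float] = BM_COEFFS) -> float:
    """Slope-intercept clearance whose one-pool correction equals ``cl``.

    Inverts the quadratic on its increasing branch (the valid range); used by
    the synthetic curve generator.
    """
    b1, b2 = coeffs
    if cl < 0:
        raise ValueError("clearance must be non-negative")
    disc = b1**2 - 4.0 * b2 * cl
    if disc < 0:
        raise ValueError(
            f"clearance {cl:.1f} exceeds the quadratic's maximum {b1**2 / (4 * b2):.1f}"
        )
    return (b1 - np.sqrt(disc)) / (2.0 * b2)


def clearance_from_samples(
    dose: float, samples, coeffs: Tuple[float, float] = BM_COEFFS
) -> ClearanceResult:
    """Full per-subject pipeline: log-linear fit → CL1 → one-pool correction."""
    t, conc = _as_arrays(samples)
    c0, k = fit_monoexponential((t, conc))
    r2 = _log_r_squared(t, conc, c0, k)
    cl1 = slope_intercept_clearance(dose, c0, k)
    cl = one_pool_correction(cl1, coeffs)
    return ClearanceResult(c0, k, cl1, cl, r2, qc_pass=r2 >= R2_QC_THRESHOLD)


def mgfr_table(samples: pd.DataFrame, coeffs: Tuple[float, float] = BM_COEFFS) -> pd.DataFrame:
    """Per-patient measured GFR from a long-format sample table.

    ``samples`` columns: patient_id, dose_mg, t_min, conc_mg_L.  Returns one
    row per patient with c0, k, r_squared, cl_slope_intercept, mgfr, qc_pass.
    """
    required = {"patient_id", "dose_mg", "t_min", "conc_mg_L"}
    missing = required - set(samples.columns)
    if missing:
        raise ValueError(f"samples table missing columns: {sorted(missing)}")
    rows = []
    for pid, grp in samples.groupby("patient_id", sort=False):
        doses = grp["dose_mg"].unique()
        if len(doses) != 1:
            raise ValueError(f"patient {pid}: inconsistent dose values {doses}")
        res = clearance_from_samples(
            float(doses[0]), (grp["t_min"].to_numpy(), grp["conc_mg_L"].to_numpy()), coeffs
        )
        rows.append(
            {
                "patient_id": pid,
                "c0": res.c0,
                "k": res.k,
                "r_squared": res.r_squared,
                "cl_slope_intercept": res.cl_slope_intercept,
                "mgfr": res.cl_corrected,
                "qc_pass": res.qc_pass,
            }
        )
    return pd.DataFrame(rows)
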