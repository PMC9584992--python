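"""Seeded generator of ADPKD-like cohorts and iohexol decay curves.

The generator emulates the statistical structure the agreement analysis
assumes, without any real patient data:

* measured GFR drawn per stratum (>90, 60–90, 30–60, <30 ml/min with default
  proportions 32/30/24/14 %), uniform within stratum ranges chosen so the
  pooled distribution has median ≈ 71 and IQR ≈ 44–97 ml/min;
* demographics: age Normal(45, 14) truncated at 18, ~50% male, sex-specific
  height/weight, optional lognormal total kidney volume (median ≈ 1008 ml);
* serum markers generated *backwards*: correlated lognormal error terms
  (ε_cr, ε_cys) set a target eGFR = mGFR·e^ε for a creatinine anchor formula
  and a cystatin anchor, and the marker value is obtained by numerically
  inverting the anchor equation (bisection on the marker).  The anchor
  formulas therefore recover mGFR up to the injected noise by construction —
  giving a known-truth TDI, ``100·(e^{z_{0.95}·σ} − 1)`` at coverage 0.90 —
  while every other formula inherits a formula-dependent extra deviation.

All draws flow from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
import pandas as pd

from .formulas import (
    BSA_REF,
    PatientRecord,
    du_bois_bsa,
    evaluate_kernel,
    get_formula,
)
from .iohexol import BM_COEFFS, one_pool_inverse

__all__ = ["CohortParams", "generate_cohort", "cohort_frame", "generate_iohexol_curves"]


@dataclass(frozen=True)
class CohortParams:
    """Tunable knobs of the synthetic cohort.

    ``sigma_cr``/``sigma_cys`` are lognormal error SDs on the eGFR/mGFR ratio
    scale; ``rho`` correlates the creatinine and cystatin error terms (shared
    non-GFR biology such as muscle mass and inflammation).
    """

    n: int = 1000
    seed: int = 0
    strata_props: Tuple[float, float, float, float] = (0.32, 0.30, 0.24, 0.14)
    #: (low, high) ml/min per stratum, ordered >90, 60–90, 30–60, <30
    strata_ranges: Tuple[Tuple[float, float], ...] = (
        (90.0, 125.0),
        (60.0, 90.0),
        (30.0, 60.0),
        (8.0, 30.0),
    )
    age_mean: float = 45.0
    age_sd: float = 14.0
    age_min: float = 18.0
    male_frac: float = 0.5
    #: Normal(mean, sd) height cm and weight kg per sex
    height_male: Tuple[float, float] = (175.0, 7.0)
    height_female: Tuple[float, float] = (162.0, 6.0)
    weight_male: Tuple[float, float] = (80.0, 12.0)
    weight_female: Tuple[float, float] = (66.0, 11.0)
    anchor_formula_cr: str = "aMDRD"
    anchor_formula_cys: str = "CKD-EPI-cy"
    sigma_cr: float = 0.20
    sigma_cys: float = 0.22
    rho: float = 0.3
    tkv_median: float = 1008.0
    tkv_log_sd: float = 0.83
    marker_bounds: Tuple[float, float] = (0.1, 25.0)
    inversion_tol: float = 1e-8
    max_resample: int = 50

    def __post_init__(self) -> None:
        if abs(sum(self.strata_props) - 1.0) > 1e-9:
            raise ValueError("strata_props must sum to 1")
        if self.sigma_cr < 0 or self.sigma_cys < 0:
            raise ValueError("sigmas must be non-negative")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError("rho must be in [-1, 1]")


def _truncated_normal(rng, mean, sd, low, size):
    out = rng.normal(mean, sd, size)
    bad = out < low
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = out < low
    return out


def _invert_anchor(formula_id, target_abs, age, male, weight, height, bounds, tol):
    """Bisection on the marker so the anchor's absolute eGFR equals target.

    The anchor is strictly decreasing in its marker, so targets inside
    [f(hi), f(lo)] have a unique root.  Returns (marker, ok) arrays.
    """
    spec = get_formula(formula_id)
    bsa_factor = du_bois_bsa(weight, height) / BSA_REF if spec.indexed_output else 1.0

    def f(marker):
        if spec.basis == "creatinine":
            raw = evaluate_kernel(formula_id, age, male, marker, None, weight)
        else:
            # cystatin anchor; pass a benign creatinine for 'both'-basis anchors
            raw = evaluate_kernel(formula_id, age, male, np.ones_like(marker), marker, weight)
        return raw * bsa_factor

    lo = np.full_like(target_abs, bounds[0])
    hi = np.full_like(target_abs, bounds[1])
    ok = (f(hi) <= target_abs) & (target_abs <= f(lo))
    for _ in range(64):
        mid = 0.5 * (lo + hi)
        high_side = f(mid) > target_abs  # marker too low -> eGFR too high
        lo = np.where(high_side, mid, lo)
        hi = np.where(high_side, hi, mid)
        if np.all(hi - lo < tol):
            break
    return 0.5 * (lo + hi), ok


def generate_cohort(params: CohortParams) -> list[PatientRecord]:
    """Draw a cohort; deterministic given ``params.seed``.

    Targets that fall outside the anchor formula's attainable range for any
    marker value in ``marker_bounds`` are resampled (fresh error draws) up to
    ``max_resample`` rounds; a residual failure raises.
    """
    n = params.n
    if n == 0:
        return []
    rng = np.random.default_rng(params.seed)

    stratum = rng.choice(4, size=n, p=params.strata_props)
    ranges = np.array(params.strata_ranges)
    mgfr = rng.uniform(ranges[stratum, 0], ranges[stratum, 1])

    age = _truncated_normal(rng, params.age_mean, params.age_sd, params.age_min, n)
    male = rng.random(n) < params.male_frac
    h_mean = np.where(male, params.height_male[0], params.height_female[0])
    h_sd = np.where(male, params.height_male[1], params.height_female[1])
    w_mean = np.where(male, params.weight_male[0], params.weight_female[0])
    w_sd = np.where(male, params.weight_male[1], params.weight_female[1])
    height = np.clip(rng.normal(h_mean, h_sd), 140.0, 210.0)
    weight = np.clip(rng.normal(w_mean, w_sd), 40.0, 160.0)
    tkv = params.tkv_median * np.exp(rng.normal(0.0, params.tkv_log_sd, n))

    cov = np.array(
        [
            [params.sigma_cr**2, params.rho * params.sigma_cr * params.sigma_cys],
            [params.rho * params.sigma_cr * params.sigma_cys, params.sigma_cys**2],
        ]
    )
    scr = np.empty(n)
    cysc = np.empty(n)
    pending = np.ones(n, dtype=bool)
    for _ in range(params.max_resample):
        idx = np.flatnonzero(pending)
        if idx.size == 0:
            break
        eps = rng.multivariate_normal([0.0, 0.0], cov, size=idx.size)
        target_cr = mgfr[idx] * np.exp(eps[:, 0])
        target_cys = mgfr[idx] * np.exp(eps[:, 1])
        s, ok_s = _invert_anchor(
            params.anchor_formula_cr, target_cr, age[idx], male[idx],
            weight[idx], height[idx], params.marker_bounds, params.inversion_tol,
        )
        c, ok_c = _invert_anchor(
            params.anchor_formula_cys, target_cys, age[idx], male[idx],
            weight[idx], height[idx], params.marker_bounds, params.inversion_tol,
        )
        good = ok_s & ok_c
        scr[idx[good]] = s[good]
        cysc[idx[good]] = c[good]
        pending[idx[good]] = False
    if pending.any():
        raise RuntimeError(
            f"{pending.sum()} subjects could not be inverted onto the marker range"
        )

    return [
        PatientRecord(
            id=f"S{i:05d}",
            age=float(age[i]),
            sex="male" if male[i] else "female",
            weight=float(weight[i]),
            height=float(height[i]),
            scr=float(scr[i]),
            cysc=float(cysc[i]),
            mgfr=float(mgfr[i]),
            tkv=float(tkv[i]),
        )
        for i in range(n)
    ]


def cohort_frame(records: Sequence[PatientRecord]) -> pd.DataFrame:
    """Cohort as a DataFrame with the canonical column order."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "age": r.age,
                "sex": r.sex,
                "weight": r.weight,
                "height": r.height,
                "scr": r.scr,
                "cysc": r.cysc,
                "mgfr": r.mgfr,
                "tkv": r.tkv,
            }
            for r in records
        ]
    )


def generate_iohexol_curves(
    records: Sequence[PatientRecord],
    schedule: Sequence[float] = (120.0, 150.0, 180.0, 240.0),
    noise_cv: float = 0.0,
    seed: int = 0,
    dose_mg: float = 3235.0,
    volume_ml: float = 15000.0,
    coeffs=BM_COEFFS,
) -> pd.DataFrame:
    """Mono-exponential iohexol sample tables consistent with each mGFR.

    The slope-intercept clearance is set to the one-pool *inverse* of the
    patient's mGFR, so running the measurement pipeline on a noise-free table
    returns mGFR to numerical precision.  ``volume_ml`` plays the role of the
    one-compartment distribution volume (c0 = dose/V, k = CL1/V).
    Multiplicative lognormal noise with coefficient of variation ``noise_cv``
    is mean-one, keeping recovery unbiased.  Long format: patient_id, dose_mg,
    t_min, conc_mg_L.
    """
    if len(schedule) < 2:
        raise ValueError("sampling schedule needs at least 2 time points")
    rng = np.random.default_rng(seed)
    t = np.asarray(schedule, dtype=float)
    rows = []
    sigma = np.sqrt(np.log1p(noise_cv**2)) if noise_cv > 0 else 0.0
    for r in records:
        if r.mgfr is None:
            raise ValueError(f"patient {r.id} has no mgfr")
        cl1 = one_pool_inverse(r.mgfr, coeffs)  # ml/min
        c0 = dose_mg / (volume_ml / 1000.0)  # mg/L
        k = cl1 / volume_ml  # 1/min
        conc = c0 * np.exp(-k * t)
        if sigma > 0:
            conc = conc * np.exp(rng.normal(-0.5 * sigma**2, sigma, len(t)))
        for ti, ci in zip(t, conc):
            rows.append(
                {"patient_id": r.id, "dose_mg": dose_mg, "t_min": float(ti),
                 "conc_mg_L": float(ci)}
            )
    return pd.DataFrame(rows)
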