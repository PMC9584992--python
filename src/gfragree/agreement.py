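"""Agreement statistics between measured and estimated GFR.

Three complementary indices quantify how well paired measurements agree:

* **CCC** — Lin's concordance correlation coefficient,
  ``2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)`` with moment (divisor-n) estimators.
  It multiplies Pearson precision by an accuracy penalty for location/scale
  shift; 1 is perfect agreement, values above ~0.90 are usually read as
  optimal concordance.  The estimator's mathematical range is [−1, 1].
* **TDI(p)** — the total deviation index: the boundary κ capturing a
  proportion p (default 0.90) of absolute paired differences.  The empirical
  estimator is the ⌈p·n⌉-th smallest |d| (no interpolation, smallest
  qualifying order statistic); the parametric one assumes Normal differences
  and uses the noncentral-χ² quantile.
* **cp(κ0)** — coverage probability: the proportion of differences within a
  pre-specified allowed boundary κ0 (default ±10%).

For GFR the error is proportional, so the pipeline works on log differences
ln(eGFR/mGFR) and back-transforms the TDI boundary to the percent scale,
``100·(e^κ − 1)``, which is read directly as "% of mGFR"; plain
percent-of-mGFR differences are available via ``scale``/``tdi_scale``.
Conservative one-sided bounds (lower for CCC and cp, upper for TDI) come from
a seeded pair-resampling percentile bootstrap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .formulas import compute_egfr_matrix, get_formula

__all__ = [
    "DifferenceSeries",
    "AgreementResult",
    "percent_differences",
    "ccc",
    "tdi_empirical",
    "tdi_parametric",
    "coverage_probability",
    "coverage_probability_parametric",
    "bootstrap_bound",
    "agreement_statistics",
    "agreement_table",
    "agreement_frame",
]


@dataclass(frozen=True)
class DifferenceSeries:
    """Aligned (mGFR, eGFR) pairs with their per-pair differences.

    ``scale`` is ``"percent_of_mgfr"`` (d = 100·(e−m)/m) or ``"log"``
    (d = 100·ln(e/m)).
    """

    mgfr: np.ndarray
    egfr: np.ndarray
    d: np.ndarray
    scale: str

    def __len__(self) -> int:
        return len(self.d)


def percent_differences(mgfr, egfr, scale: str = "percent_of_mgfr") -> DifferenceSeries:
    """Per-pair differences between estimated and measured GFR.

    percent_of_mgfr: ``100·(egfr − mgfr)/mgfr``; log: ``100·ln(egfr/mgfr)``.
    """
    m = np.asarray(mgfr, dtype=float)
    e = np.asarray(egfr, dtype=float)
    if m.shape != e.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {e.shape}")
    if np.any(m <= 0):
        raise ValueError("mgfr must be positive for relative differences")
    if scale == "percent_of_mgfr":
        d = 100.0 * (e - m) / m
    elif scale == "log":
        if np.any(e <= 0):
            raise ValueError("egfr must be positive on the log scale")
        d = 100.0 * np.log(e / m)
    else:
        raise ValueError(f"unknown scale {scale!r}")
    if not np.all(np.isfinite(d)):
        raise ValueError("differences must be finite")
    return DifferenceSeries(m, e, d, scale)


def ccc(x, y) -> float:
    """Lin's concordance correlation coefficient (moment estimators, divisor n)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d arrays of equal length")
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    sx2 = float(np.mean((x - mx) ** 2))
    sy2 = float(np.mean((y - my) ** 2))
    sxy = float(np.mean((x - mx) * (y - my)))
    denom = sx2 + sy2 + (mx - my) ** 2
    if denom == 0.0:
        raise ValueError("CCC undefined: zero variance in both series with equal means")
    return 2.0 * sxy / denom


def tdi_empirical(d, p: float = 0.90) -> float:
    """Empirical TDI: smallest κ with at least ⌈p·n⌉ of |d| ≤ κ.

    Order-statistic convention: the ⌈p·n⌉-th smallest absolute difference,
    with no interpolation.
    """
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference series")
    if not (0.0 < p < 1.0):
        raise ValueError("p must be in (0, 1)")
    a = np.sort(np.abs(d))
    k = math.ceil(p * d.size)
    return float(a[k - 1])


def tdi_parametric(mean_d: float, sd_d: float, p: float = 0.90) -> float:
    """Parametric TDI for Normal(mean_d, sd_d) differences.

    ``κ_p = sd·sqrt(q)`` with q the p-quantile of the noncentral χ²(1 df,
    noncentrality (mean/sd)²); reduces to ``sd·z_{(1+p)/2}`` at zero mean and
    to |mean| as sd → 0.
    """
    if sd_d < 0:
        raise ValueError("sd_d must be non-negative")
    if sd_d == 0:
        return abs(mean_d)
    nc = (mean_d / sd_d) ** 2
    return float(sd_d * np.sqrt(stats.ncx2.ppf(p, df=1, nc=nc)))


def coverage_probability(d, kappa0: float = 10.0) -> float:
    """Fraction of pairs with |d| ≤ κ0 (a proportion in [0, 1])."""
    d = np.asarray(d, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference series")
    if kappa0 <= 0:
        raise ValueError("kappa0 must be positive")
    return float(np.mean(np.abs(d) <= kappa0))


def coverage_probability_parametric(mean_d: float, sd_d: float, kappa0: float = 10.0) -> float:
    """Normal-model coverage: Φ((κ0−μ)/σ) − Φ((−κ0−μ)/σ)."""
    if sd_d <= 0:
        raise ValueError("sd_d must be positive")
    return float(
        stats.norm.cdf((kappa0 - mean_d) / sd_d) - stats.norm.cdf((-kappa0 - mean_d) / sd_d)
    )


def bootstrap_bound(
    statistic: Callable[[np.ndarray], float],
    data,
    B: int = 2000,
    seed: Optional[int] = None,
    level: float = 0.95,
    side: str = "lower",
) -> Tuple[float, float]:
    """Percentile-bootstrap conservative one-sided bound for a statistic.

    ``data`` is an array whose first axis indexes pairs (1-d differences or an
    (n, 2) pair matrix); rows are resampled with replacement.  ``side``
    selects the conservative direction: "lower" (CCC, cp) takes the
    (1−level)-quantile of the bootstrap distribution, "upper" (TDI) the
    level-quantile.  Returns ``(point_estimate, bound)``; fully reproducible
    given (seed, B).
    """
    data = np.asarray(data, dtype=float)
    n = data.shape[0]
    if n < 5:
        raise ValueError(f"refusing to bootstrap n = {n} < 5 pairs")
    if B < 100:
        raise ValueError("B must be at least 100")
    if seed is None:
        raise ValueError("an explicit seed is required for reproducibility")
    if side not in ("lower", "upper"):
        raise ValueError("side must be 'lower' or 'upper'")
    rng = np.random.default_rng(seed)
    est = float(statistic(data))
    boots = np.empty(B)
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        boots[b] = statistic(data[idx])
    q = 1.0 - level if side == "lower" else level
    return est, float(np.quantile(boots, q))


@dataclass(frozen=True)
class AgreementResult:
    """CCC/TDI/cp point estimates with conservative bounds for one formula."""

    formula_id: str
    basis: str
    ccc: float
    ccc_bound: float
    tdi: float  # percent of mGFR
    tdi_bound: float
    cp: float  # percent of pairs within ±kappa0
    cp_bound: float
    kappa0: float
    p: float
    n: int
    error: Optional[str] = None


def _tdi_percent_from_log(d_log_frac: np.ndarray, p: float) -> float:
    # d_log_frac = ln(e/m); boundary back-transformed to the percent scale
    kappa = tdi_empirical(d_log_frac, p)
    return 100.0 * (np.exp(kappa) - 1.0)


def agreement_statistics(
    mgfr,
    egfr,
    kappa0: float = 10.0,
    p: float = 0.90,
    B: int = 2000,
    seed: Optional[int] = None,
    level: float = 0.95,
    tdi_scale: str = "log",
    formula_id: str = "",
    basis: str = "",
) -> AgreementResult:
    """All three agreement indices with bootstrap bounds for one pair series.

    CCC is computed on the raw (mGFR, eGFR) pairs.  With ``tdi_scale="log"``
    (default) TDI and cp use log differences, back-transforming the TDI
    boundary to percent and testing cp against ln(1 + κ0/100); with
    ``"percent"`` both use d = 100·(e−m)/m directly.
    """
    m = np.asarray(mgfr, dtype=float)
    e = np.asarray(egfr, dtype=float)
    pairs = np.column_stack([m, e])

    if tdi_scale == "log":
        def tdi_stat(pr: np.ndarray) -> float:
            return _tdi_percent_from_log(np.log(pr[:, 1] / pr[:, 0]), p)

        kappa0_log = 100.0 * np.log1p(kappa0 / 100.0)

        def cp_stat(pr: np.ndarray) -> float:
            return 100.0 * coverage_probability(100.0 * np.log(pr[:, 1] / pr[:, 0]), kappa0_log)

    elif tdi_scale == "percent":
        def tdi_stat(pr: np.ndarray) -> float:
            return tdi_empirical(100.0 * (pr[:, 1] - pr[:, 0]) / pr[:, 0], p)

        def cp_stat(pr: np.ndarray) -> float:
            return 100.0 * coverage_probability(100.0 * (pr[:, 1] - pr[:, 0]) / pr[:, 0], kappa0)

    else:
        raise ValueError(f"unknown tdi_scale {tdi_scale!r}")

    def ccc_stat(pr: np.ndarray) -> float:
        return ccc(pr[:, 0], pr[:, 1])

    ss = np.random.SeedSequence(seed)
    s_ccc, s_tdi, s_cp = (int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(3))
    ccc_est, ccc_lo = bootstrap_bound(ccc_stat, pairs, B, s_ccc, level, "lower")
    tdi_est, tdi_hi = bootstrap_bound(tdi_stat, pairs, B, s_tdi, level, "upper")
    cp_est, cp_lo = bootstrap_bound(cp_stat, pairs, B, s_cp, level, "lower")
    return AgreementResult(
        formula_id, basis, ccc_est, ccc_lo, tdi_est, tdi_hi, cp_est, cp_lo,
        kappa0, p, len(m),
    )


def agreement_table(
    cohort: pd.DataFrame,
    formula_ids: Optional[Sequence[str]] = None,
    kappa0: float = 10.0,
    p: float = 0.90,
    B: int = 2000,
    seed: Optional[int] = None,
    tdi_scale: str = "log",
) -> list[AgreementResult]:
    """One :class:`AgreementResult` per formula against the cohort's mGFR.

    Per-formula failures (missing marker, degenerate data) are returned as
    flagged rows with ``error`` set, never raised.
    """
    from .formulas import list_formulas

    if formula_ids is None:
        formula_ids = [s.formula_id for s in list_formulas()]
    if "mgfr" not in cohort.columns:
        raise ValueError("cohort has no 'mgfr' column")
    mgfr = cohort["mgfr"].to_numpy(dtype=float)
    egfr_mat = compute_egfr_matrix(cohort, formula_ids)
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(len(formula_ids))]
    results = []
    for fid, fseed in zip(formula_ids, child_seeds):
        basis = get_formula(fid).basis
        e = egfr_mat[fid].to_numpy()
        try:
            if np.any(~np.isfinite(e)):
                raise ValueError("formula could not be evaluated (missing marker?)")
            results.append(
                agreement_statistics(
                    mgfr, e, kappa0, p, B, fseed, tdi_scale=tdi_scale,
                    formula_id=fid, basis=basis,
                )
            )
        except (ValueError, KeyError) as exc:
            results.append(
                AgreementResult(fid, basis, *(np.nan,) * 6, kappa0, p, len(mgfr), str(exc))
            )
    return results


def agreement_frame(results: Sequence[AgreementResult], rounded: bool = True) -> pd.DataFrame:
    """Tabulate results; ``rounded`` applies the display convention
    (CCC to 2 decimals, TDI and cp to integers)."""
    df = pd.DataFrame(
        [
            {
                "formula_id": r.formula_id,
                "basis": r.basis,
                "ccc": r.ccc,
                "ccc_bound": r.ccc_bound,
                "tdi": r.tdi,
                "tdi_bound": r.tdi_bound,
                "cp": r.cp,
                "cp_bound": r.cp_bound,
                "n": r.n,
                "error": r.error or "",
            }
            for r in results
        ]
    )
    if rounded:
        for col in ("ccc", "ccc_bound"):
            df[col] = df[col].round(2)
        for col in ("tdi", "tdi_bound", "cp", "cp_bound"):
            df[col] = df[col].round(0)
    return df
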