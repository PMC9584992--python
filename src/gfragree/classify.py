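"""CKD staging, GFR-threshold misclassification, and error-band distributions.

The clinical stakes of eGFR error in ADPKD concentrate around treatment
thresholds: tolvaptan is avoided below 30 ml/min, some payers require eGFR
above 45 ml/min/1.73 m² for reimbursement, and treatment is not recommended
between ages 55 and 60 with GFR above 60 ml/min.  This module counts, for a
given formula, how often estimation error moves a patient across those lines,
and summarises the error magnitude in <10 / 10–20 / 20–30 / >30 % bands.

A bundled reference dataset (``load_example_pairs``) of 14 ADPKD patients
grouped in pairs of similar measured GFR, each with four eGFR values, serves
as a small worked fixture for the threshold counting.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, Tuple

import numpy as np
import pandas as pd

__all__ = [
    "MisclassificationReport",
    "ErrorBandDistribution",
    "kdigo_stage",
    "strata_distribution",
    "threshold_misclassification",
    "misclassification_by_formula",
    "error_band_distribution",
    "tolvaptan_flags",
    "load_example_pairs",
]

#: default GFR band (ml/min) for the "just above threshold" undercall analysis
DEFAULT_BAND: Tuple[float, float] = (30.0, 40.0)

ERROR_BAND_EDGES = (10.0, 20.0, 30.0)
ERROR_BAND_LABELS = ("<10", "10-20", "20-30", ">30")


def kdigo_stage(gfr: float) -> str:
    """KDIGO GFR category: G1 ≥90, G2 [60,90), G3a [45,60), G3b [30,45),
    G4 [15,30), G5 <15 ml/min."""
    if gfr < 0:
        raise ValueError(f"gfr must be non-negative, got {gfr}")
    if gfr >= 90:
        return "G1"
    if gfr >= 60:
        return "G2"
    if gfr >= 45:
        return "G3a"
    if gfr >= 30:
        return "G3b"
    if gfr >= 15:
        return "G4"
    return "G5"


def strata_distribution(mgfr) -> np.ndarray:
    """Cohort fractions in the four mGFR strata >90, [60,90], [30,60), <30.

    Boundary convention: 90 and 60 belong to the middle stratum [60, 90],
    30 to [30, 60).  Fractions sum to 1.
    """
    m = np.asarray(mgfr, dtype=float)
    if m.size == 0:
        raise ValueError("empty mgfr series")
    f = np.array(
        [
            np.mean(m > 90),
            np.mean((m >= 60) & (m <= 90)),
            np.mean((m >= 30) & (m < 60)),
            np.mean(m < 30),
        ]
    )
    return f


@dataclass(frozen=True)
class MisclassificationReport:
    """Counts around a GFR treatment threshold for one eGFR series.

    Among patients truly below ``threshold`` (by mGFR): how many the formula
    estimates at or above it (overcalls that could wrongly permit treatment).
    Among patients with mGFR inside ``[band_lo, band_hi]``: how many the
    formula estimates below threshold (undercalls that could wrongly deny it).
    """

    threshold: float
    n_below_by_mgfr: int
    n_below_estimated_above: int
    pct_below_estimated_above: float
    band_lo: float
    band_hi: float
    n_in_band: int
    n_band_estimated_below: int
    pct_band_estimated_below: float
    n: int

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}


def threshold_misclassification(
    mgfr, egfr, threshold: float = 30.0, band: Tuple[float, float] = DEFAULT_BAND
) -> MisclassificationReport:
    """Count threshold crossings between measured and estimated GFR."""
    m = np.asarray(mgfr, dtype=float)
    e = np.asarray(egfr, dtype=float)
    if m.shape != e.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {e.shape}")
    lo, hi = band
    below = m < threshold
    n_below = int(below.sum())
    over = int(np.sum(below & (e >= threshold)))
    in_band = (m >= lo) & (m <= hi)
    n_band = int(in_band.sum())
    under = int(np.sum(in_band & (e < threshold)))
    return MisclassificationReport(
        threshold=threshold,
        n_below_by_mgfr=n_below,
        n_below_estimated_above=over,
        pct_below_estimated_above=100.0 * over / n_below if n_below else 0.0,
        band_lo=lo,
        band_hi=hi,
        n_in_band=n_band,
        n_band_estimated_below=under,
        pct_band_estimated_below=100.0 * under / n_band if n_band else 0.0,
        n=len(m),
    )


def misclassification_by_formula(
    mgfr, egfr_matrix: pd.DataFrame, threshold: float = 30.0,
    band: Tuple[float, float] = DEFAULT_BAND,
) -> Dict[str, MisclassificationReport]:
    """Per-formula breakdown over an eGFR matrix (one column per formula)."""
    out = {}
    for fid in egfr_matrix.columns:
        e = egfr_matrix[fid].to_numpy(dtype=float)
        if np.any(~np.isfinite(e)):
            continue
        out[fid] = threshold_misclassification(mgfr, e, threshold, band)
    return out


@dataclass(frozen=True)
class ErrorBandDistribution:
    """Fractions of estimations with |d_pct| in [0,10), [10,20), [20,30), [30,∞)."""

    fractions: np.ndarray
    labels: Tuple[str, ...] = ERROR_BAND_LABELS

    def __post_init__(self) -> None:
        if abs(float(self.fractions.sum()) - 1.0) > 1e-9:
            raise ValueError("error-band fractions must sum to 1")

    def to_dict(self) -> dict:
        return dict(zip(self.labels, (float(f) for f in self.fractions)))


def error_band_distribution(d_pct) -> ErrorBandDistribution:
    """Partition absolute percent errors into left-closed bands <10, 10–20,
    20–30, >30."""
    d = np.asarray(d_pct, dtype=float)
    if d.size == 0:
        raise ValueError("empty difference series")
    a = np.abs(d)
    edges = np.concatenate([[0.0], ERROR_BAND_EDGES, [np.inf]])
    counts, _ = np.histogram(a, bins=edges)
    return ErrorBandDistribution(counts / d.size)


def tolvaptan_flags(
    age: float,
    gfr: float,
    cutoff: float = 30.0,
    reimbursement: float = 45.0,
    age_window: Tuple[float, float] = (55.0, 60.0),
    gfr_high: float = 60.0,
) -> dict:
    """Informational eligibility flags at guideline GFR/age thresholds.

    ``below_cutoff_30``: GFR below the avoid-treatment cut-off;
    ``reimbursable_45``: GFR above the reimbursement threshold;
    ``not_recommended_55_60_gfr60``: age within [55, 60] with GFR above 60.
    Not clinical advice; thresholds configurable.
    """
    if age < 18:
        raise ValueError("adult cohort: age must be >= 18")
    if gfr < 0:
        raise ValueError("gfr must be non-negative")
    return {
        "below_cutoff_30": gfr < cutoff,
        "reimbursable_45": gfr > reimbursement,
        "not_recommended_55_60_gfr60": age_window[0] <= age <= age_window[1] and gfr > gfr_high,
    }


def load_example_pairs() -> pd.DataFrame:
    """Bundled 14-patient reference dataset: measured GFR plus four eGFR
    columns (amdrd, ckdepi_cr, ckdepi_cy, ckdepi_crcy), patients grouped in
    pairs of similar mGFR from 16 to 95 ml/min."""
    with resources.files("gfragree.data").joinpath("example_pairs.csv").open() as fh:
        return pd.read_csv(fh)
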