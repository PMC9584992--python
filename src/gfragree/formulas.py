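"""eGFR formula library: equation registry, anthropometrics, and BSA (un-)indexing.

Glomerular filtration rate (GFR) is estimated from serum creatinine (mg/dL,
IDMS-traceable) and/or cystatin C (mg/L) by published equations.  Most published
equations return GFR indexed to 1.73 m² of body surface area; this package works
throughout in absolute ml/min, so indexed outputs are un-adjusted with the
patient's Du Bois BSA:

    GFR_absolute = GFR_indexed * BSA / 1.73

The registry ships the twelve equations used in the agreement pipeline and is
extensible via :func:`register_formula`.  Every evaluator is a vectorised numpy
kernel; :func:`compute_egfr` evaluates one patient, :func:`compute_egfr_matrix`
a whole cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatientRecord",
    "FormulaSpec",
    "compute_egfr",
    "compute_egfr_matrix",
    "du_bois_bsa",
    "unadjust_bsa",
    "adjust_bsa",
    "ellipsoid_tkv",
    "register_formula",
    "get_formula",
    "list_formulas",
    "registry_to_json",
]

#: mg/dL -> µmol/L for creatinine (molar mass 113.12 g/mol)
CREATININE_MGDL_TO_UMOL = 88.4

#: reference body surface area, m²
BSA_REF = 1.73


class ValidationError(ValueError):
    """Raised when an input record or table violates a domain invariant."""


@dataclass(frozen=True)
class PatientRecord:
    """One subject: demographics, serum markers, measured GFR, optional TKV.

    Units: age years, weight kg, height cm, scr mg/dL, cysc mg/L,
    mgfr ml/min (absolute, not BSA-indexed), tkv ml.
    """

    id: str
    age: float
    sex: str  # "male" | "female"
    weight: float
    height: float
    scr: float
    cysc: Optional[float] = None
    mgfr: Optional[float] = None
    tkv: Optional[float] = None
    black: bool = False

    def __post_init__(self) -> None:
        if self.sex not in ("male", "female"):
            raise ValidationError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.age < 18:
            raise ValidationError(f"patient {self.id}: age {self.age} < 18 (adult cohort)")
        for name in ("weight", "height", "scr"):
            v = getattr(self, name)
            if not (v > 0 and np.isfinite(v)):
                raise ValidationError(f"patient {self.id}: {name} must be positive, got {v}")
        if self.cysc is not None and not (self.cysc > 0 and np.isfinite(self.cysc)):
            raise ValidationError(f"patient {self.id}: cysc must be positive, got {self.cysc}")
        if self.mgfr is not None and self.mgfr < 0:
            raise ValidationError(f"patient {self.id}: mgfr must be >= 0, got {self.mgfr}")

    @property
    def male(self) -> bool:
        return self.sex == "male"

    @property
    def bsa(self) -> float:
        return du_bois_bsa(self.weight, self.height)


# A kernel evaluates the published equation on (possibly array) inputs and
# returns the value on the equation's native scale (indexed or absolute).
Kernel = Callable[..., np.ndarray]


@dataclass(frozen=True)
class FormulaSpec:
    """A registered eGFR equation.

    ``indexed_output`` is True when the published equation returns
    ml/min/1.73 m² (and thus needs BSA un-adjustment for absolute ml/min).
    """

    formula_id: str
    basis: str  # "creatinine" | "cystatin" | "both"
    indexed_output: bool
    citation: str
    kernel: Kernel = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if self.basis not in ("creatinine", "cystatin", "both"):
            raise ValueError(f"unknown basis {self.basis!r}")


_REGISTRY: dict[str, FormulaSpec] = {}


def register_formula(formula_id: str, basis: str, indexed_output: bool, citation: str):
    """Decorator adding an equation kernel to the registry.

    The kernel signature is ``kernel(age, male, scr, cysc, weight, black)``
    with numpy-broadcastable arguments (``male``/``black`` boolean).
    """

    def deco(kernel: Kernel) -> Kernel:
        if formula_id in _REGISTRY:
            raise ValueError(f"formula_id {formula_id!r} already registered")
        _REGISTRY[formula_id] = FormulaSpec(formula_id, basis, indexed_output, citation, kernel)
        return kernel

    return deco


def get_formula(formula_id: str) -> FormulaSpec:
    try:
        return _REGISTRY[formula_id]
    except KeyError:
        raise KeyError(
            f"unknown formula {formula_id!r}; registered: {sorted(_REGISTRY)}"
        ) from None


def list_formulas() -> list[FormulaSpec]:
    return list(_REGISTRY.values())


def registry_to_json() -> list[dict]:
    """Registry metadata (id, basis, indexed_output, citation) as JSON-ready dicts."""
    return [
        {
            "formula_id": s.formula_id,
            "basis": s.basis,
            "indexed_output": s.indexed_output,
            "citation": s.citation,
        }
        for s in _REGISTRY.values()
    ]


# ---------------------------------------------------------------------------
# anthropometrics
# ---------------------------------------------------------------------------

def du_bois_bsa(weight, height):
    """Du Bois & Du Bois body surface area, m².

    ``0.007184 * weight^0.425 * height^0.725`` with weight in kg, height in cm.
    """
    weight = np.asarray(weight, dtype=float)
    height = np.asarray(height, dtype=float)
    if np.any(weight <= 0) or np.any(height <= 0):
        raise ValidationError("weight and height must be positive")
    out = 0.007184 * weight**0.425 * height**0.725
    return float(out) if out.ndim == 0 else out


def unadjust_bsa(egfr_indexed, bsa):
    """Convert ml/min/1.73 m² to absolute ml/min: ``egfr * bsa / 1.73``."""
    bsa = np.asarray(bsa, dtype=float)
    if np.any(bsa <= 0):
        raise ValidationError("bsa must be positive")
    out = np.asarray(egfr_indexed, dtype=float) * bsa / BSA_REF
    return float(out) if out.ndim == 0 else out


def adjust_bsa(egfr_absolute, bsa):
    """Index absolute ml/min to ml/min/1.73 m²; exact inverse of :func:`unadjust_bsa`."""
    bsa = np.asarray(bsa, dtype=float)
    if np.any(bsa <= 0):
        raise ValidationError("bsa must be positive")
    out = np.asarray(egfr_absolute, dtype=float) * BSA_REF / bsa
    return float(out) if out.ndim == 0 else out


def ellipsoid_tkv(kidneys: Iterable[Sequence[float]]) -> float:
    """Total kidney volume (ml) by the ellipsoid method.

    Each kidney contributes ``pi/6 * L * W * D`` with the three largest
    orthogonal diameters in cm (1 cm³ = 1 ml).
    """
    total = 0.0
    for dims in kidneys:
        l, w, d = (float(x) for x in dims)
        if l < 0 or w < 0 or d < 0:
            raise ValidationError("kidney diameters must be non-negative")
        total += np.pi / 6.0 * l * w * d
    return total


# ---------------------------------------------------------------------------
# equation kernels (each transcribed from its primary publication)
# ---------------------------------------------------------------------------

def _female(male, value):
    return np.where(male, 1.0, value)


@register_formula(
    "aMDRD", "creatinine", True,
    "Levey et al. 2006, abbreviated MDRD re-expressed for IDMS-traceable creatinine",
)
def _amdrd(age, male, scr, cysc, weight, black):
    return (
        175.0 * scr**-1.154 * age**-0.203
        * _female(male, 0.742)
        * np.where(black, 1.212, 1.0)
    )


@register_formula(
    "CKD-EPI-cr", "creatinine", True,
    "Levey et al. 2009, CKD-EPI creatinine equation",
)
def _ckdepi_cr(age, male, scr, cysc, weight, black):
    kappa = np.where(male, 0.9, 0.7)
    alpha = np.where(male, -0.411, -0.329)
    r = scr / kappa
    return (
        141.0
        * np.minimum(r, 1.0) ** alpha
        * np.maximum(r, 1.0) ** -1.209
        * 0.993**age
        * _female(male, 1.018)
        * np.where(black, 1.159, 1.0)
    )


@register_formula(
    "CKD-EPI-cy", "cystatin", True,
    "Inker et al. 2012, CKD-EPI cystatin C equation",
)
def _ckdepi_cy(age, male, scr, cysc, weight, black):
    r = cysc / 0.8
    return (
        133.0
        * np.minimum(r, 1.0) ** -0.499
        * np.maximum(r, 1.0) ** -1.328
        * 0.996**age
        * _female(male, 0.932)
    )


@register_formula(
    "CKD-EPI-cr-cy", "both", True,
    "Inker et al. 2012, CKD-EPI creatinine-cystatin C equation",
)
def _ckdepi_crcy(age, male, scr, cysc, weight, black):
    kappa = np.where(male, 0.9, 0.7)
    alpha = np.where(male, -0.207, -0.248)
    rc = scr / kappa
    ry = cysc / 0.8
    return (
        135.0
        * np.minimum(rc, 1.0) ** alpha
        * np.maximum(rc, 1.0) ** -0.601
        * np.minimum(ry, 1.0) ** -0.375
        * np.maximum(ry, 1.0) ** -0.711
        * 0.995**age
        * _female(male, 0.969)
        * np.where(black, 1.08, 1.0)
    )


@register_formula(
    "Cockcroft-Gault", "creatinine", False,
    "Cockcroft & Gault 1976, creatinine clearance estimate (ml/min)",
)
def _cockcroft_gault(age, male, scr, cysc, weight, black):
    return (140.0 - age) * weight / (72.0 * scr) * _female(male, 0.85)


def _fas_age_factor(age):
    # FAS decline term applies only after age 40
    return np.where(age > 40, 0.988 ** (np.asarray(age, dtype=float) - 40.0), 1.0)


@register_formula(
    "FAS-cr", "creatinine", True,
    "Pottel et al. 2016, full-age-spectrum creatinine equation",
)
def _fas_cr(age, male, scr, cysc, weight, black):
    q = np.where(male, 0.90, 0.70)
    return 107.3 / (scr / q) * _fas_age_factor(age)


def _fas_qcys(age):
    return np.where(np.asarray(age, dtype=float) < 70, 0.82, 0.95)


@register_formula(
    "FAS-cy", "cystatin", True,
    "Pottel et al. 2017, full-age-spectrum cystatin C equation",
)
def _fas_cy(age, male, scr, cysc, weight, black):
    return 107.3 / (cysc / _fas_qcys(age)) * _fas_age_factor(age)


@register_formula(
    "FAS-cr-cy", "both", True,
    "Pottel et al. 2017, full-age-spectrum combined equation (equal weights)",
)
def _fas_crcy(age, male, scr, cysc, weight, black):
    qcr = np.where(male, 0.90, 0.70)
    denom = 0.5 * scr / qcr + 0.5 * cysc / _fas_qcys(age)
    return 107.3 / denom * _fas_age_factor(age)


@register_formula(
    "Lund-Malmö (Rv)", "creatinine", True,
    "Björk et al. 2011, revised Lund-Malmö equation (creatinine in µmol/L)",
)
def _lund_malmo_rev(age, male, scr, cysc, weight, black):
    p = np.asarray(scr, dtype=float) * CREATININE_MGDL_TO_UMOL
    age = np.asarray(age, dtype=float)
    x_f = np.where(p < 150.0, 2.50 + 0.0121 * (150.0 - p), 2.50 - 0.926 * np.log(p / 150.0))
    x_m = np.where(p < 180.0, 2.56 + 0.00968 * (180.0 - p), 2.56 - 0.926 * np.log(p / 180.0))
    x = np.where(male, x_m, x_f)
    return np.exp(x - 0.0158 * age + 0.438 * np.log(age))


@register_formula(
    "Grubb-2014 (CAPA)", "cystatin", True,
    "Grubb et al. 2014, CAPA equation",
)
def _grubb_capa(age, male, scr, cysc, weight, black):
    return 130.0 * cysc**-1.069 * np.asarray(age, dtype=float) ** -0.117 - 7.0


@register_formula(
    "Hoek", "cystatin", True,
    "Hoek et al. 2003, cystatin C equation",
)
def _hoek(age, male, scr, cysc, weight, black):
    return -4.32 + 80.35 / cysc


@register_formula(
    "Larsson", "cystatin", False,
    "Larsson et al. 2004, cystatin C equation against absolute iohexol clearance",
)
def _larsson(age, male, scr, cysc, weight, black):
    return 77.24 * cysc**-1.2623


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _check_markers(spec: FormulaSpec, scr, cysc) -> None:
    if spec.basis in ("creatinine", "both"):
        if scr is None or np.any(~np.isfinite(np.asarray(scr, dtype=float))):
            raise ValidationError(f"{spec.formula_id}: serum creatinine required")
        if np.any(np.asarray(scr, dtype=float) <= 0):
            raise ValidationError(f"{spec.formula_id}: creatinine must be positive")
    if spec.basis in ("cystatin", "both"):
        if cysc is None or np.any(~np.isfinite(np.asarray(cysc, dtype=float))):
            raise ValidationError(f"{spec.formula_id}: cystatin C required")
        if np.any(np.asarray(cysc, dtype=float) <= 0):
            raise ValidationError(f"{spec.formula_id}: cystatin C must be positive")


def evaluate_kernel(formula_id: str, age, male, scr, cysc=None, weight=None, black=False):
    """Evaluate an equation on array inputs, on its native (published) scale."""
    spec = get_formula(formula_id)
    _check_markers(spec, scr, cysc)
    cys = np.nan if cysc is None else np.asarray(cysc, dtype=float)
    return spec.kernel(
        np.asarray(age, dtype=float),
        np.asarray(male),
        np.asarray(scr, dtype=float) if scr is not None else np.nan,
        cys,
        np.asarray(weight, dtype=float) if weight is not None else np.nan,
        np.asarray(black),
    )


def compute_egfr(formula_id: str, patient: PatientRecord, indexed: bool = False) -> float:
    """Estimated GFR for one patient.

    By default returns absolute ml/min: equations publishing an indexed value
    are un-adjusted with the patient's Du Bois BSA.  ``indexed=True`` returns
    ml/min/1.73 m² instead (converting absolute-output equations with the same
    BSA).
    """
    spec = get_formula(formula_id)
    raw = float(
        evaluate_kernel(
            formula_id, patient.age, patient.male, patient.scr, patient.cysc,
            patient.weight, patient.black,
        )
    )
    if spec.indexed_output and not indexed:
        return unadjust_bsa(raw, patient.bsa)
    if not spec.indexed_output and indexed:
        return adjust_bsa(raw, patient.bsa)
    return raw


def compute_egfr_matrix(
    cohort: pd.DataFrame, formula_ids: Optional[Sequence[str]] = None, indexed: bool = False
) -> pd.DataFrame:
    """Evaluate many equations over a cohort table.

    ``cohort`` needs columns age, sex, weight, height, scr (and cysc for
    cystatin-based equations; optional boolean ``black``).  Returns a frame
    indexed like ``cohort`` with one column per formula; formulas whose
    required marker column is absent are skipped with a NaN column.
    """
    if formula_ids is None:
        formula_ids = [s.formula_id for s in list_formulas()]
    male = cohort["sex"].to_numpy() == "male"
    black = cohort["black"].to_numpy() if "black" in cohort else np.zeros(len(cohort), bool)
    bsa = du_bois_bsa(cohort["weight"].to_numpy(), cohort["height"].to_numpy())
    has_cysc = "cysc" in cohort.columns and cohort["cysc"].notna().all()
    out = {}
    for fid in formula_ids:
        spec = get_formula(fid)
        if spec.basis in ("cystatin", "both") and not has_cysc:
            out[fid] = np.full(len(cohort), np.nan)
            continue
        raw = evaluate_kernel(
            fid, cohort["age"].to_numpy(), male, cohort["scr"].to_numpy(),
            cohort["cysc"].to_numpy() if "cysc" in cohort else None,
            cohort["weight"].to_numpy(), black,
        )
        if spec.indexed_output and not indexed:
            raw = raw * bsa / BSA_REF
        elif not spec.indexed_output and indexed:
            raw = raw * BSA_REF / bsa
        out[fid] = np.asarray(raw, dtype=float)
    return pd.DataFrame(out, index=cohort.index)
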