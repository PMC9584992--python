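"""End-to-end orchestration: cohort → eGFR matrix → agreement → classification.

A :class:`RunConfig` fully determines a run; the same config (including seed)
produces byte-identical artifacts.  Artifacts written to ``out_dir``:

* ``cohort.csv``        — the input cohort (written when synthesised)
* ``egfr_matrix.csv``   — id, mgfr, one absolute-ml/min column per formula
* ``agreement_table.csv`` — formula_id, basis, CCC, TDI, cp with bounds
* ``misclassification.json`` — per-formula threshold crossing counts
* ``error_bands.csv``   — per-formula error-magnitude distribution
* ``scatter_data.csv``  — long-format (formula, mgfr, egfr) pairs for plotting
* ``manifest.json``     — seed, config hash, package + dependency versions
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Tuple

import numpy as np
import pandas as pd

from . import __version__
from .agreement import agreement_frame, agreement_table
from .classify import (
    DEFAULT_BAND,
    error_band_distribution,
    misclassification_by_formula,
    strata_distribution,
)
from .formulas import PatientRecord, ValidationError, compute_egfr_matrix, get_formula, list_formulas
from .synth import CohortParams, cohort_frame, generate_cohort

__all__ = ["RunConfig", "run_pipeline", "read_cohort_csv", "write_cohort_csv"]

log = logging.getLogger("gfragree")

FLOAT_FMT = "%.6g"

COHORT_COLUMNS = ("id", "age", "sex", "weight", "height", "scr", "cysc", "mgfr", "tkv")
REQUIRED_COLUMNS = ("id", "age", "sex", "weight", "height", "scr", "mgfr")


@dataclass(frozen=True)
class RunConfig:
    """Everything an end-to-end run needs; hashable to a manifest digest."""

    seed: int
    cohort_path: Optional[str] = None  # None -> synthesise
    synth: CohortParams = field(default_factory=CohortParams)
    formula_ids: Optional[Tuple[str, ...]] = None  # None -> all registered
    bootstrap_B: int = 2000
    kappa0: float = 10.0
    coverage_p: float = 0.90
    threshold: float = 30.0
    band: Tuple[float, float] = DEFAULT_BAND
    tdi_scale: str = "log"
    out_dir: str = "gfragree_run"

    def semantic_dict(self) -> dict:
        """Config fields that determine results (out_dir is presentation only)."""
        d = asdict(self)
        d.pop("out_dir")
        return d

    def config_hash(self) -> str:
        payload = json.dumps(self.semantic_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def read_cohort_csv(path) -> pd.DataFrame:
    """Read and validate a cohort table.

    Required columns: id, age, sex, weight, height, scr, mgfr; optional cysc,
    tkv, black.  Decimal point notation, absolute ml/min for mgfr.  Raises
    :class:`ValidationError` naming the offending row/column.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"cohort file missing columns: {missing}")
    dup = df["id"].astype(str)[df["id"].astype(str).duplicated()]
    if len(dup):
        raise ValidationError(f"duplicate patient id(s): {sorted(set(dup))}")
    for col in ("age", "weight", "height", "scr", "mgfr"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad)[0])
            raise ValidationError(f"non-numeric value in column {col!r}, row {row}")
        if df[col].isna().any():
            row = int(np.flatnonzero(df[col].isna())[0])
            raise ValidationError(f"missing value in column {col!r}, row {row}")
        df[col] = pd.to_numeric(df[col])
    if "cysc" in df.columns:
        df["cysc"] = pd.to_numeric(df["cysc"], errors="raise")
    # validate records via the domain type
    for _, row in df.iterrows():
        PatientRecord(
            id=str(row["id"]), age=row["age"], sex=row["sex"], weight=row["weight"],
            height=row["height"], scr=row["scr"],
            cysc=row.get("cysc") if "cysc" in df.columns and pd.notna(row.get("cysc")) else None,
            mgfr=row["mgfr"],
        )
    return df


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in df.columns]
    df.to_csv(path, index=False, columns=cols, float_format=FLOAT_FMT)


def _selected_formulas(config: RunConfig, cohort: pd.DataFrame) -> Tuple[list, list]:
    """Split requested formulas into runnable and skipped (missing marker)."""
    fids = list(config.formula_ids) if config.formula_ids else [
        s.formula_id for s in list_formulas()
    ]
    has_cysc = "cysc" in cohort.columns and cohort["cysc"].notna().all()
    runnable, skipped = [], []
    for fid in fids:
        if get_formula(fid).basis in ("cystatin", "both") and not has_cysc:
            skipped.append(fid)
        else:
            runnable.append(fid)
    return runnable, skipped


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and write artifacts; returns paths + key frames."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.cohort_path is None:
        params = (
            config.synth if config.synth.seed == config.seed
            else CohortParams(**{**asdict(config.synth), "seed": config.seed})
        )
        records = generate_cohort(params)
        cohort = cohort_frame(records)
        write_cohort_csv(cohort, out / "cohort.csv")
        log.info("stage=synth n=%d seed=%d", len(cohort), config.seed)
    else:
        cohort = read_cohort_csv(config.cohort_path)
        log.info("stage=read_cohort n=%d path=%s", len(cohort), config.cohort_path)

    runnable, skipped = _selected_formulas(config, cohort)
    for fid in skipped:
        log.warning("stage=egfr formula=%s skipped=missing_cystatin", fid)

    egfr = compute_egfr_matrix(cohort, runnable)
    egfr_out = pd.concat(
        [cohort[["id"]].reset_index(drop=True), cohort[["mgfr"]].reset_index(drop=True),
         egfr.reset_index(drop=True)], axis=1,
    )
    egfr_out.to_csv(out / "egfr_matrix.csv", index=False, float_format=FLOAT_FMT)
    log.info("stage=egfr n=%d formulas=%d", len(egfr), len(runnable))

    results = agreement_table(
        cohort, runnable, kappa0=config.kappa0, p=config.coverage_p,
        B=config.bootstrap_B, seed=config.seed, tdi_scale=config.tdi_scale,
    )
    agree_df = agreement_frame(results, rounded=True)
    for fid in skipped:
        agree_df.loc[len(agree_df)] = {
            "formula_id": fid, "basis": get_formula(fid).basis, "n": len(cohort),
            "error": "skipped: cystatin C column missing",
            **{c: np.nan for c in ("ccc", "ccc_bound", "tdi", "tdi_bound", "cp", "cp_bound")},
        }
    agree_df.to_csv(out / "agreement_table.csv", index=False, float_format=FLOAT_FMT)
    log.info("stage=agreement rows=%d", len(agree_df))

    mgfr = cohort["mgfr"].to_numpy(dtype=float)
    misrep = misclassification_by_formula(mgfr, egfr, config.threshold, config.band)
    mis_json = {
        "threshold": config.threshold,
        "band": list(config.band),
        "strata_fractions": [round(float(f), 6) for f in strata_distribution(mgfr)],
        "per_formula": {fid: rep.to_dict() for fid, rep in misrep.items()},
    }
    (out / "misclassification.json").write_text(json.dumps(mis_json, indent=2, sort_keys=True))
    log.info("stage=misclassification formulas=%d", len(misrep))

    band_rows = []
    for fid in runnable:
        d_pct = 100.0 * (egfr[fid].to_numpy() - mgfr) / mgfr
        dist = error_band_distribution(d_pct)
        band_rows.append({"formula_id": fid, **dist.to_dict()})
    bands_df = pd.DataFrame(band_rows)
    bands_df.to_csv(out / "error_bands.csv", index=False, float_format=FLOAT_FMT)

    scatter = egfr_out.melt(
        id_vars=["id", "mgfr"], var_name="formula_id", value_name="egfr"
    )
    scatter.to_csv(out / "scatter_data.csv", index=False, float_format=FLOAT_FMT)

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.semantic_dict(),
        "versions": {
            "gfragree": __version__,
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "n_patients": int(len(cohort)),
        "formulas_run": runnable,
        "formulas_skipped": skipped,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    log.info("stage=manifest hash=%s", manifest["config_hash"])

    return {
        "out_dir": out,
        "cohort": cohort,
        "egfr_matrix": egfr_out,
        "agreement": agree_df,
        "misclassification": mis_json,
        "error_bands": bands_df,
        "manifest": manifest,
    }
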