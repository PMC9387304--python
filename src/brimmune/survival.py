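"""Multivariable Cox proportional-hazards survival association.

Overall survival is modeled from three alternative time origins — primary
diagnosis, first metastatic diagnosis, or brain-metastasis diagnosis —
with cancer stage (ordinal-linear by default), age at primary diagnosis,
and race (one-hot, largest group as reference) as the clinical base
model.  Gene-signature scores (or TMB) enter one at a time alongside the
base covariates, producing forest-plot-ready hazard ratios with Wald 95%
confidence intervals.  Ties are handled with the Efron approximation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .io_formats import STAGES, ClinicalRecord

logger = logging.getLogger(__name__)

ORIGINS = ("primary_dx", "any_met_dx", "brm_dx")
_ORIGIN_FIELD = {
    "primary_dx": "t_primary_dx",
    "any_met_dx": "t_met_dx",
    "brm_dx": "t_brm_dx",
}

STAGE_ORDINAL = {s: i + 1 for i, s in enumerate(STAGES)}


@dataclass(frozen=True)
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    converged: bool = True
    note: str = ""


def build_survival_table(
    clinical: Sequence[ClinicalRecord],
    origin: str,
    scores: Optional[Mapping[str, float]] = None,
    score_name: str = "signature_score",
    stage_coding: str = "ordinal",
) -> pd.DataFrame:
    """Per-patient survival rows for one time origin.

    Time is (event-or-censoring date − origin date) in days.  Patients
    lacking the origin date (or, when ``scores`` is given, a score) are
    excluded with a logged count.  Race is one-hot encoded with the
    largest group as reference; stage is ordinal-linear (I..IV -> 1..4)
    unless ``stage_coding='categorical'``.
    """
    if origin not in ORIGINS:
        raise ValueError(f"unknown origin {origin!r}; expected one of {ORIGINS}")
    field = _ORIGIN_FIELD[origin]
    rows, n_excluded = [], 0
    for rec in clinical:
        t0 = getattr(rec, field)
        if t0 is None or rec.t_event is None:
            n_excluded += 1
            continue
        if scores is not None and rec.patient_id not in scores:
            n_excluded += 1
            continue
        time = rec.t_event - t0
        if time < 0:
            raise ValueError(
                f"negative survival time for patient {rec.patient_id} "
                f"under origin {origin}"
            )
        row = {
            "patient_id": rec.patient_id,
            "time": max(time, 0.5),  # same-day events get half a day
            "event": int(rec.event),
            "age": rec.age_at_primary_dx,
            "race": rec.race,
        }
        if stage_coding == "ordinal":
            row["stage"] = STAGE_ORDINAL[rec.stage]
        else:
            row["stage"] = rec.stage
        if scores is not None:
            row[score_name] = float(scores[rec.patient_id])
        rows.append(row)
    if n_excluded:
        logger.info(
            "build_survival_table(origin=%s): excluded %d patients lacking "
            "origin date or score", origin, n_excluded,
        )
    df = pd.DataFrame(rows)
    if df.empty:
        raise ValueError(f"no patients usable under origin {origin}")
    return df


def _encode_design(df: pd.DataFrame, covariates: Sequence[str]) -> pd.DataFrame:
    """One-hot categorical covariates (largest level as reference)."""
    design = df[["time", "event"]].copy()
    for cov in covariates:
        col = df[cov]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            ref = col.value_counts().idxmax()
            for level in sorted(col.unique()):
                if level == ref:
                    continue
                design[f"{cov}[{level}]"] = (col == level).astype(float)
        else:
            design[cov] = col.astype(float)
    return design


def fit_cox(
    rows: pd.DataFrame,
    covariate_names: Sequence[str],
    penalizer: float = 0.0,
) -> list[CoxResult]:
    """Efron-tie Cox partial-likelihood fit with Wald 95% CIs.

    Raises on degenerate designs (fewer than two events, a constant
    covariate); non-convergence is returned as flagged results rather
    than silent output.
    """
    if int(rows["event"].sum()) < 2:
        raise ValueError("Cox model requires at least 2 observed events")
    design = _encode_design(rows, covariate_names)
    value_cols = [c for c in design.columns if c not in ("time", "event")]
    for c in value_cols:
        if design[c].nunique() <= 1:
            raise ValueError(f"covariate {c!r} is constant across patients")
    cph = CoxPHFitter(penalizer=penalizer)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(design, duration_col="time", event_col="event")
    except ConvergenceError as exc:
        return [
            CoxResult(
                covariate=c,
                hazard_ratio=float("nan"),
                ci_low=float("nan"),
                ci_high=float("nan"),
                p=float("nan"),
                converged=False,
                note=f"did not converge: {exc}",
            )
            for c in value_cols
        ]
    summary = cph.summary
    results = []
    for c in value_cols:
        row = summary.loc[c]
        results.append(
            CoxResult(
                covariate=c,
                hazard_ratio=float(row["exp(coef)"]),
                ci_low=float(row["exp(coef) lower 95%"]),
                ci_high=float(row["exp(coef) upper 95%"]),
                p=float(row["p"]),
            )
        )
    return results


def signature_forest(
    clinical: Sequence[ClinicalRecord],
    score_table: pd.DataFrame,
    origin: str,
    base_covariates: Sequence[str] = ("stage", "age", "race"),
    sample_to_patient: Optional[Mapping[str, str]] = None,
    penalizer: float = 0.0,
) -> pd.DataFrame:
    """One Cox fit per signature: base clinical model plus that signature.

    ``score_table`` is signatures x samples; sample columns are mapped to
    patients via ``sample_to_patient`` (identity if omitted, averaging
    when several samples map to one patient).  Returns the forest-plot
    table (one row per signature: its HR, CI, p, convergence flag).
    """
    cols = score_table.columns
    mapping = {s: (sample_to_patient or {}).get(s, s) for s in cols}
    by_patient = score_table.T.groupby(score_table.columns.map(mapping)).mean().T
    rows = []
    for sig in score_table.index:
        scores = by_patient.loc[sig].to_dict()
        try:
            table = build_survival_table(clinical, origin, scores=scores, score_name="score")
            fits = fit_cox(table, list(base_covariates) + ["score"], penalizer=penalizer)
        except ValueError as exc:
            rows.append(
                {
                    "signature": sig, "origin": origin, "hazard_ratio": np.nan,
                    "ci_low": np.nan, "ci_high": np.nan, "p": np.nan,
                    "converged": False, "note": str(exc),
                }
            )
            continue
        score_fit = next(r for r in fits if r.covariate == "score")
        rows.append(
            {
                "signature": sig,
                "origin": origin,
                "hazard_ratio": score_fit.hazard_ratio,
                "ci_low": score_fit.ci_low,
                "ci_high": score_fit.ci_high,
                "p": score_fit.p,
                "converged": score_fit.converged,
                "note": score_fit.note,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "signature", "origin", "hazard_ratio", "ci_low", "ci_high",
            "p", "converged", "note",
        ],
    )


def cox_frame(results: Sequence[CoxResult], origin: str = "") -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "covariate": r.covariate,
                "origin": origin,
                "hazard_ratio": r.hazard_ratio,
                "ci_low": r.ci_low,
                "ci_high": r.ci_high,
                "p": r.p,
                "converged": r.converged,
                "note": r.note,
            }
            for r in results
        ],
        columns=[
            "covariate", "origin", "hazard_ratio", "ci_low", "ci_high",
            "p", "converged", "note",
        ],
    )
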