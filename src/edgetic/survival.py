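"""Cox proportional-hazards screen over perturbed units.

Samples carrying >=1 interface-perturbing mutation mapped to a unit
(interface, reaction or pathway) are contrasted against non-carriers on
overall survival, adjusting for age at diagnosis and sex. Hazard ratios
are the exponentiated carrier coefficients; adjusted p-values use the
Benjamini–Hochberg procedure per level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

from .enrichment import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "SurvivalResult",
    "read_clinical",
    "derive_survival",
    "fit_cox_for_unit",
    "run_survival_screen",
    "write_survival_tsv",
]

CLINICAL_COLUMNS = (
    "sample_id",
    "vital_status",
    "gender",
    "days_to_death",
    "days_to_last_follow_up",
    "age_at_diagnosis",
)


@dataclass
class SurvivalResult:
    unit_id: str
    unit_level: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    q_value: float
    n_carriers: int
    n_total: int


def read_clinical(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def derive_survival(clinical: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, int]]:
    """Build the (time, event, age, sex) analysis table.

    event = 1 iff vital_status is 'dead'; time = days_to_death for the
    dead, days_to_last_follow_up otherwise. Rows with a missing required
    value, a gender outside {male, female}, or time <= 0 are dropped;
    reasons are tallied.
    """
    tally = {"missing": 0, "bad_gender": 0, "nonpositive_time": 0}
    rows = []
    for rec in clinical.to_dict("records"):
        status = str(rec.get("vital_status", "")).lower()
        gender = str(rec.get("gender", "")).lower()
        age = rec.get("age_at_diagnosis")
        if status not in {"alive", "dead"} or pd.isna(age):
            tally["missing"] += 1
            continue
        time = rec.get("days_to_death") if status == "dead" else rec.get(
            "days_to_last_follow_up"
        )
        if pd.isna(time):
            tally["missing"] += 1
            continue
        if gender not in {"male", "female"}:
            tally["bad_gender"] += 1
            continue
        if float(time) <= 0:
            tally["nonpositive_time"] += 1
            continue
        rows.append(
            {
                "sample_id": rec["sample_id"],
                "time": float(time),
                "event": int(status == "dead"),
                "age": float(age),
                "sex": int(gender == "male"),
            }
        )
    dropped = {k: v for k, v in tally.items() if v}
    if dropped:
        logger.info("derive_survival drops: %s", dropped)
    return pd.DataFrame(rows, columns=["sample_id", "time", "event", "age", "sex"]), tally


def fit_cox_for_unit(
    table: pd.DataFrame,
    carrier_ids: Iterable[str],
    unit_id: str = "",
    unit_level: str = "",
) -> SurvivalResult | None:
    """Fit Cox PH with {carrier, age, sex} covariates for one unit.

    Requires >=2 carriers, >=2 non-carriers and >=1 event; returns None
    (with a logged reason) otherwise or on non-convergence. Ties use the
    Efron approximation (lifelines' default).
    """
    carriers = set(carrier_ids)
    df = table.copy()
    df["carrier"] = df["sample_id"].isin(carriers).astype(int)
    n_car = int(df["carrier"].sum())
    n_non = len(df) - n_car
    if n_car < 2 or n_non < 2:
        logger.info("unit %s skipped: no contrast (%d carriers / %d non)", unit_id, n_car, n_non)
        return None
    if df["event"].sum() < 1:
        logger.info("unit %s skipped: no events", unit_id)
        return None
    cph = CoxPHFitter()
    try:
        cph.fit(
            df[["time", "event", "carrier", "age", "sex"]],
            duration_col="time",
            event_col="event",
        )
    except (ConvergenceError, ValueError) as err:
        logger.warning("unit %s skipped: Cox fit failed (%s)", unit_id, err)
        return None
    coef = float(cph.params_["carrier"])
    se = float(cph.standard_errors_["carrier"])
    z = 1.959963984540054  # 95% normal quantile

    def _exp(x: float) -> float:  # clamp: near-separated fits have huge SEs
        return float(np.exp(np.clip(x, -700.0, 700.0)))

    return SurvivalResult(
        unit_id=unit_id,
        unit_level=unit_level,
        hazard_ratio=_exp(coef),
        ci_low=_exp(coef - z * se),
        ci_high=_exp(coef + z * se),
        p_value=float(cph.summary.loc["carrier", "p"]),
        q_value=1.0,
        n_carriers=n_car,
        n_total=len(df),
    )


def run_survival_screen(
    carrier_sets: Mapping[str, Iterable[str]],
    clinical_table: pd.DataFrame,
    unit_level: str,
) -> list[SurvivalResult]:
    """Screen a family of units (one level, one cancer type) for survival
    association; BH-adjust within the family and sort by q."""
    results: list[SurvivalResult] = []
    for unit_id in sorted(carrier_sets):
        res = fit_cox_for_unit(
            clinical_table, carrier_sets[unit_id], unit_id=unit_id, unit_level=unit_level
        )
        if res is not None:
            results.append(res)
    for res, q in zip(results, bh_adjust([r.p_value for r in results])):
        res.q_value = float(q)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.unit_id))
    return results


def write_survival_tsv(
    results: Iterable[SurvivalResult], path: str | Path, alpha: float = 0.05
) -> None:
    cols = (
        "unit_id",
        "level",
        "hazard_ratio",
        "ci_low",
        "ci_high",
        "p_value",
        "q_value",
        "n_carriers",
        "n_total",
        "significant",
    )
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for r in results:
            fh.write(
                "\t".join(
                    [
                        r.unit_id,
                        r.unit_level,
                        f"{r.hazard_ratio:.6g}",
                        f"{r.ci_low:.6g}",
                        f"{r.ci_high:.6g}",
                        f"{r.p_value:.6g}",
                        f"{r.q_value:.6g}",
                        str(r.n_carriers),
                        str(r.n_total),
                        str(r.q_value < alpha),
                    ]
                )
                + "\n"
            )
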