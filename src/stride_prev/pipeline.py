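"""Ingest, validation, recruitment-flow reporting and table formatting.

The analysis input is a wide CSV, one row per older-adult/informant pair,
with column names resolved against a machine-readable data dictionary.
Rows failing validation (under-age, undefined category codes, duplicate
ids) are quarantined with a reason, never silently dropped. Percentages in
human-readable tables are reported to one decimal place with half-up
rounding; every percentage cell is recomputable from the count cells next
to it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import pandas as pd

from .weighting import LITERACY_LEVELS, SEX_LEVELS, assign_age_band

__all__ = [
    "IngestError",
    "ingest",
    "report_flow",
    "demographics_table",
    "missingness_checks",
    "pct",
]

MANDATORY_COLUMNS = (
    "respondent_id",
    "country",
    "age",
    "sex",
    "literacy",
)

AGE_SOURCES = ("self-report", "informant", "document", "calendar")


class IngestError(ValueError):
    """Fatal ingest problem (e.g. mandatory columns absent)."""


def pct(numerator: float, denominator: float) -> float:
    """Percentage at one decimal, half-up — the reporting convention."""
    if denominator == 0:
        raise ValueError("percentage with zero denominator")
    return float(
        Decimal(100 * numerator / denominator).quantize(
            Decimal("0.1"), rounding=ROUND_HALF_UP
        )
    )


@dataclass
class IngestReport:
    n_read: int
    n_valid: int
    quarantined: pd.DataFrame  # respondent_id, reason
    checksum: str = ""
    log: list[str] = field(default_factory=list)


def ingest(
    csv_path: str | Path,
    dictionary: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, IngestReport]:
    """Read and validate the wide analysis CSV.

    Demographic fields are validated here (eligibility age floor, defined
    category codes, unique ids); item-level response codes are validated
    downstream by the scoring engine against the item maps. When a data
    dictionary is given, its columns must all resolve.
    """
    df = pd.read_csv(csv_path)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise IngestError(f"mandatory columns absent: {missing}")
    if dictionary is not None:
        unresolved = [
            c for c in dictionary["column"] if c and c not in df.columns
        ]
        if unresolved:
            raise IngestError(f"dictionary columns absent from data: {unresolved}")
    return validate_records(df, source=str(csv_path))


def validate_records(
    df: pd.DataFrame, source: str = "<memory>"
) -> tuple[pd.DataFrame, IngestReport]:
    reasons = pd.Series("", index=df.index, dtype=object)

    dup = df["respondent_id"].duplicated(keep="first")
    reasons[dup] = "duplicate respondent id"
    age_num = pd.to_numeric(df["age"], errors="coerce")
    bad_age = age_num.isna()
    reasons[bad_age & (reasons == "")] = "age: not a number"
    under = age_num < 65
    reasons[under & (reasons == "")] = "eligibility: aged 65 years or older"
    bad_sex = ~df["sex"].isin(SEX_LEVELS)
    reasons[bad_sex & (reasons == "")] = (
        "undefined sex code: " + df["sex"].astype(str)
    )[bad_sex & (reasons == "")]
    bad_lit = ~df["literacy"].isin(LITERACY_LEVELS)
    reasons[bad_lit & (reasons == "")] = (
        "undefined literacy code: " + df["literacy"].astype(str)
    )[bad_lit & (reasons == "")]

    bad = reasons != ""
    quarantined = pd.DataFrame(
        {"respondent_id": df.loc[bad, "respondent_id"], "reason": reasons[bad]}
    )
    valid = df.loc[~bad].copy()
    valid["age"] = age_num[~bad].astype(int)
    valid["age_band"] = valid["age"].map(assign_age_band)
    report = IngestReport(
        n_read=len(df),
        n_valid=len(valid),
        quarantined=quarantined.reset_index(drop=True),
        log=[f"{source}: read {len(df)}, quarantined {int(bad.sum())}"],
    )
    return valid, report


def report_flow(
    flow: dict, n_insufficient: int, n_analysed: int
) -> pd.DataFrame:
    """Recruitment flow counts, telescoping stage by stage.

    ``flow`` carries ``listed``, ``ineligible`` (reason -> count) and
    ``recruited``; the completeness filter supplies the insufficient-data
    and analysed counts. Every stage equals the previous stage minus its
    removals, and that is asserted, not assumed.
    """
    listed = int(flow.get("listed", flow["recruited"]))
    ineligible = {str(k): int(v) for k, v in flow.get("ineligible", {}).items()}
    recruited = int(flow["recruited"])
    if listed - sum(ineligible.values()) != recruited:
        raise ValueError("flow does not telescope: listed - ineligible != recruited")
    if recruited - n_insufficient != n_analysed:
        raise ValueError("flow does not telescope: recruited - insufficient != analysed")
    rows = [{"stage": "listed", "count": listed, "removed": None, "reason": ""}]
    for reason, k in ineligible.items():
        rows.append(
            {"stage": "ineligible", "count": None, "removed": k, "reason": reason}
        )
    rows.append({"stage": "recruited", "count": recruited, "removed": None, "reason": ""})
    rows.append(
        {
            "stage": "insufficient_data",
            "count": None,
            "removed": n_insufficient,
            "reason": "insufficient data to run the diagnostic algorithm",
        }
    )
    rows.append({"stage": "analysed", "count": n_analysed, "removed": None, "reason": ""})
    return pd.DataFrame(rows)


def demographics_table(analysed: pd.DataFrame) -> pd.DataFrame:
    """Key demographics of the analysed cohort.

    Prior-diagnosis percentage uses the analysed denominator (the cohort
    in which prevalence is estimated).
    """
    n = len(analysed)
    if n == 0:
        raise ValueError("empty analysed cohort")
    n_female = int((analysed["sex"] == "female").sum())
    n_lit = int((analysed["literacy"] == "literate").sum())
    n_dx = int(analysed["prior_dementia_diagnosis"].astype(int).sum())
    rows = [
        {"measure": "n analysed", "value": n, "percent": None},
        {"measure": "mean age (years)", "value": round(float(analysed["age"].mean()), 1),
         "percent": None},
        {"measure": "sd age (years)", "value": round(float(analysed["age"].std(ddof=1)), 2),
         "percent": None},
        {"measure": "women", "value": n_female, "percent": pct(n_female, n)},
        {"measure": "literate", "value": n_lit, "percent": pct(n_lit, n)},
        {"measure": "prior dementia diagnosis", "value": n_dx, "percent": pct(n_dx, n)},
    ]
    for band, k in analysed["age_band"].value_counts().sort_index().items():
        rows.append({"measure": f"age {band}", "value": int(k), "percent": pct(k, n)})
    return pd.DataFrame(rows)


def missingness_checks(
    recruited: pd.DataFrame, evaluable: pd.Series
) -> pd.DataFrame:
    """Representativeness of the analysed subset: Pearson chi-squared of
    algorithm-evaluability against age band, sex and literacy."""
    from .associations import chisq_independence

    rows = []
    for factor in ("age_band", "sex", "literacy"):
        tab = pd.crosstab(recruited[factor], evaluable)
        if tab.shape[1] < 2 or tab.shape[0] < 2:
            rows.append({"factor": factor, "n": len(recruited), "chi2": None,
                         "dof": None, "p_value": None})
            continue
        stat, p, dof = chisq_independence(tab.to_numpy())
        rows.append({"factor": factor, "n": int(tab.to_numpy().sum()),
                     "chi2": stat, "dof": dof, "p_value": p})
    return pd.DataFrame(rows)
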