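"""Association analyses: odds ratios, prevalence ratios, representativeness
checks and stratified literacy-by-sex ratios.

Effect models are unweighted, as association tables in prevalence surveys
conventionally are: logistic regression gives odds ratios, and a companion
Poisson
regression with a robust (sandwich) variance gives prevalence ratios for
the same categorical exposures. Age adjustment enters as age-band
indicators. Reference levels default to the youngest band, female, and
illiterate. Pearson chi-squared (no continuity correction) checks whether
missingness relates to demographics; Mantel-Haenszel pooled ratios compare
literacy between sexes, optionally stratified.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats
from statsmodels.stats.contingency_tables import StratifiedTable
from statsmodels.tools.sm_exceptions import PerfectSeparationError

__all__ = [
    "AssociationResult",
    "DEFAULT_REFERENCES",
    "fit_effect_model",
    "association_table",
    "chisq_independence",
    "mantel_haenszel",
]

#: exposure column -> reference level (youngest band, female, illiterate)
DEFAULT_REFERENCES = {"age_band": "65-69", "sex": "female", "literacy": "illiterate"}


@dataclass(frozen=True)
class AssociationResult:
    """One exposure-level effect estimate from a fitted model."""

    measure: str  # "odds_ratio" | "prevalence_ratio"
    exposure: str
    level: str
    reference: str
    adjusted_for: tuple[str, ...]
    estimate: float | None
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    converged: bool
    n: int

    def __post_init__(self) -> None:
        if self.estimate is not None:
            assert self.estimate > 0
            assert self.ci_low <= self.estimate <= self.ci_high


def _term_name(exposure: str, ref: str, level: str) -> str:
    return f'C({exposure}, Treatment("{ref}"))[T.{level}]'


def fit_effect_model(
    df: pd.DataFrame,
    outcome: str,
    exposure: str,
    adjust: Sequence[str] = (),
    family: str = "logistic",
    references: dict[str, str] | None = None,
) -> list[AssociationResult]:
    """Fit one effect model and return per-level ratios vs. the reference.

    ``family="logistic"`` yields odds ratios from a binomial GLM;
    ``family="poisson"`` yields prevalence ratios from a log-link Poisson
    GLM with HC0 robust standard errors (binary outcomes violate the
    Poisson variance assumption, so a sandwich variance is required for
    honest CIs). Non-convergence or separation is flagged and the
    estimates withheld rather than reported.
    """
    refs = {**DEFAULT_REFERENCES, **(references or {})}
    use = df[[outcome, exposure, *adjust]].dropna()
    terms = [f'C({c}, Treatment("{refs.get(c, sorted(use[c].unique())[0])}"))'
             for c in (exposure, *adjust)]
    formula = f"{outcome} ~ " + " + ".join(terms)
    use = use.copy()
    use[outcome] = use[outcome].astype(int)

    if family == "logistic":
        measure = "odds_ratio"
        model = smf.glm(formula, data=use, family=sm.families.Binomial())
        fit_kwargs: dict = {}
    elif family == "poisson":
        measure = "prevalence_ratio"
        model = smf.glm(formula, data=use, family=sm.families.Poisson())
        fit_kwargs = {"cov_type": "HC0"}
    else:
        raise ValueError(f"unknown family {family!r}")

    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = model.fit(**fit_kwargs)
        converged = bool(getattr(res, "converged", True))
        # huge SEs signal quasi-separation even when the IRLS loop "converges"
        if converged and (np.asarray(res.bse) > 50).any():
            converged = False
    except (PerfectSeparationError, np.linalg.LinAlgError, ValueError):
        converged = False

    exp_ref = refs.get(exposure, sorted(use[exposure].unique())[0])
    levels = [lv for lv in sorted(use[exposure].astype(str).unique()) if lv != exp_ref]
    out = []
    for lv in levels:
        if not converged:
            out.append(AssociationResult(measure, exposure, lv, exp_ref,
                                         tuple(adjust), None, None, None, None,
                                         False, len(use)))
            continue
        term = _term_name(exposure, exp_ref, lv)
        coef = float(res.params[term])
        lo, hi = (float(x) for x in res.conf_int().loc[term])
        out.append(
            AssociationResult(
                measure, exposure, lv, exp_ref, tuple(adjust),
                float(np.exp(coef)), float(np.exp(lo)), float(np.exp(hi)),
                float(res.pvalues[term]), True, len(use),
            )
        )
    return out


def association_table(
    df: pd.DataFrame,
    outcome: str = "is_case",
    exposures: Sequence[str] = ("age_band", "sex", "literacy"),
    family: str = "logistic",
    references: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Crude and age-adjusted ratios for each exposure, one table row per
    non-reference level.

    Age itself is reported crude only (adjusting age for age is vacuous).
    """
    rows = []
    for exposure in exposures:
        crude = fit_effect_model(df, outcome, exposure, (), family, references)
        adjusted = (
            fit_effect_model(df, outcome, exposure, ("age_band",), family, references)
            if exposure != "age_band"
            else []
        )
        adj_by_level = {r.level: r for r in adjusted}
        for r in crude:
            a = adj_by_level.get(r.level)
            rows.append(
                {
                    "exposure": exposure,
                    "level": r.level,
                    "reference": r.reference,
                    "measure": r.measure,
                    "crude": r.estimate,
                    "crude_ci_low": r.ci_low,
                    "crude_ci_high": r.ci_high,
                    "crude_p": r.p_value,
                    "adjusted": a.estimate if a else None,
                    "adjusted_ci_low": a.ci_low if a else None,
                    "adjusted_ci_high": a.ci_high if a else None,
                    "adjusted_p": a.p_value if a else None,
                    "n": r.n,
                }
            )
    return pd.DataFrame(rows)


def chisq_independence(table: np.ndarray | pd.DataFrame) -> tuple[float, float, int]:
    """Pearson chi-squared test of independence (no continuity correction).

    Returns ``(statistic, p_value, dof)``. Zero row/column margins are an
    error: expected counts would be undefined.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or min(t.shape) < 2:
        raise ValueError("need at least a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column margin")
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), float(res.pvalue), int(res.dof)


@dataclass
class MHResult:
    measure: str  # "risk_ratio" | "odds_ratio"
    pooled_ratio: float
    mh_chi2: float
    p_value: float
    n_strata_used: int
    dropped_strata: list[str] = field(default_factory=list)


def mantel_haenszel(
    tables: Sequence[np.ndarray],
    measure: str = "risk_ratio",
    labels: Sequence[str] | None = None,
) -> MHResult:
    """Mantel-Haenszel pooled ratio across 2x2 strata, with the MH
    chi-squared test of no association.

    Each stratum is ``[[a, b], [c, d]]`` = exposed (cases, non-cases) over
    unexposed (cases, non-cases). A single stratum collapses to the crude
    ratio. All-zero strata are dropped (logged), as they carry no
    information.
    """
    if measure not in ("risk_ratio", "odds_ratio"):
        raise ValueError(f"unknown measure {measure!r}")
    labels = list(labels) if labels is not None else [str(i) for i in range(len(tables))]
    kept, dropped = [], []
    for lab, t in zip(labels, tables):
        t = np.asarray(t, dtype=float)
        if t.shape != (2, 2) or (t < 0).any():
            raise ValueError("each stratum must be a non-negative 2x2 table")
        (kept if t.sum() > 0 else dropped).append((lab, t))
    if not kept:
        raise ValueError("no informative strata")
    arr = np.stack([t for _, t in kept], axis=-1)
    st = StratifiedTable(arr)
    ratio = float(st.riskratio_pooled if measure == "risk_ratio" else st.oddsratio_pooled)
    test = st.test_null_odds(correction=False)
    return MHResult(
        measure=measure,
        pooled_ratio=ratio,
        mh_chi2=float(test.statistic),
        p_value=float(test.pvalue),
        n_strata_used=len(kept),
        dropped_strata=[lab for lab, _ in dropped],
    )
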