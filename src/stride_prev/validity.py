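"""Convergent validity of the algorithmic caseness assignment.

Two kinds of evidence: (a) standardized group differences (Hedges' g,
bias-corrected) between algorithm-positive and algorithm-negative
participants on continuous outcomes (cognitive, informant, severity, IADL
scores, and the binary needs-care flag treated as 0/1); and (b) agreement
with established screening cut-offs, summarised as balanced accuracy
(sensitivity + specificity) / 2 — called "AUC" in this literature, but a
binary-vs-binary agreement index, not a ROC integral — with a bootstrap
CI over records.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "EffectSizeResult",
    "ClassificationTable",
    "ZeroVarianceError",
    "hedges_g",
    "balanced_auc",
    "classification_table",
    "validity_battery",
]


class ZeroVarianceError(ValueError):
    """Raised when a standardized effect size is undefined (pooled SD = 0)."""


def _g_band(g: float) -> str:
    a = abs(g)
    if a > 0.8:
        return "large"
    if a > 0.5:
        return "medium"
    return "small"


def _auc_band(auc: float) -> str:
    if auc > 0.8:
        return "very good"
    if auc >= 0.7:
        return "good"
    if auc >= 0.6:
        return "acceptable"
    if auc >= 0.5:
        return "poor"
    return "worse than chance"


@dataclass(frozen=True)
class EffectSizeResult:
    outcome: str
    mean_cases: float
    sd_cases: float
    n_cases: int
    mean_noncases: float
    sd_noncases: float
    n_noncases: int
    pooled_sd: float
    g: float  # sign convention: cases minus non-cases
    p_value: float  # Welch's t-test
    band: str


def hedges_g(
    values_cases: Sequence[float],
    values_noncases: Sequence[float],
    outcome: str = "",
) -> EffectSizeResult:
    """Bias-corrected standardized mean difference (cases minus non-cases).

    g = J * (m1 - m2) / s_pooled with the df-weighted pooled SD and the
    small-sample correction J = 1 - 3/(4 df - 1), df = n1 + n2 - 2.
    Identical degenerate groups have no defined effect: pooled SD of zero
    raises :class:`ZeroVarianceError` rather than returning +/-inf.
    """
    x1 = np.asarray(values_cases, dtype=float)
    x2 = np.asarray(values_noncases, dtype=float)
    if x1.size < 2 or x2.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if not (np.isfinite(x1).all() and np.isfinite(x2).all()):
        raise ValueError("values must be finite")
    n1, n2 = x1.size, x2.size
    df = n1 + n2 - 2
    s2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / df
    if s2 == 0:
        raise ZeroVarianceError(f"pooled SD is zero for outcome {outcome!r}")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * (x1.mean() - x2.mean()) / math.sqrt(s2)
    p = float(stats.ttest_ind(x1, x2, equal_var=False).pvalue)
    return EffectSizeResult(
        outcome, float(x1.mean()), float(x1.std(ddof=1)), n1,
        float(x2.mean()), float(x2.std(ddof=1)), n2,
        float(math.sqrt(s2)), float(g), p, _g_band(g),
    )


@dataclass(frozen=True)
class ClassificationTable:
    """Agreement counts of algorithm caseness vs. a reference cut-off."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def sensitivity(self) -> float:
        if self.tp + self.fn == 0:
            raise ValueError("empty reference-positive class")
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        if self.tn + self.fp == 0:
            raise ValueError("empty reference-negative class")
        return self.tn / (self.tn + self.fp)

    @property
    def auc(self) -> float:
        """Balanced accuracy (sensitivity + specificity) / 2."""
        return (self.sensitivity + self.specificity) / 2.0


def classification_table(
    algorithm: Sequence[bool], reference: Sequence[bool]
) -> ClassificationTable:
    a = np.asarray(algorithm, dtype=bool)
    r = np.asarray(reference, dtype=bool)
    if a.shape != r.shape:
        raise ValueError("classifications must be aligned")
    return ClassificationTable(
        tp=int((a & r).sum()),
        fp=int((a & ~r).sum()),
        fn=int((~a & r).sum()),
        tn=int((~a & ~r).sum()),
    )


def balanced_auc(
    algorithm: Sequence[bool],
    reference: Sequence[bool],
    *,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
    level: float = 0.95,
) -> dict:
    """Balanced accuracy with a nonparametric bootstrap percentile CI.

    Records are resampled with replacement; resamples that lose one of the
    reference classes are redrawn implicitly by falling back to the point
    estimate for that replicate (rare unless a class is tiny).
    """
    a = np.asarray(algorithm, dtype=bool)
    r = np.asarray(reference, dtype=bool)
    table = classification_table(a, r)
    point = table.auc
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = a.size
    draws = np.empty(n_boot)
    for b in range(n_boot):
        idx = rng.integers(0, n, n)
        ab, rb = a[idx], r[idx]
        if rb.all() or (~rb).all():
            draws[b] = point
            continue
        draws[b] = classification_table(ab, rb).auc
    lo, hi = np.quantile(draws, [(1 - level) / 2, (1 + level) / 2])
    return {
        "table": table,
        "auc": float(point),
        "ci_low": float(min(lo, point)),
        "ci_high": float(max(hi, point)),
        "band": _auc_band(point),
        "n_boot": n_boot,
    }


#: continuous outcomes of the battery: column -> printable name
BATTERY_OUTCOMES = {
    "cogscore": "CSI-D cognitive score",
    "relscore": "CSI-D informant score",
    "dsrs": "DSRS total",
    "lawton": "Lawton IADL total",
    "needs_care": "Needs care (0/1)",
}


def validity_battery(
    df: pd.DataFrame,
    cutoffs: dict[str, pd.DataFrame],
    *,
    case_col: str = "is_case",
    outcomes: dict[str, str] | None = None,
    n_boot: int = 2000,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Run the full battery on an analysed cohort.

    ``df`` holds evaluable caseness plus the outcome columns (pairwise
    deletion per outcome); ``cutoffs`` maps a reference name (e.g.
    ``"dsrs"``, ``"brief_csid"``) to its per-record classification frame
    (``positive``/``evaluable`` columns). One row per effect size and one
    per agreement table.
    """
    outcomes = outcomes or BATTERY_OUTCOMES
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    is_case = df[case_col].astype(bool)
    if is_case.sum() < 2 or (~is_case).sum() < 2:
        raise ValueError(
            "validity battery needs at least 2 records in each caseness group"
        )
    rows = []
    for col, name in outcomes.items():
        if col not in df.columns:
            continue
        vals = df[col]
        ok = vals.notna()
        try:
            es = hedges_g(vals[ok & is_case], vals[ok & ~is_case], outcome=name)
        except ZeroVarianceError:
            continue
        rows.append(
            {
                "kind": "effect_size", "outcome": name,
                "case_mean": es.mean_cases, "case_sd": es.sd_cases,
                "noncase_mean": es.mean_noncases, "noncase_sd": es.sd_noncases,
                "n_cases": es.n_cases, "n_noncases": es.n_noncases,
                "estimate": es.g, "ci_low": None, "ci_high": None,
                "p_value": es.p_value, "band": es.band,
            }
        )
    for ref_name, cls in cutoffs.items():
        ok = cls["evaluable"].astype(bool)
        res = balanced_auc(
            is_case[ok], cls.loc[ok, "positive"].astype(bool),
            n_boot=n_boot, seed=rng,
        )
        t = res["table"]
        rows.append(
            {
                "kind": "agreement", "outcome": f"vs {ref_name} cut-off",
                "case_mean": None, "case_sd": None,
                "noncase_mean": None, "noncase_sd": None,
                "n_cases": t.tp + t.fn, "n_noncases": t.tn + t.fp,
                "estimate": res["auc"], "ci_low": res["ci_low"],
                "ci_high": res["ci_high"], "p_value": None, "band": res["band"],
            }
        )
    return pd.DataFrame(rows)
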