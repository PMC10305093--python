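"""Post-stratification weighting and prevalence estimation.

The sample is weighted to national demography over age band (5-year
intervals, open top band), sex and literacy. Two routes are supported,
reflecting the two forms national margin tables come in:

* full cross-classification available -> direct cell post-stratification,
  weight = population share / sample share per cell;
* marginal tables only -> raking (iterative proportional fitting over the
  three margins, "sequential computation"), iterated to convergence.

Weights are normalised to sum to the sample size (mean 1), which keeps the
Kish effective-sample-size diagnostic interpretable. Prevalence is
estimated unweighted (Wilson 95% CI) and weighted (Hajek ratio estimator
with a logit-scale CI using the Kish effective n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "AGE_BANDS",
    "DemographicCell",
    "EligibilityError",
    "PopulationMargins",
    "WeightTable",
    "PrevalenceEstimate",
    "PrecisionSpec",
    "assign_cell",
    "assign_age_band",
    "fit_weights",
    "estimate_prevalence",
    "prevalence_table",
    "extrapolate_count",
    "precision_sample_size",
]

#: default 5-year age bands with an open top band
AGE_BANDS: tuple[str, ...] = ("65-69", "70-74", "75-79", "80+")

CELL_DIMS = ("age_band", "sex", "literacy")
SEX_LEVELS = ("female", "male")
LITERACY_LEVELS = ("illiterate", "literate")


class EligibilityError(ValueError):
    """Raised for respondents below the study's age floor."""


class DemographicCell(NamedTuple):
    age_band: str
    sex: str
    literacy: str


def assign_age_band(age: float, bands: Sequence[str] = AGE_BANDS) -> str:
    """Deterministic 5-year banding of an age >= 65; top band open-ended."""
    if age < 65:
        raise EligibilityError(f"age {age} is below the eligibility floor of 65")
    lowers = [int(b.split("-")[0].rstrip("+")) for b in bands]
    idx = 0
    for i, lo in enumerate(lowers):
        if age >= lo:
            idx = i
    return bands[idx]


def assign_cell(
    age: float, sex: str, literacy: str, bands: Sequence[str] = AGE_BANDS
) -> DemographicCell:
    if sex not in SEX_LEVELS:
        raise ValueError(f"unknown sex level {sex!r}")
    if literacy not in LITERACY_LEVELS:
        raise ValueError(f"unknown literacy level {literacy!r}")
    return DemographicCell(assign_age_band(age, bands), sex, literacy)


@dataclass
class PopulationMargins:
    """National counts by demographic cell, or by margin when the full
    cross-classification is unavailable.

    ``cells`` is a DataFrame with columns age_band, sex, literacy, count;
    ``margins`` maps dimension name -> {level: count}. At least one of the
    two must be given. ``total`` defaults to the sum of the finest table.
    """

    cells: pd.DataFrame | None = None
    margins: dict[str, dict[str, float]] | None = None
    total: float | None = None

    def __post_init__(self) -> None:
        if self.cells is None and not self.margins:
            raise ValueError("need either cell counts or marginal counts")
        if self.cells is not None:
            if (self.cells["count"] < 0).any():
                raise ValueError("population counts must be non-negative")
            s = float(self.cells["count"].sum())
            if self.total is None:
                self.total = s
            elif not math.isclose(s, self.total, rel_tol=1e-9):
                raise ValueError("cell counts do not sum to the stated total")
        elif self.margins:
            sums = {d: sum(m.values()) for d, m in self.margins.items()}
            first = next(iter(sums.values()))
            if any(not math.isclose(v, first, rel_tol=1e-9) for v in sums.values()):
                raise ValueError("marginal tables disagree on the population total")
            if self.total is None:
                self.total = float(first)

    @property
    def has_cells(self) -> bool:
        return self.cells is not None


@dataclass
class WeightTable:
    """Post-stratification weights per demographic cell (mean-1 normalised)."""

    weights: pd.Series  # indexed by (age_band, sex, literacy)
    method: str  # "direct" or "raking"
    normalization: str = "sum_to_sample_size"
    iterations: int = 0
    log: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if (self.weights <= 0).any():
            raise ValueError("all weights must be positive")

    def for_records(self, cells: pd.DataFrame) -> pd.Series:
        """Per-record weights from the cell table (cells: the three key columns)."""
        key = pd.MultiIndex.from_frame(cells[list(CELL_DIMS)])
        return pd.Series(self.weights.reindex(key).to_numpy(), index=cells.index)


def _sample_cell_counts(cells: pd.DataFrame) -> pd.Series:
    return cells.groupby(list(CELL_DIMS), observed=True).size()


def fit_weights(
    sample_cells: pd.DataFrame,
    margins: PopulationMargins,
    *,
    tol: float = 1e-8,
    max_sweeps: int = 100,
    collapse_empty: bool = True,
) -> WeightTable:
    """Fit post-stratification weights for the sampled records.

    ``sample_cells`` carries one row per analysed record with columns
    age_band, sex, literacy. With a full population cross-classification
    the weight of a cell is its population share over its sample share;
    with margins only, raking (IPF) adjusts the three dimensions in turn
    until every weighted margin matches the population margin to ``tol``
    (as shares), or fails after ``max_sweeps``.

    A non-empty sample cell with zero population share is, by default,
    resolved by collapsing adjacent age bands (logged); with
    ``collapse_empty=False`` it raises.
    """
    counts = _sample_cell_counts(sample_cells).astype(float)
    n = float(counts.sum())
    if n == 0:
        raise ValueError("no records to weight")
    log: list[str] = []

    if margins.has_cells:
        pop = margins.cells.set_index(list(CELL_DIMS))["count"].astype(float)
        pop_share = pop / pop.sum()
        share = pop_share.reindex(counts.index)
        if share.isna().any() or (share <= 0).any():
            bad = list(share.index[share.isna() | (share <= 0)])
            if not collapse_empty:
                raise ValueError(f"sample cells with zero population share: {bad}")
            # coarsest safe collapse: pool all age bands per (sex, literacy)
            log.append(f"collapsed age bands over zero-population cells {bad}")
            csample = counts.groupby(["sex", "literacy"]).sum()
            cpop = pop_share.groupby(["sex", "literacy"]).sum()
            cshare = cpop.reindex(csample.index)
            if cshare.isna().any() or (cshare <= 0).any():
                raise ValueError("zero-population cells persist after collapsing")
            w_c = cshare / (csample / n)
            key = pd.MultiIndex.from_arrays(
                [counts.index.get_level_values("sex"),
                 counts.index.get_level_values("literacy")]
            )
            w = pd.Series(w_c.reindex(key).to_numpy(), index=counts.index)
        else:
            w = share / (counts / n)
        w = w * n / (w * counts).sum()  # weights sum to n over records
        return WeightTable(weights=w, method="direct", log=log)

    # raking over the three margins
    dims = {d: pd.Series(m, dtype=float) for d, m in margins.margins.items()}
    target_share = {d: s / s.sum() for d, s in dims.items()}
    w = pd.Series(1.0, index=counts.index)
    it = 0
    for it in range(1, max_sweeps + 1):
        for d, tgt in target_share.items():
            lvl = w.index.get_level_values(d)
            cur = (w * counts).groupby(lvl).sum() / (w * counts).sum()
            factor = (tgt.reindex(cur.index) / cur).fillna(1.0)
            w = w * pd.Series(factor.reindex(lvl).to_numpy(), index=w.index)
        err = _margin_error(w, counts, target_share)
        log.append(f"sweep {it}: max margin error {err:.3e}")
        if err <= tol:
            break
    else:
        raise RuntimeError(f"raking did not converge in {max_sweeps} sweeps; log: {log[-3:]}")
    w = w * n / (w * counts).sum()
    return WeightTable(weights=w, method="raking", iterations=it, log=log)


def _margin_error(w: pd.Series, counts: pd.Series, target_share) -> float:
    err = 0.0
    tot = (w * counts).sum()
    for d, tgt in target_share.items():
        cur = (w * counts).groupby(w.index.get_level_values(d)).sum() / tot
        err = max(err, float((cur - tgt.reindex(cur.index).fillna(0.0)).abs().max()))
    return err


@dataclass(frozen=True)
class PrevalenceEstimate:
    point: float
    ci_low: float
    ci_high: float
    n: int
    n_effective: float
    cases: float
    method: str  # e.g. "unweighted/wilson", "weighted/logit-kish"

    def __post_init__(self) -> None:
        assert 0.0 <= self.ci_low <= self.point <= self.ci_high <= 1.0


def _wilson(cases: float, n: float, level: float) -> tuple[float, float]:
    lo, hi = proportion_confint(cases, n, alpha=1 - level, method="wilson")
    return float(lo), float(hi)


def estimate_prevalence(
    cases: Iterable[bool],
    weights: Iterable[float] | None = None,
    *,
    level: float = 0.95,
) -> PrevalenceEstimate:
    """Point prevalence with a 95% CI.

    Unweighted: cases/n with a Wilson score interval. Weighted: the ratio
    estimator sum(w*y)/sum(w) with a logit-transformed interval whose
    standard error uses the Kish effective sample size
    n_eff = (sum w)^2 / sum w^2; at the 0/1 boundary (where the logit SE
    degenerates) the Wilson interval at n_eff is used instead. Scaling all
    weights by a positive constant changes nothing.
    """
    y = np.asarray(list(cases), dtype=float)
    n = y.size
    if n == 0:
        raise ValueError("cannot estimate prevalence on zero records")
    z = stats.norm.ppf(0.5 + level / 2)
    if weights is None:
        p = float(y.mean())
        lo, hi = _wilson(y.sum(), n, level)
        return PrevalenceEstimate(
            p, min(max(lo, 0.0), p), max(min(hi, 1.0), p), n, float(n),
            float(y.sum()), "unweighted/wilson",
        )
    w = np.asarray(list(weights), dtype=float)
    if w.shape != y.shape or (w <= 0).any():
        raise ValueError("weights must be positive and aligned with cases")
    p = float((w * y).sum() / w.sum())
    n_eff = float(w.sum() ** 2 / (w**2).sum())
    if p <= 0.0 or p >= 1.0:
        lo, hi = _wilson(p * n_eff, n_eff, level)
    else:
        se_logit = 1.0 / math.sqrt(n_eff * p * (1 - p))
        lo = 1.0 / (1.0 + math.exp(-(math.log(p / (1 - p)) - z * se_logit)))
        hi = 1.0 / (1.0 + math.exp(-(math.log(p / (1 - p)) + z * se_logit)))
    return PrevalenceEstimate(
        p, float(min(lo, p)), float(max(hi, p)), n, n_eff, float((w * y).sum()),
        "weighted/logit-kish",
    )


def prevalence_table(
    df: pd.DataFrame,
    case_col: str = "is_case",
    weights: pd.Series | None = None,
    by: Sequence[str] = CELL_DIMS,
    level: float = 0.95,
) -> pd.DataFrame:
    """Subgroup + grand-total prevalence table.

    One row per level of each grouping column (unweighted), plus an
    unweighted grand total and — when weights are given — a weighted grand
    total. Records with a missing grouping value fall out of that
    subgroup's rows but stay in the totals, so the grand total can exceed
    the subgroup sum.
    """
    rows = []

    def add(label_dim: str, label: str, sub: pd.DataFrame, w: pd.Series | None):
        est = estimate_prevalence(
            sub[case_col].astype(bool),
            None if w is None else w.loc[sub.index],
            level=level,
        )
        rows.append(
            {
                "group": label_dim,
                "level": label,
                "n": est.n,
                "cases": est.cases,
                "prevalence": est.point,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "weighted": w is not None,
            }
        )

    for dim in by:
        for lvl, sub in df.groupby(dim, observed=True, dropna=True):
            add(dim, str(lvl), sub, None)
    add("total", "all", df, None)
    if weights is not None:
        add("total", "all", df, weights)
    return pd.DataFrame(rows)


def extrapolate_count(
    estimate: PrevalenceEstimate, population_65plus: float
) -> dict[str, float]:
    """Scale a prevalence estimate to a national head count (with CI).

    Exact values are returned; human-readable reports round to the nearest
    1000 (``count_rounded_1000``).
    """
    if population_65plus <= 0:
        raise ValueError("population must be positive")
    count = estimate.point * population_65plus
    return {
        "count": count,
        "ci_low": estimate.ci_low * population_65plus,
        "ci_high": estimate.ci_high * population_65plus,
        "count_rounded_1000": round(count / 1000) * 1000,
    }


@dataclass(frozen=True)
class PrecisionSpec:
    """Inputs of the precision-based sample-size formula."""

    expected_prevalence: float
    half_width: float
    level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.expected_prevalence < 1:
            raise ValueError("expected prevalence must be in (0, 1)")
        if not 0 < self.level < 1:
            raise ValueError("confidence level must be in (0, 1)")
        if not 0 < self.half_width <= max(
            self.expected_prevalence, 1 - self.expected_prevalence
        ):
            raise ValueError("half-width infeasible for this prevalence")


def precision_sample_size(spec: PrecisionSpec) -> int:
    """n = ceil(z^2 p (1-p) / d^2): records needed to estimate a proportion
    p to within +/- d at the given confidence level (normal approximation)."""
    z = stats.norm.ppf(0.5 + spec.level / 2)
    p, d = spec.expected_prevalence, spec.half_width
    return math.ceil(z * z * p * (1 - p) / (d * d))
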