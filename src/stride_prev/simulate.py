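"""Synthetic cohort generator.

The raw survey data are external, so every pipeline stage is exercised on
generated cohorts carrying the statistical structure the analysis assumes:

* demographics drawn from a truncated-normal age distribution (floor 65),
  a sex split, and sex-specific literacy probabilities (emulating the
  observed literacy gap between men and women);
* latent dementia status drawn per demographic cell from a logistic model
  with stated odds ratios for age band, sex and literacy;
* item responses drawn conditionally on latent status: each instrument's
  items are independent Bernoulli/binomial draws whose success probability
  depends only on caseness, so cases are shifted toward impairment on the
  cognitive measures and toward higher severity scores;
* a recruitment flow (listed -> ineligible -> recruited) and a missingness
  stage (instrument-level refusal and researcher/technical error, MCAR by
  default, optionally exact counts or demographics-dependent MAR).

The class-conditional item model makes the exact posterior log-odds of
caseness *linear* in the four instrument totals, so a demo diagnostic
algorithm matched to the generator exists in closed form
(:func:`matched_algorithm_spec`); its threshold is calibrated by exact
convolution so the expected classified prevalence equals the scenario's
true prevalence. The generator is a test harness, not an estimate of any
real population; scenario prevalences are arbitrary test values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit

from .algorithm import AlgorithmSpec
from .instruments import (
    MISSING_NOT_ASKED,
    MISSING_REFUSED,
    ItemMap,
    SCORE_NAMES,
)
from .weighting import AGE_BANDS, PopulationMargins, assign_age_band

__all__ = [
    "ItemModel",
    "MissingnessEntry",
    "MissingnessSpec",
    "CohortScenario",
    "indonesia_like",
    "southafrica_like",
    "generate_cohort",
    "apply_missingness",
    "simulate_dataset",
    "make_margins",
    "matched_algorithm_spec",
    "overall_true_prevalence",
    "band_probabilities",
]

AGE_UPPER = 105.0  # truncation ceiling for simulated ages

#: latent-truth columns; the schema guard keeps them out of analysis inputs
TRUTH_COLUMNS = ("true_case", "severity", "true_cell_prevalence")


@dataclass(frozen=True)
class ItemModel:
    """Class-conditional success probabilities per item, by instrument.

    ``p_noncase``/``p_case`` give the per-item Bernoulli (or per-point
    binomial, for graded items) success probability conditional on latent
    caseness. "Success" is whatever the item's maximum code encodes:
    a correct answer for the cognitive items, an endorsed symptom or
    impairment for the informant/depression/severity items, an independent
    activity for the IADL items.
    """

    p: Mapping[str, tuple[float, float]]  # instrument -> (p_noncase, p_case)
    needs_care: tuple[float, float] = (0.10, 0.40)
    severity_mean_case: float = 2.0

    def __post_init__(self) -> None:
        for inst, (p0, p1) in self.p.items():
            if not (0 < p0 < 1 and 0 < p1 < 1):
                raise ValueError(f"item probabilities for {inst} must be in (0,1)")


DEFAULT_ITEM_MODEL = ItemModel(
    p={
        "csid_cog": (0.85, 0.45),
        "csid_inf": (0.12, 0.55),
        "cerad": (0.65, 0.25),
        "eurod": (0.15, 0.30),
        "dsrs": (0.08, 0.45),
        "lawton": (0.85, 0.35),
    }
)


@dataclass(frozen=True)
class MissingnessEntry:
    instrument: str
    amount: float  # count (exact mode) or probability (rate mode)
    reason: str = "refusal"  # refusal | researcher_error | technical_error

    @property
    def code(self) -> int:
        return MISSING_REFUSED if self.reason == "refusal" else MISSING_NOT_ASKED


@dataclass(frozen=True)
class MissingnessSpec:
    """Instrument-level missingness: whole sections are struck per record.

    ``exact`` mode strikes exactly ``amount`` disjoint records per entry
    (planted worked-example counts); ``rate`` mode strikes records
    independently with probability ``amount``. MCAR by default; ``mar``
    tilts the strike probability by demographics (rate mode only).
    """

    mode: str = "exact"
    entries: tuple[MissingnessEntry, ...] = ()
    mechanism: str = "mcar"
    mar_log_or: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "rate"):
            raise ValueError(f"unknown missingness mode {self.mode!r}")
        if self.mechanism not in ("mcar", "mar"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        for e in self.entries:
            if e.instrument not in SCORE_NAMES:
                raise ValueError(f"unknown instrument {e.instrument!r}")
            if self.mode == "rate" and not 0 <= e.amount <= 1:
                raise ValueError("rate-mode amounts must be probabilities")
            if self.mode == "exact" and (e.amount < 0 or e.amount != int(e.amount)):
                raise ValueError("exact-mode amounts must be non-negative integers")


@dataclass(frozen=True)
class CohortScenario:
    """Study conditions for one simulated country cohort."""

    name: str
    country: str
    sites: tuple[str, str]
    n_listed: int
    ineligible: Mapping[str, int]  # reason -> count; recruited = listed - sum
    age_mean: float
    age_sd: float
    prop_female: float
    literacy_by_sex: Mapping[str, float]
    baseline_prevalence: float  # reference cell: 65-69, female, illiterate
    or_age: Mapping[str, float] = field(
        default_factory=lambda: {"70-74": 1.7, "75-79": 2.8, "80+": 4.5}
    )
    or_male: float = 0.7
    or_literate: float = 0.5
    missingness: MissingnessSpec = MissingnessSpec()
    prior_diagnosis_count: int = 0
    population_65plus: float = 1_000_000.0
    item_model: ItemModel = DEFAULT_ITEM_MODEL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_recruited < 1:
            raise ValueError("scenario must recruit at least one participant")
        for p in (self.prop_female, self.baseline_prevalence,
                  *self.literacy_by_sex.values()):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.age_sd <= 0:
            raise ValueError("age SD must be positive")
        if self.prior_diagnosis_count < 0:
            raise ValueError("prior-diagnosis count must be >= 0")

    @property
    def n_recruited(self) -> int:
        return self.n_listed - sum(self.ineligible.values())

    def cell_prevalence(self, age_band: str, sex: str, literacy: str) -> float:
        lp = logit(self.baseline_prevalence)
        lp += math.log(self.or_age.get(age_band, 1.0)) if age_band != "65-69" else 0.0
        lp += math.log(self.or_male) if sex == "male" else 0.0
        lp += math.log(self.or_literate) if literacy == "literate" else 0.0
        return float(expit(lp))


def indonesia_like() -> CohortScenario:
    """Large-cohort scenario: 2794 listed, 578 ineligible (20.7%, all for
    lack of an informant), 2216 recruited, 106 planted non-evaluable."""
    return CohortScenario(
        name="indonesia-like",
        country="Indonesia",
        sites=("DKI Jakarta", "North Sumatra"),
        n_listed=2794,
        ineligible={"no_informant": 578},
        age_mean=71.1,
        age_sd=5.42,
        prop_female=0.55,
        literacy_by_sex={"female": 0.30, "male": 0.75},
        # reference-cell value fixed so the implied overall true prevalence
        # is 0.279 (arbitrary test value; magnitude chosen for realism)
        baseline_prevalence=0.276973,
        missingness=MissingnessSpec(
            mode="exact",
            entries=(
                MissingnessEntry("eurod", 60, "refusal"),
                MissingnessEntry("csid_cog", 20, "technical_error"),
                MissingnessEntry("cerad", 16, "researcher_error"),
                MissingnessEntry("csid_inf", 10, "refusal"),
                MissingnessEntry("dsrs", 5, "refusal"),
            ),
        ),
        prior_diagnosis_count=5,
        population_65plus=15_400_000.0,
        seed=20211,
    )


def southafrica_like() -> CohortScenario:
    """Small-cohort scenario: 575 listed, 85 ineligible, 490 recruited,
    82 planted non-evaluable of which 64 are EURO-D refusals."""
    return CohortScenario(
        name="southafrica-like",
        country="South Africa",
        sites=("Limpopo", "Western Cape"),
        n_listed=575,
        ineligible={"no_informant": 85},
        age_mean=74.8,
        age_sd=7.42,
        prop_female=0.635,
        literacy_by_sex={"female": 0.405, "male": 0.70},
        # reference-cell value fixed so the implied overall true prevalence
        # is 0.125 (arbitrary test value; magnitude chosen for realism)
        baseline_prevalence=0.084066,
        missingness=MissingnessSpec(
            mode="exact",
            entries=(
                MissingnessEntry("eurod", 64, "refusal"),
                MissingnessEntry("csid_cog", 10, "technical_error"),
                MissingnessEntry("cerad", 8, "researcher_error"),
                MissingnessEntry("lawton", 3, "refusal"),
            ),
        ),
        prior_diagnosis_count=2,
        population_65plus=3_600_000.0,
        seed=20212,
    )


# ---------------------------------------------------------------------------
# demographic distribution helpers

def _age_distribution(scenario: CohortScenario):
    """Truncated normal over [65, AGE_UPPER] whose expected *observed* age
    (after flooring to completed years) equals the scenario's mean age.

    Left-truncation at the eligibility floor inflates the mean of a plain
    normal, so the location parameter is solved by bisection; flooring
    lowers the mean by ~0.5 years, hence the +0.5 target shift.
    """
    sd = scenario.age_sd
    target = scenario.age_mean + 0.5
    lo, hi = scenario.age_mean - 4 * sd, scenario.age_mean + sd
    for _ in range(80):
        mid = (lo + hi) / 2
        a, b = (65.0 - mid) / sd, (AGE_UPPER - mid) / sd
        if stats.truncnorm.mean(a, b, loc=mid, scale=sd) < target:
            lo = mid
        else:
            hi = mid
    loc = (lo + hi) / 2
    a, b = (65.0 - loc) / sd, (AGE_UPPER - loc) / sd
    return stats.truncnorm(a, b, loc=loc, scale=sd)


def band_probabilities(scenario: CohortScenario) -> dict[str, float]:
    """Age-band shares implied by the truncated-normal age distribution."""
    tn = _age_distribution(scenario)
    edges = [65.0, 70.0, 75.0, 80.0, AGE_UPPER]
    probs = {}
    for band, lo, hi in zip(AGE_BANDS, edges[:-1], edges[1:]):
        probs[band] = float(tn.cdf(hi) - tn.cdf(lo))
    total = sum(probs.values())
    return {k: v / total for k, v in probs.items()}


def _cell_distribution(scenario: CohortScenario) -> pd.DataFrame:
    """Joint sampling-design distribution over (age_band, sex, literacy)."""
    bands = band_probabilities(scenario)
    rows = []
    for band, pb in bands.items():
        for sex, ps in (("female", scenario.prop_female),
                        ("male", 1 - scenario.prop_female)):
            plit = scenario.literacy_by_sex[sex]
            for lit, pl in (("literate", plit), ("illiterate", 1 - plit)):
                rows.append(
                    {
                        "age_band": band, "sex": sex, "literacy": lit,
                        "share": pb * ps * pl,
                        "prevalence": scenario.cell_prevalence(band, sex, lit),
                    }
                )
    return pd.DataFrame(rows)


def overall_true_prevalence(scenario: CohortScenario) -> float:
    """Population-level true prevalence implied by the scenario."""
    cells = _cell_distribution(scenario)
    return float((cells["share"] * cells["prevalence"]).sum())


# ---------------------------------------------------------------------------
# generation

def _draw_items(
    rng: np.random.Generator,
    imap: ItemMap,
    is_case: np.ndarray,
    p0: float,
    p1: float,
) -> dict[str, np.ndarray]:
    """Per-item draws: binomial(max_code, p_class) for each graded item."""
    p = np.where(is_case, p1, p0)
    out = {}
    for item in imap.items:
        m = int(item.max_contribution)
        out[item.item_id] = rng.binomial(m, p)
    return out


def generate_cohort(
    scenario: CohortScenario,
    item_maps: Mapping[str, ItemMap],
    seed: int | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Draw one complete (pre-missingness) cohort.

    Returns ``(records, truth, flow)``: the analysis input frame (no latent
    columns), a latent-truth sidecar aligned on respondent id, and the
    recruitment-flow counts. Deterministic given scenario and seed.
    """
    rng = np.random.default_rng(scenario.seed if seed is None else seed)
    n = scenario.n_recruited
    ids = [f"{scenario.country[:2].upper()}-{i:05d}" for i in range(1, n + 1)]

    ages = np.floor(_age_distribution(scenario).rvs(size=n, random_state=rng)).astype(int)
    sex = np.where(rng.random(n) < scenario.prop_female, "female", "male")
    plit = np.where(
        sex == "female",
        scenario.literacy_by_sex["female"],
        scenario.literacy_by_sex["male"],
    )
    literacy = np.where(rng.random(n) < plit, "literate", "illiterate")
    bands = np.array([assign_age_band(int(x)) for x in ages])

    prev = np.array(
        [scenario.cell_prevalence(bd, sx, lt)
         for bd, sx, lt in zip(bands, sex, literacy)]
    )
    true_case = rng.random(n) < prev
    severity = rng.normal(
        np.where(true_case, scenario.item_model.severity_mean_case, 0.0), 1.0
    )
    p_care0, p_care1 = scenario.item_model.needs_care
    needs_care = (rng.random(n) < np.where(true_case, p_care1, p_care0)).astype(int)

    age_source = rng.choice(
        ["self-report", "informant", "document", "calendar"],
        size=n, p=[0.55, 0.20, 0.18, 0.07],
    )
    relationship = rng.choice(
        ["child", "spouse", "other_relative", "neighbour", "other"],
        size=n, p=[0.40, 0.20, 0.185, 0.10, 0.115],
    )
    site = rng.choice(list(scenario.sites), size=n)

    df = pd.DataFrame(
        {
            "respondent_id": ids,
            "country": scenario.country,
            "site": site,
            "age": ages,
            "age_band": bands,
            "age_source": age_source,
            "sex": sex,
            "literacy": literacy,
            "informant_relationship": relationship,
            "prior_dementia_diagnosis": 0,
            "needs_care": needs_care,
        }
    )
    for inst, (p0, p1) in scenario.item_model.p.items():
        for col, vals in _draw_items(rng, item_maps[inst], true_case, p0, p1).items():
            df[col] = vals

    truth = pd.DataFrame(
        {
            "respondent_id": ids,
            "true_case": true_case.astype(int),
            "severity": severity,
            "true_cell_prevalence": prev,
            "age_band": bands,
            "sex": sex,
            "literacy": literacy,
        }
    )
    flow = {
        "listed": scenario.n_listed,
        "ineligible": dict(scenario.ineligible),
        "recruited": n,
    }
    return df, truth, flow


def apply_missingness(
    df: pd.DataFrame,
    spec: MissingnessSpec,
    item_maps: Mapping[str, ItemMap],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Strike whole instrument sections with missing codes.

    Returns the modified frame and a log with one row per entry
    (instrument, reason, records struck). Exact mode strikes disjoint
    record sets so planted non-evaluable counts add up; rate mode strikes
    independently per record (MCAR) or with demographic tilting (MAR).
    """
    out = df.copy()
    log_rows = []
    if spec.mode == "exact":
        total = int(sum(e.amount for e in spec.entries))
        if total > len(df):
            raise ValueError("more planted missingness than records")
        order = rng.permutation(len(df))
        pos = 0
        for e in spec.entries:
            k = int(e.amount)
            idx = df.index[order[pos:pos + k]]
            pos += k
            cols = [c for c in item_maps[e.instrument].item_ids if c in out.columns]
            out.loc[idx, cols] = e.code
            log_rows.append(
                {"instrument": e.instrument, "reason": e.reason, "n_struck": k}
            )
    else:
        for e in spec.entries:
            p = np.full(len(df), e.amount)
            if spec.mechanism == "mar" and spec.mar_log_or:
                tilt = np.zeros(len(df))
                for key, beta in spec.mar_log_or.items():
                    col, _, level = key.partition("=")
                    tilt += beta * (df[col].astype(str) == level).to_numpy()
                p = expit(logit(np.clip(p, 1e-9, 1 - 1e-9)) + tilt)
            struck = rng.random(len(df)) < p
            cols = [c for c in item_maps[e.instrument].item_ids if c in out.columns]
            out.loc[df.index[struck], cols] = e.code
            log_rows.append(
                {"instrument": e.instrument, "reason": e.reason,
                 "n_struck": int(struck.sum())}
            )
    return out, pd.DataFrame(log_rows)


def simulate_dataset(
    scenario: CohortScenario,
    item_maps: Mapping[str, ItemMap],
    seed: int | None = None,
) -> dict:
    """Full simulation bundle: cohort + missingness + planted prior
    diagnoses + margins + flow + latent truth sidecar."""
    base_seed = scenario.seed if seed is None else seed
    rng = np.random.default_rng(base_seed)
    df, truth, flow = generate_cohort(scenario, item_maps, seed=base_seed)
    df, miss_log = apply_missingness(df, scenario.missingness, item_maps, rng)

    # plant prior diagnoses among records untouched by required-section
    # missingness, so the planted count survives the completeness filter
    struck = df.index[
        (df[[c for m in item_maps.values() for c in m.item_ids if c in df.columns]]
         >= MISSING_REFUSED).any(axis=1)
    ]
    candidates = df.index.difference(struck)
    k = min(scenario.prior_diagnosis_count, len(candidates))
    chosen = rng.choice(candidates.to_numpy(), size=k, replace=False)
    df.loc[chosen, "prior_dementia_diagnosis"] = 1

    return {
        "scenario": scenario,
        "seed": base_seed,
        "records": df,
        "truth": truth,
        "flow": flow,
        "missingness_log": miss_log,
        "margins": make_margins(scenario),
    }


def make_margins(
    scenario: CohortScenario,
    distortion: Mapping[str, Mapping[str, float]] | None = None,
    margins_only: bool = False,
) -> PopulationMargins:
    """National margins consistent with (or distorted from) the sampling
    design.

    ``distortion`` maps dimension -> {level: factor} multiplying that
    level's population share relative to the design (then renormalised);
    a factor of 0.5 on a band the sample draws at design share emulates a
    2x-oversampled band, so its post-stratification weight lands near 0.5
    relative to the others.
    """
    cells = _cell_distribution(scenario).copy()
    share = cells["share"].to_numpy().copy()
    if distortion:
        for dim, factors in distortion.items():
            for level, f in factors.items():
                share[cells[dim] == level] *= f
        share /= share.sum()
    cells["count"] = share * scenario.population_65plus
    table = cells[["age_band", "sex", "literacy", "count"]]
    if margins_only:
        margins = {
            dim: table.groupby(dim)["count"].sum().to_dict()
            for dim in ("age_band", "sex", "literacy")
        }
        return PopulationMargins(margins=margins)
    return PopulationMargins(cells=table.reset_index(drop=True))


# ---------------------------------------------------------------------------
# matched demo algorithm

ALGORITHM_INSTRUMENTS = ("csid_cog", "csid_inf", "cerad", "eurod")


def matched_algorithm_spec(
    scenario: CohortScenario, item_maps: Mapping[str, ItemMap]
) -> AlgorithmSpec:
    """Demo algorithm exactly matched to the generator.

    With class-conditional binomial item totals k_i ~ Bin(n_i, p), the
    posterior log-odds of caseness is linear in the totals:

        logit P(case | k) = logit(pi) + sum_i [ k_i * log(p1 q0 / (p0 q1))
                                               + n_i * log(q1 / q0) ]

    with q = 1 - p and pi the overall true prevalence. The caseness
    threshold is then calibrated on the exact mixture distribution of the
    linear predictor (a convolution over the four instruments) so the
    expected classified prevalence equals pi. This is a synthetic demo
    specification, not the published short-algorithm coefficients.
    """
    pi = overall_true_prevalence(scenario)
    coefs: dict[str, float] = {}
    intercept = float(logit(pi))
    per_inst = []
    for inst in ALGORITHM_INSTRUMENTS:
        p0, p1 = scenario.item_model.p[inst]
        n_i = int(item_maps[inst].max_score)
        coef = math.log(p1 * (1 - p0) / (p0 * (1 - p1)))
        intercept += n_i * math.log((1 - p1) / (1 - p0))
        coefs[SCORE_NAMES[inst]] = coef
        per_inst.append((n_i, p0, p1, coef))

    # exact mixture distribution of the linear predictor
    lp0 = np.array([intercept])
    pr0 = np.array([1.0])  # conditional on non-case
    pr1 = np.array([1.0])  # conditional on case
    for n_i, p0, p1, coef in per_inst:
        k = np.arange(n_i + 1)
        lp0 = (lp0[:, None] + coef * k[None, :]).ravel()
        pr0 = (pr0[:, None] * stats.binom.pmf(k, n_i, p0)[None, :]).ravel()
        pr1 = (pr1[:, None] * stats.binom.pmf(k, n_i, p1)[None, :]).ravel()
    mix = pi * pr1 + (1 - pi) * pr0
    order = np.argsort(lp0)[::-1]
    cum = np.cumsum(mix[order])
    j = int(np.argmin(np.abs(cum - pi)))
    cut_lp = lp0[order][j]  # classify case when lp >= cut_lp
    threshold = float(expit(cut_lp))
    return AlgorithmSpec(
        intercept=intercept,
        coefficients=coefs,
        threshold=min(max(threshold, 1e-9), 1 - 1e-9),
        version=f"matched-demo/{scenario.name}",
        source=(
            "Synthetic demo algorithm derived from the cohort generator's "
            "class-conditional item model; stands in for the published "
            "short-algorithm coefficients, which are not distributed here."
        ),
    )


def calibrated(scenario: CohortScenario, target_overall: float) -> CohortScenario:
    """Return a copy whose baseline prevalence yields the target overall
    true prevalence (monotone bisection on the baseline)."""
    lo, hi = 1e-6, 1 - 1e-6
    for _ in range(200):
        mid = (lo + hi) / 2
        if overall_true_prevalence(replace(scenario, baseline_prevalence=mid)) < target_overall:
            lo = mid
        else:
            hi = mid
    return replace(scenario, baseline_prevalence=(lo + hi) / 2)
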