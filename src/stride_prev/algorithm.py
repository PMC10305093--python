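"""Algorithmic dementia caseness and comparison cut-off classifiers.

The short-schedule diagnostic algorithm maps the instrument scores
(COGSCORE, RELSCORE, CERAD delayed recall, EURO-D) to a predicted caseness
probability through a logistic linear predictor; a record is a case when
the probability reaches the configured threshold (ties classify as case).
Coefficients, threshold and required inputs are external configuration —
never code — so the engine also serves spec variants. An ordered
rule-chain form (first matching predicate decides) is supported for
algorithms published as decision rules rather than one equation.

Records missing any required input are non-evaluable: they are excluded
from the analysed denominator by :func:`completeness_filter`, mirroring an
exclude-don't-impute analysis policy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .instruments import SCORE_NAMES

__all__ = [
    "AlgorithmSpec",
    "RuleChainSpec",
    "CasenessResult",
    "CutoffSpec",
    "ConfigError",
    "predict_caseness",
    "predict_dataframe",
    "classify_cutoff",
    "classify_cutoff_dataframe",
    "completeness_filter",
]

_KNOWN_SCORES = frozenset(SCORE_NAMES.values())

# predicate operators for cut-off rules and rule chains
_OPS = {
    "ge": lambda a, b: a >= b,
    "gt": lambda a, b: a > b,
    "le": lambda a, b: a <= b,
    "lt": lambda a, b: a < b,
    "eq": lambda a, b: a == b,
}


class ConfigError(ValueError):
    """Raised when an algorithm/cut-off config fails validation at load time."""


@dataclass(frozen=True)
class AlgorithmSpec:
    """Logistic caseness algorithm on the instrument scores.

    probability = expit(intercept + sum coefficient * score);
    is_case when probability >= threshold.
    """

    intercept: float
    coefficients: Mapping[str, float]
    threshold: float = 0.5
    version: str = "unversioned"
    source: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ConfigError(f"threshold must be in (0, 1), got {self.threshold}")
        unknown = set(self.coefficients) - _KNOWN_SCORES
        if unknown:
            raise ConfigError(f"coefficients reference unknown scores: {sorted(unknown)}")
        if not self.coefficients:
            raise ConfigError("algorithm needs at least one predictor score")

    @property
    def required_inputs(self) -> frozenset[str]:
        return frozenset(self.coefficients)

    def linear_predictor(self, scores: Mapping[str, float]) -> float:
        return self.intercept + sum(
            coef * float(scores[name]) for name, coef in self.coefficients.items()
        )


@dataclass(frozen=True)
class RuleChainSpec:
    """Ordered decision rules over scores; the first matching clause decides.

    Each rule is ``(conjuncts, outcome)`` with conjuncts a sequence of
    ``(score, op, value)`` predicates that must all hold. A final default
    outcome applies when no rule matches. Probabilities are reported as
    0/1 so the caseness contract matches the logistic form.
    """

    rules: Sequence[tuple[Sequence[tuple[str, str, float]], bool]]
    default: bool = False
    version: str = "unversioned"
    source: str = ""

    def __post_init__(self) -> None:
        for conjuncts, _ in self.rules:
            for score, op, _value in conjuncts:
                if score not in _KNOWN_SCORES:
                    raise ConfigError(f"rule references unknown score {score!r}")
                if op not in _OPS:
                    raise ConfigError(f"unknown operator {op!r}")

    @property
    def required_inputs(self) -> frozenset[str]:
        return frozenset(s for conj, _ in self.rules for s, _, _ in conj)


@dataclass(frozen=True)
class CasenessResult:
    probability: float | None
    is_case: bool | None
    evaluable: bool
    reason_not_evaluable: str | None = None

    def __post_init__(self) -> None:
        if self.evaluable:
            assert self.probability is not None and 0.0 <= self.probability <= 1.0


@dataclass(frozen=True)
class CutoffSpec:
    """Binary screening cut-off on one or two instrument scores.

    ``clauses`` is a disjunction of conjunctions: the classification is
    positive when any clause's predicates all hold. A plain single
    threshold is one clause with one predicate; the two-threshold Brief
    CSI-D style rule is expressed with two clauses.
    """

    measure: str
    clauses: Sequence[Sequence[tuple[str, str, float]]]
    version: str = "unversioned"
    source: str = ""

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ConfigError(f"cut-off {self.measure!r} has no clauses")
        for clause in self.clauses:
            for score, op, _value in clause:
                if score not in _KNOWN_SCORES:
                    raise ConfigError(f"cut-off references unknown score {score!r}")
                if op not in _OPS:
                    raise ConfigError(f"unknown operator {op!r}")

    @property
    def required_inputs(self) -> frozenset[str]:
        return frozenset(s for clause in self.clauses for s, _, _ in clause)


def _missing_inputs(scores, required: frozenset[str]) -> list[str]:
    missing = []
    for name in sorted(required):
        val = scores.get(name) if hasattr(scores, "get") else scores[name]
        ok = scores.is_evaluable(name) if hasattr(scores, "is_evaluable") else (
            val is not None and not (isinstance(val, float) and math.isnan(val))
        )
        if not ok:
            missing.append(name)
    return missing


def predict_caseness(scores, spec: AlgorithmSpec | RuleChainSpec) -> CasenessResult:
    """Assign caseness for one respondent's :class:`InstrumentScores`.

    Non-evaluable required inputs make the whole prediction non-evaluable;
    the record is later excluded from the analysed denominator, never
    scored as a non-case.
    """
    missing = _missing_inputs(scores, spec.required_inputs)
    if missing:
        return CasenessResult(
            None, None, False, "missing_inputs:" + "+".join(missing)
        )
    if isinstance(spec, RuleChainSpec):
        outcome = spec.default
        for conjuncts, rule_outcome in spec.rules:
            if all(_OPS[op](float(scores[s]), v) for s, op, v in conjuncts):
                outcome = rule_outcome
                break
        return CasenessResult(1.0 if outcome else 0.0, bool(outcome), True)
    lp = spec.linear_predictor(scores)
    prob = 1.0 / (1.0 + math.exp(-lp)) if lp > -700 else 0.0
    return CasenessResult(prob, prob >= spec.threshold, True)


def predict_dataframe(scores: pd.DataFrame, spec: AlgorithmSpec) -> pd.DataFrame:
    """Vectorised caseness over a scored cohort.

    Returns columns ``probability``, ``is_case``, ``evaluable``,
    ``reason_not_evaluable`` aligned with ``scores``.
    """
    req = sorted(spec.required_inputs)
    evaluable = pd.Series(True, index=scores.index)
    for name in req:
        evaluable &= scores[f"{name}_evaluable"].astype(bool)
    lp = pd.Series(spec.intercept, index=scores.index, dtype=float)
    for name, coef in spec.coefficients.items():
        lp += coef * scores[name].fillna(0.0)
    prob = pd.Series(1.0 / (1.0 + np.exp(-lp)), index=scores.index)
    out = pd.DataFrame(index=scores.index)
    out["probability"] = prob.where(evaluable)
    out["is_case"] = (prob >= spec.threshold).where(evaluable)
    out["evaluable"] = evaluable
    reasons = pd.Series(None, index=scores.index, dtype=object)
    if not evaluable.all():
        miss = pd.DataFrame(
            {n: ~scores[f"{n}_evaluable"].astype(bool) for n in req}
        )
        reasons[~evaluable] = miss[~evaluable].apply(
            lambda r: "missing_inputs:" + "+".join(c for c in req if r[c]), axis=1
        )
    out["reason_not_evaluable"] = reasons
    return out


def classify_cutoff(scores, cut: CutoffSpec) -> tuple[bool | None, bool]:
    """Apply one screening cut-off; returns ``(positive, evaluable)``."""
    if _missing_inputs(scores, cut.required_inputs):
        return None, False
    positive = any(
        all(_OPS[op](float(scores[s]), v) for s, op, v in clause)
        for clause in cut.clauses
    )
    return positive, True


def classify_cutoff_dataframe(scores: pd.DataFrame, cut: CutoffSpec) -> pd.DataFrame:
    """Vectorised cut-off classification: ``positive`` and ``evaluable`` columns."""
    evaluable = pd.Series(True, index=scores.index)
    for name in sorted(cut.required_inputs):
        evaluable &= scores[f"{name}_evaluable"].astype(bool)
    positive = pd.Series(False, index=scores.index)
    for clause in cut.clauses:
        hit = pd.Series(True, index=scores.index)
        for s, op, v in clause:
            hit &= _OPS[op](scores[s].fillna(0.0), v)
        positive |= hit
    return pd.DataFrame(
        {"positive": positive.where(evaluable), "evaluable": evaluable}
    )


@dataclass
class ExclusionLog:
    """Book-keeping for the completeness filter (exclusion flow)."""

    n_input: int
    n_retained: int
    by_reason: dict[str, int] = field(default_factory=dict)
    by_missing_input: dict[str, int] = field(default_factory=dict)

    @property
    def n_excluded(self) -> int:
        return self.n_input - self.n_retained


def completeness_filter(
    df: pd.DataFrame, caseness: pd.DataFrame
) -> tuple[pd.DataFrame, ExclusionLog]:
    """Retain records with evaluable caseness; log exclusions by reason.

    Conservation holds by construction: retained + excluded = input.
    ``by_missing_input`` counts, per required score, how many excluded
    records were missing that score (a record missing several scores
    appears under each).
    """
    evaluable = caseness["evaluable"].astype(bool)
    retained = df.loc[evaluable].copy()
    reasons = caseness.loc[~evaluable, "reason_not_evaluable"]
    by_reason = reasons.value_counts().to_dict()
    by_input: dict[str, int] = {}
    for reason, count in by_reason.items():
        for name in str(reason).removeprefix("missing_inputs:").split("+"):
            by_input[name] = by_input.get(name, 0) + count
    log = ExclusionLog(
        n_input=len(df),
        n_retained=len(retained),
        by_reason={str(k): int(v) for k, v in by_reason.items()},
        by_missing_input=by_input,
    )
    return retained, log
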