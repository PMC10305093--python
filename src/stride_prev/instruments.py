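"""Item-level scoring of the survey instruments.

Six instruments feed the downstream analysis: the CSI-D cognitive test of
the older adult (COGSCORE, higher = better cognition) and its informant
interview on everyday function (RELSCORE, higher = more impairment), the
CERAD ten-word delayed recall count, the EURO-D twelve-item depression
screen, the Dementia Severity Rating Scale (DSRS, 0-54, higher = more
impaired) and the Lawton scale over eight instrumental activities of daily
living (higher = more independent).

The scoring engine is generic: item inventories, response codes and per-item
contributions live in a versioned config (an :class:`ItemMap` per
instrument), never in code. Records with more missing items than the map
allows are flagged non-evaluable rather than imputed or scored zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "ItemDef",
    "ItemMap",
    "InstrumentScores",
    "ScoringError",
    "SCORE_NAMES",
    "score_instrument",
    "score_all",
    "score_dataframe",
]

#: instrument id -> name of the derived score column
SCORE_NAMES: dict[str, str] = {
    "csid_cog": "cogscore",
    "csid_inf": "relscore",
    "cerad": "cerad",
    "eurod": "eurod",
    "dsrs": "dsrs",
    "lawton": "lawton",
}

# shared missing-data codes (data dictionary): all count as missing for scoring
MISSING_REFUSED = 901
MISSING_NOT_ASKED = 902
MISSING_DONT_KNOW = 903
DEFAULT_MISSING_CODES = frozenset({MISSING_REFUSED, MISSING_NOT_ASKED, MISSING_DONT_KNOW})


class ScoringError(ValueError):
    """Raised for invalid response codes or malformed item maps."""


@dataclass(frozen=True)
class ItemDef:
    """One questionnaire item: allowed codes and their score contributions."""

    item_id: str
    contributions: Mapping[int, float]
    missing_codes: frozenset[int] = DEFAULT_MISSING_CODES

    def __post_init__(self) -> None:
        if not self.contributions:
            raise ScoringError(f"item {self.item_id!r} has no allowed codes")
        overlap = set(self.contributions) & set(self.missing_codes)
        if overlap:
            raise ScoringError(
                f"item {self.item_id!r}: codes {sorted(overlap)} are both allowed and missing"
            )

    @property
    def max_contribution(self) -> float:
        return max(self.contributions.values())


@dataclass(frozen=True)
class ItemMap:
    """Scoring map for one instrument.

    ``max_missing_allowed`` is the number of missing items tolerated before
    the score is declared non-evaluable; the default of 0 matches the
    analysis policy of excluding, not imputing, incomplete records.
    ``prorate`` (off by default) rescales the observed sum to the full
    instrument range when a tolerated number of items is missing.
    """

    instrument_id: str
    items: tuple[ItemDef, ...]
    max_missing_allowed: int = 0
    prorate: bool = False
    version: str = "unversioned"
    source: str = ""

    def __post_init__(self) -> None:
        if self.instrument_id not in SCORE_NAMES:
            raise ScoringError(f"unknown instrument id {self.instrument_id!r}")
        ids = [it.item_id for it in self.items]
        if len(ids) != len(set(ids)):
            raise ScoringError(f"duplicate item ids in {self.instrument_id}")
        if self.max_missing_allowed < 0:
            raise ScoringError("max_missing_allowed must be >= 0")

    @property
    def score_name(self) -> str:
        return SCORE_NAMES[self.instrument_id]

    @property
    def item_ids(self) -> list[str]:
        return [it.item_id for it in self.items]

    @property
    def max_score(self) -> float:
        return sum(it.max_contribution for it in self.items)

    @property
    def min_score(self) -> float:
        return sum(min(it.contributions.values()) for it in self.items)


@dataclass
class InstrumentScores:
    """Derived instrument totals for one respondent.

    A score is ``None`` exactly when its evaluable flag is False.
    """

    scores: dict[str, float | None] = field(default_factory=dict)
    evaluable: dict[str, bool] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float | None:
        return self.scores[name]

    def is_evaluable(self, name: str) -> bool:
        return self.evaluable.get(name, False)


def score_instrument(
    record: Mapping[str, object], imap: ItemMap
) -> tuple[float | None, bool]:
    """Score one instrument for one respondent record.

    Returns ``(score, evaluable)``. Items absent from the record count as
    missing ("not asked"); a record missing more items than
    ``max_missing_allowed`` — in particular one with the whole section
    missing — is non-evaluable and gets no numeric score.
    """
    total = 0.0
    answered_max = 0.0
    n_missing = 0
    for item in imap.items:
        raw = record.get(item.item_id)
        if raw is None or (isinstance(raw, float) and pd.isna(raw)):
            n_missing += 1
            continue
        code = int(raw)
        if code in item.missing_codes:
            n_missing += 1
            continue
        if code not in item.contributions:
            raise ScoringError(
                f"instrument {imap.instrument_id}: item {item.item_id!r} "
                f"has invalid response code {code}"
            )
        total += item.contributions[code]
        answered_max += item.max_contribution
    if n_missing > imap.max_missing_allowed or n_missing == len(imap.items):
        return None, False
    if n_missing and imap.prorate and answered_max > 0:
        total *= imap.max_score / answered_max
    return total, True


def score_all(
    record: Mapping[str, object], maps: Iterable[ItemMap]
) -> InstrumentScores:
    """Compute every instrument score for one record (deterministic)."""
    out = InstrumentScores()
    for imap in maps:
        score, ok = score_instrument(record, imap)
        out.scores[imap.score_name] = score
        out.evaluable[imap.score_name] = ok
    return out


def score_dataframe(df: pd.DataFrame, maps: Iterable[ItemMap]) -> pd.DataFrame:
    """Score a whole cohort.

    Returns a DataFrame indexed like ``df`` with one ``<score>`` column
    (float, NaN when non-evaluable) and one ``<score>_evaluable`` boolean
    column per instrument. Response codes are validated item by item.
    """
    out = pd.DataFrame(index=df.index)
    for imap in maps:
        name = imap.score_name
        present = [c for c in imap.item_ids if c in df.columns]
        if not present:
            out[name] = float("nan")
            out[f"{name}_evaluable"] = False
            continue
        items = df[present]
        totals = pd.Series(0.0, index=df.index)
        answered_max = pd.Series(0.0, index=df.index)
        n_missing = pd.Series(len(imap.item_ids) - len(present), index=df.index)
        for item in imap.items:
            if item.item_id not in items.columns:
                continue
            col = items[item.item_id]
            is_na = col.isna()
            codes = col.fillna(MISSING_NOT_ASKED).astype(int)
            is_missing = is_na | codes.isin(list(item.missing_codes))
            bad = ~is_missing & ~codes.isin(list(item.contributions))
            if bad.any():
                code = int(codes[bad].iloc[0])
                raise ScoringError(
                    f"instrument {imap.instrument_id}: item {item.item_id!r} "
                    f"has invalid response code {code}"
                )
            contrib = codes.map(dict(item.contributions)).where(~is_missing, 0.0)
            totals += contrib.astype(float)
            answered_max += (~is_missing) * item.max_contribution
            n_missing += is_missing.astype(int)
        evaluable = (n_missing <= imap.max_missing_allowed) & (
            n_missing < len(imap.items)
        )
        if imap.prorate:
            scale = (imap.max_score / answered_max).where(answered_max > 0, 1.0)
            totals = totals.where(n_missing == 0, totals * scale)
        out[name] = totals.where(evaluable)
        out[f"{name}_evaluable"] = evaluable
    return out
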