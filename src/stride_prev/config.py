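"""Config loading: item maps, algorithm specs, cut-offs, margins.

All scoring/diagnostic constants are data, not code. The package ships a
set of clearly-labelled synthetic demo configs under ``configs/`` (the
published instrument inventories and short-algorithm coefficients are not
redistributed here); users supply their own transcriptions through the
same loaders. Loaded files are checksummed so run metadata can pin the
exact configuration used.
"""

from __future__ import annotations

import hashlib
from importlib import resources
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .algorithm import AlgorithmSpec, ConfigError, CutoffSpec, RuleChainSpec
from .instruments import DEFAULT_MISSING_CODES, ItemDef, ItemMap, SCORE_NAMES
from .weighting import PopulationMargins

__all__ = [
    "load_item_maps",
    "load_algorithm_spec",
    "load_cutoffs",
    "load_margins_csv",
    "default_item_maps",
    "default_algorithm_spec",
    "default_cutoffs",
    "data_dictionary",
    "file_checksum",
]


def _config_path(name: str) -> Path:
    return Path(resources.files("stride_prev") / "configs" / name)


def file_checksum(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def load_item_maps(path: str | Path) -> dict[str, ItemMap]:
    """Read a versioned item-map YAML into per-instrument :class:`ItemMap`s."""
    doc = yaml.safe_load(Path(path).read_text())
    version = str(doc.get("version", "unversioned"))
    source = str(doc.get("source", ""))
    missing = frozenset(doc.get("missing_codes", sorted(DEFAULT_MISSING_CODES)))
    maps: dict[str, ItemMap] = {}
    for inst, block in doc["instruments"].items():
        items = tuple(
            ItemDef(
                item_id=str(it["item_id"]),
                contributions={int(k): float(v) for k, v in it["codes"].items()},
                missing_codes=missing,
            )
            for it in block["items"]
        )
        imap = ItemMap(
            instrument_id=inst,
            items=items,
            max_missing_allowed=int(block.get("max_missing_allowed", 0)),
            prorate=bool(block.get("prorate", False)),
            version=version,
            source=source,
        )
        declared = block.get("max_score")
        if declared is not None and float(declared) != imap.max_score:
            raise ConfigError(
                f"{inst}: declared max score {declared} != derived {imap.max_score}"
            )
        maps[inst] = imap
    return maps


def load_algorithm_spec(path: str | Path) -> AlgorithmSpec | RuleChainSpec:
    doc = yaml.safe_load(Path(path).read_text())
    form = doc.get("form", "logistic")
    common = {
        "version": str(doc.get("version", "unversioned")),
        "source": str(doc.get("source", "")),
    }
    if form == "logistic":
        return AlgorithmSpec(
            intercept=float(doc["intercept"]),
            coefficients={str(k): float(v) for k, v in doc["coefficients"].items()},
            threshold=float(doc.get("threshold", 0.5)),
            **common,
        )
    if form == "rule_chain":
        rules = tuple(
            (
                tuple((str(s), str(op), float(v)) for s, op, v in rule["when"]),
                bool(rule["case"]),
            )
            for rule in doc["rules"]
        )
        return RuleChainSpec(rules=rules, default=bool(doc.get("default", False)), **common)
    raise ConfigError(f"unknown algorithm form {form!r}")


def load_cutoffs(
    path: str | Path, item_maps: Mapping[str, ItemMap] | None = None
) -> dict[str, CutoffSpec]:
    """Load screening cut-offs; thresholds are range-checked against the
    item maps when those are supplied."""
    doc = yaml.safe_load(Path(path).read_text())
    out: dict[str, CutoffSpec] = {}
    score_to_inst = {v: k for k, v in SCORE_NAMES.items()}
    for name, block in doc["cutoffs"].items():
        clauses = tuple(
            tuple((str(s), str(op), float(v)) for s, op, v in clause)
            for clause in block["clauses"]
        )
        cut = CutoffSpec(
            measure=name,
            clauses=clauses,
            version=str(doc.get("version", "unversioned")),
            source=str(block.get("source", doc.get("source", ""))),
        )
        if item_maps:
            for clause in clauses:
                for score, _op, value in clause:
                    imap = item_maps.get(score_to_inst[score])
                    if imap and not (imap.min_score <= value <= imap.max_score):
                        raise ConfigError(
                            f"cut-off {name}: threshold {value} outside "
                            f"{score} range [{imap.min_score}, {imap.max_score}]"
                        )
        out[name] = cut
    return out


def load_margins_csv(path: str | Path) -> PopulationMargins:
    """Read a national margins CSV (age_band, sex, literacy, count)."""
    df = pd.read_csv(path)
    required = {"age_band", "sex", "literacy", "count"}
    if not required.issubset(df.columns):
        raise ConfigError(f"margins CSV needs columns {sorted(required)}")
    return PopulationMargins(cells=df[list(required)].copy())


def default_item_maps() -> dict[str, ItemMap]:
    return load_item_maps(_config_path("item_maps_demo.yaml"))


def default_algorithm_spec() -> AlgorithmSpec | RuleChainSpec:
    return load_algorithm_spec(_config_path("algorithm_demo.yaml"))


def default_cutoffs() -> dict[str, CutoffSpec]:
    return load_cutoffs(_config_path("cutoffs_demo.yaml"), default_item_maps())


DEMOGRAPHIC_COLUMNS = (
    ("respondent_id", "identifier", "unique respondent id"),
    ("country", "categorical", "country label"),
    ("site", "categorical", "recruitment site"),
    ("age", "integer>=65", "age in completed years"),
    ("age_source", "enum:self-report|informant|document|calendar",
     "age ascertainment hierarchy"),
    ("sex", "enum:female|male", "sex"),
    ("literacy", "enum:literate|illiterate", "can read and write"),
    ("informant_relationship", "categorical", "informant's relationship"),
    ("prior_dementia_diagnosis", "enum:0|1", "self-reported prior diagnosis"),
    ("needs_care", "enum:0|1", "older adult needs care"),
)


def data_dictionary(item_maps: Mapping[str, ItemMap]) -> pd.DataFrame:
    """Machine-readable data dictionary for the wide analysis CSV."""
    rows = [
        {"column": c, "instrument": "", "item_id": "", "codes": codes, "labels": label}
        for c, codes, label in DEMOGRAPHIC_COLUMNS
    ]
    for inst, imap in item_maps.items():
        for item in imap.items:
            rows.append(
                {
                    "column": item.item_id,
                    "instrument": inst,
                    "item_id": item.item_id,
                    "codes": "|".join(str(k) for k in sorted(item.contributions)),
                    "labels": f"{inst} item; missing codes "
                              + "|".join(str(c) for c in sorted(item.missing_codes)),
                }
            )
    return pd.DataFrame(rows)
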