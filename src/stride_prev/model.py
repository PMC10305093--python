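"""Model/Results objects tying the pipeline together.

:class:`DementiaPrevalenceModel` is constructed from respondent-level data
plus the study configuration (item maps, diagnostic algorithm, screening
cut-offs, national margins); ``fit()`` runs scoring, caseness assignment,
the completeness filter, weighting and every analysis, and returns a
:class:`StudyResults` holding the estimates, their intervals, diagnostics
and report-shaped tables, with ``summary()`` and ``save()``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__ as _pkg_version
from .algorithm import (
    AlgorithmSpec,
    CutoffSpec,
    RuleChainSpec,
    classify_cutoff_dataframe,
    completeness_filter,
    predict_dataframe,
)
from .associations import association_table, mantel_haenszel
from .config import default_algorithm_spec, default_cutoffs, default_item_maps
from .instruments import ItemMap, score_dataframe
from .pipeline import (
    demographics_table,
    missingness_checks,
    pct,
    report_flow,
    validate_records,
)
from .simulate import CohortScenario, matched_algorithm_spec, simulate_dataset
from .validity import validity_battery
from .weighting import (
    PopulationMargins,
    estimate_prevalence,
    extrapolate_count,
    fit_weights,
    prevalence_table,
)

__all__ = ["DementiaPrevalenceModel", "StudyResults"]

_FLOAT_FORMAT = "%.8g"  # fixed-precision serialization for byte-reproducibility


class DementiaPrevalenceModel:
    """Prevalence-survey analysis model for one country cohort.

    Parameters
    ----------
    data:
        Wide respondent frame (validated on construction; invalid rows are
        quarantined, not dropped silently).
    item_maps, algorithm_spec, cutoffs:
        Study configuration; the shipped synthetic demo configs are used
        when omitted.
    margins:
        National population margins for post-stratification weighting;
        without them only unweighted estimates are produced.
    flow:
        Recruitment-flow counts (``listed``, ``ineligible``, ``recruited``)
        for the flow report; defaults to a flow that starts at the data.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        *,
        item_maps: Mapping[str, ItemMap] | None = None,
        algorithm_spec: AlgorithmSpec | RuleChainSpec | None = None,
        cutoffs: Mapping[str, CutoffSpec] | None = None,
        margins: PopulationMargins | None = None,
        flow: dict | None = None,
        country: str | None = None,
        n_boot: int = 2000,
        ci_level: float = 0.95,
    ) -> None:
        self.item_maps = dict(item_maps or default_item_maps())
        self.algorithm_spec = algorithm_spec or default_algorithm_spec()
        self.cutoffs = dict(cutoffs if cutoffs is not None else default_cutoffs())
        self.margins = margins
        self.n_boot = int(n_boot)
        self.ci_level = float(ci_level)
        self.data, self.ingest_report = validate_records(data)
        self.country = country or str(self.data["country"].iloc[0])
        self.flow = flow or {"listed": len(self.data), "ineligible": {},
                             "recruited": len(self.data)}

    @classmethod
    def from_csv(
        cls, path: str | Path, *, margins_csv: str | Path | None = None, **kwargs
    ) -> "DementiaPrevalenceModel":
        from .config import load_margins_csv

        margins = load_margins_csv(margins_csv) if margins_csv else None
        return cls(pd.read_csv(path), margins=margins, **kwargs)

    @classmethod
    def from_simulation(
        cls, scenario: CohortScenario, seed: int | None = None, **kwargs
    ) -> "DementiaPrevalenceModel":
        """Generate a synthetic cohort and build the model on it, using the
        algorithm spec matched to the generator."""
        item_maps = kwargs.pop("item_maps", None) or default_item_maps()
        bundle = simulate_dataset(scenario, item_maps, seed=seed)
        kwargs.setdefault(
            "algorithm_spec", matched_algorithm_spec(scenario, item_maps)
        )
        model = cls(
            bundle["records"],
            item_maps=item_maps,
            margins=bundle["margins"],
            flow=bundle["flow"],
            country=scenario.country,
            **kwargs,
        )
        model.truth = bundle["truth"]
        model.missingness_log = bundle["missingness_log"]
        model.simulation_seed = bundle["seed"]
        return model

    def fit(self, seed: int = 0) -> "StudyResults":
        """Run the full analysis; ``seed`` drives the bootstrap only."""
        df = self.data
        scores = score_dataframe(df, self.item_maps.values())
        if isinstance(self.algorithm_spec, AlgorithmSpec):
            caseness = predict_dataframe(scores, self.algorithm_spec)
        else:  # rule-chain form: row-wise evaluation
            from .algorithm import predict_caseness
            from .instruments import score_all

            recs = [predict_caseness(score_all(r._asdict() if hasattr(r, "_asdict")
                                               else r, self.item_maps.values()),
                                     self.algorithm_spec)
                    for r in df.to_dict("records")]
            caseness = pd.DataFrame(
                {
                    "probability": [r.probability for r in recs],
                    "is_case": [r.is_case for r in recs],
                    "evaluable": [r.evaluable for r in recs],
                    "reason_not_evaluable": [r.reason_not_evaluable for r in recs],
                },
                index=df.index,
            )
        full = pd.concat([df, scores, caseness], axis=1)
        analysed, exclusions = completeness_filter(full, caseness)
        if len(analysed) == 0:
            raise ValueError("no analysable records after the completeness filter")
        analysed = analysed.copy()
        analysed["is_case"] = analysed["is_case"].astype(bool)

        flow_table = report_flow(self.flow, exclusions.n_excluded, len(analysed))
        demo = demographics_table(analysed)
        miss_checks = missingness_checks(full, caseness["evaluable"])

        weights = None
        weight_table = None
        if self.margins is not None:
            weight_table = fit_weights(
                analysed[["age_band", "sex", "literacy"]], self.margins
            )
            weights = weight_table.for_records(
                analysed[["age_band", "sex", "literacy"]]
            )
        prev = prevalence_table(
            analysed, "is_case", weights, level=self.ci_level
        )
        weighted_total = None
        unweighted_total = estimate_prevalence(
            analysed["is_case"], level=self.ci_level
        )
        national = None
        if weights is not None:
            weighted_total = estimate_prevalence(
                analysed["is_case"], weights, level=self.ci_level
            )
            if self.margins.total:
                national = extrapolate_count(weighted_total, self.margins.total)

        assoc_or = association_table(analysed, family="logistic")
        assoc_pr = association_table(analysed, family="poisson")

        lit_by_sex = []
        for sex in ("male", "female"):
            sub = analysed[analysed["sex"] == sex]
            lit_by_sex.append(
                [
                    int((sub["literacy"] == "literate").sum()),
                    int((sub["literacy"] == "illiterate").sum()),
                ]
            )
        literacy_mh = mantel_haenszel(
            [np.array(lit_by_sex)], measure="risk_ratio", labels=["all"]
        )

        cutoff_frames = {
            name: classify_cutoff_dataframe(
                analysed[[c for c in analysed.columns if c in scores.columns]], cut
            )
            for name, cut in self.cutoffs.items()
        }
        validity = validity_battery(
            analysed, cutoff_frames, n_boot=self.n_boot,
            seed=np.random.default_rng(seed),
        )

        metadata = {
            "package_version": _pkg_version,
            "country": self.country,
            "seed": seed,
            "n_boot": self.n_boot,
            "ci_level": self.ci_level,
            "algorithm_version": self.algorithm_spec.version,
            "item_map_versions": {k: m.version for k, m in self.item_maps.items()},
            "weighting_method": weight_table.method if weight_table else "none",
            "simulation_seed": getattr(self, "simulation_seed", None),
        }
        return StudyResults(
            model=self,
            analysed=analysed,
            scores=scores,
            caseness=caseness,
            exclusions=exclusions,
            flow=flow_table,
            demographics=demo,
            missingness_checks=miss_checks,
            weight_table=weight_table,
            weights=weights,
            prevalence=prev,
            unweighted_total=unweighted_total,
            weighted_total=weighted_total,
            national_count=national,
            odds_ratios=assoc_or,
            prevalence_ratios=assoc_pr,
            literacy_mh=literacy_mh,
            validity=validity,
            metadata=metadata,
        )


@dataclass
class StudyResults:
    """Fitted results bundle with report-shaped tables.

    Attributes mirror a survey report: ``demographics`` (key-demographics
    table), ``prevalence`` (subgroup and grand-total prevalence table),
    ``odds_ratios`` / ``prevalence_ratios`` (association tables),
    ``validity`` (effect sizes and cut-off agreement), ``flow``
    (recruitment flow), plus per-record intermediates and run metadata.
    """

    model: DementiaPrevalenceModel
    analysed: pd.DataFrame
    scores: pd.DataFrame
    caseness: pd.DataFrame
    exclusions: object
    flow: pd.DataFrame
    demographics: pd.DataFrame
    missingness_checks: pd.DataFrame
    weight_table: object
    weights: pd.Series | None
    prevalence: pd.DataFrame
    unweighted_total: object
    weighted_total: object
    national_count: dict | None
    odds_ratios: pd.DataFrame
    prevalence_ratios: pd.DataFrame
    literacy_mh: object
    validity: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    @property
    def n_analysed(self) -> int:
        return len(self.analysed)

    @property
    def exclusion_percent(self) -> float:
        return pct(self.exclusions.n_excluded, self.exclusions.n_input)

    def summary(self) -> str:
        u = self.unweighted_total
        lines = [
            f"Dementia prevalence study results — {self.metadata['country']}",
            "=" * 60,
            f"recruited {self.exclusions.n_input}, excluded "
            f"{self.exclusions.n_excluded} ({self.exclusion_percent}%) with "
            "insufficient data, analysed "
            f"{self.n_analysed}",
            f"unweighted prevalence {100 * u.point:.1f}% "
            f"(95% CI {100 * u.ci_low:.1f}-{100 * u.ci_high:.1f})",
        ]
        if self.weighted_total is not None:
            w = self.weighted_total
            lines.append(
                f"weighted prevalence   {100 * w.point:.1f}% "
                f"(95% CI {100 * w.ci_low:.1f}-{100 * w.ci_high:.1f}) "
                f"[n_eff {w.n_effective:.0f}]"
            )
        if self.national_count is not None:
            lines.append(
                f"extrapolated national count ~"
                f"{self.national_count['count_rounded_1000']:,.0f} people"
            )
        dx = self.demographics.set_index("measure")
        lines.append(
            "prior dementia diagnosis: "
            f"{int(dx.loc['prior dementia diagnosis', 'value'])} "
            f"({dx.loc['prior dementia diagnosis', 'percent']}%)"
        )
        lines.append(
            f"literacy risk ratio men vs women {self.literacy_mh.pooled_ratio:.2f} "
            f"(MH chi2 {self.literacy_mh.mh_chi2:.2f})"
        )
        lines.append("")
        lines.append("Odds of dementia (crude / age-adjusted):")
        for _, r in self.odds_ratios.iterrows():
            crude = "withheld" if r["crude"] is None or pd.isna(r["crude"]) else f"{r['crude']:.2f}"
            adj = ("-" if r["adjusted"] is None or pd.isna(r["adjusted"])
                   else f"{r['adjusted']:.2f}")
            lines.append(
                f"  {r['exposure']}={r['level']} vs {r['reference']}: "
                f"OR {crude} / {adj}"
            )
        lines.append("")
        lines.append("Convergent validity:")
        for _, r in self.validity.iterrows():
            if r["kind"] == "effect_size":
                lines.append(f"  {r['outcome']}: g = {r['estimate']:.2f} ({r['band']})")
            else:
                lines.append(
                    f"  {r['outcome']}: balanced accuracy {r['estimate']:.2f} "
                    f"(95% CI {r['ci_low']:.2f}-{r['ci_high']:.2f}, {r['band']})"
                )
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write the report tables as UTF-8 CSVs at fixed float precision."""
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "demographics": self.demographics,
            "flow": self.flow,
            "missingness_checks": self.missingness_checks,
            "prevalence": self.prevalence,
            "odds_ratios": self.odds_ratios,
            "prevalence_ratios": self.prevalence_ratios,
            "validity": self.validity,
            "caseness": pd.concat(
                [self.model.data[["respondent_id"]], self.caseness], axis=1
            ),
        }
        written = {}
        for name, tbl in tables.items():
            path = out / f"{name}.csv"
            tbl.to_csv(path, index=False, float_format=_FLOAT_FORMAT)
            written[name] = path
        meta = dict(self.metadata)
        meta["exclusions_by_reason"] = self.exclusions.by_reason
        import json

        (out / "metadata.json").write_text(json.dumps(meta, indent=2, default=str))
        written["metadata"] = out / "metadata.json"
        return written
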