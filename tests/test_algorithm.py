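"""Diagnostic algorithm, cut-off classifiers and completeness filter."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from stride_prev.algorithm import (
    AlgorithmSpec,
    ConfigError,
    CutoffSpec,
    RuleChainSpec,
    classify_cutoff,
    completeness_filter,
    predict_caseness,
    predict_dataframe,
)
from stride_prev.instruments import InstrumentScores


def make_scores(**vals):
    s = InstrumentScores()
    for name in ("cogscore", "relscore", "cerad", "eurod", "dsrs", "lawton"):
        v = vals.get(name)
        s.scores[name] = v
        s.evaluable[name] = v is not None
    return s


FULL = dict(cogscore=5, relscore=2, cerad=4, eurod=3, dsrs=10, lawton=6)


class TestPredictCaseness:
    def test_null_spec_gives_probability_half_and_tie_is_case(self):
        spec = AlgorithmSpec(0.0, {"cogscore": 0.0}, threshold=0.5)
        res = predict_caseness(make_scores(**FULL), spec)
        assert res.probability == 0.5
        assert res.is_case is True  # >= rule: ties classify as case

    def test_missing_required_input_is_not_evaluable(self):
        spec = AlgorithmSpec(0.0, {"cogscore": -1.0, "eurod": 0.5})
        vals = dict(FULL, eurod=None)
        res = predict_caseness(make_scores(**vals), spec)
        assert not res.evaluable and res.is_case is None
        assert "eurod" in res.reason_not_evaluable

    def test_probability_matches_independent_inverse_logit(self):
        """Exhaustive grid vs. brute-force arithmetic, to 1e-12."""
        spec = AlgorithmSpec(
            -3.2, {"cogscore": -0.7, "cerad": -0.35, "eurod": 0.4, "relscore": 1.1}
        )
        for cog, cer, eur, rel in itertools.product(
            range(0, 10, 3), range(0, 11, 5), range(0, 13, 4), range(0, 7, 2)
        ):
            res = predict_caseness(
                make_scores(cogscore=cog, cerad=cer, eurod=eur, relscore=rel), spec
            )
            lp = -3.2 + -0.7 * cog + -0.35 * cer + 0.4 * eur + 1.1 * rel
            expected = 1.0 / (1.0 + math.exp(-lp))
            assert abs(res.probability - expected) <= 1e-12

    def test_monotone_in_positively_weighted_score(self):
        spec = AlgorithmSpec(-1.0, {"relscore": 1.3, "cogscore": -0.9})
        probs = [
            predict_caseness(make_scores(**dict(FULL, relscore=r)), spec).probability
            for r in range(7)
        ]
        assert probs == sorted(probs)

    def test_rerun_and_dataframe_route_agree(self, item_maps):
        spec = AlgorithmSpec(-2.0, {"cogscore": -0.5, "eurod": 0.3})
        rng = np.random.default_rng(0)
        scores = pd.DataFrame(
            {
                "cogscore": rng.integers(0, 10, 50).astype(float),
                "eurod": rng.integers(0, 13, 50).astype(float),
            }
        )
        scores["cogscore_evaluable"] = True
        scores["eurod_evaluable"] = rng.random(50) > 0.2
        scores.loc[~scores["eurod_evaluable"], "eurod"] = np.nan
        a = predict_dataframe(scores, spec)
        b = predict_dataframe(scores.sample(frac=1, random_state=1), spec)
        merged = a.join(b, how="inner", lsuffix="_a", rsuffix="_b")
        assert (merged["evaluable_a"] == merged["evaluable_b"]).all()
        ok = merged["evaluable_a"]
        assert np.allclose(
            merged.loc[ok, "probability_a"], merged.loc[ok, "probability_b"]
        )

    def test_unknown_score_name_fails_at_load_time(self):
        with pytest.raises(ConfigError, match="unknown scores"):
            AlgorithmSpec(0.0, {"mmse": 1.0})
        with pytest.raises(ConfigError, match="threshold"):
            AlgorithmSpec(0.0, {"cogscore": 1.0}, threshold=1.5)


class TestRuleChain:
    def test_first_matching_rule_decides(self):
        spec = RuleChainSpec(
            rules=(
                ((("cogscore", "le", 3.0),), True),
                ((("cogscore", "le", 6.0), ("relscore", "ge", 3.0)), True),
            ),
            default=False,
        )
        assert predict_caseness(make_scores(**dict(FULL, cogscore=2)), spec).is_case
        assert predict_caseness(
            make_scores(**dict(FULL, cogscore=5, relscore=4)), spec
        ).is_case
        assert not predict_caseness(
            make_scores(**dict(FULL, cogscore=5, relscore=1)), spec
        ).is_case
        missing = predict_caseness(make_scores(cogscore=2), spec)
        assert not missing.evaluable


class TestCutoffs:
    def test_dsrs_floor_is_negative_and_ceiling_positive(self, cutoffs):
        cut = cutoffs["dsrs"]
        assert classify_cutoff(make_scores(**dict(FULL, dsrs=0)), cut) == (False, True)
        assert classify_cutoff(make_scores(**dict(FULL, dsrs=54)), cut) == (True, True)

    def test_brief_csid_rule_matches_hand_enumerated_truth_table(self, cutoffs):
        cut = cutoffs["brief_csid"]  # cog<=4, or (cog<=6 and rel>=3)
        for cog in range(10):
            for rel in range(7):
                expected = cog <= 4 or (cog <= 6 and rel >= 3)
                got, ok = classify_cutoff(
                    make_scores(**dict(FULL, cogscore=cog, relscore=rel)), cut
                )
                assert ok and got == expected, (cog, rel)

    def test_non_evaluable_score_makes_cutoff_non_evaluable(self, cutoffs):
        vals = dict(FULL, dsrs=None)
        assert classify_cutoff(make_scores(**vals), cutoffs["dsrs"]) == (None, False)

    def test_out_of_range_threshold_rejected(self, item_maps, tmp_path):
        from stride_prev.config import load_cutoffs
        import yaml

        doc = {"cutoffs": {"dsrs": {"clauses": [[["dsrs", "ge", 99]]]}}}
        path = tmp_path / "bad_cutoff.yaml"
        path.write_text(yaml.safe_dump(doc))
        with pytest.raises(ConfigError, match="outside"):
            load_cutoffs(path, item_maps)


class TestCompletenessFilter:
    @pytest.mark.parametrize("n, n_bad", [(2216, 106), (490, 82), (30, 0)])
    def test_retained_plus_excluded_conserves_input(self, n, n_bad):
        df = pd.DataFrame({"respondent_id": range(n)})
        caseness = pd.DataFrame(
            {
                "evaluable": [i >= n_bad for i in range(n)],
                "reason_not_evaluable": [
                    "missing_inputs:eurod" if i < n_bad else None for i in range(n)
                ],
            }
        )
        retained, log = completeness_filter(df, caseness)
        assert len(retained) == n - n_bad
        assert log.n_excluded == n_bad
        assert sum(log.by_reason.values()) == n_bad
        if n_bad:
            assert log.by_missing_input == {"eurod": n_bad}
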