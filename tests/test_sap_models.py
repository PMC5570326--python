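"""Published six-horizon model set, prediction, selection and validation."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import sapmodels as sm
from sapmodels.search import FittedModel, ModelSpec


class TestPublishedModels:
    def test_set_has_six_models_sharing_the_triple(self):
        model_set = sm.published_models()
        assert sorted(model_set.models) == [1, 2, 3, 4, 5, 6]
        assert model_set.items == ("ALB", "LDH", "NEU")

    def test_printed_constants(self):
        model_set = sm.published_models()
        assert model_set.models[1].cutoff == 0.496
        assert model_set.models[1].coefficients == {"ALB": -0.701, "LDH": 0.002,
                                                    "NEU": 0.023}
        assert model_set.models[1].intercept == -0.051
        assert model_set.models[6].coefficients["ALB"] == -0.334
        assert model_set.models[6].cutoff == 0.503

    def test_cutoffs_in_open_unit_interval(self):
        for m in sm.published_models().models.values():
            assert 0.0 < m.cutoff < 1.0


class TestPredictProbability:
    def test_zero_model_gives_half(self):
        model = FittedModel(spec=ModelSpec(("ALB",), 1),
                            coefficients={"ALB": 0.0}, intercept=0.0,
                            cutoff=0.5)
        assert sm.predict_probability(model, {"ALB": 3.5}) == 0.5

    @pytest.mark.parametrize("panel,expected_expr", [
        ({"ALB": 3.5, "LDH": 250.0, "NEU": 75.0},
         0.701 * 3.5 - 0.002 * 250.0 - 0.023 * 75.0 + 0.051),
        ({"ALB": 4.5, "LDH": 150.0, "NEU": 55.0},
         0.701 * 4.5 - 0.002 * 150.0 - 0.023 * 55.0 + 0.051),
    ])
    def test_hand_evaluation_of_one_month_model(self, panel, expected_expr):
        # independent scalar evaluation of the printed formula
        expected = 1.0 / (1.0 + math.exp(expected_expr))
        model = sm.published_models().models[1]
        assert sm.predict_probability(model, panel) == pytest.approx(
            expected, abs=1e-9)

    def test_hand_values_at_three_decimals(self):
        model = sm.published_models().models[1]
        assert round(sm.predict_probability(
            model, {"ALB": 3.5, "LDH": 250.0, "NEU": 75.0}), 3) == 0.431
        assert round(sm.predict_probability(
            model, {"ALB": 4.5, "LDH": 150.0, "NEU": 55.0}), 3) == 0.162

    def test_missing_item_named_in_error(self):
        model = sm.published_models().models[1]
        with pytest.raises(KeyError, match="LDH"):
            sm.predict_probability(model, {"ALB": 3.5, "NEU": 75.0})

    def test_batch_dataframe_matches_scalar_path(self):
        model = sm.published_models().models[3]
        table = pd.DataFrame({"ALB": [3.5, 4.2], "LDH": [300.0, 180.0],
                              "NEU": [80.0, 55.0]})
        batch = sm.predict_probability(model, table)
        for i in range(2):
            assert batch[i] == pytest.approx(
                sm.predict_probability(model, table.iloc[i].to_dict()),
                abs=1e-15)

    @pytest.mark.parametrize("horizon", range(1, 7))
    def test_monotone_in_each_item_with_printed_signs(self, horizon):
        model = sm.published_models().models[horizon]
        base = {"ALB": 3.5, "LDH": 250.0, "NEU": 65.0}
        p0 = sm.predict_probability(model, base)
        for item, direction in (("ALB", -1), ("LDH", +1), ("NEU", +1)):
            for delta in (0.5, 5.0, 50.0):
                bumped = dict(base, **{item: base[item] + delta})
                diff = sm.predict_probability(model, bumped) - p0
                assert direction * diff > 0


class TestClassify:
    def test_probability_exactly_at_cutoff_is_event(self):
        model = sm.published_models().models[1]
        panel = {"ALB": 3.5, "LDH": 250.0, "NEU": 75.0}
        p = sm.predict_probability(model, panel)
        at_cutoff = dataclasses.replace(model, cutoff=p)
        assert sm.classify(at_cutoff, panel)[0] == "event"

    def test_below_and_above_cutoff(self):
        model = sm.published_models().models[1]
        label, p = sm.classify(model, {"ALB": 3.5, "LDH": 250.0, "NEU": 75.0})
        assert label == "control" and p == pytest.approx(0.431, abs=5e-4)
        label, p = sm.classify(model, {"ALB": 1.5, "LDH": 500.0, "NEU": 90.0})
        assert label == "event" and p > 0.8

    def test_consistent_with_predict_probability_on_random_panels(self):
        rng = np.random.default_rng(99)
        model_set = sm.published_models()
        for _ in range(1000):
            panel = {"ALB": rng.uniform(1.0, 5.5),
                     "LDH": rng.uniform(100.0, 1000.0),
                     "NEU": rng.uniform(30.0, 95.0)}
            h = int(rng.integers(1, 7))
            model = model_set.models[h]
            label, p = sm.classify(model, panel)
            assert p == sm.predict_probability(model, panel)
            assert label == ("event" if p >= model.cutoff else "control")


class TestJsonRoundTrip:
    def test_fitted_model_lossless(self, tmp_path):
        model = FittedModel(spec=ModelSpec(("ALB", "LDH"), 4),
                            coefficients={"ALB": -0.12345678901234567,
                                          "LDH": 1e-9},
                            intercept=0.9876543210123456, cutoff=0.4999999999,
                            reg_lambda=0.01)
        path = tmp_path / "model.json"
        model.to_json(path)
        assert FittedModel.from_json(path) == model

    def test_model_set_lossless(self, tmp_path):
        model_set = sm.published_models()
        path = tmp_path / "set.json"
        model_set.to_json(path)
        assert sm.SAPModelSet.from_json(path) == model_set


def _results_frame(rows):
    df = pd.DataFrame(rows, columns=["items", "horizon", "auc"])
    df["status"] = "ok"
    for col in ["sensitivity", "specificity", "ppv", "npv", "accuracy"]:
        df[col] = 0.5
    return df


class TestSelectFamily:
    def test_unanimous_top_rank_wins(self):
        rows = []
        for h in (1, 2):
            rows += [(("A", "B"), h, 0.9), (("A", "C"), h, 0.8),
                     (("B", "C"), h, 0.7)]
        assert sm.select_family(_results_frame(rows)).items == ("A", "B")

    def test_best_rank_sum_without_being_first_everywhere(self):
        # A ranks (2,1,1,1,1,2); B takes the two firsts A misses; C trails
        aucs = {"A": [0.88, 0.90, 0.90, 0.90, 0.90, 0.88],
                "B": [0.90, 0.70, 0.70, 0.70, 0.70, 0.90],
                "C": [0.60, 0.80, 0.60, 0.60, 0.60, 0.60]}
        rows = [((name, name + "2"), h + 1, aucs[name][h])
                for name in aucs for h in range(6)]
        selection = sm.select_family(_results_frame(rows))
        assert selection.items == ("A", "A2")
        assert selection.rank_sums[("A", "A2")] == 8

    def test_rank_sum_tie_breaks_to_higher_mean_auc(self):
        rows = [(("A", "B"), 1, 0.9), (("C", "D"), 1, 0.8),
                (("A", "B"), 2, 0.6), (("C", "D"), 2, 0.9)]
        # both rank sums are 3; C+D has the higher mean AUC
        assert sm.select_family(_results_frame(rows)).items == ("C", "D")

    def test_inconsistent_universes_rejected(self):
        rows = [(("A", "B"), 1, 0.9), (("A", "B"), 2, 0.9),
                (("C", "D"), 2, 0.8)]
        with pytest.raises(ValueError, match="universe"):
            sm.select_family(_results_frame(rows))

    def test_top10_tables_have_rank_order(self, sweep8):
        _, _, _, results = sweep8
        selection = sm.select_family(results)
        for h, table in selection.top10().items():
            assert len(table) == 10
            assert table["rank"].tolist() == list(range(1, 11))
            assert (np.diff(table["auc"]) <= 0).all()


class TestExternalValidate:
    def _model_set(self, results):
        sig = results[results["items"] == ("ALB", "LDH", "NEU")]
        return sm.SAPModelSet({int(r.horizon): r.model
                               for r in sig.itertuples()})

    def test_same_cohort_same_seed_reproduces_search_metrics(self, sweep8):
        _, _, test, results = sweep8
        model_set = self._model_set(results)
        out = sm.external_validate(model_set, test, seed=7)
        sig = results[results["items"] == ("ALB", "LDH", "NEU")]
        for row in sig.itertuples():
            r = out[row.horizon]
            assert r.auc == row.auc
            assert r.sensitivity == row.sensitivity
            assert r.ppv == row.ppv
            assert r.accuracy == row.accuracy

    def test_horizon_subset_is_respected(self, sweep8):
        _, _, test, results = sweep8
        out = sm.external_validate(self._model_set(results), test,
                                   horizons=[1, 2, 3, 4, 5], seed=0)
        assert sorted(out) == [1, 2, 3, 4, 5]

    def test_published_models_discriminate_on_fresh_synthetic_cohort(self):
        config = sm.default_config(n_patients=200, n_items=5, seed=314)
        patients, obs = sm.generate_cohort(config)
        samples = sm.assemble_time_points(obs, patients)
        out = sm.external_validate(sm.published_models(), samples, seed=1)
        assert sorted(out) == [1, 2, 3, 4, 5, 6]
        for r in out.values():
            assert r.auc > 0.5

    def test_missing_required_item_rejected(self, sweep8):
        _, _, test, results = sweep8
        samples = test.drop(columns=["LDH"])
        with pytest.raises(ValueError, match="LDH"):
            sm.external_validate(self._model_set(results), samples, seed=0)


class TestModelSetInvariants:
    def test_wrong_horizon_coverage_rejected(self):
        models = sm.published_models().models
        with pytest.raises(ValueError):
            sm.SAPModelSet({h: m for h, m in models.items() if h != 3})

    def test_mixed_item_sets_rejected(self):
        models = dict(sm.published_models().models)
        rogue = FittedModel(spec=ModelSpec(("ALB", "LDH", "WBC"), 6),
                            coefficients={"ALB": -0.3, "LDH": 0.001,
                                          "WBC": 0.1},
                            intercept=0.0, cutoff=0.5)
        models[6] = rogue
        with pytest.raises(ValueError):
            sm.SAPModelSet(models)
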