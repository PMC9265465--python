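"""Factorial analysis: improvement percentages, effects, significance."""

from itertools import product

import numpy as np
import pandas as pd
import pytest

from fqdeg import datasets
from fqdeg.factorial import (DesignTable, EffectEstimate, FactorialModel,
                             binding_improvement, factorial_effects,
                             marginal_mean, scenario_report,
                             significance_screen)
from fqdeg.synthetic import gen_factorial_response


def ols_effect_oracle(design: DesignTable, max_order=None):
    """Effects as 2x least-squares coefficients on +-1-coded regressors."""
    from itertools import combinations
    signs = 2 * design.levels - 1
    k = signs.shape[1]
    max_order = max_order or k
    cols, terms = [np.ones(len(design.response))], []
    for order in range(1, max_order + 1):
        for idx in combinations(range(k), order):
            cols.append(np.prod(signs[:, idx], axis=1))
            terms.append(tuple(design.factor_names[i] for i in idx))
    beta, *_ = np.linalg.lstsq(np.column_stack(cols), design.response, rcond=None)
    return {t: 2 * b for t, b in zip(terms, beta[1:])}


class TestBindingImprovement:
    def test_published_values(self):
        assert binding_improvement(-102.160, -113.825) == 11.42
        assert binding_improvement(-49.445, -73.608) == 48.87

    def test_equal_energies_zero(self):
        assert binding_improvement(-80.0, -80.0) == 0.0

    def test_nonnegative_blank_rejected(self):
        with pytest.raises(ValueError):
            binding_improvement(5.0, -10.0)


@pytest.fixture(scope="module")
def scenarios():
    df = datasets.load_scenario_energies()
    return {s: dict(zip(sub["group"], sub["binding_energy"]))
            for s, sub in df.groupby("scenario")}


class TestScenarioReports:

    def test_scenario_two_beneficial_set_and_range(self, scenarios):
        rep = scenario_report(scenarios[2], factor_map=datasets.GROUP_ADDITIVES)
        assert rep["beneficial_groups"] == ["G1", "G3", "G5", "G8"]
        assert rep["improvement_range"] == (21.26, 31.74)

    def test_scenario_one_single_additive(self, scenarios):
        rep = scenario_report(scenarios[1], factor_map=datasets.GROUP_ADDITIVES)
        assert rep["beneficial_additives"] == ["AP"]
        assert rep["improvements"]["G5"] == 11.42

    def test_scenario_three_no_beneficial_group(self, scenarios):
        rep = scenario_report(scenarios[3])
        assert rep["beneficial_groups"] == []
        assert rep["improvement_range"] is None

    def test_scenario_four_range(self, scenarios):
        rep = scenario_report(scenarios[4])
        assert rep["improvement_range"] == (6.11, 16.01)

    def test_all_equal_to_blank(self):
        rep = scenario_report({"G0": -50.0, "G1": -50.0, "G2": -50.0})
        assert rep["beneficial_groups"] == []

    def test_missing_blank_rejected(self):
        with pytest.raises(ValueError):
            scenario_report({"G1": -50.0}, blank="G0")


class TestMarginalMeans:
    def test_field_measure_table(self, field_design):
        design, _, _ = field_design
        assert marginal_mean(design, "organic_fertilizer", 1) == -93.266
        assert marginal_mean(design, "straw_returning", 1) == -90.919
        assert marginal_mean(design, "plowing", 1) == -92.778

    def test_single_row_level(self):
        design = DesignTable(["a", "b"], ["f"], [[0], [1]], [-10.0, -20.0])
        assert marginal_mean(design, "f", 1) == -20.0

    def test_missing_level_rejected(self):
        design = DesignTable(["a", "b"], ["f"], [[1], [1]], [-10.0, -20.0])
        with pytest.raises(ValueError):
            marginal_mean(design, "f", 0)


class TestFactorialEffects:
    def test_plowing_main_effect_contrast_oracle(self, field_design):
        """Main effect equals the high/low marginal-mean difference."""
        design, _, _ = field_design
        effects = {e.term: e.estimate for e in factorial_effects(design)}
        expected = (marginal_mean(design, "plowing", 1, ndigits=None)
                    - marginal_mean(design, "plowing", 0, ndigits=None))
        assert effects[("plowing",)] == pytest.approx(expected, abs=1e-12)
        assert round(effects[("plowing",)], 3) == -9.474

    def test_additive_noiseless_case(self):
        rows = list(product((0, 1), repeat=2))
        y = [10 + 3 * a - 2 * b for a, b in rows]
        design = DesignTable([f"g{i}" for i in range(4)], ["A", "B"], rows, y)
        effects = {e.term: e.estimate for e in factorial_effects(design)}
        assert effects[("A",)] == pytest.approx(3.0)
        assert effects[("B",)] == pytest.approx(-2.0)
        assert effects[("A", "B")] == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("k", [3, 4])
    def test_equals_twice_ols_coefficients(self, k, rng):
        rows = list(product((0, 1), repeat=k))
        design = DesignTable([f"g{i}" for i in range(2 ** k)],
                             [f"F{j}" for j in range(k)], rows,
                             rng.normal(-90, 10, 2 ** k))
        ours = {e.term: e.estimate for e in factorial_effects(design)}
        oracle = ols_effect_oracle(design)
        for term, val in oracle.items():
            assert ours[term] == pytest.approx(val, abs=1e-9)

    def test_effects_are_linear(self, rng):
        rows = list(product((0, 1), repeat=3))
        names = [f"g{i}" for i in range(8)]
        y1, y2 = rng.normal(size=8), rng.normal(size=8)
        f = lambda y: np.array([e.estimate for e in factorial_effects(
            DesignTable(names, ["A", "B", "C"], rows, y))])
        assert np.allclose(f(y1) + f(y2), f(y1 + y2), atol=1e-12)

    def test_run_order_permutation_invariant(self, rng):
        rows = np.array(list(product((0, 1), repeat=3)))
        y = rng.normal(size=8)
        perm = rng.permutation(8)
        a = factorial_effects(DesignTable([f"g{i}" for i in range(8)],
                                          ["A", "B", "C"], rows, y))
        b = factorial_effects(DesignTable([f"g{i}" for i in perm],
                                          ["A", "B", "C"], rows[perm], y[perm]))
        assert {e.term: e.estimate for e in a} == {e.term: e.estimate for e in b}

    def test_incomplete_design_rejected(self):
        design = DesignTable(["a", "b", "c"], ["A", "B"],
                             [[0, 0], [0, 1], [1, 0]], [-1.0, -2.0, -3.0])
        with pytest.raises(ValueError, match="incomplete"):
            factorial_effects(design)

    def test_replicates_averaged_per_cell(self):
        rows = [(0,), (0,), (1,), (1,)]
        design = DesignTable(["a", "b", "c", "d"], ["A"], rows,
                             [1.0, 3.0, 10.0, 20.0])
        (eff,) = factorial_effects(design)
        assert eff.estimate == pytest.approx(15.0 - 2.0)


class TestSignificance:
    def test_replicated_anova_requires_replicates(self, field_design):
        design, _, _ = field_design
        effects = factorial_effects(design)
        with pytest.raises(ValueError, match="replicate"):
            significance_screen(effects, "replicated-anova", design=design)

    def test_lenth_type_one_error_controlled(self):
        """Pure-noise designs: at most ~5% of effects flagged across seeds."""
        flagged = total = 0
        for seed in range(200):
            design, _ = gen_factorial_response(seed, ["A", "B", "C", "D"],
                                               effects={}, sigma=1.0)
            screened = significance_screen(factorial_effects(design), "lenth")
            flagged += sum(e.significant for e in screened)
            total += len(screened)
        assert flagged / total <= 0.05

    def test_lenth_power_on_huge_effect(self):
        hits = 0
        for seed in range(100):
            design, _ = gen_factorial_response(seed, ["A", "B", "C", "D"],
                                               effects={("A",): 10.0}, sigma=1.0)
            screened = {e.term: e for e in
                        significance_screen(factorial_effects(design), "lenth")}
            hits += screened[("A",)].significant
        assert hits >= 99

    def test_pool_high_order_flags_main_effect(self):
        design, _ = gen_factorial_response(5, ["A", "B", "C"],
                                           effects={("A",): 20.0}, sigma=0.5)
        screened = significance_screen(factorial_effects(design),
                                       "pool-high-order")
        by_term = {e.term: e for e in screened}
        assert by_term[("A",)].significant
        assert by_term[("A", "B", "C")].method == "pooled-as-error"

    def test_replicated_anova_on_replicated_design(self):
        design, _ = gen_factorial_response(9, ["A", "B"],
                                           effects={("A",): 5.0}, sigma=0.5,
                                           replicates=4)
        screened = significance_screen(factorial_effects(design),
                                       "replicated-anova", design=design)
        by_term = {e.term: e for e in screened}
        assert by_term[("A",)].significant
        assert by_term[("A",)].method == "replicated-anova"


class TestEffectRecovery:
    def test_injected_effects_recovered_with_replication(self):
        """2^4 with sigma=0.5 and 20 replicates recovers effects to +-0.2."""
        truth = {("A",): 3.0, ("B",): -2.0, ("A", "B"): 1.5, ("C",): 0.8}
        good = trials = 0
        for seed in range(100):
            design, _ = gen_factorial_response(seed, ["A", "B", "C", "D"],
                                               effects=truth, sigma=0.5,
                                               replicates=20)
            est = {e.term: e.estimate for e in factorial_effects(design)}
            for term, val in truth.items():
                trials += 1
                good += abs(est[term] - val) <= 0.2
        assert good >= 0.95 * trials


class TestModelResults:
    def test_summary_contains_marginal_means(self, field_design):
        design, _, _ = field_design
        res = FactorialModel(design).fit()
        text = res.summary()
        assert "-93.266" in text and "organic_fertilizer" in text
        frame = res.effects_frame()
        assert set(frame.columns) >= {"term", "order", "estimate", "significant"}

    def test_from_dataframe_roundtrip(self, rng):
        rows = list(product((0, 1), repeat=2))
        df = pd.DataFrame(rows, columns=["A", "B"])
        df.insert(0, "group", [f"g{i}" for i in range(4)])
        df["response"] = rng.normal(-90, 5, 4)
        model = FactorialModel.from_dataframe(df)
        assert model.design.to_dataframe().equals(df)
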