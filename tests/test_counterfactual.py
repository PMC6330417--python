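import math

import numpy as np
import pytest

from disattrib.additive_hazard import ModelParams
from disattrib.attribution import AttributionResult
from disattrib.counterfactual import (
    CounterfactualScenario,
    baseline_attribution,
    cohort_band_prevalences,
    decompose_gap,
    expected_attribution,
    rank_band_split,
    run_scenario,
)
from disattrib.survey_data import DEFAULT_GROUPING, AgeGrouping, StandardPopulation, StudyDesign
from disattrib.synthetic_cohort import (
    default_standard_population,
    default_truth,
    generate_cohort,
)


def _one_band_design(m):
    grouping = AgeGrouping(
        background_bands=((25, math.inf),), rank_bands=((25, math.inf),)
    )
    return StudyDesign(
        diseases=tuple(f"d{i}" for i in range(m)),
        education_levels=("low",),
        grouping=grouping,
    )


def _one_band_params(design, alpha, delta):
    return ModelParams(
        alpha=np.array([[alpha]]),
        gamma=np.array([1.0]),
        delta=np.asarray(delta, dtype=float)[:, None],
        design=design,
    )


def _one_band_stdpop(design):
    return StandardPopulation({"male": np.array([1.0])}, design.grouping)


class TestRankBandSplit:
    def test_rows_sum_to_one(self):
        split = rank_band_split(DEFAULT_GROUPING)
        np.testing.assert_allclose(split.sum(axis=1), 1.0)

    def test_straddling_band_splits_evenly(self):
        split = rank_band_split(DEFAULT_GROUPING)
        # background band [50, 60) straddles rank bands [40,55) and [55,70)
        np.testing.assert_allclose(split[2], [0.0, 0.5, 0.5, 0.0])


class TestExpectedAttribution:
    def test_single_disease_closed_form(self):
        design = _one_band_design(1)
        beta = 0.6
        params = _one_band_params(design, alpha=0.0, delta=[beta])
        res = expected_attribution(
            params, np.array([[0.5]]), "low", "male", _one_band_stdpop(design)
        )
        assert res.prevalence == pytest.approx(0.5 * (1 - math.exp(-beta)), abs=1e-12)
        assert res.background == 0.0

    def test_no_disease_gives_background_only(self):
        design = _one_band_design(3)
        params = _one_band_params(design, alpha=0.3, delta=[0.5, 0.4, 0.2])
        res = expected_attribution(
            params, np.zeros((3, 1)), "low", "male", _one_band_stdpop(design)
        )
        assert res.prevalence == pytest.approx(1 - math.exp(-0.3), abs=1e-12)
        assert all(v == 0 for v in res.contributions.values())

    def test_matches_monte_carlo(self):
        design = _one_band_design(3)
        rng = np.random.default_rng(21)
        p = rng.uniform(0.05, 0.5, 3)
        delta = rng.uniform(0.1, 0.8, 3)
        alpha = 0.2
        params = _one_band_params(design, alpha=alpha, delta=delta)
        res = expected_attribution(
            params, p[:, None], "low", "male", _one_band_stdpop(design)
        )
        n = 1_000_000
        X = (rng.random((n, 3)) < p).astype(float)
        eta = alpha + X @ delta
        pi = -np.expm1(-eta)
        ratio = pi / eta
        mc_prev = pi.mean()
        se_prev = pi.std(ddof=1) / math.sqrt(n)
        assert abs(res.prevalence - mc_prev) <= 3 * se_prev
        bg = ratio * alpha
        assert abs(res.background - bg.mean()) <= 3 * bg.std(ddof=1) / math.sqrt(n)
        for i, d in enumerate(design.diseases):
            contrib = ratio * delta[i] * X[:, i]
            assert abs(res.contributions[d] - contrib.mean()) <= 3 * contrib.std(
                ddof=1
            ) / math.sqrt(n)

    def test_additivity(self, std_pop):
        truth = default_truth()
        p = truth.disease_prevalence[:, :, 0, 0]
        res = expected_attribution(
            truth.true_params["male"], p, "low", "male", std_pop
        )
        assert res.total_causes == pytest.approx(res.prevalence, abs=1e-10)


@pytest.fixture(scope="module")
def setup():
    truth = default_truth(n=40_000, seed=5)
    cohort = generate_cohort(truth)
    return truth, cohort, default_standard_population()


class TestRunScenario:
    def test_identity_swap_impact_reproduces_baseline(self, setup):
        truth, cohort, sp = setup
        params = truth.true_params["male"].copy()
        # donor's delta column made identical to recipient's: swap is a no-op
        params.delta[:, 2] = params.delta[:, 0]
        base = baseline_attribution(params, cohort, sp, "male", "low")
        swapped = run_scenario(
            params,
            cohort,
            CounterfactualScenario("swap_impact", "high", "low", "male"),
            sp,
        )
        assert swapped.prevalence == pytest.approx(base.prevalence, abs=1e-12)
        for d in params.design.diseases:
            assert swapped.contributions[d] == pytest.approx(
                base.contributions[d], abs=1e-12
            )

    def test_identity_swap_prevalence_close_to_baseline(self, setup):
        truth, cohort, sp = setup
        params = truth.true_params["male"]
        base = baseline_attribution(params, cohort, sp, "male", "low")
        prevs = cohort_band_prevalences(cohort.filter(sex="male", education="low"))
        ident = expected_attribution(params, prevs, "low", "male", sp)
        # diseases are generated independently, so the enumeration under
        # independence agrees with the empirical cohort up to sampling noise
        assert ident.prevalence == pytest.approx(base.prevalence, abs=0.01)

    def test_swap_prevalence_uses_donor_age_specific_rates(self, setup):
        truth, cohort, sp = setup
        params = truth.true_params["male"]
        res = run_scenario(
            params,
            cohort,
            CounterfactualScenario("swap_prevalence", "high", "low", "male"),
            sp,
        )
        base = baseline_attribution(params, cohort, sp, "male", "low")
        # donor (high) has lower disease prevalence, so the counterfactual
        # prevalence must fall below baseline
        assert res.prevalence < base.prevalence

    def test_invalid_scenario_rejected(self):
        with pytest.raises(ValueError, match="differ"):
            CounterfactualScenario("swap_impact", "low", "low", "male")
        with pytest.raises(ValueError, match="kind"):
            CounterfactualScenario("swap_everything", "high", "low", "male")


class TestDecomposeGap:
    @staticmethod
    def _result(prevalence, causes):
        background = prevalence - sum(causes.values())
        return AttributionResult(
            prevalence=prevalence,
            contributions=causes,
            background=background,
            atol=1e-9,
        )

    def test_identical_inputs_give_zero_gaps(self):
        r = self._result(0.4, {"a": 0.1, "b": 0.05})
        gap = decompose_gap(r, r, r, r)
        assert gap.baseline_gap == 0.0
        assert gap.remaining_gap_equal_prevalence == 0.0
        assert gap.remaining_gap_equal_impact == 0.0
        assert (gap.per_cause[["baseline_diff"]].to_numpy() == 0).all()

    def test_arithmetic(self):
        low = self._result(0.389, {"a": 0.1})
        high = self._result(0.209, {"a": 0.05})
        cf_p = self._result(0.308, {"a": 0.07})
        cf_i = self._result(0.328, {"a": 0.08})
        gap = decompose_gap(low, high, cf_p, cf_i)
        assert gap.baseline_gap == pytest.approx(0.18)
        assert gap.remaining_gap_equal_prevalence == pytest.approx(0.099)
        assert gap.remaining_gap_equal_impact == pytest.approx(0.119)

    def test_mismatched_cause_lists_rejected(self):
        a = self._result(0.3, {"a": 0.1})
        b = self._result(0.3, {"zzz": 0.1})
        with pytest.raises(ValueError, match="cause list"):
            decompose_gap(a, b, a, a)
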