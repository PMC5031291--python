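import math

import numpy as np
import pytest

from cellphenofit.fitting import (
    AggregatedSeries,
    AlignmentError,
    DegreesOfFreedomError,
    InsufficientDataError,
    aggregate_replicates,
    compute_mape,
    compute_reduced_chi2,
    compute_sem,
    compute_wsse,
    confidence_interval,
    fit_model,
    rank_models,
    select_models,
)
from cellphenofit.growth_models import InvalidInputError

from conftest import noiseless_series


class TestAggregateReplicates:
    def test_identical_replicates_have_zero_sd(self):
        agg = aggregate_replicates([([0, 1], [100, 100]), ([0, 1], [100, 100]),
                                    ([0, 1], [100, 100])])
        np.testing.assert_array_equal(agg.mean, [100, 100])
        np.testing.assert_array_equal(agg.sd, [0, 0])
        assert np.all(agg.n_replicates == 3)

    def test_sample_standard_deviation(self):
        agg = aggregate_replicates([([0], [90]), ([0], [100]), ([0], [110])])
        assert agg.mean[0] == pytest.approx(100.0)
        assert agg.sd[0] == pytest.approx(10.0)

    def test_single_replicate_sd_unavailable(self):
        agg = aggregate_replicates([([0, 1], [5, 6])])
        np.testing.assert_array_equal(agg.mean, [5, 6])
        assert np.all(np.isnan(agg.sd))

    def test_misaligned_grids_rejected(self):
        with pytest.raises(AlignmentError):
            aggregate_replicates([([0, 1], [1, 2]), ([0, 1.5], [1, 2])])

    def test_empty_input_rejected(self):
        with pytest.raises(InvalidInputError):
            aggregate_replicates([])


class TestMetrics:
    def test_wsse_zero_for_perfect_fit(self):
        assert compute_wsse([10, 20], [10, 20], [1, 1]) == 0.0

    def test_wsse_hand_examples(self):
        assert compute_wsse([100], [90], [2]) == pytest.approx(0.5)
        assert compute_wsse([100, 200], [110, 180], [1, 2]) == pytest.approx(2.0)

    def test_wsse_length_mismatch(self):
        with pytest.raises(InvalidInputError):
            compute_wsse([1, 2], [1], [1, 1])

    def test_mape_hand_example(self):
        assert compute_mape([100, 200], [90, 220]) == pytest.approx(10.0)
        assert compute_mape([5, 5], [5, 5]) == 0.0

    def test_mape_scale_invariant(self):
        a = compute_mape([100, 200], [90, 220])
        b = compute_mape([1000, 2000], [900, 2200])
        assert a == pytest.approx(b)

    def test_reduced_chi2(self):
        assert compute_reduced_chi2(10.0, 7, 2) == pytest.approx(2.0)
        assert compute_reduced_chi2(0.0, 5, 2) == 0.0
        with pytest.raises(DegreesOfFreedomError):
            compute_reduced_chi2(1.0, 3, 3)

    def test_sem_formula(self):
        sems = compute_sem(4.0, [[0.25, 0], [0, 0.0]], names=["a", "b"])
        assert sems["a"] == pytest.approx(1.0)
        assert sems["b"] == 0.0
        identity = compute_sem(1.0, np.eye(3))
        assert all(v == pytest.approx(1.0) for v in identity.values())

    def test_sem_rejects_negative_diagonal(self):
        with pytest.raises(InvalidInputError):
            compute_sem(1.0, [[-1.0]])


class TestFitModel:
    def test_recovers_exponential_rate_from_noiseless_data(self):
        truth = {"growth_rate": 0.05, "initial_live": 100.0}
        series = noiseless_series("live", truth, np.linspace(0, 72, 7))
        fit = fit_model("live", series)
        assert fit.converged
        assert fit.estimates["growth_rate"] == pytest.approx(0.05, rel=1e-6)
        assert fit.estimates["initial_live"] == pytest.approx(100.0, rel=1e-6)

    def test_two_point_exponential_is_exact(self):
        series = {"Live": AggregatedSeries("Live", [0.0, 10.0], [100.0, 200.0],
                                           [np.nan, np.nan], [1, 1])}
        fit = fit_model("live", series)
        assert fit.estimates["growth_rate"] == pytest.approx(math.log(2) / 10,
                                                             rel=1e-12)
        # n_data == n_parameters: fit-only, no uncertainty report
        assert fit.reduced_chi2 is None
        assert fit.sem is None

    def test_insufficient_points_for_three_parameter_model(self):
        series = {"Live": AggregatedSeries("Live", [0.0, 10.0], [100.0, 200.0],
                                           [np.nan, np.nan], [1, 1])}
        with pytest.raises(InsufficientDataError):
            fit_model("live_logistic", series)

    def test_metrics_invariant_to_time_point_order(self):
        rng = np.random.default_rng(3)
        t = np.linspace(0, 72, 8)
        data = 200 * np.exp(0.03 * t) * (1 + 0.05 * rng.standard_normal(8))
        sd = 0.05 * data
        perm = rng.permutation(8)
        f1 = fit_model("live", {"Live": AggregatedSeries("Live", t, data, sd,
                                                         np.full(8, 3))})
        # re-sort the permuted series back to increasing time: same content
        order = np.argsort(t[perm])
        f2 = fit_model("live", {"Live": AggregatedSeries(
            "Live", t[perm][order], data[perm][order], sd[perm][order],
            np.full(8, 3))})
        assert f1.wsse == pytest.approx(f2.wsse, rel=1e-9)
        assert f1.mape == pytest.approx(f2.mape, rel=1e-9)
        assert f1.reduced_chi2 == pytest.approx(f2.reduced_chi2, rel=1e-9)

    def test_wsse_is_locally_minimal(self):
        rng = np.random.default_rng(11)
        t = np.linspace(0, 72, 9)
        data = 300 * np.exp(0.04 * t) * (1 + 0.08 * rng.standard_normal(9))
        sd = 0.08 * np.abs(data)
        series = {"Live": AggregatedSeries("Live", t, data, sd, np.full(9, 5))}
        fit = fit_model("live", series)
        sigma = np.where(sd > 0, sd, 1.0)

        def wsse_at(r, n0):
            sim = n0 * np.exp(r * t)
            return float(np.sum((data - sim) ** 2 / (sigma * data)))

        r, n0 = fit.estimates["growth_rate"], fit.estimates["initial_live"]
        best = wsse_at(r, n0)
        for dr in (-0.01, 0.01):
            for dn in (-0.01, 0.01):
                assert wsse_at(r * (1 + dr), n0 * (1 + dn)) >= best

    def test_sem_shrinks_with_more_data(self):
        rng = np.random.default_rng(5)
        truth_r, n0 = 0.05, 200.0
        sems = {}
        for n_points in (6, 12):
            t = np.linspace(0, 60, n_points)
            reps = [(t, n0 * np.exp(truth_r * t)
                     * (1 + 0.05 * rng.standard_normal(n_points)))
                    for _ in range(4)]
            fit = fit_model("live", {"Live": aggregate_replicates(reps)})
            sems[n_points] = fit.sem["growth_rate"]
        assert sems[12] < sems[6]


class TestSelectModels:
    def test_live_only_seven_points(self):
        names = {s.name for s in select_models({"Live": 7})}
        assert names == {"live", "live_logistic"}

    def test_live_only_two_points_exponential_fallback(self):
        names = {s.name for s in select_models({"Live": 2})}
        assert names == {"live"}

    def test_live_dead_three_points_each(self):
        names = {s.name for s in select_models({"Live": 3, "Dead": 3})}
        assert "live_dead" in names               # 5 parameters <= 6 points
        assert "live_dead_logistic" in names      # 6 parameters == 6 points
        assert {"total", "total_logistic"} <= names

    def test_live_dead_two_points_each_excludes_six_parameter_model(self):
        names = {s.name for s in select_models({"Live": 2, "Dead": 2})}
        assert "live_dead_logistic" not in names  # 6 parameters > 4 points
        assert "live_dead" not in names           # 5 parameters > 4 points

    def test_everything_too_sparse(self):
        with pytest.raises(InsufficientDataError):
            select_models({"Live": 1})


class TestRanking:
    def _fit(self, name, chi2, mape, n_par):
        from cellphenofit.fitting import FitResult
        from cellphenofit.growth_models import ParameterSet, Trajectory
        return FitResult(model_name=name, estimates=ParameterSet(), sem=None,
                         covariance=None, wsse=chi2, mape=mape,
                         reduced_chi2=chi2, n_data=10, n_parameters=n_par,
                         fitted_trajectory=Trajectory([0.0], {"Live": [1.0]}),
                         converged=True)

    def test_orders_ascending_by_metric(self):
        fits = [self._fit("a", 2.0, 5.0, 2), self._fit("b", 1.5, 7.0, 3)]
        assert [f.model_name for f in rank_models(fits, "reduced_chi2")] == ["b", "a"]
        assert [f.model_name for f in rank_models(fits, "mape")] == ["a", "b"]

    def test_tie_breaks_on_parsimony_then_name(self):
        fits = [self._fit("z", 1.0, 1.0, 3), self._fit("a", 1.0, 1.0, 2),
                self._fit("b", 1.0, 1.0, 2)]
        assert [f.model_name for f in rank_models(fits, "mape")] == ["a", "b", "z"]

    def test_singleton(self):
        fits = [self._fit("only", 1.0, 1.0, 2)]
        assert rank_models(fits, "mape") == fits


class TestConfidenceInterval:
    def test_zero_sem_degenerate(self):
        assert confidence_interval(1.0, 0.0, 95) == (1.0, 1.0)

    def test_symmetric(self):
        lo, hi = confidence_interval(0.5, 0.1, 95)
        assert hi - 0.5 == pytest.approx(0.5 - lo)

    def test_z_multiplier_reproduces_printed_interval(self):
        # 0.0354 +/- 1.96*0.0017 ~= the printed [0.0322, 0.0388]
        lo, hi = confidence_interval(0.0354, 0.0017, 95)
        assert lo == pytest.approx(0.0321, abs=2e-4)
        assert hi == pytest.approx(0.0387, abs=2e-4)

    def test_invalid_level(self):
        with pytest.raises(InvalidInputError):
            confidence_interval(1.0, 0.1, 100)
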