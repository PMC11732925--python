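"""Recreation of populations from the four published-summary formats."""

import numpy as np
import pytest
from scipy import stats

import thresholdage as ta


class TestRecreateType2:
    def test_counts_and_interval_containment(self):
        s = ta.Type2Summary("third_molar", "male", {14: {"D": 2, "E": 3}})
        pop = ta.recreate_type2(s, seed=0)
        assert pop.n == 5
        assert sorted(pop.stages).count("D") == 2
        assert np.all((pop.ages >= 14) & (pop.ages < 15))

    def test_stage_range_limits_the_uniform_draw(self):
        s = ta.Type2Summary(
            "third_molar", "male", {14: {"E": 5}}, stage_ranges={"E": (14.3, 16.0)}
        )
        pop = ta.recreate_type2(s, seed=1)
        assert np.all((pop.ages >= 14.3) & (pop.ages < 15.0))

    def test_disjoint_stage_range_errors(self):
        s = ta.Type2Summary(
            "third_molar", "male", {14: {"E": 5}}, stage_ranges={"E": (16.0, 17.0)}
        )
        with pytest.raises(ta.SchemaError, match="disjoint"):
            ta.recreate_type2(s, seed=1)

    def test_cell_mean_matches_uniform_moment_oracle(self):
        # pooled mean over many recreations ~ interval midpoint within 3 SE
        s = ta.Type2Summary("third_molar", "male", {14: {"D": 1}})
        ages = np.array(
            [ta.recreate_type2(s, seed=i).ages[0] for i in range(4000)]
        )
        se = (1 / np.sqrt(12)) / np.sqrt(len(ages))
        assert abs(ages.mean() - 14.5) < 3 * se

    def test_same_seed_reproduces(self):
        s = ta.Type2Summary("third_molar", "male", {14: {"D": 4}, 15: {"E": 2}})
        a = ta.recreate_type2(s, seed=7)
        b = ta.recreate_type2(s, seed=7)
        assert np.array_equal(a.ages, b.ages)

    def test_fractions_constructor(self):
        s = ta.Type2Summary.from_fractions(
            "third_molar", "male",
            {14: {"D": 0.25, "E": 0.75}}, {14: 8},
        )
        assert s.cohort_counts[14] == {"D": 2, "E": 6}
        with pytest.raises(ta.SchemaError, match="sum"):
            ta.Type2Summary.from_fractions(
                "third_molar", "male", {14: {"D": 0.5, "E": 0.4}}, {14: 10}
            )


class TestTruncNormMomentFit:
    def test_unbounded_range_is_identity(self):
        f = ta.fit_truncnorm_moments(50, 16.0, 2.0, None)
        assert (f.mu, f.sigma) == (16.0, 2.0)

    def test_symmetric_range_gives_midpoint_mu(self):
        d = stats.truncnorm(-2, 2, loc=16, scale=1.5)
        f = ta.fit_truncnorm_moments(50, float(d.mean()), float(d.std()), (13, 19))
        assert f.mu == pytest.approx(16.0, abs=1e-6)

    def test_recovers_known_parameters_from_exact_moments(self):
        # closed-form truncated-normal moments as the oracle
        mu, sigma, lo, hi = 18.0, 2.0, 15.0, 21.0
        d = stats.truncnorm((lo - mu) / sigma, (hi - mu) / sigma, loc=mu, scale=sigma)
        f = ta.fit_truncnorm_moments(100, float(d.mean()), float(d.std()), (lo, hi))
        assert f.mu == pytest.approx(mu, abs=1e-3)
        assert f.sigma == pytest.approx(sigma, abs=1e-3)
        m, s = f.mean_sd()
        assert m == pytest.approx(d.mean(), abs=1e-6)
        assert s == pytest.approx(d.std(), abs=1e-6)

    def test_infeasible_sd_raises(self):
        # SD above the uniform limit on a narrow interval cannot be matched
        with pytest.raises(ta.FitInfeasibleError):
            ta.fit_truncnorm_moments(100, 16.0, 3.0, (15.0, 17.0))


class TestTruncNormQuantileFit:
    def test_recovers_parameters_from_theoretical_quantiles(self):
        fit_true = ta.TruncNormFit(18.0, 2.0, 10.0, 30.0)
        n = 50
        q = [
            float(fit_true.ppf(p))
            for p in (1 / (n + 1), 0.25, 0.5, 0.75, n / (n + 1))
        ]
        f = ta.fit_truncnorm_quantiles(q, (10.0, 30.0), n_obs=n)
        assert f.mu == pytest.approx(18.0, abs=0.05)
        assert f.sigma == pytest.approx(2.0, abs=0.05)

    def test_symmetric_quantiles_give_central_mu(self):
        f = ta.fit_truncnorm_quantiles([17.0, 19.0, 20.0, 21.0, 23.0], (15.0, 25.0))
        assert f.mu == pytest.approx(20.0, abs=1e-3)

    def test_degenerate_spread_errors(self):
        with pytest.raises(ta.DegenerateSpreadError):
            ta.fit_truncnorm_quantiles([16.0, 16.0, 16.0, 16.0, 16.0])

    def test_quartiles_only_mode(self):
        fit_true = ta.TruncNormFit(18.0, 2.0, 10.0, 30.0)
        q = [10.0, float(fit_true.ppf(0.25)), float(fit_true.ppf(0.5)),
             float(fit_true.ppf(0.75)), 30.0]
        f = ta.fit_truncnorm_quantiles(q, (10.0, 30.0), include_extremes=False)
        assert f.mu == pytest.approx(18.0, abs=0.01)
        assert f.sigma == pytest.approx(2.0, abs=0.01)


class TestRecreateType3:
    def test_support_containment_and_counts(self):
        s = ta.Type3aSummary(
            "third_molar", "male",
            {"E": ta.Stage3a(100, 18.0, 1.5, (10.0, 30.0))},
        )
        pop = ta.recreate_type3(s, seed=3)
        assert pop.n == 100
        assert np.all((pop.ages >= 10) & (pop.ages <= 30))

    def test_pooled_mean_matches_truncated_moment_oracle(self):
        lo, hi = 15.0, 21.0
        d = stats.truncnorm((lo - 18) / 2, (hi - 18) / 2, loc=18, scale=2)
        s = ta.Type3aSummary(
            "third_molar", "male",
            {"F": ta.Stage3a(200, float(d.mean()), float(d.std()), (lo, hi))},
        )
        pooled = np.concatenate(
            [ta.recreate_type3(s, seed=i).ages for i in range(50)]
        )
        se = d.std() / np.sqrt(len(pooled))
        assert abs(pooled.mean() - d.mean()) < 3 * se

    def test_zero_count_stage_absent(self):
        s = ta.Type3aSummary(
            "third_molar", "male",
            {"E": ta.Stage3a(10, 16.0, 1.0), "F": ta.Stage3a(0, 18.0, 1.0)},
        )
        pop = ta.recreate_type3(s, seed=0)
        assert set(pop.stages) == {"E"}

    def test_type3b_five_number_recreation(self):
        s = ta.Type3bSummary(
            "third_molar", "male",
            {"F": ta.Stage3b(80, 14.0, 16.5, 17.5, 18.6, 21.0)},
        )
        pop = ta.recreate_type3(s, seed=5)
        assert pop.n == 80
        assert np.all((pop.ages >= 14.0) & (pop.ages <= 21.0))


class TestRecreateType4:
    @staticmethod
    def _summary(r, n=10_000):
        grid = {str(v): float(v) for v in range(10, 23)}
        return ta.Type4Summary(
            "hand_wrist", "male",
            (ta.Cohort4(n, 16.0, 2.0, 16.0, 2.0, r),),
            grid,
        )

    def test_zero_correlation_gives_independent_stages(self):
        pop = ta.recreate_type4(self._summary(0.0), seed=0)
        sa = np.array([float(s) for s in pop.stages])
        r = np.corrcoef(pop.ages, sa)[0, 1]
        assert abs(r) < 3 / np.sqrt(pop.n)

    def test_conditional_sampling_recovers_correlation(self):
        pop = ta.recreate_type4(self._summary(0.9), seed=1)
        sa = np.array([float(s) for s in pop.stages])
        r = np.corrcoef(pop.ages, sa)[0, 1]
        # discretisation to a 1-year grid attenuates r slightly; 3 SE + grid slack
        assert r == pytest.approx(0.9, abs=0.02)

    def test_single_observation(self):
        pop = ta.recreate_type4(self._summary(0.5, n=1), seed=2)
        assert pop.n == 1
        assert pop.stages[0] in {str(v) for v in range(10, 23)}

    def test_degenerate_correlation_errors(self):
        with pytest.raises(ta.SchemaError):
            self._summary(1.5)
        with pytest.raises(ta.FitError):
            ta.recreate_type4(self._summary(1.0), seed=0)

    def test_empty_label_grid_errors(self):
        with pytest.raises(ta.SchemaError):
            ta.Type4Summary(
                "hand_wrist", "male", (ta.Cohort4(5, 16, 2, 16, 2, 0.5),), {}
            )


class TestEnsemble:
    def test_reproducible_and_distinct(self):
        s = ta.Type2Summary("third_molar", "male", {14: {"D": 5}, 15: {"E": 5}})
        e1 = ta.simulate_population_ensemble(s, n_pops=3, seed=9)
        e2 = ta.simulate_population_ensemble(s, n_pops=3, seed=9)
        assert len(e1) == 3
        for a, b in zip(e1, e2):
            assert np.array_equal(a.ages, b.ages)
        assert not np.array_equal(e1[0].ages, e1[1].ages)

    def test_type1_passthrough(self, tiny_pop):
        ensemble = ta.simulate_population_ensemble(tiny_pop, n_pops=4, seed=0)
        assert len(ensemble) == 4
        assert all(p is tiny_pop for p in ensemble)


class TestSummaryDocumentIO:
    @pytest.mark.parametrize("as_type", ["type2", "type3a", "type3b", "type4"])
    def test_yaml_round_trip_is_lossless(self, tmp_path, as_type):
        truth = ta.preset_truth("third_molar", "male", n=400, seed=3)
        pop = ta.generate_population(truth)
        summary = ta.summarize(pop, as_type)
        path = tmp_path / f"{as_type}.yaml"
        ta.write_summary(summary, path)
        back = ta.read_summary(path)
        assert back == summary

    def test_unknown_type_rejected(self, tmp_path):
        path = tmp_path / "x.yaml"
        path.write_text("type: type9\n")
        with pytest.raises(ta.SchemaError, match="type9"):
            ta.read_summary(path)
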