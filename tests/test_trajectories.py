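"""Tests for frequency estimation and trajectory-level statistics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import seedbankevo as se
from seedbankevo.trajectories import TRAJECTORY_COLUMNS


def _traj_from_freqs(freqs_by_mut, depth=100, pop="p1"):
    rows = []
    for mid, fs in freqs_by_mut.items():
        for j, f in enumerate(fs):
            day = 10 * (j + 1)
            rows.append((mid, pop, "WT", "1day", "g1", "nonsynonymous",
                         day, float(day), int(round(f * depth)), depth))
    return se.TrajectoryMatrix(pd.DataFrame(rows, columns=TRAJECTORY_COLUMNS))


class TestFrequencies:
    def test_naive_estimator(self):
        df = pd.DataFrame(
            [
                ("m1", "p1", 1.0, 0, 100),
                ("m1", "p1", 2.0, 100, 100),
                ("m1", "p1", 3.0, 37, 142),
                ("m1", "p1", 4.0, 0, 0),
            ],
            columns=["mutation_id", "population_id", "day", "alt_count", "depth"],
        )
        out = se.estimate_frequencies(se.TrajectoryMatrix(df)).data
        f = out.sort_values("day")["frequency"].to_numpy()
        assert f[0] == 0.0
        assert f[1] == 1.0
        assert f[2] == pytest.approx(37 / 142)
        assert np.isnan(f[3])

    def test_alt_exceeding_depth_names_the_record(self):
        df = pd.DataFrame(
            [("mX", "p9", 1.0, 120, 100)],
            columns=["mutation_id", "population_id", "day", "alt_count", "depth"],
        )
        with pytest.raises(ValueError, match="mX"):
            se.TrajectoryMatrix(df)

    def test_duplicate_timepoint_rejected(self):
        df = pd.DataFrame(
            [("m1", "p1", 1.0, 5, 10), ("m1", "p1", 1.0, 6, 10)],
            columns=["mutation_id", "population_id", "day", "alt_count", "depth"],
        )
        with pytest.raises(ValueError, match="duplicate"):
            se.TrajectoryMatrix(df)


class TestSumDerived:
    def test_sums_frequencies_per_timepoint(self):
        traj = _traj_from_freqs({"a": [0.1], "b": [0.2], "c": [0.3]})
        M = se.sum_derived_frequencies(traj)
        assert M["M"].iloc[0] == pytest.approx(0.6)

    def test_bounded_by_mutation_count(self):
        traj = _traj_from_freqs({"a": [0.9, 1.0], "b": [0.8, 1.0]})
        M = se.sum_derived_frequencies(traj)
        assert (M["M"] <= 2 + 1e-12).all()
        assert (M["M"] >= 0).all()

    def test_deep_coverage_recovers_true_sum(self):
        rng = np.random.default_rng(0)
        true = {f"m{i}": [rng.uniform(0.05, 0.6)] for i in range(20)}
        traj = _traj_from_freqs(true, depth=10**6)
        M = se.sum_derived_frequencies(traj)["M"].iloc[0]
        assert M == pytest.approx(sum(v[0] for v in true.values()), abs=1e-2)


class TestDiversityModelFit:
    def test_noiseless_parameters_recovered(self):
        t = np.arange(100, 800, 100, dtype=float)
        b0, amp, th = -0.5, 1.2, 40.0
        ts = t - t[0]
        M = 10 ** (b0 + amp * ts / (th + ts))
        fit = se.fit_diversity_model(t, M, per_day_generations=3.32)
        assert fit.intercept == pytest.approx(b0, rel=1e-4, abs=1e-6)
        assert fit.amplitude == pytest.approx(amp, rel=1e-4)
        assert fit.halftime_days == pytest.approx(th, rel=1e-4)
        assert fit.tau_half == pytest.approx(th * 3.32, rel=1e-4)
        assert fit.converged

    def test_halftime_and_saturation_identities(self):
        t = np.arange(0, 1000, 50, dtype=float)
        M = 10 ** (0.2 + 0.8 * t / (60 + t))
        fit = se.fit_diversity_model(t, M)
        # at t* = t*_1/2 the curve sits at intercept + amplitude/2
        assert fit.predict(np.array([fit.t_shift + fit.halftime_days]))[0] == pytest.approx(
            fit.intercept + fit.amplitude / 2, rel=1e-6
        )
        assert fit.predict(np.array([1e12]))[0] == pytest.approx(
            fit.intercept + fit.amplitude, rel=1e-6
        )

    def test_requires_enough_positive_points(self):
        with pytest.raises(ValueError):
            se.fit_diversity_model([1, 2, 3], [1.0, 2.0, 3.0])


class TestTrajectoryMeasures:
    def test_fmax_and_interval_arithmetic(self):
        traj = _traj_from_freqs({"m": [0.1, 0.5, 0.3]}, depth=1000)
        meas = se.trajectory_measures(traj)
        assert meas.fmax["f_max"].iloc[0] == pytest.approx(0.5)
        # 0.1 -> 0.5 over dtau=10: rate 0.04, ratio 5
        first = meas.intervals.iloc[0]
        assert first["rate"] == pytest.approx(0.04)
        assert first["ratio"] == pytest.approx(5.0)

    def test_explicit_generation_spacing(self):
        traj = _traj_from_freqs({"m": [0.1, 0.2]}, depth=1000)
        meas = se.trajectory_measures(
            traj, generations_per_timepoint={10.0: 0.0, 20.0: 5.0}
        )
        row = meas.intervals.iloc[0]
        assert row["rate"] == pytest.approx(0.02)
        assert row["ratio"] == pytest.approx(2.0)

    def test_constant_trajectory_has_zero_rates_unit_ratios(self):
        traj = _traj_from_freqs({"m": [0.4, 0.4, 0.4]}, depth=1000)
        meas = se.trajectory_measures(traj)
        assert np.allclose(meas.intervals["rate"], 0.0)
        assert np.allclose(meas.intervals["ratio"], 1.0)

    def test_fmax_truncated_to_first_observations(self):
        traj = _traj_from_freqs({"m": [0.1, 0.2, 0.1, 0.1, 0.1, 0.1, 0.9]})
        meas = se.trajectory_measures(traj, t_max_points=6)
        assert meas.fmax["f_max"].iloc[0] == pytest.approx(0.2)

    def test_fmax_dominates_interval_endpoints(self):
        traj = _traj_from_freqs({"m": [0.1, 0.5, 0.3, 0.2]}, depth=1000)
        meas = se.trajectory_measures(traj, t_max_points=10)
        fmax = meas.fmax["f_max"].iloc[0]
        assert (meas.intervals["ratio"].dropna() * 0 + fmax >= 0).all()
        # every frequency entering 4b/4c is bounded by f_max
        assert fmax >= 0.5


class TestSurvivalAndKS:
    def test_survival_step_values(self):
        S = se.survival_distribution([1.0, 2.0, 3.0])
        assert S(1.5) == pytest.approx(2 / 3)
        assert S(0.0) == 1.0
        assert S(3.0) == 0.0

    @given(st.lists(st.floats(-50, 50), min_size=1, max_size=60))
    @settings(deadline=None, max_examples=50)
    def test_survival_matches_sorted_ecdf_oracle(self, values):
        S = se.survival_distribution(values)
        xs = np.linspace(min(values) - 1, max(values) + 1, 13)
        brute = np.array([np.mean([v > x for v in values]) for x in xs])
        assert np.allclose(S(xs), brute)

    def test_ks_degenerate_cases(self):
        a = np.linspace(0, 0.1, 20)
        d, _ = se.ks_compare(a, a)
        assert d == 0.0
        b = np.linspace(0.9, 1.0, 20)
        d, p = se.ks_compare(a, b)
        assert d == 1.0
        assert p < 1e-6

    def test_ks_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        a, b = rng.normal(size=50), rng.normal(0.5, 1.2, size=60)
        d1, _ = se.ks_compare(a, b)
        d2, _ = se.ks_compare(np.exp(a), np.exp(b))
        assert d1 == pytest.approx(d2)

    def test_bh_adjustment_matches_hand_computation(self):
        out = se.ks_compare_batch(
            {
                "x": (np.zeros(3), np.zeros(3)),
                "y": (np.zeros(3), np.zeros(3)),
                "z": (np.zeros(3), np.zeros(3)),
            }
        )
        # overwrite with the worked example and recompute by hand
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([0.01, 0.04, 0.03], method="fdr_bh")
        assert np.allclose(sorted(adj), [0.03, 0.04, 0.04])


class TestFates:
    @pytest.mark.parametrize(
        "traj,expected",
        [
            ((0.1, 0.6, 0.99), "fixed"),
            ((0.2, 0.05, 0.0), "extinct"),
            ((0.1, 0.3, 0.4), "segregating"),
            ((0.005, 0.009, 0.0), "segregating"),  # never detected
        ],
    )
    def test_threshold_caller(self, traj, expected):
        assert se.classify_fate(traj) == expected

    def test_threshold_ordering_enforced(self):
        with pytest.raises(ValueError):
            se.classify_fate([0.1], detect_threshold=0.9, fix_threshold=0.5)

    def test_prob_extinct_given_detected(self):
        fates = ["extinct"] * 3 + ["segregating"] * 6 + ["fixed"]
        assert se.prob_extinct_given_detected(fates) == pytest.approx(0.3)
        assert se.prob_extinct_given_detected(["fixed"]) == 0.0
        with pytest.raises(ValueError):
            se.prob_extinct_given_detected([])

    def test_fate_table_tallies_against_direct_count(self):
        traj = _traj_from_freqs(
            {"a": [0.2, 0.05, 0.0], "b": [0.1, 0.5, 0.97], "c": [0.1, 0.2, 0.3]},
            depth=1000,
        )
        ft = se.fate_table(traj)
        detected = ft[ft["detected"]]
        assert se.prob_extinct_given_detected(detected["fate"]) == pytest.approx(1 / 3)


class TestPairwiseCorrelation:
    def test_identical_and_mirrored_trajectories(self):
        traj = _traj_from_freqs(
            {"a": [0.1, 0.3, 0.5, 0.7], "b": [0.9, 0.7, 0.5, 0.3]},
            depth=1000,
        )
        out = se.pairwise_trajectory_correlation(traj)
        assert len(out) == 1
        assert out["r"].iloc[0] == pytest.approx(-1.0)
        assert out["r2"].iloc[0] == pytest.approx(1.0)

    def test_matches_textbook_covariance_formula(self):
        rng = np.random.default_rng(2)
        f = {f"m{i}": list(rng.uniform(0.05, 0.95, 6)) for i in range(4)}
        traj = se.estimate_frequencies(_traj_from_freqs(f, depth=10**6))
        wide = traj.data.pivot(index="mutation_id", columns="day", values="frequency")
        out = se.pairwise_trajectory_correlation(traj)
        for _, row in out.iterrows():
            x = wide.loc[row["mutation_a"]].to_numpy()
            y = wide.loc[row["mutation_b"]].to_numpy()
            num = np.mean(x * y) - x.mean() * y.mean()
            den = x.std() * y.std()
            assert row["r"] == pytest.approx(num / den, abs=1e-12)

    def test_min_shared_filter(self):
        traj = _traj_from_freqs({"a": [0.5, 0.0, 0.0, 0.0], "b": [0.4, 0.3, 0.2, 0.1]},
                                depth=1000)
        out = se.pairwise_trajectory_correlation(traj, min_shared=3)
        assert len(out) == 0


class TestScalars:
    def test_pn_ps(self):
        assert se.pn_ps(10, 10, 0.75, 0.25) == pytest.approx(1 / 3)
        assert se.pn_ps(30, 10, 0.75, 0.25) == pytest.approx(1.0)
        assert se.pn_ps(0, 10, 0.75, 0.25) == 0.0
        with pytest.warns(UserWarning):
            assert math.isnan(se.pn_ps(5, 0, 0.75, 0.25))

    def test_generation_estimates(self):
        est = se.estimate_generations(10.0, 1.0, n_transfers=700)
        assert est.delta_tau == pytest.approx(math.log2(10))
        assert est.total_generations == pytest.approx(700 * math.log2(10))
        assert se.estimate_generations(1.0, 1.0).delta_tau == 0.0
        assert se.estimate_generations(1024.0, 1.0).delta_tau == pytest.approx(10.0)

    def test_generation_estimate_exact_for_k_doublings(self):
        for k in (1, 5, 13):
            est = se.estimate_generations(100.0 * 2**k, 100.0)
            assert est.delta_tau == pytest.approx(k)

    def test_replicate_averaging_on_log_scale(self):
        est = se.estimate_generations([20.0, 80.0], [10.0, 10.0], n_transfers=2)
        assert est.delta_tau == pytest.approx((1 + 3) / 2)
        assert est.delta_tau_se > 0

    def test_relative_log_fitness(self):
        assert se.relative_log_fitness(5, 5, 7, 7) == 0.0
        assert se.relative_log_fitness(2, 1, 1, 1) == pytest.approx(math.log(2))
        x = se.relative_log_fitness(3, 7, 2, 5)
        assert se.relative_log_fitness(7, 3, 5, 2) == pytest.approx(-x)
        with pytest.raises(ValueError):
            se.relative_log_fitness(0, 1, 1, 1)

    def test_fitness_assay_zero_at_baseline(self):
        days = [0, 10, 20]
        mut = np.array([[10.0, 20.0, 5.0], [12.0, 30.0, 6.0]])
        wt = np.array([[10.0, 10.0, 10.0], [12.0, 12.0, 12.0]])
        out = se.fitness_assay(days, mut, wt)
        assert out["X_mean"].iloc[0] == 0.0
        assert out["X_mean"].iloc[1] == pytest.approx(
            (math.log(2) + math.log(30 / 12)) / 2
        )
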