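"""Ensembles, emergence statistics, estimators, and the RFA harness."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from phagelattice import (
    Trajectory,
    ValidationError,
    early_lysogenization_fit,
    emergence_contingency,
    emergence_cv,
    emergence_time,
    estimate_population_adsorption,
    invasion_metrics,
    permutation_importance,
    run_ensemble,
    sample_sweep,
    scenario,
)
from phagelattice.analysis import (
    DUMMY_COLUMN,
    Ensemble,
    SweepTable,
    _sample_parameters,
    derive_seeds,
)


def synthetic_trajectory(counts_by_label, meta=None):
    """Trajectory built directly from per-label count sequences."""
    traj = Trajectory(meta=meta or {"capacity": 2500})
    n = max(len(v) for v in counts_by_label.values())
    for t in range(n):
        traj.record(
            t, {key: float(series[t]) for key, series in counts_by_label.items()}
        )
    return traj


def synthetic_ensemble(trajectories):
    return Ensemble(None, None, list(range(len(trajectories))), trajectories)


class TestEnsemble:
    def test_single_replicate_has_zero_width_ci(self):
        traj = synthetic_trajectory({("bacterium_total", "all"): [5, 6, 7]})
        ens = synthetic_ensemble([traj])
        mean, lo, hi = ens.mean_ci("bacterium_total", "all")
        assert (mean == lo).all() and (mean == hi).all()

    def test_identical_replicates_have_zero_width_ci(self):
        trajs = [
            synthetic_trajectory({("bacterium_total", "all"): [5, 6, 7]})
            for _ in range(4)
        ]
        ens = synthetic_ensemble(trajs)
        mean, lo, hi = ens.mean_ci("bacterium_total", "all")
        assert np.allclose(lo, hi)

    def test_run_ensemble_is_deterministic(self, minimal_config_pair):
        general, eco = minimal_config_pair
        e1 = run_ensemble(general, eco, 3, master_seed=5)
        e2 = run_ensemble(general, eco, 3, master_seed=5)
        assert e1.seeds == e2.seeds
        assert all(a == b for a, b in zip(e1.trajectories, e2.trajectories))
        assert all(s < 2**31 for s in e1.seeds)


class TestEmergence:
    def _traj(self, counts):
        return synthetic_trajectory({("bacterium_class", "B:double_resistant"): counts})

    def test_never_reaching_threshold_gives_none(self):
        assert emergence_time(self._traj([0, 5, 50]), "B:double_resistant", 100) is None

    def test_first_crossing(self):
        assert emergence_time(self._traj([0, 50, 120]), "B:double_resistant", 100) == 2

    def test_threshold_one_is_first_nonzero(self):
        assert emergence_time(self._traj([0, 0, 3, 9]), "B:double_resistant", 1) == 2

    def test_unknown_label_rejected(self):
        with pytest.raises(ValidationError):
            emergence_time(self._traj([0, 1]), "nonexistent", 1)

    def test_cv_of_two_detection_times(self):
        ens = synthetic_ensemble(
            [self._traj([0] * t + [150]) for t in (10, 20)]
        )
        cv, n = emergence_cv(ens, "B:double_resistant", 100)
        assert n == 2
        assert cv == pytest.approx(5 * np.sqrt(2) / 15)

    def test_cv_zero_when_synchronous(self):
        ens = synthetic_ensemble([self._traj([0, 0, 200]) for _ in range(5)])
        cv, n = emergence_cv(ens, "B:double_resistant", 100)
        assert cv == 0.0 and n == 5

    def test_cv_none_without_detections(self):
        ens = synthetic_ensemble([self._traj([0, 0, 0]) for _ in range(5)])
        cv, n = emergence_cv(ens, "B:double_resistant", 100)
        assert cv is None and n == 0

    def test_cv_scale_invariance(self):
        times_a = (5, 8, 13)
        times_b = tuple(3 * t for t in times_a)
        ens_a = synthetic_ensemble([self._traj([0] * t + [150]) for t in times_a])
        ens_b = synthetic_ensemble([self._traj([0] * t + [150]) for t in times_b])
        cv_a, _ = emergence_cv(ens_a, "B:double_resistant", 100)
        cv_b, _ = emergence_cv(ens_b, "B:double_resistant", 100)
        assert cv_a == pytest.approx(cv_b)


class TestContingency:
    def test_identical_full_detection_is_null(self):
        stat, p = emergence_contingency(30, 30, 30, 30)
        assert stat == 0.0 and p == 1.0

    def test_identical_proportions_are_null(self):
        stat, p = emergence_contingency(15, 30, 15, 30)
        assert stat == 0.0 and p == 1.0

    def test_exhaustive_match_with_scipy_yates(self):
        """Against scipy's Yates-corrected test over every 2x2 table with
        margins n1 = n2 = 30 (the independent oracle)."""
        for k1 in range(31):
            for k2 in range(31):
                stat, p = emergence_contingency(k1, 30, k2, 30)
                table = np.array([[k1, 30 - k1], [k2, 30 - k2]])
                if 0 in table.sum(axis=0):
                    assert stat == 0.0 and p == 1.0
                    continue
                ref = scipy.stats.chi2_contingency(table, correction=True)
                assert stat == pytest.approx(ref.statistic, abs=1e-10)
                assert p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValidationError):
            emergence_contingency(5, 4, 1, 30)
        with pytest.raises(ValidationError):
            emergence_contingency(0, 0, 1, 30)


class TestAdsorptionEstimator:
    def _exponential_ensemble(self, k, hosts=200.0, p0=1e6, n_iter=8):
        """Noise-free decline P_{t+1} = P_t * exp(-k * hosts) (no decay)."""
        phage = [p0 * np.exp(-k * hosts * t) for t in range(n_iter)]
        traj = synthetic_trajectory(
            {
                ("phage_total", "free"): phage,
                ("bacterium_total", "all"): [hosts] * n_iter,
            }
        )
        return synthetic_ensemble([traj])

    def test_recovers_known_constant_within_one_percent(self):
        k = 3.7e-4
        ens = self._exponential_ensemble(k)
        est = estimate_population_adsorption(ens, window=(0, 5), decay_prob=0.0)
        assert est == pytest.approx(k, rel=0.01)

    def test_decay_correction(self):
        k, decay = 2e-4, 0.05
        hosts, p0 = 150.0, 1e6
        phage = [p0 * ((1 - decay) ** t) * np.exp(-k * hosts * t) for t in range(8)]
        traj = synthetic_trajectory(
            {
                ("phage_total", "free"): phage,
                ("bacterium_total", "all"): [hosts] * 8,
            }
        )
        est = estimate_population_adsorption(
            synthetic_ensemble([traj]), window=(0, 5), decay_prob=decay
        )
        assert est == pytest.approx(k, rel=0.01)

    def test_zero_adsorption_gives_zero_rate(self):
        ens = self._exponential_ensemble(0.0)
        est = estimate_population_adsorption(ens, window=(0, 5), decay_prob=0.0)
        assert est == pytest.approx(0.0, abs=1e-12)

    def test_refuses_short_windows(self):
        traj = synthetic_trajectory(
            {
                ("phage_total", "free"): [100.0, 0.0, 0.0, 0.0, 0.0, 0.0],
                ("bacterium_total", "all"): [50.0] * 6,
            }
        )
        with pytest.raises(ValidationError):
            estimate_population_adsorption(
                synthetic_ensemble([traj]), window=(0, 5), decay_prob=0.0
            )

    def test_monotone_in_individual_adsorption_probability(self):
        """Higher per-virion adsorption gives a larger population-level rate
        estimate in paired simulated ensembles."""
        rates = {}
        for ads in (0.2, 0.8):
            # adsorption-assay analog: no bursts or decay, so the free-virion
            # decline reflects adsorption alone
            general, eco = scenario(
                "fig2_phage",
                {"adsorption_prob": ads, "initial_phage_count": 400,
                 "decay_prob": 0.0, "burst_size": 0, "n_iterations": 6},
            )
            ens = run_ensemble(general, eco, 5, master_seed=31)
            rates[ads] = estimate_population_adsorption(ens, window=(0, 5))
        assert rates[0.8] > rates[0.2] > 0


class TestInvasionMetrics:
    def test_initial_ratio_and_partition(self):
        general, eco = scenario("fig5_invasion")
        traj = __import__("phagelattice").run(general, eco, seed=6)
        m = invasion_metrics(traj)
        row0 = m.frame.iloc[0]
        assert row0.invader / (row0.resident_sensitive + row0.resident_lysogen) == pytest.approx(0.1)
        # frequencies partition lattice capacity together with empty space
        freqs = (
            m.frame.invader_freq
            + m.frame.resident_sensitive_freq
            + m.frame.resident_lysogen_freq
        )
        assert (freqs <= 1.0 + 1e-12).all()

    def test_no_phage_no_lysogenization(self):
        general, eco = scenario("fig5_invasion", {"induction_prob": 0.0})
        traj = __import__("phagelattice").run(general, eco, seed=6)
        m = invasion_metrics(traj)
        assert (m.frame.resident_lysogen == 0).all()
        assert m.response == 0.0

    def test_missing_labels_rejected(self):
        traj = synthetic_trajectory({("bacterium_species", "other"): [1.0] * 20})
        with pytest.raises(ValidationError):
            invasion_metrics(traj)


class TestEarlyGrowthFit:
    def _quadratic_ensemble(self, a, b=0.0, c=0.0, reps=3, n=15):
        trajs = []
        for _ in range(reps):
            counts = [a * t * t + b * t + c for t in range(n)]
            trajs.append(
                synthetic_trajectory({("bacterium_class", "resident:lysogen"): counts})
            )
        return synthetic_ensemble(trajs)

    def test_exact_polynomial_recovery(self):
        ens = self._quadratic_ensemble(2.0)
        fit = early_lysogenization_fit(ens, ens, window=10)
        for coeffs in fit.coefficients.values():
            assert coeffs[0] == pytest.approx(2.0, abs=1e-8)
            assert coeffs[1] == pytest.approx(0.0, abs=1e-8)
            assert coeffs[2] == pytest.approx(0.0, abs=1e-8)

    def test_null_case_not_significant(self):
        """Identical stochastic ensembles show no significant trend
        difference in at least 19 of 20 meta-repetitions."""
        rng = np.random.default_rng(8)
        rejections = 0
        for _ in range(20):
            trajs = []
            for _ in range(8):
                noise = rng.normal(0, 1, 12).cumsum()
                counts = np.maximum(0, 3 * np.arange(12.0) + noise)
                trajs.append(
                    synthetic_trajectory(
                        {("bacterium_class", "resident:lysogen"): counts}
                    )
                )
            ens_a = synthetic_ensemble(trajs[:4])
            ens_b = synthetic_ensemble(trajs[4:])
            fit = early_lysogenization_fit(ens_a, ens_b, window=10)
            rejections += fit.interaction_pvalue < 0.05
        assert rejections <= 1

    def test_window_longer_than_trajectory_rejected(self):
        ens = self._quadratic_ensemble(1.0, n=5)
        with pytest.raises(ValidationError):
            early_lysogenization_fit(ens, ens, window=10)


class TestSweep:
    RANGES = {
        "burst_size": ("randint", 10, 100),
        "adsorption_prob": ("uniform", 0.1, 1.0),
        "lysogeny_curve": ("choice", ("Lysogeny1", "Lysogeny2", "Lysogeny3")),
    }

    def _small_sweep(self, n=4, repeats=1, seed=11):
        return sample_sweep(
            self.RANGES,
            n,
            repeats,
            seed,
            base_overrides={"width": 15, "height": 15, "count:invader": 20,
                            "count:resident": 200, "n_iterations": 16},
        )

    def test_table_shape_and_dummy_column(self):
        table = self._small_sweep(n=4)
        assert len(table.frame) == 4
        assert DUMMY_COLUMN in table.frame.columns
        assert set(table.frame[DUMMY_COLUMN]) <= {1.0, 2.0, 3.0}
        assert "response" in table.frame.columns

    def test_sweep_deterministic(self):
        t1 = self._small_sweep(n=3, seed=21)
        t2 = self._small_sweep(n=3, seed=21)
        pd.testing.assert_frame_equal(t1.frame, t2.frame)

    def test_dummy_independent_of_parameters(self):
        """By construction the dummy column is independent of every sampled
        parameter: |Spearman rho| < 0.1 (several null SDs at n = 2000; no
        simulations needed)."""
        rng = np.random.default_rng(3)
        frame, _ = _sample_parameters(self.RANGES, 2000, rng)
        for col in self.RANGES:
            rho = scipy.stats.spearmanr(frame[col], frame[DUMMY_COLUMN]).statistic
            assert abs(rho) < 0.1

    def test_empty_ranges_rejected(self):
        with pytest.raises(ValidationError):
            sample_sweep({}, 3, 1, 0)


class TestPermutationImportance:
    def _planted_table(self, n=150, seed=0):
        rng = np.random.default_rng(seed)
        frame, _ = _sample_parameters(
            {
                "driver": ("uniform", 0.0, 1.0),
                "noise_a": ("uniform", 0.0, 1.0),
                "noise_b": ("randint", 1, 50),
            },
            n,
            rng,
        )
        frame["response"] = frame["driver"] * 10 + rng.normal(0, 0.3, n)
        return SweepTable(frame)

    def test_planted_driver_ranks_first_dummy_at_noise_floor(self):
        table = self._planted_table()
        report = permutation_importance(table, n_trees=300, seed=1)
        assert report.ranking[0] == "driver"
        assert report.importances["driver"] > 3 * max(report.dummy_importance, 1.0)
        assert set(report.non_important) <= {"noise_a", "noise_b"}

    def test_constant_response_warns_and_zeroes(self):
        table = self._planted_table()
        table.frame["response"] = 1.0
        with pytest.warns(UserWarning):
            report = permutation_importance(table, n_trees=50, seed=1)
        assert all(v == 0.0 for v in report.importances.values())

    def test_shuffled_response_has_no_important_parameters(self):
        """Destroying the signal leaves every importance near the dummy's."""
        table = self._planted_table(seed=2)
        rng = np.random.default_rng(4)
        table.frame["response"] = rng.permutation(table.frame["response"].to_numpy())
        report = permutation_importance(table, n_trees=300, seed=3)
        spread = max(report.importances.values()) - min(report.importances.values())
        assert max(report.importances.values()) < 15.0
        assert spread < 15.0

    def test_planted_recovery_rate_over_seeds(self):
        """The planted driver is recovered as rank 1 in >= 95% of 20 seeded
        repetitions."""
        wins = 0
        for seed in range(20):
            table = self._planted_table(n=120, seed=seed)
            report = permutation_importance(table, n_trees=120, seed=seed)
            wins += report.ranking[0] == "driver"
        assert wins >= 19

    def test_too_few_rows_rejected(self):
        table = self._planted_table(n=20)
        with pytest.raises(ValidationError):
            permutation_importance(table, n_trees=10, seed=0, min_rows=50)


def test_derived_seeds_are_deterministic_and_bounded():
    s1 = derive_seeds(123, 5)
    s2 = derive_seeds(123, 5)
    assert s1 == s2
    assert len(set(s1)) == 5
    assert all(0 <= s < 2**31 for s in s1)
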