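"""Firing rates, selectivity tests, d-prime, ramping, durations, classes."""

import numpy as np
import pandas as pd
import pytest

from tmaze.selectivity import (
    classify_neurons,
    conjunctive_scatter,
    dprime,
    duration_comparison,
    firing_rate,
    ramping_profile,
    trajectory_selectivity,
    turn_selectivity,
)


class TestFiringRate:
    def test_empty_window_is_zero(self):
        assert firing_rate(np.array([5.0, 6.0]), 0.0, 2.0) == 0.0

    def test_count_over_duration(self):
        spikes = np.array([0.1, 0.5, 0.9, 1.3, 1.7])
        assert firing_rate(spikes, 0.0, 2.0) == pytest.approx(2.5)

    def test_half_open_window_excludes_right_edge(self):
        spikes = np.array([1.0, 2.0])
        # spike exactly at t1 is excluded, spike exactly at t0 is included
        assert firing_rate(spikes, 0.0, 2.0) == pytest.approx(0.5)
        assert firing_rate(spikes, 1.0, 2.0) == pytest.approx(1.0)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ValueError):
            firing_rate(np.array([1.0]), 2.0, 2.0)


def make_turn_samples(rng, left_mean, right_mean, n_per_turn=10, sd=1.0):
    rows = []
    for tid in range(1, 9):
        for d, mu in (("left", left_mean), ("right", right_mean)):
            for _ in range(n_per_turn):
                rows.append({"turn_id": tid, "direction": d,
                             "rate": max(rng.normal(mu, sd), 0.0)})
    return pd.DataFrame(rows)


class TestTurnSelectivity:
    def test_recovers_synthetic_left_preference(self):
        rng = np.random.default_rng(1)
        res = turn_selectivity(make_turn_samples(rng, 9.0, 5.0))
        assert res.is_selective and res.preferred_direction == "left"
        assert res.p_direction < 1e-6

    def test_anova_p_is_scale_invariant(self):
        rng = np.random.default_rng(2)
        df = make_turn_samples(rng, 6.0, 5.0)
        p1 = turn_selectivity(df).p_direction
        df2 = df.assign(rate=df["rate"] * 2)
        p2 = turn_selectivity(df2).p_direction
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_zero_variance_design_flagged_not_selective(self):
        df = make_turn_samples(np.random.default_rng(0), 5.0, 5.0, sd=0.0)
        res = turn_selectivity(df)
        assert res.degenerate and not res.is_selective
        assert np.isnan(res.p_direction)

    def test_single_direction_rejected(self):
        df = pd.DataFrame({"turn_id": [1, 1], "direction": ["left", "left"], "rate": [1, 2]})
        with pytest.raises(ValueError, match="direction 'right'"):
            turn_selectivity(df)

    def test_additive_model_option(self):
        rng = np.random.default_rng(3)
        df = make_turn_samples(rng, 8.0, 5.0)
        res = turn_selectivity(df, include_interaction=False)
        assert res.is_selective


class TestTrajectorySelectivity:
    def test_recovers_context_gain(self):
        rng = np.random.default_rng(4)
        r1 = rng.normal(8.0, 1.0, 20)
        r2 = rng.normal(5.0, 1.0, 20)
        res = trajectory_selectivity(r1, r2)
        assert res.is_selective and res.preferred_origin == "R1"

    def test_identical_samples_not_selective(self):
        a = np.array([1.0, 2.0, 3.0])
        res = trajectory_selectivity(a, a)
        assert not res.is_selective
        assert res.p == pytest.approx(1.0)

    def test_constant_equal_groups_flagged(self):
        res = trajectory_selectivity([2.0, 2.0], [2.0, 2.0])
        assert res.degenerate and not res.is_selective

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            trajectory_selectivity([1.0], [1.0, 2.0])


class TestDPrime:
    def test_hand_computed_example_pins_the_convention(self):
        # a = {2,4}, b = {1,3}: means 3 and 2, centred pool {-1,1,-1,1},
        # sigma = sqrt(4/3), d' = 1/sigma = sqrt(3)/2
        res = dprime([2.0, 4.0], [1.0, 3.0])
        assert res.mu_a == 3.0 and res.mu_b == 2.0
        assert res.sigma == pytest.approx(np.sqrt(4.0 / 3.0))
        assert res.d_prime == pytest.approx(np.sqrt(3.0) / 2.0)

    def test_identical_distributions_give_zero(self):
        a = [1.0, 2.0, 3.0]
        assert dprime(a, a).d_prime == 0.0

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(5)
        a, b = rng.normal(3, 1, 15), rng.normal(1, 1, 12)
        assert dprime(a, b).d_prime == pytest.approx(-dprime(b, a).d_prime)

    def test_matches_direct_formula_on_random_gaussian_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(200):
            a = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), rng.integers(3, 30))
            b = rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 2), rng.integers(3, 30))
            pooled = np.concatenate([a - a.mean(), b - b.mean()])
            want = (a.mean() - b.mean()) / pooled.std(ddof=1)
            assert abs(dprime(a, b).d_prime - want) <= 1e-12

    def test_group_ddof_convention_available(self):
        a, b = [2.0, 4.0], [1.0, 3.0]
        res = dprime(a, b, ddof=2)
        assert res.sigma == pytest.approx(np.sqrt(4.0 / 2.0))

    def test_zero_sigma_with_unequal_means_signalled(self):
        with pytest.raises(ValueError, match="sigma"):
            dprime([1.0, 1.0], [2.0, 2.0])


class TestDurationComparison:
    def test_identical_groups_give_p_one(self):
        med_c, med_e, p = duration_comparison([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert med_c == med_e == 2.0
        assert p == pytest.approx(1.0)

    def test_medians_match_direct_sorting(self):
        rng = np.random.default_rng(7)
        a, b = rng.uniform(0, 3, 21), rng.uniform(0, 6, 15)
        med_a, med_b, _ = duration_comparison(a, b)
        assert med_a == sorted(a)[10]
        assert med_b == np.median(b)

    def test_detects_doubled_error_durations_at_reference_group_sizes(self):
        # error trials ~2x slower, n = 16 errors vs 77 correct
        rng = np.random.default_rng(8)
        hits = 0
        for _ in range(30):
            correct = np.exp(rng.normal(np.log(1.06), 0.35, 77))
            error = np.exp(rng.normal(np.log(2.08), 0.35, 16))
            _, _, p = duration_comparison(correct, error)
            hits += p < 0.05
        assert hits >= 27

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            duration_comparison([], [1.0])


class TestRampingProfile:
    @staticmethod
    def table_one_neuron():
        rows = []
        rates = {"preferred": {"correct": 10.0, "error": 6.0},
                 "unpreferred": {"correct": 3.0, "error": 4.0}}
        for nm in "abcdefghij":
            for pref, by_out in rates.items():
                for out, r in by_out.items():
                    rows.append({"neuron": 0, "interval": nm, "preference": pref,
                                 "outcome": out, "rate": r})
        return pd.DataFrame(rows)

    def test_single_trial_curves_equal_the_neurons_rates(self):
        res = ramping_profile(self.table_one_neuron())
        assert res.curves.loc["h", ("preferred", "correct")] == 10.0
        assert res.curves.loc["h", ("unpreferred", "error")] == 4.0

    def test_averaging_invariant_to_row_order(self):
        df = self.table_one_neuron()
        shuffled = df.sample(frac=1.0, random_state=0)
        a = ramping_profile(df).curves
        b = ramping_profile(shuffled).curves
        pd.testing.assert_frame_equal(a.sort_index(axis=1), b.sort_index(axis=1))

    def test_missing_error_trials_flagged(self):
        df = self.table_one_neuron()
        df = df[df["outcome"] == "correct"]
        res = ramping_profile(df)
        assert not res.error_trials_present
        assert ("preferred", "error") not in res.curves.columns

    def test_homogeneous_neurons_show_no_condition_separation(self):
        rng = np.random.default_rng(9)
        rows = []
        for n in range(20):
            for nm in "abcdefghij":
                for pref in ("preferred", "unpreferred"):
                    for out in ("correct", "error"):
                        for _ in range(6):
                            rows.append({"neuron": n, "interval": nm, "preference": pref,
                                         "outcome": out, "rate": rng.poisson(5.0)})
        res = ramping_profile(pd.DataFrame(rows))
        at_h = res.curves.loc["h"]
        assert at_h.max() - at_h.min() < 1.5  # well within sampling error bounds

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            ramping_profile(pd.DataFrame(columns=["neuron", "interval", "preference", "outcome", "rate"]))


class TestClassification:
    def test_known_neuron_classes_recovered_end_to_end(
        self, library, small_session, labelled_neurons
    ):
        _, track, _ = small_session
        specs, spikes = labelled_neurons
        turn_windows = library.turn_table(track)
        trial_table = library.choice_trial_table(track)
        df = classify_neurons(spikes, turn_windows, trial_table).set_index("neuron")
        assert df.loc[0, "class"] == "turn"
        assert df.loc[0, "preferred_turn"] == "left"
        assert df.loc[1, "class"] == "trajectory"
        assert df.loc[1, "preferred_origin"] == "R1"
        assert df.loc[2, "class"] == "conjunctive"
        assert df.loc[3, "class"] == "none"

    def test_pure_turn_cell_has_dominant_turn_dprime(
        self, library, small_session, labelled_neurons
    ):
        _, track, _ = small_session
        _, spikes = labelled_neurons
        df = classify_neurons(
            spikes, library.turn_table(track), library.choice_trial_table(track)
        ).set_index("neuron")
        assert abs(df.loc[0, "turn_dprime"]) > 3 * abs(df.loc[0, "trajectory_dprime"])

    def test_conjunctive_scatter_excludes_unselective_neurons(
        self, library, small_session, labelled_neurons
    ):
        _, track, _ = small_session
        _, spikes = labelled_neurons
        cls = classify_neurons(
            spikes, library.turn_table(track), library.choice_trial_table(track)
        )
        table = conjunctive_scatter(cls)
        assert set(table["neuron"]) == {0, 1, 2}
        assert set(table.columns) == {"neuron", "turn_dprime", "trajectory_dprime", "class"}
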