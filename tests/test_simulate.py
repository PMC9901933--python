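"""Synthetic-session generator: determinism, state budgets, event placement,
ground-truth consistency, and regime structure."""

import numpy as np
import pytest

from pupephys.core import EpochSet
from pupephys.simulate import (
    SimParams,
    SpindleSpec,
    UnitSpec,
    generate_behavior,
    generate_lfp,
    generate_session,
    generate_spikes,
    generate_state_sequence,
    generate_urethane_session,
)


class TestStateSequence:
    def test_occupancy_matches_dwell_means(self):
        """Alternating renewal with dwell means 60/30 s gives an AS
        fraction near 2/3 over a long session."""
        p = SimParams(seed=3, duration_s=3000.0,
                      state_dwell_means_s={"AS": 60.0, "wake": 30.0},
                      include_quiescence=False)
        eps = generate_state_sequence(p)
        frac = eps.duration("AS") / eps.duration()
        # Monte-Carlo check over independent seeds stays within a few SE
        assert frac == pytest.approx(2 / 3, abs=0.08)

    def test_short_session_single_epoch(self):
        p = SimParams(seed=4, duration_s=10.0,
                      state_dwell_means_s={"AS": 60.0, "wake": 60.0},
                      include_quiescence=False)
        eps = generate_state_sequence(p)
        assert eps.duration() == pytest.approx(10.0)
        assert len(eps) >= 1

    def test_fixed_seed_is_deterministic(self):
        p = SimParams(seed=5, duration_s=500.0)
        assert generate_state_sequence(p).intervals == generate_state_sequence(p).intervals

    def test_covers_session_exactly(self):
        p = SimParams(seed=6, duration_s=777.0)
        eps = generate_state_sequence(p)
        assert eps.span() == (0.0, 777.0)
        assert eps.duration() == pytest.approx(777.0)


class TestBehavior:
    @pytest.mark.parametrize("seed", [0, 7, 42])
    def test_twitches_confined_to_as(self, seed):
        p = SimParams(seed=seed, duration_s=400.0)
        states = generate_state_sequence(p)
        _, _, events, _ = generate_behavior(states, p)
        for t in events["twitch"].onsets_s:
            assert states.label_at(t) == "AS"
        for t in events["wake_movement"].onsets_s:
            assert states.label_at(t) == "wake"

    def test_exact_stimulation_count(self):
        p = SimParams(seed=8, duration_s=300.0)
        states = generate_state_sequence(p)
        _, _, events, _ = generate_behavior(states, p)
        assert events["stimulation"].n == 50
        gaps = np.diff(events["stimulation"].onsets_s)
        assert gaps.min() >= 2.0 and gaps.max() <= 3.0

    def test_zero_twitch_rate_flat_during_as(self):
        p = SimParams(seed=9, duration_s=300.0, twitch_rate_hz=0.0,
                      movement_noise_sd=0.0)
        states = generate_state_sequence(p)
        movement, _, events, _ = generate_behavior(states, p)
        assert events["twitch"].n == 0
        from pupephys.core import restrict_signal
        as_samples, _ = restrict_signal(movement, states, "AS")
        np.testing.assert_allclose(as_samples, p.movement_baseline)

    def test_bumps_are_supra_threshold(self):
        p = SimParams(seed=10, duration_s=300.0)
        states = generate_state_sequence(p)
        movement, _, events, true_moves = generate_behavior(states, p)
        thr = 3 * p.movement_baseline
        for a, b in true_moves.intervals_for("movement")[:10]:
            seg = movement.slice_time(a + 0.01, b - 0.01).samples
            assert (seg > thr).all()


class TestLfp:
    def test_zero_amplitude_gives_no_truth(self):
        p = SimParams(seed=11, duration_s=120.0,
                      spindles=SpindleSpec(amplitude_mult=0.0))
        states = generate_state_sequence(p)
        lfp, truth = generate_lfp(states, {}, p)
        assert truth == []
        assert lfp.samples.std() == pytest.approx(p.lfp_noise_sd, rel=1e-6)

    def test_truth_durations_at_least_100ms(self):
        p = SimParams(seed=12, duration_s=600.0)
        states = generate_state_sequence(p)
        _, truth = generate_lfp(states, {}, p)
        assert truth  # non-degenerate fixture
        for a, b, _ in truth:
            assert b - a >= 0.1

    def test_burst_rate_within_3se_of_poisson_expectation(self):
        """Realized burst count across seeds stays within 3 SE of the
        state-weighted Poisson expectation."""
        counts, expects = [], []
        for seed in range(5):
            p = SimParams(seed=seed, duration_s=1200.0)
            states = generate_state_sequence(p)
            _, truth = generate_lfp(states, {}, p)
            counts.append(len(truth))
            dur_hi = p.spindles.duration_range_s[1]
            exp = sum(
                max(0.0, (b - a) - dur_hi) * {"AS": p.spindles.rate_as_per_min,
                                              "wake": p.spindles.rate_wake_per_min}.get(lab, 0.0) / 60.0
                for a, b, lab in states.intervals
            )
            expects.append(exp)
        total, exp_total = sum(counts), sum(expects)
        se = np.sqrt(exp_total)
        assert abs(total - exp_total) <= 3 * se

    def test_spindle_duration_floor_enforced(self):
        with pytest.raises(ValueError):
            SpindleSpec(duration_range_s=(0.05, 0.2))


class TestSpikes:
    def test_as_wake_rate_ratio_recovered(self):
        """Continuous-regime generator at AS 4 Hz / wake 2 Hz over 3000 s
        recovers the 2:1 ratio within 5% (pooled over the default
        multi-unit population, as in a real recording)."""
        p = SimParams(seed=13, duration_s=3000.0, regime="p12_continuous")
        states = generate_state_sequence(p)
        trains, _ = generate_spikes(states, {}, p)
        from pupephys.state_metrics import rate_by_state
        rates = rate_by_state(trains, states)
        mean = rates.groupby("condition")["rate_hz"].mean()
        assert mean["AS"] / mean["wake"] == pytest.approx(2.0, rel=0.05)

    def test_urethane_regime_has_long_silences(self):
        p = SimParams(seed=14, duration_s=600.0, regime="urethane")
        states = EpochSet([(0, 600.0, "AS")])
        trains, truth = generate_spikes(states, {}, p)
        for tr in trains:
            assert np.diff(tr.times_s).max() >= 10.0
        # bursts separated by at least the configured silence
        w = truth["burst_windows"]
        gaps = [w[i + 1][0] - w[i][1] for i in range(len(w) - 1)]
        assert min(gaps) >= p.silence_min_s

    def test_rate_scaling_scales_counts(self):
        """Scaling all baseline rates by c scales expected spike counts by c."""
        counts = {}
        for c in (0.5, 1.0, 2.0):
            p = SimParams(seed=15, duration_s=1000.0, regime="p12_continuous",
                          units=[UnitSpec("u0", "M1", rate_as_hz=4.0 * c,
                                          rate_wake_hz=2.0 * c,
                                          rate_quiescence_hz=1.0 * c)])
            states = generate_state_sequence(p)
            trains, _ = generate_spikes(states, {}, p)
            counts[c] = trains[0].n
        assert counts[2.0] / counts[1.0] == pytest.approx(2.0, rel=0.1)
        assert counts[0.5] / counts[1.0] == pytest.approx(0.5, rel=0.1)

    def test_gain_zero_behaves_like_baseline(self):
        """A unit with kernel gain 0 has the same expected count as a
        non-responsive twin (checked within 3 SD of the Poisson count)."""
        base = dict(rate_as_hz=4.0, rate_wake_hz=2.0)
        p = SimParams(seed=16, duration_s=1000.0, regime="p12_continuous",
                      units=[UnitSpec("g0", "M1", responsive=True,
                                      response_gain=0.0, **base),
                             UnitSpec("ctrl", "M1", responsive=False, **base)])
        states = generate_state_sequence(p)
        ev = generate_behavior(states, p)[2]
        trains, _ = generate_spikes(states, ev, p)
        n0, n1 = trains[0].n, trains[1].n
        assert abs(n0 - n1) <= 3 * np.sqrt(n0 + n1)


class TestWholeSession:
    def test_fixed_seed_bit_identical(self):
        a, ta = generate_session(SimParams(seed=17, duration_s=200.0))
        b, tb = generate_session(SimParams(seed=17, duration_s=200.0))
        np.testing.assert_array_equal(a.signals["lfp"].samples, b.signals["lfp"].samples)
        np.testing.assert_array_equal(a.signals["movement"].samples,
                                      b.signals["movement"].samples)
        for x, y in zip(a.spiketrains, b.spiketrains):
            np.testing.assert_array_equal(x.times_s, y.times_s)
        assert ta.true_spindles == tb.true_spindles

    def test_ground_truth_consistent_with_session(self, p8_session):
        session, truth, _ = p8_session
        session.validate()
        lo, hi = session.time_bounds()
        unit_ids = {t.unit_id for t in session.spiketrains}
        for a, b, _ in truth.true_spindles:
            assert lo <= a < b <= hi + 1e-6
        assert set(truth.true_responsive_units) <= unit_ids
        assert truth.true_movement_periods.duration() == pytest.approx(hi - lo, abs=0.1)

    def test_urethane_post_has_no_sleep_wake_labels(self, urethane_session):
        session, _, params = urethane_session
        post_start = params.pre_duration_s + params.injection_gap_s
        for a, b, lab in session.states.intervals:
            assert b <= post_start + 1e-9

    def test_full_suppression_zeroes_post_movement(self):
        p = SimParams(seed=18, pre_duration_s=120.0, post_duration_s=120.0,
                      movement_suppression=1.0, movement_noise_sd=0.0)
        session, _ = generate_urethane_session(p)
        post0 = p.pre_duration_s + p.injection_gap_s
        post = session.signals["movement"].slice_time(post0, post0 + 120.0)
        assert (post.samples - p.movement_baseline).sum() == pytest.approx(0.0)
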