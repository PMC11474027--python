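"""Peri-event histograms, shuffle significance, onsets, selectivity."""

import numpy as np
import pytest

from cinda.event_stats import (
    SignificanceMap,
    compute_peth,
    n_peth_bins,
    onset_latency,
    selectivity_index,
    sensory_motor_label,
    shuffle_significance,
)
from cinda.synth import BehaviorSpec, KernelSpec, gen_behavior, gen_spikes
from conftest import homogeneous_train


class TestPethGeometry:
    def test_599_bins_for_3s_window(self):
        assert n_peth_bins((-1.0, 2.0), 0.010, 0.005) == 599

    def test_bin_membership_matches_brute_force(self):
        # one spike at event + 0.100 s; scan every bin's half-open interval
        spikes = np.array([10.100])
        peth = compute_peth(spikes, np.array([10.0]), window=(-1.0, 2.0))
        hit = np.flatnonzero(peth.trial_counts[0])
        # exact-arithmetic oracle in integer microseconds: bin i covers
        # [-1e6 + 5000 i, -1e6 + 5000 i + 10000), spike at +100000
        brute = [
            i for i in range(peth.n_bins)
            if -1_000_000 + 5_000 * i <= 100_000 < -1_000_000 + 5_000 * i
            + 10_000
        ]
        assert list(hit) == brute
        # half-open convention: exactly the bins centered 0.100 and 0.105
        # (the bin centered 0.095 covers [0.090, 0.100) and misses it)
        np.testing.assert_allclose(peth.bin_centers[hit], [0.100, 0.105])

    def test_homogeneous_rate_unbiased_per_bin(self):
        # per-bin estimates are unbiased; individual bins fluctuate with
        # counting noise sd = sqrt(rate*bw/n)/bw = 1 Hz at these sizes
        st = homogeneous_train(5.0, 1.0, 4_000.0, seed=0)
        events = np.linspace(10.0, 3_990.0, 500)
        peth = compute_peth(st, events, session_duration=4_000.0)
        assert peth.mean_rate.mean() == pytest.approx(5.0, rel=0.02)
        sd = np.sqrt(5.0 * peth.bin_width / 500) / peth.bin_width
        assert np.all(np.abs(peth.mean_rate - 5.0) < 5 * sd)

    def test_count_conservation_with_non_overlapping_bins(self):
        st = homogeneous_train(20.0, 1.0, 200.0, seed=1)
        events = np.linspace(5.0, 195.0, 40)
        peth = compute_peth(st, events, window=(-1.0, 2.0),
                            bin_width=0.010, step=0.010)
        for ev, row in zip(events, peth.trial_counts):
            direct = np.sum((st >= ev - 1.0) & (st < ev - 1.0 + peth.n_bins *
                                                0.010))
            assert row.sum() == direct

    def test_edge_events_dropped_and_counted(self):
        st = homogeneous_train(5.0, 1.0, 100.0, seed=2)
        events = np.array([0.5, 50.0, 99.5])
        peth = compute_peth(st, events, session_duration=100.0)
        assert peth.n_trials == 1 and peth.n_dropped == 2

    def test_shift_invariance(self):
        st = homogeneous_train(8.0, 2.0, 300.0, seed=3)
        events = np.linspace(20.0, 280.0, 60)
        a = compute_peth(st, events)
        b = compute_peth(st + 512.0, events + 512.0)
        np.testing.assert_array_equal(a.trial_counts, b.trial_counts)


class TestShuffleSignificance:
    def test_deterministic_given_seed(self):
        st = homogeneous_train(6.0, 2.0, 1_000.0, seed=4)
        events = np.linspace(20.0, 980.0, 100)
        peth = compute_peth(st, events, session_duration=1_000.0)
        s1 = shuffle_significance(st, peth, 1_000.0, n_shuffles=500, seed=9)
        s2 = shuffle_significance(st, peth, 1_000.0, n_shuffles=500, seed=9)
        np.testing.assert_array_equal(s1.up, s2.up)
        np.testing.assert_array_equal(s1.down, s2.down)

    def test_up_and_down_never_both(self):
        st = homogeneous_train(6.0, 2.0, 1_000.0, seed=5)
        events = np.linspace(20.0, 980.0, 100)
        peth = compute_peth(st, events, session_duration=1_000.0)
        sig = shuffle_significance(st, peth, 1_000.0, n_shuffles=1_000,
                                   seed=0, correction="pointwise")
        assert not np.any(sig.up & sig.down)

    def test_empirical_tail_needs_enough_shuffles(self):
        st = homogeneous_train(6.0, 2.0, 1_000.0, seed=6)
        events = np.linspace(20.0, 980.0, 50)
        peth = compute_peth(st, events, session_duration=1_000.0)
        with pytest.raises(ValueError, match="insufficient shuffles"):
            shuffle_significance(
                st, peth, 1_000.0, n_shuffles=10_000, alpha=0.005,
                seed=0, correction="bonferroni", null_tail="empirical",
            )
        # pointwise tails resolve alpha = 0.005 with the same shuffles
        shuffle_significance(
            st, peth, 1_000.0, n_shuffles=10_000, alpha=0.005, seed=0,
            correction="pointwise",
        )

    def test_injected_pause_detected(self, behavior_300,
                                     session_duration_300):
        trials, gt = behavior_300
        kern = [KernelSpec("side_in", onset=0.100, duration=0.150, gain=0.2)]
        hits = 0
        for seed in range(10):
            train, _ = gen_spikes(trials, 6.0, 2.0, kern, seed=50 + seed,
                                  duration=session_duration_300,
                                  v_true=gt.v_true)
            peth = compute_peth(train.spike_times,
                                trials["side_in"].to_numpy(),
                                session_duration=session_duration_300)
            sig = shuffle_significance(
                train.spike_times, peth, session_duration_300,
                n_shuffles=2_000, alpha=0.005, seed=seed,
                correction="pointwise",
            )
            m = (peth.bin_centers >= 0.100) & (peth.bin_centers < 0.250)
            hits += bool(np.any(sig.down & m))
        assert hits >= 9

    def test_maxstat_mode_controls_familywise(self):
        st = homogeneous_train(6.0, 1.0, 600.0, seed=7)
        events = np.linspace(20.0, 580.0, 60)
        peth = compute_peth(st, events, window=(-0.2, 0.3),
                            session_duration=600.0)
        sig = shuffle_significance(st, peth, 600.0, n_shuffles=400,
                                   alpha=0.05, seed=1, correction="maxstat")
        assert isinstance(sig, SignificanceMap)
        assert sig.up.sum() + sig.down.sum() == 0


class TestOnsets:
    def make_map(self, n_bins, flag_idx, direction="down"):
        up = np.zeros(n_bins, bool)
        down = np.zeros(n_bins, bool)
        (down if direction == "down" else up)[flag_idx] = True
        return SignificanceMap(
            up=up, down=down, null_mean=0.0, null_sd=1.0, threshold_up=1.0,
            threshold_down=-1.0, alpha=0.005, n_shuffles=100,
            correction="pointwise", null_tail="empirical", seed=0,
        )

    def test_no_flags_gives_absent_onset(self):
        centers = 0.005 * np.arange(100)
        res = onset_latency(self.make_map(100, []), "down", centers, 0.010)
        assert res.onset is None and res.duration is None

    def test_contiguous_run_bookkeeping(self):
        # flags at bin centers 85..120 ms (down)
        centers = 0.005 * np.arange(100)
        idx = np.arange(17, 25)  # centers 0.085 .. 0.120
        res = onset_latency(self.make_map(100, idx), "down", centers, 0.010)
        assert res.onset == pytest.approx(0.085)
        assert res.offset == pytest.approx(0.120)
        assert res.duration == pytest.approx(0.045)

    def test_burst_onset_recovered(self, behavior_300, session_duration_300):
        trials, gt = behavior_300
        kern = [KernelSpec("go_cue", onset=0.030, duration=0.060, gain=4.0)]
        hits = 0
        for seed in range(10):
            train, _ = gen_spikes(trials, 6.0, 2.0, kern, seed=80 + seed,
                                  duration=session_duration_300,
                                  v_true=gt.v_true)
            peth = compute_peth(train.spike_times,
                                trials["go_cue"].to_numpy(),
                                session_duration=session_duration_300)
            sig = shuffle_significance(
                train.spike_times, peth, session_duration_300,
                n_shuffles=2_000, seed=seed, correction="pointwise",
            )
            res = onset_latency(sig, "up", peth.bin_centers, peth.bin_width,
                                (0.0, 0.3))
            if res.onset is not None and 0.020 <= res.onset <= 0.045:
                hits += 1
        assert hits >= 9


class TestSelectivity:
    def grouped_peth(self, contra_rate, ipsi_rate):
        # constant-rate trial counts for one contra and one ipsi trial
        n_bins = 99
        counts = np.vstack(
            [
                np.full(n_bins, contra_rate * 0.01),
                np.full(n_bins, ipsi_rate * 0.01),
            ]
        )
        from cinda.event_stats import PethResult

        return PethResult(
            align_event="go_cue", window=(0.0, 0.5), bin_width=0.010,
            step=0.005, bin_centers=0.005 + 0.005 * np.arange(n_bins),
            trial_counts=counts, mean_rate=counts.mean(0) / 0.01,
            event_times=np.array([1.0, 2.0]),
            group_labels=np.array(["contra", "ipsi"], dtype=object),
        )

    def test_equal_magnitudes_give_zero(self):
        si = selectivity_index(self.grouped_peth(4.0, 4.0), (0.0, 0.5))
        assert si == pytest.approx(0.0)

    def test_double_contra_gives_one_third(self):
        si = selectivity_index(self.grouped_peth(8.0, 4.0), (0.0, 0.5))
        assert si == pytest.approx(1.0 / 3.0)

    def test_label_swap_negates(self):
        peth = self.grouped_peth(8.0, 4.0)
        si = selectivity_index(peth, (0.0, 0.5))
        peth.group_labels = np.where(
            peth.group_labels == "contra", "ipsi", "contra"
        )
        assert selectivity_index(peth, (0.0, 0.5)) == pytest.approx(-si)


class TestSensoryMotor:
    @pytest.mark.parametrize(
        "component,kern_kw,expected",
        [
            # cue-locked burst: sharp when go-aligned, RT-smeared otherwise
            ("burst", dict(align_event="go_cue", onset=0.030, duration=0.080,
                           gain=4.0, lock="cue"), "sensory"),
            # movement-locked rebound: sharp when center-out-aligned
            ("rebound", dict(align_event="center_out", onset=0.050,
                             duration=0.150, gain=4.0, lock="movement"),
             "motor"),
        ],
    )
    def test_component_lock_labels(self, component, kern_kw, expected):
        hits = 0
        for seed in range(5):
            trials, gt = gen_behavior(BehaviorSpec(n_blocks=9),
                                      seed=300 + seed, n_trials=300)
            dur = float(trials["side_in"].max()) + 10.0
            kern = [KernelSpec(**kern_kw)]
            train, _ = gen_spikes(trials, 6.0, 2.0, kern, seed=400 + seed,
                                  duration=dur, v_true=gt.v_true)
            res = sensory_motor_label(
                train.spike_times, trials, component, dur,
                n_shuffles=2_000, seed=seed, correction="pointwise",
            )
            if res is not None and res[1] == expected:
                hits += 1
        assert hits >= 4

    def test_unknown_component_rejected(self, behavior_300,
                                        session_duration_300):
        trials, _ = behavior_300
        with pytest.raises(ValueError, match="component"):
            sensory_motor_label(np.arange(100.0), trials, "ramp",
                                session_duration_300)
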