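"""Photometry: demultiplexing, control-channel regression, alignment."""

import numpy as np
import pytest

from cinda.core_io import ContinuousSignal, PhotometryRaw
from cinda.photometry import align_dff, compute_dff, demultiplex, dff_significance
from cinda.synth import BehaviorSpec, PhotoKernelSpec, gen_behavior, gen_photometry

FAST_BEHAVIOR = BehaviorSpec(iti_range=(1.0, 2.0), reward_dwell=0.5)


def make_raw(frame_vals_470, frame_vals_405, noise=0.0, seed=0):
    """Detector trace with given per-frame channel values (alternating)."""
    n = 2 * min(len(frame_vals_470), len(frame_vals_405))
    vals = np.empty(n)
    vals[0::2] = frame_vals_470[: n // 2]
    vals[1::2] = frame_vals_405[: n // 2]
    det = np.zeros((n, 100), dtype=np.float32)
    det[:, :40] = vals[:, None]
    if noise:
        det += np.random.default_rng(seed).normal(0, noise, det.shape).astype(
            np.float32
        )
    sched = np.where(np.arange(n) % 2 == 0, 470, 405)
    return PhotometryRaw(det.ravel(), sched)


class TestDemultiplex:
    def test_constant_channels_separate_cleanly(self):
        raw = make_raw(np.full(500, 3.0), np.zeros(500))
        s470, s405 = demultiplex(raw)
        np.testing.assert_allclose(s470.samples, 3.0, atol=1e-6)
        np.testing.assert_allclose(s405.samples, 0.0, atol=1e-6)

    def test_transition_artifact_in_first_half_ms_ignored(self):
        raw = make_raw(np.full(500, 3.0), np.full(500, 1.0))
        det = raw.detector.reshape(-1, 100).copy()
        det[:, :5] += 50.0  # spike confined to the first 0.5 ms of the frame
        dirty = PhotometryRaw(det.ravel(), raw.schedule)
        s470, _ = demultiplex(dirty)
        np.testing.assert_allclose(s470.samples, 3.0, atol=1e-6)

    def test_known_frame_means_recovered(self):
        rng = np.random.default_rng(1)
        v470 = 2.0 + 0.1 * rng.standard_normal(400)
        v405 = 1.0 + 0.05 * rng.standard_normal(400)
        raw = make_raw(v470, v405)
        s470, s405 = demultiplex(raw, grid_rate=250.0)
        # grid values interpolate the per-frame means: bounded by them
        assert s470.samples.min() >= v470.min() - 1e-9
        assert s470.samples.max() <= v470.max() + 1e-9


class TestComputeDff:
    def test_proportional_channels_give_zero(self):
        rng = np.random.default_rng(2)
        x = 1.0 + 0.1 * np.abs(rng.standard_normal(5_000))
        s405 = ContinuousSignal(x, 250.0)
        s470 = ContinuousSignal(2.0 * x, 250.0)
        dff = compute_dff(s470, s405)
        np.testing.assert_allclose(dff.raw_dff, 0.0, atol=1e-12)

    def test_scale_invariance(self):
        rng = np.random.default_rng(3)
        x = 1.0 + 0.1 * np.abs(rng.standard_normal(5_000))
        y = 2.0 * x + 0.05 * rng.standard_normal(5_000)
        d1 = compute_dff(ContinuousSignal(y, 250.0),
                         ContinuousSignal(x, 250.0))
        d2 = compute_dff(ContinuousSignal(3.0 * y, 250.0),
                         ContinuousSignal(3.0 * x, 250.0))
        np.testing.assert_allclose(d1.raw_dff, d2.raw_dff, atol=1e-9)

    def test_transient_on_470_recovered(self):
        n = 25_000
        x = np.full(n, 2.0)
        x += 0.02 * np.sin(np.arange(n) / 400.0)  # slow shared trend
        y = 1.5 * x.copy()
        y[10_000:10_250] *= 1.10  # +10 % transient on 470 only
        dff = compute_dff(ContinuousSignal(y, 250.0),
                          ContinuousSignal(x, 250.0))
        assert dff.raw_dff[10_050:10_200].mean() == pytest.approx(0.10,
                                                                  rel=0.1)

    def test_constant_control_rejected(self):
        with pytest.raises(ValueError, match="control channel constant"):
            compute_dff(ContinuousSignal(np.ones(100), 250.0),
                        ContinuousSignal(np.ones(100), 250.0))

    def test_median_filter_idempotent_on_root_signals(self):
        # exact idempotence holds for median-filter root signals
        # (piecewise-constant runs longer than the kernel)
        from scipy.signal import medfilt

        rng = np.random.default_rng(4)
        x = np.repeat(rng.standard_normal(50), 10)
        once = medfilt(x, 5)
        np.testing.assert_array_equal(medfilt(once, 5)[2:-2], once[2:-2])
        np.testing.assert_array_equal(once[2:-2], x[2:-2])


class TestEndToEnd:
    def test_amplitude_recovered_from_aligned_dff(self):
        trials, gt = gen_behavior(FAST_BEHAVIOR, seed=5, n_trials=300)
        dur = float(trials["side_in"].max()) + 5.0
        amp = 0.10
        raw, _ = gen_photometry(
            trials, [PhotoKernelSpec("side_in", amplitude=amp, onset=0.1)],
            artifact=(1_000.0, 0.01), seed=6, duration=dur,
        )
        s470, s405 = demultiplex(raw)
        dff = compute_dff(s470, s405)
        al = align_dff(dff, trials["side_in"].to_numpy(), (-0.5, 1.5),
                       use="raw")
        assert al["mean"].max() == pytest.approx(amp, rel=0.2)

    def test_bleaching_only_session_is_flat(self):
        trials, _ = gen_behavior(FAST_BEHAVIOR, seed=7, n_trials=100)
        dur = float(trials["side_in"].max()) + 5.0
        for tau in (300.0, 3_000.0):
            raw, _ = gen_photometry(trials, [], artifact=(tau, 0.01),
                                    seed=8, duration=dur)
            s470, s405 = demultiplex(raw)
            dff = compute_dff(s470, s405)
            assert np.mean(np.abs(dff.raw_dff)) < 0.01

    def test_control_fit_removes_shared_motion(self):
        trials, _ = gen_behavior(FAST_BEHAVIOR, seed=9, n_trials=100)
        dur = float(trials["side_in"].max()) + 5.0
        raw, gt = gen_photometry(trials, [], artifact=(1_000.0, 0.05),
                                 seed=10, duration=dur)
        s470, s405 = demultiplex(raw)
        dff = compute_dff(s470, s405)
        tau, floor = gt.bleach
        t = s470.times
        trend = floor + (1 - floor) * np.exp(-t / tau)
        uncorrected = s470.samples / (2.0 * trend) - 1.0  # gain_470 = 2
        assert dff.raw_dff.var() < uncorrected.var()

    def test_rewarded_vs_unrewarded_group_means(self):
        trials, gt = gen_behavior(FAST_BEHAVIOR, seed=11, n_trials=300)
        dur = float(trials["side_in"].max()) + 5.0
        raw, _ = gen_photometry(
            trials,
            [PhotoKernelSpec("side_in", amplitude=0.08, onset=0.1,
                             rpe_scale=1.0)],
            artifact=(1_000.0, 0.01), seed=12, duration=dur,
            v_true=gt.v_true,
        )
        s470, s405 = demultiplex(raw)
        dff = compute_dff(s470, s405)
        groups = np.where(trials["outcome"] == 1, "rewarded", "unrewarded")
        al = align_dff(dff, trials["side_in"].to_numpy(), (-0.5, 1.5),
                       groups=groups, use="raw")
        win = (al["rel_time"] >= 0.1) & (al["rel_time"] < 0.5)
        assert (al["groups"]["rewarded"]["mean"][win].mean()
                > al["groups"]["unrewarded"]["mean"][win].mean())

    def test_null_session_has_no_significant_samples(self):
        hits = 0
        for seed in range(5):
            trials, _ = gen_behavior(FAST_BEHAVIOR, seed=20 + seed,
                                     n_trials=150)
            dur = float(trials["side_in"].max()) + 5.0
            raw, _ = gen_photometry(trials, [], artifact=(1_000.0, 0.01),
                                    seed=30 + seed, duration=dur)
            s470, s405 = demultiplex(raw)
            dff = compute_dff(s470, s405)
            sig = dff_significance(
                dff, trials["side_in"].to_numpy(), (-1.0, 2.0),
                n_shuffles=2_000, alpha=0.005, seed=seed,
            )
            hits += bool(sig.up.any() or sig.down.any())
        assert hits == 0

    def test_kernel_produces_significant_up_run(self):
        trials, _ = gen_behavior(FAST_BEHAVIOR, seed=40, n_trials=300)
        dur = float(trials["side_in"].max()) + 5.0
        raw, _ = gen_photometry(
            trials, [PhotoKernelSpec("side_in", amplitude=0.10, onset=0.1)],
            artifact=(1_000.0, 0.01), seed=41, duration=dur,
        )
        s470, s405 = demultiplex(raw)
        dff = compute_dff(s470, s405)
        sig = dff_significance(
            dff, trials["side_in"].to_numpy(), (-1.0, 2.0),
            n_shuffles=2_000, alpha=0.005, seed=42,
        )
        rel_t = np.arange(sig.up.size) / 250.0 - 1.0
        peak = (rel_t >= 0.1) & (rel_t < 0.4)
        assert sig.up[peak].mean() > 0.5
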