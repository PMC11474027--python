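"""Seeded synthetic-session generators.

These emulate the statistical structure the downstream analyses assume:

* bandit-task behavior — 35-45-trial blocks with 10/50/90 % reward
  probabilities per side, a 0.5-1.5 s hold before the Go cue, log-normal
  reaction times, and initiation latencies that shrink with the decaying-
  beta-model trial value (higher reward expectation -> faster starts);
* tonic, CIN-like spike trains — inhomogeneous gamma-renewal processes
  (shape = regularity; shape 1 is Poisson) whose rate is modulated by
  cue- or movement-locked burst/pause/rebound kernels, optionally scaled
  by the trial's reward-prediction error (outcome - V);
* laser-evoked spiking for optotagging;
* state-switching ECoG (wake vs slow-wave sleep spectra);
* two-channel time-division-multiplexed photometry with bleaching and
  shared motion artifacts.

Every generator is a pure function of (spec, seed); the returned
GroundTruth stores what recovery tests need without re-simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .core_io import (
    ContinuousSignal,
    LaserStimTable,
    PhotometryRaw,
    Session,
    SpikeTrain,
    UnitWaveform,
    validate_session,
)
from .value_model import beta_value_series

__all__ = [
    "BehaviorSpec",
    "KernelSpec",
    "PhotoKernelSpec",
    "GroundTruth",
    "gen_behavior",
    "gen_spikes",
    "gen_laser",
    "gen_laser_schedule",
    "gen_ecog",
    "gen_photometry",
    "make_waveform",
    "gen_session",
]


@dataclass
class BehaviorSpec:
    """Bandit-task parameters (defaults are the task as run)."""

    n_blocks: int = 8
    block_len_range: tuple[int, int] = (35, 45)      # inclusive, uniform
    probs: tuple[float, ...] = (0.1, 0.5, 0.9)
    hold_range: tuple[float, float] = (0.5, 1.5)     # s, uniform
    latency_intercept: float = 0.7     # a: log-s; latency = exp(a - b*V + eps)
    latency_value_slope: float = 1.5   # b >= 0
    latency_sigma: float = 0.5         # log-s noise SD
    rt_median: float = 0.161           # s; median of session median RTs
    rt_sigma: float = 0.35             # log-normal dispersion
    iti_range: tuple[float, float] = (2.0, 6.0)      # s, uniform
    move_range: tuple[float, float] = (0.15, 0.45)   # center_out -> side_in
    food_delay_range: tuple[float, float] = (0.3, 1.0)
    reward_dwell: float = 2.0          # extra time at food port when rewarded
    gamma_true: float = 0.7
    prior: tuple[float, float] = (1.0, 1.0)


@dataclass
class KernelSpec:
    """One phenomenological rate-modulation component of a unit's response.

    The multiplicative gain applies in [ref + onset, ref + onset + duration),
    where ref is ``align_event`` for cue-locked kernels and Center Out for
    movement-locked ones.  gain > 1 is a burst/rebound, gain < 1 a pause.
    rpe_scale couples the gain *deviation* to (outcome - V):
    effective gain = 1 + (gain - 1) * (1 + rpe_scale * (outcome - V)).
    """

    align_event: str
    onset: float
    duration: float
    gain: float
    lock: str = "cue"                 # "cue" | "movement"
    rpe_scale: float = 0.0
    direction_gain: float = 1.0       # multiplies the deviation on contra trials

    def __post_init__(self) -> None:
        if self.gain < 0:
            raise ValueError("kernel gain must be >= 0")
        if self.lock not in ("cue", "movement"):
            raise ValueError("lock must be 'cue' or 'movement'")


@dataclass
class PhotoKernelSpec:
    """Event-locked dopamine transient: amplitude * exp(-t/tau) from onset."""

    align_event: str
    amplitude: float
    onset: float = 0.0
    tau: float = 0.2                  # s; release/sensor decay constant
    rpe_scale: float = 0.0


@dataclass
class GroundTruth:
    """Everything recovery tests need, stored next to the generated data."""

    v_true: np.ndarray | None = None
    gamma_true: float | None = None
    kernels: dict = field(default_factory=dict)          # unit_id -> [KernelSpec...]
    base_rates: dict = field(default_factory=dict)       # unit_id -> Hz
    regularity: dict = field(default_factory=dict)       # unit_id -> gamma shape
    laser_responsive: dict = field(default_factory=dict)  # unit_id -> bool
    sws_intervals: list = field(default_factory=list)    # [(start, end), ...]
    photo_kernels: list = field(default_factory=list)    # [PhotoKernelSpec...]
    bleach: tuple | None = None                          # (tau, floor)

    def to_jsonable(self) -> dict:
        d = {
            "v_true": None if self.v_true is None else list(map(float, self.v_true)),
            "gamma_true": self.gamma_true,
            "kernels": {u: [asdict(k) for k in ks] for u, ks in self.kernels.items()},
            "base_rates": self.base_rates,
            "regularity": self.regularity,
            "laser_responsive": self.laser_responsive,
            "sws_intervals": [list(map(float, iv)) for iv in self.sws_intervals],
            "photo_kernels": [asdict(k) for k in self.photo_kernels],
            "bleach": None if self.bleach is None else list(self.bleach),
        }
        return d


# ---------------------------------------------------------------------------
# behavior

def gen_behavior(
    spec: BehaviorSpec, seed: int, n_trials: int | None = None
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate a bandit session.

    Choices are drawn by probability matching on per-side decaying-beta
    values (choose left with probability V_left / (V_left + V_right));
    outcomes are Bernoulli in the chosen side's block probability.  The
    ground-truth trial value V is the single-stream beta model run at
    ``spec.gamma_true`` on the realized outcome sequence, and initiation
    latency follows latency = exp(a - b*V + eps), eps ~ N(0, sigma^2).
    """
    if not spec.probs:
        raise ValueError("probs set must be non-empty")
    rng = np.random.default_rng(seed)
    lo, hi = spec.block_len_range
    lens = rng.integers(lo, hi + 1, size=spec.n_blocks)
    if n_trials is not None:
        while lens.sum() < n_trials:
            lens = np.append(lens, rng.integers(lo, hi + 1))
    p_left_blocks = rng.choice(spec.probs, size=lens.size)
    p_right_blocks = rng.choice(spec.probs, size=lens.size)

    block_index = np.repeat(np.arange(lens.size), lens)
    p_left = np.repeat(p_left_blocks, lens)
    p_right = np.repeat(p_right_blocks, lens)
    n = block_index.size
    if n_trials is not None:
        n = n_trials
        block_index, p_left, p_right = (
            a[:n] for a in (block_index, p_left, p_right)
        )

    g = spec.gamma_true
    a0, b0 = spec.prior
    aL, bL, aR, bR = a0, b0, a0, b0
    choices = np.empty(n, dtype=object)
    outcomes = np.empty(n, dtype=int)
    for t in range(n):
        vL, vR = aL / (aL + bL), aR / (aR + bR)
        go_left = rng.random() < vL / (vL + vR)
        p = p_left[t] if go_left else p_right[t]
        r = int(rng.random() < p)
        choices[t] = "left" if go_left else "right"
        outcomes[t] = r
        aL, bL, aR, bR = g * aL, g * bL, g * aR, g * bR
        if go_left:
            aL, bL = aL + r, bL + (1 - r)
        else:
            aR, bR = aR + r, bR + (1 - r)

    v_true = beta_value_series(outcomes, g, prior=spec.prior).V
    eps = rng.normal(0.0, spec.latency_sigma, size=n)
    latency = np.exp(
        spec.latency_intercept - spec.latency_value_slope * v_true + eps
    )
    hold = rng.uniform(*spec.hold_range, size=n)
    rt = spec.rt_median * np.exp(rng.normal(0.0, spec.rt_sigma, size=n))
    iti = rng.uniform(*spec.iti_range, size=n)
    move = rng.uniform(*spec.move_range, size=n)
    food_delay = rng.uniform(*spec.food_delay_range, size=n)

    light_on = np.empty(n)
    cursor = 0.0
    for t in range(n):
        light_on[t] = cursor + iti[t]
        cursor = light_on[t] + latency[t] + hold[t] + rt[t] + move[t]
        if outcomes[t]:
            cursor += food_delay[t] + spec.reward_dwell
    center_in = light_on + latency
    go_cue = center_in + hold
    center_out = go_cue + rt
    side_in = center_out + move
    food_in = np.where(outcomes == 1, side_in + food_delay, np.nan)

    trials = pd.DataFrame(
        {
            "light_on": light_on,
            "center_in": center_in,
            "go_cue": go_cue,
            "center_out": center_out,
            "side_in": side_in,
            "food_in": food_in,
            "choice": choices,
            "outcome": outcomes,
            "p_left": p_left,
            "p_right": p_right,
            "block_index": block_index,
            "latency": latency,
            "rt": rt,
        }
    )
    gt = GroundTruth(v_true=v_true, gamma_true=g)
    return trials, gt


# ---------------------------------------------------------------------------
# spikes

def _rate_grid(
    trials: pd.DataFrame,
    base_rate: float,
    kernels: list[KernelSpec],
    duration: float,
    v_true: np.ndarray | None,
    hemisphere: str = "left",
    dt: float = 0.001,
) -> np.ndarray:
    n_grid = int(np.ceil(duration / dt))
    rate = np.full(n_grid, base_rate)
    if not kernels:
        return rate
    outcomes = trials["outcome"].to_numpy(dtype=float)
    contra_choice = "right" if hemisphere == "left" else "left"
    is_contra = (trials["choice"] == contra_choice).to_numpy()
    for k in kernels:
        if k.align_event not in trials.columns:
            raise ValueError(f"kernel references absent event '{k.align_event}'")
        ref_col = k.align_event if k.lock == "cue" else "center_out"
        refs = trials[ref_col].to_numpy(dtype=float)
        for t, ref in enumerate(refs):
            if not np.isfinite(ref):
                continue
            dev = k.gain - 1.0
            if k.rpe_scale != 0.0 and v_true is not None:
                dev *= 1.0 + k.rpe_scale * (outcomes[t] - v_true[t])
            if k.direction_gain != 1.0 and is_contra[t]:
                dev *= k.direction_gain
            g_eff = max(1.0 + dev, 0.0)
            i0 = max(int(np.floor((ref + k.onset) / dt)), 0)
            i1 = min(int(np.floor((ref + k.onset + k.duration) / dt)), n_grid)
            if i1 > i0:
                rate[i0:i1] *= g_eff
    return rate


def gen_spikes(
    trials: pd.DataFrame,
    base_rate: float,
    regularity: float,
    kernels: list[KernelSpec],
    seed: int,
    duration: float,
    v_true: np.ndarray | None = None,
    hemisphere: str = "left",
    unit_id: str = "u0",
    dt: float = 0.001,
) -> tuple[SpikeTrain, GroundTruth]:
    """Inhomogeneous gamma-renewal spike train by time rescaling.

    ISIs are Gamma(shape=regularity, mean=1) in operational time
    Lambda(t) = integral of the kernel-modulated rate, so the realized
    rate tracks the rate function and ISI CV -> 1/sqrt(regularity).
    """
    if base_rate <= 0:
        raise ValueError("base_rate must be positive")
    if regularity <= 0:
        raise ValueError("regularity (gamma shape) must be positive")
    rng = np.random.default_rng(seed)
    rate = _rate_grid(trials, base_rate, kernels, duration, v_true, hemisphere, dt)
    cum = np.concatenate([[0.0], np.cumsum(rate) * dt])
    tgrid = np.arange(cum.size) * dt
    total = cum[-1]
    n_draw = int(total + 6.0 * np.sqrt(max(total, 1.0) / regularity) + 50)
    isis = rng.gamma(regularity, 1.0 / regularity, size=n_draw)
    s = np.cumsum(isis)
    while s[-1] < total:  # rarely needed top-up
        extra = rng.gamma(regularity, 1.0 / regularity, size=n_draw)
        s = np.concatenate([s, s[-1] + np.cumsum(extra)])
    s = s[s < total]
    spike_times = np.interp(s, cum, tgrid)
    spike_times = np.unique(spike_times)

    waveform, evoked = make_waveform(rng)
    train = SpikeTrain(
        unit_id=unit_id,
        spike_times=spike_times,
        waveform=waveform,
        tetrode_id=int(rng.integers(0, 16)),
        evoked_waveform=evoked,
    )
    gt = GroundTruth(
        v_true=v_true,
        kernels={unit_id: list(kernels)},
        base_rates={unit_id: float(base_rate)},
        regularity={unit_id: float(regularity)},
    )
    return train, gt


def make_waveform(
    rng: np.random.Generator,
    n_channels: int = 4,
    sample_rate: float = 30_000.0,
    trough_ms: float = 0.55,
    trough_sigma_ms: float = 0.18,
    valley_delay_ms: float = 0.65,
    evoked_noise: float = 0.03,
) -> tuple[UnitWaveform, np.ndarray]:
    """CIN-like mean waveform: broad negative trough then a positive hump.

    Returns the spontaneous waveform and a laser-evoked version (same
    shape plus small independent noise, correlation > 0.95 by design).
    """
    n = int(round(sample_rate * 0.002))
    t_ms = np.arange(n) / sample_rate * 1e3
    amps = np.sort(rng.uniform(0.2, 1.0, size=n_channels))[::-1]
    trough = -np.exp(-0.5 * ((t_ms - trough_ms) / trough_sigma_ms) ** 2)
    hump = 0.35 * np.exp(
        -0.5 * ((t_ms - trough_ms - valley_delay_ms) / 0.30) ** 2
    )
    shape = trough + hump
    samples = amps[:, None] * shape[None, :]
    samples = samples + rng.normal(0.0, 0.005, size=samples.shape)
    evoked = samples + rng.normal(0.0, evoked_noise * amps[:, None], samples.shape)
    return UnitWaveform(samples, sample_rate), evoked


# ---------------------------------------------------------------------------
# laser

def gen_laser_schedule(
    start: float,
    widths: tuple[float, ...] = (2.0, 5.0, 10.0),
    freqs: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0),
    n_pulses: int = 40,
    gap: float = 3.0,
) -> LaserStimTable:
    """Pulse trains for every width x frequency condition, run sequentially."""
    times, ws, fs, conds = [], [], [], []
    t = start
    cond = 0
    for w in widths:
        for f in freqs:
            onsets = t + np.arange(n_pulses) / f
            times.append(onsets)
            ws.append(np.full(n_pulses, w))
            fs.append(np.full(n_pulses, f))
            conds.append(np.full(n_pulses, cond))
            t = onsets[-1] + gap
            cond += 1
    return LaserStimTable(
        np.concatenate(times), np.concatenate(ws),
        np.concatenate(fs), np.concatenate(conds),
    )


def gen_laser(
    spikes: SpikeTrain,
    laser: LaserStimTable,
    p_follow: float,
    latency: float,
    jitter: float,
    seed: int,
) -> SpikeTrain:
    """Insert laser-evoked spikes into a baseline train.

    Each pulse evokes one spike with probability p_follow at
    pulse + latency + N(0, jitter^2); evoked spikes carry the unit's
    waveform (they are merged into the same sorted train).
    """
    if latency < 0:
        raise ValueError("latency must be >= 0")
    rng = np.random.default_rng(seed)
    follow = rng.random(laser.pulse_times.size) < p_follow
    evoked = laser.pulse_times[follow] + latency
    if jitter > 0:
        evoked = evoked + rng.normal(0.0, jitter, size=evoked.size)
    merged = np.unique(np.concatenate([spikes.spike_times, evoked]))
    return SpikeTrain(
        unit_id=spikes.unit_id,
        spike_times=merged,
        waveform=spikes.waveform,
        tetrode_id=spikes.tetrode_id,
        evoked_waveform=spikes.evoked_waveform,
    )


# ---------------------------------------------------------------------------
# ECoG

def _band_noise(
    rng: np.random.Generator, n: int, fs: float, state: str, delta_boost: float
) -> np.ndarray:
    """Spectrally shaped Gaussian noise for one wake/SWS segment.

    Wake: 1/f backbone with mild 8-12 Hz and 20-60 Hz emphasis.  SWS:
    strong delta (amplitude delta_boost x the wake level), spindle-band
    (8-12 Hz) elevation and suppressed 20-60 Hz activity -- the spectral
    shifts the band-ratio statistic k is built to detect.
    """
    white = rng.normal(size=n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    amp = 1.0 / np.sqrt(np.maximum(f, 0.5))          # 1/f backbone
    if state == "wake":
        amp *= 1.0 + 1.5 * ((f >= 8) & (f < 12))     # alpha emphasis
        amp *= 1.0 + 0.8 * ((f >= 20) & (f < 60))    # beta/gamma emphasis
    else:  # sws
        amp *= 1.0 + (delta_boost - 1.0) * ((f >= 0.5) & (f < 4))
        amp *= 1.0 + 1.0 * ((f >= 4) & (f < 8))      # residual slow activity
        amp *= 1.0 + 2.5 * ((f >= 8) & (f < 12))     # sleep spindles
        amp *= 1.0 - 0.3 * ((f >= 20) & (f < 60))    # gamma suppression
    amp[f == 0] = 0.0
    sig = np.fft.irfft(spec * amp, n=n)
    return sig / np.std(sig) if np.std(sig) > 0 else sig


def gen_ecog(
    state_schedule: list[tuple[tuple[float, float], str]],
    sample_rate: float = 200.0,
    seed: int = 0,
    delta_boost: float = 12.0,
) -> ContinuousSignal:
    """State-switching ECoG: wake = 1/f broadband with 8-12 / 20-60 Hz
    emphasis; SWS segments add strong 0.5-4 Hz power."""
    ivals = sorted(state_schedule, key=lambda x: x[0][0])
    for (a0, a1), _ in ivals:
        if a1 <= a0:
            raise ValueError("schedule intervals must have positive length")
    for ((_, a1), _), ((b0, _), _) in zip(ivals[:-1], ivals[1:]):
        if b0 < a1 - 1e-9:
            raise ValueError("schedule intervals overlap")
    rng = np.random.default_rng(seed)
    duration = ivals[-1][0][1]
    n_total = int(round(duration * sample_rate))
    out = np.zeros(n_total)
    for (t0, t1), state in ivals:
        if state not in ("wake", "sws"):
            raise ValueError(f"unknown state '{state}'")
        i0, i1 = int(round(t0 * sample_rate)), int(round(t1 * sample_rate))
        seg = _band_noise(rng, i1 - i0, sample_rate, state, delta_boost)
        # SWS raw amplitude runs well above wake (large slow waves), so
        # the delta-band amplitude ends up >= 10x the wake level
        out[i0:i1] = seg * (5.0 if state == "sws" else 1.0)
    return ContinuousSignal(out, sample_rate, t0=0.0)


# ---------------------------------------------------------------------------
# photometry

def gen_photometry(
    trials: pd.DataFrame,
    kernels: list[PhotoKernelSpec],
    artifact: tuple[float, float],
    seed: int,
    duration: float,
    v_true: np.ndarray | None = None,
    detector_noise: float = 0.002,
    bleach_floor: float = 0.4,
    gain_470: float = 2.0,
    gain_405: float = 1.0,
) -> tuple[PhotometryRaw, GroundTruth]:
    """Two-channel multiplexed detector trace at 10 kHz.

    The underlying dopamine trace is a sum of event-locked exponential
    transients (peak height = kernel amplitude, optionally RPE-scaled).
    470 frames carry (1 + DA) x bleach x (1 + motion); 405 frames carry
    bleach x (1 + motion); LEDs alternate 10 ms frames (4 ms on, 6 ms
    off), so each channel is effectively sampled at 50 Hz.
    """
    bleach_tau, motion_sd = artifact
    rng = np.random.default_rng(seed)
    frame_s = 0.010
    n_frames = int(np.floor(duration / frame_s))
    t_frame = (np.arange(n_frames) + 0.2) * frame_s  # center of the on-window

    da = np.zeros(n_frames)
    outcomes = trials["outcome"].to_numpy(dtype=float)
    for k in kernels:
        if k.align_event not in trials.columns:
            raise ValueError(f"kernel references absent event '{k.align_event}'")
        refs = trials[k.align_event].to_numpy(dtype=float)
        support = int(np.ceil(6 * k.tau / frame_s))
        decay = np.exp(-np.arange(support) * frame_s / k.tau)
        for t, ref in enumerate(refs):
            if not np.isfinite(ref):
                continue
            amp = k.amplitude
            if k.rpe_scale != 0.0 and v_true is not None:
                amp *= 1.0 + k.rpe_scale * (outcomes[t] - v_true[t])
            i0 = int(np.ceil((ref + k.onset - 0.002) / frame_s))
            if i0 < 0:
                i0 = 0
            i1 = min(i0 + support, n_frames)
            if i1 > i0:
                da[i0:i1] += amp * decay[: i1 - i0]

    bleach = bleach_floor + (1.0 - bleach_floor) * np.exp(-t_frame / bleach_tau)
    if motion_sd > 0:
        # slow shared motion: low-pass filtered noise at the frame rate
        raw = rng.normal(size=n_frames)
        kern = np.exp(-np.arange(200) / 50.0)
        motion = np.convolve(raw, kern / kern.sum(), mode="same")
        motion *= motion_sd / np.std(motion)
    else:
        motion = np.zeros(n_frames)

    ch470 = gain_470 * (1.0 + da) * bleach * (1.0 + motion)
    ch405 = gain_405 * bleach * (1.0 + motion)
    frame_vals = np.where(np.arange(n_frames) % 2 == 0, ch470, ch405)
    schedule = np.where(np.arange(n_frames) % 2 == 0, 470, 405)

    spf = 100  # samples per 10 ms frame at 10 kHz
    detector = np.zeros((n_frames, spf), dtype=np.float32)
    detector[:, :40] = frame_vals[:, None]           # 4 ms on-window
    detector += rng.normal(0.0, detector_noise, size=detector.shape).astype(
        np.float32
    )
    raw = PhotometryRaw(
        detector=detector.ravel(),
        schedule=schedule,
        sample_rate=10_000.0,
        frame_ms=10.0,
        on_ms=4.0,
        off_ms=6.0,
        t0=0.0,
    )
    gt = GroundTruth(
        v_true=v_true,
        photo_kernels=list(kernels),
        bleach=(float(bleach_tau), float(bleach_floor)),
    )
    return raw, gt


# ---------------------------------------------------------------------------
# whole sessions

def gen_session(
    seed: int,
    behavior: BehaviorSpec | None = None,
    n_trials: int | None = None,
    unit_specs: list[dict] | None = None,
    laser: bool = True,
    ecog: bool = False,
    photometry_kernels: list[PhotoKernelSpec] | None = None,
    photometry_artifact: tuple[float, float] = (1200.0, 0.01),
    sws_schedule: list[tuple[tuple[float, float], str]] | None = None,
    region_label: str = "DLS",
    hemisphere: str = "left",
    session_id: str | None = None,
) -> tuple[Session, GroundTruth]:
    """Assemble a full synthetic session plus its ground truth.

    ``unit_specs`` entries are dicts with keys base_rate, regularity,
    kernels (list of KernelSpec) and the laser parameters p_follow,
    laser_latency, laser_jitter (p_follow 0 = non-responsive unit).
    """
    rng = np.random.default_rng(seed)
    behavior = behavior or BehaviorSpec()
    trials, gt = gen_behavior(behavior, seed=int(rng.integers(2**31)),
                              n_trials=n_trials)
    task_end = float(trials["side_in"].max()) + 10.0

    laser_table = None
    if laser:
        laser_table = gen_laser_schedule(start=task_end + 20.0)
        task_end = float(laser_table.pulse_times.max()) + 10.0
    duration = task_end

    units: list[SpikeTrain] = []
    for i, uspec in enumerate(unit_specs or []):
        uid = uspec.get("unit_id", f"u{i}")
        train, ugt = gen_spikes(
            trials,
            base_rate=uspec.get("base_rate", 5.0),
            regularity=uspec.get("regularity", 2.0),
            kernels=uspec.get("kernels", []),
            seed=int(rng.integers(2**31)),
            duration=duration,
            v_true=gt.v_true,
            hemisphere=hemisphere,
            unit_id=uid,
        )
        p_follow = uspec.get("p_follow", 0.0)
        if laser_table is not None and p_follow > 0:
            train = gen_laser(
                train, laser_table, p_follow,
                uspec.get("laser_latency", 0.005),
                uspec.get("laser_jitter", 0.001),
                seed=int(rng.integers(2**31)),
            )
        units.append(train)
        gt.kernels[uid] = ugt.kernels[uid]
        gt.base_rates[uid] = ugt.base_rates[uid]
        gt.regularity[uid] = ugt.regularity[uid]
        gt.laser_responsive[uid] = bool(p_follow > 0)

    ecog_sig = None
    if ecog:
        if sws_schedule is None:
            sws_schedule = [((0.0, duration), "wake")]
        ecog_sig = gen_ecog(sws_schedule, seed=int(rng.integers(2**31)))
        gt.sws_intervals = [
            (iv[0], iv[1]) for iv, st in sws_schedule if st == "sws"
        ]

    photo = None
    if photometry_kernels is not None:
        photo, pgt = gen_photometry(
            trials, photometry_kernels, photometry_artifact,
            seed=int(rng.integers(2**31)), duration=duration,
            v_true=gt.v_true,
        )
        gt.photo_kernels = pgt.photo_kernels
        gt.bleach = pgt.bleach

    session = Session(
        session_id=session_id or f"synth-{seed}",
        duration=duration,
        trials=trials,
        units=units,
        laser=laser_table,
        ecog=ecog_sig,
        photometry=photo,
        region_label=region_label,
        hemisphere=hemisphere,
    )
    return validate_session(session), gt
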