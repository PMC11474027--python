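"""Fiber-photometry processing: demultiplexing, dF/F, event alignment.

The detector trace interleaves two excitation LEDs (470 nm dLight
dopamine signal, 405 nm dopamine-insensitive control) in 10 ms frames
(4 ms on, 6 ms off).  Each frame yields one channel value (mean of the
interior of its on-window, discarding 0.5 ms transitions at each edge);
channels are interpolated onto a common uniform grid.  The control is
rescaled to the signal by least squares and

    dF/F = (470 - 405_fit) / 405_fit

removes bleaching and shared motion artifacts.  dF/F is median-filtered
(5 points) and z-scored over the session; event-aligned significance
uses the same shared shuffle null as the spike PETHs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import medfilt

from .core_io import ContinuousSignal, PhotometryRaw
from .event_stats import SignificanceMap, null_thresholds

__all__ = [
    "DffSignal",
    "demultiplex",
    "compute_dff",
    "align_dff",
    "dff_significance",
]


@dataclass
class DffSignal:
    samples: np.ndarray        # z-scored dF/F
    raw_dff: np.ndarray        # pre-z-score dF/F (median-filtered)
    sample_rate: float
    fit_params: tuple[float, float]   # (slope, intercept) of 405 -> 470
    t0: float = 0.0

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate


def demultiplex(
    raw: PhotometryRaw,
    grid_rate: float = 250.0,
    edge_discard_ms: float = 0.5,
) -> tuple[ContinuousSignal, ContinuousSignal]:
    """Split the multiplexed detector trace into 470 and 405 channels.

    Per frame the channel value is the mean over the interior of the on
    period (the first and last 0.5 ms are discarded as LED/detector
    transitions); each channel's per-frame values are then linearly
    interpolated onto a shared uniform grid at ``grid_rate``.
    """
    spf = int(round(raw.samples_per_frame))
    n_frames = raw.n_frames
    frame_s = raw.frame_ms / 1e3
    det = raw.detector[: n_frames * spf].reshape(n_frames, spf)
    i0 = int(round(edge_discard_ms * 1e-3 * raw.sample_rate))
    i1 = int(round((raw.on_ms - edge_discard_ms) * 1e-3 * raw.sample_rate))
    if i1 <= i0:
        raise ValueError("on-window too short after edge discard")
    frame_vals = det[:, i0:i1].mean(axis=1).astype(float)
    # time of each frame's measurement: center of the on-window
    frame_t = raw.t0 + (np.arange(n_frames) + 0.5 * raw.on_ms / raw.frame_ms
                        ) * frame_s

    grid_t = raw.t0 + np.arange(
        int(np.floor(n_frames * frame_s * grid_rate))
    ) / grid_rate
    out = []
    for led in (470, 405):
        m = raw.schedule == led
        if not m.any():
            raise ValueError(f"schedule contains no {led} frames")
        # a gap in the schedule leaves a frame with neither LED assigned;
        # PhotometryRaw validation guarantees full tiling, so only check
        # that both LEDs keep alternating over the recording
        vals = np.interp(grid_t, frame_t[m], frame_vals[m])
        out.append(ContinuousSignal(vals, grid_rate, t0=raw.t0))
    return out[0], out[1]


def compute_dff(
    sig470: ContinuousSignal,
    sig405: ContinuousSignal,
    fit: str = "affine",
    median_filter: int = 5,
) -> DffSignal:
    """Control-channel regression and fractional fluorescence.

    The 405 control is rescaled to the 470 signal by least squares
    ("affine": slope + intercept; "slope": slope only), then
    dF/F = (470 - 405_fit)/405_fit, 5-point median filter, z-score over
    the session.
    """
    if sig470.sample_rate != sig405.sample_rate or (
        sig470.samples.size != sig405.samples.size
    ):
        raise ValueError("channels must share one grid")
    x = sig405.samples
    y = sig470.samples
    if np.std(x) == 0:
        raise ValueError("control channel constant")
    if fit == "affine":
        A = np.column_stack([x, np.ones_like(x)])
        (a, b), *_ = np.linalg.lstsq(A, y, rcond=None)
    elif fit == "slope":
        a = float(np.dot(x, y) / np.dot(x, x))
        b = 0.0
    else:
        raise ValueError(f"unknown fit '{fit}'")
    fit_vals = a * x + b
    if np.any(fit_vals <= 0):
        raise ValueError("fitted control non-positive; cannot form dF/F")
    dff = (y - fit_vals) / fit_vals
    if median_filter and median_filter > 1:
        dff = medfilt(dff, kernel_size=median_filter)
    sd = np.std(dff)
    z = (dff - np.mean(dff)) / sd if sd > 0 else dff - np.mean(dff)
    return DffSignal(
        samples=z,
        raw_dff=dff,
        sample_rate=sig470.sample_rate,
        fit_params=(float(a), float(b)),
        t0=sig470.t0,
    )


def align_dff(
    dff: DffSignal,
    event_times: np.ndarray,
    window: tuple[float, float],
    groups: np.ndarray | None = None,
    use: str = "z",
) -> dict:
    """Per-trial window extraction on the dF/F grid.

    Returns rel-time vector, a trials x samples matrix, group means and
    SEMs (same grouping vocabulary as the spike PETHs), and the count of
    trials dropped for truncated windows.
    """
    x = dff.samples if use == "z" else dff.raw_dff
    fs = dff.sample_rate
    event_times = np.asarray(event_times, dtype=float)
    n_win = int(round((window[1] - window[0]) * fs))
    off0 = int(round(window[0] * fs))
    idx0 = np.round((event_times - dff.t0) * fs).astype(int) + off0
    keep = (
        np.isfinite(event_times) & (idx0 >= 0) & (idx0 + n_win <= x.size)
    )
    n_dropped = int((~keep).sum())
    idx0 = idx0[keep]
    if groups is not None:
        groups = np.asarray(groups, dtype=object)[keep]
    if idx0.size == 0:
        raise ValueError("no usable events after edge dropping")
    mat = x[idx0[:, None] + np.arange(n_win)[None, :]]
    rel_t = window[0] + np.arange(n_win) / fs
    out = {
        "rel_time": rel_t,
        "matrix": mat,
        "mean": mat.mean(axis=0),
        "sem": mat.std(axis=0, ddof=1) / np.sqrt(mat.shape[0])
        if mat.shape[0] > 1 else np.zeros(n_win),
        "n_dropped": n_dropped,
        "groups": {},
    }
    if groups is not None:
        for g in dict.fromkeys(groups):
            rows = groups == g
            sub = mat[rows]
            out["groups"][g] = {
                "mean": sub.mean(axis=0),
                "sem": sub.std(axis=0, ddof=1) / np.sqrt(sub.shape[0])
                if sub.shape[0] > 1 else np.zeros(n_win),
                "n": int(rows.sum()),
            }
    return out


def dff_significance(
    dff: DffSignal,
    event_times: np.ndarray,
    window: tuple[float, float],
    n_shuffles: int = 10_000,
    alpha: float = 0.005,
    seed: int = 0,
    correction: str = "bonferroni",
    null_tail: str | None = None,
    use: str = "z",
) -> SignificanceMap:
    """Shuffle-test the event-aligned mean dF/F per time sample.

    Identical logic to the spike-PETH shuffle test: the null statistic
    is the mean dF/F over n_trials pseudo-events placed uniformly
    wherever the window fits, shared across time samples.
    """
    aligned = align_dff(dff, event_times, window, use=use)
    observed = aligned["mean"]
    n_trials = aligned["matrix"].shape[0]
    n_stats = observed.size
    x = dff.samples if use == "z" else dff.raw_dff
    fs = dff.sample_rate

    rng = np.random.default_rng(seed)
    lo_i = max(int(np.ceil(-window[0] * fs)), 0)
    hi_i = x.size - int(np.ceil(window[1] * fs)) - 1
    if hi_i <= lo_i:
        raise ValueError("signal too short to place shuffled windows")
    idx = rng.integers(lo_i, hi_i, size=(n_shuffles, n_trials))
    null_flat = x[idx].mean(axis=1)
    hi_thr, lo_thr, tail_used = null_thresholds(
        null_flat, alpha, n_stats, correction, null_tail
    )
    return SignificanceMap(
        up=observed > hi_thr,
        down=observed < lo_thr,
        null_mean=float(np.mean(null_flat)),
        null_sd=float(np.std(null_flat)),
        threshold_up=hi_thr,
        threshold_down=lo_thr,
        alpha=alpha,
        n_shuffles=n_shuffles,
        correction=correction,
        null_tail=tail_used,
        seed=seed,
        null_quantiles={
            q: float(np.quantile(null_flat, q))
            for q in (0.005, 0.025, 0.5, 0.975, 0.995)
        },
    )
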