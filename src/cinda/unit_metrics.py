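"""Per-unit descriptive metrics and the CIN-enrichment screen.

Tagged cholinergic interneurons are tonically active (~2-10 Hz), fire
regularly (ISI CV around 1), rarely fall silent for seconds at a time,
show long postspike suppression in their autocorrelogram, and have broad
spike waveforms.  These metrics quantify each property; the enrichment
filter combines them into a configurable screen for untagged units
(an enrichment screen, not ground truth).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_io import UnitWaveform

__all__ = [
    "UnitMetrics",
    "basic_metrics",
    "postspike_suppression",
    "waveform_metrics",
    "cin_enrichment_filter",
]


@dataclass
class UnitMetrics:
    mean_rate: float | None = None          # Hz
    isi_cv: float | None = None
    frac_time_long_isi: float | None = None
    postspike_suppression: float | None = None  # s
    peak_width: float | None = None             # s (FWHM)
    peak_to_valley: float | None = None          # s
    state_restriction: str = "all"


def _restrict(spike_times: np.ndarray, intervals) -> tuple[np.ndarray, float, list]:
    """Spikes inside the analyzed intervals and the total analyzed time."""
    if intervals is None:
        return spike_times, float("nan"), []
    kept = []
    total = 0.0
    ivals = []
    for a, b in intervals:
        kept.append(spike_times[(spike_times >= a) & (spike_times < b)])
        total += b - a
        ivals.append((a, b))
    return np.concatenate(kept) if kept else spike_times[:0], total, ivals


def basic_metrics(
    spike_times: np.ndarray,
    duration: float | None = None,
    state_intervals: list[tuple[float, float]] | None = None,
    isi_threshold: float = 2.0,
) -> tuple[float | None, float | None, float | None]:
    """(mean_rate, isi_cv, frac_time_long_isi) over the analyzed intervals.

    frac_time_long_isi is the fraction of analyzed time spent inside
    interspike intervals longer than ``isi_threshold`` (the "proportion
    of time not spiking").  ISIs that straddle an interval boundary are
    excluded from the CV; fewer than 2 usable spikes -> None metrics.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    if state_intervals is not None:
        isis = []
        total = 0.0
        n_spikes = 0
        long_time = 0.0
        for a, b in state_intervals:
            seg = spike_times[(spike_times >= a) & (spike_times < b)]
            n_spikes += seg.size
            total += b - a
            if seg.size >= 2:
                d = np.diff(seg)
                isis.append(d)
                long_time += d[d > isi_threshold].sum()
        isis = np.concatenate(isis) if isis else np.array([])
    else:
        if duration is None:
            raise ValueError("duration required without state intervals")
        total = float(duration)
        n_spikes = spike_times.size
        isis = np.diff(spike_times)
        long_time = isis[isis > isi_threshold].sum() if isis.size else 0.0
    if n_spikes < 2 or total <= 0:
        return None, None, None
    mean_rate = n_spikes / total
    cv = float(np.std(isis) / np.mean(isis)) if isis.size else None
    frac = float(min(long_time / total, 1.0))
    return float(mean_rate), cv, frac


def postspike_suppression(
    spike_times: np.ndarray, max_lag: float = 0.200, bin_width: float = 0.001
) -> float | None:
    """Lag (s) at which the autocorrelogram first exceeds half its mean.

    The autocorrelogram uses 1 ms bins over lags (0, max_lag]; raw pair
    counts, no normalization.  Long suppression (tens of ms) is a CIN
    hallmark.  All-zero histogram -> None.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    n_bins = int(round(max_lag / bin_width))
    edges = bin_width * np.arange(n_bins + 1)
    # pair lags within max_lag, forward direction only
    j1 = np.searchsorted(spike_times, spike_times + max_lag, side="right")
    lags = [
        spike_times[i + 1 : j1[i]] - spike_times[i]
        for i in range(spike_times.size)
        if j1[i] > i + 1
    ]
    all_lags = np.concatenate(lags) if lags else np.array([])
    counts = np.histogram(all_lags, bins=edges)[0]
    if counts.sum() == 0:
        return None
    half_mean = counts.mean() / 2.0
    above = np.flatnonzero(counts > half_mean)
    if above.size == 0:
        return None
    return float(edges[above[0]] + bin_width / 2.0)  # bin center


def waveform_metrics(waveform: UnitWaveform) -> tuple[float, float]:
    """(peak_width, peak_to_valley) in seconds, on the largest channel.

    peak_width is the full width at half maximum of the deepest
    negative deflection (linear interpolation between samples);
    peak_to_valley runs from that trough to the most positive voltage
    after it inside the 2 ms window.
    """
    w = waveform.samples
    ch = int(np.argmax(np.abs(w.min(axis=1))))
    v = w[ch]
    if v.min() >= 0:
        raise ValueError("not a spike waveform (no negative deflection)")
    i_tr = int(np.argmin(v))
    half = v[i_tr] / 2.0

    left = 0.0
    for i in range(i_tr - 1, -1, -1):
        if v[i] > half:  # crossing between samples i and i+1
            left = i + (v[i] - half) / (v[i] - v[i + 1])
            break
    right = float(v.size - 1)
    for i in range(i_tr + 1, v.size):
        if v[i] > half:  # crossing between samples i-1 and i
            right = (i - 1) + (half - v[i - 1]) / (v[i] - v[i - 1])
            break
    fwhm = (right - left) / waveform.sample_rate

    after = v[i_tr:]
    i_val = i_tr + int(np.argmax(after))
    ptv = (i_val - i_tr) / waveform.sample_rate
    return float(fwhm), float(ptv)


def cin_enrichment_filter(
    metrics: UnitMetrics,
    rate_range: tuple[float, float] = (2.0, 10.0),
    cv_max: float = 1.9,
    suppression_min: float = 0.040,
    width_min: float = 0.0003,
) -> tuple[bool, str]:
    """Multi-criterion CIN screen; returns (verdict, reason)."""
    needed = {
        "mean_rate": metrics.mean_rate,
        "isi_cv": metrics.isi_cv,
        "postspike_suppression": metrics.postspike_suppression,
        "peak_width": metrics.peak_width,
    }
    for name, val in needed.items():
        if val is None:
            return False, f"missing metric {name}"
    if not rate_range[0] <= metrics.mean_rate <= rate_range[1]:
        return False, "rate outside range"
    if metrics.isi_cv > cv_max:
        return False, "CV too high"
    if metrics.postspike_suppression < suppression_min:
        return False, "postspike suppression too short"
    if metrics.peak_width < width_min:
        return False, "waveform too narrow"
    return True, "pass"
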