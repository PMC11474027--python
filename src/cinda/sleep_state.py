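"""Slow-wave-sleep detection from ECoG band-power ratios.

Per analysis frame the statistic

    k = P(0.5-8 Hz) / P(20-60 Hz) - P(0.5-4 Hz) / P(8-12 Hz)

is computed from the frame's Welch periodogram; band power is the PSD
integrated over the band.  Frames with k above a threshold of 3 mark
putative SWS; runs shorter than 30 s are excluded.  The second ratio
subtracts off occasional low-frequency artifacts that would otherwise
inflate the first.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as ssig

from .core_io import ContinuousSignal

__all__ = ["SwsResult", "BANDS", "k_timeseries", "detect_sws", "sws_epochs"]

BANDS = {
    "r1": (0.5, 8.0),
    "r2": (20.0, 60.0),
    "r3": (0.5, 4.0),
    "r4": (8.0, 12.0),
}


@dataclass
class SwsResult:
    k_series: np.ndarray
    frame_times: np.ndarray          # frame start times (s)
    epochs: list[tuple[float, float]]
    frame: float
    threshold: float = 3.0
    min_duration: float = 30.0
    bands: dict = field(default_factory=lambda: dict(BANDS))


def _band_power(f: np.ndarray, psd: np.ndarray, band: tuple[float, float]) -> float:
    df = f[1] - f[0]
    m = (f >= band[0]) & (f < band[1])
    return float(psd[m].sum() * df)


def k_timeseries(
    ecog: ContinuousSignal,
    frame: float = 10.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame k statistic from Hann-tapered Welch periodograms.

    Frames of ``frame`` seconds advance by frame*(1-overlap); each is
    split into 5 s Welch segments (0.2 Hz resolution, enough to resolve
    the 0.5 Hz band edge).
    """
    fs = ecog.sample_rate
    if fs < 120.0:
        raise ValueError("sample rate must be >= 120 Hz to resolve 60 Hz")
    if frame < 2.0:
        raise ValueError("frame must be >= 2 s to resolve 0.5 Hz")
    n_frame = int(round(frame * fs))
    step = int(round(n_frame * (1.0 - overlap)))
    if step < 1:
        raise ValueError("overlap too large")
    x = ecog.samples
    nperseg = min(n_frame, int(round(5.0 * fs)))
    starts = np.arange(0, x.size - n_frame + 1, step)
    k = np.empty(starts.size)
    for i, s in enumerate(starts):
        f, psd = ssig.welch(
            x[s : s + n_frame], fs=fs, window="hann", nperseg=nperseg
        )
        p = {name: _band_power(f, psd, band) for name, band in BANDS.items()}
        if p["r2"] > 0 and p["r4"] > 0:
            k[i] = p["r1"] / p["r2"] - p["r3"] / p["r4"]
        else:
            k[i] = np.nan
    frame_times = ecog.t0 + starts / fs
    return frame_times, k


def detect_sws(
    k_series: np.ndarray,
    frame_times: np.ndarray,
    frame: float,
    threshold: float = 3.0,
    min_duration: float = 30.0,
    bridge_frames: int = 1,
) -> list[tuple[float, float]]:
    """Maximal runs of frames with k > threshold, as [start, end) intervals.

    Single sub-threshold frames inside a run are bridged (configurable);
    runs shorter than ``min_duration`` are discarded.
    """
    k = np.asarray(k_series, dtype=float)
    above = k > threshold
    if bridge_frames > 0:
        a = above.copy()
        i = 0
        n = a.size
        while i < n:
            if not a[i]:
                j = i
                while j < n and not a[j]:
                    j += 1
                if i > 0 and j < n and (j - i) <= bridge_frames:
                    a[i:j] = True
                i = j
            else:
                i += 1
        above = a
    epochs: list[tuple[float, float]] = []
    i = 0
    n = above.size
    while i < n:
        if above[i]:
            j = i
            while j + 1 < n and above[j + 1]:
                j += 1
            start = float(frame_times[i])
            end = float(frame_times[j] + frame)
            if end - start >= min_duration:
                epochs.append((start, end))
            i = j + 1
        else:
            i += 1
    return epochs


def sws_epochs(
    ecog: ContinuousSignal,
    frame: float = 10.0,
    overlap: float = 0.5,
    threshold: float = 3.0,
    min_duration: float = 30.0,
) -> SwsResult:
    """End-to-end SWS detection on an ECoG trace."""
    frame_times, k = k_timeseries(ecog, frame=frame, overlap=overlap)
    epochs = detect_sws(
        k, frame_times, frame, threshold=threshold, min_duration=min_duration
    )
    return SwsResult(
        k_series=k, frame_times=frame_times, epochs=epochs, frame=frame,
        threshold=threshold, min_duration=min_duration,
    )
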