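"""Peri-event rate estimation with shuffle-test significance.

PETHs use a 3 s window in 10 ms bins sliding in 5 ms steps by default.
Significance per bin comes from comparing the observed mean rate to a
null distribution of pseudo-event alignments: each shuffle places the
same number of events uniformly at random anywhere in the session that
the full analysis window fits, and contributes one sample of the mean
windowed rate.  Because pseudo-events are uniform, that null is shared
by every bin, so n_shuffles samples serve the whole map.

Bin geometry: with window [t0, t1), width w and step s, bin i is the
half-open interval [t0 + i*s, t0 + i*s + w) relative to the event, and
n_bins = floor((t1 - t0 - w)/s) + 1 (599 bins for a 3 s window at
10 ms / 5 ms).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

__all__ = [
    "PethResult",
    "SignificanceMap",
    "OnsetResult",
    "n_peth_bins",
    "compute_peth",
    "shuffle_significance",
    "onset_latency",
    "selectivity_index",
    "sensory_motor_label",
    "SENSORY_MOTOR_WINDOWS",
]


def n_peth_bins(window: tuple[float, float], bin_width: float, step: float) -> int:
    span = window[1] - window[0]
    return int(np.floor((span - bin_width) / step + 1e-9)) + 1


@dataclass
class PethResult:
    align_event: str
    window: tuple[float, float]
    bin_width: float
    step: float
    bin_centers: np.ndarray
    trial_counts: np.ndarray          # (n_trials, n_bins)
    mean_rate: np.ndarray             # Hz per bin
    event_times: np.ndarray           # events actually used
    group_labels: np.ndarray | None = None
    n_dropped: int = 0

    @property
    def n_trials(self) -> int:
        return self.trial_counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.trial_counts.shape[1]

    def group_mean_rates(self) -> dict:
        if self.group_labels is None:
            return {}
        out = {}
        for g in pd_unique(self.group_labels):
            m = self.group_labels == g
            out[g] = self.trial_counts[m].mean(axis=0) / self.bin_width
        return out


def pd_unique(a: np.ndarray) -> list:
    seen: dict = {}
    for x in a:
        seen.setdefault(x, None)
    return list(seen)


@dataclass
class SignificanceMap:
    up: np.ndarray
    down: np.ndarray
    null_mean: float
    null_sd: float
    threshold_up: float
    threshold_down: float
    alpha: float
    n_shuffles: int
    correction: str
    null_tail: str
    seed: int
    null_quantiles: dict | None = None


@dataclass
class OnsetResult:
    direction: str
    onset: float | None
    offset: float | None
    duration: float | None


def compute_peth(
    spike_times: np.ndarray,
    event_times: np.ndarray,
    window: tuple[float, float] = (-1.0, 2.0),
    bin_width: float = 0.010,
    step: float = 0.005,
    groups: np.ndarray | None = None,
    session_duration: float | None = None,
    align_event: str = "",
) -> PethResult:
    """Spike counts per trial per overlapping bin around each event.

    Events whose window would be truncated by the session edge are
    dropped (their count is reported in ``n_dropped``).
    """
    spike_times = np.asarray(spike_times, dtype=float)
    event_times = np.asarray(event_times, dtype=float)
    keep = np.isfinite(event_times)
    if session_duration is not None:
        keep &= (event_times + window[0] >= 0) & (
            event_times + window[1] <= session_duration
        )
    n_dropped = int((~keep).sum())
    events = event_times[keep]
    if groups is not None:
        groups = np.asarray(groups, dtype=object)[keep]
    if events.size == 0:
        raise ValueError("no usable events (all dropped or none supplied)")
    n_bins = n_peth_bins(window, bin_width, step)
    if n_bins < 1:
        raise ValueError("window shorter than one bin")
    left = window[0] + step * np.arange(n_bins)
    right = left + bin_width
    centers = left + bin_width / 2.0
    lo = np.searchsorted(spike_times, (events[:, None] + left[None, :]).ravel())
    hi = np.searchsorted(spike_times, (events[:, None] + right[None, :]).ravel())
    counts = (hi - lo).reshape(events.size, n_bins)
    return PethResult(
        align_event=align_event,
        window=tuple(window),
        bin_width=bin_width,
        step=step,
        bin_centers=centers,
        trial_counts=counts,
        mean_rate=counts.mean(axis=0) / bin_width,
        event_times=events,
        group_labels=groups,
        n_dropped=n_dropped,
    )


def _tail_alpha(alpha: float, n_stats: int, correction: str) -> float:
    """Per-tail exceedance probability for the requested correction."""
    if correction == "bonferroni":
        return (alpha / 2.0) / n_stats
    if correction == "pointwise":
        return alpha
    raise ValueError(f"unknown correction '{correction}'")


def null_thresholds(
    null_samples: np.ndarray,
    alpha: float,
    n_stats: int,
    correction: str,
    null_tail: str | None,
) -> tuple[float, float, str]:
    """Up/down decision thresholds from a shared null distribution."""
    if null_tail is None:
        null_tail = "gaussian" if correction == "bonferroni" else "empirical"
    a_tail = _tail_alpha(alpha, n_stats, correction)
    if null_tail == "gaussian":
        # moment-matched tail with a Cornish-Fisher skewness correction:
        # count means are right-skewed, and a plain Gaussian tail is
        # anti-conservative at the small per-tail alphas Bonferroni needs
        mu, sd = float(np.mean(null_samples)), float(np.std(null_samples))
        g1 = float(sstats.skew(null_samples))
        z = sstats.norm.ppf(1.0 - a_tail)
        z_up = z + g1 / 6.0 * (z * z - 1.0)
        z_dn = -z + g1 / 6.0 * (z * z - 1.0)
        return mu + z_up * sd, mu + z_dn * sd, null_tail
    if null_tail == "empirical":
        if null_samples.size < 1.0 / a_tail:
            raise ValueError(
                f"insufficient shuffles for requested alpha: need >= "
                f"{int(np.ceil(1.0 / a_tail))}, have {null_samples.size}"
            )
        hi = float(np.quantile(null_samples, 1.0 - a_tail))
        lo = float(np.quantile(null_samples, a_tail))
        return hi, lo, null_tail
    raise ValueError(f"unknown null_tail '{null_tail}'")


def shuffle_significance(
    spike_times: np.ndarray,
    peth: PethResult,
    session_duration: float,
    n_shuffles: int = 10_000,
    alpha: float = 0.005,
    seed: int = 0,
    correction: str = "bonferroni",
    null_tail: str | None = None,
) -> SignificanceMap:
    """Flag bins whose mean rate exceeds the shuffle-null quantiles.

    correction: "bonferroni" (alpha/2 per tail, adjusted across bins;
    Gaussian tail by default), "pointwise" (alpha per tail, raw
    quantiles, no correction) or "maxstat" (null distribution of the
    across-bin extremum).  Two-tailed semantics throughout: "up" and
    "down" flags are mutually exclusive.
    """
    spike_times = np.asarray(spike_times, dtype=float)
    rng = np.random.default_rng(seed)
    w0, w1 = peth.window
    lo_e, hi_e = -w0, session_duration - w1
    if hi_e <= lo_e:
        raise ValueError("session too short to place shuffled windows")
    n_trials, n_bins = peth.trial_counts.shape
    bw = peth.bin_width

    if correction == "maxstat":
        events = rng.uniform(lo_e, hi_e, size=(n_shuffles, n_trials))
        left = peth.bin_centers - bw / 2.0
        pts = events[:, :, None] + left[None, None, :]
        c_lo = np.searchsorted(spike_times, pts.ravel())
        c_hi = np.searchsorted(spike_times, (pts + bw).ravel())
        counts = (c_hi - c_lo).reshape(n_shuffles, n_trials, n_bins)
        pseudo = counts.mean(axis=1) / bw             # (n_shuffles, n_bins)
        hi_thr = float(np.quantile(pseudo.max(axis=1), 1.0 - alpha / 2.0))
        lo_thr = float(np.quantile(pseudo.min(axis=1), alpha / 2.0))
        null_flat = pseudo[:, 0]
        tail_used = "empirical"
    else:
        events = rng.uniform(lo_e, hi_e, size=(n_shuffles, n_trials))
        c = np.searchsorted(spike_times, events.ravel() + bw) - np.searchsorted(
            spike_times, events.ravel()
        )
        null_flat = c.reshape(n_shuffles, n_trials).mean(axis=1) / bw
        hi_thr, lo_thr, tail_used = null_thresholds(
            null_flat, alpha, n_bins, correction, null_tail
        )

    up = peth.mean_rate > hi_thr
    down = peth.mean_rate < lo_thr
    return SignificanceMap(
        up=up,
        down=down,
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


def onset_latency(
    sig: SignificanceMap,
    direction: str,
    bin_centers: np.ndarray,
    bin_width: float,
    search_window: tuple[float, float] | None = None,
) -> OnsetResult:
    """First significant bin in the requested direction.

    onset = center of the first flagged bin inside the search window,
    offset = center of the last bin of that contiguous run, duration =
    offset - onset + bin_width.  No flagged bin -> absent onset (the
    unit counts as not responsive).
    """
    flags = sig.up if direction == "up" else sig.down
    mask = np.ones_like(flags, dtype=bool)
    if search_window is not None:
        mask = (bin_centers >= search_window[0]) & (bin_centers < search_window[1])
    idx = np.flatnonzero(flags & mask)
    if idx.size == 0:
        return OnsetResult(direction=direction, onset=None, offset=None,
                           duration=None)
    first = idx[0]
    last = first
    while last + 1 < flags.size and flags[last + 1] and mask[last + 1]:
        last += 1
    onset = float(bin_centers[first])
    offset = float(bin_centers[last])
    return OnsetResult(
        direction=direction, onset=onset, offset=offset,
        duration=offset - onset + bin_width,
    )


def selectivity_index(
    peth: PethResult,
    response_window: tuple[float, float],
    contra_label: str = "contra",
    ipsi_label: str = "ipsi",
) -> float:
    """(M_contra - M_ipsi) / (M_contra + M_ipsi) over the response window."""
    if peth.group_labels is None:
        raise ValueError("selectivity_index needs a contra/ipsi-grouped PETH")
    m = (peth.bin_centers >= response_window[0]) & (
        peth.bin_centers < response_window[1]
    )
    if not m.any():
        raise ValueError("response window contains no bins")
    means = {}
    for lab in (contra_label, ipsi_label):
        rows = peth.group_labels == lab
        if not rows.any():
            raise ValueError(f"group '{lab}' is empty")
        means[lab] = peth.trial_counts[rows][:, m].mean() / peth.bin_width
    mc, mi = means[contra_label], means[ipsi_label]
    if mc + mi == 0:
        return float("nan")
    return (mc - mi) / (mc + mi)


#: component-specific significance/extremum windows (s): go-cue aligned and
#: center-out aligned, chosen from the observed onset ranges of each component
SENSORY_MOTOR_WINDOWS = {
    "burst": {"go_cue": (0.0, 0.120), "center_out": (-0.400, 0.150)},
    "pause": {"go_cue": (0.0, 0.400), "center_out": (-0.200, 0.200)},
    "rebound": {"go_cue": (0.200, 0.500), "center_out": (0.0, 0.400)},
}

_BASELINE_WINDOW = (-1.0, -0.5)


def _component_extremum(
    peth: PethResult, window: tuple[float, float], component: str
) -> float:
    m = (peth.bin_centers >= window[0]) & (peth.bin_centers < window[1])
    rate = peth.mean_rate
    if component in ("burst", "rebound"):
        return float(rate[m].max())
    # pause: deviation below the pre-event baseline
    b = (peth.bin_centers >= _BASELINE_WINDOW[0]) & (
        peth.bin_centers < _BASELINE_WINDOW[1]
    )
    baseline = float(rate[b].mean()) if b.any() else float(rate.mean())
    return baseline - float(rate[m].min())


def sensory_motor_label(
    spike_times: np.ndarray,
    trials,
    component: str,
    session_duration: float,
    n_shuffles: int = 10_000,
    alpha: float = 0.005,
    seed: int = 0,
    correction: str = "bonferroni",
) -> tuple[float, str] | None:
    """Is a response component cue-locked ("sensory") or movement-locked
    ("motor")?

    Requires a significant component of the requested type in the
    go-cue-aligned window (shuffle test); returns None otherwise (the
    unit is excluded).  ratio = movement-aligned extremum / cue-aligned
    extremum; ratio > 1 -> "motor", else "sensory" (ties sensory).
    """
    if component not in SENSORY_MOTOR_WINDOWS:
        raise ValueError(f"unknown component '{component}'")
    windows = SENSORY_MOTOR_WINDOWS[component]
    direction = "down" if component == "pause" else "up"

    peth_go = compute_peth(
        spike_times, trials["go_cue"].to_numpy(dtype=float),
        session_duration=session_duration, align_event="go_cue",
    )
    sig = shuffle_significance(
        spike_times, peth_go, session_duration,
        n_shuffles=n_shuffles, alpha=alpha, seed=seed, correction=correction,
    )
    onset = onset_latency(
        sig, direction, peth_go.bin_centers, peth_go.bin_width,
        search_window=windows["go_cue"],
    )
    if onset.onset is None:
        return None

    peth_co = compute_peth(
        spike_times, trials["center_out"].to_numpy(dtype=float),
        session_duration=session_duration, align_event="center_out",
    )
    cue_ext = _component_extremum(peth_go, windows["go_cue"], component)
    mov_ext = _component_extremum(peth_co, windows["center_out"], component)
    if cue_ext == 0:
        return float("inf"), "motor"
    ratio = mov_ext / cue_ext
    return ratio, ("motor" if ratio > 1.0 else "sensory")
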