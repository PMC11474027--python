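"""Session data model, on-disk formats, validation and configuration.

All times are seconds (float) on a single session clock starting at 0.
Windows are half-open intervals [a, b) wherever anything is binned.

On-disk layout of a session directory::

    session.json        id, duration, region, hemisphere
    trials.csv          one row per trial (TrialTable columns)
    units/<id>.csv      column spike_time_s
    units/<id>.waveform.csv   rows = channels, samples across columns
    units/<id>.evoked.csv     optional laser-evoked mean waveform, same shape
    units/<id>.meta.json      tetrode_id, waveform sample_rate
    laser.csv           optional: pulse_time_s, width_ms, freq_hz, condition
    ecog.h5             optional: dataset "samples", attrs sample_rate, t0
    photometry.h5       optional: dataset "detector", dataset "schedule",
                        attrs sample_rate, frame_ms, on_ms, off_ms, t0
"""

from __future__ import annotations

import copy
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

__all__ = [
    "UnitWaveform",
    "SpikeTrain",
    "LaserStimTable",
    "ContinuousSignal",
    "PhotometryRaw",
    "Session",
    "ValidationError",
    "LoadError",
    "validate_session",
    "load_session",
    "write_session",
    "load_config",
    "default_config",
    "DEFAULT_CONFIG",
]

#: duration of the spike-waveform analysis window (s)
WAVEFORM_WINDOW_S = 0.002

TRIAL_COLUMNS = [
    "light_on", "center_in", "go_cue", "center_out", "side_in", "food_in",
    "choice", "outcome", "p_left", "p_right", "block_index", "latency", "rt",
]

VALID_PROBS = (0.1, 0.5, 0.9)
VALID_REGIONS = ("DLS", "DMS", "VS")
VALID_HEMISPHERES = ("left", "right")


class ValidationError(ValueError):
    """A session violates one of the data-model invariants."""


class LoadError(ValueError):
    """A session directory is missing a required file or column."""


@dataclass
class UnitWaveform:
    """Mean extracellular spike waveform over a 2 ms window.

    samples has shape (n_channels, n_samples); sample_rate in samples/s.
    """

    samples: np.ndarray
    sample_rate: float

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.sample_rate <= 0:
            raise ValidationError("waveform sample_rate must be positive")
        dur = self.samples.shape[1] / self.sample_rate
        if not np.isclose(dur, WAVEFORM_WINDOW_S, rtol=0.05):
            raise ValidationError(
                f"waveform window is {dur * 1e3:.3f} ms, expected 2 ms"
            )


@dataclass
class SpikeTrain:
    """Sorted spike times plus the unit's mean waveform."""

    unit_id: str
    spike_times: np.ndarray
    waveform: UnitWaveform | None = None
    tetrode_id: int = 0
    evoked_waveform: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValidationError(f"unit {self.unit_id}: spike_times must be 1-D")
        if self.spike_times.size > 1 and not np.all(np.diff(self.spike_times) > 0):
            raise ValidationError(
                f"unit {self.unit_id}: spike times not strictly increasing"
            )


@dataclass
class LaserStimTable:
    """Laser pulse onsets with per-pulse condition parameters."""

    pulse_times: np.ndarray
    width_ms: np.ndarray
    freq_hz: np.ndarray
    condition: np.ndarray

    VALID_WIDTHS = (2.0, 5.0, 10.0)
    VALID_FREQS = (1.0, 2.0, 5.0, 10.0)

    def __post_init__(self) -> None:
        self.pulse_times = np.asarray(self.pulse_times, dtype=float)
        self.width_ms = np.asarray(self.width_ms, dtype=float)
        self.freq_hz = np.asarray(self.freq_hz, dtype=float)
        self.condition = np.asarray(self.condition, dtype=int)
        n = self.pulse_times.size
        for name in ("width_ms", "freq_hz", "condition"):
            if getattr(self, name).size != n:
                raise ValidationError(f"laser table column {name} has wrong length")
        if not np.isin(self.width_ms, self.VALID_WIDTHS).all():
            raise ValidationError("laser pulse widths must be 2, 5 or 10 ms")
        if not np.isin(self.freq_hz, self.VALID_FREQS).all():
            raise ValidationError("laser frequencies must be 1, 2, 5 or 10 Hz")

    def by_condition(self) -> dict[int, np.ndarray]:
        """Pulse times grouped by condition id (sorted keys)."""
        return {
            int(c): self.pulse_times[self.condition == c]
            for c in np.unique(self.condition)
        }


@dataclass
class ContinuousSignal:
    """Uniformly sampled signal with its own clock offset t0 (s)."""

    samples: np.ndarray
    sample_rate: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sample_rate <= 0:
            raise ValidationError("sample_rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValidationError("continuous signal contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sample_rate


@dataclass
class PhotometryRaw:
    """Time-division-multiplexed detector trace.

    The two excitation LEDs (470 nm dLight signal, 405 nm control) are
    switched in 10 ms frames, 4 ms on / 6 ms off; ``schedule[f]`` gives the
    active LED wavelength of frame f.
    """

    detector: np.ndarray
    schedule: np.ndarray
    sample_rate: float = 10_000.0
    frame_ms: float = 10.0
    on_ms: float = 4.0
    off_ms: float = 6.0
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.detector = np.asarray(self.detector, dtype=np.float32)
        self.schedule = np.asarray(self.schedule, dtype=int)
        spf = self.samples_per_frame
        if abs(spf - round(spf)) > 1e-9:
            raise ValidationError("frame length must be an integer number of samples")
        n_frames = self.detector.size // int(round(spf))
        if self.schedule.size != n_frames:
            raise ValidationError(
                f"schedule length {self.schedule.size} does not tile "
                f"{n_frames} detector frames"
            )
        if not np.isin(self.schedule, (470, 405)).all():
            raise ValidationError("schedule entries must be 470 or 405")

    @property
    def samples_per_frame(self) -> float:
        return self.sample_rate * self.frame_ms / 1e3

    @property
    def n_frames(self) -> int:
        return self.schedule.size


@dataclass
class Session:
    """One recording session on a single clock starting at 0 s."""

    session_id: str
    duration: float
    trials: pd.DataFrame
    units: list[SpikeTrain] = field(default_factory=list)
    laser: LaserStimTable | None = None
    ecog: ContinuousSignal | None = None
    photometry: PhotometryRaw | None = None
    region_label: str | None = None
    hemisphere: str | None = None


# ---------------------------------------------------------------------------
# validation

def _check_trial_order(trials: pd.DataFrame) -> None:
    order = ["light_on", "center_in", "go_cue", "center_out", "side_in"]
    vals = trials[order].to_numpy(dtype=float)
    bad = np.where(np.diff(vals, axis=1) < 0)
    if bad[0].size:
        t = int(bad[0][0])
        a, b = order[bad[1][0]], order[bad[1][0] + 1]
        raise ValidationError(f"trial {t}: event order violated ({b} < {a})")


def validate_session(session: Session) -> Session:
    """Check every data-model invariant; return the session unchanged."""
    trials = session.trials
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise LoadError(f"trial table column(s) {', '.join(missing)} missing")
    if session.duration <= 0:
        raise ValidationError("session duration must be positive")
    _check_trial_order(trials)
    if not trials["outcome"].isin([0, 1]).all():
        raise ValidationError("outcome must be 0 or 1")
    if not trials["choice"].isin(["left", "right"]).all():
        raise ValidationError("choice must be 'left' or 'right'")
    for col in ("p_left", "p_right"):
        if not np.isclose(
            trials[col].to_numpy(dtype=float)[:, None], VALID_PROBS, atol=1e-9
        ).any(axis=1).all():
            raise ValidationError(f"{col} must be one of {VALID_PROBS}")
    rt = trials["center_out"] - trials["go_cue"]
    if not np.allclose(rt, trials["rt"], atol=1e-6):
        raise ValidationError("rt column must equal center_out - go_cue")
    event_cols = ["light_on", "center_in", "go_cue", "center_out", "side_in"]
    ev = trials[event_cols].to_numpy(dtype=float)
    if ev.size and (np.nanmin(ev) < 0 or np.nanmax(ev) > session.duration):
        raise ValidationError("trial event times fall outside [0, duration]")
    fi = trials["food_in"].to_numpy(dtype=float)
    fi = fi[np.isfinite(fi)]
    if fi.size and (fi.min() < 0 or fi.max() > session.duration):
        raise ValidationError("food_in times fall outside [0, duration]")
    for u in session.units:
        if u.spike_times.size and (
            u.spike_times[0] < 0 or u.spike_times[-1] > session.duration
        ):
            raise ValidationError(f"unit {u.unit_id}: spikes outside [0, duration]")
    if session.laser is not None:
        pt = session.laser.pulse_times
        if pt.size and (pt.min() < 0 or pt.max() > session.duration):
            raise ValidationError("laser pulses outside [0, duration]")
    if session.region_label is not None and session.region_label not in VALID_REGIONS:
        raise ValidationError(f"region_label must be one of {VALID_REGIONS}")
    if session.hemisphere is not None and session.hemisphere not in VALID_HEMISPHERES:
        raise ValidationError(f"hemisphere must be one of {VALID_HEMISPHERES}")
    return session


# ---------------------------------------------------------------------------
# session IO

_FLOAT_FMT = "%.10g"  # >= 9 significant digits: lossless at analysis precision


def write_session(session: Session, path: str | Path) -> Path:
    """Write a session directory readable by :func:`load_session`.

    Overwrites files already present at ``path``.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "id": session.session_id,
        "duration": session.duration,
        "region": session.region_label,
        "hemisphere": session.hemisphere,
    }
    (path / "session.json").write_text(json.dumps(meta, indent=1))
    session.trials.to_csv(path / "trials.csv", index=False, float_format=_FLOAT_FMT)

    unit_dir = path / "units"
    unit_dir.mkdir(exist_ok=True)
    for stale in unit_dir.iterdir():
        stale.unlink()
    for u in session.units:
        pd.DataFrame({"spike_time_s": u.spike_times}).to_csv(
            unit_dir / f"{u.unit_id}.csv", index=False, float_format=_FLOAT_FMT
        )
        umeta: dict = {"tetrode_id": u.tetrode_id}
        if u.waveform is not None:
            np.savetxt(
                unit_dir / f"{u.unit_id}.waveform.csv",
                u.waveform.samples, delimiter=",", fmt=_FLOAT_FMT,
            )
            umeta["waveform_sample_rate"] = u.waveform.sample_rate
        if u.evoked_waveform is not None:
            np.savetxt(
                unit_dir / f"{u.unit_id}.evoked.csv",
                np.atleast_2d(u.evoked_waveform), delimiter=",", fmt=_FLOAT_FMT,
            )
        (unit_dir / f"{u.unit_id}.meta.json").write_text(json.dumps(umeta))

    for name in ("laser.csv", "ecog.h5", "photometry.h5"):
        stale = path / name
        if stale.exists():
            stale.unlink()
    if session.laser is not None:
        pd.DataFrame(
            {
                "pulse_time_s": session.laser.pulse_times,
                "width_ms": session.laser.width_ms,
                "freq_hz": session.laser.freq_hz,
                "condition": session.laser.condition,
            }
        ).to_csv(path / "laser.csv", index=False, float_format=_FLOAT_FMT)
    if session.ecog is not None:
        with h5py.File(path / "ecog.h5", "w") as f:
            d = f.create_dataset("samples", data=session.ecog.samples)
            d.attrs["sample_rate"] = session.ecog.sample_rate
            d.attrs["t0"] = session.ecog.t0
    if session.photometry is not None:
        p = session.photometry
        with h5py.File(path / "photometry.h5", "w") as f:
            d = f.create_dataset("detector", data=p.detector)
            f.create_dataset("schedule", data=p.schedule)
            d.attrs["sample_rate"] = p.sample_rate
            d.attrs["frame_ms"] = p.frame_ms
            d.attrs["on_ms"] = p.on_ms
            d.attrs["off_ms"] = p.off_ms
            d.attrs["t0"] = p.t0
    return path


def _load_unit(unit_dir: Path, unit_id: str) -> SpikeTrain:
    df = pd.read_csv(unit_dir / f"{unit_id}.csv")
    if "spike_time_s" not in df.columns:
        raise LoadError(f"unit {unit_id}: spike_time_s missing")
    meta_path = unit_dir / f"{unit_id}.meta.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
    waveform = None
    wf_path = unit_dir / f"{unit_id}.waveform.csv"
    if wf_path.exists():
        samples = np.atleast_2d(np.loadtxt(wf_path, delimiter=","))
        sr = meta.get("waveform_sample_rate")
        if sr is None:  # derive from the fixed 2 ms analysis window
            sr = samples.shape[1] / WAVEFORM_WINDOW_S
        waveform = UnitWaveform(samples, float(sr))
    evoked = None
    ev_path = unit_dir / f"{unit_id}.evoked.csv"
    if ev_path.exists():
        evoked = np.atleast_2d(np.loadtxt(ev_path, delimiter=","))
    return SpikeTrain(
        unit_id=unit_id,
        spike_times=df["spike_time_s"].to_numpy(dtype=float),
        waveform=waveform,
        tetrode_id=int(meta.get("tetrode_id", 0)),
        evoked_waveform=evoked,
    )


def load_session(path: str | Path) -> Session:
    """Load and validate a session directory written by :func:`write_session`."""
    path = Path(path)
    meta_path = path / "session.json"
    if not meta_path.exists():
        raise LoadError("session.json missing")
    meta = json.loads(meta_path.read_text())
    trials_path = path / "trials.csv"
    if not trials_path.exists():
        raise LoadError("trials.csv missing")
    trials = pd.read_csv(trials_path)
    missing = [c for c in TRIAL_COLUMNS if c not in trials.columns]
    if missing:
        raise LoadError(f"trial table column(s) {', '.join(missing)} missing")

    units: list[SpikeTrain] = []
    unit_dir = path / "units"
    if unit_dir.exists():
        ids = sorted(
            p.stem for p in unit_dir.glob("*.csv")
            if not p.name.endswith((".waveform.csv", ".evoked.csv"))
        )
        units = [_load_unit(unit_dir, uid) for uid in ids]

    laser = None
    if (path / "laser.csv").exists():
        df = pd.read_csv(path / "laser.csv")
        for col in ("pulse_time_s", "width_ms", "freq_hz", "condition"):
            if col not in df.columns:
                raise LoadError(f"laser.csv: {col} missing")
        laser = LaserStimTable(
            df["pulse_time_s"].to_numpy(), df["width_ms"].to_numpy(),
            df["freq_hz"].to_numpy(), df["condition"].to_numpy(),
        )

    ecog = None
    if (path / "ecog.h5").exists():
        with h5py.File(path / "ecog.h5", "r") as f:
            d = f["samples"]
            ecog = ContinuousSignal(
                d[...], float(d.attrs["sample_rate"]), float(d.attrs.get("t0", 0.0))
            )

    photometry = None
    if (path / "photometry.h5").exists():
        with h5py.File(path / "photometry.h5", "r") as f:
            d = f["detector"]
            photometry = PhotometryRaw(
                detector=d[...],
                schedule=f["schedule"][...],
                sample_rate=float(d.attrs["sample_rate"]),
                frame_ms=float(d.attrs["frame_ms"]),
                on_ms=float(d.attrs["on_ms"]),
                off_ms=float(d.attrs["off_ms"]),
                t0=float(d.attrs.get("t0", 0.0)),
            )

    session = Session(
        session_id=str(meta["id"]),
        duration=float(meta["duration"]),
        trials=trials,
        units=units,
        laser=laser,
        ecog=ecog,
        photometry=photometry,
        region_label=meta.get("region"),
        hemisphere=meta.get("hemisphere"),
    )
    return validate_session(session)


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: dict = {
    "peth": {
        "window": [-1.0, 2.0],       # s relative to the aligning event
        "bin_width": 0.010,          # s
        "step": 0.005,               # s
        "n_shuffles": 10_000,
        "alpha": 0.005,
        "correction": "bonferroni",  # bonferroni | pointwise | maxstat
        "null_tail": None,           # gaussian | empirical (None -> per-mode default)
    },
    "tagging": {
        "alpha": 0.01,
        "reliability_window": 0.015,   # s after pulse onset
        "reliability_min": 0.25,
        "waveform_window": 0.010,      # s: evoked spikes for the waveform check
        "waveform_r_min": 0.9,
        "n_null": None,                # None -> matched to pulse count
        "duplicate_coincidence": 0.5,  # +/-1 ms zero-lag coincidence fraction
    },
    "metrics": {
        "isi_threshold": 2.0,     # s; long-ISI "not spiking" criterion
        "acg_max_lag": 0.200,     # s; autocorrelogram span
        "rate_range": [2.0, 10.0],
        "cv_max": 1.9,
        "suppression_min": 0.040,  # s
        "width_min": 0.0003,       # s
    },
    "sws": {
        "frame": 10.0,       # s
        "overlap": 0.5,
        "threshold": 3.0,
        "min_duration": 30.0,
    },
    "photometry": {
        "rate_out": 250.0,
        "median_filter": 5,
        "fit": "affine",     # affine | slope
    },
    "value": {
        "gamma_grid": [0.50, 1.00, 0.01],
        "prior": [1.0, 1.0],
        "alpha": 0.05,
        "epoch": [0.100, 0.250],   # s after Side In (reward-cue RPE epoch)
        "use_post_outcome": False,
    },
    "seed": 0,
}


def default_config() -> dict:
    return copy.deepcopy(DEFAULT_CONFIG)


def _merge_checked(base: dict, override: dict, prefix: str = "") -> dict:
    out = copy.deepcopy(base)
    for key, val in override.items():
        if key not in base:
            raise ValueError(f"unknown key '{prefix}{key}' in config")
        if isinstance(base[key], dict):
            if not isinstance(val, dict):
                raise ValueError(f"config key '{prefix}{key}' must be a mapping")
            out[key] = _merge_checked(base[key], val, prefix=f"{prefix}{key}.")
        else:
            out[key] = val
    return out


def _check_ranges(cfg: dict) -> None:
    for sect in ("peth", "tagging", "value"):
        a = cfg[sect]["alpha"]
        if not 0 < a < 1:
            raise ValueError(f"config {sect}.alpha out of range (0, 1)")
    if cfg["peth"]["bin_width"] <= 0 or cfg["peth"]["step"] <= 0:
        raise ValueError("config peth bin_width/step must be positive")
    if cfg["peth"]["n_shuffles"] < 1:
        raise ValueError("config peth.n_shuffles must be >= 1")
    if cfg["sws"]["min_duration"] < 0:
        raise ValueError("config sws.min_duration must be >= 0")


def load_config(path: str | Path | None = None) -> dict:
    """Resolve a YAML config file against the defaults.

    Unknown keys raise (no silent typo acceptance); unspecified keys take
    the defaults above. The resolved dict should be echoed into results
    files for provenance.
    """
    cfg = default_config()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a mapping")
        cfg = _merge_checked(cfg, raw)
    _check_ranges(cfg)
    return cfg
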