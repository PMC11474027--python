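"""End-to-end pipeline on a session directory, with manifest + provenance.

Stages run in dependency order (tag -> metrics -> sws -> peth ->
photometry -> value); a stage whose inputs are absent is skipped with a
logged warning.  Per-stage seeds are derived deterministically from the
master seed by stable hashing of the stage name, so reruns (also of
individual stages) reproduce bit-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .core_io import Session, default_config, load_session
from .event_stats import (
    compute_peth,
    onset_latency,
    selectivity_index,
    sensory_motor_label,
    shuffle_significance,
)
from .optotagging import classify_tagged, duplicate_check
from .photometry import align_dff, compute_dff, demultiplex, dff_significance
from .sleep_state import sws_epochs
from .unit_metrics import (
    UnitMetrics,
    basic_metrics,
    cin_enrichment_filter,
    postspike_suppression,
    waveform_metrics,
)
from .value_model import beta_value_series, fit_gamma, value_regression

log = logging.getLogger("cinda")

ALL_STAGES = ("tag", "metrics", "sws", "peth", "photometry", "value")

PETH_EVENTS = ("light_on", "go_cue", "center_out", "side_in", "food_in")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed (stable across runs and platforms)."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def _echo_cols(df: pd.DataFrame, cfg_peth: dict, seed: int) -> pd.DataFrame:
    df["alpha"] = cfg_peth["alpha"]
    df["n_shuffles"] = cfg_peth["n_shuffles"]
    df["correction"] = cfg_peth["correction"]
    df["seed"] = seed
    return df


def _contra_groups(session: Session) -> np.ndarray:
    contra_choice = "right" if session.hemisphere == "left" else "left"
    return np.where(
        session.trials["choice"] == contra_choice, "contra", "ipsi"
    )


def run_pipeline(
    session_path: str | Path,
    out_dir: str | Path,
    config: dict | None = None,
    stages: tuple[str, ...] = ALL_STAGES,
    seed: int = 0,
) -> dict:
    """Run the requested stages on a session directory; returns the manifest."""
    t_start = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = config or default_config()
    session = load_session(session_path)
    manifest: dict = {
        "session_id": session.session_id,
        "session_path": str(session_path),
        "config": cfg,
        "master_seed": seed,
        "stage_seeds": {s: stage_seed(seed, s) for s in ALL_STAGES},
        "stages_run": [],
        "outputs": {},
        "version": __version__,
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "config_used.yaml").write_text(yaml.safe_dump(cfg))
    summary: list[str] = []

    tagged_ids: list[str] = []
    sws_intervals: list[tuple[float, float]] | None = None

    if "tag" in stages:
        if session.laser is None:
            log.warning("tag stage skipped: no laser table")
        else:
            rows = []
            results = []
            tcfg = cfg["tagging"]
            for u in session.units:
                res = classify_tagged(
                    u, session.laser, session.duration,
                    n_null=tcfg["n_null"], seed=stage_seed(seed, "tag"),
                    alpha=tcfg["alpha"],
                    reliability_window=tcfg["reliability_window"],
                    reliability_min=tcfg["reliability_min"],
                    waveform_window=tcfg["waveform_window"],
                    waveform_r_min=tcfg["waveform_r_min"],
                )
                results.append(res)
                for cond, cs in res.conditions.items():
                    rows.append(
                        {
                            "unit": u.unit_id, "condition": cond,
                            "n_pulses": cs.n_pulses,
                            "latency_p": cs.latency_p,
                            "reliability": cs.reliability,
                            "tested": cs.tested, "row": "condition",
                            "tagged": "", "reason": "", "waveform_r": "",
                        }
                    )
                rows.append(
                    {
                        "unit": u.unit_id, "condition": "", "n_pulses": "",
                        "latency_p": "", "reliability": "", "tested": "",
                        "row": "summary", "tagged": res.tagged,
                        "reason": res.reason,
                        "waveform_r": res.waveform_r,
                    }
                )
            tagged_ids = [r.unit_id for r in results if r.tagged]
            tagged_units = [
                u for u in session.units if u.unit_id in tagged_ids
            ]
            dups = duplicate_check(
                tagged_units,
                coincidence_threshold=tcfg["duplicate_coincidence"],
            )
            pd.DataFrame(rows).to_csv(out / "tagging.csv", index=False)
            pd.DataFrame(dups).to_csv(out / "duplicates.csv", index=False)
            manifest["outputs"]["tagging"] = str(out / "tagging.csv")
            manifest["stages_run"].append("tag")
            summary.append(
                f"tagged units: {len(tagged_ids)}/{len(session.units)}"
                f" ({', '.join(tagged_ids) if tagged_ids else 'none'});"
                f" duplicate pairs flagged: {len(dups)}"
            )

    if "sws" in stages:
        if session.ecog is None:
            log.warning("sws stage skipped: no ECoG")
        else:
            scfg = cfg["sws"]
            res = sws_epochs(
                session.ecog, frame=scfg["frame"], overlap=scfg["overlap"],
                threshold=scfg["threshold"],
                min_duration=scfg["min_duration"],
            )
            sws_intervals = res.epochs
            pd.DataFrame(res.epochs, columns=["start", "end"]).to_csv(
                out / "sws.csv", index=False
            )
            pd.DataFrame(
                {"frame_time": res.frame_times, "k": res.k_series}
            ).to_csv(out / "k.csv", index=False)
            manifest["outputs"]["sws"] = str(out / "sws.csv")
            manifest["stages_run"].append("sws")
            total = sum(e - s for s, e in res.epochs)
            summary.append(
                f"SWS: {len(res.epochs)} epoch(s), {total:.0f} s total"
            )

    if "metrics" in stages:
        mcfg = cfg["metrics"]
        rows = []
        for u in session.units:
            state = "all"
            intervals = None
            if sws_intervals:
                state, intervals = "sws", sws_intervals
            elif session.ecog is None:
                log.info(
                    "metrics: no ECoG; CV computed over the whole session"
                )
            rate, cv, frac = basic_metrics(
                u.spike_times, duration=session.duration,
                state_intervals=intervals,
                isi_threshold=mcfg["isi_threshold"],
            )
            pss = postspike_suppression(
                u.spike_times, max_lag=mcfg["acg_max_lag"]
            )
            pw = ptv = None
            if u.waveform is not None:
                try:
                    pw, ptv = waveform_metrics(u.waveform)
                except ValueError:
                    pass
            m = UnitMetrics(
                mean_rate=rate, isi_cv=cv, frac_time_long_isi=frac,
                postspike_suppression=pss, peak_width=pw,
                peak_to_valley=ptv, state_restriction=state,
            )
            ok, reason = cin_enrichment_filter(
                m, rate_range=tuple(mcfg["rate_range"]),
                cv_max=mcfg["cv_max"],
                suppression_min=mcfg["suppression_min"],
                width_min=mcfg["width_min"],
            )
            rows.append(
                {
                    "unit": u.unit_id, "mean_rate": rate, "isi_cv": cv,
                    "frac_time_long_isi": frac,
                    "postspike_suppression_s": pss,
                    "peak_width_s": pw, "peak_to_valley_s": ptv,
                    "cin_filter": ok, "filter_reason": reason,
                    "state_restriction": state,
                }
            )
        pd.DataFrame(rows).to_csv(out / "metrics.csv", index=False)
        manifest["outputs"]["metrics"] = str(out / "metrics.csv")
        manifest["stages_run"].append("metrics")
        n_pass = sum(r["cin_filter"] for r in rows)
        summary.append(f"CIN-enrichment filter: {n_pass}/{len(rows)} pass")

    if "peth" in stages:
        pcfg = cfg["peth"]
        peth_rows, sig_rows, onset_rows, sel_rows = [], [], [], []
        sseed = stage_seed(seed, "peth")
        groups = _contra_groups(session) if session.hemisphere else None
        for u in session.units:
            for ev in PETH_EVENTS:
                ev_times = session.trials[ev].to_numpy(dtype=float)
                if not np.isfinite(ev_times).any():
                    continue
                try:
                    peth = compute_peth(
                        u.spike_times, ev_times,
                        window=tuple(pcfg["window"]),
                        bin_width=pcfg["bin_width"], step=pcfg["step"],
                        groups=groups,
                        session_duration=session.duration, align_event=ev,
                    )
                except ValueError:
                    continue
                sig = shuffle_significance(
                    u.spike_times, peth, session.duration,
                    n_shuffles=pcfg["n_shuffles"], alpha=pcfg["alpha"],
                    seed=sseed, correction=pcfg["correction"],
                    null_tail=pcfg["null_tail"],
                )
                for c, r in zip(peth.bin_centers, peth.mean_rate):
                    peth_rows.append(
                        {"unit": u.unit_id, "event": ev,
                         "bin_center": c, "rate": r}
                    )
                for c, u_f, d_f in zip(peth.bin_centers, sig.up, sig.down):
                    if u_f or d_f:
                        sig_rows.append(
                            {"unit": u.unit_id, "event": ev,
                             "bin_center": c,
                             "direction": "up" if u_f else "down"}
                        )
                for direction in ("up", "down"):
                    # first significant bin *following* the event
                    o = onset_latency(
                        sig, direction, peth.bin_centers, peth.bin_width,
                        search_window=(0.0, peth.window[1]),
                    )
                    onset_rows.append(
                        {"unit": u.unit_id, "event": ev,
                         "direction": direction, "onset": o.onset,
                         "offset": o.offset, "duration": o.duration}
                    )
                if groups is not None and ev in ("go_cue", "side_in"):
                    try:
                        si = selectivity_index(peth, (0.0, 0.5))
                    except ValueError:
                        si = np.nan
                    sel_rows.append(
                        {"unit": u.unit_id, "event": ev,
                         "selectivity_index": si}
                    )
        for name, rows in (
            ("peth.csv", peth_rows), ("sigmap.csv", sig_rows),
            ("onsets.csv", onset_rows), ("selectivity.csv", sel_rows),
        ):
            df = _echo_cols(pd.DataFrame(rows), pcfg, sseed)
            df.to_csv(out / name, index=False)
            manifest["outputs"][name] = str(out / name)
        sm_rows = []
        for u in session.units:
            for comp in ("burst", "pause", "rebound"):
                res = sensory_motor_label(
                    u.spike_times, session.trials, comp, session.duration,
                    n_shuffles=pcfg["n_shuffles"], alpha=pcfg["alpha"],
                    seed=sseed, correction=pcfg["correction"],
                )
                if res is not None:
                    sm_rows.append(
                        {"unit": u.unit_id, "component": comp,
                         "ratio": res[0], "label": res[1]}
                    )
        _echo_cols(pd.DataFrame(sm_rows), pcfg, sseed).to_csv(
            out / "sensorimotor.csv", index=False
        )
        manifest["stages_run"].append("peth")
        n_resp = len({r["unit"] for r in sig_rows})
        summary.append(
            f"peri-event stats: {n_resp}/{len(session.units)} units with"
            f" significant modulation; onsets written for"
            f" {len(onset_rows)} unit x event x direction cells"
        )

    dff = None
    if "photometry" in stages:
        if session.photometry is None:
            log.warning("photometry stage skipped: no photometry data")
        else:
            phcfg = cfg["photometry"]
            pcfg = cfg["peth"]
            sig470, sig405 = demultiplex(
                session.photometry, grid_rate=phcfg["rate_out"]
            )
            dff = compute_dff(
                sig470, sig405, fit=phcfg["fit"],
                median_filter=phcfg["median_filter"],
            )
            pd.DataFrame({"t": dff.times, "dff_z": dff.samples}).to_csv(
                out / "dff.csv", index=False
            )
            sig = dff_significance(
                dff, session.trials["side_in"].to_numpy(dtype=float),
                window=tuple(pcfg["window"]),
                n_shuffles=pcfg["n_shuffles"], alpha=pcfg["alpha"],
                seed=stage_seed(seed, "photometry"),
                correction=pcfg["correction"], null_tail=pcfg["null_tail"],
            )
            n_sig = int(sig.up.sum() + sig.down.sum())
            manifest["outputs"]["dff"] = str(out / "dff.csv")
            manifest["stages_run"].append("photometry")
            summary.append(
                f"photometry: dF/F over {dff.duration:.0f} s;"
                f" {n_sig} significant samples around Side In"
            )

    if "value" in stages:
        vcfg = cfg["value"]
        trials = session.trials
        try:
            gamma_star, profile = fit_gamma(
                trials,
                grid=np.round(
                    np.arange(
                        vcfg["gamma_grid"][0],
                        vcfg["gamma_grid"][1] + 1e-9,
                        vcfg["gamma_grid"][2],
                    ), 10,
                ),
                prior=tuple(vcfg["prior"]),
                use_post_outcome=vcfg["use_post_outcome"],
            )
        except ValueError as e:
            log.warning("value stage skipped: %s", e)
            gamma_star = None
        if gamma_star is not None:
            values = beta_value_series(
                trials, gamma_star, prior=tuple(vcfg["prior"])
            )
            pd.DataFrame(
                {
                    "trial": np.arange(len(values)),
                    "alpha": values.alpha, "beta": values.beta,
                    "V": values.V, "tercile": values.tercile,
                }
            ).to_csv(out / "values.csv", index=False)
            (out / "gamma_fit.json").write_text(
                json.dumps(
                    {
                        "gamma_star": gamma_star,
                        "profile": profile.to_dict(orient="list"),
                    }
                )
            )
            reg_rows = []
            e0, e1 = vcfg["epoch"]
            rewarded = trials["outcome"].to_numpy() == 1
            side_in = trials["side_in"].to_numpy(dtype=float)
            for u in session.units:
                counts = (
                    np.searchsorted(u.spike_times, side_in + e1)
                    - np.searchsorted(u.spike_times, side_in + e0)
                )
                rates = counts / (e1 - e0)
                try:
                    rr = value_regression(
                        rates, values, scope="epoch",
                        trial_filter=rewarded, alpha=vcfg["alpha"],
                    )
                except ValueError as e:
                    log.info("regression skipped for %s: %s", u.unit_id, e)
                    continue
                reg_rows.append(
                    {
                        "unit": u.unit_id, "epoch_start": e0,
                        "epoch_end": e1,
                        "coefficient": rr.coefficient,
                        "p_value": rr.p_value,
                        "significant": rr.significant, "sign": rr.sign,
                        "rpe_consistent": rr.significant
                        and rr.sign == "negative",
                    }
                )
            pd.DataFrame(reg_rows).to_csv(
                out / "regressions.csv", index=False
            )
            manifest["outputs"]["values"] = str(out / "values.csv")
            manifest["stages_run"].append("value")
            n_rpe = sum(r["rpe_consistent"] for r in reg_rows)
            summary.append(
                f"value model: gamma* = {gamma_star:.2f};"
                f" RPE-consistent units (neg. slope, p<{vcfg['alpha']}):"
                f" {n_rpe}/{len(reg_rows)}"
            )

    manifest["elapsed_s"] = round(time.time() - t_start, 3)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    (out / "summary.txt").write_text(
        "\n".join([f"session {session.session_id}"] + summary) + "\n"
    )
    return manifest
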