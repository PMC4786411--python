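"""End-to-end orchestration on synthetic inputs.

``run_pipeline`` generates every input from the config's synthesis block,
runs the enabled stages (preprocess -> select -> spatial -> dynamics ->
geometry -> psi -> strf) and returns a single JSON-serializable report with
per-stage results alongside the planted ground truth, so recovery can be
checked directly.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from . import dynamics as dyn
from . import geometry as geo
from . import preprocess as pre
from . import psi as psi_mod
from . import selection as sel
from . import spatial as spa
from . import strf as strf_mod
from . import synth
from .config import AnalysisConfig
from .core import EventTable, get_logger
from .errors import ParameterError

log = get_logger("amecog.pipeline")

__all__ = ["run_pipeline", "make_demo_config"]


def _stage_seeds(seed: int) -> dict:
    names = ["synth_raw", "synth_evoked", "positions", "phonemes", "strf_data",
             "select", "spatial", "dynamics", "geometry", "psi", "strf_fit"]
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return {n: int(s.generate_state(1)[0] % (2**31)) for n, s in zip(names, ss)}


def _mixed_task_events(cfg_raw: dict, seed: int) -> EventTable:
    n_l, n_s = cfg_raw["n_listen_events"], cfg_raw["n_speak_events"]
    listen = synth.make_syllable_events(
        n_trials=max(1, n_l // 8), task="listen", start_s=2.0, seed=seed)
    speak = synth.make_syllable_events(
        n_trials=max(1, n_s // 8), task="speak",
        start_s=float(listen.df["offset_s"].iloc[-1]) + 2.0, seed=seed + 1)
    return EventTable(pd.concat([listen.df, speak.df], ignore_index=True))


def run_pipeline(config: AnalysisConfig) -> dict:
    """Run all enabled stages; returns (and optionally writes) the report."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    report: dict = {"seed": config.seed, "stages": list(config.stages)}
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    # ----- synthetic inputs ------------------------------------------------
    raw_cfg = dict(config.synth["raw"])
    events = _mixed_task_events(raw_cfg, seeds["synth_raw"])
    need = float(events.df["offset_s"].max()) + 2.0
    duration = max(float(raw_cfg["duration_s"]), need)
    rec, raw_gt = synth.generate_raw_recording(
        n_channels=raw_cfg["n_channels"], duration_s=duration, fs=raw_cfg["fs"],
        events=events, line_amp=raw_cfg["line_amp"],
        bank_noise_sd=raw_cfg["bank_noise_sd"], burst_snr=raw_cfg["burst_snr"],
        noise_sd=raw_cfg["noise_sd"], bank_size=raw_cfg["bank_size"],
        bad_channel=raw_cfg.get("bad_channel"), seed=seeds["synth_raw"],
    )

    ev_cfg = config.synth["evoked"]
    listen_ds, listen_el, listen_gt = synth.generate_evoked_dataset(
        ev_cfg["listen_regions"], mode="manner", n_trials=ev_cfg["n_trials"],
        latency_map=ev_cfg.get("latency_map"), noise_sd=ev_cfg["noise_sd"],
        seed=seeds["synth_evoked"], task="listen",
    )
    speak_ds, _, speak_gt = synth.generate_evoked_dataset(
        ev_cfg["speak_regions"], mode="place", n_trials=ev_cfg["n_trials"],
        latency_map=ev_cfg.get("latency_map"), noise_sd=ev_cfg["noise_sd"],
        seed=seeds["synth_evoked"] + 1, task="speak",
    )

    # ----- preprocess ------------------------------------------------------
    hg = None
    if "preprocess" in config.stages:
        p = config.preprocess
        hg, bad = pre.preprocess_recording(
            rec, events=events, notch_freqs=tuple(p["notch_freqs"]),
            bad_threshold_sd=p["bad_threshold_sd"], band=tuple(p["band"]),
            n_filters=p["n_filters"], fs_out=p["fs_out"],
        )
        planted_bad = raw_cfg.get("bad_channel")
        report["preprocess"] = {
            "n_channels": rec.n_channels,
            "rejected_channels": sorted(bad),
            "planted_bad_channel": (
                f"ch{planted_bad:03d}" if planted_bad is not None else None
            ),
        }

    # ----- electrode selection --------------------------------------------
    if "select" in config.stages:
        if hg is None:
            raise ParameterError("select stage requires preprocess")
        s = config.selection
        selection = sel.select_sites(
            hg, events, alpha=s["alpha"], stim_window=tuple(s["stim_window"]),
            base_window=tuple(s["base_window"]), n_boot=s["n_boot"],
            seed=seeds["select"],
        )
        responsive = {f"ch{c:03d}" for c in raw_gt.extra["responsive_channels"]}
        flagged = set(selection.active("both"))
        testable = [
            cid for cid in rec.channel_ids
            if not np.isnan(selection.table.set_index("id").loc[cid, "p_listen"])
        ]
        hits = sum(1 for c in testable if (c in responsive) == (c in flagged))
        report["select"] = {
            "n_active_listen": len(selection.active("listen")),
            "n_active_speak": len(selection.active("speak")),
            "n_active_both": len(flagged),
            "n_planted_responsive": len(responsive),
            "accuracy_vs_ground_truth": hits / max(len(testable), 1),
        }
        if out_dir:
            selection.table.to_csv(out_dir / "selection.csv", index=False)

    # ----- spatial clustering ---------------------------------------------
    if "spatial" in config.stages:
        pos_cfg = config.synth["positions"]
        electrodes = synth.generate_electrode_positions(
            pos_cfg["n"], pos_cfg["centers"], pos_cfg["spread_mm"],
            seed=seeds["positions"],
        )
        sp = config.spatial
        clustered, pvals = spa.dip_means_is_clustered(
            electrodes, alpha=sp["alpha"], n_boot=sp["n_boot"],
            seed=seeds["spatial"],
        )
        entry = {"clustered": bool(clustered),
                 "min_viewer_p": float(np.min(pvals)),
                 "n_planted_centers": len(pos_cfg["centers"])}
        if clustered:
            best_k, silhouettes, _ = spa.select_k(
                electrodes, k_range=range(sp["k_min"], sp["k_max"] + 1),
                seed=seeds["spatial"],
            )
            entry["best_k"] = int(best_k)
            entry["silhouettes"] = {str(k): float(v) for k, v in silhouettes.items()}
        report["spatial"] = entry

    # ----- latency & lead-lag dynamics ------------------------------------
    if "dynamics" in config.stages:
        d = config.dynamics
        rows = []
        for e, eid in enumerate(listen_ds.electrode_ids):
            trials = listen_ds.responses[e].reshape(-1, listen_ds.time_axis.size)
            onset = dyn.onset_latency(trials, listen_ds.time_axis,
                                      alpha=d["onset_alpha"])
            peak, _ = dyn.peak_latency(trials.mean(axis=0), listen_ds.time_axis)
            rows.append({"id": eid, "region": listen_gt.electrodes[eid]["region"],
                         "latency_ms": onset, "peak_ms": peak})
        lat = pd.DataFrame(rows)
        comparisons = dyn.compare_latencies(lat)
        stg = [i for i, r in enumerate(lat["region"]) if r == "STG"]
        vsmc = [i for i, r in enumerate(lat["region"]) if r.startswith("vSMC")]
        indices = []
        rng = np.random.default_rng(seeds["dynamics"])
        pairs = [(i, j) for i in stg for j in vsmc]
        if len(pairs) > d["max_pairs"]:
            pairs = [pairs[k] for k in
                     rng.choice(len(pairs), d["max_pairs"], replace=False)]
        for i, j in pairs:
            x = listen_ds.responses[i].reshape(-1, listen_ds.time_axis.size)
            y = listen_ds.responses[j].reshape(-1, listen_ds.time_axis.size)
            xc = dyn.cross_correlogram(x, y, fs=listen_ds.fs,
                                       max_lag=d["max_lag"],
                                       time_axis=listen_ds.time_axis)
            ai = dyn.asymmetry_index(xc)
            if ai is not None:
                indices.append(ai)
        med = lat.dropna(subset=["latency_ms"]).groupby("region")["latency_ms"].median()
        report["dynamics"] = {
            "median_onset_ms": {r: float(v) for r, v in med.items()},
            "comparisons": comparisons.to_dict(orient="records"),
            "asymmetry": dyn.classify_lead_lag(indices, band=d["coactive_band"]),
            "mean_asymmetry_index": float(np.mean(indices)),
        }

    # ----- representational geometry --------------------------------------
    if "geometry" in config.stages:
        g = config.geometry
        entry = {}
        for name, ds in (("listen", listen_ds), ("speak", speak_ds)):
            trm = geo.token_means(ds, window=tuple(g["window"]))
            ri_manner = geo.cluster_agreement(trm, "manner", k=g["k"],
                                              seed=seeds["geometry"])
            ri_place = geo.cluster_agreement(trm, "place", k=g["k"],
                                             seed=seeds["geometry"])
            _, stress = geo.mds_embed(geo.distance_matrix(trm),
                                      seed=seeds["geometry"])
            entry[name] = {
                "ri_adj_manner": float(ri_manner),
                "ri_adj_place": float(ri_place),
                "delta_ri": float(ri_manner - ri_place),
                "recovered_mode": "manner" if ri_manner > ri_place else "place",
                "mds_stress": float(stress),
            }
        if g.get("trajectory"):
            traj = geo.delta_ri_trajectory(
                listen_ds, window_len=g["window_len"], step=g["step"],
                n_perm=g["n_perm"], q=g["q"], seed=seeds["geometry"],
            )
            entry["trajectory"] = {
                "n_windows": int(traj["delta_ri"].size),
                "n_significant": int(traj["significant"].sum()),
            }
        report["geometry"] = entry

    # ----- phoneme selectivity --------------------------------------------
    if "psi" in config.stages:
        ph_cfg = config.synth["phonemes"]
        deviant = synth.PHONEMES_33[0]
        profile = {p: (ph_cfg["deviant_mean"] if p == deviant else 0.0)
                   for p in synth.PHONEMES_33}
        trials, _ = synth.generate_phoneme_dataset(
            profile, n_trials=ph_cfg["n_trials"], seed=seeds["phonemes"])
        null_trials, _ = synth.generate_phoneme_dataset(
            {p: 0.0 for p in synth.PHONEMES_33},
            n_trials=ph_cfg["n_trials"], seed=seeds["phonemes"] + 1)
        pv = psi_mod.psi_vector(trials, alpha=config.psi["alpha"],
                                correction=config.psi["correction"])
        pv_null = psi_mod.psi_vector(null_trials, alpha=config.psi["alpha"],
                                     correction=config.psi["correction"])
        report["psi"] = {
            "deviant_phoneme": deviant,
            "deviant_psi": int(pv.as_dict()[deviant]),
            "max_psi_selective_electrode": int(pv.psi.max()),
            "max_psi_null_electrode": int(pv_null.psi.max()),
        }

    # ----- STRF ------------------------------------------------------------
    if "strf" in config.stages:
        st_cfg = config.synth["strf"]
        H_true = synth.make_true_strf(st_cfg["n_delays"], st_cfg["n_freqs"],
                                      seed=seeds["strf_data"])
        spec, resp = synth.generate_strf_dataset(
            H_true, n_samples=st_cfg["n_samples"],
            noise_sd=st_cfg["noise_sd"], seed=seeds["strf_data"])
        model = strf_mod.fit_strf_cv(
            spec, resp, n_delays=st_cfg["n_delays"],
            n_folds=config.strf["n_folds"], criterion=config.strf["criterion"],
            sparseness_grid=tuple(config.strf["sparseness_grid"]),
            seed=seeds["strf_fit"],
        )
        model.p_value = strf_mod.strf_significance(
            model, spec, resp, n_perm=config.strf["n_perm"],
            seed=seeds["strf_fit"])
        h_corr = float(np.corrcoef(model.H.ravel(), H_true.ravel())[0, 1])
        report["strf"] = {
            "cv_correlation": float(model.cv_correlation),
            "h_correlation_vs_truth": h_corr,
            "p_value": float(model.p_value),
            "significant": bool(model.cv_correlation >= 0.10
                                and model.p_value < 0.01),
            "ridge": float(model.ridge),
            "sparseness": float(model.sparseness),
        }

    if out_dir:
        with open(out_dir / "report.json", "w") as f:
            json.dump(report, f, indent=1, sort_keys=True)
    return report


def make_demo_config(out_dir, seed: int = 42) -> Path:
    """Write a self-contained desk-scale config exercising every stage."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cfg = AnalysisConfig(seed=seed, out_dir=str(out_dir))
    cfg.validate()
    path = out_dir / "config.yaml"
    cfg.to_yaml(path)
    return path
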