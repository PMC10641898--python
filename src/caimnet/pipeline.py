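"""End-to-end orchestration: simulate (or load) -> bouts -> events ->
modulation -> connectivity -> networks -> report, with one config, seeded
RNGs, and a manifest of everything written."""

from __future__ import annotations

import copy
import json
import logging
import time
from dataclasses import asdict
from pathlib import Path

import numpy as np

from . import io
from .behavior import RUN, REST, bout_kinematics, segment_bouts, session_qc
from .connectivity import classify_session, subgroup_means
from .events import DetectorParams, annotate_metrics, detect_events, event_rate
from .modulation import binarize, classify_cells
from .network import build_graph, centrality_difference, closeness
from .stats import build_report
from .synthetic import SimConfig, simulate_speed, simulate_traces

log = logging.getLogger("caimnet")

DEFAULT_CONFIG: dict = {
    "paths": {
        "traces": None,  # delimited trace table (time_s, cell_0, ...)
        "centroids": None,
        "speed": None,  # delimited speed table (t, v)
        "out_dir": "caimnet_out",
    },
    "simulate": None,  # SimConfig fields; presence requests simulation
    "behavior": {
        "fuzzy_a": 0.8,
        "smooth_s": 1.5,
        "frac_thresh": 0.10,
        "min_bout_s": 2.0,
        "theta_deg": 78.0,
    },
    "events": {},  # DetectorParams overrides
    "modulation": {"n_shuffles": 1000},
    "correlation": {"n_shuffles": 2000, "scopes": ["rest", "run", "session"]},
    "network": {"log_base": "e"},
    "seeds": {"simulation": 0, "modulation": 1, "correlation": 2},
    "fs": 20.0,
}


def validate_config(config: dict | None) -> dict:
    """Inject defaults and range-check; unknown keys are errors."""
    config = copy.deepcopy(config) if config else {}
    out = copy.deepcopy(DEFAULT_CONFIG)

    def merge(dst: dict, src: dict, prefix: str) -> None:
        for key, val in src.items():
            if key not in dst:
                raise ValueError(f"unknown config key: {prefix}{key}")
            if isinstance(dst[key], dict) and isinstance(val, dict):
                merge(dst[key], val, prefix=f"{prefix}{key}.")
            else:
                dst[key] = val

    sim = config.pop("simulate", None)
    merge(out, config, prefix="")
    if sim is not None:
        valid = set(SimConfig().__dataclass_fields__)
        unknown = set(sim) - valid
        if unknown:
            raise ValueError(f"unknown simulate keys: {sorted(unknown)}")
        out["simulate"] = sim
    for section, key in (("modulation", "n_shuffles"), ("correlation", "n_shuffles")):
        if out[section][key] < 1:
            raise ValueError(f"{section}.{key} must be a positive integer")
    if out["behavior"]["min_bout_s"] <= 0:
        raise ValueError("behavior.min_bout_s must be positive")
    if not 0.0 < out["behavior"]["theta_deg"] < 180.0:
        raise ValueError("behavior.theta_deg must lie in (0, 180)")
    if out["network"]["log_base"] not in ("e", "10"):
        raise ValueError("network.log_base must be 'e' or '10'")
    return out


def run_all(config: dict | None) -> Path:
    """Run every requested stage; returns the output directory.

    Each stage logs its timing and headline counts; artifacts are written
    as delimited text/JSON and indexed in ``manifest.json`` with SHA-256
    hashes, parameters and seeds.
    """
    cfg = validate_config(config)
    out_dir = Path(cfg["paths"]["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    fs = cfg["fs"]
    manifest: dict = {"config": cfg, "outputs": {}, "stages": {}}

    def _stage(name):
        t0 = time.perf_counter()

        def done(**counts):
            manifest["stages"][name] = {
                "seconds": round(time.perf_counter() - t0, 3), **counts}
            log.info("stage %s done in %.2fs %s", name,
                     time.perf_counter() - t0, counts)

        return done

    def _write(name, fn, *args):
        path = out_dir / name
        fn(path, *args)
        manifest["outputs"][name] = io.sha256_file(path)

    # --- inputs: simulate or load -------------------------------------
    done = _stage("input")
    if cfg["simulate"] is not None:
        sim = SimConfig(**{**cfg["simulate"], "seed": cfg["seeds"]["simulation"]})
        speed, true_bouts = simulate_speed(sim)
        traces, truth = simulate_traces(sim, true_bouts)
        _write("speed.tsv", io.write_speed, speed)
        _write("traces.tsv", io.write_traces, traces)
        _write("centroids.tsv", io.write_centroids, traces)
        _write("ground_truth.json", io.write_json, {
            "true_bouts": truth.true_bouts,
            "true_modulated": truth.true_modulated,
            "true_correlated_pairs": truth.true_correlated_pairs,
            "true_event_onsets": [o for o in truth.true_event_onsets],
            "sim_config": asdict(sim),
        })
    else:
        if not cfg["paths"]["traces"] or not cfg["paths"]["speed"]:
            raise ValueError("need paths.traces and paths.speed unless simulating")
        speed = io.read_speed(cfg["paths"]["speed"], fs=fs)
        traces = io.read_traces(cfg["paths"]["traces"],
                                cfg["paths"]["centroids"], fs=fs)
    done(n_cells=len(traces), n_samples=speed.n_samples)

    # --- behavior ------------------------------------------------------
    done = _stage("behavior")
    b = cfg["behavior"]
    seg = segment_bouts(speed, a=b["fuzzy_a"], smooth_s=b["smooth_s"],
                        frac_thresh=b["frac_thresh"], min_s=b["min_bout_s"])
    qc = session_qc(seg)
    kin = bout_kinematics(speed, seg)
    _write("bouts.tsv", io.write_bouts, seg)
    done(n_run_bouts=qc.n_run_bouts, eligible=qc.eligible_for_locomotion_analysis)

    # --- events ---------------------------------------------------------
    done = _stage("events")
    params = DetectorParams(**cfg["events"])
    events_by_cell = {}
    for tr in traces:
        evs = detect_events(tr.values, fs=fs, params=params)
        annotate_metrics(evs, tr.values, fs=fs)
        events_by_cell[tr.cell_id] = evs
    _write("events.tsv", io.write_events, events_by_cell, fs)
    done(n_events=sum(len(v) for v in events_by_cell.values()))

    # --- modulation ------------------------------------------------------
    done = _stage("modulation")
    n = speed.n_samples
    trains = [binarize(n, events_by_cell[tr.cell_id], cell_id=tr.cell_id)
              for tr in traces]
    mod_results = []
    if qc.eligible_for_locomotion_analysis:
        rng = np.random.default_rng(cfg["seeds"]["modulation"])
        mod_results = classify_cells(
            trains, seg, n_shuffles=cfg["modulation"]["n_shuffles"], rng=rng)
        _write("modulation.tsv", _write_modulation, mod_results)
    done(n_modulated=sum(m.is_modulated for m in mod_results))

    # --- connectivity and networks ---------------------------------------
    done = _stage("connectivity")
    centroids = np.array([tr.centroid for tr in traces])
    rng = np.random.default_rng(cfg["seeds"]["correlation"])
    pair_results, fractions, graphs = {}, {}, {}
    scopes = cfg["correlation"]["scopes"]
    if not qc.eligible_for_locomotion_analysis:
        scopes = [s for s in scopes if s == "session"]
    for scope in scopes:
        pairs, frac = classify_session(
            trains, centroids, seg, scope=scope,
            n_shuffles=cfg["correlation"]["n_shuffles"], rng=rng)
        pair_results[scope] = pairs
        fractions[scope] = frac
        _write(f"pairs_{scope}.tsv", io.write_pairs, pairs)
        if scope in (REST, RUN):
            g = build_graph(pairs, nodes=[tr.cell_id for tr in traces], state=scope)
            graphs[scope] = g
            _write(f"graph_{scope}.tsv", io.write_edge_list, g)
    cent_diff = None
    log_base = cfg["network"]["log_base"]
    if REST in graphs and RUN in graphs:
        cent = {s: closeness(graphs[s], log_base=log_base) for s in (REST, RUN)}
        cent_diff = centrality_difference(cent[REST], cent[RUN])
        for s in (REST, RUN):
            _write(f"centrality_{s}.tsv", _write_centrality, cent[s])
    subgroups = None
    if mod_results and "session" in pair_results:
        subgroups = subgroup_means(pair_results["session"], mod_results, trains, seg)
        _write("subgroup_means.tsv",
               lambda p, df: df.to_csv(p, sep="\t", index=False), subgroups)
    done(**{f"fraction_{k}": (None if np.isnan(v) else round(v, 4))
            for k, v in fractions.items()})

    # --- report -----------------------------------------------------------
    done = _stage("report")
    session_summary = {
        "group": "session",
        "kinematics": kin,
        "n_cells": len(traces),
        "n_modulated": sum(m.is_modulated for m in mod_results),
        "pair_fractions": {k: (None if np.isnan(v) else v)
                           for k, v in fractions.items()},
        "centrality_difference": cent_diff,
    }
    if qc.eligible_for_locomotion_analysis:
        session_summary["event_rate_rest"] = float(np.mean([
            event_rate(events_by_cell[t.cell_id], seg, REST) for t in traces]))
        session_summary["event_rate_run"] = float(np.mean([
            event_rate(events_by_cell[t.cell_id], seg, RUN) for t in traces]))
    report = build_report([session_summary])
    report["session"] = session_summary
    report["qc"] = asdict_qc(qc)
    _write("report.json", io.write_json, report)
    _write("manifest.json", io.write_json, manifest)
    done()
    return out_dir


def asdict_qc(qc) -> dict:
    return {
        "time_in_rest_s": qc.time_in_rest_s,
        "time_in_run_s": qc.time_in_run_s,
        "n_run_bouts": qc.n_run_bouts,
        "eligible": qc.eligible_for_locomotion_analysis,
    }


def _write_modulation(path, results) -> None:
    import pandas as pd

    pd.DataFrame([{
        "cell_id": m.cell_id, "A_obs": m.A_obs, "threshold": m.threshold,
        "is_modulated": m.is_modulated,
    } for m in results]).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_centrality(path, result) -> None:
    import pandas as pd

    pd.DataFrame({
        "cell_id": result.nodes, "A_i": result.A, "C_i": result.C,
        "c_i": result.c,
    }).to_csv(path, sep="\t", index=False, float_format="%.6g")


def load_config(path) -> dict:
    return validate_config(json.loads(Path(path).read_text()))
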