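"""Readers and writers for the pipeline's plain-text artifacts.

Traces, bouts, events and pair tables travel as tab-separated text;
graphs as weighted edge lists (plus optional GraphML); reports and
manifests as JSON.  Video goes through multi-page TIFF via tifffile.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .behavior import BoutSegmentation, SpeedTrace
from .connectivity import PairResult
from .events import CalciumEvent
from .imaging import FluorescenceTrace


def write_speed(path, speed: SpeedTrace) -> None:
    pd.DataFrame({"t": speed.t, "v": speed.v}).to_csv(path, sep="\t", index=False)


def read_speed(path, fs: float = 20.0) -> SpeedTrace:
    df = pd.read_csv(path, sep="\t")
    return SpeedTrace(df["t"].to_numpy(), df["v"].to_numpy(), fs=fs)


def read_sensors(path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    df = pd.read_csv(path, sep="\t")
    return df["t"].to_numpy(), df["L"].to_numpy(), df["R"].to_numpy()


def write_traces(path, traces: list[FluorescenceTrace]) -> None:
    n = traces[0].values.size
    fs = traces[0].fs
    cols = {"time_s": np.arange(n) / fs}
    for tr in traces:
        cols[f"cell_{tr.cell_id}"] = tr.values
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_centroids(path, traces: list[FluorescenceTrace]) -> None:
    rows = [{"cell_id": tr.cell_id, "x": tr.centroid[0], "y": tr.centroid[1]}
            for tr in traces]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_traces(path, centroids_path=None, fs: float = 20.0) -> list[FluorescenceTrace]:
    df = pd.read_csv(path, sep="\t")
    cents = {}
    if centroids_path is not None:
        cdf = pd.read_csv(centroids_path, sep="\t")
        cents = {int(r.cell_id): (float(r.x), float(r.y)) for r in cdf.itertuples()}
    out = []
    for col in df.columns:
        if col.startswith("cell_"):
            cid = int(col.split("_", 1)[1])
            out.append(FluorescenceTrace(
                cell_id=cid, values=df[col].to_numpy(),
                centroid=cents.get(cid, (0.0, 0.0)), fs=fs,
            ))
    return out


def write_bouts(path, seg: BoutSegmentation) -> None:
    rows = [{"start_s": s / seg.fs, "end_s": e / seg.fs, "label": lab}
            for s, e, lab in seg.intervals]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_bouts(path, n_samples: int, fs: float = 20.0) -> BoutSegmentation:
    df = pd.read_csv(path, sep="\t")
    intervals = [
        (int(round(r.start_s * fs)), int(round(r.end_s * fs)), str(r.label))
        for r in df.itertuples()
    ]
    return BoutSegmentation(intervals, n_samples=n_samples, fs=fs)


def write_events(path, events_by_cell: dict[int, list[CalciumEvent]],
                 fs: float = 20.0) -> None:
    rows = []
    for cid, events in events_by_cell.items():
        for ev in events:
            rows.append({
                "cell_id": cid,
                "t_on_s": ev.t_on / fs,
                "t_peak_s": ev.t_peak / fs,
                "amplitude": ev.amplitude,
                "rise_s": ev.rise_time_s,
                "fwhm_s": "" if ev.fwhm_s is None else ev.fwhm_s,
                "fwhm_excluded_reason": ev.fwhm_excluded_reason,
            })
    pd.DataFrame(
        rows,
        columns=["cell_id", "t_on_s", "t_peak_s", "amplitude", "rise_s",
                 "fwhm_s", "fwhm_excluded_reason"],
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_pairs(path, pairs: list[PairResult]) -> None:
    rows = [{
        "i": p.i, "j": p.j, "scope": p.scope, "r": p.r, "null_p95": p.null_p95,
        "klass": p.klass, "distance_um": p.centroid_distance_um,
    } for p in pairs]
    pd.DataFrame(
        rows, columns=["i", "j", "scope", "r", "null_p95", "klass", "distance_um"]
    ).to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_edge_list(path, g: nx.Graph) -> None:
    rows = [{"i": i, "j": j, "w": d["weight"]} for i, j, d in g.edges(data=True)]
    pd.DataFrame(rows, columns=["i", "j", "w"]).to_csv(
        path, sep="\t", index=False, float_format="%.9g"
    )


def write_graphml(path, g: nx.Graph) -> None:
    nx.write_graphml(g, path)


def write_json(path, obj) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
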