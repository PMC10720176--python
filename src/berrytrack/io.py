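"""File formats: detection/track CSVs, tree and metrics JSON, manifests.

All CSVs are comma-separated, UTF-8, "."-decimal, with a header row.
The detection record is one row per segmented berry per frame; tracks
add a ``label`` column (-1 = unlabeled).  The matching tree and metric
reports are JSON.  Every pipeline run writes a manifest recording the
resolved configuration, seed and package version, so identical
manifests imply identical outputs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from berrytrack.features import BerryObservation
from berrytrack.geometry import Ellipse
from berrytrack.tracking import FrameSet, MatchingTree

DETECTION_COLUMNS = ["frame", "time_days", "berry_id", "x_e", "y_e", "w_e",
                     "h_e", "a_e", "score", "h_raw", "H", "A_px2", "V_px3", "V_mL"]


def series_to_frame(series: list[FrameSet]) -> pd.DataFrame:
    """Detections table (one row per observation) from a frame series."""
    rows = []
    for fs in series:
        for k, o in enumerate(fs.observations):
            e = o.ellipse
            rows.append({
                "frame": fs.t, "time_days": o.time, "berry_id": k,
                "x_e": e.x_e, "y_e": e.y_e, "w_e": e.w_e, "h_e": e.h_e,
                "a_e": e.a_e, "score": o.score, "h_raw": o.h_raw, "H": o.H,
                "A_px2": o.A, "V_px3": o.V, "V_mL": o.V_mL,
            })
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def frame_to_series(df: pd.DataFrame) -> list[FrameSet]:
    """Rebuild a frame series from a detections (or tracks) table."""
    series = []
    for t, grp in df.sort_values(["frame", "berry_id"]).groupby("frame"):
        obs = []
        for _, r in grp.iterrows():
            o = BerryObservation(
                frame=int(r["frame"]), time=float(r["time_days"]),
                ellipse=Ellipse(r["x_e"], r["y_e"], r["w_e"], r["h_e"], r["a_e"]),
                score=float(r["score"]),
                h_raw=None if pd.isna(r.get("h_raw")) else float(r["h_raw"]),
                H=None if pd.isna(r.get("H")) else float(r["H"]),
                A=None if pd.isna(r.get("A_px2")) else float(r["A_px2"]),
                V=None if pd.isna(r.get("V_px3")) else float(r["V_px3"]),
                V_mL=None if pd.isna(r.get("V_mL")) else float(r["V_mL"]),
            )
            if "label" in grp.columns:
                o.label = int(r["label"])
            obs.append(o)
        series.append(FrameSet(t=int(t), observations=obs,
                               time_days=float(grp["time_days"].iloc[0])))
    return series


def write_detections_csv(path, series: list[FrameSet]) -> None:
    # %.17g keeps the write-read round trip bit-exact for doubles
    series_to_frame(series).to_csv(path, index=False, float_format="%.17g")


def read_detections_csv(path) -> list[FrameSet]:
    # round_trip float parsing: the fast default parser loses the last ulp
    return frame_to_series(pd.read_csv(path, float_precision="round_trip"))


def write_tree_json(path, tree: MatchingTree) -> None:
    Path(path).write_text(json.dumps(tree.to_dict(), indent=2))


def read_tree_json(path) -> MatchingTree:
    d = json.loads(Path(path).read_text())
    return MatchingTree(
        root=int(d["root"]),
        parent={int(c): int(p) for c, p in d["parent"].items()},
        depth={int(f): int(k) for f, k in d["depth"].items()},
        long_distance={(int(p), int(c)) for p, c in d["long_distance"]},
    )


def write_matrix_csv(path, matrix: np.ndarray) -> None:
    pd.DataFrame(matrix).to_csv(path, index=False)


def read_matrix_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def write_json(path, payload: dict) -> None:
    Path(path).write_text(json.dumps(payload, indent=2, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    raise TypeError(f"not JSON serializable: {type(x)}")


def write_manifest(path, command: str, config: dict, seed: int | None) -> None:
    from berrytrack import __version__

    write_json(path, {"tool": "berrytrack", "version": __version__,
                      "command": command, "seed": seed, "config": config})


def read_config_file(path) -> dict[str, str]:
    """Plain-text ``key = value`` configuration (one entry per line,
    ``#`` comments allowed)."""
    out: dict[str, str] = {}
    for line in Path(path).read_text().splitlines():
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"bad config line: {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out
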