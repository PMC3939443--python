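"""Plain-text readers and writers: tracking CSV, spikes CSV, query YAML,
session JSON.  Formats are deliberately simple — one table per file."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .lca import ModelParams
from .mql import Query, QueryLine, TrackingSeries
from .simulate import SessionResult

__all__ = [
    "read_tracking_csv",
    "write_tracking_csv",
    "read_spikes_csv",
    "write_spikes_csv",
    "read_query_yaml",
    "write_query_yaml",
    "write_session_json",
    "params_from_mapping",
    "read_params",
]


def write_tracking_csv(track: TrackingSeries, path) -> None:
    track.to_frame().to_csv(path, index=False)


def read_tracking_csv(path) -> TrackingSeries:
    return TrackingSeries.from_frame(pd.read_csv(path))


def write_spikes_csv(spikes: Mapping[int, np.ndarray], path) -> None:
    """Long-format spikes: columns neuron_id, spike_time_s."""
    frames = [
        pd.DataFrame({"neuron_id": nid, "spike_time_s": np.asarray(st)})
        for nid, st in spikes.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_spikes_csv(path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {
        int(nid): np.sort(sub["spike_time_s"].to_numpy())
        for nid, sub in df.groupby("neuron_id")
    }


def _line_to_dict(ln: QueryLine) -> dict:
    return {"axis": ln.axis, "level": ln.level, "span": list(ln.span)}


def _line_from_dict(d: dict) -> QueryLine:
    return QueryLine(d["axis"], float(d["level"]), tuple(d["span"]))


def write_query_yaml(queries: Mapping[str, Query], path) -> None:
    doc = {
        name: {
            "lines": [_line_to_dict(ln) for ln in q.lines],
            "avoid": [_line_to_dict(ln) for ln in q.avoid],
        }
        for name, q in queries.items()
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def read_query_yaml(path) -> dict[str, Query]:
    doc = yaml.safe_load(Path(path).read_text())
    return {
        name: Query(
            tuple(_line_from_dict(d) for d in spec["lines"]),
            tuple(_line_from_dict(d) for d in spec.get("avoid", [])),
            name,
        )
        for name, spec in doc.items()
    }


def params_from_mapping(d: Mapping) -> ModelParams:
    known = {"w", "k", "c", "dt", "threshold", "speed", "k_wm", "seed"}
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown model parameters: {sorted(unknown)}")
    return ModelParams(**d)


def read_params(path) -> ModelParams:
    text = Path(path).read_text()
    d = yaml.safe_load(text) if str(path).endswith((".yaml", ".yml")) else json.loads(text)
    return params_from_mapping(d or {})


def write_session_json(session: SessionResult, path) -> None:
    doc = {
        "params": {
            "w": session.params.w,
            "k": session.params.k,
            "c": session.params.c,
            "dt": session.params.dt,
            "threshold": session.params.threshold,
            "speed": session.params.speed,
            "k_wm": session.params.k_wm,
        },
        "seed": session.seed,
        "duration": session.duration,
        "accuracy": None if np.isnan(session.accuracy) else session.accuracy,
        "n_choice_trials": len(session.choice_trials),
        "trials": [tr.__dict__ for tr in session.trials],
    }
    Path(path).write_text(json.dumps(doc, indent=2))
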