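"""On-disk formats: CSV event streams, JSONL session logs, JSON reports.

Conventions (enforced at read time): timestamps are Unix epoch seconds UTC;
Wi-Fi SSID sets are semicolon-joined strings; one trial per JSONL line.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .sensors import EventStreams, PoiTable
from .sst import SSTSession, TrialRecord

STREAM_FILES = {
    "screen": "screen.csv",
    "calls": "calls.csv",
    "battery": "battery.csv",
    "activity": "activity.csv",
    "gps": "gps.csv",
    "wifi": "wifi.csv",
    "noise": "noise.csv",
    "network": "network.csv",
}


def write_streams(streams: EventStreams, directory: str | Path) -> None:
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    for name, fname in STREAM_FILES.items():
        df = getattr(streams, name)
        if name == "wifi" and len(df):
            df = df.assign(ssids=[";".join(s) for s in df["ssids"]])
        df.to_csv(d / fname, index=False)


def read_streams(directory: str | Path) -> EventStreams:
    d = Path(directory)
    kwargs = {}
    for name, fname in STREAM_FILES.items():
        path = d / fname
        if not path.exists():
            continue
        df = pd.read_csv(path)
        if name == "wifi" and len(df):
            df["ssids"] = [
                tuple(s.split(";")) if isinstance(s, str) and s else ()
                for s in df["ssids"]
            ]
        kwargs[name] = df
    return EventStreams(**kwargs)


def write_sessions(sessions: dict, path: str | Path) -> None:
    """All sessions to one JSONL file; each line holds one trial tagged with
    its participant and prompt time."""
    with open(path, "w") as fh:
        for (pid, t), session in sessions.items():
            for tr in session.trials:
                fh.write(
                    json.dumps(
                        {
                            "participant_id": pid,
                            "end_s": t,
                            "index": tr.index,
                            "kind": tr.kind,
                            "stimulus": tr.go_stimulus,
                            "ssd_ms": tr.ssd_ms,
                            "response": tr.response,
                            "rt_ms": tr.rt_ms,
                        }
                    )
                    + "\n"
                )


def read_sessions(path: str | Path) -> dict:
    sessions: dict[tuple[str, float], SSTSession] = {}
    trials: dict[tuple[str, float], list[TrialRecord]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            d = json.loads(line)
            key = (d["participant_id"], float(d["end_s"]))
            trials.setdefault(key, []).append(
                TrialRecord(
                    index=d["index"],
                    kind=d["kind"],
                    go_stimulus=d["stimulus"],
                    ssd_ms=d.get("ssd_ms"),
                    response=d.get("response", "none"),
                    rt_ms=d.get("rt_ms"),
                )
            )
    for key, tr in trials.items():
        sessions[key] = SSTSession(trials=sorted(tr, key=lambda t: t.index))
    return sessions


def write_poi(poi: PoiTable, path: str | Path) -> None:
    poi.venues.to_csv(path, index=False)


def read_poi(path: str | Path) -> PoiTable:
    return PoiTable(venues=pd.read_csv(path))
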