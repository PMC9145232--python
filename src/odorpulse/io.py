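"""On-disk formats: CSV signals with JSON sidecars, spike and trial tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import TimeSeries, Trial

__all__ = [
    "save_timeseries",
    "load_timeseries",
    "save_trials",
    "load_trials",
    "save_spikes",
    "load_spikes",
]


def save_timeseries(ts: TimeSeries, prefix: str | Path) -> None:
    """Write ``<prefix>.csv`` (one 'sample' column) and ``<prefix>.json`` sidecar."""
    prefix = Path(prefix)
    pd.DataFrame({"sample": ts.samples}).to_csv(prefix.with_suffix(".csv"), index=False)
    prefix.with_suffix(".json").write_text(
        json.dumps({"fs": ts.fs, "t0": ts.t0, "units": ts.units})
    )


def load_timeseries(prefix: str | Path) -> TimeSeries:
    prefix = Path(prefix)
    samples = pd.read_csv(prefix.with_suffix(".csv"))["sample"].to_numpy()
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return TimeSeries(samples, fs=meta["fs"], t0=meta.get("t0", 0.0),
                      units=meta.get("units", "a.u."))


def save_trials(trials: list[Trial], path: str | Path) -> None:
    pd.DataFrame(
        [
            {"odour": t.odour, "freq": t.freq, "onset": t.onset,
             "duration": t.duration, "is_blank": t.is_blank, "condition": t.condition}
            for t in trials
        ]
    ).to_csv(path, index=False)


def load_trials(path: str | Path) -> list[Trial]:
    df = pd.read_csv(path)
    return [
        Trial(odour=str(r.odour), freq=float(r.freq), onset=float(r.onset),
              duration=float(r.duration), is_blank=bool(r.is_blank),
              condition=str(r.condition))
        for r in df.itertuples()
    ]


def save_spikes(spikes_by_unit: dict[int, np.ndarray], path: str | Path) -> None:
    rows = [
        {"unit_id": uid, "t": float(t)}
        for uid, st in spikes_by_unit.items()
        for t in np.asarray(st)
    ]
    pd.DataFrame(rows, columns=["unit_id", "t"]).to_csv(path, index=False)


def load_spikes(path: str | Path) -> dict[int, np.ndarray]:
    df = pd.read_csv(path)
    return {int(uid): g["t"].to_numpy() for uid, g in df.groupby("unit_id")}
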