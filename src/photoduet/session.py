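"""Session container and on-disk formats.

A session holds four aligned fluorescence traces — two sensors (ACh, DA), each
with a 465 nm signal channel and a 405 nm isosbestic control — on a common
time base, plus behavioural/optogenetic event streams and condition metadata.

Two formats are supported:

* HDF5 (``.h5``/``.hdf5``): groups ``/channels`` (datasets ``ACh_465``,
  ``ACh_405``, ``DA_465``, ``DA_405``), ``/time_s``, ``/events`` (``label``,
  ``time_s``), metadata as root attributes.
* CSV fallback (a directory): ``traces.csv`` long table with columns
  ``time_s, sensor, wavelength, value``; ``events.csv`` with
  ``label, time_s``; ``meta.json``.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError

logger = logging.getLogger(__name__)

SENSORS = ("ACh", "DA")
WAVELENGTHS = (465, 405)
CHANNEL_KEYS = tuple((s, w) for s in SENSORS for w in WAVELENGTHS)

KNOWN_EVENT_LABELS = frozenset({
    "lever_extension", "lever_press", "head_entry", "cs_on", "cs_off",
    "reward", "light_on", "light_off",
})


@dataclass
class SessionRecord:
    """One recording session: traces, events, condition metadata."""

    time_s: np.ndarray
    channels: dict[tuple[str, int], np.ndarray]
    events: pd.DataFrame            # columns: label, time_s
    meta: dict = field(default_factory=dict)

    @property
    def fs(self) -> float:
        """Sampling rate (Hz) from the median sample spacing."""
        return 1.0 / float(np.median(np.diff(self.time_s)))

    def event_times(self, label: str) -> np.ndarray:
        sel = self.events.loc[self.events["label"] == label, "time_s"]
        return np.asarray(sel, dtype=float)

    def validate(self) -> "SessionRecord":
        t = np.asarray(self.time_s, dtype=float)
        if t.ndim != 1 or t.size < 2:
            raise FormatError("time_s must be a 1-D vector with >= 2 samples")
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise FormatError("time_s must be strictly increasing")
        med = np.median(dt)
        if np.max(np.abs(dt - med)) > 0.1 * med:
            raise FormatError("time_s spacing jitter exceeds 10% of median dt")
        for key in CHANNEL_KEYS:
            if key not in self.channels:
                raise FormatError(f"missing channel ({key[0]}, {key[1]})")
            v = np.asarray(self.channels[key], dtype=float)
            if v.shape != t.shape:
                raise FormatError(
                    f"channel ({key[0]}, {key[1]}) length {v.size} != time_s length {t.size}")
        if len(self.events):
            ev_t = self.events["time_s"].to_numpy(dtype=float)
            bad = (ev_t < t[0]) | (ev_t > t[-1])
            if np.any(bad):
                rows = self.events.loc[bad]
                raise FormatError(
                    "events outside the recording: "
                    + "; ".join(f"{r.label}@{r.time_s:g}s" for r in rows.itertuples()))
            unknown = set(self.events["label"]) - KNOWN_EVENT_LABELS
            if unknown:
                warnings.warn(f"unknown event labels preserved verbatim: {sorted(unknown)}",
                              stacklevel=2)
        return self


def _channel_name(sensor: str, wavelength: int) -> str:
    return f"{sensor}_{wavelength}"


def write_session(record: SessionRecord, path: str | Path) -> None:
    """Write a session to HDF5 (``.h5``/``.hdf5``) or a CSV directory."""
    record.validate()
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as fh:
            fh.create_dataset("time_s", data=np.asarray(record.time_s, dtype=np.float64))
            grp = fh.create_group("channels")
            for (s, w), v in record.channels.items():
                grp.create_dataset(_channel_name(s, w), data=np.asarray(v, dtype=np.float64))
            ev = fh.create_group("events")
            labels = np.array(record.events["label"], dtype="S32") if len(record.events) \
                else np.empty(0, dtype="S32")
            ev.create_dataset("label", data=labels)
            ev.create_dataset("time_s",
                              data=record.events["time_s"].to_numpy(dtype=np.float64)
                              if len(record.events) else np.empty(0))
            for k, v in record.meta.items():
                fh.attrs[k] = v
    else:
        path.mkdir(parents=True, exist_ok=True)
        rows = []
        for (s, w), v in record.channels.items():
            rows.append(pd.DataFrame({"time_s": record.time_s, "sensor": s,
                                      "wavelength": w, "value": v}))
        pd.concat(rows, ignore_index=True).to_csv(path / "traces.csv", index=False)
        record.events.to_csv(path / "events.csv", index=False)
        (path / "meta.json").write_text(json.dumps(record.meta, indent=1))


def read_session(path: str | Path) -> SessionRecord:
    """Read a session written by :func:`write_session`; validates on load."""
    path = Path(path)
    if path.suffix in (".h5", ".hdf5"):
        if not path.exists():
            raise FormatError(f"no such session file: {path}")
        with h5py.File(path, "r") as fh:
            time_s = fh["time_s"][:]
            channels = {}
            for s in SENSORS:
                for w in WAVELENGTHS:
                    name = _channel_name(s, w)
                    if name not in fh["channels"]:
                        raise FormatError(f"missing channel ({s}, {w})")
                    channels[(s, w)] = fh["channels"][name][:]
            labels = [x.decode() for x in fh["events/label"][:]]
            events = pd.DataFrame({"label": labels, "time_s": fh["events/time_s"][:]})
            meta = {k: (v.item() if hasattr(v, "item") else v) for k, v in fh.attrs.items()}
    else:
        if not (path / "traces.csv").exists():
            raise FormatError(f"no such session directory: {path}")
        traces = pd.read_csv(path / "traces.csv")
        channels = {}
        time_s = None
        for (s, w), grp in traces.groupby(["sensor", "wavelength"], sort=False):
            channels[(s, int(w))] = grp["value"].to_numpy()
            if time_s is None:
                time_s = grp["time_s"].to_numpy()
        for key in CHANNEL_KEYS:
            if key not in channels:
                raise FormatError(f"missing channel ({key[0]}, {key[1]})")
        events = pd.read_csv(path / "events.csv") if (path / "events.csv").exists() \
            else pd.DataFrame(columns=["label", "time_s"])
        meta = json.loads((path / "meta.json").read_text()) if (path / "meta.json").exists() else {}
    rec = SessionRecord(time_s=np.asarray(time_s, dtype=float), channels=channels,
                        events=events, meta=meta)
    return rec.validate()
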