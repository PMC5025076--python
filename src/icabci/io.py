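"""Run-format readers/writers and model serialization.

A *run* is a directory holding three files:

* ``header.json`` — sampling rate and ordered channel labels;
* ``samples.npy`` — the (n_channels x n_samples) matrix in microvolts;
* ``events.csv``  — columns ``onset_sample,label`` with strictly
  increasing onsets and class labels 1/2/3.

An optional EDF reader maps annotation descriptions onto class labels via a
caller-supplied table (requires the ``mne`` package).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocessing import InvalidParameterError, MultichannelRecording

__all__ = ["read_run", "write_run", "read_edf"]


class RunFormatError(ValueError):
    """A run directory is missing files or internally inconsistent."""


def write_run(rec: MultichannelRecording, path: str | Path) -> Path:
    """Write a recording as header.json + samples.npy + events.csv."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    (path / "header.json").write_text(json.dumps({
        "fs": rec.fs,
        "channel_labels": rec.channel_labels,
        "n_samples": rec.n_samples,
    }, indent=1))
    np.save(path / "samples.npy", rec.samples)
    pd.DataFrame(rec.events, columns=["onset_sample", "label"]).to_csv(
        path / "events.csv", index=False)
    return path


def read_run(path: str | Path) -> MultichannelRecording:
    """Read a run directory back into a validated recording."""
    path = Path(path)
    header_file = path / "header.json"
    for f in (header_file, path / "samples.npy", path / "events.csv"):
        if not f.exists():
            raise RunFormatError(f"missing run file: {f}")
    try:
        header = json.loads(header_file.read_text())
        fs = float(header["fs"])
        labels = list(header["channel_labels"])
    except (KeyError, ValueError, json.JSONDecodeError) as exc:
        raise RunFormatError(f"malformed header {header_file}: {exc}") from exc
    samples = np.load(path / "samples.npy")
    if samples.ndim != 2 or samples.shape[0] != len(labels):
        raise RunFormatError(
            f"{path / 'samples.npy'}: shape {samples.shape} does not match "
            f"{len(labels)} channel labels"
        )
    ev = pd.read_csv(path / "events.csv")
    if list(ev.columns) != ["onset_sample", "label"]:
        raise RunFormatError(
            f"{path / 'events.csv'}: expected columns onset_sample,label"
        )
    events = list(zip(ev["onset_sample"].astype(int), ev["label"].astype(int)))
    try:
        return MultichannelRecording(samples=samples, fs=fs,
                                     channel_labels=labels, events=events)
    except InvalidParameterError as exc:
        raise RunFormatError(f"run at {path} invalid: {exc}") from exc


def read_edf(path: str | Path, label_map: dict[str, int],
             channels: list[str] | None = None) -> MultichannelRecording:
    """Read a European Data Format file, mapping annotation descriptions to
    class labels through ``label_map`` (annotations absent from the map are
    ignored).  Signal units are assumed microvolts (EEG convention)."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment dependent
        raise RunFormatError(
            "EDF support requires the optional 'mne' dependency"
        ) from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels:
        raw.pick(channels)
    samples = raw.get_data() * 1e6  # volts -> microvolts
    fs = float(raw.info["sfreq"])
    events = []
    for onset, desc in zip(raw.annotations.onset, raw.annotations.description):
        if desc in label_map:
            events.append((int(round(onset * fs)), int(label_map[desc])))
    events.sort()
    return MultichannelRecording(samples=samples, fs=fs,
                                 channel_labels=list(raw.ch_names),
                                 events=events)
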