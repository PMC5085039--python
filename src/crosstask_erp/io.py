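"""Persistence: documented HDF5 layout, marker sidecars, standard readers.

HDF5 layout of a recording file:

* ``/eeg``      — channels x samples float32, microvolts
* ``/events``   — structured table (onset_ms, color_index, grid_row,
  grid_col, is_target, condition, repetition_index,
  within_repetition_index)
* ``/meta``     — attributes: sampling_rate, channel_names, participant,
  condition, reference

Epoch sets and feature matrices use analogous layouts (see the writers).
Real recordings can be ingested from BrainVision (.vhdr) and EDF
containers via mne; event metadata beyond onsets/descriptions must then be
supplied separately.  A BrainVision-style .vmrk text sidecar can be
exported for interoperability.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .behavior import BehavioralRecord
from .containers import ContinuousRecording, EpochSet, FeatureMatrix
from .events import StimulusEvent

_EVENT_DTYPE = np.dtype([
    ("onset_ms", "i8"), ("color_index", "i4"), ("grid_row", "i4"),
    ("grid_col", "i4"), ("is_target", "?"), ("condition", "S4"),
    ("repetition_index", "i4"), ("within_repetition_index", "i4"),
])


def _events_to_table(events: list[StimulusEvent]) -> np.ndarray:
    table = np.empty(len(events), dtype=_EVENT_DTYPE)
    for i, ev in enumerate(events):
        table[i] = (ev.onset_ms, ev.color_index, ev.grid_row, ev.grid_col,
                    ev.is_target, ev.condition.encode(), ev.repetition_index,
                    ev.within_repetition_index)
    return table


def _events_from_table(table: np.ndarray) -> list[StimulusEvent]:
    return [
        StimulusEvent(
            onset_ms=int(row["onset_ms"]), color_index=int(row["color_index"]),
            grid_row=int(row["grid_row"]), grid_col=int(row["grid_col"]),
            is_target=bool(row["is_target"]),
            condition=row["condition"].decode(),
            repetition_index=int(row["repetition_index"]),
            within_repetition_index=int(row["within_repetition_index"]),
        )
        for row in table
    ]


def write_recording_h5(rec: ContinuousRecording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("eeg", data=rec.data.astype(np.float32))
        f.create_dataset("events", data=_events_to_table(rec.events))
        meta = f.create_group("meta")
        meta.attrs["sampling_rate"] = rec.sampling_rate
        meta.attrs["channel_names"] = json.dumps(list(rec.channel_names))
        meta.attrs["participant"] = rec.participant
        meta.attrs["condition"] = rec.condition
        meta.attrs["reference"] = rec.reference


def read_recording_h5(path: str | Path) -> ContinuousRecording:
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        return ContinuousRecording(
            data=f["eeg"][()].astype(float),
            sampling_rate=float(meta["sampling_rate"]),
            channel_names=json.loads(meta["channel_names"]),
            events=_events_from_table(f["events"][()]),
            participant=str(meta["participant"]),
            condition=str(meta["condition"]),
            reference=str(meta["reference"]),
        )


def write_epochs_h5(epochs: EpochSet, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("epochs", data=epochs.data.astype(np.float32))
        f.create_dataset("times_ms", data=epochs.times_ms)
        f.create_dataset("labels", data=epochs.labels.astype(np.int8))
        f.create_dataset("kept", data=epochs.kept)
        f.create_dataset("events", data=_events_to_table(epochs.events))
        meta = f.create_group("meta")
        meta.attrs["sampling_rate"] = epochs.sampling_rate
        meta.attrs["channel_names"] = json.dumps(list(epochs.channel_names))
        meta.attrs["participant"] = epochs.participant
        meta.attrs["condition"] = epochs.condition


def read_epochs_h5(path: str | Path) -> EpochSet:
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        return EpochSet(
            data=f["epochs"][()].astype(float),
            times_ms=f["times_ms"][()],
            labels=f["labels"][()].astype(int),
            channel_names=json.loads(meta["channel_names"]),
            events=_events_from_table(f["events"][()]),
            participant=str(meta["participant"]),
            condition=str(meta["condition"]),
            kept=f["kept"][()].astype(bool),
            sampling_rate=float(meta["sampling_rate"]),
        )


def write_features_h5(fm: FeatureMatrix, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=fm.X)
        f.create_dataset("y", data=fm.y.astype(np.int8))
        f.create_dataset("epoch_index", data=fm.epoch_index)
        meta = f.create_group("meta")
        meta.attrs["feature_index"] = json.dumps(
            [[c, t] for c, t in fm.feature_index])
        meta.attrs["participant"] = fm.participant
        meta.attrs["condition"] = fm.condition


def read_features_h5(path: str | Path) -> FeatureMatrix:
    with h5py.File(path, "r") as f:
        meta = f["meta"].attrs
        return FeatureMatrix(
            X=f["X"][()],
            y=f["y"][()].astype(int),
            feature_index=[(c, float(t)) for c, t in json.loads(meta["feature_index"])],
            epoch_index=f["epoch_index"][()],
            participant=str(meta["participant"]),
            condition=str(meta["condition"]),
        )


def features_to_tsv(fm: FeatureMatrix, path: str | Path) -> None:
    cols = [f"{c}@{t:g}ms" for c, t in fm.feature_index]
    df = pd.DataFrame(fm.X, columns=cols)
    df.insert(0, "label", fm.y)
    df.insert(0, "epoch", fm.epoch_index)
    df.to_csv(path, sep="\t", index=False)


def write_vmrk(events: list[StimulusEvent], sampling_rate: float,
               path: str | Path, data_file: str = "recording.eeg") -> None:
    """BrainVision-style marker sidecar: stimulus markers ``S<c>`` with the
    1-based color index; targets additionally flagged ``T``."""
    lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]",
        f"DataFile={data_file}",
        "[Marker Infos]",
        "; Mk<n>=<type>,<description>,<position_samples>,<size>,<channel>",
        f"Mk1=New Segment,,1,1,0",
    ]
    for i, ev in enumerate(events, start=2):
        pos = int(round(ev.onset_ms * sampling_rate / 1000.0)) + 1  # 1-based
        desc = f"S{ev.color_index + 1}" + ("T" if ev.is_target else "")
        lines.append(f"Mk{i}=Stimulus,{desc},{pos},1,0")
    Path(path).write_text("\n".join(lines) + "\n")


def answers_to_tsv(answers: dict[str, list[BehavioralRecord]], path: str | Path) -> None:
    """Answer table: participant, condition, repetition, correct, entered.

    M-condition position lists are encoded as ``r<row>c<col>`` tokens joined
    by ';'.
    """
    rows = []
    for participant, records in answers.items():
        for rec in records:
            rows.append({
                "participant": participant,
                "condition": rec.condition,
                "repetition": rec.repetition_index,
                "correct": _encode_answer(rec.correct),
                "entered": _encode_answer(rec.entered),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def answers_from_tsv(path: str | Path) -> dict[str, list[BehavioralRecord]]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    out: dict[str, list[BehavioralRecord]] = {}
    for _, row in df.iterrows():
        rec = BehavioralRecord(
            condition=row["condition"],
            repetition_index=int(row["repetition"]),
            correct=_decode_answer(row["correct"]),
            entered=_decode_answer(row["entered"]),
        )
        out.setdefault(row["participant"], []).append(rec)
    return out


def _encode_answer(answer) -> str:
    if isinstance(answer, list):
        return ";".join(f"r{r}c{c}" for r, c in answer)
    return str(answer)


def _decode_answer(text: str):
    text = "" if pd.isna(text) else str(text)
    if text.startswith("r") or text == "":
        out = []
        for token in filter(None, text.split(";")):
            r, c = token[1:].split("c")
            out.append((int(r), int(c)))
        return out
    return int(text)


def read_raw_mne(path: str | Path) -> ContinuousRecording:
    """Ingest a real recording from a BrainVision (.vhdr) or EDF (.edf)
    container via mne.

    Only onsets and marker descriptions are available in these containers;
    the returned events carry color/target metadata parsed from ``S<c>[T]``
    descriptions where possible, and placeholders otherwise.
    """
    import mne

    path = Path(path)
    if path.suffix.lower() == ".vhdr":
        raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    elif path.suffix.lower() == ".edf":
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    else:
        raise ValueError(f"unsupported container {path.suffix!r}; expected .vhdr or .edf")
    data_uv = raw.get_data() * 1e6
    sfreq = raw.info["sfreq"]
    events = []
    for i, ann in enumerate(raw.annotations):
        desc = str(ann["description"]).split("/")[-1].strip()
        if not desc.startswith("S"):
            continue
        body = desc[1:]
        is_target = body.endswith("T")
        if is_target:
            body = body[:-1]
        try:
            color = int(body) - 1
        except ValueError:
            continue
        events.append(StimulusEvent(
            onset_ms=int(round(ann["onset"] * 1000)), color_index=color,
            grid_row=1, grid_col=1, is_target=is_target, condition="C",
            repetition_index=1, within_repetition_index=i + 1,
        ))
    return ContinuousRecording(
        data=data_uv, sampling_rate=sfreq, channel_names=list(raw.ch_names),
        events=events,
    )
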