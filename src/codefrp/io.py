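"""File formats: gaze TSV, layout JSON, EEG/epoch containers, BrainVision.

The EEG container is deliberately simple: a little-endian float32
channel-major binary file (``*.dat``) next to a JSON sidecar (``*.json``)
holding channel names, sampling rate, units, reference, and the event
list. Epoch collections reuse the same layout with one stacked array.
A reader for BrainVision Core (vhdr/vmrk/eeg) files is provided for real
recordings; it delegates the parsing to MNE when available.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import (
    EEGRecording,
    Epoch,
    Fixation,
    FixationSequence,
    GazeStream,
    LineBox,
    Rect,
    StimulusLayout,
)

CONTAINER_VERSION = 1

# --------------------------------------------------------------------------
# gaze TSV


def write_gaze_tsv(streams: list[GazeStream], path: str | Path) -> None:
    frames = []
    for s in streams:
        frames.append(
            pd.DataFrame(
                {
                    "trial_id": s.trial_id,
                    "t_ms": s.t_ms,
                    "x_px": s.x_px,
                    "y_px": s.y_px,
                    "valid": s.valid.astype(int),
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def read_gaze_tsv(path: str | Path, rate_hz: float) -> list[GazeStream]:
    df = pd.read_csv(path, sep="\t")
    streams = []
    for trial_id, g in df.groupby("trial_id", sort=False):
        # timestamps are uniform by construction; rebuild them exactly from
        # the rate instead of trusting the rounded text representation
        t0 = float(g["t_ms"].iloc[0])
        streams.append(
            GazeStream(
                trial_id=str(trial_id),
                t_ms=t0 + np.arange(len(g)) * 1000.0 / rate_hz,
                x_px=g["x_px"].to_numpy(float),
                y_px=g["y_px"].to_numpy(float),
                valid=g["valid"].to_numpy(int).astype(bool),
                rate_hz=rate_hz,
            )
        )
    return streams


# --------------------------------------------------------------------------
# layout JSON


def layout_to_dict(layout: StimulusLayout) -> dict:
    return {
        "snippet_id": layout.snippet_id,
        "screen": list(layout.screen),
        "lines": [
            {
                "x0": ln.x0,
                "y0": ln.y0,
                "x1": ln.x1,
                "y1": ln.y1,
                "informative": ln.informative,
            }
            for ln in layout.lines
        ],
        "aoi": {
            "x0": layout.aoi.x0,
            "y0": layout.aoi.y0,
            "x1": layout.aoi.x1,
            "y1": layout.aoi.y1,
        },
    }


def layout_from_dict(d: dict) -> StimulusLayout:
    return StimulusLayout(
        snippet_id=d["snippet_id"],
        lines=tuple(
            LineBox(ln["x0"], ln["y0"], ln["x1"], ln["y1"], bool(ln["informative"]))
            for ln in d["lines"]
        ),
        aoi=Rect(**d["aoi"]),
        screen=tuple(d["screen"]),
    )


def write_layouts_json(layouts: list[StimulusLayout], path: str | Path) -> None:
    payload = [layout_to_dict(layout) for layout in layouts]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_layouts_json(path: str | Path) -> list[StimulusLayout]:
    return [layout_from_dict(d) for d in json.loads(Path(path).read_text())]


# --------------------------------------------------------------------------
# fixation / ledger TSV


def write_fixations_tsv(sequences: list[FixationSequence], path: str | Path) -> None:
    rows = []
    for seq in sequences:
        for f in seq:
            rows.append(
                (
                    seq.trial_id,
                    f.onset_ms,
                    f.offset_ms,
                    f.x,
                    f.y,
                    -1 if f.line_index is None else f.line_index,
                    int(f.in_aoi),
                    seq.correction_method,
                )
            )
    pd.DataFrame(
        rows,
        columns=[
            "trial_id",
            "onset_ms",
            "offset_ms",
            "x",
            "y",
            "line_index",
            "in_aoi",
            "correction_method",
        ],
    ).to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_fixations_tsv(path: str | Path) -> list[FixationSequence]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for trial_id, g in df.groupby("trial_id", sort=False):
        fixations = tuple(
            Fixation(
                onset_ms=r.onset_ms,
                offset_ms=r.offset_ms,
                x=r.x,
                y=r.y,
                line_index=None if r.line_index < 0 else int(r.line_index),
                in_aoi=bool(r.in_aoi),
            )
            for r in g.itertuples()
        )
        method = g["correction_method"].iloc[0] if len(g) else "none"
        out.append(FixationSequence(str(trial_id), fixations, correction_method=method))
    return out


# --------------------------------------------------------------------------
# EEG container (flat float32 + JSON sidecar)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def _data_path(path: Path) -> Path:
    return path.with_suffix(".dat")


def write_eeg(recording: EEGRecording, path: str | Path) -> None:
    path = Path(path)
    meta = {
        "version": CONTAINER_VERSION,
        "kind": "continuous",
        "channels": list(recording.channels),
        "rate_hz": recording.rate_hz,
        "units": "uV",
        "reference": recording.reference,
        "n_samples": recording.n_samples,
        "dtype": "<f4",
        "events": [[label, int(s)] for label, s in recording.events],
        "data_file": _data_path(path).name,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    recording.data.astype("<f4").tofile(_data_path(path))


def read_eeg(path: str | Path) -> EEGRecording:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    if meta.get("version") != CONTAINER_VERSION:
        raise ValueError(
            f"unsupported container version {meta.get('version')!r}"
            f" (expected {CONTAINER_VERSION})"
        )
    n_ch = len(meta["channels"])
    data = np.fromfile(_data_path(path), dtype=meta["dtype"]).reshape(n_ch, -1)
    if data.shape[1] != meta["n_samples"]:
        raise ValueError("container sample count mismatch")
    return EEGRecording(
        channels=tuple(meta["channels"]),
        rate_hz=float(meta["rate_hz"]),
        data=data.astype(np.float64),
        events=tuple((label, int(s)) for label, s in meta["events"]),
        reference=meta["reference"],
    )


def write_epochs(epochs: list[Epoch], path: str | Path) -> None:
    path = Path(path)
    if not epochs:
        raise ValueError("no epochs to write")
    ref = epochs[0]
    meta = {
        "version": CONTAINER_VERSION,
        "kind": "epochs",
        "channels": list(ref.channels),
        "times_ms": [float(t) for t in ref.times_ms],
        "window_ms": list(ref.window_ms),
        "baseline_window_ms": list(ref.baseline_window_ms),
        "dtype": "<f4",
        "epochs": [
            {
                "trial_id": e.trial_id,
                "condition": e.condition,
                "verdict": e.verdict,
                "reasons": list(e.reasons),
            }
            for e in epochs
        ],
        "data_file": _data_path(path).name,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    np.stack([e.data for e in epochs]).astype("<f4").tofile(_data_path(path))


def read_epochs(path: str | Path) -> list[Epoch]:
    path = Path(path)
    meta = json.loads(_sidecar_path(path).read_text())
    if meta.get("version") != CONTAINER_VERSION:
        raise ValueError(
            f"unsupported container version {meta.get('version')!r}"
            f" (expected {CONTAINER_VERSION})"
        )
    times = np.array(meta["times_ms"])
    n_ch = len(meta["channels"])
    data = np.fromfile(_data_path(path), dtype=meta["dtype"]).reshape(
        len(meta["epochs"]), n_ch, len(times)
    )
    return [
        Epoch(
            trial_id=e["trial_id"],
            condition=e["condition"],
            channels=tuple(meta["channels"]),
            times_ms=times.copy(),
            data=data[i].astype(np.float64),
            window_ms=tuple(meta["window_ms"]),
            baseline_window_ms=tuple(meta["baseline_window_ms"]),
            verdict=e["verdict"],
            reasons=tuple(e["reasons"]),
        )
        for i, e in enumerate(meta["epochs"])
    ]


# --------------------------------------------------------------------------
# ground-truth JSON (synthetic studies)


def write_truth_json(truth, path: str | Path) -> None:
    """Persist a SyntheticTruth for test harnesses."""
    payload = {
        "fixations": {
            tid: [
                {
                    "onset_ms": f.onset_ms,
                    "duration_ms": f.duration_ms,
                    "x": f.x,
                    "y": f.y,
                    "line_index": f.line_index,
                    "in_aoi": f.in_aoi,
                }
                for f in fixes
            ]
            for tid, fixes in truth.fixations.items()
        },
        "effect_trials": truth.effect_trials,
        "artifact_trials": sorted(truth.artifact_trials),
        "bad_gaze_trials": sorted(truth.bad_gaze_trials),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path: str | Path):
    from .synthetic import SyntheticTruth, TruthFixation

    d = json.loads(Path(path).read_text())
    truth = SyntheticTruth()
    for tid, fixes in d["fixations"].items():
        truth.fixations[tid] = tuple(TruthFixation(**f) for f in fixes)
        truth.first_aoi[tid] = next(
            (f for f in truth.fixations[tid] if f.in_aoi), None
        )
    truth.effect_trials = dict(d["effect_trials"])
    truth.artifact_trials = set(d["artifact_trials"])
    truth.bad_gaze_trials = set(d["bad_gaze_trials"])
    return truth


# --------------------------------------------------------------------------
# BrainVision Core (optional)


def read_brainvision(vhdr_path: str | Path) -> EEGRecording:
    """Read a BrainVision Core vhdr/vmrk/eeg triplet into an EEGRecording.

    Requires MNE. Amplitudes are converted to microvolts; markers become
    (description, sample) events.
    """
    try:
        import mne
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ImportError("reading BrainVision files requires mne") from exc
    raw = mne.io.read_raw_brainvision(str(vhdr_path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    events = tuple(
        (str(desc), int(round(onset * raw.info["sfreq"])))
        for onset, desc in zip(raw.annotations.onset, raw.annotations.description)
    )
    return EEGRecording(
        channels=tuple(raw.ch_names),
        rate_hz=float(raw.info["sfreq"]),
        data=data_uv,
        events=events,
        reference="left_mastoid",
    )
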