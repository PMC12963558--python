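"""Reading and writing recordings, studies and tabular results.

Recordings travel either as long CSV (columns ``time_s, channel, value_uV``)
or as 16-bit EDF.  EDF reading goes through mne's built-in reader; writing
uses a minimal classic-EDF writer implemented here (1-s data records,
per-channel physical scaling), since no installed library exports EDF.
Synthetic event logs (blink/spike times) live only in memory -- on-disk
recordings carry signal and labels.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import ChannelMontage, default_montage
from .recording import Recording
from .questionnaire import LikertTable

_EDF_DIG_MIN, _EDF_DIG_MAX = -32768, 32767


# ---------------------------------------------------------------------------
# single recordings


def write_recording_csv(rec: Recording, path) -> None:
    """Long-format CSV: one row per sample per channel, values in uV."""
    t = np.arange(rec.n_samples) / rec.fs
    frames = []
    for ch in rec.montage.ordered_labels:
        frames.append(pd.DataFrame({
            "time_s": t, "channel": ch, "value_uV": rec.channel(ch)}))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.8f")


def _read_recording_csv(path, montage: ChannelMontage) -> tuple:
    frame = pd.read_csv(path)
    for col in ("time_s", "channel", "value_uV"):
        if col not in frame.columns:
            raise ValueError(f"recording CSV missing column {col!r}")
    wide = frame.pivot(index="time_s", columns="channel", values="value_uV")
    missing = [ch for ch in montage.ordered_labels if ch not in wide.columns]
    if missing:
        raise ValueError(f"recording lacks channel(s) {missing}")
    t = wide.index.to_numpy(float)
    fs = 1.0 / np.median(np.diff(t))
    samples = wide.loc[:, list(montage.ordered_labels)].to_numpy(float).T
    return samples, float(round(fs, 6))


def write_recording_edf(rec: Recording, path) -> None:
    """Minimal classic-EDF writer: 1-s records, int16 samples, physical
    dimension uV.  Requires an integer sampling rate; a trailing partial
    second is dropped."""
    fs = int(round(rec.fs))
    if abs(fs - rec.fs) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    n_records = rec.n_samples // fs
    if n_records < 1:
        raise ValueError("recording shorter than one EDF record")
    ns = rec.montage.n_channels
    data = rec.samples[:, :n_records * fs]

    phys_min = np.floor(data.min(axis=1)) - 1.0
    phys_max = np.ceil(data.max(axis=1)) + 1.0
    scale = (_EDF_DIG_MAX - _EDF_DIG_MIN) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None]
                      + _EDF_DIG_MIN).astype("<i2")

    def pad(text: str, width: int) -> bytes:
        return text[:width].ljust(width).encode("ascii")

    header = b"".join([
        pad("0", 8), pad("X X X X", 80), pad("Startdate X X X X", 80),
        pad("01.01.00", 8), pad("00.00.00", 8),
        pad(str(256 * (1 + ns)), 8), pad("", 44),
        pad(str(n_records), 8), pad("1", 8), pad(str(ns), 4),
    ])
    labels = [pad(ch, 16) for ch in rec.montage.ordered_labels]
    fields = [
        labels,
        [pad("", 80)] * ns,
        [pad("uV", 8)] * ns,
        [pad(f"{v:g}", 8) for v in phys_min],
        [pad(f"{v:g}", 8) for v in phys_max],
        [pad(str(_EDF_DIG_MIN), 8)] * ns,
        [pad(str(_EDF_DIG_MAX), 8)] * ns,
        [pad("", 80)] * ns,
        [pad(str(fs), 8)] * ns,
        [pad("", 32)] * ns,
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for column in fields:
            fh.write(b"".join(column))
        for r in range(n_records):
            block = digital[:, r * fs:(r + 1) * fs]
            fh.write(block.tobytes())


def _read_recording_edf(path, montage: ChannelMontage) -> tuple:
    import mne

    raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    missing = [ch for ch in montage.ordered_labels
               if ch not in raw.ch_names]
    if missing:
        raise ValueError(f"recording lacks channel(s) {missing}")
    data = raw.get_data(picks=list(montage.ordered_labels), units="uV")
    return np.asarray(data, dtype=float), float(raw.info["sfreq"])


def read_recording(path, format: str | None = None,
                   montage: ChannelMontage | None = None,
                   meta: dict | None = None) -> Recording:
    """Read a recording from EDF or long CSV, re-ordered to montage order.

    ``format`` defaults to the file suffix.  A missing montage channel
    raises an error naming the label.
    """
    path = Path(path)
    montage = montage or default_montage()
    if format is None:
        format = path.suffix.lstrip(".").lower()
    if format == "csv":
        samples, fs = _read_recording_csv(path, montage)
    elif format == "edf":
        samples, fs = _read_recording_edf(path, montage)
    else:
        raise ValueError(f"unknown recording format {format!r}")
    return Recording(samples, fs, montage, dict(meta or {}))


# ---------------------------------------------------------------------------
# epochs and tables


def write_epochs_csv(epochs, data_path, mask_path) -> None:
    """Cleaned epochs as long CSV (epoch, channel, sample_index, value_uV)
    plus a per-epoch artifact-mask CSV."""
    n_ep, n_ch, n_s = epochs.epochs.shape
    ep_idx = np.repeat(np.arange(n_ep), n_ch * n_s)
    ch_idx = np.tile(np.repeat(np.arange(n_ch), n_s), n_ep)
    s_idx = np.tile(np.arange(n_s), n_ep * n_ch)
    labels = np.array(epochs.montage.ordered_labels)
    pd.DataFrame({
        "epoch": ep_idx, "channel": labels[ch_idx], "sample_index": s_idx,
        "value_uV": epochs.epochs.ravel(),
    }).to_csv(data_path, index=False, float_format="%.6f")
    pd.DataFrame({
        "epoch": np.arange(n_ep), "rejected": epochs.artifact_mask,
    }).to_csv(mask_path, index=False)


def write_questionnaire_csv(table: LikertTable, path) -> None:
    table.frame.to_csv(path, index=False)


def read_questionnaire_csv(path) -> LikertTable:
    return LikertTable(pd.read_csv(path))


# ---------------------------------------------------------------------------
# whole studies (stage isolation: simulate writes, analyse reads)


@dataclass
class StudyLayout:
    """On-disk study as read back for analysis."""

    recordings: dict         # (subject_id, condition) -> Recording
    rest_segments: dict      # subject_id -> Recording
    questionnaire: LikertTable
    ground_truth: pd.DataFrame | None
    index: pd.DataFrame


def write_study(dataset, out_dir, format: str = "csv") -> pd.DataFrame:
    """Write a generated study to ``out_dir``; returns the file index.

    ``format`` selects ``csv`` or ``edf`` recording files.  The index CSV
    records subject, group, condition, kind, sampling rate and path.
    """
    if format not in ("csv", "edf"):
        raise ValueError("format must be 'csv' or 'edf'")
    out_dir = Path(out_dir)
    (out_dir / "recordings").mkdir(parents=True, exist_ok=True)
    writer = write_recording_csv if format == "csv" else write_recording_edf
    rows = []

    def save(rec: Recording, name: str, kind: str, condition) -> None:
        rel = f"recordings/{name}.{format}"
        writer(rec, out_dir / rel)
        rows.append({"subject_id": rec.meta["subject_id"],
                     "group": rec.meta["group"], "condition": condition,
                     "kind": kind, "fs": rec.fs, "path": rel})

    for (sid, cond), rec in sorted(dataset.recordings.items()):
        save(rec, f"{sid}_{cond}", "task", cond)
    for sid, rec in sorted(dataset.rest_segments.items()):
        save(rec, f"{sid}_rest", "rest", None)
    index = pd.DataFrame(rows)
    index.to_csv(out_dir / "index.csv", index=False)
    write_questionnaire_csv(dataset.questionnaire,
                            out_dir / "questionnaire.csv")
    dataset.ground_truth.to_csv(out_dir / "ground_truth.csv", index=False)
    return index


def read_study(study_dir, montage: ChannelMontage | None = None
               ) -> StudyLayout:
    """Read back a study written by :func:`write_study`."""
    study_dir = Path(study_dir)
    index_path = study_dir / "index.csv"
    if not index_path.exists():
        raise FileNotFoundError(f"no index.csv in {study_dir}")
    montage = montage or default_montage()
    index = pd.read_csv(index_path)
    recordings, rests = {}, {}
    for _, row in index.iterrows():
        meta = {"subject_id": row["subject_id"], "group": row["group"],
                "condition": (None if pd.isna(row["condition"])
                              else row["condition"]),
                "kind": row["kind"]}
        rec = read_recording(study_dir / row["path"], montage=montage,
                             meta=meta)
        if row["kind"] == "task":
            recordings[(row["subject_id"], row["condition"])] = rec
        else:
            rests[row["subject_id"]] = rec
    questionnaire = read_questionnaire_csv(study_dir / "questionnaire.csv")
    truth_path = study_dir / "ground_truth.csv"
    truth = pd.read_csv(truth_path) if truth_path.exists() else None
    return StudyLayout(recordings, rests, questionnaire, truth, index)
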