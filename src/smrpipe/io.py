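"""Readers and writers: EDF+, BrainVision, ERDd tables, decompositions.

Reading goes through MNE (:func:`mne.io.read_raw_edf`,
:func:`mne.io.read_raw_brainvision`).  Writing is implemented here:
a minimal EDF+C writer (16-bit samples, one annotation channel holding
the trial markers as time-stamped annotation lists) and a BrainVision
triplet writer (.vhdr/.vmrk text plus IEEE-float .eeg), both verified
round-trip against the MNE readers.

Trial markers use a compact code table::

    MI_<type>      cue onset of a motor-imagery trial   (e.g. MI_FR)
    VA_<type>      cue onset of a visual-attention trial within a
                   run of imagery type <type>
    ..._FB         suffix on either code when the run was feedback-
                   assisted

Marker duration equals the trial length (6 s).
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .montage import CHANNELS, validate_channels
from .preprocess import EpochedEEG

ERDD_COLUMNS = ["subject", "day", "run", "imageryType", "isFeedbacked",
                "videoORfeed", "ERDd"]


def marker_code(condition: str, imagery_type: str, feedback: bool) -> str:
    prefix = "MI" if condition == "imagery" else "VA"
    return f"{prefix}_{imagery_type}" + ("_FB" if feedback else "")


def parse_marker(code: str) -> dict | None:
    """Invert :func:`marker_code`; None for non-trial markers."""
    code = code.split("/")[-1].strip()  # MNE may prefix "Stimulus/"
    parts = code.split("_")
    if len(parts) < 2 or parts[0] not in ("MI", "VA"):
        return None
    return {
        "condition": "imagery" if parts[0] == "MI" else "visual_attention",
        "imagery_type": parts[1],
        "feedback_flag": parts[-1] == "FB",
    }


# ---------------------------------------------------------------------------
# EDF+ writer


def _edf_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        s = s[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path,
    data: np.ndarray,
    fs: float,
    channel_names=CHANNELS,
    annotations=(),
    physical_max: float | None = None,
) -> Path:
    """Write continuous data (channels x samples, microvolt) as EDF+C.

    ``annotations`` is an iterable of (onset_s, duration_s, text).
    Records are 1 s; the trailing partial second is zero-padded.
    """
    path = Path(path)
    data = np.atleast_2d(np.asarray(data, float))
    channel_names = validate_channels(channel_names)
    n_ch, n_samples = data.shape
    if n_ch != len(channel_names):
        raise ValueError("channel count mismatch")
    spr = int(round(fs))  # samples per 1 s record
    n_records = int(np.ceil(n_samples / spr))
    if physical_max is None:
        physical_max = float(np.ceil(np.abs(data).max() + 1e-9)) or 1.0
    # digital conversion
    scaled = np.clip(data / physical_max, -1, 1)
    digital = np.round(scaled * 32767).astype("<i2")
    pad = n_records * spr - n_samples
    if pad:
        digital = np.pad(digital, ((0, 0), (0, pad)))

    # annotation channel: TALs, generously sized records
    ann_texts = [[] for _ in range(n_records)]
    for onset, duration, text in annotations:
        rec = min(int(onset), n_records - 1)
        tal = f"+{onset:.4f}\x15{duration:.4f}\x14{text}\x14"
        ann_texts[rec].append(tal)
    ann_records = []
    for rec in range(n_records):
        payload = f"+{rec}\x14\x14\x00" + "".join(ann_texts[rec])
        ann_records.append(payload.encode("utf-8"))
    ann_bytes = max(64, ((max(len(b) for b in ann_records) + 1) // 2) * 2 + 2)
    ann_spr = ann_bytes // 2

    ns = n_ch + 1
    header = b""
    header += _edf_field("0", 8)
    header += _edf_field("X X X X", 80)
    header += _edf_field("Startdate 01-JAN-2000 X smrpipe X", 80)
    header += _edf_field("01.01.00", 8)
    header += _edf_field("00.00.00", 8)
    header += _edf_field(256 * (ns + 1), 8)
    header += _edf_field("EDF+C", 44)
    header += _edf_field(n_records, 8)
    header += _edf_field(1, 8)
    header += _edf_field(ns, 4)

    labels = [f"EEG {ch}" for ch in channel_names] + ["EDF Annotations"]
    fields = [
        (labels, 16),
        (["AgAgCl electrode"] * n_ch + [""], 80),
        (["uV"] * n_ch + [""], 8),
        ([f"{-physical_max:g}"] * n_ch + ["-1"], 8),
        ([f"{physical_max:g}"] * n_ch + ["1"], 8),
        (["-32768"] * n_ch + ["-32768"], 8),
        (["32767"] * n_ch + ["32767"], 8),
        (["HP:0.0Hz LP:250Hz"] * n_ch + [""], 80),
        ([str(spr)] * n_ch + [str(ann_spr)], 8),
        ([""] * ns, 32),
    ]
    for values, width in fields:
        for v in values:
            header += _edf_field(v, width)

    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            chunk = digital[:, rec * spr:(rec + 1) * spr]
            fh.write(chunk.tobytes())
            fh.write(ann_records[rec].ljust(ann_bytes, b"\x00"))
    return path


# ---------------------------------------------------------------------------
# BrainVision triplet writer


def write_brainvision(
    basepath,
    data: np.ndarray,
    fs: float,
    channel_names=CHANNELS,
    markers=(),
) -> Path:
    """Write a BrainVision triplet (.vhdr/.vmrk/.eeg), IEEE float 32.

    ``markers`` is an iterable of (onset_s, duration_s, text); texts
    become Stimulus markers.  Returns the .vhdr path.
    """
    basepath = Path(basepath)
    stem = basepath.with_suffix("")
    data = np.atleast_2d(np.asarray(data, float))
    channel_names = validate_channels(channel_names)
    if data.shape[0] != len(channel_names):
        raise ValueError("channel count mismatch")

    eeg_path = stem.with_suffix(".eeg")
    vmrk_path = stem.with_suffix(".vmrk")
    vhdr_path = stem.with_suffix(".vhdr")

    data.astype("<f4").T.tofile(eeg_path)  # multiplexed = sample-major

    ch_lines = "\n".join(
        f"Ch{i + 1}={name},,1,µV"
        for i, name in enumerate(channel_names))
    vhdr_path.write_text(
        "Brain Vision Data Exchange Header File Version 1.0\n"
        "; written by smrpipe\n"
        "[Common Infos]\nCodepage=UTF-8\n"
        f"DataFile={eeg_path.name}\nMarkerFile={vmrk_path.name}\n"
        "DataFormat=BINARY\nDataOrientation=MULTIPLEXED\n"
        f"NumberOfChannels={len(channel_names)}\n"
        f"SamplingInterval={1e6 / fs:g}\n"
        "[Binary Infos]\nBinaryFormat=IEEE_FLOAT_32\n"
        f"[Channel Infos]\n{ch_lines}\n",
        encoding="utf-8")

    lines = [
        "Brain Vision Data Exchange Marker File, Version 1.0",
        "[Common Infos]", "Codepage=UTF-8", f"DataFile={eeg_path.name}",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,20000101000000000000",
    ]
    for k, (onset, duration, text) in enumerate(markers, start=2):
        pos = int(round(onset * fs)) + 1  # 1-based samples
        dur = int(round(duration * fs))
        lines.append(f"Mk{k}=Stimulus,{text},{pos},{dur},0")
    vmrk_path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return vhdr_path


# ---------------------------------------------------------------------------
# reading (through MNE) and epoching


def read_raw(path):
    """Read an EDF or BrainVision file; (data uV, fs, names, annotations).

    Annotations are returned as a DataFrame with onset/duration/
    description columns.  Channels are validated against the montage.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() not in (".edf", ".vhdr"):
        raise ValueError(f"unsupported EEG format: {path.name}")
    try:
        if path.suffix.lower() == ".edf":
            raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
        else:
            raw = mne.io.read_raw_brainvision(path, preload=True,
                                              verbose="error")
    except Exception as err:
        raise ValueError(f"could not read {path.name}: {err}") from err
    names = [n.removeprefix("EEG ").strip() for n in raw.ch_names]
    names = validate_channels(names)
    data = raw.get_data() * 1e6  # MNE works in volts
    ann = pd.DataFrame({
        "onset": raw.annotations.onset,
        "duration": raw.annotations.duration,
        "description": raw.annotations.description,
    })
    return data, float(raw.info["sfreq"]), names, ann


def epochs_from_raw(
    data: np.ndarray,
    fs: float,
    channel_names,
    annotations: pd.DataFrame,
    subject: str = "unknown",
    day: int = 1,
    run: int = 0,
    trial_length_s: float = 6.0,
) -> EpochedEEG:
    """Cut trial epochs at the coded cue markers of one run."""
    n_trial = int(round(trial_length_s * fs))
    epochs, rows = [], []
    k = 0
    for _, ann in annotations.iterrows():
        meta = parse_marker(str(ann["description"]))
        if meta is None:
            continue
        start = int(round(ann["onset"] * fs))
        if start + n_trial > data.shape[1]:
            continue
        epochs.append(data[:, start:start + n_trial])
        rows.append({"subject": subject, "day": day, "run": run, "trial": k,
                     **{k2: v for k2, v in meta.items()}})
        k += 1
    if not epochs:
        raise ValueError("no trial markers found in annotations")
    return EpochedEEG(np.stack(epochs), fs, list(channel_names),
                      pd.DataFrame(rows))


def write_session(
    out_dir,
    plan,
    sources,
    noise_level: float = 10.0,
    seed: int = 0,
    fmt: str = "edf",
) -> list[Path]:
    """Render a synthetic session run-by-run to EDF+ or BrainVision files.

    Epoching the written files reproduces
    :func:`smrpipe.synthetic.generate_session` with the same arguments.
    """
    from .synthetic import iter_session_runs

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for run_index, run, data, cues, rows in iter_session_runs(
            plan, sources, noise_level, seed):
        markers = [
            (cue / plan.sampling_rate_hz, plan.trial_length_s,
             marker_code(row["condition"], row["imagery_type"],
                         row["feedback_flag"]))
            for cue, row in zip(cues, rows)
        ]
        stem = out_dir / (f"{plan.subject_id}_day{plan.day_index}"
                          f"_run{run_index:02d}_{run.imagery_type}")
        if fmt == "edf":
            paths.append(write_edf(stem.with_suffix(".edf"), data,
                                   plan.sampling_rate_hz,
                                   annotations=markers))
        elif fmt == "brainvision":
            paths.append(write_brainvision(stem, data,
                                           plan.sampling_rate_hz,
                                           markers=markers))
        else:
            raise ValueError("fmt must be 'edf' or 'brainvision'")
    return paths


# ---------------------------------------------------------------------------
# tables and decompositions


def write_erdd_csv(path, table: pd.DataFrame) -> Path:
    missing = set(ERDD_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"ERDd table lacks columns {sorted(missing)}")
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_erdd_csv(path, column_map: dict | None = None) -> pd.DataFrame:
    """Read a run-level ERDd table; ``column_map`` renames foreign columns."""
    table = pd.read_csv(path)
    if column_map:
        table = table.rename(columns=column_map)
    missing = set(ERDD_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"ERDd table lacks columns {sorted(missing)}")
    table["isFeedbacked"] = table["isFeedbacked"].astype(bool)
    return table


def save_decomposition(basepath, decomp, metadata: dict | None = None):
    """Persist a decomposition as .npz matrices + JSON sidecar."""
    basepath = Path(basepath)
    np.savez(basepath.with_suffix(".npz"), W=decomp.W, A=decomp.A,
             eigenvalues=decomp.eigenvalues,
             selected_erd_indices=decomp.selected_erd_indices)
    meta = {"channel_names": list(CHANNELS)}
    meta.update(metadata or {})
    basepath.with_suffix(".json").write_text(json.dumps(meta, indent=2))
    return basepath.with_suffix(".npz")


def load_decomposition(basepath):
    from .ged import SpatialDecomposition

    basepath = Path(basepath)
    arrays = np.load(basepath.with_suffix(".npz"))
    meta = json.loads(basepath.with_suffix(".json").read_text())
    dec = SpatialDecomposition(
        W=arrays["W"], eigenvalues=arrays["eigenvalues"], A=arrays["A"],
        selected_erd_indices=arrays["selected_erd_indices"])
    return dec, meta
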