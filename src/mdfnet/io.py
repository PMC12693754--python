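"""On-disk formats: EDF export, cohort fixture bundles and segment stores.

EDF files are written directly in the 16-bit EDF layout (256-byte fixed
header, 256 bytes per signal, 1-second data records of little-endian int16
with per-channel physical scaling) and read back through MNE, which serves
as an independent decoder of what we write.  Cohort fixture bundles and
segment tensors use NumPy ``.npz`` archives with a CSV metadata/index table
alongside.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .preprocess import Segment
from .synth import CHANNELS_32, ConfigurationError, RawRecording, SubjectMeta

__all__ = [
    "write_edf", "read_edf", "write_cohort_edf",
    "save_cohort_bundle", "load_cohort_bundle",
    "save_segments", "load_segments",
]

logger = logging.getLogger("mdfnet.io")


def _ascii(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def write_edf(rec: RawRecording, path: str | Path) -> Path:
    """Write one recording as a 16-bit EDF file (1-second data records)."""
    path = Path(path)
    fs = rec.sampling_rate
    if abs(fs - round(fs)) > 1e-9:
        raise ConfigurationError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per record per signal
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ConfigurationError("recording shorter than one 1-s EDF record")
    if n_records * spr != rec.n_samples:
        logger.warning("EDF export truncates %d trailing samples",
                       rec.n_samples - n_records * spr)
    x = rec.signal[:, : n_records * spr]
    n_sig = rec.n_channels

    phys_max = np.maximum(np.abs(x).max(axis=1), 1e-6)
    scale = 32767.0 / phys_max
    digital = np.clip(np.rint(x * scale[:, None]), -32768, 32767).astype("<i2")

    m = rec.meta
    # EDF+ local patient identification: code sex birthdate name
    patient = f"{m.subject_id} {m.sex} X {m.label}-{m.age:.1f}"
    buf = _io.BytesIO()
    buf.write(_ascii("0", 8))
    buf.write(_ascii(patient, 80))
    buf.write(_ascii("synthetic EEG cohort", 80))
    buf.write(_ascii("01.01.24", 8))
    buf.write(_ascii("00.00.00", 8))
    buf.write(_ascii(256 * (1 + n_sig), 8))
    buf.write(_ascii("", 44))
    buf.write(_ascii(n_records, 8))
    buf.write(_ascii(1, 8))
    buf.write(_ascii(n_sig, 4))
    for name in rec.channel_names:
        buf.write(_ascii(f"EEG {name}", 16))
    for _ in range(n_sig):
        buf.write(_ascii("AgAgCl electrode", 80))
    for _ in range(n_sig):
        buf.write(_ascii("uV", 8))
    for pm in phys_max:
        buf.write(_ascii(f"{-pm:.6g}"[:8], 8))
    for pm in phys_max:
        buf.write(_ascii(f"{pm:.6g}"[:8], 8))
    for _ in range(n_sig):
        buf.write(_ascii(-32768, 8))
    for _ in range(n_sig):
        buf.write(_ascii(32767, 8))
    for _ in range(n_sig):
        buf.write(_ascii("", 80))
    for _ in range(n_sig):
        buf.write(_ascii(spr, 8))
    for _ in range(n_sig):
        buf.write(_ascii("", 32))
    for r in range(n_records):
        buf.write(digital[:, r * spr:(r + 1) * spr].tobytes())
    path.write_bytes(buf.getvalue())
    return path


def read_edf(path: str | Path) -> RawRecording:
    """Read an EDF file through MNE and rebuild a RawRecording (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6  # MNE returns volts
    names = tuple(n.removeprefix("EEG ").strip() for n in raw.ch_names)
    meta = _parse_patient(raw.info.get("subject_info") or {}, Path(path).stem)
    return RawRecording(meta=meta, sampling_rate=float(raw.info["sfreq"]),
                        signal=data_uv, channel_names=names)


def _parse_patient(subject_info: dict, fallback_id: str) -> SubjectMeta:
    try:
        sid = str(subject_info["his_id"])
        sex = {1: "M", 2: "F"}[subject_info["sex"]]
        label, age_text = str(subject_info["last_name"]).split("-")
        age = float(age_text)
        hy = 2 if label == "PD" else None  # stage is not carried by the EDF header
        return SubjectMeta(subject_id=sid, label=label, age=age, sex=sex, hoehn_yahr=hy)
    except (KeyError, ValueError):
        logger.warning("EDF patient field not in the cohort encoding; using defaults")
        return SubjectMeta(subject_id=fallback_id, label="HC", age=60.0, sex="F")


def write_cohort_edf(recordings: list[RawRecording], outdir: str | Path) -> Path:
    """One EDF per subject plus a metadata CSV table."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for rec in recordings:
        write_edf(rec, outdir / f"{rec.meta.subject_id}.edf")
        rows.append({"subject_id": rec.meta.subject_id, "label": rec.meta.label,
                     "age": rec.meta.age, "sex": rec.meta.sex})
    table = outdir / "metadata.csv"
    pd.DataFrame(rows).to_csv(table, index=False)
    return table


# --------------------------------------------------------------------------- #
# compact fixture bundles
# --------------------------------------------------------------------------- #
def save_cohort_bundle(recordings: list[RawRecording], path: str | Path) -> Path:
    path = Path(path).with_suffix(".npz")
    path.parent.mkdir(parents=True, exist_ok=True)
    arrays = {}
    meta_rows = []
    for i, rec in enumerate(recordings):
        arrays[f"signal_{i}"] = rec.signal.astype(np.float32)
        m = rec.meta
        meta_rows.append([m.subject_id, m.label, m.age, m.sex,
                          -1 if m.hoehn_yahr is None else m.hoehn_yahr,
                          rec.sampling_rate])
    arrays["meta"] = np.array(meta_rows, dtype=object)
    arrays["channel_names"] = np.array(
        recordings[0].channel_names if recordings else CHANNELS_32, dtype=object)
    np.savez_compressed(path, **{k: v for k, v in arrays.items()},
                        allow_pickle=True)
    return path


def load_cohort_bundle(path: str | Path) -> list[RawRecording]:
    with np.load(Path(path), allow_pickle=True) as data:
        meta = data["meta"]
        names = tuple(data["channel_names"])
        out = []
        for i, row in enumerate(meta):
            sid, label, age, sex, hy, fs = row
            m = SubjectMeta(subject_id=str(sid), label=str(label), age=float(age),
                            sex=str(sex),
                            hoehn_yahr=None if int(hy) < 0 else int(hy))
            out.append(RawRecording(meta=m, sampling_rate=float(fs),
                                    signal=np.asarray(data[f"signal_{i}"], dtype=np.float64),
                                    channel_names=names))
    return out


# --------------------------------------------------------------------------- #
# segment stores (array file + CSV index)
# --------------------------------------------------------------------------- #
def save_segments(segments: list[Segment], prefix: str | Path) -> tuple[Path, Path]:
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    data = np.stack([s.data for s in segments]).astype(np.float32)
    npz = prefix.with_suffix(".npz")
    np.savez_compressed(npz, data=data)
    index = pd.DataFrame({
        "subject_id": [s.subject_id for s in segments],
        "label": [s.label for s in segments],
        "start_time": [s.start_time for s in segments],
        "sampling_rate": [s.sampling_rate for s in segments],
    })
    csv = prefix.with_suffix(".csv")
    index.to_csv(csv, index=False)
    return npz, csv


def load_segments(prefix: str | Path) -> list[Segment]:
    prefix = Path(prefix)
    with np.load(prefix.with_suffix(".npz")) as data:
        arr = np.asarray(data["data"], dtype=np.float64)
    index = pd.read_csv(prefix.with_suffix(".csv"))
    return [
        Segment(subject_id=str(row.subject_id), label=str(row.label),
                start_time=float(row.start_time), data=arr[i],
                sampling_rate=float(row.sampling_rate))
        for i, row in enumerate(index.itertuples())
    ]
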