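"""On-disk formats: EDF/EDF+ recordings, stage-sequence and cohort CSVs.

Reading EDF goes through :mod:`mne`.  Writing is a small self-contained
16-bit EDF writer (EDF+C when annotations are present) because no EDF
export library is part of this package's dependency set; the round trip
through the mne reader is covered by tests and is exact to one quantization
step of the 16-bit encoding.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd

from .recording import Annotation, EEGRecording, StageSequence


# ---------------------------------------------------------------------------
# EDF
# ---------------------------------------------------------------------------

def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def _fmt_num(x: float, width: int) -> bytes:
    for prec in range(7, -1, -1):
        s = f"{x:.{prec}f}".rstrip("0").rstrip(".")
        if len(s) <= width:
            return _pad(s, width)
    return _pad(str(int(round(x))), width)


def write_edf(rec: EEGRecording, path) -> None:
    """Write a recording as 16-bit EDF (EDF+C when annotated).

    One data record per second; the sampling rate must therefore be a whole
    number of samples per second.  Physical scaling is per channel from the
    data extrema, so the quantization step is ``ptp/65535``.
    """
    sfreq = rec.sfreq
    spr = int(round(sfreq))
    if abs(spr - sfreq) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_records = rec.n_samples // spr
    if n_records == 0:
        raise ValueError("recording shorter than one data record")
    data = rec.data[:, :n_records * spr]

    has_ann = bool(rec.annotations)
    tals = b""
    if has_ann:
        for ann in rec.annotations:
            tals += (f"+{ann.onset:g}\x15{ann.duration:g}\x14"
                     f"{ann.label}\x14\x00").encode("utf-8")
    # annotation signal sized to hold the timestamp TAL plus all event TALs
    ann_bytes = max(64, ((len(tals) + 16) + 1) // 2 * 2)
    ann_spr = ann_bytes // 2

    n_sig = rec.n_channels + (1 if has_ann else 0)
    header_bytes = 256 * (1 + n_sig)

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-6
    pmin = np.where(flat, pmin - 1.0, pmin)
    pmax = np.where(flat, pmax + 1.0, pmax)

    now = _dt.datetime(2000, 1, 1)
    with open(path, "wb") as f:
        f.write(_pad("0", 8))
        f.write(_pad("X X X X", 80))
        f.write(_pad("Startdate 01-JAN-2000 X X X", 80))
        f.write(_pad(now.strftime("%d.%m.%y"), 8))
        f.write(_pad(now.strftime("%H.%M.%S"), 8))
        f.write(_pad(str(header_bytes), 8))
        f.write(_pad("EDF+C" if has_ann else "", 44))
        f.write(_pad(str(n_records), 8))
        f.write(_pad("1", 8))
        f.write(_pad(str(n_sig), 4))

        labels = [f"EEG {c}" for c in rec.channel_labels]
        if has_ann:
            labels.append("EDF Annotations")
        for lab in labels:
            f.write(_pad(lab, 16))
        f.write(_pad("", 80) * n_sig)                      # transducer
        for i in range(n_sig):
            f.write(_pad("uV" if i < rec.n_channels else "", 8))
        for i in range(n_sig):
            f.write(_fmt_num(pmin[i] if i < rec.n_channels else -1.0, 8))
        for i in range(n_sig):
            f.write(_fmt_num(pmax[i] if i < rec.n_channels else 1.0, 8))
        f.write(_pad("-32768", 8) * n_sig)
        f.write(_pad("32767", 8) * n_sig)
        f.write(_pad("", 80) * n_sig)                      # prefiltering
        for i in range(n_sig):
            f.write(_pad(str(spr if i < rec.n_channels else ann_spr), 8))
        f.write(_pad("", 32) * n_sig)

        scale = (pmax - pmin) / 65535.0
        for r in range(n_records):
            block = data[:, r * spr:(r + 1) * spr]
            dig = np.round((block - pmin[:, None]) / scale[:, None]) - 32768
            dig = np.clip(dig, -32768, 32767).astype("<i2")
            f.write(dig.tobytes())
            if has_ann:
                rec_tal = f"+{r}\x14\x14\x00".encode("ascii")
                payload = rec_tal + (tals if r == 0 else b"")
                payload += b"\x00" * (ann_bytes - len(payload))
                f.write(payload)


def read_edf(path) -> EEGRecording:
    """Read an EDF/EDF+ file into an :class:`EEGRecording` (microvolts)."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # V -> uV
    labels = [c.removeprefix("EEG ").strip() for c in raw.ch_names]
    annotations = [
        Annotation(onset=float(a["onset"]), duration=float(a["duration"]),
                   label=str(a["description"]))
        for a in raw.annotations
    ]
    return EEGRecording(data=data, channel_labels=labels,
                        sfreq=float(raw.info["sfreq"]),
                        annotations=annotations)


# ---------------------------------------------------------------------------
# CSV sidecars
# ---------------------------------------------------------------------------

def write_stage_csv(seq: StageSequence, path, artifact_col: bool = True
                    ) -> None:
    """Stage sequence as CSV with columns second_index, stage[, artifact]."""
    df = pd.DataFrame({
        "second_index": np.arange(len(seq)),
        "stage": seq.labels,
    })
    if artifact_col:
        df["artifact"] = (seq.labels == "ARTIFACT").astype(int)
    df.to_csv(path, index=False)


def read_stage_csv(path) -> StageSequence:
    df = pd.read_csv(path, dtype={"stage": str})
    return StageSequence(labels=df["stage"].to_numpy(dtype="U8"))


def write_cohort_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    return pd.read_csv(Path(path))
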