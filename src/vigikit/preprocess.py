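"""Filtering, analysis-window selection, 1-s segmentation, artifact masking,
and the surrogate slow-eye-movement (EOG) channel.

The clinical pipeline this mirrors band-passes with a zero-phase Butterworth
(0.5-70 Hz, 50 Hz notch), cuts 1-s segments, and screens artifacts.  Manual
screening and ICA are replaced here by deterministic amplitude/flatness rules
and a bipolar frontal derivation band-passed to 0.1-1 Hz standing in for the
ocular (SEM) component, so every step is reproducible without a human rater.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .recording import Annotation, EEGRecording, SegmentedEEG


@dataclass
class PreprocessConfig:
    highpass: float = 0.5          # Hz
    lowpass: float = 70.0          # Hz
    notch: float = 50.0            # Hz
    filter_order: int = 4          # Butterworth order, applied forward-backward
    amp_reject_uv: float = 150.0   # any |sample| above this masks the segment
    flat_reject_uv: float = 1.0    # all-channel peak-to-peak below this masks
    sem_band: tuple = (0.1, 1.0)   # Hz band of the surrogate EOG
    sem_channel_pair: tuple = ("F7", "F8")
    analysis_minutes: float = 8.0
    hyperventilation_label: str = "hyperventilation"

    def validate(self, sfreq: float) -> None:
        if not 0 < self.highpass < self.lowpass:
            raise ValueError("require 0 < highpass < lowpass")
        if self.lowpass >= sfreq / 2:
            raise ValueError(
                f"low-pass {self.lowpass} Hz requires sampling rate > "
                f"{2 * self.lowpass} Hz (got {sfreq})")


def filter_recording(rec: EEGRecording, cfg: PreprocessConfig) -> EEGRecording:
    """Zero-phase Butterworth band-pass plus line-frequency notch."""
    cfg.validate(rec.sfreq)
    if rec.duration < 10.0:
        raise ValueError("recording shorter than 10 s cannot be filtered reliably")
    sos = signal.butter(cfg.filter_order, (cfg.highpass, cfg.lowpass),
                        btype="bandpass", fs=rec.sfreq, output="sos")
    out = signal.sosfiltfilt(sos, rec.data, axis=1)
    if cfg.notch and cfg.notch < rec.sfreq / 2:
        b, a = signal.iirnotch(cfg.notch, Q=30.0, fs=rec.sfreq)
        out = signal.filtfilt(b, a, out, axis=1)
    return EEGRecording(data=out, channel_labels=list(rec.channel_labels),
                        sfreq=rec.sfreq, annotations=list(rec.annotations))


def select_analysis_window(rec: EEGRecording, cfg: PreprocessConfig
                           ) -> tuple[EEGRecording, bool]:
    """First ``analysis_minutes`` of non-hyperventilation data.

    The window starts at the recording start and is truncated at the onset of
    the first annotated hyperventilation block.  Returns ``(windowed
    recording, short_flag)``; the flag is set when less than the requested
    span was available.
    """
    usable_end = rec.duration
    for ann in rec.annotations:
        if ann.label.lower() == cfg.hyperventilation_label:
            usable_end = min(usable_end, ann.onset)
    if usable_end <= 0:
        raise ValueError("no usable (non-hyperventilation) data")
    want = cfg.analysis_minutes * 60.0
    end = min(want, usable_end)
    short = end < want
    n = int(round(end * rec.sfreq))
    kept = [Annotation(a.onset, a.duration, a.label) for a in rec.annotations
            if a.onset < end]
    return EEGRecording(data=rec.data[:, :n],
                        channel_labels=list(rec.channel_labels),
                        sfreq=rec.sfreq, annotations=kept), short


def segment_recording(rec: EEGRecording, *, short_flag: bool = False
                      ) -> SegmentedEEG:
    """Cut a (filtered) recording into consecutive 1-s segments."""
    n_per = int(round(rec.sfreq))
    n_seg = rec.n_samples // n_per
    if n_seg == 0:
        raise ValueError("recording shorter than one segment")
    data = rec.data[:, :n_seg * n_per].reshape(rec.n_channels, n_seg, n_per)
    return SegmentedEEG(data=np.swapaxes(data, 0, 1),
                        channel_labels=list(rec.channel_labels),
                        sfreq=rec.sfreq,
                        analysis_window=(0.0, float(n_seg)),
                        short_recording=short_flag)


def mark_artifacts(seg: SegmentedEEG, cfg: PreprocessConfig) -> SegmentedEEG:
    """Mask segments by amplitude excursion or all-channel flatness.

    A segment is masked when any channel exceeds ``amp_reject_uv`` in
    absolute amplitude, or when every channel's peak-to-peak falls below
    ``flat_reject_uv`` (electrode dropout).  Lowering ``amp_reject_uv`` can
    only grow the masked set.
    """
    amp = np.abs(seg.data).max(axis=(1, 2))
    ptp = seg.data.max(axis=2) - seg.data.min(axis=2)  # (n_seg, n_ch)
    mask = (amp > cfg.amp_reject_uv) | (ptp.max(axis=1) < cfg.flat_reject_uv)
    seg.artifact_mask = mask
    return seg


def derive_sem_signal(rec: EEGRecording, cfg: PreprocessConfig) -> np.ndarray:
    """Surrogate slow-eye-movement channel.

    Band-passed (``sem_band``, default 0.1-1 Hz) difference of the two
    configured frontal channels.  Horizontal ocular drifts project with
    opposite polarity onto F7 and F8, so the bipolar derivation doubles the
    ocular signal while cancelling symmetric cortical activity.  Must be
    derived from the *unfiltered* recording: the 0.5 Hz analysis high-pass
    would remove the drifts themselves.
    """
    ch_a, ch_b = cfg.sem_channel_pair
    try:
        diff = rec.channel(ch_a) - rec.channel(ch_b)
    except KeyError as err:
        raise ValueError(f"SEM channel pair {cfg.sem_channel_pair} "
                         "missing from recording") from err
    lo, hi = cfg.sem_band
    sos = signal.butter(2, (lo, hi), btype="bandpass", fs=rec.sfreq,
                        output="sos")
    return signal.sosfiltfilt(sos, diff)


def preprocess(rec: EEGRecording, cfg: PreprocessConfig | None = None
               ) -> SegmentedEEG:
    """Full preprocessing chain: window, surrogate EOG, filter, segment, mask."""
    cfg = cfg or PreprocessConfig()
    windowed, short = select_analysis_window(rec, cfg)
    sem = derive_sem_signal(windowed, cfg)
    filtered = filter_recording(windowed, cfg)
    seg = segment_recording(filtered, short_flag=short)
    seg.sem_signal = sem[:seg.n_segments * int(round(rec.sfreq))]
    return mark_artifacts(seg, cfg)
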