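"""In-memory containers for multichannel EEG and derived per-second data."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .stages import as_label_array

#: The 19 scalp electrodes of the basic international 10-20 montage, in the
#: conventional anterior-to-posterior order used by clinical EEG systems.
MONTAGE_10_20: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)


@dataclass
class Annotation:
    """A labeled time interval (seconds relative to recording start)."""

    onset: float
    duration: float
    label: str


@dataclass
class EEGRecording:
    """Multichannel EEG time series.

    Parameters
    ----------
    data
        Array of shape ``(n_channels, n_samples)`` in microvolts.
    channel_labels
        Unique 10-20 electrode names, one per row of ``data``.
    sfreq
        Sampling frequency in Hz.
    annotations
        Labeled intervals, e.g. a ``"hyperventilation"`` block.
    """

    data: np.ndarray
    channel_labels: list[str]
    sfreq: float
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.sfreq <= 0:
            raise ValueError("sampling frequency must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError("one label per data row required")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValueError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.sfreq

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channel_labels.index(label)]
        except ValueError as err:
            raise KeyError(f"channel {label!r} not in recording") from err


@dataclass
class SegmentedEEG:
    """Filtered recording cut into consecutive 1-s segments.

    ``data`` has shape ``(n_segments, n_channels, samples_per_segment)``.
    ``artifact_mask`` is True where a segment is rejected.  ``sem_signal`` is
    the surrogate slow-eye-movement channel (full-length, same sampling rate,
    derived from the *unfiltered* recording so sub-0.5 Hz ocular drifts
    survive).  ``analysis_window`` is the (start, end) of the analyzed span in
    recording-relative seconds.
    """

    data: np.ndarray
    channel_labels: list[str]
    sfreq: float
    artifact_mask: np.ndarray = None
    sem_signal: np.ndarray | None = None
    analysis_window: tuple[float, float] = (0.0, 0.0)
    short_recording: bool = False

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("segment data must be (n_segments, n_channels, n_samples)")
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.n_segments, dtype=bool)
        self.artifact_mask = np.asarray(self.artifact_mask, dtype=bool)
        if self.artifact_mask.shape != (self.n_segments,):
            raise ValueError("artifact mask length must equal segment count")

    @property
    def n_segments(self) -> int:
        return self.data.shape[0]

    def channel_indices(self, labels) -> list[int]:
        missing = [c for c in labels if c not in self.channel_labels]
        if missing:
            raise KeyError(f"channels not present: {missing}")
        return [self.channel_labels.index(c) for c in labels]


@dataclass
class StageSequence:
    """Per-second vigilance labels with artifact placeholders.

    ``labels`` holds one stage label per 1-s segment (``ARTIFACT`` for
    rejected segments); ``t0`` is the recording-relative start time of the
    first segment in seconds.
    """

    labels: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.labels = as_label_array(self.labels)

    def __len__(self) -> int:
        return self.labels.size

    @property
    def artifact_free(self) -> np.ndarray:
        """Labels of artifact-free segments, order preserved."""
        return self.labels[self.labels != "ARTIFACT"]

    @property
    def n_artifact_free(self) -> int:
        return int(np.sum(self.labels != "ARTIFACT"))

    @property
    def artifact_fraction(self) -> float:
        return 1.0 - self.n_artifact_free / len(self)
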