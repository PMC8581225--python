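"""Arousal outcome measures computed from a per-second stage sequence.

Three outcomes summarize an 8-minute resting recording:

* **stage-occurrence percentages** — share of artifact-free 1-s segments per
  stage (percentages sum to 100);
* **mean vigilance level** — artifact-free average of the numeric stage codes
  {0: 6, A1: 5, A2: 4, A3: 3, B1: 2, B2/3: 1}; higher = more aroused;
* **arousal stability index** — ordinal 1-8 score of how early and how deep
  vigilance declines, scored from the whole sequence and its 160-s thirds:

  ========================================================  =====
  criterion                                                 score
  ========================================================  =====
  > 2/3 of all segments classified as 0 or A1                 8
  >= 2/3 of all segments classified as 0, A1, A2 or A3        7
  >= 1/3 of last 160 s classified as B1                       6
  >= 1/3 of second 160 s classified as B1                     5
  >= 1/3 of first 160 s classified as B1                      4
  >= 1/3 of last 160 s classified as B2/3                     3
  >= 1/3 of second 160 s classified as B2/3                   2
  >= 1/3 of first 160 s classified as B2/3                    1
  ========================================================  =====

  When several criteria hold, the minimum satisfied score among 1-6 wins
  (the earliest/deepest drowsiness event dominates); if none of 1-6 holds,
  8 is checked before 7.  Diffuse B1 patterns can satisfy no criterion; then
  7 is returned with an explicit fallback flag rather than an out-of-range
  score.

All denominators exclude artifact segments; thirds are wall-clock thirds of
the analyzed span with per-third artifact-free denominators.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .recording import StageSequence
from .stages import STAGE_CODE, STAGE_ORDER


class UndefinedMetricError(ValueError):
    """Raised when a metric has an empty artifact-free denominator."""


@dataclass
class ArousalSummary:
    """Per-subject arousal outcomes."""

    stability: int
    mean_vigilance: float
    occurrence: dict
    n_artifact_free: int
    fallback_flag: bool = False
    short_flag: bool = False


def _artifact_free(seq: StageSequence) -> np.ndarray:
    labels = seq.artifact_free
    if labels.size == 0:
        raise UndefinedMetricError("all segments are artifacts")
    return labels


def stage_percentages(seq: StageSequence) -> dict:
    """Occurrence percentage per stage on the artifact-free denominator."""
    labels = _artifact_free(seq)
    n = labels.size
    return {s: 100.0 * np.sum(labels == s) / n for s in STAGE_ORDER}


def mean_vigilance(seq: StageSequence) -> float:
    """Mean arousal level: artifact-free average of the stage codes."""
    labels = _artifact_free(seq)
    codes = np.array([STAGE_CODE[s] for s in labels], dtype=float)
    return float(codes.mean())


def mean_vigilance_from_occurrence(occurrence: dict) -> float:
    """Occurrence-weighted stage-code sum: sum(pct * code) / 100.

    Identical to :func:`mean_vigilance` when the percentages come from the
    same sequence; also applicable to published group-mean percentage rows.
    """
    return sum(occurrence.get(s, 0.0) * STAGE_CODE[s] for s in STAGE_ORDER) / 100.0


def _third_slices(n: int) -> tuple[slice, slice, slice]:
    """Wall-clock thirds (first/second/last) of an n-second span."""
    a, b = n // 3, (2 * n) // 3
    return slice(0, a), slice(a, b), slice(b, n)


def _fraction_in(labels: np.ndarray, members: tuple) -> float:
    """Fraction of artifact-free labels within ``members``; 0 if empty."""
    free = labels[labels != "ARTIFACT"]
    if free.size == 0:
        return 0.0
    return float(np.isin(free, members).mean())


def stability_index(seq: StageSequence) -> tuple[int, bool]:
    """Arousal stability score (1-8) and a no-criterion fallback flag.

    Sequences shorter or longer than the 480-s analysis window are scored on
    wall-clock thirds of their actual span; callers should carry the
    short-recording flag from segmentation.
    """
    labels = seq.labels
    _artifact_free(seq)  # raises on empty denominator
    first, second, last = _third_slices(labels.size)

    frac_all_0A1 = _fraction_in(labels, ("0", "A1"))
    frac_all_A = _fraction_in(labels, ("0", "A1", "A2", "A3"))
    third_labels = (labels[first], labels[second], labels[last])

    satisfied = []
    # scores 1/2/3: B2/3 in first/second/last third; 4/5/6: same for B1
    for score, (stage, third) in enumerate(
        [("B23", 0), ("B23", 1), ("B23", 2), ("B1", 0), ("B1", 1), ("B1", 2)],
        start=1,
    ):
        if _fraction_in(third_labels[third], (stage,)) >= 1.0 / 3.0:
            satisfied.append(score)
    if satisfied:
        return min(satisfied), False
    if frac_all_0A1 > 2.0 / 3.0:
        return 8, False
    if frac_all_A >= 2.0 / 3.0:
        return 7, False
    return 7, True


def vigilance_timecourse(seq: StageSequence) -> np.ndarray:
    """Sliding one-minute mean-vigilance series (60-segment window, step 1).

    Window means use artifact-free members only; windows that are entirely
    artifact yield NaN.  Sequences with fewer than 60 segments give an empty
    series.
    """
    labels = seq.labels
    if labels.size < 60:
        return np.array([])
    codes = np.array([STAGE_CODE.get(s, np.nan) for s in labels], dtype=float)
    out = np.empty(labels.size - 59)
    for i in range(out.size):
        window = codes[i:i + 60]
        valid = window[~np.isnan(window)]
        out[i] = valid.mean() if valid.size else np.nan
    return out


def arousal_summary(seq: StageSequence, short_flag: bool = False) -> ArousalSummary:
    """Bundle all arousal outcomes for one subject."""
    occ = stage_percentages(seq)
    stability, fallback = stability_index(seq)
    return ArousalSummary(
        stability=stability,
        mean_vigilance=mean_vigilance(seq),
        occurrence=occ,
        n_artifact_free=seq.n_artifact_free,
        fallback_flag=fallback,
        short_flag=short_flag,
    )
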