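"""Per-second vigilance staging from adaptive alpha/theta band power.

Each artifact-free 1-s segment is classified into one of six stages by a
rule cascade over regional band powers, with the alpha band centered on the
individually estimated alpha peak frequency (iAPF):

1. occipital relative alpha >= ``alpha_dominance_threshold`` -> A-stage,
   sub-staged by the frontal/occipital alpha amplitude ratio rho
   (A1 if rho < ``anterior_ratio_a1``, A2 if rho < ``anterior_ratio_a2``,
   else A3 — alpha anteriorization marks the descent within A);
2. otherwise relative theta >= ``theta_dominance_threshold`` -> B2/3;
3. otherwise B1 if a slow eye movement is detected in that second, else 0.

Relative powers are normalized by the 4-30 Hz total band: the delta range is
deliberately excluded so that low-frequency (often non-neuronal) content
cannot change a label.  Source localization used by the reference tool is
replaced by channel-space regional power (occipital vs frontal electrode
sets), which preserves the occipital-vs-anterior logic that defines the
A-substages on a plain 10-20 montage.

Recording-level validation applies four inclusion constraints: plausible
iAPF (8.5-12.5 Hz), artifact fraction < 15%, plausibly detected alpha
(aggregate occipital alpha power above an amplifier-dependent threshold and
alpha present in early segments), and < 95% of segments in {0, B1} (to
exclude low-voltage EEG).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .recording import SegmentedEEG, StageSequence
from .synth_sets import FRONTAL_SET, OCCIPITAL_SET


@dataclass
class StagingConfig:
    iapf_search_band: tuple = (7.0, 13.0)
    alpha_halfwidth: float = 2.0            # Hz; alpha band = iapf +/- this
    theta_band: tuple = (4.0, 7.5)
    total_band: tuple = (4.0, 30.0)         # delta excluded by design
    occipital_set: tuple = OCCIPITAL_SET
    frontal_set: tuple = FRONTAL_SET
    alpha_dominance_threshold: float = 0.40
    anterior_ratio_a1: float = 0.5
    anterior_ratio_a2: float = 1.0
    theta_dominance_threshold: float = 0.50
    sem_amp_threshold: float = 15.0         # uV on the surrogate EOG
    sem_min_duration: float = 0.3           # s above threshold to count
    alpha_power_threshold: float = 25000.0  # opaque amplifier units
    early_window_s: float = 120.0           # "alpha detected early" horizon
    min_segments_iapf: int = 30
    no_alpha_factor: float = 2.0            # peak must exceed this x 1/f trend
    min_total_power: float = 1.0            # uV^2; below this a segment is
                                            # low voltage and only the SEM
                                            # rule applies

    def validate(self) -> None:
        for name in ("iapf_search_band", "theta_band", "total_band"):
            lo, hi = getattr(self, name)
            if not 0 < lo < hi:
                raise ValueError(f"{name} must be an increasing positive pair")
        if not 0 < self.anterior_ratio_a1 < self.anterior_ratio_a2:
            raise ValueError("require 0 < anterior_ratio_a1 < anterior_ratio_a2")


@dataclass
class IAPFEstimate:
    """Individual alpha peak frequency with a detection flag."""

    frequency: float
    alpha_detected: bool


@dataclass
class SpectralFeatures:
    """Regional band powers of one 1-s segment (uV^2)."""

    occ_alpha: float
    occ_theta: float
    occ_total: float
    front_alpha: float
    front_total: float

    @property
    def rel_alpha(self) -> float:
        return self.occ_alpha / self.occ_total if self.occ_total > 0 else 0.0

    @property
    def rel_theta(self) -> float:
        return self.occ_theta / self.occ_total if self.occ_total > 0 else 0.0

    @property
    def anterior_ratio(self) -> float:
        """Frontal/occipital alpha ratio on the amplitude scale."""
        if self.occ_alpha <= 0:
            return np.inf
        return float(np.sqrt(self.front_alpha / self.occ_alpha))


@dataclass
class ValidationReport:
    iapf: float
    artifact_fraction: float
    alpha_abs_power: float
    alpha_detected_early: bool
    fraction_0_or_B1: float
    passed: bool
    reasons: list = field(default_factory=list)


@dataclass
class StagingResult:
    stages: StageSequence
    iapf: IAPFEstimate
    alpha_abs_power: float
    sem_flags: np.ndarray


# ---------------------------------------------------------------------------
# iAPF
# ---------------------------------------------------------------------------

def _parabolic_refine(freqs: np.ndarray, psd: np.ndarray, i: int) -> float:
    """Parabolic interpolation of a peak across its two neighbors."""
    if i == 0 or i == psd.size - 1:
        return float(freqs[i])
    y0, y1, y2 = psd[i - 1], psd[i], psd[i + 1]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        return float(freqs[i])
    delta = 0.5 * (y0 - y2) / denom
    return float(freqs[i] + delta * (freqs[1] - freqs[0]))


def estimate_iapf(seg: SegmentedEEG, cfg: StagingConfig | None = None
                  ) -> IAPFEstimate:
    """Estimate the individual alpha peak frequency.

    Welch spectrum of the occipital-average signal over artifact-free
    segments; the peak inside ``iapf_search_band`` is refined by parabolic
    interpolation.  Near-tied peaks (within 5% relative power) resolve to
    the lower frequency.  Alpha counts as undetected when no candidate peak
    rises above ``no_alpha_factor`` times the fitted 1/f trend.
    """
    cfg = cfg or StagingConfig()
    cfg.validate()
    free = ~seg.artifact_mask
    if int(free.sum()) < cfg.min_segments_iapf:
        raise ValueError(
            f"need >= {cfg.min_segments_iapf} artifact-free segments "
            f"to estimate iAPF (got {int(free.sum())})")
    occ_idx = seg.channel_indices([c for c in cfg.occipital_set
                                   if c in seg.channel_labels])
    # occipital average, artifact-free segments concatenated
    x = seg.data[free][:, occ_idx, :].mean(axis=1).ravel()
    sfreq = seg.sfreq
    nper = min(int(4 * sfreq), x.size)
    freqs, psd = signal.welch(x, fs=sfreq, nperseg=nper)

    lo, hi = cfg.iapf_search_band
    band = (freqs >= lo) & (freqs <= hi)
    psd_band = psd[band]
    freqs_band = freqs[band]
    peak_power = psd_band.max()
    # lowest-frequency near-tie wins (determinism under symmetric spectra)
    candidates = np.flatnonzero(psd_band >= 0.95 * peak_power)
    local = candidates[0]
    i_global = int(np.flatnonzero(band)[local])
    iapf = _parabolic_refine(freqs, psd, i_global)
    iapf = float(np.clip(iapf, lo, hi))

    alpha_detected = _peak_above_trend(freqs, psd, cfg, freqs_band[local])
    return IAPFEstimate(frequency=iapf, alpha_detected=alpha_detected)


def _peak_above_trend(freqs, psd, cfg, peak_freq) -> bool:
    """Is the alpha peak above the 1/f background trend?

    Log-log linear fit over the total band excluding the alpha search band.
    """
    lo, hi = cfg.iapf_search_band
    tlo, thi = cfg.total_band
    sel = (freqs >= tlo) & (freqs <= thi) & ((freqs < lo) | (freqs > hi))
    if sel.sum() < 3:
        return True
    logf = np.log(freqs[sel])
    logp = np.log(np.maximum(psd[sel], 1e-30))
    slope, intercept = np.polyfit(logf, logp, 1)
    trend_at_peak = np.exp(intercept + slope * np.log(peak_freq))
    peak_power = psd[np.argmin(np.abs(freqs - peak_freq))]
    return bool(peak_power > cfg.no_alpha_factor * trend_at_peak)


# ---------------------------------------------------------------------------
# per-segment features and classification
# ---------------------------------------------------------------------------

def _band_power(freqs: np.ndarray, psd: np.ndarray, lo: float, hi: float
                ) -> float:
    sel = (freqs >= lo) & (freqs <= hi)
    if not sel.any():
        return 0.0
    df = freqs[1] - freqs[0]
    return float(psd[sel].sum() * df)


def segment_features(segment: np.ndarray, iapf: float, cfg: StagingConfig,
                     sfreq: float, channel_labels: list) -> SpectralFeatures:
    """Regional alpha/theta/total band powers of one 1-s segment.

    ``segment`` is ``(n_channels, n_samples)``; powers are periodogram band
    integrals of the region-average PSD, alpha band = iapf +/-
    ``alpha_halfwidth``, all normalized downstream by the 4-30 Hz total band
    (delta excluded).
    """
    if segment.shape[1] < int(round(sfreq)):
        raise ValueError("segment shorter than 1 s")
    freqs, psd = signal.periodogram(segment, fs=sfreq, window="hann", axis=1)
    occ = [channel_labels.index(c) for c in cfg.occipital_set
           if c in channel_labels]
    front = [channel_labels.index(c) for c in cfg.frontal_set
             if c in channel_labels]
    psd_occ = psd[occ].mean(axis=0)
    psd_front = psd[front].mean(axis=0)
    a_lo, a_hi = iapf - cfg.alpha_halfwidth, iapf + cfg.alpha_halfwidth
    return SpectralFeatures(
        occ_alpha=_band_power(freqs, psd_occ, a_lo, a_hi),
        occ_theta=_band_power(freqs, psd_occ, *cfg.theta_band),
        occ_total=_band_power(freqs, psd_occ, *cfg.total_band),
        front_alpha=_band_power(freqs, psd_front, a_lo, a_hi),
        front_total=_band_power(freqs, psd_front, *cfg.total_band),
    )


def classify_segment(features: SpectralFeatures, sem_flag: bool,
                     cfg: StagingConfig | None = None) -> str:
    """Rule cascade: A-substages by anteriorization, then B2/3, then B1/0.

    Segments whose total 4-30 Hz power falls below ``min_total_power`` are
    low voltage: relative band fractions of near-zero power are
    uninterpretable, so only the SEM rule (B1 vs 0) is applied to them.
    """
    cfg = cfg or StagingConfig()
    if features.occ_total < cfg.min_total_power:
        return "B1" if sem_flag else "0"
    if features.rel_alpha >= cfg.alpha_dominance_threshold:
        rho = features.anterior_ratio
        if rho < cfg.anterior_ratio_a1:
            return "A1"
        if rho < cfg.anterior_ratio_a2:
            return "A2"
        return "A3"
    if features.rel_theta >= cfg.theta_dominance_threshold:
        return "B23"
    return "B1" if sem_flag else "0"


# ---------------------------------------------------------------------------
# SEM flags
# ---------------------------------------------------------------------------

def compute_sem_flags(sem_signal: np.ndarray, sfreq: float, n_segments: int,
                      cfg: StagingConfig) -> np.ndarray:
    """Per-segment slow-eye-movement flags from the surrogate EOG.

    A run of samples with ``|sem| > sem_amp_threshold`` lasting at least
    ``sem_min_duration`` counts as one SEM; a segment is flagged when at
    least 0.1 s of a qualifying run falls inside it.
    """
    if sem_signal is None:
        return np.zeros(n_segments, dtype=bool)
    supra = np.abs(sem_signal) > cfg.sem_amp_threshold
    min_len = int(round(cfg.sem_min_duration * sfreq))
    edges = np.flatnonzero(np.diff(np.concatenate(
        ([0], supra.view(np.int8), [0]))))
    qualified = np.zeros_like(supra)
    for a, b in zip(edges[::2], edges[1::2]):
        if b - a >= min_len:
            qualified[a:b] = True
    n_per = int(round(sfreq))
    flags = np.zeros(n_segments, dtype=bool)
    need = int(round(0.1 * sfreq))
    for i in range(n_segments):
        if qualified[i * n_per:(i + 1) * n_per].sum() >= need:
            flags[i] = True
    return flags


# ---------------------------------------------------------------------------
# recording-level staging and validation
# ---------------------------------------------------------------------------

def stage_recording(seg: SegmentedEEG, cfg: StagingConfig | None = None
                    ) -> StagingResult:
    """Stage every segment of a preprocessed recording.

    Artifact segments are labeled ``ARTIFACT``; all others pass through the
    rule cascade with the recording's own iAPF.  Also aggregates the
    occipital absolute alpha power (summed over artifact-free segments) used
    by validation.
    """
    cfg = cfg or StagingConfig()
    cfg.validate()
    if int((~seg.artifact_mask).sum()) < cfg.min_segments_iapf:
        # too little clean data to estimate an alpha band: nothing can be
        # staged, and validation will fail on the artifact fraction
        labels = np.full(seg.n_segments, "ARTIFACT", dtype="U8")
        return StagingResult(
            stages=StageSequence(labels=labels, t0=seg.analysis_window[0]),
            iapf=IAPFEstimate(frequency=float("nan"), alpha_detected=False),
            alpha_abs_power=0.0,
            sem_flags=np.zeros(seg.n_segments, dtype=bool))
    est = estimate_iapf(seg, cfg)
    sem_flags = compute_sem_flags(seg.sem_signal, seg.sfreq, seg.n_segments,
                                  cfg)
    labels = np.empty(seg.n_segments, dtype="U8")
    occ_count = max(1, len([c for c in cfg.occipital_set
                            if c in seg.channel_labels]))
    abs_alpha = 0.0
    for i in range(seg.n_segments):
        if seg.artifact_mask[i]:
            labels[i] = "ARTIFACT"
            continue
        feats = segment_features(seg.data[i], est.frequency, cfg, seg.sfreq,
                                 seg.channel_labels)
        labels[i] = classify_segment(feats, bool(sem_flags[i]), cfg)
        abs_alpha += feats.occ_alpha * occ_count
    stages = StageSequence(labels=labels, t0=seg.analysis_window[0])
    return StagingResult(stages=stages, iapf=est, alpha_abs_power=abs_alpha,
                         sem_flags=sem_flags)


def classify_recording(seg: SegmentedEEG, cfg: StagingConfig | None = None
                       ) -> StageSequence:
    """Convenience wrapper returning only the stage sequence."""
    return stage_recording(seg, cfg).stages


def validate_recording(result: StagingResult, cfg: StagingConfig | None = None
                       ) -> ValidationReport:
    """Apply the four recording-inclusion constraints."""
    cfg = cfg or StagingConfig()
    stages = result.stages
    labels = stages.labels
    free = labels != "ARTIFACT"
    n_free = int(free.sum())
    artifact_fraction = 1.0 - n_free / labels.size

    early = labels[:int(cfg.early_window_s)]
    alpha_early = bool(np.isin(early, ("A1", "A2", "A3")).any())
    frac_0_b1 = (float(np.isin(labels[free], ("0", "B1")).mean())
                 if n_free else 1.0)

    reasons = []
    iapf = result.iapf.frequency
    if not 8.5 <= iapf <= 12.5:
        reasons.append("iapf out of range")
    if artifact_fraction >= 0.15:
        reasons.append("artifact fraction >= 15%")
    if not result.iapf.alpha_detected:
        reasons.append("no alpha peak above 1/f trend")
    if result.alpha_abs_power <= cfg.alpha_power_threshold:
        reasons.append("absolute alpha power below threshold")
    if not alpha_early:
        reasons.append("no alpha detected on early segments")
    if frac_0_b1 >= 0.95:
        reasons.append("low-voltage EEG: >= 95% of segments 0 or B1")

    return ValidationReport(
        iapf=iapf,
        artifact_fraction=artifact_fraction,
        alpha_abs_power=result.alpha_abs_power,
        alpha_detected_early=alpha_early,
        fraction_0_or_B1=frac_0_b1,
        passed=not reasons,
        reasons=reasons,
    )
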