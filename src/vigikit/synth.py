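"""Synthetic resting-state EEG cohorts with known latent vigilance.

No public dataset accompanies the clinical material this package targets, so
the generator produces the three layers the analysis consumes:

1. latent per-second vigilance trajectories (a dwell-time Markov chain on the
   ordered stages 0 > A1 > A2 > A3 > B1 > B23, with separate per-minute
   hazards for declining and recovering arousal);
2. 19-channel 10-20 EEG realizing each trajectory second by second
   (occipital alpha for A1, anteriorized alpha for A2/A3, desynchronized
   low voltage for 0, slow-eye-movement-bearing low voltage for B1, theta
   dominance for B2/3, 1/f background, optional line noise and blinks);
3. cohort tables (ages, CBCL-like clinical T-scores, medication) with the
   statistical structure the group comparison assumes.

Everything is deterministic under a seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import arousal_summary
from .recording import MONTAGE_10_20, EEGRecording, StageSequence
from .stages import STAGE_ORDER
from .synth_sets import FRONTAL_SET, OCCIPITAL_SET


# ---------------------------------------------------------------------------
# latent trajectories
# ---------------------------------------------------------------------------

@dataclass
class TrajectoryParams:
    """Dwell-time Markov chain on the ordered vigilance stages.

    ``decline_rate`` and ``recovery_rate`` are per-minute hazards of moving
    one stage down (toward B23) or up (toward 0); they are converted to
    per-second transition probabilities ``1 - exp(-rate/60)``.  ``dwell_min``
    is the minimum number of consecutive seconds spent in a stage before the
    next transition is allowed.
    """

    n_segments: int = 480
    start_stage_probs: dict = field(
        default_factory=lambda: {"0": 0.15, "A1": 0.85}
    )
    decline_rate: float = 0.5
    recovery_rate: float = 0.25
    dwell_min: int = 1
    seed: int = 0

    def validate(self) -> None:
        if self.n_segments < 1:
            raise ValueError("n_segments must be >= 1")
        if self.decline_rate < 0 or self.recovery_rate < 0:
            raise ValueError("hazard rates must be non-negative")
        if self.dwell_min < 1:
            raise ValueError("dwell_min must be >= 1")
        probs = self.start_probs_vector()
        if abs(probs.sum() - 1.0) > 1e-12 or np.any(probs < 0):
            raise ValueError("start_stage_probs must be a probability vector")

    def start_probs_vector(self) -> np.ndarray:
        bad = set(self.start_stage_probs) - set(STAGE_ORDER)
        if bad:
            raise ValueError(f"unknown stages in start_stage_probs: {sorted(bad)}")
        return np.array(
            [self.start_stage_probs.get(s, 0.0) for s in STAGE_ORDER], dtype=float
        )

    def step_probs(self) -> tuple[float, float]:
        """Per-second (down, up) transition probabilities, jointly capped at 1."""
        p_down = 1.0 - math.exp(-self.decline_rate / 60.0)
        p_up = 1.0 - math.exp(-self.recovery_rate / 60.0)
        total = p_down + p_up
        if total > 1.0:
            p_down, p_up = p_down / total, p_up / total
        return p_down, p_up


def simulate_trajectory(params: TrajectoryParams) -> StageSequence:
    """Draw one latent per-second vigilance trajectory."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    probs = params.start_probs_vector()
    p_down, p_up = params.step_probs()

    state = int(rng.choice(len(STAGE_ORDER), p=probs))
    labels = np.empty(params.n_segments, dtype="U8")
    labels[0] = STAGE_ORDER[state]
    dwell = 1
    u = rng.random(params.n_segments)  # one draw per second, index 0 unused
    for t in range(1, params.n_segments):
        if dwell >= params.dwell_min:
            if u[t] < p_down:
                if state < len(STAGE_ORDER) - 1:
                    state += 1
                    dwell = 0
            elif u[t] < p_down + p_up:
                if state > 0:
                    state -= 1
                    dwell = 0
        labels[t] = STAGE_ORDER[state]
        dwell += 1
    return StageSequence(labels=labels, t0=0.0)


# ---------------------------------------------------------------------------
# EEG synthesis
# ---------------------------------------------------------------------------

@dataclass
class EEGSynthesisParams:
    """Stage-signature EEG synthesis parameters (amplitudes in microvolts).

    The anterior gradients are frontal:occipital *amplitude* ratios of the
    alpha rhythm per A-substage; squared they give the band-power ratios the
    stager thresholds on.
    """

    montage: tuple[str, ...] = MONTAGE_10_20
    sampling_rate: float = 512.0
    iapf: float = 10.0
    alpha_amp_occ: float = 20.0
    alpha_anterior_gradient_a1: float = 0.3
    alpha_anterior_gradient_a2: float = 0.85
    alpha_anterior_gradient_a3: float = 1.3
    theta_freq: float = 5.5
    theta_amp: float = 20.0
    desync_amp: float = 4.0
    background_exponent: float = 1.0
    background_rms: float = 4.0
    sem_amp: float = 40.0
    sem_duration: float = 1.5
    line_noise_amp: float = 2.0
    line_noise_freq: float = 50.0
    blink_rate: float = 0.0
    blink_amp: float = 400.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate <= 140.0:
            raise ValueError("sampling rate must exceed 2 x 70 Hz")
        if not 7.5 <= self.iapf <= 13.5:
            raise ValueError("iapf must lie in [7.5, 13.5] Hz")
        for name in ("alpha_amp_occ", "theta_amp", "desync_amp",
                     "background_rms", "sem_amp", "line_noise_amp",
                     "blink_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


def _pink_noise(rng: np.random.Generator, n: int, exponent: float,
                rms: float, sfreq: float) -> np.ndarray:
    """1/f^exponent noise, band-limited to 0.5-70 Hz, scaled to target RMS."""
    if rms == 0.0:
        return np.zeros(n)
    freqs = np.fft.rfftfreq(n, d=1.0 / sfreq)
    spectrum = (rng.standard_normal(freqs.size)
                + 1j * rng.standard_normal(freqs.size))
    shaping = np.zeros_like(freqs)
    band = (freqs >= 0.5) & (freqs <= 70.0)
    shaping[band] = freqs[band] ** (-exponent / 2.0)
    x = np.fft.irfft(spectrum * shaping, n=n)
    x *= rms / np.sqrt(np.mean(x**2))
    return x


def _smooth_envelope(per_second: np.ndarray, sfreq: float) -> np.ndarray:
    """Per-second amplitudes -> per-sample envelope with ~0.1-s ramps."""
    n_samp = int(round(sfreq))
    env = np.repeat(per_second, n_samp)
    win = int(round(0.1 * sfreq))
    if win > 1:
        kernel = np.hanning(win)
        kernel /= kernel.sum()
        env = np.convolve(env, kernel, mode="same")
    return env


def _stage_amplitudes(label: str, p: EEGSynthesisParams
                      ) -> tuple[float, float, float, float]:
    """(occipital alpha, frontal alpha, theta, desync) amplitude per stage.

    Stages 0 and B1 are not silent: they carry a low-voltage broadband
    (desynchronized) component so that low-voltage seconds have physical
    power rather than numerical residue.
    """
    a = p.alpha_amp_occ
    if label == "A1":
        return a, a * p.alpha_anterior_gradient_a1, 0.0, 0.0
    if label == "A2":
        return a, a * p.alpha_anterior_gradient_a2, 0.0, 0.0
    if label == "A3":
        return a, a * p.alpha_anterior_gradient_a3, 0.0, 0.0
    if label == "B23":
        return 0.0, 0.0, p.theta_amp, 0.0
    return 0.0, 0.0, 0.0, p.desync_amp  # stages 0 and B1


def synthesize_eeg(stages: StageSequence, params: EEGSynthesisParams) -> EEGRecording:
    """Render a stage sequence as a 19-channel EEG recording.

    Each second carries the spectral signature of its latent stage; the
    alpha and theta carriers keep continuous phase across segment boundaries
    and amplitude envelopes ramp over ~0.1 s, so segment edges do not leak
    broadband power.
    """
    params.validate()
    if len(stages) == 0:
        raise ValueError("stage sequence is empty")
    rng = np.random.default_rng(params.seed)
    sfreq = params.sampling_rate
    n_seg = len(stages)
    n_samp = int(round(n_seg * sfreq))
    t = np.arange(n_samp) / sfreq
    labels = stages.labels

    amps = np.array([_stage_amplitudes(s, params) for s in labels])
    env_alpha_occ = _smooth_envelope(amps[:, 0], sfreq)[:n_samp]
    env_alpha_front = _smooth_envelope(amps[:, 1], sfreq)[:n_samp]
    env_theta = _smooth_envelope(amps[:, 2], sfreq)[:n_samp]
    env_desync = _smooth_envelope(amps[:, 3], sfreq)[:n_samp]

    phase_a = rng.uniform(0, 2 * np.pi)
    phase_t = rng.uniform(0, 2 * np.pi)
    alpha_carrier = np.sin(2 * np.pi * params.iapf * t + phase_a)
    theta_carrier = np.sin(2 * np.pi * params.theta_freq * t + phase_t)

    montage = list(params.montage)
    data = np.zeros((len(montage), n_samp))
    for i, ch in enumerate(montage):
        if ch in OCCIPITAL_SET:
            env = env_alpha_occ
            theta_gain = 1.0
        elif ch in FRONTAL_SET:
            env = env_alpha_front
            theta_gain = 0.8
        else:  # central/temporal row: intermediate alpha expression
            env = 0.5 * (env_alpha_occ + env_alpha_front)
            theta_gain = 0.9
        data[i] = env * alpha_carrier + theta_gain * env_theta * theta_carrier
        if params.desync_amp > 0:
            # band-limited white broadband, unit RMS, stage-gated envelope
            data[i] += env_desync * _pink_noise(rng, n_samp, 0.0, 1.0, sfreq)
        data[i] += _pink_noise(rng, n_samp, params.background_exponent,
                               params.background_rms, sfreq)

    if params.line_noise_amp > 0:
        line = params.line_noise_amp * np.sin(
            2 * np.pi * params.line_noise_freq * t + rng.uniform(0, 2 * np.pi))
        data += line[None, :]

    _add_sem(data, montage, labels, params, sfreq)
    _add_blinks(data, montage, params, rng, n_samp, sfreq)

    return EEGRecording(data=data, channel_labels=montage, sfreq=sfreq)


def _add_sem(data, montage, labels, params, sfreq) -> None:
    """Slow horizontal eye movements during B1: back-to-back half-sine
    deflections of alternating polarity, mirrored across F7/F8 (weaker on
    Fp1/Fp2), emulating lateral ocular dipole rotation."""
    if params.sem_amp == 0:
        return
    idx = {c: montage.index(c) for c in ("F7", "F8", "Fp1", "Fp2") if c in montage}
    if "F7" not in idx or "F8" not in idx:
        return
    half_len = int(round(params.sem_duration * sfreq))
    is_b1 = np.array([s == "B1" for s in labels])
    # maximal runs of consecutive B1 seconds
    edges = np.flatnonzero(np.diff(np.concatenate(([0], is_b1.view(np.int8), [0]))))
    for start_s, end_s in zip(edges[::2], edges[1::2]):
        a = int(start_s * sfreq)
        b = int(end_s * sfreq)
        pos = a
        sign = 1.0
        while pos < b:
            seg = min(half_len, b - pos)
            wave = params.sem_amp * np.sin(
                np.pi * np.arange(seg) / half_len) * sign
            data[idx["F7"], pos:pos + seg] += wave
            data[idx["F8"], pos:pos + seg] -= wave
            for ch in ("Fp1", "Fp2"):
                if ch in idx:
                    pol = 1.0 if ch == "Fp1" else -1.0
                    data[idx[ch], pos:pos + seg] += 0.5 * pol * wave
            pos += half_len
            sign = -sign


def _add_blinks(data, montage, params, rng, n_samp, sfreq) -> None:
    if params.blink_rate <= 0 or params.blink_amp == 0:
        return
    n_events = rng.poisson(params.blink_rate * n_samp / sfreq / 60.0)
    width = int(round(0.2 * sfreq))
    pulse = np.sin(np.pi * np.arange(width) / width) ** 2
    frontal = [montage.index(c) for c in ("Fp1", "Fp2") if c in montage]
    for _ in range(n_events):
        pos = int(rng.integers(0, max(1, n_samp - width)))
        for i in frontal:
            data[i, pos:pos + width] += params.blink_amp * pulse


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

#: CBCL-like T-score subscales: (name, ADHD mean, ADHD SD, DEP mean, DEP SD)
CLINICAL_SCALES: tuple[tuple[str, float, float, float, float], ...] = (
    ("internalizing", 59.21, 9.93, 65.95, 7.15),
    ("externalizing", 64.44, 12.10, 56.16, 10.64),
    ("total", 64.60, 9.51, 62.84, 7.26),
    ("withdrawn_depressed", 59.46, 9.59, 64.41, 7.93),
    ("somatic_complaints", 58.63, 7.59, 60.92, 8.91),
    ("anxious_depressed", 58.42, 10.58, 64.95, 7.39),
    ("social_problems", 60.89, 10.02, 57.24, 7.53),
    ("thought_problems", 58.74, 8.56, 61.82, 8.82),
    ("attention_problems", 65.32, 8.09, 59.30, 7.21),
    ("rule_breaking", 74.51, 84.08, 59.75, 9.12),
    ("aggressive", 65.89, 11.57, 57.07, 9.15),
)


@dataclass
class GroupSpec:
    """One diagnostic group of a synthetic cohort."""

    name: str
    n_subjects: int
    age_mean_months: float
    age_sd_months: float
    trajectory: TrajectoryParams
    clinical_scales: dict = field(default_factory=dict)  # name -> (mean, sd)
    medication_probs: dict = field(default_factory=lambda: {"none": 1.0})
    rho: float = 0.0  # clinical-score vs stability correlation

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if not 0.0 <= abs(self.rho) <= 1.0:
            raise ValueError("|rho| must lie in [0, 1]")
        total = sum(self.medication_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("medication probabilities must sum to 1")


@dataclass
class CohortSpec:
    groups: list
    eeg: EEGSynthesisParams = field(default_factory=EEGSynthesisParams)
    seed: int = 0


def adhd_like_trajectory(**overrides) -> TrajectoryParams:
    """Unstable arousal regulation: fast decline into drowsiness.

    Calibrated (with ``dep_like_trajectory``) so that stability-score medians
    of the two presets differ by at least one point in samples of 19.
    """
    base = TrajectoryParams(
        start_stage_probs={"0": 0.05, "A1": 0.95},
        decline_rate=0.9, recovery_rate=0.12, dwell_min=5)
    return replace(base, **overrides)


def dep_like_trajectory(**overrides) -> TrajectoryParams:
    """Hyperstable arousal regulation: slow, shallow decline.

    Both hazards are kept small so subjects dwell in A1 with occasional
    excursions to 0 or A2, matching the occurrence profile of hyperstable
    groups (A1-dominant, little drowsiness).
    """
    base = TrajectoryParams(
        start_stage_probs={"0": 0.1, "A1": 0.9},
        decline_rate=0.05, recovery_rate=0.15, dwell_min=5)
    return replace(base, **overrides)


def adhd_like_group(n_subjects: int = 76, **overrides) -> GroupSpec:
    """ADHD-like group defaults: age 118/33 months, CBCL-like T-scores."""
    spec = GroupSpec(
        name="adhd", n_subjects=n_subjects,
        age_mean_months=118.0, age_sd_months=33.0,
        trajectory=adhd_like_trajectory(),
        clinical_scales={n: (m_a, s_a) for n, m_a, s_a, _, _ in CLINICAL_SCALES},
        medication_probs={"none": 42 / 76, "neuroleptics": 11 / 76,
                          "stimulants": 23 / 76},
    )
    for key, val in overrides.items():
        setattr(spec, key, val)
    return spec


def dep_like_group(n_subjects: int = 94, **overrides) -> GroupSpec:
    """Depression-like group defaults: age 184/23 months."""
    spec = GroupSpec(
        name="dep", n_subjects=n_subjects,
        age_mean_months=184.0, age_sd_months=23.0,
        trajectory=dep_like_trajectory(),
        clinical_scales={n: (m_d, s_d) for n, _, _, m_d, s_d in CLINICAL_SCALES},
        medication_probs={"none": 79 / 94, "neuroleptics": 5 / 94,
                          "antidepressants": 10 / 94},
    )
    for key, val in overrides.items():
        setattr(spec, key, val)
    return spec


def _truncated_t_scores(rng, mean, sd, z_latent, rho):
    """T-scores correlated (Gaussian copula) with a latent normal, truncated
    to the conventional [20, 100] T-score range."""
    eps = rng.standard_normal(z_latent.size)
    z = rho * z_latent + math.sqrt(max(0.0, 1.0 - rho**2)) * eps
    return np.clip(mean + sd * z, 20.0, 100.0)


def simulate_cohort(spec: CohortSpec, include_eeg: bool = True):
    """Simulate a cohort: returns ``(table, recordings, truth)``.

    ``table`` is a per-subject :class:`pandas.DataFrame` holding group, age,
    medication, clinical T-scores, and the arousal summary computed from the
    *true* latent trajectory.  ``recordings`` is a list of
    :class:`EEGRecording` (empty when ``include_eeg`` is False) and ``truth``
    the list of latent :class:`StageSequence`, both in table row order.
    """
    master = np.random.default_rng(spec.seed)
    rows = []
    recordings: list[EEGRecording] = []
    truth: list[StageSequence] = []
    subject_id = 0
    for group in spec.groups:
        group.validate()
        seeds = master.integers(0, 2**31 - 1, size=group.n_subjects + 2)
        rng = np.random.default_rng(seeds[0])
        ages = rng.normal(group.age_mean_months, group.age_sd_months,
                          group.n_subjects)
        ages = np.clip(np.round(ages), 72, 216)  # study range 6-18 years
        meds = rng.choice(list(group.medication_probs.keys()),
                          p=list(group.medication_probs.values()),
                          size=group.n_subjects)

        summaries = []
        for i in range(group.n_subjects):
            traj_params = replace(group.trajectory, seed=int(seeds[i + 2]))
            seq = simulate_trajectory(traj_params)
            truth.append(seq)
            summaries.append(arousal_summary(seq))
            if include_eeg:
                eeg_params = replace(spec.eeg, seed=int(seeds[i + 2]))
                recordings.append(synthesize_eeg(seq, eeg_params))

        stab = np.array([s.stability for s in summaries], dtype=float)
        # rank-based latent normal for the copula linking scores to stability
        ranks = pd.Series(stab).rank(method="average").to_numpy()
        from scipy.stats import norm
        z_latent = norm.ppf(ranks / (group.n_subjects + 1.0))

        score_rng = np.random.default_rng(seeds[1])
        scores = {
            name: _truncated_t_scores(score_rng, mean, sd, z_latent, group.rho)
            for name, (mean, sd) in group.clinical_scales.items()
        }

        for i in range(group.n_subjects):
            s = summaries[i]
            row = {
                "subject_id": f"S{subject_id:03d}",
                "group": group.name,
                "age_months": float(ages[i]),
                "medication": meds[i],
                "stability": s.stability,
                "mean_vigilance": s.mean_vigilance,
                "n_artifact_free": s.n_artifact_free,
            }
            for stage in STAGE_ORDER:
                row[f"occ_{stage}"] = s.occurrence[stage]
            for name in scores:
                row[name] = float(scores[name][i])
            rows.append(row)
            subject_id += 1

    table = pd.DataFrame(rows)
    return table, recordings, truth
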