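"""iAPF estimation, spectral features, the staging cascade, validation."""

import numpy as np
import pytest

import vigikit as vk
from vigikit.recording import MONTAGE_10_20
from vigikit.staging import SpectralFeatures, StagingResult, ValidationReport


def _tone_segment(freqs_amps, sfreq=512.0):
    """One 1-s 19-channel segment holding the given (freq, amp) tones."""
    t = np.arange(int(sfreq)) / sfreq
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in freqs_amps)
    return np.tile(x, (19, 1))


def _alpha_segmented(freq, n_seg=40, sfreq=512.0, amp=20.0):
    t = np.arange(int(n_seg * sfreq)) / sfreq
    x = amp * np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (19, 1)).reshape(19, n_seg, int(sfreq))
    return vk.SegmentedEEG(data=np.swapaxes(data, 0, 1),
                           channel_labels=list(MONTAGE_10_20), sfreq=sfreq)


def _features(rel_alpha, anterior_amp_ratio, rel_theta):
    """Build SpectralFeatures with the requested derived quantities."""
    occ_total = 1.0
    occ_alpha = rel_alpha * occ_total
    return SpectralFeatures(
        occ_alpha=occ_alpha,
        occ_theta=rel_theta * occ_total,
        occ_total=occ_total,
        front_alpha=(anterior_amp_ratio ** 2) * occ_alpha,
        front_total=1.0,
    )


class TestIAPF:
    @pytest.mark.parametrize("true_freq,lo,hi", [
        (10.0, 9.8, 10.2),
        (8.7, 8.5, 8.9),
    ])
    def test_recovers_generator_frequency(self, true_freq, lo, hi):
        est = vk.estimate_iapf(_alpha_segmented(true_freq))
        assert lo <= est.frequency <= hi
        assert est.alpha_detected

    def test_tie_break_prefers_lower_frequency(self):
        seg = vk.SegmentedEEG(
            data=_tone_segment([(9.0, 15.0), (11.0, 15.0)]).reshape(
                19, 1, 512).swapaxes(0, 1).repeat(40, axis=0),
            channel_labels=list(MONTAGE_10_20), sfreq=512.0)
        est = vk.estimate_iapf(seg)
        assert abs(est.frequency - 9.0) < 0.3

    def test_no_alpha_flag_on_pink_noise(self):
        rng = np.random.default_rng(0)
        n = 40 * 512
        freqs = np.fft.rfftfreq(n, 1 / 512)
        shaping = np.where(freqs > 0.5, np.maximum(freqs, 0.5) ** -0.5, 0)
        x = np.fft.irfft((rng.standard_normal(freqs.size)
                          + 1j * rng.standard_normal(freqs.size)) * shaping,
                         n=n)
        x *= 10 / np.sqrt(np.mean(x**2))
        data = np.stack([np.fft.irfft(np.fft.rfft(x)
                                      * np.exp(1j * rng.uniform(0, 1)), n=n)
                         for _ in range(19)])
        seg = vk.SegmentedEEG(data=data.reshape(19, 40, 512).swapaxes(0, 1),
                              channel_labels=list(MONTAGE_10_20), sfreq=512.0)
        est = vk.estimate_iapf(seg)
        assert not est.alpha_detected

    def test_too_few_segments_rejected(self):
        with pytest.raises(ValueError):
            vk.estimate_iapf(_alpha_segmented(10.0, n_seg=10))


class TestSegmentFeatures:
    def test_pure_alpha_tone(self):
        f = vk.segment_features(_tone_segment([(10.0, 20.0)]), 10.0,
                                vk.StagingConfig(), 512.0,
                                list(MONTAGE_10_20))
        assert f.rel_alpha >= 0.95

    def test_pure_theta_tone(self):
        f = vk.segment_features(_tone_segment([(5.5, 20.0)]), 10.0,
                                vk.StagingConfig(), 512.0,
                                list(MONTAGE_10_20))
        assert f.rel_theta >= 0.95

    def test_equal_power_mixture_splits_half(self):
        """Parseval: equal-amplitude tones contribute equal band power."""
        f = vk.segment_features(_tone_segment([(10.0, 20.0), (5.5, 20.0)]),
                                10.0, vk.StagingConfig(), 512.0,
                                list(MONTAGE_10_20))
        assert f.rel_alpha == pytest.approx(0.5, abs=0.05)
        assert f.rel_theta == pytest.approx(0.5, abs=0.05)

    def test_short_segment_rejected(self):
        with pytest.raises(ValueError):
            vk.segment_features(np.zeros((19, 100)), 10.0,
                                vk.StagingConfig(), 512.0,
                                list(MONTAGE_10_20))


class TestClassifySegment:
    @pytest.mark.parametrize("rel_alpha,ratio,rel_theta,sem,expected", [
        (0.8, 0.3, 0.1, False, "A1"),
        (0.8, 0.7, 0.1, False, "A2"),
        (0.8, 1.3, 0.1, False, "A3"),
        (0.1, 0.3, 0.7, False, "B23"),
        (0.1, 0.3, 0.2, False, "0"),
        (0.1, 0.3, 0.2, True, "B1"),
    ])
    def test_rule_cascade(self, rel_alpha, ratio, rel_theta, sem, expected):
        label = vk.classify_segment(_features(rel_alpha, ratio, rel_theta),
                                    sem)
        assert label == expected

    def test_low_voltage_bypasses_band_rules(self):
        f = SpectralFeatures(occ_alpha=0.5, occ_theta=0.4, occ_total=0.5,
                             front_alpha=0.0, front_total=0.5)
        assert vk.classify_segment(f, False) == "0"
        assert vk.classify_segment(f, True) == "B1"

    def test_threshold_monotonicity(self, mixed_analysis, mixed_truth):
        """Raising alpha dominance never increases the A-stage count."""
        _, rec = mixed_truth
        seg = vk.preprocess(rec)
        counts = []
        for thr in (0.3, 0.4, 0.5, 0.6):
            cfg = vk.StagingConfig(alpha_dominance_threshold=thr)
            labels = vk.classify_recording(seg, cfg).labels
            counts.append(int(np.isin(labels, ("A1", "A2", "A3")).sum()))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_delta_content_does_not_change_label(self, noise_free_params):
        """The 4-30 Hz total band excludes delta by design."""
        seq = vk.StageSequence(labels=np.array(["A1"] * 40))
        rec = vk.synthesize_eeg(seq, noise_free_params)
        seg = vk.preprocess(rec)
        before = vk.classify_recording(seg).labels.copy()
        t = np.arange(seg.data.shape[2]) / seg.sfreq
        seg.data = seg.data + 30 * np.sin(2 * np.pi * 2.0 * t)  # pure delta
        after = vk.classify_recording(seg).labels
        assert np.array_equal(before, after)


class TestRoundTrip:
    def test_noise_free_recall(self, noise_free_params):
        labels = np.repeat(["0", "A1", "A2", "A3", "B1", "B23"], 20)
        seq = vk.StageSequence(labels=labels)
        rec = vk.synthesize_eeg(seq, noise_free_params)
        pred = vk.analyze_recording(rec).staging.stages.labels
        for stage in ("0", "A1", "A2", "A3", "B1", "B23"):
            sel = labels == stage
            recall = np.mean(pred[sel] == stage)
            assert recall >= 0.99, f"stage {stage}: recall {recall}"

    def test_default_snr_agreement(self, mixed_truth, mixed_analysis):
        seq, _ = mixed_truth
        pred = mixed_analysis.staging.stages.labels
        free = pred != "ARTIFACT"
        agreement = np.mean(pred[free] == seq.labels[free])
        assert agreement >= 0.80

    def test_all_masked_recording(self, all_a1_recording):
        seg = vk.preprocess(all_a1_recording)
        seg.artifact_mask[:] = True
        result = vk.stage_recording(seg)
        assert np.all(result.stages.labels == "ARTIFACT")
        report = vk.validate_recording(result)
        assert not report.passed


class TestValidation:
    def _result(self, labels, iapf=10.0, alpha_detected=True, power=1e6):
        return StagingResult(
            stages=vk.StageSequence(labels=np.asarray(labels, dtype="U8")),
            iapf=vk.IAPFEstimate(frequency=iapf,
                                 alpha_detected=alpha_detected),
            alpha_abs_power=power,
            sem_flags=np.zeros(len(labels), dtype=bool))

    def test_passing_recording(self):
        report = vk.validate_recording(self._result(["A1"] * 480))
        assert report.passed and report.reasons == []

    def test_iapf_out_of_range(self):
        report = vk.validate_recording(self._result(["A1"] * 480, iapf=13.0))
        assert not report.passed
        assert "iapf out of range" in report.reasons

    def test_artifact_fraction_bound(self):
        labels = ["A1"] * 384 + ["ARTIFACT"] * 96  # 20% artifacts
        report = vk.validate_recording(self._result(labels))
        assert not report.passed
        assert report.artifact_fraction == pytest.approx(0.20)

    def test_low_voltage_excluded(self):
        labels = ["0"] * 466 + ["A1"] * 14  # 97% in {0, B1}
        report = vk.validate_recording(self._result(labels))
        assert not report.passed
        assert report.fraction_0_or_B1 > 0.95

    def test_late_alpha_fails_early_criterion(self):
        labels = ["0"] * 240 + ["A1"] * 240
        report = vk.validate_recording(self._result(labels))
        assert not report.alpha_detected_early
        assert not report.passed

    def test_low_alpha_power_fails(self):
        report = vk.validate_recording(self._result(["A1"] * 480, power=100.0))
        assert not report.passed
        assert "absolute alpha power below threshold" in report.reasons

    def test_report_is_total(self):
        """Validation always returns a report, never raises."""
        report = vk.validate_recording(
            self._result(["B23"] * 480, iapf=float("nan"),
                         alpha_detected=False, power=0.0))
        assert isinstance(report, ValidationReport)
        assert not report.passed
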