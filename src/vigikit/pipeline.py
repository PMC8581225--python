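"""End-to-end analysis of one recording: preprocess, stage, validate,
summarize."""

from __future__ import annotations

from dataclasses import dataclass

from .metrics import ArousalSummary, arousal_summary
from .preprocess import PreprocessConfig, preprocess
from .recording import EEGRecording
from .staging import (StagingConfig, StagingResult, ValidationReport,
                      stage_recording, validate_recording)


@dataclass
class AnalysisResult:
    """Everything the pipeline derives from one recording."""

    staging: StagingResult
    summary: ArousalSummary
    validation: ValidationReport


def analyze_recording(rec: EEGRecording,
                      pre_cfg: PreprocessConfig | None = None,
                      stage_cfg: StagingConfig | None = None
                      ) -> AnalysisResult:
    """Run the full single-subject chain on a raw recording."""
    seg = preprocess(rec, pre_cfg or PreprocessConfig())
    result = stage_recording(seg, stage_cfg or StagingConfig())
    report = validate_recording(result, stage_cfg or StagingConfig())
    summary = arousal_summary(result.stages, short_flag=seg.short_recording)
    return AnalysisResult(staging=result, summary=summary, validation=report)
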