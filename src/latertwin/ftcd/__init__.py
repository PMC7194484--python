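"""fTCD laterality pipeline: raw velocity traces to subject LIs."""

from .epochs import compute_trial_li, epoch_and_reject
from .io import (
    read_recording_csv,
    read_recording_dir,
    subjects_frame,
    trial_li_frame,
    write_recording_csv,
    write_subject_summaries,
    write_trial_lis,
)
from .preprocess import detect_beats, integrate_cycles, preprocess_recording
from .summary import (
    apply_sample_exclusions,
    split_half_reliability,
    summarize_subject,
    summarize_trial_lis,
)
from .types import (
    PeriodOfInterest,
    ProcessingConfig,
    SubjectLaterality,
    TrialEpoch,
    VelocityRecording,
)

__all__ = [
    "PeriodOfInterest",
    "ProcessingConfig",
    "SubjectLaterality",
    "TrialEpoch",
    "VelocityRecording",
    "preprocess_recording",
    "detect_beats",
    "integrate_cycles",
    "epoch_and_reject",
    "compute_trial_li",
    "summarize_subject",
    "summarize_trial_lis",
    "apply_sample_exclusions",
    "split_half_reliability",
    "process_recording",
    "read_recording_csv",
    "read_recording_dir",
    "write_recording_csv",
    "write_trial_lis",
    "write_subject_summaries",
    "trial_li_frame",
    "subjects_frame",
]


def process_recording(rec: VelocityRecording, cfg: ProcessingConfig | None = None):
    """Run the full pipeline on one raw recording.

    Returns ``(epochs, subject)``: the per-trial epochs with LIs and the
    per-subject laterality summary.  Cohort-level outlier exclusion is a
    separate step (:func:`apply_sample_exclusions`)."""
    cfg = cfg or ProcessingConfig()
    clean = preprocess_recording(rec, cfg)
    epochs = epoch_and_reject(clean, cfg)
    subject = summarize_subject(
        epochs,
        poi=cfg.poi,
        min_trials=cfg.min_trials,
        alpha=cfg.alpha,
        subject_id=rec.subject_id,
    )
    return epochs, subject
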