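"""End-to-end study harness.

Wires the stages together: synthetic cohort -> segmentation -> (optional)
template-matching quality control -> per-subject data caps -> subject-level
split and cross-validation folds -> per-fold training -> majority-vote
ensemble evaluation.  The desk-scale experiment used by the test-bench and
the reproduction script lives here so the whole study is a single call.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .dataset import SplitSpec, build_fold_plan, cap_subject_hours
from .evaluate import EnsembleResult, evaluate_ensemble
from .model import (
    AugmentConfig,
    ModelConfig,
    TrainConfig,
    TrainedFold,
    normalize_segment,
    train_fold,
)
from .preprocess import Segment, segment_signal
from .quality import FilterSpec, QualityThresholds, assess_segment
from .simulate import CohortSimSpec, PPGRecord, simulate_cohort

__all__ = [
    "SegmentDataset",
    "records_to_segments",
    "dataset_from_segments",
    "run_cv_experiment",
    "SmokeConfig",
    "run_smoke_experiment",
]

LABEL_TO_INT = {"control": 0, "sepsis": 1}


@dataclass
class SegmentDataset:
    """Normalized design matrix with per-segment provenance."""

    X: np.ndarray  # (n_segments, 15000), min-max normalized to [-1, 1]
    y: np.ndarray  # (n_segments,), 1 = sepsis
    subjects: np.ndarray  # (n_segments,) subject ids

    def subset(self, subject_ids: Set[str]) -> "SegmentDataset":
        mask = np.isin(self.subjects, sorted(subject_ids))
        return SegmentDataset(self.X[mask], self.y[mask], self.subjects[mask])


def records_to_segments(
    records: Sequence[PPGRecord],
    run_qc: bool = True,
    thresholds: QualityThresholds = QualityThresholds(),
    filter_spec: FilterSpec = FilterSpec(),
) -> Tuple[List[Segment], List[bool]]:
    """Segment records and (optionally) attach QC verdicts.

    With ``run_qc=False`` every segment is marked accepted; callers that
    simulate artifact-free records can skip the quadratic QC cost.
    """
    segments: List[Segment] = []
    verdicts: List[bool] = []
    for rec in records:
        for seg in segment_signal(rec):
            segments.append(seg)
            if run_qc:
                verdicts.append(assess_segment(seg, thresholds, filter_spec).accepted)
            else:
                verdicts.append(True)
    return segments, verdicts


def dataset_from_segments(segments: Sequence[Segment],
                          verdicts: Optional[Sequence[bool]] = None,
                          split_spec: SplitSpec = SplitSpec(),
                          seed: Optional[int] = None,
                          decimate: int = 1,
                          apply_caps: bool = True) -> SegmentDataset:
    """Apply the per-subject caps to accepted segments and normalize them.

    ``decimate`` > 1 downsamples each segment by that integer factor with an
    anti-aliasing filter before normalization (used by desk-scale training,
    where the PPG band of interest sits well below the reduced Nyquist
    frequency).
    """
    from scipy.signal import decimate as sp_decimate

    by_subject: Dict[str, List[Segment]] = {}
    for i, seg in enumerate(segments):
        if verdicts is not None and not verdicts[i]:
            continue
        by_subject.setdefault(seg.subject_id, []).append(seg)
    capped = (cap_subject_hours(by_subject, split_spec, seed=seed)
              if apply_caps else by_subject)
    X, y, subjects = [], [], []
    for sid in sorted(capped):
        for seg in capped[sid]:
            x = seg.samples
            if decimate > 1:
                x = sp_decimate(x, decimate, zero_phase=True)
            X.append(normalize_segment(x))
            y.append(LABEL_TO_INT.get(seg.label, 0))
            subjects.append(sid)
    return SegmentDataset(np.asarray(X), np.asarray(y), np.asarray(subjects))


def run_cv_experiment(
    data: SegmentDataset,
    split_spec: SplitSpec = SplitSpec(),
    model_cfg: ModelConfig = ModelConfig(),
    train_cfg: TrainConfig = TrainConfig(),
    aug_cfg: AugmentConfig = AugmentConfig(),
    return_plan: bool = False,
):
    """Subject-disjoint 80/20 split, k-fold training, ensemble evaluation.

    Returns ``(result, trained_folds)``; with ``return_plan=True`` the fold
    plan is appended as a third element.
    """
    subject_labels = {}
    for sid, lab in zip(data.subjects, data.y):
        subject_labels[str(sid)] = "sepsis" if lab == 1 else "control"
    plan = build_fold_plan(subject_labels, split_spec)
    train_ids = plan.train_subjects
    trained: List[TrainedFold] = []
    for i, val_fold in enumerate(plan.folds):
        tr_ids = train_ids - val_fold
        tr = data.subset(tr_ids)
        va = data.subset(val_fold)
        cfg_i = TrainConfig(learning_rate=train_cfg.learning_rate,
                            batch_size=train_cfg.batch_size,
                            epochs=train_cfg.epochs,
                            seed=train_cfg.seed + i)
        trained.append(train_fold((tr.X, tr.y), (va.X, va.y),
                                  model_cfg, cfg_i, aug_cfg, fold_id=i,
                                  train_subjects=tr.subjects,
                                  val_subjects=va.subjects))
    test = data.subset(plan.test_subjects)
    result = evaluate_ensemble(trained, test.X, test.y,
                               test_subjects=test.subjects,
                               train_subjects=set(map(str, train_ids)))
    if return_plan:
        return result, trained, plan
    return result, trained


@dataclass(frozen=True)
class SmokeConfig:
    """Desk-scale study conditions for the learning check.

    The cohort holds 20 subjects per class with 1 h of retained signal each
    (2 h simulated; the every-other-segment rule halves it), a strong class
    effect, and no injected artifacts, so quality control is a no-op and is
    skipped.  The network is a narrow variant of the reference architecture
    (same depth, fewer filters) trained for a few epochs at learning rate
    1e-4 -- sized so a full 5-fold run takes about a minute on one CPU core.
    """

    n_per_class: int = 20
    hours_simulated: float = 2.0
    class_effect: float = 2.0
    decimate: int = 10  # train on 12.5 Hz segments (1500 samples)
    n_filters: int = 8
    epochs: int = 10
    batch_size: int = 16
    learning_rate: float = 1e-4
    seed: int = 0


def run_smoke_experiment(cfg: SmokeConfig = SmokeConfig()) -> Tuple[EnsembleResult, List[TrainedFold]]:
    """Run the full pipeline at desk scale and return the ensemble result."""
    spec = CohortSimSpec(
        n_sepsis=cfg.n_per_class,
        n_control=cfg.n_per_class,
        hours_per_subject_range=(cfg.hours_simulated, cfg.hours_simulated),
        class_effect=cfg.class_effect,
        artifact_rate=0.0,
        seed=cfg.seed,
    )
    records, _subjects = simulate_cohort(spec)
    segments, verdicts = records_to_segments(records, run_qc=False)
    split_spec = SplitSpec(seed=cfg.seed)
    data = dataset_from_segments(segments, verdicts, split_spec,
                                 decimate=cfg.decimate)
    model_cfg = ModelConfig(n_filters=cfg.n_filters,
                            input_length=15000 // cfg.decimate)
    train_cfg = TrainConfig(learning_rate=cfg.learning_rate,
                            batch_size=cfg.batch_size,
                            epochs=cfg.epochs, seed=cfg.seed)
    return run_cv_experiment(data, split_spec, model_cfg, train_cfg)
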