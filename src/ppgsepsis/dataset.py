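"""Cohort labeling, capping rules, and subject-disjoint splits.

Implements the case/control selection rules over an exported subject
metadata table (the SQL extraction from the clinical database itself is out
of scope), the 40-controls-per-diagnosis-code cap, the per-subject data caps
(at most 3 h, at least 1 h of accepted signal, counted in 2-minute
segments), the subject-level 80/20 train/test split, and the 5-fold
subject-disjoint cross-validation plan.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set

import numpy as np
from sklearn.model_selection import StratifiedKFold, train_test_split

__all__ = [
    "SubjectMeta",
    "CohortLabel",
    "SplitSpec",
    "FoldPlan",
    "SEPSIS_CODES",
    "CONTROL_CODES",
    "normalize_icd9",
    "apply_cohort_criteria",
    "cap_controls_per_code",
    "filter_has_ppg",
    "cap_subject_hours",
    "split_train_test",
    "make_cv_folds",
    "MetadataIncompleteError",
]

#: ICD-9 codes defining a sepsis diagnosis (sepsis, severe sepsis, septic shock).
SEPSIS_CODES = frozenset({"99591", "99592", "78552"})
#: Control diagnoses (depressive disorder NEC, tobacco use disorder, anxiety
#: state NOS, other persistent mental disorders, dysthymic disorder), in the
#: fixed order used to attribute multi-code controls to a single code.
CONTROL_CODE_ORDER = ("311", "3051", "30000", "2948", "3004")
CONTROL_CODES = frozenset(CONTROL_CODE_ORDER)

SEGMENTS_PER_HOUR = 30  # 2-minute segments
MIN_SEGMENTS = 30  # 1 h floor
MAX_SEGMENTS = 90  # 3 h cap


class MetadataIncompleteError(ValueError):
    """Raised when a subject's metadata row has missing fields."""


def normalize_icd9(code: str) -> str:
    """Normalize an ICD-9 code to the dot-free uppercase string convention."""
    return str(code).strip().upper().replace(".", "").replace(",", "")


@dataclass
class SubjectMeta:
    """One row of the exported subject metadata table."""

    subject_id: str
    died_in_hospital: bool
    n_icu_stays: int
    n_admissions: int
    icd9_codes: Set[str]
    in_matched_subset: bool
    has_ppg: bool

    def __post_init__(self) -> None:
        self.icd9_codes = {normalize_icd9(c) for c in self.icd9_codes}


@dataclass
class CohortLabel:
    subject_id: str
    label: str  # sepsis | control | excluded
    exclusion_reason: Optional[str] = None
    control_codes: Set[str] = field(default_factory=set)


@dataclass(frozen=True)
class SplitSpec:
    train_frac: float = 0.8
    k_folds: int = 5
    max_hours_per_subject: float = 3.0
    min_hours_per_subject: float = 1.0
    seed: int = 0
    stratify: bool = True

    def validate(self) -> None:
        if not (0.0 < self.train_frac < 1.0):
            raise ValueError("train_frac must lie in (0, 1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.min_hours_per_subject >= self.max_hours_per_subject:
            raise ValueError("min hours must be below max hours")


@dataclass
class FoldPlan:
    """Subject-disjoint test set and k training folds."""

    test_subjects: Set[str]
    folds: List[Set[str]] = field(default_factory=list)

    def validate(self) -> None:
        for i, f in enumerate(self.folds):
            if f & self.test_subjects:
                raise ValueError(f"fold {i} overlaps the test set")
            for j in range(i + 1, len(self.folds)):
                if f & self.folds[j]:
                    raise ValueError(f"folds {i} and {j} overlap")

    @property
    def train_subjects(self) -> Set[str]:
        out: Set[str] = set()
        for f in self.folds:
            out |= f
        return out


def _require_fields(m: SubjectMeta) -> None:
    for name in ("subject_id", "died_in_hospital", "n_icu_stays",
                 "n_admissions", "icd9_codes", "in_matched_subset", "has_ppg"):
        if getattr(m, name, None) is None:
            raise MetadataIncompleteError(
                f"subject {m.subject_id!r}: missing field {name!r}"
            )


def apply_cohort_criteria(subjects: Sequence[SubjectMeta]) -> List[CohortLabel]:
    """Label each subject sepsis / control / excluded.

    Sepsis: death in hospital, a single ICU stay, a single hospital
    admission, at least one sepsis diagnosis code, and presence in the
    matched waveform subset.  Control: no death in hospital, single ICU stay
    and admission, at least one control diagnosis code, no sepsis diagnosis,
    and presence in the matched subset.  Anything else is excluded with the
    first failing rule as the reason.
    """
    out = []
    for m in subjects:
        _require_fields(m)
        codes = m.icd9_codes
        has_sepsis_code = bool(codes & SEPSIS_CODES)
        has_control_code = bool(codes & CONTROL_CODES)

        if not m.in_matched_subset:
            out.append(CohortLabel(m.subject_id, "excluded", "not in matched waveform subset"))
            continue
        if m.n_icu_stays != 1:
            out.append(CohortLabel(m.subject_id, "excluded", "not a single ICU stay"))
            continue
        if m.n_admissions != 1:
            out.append(CohortLabel(m.subject_id, "excluded", "not a single hospital admission"))
            continue
        if m.died_in_hospital:
            if has_sepsis_code:
                out.append(CohortLabel(m.subject_id, "sepsis"))
            else:
                out.append(CohortLabel(m.subject_id, "excluded", "died without sepsis diagnosis code"))
            continue
        # survivor: candidate control
        if has_sepsis_code:
            out.append(CohortLabel(m.subject_id, "excluded", "sepsis diagnosis present (controls require none)"))
            continue
        if not has_control_code:
            out.append(CohortLabel(m.subject_id, "excluded", "no control diagnosis code"))
            continue
        out.append(CohortLabel(m.subject_id, "control",
                               control_codes=codes & CONTROL_CODES))
    return out


def cap_controls_per_code(
    controls: Sequence[CohortLabel], max_per_code: int = 40, seed: int = 0
) -> List[CohortLabel]:
    """Retain at most ``max_per_code`` controls per qualifying diagnosis code.

    A control qualifying under several codes is attributed to the first code
    in the fixed order (311, 3051, 30000, 2948, 3004); within each code the
    retained subset is sampled uniformly with the given seed.
    """
    rng = np.random.default_rng(seed)
    by_code: Dict[str, List[CohortLabel]] = {c: [] for c in CONTROL_CODE_ORDER}
    for lab in controls:
        if lab.label != "control":
            raise ValueError(f"subject {lab.subject_id} is not a control")
        code = next((c for c in CONTROL_CODE_ORDER if c in lab.control_codes), None)
        if code is None:
            raise ValueError(f"control {lab.subject_id} carries no control code")
        by_code[code].append(lab)
    kept: List[CohortLabel] = []
    for code in CONTROL_CODE_ORDER:
        group = by_code[code]
        if len(group) <= max_per_code:
            kept.extend(group)
        else:
            pick = rng.choice(len(group), size=max_per_code, replace=False)
            kept.extend(group[i] for i in sorted(pick))
    return kept


def filter_has_ppg(labels: Sequence[CohortLabel],
                   subjects: Sequence[SubjectMeta]) -> List[CohortLabel]:
    """Drop labelled subjects for whom no PPG signal is available."""
    ppg = {m.subject_id: m.has_ppg for m in subjects}
    return [lab for lab in labels if ppg.get(lab.subject_id, False)]


def cap_subject_hours(
    segments_by_subject: Dict[str, list],
    spec: SplitSpec = SplitSpec(),
    seed: Optional[int] = None,
) -> Dict[str, list]:
    """Apply the per-subject 3 h cap and 1 h floor, in accepted 2-min segments.

    Subjects above the cap are reduced to exactly ``MAX_SEGMENTS`` segments
    by seeded uniform sampling without replacement; subjects below the floor
    are removed entirely.
    """
    spec.validate()
    max_seg = int(round(spec.max_hours_per_subject * SEGMENTS_PER_HOUR))
    min_seg = int(round(spec.min_hours_per_subject * SEGMENTS_PER_HOUR))
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    out: Dict[str, list] = {}
    for sid in sorted(segments_by_subject):
        segs = segments_by_subject[sid]
        if len(segs) > max_seg:
            pick = rng.choice(len(segs), size=max_seg, replace=False)
            segs = [segs[i] for i in sorted(pick)]
        if len(segs) < min_seg:
            continue
        out[sid] = segs
    return out


def _split_labels(subjects: Dict[str, str]):
    sids = sorted(subjects)
    labels = [subjects[s] for s in sids]
    return sids, labels


def split_train_test(subjects: Dict[str, str], spec: SplitSpec = SplitSpec(),
                     seed: Optional[int] = None) -> FoldPlan:
    """Subject-level train/test split, class-stratified by default.

    ``subjects`` maps subject id to class label.  Segment-level disjointness
    between train and test follows from splitting at the subject level.
    """
    spec.validate()
    sids, labels = _split_labels(subjects)
    for cls in set(labels):
        if labels.count(cls) < 5:
            raise ValueError(f"class {cls!r} has fewer than 5 subjects")
    train, test = train_test_split(
        sids,
        test_size=1.0 - spec.train_frac,
        random_state=(spec.seed if seed is None else seed) % (2**32),
        stratify=labels if spec.stratify else None,
    )
    return FoldPlan(test_subjects=set(test), folds=[set(train)])


def make_cv_folds(train_subjects: Dict[str, str], k: int = 5,
                  seed: int = 0) -> List[Set[str]]:
    """Partition training subjects into ``k`` class-stratified disjoint folds.

    Per class the fold sizes differ by at most one subject; a class with
    fewer than ``k`` subjects is an error.
    """
    sids, labels = _split_labels(train_subjects)
    for cls in set(labels):
        if labels.count(cls) < k:
            raise ValueError(f"class {cls!r} has fewer than k={k} subjects")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**32))
    folds: List[Set[str]] = []
    for _, val_idx in skf.split(np.zeros(len(sids)), labels):
        folds.append({sids[i] for i in val_idx})
    return folds


def build_fold_plan(subjects: Dict[str, str], spec: SplitSpec = SplitSpec()) -> FoldPlan:
    """Full plan: stratified 80/20 subject split plus k stratified folds."""
    plan = split_train_test(subjects, spec)
    train = {s: subjects[s] for s in plan.folds[0]}
    plan.folds = make_cv_folds(train, k=spec.k_folds, seed=spec.seed + 1)
    plan.validate()
    return plan
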