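"""Cohort labeling rules, caps, and subject-disjoint splits."""

import itertools

import numpy as np
import pytest

from ppgsepsis.dataset import (
    CohortLabel,
    MetadataIncompleteError,
    SplitSpec,
    SubjectMeta,
    apply_cohort_criteria,
    build_fold_plan,
    cap_controls_per_code,
    cap_subject_hours,
    filter_has_ppg,
    make_cv_folds,
    normalize_icd9,
    split_train_test,
)


def meta(sid="s1", died=False, icu=1, adm=1, codes=("311",), matched=True, ppg=True):
    return SubjectMeta(subject_id=sid, died_in_hospital=died, n_icu_stays=icu,
                       n_admissions=adm, icd9_codes=set(codes),
                       in_matched_subset=matched, has_ppg=ppg)


class TestCohortCriteria:
    def test_sepsis_case(self):
        lab = apply_cohort_criteria([meta(died=True, codes=("99591",))])[0]
        assert lab.label == "sepsis"

    def test_control_case(self):
        lab = apply_cohort_criteria([meta(codes=("311",))])[0]
        assert lab.label == "control"

    def test_survivor_with_sepsis_code_excluded(self):
        lab = apply_cohort_criteria([meta(codes=("311", "99592"))])[0]
        assert lab.label == "excluded"
        assert "sepsis" in lab.exclusion_reason

    def test_icd9_dot_normalization(self):
        assert normalize_icd9("995.91") == "99591"
        lab = apply_cohort_criteria([meta(died=True, codes=("995.91",))])[0]
        assert lab.label == "sepsis"

    def test_missing_field_raises(self):
        m = meta()
        m.has_ppg = None
        with pytest.raises(MetadataIncompleteError):
            apply_cohort_criteria([m])

    def test_truth_table_oracle(self):
        # exhaustive sweep: every combination of the boolean conditions and
        # code-set composition must agree with a direct re-statement of the
        # selection rules
        sepsis_codes = frozenset({"99591", "99592", "78552"})
        control_codes = frozenset({"311", "3051", "30000", "2948", "3004"})

        code_options = [set(), {"99591"}, {"311"}, {"311", "99592"},
                        {"3004", "2948"}, {"78552", "3051"}, {"4019"}]
        for died, icu, adm, matched, codes in itertools.product(
                (True, False), (0, 1, 2), (1, 2), (True, False), code_options):
            m = meta(died=died, icu=icu, adm=adm, codes=codes, matched=matched)
            got = apply_cohort_criteria([m])[0].label
            if died and icu == 1 and adm == 1 and codes & sepsis_codes and matched:
                expected = "sepsis"
            elif (not died and icu == 1 and adm == 1 and codes & control_codes
                  and not (codes & sepsis_codes) and matched):
                expected = "control"
            else:
                expected = "excluded"
            assert got == expected, (died, icu, adm, matched, codes)

    def test_order_independence(self):
        ms = [meta(sid=f"s{i}", died=bool(i % 2),
                   codes=("99591",) if i % 2 else ("311",)) for i in range(6)]
        fwd = {c.subject_id: c.label for c in apply_cohort_criteria(ms)}
        rev = {c.subject_id: c.label for c in apply_cohort_criteria(ms[::-1])}
        assert fwd == rev


class TestCapControls:
    def _controls(self, n, code):
        return [CohortLabel(f"c{code}_{i}", "control", control_codes={code})
                for i in range(n)]

    def test_over_cap_sampled_down(self):
        kept = cap_controls_per_code(self._controls(55, "311"), max_per_code=40, seed=0)
        assert len(kept) == 40

    def test_under_cap_kept(self):
        kept = cap_controls_per_code(self._controls(10, "3004"), max_per_code=40, seed=0)
        assert len(kept) == 10

    def test_deterministic(self):
        ctl = self._controls(100, "311")
        a = [c.subject_id for c in cap_controls_per_code(ctl, 40, seed=3)]
        b = [c.subject_id for c in cap_controls_per_code(ctl, 40, seed=3)]
        assert a == b

    def test_multi_code_attributed_to_first_in_order(self):
        # a subject under both 3051 and 311 counts toward 311 (first in order)
        multi = [CohortLabel(f"m{i}", "control", control_codes={"311", "3051"})
                 for i in range(45)]
        only_3051 = [CohortLabel(f"t{i}", "control", control_codes={"3051"})
                     for i in range(40)]
        kept = cap_controls_per_code(multi + only_3051, 40, seed=0)
        kept_ids = {c.subject_id for c in kept}
        assert sum(1 for c in kept_ids if c.startswith("m")) == 40
        assert sum(1 for c in kept_ids if c.startswith("t")) == 40


class TestFilterPPG:
    def test_drops_missing_ppg(self):
        ms = [meta(sid="a"), meta(sid="b", ppg=False), meta(sid="c")]
        labs = apply_cohort_criteria(ms)
        kept = filter_has_ppg(labs, ms)
        assert {l.subject_id for l in kept} == {"a", "c"}

    def test_identity_when_all_have_ppg(self):
        ms = [meta(sid="a"), meta(sid="b")]
        labs = apply_cohort_criteria(ms)
        assert len(filter_has_ppg(labs, ms)) == 2


class TestCapSubjectHours:
    def test_cap_floor_and_passthrough(self):
        segs = {"over": list(range(150)), "under": list(range(29)),
                "mid": list(range(60))}
        out = cap_subject_hours(segs, SplitSpec(seed=1))
        assert len(out["over"]) == 90
        assert "under" not in out
        assert out["mid"] == list(range(60))

    def test_never_increases_and_retained_hours_in_band(self):
        rng = np.random.default_rng(0)
        segs = {f"s{i}": list(range(int(rng.integers(0, 200)))) for i in range(30)}
        out = cap_subject_hours(segs, SplitSpec(seed=2))
        for sid, kept in out.items():
            assert len(kept) <= len(segs[sid])
            assert 30 <= len(kept) <= 90
            assert set(kept) <= set(segs[sid])

    def test_sampling_deterministic(self):
        segs = {"s": list(range(200))}
        a = cap_subject_hours(segs, SplitSpec(seed=5))["s"]
        b = cap_subject_hours(segs, SplitSpec(seed=5))["s"]
        assert a == b


def _subjects(n_sepsis, n_control):
    d = {f"sep{i}": "sepsis" for i in range(n_sepsis)}
    d.update({f"ctl{i}": "control" for i in range(n_control)})
    return d


class TestSplits:
    def test_80_20_split_counts(self):
        plan = split_train_test(_subjects(10, 10), SplitSpec(seed=0))
        assert len(plan.test_subjects) == 4
        labels = ["sepsis" if s.startswith("sep") else "control"
                  for s in plan.test_subjects]
        assert labels.count("sepsis") == 2 and labels.count("control") == 2

    def test_small_class_rejected(self):
        with pytest.raises(ValueError):
            split_train_test(_subjects(3, 10))

    def test_fold_sizes_table_counts(self):
        # 68 + 81 training subjects into 5 folds: per-class sizes {13,14} and {16,17}
        folds = make_cv_folds(_subjects(68, 81), k=5, seed=0)
        for f in folds:
            n_sep = sum(1 for s in f if s.startswith("sep"))
            n_ctl = len(f) - n_sep
            assert n_sep in (13, 14)
            assert n_ctl in (16, 17)
        assert sum(len(f) for f in folds) == 149

    def test_too_few_subjects_for_folds(self):
        with pytest.raises(ValueError):
            make_cv_folds(_subjects(4, 10), k=5)

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_invariants_over_seeds(self, seed):
        subjects = _subjects(13, 17)
        spec = SplitSpec(seed=seed)
        plan = build_fold_plan(subjects, spec)
        all_train = plan.train_subjects
        # disjoint, exhaustive
        assert not (all_train & plan.test_subjects)
        assert all_train | plan.test_subjects == set(subjects)
        assert sum(len(f) for f in plan.folds) == len(all_train)
        for i, f in enumerate(plan.folds):
            for g in plan.folds[i + 1:]:
                assert not (f & g)
        # stratification within one subject per class
        frac = 13 / 30
        n_test = len(plan.test_subjects)
        n_sep_test = sum(1 for s in plan.test_subjects if s.startswith("sep"))
        assert abs(n_sep_test - frac * n_test) <= 1

    def test_same_seed_same_split(self):
        a = split_train_test(_subjects(10, 12), SplitSpec(seed=9))
        b = split_train_test(_subjects(10, 12), SplitSpec(seed=9))
        assert a.test_subjects == b.test_subjects
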