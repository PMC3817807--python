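"""Cross-validation bookkeeping, training-case selection, and protocols."""

import numpy as np
import pytest

from cytoprofile.diagnosis import COHORTS, build_cohort_profile
from cytoprofile.experiments import (
    box_stats,
    case_tb_distance,
    make_cv_plan,
    preprocess_cohorts,
    run_multi_profile,
    run_single_profile,
    select_by_distance,
    select_training_cases,
)
from cytoprofile.synth import generate_cohorts


class TestMakeCVPlan:
    def test_folds_are_disjoint_and_sized(self):
        plan = make_cv_plan(36, 21, 15, fold_size=12, seed=0)
        all_idx = np.concatenate(plan.normal_folds)
        assert len(all_idx) == 36
        assert len(np.unique(all_idx)) == 36
        assert all(len(f) == 12 for f in plan.normal_folds)

    @pytest.mark.parametrize("sizes", [(36, 21, 15, 12), (9, 4, 5, 3), (30, 10, 8, 10)])
    def test_counts_match_closed_form(self, sizes):
        n, c, f, fold = sizes
        plan = make_cv_plan(n, c, f, fold_size=fold, seed=1)
        assert plan.n_normal_evaluations == 3 * ((n - fold) + c + f)
        assert plan.n_cll_evaluations == c * (n + (c - 1) + f)
        assert plan.n_fl_evaluations == f * (n + c + (f - 1))
        assert plan.n_diagnoses == 3 * c * f * ((n - fold) + (c - 1) + (f - 1))

    def test_undersized_normal_cohort_rejected(self):
        with pytest.raises(ValueError):
            make_cv_plan(20, 21, 15, fold_size=12)


class TestSelection:
    def test_bruteforce_example(self):
        # distances {2,4,6,9,14}: mean 7, closest value 6 at index 2
        assert select_by_distance([2, 4, 6, 9, 14], fraction=0.15) == [2]

    def test_high_fraction_selects_all(self):
        assert select_by_distance([2, 4, 6, 9, 14], fraction=0.9) == [0, 1, 2, 3, 4]

    @pytest.mark.parametrize("n,expected", [(21, 3), (15, 2), (44, 7), (5, 1)])
    def test_fifteen_percent_counts(self, n, expected):
        rng = np.random.default_rng(0)
        chosen = select_by_distance(rng.uniform(1, 10, size=n), fraction=0.15)
        assert len(chosen) == expected

    def test_ties_broken_by_case_order(self):
        # mean 5; indices 0 and 3 are equally distant from it
        assert select_by_distance([4, 1, 9, 6], fraction=0.25) == [0]

    def test_distance_criterion_on_cases(self, cll_points):
        d = case_tb_distance(cll_points)
        # generating geometry: T (0,1,0) vs B (8,9,8) -> |(8,8,8)| ~ 13.9
        assert 12.0 < d < 16.0

    def test_selection_needs_two_cases(self, cll_points):
        with pytest.raises(ValueError, match="two cases"):
            select_training_cases([cll_points])


class TestBoxStats:
    def test_matches_sorted_percentile_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            values = rng.normal(size=rng.integers(5, 60))

            def percentile(sorted_v, q):
                # linear interpolation between closest ranks
                idx = (len(sorted_v) - 1) * q / 100.0
                lo, hi = int(np.floor(idx)), int(np.ceil(idx))
                frac = idx - lo
                return sorted_v[lo] * (1 - frac) + sorted_v[hi] * frac

            s = np.sort(values)
            stats = box_stats(values)
            assert stats["q1"] == pytest.approx(percentile(s, 25))
            assert stats["median"] == pytest.approx(percentile(s, 50))
            assert stats["q3"] == pytest.approx(percentile(s, 75))

    def test_outliers_beyond_whiskers(self):
        values = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        stats = box_stats(values)
        assert stats["outliers"] == [100.0]
        assert stats["whisker_high"] == 4.0


@pytest.fixture(scope="module")
def small_study():
    tables = generate_cohorts(6, 3, 3, master_seed=5, n_events_range=(700, 1000))
    return preprocess_cohorts(tables)


class TestSingleProfile:
    def test_healthy_cases_rank_highest(self, small_study):
        profile = build_cohort_profile(small_study["Normal"][:2], "Normal", seed=0)
        cases = [c for cohort in COHORTS for c in small_study[cohort]
                 if c not in small_study["Normal"][:2]]
        result = run_single_profile(cases, profile)
        med = {c: result.summaries[c]["median"] for c in COHORTS}
        assert med["Normal"] > med["CLL"]
        assert med["Normal"] > med["FL"]

    def test_single_case_single_record(self, small_study, normal_profile):
        result = run_single_profile(small_study["Normal"][:1], normal_profile)
        assert len(result.records) == 1


class TestMultiProfile:
    def test_bookkeeping_and_no_leakage(self, small_study):
        plan = make_cv_plan(6, 3, 3, fold_size=2, seed=0)
        result = run_multi_profile(plan, small_study, seed=0)
        counts = plan.counts()
        observed = result.ccr_records.groupby("profile").size()
        assert observed["Normal"] == counts["normal_profile_evaluations"]
        assert observed["CLL"] == counts["cll_profile_evaluations"]
        assert observed["FL"] == counts["fl_profile_evaluations"]
        assert result.confusion_counts.to_numpy().sum() == counts["total_diagnoses"]
        # confusion rows sum to the per-cohort diagnosis counts
        for cohort in COHORTS:
            assert (result.confusion_counts.loc[cohort].sum()
                    == plan.n_diagnoses_by_cohort[cohort])
        # leakage check: a normal case never meets a profile whose fold holds it
        normal_ids = [c.case_id for c in small_study["Normal"]]
        rec = result.ccr_records
        for f, fold in enumerate(plan.normal_folds):
            trained = {normal_ids[i] for i in fold}
            seen = set(rec[(rec.profile == "Normal") & (rec.profile_idx == f)
                           & (rec.cohort == "Normal")].case_id)
            assert not (trained & seen)

    def test_matched_profile_dominates(self, small_study):
        plan = make_cv_plan(6, 3, 3, fold_size=2, seed=0)
        result = run_multi_profile(plan, small_study, seed=0)
        mean = result.mean_ccr
        for cohort in COHORTS:
            for other in COHORTS:
                if other != cohort:
                    assert mean.loc[cohort, cohort] > mean.loc[cohort, other]

    def test_size_mismatch_rejected(self, small_study):
        plan = make_cv_plan(36, 21, 15, fold_size=12)
        with pytest.raises(ValueError, match="cohort sizes"):
            run_multi_profile(plan, small_study)
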