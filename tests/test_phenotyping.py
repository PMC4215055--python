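"""Case criteria, index dates, exclusions, control eligibility, matching."""

import numpy as np
import pandas as pd
import pytest

from prodrome.phenotyping import (
    LATE_CAPTURE,
    RETAIN,
    SHORT_HISTORY,
    PhenotypeConfig,
    apply_exclusions,
    assemble_cohort,
    first_diagnosis_date,
    is_control_eligible,
    match_controls,
    meets_case_criteria,
)
from prodrome.records import iter_records

from conftest import make_record


@pytest.fixture(scope="module")
def cfg():
    return PhenotypeConfig()


def case_events(code_day=560, term_day=580, drug_day=600):
    return [
        (0, "visit", ""),
        (code_day, "icd9", "296.30"),
        (term_day, "term", "major_depressive_disorder"),
        (drug_day, "drug_mention", "fluoxetine"),
        (700, "visit", ""),
    ]


class TestCaseCriteria:
    def test_all_three_kinds_of_evidence(self, cfg):
        record = make_record(events=case_events())
        crit = meets_case_criteria(record, cfg)
        assert crit.is_case and crit.has_icd9 and crit.has_term and crit.has_drug

    def test_negated_term_fails_term_criterion(self, cfg):
        events = case_events()
        events[2] = (580, "term", "major_depressive_disorder", True)  # negated
        crit = meets_case_criteria(make_record(events=events), cfg)
        assert not crit.is_case
        assert crit.has_icd9 and crit.has_drug and not crit.has_term

    def test_missing_drug_mention_fails(self, cfg):
        events = [e for e in case_events() if e[1] != "drug_mention"]
        crit = meets_case_criteria(make_record(events=events), cfg)
        assert not crit.is_case and not crit.has_drug

    def test_monotone_adding_events_never_unmakes_a_case(self, cfg):
        rng = np.random.default_rng(7)
        base = case_events()
        record = make_record(events=base)
        assert meets_case_criteria(record, cfg).is_case
        extra = base + [
            (int(rng.integers(0, 700)), "term", f"T{i:03d}",
             bool(rng.random() < 0.5), bool(rng.random() < 0.5))
            for i in range(30)
        ]
        assert meets_case_criteria(make_record(events=extra), cfg).is_case


class TestFirstDiagnosis:
    def test_later_of_the_two_firsts(self, cfg):
        record = make_record(events=case_events(code_day=100, drug_day=150))
        assert first_diagnosis_date(record, cfg) == 150

    def test_tie(self, cfg):
        record = make_record(events=case_events(code_day=200, drug_day=200))
        assert first_diagnosis_date(record, cfg) == 200

    def test_non_case_errors(self, cfg):
        record = make_record(events=[(0, "visit", "")])
        with pytest.raises(ValueError):
            first_diagnosis_date(record, cfg)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_streams_match_exhaustive_scan(self, cfg, seed):
        """Index date equals a brute-force scan for the earliest date with
        both a qualifying code and a qualifying drug mention in the past."""
        rng = np.random.default_rng(seed)
        events = [(0, "visit", ""), (1000, "visit", "")]
        for _ in range(rng.integers(1, 4)):
            events.append((int(rng.integers(0, 1000)), "icd9", "296.30"))
        for _ in range(rng.integers(1, 4)):
            events.append((int(rng.integers(0, 1000)), "drug_mention", "sertraline"))
        events.append((int(rng.integers(0, 1000)), "term", "depressive_disorder"))
        record = make_record(events=events)

        code_days = sorted(d for d, t, *_ in events if t == "icd9")
        drug_days = sorted(d for d, t, *_ in events if t == "drug_mention")
        oracle = next(
            day for day in range(1001)
            if any(d <= day for d in code_days) and any(d <= day for d in drug_days)
        )
        assert first_diagnosis_date(record, cfg) == oracle


class TestExclusions:
    def test_short_history(self, cfg):
        record = make_record(
            events=[(0, "visit", "")] + case_events(code_day=300, drug_day=400)[1:]
        )
        assert apply_exclusions(record, 400, cfg) == SHORT_HISTORY

    def test_late_capture_at_101_days(self, cfg):
        record = make_record(events=case_events(code_day=600, drug_day=701))
        assert apply_exclusions(record, 701, cfg) == LATE_CAPTURE

    def test_gap_of_100_days_retained(self, cfg):
        record = make_record(events=case_events(code_day=600, drug_day=700))
        assert apply_exclusions(record, 700, cfg) == RETAIN

    def test_both_rules_pass(self, cfg):
        record = make_record(events=case_events(code_day=560, drug_day=600))
        assert apply_exclusions(record, 600, cfg) == RETAIN


class TestControlEligibility:
    def test_unrelated_codes_eligible(self, cfg):
        record = make_record(events=[(0, "visit", ""), (10, "icd9", "724.2")])
        assert is_control_eligible(record, cfg)

    def test_negated_depression_term_disqualifies(self, cfg):
        # strict any-mention reading: even a negated mention disqualifies
        record = make_record(
            events=[(0, "visit", ""), (10, "term", "depressive_disorder", True)]
        )
        assert not is_control_eligible(record, cfg)

    def test_code_311_disqualifies(self, cfg):
        record = make_record(events=[(0, "visit", ""), (10, "icd9", "311")])
        assert not is_control_eligible(record, cfg)


def _pool_frame(n, birth_year=1970, history_length=800):
    return pd.DataFrame(
        {
            "patient_id": [f"c{i}" for i in range(n)],
            "birth_year": birth_year,
            "history_length": history_length,
        }
    )


def _case_frame(n=1, birth_year=1970, history_length=800):
    return pd.DataFrame(
        {
            "patient_id": [f"k{i}" for i in range(n)],
            "index_date": 900,
            "birth_year": birth_year,
            "history_length": history_length,
        }
    )


class TestMatching:
    def test_exact_stratum_draw_of_six(self, cfg):
        pairs, shortfall = match_controls(_case_frame(1), _pool_frame(10), cfg, seed=0)
        assert len(pairs) == 6 and not shortfall
        assert pairs["control_id"].nunique() == 6

    def test_shortfall_reported_not_dropped(self, cfg):
        pairs, shortfall = match_controls(_case_frame(1), _pool_frame(5), cfg, seed=0)
        assert len(pairs) == 0
        assert shortfall[0]["patient_id"] == "k0" and shortfall[0]["available"] == 5

    def test_without_replacement_across_cohort(self, cfg):
        pairs, shortfall = match_controls(
            _case_frame(100), _pool_frame(700), cfg, seed=3
        )
        assert not shortfall and len(pairs) == 600
        assert pairs["control_id"].nunique() == 600  # no control reused

    def test_stratum_mismatch_never_matched(self, cfg):
        pool = pd.concat(
            [_pool_frame(6, birth_year=1960), _pool_frame(6, history_length=100)]
        )
        pool["patient_id"] = [f"c{i}" for i in range(len(pool))]
        _, shortfall = match_controls(_case_frame(1), pool, cfg, seed=0)
        assert len(shortfall) == 1

    def test_empty_pool_errors(self, cfg):
        with pytest.raises(ValueError):
            match_controls(_case_frame(1), _pool_frame(0), cfg, seed=0)

    def test_reproducible_given_seed(self, cfg):
        a, _ = match_controls(_case_frame(3), _pool_frame(30), cfg, seed=5)
        b, _ = match_controls(_case_frame(3), _pool_frame(30), cfg, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestVectorisedAssembly:
    def test_agrees_with_record_level_operations(self, small_pamf, small_cohort, cfg):
        """The whole-table cohort assembly and the per-record rule
        applications classify every patient identically."""
        cohort = small_cohort.set_index("patient_id")
        for record in small_pamf.records():
            crit = meets_case_criteria(record, cfg)
            row = cohort.loc[record.patient_id]
            if crit.is_case:
                index_date = first_diagnosis_date(record, cfg)
                verdict = apply_exclusions(record, index_date, cfg)
                if verdict == RETAIN:
                    assert row["label"] == "case"
                    assert int(row["index_date"]) == index_date
                else:
                    assert row["label"] == "excluded"
                    assert row["exclusion_reason"] == verdict
            elif not is_control_eligible(record, cfg):
                assert row["label"] == "excluded"

    def test_matched_pairs_share_stratum_exactly(self, small_pamf, small_cohort, cfg):
        spans = {}
        for record in small_pamf.records():
            spans[record.patient_id] = record.history_length
        birth = dict(
            zip(
                small_pamf.patients["patient_id"].astype(str),
                small_pamf.patients["birth_year"],
            )
        )
        controls = small_cohort[small_cohort["label"] == "control"]
        assert len(controls) > 0
        for row in controls.itertuples():
            case = row.matched_case
            assert birth[str(row.patient_id)] == birth[str(case)]
            assert (
                spans[str(row.patient_id)] // cfg.history_bin_days
                == spans[str(case)] // cfg.history_bin_days
            )

    def test_all_generated_cases_match_at_full_ratio(self, small_cohort):
        counts = small_cohort["label"].value_counts()
        assert counts["case"] * 6 == counts["control"]
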