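"""History truncation, visit-rate binning, blackout, and matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from prodrome.features import (
    CutoffSpec,
    DEFAULT_CUTOFFS,
    apply_pretreatment_blackout,
    assert_no_phq9_columns,
    bin_visit_rate,
    build_feature_matrix,
    ghri_feature_matrix,
    pamf_feature_matrix,
    truncate_history,
    visit_rate,
)
from prodrome.outcomes import first_treatment_episodes
from prodrome.phenotyping import PhenotypeConfig

from conftest import make_record


@pytest.fixture(scope="module")
def cfg():
    return PhenotypeConfig()


class TestTruncation:
    def test_offset_zero_keeps_everything_up_to_index(self):
        record = make_record(events=[(0, "visit", ""), (50, "icd9", "401.9"),
                                     (100, "visit", "")])
        out = truncate_history(record, 100, CutoffSpec(0))
        assert len(out.events) == 3

    def test_boundary_event_dropped(self):
        record = make_record(events=[(0, "visit", ""), (636, "icd9", "401.9"),
                                     (1000, "visit", "")])
        out = truncate_history(record, 1000, CutoffSpec(-365))
        # event at index-364 lies inside the hidden year
        assert "401.9" not in set(out.events["code"])

    @pytest.mark.parametrize("seed", range(3))
    def test_random_record_matches_date_filter_oracle(self, seed):
        rng = np.random.default_rng(seed)
        events = [(int(d), "icd9", f"c{i}") for i, d in
                  enumerate(rng.integers(0, 2000, 50))]
        record = make_record(events=events)
        index, offset = 1500, -183
        out = truncate_history(record, index, CutoffSpec(offset))
        expected = sorted(d for d, _, _ in events if d <= index + offset)
        assert sorted(out.events["date"]) == expected


class TestBlackout:
    def test_event_five_days_before_start_removed(self):
        record = make_record(events=[(95, "term", "T1"), (0, "visit", "")])
        out = apply_pretreatment_blackout(record, 100)
        assert "T1" not in set(out.events["code"])

    def test_event_eleven_days_before_start_kept(self):
        record = make_record(events=[(89, "term", "T1"), (0, "visit", "")])
        out = apply_pretreatment_blackout(record, 100)
        assert "T1" in set(out.events["code"])

    def test_random_stream_matches_window_filter_oracle(self):
        rng = np.random.default_rng(4)
        events = [(int(d), "term", f"t{i}") for i, d in
                  enumerate(rng.integers(0, 200, 80))]
        record = make_record(events=events)
        out = apply_pretreatment_blackout(record, 100, blackout_days=10)
        expected = sorted(d for d, _, _ in events if not (90 < d <= 100))
        assert sorted(out.events["date"]) == expected


class TestVisitRate:
    def test_two_visits_a_month_apart(self):
        record = make_record(events=[(0, "visit", ""), (30, "visit", "")])
        assert visit_rate(record) == pytest.approx(2 / 30 * 365)

    def test_two_visits_a_year_apart(self):
        record = make_record(events=[(0, "visit", ""), (365, "visit", "")])
        assert visit_rate(record) == pytest.approx(2.0)

    def test_single_visit_uses_one_day_denominator(self):
        record = make_record(events=[(10, "visit", "")])
        assert visit_rate(record) == pytest.approx(365.0)

    def test_no_visits_errors(self):
        record = make_record(events=[(0, "icd9", "401.9")])
        with pytest.raises(ValueError):
            visit_rate(record)


class TestVisitBins:
    @pytest.mark.parametrize(
        "rate, expected",
        [(0.0, 0), (1.99, 0), (2.0, 1), (17.99, 8), (18.0, 9), (400.0, 9)],
    )
    def test_left_closed_two_wide_bins(self, rate, expected):
        assert bin_visit_rate(rate) == expected

    def test_partition_of_nonnegative_rates(self):
        rng = np.random.default_rng(0)
        for rate in rng.exponential(8, 200):
            b = bin_visit_rate(float(rate))
            assert 0 <= b <= 9
            if b < 9:
                assert 2 * b <= rate < 2 * (b + 1)
            else:
                assert rate >= 18

    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            bin_visit_rate(-0.1)


def _tiny_tables(events_spec):
    """One-patient events/patients tables from (date, type, code, neg, fh)."""
    rows = []
    for ev in events_spec:
        date, etype, code = ev[0], ev[1], ev[2]
        neg = ev[3] if len(ev) > 3 else False
        fh = ev[4] if len(ev) > 4 else False
        rows.append(("p1", date, etype, code, neg, fh, np.nan))
    events = pd.DataFrame(
        rows,
        columns=["patient_id", "date", "event_type", "code", "negated",
                 "family_history", "value"],
    )
    patients = pd.DataFrame(
        {"patient_id": ["p1"], "birth_year": [1970], "gender": ["M"]}
    )
    return events, patients


class TestMatrixConstruction:
    def test_exactly_the_present_indicators_set(self, cfg):
        events, patients = _tiny_tables(
            [(0, "visit", ""), (10, "icd9", "401.9"), (20, "term", "T1"),
             (900, "visit", "")]
        )
        m = build_feature_matrix(
            events, patients, pd.Series({"p1": 1000}), cfg
        )
        frame = m.to_frame()
        assert frame.loc["p1", "icd9:401.9"] == 1
        assert frame.loc["p1", "term:T1"] == 1
        assert frame.loc["p1", "visit_bin:0"] == 1

    def test_negated_term_contributes_nothing(self, cfg):
        events, patients = _tiny_tables(
            [(0, "visit", ""), (20, "term", "T1", True), (900, "visit", "")]
        )
        m = build_feature_matrix(events, patients, pd.Series({"p1": 1000}), cfg)
        assert "term:T1" not in m.columns

    def test_phenotype_defining_code_absent_and_logged(self, cfg):
        events, patients = _tiny_tables(
            [(0, "visit", ""), (10, "icd9", "296.31"), (20, "icd9", "401.9"),
             (900, "visit", "")]
        )
        m = build_feature_matrix(events, patients, pd.Series({"p1": 1000}), cfg)
        assert not any("296" in c for c in m.columns)
        assert {"feature": "icd9:296.31", "reason": "phenotype_defining"} in (
            m.excluded_features
        )

    def test_no_phenotype_defining_feature_in_cohort_matrix(
        self, small_pamf, small_cohort, cfg
    ):
        matrix, _ = pamf_feature_matrix(
            small_cohort, small_pamf.events, small_pamf.patients, cfg, CutoffSpec(0)
        )
        defining = (
            {f"icd9:{c}" for c in cfg.icd9_code_set}
            | {f"term:{t}" for t in cfg.depression_terms.concepts}
            | {f"term:{i}" for i in cfg.antidepressant_ingredients}
        )
        assert not (set(matrix.columns) & defining)

    def test_feature_nesting_across_cutoffs(self, small_pamf, small_cohort, cfg):
        """Per patient, indicators set at -365 are a subset of those at
        -183, which are a subset of those at 0."""
        mats = {}
        cols = None
        for cutoff in DEFAULT_CUTOFFS:
            m, _ = pamf_feature_matrix(
                small_cohort, small_pamf.events, small_pamf.patients, cfg, cutoff,
                columns=cols,
            )
            cols = cols or m.columns
            mats[cutoff.offset_days] = m
        ind_cols = np.array([
            i for i, c in enumerate(cols)
            if c.split(":")[0] in ("icd9", "term")
        ])
        dense = {off: (m.X.toarray()[:, ind_cols] > 0) for off, m in mats.items()}
        assert (dense[-365] <= dense[-183]).all()
        assert (dense[-183] <= dense[0]).all()

    def test_ghri_matrix_blackout_and_leakage_guard(self, small_ghri, cfg):
        episodes = first_treatment_episodes(small_ghri.treatments)
        with_bl = ghri_feature_matrix(
            episodes, small_ghri.events, small_ghri.patients, cfg,
            include_baseline_phq9=True,
        )
        assert "demo:baseline_phq9" in with_bl.columns
        with pytest.raises(ValueError, match="phq9"):
            assert_no_phq9_columns(with_bl)
        without = ghri_feature_matrix(
            episodes, small_ghri.events, small_ghri.patients, cfg,
            include_baseline_phq9=False,
        )
        assert_no_phq9_columns(without)
        assert "demo:age" in without.columns

    def test_positive_cutoff_rejected(self):
        with pytest.raises(ValueError):
            CutoffSpec(1)
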