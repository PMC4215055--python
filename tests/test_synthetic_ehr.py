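"""Generator structure, determinism, and the statistical laws it promises."""

import hashlib
import io

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prodrome.outcomes import SEVERITY_BINS, first_treatment_episodes
from prodrome.phenotyping import (
    PhenotypeConfig,
    assemble_cohort,
    cohort_composition,
    meets_case_criteria,
)
from prodrome.records import write_events_csv
from prodrome.synthetic_ehr import (
    SimulationConfig,
    TreatmentSimConfig,
    improvement_probability,
    simulate_ghri_population,
    simulate_pamf_population,
)


def _events_hash(events: pd.DataFrame) -> str:
    buf = io.StringIO()
    write_events_csv(events, buf)
    return hashlib.sha256(buf.getvalue().encode()).hexdigest()


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"prevalence": 1.5},
            {"prevalence": -0.1},
            {"signal_strength": 0.5},
            {"visit_rate_mean": 0.0},
            {"n_patients": 0},
            {"n_patients": 5, "prevalence": 0.01},  # prevalence x n < 1
        ],
    )
    def test_bad_pamf_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimulationConfig(**kwargs)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"baseline_phq9_distribution": (0.5, 0.5, 0.0, 0.0, 0.1)},
            {"followup_days": 0},
            {"p_medication": 0.8, "p_psychotherapy": 0.5},
        ],
    )
    def test_bad_treatment_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            TreatmentSimConfig(**kwargs)


class TestPamfStructure:
    def test_deterministic_given_seed(self):
        cfg = SimulationConfig(n_patients=300, seed=11)
        a = simulate_pamf_population(cfg)
        b = simulate_pamf_population(SimulationConfig(n_patients=300, seed=11))
        assert _events_hash(a.events) == _events_hash(b.events)
        assert _events_hash(a.events) != _events_hash(
            simulate_pamf_population(SimulationConfig(n_patients=300, seed=12)).events
        )

    def test_deterministic_stratified_case_count(self):
        pop = simulate_pamf_population(
            SimulationConfig(n_patients=700, prevalence=1 / 7, seed=0)
        )
        assert int(pop.truth["is_case"].sum()) == 100

    def test_event_dates_within_patient_span(self, small_pamf):
        spans = small_pamf.truth.set_index("patient_id")
        grouped = small_pamf.events.groupby("patient_id", observed=True)["date"]
        lo, hi = grouped.min(), grouped.max()
        for pid in spans.index:
            assert lo[pid] >= spans.loc[pid, "first_visit"]
            assert hi[pid] <= spans.loc[pid, "last_visit"]

    def test_case_index_precedes_end_of_history(self, small_pamf):
        cases = small_pamf.truth[small_pamf.truth["is_case"]]
        assert (cases["index_day"] <= cases["last_visit"]).all()

    def test_every_case_meets_criteria_and_controls_never_do(
        self, small_pamf, pheno_config
    ):
        truth = small_pamf.truth.set_index("patient_id")
        for record in small_pamf.records():
            crit = meets_case_criteria(record, pheno_config)
            assert crit.is_case == bool(truth.loc[record.patient_id, "is_case"])

    def test_null_signal_independent_of_case_status(self):
        """With signal_strength 1 the prodromal features carry no case
        information: chi-square p-values over replicates look uniform."""
        pvals = []
        for seed in range(8):
            pop = simulate_pamf_population(
                SimulationConfig(n_patients=400, signal_strength=1.0, seed=seed)
            )
            ev = pop.events
            sig = ev[ev["code"].astype(str).str.startswith("S0")]
            carriers = set(sig["patient_id"].astype(str))
            truth = pop.truth
            has = truth["patient_id"].astype(str).isin(carriers)
            table = pd.crosstab(truth["is_case"], has)
            if table.shape == (2, 2):
                pvals.append(stats.chi2_contingency(table)[1])
        assert min(pvals) > 0.001
        assert 0.2 < np.mean(pvals) < 0.8

    def test_matched_mode_supports_full_ratio_matching(self, small_cohort):
        comp = cohort_composition(small_cohort)
        assert comp["n_controls"] == 6 * comp["n_cases"]


class TestGhriStructure:
    def test_deterministic_given_seed(self):
        a = simulate_ghri_population(TreatmentSimConfig(n_patients=300, seed=5))
        b = simulate_ghri_population(TreatmentSimConfig(n_patients=300, seed=5))
        assert _events_hash(a.events) == _events_hash(b.events)
        pd.testing.assert_frame_equal(a.treatments, b.treatments)

    def test_every_patient_scored_at_start_and_followup(self, small_ghri):
        phq = small_ghri.events[small_ghri.events["event_type"] == "phq9"]
        counts = phq.groupby("patient_id", observed=True).size()
        assert (counts == 2).all()
        assert phq["value"].between(0, 27).all()

    def test_symmetric_null_improvement_rate(self):
        """Intercept 0, baseline coefficient 0, baselines all >= 5: the
        improvement fraction converges to 1/2."""
        cfg = TreatmentSimConfig(
            n_patients=10000,
            baseline_phq9_distribution=(0.0, 0.25, 0.25, 0.25, 0.25),
            improvement_logit_intercept=0.0,
            improvement_logit_baseline_coef=0.0,
            improvement_logit_modality_coef=0.0,
            seed=9,
        )
        pop = simulate_ghri_population(cfg)
        episodes = first_treatment_episodes(pop.treatments)
        rate = episodes["improved"].mean()
        assert rate == pytest.approx(0.5, abs=3 * 0.005)  # binomial 3 sigma

    def test_negative_baseline_coef_gives_decreasing_rates_matching_logistic(self):
        """Empirical improvement rates fall across severity bins and track
        the closed-form logistic curve (floor-adjusted) at large n."""
        cfg = TreatmentSimConfig(n_patients=40000, seed=10)
        pop = simulate_ghri_population(cfg)
        episodes = first_treatment_episodes(pop.treatments)
        truth = pop.truth.set_index("patient_id")
        episodes = episodes.set_index("patient_id").join(
            truth[["p_improve"]], how="left"
        )
        eligible = episodes[episodes["baseline_phq9"] >= 5]
        rates, expected = [], []
        for lo, hi, _name in SEVERITY_BINS[1:]:
            rows = eligible[eligible["baseline_phq9"].between(lo, hi)]
            rates.append(rows["improved"].mean())
            expected.append(rows["p_improve"].mean())
        assert all(a > b for a, b in zip(rates, rates[1:]))
        for emp, exp in zip(rates, expected):
            assert emp == pytest.approx(exp, abs=0.02)

    def test_improvement_probability_closed_form_interaction(self):
        cfg = TreatmentSimConfig(planted_moderator=("M", np.log(2)), seed=0)
        p_with = improvement_probability(
            cfg, np.array([15]), np.array([1]), np.array([1])
        )
        p_without = improvement_probability(
            cfg, np.array([15]), np.array([1]), np.array([0])
        )
        odds = (p_with / (1 - p_with)) / (p_without / (1 - p_without))
        assert odds[0] == pytest.approx(2.0, abs=1e-9)

    def test_both_modality_patients_emit_tied_treatment_rows(self, small_ghri):
        episodes = first_treatment_episodes(small_ghri.treatments)
        n_both = int((episodes["modality"] == "both").sum())
        truth_both = int((small_ghri.truth["modality"] == "both").sum())
        assert n_both == truth_both > 0

    def test_planted_moderator_mentions_precede_blackout(self):
        cfg = TreatmentSimConfig(
            n_patients=500, planted_moderator=("M_planted", 0.7), seed=4
        )
        pop = simulate_ghri_population(cfg)
        mentions = pop.events[pop.events["code"].astype(str) == "M_planted"]
        starts = pop.truth.set_index("patient_id")["treatment_start"]
        gap = mentions["patient_id"].astype(str).map(starts) - mentions["date"]
        assert (gap > 10).all()
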