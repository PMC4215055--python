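"""Seeded synthetic longitudinal EHR populations.

Two generators mirror the two study designs the pipeline serves:

* :func:`simulate_pamf_population` — a primary-care-like population with a
  depressed subpopulation.  Visit streams follow a homogeneous Poisson
  process over a multi-year follow-up; coded diagnoses and annotated text
  terms arrive per visit from a power-law (Zipf-like) rank frequency
  distribution.  Cases accumulate *prodromal* signal features at elevated
  odds inside a pre-index window, and carry the three depression markers
  (ICD-9 code, clean disorder term, antidepressant-ingredient mention)
  clustered around a latent index date, so the rule-based phenotyping
  recovers them.  Controls carry no depression code or term at all.

* :func:`simulate_ghri_population` — a treated cohort scored with the
  PHQ-9 at treatment start and ~90 days later.  Improvement (>= 5-point
  drop) follows a logistic model in baseline severity and modality, with
  an optional planted moderator contributing interaction log-odds under
  medication only.  A set of history features carries severity-linked
  signal so pre-treatment history is informative about baseline severity.

Defaults are calibrated to the aggregate shape of the two source systems:
~14.3% depressed prevalence, ~8-year mean follow-up and ~4.2 visits/year
with ~2 codes and ~1.9 terms per visit on the primary-care side; ~2.5-year
follow-up, ~16 visits/year, the printed five-bin baseline severity mix and
the medication / psychotherapy / both split on the treated side.

Signal mentions are drawn as a thinned Poisson mention process whose
per-visit, per-feature *presence* probability is exactly the configured
Bernoulli rate (duplicate mentions are repeat mentions; every downstream
feature is presence-based).

Identical config + seed gives byte-identical output tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np
import pandas as pd

from .outcomes import BOTH, MEDICATION, PSYCHOTHERAPY, SEVERITY_BINS
from .records import EPOCH_YEAR, EVENT_TYPES, PatientRecord, iter_records
from .terminology import (
    default_antidepressant_ingredients,
    default_depression_icd9_codes,
    default_depression_terms,
)

# Baseline PHQ-9 severity mix of the treated cohort (five bins, minimal ->
# severe).  Proportions follow the printed per-bin counts of a large
# treated cohort; they are normalised here because those counts sum to
# 5261 while the cohort size is quoted as 5651 (see docs/methods.md).
DEFAULT_SEVERITY_COUNTS = (267, 747, 1294, 1652, 1301)

# First-treatment modality mix of the same cohort.
DEFAULT_MODALITY_COUNTS = {MEDICATION: 2472, PSYCHOTHERAPY: 2401, BOTH: 778}


def _zipf_weights(size: int, offset: float = 3.0, exponent: float = 1.1) -> np.ndarray:
    w = (np.arange(size) + offset) ** -exponent
    return w / w.sum()


@dataclass
class SimulationConfig:
    """Primary-care population generator settings.

    ``signal_strength`` multiplies the per-visit odds of each prodromal
    signal feature inside the ``prodrome_days`` window before a case's
    index date; 1.0 plants no signal.
    """

    n_patients: int = 7000
    prevalence: float = 1.0 / 7.0
    prodrome_days: int = 400
    signal_strength: float = 4.0
    n_signal_features: int = 20
    vocab_size_codes: int = 150
    vocab_size_terms: int = 150
    visit_rate_mean: float = 4.2
    followup_years_mean: float = 8.0
    negation_rate: float = 0.05
    family_history_rate: float = 0.03
    seed: int = 0
    # population structure
    matched_mode: bool = True
    p_female: float = 0.552
    codes_per_visit: float = 2.0
    terms_per_visit: float = 1.9
    signal_base_rate: float = 0.02
    marker_window_days: int = 30
    post_index_max_days: int = 90
    min_pre_index_days: int = 600

    def __post_init__(self) -> None:
        if not (0.0 <= self.prevalence <= 1.0):
            raise ValueError("prevalence must lie in [0, 1]")
        for name in ("n_patients", "prodrome_days", "n_signal_features",
                     "vocab_size_codes", "vocab_size_terms"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.signal_strength < 1.0:
            raise ValueError("signal_strength must be >= 1")
        if self.visit_rate_mean <= 0 or self.followup_years_mean <= 0:
            raise ValueError("visit_rate_mean and followup_years_mean must be > 0")
        for name in ("negation_rate", "family_history_rate", "p_female"):
            if not (0.0 <= getattr(self, name) <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if round(self.prevalence * self.n_patients) < 1:
            raise ValueError(
                "prevalence x n_patients < 1: no cases can be generated"
            )


@dataclass
class Population:
    """A simulated population: canonical tables plus latent ground truth."""

    events: pd.DataFrame
    patients: pd.DataFrame
    truth: pd.DataFrame
    treatments: pd.DataFrame | None = None

    def records(self) -> Iterator[PatientRecord]:
        return iter_records(self.events, self.patients)


def _assemble_events(
    pid_codes: list[np.ndarray],
    dates: list[np.ndarray],
    type_codes: list[np.ndarray],
    code_codes: list[np.ndarray],
    negated: list[np.ndarray],
    family: list[np.ndarray],
    values: list[np.ndarray],
    patient_categories: np.ndarray,
    code_categories: list[str],
) -> pd.DataFrame:
    pid = np.concatenate(pid_codes)
    date = np.concatenate(dates)
    etype = np.concatenate(type_codes)
    code = np.concatenate(code_codes)
    neg = np.concatenate(negated)
    fam = np.concatenate(family)
    val = np.concatenate(values)
    order = np.lexsort((date, pid))
    frame = pd.DataFrame(
        {
            "patient_id": pd.Categorical.from_codes(
                pid[order], categories=patient_categories
            ),
            "date": date[order].astype(np.int64),
            "event_type": pd.Categorical.from_codes(
                etype[order], categories=list(EVENT_TYPES)
            ),
            "code": pd.Categorical.from_codes(code[order], categories=code_categories),
            "negated": neg[order],
            "family_history": fam[order],
            "value": val[order],
        }
    )
    return frame


def _poisson_mention_ids(
    rng: np.random.Generator,
    per_visit_presence: np.ndarray,
    n_features: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Thinned Poisson mention process: per visit, each of ``n_features``
    is present with its row's probability; returns (visit row indices,
    feature indices) for every mention."""
    rate = -np.log1p(-np.minimum(per_visit_presence, 0.999999)) * n_features
    counts = rng.poisson(rate)
    rows = np.repeat(np.arange(len(counts)), counts)
    feats = rng.integers(0, n_features, counts.sum())
    return rows, feats


def simulate_pamf_population(config: SimulationConfig) -> Population:
    """Generate a primary-care-like population (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    n_cases = int(round(config.prevalence * n))  # deterministic stratified count
    n_controls = n - n_cases
    is_case = np.zeros(n, dtype=bool)
    is_case[:n_cases] = True

    dep_codes = sorted(default_depression_icd9_codes())
    dep_terms = sorted(default_depression_terms().concepts)
    ingredients = sorted(default_antidepressant_ingredients())

    # --- per-patient structure -------------------------------------------
    age = np.zeros(n, dtype=np.int64)
    span = np.zeros(n, dtype=np.int64)
    start = np.zeros(n, dtype=np.int64)
    index_day = np.full(n, -1, dtype=np.int64)

    age_cases = rng.integers(18, 86, n_cases)
    tail = rng.integers(0, config.post_index_max_days + 1, n_cases)
    mean_span = config.followup_years_mean * 365.0
    pre_scale = max(mean_span - config.min_pre_index_days - tail.mean(), 1.0)
    pre = config.min_pre_index_days + rng.exponential(pre_scale, n_cases).astype(
        np.int64
    )
    span_cases = pre + tail
    start_cases = rng.integers(0, 1000, n_cases)
    age[:n_cases] = age_cases
    span[:n_cases] = span_cases
    start[:n_cases] = start_cases
    index_day[:n_cases] = start_cases + pre

    if n_controls:
        if config.matched_mode and n_cases:
            template = np.arange(n_controls) % n_cases
            bin_lo = (span_cases[template] // 183) * 183
            span_ctrl = bin_lo + rng.integers(0, 183, n_controls)
            age_ctrl = age_cases[template]
            birth_year_ctrl_like = True
        else:
            template = None
            age_ctrl = rng.integers(18, 86, n_controls)
            span_ctrl = 200 + rng.exponential(
                max(mean_span - 200, 1.0), n_controls
            ).astype(np.int64)
        start_ctrl = rng.integers(0, 1000, n_controls)
        age[n_cases:] = age_ctrl
        span[n_cases:] = span_ctrl
        start[n_cases:] = start_ctrl

    last = start + span
    # birth year gives the target integer age at the index date (cases) or
    # at end of history (unmatched controls); matched controls copy their
    # template case's birth year so the age stratum matches exactly.
    ref_day = np.where(is_case, index_day, last)
    birth_year = EPOCH_YEAR + ref_day // 365 - age
    if n_controls and config.matched_mode and n_cases:
        birth_year[n_cases:] = birth_year[:n_cases][template]
    gender = np.where(rng.random(n) < config.p_female, "F", "M")

    # --- visits -----------------------------------------------------------
    lam = np.maximum(config.visit_rate_mean * span / 365.0 - 2.0, 0.1)
    n_visits = 2 + rng.poisson(lam)
    mid = n_visits - 2
    pid_mid = np.repeat(np.arange(n), mid)
    mid_dates = start[pid_mid] + rng.integers(1, np.maximum(span[pid_mid], 2))
    visit_pid = np.concatenate([np.arange(n), np.arange(n), pid_mid])
    visit_date = np.concatenate([start, last, mid_dates])

    n_vis = len(visit_pid)
    t_visit = EVENT_TYPES.index("visit")
    t_icd9 = EVENT_TYPES.index("icd9")
    t_term = EVENT_TYPES.index("term")
    t_drug = EVENT_TYPES.index("drug_mention")

    # --- background codes and terms --------------------------------------
    bg_codes = [f"C{r:03d}" for r in range(config.vocab_size_codes)]
    bg_terms = [f"T{r:03d}" for r in range(config.vocab_size_terms)]
    sig_terms = [f"S{r:02d}" for r in range(config.n_signal_features)]
    # category 0 is the blank code carried by visit events
    categories = ([""] + bg_codes + bg_terms + sig_terms + dep_codes + dep_terms
                  + ingredients)
    off_bg = 1
    off_terms = off_bg + len(bg_codes)
    off_sig = off_terms + len(bg_terms)
    off_dep_codes = off_sig + len(sig_terms)
    off_dep_terms = off_dep_codes + len(dep_codes)
    off_ingredients = off_dep_terms + len(dep_terms)

    code_counts = rng.poisson(config.codes_per_visit, n_vis)
    code_rows = np.repeat(np.arange(n_vis), code_counts)
    code_ids = rng.choice(
        config.vocab_size_codes, code_counts.sum(), p=_zipf_weights(config.vocab_size_codes)
    )
    term_counts = rng.poisson(config.terms_per_visit, n_vis)
    term_rows = np.repeat(np.arange(n_vis), term_counts)
    term_ids = rng.choice(
        config.vocab_size_terms, term_counts.sum(), p=_zipf_weights(config.vocab_size_terms)
    )

    # --- prodromal signal mentions ---------------------------------------
    case_visit = is_case[visit_pid]
    in_window = (
        case_visit
        & (visit_date >= index_day[visit_pid] - config.prodrome_days)
        & (visit_date <= index_day[visit_pid])
    )
    p0 = config.signal_base_rate
    odds0 = p0 / (1.0 - p0)
    p_in = odds0 * config.signal_strength / (1.0 + odds0 * config.signal_strength)
    presence = np.where(in_window, p_in, p0)
    sig_rows, sig_ids = _poisson_mention_ids(rng, presence, config.n_signal_features)

    # --- depression markers for cases ------------------------------------
    gap = rng.integers(0, min(100, config.marker_window_days) + 1, n_cases)
    marker_code_day = index_day[:n_cases] - gap
    marker_drug_day = index_day[:n_cases]
    marker_term_day = index_day[:n_cases] - rng.integers(
        0, config.marker_window_days + 1, n_cases
    )
    marker_code_id = off_dep_codes + rng.integers(0, len(dep_codes), n_cases)
    marker_term_id = off_dep_terms + rng.integers(0, len(dep_terms), n_cases)
    marker_drug_id = off_ingredients + rng.integers(0, len(ingredients), n_cases)
    # repeat mentions after the index, inside the record tail
    repeat_day = np.minimum(
        index_day[:n_cases] + rng.integers(0, config.post_index_max_days + 1, n_cases),
        last[:n_cases],
    )

    case_ids = np.arange(n_cases)
    marker_pid = np.concatenate([case_ids] * 4)
    marker_date = np.concatenate(
        [marker_code_day, marker_drug_day, marker_term_day, repeat_day]
    )
    marker_type = np.concatenate(
        [
            np.full(n_cases, t_icd9),
            np.full(n_cases, t_drug),
            np.full(n_cases, t_term),
            np.full(n_cases, t_icd9),
        ]
    )
    marker_code = np.concatenate(
        [marker_code_id, marker_drug_id, marker_term_id, marker_code_id]
    )

    # --- assemble ---------------------------------------------------------
    n_code_ev = len(code_rows)
    n_term_ev = len(term_rows)
    n_sig_ev = len(sig_rows)
    term_neg = rng.random(n_term_ev) < config.negation_rate
    term_fam = rng.random(n_term_ev) < config.family_history_rate
    sig_neg = rng.random(n_sig_ev) < config.negation_rate
    sig_fam = rng.random(n_sig_ev) < config.family_history_rate

    patient_categories = np.array([f"P{i:06d}" for i in range(n)])
    events = _assemble_events(
        pid_codes=[
            visit_pid, visit_pid[code_rows], visit_pid[term_rows],
            visit_pid[sig_rows], marker_pid,
        ],
        dates=[
            visit_date, visit_date[code_rows], visit_date[term_rows],
            visit_date[sig_rows], marker_date,
        ],
        type_codes=[
            np.full(n_vis, t_visit), np.full(n_code_ev, t_icd9),
            np.full(n_term_ev, t_term), np.full(n_sig_ev, t_term), marker_type,
        ],
        code_codes=[
            np.full(n_vis, 0), off_bg + code_ids, off_terms + term_ids,
            off_sig + sig_ids, marker_code,
        ],
        negated=[
            np.zeros(n_vis, bool), np.zeros(n_code_ev, bool), term_neg,
            sig_neg, np.zeros(len(marker_pid), bool),
        ],
        family=[
            np.zeros(n_vis, bool), np.zeros(n_code_ev, bool), term_fam,
            sig_fam, np.zeros(len(marker_pid), bool),
        ],
        values=[
            np.full(n_vis, np.nan), np.full(n_code_ev, np.nan),
            np.full(n_term_ev, np.nan), np.full(n_sig_ev, np.nan),
            np.full(len(marker_pid), np.nan),
        ],
        patient_categories=patient_categories,
        code_categories=categories,
    )
    # visits carry no code: blank out (category stays but code '' clearer)
    patients = pd.DataFrame(
        {
            "patient_id": patient_categories,
            "birth_year": birth_year,
            "gender": gender,
        }
    )
    truth = pd.DataFrame(
        {
            "patient_id": patient_categories,
            "is_case": is_case,
            "index_day": np.where(is_case, index_day, -1),  # -1: no index
            "first_visit": start,
            "last_visit": last,
            "age": age,
        }
    )
    return Population(events=events, patients=patients, truth=truth)


# ---------------------------------------------------------------------------
# treated cohort


@dataclass
class TreatmentSimConfig:
    """Treated-cohort generator settings.

    ``planted_moderator`` is an optional ``(feature_id, interaction
    log-odds)`` pair: carriers of the feature get the extra log-odds of
    improvement under medication only (the differential-response signal the
    moderator analysis should recover).
    """

    n_patients: int = 5651
    baseline_phq9_distribution: tuple[float, ...] = tuple(
        c / sum(DEFAULT_SEVERITY_COUNTS) for c in DEFAULT_SEVERITY_COUNTS
    )
    p_medication: float = DEFAULT_MODALITY_COUNTS[MEDICATION] / 5651
    p_psychotherapy: float = DEFAULT_MODALITY_COUNTS[PSYCHOTHERAPY] / 5651
    improvement_logit_intercept: float = 1.8512
    improvement_logit_baseline_coef: float = -0.15
    improvement_logit_modality_coef: float = 1.372
    planted_moderator: tuple[str, float] | None = None
    planted_moderator_prevalence: float = 0.3
    followup_days: int = 90
    seed: int = 0
    # history structure
    vocab_size_terms: int = 300
    visit_rate_mean: float = 16.0
    followup_years_mean: float = 2.5
    negation_rate: float = 0.05
    family_history_rate: float = 0.03
    p_female: float = 0.703
    terms_per_visit: float = 2.0
    n_severity_features: int = 20
    severity_base_rate: float = 0.02
    severity_log_odds_per_point: float = 0.08
    min_pre_treatment_days: int = 180

    def __post_init__(self) -> None:
        probs = np.asarray(self.baseline_phq9_distribution, dtype=float)
        if len(probs) != len(SEVERITY_BINS):
            raise ValueError("baseline distribution needs one weight per severity bin")
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("baseline_phq9_distribution must sum to 1 (within 1e-9)")
        if self.followup_days <= 0:
            raise ValueError("followup_days must be > 0")
        if not (0.0 <= self.p_medication + self.p_psychotherapy <= 1.0):
            raise ValueError("modality probabilities must sum to <= 1")
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")

    @property
    def p_both(self) -> float:
        return 1.0 - self.p_medication - self.p_psychotherapy


def improvement_probability(
    config: TreatmentSimConfig,
    baseline: np.ndarray,
    medication_like: np.ndarray,
    has_moderator: np.ndarray | None = None,
) -> np.ndarray:
    """Closed-form improvement probability of the generating model."""
    logit = (
        config.improvement_logit_intercept
        + config.improvement_logit_baseline_coef * np.asarray(baseline, dtype=float)
        + config.improvement_logit_modality_coef * np.asarray(medication_like, float)
    )
    if config.planted_moderator is not None and has_moderator is not None:
        _, beta = config.planted_moderator
        logit = logit + beta * np.asarray(has_moderator, float) * np.asarray(
            medication_like, float
        )
    return 1.0 / (1.0 + np.exp(-logit))


def simulate_ghri_population(config: TreatmentSimConfig) -> Population:
    """Generate a treated cohort with first-treatment episodes, baseline and
    ~90-day PHQ-9 scores, and pre-treatment history (see module docstring)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    # baseline severity: bin then uniform integer score inside the bin
    probs = np.asarray(config.baseline_phq9_distribution, dtype=float)
    bins = rng.choice(len(SEVERITY_BINS), n, p=probs / probs.sum())
    lo = np.array([b[0] for b in SEVERITY_BINS])
    hi = np.array([b[1] for b in SEVERITY_BINS])
    baseline = rng.integers(lo[bins], hi[bins] + 1)

    modality = rng.choice(
        [MEDICATION, PSYCHOTHERAPY, BOTH],
        n,
        p=[config.p_medication, config.p_psychotherapy, config.p_both],
    )
    med_like = (modality == MEDICATION) | (modality == BOTH)

    has_mod = np.zeros(n, dtype=bool)
    if config.planted_moderator is not None:
        has_mod = rng.random(n) < config.planted_moderator_prevalence

    p_improve = improvement_probability(config, baseline, med_like, has_mod)
    improved = rng.random(n) < p_improve
    delta = np.where(
        improved,
        5 + rng.poisson(3.0, n),
        rng.integers(-8, 5, n),
    )
    followup = np.clip(baseline - delta, 0, 27)

    # --- record structure -------------------------------------------------
    mean_span = config.followup_years_mean * 365.0
    tail = rng.integers(0, 181, n)
    pre_scale = max(
        mean_span - config.min_pre_treatment_days - config.followup_days - 90, 1.0
    )
    pre = config.min_pre_treatment_days + rng.exponential(pre_scale, n).astype(np.int64)
    start = rng.integers(0, 1000, n)
    treat_start = start + pre
    last = treat_start + config.followup_days + tail
    span = last - start
    age = rng.integers(18, 86, n)
    birth_year = EPOCH_YEAR + treat_start // 365 - age
    gender = np.where(rng.random(n) < config.p_female, "F", "M")

    lam = np.maximum(config.visit_rate_mean * span / 365.0 - 2.0, 0.1)
    n_visits = 2 + rng.poisson(lam)
    mid = n_visits - 2
    pid_mid = np.repeat(np.arange(n), mid)
    mid_dates = start[pid_mid] + rng.integers(1, np.maximum(span[pid_mid], 2))
    visit_pid = np.concatenate([np.arange(n), np.arange(n), pid_mid])
    visit_date = np.concatenate([start, last, mid_dates])
    n_vis = len(visit_pid)

    bg_terms = [f"G{r:03d}" for r in range(config.vocab_size_terms)]
    sev_terms = [f"H{r:02d}" for r in range(config.n_severity_features)]
    planted_name = (
        config.planted_moderator[0] if config.planted_moderator is not None
        else "M_planted"
    )
    categories = [""] + bg_terms + sev_terms + [planted_name]
    off_bg = 1
    off_sev = off_bg + len(bg_terms)
    off_planted = off_sev + len(sev_terms)

    term_counts = rng.poisson(config.terms_per_visit, n_vis)
    term_rows = np.repeat(np.arange(n_vis), term_counts)
    term_ids = rng.choice(
        config.vocab_size_terms, term_counts.sum(),
        p=_zipf_weights(config.vocab_size_terms),
    )

    # severity-linked features: per-visit presence odds scale with the
    # patient's baseline score (centred at the scale midpoint 13.5)
    base_logit = np.log(config.severity_base_rate / (1 - config.severity_base_rate))
    sev_logit = base_logit + config.severity_log_odds_per_point * (
        baseline[visit_pid] - 13.5
    )
    sev_presence = 1.0 / (1.0 + np.exp(-sev_logit))
    sev_rows, sev_ids = _poisson_mention_ids(rng, sev_presence, config.n_severity_features)

    # planted moderator mentions: a few pre-treatment mentions per carrier
    carrier_idx = np.nonzero(has_mod)[0]
    n_mentions = rng.integers(1, 4, len(carrier_idx))
    planted_pid = np.repeat(carrier_idx, n_mentions)
    window = np.maximum(pre[planted_pid] - 15, 1)
    planted_date = start[planted_pid] + rng.integers(0, window)

    t_visit = EVENT_TYPES.index("visit")
    t_term = EVENT_TYPES.index("term")
    t_phq9 = EVENT_TYPES.index("phq9")

    n_term_ev = len(term_rows)
    n_sev_ev = len(sev_rows)
    term_neg = rng.random(n_term_ev) < config.negation_rate
    term_fam = rng.random(n_term_ev) < config.family_history_rate
    sev_neg = rng.random(n_sev_ev) < config.negation_rate
    sev_fam = rng.random(n_sev_ev) < config.family_history_rate

    ids = np.arange(n)
    phq_pid = np.concatenate([ids, ids])
    phq_date = np.concatenate([treat_start, treat_start + config.followup_days])
    phq_val = np.concatenate([baseline, followup]).astype(float)

    patient_categories = np.array([f"G{i:06d}" for i in range(n)])
    events = _assemble_events(
        pid_codes=[visit_pid, visit_pid[term_rows], visit_pid[sev_rows],
                   planted_pid, phq_pid],
        dates=[visit_date, visit_date[term_rows], visit_date[sev_rows],
               planted_date, phq_date],
        type_codes=[
            np.full(n_vis, t_visit), np.full(n_term_ev, t_term),
            np.full(n_sev_ev, t_term), np.full(len(planted_pid), t_term),
            np.full(2 * n, t_phq9),
        ],
        code_codes=[
            np.full(n_vis, 0), off_bg + term_ids, off_sev + sev_ids,
            np.full(len(planted_pid), off_planted), np.full(2 * n, 0),
        ],
        negated=[
            np.zeros(n_vis, bool), term_neg, sev_neg,
            np.zeros(len(planted_pid), bool), np.zeros(2 * n, bool),
        ],
        family=[
            np.zeros(n_vis, bool), term_fam, sev_fam,
            np.zeros(len(planted_pid), bool), np.zeros(2 * n, bool),
        ],
        values=[
            np.full(n_vis, np.nan), np.full(n_term_ev, np.nan),
            np.full(n_sev_ev, np.nan), np.full(len(planted_pid), np.nan),
            phq_val,
        ],
        patient_categories=patient_categories,
        code_categories=categories,
    )

    patients = pd.DataFrame(
        {
            "patient_id": patient_categories,
            "birth_year": birth_year,
            "gender": gender,
        }
    )
    rows = []
    for i in range(n):
        mods = (
            [MEDICATION, PSYCHOTHERAPY] if modality[i] == BOTH else [modality[i]]
        )
        for m in mods:
            rows.append(
                (
                    patient_categories[i], int(treat_start[i]), m,
                    int(baseline[i]), int(followup[i]),
                )
            )
    treatments = pd.DataFrame(
        rows,
        columns=["patient_id", "start_day", "modality", "baseline_phq9",
                 "followup_phq9"],
    )
    truth = pd.DataFrame(
        {
            "patient_id": patient_categories,
            "modality": modality,
            "baseline_phq9": baseline,
            "followup_phq9": followup,
            "p_improve": p_improve,
            "improved_draw": improved,
            "has_moderator": has_mod,
            "treatment_start": treat_start,
        }
    )
    return Population(
        events=events, patients=patients, truth=truth, treatments=treatments
    )
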