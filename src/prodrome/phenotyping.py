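"""Rule-based depression phenotyping, index dates, and case-control matching.

A patient is a *case* when three kinds of evidence co-occur in the record:
a depression ICD-9 code, a clean (non-negated, non-family-history)
depression disorder term in the clinical text, and a mention of a
depression-specific antidepressant ingredient.  The *index date* (time of
first diagnosis) is the earliest date by which both a depression code and
an ingredient mention have occurred.  Cases need at least 1.5 years of
visits before the index and at most 100 days between the first code and
first ingredient mention (patients diagnosed before their record began
mostly fail this gap rule).  Controls carry no depression code and no
depression term mention at all, and are matched 1:6 to cases on integer
age and 6-month history-length bin.

Operations exist in two forms: per-record (one :class:`PatientRecord`) and
a vectorised whole-table cohort assembly (:func:`assemble_cohort`) used at
population scale; both apply identical rules.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .records import DAYS_PER_YEAR, EPOCH_YEAR, PatientRecord
from .terminology import (
    TermSet,
    canonical_icd9,
    default_antidepressant_ingredients,
    default_depression_icd9_codes,
    default_depression_terms,
)

# exclusion reason codes
SHORT_HISTORY = "short_history"
LATE_CAPTURE = "late_capture"
INELIGIBLE = "ineligible"
NOT_SELECTED = "not_selected"
RETAIN = "retain"


@dataclass
class PhenotypeConfig:
    """Constants of the phenotyping rules.

    Durations are integer days: 1.5 years = 548 days of pre-index history,
    183-day (6-month) history bins for matching, a 100-day maximum gap
    between first code and first ingredient mention, and a 1:6 matching
    ratio mirroring ~14% depression prevalence.
    """

    icd9_code_set: set[str] = field(default_factory=default_depression_icd9_codes)
    depression_terms: TermSet = field(default_factory=default_depression_terms)
    antidepressant_ingredients: set[str] = field(
        default_factory=default_antidepressant_ingredients
    )
    min_history_days: int = 548
    max_code_drug_gap_days: int = 100
    match_ratio: int = 6
    history_bin_days: int = 183

    def __post_init__(self) -> None:
        if min(self.min_history_days, self.max_code_drug_gap_days,
               self.history_bin_days) <= 0:
            raise ValueError("durations must be positive")
        if self.match_ratio < 1:
            raise ValueError("match_ratio must be >= 1")
        self._canonical_codes = {canonical_icd9(c) for c in self.icd9_code_set}

    @property
    def canonical_codes(self) -> set[str]:
        return self._canonical_codes


@dataclass(frozen=True)
class CaseCriteria:
    """Per-criterion breakdown of the case definition."""

    has_icd9: bool
    has_term: bool
    has_drug: bool

    @property
    def is_case(self) -> bool:
        return self.has_icd9 and self.has_term and self.has_drug


@dataclass
class CohortAssignment:
    patient_id: str
    label: str  # "case" | "control" | "excluded"
    index_date: int | None = None
    matched_case: str | None = None
    exclusion_reason: str | None = None


# ---------------------------------------------------------------------------
# event-mask helpers (shared by the record-level and vectorised paths)


def _icd9_mask(events: pd.DataFrame, config: PhenotypeConfig) -> np.ndarray:
    is_code = events["event_type"].to_numpy() == "icd9"
    codes = events["code"]
    if isinstance(codes.dtype, pd.CategoricalDtype):
        cat_hit = np.fromiter(
            (canonical_icd9(str(c)) in config.canonical_codes
             for c in codes.cat.categories),
            dtype=bool, count=len(codes.cat.categories),
        )
        idx = codes.cat.codes.to_numpy()
        in_set = np.zeros(len(codes), dtype=bool)
        valid = idx >= 0
        in_set[valid] = cat_hit[idx[valid]]
    else:
        uniq = pd.unique(codes)
        hit = {c for c in uniq if canonical_icd9(str(c)) in config.canonical_codes}
        in_set = codes.isin(hit).to_numpy()
    return is_code & in_set


def _term_mask(events: pd.DataFrame, config: PhenotypeConfig,
               clean_only: bool) -> np.ndarray:
    mask = (events["event_type"].to_numpy() == "term") & events["code"].isin(
        config.depression_terms.concepts
    ).to_numpy()
    if clean_only:
        mask &= ~events["negated"].to_numpy() & ~events["family_history"].to_numpy()
    return mask


def _drug_mask(events: pd.DataFrame, config: PhenotypeConfig) -> np.ndarray:
    types = events["event_type"].to_numpy()
    mask = ((types == "drug_mention") | (types == "term")) & events["code"].isin(
        config.antidepressant_ingredients
    ).to_numpy()
    mask &= ~events["negated"].to_numpy() & ~events["family_history"].to_numpy()
    return mask


# ---------------------------------------------------------------------------
# record-level operations


def meets_case_criteria(record: PatientRecord, config: PhenotypeConfig) -> CaseCriteria:
    """Evaluate the three-way case definition on one record.

    Monotone in the event stream: adding events can only flip criteria
    false -> true.
    """
    ev = record.events
    return CaseCriteria(
        has_icd9=bool(_icd9_mask(ev, config).any()),
        has_term=bool(_term_mask(ev, config, clean_only=True).any()),
        has_drug=bool(_drug_mask(ev, config).any()),
    )


def first_diagnosis_date(record: PatientRecord, config: PhenotypeConfig) -> int:
    """Earliest date by which both a depression code and an antidepressant
    ingredient mention have occurred: max of the two first-occurrence dates."""
    crit = meets_case_criteria(record, config)
    if not crit.is_case:
        raise ValueError(
            f"patient {record.patient_id} does not meet the case criteria"
        )
    ev = record.events
    dates = ev["date"].to_numpy()
    first_code = int(dates[_icd9_mask(ev, config)].min())
    first_drug = int(dates[_drug_mask(ev, config)].min())
    return max(first_code, first_drug)


def apply_exclusions(record: PatientRecord, index_date: int,
                     config: PhenotypeConfig) -> str:
    """History-sufficiency rules for cases; returns ``"retain"`` or an
    exclusion reason code."""
    if index_date - record.first_visit < config.min_history_days:
        return SHORT_HISTORY
    ev = record.events
    dates = ev["date"].to_numpy()
    first_code = int(dates[_icd9_mask(ev, config)].min())
    first_drug = int(dates[_drug_mask(ev, config)].min())
    if abs(first_code - first_drug) > config.max_code_drug_gap_days:
        return LATE_CAPTURE
    return RETAIN


def is_control_eligible(record: PatientRecord, config: PhenotypeConfig) -> bool:
    """Controls have neither a depression code nor *any* depression term
    mention — negated or family-history mentions also disqualify (the
    strict any-mention reading)."""
    ev = record.events
    if _icd9_mask(ev, config).any():
        return False
    if _term_mask(ev, config, clean_only=False).any():
        return False
    return True


# ---------------------------------------------------------------------------
# matching


def age_at(birth_year: int, day: int) -> int:
    return EPOCH_YEAR + day // DAYS_PER_YEAR - birth_year


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    config: PhenotypeConfig,
    seed: int,
) -> tuple[pd.DataFrame, list[dict]]:
    """Match ``config.match_ratio`` controls to each case on exact integer
    age (at the case's index date) and exact 6-month history-length bin.

    ``cases`` columns: patient_id, index_date, birth_year, history_length.
    ``pool`` columns: patient_id, birth_year, history_length.

    Sampling is uniform without replacement across the whole cohort, so no
    control serves two cases.  Cases whose stratum holds fewer than
    ``match_ratio`` unused candidates are reported in the shortfall list
    and receive no controls rather than a partial set.

    Returns (pairs DataFrame with columns case_id / control_id, shortfall
    records).
    """
    if len(pool) == 0:
        raise ValueError("control pool is empty")
    rng = np.random.default_rng(seed)
    bin_days = config.history_bin_days
    strata: dict[tuple[int, int], list[str]] = {}
    for row in pool.itertuples():
        key = (int(row.birth_year), int(row.history_length) // bin_days)
        strata.setdefault(key, []).append(str(row.patient_id))
    for key in sorted(strata):
        rng.shuffle(strata[key])
    pairs: list[tuple[str, str]] = []
    shortfall: list[dict] = []
    for row in cases.itertuples():
        # same integer age at the case's index date <=> same birth year
        key = (int(row.birth_year), int(row.history_length) // bin_days)
        bucket = strata.get(key, [])
        if len(bucket) < config.match_ratio:
            shortfall.append(
                {"patient_id": str(row.patient_id), "stratum": key,
                 "available": len(bucket)}
            )
            continue
        for _ in range(config.match_ratio):
            pairs.append((str(row.patient_id), bucket.pop()))
    pairs_frame = pd.DataFrame(pairs, columns=["case_id", "control_id"])
    return pairs_frame, shortfall


# ---------------------------------------------------------------------------
# vectorised cohort assembly


def _per_patient_first(events: pd.DataFrame, mask: np.ndarray) -> pd.Series:
    sub = events.loc[mask, ["patient_id", "date"]]
    return sub.groupby("patient_id", observed=True)["date"].min()


def patient_spans(events: pd.DataFrame) -> pd.DataFrame:
    """first_visit / last_visit / history_length per patient, from visit
    events (falling back to all events for visit-free records)."""
    visits = events[events["event_type"] == "visit"]
    base = visits if len(visits) else events
    grouped = base.groupby("patient_id", observed=True)["date"]
    spans = pd.DataFrame({"first_visit": grouped.min(), "last_visit": grouped.max()})
    missing = events.loc[
        ~events["patient_id"].isin(spans.index), ["patient_id", "date"]
    ]
    if len(missing):
        grouped = missing.groupby("patient_id", observed=True)["date"]
        extra = pd.DataFrame({"first_visit": grouped.min(), "last_visit": grouped.max()})
        spans = pd.concat([spans, extra])
    spans["history_length"] = spans["last_visit"] - spans["first_visit"]
    return spans


def assemble_cohort(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    config: PhenotypeConfig,
    seed: int,
    match: bool = True,
) -> pd.DataFrame:
    """Apply the full phenotyping rule set to an event table and return one
    assignment row per patient.

    Output columns: patient_id, label (case / control / excluded),
    index_date (cases: first diagnosis; controls: end of history),
    matched_case, exclusion_reason.
    """
    spans = patient_spans(events)
    icd9_first = _per_patient_first(events, _icd9_mask(events, config))
    term_clean_first = _per_patient_first(
        events, _term_mask(events, config, clean_only=True)
    )
    term_any = {
        str(p)
        for p in events.loc[
            _term_mask(events, config, clean_only=False), "patient_id"
        ].unique()
    }
    drug_first = _per_patient_first(events, _drug_mask(events, config))

    # normalise ids to plain strings so joins align regardless of source dtype
    for series in (icd9_first, term_clean_first, drug_first):
        series.index = series.index.astype(str)
    spans.index = spans.index.astype(str)
    patients = patients.assign(patient_id=patients["patient_id"].astype(str))

    table = patients.set_index("patient_id").join(spans, how="left")
    table["f_code"] = icd9_first
    table["f_term"] = term_clean_first
    table["f_drug"] = drug_first
    is_case = table[["f_code", "f_term", "f_drug"]].notna().all(axis=1)
    index_date = table[["f_code", "f_drug"]].max(axis=1)

    label = pd.Series("excluded", index=table.index, dtype=object)
    reason = pd.Series(None, index=table.index, dtype=object)

    short = is_case & (index_date - table["first_visit"] < config.min_history_days)
    late = is_case & ~short & (
        (table["f_code"] - table["f_drug"]).abs() > config.max_code_drug_gap_days
    )
    retained = is_case & ~short & ~late
    label[retained] = "case"
    reason[short] = SHORT_HISTORY
    reason[late] = LATE_CAPTURE

    has_code = table["f_code"].notna()
    eligible = ~is_case & ~has_code & ~table.index.isin(term_any)
    reason[~is_case & ~eligible] = INELIGIBLE

    out = pd.DataFrame(
        {
            "patient_id": table.index,
            "label": label.to_numpy(),
            "index_date": np.where(retained, index_date, np.nan),
            "matched_case": None,
            "exclusion_reason": reason.to_numpy(),
        }
    ).reset_index(drop=True)

    pool_ids = table.index[eligible]
    if match and retained.any():
        cases_frame = pd.DataFrame(
            {
                "patient_id": table.index[retained],
                "index_date": index_date[retained].astype(int),
                "birth_year": table.loc[retained, "birth_year"].astype(int),
                "history_length": table.loc[retained, "history_length"].astype(int),
            }
        )
        pool_frame = pd.DataFrame(
            {
                "patient_id": pool_ids,
                "birth_year": table.loc[eligible, "birth_year"].astype(int),
                "history_length": table.loc[eligible, "history_length"].astype(int),
            }
        )
        pairs, _shortfall = match_controls(cases_frame, pool_frame, config, seed)
        control_map = dict(zip(pairs["control_id"], pairs["case_id"]))
        is_control = out["patient_id"].isin(control_map)
        out.loc[is_control, "label"] = "control"
        out.loc[is_control, "matched_case"] = out.loc[is_control, "patient_id"].map(
            control_map
        )
        out.loc[is_control, "index_date"] = out.loc[is_control, "patient_id"].map(
            spans["last_visit"]
        )
        leftover = out["patient_id"].isin(set(pool_ids) - set(control_map))
        out.loc[leftover, "exclusion_reason"] = NOT_SELECTED
    else:
        # unmatched mode: every eligible pool member is a control
        is_control = out["patient_id"].isin(pool_ids)
        out.loc[is_control, "label"] = "control"
        out.loc[is_control, "index_date"] = out.loc[is_control, "patient_id"].map(
            spans["last_visit"]
        )

    out["index_date"] = out["index_date"].astype("Int64")
    return out


def cohort_composition(cohort: pd.DataFrame) -> dict:
    """Counts and the depressed percentage of the assembled (case+control)
    modelling cohort."""
    n_cases = int((cohort["label"] == "case").sum())
    n_controls = int((cohort["label"] == "control").sum())
    total = n_cases + n_controls
    pct = 100.0 * n_cases / total if total else float("nan")
    return {
        "n_cases": n_cases,
        "n_controls": n_controls,
        "n_cohort": total,
        "percent_depressed": round(pct, 1),
    }


def assignments_from_frame(cohort: pd.DataFrame) -> list[CohortAssignment]:
    return [
        CohortAssignment(
            patient_id=str(r.patient_id),
            label=str(r.label),
            index_date=None if pd.isna(r.index_date) else int(r.index_date),
            matched_case=None if r.matched_case is None else str(r.matched_case),
            exclusion_reason=None
            if r.exclusion_reason is None
            else str(r.exclusion_reason),
        )
        for r in cohort.itertuples()
    ]
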