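"""Binary feature matrices from truncated patient histories.

Each patient row holds 0/1 indicators for every ICD-9 code and usable
(non-negated, non-family-history) text concept seen in the history up to a
per-patient cutoff date, a one-hot visit-rate bin, gender, and — for the
treated-cohort tasks — age and optionally the baseline PHQ-9 score as
numeric columns.  Everything used to *define* the phenotype (depression
codes, depression terms, antidepressant ingredients) is removed from the
matrix and logged, as are PHQ-9-derived columns.

Truncation cutoffs simulate early prediction: a cutoff of -183 days hides
the last six months before the index date from the model.  Cutoffs apply
to controls relative to their end of history, keeping truncated case and
control histories comparable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .phenotyping import PhenotypeConfig
from .records import PatientRecord
from .terminology import canonical_icd9

PHENOTYPE_DEFINING = "phenotype_defining"
PHQ9_DERIVED = "phq9_derived"

VISIT_BIN_WIDTH = 2.0
N_VISIT_BINS = 10  # [0,2), [2,4), ..., [18, inf)

#: event_type -> feature namespace, per corpus flavour
NAMESPACE_MAPS = {
    "pamf": {"icd9": "icd9", "term": "term", "drug_mention": "term"},
    "ghri": {"icd9": "cui", "term": "cui", "drug_mention": "cui",
             "rx": "cui", "cpt": "cui"},
}


@dataclass
class CutoffSpec:
    """Truncation offset in days relative to the index date (<= 0)."""

    offset_days: int = 0

    def __post_init__(self) -> None:
        if self.offset_days > 0:
            raise ValueError("cutoff offset must be <= 0 (days before index)")


DEFAULT_CUTOFFS = (CutoffSpec(0), CutoffSpec(-183), CutoffSpec(-365))


@dataclass
class FeatureMatrix:
    """Sparse binary indicator matrix with provenance metadata."""

    X: sp.csr_matrix
    patient_ids: np.ndarray
    columns: list[str]
    cutoff_applied: int = 0
    excluded_features: list[dict] = field(default_factory=list)

    @property
    def shape(self) -> tuple[int, int]:
        return self.X.shape

    def column_index(self, name: str) -> int:
        return self.columns.index(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.X.toarray(), index=self.patient_ids, columns=self.columns
        )

    def write_triplets(self, path) -> None:
        """Sparse triplet CSV: patient_id, feature_id, value."""
        coo = self.X.tocoo()
        pd.DataFrame(
            {
                "patient_id": self.patient_ids[coo.row],
                "feature_id": [self.columns[j] for j in coo.col],
                "value": coo.data,
            }
        ).to_csv(path, index=False)

    def write_dictionary(self, path) -> None:
        pd.DataFrame({"feature_id": self.columns}).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# record-level operations


def truncate_history(
    record: PatientRecord, index_date: int, cutoff: CutoffSpec
) -> PatientRecord:
    """Keep events dated at or before index + offset; order preserved."""
    limit = index_date + cutoff.offset_days
    kept = record.events[record.events["date"] <= limit]
    return record.with_events(kept)


def apply_pretreatment_blackout(
    record: PatientRecord, treatment_start: int, blackout_days: int = 10
) -> PatientRecord:
    """Remove events in the half-open window (start - blackout, start]:
    the run-up between diagnosis and treatment initiation, including the
    start day itself.  Earlier and later events are kept."""
    dates = record.events["date"]
    drop = (dates > treatment_start - blackout_days) & (dates <= treatment_start)
    return record.with_events(record.events[~drop])


def visit_rate(record: PatientRecord) -> float:
    """Average visits per year: visits per day of history, times 365.
    A single-visit record has a 0-day span; the denominator floors at one
    day, so one visit maps to 365 visits/year."""
    n_visits = int((record.events["event_type"] == "visit").sum())
    if n_visits == 0:
        raise ValueError(f"patient {record.patient_id} has no visit events")
    span = record.history_length
    return n_visits / max(1, span) * 365.0


def bin_visit_rate(rate: float) -> int:
    """Equal-width 2-visits/year bins, last bin unbounded:
    [0,2) -> 0, [2,4) -> 1, ..., [18, inf) -> 9."""
    if rate < 0:
        raise ValueError("visit rate must be >= 0")
    return min(int(rate // VISIT_BIN_WIDTH), N_VISIT_BINS - 1)


# ---------------------------------------------------------------------------
# cohort-scale matrix construction


def _cat_codes(series: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    """(integer codes, categories-as-strings) for any series dtype."""
    if isinstance(series.dtype, pd.CategoricalDtype):
        return (
            series.cat.codes.to_numpy(),
            series.cat.categories.astype(str).to_numpy(),
        )
    cat = pd.Categorical(series.astype(str))
    return cat.codes, np.asarray(cat.categories, dtype=object)


def _excluded_concepts(config: PhenotypeConfig) -> tuple[set[str], set[str]]:
    """(canonical depression codes, phenotype-defining concept ids)."""
    concepts = set(config.depression_terms.concepts) | set(
        config.antidepressant_ingredients
    )
    return config.canonical_codes, concepts


def build_feature_matrix(
    events: pd.DataFrame,
    patients: pd.DataFrame,
    cutoff_dates: pd.Series,
    config: PhenotypeConfig,
    cutoff: CutoffSpec = CutoffSpec(0),
    mode: str = "pamf",
    extra_numeric: dict[str, pd.Series] | None = None,
    columns: list[str] | None = None,
) -> FeatureMatrix:
    """Build one row per patient in ``cutoff_dates`` (a patient_id ->
    cutoff-day Series; events strictly after a patient's cutoff are hidden).

    When ``columns`` is given (the training vocabulary) the matrix is
    projected onto exactly those columns, so test matrices align with the
    trained model.
    """
    namespace = NAMESPACE_MAPS[mode]
    cutoff_dates = cutoff_dates.copy()
    cutoff_dates.index = cutoff_dates.index.astype(str)
    pids = np.array(sorted(cutoff_dates.index), dtype=object)
    row_of = {p: i for i, p in enumerate(pids)}

    # work on integer category codes throughout (string work only on the
    # small category sets, never per event row)
    p_codes, p_cats = _cat_codes(events["patient_id"])
    t_codes, t_cats = _cat_codes(events["event_type"])
    c_codes, c_cats = _cat_codes(events["code"])
    dates = events["date"].to_numpy()

    limit_by_cat = cutoff_dates.reindex(p_cats).to_numpy(dtype=float)
    row_by_cat = (
        pd.Series(np.arange(len(pids)), index=pids)
        .reindex(p_cats)
        .fillna(-1)
        .to_numpy(dtype=np.int64)
    )
    lim = limit_by_cat[p_codes]
    in_cohort = row_by_cat[p_codes] >= 0
    kept = in_cohort & ~np.isnan(lim) & (dates <= lim)

    ns_of_t = np.array([namespace.get(t, "") for t in t_cats], dtype=object)
    is_visit_t = np.array([t == "visit" for t in t_cats])
    flagged = events["negated"].to_numpy() | events["family_history"].to_numpy()
    # usable indicator mentions: negated / family-history flags exclude
    is_ind = kept & (ns_of_t != "")[t_codes] & ~flagged
    is_vis = kept & is_visit_t[t_codes]

    # unique (event_type, code) pairs define the candidate feature set
    key = t_codes[is_ind].astype(np.int64) * len(c_cats) + c_codes[is_ind]
    uniq_keys, inv = np.unique(key, return_inverse=True)
    uniq_t = uniq_keys // len(c_cats)
    uniq_c = uniq_keys % len(c_cats)
    uniq_code = np.array([c_cats[j] for j in uniq_c], dtype=object)
    uniq_ns = ns_of_t[uniq_t]
    uniq_names = np.array(
        [f"{n}:{c}" for n, c in zip(uniq_ns, uniq_code)], dtype=object
    )

    # remove phenotype-defining concepts, logging what was dropped
    canon_codes, pheno_concepts = _excluded_concepts(config)
    n_uniq = len(uniq_keys)
    uniq_is_icd9 = np.fromiter(
        (t_cats[j] == "icd9" for j in uniq_t), dtype=bool, count=n_uniq
    )
    uniq_defining = np.where(
        uniq_is_icd9,
        np.fromiter(
            (canonical_icd9(str(c)) in canon_codes for c in uniq_code),
            dtype=bool, count=n_uniq,
        ),
        np.fromiter(
            (str(c) in pheno_concepts for c in uniq_code), dtype=bool, count=n_uniq
        ),
    ).astype(bool)
    excluded = [
        {"feature": name, "reason": PHENOTYPE_DEFINING}
        for name in sorted(uniq_names[uniq_defining])
    ]
    keep_ind = ~uniq_defining[inv]
    ind_names = uniq_names[inv][keep_ind]
    ind_rows = row_by_cat[p_codes[is_ind]][keep_ind]

    # visit-rate bins from the truncated history
    vb_rows = np.asarray([], dtype=np.int64)
    vb_names = np.asarray([], dtype=object)
    if is_vis.any():
        vis = pd.DataFrame({"p": p_codes[is_vis], "d": dates[is_vis]})
        grouped = vis.groupby("p")["d"]
        stats = pd.DataFrame(
            {"n": grouped.size(), "lo": grouped.min(), "hi": grouped.max()}
        )
        rates = (
            stats["n"] / np.maximum(1, stats["hi"] - stats["lo"]) * 365.0
        ).to_numpy()
        vb_rows = row_by_cat[stats.index.to_numpy()]
        vb_names = np.array(
            [f"visit_bin:{bin_visit_rate(float(r))}" for r in rates], dtype=object
        )

    # gender indicator
    pat = patients.assign(patient_id=patients["patient_id"].astype(str))
    pat = pat[pat["patient_id"].isin(row_of)]
    female = pat[pat["gender"].astype(str).str.upper().str.startswith("F")]
    g_rows = np.array(
        [row_of[p] for p in female["patient_id"]], dtype=np.int64
    )
    g_names = np.full(len(g_rows), "demo:gender_female", dtype=object)

    all_rows = np.concatenate([ind_rows, vb_rows, g_rows]).astype(np.int64)
    all_names = np.concatenate(
        [ind_names, vb_names, g_names]
    ) if (len(ind_names) + len(vb_names) + len(g_names)) else np.array([], dtype=object)

    extra_numeric = extra_numeric or {}
    if columns is None:
        base_cols = sorted(set(all_names))
        cols = base_cols + [c for c in extra_numeric if c not in base_cols]
    else:
        cols = list(columns)
    col_of = {c: j for j, c in enumerate(cols)}

    keep = np.array([n in col_of for n in all_names], dtype=bool)
    rows = all_rows[keep]
    col_idx = np.array([col_of[n] for n in all_names[keep]], dtype=np.int64)
    data = np.ones(len(rows), dtype=np.float64)
    X = sp.coo_matrix(
        (data, (rows, col_idx)), shape=(len(pids), len(cols))
    ).tocsr()
    X.data = np.minimum(X.data, 1.0)  # presence, not counts

    numeric_present = {n: s for n, s in extra_numeric.items() if n in col_of}
    if numeric_present:
        X = X.tolil()
        for name, series in numeric_present.items():
            series = series.copy()
            series.index = series.index.astype(str)
            vals = np.array([float(series.get(p, 0.0)) for p in pids])
            X[:, col_of[name]] = vals.reshape(-1, 1)
        X = X.tocsr()

    return FeatureMatrix(
        X=X,
        patient_ids=pids,
        columns=cols,
        cutoff_applied=cutoff.offset_days,
        excluded_features=excluded,
    )


def pamf_feature_matrix(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    config: PhenotypeConfig,
    cutoff: CutoffSpec = CutoffSpec(0),
    columns: list[str] | None = None,
    case_offset: bool = True,
    control_offset: bool = True,
) -> tuple[FeatureMatrix, pd.Series]:
    """Feature matrix for the assembled case/control cohort at one cutoff.

    Cases truncate relative to their index date; controls relative to their
    end of history (their recorded index date).  Set ``control_offset``
    False for the training-time convention in which controls keep their
    full history regardless of cutoff.

    Returns (matrix, labels aligned to matrix rows; 1 = case).
    """
    kept = cohort[cohort["label"].isin(["case", "control"])]
    idx = kept["index_date"].astype(int)
    offs = np.where(
        kept["label"] == "case",
        cutoff.offset_days if case_offset else 0,
        cutoff.offset_days if control_offset else 0,
    )
    cutoff_dates = pd.Series(
        idx.to_numpy() + offs, index=kept["patient_id"].astype(str)
    )
    matrix = build_feature_matrix(
        events, patients, cutoff_dates, config, cutoff=cutoff, mode="pamf",
        columns=columns,
    )
    label_map = dict(zip(kept["patient_id"].astype(str), kept["label"] == "case"))
    labels = pd.Series(
        [int(label_map[p]) for p in matrix.patient_ids], index=matrix.patient_ids
    )
    return matrix, labels


def ghri_feature_matrix(
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    config: PhenotypeConfig,
    include_baseline_phq9: bool = True,
    blackout_days: int = 10,
    columns: list[str] | None = None,
) -> FeatureMatrix:
    """Pre-treatment history features for the treated cohort.

    Only events at least ``blackout_days`` before the first treatment start
    enter the matrix (the 10-day pre-treatment window and everything after
    the start are hidden).  Age at treatment start is a numeric column;
    the baseline PHQ-9 score is included only when permitted — the severity
    task must exclude it because it is the quantity being predicted.
    """
    episodes = episodes.assign(patient_id=episodes["patient_id"].astype(str))
    cutoff_dates = pd.Series(
        episodes["start_day"].to_numpy() - blackout_days,
        index=episodes["patient_id"],
    )
    pat = patients.assign(patient_id=patients["patient_id"].astype(str))
    by = pat.set_index("patient_id")["birth_year"]
    from .phenotyping import age_at

    age = pd.Series(
        [
            age_at(int(by[p]), int(s))
            for p, s in zip(episodes["patient_id"], episodes["start_day"])
        ],
        index=episodes["patient_id"],
    )
    extra = {"demo:age": age}
    if include_baseline_phq9:
        extra["demo:baseline_phq9"] = pd.Series(
            episodes["baseline_phq9"].to_numpy(), index=episodes["patient_id"]
        )
    matrix = build_feature_matrix(
        events, patients, cutoff_dates, config, cutoff=CutoffSpec(0), mode="ghri",
        extra_numeric=extra, columns=columns,
    )
    if not include_baseline_phq9:
        matrix.excluded_features.append(
            {"feature": "demo:baseline_phq9", "reason": PHQ9_DERIVED}
        )
    return matrix


def assert_no_phq9_columns(matrix: FeatureMatrix) -> None:
    """Leakage guard for the severity task: no PHQ-9-derived column may be
    present in the design matrix."""
    offenders = [c for c in matrix.columns if "phq9" in c.lower()]
    if offenders:
        raise ValueError(
            f"PHQ-9-derived columns present in feature matrix: {offenders}"
        )
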