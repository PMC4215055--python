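"""L1-penalised logistic models and ROC evaluation for the three tasks.

The classifier throughout is LASSO logistic regression: the penalty is
selected by stratified k-fold cross-validation (k = 10) on the training
split over a log-spaced penalty path, with the one-standard-error rule —
the sparsest model whose mean CV deviance is within one standard error of
the minimum.  Columns are scaled to unit variance (without centring, to
preserve sparsity) before penalisation; reported coefficients are mapped
back to the original scale, and feature ranking uses the standardised
magnitudes so binary indicators and numeric columns compare fairly.

Discrimination is summarised by the empirical ROC curve, the trapezoidal
AUC, a 95% DeLong confidence interval, and sensitivity at requested
specificities (linear interpolation on the curve).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss, roc_curve
from sklearn.model_selection import StratifiedShuffleSplit, StratifiedKFold

from .features import (
    CutoffSpec,
    DEFAULT_CUTOFFS,
    FeatureMatrix,
    assert_no_phq9_columns,
    ghri_feature_matrix,
    pamf_feature_matrix,
)
from .outcomes import MEDICATION, PSYCHOTHERAPY, phq9_severity_array
from .phenotyping import PhenotypeConfig


@dataclass
class SplitSpec:
    """Train/test partition: default a stratified random 80/20 split."""

    train_fraction: float = 0.8
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError("train_fraction must lie in (0, 1)")

    def split(self, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (train_idx, test_idx) row indices."""
        n = len(y)
        if self.stratified:
            splitter = StratifiedShuffleSplit(
                n_splits=1, train_size=self.train_fraction, random_state=self.seed
            )
            train, test = next(splitter.split(np.zeros(n), y))
        else:
            rng = np.random.default_rng(self.seed)
            perm = rng.permutation(n)
            k = int(round(self.train_fraction * n))
            train, test = perm[:k], perm[k:]
        return np.sort(train), np.sort(test)


@dataclass
class ModelFit:
    """A fitted sparse logistic model."""

    coefficients: dict[str, float]
    intercept: float
    penalty: float
    columns: list[str]
    scale: np.ndarray  # per-column standardisation factors
    std_coefficients: dict[str, float] = field(default_factory=dict)
    cv_path: pd.DataFrame | None = None

    @property
    def n_nonzero(self) -> int:
        return sum(1 for v in self.coefficients.values() if v != 0.0)

    def coefficient_vector(self) -> np.ndarray:
        return np.array([self.coefficients[c] for c in self.columns])

    def decision_scores(self, X) -> np.ndarray:
        w = self.coefficient_vector()
        return np.asarray(X @ w).ravel() + self.intercept

    def predict_proba(self, X) -> np.ndarray:
        z = self.decision_scores(X)
        return 1.0 / (1.0 + np.exp(-z))

    def ranked_features(self) -> pd.DataFrame:
        """Features sorted by standardised |coefficient|, largest first."""
        frame = pd.DataFrame(
            {
                "feature": self.columns,
                "coefficient": [self.coefficients[c] for c in self.columns],
                "std_coefficient": [self.std_coefficients[c] for c in self.columns],
            }
        )
        frame["abs_std"] = frame["std_coefficient"].abs()
        frame = frame.sort_values(
            ["abs_std", "feature"], ascending=[False, True], kind="stable"
        ).drop(columns="abs_std")
        frame["rank"] = np.arange(1, len(frame) + 1)
        return frame.reset_index(drop=True)

    @property
    def top_feature(self) -> str:
        return self.ranked_features().iloc[0]["feature"]


def _column_scales(X) -> np.ndarray:
    """Unit-variance scaling factors without centring (sparse-safe)."""
    if sp.issparse(X):
        mean = np.asarray(X.mean(axis=0)).ravel()
        mean_sq = np.asarray(X.multiply(X).mean(axis=0)).ravel()
    else:
        X = np.asarray(X)
        mean = X.mean(axis=0)
        mean_sq = (X**2).mean(axis=0)
    var = np.maximum(mean_sq - mean**2, 0.0)
    sd = np.sqrt(var)
    sd[sd == 0] = 1.0  # constant columns pass through unscaled
    return sd


def _scale_columns(X, sd: np.ndarray):
    inv = sp.diags(1.0 / sd) if sp.issparse(X) else np.diag(1.0 / sd)
    return X @ inv


def fit_l1_logistic(
    X,
    y,
    columns: list[str],
    k_folds: int = 10,
    n_penalties: int = 30,
    penalty_ratio: float = 1e-3,
    rule: str = "1se",
    seed: int = 0,
) -> ModelFit:
    """LASSO logistic fit with internal CV penalty selection.

    The path runs from the smallest penalty that zeroes every coefficient
    down by ``penalty_ratio``; ``rule`` is ``"1se"`` (default) or
    ``"min"``.  Raises on single-class training labels.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    n = len(y)
    sd = _column_scales(X)
    Xs = _scale_columns(X, sd)
    Xs = sp.csr_matrix(Xs) if sp.issparse(X) else np.asarray(Xs)

    ybar = y.mean()
    grad = np.abs(np.asarray(Xs.T @ (y - ybar)).ravel()) / n
    lam_max = max(grad.max(), 1e-10)
    lambdas = np.geomspace(lam_max, lam_max * penalty_ratio, n_penalties)

    def fit_at(lam: float, Xt, yt) -> LogisticRegression:
        # large intercept_scaling: liblinear L1-penalises its intercept
        # term, which would otherwise let dense uncentred columns stand in
        # for the intercept at strong penalties
        model = LogisticRegression(
            l1_ratio=1, C=1.0 / (lam * len(yt)), solver="liblinear",
            intercept_scaling=100.0, max_iter=200, tol=1e-4, random_state=0,
        )
        model.fit(Xt, yt)
        return model

    folds = list(
        StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed).split(
            np.zeros(n), y
        )
    )
    # walk the path from sparse to dense, stopping once the CV deviance has
    # clearly passed its minimum (the dense tail is never the 1-SE choice)
    means: list[float] = []
    ses: list[float] = []
    for i, lam in enumerate(lambdas):
        fold_losses = []
        for tr, va in folds:
            model = fit_at(lam, Xs[tr], y[tr])
            p = model.predict_proba(Xs[va])[:, 1]
            fold_losses.append(log_loss(y[va], p, labels=[0, 1]))
        fold_losses = np.asarray(fold_losses)
        means.append(float(fold_losses.mean()))
        ses.append(float(fold_losses.std(ddof=1) / np.sqrt(k_folds)))
        if i - int(np.argmin(means)) >= 3:
            break
    mean = np.asarray(means)
    se = np.asarray(ses)
    lambdas = lambdas[: len(mean)]
    best = int(np.argmin(mean))
    if rule == "1se":
        # largest penalty (sparsest model) within one SE of the minimum
        chosen = int(np.nonzero(mean <= mean[best] + se[best])[0][0])
    elif rule == "min":
        chosen = best
    else:
        raise ValueError(f"unknown penalty rule {rule!r}")
    lam = float(lambdas[chosen])

    final = fit_at(lam, Xs, y)
    w_std = final.coef_.ravel()
    w = w_std / sd
    coefficients = dict(zip(columns, w.tolist()))
    std_coefficients = dict(zip(columns, w_std.tolist()))
    cv_path = pd.DataFrame(
        {"penalty": lambdas, "mean_deviance": mean, "se_deviance": se}
    )
    return ModelFit(
        coefficients=coefficients,
        intercept=float(final.intercept_[0]),
        penalty=lam,
        columns=list(columns),
        scale=sd,
        std_coefficients=std_coefficients,
        cv_path=cv_path,
    )


# ---------------------------------------------------------------------------
# ROC / AUC with DeLong confidence intervals


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float
    ci_high: float
    auc_variance: float
    sensitivity_at: dict[float, float]
    n_pos: int
    n_neg: int

    def to_points_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr})

    def summary(self) -> dict:
        out = {
            "auc": self.auc,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }
        for spec, sens in self.sensitivity_at.items():
            out[f"sensitivity_at_spec_{spec:g}"] = sens
        return out


def _midrank(x: np.ndarray) -> np.ndarray:
    order = np.argsort(x, kind="stable")
    z = x[order]
    n = len(x)
    ranks = np.zeros(n)
    i = 0
    while i < n:
        j = i
        while j < n and z[j] == z[i]:
            j += 1
        ranks[i:j] = 0.5 * (i + j - 1) + 1
        i = j
    out = np.empty(n)
    out[order] = ranks
    return out


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """Mann-Whitney AUC (ties get half credit) and its DeLong variance."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tx = _midrank(pos)
    ty = _midrank(neg)
    tz = _midrank(np.concatenate([pos, neg]))
    auc = (tz[:m].sum() - m * (m + 1) / 2.0) / (m * n)
    v01 = (tz[:m] - tx) / n          # structural components over positives
    v10 = 1.0 - (tz[m:] - ty) / m    # ... and over negatives
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    var = s01 / m + s10 / n
    return float(auc), float(var)


def auc_confidence_interval(
    auc: float, var: float, level: float = 0.95
) -> tuple[float, float]:
    z = norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return float(max(0.0, auc - half)), float(min(1.0, auc + half))


def bootstrap_auc_ci(
    scores: np.ndarray, labels: np.ndarray, n_boot: int = 2000, seed: int = 0,
    level: float = 0.95,
) -> tuple[float, float]:
    """Percentile-bootstrap alternative to the DeLong interval."""
    rng = np.random.default_rng(seed)
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n = len(scores)
    stats = []
    for _ in range(n_boot):
        idx = rng.integers(0, n, n)
        yb = labels[idx]
        if yb.min() == yb.max():
            continue
        auc, _ = delong_auc_variance(scores[idx], yb)
        stats.append(auc)
    lo, hi = np.quantile(stats, [(1 - level) / 2, 0.5 + level / 2])
    return float(lo), float(hi)


def evaluate_roc(
    scores: np.ndarray,
    labels: np.ndarray,
    specificities: tuple[float, ...] = (0.8, 0.9),
    ci_level: float = 0.95,
) -> RocResult:
    """Empirical ROC, trapezoidal AUC, DeLong CI, and interpolated
    sensitivity at the requested specificities."""
    labels = np.asarray(labels).astype(int)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels are degenerate: one class only")
    scores = np.asarray(scores, dtype=float)
    fpr, tpr, _ = roc_curve(labels, scores)
    auc, var = delong_auc_variance(scores, labels)
    lo, hi = auc_confidence_interval(auc, var, level=ci_level)
    sens = {
        float(s): float(np.interp(1.0 - s, fpr, tpr)) for s in specificities
    }
    return RocResult(
        fpr=fpr, tpr=tpr, auc=auc, ci_low=lo, ci_high=hi, auc_variance=var,
        sensitivity_at=sens, n_pos=int(labels.sum()),
        n_neg=int(len(labels) - labels.sum()),
    )


def evaluate_fit(fit: ModelFit, matrix: FeatureMatrix, labels) -> RocResult:
    scores = fit.decision_scores(matrix.X)
    return evaluate_roc(scores, np.asarray(labels))


# ---------------------------------------------------------------------------
# experiments


@dataclass
class HorizonResult:
    fit: ModelFit
    per_cutoff: dict[int, RocResult]
    train_ids: np.ndarray
    test_ids: np.ndarray


def run_horizon_experiment(
    cohort: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    config: PhenotypeConfig,
    cutoffs: tuple[CutoffSpec, ...] = DEFAULT_CUTOFFS,
    split: SplitSpec | None = None,
    seed: int = 0,
) -> HorizonResult:
    """Diagnosis prediction across truncation horizons.

    One model is trained on the 80% split of the cutoff-0 matrix (cases
    truncated at their index date, controls keeping full history) and then
    evaluated on the held-out 20% at each cutoff, using a single shared
    patient partition so the three test sets differ only in truncation.
    """
    split = split or SplitSpec(seed=seed)
    train_matrix, labels = pamf_feature_matrix(
        cohort, events, patients, config, CutoffSpec(0), control_offset=False
    )
    y = labels.to_numpy()
    train_idx, test_idx = split.split(y)
    assert not set(train_idx) & set(test_idx)
    fit = fit_l1_logistic(
        train_matrix.X[train_idx], y[train_idx], train_matrix.columns, seed=seed
    )
    test_ids = set(train_matrix.patient_ids[test_idx])
    per_cutoff: dict[int, RocResult] = {}
    for cutoff in cutoffs:
        matrix, lab = pamf_feature_matrix(
            cohort, events, patients, config, cutoff, columns=train_matrix.columns
        )
        rows = np.array([p in test_ids for p in matrix.patient_ids])
        per_cutoff[cutoff.offset_days] = evaluate_roc(
            fit.decision_scores(matrix.X[rows]), lab.to_numpy()[rows]
        )
    return HorizonResult(
        fit=fit,
        per_cutoff=per_cutoff,
        train_ids=train_matrix.patient_ids[train_idx],
        test_ids=train_matrix.patient_ids[test_idx],
    )


@dataclass
class TaskResult:
    fit: ModelFit
    roc: RocResult
    n_train: int
    n_test: int

    @property
    def top_feature(self) -> str:
        return self.fit.top_feature


def run_response_experiment(
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    config: PhenotypeConfig,
    modality: str,
    split: SplitSpec | None = None,
    seed: int = 0,
    blackout_days: int = 10,
) -> TaskResult:
    """Predict >= 5-point PHQ-9 improvement after a first treatment of one
    modality (patients starting both modalities the same day are excluded).
    Features: age, gender, baseline PHQ-9, and pre-treatment history
    concepts after the 10-day blackout."""
    if modality not in (MEDICATION, PSYCHOTHERAPY):
        raise ValueError(f"modality must be medication or psychotherapy")
    split = split or SplitSpec(seed=seed)
    rows = episodes[episodes["modality"] == modality].reset_index(drop=True)
    matrix = ghri_feature_matrix(
        rows, events, patients, config, include_baseline_phq9=True,
        blackout_days=blackout_days,
    )
    improved = dict(
        zip(rows["patient_id"].astype(str), rows["improved"].astype(int))
    )
    y = np.array([improved[p] for p in matrix.patient_ids])
    train_idx, test_idx = split.split(y)
    assert not set(train_idx) & set(test_idx)
    fit = fit_l1_logistic(matrix.X[train_idx], y[train_idx], matrix.columns, seed=seed)
    roc = evaluate_roc(fit.decision_scores(matrix.X[test_idx]), y[test_idx])
    return TaskResult(fit=fit, roc=roc, n_train=len(train_idx), n_test=len(test_idx))


def run_severity_experiment(
    episodes: pd.DataFrame,
    events: pd.DataFrame,
    patients: pd.DataFrame,
    config: PhenotypeConfig,
    split: SplitSpec | None = None,
    seed: int = 0,
    blackout_days: int = 10,
) -> TaskResult:
    """Detect severe baseline depression (PHQ-9 > 19) against minimal/mild
    (PHQ-9 <= 9) from pre-treatment history alone; moderate and moderately
    severe patients are excluded, as is the baseline PHQ-9 itself (it is
    the measurement being predicted)."""
    split = split or SplitSpec(seed=seed)
    severity = phq9_severity_array(episodes["baseline_phq9"].to_numpy())
    extreme = (severity <= 1) | (severity == 4)
    rows = episodes[extreme].reset_index(drop=True)
    matrix = ghri_feature_matrix(
        rows, events, patients, config, include_baseline_phq9=False,
        blackout_days=blackout_days,
    )
    assert_no_phq9_columns(matrix)
    severe = dict(
        zip(
            rows["patient_id"].astype(str),
            (phq9_severity_array(rows["baseline_phq9"].to_numpy()) == 4).astype(int),
        )
    )
    y = np.array([severe[p] for p in matrix.patient_ids])
    train_idx, test_idx = split.split(y)
    assert not set(train_idx) & set(test_idx)
    fit = fit_l1_logistic(matrix.X[train_idx], y[train_idx], matrix.columns, seed=seed)
    roc = evaluate_roc(fit.decision_scores(matrix.X[test_idx]), y[test_idx])
    return TaskResult(fit=fit, roc=roc, n_train=len(train_idx), n_test=len(test_idx))
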