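"""Moderator discovery: information-gain screening plus interaction models.

A moderator is a patient characteristic whose *interaction* with treatment
modality predicts differential response.  The procedure: (1) rank binary
history features by information gain against the outcome (a PHQ-9 change
of at least ±5 points by default); (2) keep the top k (k = 100); (3) fit a
single logistic model containing those features, a boolean treatment
indicator (1 = medication, 0 = psychotherapy), and each feature × treatment
product; (4) read Wald p-values off the interaction terms, reporting both
raw and Benjamini–Hochberg-adjusted values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
import statsmodels.api as sm
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError

IMPROVED_OUTCOME = "improved"       # decrease >= 5 points
ABS_CHANGE_OUTCOME = "abs_change"   # |change| >= 5 points, the default


def _entropy(counts: np.ndarray) -> float:
    total = counts.sum()
    if total == 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def information_gain(feature: np.ndarray, outcome: np.ndarray) -> float:
    """Reduction in outcome entropy given a binary feature, in bits:
    H(outcome) - sum_v P(feature=v) H(outcome | feature=v), with the
    convention 0·log 0 = 0."""
    feature = np.asarray(feature).astype(int)
    outcome = np.asarray(outcome).astype(int)
    if len(feature) != len(outcome) or len(feature) == 0:
        raise ValueError("feature and outcome must have equal nonzero length")
    h = _entropy(np.bincount(outcome))
    cond = 0.0
    n = len(outcome)
    for v in np.unique(feature):
        mask = feature == v
        cond += mask.sum() / n * _entropy(np.bincount(outcome[mask]))
    return h - cond


def information_gain_matrix(X, outcome: np.ndarray) -> np.ndarray:
    """Vectorised information gain of every binary column of X."""
    outcome = np.asarray(outcome).astype(int)
    n = len(outcome)
    if sp.issparse(X):
        X = sp.csc_matrix(X)
        n1 = np.asarray(X.sum(axis=0)).ravel()                 # feature = 1
        n11 = np.asarray(X[outcome == 1].sum(axis=0)).ravel()  # feature=1, y=1
    else:
        X = np.asarray(X)
        n1 = X.sum(axis=0)
        n11 = X[outcome == 1].sum(axis=0)
    ny1 = outcome.sum()
    n10 = n1 - n11
    n01 = ny1 - n11
    n00 = n - n1 - n01

    def h2(a, b):
        tot = np.asarray(a + b, dtype=float)
        pa = np.divide(a, tot, out=np.zeros_like(tot), where=tot > 0)
        pb = np.divide(b, tot, out=np.zeros_like(tot), where=tot > 0)
        ha = -pa * np.log2(np.where(pa > 0, pa, 1.0))
        hb = -pb * np.log2(np.where(pb > 0, pb, 1.0))
        return ha + hb

    h_y = _entropy(np.bincount(outcome))
    p1 = n1 / n
    cond = p1 * h2(n11, n10) + (1 - p1) * h2(n01, n00)
    return h_y - cond


def screening_outcome(
    episodes: pd.DataFrame, kind: str = ABS_CHANGE_OUTCOME
) -> np.ndarray:
    """Binary screening outcome: |change| >= 5 (default, either direction)
    or the one-sided improvement label."""
    if kind == ABS_CHANGE_OUTCOME:
        return (episodes["change"].abs() >= 5).astype(int).to_numpy()
    if kind == IMPROVED_OUTCOME:
        return episodes["improved"].astype(int).to_numpy()
    raise ValueError(f"unknown screening outcome {kind!r}")


def screen_top_k(
    X,
    outcome: np.ndarray,
    feature_ids: list[str],
    k: int = 100,
    min_prevalence: float = 0.0,
    max_prevalence: float = 1.0,
) -> pd.DataFrame:
    """Top-k features by information gain; ties break by feature-id order.

    Optional prevalence bounds drop near-constant columns (which carry no
    usable interaction contrast) before ranking.
    """
    if X.shape[1] < k:
        raise ValueError(f"need at least k={k} features, have {X.shape[1]}")
    gains = information_gain_matrix(X, outcome)
    prev = np.asarray(X.mean(axis=0)).ravel()
    ok = (prev >= min_prevalence) & (prev <= max_prevalence)
    order = sorted(
        np.nonzero(ok)[0], key=lambda j: (-gains[j], feature_ids[j])
    )[:k]
    return pd.DataFrame(
        {
            "feature": [feature_ids[j] for j in order],
            "column": order,
            "information_gain": gains[order],
            "rank": np.arange(1, len(order) + 1),
        }
    )


@dataclass
class ModeratorReport:
    """Per-feature screening and interaction statistics."""

    table: pd.DataFrame  # feature, information_gain, main/interaction coefs, p-values
    treatment_coefficient: float
    converged: bool

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["adjusted_p"] < alpha]


def _fit_logit(design: np.ndarray, outcome: np.ndarray):
    result = sm.Logit(outcome, design).fit(method="lbfgs", maxiter=500, disp=0)
    converged = bool(result.mle_retvals.get("converged", True))
    return (
        converged,
        np.asarray(result.params, dtype=float),
        np.asarray(result.bse, dtype=float),
        np.asarray(result.pvalues, dtype=float),
    )


def interaction_analysis(
    X,
    screened: pd.DataFrame,
    treatment: np.ndarray,
    outcome: np.ndarray,
    alpha: float = 0.05,
    model: str = "joint",
    covariates: np.ndarray | None = None,
) -> ModeratorReport:
    """Logistic interaction models over the screened features.

    ``model="joint"`` (default) fits one model: all screened main effects +
    treatment + feature×treatment products, Wald p-values on the
    interactions, BH adjustment across them.  ``model="per_feature"`` fits
    one small model per screened feature (intercept, feature, treatment,
    product) — the stable alternative when the joint design is too
    collinear for trustworthy Wald intervals at the available sample size.

    ``covariates`` (n × c) are always-included main-effect adjustments —
    typically baseline severity and age, the strongest outcome predictors,
    which the screening stage would otherwise place among the selected
    features in either model form.

    Features whose interaction coefficient is not estimable (separation,
    collinearity — flagged by absent or exploding standard errors) are
    reported with NaN statistics rather than dropped silently.
    """
    treatment = np.asarray(treatment).astype(float)
    outcome = np.asarray(outcome).astype(int)
    cols = screened["column"].to_numpy()
    F = X[:, cols].toarray() if sp.issparse(X) else np.asarray(X)[:, cols]
    F = F.astype(float)
    k = len(cols)
    if covariates is None:
        Z = np.empty((len(outcome), 0))
    else:
        Z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if Z.shape[0] != len(outcome):
            Z = Z.T
    base = [np.ones(len(outcome)), treatment]
    n_head = 2 + Z.shape[1]
    if model not in ("joint", "per_feature"):
        raise ValueError(f"unknown model {model!r}")
    if model == "joint":
        inter = F * treatment[:, None]
        design = np.column_stack(base + [Z, F, inter])
        try:
            converged, params, bse, pvals = _fit_logit(design, outcome)
        except (PerfectSeparationError, np.linalg.LinAlgError):
            converged = False
            params = np.full(design.shape[1], np.nan)
            bse = np.full(design.shape[1], np.nan)
            pvals = np.full(design.shape[1], np.nan)
        main_coef = params[n_head : n_head + k]
        int_coef = params[n_head + k :]
        int_se = bse[n_head + k :]
        int_p = pvals[n_head + k :]
        treatment_coef = float(params[1])
    else:
        main_coef = np.full(k, np.nan)
        int_coef = np.full(k, np.nan)
        int_se = np.full(k, np.nan)
        int_p = np.full(k, np.nan)
        treatment_coefs = []
        converged = True
        for j in range(k):
            design = np.column_stack(base + [Z, F[:, j], F[:, j] * treatment])
            try:
                conv_j, params, bse, pvals = _fit_logit(design, outcome)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                continue
            converged &= conv_j
            main_coef[j] = params[-2]
            int_coef[j] = params[-1]
            int_se[j] = bse[-1]
            int_p[j] = pvals[-1]
            treatment_coefs.append(params[1])
        treatment_coef = float(np.nanmean(treatment_coefs)) if treatment_coefs else float("nan")
    # non-estimable flags: absent, non-finite, or exploding Wald SEs
    bad = ~np.isfinite(int_se) | (int_se > 50) | ~np.isfinite(int_coef)
    int_coef = np.where(bad, np.nan, int_coef)
    int_p = np.where(bad, np.nan, int_p)

    adjusted = np.full(k, np.nan)
    ok = np.isfinite(int_p)
    if ok.any():
        adjusted[ok] = multipletests(int_p[ok], method="fdr_bh")[1]

    table = screened[["feature", "information_gain", "rank"]].copy()
    table["main_coefficient"] = main_coef
    table["interaction_coefficient"] = int_coef
    table["interaction_se"] = np.where(bad, np.nan, int_se)
    table["raw_p"] = int_p
    table["adjusted_p"] = adjusted
    table["estimable"] = ~bad
    table = table.sort_values(
        ["adjusted_p", "feature"], kind="stable", na_position="last"
    ).reset_index(drop=True)
    return ModeratorReport(
        table=table,
        treatment_coefficient=treatment_coef,
        converged=converged,
    )


def run_moderator_analysis(
    matrix_X,
    feature_ids: list[str],
    episodes: pd.DataFrame,
    k: int = 100,
    outcome_kind: str = ABS_CHANGE_OUTCOME,
    min_prevalence: float = 0.02,
    max_prevalence: float = 0.98,
    model: str = "joint",
    adjust_baseline: bool = True,
) -> ModeratorReport:
    """End-to-end screening + interaction analysis on the single-modality
    treated cohort (episodes rows aligned with matrix rows).

    ``adjust_baseline`` keeps the baseline PHQ-9 score in the interaction
    model as a main-effect covariate (it is the strongest outcome predictor
    and belongs in the model with the screened features).

    Patients for whom the outcome is structurally impossible are excluded:
    with the one-sided improvement outcome, a baseline below 5 cannot drop
    five points, so those rows are uninformative structural zeros that
    would otherwise bias every logistic coefficient toward null.
    """
    if outcome_kind == IMPROVED_OUTCOME:
        achievable = episodes["baseline_phq9"].to_numpy() >= 5
        if not achievable.all():
            episodes = episodes[achievable].reset_index(drop=True)
            matrix_X = matrix_X[achievable]
    outcome = screening_outcome(episodes, outcome_kind)
    treatment = (episodes["modality"] == "medication").astype(int).to_numpy()
    screened = screen_top_k(
        matrix_X, outcome, feature_ids, k=k,
        min_prevalence=min_prevalence, max_prevalence=max_prevalence,
    )
    covariates = (
        episodes["baseline_phq9"].to_numpy(dtype=float)[:, None]
        if adjust_baseline
        else None
    )
    return interaction_analysis(
        matrix_X, screened, treatment, outcome, model=model, covariates=covariates
    )
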