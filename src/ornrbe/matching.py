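"""Propensity-score estimation and greedy 1:1 nearest-neighbor matching.

The propensity model is a maximum-likelihood logistic regression of proton
(vs photon) assignment on main-effect clinical covariates, fit by
Newton/IRLS from a zero start so the result is deterministic. Matching is
greedy without replacement: proton patients are processed in descending
propensity order and each takes the unused photon patient with the closest
score (ties broken by the smaller photon id).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .cohort import PatientRecord
from .inference_stats import chi_square, t_test_two_sample

__all__ = [
    "PropensityResult",
    "MatchedCohort",
    "DEFAULT_MATCHING_TERMS",
    "fit_propensity",
    "greedy_match",
    "balance_table",
]

#: the eight matching factors (age and prescription dose are diagnostics
#: only, not in the model)
DEFAULT_MATCHING_TERMS = (
    "gender",
    "stage",
    "chemo",
    "hypertension",
    "diabetes",
    "dental_extraction",
    "current_smoker",
    "smoking_history",
)

_CATEGORICAL_BASELINES = {"gender": "male", "stage": "I"}


@dataclass(frozen=True)
class PropensityResult:
    coefficients: Mapping[str, float]
    scores: Mapping[str, float]  # patient_id -> P(proton | covariates)
    converged: bool
    iterations: int


@dataclass(frozen=True)
class MatchedCohort:
    pairs: list  # (proton_id, photon_id)
    unmatched_proton: list
    match_order: list  # proton ids in processing sequence


def design_matrix(
    records: Sequence[PatientRecord], terms: Sequence[str] = DEFAULT_MATCHING_TERMS
) -> tuple[np.ndarray, list[str]]:
    """Main-effects design matrix with intercept; categorical terms are
    dummy-coded against fixed baselines (gender: male, stage: I)."""
    cols: list[np.ndarray] = [np.ones(len(records))]
    names = ["intercept"]
    for term in terms:
        if term == "gender":
            cols.append(np.array([r.gender == "female" for r in records], float))
            names.append("gender_female")
        elif term == "stage":
            for level in ("II", "III", "IV", "X"):
                cols.append(np.array([r.stage == level for r in records], float))
                names.append(f"stage_{level}")
        else:
            cols.append(np.array([bool(getattr(r, term)) for r in records], float))
            names.append(term)
    return np.column_stack(cols), names


def fit_propensity(
    records: Sequence[PatientRecord],
    covariate_terms: Sequence[str] = DEFAULT_MATCHING_TERMS,
) -> PropensityResult:
    """IRLS logistic fit of proton assignment; deterministic.

    Convergence: max absolute coefficient change < 1e-8 within 100
    iterations. On non-convergence (e.g. perfect separation) a warning is
    issued, ``converged`` is False and scores are clipped to
    ``[1e-12, 1 - 1e-12]``.
    """
    y = np.array([r.modality == "proton" for r in records], float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 patients in each modality")
    X, names = design_matrix(records, covariate_terms)
    beta = np.zeros(X.shape[1])
    converged = False
    it = 0
    for it in range(1, 101):
        eta = X @ beta
        mu = expit(eta)
        w = mu * (1.0 - mu)
        grad = X.T @ (y - mu)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(hess, grad, rcond=None)[0]
        if not np.all(np.isfinite(step)):
            break
        beta = beta + step
        if np.max(np.abs(step)) < 1e-8:
            converged = True
            break
    if not converged or np.max(np.abs(beta)) > 30:
        converged = False
        warnings.warn(
            "propensity model did not converge (possible perfect separation); "
            "scores clipped",
            RuntimeWarning,
            stacklevel=2,
        )
    scores = np.clip(expit(X @ beta), 1e-12, 1.0 - 1e-12)
    return PropensityResult(
        coefficients=dict(zip(names, beta.tolist())),
        scores={r.patient_id: float(s) for r, s in zip(records, scores)},
        converged=converged,
        iterations=it,
    )


def greedy_match(
    result: PropensityResult, records: Sequence[PatientRecord]
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement.

    Proton patients are processed in descending propensity score (ties by
    ascending id); each takes the unused photon patient minimizing the
    absolute score difference, ties broken by the smaller photon id.
    """
    proton = [(r.patient_id, result.scores[r.patient_id]) for r in records if r.modality == "proton"]
    photon = [(r.patient_id, result.scores[r.patient_id]) for r in records if r.modality == "photon"]
    if len(photon) < len(proton):
        warnings.warn(
            f"photon pool ({len(photon)}) smaller than proton pool ({len(proton)}); "
            "some proton patients will be unmatched",
            RuntimeWarning,
            stacklevel=2,
        )
    order = sorted(proton, key=lambda t: (-t[1], t[0]))
    available = sorted(photon, key=lambda t: t[0])  # id order makes ties deterministic
    pairs = []
    unmatched = []
    for pid, score in order:
        if not available:
            unmatched.append(pid)
            continue
        best = min(available, key=lambda t: (abs(t[1] - score), t[0]))
        available.remove(best)
        pairs.append((pid, best[0]))
    return MatchedCohort(
        pairs=pairs, unmatched_proton=unmatched, match_order=[pid for pid, _ in order]
    )


# ---------------------------------------------------------------------------
# balance diagnostics

_CATEGORICAL_COVARIATES = (
    "gender",
    "stage",
    "chemo",
    "hypertension",
    "diabetes",
    "dental_extraction",
    "smoking_history",
    "current_smoker",
)
_NUMERIC_COVARIATES = ("age", "prescription_dose")


def _categorical_p(records: Sequence[PatientRecord], covariate: str) -> float:
    if covariate == "gender":
        levels = ("female", "male")
        get = lambda r: r.gender
    elif covariate == "stage":
        levels = ("I", "II", "III", "IV", "X")
        get = lambda r: r.stage
    else:
        levels = (False, True)
        get = lambda r: bool(getattr(r, covariate))
    table = np.zeros((2, len(levels)))
    for r in records:
        i = 0 if r.modality == "photon" else 1
        table[i, levels.index(get(r))] += 1
    # drop empty columns (unobserved levels), keep degenerate rows -> NaN
    table = table[:, table.sum(axis=0) > 0]
    if table.shape[1] < 2:
        return float("nan")
    _, p = chi_square(table)
    return p


def _numeric_p(records: Sequence[PatientRecord], covariate: str) -> float:
    x = [getattr(r, covariate) for r in records if r.modality == "photon"]
    y = [getattr(r, covariate) for r in records if r.modality == "proton"]
    if len(x) < 2 or len(y) < 2:
        return float("nan")
    _, p = t_test_two_sample(x, y)
    return p


def balance_table(
    records: Sequence[PatientRecord], pairs: Sequence[tuple[str, str]]
) -> pd.DataFrame:
    """Per-covariate photon-vs-proton p-values before and after matching,
    overall and within the necrosis / control strata.

    Categorical covariates use the chi-square test, age and prescription
    dose Welch's t test. Undefined comparisons (empty stratum or
    degenerate table) are NaN.
    """
    matched_ids = {pid for pair in pairs for pid in pair}
    cohorts = {
        "pre": list(records),
        "post": [r for r in records if r.patient_id in matched_ids],
    }
    rows = []
    for covariate in _CATEGORICAL_COVARIATES + _NUMERIC_COVARIATES:
        row = {"covariate": covariate}
        for phase, recs in cohorts.items():
            strata = {
                "overall": recs,
                "orn": [r for r in recs if r.orn],
                "control": [r for r in recs if not r.orn],
            }
            for sname, sub in strata.items():
                if covariate in _NUMERIC_COVARIATES:
                    row[f"{phase}_{sname}"] = _numeric_p(sub, covariate)
                else:
                    row[f"{phase}_{sname}"] = _categorical_p(sub, covariate)
        rows.append(row)
    return pd.DataFrame(rows).set_index("covariate")
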