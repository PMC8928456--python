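"""Statistical machinery: rank tests, chi-square, Welch t, ROC curves with
optimal operating points, and a stratified bootstrap engine.

The tests are implemented directly (not delegated) so that their exact
conventions are pinned: Mann-Whitney uses an exact permutation p-value for
small tie-free samples and a tie-corrected, continuity-corrected normal
approximation otherwise; the chi-square is Pearson's without Yates
correction; the t test is Welch's.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Callable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "mann_whitney_u",
    "chi_square",
    "t_test_two_sample",
    "RocCurve",
    "roc_curve",
    "optimal_operating_point",
    "BootstrapSpec",
    "bootstrap_ci",
    "CriticalVolumeResult",
    "critical_volume",
    "index_significance_table",
]

from .config import BootstrapSpec  # re-exported for convenience


# ---------------------------------------------------------------------------
# rank / location tests

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for x: concordant (x > y) pairs, ties counted 1/2."""
    greater = (x[:, None] > y[None, :]).sum()
    equal = (x[:, None] == y[None, :]).sum()
    return float(greater) + 0.5 * float(equal)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` where U counts pairs with x > y (ties 1/2).  Exact
    permutation p when both samples have n <= 8 and there are no ties;
    otherwise a normal approximation with tie-corrected variance and
    continuity correction.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample")
    n1, n2 = x.size, y.size
    u_obs = _u_statistic(x, y)
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size

    if n1 <= 8 and n2 <= 8 and not has_ties:
        # enumerate all splits of the pooled sample
        mu = n1 * n2 / 2.0
        dev = abs(u_obs - mu)
        count = 0
        total = 0
        idx = range(n1 + n2)
        for comb in combinations(idx, n1):
            mask = np.zeros(n1 + n2, bool)
            mask[list(comb)] = True
            u = _u_statistic(pooled[mask], pooled[~mask])
            total += 1
            if abs(u - mu) >= dev - 1e-12:
                count += 1
        return u_obs, count / total

    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return u_obs, 1.0  # all values identical
    mu = n1 * n2 / 2.0
    z = (abs(u_obs - mu) - 0.5) / math.sqrt(var)
    z = max(z, 0.0)
    return u_obs, float(min(1.0, 2.0 * sps.norm.sf(z)))


def chi_square(table) -> tuple[float, float]:
    """Pearson chi-square for an r x k contingency table, no continuity
    correction. Degenerate tables (an all-zero row or column) return
    ``(nan, nan)``."""
    obs = np.asarray(table, float)
    if obs.ndim != 2 or np.any(obs < 0):
        raise ValueError("contingency table must be 2-D with nonnegative counts")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        return float("nan"), float("nan")
    expected = np.outer(rows, cols) / obs.sum()
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    if df == 0:
        return float("nan"), float("nan")
    return stat, float(sps.chi2.sf(stat, df))


def t_test_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Welch's two-sided two-sample t test with Welch-Satterthwaite df.

    Degenerate variances: both zero with equal means -> ``(0.0, 1.0)``;
    both zero with different means -> ``(+/-inf, 0.0)``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need n >= 2 in each sample")
    vx = x.var(ddof=1)
    vy = y.var(ddof=1)
    diff = x.mean() - y.mean()
    se2 = vx / x.size + vy / y.size
    if se2 == 0:
        if diff == 0:
            return 0.0, 1.0
        return math.copysign(math.inf, diff), 0.0
    t = diff / math.sqrt(se2)
    df = se2**2 / (
        (vx / x.size) ** 2 / (x.size - 1) + (vy / y.size) ** 2 / (y.size - 1)
    )
    return float(t), float(2.0 * sps.t.sf(abs(t), df))


# ---------------------------------------------------------------------------
# ROC

@dataclass(frozen=True)
class RocCurve:
    thresholds: np.ndarray  # ascending, +inf sentinel last
    tpr: np.ndarray  # P(value >= threshold | positive)
    fpr: np.ndarray  # P(value >= threshold | negative)
    auc: float


def roc_curve(values: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC under the rule "positive if value >= threshold".

    Thresholds are the distinct observed values plus a +inf sentinel.  The
    AUC is the trapezoidal area of the resulting curve (equivalently the
    Mann-Whitney concordance with ties counted 1/2).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels, bool)
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thresholds = np.concatenate([np.unique(values), [np.inf]])
    pos = np.sort(values[labels])
    neg = np.sort(values[~labels])
    tpr = (n_pos - np.searchsorted(pos, thresholds, side="left")) / n_pos
    fpr = (n_neg - np.searchsorted(neg, thresholds, side="left")) / n_neg
    # descending threshold order traces the curve from (0,0) to (1,1)
    auc = float(np.trapezoid(tpr[::-1], fpr[::-1]))
    return RocCurve(thresholds=thresholds, tpr=tpr, fpr=fpr, auc=auc)


def optimal_operating_point(curve: RocCurve) -> tuple[float, float, float]:
    """Threshold minimizing the Euclidean distance to (FPR 0, TPR 1).

    Ties are broken by smaller FPR, then by larger threshold (the more
    specific constraint). Returns ``(critical_value, tpr, fpr)``.
    """
    d2 = (1.0 - curve.tpr) ** 2 + curve.fpr**2
    # lexicographic: distance, then fpr, then -threshold (rounded to absorb
    # float noise in exact ties)
    order = np.lexsort((-curve.thresholds, np.round(curve.fpr, 12), np.round(d2, 12)))
    best = int(order[0])
    t = curve.thresholds[best]
    if not np.isfinite(t):  # sentinel wins only on degenerate input
        finite = curve.thresholds[np.isfinite(curve.thresholds)]
        t = float(finite[-1]) if finite.size else float("nan")
        best = int(np.where(curve.thresholds == t)[0][0]) if finite.size else best
    return float(t), float(curve.tpr[best]), float(curve.fpr[best])


# ---------------------------------------------------------------------------
# bootstrap

def _strata_indices(data: pd.DataFrame, stratification: str) -> list[np.ndarray]:
    if stratification == "modality":
        keys = [data["modality"]]
    else:
        keys = [data["modality"], data["orn"]]
    return [g.index.to_numpy() for _, g in data.groupby(keys, sort=True)]


def bootstrap_ci(
    statistic_fn: Callable[[pd.DataFrame], object],
    data: pd.DataFrame,
    spec: BootstrapSpec,
) -> tuple[object, object, object, int]:
    """Stratified percentile bootstrap.

    ``data`` must carry ``modality`` and ``orn`` columns; resamples are
    drawn with replacement within strata (group sizes preserved).
    Resamples with fewer than ``spec.min_cases`` ORN patients in either
    modality are redrawn (count returned); if more than half of all draws
    are rejected the run aborts.

    ``statistic_fn`` may return a scalar, a dict of scalars, or a 1-D
    array; the point estimate and the elementwise 2.5/97.5 percentile
    bounds have the same shape. NaN replicate entries are ignored
    per-element when taking percentiles.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    data = data.reset_index(drop=True)
    strata = _strata_indices(data, spec.stratification)

    point = statistic_fn(data)
    keys = list(point.keys()) if isinstance(point, Mapping) else None

    def as_vector(result):
        if keys is not None:
            return np.array([float(result[k]) for k in keys])
        return np.atleast_1d(np.asarray(result, float))

    point_vec = as_vector(point)
    reps = np.empty((spec.n_reps, point_vec.size))
    accepted = 0
    rejected = 0
    max_attempts = 2 * spec.n_reps + 10
    attempts = 0
    while accepted < spec.n_reps:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"bootstrap rejection rate above 50%: {rejected} rejected in "
                f"{attempts} attempts (min_cases={spec.min_cases})"
            )
        attempts += 1
        idx = np.concatenate([rng.choice(s, size=s.size, replace=True) for s in strata])
        resample = data.iloc[idx].reset_index(drop=True)
        ok = True
        for modality in resample["modality"].unique():
            cases = int(resample.loc[resample["modality"] == modality, "orn"].sum())
            if cases < spec.min_cases:
                ok = False
                break
        if not ok:
            rejected += 1
            continue
        reps[accepted] = as_vector(statistic_fn(resample))
        accepted += 1

    with np.errstate(invalid="ignore"):
        lo = np.nanpercentile(reps, 2.5, axis=0)
        hi = np.nanpercentile(reps, 97.5, axis=0)

    def as_result(vec):
        if keys is not None:
            return {k: float(v) for k, v in zip(keys, vec)}
        return float(vec[0]) if vec.size == 1 else vec

    return as_result(point_vec), as_result(lo), as_result(hi), rejected


# ---------------------------------------------------------------------------
# critical volumes & Table-2-analog

@dataclass(frozen=True)
class CriticalVolumeResult:
    index_name: str
    critical_value: float
    tpr_at: float
    fpr_at: float
    auc: float
    ci_low: Optional[float] = None
    ci_high: Optional[float] = None
    auc_ci: Optional[tuple[float, float]] = None


def critical_volume(values, labels, index_name: str = "") -> CriticalVolumeResult:
    """ROC-derived constraint threshold (point estimate only)."""
    curve = roc_curve(values, labels)
    thr, tpr_at, fpr_at = optimal_operating_point(curve)
    return CriticalVolumeResult(
        index_name=index_name,
        critical_value=thr,
        tpr_at=tpr_at,
        fpr_at=fpr_at,
        auc=curve.auc,
    )


def critical_volume_with_ci(
    values, labels, spec: BootstrapSpec, index_name: str = "", modality: str = "any"
) -> CriticalVolumeResult:
    """Critical volume with bootstrap percentile CIs (single-group data;
    resampling stratified by outcome to keep the ROC defined)."""
    data = pd.DataFrame(
        {"value": np.asarray(values, float), "orn": np.asarray(labels, bool), "modality": modality}
    )

    def stat(df):
        cv = critical_volume(df["value"].to_numpy(), df["orn"].to_numpy(), index_name)
        return {"critical": cv.critical_value, "auc": cv.auc}

    point, lo, hi, _ = bootstrap_ci(stat, data, spec)
    base = critical_volume(values, labels, index_name)
    return CriticalVolumeResult(
        index_name=index_name,
        critical_value=base.critical_value,
        tpr_at=base.tpr_at,
        fpr_at=base.fpr_at,
        auc=base.auc,
        ci_low=lo["critical"],
        ci_high=hi["critical"],
        auc_ci=(lo["auc"], hi["auc"]),
    )


def index_significance_table(
    indices: pd.DataFrame,
    index_names: Sequence[str] = ("v40", "v50", "v60", "v70", "v75", "d001cc", "dmean"),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Mann-Whitney p-values (necrosis vs control) for each DVH index,
    overall and per modality, on a cohort index table with ``modality``
    and ``orn`` columns.

    Indices with p < alpha in *both* modalities are flagged as eligible
    for constraint derivation. Groups without cases yield NaN entries.
    """
    groups = {
        "overall": indices,
        "photon": indices[indices["modality"] == "photon"],
        "proton": indices[indices["modality"] == "proton"],
    }
    rows = []
    for name in index_names:
        row = {"index": name}
        for gname, g in groups.items():
            vals = g[name].astype(float)
            labels = g["orn"].astype(bool)
            sub = vals.notna()
            vals, labels = vals[sub], labels[sub]
            if labels.sum() == 0 or (~labels).sum() == 0:
                row[f"p_{gname}"] = float("nan")
            else:
                _, p = mann_whitney_u(vals[labels].to_numpy(), vals[~labels].to_numpy())
                row[f"p_{gname}"] = p
        row["dvc_eligible"] = bool(
            row["p_photon"] < alpha and row["p_proton"] < alpha
        ) if not (math.isnan(row["p_photon"]) or math.isnan(row["p_proton"])) else False
        rows.append(row)
    return pd.DataFrame(rows).set_index("index")
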