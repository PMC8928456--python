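import itertools
import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from ornrbe.config import BootstrapSpec
from ornrbe.inference_stats import (
    bootstrap_ci,
    chi_square,
    critical_volume,
    index_significance_table,
    mann_whitney_u,
    optimal_operating_point,
    roc_curve,
    t_test_two_sample,
)


# ---------------------------------------------------------------------------
# Mann-Whitney

def test_mw_exact_small_sample():
    # All C(4,2)=6 splits enumerated; only U in {0,4} is as extreme as U=0.
    u, p = mann_whitney_u([1, 2], [3, 4])
    assert u == 0.0
    assert p == pytest.approx(2 / 6)


def test_mw_identical_samples_ties():
    x = [1.0, 2.0, 3.0, 4.0, 5.0]
    _, p = mann_whitney_u(x, x)
    assert p >= 0.99


def test_mw_empty_sample_raises():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


def test_mw_matches_reference_implementation():
    rng = np.random.default_rng(0)
    for _ in range(25):
        x = rng.normal(size=20)
        y = rng.normal(0.5, 1.2, size=20)
        u, p = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert u == pytest.approx(ref.statistic)
        assert p == pytest.approx(ref.pvalue, abs=1e-6)


def test_mw_matches_reference_with_ties():
    rng = np.random.default_rng(4)
    x = rng.integers(0, 6, 30).astype(float)
    y = rng.integers(0, 6, 25).astype(float)
    u, p = mann_whitney_u(x, y)
    ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    assert u == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, abs=1e-6)


def test_mw_exact_matches_full_enumeration():
    # independent oracle: directly enumerate all label arrangements
    x = [0.3, 1.7, 2.9]
    y = [1.1, 2.2, 3.4, 4.0]
    u_obs, p = mann_whitney_u(x, y)
    pooled = np.array(x + y)
    mu = len(x) * len(y) / 2
    count = total = 0
    for comb in itertools.combinations(range(7), 3):
        mask = np.zeros(7, bool)
        mask[list(comb)] = True
        xs, ys = pooled[mask], pooled[~mask]
        u = sum((a > b) + 0.5 * (a == b) for a in xs for b in ys)
        total += 1
        count += abs(u - mu) >= abs(u_obs - mu) - 1e-12
    assert p == pytest.approx(count / total)


# ---------------------------------------------------------------------------
# chi-square

def test_chi_square_homogeneous():
    stat, p = chi_square([[10, 10], [10, 10]])
    assert stat == pytest.approx(0.0)
    assert p == pytest.approx(1.0)


def test_chi_square_hand_computation():
    # expected 10 everywhere; sum of (20-10)^2/10 and (0-10)^2/10 over 4 cells
    stat, p = chi_square([[20, 0], [0, 20]])
    assert stat == pytest.approx(40.0)
    assert p == pytest.approx(sps.chi2.sf(40.0, 1))


def test_chi_square_df_for_stage_table():
    table = [[10, 12, 14, 50, 10], [5, 6, 7, 25, 5]]
    stat, p = chi_square(table)
    assert p == pytest.approx(sps.chi2.sf(stat, 4))


def test_chi_square_degenerate_undefined():
    stat, p = chi_square([[0, 0], [5, 5]])
    assert math.isnan(p)


def test_chi_square_matches_reference():
    rng = np.random.default_rng(8)
    table = rng.integers(1, 40, (2, 5))
    stat, p = chi_square(table)
    ref = sps.chi2_contingency(table, correction=False)
    assert stat == pytest.approx(ref.statistic)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


# ---------------------------------------------------------------------------
# t test

def test_t_identical_samples():
    stat, p = t_test_two_sample([1, 2, 3], [1, 2, 3])
    assert stat == 0.0
    assert p == pytest.approx(1.0)


def test_t_degenerate_variance():
    stat, p = t_test_two_sample([0.0, 0.0], [1.0, 1.0])
    assert math.isinf(stat)
    assert p == 0.0
    stat, p = t_test_two_sample([2.0, 2.0], [2.0, 2.0])
    assert (stat, p) == (0.0, 1.0)


def test_t_matches_reference():
    rng = np.random.default_rng(3)
    x = rng.normal(0, 1, 15)
    y = rng.normal(0.4, 2, 20)
    stat, p = t_test_two_sample(x, y)
    ref = sps.ttest_ind(x, y, equal_var=False)
    assert stat == pytest.approx(ref.statistic, abs=1e-8)
    assert p == pytest.approx(ref.pvalue, abs=1e-8)


# ---------------------------------------------------------------------------
# ROC

def test_roc_perfect_separation():
    curve = roc_curve([1, 2, 3, 4], [False, False, True, True])
    assert curve.auc == pytest.approx(1.0)
    thr, tpr, fpr = optimal_operating_point(curve)
    assert (tpr, fpr) == (1.0, 0.0)
    assert thr == pytest.approx(3.0)


def test_roc_interleaved():
    curve = roc_curve([1, 2, 3, 4], [False, True, False, True])
    assert curve.auc == pytest.approx(0.75)  # 3 of 4 concordant pairs


def test_roc_pure_ties():
    curve = roc_curve([2.0, 2.0, 2.0, 2.0], [True, True, False, False])
    assert curve.auc == pytest.approx(0.5)


def test_roc_single_class_raises():
    with pytest.raises(ValueError):
        roc_curve([1, 2], [True, True])


def test_roc_rates_monotone_in_threshold():
    rng = np.random.default_rng(2)
    values = rng.normal(size=60)
    labels = rng.random(60) < 0.4
    curve = roc_curve(values, labels)
    assert np.all(np.diff(curve.tpr) <= 1e-12)
    assert np.all(np.diff(curve.fpr) <= 1e-12)
    assert curve.tpr[0] == 1.0 and curve.fpr[0] == 1.0
    assert curve.tpr[-1] == 0.0 and curve.fpr[-1] == 0.0


def test_auc_equals_mann_whitney_concordance():
    rng = np.random.default_rng(6)
    for _ in range(30):
        n1, n0 = rng.integers(4, 25, 2)
        values = np.concatenate([rng.normal(1, 1, n1), rng.normal(0, 1, n0)])
        values = np.round(values, 1)  # induce ties
        labels = np.concatenate([np.ones(n1, bool), np.zeros(n0, bool)])
        curve = roc_curve(values, labels)
        u, _ = mann_whitney_u(values[labels], values[~labels])
        assert curve.auc == pytest.approx(u / (n1 * n0), abs=1e-12)


def test_operating_point_tie_break():
    # thresholds 2 and 4 both at distance 0.5; tie resolves to FPR 0 (thr 4)
    curve = roc_curve([1, 2, 3, 4], [False, True, False, True])
    thr, tpr, fpr = optimal_operating_point(curve)
    assert thr == pytest.approx(4.0)
    assert (tpr, fpr) == (0.5, 0.0)


@settings(max_examples=40, deadline=None)
@given(st.integers(0, 10**6))
def test_operating_point_is_exhaustive_minimum(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 40))
    values = np.round(rng.normal(size=n), 1)
    labels = rng.random(n) < 0.5
    if labels.all() or not labels.any():
        return
    curve = roc_curve(values, labels)
    thr, tpr, fpr = optimal_operating_point(curve)
    d_best = math.hypot(1 - tpr, fpr)
    for t, tp, fp in zip(curve.thresholds, curve.tpr, curve.fpr):
        assert d_best <= math.hypot(1 - tp, fp) + 1e-12


# ---------------------------------------------------------------------------
# bootstrap

def _frame(values, orn, modality="photon"):
    return pd.DataFrame({"value": values, "orn": orn, "modality": modality})


def test_bootstrap_constant_statistic():
    data = _frame(np.arange(20.0), [True] * 10 + [False] * 10)
    point, lo, hi, rejected = bootstrap_ci(
        lambda df: 3.25, data, BootstrapSpec(n_reps=50, seed=1)
    )
    assert point == lo == hi == 3.25
    assert rejected == 0


def test_bootstrap_deterministic():
    rng = np.random.default_rng(0)
    data = _frame(rng.normal(size=40), [True] * 8 + [False] * 32)
    spec = BootstrapSpec(n_reps=100, seed=42)
    r1 = bootstrap_ci(lambda df: df["value"].mean(), data, spec)
    r2 = bootstrap_ci(lambda df: df["value"].mean(), data, spec)
    assert r1 == r2


def test_bootstrap_single_rep_collapses():
    data = _frame(np.arange(10.0), [True] * 5 + [False] * 5)
    point, lo, hi, _ = bootstrap_ci(
        lambda df: df["value"].mean(), data, BootstrapSpec(n_reps=1, seed=3)
    )
    assert lo == hi  # single resample: both bounds equal its statistic


def test_bootstrap_preserves_stratum_sizes():
    data = pd.DataFrame(
        {
            "value": np.arange(30.0),
            "orn": [True] * 5 + [False] * 10 + [True] * 5 + [False] * 10,
            "modality": ["photon"] * 15 + ["proton"] * 15,
        }
    )

    def stat(df):
        counts = df.groupby(["modality", "orn"]).size()
        return {str(k): v for k, v in counts.items()}

    point, lo, hi, _ = bootstrap_ci(stat, data, BootstrapSpec(n_reps=25, seed=7))
    assert point == lo == hi  # stratified resampling preserves all group sizes


def test_bootstrap_rejection_abort():
    # modality-level stratification with min_cases larger than available
    data = _frame(np.arange(12.0), [True] * 1 + [False] * 11)
    spec = BootstrapSpec(n_reps=20, seed=1, stratification="modality", min_cases=5)
    with pytest.raises(RuntimeError, match="rejection"):
        bootstrap_ci(lambda df: df["value"].mean(), data, spec)


def test_bootstrap_coverage_of_normal_mean():
    """Percentile bootstrap CI for a mean: empirical coverage across outer
    replications within [90%, 99%] at nominal 95%."""
    outer_rng = np.random.default_rng(2024)
    hits = 0
    n_outer = 100
    for i in range(n_outer):
        sample = outer_rng.normal(5.0, 2.0, 100)
        data = _frame(sample, [True] * 50 + [False] * 50)
        _, lo, hi, _ = bootstrap_ci(
            lambda df: df["value"].mean(),
            data,
            BootstrapSpec(n_reps=300, seed=i, min_cases=1),
        )
        hits += lo <= 5.0 <= hi
    assert 0.90 <= hits / n_outer <= 0.99


# ---------------------------------------------------------------------------
# critical volume + significance table

def test_critical_volume_reports_curve_consistent_point():
    values = [1, 2, 3, 4, 5, 6, 7, 8]
    labels = [False] * 4 + [True] * 4
    cv = critical_volume(values, labels, "v40")
    assert cv.critical_value == pytest.approx(5.0)
    assert cv.tpr_at == 1.0 and cv.fpr_at == 0.0
    assert cv.auc == pytest.approx(1.0)


def _toy_indices(rng, n=120, effect=6.0):
    orn = rng.random(n) < 0.15
    rows = []
    for i in range(n):
        base = rng.normal(30, 5) + (effect if orn[i] else 0.0)
        rows.append(
            {
                "patient_id": f"P{i}",
                "modality": "photon" if i % 2 == 0 else "proton",
                "orn": int(orn[i]),
                "v40": base,
                "v50": base * 0.7,
                "v60": base * 0.3,
                "v70": base * 0.1,
                "v75": base * 0.05,
                "d001cc": rng.normal(66, 2),
                "dmean": base * 0.9,
            }
        )
    return pd.DataFrame(rows)


def test_significance_table_shape_and_consistency():
    rng = np.random.default_rng(5)
    table = _toy_indices(rng)
    result = index_significance_table(table)
    assert list(result.index) == ["v40", "v50", "v60", "v70", "v75", "d001cc", "dmean"]
    # per-group entries equal direct computation on the subset
    sub = table[table["modality"] == "photon"]
    x = sub.loc[sub["orn"] == 1, "v40"].to_numpy()
    y = sub.loc[sub["orn"] == 0, "v40"].to_numpy()
    assert result.loc["v40", "p_photon"] == pytest.approx(mann_whitney_u(x, y)[1])


def test_significance_flags_constraint_indices_under_default_generator(default_config):
    """The generator's volume-outcome effect makes v40/v50/v60 eligible
    (p < 0.05 in both modalities) in nearly all seeds."""
    from ornrbe import generate_cohort
    from ornrbe.dosimetry import index_table

    hits = 0
    n_seeds = 5
    for seed in range(100, 100 + n_seeds):
        records, samples = generate_cohort(
            default_config.covariates,
            default_config.confounding,
            default_config.dose_field,
            default_config.outcome,
            1266,
            seed,
        )
        result = index_significance_table(index_table(records, samples))
        hits += all(result.loc[i, "dvc_eligible"] for i in ("v40", "v50", "v60"))
    assert hits >= n_seeds - 1


def test_significance_table_flags_missing_cases():
    rng = np.random.default_rng(5)
    table = _toy_indices(rng)
    table.loc[table["modality"] == "proton", "orn"] = 0
    result = index_significance_table(table)
    assert math.isnan(result.loc["v40", "p_proton"])
    assert not result.loc["v40", "dvc_eligible"]
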