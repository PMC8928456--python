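import dataclasses

import numpy as np
import pytest
import statsmodels.api as sm
from scipy.optimize import linear_sum_assignment

from ornrbe import generate_cohort
from ornrbe.cohort import PatientRecord
from ornrbe.matching import (
    DEFAULT_MATCHING_TERMS,
    balance_table,
    design_matrix,
    fit_propensity,
    greedy_match,
)


def make_record(pid, modality, **kwargs):
    defaults = dict(
        age=60.0,
        gender="male",
        stage="IV",
        prescription_dose=66.0,
        chemo=False,
        hypertension=False,
        diabetes=False,
        dental_extraction=False,
        smoking_history=False,
        current_smoker=False,
        oropharynx_or_oral_cavity=True,
        orn=False,
        orn_grade=None,
    )
    defaults.update(kwargs)
    return PatientRecord(patient_id=pid, modality=modality, **defaults)


# ---------------------------------------------------------------------------
# propensity model

def test_intercept_only_fit_returns_proton_fraction():
    records = [make_record(f"P{i}", "proton" if i < 3 else "photon") for i in range(10)]
    result = fit_propensity(records)
    assert result.converged
    for score in result.scores.values():
        assert score == pytest.approx(0.3, abs=1e-6)


def test_perfect_separation_flagged():
    records = [
        make_record(f"P{i}", "proton" if i < 5 else "photon", hypertension=i < 5)
        for i in range(10)
    ]
    with pytest.warns(RuntimeWarning, match="converge"):
        result = fit_propensity(records, ["hypertension"])
    assert not result.converged
    for s in result.scores.values():
        assert 1e-12 <= s <= 1 - 1e-12


def test_coefficients_match_statsmodels_oracle():
    rng = np.random.default_rng(17)
    records = []
    for i in range(60):
        hyp = bool(rng.random() < 0.5)
        smk = bool(rng.random() < 0.5)
        p = 1 / (1 + np.exp(-(-0.5 - 0.8 * hyp + 0.9 * smk)))
        records.append(
            make_record(
                f"P{i:02d}",
                "proton" if rng.random() < p else "photon",
                hypertension=hyp,
                smoking_history=smk,
            )
        )
    result = fit_propensity(records, ["hypertension", "smoking_history"])
    assert result.converged

    X, names = design_matrix(records, ["hypertension", "smoking_history"])
    y = np.array([r.modality == "proton" for r in records], float)
    ref = sm.Logit(y, X).fit(disp=0)
    for name, coef in zip(names, ref.params):
        assert result.coefficients[name] == pytest.approx(coef, abs=1e-6)


def test_fit_deterministic(small_cohort):
    records, _ = small_cohort
    r1 = fit_propensity(records)
    r2 = fit_propensity(records)
    assert r1.coefficients == r2.coefficients
    assert r1.scores == r2.scores


def test_requires_both_modalities():
    records = [make_record(f"P{i}", "photon") for i in range(10)]
    with pytest.raises(ValueError):
        fit_propensity(records)


# ---------------------------------------------------------------------------
# greedy matching

def _result_from_scores(proton_scores, photon_scores):
    from ornrbe.matching import PropensityResult

    records = []
    scores = {}
    for i, s in enumerate(proton_scores):
        pid = f"R{i}"
        records.append(make_record(pid, "proton"))
        scores[pid] = s
    for i, s in enumerate(photon_scores):
        pid = f"V{i}"
        records.append(make_record(pid, "photon"))
        scores[pid] = s
    result = PropensityResult(coefficients={}, scores=scores, converged=True, iterations=1)
    return result, records


def test_greedy_match_worked_example():
    result, records = _result_from_scores([0.8, 0.5], [0.6, 0.55, 0.2])
    matched = greedy_match(result, records)
    assert dict(matched.pairs) == {"R0": "V0", "R1": "V1"}
    assert matched.unmatched_proton == []


def test_greedy_match_identical_scores_zero_distance():
    result, records = _result_from_scores([0.4, 0.3, 0.2], [0.4, 0.3, 0.2])
    matched = greedy_match(result, records)
    for p, g in matched.pairs:
        assert result.scores[p] == result.scores[g]


def test_greedy_no_photon_reuse(small_cohort):
    records, _ = small_cohort
    result = fit_propensity(records)
    matched = greedy_match(result, records)
    photon_ids = [g for _, g in matched.pairs]
    assert len(photon_ids) == len(set(photon_ids))
    n_proton = sum(r.modality == "proton" for r in records)
    assert len(matched.pairs) == n_proton  # all proton patients retained


def greedy_oracle(proton, photon):
    """Independent re-implementation of the stated greedy rule."""
    pairs = []
    pool = dict(photon)
    for pid, score in sorted(proton, key=lambda t: (-t[1], t[0])):
        if not pool:
            break
        best = min(pool.items(), key=lambda kv: (abs(kv[1] - score), kv[0]))
        pairs.append((pid, best[0]))
        del pool[best[0]]
    return pairs


@pytest.mark.parametrize("seed", range(10))
def test_greedy_matches_oracle_on_random_instances(seed):
    rng = np.random.default_rng(seed)
    n_p, n_g = 12, 18
    proton = [(f"R{i:02d}", float(rng.random())) for i in range(n_p)]
    photon = [(f"V{i:02d}", float(rng.random())) for i in range(n_g)]
    result, records = _result_from_scores([s for _, s in proton], [s for _, s in photon])
    # rebuild with matching ids
    scores = dict(proton + photon)
    from ornrbe.matching import PropensityResult

    records = [make_record(pid, "proton") for pid, _ in proton] + [
        make_record(pid, "photon") for pid, _ in photon
    ]
    result = PropensityResult({}, scores, True, 1)
    matched = greedy_match(result, records)
    assert matched.pairs == greedy_oracle(proton, photon)


def test_greedy_invariant_to_photon_input_order():
    rng = np.random.default_rng(5)
    proton = [(f"R{i}", float(rng.random())) for i in range(8)]
    photon = [(f"V{i}", float(rng.random())) for i in range(12)]
    from ornrbe.matching import PropensityResult

    scores = dict(proton + photon)
    records = [make_record(pid, "proton") for pid, _ in proton] + [
        make_record(pid, "photon") for pid, _ in photon
    ]
    shuffled = records[:8] + records[8:][::-1]
    r = PropensityResult({}, scores, True, 1)
    assert greedy_match(r, records).pairs == greedy_match(r, shuffled).pairs


def test_greedy_total_distance_at_least_optimal():
    rng = np.random.default_rng(11)
    for _ in range(5):
        p_scores = rng.random(6)
        g_scores = rng.random(6)
        result, records = _result_from_scores(list(p_scores), list(g_scores))
        matched = greedy_match(result, records)
        greedy_total = sum(
            abs(result.scores[a] - result.scores[b]) for a, b in matched.pairs
        )
        cost = np.abs(p_scores[:, None] - g_scores[None, :])
        ri, ci = linear_sum_assignment(cost)
        assert greedy_total >= cost[ri, ci].sum() - 1e-12


def test_insufficient_photon_pool_warns():
    result, records = _result_from_scores([0.5, 0.4, 0.3], [0.45])
    with pytest.warns(RuntimeWarning, match="unmatched"):
        matched = greedy_match(result, records)
    assert len(matched.unmatched_proton) == 2


# ---------------------------------------------------------------------------
# balance

def test_balance_identical_groups_age_p_one():
    records = []
    for i in range(10):
        records.append(make_record(f"R{i}", "proton", age=50.0 + i))
        records.append(make_record(f"V{i}", "photon", age=50.0 + i))
    pairs = [(f"R{i}", f"V{i}") for i in range(10)]
    table = balance_table(records, pairs)
    assert table.loc["age", "post_overall"] == pytest.approx(1.0)


def test_balance_detects_generator_confounding_and_matching_fixes_it(full_cohort):
    records, _ = full_cohort
    result = fit_propensity(records)
    matched = greedy_match(result, records)
    table = balance_table(records, matched.pairs)
    # generator-built pre-matching imbalance is detected...
    assert table.loc["stage", "pre_overall"] < 0.05
    assert table.loc["smoking_history", "pre_overall"] < 0.05
    # ...and the matched cohort is balanced on the modeled covariates
    for cov in ("gender", "stage", "chemo", "hypertension", "diabetes",
                "dental_extraction", "smoking_history", "current_smoker"):
        assert table.loc[cov, "post_overall"] > 0.05, cov


def test_balance_undefined_stratum_is_nan(small_cohort):
    records = [make_record(f"R{i}", "proton") for i in range(4)] + [
        make_record(f"V{i}", "photon") for i in range(4)
    ]
    table = balance_table(records, [("R0", "V0")])
    # no ORN cases at all -> orn stratum undefined
    assert np.isnan(table.loc["age", "pre_orn"])
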