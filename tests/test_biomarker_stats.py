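"""Association statistics and ROC/Youden against independent oracles."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mirpredict.biomarker_stats import (
    backward_logistic,
    categorical_association,
    compare_groups,
    outcome_indicator,
    pivot_scan,
    roc_curve,
    scan_outcomes,
    spearman_assoc,
    youden_cutpoint,
)


# ---------------------------------------------------------------------------
# compare_groups


def test_identical_groups_are_degenerate_with_p_one():
    res = compare_groups([1.0, 1.0, 1.0, 1.0], [True, True, False, False])
    assert res.p_value == 1.0
    assert res.degenerate
    assert res.direction == 0


def test_normal_samples_select_t_test(rng):
    hits = 0
    for _ in range(50):
        v = rng.normal(0, 1, 60)
        res = compare_groups(v, np.arange(60) < 30)
        hits += res.test_used == "t"
    assert hits >= 40  # Shapiro passes in the vast majority of normal draws


def test_skewed_samples_select_mann_whitney(rng):
    hits = 0
    for _ in range(50):
        v = rng.exponential(1.0, 60) ** 2
        res = compare_groups(v, np.arange(60) < 30)
        hits += res.test_used == "mann-whitney"
    assert hits >= 40


def test_small_groups_skip_normality_gate():
    res = compare_groups([1.0, 2.0, 5.0, 6.0], [True, True, False, False])
    assert res.test_used == "mann-whitney"


def test_direction_tracks_median_difference():
    res = compare_groups([5.0, 6.0, 7.0, 1.0, 2.0, 3.0], [1, 1, 1, 0, 0, 0])
    assert res.direction == 1


# ---------------------------------------------------------------------------
# categorical / spearman


def test_fisher_matches_hypergeometric_enumeration():
    # [[10,0],[0,10]]: two-sided exact p = 2 / C(20,10)
    p, test = categorical_association(
        ["a"] * 10 + ["b"] * 10, [1] * 10 + [0] * 10
    )
    assert test == "fisher"
    assert p == pytest.approx(2 / math.comb(20, 10), rel=1e-9)


def test_balanced_table_gives_p_one():
    p, _ = categorical_association(
        ["a"] * 10 + ["b"] * 10, [1, 0] * 10
    )
    assert p == pytest.approx(1.0)


def test_large_table_uses_chi2_and_is_calibrated(rng):
    pvals = []
    for _ in range(200):
        f = rng.choice(["x", "y"], 200)
        o = rng.choice([0, 1], 200)
        p, test = categorical_association(f, o)
        pvals.append(p)
    assert np.mean(np.array(pvals) < 0.05) < 0.12


def test_spearman_exact_and_permutation_oracle(rng):
    assert spearman_assoc([1, 2, 3, 4], [1, 2, 3, 4])[0] == pytest.approx(1.0)
    assert spearman_assoc([1, 2, 3, 4], [4, 3, 2, 1])[0] == pytest.approx(-1.0)
    x = rng.normal(size=6)
    y = rng.normal(size=6)
    rho, _ = spearman_assoc(x, y)
    # permutation oracle on the rank correlation
    rx = stats.rankdata(x)
    null = [
        np.corrcoef(rx, np.array(perm))[0, 1]
        for perm in itertools.permutations(stats.rankdata(y))
    ]
    p_perm = np.mean(np.abs(null) >= abs(rho) - 1e-12)
    _, p_ours = spearman_assoc(x, y)
    assert abs(p_perm - p_ours) < 0.15  # asymptotic vs exact at n=6


def test_spearman_constant_vector_flagged():
    rho, p = spearman_assoc([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])
    assert math.isnan(rho) and math.isnan(p)


# ---------------------------------------------------------------------------
# outcome scans


def test_scan_denominators_respect_missing_labels(cohort200):
    expr, clin, _ = cohort200
    df = clin.data
    ind_bm = outcome_indicator(clin, "BM-uMRD")
    ind_cr = outcome_indicator(clin, "CR")
    missing_bm_only = df["bm_mrd"].isna() & df["cr"].notna()
    assert missing_bm_only.any()
    pid = df.index[missing_bm_only][0]
    assert np.isnan(ind_bm[pid]) and not np.isnan(ind_cr[pid])
    results = scan_outcomes(expr, clin, mirnas=["miR-15b"])
    by_outcome = {r.outcome: r for r in results}
    assert by_outcome["BM-uMRD"].n_positive + by_outcome["BM-uMRD"].n_negative == int(
        df["bm_mrd"].notna().sum()
    )


def test_scan_detects_planted_tree_mirnas(cohort200):
    expr, clin, truth = cohort200
    results = scan_outcomes(expr, clin, mirnas=["miR-125b", "miR-155"])
    grid = pivot_scan(results)
    # the root split variable carries real signal for the combined outcome
    assert grid.loc["miR-125b", "CR+BM-uMRD"] < 0.05
    # a null panel member stays unremarkable
    assert grid.loc["miR-155", "CR+BM-uMRD"] > 0.001


# ---------------------------------------------------------------------------
# backward logistic


def test_backward_selection_keeps_planted_predictor(rng):
    n = 500
    x = rng.normal(size=(n, 6))
    logit = 1.5 * x[:, 0] - 0.5
    y = rng.random(n) < 1 / (1 + np.exp(-logit))
    cov = pd.DataFrame(x, columns=[f"v{i}" for i in range(6)])
    model = backward_logistic(y, cov, alpha_stay=0.05)
    assert "v0" in model.variables
    assert len(set(model.variables) - {"v0"}) <= 1


def test_alpha_one_full_model_alpha_zero_empty(rng):
    n = 120
    cov = pd.DataFrame(rng.normal(size=(n, 3)), columns=["a", "b", "c"])
    y = rng.random(n) < 0.4
    full = backward_logistic(y, cov, alpha_stay=1.0)
    assert set(full.variables) == {"a", "b", "c"}
    empty = backward_logistic(y, cov, alpha_stay=0.0)
    assert empty.variables == []
    assert set(empty.dropped) == {"a", "b", "c"}


def test_odds_ratio_consistency_at_large_n(rng):
    n = 10000
    x = rng.normal(size=n)
    y = rng.random(n) < 1 / (1 + np.exp(-(x - 0.2)))
    model = backward_logistic(y, pd.DataFrame({"x": x}), alpha_stay=0.05)
    assert model.summary.loc["x", "odds_ratio"] == pytest.approx(math.e, rel=0.10)
    lo, hi = model.summary.loc["x", ["ci_low", "ci_high"]]
    assert lo < math.e < hi


def test_perfect_separation_flagged_not_fabricated():
    y = np.array([0] * 20 + [1] * 20)
    x = pd.DataFrame({"x": np.r_[np.zeros(20), np.ones(20)]})
    model = backward_logistic(y, x, alpha_stay=1.0)
    assert model.separation or model.summary.empty or (
        model.summary["separated"].any()
    )
    if not model.summary.empty and model.summary["separated"].any():
        assert np.isinf(model.summary.loc["x", "odds_ratio"])


# ---------------------------------------------------------------------------
# ROC / Youden


def _roc_oracle(values, labels):
    """Exhaustive cutpoint enumeration: best J over midpoint thresholds."""
    v = np.asarray(values, float)
    y = np.asarray(labels, bool)
    u = np.unique(v)
    thresholds = np.concatenate(([-np.inf], (u[:-1] + u[1:]) / 2, [np.inf]))
    best = (-np.inf, None, None, None)
    for t in thresholds:
        se = np.mean(v[y] > t)
        sp = np.mean(v[~y] <= t)
        j = se + sp - 1
        if j > best[0] + 1e-12:
            best = (j, t, se, sp)
    return best


def test_perfect_separation_curve():
    roc = roc_curve([1.0, 2.0, 10.0, 11.0], [False, False, True, True])
    assert roc.auc == pytest.approx(1.0)
    assert roc.youden_j == pytest.approx(1.0)
    assert 2.0 < roc.youden_threshold < 10.0
    thr, se, sp = youden_cutpoint(roc)
    assert (se, sp) == (1.0, 1.0)


def test_roc_requires_both_classes():
    with pytest.raises(ValueError, match="both classes"):
        roc_curve([1.0, 2.0], [True, True])


def test_youden_tie_breaks_to_smallest_threshold():
    roc = roc_curve([1.0, 2.0, 3.0, 4.0], [False, True, False, True])
    # J = 0.5 at both 1.5 and 3.5; the smaller threshold wins
    assert roc.youden_threshold == pytest.approx(1.5)


def test_roc_matches_exhaustive_oracle_on_random_instances(rng):
    for _ in range(300):
        n = rng.integers(3, 13)
        v = np.round(rng.normal(size=n), 1)  # coarse values force ties
        y = rng.random(n) < 0.5
        if y.all() or not y.any():
            continue
        roc = roc_curve(v, y)
        j_star, t_star, se_star, sp_star = _roc_oracle(v, y)
        assert roc.youden_j == pytest.approx(j_star, abs=1e-12)
        # chosen threshold achieves the optimal J under oracle counting
        se = np.mean(v[y] > roc.youden_threshold)
        sp = np.mean(v[~y] <= roc.youden_threshold)
        assert se + sp - 1 == pytest.approx(j_star, abs=1e-12)


def test_auc_invariant_under_monotone_transform_and_label_swap(rng):
    v = rng.normal(size=40)
    y = rng.random(40) < 0.5
    if y.all() or not y.any():
        y[0] = ~y[0]
    base = roc_curve(v, y)
    mono = roc_curve(np.exp(v), y)
    assert mono.auc == pytest.approx(base.auc, abs=1e-12)
    assert mono.youden_j == pytest.approx(base.youden_j, abs=1e-12)
    swap = roc_curve(v, ~y)
    assert swap.auc == pytest.approx(1 - base.auc, abs=1e-9)


def test_null_auc_near_half(rng):
    v = rng.normal(size=4000)
    y = rng.random(4000) < 0.5
    assert roc_curve(v, y).auc == pytest.approx(0.5, abs=0.05)


def test_auto_orientation_flips_for_low_positive_marker(rng):
    v = np.r_[rng.normal(2, 1, 100), rng.normal(0, 1, 100)]
    y = np.r_[np.zeros(100, bool), np.ones(100, bool)]  # low values positive
    roc = roc_curve(v, y, orientation="auto")
    assert roc.orientation == "low-positive"
    assert roc.auc > 0.5
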