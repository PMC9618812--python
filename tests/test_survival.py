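"""Survival machinery against hand and grid-search oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from mirpredict.survival import (
    PAPER_THREE_TIER,
    cox_fit,
    km_estimate,
    km_frame,
    landmark_filter,
    logrank,
    pfs_by_tree_group,
)
from mirpredict.synthetic_cohort import CohortSpec, generate_cohort


# ---------------------------------------------------------------------------
# Kaplan–Meier


def test_km_hand_product_limit():
    km = km_estimate([1.0, 2.0, 3.0], [1, 1, 0])
    assert km.survival_at(1.0, side="right") == pytest.approx(2 / 3)
    assert km.survival_at(2.0, side="right") == pytest.approx(1 / 3)
    assert km.survival_at(0.5) == 1.0
    assert km.median_time == pytest.approx(2.0)


def test_km_all_censored_median_not_reached():
    km = km_estimate([5.0, 8.0, 9.0], [0, 0, 0])
    assert (km.survival == 1.0).all()
    assert km.median_time is None
    assert not km.median_reached


def test_km_without_censoring_equals_empirical_survival(rng):
    t = rng.exponential(10.0, 200)
    km = km_estimate(t, np.ones(200, int))
    for q in [1.0, 5.0, 15.0]:
        assert km.survival_at(q, side="right") == pytest.approx((t > q).mean())


def test_km_matches_exponential_survival_at_scale(rng):
    lam = 0.05
    t = rng.exponential(1 / lam, 5000)
    km = km_estimate(t, np.ones(5000, int))
    for q in [5.0, 15.0, 30.0]:
        s = np.exp(-lam * q)
        se = np.sqrt(s * (1 - s) / 5000)
        assert abs(km.survival_at(q, side="right") - s) <= 3 * se + 1e-9


# ---------------------------------------------------------------------------
# log-rank


def test_logrank_identical_groups_null():
    g = ([1.0, 2.0, 3.0, 4.0], [1, 0, 1, 0])
    res = logrank([g, g])
    assert res.chi2 == pytest.approx(0.0, abs=1e-12)
    assert res.p_value == pytest.approx(1.0)
    assert res.df == 1


def _logrank_oracle_two_groups(t1, e1, t2, e2):
    """Direct observed-minus-expected computation with hypergeometric variance."""
    times = np.concatenate([t1, t2])
    events = np.concatenate([e1, e2])
    group = np.r_[np.zeros(len(t1)), np.ones(len(t2))]
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (group == 0)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (group == 0)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e**2 / var


def test_logrank_matches_six_subject_hand_oracle():
    t1, e1 = np.array([1.0, 4.0, 6.0]), np.array([1, 0, 1])
    t2, e2 = np.array([2.0, 3.0, 5.0]), np.array([1, 1, 0])
    oracle = _logrank_oracle_two_groups(t1, e1, t2, e2)
    res = logrank([(t1, e1), (t2, e2)])
    assert res.chi2 == pytest.approx(oracle, abs=1e-10)


def test_logrank_invariant_under_relabeling(rng):
    g1 = (rng.exponential(10, 30), rng.integers(0, 2, 30))
    g2 = (rng.exponential(5, 30), rng.integers(0, 2, 30))
    a = logrank([g1, g2])
    b = logrank([g2, g1])
    assert a.chi2 == pytest.approx(b.chi2, rel=1e-12)


def test_logrank_calibrated_under_equal_hazards(rng):
    rejections = 0
    for _ in range(100):
        t1, t2 = rng.exponential(10, 40), rng.exponential(10, 40)
        res = logrank([(t1, np.ones(40, int)), (t2, np.ones(40, int))])
        rejections += res.p_value < 0.05
    assert rejections <= 12


# ---------------------------------------------------------------------------
# Cox regression


def _breslow_nll(beta, t, e, x):
    order = np.argsort(t)
    t, e, x = t[order], e[order], x[order]
    ll = 0.0
    for i in np.flatnonzero(e == 1):
        risk = t >= t[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return -ll


def test_cox_matches_grid_search_oracle_on_four_subjects():
    t = np.array([2.0, 4.0, 5.0, 7.0])
    e = np.array([1, 1, 0, 1])
    x = np.array([0.0, 1.0, 0.0, 1.0])
    res = cox_fit(t, e, pd.DataFrame({"x": x}), mode="univariate")[0]
    oracle = minimize_scalar(
        lambda b: _breslow_nll(b, t, e, x), bounds=(-10, 10), method="bounded",
        options={"xatol": 1e-10},
    ).x
    assert res.coef == pytest.approx(oracle, abs=1e-4)


def test_cox_recovers_hazard_ratio_two(rng):
    n = 2000
    x = np.r_[np.zeros(n // 2), np.ones(n // 2)]
    lam = 0.02 * np.exp(np.log(2.0) * x)
    t = rng.exponential(1 / lam)
    cens = np.full(n, 60.0)
    obs = np.minimum(t, cens)
    e = (t <= cens).astype(int)
    res = cox_fit(obs, e, pd.DataFrame({"x": x}), mode="univariate")[0]
    assert res.hazard_ratio == pytest.approx(2.0, rel=0.10)
    lo, hi = res.ci95
    assert lo < res.hazard_ratio < hi


def test_cox_null_covariate_ci_covers_one(rng):
    hits = 0
    for _ in range(100):
        t = rng.exponential(10, 120)
        x = rng.normal(size=120)
        res = cox_fit(t, np.ones(120, int), pd.DataFrame({"x": x}), mode="univariate")[0]
        lo, hi = res.ci95
        hits += lo <= 1.0 <= hi
    assert hits >= 88


def test_cox_monotone_likelihood_flagged(rng):
    # the covariate perfectly orders the event times: no finite maximizer
    t = np.arange(1.0, 13.0)
    x = np.arange(12.0)
    res = cox_fit(t, np.ones(12, int), pd.DataFrame({"x": x}), mode="univariate")[0]
    assert not res.converged
    assert res.hazard_ratio is None


def test_cox_covariate_scaling_equivariance(rng):
    t = rng.exponential(10, 300)
    e = rng.integers(0, 2, 300)
    x = rng.normal(size=300)
    a = cox_fit(t, e, pd.DataFrame({"x": x}), mode="univariate")[0]
    b = cox_fit(t, e, pd.DataFrame({"x": 10 * x}), mode="univariate")[0]
    assert b.coef == pytest.approx(a.coef / 10, rel=1e-4)


# ---------------------------------------------------------------------------
# landmark


def test_landmark_identity_and_arithmetic():
    t = np.array([2.0, 5.0, 9.0])
    e = np.array([1, 1, 0])
    t0, e0, keep0 = landmark_filter(t, e, 0.0)
    assert t0.tolist() == t.tolist() and e0.tolist() == e.tolist()
    t3, e3, keep3 = landmark_filter(t, e, 3.0)
    assert t3.tolist() == [2.0, 6.0]
    assert e3.tolist() == [1, 0]
    assert keep3.tolist() == [False, True, True]


def test_landmark_beyond_follow_up_warns():
    with pytest.warns(UserWarning, match="beyond"):
        t, e, _ = landmark_filter([1.0, 2.0], [1, 1], 10.0)
    assert t.size == 0


def test_landmark_km_equals_conditional_survival(rng):
    lam, L = 0.05, 5.0
    t = rng.exponential(1 / lam, 6000)
    tl, el, _ = landmark_filter(t, np.ones(6000, int), L)
    km = km_estimate(tl, el)
    for q in [5.0, 15.0]:
        cond = np.exp(-lam * q)  # memoryless: S(q+L)/S(L)
        assert km.survival_at(q, side="right") == pytest.approx(cond, abs=0.03)


# ---------------------------------------------------------------------------
# tree-group PFS


@pytest.fixture(scope="module")
def grouped_cohort():
    _, clin, truth = generate_cohort(CohortSpec(n_patients=600, seed=23, missingness={}))
    return clin, truth.leaf_labels


def test_six_group_curves_and_df(grouped_cohort):
    clin, labels = grouped_cohort
    curves, test = pfs_by_tree_group(labels, clin, merge="none")
    assert set(curves) == {"HHH", "HHL", "HLH", "HLL", "LH", "LL"}
    assert test.df == 5
    frame = km_frame(curves)
    assert set(frame["group"]) == set(curves)


def test_three_tier_merge_orders_survival(grouped_cohort):
    clin, labels = grouped_cohort
    curves, test = pfs_by_tree_group(labels, clin, merge="paper-three-tier")
    assert set(curves) == {"high", "intermediate", "low"}
    s = {g: c.survival_at(42.0) for g, c in curves.items()}
    assert s["high"] > s["intermediate"] > s["low"]
    assert test.p_value < 0.05
    assert test.df == 2


def test_merge_map_covers_observed_labels(grouped_cohort):
    clin, labels = grouped_cohort
    with pytest.raises(KeyError, match="HHH"):
        pfs_by_tree_group(labels, clin, merge={"LL": "low"})
    assert set(PAPER_THREE_TIER.values()) == {"high", "intermediate", "low"}


def test_single_group_yields_no_test(grouped_cohort):
    clin, labels = grouped_cohort
    only = labels[labels == "LL"]
    curves, test = pfs_by_tree_group(only, clin, merge="none")
    assert list(curves) == ["LL"] and test is None
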