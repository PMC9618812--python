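"""Univariate / multivariate biomarker association and ROC-Youden cutpoints.

The response-prediction workflow rests on a handful of classical tools,
wired together the way clinical biostatistics practice dictates:

* group comparisons gated by Shapiro–Wilk normality (Student t when both
  groups look normal, Mann–Whitney otherwise);
* chi-square / Fisher exact association for categorical factors;
* Spearman rank correlation for paired numeric data;
* backward-selection logistic regression reporting odds ratios;
* empirical ROC curves with the Youden index J = Se + Sp - 1 picking the
  working cutpoint for each miRNA.

Outcome denominators are always built from non-missing labels only.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

from .io_tables import ClinicalTable, ExpressionMatrix

__all__ = [
    "UnivariateResult",
    "RocCurve",
    "LogisticModel",
    "compare_groups",
    "scan_outcomes",
    "pivot_scan",
    "categorical_association",
    "spearman_assoc",
    "backward_logistic",
    "roc_curve",
    "youden_cutpoint",
    "OUTCOME_NAMES",
]

#: The four binary response outcomes scanned against each biomarker.
OUTCOME_NAMES = ("CR", "blood-uMRD", "BM-uMRD", "CR+BM-uMRD")


@dataclasses.dataclass
class UnivariateResult:
    variable: str | None
    outcome: str | None
    test_used: str
    p_value: float
    direction: int = 0
    n_positive: int = 0
    n_negative: int = 0
    degenerate: bool = False
    evaluable: bool = True


@dataclasses.dataclass
class RocCurve:
    """Empirical ROC sweep with its Youden-optimal cutpoint.

    ``thresholds`` are midpoints between consecutive sorted unique values
    plus -inf/+inf sentinels. For the default ``high-positive``
    orientation a patient is called positive when value > threshold
    (equality routes negative); ``low-positive`` calls positive when
    value < threshold.
    """

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    orientation: str
    youden_threshold: float
    youden_j: float
    se_at_youden: float
    sp_at_youden: float

    @property
    def j_values(self) -> np.ndarray:
        return self.sensitivity + self.specificity - 1.0


@dataclasses.dataclass
class LogisticModel:
    """Backward-selected logistic fit: one row per retained variable."""

    summary: pd.DataFrame  # columns: coef, odds_ratio, ci_low, ci_high, p_value
    dropped: list[str]
    separation: bool = False

    @property
    def variables(self) -> list[str]:
        return list(self.summary.index)


# ---------------------------------------------------------------------------
# group comparison


def _all_tied(x: np.ndarray) -> bool:
    return np.unique(x).size == 1


def compare_groups(
    values: Sequence[float],
    labels: Sequence[bool],
    alpha_normality: float = 0.05,
    variable: str | None = None,
    outcome: str | None = None,
) -> UnivariateResult:
    """Compare a numeric variable between two groups, normality-gated.

    Shapiro–Wilk is run per group (when each has >= 3 observations); a
    two-sided Student t is used iff both groups pass at
    ``alpha_normality``, otherwise the Mann–Whitney U test. ``labels``
    marks the positive (favorable-outcome) group; ``direction`` is the
    sign of (median positive - median negative).
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    a, b = v[y], v[~y]
    if a.size == 0 or b.size == 0:
        raise ValueError("compare_groups requires both groups non-empty")
    direction = int(np.sign(np.median(a) - np.median(b)))
    if _all_tied(v):
        return UnivariateResult(
            variable, outcome, "mann-whitney", 1.0, 0, a.size, b.size, degenerate=True
        )
    if a.size >= 3 and b.size >= 3:
        normal = True
        for g in (a, b):
            if _all_tied(g):
                normal = False
                break
            if stats.shapiro(g).pvalue < alpha_normality:
                normal = False
                break
    else:
        normal = False
    if normal:
        p = float(stats.ttest_ind(a, b).pvalue)
        test = "t"
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
        test = "mann-whitney"
    return UnivariateResult(variable, outcome, test, p, direction, a.size, b.size)


# ---------------------------------------------------------------------------
# outcome scans


def outcome_indicator(clinical: ClinicalTable, outcome: str) -> pd.Series:
    """Binary favorable-outcome indicator (NaN where not evaluable).

    ``CR+BM-uMRD`` uses the responder logic of
    :func:`mirpredict.cohort_report.classify_response`: no-CR suffices
    for non-responder even without marrow data, while CR with missing
    marrow data is unclassifiable.
    """
    df = clinical.data
    if outcome == "CR":
        return df["cr"].map({"CR": 1.0, "no-CR": 0.0})
    if outcome == "blood-uMRD":
        return df["blood_mrd"].map({"uMRD": 1.0, "MRD": 0.0})
    if outcome == "BM-uMRD":
        return df["bm_mrd"].map({"uMRD": 1.0, "MRD": 0.0})
    if outcome == "CR+BM-uMRD":
        from .cohort_report import classify_response

        cat, _ = classify_response(clinical)
        return cat.map({"responder": 1.0, "non-responder": 0.0})
    raise ValueError(f"unknown outcome {outcome!r}")


def scan_outcomes(
    expr: ExpressionMatrix,
    clinical: ClinicalTable,
    mirnas: Sequence[str] | None = None,
    alpha_normality: float = 0.05,
) -> list[UnivariateResult]:
    """Univariate scan of each miRNA against each response outcome.

    Patients with a missing label for an outcome are excluded from that
    outcome's denominator but still contribute to the others.
    """
    mirnas = list(mirnas) if mirnas is not None else expr.mirna_ids
    out: list[UnivariateResult] = []
    for outcome in OUTCOME_NAMES:
        ind = outcome_indicator(clinical, outcome)
        for m in mirnas:
            v = expr.values_for(m).reindex(ind.index)
            mask = ind.notna() & v.notna()
            yy = ind[mask].astype(bool).to_numpy()
            vv = v[mask].to_numpy()
            if yy.sum() < 2 or (~yy).sum() < 2:
                out.append(
                    UnivariateResult(m, outcome, "none", np.nan, evaluable=False)
                )
                continue
            out.append(
                compare_groups(vv, yy, alpha_normality, variable=m, outcome=outcome)
            )
    return out


def pivot_scan(results: Sequence[UnivariateResult]) -> pd.DataFrame:
    """Arrange scan results as a miRNA x outcome p-value grid."""
    rows = [
        {"variable": r.variable, "outcome": r.outcome, "p_value": r.p_value}
        for r in results
    ]
    return pd.DataFrame(rows).pivot(
        index="variable", columns="outcome", values="p_value"
    )


def categorical_association(
    factor: Sequence, outcome: Sequence
) -> tuple[float, str]:
    """Chi-square or Fisher exact association between a factor and a binary outcome.

    Fisher's exact test is used for 2x2 tables whenever any expected cell
    count is 5 or less (the usual small-sample guard), chi-square
    otherwise. Returns ``(p_value, test_used)``.
    """
    f = pd.Series(factor).reset_index(drop=True)
    o = pd.Series(outcome).reset_index(drop=True)
    keep = f.notna() & o.notna()
    table = pd.crosstab(f[keep], o[keep]).to_numpy()
    if table.shape[0] < 2 or table.shape[1] < 2:
        return 1.0, "degenerate"
    total = table.sum()
    expected = np.outer(table.sum(1), table.sum(0)) / total
    if table.shape == (2, 2) and (expected <= 5).any():
        return float(stats.fisher_exact(table)[1]), "fisher"
    test = "chi2" if not (expected <= 5).any() else "chi2-small-expected"
    return float(stats.chi2_contingency(table, correction=False)[1]), test


def spearman_assoc(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation on complete pairs; (nan, nan) if a vector is constant."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    keep = ~np.isnan(xv) & ~np.isnan(yv)
    xv, yv = xv[keep], yv[keep]
    if xv.size < 3:
        raise ValueError("spearman_assoc needs at least 3 complete pairs")
    if _all_tied(xv) or _all_tied(yv):
        return float("nan"), float("nan")
    rho, p = stats.spearmanr(xv, yv)
    return float(rho), float(p)


# ---------------------------------------------------------------------------
# multivariate logistic


def backward_logistic(
    outcome: Sequence[bool],
    covariates: pd.DataFrame,
    alpha_stay: float = 0.05,
) -> LogisticModel:
    """Backward-selection logistic regression.

    Starting from all candidate covariates, repeatedly drop the one with
    the largest Wald p-value until every retained covariate has
    p < ``alpha_stay``. Categorical columns are dummy-coded (first level
    as reference, one block per variable dropped or kept together, judged
    by its smallest p). Reports odds ratios with Wald 95% CIs.
    """
    y = pd.Series(outcome).astype(float).reset_index(drop=True)
    X = covariates.reset_index(drop=True).copy()
    keep_rows = y.notna() & X.notna().all(axis=1)
    y, X = y[keep_rows], X[keep_rows]
    if len(y) < 10 * max(X.shape[1], 1):
        warnings.warn(
            f"only {len(y)} complete cases for {X.shape[1]} candidates "
            "(< 10 per candidate)",
            stacklevel=2,
        )
    blocks: dict[str, list[str]] = {}
    design = pd.DataFrame(index=X.index)
    for col in X.columns:
        s = X[col]
        if s.dtype == object or isinstance(s.dtype, pd.CategoricalDtype):
            d = pd.get_dummies(s, prefix=col, drop_first=True, dtype=float)
            blocks[col] = list(d.columns)
            design = pd.concat([design, d], axis=1)
        else:
            blocks[col] = [col]
            design[col] = s.astype(float)

    active = list(blocks)
    separation = False
    fit = None
    while active:
        cols = [c for b in active for c in blocks[b]]
        Xd = sm.add_constant(design[cols], has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            try:
                fit = sm.Logit(y.to_numpy(), Xd.to_numpy()).fit(disp=0, maxiter=200)
            except (PerfectSeparationError, np.linalg.LinAlgError):
                separation = True
                fit = sm.Logit(y.to_numpy(), Xd.to_numpy()).fit(
                    disp=0, method="bfgs", maxiter=500
                )
        pvals = pd.Series(fit.pvalues[1:], index=cols)
        block_p = {b: min(pvals[c] for c in blocks[b]) for b in active}
        worst = max(block_p, key=lambda b: block_p[b])
        if alpha_stay >= 1 or (
            alpha_stay > 0 and max(block_p.values()) < alpha_stay
        ):
            break
        active.remove(worst)
        if alpha_stay <= 0 and not active:
            break

    dropped = [b for b in blocks if b not in active]
    if not active:
        empty = pd.DataFrame(
            columns=["coef", "odds_ratio", "ci_low", "ci_high", "p_value", "separated"]
        )
        return LogisticModel(empty, dropped, separation)

    cols = [c for b in active for c in blocks[b]]
    params = pd.Series(fit.params[1:], index=cols)
    ci = fit.conf_int()[1:]
    pvals = pd.Series(fit.pvalues[1:], index=cols)
    bse = pd.Series(fit.bse[1:], index=cols)
    separated = (np.abs(params) > 15) | (bse > 100) | ~np.isfinite(bse)
    np_err = np.seterr(over="ignore")
    summary = pd.DataFrame(
        {
            "coef": params,
            "odds_ratio": np.where(separated, np.inf * np.sign(params), np.exp(params)),
            "ci_low": np.where(separated, np.nan, np.exp(ci[:, 0])),
            "ci_high": np.where(separated, np.nan, np.exp(ci[:, 1])),
            "p_value": pvals,
            "separated": separated,
        }
    )
    np.seterr(**np_err)
    return LogisticModel(summary, dropped, separation or bool(separated.any()))


# ---------------------------------------------------------------------------
# ROC / Youden


def _sweep(values: np.ndarray, labels: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Thresholds (midpoints +- inf sentinels) and Se/Sp for value > t positive."""
    u = np.unique(values)
    mids = (u[:-1] + u[1:]) / 2.0
    thresholds = np.concatenate(([-np.inf], mids, [np.inf]))
    pos = np.sort(values[labels])
    neg = np.sort(values[~labels])
    # v > t  <=>  index past the right insertion point of t
    se = (pos.size - np.searchsorted(pos, thresholds, side="right")) / pos.size
    sp = np.searchsorted(neg, thresholds, side="right") / neg.size
    return thresholds, se, sp


def roc_curve(
    values: Sequence[float],
    labels: Sequence[bool],
    orientation: str = "high-positive",
) -> RocCurve:
    """Empirical ROC curve with trapezoidal AUC and Youden cutpoint.

    ``orientation="auto"`` keeps high-positive when its AUC >= 0.5 and
    flips to low-positive otherwise. Ties in J are broken toward the
    smallest threshold.
    """
    v = np.asarray(values, dtype=float)
    y = np.asarray(labels, dtype=bool)
    keep = ~np.isnan(v)
    v, y = v[keep], y[keep]
    if y.all() or not y.any():
        raise ValueError("roc_curve needs both classes present")

    def build(orient: str) -> RocCurve:
        vv = v if orient == "high-positive" else -v
        thr, se, sp = _sweep(vv, y)
        if orient == "low-positive":
            # -v > t  <=>  v < -t ; report thresholds on the original scale
            thr, se, sp = -thr[::-1], se[::-1], sp[::-1]
        # fpr is monotone along the threshold sweep; signed area gives AUC
        fpr = 1.0 - sp
        auc = float(abs(np.trapezoid(se, fpr)))
        j = se + sp - 1.0
        best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])
        return RocCurve(
            thresholds=thr,
            sensitivity=se,
            specificity=sp,
            auc=auc,
            orientation=orient,
            youden_threshold=float(thr[best]),
            youden_j=float(j[best]),
            se_at_youden=float(se[best]),
            sp_at_youden=float(sp[best]),
        )

    if orientation in ("high-positive", "low-positive"):
        return build(orientation)
    if orientation == "auto":
        hi = build("high-positive")
        return hi if hi.auc >= 0.5 else build("low-positive")
    raise ValueError(f"unknown orientation {orientation!r}")


def youden_cutpoint(roc: RocCurve) -> tuple[float, float, float]:
    """The J-maximizing ``(threshold, sensitivity, specificity)`` of a curve."""
    return roc.youden_threshold, roc.se_at_youden, roc.sp_at_youden
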