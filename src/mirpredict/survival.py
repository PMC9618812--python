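"""Kaplan–Meier, log-rank, Cox regression and landmark analysis of PFS.

Progression-free survival (PFS) runs from treatment initiation to
progression/relapse, with administrative censoring. The product-limit
estimate and the k-sample log-rank test come from lifelines; Cox models
are fitted by statsmodels' proportional-hazards regression with Breslow
tie handling. A landmark filter restricts to patients still at risk at a
fixed post-baseline time and resets their clock, and
:func:`pfs_by_tree_group` compares the decision-tree groups, optionally
merged into the three prognostic tiers (high = HHH; intermediate = HHL,
HLL, LH; low = HLH, LL).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
import statsmodels.api as sm

from .io_tables import ClinicalTable

__all__ = [
    "KmCurve",
    "LogrankResult",
    "CoxResult",
    "km_estimate",
    "logrank",
    "cox_fit",
    "landmark_filter",
    "pfs_by_tree_group",
    "PAPER_THREE_TIER",
]

#: Merge map from six tree leaves to the three published prognostic tiers.
PAPER_THREE_TIER: dict[str, str] = {
    "HHH": "high",
    "HHL": "intermediate",
    "HLL": "intermediate",
    "LH": "intermediate",
    "HLH": "low",
    "LL": "low",
}


@dataclasses.dataclass
class KmCurve:
    """Product-limit survival estimate with at-risk accounting.

    ``median_time`` is None while the curve stays above 0.5 ("median not
    reached"), never an infinity stand-in.
    """

    times: np.ndarray
    survival: np.ndarray
    n_at_risk: np.ndarray
    n_events: np.ndarray
    n_censored: np.ndarray
    median_time: float | None
    greenwood_se: np.ndarray | None = None
    label: str | None = None

    @property
    def median_reached(self) -> bool:
        return self.median_time is not None

    def survival_at(self, t: float, side: str = "left") -> float:
        """Step value of S at ``t`` (``side="left"`` gives S(t-))."""
        cmp = self.times < t if side == "left" else self.times <= t
        idx = int(cmp.sum()) - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclasses.dataclass
class LogrankResult:
    chi2: float
    df: int
    p_value: float


@dataclasses.dataclass
class CoxResult:
    variable: str
    hazard_ratio: float | None
    ci95: tuple[float, float] | None
    p_value: float | None
    coef: float | None = None
    converged: bool = True
    n: int = 0
    n_events: int = 0


def km_estimate(
    times: Sequence[float], events: Sequence[int], label: str | None = None
) -> KmCurve:
    """Kaplan–Meier product-limit estimate (ties handled events-first)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    if (t < 0).any():
        raise ValueError("times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    tab = kmf.event_table
    times_out = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(tab.index).to_numpy()
    med = kmf.median_survival_time_
    # Greenwood SE from the variance of the log-survival expansion
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    observed = tab["observed"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        incr = observed / (at_risk * (at_risk - observed))
        incr[~np.isfinite(incr)] = 0.0
        se = surv * np.sqrt(np.cumsum(incr))
    return KmCurve(
        times=times_out,
        survival=surv,
        n_at_risk=tab["at_risk"].to_numpy(dtype=int),
        n_events=tab["observed"].to_numpy(dtype=int),
        n_censored=tab["censored"].to_numpy(dtype=int),
        median_time=None if np.isinf(med) else float(med),
        greenwood_se=se,
        label=label,
    )


def logrank(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> LogrankResult:
    """k-sample log-rank test (observed-minus-expected, hypergeometric variance)."""
    if len(groups) < 2:
        raise ValueError("logrank requires at least two groups")
    times, events, labels = [], [], []
    for i, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {i} has no subjects")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, i))
    res = multivariate_logrank_test(
        np.concatenate(times), np.concatenate(labels), np.concatenate(events)
    )
    return LogrankResult(
        chi2=float(res.test_statistic),
        df=len(groups) - 1,
        p_value=float(res.p_value),
    )


def cox_fit(
    times: Sequence[float],
    events: Sequence[int],
    covariates: pd.DataFrame,
    mode: str = "multivariate",
    ties: str = "breslow",
) -> list[CoxResult]:
    """Cox proportional-hazards regression (Breslow ties by default).

    ``mode="univariate"`` fits each covariate alone, one result per
    column (the hazard-ratio-table layout); ``"multivariate"`` fits them
    jointly. Monotone partial likelihoods (e.g. a level with no events)
    are flagged non-convergent with no fabricated hazard ratio.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    X = covariates.reset_index(drop=True).astype(float)
    keep = ~X.isna().any(axis=1) & ~np.isnan(t) & ~np.isnan(e.astype(float))
    t, e, X = t[keep], e[keep], X[keep]

    def fit_block(cols: list[str]) -> list[CoxResult]:
        Xb = X[cols].to_numpy()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.PHReg(t, Xb, status=e, ties=ties)
            try:
                res = model.fit(maxiter=200)
            except Exception:
                return [
                    CoxResult(c, None, None, None, converged=False,
                              n=len(t), n_events=int(e.sum()))
                    for c in cols
                ]
        out = []
        ci = res.conf_int()
        for j, c in enumerate(cols):
            coef = float(res.params[j])
            se_j = float(res.bse[j])
            bad = not np.isfinite(se_j) or abs(coef) > 15 or se_j > 100
            if bad:
                out.append(
                    CoxResult(c, None, None, None, coef=coef, converged=False,
                              n=len(t), n_events=int(e.sum()))
                )
            else:
                out.append(
                    CoxResult(
                        c,
                        float(np.exp(coef)),
                        (float(np.exp(ci[j, 0])), float(np.exp(ci[j, 1]))),
                        float(res.pvalues[j]),
                        coef=coef,
                        n=len(t),
                        n_events=int(e.sum()),
                    )
                )
        return out

    if mode == "univariate":
        results = []
        for c in X.columns:
            results.extend(fit_block([c]))
        return results
    if mode == "multivariate":
        return fit_block(list(X.columns))
    raise ValueError(f"unknown mode {mode!r}")


def landmark_filter(
    times: Sequence[float], events: Sequence[int], landmark: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Restrict to subjects at risk at ``landmark`` and reset their clock.

    Subjects with time < landmark are removed; survivors' times become
    time - landmark. Returns ``(times, events, kept_mask)`` so callers
    can subset aligned covariates. Warns when nobody survives the
    landmark.
    """
    if landmark < 0:
        raise ValueError("landmark must be non-negative")
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    keep = t >= landmark
    if not keep.any():
        warnings.warn(f"landmark {landmark} is beyond every follow-up time", stacklevel=2)
    return t[keep] - landmark, e[keep], keep


def pfs_by_tree_group(
    assignments: pd.Series,
    clinical: ClinicalTable,
    merge: str | Mapping[str, str] = "none",
) -> tuple[dict[str, KmCurve], LogrankResult | None]:
    """Per-group Kaplan–Meier curves and log-rank across tree groups.

    ``assignments`` maps patient id to leaf label (NaN = unclassifiable,
    dropped). ``merge`` is ``"none"``, ``"paper-three-tier"`` (high /
    intermediate / low, per :data:`PAPER_THREE_TIER`), or an explicit
    label->tier map; a label missing from the map raises an error naming
    it. Returns ``(curves by group, log-rank result)``; the test is None
    when fewer than two groups remain.
    """
    labels = assignments.dropna()
    if isinstance(merge, str):
        if merge == "none":
            mapping = None
        elif merge == "paper-three-tier":
            mapping = PAPER_THREE_TIER
        else:
            raise ValueError(f"unknown merge {merge!r}")
    else:
        mapping = dict(merge)
    if mapping is not None:
        unknown = set(labels.unique()) - set(mapping)
        if unknown:
            raise KeyError(
                f"label(s) {sorted(unknown)} missing from the merge map"
            )
        labels = labels.map(mapping)

    df = clinical.data.loc[labels.index]
    curves: dict[str, KmCurve] = {}
    groups = []
    for g in sorted(labels.unique()):
        idx = labels.index[labels == g]
        t = df.loc[idx, "pfs_time"].to_numpy(dtype=float)
        e = df.loc[idx, "pfs_event"].to_numpy(dtype=int)
        curves[g] = km_estimate(t, e, label=str(g))
        groups.append((t, e))
    test = logrank(groups) if len(groups) >= 2 else None
    return curves, test


def km_frame(curves: Mapping[str, KmCurve]) -> pd.DataFrame:
    """Tidy per-group survival table (group, time, survival, at-risk, events)."""
    rows = []
    for g, c in curves.items():
        for t, s, r, d in zip(c.times, c.survival, c.n_at_risk, c.n_events):
            rows.append(
                {"group": g, "time": t, "survival": s, "n_at_risk": r, "n_events": d}
            )
    return pd.DataFrame(rows)
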