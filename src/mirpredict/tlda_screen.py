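"""Discovery-stage qPCR screening: normalization, fold change, testing, filtering.

A TaqMan low-density array screen compares two small patient groups
(responders with marrow-undetectable residual disease versus
non-responders) over a few hundred miRNA assays. The analysis steps are:

1. per-sample Ct normalization (global-mean by default, or a reference
   assay), giving dCt with relative expression 2^-dCt;
2. per-assay group comparison on dCt (two-sample t by default) and the
   geometric-mean fold change, FC = 2^(mean dCt_other - mean dCt_responder);
3. volcano-style categorization: "up"/"down" when |fold change| clears a
   2.5-fold threshold at p < alpha, in the responder-over-other direction;
4. a detection-limit filter keeping assays whose mean raw Ct stays
   strictly below a cycle limit (30 by default) in both groups.

Results come back as a tidy DataFrame, one row per assay; the detection
filter marks failures rather than deleting them.
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io_tables import CtMatrix

__all__ = [
    "normalize_ct",
    "fold_change",
    "differential_screen",
    "detection_filter",
    "significant_detected",
    "SCREEN_COLUMNS",
]

SCREEN_COLUMNS = [
    "assay",
    "fold_change",
    "log2_fc",
    "p_value",
    "mean_ct_g1",
    "mean_ct_g2",
    "passes_detection",
    "category",
    "degenerate",
]


def normalize_ct(
    ct: CtMatrix, method: str = "global-mean", reference: str | None = None
) -> pd.DataFrame:
    """Per-sample dCt normalization of a raw Ct grid.

    ``global-mean`` subtracts each sample's mean Ct over its detected
    assays (>= 2 required); ``reference-assay`` subtracts the named
    assay's Ct, yielding missing dCt (with a warning) for samples where
    the reference is undetected. Undetected target wells keep their
    ceiling Ct, so their dCt is a floor on expression.
    """
    detected = ~ct.undetected
    if method == "global-mean":
        n_det = detected.sum(axis=1)
        if (n_det < 2).any():
            bad = list(n_det.index[n_det < 2])
            raise ValueError(f"global-mean needs >=2 detected assays; offending samples: {bad}")
        normalizer = ct.ct.where(detected).mean(axis=1)
    elif method == "reference-assay":
        if reference is None or reference not in ct.ct.columns:
            raise ValueError(f"reference assay {reference!r} not in matrix")
        normalizer = ct.ct[reference].copy()
        ref_undet = ct.undetected[reference]
        if ref_undet.any():
            warnings.warn(
                f"reference assay undetected in sample(s) "
                f"{list(ref_undet.index[ref_undet])}; dCt set missing",
                stacklevel=2,
            )
            normalizer[ref_undet] = np.nan
    else:
        raise ValueError(f"unknown normalization method {method!r}")
    return ct.ct.sub(normalizer, axis=0)


def fold_change(
    expr_a: Sequence[float], expr_b: Sequence[float]
) -> float:
    """Ratio of geometric means, group a over group b.

    With relative-expression inputs (2^-dCt) this equals
    2^(mean dCt_b - mean dCt_a). Computed in the log domain for
    stability; both groups must be non-empty and strictly positive.
    """
    a = np.asarray(expr_a, dtype=float)
    b = np.asarray(expr_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("fold_change requires non-empty groups")
    if (a <= 0).any() or (b <= 0).any():
        raise ValueError("fold_change requires strictly positive values")
    return float(np.exp(np.mean(np.log(a)) - np.mean(np.log(b))))


def _categorize(fc: np.ndarray, p: np.ndarray, alpha: float, fc_threshold: float) -> np.ndarray:
    cat = np.full(fc.shape, "not-significant", dtype=object)
    sig = p < alpha
    cat[sig & (fc >= fc_threshold)] = "up"
    cat[sig & (fc <= 1.0 / fc_threshold)] = "down"
    return cat


def differential_screen(
    ct: CtMatrix,
    responder_label: str,
    alpha: float = 0.05,
    fc_threshold: float = 2.5,
    test: str = "t",
    normalization: str = "global-mean",
    reference: str | None = None,
    ct_limit: float = 30.0,
) -> pd.DataFrame:
    """Per-assay differential screen between the two arms of a Ct matrix.

    ``responder_label`` names the favorable-outcome arm; fold changes are
    reported responder over other, so values above 1 mean higher
    expression in responders. ``test`` is ``"t"`` (default), ``"mann-whitney"``,
    or ``"auto"`` (Shapiro–Wilk gate per assay, as in
    :func:`mirpredict.biomarker_stats.compare_groups`).

    Returns one row per assay with fold change, p-value, per-group mean
    raw Ct, the detection flag (strict mean-Ct < ``ct_limit`` in both
    groups) and the volcano category.
    """
    labels = ct.group
    arms = list(pd.unique(labels))
    if responder_label not in arms:
        raise ValueError(f"responder label {responder_label!r} not among arms {arms}")
    other_label = [a for a in arms if a != responder_label][0]
    # censored ("Undetermined") wells carry no expression value: they are
    # excluded from dCt statistics but still weigh on the raw-Ct detection
    # filter at the cycle ceiling
    dct = normalize_ct(ct, method=normalization, reference=reference)
    dct = dct.mask(ct.undetected)
    resp = dct[labels == responder_label].to_numpy()
    other = dct[labels == other_label].to_numpy()
    if resp.shape[0] < 2 or other.shape[0] < 2:
        raise ValueError("each arm needs at least 2 samples")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        log2fc = np.nanmean(other, axis=0) - np.nanmean(resp, axis=0)
    fc = 2.0**log2fc  # lower dCt = higher expression

    n_resp = (~np.isnan(resp)).sum(axis=0)
    n_other = (~np.isnan(other)).sum(axis=0)
    degenerate = (n_resp < 2) | (n_other < 2)
    raw = ct.ct.to_numpy()
    for j in np.flatnonzero(~degenerate):
        col = np.concatenate([resp[:, j], other[:, j]])
        # raw-constant assays carry no signal: any dCt spread is pure
        # normalizer variation, so the comparison is meaningless
        if (
            np.unique(col[~np.isnan(col)]).size == 1
            or np.unique(raw[:, j]).size == 1
        ):
            degenerate[j] = True
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if test == "t":
            p = stats.ttest_ind(resp, other, axis=0, nan_policy="omit").pvalue
        elif test == "mann-whitney":
            p = stats.mannwhitneyu(
                resp, other, axis=0, alternative="two-sided", nan_policy="omit"
            ).pvalue
        elif test == "auto":
            from .biomarker_stats import compare_groups

            p = np.empty(resp.shape[1])
            for j in range(resp.shape[1]):
                vals = np.concatenate([resp[:, j], other[:, j]])
                lab = np.r_[np.ones(resp.shape[0], bool), np.zeros(other.shape[0], bool)]
                if degenerate[j]:
                    p[j] = 1.0
                    continue
                keep = ~np.isnan(vals)
                p[j] = compare_groups(vals[keep], lab[keep]).p_value
        else:
            raise ValueError(f"unknown test {test!r}")
    p = np.where(degenerate, 1.0, np.nan_to_num(p, nan=1.0))

    raw_resp = ct.ct[labels == responder_label].mean(axis=0).to_numpy()
    raw_other = ct.ct[labels == other_label].mean(axis=0).to_numpy()
    passes = (raw_resp < ct_limit) & (raw_other < ct_limit)

    return pd.DataFrame(
        {
            "assay": list(ct.ct.columns),
            "fold_change": fc,
            "log2_fc": log2fc,
            "p_value": p,
            "mean_ct_g1": raw_resp,
            "mean_ct_g2": raw_other,
            "passes_detection": passes,
            "category": _categorize(np.nan_to_num(fc, nan=1.0), p, alpha, fc_threshold),
            "degenerate": degenerate,
        }
    )


def detection_filter(results: pd.DataFrame, ct_limit: float = 30.0) -> pd.DataFrame:
    """Re-mark the detection flag at a new cycle limit (strict, both groups).

    Returns a copy with ``passes_detection`` updated; failing assays are
    marked, never dropped.
    """
    out = results.copy()
    out["passes_detection"] = (out["mean_ct_g1"] < ct_limit) & (
        out["mean_ct_g2"] < ct_limit
    )
    return out


def significant_detected(results: pd.DataFrame) -> pd.DataFrame:
    """Convenience view: significant (up/down) assays passing detection."""
    keep = results["passes_detection"] & results["category"].isin(["up", "down"])
    return results[keep].reset_index(drop=True)
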