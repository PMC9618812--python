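"""Synthetic B-CLL cohorts and screening matrices with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage (screening, univariate scans, tree building,
survival) can be exercised and calibrated without patient-level data:

* log2 miRNA expression is normal per miRNA (log-normal expression);
* a planted binary decision tree, defined at stated quantiles of each
  split miRNA's marginal so thresholds are exactly recoverable, assigns
  each patient a true leaf from their own expression draw;
* the responder outcome (complete remission with bone-marrow
  undetectable MRD) is Bernoulli with a per-leaf probability; CR, blood-
  and marrow-MRD labels are derived consistently, never producing a
  patient with detectable blood MRD but undetectable marrow MRD;
* progression times are exponential with a per-leaf hazard,
  administratively censored at a fixed follow-up horizon;
* structured missingness gives each outcome its own evaluable
  denominator.

One RNG stream is consumed in a documented order (expression -> outcomes
-> survival -> missingness -> covariates), so a spec plus seed fully
determines the cohort.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.stats import norm

from .io_tables import ClinicalTable, CtMatrix, ExpressionMatrix

__all__ = [
    "PlantedLeaf",
    "PlantedSplit",
    "CohortSpec",
    "ScreenSpec",
    "TruthRecord",
    "default_planted_tree",
    "default_expression_model",
    "generate_cohort",
    "generate_screen",
    "FOLLOW_UP_MONTHS",
    "LEAF_PROBABILITIES",
    "LEAF_PFS_AT_FOLLOW_UP",
]

#: Administrative censoring horizon (months), matching the reported
#: median follow-up of the modeled cohort.
FOLLOW_UP_MONTHS = 42.4

#: Per-leaf responder probabilities. HHH and LL are the two published
#: anchors; the four middle leaves are figure-only in the source study
#: and carry artifact default values.
LEAF_PROBABILITIES: dict[str, float] = {
    "HHH": 0.72,
    "HHL": 0.35,
    "HLH": 0.30,
    "HLL": 0.15,
    "LH": 0.20,
    "LL": 0.04,
}

#: Progression-free survival at the follow-up horizon per leaf group,
#: used to derive per-leaf exponential hazards (HHH had no relapses; 0.99
#: keeps its hazard strictly positive).
LEAF_PFS_AT_FOLLOW_UP: dict[str, float] = {
    "HHH": 0.99,
    "HHL": 0.72,
    "HLH": 0.71,
    "HLL": 0.90,
    "LH": 0.87,
    "LL": 0.52,
}


@dataclasses.dataclass
class PlantedLeaf:
    label: str
    probability: float
    hazard: float

    def validate(self) -> None:
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"leaf {self.label}: probability outside [0,1]")
        if not self.hazard > 0:
            raise ValueError(f"leaf {self.label}: hazard must be > 0")


@dataclasses.dataclass
class PlantedSplit:
    """Internal planted node: split ``variable`` at the ``quantile`` of its marginal."""

    variable: str
    quantile: float
    high: "PlantedSplit | PlantedLeaf"
    low: "PlantedSplit | PlantedLeaf"
    threshold: float | None = None  # realized expression threshold (filled in)

    def validate(self) -> None:
        if not 0.0 < self.quantile < 1.0:
            raise ValueError(f"split {self.variable}: quantile must be in (0,1)")
        for child in (self.high, self.low):
            child.validate()

    def leaves(self) -> list[PlantedLeaf]:
        out = []
        for child in (self.high, self.low):
            out.extend(child.leaves() if isinstance(child, PlantedSplit) else [child])
        return out

    def split_variables(self) -> list[str]:
        out = [self.variable]
        for child in (self.high, self.low):
            if isinstance(child, PlantedSplit):
                out.extend(child.split_variables())
        return out

    def to_dict(self) -> dict:
        def conv(node):
            if isinstance(node, PlantedLeaf):
                return dataclasses.asdict(node)
            return {
                "variable": node.variable,
                "quantile": node.quantile,
                "threshold": node.threshold,
                "high": conv(node.high),
                "low": conv(node.low),
            }

        return conv(self)


def _hazard(pfs: float, horizon: float = FOLLOW_UP_MONTHS) -> float:
    return -math.log(pfs) / horizon


def default_planted_tree() -> PlantedSplit:
    """The six-leaf planted tree mirroring the published topology.

    Root splits on miR-125b; the high branch on miR-15b then miR-181c /
    miR-412; the low branch on miR-193b. Split quantiles reproduce the
    published high/low group sizes on a 123-patient cohort (e.g. 67/123
    miR-125b-high).
    """

    def leaf(label: str) -> PlantedLeaf:
        return PlantedLeaf(
            label, LEAF_PROBABILITIES[label], _hazard(LEAF_PFS_AT_FOLLOW_UP[label])
        )

    return PlantedSplit(
        "miR-125b",
        1 - 67 / 123,
        high=PlantedSplit(
            "miR-15b",
            1 - 58 / 123,
            high=PlantedSplit("miR-181c", 1 - 29 / 123, leaf("HHH"), leaf("HHL")),
            low=PlantedSplit("miR-412", 1 - 84 / 123, leaf("HLH"), leaf("HLL")),
        ),
        low=PlantedSplit("miR-193b", 1 - 40 / 123, leaf("LH"), leaf("LL")),
    )


#: The 11-miRNA validation panel carried by the default expression model.
PANEL_MIRNAS = (
    "miR-15b",
    "miR-125b",
    "miR-155",
    "miR-181a",
    "miR-181c",
    "miR-193b",
    "miR-324-3p",
    "miR-412",
    "miR-532-3p",
    "miR-642",
    "miR-652",
)

_PUBLISHED_THRESHOLDS = {
    "miR-15b": 0.1710,
    "miR-125b": 0.0005,
    "miR-181c": 0.0019,
    "miR-193b": 0.0113,
    "miR-412": 0.0003,
}

_OTHER_MEDIANS = {
    "miR-155": 0.01,
    "miR-181a": 0.005,
    "miR-324-3p": 0.02,
    "miR-532-3p": 0.008,
    "miR-642": 0.003,
    "miR-652": 0.015,
}

_DEFAULT_LOG2_SD = 1.5


def default_expression_model(
    tree: PlantedSplit | None = None, log2_sd: float = _DEFAULT_LOG2_SD
) -> dict[str, tuple[float, float]]:
    """Per-miRNA (log2 location, log2 scale) for the 11-miRNA panel.

    Split miRNAs are located so their planted split quantile falls exactly
    on the published working threshold; the remaining panel members take
    plausible relative-expression medians.
    """
    tree = tree or default_planted_tree()
    quantiles = {}

    def walk(node):
        if isinstance(node, PlantedSplit):
            quantiles[node.variable] = node.quantile
            walk(node.high)
            walk(node.low)

    walk(tree)
    model: dict[str, tuple[float, float]] = {}
    for m in PANEL_MIRNAS:
        if m in _PUBLISHED_THRESHOLDS and m in quantiles:
            z = norm.ppf(quantiles[m])
            mu = math.log2(_PUBLISHED_THRESHOLDS[m]) - log2_sd * z
        else:
            mu = math.log2(_OTHER_MEDIANS.get(m, 0.01))
        model[m] = (mu, log2_sd)
    return model


@dataclasses.dataclass
class CohortSpec:
    """Everything needed to draw one synthetic cohort.

    ``nonresponder_mix`` gives, conditional on not being a responder, the
    probabilities of (CR with detectable marrow MRD), (no-CR with
    undetectable marrow MRD) and (no-CR with detectable marrow MRD);
    ``blood_umrd_given_bm_mrd`` is the chance of blood uMRD when marrow
    MRD is detectable (marrow uMRD always implies blood uMRD, so a
    blood-detectable / marrow-undetectable patient can never occur).
    """

    n_patients: int = 123
    tree: PlantedSplit = dataclasses.field(default_factory=default_planted_tree)
    expr_model: dict[str, tuple[float, float]] | None = None
    expr_shifts: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=dict
    )  # leaf label -> {mirna: log2 shift}, applied after leaf assignment
    path_separation_log2: float = 0.0  # push each patient's path variables
    # away from their planted cutpoints by this many log2 units (never
    # across), sharpening the leaf-group expression signature
    nonresponder_mix: tuple[float, float, float] = (0.45, 0.15, 0.40)
    blood_umrd_given_bm_mrd: float = 0.55
    censor_time: float = FOLLOW_UP_MONTHS
    missingness: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"cr": 0.04, "blood_mrd": 0.12, "bm_mrd": 0.23}
    )
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")
        self.tree.validate()
        if abs(sum(self.nonresponder_mix) - 1.0) > 1e-9:
            raise ValueError("nonresponder_mix must sum to 1")
        for k, p in self.missingness.items():
            if not 0.0 <= p < 1.0:
                raise ValueError(f"missingness[{k!r}] must be in [0,1)")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be positive")
        n_leaves = len(self.tree.leaves())
        if self.n_patients < 5 * n_leaves:
            warnings.warn(
                f"n_patients={self.n_patients} is small for {n_leaves} leaves; "
                "leaf occupancy may be infeasible for tree building",
                stacklevel=2,
            )


@dataclasses.dataclass
class TruthRecord:
    """Planted ground truth accompanying a generated dataset."""

    seed: int
    leaf_labels: pd.Series | None = None
    responder: pd.Series | None = None
    event_times: pd.Series | None = None
    tree: dict | None = None
    de_set: dict[str, float] | None = None
    ct_locations: dict[str, float] | None = None

    def to_json(self) -> str:
        payload = {"seed": self.seed}
        for key in ("leaf_labels", "responder", "event_times"):
            s = getattr(self, key)
            if s is not None:
                payload[key] = {str(k): (bool(v) if key == "responder" else v)
                                for k, v in s.items()}
        if self.tree is not None:
            payload["tree"] = self.tree
        if self.de_set is not None:
            payload["de_set"] = self.de_set
        if self.ct_locations is not None:
            payload["ct_locations"] = self.ct_locations
        return json.dumps(payload, indent=2, sort_keys=True)


def _realize_thresholds(tree: PlantedSplit, model: Mapping[str, tuple[float, float]]) -> None:
    mu, sd = model[tree.variable]
    tree.threshold = 2.0 ** (mu + sd * norm.ppf(tree.quantile))
    for child in (tree.high, tree.low):
        if isinstance(child, PlantedSplit):
            _realize_thresholds(child, model)


def _apply_path_separation(
    tree: PlantedSplit, expr: pd.DataFrame, s: float, mask: pd.Series | None = None
) -> None:
    """Shift each patient's path variables away from the planted cutpoints.

    At every planted split, patients on the high side have that variable
    multiplied by 2^s and the low side by 2^-s, opening a 2s-wide log2
    gap around the threshold; leaf membership is untouched because no
    value ever crosses its cutpoint.
    """
    if mask is None:
        mask = pd.Series(True, index=expr.index)
    hi = (expr[tree.variable] > tree.threshold) & mask
    lo = ~(expr[tree.variable] > tree.threshold) & mask
    expr.loc[hi, tree.variable] *= 2.0**s
    expr.loc[lo, tree.variable] *= 2.0**-s
    if isinstance(tree.high, PlantedSplit):
        _apply_path_separation(tree.high, expr, s, hi)
    if isinstance(tree.low, PlantedSplit):
        _apply_path_separation(tree.low, expr, s, lo)


def _assign_leaf(tree: PlantedSplit, row: Mapping[str, float]) -> PlantedLeaf:
    node: PlantedSplit | PlantedLeaf = tree
    while isinstance(node, PlantedSplit):
        node = node.high if row[node.variable] > node.threshold else node.low
    return node


def generate_cohort(
    spec: CohortSpec,
) -> tuple[ExpressionMatrix, ClinicalTable, TruthRecord]:
    """Draw one synthetic cohort under ``spec`` (see module docstring)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients
    model = spec.expr_model or default_expression_model(spec.tree)
    tree = spec.tree
    _realize_thresholds(tree, model)
    patients = [f"P{i + 1:04d}" for i in range(n)]

    # 1. expression (per-miRNA draws in panel order)
    expr = pd.DataFrame(index=patients, columns=list(model), dtype=float)
    for m, (mu, sd) in model.items():
        expr[m] = 2.0 ** rng.normal(mu, sd, size=n)

    leaves = [_assign_leaf(tree, expr.loc[p]) for p in patients]
    leaf_labels = pd.Series([lf.label for lf in leaves], index=patients, name="leaf")
    if spec.path_separation_log2 > 0:
        _apply_path_separation(tree, expr, spec.path_separation_log2)
    for label, shifts in spec.expr_shifts.items():
        mask = leaf_labels == label
        for m, shift in shifts.items():
            expr.loc[mask, m] *= 2.0**shift

    # 2. outcomes
    u_resp = rng.random(n)
    u_state = rng.random(n)
    u_blood = rng.random(n)
    responder = u_resp < np.array([lf.probability for lf in leaves])
    cr = np.where(responder, "CR", "no-CR").astype(object)
    bm = np.where(responder, "uMRD", "MRD").astype(object)
    p_cr_det, p_nocr_umrd, _ = spec.nonresponder_mix
    nr = ~responder
    cr[nr & (u_state < p_cr_det)] = "CR"
    bm[nr & (u_state < p_cr_det)] = "MRD"
    mid = nr & (u_state >= p_cr_det) & (u_state < p_cr_det + p_nocr_umrd)
    cr[mid] = "no-CR"
    bm[mid] = "uMRD"
    blood = np.where(
        bm == "uMRD",
        "uMRD",
        np.where(u_blood < spec.blood_umrd_given_bm_mrd, "uMRD", "MRD"),
    ).astype(object)

    # 3. survival
    hazards = np.array([lf.hazard for lf in leaves])
    event_times = rng.exponential(1.0 / hazards)
    pfs_time = np.minimum(event_times, spec.censor_time)
    pfs_event = (event_times <= spec.censor_time).astype(int)

    # 4. missingness (independent per outcome)
    clin = pd.DataFrame(
        {
            "cr": cr,
            "blood_mrd": blood,
            "bm_mrd": bm,
            "pfs_time": pfs_time,
            "pfs_event": pfs_event,
        },
        index=patients,
    )
    for col in ("cr", "blood_mrd", "bm_mrd"):
        p_miss = spec.missingness.get(col, 0.0)
        mask = rng.random(n) < p_miss
        clin.loc[mask, col] = np.nan

    # 5. baseline covariates (independent of outcome)
    clin["age"] = np.round(rng.normal(57.0, 6.0, n), 1)
    clin["sex"] = np.where(rng.random(n) < 0.268, "F", "M")
    clin["binet"] = np.where(rng.random(n) < 0.74, "AB", "C")
    clin["ecog"] = (rng.random(n) >= 0.70).astype(int)
    for col, p_yes, p_miss in (
        ("ighv", 0.63, 0.03),
        ("del13q", 0.5625, 0.22),
        ("del11q", 0.20, 0.02),
        ("tri12", 0.11, 0.33),
    ):
        levels = ("unmutated", "mutated") if col == "ighv" else ("yes", "no")
        vals = np.where(rng.random(n) < p_yes, levels[0], levels[1]).astype(object)
        vals[rng.random(n) < p_miss] = np.nan
        clin[col] = vals
    clin["lymphocytes"] = np.round(rng.lognormal(math.log(71.0), 0.72, n), 1)
    clin["b2m"] = np.round(rng.lognormal(math.log(3.05), 0.38, n), 2)
    clin["arm"] = np.where(rng.random(n) < 0.504, "FCR", "Dense-FCR")
    clin["cycles"] = rng.choice(
        [2, 3, 4, 5, 6], size=n, p=[0.05, 0.05, 0.1, 0.1, 0.7]
    )

    truth = TruthRecord(
        seed=spec.seed,
        leaf_labels=leaf_labels,
        responder=pd.Series(responder, index=patients, name="responder"),
        event_times=pd.Series(event_times, index=patients, name="event_time"),
        tree=tree.to_dict(),
    )
    return ExpressionMatrix(expr), ClinicalTable(clin), truth


def published_count_cohort() -> ClinicalTable:
    """A 123-patient clinical table matching the published outcome counts.

    Synthetic reconstruction: individual patients are invented, but the
    joint outcome/missingness structure reproduces every printed
    denominator — 65 CR and 53 no-CR of 118 evaluable (5 missing), 69/108
    blood uMRD, 40/95 marrow uMRD, and 27 responders of 107 classifiable
    (the 16 unclassifiable being 5 without CR status plus 11 CR patients
    without marrow data). Marrow uMRD always implies blood uMRD.
    """
    blocks = [
        # (count, cr, bm_mrd, blood_mrd)
        (27, "CR", "uMRD", "uMRD"),       # responders
        (8, "CR", None, "uMRD"),          # CR, marrow missing -> unclassifiable
        (3, "CR", None, "MRD"),
        (12, "CR", "MRD", "uMRD"),        # CR with detectable marrow MRD
        (15, "CR", "MRD", "MRD"),
        (13, "no-CR", "uMRD", "uMRD"),    # marrow uMRD forces blood uMRD
        (6, "no-CR", "MRD", "uMRD"),
        (12, "no-CR", "MRD", "MRD"),
        (10, "no-CR", "MRD", None),
        (3, "no-CR", None, "uMRD"),
        (9, "no-CR", None, "MRD"),
        (5, None, None, None),            # no CR assessment
    ]
    rows = []
    for count, cr, bm, blood in blocks:
        for _ in range(count):
            rows.append(
                {
                    "cr": cr,
                    "bm_mrd": bm,
                    "blood_mrd": blood,
                    "pfs_time": FOLLOW_UP_MONTHS,
                    "pfs_event": 0,
                    "arm": "FCR" if len(rows) % 2 == 0 else "Dense-FCR",
                }
            )
    df = pd.DataFrame(rows, index=[f"P{i + 1:04d}" for i in range(len(rows))])
    return ClinicalTable(df)


# ---------------------------------------------------------------------------
# screening matrices


@dataclasses.dataclass
class ScreenSpec:
    """Design of a synthetic two-arm screening card.

    ``de_set`` plants log2 fold changes (responder over non-responder):
    a positive value lowers the responder arm's Ct by that many cycles.
    ``ct_location`` fixes per-assay mean Ct; when None, locations are
    drawn uniformly on [22, 33] from the seeded stream.
    """

    n_per_group: int = 8
    n_assays: int = 384
    de_set: Mapping[str, float] = dataclasses.field(default_factory=dict)
    ct_location: Mapping[str, float] | None = None
    ct_scale: float = 1.0
    undetected_fraction: float = 0.02
    max_cycles: int = 40
    seed: int = 0

    def validate(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        if self.n_assays < 1:
            raise ValueError("n_assays must be positive")
        for a, fc in self.de_set.items():
            if not np.isfinite(fc):
                raise ValueError(f"planted fold change for {a!r} must be finite")
        if not 0.0 <= self.undetected_fraction < 1.0:
            raise ValueError("undetected_fraction must be in [0,1)")
        if self.ct_scale < 0:
            raise ValueError("ct_scale must be non-negative")


def screen_assay_ids(n_assays: int) -> list[str]:
    return [f"assay-{i + 1:03d}" for i in range(n_assays)]


def generate_screen(spec: ScreenSpec) -> tuple[CtMatrix, TruthRecord]:
    """Draw one synthetic screening Ct matrix under ``spec``.

    Samples are labelled ``responder`` / ``non-responder``; planted
    assays in ``de_set`` shift the responder arm's Ct by -log2FC cycles
    (lower Ct meaning higher expression). Wells drawn undetected, or
    landing above the cycle ceiling, are stored at ``max_cycles`` and
    flagged.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    assays = screen_assay_ids(spec.n_assays)
    unknown = set(spec.de_set) - set(assays)
    if unknown:
        raise ValueError(f"de_set names unknown assays: {sorted(unknown)}")
    if spec.ct_location is None:
        loc = pd.Series(rng.uniform(22.0, 33.0, spec.n_assays), index=assays)
    else:
        loc = pd.Series({a: spec.ct_location[a] for a in assays}, dtype=float)
    m = spec.n_per_group
    samples = [f"R{i + 1:02d}" for i in range(m)] + [f"N{i + 1:02d}" for i in range(m)]
    group = pd.Series(["responder"] * m + ["non-responder"] * m, index=samples)

    ct = loc.to_numpy()[None, :] + rng.normal(0.0, spec.ct_scale, (2 * m, spec.n_assays))
    shift = np.zeros(spec.n_assays)
    for a, log2fc in spec.de_set.items():
        shift[assays.index(a)] = log2fc
    ct[:m, :] -= shift[None, :]

    undet = rng.random((2 * m, spec.n_assays)) < spec.undetected_fraction
    undet |= ct > spec.max_cycles
    ct = np.where(undet, float(spec.max_cycles), ct)
    ct = np.clip(ct, 1e-6, spec.max_cycles)

    matrix = CtMatrix(
        ct=pd.DataFrame(ct, index=samples, columns=assays),
        group=group,
        undetected=pd.DataFrame(undet, index=samples, columns=assays),
        max_cycles=spec.max_cycles,
    )
    truth = TruthRecord(
        seed=spec.seed,
        de_set=dict(spec.de_set),
        ct_locations={a: float(v) for a, v in loc.items()},
    )
    return matrix, truth
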