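"""Recursive Youden-threshold decision tree over miRNA expression.

The tree predicts the probability of complete remission with bone-marrow
undetectable minimal residual disease from pre-treatment blood miRNA
levels. Construction follows the clinical recipe this package models:

* the root variable is fixed by the analyst (miR-125b in the published
  model, chosen because it alone predicted blood uMRD) or selected as
  the overall most significant candidate (``root="auto"``);
* every split threshold is node-local: the Youden-optimal cutpoint of an
  ROC curve computed on the patients at that node;
* at each child node, every not-yet-used candidate is compared between
  responders and others (Shapiro–Wilk-gated t / Mann–Whitney); the most
  significant candidate splits the node if its p-value clears ``alpha``
  and both children keep at least ``min_leaf`` patients, otherwise the
  node becomes a leaf carrying its empirical responder probability;
* "high" means strictly greater than the threshold; equality routes low.

Leaves are labelled by the H/L letters along their path (HHH ... LL).
The published five-miRNA tree is available as a fixture via
:func:`published_tree`.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .biomarker_stats import compare_groups, roc_curve
from .io_tables import ExpressionMatrix

__all__ = [
    "Leaf",
    "Split",
    "DecisionTree",
    "TreeConfig",
    "Unclassifiable",
    "build_tree",
    "classify",
    "published_tree",
    "assign_groups",
    "PUBLISHED_ROC_PANEL",
]


@dataclasses.dataclass
class Leaf:
    n: int | None
    responders: int | None
    probability: float
    label: str
    verified: bool = True  # False for fixture leaves whose probability is a placeholder


@dataclasses.dataclass
class Split:
    variable: str
    threshold: float
    n: int | None
    high: "Split | Leaf"
    low: "Split | Leaf"
    p_value: float | None = None


@dataclasses.dataclass
class Unclassifiable:
    """Explicit marker for a patient missing a value on their path."""

    missing_variable: str
    path: list[tuple[str, float, str]]


@dataclasses.dataclass
class DecisionTree:
    root: Split | Leaf

    # -- inspection ---------------------------------------------------------
    def leaves(self) -> list[Leaf]:
        out: list[Leaf] = []

        def walk(node):
            if isinstance(node, Leaf):
                out.append(node)
            else:
                walk(node.high)
                walk(node.low)

        walk(self.root)
        return out

    def internal_nodes(self) -> list[Split]:
        out: list[Split] = []

        def walk(node):
            if isinstance(node, Split):
                out.append(node)
                walk(node.high)
                walk(node.low)

        walk(self.root)
        return out

    def node_at(self, path: str) -> "Split | Leaf":
        """Node reached by a string of H/L letters from the root."""
        node: Split | Leaf = self.root
        for letter in path:
            if not isinstance(node, Split):
                raise KeyError(f"path {path!r} descends past a leaf")
            node = node.high if letter == "H" else node.low
        return node

    def check_invariants(self) -> None:
        """Count conservation at every split and label uniqueness."""

        def walk(node) -> tuple[int | None, int | None]:
            if isinstance(node, Leaf):
                return node.n, node.responders
            nh, rh = walk(node.high)
            nl, rl = walk(node.low)
            if None not in (nh, nl, node.n) and nh + nl != node.n:
                raise AssertionError(
                    f"count conservation violated at split {node.variable}"
                )
            r = rh + rl if None not in (rh, rl) else None
            return node.n, r

        walk(self.root)
        labels = [lf.label for lf in self.leaves()]
        if len(labels) != len(set(labels)):
            raise AssertionError("leaf labels are not unique")

    # -- (de)serialization --------------------------------------------------
    def to_dict(self) -> dict:
        def conv(node):
            if isinstance(node, Leaf):
                return {"kind": "leaf", **dataclasses.asdict(node)}
            return {
                "kind": "split",
                "variable": node.variable,
                "threshold": node.threshold,
                "n": node.n,
                "p_value": node.p_value,
                "high": conv(node.high),
                "low": conv(node.low),
            }

        return conv(self.root)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "DecisionTree":
        def conv(node: dict):
            if node["kind"] == "leaf":
                return Leaf(
                    node["n"],
                    node["responders"],
                    node["probability"],
                    node["label"],
                    node.get("verified", True),
                )
            return Split(
                node["variable"],
                node["threshold"],
                node["n"],
                conv(node["high"]),
                conv(node["low"]),
                node.get("p_value"),
            )

        return cls(conv(d))

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "DecisionTree":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text_or_path).read_text()
        return cls.from_dict(json.loads(text))

    def to_dot(self) -> str:
        """Graphviz DOT rendering (high child on the left, red; low green)."""
        lines = ["digraph tree {", "  node [shape=box];"]
        counter = [0]

        def walk(node) -> int:
            nid = counter[0]
            counter[0] += 1
            if isinstance(node, Leaf):
                lines.append(
                    f'  n{nid} [label="{node.label}\\np={node.probability:.2f}'
                    f'\\nn={node.n}"];'
                )
            else:
                lines.append(
                    f'  n{nid} [label="{node.variable}\\n> {node.threshold:.4g}"];'
                )
                hid = walk(node.high)
                lid = walk(node.low)
                lines.append(f'  n{nid} -> n{hid} [label="H", color=red];')
                lines.append(f'  n{nid} -> n{lid} [label="L", color=green];')
            return nid

        walk(self.root)
        lines.append("}")
        return "\n".join(lines)


@dataclasses.dataclass
class TreeConfig:
    alpha: float = 0.05
    min_leaf: int = 5
    max_depth: int = 4
    reuse_variables: bool = False
    alpha_normality: float = 0.05


def _make_leaf(outcome: np.ndarray, label: str) -> Leaf:
    n = int(outcome.size)
    r = int(outcome.sum())
    return Leaf(n, r, r / n if n else float("nan"), label)


def _best_candidate(
    expr: pd.DataFrame,
    outcome: np.ndarray,
    candidates: Sequence[str],
    alpha_normality: float,
) -> tuple[str | None, float]:
    """Most significant candidate at a node; ties broken by larger AUC,
    then lexicographic id. Returns (variable, p) or (None, nan) if no
    candidate is testable."""
    scored = []
    for var in candidates:
        vals = expr[var].to_numpy()
        if np.unique(vals[~np.isnan(vals)]).size < 2:
            continue
        res = compare_groups(vals, outcome, alpha_normality, variable=var)
        auc = roc_curve(vals, outcome, orientation="high-positive").auc
        scored.append((res.p_value, -auc, var))
    if not scored:
        return None, float("nan")
    scored.sort()
    p, neg_auc, var = scored[0]
    return var, p


def build_tree(
    expr: ExpressionMatrix,
    outcome: Sequence[bool],
    candidates: Sequence[str] | None = None,
    root_variable: str = "auto",
    config: TreeConfig | None = None,
) -> DecisionTree:
    """Grow the recursive Youden-threshold tree (see module docstring).

    ``outcome`` must be a non-missing boolean responder indicator aligned
    with the expression matrix's patients. The root always splits on
    ``root_variable`` (or the overall most significant candidate when
    ``"auto"``); deeper splits require node-local significance below
    ``config.alpha`` and ``config.min_leaf`` patients per child, and a
    variable is consumed along its path unless ``config.reuse_variables``.
    """
    cfg = config or TreeConfig()
    candidates = list(candidates) if candidates is not None else expr.mirna_ids
    y = np.asarray(outcome, dtype=bool)
    df = expr.data
    if y.size != len(df):
        raise ValueError("outcome length must match the number of patients")

    def grow(idx: np.ndarray, used: frozenset, depth: int, label: str) -> Split | Leaf:
        sub = df.iloc[idx]
        yy = y[idx]
        if depth >= cfg.max_depth or yy.size < 2 * cfg.min_leaf:
            return _make_leaf(yy, label)
        if yy.all() or not yy.any():
            return _make_leaf(yy, label)
        avail = [c for c in candidates if cfg.reuse_variables or c not in used]
        if not avail:
            return _make_leaf(yy, label)
        var, p = _best_candidate(sub, yy, avail, cfg.alpha_normality)
        if var is None or not p < cfg.alpha:
            return _make_leaf(yy, label)
        return split_on(idx, var, used, depth, label, p_value=p)

    def split_on(
        idx: np.ndarray,
        var: str,
        used: frozenset,
        depth: int,
        label: str,
        p_value: float | None,
        force: bool = False,
    ) -> Split | Leaf:
        sub = df.iloc[idx]
        yy = y[idx]
        vals = sub[var].to_numpy()
        roc = roc_curve(vals, yy, orientation="high-positive")
        thr = roc.youden_threshold
        hi = vals > thr
        if not force and (hi.sum() < cfg.min_leaf or (~hi).sum() < cfg.min_leaf):
            return _make_leaf(yy, label)
        if hi.all() or not hi.any():
            return _make_leaf(yy, label)
        used2 = used | {var}
        return Split(
            variable=var,
            threshold=float(thr),
            n=int(yy.size),
            high=grow(idx[hi], used2, depth + 1, label + "H"),
            low=grow(idx[~hi], used2, depth + 1, label + "L"),
            p_value=p_value,
        )

    all_idx = np.arange(len(df))
    if not candidates:
        return DecisionTree(_make_leaf(y, ""))
    if y.all() or not y.any():
        return DecisionTree(_make_leaf(y, ""))
    if root_variable == "auto":
        root_var, root_p = _best_candidate(df, y, candidates, cfg.alpha_normality)
        if root_var is None:
            raise ValueError("no testable candidate for the root split")
    else:
        if root_variable not in candidates:
            raise ValueError(f"root variable {root_variable!r} not among candidates")
        vals = df[root_variable].to_numpy()
        if np.unique(vals[~np.isnan(vals)]).size < 2:
            raise ValueError(f"root variable {root_variable!r} is constant")
        root_var = root_variable
        root_p = compare_groups(vals, y, cfg.alpha_normality).p_value
    root = split_on(all_idx, root_var, frozenset(), 0, "", root_p, force=True)
    tree = DecisionTree(root)
    tree.check_invariants()
    return tree


def classify(
    tree: DecisionTree, patient_expr: Mapping[str, float]
) -> tuple[str, float, list[tuple[str, float, str]]] | Unclassifiable:
    """Route one patient down the tree.

    Returns ``(leaf label, leaf probability, path)`` where the path lists
    ``(variable, threshold, "H"/"L")`` decisions, or an
    :class:`Unclassifiable` marker if a path variable is missing (no
    imputation is ever attempted). Values strictly above a threshold go
    high; equality routes low.
    """
    node = tree.root
    path: list[tuple[str, float, str]] = []
    while isinstance(node, Split):
        val = patient_expr.get(node.variable)
        if val is None or (isinstance(val, float) and np.isnan(val)):
            return Unclassifiable(node.variable, path)
        side = "H" if val > node.threshold else "L"
        path.append((node.variable, node.threshold, side))
        node = node.high if side == "H" else node.low
    return node.label, node.probability, path


def assign_groups(
    tree: DecisionTree, expr: ExpressionMatrix
) -> tuple[pd.DataFrame, pd.Series]:
    """Assign every classifiable patient to a leaf label.

    Returns ``(assignments, counts)``: a frame with one row per patient
    (label and leaf probability; NaN where unclassifiable) and the
    per-label patient counts.
    """
    rows = []
    for pid, row in expr.data.iterrows():
        res = classify(tree, row.to_dict())
        if isinstance(res, Unclassifiable):
            rows.append({"patient_id": pid, "label": np.nan, "probability": np.nan})
        else:
            label, prob, _ = res
            rows.append({"patient_id": pid, "label": label, "probability": prob})
    frame = pd.DataFrame(rows).set_index("patient_id")
    counts = frame["label"].value_counts()
    return frame, counts


# ---------------------------------------------------------------------------
# published fixture

#: Published working characteristics of the five tree miRNAs
#: (univariate p, threshold, specificity %, sensitivity %).
PUBLISHED_ROC_PANEL: dict[str, dict[str, float]] = {
    "miR-15b": {"p_value": 0.0064, "threshold": 0.1710, "sp": 56, "se": 76},
    "miR-125b": {"p_value": 0.0231, "threshold": 0.0005, "sp": 53, "se": 78},
    "miR-181c": {"p_value": 0.0244, "threshold": 0.0019, "sp": 71, "se": 81},
    "miR-193b": {"p_value": 0.0420, "threshold": 0.0113, "sp": 86, "se": 80},
    "miR-412": {"p_value": 0.0365, "threshold": 0.0003, "sp": 82, "se": 80},
}

_UNVERIFIED_LEAF_PLACEHOLDERS = {"HHL": 0.35, "HLH": 0.30, "HLL": 0.15, "LH": 0.20}


def published_tree() -> DecisionTree:
    """The published five-miRNA decision tree as a fixture.

    Topology: root miR-125b; high branch miR-15b, then miR-181c (high)
    and miR-412 (low); low branch miR-193b. The HHH (0.72) and LL (0.04)
    leaf probabilities are the two published anchors; the four remaining
    leaves carry explicitly-unverified placeholder probabilities
    (``verified=False``). Per-node patient counts were not published and
    are stored as None.
    """

    def thr(m: str) -> float:
        return PUBLISHED_ROC_PANEL[m]["threshold"]

    def leaf(label: str) -> Leaf:
        if label == "HHH":
            return Leaf(None, None, 0.72, label, verified=True)
        if label == "LL":
            return Leaf(None, None, 0.04, label, verified=True)
        return Leaf(None, None, _UNVERIFIED_LEAF_PLACEHOLDERS[label], label, verified=False)

    root = Split(
        "miR-125b",
        thr("miR-125b"),
        None,
        high=Split(
            "miR-15b",
            thr("miR-15b"),
            None,
            high=Split("miR-181c", thr("miR-181c"), None, leaf("HHH"), leaf("HHL")),
            low=Split("miR-412", thr("miR-412"), None, leaf("HLH"), leaf("HLL")),
        ),
        low=Split("miR-193b", thr("miR-193b"), None, leaf("LH"), leaf("LL")),
    )
    return DecisionTree(root)
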