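"""Benign/malignant classification from the 33 morphometric parameters.

Single-parameter screening uses a monotone threshold rule per parameter
(equivalent to two-class LDA on one variable), characterised by a full ROC
sweep with trapezoidal AUC and a Youden-J optimal cutpoint, plus a Welch
(unequal-variance) t test.  The multivariate model is a CART decision tree
grown by Gini impurity and pruned by two structural rules: no parameter may
appear at more than one node, and the tree may carry at most three
malignant leaves (one per malignant histology: IDC, ILC, DCIS).  Validation
is leave-one-out with the tree structure held fixed and only the root
cutoff refit per fold, and a tree-level ROC is traced by sweeping the root
(StdIND) cutoff while holding the lumen rule at "more than one lumen".
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .io import DUCT_DIAGNOSES
from .nuclear import NUCLEAR_FEATURE_NAMES
from .ductmorph import DUCT_FEATURE_NAMES

__all__ = [
    "ALL_FEATURE_NAMES",
    "ROCResult",
    "Leaf",
    "TreeNode",
    "DecisionTree",
    "published_tree",
    "welch_t",
    "single_parameter_roc",
    "rank_parameters",
    "grow_tree",
    "prune_tree",
    "classify_site",
    "loocv_fixed_structure",
    "tree_roc",
]

#: canonical order of the 33 parameters (14 nuclear + 19 ductal)
ALL_FEATURE_NAMES: tuple[str, ...] = (*NUCLEAR_FEATURE_NAMES, *DUCT_FEATURE_NAMES)

_POSITIVE = "malignant"
_NEGATIVE = "benign"


# ---------------------------------------------------------------------------
# univariate statistics
# ---------------------------------------------------------------------------

def welch_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Welch t statistic, Welch-Satterthwaite df and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("degenerate (zero) variance in both groups")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


@dataclass
class ROCResult:
    """ROC of a monotone threshold rule."""

    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    cutpoint: float
    sensitivity: float
    specificity: float
    direction: str  # ">" malignant at high values, "<" at low values

    def __post_init__(self) -> None:
        self.fpr = np.asarray(self.fpr, dtype=float)
        self.tpr = np.asarray(self.tpr, dtype=float)


def single_parameter_roc(values: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC of thresholding one parameter, oriented so that AUC >= 0.5.

    ``labels`` are class strings or booleans (True/"malignant" positive).
    Missing values are excluded pairwise.  The optimal cutpoint maximises
    Youden's J; at the cutpoint, positives are predicted by
    ``value >= cut`` (direction ">") or ``value <= cut`` (direction "<").
    """
    values = np.asarray(values, dtype=float)
    y = np.asarray([
        lbl if isinstance(lbl, (bool, np.bool_)) else lbl == _POSITIVE
        for lbl in np.asarray(labels).tolist()
    ])
    ok = ~np.isnan(values)
    values, y = values[ok], y[ok]
    if y.all() or not y.any():
        raise ValueError("both classes must be present")

    fpr, tpr, thr = _sk_roc_curve(y, values)
    a = _sk_auc(fpr, tpr)
    direction = ">"
    if a < 0.5:
        fpr, tpr, thr = _sk_roc_curve(y, -values)
        a = _sk_auc(fpr, tpr)
        direction = "<"
    j = np.argmax(tpr - fpr)
    cut = float(thr[j])
    cut = -cut if direction == "<" else cut
    if direction == ">":
        pred = values >= cut
    else:
        pred = values <= cut
    sens = float((pred & y).sum() / y.sum())
    spec = float((~pred & ~y).sum() / (~y).sum())
    return ROCResult(
        fpr=fpr, tpr=tpr, auc=float(a), cutpoint=cut,
        sensitivity=sens, specificity=spec, direction=direction,
    )


def rank_parameters(table: pd.DataFrame) -> pd.DataFrame:
    """AUC / sensitivity / specificity per parameter, by site group.

    Groups mirror the standard breakdown: nuclear parameters on all sites
    (A), on non-duct sites (B) and on duct sites (C); ductal parameters on
    duct sites (D).  Within each group parameters are sorted by descending
    AUC; parameters without both classes or without valid values in a group
    are excluded from it.
    """
    is_duct = table["diagnosis"].isin(DUCT_DIAGNOSES).to_numpy()
    groups = {
        "A_nuclear_all_sites": (NUCLEAR_FEATURE_NAMES, np.ones(len(table), bool)),
        "B_nuclear_nonduct_sites": (NUCLEAR_FEATURE_NAMES, ~is_duct),
        "C_nuclear_duct_sites": (NUCLEAR_FEATURE_NAMES, is_duct),
        "D_ductal_duct_sites": (DUCT_FEATURE_NAMES, is_duct),
    }
    rows = []
    for gname, (features, sel) in groups.items():
        sub = table.loc[sel]
        labels = sub["class_label"].to_numpy()
        for feat in features:
            vals = sub[feat].to_numpy(dtype=float)
            ok = ~np.isnan(vals)
            if ok.sum() < 2:
                continue
            lab_ok = labels[ok]
            if (lab_ok == _POSITIVE).all() or (lab_ok == _NEGATIVE).all():
                continue
            roc = single_parameter_roc(vals, labels)
            rows.append(
                {
                    "group": gname,
                    "feature": feat,
                    "auc": roc.auc,
                    "sensitivity": roc.sensitivity,
                    "specificity": roc.specificity,
                    "cutpoint": roc.cutpoint,
                    "direction": roc.direction,
                    "n": int(ok.sum()),
                }
            )
    out = pd.DataFrame(rows)
    return (
        out.sort_values(["group", "auc"], ascending=[True, False]).reset_index(
            drop=True
        )
        if len(out)
        else out
    )


# ---------------------------------------------------------------------------
# decision tree
# ---------------------------------------------------------------------------

@dataclass
class Leaf:
    label: str

    def to_dict(self) -> dict:
        return {"leaf": self.label}


@dataclass
class TreeNode:
    """Binary decision node: the condition sends a site to ``left``."""

    feature: str
    cutoff: float
    op: str = "<"
    left: Union["TreeNode", Leaf] = None  # type: ignore[assignment]
    right: Union["TreeNode", Leaf] = None  # type: ignore[assignment]
    missing_side: str = "right"

    def test(self, value: float) -> Optional[bool]:
        if value is None or (isinstance(value, float) and np.isnan(value)):
            return None
        if self.op == "<":
            return value < self.cutoff
        if self.op == "<=":
            return value <= self.cutoff
        if self.op == ">":
            return value > self.cutoff
        if self.op == ">=":
            return value >= self.cutoff
        raise ValueError(f"unknown op {self.op!r}")

    def to_dict(self) -> dict:
        return {
            "feature": self.feature,
            "cutoff": self.cutoff,
            "op": self.op,
            "missing_side": self.missing_side,
            "left": self.left.to_dict(),
            "right": self.right.to_dict(),
        }


@dataclass
class DecisionTree:
    """Serializable binary benign/malignant decision tree."""

    root: Union[TreeNode, Leaf]

    def predict(self, features: dict) -> str:
        return classify_site(self, features)

    # -- structure queries ---------------------------------------------------
    def internal_nodes(self) -> list[tuple[TreeNode, int]]:
        """(node, depth) pairs in preorder."""
        out: list[tuple[TreeNode, int]] = []

        def rec(nd, depth):
            if isinstance(nd, TreeNode):
                out.append((nd, depth))
                rec(nd.left, depth + 1)
                rec(nd.right, depth + 1)

        rec(self.root, 0)
        return out

    def leaves(self) -> list[Leaf]:
        out: list[Leaf] = []

        def rec(nd):
            if isinstance(nd, Leaf):
                out.append(nd)
            else:
                rec(nd.left)
                rec(nd.right)

        rec(self.root)
        return out

    def n_nodes(self) -> int:
        return len(self.internal_nodes()) + len(self.leaves())

    # -- serialization -------------------------------------------------------
    def to_dict(self) -> dict:
        return {"tree": self.root.to_dict()}

    @classmethod
    def from_dict(cls, doc: dict) -> "DecisionTree":
        def rec(d: dict):
            if "leaf" in d:
                return Leaf(d["leaf"])
            return TreeNode(
                feature=d["feature"],
                cutoff=float(d["cutoff"]),
                op=d.get("op", "<"),
                left=rec(d["left"]),
                right=rec(d["right"]),
                missing_side=d.get("missing_side", "right"),
            )

        return cls(root=rec(doc["tree"]))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def load(cls, path: str | Path) -> "DecisionTree":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def published_tree() -> DecisionTree:
    """The reference two-node tree: malignant when StdIND < 6.83 um,
    otherwise malignant when the duct has more than one lumen, otherwise
    benign."""
    return DecisionTree(
        root=TreeNode(
            feature="std_ind",
            cutoff=6.83,
            op="<",
            left=Leaf(_POSITIVE),
            right=TreeNode(
                feature="n_lumens",
                cutoff=1.0,
                op=">",
                left=Leaf(_POSITIVE),
                right=Leaf(_NEGATIVE),
                missing_side="right",
            ),
            missing_side="right",
        )
    )


def classify_site(tree: DecisionTree, features: dict) -> str:
    """Route one site's feature dict to a benign/malignant leaf.

    A missing lumen count means the site has no segmented duct and is
    treated as zero lumens; other missing values follow each node's
    recorded majority side.
    """
    nd = tree.root
    while isinstance(nd, TreeNode):
        val = features.get(nd.feature, float("nan"))
        if nd.feature == "n_lumens" and (
            val is None or (isinstance(val, float) and np.isnan(val))
        ):
            val = 0.0
        branch = nd.test(val)
        if branch is None:
            branch = nd.missing_side == "left"
        nd = nd.left if branch else nd.right
    return nd.label


# ---------------------------------------------------------------------------
# CART growth
# ---------------------------------------------------------------------------

def _gini(labels: np.ndarray) -> float:
    if labels.size == 0:
        return 0.0
    p = (labels == _POSITIVE).mean()
    return float(2.0 * p * (1.0 - p))


def _majority(labels: np.ndarray) -> str:
    pos = int((labels == _POSITIVE).sum())
    neg = int(labels.size) - pos
    return _POSITIVE if pos > neg else _NEGATIVE


def _best_split(
    X: pd.DataFrame, y: np.ndarray, features: tuple[str, ...]
) -> Optional[tuple[str, float, str, np.ndarray]]:
    """Exhaustive Gini search over midpoint cutoffs of every feature.

    Missing values are routed to the child holding the majority of the
    node's non-missing rows (ties to the left/condition side).  Ties in
    impurity resolve to the lexicographically smaller feature, then the
    lower cutoff.  Returns (feature, cutoff, missing_side, left_mask) or
    None when no split reduces impurity.
    """
    n = y.size
    parent = _gini(y) * n
    best = None  # (score, feature, cutoff, missing_side, left_mask)
    for feat in sorted(features):
        v = X[feat].to_numpy(dtype=float)
        ok = ~np.isnan(v)
        vals = np.unique(v[ok])
        if vals.size < 2:
            continue
        cuts = (vals[:-1] + vals[1:]) / 2.0
        for c in cuts:
            left = ok & (v < c)
            right = ok & ~left
            missing_side = "left" if left.sum() >= right.sum() else "right"
            if missing_side == "left":
                left = left | ~ok
            else:
                right = right | ~ok
            score = _gini(y[left]) * left.sum() + _gini(y[right]) * right.sum()
            if score < parent - 1e-12 and (best is None or score < best[0] - 1e-12):
                best = (score, feat, float(c), missing_side, left)
    if best is None:
        return None
    return best[1], best[2], best[3], best[4]


def grow_tree(
    table: pd.DataFrame,
    features: tuple[str, ...] = ALL_FEATURE_NAMES,
    min_leaf: int = 1,
) -> DecisionTree:
    """Grow a CART tree by recursive Gini splitting to purity."""
    if len(table) == 0:
        raise ValueError("empty training table")
    y = table["class_label"].to_numpy()
    if not ((y == _POSITIVE).any() and (y == _NEGATIVE).any()):
        return DecisionTree(root=Leaf(_majority(y)))
    feats = tuple(f for f in features if f in table.columns)

    def rec(idx: np.ndarray) -> Union[TreeNode, Leaf]:
        yy = y[idx]
        if np.unique(yy).size == 1 or yy.size <= min_leaf:
            return Leaf(_majority(yy))
        split = _best_split(table.iloc[idx], yy, feats)
        if split is None:
            return Leaf(_majority(yy))
        feat, cut, missing_side, left_mask = split
        return TreeNode(
            feature=feat,
            cutoff=cut,
            op="<",
            left=rec(idx[left_mask]),
            right=rec(idx[~left_mask]),
            missing_side=missing_side,
        )

    return DecisionTree(root=rec(np.arange(y.size)))


# ---------------------------------------------------------------------------
# pruning
# ---------------------------------------------------------------------------

def _route_counts(tree: DecisionTree, table: pd.DataFrame) -> dict[int, np.ndarray]:
    """Training-row indices routed through each internal node (by id)."""
    rows = table.to_dict("records")
    routed: dict[int, list[int]] = {}

    for i, feats in enumerate(rows):
        nd = tree.root
        while isinstance(nd, TreeNode):
            routed.setdefault(id(nd), []).append(i)
            val = feats.get(nd.feature, float("nan"))
            if nd.feature == "n_lumens" and (
                val is None or (isinstance(val, float) and np.isnan(val))
            ):
                val = 0.0
            branch = nd.test(val)
            if branch is None:
                branch = nd.missing_side == "left"
            nd = nd.left if branch else nd.right
    return {k: np.asarray(v) for k, v in routed.items()}


def _side_rows(
    node: TreeNode, rows: np.ndarray, table: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    take_left = []
    for i in rows:
        val = table.iloc[int(i)].get(node.feature, float("nan"))
        if node.feature == "n_lumens" and (
            val is None or (isinstance(val, float) and np.isnan(val))
        ):
            val = 0.0
        branch = node.test(float(val) if val is not None else float("nan"))
        if branch is None:
            branch = node.missing_side == "left"
        take_left.append(branch)
    take_left = np.asarray(take_left, dtype=bool)
    return rows[take_left], rows[~take_left]


def prune_tree(
    tree: DecisionTree, table: pd.DataFrame, max_malignant_leaves: int = 3
) -> DecisionTree:
    """Apply the two structural pruning rules.

    Rule 1: no parameter may be tested at more than one node (the deeper
    repeats are violations).  Rule 2: at most ``max_malignant_leaves``
    malignant leaves (one per malignant histology).  Violations are
    resolved deepest first by finding the violation's nearest ancestor
    (including itself) whose split separates a majority-malignant side from
    a majority-benign side of its routed training sites, and turning that
    node's children into majority-class leaves.
    """
    tree = DecisionTree.from_dict(tree.to_dict())  # work on a copy
    y = table["class_label"].to_numpy()

    def collapse(node: TreeNode, rows_left: np.ndarray, rows_right: np.ndarray):
        node.left = Leaf(_majority(y[rows_left]) if rows_left.size else _NEGATIVE)
        node.right = Leaf(_majority(y[rows_right]) if rows_right.size else _NEGATIVE)

    for _ in range(64):  # each pass removes nodes; bounded loop
        routed = _route_counts(tree, table)
        nodes = tree.internal_nodes()
        parents: dict[int, TreeNode] = {}
        for nd, _d in nodes:
            for ch in (nd.left, nd.right):
                if isinstance(ch, TreeNode):
                    parents[id(ch)] = nd

        # rule 1 violations: all but the shallowest occurrence of a feature;
        # these nodes must disappear, so their ancestor search starts above
        violations: list[tuple[int, TreeNode, bool]] = []
        seen_feature_depth: dict[str, int] = {}
        for nd, depth in nodes:
            if nd.feature in seen_feature_depth:
                violations.append((depth, nd, True))
            else:
                seen_feature_depth[nd.feature] = depth

        def malignant_leaves(nd) -> list[tuple[int, TreeNode]]:
            """(depth, parent node) of each malignant leaf."""
            out = []

            def rec(n, depth, parent):
                if isinstance(n, Leaf):
                    if n.label == _POSITIVE and parent is not None:
                        out.append((depth, parent))
                else:
                    rec(n.left, depth + 1, n)
                    rec(n.right, depth + 1, n)

            rec(nd, 0, None)
            return out

        mleaves = malignant_leaves(tree.root)
        if len(mleaves) > max_malignant_leaves:
            depth, parent = max(mleaves, key=lambda t: t[0])
            violations.append((depth - 1, parent, False))

        if not violations:
            break
        _, v, must_remove = max(violations, key=lambda t: t[0])

        # nearest ancestor with one majority-malignant and one
        # majority-benign side of its routed training sites; the violating
        # node itself qualifies unless it must be removed (rule 1), and a
        # collapse that would change nothing is skipped
        a: Optional[TreeNode] = parents.get(id(v)) if must_remove else v
        target = None
        while a is not None:
            rows = routed.get(id(a), np.empty(0, int))
            rl, rr = _side_rows(a, rows, table)
            if rl.size and rr.size:
                maj_l, maj_r = _majority(y[rl]), _majority(y[rr])
                no_op = (
                    isinstance(a.left, Leaf)
                    and isinstance(a.right, Leaf)
                    and a.left.label == maj_l
                    and a.right.label == maj_r
                )
                if maj_l != maj_r and not no_op:
                    target = (a, rl, rr)
                    break
            a = parents.get(id(a))
        if target is not None:
            collapse(*target)
        else:
            # no qualifying ancestor: fold the violating node into a leaf
            rows = routed.get(id(v), np.empty(0, int))
            leaf = Leaf(_majority(y[rows]) if rows.size else _NEGATIVE)
            parent = parents.get(id(v))
            if parent is None:
                tree.root = leaf
                break
            if parent.left is v:
                parent.left = leaf
            else:
                parent.right = leaf
    return tree


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

def _confusion(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    pos = y_true == _POSITIVE
    pred_pos = y_pred == _POSITIVE
    tp = int((pos & pred_pos).sum())
    fn = int((pos & ~pred_pos).sum())
    tn = int((~pos & ~pred_pos).sum())
    fp = int((~pos & pred_pos).sum())
    return {
        "tp": tp, "fp": fp, "tn": tn, "fn": fn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
        "accuracy": (tp + tn) / y_true.size,
    }


def resubstitution(tree: DecisionTree, table: pd.DataFrame) -> dict[str, float]:
    """Training (resubstitution) confusion summary of a fitted tree."""
    preds = np.asarray(
        [classify_site(tree, row) for row in table.to_dict("records")]
    )
    return _confusion(table["class_label"].to_numpy(), preds)


def _refit_root_cutoff(
    values: np.ndarray, labels: np.ndarray
) -> float:
    """Gini-optimal cutoff for a 'value < c -> malignant side' root split."""
    ok = ~np.isnan(values)
    vals = np.unique(values[ok])
    if vals.size < 2:
        return float(vals[0]) if vals.size else float("nan")
    cuts = (vals[:-1] + vals[1:]) / 2.0
    best_c, best_score = cuts[0], np.inf
    y = labels[ok]
    v = values[ok]
    for c in cuts:
        left = v < c
        score = _gini(y[left]) * left.sum() + _gini(y[~left]) * (~left).sum()
        if score < best_score - 1e-12:
            best_score, best_c = score, float(c)
    return best_c


def loocv_fixed_structure(
    table: pd.DataFrame, tree: DecisionTree | None = None
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Leave-one-out with fixed tree structure.

    The tree's shape and every non-root cutoff (notably "lumens > 1") stay
    fixed; only the root cutoff is refit, by Gini, on each fold's training
    sites.  Returns per-site predictions and the aggregate confusion.
    """
    tree = tree or published_tree()
    if isinstance(tree.root, Leaf):
        raise ValueError("fixed-structure LOOCV needs a tree with a root split")
    root_feature = tree.root.feature
    values = table[root_feature].to_numpy(dtype=float)
    labels = table["class_label"].to_numpy()
    rows = table.to_dict("records")

    preds = []
    cutoffs = []
    n = len(table)
    for i in range(n):
        mask = np.ones(n, dtype=bool)
        mask[i] = False
        c = _refit_root_cutoff(values[mask], labels[mask])
        fold_tree = DecisionTree.from_dict(tree.to_dict())
        fold_tree.root.cutoff = c
        preds.append(classify_site(fold_tree, rows[i]))
        cutoffs.append(c)
    out = table[["site_id", "diagnosis", "class_label"]].copy() if "site_id" in table else pd.DataFrame({"class_label": labels})
    out["prediction"] = preds
    out["root_cutoff"] = cutoffs
    return out, _confusion(labels, np.asarray(preds))


def tree_roc(
    table: pd.DataFrame, feature: str = "std_ind", lumen_cutoff: float = 1.0
) -> ROCResult:
    """ROC of the two-rule model by sweeping the root cutoff.

    Sites are sorted by ascending ``feature``; at every candidate cutoff c
    a site is called malignant when ``feature < c`` or when it has more
    than ``lumen_cutoff`` lumens (missing lumen counts are zero).  The
    lumen rule gives the curve a sensitivity floor at the smallest cutoff.
    """
    v = table[feature].to_numpy(dtype=float)
    if np.isnan(v).any():
        raise ValueError(f"{feature} must be present for all sites")
    y = (table["class_label"].to_numpy() == _POSITIVE)
    lum = table["n_lumens"].to_numpy(dtype=float) if "n_lumens" in table else np.zeros(v.size)
    lum = np.where(np.isnan(lum), 0.0, lum)
    lum_pos = lum > lumen_cutoff

    n_pos = max(int(y.sum()), 1)
    n_neg = max(int((~y).sum()), 1)
    cuts = np.concatenate(([-np.inf], np.sort(np.unique(v)), [np.inf]))
    raw = []
    for c in cuts:
        pred = (v < c) | lum_pos
        raw.append(
            (float((pred & ~y).sum() / n_neg), float((pred & y).sum() / n_pos), c)
        )
    pts = np.asarray(sorted({(f, t) for f, t, _ in raw} | {(0.0, 0.0), (1.0, 1.0)}))
    fpr, tpr = pts[:, 0], pts[:, 1]
    a = float(np.trapezoid(tpr, fpr))
    j = int(np.argmax([t - f for f, t, _ in raw]))
    return ROCResult(
        fpr=fpr, tpr=tpr, auc=a,
        cutpoint=float(raw[j][2]),
        sensitivity=float(raw[j][1]), specificity=float(1 - raw[j][0]),
        direction="<",
    )
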