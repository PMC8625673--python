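"""From-scratch CHAID (Chi-square Automatic Interaction Detection) trees.

Kass-style classification trees for a binary outcome: each candidate
predictor's categories are greedily merged while the least-significant pair
of groups is non-significant, the merged-table chi-square p is inflated by a
Bonferroni multiplier counting the number of ways the original categories
could have been grouped, and the node splits on the predictor with the
smallest adjusted p.  Continuous predictors (age) enter as quantile-binned
ordinals; missing values form their own category (floating, for ordinals).

The re-split refinement of some CHAID variants and exhaustive CHAID are
deliberately not implemented; the trees of interest here are shallow.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.utils.validation import check_is_fitted

from .errors import InvalidParameterError, RoutingError

__all__ = [
    "MISSING",
    "ChaidSettings",
    "ChaidNode",
    "ChaidTree",
    "SplitDecision",
    "merge_categories",
    "bonferroni_multiplier",
    "best_split",
    "grow_tree",
    "cross_validate",
    "render_tree",
    "CHAIDClassifier",
]

#: Sentinel category for missing predictor values.
MISSING = "(missing)"


@dataclass(frozen=True)
class ChaidSettings:
    """Tree-growing controls.

    alpha_split / alpha_merge are the significance levels for splitting and
    for stopping category merging; min_parent / min_child are node-size
    minima chosen for cohorts of a few hundred subjects; age_bins is the
    number of quantile bins for continuous predictors.
    """

    alpha_split: float = 0.05
    alpha_merge: float = 0.05
    min_parent: int = 30
    min_child: int = 10
    max_depth: int = 3
    bonferroni: bool = True
    predictor_types: dict[str, str] | None = None
    age_bins: int = 10
    cv_folds: int = 10
    seed: int = 0

    def __post_init__(self):
        for name in ("alpha_split", "alpha_merge"):
            a = getattr(self, name)
            if not 0 < a <= 1:
                raise InvalidParameterError(f"{name} must be in (0, 1], got {a}")
        if self.min_child > self.min_parent:
            raise InvalidParameterError("min_child must be <= min_parent")
        if self.max_depth < 1:
            raise InvalidParameterError("max_depth must be >= 1")


def _pearson_chi2(table: np.ndarray) -> tuple[float, int, float]:
    """Pearson chi-square on a contingency table, dropping empty rows/cols.

    Degenerate tables (fewer than 2 non-empty rows or columns) return
    (0, 0, 1) so that identical-distribution groups always merge.
    """
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 0, 1.0
    chi2, p, df, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), int(df), float(p)


def _stirling2(c: int, r: int) -> int:
    """Number of ways to partition c labelled items into r non-empty
    unordered groups (Stirling number of the second kind)."""
    total = 0
    for j in range(r + 1):
        total += (-1) ** j * math.comb(r, j) * (r - j) ** c
    return total // math.factorial(r)


def bonferroni_multiplier(c: int, r: int, type: str = "nominal",
                          floating: bool = False) -> int:
    """Multiplier counting the groupings of c original categories into r
    groups: Stirling-2 for nominal predictors, C(c-1, r-1) contiguous
    groupings for ordinals, and Kass's floating-category count
    C(c-2, r-2) + r*C(c-2, r-1) for an ordinal with a missing category."""
    if not 1 <= r <= c:
        raise InvalidParameterError(f"need 1 <= r <= c, got c={c}, r={r}")
    if type == "nominal":
        return _stirling2(c, r)
    if type != "ordinal":
        raise InvalidParameterError(f"predictor type must be nominal or ordinal, got {type!r}")
    if not floating:
        return math.comb(c - 1, r - 1)
    if r < 2:
        return 1
    return math.comb(c - 2, r - 2) + r * math.comb(c - 2, r - 1)


@dataclass
class _Group:
    cats: list  # original category values
    floating: bool = False


def _class_counts(y: np.ndarray, classes: Sequence) -> np.ndarray:
    return np.array([(y == c).sum() for c in classes])


def merge_categories(values, y, type: str = "nominal", alpha_merge: float = 0.05,
                     order: Sequence | None = None) -> list[tuple]:
    """Greedy Kass merging of predictor categories.

    Repeatedly merges the pair of groups (any pair for nominal predictors,
    adjacent pairs for ordinals, with a missing category floating freely)
    whose two-group chi-square p is largest, while that p exceeds
    alpha_merge.  May merge down to a single group when the predictor is
    unrelated to the outcome; a single observed category is returned as-is.

    Returns the merged groups as tuples of original category values, in
    order of first appearance (ordinal: predictor order).
    """
    values = np.asarray(values, dtype=object)
    y = np.asarray(y)
    classes = sorted(set(y), key=str)
    observed = pd.unique(values)
    if order is not None:
        ordered = [c for c in order if c in set(observed)]
        ordered += [c for c in observed if c not in set(ordered)]
        observed = ordered
    elif type == "ordinal":
        non_missing = sorted([c for c in observed if c != MISSING])
        observed = non_missing + ([MISSING] if MISSING in set(observed) else [])

    groups = [_Group([c], floating=(type == "ordinal" and c == MISSING)) for c in observed]
    counts = {id(g): _class_counts(y[np.isin(values, g.cats)], classes) for g in groups}

    while len(groups) > 1:
        pairs = []
        if type == "nominal":
            pairs = [(i, j) for i in range(len(groups)) for j in range(i + 1, len(groups))]
        else:
            solid = [i for i, g in enumerate(groups) if not g.floating]
            pairs = [(solid[k], solid[k + 1]) for k in range(len(solid) - 1)]
            for i, g in enumerate(groups):
                if g.floating:
                    pairs += [(min(i, j), max(i, j)) for j in solid]
        if not pairs:
            break
        best_p, best_pair = -1.0, None
        for i, j in sorted(pairs):
            sub = np.vstack([counts[id(groups[i])], counts[id(groups[j])]])
            _, _, p = _pearson_chi2(sub)
            if p > best_p:
                best_p, best_pair = p, (i, j)
        if best_p <= alpha_merge:
            break
        i, j = best_pair
        merged = _Group(groups[i].cats + groups[j].cats, floating=False)
        new_counts = counts[id(groups[i])] + counts[id(groups[j])]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)]
        groups.insert(i, merged)
        counts = {id(g): counts[id(g)] for g in groups if id(g) in counts}
        counts[id(merged)] = new_counts
    return [tuple(g.cats) for g in groups]


@dataclass(frozen=True)
class SplitDecision:
    predictor: str
    groups: list[tuple]
    chi2: float
    df: int
    p_raw: float
    bonferroni_B: int
    p_adj: float


@dataclass
class _Column:
    """A prepared predictor: categorical codes plus metadata for routing."""

    name: str
    type: str  # 'nominal' or 'ordinal'
    values: np.ndarray  # object array of category values (MISSING sentinel)
    order: list | None = None
    bin_edges: np.ndarray | None = None  # set for quantile-binned continuous
    has_missing: bool = False


def _prepare_columns(X: pd.DataFrame, predictor_types: dict[str, str] | None,
                     age_bins: int) -> dict[str, _Column]:
    predictor_types = predictor_types or {}
    columns: dict[str, _Column] = {}
    for name in X.columns:
        col = X[name]
        declared = predictor_types.get(name)
        is_numeric = pd.api.types.is_numeric_dtype(col)
        if declared is None:
            if is_numeric and col.nunique(dropna=True) > 10:
                declared = "continuous"
            elif is_numeric:
                declared = "ordinal"
            else:
                declared = "nominal"
        has_missing = bool(col.isna().any())
        if declared == "continuous":
            non_na = col.dropna()
            binned, edges = pd.qcut(non_na, q=min(age_bins, non_na.nunique()),
                                    retbins=True, duplicates="drop", labels=False)
            codes = np.full(len(col), -1, dtype=int)
            codes[col.notna().to_numpy()] = binned.to_numpy()
            values = np.array(
                [f"bin{c:02d}" if c >= 0 else MISSING for c in codes], dtype=object
            )
            order = [f"bin{c:02d}" for c in range(int(codes.max()) + 1)]
            columns[name] = _Column(name, "ordinal", values, order=order,
                                    bin_edges=edges, has_missing=has_missing)
        else:
            values = np.array(
                [MISSING if pd.isna(v) else v for v in col], dtype=object
            )
            order = None
            if declared == "ordinal":
                order = sorted({v for v in values if v != MISSING})
                if has_missing:
                    order = order + [MISSING]
            columns[name] = _Column(name, declared, values, order=order,
                                    has_missing=has_missing)
    return columns


def _route_value(col: _Column, raw) -> Any:
    if pd.isna(raw):
        return MISSING
    if col.bin_edges is not None:
        idx = int(np.searchsorted(col.bin_edges, raw, side="right")) - 1
        idx = min(max(idx, 0), len(col.bin_edges) - 2)
        return f"bin{idx:02d}"
    return raw


def best_split(y: np.ndarray, columns: dict[str, _Column], rows: np.ndarray,
               settings: ChaidSettings, classes: Sequence) -> SplitDecision | None:
    """Choose the predictor with the smallest Bonferroni-adjusted p at a node.

    Splits only when that adjusted p is <= alpha_split and every resulting
    child has at least min_child subjects.  Ties break on predictor name.
    """
    y_node = y[rows]
    best: SplitDecision | None = None
    for name in sorted(columns):
        col = columns[name]
        v = col.values[rows]
        observed = pd.unique(v)
        if len(observed) < 2:
            continue
        floating = col.type == "ordinal" and MISSING in set(observed)
        order = col.order
        groups = merge_categories(v, y_node, type=col.type,
                                  alpha_merge=settings.alpha_merge, order=order)
        if len(groups) < 2:
            continue
        sizes = [np.isin(v, g).sum() for g in groups]
        if min(sizes) < settings.min_child:
            continue
        table = np.vstack([_class_counts(y_node[np.isin(v, g)], classes) for g in groups])
        chi2, df, p_raw = _pearson_chi2(table)
        B = 1
        if settings.bonferroni:
            B = bonferroni_multiplier(len(observed), len(groups), type=col.type,
                                      floating=floating)
        p_adj = min(1.0, p_raw * B)
        cand = SplitDecision(name, groups, chi2, df, p_raw, B, p_adj)
        if best is None or (cand.p_adj, cand.predictor) < (best.p_adj, best.predictor):
            best = cand
    if best is not None and best.p_adj <= settings.alpha_split:
        return best
    return None


@dataclass
class ChaidNode:
    node_id: int
    parent_id: int | None
    depth: int
    n: int
    class_counts: dict
    split_var: str | None = None
    groups: list[tuple] | None = None
    chi2: float | None = None
    df: int | None = None
    p_raw: float | None = None
    bonferroni_B: int | None = None
    p_adj: float | None = None
    children: list[int] = field(default_factory=list)
    #: category group this node represents within its parent's split
    branch: tuple | None = None

    @property
    def is_leaf(self) -> bool:
        return self.split_var is None

    def class_fractions(self) -> dict:
        return {c: k / self.n for c, k in self.class_counts.items()}


@dataclass
class ChaidTree:
    nodes: list[ChaidNode]
    classes: list
    settings: ChaidSettings
    columns: dict[str, _Column] = field(default_factory=dict, repr=False)
    cv_risk: float | None = None
    cv_risk_se: float | None = None

    @property
    def root(self) -> ChaidNode:
        return self.nodes[0]

    def leaves(self) -> list[ChaidNode]:
        return [n for n in self.nodes if n.is_leaf]

    def route(self, record: dict, unseen: str = "error") -> ChaidNode:
        """Route one record (predictor -> raw value) to its leaf."""
        node = self.root
        while not node.is_leaf:
            col = self.columns[node.split_var]
            value = _route_value(col, record.get(node.split_var))
            child_id = None
            for cid in node.children:
                child = self.nodes[cid]
                if value in child.branch:
                    child_id = cid
                    break
            if child_id is None:
                if unseen == "majority":
                    child_id = max(node.children, key=lambda cid: self.nodes[cid].n)
                else:
                    raise RoutingError(
                        f"value {value!r} of {node.split_var!r} matches no branch "
                        f"at node {node.node_id}"
                    )
            node = self.nodes[child_id]
        return node

    def predict_proba_one(self, record: dict, unseen: str = "error") -> dict:
        return self.route(record, unseen=unseen).class_fractions()

    def node_table(self) -> pd.DataFrame:
        rows = []
        for n in self.nodes:
            row = {
                "node_id": n.node_id, "parent_id": n.parent_id, "depth": n.depth,
                "n": n.n, "split_var": n.split_var, "chi2": n.chi2, "df": n.df,
                "p_raw": n.p_raw, "bonferroni_B": n.bonferroni_B, "p_adj": n.p_adj,
                "branch": "+".join(map(str, n.branch)) if n.branch else "",
            }
            for c in self.classes:
                row[f"n_{c}"] = n.class_counts[c]
                row[f"pct_{c}"] = 100.0 * n.class_counts[c] / n.n
            rows.append(row)
        return pd.DataFrame(rows)


def grow_tree(X: pd.DataFrame, y, settings: ChaidSettings = ChaidSettings(),
              predictors: Sequence[str] | None = None) -> ChaidTree:
    """Grow a CHAID tree for a binary target.

    Nodes are numbered breadth-first; recursion stops at max_depth, below
    min_parent, on pure nodes, or when no predictor reaches alpha_split.
    A degenerate (single-class) target yields the root alone.
    """
    if predictors is not None:
        X = X[list(predictors)]
    y = np.asarray(y)
    if len(X) != len(y):
        raise InvalidParameterError("X and y length mismatch")
    classes = sorted(set(y), key=str)
    columns = _prepare_columns(X.reset_index(drop=True), settings.predictor_types,
                               settings.age_bins)

    nodes: list[ChaidNode] = []
    all_rows = np.arange(len(y))

    def make_node(parent_id, depth, rows, branch):
        nid = len(nodes)
        y_node = y[rows]
        node = ChaidNode(
            node_id=nid, parent_id=parent_id, depth=depth, n=len(rows),
            class_counts={c: int((y_node == c).sum()) for c in classes},
            branch=branch,
        )
        nodes.append(node)
        return node

    queue = [(make_node(None, 0, all_rows, None), all_rows)]
    while queue:
        node, rows = queue.pop(0)
        y_node = y[rows]
        if (
            len(set(y_node)) < 2
            or node.depth >= settings.max_depth
            or node.n < settings.min_parent
        ):
            continue
        decision = best_split(y, columns, rows, settings, classes)
        if decision is None:
            continue
        node.split_var = decision.predictor
        node.groups = decision.groups
        node.chi2, node.df = decision.chi2, decision.df
        node.p_raw, node.bonferroni_B = decision.p_raw, decision.bonferroni_B
        node.p_adj = decision.p_adj
        col = columns[decision.predictor]
        for group in decision.groups:
            child_rows = rows[np.isin(col.values[rows], group)]
            child = make_node(node.node_id, node.depth + 1, child_rows, tuple(group))
            node.children.append(child.node_id)
            queue.append((child, child_rows))
    return ChaidTree(nodes=nodes, classes=classes, settings=settings, columns=columns)


def cross_validate(X: pd.DataFrame, y, settings: ChaidSettings = ChaidSettings()
                   ) -> tuple[float, float]:
    """k-fold cross-validated misclassification risk of majority-leaf
    prediction, folds stratified by the target and seeded.

    Returns (risk, standard error), se = sqrt(risk (1-risk) / n).
    """
    y = np.asarray(y)
    n = len(y)
    folds = settings.cv_folds
    if folds < 2 or n < folds:
        raise InvalidParameterError("need cv_folds >= 2 and n >= cv_folds")
    min_class = min(np.bincount(pd.factorize(y)[0]))
    if min_class < folds:
        warnings.warn(
            f"reducing folds from {folds} to {max(2, min_class)} so every fold "
            "contains both classes", stacklevel=2,
        )
        folds = max(2, min_class)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=settings.seed)
    errors = 0
    X = X.reset_index(drop=True)
    for train_idx, test_idx in skf.split(X, y):
        tree = grow_tree(X.iloc[train_idx], y[train_idx], settings)
        for i in test_idx:
            leaf = tree.route(X.iloc[i].to_dict(), unseen="majority")
            pred = max(leaf.class_counts, key=lambda c: (leaf.class_counts[c], str(c)))
            errors += int(pred != y[i])
    risk = errors / n
    return risk, math.sqrt(risk * (1 - risk) / n)


def render_tree(tree: ChaidTree) -> tuple[str, str]:
    """Render a fitted tree as a text outline and a Graphviz DOT document."""
    lines, dot = [], ["digraph chaid {", "  node [shape=box, fontname=Helvetica];"]
    for node in tree.nodes:
        pct = ", ".join(
            f"{c}: {node.class_counts[c]} ({100 * node.class_counts[c] / node.n:.0f}%)"
            for c in tree.classes
        )
        indent = "  " * node.depth
        branch = f"[{'+'.join(map(str, node.branch))}] " if node.branch else ""
        head = f"{indent}node {node.node_id} {branch}n={node.n} | {pct}"
        if not node.is_leaf:
            head += (
                f" | split {node.split_var}: chi2={node.chi2:.2f} df={node.df}"
                f" B={node.bonferroni_B} adj p={node.p_adj:.3g}"
            )
        lines.append(head)
        label = f"node {node.node_id}\\nn={node.n}\\n{pct}"
        if not node.is_leaf:
            label += f"\\n{node.split_var}: chi2={node.chi2:.2f}, adj p={node.p_adj:.3g}"
        dot.append(f'  n{node.node_id} [label="{label}"];')
        if node.parent_id is not None:
            edge = "+".join(map(str, node.branch))
            dot.append(f'  n{node.parent_id} -> n{node.node_id} [label="{edge}"];')
    dot.append("}")
    return "\n".join(lines), "\n".join(dot)


class CHAIDClassifier(BaseEstimator, ClassifierMixin):
    """CHAID decision tree with the scikit-learn estimator interface.

    Parameters mirror :class:`ChaidSettings`; ``X`` passed to :meth:`fit`
    should be a DataFrame of categorical (or continuous, auto-binned)
    predictors and ``y`` a binary label vector.

    Attributes (after fit): ``tree_`` (the :class:`ChaidTree`), ``classes_``,
    ``feature_names_in_``.
    """

    def __init__(self, alpha_split=0.05, alpha_merge=0.05, min_parent=30,
                 min_child=10, max_depth=3, bonferroni=True, predictor_types=None,
                 age_bins=10, cv_folds=10, random_state=0):
        self.alpha_split = alpha_split
        self.alpha_merge = alpha_merge
        self.min_parent = min_parent
        self.min_child = min_child
        self.max_depth = max_depth
        self.bonferroni = bonferroni
        self.predictor_types = predictor_types
        self.age_bins = age_bins
        self.cv_folds = cv_folds
        self.random_state = random_state

    def _settings(self) -> ChaidSettings:
        return ChaidSettings(
            alpha_split=self.alpha_split, alpha_merge=self.alpha_merge,
            min_parent=self.min_parent, min_child=self.min_child,
            max_depth=self.max_depth, bonferroni=self.bonferroni,
            predictor_types=self.predictor_types, age_bins=self.age_bins,
            cv_folds=self.cv_folds, seed=self.random_state or 0,
        )

    @staticmethod
    def _as_frame(X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return X
        X = np.asarray(X)
        return pd.DataFrame(X, columns=[f"x{i}" for i in range(X.shape[1])])

    def fit(self, X, y):
        X = self._as_frame(X)
        self.feature_names_in_ = np.asarray(X.columns, dtype=object)
        self.tree_ = grow_tree(X, y, self._settings())
        self.classes_ = np.asarray(self.tree_.classes)
        return self

    def predict_proba(self, X, unseen: str = "error") -> np.ndarray:
        check_is_fitted(self, "tree_")
        X = self._as_frame(X)
        out = np.empty((len(X), len(self.classes_)))
        for i, (_, row) in enumerate(X.iterrows()):
            fractions = self.tree_.predict_proba_one(row.to_dict(), unseen=unseen)
            out[i] = [fractions[c] for c in self.classes_]
        return out

    def predict(self, X, unseen: str = "error") -> np.ndarray:
        proba = self.predict_proba(X, unseen=unseen)
        return self.classes_[np.argmax(proba, axis=1)]

    def cross_validated_risk(self, X, y) -> tuple[float, float]:
        """Stratified k-fold misclassification risk and its standard error;
        also stored on ``tree_`` when the estimator is already fitted."""
        risk, se = cross_validate(self._as_frame(X), y, self._settings())
        if hasattr(self, "tree_"):
            self.tree_.cv_risk, self.tree_.cv_risk_se = risk, se
        return risk, se
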