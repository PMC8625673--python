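"""Lithium-response phenotypes from Alda A/B ratings.

Five operationalizations are computed per subject:

* ``ts`` — Total Score, A minus total B, floored at zero;
* ``alda_cat`` — the original good/non-responder category (GR iff TS >= 7);
* ``a_low_b`` — the A score restricted to subjects with total B < 4
  (others excluded, improving rating reliability at the cost of sample size);
* ``algo_cat`` — a de-novo best-estimate category from a CHAID tree over the
  five B confounder items;
* ``grp`` — the tree's leaf-level probability of good response, dichotomized
  at a configurable cutoff (default 0.62) to produce ``algo_cat``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_is_fitted

from .chaid import CHAIDClassifier, ChaidSettings, ChaidTree, grow_tree
from .cohort import AldaRecord, records_to_frame
from .errors import DegenerateTargetError, InvalidRatingError

__all__ = [
    "GR",
    "NR",
    "DEFAULT_GRP_THRESHOLD",
    "total_score",
    "alda_category",
    "a_low_b",
    "BestEstimateModel",
    "BestEstimateClassifier",
    "fit_best_estimate",
    "grp",
    "algo_category",
    "phenotype_table",
]

logger = logging.getLogger(__name__)

GR = "GR"
NR = "NR"
#: Leaf-probability cutoff above which the best-estimate category is GR.
DEFAULT_GRP_THRESHOLD = 0.62
#: A-scale threshold defining a good responder on the original scheme.
TS_GR_CUTOFF = 7

B_ITEMS = ["b1", "b2", "b3", "b4", "b5"]


def _check_range(name: str, value, low: int, high: int):
    if not low <= value <= high:
        raise InvalidRatingError(f"{name} must be in {low}..{high}, got {value}")


def total_score(a_score: int, b_total: int) -> int:
    """Total Score: A minus total B, reported as zero whenever B > A."""
    _check_range("a_score", a_score, 0, 10)
    _check_range("b_total", b_total, 0, 10)
    return max(0, a_score - b_total)


def alda_category(ts: int) -> str:
    """Original categorization: GR iff TS >= 7, NR otherwise."""
    _check_range("ts", ts, 0, 10)
    return GR if ts >= TS_GR_CUTOFF else NR


def a_low_b(a_score: int, b_total: int):
    """A score restricted to low-confounding subjects (total B < 4);
    returns None (excluded) for subjects with B >= 4."""
    _check_range("a_score", a_score, 0, 10)
    _check_range("b_total", b_total, 0, 10)
    return a_score if b_total < 4 else None


class BestEstimateClassifier(BaseEstimator, ClassifierMixin):
    """CHAID-based best-estimate lithium-response classifier.

    Fits a CHAID tree of the five B confounder items against a provisional
    binary response label and predicts GR when the leaf GR fraction exceeds
    ``grp_threshold`` (strictly).

    Attributes after fit: ``chaid_``, ``tree_``, ``classes_``.
    """

    def __init__(self, grp_threshold: float = DEFAULT_GRP_THRESHOLD,
                 settings: ChaidSettings | None = None):
        self.grp_threshold = grp_threshold
        self.settings = settings

    def fit(self, X: pd.DataFrame, y):
        y = np.asarray(y, dtype=object)
        if len(set(y)) < 2:
            raise DegenerateTargetError(
                "provisional response labels contain a single class; no tree can be fitted"
            )
        settings = self.settings or ChaidSettings()
        self.chaid_ = CHAIDClassifier(
            alpha_split=settings.alpha_split, alpha_merge=settings.alpha_merge,
            min_parent=settings.min_parent, min_child=settings.min_child,
            max_depth=settings.max_depth, bonferroni=settings.bonferroni,
            predictor_types={item: "ordinal" for item in X.columns},
            age_bins=settings.age_bins, cv_folds=settings.cv_folds,
            random_state=settings.seed,
        ).fit(X, y)
        self.tree_ = self.chaid_.tree_
        self.classes_ = np.array([NR, GR], dtype=object)
        return self

    def predict_proba(self, X) -> np.ndarray:
        """Column order [P(NR), P(GR)]; P(GR) is the routed leaf GR fraction."""
        check_is_fitted(self, "chaid_")
        raw = self.chaid_.predict_proba(X)
        gr_col = list(self.chaid_.classes_).index(GR)
        p_gr = raw[:, gr_col]
        return np.column_stack([1 - p_gr, p_gr])

    def grp(self, X) -> np.ndarray:
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return np.where(self.grp(X) > self.grp_threshold, GR, NR)


@dataclass
class BestEstimateModel:
    """A fitted best-estimate model: the CHAID tree over B items, the GRp
    cutoff, and a description of the provisional training label."""

    classifier: BestEstimateClassifier
    grp_threshold: float = DEFAULT_GRP_THRESHOLD
    provisional_label_rule: str = "GR iff a_score >= 7"

    @property
    def tree(self) -> ChaidTree:
        return self.classifier.tree_


def fit_best_estimate(records: list[AldaRecord],
                      settings: ChaidSettings | None = None,
                      grp_threshold: float = DEFAULT_GRP_THRESHOLD) -> BestEstimateModel:
    """Train the de-novo best-estimate model on a cohort's B-item ratings.

    The provisional target is GR iff the raw A score is >= 7 (the A scale's
    own good-response band); candidate predictors are B1..B5 as ordinals.
    Identical records and settings always yield an identical tree.
    """
    if len(records) < 40:
        raise DegenerateTargetError("need at least 40 records to fit the best-estimate model")
    df = records_to_frame(records)
    X = df[B_ITEMS]
    y = np.where(df["a_score"] >= TS_GR_CUTOFF, GR, NR)
    clf = BestEstimateClassifier(grp_threshold=grp_threshold, settings=settings)
    clf.fit(X, y)
    return BestEstimateModel(classifier=clf, grp_threshold=grp_threshold)


def grp(model: BestEstimateModel, record: AldaRecord) -> float:
    """Leaf-level probability of good response for one subject.

    Raises RoutingError for a B-item pattern that no tree branch covers
    (silent imputation would distort downstream concordance rates).
    """
    fractions = model.tree.predict_proba_one(
        {item: getattr(record, item) for item in B_ITEMS}, unseen="error"
    )
    return float(fractions.get(GR, 0.0))


def algo_category(grp_value: float, threshold: float = DEFAULT_GRP_THRESHOLD) -> str:
    """Best-estimate category: GR iff GRp strictly exceeds the cutoff."""
    if not 0.0 <= grp_value <= 1.0:
        raise InvalidRatingError(f"grp must be in [0, 1], got {grp_value}")
    return GR if grp_value > threshold else NR


def phenotype_table(records: list[AldaRecord], model: BestEstimateModel) -> pd.DataFrame:
    """Derive all five phenotypes for every subject.

    Returns a DataFrame with columns subject_id, b_total, ts, alda_cat,
    a_low_b (nullable: <NA> for excluded subjects), algo_cat, grp.
    """
    rows = []
    for r in records:
        ts = total_score(r.a_score, r.b_total)
        grp_value = grp(model, r)
        rows.append({
            "subject_id": r.subject_id,
            "b_total": r.b_total,
            "ts": ts,
            "alda_cat": alda_category(ts),
            "a_low_b": a_low_b(r.a_score, r.b_total),
            "algo_cat": algo_category(grp_value, model.grp_threshold),
            "grp": grp_value,
        })
    df = pd.DataFrame(rows)
    df["a_low_b"] = df["a_low_b"].astype("Int64")
    n_gr = int((df["alda_cat"] == GR).sum())
    n_algo_gr = int((df["algo_cat"] == GR).sum())
    n_excluded = int(df["a_low_b"].isna().sum())
    logger.info(
        "phenotype table: n=%d, Alda Cats GR=%d, Algo GR=%d, A/Low B excluded=%d",
        len(df), n_gr, n_algo_gr, n_excluded,
    )
    return df
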