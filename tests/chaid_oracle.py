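"""Exhaustive-partition oracle for CHAID split selection.

Independently of the greedy merge, enumerate every admissible grouping of a
predictor's observed categories (all set partitions for nominals, contiguous
groupings for ordinals with a freely-floating missing category), score each
grouping by its Bonferroni-adjusted chi-square p, and pick the predictor with
the globally smallest adjusted p.  Used as a cross-check of the greedy
splitter on small instances.
"""

import itertools
import math

import numpy as np
import pandas as pd
from scipy import stats

from lithopheno.chaid import MISSING, bonferroni_multiplier


def set_partitions(items):
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1:]
        yield [[first]] + part


def contiguous_partitions(items):
    items = list(items)
    n = len(items)
    for r in range(1, n + 1):
        for cuts in itertools.combinations(range(1, n), r - 1):
            bounds = (0,) + cuts + (n,)
            yield [items[bounds[i]:bounds[i + 1]] for i in range(r)]


def ordinal_partitions_with_floating(solid, has_missing):
    """Contiguous groupings of the solid categories, with the missing
    category either forming its own group or attached to any one group."""
    for part in contiguous_partitions(solid):
        if not has_missing:
            yield part
            continue
        yield part + [[MISSING]]
        for i in range(len(part)):
            yield [g + [MISSING] if j == i else list(g) for j, g in enumerate(part)]


def _chi2_p(table):
    t = np.asarray(table, dtype=float)
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        return 0.0, 1.0
    chi2, p, _, _ = stats.chi2_contingency(t, correction=False)
    return float(chi2), float(p)


def oracle_best_split(values_by_predictor, types_by_predictor, y, settings, classes):
    """Globally best (predictor, adjusted p) over all admissible partitions.

    Mirrors the splitter's admissibility rules: >= 2 groups, every group at
    least min_child, adjusted p = min(1, p * B) with B counting groupings of
    the observed categories into the partition's group count.
    """
    y = np.asarray(y)
    best_name, best_p = None, None
    for name in sorted(values_by_predictor):
        v = np.asarray(values_by_predictor[name], dtype=object)
        ptype = types_by_predictor[name]
        observed = list(pd.unique(v))
        if len(observed) < 2:
            continue
        has_missing = MISSING in observed
        if ptype == "ordinal":
            solid = sorted([c for c in observed if c != MISSING])
            parts = ordinal_partitions_with_floating(solid, has_missing)
        else:
            parts = set_partitions(observed)
        local_best = None
        for part in parts:
            if len(part) < 2:
                continue
            sizes = [np.isin(v, g).sum() for g in part]
            if min(sizes) < settings.min_child:
                continue
            table = [[(y[np.isin(v, g)] == c).sum() for c in classes] for g in part]
            _, p_raw = _chi2_p(table)
            B = 1
            if settings.bonferroni:
                B = bonferroni_multiplier(len(observed), len(part), type=ptype,
                                          floating=ptype == "ordinal" and has_missing)
            p_adj = min(1.0, p_raw * B)
            if local_best is None or p_adj < local_best:
                local_best = p_adj
        if local_best is None:
            continue
        if best_p is None or (local_best, name) < (best_p, best_name):
            best_name, best_p = name, local_best
    if best_p is None or best_p > settings.alpha_split:
        return None
    return best_name, best_p
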