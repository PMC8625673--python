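"""Agreement between original and machine-learning response phenotypes.

The original rating is treated as the gold standard: a false positive is a
subject classified GR by the new algorithm but not by the original rating.
Continuous phenotypes are dichotomized at their published cutoffs (7 on the
A/TS scales, the GRp threshold on probabilities) before computing PPV, NPV,
overall accuracy and the discordance rate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConsistencyError
from .phenotypes import DEFAULT_GRP_THRESHOLD, GR, NR, TS_GR_CUTOFF

__all__ = ["ConfusionSummary", "confusion", "compare_phenotype_pairs"]


@dataclass(frozen=True)
class ConfusionSummary:
    """2x2 confusion counts with predictive values; positive class is GR.

    ppv/npv are None (a distinguished undefined marker, never 0 or 1) when
    their denominator is zero.
    """

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def ppv(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def npv(self) -> float | None:
        d = self.tn + self.fn
        return self.tn / d if d else None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def discordance(self) -> float:
        return (self.fp + self.fn) / self.n

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn, "n": self.n,
            "ppv": self.ppv, "npv": self.npv,
            "accuracy": self.accuracy, "discordance": self.discordance,
        }


def confusion(gold, predicted) -> ConfusionSummary:
    """Cross-tabulate predicted GR/NR labels against gold-standard labels."""
    gold = np.asarray(gold, dtype=object)
    predicted = np.asarray(predicted, dtype=object)
    if gold.shape != predicted.shape or gold.size == 0:
        raise ConsistencyError("gold and predicted labels must have equal non-zero length")
    bad = (set(gold) | set(predicted)) - {GR, NR}
    if bad:
        raise ConsistencyError(f"labels must be GR/NR, found {sorted(bad, key=str)}")
    return ConfusionSummary(
        tp=int(((gold == GR) & (predicted == GR)).sum()),
        fp=int(((gold == NR) & (predicted == GR)).sum()),
        fn=int(((gold == GR) & (predicted == NR)).sum()),
        tn=int(((gold == NR) & (predicted == NR)).sum()),
    )


def compare_phenotype_pairs(phenotypes: pd.DataFrame,
                            grp_threshold: float = DEFAULT_GRP_THRESHOLD
                            ) -> dict[str, ConfusionSummary]:
    """The three published phenotype comparisons, gold standard first:

    * ``alda_vs_algo`` — original categories vs best-estimate categories;
    * ``ts_vs_grp`` — TS dichotomized at >= 7 vs GRp > threshold (the gold
      labels here coincide with the original categories by construction);
    * ``alowb_vs_grp`` — among subjects with total B < 4 only, the A score
      dichotomized at >= 7 vs GRp > threshold.
    """
    df = phenotypes
    out: dict[str, ConfusionSummary] = {}

    out["alda_vs_algo"] = confusion(df["alda_cat"], df["algo_cat"])

    ts_gold = np.where(df["ts"] >= TS_GR_CUTOFF, GR, NR)
    grp_pred = np.where(df["grp"] > grp_threshold, GR, NR)
    assert (ts_gold == df["alda_cat"].to_numpy()).all(), (
        "TS >= 7 dichotomization must reproduce the original categories"
    )
    out["ts_vs_grp"] = confusion(ts_gold, grp_pred)

    low_b = df["a_low_b"].notna()
    if low_b.sum() == 0:
        warnings.warn("no subjects with total B < 4; skipping the A/Low B comparison",
                      stacklevel=2)
    else:
        sub = df[low_b]
        alowb_gold = np.where(sub["a_low_b"].astype(int) >= TS_GR_CUTOFF, GR, NR)
        out["alowb_vs_grp"] = confusion(
            alowb_gold, np.where(sub["grp"] > grp_threshold, GR, NR)
        )
    return out
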