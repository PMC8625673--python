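"""Single-SNP association tests between genotypes and response phenotypes.

Genotypes enter under a dominant (carrier vs non-carrier) or codominant
(three genotype groups) coding.  Categorical phenotypes are tested with the
Pearson chi-square (Fisher's exact on sparse 2x2 tables); continuous
phenotypes with Wilcoxon rank-sum (exact enumeration at small n, otherwise
the tie-corrected normal approximation) or Kruskal-Wallis for three groups.
Significance is tiered at p < 0.017 (corrected for 3 genes) and p < 0.003
(corrected for 3 genes x 5 phenotypes).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateCodingError, InvalidParameterError
from .qc import GenotypeTable

__all__ = [
    "AssociationResult",
    "code_genotype",
    "assoc_categorical",
    "assoc_continuous",
    "association_scan",
    "DEFAULT_CODINGS",
    "GENE_TIER_P",
    "FULL_TIER_P",
]

GENE_TIER_P = 0.017
FULL_TIER_P = 0.003

#: Per-gene codings used in the published scan: minor-allele-dominant for
#: TIMELESS and PPARGC1A, codominant (three genotype groups) for RORA.
DEFAULT_CODINGS = {"TIMELESS": "dominant", "PPARGC1A": "dominant", "RORA": "codominant"}

CARRIER, NON_CARRIER = "carrier", "non-carrier"


def _tier(p: float, gene_p: float, full_p: float) -> str:
    if p < full_p:
        return "fully-corrected"
    if p < gene_p:
        return "gene-corrected"
    return "none"


@dataclass(frozen=True)
class AssociationResult:
    snp_id: str
    gene: str
    phenotype: str
    coding: str
    test: str
    statistic: float
    df: int | None
    p: float
    n: int
    tier: str

    @property
    def neglog10p(self) -> float:
        return -math.log10(self.p)

    @classmethod
    def build(cls, *, snp_id="", gene="", phenotype="", coding="", test, statistic,
              df, p, n, gene_p=GENE_TIER_P, full_p=FULL_TIER_P) -> "AssociationResult":
        return cls(snp_id=snp_id, gene=gene, phenotype=phenotype, coding=coding,
                   test=test, statistic=float(statistic), df=df, p=float(p), n=int(n),
                   tier=_tier(p, gene_p, full_p))


def code_genotype(dosages, model: str) -> pd.Series:
    """Map minor-allele dosages to group labels; missing calls are dropped.

    dominant: dosage >= 1 -> "carrier", 0 -> "non-carrier".
    codominant: the dosage itself (0, 1, 2) as three groups.
    A coding leaving fewer than two non-empty groups raises.
    """
    s = pd.Series(np.asarray(dosages, dtype=float)) if not isinstance(dosages, pd.Series) \
        else dosages.astype(float)
    s = s.dropna()
    if model == "dominant":
        labels = s.map(lambda d: CARRIER if d >= 1 else NON_CARRIER)
    elif model == "codominant":
        labels = s.map(lambda d: str(int(d)))
    else:
        raise InvalidParameterError(f"coding must be dominant or codominant, got {model!r}")
    if labels.nunique() < 2:
        raise DegenerateCodingError(
            f"{model} coding leaves {labels.nunique()} non-empty group(s)"
        )
    return labels


def assoc_categorical(labels, groups, **meta) -> AssociationResult:
    """Group x class Pearson chi-square; Fisher's exact replaces it on 2x2
    tables with any expected count below 5."""
    table = pd.crosstab(pd.Series(np.asarray(groups, dtype=object), name="group"),
                        pd.Series(np.asarray(labels, dtype=object), name="class"))
    obs = table.to_numpy(dtype=float)
    if obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DegenerateCodingError("need >= 2 groups and >= 2 classes for a chi-square test")
    n = int(obs.sum())
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if obs.shape == (2, 2) and (expected < 5).any():
        odds, p = stats.fisher_exact(obs, alternative="two-sided")
        return AssociationResult.build(test="fisher-exact", statistic=odds, df=None,
                                       p=p, n=n, **meta)
    chi2, p, df, _ = stats.chi2_contingency(obs, correction=False)
    return AssociationResult.build(test="pearson-chi2", statistic=chi2, df=df,
                                   p=p, n=n, **meta)


def _exact_rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact rank-sum p by full enumeration of group assignments,
    with midranks for ties."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1, total = len(x), len(pooled)
    w_obs = ranks[:n1].sum()
    mu = n1 * (total + 1) / 2.0
    dev = abs(w_obs - mu)
    count = denom = 0
    for combo in itertools.combinations(range(total), n1):
        w = ranks[list(combo)].sum()
        denom += 1
        if abs(w - mu) >= dev - 1e-9:
            count += 1
    return count / denom


def assoc_continuous(values, groups, exact_max_n: int = 10, **meta) -> AssociationResult:
    """Non-parametric location test of a continuous phenotype across groups.

    Two groups: Wilcoxon rank-sum, exact by enumeration when both group
    sizes are <= exact_max_n (valid under ties), else the two-sided normal
    approximation with tie correction.  Three or more groups:
    Kruskal-Wallis with tie correction.  All-identical values give p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups, dtype=object)
    ok = ~np.isnan(values)
    values, groups = values[ok], groups[ok]
    levels = sorted(set(groups), key=str)
    samples = [values[groups == g] for g in levels]
    if len(samples) < 2 or any(len(s) == 0 for s in samples):
        raise DegenerateCodingError("need >= 2 non-empty groups")
    n = len(values)
    if np.ptp(values) == 0:
        return AssociationResult.build(test="degenerate", statistic=0.0, df=None,
                                       p=1.0, n=n, **meta)
    if len(samples) == 2:
        x, y = samples
        if len(x) <= exact_max_n and len(y) <= exact_max_n:
            p = _exact_rank_sum_p(x, y)
            u = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                   use_continuity=False).statistic
            return AssociationResult.build(test="rank-sum-exact", statistic=u, df=None,
                                           p=p, n=n, **meta)
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic",
                                 use_continuity=False)
        return AssociationResult.build(test="rank-sum", statistic=res.statistic,
                                       df=None, p=res.pvalue, n=n, **meta)
    stat, p = stats.kruskal(*samples)
    return AssociationResult.build(test="kruskal-wallis", statistic=stat,
                                   df=len(samples) - 1, p=p, n=n, **meta)


#: phenotype column -> (kind, restrict-to-low-B)
PHENOTYPE_KINDS = {
    "ts": ("continuous", False),
    "alda_cat": ("categorical", False),
    "a_low_b": ("continuous", True),
    "algo_cat": ("categorical", False),
    "grp": ("continuous", False),
}


def association_scan(phenotypes: pd.DataFrame, genotypes: GenotypeTable,
                     codings: dict[str, str] | None = None,
                     gene_p: float = GENE_TIER_P, full_p: float = FULL_TIER_P
                     ) -> pd.DataFrame:
    """Test every phenotype against every SNP under its gene's coding.

    ``phenotypes`` is the table from :func:`lithopheno.phenotypes.phenotype_table`
    (indexed or keyed by subject_id); subjects are intersected with the
    genotype table.  The A/Low B phenotype is tested on its B < 4 subsample
    only.  Returns one row per SNP x phenotype with the statistic, p,
    -log10(p) and significance tier.
    """
    missing_cols = set(PHENOTYPE_KINDS) - set(phenotypes.columns)
    if missing_cols:
        raise InvalidParameterError(f"phenotype table lacks columns {sorted(missing_cols)}")
    codings = {**DEFAULT_CODINGS, **(codings or {})}
    pheno = phenotypes.set_index("subject_id") if "subject_id" in phenotypes.columns \
        else phenotypes
    common = [s for s in genotypes.subject_ids if s in pheno.index]
    pheno = pheno.loc[common]

    rows = []
    for snp_id in genotypes.snp_ids:
        gene = genotypes.genes.get(snp_id, "")
        coding = codings.get(gene, "codominant")
        dosages = genotypes.dosages.loc[common, snp_id]
        group_labels = code_genotype(dosages, coding)
        for name, (kind, low_b_only) in PHENOTYPE_KINDS.items():
            values = pheno[name]
            keep = group_labels.index
            if low_b_only:
                keep = keep[values.loc[keep].notna()]
            groups = group_labels.loc[keep]
            meta = dict(snp_id=snp_id, gene=gene, phenotype=name, coding=coding,
                        gene_p=gene_p, full_p=full_p)
            try:
                if kind == "categorical":
                    result = assoc_categorical(values.loc[keep], groups, **meta)
                else:
                    result = assoc_continuous(values.loc[keep].astype(float), groups, **meta)
            except DegenerateCodingError:
                # e.g. a single-class phenotype: report an explicit undefined
                # marker row rather than dropping the cell from the scan
                result = AssociationResult.build(test="undefined", statistic=np.nan,
                                                 df=None, p=np.nan, n=len(keep), **meta)
            rows.append({
                "snp_id": result.snp_id, "gene": result.gene,
                "phenotype": result.phenotype, "coding": result.coding,
                "test": result.test, "statistic": result.statistic, "df": result.df,
                "p": result.p, "neglog10p": result.neglog10p, "n": result.n,
                "tier": result.tier,
            })
    return pd.DataFrame(rows)
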