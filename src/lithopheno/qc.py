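"""Genotype containers, quality control and per-gene best-SNP selection.

Implements the candidate-gene QC pipeline: minor-allele frequency, per-SNP
and per-sample call rates, heterozygosity outliers, Hardy-Weinberg tests
(asymptotic chi-square and exact by enumeration), LD-based pruning at
r^2 > 0.05 and selection of the SNP most strongly associated with the
continuous lithium-response score within each gene.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptySelectionError, InvalidParameterError, ParseError

__all__ = [
    "GenotypeTable",
    "QCThresholds",
    "SNPQCReport",
    "HweResult",
    "read_genotypes",
    "maf",
    "hwe_test",
    "call_rates",
    "het_outliers",
    "apply_qc",
    "ld_r2",
    "select_best_snp",
]


@dataclass
class GenotypeTable:
    """Subjects x SNPs minor-allele dosage matrix with missingness as NaN.

    ``dosages`` rows are subjects, columns SNP ids, values in {0, 1, 2, NaN}.
    ``genes`` maps SNP id to gene label; ``alleles`` maps SNP id to a
    (major, minor) allele pair when known.
    """

    dosages: pd.DataFrame
    genes: dict[str, str] = field(default_factory=dict)
    alleles: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self):
        values = self.dosages.to_numpy(dtype=float)
        valid = np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0))
        if not valid.all():
            bad = values[~valid][0]
            raise InvalidParameterError(f"dosages must be 0, 1, 2 or missing; found {bad}")

    @property
    def subject_ids(self) -> list[str]:
        return list(self.dosages.index)

    @property
    def snp_ids(self) -> list[str]:
        return list(self.dosages.columns)

    def subset(self, subjects=None, snps=None) -> "GenotypeTable":
        df = self.dosages
        if subjects is not None:
            df = df.loc[list(subjects)]
        if snps is not None:
            df = df[list(snps)]
        return GenotypeTable(
            dosages=df.copy(),
            genes={s: g for s, g in self.genes.items() if s in df.columns},
            alleles={s: a for s, a in self.alleles.items() if s in df.columns},
        )


def _read_dosage_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA", "."])
    values = df.to_numpy(dtype=float)
    bad = ~(np.isnan(values) | np.isin(values, (0.0, 1.0, 2.0)))
    if bad.any():
        row = int(np.argwhere(bad)[0][0])
        raise ParseError("dosage values must be 0, 1, 2 or NA", line_number=row + 2)
    return df.astype(float)


def _read_vcf(path) -> tuple[pd.DataFrame, dict, dict]:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    data, genes, alleles = {}, {}, {}
    for variant in vcf:
        snp_id = variant.ID or f"{variant.CHROM}:{variant.POS}"
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = np.asarray(variant.gt_types, dtype=float)
        dosage = np.select([gt == 0, gt == 1, gt == 3], [0.0, 1.0, 2.0], default=np.nan)
        data[snp_id] = dosage
        gene = dict(variant.INFO).get("GENE")
        if gene is not None:
            genes[snp_id] = str(gene)
        alt = variant.ALT[0] if variant.ALT else "."
        alleles[snp_id] = (variant.REF, alt)
    df = pd.DataFrame(data, index=pd.Index(samples, name="subject_id"))
    return df, genes, alleles


def read_genotypes(path, format: str | None = None, gene_map: dict[str, str] | None = None,
                   recode: str = "minor") -> GenotypeTable:
    """Read a dosage TSV or a VCF into a :class:`GenotypeTable`.

    With ``recode="minor"`` (default) the dosage is re-expressed as the count
    of the *observed* minor allele: any SNP whose counted-allele frequency
    exceeds 0.5 is flipped (dosage -> 2 - dosage) and its allele pair swapped,
    so downstream MAF and codings never depend on file allele order.
    ``recode="alt"`` keeps the literal ALT-allele count (exact round-trips).
    """
    path = Path(path)
    if format is None:
        format = "vcf" if path.suffix.lower() == ".vcf" else "tsv"
    if format == "tsv":
        df = _read_dosage_tsv(path)
        genes, alleles = {}, {}
    elif format == "vcf":
        df, genes, alleles = _read_vcf(path)
    else:
        raise InvalidParameterError(f"unknown genotype format {format!r}")
    if gene_map:
        genes = {**genes, **gene_map}
    if recode == "minor":
        for snp in df.columns:
            col = df[snp]
            n_called = col.notna().sum()
            if n_called and float(col.sum()) / (2 * n_called) > 0.5:
                df[snp] = 2.0 - col
                if snp in alleles:
                    alleles[snp] = (alleles[snp][1], alleles[snp][0])
    elif recode != "alt":
        raise InvalidParameterError("recode must be 'minor' or 'alt'")
    return GenotypeTable(dosages=df, genes=genes, alleles=alleles)


def maf(dosages) -> float:
    """Minor-allele frequency among non-missing calls; NaN if all missing."""
    d = np.asarray(dosages, dtype=float)
    d = d[~np.isnan(d)]
    if d.size == 0:
        return float("nan")
    freq = d.sum() / (2 * d.size)
    return float(min(freq, 1.0 - freq))


class HweResult(NamedTuple):
    chi2: float
    p_chi2: float
    p_exact: float


def _hwe_exact(n_hom_minor: int, n_het: int, n_hom_major: int) -> float:
    """Exact Hardy-Weinberg p by full enumeration of heterozygote counts
    conditional on the observed allele counts (two-sided, by probability
    ordering)."""
    n = n_hom_minor + n_het + n_hom_major
    n_minor = 2 * n_hom_minor + n_het
    lgam = math.lgamma

    def log_prob(het: int) -> float:
        hom_min = (n_minor - het) // 2
        hom_maj = n - hom_min - het
        return (
            het * math.log(2)
            + lgam(n + 1) - lgam(hom_min + 1) - lgam(het + 1) - lgam(hom_maj + 1)
            + lgam(n_minor + 1) + lgam(2 * n - n_minor + 1) - lgam(2 * n + 1)
        )

    hets = range(n_minor % 2, min(n_minor, 2 * n - n_minor) + 1, 2)
    log_probs = {h: log_prob(h) for h in hets}
    m = max(log_probs.values())
    total = sum(math.exp(v - m) for v in log_probs.values())
    obs = log_probs[n_het]
    tail = sum(math.exp(v - m) for v in log_probs.values() if v <= obs + 1e-12)
    return min(1.0, tail / total)


def hwe_test(hom_minor: int, het: int, hom_major: int) -> HweResult:
    """Test genotype counts against Hardy-Weinberg proportions.

    Returns the 1-df chi-square statistic and p against expectations derived
    from the observed allele frequency, plus an exact p by enumeration.
    Monomorphic SNPs return p = 1 by convention.
    """
    counts = np.array([hom_minor, het, hom_major], dtype=float)
    if np.any(counts < 0) or counts.sum() < 1:
        raise InvalidParameterError("genotype counts must be non-negative with total >= 1")
    n = counts.sum()
    q = (2 * hom_minor + het) / (2 * n)
    if q == 0.0 or q == 1.0:
        return HweResult(0.0, 1.0, 1.0)
    expected = n * np.array([q**2, 2 * q * (1 - q), (1 - q) ** 2])
    chi2 = float(((counts - expected) ** 2 / expected).sum())
    p_chi2 = float(stats.chi2.sf(chi2, df=1))
    p_exact = _hwe_exact(int(hom_minor), int(het), int(hom_major))
    return HweResult(chi2, p_chi2, p_exact)


def call_rates(table: GenotypeTable) -> tuple[pd.Series, pd.Series]:
    """Fraction of non-missing calls per SNP and per sample."""
    called = table.dosages.notna()
    per_snp = called.mean(axis=0)
    per_sample = called.mean(axis=1)
    per_snp.name, per_sample.name = "call_rate", "call_rate"
    return per_snp, per_sample


def het_outliers(table: GenotypeTable, n_sd: float = 3.0) -> pd.DataFrame:
    """Per-sample heterozygosity with mean +/- n_sd outlier flags.

    Zero variance across samples yields no flags.
    """
    if len(table.subject_ids) < 3:
        raise InvalidParameterError("heterozygosity outlier detection needs >= 3 samples")
    het = (table.dosages == 1.0).sum(axis=1) / table.dosages.notna().sum(axis=1)
    sd = het.std(ddof=1)
    if not np.isfinite(sd) or sd == 0:
        flags = pd.Series(False, index=het.index)
    else:
        m = het.mean()
        flags = (het < m - n_sd * sd) | (het > m + n_sd * sd)
    return pd.DataFrame({"het_rate": het, "het_outlier": flags})


@dataclass(frozen=True)
class QCThresholds:
    """Inclusion thresholds: MAF >= 5%, per-SNP call rate >= 97%, per-sample
    call rate >= 90%, heterozygosity within mean +/- 3 sd.  HWE exclusion is
    off by default (HWE is reported, and checked on the final SNPs, rather
    than used as a hard filter)."""

    maf_min: float = 0.05
    snp_call_rate_min: float = 0.97
    sample_call_rate_min: float = 0.90
    het_sd: float = 3.0
    hwe_p_min: float | None = None


@dataclass
class SNPQCReport:
    snp_table: pd.DataFrame
    sample_table: pd.DataFrame
    thresholds: QCThresholds


def apply_qc(table: GenotypeTable, thresholds: QCThresholds = QCThresholds()
             ) -> tuple[GenotypeTable, SNPQCReport]:
    """Apply all QC filters in a single pass over the input table.

    All statistics (MAF, call rates, heterozygosity, HWE) are computed on the
    full input, then failing samples and SNPs are dropped together; this makes
    the operation idempotent on already-filtered tables.
    """
    snp_cr, sample_cr = call_rates(table)
    het = het_outliers(table, n_sd=thresholds.het_sd)

    rows = []
    for snp in table.snp_ids:
        d = table.dosages[snp].to_numpy(dtype=float)
        d = d[~np.isnan(d)]
        counts = [(d == 2).sum(), (d == 1).sum(), (d == 0).sum()]
        hwe = hwe_test(*counts) if d.size else HweResult(np.nan, np.nan, np.nan)
        snp_maf = maf(d) if d.size else np.nan
        rows.append({
            "snp_id": snp,
            "gene": table.genes.get(snp, ""),
            "maf": snp_maf,
            "call_rate": snp_cr[snp],
            "hwe_chi2": hwe.chi2,
            "hwe_p": hwe.p_chi2,
            "hwe_p_exact": hwe.p_exact,
            "pass_maf": bool(snp_maf >= thresholds.maf_min) if np.isfinite(snp_maf) else False,
            "pass_call_rate": bool(snp_cr[snp] >= thresholds.snp_call_rate_min),
            "pass_hwe": True if thresholds.hwe_p_min is None
                        else bool(hwe.p_chi2 >= thresholds.hwe_p_min),
        })
    snp_table = pd.DataFrame(rows).set_index("snp_id")
    snp_table["pass"] = snp_table[["pass_maf", "pass_call_rate", "pass_hwe"]].all(axis=1)

    sample_table = pd.DataFrame({
        "call_rate": sample_cr,
        "het_rate": het["het_rate"],
        "het_outlier": het["het_outlier"],
    })
    sample_table["pass"] = (
        (sample_table["call_rate"] >= thresholds.sample_call_rate_min)
        & ~sample_table["het_outlier"]
    )

    keep_snps = snp_table.index[snp_table["pass"]]
    keep_samples = sample_table.index[sample_table["pass"]]
    filtered = table.subset(subjects=keep_samples, snps=keep_snps)
    if filtered.dosages.empty:
        warnings.warn("quality control removed every SNP or every sample", stacklevel=2)
    return filtered, SNPQCReport(snp_table, sample_table, thresholds)


def ld_r2(dosages_a, dosages_b) -> float:
    """Squared Pearson correlation over pairwise-complete subjects; NaN when
    either vector has zero variance."""
    a = np.asarray(dosages_a, dtype=float)
    b = np.asarray(dosages_b, dtype=float)
    ok = ~(np.isnan(a) | np.isnan(b))
    a, b = a[ok], b[ok]
    if a.size < 2:
        raise InvalidParameterError("need >= 2 pairwise-complete calls for LD r^2")
    if a.std() == 0 or b.std() == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _kruskal_p(dosages: np.ndarray, phenotype: np.ndarray) -> float:
    """Non-parametric codominant single-SNP association p (Kruskal-Wallis)."""
    ok = ~(np.isnan(dosages) | np.isnan(phenotype))
    d, y = dosages[ok], phenotype[ok]
    groups = [y[d == g] for g in (0.0, 1.0, 2.0) if (d == g).any()]
    if len(groups) < 2:
        return 1.0
    try:
        return float(stats.kruskal(*groups).pvalue)
    except ValueError:  # all values identical
        return 1.0


def select_best_snp(table: GenotypeTable, gene: str, phenotype: pd.Series,
                    r2_threshold: float = 0.05) -> str:
    """Select the gene's proxy SNP: prune LD pairs at r^2 > threshold keeping
    the more associated member, then return the SNP with the smallest
    non-parametric association p against the phenotype (ties broken by id).

    Note this "best SNP" selection optimises significance and is therefore
    selection-biased by construction.
    """
    snps = [s for s in table.snp_ids if table.genes.get(s) == gene]
    if not snps:
        raise EmptySelectionError(f"no SNPs available for gene {gene!r}")
    y = phenotype.reindex(table.subject_ids).to_numpy(dtype=float)
    pvals = {
        s: _kruskal_p(table.dosages[s].to_numpy(dtype=float), y) for s in snps
    }
    kept: list[str] = []
    for s in sorted(snps, key=lambda s: (pvals[s], s)):
        in_ld = False
        for k in kept:
            r2 = ld_r2(table.dosages[s], table.dosages[k])
            if np.isfinite(r2) and r2 > r2_threshold:
                in_ld = True
                break
        if not in_ld:
            kept.append(s)
    return kept[0]
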