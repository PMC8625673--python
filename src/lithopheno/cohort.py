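"""Synthetic bipolar-disorder cohort generator.

Draws cohorts with the statistical structure the downstream analysis assumes:
Alda A scores approximately Normal and discretized to the 0-10 scale, five
B-scale confounder items with configurable category prevalences, demographics,
and candidate-SNP genotypes in Hardy-Weinberg equilibrium with optional
planted additive genotype effects on the A score.  Every draw is reproducible
from a single integer seed via a fixed stream-splitting scheme.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConsistencyError, InvalidParameterError
from .qc import GenotypeTable

__all__ = [
    "SnpSpec",
    "CohortParams",
    "AldaRecord",
    "sample_genotypes",
    "generate_cohort",
    "write_cohort",
    "records_to_frame",
    "frame_to_records",
    "read_cohort",
]

#: Printed genotype counts for the three candidate circadian SNPs; minor
#: allele frequencies are derived by allele counting (RORA is exactly 0.5).
TABLE1_GENOTYPE_COUNTS = {
    "rs17204910": {"CC": 34, "TC": 88, "TT": 34},   # RORA
    "rs2932965": {"AA": 23, "AG": 79, "GG": 53},    # PPARGC1A
    "rs774045": {"AA": 1, "AG": 45, "GG": 110},     # TIMELESS
}


@dataclass(frozen=True)
class SnpSpec:
    """One simulated SNP: id, gene label, minor-allele frequency and alleles."""

    snp_id: str
    gene: str
    maf: float
    major_allele: str = "A"
    minor_allele: str = "B"

    def __post_init__(self):
        if not 0.0 <= self.maf <= 1.0:
            raise InvalidParameterError(
                f"minor-allele frequency must be in [0, 1], got {self.maf}"
            )


def _default_snp_specs() -> list[SnpSpec]:
    return [
        SnpSpec("rs17204910", "RORA", 0.5, major_allele="T", minor_allele="C"),
        SnpSpec("rs2932965", "PPARGC1A", 125 / 310, major_allele="G", minor_allele="A"),
        SnpSpec("rs774045", "TIMELESS", 47 / 312, major_allele="G", minor_allele="A"),
    ]


def _default_b_item_probs() -> np.ndarray:
    # Published prevalences of B-item raw scores 0:1:2, normalised to sum 1.
    counts = np.array(
        [
            [112, 45, 8],
            [100, 57, 8],
            [122, 15, 28],
            [18, 140, 7],
            [57, 63, 45],
        ],
        dtype=float,
    )
    return counts / counts.sum(axis=1, keepdims=True)


@dataclass
class CohortParams:
    """Simulation parameters; defaults mirror the study sample (n=164).

    The A score is drawn Normal(a_mean, a_sd), shifted additively by
    ``effect_map[snp] * dosage`` for every configured SNP effect, rounded
    half-away-from-zero and clipped to [0, 10].  B items are drawn from the
    per-item categorical distributions ``b_item_probs`` independently of the
    A score.  Genotypes are HWE draws masked missing at ``missing_rate_geno``.
    """

    n_subjects: int = 164
    female_fraction: float = 0.60
    age_mean: float = 44.70
    age_sd: float = 12.29
    a_mean: float = 6.33
    a_sd: float = 2.99
    b_item_probs: np.ndarray = field(default_factory=_default_b_item_probs)
    snp_specs: list[SnpSpec] = field(default_factory=_default_snp_specs)
    effect_map: dict[str, float] = field(default_factory=dict)
    missing_rate_geno: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise InvalidParameterError("n_subjects must be >= 1")
        probs = np.asarray(self.b_item_probs, dtype=float)
        if probs.shape != (5, 3):
            raise InvalidParameterError("b_item_probs must be 5 rows of 3 probabilities")
        if np.any(probs < 0) or np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-12):
            raise InvalidParameterError("each b_item_probs row must sum to 1")
        self.b_item_probs = probs
        for name, value in [
            ("female_fraction", self.female_fraction),
            ("missing_rate_geno", self.missing_rate_geno),
        ]:
            if not 0.0 <= value <= 1.0:
                raise InvalidParameterError(f"{name} must be in [0, 1], got {value}")
        unknown = set(self.effect_map) - {s.snp_id for s in self.snp_specs}
        if unknown:
            raise InvalidParameterError(f"effect_map refers to unknown SNPs: {sorted(unknown)}")

    def replace(self, **kwargs) -> "CohortParams":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class AldaRecord:
    """One subject's raw Alda ratings plus demographics.

    a_score is the 0-10 A-scale benefit rating; b1..b5 are the five 0-2
    confounder items (episode count/frequency before lithium, treatment
    duration, adherence, co-prescription complexity).
    """

    subject_id: str
    a_score: int
    b1: int
    b2: int
    b3: int
    b4: int
    b5: int
    age: float
    sex: str

    def __post_init__(self):
        if not 0 <= self.a_score <= 10:
            raise InvalidParameterError(f"a_score must be in 0..10, got {self.a_score}")
        for item in ("b1", "b2", "b3", "b4", "b5"):
            value = getattr(self, item)
            if value not in (0, 1, 2):
                raise InvalidParameterError(f"{item} must be in {{0,1,2}}, got {value}")
        if self.sex not in ("female", "male"):
            raise InvalidParameterError(f"sex must be 'female' or 'male', got {self.sex!r}")

    @property
    def b_total(self) -> int:
        return self.b1 + self.b2 + self.b3 + self.b4 + self.b5


def sample_genotypes(freq: float, n: int, seed) -> np.ndarray:
    """Draw ``n`` minor-allele dosages under Hardy-Weinberg equilibrium.

    Each subject's dosage is Binomial(2, freq), i.e. P(2)=freq^2,
    P(1)=2 freq (1-freq), P(0)=(1-freq)^2.  ``seed`` may be an int or a
    numpy Generator.
    """
    if not 0.0 <= freq <= 1.0:
        raise InvalidParameterError(f"allele frequency must be in [0, 1], got {freq}")
    if n < 1:
        raise InvalidParameterError("n must be >= 1")
    rng = np.random.default_rng(seed)
    return rng.binomial(2, freq, size=n)


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round half away from zero (numpy rounds half to even)."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def generate_cohort(params: CohortParams) -> tuple[list[AldaRecord], GenotypeTable]:
    """Simulate a cohort and its genotype table, deterministic in params.seed.

    The master seed is split into named sub-streams (demographics, A scores,
    B items, one per SNP, missingness) so that, e.g., adding a SNP does not
    perturb the demographic draws.
    """
    n = params.n_subjects
    ss = np.random.SeedSequence(params.seed)
    n_streams = 4 + len(params.snp_specs) + 1
    children = ss.spawn(n_streams)
    rng_age = np.random.default_rng(children[0])
    rng_sex = np.random.default_rng(children[1])
    rng_a = np.random.default_rng(children[2])
    rng_b = np.random.default_rng(children[3])
    snp_children = children[4:4 + len(params.snp_specs)]
    rng_missing = np.random.default_rng(children[-1])

    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    ages = rng_age.normal(params.age_mean, params.age_sd, size=n).clip(18.0, None)
    sexes = np.where(rng_sex.random(n) < params.female_fraction, "female", "male")

    dosages = {}
    for spec, child in zip(params.snp_specs, snp_children):
        dosages[spec.snp_id] = sample_genotypes(spec.maf, n, np.random.default_rng(child))

    a_latent = rng_a.normal(params.a_mean, params.a_sd, size=n)
    for snp_id, effect in params.effect_map.items():
        a_latent = a_latent + effect * dosages[snp_id]
    a_scores = np.clip(_round_half_away(a_latent), 0, 10).astype(int)

    b_items = np.empty((n, 5), dtype=int)
    for j in range(5):
        b_items[:, j] = rng_b.choice(3, size=n, p=params.b_item_probs[j])

    records = [
        AldaRecord(
            subject_id=subject_ids[i],
            a_score=int(a_scores[i]),
            b1=int(b_items[i, 0]),
            b2=int(b_items[i, 1]),
            b3=int(b_items[i, 2]),
            b4=int(b_items[i, 3]),
            b5=int(b_items[i, 4]),
            age=float(ages[i]),
            sex=str(sexes[i]),
        )
        for i in range(n)
    ]

    dosage_df = pd.DataFrame(
        {s.snp_id: dosages[s.snp_id].astype(float) for s in params.snp_specs},
        index=pd.Index(subject_ids, name="subject_id"),
    )
    if params.missing_rate_geno > 0:
        mask = rng_missing.random(dosage_df.shape) < params.missing_rate_geno
        dosage_df = dosage_df.mask(mask)

    table = GenotypeTable(
        dosages=dosage_df,
        genes={s.snp_id: s.gene for s in params.snp_specs},
        alleles={s.snp_id: (s.major_allele, s.minor_allele) for s in params.snp_specs},
    )
    return records, table


def records_to_frame(records: list[AldaRecord]) -> pd.DataFrame:
    rows = [dataclasses.asdict(r) for r in records]
    df = pd.DataFrame(rows)
    return df[["subject_id", "a_score", "b1", "b2", "b3", "b4", "b5", "age", "sex"]]


def frame_to_records(df: pd.DataFrame) -> list[AldaRecord]:
    return [
        AldaRecord(
            subject_id=str(row.subject_id),
            a_score=int(row.a_score),
            b1=int(row.b1),
            b2=int(row.b2),
            b3=int(row.b3),
            b4=int(row.b4),
            b5=int(row.b5),
            age=float(row.age),
            sex=str(row.sex),
        )
        for row in df.itertuples(index=False)
    ]


def read_cohort(path) -> list[AldaRecord]:
    """Read a cohort TSV written by :func:`write_cohort`."""
    return frame_to_records(pd.read_csv(path, sep="\t"))


# Arbitrary but fixed 1-based positions so the VCF is well formed.
_VCF_CHROM = "1"


def write_cohort(records: list[AldaRecord], genotypes: GenotypeTable, out_dir) -> dict[str, Path]:
    """Write cohort TSV, dosage TSV, and a minimal GT-only VCF v4.2.

    The VCF ALT allele is the generator's minor allele, so dosage d maps to
    GT 0/0, 0/1 or 1/1 and missing calls to "./.".  Subject ids must agree
    between records and the genotype table.
    """
    record_ids = [r.subject_id for r in records]
    if list(genotypes.dosages.index) != record_ids:
        raise ConsistencyError("subject ids differ between cohort records and genotype table")

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "cohort": out_dir / "cohort.tsv",
        "dosages": out_dir / "dosages.tsv",
        "vcf": out_dir / "genotypes.vcf",
    }

    records_to_frame(records).to_csv(paths["cohort"], sep="\t", index=False)
    genotypes.dosages.to_csv(paths["dosages"], sep="\t", na_rep="NA")

    gt_codes = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(paths["vcf"], "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=lithopheno\n")
        fh.write(f'##contig=<ID={_VCF_CHROM},length=1000000>\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene label">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(record_ids) + "\n")
        for pos, snp_id in enumerate(genotypes.snp_ids, start=1):
            major, minor = genotypes.alleles.get(snp_id, ("A", "B"))
            gene = genotypes.genes.get(snp_id, ".")
            calls = [
                gt_codes[d] if not np.isnan(d) else "./."
                for d in genotypes.dosages[snp_id].to_numpy(dtype=float)
            ]
            fields = [
                _VCF_CHROM, str(pos * 100), snp_id, major, minor, ".", "PASS",
                f"GENE={gene}", "GT",
            ] + calls
            fh.write("\t".join(fields) + "\n")
    return paths
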