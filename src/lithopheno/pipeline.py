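"""End-to-end orchestration: simulate/load -> phenotype -> QC -> association
-> CHAID trees -> power, with a written report bundle.

Every stage failure is re-raised as a StageError tagged with the stage name;
reruns of the same configuration produce byte-identical numeric outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, concordance, phenotypes, power, qc
from .chaid import ChaidSettings, grow_tree, cross_validate, render_tree
from .cohort import CohortParams, generate_cohort, read_cohort, write_cohort
from .errors import StageError

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline", "genotype_category_frame", "plot_neglog10p"]


@dataclass
class PipelineConfig:
    """Run configuration: either input file paths or simulation parameters.

    ``power_d`` gives the standardized effect size probed per gene, with the
    carrier vs non-carrier group sizes taken from the observed genotypes.
    """

    cohort_path: str | None = None
    genotype_path: str | None = None
    gene_map: dict[str, str] = field(default_factory=dict)
    sim_params: CohortParams | None = None
    seed: int = 0
    grp_threshold: float = phenotypes.DEFAULT_GRP_THRESHOLD
    chaid: ChaidSettings = field(default_factory=ChaidSettings)
    codings: dict[str, str] = field(default_factory=dict)
    power_d: dict[str, float] = field(
        default_factory=lambda: {"TIMELESS": 0.5, "PPARGC1A": 0.5, "RORA": 0.6}
    )
    alpha: float = 0.05
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "sim_params" in raw and raw["sim_params"] is not None:
            raw["sim_params"] = CohortParams(**raw["sim_params"])
        if "chaid" in raw:
            raw["chaid"] = ChaidSettings(**raw["chaid"])
        if "qc_thresholds" in raw:
            raw["qc_thresholds"] = qc.QCThresholds(**raw["qc_thresholds"])
        return cls(**raw)


def genotype_category_frame(table: qc.GenotypeTable) -> pd.DataFrame:
    """Dosages as genotype-class labels (e.g. GG/AG/AA) for tree predictors;
    missing calls stay NaN and become their own category inside the tree."""
    out = {}
    for snp in table.snp_ids:
        major, minor = table.alleles.get(snp, ("M", "m"))
        label = {0.0: major + major, 1.0: minor + major, 2.0: minor + minor}
        name = table.genes.get(snp, snp)
        out[name] = table.dosages[snp].map(lambda d: label.get(d, np.nan))
    return pd.DataFrame(out, index=table.dosages.index)


def plot_neglog10p(assoc_df: pd.DataFrame, out_path) -> Path:
    """Bar chart of -log10(p) per gene, grouped by phenotype, with the two
    correction tiers drawn as horizontal lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = assoc_df.pivot_table(index="gene", columns="phenotype",
                                 values="neglog10p")
    ax = pivot.plot.bar(figsize=(8, 4.5), rot=0)
    ax.axhline(-np.log10(association.GENE_TIER_P), ls="--", c="grey",
               label="p = 0.017")
    ax.axhline(-np.log10(association.FULL_TIER_P), ls=":", c="black",
               label="p = 0.003")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.legend(fontsize=8)
    out_path = Path(out_path)
    ax.figure.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(ax.figure)
    return out_path


def _stage(name):
    def wrap(fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - tag and re-raise
            raise StageError(name, str(exc)) from exc
    return wrap


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages and write the report bundle into ``out_dir``.

    Returns a dict with the in-memory results (phenotype table, concordance
    summaries, association table, trees, power table, file paths).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    # --- input stage ------------------------------------------------------
    def load_inputs():
        if config.cohort_path:
            records = read_cohort(config.cohort_path)
            if not config.genotype_path:
                raise FileNotFoundError("genotype_path required when cohort_path is given")
            table = qc.read_genotypes(config.genotype_path, gene_map=config.gene_map)
            return records, table
        params = config.sim_params or CohortParams(seed=config.seed)
        records, table = generate_cohort(params)
        write_cohort(records, table, out_dir / "simulated")
        return records, table

    records, geno = _stage("input")(load_inputs)

    # --- phenotyping ------------------------------------------------------
    def phenotype_stage():
        model = phenotypes.fit_best_estimate(records, settings=config.chaid,
                                             grp_threshold=config.grp_threshold)
        table = phenotypes.phenotype_table(records, model)
        table.to_csv(out_dir / "phenotypes.tsv", sep="\t", index=False)
        return model, table

    model, pheno = _stage("phenotype")(phenotype_stage)

    # --- concordance ------------------------------------------------------
    def concordance_stage():
        pairs = concordance.compare_phenotype_pairs(pheno, config.grp_threshold)
        df = pd.DataFrame({k: v.as_dict() for k, v in pairs.items()}).T
        df.index.name = "comparison"
        df.to_csv(out_dir / "concordance.tsv", sep="\t")
        return pairs

    pairs = _stage("concordance")(concordance_stage)

    # --- genotype QC and best-SNP selection -------------------------------
    def qc_stage():
        filtered, report = qc.apply_qc(geno, config.qc_thresholds)
        report.snp_table.to_csv(out_dir / "qc_snps.tsv", sep="\t")
        report.sample_table.to_csv(out_dir / "qc_samples.tsv", sep="\t")
        ts = pheno.set_index("subject_id")["ts"].astype(float)
        genes = sorted(set(filtered.genes.values()))
        selected = [qc.select_best_snp(filtered, gene, ts) for gene in genes]
        best = filtered.subset(snps=selected)
        pd.Series(selected, name="snp_id").to_csv(out_dir / "selected_snps.tsv",
                                                  sep="\t", index=False)
        return best

    best = _stage("qc")(qc_stage)

    # --- association scan -------------------------------------------------
    def assoc_stage():
        scan = association.association_scan(pheno, best, codings=config.codings)
        scan.to_csv(out_dir / "association.tsv", sep="\t", index=False)
        plot_neglog10p(scan, out_dir / "association_neglog10p.png")
        return scan

    scan = _stage("assoc")(assoc_stage)

    # --- CHAID trees for the two categorical phenotypes -------------------
    def tree_stage():
        X = genotype_category_frame(best)
        demo = pd.DataFrame(
            {"age": [r.age for r in records], "sex": [r.sex for r in records]},
            index=pd.Index([r.subject_id for r in records], name="subject_id"),
        )
        common = [s for s in X.index if s in set(pheno["subject_id"])]
        X = X.join(demo).loc[common]
        trees = {}
        for target in ("alda_cat", "algo_cat"):
            y = pheno.set_index("subject_id").loc[X.index, target].to_numpy()
            tree = grow_tree(X, y, config.chaid)
            risk, se = cross_validate(X, y, config.chaid)
            tree.cv_risk, tree.cv_risk_se = risk, se
            text, dot = render_tree(tree)
            (out_dir / f"tree_{target}.txt").write_text(
                text + f"\ncv risk = {risk:.3f} +/- {se:.3f}\n")
            (out_dir / f"tree_{target}.dot").write_text(dot)
            tree.node_table().to_csv(out_dir / f"tree_{target}_nodes.tsv",
                                     sep="\t", index=False)
            trees[target] = tree
        return trees

    trees = _stage("tree")(tree_stage)

    # --- power ------------------------------------------------------------
    def power_stage():
        rows = []
        for snp in best.snp_ids:
            gene = best.genes.get(snp, snp)
            d = config.power_d.get(gene, 0.5)
            dos = best.dosages[snp].dropna()
            n_carrier = int((dos >= 1).sum())
            n_non = int((dos == 0).sum())
            req = power.PowerRequest(n1=max(n_non, 2), n2=max(n_carrier, 2), d=d,
                                     alpha=config.alpha, sides=2)
            rows.append({"gene": gene, "snp_id": snp, "n1": req.n1, "n2": req.n2,
                         "d": d, "alpha": config.alpha,
                         "power": power.t_test_power(req)})
        df = pd.DataFrame(rows)
        df.to_csv(out_dir / "power.tsv", sep="\t", index=False)
        return df

    power_df = _stage("power")(power_stage)

    # --- run log ----------------------------------------------------------
    log = {
        "seed": config.seed,
        "grp_threshold": config.grp_threshold,
        "tiers": {"gene": association.GENE_TIER_P, "full": association.FULL_TIER_P},
        "qc_thresholds": dataclasses.asdict(config.qc_thresholds),
        "chaid": {k: v for k, v in dataclasses.asdict(config.chaid).items()},
        "python": platform.python_version(),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=2, default=str))

    return {
        "records": records, "genotypes": geno, "model": model, "phenotypes": pheno,
        "concordance": pairs, "association": scan, "trees": trees,
        "power": power_df, "out_dir": out_dir,
    }
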