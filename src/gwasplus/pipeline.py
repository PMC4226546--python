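"""End-to-end pipeline driver: simulate -> QC -> GWAS -> gene tests ->
polygenic scoring -> GREML, with plots and a structured run report."""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gwasplus import diagnostics, famsim, fgls, genewise, greml, io, pgs, plots, qc

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Flat key-value run configuration; every stochastic stage has its own seed."""

    out_dir: str = "gwasplus_run"
    # stage toggles
    do_simulate: bool = True
    do_qc: bool = True
    do_gwas: bool = True
    do_genewise: bool = True
    do_pgs: bool = True
    do_greml: bool = True
    # input paths (used when do_simulate is false)
    bed_prefix: str = ""
    dosage_file: str = ""
    pedigree_file: str = ""
    pheno_file: str = ""
    genes_bed: str = ""
    # simulation design
    families_mz: int = 40
    families_dz: int = 25
    families_adopt2: int = 10
    families_bio2: int = 8
    families_mixed: int = 5
    families_step: int = 4
    n_snps: int = 2000
    ld_block_size: int = 10
    maf_low: float = 0.05
    maf_high: float = 0.5
    missing_rate: float = 0.002
    imputed_fraction: float = 0.25
    n_causal: int = 500
    h2: float = 0.5
    c2: float = 0.2
    # thresholds
    callrate_min: float = 0.99
    maf_min: float = 0.01
    hwe_alpha: float = 1e-7
    imputation_r2_min: float = 0.5
    genomewide_alpha: float = 5e-8
    grm_cutoff: float = 0.025
    n_pcs: int = 2
    # analysis sizes
    pgs_folds: int = 5
    bootstrap_iters: int = 10
    gene_size_snps: int = 25
    # seeds (one per stochastic stage)
    seed_families: int = 11
    seed_genotypes: int = 12
    seed_dosages: int = 13
    seed_phenotype: int = 14
    seed_genewise: int = 15
    seed_pgs: int = 16
    seed_bootstrap: int = 17

    def __post_init__(self):
        for name in ("callrate_min", "maf_min", "hwe_alpha", "imputation_r2_min",
                     "genomewide_alpha", "grm_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"threshold {name} must be positive")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Parse a flat ``key = value`` text file (# comments allowed)."""
        kwargs = {}
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
            line = line.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            default = getattr(defaults, key)
            if isinstance(default, bool):
                kwargs[key] = value.lower() in ("1", "true", "yes", "on")
            elif isinstance(default, int):
                kwargs[key] = int(value)
            elif isinstance(default, float):
                kwargs[key] = float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


def _tile_genes(snp_meta: pd.DataFrame, size: int) -> pd.DataFrame:
    """Synthetic annotation: tile non-overlapping genes over consecutive SNPs."""
    rows = []
    g = 0
    for chrom, grp in snp_meta.groupby("chrom"):
        pos = grp["pos"].to_numpy()
        for start in range(0, len(pos), size):
            chunk = pos[start:start + size]
            g += 1
            rows.append({"gene_id": f"gene{g:04d}", "chrom": chrom,
                         "start": int(chunk[0]), "end": int(chunk[-1])})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages, writing all outputs under ``config.out_dir``.

    Returns a report dict (also saved as report.json) recording seeds,
    per-filter counts, the genomic inflation factor, and headline estimates.
    """
    t0 = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(out / "run.log")
    fh.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("gwasplus")
    root.addHandler(fh)
    root.setLevel(logging.INFO)
    report: dict = {"config": dataclasses.asdict(config)}
    try:
        return _run_stages(config, out, report)
    finally:
        root.removeHandler(fh)
        fh.close()
        logger.info("pipeline finished in %.1f s", time.time() - t0)


def _run_stages(config: RunConfig, out: Path, report: dict) -> dict:
    if config.do_simulate:
        ped = famsim.simulate_families(
            {
                "MZ": config.families_mz,
                "DZ": config.families_dz,
                "ADOPT2": config.families_adopt2,
                "BIO2": config.families_bio2,
                "MIXED": config.families_mixed,
                "STEP": config.families_step,
            },
            seed=config.seed_families,
        )
        geno = famsim.simulate_genotypes(
            ped,
            n_snps=config.n_snps,
            ld_block_size=config.ld_block_size,
            maf_range=(config.maf_low, config.maf_high),
            missing_rate=config.missing_rate,
            seed=config.seed_genotypes,
        )
        rng = np.random.default_rng(config.seed_dosages)
        n_imp = int(config.imputed_fraction * geno.n_snps)
        imp_mask = np.zeros(geno.n_snps, dtype=bool)
        imp_mask[rng.choice(geno.n_snps, n_imp, replace=False)] = True
        targets = rng.uniform(0.3, 1.0, size=n_imp)
        dosages = famsim.simulate_dosages(geno, targets, seed=config.seed_dosages,
                                          snp_mask=imp_mask)
        arch = famsim.TraitArchitecture(
            n_causal=config.n_causal, h2_target=config.h2, c2_target=config.c2
        )
        pheno = famsim.simulate_phenotype(ped, geno, arch, seed=config.seed_phenotype)
        io.write_pedigree(ped, out / "pedigree.tsv")
        io.write_plink(geno, ped, out / "genotypes")
        io.write_dosages(dosages, out / "dosages.tsv")
        io.write_phenotypes(
            pheno[["individual_id", "family_id", "sex", "birth_year", "fsiq"]],
            out / "phenotypes.tsv")
    else:
        ped = io.read_pedigree(config.pedigree_file)
        geno = io.read_plink(config.bed_prefix)
        dosages = io.read_dosages(config.dosage_file) if config.dosage_file else None
        pheno = io.read_phenotypes(config.pheno_file, ped)
    report["n_individuals"] = len(ped)
    report["n_families"] = ped.n_families
    report["n_snps_typed"] = int(geno.n_snps)

    if config.do_qc:
        geno, qc_report = qc.qc_filter(geno, ped, config.callrate_min,
                                       config.maf_min, config.hwe_alpha)
        report["qc"] = qc_report
    if dosages is not None:
        keep = dosages.snp_meta["imputation_r2"].to_numpy() > config.imputation_r2_min
        report["dosages_pass_r2"] = int(keep.sum())
        report["dosages_fail_r2"] = int((~keep).sum())
        dosages = dosages.subset_snps(keep) if keep.any() else None

    grm = greml.compute_grm(geno)
    pcs = qc.compute_pcs(grm.A, k=config.n_pcs) if config.n_pcs else None
    pheno = pheno[pheno["individual_id"].isin(set(geno.ids))].reset_index(drop=True)
    if pcs is not None:
        row = {iid: i for i, iid in enumerate(grm.ids)}
        pcs = pcs[[row[i] for i in pheno["individual_id"]]]

    results: dict = {"pedigree": ped, "genotypes": geno, "pheno": pheno}
    if config.do_gwas:
        fit = fgls.fit_covariates_only(pheno, ped, pcs=pcs)
        io.write_covmodel(fit.covmodel, out / "covmodel.json")
        summary = fgls.run_gwas(geno, pheno, ped, fit.covmodel, pcs=pcs,
                                dosages=dosages)
        io.write_summary(summary, out / "gwas_summary.tsv")
        lam, mean_chi = diagnostics.genomic_inflation(summary["p"].dropna())
        report["lambda"] = lam
        report["mean_chisq"] = mean_chi
        report["n_snps_analyzed"] = int(summary["p"].notna().sum())
        report["n_genomewide_hits"] = int((summary["p"] <= config.genomewide_alpha).sum())
        plots.manhattan(summary.dropna(subset=["p"]), out / "manhattan.png",
                        sig_alpha=config.genomewide_alpha)
        plots.qq_uniform(summary["p"].dropna(), out / "qq.png")
        diag = diagnostics.residual_diagnostics(fit)
        diag["mahalanobis"].to_csv(out / "mahalanobis.tsv", sep="\t", index=False)
        results["gwas"] = summary
        results["covfit"] = fit

    if config.do_genewise and config.do_gwas:
        annotation = (io.read_gene_bed(config.genes_bed) if config.genes_bed
                      else _tile_genes(geno.snp_meta, config.gene_size_snps))
        typed_summary = summary[summary["typed"]]
        genes = genewise.run_genewise(typed_summary, annotation, geno,
                                      seed=config.seed_genewise)
        genes.to_csv(out / "genes.tsv", sep="\t", index=False)
        report["n_genes_tested"] = len(genes)
        report["gene_bonferroni_alpha"] = 0.05 / max(len(genes), 1)
        results["genes"] = genes

    if config.do_pgs:
        cv = pgs.crossvalidate(geno, pheno, ped, k=config.pgs_folds,
                               seed=config.seed_pgs)
        cv.cells.to_csv(out / "pgs_cv.tsv", sep="\t", index=False)
        null = pgs.bootstrap_null(geno, pheno, ped, n_iter=config.bootstrap_iters,
                                  seed=config.seed_bootstrap)
        null.samples.to_csv(out / "pgs_null.tsv", sep="\t", index=False)
        plots.scoring_trend(cv.summary, null.percentiles, out / "pgs_trend.png")
        best = cv.summary.loc[cv.summary["buse"].idxmax()]
        report["pgs_best_buse_r2"] = float(best["buse"])
        report["pgs_best_cutoff"] = float(best["cutoff"])
        results["pgs_cv"] = cv
        results["pgs_null"] = null

    if config.do_greml:
        keep_ids = greml.prune_related(grm, config.grm_cutoff)
        row = {iid: i for i, iid in enumerate(grm.ids)}
        pheno_g = pheno[pheno["individual_id"].isin(set(keep_ids))]
        idx = np.array([row[i] for i in pheno_g["individual_id"]])
        y, X, names, _ = fgls.build_design(pheno_g)
        fit_vc = greml.reml_fit(y, X, grm.A[np.ix_(idx, idx)])
        report["greml"] = {
            "n": fit_vc.n,
            "h2_snp": fit_vc.h2,
            "se_h2": fit_vc.se_h2,
            "sigma2_g": fit_vc.sigma2_g,
            "sigma2_e": fit_vc.sigma2_e,
        }
        io.save_json(report["greml"], out / "vc.json")
        blup = greml.eblup(fit_vc, grm.A[np.ix_(idx, idx)], y, X)
        plots.normal_qq(blup["g_hat"], out / "eblup_qq.png", title="eBLUP QQ")
        plots.normal_qq(blup["residual"], out / "greml_resid_qq.png",
                        title="GREML residual QQ")
        results["greml"] = fit_vc
    io.save_json(report, out / "report.json")
    results["report"] = report
    return results
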