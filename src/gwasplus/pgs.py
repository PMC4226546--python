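"""Polygenic scoring under family-stratified cross-validation.

A calibration GWAS supplies per-SNP weights (regression coefficients, or
their signs as +/-1 unit weights) at eight p-value inclusion cutoffs; scores
are weighted allele-count sums evaluated in a held-out validation sample.
Performance is Buse's R-squared -- the GLS generalization of the coefficient
of determination, with quadratic forms weighted by the inverse family
residual covariance -- alongside Nagelkerke's R-squared and the squared
Pearson correlation.  A parametric bootstrap (phenotypes resimulated from
the covariates-only fit, so they are independent of genotypes) provides the
null reference distribution of each cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from gwasplus import fgls
from gwasplus.famsim import GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)

#: the eight p-value inclusion cutoffs
DEFAULT_CUTOFFS = (0.001, 0.005, 0.01, 0.05, 0.1, 0.25, 0.5, 1.0)
DEFAULT_SCHEMES = ("regression", "signed_unit")


@dataclass
class WeightSet:
    snp_ids: np.ndarray
    weights: np.ndarray
    cutoff: float
    scheme: str
    af: np.ndarray | None = None  # calibration allele frequency per SNP

    def __post_init__(self):
        if self.scheme not in ("regression", "signed_unit"):
            raise ValueError(f"unknown weighting scheme {self.scheme!r}")
        if self.scheme == "signed_unit" and self.weights.size:
            if not np.all(np.isin(self.weights, (-1.0, 1.0))):
                raise ValueError("signed_unit weights must be +/-1")

    def __len__(self):
        return len(self.snp_ids)


@dataclass
class CVReport:
    """Per-cell cross-validation metrics and fold averages."""

    cells: pd.DataFrame  # fold x cutoff x scheme rows
    summary: pd.DataFrame  # averaged across folds


@dataclass
class BootstrapNull:
    samples: pd.DataFrame  # iteration x cutoff x scheme rows
    percentiles: pd.DataFrame  # 98th percentile per cutoff x scheme


def family_kfold(pedigree: Pedigree, k: int = 5, seed: int = 0) -> dict:
    """Assign whole families to k folds, stratified by family type.

    Within each type, shuffled families are dealt round-robin from a random
    starting fold, so fold counts per type differ by at most one.  Types with
    fewer than k families are pooled into one stratum (warned).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    fams = pedigree.table.groupby("family_id", sort=False)["family_type"].first()
    strata: dict = {}
    pooled = []
    for ftype, grp in fams.groupby(fams):
        ids = list(grp.index)
        if len(ids) < k:
            logger.warning("family_kfold: only %d %s families (< k=%d); pooling",
                           len(ids), ftype, k)
            pooled.extend(ids)
        else:
            strata[ftype] = ids
    if pooled:
        strata["_pooled"] = pooled
    folds = {}
    for ids in strata.values():
        ids = list(ids)
        rng.shuffle(ids)
        start = int(rng.integers(0, k))
        for i, fid in enumerate(ids):
            folds[fid] = (start + i) % k
    return folds


def snp_weights(calibration_gwas: pd.DataFrame, cutoff: float, scheme: str) -> WeightSet:
    """SNP weights from a calibration GWAS: all typed SNPs with p <= cutoff.

    ``regression`` copies the estimated coefficients; ``signed_unit`` maps
    their signs to +/-1 (zero coefficients are excluded, logged).
    """
    g = calibration_gwas
    sel = g["typed"].to_numpy(dtype=bool) & (g["p"].to_numpy() <= cutoff)
    sel &= np.isfinite(g["beta"].to_numpy())
    beta = g.loc[sel, "beta"].to_numpy()
    ids = g.loc[sel, "snp_id"].to_numpy()
    if scheme == "signed_unit":
        nz = beta != 0
        if (~nz).any():
            logger.info("snp_weights: excluded %d SNPs with beta exactly 0", int((~nz).sum()))
        ids, beta = ids[nz], np.sign(beta[nz])
    if ids.size == 0:
        logger.warning("snp_weights: no SNP passes cutoff %g", cutoff)
    return WeightSet(snp_ids=ids, weights=beta.astype(float), cutoff=cutoff, scheme=scheme)


def polygenic_score(genotypes: GenotypeMatrix, weights: WeightSet) -> np.ndarray:
    """score_i = sum_j w_j x_ij over the weight set's SNPs.

    Missing genotypes contribute 2 * (calibration allele frequency) * w_j; if
    the weight set carries no frequencies the genotype sample's own are used.
    """
    if len(weights) == 0:
        logger.warning("polygenic_score: empty weight set; scores undefined")
        return np.full(genotypes.n_individuals, np.nan)
    present = set(genotypes.snp_meta["snp_id"])
    absent = [s for s in weights.snp_ids if s not in present]
    if absent:
        raise KeyError(f"weighted SNPs absent from genotypes: {absent[:10]}")
    sub = genotypes.subset_snps(weights.snp_ids)
    order = {s: i for i, s in enumerate(sub.snp_meta["snp_id"])}
    cols = np.array([order[s] for s in weights.snp_ids])
    X = sub.values[:, cols].copy()
    af = weights.af
    if af is None:
        af = np.nanmean(X, axis=0) / 2.0
    miss = np.where(np.isnan(X))
    X[miss] = 2.0 * np.take(af, miss[1])
    return X @ weights.weights


def buse_r2(
    residualized_y: np.ndarray,
    score: np.ndarray,
    whitener: fgls.Whitener,
) -> dict:
    """Buse's R-squared of a GLS regression of residualized phenotype on score.

    R^2 = 1 - (e' V^-1 e) / (y~' V^-1 y~), with e the GLS residual of the
    regression on [intercept, score], and y~ the phenotype centered at its
    V-weighted mean.  Also returns Nagelkerke's generalized R^2 and the
    squared Pearson correlation.  Reduces to the OLS R^2 when V = I.
    """
    index = whitener.index
    y = np.asarray(residualized_y, dtype=float)
    s = np.asarray(score, dtype=float)
    if not np.all(np.isfinite(s)) or s.std() == 0:
        logger.warning("buse_r2: degenerate score; returning NaN")
        return {"buse": np.nan, "nagelkerke": np.nan, "pearson2": np.nan}
    yo, so = index.to_ordered(y), index.to_ordered(s)
    ones = np.ones(index.n)
    Zw = whitener.whiten(np.column_stack([ones, so]))
    yw = whitener.whiten(yo)
    onew = Zw[:, 0]
    beta = np.linalg.lstsq(Zw, yw, rcond=None)[0]
    e = yw - Zw @ beta
    ybar = float(onew @ yw) / float(onew @ onew)
    yt = yw - ybar * onew
    sse = float(e @ e)
    sst = float(yt @ yt)
    buse = 1.0 - sse / sst
    n = index.n
    ll_full = -0.5 * (n * np.log(2 * np.pi) + whitener.logdet + sse)
    ll_null = -0.5 * (n * np.log(2 * np.pi) + whitener.logdet + sst)
    cox_snell = 1.0 - np.exp(2.0 * (ll_null - ll_full) / n)
    max_cs = 1.0 - np.exp(2.0 * ll_null / n)
    nagelkerke = cox_snell / max_cs if max_cs > 0 else np.nan
    pearson2 = float(np.corrcoef(y, s)[0, 1] ** 2)
    return {"buse": float(buse), "nagelkerke": float(nagelkerke), "pearson2": pearson2}


def _evaluate_split(
    genotypes: GenotypeMatrix,
    pheno_calib: pd.DataFrame,
    pheno_val: pd.DataFrame,
    pedigree: Pedigree,
    cutoffs,
    schemes,
    covariate_cols,
) -> list:
    """Calibration GWAS -> weights -> validation scores -> R^2 per cell."""
    calib_ids = set(pheno_calib["individual_id"])
    val_ids = set(pheno_val["individual_id"])
    assert not calib_ids & val_ids, "calibration and validation sets overlap"
    typed = genotypes.subset_snps(genotypes.snp_meta["typed"].to_numpy(dtype=bool))
    calib_geno = typed.subset_individuals(pheno_calib["individual_id"].to_numpy())
    calib_fit = fgls.fit_covariates_only(pheno_calib, pedigree, covariate_cols)
    gwas = fgls.run_gwas(calib_geno, pheno_calib, pedigree, calib_fit.covmodel,
                         covariate_cols)
    calib_af = pd.Series(
        np.nanmean(calib_geno.values, axis=0) / 2.0,
        index=calib_geno.snp_meta["snp_id"],
    )
    val_geno = typed.subset_individuals(pheno_val["individual_id"].to_numpy())
    val_fit = fgls.fit_covariates_only(pheno_val, pedigree, covariate_cols)
    resid_val = val_fit.residuals
    cells = []
    for cutoff in cutoffs:
        for scheme in schemes:
            ws = snp_weights(gwas, cutoff, scheme)
            ws.af = calib_af.reindex(ws.snp_ids).to_numpy() if len(ws) else None
            score = polygenic_score(val_geno, ws)
            metrics = (
                buse_r2(resid_val, score, val_fit.whitener)
                if np.all(np.isfinite(score))
                else {"buse": np.nan, "nagelkerke": np.nan, "pearson2": np.nan}
            )
            cells.append({"cutoff": cutoff, "scheme": scheme, "n_snps": len(ws), **metrics})
    return cells


def crossvalidate(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    pedigree: Pedigree,
    k: int = 5,
    cutoffs=DEFAULT_CUTOFFS,
    schemes=DEFAULT_SCHEMES,
    seed: int = 0,
    covariate_cols=("sex", "birth_year"),
) -> CVReport:
    """k-fold cross-validated polygenic scoring (families never split).

    For each fold, a GWAS on the other k-1 folds supplies weights at every
    cutoff x scheme; scores and the three R^2 metrics are evaluated on the
    held-out fold.  With 8 cutoffs and 2 schemes there are 16 score vectors
    per validation fold.
    """
    folds = family_kfold(pedigree, k=k, seed=seed)
    fold_of = pheno["family_id"].map(folds)
    rows = []
    for f in range(k):
        pheno_val = pheno[fold_of == f]
        pheno_calib = pheno[fold_of != f]
        cells = _evaluate_split(genotypes, pheno_calib, pheno_val, pedigree,
                                cutoffs, schemes, covariate_cols)
        for c in cells:
            rows.append({"fold": f, **c})
    cells = pd.DataFrame(rows)
    summary = (
        cells.groupby(["cutoff", "scheme"], as_index=False)[["buse", "nagelkerke", "pearson2"]]
        .mean()
    )
    return CVReport(cells=cells, summary=summary)


def simulate_null_phenotype(
    fit: fgls.CovariatesOnlyFit,
    pheno: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Phenotypes resimulated from the covariates-only fit.

    Each family's new residual vector is MVN(0, fitted family block), added
    to that family's fitted (covariate-predicted) values, so covariate
    associations and within-family covariance are preserved while the
    phenotype is independent of the SNPs.
    """
    index = fit.index
    resid = np.empty(index.n)
    for fid, ftype, roles, adopted, rws in index.families:
        sigma = fit.covmodel.block(ftype, roles, adopted)
        L = np.linalg.cholesky(sigma)
        resid[rws] = L @ rng.standard_normal(len(rws))
    new = pheno.copy()
    new["fsiq"] = fit.fitted + index.to_input(resid)
    return new


def bootstrap_null(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    pedigree: Pedigree,
    n_iter: int = 50,
    calib_frac: float = 0.8,
    cutoffs=DEFAULT_CUTOFFS,
    schemes=DEFAULT_SCHEMES,
    seed: int = 0,
    covariate_cols=("sex", "birth_year"),
) -> BootstrapNull:
    """Parametric-bootstrap null distribution of polygenic-scoring R^2.

    Each iteration resimulates phenotypes from the covariates-only fit,
    splits families ``calib_frac`` / (1 - ``calib_frac``) into calibration
    and validation subsamples, reruns the calibration GWAS and validation
    scoring, and records R^2 per cutoff x scheme.  Returns all iterations and
    the 98th percentile per cell.
    """
    rng = np.random.default_rng(seed)
    full_fit = fgls.fit_covariates_only(pheno, pedigree, covariate_cols)
    fam_ids = pheno["family_id"].unique()
    n_calib = int(round(calib_frac * len(fam_ids)))
    rows = []
    for it in range(n_iter):
        sim = simulate_null_phenotype(full_fit, pheno, rng)
        perm = rng.permutation(fam_ids)
        calib_fams = set(perm[:n_calib])
        in_calib = sim["family_id"].isin(calib_fams)
        cells = _evaluate_split(genotypes, sim[in_calib], sim[~in_calib], pedigree,
                                cutoffs, schemes, covariate_cols)
        for c in cells:
            rows.append({"iteration": it, **c})
    samples = pd.DataFrame(rows)
    percentiles = (
        samples.groupby(["cutoff", "scheme"], as_index=False)["buse"]
        .quantile(0.98)
        .rename(columns={"buse": "buse_p98"})
    )
    return BootstrapNull(samples=samples, percentiles=percentiles)
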