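"""Readers and writers for the study's file formats.

PLINK bed/bim/fam hard calls (SNP-major, 2-bit codes), a tab-delimited
dosage table for imputed SNPs, pedigree and phenotype TSVs, GWAS summary
TSVs, a JSON covariance-model file, and a plain-text GRM.  bim and dosage
coordinates are 1-based; BED gene annotations are 0-based half-open on disk
and converted to 1-based inclusive on load.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from gwasplus.famsim import GenotypeMatrix, Pedigree
from gwasplus.fgls import FamilyCovarianceModel
from gwasplus.greml import GRM

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major mode

# 2-bit genotype codes -> count of the bim A1 allele (01 = missing)
_CODE_TO_COUNT = np.array([2.0, np.nan, 1.0, 0.0])
_COUNT_TO_CODE = {2.0: 0, 1.0: 2, 0.0: 3}


def write_plink(genotypes: GenotypeMatrix, pedigree: Pedigree, prefix) -> None:
    """Write hard calls as PLINK bed/bim/fam (values = A1 allele counts)."""
    prefix = Path(prefix)
    vals = genotypes.values
    if np.any(np.isfinite(vals) & (vals != np.round(vals))):
        raise ValueError("PLINK bed stores hard calls; found fractional dosages")
    n, m = vals.shape
    codes = np.full((m, n), 1, dtype=np.uint8)  # default missing
    for count, code in _COUNT_TO_CODE.items():
        codes[vals.T == count] = code
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes * 4), dtype=np.uint8)
    packed[:, :n] = codes
    packed = packed.reshape(m, n_bytes, 4)
    out = (
        packed[:, :, 0]
        | (packed[:, :, 1] << 2)
        | (packed[:, :, 2] << 4)
        | (packed[:, :, 3] << 6)
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(out.tobytes())
    meta = genotypes.snp_meta
    bim = pd.DataFrame(
        {
            "chrom": meta["chrom"],
            "snp_id": meta["snp_id"],
            "cm": 0,
            "pos": meta["pos"],
            "a1": meta["a1"],
            "a2": meta["a2"],
        }
    )
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    ped = pedigree.table.set_index("individual_id").loc[genotypes.ids]
    fam = pd.DataFrame(
        {
            "fid": ped["family_id"].to_numpy(),
            "iid": genotypes.ids,
            "father": 0,
            "mother": 0,
            "sex": np.where(ped["sex"].to_numpy() == "M", 1, 2),
            "pheno": -9,
        }
    )
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def read_plink(prefix) -> GenotypeMatrix:
    """Read PLINK bed/bim/fam into a hard-call genotype matrix."""
    prefix = Path(prefix)
    bim = pd.read_csv(
        prefix.with_suffix(".bim"),
        sep=r"\s+",
        header=None,
        names=["chrom", "snp_id", "cm", "pos", "a1", "a2"],
    )
    fam = pd.read_csv(
        prefix.with_suffix(".fam"),
        sep=r"\s+",
        header=None,
        names=["fid", "iid", "father", "mother", "sex", "pheno"],
    )
    raw = np.fromfile(prefix.with_suffix(".bed"), dtype=np.uint8)
    if raw[:3].tobytes() != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: bad magic bytes (not SNP-major PLINK bed)")
    n, m = len(fam), len(bim)
    n_bytes = (n + 3) // 4
    body = raw[3:]
    if len(body) != m * n_bytes:
        raise ValueError(f"{prefix}.bed: expected {m * n_bytes} data bytes, got {len(body)}")
    body = body.reshape(m, n_bytes)
    codes = np.empty((m, n_bytes * 4), dtype=np.uint8)
    codes[:, 0::4] = body & 0b11
    codes[:, 1::4] = (body >> 2) & 0b11
    codes[:, 2::4] = (body >> 4) & 0b11
    codes[:, 3::4] = (body >> 6) & 0b11
    vals = _CODE_TO_COUNT[codes[:, :n]].T
    meta = bim[["snp_id", "chrom", "pos", "a1", "a2"]].copy()
    meta["typed"] = True
    meta["imputation_r2"] = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        af = np.nanmean(vals, axis=0) / 2.0
    meta["maf"] = np.minimum(af, 1.0 - af)
    return GenotypeMatrix(vals, fam["iid"].to_numpy(), meta)


def write_dosages(dosages: GenotypeMatrix, path) -> None:
    """Tab-delimited dosage table: snp_id, chrom, pos, imputation_r2, then one
    dosage column per individual (1-based positions)."""
    meta = dosages.snp_meta
    out = meta[["snp_id", "chrom", "pos", "imputation_r2"]].copy()
    body = pd.DataFrame(dosages.values.T, columns=dosages.ids)
    pd.concat([out.reset_index(drop=True), body], axis=1).to_csv(
        path, sep="\t", index=False, float_format="%.4f"
    )


def read_dosages(path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t")
    fixed = ["snp_id", "chrom", "pos", "imputation_r2"]
    for i, col in enumerate(fixed):
        if df.columns[i] != col:
            raise ValueError(f"{path}: column {i + 1} must be {col!r}, got {df.columns[i]!r}")
    ids = np.asarray(df.columns[len(fixed):])
    vals = df[ids].to_numpy(dtype=float).T
    if np.nanmin(vals) < 0 or np.nanmax(vals) > 2:
        j, k = np.unravel_index(np.nanargmax(np.abs(vals - 1.0)), vals.shape)
        raise ValueError(f"{path}: dosage {vals[j, k]} outside [0, 2] (individual "
                         f"{ids[j]}, SNP {df['snp_id'].iloc[k]})")
    meta = df[fixed].copy()
    meta["a1"] = "A"
    meta["a2"] = "G"
    meta["typed"] = False
    meta["maf"] = np.minimum(vals.mean(axis=0) / 2.0, 1.0 - vals.mean(axis=0) / 2.0)
    return GenotypeMatrix(vals, ids, meta)


def write_pedigree(pedigree: Pedigree, path) -> None:
    pedigree.table.to_csv(path, sep="\t", index=False)


def read_pedigree(path) -> Pedigree:
    df = pd.read_csv(path, sep="\t")
    if "adopted" in df.columns:
        df["adopted"] = df["adopted"].astype(bool)
    return Pedigree(df)


def write_phenotypes(pheno: pd.DataFrame, path) -> None:
    pheno.to_csv(path, sep="\t", index=False)


def read_phenotypes(path, pedigree: Pedigree | None = None) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if pedigree is not None:
        orphans = set(df["individual_id"]) - set(pedigree.table["individual_id"])
        if orphans:
            raise ValueError(f"phenotype rows with no pedigree entry: {sorted(orphans)[:10]}")
    return df


def write_summary(summary: pd.DataFrame, path) -> None:
    """GWAS summary TSV: snp_id, chr, pos, a1, beta, se, stat, p, n, typed."""
    out = summary.rename(columns={"chrom": "chr"})
    out.to_csv(path, sep="\t", index=False)


def read_summary(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t").rename(columns={"chr": "chrom"})


def read_gene_bed(path) -> pd.DataFrame:
    """Gene annotation from BED (0-based half-open on disk); returns 1-based
    inclusive start/end columns."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#",
                     names=["chrom", "start0", "end0", "gene_id"])
    out = pd.DataFrame(
        {
            "gene_id": df["gene_id"],
            "chrom": df["chrom"],
            "start": df["start0"] + 1,  # 0-based half-open -> 1-based inclusive
            "end": df["end0"],
        }
    )
    if (out["start"] > out["end"]).any():
        raise ValueError(f"{path}: empty or inverted gene intervals")
    return out


def write_covmodel(model: FamilyCovarianceModel, path) -> None:
    Path(path).write_text(model.to_json())


def read_covmodel(path) -> FamilyCovarianceModel:
    return FamilyCovarianceModel.from_json(Path(path).read_text())


def write_grm(grm: GRM, prefix) -> None:
    """GRM in the conventional lower-triangle text layout: ``<prefix>.grm``
    has columns i, j (1-based, j <= i), n SNPs, relatedness; ``<prefix>.grm.id``
    has family and individual ids."""
    prefix = Path(prefix)
    n = grm.A.shape[0]
    i_idx, j_idx = np.tril_indices(n)
    table = pd.DataFrame(
        {
            "i": i_idx + 1,
            "j": j_idx + 1,
            "m": grm.m[i_idx, j_idx].astype(int),
            "a": grm.A[i_idx, j_idx],
        }
    )
    table.to_csv(str(prefix) + ".grm", sep="\t", header=False, index=False,
                 float_format="%.6f")
    pd.DataFrame({"fid": grm.ids, "iid": grm.ids}).to_csv(
        str(prefix) + ".grm.id", sep="\t", header=False, index=False
    )


def read_grm(prefix) -> GRM:
    prefix = Path(prefix)
    ids = pd.read_csv(str(prefix) + ".grm.id", sep="\t", header=None,
                      names=["fid", "iid"])["iid"].to_numpy()
    tab = pd.read_csv(str(prefix) + ".grm", sep="\t", header=None,
                      names=["i", "j", "m", "a"])
    n = len(ids)
    A = np.zeros((n, n))
    M = np.zeros((n, n))
    i, j = tab["i"].to_numpy() - 1, tab["j"].to_numpy() - 1
    A[i, j] = tab["a"]
    A[j, i] = tab["a"]
    M[i, j] = tab["m"]
    M[j, i] = tab["m"]
    return GRM(A=A, m=M, ids=ids)


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=float))
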