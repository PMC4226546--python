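"""SNP quality control and ancestry principal components.

Filters follow the conventional array-QC trio: per-SNP call rate, minor
allele frequency, and Hardy-Weinberg equilibrium (exact test).  Allele
frequencies and HWE are computed on founders only, since related individuals
bias both.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from gwasplus.famsim import GenotypeMatrix, Pedigree

logger = logging.getLogger(__name__)


def hwe_exact_pvalue(n_het: int, n_hom_rare: int, n_hom_common: int) -> float:
    """Exact Hardy-Weinberg test p-value for biallelic genotype counts.

    Sums the probabilities of all heterozygote counts (given the observed
    allele counts) no more probable than the observed one, using the stable
    recurrence on the conditional distribution of heterozygotes.
    """
    n = n_het + n_hom_rare + n_hom_common
    if n == 0:
        return 1.0
    rare = 2 * n_hom_rare + n_het
    if rare > n:  # ensure 'rare' really is the minor allele
        rare = 2 * n - rare
    het_probs = np.zeros(rare + 1)
    # heterozygote count must share parity with the rare-allele count
    mid = rare * (2 * n - rare) // (2 * n)
    if mid % 2 != rare % 2:
        mid += 1
    het_probs[mid] = 1.0
    # downward recurrence: P(h-2)/P(h) = h(h-1) / (4 (nr+1) (nc+1))
    h = mid
    hom_r = (rare - mid) // 2
    hom_c = n - mid - hom_r
    while h > 1:
        het_probs[h - 2] = het_probs[h] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
        h -= 2
        hom_r += 1
        hom_c += 1
    # upward recurrence: P(h+2)/P(h) = 4 nr nc / ((h+2)(h+1))
    h = mid
    hom_r = (rare - mid) // 2
    hom_c = n - mid - hom_r
    while h <= rare - 2:
        het_probs[h + 2] = het_probs[h] * 4.0 * hom_r * hom_c / ((h + 2.0) * (h + 1.0))
        h += 2
        hom_r -= 1
        hom_c -= 1
    het_probs /= het_probs.sum()
    p = het_probs[het_probs <= het_probs[n_het] * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def qc_filter(
    genotypes: GenotypeMatrix,
    pedigree: Pedigree,
    callrate_min: float = 0.99,
    maf_min: float = 0.01,
    hwe_alpha: float = 1e-7,
):
    """Apply the call-rate / MAF / HWE filter trio to hard-call SNPs.

    Retains SNPs with call rate >= ``callrate_min``, founder MAF >=
    ``maf_min``, and founder HWE exact p >= ``hwe_alpha``.  Returns the
    filtered matrix and an exclusion report counting removals per criterion
    (a SNP may fail several).
    """
    for thr in (callrate_min, maf_min, hwe_alpha):
        if not (0.0 < thr < 1.0):
            raise ValueError("QC thresholds must lie in (0, 1)")
    vals = genotypes.values
    founder = pedigree.founder_mask()
    fid_in = pd.Index(pedigree.table["individual_id"][founder])
    founder_rows = np.isin(genotypes.ids, fid_in)
    callrate = 1.0 - np.isnan(vals).mean(axis=0)
    fv = vals[founder_rows]
    with np.errstate(invalid="ignore"):
        af = np.nanmean(fv, axis=0) / 2.0
    maf = np.minimum(af, 1.0 - af)
    hwe_p = np.ones(genotypes.n_snps)
    for j in range(genotypes.n_snps):
        g = fv[:, j]
        g = g[np.isfinite(g)]
        n_het = int((g == 1).sum())
        n_aa = int((g == 2).sum())
        n_bb = int((g == 0).sum())
        n_hom_rare, n_hom_common = (n_aa, n_bb) if n_aa <= n_bb else (n_bb, n_aa)
        hwe_p[j] = hwe_exact_pvalue(n_het, n_hom_rare, n_hom_common)
    pass_call = callrate >= callrate_min
    pass_maf = maf >= maf_min
    pass_hwe = hwe_p >= hwe_alpha
    keep = pass_call & pass_maf & pass_hwe
    report = {
        "n_input": int(genotypes.n_snps),
        "fail_callrate": int((~pass_call).sum()),
        "fail_maf": int((~pass_maf).sum()),
        "fail_hwe": int((~pass_hwe).sum()),
        "n_retained": int(keep.sum()),
    }
    logger.info("qc_filter: %s", report)
    if not keep.any():
        raise ValueError("no SNPs survive QC")
    return genotypes.subset_snps(keep), report


def compute_pcs(grm: np.ndarray, k: int = 10) -> np.ndarray:
    """Top-k principal components of a genetic relationship matrix.

    Returns the k leading unit-norm eigenvectors (columns), each with its
    largest-magnitude loading made positive for sign stability.
    """
    grm = np.asarray(grm, dtype=float)
    n = grm.shape[0]
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    if k == 0:
        return np.empty((n, 0))
    vals, vecs = np.linalg.eigh((grm + grm.T) / 2.0)
    order = np.argsort(vals)[::-1][:k]
    pcs = vecs[:, order]
    for j in range(k):
        i = np.argmax(np.abs(pcs[:, j]))
        if pcs[i, j] < 0:
            pcs[:, j] = -pcs[:, j]
    return pcs
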