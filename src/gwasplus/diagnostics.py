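"""GWAS-scale diagnostics: genomic inflation, residual checks, analytic power."""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

#: median of the chi-square distribution on 1 df (null median test statistic)
CHISQ1_MEDIAN = float(stats.chi2.ppf(0.5, df=1))

#: the genome-wide significance line, p = 5e-8
GENOME_WIDE_ALPHA = 5e-8


def genomic_inflation(p_values: np.ndarray):
    """Genomic inflation factor lambda.

    Converts p-values to 1-df chi-square quantiles and returns
    (lambda = observed median / 0.455 null median, mean chi-square).
    """
    p = np.asarray(p_values, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values supplied")
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    chisq = stats.chi2.isf(p, df=1)
    lam = float(np.median(chisq) / CHISQ1_MEDIAN)
    return lam, float(np.mean(chisq))


def lambda_from_median(median_chisq: float) -> float:
    """Lambda implied by an observed median 1-df chi-square statistic."""
    return float(median_chisq / CHISQ1_MEDIAN)


def residual_diagnostics(fit) -> dict:
    """Model checks for a covariates-only FGLS fit.

    Returns per-role standardized residuals (for normal QQ plots) and
    per-family squared Mahalanobis distances of residual vectors under the
    fitted covariance blocks, which are chi-square distributed on
    family-size degrees of freedom when the multivariate-normal residual
    assumption holds.  A KS test against the chi-square reference is run per
    family size.
    """
    index = fit.index
    resid_o = index.to_ordered(fit.residuals)
    role_rows = []
    md_rows = []
    for fid, ftype, roles, adopted, rows in index.families:
        sigma = fit.covmodel.block(ftype, roles, adopted)
        r = resid_o[rows]
        md2 = float(r @ np.linalg.solve(sigma, r))
        md_rows.append({"family_id": fid, "size": len(rows), "md2": md2})
        for role, rr, var in zip(roles, r, np.diag(sigma)):
            role_rows.append({"role": role, "residual": rr, "z": rr / np.sqrt(var)})
    roles_df = pd.DataFrame(role_rows)
    md_df = pd.DataFrame(md_rows)
    ks_rows = []
    for size, grp in md_df.groupby("size"):
        ks = stats.kstest(grp["md2"], stats.chi2(df=size).cdf)
        ks_rows.append({"size": size, "n_families": len(grp),
                        "ks_stat": ks.statistic, "ks_p": ks.pvalue})
    return {
        "role_residuals": roles_df,
        "mahalanobis": md_df,
        "mahalanobis_ks": pd.DataFrame(ks_rows),
    }


def power_single_snp(n: int, q2: float, alpha: float) -> float:
    """Analytic power of the 1-df additive single-SNP test.

    Uses the noncentral chi-square approximation with noncentrality
    n * q2 / (1 - q2), where q2 is the fraction of phenotypic variance the
    SNP explains, against the chi-square critical value at ``alpha``.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if not (0.0 <= q2 < 1.0):
        raise ValueError("q2 must lie in [0, 1)")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    crit = stats.chi2.isf(alpha, df=1)
    ncp = n * q2 / (1.0 - q2)
    if ncp == 0.0:
        return float(alpha)
    return float(stats.ncx2.sf(crit, df=1, nc=ncp))
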