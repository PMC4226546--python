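"""Manhattan, QQ, scoring-trend, and eBLUP plots."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from gwasplus.diagnostics import GENOME_WIDE_ALPHA

#: lane labels follow the GWAS convention for real data (23 = X,
#: 25 = pseudoautosomal, 26 = mitochondrial); synthetic fixtures are autosomal
CHROM_LABELS = {23: "X", 25: "PAR", 26: "MT"}


def manhattan(summary: pd.DataFrame, path, sig_alpha: float = GENOME_WIDE_ALPHA,
              title: str = "Manhattan plot") -> None:
    fig, ax = plt.subplots(figsize=(9, 3.5))
    offset = 0
    ticks, labels = [], []
    for k, (chrom, grp) in enumerate(summary.groupby("chrom")):
        x = offset + np.arange(len(grp))
        ax.scatter(x, -np.log10(grp["p"]), s=4,
                   color="C0" if k % 2 == 0 else "C1", rasterized=True)
        ticks.append(offset + len(grp) / 2)
        labels.append(str(CHROM_LABELS.get(chrom, chrom)))
        offset += len(grp)
    ax.axhline(-np.log10(sig_alpha), color="red", lw=1, ls="--")
    ax.set_xticks(ticks, labels)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def qq_uniform(p_values, path, title: str = "QQ plot of p-values") -> None:
    p = np.sort(np.asarray(p_values, dtype=float))
    p = p[np.isfinite(p)]
    n = len(p)
    expected = (np.arange(1, n + 1) - 0.5) / n
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(-np.log10(expected), -np.log10(p), ".", ms=3)
    lim = -np.log10(0.5 / n)
    ax.plot([0, lim], [0, lim], color="red", lw=1)
    # pointwise 95% band from the beta distribution of order statistics
    lo = stats.beta.ppf(0.025, np.arange(1, n + 1), n - np.arange(1, n + 1) + 1)
    hi = stats.beta.ppf(0.975, np.arange(1, n + 1), n - np.arange(1, n + 1) + 1)
    ax.plot(-np.log10(expected), -np.log10(lo), color="black", lw=0.8)
    ax.plot(-np.log10(expected), -np.log10(hi), color="black", lw=0.8)
    ax.set_xlabel(r"expected $-\log_{10}(p)$")
    ax.set_ylabel(r"observed $-\log_{10}(p)$")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def scoring_trend(cv_summary: pd.DataFrame, null_percentiles: pd.DataFrame | None,
                  path) -> None:
    """Cross-validated R^2 by p-value cutoff: solid = regression weights,
    dashed = signed unit weights, red = null 98th percentiles."""
    fig, ax = plt.subplots(figsize=(6, 4))
    styles = {"regression": "-", "signed_unit": "--"}
    for scheme, grp in cv_summary.groupby("scheme"):
        grp = grp.sort_values("cutoff")
        ax.plot(grp["cutoff"], 100 * grp["buse"], styles[scheme] + "o",
                color="black", label=f"{scheme} weights", ms=4)
    if null_percentiles is not None:
        for scheme, grp in null_percentiles.groupby("scheme"):
            grp = grp.sort_values("cutoff")
            ax.plot(grp["cutoff"], 100 * grp["buse_p98"], styles[scheme] + "s",
                    color="red", label=f"null 98th pct ({scheme})", ms=4)
    ax.set_xscale("log")
    ax.set_xlabel("p-value cutoff")
    ax.set_ylabel(r"Buse $R^2$ (%)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def normal_qq(values, path, title: str = "normal QQ") -> None:
    v = np.sort(np.asarray(values, dtype=float))
    n = len(v)
    q = stats.norm.ppf((np.arange(1, n + 1) - 0.5) / n)
    fig, ax = plt.subplots(figsize=(4.5, 4.5))
    ax.plot(q, v, ".", ms=3)
    sd, mu = np.std(v), np.mean(v)
    ax.plot(q, mu + sd * q, color="red", lw=1)
    ax.set_xlabel("theoretical quantile")
    ax.set_ylabel("observed")
    ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
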