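"""Feasible generalized least squares for family-clustered data.

Participants are clustered in families of known design type (twin, adoptive,
biological, mixed, step-parent), so regression residuals are correlated
within families.  The residual covariance is modelled per family type with a
role-variance / relationship-correlation parameterization (spouse, biological
and adoptive parent-offspring, MZ co-twin, biological and adoptive sibling),
estimated by maximum likelihood from covariates-only residuals.  The GWAS
proper plugs that fixed covariance into one GLS regression per SNP ("rapid"
FGLS); a full variant re-estimates the covariance per SNP and serves as the
reference for the approximation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from gwasplus.famsim import GenotypeMatrix, Pedigree, ROLE_ORDER

logger = logging.getLogger(__name__)

#: relationship classes whose correlations are shared across family types
REL_CLASSES = ("spouse", "po_bio", "po_adopt", "mz_twin", "sib_bio", "sib_adopt")

#: correlations are kept inside (-CORR_BOUND, CORR_BOUND) during estimation so
#: small samples cannot drive a block to singularity (e.g. an MZ correlation
#: walking to 1 in a 16-pair subsample)
CORR_BOUND = 0.99


def _role_class(role: str) -> str:
    return "offspring" if role.startswith("offspring") else role


def _relationship(ftype: str, r1: str, r2: str, a1: bool, a2: bool) -> str:
    pair = {r1, r2}
    if pair == {"father", "mother"}:
        return "spouse"
    if pair == {"offspring1", "offspring2"}:
        if ftype == "MZ":
            return "mz_twin"
        return "sib_adopt" if (a1 or a2) else "sib_bio"
    off_adopted = a1 if r1.startswith("offspring") else a2
    return "po_adopt" if off_adopted else "po_bio"


@dataclass
class FamilyCovarianceModel:
    """Residual covariance blocks per family type.

    ``role_var`` maps a role class ("father", "mother", "offspring",
    "singleton"; or "TYPE:role_class" when variances are fit per family
    type) to a residual variance; ``corr`` maps a relationship class to a
    correlation.  Blocks for families with missing members are principal
    submatrices of the full type block.
    """

    role_var: dict
    corr: dict

    def _var(self, ftype: str, role: str) -> float:
        cls = _role_class(role)
        key = f"{ftype}:{cls}"
        if key in self.role_var:
            return self.role_var[key]
        return self.role_var[cls]

    def block(self, ftype: str, roles: tuple, adopted: tuple) -> np.ndarray:
        k = len(roles)
        sd = np.array([np.sqrt(self._var(ftype, r)) for r in roles])
        sigma = np.diag(sd**2)
        for i in range(k):
            for j in range(i + 1, k):
                rel = _relationship(ftype, roles[i], roles[j], adopted[i], adopted[j])
                sigma[i, j] = sigma[j, i] = self.corr[rel] * sd[i] * sd[j]
        return sigma

    def to_json(self) -> str:
        return json.dumps({"role_var": self.role_var, "corr": self.corr}, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "FamilyCovarianceModel":
        d = json.loads(text)
        return cls(role_var=dict(d["role_var"]), corr=dict(d["corr"]))


class FamilyIndex:
    """Grouping of data rows into families and shared covariance patterns.

    Rows are reordered into a canonical family-contiguous layout; families
    with the same (type, present roles, adoption flags) share one covariance
    block and are processed as a batch.
    """

    def __init__(self, pedigree: Pedigree, ids: np.ndarray):
        ids = np.asarray(ids)
        pos = {iid: i for i, iid in enumerate(ids)}
        ped = pedigree.table[pedigree.table["individual_id"].isin(pos)].copy()
        if len(ped) != len(ids):
            missing = set(ids) - set(ped["individual_id"])
            raise KeyError(f"ids absent from pedigree: {sorted(missing)[:5]}")
        rank = {r: i for i, r in enumerate(ROLE_ORDER + ("singleton",))}
        self.families = []  # (family_id, ftype, roles, adopted, ordered-row slice)
        perm = []
        row = 0
        for fid, fam in ped.groupby("family_id", sort=False):
            fam = fam.sort_values("role", key=lambda s: s.map(rank))
            k = len(fam)
            roles = tuple(fam["role"])
            adopted = tuple(bool(a) for a in fam["adopted"])
            ftype = fam["family_type"].iloc[0]
            self.families.append((fid, ftype, roles, adopted, np.arange(row, row + k)))
            perm.extend(pos[i] for i in fam["individual_id"])
            row += k
        self.n = row
        self.perm = np.asarray(perm)  # ordered = x[perm]
        self.inv = np.empty_like(self.perm)
        self.inv[self.perm] = np.arange(self.n)  # x = ordered[inv]
        groups: dict = {}
        for fid, ftype, roles, adopted, rows in self.families:
            groups.setdefault((ftype, roles, adopted), []).append(rows)
        self.groups = {key: np.array(rows) for key, rows in groups.items()}

    def to_ordered(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[self.perm]

    def to_input(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x)[self.inv]


class Whitener:
    """Cholesky whitening operator for a block-diagonal family covariance."""

    def __init__(self, covmodel: FamilyCovarianceModel, index: FamilyIndex):
        self.index = index
        self.blocks = []
        self.logdet = 0.0
        for (ftype, roles, adopted), idx in index.groups.items():
            sigma = covmodel.block(ftype, roles, adopted)
            L = np.linalg.cholesky(sigma)
            self.blocks.append((idx, L))
            self.logdet += 2.0 * idx.shape[0] * np.log(np.diag(L)).sum()

    def whiten(self, m: np.ndarray) -> np.ndarray:
        """Apply L^{-1} per family to an ordered vector/matrix."""
        one_d = m.ndim == 1
        m2 = m[:, None] if one_d else m
        out = np.empty_like(m2, dtype=float)
        for idx, L in self.blocks:
            out[idx] = np.linalg.solve(L, m2[idx])
        return out[:, 0] if one_d else out


def build_design(
    pheno: pd.DataFrame,
    covariate_cols=("sex", "birth_year"),
    pcs: np.ndarray | None = None,
    y_col: str = "fsiq",
):
    """Assemble (y, X, names, ids) from a phenotype/covariate table.

    Sex is coded 0/1 (female = 1); birth year is centered.  An intercept is
    always included; principal-component columns are appended when given.
    """
    y = pheno[y_col].to_numpy(dtype=float)
    cols = [np.ones(len(pheno))]
    names = ["intercept"]
    for c in covariate_cols:
        v = pheno[c]
        if c == "sex":
            cols.append((v == "F").to_numpy(dtype=float))
        else:
            arr = v.to_numpy(dtype=float)
            cols.append(arr - arr.mean())
        names.append(c)
    if pcs is not None and np.size(pcs):
        pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
        if pcs.shape[0] != len(pheno):
            pcs = pcs.T
        for j in range(pcs.shape[1]):
            cols.append(pcs[:, j])
            names.append(f"PC{j + 1}")
    X = np.column_stack(cols)
    return y, X, names, pheno["individual_id"].to_numpy()


# ---------------------------------------------------------------------------
# Covariance-parameter maximum likelihood


class _CovParamFitter:
    """ML fitter for the covariance parameters.

    By default role variances are pooled across family types (father, mother,
    offspring, singleton), which keeps every parameter identifiable at modest
    family counts; ``var_by_type=True`` gives each family type its own role
    variances.
    """

    MIN_OBS_PER_VARIANCE = 10

    def __init__(self, index: FamilyIndex, var_by_type: bool = False):
        self.index = index
        var_counts: dict = {}
        corr_keys = set()
        for (ftype, roles, adopted), idx in index.groups.items():
            n_fam = idx.shape[0]
            for r in roles:
                key = f"{ftype}:{_role_class(r)}" if var_by_type else _role_class(r)
                var_counts[key] = var_counts.get(key, 0) + n_fam
            for i in range(len(roles)):
                for j in range(i + 1, len(roles)):
                    corr_keys.add(
                        _relationship(ftype, roles[i], roles[j], adopted[i], adopted[j])
                    )
        # a variance parameter estimated from a handful of observations can
        # collapse to zero and blow up the whitening; tie sparse role classes
        # to the best-populated parameter instead
        anchor = max(var_counts, key=var_counts.get)
        self.var_alias = {
            k: (k if c >= self.MIN_OBS_PER_VARIANCE or k == anchor else anchor)
            for k, c in var_counts.items()
        }
        self.var_keys = sorted(set(self.var_alias.values()))
        self.corr_keys = sorted(corr_keys)

    def pack(self, model: FamilyCovarianceModel) -> np.ndarray:
        corrs = np.array([model.corr.get(k, 0.0) for k in self.corr_keys])
        corrs = np.clip(corrs / CORR_BOUND, -0.999, 0.999)
        return np.concatenate(
            [
                np.log([model.role_var[k] for k in self.var_keys]),
                np.arctanh(corrs),
            ]
        )

    def unpack(self, theta: np.ndarray) -> FamilyCovarianceModel:
        nv = len(self.var_keys)
        # clip the exponent so optimizer excursions cannot overflow
        fitted = dict(zip(self.var_keys, np.exp(np.clip(theta[:nv], -30.0, 30.0))))
        role_var = {k: fitted[alias] for k, alias in self.var_alias.items()}
        corr = dict(zip(self.corr_keys, CORR_BOUND * np.tanh(theta[nv:])))
        for k in REL_CLASSES:
            corr.setdefault(k, 0.0)
        return FamilyCovarianceModel(role_var=role_var, corr=corr)

    def nll(self, theta: np.ndarray, resid: np.ndarray) -> float:
        model = self.unpack(theta)
        total = 0.0
        for (ftype, roles, adopted), idx in self.index.groups.items():
            sigma = model.block(ftype, roles, adopted)
            try:
                L = np.linalg.cholesky(sigma)
            except np.linalg.LinAlgError:
                return 1e12
            z = np.linalg.solve(L, resid[idx][..., None])
            total += idx.shape[0] * 2.0 * np.log(np.diag(L)).sum() + np.sum(z**2)
        return 0.5 * total

    def fit(self, resid: np.ndarray, init: FamilyCovarianceModel) -> FamilyCovarianceModel:
        x0 = self.pack(init)
        res = optimize.minimize(
            self.nll,
            x0,
            args=(resid,),
            method="L-BFGS-B",
            options={"maxiter": 300},
        )
        return self.unpack(res.x)


def _gls_coefficients(yw: np.ndarray, Xw: np.ndarray, names) -> pd.DataFrame:
    n, p = Xw.shape
    q, r = np.linalg.qr(Xw)
    diag = np.abs(np.diag(r))
    bad = diag < 1e-10 * max(diag.max(), 1.0)
    if bad.any():
        cols = [names[i] for i in np.where(bad)[0]]
        raise np.linalg.LinAlgError(f"singular design; collinear columns: {cols}")
    beta = np.linalg.solve(r, q.T @ yw)
    xtxi = np.linalg.inv(r.T @ r)
    se = np.sqrt(np.diag(xtxi))
    t = beta / se
    p_val = 2.0 * stats.t.sf(np.abs(t), df=n - p)
    return pd.DataFrame({"term": names, "beta": beta, "se": se, "t": t, "p": p_val})


@dataclass
class CovariatesOnlyFit:
    """Converged covariates-only FGLS fit, reusable downstream.

    Residuals and fitted values are in the original row order of the input
    table; the whitener and family index use the internal family-contiguous
    order.
    """

    covmodel: FamilyCovarianceModel
    coefficients: pd.DataFrame
    residuals: np.ndarray
    fitted: np.ndarray
    loglik: float
    n_iter: int
    index: FamilyIndex
    whitener: Whitener
    ids: np.ndarray
    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    names: list = field(default_factory=list)


def fit_covariates_only(
    pheno: pd.DataFrame,
    pedigree: Pedigree,
    covariate_cols=("sex", "birth_year"),
    pcs: np.ndarray | None = None,
    y_col: str = "fsiq",
    tol: float = 1e-6,
    max_iter: int = 100,
    var_by_type: bool = False,
) -> CovariatesOnlyFit:
    """FGLS regression of the phenotype onto covariates only.

    Alternates GLS coefficient estimation with maximum-likelihood estimation
    of the per-family-type covariance parameters until the log-likelihood
    changes by less than ``tol``.  The returned fit carries the estimated
    covariance model, to be plugged into per-SNP regressions.
    """
    y, X, names, ids = build_design(pheno, covariate_cols, pcs, y_col)
    index = FamilyIndex(pedigree, ids)
    yo, Xo = index.to_ordered(y), index.to_ordered(X)
    fitter = _CovParamFitter(index, var_by_type=var_by_type)
    beta = np.linalg.lstsq(Xo, yo, rcond=None)[0]
    resid = yo - Xo @ beta
    model = FamilyCovarianceModel(
        role_var={k: float(np.var(resid)) for k in fitter.var_alias},
        corr={k: 0.2 for k in REL_CLASSES},
    )
    last_ll = -np.inf
    trace = []
    for it in range(1, max_iter + 1):
        model = fitter.fit(resid, model)
        wh = Whitener(model, index)
        yw, Xw = wh.whiten(yo), wh.whiten(Xo)
        coefs = _gls_coefficients(yw, Xw, names)
        beta = coefs["beta"].to_numpy()
        resid = yo - Xo @ beta
        rw = yw - Xw @ beta
        ll = -0.5 * (index.n * np.log(2 * np.pi) + wh.logdet + float(rw @ rw))
        trace.append(ll)
        if abs(ll - last_ll) < tol:
            break
        last_ll = ll
    else:
        raise RuntimeError(
            f"covariates-only FGLS did not converge in {max_iter} iterations; "
            f"log-likelihood trace tail: {trace[-5:]}"
        )
    return CovariatesOnlyFit(
        covmodel=model,
        coefficients=coefs,
        residuals=index.to_input(resid),
        fitted=index.to_input(Xo @ beta),
        loglik=ll,
        n_iter=it,
        index=index,
        whitener=wh,
        ids=ids,
        X=X,
        y=y,
        names=names,
    )


def fgls_fit(
    y: np.ndarray,
    X: np.ndarray,
    covmodel: FamilyCovarianceModel,
    pedigree: Pedigree,
    ids: np.ndarray,
    names=None,
) -> pd.DataFrame:
    """One GLS regression with a fixed block-diagonal family covariance.

    Returns a coefficient table (beta, se, t, p) with standard errors from
    (X'V^-1 X)^-1 and two-sided p-values on n - p degrees of freedom.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    names = list(names) if names is not None else [f"x{j}" for j in range(X.shape[1])]
    index = FamilyIndex(pedigree, np.asarray(ids))
    wh = Whitener(covmodel, index)
    yw = wh.whiten(index.to_ordered(np.asarray(y, dtype=float)))
    Xw = wh.whiten(index.to_ordered(X))
    return _gls_coefficients(yw, Xw, names)


# ---------------------------------------------------------------------------
# The GWAS scan


def _scan_missing_snp(
    g: np.ndarray,
    yo: np.ndarray,
    Xo: np.ndarray,
    index: FamilyIndex,
    covmodel: FamilyCovarianceModel,
):
    """Exact FGLS for one SNP with missing genotypes: rows with missing calls
    are dropped and each family's covariance block is subset accordingly."""
    obs = np.isfinite(g)
    A = np.zeros((Xo.shape[1] + 1, Xo.shape[1] + 1))
    b = np.zeros(Xo.shape[1] + 1)
    yty = 0.0
    n_used = 0
    for fid, ftype, roles, adopted, rows in index.families:
        keep = obs[rows]
        if not keep.any():
            continue
        rws = rows[keep]
        sigma = covmodel.block(ftype, roles, adopted)[np.ix_(keep, keep)]
        Z = np.column_stack([Xo[rws], g[rws]])
        si = np.linalg.inv(sigma)
        A += Z.T @ si @ Z
        b += Z.T @ si @ yo[rws]
        yty += float(yo[rws] @ si @ yo[rws])
        n_used += keep.sum()
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.nan, np.nan, np.nan, np.nan, n_used
    df = n_used - len(b)
    cov = np.linalg.inv(A)
    se = np.sqrt(cov[-1, -1])
    t = beta[-1] / se
    p = 2.0 * stats.t.sf(abs(t), df=df)
    return beta[-1], se, t, p, n_used


def run_gwas(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    pedigree: Pedigree,
    covmodel: FamilyCovarianceModel,
    covariate_cols=("sex", "birth_year"),
    pcs: np.ndarray | None = None,
    dosages: GenotypeMatrix | None = None,
    y_col: str = "fsiq",
) -> pd.DataFrame:
    """Rapid-FGLS genome scan: one GLS regression per SNP (SNP + covariates)
    reusing the covariance model estimated once from the covariates-only fit.

    Dosage SNPs are treated as continuous regressors.  Missing genotypes are
    handled per SNP by row subsetting of the family covariance blocks.
    Returns the GWAS summary table (snp_id, chrom, pos, a1, beta, se, stat,
    p, n, typed).
    """
    geno = genotypes if dosages is None else GenotypeMatrix.concat(genotypes, dosages)
    y, X, names, ids = build_design(pheno, covariate_cols, pcs, y_col)
    geno = geno.subset_individuals(ids)
    index = FamilyIndex(pedigree, ids)
    yo, Xo = index.to_ordered(y), index.to_ordered(X)
    Go = geno.values[index.perm]
    wh = Whitener(covmodel, index)
    yw, Xw = wh.whiten(yo), wh.whiten(Xo)
    n, p = Xw.shape
    q, _ = np.linalg.qr(Xw)
    y_res = yw - q @ (q.T @ yw)

    m = Go.shape[1]
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    tstat = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    n_used = np.full(m, n)

    complete = ~np.isnan(Go).any(axis=0)
    if complete.any():
        Gw = wh.whiten(Go[:, complete])
        G_res = Gw - q @ (q.T @ Gw)
        den = np.einsum("ij,ij->j", G_res, G_res)
        ok = den > 1e-12
        num = G_res.T @ y_res
        b = np.where(ok, num / np.where(ok, den, 1.0), np.nan)
        df = n - p - 1
        # plug-in FGLS: V is the estimated residual covariance, so the
        # sampling variance of the SNP coefficient is 1/den directly
        s = np.sqrt(np.where(ok, 1.0 / np.where(ok, den, 1.0), np.nan))
        t = b / s
        cols = np.where(complete)[0]
        beta[cols], se[cols], tstat[cols] = b, s, t
        pval[cols] = 2.0 * stats.t.sf(np.abs(t), df=df)
        n_zero = int((~ok).sum())
        if n_zero:
            logger.warning("run_gwas: %d SNPs with zero variance; p recorded missing", n_zero)
    for j in np.where(~complete)[0]:
        g = Go[:, j]
        if np.nanvar(g) < 1e-12:
            logger.warning("run_gwas: SNP %s has zero variance after subsetting",
                           geno.snp_meta["snp_id"].iloc[j])
            continue
        beta[j], se[j], tstat[j], pval[j], n_used[j] = _scan_missing_snp(
            g, yo, Xo, index, covmodel
        )
    out = geno.snp_meta[["snp_id", "chrom", "pos", "a1", "typed"]].copy()
    out["beta"] = beta
    out["se"] = se
    out["stat"] = tstat
    out["p"] = pval
    out["n"] = n_used
    return out[["snp_id", "chrom", "pos", "a1", "beta", "se", "stat", "p", "n", "typed"]]


def run_gwas_full(
    genotypes: GenotypeMatrix,
    pheno: pd.DataFrame,
    pedigree: Pedigree,
    covariate_cols=("sex", "birth_year"),
    pcs: np.ndarray | None = None,
    init: FamilyCovarianceModel | None = None,
    y_col: str = "fsiq",
    tol: float = 1e-6,
    max_iter: int = 50,
) -> pd.DataFrame:
    """Full FGLS scan: the residual covariance is re-estimated for every SNP
    model.  Slow; serves as the reference for the rapid approximation."""
    y, X, names, ids = build_design(pheno, covariate_cols, pcs, y_col)
    geno = genotypes.subset_individuals(ids)
    index = FamilyIndex(pedigree, ids)
    yo, Xo = index.to_ordered(y), index.to_ordered(X)
    fitter = _CovParamFitter(index)
    rows = []
    for j in range(geno.n_snps):
        g = index.to_ordered(geno.values[:, j])
        Z = np.column_stack([Xo, g])
        model = init or FamilyCovarianceModel(
            role_var={k: float(np.var(yo)) for k in fitter.var_alias},
            corr={k: 0.2 for k in REL_CLASSES},
        )
        last = -np.inf
        for _ in range(max_iter):
            wh = Whitener(model, index)
            yw, Zw = wh.whiten(yo), wh.whiten(Z)
            coefs = _gls_coefficients(yw, Zw, names + ["snp"])
            resid = yo - Z @ coefs["beta"].to_numpy()
            rw = yw - Zw @ coefs["beta"].to_numpy()
            ll = -0.5 * (index.n * np.log(2 * np.pi) + wh.logdet + float(rw @ rw))
            if abs(ll - last) < tol:
                break
            last = ll
            model = fitter.fit(resid, model)
        snp_row = coefs.iloc[-1]
        rows.append((snp_row["beta"], snp_row["se"], snp_row["t"], snp_row["p"]))
    out = geno.snp_meta[["snp_id", "chrom", "pos", "a1", "typed"]].copy()
    out[["beta", "se", "stat", "p"]] = rows
    out["n"] = index.n
    return out
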