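"""Synthetic family study generator.

Emulates a two-study family design with six family types -- MZ- and DZ-twin
families, adoptive two-offspring families, biological two-offspring families,
mixed (one biological, one adopted) families, and step-parents treated as
one-person families.  Genotypes are generated with haplotype-block LD and
transmitted Mendelianly to biological offspring; a quantitative FSIQ-like
trait (mean ~100, SD ~15) combines a polygenic additive component, a
rearing-family shared-environment component, covariate effects (sex and
birth year), and a unique residual.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

FAMILY_TYPES = ("MZ", "DZ", "ADOPT2", "BIO2", "MIXED", "STEP")
ROLE_ORDER = ("father", "mother", "offspring1", "offspring2")

#: Default per-type member-presence probabilities (father/mother each, and the
#: second offspring; the first offspring is always present in non-STEP
#: families).  Chosen to reproduce the per-type mean family sizes of the
#: emulated design (MZ 3.45, DZ 3.31, ADOPT2 1.30, BIO2 2.57, MIXED 1.91).
DEFAULT_PRESENCE = {
    "MZ": {"parent": 0.75, "offspring2": 0.95},
    "DZ": {"parent": 0.69, "offspring2": 0.93},
    "ADOPT2": {"parent": 0.08, "offspring2": 0.14},
    "BIO2": {"parent": 0.48, "offspring2": 0.60},
    "MIXED": {"parent": 0.20, "offspring2": 0.50},
}


@dataclass(frozen=True)
class TraitArchitecture:
    """Generative architecture of the simulated quantitative trait.

    ``h2_target`` is the fraction of (pre-scaling) phenotypic variance from
    causal SNPs, ``c2_target`` the fraction from the rearing-family shared
    environment.  Covariate effects are in final trait units.
    """

    n_causal: int
    h2_target: float
    c2_target: float = 0.0
    beta_sex: float = 1.0
    beta_birthyear: float = -0.09
    scale_mean: float = 100.0
    scale_sd: float = 15.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2_target <= 1.0 and 0.0 <= self.c2_target <= 1.0):
            raise ValueError("h2_target and c2_target must lie in [0, 1]")
        if self.h2_target + self.c2_target > 1.0:
            raise ValueError("h2_target + c2_target must be <= 1")
        if self.n_causal < 0:
            raise ValueError("n_causal must be >= 0")


@dataclass
class Pedigree:
    """Individuals clustered in families of six design types.

    ``table`` columns: individual_id, family_id, family_type, role, sex
    ("M"/"F"), birth_year, adopted (bool).  Non-STEP families have at most
    four members with distinct roles; STEP families are single step-parents
    treated as independent observations.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {
            "individual_id",
            "family_id",
            "family_type",
            "role",
            "sex",
            "birth_year",
            "adopted",
        }
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"pedigree table missing columns: {sorted(missing)}")
        if self.table["individual_id"].duplicated().any():
            raise ValueError("individual ids must be unique")
        sizes = self.table.groupby("family_id").size()
        types = self.table.groupby("family_id")["family_type"].first()
        if (sizes[types != "STEP"] > 4).any():
            raise ValueError("non-STEP families may have at most 4 members")
        if (sizes[types == "STEP"] != 1).any():
            raise ValueError("STEP families must have exactly one member")

    def __len__(self) -> int:
        return len(self.table)

    @property
    def individual_ids(self) -> np.ndarray:
        return self.table["individual_id"].to_numpy()

    @property
    def n_families(self) -> int:
        return self.table["family_id"].nunique()

    def founder_mask(self) -> np.ndarray:
        """Founders: parents, step-parents, and adopted offspring (individuals
        with no biological parent in the design)."""
        role = self.table["role"]
        return (
            role.isin(["father", "mother", "singleton"]) | self.table["adopted"]
        ).to_numpy()

    def families(self):
        """Iterate (family_id, sub-table) in stable order."""
        return self.table.groupby("family_id", sort=False)


@dataclass
class GenotypeMatrix:
    """Genotypes as individuals x SNPs, hard calls {0,1,2,NaN} or dosages [0,2].

    ``snp_meta`` has one row per SNP: snp_id, chrom, pos (1-based), a1, a2,
    typed (bool), imputation_r2 (1.0 for typed SNPs), maf.
    """

    values: np.ndarray
    ids: np.ndarray
    snp_meta: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.ids = np.asarray(self.ids)
        if self.values.shape != (len(self.ids), len(self.snp_meta)):
            raise ValueError("values shape must be (n individuals, n SNPs)")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 2):
            raise ValueError("genotype values must lie in [0, 2]")
        for chrom, grp in self.snp_meta.groupby("chrom"):
            pos = grp["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"positions not strictly increasing on chrom {chrom}")

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_snps(self) -> int:
        return self.values.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "GenotypeMatrix":
        mask = np.asarray(mask)
        if mask.dtype != bool:  # a list of snp ids
            mask = np.isin(self.snp_meta["snp_id"].to_numpy(), mask)
        return GenotypeMatrix(
            self.values[:, mask],
            self.ids,
            self.snp_meta.loc[mask].reset_index(drop=True),
        )

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        order = {i: k for k, i in enumerate(self.ids)}
        try:
            rows = np.array([order[i] for i in ids])
        except KeyError as exc:
            raise KeyError(f"individual {exc.args[0]!r} not in genotype matrix")
        return GenotypeMatrix(self.values[rows], np.asarray(ids), self.snp_meta)

    @staticmethod
    def concat(a: "GenotypeMatrix", b: "GenotypeMatrix") -> "GenotypeMatrix":
        """Column-concatenate two matrices over the same individuals (e.g.
        typed hard calls plus imputed dosages), re-sorted by chrom/pos."""
        if not np.array_equal(a.ids, b.ids):
            raise ValueError("individual ids differ")
        meta = pd.concat([a.snp_meta, b.snp_meta], ignore_index=True)
        values = np.hstack([a.values, b.values])
        order = np.lexsort((meta["pos"].to_numpy(), meta["chrom"].to_numpy()))
        return GenotypeMatrix(values[:, order], a.ids, meta.iloc[order].reset_index(drop=True))


# ---------------------------------------------------------------------------
# Pedigree simulation


def simulate_families(
    counts_by_type: dict,
    intake_year_range: tuple = (1990, 2006),
    seed: int = 0,
    presence: dict | None = None,
) -> Pedigree:
    """Simulate a pedigree with the given number of families per type.

    Member presence (parents, second offspring) is thinned per type to emulate
    partial families; twins are same-sex and share a birth year.
    """
    counts = {t: int(counts_by_type.get(t, 0)) for t in FAMILY_TYPES}
    if any(c < 0 for c in counts.values()):
        raise ValueError("family counts must be >= 0")
    if sum(counts.values()) == 0:
        raise ValueError("empty design: all family counts are zero")
    presence = presence or DEFAULT_PRESENCE
    rng = np.random.default_rng(seed)
    rows = []
    for ftype in FAMILY_TYPES:
        for i in range(counts[ftype]):
            fid = f"{ftype}{i + 1:05d}"
            intake = int(rng.integers(intake_year_range[0], intake_year_range[1] + 1))
            if ftype == "STEP":
                rows.append(
                    {
                        "individual_id": f"{fid}_singleton",
                        "family_id": fid,
                        "family_type": ftype,
                        "role": "singleton",
                        "sex": "F" if rng.random() < 0.1 else "M",
                        "birth_year": intake - int(rng.integers(30, 56)),
                        "adopted": False,
                    }
                )
                continue
            pres = presence[ftype]
            has_father = rng.random() < pres["parent"]
            has_mother = rng.random() < pres["parent"]
            has_o2 = rng.random() < pres["offspring2"]
            # offspring birth years: twins identical, sibs a few years apart
            o1_by = intake - int(np.clip(round(rng.normal(14.0, 2.5)), 10, 20))
            if ftype in ("MZ", "DZ"):
                o2_by = o1_by
                twin_sex = "F" if rng.random() < 0.5 else "M"
                o1_sex = o2_sex = twin_sex
            else:
                o2_by = o1_by + int(rng.integers(1, 4)) * (1 if rng.random() < 0.5 else -1)
                o1_sex = "F" if rng.random() < 0.5 else "M"
                o2_sex = "F" if rng.random() < 0.5 else "M"
            parent_by = o1_by - int(rng.integers(22, 39))
            members = [
                ("father", has_father, "M", parent_by, False),
                ("mother", has_mother, "F", parent_by + int(rng.integers(-3, 4)), False),
                ("offspring1", True, o1_sex, o1_by, ftype == "ADOPT2"),
                ("offspring2", has_o2, o2_sex, o2_by, ftype in ("ADOPT2", "MIXED")),
            ]
            for role, present, sex, by, adopted in members:
                if present:
                    rows.append(
                        {
                            "individual_id": f"{fid}_{role}",
                            "family_id": fid,
                            "family_type": ftype,
                            "role": role,
                            "sex": sex,
                            "birth_year": by,
                            "adopted": adopted,
                        }
                    )
    return Pedigree(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Genotype simulation


def _block_ids(n_snps: int, ld_block_size: int, chrom: np.ndarray) -> np.ndarray:
    """Assign SNPs to LD blocks; blocks never span chromosome boundaries."""
    block = np.zeros(n_snps, dtype=int)
    b = 0
    count = 0
    for j in range(n_snps):
        if j > 0 and (chrom[j] != chrom[j - 1] or count >= ld_block_size):
            b += 1
            count = 0
        block[j] = b
        count += 1
    return block


def _draw_haplotypes(
    rng: np.random.Generator,
    k: int,
    thresholds: np.ndarray,
    block: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Draw k haplotypes from the population model: latent Gaussian AR(1)
    within each block (correlation rho^distance), thresholded to give each
    SNP its target allele frequency."""
    m = len(thresholds)
    innov = rng.standard_normal((k, m))
    if rho == 0.0 or np.all(block[1:] != block[:-1]):
        return (innov < thresholds).astype(np.int8)
    z = np.empty((k, m))
    carry = np.sqrt(1.0 - rho**2)
    z[:, 0] = innov[:, 0]
    for j in range(1, m):
        if block[j] != block[j - 1]:
            z[:, j] = innov[:, j]
        else:
            z[:, j] = rho * z[:, j - 1] + carry * innov[:, j]
    return (z < thresholds).astype(np.int8)


def simulate_genotypes(
    pedigree: Pedigree,
    n_snps: int,
    ld_block_size: int = 10,
    maf_range: tuple = (0.05, 0.5),
    missing_rate: float = 0.0,
    seed: int = 0,
    n_chromosomes: int = 4,
    ld_rho: float = 0.8,
) -> GenotypeMatrix:
    """Simulate hard-call genotypes for a pedigree.

    Founders (parents, adoptees, step-parents) are drawn independently from a
    haplotype population with within-block LD; biological offspring receive
    one haplotype per parent with blocks transmitted intact and free
    recombination between blocks; MZ co-twins are genetically identical;
    adoptees are unrelated to their rearing family.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    lo, hi = maf_range
    if not (0.0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    rng = np.random.default_rng(seed)
    mafs = rng.uniform(lo, hi, size=n_snps)
    chrom = 1 + (np.arange(n_snps) * n_chromosomes) // n_snps
    pos = np.concatenate(
        [5000 * (np.arange(np.sum(chrom == c)) + 1) for c in np.unique(chrom)]
    )
    block = _block_ids(n_snps, max(1, ld_block_size), chrom)
    thresholds = stats.norm.ppf(mafs)
    n_blocks = block[-1] + 1

    tab = pedigree.table
    row_of = {iid: k for k, iid in enumerate(tab["individual_id"])}
    # first pass: enumerate the founder genomes each family needs, so all
    # founder haplotypes can be drawn from the population in one batch
    plans = []  # (ftype, roles dict, adopted dict, founder-pair slot per source)
    n_pairs = 0
    for fid, fam in pedigree.families():
        ftype = fam["family_type"].iloc[0]
        roles = dict(zip(fam["role"], fam["individual_id"]))
        adopted = dict(zip(fam["role"], fam["adopted"]))
        slots = {}
        if ftype == "STEP":
            slots["singleton"] = n_pairs
            n_pairs += 1
        else:
            slots["father"], slots["mother"] = n_pairs, n_pairs + 1
            n_pairs += 2
            for r in ("offspring1", "offspring2"):
                if r in roles and adopted[r]:
                    slots[r] = n_pairs
                    n_pairs += 1
        plans.append((ftype, roles, adopted, slots))
    pool = _draw_haplotypes(rng, 2 * n_pairs, thresholds, block, ld_rho)

    def meiosis(pair_idx: int) -> np.ndarray:
        pick = rng.integers(0, 2, size=n_blocks)[block]
        return np.where(pick == 0, pool[2 * pair_idx], pool[2 * pair_idx + 1])

    def founder_geno(pair_idx: int) -> np.ndarray:
        return pool[2 * pair_idx] + pool[2 * pair_idx + 1]

    geno = np.empty((len(tab), n_snps), dtype=float)
    for ftype, roles, adopted, slots in plans:
        if ftype == "STEP":
            geno[row_of[roles["singleton"]]] = founder_geno(slots["singleton"])
            continue
        for parent in ("father", "mother"):
            if parent in roles:
                geno[row_of[roles[parent]]] = founder_geno(slots[parent])
        twin_geno = None
        for r in ("offspring1", "offspring2"):
            if r not in roles:
                continue
            if adopted[r]:
                geno[row_of[roles[r]]] = founder_geno(slots[r])
            elif ftype == "MZ" and twin_geno is not None:
                geno[row_of[roles[r]]] = twin_geno
            else:
                g = meiosis(slots["father"]) + meiosis(slots["mother"])
                geno[row_of[roles[r]]] = g
                if ftype == "MZ":
                    twin_geno = g
    if missing_rate > 0:
        miss = rng.random(geno.shape) < missing_rate
        geno[miss] = np.nan
    snp_meta = pd.DataFrame(
        {
            "snp_id": [f"snp{j + 1:06d}" for j in range(n_snps)],
            "chrom": chrom,
            "pos": pos,
            "a1": "A",
            "a2": "G",
            "typed": True,
            "imputation_r2": 1.0,
            "maf": mafs,
        }
    )
    return GenotypeMatrix(geno, tab["individual_id"].to_numpy(), snp_meta)


def simulate_dosages(
    genotypes: GenotypeMatrix,
    target_r2,
    seed: int = 0,
    snp_mask: np.ndarray | None = None,
) -> GenotypeMatrix:
    """Produce imputed-style dosages for a set of SNPs.

    Imputation replaces part of each SNP's information with the population
    expectation: with probability ``target_r2`` an individual's dosage is the
    true genotype, otherwise the population mean dosage 2f.  This gives
    Var(dosage) = R^2 Var(genotype) and corr(dosage, genotype) = sqrt(R^2)
    exactly -- the defining properties of the imputation R-squared quality
    metric -- while keeping dosages in [0, 2].  A target of 1 returns the
    true genotypes unchanged; missing true calls always become 2f.

    The imputed copies are placed midway between their source SNP and the
    next typed position, emulating untyped SNPs tagged by the array.
    """
    mask = (
        np.ones(genotypes.n_snps, dtype=bool) if snp_mask is None else np.asarray(snp_mask)
    )
    r2 = np.broadcast_to(np.asarray(target_r2, dtype=float), (int(mask.sum()),)).copy()
    if np.any(r2 <= 0) or np.any(r2 > 1):
        raise ValueError("target imputation R^2 values must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    g = genotypes.values[:, mask]
    mean_dosage = np.nanmean(g, axis=0)
    keep = rng.random(g.shape) < r2
    d = np.where(keep & np.isfinite(g), g, mean_dosage)
    meta = genotypes.snp_meta.loc[mask].reset_index(drop=True).copy()
    meta["typed"] = False
    meta["imputation_r2"] = r2
    meta["snp_id"] = meta["snp_id"] + "_imp"
    # shift positions into the gap after each source SNP so typed and imputed
    # sets never collide
    full = genotypes.snp_meta
    next_pos = full.groupby("chrom")["pos"].shift(-1)
    gap = (next_pos - full["pos"]).fillna(2.0).to_numpy()[mask]
    meta["pos"] = meta["pos"] + np.maximum(gap // 2, 1).astype(int)
    return GenotypeMatrix(d, genotypes.ids, meta)


# ---------------------------------------------------------------------------
# Phenotype simulation


def simulate_phenotype(
    pedigree: Pedigree,
    genotypes: GenotypeMatrix,
    arch: TraitArchitecture,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate the quantitative trait.

    y = causal-SNP additive score (variance h2) + rearing-family shared
    environmental deviate (variance c2, shared by all family members
    regardless of biological relatedness) + unique residual, rescaled to
    ``scale_mean``/``scale_sd``, plus sex and birth-year covariate effects.

    Returns a table with columns individual_id, family_id, family_type, role,
    sex, birth_year, fsiq, and the simulation truths g_true / c_true; the
    causal SNP ids are stored in ``result.attrs["causal_snps"]``.
    """
    rng = np.random.default_rng(seed)
    tab = pedigree.table.reset_index(drop=True)
    geno = genotypes.subset_individuals(tab["individual_id"].to_numpy())
    n = len(tab)
    if arch.n_causal > geno.n_snps:
        raise ValueError("n_causal exceeds number of SNPs")
    causal = rng.choice(geno.n_snps, size=arch.n_causal, replace=False)
    causal.sort()
    g_score = np.zeros(n)
    if arch.n_causal and arch.h2_target > 0:
        G = geno.values[:, causal].copy()
        mu = np.nanmean(G, axis=0)
        inds = np.where(np.isnan(G))
        G[inds] = np.take(mu, inds[1])
        G = G - mu
        effects = rng.standard_normal(arch.n_causal)
        raw = G @ effects
        sd = raw.std()
        if sd > 0:
            g_score = raw / sd * np.sqrt(arch.h2_target)
    fam_codes, fam_index = pd.factorize(tab["family_id"])
    c_fam = rng.standard_normal(len(fam_index)) * np.sqrt(arch.c2_target)
    c_score = c_fam[fam_codes]
    e_var = max(1.0 - arch.h2_target - arch.c2_target, 0.0)
    e_score = rng.standard_normal(n) * np.sqrt(e_var)
    y0 = g_score + c_score + e_score
    sex_f = (tab["sex"] == "F").astype(float).to_numpy()
    by = tab["birth_year"].to_numpy(dtype=float)
    y = (
        arch.scale_mean
        + arch.scale_sd * y0
        + arch.beta_sex * sex_f
        + arch.beta_birthyear * (by - by.mean())
    )
    out = tab[["individual_id", "family_id", "family_type", "role", "sex", "birth_year"]].copy()
    out["fsiq"] = y
    out["g_true"] = arch.scale_sd * g_score
    out["c_true"] = arch.scale_sd * c_score
    out.attrs["causal_snps"] = geno.snp_meta["snp_id"].to_numpy()[causal]
    out.attrs["architecture"] = arch
    return out


def average_repeated_measures(
    measure_table: pd.DataFrame,
    id_col: str = "individual_id",
    value_col: str = "fsiq",
) -> pd.Series:
    """Collapse repeated trait measurements to one within-person mean.

    Individuals with no non-missing measures are dropped (count logged).
    """
    if len(measure_table) == 0:
        raise ValueError("empty measure table")
    means = measure_table.groupby(id_col)[value_col].mean()
    dropped = int(means.isna().sum())
    if dropped:
        logger.info("average_repeated_measures: dropped %d individuals with no measures", dropped)
    return means.dropna()
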