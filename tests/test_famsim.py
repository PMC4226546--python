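"""Tests of the family-study simulator: pedigree structure, Mendelian
transmission, imputation-style dosages, and trait architecture."""

import numpy as np
import pandas as pd
import pytest

from gwasplus import famsim
from gwasplus.famsim import TraitArchitecture

from conftest import FULL_PRESENCE, toy_genotype_matrix


class TestSimulateFamilies:
    def test_member_counts_with_full_presence(self):
        ped = famsim.simulate_families(
            {"MZ": 10, "DZ": 5, "STEP": 3}, seed=0,
            presence=FULL_PRESENCE,
        )
        # 10*4 + 5*4 + 3 singletons
        assert len(ped) == 63

    def test_emulated_design_scale(self):
        """The emulated design at one-tenth scale: ~710 individuals in ~238
        families (partial membership included)."""
        counts = {"MZ": 114, "DZ": 64, "ADOPT2": 22, "BIO2": 18, "MIXED": 11,
                  "STEP": 8}
        ped = famsim.simulate_families(counts, seed=3)
        assert ped.n_families == 237
        assert 650 <= len(ped) <= 770

    def test_determinism(self):
        a = famsim.simulate_families({"MZ": 8, "DZ": 4, "STEP": 2}, seed=42)
        b = famsim.simulate_families({"MZ": 8, "DZ": 4, "STEP": 2}, seed=42)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError, match="empty design"):
            famsim.simulate_families({"MZ": 0}, seed=0)
        with pytest.raises(ValueError):
            famsim.simulate_families({"MZ": -1}, seed=0)

    def test_twins_same_sex_and_birth_year(self):
        ped = famsim.simulate_families(
            {"MZ": 30, "DZ": 30}, seed=7, presence=FULL_PRESENCE
        ).table
        for fid, fam in ped.groupby("family_id"):
            off = fam[fam["role"].str.startswith("offspring")]
            assert off["sex"].nunique() == 1
            assert off["birth_year"].nunique() == 1
            parents = fam[fam["role"].isin(["father", "mother"])]
            # parents plausibly older than offspring
            assert (parents["birth_year"] < off["birth_year"].min() - 15).all()

    def test_structure_invariants(self, small_pedigree):
        tab = small_pedigree.table
        assert tab["individual_id"].is_unique
        sizes = tab.groupby("family_id").size()
        types = tab.groupby("family_id")["family_type"].first()
        assert (sizes[types != "STEP"] <= 4).all()
        assert (sizes[types == "STEP"] == 1).all()
        # roles distinct within families
        assert (tab.groupby("family_id")["role"].nunique() == sizes).all()
        # adoption marks: ADOPT2 offspring adopted, MIXED offspring2 adopted
        mixed_o2 = tab[(tab.family_type == "MIXED") & (tab.role == "offspring2")]
        assert mixed_o2["adopted"].all()
        mixed_o1 = tab[(tab.family_type == "MIXED") & (tab.role == "offspring1")]
        assert not mixed_o1["adopted"].any()


class TestSimulateGenotypes:
    def test_mz_twins_identical(self, small_pedigree, small_genotypes):
        tab = small_pedigree.table
        row = {i: k for k, i in enumerate(small_genotypes.ids)}
        for fid, fam in tab[tab.family_type == "MZ"].groupby("family_id"):
            off = fam[fam.role.str.startswith("offspring")]["individual_id"]
            if len(off) == 2:
                a, b = (small_genotypes.values[row[i]] for i in off)
                m = np.isfinite(a) & np.isfinite(b)
                assert np.array_equal(a[m], b[m])

    def test_mendelian_consistency(self, full_pedigree):
        """No biological offspring genotype impossible given its parents."""
        geno = famsim.simulate_genotypes(full_pedigree, 300, seed=5)
        row = {i: k for k, i in enumerate(geno.ids)}
        tab = full_pedigree.table
        checked = 0
        for fid, fam in tab.groupby("family_id"):
            roles = dict(zip(fam.role, fam.individual_id))
            adopted = dict(zip(fam.role, fam.adopted))
            if "father" not in roles or "mother" not in roles:
                continue
            f = geno.values[row[roles["father"]]]
            m = geno.values[row[roles["mother"]]]
            for r in ("offspring1", "offspring2"):
                if r not in roles or adopted[r]:
                    continue
                o = geno.values[row[roles[r]]]
                # offspring allele count bounded by what parents can transmit
                lo = np.floor(f / 2) + np.floor(m / 2)  # 2 -> must give 1
                hi = np.ceil(f / 2) + np.ceil(m / 2)  # 0 -> must give 0
                assert np.all((o >= lo) & (o <= hi))
                checked += 1
        assert checked >= 50

    def test_grm_block_means_by_relationship(self):
        """Average relatedness ~0.5 for biological parent-offspring pairs,
        ~0 for adoptee vs rearing parent (quantitative-genetic oracle)."""
        ped = famsim.simulate_families(
            {"BIO2": 120, "ADOPT2": 120}, seed=11, presence=FULL_PRESENCE
        )
        geno = famsim.simulate_genotypes(ped, 5000, ld_block_size=1, seed=12)
        from gwasplus.greml import compute_grm

        A = compute_grm(geno).A
        row = {i: k for k, i in enumerate(geno.ids)}
        po_bio, po_adopt = [], []
        for fid, fam in ped.table.groupby("family_id"):
            roles = dict(zip(fam.role, fam.individual_id))
            adopted = dict(zip(fam.role, fam.adopted))
            for r in ("offspring1", "offspring2"):
                entry = A[row[roles["father"]], row[roles[r]]]
                (po_adopt if adopted[r] else po_bio).append(entry)
        po_bio, po_adopt = np.array(po_bio), np.array(po_adopt)
        assert len(po_bio) >= 200 and len(po_adopt) >= 200
        # sample-standardized GRMs carry an O(1/n) downward bias; allow for it
        for sample, expected in ((po_bio, 0.5), (po_adopt, 0.0)):
            se = sample.std(ddof=1) / np.sqrt(len(sample))
            assert abs(sample.mean() - expected) < 3 * se + 0.01

    def test_ld_within_blocks(self):
        ped = famsim.simulate_families({"STEP": 400}, seed=13)
        geno = famsim.simulate_genotypes(ped, 100, ld_block_size=10, seed=14)
        corr = np.corrcoef(geno.values, rowvar=False)
        adjacent_same_block = [abs(corr[j, j + 1]) for j in range(9)]
        cross_block = [abs(corr[9, 10]), abs(corr[19, 20])]
        assert np.mean(adjacent_same_block) > 0.3
        assert np.mean(cross_block) < 0.15

    def test_positions_and_errors(self, small_genotypes, small_pedigree):
        meta = small_genotypes.snp_meta
        for _, grp in meta.groupby("chrom"):
            assert (np.diff(grp["pos"]) > 0).all()
        with pytest.raises(ValueError):
            famsim.simulate_genotypes(small_pedigree, 0, seed=1)
        with pytest.raises(ValueError):
            famsim.simulate_genotypes(small_pedigree, 10, maf_range=(0.0, 0.6), seed=1)

    def test_determinism(self, small_pedigree):
        a = famsim.simulate_genotypes(small_pedigree, 50, seed=9)
        b = famsim.simulate_genotypes(small_pedigree, 50, seed=9)
        np.testing.assert_array_equal(a.values, b.values)


class TestSimulateDosages:
    def test_r2_one_reproduces_truth(self, small_genotypes):
        d = famsim.simulate_dosages(small_genotypes, 1.0, seed=1)
        np.testing.assert_array_equal(
            d.values[np.isfinite(small_genotypes.values)],
            small_genotypes.values[np.isfinite(small_genotypes.values)],
        )
        assert not d.snp_meta["typed"].any()

    def test_realized_variance_ratio(self):
        ped = famsim.simulate_families({"STEP": 1000}, seed=20)
        geno = famsim.simulate_genotypes(ped, 40, ld_block_size=1, seed=21)
        d = famsim.simulate_dosages(geno, 0.5, seed=22)
        ratio = d.values.var(axis=0) / geno.values.var(axis=0)
        assert np.all(np.abs(ratio - 0.5) < 0.1)

    def test_r2_filter_drops_low_targets(self, small_genotypes):
        rng = np.random.default_rng(3)
        targets = rng.uniform(0.2, 1.0, small_genotypes.n_snps)
        d = famsim.simulate_dosages(small_genotypes, targets, seed=4)
        kept = d.subset_snps(d.snp_meta["imputation_r2"].to_numpy() > 0.5)
        assert kept.n_snps == int((targets > 0.5).sum())

    def test_invalid_targets(self, small_genotypes):
        for bad in (0.0, -0.2, 1.5):
            with pytest.raises(ValueError):
                famsim.simulate_dosages(small_genotypes, bad, seed=0)


class TestSimulatePhenotype:
    def test_scale(self, small_phenotype):
        assert abs(small_phenotype["fsiq"].mean() - 100) < 3
        assert abs(small_phenotype["fsiq"].std() - 15) < 2.5

    def test_null_architecture_uncorrelated(self, small_pedigree, small_genotypes):
        arch = TraitArchitecture(n_causal=0, h2_target=0.0, c2_target=0.0)
        ph = famsim.simulate_phenotype(small_pedigree, small_genotypes, arch, seed=30)
        y = ph["fsiq"].to_numpy()
        G = np.nan_to_num(small_genotypes.values, nan=1.0)
        keep = G.std(axis=0) > 0
        r = np.corrcoef(np.column_stack([y, G[:, keep]]), rowvar=False)[0, 1:]
        # Bonferroni-style bound on max null correlation
        bound = 5.0 / np.sqrt(len(y))
        assert np.max(np.abs(r)) < bound

    def test_variance_decomposition_across_replicates(self, small_pedigree):
        """Realized variance shares of the genetic, shared-environment and
        unique components match the architecture within Monte-Carlo error."""
        arch = TraitArchitecture(n_causal=150, h2_target=0.4, c2_target=0.3)
        geno = famsim.simulate_genotypes(small_pedigree, 300, seed=40)
        h2s, c2s = [], []
        for rep in range(50):
            ph = famsim.simulate_phenotype(small_pedigree, geno, arch, seed=500 + rep)
            tot = (
                ph["fsiq"]
                - arch.beta_sex * (ph["sex"] == "F")
                - arch.beta_birthyear * (ph["birth_year"] - ph["birth_year"].mean())
            ).var()
            h2s.append(ph["g_true"].var() / tot)
            c2s.append(ph["c_true"].var() / tot)
        for observed, target in ((h2s, 0.4), (c2s, 0.3)):
            observed = np.asarray(observed)
            se = observed.std(ddof=1) / np.sqrt(len(observed))
            assert abs(observed.mean() - target) < 3 * se + 0.02

    def test_shared_environment_follows_rearing_family(self, full_pedigree):
        arch = TraitArchitecture(n_causal=0, h2_target=0.0, c2_target=0.5)
        geno = famsim.simulate_genotypes(full_pedigree, 20, seed=50)
        ph = famsim.simulate_phenotype(full_pedigree, geno, arch, seed=51)
        # c_true identical within every family, adoptees included
        assert (ph.groupby("family_id")["c_true"].nunique() == 1).all()

    def test_determinism(self, small_pedigree, small_genotypes):
        arch = TraitArchitecture(n_causal=10, h2_target=0.2)
        a = famsim.simulate_phenotype(small_pedigree, small_genotypes, arch, seed=60)
        b = famsim.simulate_phenotype(small_pedigree, small_genotypes, arch, seed=60)
        pd.testing.assert_frame_equal(a, b)

    def test_architecture_validation(self):
        with pytest.raises(ValueError):
            TraitArchitecture(n_causal=1, h2_target=0.7, c2_target=0.4)
        with pytest.raises(ValueError):
            TraitArchitecture(n_causal=-1, h2_target=0.1)


class TestAverageRepeatedMeasures:
    def test_means_and_row_count(self):
        table = pd.DataFrame(
            {
                "individual_id": ["a", "a", "a", "b", "c", "c"],
                "fsiq": [100.0, 104.0, 108.0, 97.0, 90.0, 94.0],
            }
        )
        out = famsim.average_repeated_measures(table)
        assert out["a"] == 104.0
        assert out["b"] == 97.0
        assert len(out) == 3

    def test_retested_twins_collapse_to_one_row_each(self):
        """3,226 individuals of whom 903 tested twice and 337 three times
        collapse to 3,226 rows (miniature: 60/18/7)."""
        rng = np.random.default_rng(8)
        rows = []
        for i in range(60):
            n_tests = 3 if i < 7 else (2 if i < 25 else 1)
            for _ in range(n_tests):
                rows.append({"individual_id": f"t{i}", "fsiq": rng.normal(100, 15)})
        out = famsim.average_repeated_measures(pd.DataFrame(rows))
        assert len(out) == 60

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            famsim.average_repeated_measures(pd.DataFrame({"individual_id": [], "fsiq": []}))


def test_toy_matrix_validation():
    with pytest.raises(ValueError):
        toy_genotype_matrix([[0, 3.0]])
    with pytest.raises(ValueError):
        toy_genotype_matrix([[0, 1]], pos=[5, 5])
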