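"""Neutral-marker statistics: Weir-Cockerham theta against hand-worked
variance components, AMOVA closure and edge cases, Evanno delta-K
arithmetic, membership thresholds, file round trips."""

import numpy as np
import pandas as pd
import pytest

from spectraits.popgen import (GenotypeTable, amova, assign_membership,
                               evanno_delta_k, fst_bootstrap_ci,
                               pairwise_fst, read_genotypes, read_structure,
                               wc_theta, write_genotypes,
                               _wc_locus_components)

from conftest import balding_nichols_table


class TestTheta:
    def test_hand_computed_components(self, toy_genotypes):
        """2 pops x 2 inds, alleles (0,0),(0,1) vs (1,1),(1,1):
        summed a = 0.5, a+b+c = 0.75, theta = 2/3 (worked by hand from the
        1984 variance-component formulas)."""
        a, abc = _wc_locus_components(toy_genotypes.alleles[:, 0, :],
                                      toy_genotypes.population)
        assert np.isclose(a, 0.5)
        assert np.isclose(abc, 0.75)
        assert np.isclose(a / abc, 2 / 3)

    def test_fixed_private_alleles_theta_one(self):
        geno = np.tile(np.array([[[0, 0]], [[1, 1]]]), (5, 1, 1))
        pops = np.array(["p1", "p2"] * 5)
        g = GenotypeTable(tuple(f"s{i}" for i in range(10)), pops, pops,
                          ("L1",), geno)
        assert np.isclose(wc_theta(g, g.population), 1.0)

    def test_panmictic_pair_theta_near_zero(self):
        thetas = [wc_theta(g, g.population) for g in
                  (balding_nichols_table(0.0, n_pops=2, n_inds=30,
                                         n_loci=20, seed=s)
                   for s in range(20))]
        assert abs(np.mean(thetas)) < 0.01

    def test_allele_relabeling_invariance(self, toy_genotypes):
        relabeled = toy_genotypes.alleles.copy()
        relabeled = np.where(relabeled == 0, 7, np.where(relabeled == 1, 0,
                                                         relabeled))
        g2 = GenotypeTable(toy_genotypes.sample_ids, toy_genotypes.species,
                           toy_genotypes.population, toy_genotypes.loci,
                           relabeled)
        assert np.isclose(wc_theta(g2, g2.population),
                          wc_theta(toy_genotypes, toy_genotypes.population))

    def test_locus_order_invariance(self):
        g = balding_nichols_table(0.2, n_pops=2, n_inds=10, n_loci=6, seed=4)
        flipped = GenotypeTable(g.sample_ids, g.species, g.population,
                                g.loci[::-1], g.alleles[:, ::-1, :])
        assert np.isclose(wc_theta(g, g.population),
                          wc_theta(flipped, flipped.population))

    def test_pairwise_over_three_groups(self):
        g = balding_nichols_table(0.1, n_pops=3, n_inds=12, n_loci=8, seed=2)
        res = pairwise_fst(g, level="population")
        assert len(res) == 3
        assert all(-1 <= r.theta <= 1 for r in res)

    def test_underpowered_group_rejected(self):
        geno = np.array([[[0, 0]], [[0, 1]], [[1, 1]]])
        labels = np.array(["p1", "p1", "p2"])
        g = GenotypeTable(("a", "b", "c"), labels, labels, ("L1",), geno)
        with pytest.raises(ValueError):
            pairwise_fst(g, level="population")


class TestBootstrapCI:
    def test_identical_loci_zero_width(self):
        geno = np.tile(np.array([[[0, 0]], [[0, 1]], [[1, 1]], [[1, 1]]]),
                       (1, 5, 1))
        pops = np.array(["p1", "p1", "p2", "p2"])
        g = GenotypeTable(("a", "b", "c", "d"), pops, pops,
                          tuple(f"L{i}" for i in range(5)), geno)
        r = fst_bootstrap_ci(g, ("p1", "p2"), n_boot=200, seed=0)
        assert np.isclose(r.ci_low, r.ci_high)
        assert np.isclose(r.ci_low, r.theta)

    def test_deterministic_given_seed(self):
        g = balding_nichols_table(0.15, n_pops=2, n_inds=15, n_loci=10, seed=1)
        r1 = fst_bootstrap_ci(g, ("sp1_p1", "sp1_p2"), n_boot=100, seed=5)
        r2 = fst_bootstrap_ci(g, ("sp1_p1", "sp1_p2"), n_boot=100, seed=5)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)
        assert r1.ci_low <= r1.theta <= r1.ci_high

    def test_single_locus_rejected(self):
        g = balding_nichols_table(0.1, n_pops=2, n_inds=10, n_loci=1, seed=0)
        with pytest.raises(ValueError):
            fst_bootstrap_ci(g, ("sp1_p1", "sp1_p2"), n_boot=10, seed=0)


def nested_table(n_species=3, pops_per=2, inds=8, n_loci=6, fst=0.15, seed=0):
    from spectraits.simulate import SimConfig, gen_genotypes
    return gen_genotypes(SimConfig(n_species=n_species,
                                   pops_per_species=pops_per,
                                   inds_per_pop=inds, n_loci=n_loci,
                                   fst_target=fst, seed=seed))


class TestAmova:
    def test_percentages_close_to_100(self):
        g = nested_table(seed=3)
        res = amova(g)
        assert abs(sum(res.percentages.values()) - 100.0) < 0.1

    def test_private_species_alleles_all_among_species(self):
        # 2 species, each fixed for its own allele at every locus
        n = 8
        geno = np.concatenate([np.zeros((n, 3, 2)), np.ones((n, 3, 2))])
        species = np.array(["s1"] * n + ["s2"] * n)
        pops = np.array((["s1p1"] * 4 + ["s1p2"] * 4 +
                         ["s2p1"] * 4 + ["s2p2"] * 4))
        g = GenotypeTable(tuple(f"i{k}" for k in range(2 * n)), species,
                          pops, ("L1", "L2", "L3"), geno.astype(int))
        res = amova(g)
        assert res.percentages["among_species"] > 99.9

    def test_panmictic_relabeling_no_species_signal(self):
        pcts = []
        for seed in range(8):
            g = nested_table(n_species=1, pops_per=4, inds=15, fst=0.0,
                             seed=seed)
            # relabel panmictic populations into two fake species
            pops = g.population
            fake_species = np.where(
                np.isin(pops, pd.unique(pops)[:2]), "fakeA", "fakeB")
            g2 = GenotypeTable(g.sample_ids, fake_species, pops, g.loci,
                               g.alleles)
            pcts.append(amova(g2).percentages["among_species"])
        assert np.mean(pcts) <= 1.0

    def test_duplication_stability(self):
        """MoM components are not exactly duplication-invariant (df vs SS),
        but percentages should move only modestly at this size."""
        g = nested_table(seed=5)
        g2 = GenotypeTable(
            tuple(list(g.sample_ids) + [s + "b" for s in g.sample_ids]),
            np.tile(g.species, 2), np.tile(g.population, 2), g.loci,
            np.tile(g.alleles, (2, 1, 1)))
        p1, p2 = amova(g).percentages, amova(g2).percentages
        assert max(abs(p1[k] - p2[k]) for k in p1) < 5.0

    def test_permutation_p_values(self):
        g = nested_table(n_species=2, pops_per=2, inds=6, fst=0.3, seed=7)
        res = amova(g, n_perm=49, seed=0)
        assert set(res.p_values) == {"among_species", "among_populations",
                                     "among_individuals"}
        assert all(0 < p <= 1 for p in res.p_values.values())

    def test_single_species_rejected(self):
        g = nested_table(n_species=1, seed=0)
        with pytest.raises(ValueError):
            amova(g)


class TestEvanno:
    def test_direct_arithmetic(self):
        """mean L = (-100, -80, -75), sd(L(2)) = 3 -> delta-K(2) = 5."""
        tbl = pd.DataFrame({
            1: [-103, -100, -97],
            2: [-83, -80, -77],
            3: [-78, -75, -72],
        }, dtype=float)
        # set sd of K=2 column to exactly 3
        tbl[2] = [-80 - 3, -80.0, -80 + 3]
        sd = tbl[2].std(ddof=1)
        k_star, curve = evanno_delta_k(tbl)
        expected = abs(-75 + 160 - 100) / sd
        assert np.isclose(curve.loc[2, "delta_k"], expected)

    def test_linear_means_give_zero(self):
        # replicates symmetric about an exactly linear mean: sd > 0,
        # second difference exactly 0
        tbl = pd.DataFrame({k: [-100 + 10 * k - 1, -100 + 10 * k + 1]
                            for k in range(1, 6)}, dtype=float)
        _, curve = evanno_delta_k(tbl)
        assert (curve["delta_k"] == 0).all()

    def test_zero_sd_excluded_with_warning(self):
        tbl = pd.DataFrame({1: [-100.0, -99.0], 2: [-80.0, -80.0],
                            3: [-70.0, -69.0], 4: [-65.0, -64.0]})
        with pytest.warns(UserWarning):
            k_star, curve = evanno_delta_k(tbl)
        assert 2 not in curve.index

    def test_requires_three_consecutive_k(self):
        with pytest.raises(ValueError):
            evanno_delta_k(pd.DataFrame({1: [0, 1], 3: [0, 1], 4: [0, 1]}))


class TestMembership:
    def test_majority_assignment(self):
        q = pd.DataFrame([[0.7, 0.3]], columns=["c1", "c2"], index=["s1"])
        out = assign_membership(q, threshold=0.6)
        assert out.loc["s1", "cluster"] == "c1"
        assert not out.loc["s1", "admixed"]

    def test_tie_is_admixed(self):
        q = pd.DataFrame([[0.5, 0.5]], columns=["c1", "c2"], index=["s1"])
        assert assign_membership(q, 0.6).loc["s1", "admixed"]

    def test_spatial_clustering_variant_07(self):
        q = pd.DataFrame([[0.65, 0.35]], columns=["c1", "c2"], index=["s1"])
        assert not assign_membership(q, threshold=0.6).loc["s1", "admixed"]
        assert assign_membership(q, threshold=0.7).loc["s1", "admixed"]

    def test_bad_rows_rejected(self):
        q = pd.DataFrame([[0.7, 0.2]], columns=["c1", "c2"], index=["s1"])
        with pytest.raises(ValueError):
            assign_membership(q)


class TestIO:
    def test_genotype_roundtrip_with_missing(self, tmp_path):
        g = nested_table(seed=9)
        alleles = g.alleles.copy()
        alleles[0, 0, :] = -1
        g = GenotypeTable(g.sample_ids, g.species, g.population, g.loci,
                          alleles)
        write_genotypes(g, tmp_path / "g.csv")
        back = read_genotypes(tmp_path / "g.csv")
        assert back.loci == g.loci
        assert (back.alleles == g.alleles).all()
        assert (back.population == g.population).all()

    def test_structure_two_row_format(self, tmp_path):
        text = ("ind1 pop1 100 102\n"
                "ind1 pop1 100 104\n"
                "ind2 pop2 102 -9\n"
                "ind2 pop2 102 104\n")
        p = tmp_path / "s.str"
        p.write_text(text)
        g = read_structure(p, n_loci=2)
        assert g.n_samples == 2 and g.n_loci == 2
        assert g.alleles[1, 1, 0] == -1  # missing code
        assert g.alleles[0, 0, 0] == 100
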