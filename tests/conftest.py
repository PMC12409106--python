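import dendropy
import numpy as np
import pandas as pd
import pytest

from spectraits.popgen import GenotypeTable
from spectraits.spectra import SpectraSet


@pytest.fixture
def grid_3nm():
    """Standard 400-2500 nm grid at 3 nm."""
    return np.arange(400.0, 2500.0 + 1e-9, 3.0)


@pytest.fixture
def flat_spectra(grid_3nm):
    return SpectraSet(grid_3nm, np.full((3, grid_3nm.size), 0.5),
                      state="resampled")


def star_tree(n: int, depth: float = 1.0) -> dendropy.Tree:
    """Star phylogeny: n tips hanging directly off the root."""
    taxa = dendropy.TaxonNamespace([f"x{i}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    for i in range(n):
        node = dendropy.Node()
        node.taxon = taxa[i]
        node.edge.length = depth
        tree.seed_node.add_child(node)
    return tree


@pytest.fixture
def balanced4():
    """((a:1,b:1):1,(c:1,d:1):1); sister tips share path length 1."""
    return dendropy.Tree.get(data="((a:1,b:1):1,(c:1,d:1):1);",
                             schema="newick")


@pytest.fixture
def toy_genotypes():
    """2 pops x 2 inds, 1 locus; hand-computed WC components in tests."""
    geno = np.array([[[0, 0]], [[0, 1]], [[1, 1]], [[1, 1]]])
    pops = np.array(["p1", "p1", "p2", "p2"])
    return GenotypeTable(("s1", "s2", "s3", "s4"), pops, pops, ("L1",), geno)


def balding_nichols_table(fst, n_pops=4, n_inds=30, n_loci=20, seed=0,
                          n_species=1):
    from spectraits.simulate import SimConfig, gen_genotypes
    cfg = SimConfig(n_species=n_species, pops_per_species=n_pops,
                    inds_per_pop=n_inds, n_loci=n_loci, fst_target=fst,
                    seed=seed)
    return gen_genotypes(cfg)


@pytest.fixture
def trait_frame():
    rng = np.random.default_rng(0)
    idx = [f"s{i}" for i in range(40)]
    return pd.DataFrame({"lma": rng.normal(160, 25, 40),
                         "lignin": rng.normal(12, 2, 40)}, index=idx)
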