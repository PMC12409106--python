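"""Synthetic datasets with known ground truth for every pipeline stage.

Generates the six input kinds the analysis consumes — phylogeny, traits,
reflectance spectra, diploid microsatellite genotypes, environment tables and
coordinates — under simple, analytically tractable models:

* Yule (pure-birth) ultrametric phylogenies;
* Brownian-motion trait evolution on a tree;
* Balding-Nichols allele frequencies, which give a closed-form differentiation
  target E[theta] ~ ``fst_target``;
* spectra = smooth baseline minus Gaussian absorption features scaled by
  trait values, plus Gaussian noise;
* environment = group effect (IBE share) + smooth latitudinal gradient (IBD
  share) + noise, with the true variance shares recorded.

A single global seed fans out to fixed, named substreams (one per generator),
so adding a generator never perturbs the streams of existing ones.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .popgen import GenotypeTable
from .spectra import SpectraSet

__all__ = [
    "SimConfig",
    "gen_phylogeny",
    "gen_bm_traits",
    "gen_genotypes",
    "gen_spectra",
    "gen_env_geo",
    "gen_ibe_ibd_response",
    "simulate_dataset",
]

# fixed substream indices; append-only so streams stay stable
_SUBSTREAMS = {"phylogeny": 0, "bm_traits": 1, "genotypes": 2,
               "spectra": 3, "env_geo": 4, "labels": 5, "response": 6}

#: default six-trait archetypes: (grand mean, within-group sd) in the
#: measurement units of each trait (LMA g m-2, thickness mm, carbon
#: fractions %); group means wander around the grand mean under BM
DEFAULT_TRAITS = {
    "LMA": (160.0, 25.0),
    "thickness": (0.45, 0.06),
    "cell_solubles": (45.0, 4.0),
    "hemicellulose": (14.0, 2.0),
    "cellulose": (18.0, 2.5),
    "lignin": (12.0, 2.0),
}

#: absorption features (center nm, width nm, loading per unit trait value);
#: placed in chemically sensible neighborhoods (pigments in the VIS,
#: water/structure in NIR, carbon chemistry in the SWIR)
DEFAULT_BANDS = [
    ("LMA", 1450.0, 40.0, 6e-4),
    ("thickness", 1930.0, 45.0, 0.18),
    ("cell_solubles", 680.0, 25.0, 2.5e-3),
    ("hemicellulose", 2100.0, 35.0, 6e-3),
    ("cellulose", 2270.0, 35.0, 5e-3),
    ("lignin", 1720.0, 30.0, 7e-3),
]


@dataclass(frozen=True)
class SimConfig:
    """Knobs of the synthetic study design (defaults mirror a small
    multi-species, multi-population microsatellite + spectra survey)."""

    n_species: int = 7
    pops_per_species: int = 2
    inds_per_pop: int = 10
    n_loci: int = 11
    alleles_per_locus: int = 8
    fst_target: float = 0.15
    trait_archetypes: dict = field(default_factory=lambda: dict(DEFAULT_TRAITS))
    band_library: list = field(default_factory=lambda: list(DEFAULT_BANDS))
    noise_sd: float = 0.005
    ibe_fraction: float = 0.4
    ibd_fraction: float = 0.1
    bm_sigma2: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.fst_target < 1):
            raise ValueError("fst_target must be in [0, 1)")
        for name, frac in (("ibe_fraction", self.ibe_fraction),
                           ("ibd_fraction", self.ibd_fraction)):
            if not (0 <= frac <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.ibe_fraction + self.ibd_fraction > 1 + 1e-12:
            raise ValueError("ibe_fraction + ibd_fraction must be <= 1")
        for trait, center, width, _ in self.band_library:
            if not (400 <= center <= 2500):
                raise ValueError(f"band center {center} nm outside 400-2500 nm")
            if trait not in self.trait_archetypes:
                raise ValueError(f"band references unknown trait {trait!r}")

    def substream(self, name: str) -> np.random.Generator:
        ss = np.random.SeedSequence(self.seed, spawn_key=(_SUBSTREAMS[name],))
        return np.random.default_rng(ss)


def _rng_for(seed: int, name: str) -> np.random.Generator:
    ss = np.random.SeedSequence(seed, spawn_key=(_SUBSTREAMS[name],))
    return np.random.default_rng(ss)


# ------------------------------------------------------------- phylogeny

def gen_phylogeny(n_tips: int, seed: int = 0) -> dendropy.Tree:
    """Ultrametric Yule (pure-birth, rate 1) tree with ``n_tips`` leaves.

    Forward simulation: start from a root split into two lineages; wait an
    Exp(k) time with k extant lineages, split a uniformly chosen lineage;
    after the last split all tips are extended to the present, so root-to-tip
    depths are exactly equal.
    """
    if n_tips < 3:
        raise ValueError("n_tips must be >= 3")
    rng = _rng_for(seed, "phylogeny")

    taxa = dendropy.TaxonNamespace([f"t{i+1}" for i in range(n_tips)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    # active lineages: (node, birth_time)
    root = tree.seed_node
    active = []
    t = 0.0
    for _ in range(2):
        child = dendropy.Node()
        root.add_child(child)
        active.append((child, t))
    while len(active) < n_tips:
        t += rng.exponential(1.0 / len(active))
        i = rng.integers(len(active))
        node, born = active.pop(i)
        node.edge.length = t - born
        for _ in range(2):
            child = dendropy.Node()
            node.add_child(child)
            active.append((child, t))
    t += rng.exponential(1.0 / len(active))  # stem time after last split
    order = rng.permutation(len(active))  # random taxon placement
    for k, i in enumerate(order):
        node, born = active[i]
        node.edge.length = t - born
        node.taxon = taxa[k]
    tree.seed_node.edge.length = 0.0
    return tree


def gen_bm_traits(
    tree: dendropy.Tree,
    sigma2: float = 1.0,
    root_value: float = 0.0,
    seed: int = 0,
    trait_name: str = "trait",
) -> pd.DataFrame:
    """One Brownian-motion trait value per tip.

    Tip values are jointly Gaussian, mean ``root_value``, covariance
    ``sigma2`` times the shared-branch-length matrix.  ``sigma2 = 0`` is the
    degenerate constant trait.
    """
    from .phylo import phylo_vcv

    if sigma2 < 0:
        raise ValueError("sigma2 must be non-negative")
    V = phylo_vcv(tree)
    if (np.diag(V.to_numpy()) <= 0).any() and sigma2 > 0:
        raise ValueError("tree must have positive root-to-tip path lengths")
    n = V.shape[0]
    if sigma2 == 0:
        vals = np.full(n, float(root_value))
    else:
        rng = _rng_for(seed, "bm_traits")
        L = np.linalg.cholesky(sigma2 * V.to_numpy())
        vals = root_value + L @ rng.standard_normal(n)
    return pd.DataFrame({trait_name: vals}, index=V.index)


# ------------------------------------------------------------- genotypes

def group_labels(cfg: SimConfig) -> pd.DataFrame:
    """Sample metadata frame: sample_id, species, population."""
    rows = []
    for s in range(cfg.n_species):
        for p in range(cfg.pops_per_species):
            for i in range(cfg.inds_per_pop):
                rows.append({
                    "sample_id": f"sp{s+1}_p{p+1}_i{i+1}",
                    "species": f"sp{s+1}",
                    "population": f"sp{s+1}_p{p+1}",
                })
    return pd.DataFrame(rows).set_index("sample_id")


def gen_genotypes(cfg: SimConfig) -> GenotypeTable:
    """Diploid genotypes under the Balding-Nichols model.

    Per locus, ancestral frequencies ~ symmetric Dirichlet(1); each
    population's frequencies ~ Dirichlet(ancestral * (1 - F) / F) with
    F = ``fst_target`` (F = 0 collapses to identical frequencies), then
    two allele copies per individual are drawn independently.
    """
    if cfg.alleles_per_locus < 2:
        raise ValueError("alleles_per_locus must be >= 2")
    rng = cfg.substream("genotypes")
    meta = group_labels(cfg)
    pops = meta["population"].unique()
    n = len(meta)
    F = cfg.fst_target
    geno = np.empty((n, cfg.n_loci, 2), dtype=np.int64)
    for l in range(cfg.n_loci):
        anc = rng.dirichlet(np.ones(cfg.alleles_per_locus))
        for pop in pops:
            mask = (meta["population"] == pop).to_numpy()
            if F == 0:
                p = anc
            else:
                p = rng.dirichlet(anc * (1 - F) / F)
            geno[mask, l, :] = rng.choice(
                cfg.alleles_per_locus, size=(mask.sum(), 2), p=p
            )
    return GenotypeTable(
        sample_ids=tuple(meta.index),
        species=meta["species"].to_numpy(),
        population=meta["population"].to_numpy(),
        loci=tuple(f"L{l+1}" for l in range(cfg.n_loci)),
        alleles=geno,
    )


# ------------------------------------------------------------- spectra

def _baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth dried-leaf-like reflectance baseline: lower in the VIS, a
    red-edge rise into the NIR, gently declining through the SWIR."""
    w = wavelengths
    red_edge = 0.35 / (1.0 + np.exp(-(w - 720.0) / 30.0))
    return 0.25 + red_edge - 0.08 * (w - 400.0) / 2100.0


def gen_spectra(
    traits: pd.DataFrame,
    cfg: SimConfig,
    wavelengths: np.ndarray | None = None,
) -> SpectraSet:
    """Reflectance spectra driven by trait values.

    reflectance(lambda) = baseline(lambda)
        - sum_features loading * trait * Gaussian(lambda; center, width)
        + Normal(0, noise_sd), clipped to (0.001, 0.999).
    """
    for trait, *_ in cfg.band_library:
        if trait not in traits.columns:
            raise KeyError(f"band library references missing trait {trait!r}")
    rng = cfg.substream("spectra")
    if wavelengths is None:
        wavelengths = np.arange(400.0, 2500.0 + 1e-9, 3.0)
    base = _baseline(wavelengths)
    n = traits.shape[0]
    refl = np.tile(base, (n, 1))
    for trait, center, width, loading in cfg.band_library:
        shape = np.exp(-0.5 * ((wavelengths - center) / width) ** 2)
        refl -= loading * traits[trait].to_numpy(float)[:, None] * shape[None, :]
    if cfg.noise_sd > 0:
        refl += rng.normal(0.0, cfg.noise_sd, size=refl.shape)
    refl = np.clip(refl, 0.001, 0.999)
    return SpectraSet(wavelengths, refl, state="raw",
                      sample_ids=tuple(traits.index.astype(str)))


# ------------------------------------------------------------- env & geo

def _residualize(v: np.ndarray, block: np.ndarray) -> np.ndarray:
    """Residual of v on [1, block] (exact orthogonality of sim components)."""
    X = np.column_stack([np.ones(len(v)), block])
    beta, *_ = np.linalg.lstsq(X, v, rcond=None)
    return v - X @ beta

def gen_env_geo(
    cfg: SimConfig,
    groups: pd.Series | np.ndarray,
    variables: tuple = ("bio6", "bio12", "twi"),
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Environment table, coordinates, and the true IBE/IBD variance shares.

    Coordinates cluster by group along a latitudinal axis; each environmental
    variable is sqrt(ibe) * standardized group effect + sqrt(ibd) *
    standardized latitude + sqrt(residual) * noise, so its population
    variance decomposes into the recorded shares.
    """
    groups = pd.Series(groups)
    if groups.empty:
        raise ValueError("groups must be non-empty")
    rng = cfg.substream("env_geo")
    levels = groups.unique()
    # population centers spread over a broad latitudinal range, individuals
    # scattered around them widely enough that the gradient retains
    # within-population variation (keeps spatial and group signals separable)
    centers_lat = rng.normal(0.0, 5.0, size=len(levels))
    centers_lon = rng.normal(0.0, 5.0, size=len(levels))
    lut = {g: (centers_lat[i], centers_lon[i]) for i, g in enumerate(levels)}
    lat = np.array([lut[g][0] for g in groups]) + rng.normal(0, 3.0, len(groups))
    lon = np.array([lut[g][1] for g in groups]) + rng.normal(0, 3.0, len(groups))
    geo = pd.DataFrame({"latitude": lat, "longitude": lon},
                       index=groups.index.astype(str))

    def z(v):
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else v * 0.0

    spatial = z(lat)  # smooth gradient: standardized latitude
    resid = max(0.0, 1.0 - cfg.ibe_fraction - cfg.ibd_fraction)
    env = {}
    group_components = {}
    for var in variables:
        # group-level effects, orthogonalized against the population centers:
        # IBE is by definition the environment-linked divergence *independent
        # of* geographic position (stays constant within each group)
        eff = rng.standard_normal(len(levels))
        if len(levels) > 3:
            eff = _residualize(eff, np.column_stack([centers_lat, centers_lon]))
        effects = dict(zip(levels, eff))
        group_eff = z(np.array([effects[g] for g in groups]))
        group_components[var] = group_eff
        noise = z(rng.standard_normal(len(groups)))
        env[var] = (np.sqrt(cfg.ibe_fraction) * group_eff
                    + np.sqrt(cfg.ibd_fraction) * spatial
                    + np.sqrt(resid) * noise)
    env = pd.DataFrame(env, index=groups.index.astype(str))
    truth = {
        "ibe_fraction": cfg.ibe_fraction,
        "ibd_fraction": cfg.ibd_fraction,
        # noiseless latent drivers, for downstream recovery scoring
        "group_components": pd.DataFrame(group_components,
                                         index=groups.index.astype(str)),
        "spatial_component": pd.Series(spatial, index=groups.index.astype(str)),
    }
    return env, geo, truth


def gen_ibe_ibd_response(cfg: SimConfig, truth: dict, n_traits: int = 1,
                         seed: int | None = None) -> pd.DataFrame:
    """Phenotype matrix whose variance decomposes into the recorded shares.

    Each column = sqrt(ibe) * group driver + sqrt(ibd) * spatial gradient +
    sqrt(residual) * independent noise, all components standardized, so
    partitioning it on the (noiseless) drivers recovers ``ibe_fraction`` and
    ``ibd_fraction``.
    """
    rng = np.random.default_rng(
        np.random.SeedSequence(cfg.seed if seed is None else seed,
                               spawn_key=(_SUBSTREAMS["response"],)))
    gc = truth["group_components"]
    sc = truth["spatial_component"].to_numpy()
    resid = max(0.0, 1.0 - cfg.ibe_fraction - cfg.ibd_fraction)
    n = len(sc)
    out = {}
    for t in range(n_traits):
        driver = gc.iloc[:, t % gc.shape[1]].to_numpy()
        noise = _residualize(rng.standard_normal(n),
                             np.column_stack([driver, sc]))
        noise /= noise.std()
        out[f"pheno{t + 1}"] = (np.sqrt(cfg.ibe_fraction) * driver
                                + np.sqrt(cfg.ibd_fraction) * sc
                                + np.sqrt(resid) * noise)
    return pd.DataFrame(out, index=gc.index)


# ------------------------------------------------------------- full bundle

def simulate_dataset(cfg: SimConfig) -> dict:
    """Generate every input kind plus a ground-truth record.

    Returns a dict with keys: ``metadata`` (species/population per sample),
    ``tree`` (tips = populations), ``traits`` (per-sample, BM species means
    + within-group noise), ``spectra``, ``genotypes``, ``env``, ``geo``,
    ``truth`` (JSON-serializable ground-truth record).
    """
    meta = group_labels(cfg)
    pops = list(meta["population"].unique())
    tree = gen_phylogeny(max(len(pops), 3), seed=cfg.seed)
    tips = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
    tip_of_pop = dict(zip(pops, tips))

    rng = cfg.substream("labels")
    traits = {}
    group_means = {}
    for idx, (trait, (mean, sd)) in enumerate(cfg.trait_archetypes.items()):
        bm = gen_bm_traits(tree, sigma2=cfg.bm_sigma2, root_value=0.0,
                           seed=(cfg.seed * 131 + idx) % 2**31,
                           trait_name=trait)[trait]
        bm = (bm - bm.mean()) / (bm.std() if bm.std() > 0 else 1.0)
        pop_mean = {p: mean + bm[tip_of_pop[p]] * sd * 2.0 for p in pops}
        group_means[trait] = pop_mean
        vals = np.array([pop_mean[p] for p in meta["population"]])
        traits[trait] = vals + rng.normal(0, sd, len(meta))
    traits = pd.DataFrame(traits, index=meta.index)

    genotypes = gen_genotypes(cfg)
    spectra = gen_spectra(traits, cfg)
    env, geo, env_truth = gen_env_geo(cfg, meta["population"])
    truth = {
        "fst_target": cfg.fst_target,
        "bm_sigma2": cfg.bm_sigma2,
        "ibe_fraction": cfg.ibe_fraction,
        "ibd_fraction": cfg.ibd_fraction,
        "group_trait_means": {t: {p: float(v) for p, v in m.items()}
                              for t, m in group_means.items()},
        "tip_of_population": tip_of_pop,
    }
    return {"metadata": meta, "tree": tree, "traits": traits,
            "spectra": spectra, "genotypes": genotypes,
            "env": env, "geo": geo, "env_truth": env_truth, "truth": truth}


def write_dataset(data: dict, outdir) -> None:
    """Write a simulated bundle as plain-text files (CSV/newick/JSON)."""
    from pathlib import Path
    from .spectra import write_spectra
    from .popgen import write_genotypes

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    data["metadata"].to_csv(out / "metadata.csv")
    data["traits"].to_csv(out / "traits.csv")
    data["env"].to_csv(out / "environment.csv")
    data["geo"].to_csv(out / "coordinates.csv")
    write_spectra(data["spectra"], out / "spectra.csv")
    write_genotypes(data["genotypes"], out / "genotypes.csv")
    data["tree"].write(path=str(out / "tree.nwk"), schema="newick")
    (out / "truth.json").write_text(json.dumps(data["truth"], indent=2))
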