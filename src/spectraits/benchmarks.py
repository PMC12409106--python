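"""Desk-scale validation suite: parameter-recovery and calibration runs.

Every function simulates data with known ground truth through
:mod:`spectraits.simulate`, pushes it through the corresponding estimator,
and returns the measured quantities as plain floats.  The same routines
back the acceptance tests and the ``scripts/acceptance.py`` report, so the
numbers asserted and the numbers reported are computed by one code path.

Problem sizes are chosen so the full suite runs in minutes on one core
(replicate counts noted per function); they are the package's validation
conditions, documented in docs/methods.md.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import phylo as ph
from .chemometrics import fit_plsda, fit_plsr, vip_scores
from .popgen import GenotypeTable, amova, fst_bootstrap_ci, wc_theta
from .pstfst import critical_ratio, pst_bootstrap
from .simulate import (SimConfig, gen_bm_traits, gen_env_geo, gen_genotypes,
                       gen_ibe_ibd_response, gen_phylogeny, gen_spectra)
from .spectra import SpectraSet, cwt_transform, resample, splice_correct
from .varpart import variance_partition, _perm_pvalue

__all__ = [
    "fst_recovery", "fst_ci_coverage", "amova_checks", "pst_checks",
    "plsr_vip_checks", "plsda_checks", "varpart_checks", "blomberg_checks",
    "pgls_checks", "cwt_checks",
]


def _bn_config(fst, seed, n_pops=4, n_inds=30, n_loci=20):
    return SimConfig(n_species=1, pops_per_species=n_pops,
                     inds_per_pop=n_inds, n_loci=n_loci, fst_target=fst,
                     seed=seed)


def fst_recovery(targets=(0.05, 0.15, 0.25), n_reps: int = 50,
                 seed: int = 0) -> dict:
    """Mean Weir-Cockerham theta over replicate Balding-Nichols datasets
    (4 pops x 30 diploids x 20 loci) per target."""
    out = {}
    for t in targets:
        thetas = []
        for rep in range(n_reps):
            g = gen_genotypes(_bn_config(t, seed * 100_003 + rep))
            thetas.append(wc_theta(g, g.population))
        out[t] = float(np.mean(thetas))
    return out


def fst_ci_coverage(fst: float = 0.15, n_reps: int = 500,
                    n_boot: int = 500, seed: int = 0) -> float:
    """Fraction of replicate datasets (4 pops x 30 diploids x 20 loci)
    whose 95% locus-bootstrap CI covers the simulated differentiation
    target."""
    covered = 0
    for rep in range(n_reps):
        g = gen_genotypes(_bn_config(fst, seed * 55_001 + rep))
        groups = tuple(pd.unique(g.population))
        r = fst_bootstrap_ci(g, groups, n_boot=n_boot, seed=rep)
        covered += r.ci_low <= fst <= r.ci_high
    return covered / n_reps


def amova_checks(n_reps: int = 8, seed: int = 0) -> dict:
    """Percentage closure on nested data and the among-species component
    after relabeling panmictic populations into fake species."""
    closure_err = 0.0
    for rep in range(n_reps):
        cfg = SimConfig(n_species=3, pops_per_species=2, inds_per_pop=10,
                        n_loci=8, fst_target=0.15, seed=seed * 7_013 + rep)
        res = amova(gen_genotypes(cfg))
        closure_err = max(closure_err,
                          abs(sum(res.percentages.values()) - 100.0))
    among = []
    for rep in range(n_reps):
        g = gen_genotypes(_bn_config(0.0, seed * 9_109 + rep, n_pops=4,
                                     n_inds=15, n_loci=10))
        pops = g.population
        fake = np.where(np.isin(pops, pd.unique(pops)[:2]), "A", "B")
        g2 = GenotypeTable(g.sample_ids, fake, pops, g.loci, g.alleles)
        among.append(amova(g2).percentages["among_species"])
    return {"closure_max_abs_err": float(closure_err),
            "panmictic_among_species_pct": float(np.mean(among))}


def pst_checks(n_null: int = 100, n_power: int = 50, n_boot: int = 300,
               seed: int = 0) -> dict:
    """Monotonicity of the P_ST sweep, the neutral false-flag rate at
    c/h2 = 0.25, and the strong-divergence (d = 3) power to cross by 0.25
    against a low-F_ST (0.05) neutral background."""
    rng = np.random.default_rng(seed)
    curve = pst_bootstrap(rng.normal(1, 1, 40).astype(float),
                          np.repeat(["a", "b"], 20), n_boot=50,
                          seed=seed).pst_curve
    monotone = bool((np.diff(curve) >= -1e-12).all())

    flags = 0
    for rep in range(n_null):
        g = gen_genotypes(_bn_config(0.05, seed * 31_013 + rep, n_pops=2))
        pair = tuple(pd.unique(g.population))
        f = fst_bootstrap_ci(g, pair, n_boot=n_boot, seed=rep)
        r = np.random.default_rng(seed * 77 + rep)
        vals = r.normal(0.0, 1.0, 60)
        p = pst_bootstrap(vals, g.population, n_boot=n_boot, seed=rep,
                          pair=pair)
        critical_ratio(p, f)
        flags += p.decisions[0.25]

    power = 0
    for rep in range(n_power):
        g = gen_genotypes(_bn_config(0.05, seed * 41_011 + rep, n_pops=2))
        pair = tuple(pd.unique(g.population))
        f = fst_bootstrap_ci(g, pair, n_boot=n_boot, seed=rep)
        r = np.random.default_rng(seed * 99 + rep)
        vals = np.concatenate([r.normal(0, 1, 30), r.normal(3, 1, 30)])
        p = pst_bootstrap(vals, g.population, n_boot=n_boot, seed=rep,
                          pair=pair)
        crit = critical_ratio(p, f)
        power += crit is not None and crit <= 0.25
    return {"monotone": monotone,
            "null_flag_rate": flags / n_null,
            "power_rate": power / n_power}


def plsr_vip_checks(n_samples: int = 200, noise_sd: float = 0.005,
                    seed: int = 0) -> dict:
    """Trait recovery R2 and VIP-peak localization on synthetic spectra
    with the default six-trait absorption-feature library."""
    cfg = SimConfig(noise_sd=noise_sd, seed=seed)
    rng = np.random.default_rng(seed)
    traits = pd.DataFrame(
        {t: rng.normal(m, sd, n_samples)
         for t, (m, sd) in cfg.trait_archetypes.items()},
        index=[f"s{i}" for i in range(n_samples)])
    s = cwt_transform(resample(splice_correct(gen_spectra(traits, cfg))))
    centers = {t: c for t, c, _, _ in cfg.band_library}
    r2_min, offset_max, vip_norm_err = np.inf, 0.0, 0.0
    step = float(np.median(np.diff(s.wavelengths)))
    for trait in traits.columns:
        m = fit_plsr(s.values, traits[trait].to_numpy(), n_components=8,
                     target=trait)
        vip = vip_scores(m)
        r2_min = min(r2_min, m.metrics["r2"])
        peak = s.wavelengths[int(np.argmax(vip))]
        offset_max = max(offset_max, abs(peak - centers[trait]) / step)
        vip_norm_err = max(vip_norm_err,
                           abs((vip**2).sum() - s.n_bands))
    return {"r2_min": float(r2_min), "vip_peak_offset_bands": float(offset_max),
            "vip_norm_err": float(vip_norm_err)}


def plsda_checks(seed: int = 0) -> dict:
    """Classification of well-separated synthetic species from CWT spectra,
    and the same fit with permuted labels (chance control)."""
    cfg = SimConfig(n_species=4, pops_per_species=1, inds_per_pop=30,
                    noise_sd=0.003, seed=seed)
    rng = np.random.default_rng(seed)
    labels = np.repeat([f"sp{i}" for i in range(4)], 30)
    # well-separated species trait means (several within-group sd apart)
    traits = {}
    for t, (m, sd) in cfg.trait_archetypes.items():
        species_means = m + sd * 4.0 * rng.permutation(np.arange(4) - 1.5)
        mean_of = dict(zip([f"sp{i}" for i in range(4)], species_means))
        traits[t] = np.array([mean_of[l] for l in labels]) + \
            rng.normal(0, sd, labels.size)
    traits = pd.DataFrame(traits, index=[f"s{i}" for i in range(120)])
    s = cwt_transform(resample(splice_correct(gen_spectra(traits, cfg))))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        _, cm = fit_plsda(s.values, labels, n_components=6,
                          n_iterations=30, seed=seed)
        _, cm_perm = fit_plsda(s.values, rng.permutation(labels),
                               n_components=6, n_iterations=30,
                               seed=seed + 1)
    return {"accuracy": cm.accuracy, "kappa": cm.kappa,
            "permuted_accuracy": cm_perm.accuracy, "n_classes": 4}


def varpart_checks(n: int = 300, n_null: int = 200, seed: int = 0) -> dict:
    """IBE/IBD share recovery at the generator's recorded ground truth,
    fraction closure, and uniformity of the permutation P-value under a
    true null (KS statistic over ``n_null`` runs)."""
    from scipy import stats

    groups = pd.Series(np.repeat([f"g{i}" for i in range(30)], n // 30),
                       index=[f"s{i}" for i in range(n)])
    cfg = SimConfig(ibe_fraction=0.4, ibd_fraction=0.1, seed=seed)
    env, geo, truth = gen_env_geo(cfg, groups)
    Y = gen_ibe_ibd_response(cfg, truth)
    res = variance_partition(Y.to_numpy(),
                             truth["group_components"].iloc[:, [0]],
                             geo[["latitude", "longitude"]], n_perm=0)
    closure = abs(res.env_given_geo + res.geo_given_env + res.joint
                  - res.total_adj_r2)

    rng = np.random.default_rng(seed)
    pvals = np.empty(n_null)
    for i in range(n_null):
        Yn = rng.normal(size=60)
        E = rng.normal(size=(60, 1))
        G = rng.normal(size=(60, 1))
        pvals[i] = _perm_pvalue(Yn, E, G, n_perm=99,
                                rng=np.random.default_rng(seed * 17 + i))
    ks = stats.kstest(pvals, "uniform")
    return {"ibe_err": abs(res.env_given_geo - 0.4),
            "ibd_err": abs(res.geo_given_env - 0.1),
            "closure_err": float(closure),
            "null_p_ks_pvalue": float(ks.pvalue)}


def blomberg_checks(n_bm: int = 500, n_wn: int = 200, n_typei: int = 100,
                    n_profile: int = 20, seed: int = 0) -> dict:
    """K calibration under BM and white noise on a 50-tip tree, tip-swap
    test type-I rate, and VIS-vs-SWIR separation in the spectral-K profile
    when only VIS features carry BM signal."""
    tree = gen_phylogeny(50, seed=seed)
    Vdf = ph.phylo_vcv(tree)
    V = Vdf.to_numpy()
    machinery = ph._k_machinery(V)
    L = np.linalg.cholesky(V)
    rng = np.random.default_rng(seed)
    sims = L @ rng.standard_normal((50, n_bm))
    k_bm = [ph._k_from_x(sims[:, j], V, *machinery) for j in range(n_bm)]
    wn = rng.standard_normal((50, n_wn))
    k_wn = [ph._k_from_x(wn[:, j], V, *machinery) for j in range(n_wn)]

    tree30 = gen_phylogeny(30, seed=seed + 1)
    tips30 = [l.taxon.label for l in tree30.leaf_node_iter()]
    typei = 0
    for rep in range(n_typei):
        y = pd.Series(np.random.default_rng(seed * 3 + rep)
                      .standard_normal(30), index=tips30)
        r = ph.k_significance(tree30, y, n_perm=199, n_sim=2, seed=rep)
        typei += r.signal_present

    sep = 0
    for rep in range(n_profile):
        t = gen_phylogeny(15, seed=seed * 13 + rep)
        tips = [l.taxon.label for l in t.leaf_node_iter()]
        bm = gen_bm_traits(t, 1.0, 0.0, seed=seed * 29 + rep).iloc[:, 0]
        r2 = np.random.default_rng(seed * 37 + rep)
        vis = np.outer(bm.to_numpy(), np.linspace(1.0, 0.6, 5))
        swir = r2.standard_normal((15, 5))
        w = np.concatenate([np.linspace(450, 650, 5),
                            np.linspace(1400, 1900, 5)])
        s = SpectraSet(w, np.hstack([vis, swir]) * 0.01 + 0.5,
                       state="resampled", sample_ids=tuple(tips))
        prof = ph.spectral_k_profile(t, s, {x: x for x in tips},
                                     n_perm=19, n_sim=9, seed=rep)
        sep += (prof.loc[prof["region"] == "VIS", "k"].median()
                > prof.loc[prof["region"] == "SWIR", "k"].median())
    return {"bm_mean_k": float(np.mean(k_bm)),
            "wn_mean_k": float(np.mean(k_wn)),
            "tip_swap_type_i_rate": typei / n_typei,
            "profile_separation_rate": sep / n_profile}


def _star_tree(n, depth=1.0):
    import dendropy
    taxa = dendropy.TaxonNamespace([f"x{i}" for i in range(n)])
    tree = dendropy.Tree(taxon_namespace=taxa)
    for i in range(n):
        node = dendropy.Node()
        node.taxon = taxa[i]
        node.edge.length = depth
        tree.seed_node.add_child(node)
    return tree


def pgls_checks(n_sims: int = 200, beta: float = 1.5, seed: int = 0) -> dict:
    """Star-tree OLS identity and slope recovery (true slope ``beta``) under
    BM-distributed errors on a 50-tip tree."""
    rng = np.random.default_rng(seed)
    star = _star_tree(12)
    tips = [f"x{i}" for i in range(12)]
    x = pd.Series(rng.normal(size=12), index=tips)
    y = pd.Series(2.0 * x + rng.normal(0, 0.4, 12), index=tips)
    r = ph.pgls_fit(star, y, x)
    slope_ols, icpt_ols = np.polyfit(x.to_numpy(), y.to_numpy(), 1)
    star_diff = max(abs(r.slope - slope_ols), abs(r.intercept - icpt_ols))

    tree = gen_phylogeny(50, seed=seed + 1)
    slopes = []
    for s in range(n_sims):
        xs = gen_bm_traits(tree, 1.0, 0.0, seed=seed * 101 + 2 * s).iloc[:, 0]
        err = gen_bm_traits(tree, 0.25, 0.0,
                            seed=seed * 101 + 2 * s + 1).iloc[:, 0]
        ys = beta * xs + err
        slopes.append(ph.pgls_fit(tree, ys, xs).slope)
    return {"star_vs_ols_max_diff": float(star_diff),
            "slope_mean": float(np.mean(slopes)), "true_slope": beta}


def cwt_checks(seed: int = 0) -> dict:
    """Zero response to constants, linearity, and localization of a known
    absorption dip against an independent dense-convolution oracle."""
    from .spectra import _mexican_hat_kernel

    w = np.arange(400.0, 2500.0 + 1e-9, 3.0)
    const = SpectraSet(w, np.full((1, w.size), 0.5), state="resampled")
    const_max = float(np.abs(cwt_transform(const).values).max())

    rng = np.random.default_rng(seed)
    v1 = np.clip(0.5 + 0.05 * rng.standard_normal(w.size), 0, 1)
    v2 = np.clip(0.5 + 0.05 * rng.standard_normal(w.size), 0, 1)
    c1 = cwt_transform(SpectraSet(w, v1[None], state="resampled")).values
    c2 = cwt_transform(SpectraSet(w, v2[None], state="resampled")).values
    cmix = cwt_transform(SpectraSet(w, (0.3 * v1 + 0.7 * v2)[None],
                                    state="resampled")).values
    lin_err = float(np.abs(cmix - 0.3 * c1 - 0.7 * c2).max())

    dip = 0.5 - 0.2 * np.exp(-0.5 * ((w - 1450.0) / 20.0) ** 2)
    out = cwt_transform(SpectraSet(w, dip[None], state="resampled"))
    # independent oracle: explicit reflect padding + np.convolve
    total = np.zeros_like(dip)
    for a in (4.0, 16.0, 64.0):
        k = _mexican_hat_kernel(a)
        half = len(k) // 2
        padded = np.concatenate([dip[:half][::-1], dip, dip[-half:][::-1]])
        total += np.convolve(padded, k[::-1], mode="valid")
    keep = (w >= 400) & (w <= 2450)
    oracle_peak = w[keep][int(np.argmax(np.abs(total[keep])))]
    our_peak = out.wavelengths[int(np.argmax(np.abs(out.values[0])))]
    return {"constant_max_coef": const_max, "linearity_err": lin_err,
            "dip_offset_bands": float(abs(our_peak - oracle_peak) / 3.0)}
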