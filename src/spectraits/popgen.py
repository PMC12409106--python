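"""Neutral-marker statistics for diploid microsatellite data.

Implements the Weir & Cockerham (1984) multiallelic, multilocus theta
estimator of F_ST with locus-bootstrap confidence intervals, a hierarchical
AMOVA (infinite-alleles distance, i.e. nested ANOVA on allele indicator
variables with two gene copies per individual), Evanno's delta-K
post-processing of clustering log-likelihoods, and Q-matrix membership
thresholding.  Admixture/spatial MCMC clustering itself is out of scope:
those programs' outputs are consumed as inputs here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeTable",
    "FstResult",
    "AmovaResult",
    "pairwise_fst",
    "fst_bootstrap_ci",
    "amova",
    "evanno_delta_k",
    "assign_membership",
    "read_genotypes",
    "write_genotypes",
    "read_structure",
    "read_qmatrix",
]

MISSING = -1


@dataclass(frozen=True)
class GenotypeTable:
    """Diploid allele calls per sample x locus with species/population labels.

    ``alleles`` is an int array (n_samples, n_loci, 2); missing calls are
    coded ``-1`` (both copies of a locus missing together or not at all is
    not assumed — each copy is checked).
    """

    sample_ids: tuple
    species: np.ndarray
    population: np.ndarray
    loci: tuple
    alleles: np.ndarray

    def __post_init__(self):
        a = np.asarray(self.alleles)
        if a.ndim != 3 or a.shape[2] != 2:
            raise ValueError("alleles must have shape (n, n_loci, 2): ploidy 2")
        if a.shape[1] < 1:
            raise ValueError("need at least one locus")
        if len(self.sample_ids) != a.shape[0]:
            raise ValueError("sample_ids length mismatch")
        object.__setattr__(self, "alleles", a.astype(np.int64))
        object.__setattr__(self, "species", np.asarray(self.species))
        object.__setattr__(self, "population", np.asarray(self.population))

    @property
    def n_samples(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_loci(self) -> int:
        return self.alleles.shape[1]

    def labels(self, level: str) -> np.ndarray:
        if level == "species":
            return self.species
        if level == "population":
            return self.population
        raise ValueError("level must be 'species' or 'population'")

    def subset(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            sample_ids=tuple(np.asarray(self.sample_ids)[mask]),
            species=self.species[mask],
            population=self.population[mask],
            loci=self.loci,
            alleles=self.alleles[mask],
        )


@dataclass(frozen=True)
class FstResult:
    pair: tuple
    theta: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    n_loci: int = 0


# ------------------------------------------------ Weir-Cockerham theta

def _wc_locus_components(geno: np.ndarray, pops: np.ndarray):
    """Per-locus Weir-Cockerham variance components, summed over alleles.

    ``geno``: (n, 2) allele calls for one locus (missing = -1).
    Returns (a, a + b + c); complete-case within the locus.
    """
    ok = (geno >= 0).all(axis=1)
    geno, pops = geno[ok], pops[ok]
    groups = np.unique(pops)
    r = len(groups)
    if r < 2:
        return np.nan, np.nan
    n_i = np.array([(pops == g).sum() for g in groups], dtype=float)
    if (n_i < 1).any() or n_i.sum() < r + 1:
        return np.nan, np.nan
    nbar = n_i.mean()
    if nbar <= 1:
        return np.nan, np.nan
    nc = (r * nbar - (n_i**2).sum() / (r * nbar)) / (r - 1)
    if nc == 0:
        return np.nan, np.nan
    alleles = np.unique(geno)
    a_sum = 0.0
    abc_sum = 0.0
    for allele in alleles:
        p_i = np.array([
            (geno[pops == g] == allele).mean() for g in groups
        ])
        h_i = np.array([
            ((geno[pops == g] == allele).sum(axis=1) == 1).mean() for g in groups
        ])
        pbar = (n_i * p_i).sum() / (r * nbar)
        s2 = (n_i * (p_i - pbar) ** 2).sum() / ((r - 1) * nbar)
        hbar = (n_i * h_i).sum() / (r * nbar)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        a_sum += a
        abc_sum += a + b + c
    return a_sum, abc_sum


def wc_theta_components(g: GenotypeTable, labels: np.ndarray) -> pd.DataFrame:
    """Per-locus (a, a+b+c) components for the groups in ``labels``."""
    rows = []
    for l, locus in enumerate(g.loci):
        a, abc = _wc_locus_components(g.alleles[:, l, :], labels)
        rows.append({"locus": locus, "a": a, "abc": abc})
    return pd.DataFrame(rows).set_index("locus")


def wc_theta(g: GenotypeTable, labels: np.ndarray) -> float:
    """Multilocus Weir-Cockerham theta: ratio of summed components.

    Negative estimates are reported as computed (hierfstat convention).
    """
    comp = wc_theta_components(g, labels).dropna()
    if comp.empty or comp["abc"].sum() == 0:
        return np.nan
    return float(comp["a"].sum() / comp["abc"].sum())


def pairwise_fst(g: GenotypeTable, level: str = "population") -> list[FstResult]:
    """Pairwise multilocus theta for every pair of groups at ``level``."""
    labels = g.labels(level)
    groups = list(pd.unique(labels))
    if len(groups) < 2:
        raise ValueError(f"need >= 2 groups at level {level!r}")
    results = []
    for g1, g2 in combinations(groups, 2):
        mask = (labels == g1) | (labels == g2)
        sub = g.subset(mask)
        sub_labels = sub.labels(level)
        for grp in (g1, g2):
            gm = sub_labels == grp
            ok_per_locus = (sub.alleles[gm] >= 0).all(axis=2).sum(axis=0)
            if (ok_per_locus < 2).all():
                raise ValueError(
                    f"group {grp!r} has < 2 genotyped individuals at every locus"
                )
        comp = wc_theta_components(sub, sub_labels).dropna()
        theta = (float(comp["a"].sum() / comp["abc"].sum())
                 if not comp.empty and comp["abc"].sum() != 0 else np.nan)
        results.append(FstResult(pair=(g1, g2), theta=theta, n_loci=len(comp)))
    return results


def fst_bootstrap_ci(
    g: GenotypeTable,
    pair: tuple,
    level: str = "population",
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> FstResult:
    """Percentile CI for pairwise theta, resampling loci with replacement."""
    labels = g.labels(level)
    mask = np.isin(labels, list(pair))
    sub = g.subset(mask)
    comp = wc_theta_components(sub, sub.labels(level)).dropna()
    if len(comp) < 2:
        raise ValueError("bootstrap over loci needs >= 2 informative loci")
    a = comp["a"].to_numpy()
    abc = comp["abc"].to_numpy()
    theta = float(a.sum() / abc.sum())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(a), size=(n_boot, len(a)))
    num = a[idx].sum(axis=1)
    den = abc[idx].sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        boots = num / den
    boots = boots[np.isfinite(boots)]
    lo, hi = np.percentile(boots, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return FstResult(pair=tuple(pair), theta=theta, ci_low=float(lo),
                     ci_high=float(hi), n_loci=len(comp))


# ------------------------------------------------------------- AMOVA

@dataclass(frozen=True)
class AmovaResult:
    """Variance components and percentages for the four nested levels."""

    components: dict        # level -> variance component
    percentages: dict       # level -> % of total
    df: dict
    mean_squares: dict
    p_values: dict = field(default_factory=dict)

    LEVELS = ("among_species", "among_populations", "among_individuals",
              "within_individuals")


def _indicator_ss(counts: np.ndarray, m: float) -> float:
    """Sum over allele-indicator columns of the within-group SS for a group
    of ``m`` gene copies with allele counts ``counts``: m - sum(c^2)/m."""
    if m == 0:
        return 0.0
    return float(m - (counts**2).sum() / m)


def _amova_ss(g: GenotypeTable):
    """Nested sums of squares on allele indicators, per locus then summed.

    Units are gene copies (2 per individual); complete-case per locus.
    """
    species, pops = g.species, g.population
    ss = dict.fromkeys(AmovaResult.LEVELS, 0.0)
    sizes = {"n_species": len(np.unique(species)),
             "n_pops": len(np.unique(pops))}
    n_ind_used = 0
    pops_per_species = {s: len(np.unique(pops[species == s]))
                        for s in np.unique(species)}
    for l in range(g.n_loci):
        geno = g.alleles[:, l, :]
        ok = (geno >= 0).all(axis=1)
        geno, sp, po = geno[ok], species[ok], pops[ok]
        if ok.sum() < 2:
            continue
        n_alleles = geno.max() + 1
        flat = geno.reshape(-1)

        def counts(mask2):
            return np.bincount(flat[np.repeat(mask2, 2)], minlength=n_alleles)

        total_counts = np.bincount(flat, minlength=n_alleles)
        ss_tot = _indicator_ss(total_counts, flat.size)
        ss_within_sp = sum(
            _indicator_ss(counts(sp == s), 2.0 * (sp == s).sum())
            for s in np.unique(sp))
        ss_within_po = sum(
            _indicator_ss(counts(po == p), 2.0 * (po == p).sum())
            for p in np.unique(po))
        # within individuals: per individual of 2 copies
        same = geno[:, 0] == geno[:, 1]
        ss_within_ind = float((~same).sum()) * 1.0  # het: SS = 2 - (1+1)... = 1
        ss["among_species"] += ss_tot - ss_within_sp
        ss["among_populations"] += ss_within_sp - ss_within_po
        ss["among_individuals"] += ss_within_po - ss_within_ind
        ss["within_individuals"] += ss_within_ind
        n_ind_used += ok.sum()
    sizes["n_ind"] = n_ind_used / max(g.n_loci, 1)
    return ss, sizes, pops_per_species


def _nested_coefficients(species, pops):
    """Unbalanced nested-ANOVA expected-mean-square coefficients for the
    design species > populations > individuals > gene copies (2/individual).
    Returns (df dict, coefficient matrix rows for the 3 upper levels)."""
    sp_levels = np.unique(species)
    po_levels = np.unique(pops)
    n_i_pop = {p: (pops == p).sum() for p in po_levels}           # individuals
    M_pop = {p: 2.0 * n for p, n in n_i_pop.items()}              # copies
    M_sp = {s: 2.0 * (species == s).sum() for s in sp_levels}
    N = 2.0 * len(species)
    df = {
        "among_species": len(sp_levels) - 1,
        "among_populations": sum(
            len(np.unique(pops[species == s])) - 1 for s in sp_levels),
        "among_individuals": sum(n - 1 for n in n_i_pop.values()),
        "within_individuals": len(species),   # one df per individual
    }
    sum_m2_pop = {p: 4.0 * n for p, n in n_i_pop.items()}  # sum of (2)^2 per ind
    sum_m2_sp = {s: sum(sum_m2_pop[p] for p in np.unique(pops[species == s]))
                 for s in sp_levels}
    sum_m2_all = sum(sum_m2_pop.values())
    # E[MS_ind] = se2 + k_i * s_ind2
    k_i = (sum(M_pop[p] - sum_m2_pop[p] / M_pop[p] for p in po_levels)
           / df["among_individuals"])
    # E[MS_pop] = se2 + kp_i * s_ind2 + kp_p * s_pop2
    kp_i = (sum(
        sum(sum_m2_pop[p] / M_pop[p] for p in np.unique(pops[species == s]))
        - sum_m2_sp[s] / M_sp[s] for s in sp_levels)
        / df["among_populations"])
    kp_p = (sum(
        M_sp[s] - sum(M_pop[p] ** 2 for p in np.unique(pops[species == s]))
        / M_sp[s] for s in sp_levels)
        / df["among_populations"])
    # E[MS_sp] = se2 + ks_i * s_ind2 + ks_p * s_pop2 + ks_s * s_sp2
    ks_i = (sum(sum_m2_sp[s] / M_sp[s] for s in sp_levels) - sum_m2_all / N) \
        / df["among_species"]
    ks_p = (sum(sum(M_pop[p] ** 2 for p in np.unique(pops[species == s]))
                / M_sp[s] for s in sp_levels)
            - sum(M_pop[p] ** 2 for p in po_levels) / N) / df["among_species"]
    ks_s = (N - sum(M_sp[s] ** 2 for s in sp_levels) / N) / df["among_species"]
    coeff = {"among_individuals": (k_i,),
             "among_populations": (kp_i, kp_p),
             "among_species": (ks_i, ks_p, ks_s)}
    return df, coeff


def _amova_components(g: GenotypeTable):
    ss, _, pops_per_species = _amova_ss(g)
    df, coeff = _nested_coefficients(g.species, g.population)
    if any(v == 1 for v in pops_per_species.values()):
        warnings.warn(
            "some species have a single population; the among-populations "
            "component has reduced degrees of freedom there"
        )
    ms = {}
    for lvl in AmovaResult.LEVELS:
        ms[lvl] = ss[lvl] / df[lvl] if df[lvl] > 0 else np.nan
    s_e = ms["within_individuals"]
    (k_i,) = coeff["among_individuals"]
    s_ind = (ms["among_individuals"] - s_e) / k_i
    kp_i, kp_p = coeff["among_populations"]
    s_pop = (ms["among_populations"] - s_e - kp_i * s_ind) / kp_p \
        if df["among_populations"] > 0 else 0.0
    ks_i, ks_p, ks_s = coeff["among_species"]
    s_sp = (ms["among_species"] - s_e - ks_i * s_ind - ks_p * s_pop) / ks_s
    comp = {"among_species": s_sp, "among_populations": s_pop,
            "among_individuals": s_ind, "within_individuals": s_e}
    return comp, df, ms


def amova(g: GenotypeTable, n_perm: int = 0, seed: int = 0) -> AmovaResult:
    """Hierarchical AMOVA: species / populations-within-species /
    individuals-within-populations / within-individuals.

    Infinite-alleles distance: nested ANOVA on allele indicator variables
    with gene copies as units.  Variance components by method of moments
    with unbalanced-design coefficients.  ``n_perm > 0`` adds permutation
    P-values (units permuted at the level being tested).
    """
    if len(np.unique(g.species)) < 2:
        raise ValueError("need >= 2 species for the hierarchical design")
    comp, df, ms = _amova_components(g)
    total = sum(comp.values())
    pct = {k: 100.0 * v / total for k, v in comp.items()}

    p_values = {}
    if n_perm > 0:
        rng = np.random.default_rng(seed)
        obs = comp
        counts = dict.fromkeys(("among_species", "among_populations",
                                "among_individuals"), 0)
        pops = g.population
        species = g.species
        pop_of = pd.Series(species, index=pops).groupby(level=0).first()
        for _ in range(n_perm):
            # among species: permute whole populations across species
            perm_sp_of_pop = pd.Series(
                rng.permutation(pop_of.to_numpy()), index=pop_of.index)
            g_sp = GenotypeTable(
                g.sample_ids, perm_sp_of_pop[pops].to_numpy(), pops,
                g.loci, g.alleles)
            c1, _, _ = _amova_components(g_sp)
            counts["among_species"] += c1["among_species"] >= obs["among_species"]
            # among populations within species: permute individuals among
            # populations within each species
            new_pops = pops.copy()
            for s in np.unique(species):
                m = species == s
                new_pops[m] = rng.permutation(pops[m])
            g_po = GenotypeTable(g.sample_ids, species, new_pops,
                                 g.loci, g.alleles)
            c2, _, _ = _amova_components(g_po)
            counts["among_populations"] += (
                c2["among_populations"] >= obs["among_populations"])
            # among individuals: shuffle gene copies among individuals
            # within populations (per locus)
            alle = g.alleles.copy()
            for p in np.unique(pops):
                m = np.flatnonzero(pops == p)
                for l in range(g.n_loci):
                    flat = alle[m, l, :].reshape(-1)
                    alle[m, l, :] = rng.permutation(flat).reshape(-1, 2)
            c3, _, _ = _amova_components(
                GenotypeTable(g.sample_ids, species, pops, g.loci, alle))
            counts["among_individuals"] += (
                c3["among_individuals"] >= obs["among_individuals"])
        p_values = {k: (1 + v) / (n_perm + 1) for k, v in counts.items()}

    return AmovaResult(components=comp, percentages=pct, df=df,
                       mean_squares=ms, p_values=p_values)


# ------------------------------------------------ clustering post-processing

def evanno_delta_k(loglik_table: pd.DataFrame) -> tuple[int, pd.DataFrame]:
    """Evanno's delta-K from replicate clustering log-probabilities.

    ``loglik_table``: rows = replicates, columns = K (consecutive ints).
    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K));
    returns (K*, curve).  K values with zero replicate sd are excluded
    (with a warning).
    """
    ks = sorted(int(k) for k in loglik_table.columns)
    if len(ks) < 3 or any(b - a != 1 for a, b in zip(ks, ks[1:])):
        raise ValueError("need >= 3 consecutive K values")
    if (loglik_table.count() < 2).any():
        raise ValueError("need >= 2 replicates per K for the sd")
    mean = loglik_table.mean()
    sd = loglik_table.std(ddof=1)
    rows = []
    for k in ks[1:-1]:
        if sd[k] == 0:
            warnings.warn(f"sd of L(K={k}) is zero; delta-K undefined there")
            continue
        dk = abs(mean[k + 1] - 2 * mean[k] + mean[k - 1]) / sd[k]
        rows.append({"K": k, "delta_k": float(dk), "mean_l": float(mean[k]),
                     "sd_l": float(sd[k])})
    curve = pd.DataFrame(rows).set_index("K")
    if curve.empty:
        raise ValueError("delta-K undefined at every interior K")
    return int(curve["delta_k"].idxmax()), curve


def assign_membership(q_matrix: pd.DataFrame, threshold: float = 0.6) -> pd.DataFrame:
    """Majority-membership labels from a sample x cluster Q matrix.

    A sample is assigned to its max-fraction cluster when that fraction is
    >= ``threshold`` (0.6 for admixture-style output; 0.7 for spatial
    clustering output), otherwise flagged admixed.
    """
    q = q_matrix.to_numpy(float)
    if not np.allclose(q.sum(axis=1), 1.0, atol=1e-6):
        bad = q_matrix.index[~np.isclose(q.sum(axis=1), 1.0, atol=1e-6)]
        raise ValueError(f"Q rows must sum to 1; offending samples: {list(bad)[:5]}")
    best = q.argmax(axis=1)
    frac = q[np.arange(len(q)), best]
    admixed = frac < threshold
    return pd.DataFrame({
        "cluster": [q_matrix.columns[b] for b in best],
        "max_fraction": frac,
        "admixed": admixed,
    }, index=q_matrix.index)


# ---------------------------------------------------------------- file I/O

def write_genotypes(g: GenotypeTable, path, sep: str = ",",
                    missing_code: str = "NA") -> None:
    """Delimited genotypes: sample_id, species, population, two columns per
    locus (``<locus>_1``, ``<locus>_2``)."""
    data = {"species": g.species, "population": g.population}
    for l, locus in enumerate(g.loci):
        for copy in (0, 1):
            col = g.alleles[:, l, copy].astype(object)
            col[g.alleles[:, l, copy] == MISSING] = missing_code
            data[f"{locus}_{copy + 1}"] = col
    pd.DataFrame(data, index=list(g.sample_ids)).to_csv(
        path, sep=sep, index_label="sample_id")


def read_genotypes(path, sep: str = ",", missing_code: str = "NA") -> GenotypeTable:
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str)
    loci = []
    for c in df.columns:
        if c.endswith("_1") and c not in ("species_1",):
            loci.append(c[:-2])
    n, L = len(df), len(loci)
    alleles = np.full((n, L, 2), MISSING, dtype=np.int64)
    for l, locus in enumerate(loci):
        for copy in (0, 1):
            col = df[f"{locus}_{copy + 1}"]
            ok = col.notna() & (col != missing_code)
            alleles[ok.to_numpy(), l, copy] = col[ok].astype(int).to_numpy()
    return GenotypeTable(
        sample_ids=tuple(df.index.astype(str)),
        species=df["species"].to_numpy(),
        population=df["population"].to_numpy(),
        loci=tuple(loci),
        alleles=alleles,
    )


def read_structure(path, n_loci: int, missing_code: str = "-9",
                   sep=None) -> GenotypeTable:
    """Two-row-per-individual clustering-program input format: columns are
    sample id, population label, then one allele per locus per row."""
    raw = pd.read_csv(path, sep=sep or r"\s+", header=None, dtype=str,
                      engine="python")
    if len(raw) % 2:
        raise ValueError("two-row format requires an even number of rows")
    ids, pops, allele_rows = [], [], []
    for i in range(0, len(raw), 2):
        r1, r2 = raw.iloc[i], raw.iloc[i + 1]
        if r1.iloc[0] != r2.iloc[0]:
            raise ValueError(f"row pair mismatch at line {i}: {r1.iloc[0]}")
        ids.append(r1.iloc[0])
        pops.append(r1.iloc[1])
        allele_rows.append((r1.iloc[2:2 + n_loci], r2.iloc[2:2 + n_loci]))
    n = len(ids)
    alleles = np.full((n, n_loci, 2), MISSING, dtype=np.int64)
    for i, (a1, a2) in enumerate(allele_rows):
        for copy, row in enumerate((a1, a2)):
            vals = row.to_numpy()
            ok = vals != missing_code
            alleles[i, ok, copy] = vals[ok].astype(int)
    pops = np.asarray(pops)
    return GenotypeTable(tuple(ids), pops, pops,
                         tuple(f"L{l+1}" for l in range(n_loci)), alleles)


def read_qmatrix(path, sep: str = ",") -> pd.DataFrame:
    """Sample x cluster membership fractions (CLUMPP-style table)."""
    df = pd.read_csv(path, sep=sep, index_col=0)
    return df.astype(float)
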