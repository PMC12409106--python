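"""Phylogenetic signal and comparative regression on population means.

Blomberg's K quantifies whether trait variance lies within rather than among
clades relative to the Brownian-motion (BM) expectation: K ~ 1 under BM,
K -> 0 for phylogenetically random traits.  Significance comes from two
nulls: tip-swap permutations (white noise) and BM simulations rescaled to
the observed tip variance.  PGLS regresses a tip trait on a tip-level
environmental predictor with BM error covariance (shared branch lengths).
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "phylo_vcv",
    "read_tree",
    "write_tree",
    "population_means",
    "blomberg_k",
    "k_significance",
    "spectral_k_profile",
    "pgls_fit",
    "pearson_trait_env",
    "PhyloSignalResult",
    "PglsResult",
]


def read_tree(path_or_string, schema: str = "newick") -> dendropy.Tree:
    """Read a rooted, branch-length tree from a file path or newick string."""
    if isinstance(path_or_string, str) and path_or_string.strip().startswith("("):
        return dendropy.Tree.get(data=path_or_string, schema=schema)
    return dendropy.Tree.get(path=str(path_or_string), schema=schema)


def write_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick")


def tip_labels(tree: dendropy.Tree) -> list[str]:
    return [leaf.taxon.label for leaf in tree.leaf_node_iter()]


def phylo_vcv(tree: dendropy.Tree) -> pd.DataFrame:
    """BM covariance matrix: entry (i, j) is the root-to-MRCA path length.

    Computed in one postorder pass: every internal node contributes its depth
    as the covariance of tip pairs split between its child subtrees; the
    diagonal is each tip's root-to-tip depth.
    """
    tree = tree.clone(depth=1)
    labels = []
    depth = {}
    for node in tree.preorder_node_iter():
        parent_d = depth[node.parent_node] if node.parent_node else 0.0
        depth[node] = parent_d + (node.edge.length or 0.0)
        if node.is_leaf():
            labels.append(node.taxon.label)
    n = len(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    V = np.zeros((n, n))
    tips_below = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            i = idx[node.taxon.label]
            V[i, i] = depth[node]
            tips_below[node] = [i]
        else:
            kids = [tips_below[c] for c in node.child_nodes()]
            for a in range(len(kids)):
                for b in range(a + 1, len(kids)):
                    for i in kids[a]:
                        for j in kids[b]:
                            V[i, j] = V[j, i] = depth[node]
            tips_below[node] = [i for k in kids for i in k]
    return pd.DataFrame(V, index=labels, columns=labels)


def population_means(traits: pd.DataFrame, mapping: dict) -> pd.DataFrame:
    """Mean trait value per tip from per-sample traits.

    Parameters
    ----------
    traits : samples x traits frame, indexed by sample id.
    mapping : sample id -> tip label.  Every tip named in the mapping must
        receive at least one sample present in ``traits``.

    Returns a tips x (traits + ``n``/SE columns) frame: per-trait means plus
    per-tip sample count ``n`` and per-trait standard errors (``se_<trait>``).
    """
    missing = [s for s in traits.index if s not in mapping]
    if missing:
        raise KeyError(f"samples with no tip mapping: {missing[:5]}")
    tips = pd.Series({s: mapping[s] for s in traits.index}, name="tip")
    wanted = set(mapping.values())
    got = set(tips.unique())
    orphan_tips = wanted - got
    if orphan_tips:
        raise KeyError(f"tips with no samples: {sorted(orphan_tips)[:5]}")
    g = traits.groupby(tips)
    means = g.mean()
    n = g.size()
    se = g.std(ddof=1).div(np.sqrt(n), axis=0)
    se.columns = [f"se_{c}" for c in se.columns]
    out = pd.concat([means, se], axis=1)
    out["n"] = n
    return out


# ------------------------------------------------------------- Blomberg's K

def _k_machinery(V: np.ndarray):
    """Precompute the pieces of K that depend only on the tree."""
    n = V.shape[0]
    Vinv = np.linalg.inv(V)
    one = np.ones(n)
    s_inv = float(one @ Vinv @ one)
    expected = (np.trace(V) - n / s_inv) / (n - 1)
    return Vinv, s_inv, expected


def _k_from_x(x: np.ndarray, V: np.ndarray, Vinv, s_inv, expected) -> float:
    n = x.size
    ahat = float(np.ones(n) @ Vinv @ x) / s_inv
    d = x - ahat
    mse0 = float(d @ d) / (n - 1)
    mse = float(d @ Vinv @ d) / (n - 1)
    return (mse0 / mse) / expected


def blomberg_k(tree: dendropy.Tree, x: pd.Series | dict) -> float:
    """Blomberg's K for one tip-indexed trait.

    K = (MSE0 / MSE) / E_BM[MSE0 / MSE], where MSE0 is the mean squared
    deviation from the phylogenetically weighted mean and MSE the
    generalized (BM-covariance-weighted) mean squared error.  Invariant to
    affine transforms of the trait.
    """
    Vdf = phylo_vcv(tree)
    x = pd.Series(x).reindex(Vdf.index)
    if x.isna().any():
        raise KeyError("trait values missing for some tips")
    xv = x.to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValueError("trait is constant across tips; K undefined")
    V = Vdf.to_numpy()
    return _k_from_x(xv, V, *_k_machinery(V))


@dataclass(frozen=True)
class PhyloSignalResult:
    trait: str
    k: float
    p_wn: float
    bm_low: float
    bm_high: float
    n_perm: int
    n_sim: int
    signal_present: bool
    less_than_bm: bool


def k_significance(
    tree: dendropy.Tree,
    x: pd.Series | dict,
    n_perm: int = 999,
    n_sim: int = 1000,
    seed: int = 0,
    trait_name: str = "trait",
    alpha: float = 0.05,
) -> PhyloSignalResult:
    """K with a tip-swap (white noise) P-value and a BM simulation envelope.

    P_WN = (1 + #{K_perm >= K_obs}) / (n_perm + 1).  BM null traits are
    simulated on the tree and rescaled to the observed tip variance, so the
    envelope (2.5-97.5 percentiles) is scale-free.
    """
    rng = np.random.default_rng(seed)
    Vdf = phylo_vcv(tree)
    x = pd.Series(x).reindex(Vdf.index)
    xv = x.to_numpy(float)
    if np.ptp(xv) == 0:
        raise ValueError("trait is constant across tips; K undefined")
    V = Vdf.to_numpy()
    machinery = _k_machinery(V)
    k_obs = _k_from_x(xv, V, *machinery)

    k_perm = np.empty(n_perm)
    for i in range(n_perm):
        k_perm[i] = _k_from_x(rng.permutation(xv), V, *machinery)
    p_wn = (1 + np.sum(k_perm >= k_obs)) / (n_perm + 1)

    L = np.linalg.cholesky(V)
    sims = L @ rng.standard_normal((V.shape[0], n_sim))
    sims *= np.std(xv, ddof=1) / np.std(sims, axis=0, ddof=1)
    k_bm = np.array([_k_from_x(sims[:, j], V, *machinery) for j in range(n_sim)])
    lo, hi = np.percentile(k_bm, [2.5, 97.5])

    return PhyloSignalResult(
        trait=trait_name, k=k_obs, p_wn=float(p_wn), bm_low=float(lo),
        bm_high=float(hi), n_perm=n_perm, n_sim=n_sim,
        signal_present=bool(p_wn <= alpha), less_than_bm=bool(k_obs < lo),
    )


def spectral_k_profile(
    tree: dendropy.Tree,
    spectra,
    mapping: dict,
    n_perm: int = 199,
    n_sim: int = 199,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-band phylogenetic signal across a spectrum.

    Population-mean each band onto the tips, then run ``k_significance``
    band by band.  Constant bands are skipped (flagged in the output).
    Returns a wavelength-indexed table with K, P_WN, the BM envelope and
    the spectral region (VIS/NIR/SWIR).
    """
    from .spectra import region_of

    if spectra.state not in ("resampled", "cwt"):
        raise ValueError("spectral_k_profile needs resampled or cwt spectra")
    df = spectra.to_frame()
    tips = pd.Series({s: mapping[s] for s in df.index})
    means = df.groupby(tips).mean()
    Vdf = phylo_vcv(tree)
    means = means.reindex(Vdf.index)
    if means.isna().any().any():
        raise KeyError("some tips have no spectra")
    rows = []
    ss = np.random.SeedSequence(seed)
    for (w, band), child in zip(means.items(), ss.spawn(means.shape[1])):
        if np.ptp(band.to_numpy()) == 0:
            rows.append({"wavelength": w, "k": np.nan, "p_wn": np.nan,
                         "bm_low": np.nan, "bm_high": np.nan,
                         "constant": True, "signal_present": False})
            continue
        r = k_significance(tree, band, n_perm=n_perm, n_sim=n_sim,
                           seed=child.generate_state(1)[0] % (2**31),
                           trait_name=str(w))
        rows.append({"wavelength": w, "k": r.k, "p_wn": r.p_wn,
                     "bm_low": r.bm_low, "bm_high": r.bm_high,
                     "constant": False, "signal_present": r.signal_present})
    out = pd.DataFrame(rows).set_index("wavelength")
    out["region"] = region_of(out.index.to_numpy())
    return out


# ---------------------------------------------------------------- PGLS

@dataclass(frozen=True)
class PglsResult:
    predictor: str
    slope: float
    intercept: float
    slope_se: float
    t: float
    p_value: float
    n: int
    sigma2: float


def pgls_fit(
    tree: dendropy.Tree,
    y: pd.Series | dict,
    x: pd.Series | dict,
    predictor: str = "x",
) -> PglsResult:
    """GLS regression of tip trait y on tip predictor x with BM covariance.

    On a star phylogeny the covariance is proportional to the identity and
    the estimates coincide with OLS.  Two-sided P from t with n - 2 df.
    """
    Vdf = phylo_vcv(tree)
    y = pd.Series(y).reindex(Vdf.index).to_numpy(float)
    x = pd.Series(x).reindex(Vdf.index).to_numpy(float)
    if np.isnan(y).any() or np.isnan(x).any():
        raise KeyError("y/x missing for some tips")
    n = y.size
    if n < 4:
        raise ValueError("PGLS needs at least 4 tips")
    V = Vdf.to_numpy()
    try:
        L = np.linalg.cholesky(V)
    except np.linalg.LinAlgError as e:
        raise np.linalg.LinAlgError(
            "singular BM covariance (duplicated zero-length tips?)"
        ) from e
    X = np.column_stack([np.ones(n), x])
    # whiten and solve ordinary least squares on the transformed system
    Xw = np.linalg.solve(L, X)
    yw = np.linalg.solve(L, y)
    XtX = Xw.T @ Xw
    beta = np.linalg.solve(XtX, Xw.T @ yw)
    resid = yw - Xw @ beta
    df = n - 2
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(XtX)
    se = float(np.sqrt(cov[1, 1]))
    tstat = beta[1] / se if se > 0 else np.inf * np.sign(beta[1])
    p = 2 * stats.t.sf(abs(tstat), df) if np.isfinite(tstat) else 0.0
    return PglsResult(
        predictor=predictor, slope=float(beta[1]), intercept=float(beta[0]),
        slope_se=se, t=float(tstat), p_value=float(p), n=n, sigma2=sigma2,
    )


def pearson_trait_env(traits: pd.DataFrame, env: pd.DataFrame) -> pd.DataFrame:
    """Pearson r with two-sided t-test for every (trait, variable) pair.

    Individual-level complement to PGLS: no phylogenetic correction, all
    samples enter.  Rows are aligned on the shared sample index.
    """
    common = traits.index.intersection(env.index)
    if len(common) < 3:
        raise ValueError("need at least 3 shared samples")
    t, e = traits.loc[common], env.loc[common]
    rows = []
    for trait in t.columns:
        for var in e.columns:
            tv, ev = t[trait].to_numpy(float), e[var].to_numpy(float)
            if np.std(tv) == 0 or np.std(ev) == 0:
                raise ValueError(f"zero variance in {trait} or {var}")
            r, p = stats.pearsonr(tv, ev)
            rows.append({"trait": trait, "variable": var,
                         "r": float(r), "p_value": float(p), "n": len(common)})
    return pd.DataFrame(rows)
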