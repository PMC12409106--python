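"""Redundancy analysis (RDA) and variance partitioning of phenotypic
variation into environmental (IBE), spatial (IBD), and joint fractions.

RDA is constrained ordination: multivariate least squares of a (centered)
response matrix on a predictor block, summarised by the proportion of total
response variance captured by the fitted values, with Ezekiel's adjusted
R2.  Partial RDA residualises response and predictors on a conditioning
block first; the three-model structure

    PHENO ~ ENV | GEO     (pure environment, a)
    PHENO ~ GEO | ENV     (pure space, c)
    PHENO ~ ENV + GEO     (total explainable)

yields the unique and joint adjusted-R2 fractions.  Permutation tests use
free permutation of reduced-model residuals.  The partitioning is
block-label agnostic: genetic predictor blocks pass through the same
interface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VarPartResult",
    "vif_filter",
    "corr_filter",
    "rda",
    "partial_rda",
    "variance_partition",
    "spatial_predictors",
]


def spatial_predictors(geo: pd.DataFrame) -> pd.DataFrame:
    """Default spatial block: centered longitude/latitude, their squares
    and interaction (5 columns)."""
    lon = geo["longitude"] - geo["longitude"].mean()
    lat = geo["latitude"] - geo["latitude"].mean()
    return pd.DataFrame({
        "lon": lon, "lat": lat, "lon2": lon**2, "lat2": lat**2,
        "lon_lat": lon * lat,
    }, index=geo.index)


def _vif(X: np.ndarray) -> np.ndarray:
    """Variance inflation factor of each column regressed on the others."""
    n, p = X.shape
    out = np.empty(p)
    Xc = X - X.mean(axis=0)
    for j in range(p):
        y = Xc[:, j]
        Z = np.delete(Xc, j, axis=1)
        if Z.shape[1] == 0 or np.allclose(y, 0):
            out[j] = 1.0
            continue
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        resid = y - Z @ beta
        ss_tot = float(y @ y)
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(env: pd.DataFrame, threshold: float = 5.0) -> pd.DataFrame:
    """Iteratively drop the largest-VIF variable until all VIF < threshold.

    Ties (e.g. a perfectly collinear pair) are broken deterministically by
    column order: the later column is dropped.
    """
    if env.shape[1] < 2:
        raise ValueError("need >= 2 variables")
    if env.shape[0] <= env.shape[1]:
        raise ValueError("need more samples than variables")
    keep = list(env.columns)
    while len(keep) > 1:
        v = _vif(env[keep].to_numpy(float))
        worst = np.flatnonzero(v == v.max())[-1]
        if v[worst] < threshold:
            break
        keep.pop(worst)
    return env[keep]


def corr_filter(env: pd.DataFrame, r_max: float = 0.60) -> pd.DataFrame:
    """Greedy retention in given column order: drop any variable whose
    absolute Pearson correlation with an already-retained one exceeds
    ``r_max``.  Order-dependent by design (document the order used)."""
    if env.shape[1] < 2:
        return env
    corr = env.corr().abs()
    keep: list = []
    for col in env.columns:
        if all(corr.loc[col, k] <= r_max for k in keep):
            keep.append(col)
    return env[keep]


def _design(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    return X


def _fit_r2(Y: np.ndarray, X: np.ndarray) -> tuple[float, int]:
    """Unadjusted trace R2 of centered Y on [1, X]; returns (R2, rank of X)."""
    n = Y.shape[0]
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    rank = int(np.linalg.matrix_rank(Xc)) if Xc.size else 0
    if rank == 0:
        return 0.0, 0
    if rank < Xc.shape[1]:
        warnings.warn("rank-deficient predictor block; dependent columns "
                      "contribute no extra constrained variance")
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fit = Xc @ beta
    ss_fit = float((fit**2).sum())
    ss_tot = float((Yc**2).sum())
    return (ss_fit / ss_tot if ss_tot > 0 else 0.0), rank


def _adjust(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R2 (the vegan convention)."""
    if n - p - 1 <= 0:
        return np.nan
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def rda(Y, X) -> dict:
    """Redundancy analysis of response matrix Y on predictor block X.

    Returns R2 (trace of fitted SS over total SS), Ezekiel-adjusted R2, and
    the constrained-axis sample scores (SVD of the fitted values).
    """
    Y, X = _design(Y), _design(X)
    n = Y.shape[0]
    if n <= X.shape[1]:
        raise ValueError("need more samples than predictors")
    r2, rank = _fit_r2(Y, X)
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    fit = Xc @ beta
    u, s, _ = np.linalg.svd(fit, full_matrices=False)
    scores = u[:, :rank] * s[:rank]
    return {"r2": r2, "adj_r2": _adjust(r2, n, rank), "rank": rank,
            "axis_scores": scores}


def partial_rda(Y, X, Z=None) -> dict:
    """Semipartial RDA: effect of X on Y after removing the conditioning
    block Z from both.

    Semipartial adjusted R2 = adjR2(X u Z) - adjR2(Z); the pseudo-F uses
    the unadjusted R2 increment over the residual variance of the full
    model.  With Z empty this is plain RDA.
    """
    Y, X = _design(Y), _design(X)
    if Z is None or np.size(Z) == 0:
        out = rda(Y, X)
        return {"semipartial_adj_r2": out["adj_r2"], "pseudo_f": np.nan,
                "adj_r2_full": out["adj_r2"], "r2_increment": out["r2"]}
    Z = _design(Z)
    n = Y.shape[0]
    XZ = np.hstack([X, Z])
    r2_full, rank_full = _fit_r2(Y, XZ)
    r2_z, rank_z = _fit_r2(Y, Z)
    p_x = rank_full - rank_z
    if p_x == 0:
        warnings.warn("X lies in the span of Z; zero semipartial fraction")
        return {"semipartial_adj_r2": 0.0, "pseudo_f": 0.0,
                "adj_r2_full": _adjust(r2_full, n, rank_full),
                "r2_increment": 0.0}
    adj = _adjust(r2_full, n, rank_full) - _adjust(r2_z, n, rank_z)
    denom_df = n - rank_full - 1
    pseudo_f = ((r2_full - r2_z) / p_x) / ((1.0 - r2_full) / denom_df)
    return {"semipartial_adj_r2": adj, "pseudo_f": float(pseudo_f),
            "adj_r2_full": _adjust(r2_full, n, rank_full),
            "r2_increment": r2_full - r2_z}


@dataclass(frozen=True)
class VarPartResult:
    """IBE/IBD partition of one response block."""

    label: str
    response: str
    env_given_geo: float        # a: pure environment (adjusted R2)
    geo_given_env: float        # c: pure space
    joint: float                # b
    unexplained: float
    total_adj_r2: float
    pve: dict                   # fraction name -> % of explained variance
    p_values: dict = field(default_factory=dict)
    per_variable: dict = field(default_factory=dict)
    negative_fractions: tuple = ()


def _perm_pvalue(Y, X, Z, n_perm: int, rng) -> float:
    """Permutation P for the semipartial effect of X given Z: free
    permutation of reduced-model (Y ~ Z) residuals."""
    Y, X, Z = _design(Y), _design(X), _design(Z)
    Zc = Z - Z.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    beta, *_ = np.linalg.lstsq(Zc, Yc, rcond=None)
    fitted = Zc @ beta
    resid = Yc - fitted
    f_obs = partial_rda(Y, X, Z)["pseudo_f"]
    count = 0
    n = Y.shape[0]
    for _ in range(n_perm):
        Yp = fitted + resid[rng.permutation(n)]
        if partial_rda(Yp, X, Z)["pseudo_f"] >= f_obs:
            count += 1
    return (1 + count) / (n_perm + 1)


def variance_partition(
    Y,
    env: pd.DataFrame,
    geo: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    label: str = "",
    response: str = "",
) -> VarPartResult:
    """Partition Y's explainable variance into pure-ENV (a), pure-GEO (c)
    and joint (b) adjusted-R2 fractions, with permutation tests for the two
    testable (pure) fractions and per-variable marginal contributions.

    a = adjR2(E u G) - adjR2(G);  c = adjR2(E u G) - adjR2(E);
    b = adjR2(E u G) - a - c;     unexplained = 1 - adjR2(E u G).
    PVE % expresses each fraction relative to the total explained.
    """
    Y = _design(Y)
    E = env.to_numpy(float) if isinstance(env, pd.DataFrame) else _design(env)
    G = geo.to_numpy(float) if isinstance(geo, pd.DataFrame) else _design(geo)
    n = Y.shape[0]
    r2_eg, rank_eg = _fit_r2(Y, np.hstack([E, G]))
    r2_e, rank_e = _fit_r2(Y, E)
    r2_g, rank_g = _fit_r2(Y, G)
    total = _adjust(r2_eg, n, rank_eg)
    a = total - _adjust(r2_g, n, rank_g)
    c = total - _adjust(r2_e, n, rank_e)
    b = total - a - c
    unexplained = 1.0 - total
    negative = tuple(name for name, v in
                     (("env_given_geo", a), ("geo_given_env", c), ("joint", b))
                     if v < 0)
    if negative:
        warnings.warn(f"negative adjusted-R2 fraction(s): {negative} "
                      "(reported as computed)")
    pve = {k: (100.0 * v / total if total != 0 else np.nan)
           for k, v in (("env_given_geo", a), ("geo_given_env", c),
                        ("joint", b))}
    rng = np.random.default_rng(seed)
    p_values = {}
    if n_perm > 0:
        p_values["env_given_geo"] = _perm_pvalue(Y, E, G, n_perm, rng)
        p_values["geo_given_env"] = _perm_pvalue(Y, G, E, n_perm, rng)

    per_variable = {}
    if isinstance(env, pd.DataFrame):
        for col in env.columns:
            out = rda(Y, env[[col]].to_numpy(float))
            per_variable[col] = out["adj_r2"]
    return VarPartResult(
        label=label, response=response,
        env_given_geo=float(a), geo_given_env=float(c), joint=float(b),
        unexplained=float(unexplained), total_adj_r2=float(total),
        pve=pve, p_values=p_values, per_variable=per_variable,
        negative_fractions=negative,
    )


def varpart_table(results: list[VarPartResult], alpha: float = 0.05) -> pd.DataFrame:
    """Fig-5-style long table: label x region/trait-set with IBE/IBD/joint
    PVE % and significance flags (non-significant fractions starred)."""
    rows = []
    for r in results:
        for frac in ("env_given_geo", "geo_given_env", "joint"):
            p = r.p_values.get(frac, np.nan)
            rows.append({
                "label": r.label, "response": r.response,
                "fraction": {"env_given_geo": "IBE", "geo_given_env": "IBD",
                             "joint": "joint"}[frac],
                "adj_r2": getattr(r, frac),
                "pve_pct": r.pve[frac],
                "p_value": p,
                "not_significant": bool(np.isnan(p) or p > alpha),
            })
    return pd.DataFrame(rows)
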