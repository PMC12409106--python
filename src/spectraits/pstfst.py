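"""Phenotypic divergence (P_ST) against neutral genetic divergence (F_ST).

P_ST is the phenotypic analogue of Q_ST computed from phenotypic variance
components: P_ST = (c/h2 * s2_B) / (c/h2 * s2_B + 2 * s2_W), where s2_B and
s2_W are the between- and within-group components of a one-way
random-effects ANOVA, c is the assumed proportion of between-group variance
that is additive-genetic and h2 the heritability.  c and h2 enter only as
the ratio c/h2; the statistic is monotone in it, so robustness is assessed
by sweeping the ratio and asking for the smallest ("critical") value at
which the lower P_ST confidence limit exceeds the upper F_ST limit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .popgen import FstResult

__all__ = [
    "PstResult",
    "trait_variance_components",
    "pst",
    "pst_bootstrap",
    "critical_ratio",
    "pst_fst_scan",
    "default_ratio_grid",
    "RATIO_ANCHORS",
]

#: c/h2 values at which yes/no selection decisions are reported
RATIO_ANCHORS = (0.25, 0.5, 0.75)


def default_ratio_grid(lo: float = 0.05, hi: float = 2.0, n: int = 40) -> np.ndarray:
    """Log-spaced c/h2 sweep, always containing the decision anchors."""
    grid = np.geomspace(lo, hi, n)
    grid = np.union1d(grid, np.asarray(RATIO_ANCHORS))
    return grid


def trait_variance_components(values, groups) -> tuple[float, float]:
    """Method-of-moments one-way random-effects ANOVA components.

    s2_within = MS_within; s2_between = max(0, (MS_between - MS_within)/n0)
    with n0 = (N - sum n_i^2 / N) / (r - 1), the standard unbalanced-design
    coefficient.  The negative raw between-group estimate (if any) is
    returned truncated; callers needing diagnostics can recompute it.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("need >= 2 groups")
    n_i = np.array([(groups == g).sum() for g in levels], dtype=float)
    if (n_i < 2).any():
        raise ValueError("every group needs >= 2 samples")
    N, r = n_i.sum(), len(levels)
    means = np.array([values[groups == g].mean() for g in levels])
    grand = (n_i * means).sum() / N
    ss_between = (n_i * (means - grand) ** 2).sum()
    ss_within = sum(((values[groups == g] - means[i]) ** 2).sum()
                    for i, g in enumerate(levels))
    ms_between = ss_between / (r - 1)
    ms_within = ss_within / (N - r)
    n0 = (N - (n_i**2).sum() / N) / (r - 1)
    s2b = max(0.0, (ms_between - ms_within) / n0)
    return float(s2b), float(ms_within)


def pst(ratio: float, s2b: float, s2w: float) -> float:
    """P_ST at one c/h2 ratio."""
    if ratio <= 0:
        raise ValueError("c/h2 ratio must be positive")
    if s2b < 0 or s2w < 0:
        raise ValueError("variance components must be non-negative")
    if s2b == 0 and s2w == 0:
        raise ValueError("P_ST undefined when both components are zero")
    return float(ratio * s2b / (ratio * s2b + 2.0 * s2w))


@dataclass
class PstResult:
    """P_ST sweep for one (group pair, trait/band) with bootstrap CIs."""

    pair: tuple
    trait: str
    s2_between: float
    s2_within: float
    ratio_grid: np.ndarray
    pst_curve: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    critical_ratio: float | None = None
    decisions: dict = field(default_factory=dict)   # anchor -> bool
    fst: float = np.nan
    fst_ci_high: float = np.nan
    region: str = ""

    def pst_at(self, ratio: float) -> float:
        i = int(np.argmin(np.abs(self.ratio_grid - ratio)))
        return float(self.pst_curve[i])


def pst_bootstrap(
    values,
    groups,
    ratio_grid=None,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    pair: tuple = ("A", "B"),
    trait: str = "trait",
) -> PstResult:
    """Percentile bootstrap of the P_ST sweep.

    Individuals are resampled with replacement *within* groups (groups are
    fixed entities), recomputing the variance components and the whole
    P_ST(ratio) curve each replicate.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if ratio_grid is None:
        ratio_grid = default_ratio_grid()
    ratio_grid = np.asarray(ratio_grid, dtype=float)
    s2b, s2w = trait_variance_components(values, groups)
    curve = np.array([pst(r, s2b, s2w) if (s2b, s2w) != (0.0, 0.0) else np.nan
                      for r in ratio_grid])

    rng = np.random.default_rng(seed)
    levels = pd.unique(groups)
    idx_of = {g: np.flatnonzero(groups == g) for g in levels}
    boots = np.empty((n_boot, ratio_grid.size))
    for b in range(n_boot):
        take = np.concatenate([
            rng.choice(idx_of[g], size=idx_of[g].size, replace=True)
            for g in levels
        ])
        bs2b, bs2w = trait_variance_components(values[take], groups[take])
        if bs2b == 0 and bs2w == 0:
            boots[b] = np.nan
        else:
            boots[b] = ratio_grid * bs2b / (ratio_grid * bs2b + 2 * bs2w)
    lo, hi = np.nanpercentile(
        boots, [100 * alpha / 2, 100 * (1 - alpha / 2)], axis=0)
    return PstResult(pair=tuple(pair), trait=trait, s2_between=s2b,
                     s2_within=s2w, ratio_grid=ratio_grid, pst_curve=curve,
                     ci_low=lo, ci_high=hi)


def critical_ratio(p: PstResult, f: FstResult) -> float | None:
    """Smallest grid ratio where the lower P_ST CI exceeds the upper F_ST CI.

    Returns None when the curves never separate.  Also fills the anchor
    decision flags and F_ST fields of ``p`` in place.
    """
    if set(map(str, p.pair)) != set(map(str, f.pair)):
        raise ValueError(f"pair mismatch: {p.pair} vs {f.pair}")
    fhi = f.ci_high if np.isfinite(f.ci_high) else f.theta
    above = p.ci_low > fhi
    crit = float(p.ratio_grid[above.argmax()]) if above.any() else None
    p.critical_ratio = crit
    p.fst, p.fst_ci_high = f.theta, fhi
    p.decisions = {
        anchor: bool(above[int(np.argmin(np.abs(p.ratio_grid - anchor)))])
        for anchor in RATIO_ANCHORS
    }
    return crit


def pst_fst_scan(
    traits: pd.DataFrame,
    groups,
    fst_results: list[FstResult],
    ratio_grid=None,
    n_boot: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    vip_mask=None,
    regions=None,
) -> tuple[list[PstResult], pd.DataFrame]:
    """P_ST-F_ST comparison for every (group pair, trait/band).

    ``traits`` columns may be named traits or spectral bands (e.g. CWT
    coefficients); ``vip_mask`` (boolean per column) restricts the scan to
    discriminant bands — pass None to scan every column (the common-garden
    mode disables VIP selection).  Returns the result objects plus a
    long-format summary table.
    """
    groups = np.asarray(groups)
    if ratio_grid is None:
        ratio_grid = default_ratio_grid()
    cols = np.asarray(traits.columns, dtype=object)
    if vip_mask is not None:
        cols = cols[np.asarray(vip_mask, dtype=bool)]
    regions = {} if regions is None else regions
    fst_by_pair = {frozenset(map(str, f.pair)): f for f in fst_results}
    results = []
    rows = []
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(len(fst_by_pair) * len(cols) + 1))
    for f in fst_results:
        pmask = np.isin(groups, list(map(str, f.pair)))
        for col in cols:
            r = pst_bootstrap(
                traits.loc[pmask, col].to_numpy(float), groups[pmask],
                ratio_grid=ratio_grid, n_boot=n_boot, alpha=alpha,
                seed=int(next(seeds)) % 2**31, pair=f.pair, trait=str(col))
            r.region = str(regions.get(col, ""))
            critical_ratio(r, f)
            results.append(r)
            anchor_cols = {}
            for anchor in RATIO_ANCHORS:
                i = int(np.argmin(np.abs(r.ratio_grid - anchor)))
                anchor_cols[f"pst_{anchor}"] = r.pst_curve[i]
                anchor_cols[f"flag_{anchor}"] = r.decisions[anchor]
            rows.append({
                "pair": "/".join(map(str, f.pair)), "trait": str(col),
                "region": r.region, "s2_between": r.s2_between,
                "s2_within": r.s2_within,
                "critical_ratio": r.critical_ratio,
                "fst": f.theta, "fst_ci_high": r.fst_ci_high,
                **anchor_cols,
            })
    return results, pd.DataFrame(rows)
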