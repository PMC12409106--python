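"""PLS chemometrics: trait prediction (PLSR) and species classification
(PLS-DA) from high-dimensional band matrices.

The latent-component fits use scikit-learn's NIPALS ``PLSRegression``;
variable-importance-in-projection (VIP) scoring, cross-validated component
selection (first-minimum-within-one-SE rule), and the bootstrap-balanced
PLS-DA iteration scheme are implemented here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import KFold

__all__ = [
    "PlsModel",
    "ConfusionMatrix",
    "split_data",
    "fit_plsr",
    "select_ncomp",
    "vip_scores",
    "fit_plsda",
    "predict_traits",
]

#: VIP band-selection thresholds: primary cut, then an extended inclusion cut
VIP_PRIMARY = 0.8
VIP_EXTENDED = 0.4


def split_data(
    n_or_index,
    fraction: float = 0.70,
    strata=None,
    seed: int = 0,
):
    """Stratified train/test split by row index.

    Returns (train_idx, test_idx) integer arrays.  Per stratum the train
    fraction is within one sample of ``fraction`` (floor/ceil of n*fraction,
    keeping at least one sample on each side).
    """
    if np.isscalar(n_or_index):
        index = np.arange(int(n_or_index))
    else:
        index = np.arange(len(n_or_index))
    strata = np.zeros(len(index)) if strata is None else np.asarray(strata)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for s in pd.unique(strata):
        rows = index[strata == s]
        if rows.size < 2:
            raise ValueError(f"stratum {s!r} has a single sample; cannot split")
        rows = rng.permutation(rows)
        n_train = int(round(fraction * rows.size))
        n_train = min(max(n_train, 1), rows.size - 1)
        train.extend(rows[:n_train])
        test.extend(rows[n_train:])
    return np.sort(np.array(train)), np.sort(np.array(test))


@dataclass
class PlsModel:
    """Fitted PLS model plus training metadata.

    For regression, ``target`` is a trait name and training metrics carry
    R2/RMSEP; for discriminant analysis, ``classes`` holds the label order
    of the one-hot columns.
    """

    estimator: PLSRegression
    n_components: int
    target: str = "y"
    classes: tuple | None = None
    wavelengths: np.ndarray | None = None
    metrics: dict = field(default_factory=dict)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.estimator.predict(np.asarray(X, dtype=float))

    def predict_class(self, X: np.ndarray) -> np.ndarray:
        """Argmax over predicted one-hot scores; ties -> lowest class index."""
        if self.classes is None:
            raise ValueError("not a discriminant model")
        scores = self.predict(X)
        return np.asarray(self.classes, dtype=object)[scores.argmax(axis=1)]


def fit_plsr(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    target: str = "y",
    wavelengths=None,
) -> PlsModel:
    """NIPALS PLS regression of a trait on a band matrix (centering only;
    wavelet coefficients share units, so no per-band scaling by default)."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] != y.size:
        raise ValueError("X rows and y length differ")
    if X.shape[0] <= n_components:
        raise ValueError("need more samples than components")
    if np.ptp(y) == 0:
        raise ValueError("constant target: PLSR is degenerate")
    est = PLSRegression(n_components=n_components, scale=False)
    est.fit(X, y)
    pred = est.predict(X).ravel()
    ss_res = float(((y - pred) ** 2).sum())
    ss_tot = float(((y - y.mean()) ** 2).sum())
    metrics = {
        "r2": 1.0 - ss_res / ss_tot,
        "rmsep": float(np.sqrt(ss_res / y.size)),
    }
    return PlsModel(est, n_components, target=target,
                    wavelengths=None if wavelengths is None
                    else np.asarray(wavelengths, float),
                    metrics=metrics)


def select_ncomp(
    X: np.ndarray,
    y: np.ndarray,
    max_comp: int = 20,
    k_folds: int = 10,
    seed: int = 0,
) -> int:
    """Cross-validated component count, first-minimum-within-one-SE rule.

    Picks the smallest component count whose CV RMSEP is within one standard
    error (over folds) of the global minimum; collapses to 1 for pure noise.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if max_comp < 1:
        raise ValueError("max_comp must be >= 1")
    max_comp = min(max_comp, X.shape[0] - max(2, X.shape[0] // k_folds) - 1,
                   X.shape[1])
    max_comp = max(max_comp, 1)
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed % 2**31)
    fold_rmse = np.zeros((k_folds, max_comp))
    for f, (tr, te) in enumerate(kf.split(X)):
        est = PLSRegression(n_components=max_comp, scale=False)
        est.fit(X[tr], y[tr])
        # nested predictions for every component count from one fit
        Xc = X[te] - est._x_mean
        for a in range(1, max_comp + 1):
            coef = est.x_rotations_[:, :a] @ (
                est.y_loadings_[:, :a].T * est._y_std)
            pred = Xc @ coef.ravel() + est._y_mean
            fold_rmse[f, a - 1] = np.sqrt(np.mean((y[te] - pred) ** 2))
    mean_rmse = fold_rmse.mean(axis=0)
    best = int(mean_rmse.argmin())
    se = fold_rmse[:, best].std(ddof=1) / np.sqrt(k_folds)
    within = np.flatnonzero(mean_rmse <= mean_rmse[best] + se)
    return int(within[0]) + 1


def vip_scores(model: PlsModel) -> np.ndarray:
    """Variable importance in projection, one score per band.

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a ) with
    p bands and SSY_a the y-variance explained by component a.  Normalised
    so that sum_j VIP_j^2 = p (mean squared VIP = 1).
    """
    est = model.estimator
    if not hasattr(est, "x_weights_"):
        raise ValueError("model is not fitted")
    W = est.x_weights_            # p x A
    T = est.x_scores_             # n x A
    Q = est.y_loadings_           # targets x A
    p, _ = W.shape
    ssy = (Q**2).sum(axis=0) * (T**2).sum(axis=0)
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    vip = np.sqrt(p * (Wn**2 @ ssy) / ssy.sum())
    return vip


def select_vip_bands(
    vip: np.ndarray,
    primary: float = VIP_PRIMARY,
    extended: float = VIP_EXTENDED,
) -> np.ndarray:
    """Boolean mask of retained bands: the primary cut keeps bands with
    VIP > ``primary``; if any pass, bands with VIP >= ``extended`` are also
    included to broaden the discriminant set."""
    vip = np.asarray(vip, float)
    mask = vip > primary
    if mask.any():
        mask = mask | (vip >= extended)
    return mask


@dataclass(frozen=True)
class ConfusionMatrix:
    """Aggregated confusion counts: rows = predicted, columns = observed."""

    counts: pd.DataFrame

    @property
    def accuracy(self) -> float:
        c = self.counts.to_numpy(float)
        return float(np.trace(c) / c.sum())

    @property
    def kappa(self) -> float:
        c = self.counts.to_numpy(float)
        n = c.sum()
        po = np.trace(c) / n
        pe = float((c.sum(axis=1) * c.sum(axis=0)).sum()) / n**2
        return (po - pe) / (1 - pe) if pe < 1 else 1.0

    def percent(self) -> pd.DataFrame:
        """Column-normalised percentages (diagonal = percent correct)."""
        c = self.counts
        return 100.0 * c / c.sum(axis=0)

    def sensitivity(self) -> pd.Series:
        c = self.counts.to_numpy(float)
        return pd.Series(np.diag(c) / c.sum(axis=0), index=self.counts.columns)

    def specificity(self) -> pd.Series:
        c = self.counts.to_numpy(float)
        total = c.sum()
        out = {}
        for i, cls in enumerate(self.counts.columns):
            tn = total - c[i, :].sum() - c[:, i].sum() + c[i, i]
            fp = c[i, :].sum() - c[i, i]
            out[cls] = tn / (tn + fp) if tn + fp > 0 else np.nan
        return pd.Series(out)


def fit_plsda(
    X: np.ndarray,
    labels,
    n_components: int,
    n_iterations: int = 50,
    seed: int = 0,
    train_fraction: float = 0.70,
    min_class_size: int = 20,
) -> tuple[PlsModel, ConfusionMatrix]:
    """Iterative bootstrap-balanced PLS discriminant analysis.

    Each iteration draws a stratified train/test split, resamples every
    training class with replacement to the smallest class size (controlling
    for unequal sampling), fits a one-hot PLS regression, and classifies the
    held-out samples by argmax of the predicted class scores.  Confusion
    counts are aggregated over iterations.  The returned model is a final
    fit on all samples (classes balanced once).
    """
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = tuple(pd.unique(labels))
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least two classes")
    class_sizes = {c: int((labels == c).sum()) for c in classes}
    if min(class_sizes.values()) < min_class_size:
        warnings.warn(
            f"smallest class has {min(class_sizes.values())} samples "
            f"(recommended minimum {min_class_size})"
        )
    onehot = (labels[:, None] == np.asarray(classes, dtype=object)[None, :]) \
        .astype(float)
    rng = np.random.default_rng(seed)
    k = len(classes)
    counts = np.zeros((k, k))
    for it in range(n_iterations):
        tr, te = split_data(len(labels), fraction=train_fraction,
                            strata=labels,
                            seed=int(rng.integers(2**31)))
        target = min((labels[tr] == c).sum() for c in classes)
        boot = []
        for c in classes:
            rows = tr[labels[tr] == c]
            boot.extend(rng.choice(rows, size=target, replace=True))
        boot = np.asarray(boot)
        est = PLSRegression(n_components=n_components, scale=False)
        est.fit(X[boot], onehot[boot])
        pred = est.predict(X[te]).argmax(axis=1)
        obs = onehot[te].argmax(axis=1)
        for p_i, o_i in zip(pred, obs):
            counts[p_i, o_i] += 1

    cm = ConfusionMatrix(pd.DataFrame(counts, index=list(classes),
                                      columns=list(classes)))
    # final fit on all samples, balanced once
    target = min(class_sizes.values())
    rows = []
    for c in classes:
        rows.extend(rng.choice(np.flatnonzero(labels == c), size=target,
                               replace=True))
    est = PLSRegression(n_components=n_components, scale=False)
    est.fit(X[np.asarray(rows)], onehot[np.asarray(rows)])
    sens, spec = cm.sensitivity(), cm.specificity()
    model = PlsModel(est, n_components, target="class", classes=classes,
                     metrics={"accuracy": cm.accuracy, "kappa": cm.kappa,
                              "sensitivity": sens.to_dict(),
                              "specificity": spec.to_dict()})
    return model, cm


def predict_traits(
    models: dict,
    X: np.ndarray,
    sample_ids=None,
) -> pd.DataFrame:
    """Apply a dict of fitted per-trait PLSR models to a band matrix."""
    out = {name: m.predict(X).ravel() for name, m in models.items()}
    return pd.DataFrame(out, index=sample_ids)
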