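"""Reflectance-spectra containers and preprocessing.

The processing chain mirrors a standard dried-leaf spectroscopy workflow:
raw sensor output -> splice (detector-junction) correction -> resampling to a
uniform 3 nm grid -> continuous wavelet transform (sum of Mexican-hat scales
2^2, 2^4, 2^6) with edge-band trimming to 400-2450 nm.  Region slicing and
band-ratio vegetation indices operate on any pre-CWT state.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import convolve1d

__all__ = [
    "SpectraSet",
    "REGIONS",
    "splice_correct",
    "resample",
    "cwt_transform",
    "region_slice",
    "vegetation_indices",
    "read_spectra",
    "write_spectra",
    "species_summary",
]

#: Spectral regions in nm: lower-closed, upper-open except the last.
REGIONS = {
    "VIS": (400.0, 700.0),
    "NIR": (700.0, 1200.0),
    "SWIR": (1200.0, 2500.0),
}

_STATES = ("raw", "spliced", "resampled", "cwt")


class EmptySelectionError(ValueError):
    """Raised when a slice selects no bands."""


@dataclass(frozen=True)
class SpectraSet:
    """Samples x wavelengths reflectance matrix with processing state.

    Parameters
    ----------
    wavelengths : strictly ascending grid in nm.
    values : 2-D array, one row per sample.  Unitless reflectance fractions
        up to the ``resampled`` state; signed wavelet coefficients after CWT.
    state : one of ``raw | spliced | resampled | cwt``.
    sample_ids : one identifier per row.
    """

    wavelengths: np.ndarray
    values: np.ndarray
    state: str = "raw"
    sample_ids: tuple = field(default=None)

    def __post_init__(self):
        w = np.asarray(self.wavelengths, dtype=float)
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if w.ndim != 1 or np.any(np.diff(w) <= 0):
            raise ValueError("wavelengths must be a strictly ascending 1-D grid")
        if v.shape[1] != w.size:
            raise ValueError(
                f"values has {v.shape[1]} bands but grid has {w.size} wavelengths"
            )
        if self.state not in _STATES:
            raise ValueError(f"unknown state {self.state!r}")
        if self.state != "cwt" and (np.nanmin(v) < 0 or np.nanmax(v) > 1):
            raise ValueError("reflectance must lie in [0, 1] before CWT")
        ids = self.sample_ids
        if ids is None:
            ids = tuple(f"s{i}" for i in range(v.shape[0]))
        ids = tuple(str(s) for s in ids)
        if len(ids) != v.shape[0]:
            raise ValueError("sample_ids length does not match number of rows")
        object.__setattr__(self, "wavelengths", w)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "sample_ids", ids)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_bands(self) -> int:
        return self.wavelengths.size

    def band_index(self, wavelength: float, tol: float | None = None) -> int:
        """Nearest-band lookup; ``tol`` defaults to half the median grid step."""
        i = int(np.argmin(np.abs(self.wavelengths - wavelength)))
        if tol is None:
            tol = 0.5 * float(np.median(np.diff(self.wavelengths)))
        if abs(self.wavelengths[i] - wavelength) > tol + 1e-9:
            raise ValueError(f"no band within {tol} nm of {wavelength} nm")
        return i

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=self.wavelengths
        )


def _require_state(s: SpectraSet, allowed: tuple, op: str) -> None:
    if s.state not in allowed:
        raise ValueError(
            f"{op} requires state in {allowed}, got {s.state!r} "
            "(allowed transitions: raw -> spliced -> resampled -> cwt)"
        )


def splice_correct(s: SpectraSet, joints=(990.0, 1900.0)) -> SpectraSet:
    """Remove multiplicative steps at detector junctions.

    At each joint the segment downstream (longer wavelengths) is rescaled by
    the ratio of the upstream segment's linear extrapolation at the first
    downstream band to the observed value there, so the spectrum continues
    smoothly across the junction.  Joints are processed left to right.
    """
    _require_state(s, ("raw",), "splice_correct")
    w, v = s.wavelengths, s.values.copy()
    for joint in sorted(joints):
        if not (w[1] < joint < w[-2]):
            raise ValueError(f"splice joint {joint} nm not interior to the grid")
        # first downstream band: a band exactly at the joint belongs to the
        # downstream detector segment
        k = int(np.searchsorted(w, joint, side="left"))
        # linear extrapolation of the two last upstream bands to w[k]
        x0, x1 = w[k - 2], w[k - 1]
        y0, y1 = v[:, k - 2], v[:, k - 1]
        expected = y1 + (y1 - y0) * (w[k] - x1) / (x1 - x0)
        observed = v[:, k]
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(observed != 0, expected / observed, 1.0)
        v[:, k:] *= factor[:, None]
    v = np.clip(v, 0.0, 1.0)
    return replace(s, values=v, state="spliced")


def resample(s: SpectraSet, step: float = 3.0) -> SpectraSet:
    """Linear interpolation onto an arithmetic grid with the given step (nm)."""
    _require_state(s, ("raw", "spliced"), "resample")
    if step <= 0:
        raise ValueError("step must be positive")
    w = s.wavelengths
    grid = np.arange(w[0], w[-1] + 0.5 * step, step)
    grid = grid[grid <= w[-1] + 1e-9]
    out = np.empty((s.n_samples, grid.size))
    for i in range(s.n_samples):
        out[i] = np.interp(grid, w, s.values[i])
    return replace(s, wavelengths=grid, values=out, state="resampled")


def _mexican_hat_kernel(scale: float) -> np.ndarray:
    """Discrete Mexican-hat (second-derivative-of-Gaussian) kernel.

    Sampled on integer band offsets over +-5 scale units, explicitly
    re-centered to zero mean (so constants map to exactly zero) and
    L2-normalised (so coefficient magnitudes are comparable across scales).
    """
    half = max(int(np.ceil(5 * scale)), 1)
    t = np.arange(-half, half + 1, dtype=float) / scale
    k = (1.0 - t**2) * np.exp(-0.5 * t**2)
    k -= k.mean()
    k /= np.linalg.norm(k)
    return k


def cwt_transform(
    s: SpectraSet,
    scale_exponents=(2, 4, 6),
    trim: tuple = (400.0, 2450.0),
) -> SpectraSet:
    """Continuous wavelet transform, summed over dyadic scales.

    Each spectrum is convolved (reflect padding) with the Mexican-hat mother
    wavelet at scales ``2**e`` bands for each exponent, the per-scale
    coefficient layers are summed bandwise, and edge bands outside ``trim``
    are discarded.
    """
    _require_state(s, ("resampled",), "cwt_transform")
    scales = [2.0**e for e in scale_exponents]
    max_support = int(np.ceil(5 * max(scales)))
    if s.n_bands < max_support:
        raise ValueError(
            f"need at least {max_support} bands to support scale {max(scales):g}"
        )
    total = np.zeros_like(s.values)
    for a in scales:
        total += convolve1d(s.values, _mexican_hat_kernel(a), axis=1, mode="reflect")
    keep = (s.wavelengths >= trim[0]) & (s.wavelengths <= trim[1])
    if not keep.any():
        raise EmptySelectionError("trim window excludes every band")
    return replace(
        s, wavelengths=s.wavelengths[keep], values=total[:, keep], state="cwt"
    )


def region_slice(s: SpectraSet, region: str) -> SpectraSet:
    """Restrict to the VIS, NIR or SWIR region (lower-closed, upper-open
    except SWIR, which keeps its upper bound)."""
    lo, hi = REGIONS[region.upper()]
    w = s.wavelengths
    keep = (w >= lo) & ((w <= hi) if region.upper() == "SWIR" else (w < hi))
    if not keep.any():
        raise EmptySelectionError(f"no bands in region {region}")
    return replace(s, wavelengths=w[keep], values=s.values[:, keep])


def region_of(wavelengths: np.ndarray) -> np.ndarray:
    """Region label per wavelength, using the same boundaries as region_slice."""
    w = np.asarray(wavelengths, dtype=float)
    out = np.where(w < 700.0, "VIS", np.where(w < 1200.0, "NIR", "SWIR"))
    return out.astype(object)


def vegetation_indices(s: SpectraSet, strict: bool = False) -> pd.DataFrame:
    """Band-ratio indices per sample: CI, NDWI, ARI.

    CI (Chlorophyll Index Red Edge) = R750 / R710;
    NDWI (Normalized Difference Water Index) = (R835 - R1610) / (R835 + R1610);
    ARI (Anthocyanin Reflectance Index) = 1/R550 - 1/R700.

    Required wavelengths are resolved to the nearest band (within half a grid
    step).  Samples with zero reflectance at a required band get NaN for the
    affected index (and a warning), or raise if ``strict``.
    """
    _require_state(s, ("raw", "spliced", "resampled"), "vegetation_indices")
    r = {nm: s.values[:, s.band_index(nm)] for nm in (750, 710, 835, 1610, 550, 700)}
    bad = (r[710] == 0) | (r[835] + r[1610] == 0) | (r[550] == 0) | (r[700] == 0)
    if bad.any():
        ids = [s.sample_ids[i] for i in np.flatnonzero(bad)]
        msg = f"zero reflectance at a required band for samples {ids}; index undefined"
        if strict:
            raise ZeroDivisionError(msg)
        warnings.warn(msg)
    with np.errstate(divide="ignore", invalid="ignore"):
        ci = r[750] / r[710]
        ndwi = (r[835] - r[1610]) / (r[835] + r[1610])
        ari = 1.0 / r[550] - 1.0 / r[700]
    out = pd.DataFrame(
        {"CI": ci, "NDWI": ndwi, "ARI": ari}, index=list(s.sample_ids)
    )
    out[np.broadcast_to(bad[:, None], out.shape)] = np.nan
    return out


def species_summary(s: SpectraSet, labels) -> pd.DataFrame:
    """Bandwise mean +- SD per group (the classic spectra-figure summary)."""
    df = s.to_frame()
    g = df.groupby(np.asarray(labels))
    mean = g.mean()
    sd = g.std(ddof=1)
    mean["stat"], sd["stat"] = "mean", "sd"
    return pd.concat([mean, sd]).set_index("stat", append=True)


# ---------------------------------------------------------------- file I/O

def read_spectra(path, state: str = "raw", sep: str = ",") -> SpectraSet:
    """Read a delimited spectra matrix.

    Layout: header row of wavelengths in nm; first column sample IDs; one
    row of reflectance values per sample.
    """
    df = pd.read_csv(path, sep=sep, index_col=0)
    wavelengths = df.columns.astype(float).to_numpy()
    return SpectraSet(wavelengths, df.to_numpy(float), state=state,
                      sample_ids=tuple(df.index.astype(str)))


def write_spectra(s: SpectraSet, path, sep: str = ",") -> None:
    s.to_frame().to_csv(path, sep=sep, index_label="sample_id")
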