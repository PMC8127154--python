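"""Multi-echo processing: T2* fitting, optimal echo combination, tSNR,
percentage-difference maps, Gaussian smoothing, initial-volume dropping.

The echo combination follows the T2*-weighted "optimal combination"
scheme: weights proportional to TE * exp(-TE/T2*), which maximizes BOLD
contrast-to-noise under mono-exponential decay.  Under this scheme the
TE = 0 free-induction-decay image receives zero weight; a tSNR^2-weighted
alternative is provided for pipelines that want the FID to contribute.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = [
    "drop_initial_volumes",
    "T2StarMap",
    "fit_t2star",
    "optimal_combine",
    "TSNRMap",
    "tsnr_map",
    "percent_difference_map",
    "smooth_gaussian",
]

T2STAR_MIN = 0.005  # s
T2STAR_MAX = 0.3


def drop_initial_volumes(series: np.ndarray, n: int = 10) -> np.ndarray:
    """Remove the first ``n`` volumes (non-steady-state magnetisation)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n >= series.shape[-1]:
        raise ValueError(f"cannot drop {n} of {series.shape[-1]} volumes")
    return series[..., n:]


@dataclass
class T2StarMap:
    t2star: np.ndarray   # seconds, clamped to [T2STAR_MIN, T2STAR_MAX] in mask
    mask: np.ndarray     # bool


def fit_t2star(echo_mean_volumes, TEs) -> T2StarMap:
    """Voxel-wise T2* from log-linear least squares over all echoes.

    ``echo_mean_volumes`` is a list of temporal-mean volumes, one per TE
    (TE = 0 included).  R2* is minus the slope of log(S) on TE; T2* = 1/R2*
    clamped to [5, 300] ms.  Voxels with nonpositive signal at any echo
    are masked out rather than raising.
    """
    TEs = np.asarray(TEs, dtype=float)
    if len(echo_mean_volumes) < 2:
        raise ValueError("need >= 2 echoes")
    S = np.stack([np.asarray(v, dtype=float) for v in echo_mean_volumes], axis=-1)
    mask = np.all(S > 0, axis=-1)
    logS = np.where(S > 0, np.log(np.where(S > 0, S, 1.0)), 0.0)
    # slope of least-squares line logS ~ a + b*TE
    te_c = TEs - TEs.mean()
    denom = float(np.sum(te_c**2))
    slope = (logS @ te_c) / denom
    r2star = -slope
    with np.errstate(divide="ignore"):
        t2 = np.where(r2star > 0, 1.0 / np.where(r2star > 0, r2star, 1.0), np.inf)
    t2 = np.clip(t2, T2STAR_MIN, T2STAR_MAX)
    t2 = np.where(mask, t2, 0.0)
    return T2StarMap(t2star=t2, mask=mask)


def optimal_combine(
    echo_series,
    TEs,
    t2star: T2StarMap,
    scheme: str = "te_weighted",
) -> tuple[np.ndarray, np.ndarray]:
    """Combine per-echo series into one, weighting echoes per voxel.

    ``te_weighted``: w_e proportional to TE_e * exp(-TE_e / T2*) (the FID
    at TE = 0 gets weight 0).  ``tsnr_weighted``: w_e proportional to the
    squared per-echo tSNR.  Weights are normalized to sum 1 per voxel;
    voxels where every weight is zero are masked.

    Returns ``(combined_series, mask)``.
    """
    TEs = np.asarray(TEs, dtype=float)
    if len(echo_series) < 2:
        raise ValueError("need >= 2 echoes to combine")
    S = np.stack(echo_series, axis=0)  # (echo, x, y, z, t)
    if scheme == "te_weighted":
        t2 = np.where(t2star.mask, t2star.t2star, np.inf)
        w = TEs[:, None, None, None] * np.exp(
            -TEs[:, None, None, None] / t2[None, ...]
        )
        w = np.where(t2star.mask[None, ...], w, 0.0)
    elif scheme == "tsnr_weighted":
        w = np.stack(
            [np.nan_to_num(tsnr_map(s).tsnr) ** 2 for s in echo_series], axis=0
        )
    else:
        raise ValueError(f"unknown combination scheme {scheme!r}")
    wsum = w.sum(axis=0)
    mask = wsum > 0
    w = np.where(mask[None, ...], w / np.where(wsum > 0, wsum, 1.0)[None, ...], 0.0)
    combined = np.einsum("exyz,exyzt->xyzt", w, S)
    return combined, mask


@dataclass
class TSNRMap:
    tsnr: np.ndarray
    mask: np.ndarray
    detrend_order: int = 2


def tsnr_map(series: np.ndarray, detrend_order: int = 2) -> TSNRMap:
    """Temporal SNR: voxel mean over time divided by the residual standard
    deviation after polynomial detrending of the given order.

    The residual sd uses the regression degrees of freedom
    (n - detrend_order - 1).  Zero-variance voxels are masked and set 0.
    """
    n = series.shape[-1]
    if n < detrend_order + 2:
        raise ValueError("too few time points for the detrend order")
    t = np.linspace(-1.0, 1.0, n)
    X = np.vander(t, detrend_order + 1)  # columns t^order ... 1
    Y = series.reshape(-1, n).T
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
    resid = Y - X @ beta
    df = n - (detrend_order + 1)
    sd = np.sqrt(np.sum(resid**2, axis=0) / df)
    mean = Y.mean(axis=0)
    mask = sd > max(1e-12, 1e-12 * np.abs(mean).max())
    with np.errstate(divide="ignore", invalid="ignore"):
        tsnr = np.where(mask, mean / np.where(mask, sd, 1.0), 0.0)
    tsnr = np.maximum(tsnr, 0.0)
    shape = series.shape[:-1]
    return TSNRMap(
        tsnr=tsnr.reshape(shape), mask=mask.reshape(shape), detrend_order=detrend_order
    )


def percent_difference_map(tsnr_a: TSNRMap, tsnr_b: TSNRMap) -> np.ndarray:
    """100 * (a - b) / (a + b) on the joint mask; elsewhere NaN."""
    if tsnr_a.tsnr.shape != tsnr_b.tsnr.shape:
        raise ValueError("tSNR maps must share a grid")
    a, b = tsnr_a.tsnr, tsnr_b.tsnr
    ok = tsnr_a.mask & tsnr_b.mask & ((a + b) != 0)
    out = np.full(a.shape, np.nan)
    out[ok] = 100.0 * (a[ok] - b[ok]) / (a[ok] + b[ok])
    return out


def smooth_gaussian(
    series: np.ndarray, fwhm_mm: float = 8.0, voxel_size: float = 4.0
) -> np.ndarray:
    """Separable spatial Gaussian smoothing of a 3D or 4D (x,y,z,t) array.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, in mm, with reflective
    boundaries (mean-preserving).  fwhm = 0 is the identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm must be >= 0")
    if fwhm_mm == 0:
        return series.copy()
    sigma_vox = fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0))) / voxel_size
    sigma = (sigma_vox,) * 3 + ((0,) if series.ndim == 4 else ())
    return ndimage.gaussian_filter(series, sigma=sigma, mode="reflect")
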