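"""First- and group-level GLM for event-related fMRI.

Design matrices are built by convolving condition event streams with the
canonical double-gamma haemodynamic response function at microtime
resolution and sampling at the volume grid.  Deviant and Novel tones are
modelled as zero-duration events, silent rest blocks as boxcar epochs, and
Standard tones are left as the implicit baseline.  Drift is absorbed by a
discrete-cosine basis implementing a high-pass filter (128 s cutoff by
default).  Serial correlation is handled by a pooled-rho AR(1)
Cochrane-Orcutt prewhitening.  Group inference uses one-sample / paired t
tests and sign-flip permutation for cluster-level family-wise error
control.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

__all__ = [
    "canonical_hrf",
    "build_design",
    "DesignMatrix",
    "GLMFit",
    "fit_glm",
    "contrast_tmap",
    "CONTRAST_PRESETS",
    "contrast_vector",
    "group_ttest",
    "paired_group_ttest",
    "cluster_inference",
    "percent_signal_change",
]

#: SPM-convention double-gamma parameters: response gamma with shape 6
#: (peak delay 6 s at unit dispersion), undershoot gamma with shape 16,
#: undershoot ratio 1/6, kernel length 32 s.
HRF_PEAK_DELAY = 6.0
HRF_UNDERSHOOT_DELAY = 16.0
HRF_DISPERSION = 1.0
HRF_UNDERSHOOT_RATIO = 1.0 / 6.0
HRF_LENGTH = 32.0


def canonical_hrf(dt: float) -> np.ndarray:
    """Canonical double-gamma HRF sampled at resolution ``dt``, peak 1.

    Difference of two gamma densities (response minus scaled undershoot)
    over [0, 32 s].  The gamma with shape 6 and unit scale has its mode at
    5 s, so the sampled kernel peaks near 5 s.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    t = np.arange(0.0, HRF_LENGTH + dt / 2, dt)
    h = stats.gamma.pdf(t, HRF_PEAK_DELAY / HRF_DISPERSION, scale=HRF_DISPERSION)
    h = h - HRF_UNDERSHOOT_RATIO * stats.gamma.pdf(
        t, HRF_UNDERSHOOT_DELAY / HRF_DISPERSION, scale=HRF_DISPERSION
    )
    return h / h.max()


def _dct_basis(n: int, tr: float, cutoff: float) -> np.ndarray:
    """Discrete-cosine drift basis for periods longer than ``cutoff``.

    The number of functions is floor(2 * duration / cutoff) for the
    retained duration, excluding the constant term.
    """
    duration = n * tr
    k_max = int(np.floor(2.0 * duration / cutoff))
    t = np.arange(n)
    basis = [np.cos(np.pi * k * (2 * t + 1) / (2 * n)) for k in range(1, k_max + 1)]
    return np.column_stack(basis) if basis else np.empty((n, 0))


@dataclass
class DesignMatrix:
    matrix: np.ndarray                 # (volumes, regressors)
    names: list[str]
    TR: float
    hpf_cutoff: float
    condition_names: list[str] = field(default_factory=list)

    @property
    def n_volumes(self) -> int:
        return self.matrix.shape[0]

    def column(self, name: str) -> np.ndarray:
        return self.matrix[:, self.names.index(name)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, columns=self.names)


def _convolve_stream(onsets, durations, amplitudes, n_vols, tr, dt):
    """HRF-convolve an event stream at microtime dt, sample at the TR grid."""
    n_fine = int(np.ceil(n_vols * tr / dt)) + 1
    stream = np.zeros(n_fine)
    for onset, dur, amp in zip(onsets, durations, amplitudes):
        i0 = int(round(onset / dt))
        if i0 >= n_fine:
            continue
        if dur <= dt:           # zero-duration event: one microtime bin
            stream[i0] += amp
        else:
            i1 = min(n_fine, int(round((onset + dur) / dt)))
            stream[i0:i1] += amp
    h = canonical_hrf(dt)
    conv = np.convolve(stream, h)[:n_fine]
    sample_idx = np.round(np.arange(n_vols) * tr / dt).astype(int)
    return conv[sample_idx]


def build_design(
    schedule,
    TR: float,
    n_vols: int,
    drop: int = 10,
    hpf_cutoff: float = 128.0,
    silent_as_epochs: bool = True,
    nuisance: np.ndarray | None = None,
    microtime: int = 16,
) -> DesignMatrix:
    """Build the first-level design matrix for one run.

    Conditions: ``deviant`` and ``novel`` as zero-duration events,
    ``silent`` as rest-block epochs; Standard tones are NOT modelled
    (implicit baseline).  The first ``drop`` volumes are excluded; the DCT
    drift basis and a constant complete the matrix.
    """
    dt = TR / microtime
    n_kept = n_vols - drop
    if n_kept <= 0:
        raise ValueError("drop leaves no volumes")
    t0 = drop * TR

    cols, names = [], []
    for cond in ("deviant", "novel"):
        onsets = schedule.onsets(cond) - t0
        keep = onsets >= 0
        onsets = onsets[keep]
        col = _convolve_stream(
            onsets, np.zeros_like(onsets), np.ones_like(onsets), n_kept, TR, dt
        )
        cols.append(col)
        names.append(cond)
    rest_onsets = schedule.onsets("rest") - t0
    rest_durs = np.array(
        [e.duration for e in schedule.events if e.trial_type == "rest"], dtype=float
    )
    keep = rest_onsets >= 0
    rest_onsets, rest_durs = rest_onsets[keep], rest_durs[keep]
    if not silent_as_epochs:
        rest_durs = np.zeros_like(rest_durs)
    cols.append(
        _convolve_stream(rest_onsets, rest_durs, np.ones_like(rest_onsets), n_kept, TR, dt)
    )
    names.append("silent")
    condition_names = list(names)

    if nuisance is not None:
        nuisance = np.atleast_2d(np.asarray(nuisance, dtype=float))
        if nuisance.shape[0] != n_kept:
            raise ValueError("nuisance rows must match retained volumes")
        for j in range(nuisance.shape[1]):
            cols.append(nuisance[:, j])
            names.append(f"nuisance_{j}")

    drift = _dct_basis(n_kept, TR, hpf_cutoff)
    for j in range(drift.shape[1]):
        cols.append(drift[:, j])
        names.append(f"drift_{j + 1}")
    cols.append(np.ones(n_kept))
    names.append("constant")

    return DesignMatrix(
        matrix=np.column_stack(cols),
        names=names,
        TR=TR,
        hpf_cutoff=hpf_cutoff,
        condition_names=condition_names,
    )


@dataclass
class GLMFit:
    beta: np.ndarray        # (..., n_regressors)
    sigma2: np.ndarray      # (...,)
    df: int
    ar1_rho: float
    xtx_inv: np.ndarray     # (n_regressors, n_regressors), whitened design
    design: DesignMatrix
    mask: np.ndarray        # (...,) bool


def _match_ar1_rho(X: np.ndarray, r_obs: float) -> float:
    """AR(1) coefficient whose expected OLS-residual lag-1 autocorrelation
    matches the observed value.

    The naive residual estimate is biased towards zero because the design
    projection (notably the low-frequency drift basis) absorbs serially
    correlated noise.  With M the residual-forming matrix and V(rho) the
    AR(1) correlation matrix, E[sum e_t e_{t-1}] / E[sum e_t^2] =
    tr(M L M V) / tr(M V) with L the symmetrized lag-1 operator; solving
    this scalar equation for rho removes the bias.
    """
    from scipy.linalg import toeplitz
    from scipy.optimize import brentq

    n = X.shape[0]
    M = np.eye(n) - X @ np.linalg.pinv(X)
    L = np.zeros((n, n))
    idx = np.arange(n - 1)
    L[idx, idx + 1] = 0.5
    L[idx + 1, idx] = 0.5
    MLM = M @ L @ M

    def expected_r(rho):
        V = toeplitz(rho ** np.arange(n))
        return np.trace(MLM @ V) / np.trace(M @ V)

    f = lambda rho: expected_r(rho) - r_obs
    lo, hi = -0.95, 0.98
    try:
        if f(lo) * f(hi) > 0:
            return float(np.clip(r_obs, -0.95, 0.95))
        return float(brentq(f, lo, hi, xtol=1e-4))
    except ValueError:
        return float(np.clip(r_obs, -0.95, 0.95))


def _ols(X, Y):
    """OLS via pseudo-inverse; Y is (time, voxels)."""
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    return beta, resid


def fit_glm(series: np.ndarray, design: DesignMatrix, whiten: str = "ar1") -> GLMFit:
    """Fit the GLM voxel-wise.

    ``series`` is (..., time) with spatial axes leading.  With
    ``whiten="ar1"``, residual lag-1 autocorrelation is pooled over the
    mask and a Cochrane-Orcutt transform (row differencing with the pooled
    rho, dropping the first row) is applied before refitting.
    """
    X = design.matrix
    n, p = X.shape
    rank = np.linalg.matrix_rank(X)
    if rank < p:
        # name the collinear columns for the error message
        _, r = np.linalg.qr(X)
        bad = [design.names[j] for j in range(p) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")

    spatial_shape = series.shape[:-1]
    Y = series.reshape(-1, n).T  # (time, voxels)
    mask_flat = Y.std(axis=0) > 0

    beta, resid = _ols(X, Y)
    rho = 0.0
    if whiten == "ar1":
        r = resid[:, mask_flat]
        if r.size:
            num = np.sum(r[1:] * r[:-1])
            den = np.sum(r**2)
            r_obs = float(num / den) if den > 0 else 0.0
            rho = _match_ar1_rho(X, r_obs)
        Xw = X[1:] - rho * X[:-1]
        Yw = Y[1:] - rho * Y[:-1]
        beta, resid = _ols(Xw, Yw)
        df = Xw.shape[0] - rank
        xtx_inv = np.linalg.pinv(Xw.T @ Xw)
    elif whiten == "none":
        df = n - rank
        xtx_inv = np.linalg.pinv(X.T @ X)
    else:
        raise ValueError(f"unknown whitening {whiten!r}")

    sigma2 = np.sum(resid**2, axis=0) / df
    return GLMFit(
        beta=beta.T.reshape(spatial_shape + (p,)),
        sigma2=sigma2.reshape(spatial_shape),
        df=df,
        ar1_rho=rho,
        xtx_inv=xtx_inv,
        design=design,
        mask=mask_flat.reshape(spatial_shape),
    )


#: Named contrasts over the condition regressors (deviant, novel, silent).
#: Standard tones / rest are the implicit baseline, so "> all" contrasts
#: compare against zero without the silent regressor.
CONTRAST_PRESETS: dict[str, dict[str, float]] = {
    "dev+nov>silent": {"deviant": 1.0, "novel": 1.0, "silent": -2.0},
    "dev+nov>all": {"deviant": 1.0, "novel": 1.0},
    "nov>dev": {"novel": 1.0, "deviant": -1.0},
    "dev>nov": {"deviant": 1.0, "novel": -1.0},
    "nov>all": {"novel": 1.0},
    "dev>all": {"deviant": 1.0},
}


def contrast_vector(fit_or_design, name_or_weights) -> np.ndarray:
    """Resolve a preset name or {regressor: weight} dict to a weight vector."""
    design = fit_or_design.design if isinstance(fit_or_design, GLMFit) else fit_or_design
    if isinstance(name_or_weights, str):
        weights = CONTRAST_PRESETS[name_or_weights]
    else:
        weights = dict(name_or_weights)
    c = np.zeros(len(design.names))
    for k, v in weights.items():
        c[design.names.index(k)] = v
    return c


def contrast_tmap(fit: GLMFit, c) -> np.ndarray:
    """T statistic map for contrast ``c`` (vector, preset name, or dict).

    T = c'beta / sqrt(sigma2 * c'(X'X)^-1 c); voxels with zero variance are
    returned as NaN (masked).
    """
    if isinstance(c, (str, dict)):
        c = contrast_vector(fit, c)
    c = np.asarray(c, dtype=float)
    if c.shape[0] != fit.beta.shape[-1]:
        raise ValueError("contrast length does not match regressor count")
    if not np.any(c):
        raise ValueError("all-zero contrast")
    eff = fit.beta @ c
    var = fit.sigma2 * float(c @ fit.xtx_inv @ c)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, eff / np.sqrt(var), np.nan)
    return t


def contrast_effect(fit: GLMFit, c) -> np.ndarray:
    """Contrast effect map c'beta (for group-level analysis)."""
    if isinstance(c, (str, dict)):
        c = contrast_vector(fit, c)
    return fit.beta @ np.asarray(c, dtype=float)


def _one_sample_t(maps: np.ndarray) -> np.ndarray:
    """One-sample t over axis 0; zero-variance voxels -> NaN."""
    n = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.nan)
    return t


def group_ttest(maps: np.ndarray) -> np.ndarray:
    """One-sample group t map over subjects (axis 0), df = n - 1."""
    maps = np.asarray(maps, dtype=float)
    if maps.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return _one_sample_t(maps)


def paired_group_ttest(maps_a: np.ndarray, maps_b: np.ndarray) -> np.ndarray:
    """Paired t map: one-sample t on a-b differences."""
    maps_a, maps_b = np.asarray(maps_a, float), np.asarray(maps_b, float)
    if maps_a.shape != maps_b.shape:
        raise ValueError("paired map stacks must have identical shape")
    if maps_a.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return _one_sample_t(maps_a - maps_b)


def cluster_inference(
    maps: np.ndarray,
    cluster_forming_p: float = 0.001,
    n_perm: int = 1000,
    seed: int = 0,
    mask: np.ndarray | None = None,
) -> pd.DataFrame:
    """Sign-flip permutation cluster inference on subject contrast maps.

    ``maps`` is (subjects, x, y, z).  Clusters are 6-connected components
    of the one-sided group t map above the t threshold for
    ``cluster_forming_p``; the corrected p of each cluster is the
    proportion of sign-flip permutations whose maximum cluster size is at
    least the observed size (with the +1 correction including the identity
    permutation).
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    maps = np.asarray(maps, dtype=float)
    n = maps.shape[0]
    df = n - 1
    t_thresh = stats.t.ppf(1.0 - cluster_forming_p, df)
    structure = ndimage.generate_binary_structure(3, 1)  # 6-connectivity

    def _clusters(tmap):
        supra = np.nan_to_num(tmap, nan=-np.inf) > t_thresh
        if mask is not None:
            supra &= mask
        labels, n_lab = ndimage.label(supra, structure=structure)
        return labels, n_lab

    t_obs = _one_sample_t(maps)
    labels, n_lab = _clusters(t_obs)
    if n_lab == 0:
        return pd.DataFrame(
            columns=["peak_voxel", "size", "peak_t", "p_corrected"]
        )
    sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n_lab + 1))

    rng = np.random.default_rng(seed)
    max_null = np.zeros(n_perm)
    for i in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=n)
        t_perm = _one_sample_t(maps * signs[:, None, None, None])
        lab_p, n_p = _clusters(t_perm)
        if n_p:
            max_null[i] = ndimage.sum_labels(
                np.ones_like(lab_p), lab_p, range(1, n_p + 1)
            ).max()

    rows = []
    t_filled = np.nan_to_num(t_obs, nan=-np.inf)
    for lab in range(1, n_lab + 1):
        in_cluster = labels == lab
        size = int(sizes[lab - 1])
        peak_flat = np.argmax(np.where(in_cluster, t_filled, -np.inf))
        peak = np.unravel_index(peak_flat, t_obs.shape)
        p_corr = (1 + np.sum(max_null >= size)) / (n_perm + 1)
        rows.append(
            {
                "peak_voxel": tuple(int(v) for v in peak),
                "size": size,
                "peak_t": float(t_filled[peak]),
                "p_corrected": float(p_corr),
            }
        )
    out = pd.DataFrame(rows).sort_values("size", ascending=False, ignore_index=True)
    return out


def percent_signal_change(
    fit: GLMFit, roi: np.ndarray, condition: str, microtime: int = 16
) -> float:
    """Percent signal change for a condition, averaged over an ROI.

    PSC = 100 * beta_condition * h_peak / beta_constant, where h_peak is
    the maximum of a single isolated zero-duration event regressor built
    at microtime resolution dt = TR/16.  Voxels with nonpositive baseline
    are excluded.
    """
    design = fit.design
    if condition not in design.names:
        raise ValueError(f"no condition {condition!r} in design")
    dt = design.TR / microtime
    h_peak = float(canonical_hrf(dt).max())  # single event at microtime
    b_cond = fit.beta[..., design.names.index(condition)]
    b_const = fit.beta[..., design.names.index("constant")]
    roi = np.asarray(roi, bool)
    ok = roi & (b_const > 0)
    if not np.any(ok):
        raise ValueError("no ROI voxels with positive baseline")
    psc = 100.0 * b_cond[ok] * h_peak / b_const[ok]
    return float(psc.mean())
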