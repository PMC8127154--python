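"""Density-compensated nearest-neighbour gridding reconstruction.

Each non-Cartesian sample is deposited on its nearest Cartesian k-grid
node; a node's value is the density-weighted mean of its contributing
samples (which makes a fully sampled noiseless acquisition exactly
invertible under the matching forward model), unvisited nodes are zero,
and the image is the magnitude of the centered inverse FFT.  Radial
density compensation weights samples by max(|k|, dk/2)^2, normalized to
unit mean, correcting the oversampled k-space centre.
"""

from __future__ import annotations

import numpy as np

from .acquisition import KSpaceSeries, Trajectory, centered_ifft

__all__ = [
    "density_weights",
    "grid_reconstruct",
    "merge_center_reacquisition",
]


def density_weights(traj: Trajectory) -> np.ndarray:
    """Per-sample radial density-compensation weights, mean 1.

    weight = max(|k|, dk/2)^2 with dk the radial sample spacing; the
    clamp keeps the centre sample's weight positive.
    """
    if traj.n_spokes == 0:
        raise ValueError("empty trajectory")
    radii = traj.sample_radii()
    dk = radii[1] - radii[0] if traj.samples_per_spoke > 1 else traj.k_max
    w = np.maximum(radii, dk / 2.0) ** 2
    w = np.broadcast_to(w, (traj.n_spokes, traj.samples_per_spoke)).copy()
    return w / w.mean()


def merge_center_reacquisition(k: KSpaceSeries) -> KSpaceSeries:
    """Fill dead-time gaps of the echo-0 spokes from the reacquired pass."""
    traj = k.trajectory
    dead = traj.dead_samples
    if dead == 0:
        return k
    if k.reacquired_center is None:
        raise ValueError("dead_samples > 0 but no reacquired centre data")
    fid = np.where(traj.echo == 0)[0]
    samples = k.samples.copy()
    samples[:, fid, :dead] = k.reacquired_center
    return KSpaceSeries(
        samples=samples,
        trajectory=traj,
        TEs=k.TEs,
        reacquired_center=k.reacquired_center,
        grid_shape=k.grid_shape,
    )


def grid_reconstruct(
    k: KSpaceSeries,
    weights: np.ndarray | None = None,
    grid_shape=None,
    merge_reacquisition: bool = True,
) -> list[np.ndarray]:
    """Reconstruct per-echo magnitude series from radial k-space.

    Returns one (x, y, z, t) array per echo.  Dead-time centre gaps are
    merged from the reacquisition pass first (when present), then for
    every volume and echo the weighted samples are accumulated onto their
    nearest grid nodes, node values are weighted means, and the magnitude
    of the centered inverse FFT is taken.
    """
    traj = k.trajectory
    if grid_shape is None:
        grid_shape = k.grid_shape
    if grid_shape is None:
        raise ValueError("grid_shape required")
    grid_shape = tuple(grid_shape)
    if weights is None:
        weights = density_weights(traj)
    if merge_reacquisition and traj.dead_samples > 0:
        k = merge_center_reacquisition(k)

    nodes = traj.nearest_nodes(grid_shape)
    flat_nodes = np.ravel_multi_index(
        (nodes[..., 0], nodes[..., 1], nodes[..., 2]), grid_shape
    )
    n_nodes = int(np.prod(grid_shape))
    out = []
    for e in range(traj.n_echoes):
        sp = traj.echo == e
        if not np.any(sp):
            raise ValueError(f"echo {e} has zero spokes")
        idx = flat_nodes[sp].ravel()
        w = weights[sp].ravel()
        wsum = np.bincount(idx, weights=w, minlength=n_nodes)
        vols = np.empty(grid_shape + (k.n_volumes,))
        for t in range(k.n_volumes):
            s = k.samples[t, sp, :].ravel()
            num = (
                np.bincount(idx, weights=w * s.real, minlength=n_nodes)
                + 1j * np.bincount(idx, weights=w * s.imag, minlength=n_nodes)
            )
            grid = np.zeros(n_nodes, dtype=complex)
            hit = wsum > 0
            grid[hit] = num[hit] / wsum[hit]
            vols[..., t] = np.abs(centered_ifft(grid.reshape(grid_shape)))
        out.append(vols)
    return out


def grid_reconstruct_complex(
    k: KSpaceSeries, weights=None, grid_shape=None, merge_reacquisition=True
) -> list[np.ndarray]:
    """As :func:`grid_reconstruct` but returning complex images (no
    magnitude step); used for linearity checks."""
    traj = k.trajectory
    if grid_shape is None:
        grid_shape = k.grid_shape
    grid_shape = tuple(grid_shape)
    if weights is None:
        weights = density_weights(traj)
    if merge_reacquisition and traj.dead_samples > 0:
        k = merge_center_reacquisition(k)
    nodes = traj.nearest_nodes(grid_shape)
    flat_nodes = np.ravel_multi_index(
        (nodes[..., 0], nodes[..., 1], nodes[..., 2]), grid_shape
    )
    n_nodes = int(np.prod(grid_shape))
    out = []
    for e in range(traj.n_echoes):
        sp = traj.echo == e
        idx = flat_nodes[sp].ravel()
        w = weights[sp].ravel()
        wsum = np.bincount(idx, weights=w, minlength=n_nodes)
        vols = np.empty(grid_shape + (k.n_volumes,), dtype=complex)
        for t in range(k.n_volumes):
            s = k.samples[t, sp, :].ravel()
            num = (
                np.bincount(idx, weights=w * s.real, minlength=n_nodes)
                + 1j * np.bincount(idx, weights=w * s.imag, minlength=n_nodes)
            )
            grid = np.zeros(n_nodes, dtype=complex)
            hit = wsum > 0
            grid[hit] = num[hit] / wsum[hit]
            vols[..., t] = centered_ifft(grid.reshape(grid_shape))
        out.append(vols)
    return out
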