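"""Acquisition simulators for the two arms of the study.

The near-silent arm is a segmented 3D radial multi-echo sampler: spokes
are grouped into loops (one loop per echo) and loops into segments; each
segment's loop lies on a great circle with a segment-specific pole, and
successive loops of a segment revisit the same circle so that the echo
index equals the loop index.  The free-induction-decay (echo 0) spokes
lose their first few centre samples to receiver dead-time; those nodes
are reacquired in a separate pass and merged during reconstruction.

The forward model evaluates the object's centered discrete Fourier
transform at the nearest Cartesian k-grid node of each trajectory sample,
which makes nearest-neighbour gridding an exact inverse on a fully
sampled trajectory.  The conventional arm is a simplified single-echo
EPI-like sampler working directly in image space with polynomial drift
and AR(1) noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "make_trajectory",
    "KSpaceSeries",
    "sample_kspace",
    "simulate_epi_series",
    "centered_fft",
    "centered_ifft",
    "LS_SCAN_DEFAULTS",
    "EPI_SCAN_DEFAULTS",
]

#: Published scan parameters for the two arms.
LS_SCAN_DEFAULTS = {
    "TEs": [0.0, 0.0161, 0.0322],
    "TR": 2.648,
    "n_volumes": 240,
    "spokes_per_loop": 24,
    "n_segments": 15,
}
EPI_SCAN_DEFAULTS = {"TE": 0.0275, "TR": 2.5, "n_volumes": 240}


def centered_fft(vol: np.ndarray) -> np.ndarray:
    """Centered DFT: DC at index floor(N/2) on each axis."""
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(vol)))


def centered_ifft(k: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(k)))


@dataclass
class Trajectory:
    directions: np.ndarray        # (n_spokes, 3) unit vectors
    segment: np.ndarray           # (n_spokes,) int labels
    loop: np.ndarray              # loop index within segment
    echo: np.ndarray              # echo index (= loop index)
    within_loop: np.ndarray       # spoke index within loop
    samples_per_spoke: int
    k_max: float                  # cycles/mm
    ordering: np.ndarray          # (n_volumes_hint or 1, n_segments) permutations
    dead_samples: int = 2
    nominal_resolution: float = 4.0  # mm
    points: np.ndarray | None = None  # explicit k-space points, overrides radial

    @property
    def n_spokes(self) -> int:
        return self.directions.shape[0]

    @property
    def n_echoes(self) -> int:
        return int(self.echo.max()) + 1

    def sample_radii(self) -> np.ndarray:
        """|k| of each sample along a spoke, from 0 to k_max (cycles/mm)."""
        return np.linspace(0.0, self.k_max, self.samples_per_spoke)

    def kspace_points(self) -> np.ndarray:
        """(n_spokes, samples_per_spoke, 3) k-space coordinates, cycles/mm."""
        if self.points is not None:
            return self.points
        return self.directions[:, None, :] * self.sample_radii()[None, :, None]

    def nearest_nodes(self, grid_shape) -> np.ndarray:
        """Nearest Cartesian node index of every sample for the given grid.

        Grid spacing is dk = 2*k_max/N per axis so the spoke tips land on
        the grid edge; DC sits at index floor(N/2).
        """
        grid_shape = np.asarray(grid_shape)
        dk = 2.0 * self.k_max / grid_shape
        pts = self.kspace_points()  # cycles/mm
        idx = np.round(pts / dk[None, None, :]).astype(int) + grid_shape // 2
        return np.clip(idx, 0, grid_shape - 1)


def make_trajectory(
    spokes_per_loop: int = 24,
    n_echoes: int = 3,
    n_segments: int = 15,
    samples_per_spoke: int = 17,
    nominal_resolution: float = 4.0,
    seed: int = 0,
    n_volumes_hint: int = 1,
    dead_samples: int = 2,
) -> Trajectory:
    """Build the looping segmented radial trajectory.

    Each segment has ``n_echoes`` loops of ``spokes_per_loop`` spokes:
    spokes_per_segment = spokes_per_loop * n_echoes, and the published
    configuration (24, 3, 15) yields 72 spokes per segment and 1080 per
    volume.  Loop spokes are equally spaced on a great circle whose pole
    is segment-specific (Fibonacci-distributed poles, randomly rotated
    under ``seed``); the per-volume segment ordering is a pseudo-random
    permutation.  Equally spaced points on a circle sum to zero, so the
    mean spoke direction vanishes and coverage is near-uniform.
    """
    if min(spokes_per_loop, n_echoes, n_segments, samples_per_spoke) < 1:
        raise ValueError("all trajectory counts must be >= 1")
    if nominal_resolution <= 0:
        raise ValueError("nominal_resolution must be positive")
    rng = np.random.default_rng(seed)

    # segment poles: Fibonacci sphere for even coverage, random global rotation
    i = np.arange(n_segments) + 0.5
    phi = np.pi * (1 + 5**0.5) * i
    z = 1 - 2 * i / n_segments
    rho = np.sqrt(np.maximum(0.0, 1 - z**2))
    poles = np.column_stack([rho * np.cos(phi), rho * np.sin(phi), z])
    # random rotation from QR of a Gaussian matrix
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    poles = poles @ q.T

    dirs, seg_l, loop_l, echo_l, within_l = [], [], [], [], []
    for s in range(n_segments):
        pole = poles[s]
        # orthonormal frame spanning the great circle with this pole
        a = np.array([1.0, 0.0, 0.0])
        if abs(pole @ a) > 0.9:
            a = np.array([0.0, 1.0, 0.0])
        u = np.cross(pole, a)
        u /= np.linalg.norm(u)
        v = np.cross(pole, u)
        phase = rng.uniform(0, 2 * np.pi)
        for loop in range(n_echoes):
            ang = phase + 2 * np.pi * np.arange(spokes_per_loop) / spokes_per_loop
            pts = np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v)
            dirs.append(pts)
            seg_l.append(np.full(spokes_per_loop, s))
            loop_l.append(np.full(spokes_per_loop, loop))
            echo_l.append(np.full(spokes_per_loop, loop))  # echo = loop index
            within_l.append(np.arange(spokes_per_loop))

    directions = np.vstack(dirs)
    directions /= np.linalg.norm(directions, axis=1, keepdims=True)
    ordering = np.array(
        [rng.permutation(n_segments) for _ in range(max(1, n_volumes_hint))]
    )
    return Trajectory(
        directions=directions,
        segment=np.concatenate(seg_l),
        loop=np.concatenate(loop_l),
        echo=np.concatenate(echo_l),
        within_loop=np.concatenate(within_l),
        samples_per_spoke=samples_per_spoke,
        k_max=1.0 / (2.0 * nominal_resolution),
        ordering=ordering,
        dead_samples=dead_samples,
        nominal_resolution=nominal_resolution,
    )


@dataclass
class KSpaceSeries:
    samples: np.ndarray            # (n_volumes, n_spokes, samples_per_spoke) complex
    trajectory: Trajectory
    TEs: list[float]
    reacquired_center: np.ndarray | None = None  # (n_volumes, n_fid_spokes, dead)
    grid_shape: tuple[int, int, int] | None = None

    @property
    def n_volumes(self) -> int:
        return self.samples.shape[0]


def sample_kspace(
    ideal,
    traj: Trajectory,
    noise_sd: float = 0.0,
    interference_amp: float = 0.0,
    seed: int = 0,
    grid_shape=None,
) -> KSpaceSeries:
    """Sample the ideal series along the trajectory.

    For each volume and echo, the echo volume's centered DFT is evaluated
    at the nearest grid node of every trajectory sample and complex white
    noise of standard deviation ``noise_sd`` (per real/imag component,
    scaled by 1/sqrt(2) so the complex magnitude variance is noise_sd^2)
    is added.  With ``interference_amp > 0`` each sample additionally
    receives ``interference_amp`` times the conjugate of its time-reversed
    partner spoke's sample (echo-in/echo-out interference).  Dead-time
    centre samples of the echo-0 spokes are removed and delivered as an
    independently noisy reacquisition pass.
    """
    if len(ideal.TEs) != traj.n_echoes:
        raise ValueError(
            f"ideal series has {len(ideal.TEs)} echoes, trajectory {traj.n_echoes}"
        )
    if grid_shape is None:
        grid_shape = ideal.phantom.labels.shape
    rng = np.random.default_rng(seed)
    n_vols = ideal.n_volumes
    nodes = traj.nearest_nodes(grid_shape)  # (spokes, samples, 3)
    flat_nodes = np.ravel_multi_index(
        (nodes[..., 0], nodes[..., 1], nodes[..., 2]), grid_shape
    )

    samples = np.zeros((n_vols, traj.n_spokes, traj.samples_per_spoke), dtype=complex)
    for t in range(n_vols):
        for e in range(traj.n_echoes):
            vol = ideal.echo_volume(e, t)
            F = centered_fft(vol).ravel()
            sp = traj.echo == e
            samples[t, sp, :] = F[flat_nodes[sp]]

    if interference_amp > 0:
        # partner of a spoke is the same loop traversed in reverse:
        # reverse the within-loop order and conjugate
        partner = np.arange(traj.n_spokes)
        for s in range(int(traj.segment.max()) + 1):
            for l in range(int(traj.loop.max()) + 1):
                sel = np.where((traj.segment == s) & (traj.loop == l))[0]
                partner[sel] = sel[::-1]
        samples = samples + interference_amp * np.conj(samples[:, partner, :])

    if noise_sd > 0:
        s = noise_sd / np.sqrt(2.0)
        samples += rng.normal(0, s, samples.shape) + 1j * rng.normal(0, s, samples.shape)

    reacq = None
    dead = traj.dead_samples
    if dead > 0:
        fid = np.where(traj.echo == 0)[0]
        reacq = np.zeros((n_vols, fid.size, dead), dtype=complex)
        for t in range(n_vols):
            vol = ideal.echo_volume(0, t)
            F = centered_fft(vol).ravel()
            reacq[t] = F[flat_nodes[fid, :dead]]
        if noise_sd > 0:
            s = noise_sd / np.sqrt(2.0)
            reacq += rng.normal(0, s, reacq.shape) + 1j * rng.normal(0, s, reacq.shape)
        samples[:, fid, :dead] = 0.0  # dead-time: receiver not yet open

    return KSpaceSeries(
        samples=samples,
        trajectory=traj,
        TEs=list(ideal.TEs),
        reacquired_center=reacq,
        grid_shape=tuple(grid_shape),
    )


def full_cartesian_trajectory(
    grid_shape, nominal_resolution: float = 4.0, n_echoes: int = 1
) -> Trajectory:
    """A trajectory visiting every Cartesian node exactly once per echo.

    Used to validate the forward/adjoint pair: under the nearest-node
    forward model, gridding reconstruction of a fully sampled noiseless
    acquisition recovers the object exactly.  Each "spoke" is one x-row
    of the grid, repeated per echo.
    """
    grid_shape = tuple(grid_shape)
    nx, ny, nz = grid_shape
    k_max = 1.0 / (2.0 * nominal_resolution)
    dk = 2.0 * k_max / np.asarray(grid_shape)
    centers = np.asarray(grid_shape) // 2
    rows = []
    for y in range(ny):
        for z in range(nz):
            x = np.arange(nx)
            pts = np.column_stack(
                [
                    (x - centers[0]) * dk[0],
                    np.full(nx, (y - centers[1]) * dk[1]),
                    np.full(nx, (z - centers[2]) * dk[2]),
                ]
            )
            rows.append(pts)
    pts_one_echo = np.stack(rows)  # (ny*nz, nx, 3)
    points = np.tile(pts_one_echo, (n_echoes, 1, 1))
    n_rows = ny * nz
    n_spokes = n_rows * n_echoes
    echo = np.repeat(np.arange(n_echoes), n_rows)
    return Trajectory(
        directions=np.tile(np.array([[1.0, 0.0, 0.0]]), (n_spokes, 1)),
        segment=np.zeros(n_spokes, dtype=int),
        loop=echo.copy(),
        echo=echo,
        within_loop=np.tile(np.arange(n_rows), n_echoes),
        samples_per_spoke=nx,
        k_max=k_max,
        ordering=np.zeros((1, 1), dtype=int),
        dead_samples=0,
        nominal_resolution=nominal_resolution,
        points=points,
    )


def ar1_noise(rng, shape, rho: float, sd: float) -> np.ndarray:
    """AR(1) Gaussian noise along the last axis with stationary sd ``sd``."""
    innov_sd = sd * np.sqrt(1.0 - rho**2)
    eps = rng.normal(0.0, innov_sd, shape)
    out = np.empty(shape)
    out[..., 0] = rng.normal(0.0, sd, shape[:-1])
    for t in range(1, shape[-1]):
        out[..., t] = rho * out[..., t - 1] + eps[..., t]
    return out


def simulate_epi_series(
    ideal,
    noise_sd: float = 0.0,
    drift_coeffs=(),
    ar1_rho: float = 0.0,
    seed: int = 0,
    echo: int = 0,
) -> np.ndarray:
    """EPI-like arm: ideal image series + polynomial drift + AR(1) noise.

    ``drift_coeffs`` are coefficients of the Legendre drift polynomials
    P1, P2, ... in normalized time on [-1, 1], in signal units, added to
    every in-brain voxel.  Legendre polynomials above order 0 are
    (near-)zero-mean, so drift shifts the temporal variance structure
    without re-scaling the baseline signal.  Noise is voxel-wise AR(1)
    with stationary standard deviation ``noise_sd`` and lag-1 correlation
    ``ar1_rho``.
    """
    if not (0.0 <= ar1_rho < 1.0):
        raise ValueError("ar1_rho must be in [0, 1)")
    rng = np.random.default_rng(seed)
    series = ideal.echo_series(echo).copy()
    n = series.shape[-1]
    if len(drift_coeffs):
        from numpy.polynomial import legendre

        tn = np.linspace(-1.0, 1.0, n)
        drift = legendre.legval(tn, np.concatenate([[0.0], drift_coeffs]))
        series += ideal.phantom.brain_mask[..., None] * drift[None, None, None, :]
    if noise_sd > 0:
        series += ar1_noise(rng, series.shape, ar1_rho, noise_sd)
    return series
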