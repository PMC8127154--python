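"""Digital head phantom and TE-dependent BOLD signal model.

The phantom is a labelled 3D grid (grey matter, white matter, CSF,
background) with per-tissue proton density and R2* (=1/T2*), plus an
auditory and a motor region of interest carved inside grey matter.  The
dynamic signal model is a mono-exponential decay whose rate is modulated
by task activity:

    S(voxel, TE, t) = PD * exp(-TE * (R2* + dR2*(voxel, t)))

with dR2*(t) = peak amplitude x (HRF convolved with the condition onset
stream).  Negative dR2* raises the signal: a sustained dR2* of -0.3 1/s
at TE = 32.2 ms gives a fractional change of exp(0.0322*0.3)-1, about 1%,
and the TE = 0 free-induction-decay channel carries no task contrast at
all.  Cohorts add subject- and session-level multiplicative amplitude
variation with known variance components, so the ground-truth
test-retest ICC of the amplitudes is sigma_subject^2 /
(sigma_subject^2 + sigma_session^2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .glm import canonical_hrf

__all__ = [
    "PhantomSpec",
    "Phantom",
    "build_phantom",
    "IdealSeries",
    "simulate_bold_series",
    "CohortSpec",
    "simulate_cohort",
    "DEFAULT_TISSUE_PARAMS",
    "DEFAULT_ACTIVATION",
]

LABELS = {"background": 0, "gm": 1, "wm": 2, "csf": 3}
ROI_LABELS = {"auditory_roi": 4, "motor_roi": 5}

# plausible 3 T values; T2* in seconds -> R2* in 1/s
DEFAULT_TISSUE_PARAMS = {
    "background": {"proton_density": 0.0, "r2star": 0.0},
    "gm": {"proton_density": 100.0, "r2star": 1.0 / 0.066},
    "wm": {"proton_density": 80.0, "r2star": 1.0 / 0.053},
    "csf": {"proton_density": 120.0, "r2star": 1.0 / 0.150},
}

# peak dR2* (1/s) per (roi, condition); negative = BOLD signal increase.
# Auditory cortex responds to every tone; the button press (motor) follows
# the rare Deviant/Novel tones only.
DEFAULT_ACTIVATION = {
    ("auditory_roi", "standard"): -0.10,
    ("auditory_roi", "deviant"): -0.22,
    ("auditory_roi", "novel"): -0.28,
    ("motor_roi", "deviant"): -0.18,
    ("motor_roi", "novel"): -0.18,
}


@dataclass
class PhantomSpec:
    grid_shape: tuple[int, int, int] = (32, 32, 32)
    voxel_size: float = 4.0  # mm
    tissue_params: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_TISSUE_PARAMS.items()
    })
    activation_table: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVATION))
    roi_radius_fraction: float = 0.09   # ROI sphere radius / grid extent

    def validate(self) -> None:
        if min(self.grid_shape) < 16:
            raise ValueError("grid_shape must be >= 16 per axis")
        for name, p in self.tissue_params.items():
            if name != "background" and p["r2star"] <= 0:
                raise ValueError(f"R2* must be positive for {name}")
        if self.tissue_params["background"]["proton_density"] != 0:
            raise ValueError("background proton density must be 0")


@dataclass
class Phantom:
    spec: PhantomSpec
    labels: np.ndarray      # int volume, LABELS/ROI_LABELS codes
    pd_map: np.ndarray
    r2star_map: np.ndarray

    def roi_mask(self, roi: str) -> np.ndarray:
        return self.labels == ROI_LABELS[roi]

    @property
    def gm_mask(self) -> np.ndarray:
        # ROI voxels are grey matter with activation
        return (self.labels == LABELS["gm"]) | (self.labels >= 4)

    @property
    def brain_mask(self) -> np.ndarray:
        return self.labels > 0


def _ellipsoid(shape, center, semi):
    idx = np.indices(shape).astype(float)
    d = sum(((idx[a] - center[a]) / semi[a]) ** 2 for a in range(3))
    return d <= 1.0


def build_phantom(spec: PhantomSpec | None = None) -> Phantom:
    """Construct the labelled phantom with PD and R2* maps.

    Geometry: an outer CSF ellipsoid, a grey-matter shell, a white-matter
    core; the auditory ROI is a bilateral pair of spheres in temporal grey
    matter, the motor ROI a superior sphere.  Raises if an ROI would fall
    outside grey matter.
    """
    if spec is None:
        spec = PhantomSpec()
    spec.validate()
    shape = tuple(spec.grid_shape)
    c = tuple((s - 1) / 2.0 for s in shape)
    ext = min(shape)

    head = _ellipsoid(shape, c, tuple(0.45 * s for s in shape))
    gm_outer = _ellipsoid(shape, c, tuple(0.40 * s for s in shape))
    wm = _ellipsoid(shape, c, tuple(0.26 * s for s in shape))

    labels = np.zeros(shape, dtype=np.int16)
    labels[head] = LABELS["csf"]
    labels[gm_outer] = LABELS["gm"]
    labels[wm] = LABELS["wm"]

    gm = labels == LABELS["gm"]
    r = max(2.0, spec.roi_radius_fraction * ext)
    # bilateral auditory spheres in the lateral gm band, motor superior
    aud_centers = [
        (c[0] - 0.33 * shape[0], c[1], c[2]),
        (c[0] + 0.33 * shape[0], c[1], c[2]),
    ]
    mot_center = (c[0], c[1], c[2] + 0.33 * shape[2])
    idx = np.indices(shape).astype(float)

    def sphere(center):
        d2 = sum((idx[a] - center[a]) ** 2 for a in range(3))
        return d2 <= r**2

    aud = (sphere(aud_centers[0]) | sphere(aud_centers[1])) & gm
    mot = sphere(mot_center) & gm
    for name, mask in (("auditory_roi", aud), ("motor_roi", mot)):
        if not mask.any():
            raise ValueError(f"{name} falls outside grey matter")
    if (aud & mot).any():
        raise ValueError("auditory and motor ROIs overlap")
    labels[aud] = ROI_LABELS["auditory_roi"]
    labels[mot] = ROI_LABELS["motor_roi"]

    pd_map = np.zeros(shape)
    r2_map = np.zeros(shape)
    for name, code in LABELS.items():
        p = spec.tissue_params[name]
        pd_map[labels == code] = p["proton_density"]
        r2_map[labels == code] = p["r2star"]
    gm_p = spec.tissue_params["gm"]
    for code in ROI_LABELS.values():
        pd_map[labels == code] = gm_p["proton_density"]
        r2_map[labels == code] = gm_p["r2star"]
    return Phantom(spec=spec, labels=labels, pd_map=pd_map, r2star_map=r2_map)


@dataclass
class IdealSeries:
    """Noise-free multi-echo series in factored form.

    dR2*(voxel, t) = sum_c amp_maps[c](voxel) * timecourses[c](t); echo
    volumes are materialized on demand via :meth:`echo_series`.
    """

    phantom: Phantom
    TEs: list[float]          # seconds
    TR: float
    n_volumes: int
    amp_maps: list[np.ndarray]
    timecourses: list[np.ndarray]

    def delta_r2star(self) -> np.ndarray:
        """Full (x, y, z, t) dR2* array."""
        shape = self.phantom.labels.shape + (self.n_volumes,)
        d = np.zeros(shape)
        for amp, tc in zip(self.amp_maps, self.timecourses):
            d += amp[..., None] * tc[None, None, None, :]
        return d

    def echo_series(self, echo: int) -> np.ndarray:
        """(x, y, z, t) signal at TEs[echo]."""
        te = self.TEs[echo]
        base = self.phantom.pd_map * np.exp(-te * self.phantom.r2star_map)
        if te == 0 or not self.amp_maps:
            return np.repeat(base[..., None], self.n_volumes, axis=-1)
        return base[..., None] * np.exp(-te * self.delta_r2star())

    def echo_volume(self, echo: int, t: int) -> np.ndarray:
        te = self.TEs[echo]
        base = self.phantom.pd_map * np.exp(-te * self.phantom.r2star_map)
        if te == 0 or not self.amp_maps:
            return base
        d = np.zeros_like(base)
        for amp, tc in zip(self.amp_maps, self.timecourses):
            d += amp * tc[t]
        return base * np.exp(-te * d)


def _condition_timecourse(schedule, condition, TR, n_volumes, dt=0.1):
    """Unit-peak HRF response to the condition's onsets, sampled at the TR grid."""
    onsets = schedule.onsets(condition)
    n_fine = int(np.ceil(n_volumes * TR / dt)) + 1
    stream = np.zeros(n_fine)
    for onset in onsets:
        i = int(round(onset / dt))
        if i < n_fine:
            stream[i] += 1.0
    h = canonical_hrf(dt)
    conv = np.convolve(stream, h)[:n_fine]
    sample_idx = np.round(np.arange(n_volumes) * TR / dt).astype(int)
    return conv[sample_idx]


def simulate_bold_series(
    phantom: Phantom,
    schedule,
    TR: float,
    TEs,
    n_volumes: int,
    activation_table: dict | None = None,
    amplitude_scale: float = 1.0,
    dt: float = 0.1,
) -> IdealSeries:
    """Drive the phantom with a schedule to produce an ideal multi-echo series.

    Each (roi, condition) entry of ``activation_table`` contributes
    ``amplitude_scale * peak_dR2*`` times the unit-peak HRF response to
    that condition's onsets, restricted to the ROI.
    """
    TEs = list(TEs)
    if not TEs:
        raise ValueError("TE list must be nonempty")
    if schedule.duration() < TR * n_volumes - 1e-6:
        raise ValueError("schedule shorter than the scan")
    if activation_table is None:
        activation_table = phantom.spec.activation_table

    conditions = sorted({cond for (_, cond) in activation_table})
    tcs = {c: _condition_timecourse(schedule, c, TR, n_volumes, dt=dt) for c in conditions}

    amp_maps, timecourses = [], []
    for (roi, cond), amp in activation_table.items():
        if amp == 0:
            continue
        amp_maps.append(amplitude_scale * amp * phantom.roi_mask(roi).astype(float))
        timecourses.append(tcs[cond])
    return IdealSeries(
        phantom=phantom,
        TEs=TEs,
        TR=TR,
        n_volumes=n_volumes,
        amp_maps=amp_maps,
        timecourses=timecourses,
    )


@dataclass
class CohortSpec:
    """Study cohort: 12 subjects scanned in 2 sessions by default."""

    n_subjects: int = 12
    n_sessions: int = 2
    subject_amp_sd: float = 0.25   # fraction of mean activation amplitude
    session_amp_sd: float = 0.25
    noise_sd: float = 1.0          # image-space / k-space thermal noise, a.u.
    drift_coeffs: tuple = (0.5, 0.3)
    ar1_rho: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("need >= 2 subjects")
        if not (0 <= self.ar1_rho < 1):
            raise ValueError("ar1_rho must be in [0, 1)")

    @property
    def true_icc(self) -> float:
        """Analytic ICC of the activation amplitudes."""
        s2, e2 = self.subject_amp_sd**2, self.session_amp_sd**2
        return s2 / (s2 + e2) if (s2 + e2) > 0 else float("nan")


def simulate_cohort(
    phantom: Phantom,
    cohort: CohortSpec,
    schedule_factory,
    TR: float,
    TEs,
    n_volumes: int,
) -> tuple[dict, dict]:
    """Generate per-subject/session ideal series and a truth manifest.

    Subject amplitude factors are drawn once per subject and shared across
    sessions; independent session perturbations are added per session, so
    the amplitude multiplier for (subject i, session j) is
    1 + a_i + e_ij with a_i ~ N(0, subject_amp_sd^2) and
    e_ij ~ N(0, session_amp_sd^2).  ``schedule_factory(subject, session)``
    supplies the run's schedule (sessions use distinct schedules, as rerun
    randomized paradigms would).

    Returns ``(series, manifest)``: ``series[(i, j)]`` is an
    :class:`IdealSeries`; the manifest records every drawn value and the
    analytic ground-truth ICC.
    """
    cohort.validate()
    rng = np.random.default_rng(cohort.seed)
    subject_effects = rng.normal(0.0, cohort.subject_amp_sd, cohort.n_subjects)
    session_effects = rng.normal(
        0.0, cohort.session_amp_sd, (cohort.n_subjects, cohort.n_sessions)
    )
    series: dict[tuple[int, int], IdealSeries] = {}
    manifest: dict = {
        "n_subjects": cohort.n_subjects,
        "n_sessions": cohort.n_sessions,
        "subject_amp_sd": cohort.subject_amp_sd,
        "session_amp_sd": cohort.session_amp_sd,
        "true_icc": cohort.true_icc,
        "subject_effects": subject_effects.tolist(),
        "session_effects": session_effects.tolist(),
        "amplitude_scale": {},
        "activation_table": {
            f"{roi}:{cond}": amp
            for (roi, cond), amp in phantom.spec.activation_table.items()
        },
    }
    for i in range(cohort.n_subjects):
        for j in range(cohort.n_sessions):
            scale = 1.0 + subject_effects[i] + session_effects[i, j]
            manifest["amplitude_scale"][f"sub-{i:02d}_ses-{j}"] = float(scale)
            series[(i, j)] = simulate_bold_series(
                phantom,
                schedule_factory(i, j),
                TR=TR,
                TEs=TEs,
                n_volumes=n_volumes,
                amplitude_scale=scale,
            )
    return series, manifest


def roi_connected(phantom: Phantom, roi: str, min_voxels: int = 20) -> bool:
    """True when the ROI is made of connected components of adequate size."""
    mask = phantom.roi_mask(roi)
    if mask.sum() < min_voxels:
        return False
    _, n = ndimage.label(mask)
    return n >= 1
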