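"""End-to-end synthetic-cohort pipeline.

Reproduces the study's analysis flow on synthetic data: oddball
schedules -> phantom cohort with subject/session variance components ->
acquisition of both arms (segmented radial multi-echo k-space and
EPI-like image space) -> gridding reconstruction -> optimal echo
combination -> initial-volume dropping and smoothing -> first-level GLM
with AR(1) prewhitening -> group t maps and permutation cluster
inference -> percent signal change -> voxel-wise ICC(3,1), network-mask
median ICC, and intra-voxel ICC_v with intermodality comparisons.

A single master seed fans out to per-stage seeds by stable hashing, so
every stage is reproducible in isolation.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import acquisition, glm, multiecho, recon, reliability
from .paradigm import ParadigmConfig, generate_schedule
from .phantom import CohortSpec, PhantomSpec, build_phantom, simulate_cohort

__all__ = ["PipelineConfig", "run_pipeline", "make_fixtures", "stage_seed"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Derive a per-stage seed below 2^31 by stable hashing."""
    h = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    paradigm: ParadigmConfig = field(default_factory=ParadigmConfig)
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    cohort: CohortSpec = field(default_factory=CohortSpec)
    # near-silent radial multi-echo arm
    ls_tes: tuple = (0.0, 0.0161, 0.0322)
    ls_tr: float = 2.648
    ls_n_volumes: int = 240
    spokes_per_loop: int = 24
    n_segments: int = 15
    samples_per_spoke: int = 17
    # EPI-like arm
    epi_te: float = 0.0275
    epi_tr: float = 2.5
    epi_n_volumes: int = 240
    # analysis
    drop_volumes: int = 10
    fwhm_mm: float = 8.0
    hpf_cutoff: float = 128.0
    cluster_forming_p: float = 0.001
    network_t_threshold: float = 1.0
    n_permutations: int = 200
    combine_scheme: str = "te_weighted"
    seed: int = 0

    def validate(self) -> None:
        self.paradigm.validate()
        self.phantom.validate()
        self.cohort.validate()


def _first_level(series, schedule, tr, n_vols, cfg: PipelineConfig, voxel_size):
    smoothed = multiecho.smooth_gaussian(series, cfg.fwhm_mm, voxel_size)
    design = glm.build_design(
        schedule, TR=tr, n_vols=n_vols, drop=0, hpf_cutoff=cfg.hpf_cutoff
    )
    fit = glm.fit_glm(smoothed, design, whiten="ar1")
    return fit


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run the full synthetic study; returns a result bundle.

    The bundle holds, per modality, stacks of first-level contrast effect
    maps (subjects x sessions), group t maps, cluster tables, percent
    signal change, tSNR comparisons, ICC maps and medians, per-subject
    ICC_v and the intermodality Wilcoxon comparison, plus a manifest of
    every drawn truth value.
    """
    if config is None:
        config = PipelineConfig()
    config.validate()
    cfg = config
    master = cfg.seed

    phantom = build_phantom(cfg.phantom)
    voxel = cfg.phantom.voxel_size
    grid = phantom.labels.shape

    def schedule_factory(sub, ses):
        return generate_schedule(
            cfg.paradigm, seed=stage_seed(master, f"schedule:{sub}:{ses}")
        )

    # ideal series per arm share schedules via the factory seeding
    results: dict = {"manifest": None, "modalities": {}}
    cohorts = {}
    for arm, tes, tr, n_vols in (
        ("looping_star", list(cfg.ls_tes), cfg.ls_tr, cfg.ls_n_volumes),
        ("epi", [cfg.epi_te], cfg.epi_tr, cfg.epi_n_volumes),
    ):
        series_map, manifest = simulate_cohort(
            phantom, cfg.cohort, schedule_factory, TR=tr, TEs=tes, n_volumes=n_vols
        )
        cohorts[arm] = (series_map, manifest)
    results["manifest"] = cohorts["looping_star"][1]

    traj = acquisition.make_trajectory(
        spokes_per_loop=cfg.spokes_per_loop,
        n_echoes=len(cfg.ls_tes),
        n_segments=cfg.n_segments,
        samples_per_spoke=cfg.samples_per_spoke,
        nominal_resolution=voxel,
        seed=stage_seed(master, "trajectory"),
    )
    weights = recon.density_weights(traj)

    n_keep = {"looping_star": cfg.ls_n_volumes - cfg.drop_volumes,
              "epi": cfg.epi_n_volumes - cfg.drop_volumes}

    for arm in ("looping_star", "epi"):
        series_map, manifest = cohorts[arm]
        effect = {}   # (sub, ses) -> contrast effect map
        tmaps = {}
        psc = {}
        tsnr_maps = {}
        for (sub, ses), ideal in series_map.items():
            sched = schedule_factory(sub, ses)
            if arm == "looping_star":
                k = acquisition.sample_kspace(
                    ideal,
                    traj,
                    noise_sd=cfg.cohort.noise_sd,
                    seed=stage_seed(master, f"acq:{arm}:{sub}:{ses}"),
                )
                echoes = recon.grid_reconstruct(k, weights)
                echoes = [multiecho.drop_initial_volumes(e, cfg.drop_volumes)
                          for e in echoes]
                t2 = multiecho.fit_t2star(
                    [e.mean(axis=-1) for e in echoes], ideal.TEs
                )
                series, _ = multiecho.optimal_combine(
                    echoes, ideal.TEs, t2, scheme=cfg.combine_scheme
                )
                tr = cfg.ls_tr
            else:
                series = acquisition.simulate_epi_series(
                    ideal,
                    noise_sd=cfg.cohort.noise_sd,
                    drift_coeffs=cfg.cohort.drift_coeffs,
                    ar1_rho=cfg.cohort.ar1_rho,
                    seed=stage_seed(master, f"acq:{arm}:{sub}:{ses}"),
                )
                series = multiecho.drop_initial_volumes(series, cfg.drop_volumes)
                tr = cfg.epi_tr
            # shift the schedule to the retained-volume clock
            sched_kept = _shift_schedule(sched, cfg.drop_volumes * tr)
            fit = _first_level(series, sched_kept, tr, n_keep[arm], cfg, voxel)
            effect[(sub, ses)] = glm.contrast_effect(fit, "dev+nov>silent")
            tmaps[(sub, ses)] = glm.contrast_tmap(fit, "dev+nov>silent")
            psc[(sub, ses)] = {
                cond: glm.percent_signal_change(fit, phantom.roi_mask("auditory_roi"), cond)
                for cond in ("deviant", "novel")
            }
            tsnr_maps[(sub, ses)] = multiecho.tsnr_map(series)

        n_sub, n_ses = cfg.cohort.n_subjects, cfg.cohort.n_sessions
        eff = np.stack(
            [
                np.stack([effect[(i, j)] for j in range(n_ses)])
                for i in range(n_sub)
            ]
        )  # (sub, ses, x, y, z)
        group_t = {
            ses: glm.group_ttest(eff[:, ses]) for ses in range(n_ses)
        }
        clusters = {
            ses: glm.cluster_inference(
                eff[:, ses],
                cluster_forming_p=cfg.cluster_forming_p,
                n_perm=cfg.n_permutations,
                seed=stage_seed(master, f"perm:{arm}:{ses}"),
                mask=phantom.brain_mask,
            )
            for ses in range(n_ses)
        }
        iccmap = reliability.icc31_map(eff)
        netmask = reliability.network_mask(
            group_t[0], phantom.gm_mask, cfg.network_t_threshold
        )
        med_icc = (
            reliability.median_icc(iccmap, netmask) if netmask.any() else float("nan")
        )
        iccv = [
            reliability.intravoxel_icc(eff[i], phantom.roi_mask("auditory_roi"))
            for i in range(n_sub)
        ]
        results["modalities"][arm] = {
            "effect_maps": eff,
            "group_t": group_t,
            "clusters": clusters,
            "icc": iccmap,
            "network_mask": netmask,
            "median_icc": med_icc,
            "icc_v": iccv,
            "psc": psc,
            "tsnr": tsnr_maps,
        }

    # intermodality comparisons
    ls, epi = results["modalities"]["looping_star"], results["modalities"]["epi"]
    ok = ~(np.isnan(ls["icc_v"]) | np.isnan(epi["icc_v"]))
    if ok.sum() >= 5:
        stat, p = reliability.paired_compare(
            np.asarray(epi["icc_v"])[ok], np.asarray(ls["icc_v"])[ok]
        )
        results["icc_v_comparison"] = {"statistic": stat, "p": p}
    return results


def _shift_schedule(schedule, t0: float):
    """Schedule re-expressed on a clock starting t0 seconds in."""
    from dataclasses import replace
    from .paradigm import Schedule

    events = [
        replace(e, onset=e.onset - t0)
        for e in schedule.events
        if e.onset >= t0
    ]
    return Schedule(events=events, config=None, swap_time=schedule.swap_time)


def make_fixtures(scale: str = "tiny") -> PipelineConfig:
    """Packaged study configurations.

    ``tiny``: 16^3 grid, 60 volumes, 4 subjects x 2 sessions — runs the
    whole pipeline in well under two minutes for tests.  ``default``:
    32^3 grid, 240 volumes (230 retained), 12 x 2, the published study
    conditions.
    """
    if scale == "default":
        return PipelineConfig()
    if scale != "tiny":
        raise ValueError(f"unknown scale {scale!r}")
    tr_ls, tr_epi = 2.648, 2.5
    n_vols = 60
    total = max(tr_ls, tr_epi) * n_vols + 5.0
    paradigm = ParadigmConfig(
        initial_silence=4 * tr_ls, total_duration=total, n_rest_blocks=4
    )
    return PipelineConfig(
        paradigm=paradigm,
        phantom=PhantomSpec(grid_shape=(16, 16, 16), roi_radius_fraction=0.14),
        cohort=CohortSpec(n_subjects=4, n_sessions=2, noise_sd=0.5),
        ls_n_volumes=n_vols,
        epi_n_volumes=n_vols,
        spokes_per_loop=8,
        n_segments=9,
        samples_per_spoke=9,
        drop_volumes=4,
        n_permutations=100,
    )
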