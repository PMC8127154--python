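# Methods

This note documents the models, numerical choices and limitations of the
`silentstar` simulation and analysis pipeline.

## Oddball paradigm generator

Tones sit on a fixed slot grid of period `tone_duration + isi`
(0.705 s). Rest blocks (six 10 s blocks at the interior points dividing
the post-silence run into seven equal spans) and the mid-run swap cue
pause the grid and shift later slots in time. The run opens with
26.48 s of silence (10 volumes at the radial arm's TR of 2.648 s, the
longer of the two arms, so one schedule covers both) followed by five
forced Standard tones.

Non-standard tones are placed by a sequential per-slot draw subject to
the spacing rule (at least `m = min_standards_between` Standards between
non-standard onsets). A draw probability equal to the target rate
`r = p_deviant + p_novel` would *not* reproduce the configured
probabilities: with a forced window of m Standards after every
non-standard tone, a free-slot draw probability q yields a long-run
non-standard rate of 1/(m + 1/q) (renewal argument — one non-standard
slot, m forced Standards, then a geometric wait of mean 1/q − 1).
The generator therefore draws with q = r/(1 − m·r), whose long-run rate
is exactly r; Deviant vs Novel is an independent split with probability
p_deviant/r. The feasibility bound r ≤ 1/(m+1) is exactly q ≤ 1.
Pooled over 100 schedules the realized fractions sit within Monte-Carlo
error of .09/.07/.84.

The swap is a relabelling of the two fixed tone identities (the roles —
trial types — are unchanged); the swap cue occupies one paused slot, a
choice the configuration exposes (`swap_pauses_stream`).

## Phantom and BOLD signal model

The phantom is a set of nested ellipsoids (CSF shell, grey-matter
shell, white-matter core) on a 32³ grid of 4 mm voxels by default, with
a bilateral auditory sphere pair and a superior motor sphere carved
inside grey matter. Tissue T2\* defaults (3 T order of magnitude):
GM 66 ms, WM 53 ms, CSF 150 ms; proton densities 100/80/120 a.u., and
exactly 0 in background.

Dynamics follow S(TE, t) = PD·exp(−TE·(R2\* + ΔR2\*(t))) with
ΔR2\*(t) = peak amplitude × (unit-peak canonical HRF ⊛ condition onset
deltas), restricted to the ROI of each `(roi, condition)` activation
entry. Default peak ΔR2\* values (s⁻¹, negative = signal increase):
auditory −0.10 (Standard), −0.22 (Deviant), −0.28 (Novel); motor −0.18
for Deviant and Novel (the button press). These are free parameters of
the generator — the source study does not quantify per-condition effect
sizes — chosen to give ≈0.7–0.9% peak signal change at TE = 32.2 ms,
typical of event-related auditory BOLD; every drawn value is recorded
in the cohort manifest and tests compare against the manifest, not
against hard-coded constants. The TE = 0 FID carries no task contrast
by construction, and fractional signal change grows with TE.

Cohorts scale each run's activation amplitudes by 1 + a_i + e_ij with
a_i ~ N(0, σ_s²) per subject and e_ij ~ N(0, σ_e²) per session
(defaults σ_s = σ_e = 0.25), giving the analytic amplitude ICC
σ_s²/(σ_s² + σ_e²) = 0.5 used as ground truth in reliability tests.
BOLD is modelled purely as ΔR2\*; inflow, volume and motion effects are
not simulated, and the anatomy is schematic — passing tests demonstrate
the analysis chain's correctness and calibration, not performance on
real anatomy.

## Acquisition simulators

**Radial multi-echo arm.** Spokes are grouped into loops (one per echo)
and segments; each segment's loops lie on a great circle about a
segment-specific pole (Fibonacci-distributed poles under a random
rotation), so successive loops revisit the same directions and the echo
index equals the loop index. Equally spaced points on a circle sum to
zero, giving an exactly balanced mean direction. The published counts
(24 spokes/loop, 3 echoes, 15 segments → 1080 spokes/volume) are the
defaults; samples per spoke (17) and nominal resolution are
configuration values. The forward model evaluates the object's centered
DFT (DC at ⌊N/2⌋) at the *nearest Cartesian grid node* of each sample —
deliberately consistent with nearest-neighbour gridding so that full
sampling is exactly invertible, providing a small-scale oracle.
Complex white noise is added per sample (total complex variance
noise_sd²). The first `dead_samples` (default 2) centre samples of each
FID spoke are withheld (receiver dead time) and supplied as an
independently noisy reacquisition pass that reconstruction merges
first. Echo-in/echo-out interference is available as an optional
conjugate-partner term and defaults to 0. Undersampling relative to the
Cartesian grid produces static blur/aliasing that is identical across
volumes (the trajectory is fixed per run), so task timecourses survive
reconstruction essentially intact.

**EPI-like arm.** Works directly in image space: ideal series plus
Legendre-polynomial drift (orders ≥ 1, hence zero-mean: drift changes
temporal structure, not the baseline) and voxel-wise AR(1) noise with
stationary sd `noise_sd`.

## Reconstruction

Per volume and echo: density weights max(|k|, Δk/2)² (normalized to
mean 1), samples accumulated at nearest nodes, node value = weighted
*mean* of contributing samples (not sum — this makes full sampling
exactly invertible under the matching forward model; with identical
node values the weights only affect noise averaging), unvisited nodes
zero, magnitude of the centered inverse FFT. No oversampled grid and no
apodization: the reference pipeline describes plain nearest-neighbour
gridding, and the simple operator admits exact oracles.

## GLM

The canonical HRF is the SPM-convention double gamma (response gamma
shape 6, undershoot shape 16, unit dispersions, ratio 1/6, 32 s
support), scaled to peak 1; its sampled argmax is 5 s. Designs model
Deviant and Novel as zero-duration events and Silent rest blocks as
10 s epochs, all convolved at microtime dt = TR/16; Standard tones are
the implicit baseline. Drift uses a DCT basis with
⌊2·duration/cutoff⌋ functions (cutoff 128 s) plus a constant.

Serial correlation: OLS residual lag-1 autocorrelation is pooled over
in-mask voxels, but the naive estimate is biased toward zero because
the design projection (notably the drift basis) absorbs serially
correlated noise. The fitted ρ therefore solves the moment equation
E[r | ρ] = tr(M·L·M·V(ρ))/tr(M·V(ρ)) = r_obs, with M the
residual-forming matrix and L the symmetrized lag operator; simulation
at the study's 230 retained volumes recovers ρ = 0.3 within 0.01. A
single Cochrane–Orcutt transform (row differencing, first row dropped)
then replaces full ReML — it preserves the AR(1) intent with a closed
form that is testable at desk scale.

Contrast presets over (deviant, novel, silent) follow the study's five
comparisons; with the implicit baseline, "> all" contrasts test the
condition against zero. Group inference is a one-sample (or paired) t
with df = n − 1; family-wise cluster correction uses sign-flip
permutation of subject maps: 6-connected clusters above the one-sided
t threshold for p = .001, corrected p = (1 + #{perm max size ≥
observed})/(n_perm + 1). Permutation replaces random-field theory —
it is exact under exchangeability and verifiable by simulation; the
calibration test uses spatially smoothed subject maps (as produced by
the pipeline's 8 mm smoothing), since cluster sizes under unsmoothed
iid noise are nearly all singletons and make any cluster-size test
gravely conservative. Percent signal change is
100·β_condition·h_peak/β_constant with h_peak the maximum of a single
zero-duration event regressor at dt = TR/16.

## Reliability

ICC(3,1) uses two-way *mean* squares (Shrout & Fleiss consistency
form): BMS between subjects, EMS the residual after removing subject
and session main effects — the convention of the standard toolbox
definitions, even though the source text says "sum of squares"; for
balanced k = 2 designs the two differ, so the mean-square convention is
declared and enforced by an explicit ANOVA oracle (agreement to 1e-12)
and a cross-check against pingouin's ICC3. Intra-voxel ICC_v applies
the same decomposition with ROI voxels as rows and sessions as columns,
one scalar per subject; it is invariant to per-session additive offsets
and common positive rescaling. The Wilcoxon signed-rank comparison uses
an exact null enumerated over all sign assignments (polynomial
convolution over midranks, equivalent to full enumeration) for n ≤ 15
non-zero pairs and the normal approximation beyond; all-zero
differences report p = 1.

## Pipeline, scales and seeds

A single master seed fans out to per-stage seeds via
sha256(f"{seed}:{stage}") mod 2³¹, so any stage can be reproduced in
isolation. The packaged scales are: `tiny` — 16³ grid, 60 volumes
(4 dropped), 4 subjects × 2 sessions, 216-spoke trajectory, the whole
two-arm study in about a second; `default` — 32³ grid at 4 mm, 240
volumes (10 dropped), 12 × 2, the published design parameters. Tests
and the acceptance script run at sizes chosen to keep the full suite
under a minute while leaving every estimator at (or above) the sample
sizes where its calibration is meaningful; the tone-probability and ICC
checks use the full-length designs directly.

Cluster inference in the pipeline is restricted to the brain mask:
outside the head, reconstruction aliasing is subject-invariant and
would otherwise produce spurious infinite-t clusters. With only 4
subjects (df = 3) the p < .001 cluster-forming threshold (t ≈ 10.2)
exceeds the group-t ceiling implied by 25% amplitude variability
(≈ √n/σ_s), so the tiny fixture detects no significant clusters — the
strong-activation regression test uses 6 subjects with 10% variability
instead.

## Known limitations

No motion, physiological noise, field inhomogeneity, slice timing,
coil sensitivities or spatial normalization are simulated (the
synthetic cohort lives in a common space by construction). The radial
arm's acceleration factor and readout details beyond spoke counts are
configuration values, not derived from gradient waveforms. The
echo-combination efficiency check compares against the best
*T2\*-weighted* (TE > 0) echo: the TE-weighted scheme assigns the FID
zero weight by definition, and the FID's raw tSNR — which carries no
BOLD contrast — is not a meaningful functional reference; the
tSNR²-weighted scheme is provided for pipelines that want the FID to
contribute.
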