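# Methods

This note documents the models, defaults, and numerical choices behind
srtmkit, and what the synthetic tests do and do not demonstrate.

## Kinetic model and fitting

The SRTM describes a target-region concentration as a function of the
reference-region (cerebellum) concentration,

    C_T(t) = R1·C_R(t) + (k2 − R1·k2a) · (C_R ⊗ e^(−k2a t)),
    k2a = k2 / (1 + BP_ND),   BP_ND = k2/k2a − 1,

with R1 the target/reference delivery ratio (unitless, typically near 1),
k2 the target efflux rate (1/min) and BP_ND the non-displaceable binding
potential. Its assumptions — one-tissue kinetics in both regions, a
reference devoid of specific binding, common non-displaceable distribution
volume — are inherited, not tested, here.

**Basis-function fitting.** For fixed k2a the model is linear in
(R1, θ2 = k2 − R1·k2a). We precompute the convolution basis
C_R ⊗ e^(−k2a t) for a log-spaced grid of 128 k2a values in
[0.006, 0.6] /min (a range generously bracketing raclopride striatal and
extrastriatal kinetics), solve the 2-parameter weighted least-squares
problem per basis, and take the RSS minimum. ROI-level fits then polish
k2a by a bounded Brent minimization between the winning grid point's
neighbours, which removes the grid-discretization error (noise-free
round-trip BP error drops from ~7×10⁻³ to <10⁻⁵). Voxel fits stay
grid-only for speed; the vectorized solver handles all voxels of a mask at
once.

**Convolution and frame averaging.** All convolutions run on a regular
fine grid (dt = 0.05 min) with a recursive trapezoidal scheme implemented
as a first-order IIR filter; frame values are averages over [start, end)
computed from the cumulative trapezoidal integral, so frame edges need not
align with the grid. Against the analytic convolution of an exponential
the scheme is accurate to <10⁻⁴ at the default dt.

**Weights.** Default per-frame weights ∝ Δt·exp(−λ·t_mid) with
λ = ln2/20.4 min (¹¹C decay), normalized to sum to 1 — a standard
counts-based surrogate. A uniform mode exists for tests. No smoothing is
applied to voxel data before fitting.

**Degenerate fits.** If the target is numerically proportional to the
reference (relative weighted RSS of the reference-only fit < 10⁻¹⁶),
every k2a fits equally well; the fit is reported with BP_ND = 0 and R1
from the single-regressor solve, and additionally any |θ2| below
10⁻¹⁰·max(weight) is truncated to zero. Voxel fits are marked invalid in
the quality mask when the voxel is all-zero or non-finite, the winning
k2a sits on the grid edge, or BP_ND falls outside the plausibility clamp
(−0.9, 10); invalid voxels are excluded from all region summaries. ROI
fits carry no positivity constraint — small negative BP changes are real
features of test–retest noise.

**Reference input.** Fits never see the simulator's hidden generating
curve: the fine-grid reference is reconstructed from the measured
cerebellum frame TAC by shape-preserving (PCHIP) interpolation through
(0, 0) and the frame midpoints, followed by six multiplicative corrections
that force the reconstruction's frame averages onto the measured values.
This makes analyze mode (TSV input) and simulate mode produce identical
fits, and keeps the noise-free end-to-end ΔBP error below 0.02 points.

## Occupancy and reliability statistics

ΔBP = 100·(BP_base − BP_post)/BP_base, positive when BP falls (dopamine
elevation); a fractional (non-×100) output is available by flag. The exact
percent-change formula and the reliability formulas below are reasonable
standard choices, not reproductions of any particular prior computation:

- test–retest variability: mean over subjects of
  100·|bp1 − bp2| / ((bp1 + bp2)/2) — the symmetric two-scan-mean
  denominator;
- ICC(1,1): one-way random-effects, single-measure intraclass correlation,
  (BMS − WMS)/(BMS + (k−1)·WMS), chosen because the two baseline scans are
  unordered replicates; ICC(2,1) would add a session effect the design does
  not motivate;
- Wilcoxon signed-rank: zero differences dropped, exact null for n ≤ 25,
  normal approximation with continuity correction above; all-zero
  differences return p = 1 with a degeneracy flag.

Group contrasts: two-tailed paired t per region, reported uncorrected with
the Bonferroni threshold (α/m, m = 6 for the left/right sub-regions)
printed alongside. Voxel contrasts are paired t per voxel producing a
(1 − p) image displayed above 0.90, with the sign of the mean paired
difference stored separately so both effect directions remain
distinguishable; no voxel-level multiplicity correction is applied (the
maps are descriptive). The small single-condition arm (n = 2) is
summarized descriptively only. Pearson screens use the t-based two-sided
p-value and flag zero-variance inputs.

## The synthetic cohort

The generator emulates the study design — per subject a baseline and a
post-challenge scan in each of two sessions (crossover; exactly ⌊n/2⌋
subjects receive the LPS-containing session first), or a single session
for the LPS-alone arm — with one root seed; per-subject, per-scan and
per-covariate streams are spawned deterministically, so cohorts are
bit-reproducible.

Defaults (all configurable; chosen as typical raclopride values where no
published group statistic exists):

- reference curve: difference of exponentials scaled to peak 20 kBq/ml at
  4 min with washout half-life 25 min; per-scan amplitude jitter
  (lognormal, CV 0.15) mimics injected-dose variability;
- baseline BP_ND: striatum 2.5, caudate 2.4, putamen 2.8, ventral
  striatum 2.2, with inter-subject lognormal spread (CV 0.08);
- delivery and efflux: R1 ~ N(1.0, 0.05), k2 ~ N(0.3, 0.03) /min per
  subject;
- condition truths: subject-level true ΔBP ~ Normal(mean, SD) per
  condition cell, untruncated (negative draws are legitimate — some
  condition cells are negative); with `recenter` the draws are shifted so
  the sample mean equals the population mean exactly, which turns
  recovery of the configured mean into a sharp oracle;
- noise: zero-mean Gaussian per frame with
  σ = noise_scale·√(C(t_mid)·e^(λt_mid)/Δt), λ = ln2/20.4 min — variance
  grows with physical decay and shrinks with frame duration, a standard
  count-statistics surrogate. Default noise_scale 0.02 at ROI level
  (striatal ROIs average thousands of voxels, so percent-level TAC noise
  is realistic) and 0.3 per voxel;
- covariates: MP plasma draws at 30/90/150 min post-MP
  (condition means 12.7 / 11.7 ng/ml, absent without MP), TNFα/IL-6/IL-8
  curves at 0–240 min post-pre-treatment elevated only under LPS with
  TNFα peaking (90 min) before IL-6 (150 min), and integer POMS fatigue
  scores 0–4 at 0/60/210 min with an LPS-induced bump of 1–2. All
  covariates are generated independently of the subject's true ΔBP, so
  the downstream correlation screens face a known null.

By default targets are generated with the SRTM forward model itself
(model-consistent), which is what makes exact parameter recovery a valid
oracle. An optional two-tissue-compartment mode (plasma input recovered
from the reference under the 1-tissue assumption; k4 = 0.1/min,
k3 = BP·k4) exists for model-mismatch robustness studies and is off by
default.

**What passing tests show — and don't.** Recovery tests demonstrate the
estimator chain is correct and essentially unbiased *under its own
generating model and noise law*. They do not address violations real data
bring: non-1-tissue kinetics, reference-region specific binding, motion,
partial-volume effects, scanner resolution, or reconstruction artifacts.
Reliability numbers on synthetic data (ICC ≈ 1, sub-percent test–retest
variability at the default noise) characterize the chosen noise level, not
any empirical scanner–tracer combination.

## The phantom

Bilateral ellipsoidal regions on a 64×64×32 grid of 2.1×2.1×2.4 mm voxels
(a half-resolution desk-scale default; dims are configurable), with volume
targets matching the reference ROI set (putamen 21.9 ml, caudate 20.7 ml,
ventral striatum 2.9 ml, split per side) achieved within 10%. No
point-spread blurring is applied by default, deliberately decoupling
fitting accuracy from partial-volume effects; the ventral-striatum label
is a geometric stand-in, not an anatomically validated definition.
Label-set ROIs (e.g. whole striatum) are pooled voxelwise. Rendering
paints each region's TAC into its voxels plus independent per-voxel noise
under the cohort noise law; world coordinates are index × voxel size with
no affine rotation.

## Problem sizes and runtime choices

The default test suite and the acceptance script use the study-scale
problems directly — 8-subject cohorts, the 33-frame schedule, the
64×64×32 phantom (≈4300 striatal voxels) — since the vectorized solver
makes these sub-second to few-second computations. Monte-Carlo checks use
100–2000 replicates, sized so their expected sampling error sits well
inside the asserted tolerances.

## Known limitations

- The SRTM assumptions themselves are untested by construction
  (model-consistent generation); the 2TC mode probes mismatch only
  qualitatively.
- No arterial-input, 2TC, or partial-volume fitting; no registration or
  atlas handling — images are assumed subject-aligned on a shared grid.
- The voxel null-contrast calibration (~10% displayed at (1−p) > 0.90)
  holds for the voxel-noise-only null; with subject-level effect
  heterogeneity the displayed fraction in any single cohort is dominated
  by the shared subject draws and is intentionally not asserted.
- Whole-striatum reporting pools caudate + putamen + ventral striatum;
  the reported 42.6 ml volume column follows the reference ROI table
  (caudate + putamen), a deliberate cosmetic divergence.
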