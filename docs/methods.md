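# Methods

This note documents the models, estimators and synthetic-data design behind
`kip2traffic`, the choices made where several designs were defensible, and
what the passing tests do and do not demonstrate about real data.

## The traffic model

An astral microtubule is a 1-D lattice of 8-nm sites (one αβ-tubulin dimer,
one kinesin step), site 1 anchored at the spindle pole body (SPB,
minus-end), site *n* the plus-end. Kip2 motors obey hard-core exclusion and
five rate constants:

| symbol | process | default | units |
|---|---|---|---|
| k_in | entry at site 1 (empty) | 0.31 | (nM·s)⁻¹ |
| k_on | landing on any empty site | 6.1×10⁻⁴ | (nM·s)⁻¹ |
| k_off | detachment from non-terminal sites | 2.3×10⁻² | s⁻¹ |
| k_step | hop toward the plus-end (next site empty) | 13.125 | s⁻¹ |
| k_out | detachment from the terminal site | 3.3 | s⁻¹ |

Entry and landing propensities are proportional to the free cytoplasmic
concentration. The defaults for k_in, k_on, k_off and the 35 nM total
concentration are the published in-silico reference set for wild-type cells;
k_step = 6.3 µm·min⁻¹ ÷ 8 nm is fixed from the measured speckle speed, and
k_out = 3.3 s⁻¹ corresponds to the sub-0.3-s plus-end residence inferred in
vivo (the in-vitro scale, 1/30 s⁻¹, is provided as `K_OUT_IN_VITRO`).
At the terminal site k_out *replaces* k_off (the minimal reading of "a
different rate at the plus-end"); an additive interpretation would simply
shift k_out by k_off ≈ 0.02 s⁻¹, which is negligible at both scales.

**Finite pool.** Conservation of matter couples the lattice to the
cytoplasm: `c_free = kip2_total − n_bound · n_microtubules / (0.602 ·
volume_fl)` (1 nM·fL ≈ 0.602 molecules), with `n_microtubules` statistically
identical lattices sharing a cell of `volume_fl`. Neither constant is
experimentally printed; the defaults are **40 fL** (a haploid yeast cell)
and **12 microtubules**. The choice matters: it sets the free concentration
at the reference set (≈9 nM, strongly depleted from 35 nM, as the published
emphasis on [Kip2]_free < [Kip2]_total requires). Much stronger depletion
(free ≈ 6 nM) makes the shaft profile exactly flat — the reference set has
k_in·k_off/(k_step·k_on) ≈ 1, so entry flux then matches the Langmuir level
and joint rescalings of (k_on, k_off, total) become unidentifiable from
profiles; much weaker depletion delocalizes the plus-end traffic jam seen
with the in-vitro out-rate. A dozen microtubules in 40 fL realizes both
regimes at once and is anatomically plausible for a preanaphase cell. Both
constants are configurable, and sensitivity to them is easy to probe by
re-running `analysis/01` and `analysis/03` with `ModelParameters.with_()`.

**Three implementations, one process.**

* `gillespie_simulate` — exact stochastic simulation (direct method; numba
  core). Exclusion is enforced per event; the free pool is updated on every
  binding/unbinding (or held constant with `pool="unlimited"` — both modes
  exist because the original estimation's convention is not printed).
  Time-averaged occupancies are accumulated exactly between events.
* `master_equation_stationary` — the 2ⁿ-state generator's stationary
  distribution (sparse solve), exact for n ≤ 14 sites at fixed free
  concentration. This is the oracle the other two are tested against.
* `mean_field_steady_state` — site-wise mean-field equations (neighbour
  correlations factorized) with the pool solved self-consistently. This is
  the inference forward model; it is exact in the dilute limit and agrees
  with the oracle to a few percent at the occupancies relevant here.

**Numerics of the mean-field solver.** Fixed-c profiles are solved by
pseudo-transient continuation: implicit-Euler steps with a tridiagonal
(Thomas) linearization, accept-all stepping and SER timestep control, which
is robust through the shock-like profiles that occur at high density. The
scalar pool balance (monotone in c) is bracketed by an Illinois-safeguarded
secant, and a bordered Newton polish drives the coupled residual below the
tolerance (default 10⁻¹⁰). Warm starts (a Newton polish from a previous
solution) accelerate repeated solves during sampling. Degenerate inputs:
an empty lattice with no entry paths is a valid all-empty stationary state;
non-convergence raises a `ConvergenceError` carrying the last residual (the
sampler treats such parameter points as zero likelihood).

## From occupancy to fluorescence

`occupancy_to_profile` converts expected motors per site into expected
intensity per 133.35-nm pixel (2 pixels = one 266.7-nm length bin): site
densities are optionally blurred with a Gaussian PSF (default σ = 150 nm,
FWHM ≈ 350 nm, a spinning-disk scale), then integrated into pixels by exact
fractional overlap — integer site-per-pixel aliasing would otherwise imprint
a ±3% sawtooth that no real image shows — and a constant background is
added. The map is linear in occupancy and preserves total intensity.

Line scans are aligned by shifting whole pixels so the mCherry (SPB) peak
sits at zero; the GFP peak marks the plus-end, located with sub-pixel
quadratic interpolation after subtracting a local linear baseline (standard
spot-localization practice; without baseline correction the falling shaft
edge pulls the interpolated peak inward). Peak-to-peak distance defines the
profile length used for binning. Bins sit on multiples of 266.7 nm, store
per-position means, SEMs and 95% CIs, and keep the member intensity matrix
at positions common to all members — the between-cell covariance is what the
estimation likelihood uses.

## The estimation likelihood

For each length bin the forward model is evaluated at three stratified
quantiles (1/6, 1/2, 5/6) of the member lengths and averaged, approximating
the within-bin length mixture. Three linear nuisances are profiled by
generalized least squares at every evaluation:

* fluorescence **scale** (a.u. per motor),
* constant **background**,
* a **plus-end spot amplitude** with a known basis (the average of
  pixel-integrated Gaussians at the members' measured lengths). The spot
  stands for tip fluorescence outside the one-lane lattice — a real
  microtubule has ~13 protofilament tips plus Bik1-retained motors — and is
  what makes the plus-end peak conspicuous enough to measure per cell.

Two measurement parameters are sampled alongside the rates: a constant
**peak-detection offset** (the measured peak-to-peak length systematically
underestimates the lattice length by tens of nm because the spot rides on
the shaft edge) and its **linear trend in length** (the pull scales with
shaft brightness, which varies with length through pool depletion).

The per-bin error model is the Ledoit–Wolf-shrunk empirical covariance of
the member profiles divided by n (`log_likelihood_gls`), estimated from
every second member: weights estimated from the same draws as the mean feed
noise back into the quadratic form and both sharpen and tilt the likelihood
spuriously, while half-sample weights keep the mean unbiasedly weighted at
negligible efficiency cost. Only bins inside the 0.80–2.40 µm analysis span
enter the fit; edge bins hold truncated length slivers whose covariance is
not estimable. The cell-to-cell
expression scale (cv 0.2) moves a member's whole profile coherently; under
independent per-position SEMs that common mode would swamp the profile-shape
information, leaving the absolute rate constants identified only to a factor
of ~2 at 500 cells. The GLS form restores the shape precision. A simpler
independent-Gaussian SEM likelihood (`log_likelihood`) is kept as the
documented, swappable baseline. Before sampling, a quasi-likelihood
overdispersion factor (residual χ²/dof at the located maximum, floored at 1)
is folded in so credible intervals absorb residual forward-model
approximation error.

**Sampling.** Affine-invariant ensemble MCMC (emcee), 20,000 retained draws
by default, log-uniform ranges spanning ≥3 decades around the literature
scales (offset parameters linear). The posterior surface is needle-sharp in
the k_on/k_off ratio and multimodal in the total concentration, so the
walkers are initialized from a staged search: (i) locate the offset on a 1-D
grid; (ii) grid k_off × total coarsely and optimize (k_on, k_in, offsets)
per cell by Nelder–Mead on the smooth SEM surface; (iii) polish the best
candidates on the GLS surface and keep the best. Burn-in defaults to
max(300, steps/2); the stepping rate is fixed from the measured speed (tip
profiles constrain it only weakly) and k_out is fixed at its documented
default unless sampled on request. Every fit reports per-parameter
identifiability (posterior IQR width over sampled range width, log scale)
because uncertainty may reflect limited identifiability rather than noise.

Genotype comparisons (`compare_parameters`) bootstrap the difference of
marginal medians between two likelihood samples and report the two-sided
tail probability of crossing zero.

## Dynamic-instability quantification

Lengths are 3-D plus-end-to-SPB distances; cells with spindles > 2 µm are
excluded (strict inequality); lengths ≤ 666.7 nm (5 pixels) are censored to
0 µm. Maximum length and lifetime come from the censored series, lifetime
being the longest contiguous detectable span × 1.07 s (capped at the 85.6-s
window); isolated single-frame detections are treated as noise. Missing
frames are linearly interpolated up to two consecutive gaps, longer gaps
split the track.

Phase segmentation replaces manual annotation: recursive binary segmentation
with piecewise-linear fits (penalty 3σ̂²·log n, σ̂ from the MAD of first
differences), local boundary refinement, classification by net displacement
(growth ≥ +0.3 µm, shrinkage ≤ −0.3 µm, else pause; defaults configurable
and reported), merging of same-kind neighbours, and finally a
continuity-constrained two-piece linear fit scanned on a 0.1-frame grid that
places each switch time at noise-limited sub-frame precision. Phases share
their boundary frame, so phase displacements telescope to the net length
change. Speeds are Δlength/Δtime per phase; catastrophes (growth→shrinkage,
pauses do not mask the transition) are normalized per minute of growth time
and rescues per minute of shrinkage time, with an absent frequency (not
zero) when the denominator is zero.

Detector resolution: events whose flanking phases displace less than the
0.3-µm threshold plus a ~2σ noise margin, or that fall below the detection
limit or outside the acquisition window, are unresolvable by construction;
validation therefore scores recovery on resolvable events (≥90% within ±2
frames at 50-nm length noise). Pooled catastrophe frequencies from noisy
tracks are accordingly biased low by the unresolvable-event fraction
(≈25% at the default conditions) — exactly as manual annotation of real
movies is.

## Synthetic data: what it emulates and what it does not

`generate_profiles` emulates SPB-aligned line scans: mean-field profiles for
uniform lengths (0.8–2.4 µm, the experimental bin span), a lognormal
cell-to-cell intensity scale with mean 1 and cv 0.2 (expression
variability), a 12-motor-equivalent plus-end spot (protofilament tips and
Bik1-held motors beyond the modeled single lane; it scales with the cell's
expression level and is never used by the likelihood other than through its
nuisance), Gaussian PSF, per-pixel noise σ = 0.1 a.u. (small against the
~4 a.u. shaft signal, as in the real images where plus-end peaks are
conspicuous; the cell-to-cell scale dominates the per-bin uncertainty), a
constant background and an mCherry SPB peak at a random pixel offset.

`generate_tracks` emulates 3-D end-point tracks: a two-state telegraph
process on length (growth 1.5, shrinkage 3.0 µm·min⁻¹; catastrophe and
rescue 0.6 min⁻¹ — yeast astral-microtubule scales), reflecting at zero
length, embedded in 3-D with a pivoting axis (length is exact by
construction) and isotropic per-axis localization noise (default 25 nm),
80 frames at 1.07 s.

Not emulated: photobleaching, z-dependent PSF anisotropy, background
structure, tracking failures, microtubule bending, and any length change
during a traffic simulation. Passing the recovery tests shows the
estimation machinery is consistent and calibrated *for data with this
structure*; on real images the unmodeled effects above would add systematic
error that these tests cannot bound.

## Problem sizes and expected results

The recovery study uses 500 cells, ~6 populated length bins of 50–100 cells
(the experimental bins held 53–180), and 20,000 retained draws — a fit runs
in a few minutes on one CPU. Across generation seeds the marginal medians
recover the generating rates to within ~15–25% (total concentration within
~10%); the residual spread is posterior width at this sample size, not
structural bias (on noiseless data the likelihood peaks at the truth). The
sampler-calibration study uses 120-cell replicates with reduced draws.
The traffic-jam contrast (tip-to-interior occupancy ≈ 5.7 with the in-vitro
out-rate vs ≈ 1.3 in vivo, 2-µm lattice) is stable to <2% across simulation
seeds at 1000 s of averaged time.
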