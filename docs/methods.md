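# Methods

This note documents the models implemented in `gelsig`, the defaults and
why they were chosen, the numerical choices that matter, and what the
synthetic experiments do and do not demonstrate.

## Contact model and inversion

The forward model is Hertzian contact of a rigid sphere (radius `R`) on an
incompressible elastic half-space:

    F(δ) = 4 √R E / (3 (1 − ν²)) · δ^{3/2},   δ = max(contact_point − separation, 0).

Defaults mirror a common soft-matter AFM configuration: `R = 5 µm`
borosilicate bead, `ν = 0.5`, nominal cantilever stiffness 0.01 N/m
(carried as metadata; separation is treated as already deflection-
corrected), force setpoint 2 nN. Adhesion is neglected (small relative to
the setpoint); JKR/DMT and conical-tip models are out of scope.

**Curve generation.** The separation axis spans symmetric in/out-of-contact
ranges around the contact point. When no indentation depth is given it is
derived from the setpoint, `δ_max = (F_set/C_E)^{2/3}`, and clipped to
`0.4 R` so the small-indentation validity condition always holds; an
explicit user depth above `R/2` raises a warning instead. Noise is
additive i.i.d. Gaussian on force (thermal/detector noise; no 1/f
component). Default 256 samples/curve (128 in the pipeline, which trades
per-curve precision for many pixels); both are fixture choices, not
measured values.

**Inversion.** `fit_hertz` estimates `(E, contact point, baseline)`
jointly by least squares on the δ^{3/2} model. The baseline and the Hertz
amplitude enter linearly and are profiled out in closed form, so the
problem reduces to a 1-D search over the contact point: a coarse grid
(96 candidates) followed by bounded scalar minimization. Contact detection
thresholds a moving-average-smoothed trace at 3× the (MAD-estimated) noise
floor of the smoothed signal; curves that never exceed the threshold raise
a no-contact error. The fit is exactly invariant under force-baseline
offsets and rigid separation shifts, and on noiseless curves recovers the
modulus to better than 1e-6 relative (verified in the acceptance suite).
With 0.05 nN noise at a 2 nN setpoint the median inversion error is
~1% (256 samples) to ~1.5% (128 samples).

## Percolation model of gel elasticity

Above the gel point the modulus follows `E = A |p − p_c|^f`. The critical
exponent acquires a smooth spatial Gaussian law through heterogeneous
swelling, so per pixel

    log E = log A + f · log|p − p_c|,

an affine image of a Gaussian field — the log-normality is exact, not
asymptotic, and the closed forms

    mean(log E) = log A + f_mean · log|p − p_c|,
    sd(log E)   = f_sd · |log|p − p_c||

are asserted against simulation.

**Defaults (declared fixture parameters — the physical literature gives
no unique numbers for a swollen collagen network):** `p_c = 0.347` (2-D
triangular bond-percolation threshold, matching the lattice module),
`p = 0.447` so `|p − p_c| = 0.1`, `f_mean = 2.0`, `f_sd = 0.2`, and
amplitude `A = 3·10⁴ Pa` so the median modulus is 300 Pa — the order of
magnitude measured on collagen scaffolds. The amplitude only sets scale;
distribution shape is unaffected.

**Exponent field.** White Gaussian noise convolved with a periodic
Gaussian kernel (`σ = correlation_length_px`), rescaled by the exact
kernel norm so the marginal is exactly `N(f_mean, f_sd²)`. Default
correlation length 1.5 px: AFM pixel spacing (µm) already far exceeds the
percolation correlation length ξ (the physical requirement is
inhomogeneity scale ≫ ξ), so only mild inter-pixel correlation is
warranted. A correlation length ≥ half the grid triggers a degeneracy
warning.

**Testing normality on a correlated field.** Shapiro–Wilk and KS assume
independent observations and over-reject badly on a flattened correlated
grid (≈84% at n = 4096 with σ = 1.5 despite exactly Gaussian marginals).
All distribution verdicts on spatial data therefore use a *decorrelated
subsample*: a strided grid with stride 4× the correlation length (pair
correlation < 2%) and a seeded random phase. With 96×96 maps this yields
256 approximately independent pixels and a measured rejection rate of
0.04–0.05 at α = 0.05. Histograms always use the full map.

**Degradation.** `patch_degradation` divides the modulus by `severity`
inside randomly placed disks (radius 3 px) until the target area fraction
is covered, producing a two-component mixture on the log scale; the
boolean mask is kept as ground truth. This mechanism is a declared
modelling choice emulating localized enzymatic digestion — the real
microscopic action of metalloproteinases is not modelled.
`global_softening` divides all pixels by a constant: a log-location shift
that provably preserves log-normality, used as the negative control.
Defaults (fraction 0.3, severity 5) separate the mixture modes by
~3.5 sd of the intact log-modulus, giving near-unit power at 256 pixels.

## Kantor–Webman lattice

The network Hamiltonian combines bond stretching and bond bending,

    H = (α/2) Σ_⟨ij⟩ e_ij [(u_i − u_j)·r̂_ij]² + (β/2) Σ_⟨ijk⟩ e_ij e_ik (δθ_ijk)²,

with `e_ij ~ Bernoulli(p)` i.i.d. (the occupied-bond convention
`P(e=1) = p`), the bending sum over all occupied bond pairs at each centre
node, and δθ the linearized inter-bond angle change. In 2-D δθ is the
difference of scalar bond rotations (exactly invariant under rigid
translations and linearized rotations); in 3-D the exact first-order angle
change is used, with collinear pairs handled by the transverse-difference
norm. Energies are assembled as a sparse quadratic form, so
`network_energy` and the modulus solve share one code path.

**Geometry.** 2-D default is a triangular lattice oriented with vertical
boundary columns (constant x). This makes the zero-modulus/no-spanning
equivalence exact: a cluster touching only one pinned boundary can relax
to a rigid translation. 3-D (cubic + face diagonals) is supported to side
8 for demonstration. The effective modulus pins both boundary columns to
the affine strain, minimizes the interior energy by dense least squares
(pseudo-inverse handles floppy modes), and returns `2E_min/(ε²·V)` in
lattice units; spanning is pre-checked by connected components, and the
test suite cross-checks with an independently written union-find oracle.
Strains of 1e-3 are used; the energy is quadratic so the modulus is
strain-independent to numerical precision.

**Weak universality.** Exponent fits use OLS of `log E` on
`log(p − p_c)`. On 14² lattices with p ∈ [0.55, 0.85] the stiff-bending
regime (α = β = 1) and soft-bending regime (β = 0.02) give clearly
different fitted exponents (≈1.3–1.6 vs ≈1.8–1.9) with disjoint 95% CIs.
These are *finite-size effective* exponents — no claim is made about
thermodynamic-limit values, which is why the tests assert the reporting
contract (two CIs computed and reported) rather than specific numbers.

## Generative processes

Additive recursions `X_{j+1} = X_j + R_j` accumulate Gaussian noise (sum
variance `n·σ²`, asserted by regression); multiplicative recursions
`X_{j+1} = X_j(1 + R_j)` yield log-normal terminal laws by the log-sum
argument. Multiplicative noise is restricted to σ < 1/3; trajectories
whose factor crosses zero anyway are excluded and counted rather than
reflected, keeping the product recursion literal. The kinetic analogue
integrates `d log c = (ā + δ(t)) dt` by Euler–Maruyama with increments
`N(0, σ² dt)` (white-noise convention: integrated variance σ²t);
positivity is automatic, and the noiseless scheme is exact for constant
drift. Dichotomy defaults for the demo: multiplicative σ = 0.05 over 200
steps (log-sd ≈ 0.71); additive x₀ = 30, σ = 1 over 100 steps (CV ≈ 1/3,
keeping values essentially always positive while the log-transformed law
is detectably skewed at n = 800).

## Distribution classification

Decision rule, in priority order: **log-normal** iff Shapiro–Wilk on the
log scale *and* KS against the fitted log-normal both have p > α;
else **normal** iff Shapiro–Wilk on the linear scale has p > α; else
**neither**. α defaults to 0.05. Because the log-normal parameters are
estimated from the same sample, the naive KS p-value is conservative; the
default p-value comes from a Monte-Carlo (Lilliefors-type) null with 500
resamples, exploiting that the fitted-normal KS statistic is pivotal in
the location-scale family (so the null is simulated once from standard
normals). Measured rejection rate on true normal data: 0.054 over 1000
seeds. The naive mode remains available (`ks_mode="naive"`) for literal
reproduction of uncorrected analyses. KS on the linear scale against the
fitted log-normal equals KS of the log-sample against the fitted normal
(monotone transforms preserve ECDF gaps), which is how it is computed and
is cross-checked against `scipy.stats.kstest` in the tests. Group
comparison is the two-sided Mann–Whitney U with tie handling. Histogram
binning is Freedman–Diaconis on each scale.

## Pipeline

`gel_baseline` / `m2_like`: exponent field (96×96) → map → per-pixel
synthetic retraction curves at the decorrelated subsample (256 pixels) →
Hertz fits → classification; median |fitted − true|/true ≈ 1.3%.
`m1_like` additionally degrades a copy of the *same* base map, fits both,
classifies both and compares them (paired design isolates the degradation
effect). Per-stage RNGs derive from the global seed by a fixed
counter-based splitting rule (`SeedSequence(seed, spawn_key=(stage_id,))`),
so any stage is independently reproducible and a report is byte-identical
across runs of the same config.

Problem sizes throughout (96×96 maps, 256 fitted pixels, 200-seed
calibration loops, 50 paired degradation seeds, ≤16² lattices) are chosen
so the full suite and the acceptance script each run in about a minute on
one CPU while keeping Monte-Carlo standard errors a few times smaller than
the asserted tolerances.

## What the synthetic data does and does not show

The generator realizes the generative model exactly (affine-Gaussian
log-modulus), so the log-normality tests here validate the *pipeline and
statistics*, not the physical hypothesis itself. Real force-volume data
add contact-point artifacts, adhesion, finite-thickness and substrate
effects, cell bodies, drift, and possibly spatially varying amplitude `A`
— none of which are modelled. Passing tests therefore demonstrate that
(i) the inversion and classification machinery is calibrated and
unbiased under the stated noise model, and (ii) *if* gel elasticity is
generated by the percolation mechanism, the distribution-type signature
(log-normal intact vs neither after patchy degradation) is detectable at
realistic sample sizes and noise levels. They do not demonstrate that
real collagen gels follow the model, nor do the lattice exponents predict
experimental collagen exponents.

## Known limitations

- 3-D lattices are small (≤ 8³) and the bending linearization near
  collinear triplets switches formula at cos θ = −1 + 1e-9; exponent
  estimates in 3-D are illustrative only.
- The Hertz fitter assumes a single contact and a flat baseline; it is not
  robust to adhesion hysteresis or multiple contacts.
- Patch degradation uses hard disks with a single severity; real
  enzymatic degradation is graded and anisotropic.
- `classify_distribution` requires n ≥ 20 and strictly positive samples;
  additive ensembles are truncated to their positive part before log-scale
  testing (the excluded count is negligible at the default parameters).
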