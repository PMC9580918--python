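# Methods

This note documents the statistical models behind `clasta`, the parameter
choices that matter, and the numerical decisions taken where the design was
genuinely open. All quantities stated here are computed by the test suite
or by `scripts/acceptance.py`; nothing is asserted that the code does not
itself measure.

## Validity of Monte Carlo p-values

A p-value is *valid* if P(p ≤ a | H₀) ≤ a for every a ∈ [0, 1], and *exact*
if equality holds. Rank-based Monte Carlo p-values with n control samples
are discrete on the grid {i/(n+1)}; they are exact at grid values and
conservative between them. Two practical consequences drive the design
throughout the package: the significance level must satisfy α > 1/(n+1)
(the code warns otherwise), and any procedure that aggregates such p-values
must respect their discreteness (see "Combining experiments" below).

## Two-color SMLM simulator (`clasta.smlm`)

The simulator works at the localization-list level; no camera images or
point spread functions are rendered.

1. **Molecules.** Oligomer seeds are a homogeneous spatial Poisson process
   of intensity `molecule_density / oligomer_size` on the ROI; each seed is
   replicated `oligomer_size` times at *identical* coordinates. The
   oligomer footprint (a few nm) is far below the 30 nm localization
   precision, so zero intra-oligomer separation is an adequate model; the
   field is exposed should extensions need it.
2. **Labeling.** Each molecule is labeled independently with probability
   `degree_of_labeling` (default 0.4) and assigned to the blue channel with
   probability `label_ratio` (default 0.5, i.e. 1:1) — competitive
   two-color labeling of one species.
3. **Blinking.** Each label emits k ≥ 1 detections. The default blink model
   is geometric on {1, 2, …} with mean 5 — a maximally simple overdispersed
   overcounting law. Measured per-fluorophore blink tables can be supplied
   as an empirical distribution; the nanoclustering test's validity is
   independent of the blink law (the toroidal shift preserves it exactly),
   so the choice affects power only mildly through the localization count.
4. **Nuisance signals.** Unspecifically bound labels (default 5/µm² per
   channel) and background signals (defaults 1/µm² red, 2/µm² blue) are
   uniform on the ROI and blink like real emitters.
5. **Localization error.** Every detection is displaced by isotropic
   Gaussian noise (σ = 30 nm per axis by default) and wrapped back into the
   ROI with periodic boundary conditions.

**Why wrap rather than clip:** wrapping keeps each channel's point process
strictly stationary on the torus. The observed statistic and all
toroidal-shift statistics are then exchangeable under the null, which makes
the test's p-value exact rather than approximately valid — the simulator
and the test share the same geometry. Real data are not toroidal; on real
ROIs the shift is the standard approximation and edge effects enter at
order (shift support)/(ROI side).

Default ROI and densities (10×10 µm at 75 molecules/µm²) represent a
typical membrane-protein imaging experiment; reduced ROIs (down to 3×3 µm)
are used in repeated-simulation studies purely to vary the molecule count
or the problem size, and are stated wherever used.

## The nanoclustering test (`clasta.cluster_test`)

Summary statistic: for each localization of the query channel (blue by
default; the direction is configurable and the choice is a convention, not
physics), the Euclidean distance to the nearest reference-channel
localization is computed (KD-tree); the statistic s is the exact integral
of the empirical CDF of these distances over [0, 200] nm. The 0–200 nm
window captures the scale at which oligomer-induced cross-channel
correlation lives (co-labeled oligomers produce cross-channel pairs at
~√2·30 nm scale); the bounds are configurable.

Null controls: n random shift vectors uniform on [0, W)×[0, H); the query
channel is shifted toroidally, distances and integral recomputed against
the *unshifted* reference channel. Post-shift distances use the plain
Euclidean metric, matching the treatment of the observed data.

p-value: descending-rank rule p = #{s ∈ S : s ≥ s₀}/(n+1) with S including
s₀ itself. Ties count as "at least as extreme" — the conservative choice
that preserves validity; with continuous statistics they have measure zero.
The right-sided test targets clustering (steeper CDF ⇒ larger integral);
left-sided targets dispersion/repulsion; the two-sided p doubles the
smaller one-sided value (capped at 1), a Bonferroni-style composition that
keeps validity on the discrete grid.

Exactness: the KD-tree + step-function path is verified in the tests
against a monolithic O(N²) brute-force recomputation (all-pairs minima,
closed-form ECDF integral) to 1e-12 relative tolerance.

## Combining experiments (`clasta.combine`)

With m experiments and per-experiment p-values discrete-uniform under the
null, k = #{pᵢ ≤ p₀} is Binomial(m, p₀) whenever p₀ is an achievable grid
value, and p\* = P(X ≥ k) is a valid right-sided p-value. The threshold
comparison is inclusive (≤ p₀), matching the discrete-uniform probability
statement; p₀ defaults to 0.05 and need not itself be achievable — k simply
counts achievable values at or below it. The continuous min-p correction
1 − (1 − p_min)^m and the discrete lower bound 1 − (n/(n+1))^m are provided
as references; both are properties of the *minimum*, not of the binomial
count, and the package treats them as diagnostics of why the binomial route
is needed.

## smFRET trajectory simulator (`clasta.fret`)

A continuous-time two-state Markov process with efficiencies E₁ = 0.2,
E₂ = 0.8 and exponential dwell times with means τ₁ = 2, τ₂ = 4 (arbitrary
time units) is sampled by a camera with exposure t_ex = 0.1 and inter-frame
delay t_del = 0.2 (frame period 0.3; exposure occupies the first t_ex of
each period). The initial state is drawn from the stationary distribution
(τ₁, τ₂)/(τ₁+τ₂), so trajectories are stationary from frame 0. The apparent
per-frame efficiency is the exposure-time-weighted mean of the state
efficiencies, computed exactly from the piecewise-constant path.

Photon noise: donor and acceptor brightnesses are lognormal with means
m_don = n_phot(1 − e) and m_acc = n_phot·e (n_phot = 200) and standard
deviations σ = 0.3·m − 13.61 (donor) and σ = 0.3·m − 1.92 (acceptor).
Numerical choices, both points where the calibration as stated is
incomplete:

* σ and the mean are interpreted as moments of the lognormal *itself*; the
  underlying normal parameters follow by moment inversion
  (σ² = log(1 + (sd/mean)²), µ = log mean − σ²/2).
* The donor formula is negative for m < 45.4 — reached routinely in the
  high-FRET state (e = 0.8 ⇒ m_don = 40). σ is clamped from below at
  `sigma_floor` (default 1.0). The negative regime suggests the linear fit
  was never meant to be extrapolated there; the clamp is the mildest
  completion and is configurable.

Recorded efficiency: E = a/(d + a); noise can push E outside [0, 1], as in
real ratiometric data. Trajectory lengths are lognormal with mean 27.1 and
SD 35.5 *frames* (underlying µ ≈ 2.80, σ² ≈ 1.0 by moment inversion),
rounded to integers and floored at 1; groups default to 100 trajectories.

With these defaults the mean dwell (2–4 time units) spans ~7–13 frames, so
the lag-1 frame autocorrelation is strong (measured > 0.5 in the tests) —
the correlation that breaks pointwise permutation.

## Permutation tests (`clasta.permutation`)

The statistic is frame-weighted: all frames of a group are pooled and
averaged, so a long trajectory contributes proportionally to its length.
Pointwise mode permutes frames into pseudo-groups of the original pooled
frame counts; block mode permutes whole trajectories, preserving trajectory
counts per group (block-permuted *frame* counts therefore fluctuate, which
is fine for a mean statistic). When every trajectory has length 1 the two
modes coincide.

The default p estimator is (1 + #{|sᵢ| ≥ |s₀|})/(n_perm + 1): the observed
assignment counts as one of the permutations, guaranteeing p > 0 and
validity under exchangeability. The raw proportion estimator (strict
inequality, no add-one term) is available via `add_one=False` for
comparison with conventions that use it; it can return 0 and is
anticonservative. Statistics equal to |s₀| up to 1e-9 relative rounding are
treated as ties — discrete data generate exact ties that float arithmetic
would otherwise split arbitrarily, breaking the A/B label symmetry of the
two-sided test. Exact enumeration (`exact_block_test`) is limited to
C(n_A+n_B, n_A) ≤ 1e5 assignments and serves as the oracle for the Monte
Carlo estimator in the tests.

## Evaluation harness (`clasta.evaluate`)

Rejection rates carry Wilson 95% confidence intervals (Wald intervals are
badly calibrated at the small run counts typical here; n_runs defaults to
100). Per-run generators are spawned deterministically from the master
generator, so every estimate is reproducible from one seed. The
discrete-uniform goodness-of-fit is a chi-square over the n+1 achievable
p-values and refuses off-grid inputs rather than binning them silently.
ROC curves evaluate (FPR, TPR) at every achievable threshold; for a valid
test the curve of null-vs-null p-values lies on the diagonal.

## Problem sizes and runtime

Repeated-simulation checks use: 1000 runs on a 3×3 µm ROI for null
calibration (the ROI sets the molecule count, not the physics; calibration
is ROI-independent because the p-value is exact), 100 runs at 6.5×6.5 µm
(~3170 molecules) for the ≥ 3000-molecule dimer sensitivity claim, 100
seeds at the full 10×10 µm defaults for the clustered-case p-value, and 500
replicates of 100-trajectory groups with 1000 permutations for the
block-vs-pointwise comparison. The full suite runs in a few minutes on one
CPU.

## What passing tests do and do not show

The simulators realize the idealized conditions under which the tests are
provably valid: stationary (toroidal) channels, independent trajectories,
homogeneous Poisson nulls. Real data deviate — non-toroidal ROIs with edge
effects, spatially varying labeling and background, drift and chromatic
aberration (not simulated; small aberrations do not break cross-channel
correlations and mainly cost power), photobleaching and donor-only species
in FRET (not simulated), and possible dependence *between* trajectories
(e.g. shared cell). Passing the calibration suites therefore demonstrates
correctness of the machinery and validity under the stated models, not
robustness to every experimental artifact. Known limitations: the mean
difference is the only trajectory statistic; the nanoclustering test
reports evidence against randomness, not cluster sizes or counts.
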