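# Methods

This note documents the models, numerical choices and known
limitations behind the `nethom` pipeline. Everything quantitative
stated here is computed by the test suite or by
`scripts/acceptance.py`; nothing is quoted from external data.

## The NH statistic

For a network mask of N voxels, NH(i) is the mean Pearson correlation
of voxel i's time series with the other N − 1 in-mask series. The
production path uses the standardised-sum identity: with per-voxel
z-scored series (population sd) and S = Σ_j z_j, the row sum of the
correlation matrix is z_i·S / T, giving O(N·T) cost. A brute-force
O(N²·T) implementation (`nh_bruteforce_oracle`) is retained purely as
an independent oracle; the two agree to 1e-10 on random inputs (the
identity is exact; the residual is floating-point noise). Raw
correlations are averaged, not Fisher-z transformed, matching the
plain definition; a Fisher-z mode exists behind a flag. Zero-variance
in-mask series are a hard error naming the voxel — silent NH = 0
would mask preprocessing faults.

## Synthetic cohort model

Each subject's run is generated on a common grid (default 18×22×18 at
3 mm, 100 volumes, TR 2 s — a desk-scale stand-in for a 250-volume
acquisition) with a two-level latent structure over a union of
labelled network boxes:

    x_v(t) = sqrt(a)·G(t) + sqrt(b_r)·R_r(t) + sqrt(q)·A(t)
             + sqrt(1 − a − b_r − q)·ε_v(t)

* `G` — one global network latent per subject (weight `a`, default
  0.05), shared by every in-network voxel;
* `R_r` — one latent per region (weight `b_r = w_r − a`, where `w_r`
  is the region's within-region correlation);
* `A` — an optional motion-locked artifact whose weight `q` is
  proportional to the subject's true mean framewise displacement;
* `ε_v` — unit-variance white voxel noise; out-of-network voxels are
  pure noise.

All latents are unit-variance mixtures of 24 sinusoids confined to
0.01–0.08 Hz (the band preprocessing retains). Population correlations
are exact: `w_r + q` within a region, `a + q` across regions, so true
regional NH has a closed form used throughout as an analytic oracle
(`true_region_nh`), and regional mean NH converges to `w_r` for a
single-region network with `a = 0` (verified at T = 2000 to within
0.001, against a 0.03 acceptance band).

An earlier single-factor variant (one latent, corr = √(w_i·w_j)
across regions) was discarded: cross-region square-root coupling plus
band-pass saturation capped a planted NH increase at about +0.04 while
between-subject NH noise is ~0.08 at 100 volumes, making the planted
increase undetectable at this scale. The two-factor model confines
each planted effect to its region (cross-region correlation is `a`
regardless of patient coupling) and leaves headroom for detectable
swings.

**Planted dissociation.** Patients' `w_r` is shifted by +0.60 in the
lowest-coherence region ("mpfc", base 0.15) and −0.45 in the
highest-coherence region ("pcc", base 0.55). The asymmetric placement
is deliberate: the ideal band-pass removes ~71% of white-noise
variance, which inflates all correlations toward a ceiling
(w → w / (w + (1−w)·β), β ≈ 0.29 the in-band fraction), so increases
need low baselines and decreases high ones. Effect sizes are free
parameters of the emulation — no reported statistic pins
them — chosen once so that the full pipeline detects both effects
with comfortable margin at 20+20 subjects.

**Subject variability.** Each subject's `w_r` receives N(0, 0.03)
jitter (clipped to [a+0.01, 0.95]). Larger values would make
phenotype correlations easier to see in measured NH but inflate the
GLM's between-subject variance; 0.03 keeps the true between-subject
regional NH sd near 0.01.

**Motion.** Six-parameter random walks whose per-step sd is calibrated
so the expected Power FD per frame equals the requested scale
(E|N(0,σ)| = σ√(2/π); rotations share the budget via the 50 mm head
radius). Doubling the scale doubles every parameter exactly. Planted
QC violators get scale 1.2 mm, far beyond the 2 mm / 2° / mean-FD
0.5 mm exclusion rule.

**Phenotypes.** Demographics for everyone; clinical scales and lipids
only for patients (controls carry missing values, exercising
pairwise-complete correlation handling). A planned variable is
`mean + sd·(r·z(NH_true) + √(1−r²)·ε)` against the patient's *true*
regional NH, so the planted r is exact in expectation.

## Preprocessing

Fixed order: discard initial volumes (default 10) → OLS nuisance
regression on an intercept plus the 6 motion parameters (Friston-24
optional; global/tissue signals are meaningless for this generator
and omitted) → ideal DFT band-pass 0.01–0.08 Hz (coefficients outside
the band zeroed, DC removed). FD is Power's scalar formulation. All
constants are configurable because the convention, not a unique
truth, fixes them.

## Network mask by group ICA

Control runs only — the mask must not be shaped by patient data.
Per-subject voxel-wise variance normalisation, temporal concatenation,
PCA to k = 20 temporal components (economy eigendecomposition of the
smaller Gram matrix, verified against a dense eigensolver), then
fixed-point negentropy-maximising spatial ICA (tanh contrast,
tol 1e-6, max 1000 iterations; non-convergence raises, and the mask
driver retries with deterministically shifted seeds as ICA toolboxes
commonly do). Component maps are z-scored with a positive-skewness
sign convention.

Selection is template-matched: the Pearson correlation of each |z|
map with the binary template. Because coherent networks decompose
into *subnetwork* components (here one per region, scoring ~0.44
each against the whole-network template, versus ~−0.13 for noise
components), the mask is the union of all components scoring ≥ 0.2
(the best always kept), thresholded at z ≥ 2.3 with 26-connected
clusters below 10 voxels removed. On default cohorts the derived mask
matches the ground-truth network with Dice 1.0 across seeds.

## NH maps before group statistics

Maps are smoothed with a mask-renormalised Gaussian (FWHM 6 mm,
configurable; the kernel sees in-mask neighbours only, so edges are
not diluted). At 100 volumes the band-limited series has ~13
independent DFT bins, putting ~0.09 of sampling noise on each voxel's
NH; smoothing averages neighbouring voxels' largely independent noise
and roughly triples voxel-level t at planted effects. Mask-wise
z-standardisation of each subject's map is available but off by
default: with a nearly homogeneous synthetic network the mask-wise sd
is itself noise-dominated, and dividing by it amplifies spurious
differences.

## Group inference

Per voxel, OLS of NH on [intercept, group, age, mean FD]; the
reported t is the group coefficient, patients-minus-controls.
Candidate clusters form at two-tailed voxel p < 0.001
(26-connectivity), separately per sign. FWE control is by permutation:
group labels are shuffled (covariates stay with their subjects), the
GLM refit, and the maximum cluster extent per sign recorded;
cluster p = (1 + #{perm max ≥ observed}) / (1 + n_perm), doubled
across the two signed contrasts (Bonferroni), reported when the
adjusted p < α. Peak voxels are the maximum |t| (ties to the smallest
linear index) converted to millimetres through the affine. Permutation
rather than random-field theory because small smooth-less grids
violate RFT assumptions; the permutation null is exact under
exchangeability. Calibration: on 100 null cohorts the any-cluster
rate is ≤ a few percent at α = 0.05 (conservative, as max-extent
nulls with discrete small clusters tend to be); with a planted
group-correlated motion artifact the rate rises to ~0.5 without
covariates and returns to nominal with the mean-FD covariate, because
the artifact makes NH linear in true mean FD by construction.

## Clinical correlations

Pearson r with the exact t-based two-sided p (n − 2 df),
pairwise-complete deletion with per-test n recorded, computed within
the patient group; no multiplicity adjustment by default (matching
reporting practice for exploratory tables), Benjamini–Hochberg behind
a flag. Recovery of a planted r = 0.5 at n = 40 is exact to ±0.05 in
the mean over 50 cohorts *at the phenotype level*. In the full
pipeline the measured regional NH carries ~0.03–0.05 of
subject-level measurement noise against ~0.01 of true
between-subject sd, so measured-NH correlations attenuate to roughly
one fifth of the planted value — classical reliability attenuation,
which doubling the run length would substantially reduce. The
correlation driver prints both tables side by side.

## Classification

One region's mean NH; Gaussian-kernel soft-margin SVM; leave-one-out
cross-validation with features z-scored by training-fold statistics
inside every fold (no leakage). Hyperparameters C, γ ∈ {2⁻⁵, 2⁻³, …,
2⁵} are chosen by maximal LOO accuracy, ties to the smallest C then
smallest γ. Selecting on the reporting loop is optimistic — on
label-permuted nulls it inflates mean accuracy from ~50% to ~60% at
these sample sizes — so a nested-CV mode exists for honest estimates,
and the chance-level calibration runs at the default kernel
hyperparameters (C = 1, γ = 1), yielding ~46% mean null accuracy.
At a planted standardized separation d = 3 (Bayes error
Φ(−1.5) ≈ 6.7%) mean LOO accuracy is ~94%; a margin-separated cohort
classifies perfectly. Patients are the positive class throughout.

## Determinism and I/O

Every random stage draws from `numpy.random.SeedSequence` spawns of
one integer seed; a cohort is a pure function of its spec, permutation
and ICA results of their seeds. Volumes are written as uncompressed
NIfTI-1 so reruns are byte-identical; the run manifest records the
config hash and a SHA-256 per output file and contains no timestamps,
making "same config ⇒ identical manifest" a checkable contract
(wall-clock timings go to the log stream instead).

## Problem sizes

Default simulations run at 18×22×18 voxels, 100 volumes and 20+20 or
40+37 subjects; calibration experiments use 10×10×10 null cohorts with
12+12 subjects and 200 permutations, and the planted-recovery check
uses 500 permutations over 10 seeds. These sizes keep the full suite
and the acceptance script in the minutes range on a single CPU while
leaving all statistical contracts testable.

## Known limitations

* No spatial realignment/normalisation or physiological noise: the
  generator produces pre-aligned, artifact-free (except planted
  motion coupling) data, so passing tests say nothing about
  registration quality or cardiac/respiratory confounds in real data.
* The ideal band-pass is a frequency mask, not an FIR/IIR filter;
  edge effects differ from DPABI-style filtering.
* Measured-NH clinical correlations are attenuated at desk-scale run
  lengths (see above); recovering full-strength correlations requires
  longer runs.
* Single-feature classification only; no multi-voxel pattern
  analysis.
* LOO grid selection reports optimistic accuracy by design of the
  emulated procedure; use `nested=True` for unbiased estimates.
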