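# Methods

This note documents the models implemented in sourcestorm, the defaults
and why they were chosen, the numerical decisions that affect results, and
what the synthetic validation does and does not demonstrate.

## Conventions

All internal quantities are SI: positions in meters, times in seconds,
magnetic fields in Tesla, potentials in Volts, dipole moments in A·m.
Millimeter coordinates are accepted only at ASCII import, where a median
point norm above 0.5 triggers a mm→m rescale (overridable). Epochs use a
closed time interval: `n_samples = round((t_max − t_min)·fs) + 1`.

## Forward models

### MEG: dipole in a spherically symmetric conductor

The external magnetic field of a current dipole in a spherical conductor
has a closed form that depends only on the sphere center; volume currents
contribute no radial field and conductivity cancels entirely. Two exact
identities follow and are tested: a dipole with radial moment produces
zero field, and the radial field component equals the Biot–Savart field of
the primary current alone — an independent derivation route used as the
oracle for the full closed form, together with a finite-difference check
that the field is divergence-free. Gradiometers are synthesized as the
difference of two magnetometer evaluations at `pos ± baseline/2` divided
by the baseline length.

The overlapping-spheres variant fits one sphere per MEG sensor to the
scalp vertices weighted by `exp(−d/σ)`, where `d` is the distance from the
scalp point nearest the sensor and `σ = 0.04 m`. The weighting width is a
free choice (the method itself does not prescribe one); 4 cm covers the
scalp patch a sensor actually sees while keeping fits stable. Sensors more
than 0.3 m from the scalp fall back to the global sphere with a warning.
On an exactly spherical scalp every per-channel sphere reproduces the
global fit to float precision.

### EEG: concentric multilayer sphere

The scalp potential of a dipole inside concentric shells is expanded in
Legendre harmonics; for each degree the radial solution in shell *j* is
`A_j r^n + B_j r^{−(n+1)}` plus the primary term in the innermost shell,
and the interface continuity conditions (potential and radial current)
with a zero-current outer boundary give a small linear system per degree.
The series is truncated at 80 terms by default (geometric convergence in
`(b/R)^n`; eccentricity 0.9 still converges to ~1e−4 by n = 80, and the
comparison oracles use 120–200 terms). Radii are normalized to the outer
radius before solving to keep the per-degree systems well conditioned.

For the homogeneous sphere the series sums in closed form via
generating-function identities (`Σ(2n+1)tⁿPₙ`, `Σ(2n+1)/n·tⁿPₙ′`). This
closed form is a separate code path and serves as the oracle for the
multilayer solver in the equal-conductivity limit (agreement at float
precision, asserted at 1e−8).

Defaults: shell radii 0.88/0.93/1.0 of the scalp radius, conductivities
0.33/0.0042/0.33 S/m — the standard brain/skull/scalp values used
throughout the sphere-model literature.

### Berg three-dipole approximation

Lead-field assembly approximates the multilayer potential of a dipole at
`r_q` by three homogeneous-sphere dipoles at `λ_j r_q` with moments
`μ_j m`. The (λ, μ) pairs are fitted once per head model by least squares
over a design grid of 9 eccentricities (0.1–0.9 of the inner radius),
radial and tangential moments, and 64 electrode directions. The fit is
greedy — each term is fitted to the residual of the previous ones, with a
joint polish only when the greedy residual is above 1e−5 — because a joint
three-term fit is unidentifiable when the shells are nearly homogeneous:
the lambdas then collapse toward 1 with large cancelling magnitudes. With
the greedy scheme the equal-conductivity limit cleanly degenerates to a
single unit term. Typical fit error against the exact series is ~0.03%
relative RMS; held-out dipoles at eccentricity ≤ 0.8 stay well under the
2% acceptance bound.

### Source spaces

Dipoles sit on the vertices of a decimated cortical mesh (default target
15,000, the conventional resolution for distributed imaging). Decimation
is a seeded nearest-seed vertex clustering: `target_n` original vertices
are kept as representatives, all others collapse onto their nearest
representative, and degenerate/duplicate faces are dropped. This keeps
every dipole exactly on an original cortical vertex, hits the target count
exactly (minus the rare representative left with no face), and decimates a
120k-vertex cortex in under a second. A quadric-error edge-collapse
decimator would preserve surface detail better but needs compiled support
not available here; for dipole placement the clustering scheme is
equivalent in practice. Constrained orientations are the area-weighted
vertex normals of the decimated mesh.

## Inverse methods

With whitener `W = C^{−1/2}` (eigendecomposition, eigenvalues below
1e−10·max treated as null space) and whitened gain `G̃ = WG`:

* **Minimum norm.** `K = R G̃ᵀ (G̃ R G̃ᵀ + λ²I)⁻¹ W`. The depth prior is
  `R_ii ∝ ‖g̃_i‖^{−2γ}` per source location with γ = 0.8 — the documented
  default of the MNE family this implementation follows. The prior shape
  is normalized to mean 1 and then globally scaled so that
  `trace(G̃ R G̃ᵀ) = n_channels`; with that scaling λ² = 1/SNR² (SNR = 3
  default) refers to unit whitened signal power and the kernel is
  invariant under a joint rescaling of data and noise covariance
  (data × s, C × s²). Without the trace scaling that invariance — and the
  scale invariance of the normalized maps — would silently fail.
* **dSPM** divides row *i* by `sqrt((K C Kᵀ)_ii)`; for unconstrained
  sources by the square root of the 3×3 block trace. Under pure noise the
  resulting map has unit variance per source (verified by Monte Carlo).
* **sLORETA** divides by `sqrt((R G̃ᵀ M⁻¹ G̃ R)_ii)` with
  `M = G̃RG̃ᵀ + λ²I`; for unconstrained sources the 3×3 block
  inverse-square-root is applied. By the Cauchy–Schwarz argument the
  normalized response to a noiseless dipole at *j* is maximal exactly at
  *j* for any diagonal prior, which the tests exercise (100/100 exact).
* **LCMV** operates on whitened quantities: `w = C_d⁻¹g̃/(g̃ᵀC_d⁻¹g̃)`
  (unit gain by construction), output time series `wᵀx̃` and neural
  activity index `wᵀC_d w / wᵀC_n w` (≈1 everywhere for noise-only data).
  A singular data covariance gets 5% diagonal loading with a warning.
* **MUSIC** takes the first `n` left singular vectors of the whitened data
  as the signal subspace and scores each location by the largest principal
  angle cosine between `span(g̃)` and that subspace (values in [0, 1]).

Noise covariance: empirical, per-epoch mean removed, diagonal loading
`C ← C + 0.1·mean(diag C)·I` by default, bad channels excluded. Mixed
EEG+MEG arrays are handled purely through whitening; no per-type scaling
factors exist anywhere else.

## Registration

The subject coordinate system places the origin at the preauricular
midpoint, +X through the nasion, +Y toward the LPA, +Z up. Device-to-
anatomy alignment is the 3-point rigid Procrustes fit (Kabsch, no
scaling); ICP then refines it using digitized head points.

ICP matches each point to the **closest point on the scalp surface**
(point-to-triangle, via a KDTree over triangle centroids plus an exact
barycentric projection), not to the nearest vertex: nearest-vertex
matching has a flat cost region of roughly half the inter-vertex spacing
(~2 mm on a 10k-vertex scalp) inside which no update signal exists, making
sub-millimeter convergence impossible in principle. The update step is the
linearized **point-to-plane** solve, which converges quickly along the
shallow rotational valleys of head-like surfaces where the point-to-point
Procrustes update crawls; a point-to-point fallback is used when the
linearized step fails to lower the RMS, and only RMS-lowering steps are
accepted, so the accepted RMS sequence is non-increasing. On noiseless
head points sampled from an aspherical scalp, random rigid perturbations
up to 10° / 1 cm are recovered to machine precision.

Registration test surfaces must be aspherical — on a perfect sphere the
rotation is unidentifiable — so the generator provides a head-like scalp
(ellipsoidal axes, nose- and occiput-like protrusions, seeded bumps) for
this purpose, while the forward-model head keeps a spherical scalp
consistent with the concentric-sphere EEG model.

## Time-frequency

Morlet wavelets are parameterized by their shape at a reference frequency:
temporal FWHM of 3 s at 1 Hz, scaled as `σ_t(f) = σ_t(f0)·f0/f`, truncated
at ±4σ, L2-normalized. Decomposition is FFT-based complex convolution with
'same' alignment and zero padding; samples within 2σ_t of an edge carry an
invalid flag. Band grouping averages power (never complex coefficients)
over bins whose center falls inside the closed band interval; trials are
averaged before band grouping.

## Scouts and surface projection

Scout aggregation offers the plain mean, the sign-flipped mean, and the
first principal component (rescaled to the scout's mean variance,
sign-aligned with the mean trace). The sign-flip reference is the
principal axis of the scout's orientation cloud, not the mean orientation:
the mean cancels for exactly opposite sulcal banks, the case sign-flipping
exists to fix.

Surface projection runs per hemisphere: landmark-based rigid
pre-alignment, Laplacian smoothing of both surfaces (50 iterations, factor
0.5), ICP of the smoothed source surface onto the smoothed target, then
Shepard inverse-distance interpolation (k = 8, power 2; exact at
coincident nodes; convex weights, so outputs stay within the input range).
Laplacian smoothing pins open-boundary and isolated vertices: letting the
interhemispheric cut contract would deform the shell and bias the ICP.
A sphere shrinks under the defaults by about `iterations·factor·θ²/2`
with θ the angular vertex spacing — under 2% at ~10k vertices.

## Statistics

Permutation tests use sign flips (paired) or label shuffles (unpaired),
enumerate exhaustively when the number of arrangements is at most
`n_perm`, and report `p = (1 + #{|T*| ≥ |T|})/(1 + n_perm)` for sampled
permutations (the exact `#/N` for exhaustive ones) — never zero. The
default paired statistic is computed by a closed-form vectorization over
sign patterns (`Σd_i²` is flip-invariant); the exceedance comparison uses
a relative slack so the identity arrangement always counts.

The balanced n-way ANOVA decomposes sums of squares by marginal cell means
and inclusion–exclusion over factor subsets, vectorized over map elements;
unbalanced designs are rejected rather than silently choosing a SS type.
Residual mean squares are floored at a relative 1e−30 so constructed
noiseless designs report a large finite F. Thresholding wraps
Bonferroni and Benjamini–Hochberg (statsmodels) and implements
max-statistic familywise control from the stored permutation null.

The two-level group analysis averages each subject's usable trials,
summarizes two time windows, and runs a paired test across subjects;
optional precision weights are inverse within-subject variances and reduce
exactly to the unweighted test when variances are equal.

## Synthetic data

The generator emulates: concentric icosphere scalp/skull, a bumpy
two-hemisphere cortex strictly inside the inner shell with per-vertex
hemisphere labels and anatomical landmarks, Fibonacci-spiral EEG on the
scalp, radial magnetometers 2 cm outside it, digitized head points,
Gaussian-pulse or sinusoidal source time courses, and white / AR(1) /
arbitrary-covariance sensor noise. White noise is homogeneous within a
sensor kind, with per-kind scales set from the RMS of that kind's gain
rows and a single global factor calibrated to the requested epoch SNR —
instrument noise does not follow a channel's source sensitivity, and mixed
V/T units need per-kind scales in any case. Everything derives from one
master seed; identical specs give byte-identical output.

Group cohorts draw per-subject sub-seeds, a ±5% head-size jitter (applied
as a gain scale), and effect amplitudes from `N(d, 0.2·d)` active only in
the post-stimulus window.

What this does **not** emulate: correlated physiological background
(alpha rhythms, cardiac/ocular artifacts), realistic cortical folding and
conductivity inhomogeneity, sensor drift and line noise, or head movement.
Passing tests therefore demonstrate internal correctness of the models and
estimators under their own assumptions — not performance on real
recordings, where forward-model error and structured noise dominate.

## Validation problem sizes

The end-to-end checks (`sourcestorm.validation`, `scripts/acceptance.py`)
use a 2000-dipole constrained source space with 32 EEG + 64 MEG channels
for localization (100 trials at SNR 10), a 300-dipole space for the
500-simulation group-power pipeline (12 subjects, 20 trials each, 125 Hz),
and 4000–20000 null simulations for the calibration rates. These sizes
give each Monte-Carlo estimate enough precision that the nominal
acceptance bands act as deterministic checks of calibration rather than
coin flips, while a full run stays around a minute on one CPU.

## Known limitations

* Sphere models only; no BEM/FEM, no realistic shells.
* MN peak localization carries the method's intrinsic superficial bias
  (~1 cm median on these fixtures); use the normalized maps for
  localization claims.
* ICP assumes clean head points (no outlier trimming) and a reasonable
  initialization (fiducial alignment); it is a local method.
* The multilayer EEG solver assumes concentric spherical shells and a
  dipole strictly inside the innermost shell.
* ANOVA is fixed-effects, balanced, fully crossed, at most 4 factors.
* The study database tracks files and provenance but performs no locking;
  concurrent writers are the caller's responsibility.
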