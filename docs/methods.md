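# Methods

## Scope and model

`motoret` re-creates, on synthetic data, the cryo-electron-tomography
analysis used to characterize stator–rotor interactions in the
*Borrelia burgdorferi* flagellar motor: subtomogram averaging with
missing-wedge compensation, rotational-symmetry determination, focused
classification of the 16 stator sites with an occupancy statistic, and
ellipse-fit measurement of the C-ring wall tilt.  Real tomograms are
replaced by a parametric motor phantom whose ground truth encodes the
published strain geometry, so every estimator can be validated by parameter
recovery.

### Coordinate and pose conventions

One convention, defined in `volume_io` and used everywhere: right-handed
frame, z = motor rotation axis pointing from the C-ring toward the hook,
origin at the MS-ring center; volumes are indexed `[z, y, x]` with 0-based
voxel centers on integer coordinates; Euler angles are ZYZ intrinsic in
degrees normalized to [−180°, 180°); a pose acts rotate-then-shift about
the volume's origin voxel; interpolation is trilinear throughout.  Poses
stored in particle tables map a subtomogram *into* the canonical motor
frame (so the alignment of a particle that was physically rotated by R is
R⁻¹).

## The motor phantom

Each structural element is a sum of isotropic Gaussian blobs or a smooth
analytic body, so diameters, tilt and per-site density integrals have
closed forms:

| element | geometry | default |
|---|---|---|
| C-ring | 46 subunit columns on a frustum wall | bottom radius 28 nm, wall height 11 nm, strain tilt |
| collar | 16 blobs (σ 2.0 nm) | radius 40 nm, z = +7 nm |
| stator sites | up to 16 blobs (σ 2.5 nm) at occupied sites | radius 40 nm, z = −1 nm |
| MS-ring | analytic torus | radius 11 nm at z = 0 |
| rod | soft-edged cylinder along +z | radius ~2 nm |
| membrane | soft-edged slab | z = 4 nm, thickness 4 nm |

The wall height of 11 nm is the value that reconciles the published ring
diameters with the published tilt angles: 2·(28 + 11·tan 7.8°) ≈ 59 nm for
the stator-free mutant top ring and 2·(28 + 11·tan 1.8°) ≈ 56.7 ≈ 57 nm for
WT, with a common 56 nm bottom.  Each C-ring subunit is a column of blobs
(σ 1.2 nm, spaced ~1.8 nm along the wall) rather than a single blob so that
the wall has axial extent for the tilt measurement.  With 46 subunits on a
28 nm ring the angular blob spacing is 3.8 nm, resolvable at the default
1.25 nm voxel.

Strain presets (the study conditions): WT (tilt 1.8°, per-site occupancy
0.97), motB-D24E (3.2°, exactly 10 of 16 sites), motB-D24N (6.6°, 7/16),
ΔmotB (7.8°, 0/16), CCCP-treated WT (5.1°, 16/16).  All share n_cring = 46,
n_collar = 16, bottom radius 28 nm, stator radius 40 nm.

### Simulation

The default grid is 96³ voxels at 1.25 nm/voxel (120 nm field), which holds
the 80 nm stator ring with 20% margin at minutes-scale FFT cost.  Per
motor: sample site occupancy, render the phantom, perturb the pose by a
uniform jitter (default ±2° per Euler angle, ±1 voxel per shift axis —
the residual scale left after the coarse particle picking the particle
table's nominal poses stand in for), apply the ±60° single-axis missing
wedge in the perturbed frame by multiplying the Fourier transform with the
binary coverage mask, and add white Gaussian noise.  SNR is defined as
signal variance inside a cylindrical motor mask divided by noise variance;
the default 0.5 puts individual stator sites near the classification limit,
which is the regime the classification stage is meant to handle.

What the simulator does **not** model: CTF and defocus effects, weighted
back-projection artifacts beyond the wedge itself, membrane curvature,
structural heterogeneity of the subunits, detector differences, or
correlated noise.  Passing recovery tests therefore demonstrate the
correctness of the estimators under the stated noise/wedge model, not
performance on real tomograms.

## Missing-wedge machinery

A frequency is covered iff its inclination out of the untilted specimen
plane, `psi = atan2(k·beam, k·(axis×beam))` wrapped to [−90°, 90°), lies in
the tilt range; the tilt-axis line is always covered, and Nyquist bins are
OR-ed with their conjugate partners so masks are exactly Hermitian.  Masks
are evaluated analytically on the (rotated) frequency grid — never
resampled — so they stay binary and pooled coverage counts are exact
integers.  Note that the fraction of *cube-grid* voxels covered by a ±60°
wedge is 1 − 1/(2·tan 60°) ≈ 0.711 (corner effect); the solid-angle
fraction, measured over voxels inside the Nyquist sphere, is the textbook
2/3.

Constrained cross-correlation normalizes only over the intersection of the
two volumes' pose-rotated wedge supports (DC excluded).  Fourier-space
class averaging accumulates each particle's rotated transform and wedge
mask and divides by per-voxel coverage.  Half-set FSC uses one-voxel shells
on a seeded random split; resolution is the first linear-interpolated
crossing below the threshold (0.5 and 0.143 reported), Nyquist if never
crossed.

### Alignment

`align_particle` is a deterministic exhaustive search (z-rotation capped
separately from the two off-axis tilt parameters, integer shifts scored for
all translations at once via the FFT correlation map) followed by one local
half-step refinement; ties break toward the lexicographically smallest grid
pose.  A Gaussian low-pass (default cutoff 0.25 cycles/voxel) is applied to
the reference during scoring.  For whole-motor registration before site
extraction — where the pose error is known to be small — `refine_pose_local`
runs a bounded Powell search on the real-space NCC of 2×-binned volumes;
binning raises per-voxel SNR ~2.8× and cuts rotation cost ~8×.  At SNR 0.5
it recovers the jittered pose to ~1° / ~0.4 voxel in about a second per
motor, which is what the occupancy statistic needs (a 1° residual moves a
40 nm-radius site by 0.7 nm, well inside the 6 nm scoring mask).

## Symmetry detection

Density is resampled onto a cylindrical (θ, z, r) shell (4·n_max angular
samples for Nyquist margin at order 46 in a 96³ box; default C-ring shell
r ∈ [24, 32] nm, collar/stator shell r ∈ [34, 46] nm), averaged over z and
r, and Fourier-analyzed in θ.  A ring of N subunits excites orders N, 2N, …
and never divisors of N, so the fundamental is the candidate maximizing
`power(m) + power(2m)/2`.  Two significance guards: the winning power must
exceed 3× the median candidate power, and its raw power must exceed 10⁻⁵ of
the DC power (a continuous torus otherwise "detects" whatever order its
interpolation residue lands on).  On wedge-filtered maps the wedge imprints
an m = 2/4/6 angular envelope (measured: m=2 carries more normalized power
than m=46 on the C-ring shell), so the pipeline restricts candidates to
orders ≥ 10 there; noiseless phantoms are scanned from order 2.

## Stator-site classification and occupancy

The 16 sites of a registered motor are resampled into one canonical frame
(site at (+40 nm, 0, −1 nm)) in a single interpolation pass per site.  Each
site is scored by its mean density inside a 6 nm sphere at the canonical
stator position (the cytoplasmic stator portion is ~8 nm across), minus the
same mask displaced half a site spacing tangentially — an off-site control
that removes membrane/offset contributions and gives stator-free sites an
absolute zero.

Two systematics remain at SNR 0.5: the wedge smears neighboring density
anisotropically, making occupied-site scores depend on azimuth (~40%
site-to-site variation), and registration residuals attenuate scores.  The
azimuthal part is removed by a per-site calibration: the expected score of
every site is computed once on noiseless wedge-filtered fully-occupied
(aₖ) and fully-empty (bₖ) reference phantoms, and scores are mapped to
`(s − bₖ)/(aₖ − bₖ)`, an absolute scale with 0 = empty and 1 = occupied.

Labels come from a two-component 1D Gaussian mixture (seeded, means
initialized at the 10th/90th score percentiles): occupied/empty when the
posterior for the high/low component is ≥ 0.8, ambiguous otherwise.  An
absolute floor at 0.5 on the calibrated scale handles the degenerate
ensembles a relative mixture cannot: when both fitted component means fall
on the same side of the floor (all-empty ΔmotB, where the mixture would
happily split noise; all-occupied CCCP; a single occupied site among 15),
sites are labeled directly by the threshold.  Occupancy = occupied sites /
all sites, with ambiguous sites kept in the denominator; mean stators per
motor = occupancy × 16.

## Ring geometry and tilt

Diameters: cylindrical radial profile (1-voxel bins) over a z-slab, peak
located by parabolic sub-bin interpolation, diameter = 2× peak radius.
Slabs used: bottom of the C-ring wall (z ∈ [−14, −11] nm), top (z ∈ [−6,
−3] nm), stator ring (z ∈ [−4, 2] nm).

Tilt: (1) 16-fold symmetrization and axial cross-section extraction, fused
into one interpolation pass (the cross-section of the symmetrized map
equals the average of planes sampled at the 16 azimuths; one resampling
instead of 17 keeps the thin wall sharp); the plane is sampled at
half-voxel steps and averaged over a ±1 voxel slab.  (2) per wall
(left/right of the axis), voxels in the window r ∈ [24, 34] nm, z ∈ [−14,
−3] nm minus the top 2 nm (the FliG_N cap) are selected above the 0.75
density quantile.  Selection is *soft*: weights are the density excess over
the threshold, because hard thresholding quantizes the wall centroid to the
sample grid and biases small tilts by several degrees.  (3) an ellipse is
fitted by intensity-weighted second moments; tilt = angle between the major
axis and the rotation axis, in [0°, 90°], averaged over the two walls, with
a quality flag if they disagree by > 2° (after 16-fold symmetrization the
two walls are mirror images, so on symmetrized input they agree exactly).
A weighted direct least-squares conic fit (ellipse-constrained) is provided
as an independent cross-check; the two agree within 0.5° on all noiseless
presets.  For walls much steeper than the presets the fixed 0.75 quantile
admits relatively more background (the wall fills less of its enclosing
window); the quantile is a config parameter for that case.

## Pipeline and reproducibility

`run_strain` chains simulate → register → Fourier-average → FSC → symmetry
→ site classification → geometry, writes MRC/TSV/JSON artifacts, and is
byte-identical for a fixed (config, seed).  `compare_strains` tabulates
occupancy, stators/motor, tilt and diameters across strains and checks the
expected tilt ordering ΔmotB > D24N > D24E > WT.  All randomness (occupancy
sampling, pose jitter, noise, FSC splits, mixture seeding) flows from
`numpy.random.default_rng` seeds given explicitly.

Problem sizes used by the recovery suite and the acceptance script: 96³
voxel grids, 32 motors per strain ensemble at SNR 0.5 — large enough that
binomial sampling error on 512 sites (~0.8 pp at p = 0.97) is negligible
against the ±5 pp recovery tolerance, and small enough for a desk-scale
run.

## Known limitations

* The classification calibration uses the simulator's own noiseless
  forward model as reference; on real data the analogous anchors would
  have to come from class averages of confidently occupied/empty sites.
* `align_particle`'s exhaustive grid is meant for small search spaces
  (focused refinement); it is not a global orientation search.
* The wedge model ignores dose weighting and CTF; resolution numbers from
  the synthetic FSC say nothing about attainable resolution on real data.
* Sub-voxel shift refinement is not implemented in the exhaustive aligner
  (integer shifts only); the local Powell refiner is continuous.
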