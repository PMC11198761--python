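# Methods

## The measurement chain

MRE phase volumes arrive as 6 encoding directions (±x, ±y, ±z) × 8
phase offsets over one 60 Hz vibration period. All spatial grids are
indexed 0-based with axial slices along the third axis; NIfTI affines
are passed through untouched.

**Displacement.** Each axis is encoded twice with opposite gradient
polarity; the half-difference `u_d = (φ₊d − φ₋d)/(2s)` cancels
common-mode phase. The sensitivity `s` defaults to 1 rad per
displacement unit because the end product (NOSS) is invariant to it;
supply a physical value only if absolute displacement matters. Phase is
assumed unwrapped — unwrapping is a precondition, not an operation of
this package.

**Strain and OSS.** The small-strain tensor
`ε_ij = ½(∂u_i/∂x_j + ∂u_j/∂x_i)` is computed with central differences
in the interior and one-sided differences at grid edges, per
millimetre. No smoothing is applied before differentiation by default;
an optional Gaussian pre-filter (σ in mm, `smooth_sigma_mm`) is exposed
and off by default. The octahedral shear strain is evaluated per offset
and averaged over the 8 offsets. OSS equals (2/3)·√(sum of squared
principal-strain differences) and is therefore rotation invariant —
the test suite verifies this to 1e−6 relative through the full
finite-difference pipeline.

**Amplitude and NOSS.** The combined motion amplitude is the root sum
of squares of the per-component single-sided first-harmonic amplitudes,
`A_c = 2|X₁|/8` with `X₁` the DFT bin k = 1 of the 8-sample series.
NOSS = mean OSS / A. Voxels with `A < ε_amp` are masked (NaN) and
excluded from every downstream extremum; the default guard is
scale-free, `ε_amp = 10⁻³ × median(A over the brain mask)`, so that
rescaling the drive amplitude changes nothing. A dataset with no valid
voxel raises an error — the in-silico analogue of a technically failed
exam with insufficient wave amplitude.

## SIR

Per axial slice whose ROI has ≥ `min_roi_pixels_per_slice` (default 5)
pixels: the rectangular partial (RP) NOSS image is the ROI bounding box
padded by `rp_pad_vox` (default 3) pixels, clipped at slice edges, and
divided by its own maximum valid intensity (per-slice standardization;
an all-zero RP is flagged degenerate and left unchanged). The boundary
is every ROI pixel with a face-neighbor outside the ROI, ordered by a
clockwise Moore-neighbor trace per 8-connected component starting at
the lexicographically smallest boundary pixel (fully deterministic). A
trace around a one-pixel-wide protrusion revisits pixels; first
occurrences are kept, so each boundary point is classified once.

At each boundary point a 3×3 patch (center included — "9 pixels")
is taken; if `|patch mean − I(a)| < 0.065` the patch grows to 5×5.
Patch entries overhanging the RP are filled by edge replication, which
together with the default pad guarantees every patch is complete;
masked entries are excluded from the patch statistics. The decision
function, evaluated in order:

* **Condition I** — `I(a) > 0.85 × RP_max` or `I(a) < 1.15 × RP_min`.
  With standardization `RP_max = 1` and `RP_min` is usually ≈ 0, so the
  lower branch rarely fires; both bounds are parameters.
* **Condition II** — `|I(a) − patch mean| > τ`, `τ = 0.20 × (patch
  range)`.
* **Condition III** — `|I(a) − patch mean| ≤ τ` and `patch range >
  0.80 × I(a)`. The equality case `|diff| = τ` is deliberately assigned
  to Condition III's gate; the strictly-worded pair of inequalities
  would otherwise leave a dead zone.

A point is non-adherent if any condition holds; `fired_condition`
records the first. The non-adhesion percentage pools point counts over
all slices (boundary-point count as a proxy for interface length,
in-plane spacing being isotropic); per-slice tallies are also reported.
A boundary point whose own NOSS is masked is excluded from the
denominator and counted in an `n_unanalyzable` tally — how such points
were handled originally is unknown, so they are surfaced rather than
silently dropped. Because each RP is standardized, the output is
exactly invariant to global rescaling of the NOSS map.

Threshold defaults (0.065, 0.85/1.15, 0.20, 0.80) are the published
operating point of the decision function; they were derived on a
training subset of the original patient cohort and are taken as given
here, exposed in `SIRParams`. Parameter validation is deliberately
permissive so limiting configurations (a condition disabled, a
threshold at 0 or 1) remain expressible.

## The phantom

The generator emulates one MRE acquisition with known ground truth. A
spherical tumor (default radius 12 mm) sits in a 64×64×32 grid at
(1.875, 1.875, 3.0) mm — the in-plane resolution of a 24 cm FOV
reconstructed at 128, with 3 mm slices. The background carries a
superposition of two transverse plane waves at the vibration frequency:
a primary wave (10 µm, 30 mm wavelength — a typical brain shear
wavelength at 60 Hz — propagating along z, polarized along x) and a
weaker secondary wave (5 µm, 24 mm, along y, same polarization, fixed
phase offset). The second wave matters: a single plane wave has
spatially constant mean OSS and amplitude, hence constant NOSS, and a
constant RP makes the per-RP standardization degenerate (every point
sits at the maximum and Condition I saturates). Two-wave interference
gives the background the smoothly varying NOSS that real tissue shows.

The slip region is a spherical-cap sector around `slip_axis` with cap
half-angle θ* solving `(1 − cos θ*)/2 = slip_fraction`, so the cap's
ideal-sphere area fraction equals the requested fraction; a contiguous
cap mirrors surgical descriptions of contiguous adherent interface.
Surface voxels (face-neighbor definition) inside the cap are labeled
slip, and the realized fraction is the labeled-to-total voxel ratio.

Underneath the cap the interior oscillates as the phase-lagged,
amplitude-rescaled copy of the full background field (defaults: equal
amplitude, π/2 lag — a stiff tumor moving out of phase), producing a
sharp displacement discontinuity at the boundary and hence the bright
NOSS rim of a slip interface. Underneath the adherent sector the
interior follows the exterior field exactly, so that interface is
strain-free — the defining image feature of adhesion. A linear angular
ramp of arc width `blend_width_vox` voxels (default 2), centered on the
cap edge, joins the two interior regimes so the seam itself does not
create a spurious strain sheet; an earlier radial blend-shell variant
was abandoned because any radial ramp still concentrates strain at the
adherent interface, which per-RP standardization then amplifies into a
false slip signature. Displacement is encoded into phase as
`φ±d = ±s·u_d + η` with i.i.d. Gaussian noise (default SD 0.02 rad)
drawn from a single seeded generator; the brain mask is the grid minus
a 2-voxel border.

What the phantom does **not** model: viscoelastic propagation,
attenuation, reflections at the skull, stiffness inversion, scanner
artifacts, phase wrapping, irregular tumor shapes, or any mechanical
theory of how adhesion alters wave transmission. Passing phantom tests
therefore demonstrates that the pipeline detects displacement-field
discontinuities against a smooth background — the image signature the
method relies on — not clinical performance.

On these phantoms the SIR non-adhesion percentage runs ≈ 70% for a
fully adherent tumor and ≈ 97% for a fully slipping one, increasing
monotonically in between: SIR is a sensitive detector and its absolute
level depends on the background texture, so the percentage is
informative relative to its operating range, consistent with adhesion
percentages spanning roughly 20–67% in patients. The boundary-entropy
baseline is *lower* for fully slipping phantoms than adherent ones
here: the rim dominates both sides of every boundary normal, narrowing
the distribution of across-boundary differences. Its discriminating
direction is therefore data-dependent, one reason a boundary-point
classifier is preferable to a distributional summary.

## Boundary-entropy baseline

The comparison metric samples standardized NOSS along outward boundary
normals (central-difference tangents, outward orientation decided by
probing the ROI), takes the outside-minus-inside mean difference per
point (depth 2 voxels each side, nearest-voxel sampling, masked or
out-of-RP samples dropped), and reports the Shannon entropy (bits) of
the 32-bin histogram of these differences on [−1, 1]. The original
description leaves depth, binning and logarithm base unspecified, so
this module is an explicit reconstruction with configurable defaults,
not a numeric replication.

## Evaluation statistics

* **Cohen's κ** (unweighted) with the Fleiss–Cohen–Everitt (1969)
  asymptotic SE and κ ± 1.96·SE as the 95% CI. Agreement follows the
  table's diagonal by default; an explicit `col_mapping` permutation
  supports alternative category pairings (the clinical pairing
  "complete cleft ⇒ non-adhesion" is the reversed mapping and gives a
  different value). On the published 3×3 CSF-cleft table this yields
  κ = 0.057 with CI (−0.13, 0.24). Since the original software's SE
  formula is unknown, CI agreement is treated as approximate (±0.02).
* **AUC** as the normalized Mann–Whitney U with half-credit ties,
  verified against exhaustive pair counting.
* **DeLong's test** from the structural components V₁₀/V₀₁ (sample
  covariances, ddof 1); a zero-variance difference is flagged
  degenerate with z = 0, p = 1 instead of dividing by zero.
* **ICC(2,1)** — two-way random effects, absolute agreement, single
  measure — from the two-way ANOVA mean squares; cross-checked against
  an independent implementation in the tests. The absolute-agreement
  form is chosen because a systematic offset between two raters'
  segmentations should count against reliability.

## Numerical choices and edge cases

* Masked voxels are NaN everywhere; all extrema/means are computed
  over valid entries only.
* An RP whose valid maximum is 0 is flagged `degenerate` and left
  unscaled.
* `slip_fraction` 0 and 1 bypass the cap-angle computation so that no
  voxel / every voxel is labeled regardless of lattice discretization.
* Slices with ROI area < 5 pixels are skipped (degenerate apical-cap
  RPs); the threshold is a parameter.
* Phantom problem sizes (64×64×32 grid; 20 + 20 phantoms for the
  separation experiment, 5 seeds × 5 fractions for monotonicity) were
  chosen so a full acceptance run completes in well under a minute on
  one CPU while keeping > 200 boundary points per tumor.

## Known limitations

* Slice-wise (2D) boundary analysis, as in the original: no 3D surface
  meshing, so near-polar slices contribute short contours.
* The adherent/slip forward model is an artifact of this package; the
  method's clinical claims cannot be validated on it.
* The Condition-I lower branch is nearly inert once RP_min ≈ 0, which
  is typical after masking-free standardization; it is retained for
  fidelity and parameterized.
* Cohen's κ CI reproduces the published interval only to the precision
  that the unknown original SE formula permits.
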