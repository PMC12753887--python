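# Methods

## The simulation model

`cordsim` simulates longitudinal spinal cord atrophy as a purely
*cord-local*, in-plane areal contraction. The model makes three
assumptions: (i) atrophy expresses as a reduction of cord
cross-sectional area (CSA), uniform within each axial slice; (ii) the
surrounding anatomy — CSF, canal wall, vertebrae — is unchanged between
time points; (iii) the appearance change at the cord boundary is the
partial-volume consequence of the smaller cord, nothing else. A
prescription of `a` percent is therefore interpreted as percent *CSA*
loss, giving the linear in-plane scale `s = √(1 − a/100)`. The areal
reading makes the prescription directly comparable to the CSA-difference
estimate used for evaluation; a linear reading would simply relabel the
grid (`a_linear = 1 − s`).

### Pipeline

1. **Stripping.** The binary cord mask is dilated per axial slice with a
   lattice-disc structuring element (offsets with `dx² + dy² ≤ r²`) and
   the patch is excised. The margin exists so the cord's partial-volume
   skirt travels with the cord; it must therefore clear the image
   point-spread tail. With the default phantom PSF (0.3 mm in-plane
   Gaussian at 0.5 mm pixels) a radius of 3 px is the smallest margin
   whose outer rim is indistinguishable from pure CSF; it is a recipe
   parameter (`se_radius`).
2. **Canal filling.** The excised region is replaced by the unique
   discrete-harmonic interpolant of its 1-voxel rim: per axial slice the
   Dirichlet problem for the 5-point Laplacian, assembled sparsely and
   solved with a direct sparse solver. Per-slice solving matches the
   per-slice character of the rest of the pipeline; a 7-point 3-D variant
   exists behind `mode="3d"`. Interior values obey the discrete maximum
   principle, and voxels outside the region are untouched bit-exactly.
3. **Scaling.** The cord is carried as the *residual* of the template
   over the filled canal. The residual decays to zero at the patch rim,
   so shrinking it and adding it back creates no seam, and the
   partial-volume ramp at the cord edge is interpolated exactly once.
   (Blending the raw stripped image against its own scaled soft mask
   would double-interpolate the edge — alpha times an already-ramped
   intensity — which measurably biases intensity-derived CSA and shows up
   as a seam.) Both the residual and the mask are resliced by the
   inverse-mapped trilinear interpolant about the per-slice mask centroid
   (the fixed point; the shrunken cord stays centered in its canal),
   evaluated with *area-weighted* sampling: the bilinear pullback
   averaged over a 4×4 subpixel grid per output pixel. Single-point
   resampling carries a systematic boundary (aliasing) bias of a few
   tenths of a percent of the integral — the same order as the smallest
   prescriptions — whereas with area-weighted sampling the soft mask's
   sum and the integrated residual track `s²` to about 5·10⁻³ relative.
4. **Compositing.** Soft mode (default) alpha-blends with the scaled
   dilated-mask stencil; hard mode replaces above a threshold. After
   compositing, all voxels outside the dilated mask are restored
   bit-exactly from the template, making locality an invariant rather
   than a numerical accident.

### Noise model

Magnitude MR noise is Rician: `NI = √((I + n₁)² + n₂²)` with two
independent zero-mean Gaussian channels of equal standard deviation
`σ_l = n_l · m_sc`, where `n_l ∈ {0, 1, 2, 4, 8}%` and `m_sc` is the
median intensity inside the cord mask of the noise-free volume. `m_sc`
is measured once per template, before atrophy, so all atrophy levels of
one "subject" share a σ per level and baseline/follow-up noise is
statistically identical. Noise is applied after atrophy simulation.
Seeded; a zero level returns the input bit-exactly. `antithetic=True`
negates both channels of a seed's draw — the experiment runner draws odd
repetitions as antithetic twins of their predecessor, a standard Monte
Carlo variance-reduction device that removes the linear noise term from
seed averages and makes small-noise RMSE estimates stable at realistic
seed counts.

## The synthetic template

The phantom emulates the inputs the pipeline expects from a real
template: a bright cord (T1-w contrast) inside a dark CSF ring and a
canal wall, plus mid-disc landmarks (C1, C2/C3, C5/C6) defining the
C1C2/C2C5/C1C5 segments. Defaults, chosen once for anatomical
plausibility: 64×64×60 grid at 0.5×0.5×1.0 mm; elliptical cord
cross-section (minor/major 0.85, area-preserving) of 4 mm equivalent
radius with a 0.6 mm peak-to-peak smooth taper, 0.3 mm centerline drift
and a slow axial twist; CSF ring to 7 mm, wall to 8.5 mm; intensities
100/30/60/10 (cord/CSF/wall/background); 0.3 mm in-plane Gaussian PSF;
smooth intra-tissue texture of sd 3 intensity units and 0.8 mm
correlation length. The irregular geometry and texture are not
decoration: a perfectly circular, constant-intensity phantom centered on
the lattice phase-locks discretization, so scale-free statistics such as
Cohen's d (whose denominator is the within-ring sd) become degenerate and
report artifacts no real image would show. What the phantom does *not*
emulate: vertebral anatomy and bone texture, lesions or other pathology,
bias fields, motion, multi-coil noise correlations. Tests passing on the
phantom therefore demonstrate the correctness of the simulation and
measurement machinery under clean, known geometry — not robustness to
real-world confounds.

## Measurement backends

* **Mask backend** (`compute_csa`): per-slice area is the sum of
  (fractional) mask values times pixel area. Reading the simulation's
  own soft mask, it is the ground truth and is noise-blind. Ground-truth
  recovery over the 0.5–10 % grid is within ±0.04 points and strictly
  monotone.
* **Image backend** (`csa_from_image` via `measure_atrophy`): integrates
  the partial-volume fraction `(I − csf)/(cord − csf)` over a dilated-mask
  ROI, with cord/CSF references taken as medians of deep-cord and
  outer-band regions of the image itself (self-calibrating under the
  Rician intensity shift). Kept linear (unclipped) so zero-mean texture
  and noise cancel in expectation. This is the package's stand-in for
  image-driven CSA tools; it sees the image, so noise degrades it. It
  carries a smooth systematic error of +0.02 to +0.32 points over the
  grid (interpolation of the resolved cord edge) — within the error scale
  reported for commercial CSA tools on comparable tasks — whose sign is
  aligned with the Rician intensity shift, so measurement RMSE grows
  monotonically with the noise level.

## Numerical choices and degenerate inputs

* Thresholding soft masks uses strict `> level`; the 0.5-threshold count
  of a resampled disc is quantization-limited (±0.03–0.04 of area per
  slice for any interpolating resample), so area-accurate consumers use
  the soft sum.
* Voxels whose centers fall exactly on the cord boundary (possible only
  for degenerate integer-radius configurations) are excluded (`< r`).
* Lattice-disc voxel counts differ from `πr²` by the Gauss-circle error
  (≈3.5 % at r = 8 px); analytic-area checks use that bound, not an
  idealized one.
* `rescale_inplane` clamps out-of-grid samples to the edge (constant
  volumes stay constant); mask scaling pads with 0 (background).
* Empty mask slices pass through scaling unchanged; an empty fill region
  is a no-op; a fill region touching the slice edge is an error.
* Warp application uses trilinear pullback with nearest-edge policy (no
  zeros introduced into CSF); field inversion is fixed-point iteration,
  adequate for smooth diffeomorphic-scale warps.
* Atrophy estimates are segment means of per-slice areas (not medians).
* No multiple-testing correction is applied anywhere; p-values are
  per-comparison.

## Boundary-ring check

Reinsertion integrity is tested on the 2-pixel ring (dilate − erode with
the radius-1 cross) at the boundary of the *stripped* (dilated) mask —
the seam of the reinserted patch, which is where compositing artifacts
would physically appear. Comparing rings tied to the cord edge itself is
not well-posed on a lattice: the ring can track the sub-pixel edge only
in whole-pixel quanta, so even an artifact-free simulation shows
|d| ≈ 0.1–0.4 there. At the patch seam the statistic is stable and the
simulation achieves |d| ≤ 0.015 and p > 0.4 across the full grid.

## Subject-space scope

Cord segmentation, vertebral labeling and template registration are
external tools (the Spinal Cord Toolbox); `run_external_registration`
only builds and runs their command lines (with a dry-run mode and
distinct error types for missing tools vs. bad data). In-repo computation
is limited to applying dense mm-displacement fields, inverting them
numerically, and the KS table quantifying whether warping preserved the
simulated atrophy signal. That comparison is meaningful in the regime
where the atrophy difference field is spatially resolved (PSF ≳ 2 pixels,
as in real templates); with a deliberately sharp phantom PSF the
difference field is an under-resolved thin annulus whose histogram any
fractional-offset interpolation reshapes, and D is dominated by that
artifact.

## Problem sizes

Default experiment: 9 atrophy levels × 5 noise levels × seeds on the
64×64×60 phantom; with 10 seeds per cell this is ~450 noise draws and 10
simulations, about 1–2 minutes on one CPU. These sizes were chosen so the
full grid is a routine desk-scale run while keeping ≥ 10⁴ cord voxels per
statistic.

## Known limitations

Uniform in-plane contraction only (no asymmetric or lesion-driven
atrophy, no through-plane shrinkage); no bias fields or motion; the
image backend is a deliberately simple stand-in, not a replica of any
commercial CSA algorithm; KS p-values are asymptotic; subject-space
evaluation with real registration requires the external toolbox and
template data.
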