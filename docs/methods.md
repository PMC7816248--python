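# Methods

## Signal model

A low-resolution sodium image voxel mixes the pure tissue signals in
proportion to the tissue content of the voxel:

    S_r = P_GM,r · M_GM,r + P_WM,r · M_WM,r + P_CSF,r · M_CSF,r

where `P_t,r` are tissue probabilities from a segmentation resampled to
the sodium grid and `M_t,r` the pure (partial-volume-free) tissue
intensities. One voxel gives one equation with three unknowns, so the
pure intensities are assumed constant over a small kernel around each
voxel and estimated by least squares from the stacked kernel rows. Two
simplifications follow the standard practice for brain sodium imaging:
CSF-labelled voxels are removed from the kernel (leaving the two
unknowns `M_GM`, `M_WM`), and the CSF contribution to the *measured*
signal is removed beforehand by the spill-in correction described below.

### Spill-over (spill-in) correction

    S_target = S − Σ_t (S_t ⊗ PSF) · (P_t ⊗ PSF)

with `t` over the contaminant tissues (WM and CSF for a GM target; GM and
CSF for a WM target), `S_t` the measured image restricted to the argmax
mask of tissue `t`, and `⊗` discrete convolution with the system PSF.
Smoothing the measured contaminant signal rather than assuming a
homogeneous tissue value keeps the correction valid when WM or CSF sodium
varies spatially. The PSF is an isotropic Gaussian of FWHM 1.21 pixels
(4.8 mm at a 4 mm grid), appropriate for a Cartesian readout; the
discrete kernel is truncated at 3σ per axis and renormalized to unit sum.
The boundary condition is zero (air carries no sodium signal), the
smoothed-probability factor is not renormalized, and negative corrected
values are preserved — clipping would bias the subsequent regression.
With anisotropic voxels the FWHM in mm fixes the per-axis width.

### Kernel regression and RMSE

For each GM/WM voxel the kernel rows (inside the volume, GM- or
WM-labelled) form the design `P` (columns `p_gm`, `p_wm`) and signal
`S̄`; the estimate is `m̄ = (PᵀP)⁻¹PᵀS̄`. A fit is declared rank
deficient when the condition number of `PᵀP` exceeds 1e8, or when fewer
than 4 usable rows exist; such centers are set to zero and flagged
(`RANK_DEFICIENT_ZEROED`) so downstream statistics can exclude them.
Kernels truncated by the volume boundary keep their remaining rows and
are flagged `EDGE_TRUNCATED`. The per-voxel regression error is

    RMSE = sqrt( ‖S̄ − P·m̄‖² / (K − 2) )

with `K` the nominal kernel size (25, 49 or 27), irrespective of how many
rows survived filtering — the degrees of freedom are a property of the
declared kernel, and a per-voxel adjustment would make RMSE maps
incomparable across voxels. Residuals are computed over all usable rows,
not the trimmed subset.

### 3D-mLTS

The trimmed estimator replaces the OLS fit on kernels where the
local-constancy assumption partly fails (lesion rims, interfaces):

1. Rank rows by `|S_i − S_center|` and fit OLS on the `h` smallest — the
   central voxel is taken as representative of its own kernel. The
   absolute intensity difference is used as the similarity measure; it is
   isolated in one function should a different metric be preferred.
2. Ten concentration steps: compute residuals for all rows, sort `|r_i|`,
   refit on the `h` smallest. The iteration count is fixed (convergence
   is observed well before 10 steps); an optional log records the subset
   and trimmed SSR per step, which is non-increasing.

`h = round(α·K)` with a floor of 3 and α = 0.4 by default (h = 11 on a
3×3×3 kernel). The estimator is deterministic: ties break by row index
and the center row is always retained (an estimate that discards the
voxel it describes would be incoherent). Unlike classical FAST-LTS there
is no random subset search.

**Strict subset size.** A kernel that cannot supply `h` usable rows is
zeroed and flagged rather than fitted with a smaller subset. This is not
cosmetic: the trimming parameter is chosen by minimizing the mean
absolute error over the brain mask, and the coverage penalty of large
subsets (many kernels near CSF cannot fill h = 19 rows at α = 0.7) is one
side of the trade-off. With subset shrinking instead, the sweep over
α ∈ {0.3…0.7} is monotone — larger α always wins, because on
model-consistent data more rows only reduce variance — and no interior
optimum exists. With the strict rule the sweep reproducibly selects
α = 0.4 at both noise levels (σ = 3 and 6). For the same reason the sweep
metric is the literal difference map over the whole GM∪WM mask, zeroed
voxels included, and the sweep is run on a noisy realization (σ = 3):
noise-free data are exactly model-consistent almost everywhere, leaving
nothing for the trimming to reject.

## Digital phantom

The phantom replaces a segmented-subject TPM. Hard labels are built on a
1 mm grid and each tissue indicator is block-averaged 4³→1 to the 4 mm
sodium grid, so partial-volume probabilities arise exactly as in a
downsampled segmentation. Components, all configurable via `PhantomSpec`:

- **WM core**: the sub-level set `ρ + f ≤ 0.85` of the normalized
  ellipsoidal radius ρ (semi-axes 66×80×58 mm) plus a smooth seeded
  Gaussian random field `f` (amplitude 6 mm, correlation ~2.5 mm),
  folding the surface into sulci and gyral blades.
- **Cortical ribbon**: all voxels within 4 mm of the core (Euclidean
  distance transform), giving a constant-thickness sheet however
  convoluted the surface. The effective 4 mm thickness stands in for
  2.5–3 mm anatomical cortex plus the apposition of touching sulcal banks
  that a geometric model without self-contact cannot produce.
- **Subarachnoid/sulcal CSF**: a 2.5 mm shell beyond the ribbon.
- **Interhemispheric fissure**: a 10 mm-wide midline channel carved from
  the outer core (`ρ ≥ 0.60`); the ribbon then grows medial cortex on
  both walls with a thin CSF slit between them.
- **Deep gray nuclei** (two thalamus-like, two striatum-like ellipsoids)
  and a **cerebellum** modelled as a fine-grained (1.5 mm) GM/WM mixture
  at 90% GM — together they give the GM compartment its realistic share
  of nearly pure voxels; a cortex-only phantom over-weights boundary
  voxels and overstates the GM bias.
- **Ventricles**: two CSF ellipsoids inside the core.
- **Lesions**: spheres overwriting the ground truth regardless of label —
  a 10 mm-radius 70 mM lesion beside the fissure and a 15 mm-radius
  30 mM periventricular lesion, the typical sites of focal pathology and
  neighbourhoods that give the rims a realistic mixed-tissue environment.
  The folding field is damped to zero around each lesion so the
  partial-volume challenge a lesion poses is identical for every seed,
  as it would be with one fixed segmented subject.
- **`tissue_confidence` = 0.90**: all probabilities are scaled by 0.9,
  emulating the probability mass that real registered multi-class
  segmentations assign to non-brain classes and lose to interpolation.
  Published noise-free simulations with real TPMs show WM-mask means
  around 0.89 of truth, which only a sub-unity tissue sum can produce;
  the scaling shifts the uncorrected bias without touching the corrected
  estimates, because design and signal scale together.
- A 0.7 mm Gaussian softening of the indicators before averaging
  emulates segmentation softness and registration interpolation.

Ground truth assigns GM 48 and WM 43 mmol/L; the CSF pseudo-value
defaults to 0 (values are assigned to tissue masks only), so evaluation
ROIs exclude CSF-argmax voxels wherever an estimator is being scored.
The PVE-contaminated image is `Σ_t P_t·M_t` with the lesion value
entering through the enclosing tissue's fields; no PSF is applied on the
simulation path, isolating the tissue-fraction effect. Noise is additive
white Gaussian with SD σ (3 or 6 map units) added to the contaminated
image, seeded and reproducible.

**Evaluation ROIs.** GM and WM are the argmax masks with lesion spheres
carved out; each lesion ROI is its full sphere within the brain.
Uncorrected means use every ROI voxel; corrected means exclude
estimator-flagged voxels (they carry a zero placeholder, not an
estimate). Monte Carlo tables report the ROI mean of the absolute
difference map |truth − estimate| per iteration (mean and SD across
iterations): the absolute map is what responds to the noise level as well
as to bias — a signed ROI mean is invariant under zero-mean noise.

## What the phantom does and does not show

Passing the phantom tests demonstrates the estimator algebra (exact
recovery on model-consistent data, robustness to rim inconsistency,
correct flagging) and reproduces the scale of tissue-fraction biases at
4 mm resolution. The phantom's probabilities are *exactly* consistent
with the two-tissue model away from lesions, so corrected errors on it
are smaller than on real data, where segmentation error, registration
error, within-tissue TSC variation and Rician noise all violate the
model; in-vivo performance claims (absolute RMSE levels, between-method
significance) are outside what these simulations can certify. Geometry
parameters were set to brain-like mixture statistics (tissue volume
shares, cortical surface area, ventricle size); they are defaults of the
generator, not fitted quantities.

## Numerical choices

- All internal computation in float64; NIfTI output stored float32.
- Argmax tie-breaks: fixed priority GM > WM > CSF; probability-sum
  tolerance 1e−3.
- Condition-number limit 1e8 on `PᵀP`; minimum 4 usable rows.
- 2D kernels lie in the plane of the stored third axis.
- The regression is run twice when spill-in correction is active (GM- and
  WM-corrected signals, keeping the matching column); in pure simulation
  mode one joint regression yields both maps.
- Reference calibration scales by `138 / mean(signal over reference)`,
  measured on the signal (the regression never estimates CSF); SD is the
  sample standard deviation (n−1).
- Monte Carlo noise seeds derive from `SeedSequence([seed, level, iter])`.
- Problem sizes: the phantom is generated at 1 mm on a 160×184×144 grid
  and corrected at 4 mm (40×46×36, ~16k brain voxels); Monte Carlo runs
  use 25 iterations per noise level in the test suite and are configurable
  to 100, where across-iteration SDs are already below 0.1 mM for tissue
  ROIs.

## Known limitations

- The spill-in formula is applied literally (no renormalization of the
  smoothed probability inside the brain); near the brain edge the
  correction is therefore slightly conservative.
- The phantom has no skull, scalp or Rician noise floor, and its CSF
  carries no signal on the default simulation path; spill-in correction
  on the phantom therefore exercises the code path, not a realistic
  contamination magnitude.
- Ventricle/sulci CSF sub-labelling is accepted as a user-supplied mask;
  no automatic splitting rule is invented.
- Registration, segmentation and denoising of the anatomical image are
  upstream of this package and assumed done.
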