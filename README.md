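# napvc — voxel-wise partial volume correction for sodium MRI

Quantitative sodium MRI (²³Na-MRI) maps the tissue sodium concentration
(TSC) of the brain, a sensitive marker of cell viability. Because sodium
images are acquired at low spatial resolution (~4 mm voxels), the measured
value in each voxel is biased by **partial volume effects**: the voxel
mixes gray matter (GM), white matter (WM) and CSF (*tissue fraction
effect*), and signal leaks between neighbouring voxels through the point
spread function (*spill-over*). Left uncorrected, these effects
underestimate cortical TSC by ~20% and distort small focal lesions —
precisely the structures of clinical interest.

`napvc` implements a voxel-wise correction pipeline for researchers
working with sodium MRI (or any low-resolution quantitative modality with
co-registered tissue probability maps):

1. **Bias-field correction** by the coil sensitivity profile.
2. **Spill-in correction**: subtract the PSF-smoothed contaminant signal,
   `S_corr = S − Σ_t (S_t ⊗ PSF)·(P_t ⊗ PSF)`, with an isotropic Gaussian
   PSF (FWHM 1.21 px = 4.8 mm by default).
3. **Tissue-fraction correction** by kernel linear regression. The model
   `S_r = P_GM,r·M_GM + P_WM,r·M_WM` is solved per voxel over a small
   neighbourhood in which the pure tissue intensities `m̄ = (M_GM, M_WM)`
   are assumed constant: `m̄ = (PᵀP)⁻¹PᵀS̄` (CSF-labelled voxels are
   excluded from the kernel). Kernels: 2D 5×5 / 7×7, 3D 3×3×3.
4. **3D-mLTS**, the robust variant: a modified least-trimmed-squares fit
   on the 3×3×3 kernel that keeps only the `h = α·K` rows most consistent
   with the central voxel (initialized by intensity similarity, refined by
   10 residual-sorting concentration steps, α = 0.4). Trimming rejects
   the kernel rows that violate the local-constancy assumption, which
   sharply reduces the regression's inherent spatial blurring at lesion
   rims and tissue interfaces.
5. **Calibration** of the corrected map against a reference region
   (ventricular CSF, assumed 138 mM), and per-ROI summaries
   (mean, SD, CoV, regression RMSE with d.f. = K − 2).

A **digital brain phantom** (folded cortical ribbon, deep gray nuclei,
cerebellum, ventricles, interhemispheric fissure, two spherical lesions of
70 and 30 mM) provides ground truth for validation and Monte Carlo
experiments.

## Worked example

```python
from napvc import PhantomSpec, simulate_phantom, TissueFractionModel

ph = simulate_phantom(PhantomSpec(), seed=1)      # TPM + ground truth + PVE image
model = TissueFractionModel.from_phantom(ph)      # or .from_files(...)
res = model.fit(method="mlts")                    # 3x3x3 kernel, alpha=0.4
print(res.summary(rois=ph.rois))
```

```
     roi    n      mean           sd          cov  rmse_mean
      gm 6256 47.987819 4.622033e-01 9.631679e-01   0.090449
      wm 5004 43.000000 6.284021e-14 1.461400e-13   0.129976
lesion_0   57 69.491866 2.646677e+00 3.808614e+00  13.999143
lesion_1  120 29.979995 1.842990e-01 6.147400e-01   5.486156
```

The ground-truth values are GM 48, WM 43, lesions 70 and 30 mM; the
uncorrected image underestimates GM by ~23% and WM by ~10%. After the
3D-mLTS correction the recovered means are within 0.03% (GM), <1e-13 (WM),
0.73% (hyper-intense lesion) and 0.07% (hypo-intense lesion) of truth —
`res.delta_tsc(ph.ground_truth, ph.rois)` prints the per-ROI differences.

The same stages are available from the shell:

```bash
napvc simulate --seed 1 --out phantom/
napvc correct --sodium phantom/contaminated.nii.gz \
              --tpm-gm phantom/tpm_gm.nii.gz --tpm-wm phantom/tpm_wm.nii.gz \
              --tpm-csf phantom/tpm_csf.nii.gz \
              --method mlts --no-spillin --out corrected/
napvc optimize-alpha --alphas 0.3,0.4,0.5,0.6,0.7 --noise-sigma 3
napvc compare --methods lr2d5,lr2d7,lr3d,mlts --noise-sigma 3
```

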