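"""Digital brain phantom and Monte Carlo simulation framework.

The phantom stands in for a segmented-subject tissue probability map: a
high-resolution (1 mm) hard-label brain is built from simple geometry --
a folded cortical ribbon of gray matter over a white-matter core, sulcal
CSF filling the space out to the head envelope, and two ellipsoidal
ventricles -- and each binary tissue map is block-averaged down to the
low-resolution sodium grid (4 mm by default), yielding partial-volume
probabilities exactly as a downsampled segmentation would. A small
Gaussian softening (sub-millimetre by default) is applied to the high-resolution
masks before averaging to emulate the probability softness of real
segmentations and the interpolation of the registration chain.

Ground truth assigns literature sodium concentrations to the labels
(GM 48, WM 43 mmol/L) plus two spherical lesions: a 10 mm-radius
hyper-intense lesion (70 mM, juxtacortical) and a 15 mm-radius
hypo-intense lesion (30 mM, periventricular) -- the typical locations of
focal pathology, and the placements that give the lesion rims a realistic
mixed-tissue neighbourhood. The PVE-contaminated image is the
TPM-weighted sum of the pure-tissue value fields; the PSF is deliberately
not applied in the simulation path, which isolates the tissue-fraction
effect.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import (
    BACKGROUND,
    CSF,
    GM,
    WM,
    LabelMask,
    TissueProbabilityMap,
    Volume3D,
    tpm_to_mask,
)

__all__ = [
    "LesionSpec",
    "PhantomSpec",
    "NoiseSpec",
    "Phantom",
    "generate_highres_labels",
    "generate_synthetic_tpm",
    "make_ground_truth",
    "pure_value_fields",
    "contaminate",
    "add_noise",
    "simulate_phantom",
    "run_monte_carlo",
]


@dataclass(frozen=True)
class LesionSpec:
    """Spherical lesion: center (mm, relative to volume center), radius, TSC."""

    center_mm: tuple[float, float, float]
    radius_mm: float
    tsc: float

    def __post_init__(self) -> None:
        if self.radius_mm <= 0:
            raise ValueError("lesion radius must be > 0")
        if self.tsc < 0:
            raise ValueError("lesion TSC must be >= 0")


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and ground-truth parameters of the digital phantom.

    Defaults reproduce the simulation conditions used throughout the
    package validation: 48/43 mM tissue values, 0 mM CSF pseudo-value (so
    evaluation ROIs exclude CSF), 1 mm construction grid block-averaged
    by 4 to a 4 mm sodium grid, a folded cortical ribbon with deep gray
    nuclei, cerebellum and interhemispheric fissure, and two lesions
    (70 mM r=10 near the fissure, 30 mM r=15 periventricular).
    ``tissue_confidence`` scales all probabilities, emulating the
    probability mass real registered multi-class segmentations assign to
    non-brain classes.
    """

    tsc_gm: float = 48.0
    tsc_wm: float = 43.0
    tsc_csf: float = 0.0
    lesions: tuple[LesionSpec, ...] = (
        LesionSpec(center_mm=(6.0, 50.0, 26.0), radius_mm=10.0, tsc=70.0),
        LesionSpec(center_mm=(-32.0, -10.0, 2.0), radius_mm=15.0, tsc=30.0),
    )
    highres_voxel: float = 1.0
    downsample_factor: int = 4
    grid_shape_highres: tuple[int, int, int] = (160, 184, 144)
    brain_semiaxes: tuple[float, float, float] = (66.0, 80.0, 58.0)
    wm_level: float = 0.85
    core_cap: float = 0.93
    pial_cap: float = 0.97
    cortical_thickness_mm: float = 4.0
    csf_rim_mm: float = 2.5
    gm_nuclei: tuple[tuple[tuple[float, float, float], tuple[float, float, float]], ...] = (
        ((-20.0, -16.0, 4.0), (11.0, 14.0, 11.0)),
        ((20.0, -16.0, 4.0), (11.0, 14.0, 11.0)),
        ((-24.0, 8.0, 2.0), (10.0, 13.0, 10.0)),
        ((24.0, 8.0, 2.0), (10.0, 13.0, 10.0)),
    )
    cerebellum_center: tuple[float, float, float] = (0.0, -48.0, -26.0)
    cerebellum_semiaxes: tuple[float, float, float] = (46.0, 28.0, 22.0)
    cerebellum_gm_fraction: float = 0.90
    cerebellum_grain_mm: float = 1.5
    ventricle_semiaxes: tuple[float, float, float] = (9.0, 26.0, 10.0)
    ventricle_centers: tuple[tuple[float, float, float], ...] = (
        (-14.0, -10.0, 2.0),
        (14.0, -10.0, 2.0),
    )
    fissure_half_width_mm: float = 5.0
    fissure_floor: float = 0.60
    fold_amplitude_mm: float = 6.0
    fold_smoothing_mm: float = 2.5
    tpm_softening_mm: float = 0.7
    tissue_confidence: float = 0.90

    def __post_init__(self) -> None:
        if self.downsample_factor < 1:
            raise ValueError("downsample_factor must be >= 1")
        if any(v < 0 for v in (self.tsc_gm, self.tsc_wm, self.tsc_csf)):
            raise ValueError("tissue TSC values must be >= 0")
        if any(n % self.downsample_factor for n in self.grid_shape_highres):
            raise ValueError("high-res grid shape must be divisible by the downsample factor")

    @property
    def lowres_voxel(self) -> float:
        return self.highres_voxel * self.downsample_factor

    @property
    def mean_semiaxis(self) -> float:
        return float(np.mean(self.brain_semiaxes))


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise: the 'amplitude' is the SD in map units."""

    sigma: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def _coords_mm(shape: tuple[int, int, int], voxel: float):
    axes = [(np.arange(n) + 0.5 - n / 2.0) * voxel for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def generate_highres_labels(spec: PhantomSpec, seed: int) -> np.ndarray:
    """Hard tissue labels on the 1 mm construction grid.

    The white-matter core is the sub-level set rho + f <= wm_level, where
    rho is the normalized ellipsoidal radius and f a smooth seeded random
    field (amplitude ``fold_amplitude_mm``): its boundary folds into deep
    sulci and narrow gyral blades, giving the core a cortex-like surface
    area. The gray-matter ribbon is everything within
    ``cortical_thickness_mm`` of the core (a Euclidean distance
    transform), so the ribbon thickness is constant however convoluted
    the surface. CSF fills the rest of the head envelope (sulci and
    subarachnoid space) plus two ellipsoidal ventricles carved from the
    core.
    """
    x, y, z = _coords_mm(spec.grid_shape_highres, spec.highres_voxel)
    a, b, c = spec.brain_semiaxes
    rho = np.sqrt((x / a) ** 2 + (y / b) ** 2 + (z / c) ** 2)
    if rho[rho <= 1.0].size == 0:
        raise ValueError("brain geometry exceeds the high-res grid bounds")
    for n, half in zip(spec.grid_shape_highres, (a, b, c)):
        if half >= n * spec.highres_voxel / 2.0:
            raise ValueError("brain semi-axes exceed the high-res grid bounds")

    rng = np.random.default_rng(seed)
    f = rng.standard_normal(spec.grid_shape_highres)
    f = ndimage.gaussian_filter(f, sigma=spec.fold_smoothing_mm / spec.highres_voxel)
    f = f / max(f.std(), 1e-12)
    f = np.clip(f, -2.5, 2.5)
    # The folding is damped to zero around each lesion so that the lesion's
    # tissue environment -- and therefore the partial-volume challenge it
    # poses -- is identical for every seed, as it would be with a single
    # segmented subject.
    for lesion in spec.lesions:
        cx, cy, cz = lesion.center_mm
        d = np.sqrt((x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2)
        r_in, r_out = lesion.radius_mm + 5.0, lesion.radius_mm + 15.0
        f *= np.clip((d - r_in) / (r_out - r_in), 0.0, 1.0)
    amp = spec.fold_amplitude_mm / spec.mean_semiaxis
    core = (rho + amp * f <= spec.wm_level) & (rho <= spec.core_cap)
    # Interhemispheric fissure: a midline channel carved from the outer
    # part of the core; the ribbon then grows medial cortex on both walls
    # and a thin CSF slit remains between the hemispheres.
    if spec.fissure_half_width_mm > 0:
        fissure = (np.abs(x) <= spec.fissure_half_width_mm) & (rho >= spec.fissure_floor)
        core &= ~fissure

    dist = ndimage.distance_transform_edt(~core, sampling=spec.highres_voxel)
    ribbon = (dist > 0) & (dist <= spec.cortical_thickness_mm) & (rho <= spec.pial_cap)
    shell = (dist > spec.cortical_thickness_mm) & (
        dist <= spec.cortical_thickness_mm + spec.csf_rim_mm) & (rho <= 1.0)

    labels = np.full(spec.grid_shape_highres, BACKGROUND, dtype=np.int16)
    labels[shell] = CSF        # subarachnoid/sulcal CSF follows the folds
    labels[ribbon] = GM
    labels[core] = WM
    for (cx, cy, cz), (na, nb, nc) in spec.gm_nuclei:  # deep gray nuclei
        nuc = ((x - cx) / na) ** 2 + ((y - cy) / nb) ** 2 + ((z - cz) / nc) ** 2 <= 1.0
        labels[nuc & core] = GM
    # Cerebellum: finely laminated, GM-dominated tissue -- modelled as a
    # fine-grained GM/WM mixture at ``cerebellum_grain_mm`` feature scale.
    cx, cy, cz = spec.cerebellum_center
    na, nb, nc = spec.cerebellum_semiaxes
    cb = (((x - cx) / na) ** 2 + ((y - cy) / nb) ** 2 + ((z - cz) / nc) ** 2 <= 1.0) & core
    if cb.any():
        grain = rng.standard_normal(spec.grid_shape_highres)
        grain = ndimage.gaussian_filter(grain, sigma=spec.cerebellum_grain_mm / spec.highres_voxel)
        thr = np.quantile(grain[cb], spec.cerebellum_gm_fraction)
        labels[cb & (grain <= thr)] = GM
    va, vb, vc = spec.ventricle_semiaxes
    for cx, cy, cz in spec.ventricle_centers:
        vent = ((x - cx) / va) ** 2 + ((y - cy) / vb) ** 2 + ((z - cz) / vc) ** 2 <= 1.0
        labels[vent] = CSF
    return labels


def generate_synthetic_tpm(spec: PhantomSpec, seed: int) -> TissueProbabilityMap:
    """Block-average the high-res binary tissue maps into a low-res TPM.

    Each indicator is optionally softened with a small Gaussian
    (``tpm_softening_mm``) before averaging; softening is linear, so the
    per-voxel probability sum stays <= 1 with equality inside the head.
    Identical seeds give identical TPMs.
    """
    labels = generate_highres_labels(spec, seed)
    f = spec.downsample_factor
    vols = []
    for tissue in (GM, WM, CSF):
        mask = (labels == tissue).astype(np.float64)
        if spec.tpm_softening_mm > 0:
            mask = ndimage.gaussian_filter(
                mask, sigma=spec.tpm_softening_mm / spec.highres_voxel)
        nx, ny, nz = mask.shape
        low = mask.reshape(nx // f, f, ny // f, f, nz // f, f).mean(axis=(1, 3, 5))
        low *= spec.tissue_confidence
        vols.append(Volume3D(np.clip(low, 0.0, 1.0), voxel_size=(spec.lowres_voxel,) * 3))
    return TissueProbabilityMap(p_gm=vols[0], p_wm=vols[1], p_csf=vols[2])


def _lesion_region(lesion: LesionSpec, shape, voxel_size) -> np.ndarray:
    x, y, z = _coords_mm(shape, voxel_size[0])
    cx, cy, cz = lesion.center_mm
    return (x - cx) ** 2 + (y - cy) ** 2 + (z - cz) ** 2 <= lesion.radius_mm ** 2


def make_ground_truth(mask: LabelMask, spec: PhantomSpec) -> Volume3D:
    """Per-voxel true TSC: label value, overwritten inside lesion spheres."""
    values = {BACKGROUND: 0.0, GM: spec.tsc_gm, WM: spec.tsc_wm, CSF: spec.tsc_csf}
    gt = np.zeros(mask.shape)
    for code, val in values.items():
        gt[mask.labels == code] = val
    hit = np.zeros(mask.shape, dtype=np.int16)
    for lesion in mask_lesion_regions(mask, spec):
        hit += lesion
    if (hit > 1).any():
        raise ValueError("overlapping lesions give an ambiguous ground truth")
    for lesion, region in zip(spec.lesions, mask_lesion_regions(mask, spec)):
        gt[region] = lesion.tsc
    return Volume3D(gt, voxel_size=mask.voxel_size)


def mask_lesion_regions(mask: LabelMask, spec: PhantomSpec) -> list[np.ndarray]:
    """Boolean voxel masks of each lesion sphere on the low-res grid."""
    return [_lesion_region(l, mask.shape, mask.voxel_size) for l in spec.lesions]


def pure_value_fields(
    mask: LabelMask, spec: PhantomSpec
) -> tuple[Volume3D, Volume3D, Volume3D]:
    """Pure-tissue value maps (M_GM, M_WM, M_CSF) including lesion overrides.

    A lesion contributes to the mixed signal through its enclosing
    tissue's probability, so the GM and WM fields both take the lesion
    value inside a lesion sphere; the CSF field keeps its tissue value.
    """
    m_gm = np.full(mask.shape, spec.tsc_gm)
    m_wm = np.full(mask.shape, spec.tsc_wm)
    m_csf = np.full(mask.shape, spec.tsc_csf)
    for lesion, region in zip(spec.lesions, mask_lesion_regions(mask, spec)):
        m_gm[region] = lesion.tsc
        m_wm[region] = lesion.tsc
    vs = mask.voxel_size
    return (Volume3D(m_gm, vs), Volume3D(m_wm, vs), Volume3D(m_csf, vs))


def contaminate(
    tpm: TissueProbabilityMap,
    fields: tuple[Volume3D, Volume3D, Volume3D],
) -> Volume3D:
    """PVE-contaminated image: S_r = sum_t P_t,r * M_t,r.

    Linear in the pure-value fields; wherever the probabilities sum to 1
    the output lies between the smallest and largest contributing pure
    value.
    """
    m_gm, m_wm, m_csf = fields
    if m_gm.shape != tpm.shape:
        raise ValueError("pure-value fields must live on the TPM grid")
    data = (tpm.p_gm.data * m_gm.data + tpm.p_wm.data * m_wm.data
            + tpm.p_csf.data * m_csf.data)
    return Volume3D(data, voxel_size=tpm.voxel_size)


def add_noise(vol: Volume3D, noise: NoiseSpec) -> Volume3D:
    """Add zero-mean white Gaussian noise, seeded and reproducible."""
    if noise.sigma == 0:
        return vol.like(vol.data.copy())
    rng = np.random.default_rng(noise.seed)
    return vol.like(vol.data + noise.sigma * rng.standard_normal(vol.shape))


# ---------------------------------------------------------------------------
# simulation bundle
# ---------------------------------------------------------------------------

@dataclass
class Phantom:
    """All simulation-side volumes plus evaluation ROIs."""

    spec: PhantomSpec
    seed: int
    tpm: TissueProbabilityMap
    mask: LabelMask
    ground_truth: Volume3D
    fields: tuple[Volume3D, Volume3D, Volume3D]
    contaminated: Volume3D
    rois: dict[str, np.ndarray] = field(default_factory=dict)


def _roi_masks(mask: LabelMask, spec: PhantomSpec) -> dict[str, np.ndarray]:
    """GM/WM ROIs (lesions carved out) and one ROI per lesion sphere.

    A lesion ROI is its full sphere within the brain (background-labelled
    voxels excluded); ground truth is the lesion value throughout the
    sphere. Estimators that flag voxels (e.g. CSF-labelled voxels carry
    no regression estimate) exclude them from their ROI statistics
    downstream.
    """
    regions = mask_lesion_regions(mask, spec)
    any_lesion = np.zeros(mask.shape, dtype=bool)
    for r in regions:
        any_lesion |= r
    brain = mask.labels != BACKGROUND
    rois = {
        "gm": (mask.labels == GM) & ~any_lesion,
        "wm": (mask.labels == WM) & ~any_lesion,
    }
    for i, region in enumerate(regions):
        rois[f"lesion_{i}"] = region & brain
    return rois


def simulate_phantom(spec: PhantomSpec = PhantomSpec(), seed: int = 0) -> Phantom:
    """Build TPM, ground truth and the noise-free PVE-contaminated image."""
    tpm = generate_synthetic_tpm(spec, seed)
    mask = tpm_to_mask(tpm)
    gt = make_ground_truth(mask, spec)
    fields = pure_value_fields(mask, spec)
    contaminated = contaminate(tpm, fields)
    return Phantom(
        spec=spec, seed=seed, tpm=tpm, mask=mask, ground_truth=gt,
        fields=fields, contaminated=contaminated, rois=_roi_masks(mask, spec),
    )


def _noise_seed(base_seed: int, sigma_index: int, iteration: int) -> int:
    ss = np.random.SeedSequence([int(base_seed), int(sigma_index), int(iteration)])
    return int(ss.generate_state(1)[0] % (2**31))


def run_monte_carlo(
    spec: PhantomSpec = PhantomSpec(),
    sigmas: tuple[float, ...] = (3.0, 6.0),
    method: str = "mlts",
    n_iter: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Monte Carlo evaluation of a PVC method against ground truth.

    For each noise level and iteration, fresh white noise (seeded from
    ``seed``, the noise-level index and the iteration) is added to the
    PVE-contaminated image, the method is applied, and the per-ROI
    DeltaTSC -- the ROI mean of the absolute difference map
    |ground truth - estimate| -- is recorded (the absolute map is what
    makes the score sensitive to noise level as well as bias; voxels the
    estimator zeroes and flags are excluded from its ROI mean). Returns a
    table with the across-iteration mean and SD of DeltaTSC for the
    uncorrected and corrected images, one row per (ROI, sigma).
    """
    from .mlts import apply_method  # local import avoids a cycle at import time

    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    ph = simulate_phantom(spec, seed)
    gt = ph.ground_truth.data
    records: dict[tuple[str, float], dict[str, list[float]]] = {
        (roi, s): {"uncorrected": [], "corrected": []}
        for roi in ph.rois for s in sigmas
    }
    for si, sigma in enumerate(sigmas):
        for it in range(n_iter):
            noisy = add_noise(ph.contaminated,
                              NoiseSpec(sigma=sigma, seed=_noise_seed(seed, si, it)))
            res = apply_method(noisy, ph.tpm, ph.mask, method)
            corrected = res.combined_map().data
            valid = res.valid
            for roi, sel in ph.rois.items():
                records[(roi, sigma)]["uncorrected"].append(
                    float(np.abs(gt[sel] - noisy.data[sel]).mean()))
                sel_v = sel & valid
                records[(roi, sigma)]["corrected"].append(
                    float(np.abs(gt[sel_v] - corrected[sel_v]).mean()))
    rows = []
    for (roi, sigma), vals in records.items():
        unc = np.asarray(vals["uncorrected"])
        cor = np.asarray(vals["corrected"])
        sd = (lambda v: float(v.std(ddof=1)) if v.size > 1 else 0.0)
        rows.append({
            "roi": roi, "sigma": sigma, "n_iter": n_iter,
            "uncorrected_mean": float(unc.mean()), "uncorrected_sd": sd(unc),
            "corrected_mean": float(cor.mean()), "corrected_sd": sd(cor),
        })
    return pd.DataFrame(rows)
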