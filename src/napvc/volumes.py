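"""Core 3D volume containers, NIfTI I/O, and tissue-mask derivation.

The whole package works on scalar 3D grids: a measured sodium image in
arbitrary units (or mM after calibration), tissue probability maps in
[0, 1], and integer-coded label masks. Everything is assumed to live on a
single common grid -- registration/resampling between native spaces is out
of scope, so inputs must be pre-registered and resampled to the sodium grid
before they reach this package.

Label alphabet
--------------
``BACKGROUND=0, GM=1, WM=2, CSF=3``; optional CSF sub-labels
``VENTRICLE=4, SULCI=5`` for reference-region bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "BACKGROUND",
    "GM",
    "WM",
    "CSF",
    "VENTRICLE",
    "SULCI",
    "LABEL_NAMES",
    "Volume3D",
    "TissueProbabilityMap",
    "LabelMask",
    "read_volume",
    "write_volume",
    "write_mask",
    "tpm_to_mask",
]

BACKGROUND = 0
GM = 1
WM = 2
CSF = 3
VENTRICLE = 4
SULCI = 5

LABEL_NAMES = {
    BACKGROUND: "background",
    GM: "gm",
    WM: "wm",
    CSF: "csf",
    VENTRICLE: "ventricle",
    SULCI: "sulci",
}

#: tolerance on the per-voxel probability sum (segmentation output rounding)
PROB_SUM_TOL = 1e-3


class VolumeError(ValueError):
    """Raised for invalid volume data (non-finite voxels, bad shapes, ...)."""


@dataclass
class Volume3D:
    """A 3D scalar grid with voxel size in mm.

    Parameters
    ----------
    data
        3D array of scalar intensities (a.u. or mM). Stored as float64;
        all internal computation is done in 64-bit floating point.
    voxel_size
        (dx, dy, dz) in mm, all strictly positive.
    affine
        Optional 4x4 voxel-to-world matrix. When absent a diagonal affine
        built from ``voxel_size`` is used on write.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeError(f"expected a 3D array, got ndim={self.data.ndim}")
        if min(self.data.shape) < 1:
            raise VolumeError(f"degenerate shape {self.data.shape}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != 3 or any(v <= 0 for v in self.voxel_size):
            raise VolumeError(f"voxel_size must be 3 positive floats, got {self.voxel_size}")
        n_bad = int(np.size(self.data) - np.isfinite(self.data).sum())
        if n_bad:
            raise VolumeError(f"{n_bad} non-finite voxel(s) in volume data")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def like(self, data: np.ndarray) -> "Volume3D":
        """A new volume on the same grid with different data."""
        return replace(self, data=np.asarray(data, dtype=np.float64))

    def voxel_centers_mm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Coordinate grids (mm) of voxel centers, origin at the volume center."""
        axes = [
            (np.arange(n) + 0.5 - n / 2.0) * d
            for n, d in zip(self.shape, self.voxel_size)
        ]
        return tuple(np.meshgrid(*axes, indexing="ij"))


@dataclass
class TissueProbabilityMap:
    """Aligned GM/WM/CSF probability fields on the sodium grid.

    Invariants: shared grid shape and voxel size; every voxel satisfies
    0 <= p_t <= 1 and p_gm + p_wm + p_csf <= 1 + tol (remainder is
    background/non-brain).
    """

    p_gm: Volume3D
    p_wm: Volume3D
    p_csf: Volume3D

    def __post_init__(self) -> None:
        shapes = {self.p_gm.shape, self.p_wm.shape, self.p_csf.shape}
        if len(shapes) != 1:
            raise VolumeError(f"TPM fields have mismatched shapes: {shapes}")
        sizes = {self.p_gm.voxel_size, self.p_wm.voxel_size, self.p_csf.voxel_size}
        if len(sizes) != 1:
            raise VolumeError(f"TPM fields have mismatched voxel sizes: {sizes}")
        for name, vol in (("p_gm", self.p_gm), ("p_wm", self.p_wm), ("p_csf", self.p_csf)):
            lo, hi = float(vol.data.min()), float(vol.data.max())
            if lo < -PROB_SUM_TOL or hi > 1 + PROB_SUM_TOL:
                raise VolumeError(f"{name} outside [0,1]: range [{lo}, {hi}]")
        total = self.p_gm.data + self.p_wm.data + self.p_csf.data
        worst = float(total.max())
        if worst > 1 + PROB_SUM_TOL:
            raise VolumeError(f"probability sum exceeds 1 (max {worst})")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.p_gm.shape

    @property
    def voxel_size(self) -> tuple[float, float, float]:
        return self.p_gm.voxel_size


@dataclass
class LabelMask:
    """Integer-coded tissue labels, exactly one label per voxel."""

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    alphabet: tuple[int, ...] = (BACKGROUND, GM, WM, CSF, VENTRICLE, SULCI)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeError("labels must be integer-coded")
        if self.labels.ndim != 3:
            raise VolumeError("labels must be a 3D array")
        extra = set(np.unique(self.labels)) - set(self.alphabet)
        if extra:
            raise VolumeError(f"labels outside alphabet: {sorted(extra)}")
        self.voxel_size = tuple(float(v) for v in self.voxel_size)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def region(self, *labels: int) -> np.ndarray:
        """Boolean mask of voxels carrying any of the given labels."""
        return np.isin(self.labels, labels)


def read_volume(path: str | Path) -> Volume3D:
    """Load a single-volume NIfTI-1 image as a :class:`Volume3D`.

    Voxel size is taken from the header zooms; data are cast to float64.
    Raises :class:`VolumeError` on 4D input or non-finite voxels (the error
    names the number of affected voxels).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise VolumeError(f"{path.name}: expected a 3D volume, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    return Volume3D(
        data=np.asarray(data, dtype=np.float64),
        voxel_size=tuple(float(z) for z in zooms),
        affine=np.asarray(img.affine, dtype=np.float64),
    )


def _affine_for(vol: Volume3D) -> np.ndarray:
    if vol.affine is not None:
        return vol.affine
    aff = np.diag(list(vol.voxel_size) + [1.0])
    return aff


def write_volume(vol: Volume3D, path: str | Path, dtype=np.float32) -> None:
    """Write a volume as NIfTI-1; header voxel size equals ``vol.voxel_size``."""
    img = nib.Nifti1Image(vol.data.astype(dtype), _affine_for(vol))
    img.header.set_zooms(vol.voxel_size)
    nib.save(img, str(path))


def write_mask(mask: LabelMask, path: str | Path) -> None:
    """Write an integer label mask plus a sidecar ``<path>.labels.txt``."""
    aff = np.diag(list(mask.voxel_size) + [1.0])
    img = nib.Nifti1Image(mask.labels.astype(np.int16), aff)
    img.header.set_zooms(mask.voxel_size)
    nib.save(img, str(path))
    sidecar = Path(str(path)).with_suffix("").with_suffix("")  # strip .nii(.gz)
    with open(str(sidecar) + ".labels.txt", "w") as fh:
        for code, name in LABEL_NAMES.items():
            fh.write(f"{code}\t{name}\n")


def tpm_to_mask(tpm: TissueProbabilityMap) -> LabelMask:
    """Hard tissue labels by per-voxel argmax over (GM, WM, CSF).

    Voxels where all three probabilities are zero become BACKGROUND. Ties
    resolve by the fixed priority order GM > WM > CSF so that repeated runs
    give identical masks.
    """
    stack = np.stack([tpm.p_gm.data, tpm.p_wm.data, tpm.p_csf.data])
    # np.argmax returns the first maximum, which with this stacking order
    # implements the GM > WM > CSF tie-break.
    winner = np.argmax(stack, axis=0).astype(np.int16) + 1
    winner[stack.max(axis=0) <= 0] = BACKGROUND
    return LabelMask(labels=winner, voxel_size=tpm.voxel_size)
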