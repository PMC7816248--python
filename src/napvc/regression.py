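"""Kernel linear-regression tissue-fraction correction and RMSE maps.

Model: the measured voxel value is a probability-weighted sum of pure
tissue intensities,

    S_r = P_GM,r * M_GM + P_WM,r * M_WM  (+ P_CSF,r * M_CSF),

and the pure intensities are assumed constant over a small neighbourhood
(kernel) around each voxel, so stacking the kernel voxels gives an
overdetermined least-squares problem. CSF-labelled voxels are excluded
from the kernel (their spill-in contribution is removed beforehand), which
leaves the two unknowns (M_GM, M_WM) per center voxel. Supported kernels
are 2D in-plane (5x5, 7x7, ...) and 3D (3x3x3).

Per-voxel regression error is reported as

    RMSE = sqrt( ||S - P m||^2 / d.f. ),   d.f. = K - 2,

with K the *nominal* kernel size (n^2 or n^3) regardless of how many rows
survived masking or boundary truncation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .volumes import CSF, GM, WM, LabelMask, TissueProbabilityMap, Volume3D

__all__ = [
    "KernelSpec",
    "PVCResult",
    "RankDeficientError",
    "QC_OK",
    "QC_OUT_OF_MASK",
    "QC_RANK_DEFICIENT_ZEROED",
    "QC_EDGE_TRUNCATED",
    "extract_kernel",
    "ols_fit",
    "lr_pvc",
    "rmse_map",
]

# QC flag codes (one code per voxel; EDGE_TRUNCATED voxels still carry
# valid estimates, OUT_OF_MASK / RANK_DEFICIENT voxels are zeroed).
QC_OK = 0
QC_OUT_OF_MASK = 1
QC_RANK_DEFICIENT_ZEROED = 2
QC_EDGE_TRUNCATED = 3

#: condition-number threshold on P^T P beyond which a fit is rank deficient
COND_LIMIT = 1e8

#: minimum usable rows; with fewer the center voxel is zeroed and flagged
MIN_ROWS = 4


class RankDeficientError(np.linalg.LinAlgError):
    """The kernel design matrix is (numerically) rank deficient."""


@dataclass(frozen=True)
class KernelSpec:
    """Regression neighbourhood: 2D n x n (in-plane) or 3D n x n x n.

    Degrees of freedom for the RMSE map are K - 2 with K = n^dims.
    """

    dims: int = 3
    n: int = 3

    def __post_init__(self) -> None:
        if self.dims not in (2, 3):
            raise ValueError("dims must be 2 or 3")
        if self.n < 3 or self.n % 2 == 0:
            raise ValueError("kernel side length must be odd and >= 3")

    @property
    def size(self) -> int:
        return self.n ** self.dims

    @property
    def dof(self) -> int:
        return self.size - 2

    def offsets(self) -> np.ndarray:
        """(K, 3) integer voxel offsets; the center sits at row K // 2.

        2D kernels lie in the in-plane slice of the stored third axis.
        """
        r = self.n // 2
        if self.dims == 3:
            offs = list(itertools.product(range(-r, r + 1), repeat=3))
        else:
            offs = [(dx, dy, 0) for dx, dy in itertools.product(range(-r, r + 1), repeat=2)]
        return np.asarray(offs, dtype=np.intp)


# ---------------------------------------------------------------------------
# single-kernel operations (reference path; also the public per-voxel API)
# ---------------------------------------------------------------------------

def extract_kernel(
    vol: Volume3D,
    tpm: TissueProbabilityMap,
    mask: LabelMask,
    center: tuple[int, int, int],
    spec: KernelSpec,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Design matrix and signal vector for one kernel placement.

    Rows are the kernel voxels that fall inside the volume AND are labelled
    GM or WM (CSF and background rows are dropped). Returns ``(P, S, c)``
    with P of shape (rows, 2) holding (p_gm, p_wm), S the matching signal
    values, and c the row index of the center voxel (-1 if the center
    itself was filtered out).
    """
    shape = vol.shape
    offs = spec.offsets()
    rows_p: list[tuple[float, float]] = []
    rows_s: list[float] = []
    center_row = -1
    for k, (dx, dy, dz) in enumerate(offs):
        i, j, l = center[0] + dx, center[1] + dy, center[2] + dz
        if not (0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= l < shape[2]):
            continue
        if mask.labels[i, j, l] not in (GM, WM):
            continue
        if k == spec.size // 2:
            center_row = len(rows_s)
        rows_p.append((tpm.p_gm.data[i, j, l], tpm.p_wm.data[i, j, l]))
        rows_s.append(vol.data[i, j, l])
    P = np.asarray(rows_p, dtype=np.float64).reshape(-1, 2)
    S = np.asarray(rows_s, dtype=np.float64)
    return P, S, center_row


def ols_fit(P: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Ordinary least squares through the normal equations.

    m = (P^T P)^-1 P^T S, the exact least-squares minimizer. Raises
    :class:`RankDeficientError` when P^T P is singular or its condition
    number exceeds ``COND_LIMIT``.
    """
    P = np.asarray(P, dtype=np.float64)
    S = np.asarray(S, dtype=np.float64)
    if P.shape[0] < 3:
        raise RankDeficientError(f"need >= 3 rows, got {P.shape[0]}")
    ptp = P.T @ P
    if not np.all(np.isfinite(ptp)):
        raise RankDeficientError("non-finite normal equations")
    cond = np.linalg.cond(ptp)
    if not np.isfinite(cond) or cond > COND_LIMIT:
        raise RankDeficientError(f"ill-conditioned P^T P (cond={cond:.3g})")
    return np.linalg.solve(ptp, P.T @ S)


# ---------------------------------------------------------------------------
# vectorized volume sweep
# ---------------------------------------------------------------------------

@dataclass
class KernelStacks:
    """Batched kernel neighbourhoods for every GM/WM center voxel."""

    centers: np.ndarray          # (N, 3) voxel indices
    p: np.ndarray                # (N, K, 2) probabilities
    s: np.ndarray                # (N, K) signal
    usable: np.ndarray           # (N, K) bool: in-volume and GM/WM-labelled
    in_volume: np.ndarray        # (N, K) bool
    center_col: int              # kernel column of the center voxel
    spec: KernelSpec
    shape: tuple[int, int, int]


def build_stacks(
    vol: Volume3D,
    tpm: TissueProbabilityMap,
    mask: LabelMask,
    spec: KernelSpec,
) -> KernelStacks:
    """Assemble (N, K) kernel stacks for all GM/WM-labelled centers."""
    if vol.shape != tpm.shape or vol.shape != mask.shape:
        raise ValueError("signal, TPM and mask must share one grid")
    offs = spec.offsets()
    r = int(np.abs(offs).max())
    pad = [(r, r)] * 3

    def padded(arr, cval):
        return np.pad(arr, pad, mode="constant", constant_values=cval)

    lab_p = padded(mask.labels, -1)
    sig_p = padded(vol.data, 0.0)
    pg_p = padded(tpm.p_gm.data, 0.0)
    pw_p = padded(tpm.p_wm.data, 0.0)

    sweep = mask.region(GM, WM)
    centers = np.argwhere(sweep)
    N, K = centers.shape[0], spec.size
    s = np.empty((N, K), dtype=np.float64)
    pg = np.empty((N, K), dtype=np.float64)
    pw = np.empty((N, K), dtype=np.float64)
    lab = np.empty((N, K), dtype=np.int64)
    ci, cj, cl = centers[:, 0] + r, centers[:, 1] + r, centers[:, 2] + r
    for k, (dx, dy, dz) in enumerate(offs):
        ii, jj, ll = ci + dx, cj + dy, cl + dz
        s[:, k] = sig_p[ii, jj, ll]
        pg[:, k] = pg_p[ii, jj, ll]
        pw[:, k] = pw_p[ii, jj, ll]
        lab[:, k] = lab_p[ii, jj, ll]
    in_volume = lab >= 0
    usable = (lab == GM) | (lab == WM)
    return KernelStacks(
        centers=centers,
        p=np.stack([pg, pw], axis=-1),
        s=s,
        usable=usable,
        in_volume=in_volume,
        center_col=K // 2,
        spec=spec,
        shape=vol.shape,
    )


def weighted_fit(stacks: KernelStacks, w: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched 2-parameter weighted least squares.

    ``w`` is an (N, K) 0/1 row-selection matrix. Returns ``(m, ok)`` with
    m of shape (N, 2); ``ok`` is False where the selected design is
    rank deficient (condition number of P^T P beyond ``COND_LIMIT``), and
    the corresponding m rows are zero.
    """
    pg = stacks.p[..., 0]
    pw = stacks.p[..., 1]
    wf = w.astype(np.float64)
    a11 = np.einsum("nk,nk,nk->n", wf, pg, pg)
    a12 = np.einsum("nk,nk,nk->n", wf, pg, pw)
    a22 = np.einsum("nk,nk,nk->n", wf, pw, pw)
    b1 = np.einsum("nk,nk,nk->n", wf, pg, stacks.s)
    b2 = np.einsum("nk,nk,nk->n", wf, pw, stacks.s)
    det = a11 * a22 - a12 * a12
    tr = a11 + a22
    disc = np.sqrt(np.maximum(tr * tr - 4.0 * det, 0.0))
    lam_max = 0.5 * (tr + disc)
    lam_min = 0.5 * (tr - disc)
    ok = (lam_min > 0) & (lam_max <= COND_LIMIT * lam_min)
    safe_det = np.where(ok, det, 1.0)
    m_gm = (a22 * b1 - a12 * b2) / safe_det
    m_wm = (a11 * b2 - a12 * b1) / safe_det
    m = np.stack([np.where(ok, m_gm, 0.0), np.where(ok, m_wm, 0.0)], axis=-1)
    return m, ok


def _assemble_result(
    stacks: KernelStacks,
    m: np.ndarray,
    ok: np.ndarray,
    vol: Volume3D,
    mask: LabelMask,
) -> "PVCResult":
    """Scatter batched estimates back onto the grid with QC flags."""
    shape = stacks.shape
    m_gm = np.zeros(shape)
    m_wm = np.zeros(shape)
    flags = np.full(shape, QC_OUT_OF_MASK, dtype=np.int16)
    idx = tuple(stacks.centers.T)

    n_use = stacks.usable.sum(axis=1)
    enough = n_use >= MIN_ROWS
    good = ok & enough
    truncated = ~stacks.in_volume.all(axis=1)

    vox_flags = np.where(good, np.where(truncated, QC_EDGE_TRUNCATED, QC_OK),
                         QC_RANK_DEFICIENT_ZEROED)
    flags[idx] = vox_flags
    m_gm[idx] = np.where(good, m[:, 0], 0.0)
    m_wm[idx] = np.where(good, m[:, 1], 0.0)

    # residual RMSE over usable rows, nominal d.f. = K - 2
    pred = stacks.p[..., 0] * m[:, 0:1] + stacks.p[..., 1] * m[:, 1:2]
    resid = np.where(stacks.usable, stacks.s - pred, 0.0)
    rss = np.einsum("nk,nk->n", resid, resid)
    rmse_vals = np.where(good, np.sqrt(rss / stacks.spec.dof), 0.0)
    rmse = np.zeros(shape)
    rmse[idx] = rmse_vals

    return PVCResult(
        m_gm=vol.like(m_gm),
        m_wm=vol.like(m_wm),
        rmse=vol.like(rmse),
        qc_flags=flags,
        mask=mask,
        spec=stacks.spec,
    )


@dataclass
class PVCResult:
    """Per-tissue pure-signal maps plus per-voxel RMSE and QC flags."""

    m_gm: Volume3D
    m_wm: Volume3D
    rmse: Volume3D
    qc_flags: np.ndarray
    mask: LabelMask
    spec: KernelSpec | None = None
    meta: dict = field(default_factory=dict)

    @property
    def valid(self) -> np.ndarray:
        """Voxels carrying a usable estimate (OK or edge-truncated)."""
        return (self.qc_flags == QC_OK) | (self.qc_flags == QC_EDGE_TRUNCATED)

    def combined_map(self) -> Volume3D:
        """Corrected image: M_GM at GM voxels, M_WM at WM voxels, else 0."""
        lab = self.mask.labels
        data = np.where(lab == GM, self.m_gm.data,
                        np.where(lab == WM, self.m_wm.data, 0.0))
        return self.m_gm.like(data)

    def qc_counts(self) -> dict[str, int]:
        names = {
            QC_OK: "ok",
            QC_OUT_OF_MASK: "out_of_mask",
            QC_RANK_DEFICIENT_ZEROED: "rank_deficient_zeroed",
            QC_EDGE_TRUNCATED: "edge_truncated",
        }
        return {name: int((self.qc_flags == code).sum()) for code, name in names.items()}


def lr_pvc(
    vol: Volume3D,
    tpm: TissueProbabilityMap,
    mask: LabelMask,
    spec: KernelSpec,
) -> PVCResult:
    """Voxel-wise OLS sweep over all GM/WM voxels.

    Per center voxel the kernel rows (GM/WM-labelled, inside the volume)
    form the design; the fitted pure intensities M_GM and M_WM are stored
    at the center. Centers with fewer than ``MIN_ROWS`` usable rows or a
    rank-deficient design are zeroed and flagged RANK_DEFICIENT_ZEROED;
    voxels outside GM/WM are zero with OUT_OF_MASK.
    """
    stacks = build_stacks(vol, tpm, mask, spec)
    m, ok = weighted_fit(stacks, stacks.usable)
    return _assemble_result(stacks, m, ok, vol, mask)


def rmse_map(
    vol: Volume3D,
    tpm: TissueProbabilityMap,
    mask: LabelMask,
    spec: KernelSpec,
    estimates: PVCResult,
) -> Volume3D:
    """Recompute the per-voxel regression RMSE for existing estimates.

    RMSE = sqrt(sum of squared residuals over usable kernel rows / (K-2))
    with the nominal kernel size K; flagged voxels get RMSE 0.
    """
    stacks = build_stacks(vol, tpm, mask, spec)
    idx = tuple(stacks.centers.T)
    m = np.stack([estimates.m_gm.data[idx], estimates.m_wm.data[idx]], axis=-1)
    pred = stacks.p[..., 0] * m[:, 0:1] + stacks.p[..., 1] * m[:, 1:2]
    resid = np.where(stacks.usable, stacks.s - pred, 0.0)
    rss = np.einsum("nk,nk->n", resid, resid)
    vals = np.sqrt(rss / spec.dof)
    vals[~estimates.valid[idx]] = 0.0
    out = np.zeros(vol.shape)
    out[idx] = vals
    return vol.like(out)
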