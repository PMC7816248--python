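import numpy as np
import pytest

from napvc.regression import (
    KernelSpec,
    QC_OK,
    QC_OUT_OF_MASK,
    QC_RANK_DEFICIENT_ZEROED,
    RankDeficientError,
    extract_kernel,
    lr_pvc,
    ols_fit,
    rmse_map,
)
from napvc.volumes import (
    BACKGROUND,
    CSF,
    GM,
    WM,
    LabelMask,
    TissueProbabilityMap,
    Volume3D,
)


def normal_equations_oracle(P, S):
    """Explicit-inverse least squares (independent of ols_fit's path)."""
    ptp = np.array([[P[:, 0] @ P[:, 0], P[:, 0] @ P[:, 1]],
                    [P[:, 1] @ P[:, 0], P[:, 1] @ P[:, 1]]])
    det = ptp[0, 0] * ptp[1, 1] - ptp[0, 1] * ptp[1, 0]
    inv = np.array([[ptp[1, 1], -ptp[0, 1]], [-ptp[1, 0], ptp[0, 0]]]) / det
    return inv @ (P.T @ S)


def random_instance(rng, rows=27):
    P = rng.uniform(0.05, 1.0, size=(rows, 2))
    S = P @ np.array([48.0, 43.0]) + rng.normal(scale=2.0, size=rows)
    return P, S


class TestKernelSpec:
    @pytest.mark.parametrize("dims,n,size,dof", [(2, 5, 25, 23), (2, 7, 49, 47), (3, 3, 27, 25)])
    def test_size_and_dof(self, dims, n, size, dof):
        spec = KernelSpec(dims=dims, n=n)
        assert spec.size == size and spec.dof == dof

    def test_even_or_tiny_kernels_rejected(self):
        with pytest.raises(ValueError):
            KernelSpec(dims=3, n=4)
        with pytest.raises(ValueError):
            KernelSpec(dims=2, n=1)

    def test_center_offset_sits_at_middle_row(self):
        for spec in (KernelSpec(3, 3), KernelSpec(2, 5)):
            offs = spec.offsets()
            np.testing.assert_array_equal(offs[spec.size // 2], (0, 0, 0))

    def test_2d_kernel_stays_in_slice_plane(self):
        offs = KernelSpec(dims=2, n=5).offsets()
        assert (offs[:, 2] == 0).all()


class TestOlsFit:
    def test_consistent_system_recovers_exact_values(self):
        P = np.array([[1.0, 0.0], [0.0, 1.0], [0.5, 0.5]])
        S = np.array([48.0, 43.0, 45.5])
        np.testing.assert_allclose(ols_fit(P, S), [48.0, 43.0], atol=1e-12)

    def test_collinear_design_raises(self):
        P = np.tile([[0.5, 0.5]], (10, 1))
        with pytest.raises(RankDeficientError):
            ols_fit(P, np.full(10, 45.5))

    def test_too_few_rows_raise(self):
        with pytest.raises(RankDeficientError):
            ols_fit(np.array([[1.0, 0.0], [0.0, 1.0]]), np.array([1.0, 2.0]))

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(200):
            P, S = random_instance(rng)
            np.testing.assert_allclose(ols_fit(P, S), normal_equations_oracle(P, S),
                                       rtol=1e-10, atol=1e-10)


def _uniform_case(shape=(8, 8, 8), csf_box=None):
    """A grid where the two-tissue model holds exactly with m = (48, 43)."""
    rng = np.random.default_rng(7)
    pg = rng.uniform(0.05, 0.6, size=shape)
    pw = np.clip(rng.uniform(0.05, 0.6, size=shape), 0, 1 - pg)
    pc = np.zeros(shape)
    labels = np.where(pg >= pw, GM, WM).astype(np.int16)
    if csf_box is not None:
        sl = tuple(slice(*b) for b in csf_box)
        pc[sl] = 0.9
        pg[sl] = 0.05
        pw[sl] = 0.05
        labels[sl] = CSF
    signal = 48.0 * pg + 43.0 * pw  # CSF carries no signal
    tpm = TissueProbabilityMap(p_gm=Volume3D(pg), p_wm=Volume3D(pw), p_csf=Volume3D(pc))
    return Volume3D(signal), tpm, LabelMask(labels=labels)


class TestExtractKernel:
    def test_interior_full_kernel_has_27_rows(self):
        vol, tpm, mask = _uniform_case()
        P, S, c = extract_kernel(vol, tpm, mask, (4, 4, 4), KernelSpec(3, 3))
        assert P.shape == (27, 2) and S.shape == (27,)
        assert 0 <= c < 27

    def test_corner_kernel_truncates_to_8_candidates(self):
        vol, tpm, mask = _uniform_case()
        P, _, _ = extract_kernel(vol, tpm, mask, (0, 0, 0), KernelSpec(3, 3))
        assert P.shape[0] == 8

    def test_csf_rows_excluded(self):
        # a 3x3x3 kernel overlapping a CSF slab of 5 voxels keeps 22 rows
        vol, tpm, mask = _uniform_case(csf_box=((3, 4), (3, 6), (3, 6)))
        n_csf_in_kernel = int((mask.labels[2:5, 2:5, 2:5] == CSF).sum())
        P, _, _ = extract_kernel(vol, tpm, mask, (3, 3, 3), KernelSpec(3, 3))
        assert P.shape[0] == 27 - n_csf_in_kernel
        assert n_csf_in_kernel > 0


class TestLrPvc:
    def test_exact_recovery_on_model_consistent_volume(self):
        vol, tpm, mask = _uniform_case()
        res = lr_pvc(vol, tpm, mask, KernelSpec(3, 3))
        ok = res.qc_flags == QC_OK
        assert ok.any()
        np.testing.assert_allclose(res.m_gm.data[ok], 48.0, atol=1e-8)
        np.testing.assert_allclose(res.m_wm.data[ok], 43.0, atol=1e-8)
        np.testing.assert_allclose(res.rmse.data[ok], 0.0, atol=1e-8)

    def test_uniform_zero_image_gives_zero_maps(self):
        vol, tpm, mask = _uniform_case()
        res = lr_pvc(vol.like(np.zeros(vol.shape)), tpm, mask, KernelSpec(3, 3))
        assert np.all(res.m_gm.data == 0) and np.all(res.m_wm.data == 0)

    def test_out_of_mask_and_rank_deficient_flags(self):
        vol, tpm, mask = _uniform_case(csf_box=((0, 3), (0, 8), (0, 8)))
        res = lr_pvc(vol, tpm, mask, KernelSpec(3, 3))
        assert (res.qc_flags[mask.labels == CSF] == QC_OUT_OF_MASK).all()
        # force collinearity: pure-WM region has rank-deficient kernels
        pg = np.zeros((8, 8, 8)); pw = np.full((8, 8, 8), 0.9)
        tpm2 = TissueProbabilityMap(p_gm=Volume3D(pg), p_wm=Volume3D(pw),
                                    p_csf=Volume3D(np.zeros((8, 8, 8))))
        mask2 = LabelMask(labels=np.full((8, 8, 8), WM, dtype=np.int16))
        res2 = lr_pvc(Volume3D(43 * pw), tpm2, mask2, KernelSpec(3, 3))
        assert (res2.qc_flags == QC_RANK_DEFICIENT_ZEROED).all()
        assert np.all(res2.m_wm.data == 0)

    def test_phantom_gm_wm_means_near_truth(self, phantom):
        res = lr_pvc(phantom.contaminated, phantom.tpm, phantom.mask, KernelSpec(2, 5))
        sel = phantom.rois["gm"] & res.valid
        assert res.m_gm.data[sel].mean() == pytest.approx(48.0, abs=2.0)

    def test_blurring_grows_with_2d_kernel_size_on_lesion(self, phantom):
        errs = {}
        for n in (5, 7):
            res = lr_pvc(phantom.contaminated, phantom.tpm, phantom.mask, KernelSpec(2, n))
            sel = phantom.rois["lesion_0"] & res.valid
            errs[n] = abs(70.0 - res.combined_map().data[sel].mean())
        assert errs[7] >= errs[5]


class TestRmseMap:
    def test_hand_computed_residual_with_nominal_dof(self):
        # one interior voxel with a known inconsistent signal
        vol, tpm, mask = _uniform_case()
        bumped = vol.data.copy()
        bumped[4, 4, 4] += 5.0
        res = lr_pvc(Volume3D(bumped), tpm, mask, KernelSpec(3, 3))
        rm = rmse_map(Volume3D(bumped), tpm, mask, KernelSpec(3, 3), res)
        P, S, _ = extract_kernel(Volume3D(bumped), tpm, mask, (4, 4, 4), KernelSpec(3, 3))
        m = np.array([res.m_gm.data[4, 4, 4], res.m_wm.data[4, 4, 4]])
        r = S - P @ m
        assert rm.data[4, 4, 4] == pytest.approx(np.sqrt(r @ r / 25.0), rel=1e-10)
        np.testing.assert_allclose(rm.data, res.rmse.data, atol=1e-10)

    def test_invariant_to_adding_exact_model_component(self):
        vol, tpm, mask = _uniform_case()
        rng = np.random.default_rng(3)
        noisy = vol.like(vol.data + rng.normal(scale=1.0, size=vol.shape))
        res1 = lr_pvc(noisy, tpm, mask, KernelSpec(3, 3))
        shifted = noisy.like(noisy.data + 10.0 * tpm.p_gm.data + 4.0 * tpm.p_wm.data)
        res2 = lr_pvc(shifted, tpm, mask, KernelSpec(3, 3))
        ok = res1.valid & res2.valid
        np.testing.assert_allclose(res1.rmse.data[ok], res2.rmse.data[ok], atol=1e-8)
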