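import dataclasses

import numpy as np
import pytest

from napvc.phantom import (
    LesionSpec,
    NoiseSpec,
    PhantomSpec,
    add_noise,
    contaminate,
    generate_highres_labels,
    generate_synthetic_tpm,
    make_ground_truth,
    mask_lesion_regions,
    pure_value_fields,
    run_monte_carlo,
    simulate_phantom,
)
from napvc.volumes import BACKGROUND, CSF, GM, WM, Volume3D, tpm_to_mask


class TestSyntheticTpm:
    def test_probability_sums_bounded_and_interior_saturated(self, small_spec):
        tpm = generate_synthetic_tpm(small_spec, seed=3)
        total = tpm.p_gm.data + tpm.p_wm.data + tpm.p_csf.data
        assert total.max() <= 1 + 1e-9
        # deep inside the head every high-res voxel is some tissue
        center = tuple(s // 2 for s in tpm.shape)
        assert total[center] == pytest.approx(small_spec.tissue_confidence, abs=1e-9)

    def test_identical_seed_identical_tpm(self, small_spec):
        a = generate_synthetic_tpm(small_spec, seed=9)
        b = generate_synthetic_tpm(small_spec, seed=9)
        np.testing.assert_array_equal(a.p_gm.data, b.p_gm.data)
        np.testing.assert_array_equal(a.p_csf.data, b.p_csf.data)

    def test_downsample_factor_one_is_binary(self, small_spec):
        spec = dataclasses.replace(small_spec, downsample_factor=1)
        tpm = generate_synthetic_tpm(spec, seed=2)
        for field in (tpm.p_gm.data, tpm.p_wm.data, tpm.p_csf.data):
            assert set(np.unique(field)) <= {0.0, 1.0}

    def test_mixed_voxels_exist_at_factor_four(self, small_spec):
        # brute-force count on the high-res labels: blocks whose 4^3
        # sub-voxels disagree must yield fractional probabilities
        labels = generate_highres_labels(small_spec, seed=3)
        f = small_spec.downsample_factor
        nx, ny, nz = labels.shape
        blocks = labels.reshape(nx // f, f, ny // f, f, nz // f, f)
        gm_frac = (blocks == GM).mean(axis=(1, 3, 5))
        n_mixed = int(((gm_frac > 0) & (gm_frac < 1)).sum())
        assert n_mixed > 0
        tpm = generate_synthetic_tpm(small_spec, seed=3)
        mask = tpm_to_mask(tpm)
        sel = mask.labels == GM
        assert (tpm.p_gm.data[sel] < 1).any()

    def test_oversized_brain_rejected(self, small_spec):
        spec = dataclasses.replace(small_spec, brain_semiaxes=(80.0, 45.0, 32.0))
        with pytest.raises(ValueError, match="bounds"):
            generate_highres_labels(spec, seed=0)


class TestGroundTruth:
    def test_label_values_and_lesion_overrides(self, small_spec):
        tpm = generate_synthetic_tpm(small_spec, seed=3)
        mask = tpm_to_mask(tpm)
        gt = make_ground_truth(mask, small_spec)
        regions = mask_lesion_regions(mask, small_spec)
        outside = ~(regions[0] | regions[1])
        assert set(np.unique(gt.data[(mask.labels == GM) & outside])) == {48.0}
        assert set(np.unique(gt.data[(mask.labels == WM) & outside])) == {43.0}
        assert set(np.unique(gt.data[(mask.labels == BACKGROUND) & outside])) == {0.0}
        assert set(np.unique(gt.data[regions[0]])) == {70.0}
        assert set(np.unique(gt.data[regions[1]])) == {30.0}

    def test_overlapping_lesions_rejected(self, small_spec):
        spec = dataclasses.replace(
            small_spec,
            lesions=(LesionSpec((0.0, 0.0, 0.0), 10.0, 70.0),
                     LesionSpec((4.0, 0.0, 0.0), 10.0, 30.0)),
        )
        tpm = generate_synthetic_tpm(spec, seed=3)
        with pytest.raises(ValueError, match="verlapping"):
            make_ground_truth(tpm_to_mask(tpm), spec)


class TestContaminate:
    def test_mixture_arithmetic(self, small_spec):
        ph = simulate_phantom(small_spec, seed=3)
        pg, pw = ph.tpm.p_gm.data, ph.tpm.p_wm.data
        outside = ~np.any(mask_lesion_regions(ph.mask, small_spec), axis=0)
        expected = 48.0 * pg + 43.0 * pw
        np.testing.assert_allclose(ph.contaminated.data[outside], expected[outside])
        # a pure-GM voxel outside the lesions is unchanged at 48
        pure = (pg == 1.0) & outside
        if pure.any():
            assert set(np.unique(ph.contaminated.data[pure])) == {48.0}

    def test_linearity_in_pure_value_fields(self, small_spec):
        ph = simulate_phantom(small_spec, seed=3)
        scaled = tuple(f.like(2.5 * f.data) for f in ph.fields)
        np.testing.assert_allclose(contaminate(ph.tpm, scaled).data,
                                   2.5 * ph.contaminated.data, rtol=1e-12)

    def test_bounded_by_pure_values_where_probabilities_saturate(self, small_spec):
        ph = simulate_phantom(small_spec, seed=3)
        total = ph.tpm.p_gm.data + ph.tpm.p_wm.data + ph.tpm.p_csf.data
        m_max = np.maximum.reduce([f.data for f in ph.fields])
        m_min = np.minimum.reduce([f.data for f in ph.fields])
        sat = total > 1 - 1e-9
        assert (ph.contaminated.data[sat] <= m_max[sat] + 1e-9).all()
        assert (ph.contaminated.data[sat] >= m_min[sat] - 1e-9).all()

    def test_gm_mask_mean_underestimates_truth(self, phantom):
        sel = phantom.rois["gm"]
        assert phantom.contaminated.data[sel].mean() < 48.0

    def test_shape_mismatch_rejected(self, small_spec, phantom):
        fields = pure_value_fields(phantom.mask, PhantomSpec())
        tpm = generate_synthetic_tpm(small_spec, seed=3)
        with pytest.raises(ValueError):
            contaminate(tpm, fields)


class TestNoise:
    def test_sigma_zero_identity(self, phantom):
        out = add_noise(phantom.contaminated, NoiseSpec(sigma=0.0, seed=4))
        np.testing.assert_array_equal(out.data, phantom.contaminated.data)

    def test_same_seed_identical_different_seed_not(self, phantom):
        a = add_noise(phantom.contaminated, NoiseSpec(sigma=3.0, seed=4))
        b = add_noise(phantom.contaminated, NoiseSpec(sigma=3.0, seed=4))
        c = add_noise(phantom.contaminated, NoiseSpec(sigma=3.0, seed=5))
        np.testing.assert_array_equal(a.data, b.data)
        assert not np.array_equal(a.data, c.data)

    def test_sample_sd_matches_sigma(self, phantom):
        # ~66k voxels: the sample SD concentrates within ~1% of sigma
        out = add_noise(phantom.contaminated, NoiseSpec(sigma=3.0, seed=4))
        resid = out.data - phantom.contaminated.data
        assert resid.std() == pytest.approx(3.0, rel=0.02)
        assert abs(resid.mean()) < 0.05


class TestMonteCarlo:
    def test_single_iteration_noise_free_has_zero_sd(self, small_spec):
        tab = run_monte_carlo(small_spec, sigmas=(0.0,), method="lr3d",
                              n_iter=1, seed=3)
        assert (tab["uncorrected_sd"] == 0).all()
        assert (tab["corrected_sd"] == 0).all()

    def test_correction_reduces_delta_tsc(self, small_spec):
        tab = run_monte_carlo(small_spec, sigmas=(3.0,), method="mlts",
                              n_iter=2, seed=3)
        assert (tab["corrected_mean"] < tab["uncorrected_mean"]).all()

    def test_roi_means_stable_when_doubling_iterations(self, small_spec):
        t2 = run_monte_carlo(small_spec, sigmas=(3.0,), method="lr3d", n_iter=2, seed=3)
        t4 = run_monte_carlo(small_spec, sigmas=(3.0,), method="lr3d", n_iter=4, seed=3)
        merged = t2.merge(t4, on=["roi", "sigma"], suffixes=("_2", "_4"))
        for _, row in merged.iterrows():
            se = max(row["corrected_sd_4"] / np.sqrt(4), 1e-6)
            assert abs(row["corrected_mean_2"] - row["corrected_mean_4"]) < 3 * se + 0.05

    def test_unknown_method_rejected(self, small_spec):
        with pytest.raises(ValueError):
            run_monte_carlo(small_spec, sigmas=(0.0,), method="magic", n_iter=1)
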