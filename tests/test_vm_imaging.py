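"""Tests for the tubeness ridge filter and the VM scoring pipeline."""

import numpy as np
import pytest
from scipy import ndimage

from vmquant.synthetic_data import SyntheticImageSpec, generate_vm_image
from vmquant.vm_imaging import (
    PASCategory,
    TwoChannelImage,
    TubenessField,
    classify_pas_category,
    compare_vm_by_group,
    compute_vm_score,
    detect_tissue,
    hessian_eigenvalues,
    quantify_vm,
    segment_cd31,
    segment_networks,
    subtract_vessels,
    tubeness,
)


def _d2_6th(a, axis):
    """Sixth-order central second difference along an axis."""
    s = [np.roll(a, k, axis=axis) for k in (3, 2, 1, 0, -1, -2, -3)]
    return (
        2 * s[0] - 27 * s[1] + 270 * s[2] - 490 * s[3] + 270 * s[4] - 27 * s[5] + 2 * s[6]
    ) / 180.0


def _d1_6th(a, axis):
    s = [np.roll(a, k, axis=axis) for k in (3, 2, 1, -1, -2, -3)]
    return (-s[0] + 9 * s[1] - 45 * s[2] + 45 * s[3] - 9 * s[4] + s[5]) / 60.0


def fd_hessian_eigs(raster, sigma):
    """Independent oracle: high-order central finite differences applied to
    the Gaussian-smoothed raster (stencil error well below the 1e-3
    comparison tolerance)."""
    sm = ndimage.gaussian_filter(
        np.asarray(raster, float), sigma, mode="reflect", truncate=8.0
    )
    hrr = _d2_6th(sm, 0)
    hcc = _d2_6th(sm, 1)
    hrc = _d1_6th(_d1_6th(sm, 0), 1)
    tr = hrr + hcc
    disc = np.sqrt((hrr - hcc) ** 2 + 4 * hrc**2)
    lo, hi = (tr - disc) / 2, (tr + disc) / 2
    swap = np.abs(lo) > np.abs(hi)
    return np.where(swap, hi, lo), np.where(swap, lo, hi)


def sort_stable_mask(o1, o2, scale, tol=1e-3):
    """Pixels where the magnitude sort of the eigenvalue pair is robust.

    Where |lam1| ~ |lam2| with opposite signs the magnitude ordering flips
    under perturbations far smaller than the comparison tolerance, so those
    (rare) pixels are excluded from pointwise sorted comparisons.
    """
    return np.abs(np.abs(o1) - np.abs(o2)) > tol * scale


class TestHessianEigenvalues:
    def test_constant_raster_zero(self):
        lam1, lam2 = hessian_eigenvalues(np.full((64, 64), 3.0), 2.0)
        np.testing.assert_allclose(lam1, 0, atol=1e-12)
        np.testing.assert_allclose(lam2, 0, atol=1e-12)

    def test_pure_quadratic(self):
        # I = x^2 + y^2: Hessian diag(2, 2) at any smoothing scale (interior)
        y, x = np.mgrid[0:96, 0:96].astype(float)
        raster = (x - 48) ** 2 + (y - 48) ** 2
        # rtol accommodates discrete-kernel aliasing at sigma = 1
        for sigma, rtol in ((1.0, 1e-4), (3.0, 1e-9)):
            lam1, lam2 = hessian_eigenvalues(raster, sigma)
            interior = (slice(30, 66), slice(30, 66))
            np.testing.assert_allclose(lam1[interior], 2.0, rtol=rtol)
            np.testing.assert_allclose(lam2[interior], 2.0, rtol=rtol)

    def test_finite_difference_oracle(self):
        rng = np.random.default_rng(0)
        raster = rng.uniform(size=(64, 64))
        lam1, lam2 = hessian_eigenvalues(raster, 3.0)
        o1, o2 = fd_hessian_eigs(raster, 3.0)
        interior = (slice(8, -8), slice(8, -8))
        scale = np.abs(o2[interior]).max()
        ok = sort_stable_mask(o1[interior], o2[interior], scale)
        assert ok.mean() > 0.99
        assert np.abs((lam2[interior] - o2[interior])[ok]).max() / scale < 1e-3
        assert np.abs((lam1[interior] - o1[interior])[ok]).max() / scale < 1e-3

    def test_magnitude_sorted(self):
        rng = np.random.default_rng(1)
        lam1, lam2 = hessian_eigenvalues(rng.normal(size=(40, 40)), 2.0)
        assert (np.abs(lam1) <= np.abs(lam2) + 1e-15).all()

    def test_nonfinite_rejected(self):
        bad = np.ones((64, 64))
        bad[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            hessian_eigenvalues(bad, 2.0)

    def test_small_sigma_rejected(self):
        with pytest.raises(ValueError, match="sigma"):
            hessian_eigenvalues(np.ones((64, 64)), 0.2)


def gaussian_ridge(width, shape=(101, 101), amplitude=1.0):
    x = np.arange(shape[1], dtype=float) - shape[1] // 2
    return amplitude * np.exp(-(x**2) / (2 * width**2))[None, :] * np.ones(
        (shape[0], 1)
    )


class TestTubeness:
    def test_nonnegative_everywhere(self):
        rng = np.random.default_rng(5)
        field = tubeness(rng.normal(size=(64, 64)), [2.0, 3.0])
        assert (field.response >= 0).all()

    def test_dark_line_zero_response(self):
        img = np.ones((64, 64))
        img[:, 32] = 0.0  # dark line on bright background
        field = tubeness(img, [2.0])
        assert field.response[20:44, 32].max() == 0.0

    @pytest.mark.parametrize("w,sigma", [(2.0, 2.0), (3.0, 2.0), (2.0, 4.0)])
    def test_closed_form_ridge_crest(self, w, sigma):
        # crest response sigma^2 * w / (w^2 + sigma^2)^(3/2)
        field = tubeness(gaussian_ridge(w), [sigma])
        expected = sigma**2 * w / (w**2 + sigma**2) ** 1.5
        crest = field.response[50, 50]
        assert crest == pytest.approx(expected, rel=0.01)

    def test_per_scale_matches_fd_oracle(self):
        rng = np.random.default_rng(9)
        raster = rng.uniform(size=(64, 64))
        sigma = 3.0
        field = tubeness(raster, [sigma])
        o1, o2 = fd_hessian_eigs(raster, sigma)
        oracle = sigma**2 * np.maximum(0, -o2)
        interior = (slice(8, -8), slice(8, -8))
        scale = oracle[interior].max()
        ok = sort_stable_mask(o1[interior], o2[interior], np.abs(o2[interior]).max())
        diff = np.abs(field.response[interior] - oracle[interior])[ok]
        assert diff.max() / scale < 1e-3

    def test_response_is_max_over_scales(self):
        rng = np.random.default_rng(3)
        raster = rng.uniform(size=(64, 64))
        field = tubeness(raster, [2.0, 3.0, 4.0])
        np.testing.assert_allclose(field.response, field.per_scale.max(axis=0))

    def test_rotation_equivariance(self):
        ridge = gaussian_ridge(2.0)
        r0 = tubeness(ridge, [2.0]).response[50, 50]
        r90 = tubeness(np.rot90(ridge), [2.0]).response[50, 50]
        assert r90 == pytest.approx(r0, rel=0.02)

    def test_empty_scales_error(self):
        with pytest.raises(ValueError, match="non-empty|scales"):
            tubeness(np.ones((64, 64)), [])


class TestDetectTissue:
    def test_explicit_mask_passthrough(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[10:20, 10:20] = True
        img = TwoChannelImage(np.ones((64, 64)), np.ones((64, 64)), tissue_mask=mask)
        assert detect_tissue(img) is mask

    def test_full_tissue_covered(self):
        gt = generate_vm_image(SyntheticImageSpec(seed=3, tissue_fraction=1.0))
        assert detect_tissue(gt.image).mean() >= 0.99

    def test_disk_recovered_within_5pct(self):
        gt = generate_vm_image(SyntheticImageSpec(seed=3, tissue_fraction=0.5))
        est = detect_tissue(gt.image).sum()
        true = gt.true_tissue_mask.sum()
        assert abs(est - true) / true < 0.05

    def test_all_background_error(self):
        img = TwoChannelImage(np.zeros((64, 64)), np.zeros((64, 64)))
        with pytest.raises(ValueError, match="no tissue"):
            detect_tissue(img)


class TestSegmentation:
    def test_zero_response_empty_mask(self):
        field = TubenessField(response=np.zeros((64, 64)), scales_px=[2.0])
        nm = segment_networks(field, np.ones((64, 64), dtype=bool))
        assert not nm.mask.any()
        assert nm.n_components == 0

    def test_min_component_dominates(self):
        field = TubenessField(response=np.zeros((64, 64)), scales_px=[2.0])
        field.response[10:12, 10:12] = 5.0  # 4-px blob
        nm = segment_networks(
            field,
            np.ones((64, 64), dtype=bool),
            threshold_policy="fixed",
            threshold_value=1.0,
            min_component_px=1000,
        )
        assert not nm.mask.any()

    def test_jaccard_against_truth(self):
        gt = generate_vm_image(
            SyntheticImageSpec(seed=4, noise_sd=0.05, vessel_overlap_fraction=0.0)
        )
        field = tubeness(gt.image.pas, [2.0, 3.0, 4.0])
        nm = segment_networks(
            field,
            gt.true_tissue_mask,
            threshold_policy="fixed",
            threshold_value=0.19,
            min_component_px=20,
        )
        inter = (nm.mask & gt.true_network_mask).sum()
        union = (nm.mask | gt.true_network_mask).sum()
        assert inter / union >= 0.6

    def test_cd31_zero_channel_empty(self):
        nm = segment_cd31(np.zeros((64, 64)), np.ones((64, 64), dtype=bool))
        assert not nm.mask.any()

    def test_cd31_area_within_20pct(self):
        gt = generate_vm_image(SyntheticImageSpec(seed=6, noise_sd=0.05))
        # exp(-1/2) threshold puts the cut exactly one tube-width out
        nm = segment_cd31(
            gt.image.cd31,
            gt.true_tissue_mask,
            threshold_policy="fixed",
            threshold_value=np.exp(-0.5) + 0.075,
            min_component_px=20,
        )
        true_area = gt.true_vessel_mask.sum()
        assert abs(int(nm.mask.sum()) - true_area) / true_area < 0.20


class TestSubtractAndScore:
    def test_disjoint_masks_unchanged(self):
        a = np.zeros((16, 16), dtype=bool)
        b = np.zeros((16, 16), dtype=bool)
        a[2:5, 2:5] = True
        b[10:12, 10:12] = True
        np.testing.assert_array_equal(subtract_vessels(a, b, 0), a)

    def test_superset_empties(self):
        a = np.zeros((16, 16), dtype=bool)
        a[4:8, 4:8] = True
        b = np.ones((16, 16), dtype=bool)
        assert not subtract_vessels(a, b, 0).any()

    def test_overlap_pixel_count(self):
        # brute-force pixel count on a constructed 16x16 case
        a = np.zeros((16, 16), dtype=bool)
        b = np.zeros((16, 16), dtype=bool)
        a[0:4, 0:8] = True  # 32 px
        b[2:6, 4:12] = True  # overlap rows 2-3, cols 4-7 -> k = 8
        out = subtract_vessels(a, b, 0)
        assert out.sum() == 32 - 8

    def test_negative_dilation_error(self):
        a = np.zeros((8, 8), dtype=bool)
        with pytest.raises(ValueError, match="dilation"):
            subtract_vessels(a, a, -1)

    def test_score_bounds_and_extremes(self):
        tissue = np.ones((32, 32), dtype=bool)
        assert compute_vm_score(np.zeros_like(tissue), tissue) == 0.0
        assert compute_vm_score(tissue, tissue) == 100.0

    def test_empty_tissue_error(self):
        with pytest.raises(ValueError, match="tissue"):
            compute_vm_score(np.ones((8, 8), dtype=bool), np.zeros((8, 8), dtype=bool))

    def test_score_monotone_in_dilation(self):
        gt = generate_vm_image(SyntheticImageSpec(seed=2, vessel_overlap_fraction=0.5))
        field = tubeness(gt.image.pas, [2.0, 3.0, 4.0])
        pas = segment_networks(field, gt.true_tissue_mask, "fixed", 0.19, 20)
        cd31 = segment_cd31(gt.image.cd31, gt.true_tissue_mask, "fixed", 0.5, 20)
        scores = [
            compute_vm_score(
                subtract_vessels(pas.mask, cd31.mask, d), gt.true_tissue_mask
            )
            for d in (0, 1, 2, 4)
        ]
        assert all(s1 >= s2 for s1, s2 in zip(scores, scores[1:]))


class TestClassifyPASCategory:
    def test_empty_mask_negative(self):
        assert (
            classify_pas_category(np.zeros((32, 32), dtype=bool), 0.0)
            is PASCategory.NEG
        )

    def test_straight_tube_low_despite_area(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[18:24, :] = True  # 15% of area, no branch point
        assert classify_pas_category(mask, 0.15) is PASCategory.LOW

    def test_branched_network_high(self):
        mask = np.zeros((40, 40), dtype=bool)
        mask[18:22, :] = True
        mask[:, 18:22] = True  # cross: one branch point, ~19% area
        assert classify_pas_category(mask, 0.19) is PASCategory.HIGH

    def test_sparse_branched_network_low(self):
        mask = np.zeros((64, 64), dtype=bool)
        mask[30:32, 10:30] = True
        mask[10:30, 20:22] = True
        frac = mask.mean()
        assert frac < 0.10
        assert classify_pas_category(mask, frac) is PASCategory.LOW


class TestCompareVMByGroup:
    def test_identical_groups(self):
        scores = [(1.0, "pos"), (2.0, "pos"), (1.0, "neg"), (2.0, "neg")]
        m1, m2, p = compare_vm_by_group(scores)
        assert m1 == m2
        assert p == pytest.approx(1.0)

    def test_group_means(self):
        scores = [(0.0, "a")] * 4 + [(1.0, "b")] * 4
        m1, m2, _ = compare_vm_by_group(scores)
        assert (m1, m2) == (0.0, 1.0)

    def test_t_statistic_formula_oracle(self):
        rng = np.random.default_rng(10)
        a = rng.normal(3.0, 1.0, 1000)
        b = rng.normal(3.2, 1.5, 1000)
        scores = [(float(x), "a") for x in a] + [(float(x), "b") for x in b]
        _, _, p = compare_vm_by_group(scores)
        # from-scratch pooled-variance t-test
        na, nb = len(a), len(b)
        sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
        from scipy import stats as ss

        p_oracle = 2 * ss.t.sf(abs(t), na + nb - 2)
        assert p == pytest.approx(p_oracle, abs=1e-10)

    def test_small_group_error(self):
        with pytest.raises(ValueError, match=">= 2"):
            compare_vm_by_group([(1.0, "a"), (2.0, "b"), (3.0, "b")])


class TestFullPipeline:
    def test_full_costain_scores_zero(self):
        gt = generate_vm_image(SyntheticImageSpec(seed=8))
        img = TwoChannelImage(
            pas=gt.image.pas, cd31=gt.image.pas, tissue_mask=gt.true_tissue_mask
        )
        q = quantify_vm(img, threshold_policy="fixed", threshold_value=0.19)
        assert q.vm_score == pytest.approx(0.0, abs=0.2)

    def test_quantification_invariants(self, default_image):
        q = quantify_vm(
            default_image.image,
            scales_px=(2.0, 3.0, 4.0),
            threshold_policy="fixed",
            threshold_value=0.19,
            min_component_px=20,
            dilation_px=1,
        )
        assert 0 <= q.vm_score <= 100
        assert not (q.vm_mask & ~q.pas_network_mask).any()
        assert q.params["threshold_policy"] == "fixed"
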