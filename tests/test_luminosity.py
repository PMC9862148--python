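"""Composite construction against a per-voxel projection oracle, Q-Q
quantile behaviour, and the pair/ROI enumeration combinatorics."""

import numpy as np
import pytest

from twinscope.cohort import FamilyCohort, PAIR_SRD, PAIR_TD_OS, PAIR_TWINS
from twinscope.errors import (
    EmptyDistributionError,
    EmptyMaskError,
    StandardizationError,
    TwinscopeError,
)
from twinscope.luminosity import (
    AXES,
    CompositeImage,
    LuminosityDistribution,
    MaskVolume,
    build_composite,
    composite_from_mask,
    enumerate_roi_pairs,
    enumerate_subject_pairs,
    extract_distribution,
    most_similar_pair,
    qq_compare,
    save_composite_png,
    slice_mask,
)
from twinscope.regions import DORSAL_PATHWAY, FRONTAL_PATHWAY, VENTRAL_PATHWAY, PathwayDefinition
from twinscope.synthdata import ellipsoid_mask


def _vol(data, subject="s", roi="r"):
    return MaskVolume(np.asarray(data, dtype=np.uint8), np.eye(4), subject, roi)


def _dist(values, subject="s", roi="r", axis="axial"):
    return LuminosityDistribution(np.sort(np.asarray(values, float)), subject, roi, axis)


class TestSlicing:
    def test_ellipsoid_slice_count_matches_extent(self):
        vol = _vol(ellipsoid_mask((64, 64, 64), (32, 32, 32), (30, 30, 40)))
        assert len(slice_mask(vol, "axial")) == 40
        assert len(slice_mask(vol, "sagittal")) == 30

    def test_single_voxel_yields_one_slice_per_axis(self):
        data = np.zeros((8, 8, 8))
        data[3, 4, 5] = 1
        vol = _vol(data)
        for axis in AXES:
            stack = slice_mask(vol, axis)
            assert len(stack) == 1 and stack[0].sum() == 1

    def test_empty_mask_raises(self):
        with pytest.raises(EmptyMaskError):
            slice_mask(_vol(np.zeros((4, 4, 4))), "axial")


class TestComposite:
    def test_single_slice_saturates_foreground(self):
        s = np.zeros((5, 5), dtype=np.uint8)
        s[2, 2] = 1
        comp = build_composite([s], alpha_ref=1)
        assert comp.pixels[2, 2] == 255 and comp.pixels.sum() == 255

    def test_partial_presence_scales_linearly(self):
        """A pixel present in 20 of alpha_ref=40 layers -> round(255*20/40)."""
        on = np.ones((2, 2), dtype=np.uint8)
        off = np.zeros((2, 2), dtype=np.uint8)
        comp = build_composite([on] * 20 + [off] * 5, alpha_ref=40)
        assert comp.pixels[0, 0] == round(255 * 20 / 40) == 128

    def test_alpha_ref_below_stack_size_rejected(self):
        on = np.ones((2, 2), dtype=np.uint8)
        with pytest.raises(StandardizationError):
            build_composite([on] * 5, alpha_ref=4)

    def test_matches_voxel_projection_oracle_on_random_masks(self):
        rng = np.random.default_rng(21)
        for shape in [(8, 8, 8), (16, 16, 16), (16, 8, 12)]:
            data = (rng.random(shape) < 0.4).astype(np.uint8)
            if data.sum() == 0:
                data[0, 0, 0] = 1
            vol = _vol(data)
            for axis, dim in zip(AXES, range(3)):
                alpha = int(data.shape[dim])
                comp = composite_from_mask(vol, axis, alpha)
                counts = data.sum(axis=dim)  # independent per-voxel projection
                expected = np.minimum(255, np.rint(255.0 * counts / alpha))
                assert np.array_equal(comp.pixels, expected.astype(np.uint8))

    def test_slice_duplication_with_matching_alpha_is_invariant(self):
        """Scaling slice count and alpha_ref together preserves luminosity."""
        rng = np.random.default_rng(3)
        stack = [(rng.random((6, 6)) < 0.5).astype(np.uint8) for _ in range(9)]
        c1 = build_composite(stack, alpha_ref=10)
        c2 = build_composite([s for s in stack for _ in range(2)], alpha_ref=20)
        assert np.array_equal(c1.pixels, c2.pixels)

    def test_png_output_is_deterministic(self, tmp_path):
        comp = CompositeImage(
            pixels=np.arange(64, dtype=np.uint8).reshape(8, 8),
            axis="axial", subject_id="s", roi="r", n_slices_used=4, alpha_ref=4,
        )
        save_composite_png(comp, tmp_path / "a.png")
        save_composite_png(comp, tmp_path / "b.png")
        assert (tmp_path / "a.png").read_bytes() == (tmp_path / "b.png").read_bytes()


class TestDistribution:
    def test_uniform_composite_collapses_to_single_value(self):
        pix = np.zeros((4, 4), dtype=np.uint8)
        pix[:2] = 128
        comp = CompositeImage(pix, "axial", "s", "r", 2, 4)
        d = extract_distribution(comp)
        assert set(d.values) == {128.0} and d.values.size == 8

    def test_histogram_matches_pixel_scan(self):
        rng = np.random.default_rng(5)
        pix = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        comp = CompositeImage(pix, "axial", "s", "r", 3, 4)
        d = extract_distribution(comp)
        brute = sorted(int(v) for v in pix.ravel() if v > 0)
        assert [int(v) for v in d.values] == brute

    def test_include_zero_keeps_background(self):
        pix = np.zeros((3, 3), dtype=np.uint8)
        pix[0, 0] = 255
        comp = CompositeImage(pix, "axial", "s", "r", 1, 1)
        assert extract_distribution(comp, "include_zero").values.size == 9

    def test_all_background_raises(self):
        comp = CompositeImage(np.zeros((3, 3), dtype=np.uint8), "axial", "s", "r", 1, 1)
        with pytest.raises(EmptyDistributionError):
            extract_distribution(comp)


class TestQQ:
    def test_self_comparison_lies_on_identity(self):
        d = _dist(np.arange(1, 201))
        curve = qq_compare(d, d)
        assert curve.divergence == 0.0
        assert np.array_equal(curve.qx, curve.qy)

    def test_shift_appears_as_constant_offset(self):
        rng = np.random.default_rng(9)
        base = rng.uniform(20, 150, size=1000)
        curve = qq_compare(_dist(base), _dist(base + 50))
        assert np.allclose(curve.qy - curve.qx, 50.0, atol=1e-9)
        assert curve.divergence == pytest.approx(50 / 255, abs=1e-6)

    def test_quantiles_match_sorted_sample_oracle(self):
        rng = np.random.default_rng(13)
        values = rng.integers(1, 256, size=317).astype(float)
        curve = qq_compare(_dist(values), _dist(values), n_quantiles=49)
        srt = np.sort(values)
        for p, q in zip(curve.probs, curve.qx):
            h = (len(srt) - 1) * p  # linear interpolation between order stats
            lo = int(np.floor(h))
            expected = srt[lo] + (h - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])
            assert q == pytest.approx(expected, abs=1e-9)

    def test_divergence_is_symmetric(self):
        rng = np.random.default_rng(17)
        a, b = rng.integers(1, 256, 400).astype(float), rng.integers(1, 256, 300).astype(float)
        assert qq_compare(_dist(a), _dist(b)).divergence == pytest.approx(
            qq_compare(_dist(b), _dist(a)).divergence
        )

    def test_quantile_curves_are_monotone(self):
        rng = np.random.default_rng(19)
        a, b = rng.integers(1, 256, 211).astype(float), rng.integers(1, 256, 97).astype(float)
        curve = qq_compare(_dist(a), _dist(b))
        assert np.all(np.diff(curve.qx) >= 0) and np.all(np.diff(curve.qy) >= 0)


class TestEnumeration:
    def test_three_labelled_subject_pairs(self, cohort):
        pairs = enumerate_subject_pairs(cohort)
        assert set(pairs) == {PAIR_TWINS, PAIR_SRD, PAIR_TD_OS}

    def test_pair_set_invariant_under_subject_order(self, cohort):
        shuffled = FamilyCohort(subjects=list(reversed(cohort.subjects)))
        assert enumerate_subject_pairs(shuffled) == enumerate_subject_pairs(cohort)

    @pytest.mark.parametrize("pathway,n", [
        (VENTRAL_PATHWAY, 1), (FRONTAL_PATHWAY, 3), (DORSAL_PATHWAY, 15),
    ])
    def test_pathway_pair_counts(self, pathway, n):
        pairs = enumerate_roi_pairs(pathway)
        assert len(pairs) == n == len(pathway.rois) * (len(pathway.rois) - 1) // 2
        assert len(set(map(frozenset, pairs))) == n  # unordered, unique

    def test_single_roi_pathway_rejected(self):
        with pytest.raises(TwinscopeError):
            enumerate_roi_pairs(PathwayDefinition("tiny", "", ("fusiform",)))


class TestMostSimilarPair:
    @staticmethod
    def _curves(divs):
        return {
            label: qq_compare(_dist(np.full(50, 100.0)), _dist(np.full(50, 100.0 + 255 * d)))
            for label, d in divs.items()
        }

    def test_identical_affected_masks_pick_srd_pair(self):
        data = ellipsoid_mask((32, 32, 32), (16, 16, 16), (12, 12, 12))
        perturbed = ellipsoid_mask((32, 32, 32), (16, 16, 16), (12, 12, 18))
        vols = {
            "proband": _vol(data, "proband"),
            "older_sibling": _vol(data, "older_sibling"),
            "td_twin": _vol(perturbed, "td_twin"),
        }
        dists = {
            sid: extract_distribution(composite_from_mask(v, "axial", 18))
            for sid, v in vols.items()
        }
        curves = {
            PAIR_TWINS: qq_compare(dists["proband"], dists["td_twin"]),
            PAIR_SRD: qq_compare(dists["proband"], dists["older_sibling"]),
            PAIR_TD_OS: qq_compare(dists["td_twin"], dists["older_sibling"]),
        }
        pick = most_similar_pair(curves)
        assert pick.label == PAIR_SRD and not pick.tie

    def test_three_way_tie_breaks_to_twin_baseline(self):
        curves = self._curves({PAIR_TWINS: 0.0, PAIR_SRD: 0.0, PAIR_TD_OS: 0.0})
        pick = most_similar_pair(curves)
        assert pick.label == PAIR_TWINS and pick.tie

    def test_margin_reported(self):
        curves = self._curves({PAIR_TWINS: 0.2, PAIR_SRD: 0.05, PAIR_TD_OS: 0.4})
        pick = most_similar_pair(curves)
        assert pick.label == PAIR_SRD
        assert pick.margin == pytest.approx(0.15, abs=1e-6)
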