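"""Morphological pulp pipeline: hole filling, marker/mask/reconstruction,
crown masking and the slice-area-evolution apical guard."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage as ndi

import pulpseg as ps
from pulpseg.pulp_segmentation import (
    CrownExtent,
    PulpSegParams,
    cavity_component,
    find_crown_extent,
)

from conftest import mask_dice


def fill_holes_oracle(img):
    """Fixed point of iterated erosion-based reconstruction from the border."""
    img = np.asarray(img, float)
    seed = np.full_like(img, img.max())
    border = np.ones(img.shape, bool)
    border[tuple(slice(1, -1) for _ in img.shape)] = False
    seed[border] = img[border]
    fp = np.ones((3,) * img.ndim)
    prev = seed
    while True:
        nxt = np.maximum(ndi.minimum_filter(prev, footprint=fp, mode="nearest"), img)
        nxt[border] = np.maximum(img[border], np.minimum(prev, nxt)[border])
        nxt = np.maximum(nxt, img)
        if np.array_equal(nxt, prev):
            return nxt
        prev = nxt


def reconstruct_oracle(marker, mask):
    """Iterated dilate-then-intersect until the fixed point."""
    cur = marker & mask
    struct = np.ones((3,) * mask.ndim, bool)
    while True:
        nxt = ndi.binary_dilation(cur, structure=struct) & mask
        if np.array_equal(nxt, cur):
            return cur
        cur = nxt


class TestFillHoles:
    def test_hole_free_image_unchanged(self):
        img = np.fromfunction(lambda i, j: i + j, (10, 10))
        assert np.allclose(ps.fill_holes(img), img)

    def test_bright_ring_fills_dark_disk(self):
        img = np.zeros((15, 15))
        img[4:11, 4:11] = 10.0
        img[6:9, 6:9] = 2.0
        out = ps.fill_holes(img)
        assert np.all(out[6:9, 6:9] == 10.0)
        assert np.all(out[0, :] == img[0, :])  # border untouched

    def test_idempotent_and_extensive(self, rng):
        for _ in range(10):
            img = rng.random((16, 16)) * 100
            once = ps.fill_holes(img)
            assert np.all(once >= img - 1e-9)
            assert np.allclose(ps.fill_holes(once), once, atol=1e-9)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_extensive_and_idempotent_property(self, seed):
        img = np.round(np.random.default_rng(seed).random((12, 12)) * 25)
        once = ps.fill_holes(img)
        assert np.all(once >= img - 1e-12)
        assert np.allclose(ps.fill_holes(once), once, atol=1e-12)
        assert np.array_equal(once[[0, -1], :], img[[0, -1], :])  # border fixed

    def test_matches_fixed_point_oracle(self, rng):
        for _ in range(5):
            img = np.round(rng.random((12, 12)) * 20)
            assert np.allclose(ps.fill_holes(img), fill_holes_oracle(img), atol=1e-9)

    def test_3d_cavity_filled(self):
        img = np.zeros((9, 9, 9))
        img[2:7, 2:7, 2:7] = 8.0
        img[4, 4, 4] = 1.0
        out = ps.fill_holes(img)
        assert out[4, 4, 4] == 8.0


def _cavity_image(depths=(50.0,), size=24):
    """Bright slab with one dark square cavity per requested depth."""
    img = np.full((size, size), 100.0)
    for i, depth in enumerate(depths):
        x0 = 4 + 10 * i
        img[x0 : x0 + 4, 8:12] = 100.0 - depth
    return img


class TestBuildMarker:
    def test_marker_inside_single_cavity(self):
        img = _cavity_image((50.0,))
        marker = ps.build_marker(img, (1.0, 1.0))
        assert marker.any()
        assert np.all(img[marker] == 50.0)

    def test_hole_free_image_raises_no_cavity(self):
        img = np.fromfunction(lambda i, j: 1.0 * i, (10, 10))
        with pytest.raises(ps.NoCavityError):
            ps.build_marker(img, (1.0, 1.0))

    def test_marker_prefers_deeper_cavity(self):
        img = _cavity_image((50.0, 20.0))
        marker = ps.build_marker(img, (1.0, 1.0))
        assert np.all(img[marker] == 50.0)  # the depth-50 cavity only

    def test_marker_limited_to_radius_ball(self):
        img = np.full((40, 40), 100.0)
        img[4:36, 18:22] = 10.0  # long dark channel
        marker = ps.build_marker(img, (1.0, 1.0), PulpSegParams(marker_radius=3.0))
        peak = np.unravel_index(np.argmax(ps.fill_holes(img) - img), img.shape)
        idx = np.argwhere(marker)
        assert np.all(np.linalg.norm(idx - peak, axis=1) <= 3.0 + 1e-9)

    def test_initial_variant_picks_second_largest_component(self):
        img = _cavity_image((30.0, 30.0))
        img[4:8, 8:12] = 70.0
        img[14:20, 8:12] = 70.0  # bigger cavity -> largest component
        marker = ps.build_marker(img, (1.0, 1.0), variant="initial")
        xs = np.argwhere(marker)[:, 0]
        assert xs.min() >= 4 and xs.max() < 8  # the smaller (second-largest)


class TestValleyMask:
    def test_uniform_image_gives_empty_mask(self):
        img = np.full((20, 20), 7.0)
        assert not ps.build_valley_mask(img, (1.0, 1.0)).any()

    def test_narrow_dark_channel_is_covered(self):
        img = np.full((24, 24), 100.0)
        img[4:20, 11:13] = 10.0  # 2 px channel < 2 * tophat radius
        p = PulpSegParams(gaussian_sigma=0.0, tophat_radius=2.0, mask_threshold="positive")
        mask = ps.build_valley_mask(img, (1.0, 1.0), p)
        assert mask[6:18, 11:13].all()

    def test_zero_sigma_equals_unsmoothed_pipeline(self, rng):
        img = rng.random((16, 16)) * 50
        p0 = PulpSegParams(gaussian_sigma=0.0, tophat_radius=1.5, mask_threshold="positive")
        got = ps.build_valley_mask(img, (1.0, 1.0), p0)
        from pulpseg.pulp_segmentation import _footprint

        bth = ndi.grey_closing(img, footprint=_footprint(1.5, (1, 1))) - img
        want = ps.fill_holes(bth) > 0
        assert np.array_equal(got, want)


class TestReconstruct:
    def test_marker_equals_mask_fixed_point(self, rng):
        mask = rng.random((12, 12)) > 0.6
        assert np.array_equal(ps.reconstruct(mask, mask), mask)

    def test_empty_marker_gives_empty(self):
        mask = np.ones((8, 8), bool)
        assert not ps.reconstruct(np.zeros((8, 8), bool), mask).any()

    def test_single_voxel_marker_selects_its_component(self):
        mask = np.zeros((20, 20), bool)
        mask[2:5, 2:5] = True
        mask[8:12, 8:12] = True
        mask[15:18, 2:5] = True
        marker = np.zeros_like(mask)
        marker[9, 9] = True
        out = ps.reconstruct(marker, mask)
        want = np.zeros_like(mask)
        want[8:12, 8:12] = True
        assert np.array_equal(out, want)

    def test_matches_dilate_intersect_oracle_3d(self, rng):
        for _ in range(20):
            mask = rng.random((10, 10, 10)) > 0.7
            marker = mask & (rng.random((10, 10, 10)) > 0.8)
            assert np.array_equal(ps.reconstruct(marker, mask), reconstruct_oracle(marker, mask))


def _chamber_and_canals_mask():
    """Slices 0-4: one 5x5 chamber blob; slices 5-9: two 1x1 canals."""
    seg = np.zeros((12, 12, 10), bool)
    seg[3:8, 3:8, 0:5] = True
    seg[4, 4, 5:10] = True
    seg[6, 6, 5:10] = True
    return seg


class TestCrownExtent:
    def test_constructed_chamber_orientation_and_limit(self):
        seg = _chamber_and_canals_mask()
        ext = find_crown_extent(seg)
        assert 0 <= ext.chamber_slice <= 4
        assert ext.orientation == "crown_at_low_z"
        assert ext.crown_apical_limit == 4

    def test_single_slice_mask_degenerate(self):
        seg = np.zeros((6, 6, 5), bool)
        seg[2:4, 2:4, 3] = True
        ext = find_crown_extent(seg)
        assert ext.chamber_slice == 3 and ext.crown_apical_limit == 3

    def test_mirrored_mask_flips_orientation(self):
        seg = _chamber_and_canals_mask()
        seg[2:9, 2:9, 2] = True  # unique largest chamber slice
        ext = find_crown_extent(seg)
        assert ext.chamber_slice == 2
        mirrored = seg[:, :, ::-1].copy()
        ext_m = find_crown_extent(mirrored)
        assert ext_m.orientation == "crown_at_high_z"
        assert ext_m.chamber_slice == seg.shape[2] - 1 - ext.chamber_slice
        assert ext_m.crown_apical_limit == seg.shape[2] - 1 - ext.crown_apical_limit

    def test_empty_mask_is_error(self):
        with pytest.raises(ValueError):
            find_crown_extent(np.zeros((4, 4, 4), bool))


class TestApplyCrownMask:
    def test_midpoint_threshold_definition(self):
        img = np.full((10, 10, 4), 100.0)
        marker = np.zeros((10, 10, 4), bool)
        marker[4:6, 4:6, :] = True
        shell = ndi.binary_dilation(marker, np.ones((3, 3, 3), bool)) & ~marker
        img[shell] = 200.0
        seg = marker.copy()
        # threshold = 150: marker voxels (100) survive everywhere
        ext = CrownExtent("crown_at_low_z", 0, 3)
        out = ps.apply_crown_mask(img, seg, marker, ext)
        assert np.array_equal(out, seg)

    def test_bright_voxel_removed_in_crown_kept_in_root(self):
        img = np.full((8, 8, 6), 100.0)
        marker = np.zeros((8, 8, 6), bool)
        marker[3:5, 3:5, :] = True
        shell = ndi.binary_dilation(marker, np.ones((3, 3, 3), bool)) & ~marker
        img[shell] = 200.0
        seg = marker.copy()
        seg[6, 6, 1] = True   # crown slice, bright
        seg[6, 6, 5] = True   # root slice, bright
        img[6, 6, :] = 180.0  # above t = 150
        ext = CrownExtent("crown_at_low_z", 0, 3)
        out = ps.apply_crown_mask(img, seg, marker, ext)
        assert not out[6, 6, 1]
        assert out[6, 6, 5]

    def test_constructed_leak_removed_pulp_retained(self):
        img = np.full((14, 14, 5), 1000.0)
        pulp = np.zeros((14, 14, 5), bool)
        pulp[5:9, 5:9, :] = True
        img[pulp] = 120.0
        leak = np.zeros_like(pulp)
        leak[9:12, 5:9, :] = True
        img[leak] = 800.0  # dentine-bright leak lobe
        seg = pulp | leak
        ext = CrownExtent("crown_at_low_z", 0, 4)
        out = ps.apply_crown_mask(img, seg, pulp, ext)
        assert not (out & leak).any()
        assert (out & pulp).sum() == pulp.sum()


class TestSliceAreaVector:
    def test_constant_cylinder_is_all_ones(self):
        seg = np.zeros((10, 10, 30), bool)
        seg[3:7, 3:7, 5:25] = True
        v = ps.slice_area_vector(seg, "crown_at_low_z")
        assert np.allclose(v, 1.0)

    def test_hundred_slices_no_resampling(self):
        seg = np.zeros((30, 30, 100), bool)
        for z in range(100):
            n = z + 1
            rows = np.unravel_index(np.arange(n), (30, 30))
            seg[rows[0], rows[1], z] = True
        v = ps.slice_area_vector(seg, "crown_at_low_z")
        assert np.allclose(v, np.arange(1, 101) / 100.0, atol=1e-12)

    def test_matches_linear_resampling_oracle(self, rng):
        nz = 37
        seg = np.zeros((40, 40, nz), bool)
        for z in range(nz):
            n = int(rng.integers(1, 200))
            rows = np.unravel_index(np.arange(n), (40, 40))
            seg[rows[0], rows[1], z] = True
        v = ps.slice_area_vector(seg, "crown_at_low_z", (0.5, 0.5, 0.5))
        areas = seg.sum(axis=(0, 1)).astype(float) * 0.25
        areas /= areas.max()
        want = np.empty(100)
        for i, t in enumerate(np.linspace(0, 1, 100)):
            pos = t * (nz - 1)
            j = min(int(np.floor(pos)), nz - 2)
            f = pos - j
            want[i] = (1 - f) * areas[j] + f * areas[j + 1]
        assert np.allclose(v, want, atol=1e-9)

    def test_orientation_reverses_order(self):
        seg = np.zeros((10, 10, 20), bool)
        for z in range(20):
            seg[0, : z + 1, z] = True
        lo = ps.slice_area_vector(seg, "crown_at_low_z")
        hi = ps.slice_area_vector(seg, "crown_at_high_z")
        assert np.allclose(lo, hi[::-1], atol=1e-12)


def _cone_mask(nz=60, top=12.0, tip=3.0):
    seg = np.zeros((30, 30, nz), bool)
    zz = np.arange(nz)
    radii = top + (tip - top) * zz / (nz - 1)
    xx, yy = np.meshgrid(np.arange(30) - 14.5, np.arange(30) - 14.5, indexing="ij")
    for z in range(nz):
        seg[:, :, z] = xx**2 + yy**2 <= radii[z] ** 2
    return seg


def _tc(kind=ps.ToothKind.INCISOR, arch=ps.ArchLabel.MANDIBULAR, pos=41):
    return ps.ToothClass(kind, arch, pos)


class TestAreaModel:
    def test_single_reference_has_zero_sd(self):
        seg = ps.BinaryMask(_cone_mask(), (0.25, 0.25, 0.25))
        models = ps.fit_area_model([(seg, _tc())], uniform_filter_width=1)
        m = models[_tc().key]
        v = ps.slice_area_vector(seg.values, "crown_at_low_z", seg.spacing)
        assert np.allclose(m.mean_gradient, np.gradient(v), atol=1e-12)
        assert np.allclose(m.sd_gradient, 0.0, atol=1e-12)

    def test_two_distinct_references_match_elementwise_stats(self):
        a = ps.BinaryMask(_cone_mask(top=12, tip=3), (0.25, 0.25, 0.25))
        b = ps.BinaryMask(_cone_mask(top=10, tip=5), (0.25, 0.25, 0.25))
        models = ps.fit_area_model([(a, _tc()), (b, _tc())], uniform_filter_width=1)
        m = models[_tc().key]
        ga = np.gradient(ps.slice_area_vector(a.values, "crown_at_low_z", a.spacing))
        gb = np.gradient(ps.slice_area_vector(b.values, "crown_at_low_z", b.spacing))
        assert np.allclose(m.mean_gradient, (ga + gb) / 2, atol=1e-12)
        assert np.allclose(m.sd_gradient, np.abs(ga - gb) / 2, atol=1e-12)

    def test_molar_reference_is_rejected(self):
        seg = ps.BinaryMask(_cone_mask(), (1, 1, 1))
        molar = ps.ToothClass(ps.ToothKind.MOLAR, ps.ArchLabel.MANDIBULAR, 46)
        with pytest.raises(ValueError):
            ps.fit_area_model([(seg, molar)])

    def test_json_roundtrip(self, tmp_path):
        seg = ps.BinaryMask(_cone_mask(), (0.25, 0.25, 0.25))
        models = ps.fit_area_model([(seg, _tc())])
        path = tmp_path / "models.json"
        ps.pulp_segmentation.models_to_json(models, path)
        back = ps.pulp_segmentation.models_from_json(path)
        assert np.allclose(back[_tc().key].mean_gradient, models[_tc().key].mean_gradient)


class TestApicalCut:
    def _model(self):
        """Model from two distinct cone references.

        With two references each reference deviates from the mean by exactly
        one SD elementwise, so an in-population candidate always lies inside
        the two-SD band.
        """
        a = ps.BinaryMask(_cone_mask(top=12, tip=3), (1, 1, 1))
        b = ps.BinaryMask(_cone_mask(top=12, tip=5), (1, 1, 1))
        return ps.fit_area_model([(a, _tc()), (b, _tc())])[_tc().key]

    def test_zero_gradient_candidate_is_unchanged(self):
        """A constant-area cylinder has zero gradient: exactly the mean of a
        cylinder-reference model, so no cut is made."""
        cyl = np.zeros((20, 20, 40), bool)
        cyl[5:15, 5:15, :] = True
        model = ps.fit_area_model([(ps.BinaryMask(cyl, (1, 1, 1)), _tc())])[_tc().key]
        out = ps.apply_apical_cut(cyl, model, _tc())
        assert np.array_equal(out, cyl)

    def test_in_population_candidate_is_unchanged(self):
        member = _cone_mask(top=12, tip=3)  # one of the model's references
        out = ps.apply_apical_cut(member, self._model(), _tc())
        assert np.array_equal(out, member)

    def test_molar_always_unchanged(self):
        bulbed = _cone_mask(top=12, tip=4)
        bulbed[8:22, 8:22, 52:] = True
        molar = ps.ToothClass(ps.ToothKind.MOLAR, ps.ArchLabel.MANDIBULAR, 46)
        out = ps.apply_apical_cut(bulbed, self._model(), molar)
        assert np.array_equal(out, bulbed)

    def test_bulb_cut_improves_dice_and_spares_crown(self):
        clean = _cone_mask(top=12, tip=3)
        bulbed = clean.copy()
        bulbed[8:22, 8:22, 52:] = True  # apical bulb spikes the area gradient
        out = ps.apply_apical_cut(bulbed, self._model(), _tc())
        assert mask_dice(out, clean) > mask_dice(bulbed, clean)
        # the cut only ever removes an apical tail inside the last fifth
        removed_z = np.flatnonzero((bulbed & ~out).any(axis=(0, 1)))
        assert removed_z.size > 0
        assert removed_z[0] >= 47  # never on the crown side of the last fifth
        assert removed_z[-1] == 59
        assert np.array_equal(removed_z, np.arange(removed_z[0], 60))


class TestSegmentPulp:
    def test_clean_phantom_dice_above_floor(self, clean_tooth_case):
        seg = ps.segment_pulp(clean_tooth_case.volume)
        assert mask_dice(seg, clean_tooth_case.pulp_masks[0]) >= 0.90

    def test_solid_tooth_raises_no_cavity(self):
        spec = ps.PhantomSpec(noise_sd=0.0, blur_sigma=0.0, pulp_scale=0.05)
        case = ps.generate_tooth(spec)
        solid = case.volume.values.copy()
        solid[case.pulp_masks[0].values] = spec.intensities.dentine
        vol = ps.ImageVolume(solid, case.volume.spacing, case.volume.origin)
        with pytest.raises(ps.NoCavityError):
            ps.segment_pulp(vol)

    def test_three_rooted_molar_has_three_canal_branches(self):
        spec = ps.PhantomSpec(
            tooth_class=ps.ToothClass(ps.ToothKind.MOLAR, ps.ArchLabel.MANDIBULAR, 46),
            n_roots=3,
            crown_radius=3.4,
            root_radius=1.0,
            root_length=7.0,
            noise_sd=0.0,
            blur_sigma=0.0,
        )
        case = ps.generate_tooth(spec)
        seg = ps.segment_pulp(case.volume)
        assert mask_dice(seg, case.pulp_masks[0]) >= 0.90
        # below the root trunk the three canals are separate branches
        nz_cerv = int(round((0 - case.volume.origin[2]) / case.volume.spacing[2]))
        below_trunk = nz_cerv - int(round(0.4 * spec.root_length / spec.voxel_size))
        _, n = ndi.label(seg.values[:, :, :below_trunk], structure=np.ones((3, 3, 3), bool))
        assert n == 3
        # and the whole pulp is one connected body (canals meet the chamber)
        _, n_all = ndi.label(seg.values, structure=np.ones((3, 3, 3), bool))
        assert n_all == 1

    def test_pipeline_is_deterministic(self, default_tooth_case):
        a = ps.segment_pulp(default_tooth_case.volume)
        b = ps.segment_pulp(default_tooth_case.volume)
        assert np.array_equal(a.values, b.values)

    def test_slice_mode_on_sharp_phantom(self, quiet_tooth_case):
        """Per-axial-slice variant with the positive valley rule is exact on a
        blur-free, noise-free tooth."""
        p = PulpSegParams(mask_threshold="positive")
        seg = ps.segment_pulp(quiet_tooth_case.volume, p, mode="slice")
        assert mask_dice(seg, quiet_tooth_case.pulp_masks[0]) >= 0.95

    def test_output_subset_of_valley_reconstruction(self, clean_tooth_case):
        vol = clean_tooth_case.volume
        seg = ps.segment_pulp(vol)
        marker = ps.build_marker(vol.values, vol.spacing)
        valley = ps.build_valley_mask(vol.values, vol.spacing)
        rec = ps.reconstruct(marker, valley)
        assert not (seg.values & ~rec).any()
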