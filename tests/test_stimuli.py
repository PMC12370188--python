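"""Stimulus generation: Gabor rendering against the closed form, path
geometry, pair matching, masks, alignment jitter, and manifest counts."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st_
from scipy import ndimage

from gaborpath import stimuli as st


@pytest.fixture(scope="module")
def default_pair():
    return st.render_pair(beta=15, seed=42)


@pytest.fixture(scope="module")
def desk_pair():
    return st.render_pair(beta=0, seed=7, gabor=st.DESK_GABOR,
                          grid=st.DESK_GRID, path_params=st.DESK_PATH)


# ---------------------------------------------------------------------------
# Gabor rendering
# ---------------------------------------------------------------------------

class TestRenderGabor:
    def test_center_pixel_is_background(self):
        # phase -90 makes the carrier vanish at the origin
        for theta in (0, 33, 90, 217):
            patch = st.render_gabor(st.GaborParams(), theta)
            c = st.GaborParams().patch_size // 2
            assert patch[c, c] == pytest.approx(0.5)

    def test_orientation_is_mod_180(self):
        p = st.GaborParams()
        for theta in (0.0, 45.0, 120.5):
            np.testing.assert_array_equal(st.render_gabor(p, theta),
                                          st.render_gabor(p, theta + 180))

    @given(theta=st_.floats(0, 180, exclude_max=True),
           dx=st_.integers(-10, 10), dy=st_.integers(-10, 10))
    @settings(max_examples=50, deadline=None)
    def test_matches_closed_form_pointwise(self, theta, dx, dy):
        p = st.GaborParams()
        patch = st.render_gabor(p, theta)
        c = p.patch_size // 2
        t = math.radians(theta)
        u = -dx * math.sin(t) + dy * math.cos(t)
        expected = 0.5 + 0.5 * math.exp(-(dx * dx + dy * dy) / 32.0) * \
            math.cos(2 * math.pi * u / 8.0 - math.pi / 2.0)
        expected = min(1.0, max(0.0, expected))
        assert patch[c + dy, c + dx] == pytest.approx(expected, abs=1e-12)

    def test_rejects_nonpositive_wavelength_or_sigma(self):
        with pytest.raises(ValueError):
            st.GaborParams(wavelength=0)
        with pytest.raises(ValueError):
            st.GaborParams(sigma=-1)


# ---------------------------------------------------------------------------
# path generation
# ---------------------------------------------------------------------------

def _path(beta=15, seed=1, **kw):
    rng = np.random.default_rng(seed)
    params = st.PathParams(beta=beta, **kw)
    for _ in range(50):
        try:
            return st.generate_path(params, st.GridSpec(), rng)
        except st.PathGenerationError:
            continue
    raise AssertionError("path generation failed for test seed")


class TestGeneratePath:
    def test_thirteen_anchors_twelve_elements(self):
        anchors, placements = _path()
        assert anchors.shape == (13, 2)
        assert len(placements) == 12
        assert all(pl.role == "contour" for pl in placements)

    def test_first_anchor_at_start_radius(self):
        anchors, _ = _path(seed=3)
        assert np.linalg.norm(anchors[0] - 256.0) == pytest.approx(64.0)

    def test_zero_curvature_path_is_straight(self):
        _, placements = _path(beta=0, seed=2, delta_beta_range=0)
        oris = np.array([pl.orientation for pl in placements]) % 180.0
        assert np.ptp(oris) == pytest.approx(0.0)

    def test_anchor_distances_follow_increment_law(self):
        for seed in range(5):
            anchors, _ = _path(beta=30, seed=seed)
            d = np.linalg.norm(np.diff(anchors, axis=0), axis=1)
            steps = (d - 32.0) / 8.0
            np.testing.assert_allclose(steps, np.round(steps), atol=1e-9)
            assert np.all(d >= 32.0 - 1e-9)

    def test_elements_sit_at_segment_midpoints_along_path(self):
        anchors, placements = _path(beta=45, seed=4)
        for k, pl in enumerate(placements):
            mid = (anchors[k] + anchors[k + 1]) / 2.0
            assert pl.center_x == pytest.approx(mid[0])
            assert pl.center_y == pytest.approx(mid[1])
            seg = anchors[k + 1] - anchors[k]
            seg_angle = math.degrees(math.atan2(seg[1], seg[0]))
            wrapped = (pl.orientation - seg_angle + 180.0) % 360.0 - 180.0
            assert wrapped == pytest.approx(0, abs=1e-9)

    def test_one_element_per_cell(self):
        _, placements = _path(beta=60, seed=5)
        cells = [pl.cell_index for pl in placements]
        assert len(set(cells)) == len(cells)


# ---------------------------------------------------------------------------
# display pairs
# ---------------------------------------------------------------------------

class TestDisplayPair:
    def test_256_elements_per_display(self, default_pair):
        assert len(default_pair.placements_present) == 256
        assert len(default_pair.placements_absent) == 256
        n_contour = sum(p.role == "contour"
                        for p in default_pair.placements_present)
        assert n_contour == 12

    def test_difference_confined_to_contour_footprints(self, default_pair):
        pair = default_pair
        diff = pair.present_image != pair.absent_image
        allowed = np.zeros_like(diff)
        half = pair.gabor.patch_size // 2
        for pl in pair.placements_present:
            if pl.role != "contour":
                continue
            x0 = int(round(pl.center_x)) - half
            y0 = int(round(pl.center_y)) - half
            allowed[y0:y0 + 28, x0:x0 + 28] = True
        assert not np.any(diff & ~allowed)

    def test_background_identical_across_pair(self, default_pair):
        for a, b in zip(default_pair.placements_present,
                        default_pair.placements_absent):
            if a.role == "background":
                assert a == b
            else:
                assert (a.center_x, a.center_y) == (b.center_x, b.center_y)
                assert a.orientation != b.orientation

    def test_rasters_quantized_and_in_range(self, default_pair):
        img = default_pair.present_image
        assert img.min() >= 0.0 and img.max() <= 1.0
        np.testing.assert_allclose(img * 255, np.round(img * 255), atol=1e-9)

    def test_same_seed_is_bit_identical(self):
        a = st.render_pair(30, seed=123)
        b = st.render_pair(30, seed=123)
        np.testing.assert_array_equal(a.present_image, b.present_image)
        np.testing.assert_array_equal(a.absent_image, b.absent_image)

    def test_desk_scale_pair_counts(self, desk_pair):
        assert len(desk_pair.placements_present) == 64
        n_contour = sum(p.role == "contour"
                        for p in desk_pair.placements_present)
        assert n_contour == st.DESK_PATH.n_anchors - 1


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

class TestMasks:
    def test_threshold_255_gives_empty_masks(self, default_pair):
        ms = st.make_masks_for_pair(default_pair, threshold=255)
        assert ms.contour_mask.sum() == 0
        assert ms.background_mask.sum() == 0

    def test_footprint_is_disc_of_analytic_radius(self):
        # isolated element: count pixels where 255*exp(-r^2/(2*16)) > 140
        pl = [st.ElementPlacement(256.0, 256.0, 0.0, "contour", (8, 8))]
        ms = st.make_masks(pl, st.GaborParams(), threshold=140)
        expected = 0
        for dy in range(-14, 14):
            for dx in range(-14, 14):
                if 255.0 * math.exp(-(dx * dx + dy * dy) / 32.0) > 140.0:
                    expected += 1
        assert ms.contour_mask.sum() == expected
        # analytic radius r* = sqrt(2 sigma^2 ln(255/140)) ~ 4.38 px
        r_star = math.sqrt(32.0 * math.log(255.0 / 140.0))
        assert expected == pytest.approx(math.pi * r_star ** 2, rel=0.1)

    def test_contour_mask_has_12_components(self, default_pair):
        ms = st.make_masks_for_pair(default_pair)
        n = ndimage.label(ms.contour_mask)[1]
        assert n == 12

    def test_threshold_out_of_range_rejected(self, default_pair):
        with pytest.raises(ValueError):
            st.make_masks_for_pair(default_pair, threshold=300)


# ---------------------------------------------------------------------------
# alignment jitter
# ---------------------------------------------------------------------------

class TestAlignmentJitter:
    def test_zero_jitter_is_identity(self, default_pair):
        rng = np.random.default_rng(0)
        out = st.apply_alignment_jitter(default_pair, 0.0, rng)
        np.testing.assert_array_equal(out.present_image,
                                      default_pair.present_image)
        np.testing.assert_array_equal(out.absent_image,
                                      default_pair.absent_image)

    @pytest.mark.parametrize("jitter", [2.0, 8.0])
    def test_displacement_is_perpendicular_with_magnitude(self, default_pair,
                                                          jitter):
        rng = np.random.default_rng(1)
        out = st.apply_alignment_jitter(default_pair, jitter, rng)
        for old, new in zip(default_pair.placements_present,
                            out.placements_present):
            if old.role == "background":
                assert old == new
                continue
            d = np.array([new.center_x - old.center_x,
                          new.center_y - old.center_y])
            assert np.linalg.norm(d) == pytest.approx(jitter)
            t = math.radians(old.orientation)
            tangent = np.array([math.cos(t), math.sin(t)])
            assert abs(d @ tangent) < 1e-9
            assert new.orientation == old.orientation

    def test_jitter_identical_across_pair_members(self, default_pair):
        rng = np.random.default_rng(2)
        out = st.apply_alignment_jitter(default_pair, 6.0, rng)
        for p, a in zip(out.placements_present, out.placements_absent):
            assert (p.center_x, p.center_y) == (a.center_x, a.center_y)


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

class TestManifests:
    def test_full_scale_training_counts(self):
        df = st.build_manifest(range(0, 91), 2500, seed=0)
        assert len(df) == 455_000
        assert df["pair_id"].nunique() == 227_500

    def test_broad_training_subset_counts(self):
        df = st.build_manifest([0, 15, 30, 45, 60, 75], 416, seed=0)
        assert len(df) == 4992
        assert (df.groupby("beta_deg").size() == 832).all()

    def test_single_pair_manifest(self):
        df = st.build_manifest([20], 1, seed=0)
        assert len(df) == 2
        assert set(df["label"]) == {"present", "absent"}

    def test_rendered_dataset_writes_images_and_manifest(self, tmp_path):
        df = st.build_dataset([0], 2, seed=1, out_dir=str(tmp_path),
                              render=True, gabor=st.DESK_GABOR,
                              grid=st.DESK_GRID, path_params=st.DESK_PATH)
        assert len(df) == 4
        for p in df["image_path"]:
            assert (tmp_path / p).exists()
        assert (tmp_path / "train_manifest.csv").exists()


class TestBehavioralSet:
    def test_split_structure(self):
        df = st.build_behavioral_set(seed=5)
        assert len(df) == 1000
        assert df["pair_id"].nunique() == 1000
        counts = df.groupby(["split", "beta_deg"]).size()
        assert (counts == 40).all()
        assert df.groupby("split").size().eq(200).all()

    def test_rotation_difference_is_90_180_or_270(self):
        df = st.build_behavioral_set(seed=9)
        delta = (df["rotation_2"] - df["rotation_1"]) % 360
        assert set(delta.unique()) <= {90, 180, 270}
        assert set(df["rotation_1"].unique()) <= {0, 90, 180, 270}

    def test_indivisible_split_rejected(self):
        with pytest.raises(ValueError):
            st.build_behavioral_set(seed=0, pairs_per_beta=201)


def test_rotate90_roundtrip(default_pair):
    img = default_pair.present_image
    for deg in (90, 180, 270):
        back = st.rotate90(st.rotate90(img, deg), 360 - deg)
        np.testing.assert_array_equal(back, img)
    with pytest.raises(ValueError):
        st.rotate90(img, 45)
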