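"""Pixel-counting protocol: binning, rendering, masking, CIE76 grouping."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from equilunge.thermal import (
    BIN_EDGES,
    N_BINS,
    ThermalScene,
    bin_of_temperature,
    bins_of_temperatures,
    classify_color,
    classify_colors,
    default_palette,
    delta_e76,
    extract_color_histogram,
    mask_background,
    profile_to_pie,
    render_thermogram,
    srgb_to_lab,
    surface_profile,
)


class TestBinning:
    @pytest.mark.parametrize(
        "t,expected",
        [
            (29.0, 1),
            (30.0, 2),       # half-open: 30 belongs to the second bin
            (31.999, 2),
            (34.0, 4),
            (36.0, 5),
            (38.0, 5),       # top bin is closed
            (39.5, 5),       # clamp above scale
            (27.999, 0),     # below threshold = background
        ],
    )
    def test_edges_honor_interval_notation(self, t, expected):
        assert bin_of_temperature(t) == expected

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            bin_of_temperature(float("nan"))

    def test_vectorised_matches_scalar(self, rng):
        ts = rng.uniform(26, 40, 500)
        np.testing.assert_array_equal(
            bins_of_temperatures(ts), [bin_of_temperature(t) for t in ts]
        )


class TestRendering:
    def test_all_background_scene_is_all_black(self):
        scene = ThermalScene(np.full((4, 5), np.nan), np.zeros((4, 5), bool))
        assert not render_thermogram(scene).any()

    def test_threshold_rule_at_28(self):
        grid = np.array([[27.999, 28.0]])
        img = render_thermogram(ThermalScene.from_grid(grid))
        assert tuple(img[0, 0]) == (0, 0, 0)
        assert tuple(img[0, 1]) == default_palette().color_at(28.0) != (0, 0, 0)

    def test_rendered_color_classifies_to_its_own_bin(self):
        """0.01-degree sweep: render -> classify recovers the temperature bin."""
        pal = default_palette()
        ts = np.round(np.arange(28.0, 38.0001, 0.01), 4)
        predicted = classify_colors(pal.colors_at(ts), pal)
        np.testing.assert_array_equal(predicted, bins_of_temperatures(ts))


class TestMasking:
    def test_exact_black_rule(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[0, 0] = (1, 1, 1)      # near-black still counts as surface
        img[1, 1] = (255, 0, 0)
        surface = mask_background(img)
        assert surface.sum() == 2
        assert surface[0, 0] and surface[1, 1]

    def test_empty_surface_rejected(self):
        with pytest.raises(ValueError, match="surface"):
            mask_background(np.zeros((3, 3, 3), np.uint8))

    def test_percentages_invariant_to_background_padding(self, rng):
        scene, _ = _random_scene(rng, (40, 50))
        img = render_thermogram(scene)
        padded = np.zeros((80, 100, 3), np.uint8)
        padded[10:50, 25:75] = img
        p1 = surface_profile(img).percentages
        p2 = surface_profile(padded).percentages
        np.testing.assert_allclose(p1, p2, atol=1e-12)


class TestColorSpace:
    def test_white_and_black_anchor_points(self):
        white = srgb_to_lab((255, 255, 255))
        assert white[0] == pytest.approx(100.0, abs=0.01)
        assert abs(white[1]) < 0.01 and abs(white[2]) < 0.01
        assert srgb_to_lab((0, 0, 0))[0] == pytest.approx(0.0, abs=1e-6)

    def test_gray_matches_reference_conversion(self):
        """Mid-gray agrees with a from-scratch sRGB -> XYZ(D65) -> Lab chain."""

        def reference_lab(rgb):
            c = np.asarray(rgb, float) / 255.0
            lin = np.where(c <= 0.04045, c / 12.92, ((c + 0.055) / 1.055) ** 2.4)
            m = np.array(
                [
                    [0.4124564, 0.3575761, 0.1804375],
                    [0.2126729, 0.7151522, 0.0721750],
                    [0.0193339, 0.1191920, 0.9503041],
                ]
            )
            xyz = m @ lin / np.array([0.95047, 1.0, 1.08883])
            f = np.where(xyz > (6 / 29) ** 3, np.cbrt(xyz), xyz / (3 * (6 / 29) ** 2) + 4 / 29)
            return np.array([116 * f[1] - 16, 500 * (f[0] - f[1]), 200 * (f[1] - f[2])])

        np.testing.assert_allclose(
            srgb_to_lab((119, 119, 119)), reference_lab((119, 119, 119)), atol=0.01
        )

    @pytest.mark.parametrize(
        "c1,c2,expected",
        [
            ((50, 0, 0), (50, 0, 0), 0.0),
            ((50, 0, 0), (60, 0, 0), 10.0),
            ((50, 10, 10), (53, 14, 22), 13.0),  # 3-4-12 right triple
        ],
    )
    def test_delta_e76_known_values(self, c1, c2, expected):
        assert delta_e76(c1, c2) == pytest.approx(expected, abs=1e-12)

    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100), st.floats(-100, 100), st.floats(-100, 100)
            ),
            min_size=3,
            max_size=3,
        )
    )
    def test_delta_e76_metric_axioms(self, triple):
        a, b, c = triple
        assert delta_e76(a, b) == pytest.approx(delta_e76(b, a), rel=1e-12)
        assert delta_e76(a, a) == 0.0
        assert delta_e76(a, c) <= delta_e76(a, b) + delta_e76(b, c) + 1e-9


class TestHistogram:
    def test_uniform_surface_single_entry(self):
        img = np.full((5, 6, 3), (10, 20, 30), np.uint8)
        ((color, count),) = extract_color_histogram(img)
        assert color == (10, 20, 30) and count == 30

    def test_checkerboard_equal_counts(self):
        img = np.zeros((4, 4, 3), np.uint8)
        img[::2, ::2] = (255, 0, 0)
        img[1::2, 1::2] = (0, 0, 255)
        hist = dict(extract_color_histogram(img))
        assert hist == {(255, 0, 0): 4, (0, 0, 255): 4}

    def test_matches_brute_force_tally(self, rng):
        img = rng.integers(0, 4, size=(20, 20, 3)).astype(np.uint8) * 80
        surface = mask_background(img)
        hist = dict(extract_color_histogram(img, surface))
        brute = {}
        for i in range(20):
            for j in range(20):
                c = tuple(int(v) for v in img[i, j])
                if c != (0, 0, 0):
                    brute[c] = brute.get(c, 0) + 1
        assert hist == brute


class TestClassification:
    def test_bin_reference_classifies_to_itself(self):
        pal = default_palette()
        for b in range(1, N_BINS + 1):
            assert classify_color(pal.bin_reference(b), pal) == b

    def test_midpoint_color_lands_in_bin_three(self):
        pal = default_palette()
        assert classify_color(pal.color_at(33.0), pal) == 3


def _random_scene(rng, shape):
    grid = rng.uniform(26.0, 40.0, shape)
    grid[rng.uniform(size=shape) < 0.2] = np.nan
    return ThermalScene.from_grid(grid), grid


class TestSurfaceProfile:
    def test_constructed_quarters(self):
        grid = np.full((40, 40), np.nan)
        for i, t in enumerate((29.0, 31.0, 33.0, 35.0)):
            grid[i * 10 : (i + 1) * 10, :20] = t
        prof = surface_profile(render_thermogram(ThermalScene.from_grid(grid)))
        np.testing.assert_allclose(prof.percentages, [25, 25, 25, 25, 0], atol=1e-12)
        assert prof.percentages.sum() == pytest.approx(100.0, abs=1e-9)

    def test_random_field_matches_pixel_tally(self, rng):
        scene, _ = _random_scene(rng, (60, 80))
        prof = surface_profile(render_thermogram(scene))
        np.testing.assert_array_equal(prof.counts, scene.bin_tally())
        assert prof.counts.sum() == prof.total_surface_pixels

    def test_full_size_raster_round_trip(self, rng):
        """One study-size (968 x 709) raster stays pixel-exact end to end."""
        scene, _ = _random_scene(rng, (709, 968))
        prof = surface_profile(render_thermogram(scene))
        np.testing.assert_array_equal(prof.counts, scene.bin_tally())

    def test_monotone_shift_moves_counts_one_bin_up(self, rng):
        grid = rng.uniform(28.0, 36.0, (30, 40))  # all surface, below top bin
        scene = ThermalScene.from_grid(grid)
        shifted = ThermalScene.from_grid(grid + 2.0)
        c0 = surface_profile(render_thermogram(scene)).counts
        c1 = surface_profile(render_thermogram(shifted)).counts
        np.testing.assert_array_equal(c1[1:], c0[:-1])
        assert c1[0] == 0

    def test_translation_invariance(self, rng):
        scene, _ = _random_scene(rng, (30, 40))
        img = render_thermogram(scene)
        rolled = np.roll(img, (3, 7), axis=(0, 1))
        np.testing.assert_array_equal(
            surface_profile(img).counts, surface_profile(rolled).counts
        )


class TestPieChart:
    def test_deterministic_svg_and_zero_sector(self, tmp_path, rng):
        grid = np.full((10, 10), 29.0)
        prof = surface_profile(render_thermogram(ThermalScene.from_grid(grid)))
        assert prof.percentages[0] == 100.0 and prof.percentages[1:].sum() == 0.0
        p1 = profile_to_pie(prof, tmp_path / "a.svg")
        p2 = profile_to_pie(prof, tmp_path / "b.svg")
        assert p1.read_bytes() == p2.read_bytes()
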