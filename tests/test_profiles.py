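import itertools

import numpy as np
import pytest

from flystrip.errors import FlyStripError
from flystrip.profiles import (
    build_strip,
    equidistant_knots,
    extract_profile,
    fit_axis_spline,
    main_branch,
    skeletonize,
    stain_signal,
    ExpressionProfile,
)

from conftest import ellipse_mask, half_max_crossings


class TestSkeletonize:
    def test_wide_rectangle_gives_horizontal_line(self):
        mask = np.zeros((21, 80), dtype=np.uint8)
        mask[8:13, 5:75] = 255
        skel = skeletonize(mask)
        rows, cols = np.nonzero(skel)
        # one-pixel-wide midline away from the end caps
        interior = (cols > 15) & (cols < 65)
        assert np.all(rows[interior] == 10)

    def test_skeleton_contained_in_mask(self):
        mask = ellipse_mask()
        skel = skeletonize(mask)
        assert not np.any((skel > 0) & (mask == 0))

    def test_disk_collapses_to_few_pixels(self):
        mask = ellipse_mask(shape=(60, 60), a=20, b=20)
        assert (skeletonize(mask) > 0).sum() < 5

    def test_empty_mask_rejected(self):
        with pytest.raises(FlyStripError):
            skeletonize(np.zeros((5, 5), dtype=np.uint8))


def _brute_force_longest_geodesic(pixels):
    """All-pairs shortest paths among endpoint pixels via Floyd-Warshall."""
    pix = sorted(pixels)
    idx = {p: i for i, p in enumerate(pix)}
    n = len(pix)
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for (r, c), i in idx.items():
        for dr, dc in itertools.product((-1, 0, 1), repeat=2):
            if (dr, dc) == (0, 0):
                continue
            q = (r + dr, c + dc)
            if q in idx:
                d[i, idx[q]] = np.hypot(dr, dc)
    for k in range(n):
        d = np.minimum(d, d[:, k : k + 1] + d[k : k + 1, :])
    ends = [i for i, p in enumerate(pix) if sum(1 for q in pix if q != p and max(abs(q[0] - p[0]), abs(q[1] - p[1])) <= 1) == 1]
    best = max(((d[i, j], i, j) for i in ends for j in ends), key=lambda t: t[0])
    return best[0]


class TestMainBranch:
    def test_straight_line_is_its_own_main_branch(self):
        skel = np.zeros((5, 30), dtype=np.uint8)
        skel[2, 3:27] = 255
        path = main_branch(skel)
        assert len(path) == 24
        assert path[0][1] < path[-1][1]  # ordered anterior (left) first

    def test_y_shape_keeps_the_two_longest_arms(self):
        skel = np.zeros((20, 30), dtype=np.uint8)
        skel[10, 2:15] = 255  # long horizontal arm
        for i in range(10):  # long diagonal arm
            skel[10 - i - 1, 15 + i] = 255
        for i in range(3):  # short arm
            skel[11 + i, 15 + i] = 255
        skel[10, 15] = 255
        path = main_branch(skel)
        pixels = set(zip(*np.nonzero(skel)))
        expected = _brute_force_longest_geodesic(pixels)
        steps = np.hypot(*np.diff(path, axis=0).T)
        assert steps.sum() == pytest.approx(expected)

    def test_path_is_connected_and_duplicate_free(self):
        skel = skeletonize(ellipse_mask())
        path = main_branch(skel)
        assert len({tuple(p) for p in path}) == len(path)
        steps = np.abs(np.diff(path, axis=0))
        assert steps.max() <= 1


class TestEquidistantKnots:
    def test_straight_path_quartiles(self):
        path = np.array([[0, x] for x in range(101)])
        knots = equidistant_knots(path, 5)
        assert knots[:, 1].tolist() == [0, 25, 50, 75, 100]

    def test_default_count_is_five(self, domain_embryo):
        from flystrip.profiles import main_branch, skeletonize

        path = main_branch(skeletonize(domain_embryo["oriented_mask"]))
        assert equidistant_knots(path).shape == (5, 2)

    def test_arc_spacing_equal_within_one_pixel_on_curved_path(self):
        t = np.linspace(0, np.pi, 200)
        path = np.stack([np.rint(20 * np.sin(t)) + 5, np.arange(200)], axis=1)
        knots = equidistant_knots(path, 5)
        idx = [np.flatnonzero((path == k).all(axis=1))[0] for k in knots]
        steps = np.hypot(*np.diff(path, axis=0).T)
        arc = np.concatenate([[0], np.cumsum(steps)])
        spacings = np.diff([arc[i] for i in idx])
        assert np.ptp(spacings) <= 2.0  # within 1 px of the ideal each

    def test_path_shorter_than_knots_is_an_error(self):
        with pytest.raises(FlyStripError):
            equidistant_knots(np.array([[0, 0], [0, 1]]), 5)


class TestAxisSpline:
    def test_collinear_knots_give_a_straight_line_everywhere(self):
        knots = np.array([[10 + 0.5 * x, x] for x in (0, 25, 50, 75, 100)])
        spline = fit_axis_spline(knots)
        for x in (-20.0, 0.0, 37.5, 100.0, 130.0):
            assert spline(x) == pytest.approx(10 + 0.5 * x, abs=1e-9)

    def test_spline_interpolates_knots_exactly(self):
        knots = np.array([[12, 0], [18, 25], [9, 50], [14, 75], [11, 100]])
        spline = fit_axis_spline(knots)
        for row, col in knots:
            assert spline(col) == pytest.approx(row, abs=1e-9)

    def test_extrapolation_continuous_at_outer_knots(self):
        knots = np.array([[12, 0], [18, 25], [9, 50], [14, 75], [11, 100]])
        spline = fit_axis_spline(knots)
        for x in (0.0, 100.0):
            assert spline(x - 1e-9) == pytest.approx(spline(x + 1e-9), abs=1e-6)

    def test_duplicate_x_rejected(self):
        knots = np.array([[1, 0], [2, 10], [3, 10], [4, 20], [5, 30]])
        with pytest.raises(FlyStripError):
            fit_axis_spline(knots)


class TestStrip:
    def test_band_height_is_ten_percent_of_minor_axis(self):
        mask = ellipse_mask(shape=(260, 460), a=200, b=100)  # vertical extent 200
        knots = np.array([[129, x] for x in (30, 130, 230, 330, 430)])
        strip = build_strip(fit_axis_spline(knots), mask)
        assert 2 * strip.half_width == pytest.approx(0.10 * strip.minor_axis)
        assert strip.minor_axis == 200

    def test_band_scales_linearly_with_minor_axis(self):
        knots = np.array([[60, x] for x in (10, 60, 110, 160, 210)])
        spline = fit_axis_spline(knots)
        big = build_strip(spline, ellipse_mask(shape=(130, 230), a=100, b=50))
        small = build_strip(spline, ellipse_mask(shape=(130, 230), a=100, b=25))
        assert big.half_width == pytest.approx(2 * small.half_width, rel=0.03)

    def test_band_centred_on_spline(self):
        mask = np.zeros((50, 60), dtype=np.uint8)
        mask[10:40, 5:55] = 255
        knots = np.array([[25, x] for x in (5, 17, 29, 41, 53)])
        strip = build_strip(fit_axis_spline(knots), mask)
        assert strip.centreline(29.0) == pytest.approx(25.0)
        assert strip.col_range == (5, 54)


class TestExtractProfile:
    def test_uniform_image_gives_constant_profile(self):
        mask = np.zeros((40, 60), dtype=np.uint8)
        mask[5:35, 5:55] = 255
        img = np.full((40, 60, 3), 90, dtype=np.uint8)
        knots = np.array([[20, x] for x in (5, 17, 29, 41, 53)])
        strip = build_strip(fit_axis_spline(knots), mask)
        prof = extract_profile(img, strip)
        for channel in (prof.red, prof.green, prof.blue):
            assert channel == pytest.approx(90.0 * np.ones_like(channel))
        assert prof.positions[0] == 0.0 and prof.positions[-1] == 100.0

    def test_column_mean_arithmetic(self):
        img = np.full((11, 9, 3), 0, dtype=np.uint8)
        img[4, :, :] = 100
        img[6, :, :] = 200
        mask = np.full((11, 9), 255, dtype=np.uint8)
        mask[0], mask[-1] = 0, 0
        knots = np.array([[5, x] for x in (0, 2, 4, 6, 8)])
        strip = build_strip(fit_axis_spline(knots), mask)
        # minor axis 9 -> half width 0.45 -> rows 5 +- 0: need wider band
        prof = extract_profile(img, strip)
        assert prof.red[0] == pytest.approx(img[5, 0, 0])

    def test_profile_matches_brute_force_column_means(self):
        rng = np.random.default_rng(5)
        img = rng.integers(0, 255, (30, 40, 3), dtype=np.uint8)
        mask = np.zeros((30, 40), dtype=np.uint8)
        mask[5:25, 3:37] = 255
        knots = np.array([[14, x] for x in (3, 11, 19, 27, 35)])
        strip = build_strip(fit_axis_spline(knots), mask)
        prof = extract_profile(img, strip)
        cols = range(strip.col_range[0], strip.col_range[1] + 1)
        for i, c in enumerate(cols):
            centre = strip.centreline(float(c))
            lo = max(int(round(centre - strip.half_width)), 0)
            hi = min(int(round(centre + strip.half_width)), img.shape[0] - 1)
            acc = [0.0, 0.0, 0.0]
            count = 0
            for r in range(lo, hi + 1):
                for ch in range(3):
                    acc[ch] += img[r, c, ch]
                count += 1
            assert prof.red[i] == pytest.approx(acc[0] / count)
            assert prof.green[i] == pytest.approx(acc[1] / count)
            assert prof.blue[i] == pytest.approx(acc[2] / count)

    def test_strip_outside_image_is_an_error(self):
        mask = np.zeros((20, 20), dtype=np.uint8)
        mask[5:15, 5:15] = 255
        knots = np.array([[10, x] for x in (5, 7, 9, 11, 14)])
        strip = build_strip(fit_axis_spline(knots), mask)
        with pytest.raises(FlyStripError):
            extract_profile(np.zeros((20, 10, 3), dtype=np.uint8), strip)


class TestStainSignal:
    def _profile(self, red, green):
        n = len(red)
        return ExpressionProfile(
            positions=np.linspace(0, 100, n),
            red=np.asarray(red, dtype=float),
            green=np.asarray(green, dtype=float),
            blue=np.zeros(n),
        )

    def test_nbt_is_red_channel(self):
        prof = self._profile([10, 20], [0, 0])
        assert stain_signal(prof, "NBT_BCIP").tolist() == [10, 20]

    def test_fastred_is_green_minus_red(self):
        prof = self._profile([30, 100], [100, 30])
        assert stain_signal(prof, "FastRed").tolist() == [70, 0]  # negative clipped

    def test_unknown_stain_rejected(self):
        with pytest.raises(Exception):
            stain_signal(self._profile([1], [1]), "DAPI")

    def test_invert_option(self):
        prof = self._profile([55], [0])
        assert stain_signal(prof, "NBT_BCIP", invert_signal=True).tolist() == [200.0]


class TestEndToEnd:
    def test_domain_boundaries_recovered_within_one_percent(self, domain_embryo):
        prof = domain_embryo["profile"]
        nbt = stain_signal(prof, "NBT_BCIP")
        crossings = half_max_crossings(prof.positions, nbt)
        assert len(crossings) == 2
        assert crossings[0] == pytest.approx(40.0, abs=1.0)
        assert crossings[1] == pytest.approx(60.0, abs=1.0)

    def test_profile_covers_full_axis_uniformly(self, domain_embryo):
        prof = domain_embryo["profile"]
        strip = domain_embryo["strip"]
        assert len(prof.positions) == strip.col_range[1] - strip.col_range[0] + 1
        assert prof.positions[0] == 0.0 and prof.positions[-1] == 100.0
        assert np.allclose(np.diff(prof.positions), prof.positions[1] - prof.positions[0])
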