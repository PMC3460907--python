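import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from flystrip.errors import FormatError, NoEmbryoError, ParameterError
from flystrip.segmentation import (
    MASK_STAGES,
    SegmentationParams,
    binarize,
    dilate,
    fill_holes,
    gamma_correct,
    gaussian_smooth,
    invert,
    kill_border_blobs,
    make_mask,
    remove_small_blobs,
    sobel_edges,
    to_gray8,
)
from flystrip.synthetic import SyntheticEmbryoSpec, render_embryo

from conftest import iou

gray_images = arrays(np.uint8, (6, 7), elements=st.integers(0, 255))
binary_images = arrays(np.uint8, (6, 7), elements=st.sampled_from([0, 255]))


class TestToGray8:
    @pytest.mark.parametrize(
        "pixel,expected", [((255, 255, 255), 255), ((0, 0, 0), 0), ((30, 60, 90), 60)]
    )
    def test_channel_mean(self, pixel, expected):
        img = np.full((3, 3, 3), pixel, dtype=np.uint8)
        assert to_gray8(img)[1, 1] == expected

    def test_rejects_non_rgb(self):
        with pytest.raises(FormatError):
            to_gray8(np.zeros((4, 4), dtype=np.uint8))

    def test_custom_weights(self):
        img = np.zeros((2, 2, 3), dtype=np.uint8)
        img[..., 0] = 100
        assert to_gray8(img, weights=[1, 0, 0])[0, 0] == 100


class TestGammaCorrect:
    @pytest.mark.parametrize("value,expected", [(0, 0), (255, 255), (128, 241)])
    def test_power_law(self, value, expected):
        img = np.full((3, 3), value, dtype=np.uint8)
        assert gamma_correct(img, 0.08)[0, 0] == expected

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ParameterError):
            gamma_correct(np.zeros((3, 3), dtype=np.uint8), 0.0)


@given(gray_images)
def test_invert_is_involution(img):
    assert np.array_equal(invert(invert(img)), img)


def test_invert_values():
    img = np.array([[0, 255, 100]], dtype=np.uint8)
    assert invert(img).tolist() == [[255, 0, 155]]


class TestSobel:
    def test_constant_image_has_no_edges(self):
        assert not sobel_edges(np.full((8, 8), 77, dtype=np.uint8)).any()

    def test_vertical_step_saturates_adjacent_pixels(self):
        img = np.zeros((5, 6), dtype=np.uint8)
        img[:, 3:] = 255
        edges = sobel_edges(img)
        assert (edges[:, 2:4] == 255).all()
        assert (edges[:, :2] == 0).all() and (edges[:, 4:] == 0).all()

    def test_corner_symmetry(self):
        # a 45-degree symmetric corner must give |gx| == |gy| at the corner
        img = np.zeros((7, 7), dtype=np.uint8)
        img[4:, 4:] = 200
        from scipy.ndimage import sobel as nd_sobel

        gx = nd_sobel(img.astype(float), axis=1, mode="nearest")
        gy = nd_sobel(img.astype(float), axis=0, mode="nearest")
        assert gx[4, 4] == pytest.approx(gy[4, 4])


class TestBinarize:
    @pytest.mark.parametrize("value,t,expected", [(6, 6, 0), (7, 6, 255), (145, 145, 0)])
    def test_at_and_above_threshold(self, value, t, expected):
        img = np.full((3, 3), value, dtype=np.uint8)
        assert binarize(img, t)[0, 0] == expected

    @given(gray_images, st.integers(0, 255))
    def test_idempotent(self, img, t):
        once = binarize(img, t)
        assert np.array_equal(binarize(once, t), once)


class TestDilate:
    def test_single_pixel_grows_to_3x3_block(self):
        img = np.zeros((5, 5), dtype=np.uint8)
        img[2, 2] = 255
        out = dilate(img, 1)
        assert (out[1:4, 1:4] == 255).all()
        assert out.sum() == 9 * 255

    def test_empty_and_zero_iterations(self):
        img = np.zeros((4, 4), dtype=np.uint8)
        assert not dilate(img, 3).any()
        img[1, 1] = 255
        assert np.array_equal(dilate(img, 0), img)

    @given(binary_images, st.integers(0, 3))
    def test_extensive_and_monotone(self, img, n):
        out_n = dilate(img, n)
        out_n1 = dilate(img, n + 1)
        assert ((img > 0) <= (out_n > 0)).all()
        assert ((out_n > 0) <= (out_n1 > 0)).all()


class TestBorderAndHoles:
    def test_border_blob_removed_interior_kept(self):
        img = np.zeros((8, 8), dtype=np.uint8)
        img[0:2, 0:2] = 255  # touches border
        img[4:6, 4:6] = 255  # interior
        out = kill_border_blobs(img)
        assert not out[0:2, 0:2].any()
        assert (out[4:6, 4:6] == 255).all()

    def test_hollow_ring_becomes_solid(self):
        img = np.zeros((9, 9), dtype=np.uint8)
        img[2:7, 2:7] = 255
        img[3:6, 3:6] = 0
        out = fill_holes(img)
        assert (out[2:7, 2:7] == 255).all()

    def test_background_reaching_border_unchanged(self):
        img = np.zeros((6, 6), dtype=np.uint8)
        img[2:4, 2:4] = 255
        assert np.array_equal(fill_holes(img), img)
        assert np.array_equal(kill_border_blobs(img), img)


class TestRemoveSmallBlobs:
    def test_area_cutoff_arithmetic(self):
        # 130x100 image, beta 13 -> cutoff 1000 px: the 500-px blob goes
        img = np.zeros((130, 100), dtype=np.uint8)
        img[5:45, 5:55] = 255  # 2000 px
        img[80:90, 10:60] = 255  # 500 px
        out, warnings = remove_small_blobs(img, 13.0)
        assert (out[5:45, 5:55] == 255).all()
        assert not out[80:90, 10:60].any()
        assert warnings == []

    def test_lone_small_blob_is_never_removed(self):
        img = np.zeros((200, 200), dtype=np.uint8)
        img[3:5, 3:8] = 255
        out, _ = remove_small_blobs(img, 13.0)
        assert np.array_equal(out, img)

    def test_two_big_blobs_kept_with_warning(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        img[0:4, 0:5] = 255
        img[6:10, 0:5] = 255
        out, warnings = remove_small_blobs(img, 5.0)  # cutoff 20 px, blobs 20 px
        assert out.sum() == img.sum()
        assert len(warnings) == 1

    def test_no_blobs_is_an_error(self):
        with pytest.raises(NoEmbryoError):
            remove_small_blobs(np.zeros((5, 5), dtype=np.uint8), 13.0)


class TestGaussianSmooth:
    def test_constant_image_is_fixed_point(self):
        img = np.full((40, 40), 200, dtype=np.uint8)
        assert gaussian_smooth(img, 5.0) == pytest.approx(200.0 * np.ones((40, 40)))

    def test_impulse_response_sd_matches_sigma(self):
        img = np.zeros((301, 301), dtype=np.uint8)
        img[150, 150] = 255
        out = gaussian_smooth(img, 20.0)
        x = np.arange(301) - 150.0
        marginal = out.sum(axis=0)
        sd = np.sqrt((marginal * x**2).sum() / marginal.sum())
        assert sd == pytest.approx(20.0, rel=0.01)

    def test_interior_impulse_mass_conserved(self):
        img = np.zeros((201, 201), dtype=np.uint8)
        img[100, 100] = 255
        out = gaussian_smooth(img, 10.0, accuracy=1e-3)
        assert out.sum() == pytest.approx(255.0, rel=1e-3)


class TestMakeMask:
    def test_fixture_embryo_recovered(self):
        images, truth = render_embryo(SyntheticEmbryoSpec(seed=11))
        em = make_mask(images.dic)
        assert em.quality == "good"
        assert em.blob_count == 1
        assert iou(em.mask, truth.mask) >= 0.98
        assert list(em.intermediates) == list(MASK_STAGES)
        # mask must not touch the image border
        m = em.mask
        assert not m[0].any() and not m[-1].any() and not m[:, 0].any() and not m[:, -1].any()

    def test_blank_image_raises_no_embryo(self):
        blank = np.full((64, 64, 3), 128, dtype=np.uint8)
        with pytest.raises(NoEmbryoError) as err:
            make_mask(blank)
        assert err.value.stage in MASK_STAGES

    def test_border_touching_embryo_is_discarded(self):
        images, _ = render_embryo(SyntheticEmbryoSpec(seed=3))
        shifted = np.roll(images.dic, 190, axis=1)  # embryo rim now at the border
        with pytest.raises(NoEmbryoError):
            make_mask(shifted)

    def test_tiny_image_rejected(self):
        with pytest.raises(FormatError):
            make_mask(np.zeros((2, 2, 3), dtype=np.uint8))

    def test_invalid_params_rejected(self):
        with pytest.raises(ParameterError):
            SegmentationParams(gamma=-1.0)
        with pytest.raises(ParameterError):
            SegmentationParams(beta=0.0)
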