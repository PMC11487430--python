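import numpy as np
import pytest
from skimage.draw import line as skimage_line
from skimage.measure import label as cc_label

from p300wave import (
    ValidationError,
    bresenham_connect,
    bresenham_line,
    bundle_channels,
    render_plot,
    rescale_image,
)
from p300wave.rendering import WaveformImage, _draw_segment


def _zscore(x):
    return (x - x.mean()) / x.std()


@pytest.fixture(scope="module")
def sine_plot():
    """One full period of a z-scored sine: max = -min, the margin test case."""
    t = np.arange(204)
    x = _zscore(np.sin(2 * np.pi * t / 204))
    return x, render_plot(x)


class TestBresenham:
    @pytest.mark.parametrize(
        "p1, p2, expected",
        [
            ((0, 0), (3, 3), [(0, 0), (1, 1), (2, 2), (3, 3)]),
            ((0, 0), (0, 5), [(0, i) for i in range(6)]),
            ((4, 0), (0, 0), [(4, 0), (3, 0), (2, 0), (1, 0), (0, 0)]),
            ((2, 2), (2, 2), [(2, 2)]),
        ],
    )
    def test_axis_aligned_and_diagonal_lines(self, p1, p2, expected):
        assert bresenham_line(p1, p2) == expected

    def test_matches_independent_reference_on_random_pairs(self, rng):
        """Pixel sets agree with skimage's Bresenham on a 64x64 grid."""
        for _ in range(300):
            (x0, y0, x1, y1) = rng.integers(0, 64, size=4)
            ours = set(bresenham_line((x0, y0), (x1, y1)))
            rr, cc = skimage_line(int(y0), int(x0), int(y1), int(x1))
            theirs = set(zip(cc.tolist(), rr.tolist()))
            assert ours == theirs

    def test_vectorized_segment_equals_incremental(self, rng):
        for _ in range(200):
            x0, y0, x1, y1 = (int(v) for v in rng.integers(0, 40, size=4))
            a = np.zeros((40, 40), dtype=np.uint8)
            b = np.zeros((40, 40), dtype=np.uint8)
            bresenham_connect(a, (x0, y0), (x1, y1))
            _draw_segment(b, x0, y0, x1, y1)
            np.testing.assert_array_equal(a, b)

    def test_endpoints_included_and_out_of_bounds_rejected(self):
        img = np.zeros((10, 10), dtype=np.uint8)
        bresenham_connect(img, (0, 0), (9, 4))
        assert img[0, 0] == 255 and img[4, 9] == 255
        with pytest.raises(ValidationError):
            bresenham_connect(img, (0, 0), (10, 4))


class TestRenderPlot:
    def test_binary_values_and_geometry(self, sine_plot):
        x, img = sine_plot
        assert set(np.unique(img.pixels)) <= {0, 255}
        assert img.width == 2 * 204  # Wx = gamma_w * L
        assert img.height == int(2 * 30 * (x.max() - x.min()))

    def test_symmetric_signal_margins_are_quarter_height(self, sine_plot):
        _x, img = sine_plot
        white_rows = np.flatnonzero(img.pixels.any(axis=1))
        top_margin = white_rows[0]
        bottom_margin = img.height - 1 - white_rows[-1]
        assert top_margin == pytest.approx(0.25 * img.height, abs=1.5)
        assert bottom_margin == pytest.approx(0.25 * img.height, abs=1.5)

    def test_full_width_coverage(self, sine_plot):
        """Every column up to the last sample's column holds trace pixels."""
        _x, img = sine_plot
        last_col = 2 * 203
        assert img.pixels[:, : last_col + 1].any(axis=0).all()

    def test_trace_is_single_connected_component(self, sine_plot):
        _x, img = sine_plot
        labels = cc_label(img.pixels > 0, connectivity=2)
        assert labels.max() == 1

    def test_deterministic(self, rng):
        x = _zscore(rng.standard_normal(204))
        a = render_plot(x)
        b = render_plot(x)
        np.testing.assert_array_equal(a.pixels, b.pixels)

    def test_flat_signal_rejected(self):
        with pytest.raises(ValidationError, match="flat"):
            render_plot(np.ones(100))

    def test_rows_clamped_into_image(self, rng):
        # heavy-tailed signal: extreme values must clamp, not crash
        x = _zscore(np.concatenate([rng.standard_normal(200), [12.0, -12.0]]))
        img = render_plot(x)
        assert img.pixels.any()


class TestRescaleImage:
    def test_identity_resample(self):
        px = (np.arange(150 * 150).reshape(150, 150) % 256).astype(np.uint8)
        img = WaveformImage(pixels=px, gamma_w=2, gamma_h=30, zero_line=75.0)
        out = rescale_image(img)
        np.testing.assert_allclose(out.pixels, px, atol=1e-6)

    def test_any_input_size_becomes_150_square(self, rng):
        for h in (7, 169, 408):
            px = (rng.random((h, 408)) > 0.5).astype(np.uint8) * 255
            img = WaveformImage(pixels=px, gamma_w=2, gamma_h=30, zero_line=h / 2)
            out = rescale_image(img)
            assert out.pixels.shape == (150, 150)
            assert out.rescaled

    def test_checkerboard_upscale_interpolates_midtones(self):
        px = np.array([[0, 255], [255, 0]], dtype=np.uint8)
        img = WaveformImage(pixels=px, gamma_w=1, gamma_h=1, zero_line=1.0)
        out = rescale_image(img).pixels
        # centre of the upscaled image sits between the four corners
        assert out[75, 75] == pytest.approx(127.5, abs=3)
        assert out.min() >= 0 and out.max() <= 255


class TestBundleChannels:
    def _planes(self, rng, n=8):
        planes = []
        for i in range(n):
            px = (rng.random((150, 150)) * 255).astype(np.float32)
            planes.append(
                WaveformImage(
                    pixels=px, gamma_w=2, gamma_h=30, zero_line=75.0,
                    channel=f"ch{i}", rescaled=True,
                )
            )
        return planes

    def test_stack_shape_and_order(self, rng):
        planes = self._planes(rng)
        stack = bundle_channels(planes)
        assert stack.pixels.shape == (150, 150, 8)
        for i, plane in enumerate(planes):
            np.testing.assert_array_equal(stack.pixels[:, :, i], plane.pixels)
        # permuting inputs permutes planes identically
        perm = [3, 1, 0, 2, 7, 6, 5, 4]
        permuted = bundle_channels([planes[i] for i in perm])
        for j, i in enumerate(perm):
            np.testing.assert_array_equal(permuted.pixels[:, :, j], planes[i].pixels)

    def test_wrong_count_rejected(self, rng):
        with pytest.raises(ValidationError):
            bundle_channels(self._planes(rng, n=7))

    def test_unrescaled_planes_rejected(self, rng):
        planes = self._planes(rng)
        planes[0].rescaled = False
        with pytest.raises(ValidationError):
            bundle_channels(planes)
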