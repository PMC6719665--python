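"""Reciprocal-space rescaling kernels against arithmetic and DFT oracles."""

import numpy as np
import pytest

from cryomerge.exceptions import CryomergeError, GridMismatchError
from cryomerge.formats_io import DensityMap, ImageStack
from cryomerge.grid_rescale import (
    _pad_crop_centered,
    crop_window,
    fourier_rescale,
    fourier_rescale_to_box,
    granularity,
    pad_window,
    resample_real_space,
)
from cryomerge.synthetic_fixtures import render


class TestGranularity:
    @pytest.mark.parametrize(
        "box,apix,expected",
        [
            (100, 1.0, 0.02),  # 2% of the pixel size for a 100-pixel box
            (200, 1.0, 0.01),  # 1% for a 200-pixel box
            (400, 2.0, 0.01),
        ],
    )
    def test_step_values(self, box, apix, expected):
        assert granularity(box, apix) == pytest.approx(expected)

    def test_odd_box_rejected(self):
        with pytest.raises(ValueError, match="even"):
            granularity(99, 1.0)


def _trig_resample_1d(signal: np.ndarray, new_n: int) -> np.ndarray:
    """Brute-force oracle: evaluate the trigonometric interpolant of `signal`
    at the `new_n` positions m * N / M, keeping only frequencies below the
    smaller Nyquist.  O(N*M) explicit sums, no FFT."""
    n = len(signal)
    coeffs = {
        k: sum(signal[x] * np.exp(-2j * np.pi * k * x / n) for x in range(n))
        for k in range(-n // 2, n // 2)
    }
    keep = range(-min(n, new_n) // 2, min(n, new_n) // 2)
    out = np.empty(new_n, dtype=complex)
    for m in range(new_n):
        u = m * n / new_n
        out[m] = sum(coeffs[k] * np.exp(2j * np.pi * k * u / n) for k in keep) / n
    return out  # complex: the asymmetric Nyquist term matters for even sizes


class TestFourierRescale:
    def test_new_box_and_achieved_apix_arithmetic(self):
        stack = ImageStack(np.zeros((1, 100, 100), np.float32), apix=1.00)
        res = fourier_rescale(stack, 1.02)
        assert res.new_box == 98
        assert res.achieved_apix == pytest.approx(100 * 1.00 / 98)

    @pytest.mark.parametrize("new_n", [8, 16])
    def test_matches_direct_dft_oracle(self, rng, new_n):
        g = rng.normal(size=12)
        img = ImageStack(np.outer(g, g)[None], apix=1.0)
        res = fourier_rescale(img, 12.0 / new_n)
        expected_1d = _trig_resample_1d(g, new_n)
        expected = np.real(np.outer(expected_1d, expected_1d))
        np.testing.assert_allclose(res.object.data[0], expected, atol=1e-5)

    def test_identity_when_target_equals_current(self, phantom_map):
        res = fourier_rescale(phantom_map, phantom_map.apix)
        span = phantom_map.data.max() - phantom_map.data.min()
        assert np.max(np.abs(res.object.data - phantom_map.data)) < 1e-6 * span

    def test_micrograph_harmonization_within_granularity(self, rng):
        mic = ImageStack(rng.normal(size=(1, 128, 128)), apix=1.28)
        res = fourier_rescale(mic, 1.40)
        assert abs(res.achieved_apix - 1.40) < granularity(128, 1.28)

    def test_movie_rescales_every_frame_equally(self, rng):
        frame = rng.normal(size=(64, 64))
        movie = ImageStack(np.stack([frame, frame]), apix=1.28, is_movie=True)
        res = fourier_rescale(movie, 1.40)
        assert res.object.is_movie
        np.testing.assert_allclose(res.object.data[0], res.object.data[1], atol=1e-5)

    def test_band_limited_round_trip(self, phantom_map):
        up = fourier_rescale(phantom_map, 1.20).object  # upsample (smaller apix)
        back = fourier_rescale(up, phantom_map.apix).object
        assert back.box == phantom_map.box
        span = phantom_map.data.max() - phantom_map.data.min()
        rms = np.sqrt(np.mean((back.data - phantom_map.data) ** 2))
        assert rms < 1e-3 * span

    def test_achieved_error_bounded_by_half_local_step(self, rng):
        stack = ImageStack(rng.normal(size=(1, 64, 64)), apix=1.28)
        for target in [1.40, 1.31, 1.17, 1.05]:
            res = fourier_rescale(stack, target)
            n = 64
            neighbors = [n * 1.28 / (res.new_box - 2), n * 1.28 / (res.new_box + 2)]
            local_step = max(abs(a - res.achieved_apix) for a in neighbors)
            assert abs(res.achieved_apix - target) <= local_step / 2 + 1e-9

    def test_invalid_targets_rejected(self, phantom_map):
        with pytest.raises(ValueError):
            fourier_rescale(phantom_map, -1.0)
        with pytest.raises(CryomergeError):
            fourier_rescale(phantom_map, 100.0)  # box would collapse below 4


def test_zero_padding_conserves_spectral_power(rng):
    data = rng.normal(size=(16, 16))
    spec = np.fft.fftshift(np.fft.fftn(data))
    padded = _pad_crop_centered(spec, (24, 24), (0, 1))
    p0 = np.sum(np.abs(spec) ** 2)
    p1 = np.sum(np.abs(padded) ** 2)
    assert abs(p1 - p0) <= 1e-6 * p0


class TestFourierRescaleToBox:
    def test_spliceosome_box_pair_gives_exact_apix(self, rng):
        stack = ImageStack(rng.normal(size=(1, 560, 560)), apix=0.880)
        res = fourier_rescale_to_box(stack, 560, 440)
        assert res.achieved_apix == pytest.approx(0.880 * 560 / 440)
        assert res.achieved_apix == pytest.approx(1.120)

    def test_naive_pair_gives_slightly_off_apix(self, rng):
        stack = ImageStack(rng.normal(size=(1, 534, 534)), apix=0.880)
        res = fourier_rescale_to_box(stack, 534, 420)
        assert res.achieved_apix == pytest.approx(534 / 420 * 0.880)
        assert round(res.achieved_apix, 3) == 1.119

    def test_equal_boxes_is_identity(self, rng):
        data = rng.normal(size=(1, 32, 32)).astype(np.float32)
        stack = ImageStack(data, apix=1.0)
        res = fourier_rescale_to_box(stack, 32, 32)
        np.testing.assert_allclose(res.object.data, data, atol=1e-5)

    def test_odd_boxes_rejected(self, rng):
        stack = ImageStack(rng.normal(size=(1, 32, 32)), apix=1.0)
        with pytest.raises(ValueError, match="even-numbered"):
            fourier_rescale_to_box(stack, 32, 31)


class TestWindow:
    def test_crop_keeps_apix_and_center(self):
        data = np.zeros((1, 440, 440), np.float32)
        data[0, 220, 220] = 1.0  # delta at the center pixel
        stack = ImageStack(data, apix=1.120)
        out = crop_window(stack, 420)
        assert out.apix == pytest.approx(1.120)
        assert out.data.shape == (1, 420, 420)
        assert out.data[0, 210, 210] == 1.0

    def test_crop_to_same_size_is_identity(self, phantom_map):
        out = crop_window(phantom_map, phantom_map.box[0])
        np.testing.assert_array_equal(out.data, phantom_map.data)

    def test_crop_larger_than_box_rejected(self, phantom_map):
        with pytest.raises(ValueError):
            crop_window(phantom_map, 128)

    def test_pad_then_crop_round_trips(self, phantom_map):
        padded = pad_window(phantom_map, 80)
        back = crop_window(padded, 64)
        np.testing.assert_array_equal(back.data, phantom_map.data)
        np.testing.assert_allclose(back.origin, phantom_map.origin)


class TestResampleRealSpace:
    def test_identity_resample(self, phantom_map):
        out = resample_real_space(phantom_map, phantom_map.apix, phantom_map)
        span = phantom_map.data.max() - phantom_map.data.min()
        assert np.max(np.abs(out.data - phantom_map.data)) < 1e-5 * span

    def test_redeclared_blob_matches_analytic_evaluation(self, phantom):
        # rendering declared 5% small, resampled onto the reference grid,
        # must match the analytic phantom evaluated directly on that grid
        ref = render(phantom, 64, 1.40)
        moving = render(phantom, 64, 1.40 * 0.95)  # true scale of the data
        out = resample_real_space(moving, 1.40 * 0.95, ref)
        rms = np.sqrt(np.mean((out.data - ref.data) ** 2))
        assert rms < 0.01 * (ref.data.max() - ref.data.min())

    def test_shifted_origin_lands_at_same_physical_coordinate(self, phantom):
        ref = render(phantom, 64, 1.40)
        moving = render(phantom, 64, 1.40)
        moving.origin = moving.origin + np.array([0.0, 7.0, -14.0])
        moving_data = np.roll(moving.data, shift=(0, -5, 10), axis=(0, 1, 2))
        shifted = DensityMap(moving_data, apix=1.40, origin=moving.origin)
        out = resample_real_space(shifted, 1.40, ref)
        center = np.array(ref.box) // 2
        inner = (slice(16, 48),) * 3  # compare away from the wrap-around edges
        np.testing.assert_allclose(
            out.data[inner], ref.data[inner], atol=1e-4 * ref.data.max()
        )

    def test_zero_overlap_rejected(self, phantom_map):
        far = DensityMap(
            phantom_map.data, apix=phantom_map.apix, origin=phantom_map.origin + 1e4
        )
        with pytest.raises(GridMismatchError, match="overlap"):
            resample_real_space(far, phantom_map.apix, phantom_map)
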