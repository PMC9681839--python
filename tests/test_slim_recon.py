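"""Four-bucket phase reconstruction: closed forms, round trips, error handling."""

import numpy as np
import pytest
from scipy import ndimage

from pics.slim_recon import (
    AmplitudeFields,
    InterferogramStack,
    StackError,
    estimate_amplitude_ratio,
    extract_brightfield,
    load_stack,
    reconstruct_phase,
)
from pics.smear_sim import forward_interferograms


def _stack_from_fields(ui, us, dphi, shape=(1, 1)):
    """Forward model I_k = |Ui|^2 + |Us|^2 + 2|Ui||Us|cos(dphi + k pi/2)."""
    frames = [
        np.full(shape, ui**2 + us**2 + 2 * ui * us * np.cos(dphi + k * np.pi / 2))
        for k in range(4)
    ]
    return InterferogramStack(np.stack(frames))


def _smooth_field(rng, n=64, amplitude=1.5):
    f = ndimage.gaussian_filter(rng.normal(0, 1, (n, n)), 4)
    return f / np.abs(f).max() * amplitude


class TestReconstructPhase:
    def test_constant_frames_give_zero_phase(self):
        stack = InterferogramStack(np.full((4, 8, 8), 0.7))
        assert np.all(reconstruct_phase(stack).phi == 0.0)

    def test_single_pixel_closed_form(self):
        # |Ui|=1, |Us|=0.5, dphi=pi/3 -> I = (1.75, 0.383975, 0.75, 2.116025)
        stack = _stack_from_fields(1.0, 0.5, np.pi / 3)
        amp = estimate_amplitude_ratio(stack)
        assert amp.delta_phi[0, 0] == pytest.approx(np.pi / 3, abs=1e-9)
        assert amp.beta[0, 0] == pytest.approx(0.5, abs=1e-9)
        # full-field argument phi = atan2(b sin, 1 + b cos)
        phi = reconstruct_phase(stack).phi[0, 0]
        assert phi == pytest.approx(0.33347, abs=5e-6)

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        phi = _smooth_field(rng)
        stack = forward_interferograms(phi, beta=0.3)
        amp = estimate_amplitude_ratio(stack)
        assert np.abs(amp.delta_phi - phi).max() < 1e-6
        phi_full = np.arctan2(0.3 * np.sin(phi), 1 + 0.3 * np.cos(phi))
        assert np.abs(reconstruct_phase(stack).phi - phi_full).max() < 1e-6

    def test_shift_equivariance(self):
        rng = np.random.default_rng(1)
        phi = _smooth_field(rng, amplitude=0.8)
        c = 0.7
        d0 = estimate_amplitude_ratio(forward_interferograms(phi, 0.4)).delta_phi
        d1 = estimate_amplitude_ratio(forward_interferograms(phi + c, 0.4)).delta_phi
        wrapped = np.angle(np.exp(1j * (d1 - d0)))
        assert np.abs(wrapped - c).max() < 1e-6

    def test_beta_zero_limit(self):
        rng = np.random.default_rng(2)
        stack = forward_interferograms(_smooth_field(rng), beta=0.0)
        assert np.all(reconstruct_phase(stack).phi == 0.0)

    def test_rms_error_nondecreasing_in_noise(self):
        rng = np.random.default_rng(3)
        phi = _smooth_field(rng)
        errors = []
        for sigma in [0.0, 0.02, 0.1, 0.3]:
            stack = forward_interferograms(
                phi, 0.3, noise_sigma=sigma, rng=np.random.default_rng(42)
            )
            d = estimate_amplitude_ratio(stack).delta_phi
            errors.append(float(np.sqrt(np.mean((d - phi) ** 2))))
        assert all(a <= b + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_multichannel_modes_agree_on_identical_channels(self):
        rng = np.random.default_rng(4)
        phi = _smooth_field(rng, n=16)
        mono = forward_interferograms(phi, 0.4).frames
        rgb = InterferogramStack(np.repeat(mono[..., None], 3, axis=3))
        for mode in ("per_channel_mean", "luminance"):
            d = estimate_amplitude_ratio(rgb, mode).delta_phi
            assert np.abs(d - phi).max() < 1e-6


class TestAmplitudeRatio:
    def test_no_scattered_field_gives_zero_beta(self):
        stack = _stack_from_fields(1.0, 0.0, 0.3, shape=(4, 4))
        assert np.all(estimate_amplitude_ratio(stack).beta == 0.0)

    @pytest.mark.parametrize("dphi", [0.2, 1.0, -2.5])
    def test_equal_amplitudes_give_beta_one(self, dphi):
        # the discriminant of the equal-root case cancels to ~1e-16, so its
        # square root leaves ~1e-8 of noise in beta
        stack = _stack_from_fields(0.7, 0.7, dphi)
        assert estimate_amplitude_ratio(stack).beta[0, 0] == pytest.approx(1.0, abs=1e-6)


class TestExtractBrightfield:
    def test_identity_on_first_frame(self):
        frames = np.zeros((4, 6, 6))
        frames[0] = 0.7
        assert np.array_equal(extract_brightfield(InterferogramStack(frames)), np.full((6, 6), 0.7))

    def test_simulator_stack_frame_bit_for_bit(self, small_samples):
        s = small_samples[0]
        assert np.array_equal(extract_brightfield(s.stack), s.stack.frames[0])

    def test_channel_count_preserved(self):
        stack = InterferogramStack(np.random.default_rng(0).random((4, 5, 5, 3)))
        assert extract_brightfield(stack).shape == (5, 5, 3)


class TestValidation:
    def test_wrong_frame_count(self):
        with pytest.raises(StackError):
            InterferogramStack(np.ones((3, 4, 4)))

    def test_negative_intensity(self):
        frames = np.ones((4, 4, 4))
        frames[1, 0, 0] = -0.1
        with pytest.raises(StackError):
            InterferogramStack(frames)

    def test_ragged_frames(self):
        with pytest.raises(StackError):
            InterferogramStack([np.ones((4, 4)), np.ones((4, 4)), np.ones((5, 5)), np.ones((4, 4))])


class TestIO:
    def test_load_four_file_family(self, tmp_path):
        import tifffile

        rng = np.random.default_rng(0)
        frames = rng.random((4, 8, 8)).astype(np.float32)
        for k in range(4):
            tifffile.imwrite(tmp_path / f"field_s{k}.tif", frames[k])
        stack = load_stack(tmp_path / "field_s0.tif")
        assert np.allclose(stack.frames, frames)

    def test_load_multipage(self, tmp_path):
        import tifffile

        frames = np.random.default_rng(1).random((4, 8, 8)).astype(np.float32)
        tifffile.imwrite(tmp_path / "stack.tif", frames)
        assert np.allclose(load_stack(tmp_path / "stack.tif").frames, frames)

    def test_missing_frame_errors(self, tmp_path):
        import tifffile

        tifffile.imwrite(tmp_path / "x_s0.tif", np.ones((4, 4), np.float32))
        with pytest.raises(StackError):
            load_stack(tmp_path / "x_s0.tif")
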