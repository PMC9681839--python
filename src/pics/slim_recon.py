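"""Quantitative phase reconstruction from four phase-shifted interferograms.

Spatial light interference microscopy (SLIM) records four intensity frames
``I_k`` with the phase delay between the incident and scattered field shifted
in increments of pi/2:

    I_k = |U_i|^2 + |U_s|^2 + 2 |U_i||U_s| cos(dphi + k*pi/2),   k = 0..3

where ``dphi`` is the incident-vs-scattered phase difference.  The four-bucket
inversion recovers

    dphi = atan2(I_3 - I_1, I_0 - I_2)

and, with the amplitude ratio ``beta = |U_s| / |U_i|``, the argument of the
total field

    phi = atan2(beta * sin(dphi), 1 + beta * cos(dphi)).

``phi`` is the quantitative phase image; ``dphi`` and ``beta`` are exposed as
intermediates because some downstream uses (e.g. the forward simulator) are
phrased directly in terms of the scattered-field phase.  The halo artifact of
phase-contrast illumination is *not* corrected here: the acquisition geometry
leaves it in all four frames, so it propagates into the phase map by design.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "InterferogramStack",
    "PhaseMap",
    "AmplitudeFields",
    "reconstruct_phase",
    "estimate_amplitude_ratio",
    "extract_brightfield",
    "load_stack",
]

#: modulation below this fraction of the mean intensity is treated as absent
DEGENERATE_MODULATION_FRACTION = 1e-12


class StackError(ValueError):
    """Raised when an interferogram stack violates its structural invariants."""


@dataclass
class InterferogramStack:
    """Four co-registered intensity frames at phase shifts k*pi/2.

    Parameters
    ----------
    frames : ndarray
        Shape ``(4, H, W)`` or ``(4, H, W, C)``; nonnegative intensities.
        Frame ``k`` carries phase delay ``k*pi/2`` radians.
    pixel_size : float
        Lateral sampling in micrometres per pixel (metadata only).
    """

    frames: np.ndarray
    pixel_size: float = 1.0

    def __post_init__(self) -> None:
        try:
            self.frames = np.asarray(self.frames, dtype=np.float64)
        except ValueError as exc:  # ragged list of frames
            raise StackError(f"frames have mismatched shapes: {exc}") from exc
        if self.frames.ndim not in (3, 4):
            raise StackError(
                f"frames must be (4, H, W) or (4, H, W, C); got shape {self.frames.shape}"
            )
        if self.frames.shape[0] != 4:
            raise StackError(f"expected exactly 4 frames, got {self.frames.shape[0]}")
        if not np.all(np.isfinite(self.frames)):
            raise StackError("frames contain non-finite intensities")
        if np.any(self.frames < 0):
            raise StackError("intensities must be nonnegative")

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]

    @property
    def n_channels(self) -> int:
        return 1 if self.frames.ndim == 3 else self.frames.shape[3]


@dataclass
class PhaseMap:
    """Scalar phase field in radians, principal branch (-pi, pi]."""

    phi: np.ndarray
    provenance: str = ""
    pixel_size: float = 1.0


@dataclass
class AmplitudeFields:
    """Reconstruction intermediates: scattered-vs-incident phase and amplitude ratio."""

    delta_phi: np.ndarray
    beta: np.ndarray
    provenance: str = ""


def _single_channel_inversion(
    frames: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Four-bucket inversion of one channel; returns (phi, delta_phi, beta)."""
    i0, i1, i2, i3 = frames
    cos_term = i0 - i2  # 4 |U_i||U_s| cos(dphi)
    sin_term = i3 - i1  # 4 |U_i||U_s| sin(dphi)
    g = 0.25 * np.hypot(cos_term, sin_term)  # |U_i||U_s|
    s = 0.25 * (i0 + i1 + i2 + i3)  # |U_i|^2 + |U_s|^2

    degenerate = g < DEGENERATE_MODULATION_FRACTION * np.maximum(s, 1e-300)

    delta_phi = np.arctan2(sin_term, cos_term)
    delta_phi[degenerate] = 0.0

    # |U_i|^2, |U_s|^2 are the roots of x^2 - S x + G^2 = 0; incident field
    # dominates, so it takes the larger root.
    disc = np.clip(s * s - 4.0 * g * g, 0.0, None)
    root = np.sqrt(disc)
    ui2 = 0.5 * (s + root)
    us2 = 0.5 * (s - root)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.sqrt(np.clip(us2, 0.0, None) / np.where(ui2 > 0, ui2, 1.0))
    beta = np.where(ui2 > 0, beta, 0.0)
    beta[degenerate] = 0.0

    phi = np.arctan2(beta * np.sin(delta_phi), 1.0 + beta * np.cos(delta_phi))
    phi[degenerate] = 0.0
    return phi, delta_phi, beta


_LUMA = np.array([0.2126, 0.7152, 0.0722])


def _channel_stacks(frames: np.ndarray, channel_mode: str) -> list[np.ndarray]:
    if frames.ndim == 3:
        return [frames]
    if channel_mode == "per_channel_mean":
        return [frames[..., c] for c in range(frames.shape[3])]
    if channel_mode == "luminance":
        weights = _LUMA if frames.shape[3] == 3 else np.full(frames.shape[3], 1.0 / frames.shape[3])
        return [frames @ (weights / weights.sum())]
    raise ValueError(f"unknown channel_mode {channel_mode!r}")


def reconstruct_phase(
    stack: InterferogramStack, channel_mode: str = "per_channel_mean"
) -> PhaseMap:
    """Recover the quantitative phase map from a four-frame stack.

    Multichannel stacks are reconstructed per channel and the phase maps
    averaged (``per_channel_mean``, reduces uncorrelated noise), or collapsed
    to luminance first (``luminance``).  Pixels with zero fringe modulation
    return phi = 0 by convention.
    """
    channels = _channel_stacks(stack.frames, channel_mode)
    phi = np.mean([_single_channel_inversion(c)[0] for c in channels], axis=0)
    return PhaseMap(
        phi=phi,
        provenance=channel_mode,
        pixel_size=stack.pixel_size,
    )


def estimate_amplitude_ratio(
    stack: InterferogramStack, channel_mode: str = "per_channel_mean"
) -> AmplitudeFields:
    """Per-pixel scattered-field phase ``delta_phi`` and amplitude ratio ``beta``.

    ``beta`` is recovered from the fringe modulation G = |U_i||U_s| and the
    mean intensity S = |U_i|^2 + |U_s|^2: the two squared amplitudes are the
    roots of x^2 - S x + G^2 = 0, the incident field taking the larger root.
    Numerically negative discriminants (noise at beta ~ 1) are clamped to the
    equal-root case rather than raised.
    """
    channels = _channel_stacks(stack.frames, channel_mode)
    results = [_single_channel_inversion(c) for c in channels]
    if len(results) == 1:
        _, delta_phi, beta = results[0]
    else:
        # average the complex modulation so wrapped phases combine correctly
        z = np.mean(
            [b * np.exp(1j * d) for _, d, b in results], axis=0
        )
        delta_phi = np.angle(z)
        beta = np.mean([b for _, _, b in results], axis=0)
    return AmplitudeFields(delta_phi=delta_phi, beta=beta, provenance=channel_mode)


def extract_brightfield(stack: InterferogramStack) -> np.ndarray:
    """Return the unshifted (k = 0) frame — the ordinary brightfield image.

    With an RGB camera the zero-delay interferogram *is* a color brightfield
    micrograph; channel count is preserved.
    """
    return stack.frames[0].copy()


def load_stack(path: str | Path, pixel_size: float = 1.0) -> InterferogramStack:
    """Load a stack from a 4-page TIFF or from four files suffixed ``_s0.._s3``.

    Page order equals shift order.  Integer inputs are converted to float;
    8/16-bit integer and 32-bit float intensities are accepted.
    """
    import tifffile

    path = Path(path)
    # suffix-matched family: <stem>_s0.<ext> .. <stem>_s3.<ext>
    stem = None
    for marker in ("_s0", "_s1", "_s2", "_s3"):
        if path.stem.endswith(marker):
            stem = str(path.parent / path.stem[: path.stem.rindex(marker)])
            break
    if stem is None:
        if not (path.exists() and path.suffix.lower() in {".tif", ".tiff"}):
            raise StackError(f"{path}: expected a multi-page TIFF or a *_s0..3 family")
        frames = tifffile.imread(path)
        if frames.ndim == 2 or frames.shape[0] != 4:
            raise StackError(f"{path} is not a 4-page stack (shape {frames.shape})")
        return InterferogramStack(np.asarray(frames, dtype=np.float64), pixel_size)
    candidates = []
    for k in range(4):
        matches = sorted(Path(stem).parent.glob(f"{Path(stem).name}_s{k}.*"))
        if not matches:
            raise StackError(f"missing frame {k}: no file {stem}_s{k}.*")
        candidates.append(matches[0])
    frames = []
    for p in candidates:
        if p.suffix.lower() in {".tif", ".tiff"}:
            frames.append(tifffile.imread(p))
        else:
            import imageio.v3 as iio

            frames.append(iio.imread(p))
    shapes = {f.shape for f in frames}
    if len(shapes) != 1:
        raise StackError(f"frame shapes differ: {sorted(shapes)}")
    return InterferogramStack(np.stack(frames).astype(np.float64), pixel_size)
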