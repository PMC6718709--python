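"""Gaussian bubble masks over temporal (frame) and spatial (pixel) stimulus domains.

A "bubble" is a Gaussian window of visibility, scaled to unit height, placed at a
random position in the stimulus. Several bubbles are combined into a single
reveal profile by reflecting each around 0.5, multiplying, and re-reflecting:

    Bubbles = 1 - prod_b (1 - bubble_b)

so the combined profile is 1 wherever any constituent bubble is 1, and 0 where
all are 0. Applying the profile to a grayscale frame scales each pixel's Weber
contrast toward zero:

    displayed = mean + (frame - mean) * Bubbles

Conventions
-----------
* Frames are indexed 1..n_frames, with racket-ball contact at
  ``contact_frame`` (the last frame by default). The time before contact of
  frame k is ``(contact_frame - k) / frame_rate`` seconds.
* Temporal profiles are 1-D arrays of length ``n_frames``; index 0 holds
  frame 1. Spatial profiles are 2-D arrays of shape ``(height, width)``
  indexed ``[y, x]`` with pixel grid coordinates 0..width-1, 0..height-1.
* Bubble centers live on the continuous domain; the Gaussian is evaluated at
  grid coordinates (not snapped to the grid) and rescaled so its peak is
  exactly 1 at the nearest grid point. Gaussians are truncated at the domain
  edge, never renormalized, so edge frames/pixels are revealed less often.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "StimulusGeometry",
    "BubbleSpec",
    "gaussian_bubble",
    "combine_bubbles",
    "sample_bubble_centers",
    "temporal_profiles",
    "spatial_profile",
    "make_profile",
    "apply_mask",
    "frame_to_time",
]


@dataclass(frozen=True)
class StimulusGeometry:
    """Geometry of the video stimulus.

    Defaults reproduce the study design: 96 frames at 120 Hz starting 0.8 s
    before racket-ball contact (contact at the final frame), over a 600x400
    pixel region with the contact point at the image center unless a per-video
    point is given.
    """

    n_frames: int = 96
    frame_rate: float = 120.0
    contact_frame: int | None = None
    width: int = 600
    height: int = 400
    contact_point: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise ValueError(f"n_frames must be >= 1, got {self.n_frames}")
        if self.frame_rate <= 0:
            raise ValueError(f"frame_rate must be > 0, got {self.frame_rate}")
        if self.contact_frame is None:
            object.__setattr__(self, "contact_frame", self.n_frames)
        if not 1 <= self.contact_frame <= self.n_frames:
            raise ValueError(
                f"contact_frame must be in [1, {self.n_frames}], got {self.contact_frame}"
            )
        if self.contact_point is None:
            object.__setattr__(
                self, "contact_point", (self.width / 2.0, self.height / 2.0)
            )
        cx, cy = self.contact_point
        if not (0 <= cx < self.width and 0 <= cy < self.height):
            raise ValueError(
                f"contact_point {self.contact_point} outside "
                f"[0, {self.width}) x [0, {self.height})"
            )

    @property
    def frame_grid(self) -> np.ndarray:
        """1-based frame indices, shape (n_frames,)."""
        return np.arange(1, self.n_frames + 1, dtype=float)

    @property
    def spatial_shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    def contains_temporal(self, center: float) -> bool:
        # continuous frame axis extends half a frame beyond the first/last
        # frame centers so every frame owns an equal-width bin
        return 0.5 <= center < self.n_frames + 0.5

    def contains_spatial(self, center: Sequence[float]) -> bool:
        x, y = center
        return 0 <= x < self.width and 0 <= y < self.height


@dataclass(frozen=True)
class BubbleSpec:
    """Bubble placement for one trial: centers plus a common spread sigma.

    Temporal centers are scalar frame positions; spatial centers are (x, y)
    pixel positions. Default sigma is 3 frames (temporal) or 12 pixels
    (spatial), matching the study.
    """

    centers: tuple = field(default_factory=tuple)
    sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError(f"sigma must be > 0, got {self.sigma}")
        object.__setattr__(
            self,
            "centers",
            tuple(
                tuple(c) if np.ndim(c) else float(c) for c in self.centers
            ),
        )

    @property
    def n_bubbles(self) -> int:
        return len(self.centers)

    @property
    def is_spatial(self) -> bool:
        return bool(self.centers) and np.ndim(self.centers[0]) == 1


DEFAULT_SIGMA = {"temporal": 3.0, "spatial": 12.0}
DEFAULT_N_BUBBLES = {"temporal": 8, "spatial": 20}


def gaussian_bubble(
    center, sigma: float, geometry: StimulusGeometry
) -> np.ndarray:
    """A single unit-height Gaussian bubble evaluated on the stimulus grid.

    ``center`` is a scalar frame position (temporal) or an (x, y) pixel
    position (spatial; the 2-D Gaussian is isotropic). The profile peaks at
    exactly 1 at the grid point nearest the center and is truncated, not
    renormalized, at domain edges.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if np.ndim(center) == 0:
        center = float(center)
        if not geometry.contains_temporal(center):
            raise ValueError(
                f"temporal center {center} outside [0.5, {geometry.n_frames + 0.5})"
            )
        d = geometry.frame_grid - center
        values = np.exp(-(d**2) / (2.0 * sigma**2))
    else:
        cx, cy = (float(c) for c in center)
        if not geometry.contains_spatial((cx, cy)):
            raise ValueError(
                f"spatial center {(cx, cy)} outside "
                f"[0, {geometry.width}) x [0, {geometry.height})"
            )
        x = np.arange(geometry.width, dtype=float)
        y = np.arange(geometry.height, dtype=float)
        d2 = (x[None, :] - cx) ** 2 + (y[:, None] - cy) ** 2
        values = np.exp(-d2 / (2.0 * sigma**2))
    # unit height at the nearest grid point (exact even for off-grid centers)
    return values / values.max()


def combine_bubbles(
    bubbles: Sequence[np.ndarray], shape: tuple[int, ...] | None = None
) -> np.ndarray:
    """Combine individual bubbles into one reveal profile.

    Reflect each bubble around 0.5, multiply pointwise, re-reflect:
    ``1 - prod_b (1 - bubble_b)``. The result is order-independent, bounded in
    [0, 1], and equals 1 exactly where some bubble equals 1. An empty list
    yields the all-zeros profile (the empty product is 1), which requires
    ``shape`` to be given.
    """
    bubbles = list(bubbles)
    if not bubbles:
        if shape is None:
            raise ValueError("empty bubble list requires an explicit shape")
        return np.zeros(shape, dtype=float)
    first = np.asarray(bubbles[0], dtype=float)
    if len(bubbles) == 1:
        # one-term product: exact identity (1 - (1 - g) would round off
        # values below machine epsilon)
        return first.copy()
    out = np.ones_like(first)
    for b in bubbles:
        b = np.asarray(b, dtype=float)
        if b.shape != first.shape:
            raise ValueError(
                f"bubble shape {b.shape} does not match {first.shape}"
            )
        out *= 1.0 - b
    return 1.0 - out


def sample_bubble_centers(
    n: int,
    geometry: StimulusGeometry,
    rng: np.random.Generator,
    domain: str = "temporal",
) -> list:
    """Draw ``n`` bubble centers independently and uniformly over the domain.

    Temporal centers are uniform on the continuous frame axis
    [0.5, n_frames + 0.5), so nearest-frame binning gives every frame an
    equal-width bin; spatial centers are uniform on [0, width) x [0, height).
    """
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    if domain == "temporal":
        return list(rng.uniform(0.5, geometry.n_frames + 0.5, size=n))
    if domain == "spatial":
        x = rng.uniform(0, geometry.width, size=n)
        y = rng.uniform(0, geometry.height, size=n)
        return [(float(xi), float(yi)) for xi, yi in zip(x, y)]
    raise ValueError(f"unknown domain {domain!r}")


def temporal_profiles(
    centers: np.ndarray, sigma: float, geometry: StimulusGeometry
) -> np.ndarray:
    """Vectorized combined profiles for many temporal trials at once.

    ``centers`` has shape (n_trials, n_bubbles); returns (n_trials, n_frames).
    Equivalent to calling :func:`gaussian_bubble` + :func:`combine_bubbles`
    per trial, but in one shot — used by the simulator and by log replay.
    """
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        return np.zeros((centers.shape[0], geometry.n_frames))
    d = geometry.frame_grid[None, None, :] - centers[:, :, None]
    g = np.exp(-(d**2) / (2.0 * sigma**2))
    g /= g.max(axis=2, keepdims=True)
    return 1.0 - np.prod(1.0 - g, axis=1)


def spatial_profile(
    centers: Sequence[Sequence[float]], sigma: float, geometry: StimulusGeometry
) -> np.ndarray:
    """Combined spatial profile for one trial (vectorized over bubbles)."""
    if sigma <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma}")
    if len(centers) == 0:
        return np.zeros(geometry.spatial_shape)
    c = np.asarray(centers, dtype=float)  # (B, 2) as (x, y)
    x = np.arange(geometry.width, dtype=float)
    y = np.arange(geometry.height, dtype=float)
    d2 = (x[None, None, :] - c[:, 0, None, None]) ** 2 + (
        y[None, :, None] - c[:, 1, None, None]
    ) ** 2
    g = np.exp(-d2 / (2.0 * sigma**2))
    g /= g.max(axis=(1, 2), keepdims=True)
    return 1.0 - np.prod(1.0 - g, axis=0)


def make_profile(spec: BubbleSpec, geometry: StimulusGeometry) -> np.ndarray:
    """Combined reveal profile for one trial's :class:`BubbleSpec`."""
    if spec.n_bubbles == 0:
        raise ValueError(
            "BubbleSpec has no centers; use combine_bubbles([], shape=...) "
            "for an explicit empty profile"
        )
    if spec.is_spatial:
        return spatial_profile(spec.centers, spec.sigma, geometry)
    return temporal_profiles(
        np.asarray(spec.centers, dtype=float)[None, :], spec.sigma, geometry
    )[0]


def apply_mask(
    frame: np.ndarray,
    mask: np.ndarray,
    mean_intensity: float | None = None,
    as_uint8: bool = False,
) -> np.ndarray:
    """Apply a reveal profile to a grayscale frame.

    ``out = mean + (frame - mean) * mask``: each pixel is displayed at its
    original Weber contrast multiplied by the mask value. ``mean_intensity``
    defaults to the frame's own mean gray level. Computation is real-valued;
    pass ``as_uint8`` to clip and quantize to 8-bit storage at export.
    """
    frame = np.asarray(frame, dtype=float)
    mask = np.asarray(mask, dtype=float)
    if frame.shape != mask.shape:
        raise ValueError(f"frame shape {frame.shape} != mask shape {mask.shape}")
    if mean_intensity is None:
        mean_intensity = float(frame.mean())
    out = mean_intensity + (frame - mean_intensity) * mask
    if as_uint8:
        out = np.clip(np.rint(out), 0, 255).astype(np.uint8)
    return out


def frame_to_time(k, geometry: StimulusGeometry):
    """Seconds before racket-ball contact of frame ``k`` (1-based).

    ``(contact_frame - k) / frame_rate``; with the default geometry frame 86
    maps to 10/120 ~= 0.083 s before contact. Accepts scalars or arrays.
    """
    k = np.asarray(k)
    if np.any(k < 1) or np.any(k > geometry.contact_frame):
        raise ValueError(
            f"frame index must be in [1, {geometry.contact_frame}]"
        )
    t = (geometry.contact_frame - k) / geometry.frame_rate
    return float(t) if t.ndim == 0 else t
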