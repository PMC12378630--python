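"""Core image containers for dynamic 2D thoracic series.

An :class:`ImageSeries` is the universal carrier of the pipeline: a time-ordered
stack of 2D grayscale frames plus the physical metadata (isotropic pixel spacing
and frame interval) needed to convert pixel measurements into millimetres and
frame indices into seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np


class Plane(str, Enum):
    """Imaging plane of a dynamic series."""

    CORONAL = "coronal"
    SAGITTAL_RIGHT = "sagittal_right"
    SAGITTAL_LEFT = "sagittal_left"


class Direction(str, Enum):
    """Measurement direction of a thoracic expansion value."""

    RIGHT_HF = "right_HF"
    LEFT_HF = "left_HF"
    BILATERAL_RL = "bilateral_RL"
    RIGHT_AP = "right_AP"
    LEFT_AP = "left_AP"


@dataclass
class ImageSeries:
    """Time-ordered stack of 2D grayscale frames.

    Parameters
    ----------
    frames
        Array indexed ``(t, y, x)`` of nonnegative intensities. ``y`` increases
        footward on coronal images, so the diaphragm's *lowest* position is its
        *maximal* row index.
    pixel_spacing_mm
        Isotropic in-plane pixel size in mm/px.
    frame_interval_s
        Time between consecutive frames in seconds.
    plane
        Anatomical plane of the series.
    """

    frames: np.ndarray
    pixel_spacing_mm: float
    frame_interval_s: float
    plane: Plane = Plane.CORONAL

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.plane = Plane(self.plane)
        if self.frames.ndim != 3:
            raise ValueError(f"frames must be (t, y, x), got ndim={self.frames.ndim}")
        if self.pixel_spacing_mm <= 0:
            raise ValueError("pixel_spacing_mm must be positive")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        """Spatial shape (rows, columns) of one frame."""
        return self.frames.shape[1:]

    @property
    def fov_mm(self) -> float:
        """Physical extent of one frame edge (square frames assumed)."""
        return self.frames.shape[1] * self.pixel_spacing_mm

    def with_frames(self, frames: np.ndarray, pixel_spacing_mm: float | None = None) -> "ImageSeries":
        """Copy of the series with new frame data (and optionally new spacing)."""
        out = replace(self, frames=frames)
        if pixel_spacing_mm is not None:
            out.pixel_spacing_mm = pixel_spacing_mm
        return out


@dataclass
class ContourStack:
    """Per-frame binary, single-pixel-wide thoracic contours.

    Shares spatial/temporal metadata with the source :class:`ImageSeries`.
    The thinness contract is that no 2x2 pixel block is entirely foreground.
    """

    frames: np.ndarray
    pixel_spacing_mm: float
    frame_interval_s: float
    plane: Plane = Plane.CORONAL

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=bool)
        self.plane = Plane(self.plane)
        if self.frames.ndim != 3:
            raise ValueError("contour frames must be (t, y, x)")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class OverlaySeries:
    """Denoised grayscale frames with the contours painted in colour.

    ``frames`` is indexed ``(t, y, x, 3)``; off-contour pixels carry the
    denoised gray value replicated across the three channels.
    """

    frames: np.ndarray
    pixel_spacing_mm: float
    frame_interval_s: float
    plane: Plane = Plane.CORONAL
    contour_color: tuple[float, float, float] = field(default=(0.0, 1.0, 0.0))

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("overlay frames must be (t, y, x, 3)")
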