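"""Thoracic dimension and expansion measurement on 1D kymograms.

At the detected end-inspiratory and end-expiratory time points, the
thoracic dimension along a kymogram's spatial axis is the distance between
two lung contours: upper-to-lower lung contour for head-foot, outermost
right-to-left lung contours for the bilateral right-left direction, and
anterior-to-posterior lung contour for sagittal planes.  Measurements are
strictly orthogonal to the time axis and reported in mm using the
kymogram's (post-interpolation) spatial spacing.

Expansion is defined as the end-inspiratory minus the end-expiratory
dimension; negative values are reported, not clamped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .kymogram import Kymogram1D, RespiratoryPhases, _contour_crossings
from .series import Direction

logger = logging.getLogger(__name__)


class BoundarySpec(str, Enum):
    """Which contour pair delimits the dimension."""

    LUNG = "lung"            # single lung region (H-F and A-P directions)
    BILATERAL = "bilateral"  # outermost contours across both lungs (R-L)


class Position(str, Enum):
    SUPINE = "supine"
    SEMI_PRONE = "semi_prone"


@dataclass
class DimensionMeasurement:
    """One direction's end-phase dimensions and their difference.

    ``expansion_mm`` always equals ``end_insp_mm - end_exp_mm``.
    """

    direction: Direction
    position: Position
    end_insp_mm: float
    end_exp_mm: float
    t_end_insp: int
    t_end_exp: int
    axis_coordinate: int | None = None
    expansion_mm: float = field(init=False)

    def __post_init__(self) -> None:
        self.direction = Direction(self.direction)
        self.position = Position(self.position)
        if self.end_insp_mm <= 0 or self.end_exp_mm <= 0:
            raise ValueError("end-phase dimensions must be positive")
        self.expansion_mm = self.end_insp_mm - self.end_exp_mm
        if self.expansion_mm < 0:
            logger.info(
                "negative expansion %.2f mm for %s", self.expansion_mm, self.direction.value
            )


def _split_heterogeneous(
    span: tuple[float, float], col: np.ndarray, contrast: float, min_len_px: float
) -> list[tuple[float, float]]:
    """Recursively split a segment at strong internal intensity steps.

    A contour can locally drop out on a noisy frame, merging two tissues
    (e.g. lung and liver) into one inter-crossing segment.  If the two
    halves around the strongest internal gradient differ by more than 30%
    of the column's global contrast, the segment is split at that step.
    """
    from scipy.ndimage import median_filter

    lo, hi = span
    a, b = int(np.ceil(lo + 1)), int(np.floor(hi - 1))
    prof = col[a:b + 1]
    # ignore a margin at both ends: the bounding crossings' own intensity
    # ramps extend a few pixels into the segment
    margin = max(int(min_len_px), 5)
    if len(prof) <= 2 * margin + 1:
        return [span]
    sm = median_filter(prof, size=5, mode="nearest")
    grad = np.abs(np.gradient(sm))
    cut_i = margin + int(np.argmax(grad[margin:len(prof) - margin]))
    upper = float(np.mean(sm[:cut_i]))
    lower = float(np.mean(sm[cut_i:]))
    if abs(upper - lower) <= 0.3 * contrast:
        return [span]
    boundary = a + cut_i - 0.5
    logger.info("segment (%.1f, %.1f) split at internal step %.1f", lo, hi, boundary)
    return (_split_heterogeneous((lo, boundary), col, contrast, min_len_px)
            + _split_heterogeneous((boundary, hi), col, contrast, min_len_px))


def _lung_segments(kymo: Kymogram1D, t: int, min_len_px: float = 3.0) -> list[tuple[float, float]]:
    """Low-intensity (lung) segments between contour crossings at time ``t``.

    Crossings partition the spatial line; segments outside the outermost
    crossings are background and ignored.  Segments hiding a strong
    internal intensity step (a locally missing contour) are split at the
    step first.  Interior segments are then classified as lung when their
    mean denoised intensity lies below the midpoint of the darkest and
    brightest interior segment means.
    """
    crossings = _contour_crossings(kymo.contour_values[:, t])
    if len(crossings) < 2:
        raise ValueError(
            f"fewer than two contour crossings at t={t} "
            f"(axis {kymo.axis_kind.value} @ {kymo.fixed_coordinate})"
        )
    col = kymo.values[:, t]
    contrast = float(np.percentile(col, 95) - np.percentile(col, 5))
    spans = []
    for lo, hi in zip(crossings[:-1], crossings[1:]):
        if hi - lo < min_len_px:
            continue
        spans.extend(_split_heterogeneous((lo, hi), col, contrast, min_len_px))
    segments = []
    for lo, hi in spans:
        a, b = int(np.ceil(lo + 1)), int(np.floor(hi - 1))
        if b <= a:
            continue
        segments.append(((lo, hi), float(np.mean(col[a:b + 1]))))
    if not segments:
        raise ValueError(f"no interior segment between crossings at t={t}")
    if len(segments) == 1:
        return [segments[0][0]]  # unambiguous: the only enclosed region
    means = [m for _, m in segments]
    cut = (min(means) + max(means)) / 2
    lungs = [span for span, m in segments if m < cut]
    if not lungs:
        raise ValueError(f"no lung-intensity segment found at t={t}")
    return lungs


def measure_span(kymo: Kymogram1D, t: int, boundary_spec: BoundarySpec) -> float:
    """Distance (mm) between the specified lung contours at time ``t``.

    For :attr:`BoundarySpec.LUNG` the single lung region's bounding contours
    are used (the outermost qualifying pair if noise splits the region, with
    a logged note); for :attr:`BoundarySpec.BILATERAL` the outermost
    contours across both lung regions.
    """
    if not 0 <= t < kymo.n_times:
        raise IndexError(f"time index {t} out of range")
    lungs = _lung_segments(kymo, t)
    spec = BoundarySpec(boundary_spec)
    if spec is BoundarySpec.LUNG and len(lungs) > 1:
        logger.info(
            "%d lung segments at t=%d on %s kymogram @ %d; using outermost pair",
            len(lungs), t, kymo.axis_kind.value, kymo.fixed_coordinate,
        )
    lo = min(s[0] for s in lungs)
    hi = max(s[1] for s in lungs)
    return float((hi - lo) * kymo.spatial_spacing_mm)


def compute_expansion(
    kymo: Kymogram1D,
    phases: RespiratoryPhases,
    direction: Direction,
    position: Position = Position.SUPINE,
    boundary_spec: BoundarySpec | None = None,
) -> DimensionMeasurement:
    """Measure end-phase dimensions at the detected time points.

    The phases must come from the companion y-t kymogram of the same series;
    x-t measurements reuse those time points.
    """
    direction = Direction(direction)
    if boundary_spec is None:
        boundary_spec = (
            BoundarySpec.BILATERAL if direction is Direction.BILATERAL_RL else BoundarySpec.LUNG
        )
    return DimensionMeasurement(
        direction=direction,
        position=position,
        end_insp_mm=measure_span(kymo, phases.t_end_insp, boundary_spec),
        end_exp_mm=measure_span(kymo, phases.t_end_exp, boundary_spec),
        t_end_insp=phases.t_end_insp,
        t_end_exp=phases.t_end_exp,
        axis_coordinate=kymo.fixed_coordinate,
    )
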