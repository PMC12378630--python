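"""Space-time (kymogram) analysis of dynamic thoracic series.

A *1D kymogram* is one spatial row or column of the frame stack tracked
across all time points: a 2D array (space x time) on which respiratory
motion appears as an oscillating boundary.  Only y-t kymograms show the
diaphragm, so end-inspiratory / end-expiratory time points are detected on
a diaphragm trace extracted from a y-t kymogram and then reused for the
orthogonal (x-t) measurements.

The manual steps of the original workflow — visual exclusion of clearly
inconsistent breathing cycles and visual identification of the extreme
phases — are replaced here by deterministic, configurable rules: a
median/MAD outlier criterion on per-cycle amplitude and duration, and a
noise-tolerant global-extremum search (earliest cluster of times within a
small tolerance of the extremum, local argmax inside it).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
from scipy.signal import find_peaks

from .series import ContourStack, ImageSeries, Plane


class AxisKind(str, Enum):
    X_T = "x_t"
    Y_T = "y_t"


@dataclass
class Kymogram1D:
    """One spatial line tracked across all time points.

    ``values[s, t]`` is the denoised intensity at spatial index ``s`` and
    frame ``t``; ``contour_values`` is the matching binary line from the
    contour stack.
    """

    values: np.ndarray
    contour_values: np.ndarray
    axis_kind: AxisKind
    fixed_coordinate: int
    spatial_spacing_mm: float
    time_spacing_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.contour_values = np.asarray(self.contour_values, dtype=bool)
        if self.values.shape != self.contour_values.shape:
            raise ValueError("values and contour_values must share a shape")

    @property
    def n_times(self) -> int:
        return self.values.shape[1]

    @property
    def n_space(self) -> int:
        return self.values.shape[0]


def extract_yt(denoised: ImageSeries, contours: ContourStack, x_column: int) -> Kymogram1D:
    """Extract the y-t kymogram at a fixed image column."""
    if not 0 <= x_column < denoised.shape[1]:
        raise IndexError(f"x_column {x_column} outside [0, {denoised.shape[1]})")
    return Kymogram1D(
        values=denoised.frames[:, :, x_column].T,
        contour_values=contours.frames[:, :, x_column].T,
        axis_kind=AxisKind.Y_T,
        fixed_coordinate=x_column,
        spatial_spacing_mm=denoised.pixel_spacing_mm,
        time_spacing_s=denoised.frame_interval_s,
    )


def extract_xt(denoised: ImageSeries, contours: ContourStack, y_row: int) -> Kymogram1D:
    """Extract the x-t kymogram at a fixed image row."""
    if not 0 <= y_row < denoised.shape[0]:
        raise IndexError(f"y_row {y_row} outside [0, {denoised.shape[0]})")
    return Kymogram1D(
        values=denoised.frames[:, y_row, :].T,
        contour_values=contours.frames[:, y_row, :].T,
        axis_kind=AxisKind.X_T,
        fixed_coordinate=y_row,
        spatial_spacing_mm=denoised.pixel_spacing_mm,
        time_spacing_s=denoised.frame_interval_s,
    )


# ---------------------------------------------------------------------------
# Landmarks and measurement-axis placement
# ---------------------------------------------------------------------------

#: landmark names required to place the measurement axes of each plane
REQUIRED_LANDMARKS = {
    Plane.CORONAL: (
        "right_dome_end_1",
        "right_dome_end_2",
        "left_dome_end_1",
        "left_dome_end_2",
        "right_diaphragm_lateral_inferior_edge",
        "right_thorax_uppermost",
    ),
    Plane.SAGITTAL_RIGHT: (
        "dome_end_1",
        "dome_end_2",
        "diaphragm_dorsalmost_inferior_edge",
        "thoracic_cavity_uppermost",
    ),
    Plane.SAGITTAL_LEFT: (
        "dome_end_1",
        "dome_end_2",
        "diaphragm_dorsalmost_inferior_edge",
        "thoracic_cavity_uppermost",
    ),
}


@dataclass
class Landmarks:
    """Named anatomical points ``(x, y)`` in pixels on a reference frame."""

    points: dict[str, tuple[float, float]]
    frame_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.frame_shape is not None:
            h, w = self.frame_shape
            for name, (x, y) in self.points.items():
                if not (0 <= x < w and 0 <= y < h):
                    raise ValueError(f"landmark {name!r} at ({x}, {y}) outside frame {self.frame_shape}")

    def __getitem__(self, name: str) -> tuple[float, float]:
        try:
            return self.points[name]
        except KeyError:
            raise KeyError(f"missing landmark {name!r}") from None

    def scaled(self, factor: float) -> "Landmarks":
        """Landmarks mapped onto a grid resampled by ``factor``.

        Pixel-centre convention: index i maps to factor*(i + 1/2) - 1/2.
        """
        pts = {
            k: (factor * (x + 0.5) - 0.5, factor * (y + 0.5) - 0.5)
            for k, (x, y) in self.points.items()
        }
        shape = None
        if self.frame_shape is not None:
            shape = tuple(int(round(s * factor)) for s in self.frame_shape)
        return Landmarks(points=pts, frame_shape=shape)


@dataclass
class MeasurementAxes:
    """Rows/columns (px) at which the 1D measurement kymograms are extracted."""

    hf_right_column: int | None = None
    hf_left_column: int | None = None
    rl_row: int | None = None
    ap_row: int | None = None


def _midpoint(u: float, v: float) -> int:
    """Midpoint of two coordinates, rounded half-up to an integer index."""
    return int(np.floor((u + v) / 2 + 0.5))


def place_axes(landmarks: Landmarks, plane: Plane) -> MeasurementAxes:
    """Place measurement axes at midpoints of paired anatomical landmarks.

    Head-foot columns pass through the midpoint of each hemidiaphragm dome's
    endpoints; the right-left row lies midway between the lateral inferior
    diaphragm edge and the uppermost thorax point; the anterior-posterior row
    midway between the dorsalmost inferior diaphragm edge and the uppermost
    point of the thoracic cavity.
    """
    plane = Plane(plane)
    for name in REQUIRED_LANDMARKS[plane]:
        if name not in landmarks.points:
            raise KeyError(f"missing landmark {name!r} for plane {plane.value}")
    if plane is Plane.CORONAL:
        return MeasurementAxes(
            hf_right_column=_midpoint(
                landmarks["right_dome_end_1"][0], landmarks["right_dome_end_2"][0]
            ),
            hf_left_column=_midpoint(
                landmarks["left_dome_end_1"][0], landmarks["left_dome_end_2"][0]
            ),
            rl_row=_midpoint(
                landmarks["right_diaphragm_lateral_inferior_edge"][1],
                landmarks["right_thorax_uppermost"][1],
            ),
        )
    return MeasurementAxes(
        hf_right_column=None,
        hf_left_column=None,
        rl_row=None,
        ap_row=_midpoint(
            landmarks["diaphragm_dorsalmost_inferior_edge"][1],
            landmarks["thoracic_cavity_uppermost"][1],
        ),
    )


def sagittal_dome_column(landmarks: Landmarks) -> int:
    """Column of the hemidiaphragm dome midpoint on a sagittal plane."""
    return _midpoint(landmarks["dome_end_1"][0], landmarks["dome_end_2"][0])


# ---------------------------------------------------------------------------
# Diaphragm trace
# ---------------------------------------------------------------------------

@dataclass
class DiaphragmTrace:
    """Per-time diaphragm boundary row on a y-t kymogram.

    ``y_position`` allows sub-pixel values; ``valid_mask`` marks times where
    a contour crossing was found; ``excluded_intervals`` lists half-open
    ``(t_start, t_end)`` frame ranges removed from phase detection.
    """

    y_position: np.ndarray
    valid_mask: np.ndarray
    spatial_spacing_mm: float
    time_spacing_s: float
    excluded_intervals: list[tuple[int, int]] = field(default_factory=list)
    fallback_mask: np.ndarray | None = None  # times tracked from the gradient ridge

    @property
    def n_times(self) -> int:
        return len(self.y_position)

    def included_mask(self) -> np.ndarray:
        ok = self.valid_mask.copy()
        for t0, t1 in self.excluded_intervals:
            ok[t0:t1] = False
        return ok


def _contour_crossings(column: np.ndarray, merge_gap: int = 2) -> list[float]:
    """Cluster contour pixels along a spatial line into crossing positions."""
    idx = np.nonzero(column)[0]
    if len(idx) == 0:
        return []
    crossings = []
    start = prev = idx[0]
    total, count = float(idx[0]), 1
    for i in idx[1:]:
        if i - prev <= merge_gap:
            total += i
            count += 1
        else:
            crossings.append(total / count)
            total, count = float(i), 1
        prev = i
    crossings.append(total / count)
    return crossings


def extract_diaphragm_trace(
    yt: Kymogram1D,
    search_band: tuple[int, int],
    max_invalid_fraction: float = 0.2,
    gradient_fallback: bool = True,
    fallback_window_px: float = 15.0,
) -> DiaphragmTrace:
    """Track the diaphragm contour through a y-t kymogram.

    Within ``search_band`` (inclusive pixel rows), the diaphragm at each time
    is the contour crossing nearest the previous time's position; at the
    first valid time it is the crossing with the strongest spatial intensity
    gradient.  Positions are refined to sub-pixel precision by the centroid
    of gradient magnitude in a +/-2 px window.

    On high-noise frames the binarised contour can locally drop out.  With
    ``gradient_fallback`` (default), such times are bridged by the strongest
    intensity-gradient ridge within ``fallback_window_px`` of the previous
    position; these times are recorded in ``fallback_mask``.  Times with
    neither contour nor ridge stay invalid, and a trace with more than
    ``max_invalid_fraction`` invalid times is rejected.
    """
    lo, hi = int(search_band[0]), int(search_band[1])
    if not (0 <= lo < hi < yt.n_space):
        raise ValueError(f"search band {search_band} outside spatial bounds")
    n = yt.n_times
    pos = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    fallback = np.zeros(n, dtype=bool)
    grad = np.abs(np.gradient(yt.values, axis=0))
    prev: float | None = None
    for t in range(n):
        crossings = [c for c in _contour_crossings(yt.contour_values[:, t]) if lo <= c <= hi]
        if crossings:
            if prev is None:
                strengths = [grad[int(round(c)), t] for c in crossings]
                c = crossings[int(np.argmax(strengths))]
            else:
                c = min(crossings, key=lambda x: abs(x - prev))
        elif gradient_fallback and prev is not None:
            w_lo = max(lo, int(np.floor(prev - fallback_window_px)))
            w_hi = min(hi, int(np.ceil(prev + fallback_window_px)))
            window = grad[w_lo:w_hi + 1, t]
            if window.size == 0 or window.max() <= 0:
                continue
            c = float(w_lo + np.argmax(window))
            fallback[t] = True
        else:
            continue
        pos[t] = _subpixel_refine(grad[:, t], c)
        valid[t] = True
        prev = pos[t]
    if not valid.any():
        raise ValueError("no contour crossings found in the search band")
    invalid_frac = 1.0 - valid.mean()
    if invalid_frac > max_invalid_fraction:
        raise ValueError(
            f"diaphragm trace unusable: {invalid_frac:.0%} of times have no "
            "contour crossing in the search band"
        )
    return DiaphragmTrace(
        y_position=pos,
        valid_mask=valid,
        spatial_spacing_mm=yt.spatial_spacing_mm,
        time_spacing_s=yt.time_spacing_s,
        fallback_mask=fallback,
    )


def _subpixel_refine(grad_col: np.ndarray, center: float, half_window: int = 2) -> float:
    c = int(round(center))
    lo = max(0, c - half_window)
    hi = min(len(grad_col), c + half_window + 1)
    w = grad_col[lo:hi]
    if w.sum() <= 0:
        return float(center)
    return float(np.average(np.arange(lo, hi), weights=w))


# ---------------------------------------------------------------------------
# Cycle segmentation and exclusion
# ---------------------------------------------------------------------------

@dataclass
class Cycle:
    t_start: int
    t_end: int  # half-open
    amplitude_px: float
    duration_frames: int


def segment_cycles(trace: DiaphragmTrace) -> list[Cycle]:
    """Split the trace into breathing cycles (trough-to-trough).

    Troughs are minima of diaphragm descent (end-expiratory positions),
    found with a prominence of 30% of the trace range.
    """
    y = trace.y_position.copy()
    ok = trace.valid_mask
    if ok.sum() < 4:
        return []
    if (~ok).any():
        y[~ok] = np.interp(np.nonzero(~ok)[0], np.nonzero(ok)[0], y[ok])
    rng = float(np.nanmax(y) - np.nanmin(y))
    if rng <= 0:
        return []
    troughs, _ = find_peaks(-y, prominence=0.3 * rng)
    bounds = [0, *troughs.tolist(), len(y)]
    cycles = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if t1 - t0 < 2:
            continue
        seg = y[t0:t1]
        cycles.append(
            Cycle(
                t_start=int(t0),
                t_end=int(t1),
                amplitude_px=float(np.max(seg) - np.min(seg)),
                duration_frames=int(t1 - t0),
            )
        )
    return cycles


def flag_inconsistent_cycles(
    trace: DiaphragmTrace,
    k: float = 3.0,
    mad_floor_amplitude_px: float = 0.7,
    mad_floor_duration_frames: float = 0.5,
) -> DiaphragmTrace:
    """Exclude breathing cycles whose amplitude or duration is an outlier.

    A cycle is flagged when its amplitude or duration deviates from the
    median cycle by more than ``k * max(MAD, floor)``.  The MAD floors keep
    perfectly regular series (MAD = 0) from being flagged wholesale while
    preserving ``k`` as the single sensitivity dial.  Needs at least three
    detectable cycles; otherwise a warning is issued and nothing is
    excluded.
    """
    cycles = segment_cycles(trace)
    if len(cycles) < 3:
        warnings.warn(f"only {len(cycles)} cycles detected; no exclusion performed")
        return trace
    durs = np.array([c.duration_frames for c in cycles], dtype=float)
    # The trailing segment may be an incomplete cycle; leave it out of the
    # statistics and never flag it on amplitude alone.
    med_d0 = np.median(durs[:-1]) if len(durs) > 1 else durs[0]
    partial_tail = durs[-1] < 0.7 * med_d0
    full = cycles[:-1] if partial_tail else cycles
    amps = np.array([c.amplitude_px for c in full])
    fdur = np.array([c.duration_frames for c in full], dtype=float)
    med_a, mad_a = np.median(amps), np.median(np.abs(amps - np.median(amps)))
    med_d, mad_d = np.median(fdur), np.median(np.abs(fdur - np.median(fdur)))
    thr_a = k * max(mad_a, mad_floor_amplitude_px)
    thr_d = k * max(mad_d, mad_floor_duration_frames)
    excluded = list(trace.excluded_intervals)
    for i, c in enumerate(full):
        bad_amp = abs(c.amplitude_px - med_a) > thr_a
        bad_dur = i < len(full) - 1 and abs(c.duration_frames - med_d) > thr_d
        if bad_amp or bad_dur:
            excluded.append((c.t_start, c.t_end))
    return DiaphragmTrace(
        y_position=trace.y_position,
        valid_mask=trace.valid_mask,
        spatial_spacing_mm=trace.spatial_spacing_mm,
        time_spacing_s=trace.time_spacing_s,
        excluded_intervals=sorted(set(excluded)),
        fallback_mask=trace.fallback_mask,
    )


# ---------------------------------------------------------------------------
# Extreme-phase detection
# ---------------------------------------------------------------------------

@dataclass
class RespiratoryPhases:
    """Global end-inspiratory and end-expiratory frame indices."""

    t_end_insp: int
    t_end_exp: int

    def __post_init__(self) -> None:
        if self.t_end_insp == self.t_end_exp:
            raise ValueError("end-inspiration and end-expiration coincide")


def _earliest_extremum(
    y: np.ndarray, y_robust: np.ndarray, ok: np.ndarray, tol: float, sign: int
) -> int:
    """Earliest near-extremal cluster, local argmax inside it.

    ``sign=+1`` finds the maximum (deepest diaphragm descent), ``sign=-1``
    the minimum.  A time is a candidate when it lies within ``tol`` of the
    global extremum of any of three views of the trace: the raw values, a
    temporal 3-frame median, or a temporal 3-frame minimum (of ``sign*y``).
    The median bar discounts outliers sitting on a peak (which inflate the
    raw maximum), the raw bar discounts outliers next to a peak (which
    inflate the median), and the minimum bar is immune to any single-frame
    outlier because three consecutive frames must all be extremal.
    Candidates form runs broken by >2 frame gaps; the earliest run is
    selected and the exact frame is the raw-trace extremum inside it.
    With ``tol = 0`` this reduces to "argmax, ties broken by earliest".
    """
    from scipy.ndimage import minimum_filter

    v_raw = sign * y
    v_med = sign * y_robust
    v_min = minimum_filter(v_raw, size=3, mode="nearest")
    idx = np.nonzero(ok)[0]
    qualifies = np.zeros(len(idx), dtype=bool)
    for v in (v_raw, v_med, v_min):
        qualifies |= v[idx] >= np.max(v[idx]) - tol
    cand = idx[qualifies]
    cluster = [cand[0]]
    for t in cand[1:]:
        if t - cluster[-1] <= 2:
            cluster.append(t)
        else:
            break
    cluster = np.asarray(cluster)
    return int(cluster[np.argmax(sign * y[cluster])])


def detect_extreme_phases(trace: DiaphragmTrace, tol_mm: float = 2.0) -> RespiratoryPhases:
    """Detect the global end-inspiratory and end-expiratory time points.

    End-inspiration is the time of deepest diaphragm descent (maximal row),
    end-expiration the time of highest position, over all included times of
    the whole acquisition — regardless of whether they fall in the same
    breathing cycle.  ``tol_mm`` makes the choice noise-tolerant: among all
    times within this tolerance of the extremum, the earliest cycle wins and
    the local extremum inside it is returned.
    """
    ok = trace.included_mask()
    if not ok.any():
        raise ValueError("all times excluded or invalid; no phases detectable")
    y = trace.y_position
    # robust trace for cluster finding: invalid times interpolated, then a
    # 3-frame temporal median to suppress single-frame readout outliers
    y_filled = y.copy()
    valid = trace.valid_mask
    if (~valid).any() and valid.any():
        y_filled[~valid] = np.interp(
            np.nonzero(~valid)[0], np.nonzero(valid)[0], y[valid]
        )
    from scipy.ndimage import median_filter

    y_med = median_filter(y_filled, size=3, mode="nearest")
    tol_px = tol_mm / trace.spatial_spacing_mm
    t_ei = _earliest_extremum(y_filled, y_med, ok, tol_px, sign=+1)
    t_ee = _earliest_extremum(y_filled, y_med, ok, tol_px, sign=-1)
    vals = y[ok]
    if np.all(np.diff(vals) >= 0) or np.all(np.diff(vals) <= 0):
        warnings.warn("monotone diaphragm trace: no full breathing cycle observed")
    if t_ei == t_ee:
        # flat trace: keep the record well formed with distinct time points
        others = np.nonzero(ok)[0]
        others = others[others != t_ei]
        if len(others) == 0:
            raise ValueError("only one included time point; no phases detectable")
        warnings.warn("flat diaphragm trace: end phases assigned to distinct times arbitrarily")
        t_ee = int(others[0])
    return RespiratoryPhases(t_end_insp=t_ei, t_end_exp=t_ee)
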