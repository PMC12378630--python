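"""Session-level orchestration: from image stacks to the five expansion values.

A *session* is one participant in one position: a coronal series (right and
left head-foot plus bilateral right-left measurements) and two sagittal
series (one anterior-posterior measurement each).  Respiratory phases are
detected independently per plane on that plane's own y-t diaphragm
kymogram; the orthogonal x-t measurements reuse those time points.

For phantom sessions the anatomical landmarks and diaphragm search band —
manual inputs in the original workflow — are derived from the phantom's
closed-form geometry.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as mio
from .kymogram import (
    DiaphragmTrace,
    Landmarks,
    MeasurementAxes,
    RespiratoryPhases,
    detect_extreme_phases,
    extract_diaphragm_trace,
    extract_xt,
    extract_yt,
    flag_inconsistent_cycles,
    place_axes,
    sagittal_dome_column,
)
from .measurement import DimensionMeasurement, Position, compute_expansion
from .phantom import (
    GroundTruth,
    PhantomConfig,
    generate_phantom_series,
    geometry,
    mm_to_px,
)
from .preprocess import PreprocessResult, preprocess_pipeline
from .series import Direction, ImageSeries, Plane

logger = logging.getLogger(__name__)

_DOME_END_FRAC = 0.8   # dome endpoints at +/- this fraction of the lung half-width
_EDGE_FRAC = 0.95      # lateral/dorsal inferior diaphragm edge position


def phantom_landmarks(config: PhantomConfig) -> Landmarks:
    """Analytic landmarks (raw-grid px) on the end-expiratory reference frame."""
    g = geometry(config)

    def pt(x_mm: float, y_mm: float) -> tuple[float, float]:
        return (mm_to_px(config, x_mm), mm_to_px(config, y_mm))

    dome_y = g.d0 + g.droop * _DOME_END_FRAC**2
    edge_y = g.d0 + g.droop * _EDGE_FRAC**2
    if config.plane is Plane.CORONAL:
        points = {
            "right_dome_end_1": pt(-g.lung_cx - _DOME_END_FRAC * g.lung_w, dome_y),
            "right_dome_end_2": pt(-g.lung_cx + _DOME_END_FRAC * g.lung_w, dome_y),
            "left_dome_end_1": pt(g.lung_cx - _DOME_END_FRAC * g.lung_w, dome_y),
            "left_dome_end_2": pt(g.lung_cx + _DOME_END_FRAC * g.lung_w, dome_y),
            "right_diaphragm_lateral_inferior_edge": pt(
                -g.lung_cx - _EDGE_FRAC * g.lung_w, edge_y
            ),
            "right_thorax_uppermost": pt(-g.lung_cx, g.y_apex),
        }
    else:
        points = {
            "dome_end_1": pt(-_DOME_END_FRAC * g.sag_lung_w, dome_y),
            "dome_end_2": pt(_DOME_END_FRAC * g.sag_lung_w, dome_y),
            "diaphragm_dorsalmost_inferior_edge": pt(-_EDGE_FRAC * g.sag_lung_w, edge_y),
            "thoracic_cavity_uppermost": pt(0.0, g.y_apex),
        }
    shape = (config.matrix_size, config.matrix_size)
    return Landmarks(points=points, frame_shape=shape)


def phantom_search_band(config: PhantomConfig, max_scale: float = 1.0) -> tuple[int, int]:
    """Raw-grid pixel band bracketing the traced hemidiaphragm's motion."""
    g = geometry(config)
    side = "left" if config.plane is Plane.SAGITTAL_LEFT else "right"
    amp = getattr(config, f"amplitude_hf_{side}_mm")
    lo = mm_to_px(config, g.d0 - 15.0)
    hi = mm_to_px(config, g.d0 + amp * max_scale + g.droop + 10.0)
    return (int(np.floor(lo)), int(np.ceil(hi)))


@dataclass
class PlaneAnalysis:
    """Everything derived from one plane of a session."""

    plane: Plane
    preprocessed: PreprocessResult
    axes: MeasurementAxes
    trace: DiaphragmTrace
    phases: RespiratoryPhases
    measurements: dict[Direction, DimensionMeasurement]
    trace_column: int


def analyze_plane(
    series: ImageSeries,
    landmarks: Landmarks,
    search_band: tuple[int, int],
    position: Position = Position.SUPINE,
    target_size: int = 512,
    mad_k: float = 3.0,
    exclude_cycles: bool = True,
    phase_tol_mm: float = 2.0,
    prune_len: int = 5,
) -> PlaneAnalysis:
    """Preprocess one plane, detect phases, and measure its directions.

    ``landmarks`` and ``search_band`` are given on the raw pixel grid of
    ``series``; both are mapped onto the upsampled grid internally.
    """
    pre = preprocess_pipeline(series, target_size=target_size, prune_len=prune_len,
                              with_overlay=False)
    factor = target_size / series.shape[0]
    lm = landmarks.scaled(factor)
    band = (
        max(0, int(np.floor(factor * (search_band[0] + 0.5) - 0.5))),
        min(target_size - 1, int(np.ceil(factor * (search_band[1] + 0.5) - 0.5))),
    )
    axes = place_axes(lm, series.plane)
    if series.plane is Plane.CORONAL:
        trace_col = axes.hf_right_column
    else:
        trace_col = sagittal_dome_column(lm)
    yt_trace = extract_yt(pre.denoised, pre.contours, trace_col)
    trace = extract_diaphragm_trace(yt_trace, band)
    if exclude_cycles:
        trace = flag_inconsistent_cycles(trace, k=mad_k)
    phases = detect_extreme_phases(trace, tol_mm=phase_tol_mm)

    measurements: dict[Direction, DimensionMeasurement] = {}
    if series.plane is Plane.CORONAL:
        yt_left = extract_yt(pre.denoised, pre.contours, axes.hf_left_column)
        xt_rl = extract_xt(pre.denoised, pre.contours, axes.rl_row)
        measurements[Direction.RIGHT_HF] = compute_expansion(
            yt_trace, phases, Direction.RIGHT_HF, position
        )
        measurements[Direction.LEFT_HF] = compute_expansion(
            yt_left, phases, Direction.LEFT_HF, position
        )
        measurements[Direction.BILATERAL_RL] = compute_expansion(
            xt_rl, phases, Direction.BILATERAL_RL, position
        )
    else:
        direction = (
            Direction.RIGHT_AP if series.plane is Plane.SAGITTAL_RIGHT else Direction.LEFT_AP
        )
        xt_ap = extract_xt(pre.denoised, pre.contours, axes.ap_row)
        measurements[direction] = compute_expansion(xt_ap, phases, direction, position)
    return PlaneAnalysis(
        plane=series.plane,
        preprocessed=pre,
        axes=axes,
        trace=trace,
        phases=phases,
        measurements=measurements,
        trace_column=trace_col,
    )


@dataclass
class PhantomSession:
    """A full three-plane phantom session with its ground truth."""

    measurements: dict[Direction, DimensionMeasurement]
    truths: dict[Direction, float]
    analyses: dict[Plane, PlaneAnalysis]
    ground_truths: dict[Plane, GroundTruth]


def run_phantom_session(
    base_config: Optional[PhantomConfig] = None,
    seed: int = 0,
    position: Position = Position.SUPINE,
    target_size: int = 512,
    **config_overrides,
) -> PhantomSession:
    """Generate and analyse coronal + two sagittal phantom series.

    All three planes share the amplitude configuration of ``base_config``
    (with ``config_overrides`` applied); each plane gets an independent
    noise stream derived from ``seed``.
    """
    base = base_config or PhantomConfig()
    base = dataclasses.replace(base, **config_overrides)
    measurements: dict[Direction, DimensionMeasurement] = {}
    truths: dict[Direction, float] = {}
    analyses: dict[Plane, PlaneAnalysis] = {}
    gts: dict[Plane, GroundTruth] = {}
    for i, plane in enumerate((Plane.CORONAL, Plane.SAGITTAL_RIGHT, Plane.SAGITTAL_LEFT)):
        config = dataclasses.replace(base, plane=plane, seed=seed * 1013 + i)
        series, truth = generate_phantom_series(config)
        analysis = analyze_plane(
            series,
            phantom_landmarks(config),
            phantom_search_band(config),
            position=position,
            target_size=target_size,
        )
        measurements.update(analysis.measurements)
        truths.update({d: t.expansion_mm for d, t in truth.axes.items()})
        analyses[plane] = analysis
        gts[plane] = truth
    return PhantomSession(
        measurements=measurements, truths=truths, analyses=analyses, ground_truths=gts
    )


# ---------------------------------------------------------------------------
# File-based sessions
# ---------------------------------------------------------------------------

@dataclass
class SessionManifest:
    """Declarative description of one measurement session on disk."""

    participant: str
    position: Position
    session_index: int = 1
    stacks: dict[Plane, Path] = field(default_factory=dict)
    landmarks: dict[Plane, Path] = field(default_factory=dict)
    search_bands: dict[Plane, tuple[int, int]] = field(default_factory=dict)
    target_size: int = 512
    mad_k: float = 3.0
    phase_tol_mm: float = 2.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SessionManifest":
        import yaml

        raw = yaml.safe_load(Path(path).read_text())
        root = Path(path).parent
        stacks = {Plane(k): root / v for k, v in raw.get("stacks", {}).items()}
        landmarks = {Plane(k): root / v for k, v in raw.get("landmarks", {}).items()}
        bands = {Plane(k): tuple(v) for k, v in raw.get("search_bands", {}).items()}
        for name, paths in (("stack", stacks), ("landmarks", landmarks)):
            for plane, p in paths.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"{name} for {plane.value} not found: {p}")
        return cls(
            participant=str(raw["participant"]),
            position=Position(raw["position"]),
            session_index=int(raw.get("session_index", 1)),
            stacks=stacks,
            landmarks=landmarks,
            search_bands=bands,
            target_size=int(raw.get("target_size", 512)),
            mad_k=float(raw.get("mad_k", 3.0)),
            phase_tol_mm=float(raw.get("phase_tol_mm", 2.0)),
        )


_PLANE_DIRECTIONS = {
    Plane.CORONAL: (Direction.RIGHT_HF, Direction.LEFT_HF, Direction.BILATERAL_RL),
    Plane.SAGITTAL_RIGHT: (Direction.RIGHT_AP,),
    Plane.SAGITTAL_LEFT: (Direction.LEFT_AP,),
}


def run_session(manifest: SessionManifest, out_dir: str | Path | None = None) -> pd.DataFrame:
    """Run the full pipeline for every plane in the manifest.

    Produces one row per measurement direction; directions whose plane is
    missing from the manifest appear as explicit gap rows (NaN values).
    Writes ``results.csv`` and per-plane threshold logs when ``out_dir`` is
    given.  Reruns on identical inputs are byte-identical.
    """
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    all_measurements: list[DimensionMeasurement] = []
    gap_rows = []
    for plane, directions in _PLANE_DIRECTIONS.items():
        if plane not in manifest.stacks:
            logger.warning("plane %s missing from manifest; emitting gap rows", plane.value)
            gap_rows.extend(
                {"direction": d.value, "position": manifest.position.value}
                for d in directions
            )
            continue
        series = mio.read_stack(manifest.stacks[plane], plane=plane)
        landmarks = mio.read_landmarks(manifest.landmarks[plane], frame_shape=series.shape)
        band = manifest.search_bands.get(plane)
        if band is None:
            raise ValueError(f"manifest missing search band for plane {plane.value}")
        try:
            analysis = analyze_plane(
                series,
                landmarks,
                band,
                position=manifest.position,
                target_size=manifest.target_size,
                mad_k=manifest.mad_k,
                phase_tol_mm=manifest.phase_tol_mm,
            )
        except Exception as exc:
            raise RuntimeError(
                f"analysis failed for plane {plane.value} "
                f"(stack {manifest.stacks[plane]}): {exc}"
            ) from exc
        for d in directions:
            logger.info(
                "measured participant=%s plane=%s direction=%s expansion_mm=%.3f "
                "t_end_insp=%d t_end_exp=%d",
                manifest.participant, plane.value, d.value,
                analysis.measurements[d].expansion_mm,
                analysis.phases.t_end_insp, analysis.phases.t_end_exp,
            )
        all_measurements.extend(analysis.measurements.values())
        if out_dir is not None:
            np.savetxt(
                out_dir / f"thresholds_{plane.value}.csv",
                analysis.preprocessed.thresholds,
                delimiter=",",
                header="binarization_threshold",
                comments="",
            )
    df = mio.measurements_to_frame(all_measurements)
    if gap_rows:
        df = pd.concat([df, pd.DataFrame(gap_rows)], ignore_index=True)
    df.insert(0, "participant", manifest.participant)
    df.insert(1, "session", manifest.session_index)
    if out_dir is not None:
        df.to_csv(out_dir / "results.csv", index=False)
    return df
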