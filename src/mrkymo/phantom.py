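"""Synthetic breathing-thorax phantom with analytic ground truth.

The phantom emulates the geometry of a dynamic 2D thoracic acquisition:
192x192 matrix over a 500x500 mm field of view, one frame every 0.6 s for
60 s of deep breathing.  Two low-intensity lungs sit inside an elliptical
soft-tissue thorax; the diaphragm is a dome-shaped arc bounding the lungs
below, with a liver-intensity region under the right hemidiaphragm.  The
breathing waveform is ``phi(t) = sin^2(pi t / T)``: smooth, non-negative,
with distinct end-inspiratory (phi = 1) and end-expiratory (phi = 0)
plateaus.  At phase ``phi`` each moving boundary is displaced by
``phi * amplitude`` along its axis: the diaphragm footward, the lateral
chest walls outward, the anterior wall forward.

Because every boundary has a closed form, the phantom carries its own
oracle: a :class:`GroundTruth` sidecar records the true expansion per
measurement axis and the frame indices at which the sampled phase is
extremal.  Frames are rendered with area-weighted anti-aliasing
(supersampling) so sub-pixel motion — e.g. a few mm of right-left wall
excursion at 2.6 mm raw pixels — is representable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .series import Direction, ImageSeries, Plane

# Fixed anatomical proportions (relative to the configured thorax semi-axes).
_BODY_CENTER_Y_MM = 10.0      # thorax ellipse centre, footward of image centre
_LUNG_HALFWIDTH_FRAC = 0.32   # coronal lung half-width / thorax half-width
_LUNG_CENTER_FRAC = 0.44      # coronal lung centre offset / thorax half-width
_LUNG_APEX_FRAC = 0.42        # lung apex above body centre / thorax half-height
_LUNG_HALFHEIGHT_FRAC = 0.50  # lung vertical semi-axis / thorax half-height
_DOME_DROOP_FRAC = 0.12       # diaphragm droop at lung edge / thorax half-height
_SAG_BODY_FRAC = 0.75         # sagittal thorax half-depth / coronal half-width
_SAG_LUNG_HALFWIDTH_FRAC = 0.37
_LIVER_PAD_MM = 10.0          # liver extends this far beyond the lung laterally
_X_EXPONENT = 8               # superellipse exponent: flat lateral lung walls


@dataclass
class PhantomConfig:
    """Configuration of one synthetic dynamic series.

    Amplitudes are the ground-truth expansions in mm: ``amplitude_hf_*`` is
    diaphragm excursion, ``amplitude_rl_mm`` the *total* bilateral width
    change (each lateral wall moves half of it), ``amplitude_ap_*`` the
    anterior wall excursion on the respective sagittal plane.  Defaults
    follow the observed supine magnitudes (H-F ~80-85, R-L ~4, A-P ~14 mm).
    """

    plane: Plane = Plane.CORONAL
    matrix_size: int = 192
    fov_mm: float = 500.0
    frame_interval_s: float = 0.6
    duration_s: float = 60.0
    breathing_period_s: float = 6.0
    amplitude_hf_right_mm: float = 84.0
    amplitude_hf_left_mm: float = 81.0
    amplitude_rl_mm: float = 4.0
    amplitude_ap_right_mm: float = 14.0
    amplitude_ap_left_mm: float = 14.0
    thorax_semiaxes_mm: tuple[float, float] = (170.0, 230.0)
    diaphragm_rest_y_mm: float = 40.0
    intensity_lung: float = 15.0
    intensity_tissue: float = 100.0
    intensity_liver: float = 70.0
    noise_sigma: float = 5.0
    seed: int = 0
    supersample: int = 4
    irregular_cycle: Optional[tuple[int, float]] = None

    # -- derived quantities -------------------------------------------------

    @property
    def n_frames(self) -> int:
        return int(np.floor(self.duration_s / self.frame_interval_s + 1e-9))

    @property
    def pixel_spacing_mm(self) -> float:
        return self.fov_mm / self.matrix_size

    @property
    def n_cycles(self) -> int:
        """Number of complete breathing cycles in the acquisition."""
        return int(np.floor(self.duration_s / self.breathing_period_s + 1e-9))

    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s

    def validate(self) -> None:
        a, b = self.thorax_semiaxes_mm
        if self.matrix_size < 32:
            raise ValueError("matrix_size must be >= 32")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        for name in (
            "amplitude_hf_right_mm",
            "amplitude_hf_left_mm",
            "amplitude_rl_mm",
            "amplitude_ap_right_mm",
            "amplitude_ap_left_mm",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (self.intensity_lung < self.intensity_liver < self.intensity_tissue):
            raise ValueError("intensities must satisfy lung < liver < tissue")
        if self.duration_s / self.breathing_period_s < 2:
            raise ValueError("duration_s must cover at least two breathing cycles")
        half = self.fov_mm / 2
        if a > half - 2 or abs(_BODY_CENTER_Y_MM) + b > half - 2:
            raise ValueError("thorax_semiaxes_mm exceed the image frame")
        g = geometry(self)
        # End-inspiratory geometry must stay strictly inside the frame/body.
        if self.plane is Plane.CORONAL:
            for name, amp in (
                ("amplitude_hf_right_mm", self.amplitude_hf_right_mm),
                ("amplitude_hf_left_mm", self.amplitude_hf_left_mm),
            ):
                if g.d0 + amp + g.droop > _BODY_CENTER_Y_MM + b - 10:
                    raise ValueError(
                        f"{name}={amp} drives the diaphragm outside the thorax"
                    )
            if g.lung_cx + g.lung_w + self.amplitude_rl_mm / 2 > a - 5:
                raise ValueError(
                    f"amplitude_rl_mm={self.amplitude_rl_mm} drives the lateral "
                    "chest wall outside the thorax"
                )
        else:
            side = "right" if self.plane is Plane.SAGITTAL_RIGHT else "left"
            amp_hf = getattr(self, f"amplitude_hf_{side}_mm")
            amp_ap = getattr(self, f"amplitude_ap_{side}_mm")
            if g.d0 + amp_hf + g.droop > _BODY_CENTER_Y_MM + b - 10:
                raise ValueError(
                    f"amplitude_hf_{side}_mm={amp_hf} drives the diaphragm "
                    "outside the thorax"
                )
            if g.sag_lung_w + amp_ap / 2 > g.sag_a - 5:
                raise ValueError(
                    f"amplitude_ap_{side}_mm={amp_ap} drives the anterior wall "
                    "outside the thorax"
                )


@dataclass
class Geometry:
    """Closed-form phantom geometry shared by the renderer and the oracles."""

    a: float            # coronal thorax half-width
    b: float            # thorax half-height
    body_cy: float      # thorax ellipse centre row (mm, image-centred coords)
    lung_w: float       # coronal lung half-width
    lung_cx: float      # |x| of the coronal lung centres
    y_apex: float       # lung apex row (top of lung)
    lung_hv: float      # lung vertical semi-axis
    lung_cy: float      # lung vertical centre
    droop: float        # diaphragm droop coefficient at the lung edge
    d0: float           # diaphragm dome apex rest row
    sag_a: float        # sagittal thorax half-depth
    sag_lung_w: float   # sagittal lung half-depth


def geometry(config: PhantomConfig) -> Geometry:
    a, b = config.thorax_semiaxes_mm
    y_apex = _BODY_CENTER_Y_MM - _LUNG_APEX_FRAC * b
    hv = _LUNG_HALFHEIGHT_FRAC * b
    return Geometry(
        a=a,
        b=b,
        body_cy=_BODY_CENTER_Y_MM,
        lung_w=_LUNG_HALFWIDTH_FRAC * a,
        lung_cx=_LUNG_CENTER_FRAC * a,
        y_apex=y_apex,
        lung_hv=hv,
        lung_cy=y_apex + hv,
        droop=_DOME_DROOP_FRAC * b,
        d0=config.diaphragm_rest_y_mm,
        sag_a=_SAG_BODY_FRAC * a,
        sag_lung_w=_SAG_LUNG_HALFWIDTH_FRAC * a,
    )


def breathing_phase(config: PhantomConfig, t: np.ndarray | float) -> np.ndarray:
    """``sin^2(pi t / T)``: 0 at end-expiration, 1 at end-inspiration."""
    return np.sin(np.pi * np.asarray(t, dtype=float) / config.breathing_period_s) ** 2


def cycle_index_of(config: PhantomConfig, t: np.ndarray | float) -> np.ndarray:
    return np.floor(np.asarray(t, dtype=float) / config.breathing_period_s).astype(int)


def displacement_fraction(config: PhantomConfig, scales: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame boundary displacement as a fraction of the configured amplitude.

    ``scales`` optionally modulates whole cycles (irregular breathing); the
    fraction is ``scale(cycle(t)) * phi(t)``.
    """
    t = config.times()
    phi = breathing_phase(config, t)
    if scales is None:
        return phi
    idx = np.clip(cycle_index_of(config, t), 0, len(scales) - 1)
    return np.asarray(scales, dtype=float)[idx] * phi


@dataclass
class AxisTruth:
    """True expansion and end-phase frames for one measurement axis."""

    expansion_mm: float
    t_end_insp: int
    t_end_exp: int


@dataclass
class GroundTruth:
    """Validation sidecar: per-axis truth plus the generating configuration."""

    axes: dict[Direction, AxisTruth]
    config: PhantomConfig = None
    cycle_scales: np.ndarray | None = None

    @property
    def t_end_insp(self) -> int:
        return next(iter(self.axes.values())).t_end_insp

    @property
    def t_end_exp(self) -> int:
        return next(iter(self.axes.values())).t_end_exp


def _plane_directions(config: PhantomConfig) -> dict[Direction, float]:
    """Measurement axes applicable to the configured plane and their amplitudes."""
    if config.plane is Plane.CORONAL:
        return {
            Direction.RIGHT_HF: config.amplitude_hf_right_mm,
            Direction.LEFT_HF: config.amplitude_hf_left_mm,
            Direction.BILATERAL_RL: config.amplitude_rl_mm,
        }
    if config.plane is Plane.SAGITTAL_RIGHT:
        return {Direction.RIGHT_AP: config.amplitude_ap_right_mm}
    return {Direction.LEFT_AP: config.amplitude_ap_left_mm}


def _ground_truth(config: PhantomConfig, scales: Optional[np.ndarray]) -> GroundTruth:
    e = displacement_fraction(config, scales)
    t_ei = int(np.argmax(e))   # earliest tie by argmax convention
    t_ee = int(np.argmin(e))
    span = float(e[t_ei] - e[t_ee]) if scales is not None else 1.0
    axes = {
        d: AxisTruth(expansion_mm=a * span, t_end_insp=t_ei, t_end_exp=t_ee)
        for d, a in _plane_directions(config).items()
    }
    return GroundTruth(axes=axes, config=config, cycle_scales=scales)


# ---------------------------------------------------------------------------
# Analytic boundary oracles (mm, image-centred coordinates; y footward)
# ---------------------------------------------------------------------------

def diaphragm_apex_y_mm(config: PhantomConfig, frac: float, side: str = "right") -> float:
    """Diaphragm dome-apex row at displacement fraction ``frac``."""
    g = geometry(config)
    amp = getattr(config, f"amplitude_hf_{side}_mm")
    return g.d0 + amp * frac


def lung_outer_x_mm(config: PhantomConfig, frac: float, y_mm: float, side: str) -> float:
    """Outer lateral lung-wall position at row ``y_mm`` (coronal)."""
    g = geometry(config)
    u = (y_mm - g.lung_cy) / g.lung_hv
    half = g.lung_w * (max(0.0, 1.0 - u * u)) ** (1.0 / _X_EXPONENT)
    shift = config.amplitude_rl_mm / 2 * frac
    if side == "right":
        return -(g.lung_cx + shift) - half
    return (g.lung_cx + shift) + half


def sagittal_lung_x_mm(config: PhantomConfig, frac: float, y_mm: float) -> tuple[float, float]:
    """(posterior, anterior) lung-wall positions at row ``y_mm`` (sagittal)."""
    g = geometry(config)
    side = "right" if config.plane is Plane.SAGITTAL_RIGHT else "left"
    amp = getattr(config, f"amplitude_ap_{side}_mm")
    cx = amp / 2 * frac
    rx = g.sag_lung_w + amp / 2 * frac
    u = (y_mm - g.lung_cy) / g.lung_hv
    half = rx * (max(0.0, 1.0 - u * u)) ** (1.0 / _X_EXPONENT)
    return cx - half, cx + half


def mm_to_px(config: PhantomConfig, mm: float) -> float:
    """Image-centred mm coordinate -> raw pixel index (float)."""
    return (mm + config.fov_mm / 2) / config.pixel_spacing_mm - 0.5


def px_to_mm(config: PhantomConfig, px: float) -> float:
    return (px + 0.5) * config.pixel_spacing_mm - config.fov_mm / 2


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def _render_frame(config: PhantomConfig, g: Geometry, frac: float,
                  xg: np.ndarray, yg: np.ndarray) -> np.ndarray:
    """Noiseless supersampled frame at displacement fraction ``frac``."""
    img = np.zeros((yg.shape[0], xg.shape[1]), dtype=float)
    a_eff = g.a if config.plane is Plane.CORONAL else g.sag_a
    body = (xg / a_eff) ** 2 + ((yg - g.body_cy) / g.b) ** 2 <= 1.0
    img[body] = config.intensity_tissue

    def lung_mask(cx: float, w: float, amp_hf: float) -> tuple[np.ndarray, np.ndarray]:
        dia = g.d0 + amp_hf * frac + g.droop * ((xg - cx) / w) ** 2
        se = (np.abs(xg - cx) / w) ** _X_EXPONENT + ((yg - g.lung_cy) / g.lung_hv) ** 2 <= 1.0
        return se & (yg <= dia), dia

    if config.plane is Plane.CORONAL:
        shift = config.amplitude_rl_mm / 2 * frac
        right, dia_r = lung_mask(-(g.lung_cx + shift), g.lung_w, config.amplitude_hf_right_mm)
        left, _ = lung_mask(g.lung_cx + shift, g.lung_w, config.amplitude_hf_left_mm)
        liver = (
            body
            & (yg > dia_r)
            & (np.abs(xg + g.lung_cx + shift) <= g.lung_w + _LIVER_PAD_MM)
        )
        img[liver] = config.intensity_liver
        img[right | left] = config.intensity_lung
    else:
        side = "right" if config.plane is Plane.SAGITTAL_RIGHT else "left"
        amp_ap = getattr(config, f"amplitude_ap_{side}_mm")
        amp_hf = getattr(config, f"amplitude_hf_{side}_mm")
        cx = amp_ap / 2 * frac
        rx = g.sag_lung_w + amp_ap / 2 * frac
        dia = g.d0 + amp_hf * frac + g.droop * ((xg - cx) / rx) ** 2
        se = (np.abs(xg - cx) / rx) ** _X_EXPONENT + ((yg - g.lung_cy) / g.lung_hv) ** 2 <= 1.0
        lung = se & (yg <= dia)
        if side == "right":
            liver = body & (yg > dia) & (np.abs(xg - cx) <= rx + _LIVER_PAD_MM)
            img[liver] = config.intensity_liver
        img[lung] = config.intensity_lung
    return img


def _render_series(config: PhantomConfig, scales: Optional[np.ndarray]) -> np.ndarray:
    g = geometry(config)
    n = config.matrix_size
    ss = config.supersample
    step = config.fov_mm / (n * ss)
    coords = (np.arange(n * ss) + 0.5) * step - config.fov_mm / 2
    xg = coords[np.newaxis, :]
    yg = coords[:, np.newaxis]
    fracs = displacement_fraction(config, scales)
    frames = np.empty((config.n_frames, n, n), dtype=float)
    cache: dict[float, np.ndarray] = {}
    for k, frac in enumerate(fracs):
        key = round(float(frac), 12)
        if key not in cache:
            hi = _render_frame(config, g, float(frac), xg, yg)
            cache[key] = hi.reshape(n, ss, n, ss).mean(axis=(1, 3))
        frames[k] = cache[key]
    return frames


def generate_phantom_series(config: PhantomConfig) -> tuple[ImageSeries, GroundTruth]:
    """Render a dynamic phantom series and its ground-truth sidecar.

    Output is reproducible bit-for-bit from ``(config, config.seed)``.  If
    ``config.irregular_cycle`` is set, the indexed cycle is generated with its
    amplitude scaled (see :func:`inject_irregular_cycle`).
    """
    config.validate()
    scales = None
    if config.irregular_cycle is not None:
        idx, s = config.irregular_cycle
        scales = _cycle_scale_vector(config, int(idx), float(s))
    frames = _render_series(config, scales)
    if config.noise_sigma > 0:
        rng = np.random.default_rng(config.seed)
        frames = frames + rng.normal(0.0, config.noise_sigma, frames.shape)
        frames = np.clip(frames, 0.0, None)
    series = ImageSeries(
        frames=frames,
        pixel_spacing_mm=config.pixel_spacing_mm,
        frame_interval_s=config.frame_interval_s,
        plane=config.plane,
    )
    return series, _ground_truth(config, scales)


def _cycle_scale_vector(config: PhantomConfig, cycle_index: int, scale: float) -> np.ndarray:
    if scale < 0:
        raise ValueError("amplitude_scale must be >= 0")
    n_cycles = max(config.n_cycles, 1)
    if not 0 <= cycle_index < n_cycles:
        raise IndexError(
            f"cycle_index {cycle_index} out of range (series has {n_cycles} complete cycles)"
        )
    scales = np.ones(n_cycles + 1)  # +1: a trailing partial cycle keeps scale 1
    scales[cycle_index] = scale
    return scales


def inject_irregular_cycle(
    series: ImageSeries,
    truth: GroundTruth,
    cycle_index: int,
    amplitude_scale: float,
) -> tuple[ImageSeries, GroundTruth]:
    """Regenerate one breathing cycle with a scaled amplitude.

    Frame count, spacing, and frame interval are preserved.  The ground truth
    is recomputed from the modified displacement profile — an upscaled cycle
    may relocate the global end-inspiratory frame into itself.  The noise
    realisation of the regenerated frames is drawn from a stream derived from
    ``(seed, cycle_index)``, so an ``amplitude_scale`` of 1.0 returns the same
    series up to noise.
    """
    config = truth.config
    if config is None:
        raise ValueError("ground truth does not carry its generating config")
    scales = _cycle_scale_vector(config, cycle_index, amplitude_scale)
    frames = _render_series(config, scales)
    if config.noise_sigma > 0:
        rng = np.random.default_rng([config.seed, 7919, cycle_index])
        frames = np.clip(frames + rng.normal(0.0, config.noise_sigma, frames.shape), 0.0, None)
    out = series.with_frames(frames)
    return out, _ground_truth(config, scales)
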