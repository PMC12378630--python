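"""Synthetic-phantom validation studies.

These studies quantify how well the pipeline recovers known ground truth
from the breathing phantom: directional expansion recovery, end-phase frame
detection, inconsistent-cycle flagging, and ICC confidence-interval
coverage.  They are the package's substitute for participant data, and are
used both by the test suite and by the acceptance script.

Problem sizes are chosen to keep each study in the minutes range on one
CPU: recovery sessions use 18 s series (3 breathing cycles) at the native
192 -> 512 resolution, while the phase study — which only needs frame
indices, not millimetre accuracy — uses 128 -> 352 matrices with 24 s
series.  Breathing periods are drawn from multiples of twice the 0.6 s
frame interval so that the sampled breathing phase reaches its extremes
exactly and the ground-truth end-phase frames are unambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kymogram import (
    DiaphragmTrace,
    detect_extreme_phases,
    extract_diaphragm_trace,
    extract_yt,
    flag_inconsistent_cycles,
)
from .phantom import PhantomConfig, generate_phantom_series
from .preprocess import preprocess_pipeline
from .series import Direction, Plane
from .session import phantom_landmarks, phantom_search_band, run_phantom_session

_PERIOD_CHOICES_S = (6.0, 7.2, 8.4, 9.6)


@dataclass
class RecoveryResult:
    """Per-direction recovery errors over repeated phantom sessions."""

    errors_mm: dict[Direction, np.ndarray]  # measured - true, one per session

    def mean_abs_error_mm(self) -> dict[Direction, float]:
        return {d: float(np.mean(np.abs(e))) for d, e in self.errors_mm.items()}

    def bias_mm(self) -> dict[Direction, float]:
        return {d: float(np.mean(e)) for d, e in self.errors_mm.items()}


def expansion_recovery_study(
    n_sessions: int = 50,
    seed: int = 0,
    duration_s: float = 18.0,
    target_size: int = 512,
) -> RecoveryResult:
    """Recover the five directional expansions over seeded phantom sessions.

    Amplitudes are drawn uniformly from the observed physiological ranges:
    head-foot 60-90 mm, bilateral right-left 3-10 mm, anterior-posterior
    8-20 mm.  Each session also draws its own resting anatomy (diaphragm
    rest position, thorax semi-axes), emulating inter-subject variability.
    """
    rng = np.random.default_rng(seed)
    errors: dict[Direction, list[float]] = {d: [] for d in Direction}
    for i in range(n_sessions):
        session = run_phantom_session(
            seed=int(rng.integers(0, 2**20)),
            duration_s=duration_s,
            target_size=target_size,
            amplitude_hf_right_mm=float(rng.uniform(60, 90)),
            amplitude_hf_left_mm=float(rng.uniform(60, 90)),
            amplitude_rl_mm=float(rng.uniform(3, 10)),
            amplitude_ap_right_mm=float(rng.uniform(8, 20)),
            amplitude_ap_left_mm=float(rng.uniform(8, 20)),
            diaphragm_rest_y_mm=float(rng.uniform(35, 45)),
            thorax_semiaxes_mm=(float(rng.uniform(163, 177)), float(rng.uniform(223, 237))),
        )
        for d, m in session.measurements.items():
            errors[d].append(m.expansion_mm - session.truths[d])
    return RecoveryResult(errors_mm={d: np.asarray(v) for d, v in errors.items()})


@dataclass
class PhaseRecoveryResult:
    """Detected vs true end-phase frames over repeated noisy phantoms."""

    insp_offsets: np.ndarray  # detected - true frame index
    exp_offsets: np.ndarray

    @property
    def exact_fraction(self) -> float:
        exact = (self.insp_offsets == 0) & (self.exp_offsets == 0)
        return float(np.mean(exact))

    @property
    def within_one_fraction(self) -> float:
        ok = (np.abs(self.insp_offsets) <= 1) & (np.abs(self.exp_offsets) <= 1)
        return float(np.mean(ok))


def phase_recovery_study(
    n_runs: int = 100,
    seed: int = 0,
    matrix_size: int = 128,
    target_size: int = 352,
    duration_s: float = 24.0,
) -> PhaseRecoveryResult:
    """Detect end phases on noisy phantom traces with randomised conditions.

    Each run draws diaphragm amplitude 20-90 mm, breathing period from the
    frame-commensurate values 6.0-9.6 s, and noise up to 10% of the tissue
    intensity, then runs the full image pipeline before phase detection.
    """
    rng = np.random.default_rng(seed)
    d_insp, d_exp = [], []
    for i in range(n_runs):
        config = PhantomConfig(
            plane=Plane.CORONAL,
            matrix_size=matrix_size,
            duration_s=duration_s,
            breathing_period_s=float(rng.choice(_PERIOD_CHOICES_S)),
            amplitude_hf_right_mm=float(rng.uniform(20, 90)),
            amplitude_hf_left_mm=float(rng.uniform(20, 90)),
            noise_sigma=float(rng.uniform(0, 10)),
            seed=int(rng.integers(0, 2**20)),
        )
        series, truth = generate_phantom_series(config)
        pre = preprocess_pipeline(series, target_size=target_size, with_overlay=False)
        factor = target_size / matrix_size
        lm = phantom_landmarks(config).scaled(factor)
        from .kymogram import place_axes

        column = place_axes(lm, Plane.CORONAL).hf_right_column
        lo, hi = phantom_search_band(config)
        band = (
            max(0, int(np.floor(factor * (lo + 0.5) - 0.5))),
            min(target_size - 1, int(np.ceil(factor * (hi + 0.5) - 0.5))),
        )
        yt = extract_yt(pre.denoised, pre.contours, column)
        trace = extract_diaphragm_trace(yt, band)
        phases = detect_extreme_phases(trace)
        d_insp.append(phases.t_end_insp - truth.t_end_insp)
        d_exp.append(phases.t_end_exp - truth.t_end_exp)
    return PhaseRecoveryResult(
        insp_offsets=np.asarray(d_insp), exp_offsets=np.asarray(d_exp)
    )


@dataclass
class CycleFlagResult:
    """Sensitivity / specificity of the cycle-consistency criterion."""

    n_injected: int
    n_detected: int
    n_clean_runs: int
    n_false_flag_runs: int

    @property
    def sensitivity(self) -> float:
        return self.n_detected / self.n_injected if self.n_injected else float("nan")


def _synthetic_trace(
    rng: np.random.Generator,
    amplitude_px: float,
    n_cycles: int = 8,
    period_frames: int = 10,
    noise_px: float = 0.3,
    scaled_cycle: tuple[int, float] | None = None,
) -> DiaphragmTrace:
    """Analytic diaphragm trace (px) with optional per-cycle amplitude scaling."""
    n = n_cycles * period_frames
    t = np.arange(n)
    phi = np.sin(np.pi * t / period_frames) ** 2
    scale = np.ones(n)
    if scaled_cycle is not None:
        idx, s = scaled_cycle
        scale[(t // period_frames) == idx] = s
    y = 100.0 + amplitude_px * scale * phi + rng.normal(0, noise_px, n)
    return DiaphragmTrace(
        y_position=y,
        valid_mask=np.ones(n, dtype=bool),
        spatial_spacing_mm=500.0 / 512.0,
        time_spacing_s=0.6,
    )


def cycle_flag_study(n_runs: int = 100, seed: int = 0) -> CycleFlagResult:
    """Flag injected inconsistent cycles in otherwise regular noisy traces.

    Half of the injected scales are shallow (0.2-0.5x) and half deep
    (1.8-2.2x); clean runs use the same noise level and must produce no
    flags at all.
    """
    rng = np.random.default_rng(seed)
    n_detected = 0
    n_false = 0
    period = 10
    for i in range(n_runs):
        amp = rng.uniform(60, 92)
        clean = flag_inconsistent_cycles(_synthetic_trace(rng, amp))
        if clean.excluded_intervals:
            n_false += 1
        cycle = int(rng.integers(1, 7))
        scale = float(rng.uniform(0.2, 0.5) if i % 2 == 0 else rng.uniform(1.8, 2.2))
        flagged = flag_inconsistent_cycles(
            _synthetic_trace(rng, amp, scaled_cycle=(cycle, scale))
        )
        t0, t1 = cycle * period, (cycle + 1) * period
        hit = any(s < t1 and e > t0 for s, e in flagged.excluded_intervals)
        if hit:
            n_detected += 1
    return CycleFlagResult(
        n_injected=n_runs,
        n_detected=n_detected,
        n_clean_runs=n_runs,
        n_false_flag_runs=n_false,
    )


def icc_ci_coverage_study(
    n_sim: int = 1000,
    true_icc: float = 0.8,
    n_subjects: int = 5,
    k_raters: int = 2,
    seed: int = 0,
) -> float:
    """Fraction of 95% ICC confidence intervals covering the true ICC.

    Ratings are simulated from a one-way variance-components model
    (subject variance ``true_icc``, error variance ``1 - true_icc``) and
    assessed with the matching one-way ICC, whose F-bounds are exact under
    this model.
    """
    from .stats import ICCModel, icc

    rng = np.random.default_rng(seed)
    sd_b = np.sqrt(true_icc)
    sd_e = np.sqrt(1.0 - true_icc)
    covered = 0
    for _ in range(n_sim):
        b = rng.normal(0, sd_b, (n_subjects, 1))
        x = b + rng.normal(0, sd_e, (n_subjects, k_raters))
        res = icc(x, model=ICCModel.ONEWAY)
        if res.ci_low <= true_icc <= res.ci_high:
            covered += 1
    return covered / n_sim
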