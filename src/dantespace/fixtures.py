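"""Synthetic physiological inputs: waveforms, vessel trajectory, B1+ profile.

Real DANTE-SPACE modelling consumes literature velocity waveforms (third-
ventricle CSF, internal-carotid blood), an MPRAGE-derived vessel path and
measured 7 T B1+ maps.  None of those curves are distributable as data, so
this module generates parametric stand-ins that reproduce their *stated*
summary properties — mean |v| = 0.37 cm/s with net-zero displacement for
CSF, mean 24 cm/s with a ~16.5 cm/s diastolic floor for blood, a 25 cm
coronal-plane path with a carotid-siphon-like bend, and a B1+ profile rising
from ~0.35 in the neck to ~1 at the circle of Willis.  Waveform-shape-
sensitive results are therefore approximate; see docs/methods.md.

All generators are deterministic for a fixed seed.
"""

from __future__ import annotations

import numpy as np

from .epg import ParameterError
from .physiology import FlowTrajectory, MotionModel, PulsatileWaveform, mean_hemisphere_angle

__all__ = ["make_waveform", "make_trajectory", "standard_motion", "DEFAULT_SEED"]

DEFAULT_SEED = 7

# default mean speeds, cm/s
CSF_MEAN_VELOCITY = 0.37
BLOOD_MEAN_VELOCITY = 24.0
BLOOD_MIN_VELOCITY = 16.5
VW_MEAN_VELOCITY = 0.054


def make_waveform(
    kind: str,
    mean_abs_velocity: float | None = None,
    period: float = 1.0,
    seed: int = DEFAULT_SEED,
    n_samples: int = 256,
    min_velocity: float | None = None,
) -> PulsatileWaveform:
    """Generate a one-period velocity waveform of the requested family.

    Parameters
    ----------
    kind : {'csf_like', 'vw_like', 'blood_like'}
        'csf_like' / 'vw_like': smooth biphasic two-harmonic oscillation
        rescaled to the requested mean |v| with exactly zero net displacement
        per cycle.  'blood_like': strictly positive systolic-peaked curve
        with the requested mean and minimum.
    mean_abs_velocity : float, optional
        Target time-average of |v| in cm/s.  Defaults: 0.37 (csf_like),
        0.054 (vw_like), 24.0 (blood_like).
    period : float
        Cardiac period in s (default 1.0, i.e. 60 bpm).
    seed : int
        Unused for the default parametric shapes but kept so callers can
        thread one source of determinism through; fixed default keeps
        regeneration byte-identical.
    min_velocity : float, optional
        blood_like only: diastolic floor in cm/s (default 16.5).
    """
    if kind in ("csf_like", "vw_like"):
        mean = mean_abs_velocity if mean_abs_velocity is not None else (
            VW_MEAN_VELOCITY if kind == "vw_like" else CSF_MEAN_VELOCITY
        )
        if mean <= 0:
            raise ParameterError(f"mean_abs_velocity must be positive, got {mean}")
        t = np.arange(n_samples) * (period / n_samples)
        # biphasic shape: dominant fundamental plus a skewing second harmonic;
        # pure harmonics integrate to exactly zero displacement per period
        base = np.sin(2 * np.pi * t / period) + 0.45 * np.sin(4 * np.pi * t / period + 1.2)
        scale = mean / _grid_mean_abs(base, t, period)
        return PulsatileWaveform(t, base * scale, period=period, kind=kind)

    if kind == "blood_like":
        mean = mean_abs_velocity if mean_abs_velocity is not None else BLOOD_MEAN_VELOCITY
        vmin = min_velocity if min_velocity is not None else BLOOD_MIN_VELOCITY
        if vmin >= mean:
            raise ParameterError(
                f"blood waveform needs min < mean, got min={vmin}, mean={mean}"
            )
        t = np.arange(n_samples) * (period / n_samples)
        # systolic peak with a dicrotic shoulder, on a diastolic floor
        bump = np.exp(-0.5 * ((t - 0.18 * period) / (0.07 * period)) ** 2)
        bump += 0.35 * np.exp(-0.5 * ((t - 0.42 * period) / (0.10 * period)) ** 2)
        bump -= bump.min()  # exact zero at the diastolic floor
        v = vmin + bump * (mean - vmin) / _grid_mean_abs(bump, t, period)
        return PulsatileWaveform(t, v, period=period, kind=kind)

    raise ParameterError(f"unknown waveform kind: {kind!r}")


def _grid_mean_abs(v: np.ndarray, t: np.ndarray, period: float) -> float:
    tp = np.append(t, period)
    vp = np.abs(np.append(v, v[0]))
    return float(np.trapezoid(vp, tp) / period)


def make_trajectory(
    length: float = 25.0,
    n_points: int = 400,
    seed: int = DEFAULT_SEED,
    b1_start: float = 0.35,
    b1_end: float = 0.97,
    gradient_axis=None,
) -> FlowTrajectory:
    """Generate a smooth coronal-plane vessel path of the requested arc
    length (cm) with an attached neck-to-head B1+ profile.

    The curve runs mostly head-ward (+z) with a gentle lateral sweep and a
    tighter siphon-like double bend near the distal end.  The B1+ profile
    rises monotonically in trend from ``b1_start`` (low transmit efficiency
    in the neck) to ``b1_end`` near the imaging volume, with smooth local
    ripple seeded by ``seed``.
    """
    if length <= 0:
        raise ParameterError(f"length must be positive, got {length}")
    rng = np.random.default_rng(seed)
    u = np.linspace(0.0, 1.0, n_points)
    # coronal plane: y = 0 throughout
    siphon = np.where(u > 0.7, np.sin((u - 0.7) / 0.3 * 2.5 * np.pi), 0.0)
    x = 0.10 * np.sin(2.2 * np.pi * u) + 0.05 * siphon * (u - 0.7)
    z = u + 0.02 * np.sin(3.0 * np.pi * u)
    pts = np.column_stack([x, np.zeros_like(u), z])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    raw_len = seg.sum()
    pts *= (length * 10.0) / raw_len  # scale to requested arc length, in mm

    # B1+: smooth monotone trend + low-amplitude seeded ripple away from ends
    trend = b1_start + (b1_end - b1_start) * (3 * u**2 - 2 * u**3)
    phases = rng.uniform(0, 2 * np.pi, size=3)
    ripple = sum(
        (0.012 / (i + 1)) * np.sin(2 * np.pi * (i + 2) * u + phases[i]) for i in range(3)
    )
    b1 = trend + ripple * np.sin(np.pi * u)  # ripple vanishes at both ends
    return FlowTrajectory.from_points(pts, b1, gradient_axis)


def standard_motion(tissue: str, full_model: bool = True, n_samples: int = 100) -> MotionModel:
    """Canonical motion model for one of the study tissues.

    ``full_model=True`` returns the complete physiological description:

    * ``'vw'`` — slow wall pulsation: CSF-shaped waveform with mean |v| of
      0.054 cm/s along the preparation gradient (wall-motion direction
      effects are not modelled), 10 % intravoxel spread, 100 samples;
    * ``'csf'`` — 0.37 cm/s pulsatile oscillation at the hemisphere-mean
      angle (57.3 deg) to the gradient, 10 % spread, random cardiac phase;
    * ``'blood'`` — 24 cm/s carotid-like pulsatile inflow along the
      synthetic 25 cm trajectory with its B1+ profile, nearly perpendicular
      (85 deg) to the readout gradient, 10 % spread.

    ``full_model=False`` returns the corresponding basic description:
    constant plug velocity, no spread, pulsation, trajectory or direction
    variation (blood keeps the near-perpendicular readout projection, a
    geometric fact rather than a model enhancement; the wall is static).
    """
    if tissue == "vw":
        if not full_model:
            return MotionModel.static()
        return MotionModel(
            mean_velocity=VW_MEAN_VELOCITY, sigma_frac=0.10, n_samples=n_samples,
            waveform=make_waveform("vw_like"), beta=0.0,
        )
    if tissue == "csf":
        if not full_model:
            return MotionModel(CSF_MEAN_VELOCITY, 0.0, 1, random_phase=False)
        return MotionModel(
            mean_velocity=CSF_MEAN_VELOCITY, sigma_frac=0.10, n_samples=n_samples,
            waveform=make_waveform("csf_like"), beta=mean_hemisphere_angle(),
        )
    if tissue == "blood":
        if not full_model:
            return MotionModel(BLOOD_MEAN_VELOCITY, 0.0, 1, random_phase=False, readout_beta=85.0)
        return MotionModel(
            mean_velocity=BLOOD_MEAN_VELOCITY, sigma_frac=0.10, n_samples=n_samples,
            waveform=make_waveform("blood_like"), trajectory=make_trajectory(),
            readout_beta=85.0,
        )
    raise ParameterError(f"unknown tissue: {tissue!r} (expected vw, csf or blood)")
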