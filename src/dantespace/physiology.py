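"""Velocity ensembles, pulsatile waveforms, flow geometry and B1+ timelines.

This module turns a tissue's motion description into the per-interval
effective velocity (along the preparation gradient axis) and per-pulse B1+
scale that the sequence engine consumes:

* intravoxel velocity spread — each voxel contains spins moving at slightly
  different speeds, modelled as a normal distribution around the nominal
  velocity (sigma = 10 % of the mean by default) realised as an ensemble of
  simulations;
* cardiac pulsatility — periodic velocity waveforms (60 bpm default) with a
  random starting phase per ensemble member, since acquisitions are not
  cardiac gated;
* flow direction — only the velocity component along the gradient axis
  dephases spins, so velocities are projected by ``cos(beta)``; for CSF,
  whose direction varies across the brain, ``beta`` is fixed at the
  solid-angle mean over a hemisphere (1 rad = 57.3 deg);
* vessel trajectories — blood traverses a 25 cm vessel path before reaching
  the imaging voxel, so its direction angle and local B1+ efficiency become
  functions of time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .epg import ParameterError

__all__ = [
    "PulsatileWaveform",
    "FlowTrajectory",
    "MotionModel",
    "sample_velocity_scalars",
    "waveform_velocity",
    "effective_velocity",
    "mean_hemisphere_angle",
    "trajectory_timeline",
    "read_waveform_csv",
    "write_waveform_csv",
    "read_trajectory_csv",
    "write_trajectory_csv",
]

log = logging.getLogger("dantespace")


@dataclass(frozen=True)
class PulsatileWaveform:
    """One period of a velocity waveform, linearly interpolated periodically.

    ``times`` (s) must start at 0 and stay below ``period``; the waveform is
    wrapped so that v(period) = v(0).  ``kind`` labels the physiological
    family: 'csf_like' and 'vw_like' oscillate with net-zero displacement
    per cardiac cycle, 'blood_like' is strictly positive.
    """

    times: np.ndarray
    velocities: np.ndarray
    period: float = 1.0
    kind: str = "csf_like"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, float)
        v = np.asarray(self.velocities, float)
        if t.shape != v.shape or t.ndim != 1 or t.size < 3:
            raise ParameterError("waveform needs matching 1-D time/velocity arrays (>= 3 samples)")
        if t[0] != 0.0 or t[-1] >= self.period or np.any(np.diff(t) <= 0):
            raise ParameterError("waveform times must increase from 0 and stay below the period")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "velocities", v)

    def mean_abs_velocity(self) -> float:
        """Time-average of |v| over one period (trapezoid on the periodic grid)."""
        t = np.append(self.times, self.period)
        v = np.abs(np.append(self.velocities, self.velocities[0]))
        return float(np.trapezoid(v, t) / self.period)

    def net_displacement(self) -> float:
        """Displacement integral of v over one full period (cm)."""
        t = np.append(self.times, self.period)
        v = np.append(self.velocities, self.velocities[0])
        return float(np.trapezoid(v, t))


@dataclass(frozen=True)
class FlowTrajectory:
    """A vessel path with per-point direction angle and B1+ efficiency.

    ``points`` are 3-D coordinates in mm; ``arc_length`` the cumulative path
    length in cm (strictly increasing); ``beta_deg`` the angle between the
    local tangent and the gradient axis; ``b1`` the local transmit-field
    scale (> 0).
    """

    points: np.ndarray
    arc_length: np.ndarray
    beta_deg: np.ndarray
    b1: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.arc_length, float)
        if np.any(np.diff(s) <= 0):
            raise ParameterError("trajectory arc length must be strictly increasing")
        if np.any(np.asarray(self.b1) <= 0):
            raise ParameterError("B1+ scale must be positive along the trajectory")

    @property
    def total_length(self) -> float:
        return float(self.arc_length[-1])

    @staticmethod
    def from_points(
        points: np.ndarray, b1: np.ndarray, gradient_axis: np.ndarray | None = None
    ) -> "FlowTrajectory":
        """Build a trajectory from raw 3-D points (mm) and per-point B1+.

        The direction angle at each point is computed from consecutive point
        differences against ``gradient_axis`` (default: +z, the head-foot
        preparation-gradient direction).
        """
        pts = np.asarray(points, float)
        axis = np.array([0.0, 0.0, 1.0]) if gradient_axis is None else np.asarray(gradient_axis, float)
        axis = axis / np.linalg.norm(axis)
        seg = np.diff(pts, axis=0)
        seg_len = np.linalg.norm(seg, axis=1)
        if np.any(seg_len <= 0):
            raise ParameterError("trajectory contains duplicate consecutive points")
        arc = np.concatenate([[0.0], np.cumsum(seg_len)]) / 10.0  # mm -> cm
        tangents = seg / seg_len[:, None]
        cosb = np.clip(tangents @ axis, -1.0, 1.0)
        beta_mid = np.degrees(np.arccos(cosb))
        beta = np.concatenate([[beta_mid[0]], 0.5 * (beta_mid[1:] + beta_mid[:-1]), [beta_mid[-1]]])
        return FlowTrajectory(pts, arc, beta, np.asarray(b1, float))


@dataclass
class MotionModel:
    """Complete motion description of one tissue compartment.

    Parameters
    ----------
    mean_velocity : float
        Nominal speed in cm/s (0 for a static tissue).
    sigma_frac : float
        Intravoxel velocity spread as a fraction of the mean (default 0.10).
    n_samples : int
        Ensemble size for the velocity distribution (default 100).
    waveform : PulsatileWaveform or None
        Pulsatile profile; None means constant velocity.
    beta : float
        Angle (deg) between the motion direction and the gradient axis;
        57.3 deg (the hemisphere mean) is the CSF default, 0 for plug flow.
    trajectory : FlowTrajectory or None
        When set, beta and B1+ become time dependent as spins travel the
        vessel path at ``mean_velocity``.
    random_phase : bool
        Draw a uniform random waveform start phase per ensemble member.
    readout_beta : float or None
        Angle (deg) between the motion direction and the *readout* gradient
        axis, which generally differs from the preparation axis; blood flow
        is nearly perpendicular to the readout gradient.  None (default)
        reuses the preparation-axis geometry during the readout.
    """

    mean_velocity: float = 0.0
    sigma_frac: float = 0.10
    n_samples: int = 100
    waveform: PulsatileWaveform | None = None
    beta: float = 0.0
    trajectory: FlowTrajectory | None = None
    random_phase: bool = True
    readout_beta: float | None = None

    def __post_init__(self) -> None:
        if self.n_samples < 1:
            raise ParameterError(f"n_samples must be >= 1, got {self.n_samples}")
        if self.sigma_frac < 0:
            raise ParameterError(f"sigma_frac must be >= 0, got {self.sigma_frac}")
        if not (0.0 <= self.beta <= 180.0):
            raise ParameterError(f"beta must lie in [0, 180] deg, got {self.beta}")

    @staticmethod
    def static() -> "MotionModel":
        return MotionModel(mean_velocity=0.0, sigma_frac=0.0, n_samples=1, random_phase=False)


def sample_velocity_scalars(mean: float, sigma_frac: float, n: int, seed) -> np.ndarray:
    """Draw ``n`` velocities from Normal(mean, (sigma_frac*mean)^2), cm/s.

    ``seed`` may be an int or a ``numpy.random.Generator``.  Negative draws
    are kept (they flip the phase direction); sigma_frac = 0 degenerates to
    ``n`` copies of the mean.
    """
    if n < 1:
        raise ParameterError(f"n must be >= 1, got {n}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sigma = abs(sigma_frac * mean)
    if sigma == 0.0:
        return np.full(n, float(mean))
    return rng.normal(mean, sigma, size=n)


def waveform_velocity(w: PulsatileWaveform, t, phase_offset: float = 0.0):
    """Velocity at time ``t`` (s): periodic linear interpolation of the
    waveform evaluated at ``(t + phase_offset) mod period``."""
    tt = np.mod(np.asarray(t, float) + phase_offset, w.period)
    tp = np.append(w.times, w.period)
    vp = np.append(w.velocities, w.velocities[0])
    return np.interp(tt, tp, vp)


def effective_velocity(v, beta: float):
    """Project a speed onto the gradient axis: ``v * cos(beta)`` (beta in deg)."""
    return v * np.cos(np.deg2rad(beta))


def mean_hemisphere_angle() -> float:
    """Solid-angle-weighted mean angle between a fixed axis and all
    directions on the unit hemisphere, in degrees.

    With the polar angle beta weighted by sin(beta) over [0, pi/2]:
    ``<beta> = int beta sin(beta) dbeta / int sin(beta) dbeta = 1 rad``,
    i.e. 57.2958 deg.  Used as the fixed CSF pulsation direction.
    """
    return float(np.degrees(1.0))


def trajectory_timeline(
    traj: FlowTrajectory, speed: float, t_grid: np.ndarray, t_anchor: float
) -> tuple[np.ndarray, np.ndarray]:
    """Direction angle and B1+ versus time for spins flowing along ``traj``.

    Spins travel at ``speed`` (cm/s) and are anchored so they reach the
    trajectory end (the imaging voxel) at ``t_anchor`` (s); their arc-length
    position at time t is ``s(t) = s_end - speed * (t_anchor - t)``, clamped
    to the trajectory extent.  Returns ``(beta_deg(t), b1(t))`` arrays.
    """
    if speed <= 0:
        raise ParameterError(f"trajectory speed must be positive, got {speed}")
    t = np.asarray(t_grid, float)
    s = traj.total_length - speed * (t_anchor - t)
    n_below = int(np.sum(s < 0))
    if n_below:
        log.debug(
            "trajectory timeline clamped: %d of %d time points precede the "
            "trajectory start (traversal time %.3f s)",
            n_below, t.size, traj.total_length / speed,
        )
    s = np.clip(s, 0.0, traj.total_length)
    beta = np.interp(s, traj.arc_length, traj.beta_deg)
    b1 = np.interp(s, traj.arc_length, traj.b1)
    return beta, b1


# ---------------------------------------------------------------------------
# CSV interfaces (plain text, units in the headers)

def write_waveform_csv(w: PulsatileWaveform, path) -> None:
    pd.DataFrame({"time_s": w.times, "velocity_cm_s": w.velocities}).to_csv(path, index=False)


def read_waveform_csv(path, period: float = 1.0, kind: str = "csf_like") -> PulsatileWaveform:
    df = pd.read_csv(path)
    return PulsatileWaveform(
        df["time_s"].to_numpy(), df["velocity_cm_s"].to_numpy(), period=period, kind=kind
    )


def write_trajectory_csv(traj: FlowTrajectory, path) -> None:
    pts = traj.points
    pd.DataFrame(
        {"x_mm": pts[:, 0], "y_mm": pts[:, 1], "z_mm": pts[:, 2], "b1_scale": traj.b1}
    ).to_csv(path, index=False)


def read_trajectory_csv(path, gradient_axis=None) -> FlowTrajectory:
    df = pd.read_csv(path)
    pts = df[["x_mm", "y_mm", "z_mm"]].to_numpy()
    return FlowTrajectory.from_points(pts, df["b1_scale"].to_numpy(), gradient_axis)
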