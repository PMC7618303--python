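"""Extended phase graph (EPG) states and elementary evolution operators.

The EPG formalism represents a dephased spin ensemble by complex
configuration-state amplitudes: transverse states ``F_k`` for integer
dephasing order ``k`` and longitudinal states ``Z_k``.  An RF pulse mixes
states of equal ``|k|``, a gradient shifts the transverse orders, and
relaxation, diffusion and coherent flow act diagonally on the orders.  The
order-0 transverse amplitude ``F_0`` is the measurable voxel signal (the mean
transverse magnetization of the underlying isochromat ensemble).

Conventions
-----------
* States are stored as three arrays ``f_plus[k]``, ``f_minus[k]`` and
  ``z[k]`` for ``k = 0..k_max``; ``f_minus[k]`` holds the complex conjugate
  of the physical state at order ``-k``, so ``f_minus[0] == conj(f_plus[0])``
  at all times.
* All public parameters use the field's customary units (ms, degrees, cm/s,
  mm^2/s, rad/mm); conversion to SI (s, m, rad/m) happens inside the
  operators so that b-factor and flow-phase formulas are written in SI.
* Operators are pure functions: they return a new :class:`EPGState`.
* Arrays may carry leading batch dimensions (``(..., k_max+1)``) so that an
  ensemble of simulations (e.g. 100 velocity samples) evolves in one
  vectorised pass; scalar parameters broadcast against the batch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "EPGState",
    "TissueParams",
    "IntervalSpec",
    "ParameterError",
    "TruncationError",
    "make_equilibrium",
    "apply_rf",
    "evolve_interval",
    "signal",
    "VW",
    "CSF",
    "BLOOD",
]

# unit conversions applied at the operator boundary
_MS = 1e-3          # ms -> s
_CM_S = 1e-2        # cm/s -> m/s
_MM2_S = 1e-6       # mm^2/s -> m^2/s
_RAD_MM = 1e3       # rad/mm -> rad/m


class ParameterError(ValueError):
    """Invalid physical or structural parameter."""


class TruncationError(RuntimeError):
    """Configuration-state population pushed past k_max beyond tolerance."""


@dataclass(frozen=True)
class TissueParams:
    """Relaxation/density bundle for one tissue compartment.

    Parameters
    ----------
    name : str
        Label used in reports.
    t1, t2 : float
        Longitudinal / transverse relaxation times in ms; requires
        ``t1 >= t2 > 0``.
    pd : float
        Relative proton density (dimensionless, > 0).
    d : float
        Diffusion coefficient in mm^2/s (>= 0).
    """

    name: str
    t1: float
    t2: float
    pd: float = 1.0
    d: float = 0.0

    def __post_init__(self) -> None:
        if not (self.t1 >= self.t2 > 0):
            raise ParameterError(f"require t1 >= t2 > 0, got t1={self.t1}, t2={self.t2}")
        if self.pd <= 0:
            raise ParameterError(f"proton density must be positive, got {self.pd}")
        if self.d < 0:
            raise ParameterError(f"diffusion coefficient must be >= 0, got {self.d}")


# 7 T tissue presets: carotid vessel wall, cerebrospinal fluid, arterial blood.
# Free-water diffusion (3e-3 mm^2/s) is modelled for the fluids; the wall is
# treated as diffusion-free on the relevant b-factor scale.
VW = TissueParams("vw", t1=1628.0, t2=46.0, pd=0.72, d=0.0)
CSF = TissueParams("csf", t1=4019.0, t2=311.0, pd=1.0, d=3e-3)
BLOOD = TissueParams("blood", t1=2290.0, t2=100.0, pd=1.0, d=3e-3)


@dataclass(frozen=True)
class IntervalSpec:
    """One gradient/relaxation interval between RF pulses.

    Parameters
    ----------
    duration : float
        Interval length in ms (>= 0).
    shift : int
        Signed number of configuration orders the gradient advances the
        transverse states (gradient moment = ``shift * delta_k``).
    delta_k : float
        Per-order spatial-frequency increment in rad/mm along the gradient
        axis (>= 0).
    velocity : float or ndarray
        Effective velocity along the gradient axis in cm/s (signed); may be
        an array broadcasting against the state's batch dimensions.
    apply_diffusion, apply_flow : bool
        Enable the diffusion-attenuation / coherent-flow-phase operators.
    """

    duration: float
    shift: int = 0
    delta_k: float = 0.0
    velocity: float | np.ndarray = 0.0
    apply_diffusion: bool = False
    apply_flow: bool = False

    def __post_init__(self) -> None:
        if self.duration < 0:
            raise ParameterError(f"duration must be >= 0, got {self.duration}")
        if self.delta_k < 0:
            raise ParameterError(f"delta_k must be >= 0, got {self.delta_k}")


@dataclass
class EPGState:
    """Configuration-state amplitudes of one (batched) spin ensemble.

    ``f_plus``, ``f_minus`` and ``z`` have shape ``(..., k_max + 1)``; the
    trailing axis is the configuration order.  ``m0`` is the equilibrium
    longitudinal magnetization the ensemble relaxes toward.
    """

    f_plus: np.ndarray
    f_minus: np.ndarray
    z: np.ndarray
    m0: float = 1.0
    k_max: int = field(default=0)

    def __post_init__(self) -> None:
        self.k_max = self.f_plus.shape[-1] - 1

    def copy(self) -> "EPGState":
        return EPGState(self.f_plus.copy(), self.f_minus.copy(), self.z.copy(), self.m0)


def make_equilibrium(m0: float = 1.0, k_max: int = 32, batch_shape: tuple = ()) -> EPGState:
    """Thermal-equilibrium state: ``z[0] = m0``, everything else zero."""
    if m0 < 0:
        raise ParameterError(f"m0 must be >= 0, got {m0}")
    if k_max < 1:
        raise ParameterError(f"k_max must be >= 1, got {k_max}")
    shape = tuple(batch_shape) + (k_max + 1,)
    f_plus = np.zeros(shape, dtype=complex)
    f_minus = np.zeros(shape, dtype=complex)
    z = np.zeros(shape, dtype=complex)
    z[..., 0] = m0
    return EPGState(f_plus, f_minus, z, m0=float(m0))


def _rf_matrix(alpha: float, phi: float) -> np.ndarray:
    """Standard 3x3 EPG rotation mixing matrix for flip ``alpha`` (rad) about
    an axis at azimuth ``phi`` (rad) in the transverse plane."""
    ca2 = np.cos(alpha / 2.0) ** 2
    sa2 = np.sin(alpha / 2.0) ** 2
    sa = np.sin(alpha)
    ca = np.cos(alpha)
    eip = np.exp(1j * phi)
    return np.array(
        [
            [ca2, eip**2 * sa2, -1j * eip * sa],
            [np.conj(eip) ** 2 * sa2, ca2, 1j * np.conj(eip) * sa],
            [-0.5j * np.conj(eip) * sa, 0.5j * eip * sa, ca],
        ],
        dtype=complex,
    )


def apply_rf(state: EPGState, flip: float, phase: float = 0.0, b1_scale: float = 1.0) -> EPGState:
    """Apply an RF pulse of nominal ``flip`` (deg) and ``phase`` (deg).

    The effective flip angle is ``flip * b1_scale`` — the transmit-field
    (B1+) efficiency enters the simulation exclusively through this scaling.
    The per-order rotation conserves ``(|F+|^2 + |F-|^2)/2 + |Z|^2``.
    """
    if b1_scale < 0:
        raise ParameterError(f"b1_scale must be >= 0, got {b1_scale}")
    alpha = np.deg2rad(flip * b1_scale)
    phi = np.deg2rad(phase)
    t = _rf_matrix(alpha, phi)
    fp = t[0, 0] * state.f_plus + t[0, 1] * state.f_minus + t[0, 2] * state.z
    fm = t[1, 0] * state.f_plus + t[1, 1] * state.f_minus + t[1, 2] * state.z
    zz = t[2, 0] * state.f_plus + t[2, 1] * state.f_minus + t[2, 2] * state.z
    # re-impose the k=0 conjugate pairing exactly (guards rounding drift)
    fm[..., 0] = np.conj(fp[..., 0])
    return EPGState(fp, fm, zz, state.m0)


def _shift_transverse(
    fp: np.ndarray,
    fm: np.ndarray,
    shift: int,
    m0: float,
    truncation_tol: float,
    on_truncation: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Shift all transverse orders by ``shift`` on the full -K..K line.

    Population pushed past +/-K is dropped; its largest magnitude is
    compared against ``truncation_tol * m0`` and reported per
    ``on_truncation`` ("warn", "error" or "ignore").
    """
    k_cap = fp.shape[-1] - 1
    lead = fp.shape[:-1]
    full = np.zeros(lead + (2 * k_cap + 1,), dtype=complex)
    full[..., k_cap:] = fp
    full[..., :k_cap] = np.conj(fm[..., k_cap:0:-1])
    moved = np.zeros_like(full)
    s = int(shift)
    if s == 0:
        moved = full
        lost = 0.0
    elif s > 0:
        moved[..., s:] = full[..., :-s]
        lost = float(np.max(np.abs(full[..., -s:]))) if s <= full.shape[-1] else float(np.max(np.abs(full)))
    else:
        moved[..., :s] = full[..., -s:]
        lost = float(np.max(np.abs(full[..., :-s]))) if -s <= full.shape[-1] else float(np.max(np.abs(full)))
    if lost > truncation_tol * max(m0, np.finfo(float).tiny):
        msg = (
            f"configuration order overflow: |amplitude| {lost:.3e} shifted past "
            f"k_max={k_cap} (tolerance {truncation_tol:g} * m0)"
        )
        if on_truncation == "error":
            raise TruncationError(msg)
        if on_truncation == "warn":
            warnings.warn(msg, RuntimeWarning, stacklevel=3)
    fp_new = moved[..., k_cap:].copy()
    fm_new = np.conj(moved[..., k_cap::-1]).copy()
    return fp_new, fm_new


def evolve_interval(
    state: EPGState,
    interval: IntervalSpec,
    tissue: TissueParams,
    truncation_tol: float = 1e-3,
    on_truncation: str = "warn",
) -> EPGState:
    """Propagate the state through one gradient interval.

    Operator order is fixed and documented: (a) T1/T2 relaxation with
    recovery of ``z[0]`` toward ``m0``; (b) diffusion attenuation
    ``exp(-D * b_k)``; (c) coherent flow phase; (d) configuration shift.

    Diffusion uses the standard EPG b-factors under a constant-amplitude
    gradient of moment ``shift * delta_k`` over ``duration``: a transverse
    state traversing from order ``k`` to ``k + shift`` accrues
    ``b = tau * dk^2 * ((k + shift/2)^2 + shift^2 / 12)`` (the time integral
    of the instantaneous k(t)^2, which contains the 1/3 term), while a
    longitudinal state keeps its order and accrues ``b = tau * (k * dk)^2``.

    Coherent plug flow at velocity ``v`` multiplies a transverse state
    traversing ``k -> k + shift`` by ``exp(i * (k + shift/2) * dk * v *
    tau)`` (mean order during the traversal) and a longitudinal state by
    ``exp(i * k * dk * v * tau)``; the stored conjugate-convention arrays
    pick up the conjugate factors so ``f_minus[0] == conj(f_plus[0])`` is
    preserved.  Velocity spread across a voxel is handled by batching, not
    inside this operator.
    """
    tau = interval.duration * _MS
    fp = state.f_plus.copy()
    fm = state.f_minus.copy()
    zz = state.z.copy()

    if tau > 0:
        e1 = np.exp(-tau / (tissue.t1 * _MS))
        e2 = np.exp(-tau / (tissue.t2 * _MS))
        fp *= e2
        fm *= e2
        zz *= e1
        zz[..., 0] += state.m0 * (1.0 - e1)

    dk = interval.delta_k * _RAD_MM  # rad/m
    s = int(interval.shift)
    k = np.arange(fp.shape[-1], dtype=float)

    if interval.apply_diffusion and tissue.d > 0 and tau > 0 and dk > 0:
        d_si = tissue.d * _MM2_S
        b_t_plus = tau * dk**2 * ((k + s / 2.0) ** 2 + s**2 / 12.0)
        b_t_minus = tau * dk**2 * ((k - s / 2.0) ** 2 + s**2 / 12.0)
        b_l = tau * (k * dk) ** 2
        fp *= np.exp(-d_si * b_t_plus)
        fm *= np.exp(-d_si * b_t_minus)
        zz *= np.exp(-d_si * b_l)

    if interval.apply_flow and tau > 0 and dk > 0:
        v = np.asarray(interval.velocity, dtype=float) * _CM_S
        theta = dk * v * tau  # rad per configuration order
        if theta.ndim > 0:
            theta = theta[..., None]  # broadcast batch against the order axis
        fp = fp * np.exp(1j * (k + s / 2.0) * theta)
        fm = fm * np.exp(1j * (k - s / 2.0) * theta)
        zz = zz * np.exp(1j * k * theta)

    if s != 0:
        fp, fm = _shift_transverse(fp, fm, s, state.m0, truncation_tol, on_truncation)

    fm[..., 0] = np.conj(fp[..., 0])
    return EPGState(fp, fm, zz, state.m0)


def signal(state: EPGState):
    """Measurable echo signal: the order-0 transverse amplitude ``F_0``.

    Returns a complex scalar for unbatched states, an array otherwise.
    """
    s0 = state.f_plus[..., 0]
    return complex(s0) if s0.ndim == 0 else s0
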