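"""Modified Aliev–Panfilov phenomenological ionic model.

The two-variable model couples the normalized transmembrane potential
``phi`` (0 at rest, 1 at peak) with a recovery variable ``r``:

    f(phi, r) = c1 * phi * (phi - alpha) * (1 - phi) - c2 * r * phi
    g(phi, r) = (gamma + mu1 * r / (mu2 + phi)) * (-r - c2 * phi * (phi - b - 1))

Both are rates per millisecond, consistent with millisecond-valued time
steps and stimulus durations.  ``alpha`` is the excitation threshold of
the cubic source term; the ``c2 r phi`` term drives repolarization.  The
default parameter set (the "modified" calibration reproducing
physiological upstroke slopes and conduction velocities) is:

    alpha=0.05, c1=52, c2=8, mu1=0.1, mu2=0.3, b=0.25, gamma=0.002,
    Vr=-85 mV, Vp=15 mV, with initial recovery r0=0.1146.

Two time calibrations are supported through ``time_scale`` (tau):

* ``time_scale=1`` (default): f and g are rates per millisecond exactly
  as written above.
* ``time_scale=12.9``: the classical dimensionless-to-millisecond
  conversion of this two-variable model family (one model time unit =
  12.9 ms), i.e. both rates are divided by tau.  With the benchmark
  conductivity 0.0952 mm^2/ms this calibration yields a plane-wave
  conduction velocity of ~37 cm/s and an APD50 of ~190 ms — the
  physiological regime; with tau=1 the same conductivity gives ~135 cm/s
  and an APD50 of ~15 ms.  See docs/methods.md for the full argument.

Externally applied stimulus currents are physical rates (1/ms) and are
never divided by tau.  No clipping of ``phi`` to [0, 1] is performed
anywhere; transient overshoot is handled by the cubic's restoring terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "IonicParams",
    "MODIFIED_AP_PARAMS",
    "R0_DEFAULT",
    "AP_TIME_SCALE_MS",
    "ionic_current",
    "gating_rate",
    "dionic_dphi",
    "normalize_potential",
    "denormalize_potential",
    "gating_step",
    "gating_step_backward",
]

#: Default initial value of the recovery variable (steady-state regime).
R0_DEFAULT = 0.1146

#: Milliseconds per dimensionless time unit of the classical two-variable
#: phenomenological model; applying it to the rate functions puts the
#: kinetics in the physiological CV/APD regime (see module docstring).
AP_TIME_SCALE_MS = 12.9


@dataclass(frozen=True)
class IonicParams:
    """Modified Aliev–Panfilov constants plus resting/peak voltages (mV)."""

    alpha: float = 0.05
    c1: float = 52.0
    c2: float = 8.0
    mu1: float = 0.1
    mu2: float = 0.3
    b: float = 0.25
    gamma: float = 0.002
    Vr: float = -85.0
    Vp: float = 15.0
    r0: float = R0_DEFAULT
    time_scale: float = 1.0          # ms per model time unit (tau)

    def __post_init__(self) -> None:
        if self.Vp <= self.Vr:
            raise ValueError("peak voltage Vp must exceed resting voltage Vr")
        if self.time_scale <= 0:
            raise ValueError("time_scale must be positive")

    @property
    def v_range(self) -> float:
        """Vp - Vr in mV (the normalization span)."""
        return self.Vp - self.Vr


MODIFIED_AP_PARAMS = IonicParams()


def ionic_current(phi, r, params: IonicParams = MODIFIED_AP_PARAMS):
    """Normalized reaction term f(phi, r) in 1/ms (vectorizes elementwise)."""
    p = params
    phi = np.asarray(phi, dtype=float)
    r = np.asarray(r, dtype=float)
    return (p.c1 * phi * (phi - p.alpha) * (1.0 - phi) - p.c2 * r * phi) / p.time_scale


def dionic_dphi(phi, r, params: IonicParams = MODIFIED_AP_PARAMS):
    """Partial derivative df/dphi, used by the implicit Newton solver."""
    p = params
    phi = np.asarray(phi, dtype=float)
    r = np.asarray(r, dtype=float)
    return (p.c1 * (-3.0 * phi * phi + 2.0 * (1.0 + p.alpha) * phi - p.alpha)
            - p.c2 * r) / p.time_scale


def gating_rate(phi, r, params: IonicParams = MODIFIED_AP_PARAMS):
    """Recovery kinetics g(phi, r) in 1/ms (vectorizes elementwise)."""
    p = params
    phi = np.asarray(phi, dtype=float)
    r = np.asarray(r, dtype=float)
    denom = p.mu2 + phi
    if np.any(denom == 0.0):
        raise ZeroDivisionError("gating_rate: mu2 + phi vanished")
    return ((p.gamma + p.mu1 * r / denom)
            * (-r - p.c2 * phi * (phi - p.b - 1.0))) / p.time_scale


def normalize_potential(Vm, params: IonicParams = MODIFIED_AP_PARAMS):
    """Map transmembrane voltage (mV) to the normalized potential phi."""
    return (np.asarray(Vm, dtype=float) - params.Vr) / params.v_range


def denormalize_potential(phi, params: IonicParams = MODIFIED_AP_PARAMS):
    """Inverse of :func:`normalize_potential` (returns mV)."""
    return np.asarray(phi, dtype=float) * params.v_range + params.Vr


def gating_step(phi_n, r_n, dt: float, params: IonicParams = MODIFIED_AP_PARAMS):
    """One forward-Euler update r_{n+1} = r_n + dt * g(phi_n, r_n).

    Applied independently at each quadrature point; phi is held at t_n.
    """
    if dt < 0:
        raise ValueError("dt must be non-negative")
    return np.asarray(r_n, dtype=float) + dt * gating_rate(phi_n, r_n, params)


def gating_step_backward(phi, r_n, dt: float, params: IonicParams = MODIFIED_AP_PARAMS,
                         n_iter: int = 6):
    """Backward-Euler update solving r = r_n + dt * g(phi, r) pointwise.

    g is quadratic in r, so a few vectorized Newton iterations starting
    from r_n converge to machine precision for the time steps of interest.
    Used by the fully-implicit comparator scheme.
    """
    p = params
    phi = np.asarray(phi, dtype=float)
    r = np.asarray(r_n, dtype=float).copy()
    dtt = dt / p.time_scale
    B = p.mu1 / (p.mu2 + phi)
    C = p.c2 * phi * (phi - p.b - 1.0)
    for _ in range(n_iter):
        g = (p.gamma + B * r) * (-r - C)
        dg = -p.gamma - B * (2.0 * r + C)
        res = r - r_n - dtt * g
        r = r - res / (1.0 - dtt * dg)
    return r
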