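"""Excitation-driven active fiber tension and active second PK stress.

The active tension T_act [kPa] at a material point follows the first-order
evolution law

    dT_act/dt = eps(Phi) * [k_T (Phi - Phi_r) - T_act]

whose steady state under a sustained potential is k_T (Phi - Phi_r): with
k_T = 0.49 kPa/mV, rest at -80 mV and a +20 mV plateau this saturates at
49 kPa.  The activation rate

    eps(Phi) = eps0 + (eps_inf - eps0) * exp(-exp(-xi (Phi - Phi_bar)))

switches smoothly from a slow relaxation rate eps0 below Phi_bar to a fast
development rate eps_inf above it, so tension develops quickly on
depolarization and decays more slowly during repolarization.

The active stress is a rank-one fiber stress

    S_act = T_act * f0 (x) f0 / I4f ,

normalized by I4f so that the push-forward Cauchy stress carries exactly the
tension T_act along the deformed fiber direction, independent of stretch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .constitutive import DeformationState

__all__ = ["ActiveParams", "epsilon_rate", "tension_update", "pk2_active",
           "tangent_active", "dS_act_dPhi"]


@dataclass
class ActiveParams:
    """k_T [kPa/mV], resting potential Phi_r [mV], rate constants [1/ms, 1/mV, mV]."""
    k_T: float = 0.49
    Phi_r: float = -80.0
    eps0: float = 0.1
    eps_inf: float = 1.0
    xi: float = 1.0
    Phi_bar: float = 0.0

    def __post_init__(self):
        if self.k_T <= 0:
            raise ValueError("k_T must be positive")
        if self.eps0 <= 0 or self.eps_inf <= 0:
            raise ValueError("rate constants must be positive")


def epsilon_rate(Phi, p: ActiveParams):
    """Activation rate eps(Phi) [1/ms] and its derivative deps/dPhi."""
    Phi = np.asarray(Phi, dtype=float)
    inner = np.exp(-p.xi * (Phi - p.Phi_bar))
    outer = np.exp(-inner)
    eps = p.eps0 + (p.eps_inf - p.eps0) * outer
    deps = (p.eps_inf - p.eps0) * outer * inner * p.xi
    return eps, deps


def tension_update(T_old, Phi, dt: float, p: ActiveParams):
    """Backward-Euler step of the tension evolution law.

    Returns ``(T_new, dT_new/dPhi)``; the sensitivity (including the
    rate-switch derivative) enters the mechanical-electrical coupling block
    of the global Jacobian.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    T_old = np.asarray(T_old, dtype=float)
    Phi = np.asarray(Phi, dtype=float)
    eps, deps = epsilon_rate(Phi, p)
    target = p.k_T * (Phi - p.Phi_r)
    T = (T_old + dt * eps * target) / (1.0 + dt * eps)
    dT = dt * (eps * p.k_T + deps * (target - T)) / (1.0 + dt * eps)
    return T, dT


def pk2_active(T_act, state: DeformationState) -> np.ndarray:
    """Active second Piola-Kirchhoff stress T_act * f0(x)f0 / I4f."""
    f0 = np.broadcast_to(state.frame.f0, state.C.shape[:-2] + (3,))
    ff = np.einsum("...i,...j->...ij", f0, f0)
    return (np.asarray(T_act) / state.I4f)[..., None, None] * ff


def tangent_active(T_act, state: DeformationState) -> np.ndarray:
    """dS_act/dC = -T_act / I4f^2 * (f0 f0) (x) (f0 f0)."""
    f0 = np.broadcast_to(state.frame.f0, state.C.shape[:-2] + (3,))
    ff = np.einsum("...i,...j->...ij", f0, f0)
    coef = (-np.asarray(T_act) / state.I4f ** 2)[..., None, None, None, None]
    return coef * np.einsum("...ij,...kl->...ijkl", ff, ff)


def dS_act_dPhi(dT_dPhi, state: DeformationState) -> np.ndarray:
    """Sensitivity of the active stress to the potential at fixed C."""
    f0 = np.broadcast_to(state.frame.f0, state.C.shape[:-2] + (3,))
    ff = np.einsum("...i,...j->...ij", f0, f0)
    return (np.asarray(dT_dPhi) / state.I4f)[..., None, None] * ff
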