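"""Aliev-Panfilov excitation kinetics, conduction and stretch feedback.

The transmembrane potential is evolved by a monodomain reaction-diffusion
equation in the material (reference) configuration.  The reaction part is the
two-variable Aliev-Panfilov model in dimensionless potential ``phi`` and
recovery variable ``r``::

    dphi/dtbar = c phi (phi - alpha)(1 - phi) - r phi + I
    dr/dtbar   = [gamma + mu1 r / (mu2 + phi)] * [-r - c phi (phi - b - 1)]

with the affine conversion to physical units ``Phi = k_phi * phi - delta_phi``
(mV) and ``t = k_t * tbar`` (ms).  With the default scaling, phi = 0 is the
-80 mV resting state and phi = 0.6 corresponds to -20 mV.

Deformation enters twice:

* the material conductivity tensor ``D = J d_iso C^-1 + J d_ani f0 (x) f0 /
  lambda^2`` stiffens conduction along the (deformed) fiber direction;
* the stretch-activated-channel current ``f_m = theta * G_s (lambda - 1)
  (phi_s - phi)`` (mechano-electrical feedback, MEF) depolarizes stretched
  tissue; the switch theta is on strictly for fiber stretch lambda > 1.

Both dimensionless currents are scaled once, by k_phi / k_t, when they enter
the physical source term of the monodomain equation - never inside the
kinetics themselves.

The recovery update used inside the implicit time stepper is a backward-Euler
step of the recovery ODE; because the rate is quadratic in r it reduces to a
scalar quadratic with a closed-form root, together with the consistent
sensitivity dr/dphi needed for the coupled Newton Jacobian.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .constitutive import DeformationState, DegenerateElementError

__all__ = [
    "ElectroParams",
    "to_physical",
    "to_dimensionless",
    "f_e",
    "df_e_dphi",
    "df_e_dr",
    "recovery_rhs",
    "recovery_update",
    "f_m",
    "df_m_dphi",
    "conductivity",
    "flux",
    "integrate_cell",
]


@dataclass
class ElectroParams:
    """Aliev-Panfilov constants, unit scaling, conduction and MEF parameters.

    alpha : dimensionless oscillation threshold (0 < alpha < 1)
    c     : dimensionless reaction rate scale
    I_ext : dimensionless external stimulus current
    gamma, mu1, mu2, b_rec : recovery-law constants
    k_phi [mV], delta_phi [mV], k_t [ms] : dimensional conversion
    d_iso, d_ani [mm^2/ms] : isotropic / extra fiber conduction
    G_s : maximum stretch-activated channel conductance (dimensionless)
    phi_s : dimensionless reversal potential of those channels
    """

    alpha: float = 0.01
    c: float = 8.0
    I_ext: float = 0.0
    gamma: float = 0.002
    mu1: float = 0.2
    mu2: float = 0.3
    b_rec: float = 0.15
    k_phi: float = 100.0
    delta_phi: float = 80.0
    k_t: float = 12.9
    d_iso: float = 0.1
    d_ani: float = 0.3
    G_s: float = 0.0
    phi_s: float = 0.6

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.k_phi <= 0 or self.k_t <= 0:
            raise ValueError("k_phi and k_t must be positive")
        if self.d_iso <= 0 or self.d_ani < 0:
            raise ValueError("d_iso > 0 and d_ani >= 0 required")
        if self.G_s < 0:
            raise ValueError("G_s must be non-negative")
        if not (0.0 <= self.phi_s <= 1.0):
            raise ValueError("phi_s must lie in [0, 1]")


# -- dimensional conversion ------------------------------------------------

def to_physical(phi, p: ElectroParams):
    """Dimensionless potential -> physical potential [mV]."""
    return p.k_phi * np.asarray(phi) - p.delta_phi


def to_dimensionless(Phi, p: ElectroParams):
    """Physical potential [mV] -> dimensionless potential."""
    return (np.asarray(Phi) + p.delta_phi) / p.k_phi


# -- Aliev-Panfilov kinetics ----------------------------------------------

def f_e(phi, r, p: ElectroParams):
    """Dimensionless excitation current c*phi*(phi-alpha)*(1-phi) - r*phi + I."""
    phi = np.asarray(phi)
    return p.c * phi * (phi - p.alpha) * (1.0 - phi) - np.asarray(r) * phi + p.I_ext


def df_e_dphi(phi, r, p: ElectroParams):
    phi = np.asarray(phi)
    return p.c * (-3.0 * phi ** 2 + 2.0 * (1.0 + p.alpha) * phi - p.alpha) - np.asarray(r)


def df_e_dr(phi, r, p: ElectroParams):
    return -np.asarray(phi)


def recovery_rhs(phi, r, p: ElectroParams):
    """dr/dtbar of the recovery variable (repolarization controller)."""
    phi = np.asarray(phi)
    r = np.asarray(r)
    return (p.gamma + p.mu1 * r / (p.mu2 + phi)) * (
        -r - p.c * phi * (phi - p.b_rec - 1.0))


def recovery_update(phi, r_old, dtbar: float, p: ElectroParams):
    """Backward-Euler update of r over a dimensionless step dtbar.

    Solves ``r = r_old + dtbar * recovery_rhs(phi, r)`` in closed form (the
    rate is quadratic in r) and returns ``(r_new, dr_new/dphi)``; the
    sensitivity is obtained by implicit differentiation and feeds the
    potential-equation Jacobian.
    """
    phi = np.asarray(phi, dtype=float)
    r_old = np.asarray(r_old, dtype=float)
    B = p.mu1 / (p.mu2 + phi)
    q = p.c * phi * (phi - p.b_rec - 1.0)
    # quadratic  a2 r^2 + beta r + c0 = 0
    a2 = dtbar * B
    beta = 1.0 + dtbar * (p.gamma + B * q)
    c0 = dtbar * p.gamma * q - r_old
    disc = np.maximum(beta ** 2 - 4.0 * a2 * c0, 0.0)
    r = -2.0 * c0 / (beta + np.sqrt(disc))
    # implicit sensitivity: f(r, phi) = r - r_old - dtbar*G(r, phi) = 0
    dG_dr = B * (-r - q) - (p.gamma + B * r)
    dB_dphi = -p.mu1 / (p.mu2 + phi) ** 2
    dq_dphi = p.c * (2.0 * phi - p.b_rec - 1.0)
    dG_dphi = dB_dphi * r * (-r - q) - (p.gamma + B * r) * dq_dphi
    dr_dphi = dtbar * dG_dphi / (1.0 - dtbar * dG_dr)
    return r, dr_dphi


# -- mechano-electrical feedback ------------------------------------------

def f_m(lam, phi, p: ElectroParams):
    """Stretch-activated-channel current theta*G_s*(lam-1)*(phi_s-phi).

    theta is the sharp tension switch: the current flows only for fiber
    stretch lam > 1 (stretch-induced channel opening).
    """
    lam = np.asarray(lam)
    theta = (lam > 1.0).astype(float)
    return theta * p.G_s * (lam - 1.0) * (p.phi_s - np.asarray(phi))


def df_m_dphi(lam, phi, p: ElectroParams):
    lam = np.asarray(lam)
    theta = (lam > 1.0).astype(float)
    return -theta * p.G_s * (lam - 1.0)


# -- conduction ------------------------------------------------------------

def conductivity(state: DeformationState, p: ElectroParams) -> np.ndarray:
    """Material conductivity tensor D = J d_iso C^-1 + J d_ani f0(x)f0 / lam^2."""
    J = state.J
    f0 = np.broadcast_to(state.frame.f0, state.C.shape[:-2] + (3,))
    ff = np.einsum("...i,...j->...ij", f0, f0)
    if np.any(~np.isfinite(state.Cinv)):
        raise DegenerateElementError("singular C in conductivity")
    return (p.d_iso * J)[..., None, None] * state.Cinv \
        + (p.d_ani * J / state.I4f)[..., None, None] * ff


def flux(state: DeformationState, grad_Phi, p: ElectroParams) -> np.ndarray:
    """Material electrical flux Q = D * Grad(Phi)  [mV mm / ms]."""
    D = conductivity(state, p)
    return np.einsum("...ij,...j->...i", D, np.asarray(grad_Phi))


# -- single-cell integration ----------------------------------------------

def integrate_cell(p: ElectroParams, phi0: float, r0: float = 0.0, *,
                   t_end: float = 500.0, dt: float = 0.01,
                   stimulus: Callable[[float], float] | None = None):
    """Integrate the space-clamped cell with the same backward-Euler scheme
    as the tissue solver.

    Returns ``(t, phi, r)`` arrays sampled at every step (t in ms).  A
    time-dependent dimensionless stimulus can be supplied; it adds to f_e.
    """
    n = int(round(t_end / dt))
    t = np.linspace(0.0, n * dt, n + 1)
    phi = np.empty(n + 1)
    r = np.empty(n + 1)
    phi[0], r[0] = phi0, r0
    dtbar = dt / p.k_t
    for k in range(n):
        ph = phi[k]
        stim = 0.0 if stimulus is None else stimulus(t[k + 1])
        # Newton in phi with the BE-consistent recovery update chained in
        for _ in range(50):
            rn, drdphi = recovery_update(ph, r[k], dtbar, p)
            g = ph - phi[k] - dtbar * (f_e(ph, rn, p) + stim)
            dg = 1.0 - dtbar * (df_e_dphi(ph, rn, p) + df_e_dr(ph, rn, p) * drdphi)
            dph = -g / dg
            ph += dph
            if abs(dph) < 1e-13:
                break
        phi[k + 1] = ph
        r[k + 1], _ = recovery_update(ph, r[k], dtbar, p)
    return t, phi, r
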