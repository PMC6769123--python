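"""Monolithic implicit finite-element solver for coupled electromechanics.

Discretizes, on hex8 or tet4 meshes in the reference configuration:

* quasi-static balance of linear momentum, Div(F S) + body force = 0, with
  S = S_pas(C) + S_act(f0, Phi);
* the monodomain potential equation, dPhi/dt = Div(D Grad Phi) + F^Phi, with
  deformation-dependent conductivity D(C) and the source split into the
  Aliev-Panfilov current and the stretch-activated (MEF) current.

Time integration is backward Euler for the potential and for both internal
variables (recovery r and active tension T_act, stored per quadrature
point and updated *inside* each Newton iteration so the linearization is
consistent).  The two fields are solved monolithically: each Newton step
assembles the full 4x4-block Jacobian including the coupling blocks
(active-stress dR_u/dPhi; conductivity- and MEF-derived dR_Phi/du) and
solves the sparse system directly.  On non-convergence the step is halved
and retried (up to ``max_halvings`` levels).

Units: mm, ms, kPa, mV; the derived force unit is mN (1 kPa x 1 mm^2).
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from . import active_stress as act
from . import electrophysiology as ep
from .constitutive import (DeformationState, Frame, PassiveLaw,
                           DegenerateElementError, NonphysicalStrainError)
from .geometry import Mesh

__all__ = ["SolverConfig", "SystemState", "Protocol", "NewtonError",
           "CoupledProblem", "newton_solve", "run", "SimulationResult",
           "hex8_reference", "tet4_reference"]


_ES_PATHS: dict = {}


def _es(subscripts, *ops, **kw):
    """np.einsum with cached contraction paths (hot assembly loops)."""
    key = (subscripts, tuple(op.shape for op in ops))
    path = _ES_PATHS.get(key)
    if path is None:
        path = np.einsum_path(subscripts, *ops, optimize="greedy")[0]
        _ES_PATHS[key] = path
    return np.einsum(subscripts, *ops, optimize=path, **kw)


class NewtonError(RuntimeError):
    """Newton iteration failed; carries diagnostics."""

    def __init__(self, msg, residual_norms=None, iterations=None):
        super().__init__(msg)
        self.residual_norms = residual_norms
        self.iterations = iterations


# --------------------------------------------------------------------------
# reference elements
# --------------------------------------------------------------------------

_HEX_CORNERS = np.array([[-1, -1, -1], [1, -1, -1], [1, 1, -1], [-1, 1, -1],
                         [-1, -1, 1], [1, -1, 1], [1, 1, 1], [-1, 1, 1]],
                        dtype=float)


def _hex_shape(xi):
    """Values and gradients of the 8 trilinear shape functions at points xi."""
    xi = np.atleast_2d(xi)
    s = _HEX_CORNERS[None, :, :]                    # (1, 8, 3)
    x = xi[:, None, :]                              # (Q, 1, 3)
    terms = 1.0 + s * x                             # (Q, 8, 3)
    N = 0.125 * terms.prod(axis=2)
    dN = np.empty((xi.shape[0], 8, 3))
    for d in range(3):
        others = [i for i in range(3) if i != d]
        dN[:, :, d] = 0.125 * s[:, :, d] * terms[:, :, others].prod(axis=2)
    return N, dN


def hex8_reference(reduced: bool = False):
    """(dN/dxi (Q,8,3), weights (Q,)) of 2x2x2 Gauss (or 1-pt center)."""
    if reduced:
        pts = np.zeros((1, 3))
        w = np.array([8.0])
    else:
        g = 1.0 / np.sqrt(3.0)
        pts = np.array([[sx * g, sy * g, sz * g]
                        for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
        w = np.ones(8)
    _, dN = _hex_shape(pts)
    return dN, w


def hex8_shape(reduced: bool = False):
    if reduced:
        pts = np.zeros((1, 3))
    else:
        g = 1.0 / np.sqrt(3.0)
        pts = np.array([[sx * g, sy * g, sz * g]
                        for sx in (-1, 1) for sy in (-1, 1) for sz in (-1, 1)])
    N, _ = _hex_shape(pts)
    return N


def tet4_reference():
    """4-point degree-2 quadrature on the reference tetrahedron.

    The deformation gradient of a linear tet is constant, so mechanics is
    unchanged vs 1-point quadrature; the extra points integrate the
    potential 'mass' term N_a N_b exactly.
    """
    a, b = 0.5854101966249685, 0.1381966011250105
    bary = np.array([[a, b, b, b], [b, a, b, b], [b, b, a, b], [b, b, b, a]])
    w = np.full(4, 1.0 / 24.0)        # reference tet volume 1/6
    N = bary
    dN = np.tile(np.array([[-1.0, -1, -1], [1, 0, 0], [0, 1, 0], [0, 0, 1]]),
                 (4, 1, 1))
    return N, dN, w


# --------------------------------------------------------------------------
# configuration / state / protocol
# --------------------------------------------------------------------------

@dataclass
class SolverConfig:
    """Time step, Newton controls and formulation flags."""

    dt: float = 0.5                      # ms
    newton_tol_mech: float = 1e-5        # mN (inf-norm of mech residual)
    newton_tol_phi: float = 1e-5         # potential-equation residual
    newton_tol_dx: float = 1e-9          # increment inf-norm (mm / mV); a
    # vanishing update is accepted even if the sharp tension switches keep
    # the residual chattering marginally above the force tolerance
    newton_stall_mech: float = 1e-2      # mN; the sharp Heaviside switches
    newton_stall_phi: float = 1e-3       # make the tangent discontinuous, so
    # Newton can cycle between switch branches with a small bounded
    # residual; a stalled best iterate below these (still physically
    # negligible) levels is accepted instead of halving dt forever
    max_newton: int = 25
    max_halvings: int = 5
    mean_dilatation: bool = False        # reduced quadrature for kappa(J-1)^2
    output_every: int = 1                # record cadence (global steps)
    record_energy: bool = False
    verbose: bool = False

    def __post_init__(self):
        if self.dt <= 0 or self.newton_tol_mech <= 0 or self.newton_tol_phi <= 0:
            raise ValueError("dt and tolerances must be positive")


@dataclass
class SystemState:
    """Nodal displacement/potential and quadrature-point internal variables."""

    u: np.ndarray                        # (N, 3) mm
    Phi: np.ndarray                      # (N,) mV
    r: np.ndarray                        # (E, Q) recovery variable
    T_act: np.ndarray                    # (E, Q) kPa
    t: float = 0.0

    def copy(self) -> "SystemState":
        return SystemState(self.u.copy(), self.Phi.copy(), self.r.copy(),
                           self.T_act.copy(), self.t)


@dataclass
class Protocol:
    """Boundary conditions, loads, stimulus and probe schedule.

    mech_dirichlet : list of (node_set, components, value or fn(t)->value)
    phi_dirichlet  : list of (node_set, fn(t) -> value in mV or None);
                     None deactivates the constraint (stimulus release)
    loads          : list of (node_set, direction (3,), total force fn(t) [mN])
                     -- dead loads, split equally over the set's nodes
    probes         : dict name -> node id
    """

    t_end: float
    mech_dirichlet: list = field(default_factory=list)
    phi_dirichlet: list = field(default_factory=list)
    loads: list = field(default_factory=list)
    probes: Dict[str, int] = field(default_factory=dict)
    phi_init: float = -80.0
    stop_when_depolarized: bool = False
    depol_threshold: float = 0.0         # mV


# --------------------------------------------------------------------------
# the coupled problem
# --------------------------------------------------------------------------

class CoupledProblem:
    """Precomputed discrete operators for one mesh + parameter set."""

    def __init__(self, mesh: Mesh, law: PassiveLaw, electro: ep.ElectroParams,
                 active: act.ActiveParams, config: SolverConfig | None = None):
        self.mesh = mesh
        self.law = law
        self.electro = electro
        self.active = active
        self.config = config or SolverConfig()

        if mesh.cell_type == "tet4" and getattr(law.params, "kappa", 0) >= 1e3 \
                and not self.config.mean_dilatation:
            warnings.warn(
                "near-incompressible material on linear tetrahedra in pure "
                "displacement form is prone to volumetric locking",
                stacklevel=2)

        X = mesh.points[mesh.cells]                       # (E, nen, 3)
        if mesh.cell_type == "hex8":
            dN_ref, w_ref = hex8_reference()
            self.Nsh = hex8_shape()                       # (Q, nen)
        else:
            self.Nsh, dN_ref, w_ref = tet4_reference()
        Jg = _es("qam,ean->eqmn", dN_ref, X)        # dX/dxi
        detJ = np.linalg.det(Jg)
        if np.any(detJ <= 0):
            bad = np.unique(np.argwhere(detJ <= 0)[:, 0])
            raise DegenerateElementError(
                f"non-positive reference Jacobian in elements {bad.tolist()[:10]}")
        Jinv = np.linalg.inv(Jg)
        self.gradN = _es("eqnm,qan->eqam", Jinv, dN_ref)  # dN/dX
        self.wdet = detJ * w_ref[None, :]
        self.n_qp = self.wdet.shape[1]

        # reduced (center) quadrature for the volumetric penalty, hex only
        self.sri = (self.config.mean_dilatation and mesh.cell_type == "hex8"
                    and getattr(law.params, "kappa", None) is not None)
        if self.sri:
            dN0, w0 = hex8_reference(reduced=True)
            Jg0 = _es("qam,ean->eqmn", dN0, X)
            self.gradN0 = _es("eqnm,qan->eqam", np.linalg.inv(Jg0), dN0)
            self.wdet0 = np.linalg.det(Jg0) * w0[None, :]

        E, nen = mesh.cells.shape
        N = mesh.n_nodes
        self.n_dof = 4 * N
        edof_u = (3 * mesh.cells[:, :, None] + np.arange(3)).reshape(E, 3 * nen)
        edof_p = 3 * N + mesh.cells
        self.edof = np.concatenate([edof_u, edof_p], axis=1)   # (E, m)
        m = self.edof.shape[1]
        self.K_rows = np.repeat(self.edof, m, axis=1).ravel()
        self.K_cols = np.tile(self.edof, (1, m)).ravel()
        # precomputed CSC pattern (full diagonal appended so Dirichlet rows
        # never change the sparsity): data -> permute -> segment-sum
        diag = np.arange(self.n_dof)
        rows_all = np.concatenate([self.K_rows, diag])
        cols_all = np.concatenate([self.K_cols, diag])
        order = np.lexsort((rows_all, cols_all))
        rs, cs = rows_all[order], cols_all[order]
        starts = np.flatnonzero(
            np.r_[True, (rs[1:] != rs[:-1]) | (cs[1:] != cs[:-1])])
        self._csc_order = order
        self._csc_starts = starts
        self._csc_indices = rs[starts]
        self._csc_indptr = np.searchsorted(cs[starts], np.arange(self.n_dof + 1))
        f0 = mesh.frames.f0[:, None, :]                        # (E,1,3)
        self._frame_q = Frame(f0=f0, s0=mesh.frames.s0[:, None, :],
                              n0=mesh.frames.n0[:, None, :])
        self._warned_band = False

    # -- kinematics --------------------------------------------------------

    def _deformation(self, u: np.ndarray, gradN=None) -> DeformationState:
        gradN = self.gradN if gradN is None else gradN
        u_e = u[self.mesh.cells]                              # (E, nen, 3)
        F = np.eye(3) + _es("eai,eqaK->eqiK", u_e, gradN)
        return DeformationState.from_F(F, self._frame_q)

    # -- element-level residual and Jacobian ------------------------------

    def element_system(self, state_n: SystemState, u: np.ndarray,
                       Phi: np.ndarray, dt: float, want_jac: bool = True):
        """Dense element residuals/Jacobians for the coupled weak form.

        Returns ``(R_e (E, m), K_e (E, m, m) | None, internals)`` with the
        element dof ordering [u dofs | Phi dofs].  ``internals`` holds the
        backward-Euler-updated quadrature-point fields (r, T_act) plus
        diagnostics (J, lam).
        """
        mesh, p, ap = self.mesh, self.electro, self.active
        E, nen = mesh.cells.shape
        m = 4 * nen
        part = "dev" if self.sri else "full"

        st = self._deformation(u)
        F, S_state = st.F, st
        Phi_e = Phi[mesh.cells]                               # (E, nen)
        Phi_en = state_n.Phi[mesh.cells]
        Phi_q = _es("qa,ea->eq", self.Nsh, Phi_e)
        Phi_qn = _es("qa,ea->eq", self.Nsh, Phi_en)
        gPhi = _es("eqaK,ea->eqK", self.gradN, Phi_e)
        phi_q = ep.to_dimensionless(Phi_q, p)

        if not self._warned_band and (Phi_q.min() < -100.0 or Phi_q.max() > 60.0):
            warnings.warn("potential left the [-100, 60] mV sanity band",
                          stacklevel=2)
            self._warned_band = True

        # internal variables (backward Euler from the step-start values)
        r_new, dr_dphi = ep.recovery_update(phi_q, state_n.r, dt / p.k_t, p)
        T_new, dT_dPhi = act.tension_update(state_n.T_act, Phi_q, dt, ap)

        S = self.law.pk2(st, part=part) + act.pk2_active(T_new, st)
        R_u = _es("eqiJ,eqJK,eqaK,eq->eai", F, S, self.gradN, self.wdet)

        D = ep.conductivity(st, p)
        fe = ep.f_e(phi_q, r_new, p)
        fm = ep.f_m(st.lam, phi_q, p)
        src = (p.k_phi / p.k_t) * (fe + fm)
        Dg = _es("eqKL,eqL->eqK", D, gPhi)
        R_p = (_es("qa,eq,eq->ea", self.Nsh, (Phi_q - Phi_qn) / dt, self.wdet)
               + _es("eqaK,eqK,eq->ea", self.gradN, Dg, self.wdet)
               - _es("qa,eq,eq->ea", self.Nsh, src, self.wdet))

        st0 = None
        if self.sri:
            st0 = self._deformation(u, gradN=self.gradN0)
            S0 = self.law.pk2(st0, part="vol")
            R_u = R_u + _es("eqiJ,eqJK,eqaK,eq->eai",
                                  st0.F, S0, self.gradN0, self.wdet0)

        R_e = np.empty((E, m))
        R_e[:, :3 * nen] = R_u.reshape(E, -1)
        R_e[:, 3 * nen:] = R_p
        internals = {"r": r_new, "T_act": T_new, "J": st.J, "lam": st.lam,
                     "state": st}
        if not want_jac:
            return R_e, None, internals

        f0q = np.broadcast_to(self._frame_q.f0, (E, self.n_qp, 3))
        gN = self.gradN
        wd = self.wdet

        # ---- K_uu: geometric + material (passive + active C-dependence)
        CC = self.law.tangent(st, part=part) + act.tangent_active(T_new, st)
        T1 = _es("eqJKMN,eqmM->eqJKNm", CC, F)
        T2 = _es("eqJKNm,eqbN->eqJKbm", T1, gN)
        T3 = _es("eqiJ,eqJKbm->eqiKbm", F, T2)
        K_uu = 2.0 * _es("eqaK,eqiKbm,eq->eaibm", gN, T3, wd)
        geo = _es("eqaJ,eqJK,eqbK,eq->eab", gN, S, gN, wd)
        K_uu += _es("eab,im->eaibm", geo, np.eye(3))
        if self.sri:
            CC0 = self.law.tangent(st0, part="vol")
            T1 = _es("eqJKMN,eqmM->eqJKNm", CC0, st0.F)
            T2 = _es("eqJKNm,eqbN->eqJKbm", T1, self.gradN0)
            T3 = _es("eqiJ,eqJKbm->eqiKbm", st0.F, T2)
            K_uu += 2.0 * _es("eqaK,eqiKbm,eq->eaibm",
                                    self.gradN0, T3, self.wdet0)
            geo0 = _es("eqaJ,eqJK,eqbK,eq->eab",
                             self.gradN0, S0, self.gradN0, self.wdet0)
            K_uu += _es("eab,im->eaibm", geo0, np.eye(3))

        # ---- K_uPhi: active tension sensitivity
        Ff = _es("eqiJ,eqJ->eqi", F, f0q)
        fgN = _es("eqJ,eqaJ->eqa", f0q, gN)
        K_up = _es("eqi,eqa,eq,qb,eq->eaib",
                         Ff, fgN, dT_dPhi / st.I4f, self.Nsh, wd)

        # ---- K_PhiPhi: mass + diffusion + reaction linearization
        dsrc = (1.0 / p.k_t) * (ep.df_e_dphi(phi_q, r_new, p)
                                + ep.df_e_dr(phi_q, r_new, p) * dr_dphi
                                + ep.df_m_dphi(st.lam, phi_q, p))
        K_pp = (_es("qa,qb,eq->eab", self.Nsh, self.Nsh, wd) / dt
                + _es("eqaK,eqKL,eqbL,eq->eab", gN, D, gN, wd)
                - _es("qa,qb,eq,eq->eab", self.Nsh, self.Nsh, dsrc, wd))

        # ---- K_Phiu: conductivity and MEF deformation sensitivities
        Ci = st.Cinv
        y = _es("eqKL,eqL->eqK", Ci, gPhi)              # C^-1 gradPhi
        xa = _es("eqKL,eqaL->eqaK", Ci, gN)             # C^-1 gradN_a
        FCi = _es("eqiK,eqKL->eqiL", F, Ci)
        hb = _es("eqmL,eqbL->eqbm", FCi, gN)            # (F C^-1 gradN_b)_m
        Fxa = _es("eqmM,eqaM->eqam", F, xa)
        Fy = _es("eqmM,eqM->eqm", F, y)
        gNy = _es("eqaK,eqK->eqa", gN, y)
        xa_gNb = _es("eqaK,eqbK->eqab", xa, gN)
        Jw = st.J * wd
        # each term contracts q immediately: (e,q,X) x (e,q,Y) -> (e,X,Y)
        K_pu = _es("eqa,eqbm->eabm", p.d_iso * Jw[..., None] * gNy, hb)
        K_pu -= p.d_iso * _es("eqam,eqb->eabm", Jw[..., None, None] * Fxa, gNy)
        K_pu -= p.d_iso * _es("eqab,eqm->eabm", Jw[..., None, None] * xa_gNb, Fy)
        fg = _es("eqK,eqK->eq", f0q, gPhi)
        dbeta = (Jw / st.I4f)[..., None, None] * hb \
            - 2.0 * _es("eq,eqm,eqb->eqbm", Jw / st.I4f ** 2, Ff, fgN)
        K_pu += p.d_ani * _es("eqa,eqbm->eabm", fg[..., None] * fgN, dbeta)
        theta = (st.lam > 1.0).astype(float)
        mef_w = -(p.k_phi / p.k_t) * p.G_s * wd * theta * (p.phi_s - phi_q) / st.lam
        K_pu += _es("eqa,eqbm->eabm", mef_w[..., None] * self.Nsh[None, :, :],
                    _es("eqm,eqb->eqbm", Ff, fgN))

        K_e = np.empty((E, m, m))
        K_e[:, :3 * nen, :3 * nen] = K_uu.reshape(E, 3 * nen, 3 * nen)
        K_e[:, :3 * nen, 3 * nen:] = K_up.reshape(E, 3 * nen, nen)
        K_e[:, 3 * nen:, :3 * nen] = K_pu.reshape(E, nen, 3 * nen)
        K_e[:, 3 * nen:, 3 * nen:] = K_pp
        return R_e, K_e, internals

    # -- global assembly ---------------------------------------------------

    def assemble(self, state_n: SystemState, u: np.ndarray, Phi: np.ndarray,
                 dt: float, want_jac: bool = True,
                 fixed: np.ndarray | None = None,
                 fixed_vals: np.ndarray | None = None,
                 f_ext: np.ndarray | None = None):
        """Global residual (and Jacobian) with symmetric-style Dirichlet rows.

        Constrained rows are replaced by ``x_c - target_c`` with a unit
        diagonal, so the Newton update lands exactly on the prescribed
        values.
        """
        R_e, K_e, internals = self.element_system(state_n, u, Phi, dt, want_jac)
        R = np.zeros(self.n_dof)
        np.add.at(R, self.edof.ravel(), R_e.ravel())
        if f_ext is not None:
            R -= f_ext
        x = np.concatenate([u.ravel(), Phi])
        if fixed is not None and fixed.size:
            R[fixed] = x[fixed] - fixed_vals
        K = None
        if want_jac:
            data = K_e.ravel()
            diag_extra = np.zeros(self.n_dof)
            if fixed is not None and fixed.size:
                is_fixed = np.zeros(self.n_dof, dtype=bool)
                is_fixed[fixed] = True
                data = np.where(is_fixed[self.K_rows], 0.0, data)
                diag_extra[fixed] = 1.0
            buf = np.concatenate([data, diag_extra])[self._csc_order]
            vals = np.add.reduceat(buf, self._csc_starts)
            K = sp.csc_matrix((vals, self._csc_indices, self._csc_indptr),
                              shape=(self.n_dof, self.n_dof))
        return R, K, internals

    # -- diagnostics -------------------------------------------------------

    def strain_energy(self, u: np.ndarray) -> float:
        st = self._deformation(u)
        part = "dev" if self.sri else "full"
        e = float(_es("eq,eq->", self.law.psi(st, part=part), self.wdet))
        if self.sri:
            st0 = self._deformation(u, gradN=self.gradN0)
            e += float(_es("eq,eq->", self.law.psi(st0, part="vol"),
                                 self.wdet0))
        return e


# --------------------------------------------------------------------------
# boundary conditions from a protocol
# --------------------------------------------------------------------------

def _value_at(val, t):
    return val(t) if callable(val) else val


def build_constraints(problem: CoupledProblem, protocol: Protocol, t: float,
                      u: np.ndarray, Phi: np.ndarray):
    """(fixed dof ids, target values, external force vector) at time t."""
    mesh = problem.mesh
    N = mesh.n_nodes
    fixed: List[np.ndarray] = []
    vals: List[np.ndarray] = []
    for set_name, comps, val in protocol.mech_dirichlet:
        nodes = mesh.node_sets[set_name]
        v = _value_at(val, t)
        for c in np.atleast_1d(comps):
            fixed.append(3 * nodes + int(c))
            vals.append(np.full(nodes.size, float(v)))
    for set_name, val in protocol.phi_dirichlet:
        v = _value_at(val, t)
        if v is None:
            continue
        nodes = mesh.node_sets[set_name]
        fixed.append(3 * N + nodes)
        vals.append(np.full(nodes.size, float(v)))
    f_ext = np.zeros(problem.n_dof)
    for set_name, direction, total in protocol.loads:
        nodes = mesh.node_sets[set_name]
        P = _value_at(total, t)
        if P == 0.0 or nodes.size == 0:
            continue
        per = np.asarray(direction, dtype=float) * (float(P) / nodes.size)
        for c in range(3):
            f_ext[3 * nodes + c] += per[c]
    if fixed:
        return np.concatenate(fixed), np.concatenate(vals), f_ext
    return np.empty(0, dtype=int), np.empty(0), f_ext


# --------------------------------------------------------------------------
# Newton solve and time stepping
# --------------------------------------------------------------------------

def newton_solve(problem: CoupledProblem, state: SystemState, dt: float,
                 t_new: float, protocol: Protocol):
    """Advance one backward-Euler step with a monolithic Newton iteration.

    Returns ``(new_state, info)``; raises :class:`NewtonError` on failure.
    """
    cfg = problem.config
    u = state.u.copy()
    Phi = state.Phi.copy()
    fixed, vals, f_ext = build_constraints(problem, protocol, t_new, u, Phi)
    Nn = problem.mesh.n_nodes
    history = []
    internals = None
    best = None
    for it in range(cfg.max_newton + 1):
        R, K, internals = problem.assemble(state, u, Phi, dt, True,
                                           fixed, vals, f_ext)
        rm = np.abs(R[:3 * Nn]).max() if Nn else 0.0
        rp = np.abs(R[3 * Nn:]).max()
        history.append((rm, rp))
        if cfg.verbose:
            print(f"    newton {it}: |R_u|={rm:.3e} |R_phi|={rp:.3e}")
        if rm < cfg.newton_tol_mech and rp < cfg.newton_tol_phi:
            new = SystemState(u=u, Phi=Phi, r=internals["r"],
                              T_act=internals["T_act"], t=t_new)
            return new, {"iterations": it, "residuals": history,
                         "internals": internals}
        if best is None or max(rm, rp) < max(best[0], best[1]):
            best = (rm, rp, u.copy(), Phi.copy(), internals, it)
        stalled = (it >= 6 and history[-1][0] > 0.5 * history[-4][0]
                   and (history[-1][1] > 0.5 * history[-4][1]
                        or history[-1][1] < cfg.newton_tol_phi))
        if (it == cfg.max_newton or stalled) \
                and best[0] < cfg.newton_stall_mech \
                and best[1] < cfg.newton_stall_phi:
            rm, rp, ub, Pb, internb, itb = best
            new = SystemState(u=ub, Phi=Pb, r=internb["r"],
                              T_act=internb["T_act"], t=t_new)
            return new, {"iterations": it, "residuals": history,
                         "internals": internb, "stalled": True}
        if it == cfg.max_newton:
            break
        perm = "COLAMD" if problem.n_dof < 2000 else "MMD_AT_PLUS_A"
        lu = spla.splu(K, permc_spec=perm)
        dx = lu.solve(-R)
        if not np.all(np.isfinite(dx)):
            raise NewtonError("non-finite Newton update", history, it)
        u = u + dx[:3 * Nn].reshape(-1, 3)
        Phi = Phi + dx[3 * Nn:]
        if it > 0 and np.abs(dx).max() < cfg.newton_tol_dx:
            # update below resolution: accept (sharp Heaviside switches can
            # pin the residual marginally above the force tolerance)
            R, _, internals = problem.assemble(state, u, Phi, dt, False,
                                               fixed, vals, f_ext)
            new = SystemState(u=u, Phi=Phi, r=internals["r"],
                              T_act=internals["T_act"], t=t_new)
            return new, {"iterations": it + 1, "residuals": history,
                         "internals": internals}
    raise NewtonError(
        f"Newton failed to converge in {cfg.max_newton} iterations at "
        f"t={t_new:.3f} ms (last |R_u|={history[-1][0]:.3e}, "
        f"|R_phi|={history[-1][1]:.3e})", history, cfg.max_newton)


def _advance(problem, state, dt, protocol, depth=0):
    """Advance by dt with recursive halving on failure."""
    try:
        new, info = newton_solve(problem, state, dt, state.t + dt, protocol)
        return new, info
    except (NewtonError, DegenerateElementError, NonphysicalStrainError):
        if depth >= problem.config.max_halvings:
            raise
        half = dt / 2.0
        mid, _ = _advance(problem, state, half, protocol, depth + 1)
        return _advance(problem, mid, half, protocol, depth + 1)


@dataclass
class SimulationResult:
    """Probe traces, per-step summary and (optionally) state snapshots."""

    probes: Dict[str, pd.DataFrame]
    summary: pd.DataFrame
    snapshots: list
    final_state: SystemState
    depolarization_time: float | None = None

    def save(self, out_dir, problem: CoupledProblem | None = None,
             manifest: dict | None = None):
        """Write probes.csv, summary.csv, manifest.json and VTU snapshots."""
        import pathlib
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.probes.items():
            df.to_csv(out / f"probe_{name}.csv", index=False)
        self.summary.to_csv(out / "summary.csv", index=False)
        if manifest is not None:
            (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                          default=str))
        if problem is not None and self.snapshots:
            from .io_vtu import write_vtu
            for i, snap in enumerate(self.snapshots):
                write_vtu(out / f"state_{i:04d}.vtu", problem.mesh,
                          point_data={"u": snap["u"], "Phi": snap["Phi"]},
                          cell_data={"lambda": snap["lam"], "J": snap["J"],
                                     "T_act": snap["T_act"]})


def run(problem: CoupledProblem, protocol: Protocol,
        initial: SystemState | None = None,
        keep_snapshots: bool = False) -> SimulationResult:
    """Integrate the coupled problem from t=0 to protocol.t_end.

    Records probe traces (t, Phi, u) and a per-step summary (potential
    range, depolarized fraction, J and fiber-stretch ranges, Newton
    iterations, optionally total passive strain energy).  The
    depolarization-completion time (first time every node exceeds the
    threshold) is interpolated between steps when crossed.
    """
    cfg = problem.config
    mesh = problem.mesh
    E, Q = problem.wdet.shape
    if initial is None:
        state = SystemState(u=np.zeros((mesh.n_nodes, 3)),
                            Phi=np.full(mesh.n_nodes, protocol.phi_init),
                            r=np.zeros((E, Q)), T_act=np.zeros((E, Q)), t=0.0)
    else:
        state = initial.copy()

    probe_rows = {name: [] for name in protocol.probes}
    summary_rows = []
    snapshots = []
    depol_time = None
    prev_min = state.Phi.min()

    def record(state, info=None):
        for name, node in protocol.probes.items():
            ux, uy, uz = state.u[node]
            probe_rows[name].append(
                dict(t=state.t, Phi=state.Phi[node], ux=ux, uy=uy, uz=uz,
                     u=float(np.linalg.norm(state.u[node]))))
        row = dict(t=state.t, Phi_min=float(state.Phi.min()),
                   Phi_max=float(state.Phi.max()),
                   frac_depolarized=float(np.mean(
                       state.Phi > protocol.depol_threshold)))
        if info is not None:
            row["newton_iters"] = info["iterations"]
            row["J_min"] = float(info["internals"]["J"].min())
            row["J_max"] = float(info["internals"]["J"].max())
            row["lam_max"] = float(info["internals"]["lam"].max())
        if cfg.record_energy:
            row["strain_energy"] = problem.strain_energy(state.u)
        summary_rows.append(row)
        if keep_snapshots and info is not None:
            snapshots.append(dict(t=state.t, u=state.u.copy(),
                                  Phi=state.Phi.copy(),
                                  lam=info["internals"]["lam"].mean(axis=1),
                                  J=info["internals"]["J"].mean(axis=1),
                                  T_act=info["internals"]["T_act"].mean(axis=1)))

    record(state)
    n_steps = int(round(protocol.t_end / cfg.dt))
    t0 = time.time()
    for step in range(n_steps):
        state, info = _advance(problem, state, cfg.dt, protocol)
        if (step + 1) % cfg.output_every == 0 or step == n_steps - 1:
            record(state, info)
        cur_min = state.Phi.min()
        if depol_time is None and cur_min > protocol.depol_threshold:
            # linear interpolation of the min-potential threshold crossing
            frac = ((protocol.depol_threshold - prev_min)
                    / max(cur_min - prev_min, 1e-12))
            depol_time = state.t - cfg.dt + frac * cfg.dt
            if protocol.stop_when_depolarized:
                break
        prev_min = cur_min
        if cfg.verbose and (step % 50 == 0):
            print(f"  t={state.t:7.1f} ms  [{time.time() - t0:6.1f} s] "
                  f"Phi in [{state.Phi.min():7.2f}, {state.Phi.max():7.2f}]")

    probes = {name: pd.DataFrame(rows) for name, rows in probe_rows.items()}
    return SimulationResult(probes=probes, summary=pd.DataFrame(summary_rows),
                            snapshots=snapshots, final_state=state,
                            depolarization_time=depol_time)
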