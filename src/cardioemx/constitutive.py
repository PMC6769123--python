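"""Passive myocardium constitutive laws and finite-strain kinematics.

Three hyperelastic strain-energy functions are provided, all operating on the
right Cauchy-Green tensor C = F^T F and a local orthonormal microstructure
frame (fiber f0, sheet s0, sheet-normal n0):

* ``TIC`` -- transversely isotropic, *compressible* modified neo-Hookean law
  (polynomial type), Psi = Lambda/2 ln^2 J + mu/2 (I1 - 3 - 2 ln J)
  + theta * eta/2 (I4f - 1)^2.
* ``TII`` -- transversely isotropic, *nearly incompressible* polynomial law
  written in isochoric invariants, Psi = mu/2 (I1bar - 3)
  + theta * eta/2 (I4fbar - 1)^2 + kappa (J - 1)^2.
* ``HO`` -- orthotropic, nearly incompressible Holzapfel-Ogden exponential
  law in isochoric invariants plus the same volumetric penalty.

The fiber (and, for HO, sheet) reinforcement acts only under tension: the
switch theta is a sharp Heaviside in the respective stretch, active strictly
for lambda > 1.  The same convention is used by the stretch-activated-channel
current in :mod:`cardioemx.electrophysiology`.

Stresses are second Piola-Kirchhoff, S = 2 dPsi/dC, and tangents are
A = dS/dC (symmetric-gradient convention in C), both assembled from scalar
energy derivatives with respect to the invariant basis
(I1, I4f, I4s, I8fs, J).  Only J has a non-zero second derivative with
respect to C, which keeps the machinery compact and fully analytic.

Units: stresses and stiffness parameters in kPa, lengths in mm.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "DegenerateElementError",
    "NonphysicalStrainError",
    "Frame",
    "make_frame",
    "DeformationState",
    "kinematics",
    "TICParams",
    "TIIParams",
    "HOParams",
    "PassiveLaw",
    "TIC",
    "TII",
    "HO",
    "make_law",
]

_EYE = np.eye(3)


class DegenerateElementError(RuntimeError):
    """Raised when det(F) <= 0 (inverted/degenerate material state)."""


class NonphysicalStrainError(RuntimeError):
    """Raised when an exponential energy term would overflow (strain far
    outside the physical regime)."""


# --------------------------------------------------------------------------
# microstructure frame
# --------------------------------------------------------------------------

@dataclass
class Frame:
    """Orthonormal material frame: fiber f0, sheet s0, sheet-normal n0.

    Arrays broadcast against the leading shape of the deformation state,
    last axis of length 3.
    """

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray

    def check(self, tol: float = 1e-10) -> None:
        for v in (self.f0, self.s0, self.n0):
            if not np.allclose(np.linalg.norm(v, axis=-1), 1.0, atol=tol):
                raise ValueError("frame vectors must be unit length")
        if not np.allclose(np.sum(self.f0 * self.s0, axis=-1), 0.0, atol=tol):
            raise ValueError("f0 and s0 must be orthogonal")
        if not np.allclose(np.cross(self.f0, self.s0), self.n0, atol=1e-8):
            raise ValueError("n0 must equal f0 x s0")


def make_frame(f0, s0) -> Frame:
    """Build an orthonormal frame from (possibly unnormalized) f0, s0.

    s0 is Gram-Schmidt-orthogonalized against f0; n0 = f0 x s0.
    """
    f0 = np.asarray(f0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    f0 = f0 / np.linalg.norm(f0, axis=-1, keepdims=True)
    s0 = s0 - np.sum(s0 * f0, axis=-1, keepdims=True) * f0
    s0 = s0 / np.linalg.norm(s0, axis=-1, keepdims=True)
    return Frame(f0=f0, s0=s0, n0=np.cross(f0, s0))


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

class DeformationState:
    """Kinematic quantities at one or many material points.

    Attributes have leading shape ``shape`` (possibly ()); tensors append
    (3, 3), vectors (3,).  ``lam = sqrt(I4f)`` is the fiber stretch used by
    both the tension switch and the stretch-activated current.
    """

    __slots__ = ("F", "C", "Cinv", "J", "I1", "I4f", "I4s", "I8fs",
                 "lam", "frame")

    def __init__(self, C: np.ndarray, frame: Frame, J: np.ndarray,
                 F: np.ndarray | None = None):
        self.C = C
        self.F = F
        self.frame = frame
        self.J = J
        Cinv = np.linalg.inv(C)
        # exact numerical symmetry (the tangent's minor symmetries rely on it)
        self.Cinv = 0.5 * (Cinv + np.swapaxes(Cinv, -1, -2))
        f0, s0 = frame.f0, frame.s0
        self.I1 = np.trace(C, axis1=-2, axis2=-1)
        Cf = np.einsum("...ij,...j->...i", C, np.broadcast_to(f0, C.shape[:-2] + (3,)))
        Cs = np.einsum("...ij,...j->...i", C, np.broadcast_to(s0, C.shape[:-2] + (3,)))
        self.I4f = np.einsum("...i,...i->...", np.broadcast_to(f0, Cf.shape), Cf)
        self.I4s = np.einsum("...i,...i->...", np.broadcast_to(s0, Cs.shape), Cs)
        self.I8fs = np.einsum("...i,...i->...", np.broadcast_to(f0, Cs.shape), Cs)
        self.lam = np.sqrt(self.I4f)

    # isochoric invariants (of J^{-2/3} C)
    @property
    def I1bar(self):
        return self.J ** (-2.0 / 3.0) * self.I1

    @property
    def I4fbar(self):
        return self.J ** (-2.0 / 3.0) * self.I4f

    @property
    def I4sbar(self):
        return self.J ** (-2.0 / 3.0) * self.I4s

    @property
    def I8fsbar(self):
        return self.J ** (-2.0 / 3.0) * self.I8fs

    @classmethod
    def from_F(cls, F: np.ndarray, frame: Frame) -> "DeformationState":
        F = np.asarray(F, dtype=float)
        J = np.linalg.det(F)
        if np.any(J <= 0.0):
            bad = np.argwhere(np.atleast_2d(J <= 0.0)).ravel()
            raise DegenerateElementError(
                f"non-positive det(F) at material point index(es) {bad.tolist()[:10]}")
        C = np.einsum("...ki,...kj->...ij", F, F)
        return cls(C=C, frame=frame, J=J, F=F)

    @classmethod
    def from_C(cls, C: np.ndarray, frame: Frame) -> "DeformationState":
        C = np.asarray(C, dtype=float)
        detC = np.linalg.det(C)
        if np.any(detC <= 0.0):
            raise DegenerateElementError("non-positive det(C)")
        return cls(C=C, frame=frame, J=np.sqrt(detC))


def kinematics(F: np.ndarray, frame: Frame) -> DeformationState:
    """Deformation state (invariants, fiber stretch) from F and a frame."""
    return DeformationState.from_F(F, frame)


# --------------------------------------------------------------------------
# parameter sets
# --------------------------------------------------------------------------

def _check_positive(**kwargs):
    for k, v in kwargs.items():
        if not v > 0:
            raise ValueError(f"parameter {k} must be > 0, got {v}")


@dataclass
class TICParams:
    """Lame constants Lambda, mu and fiber stiffness eta [kPa].

    Defaults are effective organ-scale stiffnesses calibrated so that free
    contraction against the saturated active tension (49 kPa) settles at a
    bounded fiber shortening comparable to the exponential law, with a
    visible but bounded volume loss.
    """
    Lambda: float = 100.0
    mu: float = 40.0
    eta: float = 60.0
    model_id: str = field(default="TIC", init=False)

    def __post_init__(self):
        _check_positive(Lambda=self.Lambda, mu=self.mu, eta=self.eta)


@dataclass
class TIIParams:
    """Shear modulus mu, fiber stiffness eta, bulk penalty kappa [kPa].

    Defaults calibrated like :class:`TICParams` (bounded free contraction
    against the saturated active tension).
    """
    mu: float = 50.0
    eta: float = 60.0
    kappa: float = 1.0e4
    model_id: str = field(default="TII", init=False)

    def __post_init__(self):
        _check_positive(mu=self.mu, eta=self.eta, kappa=self.kappa)


@dataclass
class HOParams:
    """Holzapfel-Ogden constants: a* in kPa, b* dimensionless, bulk kappa.

    Defaults are the standard porcine simple-shear fit scaled by 0.5 for
    rat tissue.
    """
    a: float = 0.248
    b: float = 7.209
    a_f: float = 7.597
    b_f: float = 20.417
    a_s: float = 1.642
    b_s: float = 11.176
    a_fs: float = 0.331
    b_fs: float = 9.466
    kappa: float = 1.0e4
    exp_cap: float = 50.0
    model_id: str = field(default="HO", init=False)

    def __post_init__(self):
        _check_positive(a=self.a, b=self.b, a_f=self.a_f, b_f=self.b_f,
                        a_s=self.a_s, b_s=self.b_s, a_fs=self.a_fs,
                        b_fs=self.b_fs, kappa=self.kappa)


# --------------------------------------------------------------------------
# generic invariant machinery
# --------------------------------------------------------------------------

_KEYS = ("I1", "I4f", "I4s", "I8fs", "J")


def _grad_tensors(state: DeformationState) -> Dict[str, np.ndarray]:
    """dA_k/dC for the invariant basis (symmetric-gradient convention)."""
    shp = state.C.shape
    f0 = np.broadcast_to(state.frame.f0, shp[:-2] + (3,))
    s0 = np.broadcast_to(state.frame.s0, shp[:-2] + (3,))
    ff = np.einsum("...i,...j->...ij", f0, f0)
    ss = np.einsum("...i,...j->...ij", s0, s0)
    fs = 0.5 * (np.einsum("...i,...j->...ij", f0, s0)
                + np.einsum("...i,...j->...ij", s0, f0))
    return {
        "I1": np.broadcast_to(_EYE, shp).copy(),
        "I4f": ff,
        "I4s": ss,
        "I8fs": fs,
        "J": 0.5 * state.J[..., None, None] * state.Cinv,
    }


def _hess_J(state: DeformationState) -> np.ndarray:
    """d^2 J / dC dC (the only basis invariant with curvature in C)."""
    Ci = state.Cinv
    J = state.J[..., None, None, None, None]
    outer = np.einsum("...ij,...kl->...ijkl", Ci, Ci)
    sym = 0.5 * (np.einsum("...ik,...jl->...ijkl", Ci, Ci)
                 + np.einsum("...il,...jk->...ijkl", Ci, Ci))
    return 0.25 * J * outer - 0.5 * J * sym


class PassiveLaw:
    """Base class: assembles S and dS/dC from scalar invariant derivatives.

    Subclasses implement :meth:`_scalars` returning
    ``(psi, d1, d2)`` where ``d1[k] = dPsi/dA_k`` and
    ``d2[(k, l)] = d2Psi/dA_k dA_l`` with canonically ordered keys
    (k <= l in ``_KEYS`` order); off-diagonal entries are mirrored here.
    ``part`` selects 'full', 'dev' (everything but the volumetric penalty)
    or 'vol' (penalty only) to support reduced volumetric integration.
    """

    params: object

    def psi(self, state: DeformationState, part: str = "full") -> np.ndarray:
        return self._scalars(state, part, order=0)[0]

    def pk2(self, state: DeformationState, part: str = "full") -> np.ndarray:
        _, d1, _ = self._scalars(state, part, order=1)
        G = _grad_tensors(state)
        S = np.zeros(state.C.shape)
        for k, coef in d1.items():
            S = S + 2.0 * np.asarray(coef)[..., None, None] * G[k]
        return S

    def tangent(self, state: DeformationState, part: str = "full") -> np.ndarray:
        _, d1, d2 = self._scalars(state, part, order=2)
        G = _grad_tensors(state)
        A = np.zeros(state.C.shape + (3, 3))
        for (k, l), coef in d2.items():
            term = np.einsum("...ij,...kl->...ijkl", G[k], G[l])
            if k != l:
                term = term + np.einsum("...ij,...kl->...ijkl", G[l], G[k])
            A = A + 2.0 * np.asarray(coef)[..., None, None, None, None] * term
        cJ = d1.get("J")
        if cJ is not None:
            A = A + 2.0 * np.asarray(cJ)[..., None, None, None, None] * _hess_J(state)
        return A

    # -- helpers ----------------------------------------------------------
    def _scalars(self, state, part, order):  # pragma: no cover - abstract
        raise NotImplementedError


def _zero_like(x):
    return np.zeros(np.shape(x))


class TIC(PassiveLaw):
    """Compressible transversely isotropic modified neo-Hookean law."""

    def __init__(self, params: TICParams | None = None):
        self.params = params or TICParams()

    def _scalars(self, state, part="full", order=2):
        p = self.params
        J, I1, I4 = state.J, state.I1, state.I4f
        lnJ = np.log(J)
        theta = (I4 > 1.0).astype(float)
        if part == "vol":  # TIC is genuinely compressible: no penalty term
            z = _zero_like(J)
            return z, {}, {}
        psi = (0.5 * p.Lambda * lnJ ** 2
               + 0.5 * p.mu * (I1 - 3.0 - 2.0 * lnJ)
               + 0.5 * p.eta * theta * (I4 - 1.0) ** 2)
        d1 = {
            "I1": 0.5 * p.mu * np.ones_like(I1),
            "I4f": p.eta * theta * (I4 - 1.0),
            "J": (p.Lambda * lnJ - p.mu) / J,
        }
        d2 = {
            ("I4f", "I4f"): p.eta * theta,
            ("J", "J"): (p.Lambda * (1.0 - lnJ) + p.mu) / J ** 2,
        }
        return psi, d1, d2


class TII(PassiveLaw):
    """Nearly incompressible transversely isotropic polynomial law."""

    def __init__(self, params: TIIParams | None = None):
        self.params = params or TIIParams()

    def _scalars(self, state, part="full", order=2):
        p = self.params
        J, I1, I4 = state.J, state.I1, state.I4f
        w = J ** (-2.0 / 3.0)
        w1 = -2.0 * w / (3.0 * J)
        w2 = 10.0 * w / (9.0 * J ** 2)
        I4b = w * I4
        theta = (I4b > 1.0).astype(float)

        psi = _zero_like(J)
        d1: Dict[str, np.ndarray] = {}
        d2: Dict[Tuple[str, str], np.ndarray] = {}
        if part in ("full", "dev"):
            psi = psi + 0.5 * p.mu * (w * I1 - 3.0) + 0.5 * p.eta * theta * (I4b - 1.0) ** 2
            d1["I1"] = 0.5 * p.mu * w * np.ones_like(I1)
            d1["I4f"] = p.eta * theta * (I4b - 1.0) * w
            d1["J"] = 0.5 * p.mu * I1 * w1 + p.eta * theta * (I4b - 1.0) * I4 * w1
            d2[("I1", "J")] = 0.5 * p.mu * w1 * np.ones_like(I1)
            d2[("I4f", "I4f")] = p.eta * theta * w ** 2
            d2[("I4f", "J")] = p.eta * theta * w1 * (2.0 * I4b - 1.0)
            d2[("J", "J")] = (0.5 * p.mu * I1 * w2
                              + p.eta * theta * ((I4 * w1) ** 2
                                                 + (I4b - 1.0) * I4 * w2))
        if part in ("full", "vol"):
            psi = psi + p.kappa * (J - 1.0) ** 2
            d1["J"] = d1.get("J", _zero_like(J)) + 2.0 * p.kappa * (J - 1.0)
            d2[("J", "J")] = d2.get(("J", "J"), _zero_like(J)) + 2.0 * p.kappa
        return psi, d1, d2


class HO(PassiveLaw):
    """Orthotropic nearly incompressible Holzapfel-Ogden exponential law."""

    def __init__(self, params: HOParams | None = None):
        self.params = params or HOParams()

    def _scalars(self, state, part="full", order=2):
        p = self.params
        J, I1, I4f, I4s, I8 = state.J, state.I1, state.I4f, state.I4s, state.I8fs
        w = J ** (-2.0 / 3.0)
        w1 = -2.0 * w / (3.0 * J)
        w2 = 10.0 * w / (9.0 * J ** 2)
        I1b, I4fb, I4sb, I8b = w * I1, w * I4f, w * I4s, w * I8

        psi = _zero_like(J)
        d1: Dict[str, np.ndarray] = {}
        d2: Dict[Tuple[str, str], np.ndarray] = {}
        if part in ("full", "dev"):
            args = {
                "iso": p.b * (I1b - 3.0),
                "f": p.b_f * (I4fb - 1.0) ** 2,
                "s": p.b_s * (I4sb - 1.0) ** 2,
                "fs": p.b_fs * I8b ** 2,
            }
            for name, arg in args.items():
                if np.any(arg > p.exp_cap):
                    raise NonphysicalStrainError(
                        f"HO exponent '{name}' exceeds cap {p.exp_cap}: "
                        f"max arg {float(np.max(arg)):.3g}")
            thf = (I4fb > 1.0).astype(float)
            ths = (I4sb > 1.0).astype(float)
            e1 = np.exp(args["iso"])
            ef = np.exp(args["f"])
            es = np.exp(args["s"])
            e8 = np.exp(args["fs"])
            psi = psi + (p.a / (2.0 * p.b) * e1
                         + thf * p.a_f / (2.0 * p.b_f) * (ef - 1.0)
                         + ths * p.a_s / (2.0 * p.b_s) * (es - 1.0)
                         + p.a_fs / (2.0 * p.b_fs) * (e8 - 1.0))
            # first/second derivatives of psi wrt the *isochoric* invariants
            g1 = 0.5 * p.a * e1
            g1p = p.b * g1
            g4f = thf * p.a_f * (I4fb - 1.0) * ef
            g4fp = thf * p.a_f * ef * (1.0 + 2.0 * p.b_f * (I4fb - 1.0) ** 2)
            g4s = ths * p.a_s * (I4sb - 1.0) * es
            g4sp = ths * p.a_s * es * (1.0 + 2.0 * p.b_s * (I4sb - 1.0) ** 2)
            g8 = p.a_fs * I8b * e8
            g8p = p.a_fs * e8 * (1.0 + 2.0 * p.b_fs * I8b ** 2)

            d1["I1"] = g1 * w
            d1["I4f"] = g4f * w
            d1["I4s"] = g4s * w
            d1["I8fs"] = g8 * w
            d1["J"] = (g1 * I1 + g4f * I4f + g4s * I4s + g8 * I8) * w1
            d2[("I1", "I1")] = g1p * w ** 2
            d2[("I4f", "I4f")] = g4fp * w ** 2
            d2[("I4s", "I4s")] = g4sp * w ** 2
            d2[("I8fs", "I8fs")] = g8p * w ** 2
            d2[("I1", "J")] = g1p * I1 * w1 * w + g1 * w1
            d2[("I4f", "J")] = g4fp * I4f * w1 * w + g4f * w1
            d2[("I4s", "J")] = g4sp * I4s * w1 * w + g4s * w1
            d2[("I8fs", "J")] = g8p * I8 * w1 * w + g8 * w1
            d2[("J", "J")] = (g1p * (I1 * w1) ** 2 + g1 * I1 * w2
                              + g4fp * (I4f * w1) ** 2 + g4f * I4f * w2
                              + g4sp * (I4s * w1) ** 2 + g4s * I4s * w2
                              + g8p * (I8 * w1) ** 2 + g8 * I8 * w2)
        if part in ("full", "vol"):
            psi = psi + p.kappa * (J - 1.0) ** 2
            d1["J"] = d1.get("J", _zero_like(J)) + 2.0 * p.kappa * (J - 1.0)
            d2[("J", "J")] = d2.get(("J", "J"), _zero_like(J)) + 2.0 * p.kappa
        return psi, d1, d2


_LAWS = {"TIC": (TIC, TICParams), "TII": (TII, TIIParams), "HO": (HO, HOParams)}


def make_law(model_id: str, params: object | None = None) -> PassiveLaw:
    """Factory: 'TIC' | 'TII' | 'HO' (case-insensitive) -> law instance."""
    key = model_id.upper()
    if key not in _LAWS:
        raise ValueError(f"unknown passive model '{model_id}'")
    cls, pcls = _LAWS[key]
    if params is None:
        params = pcls()
    return cls(params)
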