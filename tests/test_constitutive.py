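"""Constitutive laws: kinematics, energies, stresses, tangents.

The stress/tangent implementations are checked against two independent
oracles: a symbolic (sympy) evaluation of the strain-energy formulas and
central finite differences of the energy/stress in C.
"""

import numpy as np
import pytest
import sympy as sp

from cardioemx.constitutive import (DeformationState, DegenerateElementError,
                                    NonphysicalStrainError, Frame, HOParams,
                                    TICParams, TIIParams, kinematics,
                                    make_frame, make_law)
from conftest import random_frame, random_state


# --------------------------------------------------------------------------
# kinematics
# --------------------------------------------------------------------------

def test_kinematics_identity(identity_state):
    st = identity_state
    assert st.I1 == pytest.approx(3.0)
    assert st.J == pytest.approx(1.0)
    assert st.I4f == pytest.approx(1.0)
    assert st.lam == pytest.approx(1.0)


def test_kinematics_isochoric_uniaxial():
    lam = 1.2
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
    st = kinematics(F, make_frame([1, 0, 0], [0, 1, 0]))
    assert st.J == pytest.approx(1.0, abs=1e-14)
    assert st.I4f == pytest.approx(1.44)
    assert st.lam == pytest.approx(1.2)


def test_isochoric_invariants_match_unimodular_deformation(rng):
    """Ibar of F equal the plain invariants of J^(-1/3) F (direct oracle)."""
    for _ in range(20):
        st = random_state(rng)
        Fu = st.J ** (-1.0 / 3.0) * st.F
        stu = DeformationState.from_F(Fu, st.frame)
        assert stu.J == pytest.approx(1.0, abs=1e-12)
        assert st.I1bar == pytest.approx(stu.I1, rel=1e-12)
        assert st.I4fbar == pytest.approx(stu.I4f, rel=1e-12)
        assert st.I8fsbar == pytest.approx(stu.I8fs, rel=1e-10, abs=1e-12)


def test_degenerate_deformation_rejected():
    with pytest.raises(DegenerateElementError):
        kinematics(np.diag([1.0, 1.0, -0.5]), make_frame([1, 0, 0], [0, 1, 0]))


def test_frame_constructor_orthonormalizes(rng):
    fr = make_frame(rng.standard_normal(3), rng.standard_normal(3))
    fr.check(tol=1e-12)


# --------------------------------------------------------------------------
# energy examples
# --------------------------------------------------------------------------

def test_energy_vanishes_in_reference_for_polynomial_laws(identity_state):
    assert make_law("TIC").psi(identity_state) == pytest.approx(0.0, abs=1e-14)
    assert make_law("TII").psi(identity_state) == pytest.approx(0.0, abs=1e-14)


def test_ho_reference_energy_is_isotropic_offset(identity_state):
    p = HOParams()
    assert make_law("HO").psi(identity_state) == pytest.approx(p.a / (2 * p.b))


def test_fiber_term_inactive_under_compression():
    """The anisotropic reinforcement only acts when fibers are stretched."""
    lam = 0.9
    F = np.diag([lam, 1 / np.sqrt(lam), 1 / np.sqrt(lam)])
    fr = make_frame([1, 0, 0], [0, 1, 0])
    st = kinematics(F, fr)
    for model, params_off in [
            ("TIC", TICParams(eta=1e-6)), ("TII", TIIParams(eta=1e-6)),
            ("HO", HOParams(a_f=1e-8, b_f=1e-8))]:
        law_on = make_law(model)
        law_off = make_law(model, params_off)
        assert law_on.psi(st) == pytest.approx(law_off.psi(st), rel=1e-9)
        np.testing.assert_allclose(law_on.pk2(st), law_off.pk2(st),
                                   rtol=1e-8, atol=1e-10)


def test_tii_pure_dilation_is_volumetric_only():
    p = TIIParams()
    st = kinematics(1.01 * np.eye(3), make_frame([1, 0, 0], [0, 1, 0]))
    assert make_law("TII", p).psi(st) == pytest.approx(
        p.kappa * (st.J - 1.0) ** 2, rel=1e-12)


def test_ho_shear_term_absent_without_fs_shear():
    """I8fs = 0 when shear does not couple fiber and sheet directions."""
    F = np.eye(3) + 0.3 * np.outer([1, 0, 0], [0, 0, 1])   # fn-plane shear
    st = kinematics(F, make_frame([1, 0, 0], [0, 1, 0]))
    assert st.I8fs == pytest.approx(0.0, abs=1e-14)
    strong = make_law("HO", HOParams(a_fs=1000.0))
    weak = make_law("HO", HOParams(a_fs=1e-8))
    assert strong.psi(st) == pytest.approx(weak.psi(st), rel=1e-10)


def test_ho_overflow_guard():
    st = kinematics(np.diag([3.0, 1.0, 1.0]), make_frame([1, 0, 0], [0, 1, 0]))
    with pytest.raises(NonphysicalStrainError):
        make_law("HO").psi(st)


# --------------------------------------------------------------------------
# symbolic oracle (independent formulas, evaluated with sympy)
# --------------------------------------------------------------------------

def _sym_psi(model):
    C = sp.Matrix(3, 3, lambda i, j: sp.Symbol(f"c{min(i,j)}{max(i,j)}"))
    f = sp.Matrix(sp.symbols("f0:3"))
    s = sp.Matrix(sp.symbols("s0:3"))
    J = sp.sqrt(C.det())
    I1 = C.trace()
    I4f = (f.T * C * f)[0]
    I4s = (s.T * C * s)[0]
    I8 = (f.T * C * s)[0]
    w = J ** sp.Rational(-2, 3)
    if model == "TIC":
        p = TICParams()
        expr = (p.Lambda / 2 * sp.log(J) ** 2
                + p.mu / 2 * (I1 - 3 - 2 * sp.log(J))
                + sp.Rational(1, 2) * p.eta * sp.Heaviside(I4f - 1, 0)
                * (I4f - 1) ** 2)
    elif model == "TII":
        p = TIIParams()
        expr = (p.mu / 2 * (w * I1 - 3)
                + sp.Rational(1, 2) * p.eta * sp.Heaviside(w * I4f - 1, 0)
                * (w * I4f - 1) ** 2 + p.kappa * (J - 1) ** 2)
    else:
        p = HOParams()
        expr = (p.a / (2 * p.b) * sp.exp(p.b * (w * I1 - 3))
                + p.a_f / (2 * p.b_f) * sp.Heaviside(w * I4f - 1, 0)
                * (sp.exp(p.b_f * (w * I4f - 1) ** 2) - 1)
                + p.a_s / (2 * p.b_s) * sp.Heaviside(w * I4s - 1, 0)
                * (sp.exp(p.b_s * (w * I4s - 1) ** 2) - 1)
                + p.a_fs / (2 * p.b_fs) * (sp.exp(p.b_fs * (w * I8) ** 2) - 1)
                + p.kappa * (J - 1) ** 2)
    syms = [C[i, j] for i in range(3) for j in range(i, 3)] \
        + list(f) + list(s)
    return sp.lambdify(syms, expr, modules=["numpy", {"Heaviside":
                                                      lambda x, *a: float(x > 0)}])


@pytest.mark.parametrize("model", ["TIC", "TII", "HO"])
def test_energy_matches_symbolic_oracle(model, rng):
    fn = _sym_psi(model)
    law = make_law(model)
    for _ in range(15):
        st = random_state(rng)
        C, fr = st.C, st.frame
        args = [C[i, j] for i in range(3) for j in range(i, 3)] \
            + list(fr.f0) + list(fr.s0)
        assert law.psi(st) == pytest.approx(fn(*args), rel=1e-12, abs=1e-12)


# --------------------------------------------------------------------------
# finite-difference oracles for stress and tangent
# --------------------------------------------------------------------------

def _fd_stress(law, C, frame, h=1e-6):
    S = np.zeros((3, 3))
    for i in range(3):
        for j in range(3):
            dC = np.zeros((3, 3))
            dC[i, j] += 0.5 * h
            dC[j, i] += 0.5 * h
            Sp = law.psi(DeformationState.from_C(C + dC, frame))
            Sm = law.psi(DeformationState.from_C(C - dC, frame))
            S[i, j] = 2.0 * (Sp - Sm) / (2.0 * h)
    return S


def _fd_tangent(law, C, frame, h=1e-5):
    A = np.zeros((3, 3, 3, 3))
    for k in range(3):
        for l in range(3):
            dC = np.zeros((3, 3))
            dC[k, l] += 0.5 * h
            dC[l, k] += 0.5 * h
            Sp = law.pk2(DeformationState.from_C(C + dC, frame))
            Sm = law.pk2(DeformationState.from_C(C - dC, frame))
            A[:, :, k, l] = (Sp - Sm) / (2.0 * h)
    return A


def test_stress_free_reference(law, identity_state):
    np.testing.assert_allclose(law.pk2(identity_state), 0.0, atol=1e-10)


def test_stress_matches_fd_of_energy(law, rng):
    """2 dPsi/dC reproduced to 1e-6 relative on 100 random states."""
    worst = 0.0
    for _ in range(100):
        st = random_state(rng)
        S = law.pk2(st)
        Sfd = _fd_stress(law, st.C, st.frame)
        worst = max(worst, np.abs(S - Sfd).max() / max(np.abs(S).max(), 1e-12))
    assert worst < 1e-6


def test_tangent_matches_fd_of_stress(law, rng):
    """dS/dC reproduced to 1e-5 relative on 100 random states, with a
    Richardson step-halving cross-check on a subsample."""
    worst = 0.0
    for k in range(100):
        st = random_state(rng)
        A = law.tangent(st)
        Afd = _fd_tangent(law, st.C, st.frame)
        worst = max(worst, np.abs(A - Afd).max() / np.abs(A).max())
        if k < 3:   # halved step must agree even closer (O(h^2) FD error)
            Afd2 = _fd_tangent(law, st.C, st.frame, h=5e-6)
            assert np.abs(A - Afd2).max() / np.abs(A).max() < 1e-5
    assert worst < 1e-5


def test_tangent_minor_symmetries(law, rng):
    A = law.tangent(random_state(rng))
    np.testing.assert_array_equal(A, np.swapaxes(A, 0, 1))
    np.testing.assert_array_equal(A, np.swapaxes(A, 2, 3))


def test_energy_frame_indifference(law, rng):
    """Psi(QF) = Psi(F) for rotations Q (objectivity)."""
    from scipy.stats import special_ortho_group
    st = random_state(rng)
    psi0 = law.psi(st)
    for seed in range(20):
        Q = special_ortho_group.rvs(3, random_state=seed)
        st_rot = DeformationState.from_F(Q @ st.F, st.frame)
        assert law.psi(st_rot) == pytest.approx(psi0, rel=1e-12)


def test_tic_small_strain_limit_is_isotropic_elasticity(identity_state):
    p = TICParams()
    A = make_law("TIC", p).tangent(identity_state)
    I = np.eye(3)
    # dS/dC of linear elasticity: Lambda/2 I x I + mu II_sym
    A_lin = (0.5 * p.Lambda * np.einsum("ij,kl->ijkl", I, I)
             + 0.5 * p.mu * (np.einsum("ik,jl->ijkl", I, I)
                             + np.einsum("il,jk->ijkl", I, I)))
    np.testing.assert_allclose(A, A_lin, atol=1e-12)


# --------------------------------------------------------------------------
# simple shear response of the HO law
# --------------------------------------------------------------------------

@pytest.mark.parametrize("plane", ["fs", "fn", "sf", "sn", "nf", "ns"])
def test_ho_simple_shear_monotonic(plane):
    """Shear stress strictly increasing with shear amount in all six modes."""
    law = make_law("HO")
    axes = {"f": 0, "s": 1, "n": 2}
    i, j = axes[plane[0]], axes[plane[1]]
    fr = make_frame([1, 0, 0], [0, 1, 0])
    gammas = np.linspace(0.02, 0.5, 15)
    stresses = []
    for g in gammas:
        F = np.eye(3)
        F[j, i] = g       # displace the plane[0]-normal faces along plane[1]
        st = DeformationState.from_F(F, fr)
        sigma = st.F @ law.pk2(st) @ st.F.T / st.J
        stresses.append(sigma[i, j])
    assert np.all(np.diff(stresses) > 0)
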