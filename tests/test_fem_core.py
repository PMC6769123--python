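"""Element residual/Jacobian, assembly, Newton and time stepping."""

import numpy as np
import pytest

from cardioemx import electrophysiology as ep_mod
from cardioemx.active_stress import ActiveParams
from cardioemx.constitutive import DeformationState, make_frame, make_law
from cardioemx.electrophysiology import ElectroParams
from cardioemx.fem_core import (CoupledProblem, Protocol, SolverConfig,
                                SystemState, newton_solve, run)
from cardioemx.geometry import make_cube, make_plate


def _rest_state(problem):
    E, Q = problem.wdet.shape
    N = problem.mesh.n_nodes
    return SystemState(u=np.zeros((N, 3)), Phi=np.full(N, -80.0),
                       r=np.zeros((E, Q)), T_act=np.zeros((E, Q)), t=0.0)


def _problem(mesh=None, model="TIC", gs=12.0, **cfg):
    mesh = mesh if mesh is not None else make_cube(1.0, 1)
    return CoupledProblem(mesh, make_law(model),
                          ElectroParams(G_s=gs, d_iso=0.1, d_ani=0.3),
                          ActiveParams(), SolverConfig(**cfg))


# -- residual / Jacobian ---------------------------------------------------

def test_global_rest_is_equilibrium():
    pb = _problem()
    s = _rest_state(pb)
    R, _, _ = pb.assemble(s, s.u, s.Phi, 0.5, want_jac=False)
    assert np.abs(R).max() < 1e-12


@pytest.mark.parametrize("model", ["TIC", "TII", "HO"])
def test_coupled_jacobian_matches_fd_on_distorted_element(model, rng):
    """All four Jacobian blocks versus central differences of the residual
    on a randomly distorted single hex in a random coupled state."""
    mesh = make_cube(1.0, 1)
    mesh.points = mesh.points + 0.08 * rng.standard_normal(mesh.points.shape)
    pb = _problem(mesh, model=model)
    E, Q = pb.wdet.shape
    u = 0.05 * rng.standard_normal((8, 3))
    Phi = -80.0 + 60.0 * rng.random(8)
    sn = SystemState(np.zeros((8, 3)), np.full(8, -80.0),
                     0.1 * rng.random((E, Q)), 5.0 * rng.random((E, Q)), 0.0)
    dt = 0.5
    R, K, _ = pb.assemble(sn, u, Phi, dt, True)
    K = K.toarray()
    n = pb.n_dof
    x = np.concatenate([u.ravel(), Phi])
    Kfd = np.zeros((n, n))
    h = 1e-6
    for j in range(n):
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        Rp, _, _ = pb.assemble(sn, xp[:24].reshape(-1, 3), xp[24:], dt, False)
        Rm, _, _ = pb.assemble(sn, xm[:24].reshape(-1, 3), xm[24:], dt, False)
        Kfd[:, j] = (Rp - Rm) / (2 * h)
    assert np.abs(K - Kfd).max() / np.abs(Kfd).max() < 1e-5


def test_assembly_matches_hand_scatter_on_two_elements(rng):
    """Global assembly equals the manual scatter of element blocks."""
    mesh = make_plate((2.0, 1.0, 1.0), (2, 1, 1))
    pb = _problem(mesh)
    N = mesh.n_nodes
    E, Q = pb.wdet.shape
    u = 0.01 * rng.standard_normal((N, 3))
    Phi = -80.0 + 30.0 * rng.random(N)
    sn = SystemState(np.zeros((N, 3)), np.full(N, -80.0),
                     np.zeros((E, Q)), np.zeros((E, Q)), 0.0)
    R, K, _ = pb.assemble(sn, u, Phi, 0.5, True)
    R_e, K_e, _ = pb.element_system(sn, u, Phi, 0.5, True)
    R_hand = np.zeros(pb.n_dof)
    K_hand = np.zeros((pb.n_dof, pb.n_dof))
    for e in range(mesh.n_cells):
        dofs = pb.edof[e]
        R_hand[dofs] += R_e[e]
        for i, gi in enumerate(dofs):
            K_hand[gi, dofs] += K_e[e, i]
    np.testing.assert_allclose(R, R_hand, atol=1e-12)
    np.testing.assert_allclose(K.toarray(), K_hand, atol=1e-12)


def test_jacobian_sparsity_structurally_symmetric():
    mesh = make_plate((2.0, 2.0, 1.0), (2, 2, 1))
    pb = _problem(mesh)
    s = _rest_state(pb)
    _, K, _ = pb.assemble(s, s.u, s.Phi, 0.5, True)
    import scipy.sparse as sp
    pattern = sp.csc_matrix((np.ones_like(K.data), K.indices, K.indptr),
                            shape=K.shape)
    assert (pattern != pattern.T).nnz == 0


def test_patch_test_homogeneous_stretch():
    """Affine boundary displacements on a 2x2x2 cube reproduce the
    homogeneous stress state: interior-node residual vanishes and every
    quadrature point carries the closed-form stress."""
    mesh = make_cube(1.0, 2)
    pb = _problem(mesh, model="TIC", gs=0.0)
    F = np.diag([1.05, 0.98, 1.01])
    u = mesh.points @ (F - np.eye(3)).T
    s = _rest_state(pb)
    R, _, internals = pb.assemble(s, u, s.Phi, 0.5, want_jac=False)
    interior = np.array([np.argmin(np.linalg.norm(
        mesh.points - 0.5, axis=1))])
    for c in range(3):
        assert abs(R[3 * interior[0] + c]) < 1e-10
    st = internals["state"]
    S_exact = pb.law.pk2(DeformationState.from_F(F, make_frame([1, 0, 0],
                                                               [0, 1, 0])))
    np.testing.assert_allclose(pb.law.pk2(st),
                               np.broadcast_to(S_exact, st.C.shape),
                               rtol=1e-10, atol=1e-12)


# -- Newton ----------------------------------------------------------------

def test_newton_at_rest_converges_immediately():
    pb = _problem()
    s = _rest_state(pb)
    proto = Protocol(t_end=1.0)
    new, info = newton_solve(pb, s, 0.5, 0.5, proto)
    assert info["iterations"] <= 1
    np.testing.assert_allclose(new.u, s.u, atol=1e-14)
    np.testing.assert_allclose(new.Phi, s.Phi, atol=1e-12)


def test_newton_quadratic_convergence_under_small_load():
    """Linear-regime step: few iterations, superlinear tail."""
    mesh = make_cube(1.0, 1)
    mesh.node_sets["face"] = np.flatnonzero(mesh.points[:, 0] > 0.99)
    pb = _problem(mesh, model="TIC", gs=0.0)
    proto = Protocol(
        t_end=1.0,
        mech_dirichlet=[("pin_xyz", [0, 1, 2], 0.0), ("pin_yz", [1, 2], 0.0),
                        ("pin_z", [2], 0.0)],
        loads=[("face", [1.0, 0.0, 0.0], lambda t: 0.5)])
    s = _rest_state(pb)
    new, info = newton_solve(pb, s, 0.5, 0.5, proto)
    assert info["iterations"] <= 4
    rm = [h[0] for h in info["residuals"]]
    # superlinear tail: contraction factor improves markedly each iteration
    assert rm[-1] / rm[-2] < 0.2 * (rm[-2] / rm[-3])


def test_converged_residual_below_tolerance():
    mesh = make_cube(1.0, 1)
    pb = _problem(mesh, gs=0.0)
    proto = Protocol(t_end=1.0,
                     mech_dirichlet=[("pin_xyz", [0, 1, 2], 0.0),
                                     ("pin_yz", [1, 2], 0.0),
                                     ("pin_z", [2], 0.0)],
                     phi_dirichlet=[("pin_xyz", lambda t: -20.0)])
    s = _rest_state(pb)
    new, info = newton_solve(pb, s, 0.5, 0.5, proto)
    from cardioemx.fem_core import build_constraints
    fixed, vals, f_ext = build_constraints(pb, proto, 0.5, new.u, new.Phi)
    R, _, _ = pb.assemble(s, new.u, new.Phi, 0.5, want_jac=False,
                          fixed=fixed, fixed_vals=vals, f_ext=f_ext)
    assert np.abs(R).max() < pb.config.newton_tol_mech + 1e-9


def test_zero_protocol_run_stays_at_rest():
    pb = _problem(make_plate((2.0, 2.0, 1.0), (2, 2, 1)), gs=15.0)
    res = run(pb, Protocol(t_end=5.0, probes={"n0": 0}))
    assert res.summary["Phi_min"].min() == pytest.approx(-80.0, abs=1e-9)
    assert res.summary["Phi_max"].max() == pytest.approx(-80.0, abs=1e-9)
    np.testing.assert_allclose(res.final_state.u, 0.0, atol=1e-12)


def test_mef_free_run_identical_to_feedback_term_deleted_build(monkeypatch):
    """G_s = 0 must be bitwise-equivalent to removing the MEF current from
    the source term altogether."""
    def one_run(delete_term):
        mesh = make_cube(1.0, 1)
        mesh.node_sets["face"] = np.flatnonzero(mesh.points[:, 0] > 0.99)
        pb = _problem(mesh, model="TII", gs=0.0)
        if delete_term:
            monkeypatch.setattr(ep_mod, "f_m",
                                lambda lam, phi, p: np.zeros(np.shape(lam)))
            monkeypatch.setattr(ep_mod, "df_m_dphi",
                                lambda lam, phi, p: np.zeros(np.shape(lam)))
        proto = Protocol(
            t_end=10.0,
            mech_dirichlet=[("pin_xyz", [0, 1, 2], 0.0),
                            ("pin_yz", [1, 2], 0.0), ("pin_z", [2], 0.0)],
            loads=[("face", [1.0, 0, 0], lambda t: min(t, 5.0))],
            phi_dirichlet=[("pin_xyz", lambda t: -20.0 if t < 5 else None)])
        res = run(pb, proto)
        return res.final_state
    a = one_run(False)
    b = one_run(True)
    np.testing.assert_allclose(a.u, b.u, atol=1e-12)
    np.testing.assert_allclose(a.Phi, b.Phi, atol=1e-12)
    np.testing.assert_allclose(a.T_act, b.T_act, atol=1e-12)


def test_strain_energy_nonincreasing_during_relaxation():
    """With no stimulus, load or feedback, a pre-tensioned specimen relaxes:
    the total passive strain energy decays monotonically."""
    mesh = make_cube(1.0, 1)
    pb = _problem(mesh, model="TIC", gs=0.0, dt=2.0, record_energy=True)
    E, Q = pb.wdet.shape
    init = _rest_state(pb)
    init.T_act[:] = 30.0        # pre-activated, potential at rest
    proto = Protocol(t_end=100.0,
                     mech_dirichlet=[("pin_xyz", [0, 1, 2], 0.0),
                                     ("pin_yz", [1, 2], 0.0),
                                     ("pin_z", [2], 0.0)])
    res = run(pb, proto, initial=init)
    en = res.summary["strain_energy"].to_numpy()
    assert en[1] > 1e-3                     # tension deformed the cube
    assert np.all(np.diff(en[1:]) <= 1e-10)
    assert en[-1] < 1e-6


def test_time_step_consistency_on_smooth_drive():
    """Halving dt changes the probe displacement trace by < 2% in max norm
    (uniformly driven cube; steps inside the first-order asymptotic regime
    of the activation-onset transient)."""
    from cardioemx.experiments import run_cube_isotonic
    traces = {}
    for dt in (0.125, 0.0625):
        _, res = run_cube_isotonic("TII", t_end=60.0, dt=dt)
        traces[dt] = res.probes["corner"]
    coarse, fine = traces[0.125], traces[0.0625]
    u_f = np.interp(coarse["t"], fine["t"], fine["u"])
    err = np.abs(coarse["u"].to_numpy() - u_f).max() / np.abs(u_f).max()
    assert err < 0.02


def test_element_inversion_reported_with_location():
    mesh = make_cube(1.0, 1)
    pb = _problem(mesh)
    s = _rest_state(pb)
    u = np.zeros((8, 3))
    u[mesh.points[:, 0] > 0.5, 0] = -1.2       # fold the element over
    from cardioemx.constitutive import DegenerateElementError
    with pytest.raises(DegenerateElementError):
        pb.assemble(s, u, s.Phi, 0.5, want_jac=False)


def test_vtu_output_roundtrip(tmp_path):
    from xml.etree import ElementTree
    from cardioemx.io_vtu import write_vtu
    mesh = make_cube(1.0, 1)
    path = tmp_path / "cube.vtu"
    write_vtu(path, mesh, point_data={"Phi": np.full(8, -80.0),
                                      "u": np.zeros((8, 3))},
              cell_data={"J": np.ones(1)})
    root = ElementTree.parse(path).getroot()
    piece = root.find(".//Piece")
    assert piece.get("NumberOfPoints") == "8"
    assert piece.get("NumberOfCells") == "1"
    names = {d.get("Name") for d in root.iter("DataArray")}
    assert {"connectivity", "offsets", "types", "Phi", "u", "J"} <= names


def test_mesh_refinement_consistency_of_depolarization_time():
    """The depolarization-completion time of a stimulus-initiated wave on
    the quarter-scale coupled plate changes by < 5% under a 1.5x uniform
    refinement."""
    from cardioemx.electrophysiology import ElectroParams

    def depol_time(div):
        mesh = make_plate((5.0, 5.0, 1.2), div)
        pts = mesh.points
        mesh.node_sets["stim"] = np.flatnonzero(
            (np.abs(pts[:, 0] - 2.5) < 0.6) & (np.abs(pts[:, 1] - 2.5) < 0.6))
        pb = CoupledProblem(mesh, make_law("TIC"),
                            ElectroParams(G_s=15.0, d_iso=0.1, d_ani=0.3),
                            ActiveParams(), SolverConfig(dt=0.5))
        proto = Protocol(
            t_end=60.0,
            mech_dirichlet=[("midplane_edges", [2], 0.0),
                            ("pin_xy", [0, 1], 0.0), ("pin_y", [1], 0.0)],
            phi_dirichlet=[("stim", lambda t: -20.0 if t <= 5.0 else None)],
            stop_when_depolarized=True)
        res = run(pb, proto)
        assert res.depolarization_time is not None
        return res.depolarization_time

    coarse = depol_time((10, 10, 2))
    fine = depol_time((15, 15, 3))
    assert abs(fine - coarse) / fine < 0.05
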