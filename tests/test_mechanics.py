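import numpy as np
import pytest

from plaquemech.axisym import solve_axisymmetric
from plaquemech.contours import circular_contours
from plaquemech.geometry import build_layered_mesh, open_to_zero_stress
from plaquemech.materials import (ADVENTITIA, INTIMA, MEDIA, MMHG_TO_KPA)
from plaquemech.mechanics import (LoadProtocol, SolvedState, SolverConfig,
                                  ThinSliceFE, close_sector, principal_fields,
                                  run_three_step)

LAYERS3 = [INTIMA, MEDIA, ADVENTITIA]


def row_profile(state, quantity):
    """Per-radial-row circumferential average of an element field."""
    nth = state.mesh.n_theta
    nrow = state.mesh.n_rows - 1
    cen = state.deformed_nodes[state.mesh.elems].mean(axis=1) - state.lumen_centroid()
    r = np.hypot(cen[:, 0], cen[:, 1]).reshape(nrow, nth).mean(axis=1)
    q = quantity.reshape(nrow, nth).mean(axis=1)
    return r, q


def rel_l2_vs_oracle(state, profile):
    r, stt = row_profile(state, state.sigma_theta_theta())
    oracle = np.interp(r, profile.r, profile.sigma_tt)
    return np.linalg.norm(stt - oracle) / np.linalg.norm(oracle)


@pytest.fixture(scope="module")
def ring_mesh(ring):
    return build_layered_mesh(ring, n_radial=(3, 3, 3), n_theta=48)


@pytest.fixture(scope="module")
def sector_mesh(ring):
    geo = open_to_zero_stress(ring, 120.0)
    return geo, build_layered_mesh(geo, n_radial=(3, 3, 3), n_theta=48)


@pytest.fixture(scope="module")
def closed_sector_model(sector_mesh, materials):
    _, mesh = sector_mesh
    return close_sector(mesh, materials)


# ------------------------------------------------------------------ trivial
def test_unloaded_closed_ring_is_identity(ring_mesh, materials):
    st = run_three_step(ring_mesh, materials, LoadProtocol())
    assert np.abs(st.displacements).max() < 1e-10
    assert np.abs(st.cauchy).max() < 1e-8
    assert st.J_min == pytest.approx(1.0) and st.J_max == pytest.approx(1.0)


def test_full_circle_sector_closure_is_identity(ring, materials):
    geo = open_to_zero_stress(ring, 0.0)  # sector angle 2*pi
    mesh = build_layered_mesh(geo, n_radial=(2, 2, 2), n_theta=32)
    model = close_sector(mesh, materials)
    assert np.abs(model.u).max() < 1e-8
    st = model.evaluate_state("opened")
    assert np.abs(st.cauchy).max() < 1e-6


# ------------------------------------------------------------------ closure
def test_closed_sector_matches_axisymmetric_oracle(closed_sector_model,
                                                   sector_mesh):
    geo, _ = sector_mesh
    st = closed_sector_model.evaluate_state("opened")
    Rif = [geo.radii[k][0] for k in ("lumen", "iem", "eem", "adv")]
    oracle = solve_axisymmetric(Rif, LAYERS3, geo.sector_angle, 1.0, 0.0)
    assert rel_l2_vs_oracle(st, oracle) < 0.05
    # compressive inner wall, tensile outer wall
    _, stt = row_profile(st, st.sigma_theta_theta())
    assert stt[0] < 0 < stt[-1]


def test_closed_sector_is_self_equilibrated(closed_sector_model):
    net_force, net_moment = closed_sector_model.reaction_summary()
    st = closed_sector_model.evaluate_state("opened")
    scale = np.abs(st.cauchy).max() * 2.4  # reference modulus x length scale
    assert np.linalg.norm(net_force) < 1e-6 * scale
    assert abs(net_moment) < 1e-6 * scale * 2.4


def test_closure_is_path_independent(sector_mesh, materials):
    """Doubling the wrap increments changes final stresses by < 0.5%."""
    geo, _ = sector_mesh
    mesh_a = build_layered_mesh(geo, n_radial=(2, 2, 2), n_theta=32)
    mesh_b = build_layered_mesh(geo, n_radial=(2, 2, 2), n_theta=32)
    st_a = run_three_step(mesh_a, dict(_lib()), LoadProtocol(closure_steps=3))
    st_b = run_three_step(mesh_b, dict(_lib()), LoadProtocol(closure_steps=6))
    scale = np.abs(st_a.max_principal_stress).max()
    assert np.abs(st_a.max_principal_stress
                  - st_b.max_principal_stress).max() < 0.005 * scale


def _lib():
    from plaquemech.materials import MATERIAL_LIBRARY
    return MATERIAL_LIBRARY


# ------------------------------------------------------------------ three-step
def test_three_step_with_residual_matches_oracle(sector_mesh, materials):
    geo, mesh = sector_mesh
    st = run_three_step(mesh, materials,
                        LoadProtocol(lambda_z=1 / 0.95, pressure_mmhg=80))
    Rif = [geo.radii[k][0] for k in ("lumen", "iem", "eem", "adv")]
    oracle = solve_axisymmetric(Rif, LAYERS3, geo.sector_angle, 1 / 0.95,
                                80 * MMHG_TO_KPA)
    assert rel_l2_vs_oracle(st, oracle) < 0.05
    assert st.residual_norm <= 1e-8
    assert 0.99 <= st.J_min and st.J_max <= 1.01


def test_three_step_without_residual_matches_oracle(ring_mesh, materials):
    st = run_three_step(ring_mesh, materials,
                        LoadProtocol(lambda_z=1 / 0.95, pressure_mmhg=80))
    oracle = solve_axisymmetric([1.5, 1.75, 2.0, 2.4], LAYERS3, 2 * np.pi,
                                1 / 0.95, 80 * MMHG_TO_KPA)
    assert rel_l2_vs_oracle(st, oracle) < 0.05


def test_residual_stress_shifts_load_from_inner_to_outer_wall(ring, materials):
    """Same loaded ring, with vs without the wrap step: inner mean maximum
    principal stress lower WITH residual stress, outer mean higher."""
    prot = LoadProtocol(lambda_z=1 / 0.95, pressure_mmhg=110)
    geo = open_to_zero_stress(ring, 120.0)
    st_with = run_three_step(build_layered_mesh(geo, (3, 3, 3), 48),
                             materials, prot)
    st_wo = run_three_step(build_layered_mesh(ring, (3, 3, 3), 48),
                           materials, prot)
    nth = 48
    inner_w = st_with.max_principal_stress[:nth].mean()
    inner_o = st_wo.max_principal_stress[:nth].mean()
    outer_w = st_with.max_principal_stress[-nth:].mean()
    outer_o = st_wo.max_principal_stress[-nth:].mean()
    assert inner_w < inner_o
    assert outer_w > outer_o


def test_transmural_uniformization_with_residual_stress(ring, materials):
    prot = LoadProtocol(lambda_z=1 / 0.95, pressure_mmhg=140)
    geo = open_to_zero_stress(ring, 120.0)
    st_with = run_three_step(build_layered_mesh(geo, (3, 3, 3), 48),
                             materials, prot)
    st_wo = run_three_step(build_layered_mesh(ring, (3, 3, 3), 48),
                           materials, prot)

    def cov(st):
        s = st.sigma_theta_theta()
        return np.std(s) / abs(np.mean(s))

    assert cov(st_with) < cov(st_wo)


# ------------------------------------------------------------------ principal
def test_principal_stress_of_diagonal_tensor():
    st = SolvedState.__new__(SolvedState)
    st.cauchy = np.diag([-3.0, 2.0, 1.0])[None]
    st.green = np.diag([0.105, 0.0, 0.0])[None]
    smax, emax = principal_fields(st)
    assert smax[0] == pytest.approx(2.0)
    # uniaxial stretch 1.1: E = (1.1^2 - 1)/2 = 0.105
    assert emax[0] == pytest.approx(0.105)


def test_principal_values_match_characteristic_polynomial_oracle():
    rng = np.random.default_rng(0)
    A = rng.standard_normal((1000, 3, 3))
    S = 0.5 * (A + np.swapaxes(A, -1, -2))
    lam = np.linalg.eigvalsh(S)[:, -1]
    # brute force: roots of det(S - x I) per tensor
    for i in range(0, 1000, 7):
        coeffs = np.poly(S[i])
        roots = np.roots(coeffs)
        assert lam[i] == pytest.approx(np.max(roots.real), abs=1e-10)


# ------------------------------------------------------------------ solver
def test_tangent_is_consistent_with_residual(ring, materials):
    mesh = build_layered_mesh(ring, n_radial=(1, 1, 1), n_theta=16)
    model = ThinSliceFE(mesh, materials, SolverConfig())
    rng = np.random.default_rng(5)
    model.u = 0.01 * rng.standard_normal(model.u.shape)
    model.pressure_kpa = 5.0
    u_red = model._collapse(model.u)
    K = model.tangent(u_red).toarray()
    R0, _ = model.residual(u_red)
    h = 1e-7
    cols = rng.choice(u_red.size, 12, replace=False)
    for j in cols:
        up = u_red.copy()
        up[j] += h
        R1, _ = model.residual(up)
        fd = (R1 - R0) / h
        assert np.abs(K[:, j] - fd).max() < 2e-3 * max(np.abs(K[:, j]).max(), 1.0)


def test_nonconvergence_reports_error(ring, materials):
    mesh = build_layered_mesh(ring, n_radial=(1, 1, 1), n_theta=16)
    cfg = SolverConfig(max_newton_iterations=1, line_search=False,
                       max_step_halvings=0)
    with pytest.raises(RuntimeError, match="ramp failed|converge|stalled"):
        run_three_step(mesh, materials,
                       LoadProtocol(lambda_z=1 / 0.95, pressure_mmhg=150,
                                    pressure_steps=1), cfg)
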