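import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from plaquemech.materials import (MATERIAL_LIBRARY, DeformationState,
                                  MaterialParams, cauchy_stress,
                                  fiber_direction, first_piola_stress,
                                  strain_energy, strain_invariants,
                                  uniaxial_response, MMHG_TO_KPA)

ALL = list(MATERIAL_LIBRARY.values())


def state_for(params, F):
    fib = None if params.is_isotropic else fiber_direction(
        params.fiber_angle_deg, (0.0, 1.0, 0.0))
    return DeformationState(np.asarray(F, dtype=float), fib)


def random_states(n, spread=0.06, seed=0):
    rng = np.random.default_rng(seed)
    for _ in range(n):
        F = np.eye(3) + spread * rng.standard_normal((3, 3))
        if np.linalg.det(F) <= 0.5:
            continue
        yield F


# ------------------------------------------------------------------ invariants
def test_invariants_at_identity():
    inv = strain_invariants(state_for(MATERIAL_LIBRARY["media"], np.eye(3)))
    assert inv["I1"] == pytest.approx(3.0)
    assert inv["I2"] == pytest.approx(3.0)
    assert inv["I4"] == pytest.approx(1.0)
    assert inv["J"] == pytest.approx(1.0)


def test_invariants_biaxial_example():
    # lambda_theta=1.2, lambda_z=1, lambda_r=1/1.2, fiber at 24.9 deg:
    # I1 = 1/1.44 + 1.44 + 1, I4 = 1.44 cos^2(phi) + sin^2(phi)
    st = state_for(MATERIAL_LIBRARY["media"], np.diag([1 / 1.2, 1.2, 1.0]))
    inv = strain_invariants(st)
    phi = np.deg2rad(24.9)
    assert inv["I1"] == pytest.approx(1 / 1.44 + 1.44 + 1.0, rel=1e-12)
    assert inv["I4"] == pytest.approx(1.44 * np.cos(phi)**2 + np.sin(phi)**2,
                                      rel=1e-12)
    assert inv["I1"] == pytest.approx(3.134, abs=5e-4)
    assert inv["I4"] == pytest.approx(1.362, abs=5e-4)


def test_invariants_frame_indifferent():
    rng = np.random.default_rng(1)
    F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
    st = state_for(MATERIAL_LIBRARY["media"], F)
    base = strain_invariants(st)
    for Q in Rotation.random(20, rng=np.random.default_rng(2)).as_matrix():
        inv = strain_invariants(state_for(MATERIAL_LIBRARY["media"], Q @ F))
        for key in ("I1", "I2", "I4", "J"):
            assert inv[key] == pytest.approx(base[key], rel=1e-10)


# ------------------------------------------------------------------ energy
@pytest.mark.parametrize("params", ALL, ids=lambda p: p.name)
def test_reference_state_is_stress_and_energy_free(params):
    st = state_for(params, np.eye(3))
    assert strain_energy(params, st) == pytest.approx(0.0, abs=1e-14)
    assert np.abs(cauchy_stress(params, st)).max() == pytest.approx(0.0, abs=1e-10)


def test_lipid_energy_hand_value():
    # isotropic lipid (c2 = 0) at I1 = 4, J = 1:
    # W = 0.5*(4-3) + 0.5*(exp(1.5*(4-3)) - 1)
    lam = brentq(lambda l: l**2 + 2.0 / l - 4.0, 1.1, 2.0)
    st = state_for(MATERIAL_LIBRARY["lipid"], np.diag([lam, lam**-0.5, lam**-0.5]))
    expected = 0.5 * 1.0 + 0.5 * (np.exp(1.5) - 1.0)
    assert strain_energy(params=MATERIAL_LIBRARY["lipid"], state=st) == \
        pytest.approx(expected, rel=1e-9)


def test_media_fiber_term_vanishes_at_I4_one():
    # isochoric state with lambda_theta = 1: fiber sees no stretch
    media = MATERIAL_LIBRARY["media"]
    st_iso = state_for(MaterialParams("m0", media.c1, media.c2, media.D1,
                                      media.D2), np.diag([1.1, 1.0, 1 / 1.1]))
    st = state_for(media, np.diag([1.1, 1.0, 1 / 1.1]))
    assert strain_energy(media, st) == pytest.approx(
        strain_energy(MaterialParams("m0", media.c1, media.c2, media.D1,
                                     media.D2), st_iso), rel=1e-12)


@pytest.mark.parametrize("params", ALL, ids=lambda p: p.name)
def test_frame_indifference_of_energy(params):
    rng = np.random.default_rng(3)
    F = np.eye(3) + 0.05 * rng.standard_normal((3, 3))
    st = state_for(params, F)
    W0 = strain_energy(params, st)
    for Q in Rotation.random(100, rng=np.random.default_rng(4)).as_matrix():
        W = strain_energy(params, state_for(params, Q @ F))
        assert W == pytest.approx(W0, rel=1e-10, abs=1e-12)


def test_energy_overflow_reports_invariant():
    with pytest.raises(FloatingPointError, match="I1_bar"):
        strain_energy(MATERIAL_LIBRARY["lipid"],
                      state_for(MATERIAL_LIBRARY["lipid"],
                                np.diag([20.0, 1.0, 1 / 20.0])))


# ------------------------------------------------------------------ stress
@pytest.mark.parametrize("params", ALL, ids=lambda p: p.name)
def test_stress_energy_consistency_finite_difference(params):
    """Complex-step Piola stress vs central finite differences of W."""
    h = 1e-6
    for F in random_states(5, seed=11):
        if abs(np.linalg.det(F) - 1.0) > 0.05:
            continue  # stay in J in [0.95, 1.05]
        st = state_for(params, F)
        P = first_piola_stress(params, st)
        Pfd = np.zeros((3, 3))
        for i in range(3):
            for j in range(3):
                Fp, Fm = F.copy(), F.copy()
                Fp[i, j] += h
                Fm[i, j] -= h
                Pfd[i, j] = (strain_energy(params, state_for(params, Fp))
                             - strain_energy(params, state_for(params, Fm))) / (2 * h)
        scale = max(np.abs(Pfd).max(), 1.0)
        assert np.abs(P - Pfd).max() / scale < 1e-5


@pytest.mark.parametrize("name", ["lipid", "calcification"])
def test_isotropic_stress_commutes_with_left_cauchy_green(name):
    params = MATERIAL_LIBRARY[name]
    for F in random_states(10, seed=5):
        st = state_for(params, F)
        sigma = cauchy_stress(params, st)
        B = F @ F.T
        comm = sigma @ B - B @ sigma
        assert np.abs(comm).max() <= 1e-8 * max(np.abs(sigma).max(), 1.0)


def test_fiber_in_compression_contributes_nothing():
    media = MATERIAL_LIBRARY["media"]
    iso_twin = MaterialParams("m0", media.c1, media.c2, media.D1, media.D2,
                              kappa=media.kappa)
    F = np.diag([1.15, 0.9, 0.97])  # I4 < 1 at the media fiber angle
    st = state_for(media, F)
    assert strain_invariants(st)["I4_bar"] < 1.0
    np.testing.assert_allclose(
        cauchy_stress(media, st),
        cauchy_stress(iso_twin, DeformationState(F)), atol=1e-10)


# ------------------------------------------------------------------ uniaxial
def test_uniaxial_zero_stretch_zero_stress():
    for params in ALL:
        _, sig = uniaxial_response(params, "circumferential", [1.0])
        assert sig[0] == pytest.approx(0.0, abs=1e-8)


def test_intima_circumferential_curve_strictly_increasing():
    lam, sig = uniaxial_response(MATERIAL_LIBRARY["intima"], "circumferential",
                                 np.linspace(1.0, 1.15, 8))
    assert np.all(np.diff(sig) > 0)


def test_media_stiffer_circumferentially_than_axially():
    # fiber angle 24.9 deg is near-circumferential
    _, sc = uniaxial_response(MATERIAL_LIBRARY["media"], "circumferential", [1.1])
    _, sa = uniaxial_response(MATERIAL_LIBRARY["media"], "axial", [1.1])
    assert sc[0] > sa[0] > 0


def test_mmhg_conversion_constant_used_at_boundary():
    assert 100 * MMHG_TO_KPA == pytest.approx(13.3322)
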