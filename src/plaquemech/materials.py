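"""Modified Mooney-Rivlin hyperelasticity for arterial layers and plaque components.

The vessel layers (intima, media, adventitia) are modelled as hyperelastic,
anisotropic (fiber-reinforced), nearly incompressible and homogeneous; lipid
and calcification are isotropic.  The strain-energy density is

    W_iso   = c1*(I1 - 3) + c2*(I2 - 3) + D1*[exp(D2*(I1 - 3)) - 1]
    W_aniso = W_iso + (K1/K2) * {exp[K2*(I4 - 1)^2] - 1}

with I1, I2 the first/second invariants of the right Cauchy-Green tensor
C = F^T F and I4 = a . C a the squared stretch along the collagen-fiber
direction a, which lies in the circumferential-axial plane at an angle phi
from the circumferential direction.  Near-incompressibility is imposed with
an isochoric-volumetric split: the printed parameters act on the isochoric
invariants (I_bar = J^(-2/3)-scaled) and a volumetric penalty
U(J) = kappa/2 (J - 1)^2 controls the volume change.  The fiber term is
active only in tension (I4_bar > 1), the usual collagen-recruitment switch.

Stress is evaluated as sigma = (1/J) P F^T with the first Piola-Kirchhoff
tensor P = dW/dF obtained by the complex-step derivative of W, which is
exact to machine precision and keeps the code free of hand-derived tensor
algebra; finite-difference consistency is checked in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import optimize

#: unit conversion used once at the loading boundary (pressures arrive in mmHg)
MMHG_TO_KPA = 0.133322

#: default volumetric penalty [kPa]; chosen so the element dilatation stays
#: within +/-0.5% at coronary loads including the residually stressed states
DEFAULT_KAPPA = 1.0e5

_EXP_CAP = 60.0  # exponent guard: beyond this the material model has overflowed


@dataclass(frozen=True)
class MaterialParams:
    """One modified Mooney-Rivlin parameter record.

    c1, c2, D1, K1 are in kPa; D2, K2 are dimensionless.  ``fiber_angle_deg``
    is the angle between the fiber reinforcement and the circumferential
    direction; ``None`` marks an isotropic material (K1 must then be 0).
    """

    name: str
    c1: float
    c2: float
    D1: float
    D2: float
    K1: float = 0.0
    K2: float = 0.0
    fiber_angle_deg: float | None = None
    kappa: float = DEFAULT_KAPPA

    def __post_init__(self) -> None:
        if self.D2 < 0 or self.K2 < 0:
            raise ValueError("D2 and K2 must be non-negative")
        if self.kappa <= 0:
            raise ValueError("bulk penalty kappa must be positive")
        if self.fiber_angle_deg is None and self.K1 != 0.0:
            raise ValueError("isotropic materials must have K1 = 0")

    @property
    def is_isotropic(self) -> bool:
        return self.fiber_angle_deg is None


#: layer / component parameter library (kPa where dimensional)
INTIMA = MaterialParams("intima", c1=-169.23, c2=177.40, D1=2.4, D2=13.0,
                        K1=32.0, K2=36.0, fiber_angle_deg=0.0)
MEDIA = MaterialParams("media", c1=-67.25, c2=35.01, D1=17.0, D2=2.0,
                       K1=7.0, K2=4.0, fiber_angle_deg=24.9)
ADVENTITIA = MaterialParams("adventitia", c1=-94.44, c2=102.42, D1=0.8, D2=10.0,
                            K1=10.0, K2=40.0, fiber_angle_deg=75.3)
LIPID = MaterialParams("lipid", c1=0.5, c2=0.0, D1=0.5, D2=1.5)
CALCIFICATION = MaterialParams("calcification", c1=920.0, c2=0.0, D1=360.0, D2=2.0)

#: single-layer models bind the intima record to the whole wall
MATERIAL_LIBRARY = {
    "intima": INTIMA,
    "media": MEDIA,
    "adventitia": ADVENTITIA,
    "lipid": LIPID,
    "calcification": CALCIFICATION,
    "wall": replace(INTIMA, name="wall"),
}


def material_library(overrides: dict | None = None) -> dict:
    """Return the material library, optionally overriding parameters.

    ``overrides`` maps material name -> dict of field overrides, e.g.
    ``{"intima": {"fiber_angle_deg": 10.0}}``.
    """
    lib = dict(MATERIAL_LIBRARY)
    for name, kw in (overrides or {}).items():
        lib[name] = replace(lib[name], **kw)
    return lib


@dataclass
class DeformationState:
    """A deformation gradient with an optional reference fiber direction."""

    F: np.ndarray  # (..., 3, 3)
    fiber_direction: np.ndarray | None = None  # (..., 3) unit vector

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F)
        if self.F.shape[-2:] != (3, 3):
            raise ValueError("F must be (..., 3, 3)")
        if not np.all(np.isfinite(self.F.real)):
            raise ValueError("non-finite deformation gradient")
        if self.fiber_direction is not None:
            self.fiber_direction = np.asarray(self.fiber_direction, dtype=float)

    @property
    def J(self) -> np.ndarray:
        return np.linalg.det(self.F)


def fiber_direction(phi_deg: float, e_theta, e_z=(0.0, 0.0, 1.0)) -> np.ndarray:
    """Reference fiber unit vector at +phi from circumferential, toward axial."""
    phi = np.deg2rad(phi_deg)
    e_theta = np.asarray(e_theta, dtype=float)
    e_z = np.asarray(e_z, dtype=float)
    return np.cos(phi) * e_theta + np.sin(phi) * e_z


def strain_invariants(state: DeformationState):
    """Invariants (I1, I2, I4, J) of C = F^T F plus their isochoric versions.

    Returns a dict with keys I1, I2, I4, J, I1_bar, I2_bar, I4_bar.  I4 is
    ``None`` when no fiber direction is present.
    """
    F = state.F
    J = np.linalg.det(F)
    if np.any(J.real <= 0):
        raise ValueError("det F must be positive")
    C = np.swapaxes(F, -1, -2) @ F
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1**2 - np.trace(C @ C, axis1=-2, axis2=-1))
    out = {
        "I1": I1,
        "I2": I2,
        "J": J,
        "I1_bar": J ** (-2.0 / 3.0) * I1,
        "I2_bar": J ** (-4.0 / 3.0) * I2,
        "I4": None,
        "I4_bar": None,
    }
    if state.fiber_direction is not None:
        a = state.fiber_direction
        I4 = np.einsum("...i,...ij,...j->...", a, C, a)
        out["I4"] = I4
        out["I4_bar"] = J ** (-2.0 / 3.0) * I4
    return out


def _energy_from_F(params: MaterialParams, F, fiber=None,
                   include_volumetric: bool = True):
    """W(F) evaluated on a (possibly complex) batch of deformation gradients."""
    J = np.linalg.det(F)
    C = np.swapaxes(F, -1, -2) @ F
    I1 = np.trace(C, axis1=-2, axis2=-1)
    I2 = 0.5 * (I1**2 - np.trace(C @ C, axis1=-2, axis2=-1))
    Jm23 = J ** (-2.0 / 3.0)
    I1b = Jm23 * I1
    I2b = Jm23**2 * I2
    arg = params.D2 * (I1b - 3.0)
    if np.any(arg.real > _EXP_CAP):
        raise FloatingPointError(
            f"overflow in exp(D2*(I1-3)) for {params.name}: "
            f"I1_bar reached {float(np.max(I1b.real)):.3f}"
        )
    W = (params.c1 * (I1b - 3.0) + params.c2 * (I2b - 3.0)
         + params.D1 * (np.exp(arg) - 1.0))
    if params.K1 != 0.0 and fiber is not None:
        a = fiber
        I4b = Jm23 * np.einsum("...i,...ij,...j->...", a, C, a)
        e = I4b - 1.0
        arg4 = params.K2 * e * e
        if np.any(arg4.real > _EXP_CAP):
            raise FloatingPointError(
                f"overflow in fiber exponential for {params.name}: "
                f"I4_bar reached {float(np.max(I4b.real)):.3f}"
            )
        active = (I4b.real > 1.0).astype(float)  # tension-only recruitment
        W = W + active * (params.K1 / params.K2) * (np.exp(arg4) - 1.0)
    if include_volumetric:
        W = W + 0.5 * params.kappa * (J - 1.0) ** 2
    return W


def strain_energy(params: MaterialParams, state: DeformationState,
                  include_volumetric: bool = True):
    """Strain-energy density [kPa] at the given deformation state."""
    fib = state.fiber_direction
    if params.K1 != 0.0 and fib is None:
        raise ValueError(f"material {params.name!r} needs a fiber direction")
    return _energy_from_F(params, state.F, fib, include_volumetric)


def first_piola_stress(params: MaterialParams, state: DeformationState,
                       include_volumetric: bool = True) -> np.ndarray:
    """P = dW/dF by complex-step differentiation (machine-precision exact)."""
    F = np.asarray(state.F, dtype=float)
    fib = state.fiber_direction
    h = 1e-20
    # batch the nine component perturbations in one energy evaluation
    pert = np.zeros((9,) + F.shape, dtype=complex)
    Fb = np.broadcast_to(F, (9,) + F.shape).copy().astype(complex)
    for k in range(9):
        i, j = divmod(k, 3)
        pert[k, ..., i, j] = 1j * h
    W = _energy_from_F(params, Fb + pert,
                       None if fib is None else np.broadcast_to(fib, (9,) + fib.shape),
                       include_volumetric)
    P = np.moveaxis(W.imag / h, 0, -1).reshape(F.shape[:-2] + (3, 3))
    return P


def cauchy_stress(params: MaterialParams, state: DeformationState) -> np.ndarray:
    """Cauchy stress sigma = (1/J) P F^T = (2/J) F (dW/dC) F^T, in kPa."""
    F = np.asarray(state.F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise ValueError("det F must be positive")
    P = first_piola_stress(params, state)
    sigma = P @ np.swapaxes(F, -1, -2) / J[..., None, None]
    return 0.5 * (sigma + np.swapaxes(sigma, -1, -2))


def uniaxial_response(params: MaterialParams, direction: str, stretches,
                      transverse_tol: float = 1e-6):
    """Cauchy stress-stretch curve with traction-free transverse directions.

    ``direction`` is "circumferential" or "axial"; principal axes are
    (radial, circumferential, axial).  The two transverse stretches are
    solved so the transverse Cauchy stresses vanish (|residual| <
    ``transverse_tol`` kPa).  Returns (stretches, stresses) arrays.
    """
    if direction not in ("circumferential", "axial"):
        raise ValueError("direction must be 'circumferential' or 'axial'")
    loaded = 1 if direction == "circumferential" else 2
    trans = [i for i in (0, 1, 2) if i != loaded]
    stretches = np.asarray(stretches, dtype=float)
    if np.any(stretches < 1.0):
        raise ValueError("stretches must be >= 1")
    fib = None
    if not params.is_isotropic:
        fib = fiber_direction(params.fiber_angle_deg, (0.0, 1.0, 0.0))

    def stress_at(lam_loaded, lam_trans):
        lams = np.ones(3)
        lams[loaded] = lam_loaded
        lams[trans[0]], lams[trans[1]] = lam_trans
        st = DeformationState(np.diag(lams), fib)
        return cauchy_stress(params, st)

    sigmas = np.empty_like(stretches)
    guess = None
    for k, lam in enumerate(stretches):
        if guess is None:
            guess = np.array([lam ** -0.5, lam ** -0.5])

        def resid(x, lam=lam):
            s = stress_at(lam, x)
            return [s[trans[0], trans[0]], s[trans[1], trans[1]]]

        sol = optimize.root(resid, guess, method="hybr", tol=1e-12)
        if not sol.success or np.max(np.abs(sol.fun)) > transverse_tol:
            raise RuntimeError(
                f"transverse equilibrium failed at stretch {lam:.4f} "
                f"(residual {np.max(np.abs(sol.fun)):.2e} kPa)"
            )
        guess = sol.x
        sigmas[k] = stress_at(lam, sol.x)[loaded, loaded]
    return stretches, sigmas
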