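"""Semi-analytic inflation of a layered incompressible cylinder.

The oracle for the finite-element solver: a concentric layered thick-walled
cylinder, starting from its zero-stress opened sector (central angle
Theta_s), wrapped closed, stretched axially by lambda_z and pressurized.
Under incompressibility the deformation is fully determined by the deformed
inner radius r_i through

    r(R)^2 = r_i^2 + (Theta_s / (2*pi*lambda_z)) * (R^2 - R_i^2)

with circumferential stretch lambda_theta = 2*pi*r / (Theta_s*R).  Radial
equilibrium d(sigma_rr)/dr = (sigma_tt - sigma_rr)/r is integrated outward
from sigma_rr(inner) = -pressure, and r_i is found by shooting so that the
outer wall is traction-free.  The stress differences follow from the
incompressible strain energy via

    sigma_tt - sigma_rr = lambda_theta * dW/dlambda_theta
    sigma_zz - sigma_rr = lambda_z     * dW/dlambda_z

(derivatives taken along volume-preserving paths).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

from .materials import MaterialParams, DeformationState, fiber_direction, strain_energy


@dataclass
class TransmuralProfile:
    """Radial profiles through the deformed wall at one load state."""

    r: np.ndarray  # deformed radius, mm
    R: np.ndarray  # zero-stress (reference) radius, mm
    sigma_rr: np.ndarray  # kPa
    sigma_tt: np.ndarray
    sigma_zz: np.ndarray
    lambda_theta: np.ndarray
    green_strain_tt: np.ndarray  # circumferential Green-Lagrange strain
    layer_index: np.ndarray  # per station
    inner_radius: float
    outer_residual: float  # |sigma_rr(outer)| after shooting, kPa

    @property
    def max_principal_stress(self) -> np.ndarray:
        return np.max(np.stack([self.sigma_rr, self.sigma_tt, self.sigma_zz]), axis=0)


def _incompressible_energy(mat: MaterialParams, lam_r, lam_t, lam_z):
    """Deviatoric strain energy at a principal, volume-preserving state."""
    lam_r = np.asarray(lam_r)
    dtype = complex if np.iscomplexobj(lam_r) or np.iscomplexobj(lam_t) \
        or np.iscomplexobj(lam_z) else float
    shape = np.broadcast_shapes(np.shape(lam_r), np.shape(lam_t), np.shape(lam_z))
    F = np.zeros(shape + (3, 3), dtype=dtype)
    F[..., 0, 0], F[..., 1, 1], F[..., 2, 2] = lam_r, lam_t, lam_z
    fib = None
    if not mat.is_isotropic:
        fib = np.broadcast_to(
            fiber_direction(mat.fiber_angle_deg, (0.0, 1.0, 0.0)), shape + (3,))
    from .materials import _energy_from_F
    return _energy_from_F(mat, F, fib, include_volumetric=False)


def _stress_differences(mat: MaterialParams, lam_t, lam_z, h: float = 1e-20):
    """(sigma_tt - sigma_rr, sigma_zz - sigma_rr) at lambda_r = 1/(lam_t*lam_z).

    Derivatives along volume-preserving paths by the complex-step method.
    """
    lam_t = np.asarray(lam_t, dtype=float)
    lt = lam_t + 1j * h
    dW_dt = _incompressible_energy(mat, 1.0 / (lt * lam_z), lt, lam_z).imag / h
    lz = lam_z + 1j * h
    dW_dz = _incompressible_energy(mat, 1.0 / (lam_t * lz), lam_t, lz).imag / h
    return lam_t * dW_dt, lam_z * dW_dz


def solve_axisymmetric(radii_zero_stress, materials, sector_angle: float,
                       lambda_z: float, pressure_kpa: float,
                       n_per_layer: int = 200) -> TransmuralProfile:
    """Shoot on the deformed inner radius of a layered incompressible cylinder.

    Parameters
    ----------
    radii_zero_stress : interface radii [R_0 .. R_L] of the opened
        (zero-stress) sector, innermost first, mm.
    materials : one :class:`MaterialParams` per layer (len = L).
    sector_angle : central angle Theta_s of the zero-stress sector (2*pi for
        a stress-free closed ring, i.e. no residual stress).
    lambda_z : axial stretch applied to the closed vessel.
    pressure_kpa : lumen pressure.
    """
    R_if = np.asarray(radii_zero_stress, dtype=float)
    if R_if.ndim != 1 or R_if.size < 2 or np.any(np.diff(R_if) <= 0):
        raise ValueError("interface radii must be strictly increasing")
    if len(materials) != R_if.size - 1:
        raise ValueError("need one material per layer")
    if sector_angle <= 0 or sector_angle > 2 * np.pi + 1e-12:
        raise ValueError("sector angle must lie in (0, 2*pi]")
    k = sector_angle / (2.0 * np.pi)  # dtheta_deformed = dTheta / k ... r-map factor

    # reference radial grid, layer by layer (trapezoid panels per layer)
    R_list, layer_idx = [], []
    for li in range(len(materials)):
        Rg = np.linspace(R_if[li], R_if[li + 1], n_per_layer)
        R_list.append(Rg)
        layer_idx.append(np.full(Rg.size, li))
    R = np.concatenate(R_list)
    layer_idx = np.concatenate(layer_idx)

    def profiles(r_i):
        r = np.sqrt(r_i**2 + (k / lambda_z) * (R**2 - R_if[0] ** 2))
        lam_t = r / (k * R)
        dtt = np.empty_like(r)
        dzz = np.empty_like(r)
        for li, mat in enumerate(materials):
            m = layer_idx == li
            dtt[m], dzz[m] = _stress_differences(mat, lam_t[m], lambda_z)
        return r, lam_t, dtt, dzz

    def outer_sigma_rr(r_i):
        r, _, dtt, _ = profiles(r_i)
        # piecewise trapezoid of (sigma_tt - sigma_rr)/r dr, continuous across layers
        s = -pressure_kpa
        for li in range(len(materials)):
            m = layer_idx == li
            s += np.trapezoid(dtt[m] / r[m], r[m])
        return s

    # initial estimate: midwall circumferential stretch near 1 when unloaded
    R_mid = 0.5 * (R_if[0] + R_if[-1])
    r_i0 = np.sqrt(max((k * R_mid) ** 2 - (k / lambda_z) * (R_mid**2 - R_if[0] ** 2),
                       1e-12))

    def safe(r_i):
        try:
            return outer_sigma_rr(r_i)
        except FloatingPointError:
            # material exponentials overflowed: far outside the physical range
            return np.inf if r_i > r_i0 else -np.inf

    lo, hi = 0.93 * r_i0, 1.07 * r_i0
    flo, fhi = safe(lo), safe(hi)
    grow = 0
    while flo * fhi > 0 and grow < 200:
        if fhi < 0:  # need larger inflation
            lo, flo = hi, fhi
            hi *= 1.05
            fhi = safe(hi)
        else:
            hi, fhi = lo, flo
            lo *= 0.95
            flo = safe(lo)
        grow += 1
    if not (np.isfinite(flo) and np.isfinite(fhi)) or flo * fhi > 0:
        raise RuntimeError(
            f"shooting bracket failure: sigma_rr(outer) = [{flo:.3e}, {fhi:.3e}] "
            f"kPa over r_i in [{lo:.4f}, {hi:.4f}] mm")
    r_i = optimize.brentq(outer_sigma_rr, lo, hi, xtol=1e-13, rtol=1e-15)

    r, lam_t, dtt, dzz = profiles(r_i)
    sigma_rr = np.empty_like(r)
    acc = -pressure_kpa
    pos = 0
    for li in range(len(materials)):
        m = layer_idx == li
        rl, fl = r[m], dtt[m] / r[m]
        seg = np.concatenate([[0.0], np.cumsum(0.5 * (fl[1:] + fl[:-1]) * np.diff(rl))])
        sigma_rr[m] = acc + seg
        acc = sigma_rr[m][-1]
        pos += rl.size
    sigma_tt = sigma_rr + dtt
    sigma_zz = sigma_rr + dzz
    return TransmuralProfile(
        r=r, R=R, sigma_rr=sigma_rr, sigma_tt=sigma_tt, sigma_zz=sigma_zz,
        lambda_theta=lam_t, green_strain_tt=0.5 * (lam_t**2 - 1.0),
        layer_index=layer_idx, inner_radius=float(r_i),
        outer_residual=abs(float(sigma_rr[-1])),
    )
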