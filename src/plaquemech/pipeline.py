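"""Per-case four-model orchestration and cohort comparison statistics.

For each case four thin-slice models are built and solved: multi-layer and
single-layer walls, each with and without residual stress.  The
circumferential pre-shrink is calibrated per variant so the slice
pressurized to diastolic pressure matches the imaged (in vivo) lumen to
< 0.1%.  Stress/strain are reported as the maximum principal values sampled
at 100 points per wall (inner and outer) using the four-quarter equal-step
extraction, and aggregated into cohort tables of Mean +/- STD of absolute
values and of with/without-residual percent ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .contours import LayeredContourSet
from .geometry import build_layered_mesh, open_to_zero_stress
from .materials import MATERIAL_LIBRARY
from .mechanics import (LoadProtocol, SolverConfig, SolvedState, run_three_step)

#: the four model variants: (layer mode, residual stress included)
VARIANTS = (("multi", True), ("multi", False), ("single", True), ("single", False))

QUANTITIES = (
    "inner_stress_max", "inner_stress_mean", "inner_strain_max", "inner_strain_mean",
    "outer_stress_max", "outer_stress_mean", "outer_strain_max", "outer_strain_mean",
)

_RATIO_EPS = 1e-9  # |denominator| below this: ratio undefined (excluded, counted)


# ----------------------------------------------------------------- extraction
@dataclass
class WallSamples:
    """100 paired inner/outer wall sample points with their field values."""

    inner_xy: np.ndarray  # (100, 2) mm, deformed
    outer_xy: np.ndarray
    inner_stress: np.ndarray  # (100,) kPa, max principal
    outer_stress: np.ndarray
    inner_strain: np.ndarray  # (100,) max principal Green-Lagrange
    outer_strain: np.ndarray
    quarter: np.ndarray  # (100,) quarter index 0..3

    def __post_init__(self) -> None:
        for name in ("inner_xy", "outer_xy"):
            if getattr(self, name).shape[0] != 100:
                raise ValueError("exactly 100 points per wall are required")
        counts = np.bincount(self.quarter, minlength=4)
        if not np.all(counts == 25):
            raise ValueError(f"need 25 points per quarter, got {counts}")


def _boundary_samples(x_nodes, centroid, n_per_quarter=25):
    """Equal-arc-length points per angular quarter of a closed polyline.

    Returns (points (100, 2), segment index per point, quarter index).
    """
    n = x_nodes.shape[0]
    closed = np.vstack([x_nodes, x_nodes[:1]])
    seg = np.diff(closed, axis=0)
    seg_len = np.linalg.norm(seg, axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg_len)])  # (n+1,)
    ang = np.mod(np.arctan2(closed[:, 1] - centroid[1],
                            closed[:, 0] - centroid[0]), 2 * np.pi)
    # unwrap to a monotone angle along the CCW polyline
    angu = np.concatenate([[ang[0]], ang[0] + np.cumsum(
        np.mod(np.diff(ang) + np.pi, 2 * np.pi) - np.pi)])
    # arc-length stations where the polyline crosses each quarter ray
    bounds = ang[0] + np.array([0.0, 0.5, 1.0, 1.5]) * np.pi
    bounds = np.sort(np.mod(bounds - angu[0], 2 * np.pi)) + angu[0]
    s_bounds = np.interp(bounds, angu, s)
    s_bounds = np.concatenate([s_bounds, [s_bounds[0] + s[-1]]])

    pts, seg_idx, quarter = [], [], []
    for q in range(4):
        L = s_bounds[q + 1] - s_bounds[q]
        st = s_bounds[q] + (np.arange(n_per_quarter) + 0.5) / n_per_quarter * L
        st = np.mod(st, s[-1])
        j = np.clip(np.searchsorted(s, st, side="right") - 1, 0, n - 1)
        t = (st - s[j]) / seg_len[j]
        pts.append(closed[j] + t[:, None] * seg[j])
        seg_idx.append(j)
        quarter.append(np.full(n_per_quarter, q))
    return np.vstack(pts), np.concatenate(seg_idx), np.concatenate(quarter)


def sample_wall_points(state: SolvedState) -> WallSamples:
    """Four-quarter equal-step extraction of 100 points per wall.

    Both wall contours are split into four quarters at the rays 0/90/180/270
    degrees from the deformed lumen centroid; 25 points per quarter are
    placed at equal arc-length steps and paired by index.  Fields are the
    per-element maximum principal stress/strain of the boundary element the
    point lies on.
    """
    mesh = state.mesh
    if mesh.cut_face_a is not None and mesh.closed_nodes is None:
        raise ValueError("state must come from a closed (or wrapped) configuration")
    x = state.deformed_nodes
    cen = state.lumen_centroid()
    nt = mesh.n_theta
    inner_nodes = x[mesh.lumen_edges[:, 0]]
    outer_nodes = x[mesh.outer_edges[:, 0]]
    in_xy, in_seg, quarter = _boundary_samples(inner_nodes, cen)
    out_xy, out_seg, _ = _boundary_samples(outer_nodes, cen)

    inner_elems = in_seg  # element e = i*n_theta + j; inner row i = 0
    outer_elems = (mesh.n_rows - 2) * nt + out_seg
    return WallSamples(
        inner_xy=in_xy,
        outer_xy=out_xy,
        inner_stress=state.max_principal_stress[inner_elems],
        outer_stress=state.max_principal_stress[outer_elems],
        inner_strain=state.max_principal_strain[inner_elems],
        outer_strain=state.max_principal_strain[outer_elems],
        quarter=quarter,
    )


def summarize_samples(samples: WallSamples) -> dict:
    """The eight per-variant summary quantities from the 100-point samples."""
    return {
        "inner_stress_max": float(samples.inner_stress.max()),
        "inner_stress_mean": float(samples.inner_stress.mean()),
        "inner_strain_max": float(samples.inner_strain.max()),
        "inner_strain_mean": float(samples.inner_strain.mean()),
        "outer_stress_max": float(samples.outer_stress.max()),
        "outer_stress_mean": float(samples.outer_stress.mean()),
        "outer_strain_max": float(samples.outer_strain.max()),
        "outer_strain_mean": float(samples.outer_strain.mean()),
    }


# ----------------------------------------------------------------- calibration
@dataclass
class CalibrationResult:
    s_circ: float
    lambda_z: float
    no_load_contours: LayeredContourSet
    mismatch: float  # relative lumen-circumference mismatch at convergence
    history: list  # [(s_circ, mismatch), ...]


def _variant_state(contours, layers, residual, materials, opening_angle_deg,
                   lambda_z, pressure_mmhg, n_radial, n_theta, config,
                   protocol_kw=None) -> SolvedState:
    """Solve one variant from given no-load contours."""
    single = layers == "single"
    if residual:
        geo = open_to_zero_stress(contours, opening_angle_deg)
        mesh = build_layered_mesh(geo, n_radial=n_radial, n_theta=n_theta,
                                  single_layer=single)
    else:
        mesh = build_layered_mesh(contours, n_radial=n_radial, n_theta=n_theta,
                                  single_layer=single)
    prot = LoadProtocol(lambda_z=lambda_z, pressure_mmhg=pressure_mmhg,
                        **(protocol_kw or {}))
    return run_three_step(mesh, materials, prot, config)


def calibrate_shrinkage(in_vivo: LayeredContourSet, diastolic_mmhg: float,
                        layers: str = "multi", residual: bool = True,
                        materials: dict | None = None,
                        opening_angle_deg: float = 120.0,
                        s_axial: float = 0.05, s_init: float = 0.05,
                        tol: float = 1e-3, max_iterations: int = 15,
                        n_radial=(2, 2, 2), n_theta: int = 32,
                        config: SolverConfig | None = None) -> CalibrationResult:
    """Iterate the circumferential pre-shrink until the pressurized slice
    matches the in vivo geometry.

    Starting from ``s_init`` (5%), each iteration shrinks the in vivo
    contours, runs the variant's loading programme to diastolic pressure and
    compares the pressurized lumen circumference with the imaged one; the
    shrink is updated by a secant rule until the relative mismatch is below
    ``tol`` (0.1%).
    """
    if diastolic_mmhg <= 0:
        raise ValueError("diastolic pressure must be positive")
    materials = materials or MATERIAL_LIBRARY
    lam_z = 1.0 / (1.0 - s_axial)
    # discretization-consistent target: in vivo lumen polyline at mesh resolution
    ang = np.linspace(0.0, 2 * np.pi, n_theta, endpoint=False)
    lum = in_vivo.radius("lumen", ang)
    xy = np.column_stack([lum * np.cos(ang), lum * np.sin(ang)])
    target = float(np.sum(np.linalg.norm(np.roll(xy, -1, axis=0) - xy, axis=1)))

    def mismatch(s):
        shrunk = in_vivo.scaled(1.0 - s)
        st = _variant_state(shrunk, layers, residual, materials,
                            opening_angle_deg, lam_z, diastolic_mmhg,
                            n_radial, n_theta, config)
        return (st.lumen_circumference() - target) / target, shrunk

    history = []
    s0 = float(np.clip(s_init, 0.0, 0.45))
    g0, shrunk0 = mismatch(s0)
    history.append((s0, g0))
    if abs(g0) < tol:
        return CalibrationResult(s0, lam_z, shrunk0, g0, history)
    # first update from the near-affine response C(s) ~ (1 - s)
    s1 = float(np.clip(1.0 - (1.0 - s0) / (1.0 + g0), 0.0, 0.45))
    while len(history) < max_iterations:
        g1, shrunk1 = mismatch(s1)
        history.append((s1, g1))
        if abs(g1) < tol:
            return CalibrationResult(s1, lam_z, shrunk1, g1, history)
        denom = g1 - g0
        if abs(denom) < 1e-14:
            s2 = s1
        else:
            s2 = s1 - g1 * (s1 - s0) / denom  # secant step
        s0, g0 = s1, g1
        s1 = float(np.clip(s2, 0.0, 0.45))
    raise RuntimeError(
        f"shrink calibration did not converge in {max_iterations} iterations; "
        f"history: {[(round(s, 5), round(g, 6)) for s, g in history]}")


# ----------------------------------------------------------------- comparison
@dataclass
class ComparisonRow:
    """Per-case absolute values and with/without-residual percent ratios."""

    case_id: str
    values: dict  # (layers, residual) -> {quantity: value}
    ratios: dict = field(default_factory=dict)  # (layers, quantity) -> percent
    undefined_ratios: int = 0
    extras: dict = field(default_factory=dict)

    @classmethod
    def from_values(cls, case_id: str, values: dict,
                    ratios: dict | None = None) -> "ComparisonRow":
        """Build a row from per-variant values; ratios computed when absent.

        ``ratios`` may carry externally reported percent ratios (they take
        precedence, since published ratios are often computed from unrounded
        values).
        """
        row = cls(case_id, values, dict(ratios or {}))
        for layers in ("multi", "single"):
            if (layers, True) not in values or (layers, False) not in values:
                continue
            for q in QUANTITIES:
                key = (layers, q)
                if key in row.ratios:
                    continue
                num = values[(layers, True)].get(q)
                den = values[(layers, False)].get(q)
                if num is None or den is None:
                    continue
                if abs(den) < _RATIO_EPS:
                    row.ratios[key] = np.nan
                    row.undefined_ratios += 1
                else:
                    row.ratios[key] = 100.0 * num / den
        return row


@dataclass
class CohortTable:
    """Cohort Mean +/- STD of absolute quantities and of percent ratios.

    STD is the sample (n-1) standard deviation.  Headline percentages follow
    the mean-of-ratios convention: reduction% = 100 - mean(ratio%), and
    increase% = mean(ratio%) - 100.
    """

    n: int
    abs_mean: dict  # (layers, residual, quantity) -> float
    abs_std: dict
    ratio_mean: dict  # (layers, quantity) -> float
    ratio_std: dict
    undefined_ratio_count: int = 0

    def reduction_percent(self, layers: str, quantity: str) -> float:
        return 100.0 - self.ratio_mean[(layers, quantity)]

    def increase_percent(self, layers: str, quantity: str) -> float:
        return self.ratio_mean[(layers, quantity)] - 100.0

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for (layers, residual, q), m in sorted(self.abs_mean.items()):
            rows.append({
                "layers": layers, "residual": "with" if residual else "without",
                "quantity": q, "mean": m, "std": self.abs_std[(layers, residual, q)],
            })
        return pd.DataFrame(rows)

    def ratios_frame(self) -> pd.DataFrame:
        rows = []
        for (layers, q), m in sorted(self.ratio_mean.items()):
            rows.append({
                "layers": layers, "quantity": q,
                "ratio_mean_pct": m, "ratio_std_pct": self.ratio_std[(layers, q)],
            })
        return pd.DataFrame(rows)


def _sample_std(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1)) if x.size > 1 else 0.0


def cohort_table(rows) -> CohortTable:
    """Column-wise Mean and sample STD over the cohort rows."""
    if not rows:
        raise ValueError("need at least one comparison row")
    abs_mean, abs_std, ratio_mean, ratio_std = {}, {}, {}, {}
    variants = {k for r in rows for k in r.values}
    for (layers, residual) in variants:
        for q in QUANTITIES:
            vals = [r.values[(layers, residual)][q] for r in rows
                    if (layers, residual) in r.values
                    and q in r.values[(layers, residual)]]
            if not vals:
                continue
            abs_mean[(layers, residual, q)] = float(np.mean(vals))
            abs_std[(layers, residual, q)] = _sample_std(vals)
    keys = {k for r in rows for k in r.ratios}
    for key in keys:
        vals = [r.ratios[key] for r in rows
                if key in r.ratios and np.isfinite(r.ratios[key])]
        if not vals:
            continue
        ratio_mean[key] = float(np.mean(vals))
        ratio_std[key] = _sample_std(vals)
    undef = sum(r.undefined_ratios for r in rows)
    return CohortTable(len(rows), abs_mean, abs_std, ratio_mean, ratio_std, undef)


# ----------------------------------------------------------------- four models
def run_four_models(case_id: str, in_vivo: LayeredContourSet,
                    systolic_mmhg: float, diastolic_mmhg: float,
                    opening_angle_deg: float = 120.0,
                    materials: dict | None = None,
                    reporting_pressure: str = "systolic",
                    variants=VARIANTS,
                    n_radial=(3, 3, 3), n_theta: int = 48,
                    calib_n_radial=(2, 2, 2), calib_n_theta: int = 32,
                    s_axial: float = 0.05,
                    config: SolverConfig | None = None):
    """Calibrate and solve the four model variants for one case.

    Returns (states, row): per-variant :class:`SolvedState` and the
    :class:`ComparisonRow` of 100-point extraction statistics.  Single-layer
    variants bind the intima parameters to the whole wall; with/without
    pairs share one discretization per layer mode.  The reporting pressure
    is systolic by default (diastolic pressure is consumed by the shrink
    calibration); ``reporting_pressure`` may be "systolic", "diastolic" or
    "mean" (the usual (2*dia + sys)/3 estimate).
    """
    materials = materials or MATERIAL_LIBRARY
    p_report = {
        "systolic": systolic_mmhg,
        "diastolic": diastolic_mmhg,
        "mean": (2.0 * diastolic_mmhg + systolic_mmhg) / 3.0,
    }[reporting_pressure]
    states, values, extras = {}, {}, {}
    for layers, residual in variants:
        cal = calibrate_shrinkage(
            in_vivo, diastolic_mmhg, layers=layers, residual=residual,
            materials=materials, opening_angle_deg=opening_angle_deg,
            s_axial=s_axial, n_radial=calib_n_radial, n_theta=calib_n_theta,
            config=config)
        try:
            st = _variant_state(
                cal.no_load_contours, layers, residual, materials,
                opening_angle_deg, cal.lambda_z, p_report,
                n_radial, n_theta, config)
        except RuntimeError as exc:
            raise RuntimeError(
                f"{case_id} [{layers}, residual={residual}]: {exc}") from exc
        states[(layers, residual)] = st
        values[(layers, residual)] = summarize_samples(sample_wall_points(st))
        stt = st.sigma_theta_theta()
        extras[("cov_sigma_tt", layers, residual)] = float(
            np.std(stt) / abs(np.mean(stt))) if abs(np.mean(stt)) > 0 else np.inf
        extras[("calibration", layers, residual)] = {
            "s_circ": cal.s_circ, "mismatch": cal.mismatch,
            "iterations": len(cal.history)}
    row = ComparisonRow.from_values(case_id, values)
    row.extras = extras
    return states, row


def rows_to_frame(rows) -> pd.DataFrame:
    """Flat per-case table (one row per case) for CSV export."""
    recs = []
    for r in rows:
        rec = {"case": r.case_id}
        for (layers, residual), vals in r.values.items():
            tag = f"{layers}_{'with' if residual else 'without'}"
            rec.update({f"{q}_{tag}": v for q, v in vals.items()})
        for (layers, q), v in r.ratios.items():
            rec[f"ratio_pct_{q}_{layers}"] = v
        recs.append(rec)
    return pd.DataFrame(recs)
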