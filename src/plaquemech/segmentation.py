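"""Multi-layer interface detection on polar OCT images, and contour repair.

Detection is a Canny-style pipeline adapted to the anatomy of polar OCT
slices: a Gaussian-derivative gradient along the depth axis only, two
gradient thresholds with hysteresis linking along theta, and an ordered
outward assignment of the four interfaces (lumen, IEM, EEM, ADV) with
minimum-gap constraints and the expected gradient-sign sequence
(+, -, +, -) of the bright-intima / darker-media / brighter-adventitia
appearance.  A-lines whose gradients stay below the low threshold (e.g. in
a guide-wire shadow) are marked not visible.

Missing portions are repaired by fitting the radial surface r = r(z, theta):
across slices first (where a neighbouring slice sees the interface at the
same angle) and then with a periodic cubic spline in theta within each
slice; a single slice falls back to the theta spline alone.  Interface
ordering in the output is enforced by iterated averaging of violating pairs
with a minimum radial gap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import CubicSpline

from .contours import LayeredContourSet, INTERFACES, LAYER_BANDS, LAYERS
from .synthetic import PolarImage

#: expected depth-gradient sign of each interface, inside -> outside
_EDGE_SIGN = {"lumen": +1, "iem": -1, "eem": +1, "adv": -1}


@dataclass
class DetectionParams:
    """Tunable settings of the layer-boundary detector (defaults fit phantoms)."""

    sigma_depth: float = 1.5  # px, Gaussian derivative scale along depth
    sigma_theta: float = 2.0  # rows, smoothing across A-lines
    high_fraction: float = 0.35  # high threshold, fraction of robust max gradient
    low_fraction: float = 0.12  # low threshold for hysteresis candidates
    min_gap_px: int = 4  # minimum radial separation of interfaces
    link_depth_px: int = 5  # max radial jump for theta-linking
    contrast_floor: float = 1e-6  # below this dynamic range: no edges at all
    step_window_px: int = 6  # half-window for the step-contrast validation
    step_sigmas: float = 3.0  # required step size in units of the noise scale


@dataclass
class PartialContours:
    """Per-A-line interface radii with a visibility mask (missing = NaN)."""

    angles: np.ndarray  # rad
    radii: dict  # interface -> (n,) mm, NaN where not visible
    visibility: dict  # interface -> (n,) bool

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        n = self.angles.size
        for k in INTERFACES:
            self.radii[k] = np.asarray(self.radii[k], dtype=float)
            self.visibility[k] = np.asarray(self.visibility[k], dtype=bool)
            if self.radii[k].shape != (n,) or self.visibility[k].shape != (n,):
                raise ValueError(f"bad shapes for interface {k!r}")
        all_vis = np.logical_and.reduce([self.visibility[k] for k in INTERFACES])
        for a, b in zip(INTERFACES[:-1], INTERFACES[1:]):
            if np.any(self.radii[a][all_vis] >= self.radii[b][all_vis]):
                raise ValueError(f"interfaces {a}/{b} cross where both visible")

    def coverage(self, name: str) -> float:
        return float(np.mean(self.visibility[name]))


def _ordered_chain(cands, scores, signs_ok, min_gap):
    """Best (max total score) ordered 4-chain of edge candidates in one A-line.

    ``cands``: sorted candidate depths; ``signs_ok``: (4, C) admissibility of
    each candidate for each interface.  Returns indices into cands (4,) or
    None when no admissible chain exists.
    """
    C = len(cands)
    NEG = -np.inf
    best = np.full((4, C), NEG)
    back = np.full((4, C), -1, dtype=int)
    for c in range(C):
        if signs_ok[0, c]:
            best[0, c] = scores[c]
    for k in range(1, 4):
        for c in range(C):
            if not signs_ok[k, c]:
                continue
            for p in range(c):
                if cands[c] - cands[p] < min_gap:
                    continue
                if best[k - 1, p] + scores[c] > best[k, c]:
                    best[k, c] = best[k - 1, p] + scores[c]
                    back[k, c] = p
    end = int(np.argmax(best[3]))
    if not np.isfinite(best[3, end]):
        return None
    out = [end]
    for k in range(3, 0, -1):
        out.append(back[k, out[-1]])
    return out[::-1]


def detect_layer_boundaries(image: PolarImage,
                            params: DetectionParams | None = None) -> PartialContours:
    """Detect the four wall interfaces on a polar image.

    Returns per-A-line radii (mm) and visibility masks; an all-background
    image yields an empty result (all masks False), not an exception.
    """
    params = params or DetectionParams()
    img = image.pixels
    n_rows, n_depth = img.shape
    empty = PartialContours(
        image.angle_of_row,
        {k: np.full(n_rows, np.nan) for k in INTERFACES},
        {k: np.zeros(n_rows, dtype=bool) for k in INTERFACES},
    )
    if img.max() - img.min() < params.contrast_floor:
        return empty

    # depth-directional Gaussian derivative with theta smoothing (periodic)
    g = ndimage.gaussian_filter(img, (params.sigma_theta, params.sigma_depth),
                                order=(0, 1), mode=("wrap", "nearest"))
    scale = np.percentile(np.abs(g), 99.5)
    if scale < params.contrast_floor:
        return empty
    high, low = params.high_fraction * scale, params.low_fraction * scale

    # absolute noise scale for the step-contrast test (rejects pure speckle)
    hp = img - ndimage.uniform_filter(img, (1, 5), mode="nearest")
    sigma_n = 1.4826 * np.median(np.abs(hp))
    th_sm = ndimage.gaussian_filter(img, (params.sigma_theta, 0.0), mode=("wrap", "nearest"))
    step_need = max(params.step_sigmas * sigma_n * np.sqrt(2.0 / params.step_window_px),
                    params.contrast_floor)

    def step_ok(row, d, sign):
        w = params.step_window_px
        a = th_sm[row, max(d - w - 1, 0):max(d - 1, 1)].mean()
        b = th_sm[row, d + 2:d + 2 + w].mean() if d + 2 < n_depth else a
        return sign * (b - a) >= step_need

    radii_px = np.full((4, n_rows), np.nan)
    strength = np.zeros((4, n_rows))
    interior = np.arange(1, n_depth - 1)
    for row in range(n_rows):
        gr = g[row]
        peaks = interior[(np.abs(gr[1:-1]) >= np.abs(gr[:-2]))
                         & (np.abs(gr[1:-1]) >= np.abs(gr[2:]))
                         & (np.abs(gr[1:-1]) >= low)]
        if peaks.size == 0:
            continue
        keep = np.array([step_ok(row, int(d), int(np.sign(gr[d]))) for d in peaks])
        peaks = peaks[keep]
        if peaks.size == 0:
            continue
        scores = np.abs(gr[peaks])
        signs_ok = np.array([np.sign(gr[peaks]) == _EDGE_SIGN[k]
                             for k in INTERFACES])
        chain = _ordered_chain(peaks, scores, signs_ok, params.min_gap_px)
        if chain is None:
            continue
        for k in range(4):
            radii_px[k, row] = peaks[chain[k]]
            strength[k, row] = scores[chain[k]]

    # hysteresis: strong rows seed; weaker rows join when radially close to a
    # visible neighbour (linking along theta, periodic)
    visibility = {}
    for k, name in enumerate(INTERFACES):
        has = np.isfinite(radii_px[k])
        vis = has & (strength[k] >= high)
        cand = has & ~vis
        for _ in range(n_rows):
            prev_r = np.roll(radii_px[k] * np.where(vis, 1, np.nan), 1)
            next_r = np.roll(radii_px[k] * np.where(vis, 1, np.nan), -1)
            near = cand & (
                (np.abs(radii_px[k] - prev_r) <= params.link_depth_px)
                | (np.abs(radii_px[k] - next_r) <= params.link_depth_px))
            if not np.any(near):
                break
            vis = vis | near
            cand = cand & ~near
        visibility[name] = vis
    radii = {}
    for k, name in enumerate(INTERFACES):
        r = (radii_px[k] + 0.5) * image.pixel_size
        r[~visibility[name]] = np.nan
        radii[name] = r
    return PartialContours(image.angle_of_row, radii, visibility)


# ------------------------------------------------------------------ repair
def _periodic_spline_fill(angles, values, visible):
    """Fill NaNs with an interpolating periodic cubic spline through the
    visible samples."""
    if visible.all():
        return values.copy()
    th = angles[visible]
    v = values[visible]
    th_ext = np.concatenate([th, [th[0] + 2 * np.pi]])
    v_ext = np.concatenate([v, [v[0]]])
    cs = CubicSpline(th_ext, v_ext, bc_type="periodic")
    out = values.copy()
    miss = ~visible
    out[miss] = cs(np.mod(angles[miss] - th[0], 2 * np.pi) + th[0])
    return out


def _harmonic_fit(angles, values, visible, n_harmonics):
    """Least-squares truncated Fourier series through the visible samples."""
    th = angles[visible]
    v = values[visible]
    cols = [np.ones_like(th)]
    for k in range(1, n_harmonics + 1):
        cols.extend([np.cos(k * th), np.sin(k * th)])
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, v, rcond=None)
    cols_all = [np.ones_like(angles)]
    for k in range(1, n_harmonics + 1):
        cols_all.extend([np.cos(k * angles), np.sin(k * angles)])
    return np.column_stack(cols_all) @ coef


def enforce_ordering(radii: dict, min_gap: float, max_iter: int = 200) -> dict:
    """Project radial functions onto the ordered cone (lumen < ... < ADV).

    Violating adjacent pairs are replaced by their mean -/+ min_gap/2,
    iterated to convergence; deterministic and mean-preserving.
    """
    out = {k: radii[k].copy() for k in INTERFACES}
    for _ in range(max_iter):
        changed = False
        for a, b in zip(INTERFACES[:-1], INTERFACES[1:]):
            bad = out[a] > out[b] - min_gap
            if np.any(bad):
                changed = True
                mid = 0.5 * (out[a][bad] + out[b][bad])
                out[a][bad] = mid - 0.5 * min_gap
                out[b][bad] = mid + 0.5 * min_gap
        if not changed:
            break
    return out


def repair_contours(stack, z_positions=None, smoothing_harmonics: int | None = None,
                    min_coverage: float = 0.5, min_gap_mm: float = 0.011):
    """Fill missing interface portions of a slice stack by surface fitting.

    ``stack`` is a list of :class:`PartialContours` sharing one angular grid;
    ``z_positions`` are the slice axial stations (defaults to the slice
    index).  Where an angle is missing on one slice but seen on others, the
    radial surface is interpolated across z; remaining gaps are bridged by a
    periodic interpolating cubic spline in theta (exact on fully visible
    input).  ``smoothing_harmonics`` switches to a least-squares truncated
    Fourier fit of that order (for noisy detections).  Raises when an
    interface is visible on less than ``min_coverage`` of all (z, theta)
    samples.  Returns a list of :class:`LayeredContourSet`.
    """
    if isinstance(stack, PartialContours):
        stack = [stack]
    if z_positions is None:
        z_positions = np.arange(len(stack), dtype=float)
    z_positions = np.asarray(z_positions, dtype=float)
    angles = stack[0].angles
    n = angles.size
    for pc in stack:
        if pc.angles.shape != angles.shape or not np.allclose(pc.angles, angles):
            raise ValueError("all slices must share one angular grid")

    for name in INTERFACES:
        cov = np.mean([pc.coverage(name) for pc in stack])
        if cov < min_coverage:
            raise ValueError(
                f"interface {name!r} visible on only {cov:.0%} of samples "
                f"(need >= {min_coverage:.0%})")

    out = []
    nz = len(stack)
    filled = {name: np.stack([pc.radii[name] for pc in stack]) for name in INTERFACES}
    if nz > 1:
        for name in INTERFACES:
            grid = filled[name]  # (nz, n)
            vis = np.isfinite(grid)
            for j in range(n):
                col_vis = vis[:, j]
                if col_vis.all() or col_vis.sum() < 2:
                    continue
                grid[~col_vis, j] = np.interp(
                    z_positions[~col_vis], z_positions[col_vis], grid[col_vis, j])
    for iz in range(nz):
        radii = {}
        for name in INTERFACES:
            vals = filled[name][iz]
            vis = np.isfinite(vals)
            if smoothing_harmonics is not None:
                radii[name] = _harmonic_fit(angles, vals, vis, smoothing_harmonics)
            else:
                radii[name] = _periodic_spline_fill(angles, vals, vis)
        radii = enforce_ordering(radii, min_gap_mm)
        out.append(LayeredContourSet(angles, radii, [], np.zeros(2)))
    return out


# ------------------------------------------------------------------ metrics
@dataclass
class SegmentationMetrics:
    """Per-interface radial errors and per-layer Dice coefficients."""

    mae_mm: dict  # interface -> mean absolute radial error, mm
    mae_px: dict | None  # same in pixels (when pixel size known)
    dice: dict  # layer -> Dice coefficient

    def to_row(self) -> dict:
        row = {f"mae_mm_{k}": v for k, v in self.mae_mm.items()}
        if self.mae_px:
            row.update({f"mae_px_{k}": v for k, v in self.mae_px.items()})
        row.update({f"dice_{k}": v for k, v in self.dice.items()})
        return row


def _layer_masks(contours: LayeredContourSet, grid_r, grid_t):
    masks = {}
    for layer, (a, b) in LAYER_BANDS.items():
        r_in = contours.radius(a, grid_t)
        r_out = contours.radius(b, grid_t)
        masks[layer] = (grid_r >= r_in) & (grid_r < r_out)
    return masks


def evaluate_segmentation(pred: LayeredContourSet, truth: LayeredContourSet,
                          pixel_size: float | None = None,
                          raster_n: int = 512) -> SegmentationMetrics:
    """Mean absolute radial error per interface and Dice per layer.

    Dice is computed from rasterized region masks on a common Cartesian
    pixel grid (pixel-centre point-in-annulus test about the shared
    centroid).  Contours with different centroid conventions are rejected.
    """
    if not np.allclose(pred.centroid, truth.centroid, atol=1e-9):
        raise ValueError("contour sets use different centroid conventions")
    ang = pred.angles
    mae_mm, mae_px = {}, {}
    for k in INTERFACES:
        err = np.abs(pred.radii[k] - truth.radius(k, ang))
        mae_mm[k] = float(np.mean(err))
        if pixel_size:
            mae_px[k] = mae_mm[k] / pixel_size
    rmax = 1.05 * max(pred.radii["adv"].max(), truth.radii["adv"].max())
    ax = np.linspace(-rmax, rmax, raster_n)
    X, Y = np.meshgrid(ax, ax)
    grid_r = np.hypot(X, Y).ravel()
    grid_t = np.mod(np.arctan2(Y, X), 2 * np.pi).ravel()
    masks_p = _layer_masks(pred, grid_r, grid_t)
    masks_t = _layer_masks(truth, grid_r, grid_t)
    dice = {}
    for layer in LAYERS:
        inter = np.count_nonzero(masks_p[layer] & masks_t[layer])
        total = np.count_nonzero(masks_p[layer]) + np.count_nonzero(masks_t[layer])
        dice[layer] = 2.0 * inter / total if total else 1.0
    return SegmentationMetrics(mae_mm, mae_px if pixel_size else None, dice)
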