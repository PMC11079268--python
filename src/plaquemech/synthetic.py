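"""Synthetic vessels, OCT-like phantom images and cohort generation.

Every downstream stage is testable without patient data: this module builds
irregular (Fourier-perturbed) three-layer vessel cross-sections with
optional lipid/calcification inclusions, renders them as polar OCT-like
phantom images (bright intima, darker media, brighter adventitia, a
guide-wire shadow sector, multiplicative speckle) with exact ground-truth
contours, and samples whole cohorts of cases with blood pressures in the
clinically observed range.  The phantoms exercise edge detection and repair;
they are deliberately not a physical OCT simulator (no ray tracing, catheter
eccentricity or pull-back distortion).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import imageio.v3 as iio
import numpy as np

from .contours import Component, LayeredContourSet, INTERFACES

#: mean grey level per region (arbitrary units in [0, 1])
DEFAULT_INTENSITIES = {
    "lumen": 0.04,          # blood-cleared lumen: near void
    "intima": 0.88,         # bright band
    "media": 0.42,          # darker
    "adventitia": 0.72,     # brighter again
    "periadventitia": 0.22,
    "lipid": 0.18,          # diffuse low-signal pool
    "calcification": 0.12,  # sharp-bordered low-signal region
}


@dataclass
class ComponentSpec:
    """A plaque component: angular extent, radial band and (lipid) cap.

    ``radial_band`` gives the fractions of the local intima band (between
    the lumen + cap and the IEM) that the component occupies.
    """

    kind: str  # "lipid" | "calcification"
    angular_extent: tuple  # (theta1, theta2) rad
    radial_band: tuple  # (f1, f2) in (0, 1)
    cap_thickness: float = 0.05  # mm, minimum intima between lumen and component

    def __post_init__(self) -> None:
        if self.kind not in ("lipid", "calcification"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        t1, t2 = self.angular_extent
        f1, f2 = self.radial_band
        if not t1 < t2:
            raise ValueError("angular extent must satisfy theta1 < theta2")
        if not (0.0 <= f1 < f2 <= 1.0):
            raise ValueError("radial band must satisfy 0 <= f1 < f2 <= 1")
        if self.cap_thickness <= 0:
            raise ValueError("cap thickness must be positive")


@dataclass
class VesselSpec:
    """Geometric recipe for one synthetic vessel cross-section.

    ``fourier_perturbation[i]`` lists (harmonic order k >= 2, amplitude mm,
    phase rad) terms added to interface i (lumen, IEM, EEM, ADV order).
    """

    base_radii: tuple = (1.5, 1.75, 2.0, 2.4)
    fourier_perturbation: tuple = ((), (), (), ())
    components: tuple = ()
    seed: int = 0

    def __post_init__(self) -> None:
        r = np.asarray(self.base_radii, dtype=float)
        if r.size != 4 or np.any(r <= 0) or np.any(np.diff(r) <= 0):
            raise ValueError(
                "base_radii must be four positive, strictly increasing lengths "
                "(lumen < IEM < EEM < ADV)")
        if len(self.fourier_perturbation) != 4:
            raise ValueError("need a perturbation list for each of 4 interfaces")
        min_gap = float(np.min(np.diff(r)))
        for name, terms in zip(INTERFACES, self.fourier_perturbation):
            amp = sum(abs(a) for (_, a, _) in terms)
            for (k, a, _) in terms:
                if k < 2:
                    raise ValueError(f"harmonic order must be >= 2 on {name}")
            if amp >= 0.4 * min_gap:
                raise ValueError(
                    f"perturbation amplitude sum {amp:.3f} mm on {name} exceeds "
                    f"0.4 x minimum inter-interface gap ({0.4 * min_gap:.3f} mm)")


@dataclass
class ImagingSpec:
    """Polar imaging geometry and appearance parameters of the phantom."""

    n_alines: int = 360
    n_depth: int = 320
    pixel_size: float = 0.011  # mm/pixel along depth
    shadow_sector: tuple | None = None  # (theta_a, theta_b) rad, or None
    speckle_scale: float = 0.0  # std of the unit-mean multiplicative noise
    layer_intensities: dict = field(default_factory=lambda: dict(DEFAULT_INTENSITIES))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_alines < 90 or self.n_depth < 64:
            raise ValueError("need n_alines >= 90 and n_depth >= 64")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.speckle_scale < 0:
            raise ValueError("speckle_scale must be >= 0")


@dataclass
class SyntheticCase:
    """One synthetic patient: geometry, imaging and load configuration."""

    id: str
    vessel: VesselSpec
    imaging: ImagingSpec
    systolic_bp: float = 130.0  # mmHg
    diastolic_bp: float = 80.0
    opening_angle: float = 120.0  # degrees, tip-angle convention

    def __post_init__(self) -> None:
        if not (0.0 < self.diastolic_bp < self.systolic_bp):
            raise ValueError("need 0 < diastolic < systolic blood pressure")
        if not (0.0 <= self.opening_angle < 180.0):
            raise ValueError("opening angle must lie in [0, 180) degrees")


# --------------------------------------------------------------------- geometry
def _band_polygon(comp: ComponentSpec, angles, lumen, iem, n_arc: int = 60):
    """Polygon of a component occupying a fraction band of the intima layer."""
    t1, t2 = comp.angular_extent
    th = np.linspace(t1, t2, n_arc)
    lum = np.interp(np.mod(th, 2 * np.pi), angles, lumen, period=2 * np.pi)
    iem_r = np.interp(np.mod(th, 2 * np.pi), angles, iem, period=2 * np.pi)
    base = lum + comp.cap_thickness
    width = np.maximum(iem_r - base, 0.0)
    f1, f2 = comp.radial_band
    r_in = base + f1 * width
    r_out = base + f2 * width
    outer = np.column_stack([r_out * np.cos(th), r_out * np.sin(th)])
    inner = np.column_stack([r_in * np.cos(th), r_in * np.sin(th)])[::-1]
    return np.vstack([outer, inner])


def generate_vessel_geometry(spec: VesselSpec, n_angles: int = 720) -> LayeredContourSet:
    """Deterministic layered contours from a vessel spec.

    The contours are star-shaped radial functions about the lumen centroid
    (the origin of the synthetic frame).  Raises if the Fourier perturbation
    makes any pair of interfaces cross.
    """
    ang = np.linspace(0.0, 2 * np.pi, n_angles, endpoint=False)
    radii = {}
    for name, base, terms in zip(INTERFACES, spec.base_radii,
                                 spec.fourier_perturbation):
        r = np.full(n_angles, float(base))
        for (k, a, phase) in terms:
            r = r + a * np.cos(k * ang + phase)
        radii[name] = r
    for inner, outer in zip(INTERFACES[:-1], INTERFACES[1:]):
        if np.any(radii[inner] >= radii[outer]):
            raise ValueError(
                f"perturbed interfaces cross: {inner} >= {outer}; "
                "reduce the perturbation amplitudes")
    comps = []
    for c in spec.components:
        poly = _band_polygon(c, ang, radii["lumen"], radii["iem"])
        comps.append(Component(c.kind, poly))
    return LayeredContourSet(ang, radii, comps, np.zeros(2))


# --------------------------------------------------------------------- phantom
@dataclass
class PolarImage:
    """A polar-layout image: rows are A-lines over theta, columns are depth."""

    pixels: np.ndarray  # (n_alines, n_depth) float
    pixel_size: float  # mm/pixel
    angle_of_row: np.ndarray  # rad per row

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels, dtype=float)
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        n = self.pixels.shape[0]
        d = np.diff(self.angle_of_row)
        if not (np.all(d > 0) and np.allclose(d, 2 * np.pi / n, rtol=1e-6)):
            raise ValueError("rows must cover [0, 2*pi) uniformly")

    @property
    def depth_mm(self) -> np.ndarray:
        """Radial position of pixel centres, mm."""
        return (np.arange(self.pixels.shape[1]) + 0.5) * self.pixel_size


def render_oct_phantom(contours: LayeredContourSet, imaging: ImagingSpec):
    """Render the phantom and return (PolarImage, ground-truth contours).

    Mean-intensity transitions occur at the ground-truth interface radii;
    pixels inside the shadow sector are replaced by background-level signal;
    speckle is multiplicative with unit mean (Gamma family, variance
    ``speckle_scale**2``).  The truth contours are returned unchanged.
    """
    rmax = float(contours.radii["adv"].max())
    depth_extent = imaging.n_depth * imaging.pixel_size
    if rmax >= depth_extent:
        raise ValueError(
            f"vessel exceeds imaging depth: max radius {rmax:.3f} mm >= "
            f"{depth_extent:.3f} mm")
    ang = np.linspace(0.0, 2 * np.pi, imaging.n_alines, endpoint=False)
    depth = (np.arange(imaging.n_depth) + 0.5) * imaging.pixel_size
    inten = imaging.layer_intensities

    iface = {k: contours.radius(k, ang)[:, None] for k in INTERFACES}
    r = depth[None, :]
    img = np.full((imaging.n_alines, imaging.n_depth), inten["periadventitia"])
    img[np.broadcast_to(r < iface["adv"], img.shape)] = inten["adventitia"]
    img[np.broadcast_to(r < iface["eem"], img.shape)] = inten["media"]
    img[np.broadcast_to(r < iface["iem"], img.shape)] = inten["intima"]
    img[np.broadcast_to(r < iface["lumen"], img.shape)] = inten["lumen"]

    if contours.components:
        from matplotlib.path import Path as MplPath
        xs = (r * np.cos(ang)[:, None] + contours.centroid[0]).ravel()
        ys = (r * np.sin(ang)[:, None] + contours.centroid[1]).ravel()
        pts = np.column_stack([xs, ys])
        for comp in contours.components:
            inside = MplPath(comp.polygon_xy_mm).contains_points(pts)
            img.ravel()[inside] = inten[comp.kind]

    if imaging.shadow_sector is not None:
        ta, tb = imaging.shadow_sector
        in_shadow = (np.mod(ang - ta, 2 * np.pi)
                     <= np.mod(tb - ta, 2 * np.pi))
        img[in_shadow, :] = inten["lumen"]  # background-level signal

    if imaging.speckle_scale > 0:
        rng = np.random.default_rng(imaging.seed)
        s2 = imaging.speckle_scale**2
        noise = rng.gamma(shape=1.0 / s2, scale=s2, size=img.shape)
        img = img * noise

    return PolarImage(img, imaging.pixel_size, ang), contours


# --------------------------------------------------------------------- disk I/O
def write_phantom(directory, case_id: str, image: PolarImage,
                  truth: LayeredContourSet, imaging: ImagingSpec) -> dict:
    """Write a 16-bit PNG + JSON sidecar + ground-truth contour JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    png = directory / f"{case_id}.png"
    sidecar = directory / f"{case_id}.json"
    truth_path = directory / f"{case_id}_truth.json"
    scaled = np.clip(image.pixels / max(image.pixels.max(), 1e-9), 0, 1)
    iio.imwrite(png, (scaled * 65535).astype(np.uint16))
    truth.write_json(truth_path)
    meta = {
        "image": png.name,
        "truth_contours": truth_path.name,
        "intensity_scale": float(max(image.pixels.max(), 1e-9)),
        "imaging": {**asdict(imaging),
                    "shadow_sector": list(imaging.shadow_sector)
                    if imaging.shadow_sector else None},
    }
    with open(sidecar, "w") as fh:
        json.dump(meta, fh, indent=1)
    return meta


def read_phantom(sidecar_path):
    """Read a phantom written by :func:`write_phantom`.

    Returns (PolarImage, truth contours or None, ImagingSpec).
    """
    sidecar_path = Path(sidecar_path)
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    d = dict(meta["imaging"])
    if d.get("shadow_sector"):
        d["shadow_sector"] = tuple(d["shadow_sector"])
    spec = ImagingSpec(**d)
    arr = iio.imread(sidecar_path.parent / meta["image"]).astype(float)
    arr = arr / 65535.0 * meta["intensity_scale"]
    ang = np.linspace(0.0, 2 * np.pi, spec.n_alines, endpoint=False)
    image = PolarImage(arr, spec.pixel_size, ang)
    truth = None
    tp = sidecar_path.parent / meta["truth_contours"]
    if tp.exists():
        truth = LayeredContourSet.read_json(tp)
    return image, truth, spec


# --------------------------------------------------------------------- cohort
def make_cohort(n: int, seed: int) -> list:
    """Sample ``n`` synthetic cases with varied geometry, plaque and pressures.

    Pressures are drawn within the clinically observed ranges of the study
    population (systolic 115-175, diastolic 64-92 mmHg); the opening angle is
    the literature average 120 degrees for human coronaries.  Deterministic
    given ``seed``; case seeds are distinct.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n):
        lumen = rng.uniform(1.3, 1.7)
        t_int = rng.uniform(0.22, 0.30)
        t_med = rng.uniform(0.18, 0.26)
        t_adv = rng.uniform(0.30, 0.40)
        radii = (lumen, lumen + t_int, lumen + t_int + t_med,
                 lumen + t_int + t_med + t_adv)
        min_gap = min(t_int, t_med, t_adv)
        pert = []
        for _ in INTERFACES:
            terms = []
            for k in rng.choice([2, 3, 4], size=rng.integers(1, 3), replace=False):
                amp = rng.uniform(0.01, 0.12) * min_gap  # well inside the bound
                terms.append((int(k), float(amp), float(rng.uniform(0, 2 * np.pi))))
            pert.append(tuple(terms))
        comps = []
        u = rng.uniform()
        if u < 0.4:  # lipid pool
            t1 = rng.uniform(0, 2 * np.pi)
            comps.append(ComponentSpec(
                "lipid", (t1, t1 + rng.uniform(np.pi / 4, np.pi / 2)),
                (0.25, 0.75), cap_thickness=0.08))
        elif u < 0.6:  # calcification
            t1 = rng.uniform(0, 2 * np.pi)
            comps.append(ComponentSpec(
                "calcification", (t1, t1 + rng.uniform(np.pi / 8, np.pi / 4)),
                (0.35, 0.80), cap_thickness=0.08))
        shadow = None
        if rng.uniform() < 0.5:
            ta = rng.uniform(0, 2 * np.pi)
            shadow = (ta, ta + np.deg2rad(rng.uniform(30, 60)))
        vessel = VesselSpec(radii, tuple(pert), tuple(comps),
                            seed=int(rng.integers(0, 2**31 - 1)))
        imaging = ImagingSpec(shadow_sector=shadow,
                              speckle_scale=float(rng.uniform(0.3, 0.5)),
                              seed=int(rng.integers(0, 2**31 - 1)))
        cases.append(SyntheticCase(
            id=f"C{i + 1:02d}",
            vessel=vessel,
            imaging=imaging,
            systolic_bp=float(rng.uniform(115, 175)),
            diastolic_bp=float(rng.uniform(64, 92)),
            opening_angle=120.0,
        ))
    return cases
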