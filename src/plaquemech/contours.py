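"""Layered vessel contour container and the shared contour file schema.

A slice of coronary artery wall is described by four closed interfaces —
lumen, internal elastic membrane (IEM), external elastic membrane (EEM) and
the adventitia-periadventitia interface (ADV) — stored as star-shaped radial
functions r(theta) about the lumen centroid, plus optional plaque-component
polygons (lipid pool, calcification).  All lengths are millimetres, angles
are radians measured counter-clockwise from +x, and contours are periodic.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

INTERFACES = ("lumen", "iem", "eem", "adv")
LAYERS = ("intima", "media", "adventitia")
#: layer name -> (inner interface, outer interface)
LAYER_BANDS = {
    "intima": ("lumen", "iem"),
    "media": ("iem", "eem"),
    "adventitia": ("eem", "adv"),
}

CONVENTION = "polar about lumen centroid, theta counter-clockwise from +x, periodic"


@dataclass
class Component:
    """A plaque component region (lipid pool or calcification)."""

    kind: str  # "lipid" | "calcification"
    polygon_xy_mm: np.ndarray  # (N, 2) closed implicitly (last != first)

    def __post_init__(self) -> None:
        if self.kind not in ("lipid", "calcification"):
            raise ValueError(f"unknown component kind {self.kind!r}")
        self.polygon_xy_mm = np.asarray(self.polygon_xy_mm, dtype=float)
        if self.polygon_xy_mm.ndim != 2 or self.polygon_xy_mm.shape[1] != 2:
            raise ValueError("component polygon must be (N, 2)")


@dataclass
class LayeredContourSet:
    """Four ordered periodic interfaces plus plaque components for one slice.

    ``angles`` must be uniformly spaced over [0, 2*pi) (end point excluded);
    ``radii`` maps each interface name to its radial samples.  Strict radial
    ordering lumen < IEM < EEM < ADV is enforced at every angle.
    """

    angles: np.ndarray
    radii: dict
    components: list = field(default_factory=list)
    centroid: np.ndarray = field(default_factory=lambda: np.zeros(2))

    def __post_init__(self) -> None:
        self.angles = np.asarray(self.angles, dtype=float)
        self.centroid = np.asarray(self.centroid, dtype=float)
        n = self.angles.size
        if n < 8:
            raise ValueError("need at least 8 angular samples")
        d = np.diff(self.angles)
        if not (np.all(d > 0) and np.allclose(d, d[0], rtol=1e-8, atol=1e-10)
                and abs(self.angles[0]) < 1e-12
                and abs((self.angles[-1] + d[0]) - 2 * np.pi) < 1e-8):
            raise ValueError("angles must uniformly cover [0, 2*pi), end excluded")
        self.radii = {k: np.asarray(v, dtype=float) for k, v in self.radii.items()}
        for name in INTERFACES:
            if name not in self.radii:
                raise ValueError(f"missing interface {name!r}")
            if self.radii[name].shape != (n,):
                raise ValueError(f"interface {name!r} has wrong length")
        self.check_ordering()

    # ------------------------------------------------------------------ geometry
    def check_ordering(self) -> None:
        """Raise if the interfaces cross anywhere."""
        for inner, outer in zip(INTERFACES[:-1], INTERFACES[1:]):
            bad = self.radii[inner] >= self.radii[outer]
            if np.any(bad):
                k = int(np.argmax(bad))
                raise ValueError(
                    f"interface ordering violated: {inner} >= {outer} at "
                    f"theta={self.angles[k]:.4f} rad "
                    f"({self.radii[inner][k]:.4f} >= {self.radii[outer][k]:.4f} mm)"
                )

    @property
    def n_angles(self) -> int:
        return self.angles.size

    def radius(self, name: str, theta) -> np.ndarray:
        """Periodic linear interpolation of an interface radius."""
        theta = np.mod(np.asarray(theta, dtype=float), 2 * np.pi)
        ang = np.concatenate([self.angles, [2 * np.pi]])
        rad = np.concatenate([self.radii[name], self.radii[name][:1]])
        return np.interp(theta, ang, rad)

    def xy(self, name: str) -> np.ndarray:
        """Cartesian vertices of one interface, (n, 2)."""
        r = self.radii[name]
        return self.centroid + np.column_stack(
            [r * np.cos(self.angles), r * np.sin(self.angles)]
        )

    def wall_area(self) -> float:
        """Area between lumen and ADV, exact for the star-shaped description."""
        dth = 2 * np.pi / self.n_angles
        return float(0.5 * np.sum(self.radii["adv"] ** 2 - self.radii["lumen"] ** 2) * dth)

    def layer_area(self, layer: str) -> float:
        inner, outer = LAYER_BANDS[layer]
        dth = 2 * np.pi / self.n_angles
        return float(0.5 * np.sum(self.radii[outer] ** 2 - self.radii[inner] ** 2) * dth)

    def midwall_radius(self) -> np.ndarray:
        """Per-angle midwall radius, midway between lumen and ADV."""
        return 0.5 * (self.radii["lumen"] + self.radii["adv"])

    def midwall_mean_radius(self) -> float:
        """Angular mean of the midwall radius (mean-radius circumference / 2*pi)."""
        return float(np.mean(self.midwall_radius()))

    def lumen_circumference(self) -> float:
        """Polyline length of the closed lumen contour."""
        xy = self.xy("lumen")
        return float(np.sum(np.linalg.norm(np.diff(
            np.vstack([xy, xy[:1]]), axis=0), axis=1)))

    def resample(self, n: int) -> "LayeredContourSet":
        ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
        radii = {k: self.radius(k, ang) for k in INTERFACES}
        return LayeredContourSet(ang, radii, list(self.components), self.centroid.copy())

    def scaled(self, factor: float) -> "LayeredContourSet":
        """Scale all radii (and component polygons) about the centroid."""
        radii = {k: v * factor for k, v in self.radii.items()}
        comps = [
            Component(c.kind, self.centroid + factor * (c.polygon_xy_mm - self.centroid))
            for c in self.components
        ]
        return LayeredContourSet(self.angles.copy(), radii, comps, self.centroid.copy())

    # ------------------------------------------------------------------ schema I/O
    def to_dict(self) -> dict:
        return {
            "angles_rad": self.angles.tolist(),
            "lumen": self.radii["lumen"].tolist(),
            "iem": self.radii["iem"].tolist(),
            "eem": self.radii["eem"].tolist(),
            "adv": self.radii["adv"].tolist(),
            "components": [
                {"kind": c.kind, "polygon_xy_mm": c.polygon_xy_mm.tolist()}
                for c in self.components
            ],
            "centroid_mm": self.centroid.tolist(),
            "units": "mm",
            "convention": CONVENTION,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LayeredContourSet":
        if d.get("units", "mm") != "mm":
            raise ValueError(f"unsupported units {d.get('units')!r}")
        comps = [
            Component(c["kind"], np.asarray(c["polygon_xy_mm"]))
            for c in d.get("components", [])
        ]
        radii = {k: np.asarray(d[k], dtype=float) for k in INTERFACES}
        return cls(
            np.asarray(d["angles_rad"], dtype=float),
            radii,
            comps,
            np.asarray(d.get("centroid_mm", (0.0, 0.0)), dtype=float),
        )

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def read_json(cls, path) -> "LayeredContourSet":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    def to_frame(self) -> pd.DataFrame:
        """CSV mirror of the schema: one row per angle."""
        return pd.DataFrame(
            {"angle_rad": self.angles, **{k: self.radii[k] for k in INTERFACES}}
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def read_csv(cls, path, centroid=(0.0, 0.0)) -> "LayeredContourSet":
        df = pd.read_csv(path)
        radii = {k: df[k].to_numpy() for k in INTERFACES}
        return cls(df["angle_rad"].to_numpy(), radii, [], np.asarray(centroid))


def circular_contours(
    radii=(1.5, 1.75, 2.0, 2.4), n: int = 360, centroid=(0.0, 0.0)
) -> LayeredContourSet:
    """Concentric circular interfaces — the idealised vessel used by oracles."""
    ang = np.linspace(0.0, 2 * np.pi, n, endpoint=False)
    rad = {name: np.full(n, float(r)) for name, r in zip(INTERFACES, radii)}
    return LayeredContourSet(ang, rad, [], np.asarray(centroid, dtype=float))
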