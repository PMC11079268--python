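import numpy as np
import pytest

from plaquemech.contours import circular_contours, INTERFACES
from plaquemech.geometry import (REGION_ID, build_layered_mesh,
                                 open_to_zero_stress, refine_until_converged,
                                 sector_angle_from_opening, shrink_contours,
                                 write_vtk)
from plaquemech.synthetic import (ComponentSpec, VesselSpec,
                                  generate_vessel_geometry)


def shoelace(xy):
    x, y = xy[:, 0], xy[:, 1]
    return 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)


def random_contours(rng, n=720):
    base = np.sort(rng.uniform(1.0, 2.8, 4))
    while np.any(np.diff(base) < 0.1):
        base = np.sort(rng.uniform(1.0, 2.8, 4))
    gap = 0.35 * np.min(np.diff(base))
    pert = tuple(
        tuple((int(k), float(rng.uniform(0, gap / 2)), float(rng.uniform(0, 2 * np.pi)))
              for k in rng.choice([2, 3, 4, 5], 2, replace=False))
        for _ in range(4))
    return generate_vessel_geometry(VesselSpec(tuple(base), pert), n_angles=n)


# ------------------------------------------------------------------ shrink
def test_shrink_identity_and_direct_scaling(ring):
    same, lam = shrink_contours(ring, 0.0, s_axial=0.0)
    np.testing.assert_allclose(same.radii["adv"], ring.radii["adv"])
    assert lam == 1.0
    shrunk, lam = shrink_contours(ring, 0.05)  # 5% circumferential pre-shrink
    np.testing.assert_allclose(shrunk.radii["eem"], 0.95 * 2.0)
    assert lam == pytest.approx(1.0 / 0.95)


def test_shrink_scales_wall_area_quadratically():
    rng = np.random.default_rng(2)
    cs = random_contours(rng)
    s = 0.12
    shrunk, _ = shrink_contours(cs, s)
    assert shrunk.wall_area() == pytest.approx((1 - s) ** 2 * cs.wall_area(),
                                               rel=1e-12)


# ------------------------------------------------------------------ opening
def test_opening_angle_zero_is_identity(ring):
    geo = open_to_zero_stress(ring, 0.0)
    assert geo.sector_angle == pytest.approx(2 * np.pi)
    for k in INTERFACES:
        np.testing.assert_allclose(geo.radii[k], ring.radii[k], rtol=1e-12)


def test_fung_convention_circular_example():
    # midwall radius 1.5 mm, OA = 120 deg: Theta_s = 2*pi/3, R_m = 4.5 mm
    cs = circular_contours(radii=(1.2, 1.4, 1.6, 1.8))  # midwall (1.2+1.8)/2 = 1.5
    geo = open_to_zero_stress(cs, 120.0)
    assert geo.sector_angle == pytest.approx(2 * np.pi / 3)
    assert geo.midwall_radius_opened == pytest.approx(
        2 * np.pi * 1.5 / geo.sector_angle)
    assert geo.midwall_radius_opened == pytest.approx(4.5)


def test_unsupported_opening_angle_rejected(ring):
    with pytest.raises(ValueError, match="180"):
        open_to_zero_stress(ring, 180.0)


def test_opening_conserves_area_and_midwall_on_random_contours():
    """Both conservation assumptions hold to 1e-8 relative; the area check
    uses an independent dense-polygon shoelace oracle."""
    rng = np.random.default_rng(7)
    for _ in range(50):
        cs = random_contours(rng, n=360)
        geo = open_to_zero_stress(cs, float(rng.uniform(10, 170)))
        # midwall-line conservation (mean-radius circumference)
        assert geo.midwall_arc_length() == pytest.approx(
            2 * np.pi * cs.midwall_mean_radius(), rel=1e-12)
        # quadrature-consistent wall area
        assert geo.wall_area() == pytest.approx(cs.wall_area(), rel=1e-10)
        # shoelace oracle on a densely mapped boundary (the sector polygon
        # closes through the two straight radial cut faces)
        th_p = np.linspace(0, 2 * np.pi, 50000, endpoint=False)
        closed_area = 0.0
        for k, sgn in (("adv", 1.0), ("lumen", -1.0)):
            r = cs.radius(k, th_p)
            closed_area += sgn * shoelace(
                np.column_stack([r * np.cos(th_p), r * np.sin(th_p)]))
        th = np.linspace(0, 2 * np.pi, 50001)  # sector boundary needs both ends
        adv = geo.map_radius(cs.radius("adv", th))
        lum = geo.map_radius(cs.radius("lumen", th))
        TH = th / geo.k
        boundary = np.vstack([
            np.column_stack([adv * np.cos(TH), adv * np.sin(TH)]),
            np.column_stack([lum * np.cos(TH), lum * np.sin(TH)])[::-1],
        ])
        assert shoelace(boundary) == pytest.approx(closed_area, rel=1e-8)


def test_opening_map_round_trips(ring):
    rng = np.random.default_rng(3)
    cs = random_contours(rng, n=360)
    geo = open_to_zero_stress(cs, 120.0)
    for k in INTERFACES:
        back = geo.unmap_radius(geo.radii[k])
        np.testing.assert_allclose(back, cs.radii[k], rtol=1e-12)


def test_components_are_mapped_with_the_same_polar_map():
    spec = VesselSpec(components=(ComponentSpec(
        "lipid", (0.5, 1.5), (0.2, 0.8), cap_thickness=0.1),))
    cs = generate_vessel_geometry(spec)
    geo = open_to_zero_stress(cs, 120.0)
    poly = cs.components[0].polygon_xy_mm
    mapped = geo.components[0].polygon_xy_mm
    r = np.hypot(poly[:, 0], poly[:, 1])
    np.testing.assert_allclose(np.hypot(mapped[:, 0], mapped[:, 1]),
                               geo.map_radius(r), rtol=1e-12)


# ------------------------------------------------------------------ meshing
def test_structured_mesh_element_count_and_jacobians(ring):
    mesh = build_layered_mesh(ring, n_radial=(2, 2, 2), n_theta=64)
    assert mesh.n_elems == 6 * 64 == 384
    assert np.all(mesh.jacobians() > 0)
    assert mesh.cut_face_a is None and mesh.periodic


def test_sector_mesh_has_cut_faces_and_closed_preimages(ring):
    geo = open_to_zero_stress(ring, 120.0)
    mesh = build_layered_mesh(geo, n_radial=(2, 2, 2), n_theta=48)
    assert mesh.cut_face_a is not None and mesh.cut_face_b is not None
    assert not mesh.periodic
    assert np.all(mesh.jacobians() > 0)
    # preimages of both cut faces coincide in the closed ring
    np.testing.assert_allclose(mesh.closed_nodes[mesh.cut_face_a],
                               mesh.closed_nodes[mesh.cut_face_b], atol=1e-12)


def test_component_element_labels_follow_centroids(wavy_vessel):
    from matplotlib.path import Path as MplPath
    mesh = build_layered_mesh(wavy_vessel, n_radial=(3, 2, 2), n_theta=64)
    lipid = mesh.region == REGION_ID["lipid"]
    assert lipid.any()
    path = MplPath(wavy_vessel.components[0].polygon_xy_mm)
    cents = mesh.element_centroids()[lipid]
    assert path.contains_points(cents).all()


def test_single_layer_mode_labels_whole_wall(ring):
    mesh = build_layered_mesh(ring, n_radial=(2, 2, 2), n_theta=32,
                              single_layer=True)
    assert np.all(mesh.region == REGION_ID["wall"])
    assert mesh.thickness_mm == 0.5  # slice thickness carried as metadata


def test_mesh_is_deterministic(ring):
    a = build_layered_mesh(ring, n_radial=(2, 2, 2), n_theta=32)
    b = build_layered_mesh(ring, n_radial=(2, 2, 2), n_theta=32)
    np.testing.assert_array_equal(a.nodes, b.nodes)
    np.testing.assert_array_equal(a.elems, b.elems)


# ------------------------------------------------------------------ refinement
def test_refinement_stops_immediately_on_constant_monitor(ring):
    calls = []

    def solver(mesh):
        calls.append(mesh.n_elems)
        return 42.0

    mesh, hist = refine_until_converged(ring, solver, n_radial=(1, 1, 1),
                                        n_theta=24)
    assert len(hist) == 2
    assert hist[1]["value"] == 42.0


def test_refinement_levels_shrink_element_size_ten_percent_per_step(ring):
    sizes = []
    levels = []

    def solver(mesh):
        sizes.append(mesh.n_elems)
        return float(len(sizes))  # never converges

    with pytest.raises(RuntimeError, match="refinement"):
        refine_until_converged(ring, solver, n_radial=(2, 2, 2), n_theta=32,
                               tol=1e-12, max_levels=8)
    # element counts follow the attempted 10%-per-level size reduction,
    # (1/0.9)^2 per level, up to integer rounding; levels whose radial
    # subdivision would repeat are skipped, so solved counts grow by at
    # least one whole (1/0.9)^2 factor between entries
    growth = np.array(sizes[1:]) / np.array(sizes[:-1])
    assert np.all(growth >= (1 / 0.9) ** 2 * 0.8)
    assert np.all(growth < (1 / 0.9) ** 8)
    assert len(sizes) >= 2


# ------------------------------------------------------------------ VTK
def test_vtk_export_writes_legacy_unstructured_grid(tmp_path, ring):
    mesh = build_layered_mesh(ring, n_radial=(1, 1, 1), n_theta=16)
    path = tmp_path / "mesh.vtk"
    write_vtk(path, mesh, point_data={"displacement": np.zeros((mesh.n_nodes, 2))},
              cell_data={"value": np.arange(mesh.n_elems, dtype=float)})
    lines = path.read_text().splitlines()
    assert "DATASET UNSTRUCTURED_GRID" in lines
    assert f"POINTS {mesh.n_nodes} double" in lines
    assert "SCALARS region int 1" in lines
    i = lines.index(f"CELL_TYPES {mesh.n_elems}")
    assert lines[i + 1:i + 1 + mesh.n_elems] == ["9"] * mesh.n_elems  # quads
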