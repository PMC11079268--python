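import numpy as np
import pytest

from plaquemech.contours import INTERFACES, circular_contours
from plaquemech.segmentation import (DetectionParams, PartialContours,
                                     detect_layer_boundaries, enforce_ordering,
                                     evaluate_segmentation, repair_contours)
from plaquemech.synthetic import (ImagingSpec, VesselSpec,
                                  generate_vessel_geometry, render_oct_phantom)


# ------------------------------------------------------------------ detection
def test_noiseless_detection_within_one_pixel(clean_phantom):
    image, truth = clean_phantom
    pc = detect_layer_boundaries(image)
    for k in INTERFACES:
        vis = pc.visibility[k]
        assert vis.mean() > 0.95
        err = np.abs(pc.radii[k][vis] - truth.radius(k, pc.angles[vis]))
        assert err.mean() / image.pixel_size <= 1.0


def test_fully_shadowed_image_yields_empty_result():
    cs = generate_vessel_geometry(VesselSpec())
    img, _ = render_oct_phantom(cs, ImagingSpec(
        shadow_sector=(0.0, 2 * np.pi - 1e-9), speckle_scale=0.3, seed=1))
    pc = detect_layer_boundaries(img)
    for k in INTERFACES:
        assert not pc.visibility[k].any()


def test_partial_shadow_masks_inside_detects_outside(wavy_wall):
    img, _ = render_oct_phantom(wavy_wall, ImagingSpec(
        shadow_sector=(0.0, np.pi / 3), speckle_scale=0.4, seed=2))
    pc = detect_layer_boundaries(img)
    inside = (pc.angles >= 0) & (pc.angles <= np.pi / 3)
    for k in INTERFACES:
        assert pc.visibility[k][~inside].mean() >= 0.95
        assert pc.visibility[k][inside].mean() <= 0.25  # predominantly masked


def test_detection_output_never_crosses(clean_phantom):
    image, _ = clean_phantom
    pc = detect_layer_boundaries(image)
    all_vis = np.logical_and.reduce([pc.visibility[k] for k in INTERFACES])
    for a, b in zip(INTERFACES[:-1], INTERFACES[1:]):
        assert np.all(pc.radii[a][all_vis] < pc.radii[b][all_vis])


def test_detection_error_grows_with_speckle(wavy_wall):
    """Graceful degradation: seed-averaged error monotone in noise level."""
    mean_errs = []
    for scale in (0.0, 0.35, 0.7):
        errs = []
        for seed in (0, 1, 2):
            img, truth = render_oct_phantom(
                wavy_wall, ImagingSpec(speckle_scale=scale, seed=seed))
            pc = detect_layer_boundaries(img)
            e = []
            for k in INTERFACES:
                vis = pc.visibility[k]
                if vis.any():
                    e.append(np.abs(pc.radii[k][vis]
                                    - truth.radius(k, pc.angles[vis])).mean())
            errs.append(np.mean(e))
        mean_errs.append(np.mean(errs))
    assert mean_errs[0] < mean_errs[1] < mean_errs[2]


# ------------------------------------------------------------------ repair
def _partial_from_truth(truth, n=360, missing=None):
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    vis = np.ones(n, dtype=bool)
    if missing is not None:
        a, b = missing
        vis &= ~((ang >= a) & (ang < b))
    radii, visibility = {}, {}
    for k in INTERFACES:
        r = truth.radius(k, ang)
        rr = r.copy()
        rr[~vis] = np.nan
        radii[k] = rr
        visibility[k] = vis.copy()
    return PartialContours(ang, radii, visibility)


def test_repair_identity_on_fully_visible_input(wavy_vessel):
    pc = _partial_from_truth(wavy_vessel)
    out = repair_contours(pc)[0]
    for k in INTERFACES:
        np.testing.assert_allclose(out.radii[k], pc.radii[k], atol=1e-12)


def test_three_slice_stack_fills_missing_sector_from_neighbours():
    ring = circular_contours()
    full = _partial_from_truth(ring)
    gap = _partial_from_truth(ring, missing=(0.5, 0.5 + np.pi / 3))
    out = repair_contours([full, gap, full], z_positions=[0.0, 0.5, 1.0])
    mid = out[1]
    for k, r_true in zip(INTERFACES, (1.5, 1.75, 2.0, 2.4)):
        assert np.abs(mid.radii[k] - r_true).max() / r_true < 0.01


def test_single_slice_sinusoid_bridged_within_two_percent():
    n = 360
    ang = np.linspace(0, 2 * np.pi, n, endpoint=False)
    r = 2.0 + 0.1 * np.cos(2 * ang)
    vis = ~((ang >= 1.0) & (ang < 1.0 + np.pi / 4))
    radii = {"lumen": np.where(vis, 0.7 * r, np.nan),
             "iem": np.where(vis, 0.8 * r, np.nan),
             "eem": np.where(vis, 0.9 * r, np.nan),
             "adv": np.where(vis, r, np.nan)}
    pc = PartialContours(ang, radii, {k: vis.copy() for k in INTERFACES})
    out = repair_contours(pc)[0]
    assert np.max(np.abs(out.radii["adv"] - r) / r) < 0.02


def test_repair_rejects_poor_coverage():
    ring = circular_contours()
    pc = _partial_from_truth(ring, missing=(0.0, 1.2 * np.pi))
    with pytest.raises(ValueError, match="lumen.*only|visible on only"):
        repair_contours(pc)


def test_ordering_enforcement_resolves_crossings_mean_preserving():
    n = 16
    radii = {"lumen": np.full(n, 1.5), "iem": np.full(n, 1.75),
             "eem": np.full(n, 2.0), "adv": np.full(n, 2.4)}
    radii["iem"][3] = 2.1  # crosses EEM
    fixed = enforce_ordering(radii, min_gap=0.01)
    assert fixed["iem"][3] < fixed["eem"][3] - 0.0099
    # pairwise averaging preserves the pair sum
    assert fixed["iem"][3] + fixed["eem"][3] == pytest.approx(2.1 + 2.0)


# ------------------------------------------------------------------ metrics
def test_metrics_identity(wavy_vessel):
    m = evaluate_segmentation(wavy_vessel, wavy_vessel, pixel_size=0.011)
    assert all(v == 0.0 for v in m.mae_mm.values())
    assert all(v == pytest.approx(1.0) for v in m.dice.values())


def test_metrics_single_interface_offset():
    ring = circular_contours()
    shifted = circular_contours()
    px = 0.011
    shifted.radii["adv"] = shifted.radii["adv"] + px
    for k in ("lumen", "iem", "eem"):
        assert evaluate_segmentation(shifted, ring, pixel_size=px).mae_px[k] == \
            pytest.approx(0.0, abs=1e-9)
    assert evaluate_segmentation(shifted, ring, pixel_size=px).mae_px["adv"] == \
        pytest.approx(1.0, rel=1e-6)


def test_dice_matches_independent_rasterized_iou_oracle(wavy_vessel):
    """Dice equals 2*IoU/(1+IoU) from an independently coded pixel count."""
    rng = np.random.default_rng(0)
    pred = wavy_vessel.resample(360)
    for k in INTERFACES:
        pred.radii[k] = pred.radii[k] * (1 + 0.01 * rng.standard_normal())
    m = evaluate_segmentation(pred, wavy_vessel.resample(360), raster_n=256)

    # oracle: same grid definition, masks built and combined independently
    rmax = 1.05 * max(pred.radii["adv"].max(),
                      wavy_vessel.radii["adv"].max())
    ax = np.linspace(-rmax, rmax, 256)
    X, Y = np.meshgrid(ax, ax)
    r = np.hypot(X, Y).ravel()
    t = np.mod(np.arctan2(Y, X), 2 * np.pi).ravel()
    bands = {"intima": ("lumen", "iem"), "media": ("iem", "eem"),
             "adventitia": ("eem", "adv")}
    truth360 = wavy_vessel.resample(360)
    for layer, (a, b) in bands.items():
        A = (r >= pred.radius(a, t)) & (r < pred.radius(b, t))
        B = (r >= truth360.radius(a, t)) & (r < truth360.radius(b, t))
        iou = np.count_nonzero(A & B) / np.count_nonzero(A | B)
        dice_from_iou = 2 * iou / (1 + iou)
        assert m.dice[layer] == pytest.approx(dice_from_iou, abs=1e-6)


def test_metrics_reject_mismatched_centroids(wavy_vessel):
    other = wavy_vessel.resample(360)
    other.centroid = other.centroid + 0.3
    with pytest.raises(ValueError, match="centroid|convention"):
        evaluate_segmentation(other, wavy_vessel)
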