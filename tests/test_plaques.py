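"""Plaque detection, edge distances, burden/halo metrics, region volume."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

from arraytomo.plaques import (classify_near_far, detect_plaques,
                               estimate_region_volume, halo_burden,
                               mask_burden, sample_rois)
from arraytomo.synthetic import SynthParams, generate_stack


@pytest.fixture(scope="module")
def plaque_field():
    p = SynthParams(seed=5, field_size_px=(500, 500), n_sections=6,
                    punctum_density={"PSD95": 0.3},
                    plaque_spec=[((12.0, 12.0), 5.0, 8.0)])
    return generate_stack(p)


def test_plaque_free_field_all_far(default_field):
    stack, _ = default_field
    pm = detect_plaques(stack)
    assert pm.n_plaques == 0
    assert np.isinf(pm.edge_distance_um).all()
    assert classify_near_far(pm.edge_distance_um[0, 0, 0]) == "far"


def test_single_disc_core_count_and_area(plaque_field):
    stack, _ = plaque_field
    pm = detect_plaques(stack)
    assert pm.n_plaques == 1
    assert pm.mean_plaque_area_um2 == pytest.approx(np.pi * 25.0, rel=0.10)


def test_distance_field_matches_point_to_circle(plaque_field):
    stack, _ = plaque_field
    pm = detect_plaques(stack)
    # probes at known radial distances from the disc centre (12, 12) µm
    for radial in (8.0, 15.0, 25.0, 33.0):
        got = pm.distance_at(12.0 + radial, 12.0, 0.2)
        want = radial - 5.0  # analytic distance to the circle edge
        assert abs(got - want) <= stack.pixel_size_xy + 0.05, radial


def test_inside_plaque_distance_zero(plaque_field):
    stack, _ = plaque_field
    pm = detect_plaques(stack)
    assert pm.distance_at(12.0, 12.0, 0.2) == 0.0


@pytest.mark.parametrize("d,expected", [
    (10.0, "near"),
    (19.9, "near"),
    (20.0, "far"),       # boundary goes to far (strict < 20 is near)
    (np.inf, "far"),
])
def test_near_far_rule(d, expected):
    assert classify_near_far(d) == expected


def test_negative_distance_rejected():
    with pytest.raises(ValueError):
        classify_near_far(-1.0)


def test_min_area_filter_removes_small_components():
    from arraytomo.stacks import ChannelStack
    rng = np.random.default_rng(0)
    img = rng.normal(100, 5, (2, 200, 200))
    rr = np.arange(200)[:, None] - 100
    cc = np.arange(200)[None, :] - 100
    img[:, rr**2 + cc**2 <= 40**2] += 2000           # big disc (>20 µm²)
    img[:, 20:23, 20:23] += 2000                      # 9 px = 0.09 µm² debris
    stack = ChannelStack(channels={"thios": img}, pixel_size_xy=0.1,
                         section_thickness=0.07)
    pm = detect_plaques(stack, min_plaque_area_um2=20.0)
    assert pm.n_plaques == 1
    assert not pm.core_mask[:, 20:23, 20:23].any()


def test_halo_equals_pan_minus_core_set_arithmetic():
    pan = np.zeros((1, 20, 20), dtype=bool)
    core = np.zeros_like(pan)
    pan[0, :10, :10] = True           # 100 px
    core[0, :5, :8] = True            # 40 px subset
    res = halo_burden(pan, core, pixel_size_xy=0.1)
    assert res.total_area_um2 == pytest.approx(60 * 0.01)
    # core == pan -> empty halo
    res2 = halo_burden(pan, pan, pixel_size_xy=0.1)
    assert res2.percent_area == 0.0
    assert res2.mean_plaque_area_um2 is None


def test_halo_union_core_recovers_pan_when_nested():
    pan = np.zeros((1, 30, 30), dtype=bool)
    core = np.zeros_like(pan)
    pan[0, 5:25, 5:25] = True
    core[0, 10:20, 10:20] = True
    halo = pan & ~core
    np.testing.assert_array_equal(halo | core, pan)


def test_synthetic_annulus_halo_area(plaque_field):
    stack, _ = plaque_field
    pm = detect_plaques(stack, pan_channel="abeta")
    res = halo_burden(pm.pan_mask, pm.core_mask,
                      pixel_size_xy=stack.pixel_size_xy)
    analytic = np.pi * (8.0**2 - 5.0**2)  # 122.5 µm²
    assert res.total_area_um2 == pytest.approx(analytic, rel=0.10)


def test_mask_burden_shape_mismatch_rejected():
    with pytest.raises(ValueError):
        halo_burden(np.zeros((1, 4, 4), bool), np.zeros((1, 5, 5), bool), 0.1)


# -- region volume ----------------------------------------------------------

def test_region_volume_constant_areas():
    # 3 sections of 2 mm², 1 mm spacing, one hemisphere measured
    assert estimate_region_volume([2, 2, 2], 1000.0, 2) == pytest.approx(12.0)


def test_region_volume_empty_is_zero():
    assert estimate_region_volume([]) == 0.0


def test_region_volume_linear_ramp_closed_form():
    n = 11
    areas = np.linspace(0, 5, n)
    want = areas.sum() * 1.0 * 2  # spacing 1 mm, factor 2
    assert estimate_region_volume(areas, 1000.0, 2) == pytest.approx(want)


def test_region_volume_negative_area_rejected():
    with pytest.raises(ValueError):
        estimate_region_volume([1.0, -0.1])


@given(areas=hst.lists(hst.floats(0.0, 100.0), max_size=20),
       spacing=hst.floats(1.0, 2000.0),
       factor=hst.floats(0.5, 4.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_region_volume_matches_independent_sum(areas, spacing, factor):
    import math
    want = math.fsum(areas) * (spacing / 1000.0) * factor
    assert estimate_region_volume(areas, spacing, factor) == \
        pytest.approx(want, rel=1e-9, abs=1e-12)


# -- ROI sampling -----------------------------------------------------------

def test_sample_rois_zero_requests_empty(plaque_field):
    stack, _ = plaque_field
    pm = detect_plaques(stack)
    assert sample_rois(stack, pm, 10.0, 0, 0) == []


def test_sample_rois_labels_verified_against_distance_field(plaque_field):
    stack, _ = plaque_field
    pm = detect_plaques(stack)
    rois = sample_rois(stack, pm, 5.0, 3, 3, seed=1)
    assert len(rois) == 6
    mid = stack.n_sections // 2
    centers = {r.center_px for r in rois}
    assert len(centers) == 6  # non-overlapping implies distinct centres
    for roi in rois:
        d = pm.edge_distance_um[mid, roi.center_px[0], roi.center_px[1]]
        assert classify_near_far(d) == roi.label


def test_sample_rois_plaque_free_near_request_warns(default_field):
    stack, _ = default_field
    pm = detect_plaques(stack)
    with pytest.warns(UserWarning, match="could only place"):
        rois = sample_rois(stack, pm, 3.0, 2, 1, seed=0, max_attempts=200)
    assert all(r.label == "far" for r in rois)
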