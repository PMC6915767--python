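"""3D linking, the single-section filter, and density estimation."""

import numpy as np
import pytest

from arraytomo.puncta import (filter_single_section, link_3d, punctum_density,
                              puncta_table)
from arraytomo.registration import apply_transforms, estimate_shifts
from arraytomo.segmentation import binarize_stack
from arraytomo.synthetic import SynthParams, generate_stack

from conftest import make_binary


def brute_force_components(mask: np.ndarray) -> set[frozenset]:
    """Independent oracle: flood fill over the explicit adjacency graph
    (8-neighbourhood in-plane, same-xy across consecutive sections)."""
    voxels = set(zip(*np.nonzero(mask)))
    seen = set()
    comps = []
    for start in voxels:
        if start in seen:
            continue
        comp = set()
        stack = [start]
        while stack:
            z, r, c = stack.pop()
            if (z, r, c) in comp:
                continue
            comp.add((z, r, c))
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    if (dr, dc) != (0, 0) and (z, r + dr, c + dc) in voxels:
                        stack.append((z, r + dr, c + dc))
            for dz in (-1, 1):
                if (z + dz, r, c) in voxels:
                    stack.append((z + dz, r, c))
        seen |= comp
        comps.append(frozenset(comp))
    return set(comps)


def test_empty_mask_yields_no_puncta():
    assert link_3d(make_binary(np.zeros((4, 8, 8)))) == []


def test_square_across_three_sections_is_one_punctum():
    mask = np.zeros((6, 10, 10), dtype=bool)
    mask[2:5, 3:6, 3:6] = True
    puncta = link_3d(make_binary(mask))
    assert len(puncta) == 1
    p = puncta[0]
    assert p.section_span == 3
    assert p.n_voxels == 27
    assert p.volume_um3 == pytest.approx(27 * 0.1 * 0.1 * 0.07)
    # centroid at voxel-centre convention
    assert p.centroid_um == pytest.approx((0.45, 0.45, (3.0 + 0.5) * 0.07))


def test_linking_matches_brute_force_flood_fill():
    rng = np.random.default_rng(0)
    for trial in range(8):
        mask = rng.random((6, 16, 16)) < 0.08
        puncta = link_3d(make_binary(mask))
        got = {frozenset(zip(*map(list, p.voxels))) for p in puncta}
        want = brute_force_components(mask)
        assert got == want, f"trial {trial}"


def test_voxel_conservation_before_filtering():
    rng = np.random.default_rng(1)
    mask = rng.random((5, 20, 20)) < 0.1
    puncta = link_3d(make_binary(mask))
    assert sum(p.n_voxels for p in puncta) == mask.sum()


def test_filter_removes_only_single_section_objects():
    mask = np.zeros((6, 40, 40), dtype=bool)
    mask[0, 2, 2] = True                 # span 1 -> removed
    mask[1:3, 10:12, 10:12] = True       # span 2 boundary case -> kept
    mask[2:6, 30:33, 30:33] = True       # span 4 -> kept
    puncta = link_3d(make_binary(mask))
    kept = filter_single_section(puncta)
    assert len(puncta) == 3
    assert sorted(p.section_span for p in kept) == [2, 4]


def test_filter_on_all_single_section_gives_empty():
    mask = np.zeros((3, 10, 10), dtype=bool)
    mask[0, 1, 1] = mask[1, 5, 5] = mask[2, 8, 8] = True
    assert filter_single_section(link_3d(make_binary(mask))) == []


def test_filter_is_idempotent():
    mask = np.zeros((4, 30, 30), dtype=bool)
    mask[0, 1, 1] = True
    mask[1:3, 10:12, 10:12] = True
    once = filter_single_section(link_3d(make_binary(mask)))
    twice = filter_single_section(once)
    assert [p.id for p in twice] == [p.id for p in once]


def test_exact_multisection_count_with_specks_mixed_in():
    # 100 well-separated multi-section puncta + 50 single-section specks:
    # the filter keeps exactly the 100 real ones
    mask = np.zeros((6, 130, 130), dtype=bool)
    k = 0
    for i in range(10):
        for j in range(10):
            r, c = 6 + 13 * i, 6 + 13 * j
            z = k % 4
            mask[z:z + 2, r:r + 2, c:c + 2] = True
            k += 1
    s = 0
    for i in range(10):
        for j in range(5):
            r, c = 12 + 13 * i, 12 + 13 * j
            mask[(s % 6), r, c] = True
            s += 1
    puncta = link_3d(make_binary(mask))
    assert len(puncta) == 150
    kept = filter_single_section(puncta)
    assert len(kept) == 100


def test_density_arithmetic_and_errors():
    mask = np.zeros((2, 4, 4), dtype=bool)
    assert punctum_density([], 10.0) == 0.0
    puncta = ["p"] * 70  # density only counts objects
    assert punctum_density(puncta, 350.0) == pytest.approx(0.2)
    with pytest.raises(ValueError):
        punctum_density([], 0.0)


def test_end_to_end_density_recovery_within_ten_percent():
    # truth density 1.0/µm³ at default SNR, averaged over 5 seeds
    ratios = []
    for seed in range(5):
        p = SynthParams(seed=700 + seed,
                        punctum_density={"synaptophysin": 1.0, "PSD95": 1.0})
        stack, truth = generate_stack(p)
        reg = apply_transforms(stack, estimate_shifts(stack))
        mask = binarize_stack(reg, "PSD95")
        puncta = filter_single_section(link_3d(mask))
        ratios.append(punctum_density(puncta, stack.volume_um3)
                      / truth.true_densities["PSD95"])
    assert abs(np.mean(ratios) - 1.0) <= 0.10


def test_gap_tolerance_links_across_skipped_section():
    mask = np.zeros((5, 10, 10), dtype=bool)
    mask[0, 4:6, 4:6] = True
    mask[2, 4:6, 4:6] = True  # one blank section between
    assert len(link_3d(make_binary(mask))) == 2
    assert len(link_3d(make_binary(mask), gap_tolerance=1)) == 1


def test_puncta_table_columns():
    mask = np.zeros((3, 10, 10), dtype=bool)
    mask[0:2, 2:4, 2:4] = True
    tab = puncta_table(link_3d(make_binary(mask)))
    assert list(tab.columns) == ["id", "channel", "centroid_x_um",
                                 "centroid_y_um", "centroid_z_um",
                                 "volume_um3", "section_span"]
    assert len(tab) == 1
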