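"""Generator contracts: determinism, truth consistency, calibrated rates."""

import numpy as np
import pytest

from arraytomo.behavior import total_distance
from arraytomo.synthetic import (SynthParams, generate_genotype_cohort,
                                 generate_stack, generate_trajectory)


def test_empty_field_has_no_objects():
    p = SynthParams(seed=0, punctum_density={"synaptophysin": 0.0, "PSD95": 0.0},
                    noise_speck_rate=0.0, shift_sd_px=0.0,
                    field_size_px=(40, 40), n_sections=4)
    stack, truth = generate_stack(p)
    assert truth.puncta == [] and truth.specks == []
    for name, tm in truth.truth_masks.items():
        if name == "dapi":  # nuclei are always present for registration
            continue
        assert not tm.any(), name


def test_same_seed_is_voxel_identical():
    p1, p2 = SynthParams(seed=42), SynthParams(seed=42)
    s1, t1 = generate_stack(p1)
    s2, t2 = generate_stack(p2)
    for ch in s1.channels:
        np.testing.assert_array_equal(s1.channels[ch], s2.channels[ch])
    assert np.array_equal(t1.true_shifts, t2.true_shifts)
    assert len(t1.puncta) == len(t2.puncta)
    assert all(a.centroid_um == b.centroid_um for a, b in zip(t1.puncta, t2.puncta))


def test_punctum_counts_follow_poisson_rate():
    # density 1.0/µm³ in a 10×10×1.4 µm volume: λ = 140 per channel;
    # over 100 seeds the mean count must sit within 3 standard errors.
    n_seeds = 100
    counts = []
    for seed in range(n_seeds):
        p = SynthParams(seed=seed, punctum_density={"PSD95": 1.0},
                        noise_speck_rate=0.0, shift_sd_px=0.0)
        _, truth = generate_stack(p)
        counts.append(len(truth.puncta))
    lam = 140.0
    se = np.sqrt(lam / n_seeds)
    assert abs(np.mean(counts) - lam) < 3 * se


def test_truth_puncta_have_signal_in_every_section_of_range(default_field):
    _, truth = default_field
    for p in truth.puncta:
        z0, z1 = p.section_range
        assert p.span >= 2
        tm = truth.truth_masks[p.channel]
        for z in range(z0, z1 + 1):
            assert tm[z].any()


def test_specks_span_exactly_one_section(default_field):
    _, truth = default_field
    assert truth.specks, "default speck rate should produce specks"
    for s in truth.specks:
        assert 0 <= s.section < truth.aligned.n_sections


def test_inverting_true_shifts_restores_aligned_stack(default_field):
    stack, truth = default_field
    assert np.allclose(truth.true_shifts, np.round(truth.true_shifts))
    assert np.array_equal(truth.true_shifts[0], [0, 0])
    for ch, arr in stack.channels.items():
        restored = np.stack([
            np.roll(arr[k], (-int(truth.true_shifts[k, 0]),
                             -int(truth.true_shifts[k, 1])), axis=(0, 1))
            for k in range(arr.shape[0])])
        np.testing.assert_array_equal(restored, truth.aligned.channels[ch])


def test_marker_labels_match_configured_fraction():
    # empirical tau-positive fraction over >= 2000 puncta within 3 binomial SE
    p_true = 0.05
    labels = []
    seed = 0
    while len(labels) < 2000:
        p = SynthParams(seed=500 + seed, field_size_px=(200, 200),
                        punctum_density={"PSD95": 1.0}, noise_speck_rate=0.0,
                        shift_sd_px=0.0,
                        marker_positive_fraction={"tau": p_true, "abeta": 0.05})
        _, truth = generate_stack(p)
        labels.extend(q.labels["tau"] for q in truth.puncta)
        seed += 1
    frac = np.mean(labels)
    se = np.sqrt(p_true * (1 - p_true) / len(labels))
    assert abs(frac - p_true) < 3 * se


def test_oversized_plaque_is_rejected_with_sizing_message():
    p = SynthParams(seed=0, field_size_px=(50, 50),
                    plaque_spec=[((2.5, 2.5), 5.0, 8.0)])
    with pytest.raises(ValueError, match="fit inside"):
        generate_stack(p)


def test_plaque_halo_only_in_pan_channel():
    p = SynthParams(seed=3, field_size_px=(300, 300), n_sections=4,
                    punctum_density={"PSD95": 0.0}, noise_speck_rate=0.0,
                    shift_sd_px=0.0,
                    plaque_spec=[((15.0, 15.0), 4.0, 7.0)])
    _, truth = generate_stack(p)
    core = truth.truth_masks["thios"][0]
    pan = truth.truth_masks["abeta"][0]
    assert core.any()
    assert (pan & ~core).any()  # halo
    assert not (core & ~pan).any()  # core is inside pan


@pytest.mark.parametrize("params,expected", [
    ((0, (0.25, 0.25, 0.25, 0.25)), [0, 0, 0, 0]),
    ((50, (1.0, 0.0, 0.0, 0.0)), [50, 0, 0, 0]),
])
def test_genotype_cohort_degenerate_cases(params, expected):
    n, props = params
    assert list(generate_genotype_cohort(n, props, seed=1)) == expected


def test_genotype_cohort_mendelian_sampling():
    counts = generate_genotype_cohort(4000, seed=9)
    assert counts.sum() == 4000
    se = np.sqrt(4000 * 0.25 * 0.75)  # ≈ 27.4
    assert np.all(np.abs(counts - 1000) < 3 * se)


def test_trajectory_center_only_stays_in_inner_zone():
    traj = generate_trajectory(30.0, "center_only", seed=4)
    assert traj.in_inner().all()


def test_trajectory_immobile_has_zero_path():
    traj = generate_trajectory(10.0, "immobile", seed=0)
    assert total_distance(traj) == 0.0


def test_trajectory_wall_following_lap_length():
    # one lap at 2 cm from the walls of a 40 cm arena: 4 × 36 = 144 cm;
    # dt chosen so samples land exactly on the corners
    traj = generate_trajectory(20.0, "wall_following", seed=0,
                               dt_s=0.5, speed_cm_s=7.2)
    assert total_distance(traj) == pytest.approx(144.0, abs=1e-9)


def test_trajectory_bounded_and_reproducible():
    t1 = generate_trajectory(20.0, "random_walk", seed=5)
    t2 = generate_trajectory(20.0, "random_walk", seed=5)
    np.testing.assert_array_equal(t1.x_cm, t2.x_cm)
    assert t1.x_cm.min() >= 0 and t1.x_cm.max() <= 40
    assert t1.y_cm.min() >= 0 and t1.y_cm.max() <= 40


def test_trajectory_rejects_bad_sampling():
    with pytest.raises(ValueError):
        generate_trajectory(10.0, "random_walk", dt_s=0.0)
    with pytest.raises(ValueError):
        generate_trajectory(-1.0, "random_walk")
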