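"""3D focus detection: tiny-array oracles, merge rule, invariances."""

import math

import numpy as np
import pytest

from hsrpipe import synth
from hsrpipe.foci import (
    CellFociStats,
    FociParams,
    Focus,
    cell_foci_stats,
    colocalize,
    detect_foci,
)


def brute_force_maxima(image, mask, background):
    """Independent oracle: enumerate every voxel and check all 26
    neighbors by hand."""
    out = []
    nz, ny, nx = image.shape
    for z in range(nz):
        for y in range(ny):
            for x in range(nx):
                if not mask[z, y, x] or image[z, y, x] <= background:
                    continue
                neigh = [
                    image[z + dz, y + dy, x + dx]
                    for dz in (-1, 0, 1) for dy in (-1, 0, 1) for dx in (-1, 0, 1)
                    if (dz, dy, dx) != (0, 0, 0)
                    and 0 <= z + dz < nz and 0 <= y + dy < ny and 0 <= x + dx < nx
                    and mask[z + dz, y + dy, x + dx]
                ]
                if all(image[z, y, x] >= v for v in neigh):
                    out.append((z, y, x))
    return out


def test_single_hot_voxel_matches_brute_force():
    image = np.full((3, 7, 7), 10.0)
    image[1, 3, 3] = 100.0
    mask = np.ones_like(image, dtype=bool)
    inside = image[mask]
    background = inside.mean() + inside.std()
    assert brute_force_maxima(image, mask, background) == [(1, 3, 3)]
    found = detect_foci(image, mask)
    assert len(found) == 1
    assert found[0].centroid_zyx == (1.0, 3.0, 3.0)
    assert found[0].peak_intensity == 100.0
    assert found[0].size == 1


def test_constant_image_yields_no_foci():
    image = np.full((3, 7, 7), 5.0)
    assert detect_foci(image, np.ones_like(image, bool)) == []


def test_empty_mask_rejected():
    image = np.zeros((3, 7, 7))
    with pytest.raises(ValueError, match="empty"):
        detect_foci(image, np.zeros_like(image, bool))


def test_shape_mismatch_rejected():
    with pytest.raises(ValueError, match="shape"):
        detect_foci(np.zeros((3, 7, 7)), np.ones((3, 7, 8), bool))


def _two_peak_image(saddle):
    """Peaks 100 and 90 connected through a ridge whose height is
    ``saddle``; background ~10."""
    image = np.full((3, 9, 9), 10.0)
    image[1, 2, 2] = 100.0
    image[1, 6, 6] = 90.0
    # ridge along the diagonal between the two peaks
    for y, x in ((3, 3), (4, 4), (5, 5)):
        image[1, y, x] = saddle
    return image


def test_merge_rule_hand_example():
    mask = np.ones((3, 9, 9), dtype=bool)
    # saddle 88: peak 90 rises only 2 above it, less than 0.2*(90 - B) -> merged
    assert len(detect_foci(_two_peak_image(88.0), mask)) == 1
    # saddle 50: peak 90 rises 40 above it -> stays distinct
    assert len(detect_foci(_two_peak_image(50.0), mask)) == 2


def test_merged_focus_keeps_higher_peak():
    mask = np.ones((3, 9, 9), dtype=bool)
    found = detect_foci(_two_peak_image(88.0), mask)
    assert found[0].peak_intensity == 100.0


def test_plateau_seed_is_lexicographic_minimum():
    image = np.full((3, 9, 9), 10.0)
    image[1, 4, 4] = image[1, 4, 5] = 100.0  # two-voxel plateau
    found = detect_foci(image, np.ones_like(image, bool))
    assert len(found) == 1
    # centroid is the intensity-weighted mean of the (symmetric) region
    assert found[0].centroid_zyx[2] == pytest.approx(4.5)


def test_min_size_filter():
    image = np.full((3, 9, 9), 10.0)
    image[1, 4, 4] = 100.0
    mask = np.ones_like(image, bool)
    assert len(detect_foci(image, mask, FociParams(min_size=1))) == 1
    assert detect_foci(image, mask, FociParams(min_size=2)) == []


def test_affine_intensity_invariance(rng):
    """detect_foci(a*I + b) finds identical voxels (sizes and seeds) for
    a > 0; centroids agree to floating-point precision."""
    for _ in range(10):
        truth = synth.sample_image_truth(rng, int(rng.integers(1, 6)))
        stack, _ = synth.gen_image_stack(truth)
        image = stack.astype(float)
        a, b = float(rng.uniform(0.5, 3.0)), float(rng.uniform(-5.0, 20.0))
        base = detect_foci(image, truth.nucleus_mask)
        scaled = detect_foci(a * image + b, truth.nucleus_mask)
        assert len(base) == len(scaled)
        for f, g in zip(base, scaled):
            assert f.size == g.size
            assert g.peak_intensity == pytest.approx(a * f.peak_intensity + b)
            assert np.allclose(f.centroid_zyx, g.centroid_zyx, atol=1e-9)


def test_planted_truth_recovery(rng):
    """Well-separated planted foci are all recovered with centroids within
    one voxel."""
    hits = 0
    n = 50
    for _ in range(n):
        k = int(rng.integers(1, 6))
        truth = synth.sample_image_truth(rng, k)
        stack, sidecar = synth.gen_image_stack(truth)
        found = detect_foci(stack, truth.nucleus_mask)
        if len(found) != k:
            continue
        planted = [tuple(f["centroid_zyx"]) for f in sidecar["foci"]]
        errors = [min(math.dist(f.centroid_zyx, p) for p in planted)
                  for f in found]
        if max(errors) <= 1.0:
            hits += 1
    assert hits >= math.ceil(0.98 * n)


def test_monotone_merging(rng):
    """Raising the merge threshold can only reduce the focus count."""
    for _ in range(5):
        truth = synth.sample_image_truth(rng, 4)
        stack, _ = synth.gen_image_stack(truth)
        counts = [
            len(detect_foci(stack, truth.nucleus_mask,
                            FociParams(merge_peak_fraction=frac)))
            for frac in (0.05, 0.2, 0.5, 0.9)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


# ---------------------------------------------------------------------------
# per-cell statistics and colocalization
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("counts, expected_pct",
                         [([0, 1, 3, 4], 50.0), ([0, 0, 0], 0.0),
                          ([3, 3], 100.0)])
def test_cell_foci_stats(counts, expected_pct):
    stats = cell_foci_stats({f"c{i}": c for i, c in enumerate(counts)})
    assert stats.pct_cells_gt_threshold == pytest.approx(expected_pct)
    assert stats.mean_foci_per_cell == pytest.approx(np.mean(counts))


def test_cell_foci_stats_requires_cells():
    with pytest.raises(ValueError):
        cell_foci_stats({})


def _focus(z, y, x):
    return Focus(centroid_zyx=(z, y, x), peak_intensity=1.0, size=1)


def test_colocalization_geometry():
    a = [_focus(1, 2, 2), _focus(1, 6, 6)]
    assert colocalize(a, list(a), radius=2.0) == 1.0
    far = [_focus(1, 20.0, 20.0), _focus(1, 30.0, 30.0)]
    assert colocalize(a, far, radius=2.0) == 0.0
    shifted = [_focus(1, 2 + 1.0, 2), _focus(1, 6 + 1.0, 6)]
    assert colocalize(a, shifted, radius=2.0) == 1.0


def test_colocalization_each_b_used_once():
    a = [_focus(0, 0, 0), _focus(0, 0, 1)]
    b = [_focus(0, 0, 0.5)]
    assert colocalize(a, b, radius=2.0) == 0.5


def test_colocalization_empty_a_is_flagged_null():
    assert colocalize([], [_focus(0, 0, 0)], radius=2.0) is None


def test_colocalization_z_scaling():
    a = [_focus(0, 0, 0)]
    b = [_focus(1, 0, 0)]  # one z plane away
    assert colocalize(a, b, radius=1.5, z_spacing_factor=1.0) == 1.0
    assert colocalize(a, b, radius=1.5, z_spacing_factor=4.0) == 0.0
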