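import numpy as np
import pytest

from mngmm import (
    Volume,
    brain_bbox,
    classify_nonbrain,
    default_n_search,
    generate_grid,
    grid_stats,
    merge_grids,
)


def full_volume(data, mask=None):
    data = np.asarray(data, dtype=float)
    return Volume(data, mask=mask if mask is not None else np.ones(data.shape, bool))


def three_tissue_image(shape=(60, 60), seed=0):
    """Fine-grained three-tissue texture: every grid cell sees all tissues."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 3, size=shape)
    means = np.array([40.0, 110.0, 180.0])
    img = means[labels] + rng.normal(0, 2.0, shape)
    return full_volume(img)


class TestBrainBbox:
    def test_full_mask(self):
        vol = full_volume(np.ones((10, 12)))
        assert brain_bbox(vol) == ((0, 10), (0, 12))

    def test_single_voxel(self):
        mask = np.zeros((16, 16), bool)
        mask[7, 9] = True
        vol = Volume(np.ones((16, 16)), mask=mask)
        assert brain_bbox(vol) == ((7, 8), (9, 10))

    def test_matches_coordinate_scan(self, rng):
        mask = rng.random((20, 20)) < 0.3
        mask[5, 5] = True
        vol = Volume(np.ones((20, 20)), mask=mask)
        coords = [tuple(c) for c in np.argwhere(mask)]
        lo0, lo1 = min(c[0] for c in coords), min(c[1] for c in coords)
        hi0, hi1 = max(c[0] for c in coords), max(c[1] for c in coords)
        assert brain_bbox(vol) == ((lo0, hi0 + 1), (lo1, hi1 + 1))

    def test_empty_mask_raises(self):
        vol = Volume(np.zeros((8, 8)))
        with pytest.raises(ValueError):
            brain_bbox(vol)


class TestGenerateGrid:
    def test_exact_division(self):
        vol = full_volume(np.ones((12, 12)))
        part = generate_grid(vol, 4)
        widths = {
            tuple(hi - lo for lo, hi in part.cell_bounds[idx])
            for idx in part.cells()
        }
        assert widths == {(3, 3)}
        assert len(part.cells()) == 16

    def test_remainder_goes_to_leading_cells(self):
        vol = full_volume(np.ones((13, 13)))
        part = generate_grid(vol, 4)
        first_axis = [part.cell_bounds[(i, 0)][0] for i in range(4)]
        widths = [hi - lo for lo, hi in first_axis]
        assert widths == [4, 3, 3, 3]

    def test_cells_tile_bbox_disjointly(self, rng):
        mask = np.zeros((40, 37), bool)
        mask[3:36, 2:33] = rng.random((33, 31)) < 0.7
        vol = Volume(np.ones((40, 37)), mask=mask)
        part = generate_grid(vol, 5)
        cover = np.zeros((40, 37), dtype=int)
        for idx in part.cells():
            cover[part.cell_slices(idx)] += 1
        bbox = part.brain_bbox
        inside = cover[bbox[0][0]:bbox[0][1], bbox[1][0]:bbox[1][1]]
        assert np.all(inside == 1)
        assert cover.sum() == inside.size
        assert np.all(mask <= (cover > 0))  # every masked voxel in one cell

    def test_too_small_bbox_raises(self):
        vol = full_volume(np.ones((4, 4)))
        with pytest.raises(ValueError):
            generate_grid(vol, 6)


class TestGridStats:
    def test_three_clusters_inner_distance(self, rng):
        y = np.concatenate([
            rng.normal(40, 2, 120), rng.normal(110, 2, 120), rng.normal(180, 2, 120)
        ])
        vol = full_volume(y.reshape(1, -1))
        st = grid_stats(vol, np.arange(y.size))
        assert st.inner_distance == pytest.approx(70.0, abs=5.0)

    def test_single_tissue_collapses(self, rng):
        y = 100.0 + rng.normal(0, 0.5, 100)
        vol = full_volume(y.reshape(1, -1))
        st = grid_stats(vol, np.arange(100))
        assert st.inner_distance < 5.0

    def test_two_tissues_smaller_than_three(self, rng):
        two = np.concatenate([rng.normal(40, 2, 100), rng.normal(110, 2, 100)])
        three = np.concatenate([
            rng.normal(40, 2, 70), rng.normal(110, 2, 70), rng.normal(180, 2, 70)
        ])
        vol2 = full_volume(two.reshape(1, -1))
        vol3 = full_volume(three.reshape(1, -1))
        d2 = grid_stats(vol2, np.arange(two.size)).inner_distance
        d3 = grid_stats(vol3, np.arange(three.size)).inner_distance
        assert d2 < d3

    def test_degenerate_cell_flagged(self):
        vol = full_volume(np.full((1, 10), 7.0))
        st = grid_stats(vol, np.arange(10))
        assert st.degenerate and st.inner_distance == 0.0


class TestClassifyNonbrain:
    def test_inside_outside(self):
        mask = np.zeros((12, 12), bool)
        mask[:, :6] = True  # left half brain
        mask[0, 11] = True  # stretch bbox to the full width
        vol = Volume(np.ones((12, 12)), mask=mask)
        part = generate_grid(vol, 3)
        lab = classify_nonbrain(part, vol, min_fraction=0.05)
        assert lab.L[0, 0] == 0  # fully masked cell
        assert lab.L[2, 2] == -1  # (almost) empty cell

    def test_monotone_in_threshold(self):
        # cell (i, j) gets i*6+j masked voxels of 36, a staircase of fractions
        mask = np.zeros((36, 36), bool)
        for i in range(6):
            for j in range(6):
                k = i * 6 + j
                block = np.zeros(36, bool)
                block[:k] = True
                mask[i * 6:(i + 1) * 6, j * 6:(j + 1) * 6] = block.reshape(6, 6)
        mask[0, 0] = mask[-1, -1] = True  # keep the bbox full-size
        vol = Volume(np.ones((36, 36)), mask=mask)
        part = generate_grid(vol, 6)
        counts = []
        for frac in (0.0, 0.2, 0.4, 0.6, 0.9):
            lab = classify_nonbrain(part, vol, min_fraction=frac)
            counts.append(int((lab.L == -1).sum()))
        assert counts == sorted(counts)
        assert counts[0] < counts[-1]

    def test_all_nonbrain_raises(self):
        mask = np.zeros((12, 12), bool)
        mask[0, 0] = mask[11, 11] = True
        vol = Volume(np.ones((12, 12)), mask=mask)
        part = generate_grid(vol, 3)
        with pytest.raises(ValueError):
            classify_nonbrain(part, vol, min_fraction=0.5)


class TestDefaultNSearch:
    def test_paper_ratio_gives_three(self):
        # carve 600 interior voxels out so N_brain = 3000 = 30 * N_grid(=100)
        mask = np.ones((60, 60), bool)
        mask[20:35, 10:50] = False
        vol = Volume(np.ones((60, 60)), mask=mask)
        part = generate_grid(vol, 6)
        assert part.n_grid == 100
        assert vol.n_brain == 3000
        assert default_n_search(part, vol, alpha=0.1) == 3

    def test_clamped_to_one(self):
        vol = full_volume(np.ones((12, 12)))
        part = generate_grid(vol, 6)
        # N_brain = 144, N_grid = 4 -> floor(0.1*36) = 3; shrink alpha instead
        assert default_n_search(part, vol, alpha=0.001) == 1

    def test_direct_formula(self):
        vol = full_volume(np.ones((14, 14)))
        part = generate_grid(vol, 7)
        # N_grid = 4, N_brain = 196 -> alpha=1 gives floor(196/4) = 49
        assert default_n_search(part, vol, alpha=1.0) == 49


class TestMergeGrids:
    def test_partition_completeness_and_constraints(self):
        vol = three_tissue_image()
        part = generate_grid(vol, 6)
        labeling, patches = merge_grids(part, vol)
        total = sum(p.voxel_indices.size for p in patches)
        assert total == vol.n_brain
        ids = sorted(p.id for p in patches)
        assert ids == list(range(1, len(patches) + 1))
        brain_ext = [hi - lo for lo, hi in part.brain_bbox]
        for p in patches:
            # connectivity under face adjacency
            remaining = set(p.cells)
            stack = [p.cells[0]]
            seen = set()
            while stack:
                c = stack.pop()
                if c in seen:
                    continue
                seen.add(c)
                stack.extend(
                    o for o in remaining
                    if o not in seen and sum(abs(a - b) for a, b in zip(c, o)) == 1
                )
            assert seen == remaining
            # half-extent constraint per axis; single-cell absorption in the
            # final clean-up may relax it by up to one cell on either side
            for ax in range(2):
                lo = min(part.cell_bounds[c][ax][0] for c in p.cells)
                hi = max(part.cell_bounds[c][ax][1] for c in p.cells)
                cell_w = max(
                    part.cell_bounds[c][ax][1] - part.cell_bounds[c][ax][0]
                    for c in p.cells
                )
                assert 2 * (hi - lo) <= brain_ext[ax] + 2 * cell_w

    def test_no_single_cell_patches(self):
        vol = three_tissue_image(seed=4)
        part = generate_grid(vol, 6)
        _, patches = merge_grids(part, vol)
        assert all(len(p.cells) > 1 for p in patches)

    def test_n_search_zero_still_covers_brain(self):
        vol = three_tissue_image(seed=2)
        part = generate_grid(vol, 4)
        _, patches = merge_grids(part, vol, n_search=0)
        assert len(patches) >= 1
        assert sum(p.voxel_indices.size for p in patches) == vol.n_brain
        assert all(len(p.cells) > 1 for p in patches)

    def test_deterministic(self):
        vol = three_tissue_image(seed=9)
        part = generate_grid(vol, 5)
        lab1, p1 = merge_grids(part, vol)
        part2 = generate_grid(vol, 5)
        lab2, p2 = merge_grids(part2, vol)
        assert np.array_equal(lab1.L, lab2.L)
        assert [p.cells for p in p1] == [p.cells for p in p2]

    def test_single_tissue_cell_selected_first_and_merged(self):
        vol = three_tissue_image(shape=(60, 60), seed=7)
        # overwrite one interior cell with a single tissue (+ tiny jitter)
        rng = np.random.default_rng(1)
        vol.data[40:50, 10:20] = 110.0 + rng.normal(0, 0.3, (10, 10))
        part = generate_grid(vol, 6)
        labeling, patches = merge_grids(part, vol)
        # the doctored cell is (4, 1) in cell coordinates
        from mngmm.multigrid import grid_stats as gs
        sub = np.zeros(vol.shape, bool)
        sub[part.cell_slices((4, 1))] = vol.mask[part.cell_slices((4, 1))]
        doctored = gs(vol, np.flatnonzero(sub.ravel()))
        others = []
        for idx in part.cells():
            if idx == (4, 1):
                continue
            s = np.zeros(vol.shape, bool)
            s[part.cell_slices(idx)] = vol.mask[part.cell_slices(idx)]
            others.append(gs(vol, np.flatnonzero(s.ravel())).inner_distance)
        assert doctored.inner_distance < min(others)
        # first patch (id 1) was seeded there and absorbed neighbours
        assert labeling.L[4, 1] == 1
        assert len(patches[0].cells) > 1
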