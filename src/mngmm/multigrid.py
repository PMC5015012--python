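"""Adaptive multigrid: tile the brain bounding box and merge cells into patches.

A smooth bias field is locally nearly constant, so fitting mixtures inside
small regions sidesteps intensity inhomogeneity.  But a small cell may miss a
tissue class entirely, which wrecks a K=3 fit.  The merge procedure scores
every cell by its *inner distance* — min(|C_CSF - C_GM|, |C_WM - C_GM|) of the
cell's three FCM intensity centers, which collapses toward 0 when a class is
missing — and greedily grows patches starting from the worst cell:

1.  Tile the brain bounding box into N x N cells (N x N x N for volumes) and
    mark cells with almost no brain tissue as non-brain.
2.  Score every cell with FCM (K = 3).
3.  Pick the unlabeled cell with the smallest inner distance; it starts a new
    patch.
4.  N_search times: tentatively combine each adjacent unlabeled cell, keep
    the one whose combined region has the largest inner distance, subject to
    the patch staying within half the brain extent per axis.
5.  Repeat 3-4 until every brain cell is labeled.
6.  Absorb any remaining single-cell patch into the adjacent patch giving the
    largest combined inner distance.

N_search is tied to the data size through floor(alpha * N_brain / N_grid)
so that patches stay small relative to the brain (alpha defaults to 0.1).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .gmm import fcm_fit
from .types import Volume

log = logging.getLogger(__name__)

NONBRAIN = -1


@dataclass
class GridStats:
    """FCM summary of a cell or patch: ascending centers and the inner distance."""

    centers: np.ndarray
    inner_distance: float
    n_brain_voxels: int
    degenerate: bool = False


@dataclass
class GridPartition:
    """The N-per-axis tiling of the brain bounding box.

    ``cell_bounds[idx]`` gives the half-open (start, stop) ranges per axis for
    the cell at multi-index ``idx``; cells tile the bounding box exactly.
    ``n_grid`` is the voxel count of a full (largest) cell — the paper-style
    grid size used in the N_search budget.
    """

    n_per_axis: int
    grid_shape: Tuple[int, ...]
    cell_bounds: Dict[Tuple[int, ...], Tuple[Tuple[int, int], ...]]
    brain_bbox: Tuple[Tuple[int, int], ...]
    n_grid: int

    def cell_slices(self, idx: Tuple[int, ...]) -> Tuple[slice, ...]:
        return tuple(slice(lo, hi) for lo, hi in self.cell_bounds[idx])

    def cells(self) -> List[Tuple[int, ...]]:
        """Cell multi-indices in row-major order."""
        return sorted(self.cell_bounds.keys())


@dataclass
class PatchLabeling:
    """Cell-level label matrix L: 0 unlabeled, -1 non-brain, >=1 patch id."""

    L: np.ndarray
    next_id: int = 1


@dataclass
class Patch:
    """A merged group of grid cells with its pooled FCM statistics."""

    id: int
    cells: List[Tuple[int, ...]]
    voxel_indices: np.ndarray
    stats: GridStats


def brain_bbox(volume: Volume) -> Tuple[Tuple[int, int], ...]:
    """Tight half-open bounding box of the brain mask."""
    volume.require_brain()
    coords = np.nonzero(volume.mask)
    return tuple((int(c.min()), int(c.max()) + 1) for c in coords)


def _split_extent(extent: int, n: int) -> List[Tuple[int, int]]:
    """Split ``extent`` into n near-equal half-open runs, remainder leading."""
    base, rem = divmod(extent, n)
    bounds, start = [], 0
    for i in range(n):
        width = base + (1 if i < rem else 0)
        bounds.append((start, start + width))
        start += width
    return bounds


def generate_grid(volume: Volume, n_per_axis: int = 6) -> GridPartition:
    """Tile the brain bounding box into N cells per axis.

    2D images get an N x N grid.  For 3D volumes the same construction is
    applied along every axis (an N x N x N lattice), keeping the in-plane
    N x N semantics per axial slab.
    """
    if n_per_axis < 2:
        raise ValueError("n_per_axis must be >= 2")
    bbox = brain_bbox(volume)
    extents = [hi - lo for lo, hi in bbox]
    if any(e < n_per_axis for e in extents):
        raise ValueError(
            f"brain bounding box {extents} is too small for an N={n_per_axis} grid"
        )
    per_axis = [
        [(lo + a, lo + b) for a, b in _split_extent(hi - lo, n_per_axis)]
        for lo, hi in bbox
    ]
    grid_shape = (n_per_axis,) * volume.ndim
    cell_bounds = {
        idx: tuple(per_axis[ax][i] for ax, i in enumerate(idx))
        for idx in itertools.product(*(range(n_per_axis),) * volume.ndim)
    }
    n_grid = int(np.prod([b - a for a, b in cell_bounds[(0,) * volume.ndim]]))
    return GridPartition(n_per_axis, grid_shape, cell_bounds, bbox, n_grid)


def grid_stats(volume: Volume, voxel_indices: np.ndarray) -> GridStats:
    """FCM (K=3) statistics of the masked voxels at the given flat indices.

    Regions with fewer than 3 distinct intensities cannot host three centers;
    they are flagged degenerate with inner distance 0 so they merge earliest.
    """
    y = volume.data.ravel()[voxel_indices]
    n = int(y.size)
    if n == 0 or np.unique(y).size < 3:
        centers = np.full(3, float(y.mean()) if n else 0.0)
        return GridStats(centers, 0.0, n, degenerate=True)
    res = fcm_fit(y, K=3)
    c_csf, c_gm, c_wm = res.centers
    inner = float(min(abs(c_csf - c_gm), abs(c_wm - c_gm)))
    return GridStats(res.centers.copy(), inner, n, degenerate=res.degenerate)


def classify_nonbrain(
    partition: GridPartition, volume: Volume, min_fraction: float = 0.05
) -> PatchLabeling:
    """Mark cells whose brain-voxel fraction is below ``min_fraction`` as -1."""
    L = np.zeros(partition.grid_shape, dtype=np.int64)
    any_brain = False
    for idx in partition.cells():
        sl = partition.cell_slices(idx)
        cell_vox = int(np.prod([s.stop - s.start for s in sl]))
        frac = volume.mask[sl].sum() / max(cell_vox, 1)
        if frac < min_fraction:
            L[idx] = NONBRAIN
        else:
            any_brain = True
    if not any_brain:
        raise ValueError("every grid cell is non-brain; check the mask")
    return PatchLabeling(L=L)


def default_n_search(
    partition: GridPartition, volume: Volume, alpha: float = 0.1
) -> int:
    """N_search = floor(alpha * N_brain / N_grid), at least 1."""
    if partition.n_grid <= 0:
        raise ValueError("partition has empty cells")
    return max(int(alpha * volume.n_brain / partition.n_grid), 1)


def _cell_voxel_indices(
    partition: GridPartition, volume: Volume
) -> Dict[Tuple[int, ...], np.ndarray]:
    flat_mask = volume.mask
    out = {}
    for idx in partition.cells():
        sl = partition.cell_slices(idx)
        sub = np.zeros(volume.shape, dtype=bool)
        sub[sl] = flat_mask[sl]
        out[idx] = np.flatnonzero(sub.ravel())
    return out


def _adjacent(a: Tuple[int, ...], b: Tuple[int, ...]) -> bool:
    """Face adjacency between cell multi-indices (4-neighborhood in 2D)."""
    diff = [abs(x - y) for x, y in zip(a, b)]
    return sum(diff) == 1


def _patch_extent_ok(
    cells: Sequence[Tuple[int, ...]],
    partition: GridPartition,
    brain_extents: Sequence[int],
) -> bool:
    """Patch bounding box must stay within half the brain extent per axis."""
    for ax, brain_ext in enumerate(brain_extents):
        lo = min(partition.cell_bounds[c][ax][0] for c in cells)
        hi = max(partition.cell_bounds[c][ax][1] for c in cells)
        if 2 * (hi - lo) > brain_ext:
            return False
    return True


def merge_grids(
    partition: GridPartition,
    volume: Volume,
    n_search: Optional[int] = None,
    alpha: float = 0.1,
    min_fraction: float = 0.05,
    labeling: Optional[PatchLabeling] = None,
) -> Tuple[PatchLabeling, List[Patch]]:
    """Run the 6-step merge and return the cell labeling plus final patches.

    Deterministic tie-breaks: worst-cell selection prefers row-major order;
    the best combination prefers (largest inner distance, then most brain
    voxels, then row-major order).
    """
    if labeling is None:
        labeling = classify_nonbrain(partition, volume, min_fraction)
    if n_search is None:
        n_search = default_n_search(partition, volume, alpha)
    L = labeling.L
    cell_vox = _cell_voxel_indices(partition, volume)
    cell_stats = {
        idx: grid_stats(volume, cell_vox[idx])
        for idx in partition.cells()
        if L[idx] != NONBRAIN
    }
    brain_extents = [hi - lo for lo, hi in partition.brain_bbox]

    def pooled_stats(cells: List[Tuple[int, ...]]) -> GridStats:
        vox = np.concatenate([cell_vox[c] for c in cells])
        return grid_stats(volume, vox)

    patches: Dict[int, List[Tuple[int, ...]]] = {}
    n_number = labeling.next_id
    while True:
        unlabeled = [c for c in partition.cells() if L[c] == 0]
        if not unlabeled:
            break
        # Step 3: worst remaining cell seeds the next patch.
        seed = min(unlabeled, key=lambda c: (cell_stats[c].inner_distance, c))
        L[seed] = n_number
        members = [seed]
        # Step 4: grow by the best adjacent cell, n_search times.
        for _ in range(n_search):
            candidates = sorted(
                {
                    c
                    for c in partition.cells()
                    if L[c] == 0 and any(_adjacent(c, mcell) for mcell in members)
                }
            )
            best = None
            for cand in candidates:
                trial = members + [cand]
                if not _patch_extent_ok(trial, partition, brain_extents):
                    continue
                st = pooled_stats(trial)
                key = (st.inner_distance, st.n_brain_voxels)
                if best is None or key > best[0]:
                    best = (key, cand)
            if best is None:
                break
            L[best[1]] = n_number
            members.append(best[1])
        patches[n_number] = members
        n_number += 1

    # Step 6: absorb single-cell patches into their best adjacent patch.
    while True:
        singles = sorted(pid for pid, cells in patches.items() if len(cells) == 1)
        absorbed_any = False
        for pid in singles:
            cell = patches[pid][0]
            neighbor_pids = sorted(
                {
                    int(L[c])
                    for c in partition.cells()
                    if L[c] > 0 and L[c] != pid and _adjacent(c, cell)
                }
            )
            if not neighbor_pids:
                log.warning(
                    "cell %s is an isolated single-cell patch; keeping it", cell
                )
                continue
            best = None
            for nb in neighbor_pids:
                trial = patches[nb] + [cell]
                st = pooled_stats(trial)
                if not _patch_extent_ok(trial, partition, brain_extents):
                    log.info(
                        "absorbing single cell %s into patch %d relaxes the "
                        "half-extent constraint",
                        cell,
                        nb,
                    )
                key = (st.inner_distance, st.n_brain_voxels)
                if best is None or key > best[0]:
                    best = (key, nb)
            target = best[1]
            patches[target].append(cell)
            L[cell] = target
            del patches[pid]
            absorbed_any = True
            break  # re-evaluate singles after each absorption
        if not absorbed_any:
            break

    # Renumber patch ids contiguously 1..P in order of creation.
    final: List[Patch] = []
    remap = {}
    for new_id, old_id in enumerate(sorted(patches), start=1):
        cells = sorted(patches[old_id])
        remap[old_id] = new_id
        vox = np.sort(np.concatenate([cell_vox[c] for c in cells]))
        final.append(Patch(new_id, cells, vox, pooled_stats(cells)))
    for idx in partition.cells():
        if L[idx] > 0:
            L[idx] = remap[int(L[idx])]
    return PatchLabeling(L=L, next_id=len(final) + 1), final
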