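"""Per-patch model fitting and cross-patch posterior fusion.

Each merged patch gets its own nonlocally regularized mixture fit, which makes
the segmentation insensitive to a smooth bias field (locally near-constant).
Independent patch fits can disagree near patch borders, so each voxel's final
posterior blends the posterior under its home patch model with the posteriors
induced by the models of the adjacent patches:

    fused_k = sum_j  [ N(y_i; theta_{k,j}) / sum_l N(y_i; theta_{k,l}) ] * p_{k,j}

where j = 0 is the home patch, j = 1..N_i are its face-adjacent neighbours,
p_{k,j} is the class-k posterior of model j at voxel i, and the blending
weight of model j is its class-k component density at y_i (mixing weights
excluded).  The fused value is a convex combination per class, and a voxel in
a patch with no neighbours keeps its home posterior exactly.  Classes
correspond across patches by ascending component mean (CSF < GM < WM).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional

import numpy as np
from scipy import ndimage

from .gmm import (
    MixtureModel,
    PosteriorField,
    _posterior_from_log,
    fit_em,
)
from .multigrid import (
    Patch,
    PatchLabeling,
    _adjacent,
    classify_nonbrain,
    generate_grid,
    merge_grids,
)
from .nlm import NonlocalConfig, NonlocalWeights, fit_ngmm
from .types import LabelMap, SegmentationResult, Volume

log = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class PatchModelSet:
    """Fitted models per patch plus the voxel->patch and adjacency maps.

    ``neighbor_ids`` records patch-level adjacency.  ``cell_map`` (voxel ->
    grid-cell id) and ``cell_neighbors`` (cell id -> adjacent foreign patch
    ids) localize fusion: a voxel is fused only with the patches bordering
    its own grid cell, so voxels deep inside a patch keep their home
    posterior — the observed discontinuities to repair live along cell
    borders, and models from far-away cells (under a different bias level)
    carry no information about them.
    """

    models: Dict[int, MixtureModel]
    home_patch: np.ndarray
    neighbor_ids: Dict[int, List[int]]
    home_posteriors: Optional[Dict[int, PosteriorField]] = None
    cell_map: Optional[np.ndarray] = None
    cell_neighbors: Optional[Dict[int, List[int]]] = None

    def validate(self) -> None:
        ids = set(self.models)
        present = set(int(v) for v in np.unique(self.home_patch) if v > 0)
        if not present <= ids:
            raise ValueError("home_patch refers to patches without models")
        for pid, nbs in self.neighbor_ids.items():
            for nb in nbs:
                if nb == pid or pid not in self.neighbor_ids.get(nb, []):
                    raise ValueError("neighbor relation must be symmetric and irreflexive")


@dataclass
class FusedPosterior:
    """Posterior columns under home (j=0) and neighbour models, plus the fusion."""

    p_kj: np.ndarray  # (N_i + 1, K); each row sums to 1
    model_ids: List[int]
    fused: Optional[np.ndarray] = None  # (K,)


def _component_log_dens(y, model: MixtureModel) -> np.ndarray:
    """Weight-free log component densities log N(y; mu_k, var_k), shape (..., K)."""
    y = np.asarray(y, dtype=float)
    mu = model.means
    var = model.vars
    return -0.5 * (_LOG_2PI + np.log(var)) - (y[..., None] - mu) ** 2 / (2 * var)


def _posterior_under(y, model: MixtureModel) -> np.ndarray:
    logp = _component_log_dens(y, model) + np.log(np.maximum(model.weights, 1e-300))
    return _posterior_from_log(np.atleast_2d(logp))


def neighbor_posteriors(
    voxel,
    volume: Volume,
    patchset: PatchModelSet,
    home_posterior: Optional[np.ndarray] = None,
) -> FusedPosterior:
    """Posterior columns for one voxel under its home and neighbour models.

    Column 0 is the home-model posterior; by default it is recomputed from the
    home model, but the pipeline injects the nonlocally smoothed posterior the
    home patch actually produced.  Neighbour columns follow in ascending
    patch-id order.
    """
    voxel = tuple(int(a) for a in np.atleast_1d(voxel))
    pid = int(patchset.home_patch[voxel])
    if pid <= 0:
        raise ValueError(f"voxel {voxel} has no home patch")
    y = float(volume.data[voxel])
    if patchset.cell_map is not None and patchset.cell_neighbors is not None:
        nbs = patchset.cell_neighbors.get(int(patchset.cell_map[voxel]), [])
    else:
        nbs = patchset.neighbor_ids.get(pid, [])
    ids = [pid] + sorted(nbs)
    cols = []
    for j, mid in enumerate(ids):
        if j == 0 and home_posterior is not None:
            cols.append(np.asarray(home_posterior, dtype=float))
        else:
            cols.append(_posterior_under(np.array([y]), patchset.models[mid])[0])
    return FusedPosterior(p_kj=np.stack(cols), model_ids=ids)


def fuse(voxel, fp: FusedPosterior, volume: Volume, patchset: PatchModelSet) -> np.ndarray:
    """Blend the posterior columns with likelihood weights; returns the fused K-vector."""
    voxel = tuple(int(a) for a in np.atleast_1d(voxel))
    y = float(volume.data[voxel])
    n_models, K = fp.p_kj.shape
    # dens[j, k] = N(y; theta_{k,j})
    logd = np.stack(
        [_component_log_dens(np.array([y]), patchset.models[mid])[0]
         for mid in fp.model_ids]
    )
    fused = _fuse_from_logdens(logd[None], fp.p_kj[None])[0]
    fp.fused = fused
    return fused


def _fuse_from_logdens(logd: np.ndarray, p_kj: np.ndarray) -> np.ndarray:
    """Vectorized fusion.  logd, p_kj: (n, J, K) -> fused (n, K).

    Per class k the weights are dens[:, j, k] / sum_j dens[:, j, k]; if every
    model's class-k density underflows, uniform weights 1/J are used.
    """
    m = logd.max(axis=1, keepdims=True)
    d = np.exp(logd - m)  # safe: at least one entry is 1 per (n, k)
    den = d.sum(axis=1, keepdims=True)
    w = d / den
    return (w * p_kj).sum(axis=1)


def build_patchset(
    volume: Volume,
    patches: List[Patch],
    labeling: PatchLabeling,
    partition,
    models: Dict[int, MixtureModel],
    home_posteriors: Optional[Dict[int, PosteriorField]] = None,
) -> PatchModelSet:
    """Assemble the per-voxel home-patch map and the adjacency structures."""
    home = np.zeros(volume.shape, dtype=np.int64)
    for patch in patches:
        home.ravel()[patch.voxel_indices] = patch.id
    neighbor_ids: Dict[int, List[int]] = {p.id: set() for p in patches}
    cells_of = {p.id: p.cells for p in patches}
    ids = sorted(cells_of)
    for i, a in enumerate(ids):
        for b in ids[i + 1:]:
            if any(_adjacent(ca, cb) for ca in cells_of[a] for cb in cells_of[b]):
                neighbor_ids[a].add(b)
                neighbor_ids[b].add(a)
    neighbor_ids = {pid: sorted(nbs) for pid, nbs in neighbor_ids.items()}

    cell_map = None
    cell_neighbors = None
    if partition is not None and labeling is not None:
        cell_map = np.full(volume.shape, -1, dtype=np.int64)
        all_cells = partition.cells()
        lin = {c: i for i, c in enumerate(all_cells)}
        for c in all_cells:
            cell_map[partition.cell_slices(c)] = lin[c]
        cell_map[home == 0] = -1
        L = labeling.L
        cell_neighbors = {}
        for c in all_cells:
            pid = int(L[c])
            if pid <= 0:
                continue
            nbs = {
                int(L[other])
                for other in all_cells
                if _adjacent(c, other) and L[other] > 0 and L[other] != pid
            }
            cell_neighbors[lin[c]] = sorted(nbs)
    ps = PatchModelSet(models, home, neighbor_ids, home_posteriors,
                       cell_map, cell_neighbors)
    ps.validate()
    return ps


def segment_mngmm(
    volume: Volume,
    grid_n: int = 6,
    alpha: float = 0.1,
    n_search: Optional[int] = None,
    min_brain_fraction: float = 0.05,
    nl_cfg: Optional[NonlocalConfig] = None,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> SegmentationResult:
    """Full pipeline: multigrid -> per-patch nonlocal mixture fits -> fusion.

    Returns posterior maps (renormalized over classes for export), the hard
    label map (argmax of the *raw* fused values, ties to the lower class), the
    per-patch models, and the voxel->patch map.
    """
    volume.require_brain()
    nl_cfg = nl_cfg or NonlocalConfig()
    partition = generate_grid(volume, grid_n)
    labeling = classify_nonbrain(partition, volume, min_brain_fraction)
    labeling, patches = merge_grids(
        partition, volume, n_search=n_search, alpha=alpha, labeling=labeling
    )
    weights = NonlocalWeights(volume, nl_cfg)

    models: Dict[int, MixtureModel] = {}
    home_post: Dict[int, PosteriorField] = {}
    for patch in patches:
        validity = np.zeros(volume.shape, dtype=bool)
        validity.ravel()[patch.voxel_indices] = True
        init = MixtureModel.from_arrays(
            np.full(3, 1 / 3),
            patch.stats.centers,
            np.full(3, max(float(np.var(volume.data.ravel()[patch.voxel_indices])), 1e-12)),
        )
        try:
            res = fit_ngmm(
                volume, init=init, cfg=nl_cfg, max_iter=max_iter, tol=tol,
                weights=weights, validity=validity,
            )
        except Exception:
            log.exception(
                "nonlocal fit failed for patch %d; falling back to plain EM", patch.id
            )
            sub = Volume(volume.data, volume.spacing, validity)
            res = fit_em(sub, init.sorted_by_mean(), max_iter=max_iter, tol=tol)
        models[patch.id] = res.model
        home_post[patch.id] = res.posteriors

    patchset = build_patchset(volume, patches, labeling, partition, models, home_post)

    K = 3
    fused_maps = np.zeros((K,) + volume.shape)
    flat_data = volume.data.ravel()
    flat_cells = patchset.cell_map.ravel()
    for patch in patches:
        pvox = patch.voxel_indices
        # Group the patch's voxels by grid cell: fusion partners are the
        # patches bordering each voxel's own cell.
        for cell_id in np.unique(flat_cells[pvox]):
            vox = pvox[flat_cells[pvox] == cell_id]
            y = flat_data[vox]
            ids = [patch.id] + patchset.cell_neighbors.get(int(cell_id), [])
            J = len(ids)
            rows = np.searchsorted(pvox, vox)
            logd = np.empty((y.size, J, K))
            p_kj = np.empty((y.size, J, K))
            for j, mid in enumerate(ids):
                logd[:, j, :] = _component_log_dens(y, models[mid])
                if j == 0:
                    p_kj[:, 0, :] = home_post[patch.id].values[rows]
                else:
                    p_kj[:, j, :] = _posterior_under(y, models[mid])
            fused = _fuse_from_logdens(logd, p_kj)
            for k in range(K):
                fused_maps[k].ravel()[vox] = fused[:, k]

    # Masked voxels falling in cells classified as non-brain have no home
    # patch; classify each under the model of the nearest patch voxel.
    orphans = volume.mask & (patchset.home_patch == 0)
    if orphans.any():
        log.info("classifying %d masked voxels outside brain cells", orphans.sum())
        _, nearest = ndimage.distance_transform_edt(
            patchset.home_patch == 0, return_indices=True
        )
        nearest_pid = patchset.home_patch[tuple(nearest)]
        patchset.home_patch[orphans] = nearest_pid[orphans]
        for pid in np.unique(patchset.home_patch[orphans]):
            sel = orphans & (patchset.home_patch == pid)
            post = _posterior_under(volume.data[sel], models[int(pid)])
            for k in range(K):
                fused_maps[k][sel] = post[:, k]

    # Hard labels from the raw fused values; export maps renormalized over k.
    brain = patchset.home_patch > 0
    labels = np.zeros(volume.shape, dtype=np.int64)
    stacked = fused_maps[:, brain]
    labels[brain] = 1 + np.argmax(stacked, axis=0)
    norm = stacked.sum(axis=0)
    norm[norm <= 0] = 1.0
    export = fused_maps.copy()
    export[:, brain] = stacked / norm
    return SegmentationResult(
        posteriors=export,
        labels=LabelMap(labels),
        models=models,
        patch_map=patchset.home_patch,
    )
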