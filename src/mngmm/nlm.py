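"""Nonlocal posterior regularization (the NGMM of the pipeline).

Plain mixture EM treats voxels independently, so noise flips posteriors voxel
by voxel.  Nonlocal-means weighting repairs this: two voxels i and j receive a
high mutual weight when the intensity patches around them look alike,

    W(i, j) = exp(-||patch_i - patch_j||^2_{2,r} / h^2) / normalization,

where the patch norm is a Gaussian-weighted (sd r) sum of squared intensity
differences over a (2p+1)^d window and h controls the decay.  The converged
posteriors are replaced by their W-weighted averages

    NLp(k | y_i) = sum_j W(i, j) p(k | y_j)

before MAP classification, which averages evidence across self-similar voxels
while leaving dissimilar (cross-edge) voxels untouched.

Following standard nonlocal-means practice the sum over j is restricted to a
search window around i (default half-width 5) — the exponential decay makes
more distant weights negligible — and the self-weight W(i, i) is set to the
maximum weight among the neighbours so the centre voxel cannot dominate its
own average.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .gmm import (
    EMResult,
    MixtureModel,
    PosteriorField,
    fit_em,
    init_from_fcm,
)
from .types import Volume

log = logging.getLogger(__name__)

#: h = DEFAULT_H_FACTOR * estimated noise sd when NonlocalConfig.h is None.
#: With a unit-mass patch kernel the expected patch distance between two
#: same-tissue patches is 2 sigma^2 with fluctuations of order sigma^2, so
#: h = sigma keeps same-tissue weights of order one while any structural
#: patch difference Delta contributes Delta^2/sigma^2 >> 1 to the exponent
#: and is suppressed.
DEFAULT_H_FACTOR = 1.0


@dataclass
class NonlocalConfig:
    """Parameters of the nonlocal weighting.

    patch_radius p gives (2p+1)^d comparison patches; search_radius bounds the
    window over which weights are computed; h (intensity units) controls the
    exponential decay and defaults to ``DEFAULT_H_FACTOR * estimated noise sd``
    when left as None; r (voxels) is the sd of the Gaussian kernel inside the
    patch norm.
    """

    patch_radius: int = 1
    search_radius: int = 5
    h: Optional[float] = None
    r: float = 1.0
    self_weight_rule: str = "max_neighbor"

    def __post_init__(self) -> None:
        if self.patch_radius < 1:
            raise ValueError("patch_radius must be >= 1")
        if self.search_radius < self.patch_radius:
            raise ValueError("search_radius must be >= patch_radius")
        if self.h is not None and not self.h > 0:
            raise ValueError("h must be positive")
        if not self.r > 0:
            raise ValueError("r must be positive")
        if self.self_weight_rule not in ("max_neighbor", "one"):
            raise ValueError(f"unknown self_weight_rule {self.self_weight_rule!r}")


def estimate_noise_sd(volume: Volume) -> float:
    """Robust noise sd from the Laplacian residual inside the brain.

    The discrete Laplacian of iid noise has variance (4 d^2 + 2 d) sigma^2 in
    d dimensions; the median absolute deviation makes the estimate insensitive
    to the sparse large residuals at tissue edges.
    """
    volume.require_brain()
    lap = ndimage.laplace(volume.data)
    interior = ndimage.binary_erosion(volume.mask, iterations=2)
    if interior.sum() < 16:
        interior = volume.mask
    vals = lap[interior]
    mad = float(np.median(np.abs(vals - np.median(vals))))
    d = volume.ndim
    return 1.4826 * mad / np.sqrt(4.0 * d * d + 2.0 * d)


def resolve_h(volume: Volume, cfg: NonlocalConfig) -> float:
    """The decay parameter actually used: cfg.h, or the auto rule."""
    if cfg.h is not None:
        return float(cfg.h)
    sigma = estimate_noise_sd(volume)
    scale = float(np.ptp(volume.brain_values)) or 1.0
    return max(DEFAULT_H_FACTOR * sigma, 1e-3 * scale, 1e-12)


def _patch_kernel(p: int, r: float, ndim: int) -> np.ndarray:
    """Unit-mass Gaussian kernel over the (2p+1)^ndim patch offsets."""
    ax = np.arange(-p, p + 1, dtype=float)
    g1 = np.exp(-(ax**2) / (2.0 * r * r))
    kern = g1
    for _ in range(ndim - 1):
        kern = np.multiply.outer(kern, g1)
    return kern / kern.sum()


def patch_distance(volume: Volume, i, j, cfg: NonlocalConfig) -> float:
    """Gaussian-weighted squared distance between the patches at voxels i and j.

    Patches reaching past the image border use edge-replicated intensities.
    Symmetric in (i, j); zero for identical patches.
    """
    p = cfg.patch_radius
    pad = np.pad(volume.data, p, mode="edge")
    i = tuple(int(a) for a in np.atleast_1d(i))
    j = tuple(int(a) for a in np.atleast_1d(j))
    sl_i = tuple(slice(a, a + 2 * p + 1) for a in i)
    sl_j = tuple(slice(a, a + 2 * p + 1) for a in j)
    kern = _patch_kernel(p, cfg.r, volume.ndim)
    diff = pad[sl_i] - pad[sl_j]
    return float((kern * diff * diff).sum())


def _offsets(search_radius: int, ndim: int) -> List[Tuple[int, ...]]:
    rng = range(-search_radius, search_radius + 1)
    return [t for t in itertools.product(*([rng] * ndim)) if any(t)]


def _shifted(arr: np.ndarray, t: Sequence[int], fill=0.0) -> np.ndarray:
    """out[i] = arr[i + t] where i + t is inside the array, else ``fill``."""
    out = np.full(arr.shape, fill, dtype=arr.dtype)
    src, dst = [], []
    for n_a, t_a in zip(arr.shape, t):
        if t_a >= 0:
            src.append(slice(t_a, n_a))
            dst.append(slice(0, n_a - t_a))
        else:
            src.append(slice(0, n_a + t_a))
            dst.append(slice(-t_a, n_a))
    out[tuple(dst)] = arr[tuple(src)]
    return out


class NonlocalWeights:
    """Precomputed unnormalized weights exp(-d(i, i+t)/h^2) for every window offset.

    The weights depend only on the intensities, so they are built once per
    volume and reused across every EM iteration and every patch.  Memory is
    (number of offsets) x (image size) doubles; the constructor refuses
    configurations that would exceed ``max_bytes``.
    """

    def __init__(self, volume: Volume, cfg: NonlocalConfig,
                 max_bytes: float = 2e9) -> None:
        volume.require_brain()
        self.cfg = cfg
        self.volume = volume
        self.h = resolve_h(volume, cfg)
        self.offsets = _offsets(cfg.search_radius, volume.ndim)
        nbytes = len(self.offsets) * volume.data.size * 8
        if nbytes > max_bytes:
            raise MemoryError(
                f"nonlocal weight stack would need {nbytes / 1e9:.1f} GB; "
                "reduce search_radius"
            )
        p, s = cfg.patch_radius, cfg.search_radius
        shape = volume.shape
        padded = np.pad(volume.data, p + s, mode="edge")
        # separable 1D kernel, normalized per axis
        ax = np.arange(-p, p + 1, dtype=float)
        g1 = np.exp(-(ax**2) / (2.0 * cfg.r * cfg.r))
        kern1 = g1 / g1.sum()
        base = tuple(slice(s, s + n + 2 * p) for n in shape)
        self.w = np.empty((len(self.offsets),) + shape)
        for idx, t in enumerate(self.offsets):
            shifted_sl = tuple(
                slice(s + t_a, s + t_a + n + 2 * p) for t_a, n in zip(t, shape)
            )
            diff = padded[base] - padded[shifted_sl]
            d = diff * diff
            for axis in range(volume.ndim):
                d = ndimage.correlate1d(d, kern1, axis=axis, mode="nearest")
            center = tuple(slice(p, p + n) for n in shape)
            d = d[center]
            w = np.exp(-d / (self.h * self.h))
            # zero the weight when i+t falls outside the image or the mask
            w *= _shifted(volume.mask.astype(float), t, fill=0.0)
            self.w[idx] = w

    def bind(self, validity: Optional[np.ndarray] = None) -> "BoundWeights":
        """Restrict neighbours to ``validity`` (default: the brain mask)."""
        if validity is None:
            validity = self.volume.mask
        return BoundWeights(self, np.asarray(validity, dtype=bool))


class BoundWeights:
    """Weights clipped to a voxel subset, cropped to its bounding box."""

    def __init__(self, weights: NonlocalWeights, validity: np.ndarray) -> None:
        if not validity.any():
            raise ValueError("validity mask is empty")
        self.offsets = weights.offsets
        self.rule = weights.cfg.self_weight_rule
        region = ndimage.find_objects(validity.astype(np.int8))[0]
        self.region = region
        self.validity = validity[region]
        vc = self.validity.astype(float)
        n_off = len(self.offsets)
        self.w_eff = np.empty((n_off,) + self.validity.shape)
        for idx, t in enumerate(self.offsets):
            self.w_eff[idx] = weights.w[(idx,) + region] * _shifted(vc, t)
        if self.rule == "max_neighbor":
            w0 = self.w_eff.max(axis=0)
            w0[w0 <= 0] = 1.0  # isolated voxel: all weight on itself
        else:
            w0 = np.ones(self.validity.shape)
        self.w0 = w0
        self.den = w0 + self.w_eff.sum(axis=0)

    def smooth_maps(self, maps: np.ndarray) -> np.ndarray:
        """Apply the weighting to (K, *crop_shape) maps; rows outside validity
        are left as the self-weighted identity."""
        out = np.empty_like(maps)
        for k in range(maps.shape[0]):
            acc = self.w0 * maps[k]
            for idx, t in enumerate(self.offsets):
                acc += self.w_eff[idx] * _shifted(maps[k], t)
            out[k] = acc / self.den
        return out

    def smooth_field(self, post: PosteriorField) -> PosteriorField:
        """Smooth a posterior field defined exactly on the validity voxels."""
        K = post.K
        maps = np.zeros((K,) + self.validity.shape)
        for k in range(K):
            maps[k][self.validity] = post.values[:, k]
        maps = self.smooth_maps(maps)
        values = np.stack([maps[k][self.validity] for k in range(K)], axis=1)
        return PosteriorField(values, values.sum(axis=0), post.indices, post.shape)


def nl_weights(volume: Volume, i, cfg: NonlocalConfig) -> np.ndarray:
    """Normalized weight map W(i, .) over the search window, as a full-shape array.

    Weights cover masked voxels inside the window, include the self-weight at
    i (set by ``cfg.self_weight_rule``), and sum to 1.
    """
    volume.require_brain()
    i = tuple(int(a) for a in np.atleast_1d(i))
    if not volume.mask[i]:
        raise ValueError(f"voxel {i} is outside the brain mask")
    h = resolve_h(volume, cfg)
    s = cfg.search_radius
    W = np.zeros(volume.shape)
    neighbors = []
    for t in _offsets(s, volume.ndim):
        j = tuple(a + t_a for a, t_a in zip(i, t))
        if any(a < 0 or a >= n for a, n in zip(j, volume.shape)):
            continue
        if not volume.mask[j]:
            continue
        d = patch_distance(volume, i, j, cfg)
        W[j] = np.exp(-d / (h * h))
        neighbors.append(j)
    if cfg.self_weight_rule == "max_neighbor":
        W[i] = max((W[j] for j in neighbors), default=1.0)
    else:
        W[i] = 1.0
    return W / W.sum()


def smooth_posteriors(
    post: PosteriorField,
    volume: Volume,
    cfg: NonlocalConfig,
    weights: Optional[NonlocalWeights] = None,
) -> PosteriorField:
    """Replace each posterior row by its nonlocal weighted average (masked only)."""
    if weights is None:
        weights = NonlocalWeights(volume, cfg)
    return weights.bind(volume.mask).smooth_field(post)


def fit_ngmm(
    volume: Volume,
    init: Optional[MixtureModel] = None,
    cfg: Optional[NonlocalConfig] = None,
    max_iter: int = 100,
    tol: float = 1e-6,
    weights: Optional[NonlocalWeights] = None,
    validity: Optional[np.ndarray] = None,
) -> EMResult:
    """Mixture fit with nonlocally adapted posteriors.

    Parameters are estimated by plain EM (guaranteed-ascent, stable), and the
    converged posteriors are then adapted once by the nonlocal weighting
    before MAP classification — the posterior field returned is the adapted
    one.  The adaptation is deliberately kept out of the EM loop: the
    row-normalized averaging does not conserve per-class responsibility mass,
    so feeding smoothed responsibilities back into the M-step progressively
    drains thin tissue classes (the GM ribbon) at high noise and can collapse
    components onto each other.

    ``validity`` restricts the fit (and the neighbour windows) to a voxel
    subset, which is how per-patch models are fitted independently.  A
    prebuilt :class:`NonlocalWeights` may be passed to share work across
    patches.
    """
    cfg = cfg or NonlocalConfig()
    if validity is None:
        validity = volume.mask
    sub = Volume(volume.data, volume.spacing, validity)
    sub.require_brain()
    if weights is None:
        weights = NonlocalWeights(volume, cfg)
    model = (init or init_from_fcm(sub.brain_values, 3)).sorted_by_mean()
    res = fit_em(sub, model, max_iter=max_iter, tol=tol)
    post = weights.bind(validity).smooth_field(res.posteriors)
    return EMResult(res.model, post, res.converged, res.n_iter, res.loglik_trace)
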