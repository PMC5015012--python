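"""Gaussian mixture modelling of tissue intensities.

A brain image with the skull removed contains three tissue classes (CSF, GM,
WM), so the intensity histogram is modelled as a K=3 mixture of Gaussians

    p(y | theta) = sum_k pi_k N(y; mu_k, sigma_k)

with mixing weights pi_k and per-class mean mu_k and variance sigma_k.
Parameters are estimated by expectation-maximization: the E-step computes the
posterior responsibility p(k | y_i, theta) of each class for each voxel, the
M-step re-estimates (pi, mu, sigma) from responsibility-weighted moments.
Voxels are finally assigned to the class with the largest posterior.

Fuzzy c-means (FCM) on the 1D intensities provides the deterministic
initialization and is also used to score grid cells in the multigrid stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.special import logsumexp

from .types import LabelMap, Volume

log = logging.getLogger(__name__)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass
class GaussianComponent:
    """One mixture component: weight pi_k, mean mu_k, variance var_k."""

    weight: float
    mean: float
    var: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.weight <= 1.0 + 1e-12):
            raise ValueError(f"component weight {self.weight} outside [0, 1]")
        if not self.var > 0:
            raise ValueError(f"component variance {self.var} must be positive")


@dataclass
class MixtureModel:
    """An ordered collection of K Gaussian components."""

    components: List[GaussianComponent]

    @property
    def K(self) -> int:
        return len(self.components)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.components])

    @property
    def means(self) -> np.ndarray:
        return np.array([c.mean for c in self.components])

    @property
    def vars(self) -> np.ndarray:
        return np.array([c.var for c in self.components])

    def validate(self) -> None:
        if abs(self.weights.sum() - 1.0) > 1e-9:
            raise ValueError("mixture weights must sum to 1")

    def sorted_by_mean(self) -> "MixtureModel":
        """Components in ascending-mean order (CSF < GM < WM for T1)."""
        order = np.argsort(self.means, kind="stable")
        return MixtureModel([self.components[i] for i in order])

    @classmethod
    def from_arrays(cls, weights, means, variances) -> "MixtureModel":
        return cls(
            [GaussianComponent(float(w), float(m), float(v))
             for w, m, v in zip(weights, means, variances)]
        )


@dataclass
class PosteriorField:
    """Per-voxel class posteriors p(k | y_i, theta) over the masked voxels.

    ``values`` has shape (n_masked, K) with rows summing to 1; ``alpha`` holds
    the per-class responsibility totals alpha_k = sum_i p(k | y_i, theta).
    ``indices``/``shape`` record where the rows live in the image so the field
    can be expanded back to spatial maps.
    """

    values: np.ndarray
    alpha: np.ndarray
    indices: Optional[np.ndarray] = None
    shape: Optional[Tuple[int, ...]] = None

    @property
    def K(self) -> int:
        return self.values.shape[1]

    def to_maps(self) -> np.ndarray:
        """Expand to dense (K, *shape) posterior maps, zero outside the mask."""
        if self.indices is None or self.shape is None:
            raise ValueError("posterior field carries no spatial placement")
        maps = np.zeros((self.K,) + tuple(self.shape))
        for k in range(self.K):
            maps[k].flat[self.indices] = self.values[:, k]
        return maps


def component_pdf(y, comp: GaussianComponent):
    """Gaussian density N(y; mean, var) of one component; vectorized in y."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite intensity passed to component_pdf")
    out = np.exp(-((y - comp.mean) ** 2) / (2.0 * comp.var)) / np.sqrt(
        2.0 * np.pi * comp.var
    )
    return out if out.ndim else float(out)


def _log_densities(y: np.ndarray, model: MixtureModel) -> np.ndarray:
    """log pi_k + log N(y_i; mu_k, var_k) as an (n, K) array."""
    mu = model.means[None, :]
    var = model.vars[None, :]
    logw = np.log(np.maximum(model.weights, 1e-300))[None, :]
    return logw - 0.5 * (_LOG_2PI + np.log(var)) - (y[:, None] - mu) ** 2 / (2 * var)


def _posterior_from_log(logp: np.ndarray) -> np.ndarray:
    norm = logsumexp(logp, axis=1, keepdims=True)
    bad = ~np.isfinite(norm[:, 0])
    post = np.exp(logp - np.where(np.isfinite(norm), norm, 0.0))
    if bad.any():
        # All component densities underflowed: fall back to a flat posterior.
        log.warning("posterior underflow at %d voxels; using uniform 1/K", bad.sum())
        post[bad] = 1.0 / logp.shape[1]
    return post


def e_step(volume: Volume, model: MixtureModel) -> PosteriorField:
    """E-step: responsibilities p(k|y_i) = pi_k N_k(y_i) / sum_j pi_j N_j(y_i)."""
    volume.require_brain()
    model.validate()
    y = volume.brain_values
    post = _posterior_from_log(_log_densities(y, model))
    return PosteriorField(
        values=post,
        alpha=post.sum(axis=0),
        indices=np.flatnonzero(volume.mask.ravel()),
        shape=volume.shape,
    )


def m_step(
    volume: Volume, post: PosteriorField, var_floor: Optional[float] = None
) -> MixtureModel:
    """M-step: pi_k = alpha_k/N, mu_k and var_k from responsibility-weighted moments."""
    y = volume.brain_values
    resp = post.values
    n, K = resp.shape
    if n != y.size:
        raise ValueError("posterior field does not match the volume's masked voxels")
    if var_floor is None:
        var_floor = default_var_floor(y)
    alpha = resp.sum(axis=0)
    weights = alpha / n
    means = np.zeros(K)
    variances = np.full(K, var_floor)
    for k in np.flatnonzero(alpha > 0):
        means[k] = resp[:, k] @ y / alpha[k]
        variances[k] = max(resp[:, k] @ (y - means[k]) ** 2 / alpha[k], var_floor)
    empty = np.flatnonzero(alpha <= 0)
    if empty.size:
        # Reseed collapsed components at the least-explained intensity.
        log.warning("reseeding %d empty mixture component(s)", empty.size)
        coverage = resp.sum(axis=1)
        for k in empty:
            means[k] = y[int(np.argmin(coverage))]
            variances[k] = max(np.var(y), var_floor)
            weights[k] = 1.0 / K
        weights = weights / weights.sum()
    return MixtureModel.from_arrays(weights, means, variances)


def default_var_floor(y: np.ndarray) -> float:
    """Variance floor: a small fraction of the global intensity variance."""
    gv = float(np.var(y))
    return max(1e-4 * gv, 1e-12)


def log_likelihood(volume: Volume, model: MixtureModel) -> float:
    """Total mixture log-likelihood over masked voxels."""
    return float(logsumexp(_log_densities(volume.brain_values, model), axis=1).sum())


@dataclass
class EMResult:
    model: MixtureModel
    posteriors: PosteriorField
    converged: bool
    n_iter: int
    loglik_trace: List[float] = field(default_factory=list)


def fit_em(
    volume: Volume,
    init: MixtureModel,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> EMResult:
    """Fit the mixture by plain EM until the relative log-likelihood change < tol.

    The log-likelihood trace is recorded each iteration; EM theory guarantees
    it is non-decreasing (up to the variance-floor projection).  The returned
    model is sorted by ascending mean so component k maps onto tissue class k+1.
    """
    volume.require_brain()
    var_floor = default_var_floor(volume.brain_values)
    model = init.sorted_by_mean()
    trace: List[float] = []
    converged = False
    post = e_step(volume, model)
    it = 0
    for it in range(1, max_iter + 1):
        model = m_step(volume, post, var_floor=var_floor)
        ll = log_likelihood(volume, model)
        trace.append(ll)
        if len(trace) > 1:
            denom = max(abs(trace[-2]), 1.0)
            if abs(trace[-1] - trace[-2]) / denom < tol:
                converged = True
                post = e_step(volume, model)
                break
        post = e_step(volume, model)
    model = model.sorted_by_mean()
    post = e_step(volume, model)
    if not converged:
        log.info("EM stopped at max_iter=%d without meeting tol=%g", max_iter, tol)
    return EMResult(model, post, converged, it, trace)


def classify(post: PosteriorField) -> LabelMap:
    """MAP labels: 1 + argmax_k posterior; ties go to the lower class index."""
    if post.indices is None or post.shape is None:
        raise ValueError("posterior field carries no spatial placement")
    labels = np.zeros(int(np.prod(post.shape)), dtype=np.int64)
    labels[post.indices] = 1 + np.argmax(post.values, axis=1)
    return LabelMap(labels.reshape(post.shape))


# ---------------------------------------------------------------------------
# Fuzzy c-means on 1D intensities
# ---------------------------------------------------------------------------

@dataclass
class FCMResult:
    centers: np.ndarray
    memberships: np.ndarray
    objective_trace: List[float]
    degenerate: bool = False


def fcm_fit(
    intensities: Sequence[float],
    K: int,
    m: float = 2.0,
    max_iter: int = 100,
    tol: float = 1e-4,
) -> FCMResult:
    """Fuzzy c-means clustering of scalar intensities.

    Memberships follow u_ik = 1 / sum_j (d_ik / d_ij)^(2/(m-1)) and centers are
    the u^m-weighted means.  Centers initialize at evenly spaced quantiles of
    the data, which makes the fit deterministic, and are returned ascending.
    Inputs with fewer than K distinct values are flagged degenerate; duplicate
    centers are spread slightly so the iteration stays defined.
    """
    y = np.asarray(intensities, dtype=float).ravel()
    if y.size == 0:
        raise ValueError("fcm_fit needs at least one intensity")
    if m <= 1:
        raise ValueError("fuzzifier m must exceed 1")
    uniq = np.unique(y)
    degenerate = uniq.size < K
    qs = (2.0 * np.arange(K) + 1.0) / (2.0 * K)
    centers = np.quantile(y, qs)
    if degenerate or np.unique(centers).size < K:
        spread = max(np.ptp(y), 1.0)
        centers = centers + np.linspace(0.0, 1e-6 * spread * (K - 1), K)
    expo = 2.0 / (m - 1.0)
    trace: List[float] = []
    u = np.zeros((y.size, K))
    for _ in range(max_iter):
        d = np.abs(y[:, None] - centers[None, :])
        zero = d < 1e-12
        with np.errstate(divide="ignore", invalid="ignore"):
            inv = d ** (-expo)
            u = inv / inv.sum(axis=1, keepdims=True)
        rows_zero = zero.any(axis=1)
        if rows_zero.any():
            # A point sitting exactly on a center belongs to it crisply
            # (split evenly if several centers coincide with it).
            u[rows_zero] = zero[rows_zero] / zero[rows_zero].sum(axis=1, keepdims=True)
        um = u**m
        trace.append(float((um * d**2).sum()))
        new_centers = um.T @ y / np.maximum(um.sum(axis=0), 1e-300)
        shift = float(np.max(np.abs(new_centers - centers)))
        centers = new_centers
        if shift < tol:
            break
    order = np.argsort(centers, kind="stable")
    return FCMResult(centers[order], u[:, order], trace, degenerate)


def init_from_fcm(values: np.ndarray, K: int = 3) -> MixtureModel:
    """Initial mixture from FCM: hard-assigned cluster fractions, means, variances."""
    y = np.asarray(values, dtype=float).ravel()
    res = fcm_fit(y, K)
    hard = np.argmax(res.memberships, axis=1)
    floor = default_var_floor(y)
    weights, means, variances = [], [], []
    for k in range(K):
        sel = y[hard == k]
        if sel.size == 0:
            weights.append(1.0 / y.size)
            means.append(float(res.centers[k]))
            variances.append(max(float(np.var(y)), floor))
        else:
            weights.append(sel.size / y.size)
            means.append(float(sel.mean()))
            variances.append(max(float(sel.var()), floor))
    w = np.asarray(weights)
    return MixtureModel.from_arrays(w / w.sum(), means, variances).sorted_by_mean()
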