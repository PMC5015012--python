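"""Independent brute-force reference implementations used as test oracles.

Everything here is written as plain Python loops over voxels, deliberately
sharing no code with the package, so agreement is meaningful.
"""

import math

import numpy as np


def normal_pdf(y, mean, var):
    return math.exp(-((y - mean) ** 2) / (2 * var)) / math.sqrt(2 * math.pi * var)


def posterior_rows(y_values, weights, means, variances):
    """Mixture responsibilities, one scalar loop per voxel and class."""
    K = len(weights)
    out = np.zeros((len(y_values), K))
    for i, y in enumerate(y_values):
        dens = [weights[k] * normal_pdf(y, means[k], variances[k]) for k in range(K)]
        total = sum(dens)
        for k in range(K):
            out[i, k] = dens[k] / total
    return out


def weighted_moments(y_values, responsibilities):
    """M-step parameters from responsibility-weighted moments."""
    y = np.asarray(y_values, dtype=float)
    resp = np.asarray(responsibilities, dtype=float)
    n, K = resp.shape
    weights, means, variances = [], [], []
    for k in range(K):
        a = resp[:, k].sum()
        mu = float((resp[:, k] * y).sum() / a)
        var = float((resp[:, k] * (y - mu) ** 2).sum() / a)
        weights.append(a / n)
        means.append(mu)
        variances.append(var)
    return np.array(weights), np.array(means), np.array(variances)


def gauss_kernel(p, r, ndim):
    """Unit-mass Gaussian kernel over patch offsets, dict offset -> weight."""
    from itertools import product

    offs = list(product(*([range(-p, p + 1)] * ndim)))
    raw = {o: math.exp(-sum(a * a for a in o) / (2 * r * r)) for o in offs}
    total = sum(raw.values())
    return {o: v / total for o, v in raw.items()}


def _pixel(img, idx):
    """Edge-replicated lookup."""
    clamped = tuple(min(max(a, 0), n - 1) for a, n in zip(idx, img.shape))
    return float(img[clamped])


def patch_dist(img, i, j, p, r):
    """Gaussian-weighted squared patch distance with edge replication."""
    kern = gauss_kernel(p, r, img.ndim)
    total = 0.0
    for off, g in kern.items():
        a = _pixel(img, tuple(x + o for x, o in zip(i, off)))
        b = _pixel(img, tuple(x + o for x, o in zip(j, off)))
        total += g * (a - b) ** 2
    return total


def nonlocal_weight_row(img, mask, i, p, r, h, search_radius=None):
    """Normalized weights W(i, .) over all masked voxels (or a window),
    with the max-neighbour self-weight rule.  Returns dict j -> weight."""
    from itertools import product

    idxs = [j for j in product(*[range(n) for n in img.shape]) if mask[j]]
    if search_radius is not None:
        idxs = [
            j for j in idxs
            if all(abs(a - b) <= search_radius for a, b in zip(i, j))
        ]
    raw = {}
    for j in idxs:
        if j == i:
            continue
        raw[j] = math.exp(-patch_dist(img, i, j, p, r) / (h * h))
    raw[i] = max(raw.values()) if raw else 1.0
    total = sum(raw.values())
    return {j: w / total for j, w in raw.items()}


def smooth_all_pairs(img, mask, post_map, p, r, h, search_radius=None):
    """Eq-by-eq nonlocal smoothing of a (K, *shape) posterior map."""
    K = post_map.shape[0]
    out = np.zeros_like(post_map)
    from itertools import product

    for i in product(*[range(n) for n in img.shape]):
        if not mask[i]:
            continue
        row = nonlocal_weight_row(img, mask, i, p, r, h, search_radius)
        for k in range(K):
            out[(k,) + i] = sum(w * post_map[(k,) + j] for j, w in row.items())
    return out


def fuse_vector(y, models, p_kj):
    """Likelihood-weighted fusion of posterior columns, scalar loops.

    ``models``: list of (weights, means, vars) triples; ``p_kj``: (J, K).
    """
    J = len(models)
    K = len(models[0][1])
    fused = []
    for k in range(K):
        dens = [normal_pdf(y, models[j][1][k], models[j][2][k]) for j in range(J)]
        total = sum(dens)
        if total == 0:
            w = [1.0 / J] * J
        else:
            w = [d / total for d in dens]
        fused.append(sum(w[j] * p_kj[j][k] for j in range(J)))
    return np.array(fused)


def jaccard_sets(pred, truth, cls):
    a = {tuple(idx) for idx in np.argwhere(pred == cls)}
    b = {tuple(idx) for idx in np.argwhere(truth == cls)}
    if not a and not b:
        return 1.0
    return len(a & b) / len(a | b)
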