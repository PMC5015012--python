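"""Synthetic brain-like phantoms with known tissue labels, bias, and noise.

The forward model of an MR magnitude image is

    Y_i = X_i * B_i + N_i

where X is the piecewise-constant true tissue signal, B a smooth,
slowly varying multiplicative bias field, and N additive noise.  The phantom
emulates the conventions of simulated-MRI repositories: the *noise level* is
a percentage of the brightest tissue mean (5% with means up to 180 gives
noise sd 9.0), and the *INU level* is the percentage width of the bias range
(40% gives a field spanning [0.8, 1.2]).

Geometry: an elliptical brain with an outer CSF rim, a folded gray-matter
ribbon, a white-matter core, and ventricle-like interior CSF pockets — each
tissue holds at least 5% of the brain so a K=3 fit is well posed globally.
Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import ndimage

from .types import CSF, GM, WM, LabelMap, Volume


@dataclass
class PhantomSpec:
    """Parameters of one simulated image."""

    shape: Tuple[int, ...] = (128, 128)
    tissue_means: Tuple[float, float, float] = (50.0, 110.0, 180.0)
    noise_level: float = 0.0
    inu_level: float = 0.0
    noise_model: str = "gaussian"
    bias_model: str = "polynomial"
    seed: int = 0

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        if len(self.shape) not in (2, 3):
            raise ValueError("phantoms are 2D or 3D")
        m = self.tissue_means
        if not (m[0] < m[1] < m[2]):
            raise ValueError("tissue means must be strictly increasing (CSF < GM < WM)")
        if self.noise_level < 0 or self.inu_level < 0:
            raise ValueError("noise and INU levels are percentages >= 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        if self.bias_model not in ("polynomial", "gaussian-blobs"):
            raise ValueError(f"unknown bias model {self.bias_model!r}")


@dataclass
class Phantom:
    """One simulated image with its ground truth."""

    truth: LabelMap
    intensity: Volume
    bias: np.ndarray
    clean: np.ndarray
    spec: PhantomSpec


def _normalized_coords(shape: Tuple[int, ...]):
    """Per-axis coordinates scaled to [-1, 1]."""
    axes = [np.linspace(-1.0, 1.0, n) for n in shape]
    return np.meshgrid(*axes, indexing="ij")


def make_geometry(shape: Tuple[int, ...], seed: int = 0) -> LabelMap:
    """Deterministic brain-like label geometry (0/1/2/3 codes).

    Nested structure: elliptical brain boundary, CSF rim, gray-matter ribbon
    whose inner boundary folds sinusoidally, white-matter core, and two
    ventricle-like CSF pockets.  Every tissue occupies >= 5% of the brain.
    """
    shape = tuple(int(s) for s in shape)
    if any(s < 32 for s in shape):
        raise ValueError("phantom geometry needs at least 32 voxels per axis")
    rng = np.random.default_rng(seed)
    ndim = len(shape)
    coords = _normalized_coords(shape)
    semi = [0.90 * (1.0 + 0.04 * (rng.random() - 0.5)) for _ in range(ndim)]
    rho2 = sum((c / s) ** 2 for c, s in zip(coords, semi))
    rho = np.sqrt(rho2)
    theta = np.arctan2(coords[1], coords[0])
    phase1, phase2, phase3 = rng.uniform(0, 2 * np.pi, size=3)
    # Deep gyral folding: the GM/WM boundary swings widely so white matter
    # reaches close to the rim everywhere, as in real cortex.
    fold = 0.10 * np.sin(9 * theta + phase1) + 0.05 * np.sin(4 * theta + phase2)
    if ndim == 3:
        fold = fold * np.cos(coords[2] * np.pi / 2)
    gm_outer = 0.88 + 0.015 * np.sin(5 * theta + phase3)
    wm_outer = 0.66 + fold

    labels = np.zeros(shape, dtype=np.int64)
    brain = rho <= 1.0
    labels[brain] = CSF
    labels[brain & (rho <= gm_outer)] = GM
    labels[brain & (rho <= wm_outer)] = WM

    # Deep gray structures (basal-ganglia/thalamus-like) flanking the midline,
    # so central regions contain GM as in real anatomy.
    g_off = 0.30 + 0.04 * rng.random()
    g_semi = [0.14, 0.17] + ([0.20] if ndim == 3 else [])
    for sign in (-1.0, 1.0):
        centre = [0.10, sign * g_off] + [0.0] * (ndim - 2)
        d2 = sum(((c - cc) / vs) ** 2 for c, cc, vs in zip(coords, centre, g_semi))
        labels[(d2 <= 1.0) & (labels == WM)] = GM

    # Ventricle-like CSF pockets near the centre, mirrored across the midline.
    offset = 0.16 + 0.04 * rng.random()
    v_semi = [0.12] + [0.24] + ([0.18] if ndim == 3 else [])
    for sign in (-1.0, 1.0):
        centre = [sign * offset] + [0.0] * (ndim - 1)
        d2 = sum(((c - cc) / vs) ** 2 for c, cc, vs in zip(coords, centre, v_semi))
        labels[(d2 <= 1.0) & brain] = CSF
    return LabelMap(labels)


def make_bias(
    shape: Tuple[int, ...],
    inu_level: float,
    model: str = "polynomial",
    seed: int = 0,
) -> np.ndarray:
    """Smooth positive multiplicative field spanning [1 - L/200, 1 + L/200].

    ``polynomial`` draws a random order-2 polynomial in the normalized
    coordinates; ``gaussian-blobs`` sums 2-4 wide Gaussians (sd >= 1/4 of the
    extent).  Either raw field is mildly blurred and then rescaled exactly to
    the target range, so an INU level of 0 returns a field of ones.
    """
    shape = tuple(int(s) for s in shape)
    if inu_level == 0:
        return np.ones(shape)
    rng = np.random.default_rng(seed)
    coords = _normalized_coords(shape)
    if model == "polynomial":
        raw = np.zeros(shape)
        for c in coords:
            raw += rng.uniform(-1, 1) * c + rng.uniform(-1, 1) * c**2
        for a in range(len(coords)):
            for b in range(a + 1, len(coords)):
                raw += rng.uniform(-1, 1) * coords[a] * coords[b]
        if np.ptp(raw) < 1e-9:
            raw = coords[0].copy()
    elif model == "gaussian-blobs":
        raw = np.zeros(shape)
        for _ in range(rng.integers(2, 5)):
            centre = rng.uniform(-0.8, 0.8, size=len(shape))
            width = rng.uniform(0.5, 1.0)  # sd in [-1,1] units; >= 1/4 extent
            d2 = sum((c - cc) ** 2 for c, cc in zip(coords, centre))
            raw += rng.choice([-1.0, 1.0]) * np.exp(-d2 / (2 * width**2))
    else:
        raise ValueError(f"unknown bias model {model!r}")
    raw = ndimage.gaussian_filter(raw, sigma=min(shape) / 12.0, mode="nearest")
    lo, hi = 1.0 - inu_level / 200.0, 1.0 + inu_level / 200.0
    rmin, rmax = float(raw.min()), float(raw.max())
    return lo + (raw - rmin) * (hi - lo) / (rmax - rmin)


def simulate(spec: PhantomSpec) -> Phantom:
    """Draw one phantom: truth, bias, clean signal, and noisy intensities."""
    seeds = np.random.SeedSequence(spec.seed).spawn(3)
    geom_seed = int(seeds[0].generate_state(1)[0] % (2**31))
    bias_seed = int(seeds[1].generate_state(1)[0] % (2**31))
    truth = make_geometry(spec.shape, seed=geom_seed)
    bias = make_bias(spec.shape, spec.inu_level, spec.bias_model, seed=bias_seed)
    means = np.array((0.0,) + tuple(spec.tissue_means))
    X = means[truth.labels]
    brain = truth.labels > 0
    if spec.inu_level > 0:
        # The INU level describes the field over the brain (its mean is ~1
        # there, as in simulated-MRI bias fields); re-span the smooth field so
        # the brain sees exactly [1 - L/200, 1 + L/200].
        lo, hi = 1.0 - spec.inu_level / 200.0, 1.0 + spec.inu_level / 200.0
        bmin, bmax = float(bias[brain].min()), float(bias[brain].max())
        bias = lo + (bias - bmin) * (hi - lo) / (bmax - bmin)
    clean = np.where(brain, X * bias, 0.0)
    sd = spec.noise_level / 100.0 * max(spec.tissue_means)
    rng = np.random.default_rng(seeds[2])
    if sd == 0:
        Y = clean.copy()
    elif spec.noise_model == "gaussian":
        Y = clean + np.where(brain, rng.normal(0.0, sd, spec.shape), 0.0)
    else:  # rician magnitude noise
        n1 = rng.normal(0.0, sd, spec.shape)
        n2 = rng.normal(0.0, sd, spec.shape)
        Y = np.where(brain, np.sqrt((clean + n1) ** 2 + n2**2), 0.0)
    volume = Volume(data=Y, mask=brain)
    return Phantom(truth=truth, intensity=volume, bias=bias, clean=clean, spec=spec)
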