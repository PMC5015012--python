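# mngmm — multigrid nonlocal Gaussian mixture segmentation of brain MRI

`mngmm` classifies the voxels of a skull-stripped T1-weighted brain MR image
into cerebrospinal fluid (CSF), gray matter (GM), and white matter (WM).  It
is aimed at the two artifacts that defeat plain intensity clustering:

- **noise**, which flips per-voxel class posteriors independently, and
- **intensity inhomogeneity** (the smooth multiplicative "bias field" B in
  the observed-signal model `Y = X·B + N`), which moves the absolute
  intensity of a tissue across the field of view until class histograms
  overlap.

## Method

Tissue intensities are modelled as a K = 3 Gaussian mixture
`p(y) = Σ_k π_k N(y; μ_k, σ²_k)` fitted by EM, with components ordered by
mean (CSF < GM < WM) and voxels assigned by maximum posterior.  Two layers
make this robust:

1. **Nonlocal posterior adaptation.**  Converged posteriors are replaced by
   patch-similarity-weighted averages,
   `NLp(k|y_i) = Σ_j W(i,j) p(k|y_j)` with
   `W(i,j) ∝ exp(−‖Δ_i − Δ_j‖²_{2,r}/h²)`,
   where Δ are intensity patches around the voxels.  Voxels vote with their
   self-similar neighbourhood, which cancels noise without blurring edges.
2. **Adaptive multigrid + fusion.**  The brain bounding box is tiled into
   6 × 6 cells; cells are greedily merged into patches that each contain all
   three tissues (scored by the *inner distance*
   `min(|C_CSF−C_GM|, |C_WM−C_GM|)` of per-region fuzzy-c-means centers —
   near zero when a class is missing).  A mixture is fitted inside every
   patch, where the smooth bias field is locally near-constant.  Per-voxel
   posteriors from the home patch and the patches bordering the voxel's cell
   are then blended with class-likelihood weights,
   `fused_k = Σ_j [N(y;θ_{k,j}) / Σ_l N(y;θ_{k,l})] · p_{k,j}`,
   which keeps labels spatially continuous across patch borders.

A deterministic synthetic phantom generator (three-tissue brain-like
geometry, BrainWeb-style noise/INU percentage conventions) and Jaccard
evaluation utilities make the whole pipeline testable without any external
data.  See `docs/methods.md` for the full model description and the design
rationale.

## Worked example

Simulate a 96×96 phantom with 5% noise and a 60% bias field, segment it, and
score the result against the known truth:

```bash
mngmm simulate --shape 96x96 --noise 5 --inu 60 --seed 7 \
      --out ph.nii.gz --out-truth truth.nii.gz
# phantom written to ph.nii.gz (5820 brain voxels)

mngmm segment ph.nii.gz --out-labels seg.nii.gz
# segmented: CSF=1722, GM=2226, WM=1872 voxels over 10 patches

mngmm evaluate --pred seg.nii.gz --truth truth.nii.gz
# JS CSF: 0.9971
# JS GM: 0.9969
# JS WM: 0.9989
# JS mean: 0.9976
```

The Jaccard similarity (JS) of a tissue is |pred ∩ truth| / |pred ∪ truth|
over its voxel sets — 1.0 is a perfect match.  Under the same degradation a
plain (single, whole-image) Gaussian mixture scores 0.92/0.87/0.90 for
CSF/GM/WM on this image: the bias field pushes bright GM toward dark WM, and
only the local fits recover the separation cleanly.  The gap widens with the
bias level — at 80% INU and 9% noise the plain mixture falls to ~0.6–0.77
per class while the multigrid model stays above 0.89 (see the test suite's
sweeps).

The same operations are available as a library:

```python
from mngmm import PhantomSpec, simulate, segment_mngmm, evaluate

phantom = simulate(PhantomSpec(shape=(128, 128), noise_level=9, inu_level=80, seed=1))
result = segment_mngmm(phantom.intensity)        # SegmentationResult
print(evaluate(result.labels, phantom.truth).as_dict())
```

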