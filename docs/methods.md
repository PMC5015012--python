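# Methods

`mngmm` segments skull-stripped T1-weighted brain MR images into
cerebrospinal fluid (CSF), gray matter (GM), and white matter (WM).  The two
artifacts it is built to withstand are additive acquisition noise and the
smooth multiplicative bias field ("intensity inhomogeneity", INU) left by
coil imperfections.  The forward model of the observed image is

    Y_i = X_i * B_i + N_i

with X the piecewise-constant tissue signal, B the bias field, and N noise.
The pipeline never estimates B explicitly; it relies on B being locally
near-constant.

## Intensity mixture model

Brain intensities are modelled as a K = 3 Gaussian mixture
p(y) = Σ_k π_k N(y; μ_k, σ²_k), fitted by EM over the masked voxels only.
Components are kept in ascending-mean order, which maps them deterministically
onto CSF < GM < WM (the T1 ordering).  Choices that matter:

- **Initialization.** Fuzzy c-means (fuzzifier m = 2, quantile-seeded centers,
  hence fully deterministic) clusters the 1D intensities; initial means are
  the FCM centers, weights the hard-assignment fractions, variances the
  within-cluster variances.
- **Variance floor** of 1e-4 × the global masked-intensity variance keeps
  components from collapsing onto single intensities (noise-free synthetic
  images have exactly three distinct values).
- **Stopping**: relative log-likelihood change below 1e-6, at most 100
  iterations; non-convergence returns the current state with a flag rather
  than raising.  The log-likelihood trace is recorded; plain EM ascent is a
  tested invariant.
- **Empty components** (zero responsibility mass) are reseeded at the
  least-explained observed intensity with global variance and weight 1/K.
- Posterior underflow at a voxel (all component densities zero in double
  precision) yields a uniform 1/K row, never NaN; the E-step works in log
  space throughout.

## Nonlocal posterior adaptation

Noise flips per-voxel posteriors independently.  Nonlocal-means weighting
repairs them with the redundancy of the image: for voxels i, j the weight

    W(i, j) ∝ exp( −‖Δ_i − Δ_j‖²_{2,r} / h² )

compares the (2p+1)^d intensity patches Δ around the two voxels under a
unit-mass Gaussian kernel of sd r, and the posterior of i is replaced by the
W-weighted average of the posteriors in its search window (rows remain
distributions because the weights are a convex combination).  Parameters, all
exposed on `NonlocalConfig`:

- patch radius p = 1 (3×3 patches in 2D), kernel sd r = 1.0 voxel;
- search window half-width 5 (the literal sum over all N pixels is O(N²);
  the exponential decay makes distant weights negligible, so the window
  restriction is the standard nonlocal-means practice);
- self-weight W(i, i) set to the largest neighbour weight before
  normalization, the classic rule that stops the centre voxel from dominating
  its own average (an isolated voxel keeps weight 1);
- borders: patches use edge replication, windows are clipped to the image and
  the mask.

**Decay parameter h.**  With a unit-mass patch kernel, the expected patch
distance between two same-tissue patches under noise sd σ is 2σ², with
fluctuations of order σ², while a structural intensity difference Δ adds
Δ²·(kernel mass on the differing pixels).  Setting h = σ therefore keeps
same-tissue weights of order one and suppresses cross-edge weights by
exp(−Δ²m/σ²) ≪ 1 at every noise level tested; constant offsets in the
distances cancel in the normalization, so h alone controls selectivity.  The
default is h = 1.0 × σ̂, where σ̂ is estimated from the median absolute
deviation of the Laplacian residual inside the (eroded) mask — robust to the
sparse large residuals at tissue edges.  On noise-free images σ̂ ≈ 0 and h
falls back to 1e-3 of the intensity range, making the adaptation a
near-identity there.

**Where the adaptation is applied.**  `fit_ngmm` runs plain EM to convergence
and adapts the converged posteriors once, before MAP classification.  An
earlier design applied the adaptation to every E-step before the M-step; that
variant is unstable: the row-normalized averaging does not conserve per-class
responsibility mass, so at high noise the thin GM ribbon loses mass every
iteration and the CSF/GM components drift together until the middle class
vanishes.  Keeping the parameter estimation to guaranteed-ascent EM and using
the nonlocal weighting purely as a posterior regularizer is stable at all
tested noise levels and preserves the noiseless-image identity with the plain
fit.

## Adaptive multigrid

A smooth bias field is locally near-constant, so mixtures fitted inside small
regions are insensitive to it — provided each region contains substantial
amounts of all three tissues.  The bounding box of the brain is tiled into
N × N cells (N = 6 by default; N × N × N for volumes, axis 0 treated as the
slice axis).  Cells with under 5% brain voxels are marked non-brain.  Every
region is scored by its **inner distance**

    min(|C_CSF − C_GM|, |C_WM − C_GM|)

of its three FCM centers; a region missing a tissue class collapses two
centers and scores near zero (regions with fewer than three distinct
intensities score exactly zero).  The merge then repeatedly seeds a patch at
the worst unlabeled cell and grows it N_search times by the adjacent
unlabeled cell whose absorption maximizes the combined inner distance,
subject to the patch bounding box staying within half the brain extent per
axis.  Left-over single-cell patches are absorbed into the adjacent patch
with the largest combined inner distance (this clean-up may exceed the
half-extent bound by up to one cell; it is logged).  The growth budget is
tied to the data size, N_search = floor(α·N_brain/N_grid) with α = 0.1 and
N_grid the voxel count of a full cell, clamped to at least 1.

Determinism: cell adjacency is face adjacency (4-neighbourhood in 2D, 6 in
3D); ties in worst-cell selection break by row-major cell order, ties in best
absorption by larger brain-voxel count then row-major order.  The merge is a
pure function of the image.

## Per-patch fits and fusion

Each patch gets its own nonlocally-adapted mixture fit, initialized from the
patch's pooled FCM centers, with the nonlocal windows clipped to the patch so
patch fits are mutually independent.  Class identities correspond across
patches by ascending component mean.  A patch whose nonlocal fit fails falls
back to a plain EM fit (logged).

Independent patch fits can disagree along patch borders.  For a voxel i with
home posterior p_{k,0} and neighbouring patch models θ_1..θ_N, the fused
posterior per class k is the likelihood-weighted blend

    fused_k = Σ_j [ N(y_i; θ_{k,j}) / Σ_l N(y_i; θ_{k,l}) ] · p_{k,j}

where the blending weight of model j is its class-k component density at y_i
(mixing weights excluded) and p_{k,j} for j ≥ 1 is the Eq-style posterior of
y_i under model j.  The fused value is a convex combination per class; with
no neighbours it reduces exactly to the home posterior.  The fused vector is
*not* renormalized before the argmax (the blend defines no normalization);
the exported posterior maps are renormalized for convenience only.

**Fusion locality.**  Neighbours are the patches bordering the voxel's grid
*cell*, not its whole patch.  The discontinuities fusion exists to repair
live along cell borders; a model fitted two patches away — under a different
bias level — carries no information about a voxel deep inside a foreign
patch, and letting it vote there measurably corrupts interior labels under
strong bias.  Voxels in cells surrounded by their own patch therefore keep
their home posterior untouched.

Masked voxels that fall inside cells classified as non-brain (possible
because the non-brain rule is a 5% threshold, not exact emptiness) receive
the model of the nearest patch and are classified without fusion.

## Synthetic phantoms

The generator emulates simulated-brain-MR conventions so that noise/INU
levels quoted as percentages mean the same thing here as in the public
simulators:

- **Geometry**: elliptical brain, outer CSF rim, a GM ribbon whose inner
  boundary folds deeply (0.10·sin 9θ + 0.05·sin 4θ in normalized radius) so
  WM approaches the rim as gyri do, ventricle-like CSF pockets, and two deep
  GM structures (basal-ganglia-like) flanking the midline.  The folding depth
  and deep GM are not cosmetic: they give the phantom the property — shared
  by real anatomy — that any compact region of a few grid cells contains all
  three tissues, which is the operating assumption of the multigrid stage.
  Every tissue holds ≥ 5% of the brain; the brain is a single connected
  component; everything is deterministic in the seed.
- **Bias field**: a random order-2 polynomial (or a sum of 2–4 wide
  Gaussians), mildly blurred, rescaled to [1 − L/200, 1 + L/200] — so
  INU 40% spans [0.8, 1.2] and INU 0 is exactly 1.  `simulate` re-spans the
  field over the *brain* voxels, because the INU percentage describes the
  inhomogeneity of the brain data (the field has mean ≈ 1 over the brain in
  the public simulators); rescaling over the whole image would leave the
  brain an arbitrary sub-range — a global dimming that silently raises the
  effective noise percentage.
- **Noise**: Gaussian with sd = level% × the brightest tissue mean (the
  simulator convention: 5% with means 50/110/180 gives sd 9.0), applied
  inside the brain only; a Rician option (magnitude of a complex Gaussian)
  exists because MR magnitude noise is Rician, but Gaussian is the default so
  moment-based checks are exact.
- Default tissue means 50/110/180 give CSF–GM and GM–WM gaps of 60 and 70
  intensity units, a T1-like contrast.

What the phantom does **not** emulate: real cortical topology, partial-volume
voxels (every voxel is pure tissue), spatially correlated noise, pulse
sequences, or the skull (inputs are assumed skull-stripped).  Passing on
phantoms therefore demonstrates robustness to noise and smooth multiplicative
bias on brain-like three-tissue geometry, not performance on clinical data.

## Evaluation

Per-class Jaccard similarity |pred ∩ truth| / |pred ∪ truth| over the voxel
sets of each tissue, background excluded; an empty union counts as 1.
`evaluate` also returns a 4 × 4 confusion matrix over voxels that are
non-background in either map, and `evaluate_batch` emits a per-image CSV
with a mean ± sd summary row.

## Problem sizes and test conditions

The built-in experiments run 128 × 128 phantoms with five seeds per
condition: a noise sweep {3, 5, 7, 9}% at 80% INU and an INU sweep
{0, 20, 40, 80, 100}% at 3% noise (the sweep needs some noise — a noise-free
phantom has only three distinct intensities and makes variance estimation
degenerate; 3% is mild and realistic).  At this size the default grid yields
~25–30 brain cells of roughly 19 px and N_search = 2–3.  A full segmentation
takes well under a second; the complete suite runs in about half a minute.

## Known limitations

- The nonlocal weight stack is precomputed per volume
  ((2s+1)^d − 1 arrays of image size); 3D volumes with the default search
  radius 5 are memory-hungry, and the constructor refuses stacks beyond ~2 GB
  — reduce `search_radius` for large volumes.
- The merge recomputes FCM on pooled intensities for every candidate
  absorption; cost grows with N⁴-ish in cell count but is negligible at the
  default N = 6.
- Patches elongated along one axis can still span a sizeable bias range;
  fusion mitigates but does not remove the resulting boundary errors.
- K is fixed at 3; pathology (lesions, tumours) violates the model.
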