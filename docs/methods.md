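# Methods

`dwisr` restores high-resolution diffusion-weighted MRI (DWI) from
low-resolution acquisitions with a small 3-D convolutional network, and
quantifies the result both with volumetric image-quality indices and through
its downstream effect on generalized q-sampling imaging (GQI) fiber maps.
This note records the models, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## The restoration model

**Task framing.** Training pairs are manufactured from high-resolution
volumes: each gradient volume is degraded by factor-3 block averaging, then
restored to the original grid by interpolation, and the network learns the
mapping from that interpolated (blurred) image back to the original.  At
prediction time a genuinely low-resolution volume is interpolated up by 3 and
passed through the network.  Source and target of every pair therefore share
a grid, so the network never changes dimensions.

**Architecture.** Three 3-D convolution layers with kernel edges 9, 3, 5 and
channel widths 32, 16, 1; ReLU between layers, a linear output layer, and
zero "same" padding throughout.  A residual path averages the final feature
map with the interpolated input:

    out = (1 - w) * x + w * f(x),        w = 0.5 by default.

The residual weight is exposed (`SRCNNSpec.residual_weight`) because other
weightings are conceivable; `w = 0` returns the interpolated image
unchanged.  Weights initialize from a zero-mean Gaussian of scale 1e-3
(`init_scale`), biases at zero.  With near-zero weights the whole pipeline
degenerates gracefully: `f ≈ 0`, the output is half the input, and the final
range renormalization maps it back onto the interpolated baseline — so an
untrained model predicts exactly the interpolation baseline, and training
can only move away from it by reducing the loss.

Convolutions are evaluated in plain numpy as GEMMs over sliding windows; the
backward pass reuses the same primitive with channel-transposed, spatially
flipped kernels, and is verified against finite differences and a
nested-loop direct convolution.  Inputs smaller than the largest kernel edge
are accepted (zero padding keeps the operation well-defined) with a warning
that the receptive field is then dominated by padding.

**Training.** Optimizer is AdaGrad (per-parameter accumulated squared
gradient, `step = lr * g / sqrt(acc + eps)`, `eps = 1e-8`, zero initial
accumulator), learning rate 5e-4, batch size fixed at 1, loss the mean (not
sum) squared error over voxels so differently sized volumes contribute
comparably.  Data are split into three per-shell groups — {b=0, 1000},
{1500}, {2000} s/mm² — and one model is trained per group, because signal
level and contrast change strongly with diffusion weighting; the unweighted
b=0 volumes ride along with the closest shell.  Pairs are presented subject
by subject, with subject order and within-subject gradient order reshuffled
each epoch from the run seed.  The loss is logged every iteration and
aggregated per subject; model state is checkpointed every
`checkpoint_interval` iterations (default 5000) and at the end.

**Loss curves.** Single-pair losses fluctuate with whichever volume happened
to be presented (b=0 volumes are several times brighter than b=2000
volumes in the merged group), so reported initial/final losses are epoch
means of the per-subject aggregated loss — the stable curve that training
drives down — with the raw per-iteration series retained in the log.

**Checkpoint selection.** Each checkpoint is evaluated on held-out data with
PSNR, SSIM and cosine similarity.  The selected checkpoint maximizes the
product (avg PSNR / best checkpoint-average PSNR) x (avg SSIM) x
(avg cosine); the PSNR factor of the best checkpoint is exactly 1, and ties
break toward the earlier checkpoint.

## Resolution operators

* **Downsampling** is block averaging over factor³ cubes (anti-aliased;
  decimation would alias and would break the exactness of the
  constant-volume cycle).  Dimensions must divide by the factor; training
  zero-pads targets first (zeros are background in brain DWI).
* **Interpolation** (nearest / trilinear / tricubic, default tricubic as the
  conventional baseline) uses voxel-center alignment — output center i
  samples input coordinate (i + 1/2)/factor − 1/2 — with edge replication,
  so constants are reproduced exactly and no extrapolation occurs.  With
  this alignment, output site 3j+1 falls exactly on source site j.
* **Range renormalization** after every resolution change maps an image
  linearly so its min/max equal a reference's exactly (interpolation shrinks
  dynamic range).  In training the reference is the high-resolution target;
  at prediction time the target is unknown, so the network output is
  renormalized against the interpolated source's range (a flag switches to
  the low-resolution original's range instead).  A constant image cannot be
  stretched and is returned at the reference minimum with a warning.

## Image-quality metrics

* **PSNR** = 10·log10(Imax²/MSE) dB, with Imax the reference maximum for
  floating-point data ("auto") or 2^bit−1 when a bit depth is declared.
  Identical images report +inf and are excluded from averages with a
  warning.
* **SSIM** is the global single-window form: luminance, contrast and
  structure factors from whole-volume statistics with C1 = (0.01 L)²,
  C2 = (0.03 L)², C3 = C2/2.  Variances use the population (1/N) convention
  for bit-reproducibility.  The "auto" dynamic range is the maximum over
  *both* images so the index stays symmetric.  A sliding-window variant
  exists behind a flag for comparison and plays no role in the pipeline.
* **Cosine similarity** over flattened voxels; two all-zero images count as
  identical (1, with a warning).
* **Histograms** use half-open bins with the last bin closed and clip values
  into the terminal bins so counts always conserve the voxel total.

## GQI reconstruction

The spin distribution function is evaluated per voxel over a
subdivided-icosahedron hemisphere (level 3 = 321 antipodally unique
directions; level L keeps (10·4^L + 2)/2 of the icosphere's vertices):

    psi(u) = sum_i S_i * sinc( sigma * sqrt(6 D b_i) * (g_i . u) )

with sinc(t) = sin(t)/t, sampling-length ratio sigma = 1.25 and free-water
diffusivity D = 3.0e-3 mm²/s, both exposed in `GQISpec`.  The kernel is even
in u, so one hemisphere suffices; edges of the tessellation crossing the
equator are remapped through the antipode so peak finding sees the closed
sphere.  Negative SDF samples — possible because the sinc kernel
oscillates — are clamped to zero before any index is computed, since the SDF
estimates a nonnegative spin density.

Indices per voxel (n directions): GFA = sqrt(n·Σ(psi−mean)² /
((n−1)·Σpsi²)), which is 0 for a flat SDF and exactly 1 for a one-hot SDF;
ISO = min psi; QA = strongest-peak value − ISO (0 where no strict local
maximum exists, e.g. a constant SDF); NQA = QA normalized by the masked
volume's maximum QA.  QA carries no further scaling — all normalization
lives in NQA.  Peaks are directions whose psi strictly exceeds every
adjacent direction's, ordered by value.

## The phantom generator

Real multi-shell brain DWI of the kind this pipeline targets is not freely
distributable, so validation uses multi-tensor phantoms with known ground
truth.  Defaults (all overridable):

* **Grid** 24 x 24 x 12 voxels of 3.4 x 3.4 x 4.0 mm (dimensions divisible
  by 3 so the degrade/restore cycle is exact).
* **Gradient table**: one b=0 plus the 6 icosahedral vertex axes at each of
  b = 1000/1500/2000 s/mm² — 19 entries, a desk-scale rendering of a
  four-shell, 193-direction protocol; denser tables (e.g. 21 directions per
  shell) are used where angular resolution matters and full-size tables are
  accepted.
* **Geometry**: two orthogonal straight bundles crossing at the in-plane
  center of the lower z slab, plus a CSF-like ellipsoid centered in-plane
  but shifted into the slab above.  Region priority is CSF > bundles (in
  listed order) > background; voxels claimed by two or more bundles get an
  equal-fraction two-tensor mixture.  The CSF ellipsoid is deliberately kept
  off the crossing so both features coexist.
* **Tissue model**: axially symmetric tensors with fiber axial/radial
  diffusivities 1.7e-3 / 0.3e-3 mm²/s and isotropic CSF 3.0e-3 mm²/s
  (standard adult-brain values); baseline intensity s0 = 100 with the CSF
  baseline 3x brighter (`csf_s0_factor`), reflecting CSF's long-T2
  hyperintensity on unweighted images — this brightness is what makes
  ventricles stand out in ISO maps, and without it the phantom would invert
  that contrast.
* **Noise**: Rician, sqrt((s+n1)² + n2²) with i.i.d. Gaussian n1, n2 of
  scale sigma (default 2% of s0), seeded and bit-reproducible.

A deliberate property of the two-tensor crossing: the *signal* profile of a
90° crossing has its minima on the bisectors (the sum of two exponentials is
convex in cos²θ), not along the bundles — the bundle directions are only
recoverable as ODF peaks.  The tests assert exactly this.

What the phantom does **not** emulate: anatomy, partial-volume gradients at
tissue boundaries, susceptibility/eddy artifacts, spatially varying noise,
or non-Gaussian diffusion.  Passing the phantom study shows the pipeline's
machinery is correct and that learning-based restoration beats interpolation
under these controlled conditions; it does not quantify performance on
clinical data.

## The scaled study

The shipped experiment (`run_experiment`, also what `scripts/acceptance.py`
reruns) uses 12 phantom subjects at 24 x 24 x 12 with 19 gradient entries
and 2% Rician noise, an 11:1 subject-level train/test split (subject-level,
never gradient-level, to avoid leakage), and 6 epochs per b-value group —
at most 462 batch-1 iterations per model, a problem size chosen so the whole
study runs in minutes on one CPU.  Under these conditions the network's
held-out mean PSNR and SSIM exceed the tricubic baseline and all three
epoch-mean loss curves decline; margins are reported by the acceptance
script rather than claimed here.

## Known limitations

* The AdaGrad/batch-1 loop is sequential by construction; wall-clock scales
  linearly with iterations x voxels.
* Global SSIM summarizes an entire volume in one window; it is the form used
  for evaluation here but is less sensitive to local structure than the
  sliding-window variant (available behind a flag).
* QA is unscaled apart from ISO subtraction; absolute QA values are
  comparable within a reconstruction, NQA across subjects.
* Prediction renormalizes against the interpolated source's range; if the
  true high-resolution range differs substantially from the low-resolution
  range, intensities inherit that bias.
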