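# Methods

This note records the model as implemented, the parameters that matter,
the design decisions taken where the design was genuinely open, and what
the synthetic benchmark does and does not demonstrate.

## Compute core

The package runs on its own reverse-mode automatic-differentiation tape
over numpy arrays (`stripmamba.tensor`). Feature maps are channel-last
`(B, H, W, C)`. Convolutions are expressed as sums of k² shifted
matmuls; bilinear resizing as fixed row/column interpolation matrices
(half-pixel-centre convention, so constants are preserved exactly); the
selective-scan recurrence and its adjoint are numba-compiled sequential
kernels (an associative parallel scan is deliberately out of scope at
desk scale). Gradient correctness is established in the test-suite by
central finite differences against every primitive and through whole
blocks.

## Selective state-space core

The recurrence per inner channel e and state s is

    h_t = exp(Δ_t[e]·A[e,s]) · h_{t−1} + Δ_t[e]·B_t[s]·x_t[e]
    y_t[e] = Σ_s C_t[s]·h_t[e,s] + D[e]·x_t[e],   h_0 = 0.

Decisions:

* **Discretisation** — zero-order hold on A with the simplified Euler
  rule for B (`Ā = exp(ΔA)`, `B̄ = Δ·B`), the standard convention for
  selective SSMs.
* **Positivity** — the softplus positivity transform is applied to Δ;
  D remains an unconstrained per-channel skip coefficient. (Reading the
  temporal-scaling role of the softplus as belonging to Δ is the only
  interpretation consistent with D's role as a skip connection.) The
  softplus output is floored at 1e−20 because IEEE arithmetic underflows
  softplus to exactly 0 below ≈ −87, which would violate the strict
  positivity contract.
* **A initialisation** — diagonal per (channel, state) pair, initialised
  to −(1..d_state) (S4D-real style); Δ biases start log-uniform in
  [1e−3, 1e−1].
* **Block layout** — LayerNorm → joint linear projection into an x-path
  and a z-path (width `expand·d_model` each) → per direction: causal
  depthwise 1-D convolution (kernel 4, left padding) + SiLU + scan →
  each direction multiplied by SiLU(z) → summed → output projection →
  residual add. The backward direction reverses token order, scans, and
  reverses back; forward/backward parameter sets are independent.
* **Defaults** — d_state 16, expansion 2, conv kernel 4.

With all learned weights zero the block is exactly the identity; with
backward parameters tied to forward ones it commutes with full sequence
reversal. Both are asserted in tests, as is equivalence with a naive
step-by-step recurrence on random instances.

## Vision Mamba encoder stage

Each pyramid stage tokenises its own feature map at patch size P = 1
(pixel tokens; inter-stage downsampling is handled by the backbone), in
row-major order — also the forward scan order; the 2-D→1-D ordering is
a free choice and is fixed here once. The positional table is owned per
stage at the stage's fixed resolution and zero-initialised, so at depth
0 it is the only source of spatial asymmetry. General P is supported
(flatten P²C → project to D); non-divisible extents are reflect-padded
and cropped after merging. The class-token path of the classification
formulation exists behind a flag but is dropped in segmentation mode.

## Cross Shape Transformer

Attention inside non-overlapping bands: horizontal strips are `sw`
consecutive rows, vertical strips `sw` consecutive columns. Heads are
split half/half between the two orientations with per-head dimension
d_k = C/K; softmax scaling 1/√d_k; no relative position bias inside
strips and no directional bias. Extents not divisible by `sw` are
zero-padded, padded keys are masked out of the softmax (−1e9 additive
bias), and outputs cropped; a configured `sw` larger than an extent
clamps to the extent (the full-attention limit). The block is the
standard pre-norm pair: `X̂ = CSA(LN(X)) + X`, `X' = MLP(LN(X̂)) + X̂`
with a two-layer GELU MLP of width `mlp_ratio·C`.

Default `sw = 3` (the accuracy optimum reported for this architecture
family); head counts per stage (2, 4, 8, 8, 16), chosen even, dividing
each C_i.

## MTM fusion

The module input is `X = W_fuse·concat(E_T, E_M)` (pointwise 2C→C);
this reconciles the module's stated C-channel input with its drawn 2C
concatenation. Directional mean-pooling gives Z_h (per row) and Z_w
(per column); for the square maps of this backbone they are
concatenated along channels, passed through four linear(2C→C/2)+GELU
branches, re-concatenated to 2C, split into a row half and a column
half, and combined as the per-channel outer product
`O[h,w,c] = O_row[h,c]·O_col[w,c]` — every channel slice of O has rank
≤ 1 by construction. The map is applied as a sigmoid-gated residual
`X·σ(O) + X`, chosen so zero-initialised attention starts near the
identity; `gate_enabled=False` removes the attention path entirely,
giving the ablation baseline. A non-square fallback concatenates the
pooled profiles along the length axis instead; it is exercised only off
the square default path. The row/column naming of the two halves is a
convention fixed here once (first C channels index rows).

## Backbone

Five stages at resolutions input/2^i with channels (32, 64, 128, 256,
512); the uniform half-size notation of the source description is read
as a per-stage halving pyramid, the only reading consistent with a
U-shaped decoder. Each of the three streams (CST, VME, DWConv) consumes
its **own** previous-stage output through its own bilinear-downsample +
pointwise projection — fusion happens only in MTM and the decoder. The
auxiliary stream is depthwise 3×3 + pointwise 1×1 + LayerNorm + SiLU.
The decoder walks deepest-to-shallowest; each level concatenates
(fused, upsampled previous decoder map, auxiliary map) — the deepest
level has no previous decoder input — through two 3×3 conv + LayerNorm
+ SiLU layers, then a 1×1 head and a final bilinear upsample to the
input size. The head emits one logit channel (binary task); a
multi-channel head is available via `out_channels`. Normalisation is
LayerNorm throughout: batch-size independent, deterministic, and
stable at the small batch sizes used at desk scale.

## Config reference: the calibrated default

`ModelConfig()` ships the configuration whose 256×256 budget reproduces
the printed figures for this architecture (102.2 M parameters,
135.1 GFLOPs):

| field | value |
|---|---|
| channels | (32, 64, 128, 256, 512) |
| depths (CST = VME) | (50, 3, 4, 4, 11) |
| heads | (2, 4, 8, 8, 16) |
| sw | 3 |
| mlp_ratio | 4 |
| d_state / expand / conv kernel | 16 / 2 / 4 |
| FLOP convention | 2 FLOPs per MAC |

Calibration procedure: per-stage per-block parameter and MAC costs were
measured with the profiler (block costs are exactly additive), then an
integer search over depth schedules selected the schedule above, which
lands at 102.0 M parameters and 134.9 GFLOPs. Two structural facts force
the shape of this schedule: under the halving pyramid, N_i·C_i² is
constant across stages, so every block costs ≈ 0.2–0.6 GMAC regardless
of stage, while parameters per block grow with C_i² — hence the budget
pins a deep cheap-channel first stage (FLOPs knob) together with a deep
wide fifth stage (parameter knob). MAC counting covers the dense
linear-algebra work — projections, attention score/value products,
convolutions, interpolation matrices, and the scan recurrence (≈ 4·S+1
MACs per step-channel) — and excludes normalisation and activation
arithmetic; with a MAC counted as 2 FLOPs the budget matches under this
convention.

The profiler measures, not estimates: parameters are enumerated from
the instantiated model and MACs accumulated by the tape during one real
forward pass.

## Loss and metrics

BCE is computed in the stable logit form `mean(softplus(z) − g·z)`;
probabilities supplied directly are clamped to [1e−7, 1−1e−7]. Dice
loss uses smoothing ε = 1. Defaults α = β = 1. Predictions are
binarised at 0.5 before metrics. mIoU follows the 2-class semantic
convention (mean of foreground and background IoU), with foreground-only
IoU reported alongside since conventions differ; both-empty cases score
1.0 by explicit definition.

## Synthetic data

The generator emulates the stated difficulty of endoscopic polyp
imagery: single connected lesions built from ellipses with low-order
Fourier radius modulation (3–6 harmonics, amplitudes ≤ 0.25/n),
morphologically closed; backgrounds are three-octave smoothed noise
(correlation length 12 px, amplitude 0.08) tinted to a mucosal palette
with a mild vignette; the lesion adds `contrast` (default 0.25) through
a boundary softened by a Gaussian of `boundary_blur_sigma` (default
2 px) **after** the mask is rasterised, so the ground truth stays crisp
while the image boundary is ambiguous. Area fractions default to
0.03–0.20 of the image, 1–2 lesions per image. Generation is a pure
function of (config, seed); masks are stored as {0, 255} 8-bit PNG and
the directory layout is Kvasir-SEG-compatible, so real data drops in
unchanged.

What the generator does **not** model: specular highlights, instrument
shadows, fluid and debris, perspective deformation of the lumen, and
real texture statistics. Passing the synthetic training tests therefore
demonstrates that the architecture, gradients, optimiser and pipeline
are correct and that the model can learn weak-contrast blurred-boundary
segmentation — not that it reaches clinical-benchmark accuracy.

## Training

Adam (β = 0.9/0.999), base lr 1e−4, polynomial decay
`lr·(1 − t/T)^0.9`, 5000 iterations at batch 8, inputs resized to
384×384 and standardised per channel per image — the reference recipe.
Augmentation order: joint random flips (p = 0.5 each axis), photometric
distortion on the image only (brightness ± 0.2, contrast × [0.8, 1.25],
saturation × [0.8, 1.25] — magnitudes are declared defaults, exposed in
config), reflect padding to the target extent (mask zero-padded), and a
random affine warp (rotation ≤ 10°, scale [0.9, 1.1], shear ≤ 5°) with
nearest-neighbour mask resampling so masks stay binary. No train/val
split or early stopping; best-checkpoint selection by train-set Dice
exists as an off-by-default convenience. A non-finite loss aborts with
a diagnostic.

Desk-scale smoke scenarios (used by the tests and examples) shrink the
model to channels (8, 16, 32, 64, 128) with one block per stage at
64×64 input, train 300 iterations at batch 4, and use lr 1e−3 — the
short-schedule scaling of the base rate, chosen a priori as standard
for tiny-model quick convergence — with augmentation off, since the
object under test is the learnability of the generator's conditions.
Problem sizes throughout the suite (sequence lengths ≤ 64 for scan
oracles, 8×8 grids for attention oracles, 50-image training sets) are
the package's chosen desk-scale study conditions.

## Numerical choices and degenerate inputs

* float32 parameters and activations; float64 in oracle tests.
* Softmax stabilised by subtracting a detached row max.
* LayerNorm ε = 1e−5; Adam ε = 1e−8.
* Bilinear matrices are row-stochastic; 1-pixel sources broadcast.
  Halving a 1-pixel extent is rejected (the downsample contract), but
  upsampling from 1×1 is allowed (the 32-px tiny model's deepest stage).
* `zero_all_parameters` zeroes *every* array including norm scales;
  all residual blocks then reduce to the identity exactly, which the
  identity tests rely on.
* Checkpoints are self-describing npz containers (config JSON + weights
  + seed + iteration) and refuse foreign files.

## Known limitations

* The sequential scan is O(L) per direction with a compiled inner loop;
  fine at desk scale, not competitive with fused GPU kernels.
* The calibrated default (a 50-block first stage) reproduces the
  printed budget but is not a schedule one would choose for accuracy;
  it exists to make the profiling contract concrete and testable.
* Non-square feature maps take the fallback MTM path, which is less
  principled than the square-map channel concatenation.
* Training at the full 384×384 reference scale is functional but slow
  on one CPU core; the package's tested envelope is the smoke scale.
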