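# stripmamba

Dual-encoder binary segmentation of polyp-like lesions in endoscopy-style
images, runnable end to end on a CPU with no external data.

Colorectal polyps are protruding mucosal lesions whose automatic
delineation is hard for exactly the reasons this package's synthetic
generator emulates: lesions vary widely in size, their boundaries are
blurred, and their contrast against the surrounding mucosa is weak. The
network combines three complementary encoders in a five-stage U-shaped
pyramid:

* **Cross Shape Transformer (CST)** — pre-norm transformer blocks whose
  attention is restricted to non-overlapping horizontal and vertical
  strips of width `sw` (default 3): of the `K` heads, heads `1..K/2`
  attend within row bands and heads `K/2+1..K` within column bands, so
  each position sees a cross-shaped receptive field at cost linear in
  `sw` instead of quadratic in the grid.
* **Vision Mamba Encoder (VME)** — pixel tokens in row-major order run
  through bidirectional selective state-space blocks: the linear
  recurrence `h_t = Ā_t h_{t−1} + B̄_t x_t`, `y_t = C_t·h_t + D·x_t`
  with input-dependent `B_t, C_t, Δ_t` (zero-order hold: `Ā = exp(ΔA)`,
  `B̄ = Δ·B`), scanned forward and backward with independent parameters
  and merged through a SiLU gate.
* **Depthwise-separable auxiliary stream** — a lightweight convolutional
  branch supplying locality bias to the decoder.

At every stage the CST and VME maps are fused by a
**Mamba-Transformer-Merge (MTM)** module in the coordinate-attention
style: directional average pooling, four fully-connected reduction
branches, and a per-channel rank-1 attention map
`O[h,w,c] = O_row[h,c]·O_col[w,c]` applied as a sigmoid-gated residual.
The decoder concatenates, per level, the fused map, the upsampled
previous decoder output and the auxiliary map through two 3×3
conv+norm+SiLU layers, ending in a 1×1 head that emits logits.

Training uses the combined objective
`L = α·L_BCE + β·L_Dice` with `α = β = 1`, Adam at base learning rate
1e-4 under a polynomial schedule `lr·(1−t/T)^0.9`, and evaluation
reports Dice, mIoU, Precision and Recall.

Everything — the network, reverse-mode autodiff, the compiled selective
scan, the optimiser — is implemented in this package on numpy + numba;
see `docs/methods.md` for the model account and design decisions.

## Worked example

```bash
python examples/04_train_smoke.py
```

generates 50 synthetic 64×64 image/mask pairs, trains the width-reduced
configuration (channels 8–128, one block per stage) for 300 iterations,
and prints:

```
dataset: 50 pairs, mean lesion area 16.2%
  iter   0  loss 1.2675  lr 9.97e-04
  iter  49  loss 0.3551  lr 8.49e-04
  iter  99  loss 0.2657  lr 6.94e-04
  iter 149  loss 0.1965  lr 5.36e-04
  iter 199  loss 0.1834  lr 3.72e-04
  iter 249  loss 0.1629  lr 1.99e-04
  iter 299  loss 0.1742  lr 0.00e+00
train-set Dice after 300 iterations: 0.971
```

The starting loss ≈ 1.27 is what an uninformed predictor scores
(ln 2 ≈ 0.69 from BCE at chance plus a Dice term near 0.6); the final
Dice of 0.97 means the model segments the lesions it was trained on
almost pixel-perfectly. The other examples demonstrate the synthetic
generator (`01`), the selective-scan recurrence against a naive loop
(`02`), the full-attention limit of strip attention (`03`), and the
profiler (`05`).

A command-line interface covers the same surface:

```bash
stripmamba synth --out data/demo --n 50 --size 64 --seed 0
stripmamba train --data data/demo --out runs/demo --seed 0
stripmamba evaluate --checkpoint runs/demo/checkpoint.npz --data data/demo
stripmamba profile --input-size 256
```

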