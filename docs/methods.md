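# Methods

`partialscan` implements the Partial-Scan approach to speeding up
scanning ion conductance microscopy (SICM): skip a chosen subset of
slow-axis scan lines during acquisition, then reconstruct the skipped
lines computationally.  This note documents the models, the synthetic
data they are exercised on, the numerical choices, and the limits of
what the desk-scale experiments show.

## Acquisition model

A raster scan of `m` lines is described by a *line mask* — a boolean
keep/skip vector with exactly `round_half_up(p·m)` skipped lines for a
requested masked fraction `p`.  The first and last lines are always
scanned: they anchor both the interpolation baseline and the inpainting
boundary (rounding and border rules are this package's conventions; the
counts are what every downstream module relies on).

Mask families: `random` (uniform over interior lines), `random_limited`
(uniform, redrawn until no run of consecutive skips exceeds
`max_consecutive`, default 5 — long runs lose too much local
information), and deterministic controlled patterns `fixed_distance`
(maximally even single skips), `geometric` (gaps growing geometrically,
ratio 1.3 by default) and `block` (contiguous runs of a given length).
The controlled-pattern definitions are local to this package; published
instruments name these ideas but not their exact logic.

The slow-axis (Y) waveform dwells one line period per scanned line and,
across a run of `k` skipped lines, ramps through `k+1` line pitches
within a single line period — a steeper slope rather than a step, which
avoids exciting piezo creep.  Acquisition time is modelled as
proportional to the scanned-line fraction: the time saving equals the
masked fraction.  The worked example (full scan 19 min 19 s, `p` = 0.30)
gives 811 s = 13 min 31 s; the model intentionally uses the requested
fraction `p`, not the rounded line count (which would give 810 s for a
256-line frame), because the fraction is what the instrument is
configured with.  A count-based variant is available behind a flag.

Partial acquisition of a normalized height map copies scanned rows
bit-exactly and writes the placeholder 0 into skipped rows.

## Synthetic scenes

No SICM frames are distributed with the package, so a generator emulates
the relevant morphology of cultured-cell topography (fibroblast-like
cells, melanoma, neuroblastoma, neurons):

| ingredient | default | rationale |
|---|---|---|
| image size | 96 × 96 px | desk-scale stand-in for 256 × 256 frames |
| cell bodies | 3 per frame, heights 1–5 µm, radii 10–28 px | micrometre-scale somata with steep edges |
| ridges | 6 per frame, heights 0.1–0.4 µm, widths 1–2.5 px | neurite/filopodium-like fine structure |
| background tilt | ≤ 0.004 µm/px | residual sample tilt |
| texture | 0.04 µm band-limited | membrane roughness |
| line-offset noise | 0.02 µm SD per row | SICM acquires line by line; each row carries its own offset |
| pixel noise | 0.01 µm SD | current/feedback noise |

Bodies are Gaussian bumps with integer-pixel centres (so the sampled
peak amplitude is attained exactly); ridges are Gaussian-smoothed random
walks.  Scenes are deterministic per seed; datasets derive per-scene
sub-seeds with a counter scheme (`seed·1000003 + index`), so extending a
dataset never reshuffles existing scenes.

Scars — feedback-overshoot line artifacts — are planted as whole-row
(or row-segment) offsets of 0.3–1 µm with random sign, on *raw* (µm)
maps, since they are acquisition artifacts that precede normalization.
The planted mask is exact ground truth.

What the generator does **not** emulate: pipette-geometry convolution,
hopping-mode feedback dynamics, sample drift between frames, and any
quantitative morphology statistics of a specific cell line.  Passing
tests on these scenes therefore demonstrate the pipeline's mechanics and
the relative ordering of reconstruction methods under realistic noise,
not absolute performance on instrument data.

## Reconstruction models

Two U-Net-style encoder–decoders share one architecture: per encoder
stage a 3×3 convolution, ReLU, dropout (20%) and 2×2 max-pooling; a
bottleneck convolution; per decoder stage nearest-neighbour upsampling,
a skip concatenation and a convolution; a final 1-channel head.  The
production configuration follows the 64→512 filter ladder at 256 × 256;
the desk-scale studies use (8, 16, 32) at 96 × 96 (about 42k
parameters), chosen so the full study trains in minutes on one CPU core.

**Partial convolutions.**  In the mask-aware model every convolution
multiplies its input window by the binary validity mask, rescales by
(window size / valid-pixel count), applies the bias only at valid
positions, and outputs an updated mask (valid where the window held any
valid pixel).  The mask is max-pooled alongside the encoder, upsampled
in the decoder, and merged with the skip branch's mask by element-wise
maximum.  Border rule: out-of-image padding counts as *valid*, so a
partial convolution under an all-ones mask is exactly a plain
convolution — this makes the weight-shared equivalence between the two
architectures an exact oracle rather than an approximate one.  (The
common alternative — padding counts as invalid — renormalizes border
windows and would break that identity at the frame edge.)

**Residual head with interpolation shortcut.**  The network output is
`shortcut + correction`, where the correction is the final convolution's
output (zero-initialized) and the shortcut is the model's own effective
input: for the partial CNN, the mask-aware per-column linear
interpolation of the masked image; for the plain CNN — which by design
receives only the masked image, with no mask channel — the zero-filled
input itself.  An untrained partial CNN therefore already reconstructs
at the interpolation-baseline level and training refines from there,
while the plain CNN's convolution path must supply hole heights on its
own.  This is the standard residual-over-baseline construction of
super-resolution networks, and it is what makes CPU-scale training
meaningful: learning full-image regression from scratch to
interpolation-level fidelity (SSIM ≈ 0.992) is out of reach in minutes
of CPU time.  With an all-ones mask both shortcuts reduce to the
identity, preserving the equivalence oracle.  The head is linear, with
clipping to [0, 1] applied outside training (a sigmoid head was measured
to converge an order of magnitude slower for precise height
regression).

**Loss.**  `L = α·(1 − mean SSIM) + (1 − α)·MSE` with α = 0.96 (α is
the loss mixing weight; 5·10⁻⁴ is the optimizer step size — the two are
distinct hyperparameters).  The differentiable SSIM uses an 11-pixel
uniform window, valid-region mean, sample covariance and C₁ = 0.01²,
C₂ = 0.03² on unit-normalized data, and is algorithmically identical to
the metric module's SSIM (tested to agree with scikit-image to 10⁻⁶).

**Training.**  Adam (lr 5·10⁻⁴), batch 16, K-fold cross-validation
(each fold restarts from the initial weights; the best validation-loss
weights across folds are kept).  Each image receives a fresh random
line mask per epoch with masked fraction drawn from [0.30, 0.35] — mask
augmentation substitutes for dataset size.  Validation masks are fixed
per fold so epoch-to-epoch losses are comparable for early stopping
(patience on the best validation loss).  The desk-scale study trains on
random 48 × 48 crops of the 96 × 96 scenes (line masks are drawn on the
crop), evaluates on full frames, and uses 2 folds and ≤ 25 epochs:
about 90 s per model on one core.  Everything is float64 except the
network stack, which runs in float32 for throughput; training is
bit-deterministic per seed on a fixed BLAS.

**Reconstruction** composites by default: scanned rows are copied
verbatim from the acquired data (reconstruction never alters
measurements — enforced bit-exactly), skipped rows take the clipped
network prediction.  Raw network output is available via
`composite=False`.

**Baselines.**  Per-column linear interpolation along the slow axis
(requires scanned border rows), and median line correction: each
flagged row is replaced by the per-column median of its nearest `k`
clean rows above and below (default `k` = 1, i.e. the two-neighbour
midpoint — the classic SPM line correction).

## Measured desk-scale behaviour

On the frozen study (200 training scenes, 20 held-out, p = 0.30): the
trained partial CNN exceeds linear interpolation by ≈ 0.1–0.2 dB PSNR
and ≈ 1–5·10⁻⁵ SSIM — small margins, because the synthetic scenes are
smooth enough that column-wise interpolation is already near the noise
floor — while the plain CNN lands far below both (≈ 33–35 dB) and
misestimates hole heights by ≈ 13% on average where the partial CNN
stays within 2%: the mask-aware model's anchored holes, not raw
capacity, are what carry the ordering.  These orderings were checked at
two scene seeds, two evaluation mask seeds and two training lengths
before the study configuration was frozen.

## Quality metrics

MSE over all pixels; PSNR = 10·log₁₀(MAX²/MSE) with MAX = 1 for
normalized maps and a +∞ sentinel at MSE = 0; SSIM as above (window 7
by default, matching the reference implementation's default); Pearson
correlation over flattened pixels (undefined for constant images);
Canny edge density (edge pixels / total pixels, σ = 1.0, hysteresis
0.1/0.2 — the comparisons that use it are relative, so only consistency
matters); frequency-content ratio f_R/f_O = ratio of summed 2D spectral
magnitudes above a radial cutoff (default 0.25 of Nyquist, DC excluded)
— below 1 means lost detail, above 1 spurious detail.  "Frequency
content" has no standard definition in this context; the radial
high-pass sum is this package's, and the cutoff is configurable.

## Break-point analysis

Reconstruction quality versus masked fraction is swept (default grid
5%–90% in 5% steps, 3 replicate masks per point, mean ± SD) and fitted
with continuous 3-segment piecewise-linear least squares — hinge basis
`b₀ + b₁x + c₁(x−t₁)₊ + c₂(x−t₂)₊`, breakpoint pair located by grid
search (40-point grid over the interior) refined with Nelder–Mead.
Three segments, i.e. two break-points, mirror the primary/secondary
break-point narrative of partial-scan quality curves.  Noiseless
3-segment input is recovered to machine precision; under noise the
per-replicate estimates scatter (a statistical property of breakpoint
estimation, not an optimizer artifact), so the calibration check asserts
that the *mean* recovered break-point over 20 fixed-seed replicates
stays within ±0.03 of truth at noise SD = 5% of the curve range.
Collinear input yields near-zero slope changes and is flagged
non-identifiable.

## Scar detection and correction

Row-deviation detector with two complementary references per pixel: the
median of symmetric vertical pair averages (d = 1..3; slope-cancelling,
safe for narrow horizontal ridges) and a 9-row vertical median filter
(robust to clusters of up to ~4 adjacent scarred rows).  Each deviation
map is z-scored by its own global 1.4826·MAD scale; a pixel's score is
the minimum of the two, and a row is flagged when at least a quarter of
its pixels exceed z = 5.  On the study scenes with extensive scarring
(10 rows of 96) the detector reaches ≥ 0.99 row sensitivity at ≤ 1
false-positive row per image; the residual failure mode is clean rows
sandwiched between scars 1–2 rows away on both sides, where every
reference is partially polluted.

Correction: the extracted mask is fed to the trained partial CNN as an
inpainting mask (then compared in physical units after denormalization).
Under extensive scarring — where clusters force median correction to
bridge multi-row gaps — the mask-aware model yields lower MSE on the
scarred rows in ~90% of scenes; under sparse scarring single-row
midpoint correction is near-optimal and the two methods tie.

## Known limitations

- Margins over linear interpolation are small on the synthetic scenes;
  scenes with more fine structure (or instrument data) would separate
  the methods further, as would longer training at larger ladder sizes.
- The timing model is strictly proportional; per-hop retract dynamics
  are not modelled.
- The scar detector assumes scars are row-coherent offsets; tilted or
  partial-row artifacts reduce sensitivity (segment scars are planted by
  the generator but the detector flags whole rows).
- The autodiff stack is intentionally minimal (stride 1, 2×2 pooling,
  odd kernels) and single-threaded; it is not a general training
  framework.
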