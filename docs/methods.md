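# Methods

`sonocrack` screens single seeds for slight testa cracks from air-coupled
ultrasound A-scans. The chain is: waveform → variational mode decomposition
(VMD) → sample-entropy choice of the mode count → color-polyline image
encoding → lightweight vision-transformer classification. This note records
the models, the parameters that matter, and the design choices made where
the design was genuinely open.

## Synthetic echo model

No public corpus of per-seed air-coupled A-scans exists, so the package
ships a generator that emulates 400 kHz through-transmission tone-burst
echoes. A record is

    x[n] = Σ_k G_k · exp(−(n−n_k)²/(2σ²)) · exp(−β·max(0, n−n_k))
               · cos(2π f n / f_s + φ_k)  +  ε[n],

a direct pulse plus two multipath echoes (Gaussian envelopes of SD σ = 18
samples at sample indices 80/200/320, relative gains 1.0/0.45/0.2), each
with an independent uniform phase φ_k, digitised at f_s = 5 MHz for
L = 450 samples (90 µs). ε is white Gaussian noise with SD equal to 5% of
the clean peak. A crack changes the seed's stiffness and damping; the
generator encodes this as a carrier shift f: 400 → 350 kHz, a within-burst
damping increase β: 0.015 → β·2.5 per sample, and a transmitted-gain factor
0.7. A `separation` knob in [0, 1] scales all three deltas jointly; at 0 the
two classes are statistically identical.

The digitiser rate, record window and amplitude units of the original
instrument are not public; 5 MHz/450 samples were chosen so the record
covers a direct pulse and two echoes of a 50 mm-focus geometry. The crack
deltas were calibrated once, then frozen: per-signal min–max normalisation
in the encoder removes the gain cue and the random phases hide the carrier
from time-domain statistics, so the damping cue must carry most of the
class information through the image representation; the frozen values put
the default end-to-end task clearly above chance and clearly below perfect.
What passing tests show is therefore that the pipeline transmits
frequency/damping structure from waveform to image to classifier — not
that any particular accuracy would be obtained on real cottonseed.

## Variational mode decomposition

`vmd_decompose` minimises the summed analytic-signal bandwidth of M modes
subject to reconstruction, by ADMM sweeps in the frequency domain:

    û_m ← (f̂ − Σ_{i≠m} û_i + λ̂/2) / (1 + 2α(ω − ω_m)²)       (Wiener update)
    ω_m ← ∫ ω|û_m|² dω / ∫ |û_m|² dω                           (power centroid)
    λ̂  ← λ̂ + τ(f̂ − Σ û_m)                                     (dual ascent)

until Σ_m ‖Δû_m‖²/‖û_m‖² < ε or `max_iter`. Numerical choices:

- **One-sided spectra.** Updates run on non-negative frequencies only;
  modes are the real part of the conjugate-symmetric inverse transform.
- **Boundary mirroring.** Half the signal is mirrored at each end before
  the transform and the centre section cropped after, suppressing edge
  ringing.
- **α = 1000 (default).** The Wiener denominator here carries 2α, so 1000
  matches the effective penalty of the widespread convention whose
  denominator carries α with a 2000 default. Larger α narrows modes but
  degrades reconstruction of leaky tones.
- **τ = 0 (default).** Dual ascent off — the robust choice under additive
  noise; exposed for exact-reconstruction experiments.
- **ε = 1e-7, max_iter = 500, ω initialised uniformly over (0, 0.5).**
  A "zero" initialisation is provided for reproduction experiments.
- A zero-power mode keeps its previous centre frequency; modes are returned
  sorted by ascending ω so downstream stacking is deterministic.

## Sample-entropy mode count

SampEn(z, r) = −ln(A/B), with B and A the counts of template pairs (i < j,
self-matches excluded) within Chebyshev tolerance r at embedding dimensions
z and z+1, both over the same L−z template starts. Defaults z = 2,
r = 0.2·SD of the analysed series — per-mode SD, so each mode is scored
scale-free. A constant series scores 0; if no (z+1)-matches exist the
sentinel +∞ is returned with a warning. The mode count M is chosen from
candidates {2,…,6} by the smallest arithmetic mean of the per-mode
entropies, ties toward the smaller M (cheaper decomposition). The mean was
chosen as the least-surprising reduction of per-mode entropies to one
number per M; it is config-exposed.

## Polyline encoding

The M modes of one signal are stacked into S ∈ R^{M×L}; column s_l holds
the M mode values at time l. On an 1800 × 1200 canvas with drawing origin
(288, 1010), band width W_S = 1224 and band top H_S = 190:

    x(m) = 288 + (m−1)·W_S/(M−1),
    y(l,m) = 1010 + (H_S − 1010)·(S_max − S_lm)/(S_max − S_min),

with S_max/S_min the matrix extrema (per-signal normalisation: scaling a
signal leaves its image unchanged). Each column becomes one polyline of
M vertices; colors cycle through a B = 10 palette (a 12-color master
palette serves color-count sweeps), so columns l and l+B share a color.
Coordinates round to the nearest pixel; lines are drawn 2 px wide without
anti-aliasing — determinism outweighs aesthetics. Later polylines
over-paint earlier ones.

W_S and H_S follow from symmetric margins (1800 − 2·288, 1200 − 1010),
since only the canvas and origin are fixed by the protocol. A shared
background is built by overlaying the standard encodings of 30 + 30
reserved signals (seeded random choice per class, each normalised on its
own); every remaining signal is drawn on a copy of it. With the reference
class sizes (296/304) this yields 266 intact and 274 crack images.

## Classifier

The network interleaves MobileNetV2 inverted-residual stages with
MobileViT blocks: local 3×3 conv → 1×1 projection to width d → unfold into
P = h·w patch positions × N patches → transformer (pre-norm, 2 heads,
scaled dot-product attention SoftMax(QKᵀ/√d_k)V) applied across the patch
axis independently per position → fold → 1×1 projection back → concat with
the block input → fusing 3×3 conv. Everything — layers, backprop, Adam —
is implemented in numpy inside the package; gradients of every primitive
are finite-difference-tested.

Two configurations are shipped:

- **Full-scale (`ViTConfig()` defaults):** 256 × 256 input, XXS-class
  channel plan (stem 16; MV2 16/24/48/64/80; transformer widths 64/80/96,
  depths 2/4/3; patch 2×2), batch 16, Adam 1e-3, 10 epochs,
  global-average-pool head. This mirrors the reference protocol.
- **Reduced (`small_vit_config()`, the pipeline default):** input cropped
  to the drawing band and resized to 32 × 32, a shorter plan (stem 16;
  MV2 24/24/32; transformer widths 48/64, depth 2), flatten head, Adam
  with a 5-epoch linear warmup to 2e-3 followed by cosine annealing over
  40 epochs total, and an averaged-probability ensemble of 3 restarts.
  These sizes keep one full pipeline run in CPU-minutes.

Three reduced-config choices deserve justification. The *flatten head*
replaces global average pooling because the class evidence in the polyline
braid sits at fixed canvas coordinates; pooling averages position away, and
pooled variants trained to chance while flatten variants learned reliably.
The *warmup* lets the run survive a higher peak learning rate, which
escapes the early-memorisation basins that otherwise trap a sizeable
fraction of runs. The *restart ensemble* addresses the remaining
optimisation variance: with ~430 training images a single small network's
held-out accuracy varies by ±0.1 across seeds; averaging the softmax of 3
independently initialised members recovers most of that spread. All are
config-exposed and off in the full-scale configuration.

Images are bilinear-resized, pixels scaled to [0, 1]; no augmentation.
Training is bit-reproducible for a fixed seed on one device (seed controls
init, shuffling and restart seeds).

## Pipeline, split and metrics

The stratified 80/20 split rounds each class's train count to the nearest
integer (ties up) under a seeded shuffle. Slight crack (label 0) is the
positive class for precision/recall/F1 — detection of cracks is the task —
with a flag to flip. Undefined ratios (zero denominator) are reported as
absent, never as zero. The master seed derives all stage seeds (data,
background reservation, split, training), so one integer reproduces a run;
metrics are printed Table-style as percentages to one decimal with full
precision kept in the JSON report.

To keep memory flat, the pipeline downsamples each encoded raster to the
classifier's input representation as it is produced; when an output
directory is requested the full raster is written to disk first, so both
paths train on identical inputs.

## Problem sizes used by the test suite

The suite validates the end-to-end accuracy property at the reference
dataset geometry (296 + 304 signals, 30 + 30 background, 80/20 split) with
the reduced classifier configuration, averaging 3 pipeline seeds; the
chance-level check at `separation = 0` uses 80 + 80 signals. Oracle checks
(sample entropy, Wiener update, centroid, coordinate mapping) run on
sequences of length ≤ 450 and 16–32-bin spectra.

## Known limitations

- The generator is a phenomenological echo model: no physical wave
  propagation, no seed-to-seed geometry variation beyond random phases and
  noise, no instrument drift. Results on it bound nothing about real seeds.
- VMD mode counts beyond ~L/4 are rejected; the decomposition is offline
  (no streaming) and 1-D.
- The encoder draws with integer-pixel polylines; sub-pixel geometry is
  deliberately discarded.
- The classifier runs on CPU via numpy; the full-scale configuration is
  provided for fidelity and small experiments rather than speed.
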