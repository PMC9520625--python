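# sonocrack

Non-destructive screening of single seeds for **slight testa cracks** from
**air-coupled ultrasound** A-scans.

A slight crack — a testa fissure without visible endosperm — barely changes
a seed's appearance, chemistry or temperature, so vision, spectroscopy and
thermal imaging miss it. It does change the seed's mechanical response: a
through-transmitted 400 kHz tone burst arrives with shifted frequency,
stronger damping and reduced intensity. `sonocrack` implements a complete
signal-to-decision chain on such A-scans:

1. **VMD** — variational mode decomposition of the waveform into M
   band-limited intrinsic mode functions (IMFs) by ADMM: Wiener-filter mode
   updates `û_m = (f̂ − Σ_{i≠m}û_i + λ̂/2)/(1 + 2α(ω−ω_m)²)`, power-centroid
   center-frequency updates, optional dual ascent.
2. **Sample entropy** — the mode count M is chosen from candidates 2–6 by
   the smallest mean SampEn(z=2, r=0.2·SD) of the modes,
   SampEn = −ln(A/B) with Chebyshev template matching.
3. **Sound-to-image encoding** — the M×L mode matrix S becomes L colored
   polylines on an 1800×1200 canvas: column l is a polyline through
   `x(m) = 288 + (m−1)·W_S/(M−1)`,
   `y(l,m) = 1010 + (H_S−1010)(S_max−S_lm)/(S_max−S_min)`, colors cycling
   with period B = 10; samples are drawn over a shared background built
   from 30+30 reserved signals.
4. **MobileViT-style classification** — a lightweight vision transformer
   (inverted-residual convolution stages interleaved with
   unfold–transformer–fold blocks, scaled dot-product attention
   `SoftMax(QKᵀ/√d_k)V`), trained with Adam on cross-entropy. The network,
   its backprop and the optimizer are implemented in numpy inside the
   package.

Since no per-seed ultrasound corpus is publicly deposited, the package
includes a first-class synthetic echo generator whose two classes differ in
carrier frequency, damping and intensity — the physical cues a crack
produces — with a `separation` knob that interpolates between
indistinguishable (0) and fully separated (1) classes.

It is aimed at researchers in acoustic seed phenotyping / non-destructive
testing who want a reproducible, dependency-light reference pipeline to
benchmark signal-to-image classification ideas against.

## Worked example

```python
from sonocrack import (EchoModelParams, SampEnConfig, generate_signal,
                       select_M)

record = generate_signal(1, EchoModelParams(), seed=1)   # intact seed
chosen, entropies = select_M(record.amplitudes, config=SampEnConfig(),
                             return_entropies=True)
print(chosen, {m: round(v, 3) for m, v in entropies.items()})
```

prints

```
2 {2: 0.483, 3: 0.524, 4: 0.566, 5: 0.57, 6: 0.549}
```

— the mean sample entropy of the IMFs is smallest at M = 2 for this
synthetic record (entropy selection depends on the record analysed; the
pipeline's standard configuration keeps M = 3 and exposes selection as an
optional stage). Running the full chain:

```python
from sonocrack import RunConfig, run_pipeline
report = run_pipeline(RunConfig(n_intact=80, n_crack=80,
                                n_background_per_class=10, seed=1))
print(report["metrics_percent"])
```

```
{'precision': '75.0%', 'recall': '85.7%', 'f1': '80.0%', 'accuracy': '78.6%'}
```

— on a deliberately small dataset (160 signals, 28 held-out images) the
classifier recovers most of the class structure from the encoded images;
precision/recall treat the slight-crack class as the positive detection
target. At the default full-scale geometry (296+304 signals) held-out
accuracy is substantially higher; at `separation=0` it falls to chance, as
it must.

A command-line interface mirrors the library:

```bash
sonocrack synth --n-intact 296 --n-crack 304 --out waves/
sonocrack select-m waves/intact_0000.csv
sonocrack encode waves/ --out images/
sonocrack pipeline --seed 1 --out run1/
```

`examples/` contains one short narrative script per capability.

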