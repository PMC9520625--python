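"""Sweep the number of encoding colors B and compare held-out accuracy.

All sweep rows reuse the same signals, background reservation, split and
training seed — rows differ only through the palette size, never the
polyline geometry.
"""

from sonocrack import RunConfig, sweep_colors

config = RunConfig(n_intact=60, n_crack=60, n_background_per_class=8, seed=2)
rows = sweep_colors([2, 6, 10], config)

print("colors  held-out accuracy")
for row in rows:
    print(f"  B={row['B']:<4d} {row['accuracy']:.3f}")
print("(the polyline geometry is identical across B; only colors change)")
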