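"""Encode decomposed waveforms into color-polyline images.

Each time index of the M x L mode matrix becomes one polyline of M
vertices; colors cycle with period B = 10. A shared background built
from reserved signals underlies every sample image.
"""

from pathlib import Path

from sonocrack import (
    EchoModelParams, EncoderConfig, VMDConfig, encode_dataset, generate_dataset,
)

records = generate_dataset(6, 6, EchoModelParams(), seed=3)
background, images = encode_dataset(
    records, VMDConfig(n_modes=3), EncoderConfig(),
    n_background_per_class=2, seed=4,
)

out = Path("scratch_example_images")
out.mkdir(exist_ok=True)
background.save(out / "background.png")
for image in images:
    image.save(out / f"{image.sample_id}.png")

print(f"canvas: {images[0].width} x {images[0].height} px")
print(f"background built from 2 + 2 reserved records")
print(f"encoded {len(images)} sample images "
      f"({sum(i.label == 1 for i in images)} intact, "
      f"{sum(i.label == 0 for i in images)} crack) to {out}/")
print("each image holds 450 polylines of 2 segments, colors cycling every 10")
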