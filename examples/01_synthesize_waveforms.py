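"""Generate a labelled synthetic A-scan dataset and write it as CSV files.

Each record mimics a 400 kHz through-transmission echo from one seed:
a direct tone burst plus two weaker multipath echoes. Slight-crack
seeds (label 0) carry a downshifted carrier, stronger damping and
reduced intensity.
"""

from pathlib import Path

import numpy as np

from sonocrack import EchoModelParams, generate_dataset, write_signal_csv

out = Path("scratch_example_dataset")
out.mkdir(exist_ok=True)

params = EchoModelParams()
records = generate_dataset(n_intact=20, n_crack=20, params=params, seed=1)
for record in records:
    write_signal_csv(record, out / f"{record.sample_id}.csv")

labels = [r.label for r in records]
energies = {
    label: np.mean([np.sum(r.amplitudes**2) for r in records if r.label == label])
    for label in (1, 0)
}
print(f"wrote {len(records)} records to {out}/")
print(f"intact records: {labels.count(1)}, slight-crack records: {labels.count(0)}")
print(f"mean energy  intact: {energies[1]:.3f}   crack: {energies[0]:.3f}")
print("(crack energy is lower: a crack dissipates and reflects part of the wave)")
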