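"""Decompose signals into band-limited modes with VMD.

First a controlled two-tone check — the recovered center frequencies
should sit at the known tone positions — then a synthetic seed echo.
"""

import numpy as np

from sonocrack import EchoModelParams, VMDConfig, generate_signal, vmd_decompose

# two known tones at normalized frequencies 0.06 and 0.20
n = np.arange(450)
x = np.cos(2 * np.pi * 0.06 * n) + np.cos(2 * np.pi * 0.20 * n)
result = vmd_decompose(x, VMDConfig(n_modes=2))
err = np.linalg.norm(result.reconstruction() - x) / np.linalg.norm(x)
print("two-tone check")
print(f"  center frequencies: {np.round(result.omegas, 4)}  (true: 0.06, 0.20)")
print(f"  relative reconstruction error: {err:.4f}")
print(f"  converged after {result.iterations} sweeps")

# a synthetic seed echo with measurement noise
record = generate_signal(1, EchoModelParams(), seed=1)
result = vmd_decompose(record.amplitudes, VMDConfig(n_modes=3))
fs = EchoModelParams().sample_rate
print("\nsynthetic intact-seed echo, M = 3")
print(f"  center frequencies (kHz): {np.round(result.omegas * fs / 1e3, 1)}")
print("  (the lowest mode captures the 400 kHz carrier band; the upper")
print("   modes collect the broadband measurement noise)")

# without noise all three modes chase the carrier band itself
clean = generate_signal(1, EchoModelParams(noise_sd=0.0), seed=1)
result = vmd_decompose(clean.amplitudes, VMDConfig(n_modes=3))
print("\nsame echo without noise")
print(f"  center frequencies (kHz): {np.round(result.omegas * fs / 1e3, 1)}")
print("  (all three modes now subdivide the carrier band)")
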