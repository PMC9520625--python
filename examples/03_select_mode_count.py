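"""Choose the VMD mode count M by minimum mean sample entropy.

Over-decomposition splits coherent bands and under-decomposition mixes
them; both raise the average irregularity of the modes.  The candidate
M with the smallest mean sample entropy is selected.
"""

from sonocrack import EchoModelParams, SampEnConfig, generate_signal, select_M

record = generate_signal(1, EchoModelParams(), seed=1)
config = SampEnConfig()  # z = 2, r = 0.2 * SD, candidates 2..6

chosen, entropies = select_M(record.amplitudes, config=config,
                             return_entropies=True)
print("mean sample entropy per candidate mode count:")
for m, value in entropies.items():
    marker = "  <-- selected" if m == chosen else ""
    print(f"  M = {m}: {value:.4f}{marker}")
print(f"\nselected M = {chosen} (smallest mean entropy, ties toward small M)")
print("the pipeline default keeps M = 3; entropy-based selection is the")
print("optional `select_mode_count` stage and depends on the record analysed")
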