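"""Generate a synthetic 78-line study cohort and peek at the planted truth.

The bundle carries everything downstream stages consume — raw panel
signals, log2 expression, mutation calls, tissue labels, CRISPR counts —
plus a truth record of every planted parameter.
"""

from bh3map import SimConfig, simulate_screen

config = SimConfig(seed=7)
bundle = simulate_screen(config)

print(f"cell lines: {config.n_cell_lines} across {len(config.tissues)} tissues")
print(f"panel rows: {len(bundle.viability_panel)} "
      f"(8 conditions x {config.replicates} replicates per line)")
print(f"expression matrix: {bundle.expression.shape[0]} genes x "
      f"{bundle.expression.shape[1]} lines")
print(f"CRISPR constructs: {len(bundle.crispr_counts)}")

line = bundle.tissue_labels.index[0]
dep = bundle.truth["true_dependency"][line]
print(f"\nplanted single-protein dependencies for {line}: "
      + ", ".join(f"{k}={v:.2f}" for k, v in dep.items()))
print("(fractions of viability lost under full inhibition of each protein;")
print(" downstream scoring should recover 100x these values up to noise)")
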