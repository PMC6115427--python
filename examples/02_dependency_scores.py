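"""Score a viability panel into 0-99 dependency profiles.

Each treatment condition is scored against the line's own vehicle wells:
score = 100 * (1 - mean treated / mean vehicle), clamped to [0, 99].
"""

from bh3map import SimConfig, build_profiles, score_matrix, simulate_screen

bundle = simulate_screen(SimConfig(seed=7))
profiles = build_profiles(bundle.viability_panel)
mat = score_matrix(profiles)

print("dependency score matrix (first 5 lines):")
print(mat.head().round(1).to_string())

combo_sensitive = (mat["W539+A121"] > 50).sum()
print(f"\n{combo_sensitive} of {len(mat)} lines are sensitive (>50 points "
      "viability loss) to combined BCL-XL + MCL-1 inhibition.")
print("High scores mean the line depends on the inhibited protein(s) to survive.")
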