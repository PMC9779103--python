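"""Classifying oligomeric-state types (I-VI) from elution profiles.

A protein seen only at its own monomer MW is type I; one seen at twice its
MW is dimeric (type II); appearing both as monomer and inside much larger
complexes gives the mixed types (IV-VI). The example reproduces the
textbook case of a 31-kDa protein found at 31, 250 and 440 kDa -> type V
(monomer + high-order complexes), then summarises a small cohort.
"""

from cofrac import ElutionProfile, classify_state, summarize_taxonomy

grid = (15.0, 31.0, 70.0, 130.0, 250.0, 440.0)

profiles = {
    # accession: (monomer MW, abundances over the grid)
    "APO31": (31.0, (0.0, 1.0, 0.0, 0.0, 0.8, 0.6)),   # monomer + oligomers
    "MONO70": (70.0, (0.0, 0.0, 1.2, 0.0, 0.0, 0.0)),  # pure monomer
    "DIM35": (35.3, (0.0, 0.0, 0.9, 0.0, 0.0, 0.0)),   # seen at ~2x its MW
    "MIX15": (15.0, (1.0, 1.1, 0.0, 0.9, 0.0, 0.0)),   # monomer+dimer+oligomer
}

calls = []
for acc, (mw, abundances) in profiles.items():
    call = classify_state(ElutionProfile(acc, grid, abundances), mw)
    calls.append(call)
    classes = ", ".join(sorted(c.value for c in call.class_set)) or "none"
    print(f"{acc:7s} ({mw:5.1f} kDa)  classes: {classes:28s} -> type {call.state_type.value}")

summary = summarize_taxonomy(calls)
print("\nInteractome split over this cohort:")
for group, pct in summary.group_percentages.items():
    print(f"  {group:13s} {pct:5.1f}%  ({summary.group_counts[group]} proteins)")
print("\n'multimeric' counts oligomer-involving types (III/V/VI), 'dimeric' "
      "types II/IV, 'monomer_only' type I.")
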