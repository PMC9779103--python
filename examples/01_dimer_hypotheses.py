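"""Two-stage dimer hypothesis generation on a hand-built SEC fraction.

A 45-kDa fraction at the default ±10% tolerance accepts candidate dimers
with summed MW between 40.5 and 49.5 kDa (stage 1, list #1); pairs whose
emPAI quotient exceeds 1.5 are then discarded (stage 2, list #2).
"""

from cofrac import (
    DimersConfig,
    FractionObservation,
    FractionTable,
    ProteinRecord,
    filter_list2,
    generate_list1,
    mw_window,
)

proteins = {
    "X": ProteinRecord("X", 20.0, name="protein X"),
    "Y": ProteinRecord("Y", 25.0, name="protein Y"),
    "Z": ProteinRecord("Z", 24.5, name="protein Z"),
    "W": ProteinRecord("W", 60.0, name="protein W"),
}
fraction = FractionTable(
    "F45",
    45.0,
    (
        FractionObservation("X", empai=1.4),   # comparable to Y -> plausible dimer
        FractionObservation("Y", empai=1.0),
        FractionObservation("Z", empai=4.0),   # 4x more abundant than X -> filtered
        FractionObservation("W", empai=0.5),   # too heavy to pair at 45 kDa
    ),
)

low, high = mw_window(fraction.mean_mw_kda, 0.10)
print(f"MW acceptance window for a {fraction.mean_mw_kda:g}-kDa fraction: "
      f"{low:g}-{high:g} kDa")

config = DimersConfig()  # tolerance 0.10, ratio_max 1.5, homodimers allowed
list1 = generate_list1(fraction, proteins, config)
list2 = filter_list2(list1, fraction, config)

print(f"\nlist #1 ({len(list1)} MW-compatible pairs):")
for h in list1:
    print(f"  {h.accession_a}+{h.accession_b}  sum {h.sum_mw_kda:5.1f} kDa  "
          f"deviation {h.deviation:+.1%}")
print(f"\nlist #2 ({len(list2)} pairs also passing the emPAI quotient <= "
      f"{config.ratio_max}):")
for h in list2:
    print(f"  {h.accession_a}+{h.accession_b}  emPAI {h.empai_a:g}/{h.empai_b:g}  "
          f"quotient {h.empai_ratio:.2f}")
print("\nX+Y survives (quotient 1.40 <= 1.5); X+Z is MW-compatible but its "
      "members' abundances differ 2.9-fold, so it is filtered out.")
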