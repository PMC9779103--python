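"""The per-fraction MW distribution matrix on the packaged reference data.

Rows are monomer-MW bins, columns SEC fractions (by mean MW). Counts far
below the diagonal are proteins much lighter than their fraction — they can
only be there inside complexes; counts above the fraction mean flag likely
fragments or high-adhesion proteins.
"""

from cofrac import (
    build_distribution_matrix,
    experiment_from_bin_counts,
    load_reference_distribution,
)

experiment = experiment_from_bin_counts(load_reference_distribution())
dm = build_distribution_matrix(experiment)

frame = dm.to_frame()
print(frame.to_string())
print("\nColumn totals = distinct proteins identified per fraction:")
print("  " + ", ".join(f"{mw:g} kDa: {t}" for mw, t in zip(dm.fraction_mws, dm.totals)))
print("\nProteins relative to their fraction's mean MW (above = anomalous):")
print(dm.band_summary().to_string(index=False))
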