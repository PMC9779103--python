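"""Packaged reference data.

``load_reference_distribution`` returns a published distribution matrix of
LC-MS/MS protein identifications across six SEC fractions of a liver
tissue lysate (fraction mean MWs 400, 290, 130, 90, 60 and 48 kDa), used
as a realistic end-to-end check of the matrix construction.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .matrix import DEFAULT_BIN_EDGES
from .models import Experiment, FractionObservation, FractionTable, ProteinRecord


def load_reference_distribution() -> pd.DataFrame:
    """Reference bin × fraction count table (rows = MW bins, cols = fraction MWs)."""
    ref = resources.files("cofrac.data") / "reference_distribution.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.columns = [float(c) for c in df.columns]
    return df


def experiment_from_bin_counts(counts: pd.DataFrame) -> Experiment:
    """Synthetic experiment realising a bin × fraction count table.

    For every (bin, fraction) cell, ``counts`` distinct placeholder
    proteins are created with MW at the bin midpoint and unit emPAI; the
    accessions are synthetic (``F<mw>_B<i>_<j>``), not real identifiers.
    Binning the result reproduces the input counts exactly, which makes
    the table usable as a fixture for the distribution-matrix invariants.
    """
    edges = DEFAULT_BIN_EDGES
    n_bins = len(edges) - 1
    if len(counts.index) != n_bins:
        raise ValueError(
            f"count table has {len(counts.index)} bins, expected {n_bins}"
        )
    proteins: dict[str, ProteinRecord] = {}
    fractions: list[FractionTable] = []
    for fmw in sorted(counts.columns, reverse=True):
        obs = []
        for b in range(n_bins):
            mid = (edges[b] + edges[b + 1]) / 2.0
            for j in range(int(counts.iloc[b][fmw])):
                acc = f"F{fmw:g}_B{b:02d}_{j:03d}"
                proteins[acc] = ProteinRecord(acc, mid, name="synthetic placeholder")
                obs.append(FractionObservation(acc, empai=1.0))
        fractions.append(FractionTable(f"F{fmw:g}", float(fmw), tuple(obs)))
    return Experiment(proteins=proteins, fractions=fractions)
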