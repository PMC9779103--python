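"""MW distribution matrix of identified proteins across SEC fractions.

The matrix counts, per fraction, how many distinct identified proteins fall
in each monomer-MW bin. Proteins much lighter than a fraction's mean MW can
only be there as subunits of complexes; proteins heavier than the fraction
mean are anomalous (likely proteolytic fragments or high-adhesion species
moving slowly through the column). The matrix is the first, qualitative
look at how much of a lysate's proteome is complexed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .models import Experiment

#: Default monomer-MW bin edges (kDa): 10-kDa bins up to 151, then wider
#: bins out to 701, matching the resolution a whole-lysate SEC run affords.
DEFAULT_BIN_EDGES: tuple[float, ...] = (
    0, 11, 21, 31, 41, 51, 61, 71, 81, 91, 101, 111, 121, 131, 141, 151,
    176, 201, 226, 251, 301, 351, 401, 451, 501, 601, 701,
)

#: Relative band half-width for calling a protein "at" its fraction's mean MW.
BAND_TOLERANCE = 0.10


def _bin_label(low: float, high: float) -> str:
    if low == 0:
        return f"<{high:g}"
    return f"{low:g}-{high:g}"


@dataclass
class DistributionMatrix:
    """Per-bin, per-fraction distinct-protein counts for an experiment.

    ``counts[b, f]`` is the number of distinct proteins identified in
    fraction ``f`` whose monomer MW lies in the half-open bin
    ``[edges[b], edges[b+1])``. ``band`` classifies each count relative to
    the fraction's mean MW (below / at / above, with "at" a ±10% band);
    "above" flags likely fragments or high-adhesion proteins. Proteins
    whose MW falls outside all bins are reported in ``unbinned``, never
    silently dropped.
    """

    bin_edges: tuple[float, ...]
    fraction_ids: list[str]
    fraction_mws: list[float]
    counts: np.ndarray
    unbinned: dict[str, list[str]] = field(default_factory=dict)

    @property
    def bins(self) -> list[tuple[float, float]]:
        return list(zip(self.bin_edges[:-1], self.bin_edges[1:]))

    @property
    def bin_labels(self) -> list[str]:
        return [_bin_label(lo, hi) for lo, hi in self.bins]

    @property
    def totals(self) -> np.ndarray:
        """Per-fraction column sums = distinct binned proteins per fraction."""
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        """Matrix as a DataFrame (rows = MW bins, columns = fraction mean MWs)."""
        df = pd.DataFrame(
            self.counts,
            index=pd.Index(self.bin_labels, name="mw_bin_kda"),
            columns=[f"{mw:g}" for mw in self.fraction_mws],
        )
        df.loc["Total"] = self.totals
        return df

    def band_summary(self) -> pd.DataFrame:
        """Counts of proteins below / at / above each fraction's mean MW."""
        rows = []
        for f, (fid, fmw) in enumerate(zip(self.fraction_ids, self.fraction_mws)):
            below = at = above = 0
            for b, (lo, hi) in enumerate(self.bins):
                mid = (lo + hi) / 2.0
                n = int(self.counts[b, f])
                if hi <= (1 - BAND_TOLERANCE) * fmw:
                    below += n
                elif lo >= (1 + BAND_TOLERANCE) * fmw:
                    above += n
                elif (1 - BAND_TOLERANCE) * fmw <= mid <= (1 + BAND_TOLERANCE) * fmw:
                    at += n
                elif mid < fmw:
                    below += n
                else:
                    above += n
            rows.append(
                {"fraction_id": fid, "mean_mw_kda": fmw,
                 "below": below, "at": at, "above": above}
            )
        return pd.DataFrame(rows)


def build_distribution_matrix(
    experiment: Experiment,
    bin_edges: tuple[float, ...] | list[float] | None = None,
) -> DistributionMatrix:
    """Count distinct identified proteins per MW bin per fraction.

    Bins are half-open ``[low, high)`` on the monomer MW in kDa. Each
    column total equals the number of distinct binned proteins identified
    in that fraction.
    """
    edges = tuple(float(e) for e in (bin_edges if bin_edges is not None else DEFAULT_BIN_EDGES))
    if len(edges) < 2 or any(a >= b for a, b in zip(edges, edges[1:])):
        raise ValidationError("bin edges must be strictly increasing, length >= 2")

    n_bins = len(edges) - 1
    counts = np.zeros((n_bins, len(experiment.fractions)), dtype=int)
    unbinned: dict[str, list[str]] = {}
    for f, frac in enumerate(experiment.fractions):
        mws = np.array(
            [experiment.proteins[a].mw_kda for a in frac.accessions], dtype=float
        )
        if mws.size:
            idx = np.digitize(mws, edges) - 1  # [edges[i], edges[i+1])
            in_range = (idx >= 0) & (idx < n_bins)
            counts[:, f] = np.bincount(idx[in_range], minlength=n_bins)
            out = [a for a, ok in zip(frac.accessions, in_range) if not ok]
            if out:
                unbinned[frac.fraction_id] = sorted(out)
    return DistributionMatrix(
        bin_edges=edges,
        fraction_ids=[f.fraction_id for f in experiment.fractions],
        fraction_mws=[f.mean_mw_kda for f in experiment.fractions],
        counts=counts,
        unbinned=unbinned,
    )
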