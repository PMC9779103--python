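"""Co-elution profile similarity and partner candidate ranking.

Proteins belonging to the same stable complex co-elute: their abundance
profiles over the fraction-MW grid rise and fall together. For a target
protein, candidate partners are the proteins sharing enough presence
fractions with it, ranked by the Pearson correlation of their profiles.
Correlation is computed on the union of the two proteins' presence
fractions (not the full grid), so the many fractions where both are
absent do not inflate similarity; a full-grid mode is available.

Co-occurrence alone is weak evidence — a candidate may share fractions
with the target without interacting — so each score also reports whether
the pair's summed MW matches some shared fraction's mean (the dimer-style
check), and undefined correlations (too few shared points, or zero
variance) are reported rather than dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .dimers import mw_window
from .errors import UnknownAccessionError, ValidationError
from .models import Experiment
from .taxonomy import ElutionProfile, extract_profile

DEFAULT_MIN_SHARED = 3


@dataclass(frozen=True)
class PartnerScore:
    """Similarity of one candidate's co-fractionation profile to the target's."""

    target: str
    candidate: str
    similarity: float | None       # Pearson r, None when undefined
    shared_fractions: int          # fractions where both are present
    mw_sum_match: float | None     # shared fraction mean MW matching MW(a)+MW(b)


def profile_similarity(
    p: ElutionProfile,
    q: ElutionProfile,
    mode: str = "support",
) -> float | None:
    """Pearson correlation of two elution profiles on the same grid.

    In ``support`` mode (default) the correlation is restricted to
    fractions where at least one profile is nonzero; ``full`` uses the
    whole grid. Returns None (undefined) when fewer than 3 points remain
    or either restricted vector has zero variance.
    """
    if p.grid != q.grid:
        raise ValidationError(
            f"profiles {p.accession} and {q.accession} are on different grids"
        )
    if mode not in ("support", "full"):
        raise ValidationError(f"mode must be 'support' or 'full', got {mode!r}")
    a = np.asarray(p.abundances, dtype=float)
    b = np.asarray(q.abundances, dtype=float)
    if mode == "support":
        keep = (a > 0) | (b > 0)
        a, b = a[keep], b[keep]
    if a.size < 3 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return None
    return float(stats.pearsonr(a, b).statistic)


def rank_partners(
    experiment: Experiment,
    target: str,
    min_shared: int = DEFAULT_MIN_SHARED,
    tolerance: float = 0.10,
    mode: str = "support",
) -> list[PartnerScore]:
    """Rank candidate partners of a target by co-fractionation similarity.

    Candidates are proteins observed (nonzero emPAI) together with the
    target in at least ``min_shared`` fractions. They are ranked by
    similarity descending, undefined similarities last, ties broken by
    accession. ``mw_sum_match`` reports the shared fraction whose mean MW
    the pair's summed monomer MW matches within ±``tolerance`` (the
    closest such fraction), or None.
    """
    if target not in experiment.proteins:
        raise UnknownAccessionError(f"unknown target accession {target!r}")
    p = extract_profile(experiment, target)
    pa = np.asarray(p.abundances)
    grid = np.asarray(p.grid)
    target_mw = experiment.proteins[target].mw_kda

    scores: list[PartnerScore] = []
    for acc in sorted(experiment.proteins):
        if acc == target:
            continue
        q = extract_profile(experiment, acc)
        qa = np.asarray(q.abundances)
        shared = (pa > 0) & (qa > 0)
        n_shared = int(shared.sum())
        if n_shared < min_shared:
            continue
        sim = profile_similarity(p, q, mode=mode)

        pair_mw = target_mw + experiment.proteins[acc].mw_kda
        match: float | None = None
        best_dev = np.inf
        for mw in grid[shared]:
            low, high = mw_window(float(mw), tolerance)
            dev = abs(pair_mw - mw) / mw
            if low <= pair_mw <= high and dev < best_dev:
                match, best_dev = float(mw), dev
        scores.append(
            PartnerScore(
                target=target,
                candidate=acc,
                similarity=sim,
                shared_fractions=n_shared,
                mw_sum_match=match,
            )
        )
    scores.sort(
        key=lambda s: (
            s.similarity is None,
            -(s.similarity if s.similarity is not None else 0.0),
            s.candidate,
        )
    )
    return scores


def partners_frame(scores: list[PartnerScore]) -> pd.DataFrame:
    """Partner ranking as a flat table for TSV export."""
    return pd.DataFrame(
        [
            {
                "target": s.target,
                "candidate": s.candidate,
                "similarity": s.similarity,
                "shared_fractions": s.shared_fractions,
                "mw_sum_match": s.mw_sum_match,
            }
            for s in scores
        ],
        columns=["target", "candidate", "similarity", "shared_fractions", "mw_sum_match"],
    )
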