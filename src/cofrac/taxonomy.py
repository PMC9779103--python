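"""Oligomeric-state taxonomy from SEC elution profiles.

A protein identified in a fraction of mean MW ``m`` while its monomer MW
is ``p`` implies an apparent stoichiometry ``r = m / p``; rounding to the
nearest integer ``k`` assigns the observation a size class: monomer
(k = 1), dimer (k = 2) or higher-order oligomer (k ≥ 3). Observations
with ``r < 0.5`` — the protein is heavier than the fraction — are
anomalous (likely proteolytic fragments or high-adhesion species) and
excluded from typing.

The set of size classes a protein shows across its presence fractions
maps onto six state types:

    I   monomer only             IV  monomer + dimer
    II  dimer only               V   monomer + oligomer
    III oligomer only            VI  monomer + dimer + oligomer

Any other non-empty class set (e.g. dimer + oligomer without monomer) is
reported verbatim as OTHER, never coerced into the six types.

Trace presence is suppressed by a relative threshold: a fraction counts
as "present" only if its abundance reaches ``rel_threshold`` (default
10%) of the protein's own maximum across fractions.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UnknownAccessionError, ValidationError
from .models import Experiment

DEFAULT_REL_THRESHOLD = 0.10


class SizeClass(enum.Enum):
    MONOMER = "monomer"
    DIMER = "dimer"
    OLIGOMER = "oligomer"
    ANOMALOUS = "anomalous"


class StateType(enum.Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"
    V = "V"
    VI = "VI"
    OTHER = "other"


#: Class-set → state-type mapping (ANOMALOUS calls are excluded upstream).
_TYPE_MAP: dict[frozenset[SizeClass], StateType] = {
    frozenset({SizeClass.MONOMER}): StateType.I,
    frozenset({SizeClass.DIMER}): StateType.II,
    frozenset({SizeClass.OLIGOMER}): StateType.III,
    frozenset({SizeClass.MONOMER, SizeClass.DIMER}): StateType.IV,
    frozenset({SizeClass.MONOMER, SizeClass.OLIGOMER}): StateType.V,
    frozenset({SizeClass.MONOMER, SizeClass.DIMER, SizeClass.OLIGOMER}): StateType.VI,
}


@dataclass(frozen=True)
class ElutionProfile:
    """A protein's abundance over the fraction mean-MW grid (ascending kDa)."""

    accession: str
    grid: tuple[float, ...]
    abundances: tuple[float, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "grid", tuple(float(g) for g in self.grid))
        object.__setattr__(
            self, "abundances", tuple(float(a) for a in self.abundances)
        )
        if len(self.grid) != len(self.abundances):
            raise ValidationError(
                f"{self.accession}: grid and abundances lengths differ "
                f"({len(self.grid)} vs {len(self.abundances)})"
            )
        if any(a >= b for a, b in zip(self.grid, self.grid[1:])):
            raise ValidationError(f"{self.accession}: grid must be strictly increasing")
        if any(a < 0 for a in self.abundances):
            raise ValidationError(f"{self.accession}: abundances must be non-negative")


@dataclass(frozen=True)
class SizeClassCall:
    """Size-class evidence from one presence fraction."""

    fraction_mw: float
    ratio_r: float        # fraction mean MW / protein monomer MW
    multiplicity_k: int   # round-half-up of ratio_r
    size_class: SizeClass


@dataclass(frozen=True)
class StateCall:
    """A protein's oligomeric-state type with its per-fraction evidence.

    ``state_type`` is None when the protein passes the presence threshold
    in no fraction ("not detected") or when all its calls are anomalous.
    """

    accession: str
    protein_mw_kda: float
    calls: tuple[SizeClassCall, ...]
    state_type: StateType | None
    present_fraction_mws: tuple[float, ...]
    fraction_shares: tuple[float, ...]  # abundance shares over ALL fractions

    @property
    def detected(self) -> bool:
        return bool(self.calls)

    @property
    def class_set(self) -> frozenset[SizeClass]:
        return frozenset(
            c.size_class for c in self.calls if c.size_class is not SizeClass.ANOMALOUS
        )


def extract_profile(experiment: Experiment, accession: str) -> ElutionProfile:
    """A protein's emPAI vector over the experiment's fraction-MW grid.

    The grid is ascending mean MW; fractions where the protein was not
    identified contribute zero.
    """
    if accession not in experiment.proteins:
        raise UnknownAccessionError(f"unknown protein accession {accession!r}")
    grid, abundances = [], []
    for frac in reversed(experiment.fractions):  # ascending MW
        grid.append(frac.mean_mw_kda)
        abundances.append(frac.empai_of(accession) if accession in frac else 0.0)
    return ElutionProfile(accession, tuple(grid), tuple(abundances))


def presence_mask(
    profile: ElutionProfile, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> np.ndarray:
    """True where abundance reaches ``rel_threshold`` of the profile maximum.

    At threshold 0, any strictly positive abundance counts as presence.
    An all-zero profile yields an all-false mask. The mask is invariant
    under uniform rescaling of the abundances.
    """
    if not 0 <= rel_threshold < 1:
        raise ValidationError(f"rel_threshold must be in [0, 1), got {rel_threshold}")
    ab = np.asarray(profile.abundances, dtype=float)
    peak = ab.max() if ab.size else 0.0
    if peak <= 0:
        return np.zeros_like(ab, dtype=bool)
    if rel_threshold == 0:
        return ab > 0
    return ab >= rel_threshold * peak


def size_class_call(fraction_mw: float, protein_mw: float) -> SizeClassCall:
    """Apparent stoichiometry and size class of one observation."""
    r = fraction_mw / protein_mw
    k = math.floor(r + 0.5)  # round half up
    if r < 0.5:
        cls = SizeClass.ANOMALOUS
    elif k == 1:
        cls = SizeClass.MONOMER
    elif k == 2:
        cls = SizeClass.DIMER
    else:
        cls = SizeClass.OLIGOMER
    return SizeClassCall(fraction_mw=fraction_mw, ratio_r=r, multiplicity_k=k, size_class=cls)


def classify_state(
    profile: ElutionProfile,
    protein_mw: float,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
) -> StateCall:
    """Assign a protein's state type (I–VI / OTHER) from its elution profile.

    Anomalous calls (protein heavier than the fraction) are recorded in
    the evidence but excluded from the class set. A protein present
    nowhere, or only anomalously, gets ``state_type`` None.
    """
    if protein_mw <= 0:
        raise ValidationError(f"protein MW must be positive, got {protein_mw}")
    mask = presence_mask(profile, rel_threshold)
    ab = np.asarray(profile.abundances, dtype=float)
    total = float(ab.sum())
    shares = tuple((ab / total).tolist()) if total > 0 else tuple(0.0 for _ in ab)

    calls = tuple(
        size_class_call(mw, protein_mw)
        for mw, present in zip(profile.grid, mask)
        if present
    )
    classes = frozenset(
        c.size_class for c in calls if c.size_class is not SizeClass.ANOMALOUS
    )
    state = _TYPE_MAP.get(classes, StateType.OTHER) if classes else None
    return StateCall(
        accession=profile.accession,
        protein_mw_kda=protein_mw,
        calls=calls,
        state_type=state,
        present_fraction_mws=tuple(
            mw for mw, present in zip(profile.grid, mask) if present
        ),
        fraction_shares=shares,
    )


def classify_experiment(
    experiment: Experiment, rel_threshold: float = DEFAULT_REL_THRESHOLD
) -> list[StateCall]:
    """State calls for every catalogued protein, in accession order."""
    return [
        classify_state(
            extract_profile(experiment, acc),
            experiment.proteins[acc].mw_kda,
            rel_threshold,
        )
        for acc in sorted(experiment.proteins)
    ]


@dataclass
class TaxonomySummary:
    """Per-type counts/percentages and the coarse interactome split.

    Percentages are over typed (detected) proteins. The grouped shares
    follow the usual reporting of SEC interactome surveys: *multimeric*
    covers oligomer-involving types (III, V, VI), *dimeric* the dimer
    types (II, IV), *monomer-only* type I; OTHER-typed proteins are
    counted separately and excluded from the three groups.
    """

    n_total: int
    n_detected: int
    counts: dict[StateType, int] = field(default_factory=dict)
    percentages: dict[StateType, float] = field(default_factory=dict)
    group_counts: dict[str, int] = field(default_factory=dict)
    group_percentages: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "state_type": [t.value for t in self.counts],
                "count": list(self.counts.values()),
                "percent": [self.percentages[t] for t in self.counts],
            }
        )


_GROUPS = {
    "multimeric": (StateType.III, StateType.V, StateType.VI),
    "dimeric": (StateType.II, StateType.IV),
    "monomer_only": (StateType.I,),
}


def summarize_taxonomy(calls: list[StateCall]) -> TaxonomySummary:
    """Count state types and compute the multimeric/dimeric/monomer split."""
    typed = [c for c in calls if c.state_type is not None]
    counts = {t: 0 for t in StateType}
    for call in typed:
        counts[call.state_type] += 1
    n = len(typed)
    percentages = {t: (100.0 * c / n if n else 0.0) for t, c in counts.items()}
    group_counts = {
        g: sum(counts[t] for t in members) for g, members in _GROUPS.items()
    }
    n_grouped = sum(group_counts.values())
    group_percentages = {
        g: (100.0 * c / n_grouped if n_grouped else 0.0)
        for g, c in group_counts.items()
    }
    return TaxonomySummary(
        n_total=len(calls),
        n_detected=n,
        counts=counts,
        percentages=percentages,
        group_counts=group_counts,
        group_percentages=group_percentages,
    )


def state_calls_frame(calls: list[StateCall]) -> pd.DataFrame:
    """State calls as a flat table for TSV export."""
    rows = []
    for c in calls:
        rows.append(
            {
                "accession": c.accession,
                "mw_kda": c.protein_mw_kda,
                "present_fractions": ";".join(f"{m:g}" for m in c.present_fraction_mws),
                "class_set": ";".join(
                    sorted(cls.value for cls in c.class_set)
                ),
                "state_type": c.state_type.value if c.state_type else "not_detected",
                "fraction_shares": ";".join(f"{s:.4f}" for s in c.fraction_shares),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "accession", "mw_kda", "present_fractions", "class_set",
            "state_type", "fraction_shares",
        ],
    )
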