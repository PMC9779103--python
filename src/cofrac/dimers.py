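"""Two-stage generation of dimeric protein-complex hypotheses.

Within one SEC fraction, a pair of identified proteins is a plausible
binary complex when (stage 1) the sum of their monomer MWs falls within a
±tolerance window around the fraction's mean MW — these pairs form
*list #1* — and (stage 2) their emPAI abundances are comparable: the
larger-over-smaller quotient must not exceed ``ratio_max``, since subunits
of an equimolar dimer should be present in near-equal amounts. Pairs
surviving both stages form *list #2*, the hypotheses worth downstream
verification.

Defaults: tolerance ±10% of the fraction mean MW, quotient threshold 1.5,
homodimers (self-pairs at twice the monomer MW) included. Both the window
bounds and the quotient threshold are inclusive.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .abundance import abundance_quotient
from .errors import UndefinedQuotientError, ValidationError
from .models import Experiment, FractionTable, ProteinRecord


class DimerStage(enum.Enum):
    LIST1 = "list1"  # passed the MW-sum window
    LIST2 = "list2"  # additionally passed the abundance-quotient filter


@dataclass(frozen=True)
class DimerHypothesis:
    """An unordered protein pair hypothesised to form a dimer in one fraction.

    ``accession_a <= accession_b`` lexicographically; ``a == b`` encodes a
    homodimer (MW sum is twice the monomer MW). ``deviation`` is the
    relative offset of the MW sum from the fraction mean,
    (sum − mean) / mean. ``empai_ratio`` is larger/smaller emPAI, defined
    as 1 for homodimers, None when either member lacks positive emPAI.
    """

    fraction_id: str
    accession_a: str
    accession_b: str
    mw_a: float
    mw_b: float
    sum_mw_kda: float
    deviation: float
    empai_a: float | None = None
    empai_b: float | None = None
    empai_ratio: float | None = None
    stage: DimerStage = DimerStage.LIST1

    @property
    def pair(self) -> tuple[str, str]:
        return (self.accession_a, self.accession_b)

    @property
    def is_homodimer(self) -> bool:
        return self.accession_a == self.accession_b


@dataclass(frozen=True)
class DimersConfig:
    """Thresholds of the two-stage filter."""

    tolerance: float = 0.10
    ratio_max: float = 1.5
    allow_homodimers: bool = True
    bounds_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.tolerance <= 0:
            raise ValidationError(f"tolerance must be positive, got {self.tolerance}")
        if self.ratio_max < 1:
            raise ValidationError(f"ratio_max must be >= 1, got {self.ratio_max}")


def mw_window(fraction_mw: float, tolerance: float) -> tuple[float, float]:
    """Closed MW-sum acceptance window around a fraction's mean MW.

    ``((1 − tolerance)·mw, (1 + tolerance)·mw)``; e.g. a 45-kDa fraction
    at the default ±10% accepts dimer MWs from 40.5 to 49.5 kDa.
    """
    if fraction_mw <= 0:
        raise ValidationError(f"fraction mean MW must be positive, got {fraction_mw}")
    if tolerance < 0:
        raise ValidationError(f"tolerance must be non-negative, got {tolerance}")
    half_width = tolerance * fraction_mw
    return (fraction_mw - half_width, fraction_mw + half_width)


def generate_list1(
    fraction: FractionTable,
    proteins: dict[str, ProteinRecord],
    config: DimersConfig = DimersConfig(),
) -> list[DimerHypothesis]:
    """Stage 1: all unordered pairs whose MW sum falls in the fraction window.

    Includes self-pairs (homodimers, sum = 2·MW) when the config allows
    them. Output is deterministic: sorted by |deviation|, then by the
    accession pair. Every observed accession must have a known MW.
    """
    accs = sorted(fraction.accessions)
    missing = [a for a in accs if a not in proteins]
    if missing:
        raise ValidationError(
            f"fraction {fraction.fraction_id}: no MW for accession(s) "
            f"{', '.join(missing)}"
        )
    low, high = mw_window(fraction.mean_mw_kda, config.tolerance)
    mws = np.array([proteins[a].mw_kda for a in accs], dtype=float)

    # pairwise sum matrix; upper triangle covers each unordered pair once,
    # the diagonal the homodimers (2*mw)
    sums = mws[:, None] + mws[None, :]
    if config.bounds_inclusive:
        mask = (sums >= low) & (sums <= high)
    else:
        mask = (sums > low) & (sums < high)
    k = 0 if config.allow_homodimers else 1
    ii, jj = np.nonzero(np.triu(mask, k=k))

    mean = fraction.mean_mw_kda
    hypotheses = [
        DimerHypothesis(
            fraction_id=fraction.fraction_id,
            accession_a=accs[i],
            accession_b=accs[j],
            mw_a=float(mws[i]),
            mw_b=float(mws[j]),
            sum_mw_kda=float(sums[i, j]),
            deviation=float((sums[i, j] - mean) / mean),
            stage=DimerStage.LIST1,
        )
        for i, j in zip(ii.tolist(), jj.tolist())
    ]
    hypotheses.sort(key=lambda h: (abs(h.deviation), h.accession_a, h.accession_b))
    return hypotheses


def filter_list2(
    list1: list[DimerHypothesis],
    fraction: FractionTable,
    config: DimersConfig = DimersConfig(),
) -> list[DimerHypothesis]:
    """Stage 2: keep pairs with comparable emPAI (quotient ≤ ratio_max).

    Homodimers have quotient 1 by definition. Pairs where either member
    has zero emPAI have an undefined quotient and fail the filter (its
    premise is comparable quantification of both members). Order is
    preserved from list #1.
    """
    empai = {obs.accession: obs.empai for obs in fraction.observations}
    out: list[DimerHypothesis] = []
    for hyp in list1:
        for acc in hyp.pair:
            if acc not in empai:
                raise ValidationError(
                    f"hypothesis ({hyp.accession_a}, {hyp.accession_b}) references "
                    f"{acc}, not observed in fraction {fraction.fraction_id}"
                )
        ea, eb = empai[hyp.accession_a], empai[hyp.accession_b]
        if hyp.is_homodimer:
            ratio: float | None = 1.0
        else:
            try:
                ratio = abundance_quotient(ea, eb)
            except UndefinedQuotientError:
                ratio = None
        if ratio is not None and ratio <= config.ratio_max:
            out.append(
                DimerHypothesis(
                    fraction_id=hyp.fraction_id,
                    accession_a=hyp.accession_a,
                    accession_b=hyp.accession_b,
                    mw_a=hyp.mw_a,
                    mw_b=hyp.mw_b,
                    sum_mw_kda=hyp.sum_mw_kda,
                    deviation=hyp.deviation,
                    empai_a=ea,
                    empai_b=eb,
                    empai_ratio=ratio,
                    stage=DimerStage.LIST2,
                )
            )
    return out


@dataclass
class FractionDimerResult:
    fraction_id: str
    mean_mw_kda: float
    list1: list[DimerHypothesis]
    list2: list[DimerHypothesis]

    @property
    def retention(self) -> float | None:
        """list2/list1 ratio — the fraction of MW-compatible pairs that also
        pass the abundance filter; None when list #1 is empty."""
        return len(self.list2) / len(self.list1) if self.list1 else None


@dataclass
class DimersReport:
    """Per-fraction two-stage results for a whole experiment."""

    results: list[FractionDimerResult] = field(default_factory=list)

    @property
    def n_list1(self) -> int:
        return sum(len(r.list1) for r in self.results)

    @property
    def n_list2(self) -> int:
        return sum(len(r.list2) for r in self.results)

    @property
    def retention(self) -> float | None:
        """Overall list2/list1 retention across fractions (None if list1 empty)."""
        return self.n_list2 / self.n_list1 if self.n_list1 else None

    def list2_pairs(self) -> set[tuple[str, str]]:
        """Distinct accession pairs reaching list #2 in any fraction."""
        return {h.pair for r in self.results for h in r.list2}

    def to_frame(self) -> pd.DataFrame:
        """All hypotheses as a flat table (stage column marks list #1 vs #2)."""
        rows = []
        for res in self.results:
            for hyp in itertools.chain(res.list1, res.list2):
                rows.append(
                    {
                        "fraction_id": hyp.fraction_id,
                        "accession_a": hyp.accession_a,
                        "accession_b": hyp.accession_b,
                        "mw_a": hyp.mw_a,
                        "mw_b": hyp.mw_b,
                        "sum_mw": hyp.sum_mw_kda,
                        "deviation": hyp.deviation,
                        "empai_a": hyp.empai_a,
                        "empai_b": hyp.empai_b,
                        "ratio": hyp.empai_ratio,
                        "stage": hyp.stage.value,
                    }
                )
        return pd.DataFrame(
            rows,
            columns=[
                "fraction_id", "accession_a", "accession_b", "mw_a", "mw_b",
                "sum_mw", "deviation", "empai_a", "empai_b", "ratio", "stage",
            ],
        )


def run_dimers(
    experiment: Experiment, config: DimersConfig = DimersConfig()
) -> DimersReport:
    """Run both stages on every fraction of an experiment."""
    report = DimersReport()
    for fraction in experiment.fractions:
        list1 = generate_list1(fraction, experiment.proteins, config)
        list2 = filter_list2(list1, fraction, config)
        report.results.append(
            FractionDimerResult(
                fraction_id=fraction.fraction_id,
                mean_mw_kda=fraction.mean_mw_kda,
                list1=list1,
                list2=list2,
            )
        )
    return report
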