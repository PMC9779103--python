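"""Domain types for an SEC co-fractionation experiment.

An experiment is a whole-lysate size-exclusion run: the lysate is separated
into fractions of decreasing mean molecular weight (large species elute
first), each fraction's protein content is identified by LC-MS/MS, and
abundance is semi-quantified by emPAI. These types hold that data with the
invariants the downstream algorithms rely on (unique accessions, positive
MWs, elution-ordered fractions).

All molecular weights are kilodaltons throughout the package.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .errors import UnknownAccessionError, ValidationError
from .sequences import mw_from_sequence

#: Maximum relative disagreement tolerated between a declared monomer MW and
#: the MW computed from the record's sequence.
MW_SEQUENCE_TOLERANCE = 0.01


@dataclass(frozen=True)
class ProteinRecord:
    """One protein: accession, monomer MW (kDa) and optionally its sequence.

    If ``mw_kda`` is omitted but a sequence is given, the MW is computed
    from the sequence. If both are given they must agree within 1% —
    a silent unit mixup (Da vs kDa) is the dominant failure mode here and
    is refused loudly.
    """

    accession: str
    mw_kda: float | None = None
    name: str = ""
    sequence: str | None = None

    def __post_init__(self) -> None:
        if not self.accession or not self.accession.strip():
            raise ValidationError("protein accession must be non-empty")
        if self.mw_kda is None:
            if self.sequence is None:
                raise ValidationError(
                    f"{self.accession}: either mw_kda or sequence is required"
                )
            object.__setattr__(self, "mw_kda", mw_from_sequence(self.sequence))
        if self.mw_kda <= 0:
            raise ValidationError(
                f"{self.accession}: mw_kda must be positive, got {self.mw_kda}"
            )
        if self.sequence is not None:
            computed = mw_from_sequence(self.sequence)
            rel = abs(computed - self.mw_kda) / self.mw_kda
            if rel > MW_SEQUENCE_TOLERANCE:
                raise ValidationError(
                    f"{self.accession}: declared MW {self.mw_kda:.4g} kDa disagrees "
                    f"with sequence-derived MW {computed:.4g} kDa by {rel:.1%} (>1%)"
                )


@dataclass(frozen=True)
class FractionObservation:
    """One protein identified in one fraction, with its emPAI abundance."""

    accession: str
    empai: float
    score: float | None = None

    def __post_init__(self) -> None:
        if self.empai < 0:
            raise ValidationError(
                f"{self.accession}: emPAI must be non-negative, got {self.empai}"
            )


@dataclass(frozen=True)
class FractionTable:
    """One SEC fraction: its calibrated mean MW and the proteins seen in it."""

    fraction_id: str
    mean_mw_kda: float
    observations: tuple[FractionObservation, ...] = ()

    def __post_init__(self) -> None:
        if self.mean_mw_kda <= 0:
            raise ValidationError(
                f"fraction {self.fraction_id}: mean_mw_kda must be positive"
            )
        object.__setattr__(self, "observations", tuple(self.observations))
        seen: set[str] = set()
        for obs in self.observations:
            if obs.accession in seen:
                raise ValidationError(
                    f"fraction {self.fraction_id}: duplicate accession {obs.accession}"
                )
            seen.add(obs.accession)

    @property
    def accessions(self) -> list[str]:
        return [obs.accession for obs in self.observations]

    def empai_of(self, accession: str) -> float:
        for obs in self.observations:
            if obs.accession == accession:
                return obs.empai
        raise UnknownAccessionError(
            f"{accession} not observed in fraction {self.fraction_id}"
        )

    def __contains__(self, accession: object) -> bool:
        return any(obs.accession == accession for obs in self.observations)


@dataclass
class Experiment:
    """A full SEC run: protein catalogue plus fractions in elution order.

    Fractions are stored in elution order, i.e. strictly decreasing mean
    MW (the largest species leave the column first). Every observation
    must resolve to a catalogued :class:`ProteinRecord`.
    """

    proteins: dict[str, ProteinRecord]
    fractions: list[FractionTable] = field(default_factory=list)

    def __post_init__(self) -> None:
        for acc, rec in self.proteins.items():
            if acc != rec.accession:
                raise ValidationError(
                    f"protein map key {acc!r} does not match record accession "
                    f"{rec.accession!r}"
                )
        mws = [f.mean_mw_kda for f in self.fractions]
        if any(a <= b for a, b in zip(mws, mws[1:])):
            raise ValidationError(
                "fractions must be in elution order (strictly decreasing mean MW); "
                f"got mean MWs {mws}"
            )
        for frac in self.fractions:
            missing = [a for a in frac.accessions if a not in self.proteins]
            if missing:
                raise ValidationError(
                    f"fraction {frac.fraction_id}: observations without a protein "
                    f"record: {', '.join(sorted(missing))}"
                )

    @property
    def grid(self) -> list[float]:
        """Fraction mean MWs in ascending order (the profile axis)."""
        return [f.mean_mw_kda for f in reversed(self.fractions)]

    def fraction_by_id(self, fraction_id: str) -> FractionTable:
        for frac in self.fractions:
            if frac.fraction_id == fraction_id:
                return frac
        raise UnknownAccessionError(f"no fraction with id {fraction_id!r}")

    def protein(self, accession: str) -> ProteinRecord:
        try:
            return self.proteins[accession]
        except KeyError:
            raise UnknownAccessionError(
                f"unknown protein accession {accession!r}"
            ) from None


@dataclass(frozen=True)
class Calibration:
    """Linear SEC column calibration: log10(MW/kDa) = intercept + slope * V.

    ``slope`` must be negative — larger molecules elute earlier, so MW
    falls with elution volume. Predictions outside ``valid_range`` (the
    volume span of the standards) are extrapolations and are flagged with
    a warning.
    """

    slope: float
    intercept: float
    valid_range: tuple[float, float]
    stderr: float | None = None
    r_squared: float | None = None

    def __post_init__(self) -> None:
        if self.slope >= 0:
            raise ValidationError(
                f"calibration slope must be negative (MW decreases with elution "
                f"volume), got {self.slope}"
            )

    def predict_mw(self, elution_volume_ml: float) -> float:
        """Mean MW (kDa) at an elution volume; warns outside the fitted range."""
        lo, hi = self.valid_range
        if not lo <= elution_volume_ml <= hi:
            warnings.warn(
                f"elution volume {elution_volume_ml} mL outside calibrated range "
                f"[{lo}, {hi}] mL; prediction is an extrapolation",
                stacklevel=2,
            )
        return 10.0 ** (self.intercept + self.slope * elution_volume_ml)
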