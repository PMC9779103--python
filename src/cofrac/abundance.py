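"""emPAI semi-quantification and the pairwise abundance quotient.

The exponentially modified protein abundance index (emPAI) turns spectral
coverage into a label-free abundance estimate:

    emPAI = 10^(n_observed / n_observable) - 1

where ``n_observed`` is the number of distinct peptides identified for the
protein and ``n_observable`` the number theoretically observable. The
quotient of two proteins' emPAI values (larger over smaller) is the
stage-two descriptor of the dimer filter: subunits of an equimolar binary
complex should have similar abundance, so a large quotient argues against
the pair forming a joint dimer.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import UndefinedQuotientError, ValidationError


@dataclass(frozen=True)
class PeptideCounts:
    """Observed vs theoretically observable peptide counts for one protein."""

    n_observed: int
    n_observable: int

    def __post_init__(self) -> None:
        if self.n_observable <= 0:
            raise ValidationError(
                f"n_observable must be positive, got {self.n_observable}"
            )
        if not 0 <= self.n_observed <= self.n_observable:
            raise ValidationError(
                f"need 0 <= n_observed <= n_observable, got "
                f"{self.n_observed}/{self.n_observable}"
            )

    @property
    def empai(self) -> float:
        return compute_empai(self.n_observed, self.n_observable)


def compute_empai(n_observed: int, n_observable: int) -> float:
    """emPAI = 10^(n_observed/n_observable) − 1; zero iff no peptides seen."""
    counts = (
        PeptideCounts(n_observed, n_observable)
        if not isinstance(n_observed, PeptideCounts)
        else n_observed
    )
    return 10.0 ** (counts.n_observed / counts.n_observable) - 1.0


def abundance_quotient(empai_a: float, empai_b: float) -> float:
    """Larger emPAI divided by the smaller; symmetric, always ≥ 1.

    Raises
    ------
    UndefinedQuotientError
        If either value is zero or negative — the quotient's premise is
        comparable quantification of both members, so such a pair simply
        fails the abundance filter.
    """
    if empai_a <= 0 or empai_b <= 0:
        raise UndefinedQuotientError(
            f"abundance quotient undefined for emPAI values "
            f"({empai_a}, {empai_b}); both must be strictly positive"
        )
    return max(empai_a, empai_b) / min(empai_a, empai_b)
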