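"""Protein molecular weight from amino-acid sequence.

SEC interpretation is done entirely in kDa; this module turns a sequence
into the average (not monoisotopic) chain mass so that records carrying a
sequence but no MW can still be placed on the fraction-MW axis.
"""

from __future__ import annotations

from Bio.SeqUtils import molecular_weight

from .errors import ValidationError

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def mw_from_sequence(sequence: str) -> float:
    """Average molecular weight of a protein chain, in kDa.

    The mass is the sum of average residue masses plus one water
    (peptide-bond condensation leaves a single H2O on the chain), as
    computed by Biopython's standard amino-acid weight table.

    Parameters
    ----------
    sequence : str
        Amino-acid sequence using the 20 standard one-letter codes
        (case-insensitive).

    Raises
    ------
    ValidationError
        If the sequence is empty or contains a non-standard letter; the
        message names the offending position and character.
    """
    if not sequence:
        raise ValidationError("empty sequence: cannot compute molecular weight")
    seq = sequence.upper()
    for pos, ch in enumerate(seq):
        if ch not in _STANDARD_AA:
            raise ValidationError(
                f"unknown amino-acid letter {ch!r} at position {pos} "
                f"(only the 20 standard residues are supported)"
            )
    return molecular_weight(seq, seq_type="protein", monoisotopic=False) / 1000.0
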