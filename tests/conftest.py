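import pytest

from cofrac.models import (
    Experiment,
    FractionObservation,
    FractionTable,
    ProteinRecord,
)


def make_experiment(proteins: dict[str, float], fractions: list[tuple[float, dict[str, float]]]) -> Experiment:
    """Build an Experiment from {accession: mw_kda} and
    [(mean_mw_kda, {accession: empai}), ...] (any fraction order)."""
    records = {acc: ProteinRecord(acc, mw) for acc, mw in proteins.items()}
    tables = [
        FractionTable(
            f"F{mw:g}",
            mw,
            tuple(FractionObservation(acc, e) for acc, e in sorted(obs.items())),
        )
        for mw, obs in sorted(fractions, key=lambda t: -t[0])
    ]
    return Experiment(proteins=records, fractions=tables)


@pytest.fixture
def simple_experiment() -> Experiment:
    """Four proteins over three fractions; (A, B) sums to the 45-kDa fraction."""
    return make_experiment(
        {"A": 20.0, "B": 25.0, "C": 30.0, "D": 44.8},
        [
            (90.0, {"C": 1.0, "D": 0.8}),
            (45.0, {"A": 1.0, "B": 1.2, "C": 0.2, "D": 2.0}),
            (22.0, {"A": 0.5, "B": 0.4}),
        ],
    )


@pytest.fixture
def fraction_file(tmp_path):
    """Write a fraction table file from header + rows; returns the path."""

    def _write(text: str, name: str = "frac.tsv"):
        path = tmp_path / name
        path.write_text(text, encoding="utf-8")
        return path

    return _write
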