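"""Fraction-table / manifest parsing, calibration, sequence MW, distribution matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cofrac.calibration import calibrate_column
from cofrac.datasets import experiment_from_bin_counts, load_reference_distribution
from cofrac.errors import (
    FormatError,
    InsufficientDataError,
    ValidationError,
)
from cofrac.io import (
    load_experiment,
    read_fraction_table,
    read_protein_records,
    write_fraction_table,
)
from cofrac.matrix import build_distribution_matrix
from cofrac.models import Calibration, Experiment, ProteinRecord
from cofrac.sequences import mw_from_sequence
from conftest import make_experiment

WELL_FORMED = (
    "# a comment line\n"
    "accession\tname\tmw_kda\tempai\n"
    "P00167\tcytochrome b5\t15.3\t0.4\n"
    "P04040\tcatalase\t59.8\t1.2\n"
    "Q16851\tUGP2\t56.9\t0.9\n"
)


class TestFractionTable:
    def test_well_formed_file(self, fraction_file):
        table = read_fraction_table(fraction_file(WELL_FORMED), "F1", 48.0)
        assert len(table.observations) == 3
        assert table.empai_of("P04040") == 1.2
        records = read_protein_records(fraction_file(WELL_FORMED))
        assert records["P00167"].mw_kda == 15.3
        assert records["P00167"].name == "cytochrome b5"

    def test_duplicate_accession_named(self, fraction_file):
        text = WELL_FORMED + "P00167\tdup\t15.3\t0.1\n"
        with pytest.raises(ValidationError, match="P00167"):
            read_fraction_table(fraction_file(text), "F1", 48.0)

    def test_empai_computed_from_peptide_counts(self, fraction_file):
        text = (
            "accession\tname\tmw_kda\tn_observed\tn_observable\n"
            "P1\tx\t20.0\t3\t10\n"
        )
        table = read_fraction_table(fraction_file(text), "F1", 45.0)
        assert table.empai_of("P1") == pytest.approx(10**0.3 - 1)

    def test_missing_required_column_is_format_error(self, fraction_file):
        with pytest.raises(FormatError, match="empai"):
            read_fraction_table(
                fraction_file("accession\tmw_kda\nP1\t20\n"), "F1", 45.0
            )

    def test_non_numeric_mw_reported_with_line_number(self, fraction_file):
        text = "accession\tmw_kda\tempai\nP1\ttwenty\t0.5\n"
        with pytest.raises(ValidationError, match="line 2"):
            read_fraction_table(fraction_file(text), "F1", 45.0)

    def test_dalton_like_values_rejected_without_declaration(self, fraction_file):
        text = "accession\tmw_kda\tempai\nP1\t15300\t0.5\n"
        with pytest.raises(ValidationError, match="Da"):
            read_fraction_table(fraction_file(text), "F1", 45.0)
        # explicit Da units convert instead
        table = read_fraction_table(fraction_file(text), "F1", 45.0, mw_units="Da")
        assert read_protein_records(fraction_file(text), mw_units="Da")["P1"].mw_kda == 15.3
        assert len(table.observations) == 1

    def test_round_trip_is_bit_identical(self, fraction_file, tmp_path):
        path = fraction_file(WELL_FORMED)
        table = read_fraction_table(path, "F1", 48.0)
        proteins = read_protein_records(path)
        out1 = tmp_path / "out1.tsv"
        out2 = tmp_path / "out2.tsv"
        write_fraction_table(table, proteins, out1)
        table2 = read_fraction_table(out1, "F1", 48.0)
        write_fraction_table(table2, read_protein_records(out1), out2)
        assert out1.read_bytes() == out2.read_bytes()
        assert table2 == table


class TestManifest:
    def test_load_experiment_sorts_fractions_by_elution(self, tmp_path):
        for name, mw in [("a.tsv", 45.0), ("b.tsv", 90.0)]:
            (tmp_path / name).write_text(
                "accession\tname\tmw_kda\tempai\nP1\tx\t20.0\t0.5\n"
            )
        (tmp_path / "manifest.tsv").write_text(
            "fraction_id\tpath\tmean_mw_kda\nf45\ta.tsv\t45\nf90\tb.tsv\t90\n"
        )
        exp = load_experiment(tmp_path / "manifest.tsv")
        assert [f.mean_mw_kda for f in exp.fractions] == [90.0, 45.0]
        assert exp.grid == [45.0, 90.0]

    def test_inconsistent_mw_across_fractions_rejected(self, tmp_path):
        (tmp_path / "a.tsv").write_text("accession\tmw_kda\tempai\nP1\t20.0\t0.5\n")
        (tmp_path / "b.tsv").write_text("accession\tmw_kda\tempai\nP1\t35.0\t0.5\n")
        (tmp_path / "manifest.tsv").write_text(
            "fraction_id\tpath\tmean_mw_kda\nf45\ta.tsv\t45\nf90\tb.tsv\t90\n"
        )
        with pytest.raises(ValidationError, match="P1"):
            load_experiment(tmp_path / "manifest.tsv")


class TestCalibration:
    def test_exact_log_linear_fit_recovered(self):
        volumes = [40.0, 55.0, 70.0, 85.0]
        standards = [(v, 10 ** (4 - 0.02 * v)) for v in volumes]
        cal = calibrate_column(standards)
        assert cal.slope == pytest.approx(-0.02, rel=1e-9)
        assert cal.intercept == pytest.approx(4.0, rel=1e-9)
        # prediction at a knot returns the standard's MW
        assert cal.predict_mw(55.0) == pytest.approx(10 ** (4 - 1.1), rel=1e-9)
        assert cal.valid_range == (40.0, 85.0)

    def test_noisy_standards_recover_slope_within_error(self):
        rng = np.random.default_rng(7)
        volumes = np.linspace(40, 110, 8)
        logmw = 4 - 0.02 * volumes + rng.normal(0, 0.01, 8)
        cal = calibrate_column(list(zip(volumes, 10**logmw)))
        # independent oracle: numpy least-squares fit
        slope_ref, intercept_ref = np.polyfit(volumes, logmw, 1)
        assert cal.slope == pytest.approx(slope_ref, rel=1e-9)
        assert cal.intercept == pytest.approx(intercept_ref, rel=1e-9)
        assert abs(cal.slope - (-0.02)) < 3 * cal.stderr

    def test_too_few_standards(self):
        with pytest.raises(InsufficientDataError):
            calibrate_column([(40, 400.0), (80, 20.0)])

    def test_positive_slope_rejected(self):
        standards = [(v, 10 ** (1 + 0.02 * v)) for v in (40.0, 60.0, 80.0)]
        with pytest.warns(UserWarning, match="not monotone"), pytest.raises(ValidationError):
            calibrate_column(standards)

    def test_non_monotone_standards_warn(self):
        standards = [(40.0, 400.0), (60.0, 500.0), (80.0, 20.0), (100.0, 5.0)]
        with pytest.warns(UserWarning, match="not monotone"):
            calibrate_column(standards)

    def test_extrapolation_flagged(self):
        cal = Calibration(slope=-0.02, intercept=4.0, valid_range=(40.0, 85.0))
        with pytest.warns(UserWarning, match="extrapolation"):
            cal.predict_mw(120.0)


class TestSequenceMW:
    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            mw_from_sequence("")

    def test_glycine(self):
        # glycine residue 57.05 Da + one water 18.02 Da
        assert mw_from_sequence("G") == pytest.approx(0.07507, abs=1e-4)

    def test_unknown_letter_names_position(self):
        with pytest.raises(ValidationError, match=r"'Z' at position 2"):
            mw_from_sequence("GGZ")

    @settings(derandomize=True, max_examples=100)
    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=1, max_size=30))
    def test_additive_over_concatenation(self, seq):
        """Chain mass is additive over residues up to one water term."""
        water = 0.0180153
        total = mw_from_sequence(seq + "G")
        assert total == pytest.approx(
            mw_from_sequence(seq) + mw_from_sequence("G") - water, abs=1e-6
        )

    def test_protein_record_mw_sequence_consistency(self):
        seq = "ACDEFGHIKLMNPQRSTVWY"
        mw = mw_from_sequence(seq)
        rec = ProteinRecord("P1", sequence=seq)  # MW computed from sequence
        assert rec.mw_kda == pytest.approx(mw)
        with pytest.raises(ValidationError, match="disagrees"):
            ProteinRecord("P1", mw_kda=mw * 1.05, sequence=seq)


class TestDistributionMatrix:
    def test_empty_experiment_all_zero(self):
        dm = build_distribution_matrix(Experiment(proteins={}, fractions=[]))
        assert dm.counts.size == 0 or not dm.counts.any()
        assert dm.totals.tolist() == []

    def test_direct_binning(self):
        exp = make_experiment(
            {"A": 10.0, "B": 15.0, "C": 25.0},
            [(30.0, {"A": 1.0, "B": 1.0, "C": 1.0})],
        )
        dm = build_distribution_matrix(exp, bin_edges=[0, 11, 21, 31])
        assert dm.counts[:, 0].tolist() == [1, 1, 1]
        assert dm.totals.tolist() == [3]

    def test_half_open_bins(self):
        exp = make_experiment({"A": 11.0, "B": 21.0}, [(30.0, {"A": 1.0, "B": 1.0})])
        dm = build_distribution_matrix(exp, bin_edges=[0, 11, 21, 31])
        assert dm.counts[:, 0].tolist() == [0, 1, 1]  # 11 goes to [11,21)

    def test_reference_matrix_column_totals(self):
        """The packaged liver-lysate matrix reproduces its printed totals."""
        exp = experiment_from_bin_counts(load_reference_distribution())
        dm = build_distribution_matrix(exp)
        totals = dict(zip(dm.fraction_mws, dm.totals.tolist()))
        assert totals[400.0] == 540
        assert totals[48.0] == 406
        assert totals[290.0] == 548
        assert totals[130.0] == 322
        assert totals[60.0] == 330

    def test_out_of_range_protein_reported_unbinned(self):
        exp = make_experiment({"A": 800.0, "B": 20.0}, [(400.0, {"A": 1.0, "B": 1.0})])
        dm = build_distribution_matrix(exp)
        assert dm.unbinned == {"F400": ["A"]}
        assert dm.totals.tolist() == [1]

    def test_band_summary_flags_heavier_than_fraction(self):
        exp = make_experiment(
            {"light": 15.0, "at": 45.0, "heavy": 90.0},
            [(45.0, {"light": 1.0, "at": 1.0, "heavy": 1.0})],
        )
        band = build_distribution_matrix(exp).band_summary().iloc[0]
        assert band["below"] == 1 and band["at"] == 1 and band["above"] == 1

    @settings(derandomize=True, max_examples=50)
    @given(st.data())
    def test_column_totals_equal_distinct_protein_counts(self, data):
        """Matrix invariant on random experiments (proteins within bin range)."""
        n = data.draw(st.integers(1, 20))
        mws = data.draw(
            st.lists(st.floats(1.0, 700.0, exclude_max=True), min_size=n, max_size=n)
        )
        proteins = {f"P{i}": mw for i, mw in enumerate(mws)}
        n_fracs = data.draw(st.integers(1, 4))
        fractions = []
        for j in range(n_fracs):
            members = data.draw(st.sets(st.sampled_from(sorted(proteins)), min_size=0))
            fractions.append((400.0 - 50.0 * j, {acc: 1.0 for acc in members}))
        exp = make_experiment(proteins, fractions)
        dm = build_distribution_matrix(exp)
        expected = [len(f.accessions) for f in exp.fractions]
        assert dm.totals.tolist() == expected
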