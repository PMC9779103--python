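"""Readers and writers for fraction tables, manifests and sequences.

File formats (all plain text, UTF-8, ``#`` comment lines ignored):

* **Fraction table** — tab-separated with a header row naming at least
  ``accession``, ``mw_kda`` and either ``empai`` or the pair
  ``n_observed``/``n_observable`` (emPAI is then computed); ``name`` and
  ``score`` are optional.
* **Experiment manifest** — tab-separated with header ``fraction_id``,
  ``path``, ``mean_mw_kda``, one fraction per row, paths relative to the
  manifest. A directive comment ``# units: Da`` declares that MW columns
  in the fraction files are daltons; without it, values that look like
  daltons are rejected rather than silently misread.
* **Calibration standards** — two tab-separated columns:
  elution_volume_mL, mw_kda.
* **FASTA** — protein sequences; the accession is the first
  whitespace-delimited token of each header.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

from Bio import SeqIO

from .abundance import compute_empai
from .errors import FormatError, ValidationError
from .models import Experiment, FractionObservation, FractionTable, ProteinRecord

#: kDa values above this look like daltons; refused unless units are declared.
_SUSPICIOUS_KDA = 5000.0

_REQUIRED = ("accession", "mw_kda")


def _read_rows(path: str | Path) -> tuple[list[str], list[tuple[int, list[str]]]]:
    """Header fields and (line_number, fields) rows, skipping comments/blanks."""
    header: list[str] | None = None
    rows: list[tuple[int, list[str]]] = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = [f.strip() for f in fields]
            else:
                rows.append((lineno, fields))
    if header is None:
        raise FormatError(f"{path}: no header row found")
    return header, rows


def _parse_fraction_rows(
    path: str | Path, mw_units: str = "kDa"
) -> list[dict[str, object]]:
    """Parse and validate rows of a fraction table; report bad rows by line."""
    if mw_units not in ("kDa", "Da"):
        raise ValidationError(f"mw units must be 'kDa' or 'Da', got {mw_units!r}")
    header, rows = _read_rows(path)
    missing = [c for c in _REQUIRED if c not in header]
    has_empai = "empai" in header
    has_counts = "n_observed" in header and "n_observable" in header
    if not (has_empai or has_counts):
        missing.append("empai (or n_observed + n_observable)")
    if missing:
        raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")

    idx = {name: i for i, name in enumerate(header)}
    scale = 1e-3 if mw_units == "Da" else 1.0
    parsed: list[dict[str, object]] = []
    errors: list[str] = []
    seen: set[str] = set()
    for lineno, fields in rows:
        if len(fields) < len(header):
            errors.append(f"line {lineno}: expected {len(header)} fields, got {len(fields)}")
            continue
        acc = fields[idx["accession"]].strip()
        if not acc:
            errors.append(f"line {lineno}: empty accession")
            continue
        if acc in seen:
            raise ValidationError(f"{path}: duplicate accession {acc} (line {lineno})")
        seen.add(acc)
        try:
            mw = float(fields[idx["mw_kda"]]) * scale
        except ValueError:
            errors.append(f"line {lineno}: non-numeric mw_kda {fields[idx['mw_kda']]!r}")
            continue
        if mw_units == "kDa" and mw > _SUSPICIOUS_KDA:
            errors.append(
                f"line {lineno}: mw_kda {mw:g} looks like daltons; declare "
                f"'# units: Da' in the manifest if MWs are in Da"
            )
            continue
        try:
            if has_empai:
                empai = float(fields[idx["empai"]])
            else:
                empai = compute_empai(
                    int(fields[idx["n_observed"]]), int(fields[idx["n_observable"]])
                )
        except (ValueError, ValidationError) as exc:
            errors.append(f"line {lineno}: bad abundance value ({exc})")
            continue
        name = fields[idx["name"]].strip() if "name" in idx else ""
        score = None
        if "score" in idx and fields[idx["score"]].strip():
            try:
                score = float(fields[idx["score"]])
            except ValueError:
                errors.append(f"line {lineno}: non-numeric score")
                continue
        parsed.append(
            {"accession": acc, "name": name, "mw_kda": mw, "empai": empai, "score": score}
        )
    if errors:
        raise ValidationError(f"{path}: {len(errors)} invalid row(s):\n  " + "\n  ".join(errors))
    return parsed


def read_fraction_table(
    path: str | Path,
    fraction_id: str,
    mean_mw_kda: float,
    mw_units: str = "kDa",
) -> FractionTable:
    """Read one fraction's identification table into a FractionTable."""
    rows = _parse_fraction_rows(path, mw_units)
    observations = tuple(
        FractionObservation(r["accession"], r["empai"], r["score"]) for r in rows
    )
    return FractionTable(fraction_id, mean_mw_kda, observations)


def read_protein_records(
    path: str | Path, mw_units: str = "kDa"
) -> dict[str, ProteinRecord]:
    """Protein metadata (accession, name, MW) carried by a fraction file."""
    rows = _parse_fraction_rows(path, mw_units)
    return {
        r["accession"]: ProteinRecord(r["accession"], r["mw_kda"], r["name"])
        for r in rows
    }


def write_fraction_table(
    table: FractionTable,
    proteins: dict[str, ProteinRecord],
    path: str | Path,
) -> None:
    """Write a fraction table in the canonical dialect (round-trip stable)."""
    lines = ["accession\tname\tmw_kda\tempai"]
    for obs in table.observations:
        rec = proteins[obs.accession]
        lines.append(f"{obs.accession}\t{rec.name}\t{rec.mw_kda!r}\t{obs.empai!r}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


@dataclass(frozen=True)
class ManifestEntry:
    fraction_id: str
    path: Path
    mean_mw_kda: float


def read_manifest(path: str | Path) -> tuple[list[ManifestEntry], str]:
    """Parse an experiment manifest; returns entries and the declared MW units."""
    path = Path(path)
    units = "kDa"
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            stripped = line.strip()
            if stripped.lower().replace(" ", "") in ("#units:da", "#units=da"):
                units = "Da"
    header, rows = _read_rows(path)
    for col in ("fraction_id", "path", "mean_mw_kda"):
        if col not in header:
            raise FormatError(f"{path}: manifest missing column {col!r}")
    idx = {name: i for i, name in enumerate(header)}
    entries = []
    for lineno, fields in rows:
        try:
            mw = float(fields[idx["mean_mw_kda"]])
        except ValueError:
            raise FormatError(f"{path} line {lineno}: non-numeric mean_mw_kda") from None
        entries.append(
            ManifestEntry(
                fraction_id=fields[idx["fraction_id"]].strip(),
                path=path.parent / fields[idx["path"]].strip(),
                mean_mw_kda=mw,
            )
        )
    return entries, units


def read_fasta_sequences(path: str | Path) -> dict[str, str]:
    """Accession → sequence from a FASTA file (first header token)."""
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def load_experiment(
    manifest_path: str | Path, fasta_path: str | Path | None = None
) -> Experiment:
    """Load a whole experiment from its manifest.

    Fractions are sorted into elution order (descending mean MW). Protein
    records seen in several fractions must agree on MW within 1%; FASTA
    sequences, when provided, are attached and cross-checked against the
    declared MWs by the ProteinRecord invariant.
    """
    entries, units = read_manifest(manifest_path)
    entries = sorted(entries, key=lambda e: -e.mean_mw_kda)
    sequences = read_fasta_sequences(fasta_path) if fasta_path else {}

    proteins: dict[str, ProteinRecord] = {}
    fractions: list[FractionTable] = []
    for entry in entries:
        fractions.append(
            read_fraction_table(entry.path, entry.fraction_id, entry.mean_mw_kda, units)
        )
        for acc, rec in read_protein_records(entry.path, units).items():
            if acc in proteins:
                prev = proteins[acc]
                if not math.isclose(prev.mw_kda, rec.mw_kda, rel_tol=0.01):
                    raise ValidationError(
                        f"{acc}: inconsistent MW across fractions "
                        f"({prev.mw_kda:g} vs {rec.mw_kda:g} kDa)"
                    )
            else:
                proteins[acc] = ProteinRecord(
                    acc, rec.mw_kda, rec.name, sequences.get(acc)
                )
    return Experiment(proteins=proteins, fractions=fractions)


def read_calibration_standards(path: str | Path) -> list[tuple[float, float]]:
    """(elution_volume_mL, mw_kda) pairs from a two-column TSV."""
    header, rows = _read_rows(path)
    cols = [c.lower() for c in header]
    try:
        vi = cols.index("elution_volume_ml")
        mi = cols.index("mw_kda")
    except ValueError:
        # headerless two-column file: treat the "header" as data
        rows = [(1, header)] + rows
        vi, mi = 0, 1
    standards = []
    for lineno, fields in rows:
        try:
            standards.append((float(fields[vi]), float(fields[mi])))
        except (ValueError, IndexError):
            raise FormatError(
                f"{path} line {lineno}: expected two numeric columns"
            ) from None
    return standards
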