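"""Readers and writers for the pipeline's external artifacts.

Four formats cross the package boundary: protein databases (standard
FASTA), per-run PSM tables (a documented tab-separated dialect carrying
the SEQUEST-style fields the downstream filter needs), run manifests
(TSV: run_id, condition, replicate, role, elution_pool) and the merged
protein report (TSV, one protein per row with per-run spectral counts
and NSAF values).

The PSM dialect is deliberately plain: a header row naming
``spectrum_id, peptide, prev_aa, next_aa, charge, xcorr, deltcn,
sp_rank, proteins`` and one match per data row, with multiple protein
accessions joined by ``;``. Flanking residues use ``-`` for a protein
terminus, the usual SEQUEST convention.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass
from pathlib import Path
from typing import TYPE_CHECKING, Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

if TYPE_CHECKING:  # pragma: no cover
    from copurify.merge_cluster import AbundanceMatrix

DEFAULT_DECOY_PREFIX = "shuffled_"
ACCESSION_DELIMITER = ";"
TERMINUS = "-"

PSM_COLUMNS = (
    "spectrum_id",
    "peptide",
    "prev_aa",
    "next_aa",
    "charge",
    "xcorr",
    "deltcn",
    "sp_rank",
    "proteins",
)

MANIFEST_COLUMNS = ("run_id", "condition", "replicate", "role", "elution_pool")

ROLES = ("bait", "control")


class FormatError(ValueError):
    """Raised when an external artifact violates its documented format."""


@dataclass(frozen=True)
class ProteinEntry:
    """One database sequence.

    ``length`` (used as the NSAF length normalizer) is derived from the
    sequence; ``is_decoy`` marks shuffled entries recognized by their
    accession prefix.
    """

    accession: str
    description: str
    sequence: str
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise FormatError(f"protein {self.accession!r} has an empty sequence")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PsmRecord:
    """One peptide-spectrum match with its search scores.

    ``prev_aa``/``next_aa`` are the residues flanking the peptide in the
    protein ("-" at a protein terminus); they drive the fully-tryptic
    test. ``protein_accessions`` lists every database entry the peptide
    maps to (shared peptides map to several).
    """

    spectrum_id: str
    peptide: str
    prev_aa: str
    next_aa: str
    charge: int
    xcorr: float
    deltcn: float
    sp_rank: int
    protein_accessions: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.peptide:
            raise FormatError(f"PSM {self.spectrum_id!r} has an empty peptide")
        if not self.protein_accessions:
            raise FormatError(f"PSM {self.spectrum_id!r} maps to no protein")


@dataclass(frozen=True)
class RunManifestEntry:
    run_id: str
    condition: str
    replicate: str
    role: str
    elution_pool: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise FormatError(
                f"run {self.run_id!r}: role must be one of {ROLES}, got {self.role!r}"
            )


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> list[ProteinEntry]:
    """Read a protein FASTA into :class:`ProteinEntry` records.

    Wrapped sequence lines are concatenated; an entry is a decoy iff its
    accession starts with ``decoy_prefix``. Duplicate accessions and
    empty files are format errors.
    """
    entries: list[ProteinEntry] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        accession = record.id
        if accession in seen:
            raise FormatError(f"duplicate accession {accession!r} in {path}")
        seen.add(accession)
        description = record.description[len(accession):].strip()
        entries.append(
            ProteinEntry(
                accession=accession,
                description=description,
                sequence=str(record.seq).upper(),
                is_decoy=accession.startswith(decoy_prefix),
            )
        )
    if not entries:
        raise FormatError(f"no FASTA records found in {path}")
    return entries


def write_fasta(entries: Iterable[ProteinEntry], path: str | Path, width: int = 60) -> None:
    records = [
        SeqRecord(Seq(e.sequence), id=e.accession, description=e.description)
        for e in entries
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(records)


# ---------------------------------------------------------------------------
# PSM tables


def read_psm_table(path: str | Path) -> list[PsmRecord]:
    """Parse a PSM TSV, preserving row order.

    Errors name the offending column or the 1-based data-row number so a
    malformed export is diagnosable without opening the file.
    """
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty PSM table")
        missing = [c for c in PSM_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing required column(s): {', '.join(missing)}")
        records: list[PsmRecord] = []
        for row_number, row in enumerate(reader, start=1):
            try:
                charge = int(row["charge"])
                xcorr = float(row["xcorr"])
                deltcn = float(row["deltcn"])
                sp_rank = int(row["sp_rank"])
            except (TypeError, ValueError) as exc:
                raise FormatError(
                    f"{path}: unparseable numeric field in data row {row_number}: {exc}"
                ) from exc
            accessions = tuple(
                a for a in row["proteins"].split(ACCESSION_DELIMITER) if a
            )
            records.append(
                PsmRecord(
                    spectrum_id=row["spectrum_id"],
                    peptide=row["peptide"],
                    prev_aa=row["prev_aa"],
                    next_aa=row["next_aa"],
                    charge=charge,
                    xcorr=xcorr,
                    deltcn=deltcn,
                    sp_rank=sp_rank,
                    protein_accessions=accessions,
                )
            )
    return records


def write_psm_table(psms: Iterable[PsmRecord], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(PSM_COLUMNS)
        for p in psms:
            writer.writerow(
                [
                    p.spectrum_id,
                    p.peptide,
                    p.prev_aa,
                    p.next_aa,
                    p.charge,
                    repr(p.xcorr),
                    repr(p.deltcn),
                    p.sp_rank,
                    ACCESSION_DELIMITER.join(p.protein_accessions),
                ]
            )


# ---------------------------------------------------------------------------
# Run manifests


def read_manifest(path: str | Path) -> list[RunManifestEntry]:
    with open(path, newline="") as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None:
            raise FormatError(f"{path}: empty manifest")
        missing = [c for c in MANIFEST_COLUMNS if c not in reader.fieldnames]
        if missing:
            raise FormatError(f"{path}: missing manifest column(s): {', '.join(missing)}")
        entries = [
            RunManifestEntry(
                run_id=row["run_id"],
                condition=row["condition"],
                replicate=row["replicate"],
                role=row["role"],
                elution_pool=row["elution_pool"],
            )
            for row in reader
        ]
    ids = [e.run_id for e in entries]
    if len(ids) != len(set(ids)):
        dup = next(i for i in ids if ids.count(i) > 1)
        raise FormatError(f"{path}: duplicate run_id {dup!r}")
    return entries


def write_manifest(entries: Iterable[RunManifestEntry], path: str | Path) -> None:
    with open(path, "w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(MANIFEST_COLUMNS)
        for e in entries:
            writer.writerow([e.run_id, e.condition, e.replicate, e.role, e.elution_pool])


# ---------------------------------------------------------------------------
# Merged protein report


def write_report(matrix: "AbundanceMatrix", path: str | Path) -> None:
    """Write the merged protein report: one row per protein, per-run
    spectral count and NSAF columns, pooled peptide count and coverage.

    Run annotations (condition, role) are carried in ``#`` header lines
    so the report round-trips through :func:`read_report` losslessly.
    Floats are written at full ``repr`` precision.
    """
    if not matrix.accessions or not matrix.run_ids:
        raise FormatError("cannot write a report for an empty abundance matrix")
    with open(path, "w", newline="") as handle:
        for run_id in matrix.run_ids:
            handle.write(
                f"# run\t{run_id}\t{matrix.condition_of[run_id]}\t{matrix.role_of[run_id]}\n"
            )
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        header = (
            ["accession"]
            + [f"spc:{r}" for r in matrix.run_ids]
            + [f"nsaf:{r}" for r in matrix.run_ids]
            + ["peptide_count", "coverage_pct"]
        )
        writer.writerow(header)
        for i, accession in enumerate(matrix.accessions):
            spc_row = (
                matrix.spectral_counts[i, :]
                if matrix.spectral_counts is not None
                else [0] * len(matrix.run_ids)
            )
            writer.writerow(
                [accession]
                + [int(c) for c in spc_row]
                + [repr(float(v)) for v in matrix.nsaf[i, :]]
                + [
                    matrix.peptide_count.get(accession, 0),
                    repr(float(matrix.coverage_pct.get(accession, 0.0))),
                ]
            )


def read_report(path: str | Path) -> "AbundanceMatrix":
    """Read a report written by :func:`write_report` back into an
    :class:`~copurify.merge_cluster.AbundanceMatrix`."""
    import numpy as np

    from copurify.merge_cluster import AbundanceMatrix

    condition_of: dict[str, str] = {}
    role_of: dict[str, str] = {}
    body = io.StringIO()
    with open(path, newline="") as handle:
        for line in handle:
            if line.startswith("# run\t"):
                _, run_id, condition, role = line.rstrip("\n").split("\t")
                condition_of[run_id] = condition
                role_of[run_id] = role
            else:
                body.write(line)
    body.seek(0)
    reader = csv.reader(body, delimiter="\t")
    header = next(reader, None)
    if header is None:
        raise FormatError(f"{path}: empty report")
    run_ids = [c[len("spc:"):] for c in header if c.startswith("spc:")]
    n_runs = len(run_ids)
    accessions: list[str] = []
    spc_rows: list[list[int]] = []
    nsaf_rows: list[list[float]] = []
    peptide_count: dict[str, int] = {}
    coverage_pct: dict[str, float] = {}
    for row in reader:
        accessions.append(row[0])
        spc_rows.append([int(v) for v in row[1 : 1 + n_runs]])
        nsaf_rows.append([float(v) for v in row[1 + n_runs : 1 + 2 * n_runs]])
        peptide_count[row[0]] = int(row[1 + 2 * n_runs])
        coverage_pct[row[0]] = float(row[2 + 2 * n_runs])
    return AbundanceMatrix(
        accessions=accessions,
        run_ids=run_ids,
        nsaf=np.asarray(nsaf_rows, dtype=float),
        condition_of=condition_of,
        role_of=role_of,
        spectral_counts=np.asarray(spc_rows, dtype=int),
        peptide_count=peptide_count,
        coverage_pct=coverage_pct,
    )
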