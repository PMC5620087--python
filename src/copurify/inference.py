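"""Protein-level evidence assembly and parsimonious inference.

Filtered PSMs are tallied into per-protein evidence (distinct peptides,
spectral count, sequence coverage). A protein is then retained only if
it was seen with at least two distinct peptides, or one peptide backed
by two independent spectra; proteins whose peptide set is a proper
subset of another's are removed, and proteins with identical peptide
sets are merged into one group reported under the lexicographically
smallest accession. Spectra of shared peptides count toward every
mapped protein (whole counts, no fractional splitting).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

from copurify.formats_io import ProteinEntry, PsmRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ProteinEvidence:
    accession: str
    peptide_set: frozenset[str]
    spectral_count: int
    coverage_pct: float
    is_decoy: bool
    group_members: tuple[str, ...] = ()

    @property
    def peptide_count(self) -> int:
        return len(self.peptide_set)


def _coverage(sequence: str, peptides: Iterable[str], accession: str) -> float:
    """Percent of residues covered by the union of peptide occurrences.

    Every occurrence of a peptide contributes; a peptide not found in
    the claimed sequence is excluded from coverage (but its spectra were
    already counted) and logged.
    """
    covered = bytearray(len(sequence))
    for peptide in peptides:
        start = sequence.find(peptide)
        if start < 0:
            logger.warning(
                "peptide %r not found in protein %s; excluded from coverage",
                peptide,
                accession,
            )
            continue
        while start >= 0:
            covered[start : start + len(peptide)] = b"\x01" * len(peptide)
            start = sequence.find(peptide, start + 1)
    return 100.0 * sum(covered) / len(sequence)


def assemble(
    psms: Sequence[PsmRecord], db: Sequence[ProteinEntry]
) -> list[ProteinEvidence]:
    """Tally filtered PSMs into per-protein evidence, sorted by accession."""
    by_accession = {e.accession: e for e in db}
    spectra: dict[str, int] = {}
    peptides: dict[str, set[str]] = {}
    for psm in psms:
        for accession in psm.protein_accessions:
            if accession not in by_accession:
                raise ValueError(
                    f"PSM {psm.spectrum_id!r} maps to unknown accession {accession!r}"
                )
            spectra[accession] = spectra.get(accession, 0) + 1
            peptides.setdefault(accession, set()).add(psm.peptide)
    evidence = []
    for accession in sorted(spectra):
        entry = by_accession[accession]
        peps = peptides[accession]
        evidence.append(
            ProteinEvidence(
                accession=accession,
                peptide_set=frozenset(peps),
                spectral_count=spectra[accession],
                coverage_pct=_coverage(entry.sequence, sorted(peps), accession),
                is_decoy=entry.is_decoy,
            )
        )
    return evidence


def apply_evidence_rule(evidence: Sequence[ProteinEvidence]) -> list[ProteinEvidence]:
    """Keep proteins with >= 2 distinct peptides, or 1 peptide and >= 2 spectra."""
    return [
        e
        for e in evidence
        if e.peptide_count >= 2 or (e.peptide_count == 1 and e.spectral_count >= 2)
    ]


def remove_subset_proteins(
    evidence: Sequence[ProteinEvidence],
) -> list[ProteinEvidence]:
    """Drop proteins whose peptide set is a proper subset of another's.

    Proteins with *identical* peptide sets are first merged into a single
    group: the representative is the lexicographically smallest accession
    and all members are recorded in ``group_members``. Removal compares
    each group's peptide set against every other group's, which makes the
    operation idempotent and independent of input order, and guarantees
    every observed peptide stays attributable to a retained group.
    """
    groups: dict[frozenset[str], list[ProteinEvidence]] = {}
    for e in evidence:
        groups.setdefault(e.peptide_set, []).append(e)
    merged: list[ProteinEvidence] = []
    for peptide_set, members in groups.items():
        members.sort(key=lambda e: e.accession)
        representative = members[0]
        if len(members) > 1:
            representative = replace(
                representative,
                group_members=tuple(e.accession for e in members),
            )
        merged.append(representative)
    kept = [
        g
        for g in merged
        if not any(
            g.peptide_set < other.peptide_set for other in merged if other is not g
        )
    ]
    kept.sort(key=lambda e: e.accession)
    return kept
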