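"""Target-decoy false discovery rates.

Two display formulas, deliberately asymmetric:

    spectral FDR = 2 * decoy spectra / total spectra * 100
    protein  FDR =     decoy proteins / total proteins * 100

The factor 2 at the spectral level reflects the assumption that an
incorrect match is equally likely to hit a target or a decoy sequence,
so observed decoy spectra count for half the estimated false matches;
at the protein level the retained decoy proteins are reported as-is.
FDR here is *reported*, not used as a cutoff: retention is by the score
thresholds, and the achieved FDR characterizes them.

A PSM counts as a decoy hit iff every accession it maps to is a decoy
(the conventional treatment of peptides shared with a target).
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

from copurify.formats_io import DEFAULT_DECOY_PREFIX, PsmRecord

if TYPE_CHECKING:  # pragma: no cover
    from copurify.pipeline import RunResult

COMBINED_SCOPE = "combined"


@dataclass(frozen=True)
class FdrReport:
    scope: str
    spectral_fdr_pct: float
    protein_fdr_pct: float
    decoy_spectra: int
    total_spectra: int
    decoy_proteins: int
    total_proteins: int
    spectral_fdr_sd: float | None = None


def spectral_fdr(decoy_spectra: int, total_spectra: int) -> float:
    """Spectral-level FDR in percent: ``2 * decoy / total * 100``."""
    if total_spectra <= 0:
        raise ValueError("spectral FDR undefined for zero total spectra")
    if not 0 <= decoy_spectra <= total_spectra:
        raise ValueError("decoy spectra must lie in [0, total spectra]")
    return 2.0 * decoy_spectra / total_spectra * 100.0


def protein_fdr(decoy_proteins: int, total_proteins: int) -> float:
    """Protein-level FDR in percent: ``decoy / total * 100`` (no factor 2)."""
    if total_proteins <= 0:
        raise ValueError("protein FDR undefined for zero total proteins")
    if not 0 <= decoy_proteins <= total_proteins:
        raise ValueError("decoy proteins must lie in [0, total proteins]")
    return decoy_proteins / total_proteins * 100.0


def psm_is_decoy(psm: PsmRecord, decoy_prefix: str = DEFAULT_DECOY_PREFIX) -> bool:
    return all(a.startswith(decoy_prefix) for a in psm.protein_accessions)


def summarize_fdr(
    runs: Sequence["RunResult"], decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[FdrReport]:
    """Per-run FDR reports plus one combined report on pooled counts.

    The combined report also carries the across-run sample standard
    deviation of the per-run spectral FDRs (0 for a single run), the
    dispersion conventionally quoted next to a pooled spectral FDR.
    """
    if not runs:
        raise ValueError("summarize_fdr needs at least one run")
    reports: list[FdrReport] = []
    per_run_spectral: list[float] = []
    pooled = [0, 0, 0, 0]  # decoy spectra, total spectra, decoy proteins, total proteins
    for run in runs:
        decoy_spectra = sum(psm_is_decoy(p, decoy_prefix) for p in run.filtered_psms)
        total_spectra = len(run.filtered_psms)
        decoy_proteins = sum(e.is_decoy for e in run.evidence)
        total_proteins = len(run.evidence)
        s_fdr = spectral_fdr(decoy_spectra, total_spectra)
        p_fdr = protein_fdr(decoy_proteins, total_proteins) if total_proteins else 0.0
        per_run_spectral.append(s_fdr)
        pooled[0] += decoy_spectra
        pooled[1] += total_spectra
        pooled[2] += decoy_proteins
        pooled[3] += total_proteins
        reports.append(
            FdrReport(
                scope=run.run_id,
                spectral_fdr_pct=s_fdr,
                protein_fdr_pct=p_fdr,
                decoy_spectra=decoy_spectra,
                total_spectra=total_spectra,
                decoy_proteins=decoy_proteins,
                total_proteins=total_proteins,
            )
        )
    sd = statistics.stdev(per_run_spectral) if len(per_run_spectral) > 1 else 0.0
    reports.append(
        FdrReport(
            scope=COMBINED_SCOPE,
            spectral_fdr_pct=spectral_fdr(pooled[0], pooled[1]),
            protein_fdr_pct=protein_fdr(pooled[2], pooled[3]) if pooled[3] else 0.0,
            decoy_spectra=pooled[0],
            total_spectra=pooled[1],
            decoy_proteins=pooled[2],
            total_proteins=pooled[3],
            spectral_fdr_sd=sd,
        )
    )
    return reports
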