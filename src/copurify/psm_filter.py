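"""Spectrum/peptide retention rules.

A PSM survives when every rule holds: DeltCn at least 0.08, XCorr at
least the charge-dependent minimum (1.8 / 2.0 / 3.0 for 1+ / 2+ / 3+),
Sp rank at most 10, peptide at least seven residues, and both peptide
termini tryptic. Thresholds are inclusive. Charges without an explicit
XCorr threshold fall back to the highest charge present in the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from copurify.formats_io import TERMINUS, PsmRecord

_DEFAULT_XCORR = {1: 1.8, 2: 2.0, 3: 3.0}


@dataclass(frozen=True)
class FilterCriteria:
    min_deltcn: float = 0.08
    min_xcorr_by_charge: Mapping[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_XCORR)
    )
    max_sp_rank: int = 10
    min_peptide_length: int = 7
    require_fully_tryptic: bool = True

    def __post_init__(self) -> None:
        if not self.min_xcorr_by_charge:
            raise ValueError("min_xcorr_by_charge must not be empty")
        if self.min_deltcn < 0 or self.max_sp_rank < 0 or self.min_peptide_length < 0:
            raise ValueError("filter thresholds must be nonnegative")
        if any(v < 0 for v in self.min_xcorr_by_charge.values()):
            raise ValueError("XCorr thresholds must be nonnegative")

    def xcorr_threshold(self, charge: int) -> float:
        try:
            return self.min_xcorr_by_charge[charge]
        except KeyError:
            return self.min_xcorr_by_charge[max(self.min_xcorr_by_charge)]


def is_fully_tryptic(psm: PsmRecord) -> bool:
    """True iff both peptide termini are tryptic.

    N-terminus: preceded by K/R (not followed by P, mirroring the
    digestion rule) or at the protein start. C-terminus: ends in K/R
    with the next residue not P, or at the protein end.
    """
    n_ok = psm.prev_aa == TERMINUS or (
        psm.prev_aa in ("K", "R") and not psm.peptide.startswith("P")
    )
    c_ok = psm.next_aa == TERMINUS or (
        psm.peptide[-1] in ("K", "R") and psm.next_aa != "P"
    )
    return n_ok and c_ok


def _passes(psm: PsmRecord, criteria: FilterCriteria) -> bool:
    if psm.deltcn < criteria.min_deltcn:
        return False
    if psm.xcorr < criteria.xcorr_threshold(psm.charge):
        return False
    if psm.sp_rank > criteria.max_sp_rank:
        return False
    if len(psm.peptide) < criteria.min_peptide_length:
        return False
    if criteria.require_fully_tryptic and not is_fully_tryptic(psm):
        return False
    return True


def filter_psms(
    psms: list[PsmRecord], criteria: FilterCriteria | None = None
) -> list[PsmRecord]:
    """Retain exactly the PSMs passing every criterion, in input order."""
    if criteria is None:
        criteria = FilterCriteria()
    return [p for p in psms if _passes(p, criteria)]
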