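"""Normalized spectral abundance factors.

For protein *i* in one run,

    NSAF_i = (SpC_i / L_i) / sum_k (SpC_k / L_k)

where SpC is the retained spectral count, L the protein length in
residues, and the sum runs over the proteins retained in that run. The
length division corrects the greater peptide yield of longer proteins;
the denominator makes NSAF a per-run molar-fraction-like share summing
to 1, comparable across runs of different depth. Decoy proteins are
excluded from the denominator by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

from copurify.formats_io import ProteinEntry
from copurify.inference import ProteinEvidence

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NsafVector:
    run_id: str
    values: dict[str, float] = field(default_factory=dict)
    spectral_counts: dict[str, int] = field(default_factory=dict)
    lengths: dict[str, int] = field(default_factory=dict)


def compute_nsaf(
    evidence: Sequence[ProteinEvidence],
    db: Sequence[ProteinEntry],
    run_id: str = "run",
    include_decoys: bool = False,
) -> NsafVector:
    """NSAF values for the retained proteins of one run."""
    lengths_by_accession = {e.accession: e.length for e in db}
    retained = [e for e in evidence if include_decoys or not e.is_decoy]
    if not retained:
        raise ValueError(f"run {run_id!r}: no retained proteins to normalize over")
    saf: dict[str, float] = {}
    lengths: dict[str, int] = {}
    counts: dict[str, int] = {}
    for e in retained:
        if e.accession not in lengths_by_accession:
            raise ValueError(f"no database length for accession {e.accession!r}")
        length = lengths_by_accession[e.accession]
        saf[e.accession] = e.spectral_count / length
        lengths[e.accession] = length
        counts[e.accession] = e.spectral_count
    total = sum(saf.values())
    if total <= 0:
        raise ValueError(f"run {run_id!r}: zero total spectral abundance")
    return NsafVector(
        run_id=run_id,
        values={a: s / total for a, s in saf.items()},
        spectral_counts=counts,
        lengths=lengths,
    )


def stoichiometry_ratios(vector: NsafVector, reference: str) -> dict[str, float]:
    """NSAF of each protein relative to a reference protein (ratio 1.0 for
    the reference itself). Zero-NSAF proteins are excluded with a warning."""
    if reference not in vector.values:
        raise ValueError(f"reference accession {reference!r} absent from run {vector.run_id!r}")
    ref = vector.values[reference]
    if ref <= 0:
        raise ValueError(f"reference {reference!r} has zero NSAF in run {vector.run_id!r}")
    ratios: dict[str, float] = {}
    for accession, value in vector.values.items():
        if value <= 0:
            logger.warning(
                "protein %s has zero NSAF in run %s; excluded from ratios",
                accession,
                vector.run_id,
            )
            continue
        ratios[accession] = value / ref
    return ratios
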