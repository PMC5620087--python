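"""Shuffled-decoy database construction and in-silico tryptic digestion.

Decoys are whole-sequence random permutations of target entries, so each
decoy preserves its target's length and residue composition — the decoy
population then has the same length distribution the NSAF normalizer and
the digestion statistics see for targets. Digestion follows the standard
trypsin rule: cleave C-terminal to K or R, suppressed when the next
residue is P.
"""

from __future__ import annotations

import re
import zlib

import numpy as np

from copurify.formats_io import DEFAULT_DECOY_PREFIX, ProteinEntry

# Zero-width match at every tryptic cleavage point.
_CLEAVAGE = re.compile(r"(?<=[KR])(?!P)")


class DecoyError(ValueError):
    """Raised on an attempt to shuffle an entry that is already a decoy."""


def _entry_rng(seed: int, accession: str) -> np.random.Generator:
    # Stable per-entry stream: the same (seed, accession) pair always
    # yields the same permutation, independent of database order.
    return np.random.default_rng([seed, zlib.crc32(accession.encode())])


def shuffle_entry(
    entry: ProteinEntry, seed: int, decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> ProteinEntry:
    """Return the shuffled decoy of a target entry.

    The decoy has the same length and per-residue counts as the target,
    in uniformly permuted order, and carries the decoy accession prefix.
    Deterministic for a given ``(entry, seed)``.
    """
    if entry.is_decoy:
        raise DecoyError(f"refusing to shuffle decoy entry {entry.accession!r}")
    rng = _entry_rng(seed, entry.accession)
    residues = np.frombuffer(entry.sequence.encode("ascii"), dtype=np.uint8)
    shuffled = rng.permutation(residues)
    return ProteinEntry(
        accession=decoy_prefix + entry.accession,
        description=entry.description,
        sequence=shuffled.tobytes().decode("ascii"),
        is_decoy=True,
    )


def build_decoy_database(
    db: list[ProteinEntry], seed: int, decoy_prefix: str = DEFAULT_DECOY_PREFIX
) -> list[ProteinEntry]:
    """Append one shuffled decoy per target: targets first, then decoys.

    The input must contain only targets; the output is twice its size.
    """
    if any(e.is_decoy for e in db):
        offender = next(e.accession for e in db if e.is_decoy)
        raise DecoyError(f"input database already contains decoy {offender!r}")
    decoys = [shuffle_entry(e, seed, decoy_prefix) for e in db]
    return list(db) + decoys


def digest(
    sequence: str, missed_cleavages: int = 0, min_length: int = 1
) -> list[tuple[str, int, int]]:
    """In-silico tryptic digestion.

    Returns ``(peptide, start, end)`` tuples with 1-based inclusive
    residue coordinates, including products with up to
    ``missed_cleavages`` internal cleavage sites, excluding peptides
    shorter than ``min_length``. The zero-missed-cleavage products
    concatenate back to the input sequence.
    """
    if not sequence:
        raise ValueError("cannot digest an empty sequence")
    if missed_cleavages < 0:
        raise ValueError("missed_cleavages must be >= 0")
    cut_points = [m.start() for m in _CLEAVAGE.finditer(sequence)]
    bounds = [0, *cut_points, len(sequence)]
    if bounds[-2] == bounds[-1]:  # sequence ends exactly at a cleavage site
        bounds.pop()
    peptides: list[tuple[str, int, int]] = []
    n_frag = len(bounds) - 1
    for i in range(n_frag):
        for j in range(i, min(i + missed_cleavages + 1, n_frag)):
            start, end = bounds[i], bounds[j + 1]
            if end - start >= min_length:
                peptides.append((sequence[start:end], start + 1, end))
    peptides.sort(key=lambda p: (p[1], p[2]))
    return peptides
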