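"""Run merging, control subtraction, condition intersection and NSAF
clustering.

Per-run NSAF vectors are merged into one proteins x runs matrix (zeros
for absence, column order following the manifest). Negative-control
runs are then used to strip nonspecific background; proteins not seen
in every immunopurification condition are dropped; and the surviving
NSAF profiles are clustered hierarchically so the proteins tightly
co-varying with the bait across runs — the candidate complex — can be
read off the tree.

Clustering defaults: per-row z-score transform, Pearson correlation
distance (1 - r), average linkage. Co-complex members share profile
*shape* across runs and conditions even when their stoichiometry
differs severalfold, which correlation distance captures and a
magnitude-based metric would not.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.cluster.hierarchy import leaves_list, linkage as scipy_linkage
from scipy.spatial.distance import squareform

from copurify.formats_io import RunManifestEntry
from copurify.quantify import NsafVector

logger = logging.getLogger(__name__)

MAX_CORRELATION_DISTANCE = 2.0


@dataclass
class AbundanceMatrix:
    """Proteins x runs NSAF matrix with run annotations.

    ``nsaf[i, j]`` is the NSAF of ``accessions[i]`` in ``run_ids[j]``;
    zero means not detected in that run. ``spectral_counts`` mirrors the
    shape; ``peptide_count``/``coverage_pct`` are pooled per-protein
    annotations for reporting.
    """

    accessions: list[str]
    run_ids: list[str]
    nsaf: np.ndarray
    condition_of: dict[str, str]
    role_of: dict[str, str]
    spectral_counts: np.ndarray | None = None
    peptide_count: dict[str, int] = field(default_factory=dict)
    coverage_pct: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.nsaf.shape != (len(self.accessions), len(self.run_ids)):
            raise ValueError(
                f"matrix shape {self.nsaf.shape} does not match "
                f"{len(self.accessions)} proteins x {len(self.run_ids)} runs"
            )

    def columns_with_role(self, role: str) -> list[int]:
        return [j for j, r in enumerate(self.run_ids) if self.role_of[r] == role]

    def select_rows(self, accessions: Sequence[str]) -> "AbundanceMatrix":
        """Row-subset the matrix, preserving this matrix's row order."""
        wanted = set(accessions)
        idx = [i for i, a in enumerate(self.accessions) if a in wanted]
        kept = [self.accessions[i] for i in idx]
        return AbundanceMatrix(
            accessions=kept,
            run_ids=list(self.run_ids),
            nsaf=self.nsaf[idx, :],
            condition_of=dict(self.condition_of),
            role_of=dict(self.role_of),
            spectral_counts=None
            if self.spectral_counts is None
            else self.spectral_counts[idx, :],
            peptide_count={a: self.peptide_count[a] for a in kept if a in self.peptide_count},
            coverage_pct={a: self.coverage_pct[a] for a in kept if a in self.coverage_pct},
        )

    def select_columns(self, column_idx: Sequence[int]) -> "AbundanceMatrix":
        kept_runs = [self.run_ids[j] for j in column_idx]
        return AbundanceMatrix(
            accessions=list(self.accessions),
            run_ids=kept_runs,
            nsaf=self.nsaf[:, list(column_idx)],
            condition_of={r: self.condition_of[r] for r in kept_runs},
            role_of={r: self.role_of[r] for r in kept_runs},
            spectral_counts=None
            if self.spectral_counts is None
            else self.spectral_counts[:, list(column_idx)],
            peptide_count=dict(self.peptide_count),
            coverage_pct=dict(self.coverage_pct),
        )


@dataclass(frozen=True)
class ClusterResult:
    """Agglomerative merge tree over proteins.

    ``linkage`` is a SciPy-format (n-1) x 4 matrix over ``accessions``
    (in the row order that was clustered); ``order`` is the dendrogram
    leaf ordering as accessions.
    """

    accessions: tuple[str, ...]
    linkage: np.ndarray
    order: tuple[str, ...]


def merge_runs(
    vectors: Sequence[NsafVector], manifest: Sequence[RunManifestEntry]
) -> AbundanceMatrix:
    """Merge per-run NSAF vectors into one matrix.

    Rows are the sorted union of accessions over runs (absences are
    structural zeros); columns follow manifest order, restricted to the
    runs actually supplied.
    """
    manifest_ids = [m.run_id for m in manifest]
    by_run = {}
    for v in vectors:
        if v.run_id not in manifest_ids:
            raise ValueError(f"NSAF vector for unknown run {v.run_id!r}")
        if v.run_id in by_run:
            raise ValueError(f"duplicate NSAF vector for run {v.run_id!r}")
        by_run[v.run_id] = v
    run_ids = [r for r in manifest_ids if r in by_run]
    accessions = sorted(set().union(*(v.values.keys() for v in vectors))) if vectors else []
    nsaf = np.zeros((len(accessions), len(run_ids)))
    counts = np.zeros((len(accessions), len(run_ids)), dtype=int)
    row_of = {a: i for i, a in enumerate(accessions)}
    for j, run_id in enumerate(run_ids):
        v = by_run[run_id]
        for accession, value in v.values.items():
            nsaf[row_of[accession], j] = value
            counts[row_of[accession], j] = v.spectral_counts.get(accession, 0)
    entry_of = {m.run_id: m for m in manifest}
    return AbundanceMatrix(
        accessions=accessions,
        run_ids=run_ids,
        nsaf=nsaf,
        condition_of={r: entry_of[r].condition for r in run_ids},
        role_of={r: entry_of[r].role for r in run_ids},
        spectral_counts=counts,
    )


def subtract_controls(matrix: AbundanceMatrix, mode: str = "mean-dominates") -> AbundanceMatrix:
    """Strip background using the negative-control runs, then drop the
    control columns.

    ``mean-dominates`` (default) removes every protein whose mean NSAF
    across control runs is at least its mean across bait runs;
    ``any-presence`` is the strict variant removing proteins detected in
    any control run.
    """
    control_idx = matrix.columns_with_role("control")
    bait_idx = matrix.columns_with_role("bait")
    if not control_idx:
        raise ValueError(f"mode {mode!r} requires at least one control run")
    if mode == "mean-dominates":
        control_mean = matrix.nsaf[:, control_idx].mean(axis=1)
        bait_mean = matrix.nsaf[:, bait_idx].mean(axis=1)
        keep_rows = bait_mean > control_mean
    elif mode == "any-presence":
        keep_rows = (matrix.nsaf[:, control_idx] == 0).all(axis=1)
    else:
        raise ValueError(f"unknown control-subtraction mode {mode!r}")
    kept = [a for a, k in zip(matrix.accessions, keep_rows) if k]
    return matrix.select_rows(kept).select_columns(bait_idx)


def condition_intersection(
    matrix: AbundanceMatrix,
    groups: Sequence[str],
    min_runs_per_group: int = 1,
) -> set[str]:
    """Proteins detected (NSAF > 0) in at least ``min_runs_per_group``
    runs of *every* listed condition group."""
    present_conditions = set(matrix.condition_of.values())
    common: set[str] | None = None
    for group in groups:
        if group not in present_conditions:
            raise ValueError(f"unknown condition group {group!r}")
        cols = [j for j, r in enumerate(matrix.run_ids) if matrix.condition_of[r] == group]
        detected_runs = (matrix.nsaf[:, cols] > 0).sum(axis=1)
        in_group = {
            a for a, n in zip(matrix.accessions, detected_runs) if n >= min_runs_per_group
        }
        common = in_group if common is None else common & in_group
    return common if common is not None else set()


def _row_zscore(x: np.ndarray) -> np.ndarray:
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, keepdims=True)
    out = np.zeros_like(x, dtype=float)
    np.divide(x - mean, sd, out=out, where=sd > 0)
    return out


def _correlation_distance(x: np.ndarray) -> np.ndarray:
    """1 - Pearson r between rows; constant rows get the maximal distance."""
    sd = x.std(axis=1)
    constant = sd == 0
    if constant.any():
        logger.warning(
            "%d constant row(s) under correlation distance; assigned distance %.1f",
            int(constant.sum()),
            MAX_CORRELATION_DISTANCE,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x)
    d = 1.0 - r
    d[constant, :] = MAX_CORRELATION_DISTANCE
    d[:, constant] = MAX_CORRELATION_DISTANCE
    np.fill_diagonal(d, 0.0)
    # guard against tiny negative round-off and enforce symmetry
    d = np.clip((d + d.T) / 2.0, 0.0, None)
    return d


def cluster_nsaf(
    matrix: AbundanceMatrix,
    distance: str = "pearson",
    linkage: str = "average",
    transform: str = "zscore",
) -> ClusterResult:
    """Agglomerative clustering of protein NSAF profiles.

    Rows are sorted by accession before clustering, which fixes the
    tie-break order and makes the result invariant under row permutation
    of the input matrix.
    """
    if len(matrix.accessions) < 2 or len(matrix.run_ids) < 2:
        raise ValueError("clustering needs at least 2 proteins and 2 runs")
    order = np.argsort(np.asarray(matrix.accessions, dtype=object))
    accessions = tuple(matrix.accessions[i] for i in order)
    x = matrix.nsaf[order, :].astype(float)
    if transform == "zscore":
        x = _row_zscore(x)
    elif transform == "log":
        x = np.log1p(x)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if distance == "pearson":
        d = _correlation_distance(x)
        condensed = squareform(d, checks=False)
    elif distance == "euclidean":
        from scipy.spatial.distance import pdist

        condensed = pdist(x, metric="euclidean")
    else:
        raise ValueError(f"unknown distance {distance!r}")
    z = scipy_linkage(condensed, method=linkage)
    leaf_idx = leaves_list(z)
    return ClusterResult(
        accessions=accessions,
        linkage=z,
        order=tuple(accessions[i] for i in leaf_idx),
    )


def extract_bait_cluster(
    result: ClusterResult,
    bait: str,
    max_size: int = 10,
    max_height: float | None = None,
) -> set[str]:
    """The bait's co-purification cluster.

    Walks the bait leaf's ancestor chain up the merge tree and returns
    the largest ancestor cluster whose size stays within ``max_size``
    (the cut just before the bait's cluster balloons past the size a
    single complex could plausibly have). ``max_size=1`` gives the bait
    alone; ``max_size >= leaf count`` gives the whole tree.

    ``max_height``, when given, additionally requires every merge along
    the chain to stay below that linkage height — a *tightness* bound:
    under the default correlation distance, ``max_height=0.5`` reads as
    "co-members correlate with the bait's cluster at r >= 0.5 on
    average", which is what calling a set of proteins "tightly
    clustering" with the bait means quantitatively.
    """
    if bait not in result.accessions:
        raise ValueError(f"bait {bait!r} not among clustered proteins")
    if max_size < 1:
        raise ValueError("max_size must be >= 1")
    n = len(result.accessions)
    members: dict[int, set[int]] = {i: {i} for i in range(n)}
    current = result.accessions.index(bait)
    best = members[current]
    for k, (a, b, height, _size) in enumerate(result.linkage):
        a, b = int(a), int(b)
        new_id = n + k
        members[new_id] = members[a] | members[b]
        if current in (a, b):
            current = new_id
            if len(members[new_id]) <= max_size and (
                max_height is None or height <= max_height
            ):
                best = members[new_id]
    return {result.accessions[i] for i in best}
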