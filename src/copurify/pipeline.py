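"""End-to-end orchestration: filter -> infer -> quantify -> merge ->
subtract controls -> intersect conditions -> cluster -> call the bait's
complex.

Protein retention follows the pooled reading of the evidence rule: PSMs
from all runs of the sample are combined before requiring two distinct
peptides (or one peptide with two spectra) and removing subset
proteins; per-run spectral counts and NSAF values are then computed for
the retained proteins only. A per-run variant of the rule is available
via ``pool_evidence=False``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from copurify.fdr import FdrReport, summarize_fdr
from copurify.formats_io import (
    DEFAULT_DECOY_PREFIX,
    ProteinEntry,
    PsmRecord,
    RunManifestEntry,
)
from copurify.inference import (
    ProteinEvidence,
    apply_evidence_rule,
    assemble,
    remove_subset_proteins,
)
from copurify.merge_cluster import (
    AbundanceMatrix,
    ClusterResult,
    cluster_nsaf,
    condition_intersection,
    extract_bait_cluster,
    merge_runs,
    subtract_controls,
)
from copurify.psm_filter import FilterCriteria, filter_psms
from copurify.quantify import NsafVector, compute_nsaf


@dataclass
class RunResult:
    """One run after filtering and inference: retained PSMs, the run's
    protein evidence (restricted to sample-level retained proteins) and
    its FDR report once computed."""

    run_id: str
    filtered_psms: list[PsmRecord]
    evidence: list[ProteinEvidence]
    fdr: FdrReport | None = None


@dataclass
class PipelineResult:
    runs: list[RunResult]
    pooled_evidence: list[ProteinEvidence]
    fdr_reports: list[FdrReport]
    matrix: AbundanceMatrix
    analysis_matrix: AbundanceMatrix | None
    common_accessions: set[str]
    cluster: ClusterResult | None
    bait_cluster: set[str] | None

    @property
    def combined_fdr(self) -> FdrReport:
        return self.fdr_reports[-1]


def run_pipeline(
    db: Sequence[ProteinEntry],
    psm_tables: dict[str, list[PsmRecord]],
    manifest: Sequence[RunManifestEntry],
    criteria: FilterCriteria | None = None,
    bait: str | None = None,
    max_cluster_size: int = 10,
    max_cluster_height: float | None = 0.5,
    control_mode: str = "mean-dominates",
    decoy_prefix: str = DEFAULT_DECOY_PREFIX,
    min_runs_per_condition: int = 1,
    pool_evidence: bool = True,
    distance: str = "pearson",
    linkage: str = "average",
    transform: str = "zscore",
) -> PipelineResult:
    """Run the complete analysis over a set of runs.

    Control subtraction and condition intersection are skipped when the
    manifest has no control runs or a single condition, respectively;
    clustering is skipped when fewer than two proteins survive.
    """
    criteria = criteria or FilterCriteria()
    known_runs = {m.run_id for m in manifest}
    unknown = set(psm_tables) - known_runs
    if unknown:
        raise ValueError(f"PSM table(s) for run(s) absent from manifest: {sorted(unknown)}")

    filtered: dict[str, list[PsmRecord]] = {
        run_id: filter_psms(psms, criteria) for run_id, psms in psm_tables.items()
    }

    # sample-level inference ("combining all runs")
    if pool_evidence:
        pooled_psms = [p for m in manifest if m.run_id in filtered for p in filtered[m.run_id]]
        pooled = assemble(pooled_psms, db)
        pooled = apply_evidence_rule(pooled)
        pooled = remove_subset_proteins(pooled)
        retained = {a for e in pooled for a in (e.group_members or (e.accession,))}
    else:
        pooled = []
        retained = None

    runs: list[RunResult] = []
    vectors: list[NsafVector] = []
    for m in manifest:
        if m.run_id not in filtered:
            continue
        evidence = assemble(filtered[m.run_id], db)
        if pool_evidence:
            evidence = [e for e in evidence if e.accession in retained]
        else:
            evidence = remove_subset_proteins(apply_evidence_rule(evidence))
            pooled.extend(evidence)
        runs.append(RunResult(run_id=m.run_id, filtered_psms=filtered[m.run_id], evidence=evidence))
        vectors.append(compute_nsaf(evidence, db, run_id=m.run_id))

    fdr_reports = summarize_fdr(runs, decoy_prefix)
    for run, report in zip(runs, fdr_reports):
        run.fdr = report

    matrix = merge_runs(vectors, manifest)
    matrix.peptide_count = {e.accession: e.peptide_count for e in pooled}
    matrix.coverage_pct = {e.accession: e.coverage_pct for e in pooled}

    analysis = matrix
    if analysis.columns_with_role("control"):
        analysis = subtract_controls(analysis, mode=control_mode)
    conditions = sorted(set(analysis.condition_of[r] for r in analysis.run_ids))
    if len(conditions) > 1:
        common = condition_intersection(analysis, conditions, min_runs_per_condition)
    else:
        common = set(analysis.accessions)
    analysis = analysis.select_rows(sorted(common))

    cluster = None
    bait_cluster = None
    if len(analysis.accessions) >= 2 and len(analysis.run_ids) >= 2:
        cluster = cluster_nsaf(analysis, distance=distance, linkage=linkage, transform=transform)
        if bait is not None and bait in cluster.accessions:
            bait_cluster = extract_bait_cluster(
                cluster, bait, max_cluster_size, max_cluster_height
            )
    elif bait is not None and bait in analysis.accessions:
        bait_cluster = set(analysis.accessions)

    return PipelineResult(
        runs=runs,
        pooled_evidence=pooled,
        fdr_reports=fdr_reports,
        matrix=matrix,
        analysis_matrix=analysis,
        common_accessions=common,
        cluster=cluster,
        bait_cluster=bait_cluster,
    )
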