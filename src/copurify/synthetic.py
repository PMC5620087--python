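"""Ground-truth-labeled synthetic AP-MS experiments.

The generator emulates, at desk scale, a multi-run immunopurification
study: a bait protein with three tightly co-purifying partners at
roughly 3:1:1:1 molar stoichiometry, hundreds of background proteins,
two purification conditions with 11 and 12 bait runs, a set of
negative-control runs, and a small controlled rate of shuffled-decoy
PSMs for FDR estimation. It emits exactly the artifacts the pipeline
consumes — a FASTA database with decoys, per-run PSM tables, a run
manifest — plus a ground-truth record for assertions.

Statistical model, per run:

* every protein's spectral count is Poisson with mean
  ``depth_scale * molar_i * (observable peptides of i) * run factors``,
  where observable peptides are the distinct fully-tryptic peptides of
  length >= 7 from the in-silico digest (coupling the generator to the
  same retention rule the filter applies);
* a log-normal per-run depth factor (sigma ``noise_sigma``) scales all
  proteins of the run — chromatography/loading variation;
* a capture-efficiency factor scales *complex members only* in bait
  runs: a systematic elution-pool recovery (the first HA-peptide
  elution yields far more bait than the pooled late elutions) times a
  log-normal run-to-run antibody-capture noise (sigma
  ``ip_efficiency_sigma``). This joint variation is what makes
  co-complex NSAF profiles co-vary across runs while background does
  not (NSAF's per-run normalization cancels any factor shared by all
  proteins, and nonspecific binders elute throughout);
* background proteins split into a shared fraction present in bait and
  control runs at equal abundance (nonspecific binders the control
  subtraction should remove), bait-only "sticky" contaminants present
  in all conditions, and condition-specific contaminants present in the
  bait runs of a single condition.

PSMs drawn for present proteins get scores sampled above the retention
thresholds; a configured fraction of additional sub-threshold PSMs
violates one rule each, and each passing PSM is independently converted
to a decoy hit with probability ``decoy_psm_rate``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from copurify.decoy import build_decoy_database, digest
from copurify.formats_io import (
    DEFAULT_DECOY_PREFIX,
    TERMINUS,
    ProteinEntry,
    PsmRecord,
    RunManifestEntry,
    write_fasta,
    write_manifest,
    write_psm_table,
)
from copurify.merge_cluster import AbundanceMatrix
from copurify.psm_filter import FilterCriteria

import logging

logger = logging.getLogger(__name__)

_AA = "ACDEFGHIKLMNPQRSTVWY"
# Vertebrate-proteome-like residue frequencies (normalized at import).
_AA_FREQ = np.array(
    [
        0.0777, 0.0157, 0.0530, 0.0656, 0.0405, 0.0691, 0.0227, 0.0591,
        0.0595, 0.0960, 0.0238, 0.0427, 0.0469, 0.0393, 0.0526, 0.0694,
        0.0550, 0.0667, 0.0118, 0.0311,
    ]
)
_AA_FREQ /= _AA_FREQ.sum()
_AA_BYTES = np.frombuffer(_AA.encode("ascii"), dtype=np.uint8)

_ELUTION_POOLS = ("E1", "E2-3", "E4-7")


@dataclass(frozen=True)
class ComplexMember:
    """One planted complex member: label, molar ratio relative to the
    bait, and protein length in residues."""

    label: str
    molar_ratio: float
    length: int


# Default planted complex: a large bait (scaffold-sized), two
# deacetylase-sized partners at equimolar ratio, and one WD40-repeat-
# sized partner at threefold molar excess.
DEFAULT_COMPLEX = (
    ComplexMember("BAIT", 1.0, 1550),
    ComplexMember("PARTNER_A", 1.0, 480),
    ComplexMember("PARTNER_B", 1.0, 490),
    ComplexMember("PARTNER_W", 3.0, 330),
)


@dataclass(frozen=True)
class GeneratorConfig:
    seed: int = 0
    n_background_proteins: int = 300
    protein_length_range: tuple[int, int] = (100, 2000)
    complex_spec: tuple[ComplexMember, ...] = DEFAULT_COMPLEX
    n_conditions: int = 2
    runs_per_condition: tuple[int, ...] = (11, 12)
    n_control_runs: int = 12
    bait_depth: float = 50.0
    # log-normal molar abundance of background relative to bait = 1
    background_abundance: tuple[float, float] = (np.log(0.02), 0.8)
    contaminant_overlap: float = 0.8
    enriched_multiplier: float = 3.0
    decoy_psm_rate: float = 0.0007
    noise_sigma: float = 0.25
    ip_efficiency_sigma: float = 0.5
    # relative bait recovery of the three elution pools (E1, E2-3, E4-7);
    # normalized so the across-pool mean bait count equals bait_depth
    elution_pool_recovery: tuple[float, ...] = (1.0, 0.45, 0.15)
    subthreshold_fraction: float = 0.1
    decoy_prefix: str = DEFAULT_DECOY_PREFIX
    min_observable_length: int = 7

    def __post_init__(self) -> None:
        if len(self.runs_per_condition) != self.n_conditions:
            raise ValueError("runs_per_condition must list one count per condition")
        if not self.complex_spec or any(m.molar_ratio <= 0 for m in self.complex_spec):
            raise ValueError("complex molar ratios must be positive")
        lo, hi = self.protein_length_range
        if lo < 20 or hi < lo:
            raise ValueError(f"infeasible protein length range {self.protein_length_range}")
        if not 0 <= self.decoy_psm_rate <= 1 or not 0 <= self.contaminant_overlap <= 1:
            raise ValueError("rates must lie in [0, 1]")
        if any(m.length < 20 for m in self.complex_spec):
            raise ValueError("complex member lengths must be >= 20 residues")
        if len(self.elution_pool_recovery) != len(_ELUTION_POOLS) or any(
            r <= 0 for r in self.elution_pool_recovery
        ):
            raise ValueError(
                f"elution_pool_recovery must give {len(_ELUTION_POOLS)} positive factors"
            )


@dataclass
class GroundTruth:
    bait: str
    complex_members: set[str]
    molar_ratios: dict[str, float]
    per_run_expected_counts: dict[str, float]  # "run_id/accession" -> mean
    decoy_psm_ids: set[str]
    shared_background: set[str] = field(default_factory=set)
    enriched_background: set[str] = field(default_factory=set)
    condition_specific: dict[str, str] = field(default_factory=dict)  # accession -> condition


@dataclass
class SyntheticExperiment:
    """In-memory synthetic experiment; ``write`` emits the file set."""

    config: GeneratorConfig
    database: list[ProteinEntry]
    psm_tables: dict[str, list[PsmRecord]]
    manifest: list[RunManifestEntry]
    truth: GroundTruth

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_fasta(self.database, out / "db.fasta")
        write_manifest(self.manifest, out / "manifest.tsv")
        psm_dir = out / "psms"
        psm_dir.mkdir(exist_ok=True)
        for run_id, psms in self.psm_tables.items():
            write_psm_table(psms, psm_dir / f"{run_id}.tsv")
        truth = {
            "bait": self.truth.bait,
            "complex_members": sorted(self.truth.complex_members),
            "molar_ratios": self.truth.molar_ratios,
            "per_run_expected_counts": self.truth.per_run_expected_counts,
            "decoy_psm_ids": sorted(self.truth.decoy_psm_ids),
            "shared_background": sorted(self.truth.shared_background),
            "enriched_background": sorted(self.truth.enriched_background),
            "condition_specific": self.truth.condition_specific,
        }
        (out / "ground_truth.json").write_text(
            json.dumps(truth, indent=1, sort_keys=True) + "\n"
        )


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    idx = rng.choice(len(_AA), size=length, p=_AA_FREQ)
    return _AA_BYTES[idx].tobytes().decode("ascii")


def _condition_labels(n: int) -> list[str]:
    if n == 2:
        return ["low_salt", "high_salt"]
    return [f"cond{i + 1}" for i in range(n)]


def _build_manifest(config: GeneratorConfig) -> list[RunManifestEntry]:
    conditions = _condition_labels(config.n_conditions)
    entries: list[RunManifestEntry] = []
    for condition, n_runs in zip(conditions, config.runs_per_condition):
        for k in range(n_runs):
            entries.append(
                RunManifestEntry(
                    run_id=f"{condition}_b{k + 1:02d}",
                    condition=condition,
                    replicate=f"rep{k // len(_ELUTION_POOLS) + 1}",
                    role="bait",
                    elution_pool=_ELUTION_POOLS[k % len(_ELUTION_POOLS)],
                )
            )
    for j in range(config.n_control_runs):
        condition = conditions[j % len(conditions)]
        entries.append(
            RunManifestEntry(
                run_id=f"ctrl_{j + 1:02d}",
                condition=condition,
                replicate=f"rep{j // len(_ELUTION_POOLS) + 1}",
                role="control",
                elution_pool=_ELUTION_POOLS[j % len(_ELUTION_POOLS)],
            )
        )
    return entries


def generate_experiment(
    config: GeneratorConfig, out_dir: str | Path | None = None
) -> SyntheticExperiment:
    """Generate a complete synthetic experiment; optionally write its
    file set to ``out_dir``. Fully deterministic for a given config."""
    rng = np.random.default_rng(config.seed)
    criteria = FilterCriteria()

    # --- protein database -------------------------------------------------
    targets: list[ProteinEntry] = [
        ProteinEntry(
            accession=m.label,
            description="planted complex member",
            sequence=_random_sequence(rng, m.length),
        )
        for m in config.complex_spec
    ]
    lo, hi = config.protein_length_range
    bg_lengths = rng.integers(lo, hi + 1, size=config.n_background_proteins)
    bg_accessions = [f"BG{i + 1:04d}" for i in range(config.n_background_proteins)]
    for accession, length in zip(bg_accessions, bg_lengths):
        targets.append(
            ProteinEntry(
                accession=accession,
                description="background protein",
                sequence=_random_sequence(rng, int(length)),
            )
        )
    database = build_decoy_database(targets, config.seed, config.decoy_prefix)

    peptides: dict[str, list[tuple[str, int, int]]] = {}
    for entry in database:
        peptides[entry.accession] = digest(
            entry.sequence, 0, config.min_observable_length
        )
    for entry in targets:
        if not peptides[entry.accession]:
            raise ValueError(
                f"infeasible config: protein {entry.accession!r} yields no "
                f"observable peptide of length >= {config.min_observable_length}"
            )
    obs = {a: len(p) for a, p in peptides.items()}
    decoy_pool = [e.accession for e in database if e.is_decoy and obs[e.accession] > 0]

    # --- abundances and background partition ------------------------------
    complex_labels = [m.label for m in config.complex_spec]
    molar = {m.label: m.molar_ratio for m in config.complex_spec}
    mu, sigma = config.background_abundance
    for accession in bg_accessions:
        molar[accession] = float(rng.lognormal(mu, sigma))
    depth_scale = config.bait_depth / (
        molar[complex_labels[0]] * obs[complex_labels[0]]
    )

    order = rng.permutation(config.n_background_proteins)
    n_shared = round(config.contaminant_overlap * config.n_background_proteins)
    n_bait_only = config.n_background_proteins - n_shared
    n_cond_specific = n_bait_only // 2
    shared = {bg_accessions[i] for i in order[:n_shared]}
    enriched = {bg_accessions[i] for i in order[n_shared : n_shared + (n_bait_only - n_cond_specific)]}
    conditions = _condition_labels(config.n_conditions)
    condition_specific: dict[str, str] = {}
    for k, i in enumerate(order[n_shared + (n_bait_only - n_cond_specific):]):
        condition_specific[bg_accessions[i]] = conditions[k % len(conditions)]

    manifest = _build_manifest(config)
    truth = GroundTruth(
        bait=complex_labels[0],
        complex_members=set(complex_labels),
        molar_ratios=dict(molar),
        per_run_expected_counts={},
        decoy_psm_ids=set(),
        shared_background=shared,
        enriched_background=enriched,
        condition_specific=condition_specific,
    )

    # --- per-run PSM synthesis --------------------------------------------
    psm_tables: dict[str, list[PsmRecord]] = {}
    pool_recovery = {
        pool: r / (sum(config.elution_pool_recovery) / len(config.elution_pool_recovery))
        for pool, r in zip(_ELUTION_POOLS, config.elution_pool_recovery)
    }
    for run in manifest:
        depth_factor = float(rng.lognormal(0.0, config.noise_sigma))
        capture = (
            float(rng.lognormal(0.0, config.ip_efficiency_sigma))
            * pool_recovery[run.elution_pool]
            if run.role == "bait"
            else 0.0
        )
        present: list[str] = []
        means: list[float] = []
        if run.role == "bait":
            for label in complex_labels:
                present.append(label)
                means.append(
                    depth_scale * molar[label] * obs[label] * depth_factor * capture
                )
        for accession in bg_accessions:
            base = depth_scale * molar[accession] * obs[accession] * depth_factor
            if accession in shared:
                present.append(accession)
                means.append(base)
            elif run.role == "bait" and accession in enriched:
                present.append(accession)
                means.append(base * config.enriched_multiplier)
            elif (
                run.role == "bait"
                and condition_specific.get(accession) == run.condition
            ):
                present.append(accession)
                means.append(base * config.enriched_multiplier)
        counts = rng.poisson(np.asarray(means))
        if run.role == "bait":
            for label in complex_labels:
                truth.per_run_expected_counts[f"{run.run_id}/{label}"] = means[
                    present.index(label)
                ]

        psms = _draw_run_psms(
            rng, run.run_id, present, counts, peptides, database, decoy_pool,
            config, criteria, truth,
        )
        psm_tables[run.run_id] = psms

    experiment = SyntheticExperiment(
        config=config,
        database=database,
        psm_tables=psm_tables,
        manifest=manifest,
        truth=truth,
    )
    if out_dir is not None:
        experiment.write(out_dir)
    return experiment


def _passing_scores(
    rng: np.random.Generator, criteria: FilterCriteria, n: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    charges = rng.choice([1, 2, 3], size=n, p=[0.1, 0.6, 0.3])
    thresholds = np.array([criteria.xcorr_threshold(int(c)) for c in charges])
    xcorr = thresholds + 2.0 * rng.random(n)
    deltcn = criteria.min_deltcn + 0.32 * rng.random(n)
    sp_rank = rng.integers(1, criteria.max_sp_rank + 1, size=n)
    return charges, xcorr, deltcn, sp_rank


def _draw_run_psms(
    rng: np.random.Generator,
    run_id: str,
    present: list[str],
    counts: np.ndarray,
    peptides: dict[str, list[tuple[str, int, int]]],
    database: list[ProteinEntry],
    decoy_pool: list[str],
    config: GeneratorConfig,
    criteria: FilterCriteria,
    truth: GroundTruth,
) -> list[PsmRecord]:
    sequence_of = {e.accession: e.sequence for e in database}

    source: list[tuple[str, int]] = []  # (accession, peptide index)
    for accession, count in zip(present, counts):
        if count == 0:
            continue
        for idx in rng.integers(0, len(peptides[accession]), size=int(count)):
            source.append((accession, int(idx)))
    n_pass = len(source)

    decoy_flags = rng.random(n_pass) < config.decoy_psm_rate
    for i in np.flatnonzero(decoy_flags):
        accession = decoy_pool[int(rng.integers(0, len(decoy_pool)))]
        source[i] = (accession, int(rng.integers(0, len(peptides[accession]))))

    n_sub = int(rng.poisson(config.subthreshold_fraction * n_pass)) if present else 0
    for _ in range(n_sub):
        accession = present[int(rng.integers(0, len(present)))]
        source.append((accession, int(rng.integers(0, len(peptides[accession])))))

    n_total = len(source)
    charges, xcorr, deltcn, sp_rank = _passing_scores(rng, criteria, n_total)

    # violate exactly one retention rule per sub-threshold PSM
    violations = rng.integers(0, 4, size=n_sub)
    force_nontryptic = np.zeros(n_total, dtype=bool)
    for k, v in enumerate(violations):
        i = n_pass + k
        if v == 0:
            xcorr[i] = criteria.xcorr_threshold(int(charges[i])) * (0.3 + 0.6 * rng.random())
        elif v == 1:
            deltcn[i] = criteria.min_deltcn * rng.random() * 0.95
        elif v == 2:
            sp_rank[i] = int(rng.integers(criteria.max_sp_rank + 1, 51))
        else:
            force_nontryptic[i] = True

    psms: list[PsmRecord] = []
    for i, (accession, pep_idx) in enumerate(source):
        peptide, start, end = peptides[accession][pep_idx]
        seq = sequence_of[accession]
        prev_aa = seq[start - 2] if start > 1 else TERMINUS
        next_aa = seq[end] if end < len(seq) else TERMINUS
        if force_nontryptic[i]:
            prev_aa = "G"
        spectrum_id = f"{run_id}.{i + 1:05d}"
        if i < n_pass and decoy_flags[i]:
            truth.decoy_psm_ids.add(spectrum_id)
        psms.append(
            PsmRecord(
                spectrum_id=spectrum_id,
                peptide=peptide,
                prev_aa=prev_aa,
                next_aa=next_aa,
                charge=int(charges[i]),
                xcorr=float(xcorr[i]),
                deltcn=float(deltcn[i]),
                sp_rank=int(sp_rank[i]),
                protein_accessions=(accession,),
            )
        )
    return psms


def planted_ratio_check(
    truth: GroundTruth, matrix: AbundanceMatrix
) -> dict[str, tuple[float, float]]:
    """Pair each complex member's planted molar ratio with the ratio the
    pipeline recovered: the mean over bait runs of NSAF_i / NSAF_bait.

    Bait runs where the bait itself was not quantified are excluded with
    a warning.
    """
    if truth.bait not in matrix.accessions:
        raise ValueError(f"bait {truth.bait!r} absent from abundance matrix")
    bait_cols = matrix.columns_with_role("bait")
    bait_row = matrix.accessions.index(truth.bait)
    usable = [j for j in bait_cols if matrix.nsaf[bait_row, j] > 0]
    for j in bait_cols:
        if matrix.nsaf[bait_row, j] <= 0:
            logger.warning(
                "bait not quantified in run %s; excluded from ratio recovery",
                matrix.run_ids[j],
            )
    result: dict[str, tuple[float, float]] = {}
    for member in sorted(truth.complex_members):
        if member not in matrix.accessions:
            continue
        row = matrix.accessions.index(member)
        ratios = [
            matrix.nsaf[row, j] / matrix.nsaf[bait_row, j] for j in usable
        ]
        recovered = float(np.mean(ratios)) if ratios else float("nan")
        planted = truth.molar_ratios[member] / truth.molar_ratios[truth.bait]
        result[member] = (planted, recovered)
    return result
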