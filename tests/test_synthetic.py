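import filecmp
from dataclasses import replace

import numpy as np
import pytest

from copurify import (
    FilterCriteria,
    GeneratorConfig,
    filter_psms,
    generate_experiment,
    planted_ratio_check,
    run_pipeline,
)
from copurify.psm_filter import is_fully_tryptic
from copurify.synthetic import ComplexMember

SMALL = GeneratorConfig(
    seed=11,
    n_background_proteins=60,
    runs_per_condition=(4, 4),
    n_control_runs=4,
)


def assert_trees_identical(dir_a, dir_b):
    comparison = filecmp.dircmp(dir_a, dir_b)
    assert not comparison.left_only and not comparison.right_only

    def walk(cmp):
        for name in cmp.common_files:
            a, b = cmp.left + "/" + name, cmp.right + "/" + name
            assert open(a, "rb").read() == open(b, "rb").read(), name
        for sub in cmp.subdirs.values():
            walk(sub)

    walk(comparison)


def test_same_seed_gives_byte_identical_files(tmp_path):
    generate_experiment(SMALL, tmp_path / "a")
    generate_experiment(SMALL, tmp_path / "b")
    assert_trees_identical(str(tmp_path / "a"), str(tmp_path / "b"))


def test_different_seed_changes_output():
    exp1 = generate_experiment(SMALL)
    exp2 = generate_experiment(replace(SMALL, seed=12))
    assert exp1.database[0].sequence != exp2.database[0].sequence


def test_zero_decoy_rate_gives_exactly_zero_spectral_fdr():
    exp = generate_experiment(replace(SMALL, decoy_psm_rate=0.0))
    res = run_pipeline(exp.database, exp.psm_tables, exp.manifest)
    assert res.combined_fdr.spectral_fdr_pct == 0.0
    assert not exp.truth.decoy_psm_ids


def test_database_doubles_targets_and_manifest_matches_design(default_experiment):
    exp = default_experiment
    config = exp.config
    n_targets = len(config.complex_spec) + config.n_background_proteins
    assert len(exp.database) == 2 * n_targets
    baits = [m for m in exp.manifest if m.role == "bait"]
    controls = [m for m in exp.manifest if m.role == "control"]
    assert len(baits) == sum(config.runs_per_condition)
    assert len(controls) == config.n_control_runs
    assert len({m.condition for m in baits}) == config.n_conditions


def test_passing_psms_are_observable_peptides(default_experiment):
    run_id = default_experiment.manifest[0].run_id
    kept = filter_psms(default_experiment.psm_tables[run_id], FilterCriteria())
    assert kept, "a bait run must yield retained PSMs"
    assert all(len(p.peptide) >= 7 and is_fully_tryptic(p) for p in kept)


def test_complex_members_absent_from_control_runs(default_experiment):
    exp = default_experiment
    for m in exp.manifest:
        accessions = {
            a for p in exp.psm_tables[m.run_id] for a in p.protein_accessions
        }
        if m.role == "control":
            assert not accessions & exp.truth.complex_members


def test_decoy_psm_ids_map_to_decoy_proteins(default_experiment):
    exp = default_experiment
    by_id = {p.spectrum_id: p for t in exp.psm_tables.values() for p in t}
    assert exp.truth.decoy_psm_ids  # the default rate plants some decoys
    for sid in exp.truth.decoy_psm_ids:
        assert all(
            a.startswith(exp.config.decoy_prefix)
            for a in by_id[sid].protein_accessions
        )


def test_doubling_bait_depth_preserves_mean_complex_nsaf():
    config = replace(SMALL, runs_per_condition=(6, 6))
    shallow = generate_experiment(config)
    deep = generate_experiment(replace(config, bait_depth=2 * config.bait_depth))

    def mean_bait_nsaf(exp):
        res = run_pipeline(exp.database, exp.psm_tables, exp.manifest)
        m = res.matrix
        row = m.accessions.index("BAIT")
        bait_cols = m.columns_with_role("bait")
        return m.nsaf[row, bait_cols].mean()

    a, b = mean_bait_nsaf(shallow), mean_bait_nsaf(deep)
    assert b == pytest.approx(a, rel=0.35)  # NSAF is depth-normalized


def test_planted_ratio_check_bait_is_exactly_one(
    default_experiment, default_pipeline_result
):
    ratios = planted_ratio_check(
        default_experiment.truth, default_pipeline_result.matrix
    )
    planted, recovered = ratios["BAIT"]
    assert planted == 1.0 and recovered == 1.0


def test_complex_profiles_outcorrelate_background(default_pipeline_result):
    """Co-complex NSAF profiles across bait runs correlate more strongly
    than the bulk of background pairs."""
    m = default_pipeline_result.matrix
    bait_cols = m.columns_with_role("bait")
    x = m.nsaf[:, bait_cols]
    keep = (x > 0).sum(axis=1) >= 5  # correlations need support
    x = x[keep]
    names = [a for a, k in zip(m.accessions, keep) if k]
    r = np.corrcoef(x)
    complex_idx = [names.index(a) for a in ["BAIT", "PARTNER_A", "PARTNER_B", "PARTNER_W"]]
    complex_rs = [r[i, j] for i in complex_idx for j in complex_idx if i < j]
    bg_idx = [i for i in range(len(names)) if i not in complex_idx]
    bg_rs = np.array([r[i, j] for i in bg_idx for j in bg_idx if i < j])
    assert min(complex_rs) > np.quantile(bg_rs, 0.95)


def test_infeasible_config_rejected():
    with pytest.raises(ValueError):
        GeneratorConfig(protein_length_range=(0, 10))
    with pytest.raises(ValueError):
        GeneratorConfig(runs_per_condition=(5,))
    with pytest.raises(ValueError):
        GeneratorConfig(
            complex_spec=(ComplexMember("BAIT", -1.0, 500),)
        )
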