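import numpy as np
import pytest

from copurify import (
    AbundanceMatrix,
    NsafVector,
    RunManifestEntry,
    cluster_nsaf,
    condition_intersection,
    extract_bait_cluster,
    merge_runs,
    subtract_controls,
)


def vec(run_id, values):
    return NsafVector(
        run_id=run_id,
        values=dict(values),
        spectral_counts={a: 1 for a in values},
        lengths={a: 100 for a in values},
    )


def man(run_id, condition="c1", role="bait"):
    return RunManifestEntry(run_id, condition, "rep1", role, "E1")


def test_merge_union_with_structural_zeros():
    m = merge_runs(
        [vec("r1", {"A": 0.5, "B": 0.5}), vec("r2", {"B": 0.4, "C": 0.6})],
        [man("r1"), man("r2")],
    )
    assert m.accessions == ["A", "B", "C"]
    assert m.run_ids == ["r1", "r2"]
    assert (m.nsaf == 0).sum() == 2
    assert m.nsaf[m.accessions.index("B"), :].tolist() == [0.5, 0.4]


def test_merge_single_run_is_identity():
    v = vec("r1", {"A": 0.25, "B": 0.75})
    m = merge_runs([v], [man("r1")])
    assert {a: m.nsaf[i, 0] for i, a in enumerate(m.accessions)} == v.values


def test_merge_invariant_under_vector_order_and_rejects_unknown_run():
    vectors = [vec("r1", {"A": 1.0}), vec("r2", {"B": 1.0})]
    manifest = [man("r1"), man("r2")]
    m1 = merge_runs(vectors, manifest)
    m2 = merge_runs(vectors[::-1], manifest)
    assert m1.run_ids == m2.run_ids and np.array_equal(m1.nsaf, m2.nsaf)
    with pytest.raises(ValueError, match="unknown run"):
        merge_runs([vec("ghost", {"A": 1.0})], manifest)


def control_matrix():
    # rows: only-in-controls, only-in-bait, stronger-in-controls, stronger-in-bait
    nsaf = np.array(
        [
            [0.0, 0.0, 0.5, 0.5],
            [0.3, 0.3, 0.0, 0.0],
            [0.2, 0.2, 0.4, 0.3],
            [0.5, 0.5, 0.1, 0.2],
        ]
    )
    return AbundanceMatrix(
        accessions=["CTL_ONLY", "BAIT_ONLY", "CTL_HEAVY", "BAIT_HEAVY"],
        run_ids=["b1", "b2", "c1", "c2"],
        nsaf=nsaf,
        condition_of={r: "cond" for r in ["b1", "b2", "c1", "c2"]},
        role_of={"b1": "bait", "b2": "bait", "c1": "control", "c2": "control"},
    )


def test_subtract_controls_mean_dominates():
    out = subtract_controls(control_matrix())
    assert out.accessions == ["BAIT_ONLY", "BAIT_HEAVY"]
    assert out.run_ids == ["b1", "b2"]  # control columns dropped


def test_subtract_controls_any_presence_strict_mode():
    out = subtract_controls(control_matrix(), mode="any-presence")
    assert out.accessions == ["BAIT_ONLY"]


def test_subtract_controls_matches_row_by_row_hand_rule(rng):
    n = 20
    nsaf = rng.uniform(0, 1, size=(n, 6)) * (rng.random((n, 6)) > 0.3)
    run_ids = [f"b{i}" for i in range(3)] + [f"c{i}" for i in range(3)]
    m = AbundanceMatrix(
        accessions=[f"P{i:02d}" for i in range(n)],
        run_ids=run_ids,
        nsaf=nsaf,
        condition_of={r: "cond" for r in run_ids},
        role_of={r: ("bait" if r.startswith("b") else "control") for r in run_ids},
    )
    out = subtract_controls(m)
    expected = [
        f"P{i:02d}" for i in range(n) if nsaf[i, :3].mean() > nsaf[i, 3:].mean()
    ]
    assert out.accessions == expected


def test_subtract_controls_requires_controls():
    m = merge_runs([vec("r1", {"A": 1.0})], [man("r1")])
    with pytest.raises(ValueError, match="control"):
        subtract_controls(m)


def intersection_matrix():
    run_ids = ["g1a", "g1b", "g2a", "g2b"]
    nsaf = np.array(
        [
            [0.5, 0.0, 0.3, 0.0],  # BOTH: one run in each group
            [0.5, 0.5, 0.0, 0.0],  # G1_ONLY
            [0.4, 0.5, 0.7, 1.0],  # EVERYWHERE
        ]
    )
    return AbundanceMatrix(
        accessions=["BOTH", "G1_ONLY", "RICH"],
        run_ids=run_ids,
        nsaf=nsaf,
        condition_of={"g1a": "g1", "g1b": "g1", "g2a": "g2", "g2b": "g2"},
        role_of={r: "bait" for r in run_ids},
    )


def test_condition_intersection_presence_rule():
    m = intersection_matrix()
    assert condition_intersection(m, ["g1", "g2"]) == {"BOTH", "RICH"}
    assert condition_intersection(m, ["g1"]) == {"BOTH", "G1_ONLY", "RICH"}
    with pytest.raises(ValueError, match="unknown"):
        condition_intersection(m, ["g3"])


def test_condition_intersection_anti_monotone_and_min_runs():
    m = intersection_matrix()
    assert condition_intersection(m, ["g1", "g2"]) <= condition_intersection(m, ["g1"])
    # requiring two detections per group drops the single-run protein
    assert condition_intersection(m, ["g1", "g2"], min_runs_per_group=2) == {"RICH"}


def profile_matrix(rows: np.ndarray, accessions=None) -> AbundanceMatrix:
    n, k = rows.shape
    accessions = accessions or [f"P{i:02d}" for i in range(n)]
    run_ids = [f"r{j}" for j in range(k)]
    return AbundanceMatrix(
        accessions=list(accessions),
        run_ids=run_ids,
        nsaf=rows,
        condition_of={r: "cond" for r in run_ids},
        role_of={r: "bait" for r in run_ids},
    )


def test_identical_rows_merge_first_at_height_zero(rng):
    rows = rng.uniform(0.0, 1.0, size=(5, 6))
    rows[3] = rows[0]  # P00 and P03 identical
    result = cluster_nsaf(profile_matrix(rows))
    first = result.linkage[0]
    assert first[2] == pytest.approx(0.0, abs=1e-12)
    assert {int(first[0]), int(first[1])} == {0, 3}


def test_cluster_invariant_under_row_permutation(rng):
    rows = rng.uniform(0.0, 1.0, size=(8, 7))
    m1 = profile_matrix(rows)
    perm = rng.permutation(8)
    m2 = profile_matrix(rows[perm], accessions=[f"P{i:02d}" for i in perm])
    r1, r2 = cluster_nsaf(m1), cluster_nsaf(m2)
    assert r1.accessions == r2.accessions
    assert np.allclose(r1.linkage, r2.linkage)
    assert r1.order == r2.order


def test_constant_row_gets_maximal_distance_not_a_crash(rng):
    rows = rng.uniform(0.0, 1.0, size=(4, 6))
    rows[2] = 0.25  # constant profile
    result = cluster_nsaf(profile_matrix(rows))
    # the constant row is the last thing merged, at the max distance
    assert result.linkage[-1][2] == pytest.approx(2.0)


def naive_average_linkage(rows: np.ndarray):
    """Exhaustive nearest-pair agglomeration on z-scored Pearson distance."""
    z = (rows - rows.mean(1, keepdims=True)) / rows.std(1, keepdims=True)
    d = 1 - np.corrcoef(z)
    n = len(rows)
    active = {i: [i] for i in range(n)}
    merges = []
    next_id = n
    while len(active) > 1:
        best = None
        for a in sorted(active):
            for b in sorted(active):
                if a >= b:
                    continue
                dist = np.mean([d[i, j] for i in active[a] for j in active[b]])
                if best is None or dist < best[0]:
                    best = (dist, a, b)
        dist, a, b = best
        merges.append((dist, frozenset(active[a] + active[b])))
        active[next_id] = active.pop(a) + active.pop(b)
        next_id += 1
    return merges


def test_cluster_agrees_with_exhaustive_agglomeration_oracle(rng):
    for _ in range(10):
        rows = rng.uniform(0.0, 1.0, size=(int(rng.integers(4, 9)), 6))
        result = cluster_nsaf(profile_matrix(rows))
        expected = naive_average_linkage(rows)
        n = rows.shape[0]
        members = {i: frozenset({i}) for i in range(n)}
        for k, (a, b, height, _size) in enumerate(result.linkage):
            merged = members[int(a)] | members[int(b)]
            members[n + k] = merged
            assert height == pytest.approx(expected[k][0], abs=1e-9)
            assert merged == expected[k][1]


def test_extract_bait_cluster_size_bounds(rng):
    rows = rng.uniform(0.0, 1.0, size=(6, 6))
    result = cluster_nsaf(profile_matrix(rows))
    assert extract_bait_cluster(result, "P02", max_size=1) == {"P02"}
    assert extract_bait_cluster(result, "P02", max_size=6) == set(result.accessions)
    with pytest.raises(ValueError, match="not among"):
        extract_bait_cluster(result, "GHOST")


def test_extract_bait_cluster_height_bound_stops_at_loose_merges(rng):
    # two tight pairs, far apart: the height bound keeps the bait's pair
    base = rng.uniform(0.0, 1.0, size=6)
    rows = np.vstack(
        [
            base + rng.normal(0, 0.01, 6),
            base + rng.normal(0, 0.01, 6),
            -base + rng.normal(0, 0.01, 6),
            -base + rng.normal(0, 0.01, 6),
        ]
    )
    result = cluster_nsaf(profile_matrix(rows))
    assert extract_bait_cluster(result, "P00", max_size=4) == set(result.accessions)
    assert extract_bait_cluster(result, "P00", max_size=4, max_height=0.5) == {
        "P00",
        "P01",
    }
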