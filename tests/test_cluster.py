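"""Constrained k-means stratification: oracles and invariants."""

import itertools

import numpy as np
import pandas as pd
import pytest

from hrvreact import cluster as clu
from hrvreact.simulate import SimulationConfig, generate_cohort


def test_z_transform_basics():
    z = clu.z_transform([1.0, 2.0, 3.0])
    assert np.allclose(z, [-1.0, 0.0, 1.0])
    rng = np.random.default_rng(0)
    x = rng.normal(3.0, 2.0, 100)
    z = clu.z_transform(x)
    assert abs(z.mean()) < 1e-12
    assert np.std(z, ddof=1) == pytest.approx(1.0, rel=1e-12)
    # affine invariance
    assert np.allclose(clu.z_transform(5.0 * x - 2.0), z)
    with pytest.raises(ValueError):
        clu.z_transform([1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        clu.z_transform([1.0])


def test_enumerate_paper_mode_for_51_patients():
    configs = clu.enumerate_feasible_configs(51, mode="paper")
    assert len(configs) == 5
    shapes = [(c.d, c.k) for c in configs]
    assert shapes.count((2, 2)) == 1
    assert shapes.count((1, 2)) == 2 and shapes.count((1, 3)) == 2


def test_enumerate_rule_mode():
    with pytest.raises(ValueError):
        clu.enumerate_feasible_configs(19, mode="rule")
    configs = clu.enumerate_feasible_configs(51, mode="rule", max_k=5)
    shapes = {(tuple(c.variables), c.k) for c in configs}
    assert (("delta_rr_mean_s",), 5) in shapes  # 10*1*5 = 50 <= 51
    assert not any(c.k == 3 and c.d == 2 for c in configs)  # 10*2*3 = 60 > 51


def _brute_force_wss(points, k):
    n = points.shape[0]
    best = np.inf
    for labels in itertools.product(range(k), repeat=n):
        if len(set(labels)) < k:
            continue
        best = min(best, clu.total_wss(points, np.array(labels)))
    return best


def test_kmeans_matches_exhaustive_enumeration():
    """Global-optimum WSS on small point sets (exhaustive oracle)."""
    rng = np.random.default_rng(3)
    hits = 0
    trials = 20
    for t in range(trials):
        n = int(rng.integers(6, 11))
        k = int(rng.integers(2, 4))
        pts = rng.normal(size=(n, 1))
        res = clu.kmeans(pts, k, seed=t, n_init=100)
        assert res.wss <= _brute_force_wss(pts, k) + 1e-8
        hits += 1
    assert hits == trials


def test_kmeans_separated_pairs_and_edge_cases():
    pts = np.array([0.0, 0.1, 10.0, 10.1])
    res = clu.kmeans(pts, 2, seed=0)
    assert res.wss == pytest.approx(0.01)
    assert res.sizes == [2, 2]
    assert res.assignments[0] == res.assignments[1]
    assert res.assignments[2] == res.assignments[3]
    # k = n -> zero WSS
    res_n = clu.kmeans(np.array([1.0, 2.0, 3.0]), 3, seed=0)
    assert res_n.wss == pytest.approx(0.0, abs=1e-12)
    # determinism under seed
    a = clu.kmeans(np.random.default_rng(1).normal(size=30), 3, seed=5)
    b = clu.kmeans(np.random.default_rng(1).normal(size=30), 3, seed=5)
    assert np.array_equal(a.assignments, b.assignments)
    with pytest.raises(ValueError):
        clu.kmeans(np.array([1.0, 1.0]), 3, seed=0)


def test_wss_non_increasing_and_fixed_point():
    """The returned assignment is a Lloyd fixed point."""
    rng = np.random.default_rng(4)
    pts = rng.normal(size=(40, 2))
    res = clu.kmeans(pts, 3, seed=0)
    # reassigning each point to its nearest returned centroid changes nothing
    d = ((pts[:, None, :] - res.centroids[None]) ** 2).sum(-1)
    nearest = d.argmin(1) + 1
    assert np.array_equal(nearest, res.assignments)
    assert clu.total_wss(pts, res.assignments) == pytest.approx(res.wss, rel=1e-9)


def test_select_clustering_min_wss_and_ties():
    r1 = clu.kmeans(np.array([0.0, 0.1, 5.0, 5.1]), 2, seed=0)
    assert clu.select_clustering([r1]) is r1
    import dataclasses

    r_big_d = dataclasses.replace(
        r1, config=dataclasses.replace(r1.config, variables=("a", "b"))
    )
    # equal WSS -> the smaller-d config wins
    assert clu.select_clustering([r_big_d, r1]) is r1


def test_relabel_by_baseline_hr_invariance():
    rng = np.random.default_rng(5)
    pts = np.concatenate([rng.normal(-3, 0.3, 10), rng.normal(0, 0.3, 10),
                          rng.normal(3, 0.3, 10)])
    res = clu.kmeans(pts, 3, seed=1)
    hr = np.where(pts < -1.5, 90.0, np.where(pts > 1.5, 60.0, 75.0))
    hr = hr + rng.normal(0, 0.5, 30)
    out = clu.relabel_by_baseline_hr(res, hr)
    means = [hr[out.assignments == c].mean() for c in (1, 2, 3)]
    assert means[0] < means[1] < means[2]
    assert sorted(out.sizes) == sorted(res.sizes)


def test_characterize_excludes_high_missingness_items():
    cfg = SimulationConfig(n_fm=30, n_control=0, master_seed=9,
                           fiq_item_34_missing_prob=0.5)
    cohort = generate_cohort(cfg)
    fm = [s for s in cohort.subjects if s.group == "FM"]
    ids = [s.id for s in fm]
    deltas = np.array([cohort.profiles[i].baseline_hr_bpm for i in ids])
    res = clu.kmeans(clu.z_transform(deltas), 3, seed=0)
    report = clu.characterize_clusters(fm, res, ids)
    assert any(v.startswith("fiq_item_") for v in report.excluded_items)
    tested = set(report.questionnaire_tests["variable"])
    assert not (tested & set(report.excluded_items))
    assert "pss" in tested


def test_characterize_detects_cluster_graded_anxiety():
    """Cluster-graded FIQ anxiety yields Tukey separation of 2,3 vs 1."""
    detections = 0
    reps = 20
    for r in range(reps):
        cfg = SimulationConfig(n_fm=51, n_control=0, master_seed=300 + r)
        cohort = generate_cohort(cfg)
        fm = [s for s in cohort.subjects if s.group == "FM"]
        ids = [s.id for s in fm]
        truth = np.array([s.true_cluster for s in fm])
        import dataclasses

        res = clu.ClusterResult(
            config=clu.ClusterConfig(("truth",), 3, len(ids)),
            assignments=truth,
            centroids=np.zeros((3, 1)),
            wss=0.0,
        )
        report = clu.characterize_clusters(fm, res, ids)
        q = report.questionnaire_tests
        tuk = q[(q["variable"] == "fiq_item_9") & (q["method"] == "tukey_hsd")]
        ps = {eval(p): row for p, row in zip(tuk["pair"], tuk["p"])}
        ok = all(
            row < 0.05
            for pair, row in ps.items()
            if set(pair) in ({"1", "2"}, {"1", "3"})
        )
        detections += ok
    assert detections >= int(0.9 * reps)


def test_characterize_null_clusters_rarely_significant():
    """Identically drawn clusters: ANOVA p<0.05 in roughly 5% of variables."""
    import dataclasses

    sig = total = 0
    for r in range(10):
        cfg = SimulationConfig(n_fm=51, n_control=0, master_seed=600 + r)
        eff = cfg.cluster_effects
        flat = dataclasses.replace(
            eff,
            fiq_total=(55.0,) * 3, fiq_anxiety=(5.0,) * 3,
            fiq_depression=(4.0,) * 3, pcs=(22.0,) * 3, pss=(18.0,) * 3,
            stai=(40.0,) * 3,
        )
        cfg = dataclasses.replace(cfg, cluster_effects=flat)
        cohort = generate_cohort(cfg)
        fm = [s for s in cohort.subjects if s.group == "FM"]
        ids = [s.id for s in fm]
        truth = np.array([s.true_cluster for s in fm])
        res = clu.ClusterResult(
            config=clu.ClusterConfig(("truth",), 3, len(ids)),
            assignments=truth,
            centroids=np.zeros((3, 1)),
            wss=0.0,
        )
        q = clu.characterize_clusters(fm, res, ids).questionnaire_tests
        anova = q[q["method"] == "anova"]
        sig += int((anova["p"] < 0.05).sum())
        total += len(anova)
    assert sig / total < 0.15


def test_characterize_rejects_empty_cluster():
    cfg = SimulationConfig(n_fm=10, n_control=0, master_seed=1)
    cohort = generate_cohort(cfg)
    fm = cohort.subjects
    ids = [s.id for s in fm]
    res = clu.ClusterResult(
        config=clu.ClusterConfig(("x",), 3, len(ids)),
        assignments=np.array([1] * 5 + [2] * 5),
        centroids=np.zeros((3, 1)),
        wss=0.0,
        sizes=[5, 5, 0],
    )
    with pytest.raises(ValueError, match="empty"):
        clu.characterize_clusters(fm, res, ids)
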