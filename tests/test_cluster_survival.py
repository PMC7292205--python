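import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform
from sklearn.metrics import rand_score

import dlbcl_coo as dc
from dlbcl_coo.cluster_survival import complete_linkage, km_curve, logrank_test, pearson_distance

from conftest import labels_of


def expr_from(values, genes, samples):
    return dc.ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


class TestPearsonDistance:
    def test_self_distance_zero_negation_two(self):
        profile = np.array([1.0, 2.0, 4.0, 3.0])
        X = expr_from(
            np.column_stack([profile, profile, -profile]),
            [f"g{i}" for i in range(4)], ["a", "b", "c"],
        )
        d = pearson_distance(X, axis="samples")
        assert d.loc["a", "b"] == pytest.approx(0.0, abs=1e-12)
        assert d.loc["a", "c"] == pytest.approx(2.0, abs=1e-12)
        assert np.allclose(np.diag(d), 0.0)

    def test_matches_direct_formula(self):
        # Brute-force Pearson r from its definition on hand-entered profiles.
        profiles = {
            "a": np.array([1.0, 2.0, 3.0, 5.0]),
            "b": np.array([2.0, 1.0, 4.0, 4.0]),
            "c": np.array([5.0, 4.0, 1.0, 0.0]),
        }
        X = expr_from(
            np.column_stack(list(profiles.values())),
            [f"g{i}" for i in range(4)], list(profiles),
        )
        d = pearson_distance(X, axis="samples")
        for u, v in itertools.combinations(profiles, 2):
            x, y = profiles[u], profiles[v]
            r = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
                ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
            )
            assert d.loc[u, v] == pytest.approx(1 - r, abs=1e-12)

    def test_constant_profile_rejected_by_name(self):
        X = expr_from(
            np.column_stack([[1, 2, 3], [4.0, 4.0, 4.0]]),
            ["g1", "g2", "g3"], ["ok", "flat"],
        )
        with pytest.raises(ValueError, match="flat"):
            pearson_distance(X, axis="samples")

    def test_gene_axis(self):
        rng = np.random.default_rng(0)
        X = expr_from(rng.normal(size=(5, 10)),
                      [f"g{i}" for i in range(5)], [f"s{i}" for i in range(10)])
        d = pearson_distance(X, axis="genes")
        assert d.shape == (5, 5)
        assert list(d.columns) == [f"g{i}" for i in range(5)]


def dist_frame(d, labels):
    return pd.DataFrame(d, index=labels, columns=labels)


class TestCompleteLinkage:
    def test_hand_traced_three_points(self):
        d = dist_frame(
            [[0, 1, 5], [1, 0, 4], [5, 4, 0]], ["A", "B", "C"]
        )
        dendro = complete_linkage(d)
        assert dendro.merges[0].members_a == ("A",)
        assert dendro.merges[0].members_b == ("B",)
        assert dendro.merges[0].height == 1
        assert dendro.merges[1].height == 5  # max(d(A,C), d(B,C))

    def test_equidistant_degenerate(self):
        n = 4
        d = np.full((n, n), 2.0)
        np.fill_diagonal(d, 0.0)
        dendro = complete_linkage(dist_frame(d, list("ABCD")))
        assert len(dendro.merges) == n - 1
        assert all(m.height == 2.0 for m in dendro.merges)

    def test_heights_match_brute_force(self):
        # Oracle: recompute the true max inter-cluster distance at every
        # merge directly from the distance matrix.
        rng = np.random.default_rng(5)
        for _ in range(5):
            n = rng.integers(4, 12)
            pts = rng.normal(size=(n, 3))
            d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
            labels = [f"s{i}" for i in range(n)]
            dendro = complete_linkage(dist_frame(d, labels))
            idx = {l: i for i, l in enumerate(labels)}
            heights = [m.height for m in dendro.merges]
            assert heights == sorted(heights)
            for m in dendro.merges:
                brute = max(
                    d[idx[a], idx[b]]
                    for a in m.members_a for b in m.members_b
                )
                assert m.height == pytest.approx(brute, abs=1e-12)

    def test_matches_scipy_heights(self):
        rng = np.random.default_rng(8)
        pts = rng.normal(size=(10, 4))
        d = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        dendro = complete_linkage(dist_frame(d, [f"s{i}" for i in range(10)]))
        ours = sorted(m.height for m in dendro.merges)
        scipy_heights = sorted(linkage(squareform(d, checks=False),
                                       method="complete")[:, 2])
        np.testing.assert_allclose(ours, scipy_heights, atol=1e-10)

    def test_asymmetric_matrix_rejected(self):
        d = dist_frame([[0, 1], [2, 0]], ["A", "B"])
        with pytest.raises(ValueError, match="symmetric"):
            complete_linkage(d)

    def test_planted_partition_recovery(self):
        # Two well-separated classes: cutting at k=2 recovers the labels.
        spec = dc.CohortSpec(n_abc=30, n_gcb=30, effect_size=3.0, seed=13)
        expr, ann = dc.generate_expression(spec)
        dendro = complete_linkage(pearson_distance(expr, axis="samples"))
        clusters = dendro.cut(2)
        truth = pd.Series(labels_of(ann), index=expr.sample_ids)
        assert rand_score(truth, clusters.reindex(truth.index)) > 0.9


class TestKmCurve:
    def test_all_censored_flat_at_one(self):
        curve = km_curve([5, 8, 12], [False, False, False])
        assert np.allclose(curve.survival, 1.0)

    def test_all_events_product_limit_by_hand(self):
        curve = km_curve([1.0, 2.0, 3.0], [True, True, True])
        assert curve.survival_at(1.0) == pytest.approx(2 / 3)
        assert curve.survival_at(2.0) == pytest.approx(1 / 3)
        assert curve.survival_at(3.0) == pytest.approx(0.0)

    def test_single_event_with_later_censoring(self):
        curve = km_curve([2.0, 5.0, 6.0, 7.0], [True, False, False, False])
        assert curve.survival_at(2.0) == pytest.approx(3 / 4)
        assert curve.survival_at(10.0) == pytest.approx(3 / 4)

    def test_no_censoring_equals_empirical_survival(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(10, 40)
        curve = km_curve(t, [True] * 40)
        for q in (2.0, 5.0, 15.0):
            assert curve.survival_at(q) == pytest.approx((t > q).mean())

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            km_curve([], [])

    def test_monotone_nonincreasing(self):
        rng = np.random.default_rng(4)
        curve = km_curve(rng.exponential(10, 50), rng.uniform(size=50) < 0.7)
        assert (np.diff(curve.survival) <= 1e-12).all()
        assert curve.survival[0] <= 1.0 and curve.survival_at(0) == 1.0


def two_group_logrank_oracle(times, events, groups):
    """Direct observed-minus-expected tabulation over pooled event times."""
    times, events = np.asarray(times, float), np.asarray(events, bool)
    groups = np.asarray(groups)
    g0 = np.unique(groups)[0]
    O = E = V = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n0 = (at_risk & (groups == g0)).sum()
        d = (events & (times == t)).sum()
        d0 = (events & (times == t) & (groups == g0)).sum()
        O += d0
        E += d * n0 / n
        if n > 1:
            V += d * (n0 / n) * (1 - n0 / n) * (n - d) / (n - 1)
    return (O - E) ** 2 / V


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [1.0, 2.0, 3.0, 4.0]
        e = [True, False, True, True]
        res = logrank_test(t + t, e + e, ["a"] * 4 + ["b"] * 4)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_matches_hand_tabulated_oracle(self):
        rng = np.random.default_rng(10)
        times = np.concatenate([rng.exponential(5, 10), rng.exponential(12, 10)])
        events = rng.uniform(size=20) < 0.8
        groups = ["a"] * 10 + ["b"] * 10
        res = logrank_test(times, events, groups)
        assert res.df == 1
        assert res.statistic == pytest.approx(
            two_group_logrank_oracle(times, events, groups), rel=1e-9
        )

    def test_group_label_permutation_invariant(self):
        rng = np.random.default_rng(12)
        times = rng.exponential(8, 30)
        events = rng.uniform(size=30) < 0.7
        groups = np.array(["x"] * 10 + ["y"] * 10 + ["z"] * 10)
        res1 = logrank_test(times, events, groups)
        relabel = {"x": "z", "y": "x", "z": "y"}
        res2 = logrank_test(times, events, [relabel[g] for g in groups])
        assert res1.statistic == pytest.approx(res2.statistic, rel=1e-9)
        assert res1.df == res2.df == 2

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            logrank_test([1, 2], [True, True], ["a", "a"])

    def test_power_on_hazard_ratio_two(self):
        # HR 2 at n=200 should be detected in the large majority of runs.
        hits = 0
        n_runs = 25
        for seed in range(n_runs):
            spec = dc.CohortSpec(n_abc=100, n_gcb=100, hazard_abc=0.04,
                                 hazard_gcb=0.02, seed=seed)
            _, ann = dc.generate_expression(spec)
            _, ann = dc.generate_ihc_and_survival(spec, ann)
            res = logrank_test(
                [a.survival_time for a in ann],
                [a.event for a in ann],
                labels_of(ann),
            )
            hits += res.p_value < 0.05
        assert hits >= 0.9 * n_runs
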