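"""Dimension scores, weighted K-means, mixed-space rule, Jenks, zones."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from corridorpa.zoning import (advantage_zones, classify_space_type,
                               dimension_scores, jenks_breaks,
                               weighted_kmeans)


class TestDimensionScores:
    def test_constant_factors_score_zero(self):
        factors = pd.DataFrame({"a": [2.0, 2.0, 2.0], "b": [1.0, 1.0, 1.0]})
        w = pd.Series({"a": 0.6, "b": 0.4})
        s = dimension_scores(factors, w, {"a": "service", "b": "living"},
                             dimensions=("service", "living"))
        assert (s.to_numpy() == 0).all()

    def test_single_factor_dimension_is_its_zscore(self):
        factors = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
        w = pd.Series({"a": 0.3})
        s = dimension_scores(factors, w, {"a": "ecology"},
                             dimensions=("ecology",))
        z = (factors["a"] - 2.0) / factors["a"].std(ddof=0)
        np.testing.assert_allclose(s["ecology"], z)

    def test_hand_built_weighted_mean(self):
        """3 units x 2 factors: matches direct spreadsheet arithmetic."""
        factors = pd.DataFrame({"a": [0.0, 1.0, 2.0], "b": [4.0, 0.0, 2.0]})
        w = pd.Series({"a": 0.75, "b": 0.25})
        s = dimension_scores(factors, w, {"a": "service", "b": "service"},
                             dimensions=("service",))
        za = (factors["a"] - 1.0) / factors["a"].std(ddof=0)
        zb = (factors["b"] - 2.0) / factors["b"].std(ddof=0)
        np.testing.assert_allclose(s["service"], 0.75 * za + 0.25 * zb)

    def test_empty_dimension_rejected(self):
        factors = pd.DataFrame({"a": [0.0, 1.0, 2.0]})
        w = pd.Series({"a": 1.0})
        with pytest.raises(ValueError, match="living"):
            dimension_scores(factors, w, {"a": "service"},
                             dimensions=("service", "living"))


class TestWeightedKMeans:
    def test_k1_returns_weighted_mean_centroid(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.standard_normal((40, 3)), columns=list("abc"))
        w = pd.Series({"a": 1.0, "b": 0.5, "c": 0.1})
        res = weighted_kmeans(X, w, k=1, seed=0)
        assert set(res.labels) == {0}
        np.testing.assert_allclose(res.centroids.iloc[0], X.mean(), atol=1e-9)

    def test_planted_archetypes_recovered(self):
        """4 Gaussian archetypes at 6-sigma separation: ARI >= 0.95."""
        aris = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            cents = np.array([[0, 0, 0], [6, 0, 0], [0, 6, 0], [0, 0, 6]],
                             dtype=float)
            labels = rng.integers(0, 4, 600)
            X = pd.DataFrame(cents[labels] + rng.standard_normal((600, 3)),
                             columns=list("abc"))
            w = pd.Series(1.0, index=X.columns)
            res = weighted_kmeans(X, w, k=4, seed=seed)
            aris.append(adjusted_rand_score(labels, res.labels))
        assert np.mean(np.array(aris) >= 0.95) >= 0.95

    def test_weighting_flips_borderline_assignment(self):
        """A point equidistant between two centroids in the raw metric
        moves to the centroid favoured by an up-weighted feature."""
        anchors = pd.DataFrame(
            {"f1": [0.0] * 10 + [4.0] * 10,
             "f2": [0.0] * 10 + [4.0] * 10})
        # borderline unit: f1 says cluster A (0), f2 says cluster B (4)
        border = pd.DataFrame({"f1": [1.0], "f2": [3.0]})
        X = pd.concat([anchors, border], ignore_index=True)
        uniform = pd.Series({"f1": 1.0, "f2": 1.0})
        up_f1 = pd.Series({"f1": 4.0, "f2": 1.0})
        res_u = weighted_kmeans(X, uniform, k=2, seed=0)
        res_w = weighted_kmeans(X, up_f1, k=2, seed=0)
        # raw metric: distance to A-cluster = sqrt(1+9), to B = sqrt(9+1):
        # tie broken by f2 proximity after weighting f1 x4:
        # d_A = sqrt(4*1+9) < d_B = sqrt(4*9+1) -> flips to A's side
        label_a = res_w.labels[0]
        assert res_w.labels[-1] == label_a
        assert res_u.labels[-1] == res_u.labels[10]

    def test_inertia_best_of_restarts(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((100, 2)), columns=list("ab"))
        w = pd.Series(1.0, index=X.columns)
        multi = weighted_kmeans(X, w, k=5, n_init=10, seed=0)
        single = weighted_kmeans(X, w, k=5, n_init=1, seed=0)
        assert multi.inertia <= single.inertia + 1e-9

    def test_k_exceeding_n_rejected(self):
        X = pd.DataFrame({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            weighted_kmeans(X, pd.Series({"a": 1.0}), k=3)


class TestClassifySpaceType:
    def test_rule_cases(self):
        """Mixed at 0.15 gap, dominant at 0.3 gap, tie is mixed."""
        scores = pd.DataFrame({
            "ecology": [1.0, 1.0, 0.7],
            "service": [0.85, 0.7, 0.7],
            "living": [0.2, 0.2, 0.2],
        })
        t = classify_space_type(scores, theta=0.2)
        assert list(t.final_type) == ["mixed", "ecology", "mixed"]
        assert t.s_max.iloc[0] == 1.0 and t.s_second.iloc[0] == 0.85

    def test_scale_invariance(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(rng.uniform(0.1, 2.0, (50, 3)),
                              columns=["service", "living", "ecology"])
        t1 = classify_space_type(scores, theta=0.2)
        t2 = classify_space_type(scores * 7.3, theta=0.2)
        assert (t1.final_type == t2.final_type).all()

    def test_mixed_share_monotone_in_theta(self):
        rng = np.random.default_rng(5)
        scores = pd.DataFrame(rng.uniform(0.05, 1.5, (400, 3)),
                              columns=["service", "living", "ecology"])
        shares = [
            (classify_space_type(scores, theta=th).final_type == "mixed").mean()
            for th in np.arange(0.05, 0.51, 0.05)
        ]
        assert all(b >= a - 1e-12 for a, b in zip(shares, shares[1:]))

    def test_low_signal_units_flagged_not_mixed(self):
        scores = pd.DataFrame({"service": [-1.0], "living": [-1.1],
                               "ecology": [-2.0]})
        t = classify_space_type(scores, theta=0.2)
        assert t.low_signal.iloc[0]
        assert t.final_type.iloc[0] == "service"

    def test_invalid_theta_rejected(self):
        scores = pd.DataFrame({"service": [1.0], "living": [0.5],
                               "ecology": [0.2]})
        for bad in (0.0, 1.0, -0.2):
            with pytest.raises(ValueError):
                classify_space_type(scores, theta=bad)

    def test_clusters_named_by_top_dimension(self):
        scores = pd.DataFrame({
            "service": [2.0, 2.1, 0.1, 0.0],
            "living": [0.1, 0.0, 1.9, 2.2],
            "ecology": [0.0, 0.1, 0.2, 0.1],
        })
        labels = np.array([0, 0, 1, 1])
        t = classify_space_type(scores, labels, theta=0.2)
        assert t.cluster_name == {0: "service", 1: "living"}


def brute_force_jenks_ssd(values, k):
    """Minimum within-class SSD over all contiguous partitions."""
    s = np.sort(np.asarray(values, float))
    n = len(s)

    def ssd(seg):
        return ((seg - seg.mean()) ** 2).sum()

    best = np.inf
    for cuts in combinations(range(1, n), k - 1):
        bounds = [0, *cuts, n]
        total = sum(ssd(s[a:b]) for a, b in zip(bounds[:-1], bounds[1:]))
        best = min(best, total)
    return best


class TestJenks:
    def test_obvious_gap_split(self):
        breaks, labels = jenks_breaks([1, 2, 3, 100, 101, 102], 2)
        assert list(labels) == [0, 0, 0, 1, 1, 1]
        assert breaks == [3.0, 102.0]

    def test_single_class_degenerate(self):
        breaks, labels = jenks_breaks([5.0, 1.0, 3.0], 1)
        assert breaks == [5.0]
        assert set(labels) == {0}

    def test_matches_exhaustive_enumeration(self):
        """Optimality oracle: 100 random instances, n <= 12, k <= 4."""
        rng = np.random.default_rng(6)
        for _ in range(100):
            n = int(rng.integers(4, 13))
            k = int(rng.integers(1, min(4, n) + 1))
            v = np.round(rng.uniform(0, 10, n), 3)
            if len(np.unique(v)) < k:
                continue
            _, labels = jenks_breaks(v, k)
            got = sum(((v[labels == c] - v[labels == c].mean()) ** 2).sum()
                      for c in range(k))
            assert got == pytest.approx(brute_force_jenks_ssd(v, k), abs=1e-9)

    def test_classes_contiguous_in_sorted_order(self):
        rng = np.random.default_rng(7)
        v = rng.uniform(0, 1, 30)
        _, labels = jenks_breaks(v, 3)
        order = np.argsort(v)
        assert (np.diff(labels[order]) >= 0).all()

    def test_too_many_classes_rejected(self):
        with pytest.raises(ValueError):
            jenks_breaks([1.0, 1.0, 2.0], 3)


class TestAdvantageZones:
    @staticmethod
    def types_of(scores):
        return classify_space_type(scores, theta=0.2)

    def test_single_activity_four_types_in_high_group(self):
        idx = pd.Index(range(8), name="unit_id")
        scores = pd.DataFrame({
            "service": [3, 0, 0, 1.0, 3, 0, 0, 1.0],
            "living": [0, 3, 0, 1.1, 0, 3, 0, 1.1],
            "ecology": [0, 0, 3, 1.05, 0, 0, 3, 1.05],
        }, index=idx)
        types = self.types_of(scores)
        surfaces = pd.DataFrame({
            "hiking": [10.0, 11, 12, 10, 1, 1, 2, 1],
            "jogging": np.ones(8), "cycling": np.ones(8)}, index=idx)
        with pytest.warns(UserWarning):
            zones = advantage_zones(surfaces, types, n_classes=2)
        high_cats = set(zones.category[zones.flags["hiking"]])
        assert high_cats == {"service|H", "living|H", "ecology|H", "mixed|H"}

    def test_all_three_advantaged_in_mixed_unit(self):
        idx = pd.Index(range(4), name="unit_id")
        scores = pd.DataFrame({"service": [1.0, 0, 0, 3],
                               "living": [1.05, 3, 0, 0],
                               "ecology": [1.02, 0, 3, 0]}, index=idx)
        types = self.types_of(scores)
        surfaces = pd.DataFrame({a: [9.0, 1, 1, 1] for a in
                                 ("hiking", "jogging", "cycling")}, index=idx)
        zones = advantage_zones(surfaces, types, n_classes=2)
        assert zones.category.iloc[0] == "mixed|H+J+C"
        assert zones.category.iloc[1].endswith("|-")

    def test_at_most_28_categories(self, pipeline_run):
        res, _ = pipeline_run
        cats = set(res.zones.category) - {
            c for c in res.zones.category if c.endswith("|-")}
        assert len(cats) <= 28

    def test_advantage_density_decays_from_corridor(self, pipeline_run):
        """Planted distance decay: advantage-flag density strictly
        decreases across three increasing distance bands."""
        res, _ = pipeline_run
        dist = res.truth.corridor_distance
        adv = res.zones.flags.any(axis=1)
        bands = pd.cut(dist, [0, 3000, 6000, np.inf])
        dens = adv.groupby(bands, observed=True).mean().to_numpy()
        assert dens[0] > dens[1] > dens[2]
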