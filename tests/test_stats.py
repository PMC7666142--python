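"""Range summaries, ANOVA/Tukey, Ward clustering and PERMANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform

from seacosm.stats import (
    anova_tukey,
    permanova,
    range_summary,
    round_half_up,
    ward_cluster,
)


class TestRangeSummary:
    def test_overall_range_row_spreads(self):
        df = pd.DataFrame(
            {
                "group": ["ALT", "PRK"],
                "k_min": [0.1, 0.1],
                "k_max": [5.8, 1.7],
            }
        )
        out = range_summary(df).set_index("group")
        assert out.loc["ALT", "spread_1dp"] == 5.7
        assert out.loc["PRK", "spread_1dp"] == 1.6

    def test_single_experiment_zero_spread(self):
        out = range_summary(
            pd.DataFrame({"group": ["X"], "k_min": [0.5], "k_max": [0.5]})
        )
        assert out["spread"].iloc[0] == 0.0

    def test_min_over_mins_max_over_maxes(self):
        df = pd.DataFrame(
            {
                "group": ["X"] * 3,
                "k_min": [0.4, 0.2, 0.3],
                "k_max": [1.0, 0.9, 1.4],
            }
        )
        out = range_summary(df)
        assert out["k_min"].iloc[0] == 0.2
        assert out["k_max"].iloc[0] == 1.4
        assert out["spread"].iloc[0] == pytest.approx(1.2)

    def test_invariant_to_order_and_duplication(self):
        df = pd.DataFrame(
            {"group": ["X", "X"], "k_min": [0.2, 0.5], "k_max": [1.1, 0.8]}
        )
        base = range_summary(df)
        shuffled = range_summary(df.iloc[::-1].reset_index(drop=True))
        duplicated = range_summary(pd.concat([df, df], ignore_index=True))
        for other in (shuffled, duplicated):
            assert other["spread"].iloc[0] == base["spread"].iloc[0]

    def test_inverted_range_rejected(self):
        with pytest.raises(ValueError, match="k_min > k_max"):
            range_summary(
                pd.DataFrame({"group": ["X"], "k_min": [1.0], "k_max": [0.5]})
            )

    def test_half_up_display_rounding(self):
        assert round_half_up(0.25) == 0.3  # bankers' rounding would give 0.2
        assert round_half_up(1.68) == 1.7
        assert round_half_up(1.77) == 1.8


class TestAnovaTukey:
    def test_separated_groups_detected(self):
        values = np.r_[np.zeros(5), np.ones(5) * 3]
        labels = np.r_[["a"] * 5, ["b"] * 5]
        values += np.random.default_rng(0).normal(0, 0.1, 10)
        res = anova_tukey(values, labels)
        assert res.p_value < 1e-6
        assert res.tukey["reject"].iloc[0]

    def test_degenerate_zero_variance_groups(self):
        res = anova_tukey([1, 1, 1, 2, 2, 2], ["a"] * 3 + ["b"] * 3)
        assert np.isinf(res.f_statistic)
        assert res.p_value == 0.0
        assert res.tukey["reject"].all()

    def test_null_groups_not_flagged(self):
        rng = np.random.default_rng(1234)
        values = rng.normal(0, 1, 18)
        labels = np.repeat(["a", "b", "c"], 6)
        res = anova_tukey(values, labels)
        assert not res.tukey["reject"].any()

    def test_pairwise_conclusions_symmetric(self):
        rng = np.random.default_rng(7)
        values = np.concatenate(
            [rng.normal(0, 1, 6), rng.normal(2, 1, 6), rng.normal(4, 1, 6)]
        )
        labels = np.repeat(["a", "b", "c"], 6)
        res = anova_tukey(values, labels)
        flipped = anova_tukey(values[::-1], labels[::-1])  # reversed sample order
        pairs = {
            frozenset((r.group1, r.group2)): r.reject for r in res.tukey.itertuples()
        }
        pairs_flipped = {
            frozenset((r.group1, r.group2)): r.reject
            for r in flipped.tukey.itertuples()
        }
        assert pairs == pairs_flipped

    def test_single_observation_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            anova_tukey([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestWardCluster:
    def test_identical_samples_merge_at_zero(self):
        x = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        res = ward_cluster(x)
        assert res.linkage[0, 2] == pytest.approx(0.0)
        assert set(res.linkage[0, :2].astype(int)) == {0, 1}

    def test_coincident_pair_merges_first(self):
        x = np.array([[0.0, 0.0], [3.0, 3.0], [3.0, 3.0]])
        res = ward_cluster(x)
        assert set(res.linkage[0, :2].astype(int)) == {1, 2}

    def test_heights_non_decreasing(self):
        rng = np.random.default_rng(5)
        res = ward_cluster(rng.normal(size=(10, 4)))
        assert (np.diff(res.linkage[:, 2]) >= -1e-12).all()

    def test_matches_centroid_based_ward_oracle(self):
        """Merge heights agree with an independent O(n^3) Ward agglomeration
        that recomputes every inter-cluster distance from cluster centroids."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            x = rng.normal(size=(8, 5))
            res = ward_cluster(x)
            oracle_heights = centroid_ward_heights(x)
            assert np.allclose(np.sort(res.linkage[:, 2]), np.sort(oracle_heights))

    def test_nan_rejected(self):
        x = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError, match="NaN"):
            ward_cluster(x)

    def test_newick_export_parses(self):
        rng = np.random.default_rng(2)
        res = ward_cluster(rng.normal(size=(5, 3)), labels=list("abcde"))
        text = res.to_newick()
        assert text.endswith(";")
        for leaf in "abcde":
            assert leaf in text
        assert text.count("(") == text.count(")") == 4

    def test_bray_curtis_distance_mode(self):
        rng = np.random.default_rng(8)
        x = np.abs(rng.normal(size=(6, 4)))
        res = ward_cluster(x, distance="bray-curtis")
        assert res.linkage.shape == (5, 4)


def centroid_ward_heights(x):
    """Independent Ward oracle: greedy agglomeration minimising the Ward
    merge cost 2|A||B|/(|A|+|B|) ||c_A − c_B||², recomputed from raw points
    at every step."""
    clusters = [[i] for i in range(x.shape[0])]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                ca, cb = x[a].mean(axis=0), x[b].mean(axis=0)
                cost = 2 * len(a) * len(b) / (len(a) + len(b)) * ((ca - cb) ** 2).sum()
                if best is None or cost < best[0]:
                    best = (cost, i, j)
        cost, i, j = best
        heights.append(np.sqrt(cost))
        clusters[i] = clusters[i] + clusters[j]
        del clusters[j]
    return np.array(heights)


class TestPermanova:
    def _two_clusters(self, sep=10.0, seed=0, n_per=6):
        rng = np.random.default_rng(seed)
        x = np.vstack(
            [rng.normal(0, 1, (n_per, 3)), rng.normal(sep, 1, (n_per, 3))]
        )
        labels = np.array(["a"] * n_per + ["b"] * n_per)
        return squareform(pdist(x)), labels

    def test_maximal_separation_gives_minimal_p(self):
        d, labels = self._two_clusters()
        res = permanova(d, labels, n_perm=199, seed=1)
        assert res.p_value == pytest.approx(1 / 200)
        assert res.pseudo_f > 10

    def test_bit_reproducible_for_fixed_seed(self):
        d, labels = self._two_clusters(sep=1.0)
        a = permanova(d, labels, n_perm=299, seed=7)
        b = permanova(d, labels, n_perm=299, seed=7)
        assert a == b

    def test_sample_reordering_preserves_pseudo_f(self):
        d, labels = self._two_clusters(sep=2.0)
        rng = np.random.default_rng(3)
        perm = rng.permutation(len(labels))
        res = permanova(d, labels, n_perm=99, seed=0)
        res_perm = permanova(d[np.ix_(perm, perm)], labels[perm], n_perm=99, seed=0)
        assert res.pseudo_f == pytest.approx(res_perm.pseudo_f)

    def test_single_member_group_rejected(self):
        d = squareform(pdist(np.random.default_rng(0).normal(size=(5, 2))))
        with pytest.raises(ValueError, match="single member"):
            permanova(d, np.array(["a", "a", "a", "a", "b"]))

    def test_asymmetric_matrix_rejected(self):
        d = np.array([[0.0, 1.0], [2.0, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            permanova(d, np.array(["a", "b"]))

    def test_agrees_with_reference_implementation(self):
        """Pseudo-F matches scikit-bio's PERMANOVA on the same inputs."""
        skbio_stats = pytest.importorskip("skbio.stats.distance")
        d, labels = self._two_clusters(sep=1.5, seed=9)
        ours = permanova(d, labels, n_perm=99, seed=0)
        ref = skbio_stats.permanova(
            skbio_stats.DistanceMatrix(d), labels.tolist(), permutations=99, seed=0
        )
        assert ours.pseudo_f == pytest.approx(ref["test statistic"], rel=1e-10)
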