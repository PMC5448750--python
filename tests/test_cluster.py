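import numpy as np
import pandas as pd
import pytest

from connscreen.cluster import (
    cluster_correspondence,
    kmeans,
    summarize_clusters,
    sweep_k,
)
from connscreen.io_tables import ExpressionTable
from connscreen.normalize import normalize_per_gene
from connscreen.synthetic_data import SyntheticSpec, simulate_expression

# 12 points in 2D, three tight triads; the exhaustive optimum over all
# 3-partitions (brute force over 3^12 label vectors) is inertia 4.255 with the
# triads as clusters.
TRIADS = np.array([
    [0.0, 0.0], [1.0, 0.2], [0.3, 1.1], [0.9, 0.9],
    [10.0, 0.0], [11.0, 0.3], [10.2, 1.0], [10.8, 0.8],
    [5.0, 8.0], [5.9, 8.1], [5.2, 9.0], [5.8, 8.9],
])
TRIADS_OPT_INERTIA = 4.255


def _counts_per_label(labels):
    return sorted(np.bincount(labels).tolist())


class TestKmeans:
    def test_separable_clouds_recovered_any_seed(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (20, 3)), rng.normal(5, 0.1, (20, 3))])
        for seed in (0, 1, 99):
            model = kmeans(X, 2, restarts=3, seed=seed)
            assert len(set(model.assignments[:20])) == 1
            assert len(set(model.assignments[20:])) == 1
            assert model.assignments[0] != model.assignments[-1]

    def test_k_equals_n_gives_zero_inertia_singletons(self):
        X = np.arange(10, dtype=float).reshape(5, 2)
        model = kmeans(X, 5, restarts=2, seed=0)
        assert model.inertia == pytest.approx(0.0)
        assert _counts_per_label(model.assignments) == [1] * 5

    def test_matches_exhaustive_optimum_on_triads(self):
        model = kmeans(TRIADS, 3, restarts=50, seed=0)
        assert model.inertia == pytest.approx(TRIADS_OPT_INERTIA, abs=1e-9)
        assert _counts_per_label(model.assignments) == [4, 4, 4]

    def test_inertia_recomputable_from_assignments(self):
        model = kmeans(TRIADS, 3, restarts=10, seed=1)
        d = TRIADS - model.centroids[model.assignments]
        assert model.inertia == pytest.approx((d ** 2).sum())

    def test_best_of_restarts_no_worse_than_single(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(40, 4))
        single = kmeans(X, 5, restarts=1, seed=7)
        many = kmeans(X, 5, restarts=25, seed=7)
        assert many.inertia <= single.inertia + 1e-12

    def test_deterministic_given_seed(self):
        a = kmeans(TRIADS, 3, restarts=5, seed=42)
        b = kmeans(TRIADS, 3, restarts=5, seed=42)
        assert np.array_equal(a.assignments, b.assignments)
        assert a.inertia == b.inertia

    def test_errors(self):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans(TRIADS, 13, restarts=1)
        with pytest.raises(ValueError, match="non-finite"):
            kmeans(np.array([[1.0, np.nan]]), 1)

    def test_agrees_with_sklearn_from_shared_init(self):
        """From identical initial centroids, Lloyd's algorithm here and in
        scikit-learn converge to identical assignments."""
        from sklearn.cluster import KMeans

        from connscreen.cluster import _lloyd

        rng = np.random.default_rng(3)
        X = np.vstack([rng.normal(c, 0.4, (15, 3)) for c in (0, 4, 9)])
        init = X[[0, 15, 30]]
        labels, _, inertia, _ = _lloyd(X, init, max_iter=300, tol=1e-10)
        sk = KMeans(n_clusters=3, init=init, n_init=1, max_iter=300,
                    tol=1e-10, algorithm="lloyd").fit(X)
        assert np.array_equal(labels, sk.labels_)
        assert inertia == pytest.approx(sk.inertia_, rel=1e-9)


class TestCorrespondence:
    def test_identity_stability_one(self):
        a = np.array([0, 0, 1, 1, 2, 2])
        parent, stab = cluster_correspondence(a, a)
        assert stab == 1.0
        assert parent == {0: 0, 1: 1, 2: 2}

    def test_pure_subdivision_stability_one(self):
        a = np.zeros(6, dtype=int)
        b = np.array([0, 0, 0, 1, 1, 1])
        parent, stab = cluster_correspondence(a, b)
        assert stab == 1.0
        assert parent == {0: 0, 1: 0}

    def test_reshuffle_stability_half(self):
        a = np.array([0, 0, 1, 1])
        b = np.array([0, 1, 0, 1])
        _, stab = cluster_correspondence(a, b)
        assert stab == 0.5

    def test_tie_goes_to_lower_label(self):
        a = np.array([0, 1])
        b = np.array([0, 0])
        parent, _ = cluster_correspondence(a, b)
        assert parent == {0: 0}

    def test_mismatched_gene_sets_error(self):
        with pytest.raises(ValueError):
            cluster_correspondence(np.array([0, 1]), np.array([0, 1, 2]))


class TestSweep:
    def test_planted_archetypes_recovered_and_scored(self):
        spec = SyntheticSpec(
            n_genes=200, noise=0.0, missing_rate=0.0,
            archetypes=[(0, 0.25), (2, 0.25), (4, 0.25), (6, 0.25)],
        )
        table, truth = simulate_expression(spec, seed=0)
        nt = normalize_per_gene(table)
        X = nt.data.to_numpy()
        res = sweep_k(X, 2, 6, restarts=10, seed=0)
        assert set(res.stability) == {2, 3, 4, 5}
        model = res.models[4]
        # noiseless archetypes: partition must match the planted labels
        mapping = pd.crosstab(pd.Series(truth), pd.Series(model.assignments))
        assert (mapping.gt(0).sum(axis=1) == 1).all()

    def test_random_relabeling_scores_below_one(self):
        rng = np.random.default_rng(0)
        a = np.repeat(np.arange(4), 25)
        b = a.copy()
        flip = rng.choice(100, 50, replace=False)
        b[flip] = (b[flip] + 1 + rng.integers(0, 3, 50)) % 4
        b[0] = 4  # ensure 5 labels so it is a (k, k+1) comparison
        _, stab = cluster_correspondence(a, b)
        assert stab < 1.0


class TestSummarize:
    def _nt(self, rows, ages):
        return normalize_per_gene(
            ExpressionTable(pd.DataFrame.from_dict(rows, orient="index", columns=ages))
        )

    def test_singleton_cluster_profile_is_gene_profile(self):
        nt = self._nt({"a": [1.0, 2.0, 3.0]}, ["t0", "t1", "t2"])
        model = kmeans(nt.data.to_numpy(), 1, restarts=1, seed=0, gene_ids=["a"])
        summary = summarize_clusters(nt, model)
        assert np.allclose(summary.profiles.loc[0], nt.data.loc["a"])

    def test_symmetric_pair_peaks_at_earliest_age(self):
        nt = self._nt({"a": [0.0, 2.0], "b": [2.0, 0.0]}, ["t0", "t1"])
        model = kmeans(nt.data.to_numpy(), 1, restarts=1, seed=0, gene_ids=["a", "b"])
        summary = summarize_clusters(nt, model)
        assert summary.peak_age.loc[0] == "t0"  # flat profile, tie -> earliest

    def test_chronological_ranks_span_ages(self):
        spec = SyntheticSpec(n_genes=140, noise=0.0, missing_rate=0.0)
        table, _ = simulate_expression(spec, seed=1)
        nt = normalize_per_gene(table)
        model = kmeans(nt.data.to_numpy(), 7, restarts=20, seed=0,
                       gene_ids=nt.gene_ids)
        summary = summarize_clusters(nt, model)
        assert sorted(summary.rank) == list(range(7))
        ranked_peaks = summary.peak_age[summary.rank.sort_values().index]
        assert list(ranked_peaks) == list(table.age_labels)
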