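"""PCA, Ward clustering, bootstrap stability, naming, and IQR classification."""

import numpy as np
import pandas as pd
import pytest

import divetype as dt
from divetype.classify import (DiveTypeModel, NamingThresholds,
                               assign_type_names, bootstrap_jaccard,
                               build_type_quantiles, classify_summary_dive,
                               standardize_and_pca, ward_cluster)


def naive_ward(X, k):
    """O(n^3) Lance-Williams Ward agglomeration; independent of scipy.

    Merges the pair with the smallest Ward cost at each step; returns flat
    labels at k clusters.
    """
    X = np.asarray(X, dtype=float)
    n = len(X)
    clusters = {i: [i] for i in range(n)}
    centroids = {i: X[i].copy() for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    nxt = n
    while len(clusters) > k:
        best = None
        ids = sorted(clusters)
        for a_i in range(len(ids)):
            for b_i in range(a_i + 1, len(ids)):
                a, b = ids[a_i], ids[b_i]
                na, nb = sizes[a], sizes[b]
                d2 = np.sum((centroids[a] - centroids[b]) ** 2)
                cost = (2.0 * na * nb / (na + nb)) * d2
                if best is None or cost < best[0]:
                    best = (cost, a, b)
        _, a, b = best
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        centroids[nxt] = (sizes[a] * centroids[a] + sizes[b] * centroids[b]) / (sizes[a] + sizes[b])
        sizes[nxt] = sizes[a] + sizes[b]
        del centroids[a], centroids[b], sizes[a], sizes[b]
        nxt += 1
    labels = np.empty(n, dtype=int)
    for lab, (_, members) in enumerate(sorted(clusters.items())):
        labels[members] = lab
    return labels


def same_partition(a, b):
    a, b = np.asarray(a), np.asarray(b)
    return len({(x, y) for x, y in zip(a, b)}) == len(set(a)) == len(set(b))


class TestPCA:
    def test_single_axis_variance(self):
        rng = np.random.default_rng(0)
        t = rng.normal(size=200)
        table = pd.DataFrame({"a": t, "b": 2 * t + 1e-9 * rng.normal(size=200),
                              "c": -t + 1e-9 * rng.normal(size=200)})
        scores, model, _ = standardize_and_pca(table)
        assert model.n_components == 1
        assert model.variance_fractions[0] > 0.999

    def test_eigenvalues_match_dense_oracle(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(2000, 12)),
                             columns=[f"v{i}" for i in range(12)])
        _, model, _ = standardize_and_pca(table, variance_target=1.0)
        Z = (table - table.mean()) / table.std(ddof=1)
        cov = np.cov(Z.to_numpy().T, ddof=1)
        oracle = np.sort(np.linalg.eigvalsh(cov))[::-1]
        got = model.variance_fractions * oracle.sum()
        assert np.allclose(got, oracle, atol=1e-8)

    def test_matches_sklearn(self):
        from sklearn.decomposition import PCA

        rng = np.random.default_rng(5)
        base = rng.normal(size=(500, 4))
        table = pd.DataFrame(base @ rng.normal(size=(4, 12)) + rng.normal(size=(500, 12)) * 0.3,
                             columns=[f"v{i}" for i in range(12)])
        scores, model, _ = standardize_and_pca(table, variance_target=0.85)
        Z = ((table - table.mean()) / table.std(ddof=1)).to_numpy()
        sk = PCA(n_components=model.n_components).fit(Z)
        # same subspace: scores agree up to per-component sign
        sk_scores = sk.transform(Z)
        for j in range(model.n_components):
            corr = np.corrcoef(scores[:, j], sk_scores[:, j])[0, 1]
            assert abs(corr) > 1 - 1e-9

    def test_minimal_k(self):
        rng = np.random.default_rng(6)
        table = pd.DataFrame(rng.normal(size=(300, 12)),
                             columns=[f"v{i}" for i in range(12)])
        _, model, _ = standardize_and_pca(table, variance_target=0.85)
        cum = np.cumsum(model.variance_fractions)
        assert cum[model.n_components - 1] >= 0.85
        assert cum[model.n_components - 2] < 0.85

    def test_variance_target_one_keeps_all(self):
        rng = np.random.default_rng(7)
        table = pd.DataFrame(rng.normal(size=(100, 12)),
                             columns=[f"v{i}" for i in range(12)])
        _, model, _ = standardize_and_pca(table, variance_target=1.0)
        assert model.n_components == 12
        assert model.variance_fractions.sum() == pytest.approx(1.0)

    def test_scores_centered_and_loadings_orthonormal(self):
        rng = np.random.default_rng(8)
        table = pd.DataFrame(rng.normal(size=(400, 6)),
                             columns=list("abcdef"))
        scores, model, _ = standardize_and_pca(table, variance_target=0.9)
        assert np.all(np.abs(scores.mean(axis=0)) < 1e-8)
        gram = model.loadings.T @ model.loadings
        assert np.allclose(gram, np.eye(model.n_components), atol=1e-8)
        assert np.all(np.diff(model.variance_fractions) <= 1e-12)

    def test_constant_column_rejected_by_name(self):
        table = pd.DataFrame({"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0]})
        with pytest.raises(ValueError, match="flat"):
            standardize_and_pca(table)

    def test_missing_rows_excluded(self):
        rng = np.random.default_rng(9)
        table = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        table.loc[7, "a"] = np.nan
        _, _, used = standardize_and_pca(table, variance_target=1.0)
        assert 7 not in used and len(used) == 49


class TestWard:
    def test_two_point_masses(self):
        X = np.vstack([np.zeros((50, 2)), np.ones((50, 2)) * 10])
        labels, _ = ward_cluster(X, 2)
        assert same_partition(labels, [0] * 50 + [1] * 50)

    def test_three_blobs_recovered(self):
        for seed in range(50):
            rng = np.random.default_rng(seed)
            centers = np.array([[0, 0], [10, 0], [0, 10]])
            truth = np.repeat([0, 1, 2], 30)
            X = centers[truth] + rng.normal(0, 0.1, size=(90, 2))
            labels, _ = ward_cluster(X, 3)
            assert same_partition(labels, truth)

    def test_k_one_single_cluster(self):
        rng = np.random.default_rng(1)
        labels, _ = ward_cluster(rng.normal(size=(20, 3)), 1)
        assert len(set(labels)) == 1

    def test_k_exceeds_n_rejected(self):
        with pytest.raises(ValueError):
            ward_cluster(np.zeros((3, 2)), 5)

    def test_merge_heights_monotone(self):
        rng = np.random.default_rng(2)
        _, Z = ward_cluster(rng.normal(size=(100, 4)), 5)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_agrees_with_naive_agglomeration(self):
        """scipy-backed Ward == brute-force Lance-Williams on small instances."""
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(10, 50))
            X = rng.normal(size=(n, 3))
            for k in (2, 3, 4):
                labels, _ = ward_cluster(X, k)
                assert same_partition(labels, naive_ward(X, k))


class TestBootstrapJaccard:
    def test_point_masses_perfectly_stable(self):
        X = np.vstack([np.zeros((40, 2)), np.ones((40, 2)) * 8])
        rep = bootstrap_jaccard(X, 2, B=100, seed=0)
        assert np.allclose(rep["mean_jaccard"], 1.0)

    def test_arbitrary_split_unstable(self):
        rng = np.random.default_rng(10)
        X = rng.normal(size=(120, 2))
        rep = bootstrap_jaccard(X, 2, B=100, seed=1)
        assert rep["mean_jaccard"].mean() < 0.75

    def test_single_iteration_matches_manual(self):
        X = np.vstack([np.zeros((10, 1)), np.ones((10, 1)) * 5])
        rep = bootstrap_jaccard(X, 2, B=1, seed=3)
        # manual replay of the same resample
        rng = np.random.default_rng(3)
        base, _ = ward_cluster(X, 2)
        idx = rng.integers(0, 20, size=20)
        boot, _ = ward_cluster(X[idx], 2)
        for c in rep["cluster"]:
            orig = set(np.flatnonzero(base == c)) & set(idx.tolist())
            best = max(
                len(orig & set(np.unique(idx[boot == b]).tolist()))
                / len(orig | set(np.unique(idx[boot == b]).tolist()))
                for b in (0, 1)
            )
            assert rep.loc[rep["cluster"] == c, "mean_jaccard"].iloc[0] == pytest.approx(best)

    def test_jaccard_in_unit_interval(self):
        rng = np.random.default_rng(12)
        rep = bootstrap_jaccard(rng.normal(size=(60, 3)), 3, B=25, seed=5)
        assert ((rep["mean_jaccard"] >= 0) & (rep["mean_jaccard"] <= 1)).all()


def cluster_metrics_frame(rows):
    """rows: per-cluster dicts of raw-metric medians replicated 3x."""
    frames = []
    for label, med in enumerate(rows):
        df = pd.DataFrame([med] * 3)
        df["label"] = label
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    return out.drop(columns="label"), out["label"].to_numpy()


class TestNaming:
    def test_published_median_rows_named_correctly(self):
        rows = [
            dict(MaxDepth=340.0, DiveDur=30.3, BottFrac=0.5, SDBottDepth=19.4, DistToSeaFlr=388.9),
            dict(MaxDepth=16.0, DiveDur=2.3, BottFrac=0.0, SDBottDepth=0.0, DistToSeaFlr=547.1),
            dict(MaxDepth=290.0, DiveDur=21.4, BottFrac=0.2, SDBottDepth=5.9, DistToSeaFlr=458.3),
            dict(MaxDepth=456.5, DiveDur=45.8, BottFrac=0.7, SDBottDepth=6.9, DistToSeaFlr=0.0),
            dict(MaxDepth=635.0, DiveDur=33.1, BottFrac=0.5, SDBottDepth=60.3, DistToSeaFlr=80.1),
            dict(MaxDepth=21.4, DiveDur=11.0, BottFrac=0.7, SDBottDepth=1.8, DistToSeaFlr=434.8),
        ]
        table, labels = cluster_metrics_frame(rows)
        names = assign_type_names(labels, table)
        assert names == {0: "Mid-water", 1: "Short-shallow", 2: "V-shaped",
                         3: "Benthic", 4: "Variable", 5: "Long-shallow"}

    def test_collision_reported_as_ambiguous(self):
        rows = [dict(MaxDepth=16.0, DiveDur=2.0, BottFrac=0.0, SDBottDepth=0.0, DistToSeaFlr=500.0)] * 2
        table, labels = cluster_metrics_frame(rows)
        names = assign_type_names(labels, table)
        assert names[0] == "Short-shallow"
        assert "ambiguous" in names[1]


class TestQuantilesAndSummaryClassification:
    def test_hand_enumerated_quartiles(self):
        vals = np.array([10.0, 20.0, 30.0, 40.0])
        table = pd.DataFrame({"MaxDepth": vals, "DiveDur": vals})
        q = build_type_quantiles(np.zeros(4, dtype=int), table, {0: "T"})
        # linear-interpolation (type-7) quartiles of {10,20,30,40}
        assert q["T"]["MaxDepth"] == pytest.approx((17.5, 25.0, 32.5))

    def test_single_member_degenerate(self):
        table = pd.DataFrame({"MaxDepth": [99.0], "DiveDur": [5.0]})
        q = build_type_quantiles(np.zeros(1, dtype=int), table, {0: "T"})
        assert q["T"]["MaxDepth"] == (99.0, 99.0, 99.0)

    def test_quantiles_monotone(self, big_pipeline):
        for name, q in big_pipeline.model.type_quantiles.items():
            for var in ("MaxDepth", "DiveDur"):
                q1, med, q3 = q[var]
                assert q1 <= med <= q3

    def test_probe_outside_all_windows_unknown(self, big_pipeline):
        name, n = classify_summary_dive(5000.0, 1.0, big_pipeline.model.type_quantiles)
        assert name == "Unknown" and n == 0

    def test_unique_window_classifies(self):
        q = {
            "A": {"MaxDepth": (10.0, 20.0, 30.0), "DiveDur": (1.0, 2.0, 3.0)},
            "B": {"MaxDepth": (100.0, 200.0, 300.0), "DiveDur": (10.0, 20.0, 30.0)},
        }
        assert classify_summary_dive(15.0, 2.5, q) == ("A", 1)
        assert classify_summary_dive(250.0, 15.0, q) == ("B", 1)

    def test_tie_break_by_normalized_median_distance(self):
        q = {
            "A": {"MaxDepth": (0.0, 10.0, 40.0), "DiveDur": (0.0, 10.0, 40.0)},
            "B": {"MaxDepth": (0.0, 30.0, 40.0), "DiveDur": (0.0, 30.0, 40.0)},
        }
        assert classify_summary_dive(12.0, 12.0, q) == ("A", 2)
        assert classify_summary_dive(28.0, 28.0, q) == ("B", 2)


def test_model_json_round_trip(big_pipeline):
    model = big_pipeline.model
    back = DiveTypeModel.from_json(model.to_json())
    assert back.columns == model.columns
    assert np.allclose(back.loadings, model.loadings)
    assert back.type_names == model.type_names
    assert back.type_quantiles == model.type_quantiles
    name_a, _ = classify_summary_dive(400.0, 30.0, model.type_quantiles)
    name_b, _ = classify_summary_dive(400.0, 30.0, back.type_quantiles)
    assert name_a == name_b
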