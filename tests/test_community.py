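"""Clustering and the four-metric quality suite, against brute-force oracles."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

import synovnet as sn
from synovnet.community import quality_report


def brute_modularity(g, partition):
    """Direct edge-sum evaluation of Q = sum_c (w_c/W - (s_c/2W)^2)."""
    total = sum(w for _, _, w in g.edges(data="weight", default=1.0))
    clusters = set(partition.values())
    q = 0.0
    for c in clusters:
        members = {v for v in g.nodes if partition[v] == c}
        w_c = sum(w for u, v, w in g.edges(data="weight", default=1.0)
                  if u in members and v in members)
        s_c = sum(
            w
            for u, v, w in g.edges(data="weight", default=1.0)
            for end in (u, v)
            if end in members
        )
        q += w_c / total - (s_c / (2 * total)) ** 2
    return q


def brute_silhouette(values, labels):
    n = len(values)
    out = []
    for i in range(n):
        own = [j for j in range(n) if labels[j] == labels[i] and j != i]
        if not own:
            out.append(0.0)
            continue
        a = np.mean([np.linalg.norm(values[i] - values[j]) for j in own])
        b = min(
            np.mean([np.linalg.norm(values[i] - values[j])
                     for j in range(n) if labels[j] == c])
            for c in set(labels) if c != labels[i]
        )
        out.append(0.0 if max(a, b) == 0 else (b - a) / max(a, b))
    return float(np.mean(out))


def brute_reliability(values, labels):
    cents = {c: values[[j for j in range(len(values)) if labels[j] == c]].mean(axis=0)
             for c in set(labels)}
    hits = 0
    for i in range(len(values)):
        nearest = min(sorted(cents), key=lambda c: np.linalg.norm(values[i] - cents[c]))
        hits += nearest == labels[i]
    return hits / len(values)


def _rmatrix(values, ids=None):
    values = np.asarray(values, dtype=float)
    ids = ids or [f"p{i:02d}" for i in range(len(values))]
    return sn.RescaledMatrix(ids, [f"f{j}" for j in range(values.shape[1])], values)


class TestModularity:
    def test_trivial_partition_is_zero(self):
        g = nx.complete_graph(5)
        part = {v: 1 for v in g.nodes}
        assert sn.modularity(g, part) == pytest.approx(0.0, abs=1e-15)

    def test_two_disconnected_cliques_half(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        part = {v: (1 if v < 5 else 2) for v in g.nodes}
        assert sn.modularity(g, part) == pytest.approx(0.5, abs=1e-15)

    def test_matches_brute_force_and_networkx(self, rng):
        for _ in range(15):
            g = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1 << 30)))
            if g.number_of_edges() == 0:
                continue
            for u, v in g.edges:
                g[u][v]["weight"] = float(rng.uniform(0.1, 1.0))
            part = {v: int(rng.integers(1, 4)) for v in g.nodes}
            q = sn.modularity(g, part)
            assert q == pytest.approx(brute_modularity(g, part), abs=1e-12)
            comms = {}
            for v, c in part.items():
                comms.setdefault(c, set()).add(v)
            q_nx = nx.community.modularity(g, comms.values(), weight="weight")
            assert q == pytest.approx(q_nx, abs=1e-12)

    def test_missing_vertex_rejected(self):
        g = nx.path_graph(3)
        with pytest.raises(ValueError):
            sn.modularity(g, {0: 1, 1: 1})


class TestLouvain:
    def test_two_cliques_recovered(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        nx.set_edge_attributes(g, 1.0, "weight")
        part = sn.louvain_partition(g, seed=0)
        assert len(set(part.values())) == 2
        assert len({part[v] for v in range(5)}) == 1
        assert len({part[v] for v in range(5, 10)}) == 1

    def test_complete_graph_single_cluster(self):
        g = nx.complete_graph(6)
        nx.set_edge_attributes(g, 1.0, "weight")
        part = sn.louvain_partition(g, seed=0)
        assert len(set(part.values())) == 1

    def test_deterministic_given_seed(self, archetype_cohort):
        r = sn.rescale_features(archetype_cohort.marker_matrix())
        g = sn.lrnet_build(r)
        p1 = sn.louvain_partition(g, seed=5)
        p2 = sn.louvain_partition(g, seed=5)
        assert p1 == p2

    def test_cluster_ids_contiguous_from_one(self, archetype_cohort):
        r = sn.rescale_features(archetype_cohort.marker_matrix())
        part = sn.louvain_partition(sn.lrnet_build(r), seed=1)
        ids = sorted(set(part.values()))
        assert ids == list(range(1, len(ids) + 1))

    def test_returned_q_is_best_across_restarts(self, archetype_cohort):
        r = sn.rescale_features(archetype_cohort.marker_matrix())
        g = sn.lrnet_build(r)
        best = sn.louvain_partition(g, seed=0, restarts=20)
        single = sn.louvain_partition(g, seed=0, restarts=1)
        assert sn.modularity(g, best) >= sn.modularity(g, single) - 1e-12


class TestSilhouette:
    def test_far_separated_pairs(self):
        values = np.array([[0.0], [0.01], [10.0], [10.01]])
        part = {"p00": 1, "p01": 1, "p02": 2, "p03": 2}
        s = sn.silhouette_mean(_rmatrix(values), part)
        assert s > 0.9

    def test_matches_brute_force_and_sklearn(self, rng):
        from sklearn.metrics import silhouette_score

        for _ in range(10):
            n = int(rng.integers(4, 9))
            values = rng.uniform(size=(n, 2))
            labels = rng.integers(1, 3, size=n)
            if len(set(labels)) < 2:
                labels[0] = 1 + (labels[0] % 2)
            ids = [f"p{i:02d}" for i in range(n)]
            part = dict(zip(ids, (int(c) for c in labels)))
            mine = sn.silhouette_mean(_rmatrix(values, ids), part)
            assert mine == pytest.approx(brute_silhouette(values, labels), abs=1e-12)
            if min(np.bincount(labels)[1:]) >= 2:
                skl = silhouette_score(values, labels, metric="euclidean")
                assert mine == pytest.approx(skl, abs=1e-9)

    def test_single_cluster_rejected(self):
        with pytest.raises(ValueError):
            sn.silhouette_mean(_rmatrix(np.zeros((3, 1))), {f"p{i:02d}": 1 for i in range(3)})


class TestCentroidReliability:
    def test_perfect_separation(self):
        values = np.vstack([np.zeros((4, 2)), np.ones((4, 2))])
        part = {f"p{i:02d}": (1 if i < 4 else 2) for i in range(8)}
        assert sn.centroid_reliability(_rmatrix(values), part) == 1.0

    def test_shuffled_labels_near_half(self, rng):
        values = rng.uniform(size=(200, 2))
        labels = rng.permutation([1] * 100 + [2] * 100)
        ids = [f"p{i:03d}" for i in range(200)]
        part = dict(zip(ids, (int(c) for c in labels)))
        rel = sn.centroid_reliability(
            sn.RescaledMatrix(ids, ["a", "b"], values), part
        )
        assert 0.35 < rel < 0.65

    def test_matches_brute_force(self, rng):
        for _ in range(10):
            n = int(rng.integers(4, 9))
            values = rng.uniform(size=(n, 3))
            labels = rng.integers(1, 3, size=n)
            if len(set(labels)) < 2:
                labels[0] = 1 + (labels[0] % 2)
            ids = [f"p{i:02d}" for i in range(n)]
            part = dict(zip(ids, (int(c) for c in labels)))
            mine = sn.centroid_reliability(_rmatrix(values, ids), part)
            assert mine == pytest.approx(brute_reliability(values, labels), abs=1e-12)


class TestWithinClusterVariance:
    def test_identical_vectors_zero(self):
        values = np.vstack([np.full((3, 2), 0.3), np.full((3, 2), 0.9)])
        part = {f"p{i:02d}": (1 if i < 3 else 2) for i in range(6)}
        table, grand = sn.within_cluster_variance(_rmatrix(values), part)
        assert grand == 0.0

    def test_two_point_sd(self):
        values = np.array([[0.0], [1.0]])
        part = {"p00": 1, "p01": 1}
        _, grand = sn.within_cluster_variance(_rmatrix(values), part)
        assert grand == pytest.approx(0.5)

    def test_matches_direct_formula(self, rng):
        values = rng.uniform(size=(9, 3))
        labels = [1, 1, 1, 2, 2, 2, 3, 3, 3]
        ids = [f"p{i:02d}" for i in range(9)]
        part = dict(zip(ids, labels))
        table, grand = sn.within_cluster_variance(_rmatrix(values, ids), part)
        expected = np.mean(
            [values[np.array(labels) == c].std(axis=0, ddof=0).mean()
             for c in (1, 2, 3)]
        )
        assert grand == pytest.approx(expected, abs=1e-12)


class TestBoundaryScore:
    def test_interior_and_boundary_extremes(self):
        g = nx.Graph()
        g.add_edge("a", "b", weight=1.0)
        g.add_edge("c", "d", weight=1.0)
        part = {"a": 1, "b": 1, "c": 1, "d": 2}
        scores = sn.boundary_score(g, part)
        assert scores["a"] == 0.0 and scores["c"] == 1.0 and scores["d"] == 1.0

    def test_mixed_fraction(self):
        g = nx.Graph()
        for other, cluster in [("b", 1), ("c", 2), ("d", 2), ("e", 2)]:
            g.add_edge("a", other, weight=1.0)
        part = {"a": 1, "b": 1, "c": 2, "d": 2, "e": 2}
        assert sn.boundary_score(g, part)["a"] == pytest.approx(0.75)


class TestProfilesAndCrosstab:
    def test_profile_normalised_to_dataset_max(self):
        df = pd.DataFrame(
            {"patient_id": ["a", "b"], "group": ["g1", "g2"], "m": [2.0, 4.0]}
        )
        cohort = sn.CohortTable(df)
        prof = sn.cluster_profile(cohort, {"a": 1, "b": 2})
        assert prof.loc[1, "m"] == pytest.approx(0.5)
        assert prof.loc[2, "m"] == pytest.approx(1.0)

    def test_zero_max_convention(self):
        df = pd.DataFrame(
            {"patient_id": ["a", "b"], "group": ["g", "g"], "m": [0.0, 0.0]}
        )
        prof = sn.cluster_profile(sn.CohortTable(df), {"a": 1, "b": 2})
        assert (prof["m"] == 0.0).all()

    def test_calibrated_cohort_neutrophil_contrast(self, calibrated_cohort):
        """Clusters dominated by infected-implant patients show a higher
        neutrophil centroid than aseptic-loosening clusters (published
        group means 73.2 vs 19.5)."""
        part = {
            pid: (1 if grp in ("PJI", "LG-PJI") else 2 if grp == "OL/AL" else 3)
            for pid, grp in zip(
                calibrated_cohort.patient_ids, calibrated_cohort.group_labels
            )
        }
        prof = sn.cluster_profile(calibrated_cohort, part)
        assert prof.loc[1, "neu_pct"] > prof.loc[2, "neu_pct"]

    def test_crosstab_counts_sum_to_n(self, archetype_cohort):
        r = sn.rescale_features(archetype_cohort.marker_matrix())
        part = sn.louvain_partition(sn.lrnet_build(r), seed=0)
        tab = sn.cross_tabulate(archetype_cohort, part)
        assert tab.to_numpy().sum() == len(archetype_cohort)

    def test_aligned_archetypes_near_diagonal(self, archetype_cohort):
        r = sn.rescale_features(archetype_cohort.marker_matrix())
        part = sn.louvain_partition(sn.lrnet_build(r), seed=0)
        tab = pd.crosstab(
            archetype_cohort.df["patient_id"].map(part),
            archetype_cohort.df["archetype"],
        )
        # each cluster is dominated by a single generating archetype
        assert (tab.max(axis=1) / tab.sum(axis=1) > 0.8).all()


class TestSelectNetwork:
    def test_single_candidate_ranks_first(self, archetype_cohort):
        feats = archetype_cohort.marker_names[:3]
        ranked = sn.select_network(
            archetype_cohort, feats, range(3, 4), seed=0, restarts=3
        )
        assert len(ranked) == 1 and ranked[0].feature_subset == tuple(sorted(feats))

    def test_signal_subset_beats_noise(self, archetype_cohort, rng):
        df = archetype_cohort.df.copy()
        for j in range(3):
            df[f"noise{j}"] = rng.uniform(0, 1, len(df))
        cohort = sn.CohortTable(df)
        signal = ["lym_pct", "nk_pct", "hladr_nk_pct"]
        ranked = sn.select_network(
            cohort, signal + ["noise0", "noise1", "noise2"],
            range(3, 4), seed=0, restarts=3,
        )
        by_subset = {frozenset(c.feature_subset): c for c in ranked}
        pure_signal = by_subset[frozenset(signal)]
        noise_only = [c for c in ranked
                      if all(f.startswith("noise") for f in c.feature_subset)]
        assert all(c.balance_score < pure_signal.balance_score for c in noise_only)
        # the winner is never a noise-only subset
        assert any(not f.startswith("noise") for f in ranked[0].feature_subset)

    def test_candidate_order_invariance(self, archetype_cohort):
        feats = archetype_cohort.marker_names[:4]
        r1 = sn.select_network(archetype_cohort, feats, range(2, 3), seed=0, restarts=3)
        r2 = sn.select_network(
            archetype_cohort, list(reversed(feats)), range(2, 3), seed=0, restarts=3
        )
        assert [c.feature_subset for c in r1] == [c.feature_subset for c in r2]

    def test_empty_size_range_rejected(self, archetype_cohort):
        with pytest.raises(ValueError):
            sn.select_network(archetype_cohort, ["lym_pct"], range(5, 5))


class TestQualityReport:
    def test_report_consistent_with_metrics(self, archetype_cohort):
        r = sn.rescale_features(archetype_cohort.marker_matrix())
        g = sn.lrnet_build(r)
        part = sn.louvain_partition(g, seed=0)
        q = quality_report(g, r, part)
        assert q.modularity == pytest.approx(sn.modularity(g, part))
        assert q.silhouette_mean == pytest.approx(sn.silhouette_mean(r, part))
        assert -1 <= q.silhouette_mean <= 1
        assert 0 <= q.centroid_reliability <= 1
        assert q.mean_within_cluster_sd >= 0
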