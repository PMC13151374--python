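"""Cluster detection and quality scoring on the patient similarity network.

Louvain modularity optimisation partitions the weighted graph into patient
clusters (every patient in exactly one cluster). Candidate networks —
built from different feature subsets — are then compared on four metrics:

- **modularity** Q: structural quality of the partition on the graph;
- **mean silhouette**: unambiguity of patient assignment, computed in the
  rescaled feature space;
- **centroid reliability**: fraction of patients closest to their own
  cluster's centroid (how well "average patients" represent clusters);
- **mean within-cluster sd**: spread of parameter values inside clusters
  (lower is better).

The "most balanced" network is selected by a maximin rule: each metric is
min-max normalised across candidates (variance inverted), and a
candidate's balance score is its worst normalised metric.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from synovnet.cohort import CohortTable
from synovnet.network import RescaledMatrix, SimilarityParams, lrnet_build, rescale_features

Partition = dict[str, int]


@dataclass
class QualityReport:
    """The four selection metrics for one candidate network."""

    modularity: float
    silhouette_mean: float
    centroid_reliability: float
    mean_within_cluster_sd: float
    n_clusters: int

    def as_dict(self) -> dict[str, float]:
        return {
            "modularity": self.modularity,
            "silhouette_mean": self.silhouette_mean,
            "centroid_reliability": self.centroid_reliability,
            "mean_within_cluster_sd": self.mean_within_cluster_sd,
            "n_clusters": self.n_clusters,
        }


@dataclass
class CandidateNetwork:
    """One feature subset with its graph, partition, quality and rank score."""

    feature_subset: tuple[str, ...]
    graph: nx.Graph
    partition: Partition
    quality: QualityReport
    balance_score: float = float("nan")
    normalised_metrics: dict[str, float] = field(default_factory=dict)


def _relabel_contiguous(partition: Partition) -> Partition:
    """Relabel cluster ids 1..K, ordered by each cluster's smallest patient id."""
    clusters: dict[int, list[str]] = {}
    for pid, c in partition.items():
        clusters.setdefault(c, []).append(pid)
    ordered = sorted(clusters.values(), key=lambda members: min(members))
    return {pid: i + 1 for i, members in enumerate(ordered) for pid in members}


def louvain_partition(
    g: nx.Graph,
    resolution: float = 1.0,
    seed: int = 0,
    restarts: int = 20,
) -> Partition:
    """Louvain community detection with restarts; best modularity wins.

    Runs the (randomised) Louvain algorithm ``restarts`` times with seeds
    derived deterministically from ``seed`` and returns the partition with
    the highest weighted modularity; ties keep the earliest restart.
    Cluster ids are contiguous from 1, ordered by smallest patient id.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: Partition | None = None
    best_q = -np.inf
    for r in range(restarts):
        communities = nx.community.louvain_communities(
            g, weight="weight", resolution=resolution, seed=seed + r
        )
        part = {pid: i for i, comm in enumerate(communities) for pid in comm}
        q = modularity(g, part) if g.number_of_edges() else 0.0
        if q > best_q + 1e-15:
            best_q, best = q, part
    assert best is not None
    return _relabel_contiguous(best)


def modularity(g: nx.Graph, partition: Partition) -> float:
    """Weighted Newman modularity Q = sum_c (w_c/W - (s_c/(2W))^2).

    W is the total edge weight, w_c the intra-cluster weight of cluster c
    and s_c the summed strength (weighted degree) of its vertices.
    """
    missing = [v for v in g.nodes if v not in partition]
    if missing:
        raise ValueError(f"partition is missing vertex {missing[0]!r}")
    if g.number_of_edges() == 0:
        raise ValueError("modularity undefined on an empty edge set")
    total_w = g.size(weight="weight")
    intra: dict[int, float] = {}
    strength: dict[int, float] = {}
    for v in g.nodes:
        strength.setdefault(partition[v], 0.0)
    for u, v, w in g.edges(data="weight", default=1.0):
        strength[partition[u]] += w
        strength[partition[v]] += w
        if partition[u] == partition[v]:
            intra[partition[u]] = intra.get(partition[u], 0.0) + w
    q = 0.0
    for c, s in strength.items():
        q += intra.get(c, 0.0) / total_w - (s / (2.0 * total_w)) ** 2
    return q


def _groups_of(partition: Partition, ids: list[str]) -> dict[int, np.ndarray]:
    idx: dict[int, list[int]] = {}
    for i, pid in enumerate(ids):
        idx.setdefault(partition[pid], []).append(i)
    return {c: np.array(v) for c, v in idx.items()}


def silhouette_mean(r: RescaledMatrix, partition: Partition) -> float:
    """Mean silhouette in the rescaled feature space.

    Per patient, s = (b - a) / max(a, b) with a the mean distance to the
    patient's own cluster (excluding itself) and b the smallest mean
    distance to any other cluster. Members of singleton clusters
    contribute 0. Undefined for fewer than two clusters.
    """
    groups = _groups_of(partition, r.patient_ids)
    if len(groups) < 2:
        raise ValueError("silhouette undefined for a single cluster")
    dist = r.distances()
    scores = np.zeros(len(r.patient_ids))
    for c, members in groups.items():
        for i in members:
            if len(members) == 1:
                scores[i] = 0.0
                continue
            a = dist[i, members].sum() / (len(members) - 1)
            b = min(
                dist[i, other].mean()
                for co, other in groups.items()
                if co != c
            )
            denom = max(a, b)
            scores[i] = 0.0 if denom == 0 else (b - a) / denom
    return float(scores.mean())


def centroid_reliability(r: RescaledMatrix, partition: Partition) -> float:
    """Fraction of patients whose nearest cluster centroid is their own.

    Centroids are per-cluster feature means in the rescaled space. A value
    of 1 means every cluster is perfectly represented by its "average
    patient"; chance level for two interchangeable clusters is about 0.5.
    """
    groups = _groups_of(partition, r.patient_ids)
    if len(groups) < 2:
        raise ValueError("centroid reliability undefined for a single cluster")
    labels = sorted(groups)
    centroids = np.vstack([r.values[groups[c]].mean(axis=0) for c in labels])
    own = np.array([labels.index(partition[pid]) for pid in r.patient_ids])
    d2 = ((r.values[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
    nearest = d2.argmin(axis=1)
    return float((nearest == own).mean())


def within_cluster_variance(
    r: RescaledMatrix, partition: Partition
) -> tuple[pd.DataFrame, float]:
    """Population sd per cluster x feature, and their grand mean.

    The grand mean (over all cluster x feature cells) is the scalar
    criterion used in network selection; lower means tighter clusters.
    """
    groups = _groups_of(partition, r.patient_ids)
    rows = {
        c: r.values[members].std(axis=0, ddof=0)
        for c, members in sorted(groups.items())
    }
    table = pd.DataFrame.from_dict(rows, orient="index", columns=r.feature_names)
    table.index.name = "cluster"
    return table, float(table.to_numpy().mean())


def quality_report(
    g: nx.Graph, r: RescaledMatrix, partition: Partition
) -> QualityReport:
    """All four selection metrics for one network/partition."""
    n_clusters = len(set(partition.values()))
    if n_clusters >= 2:
        sil = silhouette_mean(r, partition)
        rel = centroid_reliability(r, partition)
    else:  # degenerate single-cluster partition: metrics undefined
        sil, rel = float("nan"), float("nan")
    _, grand_sd = within_cluster_variance(r, partition)
    return QualityReport(
        modularity=modularity(g, partition),
        silhouette_mean=sil,
        centroid_reliability=rel,
        mean_within_cluster_sd=grand_sd,
        n_clusters=n_clusters,
    )


def _normalise(values: np.ndarray, invert: bool = False) -> np.ndarray:
    """Min-max normalise across candidates; constant metrics map to 1 (no
    discriminating power, so they never dominate the maximin)."""
    values = np.where(np.isnan(values), -np.inf if not invert else np.inf, values)
    if invert:
        values = -values
    lo, hi = values.min(), values.max()
    if hi == lo:
        return np.ones_like(values, dtype=float)
    return (values - lo) / (hi - lo)


def select_network(
    cohort: CohortTable,
    candidate_features: list[str],
    subset_sizes: range,
    params: SimilarityParams | None = None,
    resolution: float = 1.0,
    seed: int = 0,
    restarts: int = 20,
    max_candidates: int = 5000,
) -> list[CandidateNetwork]:
    """Exhaustive feature-subset sweep ranked by the maximin balance score.

    For every subset of ``candidate_features`` whose size is in
    ``subset_sizes``, builds the rescale -> LRNet -> Louvain pipeline and
    computes the four-metric quality report. Each metric is min-max
    normalised across candidates (within-cluster sd inverted so higher is
    better) and the balance score is the minimum of the four normalised
    metrics. Output is sorted by balance score descending; ties are broken
    by the sum of normalised metrics, then by the subset name tuple.
    """
    sizes = [s for s in subset_sizes if 1 <= s <= len(candidate_features)]
    if not sizes:
        raise ValueError("subset size range is empty or out of bounds")
    n_cand = sum(
        len(list(itertools.combinations(candidate_features, s))) for s in sizes
    )
    if n_cand > max_candidates:
        raise ValueError(
            f"{n_cand} candidate subsets exceed max_candidates={max_candidates}"
        )
    candidates: list[CandidateNetwork] = []
    for size in sizes:
        for subset in itertools.combinations(sorted(candidate_features), size):
            r = rescale_features(cohort.marker_matrix(list(subset)))
            g = lrnet_build(r, params)
            part = louvain_partition(g, resolution=resolution, seed=seed,
                                     restarts=restarts)
            candidates.append(
                CandidateNetwork(subset, g, part, quality_report(g, r, part))
            )

    metric_cols = {
        "modularity": np.array([c.quality.modularity for c in candidates]),
        "silhouette_mean": np.array([c.quality.silhouette_mean for c in candidates]),
        "centroid_reliability": np.array(
            [c.quality.centroid_reliability for c in candidates]
        ),
        "mean_within_cluster_sd": np.array(
            [c.quality.mean_within_cluster_sd for c in candidates]
        ),
    }
    normed = {
        name: _normalise(vals, invert=(name == "mean_within_cluster_sd"))
        for name, vals in metric_cols.items()
    }
    for i, cand in enumerate(candidates):
        cand.normalised_metrics = {name: float(vals[i]) for name, vals in normed.items()}
        cand.balance_score = float(min(vals[i] for vals in normed.values()))
    candidates.sort(
        key=lambda c: (
            -c.balance_score,
            -sum(c.normalised_metrics.values()),
            c.feature_subset,
        )
    )
    return candidates


def cluster_profile(cohort: CohortTable, partition: Partition) -> pd.DataFrame:
    """Per-cluster marker means normalised to each marker's data-set maximum.

    Returns a clusters x markers table of display values in [0, 1]; a
    marker whose data-set maximum is 0 displays as 0 by convention. The
    raw (unnormalised) means are attached as ``.attrs['raw_means']``.
    """
    m = cohort.marker_matrix()
    labels = pd.Series({pid: partition[pid] for pid in m.index}, name="cluster")
    means = m.groupby(labels).mean().sort_index()
    maxima = m.max(axis=0)
    display = means.divide(maxima.where(maxima != 0, 1.0), axis=1)
    display[maxima.index[maxima == 0]] = 0.0
    display.index.name = "cluster"
    display.attrs["raw_means"] = means
    return display


def boundary_score(g: nx.Graph, partition: Partition) -> dict[str, float]:
    """Per-patient fraction of incident edge weight crossing cluster borders.

    0 marks an interior patient (all similarity stays within the cluster),
    1 a fully boundary patient. Patients near 1 sit between clusters and
    are the diagnostically ambiguous cases.
    """
    scores: dict[str, float] = {}
    for v in g.nodes:
        total = inter = 0.0
        for _, u, w in g.edges(v, data="weight", default=1.0):
            total += w
            if partition[u] != partition[v]:
                inter += w
        scores[v] = 0.0 if total == 0 else inter / total
    return scores


def cross_tabulate(cohort: CohortTable, partition: Partition) -> pd.DataFrame:
    """Cluster x clinical-group contingency table (counts sum to cohort size)."""
    df = cohort.df
    if df["group"].isna().any():
        pid = df.loc[df["group"].isna(), "patient_id"].iloc[0]
        raise ValueError(f"patient {pid!r} has no group label")
    clusters = df["patient_id"].map(partition)
    if clusters.isna().any():
        pid = df.loc[clusters.isna(), "patient_id"].iloc[0]
        raise ValueError(f"patient {pid!r} missing from partition")
    table = pd.crosstab(clusters.astype(int), df["group"])
    table.index.name = "cluster"
    return table
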