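"""Patient similarity network construction.

Pipeline: per-feature min-max rescaling to [0,1] -> Euclidean distances ->
Gaussian-kernel similarities -> local-representativeness edge selection.

The edge-selection rule follows the local representative network (LRNet)
idea: a patient's *representativeness* is the number of other patients for
whom they are the single nearest neighbour (reverse-nearest-neighbour
votes), and it determines how many nearest neighbours that patient links
to. Locally representative patients (hubs of their neighbourhood) connect
more widely; peripheral patients still link to at least their one nearest
neighbour, so the graph never has isolated vertices.

All nearest-neighbour ties are broken by ascending patient id so that runs
are bit-reproducible.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from synovnet.cohort import CohortError


@dataclass
class SimilarityParams:
    """Gaussian-kernel bandwidth configuration.

    ``sigma_rule`` chooses how the bandwidth is set from the data:
    ``median_distance`` (default) and ``mean_distance`` use the pairwise
    Euclidean distances on the rescaled matrix; ``fixed`` uses ``sigma``
    as given.
    """

    sigma: float = 1.0
    sigma_rule: str = "median_distance"
    degree_cap: int | None = None  # default cap is ceil(sqrt(n))
    degree_floor: int | None = None  # default floor is ceil(log2(n))

    def __post_init__(self) -> None:
        if self.sigma_rule not in ("median_distance", "mean_distance", "fixed"):
            raise ValueError(f"unknown sigma_rule {self.sigma_rule!r}")
        if self.sigma_rule == "fixed" and self.sigma <= 0:
            raise ValueError("sigma must be > 0")


@dataclass
class RescaledMatrix:
    """Patients x features matrix with every value min-max rescaled to [0,1].

    The observed per-feature (min, max) used for the transform are stored
    so the same rescaling can be replayed on new data.
    """

    patient_ids: list[str]
    feature_names: list[str]
    values: np.ndarray
    observed_min: np.ndarray = field(default_factory=lambda: np.empty(0))
    observed_max: np.ndarray = field(default_factory=lambda: np.empty(0))

    def distances(self) -> np.ndarray:
        """Dense Euclidean distance matrix over patients."""
        from scipy.spatial.distance import squareform, pdist

        if len(self.patient_ids) < 2:
            return np.zeros((len(self.patient_ids), len(self.patient_ids)))
        return squareform(pdist(self.values, metric="euclidean"))


def rescale_features(
    matrix: pd.DataFrame | RescaledMatrix, features: list[str] | None = None
) -> RescaledMatrix:
    """Min-max rescale each feature column to [0,1].

    Accepts a patients x features DataFrame indexed by patient id (e.g.
    from :meth:`CohortTable.marker_matrix`). Per feature, the observed min
    maps to 0 and the observed max to 1; constant features map to 0
    everywhere. Missing entries are rejected with an error naming the
    patient and feature.
    """
    if isinstance(matrix, RescaledMatrix):
        return matrix
    df = matrix[features] if features is not None else matrix
    if df.isna().any().any():
        feat = df.columns[df.isna().any()][0]
        patient = df.index[df[feat].isna()][0]
        raise CohortError(f"missing value for feature {feat!r} in patient {patient!r}")
    values = df.to_numpy(dtype=float)
    lo = values.min(axis=0)
    hi = values.max(axis=0)
    span = hi - lo
    with np.errstate(invalid="ignore", divide="ignore"):
        scaled = np.where(span > 0, (values - lo) / np.where(span > 0, span, 1.0), 0.0)
    return RescaledMatrix(
        patient_ids=[str(i) for i in df.index],
        feature_names=list(df.columns),
        values=scaled,
        observed_min=lo,
        observed_max=hi,
    )


def gaussian_similarity(d: float | np.ndarray, sigma: float) -> float | np.ndarray:
    """Gaussian-kernel similarity s = exp(-d^2 / (2 sigma^2)).

    Maps distance 0 to similarity 1 and decreases strictly with distance.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d = np.asarray(d, dtype=float)
    if (d < 0).any():
        raise ValueError("distances must be >= 0")
    out = np.exp(-(d**2) / (2.0 * sigma**2))
    return float(out) if out.ndim == 0 else out


def resolve_sigma(r: RescaledMatrix, params: SimilarityParams) -> float:
    """Bandwidth per the configured rule, on the rescaled distances."""
    if params.sigma_rule == "fixed":
        return params.sigma
    dist = r.distances()
    off_diag = dist[np.triu_indices_from(dist, k=1)]
    sigma = float(
        np.median(off_diag) if params.sigma_rule == "median_distance"
        else np.mean(off_diag)
    )
    if sigma <= 0:
        warnings.warn(
            "all patient vectors identical; falling back to sigma=1",
            stacklevel=2,
        )
        sigma = 1.0
    return sigma


def _neighbour_order(dist: np.ndarray, ids: list[str]) -> np.ndarray:
    """Row-wise neighbour ranking by (distance, patient id), self excluded.

    Returns an (n, n-1) index array: row i lists all other patients from
    nearest to farthest, distance ties broken by ascending patient id.
    """
    n = dist.shape[0]
    id_rank = np.argsort(np.argsort(ids, kind="stable"), kind="stable")
    order = np.empty((n, n - 1), dtype=int)
    for i in range(n):
        others = np.array([j for j in range(n) if j != i])
        key = sorted(others, key=lambda j: (dist[i, j], id_rank[j]))
        order[i] = key
    return order


def representativeness(r: RescaledMatrix) -> np.ndarray:
    """Reverse-nearest-neighbour vote counts, one per patient.

    The representativeness of patient v is the number of other patients
    whose single nearest neighbour (Euclidean, ties by ascending patient
    id) is v. Votes sum to the number of patients.
    """
    n = len(r.patient_ids)
    if n < 2:
        raise ValueError("need at least 2 patients")
    order = _neighbour_order(r.distances(), r.patient_ids)
    counts = np.zeros(n, dtype=int)
    for i in range(n):
        counts[order[i, 0]] += 1
    return counts


def lrnet_build(r: RescaledMatrix, params: SimilarityParams | None = None) -> nx.Graph:
    """Build the weighted patient similarity graph by the LRNet-style rule.

    Each vertex v links to its k(v) nearest neighbours, where
    ``k(v) = min(max(representativeness(v), floor), cap)``. The cap
    defaults to ceil(sqrt(n)), guarding against hubs; the floor defaults
    to ceil(log2(n)), the classic connectivity scale of nearest-neighbour
    graphs. Without the floor, the union of reverse-nearest-neighbour
    links is a forest of small stars, and modularity optimisation then
    fragments genuinely homogeneous patient groups into their connected
    components; the log-scale floor keeps each similarity neighbourhood
    connected while the representativeness term still widens hubs up to
    the cap. The edge set is the deduplicated union over both endpoints'
    neighbour lists; weights are Gaussian-kernel similarities. Vertices
    carry ``representativeness`` and ``k`` attributes; the graph carries
    the resolved ``sigma``.
    """
    params = params or SimilarityParams()
    n = len(r.patient_ids)
    if n < 2:
        raise ValueError("need at least 2 patients")
    dist = r.distances()
    if np.all(dist[np.triu_indices(n, k=1)] == 0):
        warnings.warn(
            "all patient vectors identical (complete tie); "
            "deterministic id-order tie-break applied",
            stacklevel=2,
        )
    sigma = resolve_sigma(r, params)
    order = _neighbour_order(dist, r.patient_ids)
    rep = np.zeros(n, dtype=int)
    for i in range(n):
        rep[order[i, 0]] += 1
    cap = params.degree_cap if params.degree_cap is not None else math.ceil(math.sqrt(n))
    floor = (
        params.degree_floor
        if params.degree_floor is not None
        else math.ceil(math.log2(n))
    )
    k = np.minimum(np.maximum(rep, max(floor, 1)), min(cap, n - 1))

    g = nx.Graph(sigma=sigma)
    for i, pid in enumerate(r.patient_ids):
        g.add_node(pid, representativeness=int(rep[i]), k=int(k[i]))
    for i in range(n):
        for j in order[i, : k[i]]:
            u, v = r.patient_ids[i], r.patient_ids[j]
            if not g.has_edge(u, v):
                g.add_edge(u, v, weight=gaussian_similarity(dist[i, j], sigma))
    return g


def write_graph(g: nx.Graph, graphml_path=None, edgelist_path=None) -> None:
    """Export the graph as GraphML and/or an edge-list TSV (source, target, weight)."""
    if graphml_path is not None:
        nx.write_graphml(g, graphml_path)
    if edgelist_path is not None:
        with open(edgelist_path, "w") as fh:
            fh.write("source\ttarget\tweight\n")
            for u, v, w in sorted(g.edges(data="weight")):
                fh.write(f"{u}\t{v}\t{w:.12g}\n")
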