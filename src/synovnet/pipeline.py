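"""End-to-end pipeline: simulate/read -> rescale -> network -> cluster ->
(optionally) select -> profile -> stats/ROC, with a reproducibility manifest.

Every artefact is a plain-text file (CSV/TSV/GraphML/JSON) under the output
directory; the manifest records the config snapshot, the master seed, the
package version and a SHA-256 checksum per artefact so that re-runs with an
identical config and seed can be verified bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from synovnet.cohort import CohortTable, read_cohort, write_cohort
from synovnet.community import (
    boundary_score,
    cluster_profile,
    cross_tabulate,
    louvain_partition,
    quality_report,
    select_network,
)
from synovnet.network import SimilarityParams, lrnet_build, rescale_features, write_graph
from synovnet.simulate import default_archetypes, default_generator_config, generate_cohort
from synovnet.stats import combined_roc, compare_groups, full_roc

log = logging.getLogger("synovnet")


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`.

    ``cohort_csv=None`` triggers the simulate stage (``simulate_mode``
    "calibrated" for the published-group generator, "archetype" for
    planted clusters). ``contrasts`` is a list of dicts with keys
    ``name``, ``positive`` and ``negative`` (lists of group labels);
    each contrast yields per-marker ROC reports and, when ``features``
    has two or more markers, a combined ridge-logistic model.
    """

    out_dir: str = "synovnet_out"
    seed: int = 0
    cohort_csv: str | None = None
    simulate_mode: str = "calibrated"
    features: list[str] = field(default_factory=list)
    contrasts: list[dict] = field(default_factory=list)
    sigma_rule: str = "median_distance"
    degree_cap: int | None = None
    resolution: float = 1.0
    restarts: int = 20
    select_sizes: tuple[int, int] | None = None
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        if "select_sizes" in raw and raw["select_sizes"] is not None:
            raw["select_sizes"] = tuple(raw["select_sizes"])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode("utf8")).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages and return the manifest (also written to disk).

    Stages: simulate (optional) -> rescale -> network -> cluster ->
    select (optional) -> profile/cross-tab/boundary -> stats/ROC per
    contrast. Any stage failure aborts with the stage name; artefacts
    written before the failure are preserved.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    from synovnet import __version__ as version

    manifest: dict = {
        "config": dataclasses.asdict(config),
        "config_hash": _config_hash(config),
        "version": version,
        "seed": config.seed,
        "stages": [],
        "artifacts": {},
    }
    stage = "simulate"
    try:
        # --- cohort -----------------------------------------------------
        if config.cohort_csv is None:
            log.info("stage=simulate mode=%s seed=%d", config.simulate_mode, config.seed)
            if config.simulate_mode == "archetype":
                rng = np.random.default_rng(config.seed)
                from synovnet.simulate import generate_archetype_cohort

                cohort = generate_archetype_cohort(default_archetypes(), rng)
            else:
                cohort = generate_cohort(default_generator_config(seed=config.seed))
            cohort_path = out / "cohort.csv"
            write_cohort(cohort, cohort_path)
            manifest["artifacts"]["cohort"] = str(cohort_path)
        else:
            stage = "read_cohort"
            cohort = read_cohort(config.cohort_csv)
        manifest["stages"].append(stage)

        features = config.features or cohort.marker_names
        params = SimilarityParams(
            sigma_rule=config.sigma_rule, degree_cap=config.degree_cap
        )

        # --- network -----------------------------------------------------
        stage = "network"
        log.info("stage=network features=%s", ",".join(features))
        rescaled = rescale_features(cohort.marker_matrix(features))
        graph = lrnet_build(rescaled, params)
        write_graph(graph, out / "network.graphml", out / "network_edges.tsv")
        manifest["artifacts"]["graphml"] = str(out / "network.graphml")
        manifest["artifacts"]["edgelist"] = str(out / "network_edges.tsv")
        manifest["stages"].append(stage)

        # --- cluster -----------------------------------------------------
        stage = "cluster"
        partition = louvain_partition(
            graph, resolution=config.resolution, seed=config.seed,
            restarts=config.restarts,
        )
        part_path = out / "partition.csv"
        with open(part_path, "w") as fh:
            fh.write("patient_id,cluster\n")
            for pid in cohort.patient_ids:
                fh.write(f"{pid},{partition[pid]}\n")
        quality = quality_report(graph, rescaled, partition)
        (out / "quality.json").write_text(
            json.dumps(quality.as_dict(), indent=1, sort_keys=True) + "\n"
        )
        manifest["artifacts"]["partition"] = str(part_path)
        manifest["artifacts"]["quality"] = str(out / "quality.json")
        manifest["stages"].append(stage)
        log.info("stage=cluster n_clusters=%d Q=%.4f", quality.n_clusters,
                 quality.modularity)

        # --- selection sweep (optional) ----------------------------------
        if config.select_sizes is not None:
            stage = "select"
            lo, hi = config.select_sizes
            ranked = select_network(
                cohort, features, range(lo, hi + 1), params,
                resolution=config.resolution, seed=config.seed,
                restarts=config.restarts,
            )
            log.info("stage=select candidates=%d", len(ranked))
            rows = ["rank,features,balance_score,modularity,silhouette_mean,"
                    "centroid_reliability,mean_within_cluster_sd,n_clusters"]
            for i, cand in enumerate(ranked):
                q = cand.quality
                rows.append(
                    f"{i + 1},{'|'.join(cand.feature_subset)},"
                    f"{cand.balance_score:.6f},{q.modularity:.6f},"
                    f"{q.silhouette_mean:.6f},{q.centroid_reliability:.6f},"
                    f"{q.mean_within_cluster_sd:.6f},{q.n_clusters}"
                )
            (out / "candidates.csv").write_text("\n".join(rows) + "\n")
            manifest["artifacts"]["candidates"] = str(out / "candidates.csv")
            manifest["stages"].append(stage)

        # --- profiling ---------------------------------------------------
        stage = "profile"
        profile = cluster_profile(cohort, partition)
        profile.to_csv(out / "centroid_profile.csv")
        crosstab = cross_tabulate(cohort, partition)
        crosstab.to_csv(out / "cluster_by_group.csv")
        bscore = boundary_score(graph, partition)
        with open(out / "boundary_scores.csv", "w") as fh:
            fh.write("patient_id,boundary_score\n")
            for pid in cohort.patient_ids:
                fh.write(f"{pid},{bscore[pid]:.6f}\n")
        for key, name in (
            ("profile", "centroid_profile.csv"),
            ("crosstab", "cluster_by_group.csv"),
            ("boundary", "boundary_scores.csv"),
        ):
            manifest["artifacts"][key] = str(out / name)
        manifest["stages"].append(stage)

        # --- statistics / ROC --------------------------------------------
        for contrast in config.contrasts:
            stage = f"stats:{contrast['name']}"
            pos, neg = set(contrast["positive"]), set(contrast["negative"])
            mask = cohort.df["group"].isin(pos | neg)
            sub = cohort.df[mask]
            labels = sub["group"].isin(pos).to_numpy(dtype=int)
            stat_rows = []
            roc_rows = []
            for marker in features:
                for res in compare_groups(
                    CohortTable(sub.copy(), units=cohort.units), marker
                ):
                    stat_rows.append(
                        f"{marker},{'|'.join(res.groups)},{res.test},"
                        f"{res.statistic:.6g},{res.p_raw:.6g},"
                        f"{res.p_adjusted:.6g},{res.tier}"
                    )
                roc = full_roc(sub[marker].to_numpy(dtype=float), labels, marker=marker)
                roc_rows.append(
                    f"{marker},{roc.auc:.6f},{roc.ci_low:.6f},{roc.ci_high:.6f},"
                    f"{roc.youden_j:.6f},{roc.cutoff:.6g}"
                )
            name = contrast["name"].replace("/", "_").replace(":", "_")
            (out / f"stats_{name}.csv").write_text(
                "marker,groups,test,statistic,p_raw,p_adjusted,tier\n"
                + "\n".join(stat_rows) + "\n"
            )
            (out / f"roc_{name}.csv").write_text(
                "marker,auc,ci_low,ci_high,youden_j,cutoff\n"
                + "\n".join(roc_rows) + "\n"
            )
            manifest["artifacts"][f"stats_{name}"] = str(out / f"stats_{name}.csv")
            manifest["artifacts"][f"roc_{name}"] = str(out / f"roc_{name}.csv")
            if len(features) >= 2:
                model = combined_roc(
                    CohortTable(sub.copy(), units=cohort.units),
                    features, labels, seed=config.seed,
                )
                payload = {
                    "markers": list(model.markers),
                    "lambda": model.lam,
                    "coefficients": model.coefficients.tolist(),
                    "intercept": model.intercept,
                    "auc": model.roc.auc,
                    "auc_ci": [model.roc.ci_low, model.roc.ci_high],
                    "cv_auc": model.cv_auc,
                    "youden_j": model.roc.youden_j,
                    "cutoff": model.roc.cutoff,
                    "note": "auc is in-sample; cv_auc is out-of-fold at the chosen penalty",
                }
                (out / f"combined_{name}.json").write_text(
                    json.dumps(payload, indent=1, sort_keys=True) + "\n"
                )
                manifest["artifacts"][f"combined_{name}"] = str(
                    out / f"combined_{name}.json"
                )
            manifest["stages"].append(stage)
    except Exception as exc:  # annotate failures with the stage name
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest["checksums"] = {
        key: _sha256(Path(p)) for key, p in sorted(manifest["artifacts"].items())
    }
    manifest["timestamp"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n"
    )
    return manifest
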