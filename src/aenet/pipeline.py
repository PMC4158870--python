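"""End-to-end pipeline: stratification, cluster characterization, and both
co-occurrence networks, with every artifact written to an output directory.

The pipeline chains the library stages in the order a full analysis runs:

1. patient tf-idf profiles over AEs and the cosine dissimilarity matrix;
2. average-linkage clustering at the cutoff, size filtering, and the
   patient similarity network;
3. cluster-level tf-idf vectors (AEs, drugs, diagnoses), characteristic
   fractions, heat-map tables, and the cluster-of-clusters orderings;
4. co-occurrence method 1 (pseudocount score + Fisher/BH network) and
   method 2 (weighted edges + multiscale backbone) — computed over *all*
   AE-bearing patients, not only those in retained clusters;
5. the overlap comparison between the two networks.

A JSON manifest records the configuration, library versions, stage counts
and every artifact path, so a run can be audited and reproduced.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, asdict
from pathlib import Path

import networkx
import numpy
import pandas
import scipy

from . import __version__
from .cooccurrence import compare_networks, extract_backbone, score_network, weighted_edges
from .events import subset_by_type, term_prevalence
from .io import (
    read_annotations,
    read_event_table,
    write_heatmap_table,
    write_network,
    write_pair_stats,
    write_profile_matrix,
)
from .profiles import characteristic_profiles, compute_tfidf
from .stratification import (
    build_patient_network,
    cluster_clusters,
    cosine_dissimilarity_matrix,
    filter_clusters,
    hierarchical_cluster,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Thresholds and mode switches for a full pipeline run."""

    cutoff: float = 0.6
    min_cluster_size: int = 10
    alpha: float = 0.01
    drop_top_prevalent: int = 10
    fisher_sided: str = "greater"
    bh_monotone: bool = True
    m_mode: str = "all_pairs"
    backbone_rule: str = "either"
    idf_corpus: str = "patients"
    heatmap_top_k: int = 2
    seed: int = 0

    def validate(self) -> None:
        if not 0 < self.cutoff <= 1:
            raise ValueError("cutoff must lie in (0, 1]")
        if not 0 < self.alpha <= 1:
            raise ValueError("alpha must lie in (0, 1]")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")
        if self.drop_top_prevalent < 0:
            raise ValueError("drop_top_prevalent must be >= 0")


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def run_pipeline(
    config: PipelineConfig,
    events_path: str | Path,
    out_dir: str | Path,
    annotations_path: str | Path | None = None,
) -> dict:
    """Run the full analysis and return the manifest (also written as JSON)."""
    config.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, str] = {}

    def save(key: str, filename: str) -> Path:
        path = out_dir / filename
        artifacts[key] = filename
        return path

    events = read_event_table(events_path)
    annotations = read_annotations(annotations_path) if annotations_path else None

    # 1-2. stratification
    profiles = _stage("profiles")(compute_tfidf)(events, term_type="AE")
    dist = _stage("dissimilarity")(cosine_dissimilarity_matrix)(profiles)
    assignment = _stage("clustering")(hierarchical_cluster)(dist, config.cutoff)
    retained = filter_clusters(assignment, config.min_cluster_size)
    network = _stage("patient_network")(build_patient_network)(
        dist, retained, threshold=config.cutoff
    )
    write_profile_matrix(
        profiles, save("patient_profiles_wide", "patient_profiles.csv"),
        save("patient_profiles_long", "patient_profiles.tsv"),
    )
    pandas.DataFrame(
        sorted(assignment.labels.items()), columns=["patient_id", "cluster"]
    ).to_csv(save("clusters", "clusters.tsv"), sep="\t", index=False)
    write_network(
        network, save("patient_network_graphml", "patient_network.graphml"),
        save("patient_network_edges", "patient_network_edges.tsv"),
    )

    # 3. cluster characterization in AE / drug / diagnosis space
    grouping = {d: f"C{c:03d}" for d, c in retained.labels.items()}
    heatmaps = {}
    if len(set(grouping.values())) >= 1:
        for term_type in ("AE", "drug", "diagnosis"):
            if len(subset_by_type(events, term_type)) == 0:
                continue
            try:
                cluster_prof = compute_tfidf(
                    events, term_type=term_type,
                    document_grouping=grouping, idf_corpus=config.idf_corpus,
                )
            except ValueError:
                continue
            fractions = characteristic_profiles(cluster_prof)
            order = None
            if len(fractions.document_ids) >= 2:
                order = cluster_clusters(fractions).leaf_order
            prev = term_prevalence(events, term_type).to_dict()
            table = write_heatmap_table(
                fractions, prev,
                save(f"heatmap_{term_type}", f"heatmap_{term_type}.tsv"),
                top_k=config.heatmap_top_k, column_order=order,
            )
            heatmaps[term_type] = table.shape

    # 4. co-occurrence, both methods, over all AE-bearing patients
    g_score = _stage("score_network")(score_network)(
        events, alpha=config.alpha, m_mode=config.m_mode,
        alternative=config.fisher_sided, annotations=annotations,
    )
    write_pair_stats(
        g_score.graph["pair_stats"], save("pair_stats", "pair_stats.tsv")
    )
    write_network(
        g_score, save("score_network_graphml", "score_network.graphml"),
        save("score_network_edges", "score_network_edges.tsv"),
    )

    weights = _stage("weighted_edges")(weighted_edges)(events)
    aes = subset_by_type(events, "AE")
    prevalence = aes.groupby("term")["patient_id"].nunique().to_dict()
    g_backbone = _stage("backbone")(extract_backbone)(
        weights, alpha=config.alpha,
        drop_top_prevalent=min(config.drop_top_prevalent, len(weights.terms)),
        prevalence=prevalence, n_patients=aes["patient_id"].nunique(),
        rule=config.backbone_rule, annotations=annotations,
    )
    write_network(
        g_backbone, save("backbone_network_graphml", "backbone_network.graphml"),
        save("backbone_network_edges", "backbone_network_edges.tsv"),
    )

    # 5. cross-method comparison
    overlap = compare_networks(g_score, g_backbone)

    manifest = {
        "config": asdict(config),
        "versions": {
            "aenet": __version__,
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pandas.__version__,
            "networkx": networkx.__version__,
        },
        "counts": {
            "patients_with_ae": int(aes["patient_id"].nunique()),
            "unique_aes": int(aes["term"].nunique()),
            "clusters_total": assignment.n_clusters,
            "clusters_retained": retained.n_clusters,
            "patients_retained": len(retained.labels),
            "patient_network_edges": network.number_of_edges(),
            "score_network_nodes": g_score.number_of_nodes(),
            "score_network_edges": g_score.number_of_edges(),
            "backbone_network_nodes": g_backbone.number_of_nodes(),
            "backbone_network_edges": g_backbone.number_of_edges(),
        },
        "network_overlap": overlap.summary(),
        "heatmap_shapes": {k: list(v) for k, v in heatmaps.items()},
        "artifacts": artifacts,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
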