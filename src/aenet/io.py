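"""Readers and writers for the pipeline's tabular and network artifacts.

Tabular formats are tab-separated UTF-8 with a header row; networks are
written both as GraphML (attributes preserved) and as a plain edge-list TSV
for grep-ability. Terms are opaque case-sensitive strings throughout.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import networkx as nx
import pandas as pd

from .events import COLUMNS, TERM_TYPES, validate_events
from .profiles import ProfileMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "read_event_table",
    "write_event_table",
    "read_annotations",
    "write_pair_stats",
    "read_pair_stats",
    "write_network",
    "read_network",
    "write_profile_matrix",
    "write_heatmap_table",
]


def read_event_table(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format event table.

    Duplicate (patient_id, term, term_type) rows are summed with a logged
    warning; malformed counts and unknown term types are reported with
    their 1-based line number (header is line 1).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: header is missing columns {missing}")
    if df[list(COLUMNS[:3])].isna().any(axis=None):
        line = int(df[df[list(COLUMNS[:3])].isna().any(axis=1)].index[0]) + 2
        raise ValueError(f"{path}:{line}: incomplete row")

    counts = pd.to_numeric(df["count"], errors="coerce")
    bad = counts.isna() | (counts < 1) | (counts != counts.round())
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise ValueError(
            f"{path}:{line}: count must be a positive integer, got {df['count'][bad].iloc[0]!r}"
        )
    df["count"] = counts.astype("int64")

    bad_type = ~df["term_type"].isin(TERM_TYPES)
    if bad_type.any():
        line = int(df.index[bad_type][0]) + 2
        raise ValueError(
            f"{path}:{line}: unknown term_type {df['term_type'][bad_type].iloc[0]!r}; "
            f"expected one of {TERM_TYPES}"
        )

    dup = df.duplicated(subset=["patient_id", "term", "term_type"])
    if dup.any():
        logger.warning("%s: %d duplicate records summed", path, int(dup.sum()))
        df = (
            df.groupby(["patient_id", "term", "term_type"], as_index=False, sort=True)
            ["count"].sum()
        )
    return validate_events(df)


def write_event_table(events: pd.DataFrame, path: str | Path) -> None:
    validate_events(events).to_csv(path, sep="\t", index=False)


def read_annotations(path: str | Path) -> dict[str, str]:
    """Read a term -> anatomical class map (TSV: term, anatomical_class)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("term", "anatomical_class"):
        if col not in df.columns:
            raise ValueError(f"{path}: annotation file is missing column {col!r}")
    return dict(zip(df["term"], df["anatomical_class"]))


def write_pair_stats(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_pair_stats(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "significant" in df.columns:
        df["significant"] = df["significant"].astype(bool)
    return df


def write_network(
    g: nx.Graph, graphml_path: str | Path, edgelist_path: str | Path | None = None
) -> None:
    """Write a network as GraphML plus an optional edge-list TSV.

    The edge list carries source, target and every edge attribute; non-
    scalar graph attributes (attached tables) are left out of the GraphML.
    """
    slim = g.copy()
    slim.graph = {
        k: v for k, v in g.graph.items() if isinstance(v, (str, int, float, bool))
    }
    nx.write_graphml(slim, graphml_path)
    if edgelist_path is not None:
        attr_names = sorted({k for *_, d in g.edges(data=True) for k in d})
        rows = [
            {"source": u, "target": v, **{k: d.get(k) for k in attr_names}}
            for u, v, d in g.edges(data=True)
        ]
        pd.DataFrame(rows, columns=["source", "target", *attr_names]).to_csv(
            edgelist_path, sep="\t", index=False
        )


def read_network(graphml_path: str | Path) -> nx.Graph:
    return nx.read_graphml(graphml_path)


def write_profile_matrix(
    profiles: ProfileMatrix, wide_path: str | Path, long_path: str | Path | None = None
) -> None:
    """Write a ProfileMatrix as wide CSV and optionally long TSV."""
    frame = profiles.to_frame()
    frame.rename_axis("document").to_csv(wide_path)
    if long_path is not None:
        long = (
            frame.rename_axis("document")
            .reset_index()
            .melt(id_vars="document", var_name="term", value_name="value")
        )
        long = long.loc[long["value"] > 0].sort_values(["document", "term"])
        long.to_csv(long_path, sep="\t", index=False)


def write_heatmap_table(
    fractions: ProfileMatrix,
    prevalence: Mapping[str, int],
    path: str | Path,
    top_k: int = 1,
    column_order: list[str] | None = None,
) -> pd.DataFrame:
    """Heat-map-ready table of characteristic fractions.

    Keeps the union of each document's ``top_k`` most distinguishing terms,
    orders rows (terms) by corpus prevalence with the most prevalent first,
    and orders columns (documents) by ``column_order`` when given (the
    dendrogram leaf order of a cluster-of-clusters run).
    """
    frame = fractions.to_frame()
    keep: set[str] = set()
    for _, row in frame.iterrows():
        nz = row[row > 0]
        keep.update(nz.sort_values(ascending=False, kind="stable").head(top_k).index)
    terms = sorted(keep, key=lambda t: (-prevalence.get(t, 0), t))
    table = frame.loc[:, terms].T
    if column_order is not None:
        table = table.loc[:, column_order]
    table.rename_axis("term").to_csv(path, sep="\t")
    return table
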