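"""Readers and writers for the pipeline's plain-text interchange formats.

Expression matrices are tab-separated with genes in rows and a header row
of sample identifiers; interactomes are three-column edge lists
(protein_a, protein_b, confidence); flow events are one CSV per patient
with one column per marker; gene sets use GMT (see :mod:`.enrichment`).
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import pandas as pd

__all__ = [
    "read_expression",
    "write_expression",
    "read_labels",
    "write_labels",
    "read_edge_list",
    "write_edge_list",
    "read_reference_intervals",
    "write_reference_intervals",
    "write_network_scores",
]


def read_expression(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_expression(matrix: pd.DataFrame, path) -> None:
    matrix.to_csv(path, sep="\t")


def read_labels(path) -> pd.Series:
    table = pd.read_csv(path, sep="\t", index_col=0)
    return table.iloc[:, 0]


def write_labels(labels: pd.Series, path) -> None:
    labels.rename("group").to_csv(path, sep="\t")


def read_edge_list(path) -> nx.Graph:
    table = pd.read_csv(path, sep="\t")
    graph = nx.Graph()
    for row in table.itertuples(index=False):
        graph.add_edge(row.protein_a, row.protein_b, confidence=float(row.confidence))
    return graph


def write_edge_list(graph: nx.Graph, path) -> None:
    rows = [
        {"protein_a": u, "protein_b": v, "confidence": d.get("confidence", 1.0)}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["protein_a", "protein_b", "confidence"]).to_csv(
        path, sep="\t", index=False
    )


def read_reference_intervals(path):
    from .flow import ReferenceInterval

    table = pd.read_csv(path, sep="\t")
    return {
        row.marker: ReferenceInterval(
            marker=row.marker,
            marker_class=row.marker_class,
            boundaries=(row.b_neg_dim, row.b_dim_normal, row.b_normal_bright),
        )
        for row in table.itertuples(index=False)
    }


def write_reference_intervals(intervals, path) -> None:
    rows = [
        {
            "marker": ref.marker,
            "marker_class": ref.marker_class,
            "b_neg_dim": ref.boundaries[0],
            "b_dim_normal": ref.boundaries[1],
            "b_normal_bright": ref.boundaries[2],
        }
        for ref in intervals.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_network_scores(scores, out_dir) -> None:
    """Network results TSV plus a per-network member-list JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = [
        {
            "seed": sc.network.seed,
            "n": sc.n_mapped,
            "n_excluded": sc.n_excluded,
            "S": sc.S,
            "p_int": sc.p_int,
            "perm_count": sc.perm_count,
            "p_emp": sc.p_emp,
            "selected": sc.selected,
        }
        for sc in scores
    ]
    pd.DataFrame(rows).to_csv(out_dir / "network_scores.tsv", sep="\t", index=False)
    members = {sc.network.seed: sorted(sc.network.members) for sc in scores}
    (out_dir / "network_members.json").write_text(json.dumps(members, indent=1))
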