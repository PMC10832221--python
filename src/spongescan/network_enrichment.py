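"""Sponge subnetwork construction/export and local gene-set enrichment.

A subnetwork is a star graph around a (miRNA, circRNA) interaction: the
circRNA-miRNA edge weighted by SS plus the miRNA's co-directional mRNA
targets ranked by SG, truncated to the top fraction (default 10%, ceiling,
minimum 1), weighted by SG. Gene-set enrichment is a local one-sided
hypergeometric over-representation test against user-supplied GMT files.
"""

from __future__ import annotations

import json
import logging
import math
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._stats import bh_adjust
from .data_io import GeneSetCollection
from .errors import EmptyQueryError, FormatError, NotFoundError

logger = logging.getLogger(__name__)

EXPORT_FORMATS = ("graphml", "json")

EDGE_MIRNA_CIRC = "miRNA-circRNA"
EDGE_MIRNA_MRNA = "miRNA-mRNA"

FOCUS_NODE_SIZE = 2.0
DEFAULT_NODE_SIZE = 1.0


def _truncate_targets(n_targets: int, fraction: float) -> int:
    return max(1, math.ceil(fraction * n_targets))


def build_subnetwork(
    matrix: pd.DataFrame,
    sg: pd.DataFrame,
    selection: tuple[str, str] | str,
    target_fraction: float = 0.10,
    known_pairs: set[tuple[str, str]] | None = None,
) -> nx.Graph:
    """Star subnetwork(s) for a (miRNA, circRNA) pair or a single RNA id.

    A single-id selection matching several score-matrix rows yields the union
    of the corresponding stars. Focus nodes (those named by the selection)
    get a larger display size.
    """
    if isinstance(selection, tuple):
        rows = matrix[
            (matrix["mirna_id"] == selection[0]) & (matrix["circ_id"] == selection[1])
        ]
        focus_ids = set(selection)
    else:
        rows = matrix[
            (matrix["mirna_id"] == selection) | (matrix["circ_id"] == selection)
        ]
        focus_ids = {selection}
    if rows.empty:
        raise NotFoundError(f"selection {selection!r} matches no score-matrix row")

    known = known_pairs or set()
    sg_by_pair = sg.set_index(["mirna_id", "mrna_id"])["sg"]
    net = nx.Graph()

    def add_node(node_id: str, rna_type: str) -> None:
        is_focus = node_id in focus_ids
        if node_id not in net:
            net.add_node(
                node_id,
                rna_type=rna_type,
                is_focus=is_focus,
                display_size=FOCUS_NODE_SIZE if is_focus else DEFAULT_NODE_SIZE,
            )

    for _, row in rows.iterrows():
        mirna, circ = row["mirna_id"], row["circ_id"]
        add_node(mirna, "miRNA")
        add_node(circ, "circRNA")
        net.add_edge(
            mirna,
            circ,
            kind=EDGE_MIRNA_CIRC,
            weight=float(row["ss"]),
            in_literature=(mirna, circ) in known,
        )
        targets = str(row["mrna_target_list"]).split(";")
        ranked = sorted(
            targets, key=lambda m: (-sg_by_pair.loc[(mirna, m)], m)
        )
        for mrna in ranked[: _truncate_targets(len(ranked), target_fraction)]:
            add_node(mrna, "mRNA")
            net.add_edge(
                mirna,
                mrna,
                kind=EDGE_MIRNA_MRNA,
                weight=float(sg_by_pair.loc[(mirna, mrna)]),
                in_literature=False,
            )
    return net


def export_network(net: nx.Graph, path: str | Path, format: str = "graphml") -> None:
    """Write a network as GraphML or documented JSON; both re-import losslessly."""
    if format not in EXPORT_FORMATS:
        raise FormatError(
            f"unsupported network format {format!r}; supported: {EXPORT_FORMATS}"
        )
    if format == "graphml":
        nx.write_graphml(net, path)
        return
    payload = {
        "nodes": [{"id": n, **attrs} for n, attrs in sorted(net.nodes(data=True))],
        "edges": [
            {"source": u, "target": v, **attrs}
            for u, v, attrs in sorted(net.edges(data=True))
        ],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def import_network(path: str | Path, format: str = "graphml") -> nx.Graph:
    if format not in EXPORT_FORMATS:
        raise FormatError(
            f"unsupported network format {format!r}; supported: {EXPORT_FORMATS}"
        )
    if format == "graphml":
        return nx.read_graphml(path)
    payload = json.loads(Path(path).read_text())
    net = nx.Graph()
    for node in payload["nodes"]:
        attrs = dict(node)
        net.add_node(attrs.pop("id"), **attrs)
    for edge in payload["edges"]:
        attrs = dict(edge)
        net.add_edge(attrs.pop("source"), attrs.pop("target"), **attrs)
    return net


def ora_enrichment(
    query_genes: set[str],
    collection: GeneSetCollection,
    background: set[str],
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of the query in each set.

    Gene sets are intersected with the background before testing; the query
    must be a subset of the background. Rows are sorted by p-value ascending.
    """
    query = {g.upper() for g in query_genes}
    background = {g.upper() for g in background}
    if not query:
        raise EmptyQueryError("empty query gene set")
    stray = query - background
    if stray:
        raise EmptyQueryError(
            f"query genes outside the background: {sorted(stray)[:5]}"
        )
    m_bg = len(background)
    rows = []
    for name, (_, genes) in collection.sets.items():
        members = set(genes) & background
        if not members:
            continue
        overlap = len(query & members)
        # P(X >= overlap), X ~ Hypergeom(M=m_bg, n=len(members), N=len(query))
        p = float(stats.hypergeom.sf(overlap - 1, m_bg, len(members), len(query)))
        rows.append(
            {
                "set_name": name,
                "overlap_count": overlap,
                "set_size": len(members),
                "query_size": len(query),
                "background_size": m_bg,
                "pvalue": min(p, 1.0),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "set_name", "overlap_count", "set_size", "query_size",
            "background_size", "pvalue",
        ],
    )
    if out.empty:
        return out.assign(adjusted_pvalue=pd.Series(dtype=float))
    out["adjusted_pvalue"] = bh_adjust(out["pvalue"].to_numpy())
    return out.sort_values(["pvalue", "set_name"], kind="stable").reset_index(drop=True)


def top_enriched(table: pd.DataFrame, n: int = 10) -> pd.DataFrame:
    """Convenience top-n view of an enrichment table."""
    return table.head(n).reset_index(drop=True)
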