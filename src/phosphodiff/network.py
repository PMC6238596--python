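"""Kinase-substrate network construction and Cytoscape-compatible export.

Nodes are kinases and substrate phosphosites (site nodes labeled
``GENE_S123``); a directed edge kinase -> site carries the site's log2
fold-change contrasts so the visualization can color edges by either
the acute-vs-control response or the chronic-vs-acute differential.
Exports: SIF with relation "phosphorylates", GraphML with typed
attribute keys, and plain node/edge attribute TSVs.  All exports are
canonically ordered so identical networks serialize byte-identically.
"""

from __future__ import annotations

import logging
import os
from typing import Mapping

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

RELATION = "phosphorylates"


def _site_label(ms_key: str, genes: Mapping[str, str] | None) -> str:
    acc, respos = ms_key.split("|", 1)
    gene = (genes or {}).get(acc, acc)
    return f"{gene}_{respos}"


def build_network(
    annotated: pd.DataFrame,
    differentials: pd.DataFrame,
    groups: pd.Series | None = None,
    group_colors: Mapping[str, str] | None = None,
    genes: Mapping[str, str] | None = None,
    collapse_to_proteins: bool = False,
) -> nx.DiGraph:
    """Build the kinase -> substrate-site graph.

    ``annotated`` is the kinase-annotated match table (``ms_key``,
    semicolon-joined ``kinases``); ``differentials`` a site-keyed frame
    with ``log2fc_acute`` and ``differential`` columns.  One node per
    distinct kinase and per annotated site (or per protein when
    ``collapse_to_proteins``); one deduplicated edge per (kinase, site)
    pair.  Sites lacking a differential keep their edge with
    missing-value attributes (logged).
    """
    g = nx.DiGraph()
    groups = groups if groups is not None else pd.Series(dtype=object)
    n_missing = 0
    for rec in annotated.to_dict("records") if len(annotated) else []:
        kinases = [k for k in str(rec.get("kinases", "")).split(";") if k]
        if not kinases:
            continue
        ms_key = rec["ms_key"]
        if collapse_to_proteins:
            acc = ms_key.split("|", 1)[0]
            site_id = (genes or {}).get(acc, acc)
        else:
            site_id = _site_label(ms_key, genes)
        grp = groups.get(ms_key, "unclassified")
        color = (group_colors or {}).get(grp, "")
        if site_id not in g:
            g.add_node(site_id, kind="site", label=site_id, group=grp, color=color)
        if ms_key in differentials.index:
            row = differentials.loc[ms_key]
            fc_a = float(row["log2fc_acute"])
            diff = float(row["differential"])
        else:
            fc_a = diff = float("nan")
            n_missing += 1
        for kin in kinases:
            kin_id = f"kinase:{kin}"
            if kin_id not in g:
                g.add_node(kin_id, kind="kinase", label=kin, group="kinase", color="")
            if not g.has_edge(kin_id, site_id):
                g.add_edge(kin_id, site_id, log2fc_acute=fc_a, differential=diff)
    if n_missing:
        logger.info("build_network: %d sites without differentials (missing-coded edges)", n_missing)
    logger.info("build_network: %d nodes, %d edges", g.number_of_nodes(), g.number_of_edges())
    return g


def _sorted_copy(g: nx.DiGraph) -> nx.DiGraph:
    out = nx.DiGraph()
    for n in sorted(g.nodes):
        out.add_node(n, **g.nodes[n])
    for u, v in sorted(g.edges):
        out.add_edge(u, v, **g.edges[u, v])
    return out


def export_sif(g: nx.DiGraph, path) -> None:
    """Write edges as SIF lines ``KINASE<TAB>phosphorylates<TAB>SITE``."""
    with open(path, "wt", encoding="utf-8") as fh:
        for u, v in sorted(g.edges):
            fh.write(f"{g.nodes[u].get('label', u)}\t{RELATION}\t{g.nodes[v].get('label', v)}\n")


def export_graphml(g: nx.DiGraph, path) -> None:
    """Write GraphML with node/edge attributes as typed keys.

    NaN fold-change attributes are omitted on the edge (missing-coded),
    matching the TSV convention of an empty field.
    """
    out = _sorted_copy(g)
    for _u, _v, data in out.edges(data=True):
        for key in ("log2fc_acute", "differential"):
            if key in data and pd.isna(data[key]):
                del data[key]
    nx.write_graphml(out, path, named_key_ids=True, edge_id_from_attribute=None)


def export_attribute_tables(g: nx.DiGraph, directory) -> tuple[str, str]:
    """Write node and edge attribute TSVs; returns their paths."""
    os.makedirs(directory, exist_ok=True)
    node_path = os.path.join(directory, "node_attributes.tsv")
    edge_path = os.path.join(directory, "edge_attributes.tsv")
    nodes = pd.DataFrame(
        [
            {"id": n, "kind": d.get("kind", ""), "label": d.get("label", n),
             "group": d.get("group", ""), "color": d.get("color", "")}
            for n, d in sorted(g.nodes(data=True))
        ],
        columns=["id", "kind", "label", "group", "color"],
    )
    edges = pd.DataFrame(
        [
            {"kinase": g.nodes[u].get("label", u), "site": g.nodes[v].get("label", v),
             "log2fc_acute": d.get("log2fc_acute", float("nan")),
             "differential": d.get("differential", float("nan"))}
            for (u, v), d in ((e, g.edges[e]) for e in sorted(g.edges))
        ],
        columns=["kinase", "site", "log2fc_acute", "differential"],
    )
    nodes.to_csv(node_path, sep="\t", index=False)
    edges.to_csv(edge_path, sep="\t", index=False, na_rep="")
    return node_path, edge_path
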