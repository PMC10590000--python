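"""Trajectory-graph assembly, transitive pruning, layering and export.

Confirmed pairs become directed edges annotated with OR and pair count;
nodes carry the PheWAS hazard ratio and case count. Pruning removes
shortcut edges a->c whenever a longer path a->..->c exists, preserving
reachability exactly (on DAGs this is the transitive reduction). Edges on
directed cycles are exempt from pruning and reported instead of silently
deleted.
"""
from __future__ import annotations

import json
import pathlib

import networkx as nx
import numpy as np
import pandas as pd

SUPPORTED_FORMATS = ("graphml", "json", "tsv")

_NODE_ATTRS = ("hr", "n_cases")
_EDGE_ATTRS = ("or_", "n_both", "binom_p", "logit_p")


def assemble_graph(phewas_results: pd.DataFrame, confirmed_pairs: pd.DataFrame
                   ) -> nx.DiGraph:
    """Build the annotated directed graph from confirmed pairs.

    Every pair endpoint must have a PheWAS result row; cycles are permitted
    here and surfaced via ``graph.graph["cycles"]``.
    """
    g = nx.DiGraph()
    annot = phewas_results.set_index("outcome")
    nodes = sorted(
        set(confirmed_pairs["d1"]).union(confirmed_pairs["d2"])
        if len(confirmed_pairs) else set()
    )
    for node in nodes:
        if node not in annot.index:
            raise KeyError(f"pair endpoint {node!r} has no PheWAS annotation")
        row = annot.loc[node]
        g.add_node(node, hr=float(row["hr"]), n_cases=int(row["n_cases"]))
    for row in confirmed_pairs.sort_values(["d1", "d2"]).itertuples(index=False):
        if row.d1 == row.d2:
            continue
        g.add_edge(
            row.d1, row.d2,
            or_=float(row[confirmed_pairs.columns.get_loc("or")]),
            n_both=int(row.n_both),
            binom_p=float(row.binom_p),
            logit_p=float(row.logit_p),
        )
    cycles = [sorted(c) for c in nx.strongly_connected_components(g) if len(c) > 1]
    g.graph["cycles"] = sorted(map(tuple, cycles))
    return g


def transitive_prune(g: nx.DiGraph) -> nx.DiGraph:
    """Remove transitive shortcut edges; reachability is preserved.

    Works on the condensation (the DAG of strongly connected components):
    a cross-component edge is redundant when a longer component-level path
    exists, and every original edge mapping to a redundant condensation edge
    is removed. Edges inside components (cycles) are kept untouched, so on a
    DAG this is exactly the transitive reduction. Pruned edges (with their
    attributes) are recorded in ``graph.graph["pruned_edges"]``.
    """
    cond = nx.condensation(g)
    comp = cond.graph["mapping"]
    desc = {c: nx.descendants(cond, c) for c in cond.nodes}
    redundant_cond = set()
    for cu, cv in cond.edges:
        for cw in cond.successors(cu):
            if cw != cv and cv in desc[cw]:
                redundant_cond.add((cu, cv))
                break
    redundant = [
        (u, v) for u, v in g.edges
        if comp[u] != comp[v] and (comp[u], comp[v]) in redundant_cond
    ]
    pruned = g.copy()
    removed = []
    for u, v in sorted(redundant):
        removed.append((u, v, dict(g.edges[u, v])))
    pruned.remove_edges_from(redundant)
    prior = list(g.graph.get("pruned_edges", []))
    pruned.graph["pruned_edges"] = prior + removed
    return pruned


def layer_nodes(g: nx.DiGraph) -> pd.DataFrame:
    """Label nodes original / intermediary / terminal on the pruned graph.

    Sources (in-degree 0) are original, sinks (out-degree 0) terminal,
    isolates original-terminal, members of directed cycles cyclic. Both the
    direct-successor count and the distinct-descendant count are emitted
    (the downstream-tally definition is ambiguous; take your pick).
    """
    cyclic = set()
    for scc in nx.strongly_connected_components(g):
        if len(scc) > 1:
            cyclic.update(scc)
    rows = []
    for node in sorted(g.nodes):
        indeg, outdeg = g.in_degree(node), g.out_degree(node)
        if node in cyclic:
            layer = "cyclic"
        elif indeg == 0 and outdeg == 0:
            layer = "original-terminal"
        elif indeg == 0:
            layer = "original"
        elif outdeg == 0:
            layer = "terminal"
        else:
            layer = "intermediary"
        rows.append({
            "node": node,
            "layer": layer,
            "n_successors": outdeg,
            "n_descendants": len(nx.descendants(g, node)),
        })
    return pd.DataFrame(rows, columns=["node", "layer", "n_successors",
                                       "n_descendants"])


def _ordered_copy(g: nx.DiGraph) -> nx.DiGraph:
    out = nx.DiGraph(**{k: v for k, v in g.graph.items() if k not in
                        ("pruned_edges", "cycles")})
    for node in sorted(g.nodes):
        out.add_node(node, **g.nodes[node])
    for u, v in sorted(g.edges):
        out.add_edge(u, v, **g.edges[u, v])
    return out


def export_graph(g: nx.DiGraph, outdir, formats=SUPPORTED_FORMATS,
                 stem: str = "graph") -> list[pathlib.Path]:
    """Write GraphML, JSON node-link and flat TSV views of the graph.

    TSV output includes pruned edges flagged ``pruned=True`` rather than
    dropping them. Outputs are byte-stable for a fixed graph.
    """
    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []
    for fmt in formats:
        if fmt not in SUPPORTED_FORMATS:
            raise ValueError(
                f"unknown export format {fmt!r}; supported: {SUPPORTED_FORMATS}"
            )
    ordered = _ordered_copy(g)
    if "graphml" in formats:
        path = outdir / f"{stem}.graphml"
        nx.write_graphml(ordered, path, encoding="utf-8")
        written.append(path)
    if "json" in formats:
        path = outdir / f"{stem}.json"
        payload = nx.node_link_data(ordered, edges="edges")
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True, ensure_ascii=False)
        written.append(path)
    if "tsv" in formats:
        node_rows = [
            {"node": n, **{k: g.nodes[n].get(k, np.nan) for k in _NODE_ATTRS}}
            for n in sorted(g.nodes)
        ]
        nodes_df = pd.DataFrame(node_rows, columns=["node", *_NODE_ATTRS])
        if len(nodes_df):
            nodes_df = nodes_df.merge(layer_nodes(g), on="node", how="left")
        npath = outdir / f"{stem}_nodes.tsv"
        nodes_df.to_csv(npath, sep="\t", index=False)
        written.append(npath)
        edge_rows = [
            {"d1": u, "d2": v, **{k: g.edges[u, v].get(k, np.nan) for k in _EDGE_ATTRS},
             "pruned": False}
            for u, v in sorted(g.edges)
        ] + [
            {"d1": u, "d2": v, **{k: attrs.get(k, np.nan) for k in _EDGE_ATTRS},
             "pruned": True}
            for u, v, attrs in sorted(g.graph.get("pruned_edges", []),
                                      key=lambda t: (t[0], t[1]))
        ]
        edges_df = pd.DataFrame(edge_rows, columns=["d1", "d2", *_EDGE_ATTRS, "pruned"])
        epath = outdir / f"{stem}_edges.tsv"
        edges_df.to_csv(epath, sep="\t", index=False)
        written.append(epath)
    return written


def import_graphml(path) -> nx.DiGraph:
    """Round-trip reader for :func:`export_graph` GraphML output."""
    g = nx.read_graphml(path)
    out = nx.DiGraph()
    for node, attrs in g.nodes(data=True):
        out.add_node(node, **attrs)
    for u, v, attrs in g.edges(data=True):
        out.add_edge(u, v, **attrs)
    return out
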