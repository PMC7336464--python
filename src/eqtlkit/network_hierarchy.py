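"""TF -> target network from distant eQTLs, and its hierarchy.

A distant eQTL whose lead SNP falls inside a transcription-factor gene
body is read as evidence that the TF (or a variant regulating it)
controls the etrait: a directed edge TF -> etrait.  Each TF node is
then scored by its hierarchy height

    h = (O - I) / (O + I),

with O the out-degree and I the in-degree *through TF regulators only*
(edges whose target is itself a TF), so h = 1 marks pure sources and
h = -1 pure targets.  Normalized heights place TFs (or TF families,
with degrees summed over members first) into three tiers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .io_formats import GeneAnnotation

EDGE_COLUMNS = ["regulator", "target", "conditions", "dynamics", "eqtl_id"]


def resolve_eqtls_to_tfs(
    eqtls: pd.DataFrame, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Edges TF -> etrait from distant eQTLs whose lead SNP sits in a TF body.

    Only distant eQTLs are considered; a lead SNP inside two overlapping
    TF genes yields both edges (with a warning).  Edges are deduplicated
    per (regulator, target) with condition sets unioned; dynamics labels
    are kept per source record and unioned as well.
    """
    rows = []
    for _, r in eqtls.iterrows():
        if r.get("locality") != "distant":
            continue
        genes = annotation.genes_containing(r["lead_chrom"], int(r["lead_pos"]))
        tf_hits = [g for g in genes if annotation.loc(g)["is_tf"]]
        if len(tf_hits) > 1:
            warnings.warn(
                f"lead SNP {r['lead_snp']} inside {len(tf_hits)} overlapping TF genes"
            )
        conds = r.get("conditions_detected", r.get("condition", ""))
        dyn = r.get("dynamics", "")
        eqtl_id = r.get("locus_id", r.get("lead_snp"))
        for tf in tf_hits:
            if tf == r["etrait_gene"]:
                continue
            rows.append(
                {
                    "regulator": tf,
                    "target": r["etrait_gene"],
                    "conditions": conds,
                    "dynamics": dyn,
                    "eqtl_id": eqtl_id,
                }
            )
    edges = pd.DataFrame(rows, columns=EDGE_COLUMNS)
    if edges.empty:
        return edges

    def _union(series: pd.Series) -> str:
        vals: set[str] = set()
        for v in series:
            vals.update(x for x in str(v).split(",") if x)
        return ",".join(sorted(vals))

    return (
        edges.groupby(["regulator", "target"], as_index=False)
        .agg(conditions=("conditions", _union), dynamics=("dynamics", _union),
             eqtl_id=("eqtl_id", "first"))
    )


def hierarchy_height(
    edges: pd.DataFrame, annotation: GeneAnnotation | None = None
) -> pd.DataFrame:
    """Per-TF out/in degrees and h = (O - I) / (O + I).

    O counts all outgoing edges of the node; I counts incoming edges,
    which by construction of the edge list all come from TF regulators.
    Scored nodes are the TFs of the network: every regulator, plus any
    target the annotation flags as a TF.  Nodes with O + I = 0 are
    excluded.
    """
    tf_nodes = set(edges["regulator"])
    if annotation is not None:
        tf_nodes |= {
            g
            for g in set(edges["target"])
            if g in annotation and bool(annotation.loc(g)["is_tf"])
        }
    else:
        tf_nodes |= set(edges["target"]) & set(edges["regulator"])
    rows = []
    for node in sorted(tf_nodes):
        O = int((edges["regulator"] == node).sum())
        I = int((edges["target"] == node).sum())
        if O + I == 0:
            continue
        rows.append(
            {"node": node, "out_degree": O, "in_degree": I, "h": (O - I) / (O + I)}
        )
    return pd.DataFrame(rows, columns=["node", "out_degree", "in_degree", "h"])


def family_hierarchy(
    edges: pd.DataFrame, annotation: GeneAnnotation
) -> pd.DataFrame:
    """Family-level heights: degrees summed over member TFs before h."""
    scores = hierarchy_height(edges, annotation)
    if scores.empty:
        return scores.assign(node=[])
    fam = scores["node"].map(
        lambda g: annotation.loc(g)["tf_family"] if g in annotation else None
    )
    agg = (
        scores.assign(family=fam)
        .dropna(subset=["family"])
        .groupby("family", as_index=False)[["out_degree", "in_degree"]]
        .sum()
    )
    agg["h"] = (agg["out_degree"] - agg["in_degree"]) / (
        agg["out_degree"] + agg["in_degree"]
    )
    return agg.rename(columns={"family": "node"})


def assign_tiers(scores: pd.DataFrame, n_tiers: int = 3, mode: str = "equal_width") -> pd.DataFrame:
    """Tier 1..n_tiers from normalized hierarchy height.

    Heights are min-max normalized to [0, 1]; equal-width thirds give
    tier 1 for [2/3, 1], tier 2 for [1/3, 2/3) and tier 3 for [0, 1/3).
    If every height is equal all nodes land in the middle tier (with a
    warning).  ``mode='quantile'`` splits at quantiles instead.
    """
    if scores.empty:
        raise ValueError("no scored nodes")
    out = scores.copy()
    h = out["h"].to_numpy(float)
    if np.ptp(h) == 0:
        warnings.warn("all hierarchy heights equal; assigning middle tier")
        out["h_norm"] = 0.5
        out["tier"] = (n_tiers + 1) // 2
        return out
    hn = (h - h.min()) / (h.max() - h.min())
    out["h_norm"] = hn
    if mode == "equal_width":
        # tier 1 is the top band; the epsilon keeps exact band edges
        # (e.g. h_norm = 2/3) in the upper tier despite float rounding
        band = np.minimum((hn * n_tiers + 1e-9).astype(int), n_tiers - 1)
        out["tier"] = n_tiers - band
    elif mode == "quantile":
        out["tier"] = n_tiers - pd.qcut(hn, n_tiers, labels=False, duplicates="drop")
    else:
        raise ValueError("mode must be 'equal_width' or 'quantile'")
    return out


def to_graph(edges: pd.DataFrame, scores: pd.DataFrame | None = None) -> nx.DiGraph:
    g = nx.DiGraph()
    for _, r in edges.iterrows():
        g.add_edge(r["regulator"], r["target"],
                   conditions=str(r["conditions"]), dynamics=str(r["dynamics"]))
    if scores is not None:
        for _, r in scores.iterrows():
            if r["node"] in g:
                g.nodes[r["node"]]["h"] = float(r["h"])
                if "tier" in r:
                    g.nodes[r["node"]]["tier"] = int(r["tier"])
    return g


def export_network(
    edges: pd.DataFrame,
    scores: pd.DataFrame | None,
    edges_path: str,
    graphml_path: str | None = None,
) -> None:
    """Deterministically ordered edge-list TSV plus optional GraphML."""
    ordered = edges.sort_values(["regulator", "target"], kind="stable")
    ordered.to_csv(edges_path, sep="\t", index=False)
    if graphml_path is not None:
        nx.write_graphml(to_graph(ordered, scores), graphml_path)
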