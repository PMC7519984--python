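"""Heterogeneous miRNA-family/PPI network assembly and module discovery.

Nodes are miRNA families and target genes; edges are family->gene
regulation (kind ``cleavage`` or ``translation_inhibition``, taken from the
pair's best predicted site) and gene-gene protein interactions (kind
``ppi``, carrying the combined confidence score).  Only PPI edges with
score strictly greater than the cutoff (default 0.7) and with both
endpoints already in the network are admitted.

A *coregulatory module* is a connected component of the heterogeneous graph
containing at least two family nodes -- a group of families tied together
by shared target genes and/or interactions among their target proteins.
The module hub is the family of maximum degree (ties broken by
lexicographically smallest id).
"""

from __future__ import annotations

import networkx as nx
import pandas as pd

from heatmir.containers import CoregModule, FamilyProfile


def build_mirna_ppi_network(
    hc_pairs: pd.DataFrame,
    ppi_edges: pd.DataFrame | None = None,
    min_ppi_score: float = 0.7,
) -> nx.Graph:
    """Assemble the family/gene network from high-confidence pairs + PPI.

    ``hc_pairs`` needs columns family, gene_id, family_overall,
    gene_overall, and mode (the regulation mode of the pair's best site).
    PPI edges are kept iff score > ``min_ppi_score`` (strict) and both
    endpoint genes already appear in a pair.
    """
    g = nx.Graph()
    for _, row in hc_pairs.sort_values(["family", "gene_id"]).iterrows():
        g.add_node(row["family"], type="family", direction=row["family_overall"])
        g.add_node(row["gene_id"], type="gene", direction=row["gene_overall"])
        g.add_edge(row["family"], row["gene_id"], kind=row["mode"])
    if ppi_edges is not None:
        genes = {n for n, d in g.nodes(data=True) if d["type"] == "gene"}
        for _, e in ppi_edges.iterrows():
            if e["combined_score"] <= min_ppi_score:
                continue
            if e["protein_a"] in genes and e["protein_b"] in genes:
                g.add_edge(
                    e["protein_a"], e["protein_b"],
                    kind="ppi", score=float(e["combined_score"]),
                )
    return g


def find_coregulatory_modules(net: nx.Graph) -> list[CoregModule]:
    """Connected components holding >= 2 family nodes, largest first."""
    modules = []
    for comp in nx.connected_components(net):
        families = sorted(n for n in comp if net.nodes[n]["type"] == "family")
        if len(families) < 2:
            continue
        genes = sorted(n for n in comp if net.nodes[n]["type"] == "gene")
        # hub: maximum degree, ties -> lexicographically smallest id
        top_degree = max(net.degree(f) for f in families)
        hub = min(f for f in families if net.degree(f) == top_degree)
        edges = sorted(
            (min(u, v), max(u, v), net.edges[u, v]["kind"])
            for u, v in net.subgraph(comp).edges
        )
        modules.append(CoregModule(families=families, genes=genes, hub=hub,
                                   edges=edges))
    modules.sort(key=lambda m: (-m.size, m.hub))
    return modules


def build_family_stress_bipartite(
    family_profiles: dict[str, FamilyProfile],
    stress_node: str = "heat_stress",
) -> nx.Graph:
    """Single stress node linked to every DE family (direction as attribute)."""
    g = nx.Graph()
    g.add_node(stress_node, type="stress")
    for fam, prof in sorted(family_profiles.items()):
        g.add_node(fam, type="family", direction=prof.overall_direction)
        g.add_edge(stress_node, fam, kind="responds_to")
    return g


def degree_report(net: nx.Graph) -> pd.DataFrame:
    """Per-node degree and regulation counts, sorted descending.

    ``target_count`` is the number of distinct gene targets (family nodes)
    or the number of distinct regulating families (gene nodes).
    """
    rows = []
    for node, data in net.nodes(data=True):
        neighbors = list(net.neighbors(node))
        if data["type"] == "family":
            tc = sum(1 for n in neighbors if net.nodes[n]["type"] == "gene")
        elif data["type"] == "gene":
            tc = sum(1 for n in neighbors if net.nodes[n]["type"] == "family")
        else:
            tc = 0
        rows.append({
            "node": node,
            "type": data["type"],
            "degree": net.degree(node),
            "target_count": tc,
        })
    df = pd.DataFrame(rows, columns=["node", "type", "degree", "target_count"])
    return df.sort_values(
        ["target_count", "degree", "node"], ascending=[False, False, True]
    ).reset_index(drop=True)


def module_table(modules: list[CoregModule]) -> pd.DataFrame:
    """Tabular module membership (one row per module)."""
    return pd.DataFrame(
        [
            {
                "module": i + 1,
                "hub": m.hub,
                "n_families": len(m.families),
                "n_genes": len(m.genes),
                "families": ",".join(m.families),
                "genes": ",".join(m.genes),
            }
            for i, m in enumerate(modules)
        ],
        columns=["module", "hub", "n_families", "n_genes", "families", "genes"],
    )
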