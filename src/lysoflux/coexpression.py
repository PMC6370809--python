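"""Pearson co-expression network construction and k-core hub ranking.

Every unordered gene pair is tested for correlation (two-sided t test on
r·sqrt((n−2)/(1−r²)) with n−2 degrees of freedom), p-values are BH-corrected
jointly across all tested pairs, and pairs below the FDR ceiling (0.05 in the
source analysis) become undirected edges. Key regulatory genes are nominated
by coreness (the largest k such that the gene survives iterative removal of
all vertices of degree < k), with degree and then gene id breaking ties.
"""

from __future__ import annotations

import logging

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .diffexp import bh_fdr
from .io_core import ExpressionMatrix, GeneSet

logger = logging.getLogger(__name__)


def build_network(
    matrix: ExpressionMatrix,
    genes: GeneSet | None = None,
    fdr_max: float = 0.05,
    r_min: float | None = None,
) -> nx.Graph:
    """FDR-thresholded Pearson correlation graph over all gene pairs.

    Constant genes are excluded with a warning (their correlation is
    undefined). Nodes are all tested genes; edges carry r, p_value and fdr.
    """
    if genes is not None:
        matrix = matrix.restrict_genes(genes.members)
    if matrix.n_samples < 3:
        raise ValueError("need at least 3 samples to test correlations")
    vals = matrix.values.to_numpy(dtype=float)
    keep = vals.std(axis=1) > 0
    if (~keep).any():
        dropped = [g for g, k in zip(matrix.gene_ids, keep) if not k]
        logger.warning("excluding %d constant gene(s): %s", len(dropped), dropped)
    vals = vals[keep]
    gene_ids = [g for g, k in zip(matrix.gene_ids, keep) if k]
    if len(gene_ids) < 2:
        raise ValueError("need at least 2 non-constant genes")

    n = matrix.n_samples
    r = np.corrcoef(vals)
    iu, ju = np.triu_indices(len(gene_ids), k=1)
    r_pairs = np.clip(r[iu, ju], -1.0, 1.0)
    with np.errstate(divide="ignore"):
        t = r_pairs * np.sqrt((n - 2) / np.maximum(1 - r_pairs**2, 1e-300))
    p = 2 * stats.t.sf(np.abs(t), n - 2)
    q = bh_fdr(p)

    keep_edge = q < fdr_max
    if r_min is not None:
        keep_edge &= np.abs(r_pairs) >= r_min

    G = nx.Graph()
    G.add_nodes_from(gene_ids)
    for i, j, rr, pp, qq in zip(
        iu[keep_edge], ju[keep_edge], r_pairs[keep_edge], p[keep_edge], q[keep_edge]
    ):
        a, b = sorted((gene_ids[i], gene_ids[j]))
        G.add_edge(a, b, r=float(rr), p_value=float(pp), fdr=float(qq))
    return G


def kcore_decomposition(network: nx.Graph) -> dict[str, int]:
    """Coreness per node: the largest k whose k-core still contains the node."""
    if network.number_of_nodes() == 0:
        return {}
    return dict(nx.core_number(network))


def rank_hubs(network: nx.Graph) -> pd.DataFrame:
    """Hub table: coreness desc, then correlation strength, then degree, gene id.

    Strength is the sum of |r| over incident edges (1 per edge when the graph
    is unweighted, where it coincides with degree). Weighting the tie-break
    by correlation strength keeps a planted hub ahead of module members that
    pick up weak spurious edges, which raw degree cannot distinguish.
    """
    coreness = kcore_decomposition(network)
    rows = []
    for g in network.nodes:
        strength = sum(
            abs(d.get("r", 1.0)) for _, _, d in network.edges(g, data=True)
        )
        rows.append((g, network.degree[g], coreness.get(g, 0), strength))
    out = pd.DataFrame(rows, columns=["gene_id", "degree", "coreness", "strength"])
    out = out.sort_values(
        ["coreness", "strength", "degree", "gene_id"],
        ascending=[False, False, False, True],
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def edge_table(network: nx.Graph) -> pd.DataFrame:
    rows = [
        (a, b, d["r"], d["p_value"], d["fdr"])
        for a, b, d in sorted(network.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "r", "p", "fdr"])


def write_network(network: nx.Graph, graphml_path=None, edges_path=None) -> None:
    """Export GraphML (with degree/coreness node attributes) and/or edge-list TSV."""
    if graphml_path is not None:
        G = network.copy()
        coreness = kcore_decomposition(G)
        for g in G.nodes:
            G.nodes[g]["degree"] = G.degree[g]
            G.nodes[g]["coreness"] = coreness.get(g, 0)
        nx.write_graphml(G, graphml_path)
    if edges_path is not None:
        from .io_core import write_results_table

        write_results_table(edge_table(network), edges_path)
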