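"""Cross-source PPI integration, centralities, hub selection, enrichment.

The integrated network restricts a confidence-scored PPI edge table to the
union of the three evidence gene lists (differentially expressed genes,
DMR genes, methylation-module genes), keeps only edges whose endpoints can
be labelled with two *different* sources, and retains the largest
connected component — so every surviving node is supported by at least two
data modalities through the interaction structure.

Hubs are nodes at or above the 95th percentile of at least one of seven
topology metrics: degree, average neighbour degree, closeness,
eigenvector, Katz, betweenness, and local clustering coefficient.
Over-representation of gene sets in the hub list uses the hypergeometric
upper tail with BH correction (minimum effective set size 5).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx
from scipy import stats

from .diffmeth import bh_adjust
from .errors import (
    EmptyNetworkError,
    InvalidArgumentError,
)

METRICS = (
    "degree",
    "neighbor_degree",
    "closeness",
    "eigenvector",
    "katz",
    "betweenness",
    "clustering_coeff",
)

SOURCES = ("DEG", "DMR", "FEM")


def dedupe_ppi(ppi: pd.DataFrame) -> pd.DataFrame:
    """Drop self-loops; collapse (a,b)/(b,a) duplicates keeping max confidence."""
    ppi = ppi[ppi["gene_a"] != ppi["gene_b"]].copy()
    ga = ppi["gene_a"].astype(str).to_numpy()
    gb = ppi["gene_b"].astype(str).to_numpy()
    swap = ga > gb
    lo = np.where(swap, gb, ga)
    hi = np.where(swap, ga, gb)
    out = pd.DataFrame(
        {"gene_a": lo, "gene_b": hi, "confidence": ppi["confidence"].to_numpy()}
    )
    out = out.sort_values("confidence", ascending=False).drop_duplicates(
        ["gene_a", "gene_b"]
    )
    return out.sort_values(["gene_a", "gene_b"]).reset_index(drop=True)


def build_integrated_network(
    ppi: pd.DataFrame,
    deg: set[str],
    dmr_genes: set[str],
    fem_genes: set[str],
    min_conf: float = 0.7,
) -> nx.Graph:
    """Cross-source subnetwork: edges must join two different source labels.

    Node attribute ``sources`` records the (possibly multiple) evidence
    lists each gene appears in.  An edge survives when some pairing of
    endpoint labels is heterogeneous, i.e. it is dropped only when both
    endpoints carry exactly the same single label.  Returns the largest
    connected component (ties broken by the lexicographically smallest
    sorted node list).
    """
    labels: dict[str, set[str]] = {}
    for name, genes in zip(SOURCES, (deg, dmr_genes, fem_genes)):
        for g in genes:
            labels.setdefault(g, set()).add(name)
    if not labels:
        raise InvalidArgumentError("all three source gene sets are empty")

    ppi = dedupe_ppi(ppi)
    g = nx.Graph()
    for a, b, conf in ppi.itertuples(index=False):
        if conf < min_conf or a not in labels or b not in labels:
            continue
        la, lb = labels[a], labels[b]
        if len(la | lb) < 2:  # both endpoints single-source, identical label
            continue
        g.add_edge(a, b, confidence=float(conf))
    if g.number_of_edges() == 0:
        raise EmptyNetworkError("no cross-source edges above the confidence cutoff")

    comps = [sorted(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), c))
    major = g.subgraph(comps[0]).copy()
    nx.set_node_attributes(
        major, {n: sorted(labels[n]) for n in major.nodes}, "sources"
    )
    return major


def compute_centralities(net: nx.Graph) -> pd.DataFrame:
    """Seven per-node topology metrics on a connected graph.

    Degree is the raw count; closeness is (n-1)/sum of distances;
    betweenness uses the standard 2/((n-1)(n-2)) normalisation;
    eigenvector and Katz (alpha = 0.9/lambda_max, beta = 1) are computed
    by dense symmetric eigendecomposition / linear solve and
    L2-normalised.
    """
    n = net.number_of_nodes()
    if n < 2:
        raise InvalidArgumentError("need at least 2 nodes")
    if not nx.is_connected(net):
        raise InvalidArgumentError("graph must be connected (pass the major component)")

    nodes = sorted(net.nodes)
    a = nx.to_numpy_array(net, nodelist=nodes, weight=None)

    evals, evecs = np.linalg.eigh(a)
    lam_max = float(evals[-1])
    eig = evecs[:, -1]
    eig = np.abs(eig) / np.linalg.norm(eig)

    alpha = 0.9 / lam_max
    katz = np.linalg.solve(np.eye(n) - alpha * a, np.ones(n))
    katz = katz / np.linalg.norm(katz)

    deg = dict(net.degree())
    nbr_deg = nx.average_neighbor_degree(net)
    closeness = nx.closeness_centrality(net)
    tab = pd.DataFrame(
        {
            "degree": [deg[v] for v in nodes],
            "neighbor_degree": [nbr_deg[v] for v in nodes],
            "closeness": [closeness[v] for v in nodes],
            "eigenvector": eig,
            "katz": katz,
            "betweenness": list(
                pd.Series(nx.betweenness_centrality(net, normalized=True))[nodes]
            ),
            "clustering_coeff": [nx.clustering(net, v) for v in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )
    return tab


def select_hubs(
    ct: pd.DataFrame, percentile: float = 95.0, method: str = "linear"
) -> tuple[set[str], dict[str, list[str]]]:
    """Nodes at or above the given percentile of any metric.

    The per-metric threshold is the empirical percentile
    (linear-interpolation by default, ``method="lower"`` for nearest-rank
    style); ties at the threshold are included.  Returns the union and a
    provenance map node -> metrics that selected it.
    """
    if ct.empty:
        raise InvalidArgumentError("centrality table is empty")
    provenance: dict[str, list[str]] = {}
    for metric in METRICS:
        vals = ct[metric].to_numpy(float)
        thr = np.percentile(vals, percentile, method=method)
        for node in ct.index[vals >= thr]:
            provenance.setdefault(node, []).append(metric)
    return set(provenance), provenance


def mark_selected(ct: pd.DataFrame, percentile: float = 95.0) -> pd.DataFrame:
    """Centrality table with the hub ``selected`` flag column attached."""
    hubs, _ = select_hubs(ct, percentile)
    out = ct.copy()
    out["selected"] = [n in hubs for n in out.index]
    return out


def hub_source_breakdown(
    hubs: set[str], net: nx.Graph
) -> dict[str, int]:
    """Reporting view: hub counts per evidence source (multi-label nodes
    count once per label, mirroring the per-source percentage breakdown)."""
    counts = {s: 0 for s in SOURCES}
    for h in hubs:
        for s in net.nodes[h].get("sources", []):
            counts[s] += 1
    return counts


def hypergeom_enrich(
    query: set[str],
    sets: dict[str, set[str]],
    universe: set[str],
    min_size: int = 5,
    fdr_cut: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of gene sets in a query list.

    Sets are intersected with the universe before sizing; sets smaller
    than ``min_size`` after intersection are excluded before testing.
    Returns all tested sets with p and BH fdr plus a ``significant``
    column at ``fdr_cut``.
    """
    if not query <= universe:
        raise InvalidArgumentError("query genes must be a subset of the universe")
    n_universe = len(universe)
    n_query = len(query)
    rows = []
    for name, genes in sorted(sets.items()):
        eff = genes & universe
        if len(eff) < min_size:
            continue
        overlap = len(eff & query)
        p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(eff), n_query))
        rows.append(
            {"set_name": name, "set_size": len(eff), "overlap": overlap, "p": p}
        )
    out = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_cut
        out = out.sort_values("p", kind="mergesort").reset_index(drop=True)
    else:
        out["fdr"] = []
        out["significant"] = []
    return out
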