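"""Functional-epigenetic-module detection on a PPI graph.

Finds subnetworks of a protein-interaction graph whose members show
coordinated differential methylation.  Each gene carries a statistic
aggregated from its mapped probes (|t|); edges are weighted by the mean of
their endpoint statistics; modules are grown greedily from high-statistic
seeds and scored by the mean internal edge weight; significance comes from
permuting the gene statistics over the graph and comparing the observed
module score to the permutation distribution of the *maximum* module
score, which keeps the family-wise false-positive rate of "any significant
module" at the nominal level under an exchangeable null.

The greedy seed-and-grow search is this package's own documented
procedure (a spin-glass-style optimiser would satisfy the same contract);
see docs/methods.md.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .errors import NoOverlapError


@dataclass
class EpiModule:
    """One detected module with permutation significance."""

    seed_gene: str
    members: list[str]
    score: float       # mean internal edge weight
    emp_p: float
    direction_summary: float  # fraction of members with hypermethylation sign
    sig_score: float = 0.0    # size-aware statistic used for the permutation test

    def to_dict(self) -> dict:
        return asdict(self)


def gene_stats(
    dms: pd.DataFrame,
    ann: pd.DataFrame,
    aggregation: str = "mean",
    feature_filter: str | None = None,
) -> pd.DataFrame:
    """Aggregate per-probe |t| statistics to gene level.

    ``aggregation`` is ``mean`` or ``max`` over the probes mapped to each
    gene; ``feature_filter`` (e.g. ``"promoter"``) restricts to probes in
    that feature class.  ``signed_mean_delta_beta`` carries the direction.
    """
    if aggregation not in ("mean", "max"):
        raise ValueError("aggregation must be 'mean' or 'max'")
    ann = ann.loc[dms.index]
    mask = ann["gene"].astype(str) != ""
    if feature_filter is not None:
        mask &= ann["feature"] == feature_filter
    sub = dms[mask.to_numpy()]
    genes = ann.loc[mask, "gene"].astype(str)

    rows: dict[str, list] = {}
    for probe, gene_field in genes.items():
        for g in gene_field.split(";"):
            if g:
                rows.setdefault(g, []).append(probe)
    records = []
    for g, probes in rows.items():
        t = np.abs(sub.loc[probes, "t"].to_numpy(float))
        db = sub.loc[probes, "delta_beta"].to_numpy(float)
        stat = t.mean() if aggregation == "mean" else t.max()
        records.append(
            {"gene": g, "stat": stat, "n_probes": len(probes),
             "signed_mean_delta_beta": db.mean()}
        )
    out = pd.DataFrame(records, columns=["gene", "stat", "n_probes",
                                         "signed_mean_delta_beta"])
    return out.set_index("gene").sort_index()


def _build_adjacency(ppi: pd.DataFrame) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for a, b in zip(ppi["gene_a"], ppi["gene_b"]):
        if a == b:
            continue
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)
    return adj


GROWTH_TOL = 0.85  # admit a neighbour while its new-edge mean stays within
                   # this fraction of the current mean internal edge weight


def _greedy_modules(
    adj: dict[str, set[str]],
    weight: dict[str, float],
    max_modules: int,
    max_size: int,
    growth_tol: float = GROWTH_TOL,
) -> list[tuple[str, frozenset, float, float]]:
    """Seed-and-grow search; returns (seed, members, score, sig) per module.

    Edge weight = mean of the endpoint node weights; ``score`` = mean
    internal edge weight; ``sig`` = sum of internal edge weights divided
    by sqrt(edge count) — a size-aware statistic, so a genuinely dense
    high-weight module outranks a lucky high-weight pair in the
    permutation null.  Seeds are local maxima of the node weight, ranked
    by weight.  Growth adds the neighbour whose new internal edges have
    the highest mean, admitting it while that mean stays within
    ``growth_tol`` of the current module mean (so weakly attached
    background nodes are refused); a singleton has mean 0, so the first
    neighbour is always admissible.
    """
    def edge_w(u: str, v: str) -> float:
        return 0.5 * (weight[u] + weight[v])

    local_max = [
        g for g, nbrs in adj.items()
        if all(weight[g] >= weight[n] for n in nbrs)
    ]
    local_max.sort(key=lambda g: (-weight[g], g))
    seeds = local_max[:max_modules]

    modules: list[tuple[str, frozenset, float, float]] = []
    for seed in seeds:
        members = {seed}
        esum, ecount = 0.0, 0
        boundary = set(adj[seed])
        while boundary and len(members) < max_size:
            best_mean, best_node, best_add, best_k = -1.0, None, 0.0, 0
            for cand in sorted(boundary):
                new_edges = adj[cand] & members
                k = len(new_edges)
                add = sum(edge_w(cand, m) for m in new_edges)
                mean_new = add / k
                if mean_new > best_mean:
                    best_mean, best_node, best_add, best_k = mean_new, cand, add, k
            current_mean = esum / ecount if ecount else 0.0
            if best_node is None or best_mean < growth_tol * current_mean:
                break
            esum += best_add
            ecount += best_k
            members.add(best_node)
            boundary |= adj[best_node] - members
            boundary.discard(best_node)
        members = _prune(members, adj, edge_w, growth_tol)
        esum, ecount = _module_edges(members, adj, edge_w)
        score = esum / ecount if ecount else 0.0
        sig = esum / np.sqrt(ecount) if ecount else 0.0
        modules.append((seed, frozenset(members), score, sig))

    # deduplicate modules sharing any seed gene, keeping the best statistic
    modules.sort(key=lambda m: -m[3])
    kept: list[tuple[str, frozenset, float, float]] = []
    claimed: set[str] = set()
    seen_members: set[frozenset] = set()
    seed_set = set(seeds)
    for seed, members, score, sig in modules:
        if members in seen_members or (members & seed_set) & claimed:
            continue
        kept.append((seed, members, score, sig))
        seen_members.add(members)
        claimed |= members & seed_set
    return kept


def _module_edges(members: set[str] | frozenset, adj, edge_w) -> tuple[float, int]:
    esum, ecount = 0.0, 0
    for u in members:
        for v in adj[u] & set(members):
            if u < v:
                esum += edge_w(u, v)
                ecount += 1
    return esum, ecount


def _prune(members, adj, edge_w, growth_tol: float) -> set[str]:
    """Iteratively drop the member most weakly attached to the rest.

    A member whose mean internal edge weight falls below ``growth_tol``
    of the module's overall mean is removed (worst first); this strips
    background nodes picked up while a low-weight seed climbed toward a
    dense region.  If removal disconnects the module, the largest
    connected piece is kept.
    """
    members = set(members)
    while len(members) > 2:
        esum, ecount = _module_edges(members, adj, edge_w)
        if ecount == 0:
            break
        mean = esum / ecount
        worst, worst_mean = None, np.inf
        for u in sorted(members):
            internal = adj[u] & members
            if not internal:
                worst, worst_mean = u, 0.0
                break
            m = sum(edge_w(u, v) for v in internal) / len(internal)
            if m < worst_mean:
                worst, worst_mean = u, m
        if worst_mean >= growth_tol * mean:
            break
        members.discard(worst)
        members = _largest_component(members, adj)
    return members


def _largest_component(members: set[str], adj) -> set[str]:
    best: set[str] = set()
    todo = set(members)
    while todo:
        start = todo.pop()
        comp = {start}
        stack = [start]
        while stack:
            u = stack.pop()
            for v in adj[u] & members:
                if v not in comp:
                    comp.add(v)
                    stack.append(v)
        todo -= comp
        if len(comp) > len(best) or (len(comp) == len(best) and sorted(comp) < sorted(best)):
            best = comp
    return best


def detect_modules(
    stats: pd.DataFrame,
    ppi: pd.DataFrame,
    max_modules: int = 10,
    max_size: int = 100,
    n_perm: int = 1000,
    seed: int | None = 0,
) -> list[EpiModule]:
    """Detect differential-methylation modules with permutation p-values.

    Node weight = gene statistic (0 for graph genes without a statistic);
    emp_p uses the add-one estimator against the permutation distribution
    of the maximum module score, so it is never 0 and "any emp_p < alpha"
    is calibrated at alpha when statistics are exchangeable.
    """
    adj = _build_adjacency(ppi)
    graph_genes = sorted(adj)
    overlap = set(stats.index) & set(graph_genes)
    if not overlap:
        raise NoOverlapError("no genes shared between statistics and PPI graph")

    stat_map = stats["stat"].to_dict()
    weights = np.array([float(stat_map.get(g, 0.0)) for g in graph_genes])
    weight = dict(zip(graph_genes, weights))

    observed = _greedy_modules(adj, weight, max_modules, max_size)
    if not observed:
        return []

    rng = np.random.default_rng(seed)
    perm_max = np.empty(n_perm)
    for i in range(n_perm):
        shuffled = rng.permutation(weights)
        w = dict(zip(graph_genes, shuffled))
        mods = _greedy_modules(adj, w, max_modules, max_size)
        perm_max[i] = max((m[3] for m in mods), default=0.0)

    db = stats["signed_mean_delta_beta"].to_dict()
    out = []
    for seed_gene, members, score, sig in observed:
        emp_p = (1.0 + np.sum(perm_max >= sig)) / (1.0 + n_perm)
        signs = [db.get(g, 0.0) for g in members if db.get(g, 0.0) != 0.0]
        frac_hyper = (
            float(np.mean([s > 0 for s in signs])) if signs else 0.5
        )
        out.append(
            EpiModule(
                seed_gene=seed_gene,
                members=sorted(members),
                score=float(score),
                emp_p=float(emp_p),
                direction_summary=frac_hyper,
                sig_score=float(sig),
            )
        )
    out.sort(key=lambda m: (m.emp_p, -m.score))
    return out


def module_genes(modules: list[EpiModule], emp_p_cut: float = 0.05) -> set[str]:
    """Union of member genes over modules with emp_p <= cut."""
    genes: set[str] = set()
    for m in modules:
        if m.emp_p <= emp_p_cut:
            genes.update(m.members)
    return genes
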