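"""Regulatory-network assembly, Markov clustering and module annotation.

The network joins three edge layers around a focal TF: direct TF->target
edges from the binding analysis, lncRNA-PCG co-expression edges supported
by at least two of three datasets, and protein-protein interactions among
protein-coding targets.  Modules are found with the Markov Cluster
algorithm (MCL): a random walk on the graph is alternately expanded
(matrix power) and inflated (elementwise power with column renormalisation)
until the flow matrix converges to a union of star-shaped attractor
systems, which are read out as clusters.  Modules are annotated by
hypergeometric gene-set enrichment, and a single lncRNA's function is
predicted from the annotation of its co-expressed partners
(guilt-by-association).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from tfnetminer.coexpr import pair_support, partners
from tfnetminer.cofactor import OverlapCounts, hypergeom_upper_tail
from tfnetminer.diffexpr import bh_adjust
from tfnetminer.targets import TargetSet


@dataclass
class Module:
    module_id: int
    genes: frozenset[str]
    enriched_terms: list = field(default_factory=list)

    @property
    def size(self) -> int:
        return len(self.genes)


def build_network(
    target_set: TargetSet,
    coexpr_datasets: Sequence,
    ppi_edges,
    tf: str = "TF",
    min_datasets: int = 2,
) -> nx.Graph:
    """Assemble the TF-centric regulatory network.

    Nodes carry ``kind`` (TF/PCG/lncRNA) and ``direction`` attributes;
    edges carry ``type`` (target/coexpression/ppi) and, for co-expression,
    the dataset ``support`` count.  Edge endpoints outside the target set
    (plus the TF) are dropped; the number dropped is recorded on the
    graph as ``graph["n_dropped_edges"]``.
    """
    g = nx.Graph(n_dropped_edges=0)
    directions = target_set.directions()
    g.add_node(tf, kind="TF", direction="none")
    for gene in sorted(target_set.lncrna_ids):
        g.add_node(gene, kind="lncRNA", direction=directions[gene])
    for gene in sorted(target_set.pcg_ids):
        g.add_node(gene, kind="PCG", direction=directions[gene])
    for gene in sorted(target_set.all_ids):
        g.add_edge(tf, gene, type="target")
    allowed = target_set.all_ids | {tf}
    for pair, n in sorted(
        pair_support(coexpr_datasets).items(), key=lambda kv: sorted(kv[0])
    ):
        if n < min_datasets:
            continue
        a, b = sorted(pair)
        if a in allowed and b in allowed:
            if not g.has_edge(a, b):
                g.add_edge(a, b, type="coexpression", support=n)
        else:
            g.graph["n_dropped_edges"] += 1
    ppi_iter = (
        zip(ppi_edges["gene_a"], ppi_edges["gene_b"])
        if isinstance(ppi_edges, pd.DataFrame)
        else ((a, b) for a, b, *_ in ppi_edges)
    )
    for a, b in ppi_iter:
        if a == b:
            continue
        if a in allowed and b in allowed:
            if not g.has_edge(a, b):
                g.add_edge(a, b, type="ppi")
        else:
            g.graph["n_dropped_edges"] += 1
    return g


def mcl_cluster(
    network: nx.Graph | np.ndarray,
    inflation: float = 2.0,
    expansion: int = 2,
    prune: float = 1e-5,
    max_iter: int = 100,
    tol: float = 1e-8,
    nodes: Sequence | None = None,
    weighted: bool = False,
) -> tuple[list[frozenset], bool]:
    """Markov clustering; returns (clusters, converged).

    Self-loops of weight 1 are added, the adjacency matrix is column-
    normalised, then expansion (matrix power), inflation (elementwise
    power + renormalisation) and pruning of entries below ``prune``
    alternate until the largest entry change drops below ``tol``.
    Clusters are read from the attractor rows (positive diagonal); a node
    attracted by several systems is assigned to the lowest cluster index.
    """
    if isinstance(network, nx.Graph):
        if network.number_of_nodes() == 0:
            raise ValueError("empty network")
        nodes = list(network.nodes())
        weight = "support" if weighted else None
        mat = nx.to_numpy_array(network, nodelist=nodes, weight=weight)
        if not weighted:
            mat = (mat > 0).astype(float)
    else:
        mat = np.asarray(network, dtype=float)
        if nodes is None:
            nodes = list(range(mat.shape[0]))
    n = mat.shape[0]
    m = mat.copy()
    np.fill_diagonal(m, 1.0)
    m /= m.sum(axis=0, keepdims=True)
    converged = False
    for _ in range(max_iter):
        prev = m
        m = np.linalg.matrix_power(m, expansion)
        m = m**inflation
        m /= m.sum(axis=0, keepdims=True)
        m[m < prune] = 0.0
        colsum = m.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        m /= colsum
        if prev.shape == m.shape and np.abs(m - prev).max() < tol:
            converged = True
            break
    if not converged:
        warnings.warn("MCL did not converge within max_iter", RuntimeWarning)
    attractors = [i for i in range(n) if m[i, i] > tol]
    raw: list[set[int]] = []
    for i in attractors:
        members = set(np.nonzero(m[i] > tol)[0]) | {i}
        for cluster in raw:  # merge attractor systems sharing attractors
            if i in cluster or (members & cluster & set(attractors)):
                cluster |= members
                break
        else:
            raw.append(members)
    assigned: dict[int, int] = {}
    for idx, cluster in enumerate(raw):
        for node in sorted(cluster):
            assigned.setdefault(node, idx)
    for node in range(n):  # isolated mass: singleton
        assigned.setdefault(node, len(raw) + node)
    clusters: dict[int, set] = {}
    for node, cid in assigned.items():
        clusters.setdefault(cid, set()).add(nodes[node])
    return [frozenset(c) for _, c in sorted(clusters.items())], converged


def cluster_modules(
    network: nx.Graph,
    exclude_tf: bool = True,
    inflation: float = 2.0,
    min_module_size: int = 25,
    **mcl_kwargs,
) -> tuple[list[Module], bool]:
    """MCL module detection on the relationship layers of the network.

    By default the focal TF node is removed first: it is connected to
    every target by construction, so its star edges carry no grouping
    information and, on small networks, the hub funnels all flow into a
    single cluster.  Module structure lives in the co-expression and
    PPI layers among the targets.
    """
    g = network
    if exclude_tf:
        tf_nodes = [n for n, d in network.nodes(data=True) if d.get("kind") == "TF"]
        if tf_nodes:
            g = network.copy()
            g.remove_nodes_from(tf_nodes)
    if g.number_of_nodes() == 0:
        return [], True
    clusters, converged = mcl_cluster(g, inflation=inflation, **mcl_kwargs)
    return filter_modules(clusters, min_module_size), converged


def filter_modules(clusters: Sequence[frozenset], min_module_size: int = 25) -> list[Module]:
    """Keep clusters of size >= ``min_module_size``, renumbered by size."""
    kept = [c for c in clusters if len(c) >= min_module_size]
    kept.sort(key=lambda c: (-len(c), sorted(c)))
    return [Module(i + 1, frozenset(c)) for i, c in enumerate(kept)]


def module_enrichment(
    module_genes: frozenset | set,
    genesets: Mapping[str, tuple[str, frozenset]],
    universe: set[str],
    fdr: float = 0.05,
) -> list[tuple[str, float, float]]:
    """Hypergeometric gene-set enrichment of one module, BH across terms.

    Returns (term_id, p, q) for terms with q < ``fdr``, most significant
    first.  Counting is restricted to the universe.
    """
    module = set(module_genes) & universe
    if not module:
        raise ValueError("module shares no genes with the universe")
    terms, pvals = [], []
    for term_id, (_, members) in genesets.items():
        members = members & universe
        if not members:
            continue
        counts = OverlapCounts(len(universe), len(members), len(module), len(module & members))
        terms.append(term_id)
        pvals.append(hypergeom_upper_tail(counts))
    if not terms:
        return []
    qvals = bh_adjust(pvals)
    rows = [
        (t, p, q) for t, p, q in zip(terms, pvals, qvals) if q < fdr
    ]
    rows.sort(key=lambda r: (r[1], r[0]))
    return rows


def predict_lncrna_function(
    lncrna_id: str,
    coexpr_datasets: Sequence,
    genesets: Mapping[str, tuple[str, frozenset]],
    universe: set[str],
    min_datasets: int = 2,
    top_n: int = 10,
    pcg_ids: set[str] | None = None,
) -> list[tuple[str, float, float]]:
    """Guilt-by-association function prediction for one lncRNA.

    Partners are the genes co-expressed with the lncRNA in at least
    ``min_datasets`` datasets (restricted to ``pcg_ids`` when given);
    their gene-set enrichment is ranked and the top ``top_n`` terms are
    returned as (term_id, p, q), unfiltered by FDR so that a ranking is
    always available.
    """
    part = partners(lncrna_id, coexpr_datasets, min_datasets)
    if pcg_ids is not None:
        part &= pcg_ids
    part &= universe
    if not part:
        return []
    terms, pvals = [], []
    for term_id, (_, members) in genesets.items():
        members = members & universe
        if not members:
            continue
        counts = OverlapCounts(len(universe), len(members), len(part), len(part & members))
        terms.append(term_id)
        pvals.append(hypergeom_upper_tail(counts))
    qvals = bh_adjust(pvals)
    rows = sorted(zip(terms, pvals, qvals), key=lambda r: (r[1], r[0]))
    return rows[:top_n]


def recovery_ari(truth_modules: Sequence[Sequence[str]], clusters: Sequence[frozenset]) -> float:
    """Adjusted Rand index between planted modules and a clustering.

    Restricted to genes belonging to a planted module; cluster labels for
    those genes come from the clustering (unclustered genes get their own
    label).
    """
    genes = sorted({g for mod in truth_modules for g in mod})
    truth_label = {g: i for i, mod in enumerate(truth_modules) for g in mod}
    pred_label: dict[str, int] = {}
    for i, cluster in enumerate(clusters):
        for g in cluster:
            pred_label.setdefault(g, i)
    next_free = len(clusters)
    pred = []
    for g in genes:
        if g not in pred_label:
            pred_label[g] = next_free
            next_free += 1
        pred.append(pred_label[g])
    return float(adjusted_rand_score([truth_label[g] for g in genes], pred))
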