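"""Candidate–PluriNet interaction subnetwork and its significance.

Candidates (altered glycoproteins) are joined to a pluripotency-associated
gene set (PluriNet) through a confidence-scored interaction database. Only
high-confidence edges (score >= 0.7) count, and a candidate enters the
subnetwork only with at least one direct PluriNet interaction. Topology
(average clustering coefficient, mean shortest path in the largest
component) is compared against degree-preserving randomized networks
(double-edge swaps); significance is the add-one empirical p-value
(b + 1)/(n + 1), which is never zero. Candidate–PluriNet association is
additionally tested with a one-sided Fisher's exact test, and pathway
enrichment uses the hypergeometric tail with Benjamini–Hochberg correction.
"""

from __future__ import annotations

import random
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

CANDIDATE = "candidate"
PLURINET = "plurinet"
OTHER = "other"


@dataclass
class InteractionNetwork:
    """Undirected confidence-weighted graph with node role labels."""

    graph: nx.Graph
    confidence_threshold: float = 0.7

    @property
    def candidates(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("label") == CANDIDATE
        )

    @property
    def plurinet_nodes(self) -> list[str]:
        return sorted(
            n for n, d in self.graph.nodes(data=True) if d.get("label") == PLURINET
        )


@dataclass
class NetworkMetrics:
    """Observed topology metrics and their empirical significance."""

    clustering_coefficient: float
    mean_shortest_path: float
    empirical_p_clustering: float
    empirical_p_path: float
    n_random: int
    random_clustering: np.ndarray = field(default_factory=lambda: np.empty(0))
    random_path: np.ndarray = field(default_factory=lambda: np.empty(0))


def load_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a tab-delimited {node_a, node_b, confidence} edge list."""
    edges = pd.read_csv(path, sep="\t")
    for col in ("node_a", "node_b", "confidence"):
        if col not in edges.columns:
            raise ValueError(f"edge list missing column {col!r}")
    return edges


def load_gene_list(path: str | Path) -> list[str]:
    """One gene symbol per line; blank lines ignored."""
    return [
        line.strip()
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]


def _threshold_graph(edges: pd.DataFrame, threshold: float) -> nx.Graph:
    g = nx.Graph()
    for a, b, c in edges[["node_a", "node_b", "confidence"]].itertuples(index=False):
        a, b = str(a).upper(), str(b).upper()
        if a == b or float(c) < threshold:
            continue
        if g.has_edge(a, b):  # duplicate edge: keep the highest confidence
            g[a][b]["confidence"] = max(g[a][b]["confidence"], float(c))
        else:
            g.add_edge(a, b, confidence=float(c))
    return g


def build_subnetwork(
    candidates: Iterable[str],
    plurinet: Iterable[str],
    edges: pd.DataFrame,
    threshold: float = 0.7,
) -> InteractionNetwork:
    """Induce the candidate–PluriNet subnetwork from a confidence edge list.

    Gene symbols match case-insensitively. A candidate is kept only if it
    has >=1 retained (confidence >= threshold) edge to a PluriNet node; the
    subnetwork is the induced subgraph on kept candidates plus the PluriNet
    nodes they touch.
    """
    cand = {str(c).upper() for c in candidates}
    pluri = {str(p).upper() for p in plurinet} - cand
    g = _threshold_graph(edges, threshold)
    kept_cand: set[str] = set()
    kept_pluri: set[str] = set()
    for c in cand & set(g.nodes):
        partners = pluri & set(g.neighbors(c))
        if partners:
            kept_cand.add(c)
            kept_pluri.update(partners)
    if not kept_cand:
        warnings.warn("no candidate has a direct PluriNet interaction", stacklevel=2)
    sub = g.subgraph(kept_cand | kept_pluri).copy()
    nx.set_node_attributes(
        sub, {n: CANDIDATE if n in kept_cand else PLURINET for n in sub.nodes}, "label"
    )
    return InteractionNetwork(graph=sub, confidence_threshold=threshold)


def clustering_coefficient(net: InteractionNetwork | nx.Graph) -> float:
    """Average local clustering coefficient; degree-<2 nodes contribute 0."""
    g = net.graph if isinstance(net, InteractionNetwork) else net
    if g.number_of_nodes() == 0:
        raise ValueError("clustering coefficient undefined on the empty graph")
    return float(nx.average_clustering(g, count_zeros=True))


def mean_shortest_path(net: InteractionNetwork | nx.Graph) -> float:
    """Mean shortest-path length over pairs in the largest connected component.

    NaN (with a warning) when the largest component is a single node.
    """
    g = net.graph if isinstance(net, InteractionNetwork) else net
    if g.number_of_nodes() < 2:
        raise ValueError("mean shortest path requires >=2 nodes")
    # largest component; ties broken by lexicographically smallest member
    component = min(nx.connected_components(g), key=lambda c: (-len(c), min(map(str, c))))
    if len(component) < 2:
        warnings.warn("all components are singletons; mean path undefined", stacklevel=2)
        return float("nan")
    return float(nx.average_shortest_path_length(g.subgraph(component)))


def _randomized_copy(g: nx.Graph, rng: random.Random, swaps_per_edge: int) -> nx.Graph:
    h = g.copy()
    m = h.number_of_edges()
    nswap = swaps_per_edge * m
    try:
        nx.double_edge_swap(h, nswap=nswap, max_tries=100 * nswap, seed=rng)
    except nx.NetworkXError:
        # too few swappable edges; partial (possibly zero) swaps still
        # preserve the degree sequence
        pass
    return h


def randomization_test(
    net: InteractionNetwork | nx.Graph,
    n_random: int = 1000,
    seed: int | None = None,
    swaps_per_edge: int = 10,
) -> NetworkMetrics:
    """Empirical significance of clustering and mean path vs a degree-
    preserving null (double-edge-swap randomization).

    p_clustering counts random networks with clustering >= observed;
    p_path counts random networks with mean shortest path <= observed;
    both use the add-one formula (b + 1)/(n_random + 1).
    """
    g = net.graph if isinstance(net, InteractionNetwork) else net
    if g.number_of_edges() < 2:
        warnings.warn("fewer than 2 edges; randomization is degenerate", stacklevel=2)
        obs_cc = clustering_coefficient(g) if g.number_of_nodes() else float("nan")
        obs_sp = mean_shortest_path(g) if g.number_of_nodes() >= 2 else float("nan")
        return NetworkMetrics(obs_cc, obs_sp, 1.0, 1.0, n_random)
    obs_cc = clustering_coefficient(g)
    obs_sp = mean_shortest_path(g)
    degrees = sorted(d for _, d in g.degree())
    rng = random.Random(seed)
    rand_cc = np.empty(n_random)
    rand_sp = np.empty(n_random)
    for i in range(n_random):
        h = _randomized_copy(g, rng, swaps_per_edge)
        assert sorted(d for _, d in h.degree()) == degrees
        rand_cc[i] = clustering_coefficient(h)
        rand_sp[i] = mean_shortest_path(h)
    p_cc = (float(np.sum(rand_cc >= obs_cc)) + 1.0) / (n_random + 1.0)
    p_sp = (float(np.sum(rand_sp <= obs_sp)) + 1.0) / (n_random + 1.0)
    return NetworkMetrics(
        clustering_coefficient=obs_cc,
        mean_shortest_path=obs_sp,
        empirical_p_clustering=p_cc,
        empirical_p_path=p_sp,
        n_random=n_random,
        random_clustering=rand_cc,
        random_path=rand_sp,
    )


def fisher_overlap(
    candidates: Iterable[str],
    plurinet: Iterable[str],
    universe: Iterable[str],
    edges: pd.DataFrame,
    threshold: float = 0.7,
) -> tuple[float, np.ndarray]:
    """One-sided Fisher's exact test for candidate–PluriNet association.

    The 2x2 table crosses candidate membership with "has >=1 high-confidence
    direct PluriNet interaction" over the gene universe (PluriNet members
    themselves are excluded from the universe rows to avoid trivial
    self-interaction). Returns (p, table).
    """
    cand = {str(c).upper() for c in candidates}
    pluri = {str(p).upper() for p in plurinet}
    uni = {str(u).upper() for u in universe} - pluri
    if not uni:
        raise ValueError("empty universe")
    if not cand <= uni | pluri:
        raise ValueError("candidates must be drawn from the universe")
    g = _threshold_graph(edges, threshold)
    interacting = {
        n for n in uni if n in g and pluri & set(g.neighbors(n))
    }
    a = len(cand & interacting)
    b = len((cand & uni) - interacting)
    c = len(interacting - cand)
    d = len(uni - cand - interacting)
    table = np.array([[a, b], [c, d]])
    _, p = stats.fisher_exact(table, alternative="greater")
    return float(p), table


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """Parse a GMT file: name <tab> description <tab> gene1 <tab> gene2 ..."""
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3 or not parts[0]:
            continue
        sets[parts[0]] = {g.upper() for g in parts[2:] if g}
    return sets


def enrich_pathways(
    genes: Iterable[str],
    gmt: Mapping[str, set[str]] | str | Path,
    universe: Iterable[str],
) -> pd.DataFrame:
    """Hypergeometric gene-set enrichment with Benjamini–Hochberg correction.

    For each set: p = P(overlap >= observed) under sampling |genes| genes
    from the universe without replacement. Returns a table sorted by
    corrected p (ties by raw p, then set name).
    """
    if not isinstance(gmt, Mapping):
        gmt = read_gmt(gmt)
    uni = {str(u).upper() for u in universe}
    query = {str(g).upper() for g in genes} & uni
    if not query <= uni:
        raise ValueError("query genes must be contained in the universe")
    rows = []
    for name in sorted(gmt):
        members = gmt[name] & uni
        k = len(query & members)
        p = float(stats.hypergeom.sf(k - 1, len(uni), len(members), len(query)))
        rows.append({"set": name, "n_set": len(members), "overlap": k, "p": p})
    table = pd.DataFrame(rows, columns=["set", "n_set", "overlap", "p"])
    if len(table):
        table["p_adj"] = multipletests(table["p"], method="fdr_bh")[1]
        table = table.sort_values(
            ["p_adj", "p", "set"], kind="mergesort"
        ).reset_index(drop=True)
    else:
        table["p_adj"] = pd.Series(dtype=float)
    return table
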