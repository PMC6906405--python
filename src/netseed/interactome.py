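"""Background interactome model, seed-network expansion and topology metrics.

The background interactome is an undirected simple graph over opaque
protein/gene identifiers (a :class:`networkx.Graph`).  A *seed network* is the
union of a curated seed set and all of its direct interactors — the standard
first-neighbour expansion used to focus an exome analysis on a disease-relevant
gene set.  Topology metrics (average path length, average clustering
coefficient) are computed on the largest connected component and feed the
permutation null model in :mod:`netseed.topology_null`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import nan
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SeedNetwork:
    """A seed set plus its first PPI neighbours.

    Attributes
    ----------
    seeds:
        The curated seed identifiers (whether or not present in the
        background graph).
    members:
        Seeds plus every direct interactor of a seed.  Seeds absent from the
        background are retained as isolated members.
    missing_seeds:
        Seeds with no record in the background interactome.
    """

    seeds: frozenset[str]
    members: frozenset[str]
    missing_seeds: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        if not self.seeds <= self.members:
            raise ValueError("seeds must be a subset of members")


@dataclass
class CategorizedSubnetwork:
    """Induced subgraph over nodes carrying category labels.

    ``categories`` maps each node to its label set (e.g. SEED, GWAS_HIT,
    WES_HIT, CANDIDATE); ``graph`` is the induced subgraph in the background
    interactome; ``lcc_size`` the order of its largest connected component.
    """

    categories: dict[str, frozenset[str]]
    graph: nx.Graph
    lcc_size: int

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def category_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for labels in self.categories.values():
            for lab in labels:
                counts[lab] = counts.get(lab, 0) + 1
        return counts


@dataclass(frozen=True)
class TopologyMetrics:
    """APL/ACC of a graph's largest connected component.

    ``apl`` is the mean shortest-path length over unordered node pairs of the
    LCC (NaN and flagged when the LCC has fewer than two nodes); ``acc`` the
    mean local clustering coefficient over LCC nodes, nodes of degree < 2
    contributing zero.
    """

    apl: float
    acc: float
    lcc_size: int
    apl_defined: bool = True


# ---------------------------------------------------------------------------
# i/o
# ---------------------------------------------------------------------------

def load_interactome(edge_list_path) -> nx.Graph:
    """Read an undirected interactome from a 2+ column edge-list file.

    Whitespace/tab separated; the first two columns are identifiers, extra
    columns are ignored.  Duplicate edges are collapsed, self-loops dropped
    (count logged).  Node insertion order is lexicographic so downstream
    iteration is deterministic.
    """
    edges: set[tuple[str, str]] = set()
    nodes: set[str] = set()
    n_self = 0
    with open(edge_list_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(
                    f"{edge_list_path}: line {lineno}: expected >=2 columns, got {len(parts)}"
                )
            a, b = parts[0], parts[1]
            if a == b:
                n_self += 1
                continue
            nodes.update((a, b))
            edges.add((min(a, b), max(a, b)))
    if n_self:
        logger.info("dropped %d self-loop(s) from %s", n_self, edge_list_path)
    if not nodes:
        logger.warning("empty interactome read from %s", edge_list_path)
    g = nx.Graph()
    g.add_nodes_from(sorted(nodes))
    g.add_edges_from(sorted(edges))
    return g


def load_seed_list(path) -> list[str]:
    """Read a seed list: one identifier per line, '#' comments allowed."""
    seeds = []
    with open(path) as fh:
        for line in fh:
            line = line.split("#", 1)[0].strip()
            if line:
                seeds.append(line)
    return seeds


def load_category_map(path) -> dict[str, frozenset[str]]:
    """Read a two-column TSV of (identifier, category); multi-label allowed."""
    cats: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected (identifier, category)")
            cats.setdefault(parts[0], set()).add(parts[1])
    return {k: frozenset(v) for k, v in cats.items()}


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def expand_seed_network(interactome: nx.Graph, seeds: Iterable[str]) -> SeedNetwork:
    """First-neighbour expansion: seeds plus every direct interactor.

    Seeds not found in the interactome (e.g. mitochondrially encoded proteins
    without PPI records) are retained as isolated members and logged.
    """
    seed_set = frozenset(seeds)
    if not seed_set:
        raise ValueError("seed list is empty")
    present = seed_set & set(interactome.nodes)
    missing = seed_set - present
    if missing:
        logger.info(
            "%d seed(s) absent from the interactome kept as isolated members: %s",
            len(missing), ", ".join(sorted(missing)),
        )
    members = set(seed_set)
    for s in present:
        members.update(interactome.neighbors(s))
    return SeedNetwork(seeds=seed_set, members=frozenset(members),
                       missing_seeds=frozenset(missing))


def build_categorized_subnetwork(
    interactome: nx.Graph, category_map: Mapping[str, Iterable[str]]
) -> CategorizedSubnetwork:
    """Induce the subgraph on the categorised nodes and size its LCC."""
    if not category_map:
        raise ValueError("category map is empty")
    cats = {n: frozenset(v) for n, v in category_map.items()}
    sub = nx.Graph()
    sub.add_nodes_from(cats)
    present = [n for n in cats if n in interactome]
    sub.add_edges_from(interactome.subgraph(present).edges())
    lcc = largest_connected_component(sub)
    return CategorizedSubnetwork(categories=cats, graph=sub,
                                 lcc_size=lcc.number_of_nodes())


def genes_near_loci(
    gene_intervals: Sequence, loci: Sequence[tuple[str, int]], flank: int
) -> set[str]:
    """Genes whose interval overlaps [pos - flank, pos + flank] at any locus.

    ``gene_intervals`` is any sequence of objects with ``gene_id``,
    ``chromosome``, ``start``, ``end`` attributes (1-based inclusive);
    ``loci`` are (chromosome, position) pairs.
    """
    if flank < 0:
        raise ValueError("flank must be non-negative")
    hits: set[str] = set()
    by_chrom: dict[str, list] = {}
    for g in gene_intervals:
        by_chrom.setdefault(str(g.chromosome), []).append(g)
    for chrom, pos in loci:
        lo, hi = pos - flank, pos + flank
        for g in by_chrom.get(str(chrom), ()):
            if g.start <= hi and g.end >= lo:
                hits.add(g.gene_id)
    return hits


def largest_connected_component(graph: nx.Graph) -> nx.Graph:
    """Node-maximal connected induced subgraph.

    Ties between equally large components are broken by the smallest
    lexicographic node identifier, so the result is deterministic.
    """
    if graph.number_of_nodes() == 0:
        return nx.Graph()
    comps = [sorted(c, key=str) for c in nx.connected_components(graph)]
    largest = max(len(c) for c in comps)
    best = min((c for c in comps if len(c) == largest), key=lambda c: str(c[0]))
    return graph.subgraph(best).copy()


def topology_metrics(graph: nx.Graph) -> TopologyMetrics:
    """APL and ACC of the largest connected component.

    APL averages shortest-path distances over unordered node pairs of the
    LCC (for an undirected graph this equals the ordered-pair mean).  ACC
    averages the local clustering coefficient over all LCC nodes with
    degree-<2 nodes contributing 0.  A LCC with fewer than two nodes has no
    path length; ``apl`` is NaN and ``apl_defined`` False, ``acc`` is 0.
    """
    lcc = largest_connected_component(graph)
    n = lcc.number_of_nodes()
    if n < 2:
        return TopologyMetrics(apl=nan, acc=0.0, lcc_size=n, apl_defined=False)
    apl = nx.average_shortest_path_length(lcc)
    acc = sum(nx.clustering(lcc).values()) / n
    return TopologyMetrics(apl=float(apl), acc=float(acc), lcc_size=n)
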