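"""Degree-binned label-permutation null model for subnetwork topology.

A candidate subnetwork (a node subset of the background interactome) that is
biologically coherent tends to be "small-world" relative to chance: shorter
average path length (APL) and higher average clustering coefficient (ACC)
than a random node set with the same degree profile.  The null model here
preserves degree structure by ranking all background nodes by degree, cutting
them into equal-sized bins, and swapping subset labels only within bins —
each permutation draws, per bin, a without-replacement sample of bin members
to stand in for the subset nodes of that bin.  One-sided Monte Carlo p-values
use the add-one (Davison–Hinkley) estimator so p is never zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .interactome import TopologyMetrics, topology_metrics

logger = logging.getLogger(__name__)

DEFAULT_N_BINS = 30
DEFAULT_N_PERMUTATIONS = 10_000


@dataclass
class DegreeBinning:
    """Equal-sized degree bins over all background nodes.

    Nodes are sorted by (degree, identifier) and cut into ``n_bins``
    contiguous rank blocks; when the node count is not divisible the first
    ``count mod n_bins`` bins take one extra node.
    """

    n_bins: int
    assignment: dict[str, int]
    members: list[list[str]]

    def bin_of(self, node: str) -> int:
        return self.assignment[node]


@dataclass
class TopologyNullResult:
    """Observed metrics, permutation nulls and one-sided Monte Carlo p-values."""

    observed: TopologyMetrics
    null_apl: np.ndarray
    null_acc: np.ndarray
    p_apl_lower: float
    p_acc_upper: float
    n_permutations: int
    n_degenerate: int = 0
    rng_seed: int | None = None
    settings: dict = field(default_factory=dict)


def bin_by_degree(interactome: nx.Graph, n_bins: int = DEFAULT_N_BINS) -> DegreeBinning:
    """Partition the background nodes into equal-sized degree-rank bins."""
    n = interactome.number_of_nodes()
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    if n_bins > n:
        raise ValueError(f"n_bins={n_bins} exceeds node count {n}")
    ranked = sorted(interactome.nodes, key=lambda v: (interactome.degree[v], str(v)))
    base, extra = divmod(n, n_bins)
    members: list[list[str]] = []
    assignment: dict[str, int] = {}
    idx = 0
    for b in range(n_bins):
        size = base + (1 if b < extra else 0)
        block = ranked[idx: idx + size]
        idx += size
        members.append(block)
        for v in block:
            assignment[v] = b
    return DegreeBinning(n_bins=n_bins, assignment=assignment, members=members)


def permute_labels(
    binning: DegreeBinning, subset: set[str] | frozenset[str], rng: np.random.Generator
) -> set[str]:
    """One degree-preserving relabelling of ``subset``.

    Within each bin, the subset nodes of that bin are replaced by a uniform
    without-replacement sample of the bin's members (a node may map to
    itself).  The returned set has the same size and the same per-bin counts
    as the input subset.
    """
    per_bin: dict[int, int] = {}
    for v in subset:
        try:
            per_bin[binning.assignment[v]] = per_bin.get(binning.assignment[v], 0) + 1
        except KeyError:
            raise KeyError(f"subset node {v!r} not in background binning") from None
    out: set[str] = set()
    for b, k in per_bin.items():
        pool = binning.members[b]
        if k > len(pool):  # impossible when subset <= background
            raise RuntimeError(f"bin {b} holds {k} subset nodes but only {len(pool)} members")
        picked = rng.choice(len(pool), size=k, replace=False)
        out.update(pool[i] for i in picked)
    return out


def monte_carlo_p(observed: float, nulls, tail: str) -> float:
    """One-sided add-one Monte Carlo p-value, ties counted as extreme.

    p = (1 + #{nulls at least as extreme}) / (1 + n_nulls); ``tail='lower'``
    counts nulls <= observed, ``tail='upper'`` nulls >= observed.
    """
    nulls = np.asarray(nulls, dtype=float)
    if nulls.size == 0:
        raise ValueError("empty null distribution")
    if tail == "lower":
        k = int(np.sum(nulls <= observed))
    elif tail == "upper":
        k = int(np.sum(nulls >= observed))
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    return (1 + k) / (1 + nulls.size)


def null_topology_distribution(
    interactome: nx.Graph,
    subset,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    n_bins: int = DEFAULT_N_BINS,
    rng: np.random.Generator | int | None = None,
) -> TopologyNullResult:
    """Permutation null for the APL/ACC of a candidate node subset.

    For each permutation the subset is relabelled within degree bins, the
    induced subgraph taken in the background, and APL/ACC computed on its
    largest connected component.  Draws whose LCC has fewer than 3 nodes are
    degenerate: excluded from the APL null (count logged and reported) and
    retained in the ACC null with their (zero) clustering.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    subset = set(subset)
    rng_seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng)
    binning = bin_by_degree(interactome, n_bins)
    observed = topology_metrics(interactome.subgraph(subset))

    null_apl: list[float] = []
    null_acc: list[float] = []
    n_degenerate = 0
    for _ in range(n_permutations):
        relabelled = permute_labels(binning, subset, gen)
        m = topology_metrics(interactome.subgraph(relabelled))
        null_acc.append(m.acc)
        if m.lcc_size < 3 or not m.apl_defined:
            n_degenerate += 1
        else:
            null_apl.append(m.apl)
    if n_degenerate:
        logger.info("%d/%d degenerate permutations (LCC < 3) excluded from APL null",
                    n_degenerate, n_permutations)

    apl_arr = np.asarray(null_apl)
    acc_arr = np.asarray(null_acc)
    p_apl = monte_carlo_p(observed.apl, apl_arr, "lower") if apl_arr.size else float("nan")
    p_acc = monte_carlo_p(observed.acc, acc_arr, "upper")
    return TopologyNullResult(
        observed=observed,
        null_apl=apl_arr,
        null_acc=acc_arr,
        p_apl_lower=p_apl,
        p_acc_upper=p_acc,
        n_permutations=n_permutations,
        n_degenerate=n_degenerate,
        rng_seed=rng_seed,
        settings={"n_bins": n_bins},
    )
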