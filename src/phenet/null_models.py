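"""Label-shuffle null networks and empirical-p machinery.

The null model keeps the topology and link weights of the observed
network untouched and permutes only the node labels (disease names), so
a null replicate has the identical degree sequence; the network-level
statistic of interest is then recomputed per replicate.  Empirical
p-values are the fraction of null values strictly greater than the
observed value (ties therefore favour significance); when no null value
exceeds the observation the p-value is reported as 0 with a display
string of the form ``"< 1e-04"`` at 1e4 replicates.

One master seed spawns an independent substream per replicate, so the
null distribution depends only on the master seed, not on the order in
which replicates are evaluated.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)

DEFAULT_N_REPS = 10_000


@dataclass
class NullDistribution:
    """Replicate values of one statistic under the label-shuffle null."""

    statistic: str
    n_reps: int
    seed: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.values) != self.n_reps:
            raise ValueError("values length must equal n_reps")

    def write_tsv(self, path) -> None:
        header = f"{self.statistic}__reps{self.n_reps}__seed{self.seed}"
        with open(path, "w") as fh:
            fh.write(header + "\n")
            for v in self.values:
                fh.write(f"{v:g}\n")


def replicate_rngs(seed: int, n_reps: int) -> list[np.random.Generator]:
    """Independent per-replicate generators spawned from one master seed."""
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n_reps)]


def shuffle_node_labels(graph: nx.Graph, rng: np.random.Generator) -> nx.Graph:
    """Relabel the nodes by a uniform random permutation of the node names.

    Topology and weights are untouched; only which disease name sits at
    which network position changes, so the relabelled network has the
    same degree sequence as the input.
    """
    names = sorted(graph.nodes)
    perm = rng.permutation(len(names))
    mapping = {names[i]: names[perm[i]] for i in range(len(names))}
    return nx.relabel_nodes(graph, mapping, copy=True)


def overlap_null_distribution(
    graph: nx.Graph,
    significant_pairs: set[frozenset],
    n_reps: int = DEFAULT_N_REPS,
    seed: int = 0,
) -> NullDistribution:
    """Null distribution of the count of network links that land on a
    significantly co-occurring disease pair.

    ``significant_pairs`` holds the disease pairs (as frozensets) whose
    cohort co-occurrence passed the Bonferroni threshold; the threshold
    is fixed by the observed network's test count and is *not*
    recomputed per replicate.  Each replicate permutes the node labels
    and counts relabelled links falling on a significant pair; a
    relabelled link touching a disease with no cohort record simply
    fails the set lookup and counts as not significant.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("overlap null undefined for an empty network")
    names = sorted(graph.nodes)
    index = {n: i for i, n in enumerate(names)}
    edges = np.array([(index[u], index[v]) for u, v in graph.edges], dtype=int)
    values = np.zeros(n_reps)
    for r, rng in enumerate(replicate_rngs(seed, n_reps)):
        perm = rng.permutation(len(names))
        count = 0
        for u, v in edges:
            if frozenset((names[perm[u]], names[perm[v]])) in significant_pairs:
                count += 1
        values[r] = count
    return NullDistribution(statistic="significant_link_count",
                            n_reps=n_reps, seed=seed, values=values)


def observed_overlap(graph: nx.Graph, significant_pairs: set[frozenset]) -> int:
    """Observed count of links on significantly co-occurring pairs."""
    return sum(frozenset((u, v)) in significant_pairs for u, v in graph.edges)


def empirical_p(
    observed: float, null_values, tail: str = "upper"
) -> tuple[float, str]:
    """Empirical p-value against a null sample, with a display string.

    Upper tail: fraction of null values strictly greater than the
    observation.  A p-value of exactly 0 is displayed as ``"< 1/n"``
    (e.g. ``"< 1e-04"`` at 1e4 replicates) since the resolution of the
    empirical distribution is 1/n.
    """
    null_values = np.asarray(null_values, dtype=float)
    if null_values.size == 0:
        raise ValueError("empirical_p needs a nonempty null sample")
    if tail == "upper":
        p = float(np.mean(null_values > observed))
    elif tail == "lower":
        p = float(np.mean(null_values < observed))
    else:
        raise ValueError(f"unknown tail {tail!r}")
    display = f"< {1.0 / null_values.size:.0e}" if p == 0.0 else f"{p:.3g}"
    return p, display
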