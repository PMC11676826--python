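"""LD-block grouping of PheWAS top hits and PheNet construction.

Top-hit SNPs that are in high linkage disequilibrium (r^2 >= 0.8 within
500 kb on the same chromosome) represent the same associated locus even
though different diseases may report different member SNPs.  Such SNPs
are merged into *units* (LD-blocks; singletons stay bare SNPs) by
connected components over the qualifying pairs — single linkage, so a
chain of pairwise-close SNPs may span more than 500 kb overall while
every merged pair respects the distance constraint.

Two diseases sharing one or more units are linked in the PheNet.  The
link weight follows a mean-based polygenic-score construction: for each
shared unit i, the per-disease effect sizes are merged by the geometric
mean of their absolute values, beta_12,i = sqrt(|b1_i| * |b2_i|), and
the n shared units are summed, beta_12 = sum_i beta_12,i.  For an
LD-block, the per-disease effect size b_i is first formed as the sum of
the absolute effect sizes of the member SNPs associated with that
disease, so a block counts as ONE shared unit and its multiplicity
enters only through the summed effect.
"""

from __future__ import annotations

import logging
import math

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_R2_MIN = 0.8
DEFAULT_MAX_DIST = 500_000


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a, b):
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def build_ld_blocks(
    associations: pd.DataFrame,
    r2_table: pd.DataFrame,
    r2_min: float = DEFAULT_R2_MIN,
    max_dist: int = DEFAULT_MAX_DIST,
) -> tuple[dict[str, frozenset[str]], dict[str, str]]:
    """Group association SNPs into LD-block units.

    Units are the connected components of the graph whose edges are SNP
    pairs with ``r2 >= r2_min``, pairwise distance ``<= max_dist`` and a
    common chromosome.  Returns ``(units, snp_to_unit)`` where ``units``
    maps a unit id to its member set (size >= 2; singleton SNPs map to
    themselves and are not listed in ``units``) and ``snp_to_unit`` maps
    every association SNP to its unit id.  LD rows naming SNPs absent
    from the associations are ignored with a warning.
    """
    info = (associations[["snp_id", "chrom", "pos"]]
            .drop_duplicates("snp_id").set_index("snp_id"))
    uf = _UnionFind(info.index)
    unknown = 0
    for row in r2_table.itertuples(index=False):
        if row.snp1 not in info.index or row.snp2 not in info.index:
            unknown += 1
            continue
        if row.r2 < r2_min:
            continue
        a, b = info.loc[row.snp1], info.loc[row.snp2]
        if a.chrom != b.chrom or abs(int(a.pos) - int(b.pos)) > max_dist:
            continue
        uf.union(row.snp1, row.snp2)
    if unknown:
        logger.warning("build_ld_blocks: ignored %d LD rows naming SNPs "
                       "absent from the associations", unknown)

    components: dict[str, set[str]] = {}
    for snp in info.index:
        components.setdefault(uf.find(snp), set()).add(snp)

    units: dict[str, frozenset[str]] = {}
    snp_to_unit: dict[str, str] = {}
    for members in components.values():
        if len(members) == 1:
            (snp,) = members
            snp_to_unit[snp] = snp
            continue
        # deterministic block id from chromosome and leftmost position
        chrom = info.loc[sorted(members)[0], "chrom"]
        min_pos = min(int(info.loc[s, "pos"]) for s in members)
        unit_id = f"ldb_{chrom}_{min_pos}"
        units[unit_id] = frozenset(members)
        for snp in members:
            snp_to_unit[snp] = unit_id
    return units, snp_to_unit


def block_effect_size(
    associations: pd.DataFrame, disease: str, members
) -> float:
    """Per-disease effect size of one unit: sum of |beta| over the member
    SNPs associated with the disease (a bare SNP is a 1-member unit)."""
    if isinstance(members, str):
        members = (members,)
    sub = associations[(associations["phenocode"] == disease)
                       & associations["snp_id"].isin(members)]
    if sub.empty:
        raise ValueError(f"disease {disease!r} has no association in unit "
                         f"{sorted(members)}")
    return float(sub["beta"].abs().sum())


def link_weight(betas_a, betas_b) -> float:
    """Summed geometric-mean weight over shared units:
    beta_12 = sum_i sqrt(b_a,i * b_b,i)."""
    if len(betas_a) != len(betas_b) or len(betas_a) == 0:
        raise ValueError("link_weight needs one (b_a, b_b) pair per shared unit")
    return float(sum(math.sqrt(a * b) for a, b in zip(betas_a, betas_b)))


def build_phenet(
    associations: pd.DataFrame,
    snp_to_unit: dict[str, str] | None = None,
    units: dict[str, frozenset[str]] | None = None,
) -> nx.Graph:
    """Build the PheNet from filtered associations and the unit partition.

    Nodes are diseases with at least one link (isolated diseases are
    excluded); the node attribute ``n_units`` counts the disease's
    associated units.  Edges carry ``n_shared`` (number of shared units),
    ``shared_units`` (sorted unit ids) and ``weight`` (the summed
    geometric-mean effect size).  The construction is invariant to the
    input row order.
    """
    snp_to_unit = snp_to_unit or {}
    units = units or {}

    # disease -> unit -> summed |beta| over member SNP associations
    effect: dict[str, dict[str, float]] = {}
    for row in associations.itertuples(index=False):
        unit = snp_to_unit.get(row.snp_id, row.snp_id)
        per = effect.setdefault(row.phenocode, {})
        per[unit] = per.get(unit, 0.0) + abs(float(row.beta))

    unit_diseases: dict[str, set[str]] = {}
    for disease, per in effect.items():
        for unit in per:
            unit_diseases.setdefault(unit, set()).add(disease)

    edges: dict[tuple[str, str], list[str]] = {}
    for unit, diseases in unit_diseases.items():
        if len(diseases) < 2:
            continue
        diseases = sorted(diseases)
        for i in range(len(diseases)):
            for j in range(i + 1, len(diseases)):
                edges.setdefault((diseases[i], diseases[j]), []).append(unit)

    g = nx.Graph()
    for (a, b), shared in sorted(edges.items()):
        shared = sorted(shared)
        weight = link_weight([effect[a][u] for u in shared],
                             [effect[b][u] for u in shared])
        g.add_edge(a, b, n_shared=len(shared), shared_units=shared, weight=weight)
    for node in g.nodes:
        g.nodes[node]["n_units"] = len(effect[node])
    return g


def annotate_phenet(graph: nx.Graph, metadata: pd.DataFrame) -> nx.Graph:
    """Attach category, description and phenocode level node attributes
    from the metadata table (in place; also returned)."""
    from .io_phenome import phenocode_level

    meta = metadata.set_index("phenocode")
    for node in graph.nodes:
        if node in meta.index:
            graph.nodes[node]["category"] = meta.at[node, "category"]
            graph.nodes[node]["description"] = meta.at[node, "description"]
        graph.nodes[node]["level"] = phenocode_level(node)
    return graph


def phenet_edgelist(graph: nx.Graph) -> pd.DataFrame:
    """S3-schema edge list of a PheNet (From/To are disease descriptions,
    FromCode/ToCode the phenocodes, SNPs the ``;``-joined shared units)."""
    rows = []
    for a, b, data in sorted(graph.edges(data=True)):
        rows.append({
            "From": graph.nodes[a].get("description", a),
            "To": graph.nodes[b].get("description", b),
            "N": data["n_shared"],
            "betaMerged": data["weight"],
            "FromCode": a,
            "ToCode": b,
            "SNPs": ";".join(data["shared_units"]),
        })
    return pd.DataFrame(
        rows, columns=["From", "To", "N", "betaMerged", "FromCode", "ToCode", "SNPs"])
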