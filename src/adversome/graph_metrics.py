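"""Community structure and mixing patterns of the Adversome.

Louvain multi-level modularity optimization groups commonly co-reported
events into syndrome-like communities; Newman assortativity coefficients
quantify whether connected events tend to share an attribute — their
degree, their primary System Organ Class, or their disproportionality
profile (the set of drugs for which the event is a signal).

Community detection requires non-negative edge weights (modularity is not
defined for signed graphs); apply
:func:`adversome.adversome_net.positive_subnetwork` first.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .adversome_net import IsingNetwork, to_networkx
from .dispro import SDRResult
from .meddra import MedDRAHierarchy


@dataclass
class CommunityPartition:
    """Louvain output: node assignment, modularity, intermediate levels."""

    assignment: dict[str, int]
    modularity: float
    levels: list[dict[str, int]] = field(default_factory=list)
    seed: int | None = None

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def communities(self) -> list[set[str]]:
        out: dict[int, set[str]] = {}
        for node, c in self.assignment.items():
            out.setdefault(c, set()).add(node)
        return [out[c] for c in sorted(out)]


@dataclass
class AssortativityResult:
    """One Newman assortativity coefficient; ``None`` when degenerate."""

    attribute: str
    kind: str  # numeric | categorical
    coefficient: float | None


def _as_graph(net) -> nx.Graph:
    if isinstance(net, IsingNetwork):
        return to_networkx(net)
    return net


def _relabel(communities: list[set[str]]) -> dict[str, int]:
    # contiguous integer labels from 0, deterministic order by smallest member
    ordered = sorted(communities, key=lambda c: min(map(str, c)))
    return {node: i for i, comm in enumerate(ordered) for node in comm}


def louvain(net, seed: int = 0, resolution: float = 1.0) -> CommunityPartition:
    """Greedy multi-level (Louvain) modularity optimization.

    Node visit order is shuffled by ``seed`` (fully deterministic for a
    fixed seed).  Isolated nodes become singleton communities.  Negative
    edge weights are rejected — take the positive subnetwork first.
    """
    g = _as_graph(net)
    for u, v, w in g.edges(data="weight", default=1.0):
        if w < 0:
            raise ValueError(
                f"negative edge weight on ({u}, {v}); run positive_subnetwork first"
            )
    if g.number_of_nodes() == 0:
        return CommunityPartition({}, 0.0, [], seed)
    levels = list(
        nx.community.louvain_partitions(g, weight="weight", resolution=resolution, seed=seed)
    )
    final = levels[-1] if levels else [{n} for n in g.nodes]
    assignment = _relabel([set(c) for c in final])
    q = modularity(g, assignment)
    level_maps = [_relabel([set(c) for c in lv]) for lv in levels]
    return CommunityPartition(assignment, q, level_maps, seed)


def modularity(net, partition: dict[str, int] | CommunityPartition) -> float:
    """Weighted Newman–Girvan modularity Q of a partition.

    Q = (1/2m) Σ_ij (A_ij − k_i k_j / 2m) δ(c_i, c_j) with weighted degrees;
    an edgeless graph has Q = 0 by convention.
    """
    g = _as_graph(net)
    assignment = partition.assignment if isinstance(partition, CommunityPartition) else partition
    missing = [n for n in g.nodes if n not in assignment]
    if missing:
        raise ValueError(f"partition does not cover nodes: {sorted(map(str, missing))[:10]}")
    if g.number_of_edges() == 0:
        return 0.0
    groups: dict[int, set] = {}
    for node, c in assignment.items():
        if node in g:
            groups.setdefault(c, set()).add(node)
    return float(nx.community.modularity(g, list(groups.values()), weight="weight"))


def assortativity_degree(net) -> AssortativityResult:
    """Degree assortativity: Pearson correlation of the unweighted degrees
    at the two ends of each edge (each edge counted in both orientations).

    Undefined (``None``) for edgeless graphs or when every edge endpoint
    has the same degree (zero variance).
    """
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        return AssortativityResult("degree", "numeric", None)
    deg = dict(g.degree())  # unweighted: number of links
    ends = np.array([(deg[u], deg[v]) for u, v in g.edges()], dtype=float)
    xs = np.concatenate([ends[:, 0], ends[:, 1]])
    ys = np.concatenate([ends[:, 1], ends[:, 0]])
    if np.var(xs) == 0 or np.var(ys) == 0:
        return AssortativityResult("degree", "numeric", None)
    r = float(nx.degree_assortativity_coefficient(g))
    return AssortativityResult("degree", "numeric", r)


def assortativity_categorical(
    net, labels: dict[str, object], attribute: str = "categorical"
) -> AssortativityResult:
    """Newman categorical assortativity on the edge-end mixing matrix.

    r = (Σ_i e_ii − Σ_i a_i b_i) / (1 − Σ_i a_i b_i), with e the fraction
    of edge ends joining label i to label j (edges counted once per
    orientation).  Undefined when all edge endpoints carry one label.
    """
    g = _as_graph(net)
    if g.number_of_edges() == 0:
        return AssortativityResult(attribute, "categorical", None)
    unlabeled = [n for n in g.nodes if n not in labels]
    if unlabeled:
        raise ValueError(f"nodes without a label: {sorted(map(str, unlabeled))[:10]}")
    edge_labels = {lab for u, v in g.edges() for lab in (labels[u], labels[v])}
    if len(edge_labels) < 2:
        return AssortativityResult(attribute, "categorical", None)
    h = g.copy()
    nx.set_node_attributes(h, {n: str(labels[n]) for n in h.nodes}, "_attr")
    r = float(nx.attribute_assortativity_coefficient(h, "_attr"))
    return AssortativityResult(attribute, "categorical", r)


def sdr_profiles(nodes: list[str], sdrs: list[SDRResult]) -> dict[str, tuple[str, ...]]:
    """Per-event disproportionality profile: the sorted tuple of drugs with
    a significant signal for that event (empty tuple = its own class)."""
    prof: dict[str, set[str]] = {n: set() for n in nodes}
    for r in sdrs:
        if r.is_sdr and r.event in prof:
            prof[r.event].add(r.drug)
    return {n: tuple(sorted(s)) for n, s in prof.items()}


def annotate_nodes(
    net: IsingNetwork,
    sdrs: list[SDRResult],
    hierarchy: MedDRAHierarchy,
    partition: CommunityPartition | None = None,
) -> pd.DataFrame:
    """Node annotation table joining hierarchy, SDRs and communities."""
    profiles = sdr_profiles(net.nodes, sdrs)
    deg = net.degrees()
    rows = []
    for node in net.nodes:
        rows.append(
            {
                "hlt": node,
                "hlt_name": hierarchy.name_of(node),
                "primary_soc": hierarchy.hlt_to_primary_soc.get(node, "unknown"),
                "community": partition.assignment.get(node) if partition else None,
                "degree": deg[node],
                "report_count": net.node_counts.get(node, 0),
                "sdr_profile": "|".join(profiles[node]),
            }
        )
    return pd.DataFrame(rows)


def write_partition(partition: CommunityPartition, path: str | Path) -> None:
    pd.DataFrame(
        sorted(partition.assignment.items()), columns=["node", "community"]
    ).to_csv(path, sep="\t", index=False)
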