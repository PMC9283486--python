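"""Most-likely disease trajectories via inverted-weight shortest paths.

Heavily traveled edges (many patients) should be *short*, so each edge
weight w is inverted to a distance 1/w before running shortest paths.
The minimum-cost directed path between two diagnoses is read as the most
likely progression route; all co-optimal paths are kept and query sets
(e.g. every disease of a chapter) are aggregated into a trajectory
network whose edge multiplicities count the trajectories using each step.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx

from tdnet.communities import ChapterMap
from tdnet.network import TemporalDiseaseNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Trajectory:
    """A simple directed path of 3-digit codes with its inverted-weight cost."""

    nodes: tuple[str, ...]
    cost: float


@dataclass
class TrajectoryNetwork:
    """Aggregation of trajectories: ordered pair -> multiplicity."""

    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    sources: set[str] = field(default_factory=set)
    targets: set[str] = field(default_factory=set)
    skipped_targets: int = 0

    @property
    def nodes(self) -> set[str]:
        out = set()
        for i, j in self.edges:
            out.add(i)
            out.add(j)
        return out


def invert_weights(network: TemporalDiseaseNetwork) -> nx.DiGraph:
    """Distance graph with edge distance 1/w; topology unchanged."""
    g = nx.DiGraph()
    g.add_nodes_from(network.graph.nodes)
    for u, v, d in network.graph.edges(data=True):
        w = d["w"]
        if w <= 0:
            raise ValueError(f"edge {u}->{v} has non-positive weight {w}")
        g.add_edge(u, v, dist=1.0 / w)
    return g


def shortest_trajectory(
    network: TemporalDiseaseNetwork, source: str, target: str
) -> list[Trajectory]:
    """All co-optimal minimum-cost trajectories from source to target.

    Returns an empty list when the target is unreachable; co-optimal
    paths are ordered lexicographically by node sequence.
    """
    if source == target:
        raise ValueError("source and target must differ")
    g = invert_weights(network)
    for node in (source, target):
        if node not in g:
            raise KeyError(f"unknown node {node!r}")
    try:
        paths = sorted(
            tuple(p) for p in nx.all_shortest_paths(g, source, target, weight="dist")
        )
    except nx.NetworkXNoPath:
        return []
    out = []
    for p in paths:
        cost = sum(g.edges[u, v]["dist"] for u, v in zip(p, p[1:]))
        out.append(Trajectory(nodes=p, cost=cost))
    return out


def aggregate_trajectories(trajectories: Iterable[Trajectory]) -> TrajectoryNetwork:
    """Count, per ordered pair, how many trajectories traverse that step."""
    net = TrajectoryNetwork()
    for traj in trajectories:
        net.sources.add(traj.nodes[0])
        net.targets.add(traj.nodes[-1])
        for step in zip(traj.nodes, traj.nodes[1:]):
            net.edges[step] = net.edges.get(step, 0) + 1
    return net


def resolve_chapter_targets(
    network: TemporalDiseaseNetwork, chapter_name: str, chapter_map: ChapterMap
) -> set[str]:
    """Network nodes falling in the named chapter (case-insensitive substring)."""
    wanted = chapter_name.strip().lower()
    matches = [
        (low, high, name)
        for low, high, name in chapter_map.ranges
        if wanted in name.lower()
    ]
    if len(matches) != 1:
        raise ValueError(
            f"chapter name {chapter_name!r} matches {len(matches)} chapters"
        )
    low, high, _ = matches[0]
    return {
        n
        for n in network.graph.nodes
        if n.isdigit() and int(low) <= int(n) <= int(high)
    }


def trajectories_to_set(
    network: TemporalDiseaseNetwork,
    source: str,
    target_set: Iterable[str],
) -> TrajectoryNetwork:
    """Aggregate shortest trajectories from ``source`` to every reachable
    member of ``target_set``; unreachable targets are skipped and counted."""
    targets = sorted(set(target_set) - {source})
    if not targets:
        raise ValueError("empty resolved target set")
    if source not in network.graph:
        raise KeyError(f"unknown node {source!r}")
    all_trajs: list[Trajectory] = []
    skipped = 0
    for t in targets:
        if t not in network.graph:
            skipped += 1
            continue
        trajs = shortest_trajectory(network, source, t)
        if not trajs:
            skipped += 1
            continue
        all_trajs.extend(trajs)
    if skipped:
        logger.info("trajectories_to_set: %d unreachable targets skipped", skipped)
    net = aggregate_trajectories(all_trajs)
    net.skipped_targets = skipped
    net.sources = {source}
    net.targets = set(targets)
    return net


def trajectory_network_frame(net: TrajectoryNetwork):
    """Edge list (source, target, multiplicity) as a DataFrame."""
    import pandas as pd

    rows = [(i, j, m) for (i, j), m in sorted(net.edges.items())]
    return pd.DataFrame(rows, columns=["source", "target", "multiplicity"])
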