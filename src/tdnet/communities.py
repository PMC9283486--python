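"""Flow communities of the disease network and their chapter entropy.

Communities are detected with the map equation (Infomap): groups of
diagnoses among which the random-walk flow of patients is trapped.
Detected modules smaller than a minimum size are dropped and the
survivors labeled TDN1..TDNk by decreasing total flow. Each community's
mix of ICD-9 chapters is summarized by the normalized entropy score

    H = sum_i  -p_i log2(p_i) / log2(n)

where p_i is the fraction of the community's n diseases falling in
chapter i: H = 0 when all members share one chapter, H = 1 when each of
the n members comes from a distinct chapter.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import igraph as ig
import pandas as pd

from tdnet.network import TemporalDiseaseNetwork


@dataclass(frozen=True)
class ChapterMap:
    """Ordered, non-overlapping numeric code ranges naming ICD-9 chapters."""

    ranges: tuple[tuple[str, str, str], ...]  # (low, high, chapter name)

    def __post_init__(self) -> None:
        prev_high = 0
        for low, high, _ in self.ranges:
            lo, hi = int(low), int(high)
            if lo > hi or lo <= prev_high:
                raise ValueError("chapter ranges must be ordered and disjoint")
            prev_high = hi


def load_chapter_map(source=None) -> ChapterMap:
    """Load the bundled 17-chapter ICD-9-CM map, or a user TSV override."""
    if source is None:
        ref = resources.files("tdnet").joinpath("data/icd9_chapters.tsv")
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", dtype=str)
    else:
        df = pd.read_csv(source, sep="\t", dtype=str)
    return ChapterMap(
        ranges=tuple(
            (row["low"], row["high"], row["chapter"]) for _, row in df.iterrows()
        )
    )


def chapter_of(code: str, chapter_map: ChapterMap) -> str:
    """Chapter whose numeric range contains the 3-digit ``code``."""
    if not (len(code) == 3 and code.isdigit()):
        raise ValueError(f"{code!r} is not a numeric 3-digit code")
    value = int(code)
    for low, high, name in chapter_map.ranges:
        if int(low) <= value <= int(high):
            return name
    raise ValueError(f"code {code!r} maps to no chapter")


def h_score(members: Iterable[str], chapter_map: ChapterMap) -> float:
    """Normalized chapter entropy of a community.

    ``p_i`` is the per-chapter proportion of members and the
    normalization is 1/log2(n) with n the community size, so the score
    reaches 1 exactly when every member sits in its own chapter. A
    singleton community is trivially homogeneous: H = 0.
    """
    members = list(members)
    n = len(members)
    if n == 0:
        raise ValueError("empty community")
    if n == 1:
        return 0.0
    counts: dict[str, int] = {}
    for code in members:
        ch = chapter_of(code, chapter_map)
        counts[ch] = counts.get(ch, 0) + 1
    h = 0.0
    for c in counts.values():
        p = c / n
        h -= p * math.log2(p)
    return h / math.log2(n)


@dataclass
class Community:
    """A labeled flow community of the disease network."""

    label: str
    members: frozenset[str]
    flow: float
    h: float | None = None
    chapter_counts: dict[str, int] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.members)


def detect_communities(
    network: TemporalDiseaseNetwork,
    trials: int = 10,
    seed: int = 0,
) -> tuple[list[set[str]], dict[str, float]]:
    """Two-level map-equation partition of the TDN.

    Edge weights act as random-walk flow; the best of ``trials``
    optimizations is kept. Returns the partition (list of node sets,
    covering every network node exactly once) and the per-node flow,
    measured as the stationary visit density of the damped walk
    (teleportation 0.15) used throughout the pipeline.

    Deterministic given (network, trials, seed): igraph draws its
    randomness from Python's ``random`` module, which is re-seeded here.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    nodes = sorted(g.nodes)
    index = {n: k for k, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in g.edges]
    weights = [float(g.edges[u, v]["w"]) for u, v in g.edges]
    h = ig.Graph(n=len(nodes), edges=edges, directed=True)
    random.seed(seed)
    clustering = h.community_infomap(edge_weights=weights or None, trials=trials)
    partition = [set() for _ in range(max(clustering.membership) + 1)]
    for node, mod in zip(nodes, clustering.membership):
        partition[mod].add(node)

    from tdnet.centrality import pagerank

    flow = pagerank(network)
    return [p for p in partition if p], flow


def filter_and_label(
    partition: Sequence[set[str]],
    flow: Mapping[str, float],
    min_size: int = 5,
) -> list[Community]:
    """Drop communities below ``min_size`` and label survivors TDN1..TDNk.

    Labels are ordered by non-increasing total member flow; ties break
    to the larger community, then to the lexicographically smallest
    member code, so labeling is reproducible.
    """
    survivors = [p for p in partition if len(p) >= min_size]
    keyed = [
        (-sum(flow.get(n, 0.0) for n in p), -len(p), min(p), p) for p in survivors
    ]
    keyed.sort(key=lambda t: (t[0], t[1], t[2]))
    return [
        Community(label=f"TDN{rank}", members=frozenset(p), flow=-negflow)
        for rank, (negflow, _, _, p) in enumerate(keyed, start=1)
    ]


def annotate_communities(
    communities: Sequence[Community], chapter_map: ChapterMap
) -> None:
    """Fill in H scores and chapter composition in place."""
    for com in communities:
        counts: dict[str, int] = {}
        for code in com.members:
            ch = chapter_of(code, chapter_map)
            counts[ch] = counts.get(ch, 0) + 1
        com.chapter_counts = counts
        com.h = h_score(com.members, chapter_map)


def community_summary(
    communities: Sequence[Community],
    fatality_by_code: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Summary table: label, n, flow, H, mean member fatality."""
    rows = []
    for com in communities:
        if fatality_by_code:
            vals = [
                fatality_by_code[c]
                for c in com.members
                if fatality_by_code.get(c) is not None
                and not (isinstance(fatality_by_code[c], float) and math.isnan(fatality_by_code[c]))
            ]
            mean_fat = sum(vals) / len(vals) if vals else math.nan
        else:
            mean_fat = math.nan
        rows.append((com.label, com.n, com.flow, com.h, mean_fat))
    return pd.DataFrame(rows, columns=["label", "n", "flow", "H", "mean_fatality"])


def chapter_incidence(
    communities: Sequence[Community], chapter_map: ChapterMap
) -> pd.DataFrame:
    """Chapter-by-community member-count incidence matrix."""
    chapters = [name for _, _, name in chapter_map.ranges]
    data = {
        com.label: [com.chapter_counts.get(ch, 0) for ch in chapters]
        for com in communities
    }
    return pd.DataFrame(data, index=chapters)
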