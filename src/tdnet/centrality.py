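"""Node-level characterization of the disease network.

Weighted degree counts incoming plus outgoing patients; PageRank gives
the stationary density of random walkers (patient flow); betweenness
captures diseases that intermediate progression routes; fatality is the
fraction of patients deceased within a fixed horizon (default 8 years)
of their first diagnosis of a disease.
"""

from __future__ import annotations

from datetime import date, timedelta
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from tdnet.ingest import PatientMeta, PatientPath
from tdnet.network import TemporalDiseaseNetwork

DAYS_PER_YEAR = 365.25


def weighted_degree(network: TemporalDiseaseNetwork, node: str) -> int:
    """Sum of edge weights w over in- and out-edges of ``node``."""
    g = network.graph
    if node not in g:
        raise KeyError(f"unknown node {node!r}")
    return sum(d["w"] for _, _, d in g.in_edges(node, data=True)) + sum(
        d["w"] for _, _, d in g.out_edges(node, data=True)
    )


def pagerank(
    network: TemporalDiseaseNetwork,
    damping: float = 0.85,
    tol: float = 1e-12,
    max_iter: int = 1000,
) -> dict[str, float]:
    """Weighted directed PageRank; transition probability ∝ w_ij.

    Dangling nodes redistribute uniformly; teleportation is uniform.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    pr = nx.pagerank(g, alpha=damping, weight="w", tol=tol, max_iter=max_iter)
    return {n: float(v) for n, v in pr.items()}


def betweenness(
    network: TemporalDiseaseNetwork, weighted: bool = True
) -> dict[str, float]:
    """Directed betweenness centrality, normalized by (n-1)(n-2).

    With ``weighted`` (default) shortest paths use distance 1/w, so
    heavy-traffic edges are short — consistent with the trajectory
    extraction; the unweighted variant is available for sensitivity.
    """
    g = network.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    if weighted:
        h = nx.DiGraph()
        h.add_nodes_from(g.nodes)
        for u, v, d in g.edges(data=True):
            h.add_edge(u, v, dist=1.0 / d["w"])
        bc = nx.betweenness_centrality(h, weight="dist", normalized=True)
    else:
        bc = nx.betweenness_centrality(g, weight=None, normalized=True)
    return {n: float(v) for n, v in bc.items()}


def fatality(
    paths: Iterable[PatientPath],
    meta: Mapping[str, PatientMeta],
    code: str,
    horizon_years: float = 8.0,
    data_end: date | None = None,
) -> float | None:
    """Fraction of patients deceased within ``horizon_years`` of their
    first diagnosis of ``code``.

    The denominator is restricted to patients whose first diagnosis is at
    least a full horizon before ``data_end`` or who died within the
    horizon, so that incompletely followed survivors do not dilute the
    estimate. Returns ``None`` when no patient is evaluable.
    """
    if data_end is None:
        raise ValueError("data_end must be provided")
    horizon = timedelta(days=horizon_years * DAYS_PER_YEAR)
    num = den = 0
    for path in paths:
        t = path.first_date(code)
        if t is None:
            continue
        m = meta.get(path.patient_id)
        death = m.death_date if m is not None else None
        died_within = death is not None and death <= t + horizon
        if t + horizon <= data_end or died_within:
            den += 1
            if died_within:
                num += 1
    if den == 0:
        return None
    return num / den


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float | None, float | None]:
    """Spearman rank correlation with average-rank ties.

    Pairs where either value is missing (None/NaN) are dropped; a
    constant vector yields ``(None, None)``.
    """
    xs, ys = [], []
    for a, b in zip(x, y):
        if a is None or b is None or (isinstance(a, float) and np.isnan(a)) or (
            isinstance(b, float) and np.isnan(b)
        ):
            continue
        xs.append(a)
        ys.append(b)
    if len(xs) < 3 or len(set(xs)) == 1 or len(set(ys)) == 1:
        return None, None
    rho, p = stats.spearmanr(xs, ys)
    return float(rho), float(p)


def centrality_table(
    network: TemporalDiseaseNetwork,
    paths: Iterable[PatientPath] | None = None,
    meta: Mapping[str, PatientMeta] | None = None,
    horizon_years: float = 8.0,
    data_end: date | None = None,
) -> pd.DataFrame:
    """Per-node table of k_w, pr, bc and (when paths given) fatality."""
    pr = pagerank(network)
    bc = betweenness(network)
    paths = list(paths) if paths is not None else None
    rows = []
    for node in sorted(network.graph.nodes):
        fat = (
            fatality(paths, meta, node, horizon_years, data_end)
            if paths is not None and meta is not None
            else None
        )
        rows.append(
            (
                node,
                weighted_degree(network, node),
                pr[node],
                bc[node],
                np.nan if fat is None else fat,
            )
        )
    return pd.DataFrame(rows, columns=["code", "k_w", "pr", "bc", "fatality"])


def correlation_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Spearman correlations among k_w, pr, bc, fatality."""
    cols = ["k_w", "pr", "bc", "fatality"]
    rows = []
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            sub = table[[a, b]].dropna()
            rho, p = spearman(sub[a].tolist(), sub[b].tolist())
            rows.append((a, b, rho, p, len(sub)))
    return pd.DataFrame(rows, columns=["x", "y", "rho", "p", "n"])
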