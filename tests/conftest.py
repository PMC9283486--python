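"""Shared fixtures: hand-built networks and a small deterministic cohort."""

from __future__ import annotations

from datetime import date

import networkx as nx
import pytest

from tdnet.network import TemporalDiseaseNetwork, TransitionEdge
from tdnet.ingest import PatientPath


def make_network(weights: dict[tuple[str, str], float]) -> TemporalDiseaseNetwork:
    """Wrap an explicit weighted edge dict as a TemporalDiseaseNetwork."""
    g = nx.DiGraph()
    prevalence: dict[str, int] = {}
    for (u, v), w in weights.items():
        g.add_edge(
            u,
            v,
            w=w,
            p_adj=0.0,
            phi=0.0,
            edge=TransitionEdge(u, v, int(w), (int(w), 0, 0, 0)),
        )
    for n in g.nodes:
        prevalence[n] = sum(d["w"] for _, _, d in g.in_edges(n, data=True)) + sum(
            d["w"] for _, _, d in g.out_edges(n, data=True)
        )
        g.nodes[n]["prevalence"] = prevalence[n]
    return TemporalDiseaseNetwork(graph=g, prevalence=prevalence)


def make_path(pid: str, *buckets) -> PatientPath:
    """make_path("P1", ("2003-01-01", "250"), ("2003-02-01", "401", "428"))"""
    out = []
    for d, *codes in buckets:
        out.append((date.fromisoformat(d), frozenset(codes)))
    return PatientPath(patient_id=pid, buckets=out)


@pytest.fixture
def diamond_network() -> TemporalDiseaseNetwork:
    """4-node fixture with unequal weights for PageRank/betweenness oracles."""
    return make_network(
        {
            ("A", "B"): 5.0,
            ("A", "C"): 1.0,
            ("B", "D"): 2.0,
            ("C", "D"): 7.0,
            ("D", "A"): 3.0,
            ("B", "C"): 4.0,
        }
    )


@pytest.fixture
def chain_vs_direct_network() -> TemporalDiseaseNetwork:
    """The diabetes→hypertension→cerebrovascular→occlusion motif: a heavy
    3-step chain competing with a weak direct edge."""
    return make_network(
        {
            ("250", "401"): 100.0,
            ("401", "436"): 100.0,
            ("436", "434"): 100.0,
            ("250", "434"): 10.0,
        }
    )
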