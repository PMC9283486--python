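"""End-to-end orchestration: ingest -> network -> centrality ->
communities -> trajectories, with provenance reporting."""

from __future__ import annotations

import hashlib
import json
import logging
import os
from datetime import date

import pandas as pd

from tdnet import __version__
from tdnet.centrality import centrality_table, correlation_summary
from tdnet.communities import (
    annotate_communities,
    chapter_incidence,
    community_summary,
    detect_communities,
    filter_and_label,
    load_chapter_map,
)
from tdnet.config import RunConfig
from tdnet.ingest import (
    extract_paths,
    filter_cohort,
    parse_patients,
    parse_records,
    paths_to_frame,
)
from tdnet.network import (
    apply_filters,
    build_candidate_edges,
    count_transitions,
    edges_to_frame,
    write_graphml,
)
from tdnet.trajectories import (
    resolve_chapter_targets,
    trajectories_to_set,
    trajectory_network_frame,
)

logger = logging.getLogger(__name__)


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the requested stages and write artifacts to ``out_dir``.

    Returns the provenance dict (also written as provenance.json):
    parameter values, input hashes, and record counts in and out of
    every filter.
    """
    if config.visits is None:
        raise ValueError("config.visits is required")
    os.makedirs(config.out_dir, exist_ok=True)
    prov: dict = {
        "version": __version__,
        "config": config.to_dict(),
        "inputs": {"visits_sha256": _sha256(config.visits)},
    }
    if config.patients:
        prov["inputs"]["patients_sha256"] = _sha256(config.patients)

    # --- ingest
    records, rejected = parse_records(config.visits, delimiter=config.delimiter)
    prov["ingest"] = {"rows": len(records) + rejected, "rejected_rows": rejected}
    meta = parse_patients(config.patients) if config.patients else {}
    if config.sex_filter or meta:
        records = filter_cohort(
            records,
            meta,
            max_age=config.max_age,
            reference_date=config.reference_date_parsed(),
            sex_filter=config.sex_filter,
        )
    prov["ingest"]["records_after_cohort_filter"] = len(records)
    paths = extract_paths(records)
    prov["ingest"]["patients_with_paths"] = len(paths)
    paths_to_frame(paths).to_csv(
        os.path.join(config.out_dir, "paths.tsv"), sep="\t", index=False
    )

    # --- network
    transitions, prevalence = count_transitions(paths)
    edges = build_candidate_edges(transitions)
    network = apply_filters(
        edges,
        prevalence,
        alpha=config.alpha,
        node_percentile=config.node_percentile,
        min_pair=config.min_pair,
        death_codes=config.death_codes,
        explicit_min_node=config.explicit_min_node,
    )
    prov["network"] = network.provenance
    edges_to_frame(network.edges).to_csv(
        os.path.join(config.out_dir, "edges.tsv"), sep="\t", index=False
    )
    write_graphml(network, os.path.join(config.out_dir, "network.graphml"))

    # --- centrality & fatality
    data_end = config.data_end_parsed()
    if data_end is None:
        data_end = max(
            (d for p in paths for d, _ in p.buckets), default=date(2018, 10, 1)
        )
    table = centrality_table(
        network, paths, meta, horizon_years=config.horizon_years, data_end=data_end
    )
    table.to_csv(
        os.path.join(config.out_dir, "centrality.tsv"), sep="\t", index=False
    )
    correlation_summary(table).to_csv(
        os.path.join(config.out_dir, "correlations.tsv"), sep="\t", index=False
    )

    # --- communities
    chapter_map = load_chapter_map()
    result = {"network": network, "paths": paths, "meta": meta, "table": table}
    if network.graph.number_of_nodes() > 0:
        partition, flow = detect_communities(
            network, trials=config.infomap_trials, seed=config.seed
        )
        communities = filter_and_label(
            partition, flow, min_size=config.community_min_size
        )
        annotate_communities(communities, chapter_map)
        prov["communities"] = {
            "modules_detected": len(partition),
            "modules_labeled": len(communities),
        }
        fat = dict(zip(table["code"], table["fatality"]))
        community_summary(communities, fat).to_csv(
            os.path.join(config.out_dir, "communities.tsv"), sep="\t", index=False
        )
        from tdnet.communities import chapter_of

        member_rows = [
            (code, com.label, chapter_of(code, chapter_map))
            for com in communities
            for code in sorted(com.members)
        ]
        pd.DataFrame(
            member_rows, columns=["code", "community_label", "chapter"]
        ).to_csv(
            os.path.join(config.out_dir, "membership.tsv"), sep="\t", index=False
        )
        chapter_incidence(communities, chapter_map).to_csv(
            os.path.join(config.out_dir, "chapter_incidence.tsv"), sep="\t"
        )
        result["communities"] = communities
        result["partition"] = partition

    # --- trajectories
    if config.trajectory_source:
        if config.trajectory_chapter:
            targets = resolve_chapter_targets(
                network, config.trajectory_chapter, chapter_map
            )
        else:
            targets = set(config.trajectory_targets)
        net = trajectories_to_set(network, config.trajectory_source, targets)
        trajectory_network_frame(net).to_csv(
            os.path.join(config.out_dir, "trajectory_network.tsv"),
            sep="\t",
            index=False,
        )
        prov["trajectories"] = {
            "source": config.trajectory_source,
            "targets": len(targets),
            "skipped_targets": net.skipped_targets,
            "edges": len(net.edges),
        }
        result["trajectory_network"] = net

    with open(os.path.join(config.out_dir, "provenance.json"), "w") as fh:
        json.dump(prov, fh, indent=2, default=str)
    result["provenance"] = prov
    return result
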