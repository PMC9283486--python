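"""Run configuration: every tunable of the pipeline in one place.

Unknown keys in a config file are a fatal error, so typos cannot
silently fall back to defaults.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from datetime import date

import yaml


@dataclass
class RunConfig:
    # inputs / outputs
    visits: str | None = None
    patients: str | None = None
    out_dir: str = "tdn_out"
    delimiter: str | None = None

    # cohort filters
    sex_filter: str | None = "male"
    max_age: float = 99.0
    reference_date: str = "2018-10-01"

    # network filters
    alpha: float = 0.05
    node_percentile: float = 10.0
    explicit_min_node: int | None = None
    min_pair: int = 100
    death_codes: list[str] = field(default_factory=lambda: ["798"])

    # centrality / fatality
    pagerank_damping: float = 0.85
    betweenness_weighted: bool = True
    horizon_years: float = 8.0
    data_end: str | None = None

    # communities
    community_min_size: int = 5
    infomap_trials: int = 10

    # trajectories
    trajectory_source: str | None = None
    trajectory_targets: list[str] = field(default_factory=list)
    trajectory_chapter: str | None = None

    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        return cls(**raw)

    def reference_date_parsed(self) -> date:
        return date.fromisoformat(self.reference_date)

    def data_end_parsed(self) -> date | None:
        return date.fromisoformat(self.data_end) if self.data_end else None

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}
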