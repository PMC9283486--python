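"""Synthetic longitudinal cohorts with planted ground truth.

Real outpatient extracts of the kind this pipeline targets cannot be
redistributed, so every stage is exercised on generated cohorts whose
structure mimics such data: multiple visits per patient, several codes
per visit date, 3-to-5-digit ICD-9 codes including supplementary V/E
codes, patient ages, death dates. Three kinds of signal can be planted:

* **precedence pairs** (i, j, excess): among patients carrying both
  diseases, i's first occurrence precedes j's with probability
  (1 + excess) / 2, at adjacent visits, creating a directed transition
  tendency detectable by the Fisher stage;
* **disease blocks** (members, p_within): with probability ``p_within`` a
  patient "flows through" a block, receiving a shuffled run of block
  members on consecutive visits — high within-block patient flow that
  the community stage should recover;
* **death model** (code -> probability): after the first diagnosis of a
  triggering code the patient dies within the 8-year horizon with the
  given probability, at a uniform time in the window.

Everything is drawn from one ``numpy`` generator seeded from the spec,
so a spec generates byte-identical tables on every run.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date, timedelta
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

DAYS_PER_YEAR = 365.25
HORIZON_DAYS = int(8 * DAYS_PER_YEAR)

#: supplementary-classification codes sprinkled in as exclusion fodder
VE_CODES = ("V70.0", "V58.69", "E849.0", "E888")


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort; defaults give a background-only
    cohort of moderate size."""

    n_patients: int = 1000
    code_universe: tuple[str, ...] = tuple(f"{c:03d}" for c in range(250, 280))
    disease_blocks: list[tuple[tuple[str, ...], float]] = field(default_factory=list)
    precedence_pairs: list[tuple[str, str, float]] = field(default_factory=list)
    pair_carrier_rate: float = 0.5
    background_rate: float = 0.6
    mean_visits: float = 8.0
    ve_rate: float = 0.05
    five_digit_rate: float = 0.5
    female_rate: float = 0.02
    death_model: dict[str, float] = field(default_factory=dict)
    date_range: tuple[date, date] = (date(2002, 1, 1), date(2018, 10, 1))
    seed: int = 0

    def validate(self) -> None:
        for p in (
            self.pair_carrier_rate,
            self.background_rate,
            self.ve_rate,
            self.five_digit_rate,
            self.female_rate,
            *(p for _, p in self.disease_blocks),
            *(e for _, _, e in self.precedence_pairs),
            *self.death_model.values(),
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        seen: set[str] = set()
        for members, _ in self.disease_blocks:
            ms = set(members)
            if ms & seen:
                raise ValueError("disease blocks must be disjoint")
            seen |= ms
        all_codes = set(self.code_universe) | seen
        all_codes |= {i for i, _, _ in self.precedence_pairs}
        all_codes |= {j for _, j, _ in self.precedence_pairs}
        for c in all_codes:
            if not (len(c) == 3 and c.isdigit()):
                raise ValueError(f"code {c!r} is not a 3-digit numeric code")
        if self.n_patients < 1 or self.mean_visits < 1:
            raise ValueError("need at least one patient and one visit")
        if self.date_range[0] >= self.date_range[1]:
            raise ValueError("empty date range")


@dataclass
class GroundTruth:
    """What was planted, for recovery scoring."""

    planted_edges: set[tuple[str, str]]
    blocks: list[set[str]]
    death_model: dict[str, float]
    pair_orientations: dict[tuple[str, str], int]  # (i,j) -> count drawn i-first


def _render_code(code: str, rng: np.random.Generator, five_digit_rate: float) -> str:
    if rng.random() < five_digit_rate:
        return f"{code}.{rng.integers(0, 100):02d}"
    return code


def generate_cohort(
    spec: CohortSpec,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw a cohort: (visits table, patients table, ground truth).

    Tables conform to the ingest schema: ``visits`` has columns
    patient_id, visit_date, icd9 (long format, one code per row);
    ``patients`` has patient_id, birth_date, death_date, sex.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    start, end = spec.date_range
    span = (end - start).days

    visit_rows: list[tuple[str, str, str]] = []
    patient_rows: list[tuple[str, str, str, str]] = []
    orientations = {(i, j): 0 for i, j, _ in spec.precedence_pairs}
    background = list(spec.code_universe)

    for k in range(spec.n_patients):
        pid = f"P{k:06d}"
        n_visits = int(rng.geometric(1.0 / spec.mean_visits))
        n_visits = max(1, min(n_visits, 60, span - 1))
        days = np.sort(rng.choice(span, size=n_visits, replace=False))
        dates = [start + timedelta(days=int(d)) for d in days]

        # per-visit code lists
        per_visit: list[list[str]] = [[] for _ in range(n_visits)]
        for v in range(n_visits):
            if rng.random() < spec.background_rate:
                per_visit[v].append(str(rng.choice(background)))

        for members, p_within in spec.disease_blocks:
            if n_visits >= 2 and rng.random() < p_within:
                k_run = int(rng.integers(2, len(members) + 1))
                run = list(rng.permutation(members)[:k_run])
                run = run[: n_visits]
                v0 = int(rng.integers(0, n_visits - len(run) + 1))
                for off, code in enumerate(run):
                    per_visit[v0 + off].append(code)

        for i, j, excess in spec.precedence_pairs:
            if n_visits >= 2 and rng.random() < spec.pair_carrier_rate:
                v0 = int(rng.integers(0, n_visits - 1))
                if rng.random() < (1.0 + excess) / 2.0:
                    first, second = i, j
                    orientations[(i, j)] += 1
                else:
                    first, second = j, i
                per_visit[v0].append(first)
                per_visit[v0 + 1].append(second)

        diagnosed_at: dict[str, int] = {}
        for v in range(n_visits):
            for code in per_visit[v]:
                if code not in diagnosed_at:
                    diagnosed_at[code] = int(days[v])
                visit_rows.append(
                    (
                        pid,
                        dates[v].isoformat(),
                        _render_code(code, rng, spec.five_digit_rate),
                    )
                )
            if rng.random() < spec.ve_rate:
                visit_rows.append(
                    (pid, dates[v].isoformat(), str(rng.choice(VE_CODES)))
                )

        death_day: int | None = None
        for code, p_death in spec.death_model.items():
            if code in diagnosed_at and rng.random() < p_death:
                d = diagnosed_at[code] + int(rng.integers(1, HORIZON_DAYS + 1))
                if death_day is None or d < death_day:
                    death_day = d

        birth_year = int(rng.integers(1930, 1981))
        birth = date(birth_year, int(rng.integers(1, 13)), int(rng.integers(1, 29)))
        sex = "female" if rng.random() < spec.female_rate else "male"
        death = (
            (start + timedelta(days=death_day)).isoformat()
            if death_day is not None
            else ""
        )
        patient_rows.append((pid, birth.isoformat(), death, sex))

    visits = pd.DataFrame(visit_rows, columns=["patient_id", "visit_date", "icd9"])
    patients = pd.DataFrame(
        patient_rows, columns=["patient_id", "birth_date", "death_date", "sex"]
    )
    truth = GroundTruth(
        planted_edges={(i, j) for i, j, _ in spec.precedence_pairs},
        blocks=[set(m) for m, _ in spec.disease_blocks],
        death_model=dict(spec.death_model),
        pair_orientations=orientations,
    )
    return visits, patients, truth


def _pair_counting_agreement(
    partition: Sequence[set[str]], reference: Sequence[set[str]]
) -> float:
    """Rand index between two partitions of the union of reference nodes."""
    nodes = sorted(set().union(*reference)) if reference else []
    if len(nodes) < 2:
        return 1.0
    lab_a = {n: k for k, block in enumerate(partition) for n in block}
    lab_b = {n: k for k, block in enumerate(reference) for n in block}
    agree = total = 0
    for x in range(len(nodes)):
        for y in range(x + 1, len(nodes)):
            u, v = nodes[x], nodes[y]
            if u not in lab_a or v not in lab_a:
                continue
            total += 1
            same_a = lab_a[u] == lab_a[v]
            same_b = lab_b[u] == lab_b[v]
            agree += same_a == same_b
    return agree / total if total else 1.0


def ground_truth_report(
    truth: GroundTruth,
    network=None,
    partition: Sequence[set[str]] | None = None,
    fatality_estimates: Mapping[str, float | None] | None = None,
) -> dict:
    """Score pipeline outputs against what was planted.

    Edge recall is the fraction of planted directed pairs retained in
    the network; precision is measured over ordered pairs of planted
    endpoints, the universe on which the planting statement is exact.
    Partition agreement reports an exact-match flag plus the pair-counting
    Rand index restricted to planted block members. Fatality error is
    estimated minus planted probability per triggering disease.
    """
    report: dict = {}
    if network is not None and truth.planted_edges:
        retained = {(u, v) for u, v in network.graph.edges}
        planted_nodes = {n for e in truth.planted_edges for n in e}
        candidate = {
            (u, v) for u in planted_nodes for v in planted_nodes if u != v
        }
        hits = truth.planted_edges & retained
        found = candidate & retained
        report["edge_recall"] = len(hits) / len(truth.planted_edges)
        report["edge_precision"] = len(hits) / len(found) if found else None
    if partition is not None and truth.blocks:
        union = set().union(*truth.blocks)
        exact = all(
            any(p & union == block for p in partition) for block in truth.blocks
        )
        report["partition_exact"] = bool(exact)
        report["partition_rand_index"] = _pair_counting_agreement(
            partition, truth.blocks
        )
    if fatality_estimates is not None and truth.death_model:
        report["fatality_error"] = {
            code: (
                None
                if fatality_estimates.get(code) is None
                else float(fatality_estimates[code]) - p
            )
            for code, p in truth.death_model.items()
        }
    return report
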