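"""Transition counting, exact test, phi, BH and the network filters."""

import math

import pytest
from hypothesis import given, settings, strategies as st

from tdnet.network import (
    apply_filters,
    bh_adjust,
    build_candidate_edges,
    build_contingency,
    count_transitions,
    fisher_one_sided,
    nearest_rank_percentile,
    phi_coefficient,
)
from tests.conftest import make_path


def exact_tail_probability(a, b, c, d):
    """Independent oracle: P(X >= a) for the hypergeometric with margins
    fixed, summed in exact integer arithmetic."""
    n = a + b + c + d
    row1, col1 = a + b, a + c
    denom = math.comb(n, col1)
    num = sum(
        math.comb(row1, k) * math.comb(n - row1, col1 - k)
        for k in range(a, min(row1, col1) + 1)
    )
    return num / denom if denom else 1.0


class TestCountTransitions:
    def test_bucket_bipartite_rule(self):
        path = make_path(
            "P1", ("2003-01-01", "A"), ("2003-02-01", "B", "C"), ("2003-03-01", "D")
        )
        w, prev = count_transitions([path])
        assert w == {("A", "B"): 1, ("A", "C"): 1, ("B", "D"): 1, ("C", "D"): 1}
        assert prev == {"A": 1, "B": 1, "C": 1, "D": 1}

    def test_additivity_across_patients(self):
        paths = [
            make_path(p, ("2003-01-01", "A"), ("2003-02-01", "B")) for p in ("P1", "P2")
        ]
        w, prev = count_transitions(paths)
        assert w == {("A", "B"): 2}
        assert prev == {"A": 2, "B": 2}

    def test_single_bucket_no_transitions(self):
        w, prev = count_transitions([make_path("P1", ("2003-01-01", "A", "B"))])
        assert w == {}
        assert prev == {"A": 1, "B": 1}


class TestContingency:
    TRANSITIONS = {("A", "B"): 1, ("A", "C"): 1, ("D", "B"): 1, ("D", "E"): 1}

    def test_direct_count(self):
        assert build_contingency("A", "B", self.TRANSITIONS) == (1, 1, 1, 1)

    def test_absent_pair(self):
        a, b, c, d = build_contingency("B", "A", self.TRANSITIONS)
        assert a == 0 and a + b + c + d == 4

    def test_degenerate_all_one_pair(self):
        assert build_contingency("A", "B", {("A", "B"): 7}) == (7, 0, 0, 0)

    def test_self_loop_rejected(self):
        with pytest.raises(ValueError):
            build_contingency("A", "A", self.TRANSITIONS)


class TestFisher:
    def test_known_value(self):
        # P(X>=4) for margins (5,5,5,5): (25 + 1)/252
        assert fisher_one_sided((4, 1, 1, 4)) == pytest.approx(26 / 252, abs=1e-12)

    def test_zero_a_is_one(self):
        assert fisher_one_sided((0, 3, 2, 5)) == 1.0

    def test_all_zero_table(self):
        assert fisher_one_sided((0, 0, 0, 0)) == 1.0

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 12)] * 4))
    def test_matches_exact_enumeration(self, table):
        assert fisher_one_sided(table) == pytest.approx(
            exact_tail_probability(*table), abs=1e-12
        )


class TestPhi:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ((1, 0, 0, 1), 1.0),
            ((0, 1, 1, 0), -1.0),
            ((4, 1, 1, 4), 0.6),
            ((1, 1, 1, 1), 0.0),
            ((5, 0, 3, 0), 0.0),  # zero marginal convention
            ((0, 0, 0, 0), 0.0),
        ],
    )
    def test_values(self, table, expected):
        assert phi_coefficient(table) == pytest.approx(expected, abs=1e-12)

    @settings(derandomize=True, max_examples=200)
    @given(st.tuples(*[st.integers(0, 30)] * 4))
    def test_bounded_and_sign(self, table):
        a, b, c, d = table
        phi = phi_coefficient(table)
        assert -1.0 <= phi <= 1.0
        if (a + b) * (c + d) * (a + c) * (b + d) > 0:
            assert math.copysign(1, phi) == math.copysign(1, a * d - b * c) or phi == 0


class TestBH:
    def test_step_up_example(self):
        assert bh_adjust([0.01, 0.02, 0.04]) == pytest.approx([0.03, 0.03, 0.04])

    def test_single_value_identity(self):
        assert bh_adjust([0.5]) == [0.5]

    def test_empty(self):
        assert bh_adjust([]) == []

    def test_all_equal_stay_equal(self):
        out = bh_adjust([0.2] * 5)
        assert all(x == pytest.approx(0.2) for x in out)

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_matches_manual_step_up(self, pvals):
        """Oracle: sort, multiply by m/rank, cumulative min from the top."""
        m = len(pvals)
        order = sorted(range(m), key=lambda k: pvals[k])
        expected = [0.0] * m
        running = 1.0
        for rank in range(m, 0, -1):
            k = order[rank - 1]
            running = min(running, pvals[k] * m / rank)
            expected[k] = running
        out = bh_adjust(pvals)
        for got, want, p in zip(out, expected, pvals):
            assert got == pytest.approx(want, abs=1e-12)
            assert got >= p - 1e-15


class TestPercentileAndFilters:
    def test_nearest_rank_percentile(self):
        assert nearest_rank_percentile(list(range(1, 101)), 10) == 10
        assert nearest_rank_percentile([5], 10) == 5

    @staticmethod
    def _cohort_edges():
        """Synthetic candidate set exercising each filter step once."""
        paths = []
        # 30 patients A→B (strong directed pair), 5 patients C→D (weak pair)
        for k in range(30):
            paths.append(make_path(f"P{k}", ("2003-01-01", "100"), ("2003-02-01", "200")))
        for k in range(5):
            paths.append(
                make_path(f"Q{k}", ("2003-01-01", "300"), ("2003-02-01", "310"))
            )
        # a rare node (prevalence 1) and a death-code edge
        paths.append(make_path("R0", ("2003-01-01", "320"), ("2003-02-01", "100")))
        for k in range(12):
            paths.append(
                make_path(f"S{k}", ("2003-01-01", "250"), ("2003-02-01", "798"))
            )
        transitions, prevalence = count_transitions(paths)
        return build_candidate_edges(transitions), prevalence

    def test_filters_are_contractive_with_provenance(self):
        edges, prevalence = self._cohort_edges()
        net = apply_filters(
            edges, prevalence, alpha=0.05, node_percentile=10, min_pair=10
        )
        prov = net.provenance
        assert prov["output_edges"] <= prov["input_edges"]
        removed = (
            prov["edges_removed_prevalence"]
            + prov["edges_removed_min_pair"]
            + prov["edges_removed_death_codes"]
            + prov["edges_removed_significance"]
        )
        assert prov["input_edges"] - removed == prov["output_edges"]
        for e in net.edges:
            assert e.w <= min(net.prevalence[e.source], net.prevalence[e.target])

    def test_min_pair_boundary(self):
        edges, prevalence = self._cohort_edges()
        net = apply_filters(edges, prevalence, min_pair=31, node_percentile=0)
        assert all(e.w >= 31 for e in net.edges)
        assert ("100", "200") not in {(e.source, e.target) for e in net.edges}

    def test_death_code_edges_removed(self):
        edges, prevalence = self._cohort_edges()
        net = apply_filters(
            edges, prevalence, min_pair=1, node_percentile=0, death_codes=("798",)
        )
        assert all("798" not in (e.source, e.target) for e in net.edges)

    def test_death_codes_must_be_normalized(self):
        edges, prevalence = self._cohort_edges()
        with pytest.raises(ValueError, match="death code"):
            apply_filters(edges, prevalence, death_codes=("798.1",))

    def test_explicit_min_node_overrides_percentile(self):
        edges, prevalence = self._cohort_edges()
        net = apply_filters(
            edges, prevalence, min_pair=1, explicit_min_node=6, alpha=1.1
        )
        assert all(prevalence[n] >= 6 for n in net.nodes)
        assert "320" not in net.nodes
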