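"""Dynamic-programming phaser: scores, backtracking, blocks, oracle checks."""

import random

import pytest

from localhap import (
    CandidateSite,
    ReadObservation,
    backtrack,
    brute_force_phase,
    build_graph,
    init_scores,
    phase_graph,
    phase_sites,
    recurrence_step,
)
from localhap.dp_phaser import compute_score_table, table_to_tsv

from conftest import random_instance


class TestTwoSiteExample:
    """Exact hand-checkable scores on the canonical two-site instance."""

    def test_initialization_scores(self, we_graph):
        table = init_scores(we_graph, 0)
        assert table.cells[(0, 0, 0)] == 5
        assert table.cells[(0, 0, 1)] == 11
        assert table.cells[(0, 1, 1)] == 6
        # unions are symmetric at initialization
        assert table.cells[(0, 1, 0)] == 11

    def test_recursion_scores(self, we_graph):
        table = init_scores(we_graph, 0)
        recurrence_step(we_graph, table, 1)
        assert table.cells[(1, 0, 0)] == 15
        assert table.cells[(1, 0, 1)] == 19
        assert table.cells[(1, 1, 0)] == 14
        # symmetric-orientation cell: 11 + |{r4,r5} ∪ {r7..r11}| = 18 by hand
        assert table.cells[(1, 1, 1)] == 18

    def test_backtrack_selects_best_pair(self, we_graph):
        assignment, blocks = phase_graph(we_graph)
        assert assignment.block_best_scores == [19]
        assert (assignment.phase1, assignment.phase2) == ([0, 0], [1, 1])
        assert len(blocks) == 1
        assert (blocks[0].first_site, blocks[0].last_site) == (0, 1)
        assert blocks[0].anchor_position == 100

    def test_matches_brute_force(self, we_graph):
        assert brute_force_phase(we_graph) == 19


class TestDegenerateAndTies:
    def test_single_site_unique_maximum(self):
        sites = [CandidateSite("c", 10, ("A", "G"), 0)]
        obs = [ReadObservation(f"p{i}", 0, 0) for i in range(5)] + [
            ReadObservation(f"q{i}", 0, 1) for i in range(6)
        ]
        g = build_graph(sites, obs)
        assignment, _ = phase_graph(g)
        assert (assignment.phase1[0], assignment.phase2[0]) == (0, 1)

    def test_tied_maxima_pick_lexicographically_smaller_pair(self):
        # disjoint equal supports: (0,1) and (1,0) tie at 6
        sites = [CandidateSite("c", 10, ("A", "G"), 0)]
        obs = [ReadObservation(f"p{i}", 0, 0) for i in range(3)] + [
            ReadObservation(f"q{i}", 0, 1) for i in range(3)
        ]
        assignment, _ = phase_graph(build_graph(sites, obs))
        assert (assignment.phase1[0], assignment.phase2[0]) == (0, 1)

    def test_disconnected_pairs_reinitialize_into_two_blocks(self):
        sites = [CandidateSite("c", 10 * (i + 1), ("A", "G"), i) for i in range(4)]
        obs = []
        for r in range(4):  # reads span sites 0-1 only
            obs += [ReadObservation(f"a{r}", 0, r % 2), ReadObservation(f"a{r}", 1, r % 2)]
        for r in range(4):  # and sites 2-3 only
            obs += [ReadObservation(f"b{r}", 2, r % 2), ReadObservation(f"b{r}", 3, r % 2)]
        g = build_graph(sites, obs)
        assignment, blocks = phase_graph(g)
        assert len(blocks) == 2
        assert [b.first_site for b in blocks] == [0, 2]
        assert assignment.block_ids == [0, 0, 1, 1]

    def test_empty_graph(self):
        g = build_graph([], [])
        assignment, blocks = phase_graph(g)
        assert assignment.n_sites == 0 and blocks == []
        assert brute_force_phase(g) == 0

    def test_vertex_without_incoming_edge_gets_artificial_edges(self):
        # allele (1,1) is observed only by a fresh read: no incoming edge,
        # but the DP must still score pairs involving it
        sites = [CandidateSite("c", 10, ("A", "G"), 0), CandidateSite("c", 20, ("C", "T"), 1)]
        obs = [
            ReadObservation("r1", 0, 0),
            ReadObservation("r1", 1, 0),
            ReadObservation("r2", 0, 1),
            ReadObservation("r2", 1, 0),
            ReadObservation("r3", 1, 1),  # fresh, supports the edge-less vertex
        ]
        g = build_graph(sites, obs)
        assert g.has_artificial_incoming((1, 1))
        table = compute_score_table(g)
        assert table.block_starts == [0]  # no reinitialization
        assignment, _ = phase_graph(g)
        assert sum(assignment.block_best_scores) == brute_force_phase(g)

    def test_brute_force_rejects_oversized_instances(self):
        sites = [CandidateSite("c", 10 * (i + 1), ("A", "C", "G", "T"), i) for i in range(12)]
        obs = [ReadObservation("r", i, 0) for i in range(12)]
        with pytest.raises(ValueError, match="too large"):
            brute_force_phase(build_graph(sites, obs))


class TestProperties:
    @pytest.mark.parametrize("seed", range(40))
    def test_oracle_equivalence_random_instances(self, seed):
        """DP total equals exhaustive enumeration on random small graphs."""
        g = random_instance(random.Random(1000 + seed))
        assignment, _ = phase_graph(g)
        assert sum(assignment.block_best_scores) == brute_force_phase(g)

    @pytest.mark.parametrize("seed", range(10))
    def test_read_relabeling_leaves_scores_unchanged(self, seed):
        g = random_instance(random.Random(2000 + seed))
        table1 = compute_score_table(g)

        relabel = {r: f"x{i}" for i, r in enumerate(sorted(g.reads()))}
        obs = [
            ReadObservation(relabel[r], n, m)
            for (n, m), reads in g.support.items()
            for r in reads
        ]
        g2 = build_graph(g.sites, obs)
        table2 = compute_score_table(g2)
        assert table1.cells == table2.cells

    @pytest.mark.parametrize("seed", range(10))
    def test_scores_monotone_along_backpointer_chain(self, seed):
        g = random_instance(random.Random(3000 + seed))
        table = compute_score_table(g)
        for (n, i, j), bp in table.backpointer.items():
            if bp is None:
                continue
            k, l = bp
            prev = max(table.cells[(n - 1, k, l)], table.cells[(n - 1, l, k)])
            assert table.cells[(n, i, j)] >= prev

    def test_determinism_identical_graphs_identical_assignments(self):
        g1 = random_instance(random.Random(77))
        g2 = random_instance(random.Random(77))
        a1, b1 = phase_graph(g1)
        a2, b2 = phase_graph(g2)
        assert (a1.phase1, a1.phase2, a1.block_ids) == (a2.phase1, a2.phase2, a2.block_ids)
        assert b1 == b2


class TestRefinement:
    def test_effectively_homozygous_site_is_removed_and_linkage_restored(self):
        # middle site is a false het (both haplotypes carry the ref allele);
        # the DP takes its diagonal, refinement drops it and reconnects
        sites = [CandidateSite("c", 10 * (i + 1), ("A", "G"), i) for i in range(3)]
        obs = []
        for r in range(4):  # haplotype 1
            allele_mid = 1 if r == 3 else 0
            obs += [
                ReadObservation(f"h1_{r}", 0, 0),
                ReadObservation(f"h1_{r}", 1, allele_mid),
                ReadObservation(f"h1_{r}", 2, 0),
            ]
        for r in range(4):  # haplotype 2
            allele_mid = 1 if r == 3 else 0
            obs += [
                ReadObservation(f"h2_{r}", 0, 1),
                ReadObservation(f"h2_{r}", 1, allele_mid),
                ReadObservation(f"h2_{r}", 2, 1),
            ]
        graph, assignment, blocks = phase_sites(sites, obs)
        assert graph.n_sites == 2
        assert [s.position for s in graph.sites] == [10, 30]
        assert len(blocks) == 1
        # both remaining sites phased heterozygous with consistent orientation
        assert assignment.phase1 != assignment.phase2
        assert assignment.phase1[0] == assignment.phase1[1]

    def test_refinement_noop_without_diagonal(self, we_sites_obs):
        graph, assignment, blocks = phase_sites(*we_sites_obs)
        assert graph.n_sites == 2
        assert assignment.block_best_scores == [19]


def test_debug_tsv_lists_every_cell(we_graph):
    table = compute_score_table(we_graph)
    text = table_to_tsv(table)
    assert len(text.strip().splitlines()) == 1 + len(table.cells)
    assert "19" in text
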