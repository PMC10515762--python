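"""Dynamic-programming phase assignment over a phasing graph.

For ordered allele pairs (i assigned phase-1, j assigned phase-2) at each
site, the score S(n, i, j) is the largest number of distinct reads consistent
with some phasing path ending in that pair:

* initialization (first site of a block):
  ``S(1, i, j) = |R(i) ∪ R(j)|`` — all reads supporting either allele;
* recursion: ``S(n, i, j) = max over unordered predecessor pairs {k, l}
  (taken in canonical orientation k ≤ l, k extending phase-1 and l phase-2,
  subject to edges k→i and l→j) of best(n-1, {k, l}) +
  |span(k,i) ∪ span(l,j) ∪ fresh(i) ∪ fresh(j)|``
  where ``span`` is the reads covering both edge endpoints, ``fresh`` the
  reads first seen at site n, and ``best(n-1, {k, l})`` the larger of the
  pair's two orientation cells.

Phase labels are symmetric — globally flipping every state of a path
preserves its score — so the two orientation cells (i, j) and (j, i) jointly
cover every ordered transition and their maximum equals the optimum of the
unrestricted recursion; backtracking switches to the mirror chain (a flip
flag) whenever a predecessor's best orientation is the flipped one.

A vertex with no incoming edge is connected to every previous-site vertex by
artificial edges carrying empty read sets, so the recursion stays defined.
When *no* vertex at a site has incoming edges, phasing cannot be extended:
scoring reinitializes there and a new phase block begins.  Backtracking from
the best final-site cell of each block yields the per-site phase-1/phase-2
allele assignment.  All scores are exact integers.

Ties are broken deterministically: smallest (k, l) predecessor tuple in the
max, smallest (i, j) cell in backtracking.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional

from .allele_graph import CandidateSite, PhasingGraph, ReadObservation, build_graph, subset_sites

Cell = tuple[int, int, int]  # (site_index, phase1 allele, phase2 allele)


@dataclass
class ScoreTable:
    """DP cells S(site, i, j) with backpointers and block boundaries."""

    cells: dict[Cell, int] = field(default_factory=dict)
    backpointer: dict[Cell, Optional[tuple[int, int]]] = field(default_factory=dict)
    block_starts: list[int] = field(default_factory=list)


@dataclass
class PhaseAssignment:
    """Per-site (phase-1 allele, phase-2 allele) labels plus block membership."""

    phase1: list[int]
    phase2: list[int]
    block_ids: list[int]
    block_best_scores: list[int]

    @property
    def n_sites(self) -> int:
        return len(self.phase1)


@dataclass(frozen=True)
class PhaseBlock:
    """A maximal run of sites phased without reinitialization."""

    block_id: int
    first_site: int
    last_site: int
    anchor_position: int  # 0-based position of first_site; phase-set anchor


def init_scores(graph: PhasingGraph, site: int, table: Optional[ScoreTable] = None) -> ScoreTable:
    """Fill block-initial scores ``S = |R(i) ∪ R(j)|`` for every ordered pair.

    The diagonal i == j is included so effectively-homozygous sites pass
    through without breaking blocks.
    """
    if table is None:
        table = ScoreTable()
    a = graph.n_alleles(site)
    for i in range(a):
        for j in range(a):
            cell = (site, i, j)
            table.cells[cell] = len(graph.support[(site, i)] | graph.support[(site, j)])
            table.backpointer[cell] = None
    table.block_starts.append(site)
    return table


def recurrence_step(graph: PhasingGraph, table: ScoreTable, site: int) -> ScoreTable:
    """Extend scores from site-1 to ``site``; reinitialize if disconnected."""
    n = site
    a = graph.n_alleles(n)
    a_prev = graph.n_alleles(n - 1)

    real_preds = {i: graph.incoming((n, i)) for i in range(a)}
    if not any(real_preds.values()):
        # no vertex has an incoming edge: phasing cannot be extended
        return init_scores(graph, n, table)

    # artificial edges: fully connect an edge-less vertex to all previous
    # vertices, contributing empty read sets
    preds = {
        i: (real_preds[i] if real_preds[i] else list(range(a_prev))) for i in range(a)
    }
    real_edge = {
        i: {k: graph.span_support.get(((n - 1, k), (n, i)), frozenset()) for k in preds[i]}
        for i in range(a)
    }

    for i in range(a):
        fresh_i = graph.fresh_reads[(n, i)]
        for j in range(a):
            fresh_j = graph.fresh_reads[(n, j)]
            pairs = [(k, l) for k in sorted(preds[i]) for l in sorted(preds[j]) if k <= l]
            if not pairs:
                # no canonically oriented pair reaches this cell; its value is
                # defined by the mirrored transitions (equals the mirror cell)
                pairs = [(k, l) for k in sorted(preds[i]) for l in sorted(preds[j])]
            best = -1
            best_kl: Optional[tuple[int, int]] = None
            for k, l in pairs:
                gain = len(real_edge[i][k] | real_edge[j][l] | fresh_i | fresh_j)
                prev = max(table.cells[(n - 1, k, l)], table.cells[(n - 1, l, k)])
                score = prev + gain
                if score > best:
                    best, best_kl = score, (k, l)
            table.cells[(n, i, j)] = best
            table.backpointer[(n, i, j)] = best_kl
    return table


def backtrack(table: ScoreTable, graph: PhasingGraph) -> PhaseAssignment:
    """Select the best final-site cell of each block and follow backpointers."""
    n_sites = graph.n_sites
    if n_sites == 0 or not table.cells:
        return PhaseAssignment([], [], [], [])

    phase1 = [0] * n_sites
    phase2 = [0] * n_sites
    block_ids = [0] * n_sites
    block_scores: list[int] = []

    starts = list(table.block_starts)
    for b, start in enumerate(starts):
        last = (starts[b + 1] - 1) if b + 1 < len(starts) else n_sites - 1
        a = graph.n_alleles(last)
        best_cell = min(
            ((last, i, j) for i in range(a) for j in range(a)),
            key=lambda c: (-table.cells[c], c[1], c[2]),
        )
        block_scores.append(table.cells[best_cell])
        n, i, j = best_cell
        flip = False  # True while following the mirror of the actual path
        while True:
            p1, p2 = (j, i) if flip else (i, j)
            phase1[n], phase2[n], block_ids[n] = p1, p2, b
            bp = table.backpointer[(n, i, j)]
            if bp is None:
                break
            k, l = bp
            # actual predecessor state under the current orientation
            dk, dl = (l, k) if flip else (k, l)
            # follow whichever orientation cell realizes the predecessor's
            # best score; if it is the mirror of the actual state, flip
            if table.cells[(n - 1, dk, dl)] >= table.cells[(n - 1, dl, dk)]:
                i, j, flip = dk, dl, False
            else:
                i, j, flip = dl, dk, True
            n -= 1
    return PhaseAssignment(phase1, phase2, block_ids, block_scores)


def phase_graph(graph: PhasingGraph) -> tuple[PhaseAssignment, list[PhaseBlock]]:
    """Run the full dynamic program: initialize, recur, backtrack.

    Returns the per-site assignment and one :class:`PhaseBlock` per
    reinitialized segment (anchored at its first site's position).
    """
    table = compute_score_table(graph)
    assignment = backtrack(table, graph)
    blocks = blocks_from_table(table, graph)
    return assignment, blocks


def compute_score_table(graph: PhasingGraph) -> ScoreTable:
    table = ScoreTable()
    if graph.n_sites == 0:
        return table
    init_scores(graph, 0, table)
    for n in range(1, graph.n_sites):
        recurrence_step(graph, table, n)
    return table


def blocks_from_table(table: ScoreTable, graph: PhasingGraph) -> list[PhaseBlock]:
    starts = list(table.block_starts)
    blocks = []
    for b, start in enumerate(starts):
        last = (starts[b + 1] - 1) if b + 1 < len(starts) else graph.n_sites - 1
        blocks.append(
            PhaseBlock(
                block_id=b,
                first_site=start,
                last_site=last,
                anchor_position=graph.sites[start].position,
            )
        )
    return blocks


def phase_sites(
    sites: list[CandidateSite], observations: list[ReadObservation]
) -> tuple[PhasingGraph, PhaseAssignment, list[PhaseBlock]]:
    """Phase an interval, iteratively dropping effectively-homozygous sites.

    A candidate whose backtracked pair is the diagonal (the same allele in
    both phase slots) behaves as homozygous: it carries no phase linkage,
    and the orientation of the chain across it is arbitrary — the transition
    gain out of a diagonal pair is identical for both orientations.  Such
    sites (typically error pileups misread as heterozygous) are removed and
    the interval re-phased, which makes their true-site neighbours
    consecutive and restores the reads' direct linkage between them.
    Repeats until no diagonal remains on the backtracked path; unchanged for
    intervals whose first pass is diagonal-free.
    """
    while True:
        graph = build_graph(sites, observations)
        assignment, blocks = phase_graph(graph)
        hom = {
            n
            for n in range(graph.n_sites)
            if assignment.phase1[n] == assignment.phase2[n]
        }
        if not hom:
            return graph, assignment, blocks
        sites, observations = subset_sites(
            sites, observations, set(range(graph.n_sites)) - hom
        )


_BRUTE_FORCE_MAX_STATES = 2_000_000


def brute_force_phase(graph: PhasingGraph) -> int:
    """Exhaustive-enumeration oracle: best total score over all assignments.

    Enumerates every sequence of per-site ordered allele pairs, scoring each
    with the same transition counting as the DP (including artificial edges
    and reinitialization), and returns the maximum total — summed over blocks
    when reinitialization splits the interval.  Only feasible on small
    instances; larger ones are rejected.
    """
    if graph.n_sites == 0:
        return 0
    n_states = 1
    for n in range(graph.n_sites):
        n_states *= graph.n_alleles(n) ** 2
        if n_states > _BRUTE_FORCE_MAX_STATES:
            raise ValueError("instance too large for brute-force enumeration")

    pair_lists = [
        list(itertools.product(range(graph.n_alleles(n)), repeat=2))
        for n in range(graph.n_sites)
    ]
    reinit = [False] * graph.n_sites
    for n in range(1, graph.n_sites):
        reinit[n] = not any(graph.incoming((n, i)) for i in range(graph.n_alleles(n)))

    def init_count(n: int, i: int, j: int) -> int:
        return len(graph.support[(n, i)] | graph.support[(n, j)])

    def trans(n: int, k: int, l: int, i: int, j: int) -> Optional[int]:
        sets = []
        for prev, cur in ((k, i), (l, j)):
            edge = ((n - 1, prev), (n, cur))
            if edge in graph.span_support:
                sets.append(graph.span_support[edge])
            elif graph.incoming((n, cur)):
                return None  # real incoming edges exist but not from this predecessor
            # else: artificial edge, empty read set
        union = graph.fresh_reads[(n, i)] | graph.fresh_reads[(n, j)]
        for s in sets:
            union = union | s
        return len(union)

    best_total = -1
    for seq in itertools.product(*pair_lists):
        total = init_count(0, *seq[0])
        ok = True
        for n in range(1, graph.n_sites):
            i, j = seq[n]
            if reinit[n]:
                total += init_count(n, i, j)
                continue
            k, l = seq[n - 1]
            gain = trans(n, k, l, i, j)
            if gain is None:
                ok = False
                break
            total += gain
        if ok and total > best_total:
            best_total = total
    return best_total


def table_to_tsv(table: ScoreTable) -> str:
    """Debug dump: one row per DP cell (site, i, j, score, backpointer)."""
    lines = ["site\tphase1_allele\tphase2_allele\tscore\tbackpointer"]
    for (n, i, j), score in sorted(table.cells.items()):
        bp = table.backpointer[(n, i, j)]
        lines.append(f"{n}\t{i}\t{j}\t{score}\t{'' if bp is None else f'{bp[0]},{bp[1]}'}")
    return "\n".join(lines) + "\n"
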