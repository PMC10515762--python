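"""Per-read haplotag assignment by majority vote over phased alleles.

Once every allele carries a phase-1/phase-2 label, each read votes with the
alleles it overlaps: an observation of a phase-1 allele is one vote for
haplotag 1, of a phase-2 allele one vote for haplotag 2.  A strict majority
decides the tag; a tie or no votes leaves the read untagged.  Phase labels
are only comparable within one phase block, so a read spanning several blocks
votes only inside the block holding most of its observations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .allele_graph import PhasingGraph
from .dp_phaser import PhaseAssignment, PhaseBlock

UNTAGGED = 0


@dataclass(frozen=True)
class HaplotagResult:
    """Haplotag for one read: 1, 2 or 0 (untagged), with its vote counts.

    ``phase_set`` is the 1-based anchor position of the phase block the tag
    is relative to (the conventional PS value); it is present iff the read is
    tagged.
    """

    read_id: str
    tag: int
    phase_set: Optional[int]
    votes_phase1: int
    votes_phase2: int
    contig: Optional[str] = None

    def __post_init__(self) -> None:
        if self.tag not in (0, 1, 2):
            raise ValueError(f"invalid haplotag {self.tag}")
        if (self.tag != UNTAGGED) != (self.phase_set is not None):
            raise ValueError("phase_set must be present exactly when the read is tagged")


def assign_read_haplotags(
    graph: PhasingGraph,
    assignment: PhaseAssignment,
    blocks: list[PhaseBlock],
) -> list[HaplotagResult]:
    """Tag every observed read by majority vote over its phased alleles.

    An observation whose allele sits in neither phase slot (a dropped extra
    allele) or whose site carries the same allele in both slots contributes
    no vote.  Each read with at least one observation appears exactly once.
    """
    if assignment.n_sites != graph.n_sites:
        raise ValueError("assignment does not cover all sites in the graph")
    contig = graph.sites[0].contig if graph.sites else None

    # read -> {site: allele} from vertex support; one observation per site
    read_sites: dict[str, dict[int, int]] = {}
    for (n, m), reads in graph.support.items():
        for r in reads:
            read_sites.setdefault(r, {})[n] = m

    results = []
    for read_id in sorted(read_sites):
        per_site = read_sites[read_id]
        # vote within the single block holding most of this read's
        # observations; ties go to the earlier block
        counts: dict[int, int] = {}
        for n in per_site:
            counts[assignment.block_ids[n]] = counts.get(assignment.block_ids[n], 0) + 1
        home = min(counts, key=lambda b: (-counts[b], b))

        v1 = v2 = 0
        for n, m in per_site.items():
            if assignment.block_ids[n] != home:
                continue
            p1, p2 = assignment.phase1[n], assignment.phase2[n]
            if p1 == p2:
                continue
            if m == p1:
                v1 += 1
            elif m == p2:
                v2 += 1
        if v1 > v2:
            tag, ps = 1, blocks[home].anchor_position + 1
        elif v2 > v1:
            tag, ps = 2, blocks[home].anchor_position + 1
        else:
            tag, ps = UNTAGGED, None
        results.append(
            HaplotagResult(
                read_id=read_id,
                tag=tag,
                phase_set=ps,
                votes_phase1=v1,
                votes_phase2=v2,
                contig=contig,
            )
        )
    return results
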