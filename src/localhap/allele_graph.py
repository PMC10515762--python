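"""Per-interval allele graph for read-backed phasing.

Vertices are alleles at candidate heterozygous sites; an edge connects an
allele at site ``n-1`` to an allele at site ``n`` whenever at least one read
supports both.  The graph also records, per vertex, which supporting reads are
"fresh" — reads whose first overlapped site is the vertex's site — because the
phasing recursion credits those reads separately from edge-spanning reads.
"""

from __future__ import annotations

import json
from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Optional

Vertex = tuple[int, int]  # (site_index, allele_index)


@dataclass(frozen=True)
class CandidateSite:
    """A putative heterozygous position with its observed alleles.

    ``alleles`` is ordered: by convention the reference allele first, then
    alternates.  ``site_index`` is the rank of the site within its interval
    and is what the dynamic program iterates over; ``position`` (0-based) is
    kept for chunking and output.
    """

    contig: str
    position: int
    alleles: tuple[str, ...]
    site_index: int

    def __post_init__(self) -> None:
        if not self.alleles:
            raise ValueError(f"site {self.contig}:{self.position} has no alleles")
        if len(set(self.alleles)) != len(self.alleles):
            raise ValueError(
                f"site {self.contig}:{self.position} has duplicate alleles {self.alleles}"
            )


@dataclass(frozen=True)
class ReadObservation:
    """One read supporting one allele at one site.

    ``read_start_site``/``read_end_site`` bound the sites the read overlaps
    (first/last site_index).  They may be omitted, in which case the graph
    derives them from the read's observations; passing them explicitly lets a
    read overlap a site without an observation there (e.g. a deletion).
    """

    read_id: str
    site_index: int
    allele_index: int
    read_start_site: Optional[int] = None
    read_end_site: Optional[int] = None


@dataclass
class PhasingGraph:
    """Alleles, consecutive-site edges and their read support for one interval."""

    sites: list[CandidateSite]
    support: dict[Vertex, frozenset[str]] = field(default_factory=dict)
    span_support: dict[tuple[Vertex, Vertex], frozenset[str]] = field(default_factory=dict)
    fresh_reads: dict[Vertex, frozenset[str]] = field(default_factory=dict)

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    def n_alleles(self, site_index: int) -> int:
        return len(self.sites[site_index].alleles)

    def vertices_at(self, site_index: int) -> list[Vertex]:
        return [(site_index, m) for m in range(self.n_alleles(site_index))]

    @property
    def edges(self) -> set[tuple[Vertex, Vertex]]:
        return set(self.span_support)

    def incoming(self, vertex: Vertex) -> list[int]:
        """Allele indices at site n-1 with a real edge into ``vertex``."""
        n, i = vertex
        return [
            k
            for k in range(self.n_alleles(n - 1))
            if ((n - 1, k), (n, i)) in self.span_support
        ]

    def has_artificial_incoming(self, vertex: Vertex) -> bool:
        """True for a vertex at site n>0 with no real incoming edge.

        The phaser fully connects such a vertex to every previous-site vertex
        with score-neutral (empty read set) artificial edges.
        """
        n, _ = vertex
        return n > 0 and not self.incoming(vertex)

    def reads(self) -> set[str]:
        out: set[str] = set()
        for s in self.support.values():
            out |= s
        return out

    def to_debug_dict(self) -> dict:
        """JSON-serializable vertex/edge/support listing for inspection."""
        return {
            "sites": [
                {
                    "contig": s.contig,
                    "position": s.position,
                    "alleles": list(s.alleles),
                    "site_index": s.site_index,
                }
                for s in self.sites
            ],
            "support": {
                f"{n}:{m}": sorted(reads) for (n, m), reads in sorted(self.support.items())
            },
            "edges": {
                f"{u[0]}:{u[1]}->{v[0]}:{v[1]}": sorted(reads)
                for (u, v), reads in sorted(self.span_support.items())
            },
            "fresh_reads": {
                f"{n}:{m}": sorted(reads)
                for (n, m), reads in sorted(self.fresh_reads.items())
                if reads
            },
        }

    def to_debug_json(self) -> str:
        return json.dumps(self.to_debug_dict(), indent=2)


def build_graph(
    sites: list[CandidateSite], observations: Iterable[ReadObservation]
) -> PhasingGraph:
    """Assemble the phasing graph from candidate sites and read observations.

    Sites must be sorted by position with ``site_index`` equal to their rank.
    A read contributes an edge only between *consecutive* site indices where
    it has observations at both.  Duplicate (read, site) observations are
    rejected.
    """
    sites = list(sites)
    for rank, site in enumerate(sites):
        if site.site_index != rank:
            raise ValueError(
                f"site at {site.contig}:{site.position} has site_index "
                f"{site.site_index}, expected rank {rank}"
            )
        if rank and (
            site.position <= sites[rank - 1].position
            or site.contig != sites[rank - 1].contig
        ):
            raise ValueError(
                f"sites not strictly increasing at {site.contig}:{site.position}"
            )

    graph = PhasingGraph(sites=sites)
    if not sites:
        return graph

    by_read: dict[str, dict[int, ReadObservation]] = {}
    for obs in observations:
        if not 0 <= obs.site_index < len(sites):
            raise ValueError(f"read {obs.read_id}: site_index {obs.site_index} out of range")
        if not 0 <= obs.allele_index < len(sites[obs.site_index].alleles):
            raise ValueError(
                f"read {obs.read_id}: allele_index {obs.allele_index} invalid for "
                f"site {obs.site_index}"
            )
        per_site = by_read.setdefault(obs.read_id, {})
        if obs.site_index in per_site:
            raise ValueError(
                f"read {obs.read_id} has duplicate observations at site {obs.site_index}"
            )
        per_site[obs.site_index] = obs

    support: dict[Vertex, set[str]] = {v: set() for n in range(len(sites)) for v in graph.vertices_at(n)}
    span: dict[tuple[Vertex, Vertex], set[str]] = {}
    fresh: dict[Vertex, set[str]] = {v: set() for v in support}

    for read_id, per_site in by_read.items():
        start = min(per_site)
        for obs in per_site.values():
            if obs.read_start_site is not None:
                start = min(start, obs.read_start_site)
        for n, obs in per_site.items():
            v = (n, obs.allele_index)
            support[v].add(read_id)
            if start > n - 1:
                fresh[v].add(read_id)
        for n in sorted(per_site):
            if n + 1 in per_site:
                u = (n, per_site[n].allele_index)
                w = (n + 1, per_site[n + 1].allele_index)
                span.setdefault((u, w), set()).add(read_id)

    graph.support = {v: frozenset(r) for v, r in support.items()}
    graph.span_support = {e: frozenset(r) for e, r in span.items()}
    graph.fresh_reads = {v: frozenset(r) for v, r in fresh.items()}
    return graph


def subset_sites(
    sites: list[CandidateSite],
    observations: list[ReadObservation],
    keep: set[int],
) -> tuple[list[CandidateSite], list[ReadObservation]]:
    """Restrict to the given site indices, reindexing sites and observations.

    Observations at dropped sites are discarded; explicit read span bounds
    are remapped to the rank the old index would occupy among kept sites, so
    freshness (did the read start after the previous kept site?) is
    preserved.
    """
    kept = sorted(keep)
    rank = {old: new for new, old in enumerate(kept)}
    new_sites = [
        CandidateSite(
            contig=sites[old].contig,
            position=sites[old].position,
            alleles=sites[old].alleles,
            site_index=new,
        )
        for new, old in enumerate(kept)
    ]

    def remap_bound(bound: Optional[int]) -> Optional[int]:
        if bound is None:
            return None
        return bisect_left(kept, bound)

    new_obs = [
        ReadObservation(
            read_id=o.read_id,
            site_index=rank[o.site_index],
            allele_index=o.allele_index,
            read_start_site=remap_bound(o.read_start_site),
            read_end_site=remap_bound(o.read_end_site),
        )
        for o in observations
        if o.site_index in rank
    ]
    return new_sites, new_obs


def cap_site_alleles(
    sites: list[CandidateSite],
    observations: list[ReadObservation],
    max_alleles: int = 4,
) -> tuple[list[CandidateSite], list[ReadObservation]]:
    """Drop excess alleles per site, lowest support first, and reindex.

    The dynamic program is quartic in alleles per site, so sites are capped
    (default: reference + 3 alternates).  Observations of dropped alleles are
    discarded; remaining allele indices are remapped.  The reference allele
    (index 0) is always kept.
    """
    if max_alleles < 2:
        raise ValueError("max_alleles must be at least 2")
    counts: dict[Vertex, int] = {}
    for obs in observations:
        counts[(obs.site_index, obs.allele_index)] = (
            counts.get((obs.site_index, obs.allele_index), 0) + 1
        )

    keep_map: dict[Vertex, int] = {}
    new_sites: list[CandidateSite] = []
    for site in sites:
        n = site.site_index
        if len(site.alleles) <= max_alleles:
            kept = list(range(len(site.alleles)))
        else:
            others = sorted(
                range(1, len(site.alleles)),
                key=lambda m: (-counts.get((n, m), 0), m),
            )
            kept = [0] + sorted(others[: max_alleles - 1])
        for new_m, old_m in enumerate(kept):
            keep_map[(n, old_m)] = new_m
        new_sites.append(
            CandidateSite(
                contig=site.contig,
                position=site.position,
                alleles=tuple(site.alleles[m] for m in kept),
                site_index=n,
            )
        )

    new_obs = [
        ReadObservation(
            read_id=o.read_id,
            site_index=o.site_index,
            allele_index=keep_map[(o.site_index, o.allele_index)],
            read_start_site=o.read_start_site,
            read_end_site=o.read_end_site,
        )
        for o in observations
        if (o.site_index, o.allele_index) in keep_map
    ]
    return new_sites, new_obs
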