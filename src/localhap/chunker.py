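"""Chunked processing: 25 kb intervals phased independently, then merged.

The phasing method is deliberately local: each contig is tiled into 25 kb
chunks, each chunk runs candidate finding, graph construction, the phasing
DP and read tagging on reads overlapping the chunk plus an overlap margin,
and per-chunk taggings are merged into one consistent output.  Phase labels
are arbitrary per chunk, so merging walks chunks left to right and globally
flips a chunk's labels when the majority of reads shared with the
already-merged output disagree; remaining per-read conflicts are untagged.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Union

import pysam

from .allele_graph import CandidateSite
from .candidate_finder import CandidateParams, find_candidates
from .dp_phaser import phase_sites
from .read_tagger import UNTAGGED, HaplotagResult, assign_read_haplotags

DEFAULT_CHUNK_SIZE = 25_000
DEFAULT_OVERLAP_MARGIN = 5_000


@dataclass(frozen=True)
class ChunkSpec:
    """One processing interval: [start, end) plus the shared overlap margin."""

    contig: str
    start: int
    end: int
    overlap_margin: int = DEFAULT_OVERLAP_MARGIN

    @property
    def window(self) -> tuple[int, int]:
        """The interval actually scanned: chunk plus margins, clipped at 0."""
        return max(0, self.start - self.overlap_margin), self.end + self.overlap_margin


def make_chunks(
    contig_lengths: dict[str, int],
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    overlap_margin: int = DEFAULT_OVERLAP_MARGIN,
) -> list[ChunkSpec]:
    """Tile every contig with fixed-size chunks (final chunk may be short)."""
    if chunk_size <= 0:
        raise ValueError("chunk_size must be positive")
    chunks = []
    for contig, length in contig_lengths.items():
        if length <= 0:
            raise ValueError(f"contig {contig} has non-positive length {length}")
        for start in range(0, length, chunk_size):
            chunks.append(
                ChunkSpec(
                    contig=contig,
                    start=start,
                    end=min(start + chunk_size, length),
                    overlap_margin=overlap_margin,
                )
            )
    return chunks


def process_chunk(
    alignments: Union[str, pysam.AlignmentFile],
    reference: Union[str, pysam.FastaFile],
    chunk: ChunkSpec,
    params: Optional[CandidateParams] = None,
    candidate_sites: Optional[list[CandidateSite]] = None,
) -> list[HaplotagResult]:
    """Phase and tag one chunk.

    Reads overlapping the margin-extended window contribute evidence; tags
    are emitted for reads starting before the chunk end and not already owned
    by the next chunk — reads starting inside the preceding margin are
    deliberately emitted by both neighbours so the merge step can reconcile
    labels.
    """
    w_start, w_end = chunk.window
    sites, observations = find_candidates(
        alignments,
        reference,
        chunk.contig,
        w_start,
        w_end,
        params=params,
        sites=candidate_sites,
    )
    graph, assignment, blocks = phase_sites(sites, observations)
    tags = assign_read_haplotags(graph, assignment, blocks)

    own_bam = isinstance(alignments, str)
    bam = pysam.AlignmentFile(alignments) if own_bam else alignments
    try:
        read_start = {}
        for rec in bam.fetch(chunk.contig, w_start, w_end):
            if rec.is_secondary or rec.is_supplementary or rec.is_unmapped:
                continue
            prev = read_start.get(rec.query_name)
            if prev is None or rec.reference_start < prev:
                read_start[rec.query_name] = rec.reference_start
    finally:
        if own_bam:
            bam.close()
    emitted = [
        t
        for t in tags
        if t.read_id in read_start and w_start <= read_start[t.read_id] < chunk.end
    ]
    # reads with no observation at any candidate site: untagged, zero votes
    observed = {t.read_id for t in tags}
    for read_id, start in read_start.items():
        if read_id not in observed and w_start <= start < chunk.end:
            emitted.append(
                HaplotagResult(
                    read_id=read_id,
                    tag=UNTAGGED,
                    phase_set=None,
                    votes_phase1=0,
                    votes_phase2=0,
                    contig=chunk.contig,
                )
            )
    return emitted


def _flipped(tag: HaplotagResult) -> HaplotagResult:
    if tag.tag == UNTAGGED:
        return tag
    return replace(
        tag,
        tag=3 - tag.tag,
        votes_phase1=tag.votes_phase2,
        votes_phase2=tag.votes_phase1,
    )


def merge_chunks(per_chunk_tags: list[list[HaplotagResult]]) -> list[HaplotagResult]:
    """Reconcile per-chunk taggings into one record per read.

    Walking chunks in coordinate order: a chunk is globally flipped when most
    reads shared with the merged output disagree with it; a read tagged in
    several chunks keeps the tag from the chunk with the larger vote total;
    a tag conflict that survives flipping untags the read.
    """
    merged: dict[str, HaplotagResult] = {}
    order: list[str] = []
    for chunk_tags in per_chunk_tags:
        agree = disagree = 0
        for t in chunk_tags:
            prev = merged.get(t.read_id)
            if prev is None or prev.tag == UNTAGGED or t.tag == UNTAGGED:
                continue
            if prev.tag == t.tag:
                agree += 1
            else:
                disagree += 1
        if disagree > agree:
            chunk_tags = [_flipped(t) for t in chunk_tags]

        for t in chunk_tags:
            prev = merged.get(t.read_id)
            if prev is None:
                merged[t.read_id] = t
                order.append(t.read_id)
                continue
            if prev.tag == UNTAGGED and t.tag != UNTAGGED:
                merged[t.read_id] = t
            elif prev.tag != UNTAGGED and t.tag != UNTAGGED:
                if prev.tag != t.tag:
                    merged[t.read_id] = replace(
                        prev, tag=UNTAGGED, phase_set=None, votes_phase1=0, votes_phase2=0
                    )
                elif (t.votes_phase1 + t.votes_phase2) > (
                    prev.votes_phase1 + prev.votes_phase2
                ):
                    merged[t.read_id] = t
            # tagged prev + untagged current: keep prev
    return [merged[r] for r in order]


def run_haplotagging(
    alignments: str,
    reference: str,
    region: Optional[tuple[str, int, int]] = None,
    params: Optional[CandidateParams] = None,
    candidate_sites: Optional[list[CandidateSite]] = None,
    chunk_size: int = DEFAULT_CHUNK_SIZE,
    overlap_margin: int = DEFAULT_OVERLAP_MARGIN,
    merge: bool = True,
) -> list[HaplotagResult]:
    """End-to-end tagging: chunk, phase each chunk, merge.

    With ``merge=False`` per-chunk taggings are concatenated as-is (first
    occurrence of a read wins), keeping each chunk's own phase sets.
    """
    with pysam.AlignmentFile(alignments) as bam:
        lengths = dict(zip(bam.references, bam.lengths))
    if region is not None:
        contig, start, end = region
        if contig not in lengths:
            raise ValueError(f"contig {contig} not present in {alignments}")
        end = min(end, lengths[contig])
        chunks = [
            replace(c, start=max(c.start, start), end=min(c.end, end))
            for c in make_chunks({contig: lengths[contig]}, chunk_size, overlap_margin)
            if c.start < end and c.end > start
        ]
    else:
        chunks = make_chunks(lengths, chunk_size, overlap_margin)

    per_chunk = []
    with pysam.AlignmentFile(alignments) as bam, pysam.FastaFile(reference) as fasta:
        for chunk in chunks:
            per_chunk.append(
                process_chunk(bam, fasta, chunk, params=params, candidate_sites=candidate_sites)
            )
    if merge:
        return merge_chunks(per_chunk)
    seen: set[str] = set()
    out = []
    for chunk_tags in per_chunk:
        for t in chunk_tags:
            if t.read_id not in seen:
                seen.add(t.read_id)
                out.append(t)
    return out
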