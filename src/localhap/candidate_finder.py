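"""Candidate heterozygous-site detection from alignment pileups.

Scans pileup columns of an indexed alignment file and emits sites where a
non-reference allele has enough well-supported reads to suggest
heterozygosity.  Thresholds are deliberately permissive defaults exposed as
configuration: the downstream dynamic program tolerates noisy candidates,
whereas a missed true site costs phasing signal.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pysam

from .allele_graph import CandidateSite, ReadObservation, cap_site_alleles

DELETION_ALLELE = "*"
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}


@dataclass(frozen=True)
class CandidateParams:
    """Filters for candidate emission.

    An alternate allele passes if supported by >= min_alt_count reads with an
    allele fraction inside [min_alt_fraction, 1 - min_alt_fraction]; bases
    below min_base_quality or reads below min_mapping_quality are ignored.
    SNVs only unless include_indels enables length-1 indel candidates.
    """

    min_alt_count: int = 2
    min_alt_fraction: float = 0.12
    min_base_quality: int = 10
    min_mapping_quality: int = 5
    max_alleles: int = 4
    include_indels: bool = False


@dataclass(frozen=True)
class PileupColumn:
    """Qualifying read observations at one position."""

    contig: str
    position: int  # 0-based
    entries: tuple[tuple[str, str, int, int], ...]  # (read_id, allele, baseq, mapq)


def _require_index(bam: pysam.AlignmentFile) -> None:
    try:
        ok = bam.check_index()
    except (ValueError, AttributeError) as exc:
        raise ValueError(f"alignment file {bam.filename.decode()} is not indexed: {exc}") from exc
    if not ok:
        raise ValueError(f"alignment file {bam.filename.decode()} is not indexed")


def prescan_mismatch_positions(
    bam: pysam.AlignmentFile,
    fasta: pysam.FastaFile,
    contig: str,
    start: int,
    end: int,
    params: CandidateParams,
) -> set[int]:
    """Fast vectorized pass flagging positions that could host a candidate.

    Counts, per position and substituted base, the reads whose aligned base
    differs from the reference (after base/mapping-quality filtering) and
    returns positions where any single alternate base reaches min_alt_count.
    The exact per-column filters are re-applied by the pileup pass at these
    positions only, so this is purely a superset prefilter for SNVs.
    """
    length = end - start
    ref = np.frombuffer(fasta.fetch(contig, start, end).upper().encode(), dtype="S1")
    counts = np.zeros((4, length), dtype=np.int32)
    base_codes = np.frombuffer(b"ACGT", dtype="S1")
    for read in bam.fetch(contig, start, end):
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        if read.mapping_quality < params.min_mapping_quality:
            continue
        seq = read.query_sequence
        if seq is None:
            continue
        quals = read.query_qualities
        cig = read.cigartuples
        if cig is not None and len(cig) == 1 and cig[0][0] == 0:
            # ungapped alignment: compare the overlap slice directly
            rs = read.reference_start
            lo, hi = max(rs, start), min(rs + len(seq), end)
            if hi <= lo:
                continue
            qoff = lo - rs
            bases = np.frombuffer(seq.upper().encode(), dtype="S1")[qoff : qoff + hi - lo]
            keep = bases != ref[lo - start : hi - start]
            if quals is not None:
                keep &= np.asarray(quals, dtype=np.int32)[qoff : qoff + hi - lo] >= (
                    params.min_base_quality
                )
            for b in range(4):
                np.add.at(counts[b], (lo - start) + np.flatnonzero(keep & (bases == base_codes[b])), 1)
        else:
            for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                if not start <= rpos < end:
                    continue
                if quals is not None and quals[qpos] < params.min_base_quality:
                    continue
                base = seq[qpos].upper()
                b = _BASE_INDEX.get(base)
                if b is not None and ref[rpos - start] != base.encode():
                    counts[b, rpos - start] += 1
    flagged = np.flatnonzero((counts >= params.min_alt_count).any(axis=0))
    return {start + int(p) for p in flagged}


def iter_pileup_columns(
    bam: pysam.AlignmentFile,
    contig: str,
    start: int,
    end: int,
    params: CandidateParams,
    positions: Optional[set[int]] = None,
) -> "list[PileupColumn]":
    """Collect per-read alleles for covered columns in [start, end).

    With ``positions`` given, only those columns are materialized (the
    others are skipped before any per-read work).
    """
    columns = []
    for col in bam.pileup(
        contig,
        start,
        end,
        truncate=True,
        min_base_quality=params.min_base_quality,
        min_mapping_quality=params.min_mapping_quality,
        ignore_overlaps=False,
        stepper="samtools",
    ):
        if positions is not None and col.reference_pos not in positions:
            continue
        if params.include_indels:
            entries = []
            for pr in col.pileups:
                aln = pr.alignment
                if pr.is_refskip:
                    continue
                if pr.is_del:
                    entries.append((aln.query_name, DELETION_ALLELE, 0, aln.mapping_quality))
                    continue
                qpos = pr.query_position
                base = aln.query_sequence[qpos].upper()
                baseq = aln.query_qualities[qpos] if aln.query_qualities is not None else 0
                allele = base
                if pr.indel == 1:
                    # length-1 insertion immediately after this column, keyed here
                    allele = base + aln.query_sequence[qpos + 1].upper()
                entries.append((aln.query_name, allele, baseq, aln.mapping_quality))
        else:
            # C-level column accessors: avoids decoding whole read sequences
            names = col.get_query_names()
            seqs = col.get_query_sequences(mark_matches=False, mark_ends=False, add_indels=False)
            quals = col.get_query_qualities()
            mapqs = col.get_mapping_qualities()
            entries = [
                (name, base.upper(), baseq, mapq)
                for name, base, baseq, mapq in zip(names, seqs, quals, mapqs)
                if base  # empty string marks a deletion / reference skip
            ]
        if entries:
            columns.append(
                PileupColumn(contig=contig, position=col.reference_pos, entries=tuple(entries))
            )
    return columns


def _passing_alts(
    column: PileupColumn, ref_allele: str, params: CandidateParams
) -> list[str]:
    counts: dict[str, int] = {}
    for _, allele, _, _ in column.entries:
        counts[allele] = counts.get(allele, 0) + 1
    depth = sum(counts.values())
    alts = []
    for allele, count in counts.items():
        if allele == ref_allele:
            continue
        if not params.include_indels and (len(allele) != 1 or allele not in "ACGT"):
            continue
        if count < params.min_alt_count:
            continue
        frac = count / depth
        if not (params.min_alt_fraction <= frac <= 1.0 - params.min_alt_fraction):
            continue
        alts.append(allele)
    return sorted(alts, key=lambda a: (-counts[a], a))


def find_candidates(
    alignments: Union[str, pysam.AlignmentFile],
    reference: Union[str, pysam.FastaFile],
    contig: str,
    start: int,
    end: int,
    params: Optional[CandidateParams] = None,
    sites: Optional[list[CandidateSite]] = None,
) -> tuple[list[CandidateSite], list[ReadObservation]]:
    """Emit candidate heterozygous sites and per-read allele observations.

    With ``sites`` given (e.g. ingested from a VCF), candidate detection is
    bypassed and observations are recomputed from the pileup at exactly those
    positions.  Site indices are assigned by rank within [start, end).
    """
    params = params or CandidateParams()
    own_bam = isinstance(alignments, str)
    bam = pysam.AlignmentFile(alignments) if own_bam else alignments
    own_fa = isinstance(reference, str)
    fasta = pysam.FastaFile(reference) if own_fa else reference
    try:
        _require_index(bam)
        if sites is not None:
            positions = {
                s.position for s in sites if s.contig == contig and start <= s.position < end
            }
        elif params.include_indels:
            positions = None  # indel candidates need the full column scan
        else:
            positions = prescan_mismatch_positions(bam, fasta, contig, start, end, params)
        columns = iter_pileup_columns(bam, contig, start, end, params, positions=positions)
        if sites is None:
            out_sites: list[CandidateSite] = []
            kept_columns = []
            for col in columns:
                ref_allele = fasta.fetch(contig, col.position, col.position + 1).upper()
                alts = _passing_alts(col, ref_allele, params)
                if not alts:
                    continue
                out_sites.append(
                    CandidateSite(
                        contig=contig,
                        position=col.position,
                        alleles=(ref_allele, *alts),
                        site_index=len(out_sites),
                    )
                )
                kept_columns.append(col)
        else:
            wanted = {
                s.position: s
                for s in sorted(sites, key=lambda s: s.position)
                if s.contig == contig and start <= s.position < end
            }
            out_sites = [
                CandidateSite(
                    contig=s.contig, position=s.position, alleles=s.alleles, site_index=i
                )
                for i, s in enumerate(wanted.values())
            ]
            kept_columns = [c for c in columns if c.position in wanted]

        allele_index = {
            (s.position, a): (s.site_index, m)
            for s in out_sites
            for m, a in enumerate(s.alleles)
        }
        observations: list[ReadObservation] = []
        seen: set[tuple[str, int]] = set()
        for col in kept_columns:
            for read_id, allele, _, _ in col.entries:
                key = allele_index.get((col.position, allele))
                if key is None or (read_id, key[0]) in seen:
                    continue
                seen.add((read_id, key[0]))
                observations.append(
                    ReadObservation(read_id=read_id, site_index=key[0], allele_index=key[1])
                )
        return cap_site_alleles(out_sites, observations, params.max_alleles)
    finally:
        if own_bam:
            bam.close()
        if own_fa:
            fasta.close()
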