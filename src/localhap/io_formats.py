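"""Standard-format I/O: tagged BAM (HP/PS), candidate VCF, tag TSV tables.

Haplotags follow the de-facto convention of haplotagging tools: ``HP`` is 1
or 2 and absent for untagged reads; ``PS`` is the 1-based phase-block anchor
position, written iff ``HP`` is.  Stale HP/PS on input records are stripped
before re-tagging, and secondary/supplementary alignments inherit the
primary's tag (tags are keyed by read name).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Optional, Union

import pandas as pd
import pysam

from .allele_graph import CandidateSite
from .read_tagger import UNTAGGED, HaplotagResult

logger = logging.getLogger(__name__)

TSV_COLUMNS = ["read_id", "contig", "tag", "phase_set", "votes_phase1", "votes_phase2"]


def write_tagged_bam(
    input_alignments: Union[str, Path],
    tags: Iterable[HaplotagResult],
    output_path: Union[str, Path],
) -> None:
    """Copy alignments with HP/PS set per the tag list; sort order preserved.

    Records keep every field except HP/PS.  A tag whose read is absent from
    the input is logged and skipped.
    """
    tag_map = {t.read_id: t for t in tags}
    seen: set[str] = set()
    output_path = str(output_path)
    with pysam.AlignmentFile(str(input_alignments)) as bam_in:
        with pysam.AlignmentFile(output_path, "wb", template=bam_in) as bam_out:
            for rec in bam_in.fetch(until_eof=True):
                for tag_name in ("HP", "PS"):
                    if rec.has_tag(tag_name):
                        rec.set_tag(tag_name, None)
                t = tag_map.get(rec.query_name)
                if t is not None:
                    seen.add(rec.query_name)
                    if t.tag != UNTAGGED:
                        rec.set_tag("HP", t.tag, value_type="i")
                        rec.set_tag("PS", t.phase_set, value_type="i")
                bam_out.write(rec)
    for read_id in set(tag_map) - seen:
        logger.warning("tag for read %s skipped: read absent from input", read_id)
    pysam.index(output_path)


def read_tagged_bam(path: Union[str, Path]) -> dict[str, tuple[int, Optional[int]]]:
    """read_id -> (HP, PS) from primary records; untagged reads map to (0, None)."""
    out: dict[str, tuple[int, Optional[int]]] = {}
    with pysam.AlignmentFile(str(path)) as bam:
        for rec in bam.fetch(until_eof=True):
            if rec.is_secondary or rec.is_supplementary:
                continue
            if rec.has_tag("HP"):
                out[rec.query_name] = (
                    rec.get_tag("HP"),
                    rec.get_tag("PS") if rec.has_tag("PS") else None,
                )
            else:
                out[rec.query_name] = (UNTAGGED, None)
    return out


def write_tags_tsv(tags: Iterable[HaplotagResult], path: Union[str, Path]) -> None:
    rows = [
        {
            "read_id": t.read_id,
            "contig": t.contig if t.contig is not None else ".",
            "tag": t.tag,
            "phase_set": t.phase_set if t.phase_set is not None else ".",
            "votes_phase1": t.votes_phase1,
            "votes_phase2": t.votes_phase2,
        }
        for t in tags
    ]
    pd.DataFrame(rows, columns=TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tags_tsv(path: Union[str, Path]) -> list[HaplotagResult]:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "contig": str})
    out = []
    for row in df.itertuples(index=False):
        ps = None if str(row.phase_set) in (".", "nan") else int(float(row.phase_set))
        out.append(
            HaplotagResult(
                read_id=str(row.read_id),
                tag=int(row.tag),
                phase_set=ps,
                votes_phase1=int(row.votes_phase1),
                votes_phase2=int(row.votes_phase2),
                contig=None if str(row.contig) == "." else str(row.contig),
            )
        )
    return out


def read_candidates_vcf(path: Union[str, Path]) -> list[CandidateSite]:
    """Candidate sites from a VCF; multi-allelic records keep all alternates.

    VCF POS is 1-based; returned positions are 0-based.  site_index is the
    record rank (re-ranked per interval when the sites are used).
    """
    sites: list[CandidateSite] = []
    record_no = 0
    try:
        with pysam.VariantFile(str(path)) as vcf:
            for rec in vcf.fetch() if vcf.index is not None else vcf:
                record_no += 1
                alts = tuple(a for a in (rec.alts or ()) if a is not None)
                sites.append(
                    CandidateSite(
                        contig=rec.contig,
                        position=rec.start,
                        alleles=(rec.ref, *alts),
                        site_index=len(sites),
                    )
                )
    except (ValueError, OSError) as exc:
        raise ValueError(
            f"malformed VCF {path} at record {record_no + 1}: {exc}"
        ) from exc
    return sites


def write_candidates_vcf(
    sites: list[CandidateSite],
    path: Union[str, Path],
    contig_lengths: Optional[dict[str, int]] = None,
    support_counts: Optional[dict[tuple[int, int], int]] = None,
) -> None:
    """Dump candidate sites as a minimal VCF (INFO/SUP carries allele support)."""
    header = pysam.VariantHeader()
    header.add_meta("source", "localhap-candidates")
    header.add_line(
        '##INFO=<ID=SUP,Number=R,Type=Integer,Description="Supporting read count per allele">'
    )
    contigs = contig_lengths or {}
    for site in sites:
        if site.contig not in contigs:
            contigs[site.contig] = site.position + 1_000_000
    for name, length in contigs.items():
        header.contigs.add(name, length=length)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for site in sites:
            rec = vcf.new_record(
                contig=site.contig,
                start=site.position,
                stop=site.position + len(site.alleles[0]),
                alleles=site.alleles,
            )
            if support_counts is not None:
                rec.info["SUP"] = tuple(
                    support_counts.get((site.site_index, m), 0)
                    for m in range(len(site.alleles))
                )
            vcf.write(rec)
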