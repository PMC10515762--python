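"""Diploid long-read simulator with known per-read haplotype truth.

Generates a random reference, plants heterozygous SNVs at a configurable
density, and draws reads from the two haplotypes with lognormal lengths and
i.i.d. substitution errors.  Defaults emulate a HiFi-like library (~18 kb
reads, 0.2% error); an ONT-like preset (30 kb, 3% error) is provided for
stress tests.  Errors are substitution-only: indel errors would entangle
candidate finding with alignment conventions, and SNV phasing is what the
downstream dynamic program consumes.

The same per-read sequences back two output modes — an aligned BAM (reads
placed at their known positions, no aligner involved) and a direct
observation table feeding the allele graph — so both modes are guaranteed to
agree for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pysam

from .allele_graph import CandidateSite, ReadObservation

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters.

    het_snv_rate is per bp (default 1/kb, a typical human heterozygosity
    scale); coverage is mean depth; read lengths are lognormal with the given
    linear-scale mean and log-scale sd; per_base_error is the substitution
    rate (0.002 HiFi-like, 0.03 ONT-like).
    """

    seed: int = 0
    genome_length: int = 50_000
    het_snv_rate: float = 0.001
    coverage: float = 30.0
    read_length_mean: float = 18_000.0
    read_length_sd: float = 0.3
    per_base_error: float = 0.002
    contig: str = "sim1"

    def __post_init__(self) -> None:
        for name in ("het_snv_rate", "per_base_error"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.genome_length <= 0 or self.read_length_mean <= 0 or self.coverage <= 0:
            raise ValueError("lengths and coverage must be positive")

    def ont_like(self) -> "SimConfig":
        """This configuration with ONT-like error rate and read length."""
        return replace(self, per_base_error=0.03, read_length_mean=30_000.0)


@dataclass(frozen=True)
class HetSite:
    position: int  # 0-based
    ref_allele: str  # reference (and one haplotype's) base
    alt_allele: str
    alt_haplotype: int  # 1 or 2: which haplotype carries the alternate


@dataclass(frozen=True)
class SimRead:
    read_id: str
    haplotype: int  # truth: 1 or 2
    start: int  # 0-based reference start
    sequence: str  # with errors applied

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Simulation:
    """A simulated diploid sample: reference, het sites, reads, truth."""

    config: SimConfig
    reference: str
    het_sites: list[HetSite]
    reads: list[SimRead]

    def haplotype_sequence(self, hap: int) -> str:
        seq = np.frombuffer(self.reference.encode(), dtype="S1").copy()
        for site in self.het_sites:
            if site.alt_haplotype == hap:
                seq[site.position] = site.alt_allele.encode()
        return seq.tobytes().decode()

    def truth_tags(self) -> dict[str, int]:
        return {r.read_id: r.haplotype for r in self.reads}

    def base_quality(self) -> int:
        e = max(self.config.per_base_error, 1e-6)
        return min(60, int(round(-10 * np.log10(e))))

    # ------------------------------------------------------------------ #
    # observation-table mode

    def observations(self) -> tuple[list[CandidateSite], list[ReadObservation]]:
        """Read observations at the truth het sites, bypassing alignment.

        Site alleles are (reference base, alternate); a read base matching
        neither (a substitution error to a third base) yields no observation.
        """
        sites = [
            CandidateSite(
                contig=self.config.contig,
                position=s.position,
                alleles=(s.ref_allele, s.alt_allele),
                site_index=i,
            )
            for i, s in enumerate(self.het_sites)
        ]
        positions = np.array([s.position for s in self.het_sites], dtype=int)
        obs: list[ReadObservation] = []
        for read in self.reads:
            lo = int(np.searchsorted(positions, read.start, side="left"))
            hi = int(np.searchsorted(positions, read.start + read.length, side="left"))
            for idx in range(lo, hi):
                base = read.sequence[positions[idx] - read.start]
                site = self.het_sites[idx]
                if base == site.ref_allele:
                    allele = 0
                elif base == site.alt_allele:
                    allele = 1
                else:
                    continue
                obs.append(
                    ReadObservation(
                        read_id=read.read_id,
                        site_index=idx,
                        allele_index=allele,
                        read_start_site=lo,
                        read_end_site=hi - 1,
                    )
                )
        return sites, obs

    # ------------------------------------------------------------------ #
    # file outputs

    def write_fasta(self, path: str | Path) -> None:
        path = str(path)
        with open(path, "w") as fh:
            fh.write(f">{self.config.contig}\n")
            for i in range(0, len(self.reference), 80):
                fh.write(self.reference[i : i + 80] + "\n")
        pysam.faidx(path)

    def write_bam(self, path: str | Path) -> None:
        """Coordinate-sorted, indexed BAM with reads at their true positions."""
        path = str(path)
        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.config.contig, "LN": len(self.reference)}],
        }
        qual = self.base_quality()
        with pysam.AlignmentFile(path, "wb", header=header) as bam:
            for read in sorted(self.reads, key=lambda r: (r.start, r.read_id)):
                a = pysam.AlignedSegment(bam.header)
                a.query_name = read.read_id
                a.query_sequence = read.sequence
                a.flag = 0
                a.reference_id = 0
                a.reference_start = read.start
                a.mapping_quality = 60
                a.cigarstring = f"{read.length}M"
                a.query_qualities = pysam.qualitystring_to_array(
                    chr(qual + 33) * read.length
                )
                bam.write(a)
        pysam.index(path)

    def write_truth_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("read_id\thaplotype\tstart\tlength\n")
            for r in self.reads:
                fh.write(f"{r.read_id}\t{r.haplotype}\t{r.start}\t{r.length}\n")


def simulate(config: SimConfig) -> Simulation:
    """Generate a diploid sample; deterministic for a given config."""
    rng = np.random.default_rng(config.seed)
    L = config.genome_length

    ref = _BASES[rng.integers(0, 4, size=L)]

    het_mask = rng.random(L) < config.het_snv_rate
    het_positions = np.flatnonzero(het_mask)
    het_sites = []
    for pos in het_positions:
        ref_base = ref[pos].decode()
        alt_base = "ACGT".replace(ref_base, "")[rng.integers(0, 3)]
        het_sites.append(
            HetSite(
                position=int(pos),
                ref_allele=ref_base,
                alt_allele=alt_base,
                alt_haplotype=int(rng.integers(1, 3)),
            )
        )

    haps = {
        1: ref.copy(),
        2: ref.copy(),
    }
    for site in het_sites:
        haps[site.alt_haplotype][site.position] = site.alt_allele.encode()

    n_reads = max(1, int(round(config.coverage * L / config.read_length_mean)))
    pad = len(str(n_reads))
    reads = []
    for r in range(n_reads):
        length = int(round(rng.lognormal(np.log(config.read_length_mean), config.read_length_sd)))
        length = max(200, min(length, L))
        start = int(rng.integers(0, L - length + 1))
        hap = int(rng.integers(1, 3))
        seq = haps[hap][start : start + length].copy()
        err = rng.random(length) < config.per_base_error
        for pos in np.flatnonzero(err):
            cur = seq[pos].decode()
            seq[pos] = "ACGT".replace(cur, "")[rng.integers(0, 3)].encode()
        reads.append(
            SimRead(
                read_id=f"read{r + 1:0{pad}d}",
                haplotype=hap,
                start=start,
                sequence=seq.tobytes().decode(),
            )
        )

    return Simulation(
        config=config,
        reference=ref.tobytes().decode(),
        het_sites=het_sites,
        reads=reads,
    )


def write_fixture(
    config: SimConfig, out_dir: str | Path, prefix: str = "sim"
) -> dict[str, Path]:
    """Simulate and write FASTA + BAM + truth TSV under ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sim = simulate(config)
    paths = {
        "fasta": out_dir / f"{prefix}.fa",
        "bam": out_dir / f"{prefix}.bam",
        "truth": out_dir / f"{prefix}.truth.tsv",
    }
    sim.write_fasta(paths["fasta"])
    sim.write_bam(paths["bam"])
    sim.write_truth_tsv(paths["truth"])
    return paths
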