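"""Shared fixtures: the canonical two-site example, random graph instances,
and end-to-end simulated datasets."""

from __future__ import annotations

import random

import pysam
import pytest

from localhap import (
    CandidateSite,
    PhasingGraph,
    ReadObservation,
    SimConfig,
    build_graph,
    run_haplotagging,
    simulate,
)

# --------------------------------------------------------------------------- #
# canonical two-site example: 11 reads over two het sites with a clean
# 5-vs-6 split at site 1 and a 4-vs-7 split at site 2


def two_site_example() -> tuple[list[CandidateSite], list[ReadObservation]]:
    sites = [
        CandidateSite("chr1", 100, ("A", "C"), 0),
        CandidateSite("chr1", 200, ("G", "T"), 1),
    ]
    obs = []
    for r in range(1, 6):
        obs.append(ReadObservation(f"read{r}", 0, 0))
    for r in range(6, 12):
        obs.append(ReadObservation(f"read{r}", 0, 1))
    for r in (1, 2, 3, 6):
        obs.append(ReadObservation(f"read{r}", 1, 0))
    for r in (4, 5, 7, 8, 9, 10, 11):
        obs.append(ReadObservation(f"read{r}", 1, 1))
    return sites, obs


@pytest.fixture
def we_sites_obs():
    return two_site_example()


@pytest.fixture
def we_graph(we_sites_obs) -> PhasingGraph:
    return build_graph(*we_sites_obs)


# --------------------------------------------------------------------------- #
# random small phasing instances for oracle / property tests


def random_instance(
    rng: random.Random,
    max_sites: int = 6,
    max_alleles: int = 3,
    max_reads: int = 20,
    gap_prob: float = 0.15,
) -> PhasingGraph:
    n_sites = rng.randint(1, max_sites)
    alleles = [rng.randint(1, max_alleles) for _ in range(n_sites)]
    sites = [
        CandidateSite("c", 10 * (i + 1), tuple("ACGT"[: alleles[i]]), i)
        for i in range(n_sites)
    ]
    obs = []
    for r in range(rng.randint(1, max_reads)):
        first = rng.randrange(n_sites)
        last = min(n_sites - 1, first + rng.randint(0, 3))
        for s in range(first, last + 1):
            if rng.random() >= gap_prob:
                obs.append(ReadObservation(f"r{r}", s, rng.randrange(alleles[s])))
    return build_graph(sites, obs)


# --------------------------------------------------------------------------- #
# simulated datasets (written once per session)


def _write_sim(tmp_path_factory, config: SimConfig, name: str):
    sim = simulate(config)
    d = tmp_path_factory.mktemp(name)
    fasta, bam = d / f"{name}.fa", d / f"{name}.bam"
    sim.write_fasta(fasta)
    sim.write_bam(bam)
    return sim, str(fasta), str(bam)


HIFI_CONFIG = SimConfig(seed=11, genome_length=200_000, coverage=30, per_base_error=0.002)


@pytest.fixture(scope="session")
def hifi_dataset(tmp_path_factory):
    """HiFi-like 200 kb diploid sample: (Simulation, fasta path, bam path)."""
    return _write_sim(tmp_path_factory, HIFI_CONFIG, "hifi")


@pytest.fixture(scope="session")
def ont_dataset(tmp_path_factory):
    """ONT-like (3% error, 30 kb reads) version of the same sample."""
    return _write_sim(tmp_path_factory, HIFI_CONFIG.ont_like(), "ont")


@pytest.fixture(scope="session")
def hifi_tags(hifi_dataset):
    sim, fasta, bam = hifi_dataset
    return run_haplotagging(bam, fasta)


# --------------------------------------------------------------------------- #
# tiny hand-built alignment files


def make_bam(path, reads, reference, contig="ctg1", mapq=60, baseq=30):
    """Write a coordinate-sorted, indexed BAM of ungapped reads.

    ``reads`` is a list of (name, start, sequence[, tags]) tuples.
    """
    header = {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": contig, "LN": len(reference)}]}
    with pysam.AlignmentFile(str(path), "wb", header=header) as bam:
        for entry in sorted(reads, key=lambda e: (e[1], e[0])):
            name, start, seq = entry[:3]
            a = pysam.AlignedSegment(bam.header)
            a.query_name = name
            a.query_sequence = seq
            a.flag = 0
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = mapq
            a.cigarstring = f"{len(seq)}M"
            a.query_qualities = pysam.qualitystring_to_array(chr(baseq + 33) * len(seq))
            if len(entry) > 3:
                for tag_name, value in entry[3].items():
                    a.set_tag(tag_name, value)
            bam.write(a)
    pysam.index(str(path))
    return str(path)


def make_fasta(path, reference, contig="ctg1"):
    with open(path, "w") as fh:
        fh.write(f">{contig}\n{reference}\n")
    pysam.faidx(str(path))
    return str(path)
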