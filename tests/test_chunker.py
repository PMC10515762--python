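"""Chunk tiling, per-chunk processing, and label-flip merging."""

from dataclasses import replace

import pytest

from localhap import (
    HaplotagResult,
    SimConfig,
    haplotag_accuracy,
    make_chunks,
    merge_chunks,
    process_chunk,
    run_haplotagging,
    simulate,
)
from localhap.chunker import ChunkSpec


def _tag(read_id, tag, ps=1, v1=None, v2=None):
    if tag == 0:
        return HaplotagResult(read_id, 0, None, 0, 0)
    v1 = v1 if v1 is not None else (3 if tag == 1 else 0)
    v2 = v2 if v2 is not None else (3 if tag == 2 else 0)
    return HaplotagResult(read_id, tag, ps, v1, v2)


class TestMakeChunks:
    def test_tiling_with_remainder(self):
        chunks = make_chunks({"c": 60_000}, chunk_size=25_000)
        assert [(c.start, c.end) for c in chunks] == [
            (0, 25_000),
            (25_000, 50_000),
            (50_000, 60_000),
        ]

    def test_exact_single_chunk(self):
        chunks = make_chunks({"c": 25_000})
        assert [(c.start, c.end) for c in chunks] == [(0, 25_000)]

    def test_short_contig_single_chunk(self):
        chunks = make_chunks({"c": 100})
        assert [(c.start, c.end) for c in chunks] == [(0, 100)]

    def test_window_includes_margin(self):
        c = ChunkSpec("c", 25_000, 50_000, overlap_margin=5_000)
        assert c.window == (20_000, 55_000)
        assert ChunkSpec("c", 0, 25_000).window == (0, 30_000)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_chunks({"c": 0})
        with pytest.raises(ValueError):
            make_chunks({"c": 100}, chunk_size=0)


class TestMergeChunks:
    def test_inverted_chunk_is_flipped_to_agree(self):
        shared = [f"s{i}" for i in range(10)]
        first = [_tag(r, 1 + i % 2, ps=1) for i, r in enumerate(shared)]
        second = [_tag(r, 2 - i % 2, ps=2) for i, r in enumerate(shared)]  # all inverted
        second += [_tag("new1", 1, ps=2), _tag("new2", 2, ps=2)]
        merged = {t.read_id: t for t in merge_chunks([first, second])}
        for i, r in enumerate(shared):
            assert merged[r].tag == 1 + i % 2
        # the unshared reads were flipped along with their chunk
        assert merged["new1"].tag == 2 and merged["new2"].tag == 1

    def test_disjoint_chunks_concatenate_with_own_phase_sets(self):
        first = [_tag("a", 1, ps=1), _tag("b", 2, ps=1)]
        second = [_tag("c", 1, ps=30_001), _tag("d", 2, ps=30_001)]
        merged = merge_chunks([first, second])
        assert [t.read_id for t in merged] == ["a", "b", "c", "d"]
        assert {t.phase_set for t in merged} == {1, 30_001}

    def test_merge_is_idempotent(self):
        chunk1 = [_tag("a", 1), _tag("b", 2), _tag("c", 0)]
        chunk2 = [_tag("b", 2, ps=7), _tag("d", 1, ps=7)]
        merged = merge_chunks([chunk1, chunk2])
        assert merge_chunks([merged, merged]) == merged

    def test_global_swap_of_all_chunks_preserves_partition(self):
        chunk1 = [_tag("a", 1), _tag("b", 2), _tag("s", 1)]
        chunk2 = [_tag("s", 1, ps=9), _tag("c", 2, ps=9)]
        merged = {t.read_id: t.tag for t in merge_chunks([chunk1, chunk2])}

        def swap(tags):
            return [
                replace(t, tag=3 - t.tag, votes_phase1=t.votes_phase2, votes_phase2=t.votes_phase1)
                if t.tag
                else t
                for t in tags
            ]

        swapped = {t.read_id: t.tag for t in merge_chunks([swap(chunk1), swap(chunk2)])}
        assert swapped == {r: (3 - t if t else 0) for r, t in merged.items()}

    def test_conflicting_tag_after_flip_untags_the_read(self):
        # shared reads mostly agree (no flip), but one read conflicts
        first = [_tag("a", 1), _tag("b", 2), _tag("x", 1)]
        second = [_tag("a", 1, ps=5), _tag("b", 2, ps=5), _tag("x", 2, ps=5)]
        merged = {t.read_id: t for t in merge_chunks([first, second])}
        assert merged["x"].tag == 0 and merged["x"].phase_set is None

    def test_read_keeps_tag_from_chunk_with_more_votes(self):
        first = [_tag("a", 1), _tag("s", 1, v1=2, v2=0)]
        second = [_tag("a", 1, ps=5), _tag("s", 1, ps=5, v1=8, v2=1)]
        merged = {t.read_id: t for t in merge_chunks([first, second])}
        assert merged["s"].votes_phase1 == 8 and merged["s"].phase_set == 5


class TestEndToEnd:
    @pytest.fixture(scope="class")
    @staticmethod
    def small_sim(tmp_path_factory):
        cfg = SimConfig(seed=9, genome_length=75_000, coverage=30, per_base_error=0.002)
        sim = simulate(cfg)
        d = tmp_path_factory.mktemp("chunk75")
        fasta, bam = d / "s.fa", d / "s.bam"
        sim.write_fasta(fasta)
        sim.write_bam(bam)
        return sim, str(fasta), str(bam)

    def test_merged_accuracy_not_below_per_chunk(self, small_sim):
        """Merging three 25 kb chunks loses at most 1% haplotag accuracy."""
        import pysam

        sim, fasta, bam = small_sim
        truth = sim.truth_tags()
        chunks = make_chunks({"sim1": sim.config.genome_length})
        assert len(chunks) == 3
        with pysam.AlignmentFile(bam) as b, pysam.FastaFile(fasta) as f:
            per = [process_chunk(b, f, c) for c in chunks]
        per_acc = [
            haplotag_accuracy(p, truth).accuracy for p in per if haplotag_accuracy(p, truth).n_compared
        ]
        merged_acc = haplotag_accuracy(merge_chunks(per), truth).accuracy
        assert merged_acc >= min(per_acc) - 1.0

    def test_chunks_emit_each_read_once_after_merge(self, small_sim):
        sim, fasta, bam = small_sim
        tags = run_haplotagging(bam, fasta)
        ids = [t.read_id for t in tags]
        assert len(ids) == len(set(ids))
        assert set(ids) == {r.read_id for r in sim.reads}

    def test_no_merge_keeps_per_chunk_phase_sets(self, small_sim):
        sim, fasta, bam = small_sim
        merged = run_haplotagging(bam, fasta, merge=True)
        unmerged = run_haplotagging(bam, fasta, merge=False)
        assert len(unmerged) == len(merged)

    def test_region_restriction(self, small_sim):
        sim, fasta, bam = small_sim
        tags = run_haplotagging(bam, fasta, region=("sim1", 0, 25_000))
        assert 0 < len(tags) < len(sim.reads)
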