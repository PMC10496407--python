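"""Cluster assembly, anchor extension, and the iterative driver."""

import numpy as np
import pytest

import edlib
from sdweaver import (AnchorState, AssemblyFailure, Sequence, Status,
                      assemble_cluster, build_index, extend_anchor, run,
                      run_bidirectional, truncate_reads)
from sdweaver.assembly import TruncatedRead, history_tsv
from sdweaver.clustering import PileupRead
from sdweaver.seqcore import hpc_compress
from sdweaver.simulator import random_bases


def pileup_read(read: Sequence, span: tuple[int, int]) -> PileupRead:
    return PileupRead(read=read, hpc=hpc_compress(read), raw_span=span,
                      identity=1.0)


def tiling_reads(region: str, read_len: int = 3000, step: int = 1000,
                 prefix: str = "t") -> list[Sequence]:
    return [Sequence(f"{prefix}{i}", region[s:s + read_len])
            for i, s in enumerate(range(0, len(region) - read_len + 1, step))]


class TestTruncate:
    def test_read_inside_anchor_unchanged(self):
        read = Sequence("r", "ACGT" * 100)
        out = truncate_reads([pileup_read(read, (0, 400))], flank=500)
        assert out[0].seq.bases == read.bases
        assert out[0].anchor_span == (0, 400)

    def test_flank_clipping_arithmetic(self):
        read = Sequence("r", random_bases(np.random.default_rng(0), 15000))
        # anchor occupies [1000, 3000); read extends 12 kb past it
        out = truncate_reads([pileup_read(read, (1000, 3000))], flank=9000)
        assert out[0].seq.bases == read.bases[0:12000]
        assert out[0].anchor_span == (1000, 3000)

    def test_zero_flank_ends_at_alignment(self):
        read = Sequence("r", random_bases(np.random.default_rng(1), 5000))
        out = truncate_reads([pileup_read(read, (1200, 3400))], flank=0)
        assert out[0].seq.bases == read.bases[1200:3400]


class TestAssembleCluster:
    def test_error_free_tiling_lossless(self):
        region = random_bases(np.random.default_rng(2), 12000)
        anchor = Sequence("a", region[4000:6000])
        reads = []
        for i, s in enumerate(range(0, 9001, 500)):
            seq = Sequence(f"r{i}", region[s:s + 3000])
            if s <= 4000 and s + 3000 >= 6000:
                reads.append(TruncatedRead(seq, (4000 - s, 6000 - s)))
        contig = assemble_cluster(reads, anchor, min_reads=2)
        assert contig.bases in region

    def test_min_reads_enforced(self):
        reads = [TruncatedRead(Sequence("r", "ACGT" * 300), (0, 100))] * 3
        with pytest.raises(AssemblyFailure):
            assemble_cluster(reads, Sequence("a", "ACGT" * 25), min_reads=5)


class TestExtendAnchor:
    def _state(self, anchor_bases):
        anchor = Sequence("a0", anchor_bases)
        return AnchorState(anchor=anchor, assembled=anchor_bases)

    def test_novel_suffix_appended(self):
        rng = np.random.default_rng(3)
        anchor_bases = random_bases(rng, 2000)
        suffix = random_bases(rng, 800)
        contig = Sequence("c", anchor_bases + suffix)
        state, out = extend_anchor(self._state(anchor_bases), contig,
                                   step_cap=10000, anchor_len=2000)
        assert out.status is Status.EXTENDED
        assert out.extension_bp == 800
        assert state.assembled == anchor_bases + suffix
        assert state.anchor.bases == (anchor_bases + suffix)[-2000:]

    def test_contig_equals_anchor_no_extension(self):
        anchor_bases = random_bases(np.random.default_rng(4), 1500)
        _, out = extend_anchor(self._state(anchor_bases),
                               Sequence("c", anchor_bases), 1000, 1500)
        assert out.status is Status.NO_EXTENSION

    def test_step_cap_limits_extension(self):
        rng = np.random.default_rng(5)
        anchor_bases = random_bases(rng, 1000)
        contig = Sequence("c", anchor_bases + random_bases(rng, 25000))
        _, out = extend_anchor(self._state(anchor_bases), contig, 10000, 1000)
        assert out.extension_bp == 10000

    def test_unrelated_contig_lost_track(self):
        rng = np.random.default_rng(6)
        state = self._state(random_bases(rng, 1000))
        _, out = extend_anchor(state, Sequence("c", random_bases(rng, 3000)),
                               1000, 1000)
        assert out.status is Status.LOST_TRACK


class TestDriver:
    def test_single_copy_error_free_reconstructs(self):
        """With no duplication and no errors the driver acts as a plain
        targeted assembler and reproduces the region exactly."""
        region = random_bases(np.random.default_rng(7), 22000)
        reads = tiling_reads(region, read_len=3000, step=150)
        index = build_index(reads)
        anchor = Sequence("anchor", region[2000:3500])
        res = run(anchor, index, seed=1, coverage=20, read_mean=3000,
                  min_reads=3, target_extension=12000)
        assert res.status in (Status.TARGET_REACHED, Status.NO_EXTENSION,
                              Status.NO_READS)
        assembled = res.contig.bases
        assert len(assembled) >= 10000
        d = edlib.align(assembled, region[2000:2000 + len(assembled) + 50],
                        mode="SHW")["editDistance"]
        assert d == 0

    def test_extension_monotone_and_capped(self):
        region = random_bases(np.random.default_rng(8), 15000)
        reads = tiling_reads(region, read_len=3000, step=200)
        index = build_index(reads)
        res = run(Sequence("a", region[0:1500]), index, seed=2, coverage=15,
                  read_mean=3000, step_cap=700, min_reads=3,
                  target_extension=6000)
        lens = [h["assembled_bp"] for h in res.history]
        assert all(b >= a for a, b in zip(lens, lens[1:]))
        assert all(h["extension_bp"] <= 700 for h in res.history)

    def test_deterministic(self):
        region = random_bases(np.random.default_rng(9), 12000)
        reads = tiling_reads(region, read_len=3000, step=300)
        index = build_index(reads)
        a = run(Sequence("a", region[:1500]), index, seed=5, coverage=10,
                read_mean=3000, min_reads=3, target_extension=5000)
        b = run(Sequence("a", region[:1500]), index, seed=5, coverage=10,
                read_mean=3000, min_reads=3, target_extension=5000)
        assert a.contig.bases == b.contig.bases

    def test_anchor_outside_reads_terminates(self):
        rng = np.random.default_rng(10)
        region = random_bases(rng, 10000)
        reads = tiling_reads(region, read_len=3000, step=500)
        index = build_index(reads)
        with pytest.raises(RuntimeError):
            run(Sequence("a", random_bases(rng, 1500)), index, seed=1,
                coverage=10, read_mean=3000)

    def test_bidirectional_stitches(self):
        region = random_bases(np.random.default_rng(11), 20000)
        reads = tiling_reads(region, read_len=3000, step=200)
        index = build_index(reads)
        anchor = Sequence("mid", region[9000:10500])
        res = run_bidirectional(anchor, index, seed=3, coverage=15,
                                read_mean=3000, min_reads=3,
                                target_extension=4000)
        assert len(res.contig) >= 1500 + 6000
        d = edlib.align(res.contig.bases, region, mode="HW")["editDistance"]
        assert d == 0

    def test_history_tsv_shape(self):
        region = random_bases(np.random.default_rng(12), 10000)
        reads = tiling_reads(region, read_len=3000, step=400)
        index = build_index(reads)
        res = run(Sequence("a", region[1000:2500]), index, seed=4, coverage=10,
                  read_mean=3000, min_reads=3, target_extension=3000)
        tsv = history_tsv(res.history)
        lines = tsv.strip().split("\n")
        assert lines[0].startswith("iteration\t")
        assert len(lines) == len(res.history) + 1
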