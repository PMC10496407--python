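"""Cis-morphism calling, similarity graph, randomized recursive
clustering, and cluster selection."""

import numpy as np
import pytest

from sdweaver import (CannotCluster, LostTrack, Sequence, build_pileup,
                      call_cismorphisms, genotype_matrix, hpc_compress,
                      random_partition, select_cluster, similarity_graph)
from sdweaver.clustering import Clustering, Pileup, anchor_genotype
from sdweaver.simulator import random_bases


def make_pileup(rows: list[str], anchor: str | None = None) -> Pileup:
    """Pileup directly from aligned row strings ('.' = missing)."""
    code = {"A": 0, "C": 1, "G": 2, "T": 3, ".": -1}
    matrix = np.array([[code[c] for c in row] for row in rows], dtype=np.int8)
    ids = [f"r{i}" for i in range(len(rows))]
    return Pileup(anchor_hpc=Sequence("a", anchor or "A" * len(rows[0])),
                  read_ids=ids, matrix=matrix, reads={})


@pytest.fixture(scope="module")
def two_unit_pileup():
    """Error-free reads from two SD copies differing at 5 substitution
    sites, piled on an anchor taken from the first copy."""
    rng = np.random.default_rng(77)
    unit1 = random_bases(rng, 1500)
    # substitutions chosen so homopolymer structure is preserved: the
    # position and both neighbours are pairwise distinct, and the new
    # base differs from all three
    u2 = list(unit1)
    planted = 0
    p = 100
    while planted < 5 and p < 1400:
        trip = {unit1[p - 1], unit1[p], unit1[p + 1]}
        if len(trip) == 3:
            u2[p] = next(b for b in "ACGT" if b not in trip)
            planted += 1
            p += 300
        else:
            p += 1
    assert planted == 5
    unit2 = "".join(u2)
    pad = random_bases(rng, 200)
    reads = ([Sequence(f"u1_{i}", pad + unit1 + pad) for i in range(10)]
             + [Sequence(f"u2_{i}", pad + unit2 + pad) for i in range(10)])
    anchor_hpc = hpc_compress(Sequence("anchor", unit1)).compressed
    return build_pileup(anchor_hpc, reads), anchor_hpc


class TestPileup:
    def test_identical_copies_unanimous(self):
        rng = np.random.default_rng(5)
        region = random_bases(rng, 1200)
        pad = random_bases(rng, 100)
        anchor_hpc = hpc_compress(Sequence("a", region)).compressed
        reads = [Sequence(f"r{i}", pad + region + pad) for i in range(10)]
        pileup = build_pileup(anchor_hpc, reads)
        assert len(pileup.read_ids) == 10
        counts = np.stack([(pileup.matrix == b).sum(axis=0) for b in range(4)])
        covered = counts.sum(axis=0) > 0
        assert ((counts > 0).sum(axis=0)[covered] == 1).all()

    def test_divergent_sites_bimodal(self, two_unit_pileup):
        pileup, _ = two_unit_pileup
        counts = np.stack([(pileup.matrix == b).sum(axis=0) for b in range(4)])
        bimodal = ((counts >= 5).sum(axis=0) == 2).sum()
        assert bimodal == 5

    def test_half_anchor_read_excluded(self):
        rng = np.random.default_rng(6)
        region = random_bases(rng, 1500)
        pad = random_bases(rng, 300)
        anchor_hpc = hpc_compress(Sequence("a", region)).compressed
        full = [Sequence(f"f{i}", pad + region + pad) for i in range(3)]
        half = Sequence("h", pad + region[:700] + random_bases(rng, 1100))
        pileup = build_pileup(anchor_hpc, full + [half])
        assert "h" not in pileup.read_ids

    def test_no_full_span_read_signals(self):
        anchor_hpc = hpc_compress(Sequence("a", random_bases(np.random.default_rng(7), 1000))).compressed
        short = [Sequence("s", random_bases(np.random.default_rng(8), 300))]
        with pytest.raises(CannotCluster):
            build_pileup(anchor_hpc, short)


class TestCallCisMorphisms:
    def test_qualifying_column(self):
        pileup = make_pileup(["A" * 30] * 18 + ["C" + "A" * 29] * 12)
        sites = call_cismorphisms(pileup, min_f2=0.2)
        assert [s.position for s in sites] == [0]
        assert sites[0].f2 == pytest.approx(12 / 30)
        assert (sites[0].major, sites[0].second) == ("A", "C")

    def test_rare_base_not_called(self):
        pileup = make_pileup(["A" * 10] * 29 + ["C" + "A" * 9] * 1)
        assert call_cismorphisms(pileup, min_f2=0.2) == []

    def test_max_sites_keeps_largest_f2(self):
        # 30 columns: f2 rises with position; cap at 10 keeps the top 10
        rows = []
        for r in range(40):
            rows.append("".join("C" if r < 5 + c // 2 else "A" for c in range(30)))
        pileup = make_pileup(rows)
        sites = call_cismorphisms(pileup, min_f2=0.1, max_sites=10)
        assert len(sites) == 10
        kept_f2 = {s.f2 for s in sites}
        all_sites = call_cismorphisms(pileup, min_f2=0.1, max_sites=1000)
        dropped = [s.f2 for s in all_sites if s.position not in {t.position for t in sites}]
        assert all(min(kept_f2) >= f for f in dropped)

    def test_two_unit_fixture_called(self, two_unit_pileup):
        pileup, _ = two_unit_pileup
        sites = call_cismorphisms(pileup, min_f2=0.25)
        assert len(sites) == 5
        assert all(s.f2 == pytest.approx(0.5) for s in sites)


class TestSimilarityGraph:
    def test_identical_genotypes_one_block(self):
        G = np.zeros((2, 4), dtype=np.int8)
        blocks = similarity_graph(G)
        assert len(blocks) == 1 and blocks[0].size == 2

    def test_distant_genotypes_split(self):
        G = np.array([[0, 0, 0, 0], [3, 3, 3, 3]], dtype=np.int8)
        blocks = similarity_graph(G, max_dist=0.4)
        assert len(blocks) == 2

    def test_component_structure(self):
        # 3 reads pairwise distance 0.25 plus 1 read at distance 1.0
        G = np.array([
            [0, 0, 0, 0], [0, 0, 0, 1], [0, 0, 1, 0],
            [3, 3, 3, 3],
        ], dtype=np.int8)
        blocks = sorted(similarity_graph(G, max_dist=0.4), key=len)
        assert [b.size for b in blocks] == [1, 3]

    def test_min_shared_forces_singletons(self):
        G = np.array([[0, 0, -1, -1], [0, 0, -1, -1]], dtype=np.int8)
        assert len(similarity_graph(G, min_shared=3)) == 2


class TestRandomPartition:
    def test_no_loci_single_cluster(self):
        G = np.empty((8, 0), dtype=np.int8)
        clu = random_partition(G, coverage=10, seed=0)
        assert len(clu.clusters) == 1
        assert clu.score == 0

    def test_floor_blocks_split_at_default(self):
        """Two pure 20-read groups, coverage 40, floor 0.8*40=32: children
        of 20 < 32, so no split is allowed."""
        G = np.array([[0] * 6] * 20 + [[3] * 6] * 20, dtype=np.int8)
        clu = random_partition(G, coverage=40, min_frac=0.8, seed=1)
        assert len(clu.clusters) == 1

    def test_lower_floor_splits_pure(self):
        G = np.array([[0] * 6] * 20 + [[3] * 6] * 20, dtype=np.int8)
        clu = random_partition(G, coverage=40, min_frac=0.4, seed=1)
        assert len(clu.clusters) == 2
        assert clu.score == 0
        sizes = sorted(c.size for c in clu.clusters)
        assert sizes == [20, 20]

    def test_missing_follows_majority(self):
        G = np.array([[0]] * 12 + [[3]] * 10 + [[-1]] * 3, dtype=np.int8)
        clu = random_partition(G, coverage=10, min_frac=0.8, seed=2, reassign=False)
        sizes = sorted(c.size for c in clu.clusters)
        assert sizes == [10, 15]  # the 3 missing go with the 12-majority

    def test_deterministic_with_seed(self):
        rng = np.random.default_rng(9)
        G = rng.integers(0, 4, size=(50, 12)).astype(np.int8)
        a = random_partition(G, coverage=10, seed=33)
        b = random_partition(G, coverage=10, seed=33)
        assert [c.tolist() for c in a.clusters] == [c.tolist() for c in b.clusters]

    def test_partition_property(self):
        rng = np.random.default_rng(10)
        G = rng.integers(0, 4, size=(60, 10)).astype(np.int8)
        clu = random_partition(G, coverage=20, min_frac=0.5, seed=4)
        all_idx = np.sort(np.concatenate(clu.clusters))
        assert np.array_equal(all_idx, np.arange(60))

    def test_empty_block_rejected(self):
        with pytest.raises(ValueError):
            random_partition(np.empty((0, 3), dtype=np.int8), coverage=10)


class TestSelectCluster:
    def _clustering(self, groups):
        clusters = []
        offset = 0
        ids = []
        for size in groups:
            clusters.append(np.arange(offset, offset + size))
            offset += size
        consensus = np.zeros((len(groups), 1), dtype=np.int8)
        return Clustering(clusters=clusters, consensus=consensus, score=0)

    def test_max_intersection_wins(self):
        ids = [f"r{i:02d}" for i in range(20)]
        clu = self._clustering([10, 10])
        prev = set(ids[:8]) | {"r19"}
        sel = select_cluster([(ids, clu)], prev, None)
        assert sel.read_ids == sorted(ids[:10])

    def test_first_iteration_uses_anchor_genotype(self):
        ids = [f"r{i}" for i in range(6)]
        clusters = [np.arange(0, 3), np.arange(3, 6)]
        consensus = np.array([[0, 0], [3, 3]], dtype=np.int8)
        clu = Clustering(clusters=clusters, consensus=consensus, score=0)
        anchor_gt = np.array([3, 3], dtype=np.int8)
        sel = select_cluster([(ids, clu)], None, anchor_gt)
        assert sel.read_ids == ids[3:]

    def test_tie_broken_by_size(self):
        ids = [f"r{i:02d}" for i in range(30)]
        clusters = [np.arange(0, 10), np.arange(10, 30)]
        consensus = np.zeros((2, 0), dtype=np.int8)
        clu = Clustering(clusters=clusters, consensus=consensus, score=0)
        prev = set(ids[5:10]) | set(ids[10:15])  # 5 shared with each
        sel = select_cluster([(ids, clu)], prev, np.empty(0, dtype=np.int8))
        assert len(sel.read_ids) == 20

    def test_lost_track(self):
        ids = ["a", "b"]
        clu = self._clustering([2])
        with pytest.raises(LostTrack):
            select_cluster([(ids, clu)], {"zz"}, None)


class TestEndToEndClustering:
    def test_two_units_fully_separated(self, two_unit_pileup):
        pileup, anchor_hpc = two_unit_pileup
        sites = call_cismorphisms(pileup, min_f2=0.25)
        G = genotype_matrix(pileup, sites)
        blocks = similarity_graph(G)
        assert len(blocks) == 2
        for block in blocks:
            labels = {pileup.read_ids[i][:2] for i in block}
            assert len(labels) == 1

    def test_anchor_genotype_matches_unit1(self, two_unit_pileup):
        pileup, anchor_hpc = two_unit_pileup
        sites = call_cismorphisms(pileup, min_f2=0.25)
        agt = anchor_genotype(anchor_hpc, sites)
        G = genotype_matrix(pileup, sites)
        u1_rows = [i for i, r in enumerate(pileup.read_ids) if r.startswith("u1")]
        assert (G[u1_rows] == agt).all()
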