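"""Clustering phase: separate reads by SD copy of origin.

Full-span homopolymer-compressed (HPC) reads are piled on the HPC
anchor; columns where the second most common base is unexpectedly
frequent are called cis-morphisms (single-nucleotide differences
between SD copies).  Reads become genotype vectors over those loci, a
similarity graph splits them into blocks (connected components), each
block is partitioned by randomized recursive splitting on cis-morphism
loci, and the best-scoring clustering is kept.  Finally one cluster is
selected to continue the extension: the one sharing most reads with the
previous iteration's cluster (or, in the first iteration, the one whose
consensus genotype is closest to the anchor itself).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .seqcore import HPCMap, Sequence, edit_align, hpc_compress

_CODE = {b: i for i, b in enumerate("ACGT")}
_BASE = "ACGT"
MISSING = -1


class CannotCluster(Exception):
    """No read spans the full HPC anchor; the iteration must terminate."""


class LostTrack(Exception):
    """No cluster continues the previously selected cluster."""


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

@dataclass
class PileupRead:
    """Bookkeeping for one full-span read in the pileup."""

    read: Sequence                 # oriented raw read
    hpc: HPCMap
    raw_span: tuple[int, int]      # anchor alignment span in raw read coords
    identity: float                # HPC alignment identity vs anchor


@dataclass
class Pileup:
    """Per-position base calls of full-span HPC reads on the HPC anchor.

    ``matrix`` is (n_reads x anchor_len) int8 with 0..3 base codes and
    -1 for missing (deletion in the read or N).
    """

    anchor_hpc: Sequence
    read_ids: list[str]
    matrix: np.ndarray
    reads: dict[str, PileupRead]

    @property
    def depth(self) -> float:
        return float((self.matrix >= 0).sum(axis=0).mean())


def _codes(bases: str) -> np.ndarray:
    arr = np.frombuffer(bases.encode(), dtype=np.uint8)
    out = np.full(arr.size, MISSING, dtype=np.int8)
    for b, i in _CODE.items():
        out[arr == ord(b)] = i
    return out


def _half_identities(ops: list[tuple[str, int]], query_len: int) -> tuple[float, float]:
    """Alignment identity over the first and second half of the query."""
    mid = query_len // 2
    cols = [0, 0]
    edits = [0, 0]
    q = 0
    for op, n in ops:
        half = 1 if q >= mid else 0
        if op in "=XI":
            # split an op straddling the midpoint
            n_first = max(0, min(n, mid - q)) if half == 0 else 0
            for h, nn in ((0, n_first), (1, n - n_first)) if half == 0 else ((1, n),):
                cols[h] += nn
                if op != "=":
                    edits[h] += nn
            q += n
        else:  # 'D' consumes target only
            cols[half] += n
            edits[half] += n
    return (1.0 - edits[0] / cols[0] if cols[0] else 1.0,
            1.0 - edits[1] / cols[1] if cols[1] else 1.0)


def build_pileup(anchor_hpc: Sequence, reads: list[Sequence],
                 min_identity: float = 0.78,
                 hpc_cache: dict | None = None) -> Pileup:
    """Align each read (HPC) to the HPC anchor and keep full-span reads.

    A read is full-span when the whole anchor aligns strictly inside it
    at ``min_identity`` or better — enforced on each half of the anchor
    separately, because a read overlapping only part of the anchor can
    still reach a borderline overall identity once the aligner smears
    its missing portion, while its uncovered half drops to near-random
    identity.  Insertions in the read are ignored; deletions are
    recorded as missing.  Raises :class:`CannotCluster` when no read
    qualifies.
    """
    L = len(anchor_hpc)
    rows: list[np.ndarray] = []
    ids: list[str] = []
    kept: dict[str, PileupRead] = {}
    for read in reads:
        if hpc_cache is not None:
            cached = hpc_cache.get(read.id)
            if cached is not None and cached[0] == read.bases:
                hmap = cached[1]
            else:
                hmap = hpc_compress(read)
                hpc_cache[read.id] = (read.bases, hmap)
        else:
            hmap = hpc_compress(read)
        if len(hmap.compressed) <= L:
            continue
        aln = edit_align(anchor_hpc, hmap.compressed, mode="infix",
                         max_edit_frac=1.0 - min_identity + 0.12)
        if aln is None:
            continue
        ts, te = aln.target_span
        if aln.identity < min_identity:
            continue
        if min(_half_identities(aln.ops, L)) < min_identity:
            continue
        row = np.full(L, MISSING, dtype=np.int8)
        rcodes = _codes(hmap.compressed.bases)
        q = t = 0
        for op, n in aln.ops:
            if op in "=X":
                row[q:q + n] = rcodes[ts + t:ts + t + n]
                q += n
                t += n
            elif op == "I":       # anchor bases missing from the read
                q += n
            else:                 # 'D': read bases absent from the anchor
                t += n
        rows.append(row)
        ids.append(read.id)
        kept[read.id] = PileupRead(read=read, hpc=hmap,
                                   raw_span=hmap.lift(ts, te),
                                   identity=aln.identity)
    if not rows:
        raise CannotCluster("no read spans the full HPC anchor")
    return Pileup(anchor_hpc=anchor_hpc, read_ids=ids,
                  matrix=np.vstack(rows), reads=kept)


# ---------------------------------------------------------------------------
# Cis-morphism calling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CisMorphism:
    """A paralog-distinguishing column on the HPC anchor."""

    position: int
    major: str
    second: str
    f2: float


def auto_min_f2(noise_fraction: float, depth: float) -> float:
    """Coverage-dependent cis-morphism threshold.

    ``noise_fraction`` is the frequency of the second most common base
    expected from sequencing error alone; the threshold sits 3 sigma
    above it at the observed depth so that error noise rarely
    qualifies.
    """
    if depth <= 0:
        return 1.0
    return noise_fraction + 3.0 * float(
        np.sqrt(noise_fraction * (1.0 - noise_fraction) / depth))


def call_cismorphisms(pileup: Pileup, min_f2: float | None = 0.25,
                      max_sites: int = 200, noise_fraction: float | None = None,
                      min_count: int = 3, auto_sigma: float = 2.5) -> list[CisMorphism]:
    """Columns whose second most common base exceeds the threshold.

    ``min_f2=None`` selects an automatic, depth-dependent threshold via
    :func:`auto_min_f2`; the noise level is then estimated from the
    pileup itself (the mean second-base fraction over all columns — at
    realistic cis-morphism densities almost every column is pure noise)
    unless ``noise_fraction`` overrides it.  When more than
    ``max_sites`` qualify, the ones with the largest second-base
    fraction are kept (ties: leftmost).
    """
    m = pileup.matrix
    counts = np.stack([(m == b).sum(axis=0) for b in range(4)])  # 4 x L
    order = np.argsort(-counts, axis=0, kind="stable")           # ties -> smaller base
    c_sorted = np.take_along_axis(counts, order, axis=0)
    n_cov = counts.sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        f2 = np.where(n_cov > 0, c_sorted[1] / np.maximum(n_cov, 1), 0.0)
    if min_f2 is None:
        # 2.5 sigma rather than 3: a copy whose full-span representation
        # dips (typical right after the anchor enters the duplicated
        # unit) has its private sites hovering at the detection limit,
        # and losing them costs far more downstream than the extra
        # noise columns cost the partition, which weights and penalizes
        # them away
        noise = float(f2[n_cov > 0].mean()) if noise_fraction is None else noise_fraction
        thr = noise + auto_sigma * np.sqrt(noise * (1.0 - noise) / np.maximum(n_cov, 1))
    else:
        thr = np.full(f2.shape, min_f2)
    qual = (f2 > thr) & (c_sorted[1] >= min_count)
    pos = np.flatnonzero(qual)
    if pos.size > max_sites:
        pick = np.lexsort((pos, -f2[pos]))[:max_sites]
        pos = np.sort(pos[pick])
    return [
        CisMorphism(position=int(p), major=_BASE[order[0, p]],
                    second=_BASE[order[1, p]], f2=float(f2[p]))
        for p in pos
    ]


def genotype_matrix(pileup: Pileup, sites: list[CisMorphism]) -> np.ndarray:
    """Reads x retained-loci base codes (-1 = missing)."""
    if not sites:
        return np.empty((len(pileup.read_ids), 0), dtype=np.int8)
    cols = np.array([s.position for s in sites])
    return pileup.matrix[:, cols]


def anchor_genotype(anchor_hpc: Sequence, sites: list[CisMorphism]) -> np.ndarray:
    """The anchor's own bases at the cis-morphism loci."""
    codes = _codes(anchor_hpc.bases)
    return codes[np.array([s.position for s in sites], dtype=int)] if sites else \
        np.empty(0, dtype=np.int8)


# ---------------------------------------------------------------------------
# Similarity graph
# ---------------------------------------------------------------------------

def similarity_graph(genotypes: np.ndarray, max_dist: float = 0.4,
                     min_shared: int = 3) -> list[np.ndarray]:
    """Blocks of reads (index arrays) = connected components of the graph.

    An edge joins two reads when, over loci covered in both, they share
    at least ``min_shared`` loci and their normalized Hamming distance
    is at most ``max_dist``.  Reads with no qualifying partner form
    singleton blocks.
    """
    n = genotypes.shape[0]
    if n == 0:
        raise ValueError("need at least one genotype")
    g = nx.Graph()
    g.add_nodes_from(range(n))
    if genotypes.shape[1] > 0 and n > 1:
        valid = genotypes >= 0
        shared = (valid[:, None, :] & valid[None, :, :])
        n_shared = shared.sum(axis=2)
        diff = ((genotypes[:, None, :] != genotypes[None, :, :]) & shared).sum(axis=2)
        with np.errstate(divide="ignore", invalid="ignore"):
            dist = np.where(n_shared > 0, diff / np.maximum(n_shared, 1), 1.0)
        ok = (n_shared >= min_shared) & (dist <= max_dist)
        ii, jj = np.nonzero(np.triu(ok, k=1))
        g.add_edges_from(zip(ii.tolist(), jj.tolist()))
    return [np.array(sorted(c), dtype=np.int64)
            for c in nx.connected_components(g)]


# ---------------------------------------------------------------------------
# Randomized recursive clustering
# ---------------------------------------------------------------------------

@dataclass
class Clustering:
    """A partition of one block's reads into clusters.

    ``clusters`` are index arrays into the block's genotype matrix;
    ``consensus`` is (n_clusters x n_loci) majority genotype codes;
    ``score`` is the sum over reads of the Hamming distance to the
    nearest cluster consensus.
    """

    clusters: list[np.ndarray]
    consensus: np.ndarray
    score: int
    n_simulations: int = 0


def _consensus_of(G: np.ndarray, idx: np.ndarray) -> np.ndarray:
    sub = G[idx]
    counts = np.stack([(sub == b).sum(axis=0) for b in range(4)])
    cons = counts.argmax(axis=0).astype(np.int8)   # first max -> smallest base
    cons[counts.sum(axis=0) == 0] = MISSING
    return cons


def _pairwise_to_consensus(G: np.ndarray, consensus: np.ndarray) -> np.ndarray:
    """(n_reads x n_clusters) Hamming distances over jointly defined loci."""
    valid = (G[:, None, :] >= 0) & (consensus[None, :, :] >= 0)
    return ((G[:, None, :] != consensus[None, :, :]) & valid).sum(axis=2)


def _score(G: np.ndarray, clusters: list[np.ndarray]) -> tuple[int, np.ndarray]:
    consensus = np.stack([_consensus_of(G, c) for c in clusters])
    D = _pairwise_to_consensus(G, consensus)
    return int(D.min(axis=1).sum()), consensus


def _split_once(G: np.ndarray, idx: np.ndarray, floor: float,
                rng: np.random.Generator) -> list[np.ndarray] | None:
    """One recursion step: pick a random admissible locus and split.

    The split is binary on the locus's two most common bases: reads
    carrying the second base go one way, everything else (major base,
    sporadic error bases, missing) goes with the majority branch.  A
    locus is admissible when both children would keep at least
    ``floor`` reads.  Returns None when no locus is admissible
    (recursion base case).
    """
    sub = G[idx]
    n = idx.size
    counts = np.stack([(sub == b).sum(axis=0) for b in range(4)])  # 4 x m
    order = np.argsort(-counts, axis=0, kind="stable")
    c2 = np.take_along_axis(counts, order[1:2], axis=0)[0]
    admissible = np.flatnonzero((c2 >= floor) & (n - c2 >= floor))
    if admissible.size == 0:
        return None
    # weight the random choice by the within-subset minority fraction
    # (squared): a locus genuinely segregating inside this subset has a
    # far larger minority share than an error-artifact column, so clean
    # split paths dominate the simulations instead of being rare luck
    w = (c2[admissible] / n) ** 2
    locus = int(rng.choice(admissible, p=w / w.sum()))
    second = int(order[1, locus])
    mask = sub[:, locus] == second
    return [idx[mask], idx[~mask]]


def _simulate(G: np.ndarray, idx: np.ndarray, floor: float,
              rng: np.random.Generator) -> list[np.ndarray]:
    stack = [idx]
    leaves: list[np.ndarray] = []
    while stack:
        cur = stack.pop()
        children = _split_once(G, cur, floor, rng)
        if children is None:
            leaves.append(np.sort(cur))
        else:
            stack.extend(children)
    return leaves


def _reassign(G: np.ndarray, clustering: Clustering) -> Clustering:
    """One nearest-consensus reassignment pass (cluster count preserved,
    empty clusters dropped)."""
    D = _pairwise_to_consensus(G, clustering.consensus)
    labels = D.argmin(axis=1)
    clusters = [np.flatnonzero(labels == c) for c in range(len(clustering.clusters))]
    clusters = [c for c in clusters if c.size]
    score, consensus = _score(G, clusters)
    return Clustering(clusters=clusters, consensus=consensus, score=score,
                      n_simulations=clustering.n_simulations)


def random_partition(G: np.ndarray, coverage: float, min_frac: float = 0.8,
                     n_sim: int = 100, seed: int = 0, reassign: bool = True,
                     split_penalty: float = 1.5) -> Clustering:
    """Best-of-``n_sim`` randomized recursive clustering of one block.

    Each simulation repeatedly splits on a uniformly chosen admissible
    cis-morphism locus until none remains or a child would fall below
    ``min_frac x coverage`` reads.  The winning clustering minimizes
    the sum of read-to-nearest-consensus distances **plus**
    ``split_penalty x coverage`` per cluster (ties: fewer clusters,
    then first found).  The penalty matters in deep pileups: the sum of
    distances alone decreases with *every* split, and a split on a
    noise locus — whose minority count grows with block size and so
    clears any fixed floor — saves about one mismatch per carved-off
    read, fragmenting real clusters.  A genuine copy split saves one
    mismatch per read per distinguishing locus, comfortably above the
    penalty; a noise split saves less than it costs.  A final
    nearest-consensus reassignment pass cleans up reads that erred at
    the split locus itself.
    """
    n = G.shape[0]
    if n == 0:
        raise ValueError("empty block")
    if n_sim < 1 or coverage <= 0:
        raise ValueError("n_sim >= 1 and coverage > 0 required")
    idx = np.arange(n)
    if G.shape[1] == 0:
        score, consensus = _score(G, [idx])
        return Clustering([idx], consensus, score, 0)
    floor = min_frac * coverage
    penalty = split_penalty * coverage
    rng = np.random.default_rng(seed)
    best: Clustering | None = None
    best_key: tuple | None = None
    for _ in range(n_sim):
        clusters = _simulate(G, idx, floor, rng)
        score, consensus = _score(G, clusters)
        key = (score + penalty * len(clusters), len(clusters))
        if best_key is None or key < best_key:
            best = Clustering(clusters, consensus, score, n_sim)
            best_key = key
    assert best is not None
    if reassign and len(best.clusters) > 1:
        best = _reassign(G, best)
    return best


# ---------------------------------------------------------------------------
# Cluster selection
# ---------------------------------------------------------------------------

@dataclass
class SelectedCluster:
    read_ids: list[str]
    consensus: np.ndarray
    block_index: int
    cluster_index: int


def select_cluster(block_clusterings: list[tuple[list[str], Clustering]],
                   previous_reads: set[str] | None,
                   anchor_gt: np.ndarray | None,
                   min_size: int = 5) -> SelectedCluster:
    """Pick the cluster that continues the assembly.

    The anchor's own genotype is the primary criterion: the anchor
    carries the committed paralog's bases at the cis-morphism loci
    (refreshed every iteration at consensus accuracy), so the cluster
    whose consensus is nearest to it continues the same copy.  The
    normalized distance is binned so that differences below ~2% of loci
    — consensus noise — count as ties, and ties fall to the number of
    reads shared with the previous iteration's selected cluster, then
    cluster size, then the lexicographically smallest member.  Clusters
    below ``min_size`` only compete when nothing larger exists (a tiny
    fragment can match the anchor perfectly by chance but cannot carry
    an assembly).  Raises :class:`LostTrack` when there is nothing to
    select from.
    """
    all_clusters: list[SelectedCluster] = []
    for b, (block_ids, clustering) in enumerate(block_clusterings):
        for c, cluster in enumerate(clustering.clusters):
            ids = sorted(block_ids[i] for i in cluster)
            all_clusters.append(SelectedCluster(ids, clustering.consensus[c], b, c))
    if not all_clusters:
        raise LostTrack("no clusters at all")
    if previous_reads is None and anchor_gt is None:
        raise LostTrack("no previous cluster and no initial anchor")

    candidates = [sel for sel in all_clusters if len(sel.read_ids) >= min_size]
    if not candidates:
        candidates = all_clusters

    def anchor_bin(sel: SelectedCluster) -> int:
        if anchor_gt is None or anchor_gt.size == 0:
            return 0
        valid = (sel.consensus >= 0) & (anchor_gt >= 0)
        mism = int(((sel.consensus != anchor_gt) & valid).sum())
        return round(50 * (mism + 1) / (int(valid.sum()) + 2))

    def shared(sel: SelectedCluster) -> int:
        if previous_reads is None:
            return 0
        return len(previous_reads.intersection(sel.read_ids))

    candidates.sort(key=lambda sel: (anchor_bin(sel), -shared(sel),
                                     -len(sel.read_ids), sel.read_ids[0]))
    best = candidates[0]
    if previous_reads is not None and shared(best) == 0 and anchor_gt is None:
        raise LostTrack("no cluster shares reads with the previous iteration "
                        "and no anchor genotype is available")
    return best


# ---------------------------------------------------------------------------
# Diagnostics
# ---------------------------------------------------------------------------

def cismorphism_table(sites: list[CisMorphism]) -> str:
    """TSV dump: position, major, minor, f2."""
    lines = ["position\tmajor\tminor\tf2"]
    lines += [f"{s.position}\t{s.major}\t{s.second}\t{s.f2:.4f}" for s in sites]
    return "\n".join(lines) + "\n"


def assignment_table(block_clusterings: list[tuple[list[str], Clustering]],
                     selected: SelectedCluster | None) -> str:
    """TSV dump: read id, block, cluster, selected flag."""
    sel_ids = set(selected.read_ids) if selected else set()
    lines = ["read_id\tblock\tcluster\tselected"]
    for b, (block_ids, clustering) in enumerate(block_clusterings):
        for c, cluster in enumerate(clustering.clusters):
            for i in cluster:
                rid = block_ids[i]
                lines.append(f"{rid}\t{b}\t{c}\t{int(rid in sel_ids)}")
    return "\n".join(lines) + "\n"
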