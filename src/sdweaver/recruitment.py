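"""Mapping phase: minimizer-index read recruitment.

An in-memory minimizer index over the whole read set is built once; at
every iteration the current anchor is queried against it and reads
whose colinear chain of shared minimizers covers at least half the
anchor (by default) are recruited, strand-normalized to the anchor.

The index is native (no external mapper): canonical 2-bit k-mer codes,
a splitmix64-style hash, window minimizers, and a longest-increasing-
subsequence colinear chain per (read, strand).
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass

import numpy as np

from .seqcore import Sequence, revcomp

_CODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i

_U64_MAX = np.uint64(0xFFFFFFFFFFFFFFFF)


def _mix64(x: np.ndarray) -> np.ndarray:
    """splitmix64 finalizer: invertible uint64 mixing for k-mer hashing."""
    x = x.astype(np.uint64, copy=True)
    x += np.uint64(0x9E3779B97F4A7C15)
    x = (x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return x ^ (x >> np.uint64(31))


def _kmer_codes(bases: str, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Return (canonical hash, strand flag, valid mask) per k-mer start.

    strand flag is True where the forward k-mer is the canonical one.
    k-mers containing N are invalid.
    """
    codes = _CODE[np.frombuffer(bases.encode(), dtype=np.uint8)]
    n = codes.size - k + 1
    if n <= 0:
        e = np.empty(0)
        return e.astype(np.uint64), e.astype(bool), e.astype(bool)
    fwd = np.zeros(n, dtype=np.uint64)
    rev = np.zeros(n, dtype=np.uint64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        c = codes[j:j + n]
        valid &= c != 255
        cc = np.where(c == 255, 0, c).astype(np.uint64)
        fwd |= cc << np.uint64(2 * (k - 1 - j))
        rev |= (np.uint64(3) - cc) << np.uint64(2 * j)
    strand_fwd = fwd <= rev
    canon = np.where(strand_fwd, fwd, rev)
    h = _mix64(canon)
    h[~valid] = _U64_MAX
    return h, strand_fwd, valid


def _minimizer_positions(h: np.ndarray, w: int) -> np.ndarray:
    """Positions of window minimizers (smallest hash in each w-window)."""
    if h.size == 0:
        return np.empty(0, dtype=np.int64)
    if h.size <= w:
        p = int(np.argmin(h))
        return np.empty(0, dtype=np.int64) if h[p] == _U64_MAX else np.array([p])
    win = np.lib.stride_tricks.sliding_window_view(h, w)
    pos = win.argmin(axis=1) + np.arange(win.shape[0])
    pos = np.unique(pos)
    return pos[h[pos] != _U64_MAX]


@dataclass(frozen=True)
class RecruitmentHit:
    """A read recruited by the anchor query."""

    read_id: str
    strand: str              # read orientation relative to the anchor
    anchor_span: int         # anchor bp covered by the colinear chain
    n_chained: int           # minimizer hits in the chain


class MinimizerIndex:
    """Immutable minimizer index over a read collection.

    Stores, per minimizer hash, the (read, position, strand) triples of
    its occurrences, in flat sorted numpy arrays for fast lookup.
    """

    def __init__(self, reads: list[Sequence], k: int = 15, w: int = 10):
        if not reads:
            raise ValueError("cannot index an empty read set")
        if k < 11:
            raise ValueError("k must be >= 11")
        if w < 1:
            raise ValueError("w must be >= 1")
        self.k = k
        self.w = w
        self.reads = {r.id: r for r in reads}
        self._read_ids = [r.id for r in reads]
        hashes, ridx, pos, strands = [], [], [], []
        for i, r in enumerate(reads):
            h, sf, _ = _kmer_codes(r.bases, k)
            mp = _minimizer_positions(h, w)
            hashes.append(h[mp])
            ridx.append(np.full(mp.size, i, dtype=np.int32))
            pos.append(mp.astype(np.int32))
            strands.append(sf[mp])
        h_all = np.concatenate(hashes)
        order = np.argsort(h_all, kind="stable")
        self._hashes = h_all[order]
        self._ridx = np.concatenate(ridx)[order]
        self._pos = np.concatenate(pos)[order]
        self._strand = np.concatenate(strands)[order]

    def __len__(self) -> int:
        return int(self._hashes.size)

    def lookup(self, h: np.ndarray) -> tuple[np.ndarray, ...]:
        """All index entries whose hash occurs in ``h`` (parallel arrays:
        query slot, read index, read position, read-strand flag)."""
        lo = np.searchsorted(self._hashes, h, side="left")
        hi = np.searchsorted(self._hashes, h, side="right")
        counts = hi - lo
        qslot = np.repeat(np.arange(h.size), counts)
        if qslot.size == 0:
            z = np.empty(0, dtype=np.int64)
            return z, z.astype(np.int32), z.astype(np.int32), z.astype(bool)
        idx = np.concatenate([np.arange(a, b) for a, b in zip(lo, hi) if b > a])
        return qslot, self._ridx[idx], self._pos[idx], self._strand[idx]


def _lis_chain(read_pos: np.ndarray) -> np.ndarray:
    """Indices of a longest strictly increasing subsequence (patience)."""
    tails: list[int] = []       # read positions of pile tops
    tails_idx: list[int] = []
    back = np.full(read_pos.size, -1, dtype=np.int64)
    for i, v in enumerate(read_pos):
        j = bisect_left(tails, v)
        if j == len(tails):
            tails.append(v)
            tails_idx.append(i)
        else:
            tails[j] = v
            tails_idx[j] = i
        back[i] = tails_idx[j - 1] if j > 0 else -1
    out = []
    i = tails_idx[-1]
    while i != -1:
        out.append(i)
        i = back[i]
    return np.array(out[::-1], dtype=np.int64)


def build_index(reads: list[Sequence], k: int = 15, w: int = 10) -> MinimizerIndex:
    """Build the minimizer index once for a read set (deterministic)."""
    return MinimizerIndex(reads, k=k, w=w)


def recruit(index: MinimizerIndex, anchor: Sequence,
            min_cov_frac: float = 0.5) -> list[RecruitmentHit]:
    """Find reads whose chained minimizer hits cover enough of the anchor.

    Shared minimizers are grouped per (read, relative strand), chained
    colinearly (longest increasing subsequence in read coordinates after
    sorting by anchor position), and the chain's anchor extent must
    reach ``min_cov_frac`` x anchor length.  Results are sorted by read
    id, making the output invariant to read input order.
    """
    if len(anchor) < index.k:
        raise ValueError("anchor shorter than k")
    h, sf, _ = _kmer_codes(anchor.bases, index.k)
    mp = _minimizer_positions(h, index.w)
    if mp.size == 0:
        return []
    qslot, ridx, rpos, rstrand = index.lookup(h[mp])
    if qslot.size == 0:
        return []
    apos = mp[qslot]
    astrand = sf[mp][qslot]
    rel_fwd = rstrand == astrand   # same canonical orientation => '+'
    k = index.k

    hits: list[RecruitmentHit] = []
    # group by (read, rel strand)
    key = ridx.astype(np.int64) * 2 + rel_fwd
    order = np.argsort(key, kind="stable")
    bounds = np.flatnonzero(np.diff(key[order])) + 1
    for grp in np.split(order, bounds):
        rid = int(ridx[grp[0]])
        fwd = bool(rel_fwd[grp[0]])
        read = index.reads[index._read_ids[rid]]
        a = apos[grp]
        r = rpos[grp].astype(np.int64)
        if not fwd:
            r = len(read) - k - r   # read positions on the reverse strand
        srt = np.argsort(a, kind="stable")
        a, r = a[srt], r[srt]
        chain = _lis_chain(r)
        if chain.size < 2:
            continue
        span = int(a[chain[-1]] + k - a[chain[0]])
        if span >= min_cov_frac * len(anchor):
            hits.append(RecruitmentHit(
                read_id=index._read_ids[rid],
                strand="+" if fwd else "-",
                anchor_span=span,
                n_chained=int(chain.size),
            ))
    # a read hitting on both strands keeps its better chain only
    best: dict[str, RecruitmentHit] = {}
    for hit in hits:
        cur = best.get(hit.read_id)
        if cur is None or (hit.anchor_span, hit.n_chained) > (cur.anchor_span, cur.n_chained):
            best[hit.read_id] = hit
    return sorted(best.values(), key=lambda x: x.read_id)


def oriented_reads(index: MinimizerIndex, hits: list[RecruitmentHit]) -> list[Sequence]:
    """Recruited read sequences, reverse-complemented where needed so
    every returned read runs in the anchor's orientation."""
    out = []
    for hit in hits:
        read = index.reads[hit.read_id]
        if hit.strand == "-":
            out.append(Sequence(read.id, revcomp(read.bases)))
        else:
            out.append(read)
    return out
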