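"""Assembling + extending phases and the outer iteration driver.

The selected cluster's reads are truncated to the anchor window plus a
flank, assembled into a contig by a native draft-and-polish consensus
(reads are already positioned by their anchor alignment, so full
overlap-layout machinery is unnecessary), the anchor is located in the
contig by infix alignment, and the contig suffix beyond it extends the
growing assembly.  The driver loops recruitment -> clustering ->
assembly -> extension until termination.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum

import edlib
import numpy as np

from . import clustering as cl
from . import recruitment as rc
from .seqcore import Sequence, edit_align, hpc_compress, revcomp

logger = logging.getLogger("sdweaver")

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i
_BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


class AssemblyFailure(Exception):
    """Cluster assembly could not produce a usable contig."""


class Status(str, Enum):
    EXTENDED = "extended"
    NO_EXTENSION = "terminated_no_extension"
    NO_READS = "terminated_no_reads"
    LOST_TRACK = "terminated_lost_track"
    MAX_ITERS = "terminated_max_iters"
    TARGET_REACHED = "terminated_target_reached"


@dataclass
class IterationOutcome:
    status: Status
    extension_bp: int = 0


@dataclass
class AnchorState:
    """The driver's working state: current anchor + growing assembly."""

    anchor: Sequence
    iteration: int = 0
    selected_reads: set[str] = field(default_factory=set)
    assembled: str = ""
    history: list[dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Read truncation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TruncatedRead:
    seq: Sequence
    anchor_span: tuple[int, int]   # anchor alignment interval in the
                                   # truncated read's own coordinates


def truncate_reads(cluster_reads: list[cl.PileupRead], flank: int,
                   left_flank: int | None = None) -> list[TruncatedRead]:
    """Clip each read to its anchor alignment extended by <= ``flank`` bp
    (``left_flank`` overrides the upstream side).

    Ensures even coverage and a bounded assembly length: read sequence
    farther than ``flank`` from the anchor never enters the consensus.
    The driver keeps the upstream side short — everything left of the
    anchor is committed already, and polishing it again every iteration
    is pure overhead.
    """
    if left_flank is None:
        left_flank = flank
    out = []
    for pr in cluster_reads:
        s, e = pr.raw_span
        lo = max(0, s - left_flank)
        hi = min(len(pr.read), e + flank)
        out.append(TruncatedRead(
            seq=Sequence(pr.read.id, pr.read.bases[lo:hi]),
            anchor_span=(s - lo, e - lo),
        ))
    return out


# ---------------------------------------------------------------------------
# Native consensus assembly
# ---------------------------------------------------------------------------

def _expand_cigar(ops: list[tuple[str, int]]) -> tuple[np.ndarray, ...]:
    """Vectorized cigar expansion.

    Returns (q_idx, t_idx) for match/mismatch columns, t_idx for
    deleted target positions, and (t_boundary, q_first) for insertions.
    """
    kinds = np.array([{"=": 0, "X": 0, "I": 1, "D": 2}[op] for op, _ in ops])
    lens = np.array([n for _, n in ops], dtype=np.int64)
    qcons = kinds != 2
    tcons = kinds != 1
    qstart = np.concatenate(([0], np.cumsum(lens * qcons)))[:-1]
    tstart = np.concatenate(([0], np.cumsum(lens * tcons)))[:-1]

    m = kinds == 0
    ml = lens[m]
    total = int(ml.sum())
    if total:
        offs = np.repeat(np.cumsum(ml) - ml, ml)
        within = np.arange(total) - offs
        q_idx = np.repeat(qstart[m], ml) + within
        t_idx = np.repeat(tstart[m], ml) + within
    else:
        q_idx = t_idx = np.empty(0, dtype=np.int64)

    d = kinds == 2
    dl = lens[d]
    if dl.sum():
        offs = np.repeat(np.cumsum(dl) - dl, dl)
        t_del = np.repeat(tstart[d], dl) + (np.arange(int(dl.sum())) - offs)
    else:
        t_del = np.empty(0, dtype=np.int64)

    i = kinds == 1
    return q_idx, t_idx, t_del, tstart[i], qstart[i]


def _pick_tail(tails: list[str], top: int = 8, min_support_identity: float = 0.55
               ) -> str:
    """Choose a draft tail backbone that the cluster corroborates.

    All tails start at the anchor boundary, so same-origin tails agree
    over their shared prefix (identity ~0.7 for 15%-error read pairs)
    while a contaminant read's tail is unrelated sequence (~0.45).  The
    longest tail endorsed by at least half of the other long tails
    wins; picking purely by length would hand the backbone to whichever
    read sticks out farthest, contaminant or not.
    """
    cands = sorted((t for t in tails if t), key=len, reverse=True)[:top]
    if not cands:
        return ""
    if len(cands) == 1:
        return cands[0]
    for i, backbone in enumerate(cands):
        others = [t for j, t in enumerate(cands) if j != i]
        support = 0
        for other in others:
            n = min(len(backbone), len(other), 1500)
            res = edlib.align(other[:n], backbone[:n], mode="NW", task="distance")
            if 1.0 - res["editDistance"] / n >= min_support_identity:
                support += 1
        if support * 2 >= len(others):
            return backbone
    return cands[-1]


def _polish_round(draft: str, reads: list[TruncatedRead]
                  ) -> tuple[str, np.ndarray]:
    """One pileup-polish pass: majority base/deletion per draft position,
    plus insertions supported by more than half of the covering reads.
    Returns the polished draft and its per-position coverage."""
    L = len(draft)
    votes = np.zeros((4, L), dtype=np.int32)
    dels = np.zeros(L, dtype=np.int32)
    ins_n = np.zeros(L + 1, dtype=np.int32)
    ins_votes = np.zeros((4, L + 1), dtype=np.int32)
    for tr in reads:
        aln = edit_align(tr.seq.bases, draft, mode="infix", max_edit_frac=0.32)
        if aln is None:
            continue
        ts = aln.target_span[0]
        q_idx, t_idx, t_del, t_ins, q_ins = _expand_cigar(aln.ops)
        codes = _CODE[np.frombuffer(tr.seq.bases.encode(), dtype=np.uint8)]
        ok = codes[q_idx] >= 0
        np.add.at(votes, (codes[q_idx[ok]], ts + t_idx[ok]), 1)
        np.add.at(dels, ts + t_del, 1)
        if t_ins.size:
            first = codes[q_ins]
            okk = first >= 0
            np.add.at(ins_n, ts + t_ins[okk], 1)
            np.add.at(ins_votes, (first[okk], ts + t_ins[okk]), 1)
    cov = votes.sum(axis=0) + dels
    best = votes.argmax(axis=0)
    best_n = votes.max(axis=0)
    draft_arr = np.frombuffer(draft.encode(), dtype=np.uint8)

    base_out = np.where(cov > 0, _BASE[best], draft_arr)
    delete = (cov > 0) & (dels > best_n)
    # coverage at the boundary before position t, for the insertion vote
    bcov = np.empty(L + 1, dtype=np.int64)
    bcov[0], bcov[L] = cov[0], cov[-1]
    if L > 1:
        bcov[1:L] = np.maximum(cov[:-1], cov[1:])
    ins_pos = np.flatnonzero(ins_n * 2 > np.maximum(1, bcov))

    pieces: list[bytes] = []
    prev = 0
    for t in ins_pos:
        t = int(t)
        seg = base_out[prev:t][~delete[prev:t]]
        pieces.append(seg.tobytes())
        pieces.append(_BASE[int(ins_votes[:, t].argmax())].tobytes())
        prev = t
    pieces.append(base_out[prev:][~delete[prev:]].tobytes())
    return b"".join(pieces).decode(), cov


def assemble_cluster(truncated: list[TruncatedRead], anchor: Sequence,
                     min_reads: int = 5, polish_rounds: int = 2,
                     trim_frac: float = 0.5) -> Sequence:
    """Assemble one cluster's truncated reads into a single contig.

    The draft is the anchor sequence extended left and right by the
    longest read overhangs, then polished by ``polish_rounds`` majority
    pileup passes.  Contig ends where fewer than ``trim_frac`` of the
    cluster's reads still cover the draft are trimmed (single-read tails
    carry raw error rates).
    """
    if len(truncated) < min_reads:
        raise AssemblyFailure(f"cluster has {len(truncated)} reads < min_reads={min_reads}")
    left_tail = _pick_tail([tr.seq.bases[:tr.anchor_span[0]][::-1] for tr in truncated])[::-1]
    right_tail = _pick_tail([tr.seq.bases[tr.anchor_span[1]:] for tr in truncated])
    draft = left_tail + anchor.bases + right_tail

    cov = np.empty(0)
    for _ in range(max(1, polish_rounds)):
        draft, cov = _polish_round(draft, truncated)
    min_cov = max(2.0, trim_frac * len(truncated))
    covered = np.flatnonzero(cov >= min_cov)
    if covered.size == 0:
        raise AssemblyFailure("no draft position reaches the coverage floor")
    draft = draft[int(covered[0]):int(covered[-1]) + 1]
    if not draft:
        raise AssemblyFailure("empty contig after trimming")
    return Sequence("cluster_contig", draft)


# ---------------------------------------------------------------------------
# Anchor extension
# ---------------------------------------------------------------------------

def extend_anchor(state: AnchorState, contig: Sequence, step_cap: int,
                  anchor_len: int, min_anchor_identity: float = 0.9
                  ) -> tuple[AnchorState, IterationOutcome]:
    """Locate the anchor in the contig and append the suffix beyond it.

    The contig suffix past the anchor's end (capped at ``step_cap`` bp)
    is committed to the growing assembly; the new anchor is the last
    ``anchor_len`` bp of the updated assembly (a sliding window).  The
    anchor window itself is refreshed with the contig's copy of it —
    the cluster consensus just re-polished those bases at full
    coverage, so they supersede the version committed from an earlier,
    shallower contig end.
    """
    if not contig.bases:
        raise ValueError("empty contig")
    aln = edit_align(state.anchor, contig, mode="infix")
    if aln.identity < min_anchor_identity:
        return state, IterationOutcome(Status.LOST_TRACK)
    t_start, t_end = aln.target_span
    ext = contig.bases[t_end:t_end + step_cap]
    if not ext:
        return state, IterationOutcome(Status.NO_EXTENSION)
    polished_anchor = contig.bases[t_start:t_end]
    state.assembled = state.assembled[:-len(state.anchor)] + polished_anchor + ext
    new_anchor = state.assembled[-anchor_len:]
    state.anchor = Sequence(f"anchor_iter{state.iteration + 1}", new_anchor)
    return state, IterationOutcome(Status.EXTENDED, extension_bp=len(ext))


# ---------------------------------------------------------------------------
# Driver
# ---------------------------------------------------------------------------

@dataclass
class RunResult:
    contig: Sequence
    status: Status
    history: list[dict]
    diagnostics: list[dict] = field(default_factory=list)


def fullspan_coverage(coverage: float, read_mean: float, anchor_len: int) -> float:
    """Expected number of reads per SD copy spanning the whole anchor.

    Only reads containing the full anchor are clustered, so the cluster
    floor must scale with this, not with raw sequencing coverage."""
    return coverage * max(0.0, read_mean - anchor_len) / read_mean


def run(initial_anchor: Sequence, index: rc.MinimizerIndex, *,
        seed: int = 0,
        coverage: float = 40.0,
        read_mean: float = 5000.0,
        min_cov_frac: float = 0.5,
        min_f2: float | None = None,
        noise_fraction: float | None = None,
        max_sites: int = 200,
        max_dist: float = 0.4,
        min_shared: int = 3,
        min_frac: float = 0.8,
        n_sim: int = 100,
        flank: int | None = None,
        step_cap: int | None = None,
        anchor_len: int | None = None,
        min_reads: int = 5,
        max_iters: int = 500,
        min_identity: float = 0.78,
        polish_rounds: int = 2,
        trim_frac: float = 0.5,
        target_extension: int | None = None,
        collect_diagnostics: bool = False) -> RunResult:
    """Iteratively extend ``initial_anchor`` through the read set.

    Loops mapping -> clustering -> assembly -> extension until a
    termination status.  The returned contig is the growing assembly,
    which starts as (and always begins with) the initial anchor.
    ``target_extension`` optionally stops the run once that many bases
    have been added beyond the initial anchor and truncates the
    assembly to exactly that budget.
    """
    flank = int(read_mean / 2) if flank is None else flank
    step_cap = int(read_mean / 2) if step_cap is None else step_cap
    anchor_len = len(initial_anchor) if anchor_len is None else anchor_len
    state = AnchorState(anchor=initial_anchor, assembled=initial_anchor.bases)
    cov_fs = fullspan_coverage(coverage, read_mean, anchor_len)
    hpc_cache: dict = {}   # oriented-read HPC maps, reused across iterations
    diagnostics: list[dict] = []
    status = Status.MAX_ITERS

    for iteration in range(max_iters):
        state.iteration = iteration
        hits = rc.recruit(index, state.anchor, min_cov_frac)
        if iteration == 0 and not hits:
            raise RuntimeError(
                "initial anchor recruited zero reads — check that the anchor "
                "comes from the sequenced region and that k/w suit the error rate")
        if len(hits) < min_reads:
            status = Status.NO_READS
            break
        # only reads whose minimizer chain nearly covers the anchor can
        # be full-span; skip aligning the rest
        span_floor = 0.72 * len(state.anchor)
        candidates = [h for h in hits if h.anchor_span >= span_floor]
        oriented = rc.oriented_reads(index, candidates)
        anchor_hpc = hpc_compress(state.anchor).compressed
        try:
            pileup = cl.build_pileup(anchor_hpc, oriented, min_identity=min_identity,
                                     hpc_cache=hpc_cache)
        except cl.CannotCluster:
            status = Status.NO_READS
            break
        sites = cl.call_cismorphisms(pileup, min_f2=min_f2, max_sites=max_sites,
                                     noise_fraction=noise_fraction)
        G = cl.genotype_matrix(pileup, sites)
        if sites:
            blocks = cl.similarity_graph(G, max_dist=max_dist, min_shared=min_shared)
        else:
            blocks = [np.arange(len(pileup.read_ids))]
        block_clusterings = []
        for b, block in enumerate(blocks):
            sub_seed = int(np.random.SeedSequence([seed, iteration, b]).generate_state(1)[0] % (2 ** 31))
            clu = cl.random_partition(G[block], cov_fs, min_frac=min_frac,
                                      n_sim=n_sim, seed=sub_seed)
            block_clusterings.append(([pileup.read_ids[i] for i in block], clu))
        anchor_gt = cl.anchor_genotype(anchor_hpc, sites)
        try:
            selected = cl.select_cluster(
                block_clusterings,
                state.selected_reads if iteration > 0 else None,
                anchor_gt, min_size=min_reads)
        except cl.LostTrack:
            status = Status.LOST_TRACK
            break

        cluster_reads = [pileup.reads[rid] for rid in selected.read_ids]
        truncated = truncate_reads(cluster_reads, flank, left_flank=600)
        try:
            contig = assemble_cluster(truncated, state.anchor, min_reads=min_reads,
                                      polish_rounds=polish_rounds,
                                      trim_frac=trim_frac)
        except AssemblyFailure:
            status = Status.NO_EXTENSION
            break

        state, outcome = extend_anchor(state, contig, step_cap, anchor_len)
        state.selected_reads = set(selected.read_ids)
        record = {
            "iteration": iteration,
            "recruited": len(hits),
            "full_span": len(pileup.read_ids),
            "cis_morphisms": len(sites),
            "blocks": len(blocks),
            "clusters": sum(len(c.clusters) for _, c in block_clusterings),
            "selected_size": len(selected.read_ids),
            "extension_bp": outcome.extension_bp,
            "status": outcome.status.value,
            "assembled_bp": len(state.assembled),
        }
        state.history.append(record)
        logger.info("iter=%(iteration)d recruited=%(recruited)d full_span=%(full_span)d "
                    "cis=%(cis_morphisms)d blocks=%(blocks)d clusters=%(clusters)d "
                    "selected=%(selected_size)d ext=%(extension_bp)d", record)
        if collect_diagnostics:
            diagnostics.append({
                "iteration": iteration,
                "cismorphisms": cl.cismorphism_table(sites),
                "assignments": cl.assignment_table(block_clusterings, selected),
            })
        if outcome.status is not Status.EXTENDED:
            status = outcome.status
            break
        # stall guard: healthy runs advance by roughly a fifth of the
        # read length per iteration; one creeping far below that is
        # reassembling the same window without real progress — stop it
        # rather than crawl to max_iters
        recent = [h["extension_bp"] for h in state.history[-6:]]
        if len(recent) == 6 and sum(recent) < 0.36 * read_mean:
            status = Status.NO_EXTENSION
            break
        budget = None if target_extension is None else target_extension + len(initial_anchor)
        if budget is not None and len(state.assembled) >= budget:
            state.assembled = state.assembled[:budget]
            state.anchor = Sequence(state.anchor.id, state.assembled[-anchor_len:])
            status = Status.TARGET_REACHED
            break

    if state.history:
        _refresh_tail(state, index, min_cov_frac=min_cov_frac, min_f2=min_f2,
                      noise_fraction=noise_fraction, max_sites=max_sites,
                      max_dist=max_dist, min_shared=min_shared, min_frac=min_frac,
                      n_sim=n_sim, coverage=cov_fs, flank=flank, seed=seed,
                      min_reads=min_reads, min_identity=min_identity,
                      polish_rounds=polish_rounds, trim_frac=trim_frac)
    contig = Sequence(f"{initial_anchor.id}_assembly", state.assembled)
    return RunResult(contig=contig, status=status, history=state.history,
                     diagnostics=diagnostics)


def _refresh_tail(state: AnchorState, index: rc.MinimizerIndex, *, min_cov_frac,
                  min_f2, noise_fraction, max_sites, max_dist, min_shared,
                  min_frac, n_sim, coverage, flank, seed, min_reads,
                  min_identity, polish_rounds, trim_frac) -> None:
    """Re-polish the assembly's tail once after the iteration loop.

    Interior bases are refreshed by the sliding anchor window as it
    passes over them, but bases committed in the final iterations exit
    the loop having been polished only at a contig end, where coverage
    is at its thinnest; one more consensus pass over the final window
    brings them up to interior quality.
    """
    anchor = state.anchor
    try:
        hits = rc.recruit(index, anchor, min_cov_frac)
        if len(hits) < min_reads:
            return
        oriented = rc.oriented_reads(index, hits)
        anchor_hpc = hpc_compress(anchor).compressed
        pileup = cl.build_pileup(anchor_hpc, oriented, min_identity=min_identity)
        sites = cl.call_cismorphisms(pileup, min_f2=min_f2, max_sites=max_sites,
                                     noise_fraction=noise_fraction)
        G = cl.genotype_matrix(pileup, sites)
        if sites:
            blocks = cl.similarity_graph(G, max_dist=max_dist, min_shared=min_shared)
        else:
            blocks = [np.arange(len(pileup.read_ids))]
        block_clusterings = []
        for b, block in enumerate(blocks):
            sub_seed = int(np.random.SeedSequence([seed, 10 ** 6, b]).generate_state(1)[0] % (2 ** 31))
            clu = cl.random_partition(G[block], coverage, min_frac=min_frac,
                                      n_sim=n_sim, seed=sub_seed)
            block_clusterings.append(([pileup.read_ids[i] for i in block], clu))
        selected = cl.select_cluster(block_clusterings,
                                     state.selected_reads or None,
                                     cl.anchor_genotype(anchor_hpc, sites),
                                     min_size=min_reads)
        truncated = truncate_reads([pileup.reads[r] for r in selected.read_ids], flank)
        contig = assemble_cluster(truncated, anchor, min_reads=min_reads,
                                  polish_rounds=polish_rounds,
                                  trim_frac=trim_frac)
    except (cl.CannotCluster, cl.LostTrack, AssemblyFailure):
        return
    aln = edit_align(anchor, contig, mode="infix")
    if aln.identity < 0.9:
        return
    t_start, t_end = aln.target_span
    state.assembled = state.assembled[:-len(anchor)] + contig.bases[t_start:t_end]


def run_bidirectional(initial_anchor: Sequence, index: rc.MinimizerIndex,
                      **kwargs) -> RunResult:
    """Extend in both directions by running once on the anchor and once
    on its reverse complement, stitching at the shared anchor."""
    fwd = run(initial_anchor, index, **kwargs)
    rev = run(initial_anchor.reverse_complement(), index, **kwargs)
    # rev contig = rc(anchor) + leftward extension; rc(it) ends with the anchor
    merged = revcomp(rev.contig.bases) + fwd.contig.bases[len(initial_anchor):]
    return RunResult(
        contig=Sequence(f"{initial_anchor.id}_assembly", merged),
        status=fwd.status,
        history=rev.history + fwd.history,
    )


def history_tsv(history: list[dict]) -> str:
    if not history:
        return ""
    cols = list(history[0].keys())
    lines = ["\t".join(cols)]
    lines += ["\t".join(str(h[c]) for c in cols) for h in history]
    return "\n".join(lines) + "\n"
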