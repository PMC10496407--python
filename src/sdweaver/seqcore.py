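"""Elementary sequence machinery shared by all assembly stages.

Homopolymer compression with exact coordinate maps, edit-distance
alignment (via edlib), identity -> Phred conversion, and column-wise
majority consensus. Everything downstream (recruitment, clustering,
assembly, evaluation) builds on these primitives.

Coordinates are 0-based half-open throughout.
"""

from __future__ import annotations

import gzip
import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Literal

import edlib
import numpy as np

ALPHABET = frozenset("ACGTN")
#: Phred ceiling used when an alignment is perfect (p = 0 is undefined
#: on a log scale); 60 is the conventional FASTQ quality ceiling.
PHRED_CAP = 60.0

_SANITIZE = re.compile(r"[^ACGTN]")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(bases: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Sequence:
    """A named DNA sequence over {A,C,G,T,N}.

    Bases are upper-cased on ingest; any symbol outside the alphabet is
    mapped to N.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        b = self.bases.upper()
        if _SANITIZE.search(b):
            b = _SANITIZE.sub("N", b)
        object.__setattr__(self, "bases", b)

    def __len__(self) -> int:
        return len(self.bases)

    def reverse_complement(self, id_suffix: str = "_rc") -> "Sequence":
        return Sequence(self.id + id_suffix, revcomp(self.bases))


# ---------------------------------------------------------------------------
# Homopolymer compression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HPCMap:
    """Homopolymer-compressed view of a sequence plus its coordinate map.

    ``to_original[i]`` is the 0-based half-open run of original
    coordinates collapsed into compressed position ``i``.  Runs are
    contiguous, non-overlapping, and tile the original sequence exactly.
    """

    compressed: Sequence
    to_original: list[tuple[int, int]]

    def lift(self, start: int, end: int) -> tuple[int, int]:
        """Map a compressed half-open interval back to original coordinates."""
        if start == end:
            pos = self.to_original[start][0] if start < len(self.to_original) else (
                self.to_original[-1][1] if self.to_original else 0)
            return pos, pos
        return self.to_original[start][0], self.to_original[end - 1][1]

    def expand(self, original: str) -> str:
        """Reconstruct the original string this map was built from."""
        return "".join(original[s:e] for s, e in self.to_original)


def hpc_compress(seq: Sequence) -> HPCMap:
    """Collapse every maximal homopolymer run to a single base.

    The returned map is the single source of truth for lifting
    HPC-space alignment coordinates back to raw read coordinates.
    """
    bases = seq.bases
    if not bases:
        return HPCMap(Sequence(seq.id, ""), [])
    arr = np.frombuffer(bases.encode(), dtype=np.uint8)
    starts = np.concatenate(([0], np.flatnonzero(arr[1:] != arr[:-1]) + 1))
    ends = np.concatenate((starts[1:], [arr.size]))
    compressed = arr[starts].tobytes().decode()
    runs = list(zip(starts.tolist(), ends.tolist()))
    return HPCMap(Sequence(seq.id, compressed), runs)


# ---------------------------------------------------------------------------
# Edit-distance alignment
# ---------------------------------------------------------------------------

AlignMode = Literal["global", "semiglobal", "infix"]

_EDLIB_MODE = {"global": "NW", "semiglobal": "SHW", "infix": "HW"}

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of a pairwise Levenshtein alignment.

    ``ops`` is a list of (op, length) with op in {'=', 'X', 'I', 'D'};
    'I' consumes query only, 'D' consumes target only.  ``identity`` is
    1 - edits / alignment_length where alignment_length counts matches,
    mismatches and indels.
    """

    edit_distance: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    ops: list[tuple[str, int]] = field(repr=False)
    identity: float

    @property
    def alignment_length(self) -> int:
        return sum(n for _, n in self.ops)

    def to_paf_like(self, query: Sequence, target: Sequence) -> str:
        """Tab record: query, qlen, qspan, strand, target, tlen, tspan, edits, identity."""
        qs, qe = self.query_span
        ts, te = self.target_span
        return "\t".join(str(x) for x in (
            query.id, len(query), qs, qe, "+",
            target.id, len(target), ts, te,
            self.edit_distance, f"{self.identity:.6f}"))


def parse_cigar(cigar: str) -> list[tuple[str, int]]:
    return [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]


def edit_align(query: Sequence | str, target: Sequence | str,
               mode: AlignMode = "global",
               max_edit_frac: float | None = None) -> AlignmentResult | None:
    """Minimal-edit-distance alignment of ``query`` against ``target``.

    Modes: ``global`` (ends anchored both sides), ``semiglobal`` (gaps
    after the query's end in the target are free), ``infix`` (gaps at
    both target ends are free; the query aligns somewhere inside the
    target).  ``max_edit_frac`` bounds the edit distance at that
    fraction of the query length (banded alignment, considerably
    faster); None is returned when the bound is exceeded.
    """
    q = query.bases if isinstance(query, Sequence) else query
    t = target.bases if isinstance(target, Sequence) else target
    if not q or not t:
        raise ValueError("edit_align requires non-empty query and target")
    k = -1 if max_edit_frac is None else max(1, int(max_edit_frac * len(q)))
    res = edlib.align(q, t, mode=_EDLIB_MODE[mode], task="path", k=k)
    if res["editDistance"] < 0:
        return None   # beyond the edit budget — caller treats as no alignment
    ops: list[tuple[str, int]] = []
    aln_len = 0
    for n, op in _CIGAR_RE.findall(res["cigar"]):
        ni = int(n)
        ops.append((op, ni))
        aln_len += ni
    dist = res["editDistance"]
    loc = res["locations"][0]
    t_start = loc[0] if loc[0] is not None else 0
    t_end = loc[1] + 1  # edlib end is inclusive
    identity = 1.0 - dist / aln_len if aln_len else 1.0
    return AlignmentResult(
        edit_distance=dist,
        query_span=(0, len(q)),
        target_span=(t_start, t_end),
        ops=ops,
        identity=identity,
    )


def strip_terminal_indels(aln: AlignmentResult) -> AlignmentResult:
    """Drop leading/trailing indel runs from an alignment.

    Useful when a query extends past the target (or vice versa): the
    overhang shows up as terminal I/D runs that should not count toward
    identity of the genuinely aligned core.
    """
    ops = list(aln.ops)
    qs, qe = aln.query_span
    ts, te = aln.target_span
    trimmed_edits = 0
    while ops and ops[0][0] in "ID":
        op, n = ops.pop(0)
        trimmed_edits += n
        if op == "I":
            qs += n
        else:
            ts += n
    while ops and ops[-1][0] in "ID":
        op, n = ops.pop()
        trimmed_edits += n
        if op == "I":
            qe -= n
        else:
            te -= n
    aln_len = sum(n for _, n in ops)
    dist = aln.edit_distance - trimmed_edits
    identity = 1.0 - dist / aln_len if aln_len else 1.0
    return AlignmentResult(dist, (qs, qe), (ts, te), ops, identity)


# ---------------------------------------------------------------------------
# Phred
# ---------------------------------------------------------------------------

def phred_from_identity(identity: float, cap: float = PHRED_CAP) -> float:
    """Convert an alignment identity to a Phred quality score.

    Q = -10 * log10(1 - identity); a perfect identity maps to ``cap``
    (the error probability would be 0, undefined on a log scale).
    """
    if not 0.0 <= identity <= 1.0:
        raise ValueError(f"identity must be in [0,1], got {identity}")
    if identity >= 1.0:
        return cap
    return min(cap, -10.0 * math.log10(1.0 - identity))


# ---------------------------------------------------------------------------
# Column consensus
# ---------------------------------------------------------------------------

_BASE_ORDER = "ACGT"  # lexicographic; used for deterministic tie-breaks


def column_consensus(rows: list[str], seq_id: str = "consensus") -> Sequence:
    """Majority base per column of a gapped block of equal-length rows.

    '-' marks a gap and N marks a missing call; both are excluded from
    the vote.  Columns with no votes are dropped.  Ties go to the
    lexicographically smallest base (determinism).
    """
    if not rows:
        raise ValueError("column_consensus requires at least one row")
    width = len(rows[0])
    if any(len(r) != width for r in rows):
        raise ValueError("ragged rows")
    out: list[str] = []
    for col in range(width):
        counts = {b: 0 for b in _BASE_ORDER}
        for r in rows:
            c = r[col]
            if c in counts:
                counts[c] += 1
        best = max(_BASE_ORDER, key=lambda b: (counts[b], ))
        # max() keeps the first maximum, i.e. lexicographically smallest
        if counts[best] > 0:
            out.append(best)
    return Sequence(seq_id, "".join(out))


# ---------------------------------------------------------------------------
# FASTA / FASTQ I/O (gz-transparent)
# ---------------------------------------------------------------------------

def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_sequences(path: str | Path) -> list[Sequence]:
    """Read a (possibly gzipped) FASTA or FASTQ file into Sequence records."""
    from Bio import SeqIO
    path = Path(path)
    stem = path.name[:-3] if path.name.endswith(".gz") else path.name
    fmt = "fastq" if stem.endswith((".fastq", ".fq")) else "fasta"
    with _open_text(path) as fh:
        return [Sequence(rec.id, str(rec.seq)) for rec in SeqIO.parse(fh, fmt)]


def write_fasta(seqs: Iterable[Sequence], path: str | Path, width: int = 80) -> None:
    with _open_text(path, "wt") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.bases), width):
                fh.write(s.bases[i:i + width] + "\n")


def write_fastq(seqs: Iterable[Sequence], path: str | Path, quality_char: str = "I") -> None:
    """Write reads as FASTQ with a uniform placeholder quality string."""
    with _open_text(path, "wt") as fh:
        for s in seqs:
            fh.write(f"@{s.id}\n{s.bases}\n+\n{quality_char * len(s.bases)}\n")


def iter_fasta(path: str | Path) -> Iterator[Sequence]:
    yield from read_sequences(path)
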