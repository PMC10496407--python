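"""Validation layer: assign assembled contigs to truth SD units and
score them on the Phred scale.

A contig is assigned to the simulated SD unit whose alignment (i)
covers at least 95% of the contig length and (ii) has the highest Phred
quality score among all units; a truth unit is *resolved* when at least
one contig is assigned to it.  A separate BAC-style rule declares a
reference clone resolved when an alignment covers >= 99.5% of the
clone's length.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .seqcore import Sequence, edit_align, phred_from_identity, revcomp


@dataclass(frozen=True)
class AssignmentResult:
    contig_id: str
    unit_id: str | None
    coverage: float        # fraction of the contig covered by the alignment
    identity: float
    q: float
    ambiguous: bool = False


@dataclass(frozen=True)
class BenchmarkSummary:
    scenario: str
    n_units: int
    n_resolved: int
    percent_resolved: float
    median_q: float | None
    min_q: float | None


@dataclass(frozen=True)
class LocalCore:
    """Highest-scoring contiguous stretch of a pairwise alignment."""

    query_span: tuple[int, int]
    target_span: tuple[int, int]
    edit_distance: int
    alignment_length: int

    @property
    def identity(self) -> float:
        if self.alignment_length == 0:
            return 0.0
        return 1.0 - self.edit_distance / self.alignment_length


def _local_core(query: Sequence | str, target: Sequence | str) -> LocalCore:
    """Infix-align query into target, then trim to the best local core.

    The full query is always consumed by the aligner, so unrelated query
    overhangs get smeared across the target as a low-identity fringe
    rather than clean terminal gaps.  Scoring each op run (+1 match,
    -2 edit) and taking the maximum-scoring contiguous stretch recovers
    the genuinely homologous core, the way a local aligner would.
    """
    aln = edit_align(query, target, mode="infix")
    scores, q_len, t_len = [], [], []
    for op, n in aln.ops:
        scores.append(n if op == "=" else -2 * n)
        q_len.append(n if op in "=XI" else 0)
        t_len.append(n if op in "=XD" else 0)
    best = (0, 0, 0)  # score, start op, end op (half-open)
    run_score, run_start = 0, 0
    for i, s in enumerate(scores):
        if run_score <= 0:
            run_score, run_start = s, i
        else:
            run_score += s
        if run_score > best[0]:
            best = (run_score, run_start, i + 1)
    _, lo, hi = best
    q0 = sum(q_len[:lo])
    t0 = aln.target_span[0] + sum(t_len[:lo])
    core_ops = aln.ops[lo:hi]
    edits = sum(n for op, n in core_ops if op != "=")
    return LocalCore(
        query_span=(q0, q0 + sum(q_len[lo:hi])),
        target_span=(t0, t0 + sum(t_len[lo:hi])),
        edit_distance=edits,
        alignment_length=sum(n for _, n in core_ops),
    )


def _contig_vs_unit(contig: Sequence, unit: Sequence) -> tuple[float, float, int]:
    """(contig coverage fraction, identity, edit distance) for the best
    strand: the contig is aligned into the unit and trimmed to its local
    core; coverage is the core's share of the contig length."""
    best = None
    for bases in (contig.bases, revcomp(contig.bases)):
        core = _local_core(bases, unit)
        qs, qe = core.query_span
        coverage = (qe - qs) / len(contig) if len(contig) else 0.0
        cand = (coverage, core.identity, core.edit_distance)
        # rank by coverage before identity: the wrong strand can hold a
        # short perfect core whose identity beats the true alignment's
        if best is None or cand[:2] > best[:2]:
            best = cand
    return best


def assign_contigs(contigs: list[Sequence], truth_units: list[Sequence],
                   min_coverage: float = 0.95) -> list[AssignmentResult]:
    """Assign each contig to a truth unit by the coverage + max-Q rule.

    Ties on Q are broken by lower edit distance, then unit input order,
    and flagged ambiguous.
    """
    if not contigs or not truth_units:
        raise ValueError("need at least one contig and one truth unit")
    out = []
    for contig in contigs:
        rows = []
        for order, unit in enumerate(truth_units):
            coverage, identity, dist = _contig_vs_unit(contig, unit)
            if coverage >= min_coverage:
                q = phred_from_identity(identity)
                rows.append((-q, dist, order, coverage, identity, unit.id))
        if not rows:
            out.append(AssignmentResult(contig.id, None, 0.0, 0.0, 0.0))
            continue
        rows.sort()
        negq, dist, order, coverage, identity, unit_id = rows[0]
        ambiguous = len(rows) > 1 and math.isclose(-rows[1][0], -negq, abs_tol=1e-9)
        out.append(AssignmentResult(contig.id, unit_id, coverage, identity,
                                    -negq, ambiguous))
    return out


def bac_style_resolution(contig: Sequence, reference_clone: Sequence,
                         min_coverage: float = 0.995) -> tuple[bool, float]:
    """BAC-clone validation rule: resolved iff an alignment covers
    >= ``min_coverage`` of the clone length; Q scores that alignment."""
    if not contig.bases or not reference_clone.bases:
        raise ValueError("contig and clone must be non-empty")
    best = None
    for bases in (contig.bases, revcomp(contig.bases)):
        core = _local_core(reference_clone, Sequence(contig.id, bases))
        qs, qe = core.query_span
        coverage = (qe - qs) / len(reference_clone)
        cand = (coverage, core.identity)
        if best is None or cand > best:
            best = cand
    coverage, identity = best
    return coverage >= min_coverage, phred_from_identity(identity)


def summarize(scenario: str, assignments: list[AssignmentResult],
              truth_unit_ids: list[str]) -> BenchmarkSummary:
    """Per-scenario resolution percentage and Q statistics.

    resolved% = 100 x (units with >= 1 assigned contig) / units; Q
    statistics are over assigned contigs (median uses linear
    interpolation; None when nothing was assigned).
    """
    resolved_units = {a.unit_id for a in assignments if a.unit_id is not None}
    resolved_units &= set(truth_unit_ids)
    qs = sorted(a.q for a in assignments if a.unit_id is not None)
    if qs:
        n = len(qs)
        mid = (n - 1) / 2
        lo, hi = qs[int(math.floor(mid))], qs[int(math.ceil(mid))]
        median_q = (lo + hi) / 2
        min_q = qs[0]
    else:
        median_q = min_q = None
    n_units = len(truth_unit_ids)
    return BenchmarkSummary(
        scenario=scenario,
        n_units=n_units,
        n_resolved=len(resolved_units),
        percent_resolved=100.0 * len(resolved_units) / n_units if n_units else 0.0,
        median_q=median_q,
        min_q=min_q,
    )


def summary_tsv(summaries: list[BenchmarkSummary]) -> str:
    lines = ["scenario\tn_units\tn_resolved\tpercent_resolved\tmedian_q\tmin_q"]
    for s in summaries:
        med = "NA" if s.median_q is None else f"{s.median_q:.2f}"
        mn = "NA" if s.min_q is None else f"{s.min_q:.2f}"
        lines.append(f"{s.scenario}\t{s.n_units}\t{s.n_resolved}\t"
                     f"{s.percent_resolved:.1f}\t{med}\t{mn}")
    return "\n".join(lines) + "\n"


def report_tsv(scenario: str, assignments: list[AssignmentResult]) -> str:
    """Per-contig report: scenario, unit, contig, coverage, identity, Q, resolved."""
    lines = ["scenario\tunit\tcontig\tcoverage\tidentity\tq\tresolved"]
    for a in assignments:
        unit = a.unit_id or "NA"
        lines.append(f"{scenario}\t{unit}\t{a.contig_id}\t{a.coverage:.4f}\t"
                     f"{a.identity:.6f}\t{a.q:.2f}\t{int(a.unit_id is not None)}")
    return "\n".join(lines) + "\n"
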