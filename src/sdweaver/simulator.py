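"""Synthetic collapsed-segmental-duplication data generator.

Emulates the evolution of SD copies on a tree: a root unit sequence is
assigned to the root, and each child node receives a copy of its parent
mutated at a fixed per-base substitution rate.  Leaf units are laid out
on a single "collapsed" contig flanked (and optionally separated) by
unique random sequence, and error-prone long reads with truth labels
are sampled from that contig.

All randomness flows from explicit integer seeds through
``numpy.random.default_rng``; identical seeds give byte-identical
output.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

from .seqcore import Sequence, revcomp

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


# ---------------------------------------------------------------------------
# Tree topologies
# ---------------------------------------------------------------------------

TOPOLOGY_KINDS = ("flat", "bifurcating", "cascading", "random")


@dataclass(frozen=True)
class TopologySpec:
    """Shape of the SD evolution tree.

    kinds: ``flat`` (star: every leaf is a child of the root),
    ``bifurcating`` (balanced binary), ``cascading`` (caterpillar:
    each internal node sprouts one leaf and one deeper internal node),
    ``random`` (random recursive tree).  ``skew`` > 0 unbalances a
    bifurcating tree by sending that many extra leaves to one side.
    """

    kind: str
    n_leaves: int
    seed: int = 0
    skew: int = 0

    def __post_init__(self) -> None:
        if self.kind not in TOPOLOGY_KINDS:
            raise ValueError(f"unknown topology kind {self.kind!r}")
        if self.n_leaves < 1:
            raise ValueError("n_leaves must be >= 1")


def build_tree(topo: TopologySpec) -> tuple[list[tuple[int, int]], list[int]]:
    """Return (edges as (parent, child) pairs, leaf node ids).

    Node 0 is the root.  Deterministic given the topology description
    (the ``random`` kind draws from a generator seeded with
    ``topo.seed``).
    """
    edges: list[tuple[int, int]] = []
    if topo.kind == "flat":
        leaves = list(range(1, topo.n_leaves + 1))
        edges = [(0, child) for child in leaves]
        return edges, leaves

    if topo.kind == "bifurcating":
        next_id = [0]

        def grow(parent: int, n: int, skew: int) -> list[int]:
            if n == 1:
                return [parent]
            left_n = (n + 1) // 2 + skew
            left_n = min(max(left_n, 1), n - 1)
            out: list[int] = []
            for sub_n in (left_n, n - left_n):
                next_id[0] += 1
                child = next_id[0]
                edges.append((parent, child))
                out.extend(grow(child, sub_n, skew))
            return out

        leaves = grow(0, topo.n_leaves, topo.skew)
        return edges, leaves

    if topo.kind == "cascading":
        leaves = []
        spine = 0
        next_id = 0
        for i in range(topo.n_leaves - 1):
            next_id += 1
            leaf = next_id
            edges.append((spine, leaf))
            leaves.append(leaf)
            next_id += 1
            edges.append((spine, next_id))
            spine = next_id
        leaves.append(spine if topo.n_leaves > 1 else 0)
        if topo.n_leaves == 1:
            return [], [0]
        return edges, leaves

    # random recursive tree: attach new nodes to uniformly chosen
    # existing nodes until the leaf count reaches n_leaves
    rng = np.random.default_rng(topo.seed)
    children: dict[int, list[int]] = {0: []}
    nodes = [0]
    while True:
        leaves = [n for n in nodes if not children[n]]
        if len(leaves) == topo.n_leaves and len(nodes) > 1:
            return edges, leaves
        parent = int(rng.choice(nodes))
        child = len(nodes)
        nodes.append(child)
        children[child] = []
        children[parent].append(child)
        edges.append((parent, child))


def max_leaf_depth(edges: list[tuple[int, int]], leaves: list[int]) -> int:
    depth = {0: 0}
    for parent, child in edges:
        depth[child] = depth[parent] + 1
    return max(depth[leaf] for leaf in leaves) if leaves else 0


def rate_for_leaf_identity(identity: float, depth: int = 1) -> float:
    """Per-edge substitution rate so leaf-vs-root identity hits a target.

    With one edge the rate is exactly 1 - identity (every substitution
    changes the base); for deeper trees the per-edge rate compounds as
    (1-r)^depth, ignoring the small back-mutation correction.
    """
    if not 0.0 < identity <= 1.0:
        raise ValueError("identity must be in (0, 1]")
    if depth < 1:
        raise ValueError("depth must be >= 1")
    return 1.0 - identity ** (1.0 / depth)


# ---------------------------------------------------------------------------
# Unit evolution
# ---------------------------------------------------------------------------

@dataclass
class SDTruthSet:
    """Complete simulator output: tree, unit sequences, contig, layout."""

    topology: TopologySpec
    edges: list[tuple[int, int]]
    leaf_ids: list[int]
    root_unit: Sequence
    leaf_units: dict[str, Sequence]
    mutation_rate: float
    collapsed_contig: Sequence | None = None
    unit_intervals: dict[str, tuple[int, int]] = field(default_factory=dict)
    left_flank: Sequence | None = None
    right_flank: Sequence | None = None
    #: unique random sequence immediately preceding each unit on the
    #: contig (the left flank tail for the first unit); anchors come
    #: from here
    preceding_unique: dict[str, tuple[int, int]] = field(default_factory=dict)

    def leaf_names(self) -> list[str]:
        return [f"leaf{idx}" for idx in self.leaf_ids]

    def initial_anchor(self, leaf: str, anchor_len: int) -> Sequence:
        """The designated initial anchor for a leaf: the tail of the
        unique sequence immediately preceding its unit on the contig."""
        if self.collapsed_contig is None:
            raise ValueError("contig not built yet")
        s, e = self.preceding_unique[leaf]
        if e - s < anchor_len:
            raise ValueError(f"preceding unique sequence shorter than {anchor_len}")
        return Sequence(f"anchor_{leaf}", self.collapsed_contig.bases[e - anchor_len:e])


def random_bases(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _mutate(arr: np.ndarray, rate: float, rng: np.random.Generator) -> tuple[np.ndarray, int]:
    """Substitute each base independently with probability ``rate``,
    always to a different base (uniform over the other three)."""
    out = arr.copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        shift = rng.integers(1, 4, size=hit.size)
        idx = np.searchsorted(_BASES, out[hit])  # A,C,G,T are sorted
        out[hit] = _BASES[(idx + shift) % 4]
    return out, int(hit.size)


def evolve_units(root_unit: Sequence, topo: TopologySpec, mutation_rate: float,
                 seed: int) -> SDTruthSet:
    """Evolve the root unit down the tree by per-base substitution.

    Each edge applies independent substitutions at ``mutation_rate``
    per base; leaf sequences differ from their ancestors only by
    substitutions (no indels).
    """
    if not root_unit.bases:
        raise ValueError("root unit must be non-empty")
    if not 0.0 <= mutation_rate < 0.5:
        raise ValueError("mutation_rate must be in [0, 0.5)")
    edges, leaves = build_tree(topo)
    rng = np.random.default_rng(seed)
    root_arr = np.frombuffer(root_unit.bases.encode(), dtype=np.uint8)
    node_seq: dict[int, np.ndarray] = {0: root_arr}
    for parent, child in edges:  # edges are emitted parent-first
        node_seq[child], _ = _mutate(node_seq[parent], mutation_rate, rng)
    leaf_units = {
        f"leaf{idx}": Sequence(f"leaf{idx}", node_seq[idx].tobytes().decode())
        for idx in leaves
    }
    return SDTruthSet(
        topology=topo, edges=edges, leaf_ids=leaves, root_unit=root_unit,
        leaf_units=leaf_units, mutation_rate=mutation_rate,
    )


# ---------------------------------------------------------------------------
# Collapsed contig
# ---------------------------------------------------------------------------

def _kmers(bases: str, k: int) -> set[str]:
    return {bases[i:i + k] for i in range(len(bases) - k + 1)}


def _unique_random(rng: np.random.Generator, length: int, forbidden: set[str],
                   k: int = 21, max_tries: int = 50) -> str:
    """Random sequence none of whose k-mers occur in ``forbidden``."""
    for _ in range(max_tries):
        cand = random_bases(rng, length)
        if not (_kmers(cand, k) & forbidden):
            return cand
    raise RuntimeError("could not generate a unique random flank")


def build_collapsed_contig(truth: SDTruthSet, flank_len: int, seed: int,
                           spacer_len: int = 0) -> SDTruthSet:
    """Lay the leaf units out on one contig with unique random flanks.

    ``spacer_len`` > 0 inserts a unique random spacer before every unit
    after the first, so each unit is preceded by unique sequence usable
    as its initial anchor (the left flank plays that role for the first
    unit).  Flank/spacer 21-mers are checked against all unit sequences
    and regenerated on collision.
    """
    if flank_len <= 0:
        raise ValueError("flank_len must be positive")
    rng = np.random.default_rng(seed)
    forbidden: set[str] = set()
    for unit in truth.leaf_units.values():
        forbidden |= _kmers(unit.bases, 21)

    left = _unique_random(rng, flank_len, forbidden)
    forbidden |= _kmers(left, 21)
    parts = [left]
    pos = flank_len
    intervals: dict[str, tuple[int, int]] = {}
    preceding: dict[str, tuple[int, int]] = {}
    names = truth.leaf_names()
    for i, name in enumerate(names):
        if i > 0 and spacer_len > 0:
            spacer = _unique_random(rng, spacer_len, forbidden)
            forbidden |= _kmers(spacer, 21)
            parts.append(spacer)
            preceding[name] = (pos, pos + spacer_len)
            pos += spacer_len
        elif i == 0:
            preceding[name] = (0, flank_len)
        # with spacer_len == 0, units after the first have no unique
        # preceding sequence and get no anchor-source entry
        unit = truth.leaf_units[name]
        parts.append(unit.bases)
        intervals[name] = (pos, pos + len(unit))
        pos += len(unit)
    right = _unique_random(rng, flank_len, forbidden)
    parts.append(right)

    truth.collapsed_contig = Sequence("collapsed_contig", "".join(parts))
    truth.unit_intervals = intervals
    truth.left_flank = Sequence("left_flank", left)
    truth.right_flank = Sequence("right_flank", right)
    truth.preceding_unique = preceding
    return truth


# ---------------------------------------------------------------------------
# Read sampling
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedRead:
    """One sampled read with its truth provenance."""

    seq: Sequence
    start: int            # origin on the contig, forward strand
    end: int
    strand: str           # '+' or '-'
    truth_leaf: str       # leaf name or 'flank'
    n_errors: int


#: error-type mix as fractions of the total error rate; approximates
#: CLR-like behaviour (substitution-heavy after basecalling)
DEFAULT_ERROR_MIX = (0.60, 0.25, 0.15)  # substitution, insertion, deletion


def _apply_errors(bases: str, error_rate: float, rng: np.random.Generator,
                  mix: tuple[float, float, float]) -> tuple[str, int]:
    """Apply per-base errors; returns (mutated bases, error op count)."""
    if error_rate == 0.0:
        return bases, 0
    arr = np.frombuffer(bases.encode(), dtype=np.uint8)
    n = arr.size
    u = rng.random(n)
    err_pos = np.nonzero(u < error_rate)[0]
    if err_pos.size == 0:
        return bases, 0
    sub_f, ins_f, _ = mix
    kind_draw = rng.random(err_pos.size)
    # 0 = substitution, 1 = insertion (random base before), 2 = deletion
    kinds = np.where(kind_draw < sub_f, 0, np.where(kind_draw < sub_f + ins_f, 1, 2))
    ins_bases = rng.choice(_BASES, size=err_pos.size)
    sub_shift = rng.integers(1, 4, size=err_pos.size)
    out: list[bytes] = []
    prev = 0
    for j, p in enumerate(err_pos):
        p = int(p)
        out.append(arr[prev:p].tobytes())
        k = kinds[j]
        if k == 0:
            idx = int(np.searchsorted(_BASES, arr[p]))
            out.append(_BASES[(idx + int(sub_shift[j])) % 4].tobytes())
            prev = p + 1
        elif k == 1:
            out.append(ins_bases[j].tobytes())
            prev = p  # base itself kept after the inserted one
        else:
            prev = p + 1  # deletion: skip the base
    out.append(arr[prev:].tobytes())
    return b"".join(out).decode(), int(err_pos.size)


def sample_reads(contig: Sequence, coverage: float, mean_len: float, sd_len: float,
                 error_rate: float, seed: int,
                 unit_intervals: dict[str, tuple[int, int]] | None = None,
                 error_mix: tuple[float, float, float] = DEFAULT_ERROR_MIX,
                 rc_prob: float = 0.5, min_len: int = 200) -> list[SimulatedRead]:
    """Sample error-prone reads until total bases >= coverage x contig length.

    Read starts are uniform over the contig; lengths are
    Normal(mean_len, sd_len) truncated to [min_len, contig length];
    each read is reverse-complemented with probability ``rc_prob``.
    The truth label is the unit whose interval contains the read
    midpoint (``'flank'`` otherwise).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if mean_len < min_len:
        raise ValueError(f"mean_len must be >= {min_len}")
    if not 0.0 <= error_rate < 0.5:
        raise ValueError("error_rate must be in [0, 0.5)")
    rng = np.random.default_rng(seed)
    L = len(contig)
    target_bases = coverage * L
    reads: list[SimulatedRead] = []
    total = 0
    i = 0
    intervals = unit_intervals or {}
    while total < target_bases:
        start = int(rng.integers(0, L))
        length = int(round(rng.normal(mean_len, sd_len)))
        length = max(min_len, min(length, L))
        end = min(L, start + length)
        if end - start < min_len:
            continue
        frag = contig.bases[start:end]
        mutated, n_err = _apply_errors(frag, error_rate, rng, error_mix)
        strand = "-" if rng.random() < rc_prob else "+"
        if strand == "-":
            mutated = revcomp(mutated)
        mid = (start + end) // 2
        label = "flank"
        for name, (s, e) in intervals.items():
            if s <= mid < e:
                label = name
                break
        reads.append(SimulatedRead(
            seq=Sequence(f"read{i:06d}", mutated),
            start=start, end=end, strand=strand, truth_leaf=label,
            n_errors=n_err,
        ))
        total += end - start
        i += 1
    return reads


# ---------------------------------------------------------------------------
# Benchmark scenario suite
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScenarioScale:
    """Problem-size knobs shared by every benchmark scenario."""

    unit_len: int = 20_000
    flank_len: int = 8_000
    spacer_len: int = 3_000
    identity: float = 0.995      # leaf-vs-root SD sequence identity
    coverage: float = 40.0
    error_rate: float = 0.15
    read_mean: float = 5_000.0
    read_sd: float = 1_000.0


#: desk-scale preset: full benchmark topology suite at sizes that run on
#: a single workstation core
DESK_SCALE = ScenarioScale()

#: original-scale preset (0.5 Mb contigs, 18 kb reads); slow — hours of
#: compute per scenario
PAPER_SCALE = ScenarioScale(unit_len=110_000, flank_len=20_000, spacer_len=10_000,
                            read_mean=18_000.0, read_sd=3_000.0)


def scenario_topologies() -> list[tuple[str, TopologySpec]]:
    """The ten benchmark evolutionary scenarios: flat with 2/4/8 leaves,
    three bifurcating shapes, cascading with 4/8, and two random with 10."""
    return [
        ("flat-2", TopologySpec("flat", 2)),
        ("flat-4", TopologySpec("flat", 4)),
        ("flat-8", TopologySpec("flat", 8)),
        ("bifurcating-4", TopologySpec("bifurcating", 4)),
        ("bifurcating-8", TopologySpec("bifurcating", 8)),
        ("bifurcating-8-skew", TopologySpec("bifurcating", 8, skew=2)),
        ("cascading-4", TopologySpec("cascading", 4)),
        ("cascading-8", TopologySpec("cascading", 8)),
        ("random-10a", TopologySpec("random", 10, seed=101)),
        ("random-10b", TopologySpec("random", 10, seed=202)),
    ]


def make_scenario(name: str, topo: TopologySpec, scale: ScenarioScale,
                  seed: int) -> tuple[SDTruthSet, list[SimulatedRead]]:
    """Generate one scenario: evolve units, build the contig, sample reads."""
    ss = np.random.SeedSequence([seed, zlib.crc32(name.encode()) % (2 ** 31)])
    s_root, s_evo, s_contig, s_reads = [int(c.generate_state(1)[0] % (2 ** 31))
                                        for c in ss.spawn(4)]
    root = Sequence("root_unit", random_bases(np.random.default_rng(s_root), scale.unit_len))
    edges, leaves = build_tree(topo)
    depth = max_leaf_depth(edges, leaves)
    rate = rate_for_leaf_identity(scale.identity, depth)
    truth = evolve_units(root, topo, rate, s_evo)
    truth = build_collapsed_contig(truth, scale.flank_len, s_contig,
                                   spacer_len=scale.spacer_len)
    reads = sample_reads(truth.collapsed_contig, scale.coverage, scale.read_mean,
                         scale.read_sd, scale.error_rate, s_reads,
                         unit_intervals=truth.unit_intervals)
    return truth, reads


def benchmark_suite(seed: int, scale: ScenarioScale = DESK_SCALE
                    ) -> list[tuple[str, SDTruthSet, list[SimulatedRead]]]:
    """Generate the full ten-scenario benchmark suite."""
    out = []
    for name, topo in scenario_topologies():
        truth, reads = make_scenario(name, topo, scale, seed)
        out.append((name, truth, reads))
    return out
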