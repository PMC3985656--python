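"""G-quadruplex topology inference from NOE connectivity.

The fold of an intramolecular quadruplex is read off three layers of NMR
evidence:

1. **Tetrads** — guanine imino(H1) -> aromatic(H8) NOEs trace the Hoogsteen
   hydrogen-bond direction around each G-tetrad; a tetrad is a directed
   4-cycle whose members come from four distinct G-tracts.
2. **Glycosidic conformations** — a syn guanine shows a short (strong)
   intra-residue H1'-H8 contact, an anti guanine a long (weak) one; within a
   tetrad, guanines from parallel strands share the same conformation and an
   antiparallel strand carries the opposite one.
3. **Loops** — a loop joining two parallel adjacent tracts wraps the groove
   exterior (double-chain-reversal); antiparallel adjacent tracts give a
   lateral loop, antiparallel diagonal tracts a diagonal loop.

The final label comes from a decision table over the orientation multiset
and the loop sequence: parallel propeller, antiparallel basket/chair, the
two (3+1) hybrids — distinguished by whether the double-chain-reversal loop
comes first (hybrid-I) or last (hybrid-II) — and (2+2) folds.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx

from .core import G4Sequence, PeakTable, ValidationError
from .noe import REFERENCE_DISTANCE, BuildupSeries, buildup_slope, calibrate_distance

#: Intra-residue H1'-H8 distance threshold separating syn (short) from anti.
SYN_ANTI_THRESHOLD = 3.3

#: Peaks below this fraction of the median tetrad-peak intensity are treated
#: as minor-conformation signals and excluded from connectivity analysis.
MINOR_INTENSITY_FLOOR = 0.10

TOPOLOGY_LABELS = (
    "parallel propeller",
    "antiparallel basket",
    "antiparallel chair",
    "hybrid-I (3+1)",
    "hybrid-II (3+1)",
    "(2+2)",
)


class TopologyError(ValueError):
    """Connectivity/conformation evidence does not support a consistent fold."""


@dataclass
class GlycosidicCall:
    residue_index: int
    conformation: str  # "syn" | "anti"
    evidence: float  # calibrated intra-residue H1'-H8 distance (angstroms)


@dataclass
class TetradModel:
    cycle: tuple[int, int, int, int]  # residue indices along H1 -> H8 direction
    layer: str = ""  # "top" | "central" | "bottom"
    sense: str = ""  # "clockwise" | "anticlockwise"

    def __post_init__(self) -> None:
        if len(set(self.cycle)) != 4:
            raise ValidationError("a tetrad needs 4 distinct residues")


@dataclass
class TopologyModel:
    tetrads: list[TetradModel]
    strand_orientations: dict[int, str]  # tract index -> "up" | "down"
    loops: list[str]
    glycosidic_pattern: list[tuple[str, str, str, str]]
    label: str
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Glycosidic calls
# ---------------------------------------------------------------------------


def classify_glycosidic(
    peaks: PeakTable,
    seq: G4Sequence,
    threshold: float = SYN_ANTI_THRESHOLD,
) -> tuple[list[GlycosidicCall], list[int]]:
    """Syn/anti calls for every tract guanine from intra-residue H1'-H8 NOEs.

    Distances are calibrated against the thymine H6-CH3 reference in the
    same table.  Returns (calls, uncalled residue indices); tetrad guanines
    without an intra-residue peak are listed rather than failing the run.
    """
    from .noe import find_reference_slope

    ref = find_reference_slope(peaks)
    groups = peaks.buildup_groups()
    dist: dict[int, float] = {}
    for (pair, _cond), plist in groups.items():
        (r1, a1), (r2, a2) = pair
        if r1 != r2 or {a1, a2} != {"H1'", "H8"}:
            continue
        est = buildup_slope(BuildupSeries.from_peaks(plist))
        if "zero_slope" in est.flags:
            continue
        dist[r1] = calibrate_distance(est.slope, ref.slope, REFERENCE_DISTANCE)
    calls: list[GlycosidicCall] = []
    uncalled: list[int] = []
    for tract in seq.g_tracts:
        for ridx in tract:
            if ridx in dist:
                conf = "syn" if dist[ridx] < threshold else "anti"
                calls.append(GlycosidicCall(ridx, conf, dist[ridx]))
            else:
                uncalled.append(ridx)
    return calls, uncalled


# ---------------------------------------------------------------------------
# Tetrad detection
# ---------------------------------------------------------------------------


def _tetrad_edges(peaks: PeakTable, seq: G4Sequence, intensity_floor_frac: float):
    """Directed guanine H1->H8 edges, minor-conformation peaks filtered out."""
    candidates = []
    for p in peaks.peaks:
        d = p.h1_to_h8()
        if d is None:
            continue
        donor, acceptor = d
        if donor == acceptor:
            continue
        if seq.tract_of(donor) is None or seq.tract_of(acceptor) is None:
            continue
        candidates.append((donor, acceptor, p.intensity))
    if not candidates:
        return []
    # pool intensity per directed pair (max over mixing times)
    pooled: dict[tuple[int, int], float] = defaultdict(float)
    for donor, acceptor, inten in candidates:
        pooled[(donor, acceptor)] = max(pooled[(donor, acceptor)], inten)
    med = sorted(pooled.values())[len(pooled) // 2]
    floor = intensity_floor_frac * med
    return [(d, a) for (d, a), i in pooled.items() if i >= floor]


def find_tetrad_cycles(
    edges: list[tuple[int, int]], tract_of
) -> set[tuple[int, int, int, int]]:
    """Directed 4-cycles over ``edges`` whose nodes lie in 4 distinct tracts.

    ``tract_of`` maps a residue index to its tract id (or None).  Cycles are
    returned in canonical rotation (starting at the smallest residue index);
    a node set traversable in both directions yields two distinct cycles.
    """
    g = nx.DiGraph(edges)
    cycles: set[tuple[int, int, int, int]] = set()
    for cyc in nx.simple_cycles(g, length_bound=4):
        if len(cyc) != 4:
            continue
        tracts = {tract_of(r) for r in cyc}
        if len(tracts) != 4 or None in tracts:
            continue
        i0 = cyc.index(min(cyc))
        cycles.add(tuple(cyc[i0:] + cyc[:i0]))
    return cycles


def detect_tetrads(
    peaks: PeakTable,
    seq: G4Sequence,
    intensity_floor_frac: float = MINOR_INTENSITY_FLOOR,
) -> list[TetradModel]:
    """Find G-tetrads as directed H1->H8 4-cycles spanning 4 distinct tracts.

    Layers (top/central/bottom) are ordered along the stack by the position
    of each tetrad's first-tract member (validated against inter-tetrad
    H1-H1 stacking NOEs when present).  The rotational sense of each cycle
    is labelled relative to the majority direction, which is called
    clockwise by convention.
    """
    edges = _tetrad_edges(peaks, seq, intensity_floor_frac)
    raw = find_tetrad_cycles(edges, seq.tract_of)
    # a tetrad observed in both traversal directions counts once
    cycles = []
    seen: set[frozenset] = set()
    for cyc in sorted(raw):
        key = frozenset(cyc)
        if key not in seen:
            seen.add(key)
            cycles.append(cyc)
    if not cycles:
        g = nx.DiGraph(edges)
        if g.number_of_nodes():
            comp = max(nx.weakly_connected_components(g), key=len)
            raise TopologyError(
                f"no tetrad 4-cycle found; largest connected component: {sorted(comp)}"
            )
        return []

    tetrads = [TetradModel(cycle=c) for c in sorted(cycles)]
    _assign_layers(tetrads, peaks, seq)
    _assign_sense(tetrads, seq)
    return tetrads


def _first_tract_rank(t: TetradModel, seq: G4Sequence) -> int:
    """Position within tract 0 of this tetrad's tract-0 member.

    Each tetrad holds exactly one guanine from each tract, so ranking the
    tetrads by where their first-tract member sits along that tract (5'->3')
    orders the stack without ties; with the 5'-most tract read top-to-bottom
    this reproduces the conventional top/central/bottom naming.
    """
    for r in t.cycle:
        if seq.tract_of(r) == 0:
            return seq.tract_position(r)
    raise TopologyError(f"tetrad {t.cycle} has no member in the first G-tract")


def _assign_layers(tetrads: list[TetradModel], peaks: PeakTable, seq: G4Sequence) -> None:
    names_by_count = {1: ["top"], 2: ["top", "bottom"], 3: ["top", "central", "bottom"]}
    if len(tetrads) > 3:
        raise TopologyError(f"{len(tetrads)} tetrad cycles found; expected <= 3")
    order = sorted(tetrads, key=lambda t: _first_tract_rank(t, seq))
    middle = _middle_from_stacking(tetrads, peaks)
    if middle is not None and len(order) == 3 and order[1] is not middle:
        raise TopologyError(
            "inter-tetrad H1-H1 stacking NOEs contradict the tract-position layer order"
        )
    for name, t in zip(names_by_count[len(tetrads)], order):
        t.layer = name
    tetrads.sort(key=order.index)


def _middle_from_stacking(
    tetrads: list[TetradModel], peaks: PeakTable
) -> TetradModel | None:
    """The central tetrad implied by inter-tetrad H1-H1 NOEs, if resolvable."""
    if len(tetrads) != 3:
        return None
    member_of = {r: i for i, t in enumerate(tetrads) for r in t.cycle}
    adj: set[tuple[int, int]] = set()
    for p in peaks.peaks:
        if p.atoms != frozenset({"H1"}):
            continue
        ta = member_of.get(p.a.residue_index)
        tb = member_of.get(p.b.residue_index)
        if ta is None or tb is None or ta == tb:
            continue
        adj.add((min(ta, tb), max(ta, tb)))
    if len(adj) != 2:
        return None  # too little (or contradictory) stacking evidence
    degree: dict[int, int] = defaultdict(int)
    for a, b in adj:
        degree[a] += 1
        degree[b] += 1
    middle = [i for i, d in degree.items() if d == 2]
    if len(middle) != 1:
        return None
    return tetrads[middle[0]]


def _cyclic_tract_order(t: TetradModel, seq: G4Sequence) -> tuple[int, ...]:
    return tuple(seq.tract_of(r) for r in t.cycle)


def _rotation_matches(order: tuple[int, ...], ref: tuple[int, ...]) -> bool:
    """True if ``order`` is a cyclic rotation of ``ref`` (same direction)."""
    n = len(ref)
    return any(tuple(ref[(i + k) % n] for i in range(n)) == order for k in range(n))


def _assign_sense(tetrads: list[TetradModel], seq: G4Sequence) -> None:
    if not tetrads:
        return
    ref = _cyclic_tract_order(tetrads[0], seq)
    dirs = []
    for t in tetrads:
        order = _cyclic_tract_order(t, seq)
        if _rotation_matches(order, ref):
            dirs.append(+1)
        elif _rotation_matches(order, tuple(reversed(ref))):
            dirs.append(-1)
        else:
            raise TopologyError(
                f"tetrad {t.cycle} is not laid out on the same tract square as {tetrads[0].cycle}"
            )
    majority = +1 if sum(dirs) >= 0 else -1
    for t, d in zip(tetrads, dirs):
        t.sense = "clockwise" if d == majority else "anticlockwise"


# ---------------------------------------------------------------------------
# Strand orientations
# ---------------------------------------------------------------------------


def infer_orientations(
    tetrads: list[TetradModel],
    glycosidic: list[GlycosidicCall],
    seq: G4Sequence,
) -> dict[int, str]:
    """Per-tract strand directions from within-tetrad glycosidic patterns.

    Within one tetrad, guanines on parallel strands share the glycosidic
    conformation and an antiparallel strand carries the opposite one.  Each
    tetrad therefore contributes same/opposite constraints between tracts;
    the constraint graph is 2-colored, conflicts are reported, and the
    majority color is labelled "up" (ties resolved by the 5'-most tract).
    """
    conf = {c.residue_index: c.conformation for c in glycosidic}
    missing = [r for t in tetrads for r in t.cycle if r not in conf]
    if missing:
        raise TopologyError(f"glycosidic conformation missing for residues {missing}")

    n_tracts = len(seq.g_tracts)
    # parity constraint graph: edge weight 0 = same orientation, 1 = opposite
    g = nx.Graph()
    g.add_nodes_from(range(n_tracts))
    conflicts: list[str] = []
    for t in tetrads:
        members = [(seq.tract_of(r), conf[r]) for r in t.cycle]
        for i in range(4):
            for j in range(i + 1, 4):
                (ta, ca), (tb, cb) = members[i], members[j]
                parity = 0 if ca == cb else 1
                if g.has_edge(ta, tb):
                    if g[ta][tb]["parity"] != parity:
                        conflicts.append(
                            f"tracts {ta} and {tb}: tetrad {t.cycle} contradicts earlier evidence"
                        )
                else:
                    g.add_edge(ta, tb, parity=parity)
    if conflicts:
        raise TopologyError("inconsistent glycosidic pattern: " + "; ".join(conflicts))

    color: dict[int, int] = {}
    for comp in nx.connected_components(g):
        start = min(comp)
        color[start] = 0
        stack = [start]
        while stack:
            u = stack.pop()
            for v in g.neighbors(u):
                want = color[u] ^ g[u][v]["parity"]
                if v in color:
                    if color[v] != want:
                        raise TopologyError(
                            f"inconsistent glycosidic pattern around tracts {u} and {v}"
                        )
                else:
                    color[v] = want
                    stack.append(v)
    ones = sum(color.values())
    majority = 1 if ones * 2 > n_tracts else 0
    if ones * 2 == n_tracts:
        majority = color[0]  # tie: the 5'-most tract defines "up"
    return {t: ("up" if c == majority else "down") for t, c in color.items()}


# ---------------------------------------------------------------------------
# Loops and the final label
# ---------------------------------------------------------------------------


def classify_loops(
    orientations: dict[int, str],
    seq: G4Sequence,
    arrangement: tuple[int, ...] | None = None,
) -> list[str]:
    """Classify the n_tracts - 1 loops joining consecutive G-tracts.

    ``arrangement`` is the cyclic order of tracts around the tetrad square
    (taken from a detected tetrad); without it, sequence order is assumed.
    Parallel adjacent tracts give a double-chain-reversal loop, antiparallel
    adjacent tracts a lateral loop, antiparallel diagonal tracts a diagonal
    loop.
    """
    n = len(seq.g_tracts)
    if arrangement is None:
        arrangement = tuple(range(n))
    loops: list[str] = []
    for t in range(n - 1):
        a, b = t, t + 1
        parallel = orientations[a] == orientations[b]
        ia, ib = arrangement.index(a), arrangement.index(b)
        adjacent = (ia - ib) % n in (1, n - 1)
        if parallel and adjacent:
            loops.append("double-chain-reversal")
        elif not parallel and adjacent:
            loops.append("lateral")
        elif not parallel and not adjacent:
            loops.append("diagonal")
        else:
            raise TopologyError(
                f"loop {t}: parallel tracts across the diagonal are not a valid G4 geometry"
            )
    return loops


def classify_topology(
    tetrads: list[TetradModel],
    orientations: dict[int, str],
    loops: list[str],
    glycosidic: list[GlycosidicCall],
    seq: G4Sequence,
) -> TopologyModel:
    """Assign the named fold from the orientation multiset and loop sequence."""
    conf = {c.residue_index: c.conformation for c in glycosidic}
    pattern = [tuple(conf.get(r, "?") for r in t.cycle) for t in tetrads]
    n_down = sum(1 for v in orientations.values() if v == "down")
    notes: list[str] = []
    label = "unclassified"
    if n_down == 0:
        if all(l == "double-chain-reversal" for l in loops):
            label = "parallel propeller"
        else:
            notes.append("all-parallel tracts but non-propeller loops")
    elif n_down == 1:
        if loops == ["double-chain-reversal", "lateral", "lateral"]:
            label = "hybrid-I (3+1)"
        elif loops == ["lateral", "lateral", "double-chain-reversal"]:
            label = "hybrid-II (3+1)"
        else:
            notes.append(
                "(3+1) orientations with loop sequence "
                f"{loops}; nearest folds: hybrid-I, hybrid-II"
            )
    elif n_down == 2:
        if loops == ["lateral", "diagonal", "lateral"]:
            label = "antiparallel basket"
        elif all(l == "lateral" for l in loops):
            label = "antiparallel chair"
        elif "double-chain-reversal" in loops:
            label = "(2+2)"
        else:
            notes.append(f"2+2 orientations with loop sequence {loops}")
    else:
        notes.append("more tracts down than up after majority normalization")
    return TopologyModel(
        tetrads=tetrads,
        strand_orientations=dict(sorted(orientations.items())),
        loops=loops,
        glycosidic_pattern=pattern,
        label=label,
        notes=notes,
    )


def infer_topology(
    peaks: PeakTable,
    seq: G4Sequence,
    syn_threshold: float = SYN_ANTI_THRESHOLD,
    intensity_floor_frac: float = MINOR_INTENSITY_FLOOR,
) -> TopologyModel:
    """End-to-end topology call: tetrads, conformations, orientations, loops, label."""
    tetrads = detect_tetrads(peaks, seq, intensity_floor_frac)
    if not tetrads:
        raise TopologyError("no tetrads detected")
    calls, uncalled = classify_glycosidic(peaks, seq, syn_threshold)
    orientations = infer_orientations(tetrads, calls, seq)
    arrangement = _cyclic_tract_order(tetrads[0], seq)
    loops = classify_loops(orientations, seq, arrangement)
    model = classify_topology(tetrads, orientations, loops, calls, seq)
    if uncalled:
        model.notes.append(f"glycosidic conformation uncalled for residues {uncalled}")
    return model
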