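"""Tetrad detection, glycosidic calls, orientations, loops, fold labels."""

import itertools

import numpy as np
import pytest

from g4ionx.core import AtomRef, G4Sequence, NOESYPeak, PeakTable
from g4ionx.noe import REFERENCE_DISTANCE
from g4ionx.synthetic import (
    CANONICAL_TOPOLOGIES,
    ScenarioConfig,
    fold_syn_residues,
    fold_tetrad_cycles,
    gen_noesy_peaks,
)
from g4ionx.topology import (
    TopologyError,
    classify_glycosidic,
    classify_loops,
    detect_tetrads,
    find_tetrad_cycles,
    infer_orientations,
    infer_topology,
)

# The three published Tel23 tetrad cycles (imino -> aromatic direction).
TEL23_CYCLES = [(3, 21, 17, 9), (4, 10, 16, 22), (5, 11, 15, 23)]
TEL23_SYN = {3, 9, 21, 15, 16}


def hybrid1_table(noise=0.0, seed=0):
    return gen_noesy_peaks(
        ScenarioConfig(seed=seed, scenario="canonical_topology:hybrid-I (3+1)", noise_sd=noise)
    )


class TestGlycosidic:
    def test_five_syn_calls_on_tel23_fixture(self, seq):
        calls, uncalled = classify_glycosidic(hybrid1_table(), seq)
        assert not uncalled
        syn = {c.residue_index for c in calls if c.conformation == "syn"}
        assert syn == TEL23_SYN

    def test_all_weak_peaks_give_zero_syn(self, seq):
        dists = [
            (AtomRef(r, "H1'", "G"), AtomRef(r, "H8", "G"), 3.7)
            for tract in seq.g_tracts
            for r in tract
        ]
        table = gen_noesy_peaks(
            ScenarioConfig(seed=0, scenario="tel23_noesy_na", noise_sd=0.0),
            distances=dists,
        )
        calls, _ = classify_glycosidic(table, seq)
        assert all(c.conformation == "anti" for c in calls)

    def test_threshold_sweep_is_stable(self, seq):
        """Syn (2.5 A) and anti (3.7 A) bracket any threshold in 2.6-3.6 A."""
        table = hybrid1_table()
        reference = None
        for thr in np.arange(2.6, 3.601, 0.1):
            calls, _ = classify_glycosidic(table, seq, threshold=float(thr))
            syn = frozenset(c.residue_index for c in calls if c.conformation == "syn")
            if reference is None:
                reference = syn
            assert syn == reference == frozenset(TEL23_SYN)

    def test_missing_intra_residue_peak_is_reported_not_fatal(self, seq):
        table = hybrid1_table()
        table.peaks = [
            p
            for p in table.peaks
            if not (p.atoms == frozenset({"H1'", "H8"}) and p.a.residue_index == 22)
        ]
        calls, uncalled = classify_glycosidic(table, seq)
        assert uncalled == [22]
        assert len(calls) == 11


class TestDetectTetrads:
    def test_published_connectivity_returns_published_tetrads(self, seq):
        tetrads = detect_tetrads(hybrid1_table(), seq)
        assert [t.cycle for t in tetrads] == TEL23_CYCLES
        assert [t.layer for t in tetrads] == ["top", "central", "bottom"]
        assert [t.sense for t in tetrads] == ["anticlockwise", "clockwise", "clockwise"]

    def test_empty_table_returns_nothing(self, seq):
        assert detect_tetrads(PeakTable([], source="synthetic"), seq) == []

    def test_peak_order_invariance(self, seq, rng):
        table = hybrid1_table()
        shuffled = list(table.peaks)
        rng.shuffle(shuffled)
        tetrads = detect_tetrads(PeakTable(shuffled, source="synthetic"), seq)
        assert [t.cycle for t in tetrads] == TEL23_CYCLES

    def test_minor_conformation_peaks_filtered(self, seq):
        """A weak spurious H1->H8 peak below the intensity floor is ignored."""
        table = hybrid1_table()
        # weak edges that would close a spurious 4th cycle (3,11,15,23) via
        # the genuine 11->15 and 15->23 links if not filtered out
        ghost = [(3, 11), (23, 3)]
        extra = [
            NOESYPeak(AtomRef(a, "H1", "G"), AtomRef(b, "H8", "G"), tm, 0.01 * tm, "na")
            for a, b in ghost
            for tm in (50.0, 100.0, 150.0, 200.0)
        ]
        table2 = PeakTable(table.peaks + extra, source="synthetic")
        tetrads = detect_tetrads(table2, seq)
        assert [t.cycle for t in tetrads] == TEL23_CYCLES

    def test_matches_exhaustive_enumeration_on_random_graphs(self):
        """Cycle finding agrees with brute force over all ordered 4-subsets."""
        seq16 = G4Sequence.from_string("GGGGTGGGGTGGGGTGGGG")
        nodes = [r for tract in seq16.g_tracts for r in tract]
        rng = np.random.default_rng(7)
        for _ in range(25):
            edges = [
                (a, b)
                for a in nodes
                for b in nodes
                if a != b and rng.random() < 0.12
            ]
            found = find_tetrad_cycles(edges, seq16.tract_of)
            eset = set(edges)
            brute = set()
            for quad in itertools.permutations(nodes, 4):
                if len({seq16.tract_of(r) for r in quad}) != 4:
                    continue
                if all(
                    (quad[i], quad[(i + 1) % 4]) in eset for i in range(4)
                ):
                    i0 = quad.index(min(quad))
                    brute.add(tuple(quad[i0:] + quad[:i0]))
            assert found == brute


class TestOrientations:
    def test_tel23_has_exactly_one_antiparallel_tract(self, seq):
        table = hybrid1_table()
        tetrads = detect_tetrads(table, seq)
        calls, _ = classify_glycosidic(table, seq)
        orient = infer_orientations(tetrads, calls, seq)
        assert sorted(orient.values()).count("down") == 1
        assert orient[2] == "down"  # the G15-G17 tract

    def test_all_anti_gives_all_parallel(self, seq):
        table = gen_noesy_peaks(
            ScenarioConfig(seed=0, scenario="canonical_topology:parallel propeller", noise_sd=0.0)
        )
        tetrads = detect_tetrads(table, seq)
        calls, _ = classify_glycosidic(table, seq)
        orient = infer_orientations(tetrads, calls, seq)
        assert set(orient.values()) == {"up"}

    def test_contradictory_pattern_raises(self, seq):
        """Glycosidic calls incompatible across tetrads trigger an inference error."""
        from g4ionx.topology import GlycosidicCall, TetradModel

        tetrads = [
            TetradModel(cycle=(3, 9, 15, 21)),
            TetradModel(cycle=(4, 10, 16, 22)),
        ]
        # tetrad 1 says tracts 0,1 same; tetrad 2 says they differ
        calls = [
            GlycosidicCall(3, "syn", 2.5),
            GlycosidicCall(9, "syn", 2.5),
            GlycosidicCall(15, "anti", 3.7),
            GlycosidicCall(21, "anti", 3.7),
            GlycosidicCall(4, "syn", 2.5),
            GlycosidicCall(10, "anti", 3.7),
            GlycosidicCall(16, "anti", 3.7),
            GlycosidicCall(22, "anti", 3.7),
        ]
        with pytest.raises(TopologyError, match="inconsistent"):
            infer_orientations(tetrads, calls, seq)


class TestLoops:
    def test_tel23_loop_sequence(self, seq):
        orient = {0: "up", 1: "up", 2: "down", 3: "up"}
        loops = classify_loops(orient, seq, arrangement=(0, 3, 2, 1))
        assert loops == ["double-chain-reversal", "lateral", "lateral"]

    def test_parallel_propeller_loops(self, seq):
        orient = {t: "up" for t in range(4)}
        loops = classify_loops(orient, seq, arrangement=(0, 1, 2, 3))
        assert loops == ["double-chain-reversal"] * 3

    def test_basket_loops(self, seq):
        orient = {0: "up", 1: "down", 2: "up", 3: "down"}
        loops = classify_loops(orient, seq, arrangement=(0, 1, 3, 2))
        assert loops == ["lateral", "diagonal", "lateral"]

    def test_loop_count_matches_tract_count(self, seq):
        for label in CANONICAL_TOPOLOGIES:
            table = gen_noesy_peaks(
                ScenarioConfig(seed=0, scenario=f"canonical_topology:{label}", noise_sd=0.0)
            )
            model = infer_topology(table, seq)
            assert len(model.loops) == len(seq.g_tracts) - 1


class TestClassification:
    def test_tel23_is_hybrid_one(self, seq):
        model = infer_topology(hybrid1_table(), seq)
        assert model.label == "hybrid-I (3+1)"
        assert [t.cycle for t in model.tetrads] == TEL23_CYCLES
        assert model.loops == ["double-chain-reversal", "lateral", "lateral"]
        assert model.glycosidic_pattern[0] == ("syn", "syn", "anti", "syn")
        assert model.glycosidic_pattern[1] == ("anti", "anti", "syn", "anti")

    @pytest.mark.parametrize("label", CANONICAL_TOPOLOGIES)
    def test_round_trip_all_canonical_folds(self, seq, label):
        table = gen_noesy_peaks(
            ScenarioConfig(seed=0, scenario=f"canonical_topology:{label}", noise_sd=0.0)
        )
        model = infer_topology(table, seq)
        assert model.label == label

    def test_labels_are_distinct_and_deterministic(self, seq):
        labels = []
        for label in CANONICAL_TOPOLOGIES:
            table = gen_noesy_peaks(
                ScenarioConfig(seed=1, scenario=f"canonical_topology:{label}", noise_sd=0.0)
            )
            labels.append(infer_topology(table, seq).label)
        assert len(set(labels)) == len(CANONICAL_TOPOLOGIES)

    def test_mirrored_loop_order_is_hybrid_two(self, seq):
        """Loops [lateral, lateral, double-chain-reversal] map to hybrid-II."""
        table = gen_noesy_peaks(
            ScenarioConfig(seed=0, scenario="canonical_topology:hybrid-II (3+1)", noise_sd=0.0)
        )
        model = infer_topology(table, seq)
        assert model.loops == ["lateral", "lateral", "double-chain-reversal"]
        assert model.label == "hybrid-II (3+1)"

    def test_unknown_generator_label_lists_available(self):
        with pytest.raises(ValueError, match="available"):
            gen_noesy_peaks(
                ScenarioConfig(seed=0, scenario="canonical_topology:moebius", noise_sd=0.0)
            )
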