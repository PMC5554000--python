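"""Segmentation, event classification, and simulator round trips."""

import numpy as np
import pandas as pd
import pytest

import tetradscape as ts
from tetradscape.events import call_events, segment_chromosome
from tetradscape.markers import MarkerMap
from tetradscape.simulate import TetradGenotypes


def tetrad_from_rows(rows, positions, chrom="c1"):
    codes = np.asarray(rows, dtype=np.int8)
    mm = MarkerMap(
        pd.DataFrame(
            {
                "chrom": [chrom] * len(positions),
                "pos": positions,
                "allele_P1": ["A"] * len(positions),
                "allele_P2": ["G"] * len(positions),
            }
        )
    )
    return TetradGenotypes(mm, codes, "t1")


def call(rows, positions, chrom_len, **kw):
    codes = np.asarray(rows, dtype=np.int8)
    segs = segment_chromosome(codes, "c1")
    return call_events(segs, np.asarray(positions, float), chrom="c1", chrom_end=chrom_len, **kw)


class TestSegmentation:
    def test_constant_matrix_is_one_segment(self):
        segs = segment_chromosome(np.tile([0, 1, 0, 1], (6, 1)))
        assert len(segs) == 1 and segs[0].n_markers == 6

    def test_single_switch_splits_in_two(self):
        rows = np.tile([0, 0, 1, 1], (8, 1))
        rows[4:, 0] = 1
        rows[4:, 2] = 0
        segs = segment_chromosome(rows)
        assert [s.n_markers for s in segs] == [4, 4]

    def test_alternating_patterns_worst_case(self):
        rows = np.array([[0, 0, 1, 1], [0, 1, 0, 1]] * 4)
        segs = segment_chromosome(rows)
        assert len(segs) == 8

    def test_segments_tile_markers_exactly(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(0, 2, size=(50, 4))
        segs = segment_chromosome(rows)
        covered = [(s.start_idx, s.end_idx) for s in segs]
        assert covered[0][0] == 0 and covered[-1][1] == 50
        assert all(a[1] == b[0] for a, b in zip(covered, covered[1:]))


class TestCallEvents:
    def test_plain_co_between_differing_anchors(self):
        # anchors (P1,P1,P2,P2) then (P2,P1,P2,P1): spores 0 and 3 switch
        rows = [[0, 0, 1, 1]] * 4 + [[1, 0, 1, 0]] * 4
        events = call(rows, np.arange(8) * 1000, 10_000)
        assert [e.cls for e in events] == ["CO_plain"]
        assert events[0].spores == (0, 3)

    def test_nco31_needs_three_markers(self):
        base = [0, 0, 1, 1]
        conv = [1, 0, 1, 1]  # spore 0 converted
        rows3 = [base] * 3 + [conv] * 3 + [base] * 3
        rows2 = [base] * 3 + [conv] * 2 + [base] * 3
        ev3 = call(rows3, np.arange(9) * 1000, 10_000)
        ev2 = call(rows2, np.arange(8) * 1000, 10_000)
        assert [e.cls for e in ev3] == ["NCO_31"]
        assert ev3[0].spores == (0,)
        assert ev2 == []  # below the minimum marker rule: no event

    def test_two_marker_tract_with_phase_change_is_plain_co(self):
        base = [0, 0, 1, 1]
        conv = [1, 0, 1, 1]
        right = [1, 0, 0, 1]
        rows = [base] * 3 + [conv] * 2 + [right] * 3
        events = call(rows, np.arange(8) * 1000, 10_000)
        assert [e.cls for e in events] == ["CO_plain"]

    def test_co_with_gc31(self):
        base = [0, 0, 1, 1]
        conv = [1, 0, 1, 1]
        right = [1, 0, 0, 1]  # spores 0, 2 switched
        rows = [base] * 3 + [conv] * 3 + [right] * 3
        events = call(rows, np.arange(9) * 1000, 10_000)
        assert [e.cls for e in events] == ["CO_with_GC31"]
        assert events[0].spores == (0, 2)

    def test_internal_loh_has_two_lohips(self):
        base = [0, 0, 1, 1]
        rows = [base] * 3 + [[1, 1, 1, 1]] * 20 + [base] * 3
        pos = np.concatenate([np.arange(3) * 200, 10_000 + np.arange(20) * 11_800, [260_000, 260_200, 260_400]])
        events = call(rows, pos, 300_000)
        loh = [e for e in events if e.cls == "LOH"]
        assert len(loh) == 1
        assert loh[0].lohips == 2 and not loh[0].telomeric
        assert loh[0].retained_parent == "P2"
        assert loh[0].size_bp > 200_000

    def test_boundary_touching_loh_is_telomeric(self):
        rows = [[0, 0, 1, 1]] * 3 + [[0, 0, 0, 0]] * 10
        pos = np.concatenate([np.arange(3) * 200, 5_000 + np.arange(10) * 2_000])
        events = call(rows, pos, 50_000)
        assert [e.cls for e in events] == ["LOH"]
        assert events[0].telomeric and events[0].lohips == 1
        assert events[0].end == 50_000

    def test_double_co_all_four_spores(self):
        rows = [[0, 0, 1, 1]] * 4 + [[1, 1, 0, 0]] * 4
        events = call(rows, np.arange(8) * 1000, 10_000)
        assert [e.cls for e in events] == ["doubleCO"]
        assert events[0].spores == (0, 1, 2, 3)

    def test_double_co_with_gc40(self):
        rows = [[0, 0, 1, 1]] * 3 + [[1, 1, 1, 1]] * 3 + [[1, 1, 0, 0]] * 3
        events = call(rows, np.arange(9) * 1000, 10_000)
        assert [e.cls for e in events] == ["doubleCO_with_GC40"]

    def test_short_40_is_nco40(self):
        base = [0, 0, 1, 1]
        rows = [base] * 3 + [[0, 0, 0, 0]] * 3 + [base] * 3
        events = call(rows, np.arange(9) * 500, 10_000)
        assert [e.cls for e in events] == ["NCO_40"]
        assert events[0].retained_parent == "P1"

    def test_exactly_threshold_size_is_not_loh(self):
        # midpoint-convention size exactly 10 kb stays a 4:0 conversion
        base = [0, 0, 1, 1]
        rows = [base] * 2 + [[1, 1, 1, 1]] * 5 + [base] * 2
        pos = [0, 1000, 2000, 4000, 6000, 8000, 10_000, 11_000, 12_000]
        events = call(rows, np.asarray(pos, float), 20_000)
        # tract spans midpoints 1500 .. 10500 -> 9 kb
        assert [e.cls for e in events] == ["NCO_40"]

    def test_fewer_than_two_markers_warns(self):
        with pytest.warns(UserWarning):
            out = call([[0, 0, 1, 1]], [100.0], 1_000)
        assert out == []


class TestEventSize:
    def test_midpoint_arithmetic(self):
        # tract markers at 10-12 kb, anchors at 9 and 13 kb -> [9.5, 12.5) kb
        base = [0, 0, 1, 1]
        rows = [base] * 1 + [[1, 0, 1, 1]] * 3 + [base] * 1
        pos = np.array([9_000, 10_000, 11_000, 12_000, 13_000], float)
        events = call(rows, pos, 20_000)
        e = events[0]
        assert (e.start, e.end) == (9_500, 12_500)
        assert ts.event_size(e) == 3_000

    def test_telomeric_tract_extends_to_boundary(self):
        rows = [[0, 0, 1, 1]] * 1 + [[1, 0, 1, 1]] * 3
        pos = np.array([9_000, 10_000, 11_000, 12_000], float)
        events = call(rows, pos, 50_000)
        e = events[0]
        assert (e.start, e.end) == (9_500, 50_000)


class TestInvariants:
    def test_complement_symmetry(self, genome, dense_markers, params):
        tet, _ = ts.simulate_rtg_then_meiosis(genome, dense_markers, params, seed=5)
        flipped = TetradGenotypes(dense_markers, (1 - tet.codes).astype(np.int8), tet.name)
        a = ts.call_tetrad(tet, chrom_lengths=genome.chrom_lengths)
        b = ts.call_tetrad(flipped, chrom_lengths=genome.chrom_lengths)
        assert [(e.cls, e.chrom, e.start, e.end) for e in a] == [
            (e.cls, e.chrom, e.start, e.end) for e in b
        ]
        for ea, eb in zip(a, b):
            if ea.retained_parent:
                assert {ea.retained_parent, eb.retained_parent} == {"P1", "P2"}

    def test_min_gc_markers_monotonicity(self, genome, dense_markers, params):
        tet, _ = ts.simulate_meiosis(genome, dense_markers, params, seed=6)
        gc_classes = ("CO_with_GC31", "NCO_31", "NCO_40", "doubleCO_with_GC40")
        counts = []
        for k in (2, 3, 5, 8):
            evs = ts.call_tetrad(tet, chrom_lengths=genome.chrom_lengths, min_gc_markers=k)
            counts.append(sum(e.cls in gc_classes for e in evs))
        assert counts == sorted(counts, reverse=True)

    def test_lohip_arithmetic(self, genome, dense_markers, params):
        for seed in range(6):
            tet, _ = ts.simulate_rtg_then_meiosis(genome, dense_markers, params, seed)
            evs = ts.call_tetrad(tet, chrom_lengths=genome.chrom_lengths)
            loh = [e for e in evs if e.cls == "LOH"]
            internal = sum(1 for e in loh if not e.telomeric)
            telomeric = sum(1 for e in loh if e.telomeric and e.lohips == 1)
            whole = sum(1 for e in loh if e.lohips == 0)
            assert sum(e.lohips for e in loh) == 2 * internal + telomeric
            assert internal + telomeric + whole == len(loh)


def resolvable_chromosomes(truth, markers, genome, pad_markers=1):
    """Chromosomes where every truth event is separable by the caller.

    Requires all truth tracts pairwise separated by at least one marker and
    every visible CO tract flanked by markers on both sides.
    """
    out = []
    for chrom, L in genome.chromosomes:
        pos = markers.positions(chrom)
        evs = [e for e in truth.events if e.chrom == chrom and e.provenance != "rtg_prophase"]
        tracts = sorted((e.start, e.end, e) for e in evs if e.visible or e.cls == "CO")
        ok = True
        for (s0, e0, _), (s1, e1, _) in zip(tracts, tracts[1:]):
            between = np.searchsorted(pos, s1) - np.searchsorted(pos, e0)
            if between < pad_markers:
                ok = False
        for s, e, ev in tracts:
            if ev.cls == "CO" and ev.visible:
                if np.searchsorted(pos, s) == 0 or np.searchsorted(pos, e) >= pos.size:
                    ok = False
        if ok:
            out.append(chrom)
    return out


class TestRoundTrip:
    def test_caller_recovers_visible_truth_cos_exactly(self, genome, dense_markers, params):
        n_res = n_tot = 0
        for seed in range(12):
            tet, truth = ts.simulate_meiosis(genome, dense_markers, params, seed)
            evs = ts.call_tetrad(tet, chrom_lengths=genome.chrom_lengths)
            res = resolvable_chromosomes(truth, dense_markers, genome)
            n_res += len(res)
            n_tot += len(genome.chromosomes)
            for chrom in res:
                truth_n = sum(
                    1 for e in truth.select("CO") if e.chrom == chrom and e.visible
                )
                called_n = sum(
                    1 for e in evs if e.chrom == chrom and e.cls in ("CO_plain", "CO_with_GC31")
                )
                assert called_n == truth_n, (seed, chrom)
        assert n_res / n_tot >= 0.9  # the exactness check is not vacuous

    def test_loh_boundaries_within_one_marker_interval(self, genome, dense_markers, params):
        max_gap = 0.0
        for seed in range(6):
            tet, truth = ts.simulate_rtg_then_meiosis(genome, dense_markers, params, seed)
            evs = ts.call_tetrad(tet, chrom_lengths=genome.chrom_lengths)
            called = [e for e in evs if e.cls == "LOH"]
            truth_loh = truth.select("LOH", "rtg")
            assert len(called) == len(truth_loh)
            for t in truth_loh:
                best = min(
                    max(abs(c.start - t.start), abs(c.end - t.end))
                    for c in called
                    if c.chrom == t.chrom
                )
                pos = dense_markers.positions(t.chrom)
                local_gap = np.diff(pos).max()
                assert best <= local_gap

    def test_rtg_double_cos_recovered(self, genome, dense_markers, params):
        for seed in range(6):
            tet, truth = ts.simulate_rtg_then_meiosis(genome, dense_markers, params, seed)
            evs = ts.call_tetrad(tet, chrom_lengths=genome.chrom_lengths)
            called = sum(1 for e in evs if e.cls.startswith("doubleCO"))
            assert called == len(truth.select("doubleCO", "rtg"))


class TestPooledLOH:
    def test_fully_heterozygous_tetrad_is_empty(self, genome, dense_markers):
        quiet = ts.SimParams(co_per_meiosis_mean=0, nco_per_meiosis_mean=0)
        tet, _ = ts.simulate_meiosis(genome, dense_markers, quiet, 0)
        assert ts.detect_loh_pooled(tet) == []

    def test_jaccard_agreement_with_caller(self, genome, dense_markers, params):
        inter = union = 0.0
        for seed in range(15):
            tet, _ = ts.simulate_rtg_then_meiosis(genome, dense_markers, params, seed)
            pooled = ts.detect_loh_pooled(tet)
            called = [
                (e.chrom, e.start, e.end)
                for e in ts.call_tetrad(tet, chrom_lengths=genome.chrom_lengths)
                if e.cls == "LOH"
            ]
            for chrom, _ in genome.chromosomes:
                a = [(s, e) for c, s, e in pooled if c == chrom]
                b = [(s, e) for c, s, e in called if c == chrom]
                grid = np.linspace(0, genome.chrom_lengths[chrom], 4000)
                in_a = np.zeros(grid.size, bool)
                in_b = np.zeros(grid.size, bool)
                for s, e in a:
                    in_a |= (grid >= s) & (grid < e)
                for s, e in b:
                    in_b |= (grid >= s) & (grid < e)
                inter += (in_a & in_b).sum()
                union += (in_a | in_b).sum()
        assert union > 0
        assert inter / union >= 0.95


class TestDropNA:
    def test_na_marker_removed(self):
        codes = np.array([[0, 1, 0, 1], [0, -1, 1, 1], [1, 0, 1, 0]], dtype=np.int8)
        kept, idx = ts.drop_na_markers(codes)
        assert list(idx) == [0, 2]
        assert kept.shape == (2, 4)

    def test_no_na_is_identity(self):
        codes = np.array([[0, 1, 0, 1]] * 3, dtype=np.int8)
        kept, idx = ts.drop_na_markers(codes)
        assert np.array_equal(kept, codes) and list(idx) == [0, 1, 2]

    def test_all_na_gives_empty_calls(self, params):
        g = ts.GenomeModel(chromosomes=(("c1", 10_000),), centromeres={"c1": 5_000})
        mm = ts.place_markers(g, 500, seed=1)
        codes = np.full((len(mm), 4), -1, dtype=np.int8)
        tet = TetradGenotypes(mm, codes, "t")
        assert ts.call_tetrad(tet, chrom_lengths=g.chrom_lengths) == []
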