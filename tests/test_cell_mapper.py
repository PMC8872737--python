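"""Drop rules, per-gap count verification and the mapping table."""

import numpy as np
import pytest

from beadmap import cell_mapper as cm
from beadmap import marker_codec as mc
from beadmap import stream_sim as ss
from beadmap.mc_experiments import run_pipeline_once
from beadmap.seq_align import classify_errors, global_align


def pipeline(stream_a, stream_b):
    mseq_a, mseq_b = mc.encode(stream_a), mc.encode(stream_b)
    aln = global_align(mseq_a.symbols, mseq_b.symbols)
    report = classify_errors(aln)
    segments = cm.match_segments(mseq_a, mseq_b, aln, report)
    return mseq_a, mseq_b, aln, report, segments


def make_stream(pattern: str) -> ss.EventStream:
    events = []
    for i, ch in enumerate(pattern):
        kind = "cell" if ch == "." else "marker"
        events.append(ss.Event(uid=i, kind=kind, source_index=i,
                               symbol=None if ch == "." else ch))
    return ss.EventStream(events)


def line_positions(stream):
    return {e.uid: (e.source_index * 250.0, 0.0) for e in stream.events}


class TestMatchSegments:
    def test_identical_streams_interior_matched(self):
        s = make_stream(".A..T")
        mseq_a, mseq_b, aln, report, segments = pipeline(s, s)
        statuses = [seg.status for seg in segments]
        assert statuses == [cm.STATUS_FLANK, cm.STATUS_MATCHED, cm.STATUS_FLANK]
        assert segments[1].count_a == segments[1].count_b == 2

    def test_count_mismatch_dropped(self):
        a = make_stream("A..T")
        b = make_stream("A.T")
        *_, segments = pipeline(a, b)
        assert segments[1].status == cm.STATUS_COUNT
        assert (segments[1].count_a, segments[1].count_b) == (2, 1)

    def test_marker_deletion_drops_adjacent_gaps(self):
        a = make_stream("A.T.C.A")  # four markers, three interior gaps
        b = make_stream("A.T..A")  # C missing on the plate side
        *_, segments = pipeline(a, b)
        interior = [seg.status for seg in segments[1:-1]]
        # both gaps flanking the deleted C are unverifiable
        assert interior == [cm.STATUS_MATCHED, cm.STATUS_MARKER, cm.STATUS_MARKER]

    def test_partition_covers_every_cell(self):
        stream = ss.generate_stream(200, seed=1)
        plate, _ = ss.apply_deletion(stream, 0.05, seed=2)
        mseq_a, *_, segments = pipeline(stream, plate)
        assert sum(seg.count_a for seg in segments) == mseq_a.n_cells
        assert len(segments) == len(mseq_a.symbols) + 1

    def test_inconsistent_alignment_rejected(self):
        a, b = make_stream("A.T"), make_stream("A.T")
        mseq_a, mseq_b = mc.encode(a), mc.encode(b)
        aln = global_align("AC", "AC")
        with pytest.raises(ValueError):
            cm.match_segments(mseq_a, mseq_b, aln, classify_errors(aln))


class TestBuildMapping:
    def test_zero_error_maps_every_interior_cell(self):
        stream = ss.generate_stream(100, seed=3)
        mseq_a, mseq_b, aln, report, segments = pipeline(stream, stream)
        table = cm.build_mapping(segments, mseq_a, mseq_b, line_positions(stream))
        cells = table[table.entity == "cell"]
        assert len(cells) == sum(mseq_a.interior_gap_counts)
        assert (cells.image_uid == cells.plate_uid).all()

    def test_dropped_segment_cells_omitted(self):
        a = make_stream("A...T.C")
        b = make_stream("A..T.C")  # one cell missing in the first gap
        mseq_a, mseq_b, aln, report, segments = pipeline(a, b)
        table = cm.build_mapping(segments, mseq_a, mseq_b, line_positions(b))
        cells = table[table.entity == "cell"]
        assert len(cells) == 1  # only the verified 1-cell gap survives
        assert segments[1].status == cm.STATUS_COUNT

    def test_out_of_focus_kept_but_unusable(self):
        stream = ss.generate_stream(60, p_out_of_focus=0.5, seed=4)
        mseq_a, mseq_b, aln, report, segments = pipeline(stream, stream)
        oof = {e.uid for e in stream.cells if e.out_of_focus}
        table = cm.build_mapping(segments, mseq_a, mseq_b, line_positions(stream), oof)
        cells = table[table.entity == "cell"]
        assert set(cells[~cells.usable].image_uid) <= oof
        assert (~cells.usable).sum() == len(oof & set(cells.image_uid))

    def test_missing_position_is_error(self):
        stream = make_stream("A.T")
        mseq_a, mseq_b, aln, report, segments = pipeline(stream, stream)
        with pytest.raises(ValueError):
            cm.build_mapping(segments, mseq_a, mseq_b, {})


class TestRetentionStats:
    def test_zero_error_run(self):
        stats = run_pipeline_once(150, 2.0, 0.0, 0.0, seed=5)
        assert stats["retention_fraction"] == 1.0
        assert stats["misassignment_rate"] == 0.0
        assert stats["usable_fraction"] == 1.0

    def test_single_cell_deletion_loses_one_gap_only(self):
        stream = ss.generate_stream(100, seed=6)
        # delete exactly one interior cell from the plate side
        mseq = mc.encode(stream)
        victim_gap = next(i for i, c in enumerate(mseq.gap_counts[1:-1], start=1) if c > 0)
        victim = mseq.gap_members[victim_gap][0]
        events = [e for e in stream.events if e.uid != victim]
        plate = ss.EventStream(
            [ss.Event(e.uid, e.kind, i, e.symbol, e.out_of_focus)
             for i, e in enumerate(events)]
        )
        mseq_a, mseq_b, aln, report, segments = pipeline(stream, plate)
        table = cm.build_mapping(segments, mseq_a, mseq_b, line_positions(plate))
        stats = cm.retention_stats(table, segments, mseq_a,
                                   {e.uid: e.uid for e in stream.cells})
        lost = mseq.gap_counts[victim_gap]
        n_interior = sum(mseq.interior_gap_counts)
        assert stats["misassignment_rate"] == 0.0
        assert stats["n_mapped"] == n_interior - lost

    def test_rates_bounded(self):
        stats = run_pipeline_once(200, 2.0, 0.02, 0.02, seed=7)
        for key in ("retention_fraction", "misassignment_rate", "usable_fraction"):
            assert 0.0 <= stats[key] <= 1.0

    def test_truth_mismatch_rejected(self):
        stream = ss.generate_stream(30, seed=8)
        mseq_a, mseq_b, aln, report, segments = pipeline(stream, stream)
        table = cm.build_mapping(segments, mseq_a, mseq_b, line_positions(stream))
        with pytest.raises(ValueError):
            cm.retention_stats(table, segments, mseq_a, truth_pairs={})

    def test_safety_no_misassignment_when_errors_all_dropped(self):
        # markers-only errors: any corrupted marker drops its gaps, so the
        # retained cells are exactly right
        rng = np.random.default_rng(9)
        for seed in rng.integers(0, 2**20, 5):
            stream = ss.generate_stream(150, seed=int(seed))
            # delete only markers
            markers = [e.uid for e in stream.markers]
            victim = markers[int(seed) % len(markers)]
            events = [e for e in stream.events if e.uid != victim]
            plate = ss.EventStream(
                [ss.Event(e.uid, e.kind, i, e.symbol, e.out_of_focus)
                 for i, e in enumerate(events)]
            )
            mseq_a, mseq_b, aln, report, segments = pipeline(stream, plate)
            table = cm.build_mapping(segments, mseq_a, mseq_b, line_positions(plate))
            stats = cm.retention_stats(table, segments, mseq_a,
                                       {e.uid: e.uid for e in stream.cells})
            assert stats["misassignment_rate"] == 0.0
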