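"""Junction evidence, breakpoint calling, coordinate conventions, annotation."""

import pytest

import vectrace as vt
from vectrace._kmer import revcomp
from vectrace.caller import (
    InsertionCall,
    JunctionEvidence,
    annotate_insertion,
    call_insertions,
    find_junction_reads,
    mate_junction_bounds,
)
from vectrace.genome import GeneModel
from vectrace.mapping import LocusGroup, ReferenceIndex, anchor_host_mates
from vectrace.screen import EvidenceRead, VectorHit


def _flank_ev(kind, seq, read_start=50, read_end=100):
    hit = VectorHit("rj", 1, read_start, read_end, 0, read_end - read_start, "+", 1.0, "Cre")
    return EvidenceRead("rj", 1, kind, seq, hit)


class TestFindJunctionReads:
    def test_left_junction_split_read(self, tiny_sim):
        """50 bp host ending at the true left breakpoint + 50 bp vector:
        exact left evidence at the truth coordinate."""
        ref, left = tiny_sim["ref"], tiny_sim["left"]
        idx = ReferenceIndex(ref, k=20)
        flank = ref.contigs["chr5"][left - 50 : left]
        (ev,), _ = find_junction_reads([_flank_ev("flank_left", flank)], idx)
        assert (ev.side, ev.position, ev.exact) == ("left", left, True)

    def test_right_junction_split_read(self, tiny_sim):
        ref, right = tiny_sim["ref"], tiny_sim["right"]
        idx = ReferenceIndex(ref, k=20)
        flank = ref.contigs["chr5"][right : right + 50]
        (ev,), _ = find_junction_reads([_flank_ev("flank_right", flank, 0, 50)], idx)
        assert (ev.side, ev.position, ev.exact) == ("right", right, True)

    def test_reverse_strand_flank_geometry(self, tiny_sim):
        """A 5' flank that anchors on '-' is evidence for the *right* side."""
        ref, right = tiny_sim["ref"], tiny_sim["right"]
        idx = ReferenceIndex(ref, k=20)
        flank = revcomp(ref.contigs["chr5"][right : right + 50])
        (ev,), _ = find_junction_reads([_flank_ev("flank_left", flank)], idx)
        assert (ev.side, ev.position) == ("right", right)

    def test_short_flank_dropped(self, tiny_sim):
        idx = ReferenceIndex(tiny_sim["ref"], k=20)
        evs, anchors = find_junction_reads(
            [_flank_ev("flank_left", tiny_sim["ref"].contigs["chr5"][100:110])], idx
        )
        assert evs == [] and anchors == []

    def test_fully_vector_read_gives_no_evidence(self, tiny_sim, vector):
        """A read entirely inside the vector has no flanks to anchor."""
        from vectrace.screen import classify_pairs

        vs = vector.full_sequence
        pairs = [("p", vs[0:100], revcomp(vs[150:250]))]
        screen = vt.VectorScreen(vector)
        hits = screen.screen_reads([("p", 1, pairs[0][1]), ("p", 2, pairs[0][2])])
        _, evidence = classify_pairs(pairs, hits, min_flank=20)
        assert [e for e in evidence if e.kind != "mate"] == []


class TestMateJunctionBounds:
    def test_plus_mate_bounds_left(self):
        from vectrace.mapping import HostAnchor

        a = HostAnchor("r", 2, "mate", "unique", "c", 1000, 1100, "+", 0,
                       [("c", 1000, 1100, "+")])
        (ev,) = mate_junction_bounds([a])
        assert (ev.side, ev.position, ev.exact) == ("left", 1100, False)

    def test_minus_mate_bounds_right(self):
        from vectrace.mapping import HostAnchor

        a = HostAnchor("r", 2, "mate", "unique", "c", 1000, 1100, "-", 0,
                       [("c", 1000, 1100, "-")])
        (ev,) = mate_junction_bounds([a])
        assert (ev.side, ev.position, ev.exact) == ("right", 1000, False)


def _group(contig="chr5", start=36_381_000, end=36_383_000, n_unique=6):
    return LocusGroup(contig, start, end, n_unique, 0, [f"r{i}" for i in range(n_unique)], [])


def _ev(side, pos, exact=True, rid="r"):
    return JunctionEvidence(side, "chr5", pos, exact, rid)


class TestCallInsertions:
    def test_published_coordinate_worked_example(self):
        """Outer coordinates 36382105/36382309 imply a 204 bp deletion
        under the half-open difference convention."""
        evidence = [_ev("left", 36_382_105, rid=f"l{i}") for i in range(3)]
        evidence += [_ev("right", 36_382_309, rid=f"r{i}") for i in range(3)]
        (call,) = call_insertions([_group()], evidence, min_support=3)
        assert call.deletion_length == 204
        rep = call.to_report()
        assert rep["left_position_1based"] == 36_382_105
        assert rep["right_position_1based"] == 36_382_309
        assert rep["right_position_1based"] - rep["left_position_1based"] == 204

    def test_clean_insertion_zero_deletion(self):
        evidence = [_ev("left", 500, rid="a"), _ev("right", 500, rid="b"),
                    _ev("left", 500, rid="c")]
        (call,) = call_insertions(
            [_group(start=400, end=600, n_unique=3)], evidence, min_support=3
        )
        assert call.deletion_length == 0

    def test_min_support_suppression(self):
        evidence = [_ev("left", 500, rid="a"), _ev("right", 700, rid="b")]
        calls = call_insertions(
            [_group(start=400, end=800, n_unique=2)], evidence, min_support=3
        )
        assert calls == []

    def test_mate_only_bounds_used_without_exact(self):
        evidence = [
            _ev("left", 480, exact=False, rid="a"),
            _ev("left", 495, exact=False, rid="b"),
            _ev("right", 710, exact=False, rid="c"),
            _ev("right", 730, exact=False, rid="d"),
        ]
        (call,) = call_insertions(
            [_group(start=400, end=800, n_unique=4)], evidence, min_support=3
        )
        assert (call.left_bp, call.right_bp) == (495, 710)
        assert call.n_exact == 0

    def test_exact_beats_mate_bounds(self):
        evidence = [
            _ev("left", 495, exact=False, rid="a"),
            _ev("left", 505, exact=True, rid="b"),
            _ev("right", 700, exact=True, rid="c"),
        ]
        (call,) = call_insertions(
            [_group(start=400, end=800, n_unique=3)], evidence, min_support=3
        )
        assert (call.left_bp, call.right_bp) == (505, 700)

    def test_report_round_trip(self):
        call = InsertionCall("chr5", 36_382_105, 36_382_309, 7, 6, 4, False)
        back = InsertionCall.from_report(call.to_report())
        assert (back.left_bp, back.right_bp) == (call.left_bp, call.right_bp)
        assert back.deletion_length == 204


@pytest.fixture()
def plus_gene():
    # exons at [0,100), [200,300), [400,500): introns 1=[100,200), 2=[300,400)
    return GeneModel("g+", "c", "+", [(0, 100), (200, 300), (400, 500)])


@pytest.fixture()
def minus_gene():
    return GeneModel("g-", "c", "-", [(1000, 1100), (1200, 1300), (1400, 1500)])


def _call_at(pos, contig="c"):
    return InsertionCall(contig, pos, pos + 10, 3, 3, 2, False)


class TestAnnotateInsertion:
    def test_intron_offset_plus_strand(self, tiny_sim):
        """A breakpoint planted 5 kb into intron 1 annotates as intron 1,
        offset 5000."""
        gene = tiny_sim["ref"].gene_models[0]
        call = InsertionCall("chr5", tiny_sim["left"], tiny_sim["right"], 5, 5, 2, False)
        ann = annotate_insertion(call, [gene])
        assert (ann.gene_id, ann.region, ann.ordinal) == ("Sorcs2", "intron", 1)
        assert ann.offset_into_region == 5000

    def test_exon_one_offset(self, plus_gene):
        ann = annotate_insertion(_call_at(42), [plus_gene])
        assert (ann.region, ann.ordinal, ann.offset_into_region) == ("exon", 1, 42)
        assert ann.distance_from_tss == 42

    def test_minus_strand_hand_computed(self, minus_gene):
        # position 1250 sits in the genomically-middle exon; transcription
        # runs right-to-left so that exon is exon 2 and the offset from its
        # 5' (right) edge is 1299 - 1250 = 49; TSS is at 1499.
        ann = annotate_insertion(_call_at(1250), [minus_gene])
        assert (ann.region, ann.ordinal, ann.offset_into_region) == ("exon", 2, 49)
        assert ann.distance_from_tss == 249

    def test_minus_strand_intron_numbering(self, minus_gene):
        # genomic gap [1100,1200) is the transcriptionally *last* intron (2)
        ann = annotate_insertion(_call_at(1150), [minus_gene])
        assert (ann.region, ann.ordinal) == ("intron", 2)
        assert ann.offset_into_region == 1199 - 1150

    def test_intergenic_distance(self, plus_gene):
        ann = annotate_insertion(_call_at(700), [plus_gene])
        assert ann.region == "intergenic"
        assert ann.distance_to_nearest == 700 - 499
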