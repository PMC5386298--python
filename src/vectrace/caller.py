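"""Calling integration loci: breakpoints, deleted interval, annotation.

Breakpoints are host-frame, 0-based half-open internally: ``left_bp`` is
the start of the deleted interval (first host base replaced) and
``right_bp`` its end (first host base retained on the right), so
``deletion_length = right_bp - left_bp``.  Reports print the conventional
1-based *outer* coordinates — the last retained base on the left and the
last deleted base on the right — whose printed difference equals the
deletion length (e.g. 36382105 / 36382309 for a 204 bp deletion).

Split reads whose host/vector boundary anchors uniquely give *exact*
evidence at a single base; uniquely mapped host mates of discordant pairs
give *inexact* one-sided bounds (the junction lies beyond the mate's inner
end).  Ambiguous anchors never contribute coordinates.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import json

from .genome import GeneModel
from .mapping import HostAnchor, LocusGroup, ReferenceIndex, anchor_host_mates
from .screen import EvidenceRead

log = logging.getLogger(__name__)


@dataclass
class JunctionEvidence:
    """One read's statement about one side of the insertion.

    ``side`` is "left" (host retained 5' of the insertion, in reference
    orientation) or "right"; ``position`` is the breakpoint estimate
    (exact base for split reads, outer bound for mate evidence)."""

    side: str
    contig: str
    position: int
    exact: bool
    read_id: str


@dataclass
class InsertionCall:
    contig: str
    left_bp: int
    right_bp: int
    support_left: int
    support_right: int
    n_exact: int
    ambiguous_flag: bool
    candidate_loci: list[tuple[str, int, int, str]] = field(default_factory=list)
    genome_build: str = "synthetic"

    @property
    def deletion_length(self) -> int:
        return self.right_bp - self.left_bp

    @property
    def total_support(self) -> int:
        return self.support_left + self.support_right

    def to_report(self) -> dict:
        """1-based outer-coordinate report (printed difference = deletion)."""
        return {
            "contig": self.contig,
            "genome_build": self.genome_build,
            "left_position_1based": self.left_bp,
            "right_position_1based": self.right_bp,
            "deletion_length": self.deletion_length,
            "support_left": self.support_left,
            "support_right": self.support_right,
            "n_exact": self.n_exact,
            "ambiguous": self.ambiguous_flag,
        }

    @classmethod
    def from_report(cls, rep: dict) -> "InsertionCall":
        return cls(
            contig=rep["contig"],
            left_bp=int(rep["left_position_1based"]),
            right_bp=int(rep["right_position_1based"]),
            support_left=int(rep["support_left"]),
            support_right=int(rep["support_right"]),
            n_exact=int(rep["n_exact"]),
            ambiguous_flag=bool(rep["ambiguous"]),
            genome_build=rep.get("genome_build", "synthetic"),
        )


# ---------------------------------------------------------------------------
# junction evidence


def _flank_side_and_position(kind: str, anchor: HostAnchor) -> tuple[str, int]:
    """Side/coordinate geometry of a uniquely anchored flank.

    A flank 5' of the vector match in read orientation ("flank_left")
    anchored on '+' means host sequence runs rightwards into the vector:
    left junction, breakpoint at the anchor's end.  The other three
    kind/strand combinations follow by symmetry; in every case left
    evidence sits at an anchor end and right evidence at an anchor start.
    """
    if (kind == "flank_left") == (anchor.strand == "+"):
        return "left", anchor.end
    return "right", anchor.start


def find_junction_reads(
    flank_evidence: list[EvidenceRead],
    index: ReferenceIndex,
    max_mismatch: int = 3,
) -> tuple[list[JunctionEvidence], list[HostAnchor]]:
    """Anchor unmatched flanks of vector-hit reads; unique anchors become
    base-exact junction evidence.  Flanks shorter than the index k are
    dropped (counted in the log); so are non-unique flank anchors.
    """
    usable = [ev for ev in flank_evidence if len(ev.seq) >= index.k]
    dropped = len(flank_evidence) - len(usable)
    if dropped:
        log.info("dropped %d flanks shorter than k=%d", dropped, index.k)
    anchors = anchor_host_mates(usable, index, max_mismatch=max_mismatch)
    out: list[JunctionEvidence] = []
    for a in anchors:
        if a.status != "unique":
            continue
        side, pos = _flank_side_and_position(a.kind, a)
        out.append(JunctionEvidence(side, a.contig, pos, True, a.read_id))
    return out, anchors


def mate_junction_bounds(mate_anchors: list[HostAnchor]) -> list[JunctionEvidence]:
    """Inexact one-sided bounds from uniquely anchored host mates.

    In FR orientation a host mate on '+' points rightwards at the junction
    (left-side evidence bounded by its end); on '-' the junction is to its
    left (right-side evidence bounded by its start).
    """
    out = []
    for a in mate_anchors:
        if a.status != "unique" or a.kind != "mate":
            continue
        if a.strand == "+":
            out.append(JunctionEvidence("left", a.contig, a.end, False, a.read_id))
        else:
            out.append(JunctionEvidence("right", a.contig, a.start, False, a.read_id))
    return out


# ---------------------------------------------------------------------------
# calling


def _consensus(exact_positions: list[int], prefer_max: bool) -> int:
    """Modal exact coordinate; ties broken towards the inner (conservative)
    side of the deleted interval."""
    counts = Counter(exact_positions)
    top = max(counts.values())
    tied = [p for p, c in counts.items() if c == top]
    return max(tied) if prefer_max else min(tied)


def call_insertions(
    groups: list[LocusGroup],
    evidence: list[JunctionEvidence],
    min_support: int = 3,
    merge_distance: int = 1000,
    genome_build: str = "synthetic",
) -> list[InsertionCall]:
    """One call per locus group with enough junction support.

    Per side, the breakpoint is the modal exact (split-read) coordinate
    when available, otherwise the tightest mate bound (max of left ends /
    min of right starts).  Groups without any unique junction evidence
    (e.g. a repeat family attracting only ambiguous anchors) produce no
    coordinate call — they remain visible in the group ranking.
    """
    if min_support < 1:
        raise ValueError("min_support must be >= 1")
    calls: list[InsertionCall] = []
    unassigned = 0
    assigned: dict[int, list[JunctionEvidence]] = {i: [] for i in range(len(groups))}
    for ev in evidence:
        best_i, best_d = None, None
        for i, g in enumerate(groups):
            if g.contig != ev.contig:
                continue
            d = max(g.start - ev.position, ev.position - g.end, 0)
            if d <= merge_distance and (best_d is None or d < best_d):
                best_i, best_d = i, d
        if best_i is None:
            unassigned += 1
        else:
            assigned[best_i].append(ev)
    if unassigned:
        log.info("%d junction evidence reads matched no locus group", unassigned)

    for i, g in enumerate(groups):
        evs = assigned[i]
        lefts = [e for e in evs if e.side == "left"]
        rights = [e for e in evs if e.side == "right"]
        exact_l = [e.position for e in lefts if e.exact]
        exact_r = [e.position for e in rights if e.exact]
        left_bp = (
            _consensus(exact_l, prefer_max=True)
            if exact_l
            else (max(e.position for e in lefts) if lefts else None)
        )
        right_bp = (
            _consensus(exact_r, prefer_max=False)
            if exact_r
            else (min(e.position for e in rights) if rights else None)
        )
        if left_bp is None and right_bp is None:
            continue
        if left_bp is None:
            left_bp = right_bp
        if right_bp is None:
            right_bp = left_bp
        if right_bp < left_bp:
            # inexact bounds can cross when one side is mate-only; collapse
            # to the exact side if there is one, else to a zero-length locus
            if exact_l and not exact_r:
                right_bp = left_bp
            elif exact_r and not exact_l:
                left_bp = right_bp
            else:
                left_bp = right_bp = min(left_bp, right_bp)
        support = len(lefts) + len(rights)
        if support < min_support:
            continue
        amb_cands: list[tuple[str, int, int, str]] = []
        for a in g.anchors:
            if a.status == "ambiguous":
                amb_cands.extend(a.candidates)
        calls.append(
            InsertionCall(
                contig=g.contig,
                left_bp=left_bp,
                right_bp=right_bp,
                support_left=len(lefts),
                support_right=len(rights),
                n_exact=len(exact_l) + len(exact_r),
                ambiguous_flag=g.n_ambiguous > g.n_unique,
                candidate_loci=sorted(set(amb_cands)),
                genome_build=genome_build,
            )
        )
    calls.sort(key=lambda c: (-c.total_support, c.contig, c.left_bp))
    return calls


def calls_to_json(calls: list[InsertionCall], path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump([c.to_report() for c in calls], fh, indent=2)


# ---------------------------------------------------------------------------
# annotation


@dataclass
class InsertionAnnotation:
    """Placement of a breakpoint within a gene's exon/intron structure.

    Ordinals count in transcription order (intron 1 lies between exons 1
    and 2); ``offset_into_region`` is measured from the region's
    transcriptionally 5' end.  ``region`` is "intergenic" when no gene
    overlaps, with ``distance_to_nearest`` filled instead.
    """

    gene_id: str | None
    region: str
    ordinal: int | None
    offset_into_region: int | None
    distance_from_tss: int | None
    distance_to_nearest: int | None = None


def annotate_insertion(
    call: InsertionCall, gene_models: list[GeneModel]
) -> InsertionAnnotation:
    """Locate ``call.left_bp`` within the nearest overlapping gene model."""
    p = call.left_bp
    on_contig = [g for g in gene_models if g.contig == call.contig]
    if not on_contig and not gene_models:
        raise ValueError("no gene models supplied")
    overlapping = [g for g in on_contig if g.start <= p < g.end]
    if not overlapping:
        if not on_contig:
            return InsertionAnnotation(None, "intergenic", None, None, None, None)
        nearest = min(on_contig, key=lambda g: min(abs(p - g.start), abs(p - (g.end - 1))))
        dist = min(abs(p - nearest.start), abs(p - (nearest.end - 1)))
        return InsertionAnnotation(nearest.gene_id, "intergenic", None, None, None, dist)
    gene = min(overlapping, key=lambda g: abs(p - g.tss))

    # genomic-order regions: exon 1g, intron 1g, exon 2g, ...
    regions: list[tuple[str, int, int, int]] = []  # (type, genomic_ordinal, start, end)
    for i, (s, e) in enumerate(gene.exons, start=1):
        regions.append(("exon", i, s, e))
    for i, (s, e) in enumerate(gene.introns, start=1):
        regions.append(("intron", i, s, e))
    rtype, g_ord, rs, re_ = next(
        (r for r in regions if r[2] <= p < r[3])
    )
    n_ex = gene.n_exons()
    if gene.strand == "+":
        ordinal = g_ord
        offset = p - rs
        tss_dist = p - gene.start
    else:
        # transcription runs right-to-left: renumber and measure from the
        # region's genomically-right edge
        ordinal = (n_ex - g_ord + 1) if rtype == "exon" else (n_ex - g_ord)
        offset = re_ - 1 - p
        tss_dist = (gene.end - 1) - p
    return InsertionAnnotation(
        gene_id=gene.gene_id,
        region=rtype,
        ordinal=ordinal,
        offset_into_region=offset,
        distance_from_tss=tss_dist,
    )
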