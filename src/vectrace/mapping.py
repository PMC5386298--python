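"""Anchoring host-side evidence reads on the reference genome.

Placement is seed-and-vote: exact k-mer seeds against an index of the
reference (queried with both read orientations), candidate placements
scored by the mismatch count of a full ungapped alignment.  A read whose
best score is attained at two or more loci is flagged *ambiguous* — the
situation a large, closely related gene family creates — and ambiguous
anchors count towards locus support but never towards breakpoint
coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._kmer import encode, kmer_codes, revcomp
from .genome import ReferenceGenome
from .screen import EvidenceRead


class ReferenceIndex:
    """Sorted-array index of every k-mer of the reference (forward strand).

    Contigs are concatenated with runs of ``N`` so no k-mer spans two
    contigs; reverse-strand placements come from querying the reverse
    complement of the read.
    """

    def __init__(self, contigs: dict[str, str] | ReferenceGenome, k: int = 31):
        if isinstance(contigs, ReferenceGenome):
            contigs = contigs.contigs
        if not contigs:
            raise ValueError("empty reference")
        self.k = k
        self.contig_bounds: dict[str, tuple[int, int]] = {}
        parts: list[str] = []
        off = 0
        sep = "N" * k
        for name, seq in contigs.items():
            if parts:
                parts.append(sep)
                off += k
            self.contig_bounds[name] = (off, off + len(seq))
            parts.append(seq.upper())
            off += len(seq)
        self.enc = encode("".join(parts))
        codes, valid = kmer_codes(self.enc, k)
        vpos = np.nonzero(valid)[0]
        vcodes = codes[valid]
        order = np.argsort(vcodes, kind="stable")
        self._codes = vcodes[order]
        self._pos = vpos[order]
        # global position -> contig, resolved by interval search
        self._starts = np.array([b[0] for b in self.contig_bounds.values()])
        self._names = list(self.contig_bounds)

    def contig_of(self, gpos: int) -> str:
        i = int(np.searchsorted(self._starts, gpos, side="right")) - 1
        return self._names[i]

    def lookup(self, codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For an array of query codes return (query_idx, genome_pos) pairs."""
        lo = np.searchsorted(self._codes, codes, side="left")
        hi = np.searchsorted(self._codes, codes, side="right")
        qi = np.repeat(np.arange(codes.size), hi - lo)
        if qi.size == 0:
            return qi, qi
        gp = np.concatenate([self._pos[a:b] for a, b in zip(lo, hi) if b > a])
        return qi, gp


@dataclass
class HostAnchor:
    """Placement of one evidence read (or flank) on the reference.

    ``status`` is "unique", "ambiguous" (>= 2 co-optimal placements, all in
    ``candidates``) or "unmapped".  Coordinates are contig-local, 0-based
    half-open; ``strand`` is the read orientation relative to the reference.
    """

    read_id: str
    mate: int
    kind: str  # "mate" | "flank_left" | "flank_right"
    status: str
    contig: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None
    mismatches: int | None = None
    candidates: list[tuple[str, int, int, str]] = field(default_factory=list)
    evidence: EvidenceRead | None = None


def _place_read(
    index: ReferenceIndex, seq: str, max_mismatch: int
) -> tuple[list[tuple[int, str, int]], int | None]:
    """All co-optimal placements of one read: list of (global_start, strand,
    mismatches) plus the best mismatch count (None when unmapped)."""
    L = len(seq)
    if L < index.k:
        return [], None
    cands: set[tuple[int, str]] = set()
    encs = {"+": encode(seq), "-": encode(revcomp(seq))}
    for strand, e in encs.items():
        codes, valid = kmer_codes(e, index.k)
        vpos = np.nonzero(valid)[0]
        if vpos.size == 0:
            continue
        qi, gp = index.lookup(codes[vpos])
        for q, g in zip(vpos[qi], gp):
            cands.add((int(g) - int(q), strand))
    genc = index.enc
    scored: list[tuple[int, str, int]] = []
    best: int | None = None
    for start, strand in cands:
        if start < 0 or start + L > genc.size:
            continue
        contig = index.contig_of(start)
        cs, ce = index.contig_bounds[contig]
        if start < cs or start + L > ce:
            continue
        e = encs[strand]
        seg = genc[start : start + L]
        mm = int(np.count_nonzero((seg != e) | (e == 4) | (seg == 4)))
        if mm <= max_mismatch:
            scored.append((start, strand, mm))
            if best is None or mm < best:
                best = mm
    return scored, best


def anchor_host_mates(
    reads: list[EvidenceRead] | list[tuple[str, str]],
    index: ReferenceIndex,
    max_mismatch: int = 3,
) -> list[HostAnchor]:
    """Anchor evidence reads; one HostAnchor per read (possibly unmapped)."""
    evs: list[EvidenceRead] = []
    for r in reads:
        if isinstance(r, EvidenceRead):
            evs.append(r)
        else:
            rid, seq = r
            evs.append(EvidenceRead(rid, 1, "mate", seq))
    anchors: list[HostAnchor] = []
    for ev in evs:
        placements, best = _place_read(index, ev.seq, max_mismatch)
        if best is None:
            anchors.append(
                HostAnchor(ev.read_id, ev.mate, ev.kind, "unmapped", evidence=ev)
            )
            continue
        opt = sorted(p for p in placements if p[2] == best)
        L = len(ev.seq)
        cand_loci = []
        for gstart, strand, _ in opt:
            contig = index.contig_of(gstart)
            cs, _ = index.contig_bounds[contig]
            cand_loci.append((contig, gstart - cs, gstart - cs + L, strand))
        cand_loci.sort()
        status = "unique" if len(opt) == 1 else "ambiguous"
        c0 = cand_loci[0]
        anchors.append(
            HostAnchor(
                read_id=ev.read_id,
                mate=ev.mate,
                kind=ev.kind,
                status=status,
                contig=c0[0],
                start=c0[1],
                end=c0[2],
                strand=c0[3],
                mismatches=best,
                candidates=cand_loci,
                evidence=ev,
            )
        )
    return anchors


@dataclass
class LocusGroup:
    """A cluster of anchors on one contig, the unit an insertion is called
    from.  Ranking is by unique support first (mirroring how an ambiguously
    mapping family locus is down-weighted), then total support."""

    contig: str
    start: int
    end: int
    n_unique: int
    n_ambiguous: int
    read_ids: list[str]
    anchors: list[HostAnchor]

    @property
    def total_support(self) -> int:
        return self.n_unique + self.n_ambiguous


def resolve_ambiguity(
    anchors: list[HostAnchor], merge_distance: int = 1000
) -> list[LocusGroup]:
    """Cluster anchors into candidate integration loci.

    Unique anchors are single-linkage clustered per contig within
    ``merge_distance``.  Each ambiguous anchor then increments the ambiguous
    support of every group one of its candidate loci falls near; ambiguous
    anchors near no unique-supported group form their own (zero-unique)
    groups seeded from their first candidate locus.  Output is sorted by
    unique support, then total support, and is invariant to input order.
    """
    uniq = sorted(
        (a for a in anchors if a.status == "unique"),
        key=lambda a: (a.contig, a.start, a.end, a.read_id, a.mate, a.kind),
    )
    groups: list[LocusGroup] = []
    for a in uniq:
        g = groups[-1] if groups else None
        if g is not None and g.contig == a.contig and a.start - g.end <= merge_distance:
            g.end = max(g.end, a.end)
            g.n_unique += 1
            g.read_ids.append(a.read_id)
            g.anchors.append(a)
        else:
            groups.append(
                LocusGroup(a.contig, a.start, a.end, 1, 0, [a.read_id], [a])
            )

    amb = sorted(
        (a for a in anchors if a.status == "ambiguous"),
        key=lambda a: (a.read_id, a.mate, a.kind),
    )
    leftover: list[HostAnchor] = []
    for a in amb:
        matched = False
        for g in groups:
            if any(
                c[0] == g.contig
                and c[1] <= g.end + merge_distance
                and c[2] >= g.start - merge_distance
                for c in a.candidates
            ):
                g.n_ambiguous += 1
                g.read_ids.append(a.read_id)
                g.anchors.append(a)
                matched = True
        if not matched:
            leftover.append(a)

    # zero-unique groups from unattached ambiguous anchors (clustered on
    # their first candidate locus)
    leftover.sort(key=lambda a: (a.candidates[0], a.read_id, a.mate, a.kind))
    amb_groups: list[LocusGroup] = []
    for a in leftover:
        c = a.candidates[0]
        g = amb_groups[-1] if amb_groups else None
        if g is not None and g.contig == c[0] and c[1] - g.end <= merge_distance:
            g.end = max(g.end, c[2])
            g.n_ambiguous += 1
            g.read_ids.append(a.read_id)
            g.anchors.append(a)
        else:
            amb_groups.append(LocusGroup(c[0], c[1], c[2], 0, 1, [a.read_id], [a]))

    out = groups + amb_groups
    for g in out:
        g.read_ids = sorted(set(g.read_ids))
    out.sort(key=lambda g: (-g.n_unique, -g.total_support, g.contig, g.start))
    return out


def anchors_to_tsv(anchors: list[HostAnchor], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": a.read_id,
                "mate": a.mate,
                "kind": a.kind,
                "status": a.status,
                "contig": a.contig if a.contig is not None else ".",
                "start": a.start if a.start is not None else -1,
                "end": a.end if a.end is not None else -1,
                "strand": a.strand if a.strand is not None else ".",
                "mismatches": a.mismatches if a.mismatches is not None else -1,
                "n_candidates": len(a.candidates),
            }
            for a in anchors
        ]
    ).to_csv(path, sep="\t", index=False)


def groups_to_tsv(groups: list[LocusGroup], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "rank": i + 1,
                "contig": g.contig,
                "start": g.start,
                "end": g.end,
                "n_unique": g.n_unique,
                "n_ambiguous": g.n_ambiguous,
                "total_support": g.total_support,
                "read_ids": ",".join(g.read_ids),
            }
            for i, g in enumerate(groups)
        ]
    ).to_csv(path, sep="\t", index=False)
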