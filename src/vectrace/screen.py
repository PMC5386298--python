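"""Screening reads for vector sequence and triaging read pairs.

A read "contains part of the vector" when some substring of length >=
``min_match_len`` matches the vector's concatenated sequence (either
strand) at >= ``min_identity``.  Matches are found by exact k-mer seeding
followed by ungapped extension along the seed diagonal; one best hit per
read is kept (longest, then highest identity, then smallest vector offset,
then '+' strand).

Pairs are then partitioned: vector at both ends (discarded from insertion
mapping — wholly internal to the transgene), vector at exactly one end
(the informative discordant pairs, forwarded with their host-side
evidence), or no vector at all.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from ._kmer import encode, kmer_codes, kmer_codes_matrix, revcomp
from .genome import VectorConstruct

log = logging.getLogger(__name__)


@dataclass
class VectorHit:
    """Best vector match within one mate.

    ``read_start/read_end`` are half-open on the read as sequenced;
    ``vec_start/vec_end`` are half-open on the vector full sequence.
    ``strand`` is '+' when the read matches the vector forward strand.
    """

    read_id: str
    mate: int
    read_start: int
    read_end: int
    vec_start: int
    vec_end: int
    strand: str
    identity: float
    component: str

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


class PairClass(str, Enum):
    VECTOR_BOTH = "VECTOR_BOTH"
    VECTOR_HOST = "VECTOR_HOST"
    HOST_HOST = "HOST_HOST"


@dataclass
class EvidenceRead:
    """Host-side evidence forwarded from a VECTOR_HOST pair: either the
    entire non-vector mate, or an unmatched flank of the vector-hit mate.

    ``kind`` is "mate", "flank_left" (read bases 5' of the vector match) or
    "flank_right"; flanks keep a reference to the hit they flank so the
    caller can turn a uniquely anchored flank into a base-exact breakpoint.
    """

    read_id: str
    mate: int
    kind: str
    seq: str
    hit: VectorHit | None = None


class VectorScreen:
    """k-mer screen against one vector construct."""

    def __init__(
        self,
        vector: VectorConstruct,
        k: int = 15,
        min_match_len: int = 25,
        min_identity: float = 0.9,
    ):
        if not 0 < min_identity <= 1:
            raise ValueError("min_identity must be in (0, 1]")
        if k > min_match_len:
            raise ValueError(f"k={k} must not exceed min_match_len={min_match_len}")
        self.vector = vector
        self.k = k
        self.min_match_len = min_match_len
        self.min_identity = min_identity
        self.vseq = vector.full_sequence
        self.venc = encode(self.vseq)
        codes, valid = kmer_codes(self.venc, k)
        self._codes = codes[valid]
        order = np.argsort(self._codes, kind="stable")
        self._sorted_codes = self._codes[order]
        self._sorted_pos = np.nonzero(valid)[0][order]

    # -- seeding -----------------------------------------------------------

    def _seed_positions(self, code: int) -> np.ndarray:
        lo = np.searchsorted(self._sorted_codes, code, side="left")
        hi = np.searchsorted(self._sorted_codes, code, side="right")
        return self._sorted_pos[lo:hi]

    def _candidate_mask(self, mat: np.ndarray) -> np.ndarray:
        """Rows of an encoded read matrix with at least one exact vector
        k-mer on the given orientation."""
        codes, valid = kmer_codes_matrix(mat, self.k)
        hit = np.isin(codes, self._sorted_codes)
        return (hit & valid).any(axis=1)

    # -- extension ---------------------------------------------------------

    def _best_hit_on_strand(self, enc: np.ndarray) -> tuple | None:
        """Best (length, identity, vec_start, read_start, read_end, vec_end)
        over all seeded diagonals of one read orientation."""
        L = enc.size
        if self.k > L:
            raise ValueError(f"k={self.k} exceeds read length {L}")
        codes, valid = kmer_codes(enc, self.k)
        diags: set[int] = set()
        for rpos in np.nonzero(valid)[0]:
            for vpos in self._seed_positions(int(codes[rpos])):
                diags.add(int(vpos) - int(rpos))
        best = None
        VL = self.venc.size
        for d in sorted(diags):
            i0 = max(0, -d)
            i1 = min(L, VL - d)
            if i1 - i0 < self.min_match_len:
                continue
            seg_r = enc[i0:i1]
            seg_v = self.venc[i0 + d : i1 + d]
            mism = (seg_r != seg_v) | (seg_r == 4)
            pref = np.concatenate(([0], np.cumsum(mism)))
            n = i1 - i0
            # longest window [a, b) with identity >= min_identity
            for a in range(0, n - self.min_match_len + 1):
                for b in range(n, a + self.min_match_len - 1, -1):
                    wlen = b - a
                    if best is not None and wlen < best[0]:
                        break
                    ident = 1.0 - (pref[b] - pref[a]) / wlen
                    if ident >= self.min_identity:
                        cand = (wlen, ident, -(i0 + a + d), i0 + a, i0 + b, i0 + b + d)
                        if best is None or (cand[0], cand[1], cand[2]) > (
                            best[0],
                            best[1],
                            best[2],
                        ):
                            best = cand
                        break
        return best

    def screen_read(self, read_id: str, mate: int, seq: str) -> VectorHit | None:
        """Screen one read; returns the best hit or None."""
        seq = seq.upper()
        if any(c not in "ACGTN" for c in seq):
            log.warning("read %s/%d contains non-ACGTN characters; skipped", read_id, mate)
            return None
        enc = encode(seq)
        best = None
        best_strand = "+"
        for strand, e in (("+", enc), ("-", encode(revcomp(seq)))):
            h = self._best_hit_on_strand(e)
            if h is not None and (best is None or (h[0], h[1], h[2]) > (best[0], best[1], best[2])):
                best = h
                best_strand = strand
        if best is None:
            return None
        wlen, ident, _negvs, rs, re_, ve = best
        vs = ve - wlen
        if best_strand == "-":
            # coordinates were computed on the reverse-complemented read;
            # map the read interval back to as-sequenced orientation
            L = len(seq)
            rs, re_ = L - re_, L - rs
        mid = (vs + ve - 1) // 2
        return VectorHit(
            read_id=read_id,
            mate=mate,
            read_start=rs,
            read_end=re_,
            vec_start=vs,
            vec_end=ve,
            strand=best_strand,
            identity=ident,
            component=self.vector.component_at(mid),
        )

    def screen_reads(
        self, reads: Iterable[tuple[str, int, str]]
    ) -> list[VectorHit]:
        """Screen a stream of (read_id, mate, sequence).

        Equal-length reads are batched so the k-mer seeding runs vectorised;
        only seeded reads go through per-read extension.
        """
        by_len: dict[int, list[tuple[str, int, str]]] = {}
        for rid, mate, seq in reads:
            by_len.setdefault(len(seq), []).append((rid, mate, seq.upper()))
        hits: list[VectorHit] = []
        for L, group in by_len.items():
            if self.k > L:
                raise ValueError(f"k={self.k} exceeds read length {L}")
            mat = np.empty((len(group), L), dtype=np.int8)
            rc = np.empty_like(mat)
            for i, (_, _, seq) in enumerate(group):
                e = encode(seq)
                mat[i] = e
                rc[i] = encode(revcomp(seq))
            cand = self._candidate_mask(mat) | self._candidate_mask(rc)
            for i in np.nonzero(cand)[0]:
                rid, mate, seq = group[i]
                h = self.screen_read(rid, mate, seq)
                if h is not None:
                    hits.append(h)
        return hits


def screen_reads(
    reads: Iterable[tuple[str, int, str]],
    vector: VectorConstruct,
    k: int = 15,
    min_match_len: int = 25,
    min_identity: float = 0.9,
) -> list[VectorHit]:
    """Functional wrapper over :class:`VectorScreen`."""
    return VectorScreen(vector, k=k, min_match_len=min_match_len, min_identity=min_identity).screen_reads(reads)


def classify_pairs(
    pairs: Iterable[tuple[str, str, str]],
    hits: Iterable[VectorHit],
    min_flank: int = 1,
) -> tuple[dict[str, PairClass], list[EvidenceRead]]:
    """Partition pairs by where the vector was seen and forward evidence.

    ``pairs`` yields (read_id, mate1_seq, mate2_seq).  Returns the class per
    pair and the host-side evidence reads of every VECTOR_HOST pair: the
    non-vector mate plus any unmatched flank (>= ``min_flank`` bp) of the
    hit mate.
    """
    pair_seqs: dict[str, tuple[str, str]] = {}
    for rid, s1, s2 in pairs:
        if rid in pair_seqs:
            raise ValueError(f"duplicate pair id {rid!r}")
        pair_seqs[rid] = (s1, s2)

    hit_by_mate: dict[tuple[str, int], VectorHit] = {}
    for h in hits:
        if h.read_id not in pair_seqs:
            raise ValueError(f"orphan mate: hit on unknown read_id {h.read_id!r}")
        hit_by_mate[(h.read_id, h.mate)] = h

    classes: dict[str, PairClass] = {}
    evidence: list[EvidenceRead] = []
    for rid, (s1, s2) in pair_seqs.items():
        h1 = hit_by_mate.get((rid, 1))
        h2 = hit_by_mate.get((rid, 2))
        if h1 and h2:
            classes[rid] = PairClass.VECTOR_BOTH
            continue
        if not h1 and not h2:
            classes[rid] = PairClass.HOST_HOST
            continue
        classes[rid] = PairClass.VECTOR_HOST
        hit = h1 or h2
        host_mate, host_seq = (2, s2) if h1 else (1, s1)
        evidence.append(EvidenceRead(rid, host_mate, "mate", host_seq))
        hit_seq = s1 if h1 else s2
        left = hit_seq[: hit.read_start]
        right = hit_seq[hit.read_end :]
        if len(left) >= min_flank:
            evidence.append(EvidenceRead(rid, hit.mate, "flank_left", left, hit))
        if len(right) >= min_flank:
            evidence.append(EvidenceRead(rid, hit.mate, "flank_right", right, hit))
    return classes, evidence


def hits_to_tsv(hits: list[VectorHit], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "read_id": h.read_id,
                "mate": h.mate,
                "read_start": h.read_start,
                "read_end": h.read_end,
                "vec_start": h.vec_start,
                "vec_end": h.vec_end,
                "strand": h.strand,
                "identity": round(h.identity, 4),
                "component": h.component,
            }
            for h in hits
        ],
        columns=[
            "read_id", "mate", "read_start", "read_end", "vec_start",
            "vec_end", "strand", "identity", "component",
        ],
    ).to_csv(path, sep="\t", index=False)


def hits_from_tsv(path: str | Path) -> list[VectorHit]:
    df = pd.read_csv(path, sep="\t")
    return [
        VectorHit(
            read_id=str(r.read_id),
            mate=int(r.mate),
            read_start=int(r.read_start),
            read_end=int(r.read_end),
            vec_start=int(r.vec_start),
            vec_end=int(r.vec_end),
            strand=str(r.strand),
            identity=float(r.identity),
            component=str(r.component),
        )
        for r in df.itertuples()
    ]
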