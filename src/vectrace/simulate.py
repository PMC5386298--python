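"""Synthetic data with machine-readable ground truth.

This module emulates the data-generating processes of a random-transgenesis
mapping study: a host contig carrying one large multi-exon gene (and
optionally a family of ~180 diverged repeat copies as a multi-mapping
decoy), a multi-component vector cassette integrated at chosen loci with a
short deletion of host sequence, Illumina-style paired-end reads (100 bp
mates from ~300 bp fragments), per-animal qPCR Ct tables with non-detects,
and normally distributed morphometric measurements.

Every generator is deterministic given its seed.  Read names carry truth
tags (``name|contig|frag_start|frag_end``) so downstream classification and
breakpoint calls can be validated by coordinate arithmetic alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GeneModel, ReferenceGenome, VectorConstruct
from ._kmer import revcomp

TRUTH_DELIM = "|"

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode("ascii")


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base independently with probability ``rate``."""
    if rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    hit = np.nonzero(rng.random(arr.size) < rate)[0]
    if hit.size:
        # shift by 1..3 in base space guarantees a different base
        idx = np.searchsorted(_BASES, arr[hit])
        arr[hit] = _BASES[(idx + rng.integers(1, 4, size=hit.size)) % 4]
    return arr.tobytes().decode("ascii")


@dataclass
class GeneSpec:
    """Layout parameters for the planted gene model.

    Defaults follow a SorCS2-like architecture: 27 exons over ~380 kb with a
    disproportionately long first intron (so a breakpoint can fall ~15 kb
    into intron 1).  ``intron1_frac`` is the share of total intronic length
    given to intron 1; the remaining introns share the rest equally.
    """

    gene_id: str = "Sorcs2"
    n_exons: int = 27
    exon_len: int = 150
    span: int = 380_000
    start: int | None = None
    strand: str = "+"
    intron1_frac: float = 0.3

    def exon_intervals(self, start: int) -> list[tuple[int, int]]:
        if self.n_exons < 1:
            raise ValueError("need at least one exon")
        if self.n_exons == 1:
            return [(start, start + self.span)]
        exonic = self.n_exons * self.exon_len
        intronic = self.span - exonic
        if intronic <= 0:
            raise ValueError(
                f"gene span {self.span} too small for {self.n_exons} exons of {self.exon_len} bp"
            )
        n_introns = self.n_exons - 1
        intron1 = int(round(self.intron1_frac * intronic)) if n_introns > 1 else intronic
        rest = (intronic - intron1) // max(n_introns - 1, 1)
        lens = [intron1] + [rest] * (n_introns - 1)
        # absorb rounding remainder into the final intron
        lens[-1] += intronic - sum(lens)
        exons = []
        pos = start
        for i in range(self.n_exons):
            exons.append((pos, pos + self.exon_len))
            pos += self.exon_len
            if i < n_introns:
                pos += lens[i]
        return exons


@dataclass
class FamilySpec:
    """A decoy repeat family: ``n_copies`` of one master sequence, each copy
    independently substituted per-base at ``divergence_rate`` (emulating a
    large, closely related gene family that defeats unique mapping)."""

    n_copies: int
    divergence_rate: float
    copy_len: int = 500

    def __post_init__(self) -> None:
        if self.n_copies < 1:
            raise ValueError("family needs at least one copy")
        if not 0 <= self.divergence_rate < 0.25:
            raise ValueError("divergence_rate must be in [0, 0.25)")


def generate_reference(
    contig_len: int,
    gene_spec: GeneSpec | None = None,
    family_spec: FamilySpec | None = None,
    seed: int = 0,
    contig_name: str = "chr5",
) -> ReferenceGenome:
    """Random host contig with one planted gene model and an optional
    diverged repeat family outside the gene footprint."""
    contig_len = int(contig_len)
    rng = np.random.default_rng(seed)
    seq = np.frombuffer(_random_dna(rng, contig_len).encode("ascii"), dtype=np.uint8).copy()

    gene_models: list[GeneModel] = []
    gene_iv: tuple[int, int] | None = None
    if gene_spec is not None:
        start = gene_spec.start
        if start is None:
            start = (contig_len - gene_spec.span) // 2
        if start < 0 or start + gene_spec.span > contig_len:
            raise ValueError(
                f"gene footprint [{start}, {start + gene_spec.span}) exceeds contig of "
                f"length {contig_len} by {start + gene_spec.span - contig_len} bp"
            )
        exons = gene_spec.exon_intervals(start)
        gene_models.append(
            GeneModel(gene_spec.gene_id, contig_name, gene_spec.strand, exons)
        )
        gene_iv = (start, start + gene_spec.span)

    repeat_regions: list[tuple[str, int, int]] = []
    master: str | None = None
    if family_spec is not None:
        master = _random_dna(rng, family_spec.copy_len)
        placed: list[tuple[int, int]] = [] if gene_iv is None else [gene_iv]
        L = family_spec.copy_len
        for _ in range(family_spec.n_copies):
            for _try in range(10_000):
                s = int(rng.integers(0, contig_len - L + 1))
                iv = (s, s + L)
                if all(iv[1] <= a or iv[0] >= b for a, b in placed):
                    placed.append(iv)
                    break
            else:
                raise ValueError(
                    "could not place repeat family copies without overlap; "
                    "contig too small for family footprint"
                )
            copy = _mutate(rng, master, family_spec.divergence_rate)
            seq[iv[0] : iv[1]] = np.frombuffer(copy.encode("ascii"), dtype=np.uint8)
            repeat_regions.append((contig_name, iv[0], iv[1]))
        repeat_regions.sort()

    return ReferenceGenome(
        contigs={contig_name: seq.tobytes().decode("ascii")},
        gene_models=gene_models,
        repeat_regions=repeat_regions,
        family_master=master,
    )


def default_vector(seed: int = 0) -> VectorConstruct:
    """A synthetic four-component cassette (promoter, recombinase cDNA,
    polyA signal, enhancer) with realistic component lengths, generated
    independently of any host genome."""
    rng = np.random.default_rng(seed)
    lens = {"Tie2_promoter": 2000, "Cre": 1030, "MT1_polyA": 240, "Tie2_enhancer": 1700}
    return VectorConstruct([(name, _random_dna(rng, n)) for name, n in lens.items()])


@dataclass
class InsertionSpec:
    """Replace host interval [del_start, del_end) with ``copies`` tandem
    copies of the vector; del_start == del_end is a clean insertion."""

    contig: str
    del_start: int
    del_end: int
    copies: int = 1

    def __post_init__(self) -> None:
        if self.del_end < self.del_start or self.del_start < 0:
            raise ValueError(f"invalid deletion interval [{self.del_start}, {self.del_end})")
        if self.copies < 1:
            raise ValueError("copies must be >= 1")


@dataclass
class PlantedInsertion:
    contig: str
    del_start: int
    del_end: int
    copies: int
    sample_start: int  # vector occupancy in the sample genome (half-open)
    sample_end: int

    @property
    def deletion_length(self) -> int:
        return self.del_end - self.del_start


@dataclass
class SimTruth:
    """Ground truth of planted insertions plus the read design used."""

    insertions: list[PlantedInsertion]
    seed: int | None = None
    read_design: dict | None = None

    def vector_intervals(self, contig: str) -> list[tuple[int, int]]:
        return [
            (p.sample_start, p.sample_end)
            for p in self.insertions
            if p.contig == contig
        ]

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                {
                    "contig": p.contig,
                    "del_start": p.del_start,
                    "del_end": p.del_end,
                    "deletion_length": p.deletion_length,
                    "copies": p.copies,
                    "sample_start": p.sample_start,
                    "sample_end": p.sample_end,
                }
                for p in self.insertions
            ]
        ).to_csv(path, sep="\t", index=False)


def plant_insertions(
    ref: ReferenceGenome | dict[str, str],
    vector: VectorConstruct,
    specs: list[InsertionSpec],
) -> tuple[dict[str, str], SimTruth]:
    """Build the sample genome: each spec's deleted interval is replaced by
    the vector sequence (tandem-repeated per copy count)."""
    contigs = ref.contigs if isinstance(ref, ReferenceGenome) else ref
    by_contig: dict[str, list[InsertionSpec]] = {}
    for sp in specs:
        if sp.contig not in contigs:
            raise ValueError(f"insertion on unknown contig {sp.contig!r}")
        if sp.del_end > len(contigs[sp.contig]):
            raise ValueError(
                f"deletion [{sp.del_start}, {sp.del_end}) exceeds contig {sp.contig}"
            )
        by_contig.setdefault(sp.contig, []).append(sp)
    for name, lst in by_contig.items():
        lst.sort(key=lambda s: s.del_start)
        for a, b in zip(lst, lst[1:]):
            if b.del_start < a.del_end:
                raise ValueError(
                    f"overlapping insertion specs on {name}: "
                    f"[{a.del_start},{a.del_end}) and [{b.del_start},{b.del_end})"
                )

    vseq = vector.full_sequence
    sample: dict[str, str] = {}
    planted: list[PlantedInsertion] = []
    for name, seq in contigs.items():
        lst = by_contig.get(name, [])
        pieces: list[str] = []
        pos = 0
        out = 0
        for sp in lst:
            pieces.append(seq[pos : sp.del_start])
            out += sp.del_start - pos
            ins = vseq * sp.copies
            planted.append(
                PlantedInsertion(
                    contig=name,
                    del_start=sp.del_start,
                    del_end=sp.del_end,
                    copies=sp.copies,
                    sample_start=out,
                    sample_end=out + len(ins),
                )
            )
            pieces.append(ins)
            out += len(ins)
            pos = sp.del_end
        pieces.append(seq[pos:])
        sample[name] = "".join(pieces)
    return sample, SimTruth(insertions=planted)


# ---------------------------------------------------------------------------
# paired-end reads


@dataclass
class ReadPairs:
    """In-memory paired reads; names carry ``|contig|frag_start|frag_end``
    truth tags.  Mate 1 is the forward strand of the fragment start, mate 2
    the reverse complement of the fragment end (FR orientation)."""

    names: list[str]
    r1: list[str]
    r2: list[str]
    read_len: int

    def __len__(self) -> int:
        return len(self.names)

    def extend(self, other: "ReadPairs") -> None:
        if other.read_len != self.read_len:
            raise ValueError("cannot merge read sets with different read lengths")
        self.names.extend(other.names)
        self.r1.extend(other.r1)
        self.r2.extend(other.r2)

    def mates(self):
        """Iterate (name, mate_number, sequence) over all reads."""
        for name, s1, s2 in zip(self.names, self.r1, self.r2):
            yield name, 1, s1
            yield name, 2, s2

    def write_fastq(self, r1_path: str | Path, r2_path: str | Path) -> None:
        qual = "I" * self.read_len
        with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
            for name, s1, s2 in zip(self.names, self.r1, self.r2):
                f1.write(f"@{name}/1\n{s1}\n+\n{qual[: len(s1)]}\n")
                f2.write(f"@{name}/2\n{s2}\n+\n{qual[: len(s2)]}\n")

    @classmethod
    def from_fastq(cls, r1_path: str | Path, r2_path: str | Path) -> "ReadPairs":
        import pysam

        names: list[str] = []
        r1: list[str] = []
        r2: list[str] = []
        with pysam.FastxFile(str(r1_path)) as f1, pysam.FastxFile(str(r2_path)) as f2:
            for a, b in zip(f1, f2):
                n1 = a.name[:-2] if a.name.endswith("/1") else a.name
                n2 = b.name[:-2] if b.name.endswith("/2") else b.name
                if n1 != n2:
                    raise ValueError(f"unpaired reads: {a.name} vs {b.name}")
                names.append(n1)
                r1.append(a.sequence.upper())
                r2.append(b.sequence.upper())
        if not names:
            raise ValueError("empty FASTQ input")
        return cls(names=names, r1=r1, r2=r2, read_len=max(len(s) for s in r1))

    def write_truth_tsv(self, path: str | Path) -> None:
        rows = []
        for name in self.names:
            contig, start, end = parse_truth_tag(name)
            rows.append({"name": name, "contig": contig, "frag_start": start, "frag_end": end})
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def parse_truth_tag(name: str) -> tuple[str, int, int]:
    """Decode ``id|contig|frag_start|frag_end`` from a read name."""
    parts = name.split(TRUTH_DELIM)
    if len(parts) < 4:
        raise ValueError(f"read name {name!r} carries no truth tag")
    return parts[-3], int(parts[-2]), int(parts[-1])


def mate_truth_interval(
    name: str, mate: int, read_len: int
) -> tuple[str, int, int, str]:
    """True origin of one mate: (contig, start, end, strand)."""
    contig, fs, fe = parse_truth_tag(name)
    if mate == 1:
        return contig, fs, fs + read_len, "+"
    return contig, fe - read_len, fe, "-"


def simulate_read_pairs(
    sample: dict[str, str],
    n_pairs: int,
    read_len: int = 100,
    frag_mean: float = 300.0,
    frag_sd: float = 30.0,
    err_rate: float = 0.0,
    seed: int = 0,
    name_prefix: str = "rp",
) -> ReadPairs:
    """Uniform-coverage FR paired-end reads with i.i.d. substitution errors.

    Fragment lengths are Normal(frag_mean, frag_sd) rounded, rejection-
    resampled until they fit [read_len, contig length]; fragment starts are
    uniform.  Deterministic given ``seed``; truth rides in read names.
    """
    if n_pairs <= 0:
        raise ValueError("n_pairs must be positive")
    if not 0 <= err_rate < 1:
        raise ValueError("err_rate must be in [0, 1)")
    usable = {n: s for n, s in sample.items() if len(s) >= read_len}
    if not usable:
        raise ValueError(f"no contig is at least read_len={read_len} bp long")

    rng = np.random.default_rng(seed)
    names_c = list(usable)
    lens = np.array([len(usable[c]) for c in names_c], dtype=np.int64)
    counts = rng.multinomial(n_pairs, lens / lens.sum())

    names: list[str] = []
    r1: list[str] = []
    r2: list[str] = []
    pair_i = 0
    for ci, contig in enumerate(names_c):
        n = int(counts[ci])
        if n == 0:
            continue
        clen = int(lens[ci])
        seq = np.frombuffer(usable[contig].encode("ascii"), dtype=np.uint8)
        flens = np.empty(n, dtype=np.int64)
        todo = np.ones(n, dtype=bool)
        while todo.any():
            m = int(todo.sum())
            draw = np.rint(rng.normal(frag_mean, frag_sd, size=m)).astype(np.int64)
            ok = (draw >= read_len) & (draw <= clen)
            idx = np.nonzero(todo)[0]
            flens[idx[ok]] = draw[ok]
            todo[idx[ok]] = False
        starts = rng.integers(0, clen - flens + 1)
        ends = starts + flens

        offs = np.arange(read_len)
        m1 = seq[starts[:, None] + offs]
        m2 = seq[(ends - read_len)[:, None] + offs]
        # mate 2 reports the reverse complement of the fragment end
        m2 = _revcomp_matrix(m2)
        if err_rate > 0:
            m1 = _apply_errors(rng, m1, err_rate)
            m2 = _apply_errors(rng, m2, err_rate)
        for j in range(n):
            names.append(
                f"{name_prefix}{pair_i}{TRUTH_DELIM}{contig}{TRUTH_DELIM}{int(starts[j])}{TRUTH_DELIM}{int(ends[j])}"
            )
            r1.append(m1[j].tobytes().decode("ascii"))
            r2.append(m2[j].tobytes().decode("ascii"))
            pair_i += 1
    return ReadPairs(names=names, r1=r1, r2=r2, read_len=read_len)


_COMP_U8 = np.zeros(256, dtype=np.uint8)
for _a, _b in zip(b"ACGTNacgtn", b"TGCANTGCAN"):
    _COMP_U8[_a] = _b


def _revcomp_matrix(mat: np.ndarray) -> np.ndarray:
    return _COMP_U8[mat[:, ::-1]]


def _apply_errors(rng: np.random.Generator, mat: np.ndarray, rate: float) -> np.ndarray:
    mat = mat.copy()
    rows, cols = np.nonzero(rng.random(mat.shape) < rate)
    if rows.size:
        idx = np.searchsorted(_BASES, mat[rows, cols])
        mat[rows, cols] = _BASES[(idx + rng.integers(1, 4, size=rows.size)) % 4]
    return mat


def true_vector_span(
    name: str,
    mate: int,
    read_len: int,
    truth: SimTruth,
    sample: dict[str, str],
    vector_len: int,
) -> int:
    """Length of the longest exact vector match within a mate, computed by
    coordinate arithmetic on the truth tag (independent of any screening).

    The overlap of the mate's fragment interval with a planted vector
    interval is extended outwards base-by-base while flanking host sequence
    happens to continue the vector — the same maximal-exact-run definition a
    perfect-identity screen reports.
    """
    contig, s, e, _ = mate_truth_interval(name, mate, read_len)
    seq = sample[contig]
    best = 0
    for p in truth.insertions:
        if p.contig != contig:
            continue
        vs, ve = p.sample_start, p.sample_end
        ov_s, ov_e = max(s, vs), min(e, ve)
        if ov_e <= ov_s:
            continue
        # vector base at sample position x (tandem copies wrap around)
        left = ov_s
        while left > s and _vec_base(seq, vs, ve, vector_len, left - 1) == seq[left - 1]:
            left -= 1
        right = ov_e
        while right < e and _vec_base(seq, vs, ve, vector_len, right) == seq[right]:
            right += 1
        best = max(best, right - left)
    return best


def _vec_base(seq: str, vs: int, ve: int, vlen: int, pos: int) -> str:
    """Vector base that would sit at sample position ``pos`` if the planted
    vector run [vs, ve) extended that far (wrapping tandem copies)."""
    return seq[vs + ((pos - vs) % vlen)]


# ---------------------------------------------------------------------------
# qPCR Ct tables


@dataclass
class AnimalDesign:
    animal_id: str
    group: str
    expression: dict[str, float]  # assay_id -> true expression relative to calibrator


def simulate_ct_table(
    design: list[AnimalDesign],
    baseline_ct: float = 26.0,
    control_ct: float = 12.0,
    ct_sd: float = 0.2,
    nondetect_ct_threshold: float = 40.0,
    replicates: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-replicate Ct values under the exponential-doubling model.

    Target Ct = baseline_ct − log2(expression) + N(0, ct_sd); the multiplexed
    endogenous control sits at control_ct + N(0, ct_sd).  Zero expression
    (or a Ct beyond the cycle cutoff) is emitted as a non-detect (NaN here,
    "ND" in TSV).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for an in design:
        for assay, expr in an.expression.items():
            if expr < 0:
                raise ValueError(
                    f"negative expression {expr} for {an.animal_id}/{assay}"
                )
            for rep in range(1, replicates + 1):
                ct_c = control_ct + rng.normal(0.0, ct_sd)
                if expr == 0:
                    ct_t = math.nan
                else:
                    ct_t = baseline_ct - math.log2(expr) + rng.normal(0.0, ct_sd)
                    if ct_t >= nondetect_ct_threshold:
                        ct_t = math.nan
                rows.append(
                    {
                        "animal_id": an.animal_id,
                        "group": an.group,
                        "assay_id": assay,
                        "replicate": rep,
                        "ct_target": ct_t,
                        "ct_control": ct_c,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["animal_id", "group", "assay_id", "replicate", "ct_target", "ct_control"],
    )


# ---------------------------------------------------------------------------
# morphometric measurements


def simulate_measurements(
    groups: list[tuple[str, float, float, int]],
    metric: str = "measurement",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-group i.i.d. Normal(mean, sd) draws, one row per cell."""
    rng = np.random.default_rng(seed)
    rows = []
    for label, mean, sd, n in groups:
        if n <= 0:
            raise ValueError(f"group {label!r} has non-positive n={n}")
        if sd < 0:
            raise ValueError(f"group {label!r} has negative sd={sd}")
        vals = rng.normal(mean, sd, size=n) if sd > 0 else np.full(n, float(mean))
        for i, v in enumerate(vals, start=1):
            rows.append(
                {"cell_id": f"{label}_{i}", "group": label, "metric": metric, "value": float(v)}
            )
    return pd.DataFrame(rows, columns=["cell_id", "group", "metric", "value"])
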