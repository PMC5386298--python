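"""Reference genomes, gene models and transgene vector constructs.

Coordinates are 0-based half-open throughout the library; report writers
convert to the 1-based style used in genome browsers and publications.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


@dataclass
class GeneModel:
    """An exon/intron structure on one contig.

    ``exons`` are 0-based half-open intervals sorted ascending and pairwise
    disjoint; introns are the gaps between consecutive exons.  Exon and
    intron *ordinals* are counted in transcription order: for a minus-strand
    gene, exon 1 is the genomically last exon.
    """

    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exons:
            raise ValueError("gene model needs at least one exon")
        self.exons = [(int(s), int(e)) for s, e in self.exons]
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"empty or inverted exon [{s}, {e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError("exons must be sorted and disjoint")

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def tss(self) -> int:
        """Transcription start: genomically first base for '+', last for '-'."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:])]

    def n_exons(self) -> int:
        return len(self.exons)


@dataclass
class ReferenceGenome:
    """Named contigs (ACGTN alphabet) plus gene models.

    ``repeat_regions`` records planted repeat-family copies as
    ``(contig, start, end)`` so simulations can validate multi-mapping
    behaviour against known repeat placement; ``family_master`` keeps the
    un-mutated master repeat sequence.
    """

    contigs: dict[str, str]
    gene_models: list[GeneModel] = field(default_factory=list)
    repeat_regions: list[tuple[str, int, int]] = field(default_factory=list)
    family_master: str | None = None

    def __post_init__(self) -> None:
        if not self.contigs:
            raise ValueError("genome needs at least one contig")
        for name, seq in self.contigs.items():
            if not seq:
                raise ValueError(f"contig {name!r} is empty")
        for gm in self.gene_models:
            if gm.contig not in self.contigs:
                raise ValueError(f"gene {gm.gene_id} on unknown contig {gm.contig}")
            if gm.end > len(self.contigs[gm.contig]):
                raise ValueError(
                    f"gene {gm.gene_id} extends past end of contig {gm.contig}"
                )

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.contigs.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path, gene_models: Iterable[GeneModel] = ()) -> "ReferenceGenome":
        contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}
        return cls(contigs=contigs, gene_models=list(gene_models))

    def write_gff3(self, path: str | Path) -> None:
        """Write gene models as GFF3 gene + exon features (1-based inclusive)."""
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for gm in self.gene_models:
                fh.write(
                    f"{gm.contig}\tvectrace\tgene\t{gm.start + 1}\t{gm.end}\t.\t"
                    f"{gm.strand}\t.\tID={gm.gene_id}\n"
                )
                for i, (s, e) in enumerate(gm.exons, start=1):
                    fh.write(
                        f"{gm.contig}\tvectrace\texon\t{s + 1}\t{e}\t.\t{gm.strand}\t.\t"
                        f"ID={gm.gene_id}.exon{i};Parent={gm.gene_id}\n"
                    )


def read_gene_models_gff3(path: str | Path) -> list[GeneModel]:
    """Read gene models (gene + exon features) from a GFF3 file."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    models = []
    for gene in db.features_of_type("gene"):
        exons = sorted(
            (f.start - 1, f.end) for f in db.children(gene, featuretype="exon")
        )
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        models.append(
            GeneModel(
                gene_id=gene.id, contig=gene.seqid, strand=gene.strand, exons=exons
            )
        )
    return models


@dataclass
class VectorConstruct:
    """The transgene cassette: ordered components and their concatenation.

    Mirrors a typical promoter / recombinase cDNA / polyA / enhancer
    construct; ``full_sequence`` is what integrates into the host genome, so
    screening is done against the concatenation and hits are attributed to
    the component under the match midpoint.
    """

    components: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if not self.components:
            raise ValueError("vector needs at least one component")
        self.components = [(n, s.upper()) for n, s in self.components]
        for name, seq in self.components:
            if not seq:
                raise ValueError(f"vector component {name!r} is empty")

    @property
    def full_sequence(self) -> str:
        return "".join(seq for _, seq in self.components)

    def __len__(self) -> int:
        return len(self.full_sequence)

    def component_at(self, pos: int) -> str:
        """Component name covering position ``pos`` of the full sequence."""
        if not 0 <= pos < len(self):
            raise ValueError(f"position {pos} outside vector of length {len(self)}")
        off = 0
        for name, seq in self.components:
            off += len(seq)
            if pos < off:
                return name
        raise AssertionError("unreachable")

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(seq), id=name, description="") for name, seq in self.components
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "VectorConstruct":
        comps = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
        return cls(components=comps)
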