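"""Gene models with exon/CDS structure and strand-aware 5-kb flanks."""

from __future__ import annotations

import os
import tempfile
from dataclasses import dataclass, field

from Bio.Seq import Seq

FLANK_BP = 5000


@dataclass
class GeneModel:
    """Protein-coding gene model, 1-based inclusive coordinates.

    ``exons`` and ``cds`` are sorted lists of (start, end) spans in genomic
    orientation; for minus-strand genes the *transcript* order is the reverse.
    """

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int
    end: int
    exons: list = field(default_factory=list)
    cds: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad gene span {self.start}-{self.end}")
        self.exons = sorted(tuple(e) for e in self.exons)
        self.cds = sorted(tuple(c) for c in self.cds)
        for s, e in self.exons:
            if s < self.start or e > self.end:
                raise ValueError(f"exon {s}-{e} outside gene span of {self.gene_id}")

    # ------------------------------------------------------------------
    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def upstream_flank(self):
        """5-kb span 5' of the gene (strand-aware), clipped at position 1."""
        if self.strand == "+":
            return (max(1, self.start - FLANK_BP), self.start - 1)
        return (self.end + 1, self.end + FLANK_BP)

    def downstream_flank(self):
        if self.strand == "+":
            return (self.end + 1, self.end + FLANK_BP)
        return (max(1, self.start - FLANK_BP), self.start - 1)

    def introns(self):
        """Spans between consecutive exons, genomic orientation."""
        out = []
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def contains(self, pos: int) -> bool:
        return self.start <= pos <= self.end

    # ------------------------------------------------------------------
    def cds_offset(self, pos: int):
        """0-based position of ``pos`` within the spliced CDS (transcript orientation).

        Returns None if ``pos`` is not inside any CDS span.
        """
        off = 0
        if self.strand == "+":
            for s, e in self.cds:
                if s <= pos <= e:
                    return off + (pos - s)
                off += e - s + 1
        else:
            for s, e in reversed(self.cds):
                if s <= pos <= e:
                    return off + (e - pos)
                off += e - s + 1
        return None

    def cds_sequence(self, reference: dict) -> str:
        """Spliced CDS nucleotide sequence in transcript orientation."""
        seq = "".join(reference[self.chrom][s - 1 : e] for s, e in self.cds)
        if self.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


# ----------------------------------------------------------------------
def write_gff3(genes, path) -> None:
    """Emit gene/mRNA/exon/CDS features as GFF3."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda x: (x.chrom, x.start)):
            fh.write(
                f"{g.chrom}\tsvmosaic\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
            )
            mrna = f"{g.gene_id}.1"
            fh.write(
                f"{g.chrom}\tsvmosaic\tmRNA\t{g.start}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tsvmosaic\texon\t{s}\t{e}\t.\t{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )
            frame = 0
            spans = g.cds if g.strand == "+" else list(reversed(g.cds))
            for i, (s, e) in enumerate(spans, 1):
                fh.write(
                    f"{g.chrom}\tsvmosaic\tCDS\t{s}\t{e}\t.\t{g.strand}\t{frame}\tID={mrna}.cds{i};Parent={mrna}\n"
                )
                frame = (3 - ((e - s + 1 - frame) % 3)) % 3


def read_gff3(path):
    """Parse a GFF3 into GeneModel objects (gffutils-backed)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="merge",
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons, cds = [], []
        for mrna in db.children(g, featuretype="mRNA"):
            exons = [(f.start, f.end) for f in db.children(mrna, featuretype="exon")]
            cds = [(f.start, f.end) for f in db.children(mrna, featuretype="CDS")]
            break  # one transcript per synthetic gene
        genes.append(
            GeneModel(
                gene_id=g.id,
                chrom=g.seqid,
                strand=g.strand,
                start=g.start,
                end=g.end,
                exons=exons,
                cds=cds,
            )
        )
    genes.sort(key=lambda x: (x.chrom, x.start))
    return genes
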