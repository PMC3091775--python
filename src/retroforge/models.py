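"""Annotation data model and FASTA/GFF3 input-output.

Coordinates are 0-based half-open internally and converted to 1-based
inclusive only when writing or reading GFF3.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Transcript",
    "GeneModel",
    "spliced_sequence",
    "cds_sequence",
    "extract_proteome",
    "write_fasta",
    "read_fasta",
    "write_gff3",
    "read_gff3",
]


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    contig: str
    strand: str
    exons: list[tuple[int, int]] = field(default_factory=list)
    cds: list[tuple[int, int]] = field(default_factory=list)

    @property
    def start(self) -> int:
        return min(s for s, _ in self.exons)

    @property
    def end(self) -> int:
        return max(e for _, e in self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def n_coding_exons(self) -> int:
        return len(self.cds)

    def introns(self) -> list[tuple[int, int]]:
        """Genomic intervals between consecutive exons, sorted by position."""
        exons = sorted(self.exons)
        return [(e0, s1) for (_, e0), (s1, _) in zip(exons, exons[1:])]


@dataclass
class GeneModel:
    """An annotated gene: span, strand, transcripts and biotype."""

    gene_id: str
    contig: str
    strand: str
    start: int
    end: int
    transcripts: list[Transcript] = field(default_factory=list)
    biotype: str = "protein_coding"

    @property
    def span(self) -> tuple[int, int]:
        return self.start, self.end


def _oriented(seq: str, strand: str) -> str:
    return seq if strand == "+" else str(Seq(seq).reverse_complement())


def spliced_sequence(genome: dict[str, str], tx: Transcript) -> str:
    """Exon sequence of a transcript in transcript (5'->3') orientation."""
    parts = [genome[tx.contig][s:e] for s, e in sorted(tx.exons)]
    return _oriented("".join(parts), tx.strand)


def cds_sequence(genome: dict[str, str], tx: Transcript) -> str:
    """Coding sequence of a transcript in 5'->3' orientation."""
    parts = [genome[tx.contig][s:e] for s, e in sorted(tx.cds)]
    return _oriented("".join(parts), tx.strand)


def extract_proteome(
    genome: dict[str, str],
    genes: list[GeneModel],
    biotypes: tuple[str, ...] = ("protein_coding",),
) -> dict[str, str]:
    """Translate every coding transcript of the selected biotypes.

    Returns protein id (the transcript id) -> amino-acid sequence without
    the terminal stop.
    """
    proteome: dict[str, str] = {}
    for gene in genes:
        if gene.biotype not in biotypes:
            continue
        for tx in gene.transcripts:
            if not tx.cds:
                continue
            cds = cds_sequence(genome, tx)
            usable = len(cds) - len(cds) % 3
            prot = str(Seq(cds[:usable]).translate()).rstrip("*")
            if prot:
                proteome[tx.transcript_id] = prot
    return proteome


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(sequences: dict[str, str], path) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="")
               for name, seq in sequences.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(genes: list[GeneModel], path) -> None:
    """Write gene/mRNA/exon/CDS features, 1-based inclusive coordinates."""
    lines = ["##gff-version 3"]
    for gene in genes:
        attrs = f"ID={gene.gene_id};biotype={gene.biotype}"
        lines.append("\t".join([
            gene.contig, "retroforge", "gene",
            str(gene.start + 1), str(gene.end), ".", gene.strand, ".", attrs]))
        for tx in gene.transcripts:
            lines.append("\t".join([
                gene.contig, "retroforge", "mRNA",
                str(tx.start + 1), str(tx.end), ".", tx.strand, ".",
                f"ID={tx.transcript_id};Parent={gene.gene_id}"]))
            for k, (s, e) in enumerate(sorted(tx.exons)):
                lines.append("\t".join([
                    gene.contig, "retroforge", "exon",
                    str(s + 1), str(e), ".", tx.strand, ".",
                    f"ID={tx.transcript_id}.exon{k};Parent={tx.transcript_id}"]))
            for k, (s, e) in enumerate(sorted(tx.cds)):
                lines.append("\t".join([
                    gene.contig, "retroforge", "CDS",
                    str(s + 1), str(e), ".", tx.strand, "0",
                    f"ID={tx.transcript_id}.cds{k};Parent={tx.transcript_id}"]))
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def read_gff3(path_or_text) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS features back into :class:`GeneModel` objects."""
    text = path_or_text
    try:
        with open(path_or_text) as fh:
            text = fh.read()
    except (OSError, TypeError):
        pass
    db = gffutils.create_db(
        io.StringIO(text).getvalue(), ":memory:", from_string=True,
        merge_strategy="create_unique", keep_order=True)
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene"):
        gene = GeneModel(
            gene_id=g.id, contig=g.seqid, strand=g.strand,
            start=g.start - 1, end=g.end,
            biotype=g.attributes.get("biotype", ["protein_coding"])[0],
        )
        for t in db.children(g, featuretype="mRNA"):
            tx = Transcript(
                transcript_id=t.id, gene_id=g.id, contig=t.seqid, strand=t.strand)
            for ex in db.children(t, featuretype="exon"):
                tx.exons.append((ex.start - 1, ex.end))
            for c in db.children(t, featuretype="CDS"):
                tx.cds.append((c.start - 1, c.end))
            tx.exons.sort()
            tx.cds.sort()
            gene.transcripts.append(tx)
        genes.append(gene)
    return genes
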