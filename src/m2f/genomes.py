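"""Annotated-genome container and plain-text I/O (FASTA, GFF3, protein FASTA).

An :class:`AnnotatedGenome` bundles contig sequences with gene records read
from (or destined for) a GFF3 file.  Coordinates follow the GFF3 convention
(1-based, inclusive); all internal slicing converts to half-open 0-based at
the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

_COMPLEMENT = str.maketrans("ACGTRYMKSWBDHVN", "TGCAYRKMSWVHDBN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str, table: int = 11) -> str:
    """Translate a coding sequence (bacterial code), dropping a trailing stop."""
    prot = str(Seq(cds).translate(table=table))
    return prot[:-1] if prot.endswith("*") else prot


@dataclass
class GeneRecord:
    """One annotated gene (CDS or rRNA) on a contig."""

    gene_id: str
    feature_type: str  # "CDS" or "rRNA"
    product: str
    contig: str
    start: int  # 1-based inclusive
    end: int  # 1-based inclusive
    strand: str  # "+" or "-"
    sequence: str = ""  # gene sequence, 5'->3'
    family: str = ""  # gene-family label (synthetic corpora only)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class AnnotatedGenome:
    """Contig sequences plus gene annotations plus taxonomy for one genome."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[GeneRecord]
    taxonomy: dict[str, str] = field(default_factory=dict)
    # inter-gene spacer sequences kept so the assembly can be rebuilt after
    # in-place edits of gene sequences (synthetic corpora only)
    spacers: list[str] | None = None

    def gene_sequence(self, gene: GeneRecord) -> str:
        """Excise a gene from its contig, reverse-complementing '-' features."""
        try:
            contig = self.contigs[gene.contig]
        except KeyError:
            raise KeyError(
                f"feature {gene.gene_id} references unknown contig {gene.contig!r}"
            ) from None
        if gene.start < 1 or gene.end > len(contig):
            raise ValueError(
                f"feature {gene.gene_id} ({gene.start}..{gene.end}) outside "
                f"contig {gene.contig!r} of length {len(contig)}"
            )
        sub = contig[gene.start - 1 : gene.end]
        return reverse_complement(sub) if gene.strand == "-" else sub

    def proteins(self) -> dict[str, str]:
        """Translate every CDS (bacterial code, table 11)."""
        out: dict[str, str] = {}
        for g in self.genes:
            if g.feature_type == "CDS":
                cds = g.sequence or self.gene_sequence(g)
                out[g.gene_id] = translate_cds(cds)
        return out


def assemble_genome(
    genome_id: str,
    genes: list[GeneRecord],
    spacers: list[str],
    taxonomy: dict[str, str] | None = None,
) -> AnnotatedGenome:
    """Lay genes out on a single replicon separated by the given spacers.

    ``spacers`` must hold ``len(genes) + 1`` entries (leading, between, and
    trailing).  Gene coordinates and the contig sequence are derived from the
    gene sequences; '-' strand genes are embedded as their reverse complement.
    """
    if len(spacers) != len(genes) + 1:
        raise ValueError("need len(genes) + 1 spacer sequences")
    parts: list[str] = []
    pos = 0
    placed: list[GeneRecord] = []
    for gene, spacer in zip(genes, spacers[:-1]):
        parts.append(spacer)
        pos += len(spacer)
        start = pos + 1
        end = pos + len(gene.sequence)
        embedded = (
            reverse_complement(gene.sequence) if gene.strand == "-" else gene.sequence
        )
        parts.append(embedded)
        pos = end
        placed.append(
            replace(gene, contig=genome_id, start=start, end=end)
        )
    parts.append(spacers[-1])
    return AnnotatedGenome(
        genome_id=genome_id,
        contigs={genome_id: "".join(parts)},
        genes=placed,
        taxonomy=dict(taxonomy or {}),
        spacers=list(spacers),
    )


def rebuild_assembly(genome: AnnotatedGenome) -> AnnotatedGenome:
    """Re-assemble the contig from (possibly edited) gene sequences."""
    if genome.spacers is None:
        raise ValueError("genome was not built by assemble_genome")
    return assemble_genome(
        genome.genome_id, genome.genes, genome.spacers, genome.taxonomy
    )


# ---------------------------------------------------------------------------
# plain-text I/O


def write_fasta(path: str | Path, records: dict[str, str], width: int = 70) -> None:
    seqs = [SeqRecord(Seq(s), id=name, description="") for name, s in records.items()]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seqs)


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_gff(path: str | Path, genome: AnnotatedGenome) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, seq in genome.contigs.items():
            fh.write(f"##sequence-region {name} 1 {len(seq)}\n")
        for g in genome.genes:
            attrs = f"ID={g.gene_id};product={g.product}"
            if g.family:
                attrs += f";family={g.family}"
            fh.write(
                "\t".join(
                    [
                        g.contig,
                        "m2f_sim",
                        g.feature_type,
                        str(g.start),
                        str(g.end),
                        ".",
                        g.strand,
                        ".",
                        attrs,
                    ]
                )
                + "\n"
            )


def parse_gff_attributes(text: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for chunk in text.strip().split(";"):
        if not chunk:
            continue
        key, _, value = chunk.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_gff(path: str | Path) -> list[GeneRecord]:
    genes: list[GeneRecord] = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}: malformed GFF3 line: {line!r}")
            contig, _src, ftype, start, end, _score, strand, _phase, attrs = cols
            a = parse_gff_attributes(attrs)
            genes.append(
                GeneRecord(
                    gene_id=a.get("ID", f"{contig}:{start}-{end}"),
                    feature_type=ftype,
                    product=a.get("product", ""),
                    contig=contig,
                    start=int(start),
                    end=int(end),
                    strand=strand if strand in "+-" else "+",
                    family=a.get("family", ""),
                )
            )
    return genes


def load_genome(
    genome_id: str,
    fna: str | Path,
    gff: str | Path,
    taxonomy: dict[str, str] | None = None,
) -> AnnotatedGenome:
    genome = AnnotatedGenome(
        genome_id=genome_id,
        contigs=read_fasta(fna),
        genes=read_gff(gff),
        taxonomy=dict(taxonomy or {}),
    )
    for g in genome.genes:
        g.sequence = genome.gene_sequence(g)
    return genome


def write_genome(genome: AnnotatedGenome, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(outdir / f"{genome.genome_id}.fna", genome.contigs)
    write_gff(outdir / f"{genome.genome_id}.gff", genome)
    write_fasta(outdir / f"{genome.genome_id}.faa", genome.proteins())
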