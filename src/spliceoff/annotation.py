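"""Genome and annotation I/O.

Reads genome FASTA and Ensembl-dialect GTF into light gene/transcript models,
extracts pre-spliced (genomic-span, sense-orientation) gene sequences — the
search space an antisense oligonucleotide hybridizes to — and converts between
gene-local and genomic coordinates.

All internal coordinates are 0-based half-open.  GTF (1-based inclusive) is
converted at the reader; the inverse conversion is applied on export.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import gffutils
from Bio import SeqIO
from Bio.Seq import Seq

from .errors import BoundsError, FormatError

# IUPAC nucleotide one-letter codes accepted in genome FASTA input.
IUPAC_NT = set("ACGTUNRYSWKMBDHV")


@dataclass(frozen=True)
class TranscriptModel:
    """One transcript: an ordered list of exon intervals on the genome."""

    transcript_id: str
    exons: tuple[tuple[int, int], ...]  # sorted, non-overlapping, half-open
    tags: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not self.exons:
            raise FormatError(f"transcript {self.transcript_id} has no exons")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise FormatError(
                    f"transcript {self.transcript_id}: exons overlap or unsorted"
                )

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])


@dataclass(frozen=True)
class GeneModel:
    """One gene: shared contig/strand plus its transcripts."""

    gene_id: str
    symbol: str
    contig: str
    strand: str
    span: tuple[int, int]
    transcripts: tuple[TranscriptModel, ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise FormatError(f"gene {self.gene_id}: bad strand {self.strand!r}")

    @property
    def exons(self) -> list[tuple[int, int]]:
        out = {iv for tx in self.transcripts for iv in tx.exons}
        return sorted(out)


@dataclass
class GenomeAnnotation:
    """A set of gene models plus (optionally) contig lengths."""

    genes: list[GeneModel]
    contig_lengths: dict[str, int] = field(default_factory=dict)

    def by_id(self, gene_id: str) -> GeneModel:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def validate(self) -> None:
        """Check structural invariants; raises on violation."""
        for g in self.genes:
            lo, hi = g.span
            if self.contig_lengths:
                clen = self.contig_lengths.get(g.contig)
                if clen is None:
                    raise BoundsError(f"gene {g.gene_id}: unknown contig {g.contig}")
                if not (0 <= lo <= hi <= clen):
                    raise BoundsError(
                        f"gene {g.gene_id}: span {g.span} outside contig "
                        f"{g.contig} (length {clen})"
                    )
            for tx in g.transcripts:
                ts, te = tx.span
                if ts < lo or te > hi:
                    raise BoundsError(
                        f"gene {g.gene_id}: transcript {tx.transcript_id} "
                        "outside gene span"
                    )


@dataclass(frozen=True)
class PresplicedRecord:
    """The sense-orientation pre-mRNA sequence over a gene's genomic span."""

    gene_id: str
    contig: str
    strand: str
    span: tuple[int, int]
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) != self.span[1] - self.span[0]:
            raise BoundsError(
                f"{self.gene_id}: sequence length {len(self.sequence)} != "
                f"span length {self.span[1] - self.span[0]}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def read_genome(fasta_path: str | Path) -> dict[str, str]:
    """Read a multi-record FASTA into a contig→sequence map.

    Sequences are uppercased and U is converted to T.  Duplicate record names
    and non-IUPAC characters are format errors.
    """
    contigs: dict[str, str] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in contigs:
            raise FormatError(f"duplicate contig name {rec.id!r} in {fasta_path}")
        seq = str(rec.seq).upper().replace("U", "T")
        bad = set(seq) - IUPAC_NT
        if bad:
            pos = next(i for i, c in enumerate(seq) if c in bad)
            raise FormatError(
                f"record {rec.id!r}: non-IUPAC character {seq[pos]!r} at "
                f"position {pos}"
            )
        contigs[rec.id] = seq
    return contigs


def contig_lengths(genome: dict[str, str]) -> dict[str, int]:
    return {name: len(seq) for name, seq in genome.items()}


def read_gtf(gtf_path: str | Path, basic_only: bool = False) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF into a :class:`GenomeAnnotation`.

    When *basic_only* is set, transcripts lacking ``tag "basic"`` are dropped
    and genes left without transcripts are dropped; gene spans are recomputed
    from the retained exons.
    """
    db = gffutils.create_db(
        str(gtf_path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    # exons grouped per transcript, transcript metadata per gene
    tx_exons: dict[str, list[tuple[int, int]]] = {}
    tx_tags: dict[str, set[str]] = {}
    tx_gene: dict[str, str] = {}
    gene_meta: dict[str, tuple[str, str, str]] = {}  # gene_id -> (symbol, contig, strand)

    for feat in db.features_of_type("exon", order_by=("seqid", "start")):
        if feat.end < feat.start:
            raise FormatError(
                f"{gtf_path}: exon with end < start at {feat.seqid}:{feat.start}"
            )
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise FormatError(
                f"{gtf_path}: exon feature missing {exc} at "
                f"{feat.seqid}:{feat.start}-{feat.end}"
            ) from None
        symbol = feat.attributes.get("gene_name", [gene_id])[0]
        interval = (feat.start - 1, feat.end)  # 1-based inclusive -> half-open
        tx_exons.setdefault(tx_id, []).append(interval)
        tx_tags.setdefault(tx_id, set()).update(feat.attributes.get("tag", []))
        prev = tx_gene.setdefault(tx_id, gene_id)
        if prev != gene_id:
            raise FormatError(f"transcript {tx_id} assigned to two genes")
        meta = (symbol, feat.seqid, feat.strand)
        prev_meta = gene_meta.setdefault(gene_id, meta)
        if prev_meta[1:] != meta[1:]:
            raise FormatError(f"gene {gene_id}: transcripts on different contigs/strands")

    genes: list[GeneModel] = []
    by_gene: dict[str, list[TranscriptModel]] = {}
    for tx_id, exons in tx_exons.items():
        tags = frozenset(tx_tags[tx_id])
        if basic_only and "basic" not in tags:
            continue
        tx = TranscriptModel(tx_id, tuple(sorted(exons)), tags)
        by_gene.setdefault(tx_gene[tx_id], []).append(tx)

    for gene_id, txs in by_gene.items():
        symbol, contig, strand = gene_meta[gene_id]
        txs = tuple(sorted(txs, key=lambda t: t.transcript_id))
        lo = min(t.span[0] for t in txs)
        hi = max(t.span[1] for t in txs)
        genes.append(GeneModel(gene_id, symbol, contig, strand, (lo, hi), txs))

    genes.sort(key=lambda g: (g.contig, g.span, g.gene_id))
    return GenomeAnnotation(genes=genes)


def extract_prespliced(
    annotation: GenomeAnnotation, genome: dict[str, str]
) -> list[PresplicedRecord]:
    """One sense-orientation pre-mRNA record per gene (union genomic span)."""
    records = []
    for g in annotation.genes:
        if g.contig not in genome:
            raise BoundsError(f"gene {g.gene_id}: contig {g.contig} not in genome")
        contig_seq = genome[g.contig]
        lo, hi = g.span
        if hi > len(contig_seq) or lo < 0:
            raise BoundsError(
                f"gene {g.gene_id}: span {g.span} exceeds contig "
                f"{g.contig} length {len(contig_seq)}"
            )
        seq = contig_seq[lo:hi]
        if g.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        records.append(PresplicedRecord(g.gene_id, g.contig, g.strand, g.span, seq))
    return records


def gene_offset_to_genomic(
    record: PresplicedRecord, local_interval: tuple[int, int]
) -> tuple[int, int]:
    """Map a gene-local (sense pre-mRNA) interval to a genomic interval."""
    s, e = local_interval
    if not (0 <= s <= e <= len(record)):
        raise BoundsError(
            f"local interval {local_interval} outside record {record.gene_id} "
            f"(length {len(record)})"
        )
    lo, hi = record.span
    if record.strand == "+":
        return (lo + s, lo + e)
    return (hi - e, hi - s)


def genomic_to_gene_offset(
    record: PresplicedRecord, genomic_interval: tuple[int, int]
) -> tuple[int, int]:
    """Inverse of :func:`gene_offset_to_genomic`."""
    s, e = genomic_interval
    lo, hi = record.span
    if not (lo <= s <= e <= hi):
        raise BoundsError(
            f"genomic interval {genomic_interval} outside span of {record.gene_id}"
        )
    if record.strand == "+":
        return (s - lo, e - lo)
    return (hi - e, hi - s)


def write_prespliced_fasta(records: Iterable[PresplicedRecord], path: str | Path) -> None:
    """Export pre-spliced records with ``gene_id|contig|strand|start-end`` headers."""
    with open(path, "w") as fh:
        for rec in records:
            lo, hi = rec.span
            fh.write(f">{rec.gene_id}|{rec.contig}|{rec.strand}|{lo}-{hi}\n")
            for i in range(0, len(rec.sequence), 70):
                fh.write(rec.sequence[i : i + 70] + "\n")


def write_gtf(annotation: GenomeAnnotation, path: str | Path, source: str = "spliceoff") -> None:
    """Write the annotation back out as Ensembl-dialect GTF."""
    with open(path, "w") as fh:
        for g in annotation.genes:
            lo, hi = g.span
            attrs = f'gene_id "{g.gene_id}"; gene_name "{g.symbol}";'
            fh.write(
                f"{g.contig}\t{source}\tgene\t{lo + 1}\t{hi}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for tx in g.transcripts:
                ts, te = tx.span
                tag_str = "".join(f' tag "{t}";' for t in sorted(tx.tags))
                tx_attrs = (
                    f'gene_id "{g.gene_id}"; gene_name "{g.symbol}"; '
                    f'transcript_id "{tx.transcript_id}";{tag_str}'
                )
                fh.write(
                    f"{g.contig}\t{source}\ttranscript\t{ts + 1}\t{te}\t.\t"
                    f"{g.strand}\t.\t{tx_attrs}\n"
                )
                for es, ee in tx.exons:
                    fh.write(
                        f"{g.contig}\t{source}\texon\t{es + 1}\t{ee}\t.\t"
                        f"{g.strand}\t.\t{tx_attrs}\n"
                    )


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in genome:
            fh.write(f">{name}\n")
            seq = genome[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_gtf_text(text: str, basic_only: bool = False) -> GenomeAnnotation:
    """Convenience wrapper: parse GTF from an in-memory string (tests)."""
    with tempfile.NamedTemporaryFile("w", suffix=".gtf", delete=False) as fh:
        fh.write(text)
        name = fh.name
    try:
        return read_gtf(name, basic_only=basic_only)
    finally:
        Path(name).unlink(missing_ok=True)
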