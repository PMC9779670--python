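"""Sequence and gene-model data structures plus the standard-format I/O layer.

All coordinates inside the package are 0-based half-open.  GFF3 (1-based,
inclusive) is converted at the I/O boundary and nowhere else.  Minus-strand
genes store their exons in genomic order with a strand flag; transcription
order is always computed on demand.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Sequence as TypingSequence

from Bio.Seq import Seq

logger = logging.getLogger("silkarch")

DNA_ALPHABET = set("ACGTN")
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWY") | {"X", "*"}
#: sentinel used by motif discovery to mask residues; never a valid residue
MASK_CHAR = "#"


class Alphabet(str, Enum):
    DNA = "DNA"
    PROTEIN = "PROTEIN"


class SilkarchError(Exception):
    """Base class for package errors."""


class ParseError(SilkarchError):
    """Malformed input file."""


class ValidationError(SilkarchError):
    """Structurally invalid data."""


@dataclass(frozen=True)
class Sequence:
    """A named sequence over a declared alphabet (residues stored uppercase)."""

    id: str
    residues: str
    alphabet: Alphabet = Alphabet.DNA

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: empty residues")
        allowed = DNA_ALPHABET if self.alphabet is Alphabet.DNA else PROTEIN_ALPHABET
        bad = set(self.residues) - allowed - {MASK_CHAR}
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: characters {sorted(bad)} not in "
                f"{self.alphabet.value} alphabet"
            )

    def __len__(self) -> int:
        return len(self.residues)

    def subseq(self, start: int, end: int, new_id: str | None = None) -> "Sequence":
        return Sequence(new_id or self.id, self.residues[start:end], self.alphabet)

    def reverse_complement(self, new_id: str | None = None) -> "Sequence":
        if self.alphabet is not Alphabet.DNA:
            raise ValidationError("reverse_complement requires a DNA sequence")
        return Sequence(new_id or self.id, str(Seq(self.residues).reverse_complement()),
                        Alphabet.DNA)


@dataclass(frozen=True)
class GeneModel:
    """Exon structure of one gene on one contig.

    ``exons`` are stored in genomic (coordinate-ascending) order regardless of
    strand; use :meth:`exons_transcription_order` for transcript order.
    """

    gene_id: str
    contig_id: str
    strand: str  # '+' or '-'
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise ValidationError(f"gene {self.gene_id!r}: unknown strand {self.strand!r}")
        if not self.exons:
            raise ValidationError(f"gene {self.gene_id!r}: no exons")
        exons = tuple(sorted(tuple(e) for e in self.exons))
        for start, end in exons:
            if start >= end:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exon ({start},{end}) has start >= end")
        for (s1, e1), (s2, e2) in zip(exons, exons[1:]):
            if s2 < e1:
                raise ValidationError(
                    f"gene {self.gene_id!r}: exons ({s1},{e1}) and ({s2},{e2}) overlap")
            if s2 == e1:
                raise ValidationError(
                    f"gene {self.gene_id!r}: implied intron between ({s1},{e1}) and "
                    f"({s2},{e2}) has length 0")
        object.__setattr__(self, "exons", exons)

    def exons_transcription_order(self) -> tuple[tuple[int, int], ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns_genomic(self) -> tuple[tuple[int, int], ...]:
        """Implied introns (gaps between exons) in genomic order."""
        return tuple((e1, s2) for (_, e1), (s2, _) in zip(self.exons, self.exons[1:]))

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]


@dataclass(frozen=True)
class AlignmentMatrix:
    """Gapped sequences of equal length, gap character '-'."""

    rows: tuple[str, ...]
    row_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.row_ids):
            raise ValidationError("rows and row_ids differ in length")
        if not self.rows:
            raise ValidationError("empty alignment")
        n = len(self.rows[0])
        if any(len(r) != n for r in self.rows):
            raise ValidationError("alignment rows differ in length")
        for j in range(n):
            if all(r[j] == "-" for r in self.rows):
                raise ValidationError(f"alignment column {j} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def column(self, j: int) -> tuple[str, ...]:
        return tuple(r[j] for r in self.rows)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path, alphabet: Alphabet = Alphabet.DNA) -> list[Sequence]:
    """Read a (wrapped or unwrapped) multi-record FASTA file.

    The id is the header text up to the first whitespace; residues are
    uppercased.  Raises :class:`ParseError` (with a line number) on sequence
    text appearing before the first header, and on duplicate ids.
    """
    path = Path(path)
    records: list[Sequence] = []
    seen: set[str] = set()
    cur_id: str | None = None
    cur_chunks: list[str] = []

    def flush(line_no: int) -> None:
        nonlocal cur_id, cur_chunks
        if cur_id is None:
            return
        if cur_id in seen:
            raise ParseError(f"{path}: duplicate record id {cur_id!r} (line {line_no})")
        seen.add(cur_id)
        residues = "".join(cur_chunks).upper()
        if not residues:
            raise ParseError(f"{path}: record {cur_id!r} has no sequence (line {line_no})")
        records.append(Sequence(cur_id, residues, alphabet))
        cur_id, cur_chunks = None, []

    with open(path, encoding="utf-8") as fh:
        for line_no, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush(line_no)
                cur_id = line[1:].split()[0] if line[1:].split() else ""
                if not cur_id:
                    raise ParseError(f"{path}: empty FASTA header at line {line_no}")
            else:
                if cur_id is None:
                    raise ParseError(
                        f"{path}: sequence before first header at line {line_no}")
                cur_chunks.append(line)
        flush(line_no if records or cur_id else 0)
    return records


def write_fasta(path: str | Path, seqs: Iterable[Sequence], width: int = 60) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.residues), width):
                fh.write(s.residues[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# Gene models (GFF3 exon subset / TSV exon table)
# ---------------------------------------------------------------------------

TSV_COLUMNS = ("gene_id", "contig_id", "strand", "exon_start", "exon_end")


def _gff3_gene_id(attributes: str) -> str | None:
    for entry in attributes.strip().split(";"):
        entry = entry.strip()
        if not entry:
            continue
        if "=" in entry:
            key, value = entry.split("=", 1)
            if key in {"Parent", "gene_id", "ID"}:
                return value
    return None


def read_gene_models(path: str | Path, dialect: str = "GFF3") -> list[GeneModel]:
    """Read gene models from GFF3 (exon features) or from a TSV exon table.

    GFF3 coordinates are 1-based inclusive and converted to the internal
    0-based half-open convention; the TSV dialect is already 0-based half-open
    with columns gene_id, contig_id, strand, exon_start, exon_end.
    """
    path = Path(path)
    dialect = dialect.upper()
    # gene_id -> (contig, strand, [exons])
    acc: dict[str, tuple[str, str, list[tuple[int, int]]]] = {}

    def add(gene_id: str, contig: str, strand: str, start: int, end: int,
            line_no: int) -> None:
        if gene_id in acc:
            contig0, strand0, exons = acc[gene_id]
            if contig0 != contig or strand0 != strand:
                raise ParseError(
                    f"{path}:{line_no}: gene {gene_id!r} spans multiple contigs/strands")
            exons.append((start, end))
        else:
            acc[gene_id] = (contig, strand, [(start, end)])

    with open(path, encoding="utf-8") as fh:
        if dialect == "GFF3":
            for line_no, raw in enumerate(fh, start=1):
                line = raw.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                fields = line.split("\t")
                if len(fields) != 9:
                    raise ParseError(f"{path}:{line_no}: expected 9 GFF3 columns, "
                                     f"got {len(fields)}")
                contig, _, feature, start, end, _, strand, _, attrs = fields
                if feature != "exon":
                    continue
                gene_id = _gff3_gene_id(attrs)
                if gene_id is None:
                    raise ParseError(f"{path}:{line_no}: exon without Parent/ID/gene_id")
                add(gene_id, contig, strand, int(start) - 1, int(end), line_no)
        elif dialect == "TSV":
            header = fh.readline().rstrip("\n").split("\t")
            if tuple(header) != TSV_COLUMNS:
                raise ParseError(f"{path}:1: expected header {TSV_COLUMNS}, got {header}")
            for line_no, raw in enumerate(fh, start=2):
                line = raw.rstrip("\n")
                if not line:
                    continue
                fields = line.split("\t")
                if len(fields) != 5:
                    raise ParseError(f"{path}:{line_no}: expected 5 columns")
                gene_id, contig, strand, start, end = fields
                add(gene_id, contig, strand, int(start), int(end), line_no)
        else:
            raise ValueError(f"unknown dialect {dialect!r}")

    return [GeneModel(gene_id, contig, strand, tuple(exons))
            for gene_id, (contig, strand, exons) in acc.items()]


def write_gene_models_tsv(path: str | Path, genes: Iterable[GeneModel]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("\t".join(TSV_COLUMNS) + "\n")
        for g in genes:
            for start, end in g.exons:
                fh.write(f"{g.gene_id}\t{g.contig_id}\t{g.strand}\t{start}\t{end}\n")


# ---------------------------------------------------------------------------
# Translation and flanking extraction
# ---------------------------------------------------------------------------

def spliced_cds(gene: GeneModel, genome: Sequence) -> Sequence:
    """Concatenate exon sequence in transcription order (strand-applied)."""
    if gene.contig_id != genome.id:
        raise ValidationError(
            f"gene {gene.gene_id!r} is on contig {gene.contig_id!r}, not {genome.id!r}")
    parts = [genome.residues[s:e] for s, e in gene.exons]
    cds = "".join(parts)
    if gene.strand == "-":
        cds = str(Seq(cds).reverse_complement())
    return Sequence(f"{gene.gene_id}_cds", cds, Alphabet.DNA)


def extract_cds_and_translate(
    gene: GeneModel, genome: Sequence
) -> tuple[Sequence, Sequence, bool]:
    """Splice, reverse-complement on '-', and translate with the standard code.

    Returns ``(cds, protein, premature_stop)``.  The terminal stop is removed
    from the protein; a ``*`` before the final codon flags a premature stop
    (pseudogene candidate).  Ambiguous bases translate to ``X`` with a logged
    warning.
    """
    cds = spliced_cds(gene, genome)
    if len(cds) % 3 != 0:
        raise ValidationError(
            f"gene {gene.gene_id!r}: CDS length {len(cds)} not divisible by 3")
    aa = str(Seq(cds.residues).translate())
    if "X" in aa:
        logger.warning("gene %s: ambiguous base(s) translated to X", gene.gene_id)
    if aa.endswith("*"):
        aa = aa[:-1]
    premature_stop = "*" in aa
    protein = Sequence(f"{gene.gene_id}_protein", aa, Alphabet.PROTEIN)
    return cds, protein, premature_stop


def extract_flanking(
    gene: GeneModel,
    genome: Sequence,
    up_len: int = 1000,
    down_len: int = 1000,
) -> tuple[Sequence, bool, Sequence, bool]:
    """Strand-aware upstream/downstream flanking sequence of a gene.

    Upstream covers ``up_len`` bases 5' of the first coding base and downstream
    ``down_len`` bases 3' of the stop codon; both truncated at the contig edge.
    Returns ``(upstream, up_truncated, downstream, down_truncated)``.
    Minus-strand flanks are reverse-complemented into transcript orientation.
    """
    if gene.contig_id != genome.id:
        raise ValidationError(
            f"gene {gene.gene_id!r} is on contig {gene.contig_id!r}, not {genome.id!r}")
    if up_len < 1 or down_len < 1:
        raise ValidationError("flanking lengths must be >= 1")
    n = len(genome)
    if gene.strand == "+":
        up_s, up_e = max(0, gene.start - up_len), gene.start
        dn_s, dn_e = gene.end, min(n, gene.end + down_len)
        up = genome.residues[up_s:up_e]
        dn = genome.residues[dn_s:dn_e]
    else:
        up_s, up_e = gene.end, min(n, gene.end + up_len)
        dn_s, dn_e = max(0, gene.start - down_len), gene.start
        up = str(Seq(genome.residues[up_s:up_e]).reverse_complement())
        dn = str(Seq(genome.residues[dn_s:dn_e]).reverse_complement())
    up_trunc = len(up) < up_len
    dn_trunc = len(dn) < down_len
    upstream = Sequence(f"{gene.gene_id}_up", up, Alphabet.DNA) if up else None
    downstream = Sequence(f"{gene.gene_id}_down", dn, Alphabet.DNA) if dn else None
    if upstream is None or downstream is None:
        raise ValidationError(
            f"gene {gene.gene_id!r}: flanking region empty at contig edge")
    return upstream, up_trunc, downstream, dn_trunc
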