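"""Linked-read barcode analysis: molecule calling, equal-molecule segment
partition, barcode similarity and contig adjacency/orientation inference.

Linked-read libraries tag short reads with a barcode identifying the long
source DNA molecule.  Clustering same-barcode reads that map within a maximum
gap reconstructs those molecules; contigs whose terminal windows share many
molecule barcodes are likely adjacent in the genome.

Input is a 4-column TSV projection of barcoded alignments
(contig, start, end, barcode; header required) rather than BAM.  From a
BX-tagged SAM the projection is one line of awk::

    samtools view in.bam | awk -v OFS='\\t' \\
      '{for(i=12;i<=NF;i++) if($i~/^BX:Z:/) print $3, $4-1, $4-1+length($10), substr($i,6)}'
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable

from .core_io import ParseError, ValidationError

__all__ = [
    "BarcodedAlignment",
    "Molecule",
    "Segment",
    "SegmentPartition",
    "AdjacencyCandidate",
    "read_alignments_tsv",
    "write_molecules_tsv",
    "call_molecules",
    "partition_segments",
    "barcode_similarity",
    "infer_adjacencies",
]

ALIGNMENT_COLUMNS = ("contig", "start", "end", "barcode")


@dataclass(frozen=True)
class BarcodedAlignment:
    contig_id: str
    start: int
    end: int
    barcode: str

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"alignment on {self.contig_id}: start {self.start} >= end {self.end}")
        if not self.barcode:
            raise ValidationError("alignment with empty barcode")


@dataclass(frozen=True)
class Molecule:
    contig_id: str
    barcode: str
    start: int
    end: int
    read_count: int


@dataclass(frozen=True)
class Segment:
    contig_id: str
    start: int
    end: int
    molecules: frozenset[int]  # indices into the molecule list


@dataclass(frozen=True)
class SegmentPartition:
    contig_id: str
    segments: tuple[Segment, ...]


@dataclass(frozen=True)
class AdjacencyCandidate:
    contig_a: str
    end_a: str  # "5p" | "3p"
    contig_b: str
    end_b: str
    jaccard: float
    shared_barcodes: int
    rank: int

    @property
    def implied_orientation(self) -> str:
        """Relative orientation implied by the paired ends: joining 3'->5'
        keeps both contigs forward; 3'-3' or 5'-5' implies an inversion."""
        if {self.end_a, self.end_b} == {"3p", "5p"}:
            return "forward"
        return "inverted"


def read_alignments_tsv(path: str | Path) -> list[BarcodedAlignment]:
    path = Path(path)
    out: list[BarcodedAlignment] = []
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != ALIGNMENT_COLUMNS:
            raise ParseError(f"{path}:1: expected header {ALIGNMENT_COLUMNS}, "
                             f"got {header}")
        for line_no, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise ParseError(f"{path}:{line_no}: expected 4 columns")
            contig, start, end, barcode = fields
            out.append(BarcodedAlignment(contig, int(start), int(end), barcode))
    return out


def write_molecules_tsv(path: str | Path, molecules: Iterable[Molecule]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("contig\tstart\tend\tbarcode\tread_count\n")
        for m in molecules:
            fh.write(f"{m.contig_id}\t{m.start}\t{m.end}\t{m.barcode}\t"
                     f"{m.read_count}\n")


def call_molecules(
    alignments: list[BarcodedAlignment],
    max_gap: int = 50_000,
    min_reads: int = 2,
) -> list[Molecule]:
    """Single-linkage chaining of same-barcode alignments into molecules.

    Per (contig, barcode), alignments sorted by start are chained while the
    gap to the next alignment (next.start - current extent end; negative
    treated as 0) is <= ``max_gap``.  Molecule start/end are the leftmost
    alignment start and rightmost alignment end; clusters with fewer than
    ``min_reads`` reads are discarded.  Order-independent by construction.
    """
    by_key: dict[tuple[str, str], list[BarcodedAlignment]] = defaultdict(list)
    for a in alignments:
        by_key[(a.contig_id, a.barcode)].append(a)
    molecules: list[Molecule] = []
    for (contig, barcode) in sorted(by_key):
        group = sorted(by_key[(contig, barcode)], key=lambda a: (a.start, a.end))
        cluster: list[BarcodedAlignment] = []
        cur_end = None
        for a in group:
            if cur_end is not None and max(0, a.start - cur_end) > max_gap:
                if len(cluster) >= min_reads:
                    molecules.append(Molecule(
                        contig, barcode, cluster[0].start,
                        max(x.end for x in cluster), len(cluster)))
                cluster = []
                cur_end = None
            cluster.append(a)
            cur_end = a.end if cur_end is None else max(cur_end, a.end)
        if len(cluster) >= min_reads:
            molecules.append(Molecule(contig, barcode, cluster[0].start,
                                      max(x.end for x in cluster), len(cluster)))
    molecules.sort(key=lambda m: (m.contig_id, m.start, m.end, m.barcode))
    return molecules


def partition_segments(molecules: list[Molecule], contig_id: str) -> SegmentPartition:
    """Partition molecule-covered territory into maximal intervals whose every
    base is overlapped by exactly the same molecule set.

    Breakpoints are placed at every molecule start and end; intervals covered
    by no molecule are omitted.
    """
    mols = [(i, m) for i, m in enumerate(molecules) if m.contig_id == contig_id]
    if not mols:
        return SegmentPartition(contig_id, ())
    points = sorted({m.start for _, m in mols} | {m.end for _, m in mols})
    segments: list[Segment] = []
    for s, e in zip(points, points[1:]):
        cover = frozenset(i for i, m in mols if m.start <= s and m.end >= e)
        if cover:
            segments.append(Segment(contig_id, s, e, cover))
    return SegmentPartition(contig_id, tuple(segments))


def _region_barcodes(
    molecules: list[Molecule], contig_id: str, start: int, end: int
) -> set[str]:
    return {m.barcode for m in molecules
            if m.contig_id == contig_id and m.start < end and m.end > start}


def barcode_similarity(
    region_a: tuple[str, int, int],
    region_b: tuple[str, int, int],
    molecules: list[Molecule],
) -> tuple[float, int, bool]:
    """Jaccard similarity of the molecule-backed barcode sets of two regions.

    Returns ``(jaccard, shared, empty_union)``; an empty union yields 0.0 with
    the flag set.
    """
    set_a = _region_barcodes(molecules, *region_a)
    set_b = _region_barcodes(molecules, *region_b)
    union = set_a | set_b
    shared = len(set_a & set_b)
    if not union:
        return 0.0, 0, True
    return shared / len(union), shared, False


def infer_adjacencies(
    contigs: dict[str, int],
    molecules: list[Molecule],
    window: int = 25_000,
    top_n: int | None = None,
) -> list[AdjacencyCandidate]:
    """Rank candidate adjacencies between contig ends by barcode similarity.

    ``contigs`` maps contig id -> length.  Each contig contributes a 5' end
    window [0, window) and a 3' end window [length - window, length); all
    cross-contig end pairs are scored by the Jaccard similarity of their
    barcode sets and ranked descending (ties broken by shared count, then
    lexicographically).  Self-pairs are excluded.  ``top_n`` truncates the
    returned list.
    """
    if len(contigs) < 2:
        raise ValidationError("infer_adjacencies requires >= 2 contigs")
    ends: dict[tuple[str, str], set[str]] = {}
    for cid, length in contigs.items():
        ends[(cid, "5p")] = _region_barcodes(molecules, cid, 0, min(window, length))
        ends[(cid, "3p")] = _region_barcodes(molecules, cid,
                                             max(0, length - window), length)
    scored: list[tuple[float, int, str, str, str, str]] = []
    for (a, ea), (b, eb) in combinations(sorted(ends), 2):
        if a == b:
            continue
        sa, sb = ends[(a, ea)], ends[(b, eb)]
        union = sa | sb
        shared = len(sa & sb)
        jac = shared / len(union) if union else 0.0
        scored.append((jac, shared, a, ea, b, eb))
    scored.sort(key=lambda t: (-t[0], -t[1], t[2], t[3], t[4], t[5]))
    out = [AdjacencyCandidate(a, ea, b, eb, jac, shared, rank)
           for rank, (jac, shared, a, ea, b, eb) in enumerate(scored, start=1)]
    return out[:top_n] if top_n else out
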