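"""Intron extraction, homology grouping, periodicity classification and
repeat-homogenization statistics.

Repetitive silk genes often carry nearly identical small introns interspersed
between similarly sized exons.  Within a gene those introns fall into one or
more homology groups; the ordinal pattern of group labels distinguishes
single-type intron arrays (AAAA...), alternating arrays (ABAB...), and mixed
architectures where the regime switches partway through the gene.

Identity convention: global end-gap-penalized alignment, match 1 / mismatch 0,
affine gap open 4 extend 1; identity = identical aligned columns divided by
full alignment length (gap columns included).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from itertools import combinations

from Bio import Align

from .core_io import Alphabet, GeneModel, Sequence, ValidationError, spliced_cds

__all__ = [
    "IntronSet",
    "HomologyGrouping",
    "PatternClass",
    "IntronPatternReport",
    "HomogenizationStats",
    "extract_introns",
    "pairwise_identity",
    "group_introns",
    "classify_pattern",
    "intron_homogenization",
]


@dataclass(frozen=True)
class IntronSet:
    """Ordered introns of one gene, oriented in the sense of transcription."""

    gene_id: str
    introns: tuple[Sequence, ...]

    def __len__(self) -> int:
        return len(self.introns)


@dataclass(frozen=True)
class HomologyGrouping:
    """One label per intron; labels A, B, C, ... by first appearance."""

    labels: tuple[str, ...]
    threshold: float

    def __post_init__(self) -> None:
        seen: list[str] = []
        for lab in self.labels:
            if lab not in seen:
                seen.append(lab)
        expected = [chr(ord("A") + i) for i in range(len(seen))]
        if seen != expected:
            raise ValidationError(f"labels not in first-appearance order: {self.labels}")

    @property
    def label_string(self) -> str:
        return "".join(self.labels)


class PatternClass(str, Enum):
    NONE = "NONE"
    NON_REPETITIVE = "NON_REPETITIVE"
    SINGLE_TYPE = "SINGLE_TYPE"
    ALTERNATING = "ALTERNATING"
    MIXED = "MIXED"


@dataclass(frozen=True)
class IntronPatternReport:
    gene_id: str
    pattern_class: PatternClass
    label_string: str
    change_points: tuple[int, ...]


@dataclass(frozen=True)
class HomogenizationStats:
    n_pairs: int
    mean_identity: float | None
    min_identity: float | None
    max_identity: float | None


def extract_introns(gene: GeneModel, genome: Sequence) -> IntronSet:
    """Extract the implied introns of a gene, strand-oriented.

    Count equals exons - 1; on the minus strand introns are
    reverse-complemented and their order reversed (transcription order).
    """
    if gene.contig_id != genome.id:
        raise ValidationError(
            f"gene {gene.gene_id!r} is on contig {gene.contig_id!r}, not {genome.id!r}")
    spans = gene.introns_genomic()
    seqs: list[Sequence] = []
    if gene.strand == "+":
        ordered = spans
        for i, (s, e) in enumerate(ordered):
            seqs.append(genome.subseq(s, e, f"{gene.gene_id}_intron{i + 1}"))
    else:
        ordered = tuple(reversed(spans))
        for i, (s, e) in enumerate(ordered):
            seqs.append(genome.subseq(s, e).reverse_complement(
                f"{gene.gene_id}_intron{i + 1}"))
    return IntronSet(gene.gene_id, tuple(seqs))


def _make_aligner(alphabet: Alphabet) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -4.0
    aligner.extend_gap_score = -1.0
    return aligner


def pairwise_identity(a: Sequence, b: Sequence) -> float:
    """Percent identity of a global alignment of two sequences.

    identity = 100 * identical aligned columns / alignment length (gap columns
    count in the denominator).  Symmetric; 100.0 for identical inputs.
    """
    if a.alphabet is not b.alphabet:
        raise ValidationError("pairwise_identity requires matching alphabets")
    if not a.residues or not b.residues:
        raise ValidationError("pairwise_identity requires non-empty sequences")
    if a.residues == b.residues:
        return 100.0
    aligner = _make_aligner(a.alphabet)
    aln = aligner.align(a.residues, b.residues)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    matches = sum(1 for x, y in zip(row_a, row_b) if x == y and x != "-")
    return 100.0 * matches / len(row_a)


def _identity_matrix(seqs: tuple[Sequence, ...]) -> list[list[float]]:
    n = len(seqs)
    mat = [[100.0] * n for _ in range(n)]
    for i, j in combinations(range(n), 2):
        ident = pairwise_identity(seqs[i], seqs[j])
        mat[i][j] = mat[j][i] = ident
    return mat


def group_introns(introns: IntronSet, threshold: float = 80.0) -> HomologyGrouping:
    """Single-linkage clustering of introns at a percent-identity threshold.

    At a fixed threshold, single linkage is exactly the connected components of
    the graph joining pairs at >= threshold identity.  Labels are assigned by
    first appearance, so they are stable under relabeling.
    """
    if len(introns) == 0:
        raise ValidationError("group_introns requires at least one intron")
    n = len(introns)
    mat = _identity_matrix(introns.introns)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in combinations(range(n), 2):
        if mat[i][j] >= threshold:
            parent[find(i)] = find(j)

    labels: list[str] = []
    root_to_label: dict[int, str] = {}
    for i in range(n):
        r = find(i)
        if r not in root_to_label:
            root_to_label[r] = chr(ord("A") + len(root_to_label))
        labels.append(root_to_label[r])
    return HomologyGrouping(tuple(labels), threshold)


def _segment_violations(labels: tuple[str, ...]) -> int:
    """Edits needed to make a label run a valid SINGLE or ALTERNATING regime."""
    n = len(labels)
    if n == 0:
        return 0
    from collections import Counter

    v_single = n - max(Counter(labels).values())
    even = Counter(labels[0::2])
    odd = Counter(labels[1::2])
    best_even = max(even.values()) if even else 0
    best_odd = max(odd.values()) if odd else 0
    v_alt = n - best_even - best_odd
    return min(v_single, v_alt)


def _segment_regimes(labels: tuple[str, ...]) -> tuple[int, ...]:
    """Optimal regime segmentation: minimize (total violations, n_regimes).

    Dynamic programming over split positions; returns the ordinal positions at
    which a new regime starts (excluding position 0).
    """
    n = len(labels)
    if n == 0:
        return ()
    cost: dict[tuple[int, int], int] = {}
    for i in range(n):
        for j in range(i + 1, n + 1):
            cost[(i, j)] = _segment_violations(labels[i:j])
    INF = (10 ** 9, 10 ** 9)
    best: list[tuple[int, int]] = [INF] * (n + 1)
    back: list[int] = [-1] * (n + 1)
    best[0] = (0, 0)
    for j in range(1, n + 1):
        for i in range(j):
            if best[i] == INF:
                continue
            cand = (best[i][0] + cost[(i, j)], best[i][1] + 1)
            if cand < best[j]:
                best[j] = cand
                back[j] = i
    cuts: list[int] = []
    j = n
    while j > 0:
        i = back[j]
        if i > 0:
            cuts.append(i)
        j = i
    return tuple(sorted(cuts))


def classify_pattern(
    grouping: HomologyGrouping, gene_id: str = ""
) -> IntronPatternReport:
    """Classify the within-gene intron periodicity pattern.

    Interior labels (first and last intron dropped when there are >= 4
    introns, since terminal introns often diverge) decide the class:
    SINGLE_TYPE when all identical, ALTERNATING when they strictly alternate
    between exactly two groups, MIXED otherwise when >= 2 groups are present.
    Genes with <= 3 introns and no repeated label are NON_REPETITIVE.
    Change points mark regime switches (e.g. a 5' single-intron region
    followed by a 3' alternating region).
    """
    labels = grouping.labels
    n = len(labels)
    if n == 0:
        return IntronPatternReport(gene_id, PatternClass.NONE, "", ())
    label_string = grouping.label_string
    change_points = _segment_regimes(labels)

    has_repeat = len(set(labels)) < n
    if not has_repeat:
        cls = PatternClass.NON_REPETITIVE if n <= 3 else PatternClass.MIXED
        if n == 1:
            cls = PatternClass.NON_REPETITIVE
        return IntronPatternReport(gene_id, cls, label_string,
                                   change_points if cls is PatternClass.MIXED else ())

    interior = labels[1:-1] if n >= 4 else labels
    if len(set(interior)) == 1:
        return IntronPatternReport(gene_id, PatternClass.SINGLE_TYPE, label_string, ())
    distinct = set(interior)
    alternating = (
        len(distinct) == 2
        and all(x != y for x, y in zip(interior, interior[1:]))
    )
    if alternating:
        return IntronPatternReport(gene_id, PatternClass.ALTERNATING, label_string, ())
    return IntronPatternReport(gene_id, PatternClass.MIXED, label_string, change_points)


def intron_homogenization(
    introns: IntronSet,
    grouping: HomologyGrouping,
    exclude_terminal: bool = True,
    within_group_only: bool = True,
) -> dict[str, HomogenizationStats]:
    """Pairwise-identity statistics per homology group.

    The first and last intron of the gene are excluded before group membership
    is counted (terminal introns are typically less homogenized).  Groups left
    with fewer than two members yield ``n_pairs=0`` and absent means.  When
    ``within_group_only`` is false a single pooled entry keyed ``"*"`` is
    returned instead, covering all retained introns.
    """
    n = len(introns)
    if len(grouping.labels) != n:
        raise ValidationError("grouping does not match intron count")
    keep = list(range(n))
    if exclude_terminal:
        if n < 3:
            return {}
        keep = keep[1:-1]

    def stats(indices: list[int]) -> HomogenizationStats:
        pairs = list(combinations(indices, 2))
        if not pairs:
            return HomogenizationStats(0, None, None, None)
        idents = [pairwise_identity(introns.introns[i], introns.introns[j])
                  for i, j in pairs]
        return HomogenizationStats(
            len(pairs), sum(idents) / len(idents), min(idents), max(idents))

    if not within_group_only:
        return {"*": stats(keep)}
    out: dict[str, HomogenizationStats] = {}
    for lab in sorted(set(grouping.labels[i] for i in keep)):
        out[lab] = stats([i for i in keep if grouping.labels[i] == lab])
    return out
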