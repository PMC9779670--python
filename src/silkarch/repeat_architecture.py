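"""Decomposition of repetitive silk proteins into poly-A units and ensemble
repeats, plus profile statistics, consensus units, linker detection and
alignment-column classification.

The core repeat (a "poly-A unit") is one glycine-rich region followed by one
uninterrupted poly-alanine run; several poly-A units iterate as a larger
ensemble repeat.  A unit ENDS at the end of its poly-alanine run (the
glycine-rich region comes first), so units tile the repetitive region with an
optional glycine-rich remainder after the final run.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass
from enum import Enum
from itertools import combinations

from .core_io import AlignmentMatrix, Alphabet, GeneModel, Sequence, ValidationError
from .gene_structure import PatternClass, pairwise_identity

__all__ = [
    "PolyARun",
    "PolyAUnit",
    "BoundarySource",
    "EnsembleRepeat",
    "EnsembleProfile",
    "LinkerHit",
    "ColumnClassification",
    "find_polyA_runs",
    "segment_polyA_units",
    "detect_ensembles",
    "ensemble_profile",
    "consensus_sequence",
    "find_linker",
    "classify_columns",
    "mask_intervals",
]


@dataclass(frozen=True)
class PolyARun:
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class PolyAUnit:
    """One glycine-rich region + one poly-alanine run, in protein coordinates."""

    start: int
    end: int
    glycine_region: tuple[int, int]
    polyA_run: tuple[int, int]
    type_label: int | None = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def with_type(self, label: int) -> "PolyAUnit":
        return PolyAUnit(self.start, self.end, self.glycine_region,
                         self.polyA_run, label)


class BoundarySource(str, Enum):
    EXON = "EXON"
    PERIODICITY = "PERIODICITY"


@dataclass(frozen=True)
class EnsembleRepeat:
    units: tuple[PolyAUnit, ...]
    boundary_source: BoundarySource
    non_periodic: bool = False

    @property
    def size(self) -> int:
        return len(self.units)

    @property
    def start(self) -> int:
        return self.units[0].start

    @property
    def end(self) -> int:
        return self.units[-1].end


@dataclass(frozen=True)
class EnsembleProfile:
    gene_id: str
    ensembles: tuple[EnsembleRepeat, ...]
    modal_size: int
    regularity: float
    mean_identity: float | None
    consensus_units: tuple[Sequence, ...]


@dataclass(frozen=True)
class LinkerHit:
    start: int
    end: int
    mismatches: int


@dataclass(frozen=True)
class ColumnClassification:
    n_columns: int
    n_variable: int
    substitution: int
    small_indel: int
    unit_gain_loss: int


# ---------------------------------------------------------------------------
# Poly-A unit segmentation
# ---------------------------------------------------------------------------

def find_polyA_runs(protein: Sequence, min_run: int = 4) -> list[PolyARun]:
    """Maximal uninterrupted runs of 'A' of length >= min_run, left to right."""
    if protein.alphabet is not Alphabet.PROTEIN:
        raise ValidationError("find_polyA_runs requires a protein sequence")
    return [PolyARun(m.start(), m.end())
            for m in re.finditer(r"A{%d,}" % min_run, protein.residues)]


def segment_polyA_units(
    protein: Sequence,
    repetitive_region: tuple[int, int] | None = None,
    min_run: int = 4,
) -> tuple[list[PolyAUnit], tuple[int, int] | None]:
    """Tile a repetitive region into poly-A units.

    Unit i spans from the end of run i-1 (or the region start) to the end of
    run i.  Trailing glycine-rich sequence after the last run is returned as a
    remainder interval, not a unit.  With zero runs the whole region is the
    remainder.  Coordinates are absolute protein coordinates.
    """
    region = repetitive_region or (0, len(protein))
    rs, re_ = region
    sub = protein.subseq(rs, re_)
    runs = [PolyARun(r.start + rs, r.end + rs) for r in find_polyA_runs(sub, min_run)]
    if not runs:
        return [], region
    units: list[PolyAUnit] = []
    prev_end = rs
    for run in runs:
        units.append(PolyAUnit(
            start=prev_end, end=run.end,
            glycine_region=(prev_end, run.start),
            polyA_run=(run.start, run.end)))
        prev_end = run.end
    remainder = (prev_end, re_) if prev_end < re_ else None
    return units, remainder


# ---------------------------------------------------------------------------
# Ensemble detection
# ---------------------------------------------------------------------------

def _unit_seq(protein: Sequence, unit: PolyAUnit) -> Sequence:
    return protein.subseq(unit.start, unit.end, f"unit_{unit.start}_{unit.end}")


def assign_unit_types(
    units: list[PolyAUnit], protein: Sequence, threshold: float = 75.0
) -> list[PolyAUnit]:
    """Cluster units into types by single-linkage identity; small-int labels
    numbered by first appearance (1, 2, ...)."""
    n = len(units)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    seqs = [_unit_seq(protein, u) for u in units]
    for i, j in combinations(range(n), 2):
        if pairwise_identity(seqs[i], seqs[j]) >= threshold:
            parent[find(i)] = find(j)
    root_to_label: dict[int, int] = {}
    out: list[PolyAUnit] = []
    for i, u in enumerate(units):
        r = find(i)
        if r not in root_to_label:
            root_to_label[r] = len(root_to_label) + 1
        out.append(u.with_type(root_to_label[r]))
    return out


def _best_period(labels: list[int], min_agreement: float = 0.8) -> int | None:
    """Shortest period p whose positional modal labels explain >= min_agreement
    of all positions."""
    n = len(labels)
    for p in range(1, n // 2 + 1):
        agree = 0
        for r in range(p):
            cls = labels[r::p]
            agree += max(Counter(cls).values())
        if agree / n >= min_agreement:
            return p
    return None


def _exon_index_of_codon(aa_pos: int, exon_lengths: list[int]) -> int:
    """Exon (transcription order) containing the first base of codon aa_pos."""
    nt = 3 * aa_pos
    acc = 0
    for idx, ln in enumerate(exon_lengths):
        acc += ln
        if nt < acc:
            return idx
    return len(exon_lengths) - 1


def detect_ensembles(
    units: list[PolyAUnit],
    protein: Sequence,
    gene: GeneModel | None = None,
    intron_pattern: PatternClass | None = None,
    type_threshold: float = 75.0,
    min_agreement: float = 0.8,
) -> list[EnsembleRepeat]:
    """Group tiled poly-A units into ensemble repeats.

    EXON mode (gene given): the ensemble repeat is demarcated by the exon
    encoding it, or by a pair of exons when the gene's introns alternate
    between two homology groups.  PERIODICITY mode (no gene): units are
    clustered into types by identity and the shortest type-label period with
    >= ``min_agreement`` positional agreement defines ensembles of that many
    units; with no adequate period a single ensemble covering all units is
    returned, flagged non-periodic.
    """
    if not units:
        return []
    if gene is not None:
        exon_lengths = [e - s for s, e in gene.exons_transcription_order()]
        pair = intron_pattern is PatternClass.ALTERNATING
        groups: list[list[PolyAUnit]] = []
        last_key: int | None = None
        for u in units:
            idx = _exon_index_of_codon(u.start, exon_lengths)
            key = idx // 2 if pair else idx
            if key != last_key:
                groups.append([])
                last_key = key
            groups[-1].append(u)
        return [EnsembleRepeat(tuple(g), BoundarySource.EXON) for g in groups]

    typed = assign_unit_types(units, protein, type_threshold)
    labels = [u.type_label for u in typed]
    p = _best_period(labels, min_agreement)
    if p is None:
        return [EnsembleRepeat(tuple(typed), BoundarySource.PERIODICITY,
                               non_periodic=True)]
    return [EnsembleRepeat(tuple(typed[i:i + p]), BoundarySource.PERIODICITY)
            for i in range(0, len(typed), p)]


# ---------------------------------------------------------------------------
# Profile, consensus
# ---------------------------------------------------------------------------

def _ensemble_seq(protein: Sequence, ens: EnsembleRepeat) -> Sequence:
    return protein.subseq(ens.start, ens.end, f"ens_{ens.start}_{ens.end}")


def consensus_sequence(aligned_units: AlignmentMatrix) -> Sequence:
    """Per-column majority consensus of an alignment.

    Columns whose majority character is a gap are dropped.  Ties are broken by
    overall residue frequency across the matrix, then lexicographically, so
    the result is deterministic.
    """
    if len(aligned_units.rows) < 2:
        raise ValidationError("consensus requires >= 2 rows")
    global_freq = Counter("".join(aligned_units.rows).replace("-", ""))
    out: list[str] = []
    for j in range(aligned_units.n_columns):
        col = aligned_units.column(j)
        counts = Counter(col)
        top = max(counts.values())
        winners = sorted(c for c, k in counts.items() if k == top)
        if len(winners) > 1:
            winners.sort(key=lambda c: (-global_freq.get(c, 0), c))
        choice = winners[0]
        if choice == "-":
            continue
        out.append(choice)
    return Sequence("consensus", "".join(out), Alphabet.PROTEIN)


def _stack_same_length(seqs: list[str]) -> AlignmentMatrix | None:
    lengths = Counter(len(s) for s in seqs)
    modal_len, count = lengths.most_common(1)[0]
    rows = [s for s in seqs if len(s) == modal_len]
    if len(rows) < 2:
        return None
    return AlignmentMatrix(tuple(rows), tuple(f"r{i}" for i in range(len(rows))))


def ensemble_profile(
    ensembles: list[EnsembleRepeat], protein: Sequence, gene_id: str = ""
) -> EnsembleProfile:
    """Modal size, regularity, mean pairwise identity and consensus units.

    regularity = fraction of ensembles having the modal size (ties on modal
    size break toward the smaller size).  mean_identity averages
    pairwise_identity over all pairs of modal-size ensembles, compared on
    their concatenated protein sequence.  Consensus units are per-position
    majorities over homologous units (slot k of every modal-size ensemble).
    """
    if not ensembles:
        raise ValidationError("ensemble_profile requires >= 1 ensemble")
    sizes = [e.size for e in ensembles]
    counts = Counter(sizes)
    top = max(counts.values())
    modal_size = min(s for s, k in counts.items() if k == top)
    regularity = counts[modal_size] / len(ensembles)
    modal = [e for e in ensembles if e.size == modal_size]

    mean_identity: float | None = None
    pairs = list(combinations(modal, 2))
    if pairs:
        idents = [pairwise_identity(_ensemble_seq(protein, a), _ensemble_seq(protein, b))
                  for a, b in pairs]
        mean_identity = sum(idents) / len(idents)

    consensus_units: list[Sequence] = []
    for k in range(modal_size):
        slot = [protein.residues[e.units[k].start:e.units[k].end] for e in modal]
        if len(slot) == 1:
            consensus_units.append(Sequence(f"consensus_unit{k + 1}", slot[0],
                                            Alphabet.PROTEIN))
            continue
        stacked = _stack_same_length(slot)
        if stacked is None:
            # fall back to the most common sequence among the slot copies
            best = Counter(slot).most_common(1)[0][0]
            consensus_units.append(Sequence(f"consensus_unit{k + 1}", best,
                                            Alphabet.PROTEIN))
        else:
            cons = consensus_sequence(stacked)
            consensus_units.append(Sequence(f"consensus_unit{k + 1}", cons.residues,
                                            Alphabet.PROTEIN))
    return EnsembleProfile(gene_id, tuple(ensembles), modal_size, regularity,
                           mean_identity, tuple(consensus_units))


# ---------------------------------------------------------------------------
# Linker detection
# ---------------------------------------------------------------------------

def find_linker(
    protein: Sequence,
    motif: str = "KEIIKKIIVHRR",
    max_mismatch: int = 3,
) -> list[LinkerHit]:
    """Non-overlapping windows within Hamming distance max_mismatch of the
    linker motif, chosen best-first (fewest mismatches, then leftmost)."""
    m = len(motif)
    if m > len(protein):
        return []
    hits: list[LinkerHit] = []
    res = protein.residues
    for i in range(len(res) - m + 1):
        d = sum(1 for a, b in zip(res[i:i + m], motif) if a != b)
        if d <= max_mismatch:
            hits.append(LinkerHit(i, i + m, d))
    hits.sort(key=lambda h: (h.mismatches, h.start))
    chosen: list[LinkerHit] = []
    for h in hits:
        if all(h.end <= c.start or h.start >= c.end for c in chosen):
            chosen.append(h)
    chosen.sort(key=lambda h: h.start)
    return chosen


def mask_intervals(protein: Sequence, intervals: list[tuple[int, int]],
                   fill: str = "G") -> Sequence:
    """Replace the given intervals (e.g. linker hits) with a neutral filler so
    they do not interrupt unit segmentation."""
    res = list(protein.residues)
    for s, e in intervals:
        for i in range(s, e):
            res[i] = fill
    return Sequence(protein.id, "".join(res), protein.alphabet)


# ---------------------------------------------------------------------------
# Alignment column classification
# ---------------------------------------------------------------------------

def _row_column_maps(row: str) -> list[int]:
    """For each ungapped residue index, the alignment column holding it."""
    cols = []
    for j, c in enumerate(row):
        if c != "-":
            cols.append(j)
    return cols


def classify_columns(
    aln: AlignmentMatrix,
    units: dict[str, list[tuple[int, int]]],
    unit_cover_threshold: float = 0.9,
) -> ColumnClassification:
    """Classify variable alignment columns as substitution, small indel or
    whole-unit gain/loss.

    ``units`` maps row id -> poly-A unit intervals in ungapped row coordinates.
    A column with >= 2 distinct residues and no gap is a substitution.  Gap
    columns are merged into maximal per-row gap blocks; a block covering
    >= ``unit_cover_threshold`` of the alignment span of an annotated unit (in
    any other row) classifies all its columns as unit gain/loss, otherwise as
    small indel.
    """
    for rid in aln.row_ids:
        if rid not in units:
            raise ValidationError(f"unit annotation missing for row {rid!r}")
    n_cols = aln.n_columns
    n_rows = len(aln.rows)

    # alignment-column spans of every annotated unit
    unit_spans: list[tuple[int, int]] = []
    for rid, row in zip(aln.row_ids, aln.rows):
        colmap = _row_column_maps(row)
        for s, e in units[rid]:
            if e > len(colmap):
                raise ValidationError(
                    f"unit ({s},{e}) outside row {rid!r} of length {len(colmap)}")
            unit_spans.append((colmap[s], colmap[e - 1] + 1))

    col_class = [None] * n_cols  # None | 'sub' | 'small' | 'unit'
    for j in range(n_cols):
        col = aln.column(j)
        if "-" not in col and len(set(col)) >= 2:
            col_class[j] = "sub"

    for row in aln.rows:
        j = 0
        while j < n_cols:
            if row[j] != "-":
                j += 1
                continue
            k = j
            while k < n_cols and row[k] == "-":
                k += 1
            block = (j, k)
            is_unit = False
            for us, ue in unit_spans:
                span = ue - us
                overlap = max(0, min(k, ue) - max(j, us))
                if span > 0 and overlap / span >= unit_cover_threshold:
                    is_unit = True
                    break
            kind = "unit" if is_unit else "small"
            for c in range(j, k):
                # unit gain/loss takes precedence over small indel
                if col_class[c] != "unit":
                    col_class[c] = kind
            j = k

    subs = sum(1 for c in col_class if c == "sub")
    small = sum(1 for c in col_class if c == "small")
    unit = sum(1 for c in col_class if c == "unit")
    n_variable = subs + small + unit
    return ColumnClassification(n_cols, n_variable, subs, small, unit)
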