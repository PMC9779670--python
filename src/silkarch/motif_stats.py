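"""Amino-acid composition, stereotypical-motif statistics and iterative
k-mer overrepresentation motif discovery.

The discovery algorithm scores every k-mer of size kmin..kmax across a set of
sequences by its *additional occurrences* (occurrences beyond the first in
each sequence, summed over sequences), normalized by the total additional
occurrences of all k-mers of that size.  The top-scoring k-mer across all
sizes is masked from every sequence and scoring repeats until no k-mer occurs
more than ``stop_count`` times in total.
"""

from __future__ import annotations

import re
from collections import Counter, defaultdict
from dataclasses import dataclass

from .core_io import MASK_CHAR, Sequence, ValidationError

__all__ = [
    "CompositionTable",
    "KmerRecord",
    "MotifDiscoveryResult",
    "composition",
    "motif_coverage",
    "count_motif",
    "adjacency_fraction",
    "kmer_table",
    "discover_motifs",
    "compile_pattern",
]


@dataclass(frozen=True)
class CompositionTable:
    proportions: dict[str, float]
    length: int

    def fraction(self, residues: str) -> float:
        """Summed proportion of a set of residues (e.g. 'AQGP')."""
        return sum(self.proportions.get(r, 0.0) for r in residues)


@dataclass(frozen=True)
class KmerRecord:
    kmer: str
    k: int
    total_occ: int
    add_occ: int
    rel_score: float


@dataclass(frozen=True)
class MotifDiscoveryResult:
    selections: tuple[tuple[int, str, float], ...]  # (iteration, kmer, rel_score)
    masked: tuple[str, ...]

    @property
    def motifs(self) -> tuple[str, ...]:
        return tuple(kmer for _, kmer, _ in self.selections)


def composition(region: Sequence) -> CompositionTable:
    """Exact per-residue proportions of a region."""
    n = len(region)
    counts = Counter(region.residues)
    return CompositionTable({r: c / n for r, c in sorted(counts.items())}, n)


def compile_pattern(pattern: str) -> re.Pattern:
    """Compile a motif pattern to a regex.

    ``X`` is a single-residue wildcard; bracket classes like ``GP[GS]`` pass
    through.  Everything else is literal.
    """
    if len(pattern.replace("[", "").replace("]", "")) < 2:
        raise ValidationError(f"pattern {pattern!r} too short")
    out: list[str] = []
    i = 0
    while i < len(pattern):
        c = pattern[i]
        if c == "[":
            j = pattern.index("]", i)
            out.append(pattern[i:j + 1])
            i = j + 1
        elif c == "X":
            out.append("[ACDEFGHIKLMNPQRSTVWYX]")
            i += 1
        else:
            out.append(re.escape(c))
            i += 1
    return re.compile("".join(out))


def motif_coverage(region: Sequence, pattern: str) -> float:
    """Fraction of residues covered by greedy left-to-right non-overlapping
    matches of a wildcard pattern."""
    rx = compile_pattern(pattern)
    covered = 0
    pos = 0
    res = region.residues
    while True:
        m = rx.search(res, pos)
        if m is None:
            break
        covered += m.end() - m.start()
        pos = m.end()
    return covered / len(res)


def count_motif(regions: list[Sequence], motif: str) -> int:
    """Count all (possibly overlapping) occurrences of an exact motif."""
    if any(ch in "X[]" for ch in motif):
        raise ValidationError("count_motif takes an exact motif without wildcards")
    total = 0
    for region in regions:
        res = region.residues
        start = 0
        while True:
            i = res.find(motif, start)
            if i < 0:
                break
            total += 1
            start = i + 1
    return total


def adjacency_fraction(
    region: Sequence,
    residue: str = "Y",
    context: str = "GP[GS]",
    side: str = "precedes",
) -> tuple[float | None, int]:
    """Fraction of ``residue`` occurrences adjacent to a context motif.

    ``precedes``: the residue is immediately followed by a context match;
    ``flanks``: immediately followed OR immediately preceded.  Returns
    ``(fraction, n_occurrences)``; fraction is None when the residue is
    absent.
    """
    rx = compile_pattern(context)
    res = region.residues
    positions = [i for i, c in enumerate(res) if c == residue]
    if not positions:
        return None, 0
    ctx_len = len(re.sub(r"\[[^\]]*\]", ".", context))
    starts = {m.start() for m in _iter_all(rx, res)}
    hits = 0
    for i in positions:
        after = (i + 1) in starts
        before = (i - ctx_len) in starts
        if side == "precedes":
            ok = after
        elif side == "flanks":
            ok = after or before
        else:
            raise ValidationError(f"unknown side {side!r}")
        hits += ok
    return hits / len(positions), len(positions)


def _iter_all(rx: re.Pattern, s: str):
    """All (overlapping) matches of a compiled pattern."""
    pos = 0
    while True:
        m = rx.search(s, pos)
        if m is None:
            return
        yield m
        pos = m.start() + 1


# ---------------------------------------------------------------------------
# k-mer overrepresentation
# ---------------------------------------------------------------------------

def kmer_table(
    seqs: list[Sequence],
    kmin: int = 3,
    kmax: int = 10,
    pooled_counting: bool = False,
) -> list[KmerRecord]:
    """Score every k-mer of sizes kmin..kmax across a set of sequences.

    Overlapping occurrences count; windows containing the mask sentinel never
    count.  K-mers occurring no more than once across all sequences are
    excluded.  ``add_occ`` sums, per sequence, the occurrences beyond the
    first (or beyond the first across the pool when ``pooled_counting``);
    ``rel_score`` divides by the total additional occurrences of all k-mers of
    that size.
    """
    if kmin > kmax:
        raise ValidationError("kmin > kmax")
    total: dict[str, int] = defaultdict(int)
    per_seq_extra: dict[str, int] = defaultdict(int)
    for seq in seqs:
        res = seq.residues
        for k in range(kmin, kmax + 1):
            counts: Counter[str] = Counter()
            for i in range(len(res) - k + 1):
                w = res[i:i + k]
                if MASK_CHAR in w:
                    continue
                counts[w] += 1
            for w, c in counts.items():
                total[w] += c
                per_seq_extra[w] += c - 1

    records: list[KmerRecord] = []
    denom_by_k: dict[int, int] = defaultdict(int)
    kept: list[tuple[str, int, int]] = []
    for w, t in total.items():
        if t <= 1:
            continue
        add = (t - 1) if pooled_counting else per_seq_extra[w]
        kept.append((w, t, add))
        denom_by_k[len(w)] += add
    for w, t, add in kept:
        denom = denom_by_k[len(w)]
        rel = add / denom if denom > 0 else 0.0
        records.append(KmerRecord(w, len(w), t, add, rel))
    records.sort(key=lambda r: (-r.rel_score, -r.k, r.kmer))
    return records


def _mask_kmer(res: str, kmer: str) -> str:
    """Replace every residue of every (overlapping) occurrence with the mask
    sentinel."""
    k = len(kmer)
    out = list(res)
    start = 0
    while True:
        i = res.find(kmer, start)
        if i < 0:
            break
        for j in range(i, i + k):
            out[j] = MASK_CHAR
        start = i + 1
    return "".join(out)


def discover_motifs(
    seqs: list[Sequence],
    kmin: int = 3,
    kmax: int = 10,
    stop_count: int = 5,
    pooled_counting: bool = False,
    stop_on_total: bool = True,
    max_iterations: int = 1000,
) -> MotifDiscoveryResult:
    """Iterative overrepresented-motif discovery with masking.

    Each iteration selects the k-mer with maximal ``rel_score`` across all
    sizes (ties prefer larger k, then lexicographic order), masks all of its
    occurrences in every sequence, and rescores.  Termination: no remaining
    k-mer appears more than ``stop_count`` times (total occurrences by
    default; additional occurrences when ``stop_on_total`` is false).
    """
    if not seqs:
        return MotifDiscoveryResult((), ())
    residues = [s.residues for s in seqs]
    selections: list[tuple[int, str, float]] = []
    for iteration in range(1, max_iterations + 1):
        working = [Sequence(f"s{i}", r, seqs[0].alphabet)
                   for i, r in enumerate(residues)]
        table = kmer_table(working, kmin, kmax, pooled_counting)
        if not table:
            break
        metric = (lambda r: r.total_occ) if stop_on_total else (lambda r: r.add_occ)
        eligible = [r for r in table if metric(r) > stop_count]
        if not eligible:
            break
        best = min(eligible, key=lambda r: (-r.rel_score, -r.k, r.kmer))
        selections.append((iteration, best.kmer, best.rel_score))
        residues = [_mask_kmer(r, best.kmer) for r in residues]
    return MotifDiscoveryResult(tuple(selections), tuple(residues))
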