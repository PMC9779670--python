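"""Seed-deterministic generators emulating the statistical structure of
clustered silk-gene data, with truth records for parameter recovery.

Three generators cover the pipeline's inputs:

* :func:`simulate_gene` — a repetitive spidroin-like gene: a master ensemble
  of several poly-A units (glycine-rich region + poly-alanine run) copied
  with per-residue substitutions and whole-unit duplications/deletions, and
  small homogenized introns inserted in SINGLE or ALTERNATING layouts.
* :func:`simulate_linked_reads` — barcoded molecules of tens of kb scattered
  on a genome that is then split into contigs at known junctions.
* :func:`simulate_tpm` — log-normal TPM replicates concentrated in one
  dominant tissue per gene.

All randomness flows through one :class:`numpy.random.Generator` (PCG64)
seeded from the spec; the same seed yields byte-identical outputs.

Default rates are chosen to reproduce the homogenization regime reported for
*Argiope* MaSp genes: within-group intron identity around 97.6%, ensemble
repeat identity around 93.5%, and ensemble-size regularity around 0.835.
Substitutions are confined to glycine-rich regions (poly-alanine runs are
treated as under strict purifying constraint), so the planted unit boundaries
stay exact and recovery can be scored against them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

from .core_io import Alphabet, GeneModel, Sequence

__all__ = [
    "GeneSimSpec",
    "GeneTruth",
    "ReadSimSpec",
    "ReadTruth",
    "ExprSimSpec",
    "simulate_gene",
    "simulate_linked_reads",
    "simulate_tpm",
    "DEFAULT_GLYCINE_WEIGHTS",
]

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: residue weights of glycine-rich regions; named residues follow the
#: composition of MaSp2 repetitive regions, the rest share the remainder.
DEFAULT_GLYCINE_WEIGHTS: dict[str, float] = {
    "G": 0.40, "P": 0.14, "Q": 0.13, "S": 0.07, "A": 0.06, "Y": 0.04,
}
_others = [a for a in AMINO_ACIDS if a not in DEFAULT_GLYCINE_WEIGHTS]
_rest = 1.0 - sum(DEFAULT_GLYCINE_WEIGHTS.values())
for _a in _others:
    DEFAULT_GLYCINE_WEIGHTS[_a] = _rest / len(_others)

_CODONS: dict[str, list[str]] = {}
for _codon, _aa in standard_dna_table.forward_table.items():
    _CODONS.setdefault(_aa, []).append(_codon)
for _aa in _CODONS:
    _CODONS[_aa].sort()


@dataclass(frozen=True)
class GeneSimSpec:
    n_ensembles: int = 16
    units_per_ensemble: int = 4
    unit_glycine_len: int = 35
    polyA_len: int = 7
    glycine_alphabet_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_GLYCINE_WEIGHTS))
    sub_rate: float = 0.04
    indel_rate: float = 0.15
    intron_mode: str = "SINGLE"  # NONE | SINGLE | ALTERNATING
    intron_len: int = 60
    intron_sub_rate: float = 0.012
    flank_len: int = 1200
    min_run: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.sub_rate, self.indel_rate, self.intron_sub_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError(f"rate {r} outside [0, 1]")
        for n in (self.n_ensembles, self.units_per_ensemble,
                  self.unit_glycine_len, self.polyA_len, self.intron_len):
            if n < 1:
                raise ValueError("lengths/counts must be >= 1")
        if self.intron_mode not in {"NONE", "SINGLE", "ALTERNATING"}:
            raise ValueError(f"unknown intron_mode {self.intron_mode!r}")


@dataclass(frozen=True)
class GeneTruth:
    master_units: tuple[str, ...]
    units_per_ensemble: int
    n_ensembles: int
    ensemble_sizes: tuple[int, ...]
    intron_mode: str
    intron_labels: str
    master_introns: tuple[str, ...]
    repetitive_region: tuple[int, int]


def _weighted_residues(rng: np.random.Generator, weights: dict[str, float],
                       n: int, forbid: str = "") -> str:
    letters = [a for a in sorted(weights) if a not in forbid]
    probs = np.array([weights[a] for a in letters], dtype=float)
    probs /= probs.sum()
    return "".join(rng.choice(letters, size=n, p=probs))


def _break_a_runs(s: str, min_run: int) -> str:
    """Cap internal alanine runs below min_run so they cannot merge with a
    planted poly-A run."""
    out = list(s)
    run = 0
    for i, c in enumerate(out):
        if c == "A":
            run += 1
            if run >= min_run - 1:
                out[i] = "G"
                run = 0
        else:
            run = 0
    return "".join(out)


def _mutate_glycine(rng: np.random.Generator, s: str, rate: float,
                    weights: dict[str, float]) -> str:
    if rate == 0.0:
        return s
    out = list(s)
    hits = np.nonzero(rng.random(len(s)) < rate)[0]
    for i in hits:
        out[i] = _weighted_residues(rng, weights, 1, forbid="A" + out[i])[0]
    return "".join(out)


def _random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def _mutate_dna(rng: np.random.Generator, s: str, rate: float) -> str:
    if rate == 0.0:
        return s
    out = list(s)
    hits = np.nonzero(rng.random(len(s)) < rate)[0]
    for i in hits:
        alts = [b for b in "ACGT" if b != out[i]]
        out[i] = alts[rng.integers(len(alts))]
    return "".join(out)


def _reverse_translate(rng: np.random.Generator, protein: str) -> str:
    return "".join(_CODONS[aa][rng.integers(len(_CODONS[aa]))] for aa in protein)


def simulate_gene(spec: GeneSimSpec) -> tuple[Sequence, GeneModel, Sequence, GeneTruth]:
    """Simulate one repetitive gene; returns (genome, model, protein, truth).

    The master ensemble (``units_per_ensemble`` distinct poly-A units) is
    copied ``n_ensembles`` times.  Each copy may duplicate or delete one whole
    unit (probability ``indel_rate``), then glycine-region residues substitute
    at ``sub_rate``.  Introns (mutated from one or two masters at
    ``intron_sub_rate``) are inserted at the homologous boundary of each
    ensemble-encoding exon: SINGLE puts one intron between consecutive
    ensembles; ALTERNATING additionally splits each ensemble into an exon
    pair, so intron types alternate A B A B ... along the gene.
    """
    rng = np.random.default_rng(spec.seed)
    master_units: list[str] = []
    for _ in range(spec.units_per_ensemble):
        gly = _weighted_residues(rng, spec.glycine_alphabet_weights,
                                 spec.unit_glycine_len)
        gly = _break_a_runs(gly, spec.min_run)
        # unit boundaries stay exact: the region may not start/end in alanine
        if gly[0] == "A":
            gly = "G" + gly[1:]
        if gly[-1] == "A":
            gly = gly[:-1] + "G"
        master_units.append(gly + "A" * spec.polyA_len)

    copies: list[list[str]] = []
    sizes: list[int] = []
    for _ in range(spec.n_ensembles):
        units = list(master_units)
        if rng.random() < spec.indel_rate:
            idx = int(rng.integers(len(units)))
            if rng.random() < 0.5 and len(units) > 1:
                del units[idx]
            else:
                units.insert(idx, units[idx])
        mutated = []
        for u in units:
            gly_len = len(u) - spec.polyA_len
            gly = _mutate_glycine(rng, u[:gly_len], spec.sub_rate,
                                  spec.glycine_alphabet_weights)
            mutated.append(gly + u[gly_len:])
        copies.append(mutated)
        sizes.append(len(mutated))

    protein_parts = ["".join(c) for c in copies]
    protein_str = "".join(protein_parts)
    protein = Sequence("simgene_protein", protein_str, Alphabet.PROTEIN)

    # exon layout in amino acids, per ensemble copy (NONE: one exon overall)
    exon_aa: list[list[int]] = []
    if spec.intron_mode == "NONE":
        exon_aa.append([len(protein_str)])
    else:
        for c in copies:
            total = sum(len(u) for u in c)
            if spec.intron_mode == "ALTERNATING":
                first = sum(len(u) for u in c[: (len(c) + 1) // 2])
                exon_aa.append([first, total - first])
            else:
                exon_aa.append([total])

    n_introns_within = 1 if spec.intron_mode == "ALTERNATING" else 0
    master_introns: tuple[str, ...]
    if spec.intron_mode == "NONE":
        master_introns = ()
    elif spec.intron_mode == "SINGLE":
        master_introns = (_random_dna(rng, spec.intron_len),)
    else:
        master_introns = (_random_dna(rng, spec.intron_len),
                          _random_dna(rng, spec.intron_len))

    pieces: list[str] = []
    exons: list[tuple[int, int]] = []
    intron_labels: list[str] = []
    pos = 0
    upstream = _random_dna(rng, spec.flank_len)
    pieces.append(upstream)
    pos += len(upstream)
    last_copy = len(copies) - 1
    for ci, aa_lens in enumerate(exon_aa):
        consumed = sum(sum(x) for x in exon_aa[:ci])
        offset = consumed
        for ei, aa_len in enumerate(aa_lens):
            aa_seq = protein_str[offset:offset + aa_len]
            offset += aa_len
            dna = _reverse_translate(rng, aa_seq)
            if ci == last_copy and ei == len(aa_lens) - 1:
                dna += "TAA"
            pieces.append(dna)
            exons.append((pos, pos + len(dna)))
            pos += len(dna)
            is_last_exon = ci == last_copy and ei == len(aa_lens) - 1
            if not is_last_exon:
                if spec.intron_mode == "SINGLE":
                    master, label = master_introns[0], "A"
                elif spec.intron_mode == "ALTERNATING":
                    within = ei < n_introns_within
                    master = master_introns[0] if within else master_introns[1]
                    label = "A" if within else "B"
                else:
                    continue
                intron = _mutate_dna(rng, master, spec.intron_sub_rate)
                pieces.append(intron)
                intron_labels.append(label)
                pos += len(intron)
    downstream = _random_dna(rng, spec.flank_len)
    pieces.append(downstream)
    genome = Sequence("simcontig", "".join(pieces), Alphabet.DNA)
    model = GeneModel("simgene", "simcontig", "+", tuple(exons))
    truth = GeneTruth(
        master_units=tuple(master_units),
        units_per_ensemble=spec.units_per_ensemble,
        n_ensembles=spec.n_ensembles,
        ensemble_sizes=tuple(sizes),
        intron_mode=spec.intron_mode,
        intron_labels="".join(intron_labels),
        master_introns=master_introns,
        repetitive_region=(0, len(protein_str)),
    )
    return genome, model, protein, truth


# ---------------------------------------------------------------------------
# Linked reads
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReadSimSpec:
    genome_length: int = 300_000
    n_cuts: int = 2
    molecule_len_mean: int = 40_000
    molecules_per_junction: int = 30
    reads_per_molecule: int = 8
    read_len: int = 150
    barcode_pool: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.n_cuts < self.genome_length:
            raise ValueError("n_cuts must be positive and fit in the genome")
        for n in (self.reads_per_molecule, self.barcode_pool, self.read_len,
                  self.molecule_len_mean):
            if n < 1:
                raise ValueError("counts must be >= 1")


@dataclass(frozen=True)
class ReadTruth:
    contig_lengths: dict[str, int]
    cut_points: tuple[int, ...]
    junctions: tuple[tuple[str, str, str, str], ...]
    n_spanning: tuple[int, ...]


def simulate_linked_reads(
    spec: ReadSimSpec,
) -> tuple[list[tuple[str, int, int, str]], ReadTruth]:
    """Simulate barcoded read alignments on a genome split into contigs.

    Molecules with exponential lengths (mean ``molecule_len_mean``) are placed
    uniformly on the *uncut* genome and their reads re-projected onto the
    contigs produced by ``n_cuts`` interior cuts; reads crossing a cut are
    dropped.  With ``molecules_per_junction`` = 0, molecules are rejected
    until none spans a cut.  Returns alignment rows
    (contig, start, end, barcode) and the ground truth.
    """
    rng = np.random.default_rng(spec.seed)
    G = spec.genome_length
    base = [G * (i + 1) // (spec.n_cuts + 1) for i in range(spec.n_cuts)]
    jitter = rng.integers(-G // 20, G // 20 + 1, size=spec.n_cuts)
    cuts = tuple(int(b + j) for b, j in zip(base, jitter))
    bounds = [0, *cuts, G]
    names = [f"contig{i + 1}" for i in range(spec.n_cuts + 1)]
    lengths = {n: bounds[i + 1] - bounds[i] for i, n in enumerate(names)}

    def locate(x: int) -> int:
        for i in range(len(bounds) - 1):
            if bounds[i] <= x < bounds[i + 1]:
                return i
        return len(bounds) - 2

    target = spec.molecules_per_junction
    n_molecules = max(1, round(max(target, 5) * G / spec.molecule_len_mean))
    rows: list[tuple[str, int, int, str]] = []
    n_spanning = [0] * spec.n_cuts
    made = 0
    attempts = 0
    while made < n_molecules and attempts < n_molecules * 50:
        attempts += 1
        length = max(spec.read_len * 2, int(rng.exponential(spec.molecule_len_mean)))
        length = min(length, G - 1)
        start = int(rng.integers(0, G - length))
        end = start + length
        spans = [c for c in cuts if start < c < end]
        if target == 0 and spans:
            continue
        barcode = f"BX{int(rng.integers(spec.barcode_pool)):06d}"
        for c in spans:
            n_spanning[cuts.index(c)] += 1
        for _ in range(spec.reads_per_molecule):
            rs = int(rng.integers(start, max(start + 1, end - spec.read_len)))
            re_ = min(rs + spec.read_len, end)
            ci = locate(rs)
            if re_ > bounds[ci + 1]:  # read crosses a cut: unmappable
                continue
            rows.append((names[ci], rs - bounds[ci], re_ - bounds[ci], barcode))
        made += 1
    junctions = tuple((names[i], "3p", names[i + 1], "5p")
                      for i in range(spec.n_cuts))
    truth = ReadTruth(lengths, cuts, junctions, tuple(n_spanning))
    return rows, truth


def write_alignments_tsv(path: str | Path,
                         rows: list[tuple[str, int, int, str]]) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("contig\tstart\tend\tbarcode\n")
        for contig, start, end, barcode in rows:
            fh.write(f"{contig}\t{start}\t{end}\t{barcode}\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

DEFAULT_TISSUES = (
    "aciniform", "aggregate", "flagelliform", "major_ampullate",
    "minor_ampullate", "pyriform", "tubuliform", "cephalothorax",
)


@dataclass(frozen=True)
class ExprSimSpec:
    n_genes: int = 30
    tissues: tuple[str, ...] = DEFAULT_TISSUES
    n_replicates: int = 2
    dominant_log_mean: float = 8.0
    dominant_log_sd: float = 1.0
    background_mean: float = 0.5
    replicate_noise_sd: float = 0.2
    seed: int = 0


def simulate_tpm(spec: ExprSimSpec):
    """Simulate a TPM matrix with one dominant tissue per gene.

    Dominant-tissue expression is log-normal (ln-space mean/sd from the
    spec); other tissues get small exponential background.  Replicates apply
    multiplicative log-normal jitter.  Returns (TpmMatrix, truth) where truth
    maps gene -> dominant tissue.
    """
    import pandas as pd

    from .expression_summary import TpmMatrix

    rng = np.random.default_rng(spec.seed)
    genes = [f"gene{i + 1:03d}" for i in range(spec.n_genes)]
    samples = [f"{t}_r{r + 1}" for t in spec.tissues
               for r in range(spec.n_replicates)]
    truth: dict[str, str] = {}
    data = np.zeros((spec.n_genes, len(samples)))
    for gi, gene in enumerate(genes):
        dom = spec.tissues[int(rng.integers(len(spec.tissues)))]
        truth[gene] = dom
        base = {t: float(rng.exponential(spec.background_mean))
                for t in spec.tissues}
        base[dom] = float(rng.lognormal(spec.dominant_log_mean,
                                        spec.dominant_log_sd))
        for si, sample in enumerate(samples):
            tissue = sample.rsplit("_r", 1)[0]
            noise = float(rng.lognormal(0.0, spec.replicate_noise_sd))
            data[gi, si] = base[tissue] * noise
    values = pd.DataFrame(data, index=pd.Index(genes, name="gene_id"),
                          columns=samples)
    metadata = pd.DataFrame({
        "sample_id": samples,
        "tissue": [s.rsplit("_r", 1)[0] for s in samples],
        "replicate": [s.rsplit("_r", 1)[1] for s in samples],
        "subregion": ["" for _ in samples],
    })
    return TpmMatrix(values, metadata), truth
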