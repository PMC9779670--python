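# Methods

This note documents the models, conventions and numerical choices behind
`silkarch`, and what the synthetic-data generators do and do not emulate.

## Coordinates and sequence model

All intervals are 0-based half-open. GFF3 (1-based inclusive) is converted at
the I/O boundary only. Minus-strand genes store exons in genomic order with a
strand flag; transcription order, splicing and intron orientation are computed
on demand, never stored twice. Translation uses the standard genetic code;
ambiguous bases become `X` with a warning, and a `*` before the final codon
sets a premature-stop flag rather than raising, because truncated silk-gene
paralogs with internal stops (pseudogene candidates) are part of the data.

## Pairwise identity

There is no single community convention for "percent similarity" of repeat
copies, so the package fixes one and uses it everywhere: global
(end-gap-penalized) alignment with match 1, mismatch 0, affine gap open 4 and
extend 1 (Bio.Align.PairwiseAligner), identity = identical aligned columns /
full alignment length, gap columns included. This is deliberately simple and
fully reproducible; statistics computed under other aligners (e.g. MAFFT
pairwise projections) can differ by up to roughly a percentage point on
diverged sequences. The toy values frozen into the tests (6/7 = 85.71% for a
single mismatch, 4/6 = 66.67% for two terminal gaps) pin the convention.

## Intron homology groups and periodicity

Single-linkage clustering at a fixed identity threshold is exactly the
connected components of the "≥ threshold" graph, which is what the package
computes (union–find; deterministic labels by first appearance). The default
threshold is 80%: observed within-group identity in repetitive silk-gene
introns is ≳ 94% while between-group identity is ≲ 50%, so 80 separates the
regimes with a wide margin and the exact value is not critical.

Pattern classification drops the first and last intron when a gene has ≥ 4
introns (terminal introns are systematically less homogenized) and then asks
whether the interior labels are all identical (SINGLE_TYPE), strictly
alternate between exactly two groups (ALTERNATING, truncation allowed), or
neither (MIXED). Genes with ≤ 3 introns and no repeated label are
NON_REPETITIVE. Change points — e.g. a gene whose 5' half carries one
repetitive intron type and whose 3' half alternates two — come from a dynamic
program that segments the label string into regimes, minimizing first the
total number of label positions violating a valid SINGLE/ALTERNATING regime
and then the number of regimes. Minimizing violations first is what makes a
split preferable to calling one sloppy regime; ties resolve to fewer regimes.

Homogenization statistics exclude the terminal introns *before* group
membership is counted, report mean/min/max identity and the pair count per
group, and flag groups left with fewer than two members rather than emitting
NaNs. Both a per-group and a pooled (`within_group_only=False`) variant exist
because "average pairwise similarity within a gene" can be read either way.

## Poly-A units and ensemble repeats

A poly-A run is a maximal uninterrupted `A`-run of ≥ 4 residues (`min_run`,
configurable). Four separates genuine poly-alanine blocks from incidental
alanines inside GAG-style motifs. A unit spans from the end of the previous
run (or the region start) to the end of its own run — glycine-rich region
first, then run — so units tile the region exactly, with any trailing
glycine-rich sequence reported as a remainder rather than forced into a unit.
Linker motifs (MaSp3's KEIIKKIIVHRR, Hamming distance ≤ 3) are masked before
segmentation because they interrupt the repeat array.

Ensemble detection has two modes. EXON mode groups units by the exon (or exon
pair, when the intron pattern alternates) that encodes their first codon —
this is the biologically grounded definition for intron-bearing genes.
PERIODICITY mode, for intronless genes, clusters units into types by identity
(single-linkage at 75%) and takes the shortest type-label period explaining
≥ 80% of positions; both thresholds were fixed by calibrating on synthetic
genes, where type separation is clean across a broad band, and are exposed in
configuration. If no period reaches 80% agreement the gene is flagged
non-periodic instead of inventing structure.

Profile statistics: modal ensemble size by plurality (ties toward the smaller
size, so one duplication never inflates the call), regularity = fraction of
ensembles at the modal size, mean identity over all pairs of modal-size
ensembles on their concatenated protein sequence, and consensus units by
per-column majority over the homologous unit slots (majority-gap columns
dropped; ties resolved by whole-matrix residue frequency, then
lexicographically — determinism over elegance).

Column classification of unit alignments calls a no-gap column with ≥ 2
residues a substitution; per-row gap blocks are merged and a block covering
≥ 90% of the aligned span of any annotated unit in another row classifies all
its columns as whole-unit gain/loss, otherwise small indel. The 90% coverage
threshold absorbs ragged block edges caused by substitutions next to the gap.

## Motif discovery

Exhaustive enumeration of fixed-length k-mers (k = 3–10) replaces
closed-pattern mining: for wildcard-free k-mers of bounded length on inputs of
≤ 10⁴ residues the counts are identical and the enumeration is trivially
auditable. Additional occurrences are counted per sequence (occurrences
beyond the first in each sequence, summed); a pooled-counting switch exists.
Termination tests *total* occurrences > 5, reading "appeared more than five
times" literally; this too is switchable. Selection ties prefer the larger k
(the more specific motif) and then lexicographic order. Masking replaces
every residue of every overlapping occurrence with a sentinel that no window
may span, which guarantees strictly decreasing countable occurrences and
hence termination, and makes the reported motif list leakage-free.

## Linked-read linkage

Molecules are single-linkage chains of same-barcode alignments on one contig
with inter-alignment gap (next start − current extent end, negatives
clamped to 0) ≤ 50 kb; molecule coordinates are the leftmost alignment start
and rightmost alignment end, and chains with < 2 reads are dropped as
carrying no linkage signal. The segment partition places breakpoints at every
molecule boundary, so every base of a segment has the identical covering
set — verified against a per-base oracle in the tests. Barcode similarity is
Jaccard over molecule-backed barcode sets with the raw shared count reported
alongside; Jaccard is scale-free, but no particular statistic is canonical
for this step, and the terminal window (25 kb) is likewise a calibration
default recorded in configuration. Input is a 4-column TSV projection of
BX-tagged alignments, keeping the module free of BAM dependencies; the
conversion one-liner is in the module docstring.

## Expression

Aggregation is a two-stage arithmetic mean — subregions into their parent
gland, then replicates — not a TPM re-normalization. Proportions are computed
on untransformed TPM and only the summed score is log-transformed
(log2(x + 1); base and pseudocount configurable, as the transform is stated
without them in common usage). All-zero genes are flagged undefined rather
than silently zero-filled. Group summaries sum member TPM before the
transform, so a group proportion is not the mean of member proportions.

## Synthetic data: what it emulates and what it does not

`simulate_gene` plants a master ensemble of distinct poly-A units (glycine
regions drawn from weights G .40, P .14, Q .13, S .07, A .06, Y .04, the rest
uniform — matching observed MaSp2 repetitive-region composition), copies it
`n_ensembles` times with whole-unit duplications/deletions (probability 0.15
per copy) and per-residue substitutions in the glycine regions (rate 0.04),
reverse-translates with uniform codon choice, and inserts introns mutated
from one or two masters (rate 0.012) in SINGLE or ALTERNATING layouts. The
default rates place the simulated study in the regime reported for these gene
families: within-group intron identity ≈ 97.6%, ensemble identity ≈ 93.5%,
ensemble-size regularity ≈ 0.835. Substitutions are confined to glycine-rich
regions — poly-alanine runs are modeled as under strict purifying
constraint — which keeps the planted unit boundaries exact so that recovery
can be scored against truth. Consequences: the generator does not produce
run-length polymorphism, codon-usage bias, replication-slippage indels inside
glycine regions, sequencing error, or N/C-terminal domains, and passing
recovery tests therefore demonstrates correctness of the decomposition logic
under the stated model, not robustness to every feature of real assemblies.

`simulate_linked_reads` places exponential-length molecules (mean 40 kb)
uniformly on an uncut genome (300 kb, 1–3 interior cuts with ±5% jitter),
scatters fixed-count 150 bp reads within each, and re-projects coordinates
onto the split contigs, dropping reads that straddle a cut; barcodes come
from a 10 000-barcode pool, so rare collisions (a realistic nuisance) occur.
`simulate_tpm` draws one dominant tissue per gene with log-normal expression
(ln-space mean 8, sd 1), small exponential background elsewhere and
multiplicative log-normal replicate noise (sd 0.2). Every generator is a pure
function of its spec (single numpy PCG64 stream; recorded in truth output)
and emits a truth record sufficient to score the downstream stage.

## Problem sizes

The acceptance script simulates a 12-gene panel for the architecture
statistics, a 54-run recovery grid (3 seeds × sizes {3,4,6} × substitution
rates {0, .01, .03} × two intron modes), 12 split-genome linkage trials, a
50-gene expression panel and 10 planted-motif trials; the test suite's
recovery grid uses 6 seeds per condition (108 runs). These sizes give
binomial standard errors of a few percent on the recovery rates while keeping
a full run in seconds, and they scale linearly if tighter intervals are
wanted.

## Known limitations

- Identity values depend on the fixed alignment convention (above).
- EXON-mode ensembles assign a unit to the exon holding its first codon;
  introns splitting a codon inside a unit shift nothing, but exotic exon
  layouts in which one exon encodes a fraction of a unit would mis-assign.
- Consensus units assume homologous unit slots are length-conserved (true
  under the substitution-dominated model); heavily length-variable slots fall
  back to the most common sequence of the slot.
- Adjacency inference ranks candidate end pairs; it does not scaffold, and no
  significance threshold is attached to a rank-1 call.
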