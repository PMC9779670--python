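"""Intron extraction, identity, homology grouping and pattern classification."""

import numpy as np
import pytest

from silkarch.core_io import GeneModel, Sequence, ValidationError
from silkarch.gene_structure import (
    HomologyGrouping,
    IntronSet,
    PatternClass,
    classify_pattern,
    extract_introns,
    group_introns,
    intron_homogenization,
    pairwise_identity,
)

REVCOMP = str.maketrans("ACGT", "TGCA")


def rc(s):
    return s.translate(REVCOMP)[::-1]


class TestExtractIntrons:
    def test_single_exon_gene_empty(self, dna):
        gene = GeneModel("g", "d", "+", ((0, 9),))
        assert len(extract_introns(gene, dna("ACGTACGTA"))) == 0

    def test_plus_strand(self, dna):
        genome = dna("A" * 10 + "CCCCCCCCCC" + "G" * 10 + "TTTTTTTTTT" + "A" * 10)
        gene = GeneModel("g", "d", "+", ((0, 10), (20, 30), (40, 50)))
        introns = extract_introns(gene, genome)
        assert [i.residues for i in introns.introns] == ["C" * 10, "T" * 10]

    def test_minus_strand_reversed_and_complemented(self, dna):
        contig = "ACGTACGTAC" + "GGATCCGGAT" + "TTTTAAAACC" + "CATGCATGCA" + "GATTACAGAT"
        genome = dna(contig)
        gene = GeneModel("g", "d", "-", ((0, 10), (20, 30), (40, 50)))
        introns = extract_introns(gene, genome)
        # transcription runs right to left: first intron is the rightmost gap
        assert introns.introns[0].residues == rc(contig[30:40])
        assert introns.introns[1].residues == rc(contig[10:20])


class TestPairwiseIdentity:
    def test_identical(self, dna):
        assert pairwise_identity(dna("GATTACA"), dna("GATTACA")) == 100.0

    def test_single_mismatch_no_gaps(self, dna):
        assert pairwise_identity(dna("GATTACA"), dna("GATTATA")) == pytest.approx(
            100 * 6 / 7, abs=0.01)

    def test_terminal_gaps_count_in_denominator(self, dna):
        assert pairwise_identity(dna("AAAA"), dna("AAAAAA")) == pytest.approx(
            100 * 4 / 6, abs=0.01)

    def test_symmetry_and_revcomp_invariance(self, dna):
        rng = np.random.default_rng(11)
        for _ in range(10):
            a = "".join(rng.choice(list("ACGT"), size=30))
            b = "".join(rng.choice(list("ACGT"), size=34))
            ab = pairwise_identity(dna(a), dna(b))
            assert ab == pytest.approx(pairwise_identity(dna(b), dna(a)))
            assert 0.0 <= ab <= 100.0
            assert ab == pytest.approx(
                pairwise_identity(dna(rc(a)), dna(rc(b))), abs=1e-9)

    def test_empty_rejected(self, dna):
        with pytest.raises(ValidationError):
            Sequence("x", "")


def _intron_set(seqs, dna):
    return IntronSet("g", tuple(dna(s, f"i{i}") for i, s in enumerate(seqs)))


class TestGrouping:
    def test_identical_introns_one_group(self, dna):
        grouping = group_introns(_intron_set(["ACGTACGT"] * 4, dna))
        assert grouping.label_string == "AAAA"

    def test_alternating_types(self, dna):
        rng = np.random.default_rng(5)
        t1 = "".join(rng.choice(list("ACGT"), size=100))
        t2 = "".join(rng.choice(list("ACGT"), size=100))

        def mutate(s, k):
            out = list(s)
            for i in rng.choice(len(s), size=k, replace=False):
                out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
            return "".join(out)

        introns = _intron_set([mutate(t1, 5), mutate(t2, 4),
                               mutate(t1, 5), mutate(t2, 4)], dna)
        # verify the planted structure with the exhaustive pairwise matrix
        mat = [[pairwise_identity(a, b) for b in introns.introns]
               for a in introns.introns]
        assert mat[0][2] > 90 and mat[1][3] > 90
        assert mat[0][1] < 80 and mat[0][3] < 80 and mat[1][2] < 80
        assert group_introns(introns).label_string == "ABAB"

    def test_two_distant_introns_two_groups(self, dna):
        grouping = group_introns(_intron_set(["ACGTACGTACGT", "TTGCAATGCACC"], dna))
        assert grouping.label_string == "AB"

    def test_partition_stable_under_input_order(self, dna):
        rng = np.random.default_rng(9)
        t1 = "".join(rng.choice(list("ACGT"), size=80))
        t2 = "".join(rng.choice(list("ACGT"), size=80))
        seqs = [t1, t2, t1, t2, t1]
        base = group_introns(_intron_set(seqs, dna))

        def partition(labels):
            groups = {}
            for i, lab in enumerate(labels):
                groups.setdefault(lab, set()).add(seqs[i])
            return {frozenset(v) for v in groups.values()}

        shuffled = [seqs[i] for i in [4, 2, 0, 1, 3]]
        other = group_introns(_intron_set(shuffled, dna))
        groups_other = {}
        for i, lab in enumerate(other.labels):
            groups_other.setdefault(lab, set()).add(shuffled[i])
        assert partition(base.labels) == {frozenset(v)
                                          for v in groups_other.values()}


class TestClassifyPattern:
    @pytest.mark.parametrize("labels,expected,change_points", [
        ("AAAAAA", PatternClass.SINGLE_TYPE, ()),
        ("ABABABAB", PatternClass.ALTERNATING, ()),
        ("AAAABCBCBC", PatternClass.MIXED, (4,)),
        ("AB", PatternClass.NON_REPETITIVE, ()),
        ("A", PatternClass.NON_REPETITIVE, ()),
        ("ABAB", PatternClass.ALTERNATING, ()),
        ("BAAAAB", PatternClass.SINGLE_TYPE, ()),  # divergent terminals
    ])
    def test_classes(self, labels, expected, change_points):
        # normalize to first-appearance label order
        order = {}
        canon = "".join(order.setdefault(c, chr(ord("A") + len(order)))
                        for c in labels)
        grouping = HomologyGrouping(tuple(canon), 80.0)
        report = classify_pattern(grouping, "g")
        assert report.pattern_class is expected
        assert report.change_points == change_points

    def test_change_point_matches_bruteforce_split(self):
        # oracle: best single split point minimizing regime violations
        labels = tuple("AAAABCBCBC")

        def violations(seg):
            from collections import Counter
            if not seg:
                return 0
            v1 = len(seg) - max(Counter(seg).values())
            ev = Counter(seg[0::2])
            od = Counter(seg[1::2])
            v2 = len(seg) - (max(ev.values()) if ev else 0) - \
                (max(od.values()) if od else 0)
            return min(v1, v2)

        best = min(range(1, len(labels)),
                   key=lambda cut: violations(labels[:cut]) + violations(labels[cut:]))
        report = classify_pattern(HomologyGrouping(labels, 80.0), "g")
        assert report.change_points == (best,)


class TestHomogenization:
    def test_terminal_exclusion_and_pair_count(self, dna):
        introns = _intron_set(["ACGTACGTAC"] * 5, dna)
        grouping = group_introns(introns)
        stats = intron_homogenization(introns, grouping)
        assert stats["A"].n_pairs == 3  # middle three introns
        assert stats["A"].mean_identity == 100.0

    def test_fewer_than_three_introns_empty(self, dna):
        introns = _intron_set(["ACGTACGT", "ACGTACGT"], dna)
        grouping = group_introns(introns)
        assert intron_homogenization(introns, grouping) == {}

    def test_singleton_group_flagged_absent(self, dna):
        introns = _intron_set(["ACGTACGTACGT", "TTGCAATGCACC",
                               "ACGTACGTACGT", "ACGTACGTACGT"], dna)
        grouping = group_introns(introns)
        stats = intron_homogenization(introns, grouping)
        assert stats["B"].n_pairs == 0 and stats["B"].mean_identity is None

    def test_simulated_divergence_matches_direct_matrix(self, dna):
        rng = np.random.default_rng(21)
        master = "".join(rng.choice(list("ACGT"), size=200))

        def mutate(s, rate):
            out = list(s)
            for i in np.nonzero(rng.random(len(s)) < rate)[0]:
                out[i] = {"A": "C", "C": "G", "G": "T", "T": "A"}[out[i]]
            return "".join(out)

        seqs = [mutate(master, 0.02) for _ in range(6)]
        introns = _intron_set(seqs, dna)
        grouping = group_introns(introns)
        stats = intron_homogenization(introns, grouping)
        # direct pairwise matrix over the retained (middle) introns
        from itertools import combinations
        direct = [pairwise_identity(introns.introns[i], introns.introns[j])
                  for i, j in combinations(range(1, 5), 2)]
        assert stats["A"].mean_identity == pytest.approx(np.mean(direct))
        assert 92.0 < stats["A"].mean_identity < 100.0

    def test_mean_decreases_with_mutation_rate(self, dna):
        rng = np.random.default_rng(33)
        master = "".join(rng.choice(list("ACGT"), size=300))

        def gene_mean(rate, seed):
            r = np.random.default_rng(seed)

            def mutate(s):
                out = list(s)
                for i in np.nonzero(r.random(len(s)) < rate)[0]:
                    out[i] = "ACGT"[(("ACGT".index(out[i])) + 1 + r.integers(3)) % 4]
                return "".join(out)

            introns = _intron_set([mutate(master) for _ in range(8)], dna)
            grouping = group_introns(introns, threshold=50)
            return intron_homogenization(introns, grouping)["A"].mean_identity

        means = [np.mean([gene_mean(rate, s) for s in range(3)])
                 for rate in (0.0, 0.02, 0.05)]
        assert means[0] == 100.0
        assert means[0] > means[1] > means[2]
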