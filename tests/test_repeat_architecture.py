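"""Poly-A unit segmentation, ensembles, consensus, linkers, column classes."""

import numpy as np
import pytest

from silkarch.core_io import AlignmentMatrix, GeneModel, ValidationError
from silkarch.gene_structure import PatternClass
from silkarch.repeat_architecture import (
    BoundarySource,
    classify_columns,
    consensus_sequence,
    detect_ensembles,
    ensemble_profile,
    find_linker,
    find_polyA_runs,
    mask_intervals,
    segment_polyA_units,
)


class TestPolyARuns:
    @pytest.mark.parametrize("seq,expected", [
        ("GGQGPGAAAAAGPGG", [(6, 11)]),
        ("GAGAGA", []),
        ("AAAA", [(0, 4)]),
        ("AAAAGPGAAAAA", [(0, 4), (7, 12)]),
    ])
    def test_runs_match_regex_scan(self, protein, seq, expected):
        runs = find_polyA_runs(protein(seq))
        assert [(r.start, r.end) for r in runs] == expected

    def test_matches_naive_scan_on_random(self, protein):
        rng = np.random.default_rng(2)
        for _ in range(20):
            s = "".join(rng.choice(list("AG"), size=60, p=[0.4, 0.6]))
            runs = find_polyA_runs(protein(s))
            naive = []
            i = 0
            while i < len(s):
                if s[i] == "A":
                    j = i
                    while j < len(s) and s[j] == "A":
                        j += 1
                    if j - i >= 4:
                        naive.append((i, j))
                    i = j
                else:
                    i += 1
            assert [(r.start, r.end) for r in runs] == naive


class TestSegmentation:
    def test_boundary_rule(self, protein):
        units, remainder = segment_polyA_units(protein("GPGGAAAAAGPGQAAAA"))
        assert [(u.start, u.end) for u in units] == [(0, 9), (9, 17)]
        assert units[0].glycine_region == (0, 4)
        assert units[0].polyA_run == (4, 9)
        assert remainder is None

    def test_degenerate_pure_polyA(self, protein):
        units, remainder = segment_polyA_units(protein("AAAA"))
        assert len(units) == 1
        assert units[0].glycine_region == (0, 0)
        assert remainder is None

    def test_trailing_remainder_not_a_unit(self, protein):
        units, remainder = segment_polyA_units(protein("GPGGAAAAAGPGQ"))
        assert len(units) == 1 and remainder == (9, 13)

    def test_no_runs_whole_region_is_remainder(self, protein):
        units, remainder = segment_polyA_units(protein("GPGQGPGQ"))
        assert units == [] and remainder == (0, 8)

    def test_units_tile_region(self, protein):
        rng = np.random.default_rng(7)
        for _ in range(10):
            parts = []
            for _ in range(rng.integers(2, 6)):
                gly = "".join(rng.choice(list("GPQS"), size=int(rng.integers(5, 20))))
                parts.append(gly + "A" * int(rng.integers(4, 9)))
            seq = "".join(parts)
            p = protein(seq)
            units, remainder = segment_polyA_units(p)
            covered = "".join(seq[u.start:u.end] for u in units)
            if remainder:
                covered += seq[remainder[0]:remainder[1]]
            assert covered == seq
            for a, b in zip(units, units[1:]):
                assert a.end == b.start


class TestDetectEnsembles:
    def test_periodicity_brute_force_oracle(self, protein):
        # 12 units of two clearly distinct types in pattern 121212121212
        t1 = "GPGQQGPGQGPGQQGPGQGPGQQGPGQGPGQGQ" + "AAAAA"
        t2 = "SPSQYSPSYSPSQYSPSYSPSQYSPSYSPSYSY" + "AAAAA"
        seq = (t1 + t2) * 6
        p = protein(seq)
        units, _ = segment_polyA_units(p)
        assert len(units) == 12
        ens = detect_ensembles(units, p)
        assert [e.size for e in ens] == [2] * 6
        assert all(e.boundary_source is BoundarySource.PERIODICITY for e in ens)
        # brute force: smallest period over type labels with full agreement
        labels = [u.type_label for u in ens[0].units + tuple(
            u for e in ens[1:] for u in e.units)]
        best = next(pp for pp in range(1, 7)
                    if all(labels[i] == labels[i % pp] for i in range(len(labels))))
        assert best == 2

    def test_exon_mode_groups_by_exon(self, protein):
        unit = "GPGQGPGQGPGQGPGQ" + "AAAA"  # 20 aa
        seq = unit * 9
        p = protein(seq)
        units, _ = segment_polyA_units(p)
        # one exon per 3 units (60 aa = 180 nt each), single-type introns
        exons = []
        pos = 0
        for _ in range(3):
            exons.append((pos, pos + 180))
            pos += 180 + 50
        gene = GeneModel("g", "c", "+", tuple(exons))
        ens = detect_ensembles(units, p, gene, PatternClass.SINGLE_TYPE)
        assert [e.size for e in ens] == [3, 3, 3]
        assert all(e.boundary_source is BoundarySource.EXON for e in ens)

    def test_uniform_labels_period_one(self, protein):
        unit = "GPGQGPGQGPGQ" + "AAAA"
        p = protein(unit * 6)
        units, _ = segment_polyA_units(p)
        ens = detect_ensembles(units, p)
        assert [e.size for e in ens] == [1] * 6

    def test_non_periodic_flagged(self, protein):
        rng = np.random.default_rng(13)
        parts = []
        for _ in range(8):
            gly = "".join(rng.choice(list("GPQSYNDEKR"), size=30))
            parts.append(gly + "AAAAA")
        p = protein("".join(parts))
        units, _ = segment_polyA_units(p)
        ens = detect_ensembles(units, p)
        assert len(ens) == 1 and ens[0].non_periodic


class TestEnsembleProfile:
    def test_modal_and_regularity(self, protein):
        unit = "GPGQGPGQGPGQ" + "AAAA"
        seq = unit * 13
        p = protein(seq)
        units, _ = segment_polyA_units(p)
        sizes = [3, 3, 3, 4]
        ens = []
        idx = 0
        from silkarch.repeat_architecture import EnsembleRepeat
        for s in sizes:
            ens.append(EnsembleRepeat(tuple(units[idx:idx + s]),
                                      BoundarySource.EXON))
            idx += s
        prof = ensemble_profile(ens, p)
        assert prof.modal_size == 3
        assert prof.regularity == pytest.approx(0.75)

    def test_identical_ensembles_identity_100_and_consensus(self, protein):
        unit1 = "GPGQQGPGQGPGQQGPG" + "AAAA"
        unit2 = "SPSYSPSYSPSYSPSYS" + "AAAAA"
        seq = (unit1 + unit2) * 4
        p = protein(seq)
        units, _ = segment_polyA_units(p)
        ens = detect_ensembles(units, p)
        prof = ensemble_profile(ens, p)
        assert prof.mean_identity == 100.0
        assert prof.regularity == 1.0
        assert [c.residues for c in prof.consensus_units] == [unit1, unit2]


class TestConsensus:
    def test_majority(self):
        aln = AlignmentMatrix(("GPA", "GPG", "GPG"), ("a", "b", "c"))
        assert consensus_sequence(aln).residues == "GPG"

    def test_majority_gap_column_dropped(self):
        aln = AlignmentMatrix(("GP-G", "GPAG", "GP-G"), ("a", "b", "c"))
        assert consensus_sequence(aln).residues == "GPG"

    def test_tie_break_deterministic(self):
        aln = AlignmentMatrix(("GA", "GC"), ("a", "b"))
        first = consensus_sequence(aln).residues
        for _ in range(5):
            assert consensus_sequence(aln).residues == first
        assert first == "GA"  # tie: equal global frequency, lexicographic

    def test_identical_rows_identity(self):
        aln = AlignmentMatrix(("GPGQA",) * 4, tuple("abcd"))
        assert consensus_sequence(aln).residues == "GPGQA"


class TestLinker:
    def test_exact_hit(self, protein):
        p = protein("GPGQ" * 5 + "KEIIKKIIVHRR" + "GPGQ" * 5)
        (hit,) = find_linker(p)
        assert hit.mismatches == 0 and hit.start == 20

    def test_one_mismatch(self, protein):
        p = protein("GPGQ" * 5 + "KEIIKKIIVHRK" + "GPGQ" * 5)
        (hit,) = find_linker(p)
        assert hit.mismatches == 1

    def test_no_hit_in_glycine_repeat(self, protein):
        assert find_linker(protein("GPG" * 30)) == []

    def test_mask_intervals_removes_linker(self, protein):
        p = protein("GPGQ" * 3 + "KEIIKKIIVHRR" + "GPGQ" * 3)
        hits = find_linker(p)
        masked = mask_intervals(p, [(h.start, h.end) for h in hits])
        assert find_linker(masked) == []
        assert len(masked) == len(p)


class TestClassifyColumns:
    def test_substitution_only(self):
        aln = AlignmentMatrix(("GPGQA", "GPGGA", "GPGQA"), ("a", "b", "c"))
        units = {rid: [(0, 5)] for rid in "abc"}
        res = classify_columns(aln, units)
        assert (res.substitution, res.small_indel, res.unit_gain_loss) == (1, 0, 0)
        assert res.n_variable == 1

    def test_whole_unit_loss(self):
        unit = "GPGQQGPGQGPGQQGPGQGPGQQGPGQGPGQGAAAAAAAA"  # 40 aa
        row_full = unit + unit
        row_miss = unit + "-" * 40
        aln = AlignmentMatrix((row_full, row_full, row_miss), ("a", "b", "c"))
        units = {
            "a": [(0, 40), (40, 80)],
            "b": [(0, 40), (40, 80)],
            "c": [(0, 40)],
        }
        res = classify_columns(aln, units)
        assert res.unit_gain_loss == 40
        assert res.small_indel == 0 and res.substitution == 0

    def test_small_indel(self):
        aln = AlignmentMatrix(("GPGQQGPGQA", "GPG--GPGQA"), ("a", "b"))
        units = {"a": [(0, 10)], "b": [(0, 8)]}
        res = classify_columns(aln, units)
        assert res.small_indel == 2 and res.unit_gain_loss == 0

    def test_counts_sum_to_n_variable(self):
        aln = AlignmentMatrix(("GPGQQGPGQA", "GPG--GPGGA", "GPGQQGPGQA"),
                              ("a", "b", "c"))
        units = {"a": [(0, 10)], "b": [(0, 8)], "c": [(0, 10)]}
        res = classify_columns(aln, units)
        assert res.substitution + res.small_indel + res.unit_gain_loss \
            == res.n_variable
        assert res.n_variable <= res.n_columns

    def test_missing_annotation_rejected(self):
        aln = AlignmentMatrix(("GPG", "GPG"), ("a", "b"))
        with pytest.raises(ValidationError):
            classify_columns(aln, {"a": [(0, 3)]})
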