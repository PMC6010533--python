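"""Peptide model, scanning, dataset-assembly rules and fold clustering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cd4imm.peptides import (
    AA_ALPHABET,
    AssayRecord,
    LabeledPeptide,
    Peptide,
    PeptideError,
    build_tetramer_negatives,
    cluster_and_assign_folds,
    deconstruct_long_epitope,
    read_labeled_tsv,
    remove_cross_redundancy,
    scan_overlapping_kmers,
    select_negatives,
    shares_common_kmer,
    write_labeled_tsv,
)

PROT20 = "ACDEFGHIKLMNPQRSTVWY"

aa_seq = st.text(alphabet=AA_ALPHABET, min_size=1, max_size=60)


def _lp(seq, label=0, study=""):
    return LabeledPeptide(Peptide(seq), label, study)


class TestPeptide:
    def test_lowercase_normalised_and_alphabet_enforced(self):
        assert Peptide("acdef").sequence == "ACDEF"
        with pytest.raises(PeptideError):
            Peptide("ACDEZ")
        with pytest.raises(PeptideError):
            Peptide("")

    def test_unknown_residue_flagged_but_allowed(self):
        assert Peptide("ACDXF").has_unknown
        assert not Peptide("ACDEF").has_unknown

    def test_label_validation(self):
        with pytest.raises(PeptideError):
            LabeledPeptide(Peptide("ACDEF"), 2)


class TestScanning:
    @pytest.mark.parametrize(
        "protein, k, step, offsets",
        [
            (PROT20, 15, 5, [0, 5]),
            (PROT20[:15], 15, 5, [0]),
            (PROT20[:14], 15, 5, []),
            (PROT20, 15, 1, list(range(6))),
            (PROT20, 20, 5, [0]),
        ],
    )
    def test_windows_and_offsets(self, protein, k, step, offsets):
        peps = scan_overlapping_kmers(protein, k=k, step=step)
        assert [p.offset for p in peps] == offsets
        assert all(p.sequence == protein[p.offset : p.offset + k] for p in peps)

    @settings(max_examples=200, deadline=None)
    @given(protein=aa_seq, k=st.integers(1, 20), step=st.integers(1, 8))
    def test_window_count_formula(self, protein, k, step):
        n = len(scan_overlapping_kmers(protein, k=k, step=step))
        expected = (len(protein) - k) // step + 1 if len(protein) >= k else 0
        assert n == expected

    def test_invalid_parameters(self):
        with pytest.raises(PeptideError):
            scan_overlapping_kmers(PROT20, k=0)
        with pytest.raises(PeptideError):
            scan_overlapping_kmers("ACB*", k=2)


class TestDeconstruction:
    def test_15mer_is_itself(self):
        out = deconstruct_long_epitope(Peptide(PROT20[:15]))
        assert len(out) == 1 and out[0].sequence == PROT20[:15]

    def test_17mer_step1_gives_three(self):
        seq = PROT20[:17]
        out = deconstruct_long_epitope(seq, step=1)
        assert [p.sequence for p in out] == [seq[i : i + 15] for i in range(3)]

    def test_20mer_step5_gives_two(self):
        assert [p.offset for p in deconstruct_long_epitope(PROT20, step=5)] == [0, 5]

    def test_too_short_rejected(self):
        with pytest.raises(PeptideError):
            deconstruct_long_epitope(PROT20[:10])


class TestTetramerNegatives:
    def test_positive_window_excluded(self):
        protein = PROT20 + "ACDEF"  # length 25 -> windows at 0, 5, 10
        positive = protein[5:20]
        negs = build_tetramer_negatives(positive, protein)
        assert [n.peptide.offset for n in negs] == [0, 10]
        assert all(n.label == 0 for n in negs)

    def test_identical_protein_gives_no_negatives(self):
        assert build_tetramer_negatives(PROT20[:15], PROT20[:15]) == []

    def test_off_grid_positive_keeps_all_windows(self):
        # exclusion is by sequence identity against the step-5 windows; a
        # positive that sits off the scanning grid matches none of them
        protein = PROT20 + "ACDEF"
        positive = protein[3:18]
        windows = {protein[o : o + 15] for o in (0, 5, 10)}
        assert positive not in windows
        assert len(build_tetramer_negatives(positive, protein)) == 3

    def test_non_15mer_positive_rejected(self):
        with pytest.raises(PeptideError):
            build_tetramer_negatives(PROT20, PROT20 + PROT20)


class TestSelectNegatives:
    def _rec(self, seq, donor, outcome, protein):
        return AssayRecord(Peptide(seq, source_id=protein), donor, outcome, protein)

    def test_requires_protein_with_a_positive(self):
        records = [
            self._rec("AAAAAAAAAAAAAAA", "d1", 1, "P1"),
            self._rec("CCCCCCCCCCCCCCC", "d1", 0, "P1"),
            self._rec("DDDDDDDDDDDDDDD", "d1", 0, "P2"),  # protein with no positive
        ]
        negs = {lp.sequence for lp in select_negatives(records)}
        assert negs == {"CCCCCCCCCCCCCCC"}

    def test_contradictory_donor_outcomes_drop_peptide(self):
        records = [
            self._rec("AAAAAAAAAAAAAAA", "d1", 1, "P1"),
            self._rec("CCCCCCCCCCCCCCC", "d1", 1, "P1"),
            self._rec("CCCCCCCCCCCCCCC", "d1", 0, "P1"),  # same donor, opposite
            self._rec("EEEEEEEEEEEEEEE", "d2", 0, "P1"),
        ]
        negs = {lp.sequence for lp in select_negatives(records)}
        assert negs == {"EEEEEEEEEEEEEEE"}

    def test_no_positives_anywhere_gives_empty(self):
        records = [self._rec("AAAAAAAAAAAAAAA", "d1", 0, "P1")]
        assert select_negatives(records) == []
        assert select_negatives([]) == []

    def test_negatives_disjoint_from_positives(self):
        rng = np.random.default_rng(0)
        letters = np.array(list(AA_ALPHABET))
        records = []
        for i in range(60):
            seq = "".join(rng.choice(letters, 15))
            records.append(self._rec(seq, f"d{i % 5}", int(rng.random() < 0.3), f"P{i % 4}"))
        positives = {r.peptide.sequence for r in records if r.outcome == 1}
        negs = {lp.sequence for lp in select_negatives(records)}
        assert negs.isdisjoint(positives)


class TestKmerRedundancy:
    def test_identical_peptides_share(self):
        assert shares_common_kmer(PROT20[:15], PROT20[:15])

    def test_disjoint_alphabets_do_not(self):
        assert not shares_common_kmer("A" * 15, "C" * 15)

    def test_overlapping_windows_share(self):
        assert shares_common_kmer(PROT20[0:15], PROT20[5:20], k=9)

    def test_shorter_than_k_never_shares(self):
        assert not shares_common_kmer("ACDEF", PROT20)

    def test_filter_matches_bruteforce_all_pairs(self, rng):
        letters = np.array(list(AA_ALPHABET[:6]))  # small alphabet forces collisions
        train = [_lp("".join(rng.choice(letters, 15))) for _ in range(200)]
        ev = [_lp("".join(rng.choice(letters, 15))) for _ in range(200)]
        got = remove_cross_redundancy(train, ev, k=9)
        expected = [
            t for t in train
            if not any(shares_common_kmer(t.sequence, e.sequence, 9) for e in ev)
        ]
        assert [t.sequence for t in got] == [t.sequence for t in expected]

    def test_filter_is_idempotent(self, rng):
        letters = np.array(list(AA_ALPHABET[:4]))
        train = [_lp("".join(rng.choice(letters, 15))) for _ in range(100)]
        ev = [_lp("".join(rng.choice(letters, 15))) for _ in range(50)]
        once = remove_cross_redundancy(train, ev)
        assert remove_cross_redundancy(once, ev) == once

    def test_verbatim_eval_peptide_removed(self):
        train = [_lp(PROT20[:15]), _lp("W" * 15)]
        ev = [_lp(PROT20[:15])]
        assert [t.sequence for t in remove_cross_redundancy(train, ev)] == ["W" * 15]


class TestFoldAssignment:
    def test_balanced_folds_for_independent_peptides(self, rng):
        # mutually non-overlapping peptides: single-residue repeats
        peps = [_lp(aa * 15) for aa in AA_ALPHABET[:10]]
        fa = cluster_and_assign_folds(peps, n_folds=5, seed=1)
        assert sorted(fa.fold_sizes()) == [2, 2, 2, 2, 2]

    def test_shared_kmer_peptides_co_fold(self):
        a, b = PROT20[:15], PROT20[5:20]
        fa = cluster_and_assign_folds([_lp(a), _lp(b), _lp("W" * 15)], n_folds=2, seed=0)
        assert fa[a] == fa[b]

    def test_sharing_implies_same_fold_all_pairs(self, rng):
        letters = np.array(list(AA_ALPHABET[:5]))
        peps = [_lp("".join(rng.choice(letters, 15))) for _ in range(300)]
        fa = cluster_and_assign_folds(peps, n_folds=5, seed=3)
        seqs = sorted({p.sequence for p in peps})
        for i, s1 in enumerate(seqs):
            for s2 in seqs[i + 1 :]:
                if shares_common_kmer(s1, s2, 9):
                    assert fa[s1] == fa[s2]

    def test_every_peptide_assigned_exactly_once(self, planted_small):
        fa = cluster_and_assign_folds(planted_small, n_folds=5, seed=0)
        assert set(fa.folds) == {lp.sequence for lp in planted_small}
        assert sum(fa.fold_sizes()) == len(fa.folds)

    def test_more_folds_than_components_warns(self):
        with pytest.warns(UserWarning):
            cluster_and_assign_folds([_lp("A" * 15), _lp("C" * 15)], n_folds=5, seed=0)

    def test_deterministic_under_seed(self, planted_small):
        a = cluster_and_assign_folds(planted_small, seed=7)
        b = cluster_and_assign_folds(planted_small, seed=7)
        assert a.folds == b.folds


class TestLabeledTsvRoundTrip:
    def test_round_trip(self, tmp_path, planted_small):
        path = tmp_path / "data.tsv"
        write_labeled_tsv(planted_small, path)
        back = read_labeled_tsv(path)
        assert [(lp.sequence, lp.label) for lp in back] == [
            (lp.sequence, lp.label) for lp in planted_small
        ]

    def test_missing_column_reports_file(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("peptide\nACDEF\n")
        with pytest.raises(PeptideError, match="label"):
            read_labeled_tsv(path)

    def test_bad_sequence_reports_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("peptide\tlabel\tstudy_id\nACDEF\t1\ts\nAC*EF\t0\ts\n")
        with pytest.raises(PeptideError, match="line 3"):
            read_labeled_tsv(path)
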