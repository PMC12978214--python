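"""Repeat detection, motif scanning, logos, cysteine and codon statistics."""

import numpy as np
import pytest

from icenuc import (
    cys_profile,
    find_period_repeats,
    gc_content,
    motif_positions,
    repeat_logo,
    rscu,
)
from icenuc.screen import AA_ALPHABET
from icenuc.sequences import CONSENSUS_COIL, reverse_translate, synthetic_inpro_protein

COIL = "AGYGSTQTAGESSLTA"  # 16-residue synthetic solenoid coil


class TestFindPeriodRepeats:
    def test_exact_repeats_single_block(self):
        seq = COIL * 10
        blocks = find_period_repeats(seq)
        assert len(blocks) == 1
        b = blocks[0]
        assert (b.start, b.end) == (0, 160)
        assert b.n_copies == 10
        assert b.mean_identity == 1.0
        assert b.consensus == COIL

    def test_noisy_repeats_still_one_block(self):
        rng = np.random.default_rng(12)
        letters = list(AA_ALPHABET)
        seq = list(COIL * 10)
        for i in range(len(seq)):
            if rng.random() < 0.05:
                seq[i] = letters[rng.integers(20)]
        blocks = find_period_repeats("".join(seq))
        assert len(blocks) == 1
        assert blocks[0].n_copies == 10
        assert blocks[0].mean_identity >= 0.9

    def test_random_sequences_rarely_hit(self):
        rng = np.random.default_rng(99)
        letters = np.array(list(AA_ALPHABET))
        hits = sum(
            bool(find_period_repeats("".join(rng.choice(letters, size=1000))))
            for _ in range(100)
        )
        assert hits <= 5

    def test_reverse_consistency(self):
        rng = np.random.default_rng(5)
        letters = np.array(list(AA_ALPHABET))
        flank1 = "".join(rng.choice(letters, size=57))
        flank2 = "".join(rng.choice(letters, size=83))
        seq = flank1 + COIL * 7 + flank2
        fwd = find_period_repeats(seq)
        rev = find_period_repeats(seq[::-1])
        n = len(seq)
        mirrored = sorted((n - b.end, n - b.start) for b in rev)
        assert sorted((b.start, b.end) for b in fwd) == mirrored

    def test_embedded_block_coordinates(self):
        seq = "W" * 40 + COIL * 6 + "D" * 40
        blocks = find_period_repeats(seq)
        assert len(blocks) >= 1
        b = max(blocks, key=lambda x: x.n_copies)
        # the detected block must cover the repeat array (window edges may blur)
        assert b.start <= 40 + 16
        assert b.end >= 40 + 16 * 5
        assert b.n_copies >= 5

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            find_period_repeats("")


class TestMotifPositions:
    def test_tqt_matches_txt_too(self):
        sites = motif_positions("TQT")
        assert ("TxT", 0) in sites
        assert ("TQT", 0) in sites

    def test_tandem_ygs(self):
        sites = [s for s in motif_positions("YGSYGS") if s[0] == "YGS"]
        assert sites == [("YGS", 0), ("YGS", 3)]

    def test_matches_naive_scan_on_random_sequences(self):
        rng = np.random.default_rng(3)
        letters = np.array(list(AA_ALPHABET))
        motifs = {"TxT": "TxT", "SLT": "SLT", "SxLT": "SxLT"}
        for _ in range(100):
            seq = "".join(rng.choice(letters, size=60))
            got = sorted(motif_positions(seq, motifs))
            naive = []
            for name, pat in motifs.items():
                for i in range(len(seq) - len(pat) + 1):
                    if all(
                        p == "x" or p == seq[i + j] for j, p in enumerate(pat)
                    ):
                        naive.append((name, i))
            assert got == sorted(naive)

    def test_specialization_is_subset(self):
        seq = synthetic_inpro_protein(seed=8)
        tqt = {p for n, p in motif_positions(seq) if n == "TQT"}
        txt = {p for n, p in motif_positions(seq) if n == "TxT"}
        assert tqt <= txt

    def test_malformed_motif_rejected(self):
        with pytest.raises(ValueError):
            motif_positions("AAA", {"bad": "T1T"})


class TestRepeatLogo:
    def test_identical_copies_are_fully_informative(self):
        blocks = find_period_repeats(COIL * 5)
        pfm, info = repeat_logo(blocks[0], COIL * 5)
        assert pfm.shape == (16, 20)
        assert np.allclose(pfm.sum(axis=1), 1.0)
        assert np.allclose(pfm.max(axis=1), 1.0)
        assert np.allclose(info, np.log2(20))

    def test_single_substitution_splits_column(self):
        seq = COIL + COIL[:-1] + "W"
        blocks = find_period_repeats(seq, min_copies=2)
        pfm, info = repeat_logo(blocks[0], seq)
        last = pfm[15]
        assert sorted(last[last > 0]) == [0.5, 0.5]
        assert info[15] == pytest.approx(np.log2(20) - 1.0)

    def test_hand_tally_three_copies(self):
        # three 4-mer copies: ABCD, ABCE, ABDD -> col2 {C:2/3, D:1/3}
        seq = "ABCDABCEABDD".replace("B", "G").replace("A", "A")
        seq = "AGCDAGCEAGDD"
        blocks = find_period_repeats(seq, period=4, min_copies=2, min_identity=0.4)
        b = blocks[0]
        assert b.n_copies == 3
        pfm, _ = repeat_logo(b, seq)
        idx = {aa: i for i, aa in enumerate(AA_ALPHABET)}
        assert pfm[2, idx["C"]] == pytest.approx(2 / 3)
        assert pfm[2, idx["D"]] == pytest.approx(1 / 3)


class TestCysProfile:
    def test_no_cysteines(self):
        assert cys_profile("AGTY" * 10) == (0, 0, 0, [])

    def test_capping_architecture(self):
        seq = "CC" + "A" * 96 + "CCCCCC"  # 104 aa, window 15
        n_tot, n_cterm, n_nterm, pos = cys_profile(seq)
        assert (n_tot, n_cterm, n_nterm) == (8, 6, 2)
        assert pos[:2] == [0, 1]

    def test_invariant_under_non_cys_substitutions(self):
        rng = np.random.default_rng(1)
        letters = np.array(list(AA_ALPHABET.replace("C", "")))
        seq = list("CC" + "A" * 96 + "CCCCCC")
        for i, c in enumerate(seq):
            if c != "C" and rng.random() < 0.5:
                seq[i] = str(rng.choice(letters))
        assert cys_profile("".join(seq))[:3] == (8, 6, 2)


class TestComposition:
    @pytest.mark.parametrize(
        "cds,expected", [("GCGC", 1.0), ("ATAT", 0.0), ("ATGC", 0.5)]
    )
    def test_gc_content_values(self, cds, expected):
        assert gc_content(cds) == expected

    def test_n_bases_drop_from_denominator(self):
        assert gc_content("GCNN") == 1.0

    def test_gc_plus_at_is_one(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            cds = "".join(rng.choice(list("ACGT"), size=90))
            at = (cds.count("A") + cds.count("T")) / len(cds)
            assert gc_content(cds) + at == pytest.approx(1.0)

    def test_uniform_codon_usage_gives_unit_rscu(self):
        # every Phe and Lys codon used once
        vals = rscu("TTTTTCAAAAAG")
        assert vals["TTT"] == vals["TTC"] == vals["AAA"] == vals["AAG"] == 1.0

    def test_two_fold_family_extreme(self):
        vals = rscu("AAAAAA")
        assert vals == {"AAA": 2.0, "AAG": 0.0}

    def test_hand_tally_toy_gene(self):
        # Gly: GGT x2, GGC x1 (4-fold family, total 3); Lys: AAA x1 (2-fold)
        vals = rscu("GGTGGCGGTAAA")
        assert vals["GGT"] == pytest.approx(2 / (3 / 4))
        assert vals["GGC"] == pytest.approx(1 / (3 / 4))
        assert vals["GGA"] == 0.0
        assert vals["AAA"] == 2.0

    def test_family_means_are_one(self):
        cds = reverse_translate(synthetic_inpro_protein(seed=4), gc_bias=0.7, seed=4)
        vals = rscu(cds)
        from icenuc.screen import _standard_code

        _, aa_to_codons = _standard_code()
        for aa, fam in aa_to_codons.items():
            observed = [vals[c] for c in fam if c in vals]
            if observed:
                assert np.mean(observed) == pytest.approx(1.0, abs=1e-9)

    def test_terminal_stop_trimmed_internal_warned(self):
        assert rscu("AAATAA") == {"AAA": 2.0, "AAG": 0.0}
        with pytest.warns(UserWarning):
            rscu("AAATAAAAA")
        with pytest.raises(ValueError):
            rscu("AAAA")

    def test_gc_bias_shifts_synthetic_gene_composition(self):
        protein = synthetic_inpro_protein(seed=6)
        high = gc_content(reverse_translate(protein, gc_bias=0.9, seed=1))
        low = gc_content(reverse_translate(protein, gc_bias=0.1, seed=1))
        assert high - low > 0.1


def test_synthetic_inpro_has_expected_architecture():
    seq = synthetic_inpro_protein(n_repeats=31, seed=0)
    blocks = find_period_repeats(seq)
    assert len(blocks) == 1
    assert blocks[0].n_copies >= 28
    n_tot, n_cterm, n_nterm, _ = cys_profile(seq)
    assert n_cterm >= 6
    names = {n for n, _ in motif_positions(seq)}
    assert {"TQT", "SLT", "YGS"} <= names
    assert CONSENSUS_COIL in (blocks[0].consensus * 2)  # phase-shifted consensus
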