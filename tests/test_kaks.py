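"""NG86 estimator: codon counting, pathway averaging, JC correction."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from oracles import oracle_kaks
from wgdkit.kaks import (
    SENSE_CODONS,
    CodonAlignment,
    EmptyAlignmentError,
    RejectedCodonError,
    SaturationError,
    count_differences,
    count_sites,
    jukes_cantor,
    kaks_pair,
)

codon_st = st.sampled_from(SENSE_CODONS)


def _aln(seq_a, seq_b):
    return CodonAlignment("a", "b", seq_a, seq_b)


class TestCountSites:
    @pytest.mark.parametrize(
        "codon, expected",
        [
            ("ATG", (3.0, 0.0)),  # Met: every mutant changes the amino acid
            ("TGG", (3.0, 0.0)),  # Trp: likewise (mutants include stops)
            ("TTT", (8 / 3, 1 / 3)),  # Phe: only TTT->TTC is synonymous
            ("CTG", (5 / 3, 4 / 3)),  # Leu: 4-fold third position plus CTG->TTG
        ],
    )
    def test_known_codons(self, codon, expected):
        n, s = count_sites(codon)
        assert n == pytest.approx(expected[0], abs=1e-12)
        assert s == pytest.approx(expected[1], abs=1e-12)

    def test_fractions_partition_three_for_every_sense_codon(self):
        for codon in SENSE_CODONS:
            n, s = count_sites(codon)
            assert n + s == pytest.approx(3.0, abs=1e-12)
            assert 0.0 <= s <= 3.0

    @pytest.mark.parametrize("codon", ["TAA", "TGA", "NNA", "A-G"])
    def test_stop_and_ambiguous_codons_rejected(self, codon):
        with pytest.raises(RejectedCodonError):
            count_sites(codon)


class TestCountDifferences:
    @pytest.mark.parametrize(
        "a, b, expected",
        [
            ("TTT", "TTT", (0.0, 0.0)),  # identical
            ("TTT", "TTC", (0.0, 1.0)),  # single synonymous step
            ("TTT", "GTA", (1.5, 0.5)),  # two 2-step pathways averaged
        ],
    )
    def test_examples(self, a, b, expected):
        assert count_differences(a, b) == pytest.approx(expected, abs=1e-12)

    @given(codon_st, codon_st)
    def test_sum_equals_hamming_distance(self, a, b):
        n, s = count_differences(a, b)
        hamming = sum(x != y for x, y in zip(a, b))
        assert n + s == pytest.approx(hamming, abs=1e-12)

    @given(codon_st, codon_st)
    def test_symmetric_in_codon_order(self, a, b):
        assert count_differences(a, b) == pytest.approx(count_differences(b, a), abs=1e-12)


class TestJukesCantor:
    def test_zero_divergence(self):
        assert jukes_cantor(0.0) == 0.0

    def test_closed_form_value(self):
        assert jukes_cantor(0.3) == pytest.approx(-0.75 * math.log(0.6), abs=1e-15)

    @pytest.mark.parametrize("p", [0.75, 0.9, -0.01])
    def test_domain_boundary(self, p):
        with pytest.raises(SaturationError):
            jukes_cantor(p)

    @given(st.floats(min_value=0.0, max_value=0.74))
    def test_correction_never_shrinks_the_proportion(self, p):
        assert jukes_cantor(p) >= p - 1e-15


class TestKaKsPair:
    def test_identical_pair_has_zero_rates_and_undefined_omega(self):
        seq = "".join(SENSE_CODONS[:100])
        est = kaks_pair(_aln(seq, seq))
        assert est.ka == 0.0 and est.ks == 0.0
        assert est.omega is None
        assert "ks_zero" in est.flags

    def test_sites_partition_identity(self, rng):
        from conftest import random_sense_codons

        a = "".join(random_sense_codons(rng, 200))
        b = "".join(random_sense_codons(rng, 200))
        est = kaks_pair(_aln(a, b))
        assert est.n_sites + est.s_sites == pytest.approx(3 * est.codons_used, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        from conftest import random_sense_codons

        for _ in range(150):
            a = "".join(random_sense_codons(rng, 60))
            b = "".join(random_sense_codons(rng, 60))
            est = kaks_pair(_aln(a, b))
            ref = oracle_kaks(a, b)
            for key in ("n_sites", "s_sites", "n_diff", "s_diff", "pn", "ps"):
                assert getattr(est, key) == pytest.approx(ref[key], abs=1e-12)
            for key in ("ka", "ks", "omega"):
                got = getattr(est, key)
                assert (got is None) == (ref[key] is None)
                if got is not None:
                    assert got == pytest.approx(ref[key], abs=1e-12)

    @given(st.lists(st.tuples(codon_st, codon_st), min_size=5, max_size=40))
    def test_symmetry_under_sequence_swap(self, codon_pairs):
        a = "".join(p[0] for p in codon_pairs)
        b = "".join(p[1] for p in codon_pairs)
        try:
            fwd = kaks_pair(_aln(a, b))
            rev = kaks_pair(_aln(b, a))
        except ValueError:
            return  # random concatenation produced an internal stop context
        for key in ("n_sites", "s_sites", "n_diff", "s_diff", "pn", "ps"):
            assert getattr(fwd, key) == pytest.approx(getattr(rev, key), abs=1e-12)

    def test_extra_nonsynonymous_difference_never_decreases_pn(self, rng):
        from conftest import random_sense_codons

        codons = random_sense_codons(rng, 80)
        a = "".join(codons)
        base = kaks_pair(_aln(a, a))
        # replace one codon with a nonsynonymous single-base neighbour
        mutated = list(codons)
        mutated[10] = "ATG" if codons[10] != "ATG" else "ACG"
        est = kaks_pair(_aln(a, "".join(mutated)))
        assert est.pn >= base.pn

    def test_gapped_and_ambiguous_codons_skipped_pairwise(self):
        a = "ATGAAA---TTT"
        b = "ATGAAANNNTTC"
        est = kaks_pair(_aln(a, b))
        assert est.codons_used == 3  # the gapped/N column is dropped, not the pair

    def test_all_unscorable_raises_empty_alignment(self):
        with pytest.raises(EmptyAlignmentError):
            kaks_pair(_aln("---", "---"))

    def test_synonymous_only_process_yields_zero_ka(self):
        from wgdkit.simulate import SimulationConfig, simulate_gene_pairs

        cfg = SimulationConfig(seed=11, n_genes=20, codon_length=120, omega_default=0.0)
        alignments, _ = simulate_gene_pairs(cfg)
        for aln in alignments:
            est = kaks_pair(aln)
            assert est.ka == 0.0
            assert est.ks > 0.0

    def test_omega_recovery_within_15_percent(self):
        from wgdkit.simulate import SimulationConfig, simulate_gene_pairs

        omega_true = 0.2
        cfg = SimulationConfig(
            seed=3,
            n_genes=200,
            codon_length=200,
            omega_default=omega_true,
            accelerated_categories=(),
            pair_ks_range=(0.15, 0.25),
        )
        alignments, _ = simulate_gene_pairs(cfg)
        omegas = [kaks_pair(aln).omega for aln in alignments]
        omegas = np.array([w for w in omegas if w is not None])
        assert abs(np.median(omegas) - omega_true) / omega_true < 0.15


class TestCodonAlignmentValidation:
    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            CodonAlignment("a", "b", "ATGATG", "ATG")

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError, match="multiple of 3"):
            CodonAlignment("a", "b", "ATGA", "ATGA")

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError, match="stop"):
            CodonAlignment("a", "b", "ATGTAAATG", "ATGAAAATG")

    def test_illegal_alphabet_rejected(self):
        with pytest.raises(ValueError, match="illegal"):
            CodonAlignment("a", "b", "ATGXXX", "ATGAAA")
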