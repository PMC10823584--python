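"""Feature computations: compositions, agretopicity, mutation scores,
kernel similarity, physico-chemical descriptors, vector assembly."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from Bio.SeqUtils.ProtParam import ProteinAnalysis

import neoforest as nf
from neoforest.features import (
    Encoding,
    FeatureConfig,
    FeatureFlags,
    KernelSimilarity,
    assemble_features,
    kernel_similarity,
    mutation_scores,
    physchem,
    scaled_agretopicity,
    weighted_composition,
)
from neoforest.matrices import ALPHABET, AA_INDEX, BLOSUM62
from neoforest.profiles import WeightScheme
from neoforest.binding import random_peptides


def test_blosum62_table_matches_biopython():
    from Bio.Align import substitution_matrices

    ref = substitution_matrices.load("BLOSUM62")
    for a in ALPHABET:
        for b in ALPHABET:
            assert BLOSUM62[AA_INDEX[a], AA_INDEX[b]] == ref[a, b]


class TestWeightedComposition:
    def test_monocomposition(self):
        out = weighted_composition("AAAAAAAAA", np.ones(9))
        assert out[AA_INDEX["A"]] == 1.0 and out.sum() == pytest.approx(1.0)

    def test_alternating(self):
        out = weighted_composition("ACACACAC", np.ones(8))
        assert out[AA_INDEX["A"]] == pytest.approx(0.5)
        assert out[AA_INDEX["C"]] == pytest.approx(0.5)

    def test_masking_limit(self):
        w = np.zeros(9)
        w[1] = 1.0
        out = weighted_composition("ACDEFGHIK", w)
        expected = np.zeros(20)
        expected[AA_INDEX["C"]] = 1.0
        assert np.allclose(out, expected)

    def test_blosum_encoding_of_homopolymer(self):
        out = weighted_composition("AAA", np.ones(3), Encoding.BLOSUM62)
        assert np.allclose(out, BLOSUM62[AA_INDEX["A"]])

    def test_zero_weights_fall_back_to_uniform(self, caplog):
        out = weighted_composition("ACAC", np.zeros(4))
        assert out[AA_INDEX["A"]] == pytest.approx(0.5)

    def test_probability_vector_under_all_schemes(self, predictor, allele_set):
        """OneHot composition is a probability vector for every weighting
        scheme (the fully masked case falls back to uniform)."""
        allele = allele_set.alleles[0].name
        binders = nf.sample_strong_binders(predictor, allele, 9, 200, seed=1)
        prof = nf.build_frequency_profile(binders, allele=allele)
        rng = np.random.default_rng(2)
        for scheme in WeightScheme:
            w = nf.make_weights(prof, scheme)
            for pep in random_peptides(20, 9, rng):
                out = weighted_composition(pep, w)
                assert np.all(out >= 0)
                assert out.sum() == pytest.approx(1.0)


class TestScaledAgretopicity:
    def test_worked_example(self):
        """(0.1, 1) and (10, 100) share the unscaled ratio 0.1 but scale to
        0.09 and 9 respectively."""
        s1, r1 = scaled_agretopicity(0.1, 1.0)
        s2, r2 = scaled_agretopicity(10.0, 100.0)
        assert r1 == pytest.approx(0.1) and r2 == pytest.approx(0.1)
        assert s1 == pytest.approx(0.09)
        assert s2 == pytest.approx(9.0)

    def test_equal_ranks_scale_to_zero(self):
        for r in (0.05, 1.0, 37.5):
            assert scaled_agretopicity(r, r)[0] == 0.0

    def test_zero_on_diagonal_only_and_nonnegative(self):
        grid = np.linspace(0.05, 50, 15)
        for rm, rw in itertools.product(grid, grid):
            s, _ = scaled_agretopicity(rm, rw)
            assert s >= 0
            assert (s == 0) == (rm == rw)

    def test_zero_wt_rank_clamped(self):
        with pytest.warns(UserWarning):
            s, ratio = scaled_agretopicity(1.0, 0.0)
        assert np.isfinite(s) and ratio == pytest.approx(1000.0)


from _util import codon_oracle as _codon_oracle


class TestMutationScores:
    def test_identical_sequences(self):
        assert mutation_scores("SLLMWITQV", "SLLMWITQV") == (0.0, 0.0)

    def test_single_known_substitutions(self):
        # A->V is reachable by one substitution of any Ala codon; A->L is not
        _, codon_av = mutation_scores("VAAAAAAAA", "AAAAAAAAA")
        _, codon_al = mutation_scores("LAAAAAAAA", "AAAAAAAAA")
        assert codon_av == pytest.approx(1 / 9)
        assert codon_al == 0.0

    def test_discussion_pair_blosum(self):
        blosum, _ = mutation_scores("SLLMWITQV", "SLLMWITQC")
        assert blosum == BLOSUM62[AA_INDEX["C"], AA_INDEX["V"]]

    def test_codon_matrix_matches_brute_force_for_all_380_pairs(self):
        oracle = _codon_oracle()
        for wt, mut in itertools.permutations(ALPHABET, 2):
            _, codon = mutation_scores(mut + "A" * 8, wt + "A" * 8)
            assert codon == pytest.approx(oracle[(wt, mut)]), (wt, mut)
            assert 0.0 <= codon <= 1.0

    def test_length_mismatch_errors(self):
        with pytest.raises(ValueError):
            mutation_scores("AAA", "AAAA")


class TestKernelSimilarity:
    def test_self_similarity_is_one(self):
        for pep in ("SLLMWITQV", "ACDEFGHK", "ACDEFGHIKLMN"):
            assert kernel_similarity(pep, pep) == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        for a, b in zip(random_peptides(20, 9, rng), random_peptides(20, 10, rng)):
            assert kernel_similarity(a, b) == pytest.approx(kernel_similarity(b, a))

    def test_single_substitution_more_similar_than_unrelated(self):
        """Averaged over 100 seeded draws, a single-substitution pair is
        strictly more similar than two unrelated random peptides."""
        rng = np.random.default_rng(8)
        from neoforest.synthetic import _mutate

        related, unrelated = [], []
        for _ in range(100):
            a = random_peptides(1, 9, rng)[0]
            related.append(kernel_similarity(a, _mutate(a, 1, rng)))
            unrelated.append(kernel_similarity(*random_peptides(2, 9, rng)))
        assert np.mean(related) > np.mean(unrelated)

    def test_identity_of_indiscernibles(self):
        rng = np.random.default_rng(9)
        from neoforest.synthetic import _mutate

        for a in random_peptides(50, 9, rng):
            b = _mutate(a, 1, rng)
            assert kernel_similarity(a, b) < 1.0

    def test_short_peptides_error(self):
        with pytest.raises(ValueError):
            kernel_similarity("AC", "ACDEFGHIK")

    def test_batched_matches_pairwise(self):
        rng = np.random.default_rng(10)
        query = random_peptides(1, 9, rng)[0]
        others = random_peptides(10, 9, rng) + random_peptides(5, 11, rng)
        batched = KernelSimilarity().one_vs_many(query, others)
        singles = [kernel_similarity(query, o) for o in others]
        assert np.allclose(batched, singles)


class TestPhyschem:
    def test_all_alanine(self):
        ai, hydro, _, boman = physchem("AAAAAAAAA")
        assert ai == pytest.approx(100.0)  # Ikai: 100 * mole fraction of Ala
        assert hydro == pytest.approx(1.8)  # Kyte-Doolittle value of Ala
        assert boman == pytest.approx(-1.81)

    def test_against_independent_formula_reimplementation(self):
        """All four descriptors agree with direct in-test evaluations of the
        published formulas (GRAVY and pI via Biopython's ProtParam)."""
        from neoforest.matrices import BOMAN_SCALE, KYTE_DOOLITTLE

        rng = np.random.default_rng(11)
        for pep in random_peptides(50, 10, rng):
            ai, hydro, pi, boman = physchem(pep)
            n = len(pep)
            ref_ai = 100 * (
                pep.count("A") / n
                + 2.9 * pep.count("V") / n
                + 3.9 * (pep.count("I") + pep.count("L")) / n
            )
            assert ai == pytest.approx(ref_ai, abs=1e-3)
            assert hydro == pytest.approx(
                ProteinAnalysis(pep).gravy(), abs=1e-3
            )
            assert pi == pytest.approx(
                ProteinAnalysis(pep).isoelectric_point(), abs=1e-3
            )
            assert boman == pytest.approx(
                sum(BOMAN_SCALE[aa] for aa in pep) / n, abs=1e-3
            )


@pytest.fixture(scope="module")
def prepared(allele_set, predictor):
    records = nf.make_neoepitope_dataset(60, allele_set, nf.SignalSpec(seed=13))
    profiles = nf.ProfileStore.build(
        predictor,
        sorted({r.allele for r in records}),
        lengths=sorted({r.icore.length for r in records}),
        n_binders=100,
        seed=0,
    )
    return records, profiles


class TestAssembleFeatures:
    def test_base_vector_dimension_21(self, prepared):
        records, profiles = prepared
        vec = assemble_features(records[0], profiles, FeatureConfig())
        assert len(vec) == 21

    def test_expression_appends_one_dimension(self, prepared):
        records, profiles = prepared
        config = FeatureConfig(flags=FeatureFlags(expression=True))
        assert len(assemble_features(records[0], profiles, config)) == 22

    def test_full_optional_block_and_order(self, prepared):
        records, profiles = prepared
        flags = FeatureFlags(
            rank_wt=True, scaled_agretopicity=True, blosum_mutation_score=True,
            codon_mutation_score=True, self_similarity=True, physchem=True,
            expression=True, foreignness=True,
        )
        config = FeatureConfig(flags=flags)
        names = config.feature_names()
        assert len(names) == 21 + 11
        vec = assemble_features(records[0], profiles, config)
        assert len(vec) == len(names)
        rec = records[0]
        assert vec[names.index("rank_mut")] == rec.icore.mut_rank
        assert vec[names.index("rank_wt")] == rec.icore.wt_rank
        assert vec[names.index("expression_tpm")] == rec.expression_tpm

    def test_determinism(self, prepared):
        records, profiles = prepared
        config = FeatureConfig(scheme=WeightScheme.NORMAL_MASK)
        v1 = assemble_features(records[3], profiles, config)
        v2 = assemble_features(records[3], profiles, config)
        assert np.array_equal(v1, v2)

    def test_missing_tpm_without_median_errors(self, prepared):
        records, profiles = prepared
        rec = records[0]
        rec2 = nf.NeoEpitopeRecord(
            rec.mutant_peptide, rec.wt_peptide, rec.allele, icore=rec.icore
        )
        config = FeatureConfig(flags=FeatureFlags(expression=True))
        with pytest.raises(ValueError, match="TPM"):
            assemble_features(rec2, profiles, config)
        config.tpm_median = 7.5
        vec = assemble_features(rec2, profiles, config)
        assert vec[-1] == 7.5
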