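from collections import Counter
from itertools import combinations

import numpy as np
import pytest

from coevo.alignment import ALPHABET, N_SYMBOLS
from coevo.integrated import (G_FAMILIES, ConcatenatedAlignment,
                              build_concatenated_alignment,
                              load_coupling_table)
from coevo.patterns import (VECTOR_LENGTH, all_partitions, canonical_partition,
                            classify_pattern, logo_frequencies,
                            make_pattern_cell, pattern_map,
                            pattern_similarity, pattern_table,
                            subtype_pair_frequencies)
from conftest import make_alignment

PAIRS = list(combinations(G_FAMILIES, 2))


def concat_fixture(pairs_by_family):
    """Concatenated alignment with one receptor and one G-alpha column.

    pairs_by_family: {family: list of (receptor_symbol, galpha_symbol)}.
    """
    import pandas as pd
    rows, fams, ids = [], [], []
    for fam, pairs in pairs_by_family.items():
        for k, (a, b) in enumerate(pairs):
            rows.append(a + b)
            fams.append(fam)
            ids.append(f"{fam.replace('/', '')}_{k}")
    aln = make_alignment(rows, labels=["R:3.50", "G:G.H5.23"],
                         families=fams, ids=ids)
    prov = pd.DataFrame({"receptor_seq_id": ids, "galpha_seq_id": ids,
                         "g_family": fams,
                         "species": ["sp"] * len(ids)})
    return ConcatenatedAlignment(aln, prov, boundary=1)


class TestPairFrequencies:
    def test_single_row_is_one_hot(self):
        concat = concat_fixture({"Gi/o": [("A", "R")]})
        F = subtype_pair_frequencies(concat, "3.50", "G.H5.23")
        expected = np.zeros((N_SYMBOLS, N_SYMBOLS))
        expected[ALPHABET.index("A"), ALPHABET.index("R")] = 1.0
        assert np.array_equal(F["Gi/o"], expected)
        assert F["Gs"] is None  # no rows for that family

    def test_counting_matches_hand_computation(self):
        concat = concat_fixture(
            {"Gq/11": [("A", "R"), ("A", "R"), ("G", "K"), ("A", "K")]})
        F = subtype_pair_frequencies(concat, "3.50", "G.H5.23")["Gq/11"]
        A, R = ALPHABET.index("A"), ALPHABET.index("R")
        G, K = ALPHABET.index("G"), ALPHABET.index("K")
        assert F[A, R] == pytest.approx(0.5)
        assert F[G, K] == pytest.approx(0.25)
        assert F[A, K] == pytest.approx(0.25)

    def test_every_non_empty_matrix_sums_to_one(self, small_family):
        # oracle check on a real concatenated alignment
        receptor_aln, galpha_aln, coupling, truth = small_family
        concat = build_concatenated_alignment(
            receptor_aln, galpha_aln, coupling,
            truth.receptor_sectors["selectivity"],
            truth.galpha_sectors["selectivity"])
        F = subtype_pair_frequencies(concat,
                                     truth.receptor_sectors["selectivity"][0],
                                     truth.galpha_sectors["selectivity"][0])
        for fam, mat in F.items():
            if mat is not None:
                assert mat.sum() == pytest.approx(1.0)

    def test_matches_nested_loop_oracle(self):
        rng = np.random.default_rng(2)
        pairs = [(ALPHABET[rng.integers(21)], ALPHABET[rng.integers(21)])
                 for _ in range(40)]
        concat = concat_fixture({"Gs": pairs})
        F = subtype_pair_frequencies(concat, "3.50", "G.H5.23")["Gs"]
        oracle = np.zeros((N_SYMBOLS, N_SYMBOLS))
        for a, b in pairs:  # independent nested-loop count
            oracle[ALPHABET.index(a), ALPHABET.index(b)] += 1 / len(pairs)
        assert np.allclose(F, oracle, atol=1e-15)

    def test_two_receptor_positions_rejected(self):
        concat = concat_fixture({"Gi/o": [("A", "R")]})
        with pytest.raises(ValueError):
            subtype_pair_frequencies(concat, "R:3.50", "R:3.50")


class TestPatternSimilarity:
    def one_hot(self, a, b):
        F = np.zeros((N_SYMBOLS, N_SYMBOLS))
        F[ALPHABET.index(a), ALPHABET.index(b)] = 1.0
        return F

    def test_identical_matrices_give_one(self):
        F = self.one_hot("A", "R")
        assert pattern_similarity(F, F) == pytest.approx(1.0)

    def test_disjoint_support_gives_zero(self):
        assert pattern_similarity(self.one_hot("A", "R"),
                                  self.one_hot("G", "K")) == pytest.approx(0.0)

    def test_hand_computed_cosine(self):
        # one-hot at (A,R) vs uniform over {(A,R),(G,K)}: cosine = 1/sqrt(2)
        half = 0.5 * (self.one_hot("A", "R") + self.one_hot("G", "K"))
        assert pattern_similarity(self.one_hot("A", "R"), half) == \
            pytest.approx(1 / np.sqrt(2))

    def test_scale_invariance_and_symmetry(self):
        rng = np.random.default_rng(0)
        Fa = rng.random((N_SYMBOLS, N_SYMBOLS))
        Fb = rng.random((N_SYMBOLS, N_SYMBOLS))
        assert pattern_similarity(Fa, Fb) == pytest.approx(
            pattern_similarity(Fb, Fa))
        assert pattern_similarity(3.7 * Fa, Fb) == pytest.approx(
            pattern_similarity(Fa, Fb))

    def test_raw_inner_product_available(self):
        F = self.one_hot("A", "R") * 0.5
        assert pattern_similarity(F, F, normalized=False) == \
            pytest.approx(0.25)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            pattern_similarity(np.zeros((N_SYMBOLS, N_SYMBOLS)),
                               self.one_hot("A", "R"))

    def test_flattened_vector_length_is_441(self):
        assert VECTOR_LENGTH == 441 == N_SYMBOLS * N_SYMBOLS


class TestClassifyPattern:
    def sims(self, high_pairs):
        return {frozenset(p): (0.9 if set(p) in
                               [set(h) for h in high_pairs] else 0.1)
                for p in PAIRS}

    def test_four_families_give_six_comparisons(self):
        assert len(PAIRS) == 6

    def test_all_similar_gives_single_block(self):
        part = classify_pattern(self.sims(PAIRS), 0.6)
        assert part == (tuple(G_FAMILIES),)

    def test_all_different_gives_four_singletons(self):
        part = classify_pattern(self.sims([]), 0.6)
        assert part == tuple((f,) for f in G_FAMILIES)

    def test_intransitive_chain_closes_into_one_block(self):
        # A~B, B~C only: component closure puts {A,B,C} together
        a, b, c, d = G_FAMILIES
        part = classify_pattern(self.sims([(a, b), (b, c)]), 0.6)
        assert part == (canonical_partition([(a, b, c)])[0], (d,))

    def test_planted_dichotomy(self):
        gi, gq, gs, g12 = G_FAMILIES
        part = classify_pattern(self.sims([(gi, g12), (gq, gs)]), 0.6)
        assert part == canonical_partition([(gi, g12), (gq, gs)])

    def test_exhaustive_64_configurations_cover_all_15_partitions(self):
        seen = set()
        valid = set(all_partitions())
        for mask in range(64):
            sims = {frozenset(p): (1.0 if mask & (1 << i) else 0.0)
                    for i, p in enumerate(PAIRS)}
            part = classify_pattern(sims, 0.6)
            # partition validity: disjoint blocks covering all four families
            flat = [f for block in part for f in block]
            assert sorted(flat) == sorted(G_FAMILIES)
            assert part in valid
            seen.add(part)
        assert len(seen) == 15

    def test_missing_family_classified_on_remainder(self):
        present = ("Gi/o", "Gq/11", "Gs")
        sims = {frozenset(p): 0.9 for p in combinations(present, 2)}
        part = classify_pattern(sims, 0.6, families=present)
        assert part == (present,)

    def test_there_are_exactly_15_partitions_of_four(self):
        assert len(all_partitions()) == 15


class TestPatternMap:
    def test_grid_shape_and_histogram(self):
        concat = concat_fixture({
            "Gi/o": [("A", "R")] * 3, "Gq/11": [("A", "R")] * 3,
            "Gs": [("A", "R")] * 3, "G12/13": [("A", "R")] * 3})
        grid, hist = pattern_map(concat, ["3.50"], ["G.H5.23"])
        assert len(grid) == 1 and len(grid[0]) == 1
        assert hist == Counter({"|".join(["+".join(G_FAMILIES)]): 1})

    def test_identical_column_across_couplings_gives_single_block(self):
        concat = concat_fixture({fam: [("A", "R"), ("A", "K")]
                                 for fam in G_FAMILIES})
        cell = make_pattern_cell(concat, "3.50", "G.H5.23")
        assert cell.partition == (tuple(G_FAMILIES),)

    def test_planted_dichotomy_recovered(self):
        concat = concat_fixture({
            "Gi/o": [("A", "R")] * 4, "G12/13": [("A", "R")] * 4,
            "Gq/11": [("G", "K")] * 4, "Gs": [("G", "K")] * 4})
        cell = make_pattern_cell(concat, "3.50", "G.H5.23")
        assert cell.partition == canonical_partition(
            [("Gi/o", "G12/13"), ("Gq/11", "Gs")])

    def test_pattern_table_has_six_similarity_columns(self):
        concat = concat_fixture({fam: [("A", "R")] for fam in G_FAMILIES})
        grid, _ = pattern_map(concat, ["3.50"], ["G.H5.23"])
        table = pattern_table(grid)
        sim_cols = [c for c in table.columns if c.startswith("s_")]
        assert len(sim_cols) == 6

    def test_empty_sector_rejected(self):
        concat = concat_fixture({"Gi/o": [("A", "R")]})
        with pytest.raises(ValueError):
            pattern_map(concat, [], ["G.H5.23"])

    def test_logo_frequencies_sum_to_one_per_family(self):
        concat = concat_fixture({
            "Gi/o": [("A", "R"), ("G", "R")], "Gs": [("A", "K")]})
        logos = logo_frequencies(concat, ["3.50"])
        for fam, grp in logos.groupby("g_family"):
            assert grp.freq.sum() == pytest.approx(1.0)
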