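import math

import numpy as np
import pytest

from coevo.alignment import ALPHABET, N_SYMBOLS, SequenceWeights, compute_sequence_weights
from coevo.sca import (Sector, assign_conservation_classes,
                       background_frequencies, compare_sector_conservation,
                       coupling_matrix, estimate_frequencies, extract_sectors,
                       noise_clean, positional_conservation,
                       significance_stars)
from coevo.simulate import generate_null_alignment
from conftest import make_alignment


def brute_force_coupling(aln, weights, lambda_pc, q):
    """Independent oracle: nested-loop frequency counting + formula."""
    n_seq, n_pos = aln.matrix.shape
    sym = {c: i for i, c in enumerate(ALPHABET)}
    w, M = weights.w_s, weights.M_eff
    f1 = np.zeros((n_pos, N_SYMBOLS))
    for i in range(n_pos):
        for s in range(n_seq):
            f1[i, sym[aln.matrix[s, i]]] += w[s]
    f1 = (1 - lambda_pc) * f1 / M + lambda_pc * q[None, :]
    f2 = np.zeros((n_pos, n_pos, N_SYMBOLS, N_SYMBOLS))
    for i in range(n_pos):
        for j in range(n_pos):
            if i == j:
                for a in range(N_SYMBOLS):
                    f2[i, i, a, a] = f1[i, a]
                continue
            for s in range(n_seq):
                f2[i, j, sym[aln.matrix[s, i]], sym[aln.matrix[s, j]]] += w[s]
            f2[i, j] = (1 - lambda_pc) * f2[i, j] / M \
                + lambda_pc * np.outer(q, q)
    lam = max(lambda_pc, 1e-6)
    f = np.clip(f1, lam * q[None, :], 1 - lam * (1 - q[None, :]))
    phi = np.log(f * (1 - q[None, :]) / ((1 - f) * q[None, :]))
    C = np.zeros((n_pos, n_pos))
    for i in range(n_pos):
        for j in range(n_pos):
            acc = 0.0
            for a in range(N_SYMBOLS):
                for b in range(N_SYMBOLS):
                    t = phi[i, a] * phi[j, b] * (
                        f2[i, j, a, b] - f1[i, a] * f1[j, b])
                    acc += t * t
            C[i, j] = math.sqrt(acc)
    return C


class TestFrequencies:
    def test_single_sequence_is_one_hot(self):
        aln = make_alignment(["A"])
        w = SequenceWeights.uniform(1)
        fm = estimate_frequencies(aln, w, lambda_pc=0.0)
        expected = np.zeros(N_SYMBOLS)
        expected[ALPHABET.index("A")] = 1.0
        assert np.allclose(fm.f1[0], expected)

    def test_half_half_column(self):
        aln = make_alignment(["A", "A", "G", "G"])
        fm = estimate_frequencies(aln, SequenceWeights.uniform(4), lambda_pc=0.0)
        assert fm.f1[0, ALPHABET.index("A")] == pytest.approx(0.5)
        assert fm.f1[0, ALPHABET.index("G")] == pytest.approx(0.5)

    def test_pseudocount_pulls_toward_background_monotonically(self):
        aln = make_alignment(["A", "A", "A"])
        q = background_frequencies()
        a_idx = ALPHABET.index("A")
        prev = 1.0
        for lam in (0.0, 0.1, 0.5, 0.9):
            fm = estimate_frequencies(aln, SequenceWeights.uniform(3),
                                      lambda_pc=lam, q=q)
            val = fm.f1[0, a_idx]
            assert val <= prev + 1e-12
            prev = val
        assert prev == pytest.approx((1 - 0.9) + 0.9 * q[a_idx])

    def test_lambda_one_rejected(self):
        aln = make_alignment(["A"])
        with pytest.raises(ValueError):
            estimate_frequencies(aln, SequenceWeights.uniform(1), lambda_pc=1.0)

    def test_normalization_and_symmetry_invariants(self):
        aln = make_alignment(["ARNDC", "GRN-C", "ARKDC", "AWNDC"])
        w = compute_sequence_weights(aln)
        fm = estimate_frequencies(aln, w, lambda_pc=0.03)
        assert np.allclose(fm.f1.sum(axis=1), 1.0, atol=1e-12)
        for i in range(aln.n_pos):
            for j in range(aln.n_pos):
                assert abs(fm.f2(i, j).sum() - 1.0) < 1e-12
                assert np.allclose(fm.f2(i, j), fm.f2(j, i).T, atol=1e-12)
            assert np.allclose(np.diag(fm.f2(i, i)), fm.f1[i], atol=1e-12)


class TestConservation:
    def test_background_column_has_zero_kld(self):
        q = background_frequencies()
        aln = make_alignment(["A"])
        fm = estimate_frequencies(aln, SequenceWeights.uniform(1), lambda_pc=0.0)
        fm.f1[0] = q  # force f1 = q at this position
        prof = positional_conservation(fm)
        assert prof.D[0] == pytest.approx(0.0, abs=1e-12)

    def test_fully_conserved_closed_form(self):
        # D = ln(1/q_a) for a one-hot column
        q = np.full(N_SYMBOLS, 1 / N_SYMBOLS)
        q = np.where(np.arange(N_SYMBOLS) == 0, 0.05, (1 - 0.05) / 20)
        aln = make_alignment(["A", "A", "A"])
        fm = estimate_frequencies(aln, SequenceWeights.uniform(3),
                                  lambda_pc=0.0, q=q)
        prof = positional_conservation(fm)
        assert prof.D[0] == pytest.approx(math.log(20), rel=1e-9)

    def test_two_residue_column_closed_form(self):
        # 0.5/0.5 over two residues with q = 0.05 each: D = ln(10)
        q = np.full(N_SYMBOLS, 0.05)
        q[2:] = 0.9 / 19  # arbitrary but positive, A and R stay at 0.05
        aln = make_alignment(["A", "R"])
        fm = estimate_frequencies(aln, SequenceWeights.uniform(2), lambda_pc=0.0, q=q)
        prof = positional_conservation(fm)
        assert prof.D[0] == pytest.approx(math.log(10), rel=1e-9)

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError):
            background_frequencies(gap_background=0.0)


class TestCouplingMatrix:
    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        rows = ["".join(rng.choice(list("ARND-"), size=8)) for _ in range(10)]
        aln = make_alignment(rows)
        w = compute_sequence_weights(aln, 0.8)
        q = background_frequencies()
        fm = estimate_frequencies(aln, w, lambda_pc=0.01, q=q)
        C = coupling_matrix(aln, w, fm)
        oracle = brute_force_coupling(aln, w, 0.01, q)
        assert np.max(np.abs(C.values - oracle)) < 1e-10

    def test_perfectly_covarying_pair_matches_oracle(self):
        rows = ["AR", "AR", "AR", "AR", "GK", "GK", "GK", "GK"]
        aln = make_alignment(rows)
        w = SequenceWeights.uniform(8)
        q = background_frequencies()
        fm = estimate_frequencies(aln, w, lambda_pc=0.01, q=q)
        C = coupling_matrix(aln, w, fm)
        oracle = brute_force_coupling(aln, w, 0.01, q)
        assert np.max(np.abs(C.values - oracle)) < 1e-10
        assert C.values[0, 1] > 0.5  # strong planted covariation

    def test_independent_columns_give_zero_coupling(self):
        # every combination equally represented: f2 factorizes exactly
        rows = ["AR", "AK", "GR", "GK"]
        aln = make_alignment(rows)
        fm = estimate_frequencies(aln, SequenceWeights.uniform(4), lambda_pc=0.0)
        C = coupling_matrix(aln, SequenceWeights.uniform(4), fm)
        assert C.values[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_symmetry(self):
        rng = np.random.default_rng(7)
        rows = ["".join(rng.choice(list(ALPHABET), size=6)) for _ in range(12)]
        aln = make_alignment(rows)
        w = compute_sequence_weights(aln)
        fm = estimate_frequencies(aln, w)
        C = coupling_matrix(aln, w, fm)
        assert np.allclose(C.values, C.values.T, atol=1e-12)
        assert np.all(C.values >= 0)


class TestNoiseCleanAndSectors:
    def test_eigenvalues_sorted_and_complete(self):
        aln = generate_null_alignment(60, 12, seed=5)
        w = compute_sequence_weights(aln)
        fm = estimate_frequencies(aln, w)
        C = coupling_matrix(aln, w, fm)
        spec = noise_clean(C, aln, w, n_rand=10, seed=6)
        assert len(spec.eigenvalues) == 12
        assert np.all(np.diff(spec.eigenvalues) <= 1e-12)

    def test_n_rand_minimum_enforced(self):
        aln = generate_null_alignment(20, 5, seed=1)
        w = compute_sequence_weights(aln)
        fm = estimate_frequencies(aln, w)
        C = coupling_matrix(aln, w, fm)
        with pytest.raises(ValueError):
            noise_clean(C, aln, w, n_rand=5, seed=2)

    def test_planted_block_dominates_top_mode(self):
        rng = np.random.default_rng(123)
        n_seq, n_pos, block = 200, 30, list(range(10))
        idx = rng.integers(0, 20, size=(n_seq, n_pos))
        state = rng.integers(0, 2, size=n_seq)  # two covarying classes
        for j in block:
            res = rng.choice(20, size=2, replace=False)
            idx[:, j] = res[state]
        rows = ["".join(ALPHABET[a] for a in r) for r in idx]
        aln = make_alignment(rows)
        w = compute_sequence_weights(aln)
        fm = estimate_frequencies(aln, w)
        C = coupling_matrix(aln, w, fm)
        spec = noise_clean(C, aln, w, n_rand=10, seed=9)
        assert spec.k_star >= 1
        top_positions = np.argsort(np.abs(spec.W[:, 0]))[-10:]
        assert set(top_positions) == set(block)
        sectors = extract_sectors(spec, C)
        assert len(sectors) >= 1
        best = max(sectors, key=lambda s: len(set(s.positions)
                                              & {f"p{j}" for j in block}))
        recovered = set(best.positions) & {f"p{j}" for j in block}
        assert len(recovered) >= 9

    def test_k_star_zero_yields_no_sectors(self):
        aln = generate_null_alignment(150, 20, seed=21)
        w = compute_sequence_weights(aln)
        fm = estimate_frequencies(aln, w)
        C = coupling_matrix(aln, w, fm)
        spec = noise_clean(C, aln, w, n_rand=20, seed=22)
        if spec.k_star == 0:
            assert spec.W.shape == (20, 0)
            assert extract_sectors(spec, C) == []
        else:  # rare by construction; sectors must then be small or absent
            assert spec.k_star <= 2


class TestSectorConservationStats:
    def _profile(self, values):
        class P:
            positions = [f"p{i}" for i in range(len(values))]
            D = np.asarray(values, dtype=float)
        return P()

    def _sector(self, name, idx):
        return Sector(name=name, positions=[f"p{i}" for i in idx],
                      loadings={f"p{i}": 1.0 for i in idx})

    def test_identical_distributions_give_p_one(self):
        prof = self._profile([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        secs = [self._sector("a", [0, 1, 2]), self._sector("b", [3, 4, 5])]
        table = compare_sector_conservation(prof, secs)
        assert table.p.iloc[0] == pytest.approx(1.0)
        assert table.stars.iloc[0] == "ns"

    def test_strong_shift_earns_four_stars(self):
        rng = np.random.default_rng(3)
        hi = 2.5 + rng.random(30) * 0.5
        lo = rng.random(30) * 0.5
        prof = self._profile(np.concatenate([hi, lo]))
        secs = [self._sector("cons", range(30)),
                self._sector("coev", range(30, 60))]
        table = compare_sector_conservation(prof, secs)
        assert table.p.iloc[0] <= 1e-4
        assert table.stars.iloc[0] == "****"

    def test_swapping_sectors_leaves_p_unchanged(self):
        rng = np.random.default_rng(4)
        prof = self._profile(rng.random(20))
        a, b = self._sector("a", range(10)), self._sector("b", range(10, 20))
        t1 = compare_sector_conservation(prof, [a, b])
        t2 = compare_sector_conservation(prof, [b, a])
        assert t1.p.iloc[0] == pytest.approx(t2.p.iloc[0])

    def test_tiny_sector_skipped_with_warning(self):
        prof = self._profile([1.0, 2.0, 3.0, 4.0])
        secs = [self._sector("tiny", [0]), self._sector("ok", [1, 2, 3])]
        with pytest.warns(UserWarning, match="tiny"):
            table = compare_sector_conservation(prof, secs)
        assert table.empty

    def test_conserved_class_requires_dominance_and_significance(self):
        rng = np.random.default_rng(5)
        hi = 2.5 + rng.random(30) * 0.5
        lo = rng.random(30) * 0.5
        prof = self._profile(np.concatenate([hi, lo]))
        secs = [self._sector("blue", range(30)),
                self._sector("red", range(30, 60))]
        assign_conservation_classes(prof, secs)
        assert secs[0].conservation_class == "conserved"
        assert secs[1].conservation_class == "coevolved"

    def test_star_convention(self):
        assert significance_stars(2e-5) == "****"
        assert significance_stars(5e-4) == "***"
        assert significance_stars(0.2) == "ns"
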