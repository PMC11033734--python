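"""Structured-matrix family, sparse injectivity number, and the search."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cspapi.cs_design import (
    CSStructure,
    assemble_block_diagonal,
    best_s_term_error,
    compression_sweep,
    is_feasible,
    make_cs_matrix,
    normalized_sin,
    replicate_group,
    rip_delta,
    sample_feasible_matrix,
    search_design,
    sin,
)

# the worked 2x16 example: row 1 activates sensor 1 in blocks 1 and 3 and
# sensor 2 in block 4; row 2 activates sensor 4 in blocks 1 and 3 and
# sensor 1 in block 2
EXAMPLE_SELECTION = [[1, 0, 1, 2], [4, 1, 4, 0]]
EXAMPLE_ROWS = [
    [1, 0, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 1, 0, 0],
    [0, 0, 0, 1, 1, 0, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0],
]


class TestMakeCSMatrix:
    def test_worked_example(self):
        st2 = CSStructure(m0=2)
        gm = make_cs_matrix(EXAMPLE_SELECTION, st2)
        assert gm.entries.tolist() == EXAMPLE_ROWS

    def test_all_off_gives_zero_matrix(self):
        st2 = CSStructure(m0=3)
        gm = make_cs_matrix(np.zeros((3, 4), dtype=int), st2)
        assert not gm.entries.any()

    def test_full_rows_have_blocksize_sum(self):
        st2 = CSStructure(m0=5)
        gm = make_cs_matrix(np.ones((5, 4), dtype=int), st2)
        assert (gm.entries.sum(axis=1) == st2.blocks_per_group).all()

    def test_invalid_entry_names_row_and_block(self):
        st2 = CSStructure(m0=2)
        bad = [[1, 0, 1, 2], [4, 7, 4, 0]]
        with pytest.raises(ValueError, match="row 1, block 1"):
            make_cs_matrix(bad, st2)

    def test_selection_round_trip(self):
        st2 = CSStructure(m0=2)
        gm = make_cs_matrix(EXAMPLE_SELECTION, st2)
        assert gm.selection().tolist() == EXAMPLE_SELECTION


class TestFeasibility:
    def test_example_is_feasible(self):
        assert is_feasible(np.array(EXAMPLE_ROWS), CSStructure(m0=2))

    def test_two_ones_in_a_block_infeasible(self):
        M = np.array(EXAMPLE_ROWS)
        M[0, 1] = 1  # second active sensor in block 1 of row 1
        assert not is_feasible(M, CSStructure(m0=2))

    def test_zero_matrix_feasible(self):
        assert is_feasible(np.zeros((2, 16)), CSStructure(m0=2))

    def test_nonbinary_infeasible(self):
        M = np.array(EXAMPLE_ROWS, dtype=float)
        M[0, 0] = 0.5
        assert not is_feasible(M, CSStructure(m0=2))

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="shape"):
            is_feasible(np.zeros((3, 16)), CSStructure(m0=2))


class TestSampling:
    def test_seeded_determinism(self, default_structure):
        a = sample_feasible_matrix(default_structure, np.random.default_rng(7))
        b = sample_feasible_matrix(default_structure, np.random.default_rng(7))
        assert np.array_equal(a[1].entries, b[1].entries)

    def test_feasibility_closure(self, default_structure, rng):
        for _ in range(50):
            _, gm = sample_feasible_matrix(default_structure, rng)
            assert is_feasible(gm.entries, default_structure)

    def test_off_frequency_law_of_large_numbers(self, rng):
        # per (row, block) cell P(off) = 1/(block_size+1) = 1/5
        st2 = CSStructure(m0=10)
        sels = np.stack(
            [sample_feasible_matrix(st2, rng)[0] for _ in range(2500)]
        )  # 2500 draws x 10 rows x 4 blocks = 1e5 cells
        assert abs((sels == 0).mean() - 0.2) < 0.01


class TestSIN:
    def test_identity_matrix(self):
        assert sin(np.eye(16), 2) == pytest.approx(1.0)

    def test_zero_column_gives_zero(self):
        M = np.eye(16)
        M[:, 3] = 0.0
        assert sin(M, 2) == 0.0

    def test_worked_example_matrix_is_singular(self):
        # the m0=2 example has many all-zero columns
        assert sin(np.array(EXAMPLE_ROWS), 2) == 0.0

    def test_guard_on_support_size(self):
        with pytest.raises(ValueError):
            sin(np.eye(4), 3)

    def test_monotone_in_sparsity(self, default_structure, rng):
        for _ in range(10):
            _, gm = sample_feasible_matrix(default_structure, rng)
            M = gm.entries
            values = [sin(M, s) for s in (1, 2, 3)]
            assert values[0] >= values[1] >= values[2]

    def test_bounded_by_spectral_norm(self, default_structure, rng):
        for _ in range(10):
            M = sample_feasible_matrix(default_structure, rng)[1].entries.astype(float)
            assert 0.0 <= sin(M, 2) <= np.linalg.norm(M, 2) + 1e-12

    @given(perm_seed=st.integers(0, 10_000))
    @settings(max_examples=15, deadline=None, derandomize=True)
    def test_permutation_invariance(self, perm_seed):
        prng = np.random.default_rng(perm_seed)
        M = sample_feasible_matrix(CSStructure(m0=8), prng)[1].entries.astype(float)
        P = M[prng.permutation(8)][:, prng.permutation(16)]
        assert sin(P, 2) == pytest.approx(sin(M, 2), abs=1e-12)

    def test_oracle_equivalence_small_matrices(self, rng):
        # on <= 8 columns: enumeration equals direct minimization over the
        # per-support singular directions; densely sampled sparse
        # differences never undercut it
        st2 = CSStructure(m0=6, block_size=2, blocks_per_group=4)
        for _ in range(5):
            M = sample_feasible_matrix(st2, rng)[1].entries.astype(float)
            claimed = sin(M, 2)
            per_support = min(
                np.linalg.svd(M[:, list(S)], compute_uv=False)[-1]
                for S in itertools.combinations(range(8), 4)
            )
            if claimed == 0.0:
                assert per_support < 1e-7
            else:
                assert claimed == pytest.approx(per_support, abs=1e-6)
            for _ in range(2000):
                x = np.zeros(8)
                x[rng.choice(8, 2, replace=False)] = rng.normal(size=2)
                x[rng.choice(8, 2, replace=False)] -= rng.normal(size=2)
                nx = np.linalg.norm(x)
                if nx > 1e-9:
                    assert np.linalg.norm(M @ x) / nx >= claimed - 1e-9

    def test_identifiability_iff_full_rank_submatrices(self, default_structure, rng):
        for _ in range(10):
            M = sample_feasible_matrix(default_structure, rng)[1].entries.astype(float)
            full_rank = all(
                np.linalg.matrix_rank(M[:, list(S)]) == 4
                for S in itertools.combinations(range(16), 4)
            )
            assert (sin(M, 2) > 0) == full_rank

    def test_normalized_variant(self, optimized_design):
        M = optimized_design.best_matrix.entries.astype(float)
        assert normalized_sin(M, 2) == pytest.approx(
            sin(M, 2) / np.linalg.norm(M, 2)
        )


class TestRIPDelta:
    def test_identity_is_isometry(self):
        assert rip_delta(np.eye(8), 3) == 0.0

    def test_zero_matrix(self):
        assert rip_delta(np.zeros((4, 6)), 1) == pytest.approx(1.0)

    @pytest.mark.parametrize("eps", [0.1, 0.5, 0.9])
    def test_2x2_closed_form(self, eps):
        # columns (1,0) and (eps, sqrt(1-eps^2)): Gram [[1,eps],[eps,1]],
        # eigenvalues 1 +/- eps, so delta = eps
        M = np.array([[1.0, eps], [0.0, np.sqrt(1 - eps**2)]])
        assert rip_delta(M, 2) == pytest.approx(eps, abs=1e-12)

    def test_enumeration_guard(self):
        with pytest.raises(ValueError, match="guard"):
            rip_delta(np.zeros((4, 30)), 2)

    def test_permutation_invariance(self, rng):
        M = sample_feasible_matrix(CSStructure(m0=8), rng)[1].entries.astype(float)
        P = M[rng.permutation(8)][:, rng.permutation(16)]
        assert rip_delta(P, 2) == pytest.approx(rip_delta(M, 2), abs=1e-12)


class TestBestSTerm:
    def test_full_sparsity_is_zero(self):
        assert best_s_term_error([3.0, -1.0, 0.5], 3) == 0.0

    def test_worked_example(self):
        assert best_s_term_error([3.0, -1.0, 0.5], 1) == pytest.approx(1.5)

    def test_s_zero_is_l1_norm(self):
        x = [3.0, -1.0, 0.5]
        assert best_s_term_error(x, 0) == pytest.approx(4.5)


class TestSearchDesign:
    def test_zero_iterations(self, default_structure):
        res = search_design(default_structure, 2, 0, seed=0)
        assert res.best_sin == 0.0
        assert not res.best_matrix.entries.any()

    def test_bit_reproducible(self, default_structure):
        a = search_design(default_structure, 2, 50, seed=3)
        b = search_design(default_structure, 2, 50, seed=3)
        assert np.array_equal(a.best_matrix.entries, b.best_matrix.entries)
        assert a.best_sin == b.best_sin

    def test_trace_monotone(self, optimized_design):
        assert (np.diff(optimized_design.trace) >= 0).all()

    def test_best_sin_recomputes(self, optimized_design):
        M = optimized_design.best_matrix.entries
        assert sin(M, 2) == pytest.approx(optimized_design.best_sin)

    def test_early_rejection_equivalent(self, default_structure):
        a = search_design(default_structure, 2, 60, seed=9, early_reject=True)
        b = search_design(default_structure, 2, 60, seed=9, early_reject=False)
        assert a.best_sin == pytest.approx(b.best_sin)


class TestBlockDiagonal:
    def test_assembled_shape(self, optimized_design):
        bd = replicate_group(optimized_design.best_matrix, 4)
        assert bd.entries.shape == (48, 64)

    def test_single_group_identity_packaging(self, optimized_design):
        bd = assemble_block_diagonal([optimized_design.best_matrix])
        assert np.array_equal(bd.entries, optimized_design.best_matrix.entries)

    def test_nonzero_count_adds(self, optimized_design):
        gm = optimized_design.best_matrix
        bd = replicate_group(gm, 4)
        assert bd.entries.sum() == 4 * gm.entries.sum()

    def test_off_diagonal_blocks_zero(self, optimized_design):
        bd = replicate_group(optimized_design.best_matrix, 2)
        E = bd.entries
        assert not E[:12, 16:].any() and not E[12:, :16].any()

    def test_inconsistent_shapes_rejected(self, optimized_design):
        other = make_cs_matrix(np.zeros((2, 4), dtype=int), CSStructure(m0=2))
        with pytest.raises(ValueError, match="shapes"):
            assemble_block_diagonal([optimized_design.best_matrix, other])


class TestCompressionSweep:
    def test_flags_and_compression(self):
        st2 = CSStructure(m0=12)
        table = compression_sweep(st2, [12, 14, 16], s=2, n_iter=60, seed=0)
        assert (table["compression"] == [16 / 12, 16 / 14, 1.0]).all()
        flagged = table[table["flagged"]]
        assert len(flagged) >= 1
        assert 16 / flagged["m0"].min() >= 1.0

    def test_permutation_selection_reaches_sin_one(self):
        # m0 = n0 with one distinct sensor per row -> a permutation matrix,
        # whose every submatrix is orthonormal
        st2 = CSStructure(m0=16)
        sel = np.zeros((16, 4), dtype=int)
        for i in range(16):
            sel[i, i // 4] = i % 4 + 1
        gm = make_cs_matrix(sel, st2)
        assert sin(gm.entries, 2) == pytest.approx(1.0)

    def test_m0_out_of_range(self):
        with pytest.raises(ValueError):
            compression_sweep(CSStructure(m0=1), [0], 2, 5)
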