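import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from mixnet.core_data import OccurrenceMatrix
from mixnet.margin_randomizer import (
    MarginChainState,
    bc_pvalue,
    checkerboard_step,
    enumerate_margin_class,
    sample_tilted_matrix,
)


def om(cells, habitats=None):
    cells = np.asarray(cells, dtype=np.uint8)
    rows = [f"r{i}" for i in range(cells.shape[0])]
    cols = [f"s{j}" for j in range(cells.shape[1])]
    hab = dict(zip(rows, habitats)) if habitats else {}
    return OccurrenceMatrix(cells, rows, cols, hab)


class TestCheckerboardStep:
    def test_forced_swap_on_2x2_checkerboard(self, rng):
        state = MarginChainState(om([[1, 0], [0, 1]]))
        checkerboard_step(state, rng)
        assert state.matrix.cells.tolist() in ([[0, 1], [1, 0]], [[1, 0], [0, 1]])
        # the only reachable other state must be hit quickly
        for _ in range(20):
            checkerboard_step(state, rng)
        assert state.step_count == 21

    def test_all_ones_matrix_never_changes(self, rng):
        state = MarginChainState(om(np.ones((3, 3))))
        state.advance(5000, rng)
        assert (state.matrix.cells == 1).all()

    @given(st.integers(0, 2**31 - 1))
    def test_margins_conserved_exactly(self, seed):
        rng = np.random.default_rng(seed)
        cells = (rng.random((8, 5)) < 0.4).astype(np.uint8)
        m = om(cells)
        r0, c0 = m.row_sums.copy(), m.col_sums.copy()
        state = MarginChainState(m)
        state.advance(2000, rng)
        assert (state.matrix.row_sums == r0).all()
        assert (state.matrix.col_sums == c0).all()

    def test_stratified_chain_conserves_per_stratum_margins(self, rng):
        cells = (rng.random((10, 4)) < 0.5).astype(np.uint8)
        habitats = ["grassland"] * 5 + ["woodland"] * 5
        m = om(cells, habitats)
        per_stratum_before = [cells[:5].sum(axis=0).copy(), cells[5:].sum(axis=0).copy()]
        state = MarginChainState(m, stratum_of_row={r: h for r, h in zip(m.row_labels, habitats)})
        state.advance(20000, rng)
        after = state.matrix.cells
        assert (after[:5].sum(axis=0) == per_stratum_before[0]).all()
        assert (after[5:].sum(axis=0) == per_stratum_before[1]).all()


class TestChainUniformity:
    def test_long_run_frequencies_uniform_on_enumerable_class(self, rng):
        """3x3 permutation matrices: the chain must visit all 6 states uniformly."""
        mats = enumerate_margin_class([1, 1, 1], [1, 1, 1])
        assert len(mats) == 6
        index = {m.tobytes(): i for i, m in enumerate(mats)}
        state = MarginChainState(om(mats[0]))
        counts = np.zeros(6)
        n_samples = 50_000
        for _ in range(n_samples):
            state.advance(20, rng)
            counts[index[state.matrix.cells.tobytes()]] += 1
        res = stats.chisquare(counts)
        assert res.pvalue > 0.001

    def test_tilted_chain_matches_exact_tilted_law(self, rng):
        """Metropolis tilt: state frequencies follow prod(phi^w) exactly."""
        mats = enumerate_margin_class([2, 1, 1], [2, 1, 1])
        phi = np.ones((3, 3))
        phi[0, 1] = phi[1, 0] = 8.0
        logphi = np.log(phi)

        def weight(m):
            x = m.astype(int)
            w = x.T @ x
            np.fill_diagonal(w, 0)
            return float(np.prod(phi ** np.triu(w, 1)))

        weights = np.array([weight(m) for m in mats])
        expected = weights / weights.sum()
        cells = np.ascontiguousarray(mats[0].copy())
        counts = {m.tobytes(): 0 for m in mats}
        n_samples = 30_000
        for _ in range(n_samples):
            sample_tilted_matrix(cells, logphi, 30, rng)
            counts[cells.tobytes()] += 1
        emp = np.array([counts[m.tobytes()] for m in mats]) / n_samples
        res = stats.chisquare(emp * n_samples, expected * n_samples)
        assert res.pvalue > 0.001


class TestEnumeration:
    @pytest.mark.parametrize(
        "rows, cols, expected",
        [
            ([1, 1, 1], [1, 1, 1], 6),  # permutation matrices
            ([1, 1], [2], 1),
            ([2, 2], [2, 2], 1),
            ([1, 1], [1, 1], 2),
        ],
    )
    def test_class_sizes(self, rows, cols, expected):
        assert len(enumerate_margin_class(rows, cols)) == expected

    def test_all_members_have_requested_margins(self):
        for m in enumerate_margin_class([2, 2, 1, 1, 1], [3, 2, 1, 1]):
            assert m.sum(axis=1).tolist() == [2, 2, 1, 1, 1]
            assert m.sum(axis=0).tolist() == [3, 2, 1, 1]


class TestBCPvalue:
    def test_constant_statistic_gives_p_one_both_tails(self):
        m = om([[1, 0], [0, 1], [1, 1]])
        res = bc_pvalue(m, lambda mat: 7.0, m=50, seed=0)
        assert res.p_upper == 1.0 and res.p_lower == 1.0

    def test_m_equal_one_formula(self):
        # a statistic maximal at the observed matrix: the single sample
        # cannot exceed it, so the lower tail must be (1+1)/2 = 1
        m = om([[1, 0], [0, 1]])
        res = bc_pvalue(m, lambda mat: float(mat.cells[0, 0]), m=1, seed=3)
        assert res.p_upper in (0.5, 1.0)
        assert res.p_lower in (0.5, 1.0)
        assert res.p_upper + res.p_lower >= 1.5  # ties count in both tails

    def test_p_bounded_away_from_zero(self):
        m = om([[1, 0], [0, 1], [1, 1], [0, 1]])
        res = bc_pvalue(m, lambda mat: float(mat.cells.sum()), m=9, seed=0)
        assert 1 / 10 <= res.p_upper <= 1.0
        assert 1 / 10 <= res.p_lower <= 1.0

    def test_statistic_error_propagates_with_context(self):
        m = om([[1, 0], [0, 1]])

        def bad(mat):
            raise KeyError("boom")

        with pytest.raises(RuntimeError, match="statistic failed"):
            bc_pvalue(m, bad, m=5, seed=0)

    def test_reproducible_given_seed(self):
        rng = np.random.default_rng(0)
        cells = (rng.random((12, 6)) < 0.35).astype(np.uint8)
        m = om(cells)
        stat = lambda mat: float((mat.cells[:, 0] & mat.cells[:, 1]).sum())
        r1 = bc_pvalue(m, stat, m=200, seed=42)
        r2 = bc_pvalue(m, stat, m=200, seed=42)
        assert r1 == r2

    def test_dyad_null_support_bounds(self, rng):
        """Sampled dyad statistics stay within the fixed-margin support."""
        cells = (rng.random((15, 5)) < 0.4).astype(np.uint8)
        m = om(cells)
        k = m.col_sums
        n = m.n_clusters
        lo = max(0, int(k[0] + k[1]) - n)
        hi = min(int(k[0]), int(k[1]))
        seen = []
        stat = lambda mat: float((mat.cells[:, 0] & mat.cells[:, 1]).sum())
        res = bc_pvalue(m, lambda mat: seen.append(stat(mat)) or stat(mat), m=300, seed=7)
        assert all(lo <= s <= hi for s in seen)
        assert lo <= res.observed_stat <= hi
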