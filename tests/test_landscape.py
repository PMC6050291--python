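import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from switchkin.landscape import (
    PotentialLandscape,
    ProductionHistogram2D,
    direct_barriers,
    find_basins_and_saddles,
    histogram2d,
    interpolate,
    local_minima,
    merge_levels,
    minimax_level,
    potential,
)
from switchkin.traces import LineageTrace


def trace_from_counts(counts):
    counts = np.asarray(counts)
    n = len(counts)
    return LineageTrace(
        lineage_id="t", frame_interval=5.0,
        time_min=np.arange(n) * 5.0,
        cro=counts[:, 0], ci=counts[:, 1],
        cell_age=np.full(n, 0.5), division_flag=np.zeros(n, dtype=bool),
    )


# ---------------------------------------------------------------------------
# independent oracles for minimax barriers
# ---------------------------------------------------------------------------

def minimax_by_threshold_connectivity(U, src, dst):
    """Oracle: smallest level L such that src and dst are connected in the
    subgraph of nodes with U <= L (exhaustive sweep over levels)."""
    n0, n1 = U.shape
    for L in np.unique(U):
        if U[src] > L or U[dst] > L:
            continue
        # flood fill
        seen = {src}
        stack = [src]
        while stack:
            i, j = stack.pop()
            for di, dj in itertools.product((-1, 0, 1), repeat=2):
                if di == dj == 0:
                    continue
                a, b = i + di, j + dj
                if 0 <= a < n0 and 0 <= b < n1 and (a, b) not in seen and U[a, b] <= L:
                    seen.add((a, b))
                    stack.append((a, b))
        if dst in seen:
            return float(L)
    return float("inf")


def minimax_by_path_enumeration(U, src, dst):
    """Oracle: exhaustive DFS over all simple paths (tiny grids only)."""
    n0, n1 = U.shape
    best = [float("inf")]

    def dfs(node, visited, level):
        level = max(level, U[node])
        if level >= best[0]:
            return
        if node == dst:
            best[0] = level
            return
        i, j = node
        for di, dj in itertools.product((-1, 0, 1), repeat=2):
            if di == dj == 0:
                continue
            a, b = i + di, j + dj
            if 0 <= a < n0 and 0 <= b < n1 and (a, b) not in visited:
                dfs((a, b), visited | {(a, b)}, level)

    dfs(src, {src}, U[src])
    return best[0]


class TestHistogram2D:
    def test_single_frame(self):
        h = histogram2d([trace_from_counts([(0, 0)])])
        assert h.probabilities[0, 0] == 1.0
        assert h.probabilities.sum() == 1.0

    def test_uniform_3x3(self):
        counts = [(i, j) for i in range(3) for j in range(3)]
        h = histogram2d([trace_from_counts(counts)])
        np.testing.assert_allclose(h.probabilities, np.full((3, 3), 1 / 9))

    def test_overflow_pooled(self):
        h = histogram2d([trace_from_counts([(0, 0), (9, 9)])], max_count=3)
        assert h.probabilities[3, 3] == 0.5

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            histogram2d([])

    def test_permutation_invariant_and_normalized(self, default_dataset):
        h1 = histogram2d(default_dataset)
        h2 = histogram2d(default_dataset[::-1])
        np.testing.assert_array_equal(h1.probabilities, h2.probabilities)
        assert h1.probabilities.sum() == pytest.approx(1.0, abs=1e-12)

    def test_table_model_mass_near_four_modes(self, default_dataset):
        h = histogram2d(default_dataset)
        P = h.probabilities
        # mass within +-1 bin of the four generator modes (oracle = the
        # generator's emission means (0,0), (5,0), (0,5), (4-5,4-5))
        for (c, i) in [(0, 0), (5, 0), (0, 5), (4, 4)]:
            m = P[max(c - 1, 0) : c + 2, max(i - 1, 0) : i + 2].sum()
            assert m > 0.03, ((c, i), m)


class TestPotential:
    def test_single_bin(self):
        h = ProductionHistogram2D(np.array([[1.0]]), n_frames=10, max_count=0)
        land = potential(h, pseudocount=0)
        assert land.potential[0, 0] == 0.0

    def test_log_identity(self):
        c = 1.0 / (1 + np.exp(-1.0))
        h = ProductionHistogram2D(
            np.array([[np.exp(-1) * c, c]]), n_frames=10, max_count=1
        )
        land = potential(h, pseudocount=0)
        assert land.potential[0, 0] - land.potential[0, 1] == pytest.approx(1.0)

    def test_uniform_constant(self):
        h = ProductionHistogram2D(np.full((4, 4), 1 / 16), n_frames=16, max_count=3)
        land = potential(h, pseudocount=0)
        assert land.potential.max() - land.potential.min() < 1e-12

    def test_zero_pseudocount_with_empty_bins_rejected(self):
        h = ProductionHistogram2D(
            np.array([[0.5, 0.5], [0.0, 0.0]]), n_frames=2, max_count=1
        )
        with pytest.raises(ValueError):
            potential(h, pseudocount=0)

    def test_monotone_in_probability(self, default_dataset):
        h = histogram2d(default_dataset)
        land = potential(h)
        P, U = h.probabilities.ravel(), land.potential.ravel()
        order = np.argsort(P)
        assert np.all(np.diff(U[order]) <= 1e-12)


class TestInterpolate:
    def _landscape(self, U):
        return PotentialLandscape(
            potential=np.asarray(U, float),
            probabilities=np.asarray(U, float) * 0,
            pseudocount=0.5, n_frames=0,
        )

    def test_factor_one_identity(self):
        land = self._landscape(np.random.default_rng(0).random((5, 5)))
        assert interpolate(land, 1) is land

    def test_constant_surface(self):
        land = self._landscape(np.full((4, 6), 2.5))
        out = interpolate(land, 3)
        np.testing.assert_allclose(out.potential, 2.5, atol=1e-9)

    def test_nodes_preserved(self):
        rng = np.random.default_rng(3)
        land = self._landscape(rng.random((7, 9)))
        out = interpolate(land, 4)
        np.testing.assert_allclose(
            out.potential[::4, ::4], land.potential, atol=1e-9
        )

    def test_invalid_factor(self):
        land = self._landscape(np.zeros((3, 3)))
        with pytest.raises(ValueError):
            interpolate(land, 0)


class TestBasinsAndBarriers:
    def _landscape(self, U):
        return PotentialLandscape(
            potential=np.asarray(U, float),
            probabilities=np.zeros_like(np.asarray(U, float)),
            pseudocount=0.5, n_frames=0,
        )

    def test_single_well(self):
        x = np.linspace(-1, 1, 9)
        U = x[:, None] ** 2 + x[None, :] ** 2
        basins, saddles, barriers = find_basins_and_saddles(self._landscape(U))
        assert len(basins) == 1
        assert barriers.size == 0

    def test_flat_landscape_zero_basins(self):
        basins, saddles, barriers = find_basins_and_saddles(
            self._landscape(np.ones((6, 6)))
        )
        assert basins == [] and barriers is None

    def test_hand_built_two_wells(self):
        # wells of depth 0 (at [1,1]) and 1 (at [3,3]) split by a ridge of 3
        U = np.array(
            [
                [2, 2, 3, 2, 2],
                [2, 0, 3, 2, 2],
                [3, 3, 3, 3, 3],
                [2, 2, 3, 1, 2],
                [2, 2, 3, 2, 2],
            ],
            dtype=float,
        )
        land = self._landscape(U)
        basins, saddles, barriers = find_basins_and_saddles(land, min_depth=0.5)
        assert len(basins) == 2
        depths = sorted(b.depth for b in basins)
        assert depths == [0.0, 1.0]
        # oracle: exhaustive enumeration of all simple paths
        oracle = minimax_by_path_enumeration(U, (1, 1), (3, 3))
        assert oracle == 3.0
        i_deep = [i for i, b in enumerate(basins) if b.depth == 0.0][0]
        i_shallow = 1 - i_deep
        assert barriers[i_deep, i_shallow] == pytest.approx(3.0)
        assert barriers[i_shallow, i_deep] == pytest.approx(2.0)

    def test_barrier_matrix_symmetry_offset(self, default_dataset):
        from switchkin.landscape import histogram2d as h2d

        land = potential(h2d(default_dataset))
        ref = interpolate(land, 2)
        basins, _, barriers = find_basins_and_saddles(ref)
        U = [b.depth for b in basins]
        for i in range(len(basins)):
            for j in range(len(basins)):
                if i != j:
                    assert barriers[i, j] + U[i] == pytest.approx(
                        barriers[j, i] + U[j], abs=1e-9
                    )

    @given(
        arrays(
            np.float64, (5, 6),
            elements=st.floats(0.0, 10.0, allow_nan=False),
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_minimax_matches_threshold_connectivity_oracle(self, U):
        src, dst = (0, 0), (4, 5)
        assert minimax_level(U, src, dst) == pytest.approx(
            minimax_by_threshold_connectivity(U, src, dst)
        )

    @given(
        arrays(
            np.float64, (3, 3),
            elements=st.floats(0.0, 5.0, allow_nan=False),
        )
    )
    @settings(max_examples=25, deadline=None)
    def test_minimax_matches_full_path_enumeration(self, U):
        src, dst = (0, 0), (2, 2)
        assert minimax_level(U, src, dst) == pytest.approx(
            minimax_by_path_enumeration(U, src, dst)
        )

    def test_merge_levels_match_dijkstra(self):
        rng = np.random.default_rng(5)
        U = rng.random((8, 8)) * 4
        minima = local_minima(U)
        if len(minima) < 2:
            return
        levels = merge_levels(U, minima)
        for a in minima:
            for b in minima:
                if a != b:
                    assert levels[(a, b)] == pytest.approx(
                        minimax_level(U, a, b)
                    )

    def test_table_model_landscape_four_basins(self, default_dataset):
        land = potential(histogram2d(default_dataset))
        ref = interpolate(land, 4)
        basins, saddles, barriers = find_basins_and_saddles(ref)
        assert len(basins) == 4
        locs = np.array([b.location for b in basins])
        targets = np.array([(0, 0), (5, 0), (0, 5), (4.5, 4.5)])
        for t in targets:
            assert np.min(np.linalg.norm(locs - t, axis=1)) <= 2.0, (t, locs)


class TestDirectBarriers:
    def test_direct_ordering_on_table_model(self, default_dataset):
        land = potential(histogram2d(default_dataset))
        ref = interpolate(land, 4)
        basins, _, _ = find_basins_and_saddles(ref)
        assert len(basins) == 4

        def near(t):
            return min(
                range(4),
                key=lambda i: np.hypot(
                    basins[i].location[0] - t[0], basins[i].location[1] - t[1]
                ),
            )

        iLL, iHL, iLH, iHH = (
            near((0, 0)), near((5, 0)), near((0, 5)), near((4.5, 4.5))
        )
        B = direct_barriers(ref, basins)
        lvl = lambda i, j: B[i, j] + basins[i].depth
        diag = [lvl(iLL, iHH), lvl(iHL, iLH)]
        adjacent_ll = [lvl(iLL, iLH), lvl(iLL, iHL)]
        assert min(diag) > max(adjacent_ll)
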