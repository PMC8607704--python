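import math

import numpy as np
import pandas as pd
import pytest

from popproxy import (
    ConductanceRaster,
    HaplotypeSet,
    euclidean_trait_distance,
    great_circle_distance,
    habitat_divergence,
    phi_st,
    resistance_distance,
    vincenty,
)
from popproxy.datasets import load_lake_coordinates
from popproxy.distances import bray_curtis, hamming, pca_scores

from conftest import random_distance_matrix


class TestEuclideanTrait:
    def test_scalar_differences(self):
        s = pd.Series([1.0, 4.0], index=["a", "b"])
        m = euclidean_trait_distance(s)
        assert m.values[0, 1] == 3.0

    def test_matches_brute_force(self, rng):
        x = rng.normal(size=9)
        s = pd.Series(x, index=[f"r{i}" for i in range(9)])
        m = euclidean_trait_distance(s)
        for i in range(9):
            for j in range(9):
                assert m.values[i, j] == pytest.approx(abs(x[i] - x[j]))

    def test_missing_replicate_rejected(self):
        s = pd.Series([1.0, np.nan], index=["a", "b"])
        with pytest.raises(ValueError, match="b"):
            euclidean_trait_distance(s)


class TestHabitatDivergence:
    def test_identical_sites_zero_distance(self, rng):
        env = pd.DataFrame(rng.normal(size=(4, 6)), index=list("ABCD"))
        env.loc["B"] = env.loc["A"]
        m = habitat_divergence(env)
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_kaiser_guttman_mean_eigenvalue_rule(self):
        # eigenvalues {3.0, 0.6, 0.4}: mean 4/3, one axis retained
        eigval = np.array([3.0, 0.6, 0.4])
        assert int(np.sum(eigval > eigval.mean())) == 1

    def test_scores_match_independent_eigendecomposition(self, rng):
        env = pd.DataFrame(rng.normal(size=(7, 26)),
                           index=[f"S{i}" for i in range(7)])
        scores, eigval, n_keep = pca_scores(env)
        # independent oracle: SVD of the z-scored matrix
        z = (env - env.mean()) / env.std(ddof=1)
        u, s, vt = np.linalg.svd(z.to_numpy(), full_matrices=False)
        eig_oracle = s**2 / (len(env) - 1)
        np.testing.assert_allclose(
            sorted(eigval[eigval > 1e-9], reverse=True), eig_oracle[eig_oracle > 1e-9],
            rtol=1e-8,
        )
        # retained count: eigenvalue above the mean over all 26 variables
        mean_eig = eig_oracle.sum() / 26
        assert n_keep == int(np.sum(eig_oracle > mean_eig))
        # scores identical up to per-axis sign
        oracle_scores = z.to_numpy() @ vt.T
        for ax in range(n_keep):
            assert (
                np.allclose(scores[:, ax], oracle_scores[:, ax], atol=1e-8)
                or np.allclose(scores[:, ax], -oracle_scores[:, ax], atol=1e-8)
            )

    def test_constant_variable_dropped(self, rng, caplog):
        env = pd.DataFrame(rng.normal(size=(5, 4)), index=list("ABCDE"))
        env["const"] = 1.0
        with caplog.at_level("WARNING"):
            habitat_divergence(env)
        assert "constant" in caplog.text

    def test_shifted_mode_keeps_bray_curtis_in_unit_interval(self, rng):
        env = pd.DataFrame(rng.normal(size=(6, 10)), index=list("ABCDEF"))
        m = habitat_divergence(env, mode="shifted")
        assert m.condensed().max() <= 1.0 + 1e-12

    def test_replicate_map_gives_zero_within_site(self, rng):
        env = pd.DataFrame(rng.normal(size=(3, 5)), index=["X", "Y", "Z"])
        rep_map = {f"{s}::T{t}": s for s in "XYZ" for t in (1, 2)}
        m = habitat_divergence(env, replicate_map=rep_map)
        assert m.level == "replicate"
        assert m.values[0, 1] == 0.0

    def test_bray_curtis_formula(self):
        assert bray_curtis(np.array([1.0, 2.0]), np.array([3.0, 2.0])) == pytest.approx(2 / 8)
        assert bray_curtis(np.zeros(2), np.zeros(2)) == 0.0


class TestVincenty:
    # oracle distances frozen from an independent geodesic implementation
    FROZEN = [
        ((0.0, 0.0, 0.0, 1.0), 111319.490792),   # equatorial degree
        ((0.0, 0.0, 1.0, 0.0), 110574.388557),   # meridian degree
    ]

    @pytest.mark.parametrize("args, expected", FROZEN)
    def test_frozen_geodesic_values(self, args, expected):
        assert vincenty(*args) == pytest.approx(expected, abs=1e-3)

    def test_same_point_zero(self):
        assert vincenty(50.0, 10.0, 50.0, 10.0) == 0.0

    def test_lake_pairs_match_independent_oracle(self):
        coords = load_lake_coordinates()
        m = great_circle_distance(coords)
        frozen_km = {
            ("VAL", "ISO"): 66.170168114,
            ("VAL", "BAL"): 1656.657574308,
            ("GEN", "BOU"): 83.643284322,
        }
        idx = {p: i for i, p in enumerate(m.labels)}
        for (a, b), km in frozen_km.items():
            assert m.values[idx[a], idx[b]] == pytest.approx(km, abs=1e-6)

    def test_triangle_inequality_over_study_lakes(self):
        m = great_circle_distance(load_lake_coordinates()).values
        n = len(m)
        for i in range(n):
            for j in range(n):
                for k in range(n):
                    assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            vincenty(91.0, 0.0, 0.0, 0.0)


def _resistance_oracle_solve(grid, cells):
    """Independent oracle: current injection via a grounded linear solve."""
    nrows, ncols = grid.shape
    valid = np.isfinite(grid)
    index = -np.ones(grid.shape, int)
    index[valid] = np.arange(valid.sum())
    n = int(valid.sum())
    lap = np.zeros((n, n))
    for r in range(nrows):
        for c in range(ncols):
            if not valid[r, c]:
                continue
            for dr, dc in ((0, 1), (1, 0)):
                rr, cc = r + dr, c + dc
                if rr < nrows and cc < ncols and valid[rr, cc]:
                    g = 0.5 * (grid[r, c] + grid[rr, cc])
                    i, j = index[r, c], index[rr, cc]
                    lap[i, i] += g
                    lap[j, j] += g
                    lap[i, j] -= g
                    lap[j, i] -= g
    out = {}
    nodes = {label: index[rc] for label, rc in cells.items()}
    labels = list(nodes)
    for a in range(len(labels)):
        for b in range(a):
            i, j = nodes[labels[a]], nodes[labels[b]]
            keep = [x for x in range(n) if x != j]  # ground node j
            rhs = np.zeros(n)
            rhs[i] = 1.0
            v = np.zeros(n)
            v[keep] = np.linalg.solve(lap[np.ix_(keep, keep)], rhs[keep])
            out[(labels[a], labels[b])] = v[i] - v[j]
    return out


class TestResistance:
    def test_series_chain_of_unit_resistors(self):
        raster = ConductanceRaster(np.ones((1, 3)), {"a": (0, 0), "b": (0, 2)})
        m = resistance_distance(raster)
        assert m.values[0, 1] == pytest.approx(2.0, abs=1e-10)

    def test_square_grid_diagonal(self):
        raster = ConductanceRaster(np.ones((2, 2)), {"a": (0, 0), "b": (1, 1)})
        m = resistance_distance(raster)
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_random_raster_matches_linear_solve_oracle(self, rng):
        grid = rng.uniform(0.5, 10.0, size=(8, 8))
        cells = {"a": (0, 0), "b": (7, 7), "c": (3, 5), "d": (6, 1)}
        m = resistance_distance(ConductanceRaster(grid, cells))
        oracle = _resistance_oracle_solve(grid, cells)
        idx = {p: i for i, p in enumerate(m.labels)}
        for (a, b), r in oracle.items():
            assert m.values[idx[a], idx[b]] == pytest.approx(r, abs=1e-8)

    def test_triangle_inequality_on_random_rasters(self, rng):
        for _ in range(3):
            grid = rng.uniform(0.5, 5.0, size=(6, 6))
            cells = {f"s{i}": (int(rng.integers(6)), i) for i in range(5)}
            m = resistance_distance(ConductanceRaster(grid, cells)).values
            n = len(m)
            for i in range(n):
                for j in range(n):
                    for k in range(n):
                        assert m[i, j] <= m[i, k] + m[k, j] + 1e-9

    def test_disconnected_sites_named_in_error(self):
        grid = np.ones((3, 3))
        grid[:, 1] = np.nan  # NODATA wall
        raster = ConductanceRaster(grid, {"west": (0, 0), "east": (0, 2)})
        with pytest.raises(ValueError, match="west"):
            resistance_distance(raster)

    def test_site_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            ConductanceRaster(np.ones((3, 3)), {"a": (5, 0)})

    def test_shared_cell_rejected(self):
        with pytest.raises(ValueError, match="share"):
            ConductanceRaster(np.ones((3, 3)), {"a": (0, 0), "b": (0, 0)})


def _phi_st_oracle(seqs_a, seqs_b):
    """Brute-force two-level AMOVA with explicit double loops."""
    seqs = seqs_a + seqs_b
    na, nb = len(seqs_a), len(seqs_b)
    n = na + nb

    def d2(x, y):
        return sum(p != q for p, q in zip(x, y))

    ssd_tot = sum(d2(seqs[i], seqs[j]) for i in range(n) for j in range(i)) / n
    ssd_a = sum(d2(seqs_a[i], seqs_a[j]) for i in range(na) for j in range(i)) / na
    ssd_b = sum(d2(seqs_b[i], seqs_b[j]) for i in range(nb) for j in range(i)) / nb
    ssd_within = ssd_a + ssd_b
    ssd_among = ssd_tot - ssd_within
    sigma_w = ssd_within / (n - 2)
    n0 = n - (na**2 + nb**2) / n
    sigma_a = (ssd_among - sigma_w) / n0
    if sigma_a + sigma_w == 0:
        return 0.0
    return sigma_a / (sigma_a + sigma_w)


class TestPhiSt:
    def test_identical_pools_give_zero(self):
        pool = ["ACGT", "ACGA", "ACGT"]
        m = phi_st([HaplotypeSet("A", pool), HaplotypeSet("B", list(pool))])
        assert m.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_fixed_differences_give_one(self):
        a = HaplotypeSet("A", ["AAAAAAAAAA"] * 5)
        b = HaplotypeSet("B", ["CCCCCCCCCC"] * 5)
        m = phi_st([a, b])
        assert m.values[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_random_pools_match_brute_force_amova(self, rng):
        from popproxy.distances import pairwise_phi_st

        bases = np.array(list("ACGT"))
        for _ in range(10):
            seqs_a = ["".join(rng.choice(bases, size=20)) for _ in range(5)]
            seqs_b = ["".join(rng.choice(bases, size=20)) for _ in range(5)]
            raw = pairwise_phi_st(HaplotypeSet("A", seqs_a), HaplotypeSet("B", seqs_b))
            oracle = _phi_st_oracle(seqs_a, seqs_b)
            assert raw == pytest.approx(oracle, abs=1e-10)
            m = phi_st([HaplotypeSet("A", seqs_a), HaplotypeSet("B", seqs_b)])
            assert m.values[0, 1] == pytest.approx(max(oracle, 0.0), abs=1e-10)

    def test_hamming_counts_positions(self):
        assert hamming("ACGT", "ACCA") == 2
        with pytest.raises(ValueError):
            hamming("AC", "A")

    def test_ragged_alignment_rejected(self):
        with pytest.raises(ValueError, match="ragged"):
            HaplotypeSet("A", ["ACG", "AC"])
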