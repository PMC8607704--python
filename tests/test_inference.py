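import numpy as np
import pytest
from scipy import stats

from popproxy import (
    DistanceMatrix,
    bh_adjust,
    commonality,
    detect_suppressors,
    mantel,
    mrdm,
    mrdm_ca_loop,
    unfold,
)
from popproxy.inference import CLASSICAL, CROSS_OVER, MRDMResult, _r_squared

from conftest import random_distance_matrix


def _dm_from_condensed(vec, n, labels=None):
    m = np.zeros((n, n))
    idx = 0
    for i in range(n):
        for j in range(i):
            m[i, j] = m[j, i] = vec[idx]
            idx += 1
    return DistanceMatrix(labels or [f"U{i}" for i in range(n)], m)


class TestUnfold:
    def test_vector_lengths(self, rng):
        a = random_distance_matrix(rng, 3)
        u = unfold(a, {"p": random_distance_matrix(rng, 3, labels=a.labels)})
        assert len(u.response) == 3
        b = random_distance_matrix(rng, 21)
        u21 = unfold(b, {"p": random_distance_matrix(rng, 21, labels=b.labels)})
        assert len(u21.response) == 210

    def test_order_matches_brute_force_loop(self, rng):
        a = random_distance_matrix(rng, 6)
        u = unfold(a, {"p": random_distance_matrix(rng, 6, labels=a.labels)})
        brute = []
        for i in range(6):
            for j in range(i):
                brute.append(a.values[i, j])
        np.testing.assert_array_equal(u.response, brute)

    def test_predictors_standardised(self, rng):
        a = random_distance_matrix(rng, 8)
        u = unfold(a, {"p": random_distance_matrix(rng, 8, labels=a.labels)})
        assert u.predictors[:, 0].mean() == pytest.approx(0.0, abs=1e-12)
        assert u.predictors[:, 0].std() == pytest.approx(1.0)

    def test_label_mismatch_rejected(self, rng):
        a = random_distance_matrix(rng, 4, labels=list("ABCD"))
        b = random_distance_matrix(rng, 4, labels=list("ABCE"))
        with pytest.raises(ValueError):
            unfold(a, {"p": b})


class TestMrdm:
    def test_response_equal_to_predictor(self, rng):
        p1 = random_distance_matrix(rng, 8)
        p2 = random_distance_matrix(rng, 8, labels=p1.labels)
        u = unfold(p1, {"a": p1, "b": p2})
        res = mrdm(u, n_perm=99, seed=0)
        assert res.r_squared == pytest.approx(1.0)
        # response = a exactly: standardised weight of a is sd-scaled
        assert res.beta["a"] * p1.condensed().std() / p1.condensed().std() == pytest.approx(
            res.beta["a"]
        )
        assert abs(res.beta["b"]) < 1e-10
        assert res.p_r_squared == pytest.approx(1 / 100)

    def test_two_predictor_beta_matches_normal_equations(self, rng):
        y_m = random_distance_matrix(rng, 10)
        p1 = random_distance_matrix(rng, 10, labels=y_m.labels)
        p2 = random_distance_matrix(rng, 10, labels=y_m.labels)
        u = unfold(y_m, {"a": p1, "b": p2})
        res = mrdm(u, n_perm=0)
        # closed-form standardised two-variable solution
        y = (u.response - u.response.mean()) / u.response.std()
        x1, x2 = u.predictors[:, 0], u.predictors[:, 1]
        r12 = np.corrcoef(x1, x2)[0, 1]
        r1y, r2y = np.corrcoef(x1, y)[0, 1], np.corrcoef(x2, y)[0, 1]
        beta1 = (r1y - r12 * r2y) / (1 - r12**2)
        beta2 = (r2y - r12 * r1y) / (1 - r12**2)
        assert res.beta["a"] == pytest.approx(beta1)
        assert res.beta["b"] == pytest.approx(beta2)
        assert res.r["a"] == pytest.approx(r1y)

    def test_single_predictor_r2_equals_r_squared_of_r(self, rng):
        y_m = random_distance_matrix(rng, 9)
        p = random_distance_matrix(rng, 9, labels=y_m.labels)
        res = mrdm(unfold(y_m, {"p": p}), n_perm=0)
        assert res.r_squared == pytest.approx(res.r["p"] ** 2)
        assert mantel(y_m, p, n_perm=9, seed=0).r == pytest.approx(res.r["p"])

    def test_singular_design_names_collinear_pair(self, rng):
        p1 = random_distance_matrix(rng, 6)
        y_m = random_distance_matrix(rng, 6, labels=p1.labels)
        with pytest.raises(np.linalg.LinAlgError):
            mrdm(unfold(y_m, {"a": p1, "b": p1}), n_perm=0)

    def test_null_p_values_roughly_uniform(self, rng):
        # small calibration here; the full KS check lives in the acceptance suite
        pvals = []
        for s in range(60):
            y_m = random_distance_matrix(np.random.default_rng(1000 + s), 8)
            p = random_distance_matrix(np.random.default_rng(5000 + s), 8, labels=y_m.labels)
            pvals.append(mrdm(unfold(y_m, {"p": p}), n_perm=49, seed=s).p_r_squared)
        assert 0.2 < np.mean(pvals) < 0.8


class TestCommonality:
    def test_orthogonal_predictors(self):
        n = 16
        t = np.arange(n)
        x1 = np.where(t % 2 == 0, 1.0, -1.0)
        x2 = np.where((t // 2) % 2 == 0, 1.0, -1.0)
        y = 0.8 * x1 + 0.3 * x2
        from popproxy.inference import UnfoldedVectors

        u = UnfoldedVectors(y, np.column_stack([x1, x2]), ["a", "b"], 0)
        part = commonality(u)
        r1 = np.corrcoef(y, x1)[0, 1]
        r2 = np.corrcoef(y, x2)[0, 1]
        assert part.coefficients[("a", "b")] == pytest.approx(0.0, abs=1e-10)
        assert part.unique["a"] == pytest.approx(r1**2)
        assert part.unique["b"] == pytest.approx(r2**2)

    def test_sum_identity_on_random_instances(self, rng):
        for _ in range(50):
            y = rng.normal(size=40)
            x = rng.normal(size=(40, 3)) + 0.5 * y[:, None]
            from popproxy.inference import UnfoldedVectors

            u = UnfoldedVectors(y, x, ["a", "b", "c"], 0)
            part = commonality(u)
            assert sum(part.coefficients.values()) == pytest.approx(
                part.r_squared, abs=1e-10
            )

    def test_three_predictor_coefficients_match_textbook_formulas(self, rng):
        import statsmodels.api as sm

        y = rng.normal(size=60)
        x = rng.normal(size=(60, 3)) + 0.4 * y[:, None]
        from popproxy.inference import UnfoldedVectors

        u = UnfoldedVectors(y, x, ["1", "2", "3"], 0)
        part = commonality(u)

        def r2(*cols):
            xx = sm.add_constant(x[:, [int(c) - 1 for c in cols]])
            return sm.OLS(y, xx).fit().rsquared

        expected = {
            ("1",): r2(1, 2, 3) - r2(2, 3),
            ("2",): r2(1, 2, 3) - r2(1, 3),
            ("3",): r2(1, 2, 3) - r2(1, 2),
            ("1", "2"): r2(1, 3) + r2(2, 3) - r2(3) - r2(1, 2, 3),
            ("1", "3"): r2(1, 2) + r2(2, 3) - r2(2) - r2(1, 2, 3),
            ("2", "3"): r2(1, 2) + r2(1, 3) - r2(1) - r2(1, 2, 3),
            ("1", "2", "3"): (
                r2(1, 2, 3) + r2(1) + r2(2) + r2(3) - r2(1, 2) - r2(1, 3) - r2(2, 3)
            ),
        }
        for subset, value in expected.items():
            assert part.coefficients[subset] == pytest.approx(value, abs=1e-10)


class TestSuppressors:
    def _partition(self, unique, common):
        from popproxy.inference import CommonalityPartition

        names = list(unique)
        return CommonalityPartition({}, unique, common, 0.5)

    def test_classical_rule(self):
        m = MRDMResult(0.5, 0.01, {"a": 0.3}, {"a": 0.2})
        c = self._partition({"a": 0.01}, {"a": -0.05})
        assert detect_suppressors(m, c) == [("a", CLASSICAL)]

    def test_cross_over_rule(self):
        m = MRDMResult(0.5, 0.01, {"a": 0.3}, {"a": -0.2})
        c = self._partition({"a": 0.10}, {"a": 0.02})
        assert detect_suppressors(m, c) == [("a", CROSS_OVER)]

    def test_healthy_predictor_not_flagged(self):
        m = MRDMResult(0.5, 0.01, {"a": 0.3}, {"a": 0.25})
        c = self._partition({"a": 0.10}, {"a": 0.02})
        assert detect_suppressors(m, c) == []


class TestMrdmCaLoop:
    def test_clean_fit_has_single_round(self, rng):
        y_m = random_distance_matrix(rng, 10)
        # response built from p1 so p1 is genuinely informative
        p1 = y_m
        p2 = random_distance_matrix(rng, 10, labels=y_m.labels)
        rep = mrdm_ca_loop(y_m, {"a": p1, "b": p2}, n_perm=99, seed=1)
        if len(rep.trace.rounds) == 1:
            assert rep.trace.rounds[0].removed == []
        assert rep.mrdm.r_squared == pytest.approx(1.0)

    def test_engineered_cross_over_suppressor_removed(self, rng):
        # signal A; B = A + strong opposing component correlated with -y
        n = 15
        a = random_distance_matrix(rng, n)
        y_vals = a.values.copy()
        y_m = DistanceMatrix(a.labels, y_vals)
        noise = random_distance_matrix(rng, n, labels=a.labels)
        b_vals = 0.4 * a.values + 2.0 * (y_vals.max() - y_vals) * (noise.values > noise.condensed().mean())
        b_vals = (b_vals + b_vals.T) / 2
        np.fill_diagonal(b_vals, 0)
        b = DistanceMatrix(a.labels, b_vals)
        rep = mrdm_ca_loop(y_m, {"signal": a, "mixed": b}, n_perm=49, seed=2)
        assert "signal" in rep.predictors

    def test_terminates_within_p_rounds_on_random_inputs(self, rng):
        for trial in range(10):
            n = 9
            y_m = random_distance_matrix(rng, n)
            proxies = {
                f"p{i}": random_distance_matrix(rng, n, labels=y_m.labels)
                for i in range(4)
            }
            rep = mrdm_ca_loop(y_m, proxies, n_perm=19, seed=trial)
            assert len(rep.trace.rounds) <= 4
            if rep.predictors:
                assert rep.trace.rounds[-1].removed == []


class TestMantel:
    def test_identity_gives_r_one_min_p(self, rng):
        a = random_distance_matrix(rng, 8)
        res = mantel(a, a, n_perm=99, seed=0)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 100)

    def test_affine_invariance(self, rng):
        a = random_distance_matrix(rng, 8)
        b = DistanceMatrix(a.labels, 3.0 * a.values)
        assert mantel(a, b, n_perm=9, seed=0).r == pytest.approx(1.0)

    def test_r_matches_skbio(self, rng):
        from skbio import DistanceMatrix as SkbioDM
        from skbio.stats.distance import mantel as skbio_mantel

        a = random_distance_matrix(rng, 10)
        b = random_distance_matrix(rng, 10, labels=a.labels)
        ours = mantel(a, b, n_perm=99, seed=0)
        ref_r, ref_p, _ = skbio_mantel(
            SkbioDM(a.values, a.labels), SkbioDM(b.values, b.labels),
            method="pearson", permutations=999, alternative="greater",
        )
        assert ours.r == pytest.approx(float(ref_r))
        # both permutation p-values estimate the same quantity
        assert abs(ours.p - float(ref_p)) < 0.2

    def test_constant_matrix_rejected(self, rng):
        a = random_distance_matrix(rng, 5)
        flat = DistanceMatrix(a.labels, np.ones((5, 5)) - np.eye(5))
        with pytest.raises(ValueError, match="constant"):
            mantel(flat, a, n_perm=9, seed=0)


class TestBhAdjust:
    def test_textbook_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == [0.37]

    def test_matches_statsmodels_on_random_vectors(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(20):
            p = rng.uniform(size=12)
            ours = bh_adjust(list(p))
            ref = multipletests(p, method="fdr_bh")[1]
            np.testing.assert_allclose(ours, ref, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
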