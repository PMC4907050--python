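"""G matrix construction, GBLUP/RR-BLUP solvers and their exact equivalence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from croaker_gs.exceptions import (
    ConfigurationError,
    MarkerAlignmentError,
    MonomorphicMarkerError,
)
from croaker_gs.gblup import (
    build_g_matrix,
    cross_kernel,
    predict_gebv,
    predict_gebv_kernel,
    solve_gblup,
    solve_rrblup,
)
from croaker_gs.genotype_data import standardize

from conftest import random_training_fixture


class TestBuildGMatrix:
    def test_hand_computed_two_by_two(self):
        """codes [(0,2),(2,0)] at p=(0.5,0.5): denominator 1, G = [[2,-2],[-2,2]]."""
        G = build_g_matrix(np.array([[0.0, 2.0], [2.0, 0.0]]), np.array([0.5, 0.5]))
        assert G.denominator == pytest.approx(1.0)
        np.testing.assert_allclose(G.G, [[2, -2], [-2, 2]])

    def test_single_individual(self):
        G = build_g_matrix(np.array([[0.0, 2.0]]), np.array([0.4, 0.6]))
        assert G.G.shape == (1, 1)

    def test_duplicated_rows_share_diagonal(self, rng):
        codes = rng.binomial(2, 0.4, size=(5, 30)).astype(float)
        codes[4] = codes[0]
        f = codes.mean(axis=0) / 2
        keep = (f > 0) & (f < 1)
        G = build_g_matrix(codes[:, keep], f[keep]).G
        assert G[0, 4] == pytest.approx(G[0, 0])

    def test_monomorphic_rejected(self):
        with pytest.raises(MonomorphicMarkerError):
            build_g_matrix(np.zeros((3, 2)), np.array([0.0, 0.5]))


def _brute_force_mme(y, sex, G, h2):
    """Dense mixed-model-equation solve by direct inversion of G."""
    n = len(y)
    lam = (1 - h2) / h2
    W = np.column_stack([np.ones(n), (np.asarray(sex) == 2).astype(float)])
    Ginv = np.linalg.inv(G)
    top = np.hstack([W.T @ W, W.T])
    bottom = np.hstack([W, np.eye(n) + Ginv * lam])
    lhs = np.vstack([top, bottom])
    rhs = np.concatenate([W.T @ y, y])
    sol = np.linalg.solve(lhs, rhs)
    return sol[:2], sol[2:]


class TestSolveGblup:
    def test_matches_dense_mme_oracle(self, rng):
        # External frequencies keep G full rank (cohort-own frequencies center
        # the columns exactly, making G singular and the dense oracle moot).
        n, p = 6, 12
        f = rng.uniform(0.2, 0.5, size=p)
        codes = rng.binomial(2, f, size=(n, p)).astype(float)
        sex = np.tile([1, 2], n // 2)
        y = rng.normal(size=n) + 0.3 * (sex == 2)
        G = build_g_matrix(codes, f)
        fit = solve_gblup(y, sex, G, 0.5)
        b_o, g_o = _brute_force_mme(y, sex, G.G, 0.5)
        np.testing.assert_allclose(fit.gebv, g_o, atol=1e-8)
        assert fit.mu == pytest.approx(b_o[0], abs=1e-8)
        assert fit.sex_effect == pytest.approx(b_o[1], abs=1e-8)

    def test_vanishing_shrinkage_limit(self, rng):
        """h2 -> 1 makes GEBV approach the fixed-effect-adjusted phenotypes."""
        codes, freqs, xs, sex, y = random_training_fixture(rng, 20, 60)
        G = build_g_matrix(codes, freqs)
        fit = solve_gblup(y, sex, G, 0.9999)
        W = np.column_stack([np.ones(20), (sex == 2).astype(float)])
        adj = y - W @ np.array([fit.mu, fit.sex_effect])
        np.testing.assert_allclose(fit.gebv, adj, atol=1e-2)

    def test_permutation_equivariance(self, rng):
        codes, freqs, xs, sex, y = random_training_fixture(rng, 16, 40)
        G = build_g_matrix(codes, freqs)
        fit = solve_gblup(y, sex, G, 0.4)
        perm = rng.permutation(16)
        Gp = build_g_matrix(codes[perm], freqs)
        fitp = solve_gblup(y[perm], sex[perm], Gp, 0.4)
        np.testing.assert_allclose(fitp.gebv, fit.gebv[perm], atol=1e-8)

    def test_training_gebv_mean_zero_with_own_frequencies(self, rng):
        codes, freqs, xs, sex, y = random_training_fixture(rng, 30, 80)
        fit = solve_gblup(y, sex, build_g_matrix(codes), 0.5)
        assert abs(fit.gebv.mean()) < 1e-6

    def test_shift_invariance(self, rng):
        codes, freqs, xs, sex, y = random_training_fixture(rng, 20, 50)
        G = build_g_matrix(codes, freqs)
        a = solve_gblup(y, sex, G, 0.5)
        b = solve_gblup(y + 100.0, sex, G, 0.5)
        np.testing.assert_allclose(a.gebv, b.gebv, atol=1e-8)
        assert b.mu - a.mu == pytest.approx(100.0, abs=1e-8)

    def test_bad_h2_rejected(self, rng):
        codes, freqs, xs, sex, y = random_training_fixture(rng, 10, 20)
        with pytest.raises(ConfigurationError):
            solve_gblup(y, sex, build_g_matrix(codes, freqs), 1.2)


class TestSolveRrblup:
    def test_single_marker_ridge_closed_form(self, rng):
        """One standardized column orthogonal to the design: x'y/(x'x + lambda)."""
        n = 40
        sex = np.tile([1, 2], n // 2)
        W = np.column_stack([np.ones(n), (sex == 2).astype(float)])
        x = rng.normal(size=n)
        x -= W @ np.linalg.lstsq(W, x, rcond=None)[0]   # orthogonal to design
        x = (x / x.std()).reshape(-1, 1)
        y = rng.normal(size=n)
        h2 = 0.3
        lam = 1 * (1 - h2) / h2
        eff = solve_rrblup(y, sex, x, h2)
        y_adj = y - W @ np.linalg.lstsq(W, y, rcond=None)[0]
        expected = float(x[:, 0] @ y_adj) / (float(x[:, 0] @ x[:, 0]) + lam)
        assert eff.effects[0] == pytest.approx(expected, abs=1e-6)

    def test_zero_signal_gives_zero_effects(self, rng):
        n, p = 30, 10
        sex = np.tile([1, 2], n // 2)
        W = np.column_stack([np.ones(n), (sex == 2).astype(float)])
        x = rng.normal(size=(n, p))
        x -= W @ np.linalg.lstsq(W, x, rcond=None)[0]
        y = W @ np.array([2.0, 1.0])   # orthogonal to all genotype columns
        eff = solve_rrblup(y, sex, x, 0.5)
        np.testing.assert_allclose(eff.effects, 0.0, atol=1e-10)


class TestEquivalence:
    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_gblup_equals_rrblup_on_standardized_kernel(self, seed):
        """GBLUP with lambda=(1-h2)/h2 and RR-BLUP with p(1-h2)/h2 give identical GEBV."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(20, 200))
        p = int(rng.integers(30, 1000))
        h2 = float(rng.uniform(0.1, 0.9))
        codes, freqs, xs, sex, y = random_training_fixture(rng, n, p)
        Gs = build_g_matrix(codes, freqs, method="standardized")
        gebv_g = solve_gblup(y, sex, Gs, h2).gebv
        eff = solve_rrblup(y, sex, xs, h2)
        np.testing.assert_allclose(xs @ eff.effects, gebv_g, atol=1e-6)


class TestPrediction:
    def _trained(self, rng, n=30, p=80):
        codes, freqs, xs, sex, y = random_training_fixture(rng, n, p)
        Gs = build_g_matrix(codes, freqs, method="standardized")
        fit = solve_gblup(y, sex, Gs, 0.5)
        eff = solve_rrblup(y, sex, xs, 0.5)
        return codes, freqs, xs, fit, eff, Gs

    def test_candidate_identical_to_training_individual(self, rng):
        codes, freqs, xs, fit, eff, Gs = self._trained(rng)
        gebv_c = predict_gebv(eff, xs[[3]])
        assert gebv_c[0] == pytest.approx(fit.gebv[3], abs=1e-6)

    def test_all_mean_dosage_candidate_is_zero(self, rng):
        codes, freqs, xs, fit, eff, Gs = self._trained(rng)
        assert predict_gebv(eff, np.zeros((1, xs.shape[1])))[0] == pytest.approx(0.0)

    def test_marker_and_kernel_routes_agree(self, rng):
        codes, freqs, xs, fit, eff, Gs = self._trained(rng)
        cand = rng.binomial(2, freqs, size=(20, len(freqs))).astype(float)
        xs_c = standardize(cand, freqs=freqs)
        via_markers = predict_gebv(eff, xs_c)
        via_kernel = predict_gebv_kernel(cross_kernel(cand, codes, Gs), fit)
        assert np.max(np.abs(via_markers - via_kernel)) < 1e-6

    def test_marker_count_mismatch_rejected(self, rng):
        codes, freqs, xs, fit, eff, Gs = self._trained(rng)
        with pytest.raises(MarkerAlignmentError):
            predict_gebv(eff, xs[:, :10])


@settings(max_examples=10, deadline=None)
@given(st.integers(0, 2**32 - 1))
def test_equivalence_property_random_fixtures(seed):
    """The lambda-scaling pair is pinned by GEBV equality on arbitrary fixtures."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(10, 60))
    p = int(rng.integers(12, 120))
    codes, freqs, xs, sex, y = random_training_fixture(rng, n, p)
    h2 = float(rng.uniform(0.05, 0.95))
    Gs = build_g_matrix(codes, freqs, method="standardized")
    gebv_g = solve_gblup(y, sex, Gs, h2).gebv
    gebv_r = xs @ solve_rrblup(y, sex, xs, h2).effects
    assert np.max(np.abs(gebv_g - gebv_r)) < 1e-6
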