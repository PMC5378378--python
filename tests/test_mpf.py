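"""MPF inference: objective, gradients, consistency, reduced parametrization."""

import numpy as np
import pytest
from scipy.optimize import approx_fprime, minimize

from statescape.data import BinaryStateSeries
from statescape.fixtures import enumerate_gibbs, small_ising_exact
from statescape.hopfield import CouplingMatrix, MCConfig, energy, simulate_mc
from statescape.meanshift import ClusterResult
from statescape.mpf_inference import (
    ReducedIsingModel,
    coupling_error,
    dedup_centroids,
    infer_full,
    infer_reduced,
    mpf_objective,
    reduced_to_full,
    weight_significance,
)


class TestReducedToFull:
    def test_zero_weights_give_zero_matrix(self):
        m = ReducedIsingModel(np.ones((1, 6), dtype=np.int8), np.zeros(1))
        assert np.allclose(reduced_to_full(m).J, 0.0)

    def test_direct_summation_oracle(self, rng):
        C = rng.choice([-1, 1], size=(2, 4)).astype(np.int8)
        w = np.array([0.7, -1.2])
        J = reduced_to_full(ReducedIsingModel(C, w)).J
        for i in range(4):
            for j in range(4):
                expected = 0.0 if i == j else sum(w[m] * C[m, i] * C[m, j] for m in range(2)) / 4
                assert J[i, j] == pytest.approx(expected)

    def test_mirror_pair_collapses_to_one_basis_element(self):
        c = np.array([[1, -1, 1, 1]], dtype=np.int8)
        cents = np.vstack([c, -c, c])
        basis, dmap = dedup_centroids(cents)
        assert basis.shape[0] == 1
        assert np.array_equal(dmap, [0, 0, 0])

    def test_dedup_count_mirrors(self):
        # 18 centroids of which 14 form 7 mirror pairs -> 11 free weights
        rng = np.random.default_rng(0)
        singles = rng.choice([-1, 1], size=(4, 20)).astype(np.int8)
        pairs = rng.choice([-1, 1], size=(7, 20)).astype(np.int8)
        cents = np.vstack([singles, pairs, -pairs])
        basis, _ = dedup_centroids(cents)
        assert cents.shape[0] == 18 and basis.shape[0] == 11


class TestObjective:
    def test_flat_energy_gives_n(self, rng):
        X = rng.choice([-1, 1], size=(20, 7)).astype(np.int8)
        v, g = mpf_objective(np.zeros(21), X, "full")
        assert v == pytest.approx(7.0)

    def test_hand_computed_n2(self):
        # single data state (+1,+1), coupling j: flow to each flipped neighbor
        j = 0.4
        X = np.array([[1, 1]], dtype=np.int8)
        v, _ = mpf_objective(np.array([j]), X, "full")
        # H[(1,1)] = -j ; flipping either spin gives H = +j ; Gamma = exp(-j) each
        assert v == pytest.approx(2 * np.exp(-j))

    @pytest.mark.parametrize("parametrization", ["full", "reduced"])
    def test_gradient_matches_finite_differences(self, parametrization, rng):
        X = rng.choice([-1, 1], size=(40, 6)).astype(np.int8)
        if parametrization == "full":
            theta = rng.normal(0, 0.4, size=15)
            kw = {}
        else:
            kw = {"centroids": rng.choice([-1, 1], size=(3, 6)).astype(np.int8)}
            theta = rng.normal(0, 0.6, size=3)
        v, g = mpf_objective(theta, X, parametrization, **kw)
        g_fd = approx_fprime(theta, lambda t: mpf_objective(t, X, parametrization, **kw)[0], 1e-6)
        assert np.abs(g - g_fd).max() / max(np.abs(g_fd).max(), 1e-12) < 1e-5

    def test_detailed_balance_of_rates(self, rng):
        # Gamma(a->b) exp(-H[a]) == Gamma(b->a) exp(-H[b]) for flip neighbors
        J = rng.normal(0, 0.5, (5, 5))
        J = (J + J.T) / 2
        np.fill_diagonal(J, 0)
        for _ in range(20):
            a = rng.choice([-1, 1], size=5)
            k = rng.integers(5)
            b = a.copy()
            b[k] = -b[k]
            Ha, Hb = energy(a, J), energy(b, J)
            g_ab = np.exp(0.5 * (Ha - Hb))
            g_ba = np.exp(0.5 * (Hb - Ha))
            assert g_ab * np.exp(-Ha) == pytest.approx(g_ba * np.exp(-Hb))

    def test_overflow_reports_rescaling(self):
        X = np.array([[1, 1]], dtype=np.int8)
        with pytest.raises(FloatingPointError, match="rescale"):
            mpf_objective(np.array([-2000.0]), X, "full")


def _exact_ml_fit(states, J0_shape):
    """Exact maximum likelihood by brute-force partition function (N small)."""
    N = states.shape[1]
    iu = np.triu_indices(N, k=1)
    all_states, _ = enumerate_gibbs(np.zeros((N, N)))
    Xa = all_states.astype(float)
    Xd = states.astype(float)
    pair_data = (Xd[:, iu[0]] * Xd[:, iu[1]]).mean(axis=0)

    def nll(theta):
        J = np.zeros((N, N))
        J[iu] = theta
        J = J + J.T
        Ha = -0.5 * np.einsum("si,ij,sj->s", Xa, J, Xa)
        logZ = np.logaddexp.reduce(-Ha)
        # mean energy of the data under J
        Hd = -0.5 * np.einsum("si,ij,sj->s", Xd, J, Xd)
        return Hd.mean() + logZ

    res = minimize(nll, np.zeros(len(iu[0])), method="L-BFGS-B")
    J = np.zeros((N, N))
    J[iu] = res.x
    return J + J.T


class TestInference:
    def test_uniform_data_gives_zero_couplings(self):
        N = 4
        states, _ = enumerate_gibbs(np.zeros((N, N)))
        fit = infer_full(states)
        assert np.abs(fit.parameters).max() < 1e-6

    def test_recovers_known_couplings_and_matches_exact_ml(self):
        series, J_true, _, _ = small_ising_exact(N=8, beta=1.0, n_samples=100000, seed=4)
        fit = infer_full(series)
        err = coupling_error(fit.parameters, J_true)["mean_abs"]
        assert err < 0.10
        J_ml = _exact_ml_fit(series.states, J_true.shape)
        # MPF and exact ML agree on large samples
        assert coupling_error(fit.parameters, J_ml)["mean_abs"] < 0.05

    def test_error_shrinks_with_sample_size(self):
        errs = []
        for n in (1000, 10000, 100000):
            series, J_true, _, _ = small_ising_exact(N=6, beta=1.0, n_samples=n, seed=5)
            fit = infer_full(series)
            errs.append(coupling_error(fit.parameters, J_true)["mean_abs"])
        assert errs[2] < errs[1] < errs[0]

    def test_reduced_beats_full_on_planted_reduced_model(self, rng):
        # data from a centroid-parametrized model, limited samples
        C = rng.choice([-1, 1], size=(3, 20)).astype(np.int8)
        truth = ReducedIsingModel(C, np.array([1.0, 0.8, 0.9]))
        J_true = reduced_to_full(truth)
        series = simulate_mc(J_true, MCConfig(beta=1.0, steps=15000, burn_in=500, seed=6))
        fit_r = infer_reduced(series, C)
        fit_f = infer_full(series)
        err_r = coupling_error(fit_r.coupling_matrix, J_true)["mean_abs"]
        err_f = coupling_error(fit_f.coupling_matrix, J_true)["mean_abs"]
        assert err_r <= err_f

    def test_reduced_recovers_planted_weights(self, rng):
        C = rng.choice([-1, 1], size=(3, 20)).astype(np.int8)
        w_true = np.array([1.1, 0.9, 1.0])
        J_true = reduced_to_full(ReducedIsingModel(C, w_true))
        series = simulate_mc(J_true, MCConfig(beta=1.0, steps=30000, burn_in=500, seed=7))
        fit = infer_reduced(series, C)
        # basis order preserved by dedup (no mirrors among random C)
        assert np.allclose(fit.parameters, w_true, atol=0.15)


class TestCouplingError:
    def test_exact_match_is_zero(self):
        J = np.array([[0, 1.0], [1.0, 0]])
        r = coupling_error(J, J)
        assert r["mean_abs"] == 0.0

    def test_hand_arithmetic(self):
        J_true = np.array([[0, 2.0, -1.0], [2.0, 0, 1.0], [-1.0, 1.0, 0]])
        J_inf = J_true.copy()
        J_inf[0, 1] = J_inf[1, 0] = 2.5
        r = coupling_error(J_inf, J_true)
        norm = np.abs(J_true[~np.eye(3, dtype=bool)]).mean()  # = 4/3
        assert norm == pytest.approx(4 / 3)
        assert r["mean_abs"] == pytest.approx((2 * 0.5 / norm) / 6)

    def test_zero_truth_rejected(self):
        with pytest.raises(ValueError):
            coupling_error(np.ones((2, 2)) - np.eye(2), np.zeros((2, 2)))


class TestSignificance:
    def test_nboot_minimum(self, rng):
        C = rng.choice([-1, 1], size=(2, 10)).astype(np.int8)
        series = BinaryStateSeries(rng.choice([-1, 1], size=(200, 10)))
        fit = infer_reduced(series, C)
        with pytest.raises(ValueError):
            weight_significance(fit, series, n_boot=5)

    def test_iid_noise_yields_no_significant_weights(self):
        hits = 0
        n_seeds = 4
        for seed in range(n_seeds):
            r = np.random.default_rng(seed)
            series = BinaryStateSeries(r.choice([-1, 1], size=(5000, 12)))
            C = r.choice([-1, 1], size=(3, 12)).astype(np.int8)
            fit = infer_reduced(series, C)
            rep = weight_significance(fit, series, n_boot=40, block_length=20, seed=seed)
            hits += rep.significant.any()
        assert hits == 0  # structureless data must not flag weights

    def test_planted_zero_weight_not_flagged(self, rng):
        C = rng.choice([-1, 1], size=(3, 16)).astype(np.int8)
        truth = ReducedIsingModel(C, np.array([1.0, 1.0, 0.0]))
        series = simulate_mc(
            reduced_to_full(truth), MCConfig(beta=1.0, steps=8000, burn_in=500, seed=8)
        )
        fit = infer_reduced(series, C)
        rep = weight_significance(fit, series, n_boot=40, block_length=50, seed=1)
        assert rep.significant[0] and rep.significant[1]
        assert not rep.significant[2]
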