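"""VB machinery: conjugate M-step, ELBO guarantees, determinism, pruning,
ARD, and group -> subject refitting."""

import numpy as np
import pytest

from bsds.inference import (
    Expectations,
    Priors,
    QTheta,
    SuffStats,
    _initial_qtheta,
    estep_latents,
    estep_states,
    expected_scores,
    fit_group,
    fit_subject,
    mstep,
    parameter_elbo_terms,
    posterior_state_parameters,
)
from bsds.model import ModelError, TimeSeriesDataset
from bsds.simulate import default_state_parameters, simulate_switching_series


def elbo_is_monotone(trace, tol_scale=1e-8):
    trace = np.asarray(trace)
    return bool(np.all(np.diff(trace) >= -tol_scale * np.abs(trace[:-1])))


class TestMStep:
    def test_no_data_returns_prior(self):
        K, D, P = 2, 3, 2
        priors = Priors.default(K, D, P)
        q0 = _initial_qtheta(K, D, P)
        q = mstep(SuffStats.zeros(K, D, P), priors, q0)
        assert np.allclose(q.alpha_pi, priors.alpha0_pi)
        assert np.allclose(q.alpha_A, priors.alpha0_A)
        assert np.allclose(q.m_w, 0.0)
        assert np.allclose(q.m_g, 0.0)
        assert np.allclose(q.a_psi, priors.a0_psi)
        assert np.allclose(q.b_psi, priors.b0_psi)
        assert np.allclose(q.a_sig, priors.a0_sig)

    def test_moment_matching_single_state(self, make_params):
        # K=1, v=0: fitted stationary covariance ~ sample covariance,
        # fitted mean ~ sample mean, on a large single-state simulation
        from bsds.model import state_observed_cov, state_stationary_latent_cov

        params = default_state_parameters(K=1, D=4, P=2, ar_coef=0.0, seed=2)
        data, _ = simulate_switching_series(
            params, None, n_subjects=1, n_frames=20000, tr=1.0, seed=3
        )
        fit = fit_group(data, K_max=1, P_max=2, n_restarts=1, seed=0,
                        max_iter=200)
        y = data.subjects["sub-01"]
        fa, ar = fit.params.fa[0], fit.params.ar[0]
        _, mstar = state_stationary_latent_cov(ar)
        model_mean = fa.mu + fa.U @ mstar
        assert np.abs(model_mean - y.mean(axis=0)).max() < 0.05
        C = state_observed_cov(fa, ar)
        Chat = np.cov(y.T)
        assert np.linalg.norm(C - Chat) / np.linalg.norm(Chat) < 0.05

    def test_ard_suppresses_null_dimension(self):
        # generating loadings use only 1 of 2 latent dims; the ARD
        # precision of the unused column must grow far beyond the active one
        from bsds.model import ARParams, FAParams, HMMParams, StateParameters

        rng = np.random.default_rng(4)
        D = 5
        U = np.zeros((D, 1))
        U[:, 0] = rng.normal(size=D)
        gen = StateParameters(
            hmm=HMMParams(pi=[1.0], A=[[1.0]]),
            fa=(FAParams(U=U, mu=np.zeros(D), psi=np.full(D, 0.3)),),
            ar=(ARParams(V=np.zeros((1, 1)), m=np.zeros(1), sigma=np.ones(1)),),
        )
        data, _ = simulate_switching_series(
            gen, None, n_subjects=1, n_frames=4000, tr=1.0, seed=5
        )
        fit = fit_group(data, K_max=1, P_max=2, n_restarts=1, seed=0,
                        max_iter=300)
        nu = fit.qtheta.a_nu / fit.qtheta.b_nu
        assert nu[0].max() >= 10 * nu[0].min()
        assert fit.effective_P[0] >= 1


class TestELBO:
    def test_prior_equals_posterior_zero_kl(self):
        q = _initial_qtheta(2, 3, 2)
        # make the factors non-trivial first
        rng = np.random.default_rng(0)
        q.m_w = rng.normal(size=q.m_w.shape)
        q.m_g = rng.normal(size=q.m_g.shape) * 0.3
        q.alpha_pi = np.array([3.0, 5.0])
        q.alpha_A = rng.uniform(1, 4, size=(2, 2))
        q.a_psi = np.array([4.0, 6.0])
        q.b_psi = rng.uniform(1, 3, size=(2, 3))
        q.a_sig = np.array([3.0, 2.0])
        q.b_sig = rng.uniform(1, 2, size=(2, 2))
        priors = Priors.from_posterior(q)
        assert abs(parameter_elbo_terms(q, priors)) < 1e-8

    def test_monotone_on_switching_data(self):
        params = default_state_parameters(K=2, D=3, seed=3)
        from bsds.designs import make_block_design

        design = make_block_design("tvb", tr=0.7)
        data, _ = simulate_switching_series(params, design, n_subjects=1, seed=5)
        fit = fit_group(data, K_max=3, n_restarts=1, seed=0, max_iter=150)
        assert elbo_is_monotone(fit.elbo_trace)

    def test_monotone_on_pure_noise(self, rng):
        data = TimeSeriesDataset(
            subjects={"s1": rng.normal(size=(250, 4))}, tr=1.0
        )
        fit = fit_group(data, K_max=3, n_restarts=1, seed=1, max_iter=100)
        assert elbo_is_monotone(fit.elbo_trace)

    def test_factor_analysis_reduction_matches_sample_estimates(self):
        # K=1, v=0 reduces to Bayesian FA; posterior-mean observed moments
        # must approach the empirical moments used by any FA implementation
        rng = np.random.default_rng(1)
        W = rng.normal(size=(5, 2))
        x = rng.normal(size=(6000, 2))
        y = x @ W.T + rng.normal(scale=0.5, size=(6000, 5))
        data = TimeSeriesDataset(subjects={"s": y}, tr=1.0)
        fit = fit_group(data, K_max=1, P_max=2, n_restarts=1, seed=0,
                        max_iter=200)
        from bsds.model import state_observed_cov

        C = state_observed_cov(fit.params.fa[0], fit.params.ar[0])
        assert np.linalg.norm(C - np.cov(y.T)) / np.linalg.norm(np.cov(y.T)) < 0.05


class TestFitGroup:
    @pytest.fixture(scope="class")
    def tvb_fit(self):
        from bsds.designs import make_block_design

        params = default_state_parameters(K=2, D=3, seed=3)
        design = make_block_design("tvb", tr=0.7)
        data, truth = simulate_switching_series(params, design, n_subjects=3,
                                                seed=5)
        fit = fit_group(data, K_max=5, n_restarts=2, seed=0)
        return params, design, data, truth, fit

    def test_two_state_recovery_and_pruning(self, tvb_fit):
        from sklearn.metrics import adjusted_rand_score

        from bsds.dynamics import viterbi_decode

        _, _, data, truth, fit = tvb_fit
        assert fit.K_effective == 2
        for sid, y in data.subjects.items():
            lab = viterbi_decode(fit.params, y, tr=0.7).labels
            assert adjusted_rand_score(truth.state_sequence[sid], lab) >= 0.9

    def test_single_state_data_prunes_to_one(self, rng):
        params = default_state_parameters(K=1, D=3, seed=6)
        data, _ = simulate_switching_series(
            params, None, n_subjects=2, n_frames=400, tr=1.0, seed=7
        )
        fit = fit_group(data, K_max=5, n_restarts=2, seed=0, max_iter=300)
        assert fit.K_effective == 1

    def test_deterministic_given_seed(self):
        params = default_state_parameters(K=2, D=3, seed=3)
        data, _ = simulate_switching_series(
            params, None, n_subjects=1, n_frames=300, tr=1.0, seed=8
        )
        f1 = fit_group(data, K_max=3, n_restarts=2, seed=42, max_iter=60)
        f2 = fit_group(data, K_max=3, n_restarts=2, seed=42, max_iter=60)
        assert np.array_equal(f1.elbo_trace, f2.elbo_trace)  # bitwise
        assert np.array_equal(f1.qtheta.m_w, f2.qtheta.m_w)

    def test_short_series_rejected(self, rng):
        data = TimeSeriesDataset(subjects={"s": rng.normal(size=(2, 3))}, tr=1.0)
        with pytest.raises(ModelError, match="T="):
            fit_group(data, K_max=2)

    def test_constant_channel_named(self, rng):
        y = rng.normal(size=(50, 3))
        y[:, 1] = 2.0
        data = TimeSeriesDataset(subjects={"s": y}, tr=1.0,
                                 channel_names=("a", "bad", "c"))
        with pytest.raises(ModelError, match="'bad'"):
            fit_group(data, K_max=2)


class TestFitSubject:
    @pytest.fixture(scope="class")
    def group_and_data(self):
        # D=4 so the two states' 2-D loading subspaces can be disjoint
        # (two 2-D subspaces in R^3 always share a direction)
        params = default_state_parameters(K=2, D=4, seed=9)
        data, truth = simulate_switching_series(
            params, None, n_subjects=4, n_frames=500, tr=1.0, seed=10
        )
        held, heldz = simulate_switching_series(
            params, None, n_subjects=1, n_frames=500, tr=1.0, seed=11
        )
        group = fit_group(data, K_max=3, n_restarts=2, seed=0, max_iter=200)
        return params, group, data, held, heldz

    def test_refit_of_group_of_one_stays_close(self):
        # a subject refit against a group model fit on that subject alone
        # brings no new evidence direction: posteriors barely move
        from bsds.model import state_observed_cov

        params = default_state_parameters(K=2, D=4, seed=9)
        data, _ = simulate_switching_series(
            params, None, n_subjects=1, n_frames=500, tr=1.0, seed=13
        )
        group = fit_group(data, K_max=2, n_restarts=1, seed=0, max_iter=200)
        refit = fit_subject(group, data)
        for k in range(group.params.K):
            C0 = state_observed_cov(group.params.fa[k], group.params.ar[k])
            C1 = state_observed_cov(refit.params.fa[k], refit.params.ar[k])
            assert np.linalg.norm(C1 - C0) / np.linalg.norm(C0) < 0.05
        assert elbo_is_monotone(refit.elbo_trace)

    def test_held_out_subject_decoding(self, group_and_data):
        from sklearn.metrics import adjusted_rand_score

        from bsds.dynamics import viterbi_decode

        _, group, _, held, heldz = group_and_data
        refit = fit_subject(group, held)
        y = held.subjects["sub-01"]
        lab = viterbi_decode(refit.params, y, tr=1.0).labels
        ari = adjusted_rand_score(heldz.state_sequence["sub-01"], lab)
        assert ari >= 0.85

    def test_dimension_mismatch_rejected(self, group_and_data, rng):
        _, group, _, _, _ = group_and_data
        bad = TimeSeriesDataset(subjects={"x": rng.normal(size=(100, 5))}, tr=1.0)
        with pytest.raises(ModelError, match="D="):
            fit_subject(group, bad)

    def test_permuted_channels_rejected(self, group_and_data, rng):
        _, group, data, _, _ = group_and_data
        names = tuple(reversed(data.channel_names))
        bad = TimeSeriesDataset(
            subjects={"x": rng.normal(size=(100, len(names)))}, tr=1.0,
            channel_names=names,
        )
        with pytest.raises(ModelError, match="channel names"):
            fit_subject(group, bad)


class TestLabelPermutationEquivariance:
    def test_permuted_init_permutes_solution(self):
        """Relabeling the initial responsibilities relabels the fit."""
        from bsds.inference import _vb_run

        params = default_state_parameters(K=2, D=3, seed=3)
        data, _ = simulate_switching_series(
            params, None, n_subjects=1, n_frames=200, tr=1.0, seed=12
        )
        K, P = 3, 2
        priors = Priors.default(K, data.D, P)
        rng = np.random.default_rng(0)
        g0 = {"sub-01": rng.dirichlet(np.ones(K), size=200)}
        perm = np.array([2, 0, 1])
        g1 = {"sub-01": g0["sub-01"][:, perm]}
        q0, z0, _, e0 = _vb_run(data, priors, g0, P, 40, 1e-9, 2, 10.0)
        q1, z1, _, e1 = _vb_run(data, priors, g1, P, 40, 1e-9, 2, 10.0)
        assert np.allclose(e0, e1, rtol=1e-9)
        assert np.allclose(z0["sub-01"].gamma[:, perm], z1["sub-01"].gamma,
                           atol=1e-8)
        assert np.allclose(q0.m_w[perm], q1.m_w, atol=1e-6)
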