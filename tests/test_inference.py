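import numpy as np
import pytest
from scipy.special import logsumexp

from groupfa.datasets import GroupedDataset, Hyperparameters, split
from groupfa.gfa import (
    GFA,
    _fit_cycle,
    compute_elbo,
    init_posterior,
    latent_posterior,
    prune_factors,
    update_alpha,
    update_latent,
    update_loadings,
    update_tau,
)
from groupfa.simulate import (
    generate,
    make_design,
    remove_random_elements,
    remove_random_samples,
    remove_tails,
)

# ---------------------------------------------------------------------------
# dense (unmasked) reference implementation: straightforward loops
# ---------------------------------------------------------------------------


def dense_update_latent(post, data):
    K, N = post.n_factors, post.n_samples
    for n in range(N):
        prec = np.eye(K)
        rhs = np.zeros(K)
        for m in range(post.n_groups):
            tau = post.tau_mean(m)
            for j in range(data.groups[m].shape[0]):
                ww = post.W_cov[m][j] + np.outer(post.W_mean[m][j], post.W_mean[m][j])
                prec += tau[j] * ww
                rhs += tau[j] * post.W_mean[m][j] * data.groups[m][j, n]
        cov = np.linalg.inv(prec)
        post.Z_cov[n] = cov
        post.Z_mean[:, n] = cov @ rhs
    return post


def dense_update_loadings(post, data, hyper):
    K, N = post.n_factors, post.n_samples
    zz = sum(
        post.Z_cov[n] + np.outer(post.Z_mean[:, n], post.Z_mean[:, n])
        for n in range(N)
    )
    for m in range(post.n_groups):
        tau = post.tau_mean(m)
        alpha = post.alpha_mean(m)
        for j in range(data.groups[m].shape[0]):
            prec = np.diag(alpha) + tau[j] * zz
            cov = np.linalg.inv(prec)
            rhs = sum(post.Z_mean[:, n] * data.groups[m][j, n] for n in range(N))
            post.W_cov[m][j] = cov
            post.W_mean[m][j] = tau[j] * cov @ rhs
    return post


def dense_update_alpha(post, data, hyper):
    for m in range(post.n_groups):
        dm, K = post.W_mean[m].shape
        for k in range(K):
            ew2 = sum(
                post.W_mean[m][j, k] ** 2 + post.W_cov[m][j][k, k]
                for j in range(dm)
            )
            post.alpha_shape[m][k] = hyper.a_alpha + dm / 2
            post.alpha_rate[m][k] = hyper.b_alpha + 0.5 * ew2
    return post


def dense_update_tau(post, data, hyper):
    N = post.n_samples
    for m in range(post.n_groups):
        dm = post.W_mean[m].shape[0]
        for j in range(dm):
            ww = post.W_cov[m][j] + np.outer(post.W_mean[m][j], post.W_mean[m][j])
            resid = 0.0
            for n in range(N):
                zz = post.Z_cov[n] + np.outer(post.Z_mean[:, n], post.Z_mean[:, n])
                x = data.groups[m][j, n]
                resid += (
                    x ** 2
                    - 2 * x * post.W_mean[m][j] @ post.Z_mean[:, n]
                    + np.trace(ww @ zz)
                )
            post.tau_shape[m][j] = hyper.a_tau + N / 2
            post.tau_rate[m][j] = hyper.b_tau + 0.5 * resid
    return post


@pytest.fixture
def complete_small():
    data, _ = generate(make_design(25), D=(6, 4), seed=13)
    hyper = Hyperparameters(K=3, seed=5)
    return data, hyper


class TestDenseEquivalence:
    """With a full mask every masked update must equal the dense formulas."""

    def test_full_cycle_matches_dense_oracle(self, complete_small):
        data, hyper = complete_small
        post = init_posterior(data, hyper)
        ref = post.copy()
        for _ in range(3):
            update_latent(post, data, hyper)
            dense_update_latent(ref, data)
            np.testing.assert_allclose(post.Z_mean, ref.Z_mean, atol=1e-10)
            np.testing.assert_allclose(post.Z_cov, ref.Z_cov, atol=1e-10)
            update_loadings(post, data, hyper)
            dense_update_loadings(ref, data, hyper)
            for m in range(2):
                np.testing.assert_allclose(post.W_mean[m], ref.W_mean[m], atol=1e-10)
                np.testing.assert_allclose(post.W_cov[m], ref.W_cov[m], atol=1e-10)
            update_alpha(post, data, hyper)
            dense_update_alpha(ref, data, hyper)
            for m in range(2):
                np.testing.assert_allclose(post.alpha_rate[m], ref.alpha_rate[m],
                                           rtol=1e-10)
            update_tau(post, data, hyper)
            dense_update_tau(ref, data, hyper)
            for m in range(2):
                np.testing.assert_allclose(post.tau_rate[m], ref.tau_rate[m],
                                           rtol=1e-10)

    def test_fused_cycle_matches_sequential_updates(self, complete_small):
        data, hyper = complete_small
        p1 = init_posterior(data, hyper)
        p2 = p1.copy()
        cache = {
            "xz": [np.where(data.masks[m], data.groups[m], 0.0) for m in range(2)],
            "maskf": [m.astype(float) for m in data.masks],
            "n_obs": [m.sum(axis=1) for m in data.masks],
        }
        for _ in range(4):
            update_latent(p1, data, hyper)
            update_loadings(p1, data, hyper)
            update_alpha(p1, data, hyper)
            update_tau(p1, data, hyper)
            e1 = compute_elbo(p1, data, hyper)
            e2 = _fit_cycle(p2, data, hyper, cache)
            assert abs(e1 - e2) < 1e-9 * abs(e1)
        np.testing.assert_allclose(p1.Z_mean, p2.Z_mean, atol=1e-12)


class TestMaskedUpdates:
    def test_unobserved_sample_gets_prior_latent(self):
        # a sample observed in one group only: excluding that group, its
        # latent posterior must fall back to the standard-normal prior
        data, _ = generate(make_design(20), D=(5, 4), seed=2)
        mask0 = data.masks[0].copy()
        mask0[:, 3] = False
        data = GroupedDataset(groups=data.groups, masks=[mask0, data.masks[1]])
        hyper = Hyperparameters(K=3, seed=0)
        post = init_posterior(data, hyper)
        update_latent(post, data, hyper)
        mean, cov = latent_posterior(post, data, exclude_groups=[1])
        np.testing.assert_allclose(mean[:, 3], 0.0, atol=1e-12)
        np.testing.assert_allclose(cov[3], np.eye(3), atol=1e-12)

    def test_scalar_closed_form(self):
        # K=1, one variable, one group: q(z_n) has textbook 1-D Gaussian form
        x = np.array([[1.7, -0.4, 0.9]])
        data = GroupedDataset(groups=[x])
        hyper = Hyperparameters(K=1, seed=0)
        post = init_posterior(data, hyper)
        post.W_mean[0][:] = 0.8
        post.W_cov[0][:] = 0.05
        post.tau_shape[0][:] = 6.0
        post.tau_rate[0][:] = 2.0   # <tau> = 3
        update_latent(post, data, hyper)
        tau, w, wvar = 3.0, 0.8, 0.05
        var = 1.0 / (1.0 + tau * (w ** 2 + wvar))
        np.testing.assert_allclose(post.Z_cov[:, 0, 0], var, rtol=1e-12)
        np.testing.assert_allclose(post.Z_mean[0], var * tau * w * x[0], rtol=1e-12)

    def test_tau_shape_counts_observed_cells_only(self):
        data, _ = generate(make_design(40), D=(5, 4), seed=4)
        masked = remove_random_elements(data, 1, 0.25, seed=1)
        hyper = Hyperparameters(K=3, seed=0)
        post = init_posterior(masked, hyper)
        update_tau(post, masked, hyper)
        n_obs = masked.masks[1].sum(axis=1)
        np.testing.assert_allclose(post.tau_shape[1], hyper.a_tau + n_obs / 2)
        assert (n_obs < 40).any()

    def test_ard_shrinkage_limit(self, complete_small):
        data, hyper = complete_small
        post = init_posterior(data, hyper)
        update_latent(post, data, hyper)
        post.alpha_shape[0][:] = 1e12   # <alpha> enormous for group 1
        post.alpha_rate[0][:] = 1.0
        update_loadings(post, data, hyper)
        assert np.abs(post.W_mean[0]).max() < 1e-6

    def test_alpha_explodes_for_dead_factor(self, complete_small):
        data, hyper = complete_small
        post = init_posterior(data, hyper)
        post.W_mean[0][:, 0] = 0.0
        post.W_cov[0][:, 0, 0] = 1e-20
        update_alpha(post, data, hyper)
        assert post.alpha_mean(0)[0] > 1e10

    def test_masked_cell_value_never_enters_elbo(self):
        data, _ = generate(make_design(30), D=(5, 4), seed=6)
        masked = remove_random_elements(data, 0, 0.2, seed=2)
        hyper = Hyperparameters(K=3, seed=1)
        post = init_posterior(masked, hyper)
        for _ in range(2):
            update_latent(post, masked, hyper)
            update_loadings(post, masked, hyper)
            update_alpha(post, masked, hyper)
            update_tau(post, masked, hyper)
        e1 = compute_elbo(post, masked, hyper)
        tampered = masked.copy()
        tampered.groups[0][~tampered.masks[0]] = 1e6
        e2 = compute_elbo(post, tampered, hyper)
        assert e1 == e2


def _scenario(data, name):
    if name == "complete":
        return data
    if name == "elements":
        return remove_random_elements(data, 1, 0.2, seed=3)
    if name == "modality":
        return remove_random_samples(data, 0, 0.2, seed=3)
    return remove_tails(data, 1, 0.2, seed=3)


class TestFit:
    @pytest.mark.parametrize("scenario", ["complete", "elements", "modality", "tails"])
    def test_elbo_monotone_under_every_missingness_mechanism(self, scenario):
        data, _ = generate(make_design(80), D=(8, 6), seed=17)
        masked = _scenario(data, scenario)
        model = GFA(n_factors=5, random_state=1, max_iter=300).fit(masked)
        assert model.trace_.check_monotone(1e-8)

    def test_seed_reproducibility(self, small_data):
        data, _ = small_data
        m1 = GFA(n_factors=5, random_state=42, max_iter=150).fit(data)
        m2 = GFA(n_factors=5, random_state=42, max_iter=150).fit(data)
        assert m1.trace_.values == m2.trace_.values
        np.testing.assert_array_equal(m1.loadings_[0], m2.loadings_[0])

    def test_overspecified_k_prunes_to_true_factors(self, small_fit):
        model, train, test, truth = small_fit
        pruned, keep = model.prune()
        assert len(keep) == 4

    def test_larger_k_converges_to_same_active_set(self, small_data):
        data, truth = small_data
        model = GFA(n_factors=12, random_state=3).fit(data)
        pruned, keep = model.prune()
        assert len(keep) == 4

    def test_max_iter_reached_flags_not_converged(self, small_data):
        data, _ = small_data
        model = GFA(n_factors=4, random_state=0, max_iter=5).fit(data)
        assert not model.converged_
        assert model.n_iter_ == 5

    def test_single_group_recovers_low_rank_structure(self):
        # M=1 reduces to Bayesian factor analysis; a noiseless rank-2
        # matrix must be reconstructed nearly exactly (SVD oracle: the
        # best rank-2 approximation has zero error)
        rng = np.random.default_rng(8)
        w = rng.normal(size=(8, 2))
        z = rng.normal(size=(2, 60))
        x = w @ z
        model = GFA(n_factors=4, random_state=0, max_iter=2000).fit(
            GroupedDataset(groups=[x])
        )
        recon = model.loadings_[0] @ model.latent_mean_
        rel = np.linalg.norm(recon - x) / np.linalg.norm(x)
        assert rel < 1e-3

    def test_sklearn_estimator_protocol(self, small_data):
        data, _ = small_data
        model = GFA(n_factors=3, max_iter=50, random_state=0)
        params = model.get_params()
        assert params["n_factors"] == 3
        model.set_params(max_iter=60)
        assert model.max_iter == 60
        # list-of-arrays input in the samples x features orientation
        xs = [g.T for g in data.groups]
        model.fit(xs)
        assert model.latent_mean_.shape == (3, data.n_samples)
        assert model.transform(xs).shape == (data.n_samples, 3)


class TestElboOracle:
    def test_elbo_below_quadrature_log_evidence(self):
        # one factor, one group, one variable, three samples, proper
        # Exp(1) priors on alpha and tau: the marginal likelihood is a
        # 2-D integral (alpha integrates out analytically into a
        # Student-type prior on w), computed here by brute-force
        # quadrature; any ELBO must lie below it
        x = np.array([[0.6, -1.1, 0.4]])
        data = GroupedDataset(groups=[x])
        a = b = 1.0
        w = np.linspace(-25, 25, 6001)
        tau = np.linspace(1e-4, 60, 6001)
        # log p(w) = log Gamma(1.5) - 0.5 log(2 pi) - 1.5 log(1 + w^2/2)
        from scipy.special import gammaln

        log_pw = gammaln(1.5) - 0.5 * np.log(2 * np.pi) - 1.5 * np.log1p(w ** 2 / 2)
        log_ptau = -tau  # Exp(1) density, log
        var = w[:, None] ** 2 + 1.0 / tau[None, :]
        loglik = np.zeros_like(var)
        for xn in x[0]:
            loglik += -0.5 * (np.log(2 * np.pi * var) + xn ** 2 / var)
        grid = log_pw[:, None] + log_ptau[None, :] + loglik
        dw = w[1] - w[0]
        dtau = tau[1] - tau[0]
        log_evidence = logsumexp(grid) + np.log(dw) + np.log(dtau)

        model = GFA(n_factors=1, a_alpha=a, b_alpha=b, a_tau=a, b_tau=b,
                    random_state=0, max_iter=2000).fit(data)
        assert model.elbo_ <= log_evidence + 1e-6
        # and the bound should be reasonably tight for this tiny model
        assert model.elbo_ > log_evidence - 2.0


class TestPrune:
    def test_zero_thresholds_keep_everything(self, small_fit):
        model, *_ = small_fit
        pruned, keep = prune_factors(model.posterior_, 0.0, rel_threshold=0.0)
        assert len(keep) == model.posterior_.n_factors

    def test_all_pruned_raises(self, small_fit):
        model, *_ = small_fit
        with pytest.raises(ValueError, match="pruning threshold"):
            prune_factors(model.posterior_, np.inf)

    def test_prune_commutes_with_permutation(self, small_fit):
        model, *_ = small_fit
        post = model.posterior_
        K = post.n_factors
        rng = np.random.default_rng(0)
        perm = rng.permutation(K)
        permuted = post.copy()
        permuted.Z_mean = post.Z_mean[perm]
        permuted.Z_cov = post.Z_cov[:, perm][:, :, perm]
        permuted.W_mean = [w[:, perm] for w in post.W_mean]
        permuted.W_cov = [c[:, perm][:, :, perm] for c in post.W_cov]
        permuted.alpha_shape = [a[perm] for a in post.alpha_shape]
        permuted.alpha_rate = [a[perm] for a in post.alpha_rate]
        p1, keep1 = prune_factors(post, 1e-3)
        p2, keep2 = prune_factors(permuted, 1e-3)
        np.testing.assert_array_equal(np.sort(perm[keep2]), np.sort(keep1))
        # retained loading columns coincide as sets
        np.testing.assert_allclose(
            np.sort(p1.W_mean[0], axis=1), np.sort(p2.W_mean[0], axis=1)
        )
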