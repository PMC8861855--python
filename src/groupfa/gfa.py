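"""Group factor analysis with missing-data-aware variational inference.

The model couples M groups of variables measured on the same N samples
through K shared latent variables::

    z_n ~ N(0, I_K)
    x_n^(m) ~ N(W^(m) z_n, diag(tau^(m))^-1)

with automatic-relevance-determination (ARD) priors on the loadings,
``w_jk^(m) ~ N(0, 1/alpha_k^(m))`` and gamma hyperpriors on the
``alpha_k^(m)`` and on the per-variable noise precisions ``tau_j^(m)``.
Group-wise ARD lets a factor stay active in some groups and be driven to
zero in others, separating shared from group-specific structure;
factors inactive in every group are pruned after convergence.

Inference is mean-field variational EM with a fully factorised posterior
``q(Z) q(W) q(alpha) q(tau)``. Every update sums only over the observed
index sets — the loadings/noise of the non-missing variables of sample n
when updating q(z_n), and the latent variables of the non-missing samples
of variable j when updating q(W_j) and q(tau_j) — so the algorithm runs
unchanged on data with missing cells or wholly missing modalities, and
reduces exactly to the dense updates on complete data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import digamma, gammaln
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils import check_random_state

from .datasets import GroupedDataset, Hyperparameters

logger = logging.getLogger(__name__)

__all__ = [
    "GFA",
    "GFAPosterior",
    "ELBOTrace",
    "init_posterior",
    "update_latent",
    "update_loadings",
    "update_alpha",
    "update_tau",
    "compute_elbo",
    "prune_factors",
]

_LOG2PI = np.log(2.0 * np.pi)
_TAU_CAP = 1e12  # guards zero-residual degenerate data; keeps the ELBO finite


# ---------------------------------------------------------------------------
# posterior container
# ---------------------------------------------------------------------------

@dataclass
class GFAPosterior:
    """Variational parameters of q(Z), q(W), q(alpha), q(tau).

    Shapes: ``Z_mean (K, N)``; ``Z_cov (N, K, K)``; per group
    ``W_mean (Dm, K)``, ``W_cov (Dm, K, K)``, ``alpha_shape/rate (K,)``,
    ``tau_shape/rate (Dm,)``.
    """

    Z_mean: np.ndarray
    Z_cov: np.ndarray
    W_mean: list
    W_cov: list
    alpha_shape: list
    alpha_rate: list
    tau_shape: list
    tau_rate: list

    @property
    def n_factors(self) -> int:
        return self.Z_mean.shape[0]

    @property
    def n_samples(self) -> int:
        return self.Z_mean.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.W_mean)

    def alpha_mean(self, m: int) -> np.ndarray:
        return self.alpha_shape[m] / self.alpha_rate[m]

    def tau_mean(self, m: int) -> np.ndarray:
        return np.minimum(self.tau_shape[m] / self.tau_rate[m], _TAU_CAP)

    def ww_moment(self, m: int) -> np.ndarray:
        """Per-row second moment <w_j w_j^T>, shape (Dm, K, K)."""
        w = self.W_mean[m]
        return self.W_cov[m] + w[:, :, None] * w[:, None, :]

    def zz_moment(self) -> np.ndarray:
        """Per-sample second moment <z_n z_n^T>, shape (N, K, K)."""
        mu = self.Z_mean.T
        return self.Z_cov + mu[:, :, None] * mu[:, None, :]

    def copy(self) -> "GFAPosterior":
        return GFAPosterior(
            Z_mean=self.Z_mean.copy(),
            Z_cov=self.Z_cov.copy(),
            W_mean=[w.copy() for w in self.W_mean],
            W_cov=[c.copy() for c in self.W_cov],
            alpha_shape=[a.copy() for a in self.alpha_shape],
            alpha_rate=[a.copy() for a in self.alpha_rate],
            tau_shape=[t.copy() for t in self.tau_shape],
            tau_rate=[t.copy() for t in self.tau_rate],
        )


@dataclass
class ELBOTrace:
    """Per-iteration lower-bound values and the stopping outcome."""

    values: list = field(default_factory=list)
    converged: bool = False

    @property
    def n_iter(self) -> int:
        return len(self.values)

    def check_monotone(self, rel_slack: float = 1e-8) -> bool:
        v = np.asarray(self.values)
        if len(v) < 2:
            return True
        dips = np.diff(v) < -rel_slack * np.abs(v[:-1])
        return not dips.any()


# ---------------------------------------------------------------------------
# numerics helpers
# ---------------------------------------------------------------------------

def _inv_batch(a: np.ndarray, what: str) -> np.ndarray:
    """Batched symmetric inverse with jitter escalation (1e-10 -> 1e-6)."""
    eye = np.eye(a.shape[-1])
    for jit in (0.0, 1e-10, 1e-8, 1e-6):
        try:
            inv = np.linalg.inv(a + jit * eye)
            if np.isfinite(inv).all():
                if jit > 0.0:
                    logger.warning("jitter %g applied inverting %s", jit, what)
                return 0.5 * (inv + np.swapaxes(inv, -1, -2))
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(f"could not invert {what} even with jitter")


def _logdet_batch(a: np.ndarray) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(a)
    if np.any(sign <= 0):
        # fall back to a jittered determinant for near-singular blocks
        sign, logdet = np.linalg.slogdet(a + 1e-10 * np.eye(a.shape[-1]))
    return logdet


def _masked(data: GroupedDataset, m: int):
    """(values-with-zeros-at-missing, float mask) for group m."""
    mask = data.masks[m]
    return np.where(mask, data.groups[m], 0.0), mask.astype(float)


def _gamma_kl(shape_q, rate_q, shape_p, rate_p) -> float:
    """KL( Gamma(shape_q, rate_q) || Gamma(shape_p, rate_p) ), summed."""
    shape_q = np.asarray(shape_q, dtype=float)
    rate_q = np.asarray(rate_q, dtype=float)
    kl = (
        (shape_q - shape_p) * digamma(shape_q)
        - gammaln(shape_q)
        + gammaln(shape_p)
        + shape_p * (np.log(rate_q) - np.log(rate_p))
        + shape_q * (rate_p - rate_q) / rate_q
    )
    return float(np.sum(kl))


# ---------------------------------------------------------------------------
# variational updates (each mutates `post` in place and returns it)
# ---------------------------------------------------------------------------

def init_posterior(data: GroupedDataset, hyper: Hyperparameters,
                   rng=None) -> GFAPosterior:
    """Random starting point: N(0,1) latent means, small random loadings,
    identity covariances, gamma parameters at their prior values."""
    rng = np.random.default_rng(hyper.seed) if rng is None else rng
    K, N = hyper.K, data.n_samples
    eye = np.eye(K)
    post = GFAPosterior(
        Z_mean=rng.standard_normal((K, N)),
        Z_cov=np.broadcast_to(eye, (N, K, K)).copy(),
        W_mean=[0.01 * rng.standard_normal((d, K)) for d in data.n_variables],
        W_cov=[np.broadcast_to(eye, (d, K, K)).copy() for d in data.n_variables],
        alpha_shape=[np.full(K, hyper.a_alpha) for _ in data.groups],
        alpha_rate=[np.full(K, hyper.b_alpha) for _ in data.groups],
        tau_shape=[np.full(d, hyper.a_tau) for d in data.n_variables],
        tau_rate=[np.full(d, hyper.b_tau) for d in data.n_variables],
    )
    return post


def update_latent(post: GFAPosterior, data: GroupedDataset,
                  hyper: Hyperparameters) -> GFAPosterior:
    """q(z_n) update using only the observed variables of each sample."""
    K, N = post.n_factors, post.n_samples
    prec = np.broadcast_to(np.eye(K), (N, K, K)).copy()
    rhs = np.zeros((N, K))
    for m in range(post.n_groups):
        xz, maskf = _masked(data, m)
        tau = post.tau_mean(m)
        tww = tau[:, None, None] * post.ww_moment(m)          # (Dm, K, K)
        prec += (maskf.T @ tww.reshape(len(tau), -1)).reshape(N, K, K)
        rhs += xz.T @ (tau[:, None] * post.W_mean[m])         # (N, K)
    post.Z_cov = _inv_batch(prec, "latent precision")
    post.Z_mean = np.einsum("nkl,nl->nk", post.Z_cov, rhs).T
    return post


def update_loadings(post: GFAPosterior, data: GroupedDataset,
                    hyper: Hyperparameters) -> GFAPosterior:
    """q(W_j) update per row, using only the samples observing variable j."""
    K = post.n_factors
    zz = post.zz_moment()                                     # (N, K, K)
    for m in range(post.n_groups):
        xz, maskf = _masked(data, m)
        tau = post.tau_mean(m)
        s = (maskf @ zz.reshape(post.n_samples, -1)).reshape(-1, K, K)
        prec = np.diag(post.alpha_mean(m))[None] + tau[:, None, None] * s
        post.W_cov[m] = _inv_batch(prec, f"loading precision (group {m})")
        b = xz @ post.Z_mean.T                                # (Dm, K)
        post.W_mean[m] = tau[:, None] * np.einsum(
            "jkl,jl->jk", post.W_cov[m], b
        )
    return post


def update_alpha(post: GFAPosterior, data: GroupedDataset,
                 hyper: Hyperparameters) -> GFAPosterior:
    """q(alpha_k^(m)) update: the ARD precisions tracking column energy."""
    for m in range(post.n_groups):
        dm = post.W_mean[m].shape[0]
        ew2 = post.W_mean[m] ** 2 + np.diagonal(post.W_cov[m], axis1=1, axis2=2)
        post.alpha_shape[m] = np.full(post.n_factors, hyper.a_alpha + 0.5 * dm)
        post.alpha_rate[m] = hyper.b_alpha + 0.5 * ew2.sum(axis=0)
    return post


def _residual_moment(post: GFAPosterior, data: GroupedDataset, m: int):
    """Per-variable sum over observed cells of <(x_jn - w_j . z_n)^2>."""
    xz, maskf = _masked(data, m)
    recon = post.W_mean[m] @ post.Z_mean                      # (Dm, N)
    zz = post.zz_moment()
    s = (maskf @ zz.reshape(post.n_samples, -1)).reshape(-1, post.n_factors,
                                                         post.n_factors)
    tr = np.einsum("jkl,jkl->j", post.ww_moment(m), s)
    return (xz ** 2).sum(axis=1) - 2.0 * (xz * recon).sum(axis=1) + tr


def update_tau(post: GFAPosterior, data: GroupedDataset,
               hyper: Hyperparameters) -> GFAPosterior:
    """q(tau_j^(m)) update from observed-cell residual moments only."""
    for m in range(post.n_groups):
        n_obs = data.masks[m].sum(axis=1)
        post.tau_shape[m] = hyper.a_tau + 0.5 * n_obs
        post.tau_rate[m] = hyper.b_tau + 0.5 * _residual_moment(post, data, m)
    return post


def compute_elbo(post: GFAPosterior, data: GroupedDataset,
                 hyper: Hyperparameters) -> float:
    """Evidence lower bound: observed-cell likelihood minus KL terms."""
    K = post.n_factors
    terms = {}

    ll = 0.0
    for m in range(post.n_groups):
        n_obs = data.masks[m].sum(axis=1)
        tau = post.tau_mean(m)
        tau_ln = digamma(post.tau_shape[m]) - np.log(post.tau_rate[m])
        resid = _residual_moment(post, data, m)
        ll += 0.5 * np.sum(n_obs * (tau_ln - _LOG2PI)) - 0.5 * np.sum(tau * resid)
    terms["likelihood"] = ll

    mu = post.Z_mean.T
    kl_z = 0.5 * np.sum(
        np.trace(post.Z_cov, axis1=1, axis2=2)
        + np.sum(mu ** 2, axis=1)
        - K
        - _logdet_batch(post.Z_cov)
    )
    terms["kl_latent"] = -kl_z

    w_term = 0.0
    kl_alpha = 0.0
    kl_tau = 0.0
    for m in range(post.n_groups):
        dm = post.W_mean[m].shape[0]
        alpha_ln = digamma(post.alpha_shape[m]) - np.log(post.alpha_rate[m])
        ew2 = post.W_mean[m] ** 2 + np.diagonal(post.W_cov[m], axis1=1, axis2=2)
        w_term += (
            0.5 * dm * alpha_ln.sum()
            - 0.5 * np.sum(post.alpha_mean(m) * ew2.sum(axis=0))
            + 0.5 * np.sum(_logdet_batch(post.W_cov[m]))
            + 0.5 * dm * K
        )
        kl_alpha += _gamma_kl(post.alpha_shape[m], post.alpha_rate[m],
                              hyper.a_alpha, hyper.b_alpha)
        kl_tau += _gamma_kl(post.tau_shape[m], post.tau_rate[m],
                            hyper.a_tau, hyper.b_tau)
    terms["loadings"] = w_term
    terms["kl_alpha"] = -kl_alpha
    terms["kl_tau"] = -kl_tau

    elbo = sum(terms.values())
    if not np.isfinite(elbo):
        bad = [k for k, v in terms.items() if not np.isfinite(v)]
        raise FloatingPointError(f"non-finite ELBO term(s): {bad}")
    return float(elbo)


def _fit_cycle(post: GFAPosterior, data: GroupedDataset,
               hyper: Hyperparameters, cache: dict) -> float:
    """One full update cycle (latent -> loadings -> alpha -> tau) plus the
    ELBO, sharing intermediates across the steps.

    Numerically identical to calling the public update functions in the
    same order followed by :func:`compute_elbo`; the shared moments just
    avoid recomputing them.
    """
    K, N = post.n_factors, post.n_samples
    xz_l, maskf_l, n_obs_l = cache["xz"], cache["maskf"], cache["n_obs"]

    # q(Z)
    prec = np.broadcast_to(np.eye(K), (N, K, K)).copy()
    rhs = np.zeros((N, K))
    for m in range(post.n_groups):
        tau = post.tau_mean(m)
        tww = tau[:, None, None] * post.ww_moment(m)
        prec += (maskf_l[m].T @ tww.reshape(len(tau), -1)).reshape(N, K, K)
        rhs += xz_l[m].T @ (tau[:, None] * post.W_mean[m])
    post.Z_cov = _inv_batch(prec, "latent precision")
    post.Z_mean = np.einsum("nkl,nl->nk", post.Z_cov, rhs).T

    zz = post.zz_moment()
    zz_flat = zz.reshape(N, -1)
    elbo = 0.0

    for m in range(post.n_groups):
        xz, maskf, n_obs = xz_l[m], maskf_l[m], n_obs_l[m]
        dm = post.W_mean[m].shape[0]

        # q(W), row-wise
        tau = post.tau_mean(m)
        s = (maskf @ zz_flat).reshape(dm, K, K)
        wprec = np.diag(post.alpha_mean(m))[None] + tau[:, None, None] * s
        post.W_cov[m] = _inv_batch(wprec, f"loading precision (group {m})")
        b = xz @ post.Z_mean.T
        post.W_mean[m] = tau[:, None] * np.einsum("jkl,jl->jk", post.W_cov[m], b)

        # q(alpha)
        w_diag = np.diagonal(post.W_cov[m], axis1=1, axis2=2)
        ew2 = post.W_mean[m] ** 2 + w_diag
        post.alpha_shape[m] = np.full(K, hyper.a_alpha + 0.5 * dm)
        post.alpha_rate[m] = hyper.b_alpha + 0.5 * ew2.sum(axis=0)

        # q(tau), reusing the per-row moment sums
        ww = post.ww_moment(m)
        recon = post.W_mean[m] @ post.Z_mean
        resid = (
            (xz ** 2).sum(axis=1)
            - 2.0 * (xz * recon).sum(axis=1)
            + np.einsum("jkl,jkl->j", ww, s)
        )
        post.tau_shape[m] = hyper.a_tau + 0.5 * n_obs
        post.tau_rate[m] = hyper.b_tau + 0.5 * resid

        # group contributions to the bound
        tau = post.tau_mean(m)
        tau_ln = digamma(post.tau_shape[m]) - np.log(post.tau_rate[m])
        elbo += 0.5 * np.sum(n_obs * (tau_ln - _LOG2PI)) - 0.5 * np.sum(tau * resid)
        alpha_ln = digamma(post.alpha_shape[m]) - np.log(post.alpha_rate[m])
        elbo += (
            0.5 * dm * alpha_ln.sum()
            - 0.5 * np.sum(post.alpha_mean(m) * ew2.sum(axis=0))
            + 0.5 * np.sum(_logdet_batch(post.W_cov[m]))
            + 0.5 * dm * K
        )
        elbo -= _gamma_kl(post.alpha_shape[m], post.alpha_rate[m],
                          hyper.a_alpha, hyper.b_alpha)
        elbo -= _gamma_kl(post.tau_shape[m], post.tau_rate[m],
                          hyper.a_tau, hyper.b_tau)

    mu = post.Z_mean.T
    elbo -= 0.5 * np.sum(
        np.trace(post.Z_cov, axis1=1, axis2=2)
        + np.sum(mu ** 2, axis=1)
        - K
        - _logdet_batch(post.Z_cov)
    )
    if not np.isfinite(elbo):
        raise FloatingPointError("non-finite ELBO")
    return float(elbo)


def prune_factors(post: GFAPosterior, threshold: float = 1e-3,
                  rel_threshold: float = 0.05):
    """Drop factors whose loadings are close to zero in every group.

    A factor counts as dead in group m when its loading-column RMS falls
    below ``max(threshold, rel_threshold * max-column-RMS of group m)``;
    factors dead in all groups are removed. The relative part makes
    "close to zero" scale-free: a residual column at a few percent of
    the dominant factor's magnitude is inactive for any practical
    reading of the fit, while genuinely active columns sit at the same
    order as the maximum. Set ``rel_threshold=0`` for a purely absolute
    rule.

    Returns ``(pruned_posterior, retained_indices)``. Raises if everything
    would be pruned (degenerate fit).
    """
    rms = np.stack(
        [np.sqrt(np.mean(w ** 2, axis=0)) for w in post.W_mean]
    )  # (M, K)
    cutoff = np.maximum(threshold, rel_threshold * rms.max(axis=1))
    keep = np.where((rms >= cutoff[:, None]).any(axis=0))[0]
    if keep.size == 0:
        raise ValueError("all factors fell below the pruning threshold")
    ix = np.ix_(keep, keep)
    pruned = GFAPosterior(
        Z_mean=post.Z_mean[keep],
        Z_cov=post.Z_cov[:, ix[0], ix[1]],
        W_mean=[w[:, keep] for w in post.W_mean],
        W_cov=[c[:, ix[0], ix[1]] for c in post.W_cov],
        alpha_shape=[a[keep] for a in post.alpha_shape],
        alpha_rate=[a[keep] for a in post.alpha_rate],
        tau_shape=[t.copy() for t in post.tau_shape],
        tau_rate=[t.copy() for t in post.tau_rate],
    )
    return pruned, keep


def latent_posterior(post: GFAPosterior, data: GroupedDataset,
                     exclude_groups=()):
    """Posterior of z for (possibly new) samples given fitted W and tau.

    Observed cells of all groups not listed in ``exclude_groups``
    contribute; masked cells are dropped from the sums. Returns
    ``(mean (K, N*), cov (N*, K, K))``.
    """
    K = post.n_factors
    n = data.n_samples
    exclude = {int(g) for g in np.atleast_1d(np.asarray(exclude_groups, dtype=int))}
    prec = np.broadcast_to(np.eye(K), (n, K, K)).copy()
    rhs = np.zeros((n, K))
    for m in range(post.n_groups):
        if m in exclude:
            continue
        xz, maskf = _masked(data, m)
        tau = post.tau_mean(m)
        tww = tau[:, None, None] * post.ww_moment(m)
        prec += (maskf.T @ tww.reshape(len(tau), -1)).reshape(n, K, K)
        rhs += xz.T @ (tau[:, None] * post.W_mean[m])
    cov = _inv_batch(prec, "predictive latent precision")
    mean = np.einsum("nkl,nl->nk", cov, rhs).T
    return mean, cov


# ---------------------------------------------------------------------------
# estimator
# ---------------------------------------------------------------------------

class GFA(TransformerMixin, BaseEstimator):
    """Group factor analysis estimator with missing-data-aware inference.

    Parameters
    ----------
    n_factors : int, default=15
        Initial number of latent factors K; irrelevant ones are driven to
        zero by the ARD prior and can be removed with :meth:`prune`.
    a_alpha, b_alpha, a_tau, b_tau : float, default=1e-14
        Gamma hyperparameters of the ARD and noise precision priors
        (uninformative by default).
    tol : float, default=1e-6
        Relative ELBO change below which the fit is declared converged.
    max_iter : int, default=10000
        Iteration cap; hitting it sets ``converged_ = False``.
    random_state : int, RandomState or None
        Seed for the random initialisation.

    Attributes
    ----------
    loadings_ : list of ndarray ``(Dm, K)``
        Posterior mean loading matrix per group.
    latent_mean_ : ndarray ``(K, N)``
        Posterior mean latent variables of the training samples.
    alpha_ : list of ndarray ``(K,)``
        Posterior mean ARD precisions per group.
    tau_ : list of ndarray ``(Dm,)``
        Posterior mean noise precisions per variable.
    elbo_ : float
        Final evidence lower bound.
    trace_ : :class:`ELBOTrace`
    posterior_ : :class:`GFAPosterior`
        Full variational posterior.

    Examples
    --------
    >>> from groupfa.simulate import make_design, generate
    >>> data, truth = generate(make_design(200), D=(12, 8), seed=0)
    >>> model = GFA(n_factors=6, random_state=0).fit(data)
    >>> model.latent_mean_.shape
    (6, 160)
    """

    def __init__(self, n_factors=15, a_alpha=1e-14, b_alpha=1e-14,
                 a_tau=1e-14, b_tau=1e-14, tol=1e-6, max_iter=10000,
                 random_state=None, verbose=0):
        self.n_factors = n_factors
        self.a_alpha = a_alpha
        self.b_alpha = b_alpha
        self.a_tau = a_tau
        self.b_tau = b_tau
        self.tol = tol
        self.max_iter = max_iter
        self.random_state = random_state
        self.verbose = verbose

    # -- plumbing ---------------------------------------------------------
    def _hyper(self, seed=0) -> Hyperparameters:
        return Hyperparameters(
            K=self.n_factors, a_alpha=self.a_alpha, b_alpha=self.b_alpha,
            a_tau=self.a_tau, b_tau=self.b_tau, tol=self.tol,
            max_iter=self.max_iter, seed=seed,
        )

    @staticmethod
    def _as_dataset(X) -> GroupedDataset:
        if isinstance(X, GroupedDataset):
            return X
        if isinstance(X, (list, tuple)):
            # sklearn orientation: one (n_samples, n_features_m) block per group
            return GroupedDataset(groups=[np.asarray(x, dtype=float).T for x in X])
        raise TypeError(
            "X must be a GroupedDataset or a list of (n_samples, n_features) arrays"
        )

    # -- fitting ----------------------------------------------------------
    def fit(self, X, y=None):
        """Run variational EM to convergence on ``X``.

        ``X`` is a :class:`GroupedDataset` or a list of
        ``(n_samples, n_features_m)`` arrays (NaN marks missing cells).
        """
        data = self._as_dataset(X)
        data.check_variable_coverage()
        rng = check_random_state(self.random_state)
        hyper = self._hyper()
        post = init_posterior(data, hyper, rng=np.random.default_rng(
            rng.randint(np.iinfo(np.int32).max)))
        trace = ELBOTrace()
        prev = -np.inf
        cache = {
            "xz": [np.where(data.masks[m], data.groups[m], 0.0)
                   for m in range(data.n_groups)],
            "maskf": [m.astype(float) for m in data.masks],
            "n_obs": [m.sum(axis=1) for m in data.masks],
        }
        for it in range(self.max_iter):
            elbo = _fit_cycle(post, data, hyper, cache)
            trace.values.append(elbo)
            if self.verbose and it % 50 == 0:
                logger.info("iter %d ELBO %.6f", it, elbo)
            if np.isfinite(prev) and abs(elbo - prev) < self.tol * abs(elbo):
                trace.converged = True
                break
            prev = elbo
        self.posterior_ = post
        self.trace_ = trace
        self.converged_ = trace.converged
        self.n_iter_ = trace.n_iter
        self.elbo_ = trace.values[-1]
        self.loadings_ = post.W_mean
        self.latent_mean_ = post.Z_mean
        self.alpha_ = [post.alpha_mean(m) for m in range(post.n_groups)]
        self.tau_ = [post.tau_mean(m) for m in range(post.n_groups)]
        self.n_groups_ = post.n_groups
        return self

    def transform(self, X):
        """Posterior mean latent variables for new samples, ``(n_samples, K)``."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "posterior_")
        data = self._as_dataset(X)
        mean, _ = latent_posterior(self.posterior_, data)
        return mean.T

    def prune(self, threshold: float = 1e-3, rel_threshold: float = 0.05):
        """Return ``(pruned GFA, retained factor indices)``.

        The returned estimator shares hyperparameters but holds only the
        factors that :func:`prune_factors` considers active in at least
        one group.
        """
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "posterior_")
        pruned, keep = prune_factors(self.posterior_, threshold, rel_threshold)
        logger.info("pruning threshold %g: retained %d of %d factors",
                    threshold, len(keep), self.posterior_.n_factors)
        out = GFA(**self.get_params())
        out.n_factors = len(keep)
        out.posterior_ = pruned
        out.trace_ = self.trace_
        out.converged_ = self.converged_
        out.n_iter_ = self.n_iter_
        out.elbo_ = self.elbo_
        out.loadings_ = pruned.W_mean
        out.latent_mean_ = pruned.Z_mean
        out.alpha_ = [pruned.alpha_mean(m) for m in range(pruned.n_groups)]
        out.tau_ = [pruned.tau_mean(m) for m in range(pruned.n_groups)]
        out.n_groups_ = pruned.n_groups
        return out, keep

    def score(self, X=None, y=None):
        """Final ELBO of the fit (higher is better)."""
        return self.elbo_
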