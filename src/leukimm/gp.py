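"""Variational Gaussian-process binary classification.

A full-rank GP classifier with a Bernoulli-logit likelihood and a whitened
mean-field variational posterior over the latent function at the training
points.  The evidence lower bound is maximized with Adam; expectations of the
log likelihood under the Gaussian posterior are computed with Gauss-Hermite
quadrature, so the fit is deterministic (no Monte Carlo sampling).

Model
-----
    f ~ GP(0, k),   k(x, x') = sigma_f^2 * exp(-||x - x'||^2 / (2 l^2))
    y_i | f_i ~ Bernoulli(sigmoid(f_i)),  y_i in {-1, +1}

With K = k(X, X) + jitter*I and L = chol(K), the latent vector is whitened as
f = L v with q(v) = N(m, diag(s)).  The KL term of the ELBO is then the
standard-normal KL, independent of the kernel hyperparameters, which keeps
every Adam step at O(n^2) cost.  Hyperparameters (log lengthscale, log signal
variance) enter only through the expected log likelihood and are updated on a
thinned schedule with central-difference gradients and an integrated step size
(see `hyper_every`).
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.linalg import cholesky, solve_triangular
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

__all__ = ["VariationalGPClassifier", "rbf_kernel_matrix"]


def rbf_kernel_matrix(
    X1: np.ndarray,
    X2: np.ndarray,
    lengthscale: float = 1.0,
    signal_variance: float = 1.0,
) -> np.ndarray:
    """Squared-exponential kernel Gram matrix.

    K[i, j] = signal_variance * exp(-||x1_i - x2_j||^2 / (2 * lengthscale^2)).
    Symmetric when called with X1 is X2.
    """
    X1 = np.atleast_2d(np.asarray(X1, dtype=float))
    X2 = np.atleast_2d(np.asarray(X2, dtype=float))
    if X1.shape[1] != X2.shape[1]:
        raise ValueError(
            f"inconsistent encoding dimensions: {X1.shape[1]} vs {X2.shape[1]}"
        )
    d2 = cdist(X1, X2, metric="sqeuclidean")
    return signal_variance * np.exp(-d2 / (2.0 * lengthscale**2))


def _log_sigmoid(z: np.ndarray) -> np.ndarray:
    # log(sigmoid(z)) computed stably for large |z|
    return np.where(z >= 0, -np.log1p(np.exp(-np.abs(z))), z - np.log1p(np.exp(-np.abs(z))))


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


class _Adam:
    def __init__(self, shape, lr, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = np.zeros(shape)
        self.v = np.zeros(shape)
        self.t = 0

    def step(self, grad):
        """Return the parameter increment for an ascent step along `grad`."""
        self.t += 1
        self.m = self.b1 * self.m + (1 - self.b1) * grad
        self.v = self.b2 * self.v + (1 - self.b2) * grad**2
        mhat = self.m / (1 - self.b1**self.t)
        vhat = self.v / (1 - self.b2**self.t)
        return self.lr * mhat / (np.sqrt(vhat) + self.eps)


class VariationalGPClassifier(BaseEstimator, ClassifierMixin):
    """GP binary classifier on numeric features.

    Parameters
    ----------
    lengthscale, signal_variance:
        Initial values of the kernel hyperparameters; both are learned.
    iterations:
        Number of Adam steps on the variational parameters.
    learning_rate:
        Adam step size.
    hyper_every:
        Kernel hyperparameters are updated every `hyper_every`-th iteration
        with an integrated step size of ``learning_rate * hyper_every``, so the
        per-iteration movement matches a dense schedule while the Cholesky
        refactorizations stay cheap.  The signal-variance gradient is analytic
        (the whitened latent scales with its square root); the lengthscale
        gradient uses a central finite difference of the expected log
        likelihood.
    jitter:
        Added to the kernel diagonal for numerical stability.
    n_quad:
        Number of Gauss-Hermite nodes for likelihood expectations.

    Attributes
    ----------
    X_train_, y_train_ : training data (labels in {-1, +1})
    m_, s_ : whitened variational mean and variances
    lengthscale_, signal_variance_ : learned hyperparameters
    L_ : Cholesky factor of the final training kernel
    elbo_ : final evidence lower bound (raises if non-finite during fit)
    """

    def __init__(
        self,
        lengthscale: float = 1.0,
        signal_variance: float = 1.0,
        iterations: int = 2000,
        learning_rate: float = 0.005,
        hyper_every: int = 10,
        jitter: float = 1e-6,
        n_quad: int = 20,
        random_state: int = 0,
    ):
        self.lengthscale = lengthscale
        self.signal_variance = signal_variance
        self.iterations = iterations
        self.learning_rate = learning_rate
        self.hyper_every = hyper_every
        self.jitter = jitter
        self.n_quad = n_quad
        self.random_state = random_state

    # -- ELBO pieces ------------------------------------------------------

    def _chol(self, d2: np.ndarray, log_ls: float, log_sv: float) -> np.ndarray:
        K = np.exp(log_sv) * np.exp(-d2 / (2.0 * np.exp(2.0 * log_ls)))
        K[np.diag_indices_from(K)] += self.jitter
        return cholesky(K, lower=True)

    def _expected_loglik(self, L, m, s, y, t_nodes, w_nodes, return_grads=False):
        mu = L @ m
        var = (L**2) @ s
        sd = np.sqrt(2.0 * var)
        # f values at quadrature nodes: (n, q)
        f = mu[:, None] + sd[:, None] * t_nodes[None, :]
        yz = y[:, None] * f
        E = float(np.sum(_log_sigmoid(yz) @ w_nodes))
        if not return_grads:
            return E
        g = _sigmoid(-yz) * y[:, None]  # d log sigmoid(y f)/df
        g_mu = g @ w_nodes
        g_var = (g * t_nodes[None, :]) @ w_nodes / sd
        grad_m = L.T @ g_mu
        grad_s = (L**2).T @ g_var
        return E, grad_m, grad_s

    # -- sklearn API ------------------------------------------------------

    def fit(self, X, y):
        X, y01 = check_X_y(np.asarray(X, dtype=float), y)
        self.classes_ = np.unique(y01)
        if len(self.classes_) != 2:
            raise ValueError("VariationalGPClassifier requires exactly two classes")
        y = np.where(y01 == self.classes_[1], 1.0, -1.0)
        n = X.shape[0]

        t_nodes, w_nodes = hermegauss(self.n_quad)  # weight exp(-t^2/2)
        w_nodes = w_nodes / np.sqrt(2.0 * np.pi)

        d2 = cdist(X, X, metric="sqeuclidean")
        log_ls = np.log(float(self.lengthscale))
        log_sv = np.log(float(self.signal_variance))
        L = self._chol(d2, log_ls, log_sv)

        m = np.zeros(n)
        rho = np.zeros(n)  # log variational variances
        adam_m = _Adam(n, self.learning_rate)
        adam_rho = _Adam(n, self.learning_rate)
        adam_hyp = _Adam(2, self.learning_rate * self.hyper_every)
        fd_eps = 1e-3

        elbo = -np.inf
        for it in range(int(self.iterations)):
            s = np.exp(rho)
            E, gm, gs = self._expected_loglik(L, m, s, y, t_nodes, w_nodes, True)
            kl = 0.5 * float(np.sum(m**2 + s - rho - 1.0))
            elbo = E - kl
            if not np.isfinite(elbo):
                raise FloatingPointError(f"non-finite ELBO at iteration {it}")
            grad_m = gm - m
            grad_rho = (gs - 0.5 * (1.0 - 1.0 / s)) * s
            m = m + adam_m.step(grad_m)
            rho = rho + adam_rho.step(grad_rho)

            if (it + 1) % self.hyper_every == 0:
                # gradient of the expected log likelihood in the hyperparameters
                # (the whitened KL does not depend on them): central finite
                # difference for log lengthscale, analytic for log signal
                # variance (mu and var scale with sv and sv^... via f ~ sqrt(sv))
                Ep = self._expected_loglik(
                    self._chol(d2, log_ls + fd_eps, log_sv), m, s, y, t_nodes, w_nodes
                )
                Em = self._expected_loglik(
                    self._chol(d2, log_ls - fd_eps, log_sv), m, s, y, t_nodes, w_nodes
                )
                g_ls = (Ep - Em) / (2 * fd_eps)
                mu = L @ m
                var = (L**2) @ s
                sd = np.sqrt(2.0 * var)
                f = mu[:, None] + sd[:, None] * t_nodes[None, :]
                g = _sigmoid(-(y[:, None] * f)) * y[:, None]
                g_mu = g @ w_nodes
                g_var = (g * t_nodes[None, :]) @ w_nodes / sd
                # d mu/d log sv = mu/2, d var/d log sv = var (jitter negligible)
                g_sv = float(np.sum(g_mu * 0.5 * mu + g_var * var))
                step = adam_hyp.step(np.array([g_ls, g_sv]))
                log_ls += step[0]
                log_sv += step[1]
                L = self._chol(d2, log_ls, log_sv)

        self.X_train_ = X
        self.y_train_ = y
        self.m_ = m
        self.s_ = np.exp(rho)
        self.lengthscale_ = float(np.exp(log_ls))
        self.signal_variance_ = float(np.exp(log_sv))
        self.L_ = L
        self.elbo_ = float(elbo)
        self._t_nodes = t_nodes
        self._w_nodes = w_nodes
        return self

    def decision_function(self, X):
        """Posterior mean of the latent function at X."""
        check_is_fitted(self, "L_")
        X = check_array(np.asarray(X, dtype=float))
        Ks = rbf_kernel_matrix(
            self.X_train_, X, self.lengthscale_, self.signal_variance_
        )
        a = solve_triangular(self.L_, Ks, lower=True)
        return a.T @ self.m_

    def _latent(self, X):
        Ks = rbf_kernel_matrix(
            self.X_train_, X, self.lengthscale_, self.signal_variance_
        )
        a = solve_triangular(self.L_, Ks, lower=True)
        mu = a.T @ self.m_
        kss = self.signal_variance_ + self.jitter
        var = kss - np.sum(a**2, axis=0) + (a**2).T @ self.s_
        return mu, np.maximum(var, 1e-12)

    def predict_proba(self, X):
        check_is_fitted(self, "L_")
        X = check_array(np.asarray(X, dtype=float))
        mu, var = self._latent(X)
        f = mu[:, None] + np.sqrt(2.0 * var)[:, None] * self._t_nodes[None, :]
        p1 = _sigmoid(f) @ self._w_nodes
        return np.column_stack([1.0 - p1, p1])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        return self.classes_[(p >= 0.5).astype(int)]
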