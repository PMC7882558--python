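"""Bayesian Gaussian regression with autoregressive residuals.

Model for an annual response y_t with design row x_t:

    y_t = x_t' beta + eps_t,        eps_t = sum_k phi_k eps_{t-k} + u_t,
    u_t ~ Normal(0, sigma^2)  (innovation variance).

Estimation is by conjugate-block Gibbs sampling: the regression block uses
quasi-differenced data given the AR coefficients, the AR block is a
regression of residuals on their own lags given beta, and the innovation
variance is inverse-gamma. The likelihood conditions on the first `ar_order`
observations. Missing responses are treated as latent and re-imputed from
their Gaussian full conditional each sweep; missing covariates are not
allowed.

Priors (diffuse, configurable): coefficients and AR terms Normal(0, 1e6),
variance InverseGamma(0.001, 0.001). AR coefficients are not truncated to
the stationary region; a stationarity diagnostic is reported instead.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .summaries import Draws, summarize


def _sample_mvn_coef(rng, XtX, Xty, sig2, prior_prec):
    """Draw from N(A^-1 b, A^-1) with A = XtX/sig2 + prior_prec*I."""
    k = XtX.shape[0]
    A = XtX / sig2 + prior_prec * np.eye(k)
    b = Xty / sig2
    L = np.linalg.cholesky(A)
    mean = np.linalg.solve(A, b)
    z = rng.standard_normal(k)
    return mean + np.linalg.solve(L.T, z)


class BayesianARRegression(BaseEstimator):
    """Linear regression with AR(p) residuals, fit by Gibbs sampling.

    Parameters
    ----------
    ar_order : int
        Order p of the residual autoregression (0 = ordinary regression);
        shorthand for ``ar_lags = (1, ..., p)``.
    ar_lags : tuple of int or None
        Explicit residual lags, possibly non-contiguous (e.g. ``(2,)`` for a
        pure second-order term). Overrides `ar_order` when given.
    fit_intercept : bool
        Prepend a constant column to the design.
    chains, draws : int
        Number of chains and retained draws per chain; an equal number of
        warm-up sweeps is run and discarded first.
    coef_prior_var : float
        Prior variance of regression and AR coefficients (Normal, mean 0).
    var_prior_a, var_prior_b : float
        Inverse-gamma shape/scale for the innovation variance.
    random_state : int or None
        Seed; fixed seeds give bit-reproducible draws.

    Attributes
    ----------
    draws_ : Draws
        Posterior draws for "beta[...]", "phi[k]" and "sigma2".
    summary_ : pandas.DataFrame
        Median / 95% CI / R-hat table.
    converged_ : bool
        All R-hat below `rhat_threshold`.
    stationary_frac_ : float
        Fraction of draws whose AR polynomial is stationary (1.0 when p = 0).
    """

    def __init__(self, ar_order: int = 0, ar_lags=None, fit_intercept: bool = True,
                 chains: int = 2, draws: int = 1000,
                 coef_prior_var: float = 1e6,
                 var_prior_a: float = 0.001, var_prior_b: float = 0.001,
                 rhat_threshold: float = 1.05, random_state=None):
        self.ar_order = ar_order
        self.ar_lags = ar_lags
        self.fit_intercept = fit_intercept
        self.chains = chains
        self.draws = draws
        self.coef_prior_var = coef_prior_var
        self.var_prior_a = var_prior_a
        self.var_prior_b = var_prior_b
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def _lags(self) -> list[int]:
        if self.ar_lags is not None:
            lags = sorted(set(int(l) for l in self.ar_lags))
            if lags and lags[0] < 1:
                raise ValueError("ar_lags must be >= 1")
            return lags
        if self.ar_order < 0:
            raise ValueError("ar_order must be >= 0")
        return list(range(1, self.ar_order + 1))

    def fit(self, X, y, param_names: list[str] | None = None):
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        if not np.all(np.isfinite(X)):
            raise ValueError("design matrix contains non-finite values; "
                             "missing covariates are not supported")
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        n, k = X.shape
        lags = self._lags()
        p = max(lags) if lags else 0
        q = len(lags)
        if n <= p + k:
            raise ValueError(f"series too short: n={n}, need > max lag + n_coef = {p + k}")

        if param_names is None:
            param_names = [f"beta[{i}]" for i in range(k - int(self.fit_intercept))]
        names = (["intercept"] if self.fit_intercept else []) + list(param_names)
        if len(names) != k:
            raise ValueError("param_names length mismatch")
        all_names = names + [f"phi[{l}]" for l in lags] + ["sigma2"]

        obs = np.isfinite(y)
        if obs.sum() <= p + k:
            raise ValueError("too few observed responses")
        missing = np.where(~obs)[0]
        lag_index = {l: j for j, l in enumerate(lags)}

        seed_seq = np.random.SeedSequence(self.random_state)
        chain_seeds = seed_seq.spawn(self.chains)
        keep = self.draws
        total = 2 * keep  # first half warm-up
        store = {nm: np.empty((self.chains, keep)) for nm in all_names}
        n_station = 0

        for c in range(self.chains):
            rng = np.random.default_rng(chain_seeds[c])
            y_imp = y.copy()
            y_imp[missing] = np.nanmean(y) + rng.standard_normal(len(missing)) * np.nanstd(y)
            beta = np.linalg.lstsq(X[obs], y[obs], rcond=None)[0]
            beta += rng.standard_normal(k) * 0.1 * (np.abs(beta) + 0.1)
            phi = np.zeros(q)
            sig2 = max(np.var(y_imp - X @ beta), 1e-8)

            for it in range(total):
                # --- beta | phi, sigma2 (quasi-differenced rows t >= p)
                if q:
                    yt = y_imp[p:].copy()
                    Xt = X[p:].copy()
                    for l in lags:
                        yt -= phi[lag_index[l]] * y_imp[p - l:n - l]
                        Xt -= phi[lag_index[l]] * X[p - l:n - l]
                else:
                    yt, Xt = y_imp, X
                beta = _sample_mvn_coef(rng, Xt.T @ Xt, Xt.T @ yt, sig2,
                                        1.0 / self.coef_prior_var)
                eps = y_imp - X @ beta

                # --- phi | beta, sigma2
                if q:
                    E = np.column_stack([eps[p - l:n - l] for l in lags])
                    phi = _sample_mvn_coef(rng, E.T @ E, E.T @ eps[p:], sig2,
                                           1.0 / self.coef_prior_var)
                    u = eps[p:] - E @ phi
                else:
                    u = eps

                # --- sigma2
                m = n - p
                sig2 = 1.0 / rng.gamma(self.var_prior_a + 0.5 * m,
                                       1.0 / (self.var_prior_b + 0.5 * float(u @ u)))

                # --- impute missing responses; each latent residual carries a
                # weak proper prior N(0, 100 sigma^2) so that residuals barely
                # tied to the likelihood (e.g. via a near-zero AR weight)
                # cannot wander off and destabilise the AR block
                for t in missing:
                    prec = 0.01
                    lin = 0.0
                    for s in range(max(t, p), min(t + p, n - 1) + 1):
                        if s == t:
                            c_s = 1.0
                        elif (s - t) in lag_index:
                            c_s = -phi[lag_index[s - t]]
                        else:
                            continue
                        if c_s == 0.0:
                            continue
                        u_s = eps[s] - sum(phi[lag_index[l]] * eps[s - l] for l in lags)
                        a_s = u_s - c_s * eps[t]
                        prec += c_s * c_s
                        lin += -c_s * a_s
                    if prec > 0:
                        eps_t = lin / prec + rng.standard_normal() * np.sqrt(sig2 / prec)
                    else:  # an initial conditioned-on value with no usable term
                        eps_t = rng.standard_normal() * np.sqrt(sig2)
                    eps[t] = eps_t
                    y_imp[t] = X[t] @ beta + eps_t

                if it >= keep:
                    i = it - keep
                    for nm, val in zip(names, beta):
                        store[nm][c, i] = val
                    for l in lags:
                        store[f"phi[{l}]"][c, i] = phi[lag_index[l]]
                    store["sigma2"][c, i] = sig2
                    if q == 0:
                        n_station += 1
                    else:
                        poly = np.zeros(p + 1)
                        poly[0] = 1.0
                        for l in lags:
                            poly[l] = -phi[lag_index[l]]
                        if np.all(np.abs(np.roots(poly)) < 1):
                            n_station += 1

        self.ar_lags_ = lags
        self.param_names_ = all_names
        self.draws_ = Draws(store)
        self.summary_ = summarize(self.draws_)
        psr = self.summary_["psr"].to_numpy()
        self.converged_ = bool(np.all(psr[np.isfinite(psr)] < self.rhat_threshold))
        self.stationary_frac_ = n_station / (self.chains * keep)
        self.coef_ = np.array([np.median(store[nm]) for nm in names])
        self.n_obs_ = int(obs.sum())
        return self

    def predict(self, X):
        """Posterior-median structural mean (no AR residual forecast)."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if self.fit_intercept:
            X = np.column_stack([np.ones(len(X)), X])
        return X @ self.coef_


def sample_ar_regression(y, X, ar_order=0, chains=2, draws=1000, seed=None,
                         param_names=None, **priors) -> Draws:
    """Functional wrapper over :class:`BayesianARRegression`; returns draws."""
    est = BayesianARRegression(ar_order=ar_order, chains=chains, draws=draws,
                               fit_intercept=True, random_state=seed, **priors)
    est.fit(X, y, param_names=param_names)
    return est.draws_
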