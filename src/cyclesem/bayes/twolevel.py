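"""Two-level Gaussian regression with latent-group-mean centering.

Clusters j (years) contain units i (nests). Within-cluster predictors are
decomposed into latent cluster means and within deviations, and the within
slopes act on the deviations only:

    x_ij = mu_j + delta_ij,                delta_ij ~ N(0, diag(s2_x))
    y_ij = alpha_j + w'(x_ij - mu_j) + e,  e ~ N(0, s2_e)
    alpha_j = g0 + g'z_j [+ c'mu_j] + u_j, u ~ N(0, psi)
    mu_j ~ N(nu, diag(tau2))

The random intercept alpha_j is the latent cluster mean of y, regressed on
cluster-level covariates z_j and (optionally, `contextual=True`) on the
latent predictor means. All blocks are conjugate and sampled by Gibbs.
Observed-mean centering is available as a fallback (`centering="observed"`),
in which case cluster means of x are fixed at their sample values.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .summaries import Draws, summarize


def _ig_draw(rng, a, b):
    return 1.0 / rng.gamma(a, 1.0 / b)


class TwoLevelRegression(BaseEstimator):
    """Gibbs sampler for the two-level latent-mean-centered regression.

    Attributes after fit: ``draws_``, ``summary_``, ``converged_``,
    ``latent_means_`` (posterior-mean cluster intercepts).
    """

    def __init__(self, chains: int = 2, draws: int = 800, contextual: bool = False,
                 centering: str = "latent", coef_prior_var: float = 1e6,
                 var_prior_a: float = 0.001, var_prior_b: float = 0.001,
                 rhat_threshold: float = 1.05, random_state=None):
        self.chains = chains
        self.draws = draws
        self.contextual = contextual
        self.centering = centering
        self.coef_prior_var = coef_prior_var
        self.var_prior_a = var_prior_a
        self.var_prior_b = var_prior_b
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    def fit(self, X, y, groups, Z=None, within_names=None, between_names=None):
        """Fit from unit-level X (n, q), y (n,), cluster codes and optional
        cluster-level covariates Z (J, r) aligned with sorted unique groups."""
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        y = np.asarray(y, dtype=float).ravel()
        codes, uniq = _group_codes(groups)
        J = len(uniq)
        if J < 2:
            raise ValueError("need >= 2 clusters; the between level is unidentified")
        n, q = X.shape
        nj = np.bincount(codes, minlength=J).astype(float)
        Z = np.zeros((J, 0)) if Z is None else np.asarray(Z, dtype=float)
        r = Z.shape[1]
        if within_names is None:
            within_names = [f"x{i}" for i in range(q)]
        if between_names is None:
            between_names = [f"z{i}" for i in range(r)]

        a0, b0 = self.var_prior_a, self.var_prior_b
        pp = 1.0 / self.coef_prior_var
        names = ([f"w[{nm}]" for nm in within_names] + ["between_intercept"]
                 + [f"b[{nm}]" for nm in between_names]
                 + ([f"b_mu[{nm}]" for nm in within_names] if self.contextual else [])
                 + ["sigma2_within", "psi_between"])
        keep = self.draws
        store = {nm: np.empty((self.chains, keep)) for nm in names}
        alpha_accum = np.zeros(J)

        xbar = np.stack([np.bincount(codes, X[:, d], minlength=J) / nj for d in range(q)], axis=1)
        ybar = np.bincount(codes, y, minlength=J) / nj
        seeds = np.random.SeedSequence(self.random_state).spawn(self.chains)

        for ci in range(self.chains):
            rng = np.random.default_rng(seeds[ci])
            mu = xbar.copy()
            alpha = ybar + rng.standard_normal(J) * 0.1
            cx = X - mu[codes]
            w = np.linalg.lstsq(cx, y - alpha[codes], rcond=None)[0]
            s2_e = max(np.var(y - alpha[codes] - cx @ w), 1e-8)
            s2_x = np.maximum(cx.var(axis=0), 1e-8)
            psi = max(np.var(ybar), 1e-8)
            tau2 = np.maximum(xbar.var(axis=0), 1e-8)
            nu = xbar.mean(axis=0)
            nb = 1 + r + (q if self.contextual else 0)
            gam = np.zeros(nb)
            gam[0] = alpha.mean()

            for it in range(2 * keep):
                B = np.column_stack([np.ones(J), Z] + ([mu] if self.contextual else []))
                # latent predictor means
                if self.centering == "latent":
                    sx = np.stack([np.bincount(codes, X[:, d], minlength=J) for d in range(q)], axis=1)
                    rres = y - alpha[codes] - X @ w  # = resid - w'mu
                    sr = np.bincount(codes, rres, minlength=J)
                    A = (nj[:, None, None] * (np.diag(1.0 / s2_x) + np.outer(w, w) / s2_e)[None]
                         + np.diag(1.0 / tau2)[None])
                    bvec = sx / s2_x + (-sr[:, None]) * w / s2_e + nu / tau2
                    if self.contextual:
                        cvec = gam[1 + r:]
                        A = A + (np.outer(cvec, cvec) / psi)[None]
                        resid_b = alpha - B[:, :1 + r] @ gam[:1 + r]
                        bvec = bvec + resid_b[:, None] * cvec / psi
                    L = np.linalg.cholesky(A)
                    mean = np.linalg.solve(A, bvec[..., None])[..., 0]
                    zdraw = rng.standard_normal((J, q))
                    mu = mean + np.linalg.solve(np.transpose(L, (0, 2, 1)), zdraw[..., None])[..., 0]
                    cx = X - mu[codes]
                    B = np.column_stack([np.ones(J), Z] + ([mu] if self.contextual else []))
                # cluster intercepts
                mjm = B @ gam
                prec = nj / s2_e + 1.0 / psi
                lin = np.bincount(codes, y - cx @ w, minlength=J) / s2_e + mjm / psi
                alpha = lin / prec + rng.standard_normal(J) / np.sqrt(prec)
                # within slopes
                A = cx.T @ cx / s2_e + pp * np.eye(q)
                bvec = cx.T @ (y - alpha[codes]) / s2_e
                L = np.linalg.cholesky(A)
                w = np.linalg.solve(A, bvec) + np.linalg.solve(L.T, rng.standard_normal(q))
                # between coefficients
                A = B.T @ B / psi + pp * np.eye(nb)
                bvec = B.T @ alpha / psi
                L = np.linalg.cholesky(A)
                gam = np.linalg.solve(A, bvec) + np.linalg.solve(L.T, rng.standard_normal(nb))
                # variances
                res_w = y - alpha[codes] - cx @ w
                s2_e = _ig_draw(rng, a0 + 0.5 * n, b0 + 0.5 * res_w @ res_w)
                res_b = alpha - B @ gam
                psi = _ig_draw(rng, a0 + 0.5 * J, b0 + 0.5 * res_b @ res_b)
                for d in range(q):
                    s2_x[d] = _ig_draw(rng, a0 + 0.5 * n, b0 + 0.5 * cx[:, d] @ cx[:, d])
                    dm = mu[:, d] - nu[d]
                    tau2[d] = _ig_draw(rng, a0 + 0.5 * J, b0 + 0.5 * dm @ dm)
                nu = mu.mean(axis=0) + rng.standard_normal(q) * np.sqrt(tau2 / J)

                if it >= keep:
                    i = it - keep
                    vals = np.concatenate([w, gam, [s2_e, psi]])
                    for nm, v in zip(names, vals):
                        store[nm][ci, i] = v
                    alpha_accum += alpha / (keep * self.chains)

        self.draws_ = Draws(store)
        self.summary_ = summarize(self.draws_)
        psr = self.summary_["psr"].to_numpy()
        self.converged_ = bool(np.all(psr[np.isfinite(psr)] < self.rhat_threshold))
        self.latent_means_ = alpha_accum
        self.groups_ = uniq
        return self


def _group_codes(groups):
    uniq, codes = np.unique(np.asarray(groups), return_inverse=True)
    return codes, uniq


def sample_twolevel(X, y, groups, Z=None, chains=2, draws=800, seed=None,
                    **kwargs) -> Draws:
    """Functional wrapper over :class:`TwoLevelRegression`; returns draws."""
    est = TwoLevelRegression(chains=chains, draws=draws, random_state=seed, **kwargs)
    est.fit(X, y, groups, Z=Z)
    return est.draws_
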