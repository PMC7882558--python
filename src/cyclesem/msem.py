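"""Two-level structural equation model for nest-level fledgling production.

Nests i are clustered in years j. Every within-year response has a random
intercept — its latent year mean — and within-year predictors are centered
at their latent year means (latent-group-mean centering), so within and
between associations are cleanly separated.

Within a year (deviations from latent year means, d = value - alpha_j):

    d_clutch = bH * d_hatch + e_C
    d_fled   = bC * d_clutch + bT * d_temp + bP * d_precip
               + bTP * d_temp * d_precip + e_F
    (d_temp, d_precip) ~ N(0, Sigma_w),  d_hatch ~ N(0, s2_H)

Between years, with annual winter-temperature windows Eur_j and Afr_j:

    alpha_hatch  = g_H0 + g_HE Eur + g_HA Afr + u_H
    alpha_clutch = g_C0 + g_Ch alpha_hatch + g_CE Eur + g_CA Afr + u_C
    alpha_fled   = g_F0 + g_Fc alpha_clutch + g_FT alpha_temp
                   + g_FP alpha_precip + g_FE Eur + g_FA Afr + u_F
    (alpha_temp, alpha_precip) ~ N(mu_b, Sigma_b)

Hatching date reaches fledglings only through clutch size (no direct
hatch -> fledglings path by default; `direct_hatch_path=True` adds it at
the between level as a sensitivity option). Climate windows exist only at
the between level. Everything is Gaussian; fledgling counts are modelled
linearly.

Sampling is conjugate-block Gibbs: latent year means one variable at a time
(each full conditional is Gaussian — the bilinear interaction is linear in
one weather mean given the other), then within slopes, within
(co)variances, between regressions and between (co)variances. Effect
decompositions (total = direct + indirect, indirect split into the hatch
and clutch routes) and interaction simple slopes are evaluated draw by
draw.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import invwishart
from sklearn.base import BaseEstimator

from .bayes import Draws, summarize

WITHIN_PARAMS = [
    "w_fled_on_temp", "w_fled_on_precip", "w_fled_on_interaction",
    "w_fled_on_clutch", "w_clutch_on_hatch",
    "w_temp_precip_cov", "w_temp_var", "w_precip_var", "w_hatch_var",
    "w_fled_resid_var", "w_clutch_resid_var",
]
BETWEEN_PARAMS = [
    "b_fled_on_clutch", "b_fled_on_temp", "b_fled_on_precip",
    "b_fled_on_eur_winter_temp", "b_fled_on_afr_winter_temp",
    "b_clutch_on_hatch", "b_clutch_on_eur_winter_temp", "b_clutch_on_afr_winter_temp",
    "b_hatch_on_eur_winter_temp", "b_hatch_on_afr_winter_temp",
    "b_temp_mean", "b_precip_mean",
    "b_fled_intercept", "b_clutch_intercept", "b_hatch_intercept",
    "b_temp_precip_cov", "b_temp_var", "b_precip_var",
    "b_fled_resid_var", "b_clutch_resid_var", "b_hatch_resid_var",
]


class MSEMSpec:
    """Nest table keyed to year clusters plus the two between covariates."""

    def __init__(self, nests: pd.DataFrame, between: pd.DataFrame):
        need = {"year", "hatch_date", "clutch", "fledglings", "nest_temp", "nest_precip"}
        if not need <= set(nests.columns):
            raise ValueError(f"nest table missing columns {sorted(need - set(nests.columns))}")
        bneed = {"year", "eur_winter_temp", "afr_winter_temp"}
        if not bneed <= set(between.columns):
            raise ValueError(f"between table missing columns {sorted(bneed - set(between.columns))}")
        orphans = sorted(set(nests["year"]) - set(between["year"]))
        if orphans:
            raise ValueError(f"nest years without between-level covariates: {orphans}")
        self.nests = nests.reset_index(drop=True)
        b = between.set_index("year")
        self.years = np.sort(nests["year"].unique())
        self.between = b.loc[self.years, ["eur_winter_temp", "afr_winter_temp"]].reset_index()
        sizes = nests.groupby("year").size()
        single = sizes[sizes == 1].index.tolist()
        if single:
            warnings.warn(f"years with a single nest retained: {single}", stacklevel=2)
        self.n_clusters = len(self.years)
        self.n_nests = len(nests)


def build_msem(nests: pd.DataFrame, between: pd.DataFrame) -> MSEMSpec:
    """Validate and key the nest table to its year clusters."""
    return MSEMSpec(nests, between)


class MultilevelSEM(BaseEstimator):
    """Gibbs-sampled two-level SEM for fledgling production.

    Attributes after fit: ``draws_``, ``summary_``, ``converged_``,
    ``latent_means_`` (posterior means of the five latent year means),
    ``precip_deviations_`` (within precip deviations for simple slopes).
    """

    def __init__(self, chains: int = 2, draws: int = 800,
                 direct_hatch_path: bool = False,
                 coef_prior_var: float = 1e6,
                 var_prior_a: float = 0.001, var_prior_b: float = 0.001,
                 iw_df: float = 3.0, iw_scale: float = 1e-3,
                 rhat_threshold: float = 1.05, random_state=None):
        self.chains = chains
        self.draws = draws
        self.direct_hatch_path = direct_hatch_path
        self.coef_prior_var = coef_prior_var
        self.var_prior_a = var_prior_a
        self.var_prior_b = var_prior_b
        self.iw_df = iw_df
        self.iw_scale = iw_scale
        self.rhat_threshold = rhat_threshold
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, nests, between=None):
        spec = nests if isinstance(nests, MSEMSpec) else build_msem(nests, between)
        if spec.n_clusters < 2:
            raise ValueError("need >= 2 year clusters")
        nest = spec.nests
        year_codes = pd.Categorical(nest["year"], categories=spec.years).codes
        codes = np.asarray(year_codes)
        J = spec.n_clusters
        n = spec.n_nests
        nj = np.bincount(codes, minlength=J).astype(float)
        H = nest["hatch_date"].to_numpy(dtype=float)
        C = nest["clutch"].to_numpy(dtype=float)
        F = nest["fledglings"].to_numpy(dtype=float)
        T = nest["nest_temp"].to_numpy(dtype=float)
        P = nest["nest_precip"].to_numpy(dtype=float)
        for nm, arr in (("hatch_date", H), ("clutch", C), ("fledglings", F),
                        ("nest_temp", T), ("nest_precip", P)):
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite values in {nm}")
        Eur = spec.between["eur_winter_temp"].to_numpy(dtype=float)
        Afr = spec.between["afr_winter_temp"].to_numpy(dtype=float)

        a0, b0 = self.var_prior_a, self.var_prior_b
        pp = 1.0 / self.coef_prior_var
        S0 = self.iw_scale * np.eye(2)
        dh = self.direct_hatch_path

        def cmean(x):
            return np.bincount(codes, x, minlength=J) / nj

        def csum(x):
            return np.bincount(codes, x, minlength=J)

        names = WITHIN_PARAMS + BETWEEN_PARAMS + (["b_fled_on_hatch"] if dh else [])
        keep = self.draws
        store = {nm: np.empty((self.chains, keep)) for nm in names}
        latent_accum = {nm: np.zeros(J) for nm in
                        ("alpha_hatch", "alpha_clutch", "alpha_fledglings",
                         "alpha_temp", "alpha_precip")}
        seeds = np.random.SeedSequence(self.random_state).spawn(self.chains)

        for ci in range(self.chains):
            rng = np.random.default_rng(seeds[ci])
            # --- initial values: observed cluster means and moment estimates
            aH, aC, aF = cmean(H), cmean(C), cmean(F)
            aT, aP = cmean(T), cmean(P)
            aH = aH + 0.05 * rng.standard_normal(J)
            aC = aC + 0.05 * rng.standard_normal(J)
            aF = aF + 0.05 * rng.standard_normal(J)
            dT, dP, dHc = T - aT[codes], P - aP[codes], H - aH[codes]
            dC, dF = C - aC[codes], F - aF[codes]
            bH = float(np.polyfit(dHc, dC, 1)[0])
            M = np.column_stack([dT, dP, dT * dP, dC])
            wF = np.linalg.lstsq(M, dF, rcond=None)[0]
            s2H = max(dHc.var(), 1e-6)
            s2C = max((dC - bH * dHc).var(), 1e-6)
            s2F = max((dF - M @ wF).var(), 1e-6)
            Sw = np.cov(np.column_stack([dT, dP]).T) + 1e-6 * np.eye(2)
            gH = np.zeros(3); gH[0] = aH.mean()
            gC = np.zeros(4); gC[0] = aC.mean()
            gF = np.zeros(6 + dh); gF[0] = aF.mean()
            psiH = max(aH.var(), 1e-4)
            psiC = max(aC.var(), 1e-4)
            psiF = max(aF.var(), 1e-4)
            mu_b = np.array([aT.mean(), aP.mean()])
            Sb = np.cov(np.column_stack([aT, aP]).T) + 1e-6 * np.eye(2)

            for it in range(2 * keep):
                bT, bP, bTP, bC_ = wF
                Lw = np.linalg.inv(Sw)
                Lb = np.linalg.inv(Sb)

                # ---- latent weather means (aT | aP, then aP | aT)
                for which in (0, 1):
                    if which == 0:
                        x, o, ax_other = T, P, aP
                        slope, oslope = bT, bP
                        l_self, l_cross = Lw[0, 0], Lw[0, 1]
                        lb_self, lb_cross = Lb[0, 0], Lb[0, 1]
                        mu_self, mu_other = mu_b[0], mu_b[1]
                        gF_self, gF_other = gF[2], gF[3]
                    else:
                        x, o, ax_other = P, T, aT
                        slope, oslope = bP, bT
                        l_self, l_cross = Lw[1, 1], Lw[0, 1]
                        lb_self, lb_cross = Lb[1, 1], Lb[0, 1]
                        mu_self, mu_other = mu_b[1], mu_b[0]
                        gF_self, gF_other = gF[3], gF[2]
                    d_other = o - ax_other[codes]
                    # weather likelihood (joint bivariate normal) plus the
                    # between prior conditioned on the other latent mean
                    prec = nj * l_self + lb_self
                    lin = (l_self * csum(x) + l_cross * csum(d_other)
                           + lb_self * mu_self - lb_cross * (ax_other - mu_other))
                    # fledgling within equation: coefficient of this latent mean
                    ci_coef = slope + bTP * d_other
                    base = aF[codes] + bC_ * (C - aC[codes]) + oslope * d_other
                    r = F - base - ci_coef * x
                    prec = prec + csum(ci_coef ** 2) / s2F
                    lin = lin - csum(ci_coef * r) / s2F
                    # between fledgling equation
                    mF_wo = (gF[0] + gF[1] * aC + gF_other * ax_other
                             + gF[4] * Eur + gF[5] * Afr + (gF[6] * aH if dh else 0.0))
                    rb = aF - mF_wo
                    prec = prec + gF_self ** 2 / psiF
                    lin = lin + gF_self * rb / psiF
                    draw = lin / prec + rng.standard_normal(J) / np.sqrt(prec)
                    if which == 0:
                        aT = draw
                    else:
                        aP = draw
                dT, dP = T - aT[codes], P - aP[codes]

                # ---- latent hatch means
                prec = nj / s2H + nj * bH ** 2 / s2C + 1.0 / psiH
                rC = C - aC[codes] - bH * H          # = e_C - bH*aH
                lin = (csum(H) / s2H - bH * csum(rC) / s2C
                       + (gH[0] + gH[1] * Eur + gH[2] * Afr) / psiH)
                rbC = aC - (gC[0] + gC[2] * Eur + gC[3] * Afr)
                prec = prec + gC[1] ** 2 / psiC
                lin = lin + gC[1] * rbC / psiC
                if dh:
                    mF_woH = (gF[0] + gF[1] * aC + gF[2] * aT + gF[3] * aP
                              + gF[4] * Eur + gF[5] * Afr)
                    prec = prec + gF[6] ** 2 / psiF
                    lin = lin + gF[6] * (aF - mF_woH) / psiF
                aH = lin / prec + rng.standard_normal(J) / np.sqrt(prec)
                dHc = H - aH[codes]

                # ---- latent clutch means
                oth = bT * dT + bP * dP + bTP * dT * dP
                prec = nj / s2C + nj * bC_ ** 2 / s2F + 1.0 / psiC
                rF = F - aF[codes] - bC_ * C - oth    # = e_F - bC*aC
                lin = (csum(C - bH * dHc) / s2C - bC_ * csum(rF) / s2F
                       + (gC[0] + gC[1] * aH + gC[2] * Eur + gC[3] * Afr) / psiC)
                mF_woC = (gF[0] + gF[2] * aT + gF[3] * aP + gF[4] * Eur
                          + gF[5] * Afr + (gF[6] * aH if dh else 0.0))
                prec = prec + gF[1] ** 2 / psiF
                lin = lin + gF[1] * (aF - mF_woC) / psiF
                aC = lin / prec + rng.standard_normal(J) / np.sqrt(prec)
                dC = C - aC[codes]

                # ---- latent fledgling means
                mF = (gF[0] + gF[1] * aC + gF[2] * aT + gF[3] * aP
                      + gF[4] * Eur + gF[5] * Afr + (gF[6] * aH if dh else 0.0))
                prec = nj / s2F + 1.0 / psiF
                lin = csum(F - bC_ * dC - oth) / s2F + mF / psiF
                aF = lin / prec + rng.standard_normal(J) / np.sqrt(prec)
                dF = F - aF[codes]

                # ---- within slopes
                M = np.column_stack([dT, dP, dT * dP, dC])
                A = M.T @ M / s2F + pp * np.eye(4)
                L = np.linalg.cholesky(A)
                wF = (np.linalg.solve(A, M.T @ dF / s2F)
                      + np.linalg.solve(L.T, rng.standard_normal(4)))
                prec_bH = dHc @ dHc / s2C + pp
                bH = rng.normal((dHc @ dC / s2C) / prec_bH, 1.0 / np.sqrt(prec_bH))

                # ---- within (co)variances
                eF = dF - M @ wF
                s2F = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * eF @ eF))
                eC = dC - bH * dHc
                s2C = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * eC @ eC))
                s2H = 1.0 / rng.gamma(a0 + 0.5 * n, 1.0 / (b0 + 0.5 * dHc @ dHc))
                D = np.column_stack([dT, dP])
                Sw = invwishart.rvs(df=self.iw_df + n, scale=S0 + D.T @ D, random_state=rng)

                # ---- between regressions
                BH = np.column_stack([np.ones(J), Eur, Afr])
                gH, psiH = _conj_reg(rng, BH, aH, psiH, pp, a0, b0)
                BC = np.column_stack([np.ones(J), aH, Eur, Afr])
                gC, psiC = _conj_reg(rng, BC, aC, psiC, pp, a0, b0)
                cols = [np.ones(J), aC, aT, aP, Eur, Afr] + ([aH] if dh else [])
                BF = np.column_stack(cols)
                gF, psiF = _conj_reg(rng, BF, aF, psiF, pp, a0, b0)

                # ---- between weather means and covariance
                W = np.column_stack([aT, aP])
                dev = W - mu_b
                Sb = invwishart.rvs(df=self.iw_df + J, scale=S0 + dev.T @ dev, random_state=rng)
                mu_b = rng.multivariate_normal(W.mean(axis=0), Sb / J)

                if it >= keep:
                    i = it - keep
                    vals = {
                        "w_fled_on_temp": wF[0], "w_fled_on_precip": wF[1],
                        "w_fled_on_interaction": wF[2], "w_fled_on_clutch": wF[3],
                        "w_clutch_on_hatch": bH,
                        "w_temp_var": Sw[0, 0], "w_precip_var": Sw[1, 1],
                        "w_temp_precip_cov": Sw[0, 1], "w_hatch_var": s2H,
                        "w_fled_resid_var": s2F, "w_clutch_resid_var": s2C,
                        "b_fled_intercept": gF[0], "b_fled_on_clutch": gF[1],
                        "b_fled_on_temp": gF[2], "b_fled_on_precip": gF[3],
                        "b_fled_on_eur_winter_temp": gF[4],
                        "b_fled_on_afr_winter_temp": gF[5],
                        "b_clutch_intercept": gC[0], "b_clutch_on_hatch": gC[1],
                        "b_clutch_on_eur_winter_temp": gC[2],
                        "b_clutch_on_afr_winter_temp": gC[3],
                        "b_hatch_intercept": gH[0],
                        "b_hatch_on_eur_winter_temp": gH[1],
                        "b_hatch_on_afr_winter_temp": gH[2],
                        "b_temp_mean": mu_b[0], "b_precip_mean": mu_b[1],
                        "b_temp_var": Sb[0, 0], "b_precip_var": Sb[1, 1],
                        "b_temp_precip_cov": Sb[0, 1],
                        "b_fled_resid_var": psiF, "b_clutch_resid_var": psiC,
                        "b_hatch_resid_var": psiH,
                    }
                    if dh:
                        vals["b_fled_on_hatch"] = gF[6]
                    for nm, v in vals.items():
                        store[nm][ci, i] = v
                    scale = 1.0 / (keep * self.chains)
                    for nm, arr in (("alpha_hatch", aH), ("alpha_clutch", aC),
                                    ("alpha_fledglings", aF), ("alpha_temp", aT),
                                    ("alpha_precip", aP)):
                        latent_accum[nm] += arr * scale

        self.spec_ = spec
        self.draws_ = Draws(store)
        self.summary_ = summarize(self.draws_)
        psr = self.summary_["psr"].to_numpy()
        self.converged_ = bool(np.all(psr[np.isfinite(psr)] < self.rhat_threshold))
        self.latent_means_ = pd.DataFrame({"year": spec.years, **latent_accum})
        self.precip_deviations_ = P - latent_accum["alpha_precip"][codes]
        self.precip_raw_ = P
        return self

    # ------------------------------------------------------------------
    def summary_table(self) -> pd.DataFrame:
        """Within/between block layout of every reported parameter."""
        s = self.summary_.set_index("parameter")
        rows = []
        for level, keys in (("Within-level", WITHIN_PARAMS),
                            ("Between-level", BETWEEN_PARAMS
                             + (["b_fled_on_hatch"] if self.direct_hatch_path else []))):
            for key in keys:
                r = s.loc[key]
                rows.append({"level": level, "parameter": key,
                             "median": r["median"], "ci_lower": r["ci_lower"],
                             "ci_upper": r["ci_upper"], "nonzero": r["nonzero"]})
        return pd.DataFrame(rows)


def _conj_reg(rng, B, y, psi, pp, a0, b0):
    """One conjugate sweep of a between-level regression block."""
    k = B.shape[1]
    A = B.T @ B / psi + pp * np.eye(k)
    L = np.linalg.cholesky(A)
    g = np.linalg.solve(A, B.T @ y / psi) + np.linalg.solve(L.T, rng.standard_normal(k))
    res = y - B @ g
    psi = 1.0 / rng.gamma(a0 + 0.5 * len(y), 1.0 / (b0 + 0.5 * res @ res))
    return g, psi


# ---------------------------------------------------------------------------
# derived quantities

def decompose_effects(fit: MultilevelSEM) -> pd.DataFrame:
    """Between-level total/direct/indirect effects on annual fledgling number.

    For each winter-temperature window: the direct path, the route via
    hatching date (window -> hatch -> clutch -> fledglings), the route via
    clutch size (window -> clutch -> fledglings), their sum (indirect), and
    total = direct + indirect — all per posterior draw. The hatching-date
    total itself has no direct path: it is hatch -> clutch -> fledglings.
    """
    d = fit.draws_
    cf = d["b_fled_on_clutch"]
    hc = d["b_clutch_on_hatch"]
    rows = []
    for label, key in (("eur_winter_temp", "eur_winter_temp"),
                       ("afr_winter_temp", "afr_winter_temp")):
        direct = d[f"b_fled_on_{key}"]
        via_hatch = d[f"b_hatch_on_{key}"] * hc * cf
        if fit.direct_hatch_path:
            via_hatch = via_hatch + d[f"b_hatch_on_{key}"] * d["b_fled_on_hatch"]
        via_clutch = d[f"b_clutch_on_{key}"] * cf
        indirect = via_hatch + via_clutch
        total = direct + indirect
        tmp = Draws({"total": total, "direct": direct, "indirect": indirect,
                     "via_hatch": via_hatch, "via_clutch": via_clutch})
        out = summarize(tmp)
        out.insert(0, "predictor", label)
        rows.append(out)
    hatch_total = hc * cf
    if fit.direct_hatch_path:
        hatch_total = hatch_total + d["b_fled_on_hatch"]
    parts = {"total": hatch_total, "indirect": hc * cf, "via_clutch": hc * cf}
    if fit.direct_hatch_path:
        parts["direct"] = d["b_fled_on_hatch"]
    out = summarize(Draws(parts))
    out.insert(0, "predictor", "hatch_date")
    rows.append(out)
    res = pd.concat(rows, ignore_index=True)
    return res.rename(columns={"parameter": "effect"})


def within_total_hatch_effect(fit: MultilevelSEM) -> pd.Series:
    """Within-year total effect of hatching date on fledgling number.

    Per draw: (hatch -> clutch) x (clutch -> fledglings) at the within
    level; hatching date has no other within route to fledglings.
    """
    d = fit.draws_["w_clutch_on_hatch"] * fit.draws_["w_fled_on_clutch"]
    return summarize(Draws({"within_total_hatch": d})).iloc[0]


def simple_slopes(fit: MultilevelSEM, percentiles=(10, 25, 50, 75, 90)) -> pd.DataFrame:
    """Temperature slope on fledglings at precipitation percentiles.

    The moderator enters on the latent-centered scale (offset 0), so
    slope(p) = bT + bTP * q_p with q_p the requested percentile of the
    within-year precipitation deviations; the matching raw-scale
    precipitation percentile is reported alongside.
    """
    percentiles = list(percentiles)
    if not percentiles:
        raise ValueError("need at least one percentile")
    bT = fit.draws_["w_fled_on_temp"]
    bTP = fit.draws_["w_fled_on_interaction"]
    rows = []
    for p in percentiles:
        q = float(np.percentile(fit.precip_deviations_, p))
        q_raw = float(np.percentile(fit.precip_raw_, p))
        s = summarize(Draws({"slope": bT + bTP * q})).iloc[0]
        rows.append({"percentile": p, "precip_deviation": q, "precip_raw": q_raw,
                     "median": s["median"], "ci_lower": s["ci_lower"],
                     "ci_upper": s["ci_upper"]})
    return pd.DataFrame(rows)
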