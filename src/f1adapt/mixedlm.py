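"""Linear mixed models with random intercepts and Satterthwaite df.

The models needed here are all of one family: Gaussian responses with a
small number of crossed random *intercepts* (participant, study).  For
that family the covariance V = sigma_e^2 I + sum_k sigma_k^2 Z_k Z_k' has
low-rank structure, so the restricted likelihood, the GLS coefficients
and their covariance can be evaluated exactly with the Woodbury identity
at O(n q^2) cost (q = total number of random levels).  REML estimation
is a direct Nelder-Mead search over log-variances on that exact
criterion, which is fast and does not stall on the variance boundary.

Fixed-effect inference uses Satterthwaite degrees of freedom: for a
coefficient with sampling variance phi(theta) = [ (X' V(theta)^-1 X)^-1 ]_jj,

    df = 2 * phi^2 / Var(phi),   Var(phi) ~= g' A g,

where g is the gradient of phi in theta = (sigma^2_1..K, sigma^2_e) and
A is the inverse observed REML information (numerical Hessian).  The
whole stack is validated in the test suite against statsmodels MixedLM
and against R's lme4/lmerTest on shared fixtures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from patsy import dmatrices
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

__all__ = ["MixedFit", "fit_random_intercepts", "satterthwaite_df"]


@dataclass
class MixedFit:
    """A fitted random-intercepts model with Satterthwaite inference."""

    terms: pd.DataFrame  # term, estimate, se, df, tvalue, pvalue
    residual_sd: float
    vcomp: dict[str, float]  # random-intercept variances by factor
    converged: bool
    method: str
    n_obs: int
    loglik: float = np.nan
    warnings: list[str] = field(default_factory=list)

    def term(self, name_part: str) -> pd.Series:
        """First term whose name contains ``name_part``."""
        hit = self.terms[self.terms["term"].str.contains(name_part, regex=False)]
        if hit.empty:
            raise KeyError(f"no term matching {name_part!r}")
        return hit.iloc[0]


def _chol(A: np.ndarray):
    jitter = 0.0
    for _ in range(6):
        try:
            return cho_factor(A + jitter * np.eye(A.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            jitter = max(jitter * 10, 1e-10 * np.trace(A) / A.shape[0])
    raise np.linalg.LinAlgError("matrix not positive definite")


class _RemlWorkspace:
    """Precomputed cross-products for exact REML evaluation via Woodbury."""

    def __init__(self, X: np.ndarray, y: np.ndarray, Zs: list[np.ndarray]):
        self.n, self.p = X.shape
        self.q_sizes = [Z.shape[1] for Z in Zs]
        Z = np.hstack(Zs) if Zs else np.zeros((self.n, 0))
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.Zty = Z.T @ y
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)

    def _core(self, theta: np.ndarray):
        """(cov_beta, beta, neg restricted loglik) at
        theta = (sigma^2_1..K, sigma^2_e)."""
        se = max(theta[-1], 1e-12)
        g = np.concatenate(
            [np.full(q, max(theta[k], 1e-12)) for k, q in enumerate(self.q_sizes)]
        ) if self.q_sizes else np.zeros(0)
        q = g.size
        if q:
            M = self.ZtZ + np.diag(se / g)
            cM = _chol(M)
            W_ZtX = cho_solve(cM, self.ZtX)
            W_Zty = cho_solve(cM, self.Zty)
            XtVinvX = (self.XtX - self.ZtX.T @ W_ZtX) / se
            XtVinvy = (self.Xty - self.ZtX.T @ W_Zty) / se
            ytVinvy = (self.yty - self.Zty @ W_Zty) / se
            logdetM = 2.0 * np.sum(np.log(np.diag(cM[0])))
            logdetV = (self.n - q) * np.log(se) + np.sum(np.log(g)) + logdetM
        else:
            XtVinvX = self.XtX / se
            XtVinvy = self.Xty / se
            ytVinvy = self.yty / se
            logdetV = self.n * np.log(se)
        cB = _chol(XtVinvX)
        cov_beta = cho_solve(cB, np.eye(self.p))
        beta = cov_beta @ XtVinvy
        ytPy = ytVinvy - XtVinvy @ beta
        logdetXtVinvX = 2.0 * np.sum(np.log(np.diag(cB[0])))
        nll = 0.5 * (
            logdetV + logdetXtVinvX + ytPy
            + (self.n - self.p) * np.log(2.0 * np.pi)
        )
        return cov_beta, beta, float(nll)

    def cov_beta(self, theta: np.ndarray) -> np.ndarray:
        return self._core(theta)[0]

    def neg_loglik(self, theta: np.ndarray) -> float:
        return self._core(theta)[2]

    def fit(self) -> tuple[np.ndarray, bool]:
        """REML estimate of theta by Nelder-Mead over log-variances,
        multi-started; returns (theta_hat, converged)."""
        vary = max(self.yty / self.n, 1e-10)
        K = len(self.q_sizes)
        starts = [
            np.log(np.r_[np.full(K, 0.2 * vary), 0.8 * vary]),
            np.log(np.r_[np.full(K, 0.02 * vary), vary]),
        ]
        best, best_val, conv = None, np.inf, False
        for x0 in starts:
            res = optimize.minimize(
                lambda eta: self.neg_loglik(np.exp(eta)), x0,
                method="Nelder-Mead",
                options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000},
            )
            if res.fun < best_val:
                best, best_val, conv = res.x, res.fun, bool(res.success)
        theta = np.exp(best)
        # snap effectively-zero variance components to the boundary
        theta[:-1][theta[:-1] < 1e-8 * vary] = 0.0
        return theta, conv


def satterthwaite_df(
    X: np.ndarray,
    y: np.ndarray,
    Zs: list[np.ndarray],
    variances: list[float],
    resid_var: float,
) -> np.ndarray:
    """Satterthwaite degrees of freedom for each fixed-effect coefficient.

    ``Zs`` are 0/1 indicator matrices of the random-intercept factors,
    ``variances`` the fitted variances in the same order, ``resid_var``
    the residual variance.
    """
    ws = _RemlWorkspace(np.asarray(X, float), np.asarray(y, float),
                        [np.asarray(Z, float) for Z in Zs])
    return _satterthwaite(ws, np.array(list(variances) + [resid_var], dtype=float))


def _satterthwaite(ws: _RemlWorkspace, theta: np.ndarray) -> np.ndarray:
    scale = max(float(np.sum(theta)), 1e-12)
    d = theta.size
    p = ws.p

    def phi(th: np.ndarray) -> np.ndarray:
        return np.diag(ws.cov_beta(th))

    steps = np.maximum(1e-4 * np.abs(theta), 1e-7 * scale)
    G = np.zeros((p, d))
    for i in range(d):
        tp, tm = theta.copy(), theta.copy()
        tp[i] += steps[i]
        tm[i] = max(tm[i] - steps[i], 0.0)
        G[:, i] = (phi(tp) - phi(tm)) / (tp[i] - tm[i])

    H = np.zeros((d, d))
    f0 = ws.neg_loglik(theta)
    hs = np.maximum(1e-3 * np.abs(theta), 1e-6 * scale)
    for i in range(d):
        for j in range(i, d):
            ei = np.zeros(d); ei[i] = hs[i]
            ej = np.zeros(d); ej[j] = hs[j]
            if i == j:
                fp = ws.neg_loglik(np.maximum(theta + ei, 0.0))
                fm = ws.neg_loglik(np.maximum(theta - ei, 0.0))
                H[i, i] = (fp - 2 * f0 + fm) / hs[i] ** 2
            else:
                fpp = ws.neg_loglik(np.maximum(theta + ei + ej, 0.0))
                fpm = ws.neg_loglik(np.maximum(theta + ei - ej, 0.0))
                fmp = ws.neg_loglik(np.maximum(theta - ei + ej, 0.0))
                fmm = ws.neg_loglik(np.maximum(theta - ei - ej, 0.0))
                H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * hs[i] * hs[j])
    A = np.linalg.pinv(H)

    phi0 = phi(theta)
    denom = np.einsum("jd,de,je->j", G, A, G)
    df = np.full(p, float(ws.n - p))
    ok = denom > 0
    df[ok] = 2.0 * phi0[ok] ** 2 / denom[ok]
    return np.clip(df, 1.0, ws.n - p)


def _indicator(values: pd.Series) -> np.ndarray:
    return pd.get_dummies(values.astype(str)).to_numpy(dtype=float)


def fit_random_intercepts(
    data: pd.DataFrame,
    formula: str,
    random_factors: list[str],
    reml: bool = True,
) -> MixedFit:
    """Fit ``formula`` with crossed random intercepts for each factor in
    ``random_factors``, by REML, with Satterthwaite degrees of freedom.

    Factors with a single level are dropped with a note recorded in the
    result (their variance is not estimable); with no usable factors the
    model reduces to ordinary least squares.
    """
    if not reml:
        raise NotImplementedError("only REML estimation is provided")
    notes: list[str] = []
    factors = []
    for f in random_factors:
        if data[f].nunique() < 2:
            notes.append(f"random factor '{f}' has one level; dropped")
        else:
            factors.append(f)

    y_df, X_df = dmatrices(formula, data, return_type="dataframe")
    X = X_df.to_numpy(dtype=float)
    y = y_df.to_numpy(dtype=float).ravel()
    exog_names = list(X_df.columns)
    n, p = X.shape
    if n <= p:
        raise ValueError("more coefficients than observations")

    if not factors:
        # ordinary least squares with residual df
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        dof = n - p
        s2 = float(resid @ resid) / dof
        cov = s2 * np.linalg.pinv(X.T @ X)
        bse = np.sqrt(np.diag(cov))
        df = np.full(p, float(dof))
        vcomp: dict[str, float] = {}
        resid_var = s2
        converged = True
        ll = np.nan
    else:
        aligned = data.loc[X_df.index]  # rows patsy kept after NA handling
        Zs = [_indicator(aligned[f]) for f in factors]
        ws = _RemlWorkspace(X, y, Zs)
        theta, converged = ws.fit()
        if not converged:
            notes.append("REML optimizer did not report convergence")
        cov_beta, beta, nll = ws._core(theta)
        bse = np.sqrt(np.diag(cov_beta))
        vcomp = {f: float(theta[k]) for k, f in enumerate(factors)}
        resid_var = float(theta[-1])
        ll = -nll
        try:
            df = _satterthwaite(ws, theta)
        except np.linalg.LinAlgError as exc:
            notes.append(f"Satterthwaite failed ({exc}); residual df used")
            df = np.full(p, float(n - p))

    tvals = np.divide(beta, bse, out=np.full(p, np.nan), where=bse > 0)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df)
    terms = pd.DataFrame(
        {
            "term": exog_names,
            "estimate": beta,
            "se": bse,
            "df": df,
            "tvalue": tvals,
            "pvalue": pvals,
        }
    )
    return MixedFit(
        terms=terms,
        residual_sd=float(np.sqrt(resid_var)),
        vcomp=vcomp,
        converged=converged,
        method="REML" if factors else "OLS",
        n_obs=int(n),
        loglik=ll,
        warnings=notes,
    )
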