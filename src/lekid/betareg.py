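"""Beta regression with logit mean link, AIC model selection and diagnostics.

The agreement indices live on [0, 1], so they are modelled with a beta GLM:
y_i ~ Beta(mu_i * phi, (1 - mu_i) * phi) with logit(mu_i) = x_i' beta and a
common precision phi.  The model is fitted by maximum likelihood in
(beta, log phi) with analytic gradients; standard errors come from the inverse
observed information, Wald z and two-sided p-values from the normal reference.

Boundary index values (exactly 0 or 1) are inadmissible under the beta density
and are compressed with the standard transform y' = (y (n - 1) + 0.5) / n
before fitting (:func:`squeeze_to_open_interval`).

Model selection follows backward elimination on AIC: from the full additive
model, repeatedly drop the single term whose removal lowers AIC most, stopping
when no removal helps.  Every model visited enters a selection table with
delta-AIC and Akaike weights; models with delta-AIC below a threshold
(default 2) form the retained set.  An exhaustive all-subsets mode is
available.  Goodness of fit is checked with simulation-based scaled quantile
residuals: each observation's position within draws from its fitted beta
distribution, uniform on [0, 1] under a correctly specified model
(Kolmogorov-Smirnov test).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import patsy
from scipy import optimize, special, stats

__all__ = [
    "CollinearityError",
    "squeeze_to_open_interval",
    "BetaRegression",
    "BetaRegressionResults",
    "ModelSelectionTable",
    "backward_select",
    "ResidualDiagnostics",
    "scaled_residuals",
]


class CollinearityError(ValueError):
    """The design matrix is rank deficient."""


class NotConvergedError(RuntimeError):
    """An operation requiring a converged fit received a failed one."""


def squeeze_to_open_interval(y, n: int | None = None) -> np.ndarray:
    """Compress values from [0, 1] strictly into (0, 1).

    Applies y' = (y (n - 1) + 0.5) / n with n the sample size (default
    ``len(y)``); order-preserving, fixed point at 0.5.  Raises ``ValueError``
    for values outside [0, 1] or n < 2.
    """
    y = np.asarray(y, dtype=float)
    if np.any((y < 0) | (y > 1)) or np.any(np.isnan(y)):
        raise ValueError("squeeze_to_open_interval requires values in [0, 1]")
    if n is None:
        n = y.size
    if n < 2:
        raise ValueError("sample size n must be >= 2")
    return (y * (n - 1) + 0.5) / n


class BetaRegression:
    """Beta regression model for responses in the open unit interval.

    Parameters
    ----------
    endog : array-like
        Response values, strictly inside (0, 1).
    exog : array-like
        Design matrix including an intercept column.
    exog_names : list of str, optional
        Column names for ``exog``; defaults to x0..xk (x0 = const).
    response_name : str
        Label used in summaries.

    Use :meth:`from_formula` to build the design from a patsy formula and a
    DataFrame.
    """

    def __init__(self, endog, exog, exog_names: list[str] | None = None,
                 response_name: str = "y", formula: str | None = None):
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.atleast_2d(np.asarray(exog, dtype=float))
        if self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("endog and exog have incompatible shapes")
        if np.any((self.endog <= 0) | (self.endog >= 1)):
            raise ValueError("endog must lie strictly in (0, 1); "
                             "apply squeeze_to_open_interval first")
        k = self.exog.shape[1]
        if np.linalg.matrix_rank(self.exog) < k:
            raise CollinearityError("design matrix is rank deficient")
        self.exog_names = list(exog_names) if exog_names is not None else (
            ["const"] + [f"x{i}" for i in range(1, k)])
        self.response_name = response_name
        self.formula = formula
        self.nobs = self.endog.shape[0]
        self.k_exog = k

    @classmethod
    def from_formula(cls, formula: str, data: pd.DataFrame) -> "BetaRegression":
        y, X = patsy.dmatrices(formula, data, return_type="dataframe")
        return cls(endog=y.to_numpy().ravel(), exog=X.to_numpy(),
                   exog_names=list(X.columns),
                   response_name=y.columns[0], formula=formula)

    # -- likelihood -----------------------------------------------------------

    def loglike(self, beta, phi: float) -> float:
        """Log-likelihood at coefficients ``beta`` and precision ``phi``."""
        mu = special.expit(self.exog @ np.asarray(beta, dtype=float))
        a, b = mu * phi, (1.0 - mu) * phi
        return float(np.sum(stats.beta.logpdf(self.endog, a, b)))

    # clip bounds keep the surface finite when the optimizer overshoots;
    # any interior optimum is unaffected
    _MU_EPS = 1e-10
    _LOGPHI_MAX = 30.0

    def _unpack(self, params: np.ndarray) -> tuple[np.ndarray, float]:
        logphi = float(np.clip(params[-1], -self._LOGPHI_MAX, self._LOGPHI_MAX))
        return params[:-1], float(np.exp(logphi))

    def _mu(self, beta: np.ndarray) -> np.ndarray:
        return np.clip(special.expit(self.exog @ beta),
                       self._MU_EPS, 1.0 - self._MU_EPS)

    def _negloglike(self, params: np.ndarray) -> float:
        beta, phi = self._unpack(params)
        mu = self._mu(beta)
        a, b = mu * phi, (1.0 - mu) * phi
        y = self.endog
        ll = (special.gammaln(phi) - special.gammaln(a) - special.gammaln(b)
              + (a - 1.0) * np.log(y) + (b - 1.0) * np.log1p(-y))
        total = float(np.sum(ll))
        return -total if np.isfinite(total) else np.inf

    def _neggrad(self, params: np.ndarray) -> np.ndarray:
        beta, phi = self._unpack(params)
        mu = self._mu(beta)
        a, b = mu * phi, (1.0 - mu) * phi
        y = self.endog
        ystar = np.log(y) - np.log1p(-y)
        mustar = special.digamma(a) - special.digamma(b)
        # d ll / d eta with logit link: phi (y* - mu*) mu (1 - mu)
        g_beta = self.exog.T @ (phi * (ystar - mustar) * mu * (1.0 - mu))
        dphi = (special.digamma(phi) - mu * special.digamma(a)
                - (1.0 - mu) * special.digamma(b)
                + mu * np.log(y) + (1.0 - mu) * np.log1p(-y))
        g_logphi = phi * float(np.sum(dphi))
        return -np.append(g_beta, g_logphi)

    def _start_params(self) -> np.ndarray:
        ybar = float(np.mean(self.endog))
        yvar = float(np.var(self.endog, ddof=1)) if self.nobs > 1 else 0.01
        phi0 = max(ybar * (1.0 - ybar) / max(yvar, 1e-8) - 1.0, 1.0)
        start = np.zeros(self.k_exog + 1)
        # put logit(mean) on the (first) constant-like column
        const_cols = [j for j in range(self.k_exog)
                      if np.allclose(self.exog[:, j], self.exog[0, j])]
        if const_cols:
            start[const_cols[0]] = special.logit(np.clip(ybar, 1e-6, 1 - 1e-6))
        start[-1] = np.log(phi0)
        return start

    def fit(self, start_params=None, maxiter: int = 500) -> "BetaRegressionResults":
        """Maximize the likelihood (BFGS in (beta, log phi)) and return results."""
        x0 = np.asarray(start_params, dtype=float) if start_params is not None \
            else self._start_params()
        res = optimize.minimize(self._negloglike, x0, jac=self._neggrad,
                                method="BFGS",
                                options={"maxiter": maxiter, "gtol": 1e-7})
        if not res.success:  # one careful retry from the rough optimum
            res2 = optimize.minimize(self._negloglike, res.x, jac=self._neggrad,
                                     method="L-BFGS-B",
                                     options={"maxiter": maxiter, "ftol": 1e-12})
            if res2.fun <= res.fun:
                res = res2
        params = res.x
        hess = _numerical_hessian(self._negloglike, params)
        cov = _safe_inverse(hess)
        return BetaRegressionResults(model=self, packed_params=params,
                                     packed_cov=cov, llf=-float(res.fun),
                                     converged=bool(res.success),
                                     optimizer_message=str(res.message))


def _numerical_hessian(fun, x: np.ndarray, eps: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian; symmetric by construction."""
    k = x.size
    h = eps * np.maximum(1.0, np.abs(x))
    hess = np.empty((k, k))
    for i in range(k):
        for j in range(i, k):
            ei = np.zeros(k); ei[i] = h[i]
            ej = np.zeros(k); ej[j] = h[j]
            f_pp = fun(x + ei + ej)
            f_pm = fun(x + ei - ej)
            f_mp = fun(x - ei + ej)
            f_mm = fun(x - ei - ej)
            hess[i, j] = hess[j, i] = (f_pp - f_pm - f_mp + f_mm) / (4 * h[i] * h[j])
    return hess


def _safe_inverse(hess: np.ndarray) -> np.ndarray:
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    diag = np.diag(cov).copy()
    diag[diag < 0] = np.nan  # saddle / non-identified direction
    np.fill_diagonal(cov, diag)
    return cov


class BetaRegressionResults:
    """Estimates, uncertainties and diagnostics from a fitted beta regression.

    Attributes mirror the statsmodels results API: ``params``, ``bse``,
    ``zvalues``, ``pvalues`` (pandas Series over coefficient names), ``phi``
    and ``phi_se`` for the precision, ``llf``, ``aic``, ``nobs``,
    ``converged``.  ``k_params`` counts the mean coefficients plus phi, and
    AIC = -2 llf + 2 k_params.
    """

    def __init__(self, model: BetaRegression, packed_params: np.ndarray,
                 packed_cov: np.ndarray, llf: float, converged: bool,
                 optimizer_message: str = ""):
        self.model = model
        self._packed = np.asarray(packed_params, dtype=float)
        self._packed_cov = np.asarray(packed_cov, dtype=float)
        self.llf = float(llf)
        self.converged = converged
        self.optimizer_message = optimizer_message

        names = model.exog_names
        beta = self._packed[:-1]
        se = np.sqrt(np.diag(self._packed_cov)[:-1])
        self.params = pd.Series(beta, index=names, name="estimate")
        self.bse = pd.Series(se, index=names, name="se")
        with np.errstate(divide="ignore", invalid="ignore"):
            z = beta / se
        self.zvalues = pd.Series(z, index=names, name="z")
        self.pvalues = pd.Series(2.0 * stats.norm.sf(np.abs(z)), index=names, name="p")
        self.phi = float(np.exp(self._packed[-1]))
        logphi_se = float(np.sqrt(self._packed_cov[-1, -1]))
        self.phi_se = self.phi * logphi_se  # delta method
        self.nobs = model.nobs
        self.k_params = model.k_exog + 1
        self.aic = -2.0 * self.llf + 2.0 * self.k_params
        self.bic = -2.0 * self.llf + np.log(self.nobs) * self.k_params

    # -- prediction and simulation -------------------------------------------

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.predict()

    def predict(self, exog=None) -> np.ndarray:
        """Fitted means mu on the response scale; all in (0, 1)."""
        X = self.model.exog if exog is None else np.atleast_2d(np.asarray(exog, float))
        return special.expit(X @ self.params.to_numpy())

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        q = stats.norm.ppf(1.0 - alpha / 2.0)
        return pd.DataFrame({"lower": self.params - q * self.bse,
                             "upper": self.params + q * self.bse})

    def simulate(self, rng: np.random.Generator, n_sims: int = 1) -> np.ndarray:
        """Draw (n_sims, nobs) responses from the fitted beta distributions."""
        mu = self.predict()
        a, b = mu * self.phi, (1.0 - mu) * self.phi
        return rng.beta(a, b, size=(n_sims, mu.size))

    def summary(self) -> str:
        """Plain-text coefficient table in the statsmodels style."""
        table = pd.DataFrame({
            "estimate": self.params, "se": self.bse,
            "z": self.zvalues, "p": self.pvalues,
        })
        head = (f"Beta regression (logit link), response: {self.model.response_name}\n"
                f"n = {self.nobs}, logLik = {self.llf:.3f}, AIC = {self.aic:.3f}, "
                f"phi = {self.phi:.3f} (SE {self.phi_se:.3f}), "
                f"converged = {self.converged}\n")
        return head + table.to_string(float_format=lambda v: f"{v: .4f}")

    def __repr__(self) -> str:  # pragma: no cover
        return (f"<BetaRegressionResults {self.model.response_name!r} "
                f"n={self.nobs} aic={self.aic:.2f}>")


# -- model selection ----------------------------------------------------------

@dataclass
class ModelSelectionTable:
    """Ranked candidate models with delta-AIC and Akaike weights.

    ``frame`` has one row per visited model (formula, k_params, loglik, aic,
    delta_aic, weight) sorted by AIC; ``fits`` maps formula -> results;
    ``retained`` lists formulas with delta_aic < the threshold.
    """

    frame: pd.DataFrame
    fits: dict[str, BetaRegressionResults]
    best_formula: str
    delta_threshold: float
    path: list[str] = field(default_factory=list)

    @property
    def best_fit(self) -> BetaRegressionResults:
        return self.fits[self.best_formula]

    @property
    def retained(self) -> list[str]:
        return self.frame.loc[self.frame["delta_aic"] < self.delta_threshold,
                              "formula"].tolist()

    def to_csv(self, path) -> None:
        self.frame.to_csv(path, index=False)


def _formula(response: str, terms: tuple[str, ...]) -> str:
    rhs = " + ".join(terms) if terms else "1"
    return f"{response} ~ {rhs}"


def _weights_frame(fits: dict[str, BetaRegressionResults],
                   delta_threshold: float) -> pd.DataFrame:
    rows = [{"formula": f, "k_params": r.k_params, "loglik": r.llf, "aic": r.aic}
            for f, r in fits.items()]
    frame = pd.DataFrame(rows).sort_values(["aic", "formula"]).reset_index(drop=True)
    frame["delta_aic"] = frame["aic"] - frame["aic"].min()
    rel = np.exp(-0.5 * frame["delta_aic"])
    frame["weight"] = rel / rel.sum()
    return frame


def backward_select(data: pd.DataFrame, response: str, candidate_terms: list[str],
                    delta_threshold: float = 2.0,
                    mode: str = "backward") -> ModelSelectionTable:
    """Select covariates of a beta regression by AIC.

    ``mode='backward'`` starts from the full additive model and repeatedly
    drops the single term whose removal most reduces AIC, stopping when no
    removal helps; every model visited (including rejected drops) enters the
    table.  ``mode='all_subsets'`` fits every subset of ``candidate_terms``.
    Akaike weights are normalized over the tabled models.
    """
    if mode not in ("backward", "all_subsets"):
        raise ValueError("mode must be 'backward' or 'all_subsets'")

    def fit_terms(terms: tuple[str, ...]) -> tuple[str, BetaRegressionResults]:
        f = _formula(response, terms)
        return f, BetaRegression.from_formula(f, data).fit()

    fits: dict[str, BetaRegressionResults] = {}
    path: list[str] = []

    if mode == "all_subsets":
        for k in range(len(candidate_terms), -1, -1):
            for terms in combinations(candidate_terms, k):
                f, r = fit_terms(terms)
                fits[f] = r
        frame = _weights_frame(fits, delta_threshold)
        best = frame.loc[0, "formula"]
        return ModelSelectionTable(frame=frame, fits=fits, best_formula=best,
                                   delta_threshold=delta_threshold, path=path)

    current = tuple(candidate_terms)
    cur_formula, cur_fit = fit_terms(current)
    fits[cur_formula] = cur_fit
    path.append(cur_formula)
    while current:
        trials = []
        for term in current:
            reduced = tuple(t for t in current if t != term)
            f = _formula(response, reduced)
            if f not in fits:
                fits[f] = BetaRegression.from_formula(f, data).fit()
            trials.append((fits[f].aic, f, reduced))
        trials.sort(key=lambda t: (t[0], t[1]))
        best_aic, best_f, best_terms = trials[0]
        if best_aic < fits[cur_formula].aic:
            current, cur_formula = best_terms, best_f
            path.append(cur_formula)
        else:
            break

    frame = _weights_frame(fits, delta_threshold)
    return ModelSelectionTable(frame=frame, fits=fits, best_formula=cur_formula,
                               delta_threshold=delta_threshold, path=path)


# -- diagnostics --------------------------------------------------------------

@dataclass
class ResidualDiagnostics:
    """Simulation-based scaled quantile residuals and their uniformity test."""

    scaled_residuals: np.ndarray
    uniformity_statistic: float
    uniformity_p: float
    n_simulations: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"scaled_residual": self.scaled_residuals})


def scaled_residuals(results: BetaRegressionResults, y=None,
                     n_simulations: int = 250,
                     rng: np.random.Generator | int | None = None) -> ResidualDiagnostics:
    """Scaled quantile residuals of a fitted beta regression.

    For each observation, ``n_simulations`` responses are drawn from its
    fitted beta distribution; the residual is the fraction of draws below the
    observed value (ties randomized uniformly).  Under a correctly specified
    model the residuals are approximately Uniform(0, 1); uniformity is tested
    with a Kolmogorov-Smirnov test.  Requires a converged fit.
    """
    if not results.converged:
        raise NotConvergedError("scaled residuals require a converged fit")
    if n_simulations < 1:
        raise ValueError("n_simulations must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    obs = results.model.endog if y is None else np.asarray(y, dtype=float).ravel()
    sims = results.simulate(rng, n_sims=n_simulations)  # (n_sims, nobs)
    below = np.sum(sims < obs[None, :], axis=0)
    ties = np.sum(sims == obs[None, :], axis=0)
    resid = (below + rng.uniform(size=obs.size) * ties) / n_simulations
    stat, p = stats.kstest(resid, "uniform")
    return ResidualDiagnostics(scaled_residuals=resid,
                               uniformity_statistic=float(stat),
                               uniformity_p=float(p),
                               n_simulations=int(n_simulations))
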