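"""Person-level gaussian linear model: Gibbs sampler plus analytic oracles.

The model for one participant's daily series is

    y_t = b0 + b1 * x_t(or t-1) + b2' * DayOfWeek_t + eps_t,
    eps_t ~ Normal(0, sigma^2),

with y in minutes of sleep and x a 1-5 Likert report, so b1 is in minutes
per Likert unit.  Estimation is Bayesian with weakly informative priors
(gaussian, mean 0, scale 2.5, autoscaled by the data SDs as in mainstream
applied-regression defaults): the working prior SD is 2.5*sd(y) for the
intercept and 2.5*sd(y)/sd(x_j) for slope j.  As in those defaults, the
predictors are centered internally and the intercept prior applies to the
centered intercept (the expected outcome at average predictor values);
the fitted intercept is translated back to the raw scale.  Without
centering, a mean-zero prior on an intercept of several hundred minutes
would leak shrinkage into the slope through the intercept-predictor
correlation.  Internally the coefficient
prior is carried in normal-inverse-gamma form, beta | sigma^2 ~
N(0, sigma^2 V0) with V0 chosen so the prior SD of beta_j equals the
working SD at the prior-mean residual variance; this makes the posterior
available in closed form (:class:`ConjugateILM`), and the Gibbs sampler
(:class:`BayesianILM`) targets exactly that posterior, so the sampler is
checkable against an analytic oracle.  The residual variance gets a vague
inverse-gamma prior IG(2, sd(y)^2).

Estimators follow the scikit-learn protocol (``fit(X, y)``, fitted
attributes with trailing underscores, ``get_params``/``set_params``); X is
the design without the intercept column (predictor first, then weekday
dummies), and the intercept is handled internally.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg
from sklearn.base import BaseEstimator, RegressorMixin

from .prep import InsufficientDataError, ModelData

__all__ = [
    "PriorSpec",
    "PosteriorDraws",
    "BayesianILM",
    "ConjugateILM",
    "OLSResult",
    "RankDeficiencyError",
    "fit_ols",
    "fit_conjugate",
    "fit_mcmc",
]

DEFAULT_CHAINS = 4
DEFAULT_ITERATIONS = 5000
DEFAULT_WARMUP = 2500


class RankDeficiencyError(ValueError):
    """The design matrix does not identify the requested coefficient."""


@dataclass(frozen=True)
class PriorSpec:
    """Weakly informative gaussian prior on the regression coefficients.

    With ``autoscale`` on (the default), the working prior SD for slope j
    is ``scale * sd(y) / sd(x_j)`` and for the intercept ``scale * sd(y)``;
    with it off, every coefficient gets prior SD ``scale`` on the raw
    scale.  ``scale = inf`` gives the flat-prior (OLS) limit.
    """

    location: float = 0.0
    scale: float = 2.5
    autoscale: bool = True

    def __post_init__(self) -> None:
        if not self.scale > 0:
            raise ValueError("prior scale must be > 0")

    def working_sds(self, X: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Prior SDs for [intercept, columns of X]."""
        p = X.shape[1]
        if not np.isfinite(self.scale):
            return np.full(p + 1, np.inf)
        if not self.autoscale:
            return np.full(p + 1, self.scale)
        sy = float(np.std(y, ddof=1)) if len(y) > 1 else 1.0
        sy = sy if sy > 0 else 1.0
        sds = np.empty(p + 1)
        sds[0] = self.scale * sy
        for j in range(p):
            sx = float(np.std(X[:, j], ddof=1)) if len(y) > 1 else 0.0
            sds[j + 1] = self.scale * sy / sx if sx > 0 else self.scale * sy
        return sds


class PosteriorDraws:
    """Multi-chain MCMC output for the model's parameters.

    ``draws`` is shaped (chains, iterations, parameters); the last
    parameter is the residual SD ``sigma``, the rest are regression
    coefficients in ``parameter_names`` order.
    """

    def __init__(self, draws: np.ndarray, parameter_names: list[str]):
        draws = np.asarray(draws, dtype=float)
        if draws.ndim != 3 or draws.shape[2] != len(parameter_names):
            raise ValueError("draws must be (chains, iterations, parameters)")
        self.draws = draws
        self.parameter_names = list(parameter_names)

    @property
    def chains(self) -> int:
        return self.draws.shape[0]

    @property
    def iterations_per_chain(self) -> int:
        return self.draws.shape[1]

    @property
    def total(self) -> int:
        return self.chains * self.iterations_per_chain

    def _idx(self, parameter: str) -> int:
        try:
            return self.parameter_names.index(parameter)
        except ValueError:
            raise KeyError(f"unknown parameter {parameter!r}") from None

    def get(self, parameter: str) -> np.ndarray:
        """(chains, iterations) array for one parameter."""
        return self.draws[:, :, self._idx(parameter)]

    def pooled(self, parameter: str) -> np.ndarray:
        """All post-warmup draws of one parameter, chains concatenated."""
        return self.get(parameter).reshape(-1)

    def median(self, parameter: str) -> float:
        return float(np.median(self.pooled(parameter)))

    def coefficient_names(self) -> list[str]:
        return [n for n in self.parameter_names if n != "sigma"]

    def coefficient_draws(self) -> np.ndarray:
        """(total, n_coefficients) pooled coefficient draws."""
        cols = [self._idx(n) for n in self.coefficient_names()]
        return self.draws.reshape(self.total, -1)[:, cols]

    def to_frame(self):
        """Long-format (chain, iteration, parameter, value) DataFrame."""
        import pandas as pd

        c, n, p = self.draws.shape
        chain = np.repeat(np.arange(c), n * p)
        iteration = np.tile(np.repeat(np.arange(n), p), c)
        name = np.tile(np.array(self.parameter_names, dtype=object), c * n)
        return pd.DataFrame(
            {
                "chain": chain,
                "iteration": iteration,
                "parameter": name,
                "value": self.draws.reshape(-1),
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# estimators


def _check_Xy(X, y):
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).reshape(-1)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X must be 2-D with one row per element of y")
    if not (np.isfinite(X).all() and np.isfinite(y).all()):
        raise ValueError("X and y must be finite")
    return X, y


def _nig_prior(X, y, prior: PriorSpec):
    """Return (V0_inv diagonal, a0, b0, sy2) for the NIG parameterization."""
    n = len(y)
    sy = float(np.std(y, ddof=1)) if n > 1 else 1.0
    sy2 = sy * sy if sy > 0 else 1.0
    a0, b0 = 2.0, sy2  # vague inverse-gamma on sigma^2, prior mean sd(y)^2
    w = prior.working_sds(X, y)
    with np.errstate(divide="ignore"):
        v0_inv = np.where(np.isinf(w), 0.0, sy2 / np.square(w))
    return v0_inv, a0, b0, sy2


class ConjugateILM(BaseEstimator, RegressorMixin):
    """Closed-form normal-inverse-gamma posterior for the person-level model.

    Analytic oracle for :class:`BayesianILM`: both target the identical
    posterior, so MCMC summaries must agree with these moments up to
    Monte-Carlo error.  In the flat-prior limit the posterior mean equals
    the OLS solution; with no data the posterior equals the prior.
    """

    def __init__(self, prior: PriorSpec | None = None):
        self.prior = prior

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        prior = self.prior if self.prior is not None else PriorSpec()
        n, p = X.shape
        col_means = X.mean(axis=0) if n else np.zeros(p)
        Xc = X - col_means
        Xd = np.column_stack([np.ones(n), Xc]) if n else np.empty((0, p + 1))
        v0_inv, a0, b0, _ = _nig_prior(X, y, prior)
        if n == 0 and not np.all(v0_inv > 0):
            raise ValueError("no data requires a proper prior")
        A = (Xd.T @ Xd if n else np.zeros((p + 1, p + 1))) + np.diag(v0_inv)
        if np.linalg.matrix_rank(A) < p + 1:
            raise RankDeficiencyError(
                "design is rank deficient under a flat prior; drop the "
                "unidentified column or use a proper prior"
            )
        c = Xd.T @ y if n else np.zeros(p + 1)
        Vn = np.linalg.inv(A)
        mn = Vn @ c
        an = a0 + n / 2.0
        bn = b0 + 0.5 * (float(y @ y) - float(mn @ A @ mn))
        # translate the centered-scale posterior back to the raw scale
        T = np.eye(p + 1)
        T[0, 1:] = -col_means
        mn_raw = T @ mn
        Vn_raw = T @ Vn @ T.T
        self.n_features_in_ = p
        self.col_means_ = col_means
        self.posterior_mean_ = mn_raw
        self.V_n_ = Vn_raw
        self.a_n_ = an
        self.b_n_ = bn
        self.n_obs_ = n
        # marginal posterior of beta is multivariate-t; its covariance:
        self.posterior_cov_ = (
            (bn / (an - 1.0)) * Vn_raw if an > 1 else np.full_like(Vn_raw, np.nan)
        )
        self.sigma2_mean_ = bn / (an - 1.0) if an > 1 else np.nan
        self.coef_ = mn_raw[1:]
        self.intercept_ = float(mn_raw[0])
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


class BayesianILM(BaseEstimator, RegressorMixin):
    """Gibbs-sampled Bayesian linear regression for one participant.

    Alternates exact conjugate conditionals — coefficients | sigma from a
    multivariate normal, sigma^2 | coefficients from an inverse gamma — so
    the stationary distribution is precisely the :class:`ConjugateILM`
    posterior.  ``iterations`` counts all sampling iterations per chain
    *including* the ``warmup`` burn-in that is discarded; the default
    4 x (5000 - 2500) leaves 10,000 retained draws.  Chains start from
    overdispersed draws of the prior and the run is deterministic given
    ``random_state``.
    """

    def __init__(
        self,
        prior: PriorSpec | None = None,
        chains: int = DEFAULT_CHAINS,
        iterations: int = DEFAULT_ITERATIONS,
        warmup: int = DEFAULT_WARMUP,
        random_state: int | None = None,
        feature_names: list[str] | None = None,
    ):
        self.prior = prior
        self.chains = chains
        self.iterations = iterations
        self.warmup = warmup
        self.random_state = random_state
        self.feature_names = feature_names

    def fit(self, X, y):
        X, y = _check_Xy(X, y)
        if self.chains < 2:
            raise ValueError("at least 2 chains are required")
        if not 0 <= self.warmup < self.iterations:
            raise ValueError("need 0 <= warmup < iterations")
        prior = self.prior if self.prior is not None else PriorSpec()
        n, p = X.shape
        if n <= p + 1:
            raise InsufficientDataError(
                f"n={n} observations cannot support {p + 1} coefficients"
            )
        col_means = X.mean(axis=0)
        Xd = np.column_stack([np.ones(n), X - col_means])
        v0_inv, a0, b0, sy2 = _nig_prior(X, y, prior)
        A = Xd.T @ Xd + np.diag(v0_inv)
        c = Xd.T @ y
        yty = float(y @ y)
        Vn = np.linalg.inv(A)
        mn = Vn @ c
        L = np.linalg.cholesky(Vn)

        kept = self.iterations - self.warmup
        k = p + 1
        out = np.empty((self.chains, kept, k + 1))
        an_cond = a0 + (n + k) / 2.0
        ss = np.random.SeedSequence(self.random_state)
        for ci, child in enumerate(ss.spawn(self.chains)):
            rng = np.random.default_rng(child)
            # overdispersed start: sigma^2 from its (heavy-tailed) prior
            sig2 = b0 / rng.gamma(a0)
            z = rng.standard_normal((self.iterations, k))
            g = rng.gamma(an_cond, 1.0, size=self.iterations)
            for t in range(self.iterations):
                beta = mn + np.sqrt(sig2) * (L @ z[t])
                quad = yty - 2.0 * (beta @ c) + beta @ (A @ beta)
                sig2 = (b0 + 0.5 * quad) / g[t]
                if t >= self.warmup:
                    row = out[ci, t - self.warmup]
                    row[:k] = beta
                    row[0] = beta[0] - beta[1:] @ col_means  # raw-scale intercept
                    row[k] = np.sqrt(sig2)
        if not np.isfinite(out).all():
            raise FloatingPointError("sampler produced non-finite draws")

        names = list(self.feature_names) if self.feature_names else (
            ["intercept"] + [f"x{j}" for j in range(p)]
        )
        if len(names) != k:
            raise ValueError("feature_names must name intercept + each column of X")
        self.parameter_names_ = names + ["sigma"]
        self.draws_ = PosteriorDraws(out, self.parameter_names_)
        med = np.median(out.reshape(-1, k + 1), axis=0)
        self.intercept_ = float(med[0])
        self.coef_ = med[1:k]
        self.sigma_ = float(med[k])
        self.n_features_in_ = p
        self.n_obs_ = n
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        return self.intercept_ + X @ self.coef_


# ---------------------------------------------------------------------------
# OLS


@dataclass
class OLSResult:
    """Frequentist companion fit (point estimates and standard errors)."""

    coef: dict[str, float]
    se: dict[str, float]
    sigma: float
    n_obs: int
    dropped: list[str] = field(default_factory=list)

    @property
    def slope(self) -> float:
        return self.coef["slope"]


def fit_ols(model_data: ModelData) -> OLSResult:
    """Ordinary least squares on a :class:`~idiolm.prep.ModelData` design.

    Weekday contrasts whose day was never observed are dropped with a
    warning; a constant main predictor raises
    :class:`RankDeficiencyError`.  Serves as the flat-prior oracle for the
    Bayesian fits.
    """
    X = model_data.design_matrix()
    names = model_data.feature_names()
    y = model_data.y
    n = len(y)
    if n <= X.shape[1]:
        raise InsufficientDataError(
            f"n={n} observations cannot support {X.shape[1]} coefficients"
        )
    if np.std(model_data.x) == 0.0:
        raise RankDeficiencyError(
            f"predictor is constant for participant {model_data.participant_id}; "
            "the slope is not identified"
        )
    keep = [j for j in range(X.shape[1]) if j < 2 or X[:, j].any()]
    dropped = [names[j] for j in range(X.shape[1]) if j not in keep]
    if dropped:
        warnings.warn(
            f"dropping never-observed weekday contrasts {dropped} for "
            f"participant {model_data.participant_id}",
            stacklevel=2,
        )
    Xk = X[:, keep]
    if np.linalg.matrix_rank(Xk) < Xk.shape[1]:
        raise RankDeficiencyError("design remains rank deficient after dropping")
    beta, _, _, _ = np.linalg.lstsq(Xk, y, rcond=None)
    resid = y - Xk @ beta
    dof = n - Xk.shape[1]
    sigma2 = float(resid @ resid) / dof if dof > 0 else 0.0
    cov = sigma2 * np.linalg.inv(Xk.T @ Xk)
    kept_names = [names[j] for j in keep]
    return OLSResult(
        coef=dict(zip(kept_names, map(float, beta))),
        se=dict(zip(kept_names, map(float, np.sqrt(np.maximum(np.diag(cov), 0.0))))),
        sigma=float(np.sqrt(sigma2)),
        n_obs=n,
        dropped=dropped,
    )


# ---------------------------------------------------------------------------
# ModelData-level wrappers


def _split_design(model_data: ModelData):
    X = model_data.design_matrix()
    return X[:, 1:], model_data.y, model_data.feature_names()


def fit_conjugate(model_data: ModelData, prior: PriorSpec | None = None) -> ConjugateILM:
    Xnoint, y, _ = _split_design(model_data)
    return ConjugateILM(prior=prior).fit(Xnoint, y)


def fit_mcmc(
    model_data: ModelData,
    prior: PriorSpec | None = None,
    chains: int = DEFAULT_CHAINS,
    iterations: int = DEFAULT_ITERATIONS,
    warmup: int = DEFAULT_WARMUP,
    seed: int | None = None,
) -> PosteriorDraws:
    Xnoint, y, names = _split_design(model_data)
    est = BayesianILM(
        prior=prior,
        chains=chains,
        iterations=iterations,
        warmup=warmup,
        random_state=seed,
        feature_names=names,
    ).fit(Xnoint, y)
    return est.draws_
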