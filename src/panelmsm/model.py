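"""Maximum-likelihood fitting of the panel multi-state model.

`PanelMarkovModel` is a scikit-learn-style estimator: construct with the
transition structure and covariate terms, call :meth:`fit` on a
gender-stratum :class:`~panelmsm.data.PanelDataset` (or a raw records
DataFrame), and read the fitted attributes (``params_``, ``loglik_``,
``aic_``, ``covariance_``, ``converged_``).  Hazard ratios, mean sojourn
times, transition probabilities and likelihood-ratio tests are derived from
a fitted instance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize
from sklearn.base import BaseEstimator

from .covariates import CovariateVector
from .data import PanelDataset
from .likelihood import PanelLikelihood
from .states import (
    DEATH,
    STATE_LABELS,
    ModelParameters,
    TransitionStructure,
    default_transition_structure,
    intensity_matrix,
    transition_probability_matrix,
)

#: Fixed normal quantile for 95% intervals (bit-reproducible).
Z95 = 1.959964


def count_parameters(structure: TransitionStructure, covariate_terms=()) -> int:
    """Baseline intensities plus one coefficient per transition and term."""
    return len(structure) * (1 + len(covariate_terms))


@dataclass
class FitResult:
    """MLE output: parameters, likelihood, covariance and bookkeeping."""

    params: ModelParameters
    loglik: float
    n_params: int
    covariance: np.ndarray | None
    converged: bool
    theta: np.ndarray
    terms: tuple
    n_individuals: int
    message: str = ""

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik


class PanelMarkovModel(BaseEstimator):
    """Continuous-time multi-state Markov model for panel observations.

    Parameters
    ----------
    structure : TransitionStructure, optional
        Permitted transitions (default: the 14-transition residency topology).
    covariate_terms : sequence of str
        Design columns (subset of :data:`~panelmsm.covariates.DESIGN_TERMS`);
        empty for the covariate-free (null) model.
    death_mode : {"exact", "panel"}
        Whether a terminal death record is an exactly dated event or an
        interval-censored panel observation.
    tol : float
        Relative log-likelihood convergence tolerance.
    max_iter : int
        Total quasi-Newton iteration cap across restarts; exceeding it flags
        non-convergence.  The 140-parameter covariate model routinely needs
        several hundred iterations.
    compute_covariance : bool
        Invert the observed information at the optimum (finite differences
        of the analytic score); disable to skip the extra work.
    """

    def __init__(self, structure=None, covariate_terms=(), death_mode="exact",
                 tol=1e-8, max_iter=2000, compute_covariance=True):
        self.structure = structure
        self.covariate_terms = covariate_terms
        self.death_mode = death_mode
        self.tol = tol
        self.max_iter = max_iter
        self.compute_covariance = compute_covariance

    # -- fitting -----------------------------------------------------------
    def fit(self, X, y=None):
        """Fit by quasi-Newton ascent from a crude-rate initializer.

        ``X`` is a PanelDataset or an observation DataFrame for one stratum.
        """
        if self.death_mode not in ("exact", "panel"):
            raise ValueError("death_mode must be 'exact' or 'panel'")
        data = self._as_dataset(X)
        structure = self.structure or default_transition_structure()
        terms = tuple(self.covariate_terms)
        engine = PanelLikelihood(
            data, structure, terms, death_exact=(self.death_mode == "exact")
        )

        theta0 = engine.initial_theta()
        ll0 = engine.value(theta0)

        def negloglik(theta):
            ll, g = engine.value_and_grad(theta)
            return -ll, -g

        K = engine.K
        bounds = [(-20.0, 5.0)] * K + [(-10.0, 10.0)] * (engine.n_params - K)
        # L-BFGS-B restarts: resetting the curvature memory escapes the slow
        # plateaus of this badly conditioned likelihood surface
        theta, prev, res = theta0, -np.inf, None
        iters_left = self.max_iter
        settled = False
        while iters_left > 0:
            res = minimize(
                negloglik, theta, jac=True, method="L-BFGS-B", bounds=bounds,
                options={"maxiter": iters_left, "ftol": self.tol,
                         "maxcor": 30},
            )
            theta = res.x
            iters_left -= max(res.nit, 1)
            loglik = -res.fun
            if loglik - prev < max(self.tol * abs(loglik), 1e-4):
                settled = True
                break
            prev = loglik
        loglik = -res.fun
        converged = bool(settled and loglik >= ll0 - 1e-6)

        cov = None
        if self.compute_covariance:
            cov = _observed_information_covariance(engine, theta)
            if cov is not None:
                d = engine.natural_scale_vector()
                cov = cov * np.outer(d, d)

        self.engine_ = engine
        self.result_ = FitResult(
            params=engine.params_from_theta(theta),
            loglik=float(loglik),
            n_params=engine.n_params,
            covariance=cov,
            converged=converged,
            theta=engine.to_natural(theta),
            terms=terms,
            n_individuals=engine.n_ind,
            message=str(res.message),
        )
        self.params_ = self.result_.params
        self.loglik_ = self.result_.loglik
        self.aic_ = self.result_.aic
        self.covariance_ = cov
        self.converged_ = converged
        self.n_params_ = engine.n_params
        self.initial_loglik_ = float(ll0)
        return self

    @staticmethod
    def _as_dataset(X) -> PanelDataset:
        if isinstance(X, PanelDataset):
            return X
        df = pd.DataFrame(X)
        genders = df["gender"].unique()
        if len(genders) != 1:
            raise ValueError(
                "fit expects a single gender stratum; use panelmsm.data."
                "split_by_gender first"
            )
        return PanelDataset(df, str(genders[0]))

    # -- derived quantities -------------------------------------------------
    def hazard_ratios(self) -> pd.DataFrame:
        """HR = exp(beta) with 95% Wald intervals, one row per (transition, term)."""
        self._check_fitted()
        return hazard_ratios(self.result_)

    def sojourn_times(self, z: CovariateVector | None = None) -> pd.DataFrame:
        """Mean sojourn times per transient state with delta-method intervals."""
        self._check_fitted()
        return mean_sojourn_times(self.result_, z)

    def transition_probabilities(self, elapsed: float, z=None) -> np.ndarray:
        self._check_fitted()
        q = intensity_matrix(self.params_, z)
        return transition_probability_matrix(q, elapsed).p

    def _check_fitted(self):
        if not hasattr(self, "result_"):
            raise RuntimeError("model is not fitted; call fit first")


def fit_model(data, structure=None, covariate_terms=(), death_mode="exact",
              **options) -> FitResult:
    """Functional wrapper over :class:`PanelMarkovModel`."""
    est = PanelMarkovModel(
        structure=structure, covariate_terms=covariate_terms,
        death_mode=death_mode, **options,
    )
    return est.fit(data).result_


def _observed_information_covariance(engine: PanelLikelihood, theta,
                                     step: float = 1e-5):
    """Covariance = inverse negative Hessian, by central FD of the score."""
    p = len(theta)
    H = np.empty((p, p))
    for c in range(p):
        h = step * max(1.0, abs(theta[c]))
        tp = theta.copy(); tp[c] += h
        tm = theta.copy(); tm[c] -= h
        _, gp = engine.value_and_grad(tp)
        _, gm = engine.value_and_grad(tm)
        H[:, c] = (gp - gm) / (2.0 * h)
    H = 0.5 * (H + H.T)
    try:
        info = -H
        cov = np.linalg.inv(info)
        if not np.all(np.isfinite(cov)) or np.any(np.diag(cov) <= 0):
            return None
        return cov
    except np.linalg.LinAlgError:
        return None


# ---------------------------------------------------------------------------
# derived tables
# ---------------------------------------------------------------------------

def _theta_index(fit: FitResult, pair, term=None) -> int:
    K = len(fit.params.structure)
    k = fit.params.structure.index(pair)
    if term is None:
        return k
    return K + fit.terms.index(term) * K + k


def hazard_ratios(fit: FitResult, require_covariance: bool = True) -> pd.DataFrame:
    """Per-transition hazard ratios ``exp(beta)`` with 95% CIs.

    Requires the fit's covariance; raises if it is unavailable unless
    ``require_covariance`` is off (then SEs and CI bounds are NaN).
    """
    if fit.covariance is None and require_covariance:
        raise ValueError("covariance unavailable; cannot form confidence intervals")
    rows = []
    for term in fit.terms:
        for pair in fit.params.structure.allowed:
            idx = _theta_index(fit, pair, term)
            beta = fit.theta[idx]
            se = float(np.sqrt(fit.covariance[idx, idx])) \
                if fit.covariance is not None else np.nan
            with np.errstate(over="ignore"):  # an unidentified term has
                rows.append({                 # infinite upper bound
                    "transition": f"{STATE_LABELS[pair[0]]} - {STATE_LABELS[pair[1]]}",
                    "from_state": pair[0],
                    "to_state": pair[1],
                    "term": term,
                    "estimate": beta,
                    "se": se,
                    "hr": np.exp(beta),
                    "ci_low": np.exp(beta - Z95 * se),
                    "ci_high": np.exp(beta + Z95 * se),
                })
    return pd.DataFrame(rows)


def mean_sojourn_times(fit: FitResult, z: CovariateVector | None = None,
                       states=None) -> pd.DataFrame:
    """Mean sojourn time ``-1/q_ii(z)`` per transient state, with 95% CI.

    The standard error comes from the delta method on the log scale
    (``log mean = -log total exit rate``), and the interval is exponentiated
    so its lower bound stays positive.  The absorbing Death state has no
    sojourn time and is rejected if requested explicitly.
    """
    structure = fit.params.structure
    if states is None:
        states = sorted({i for i, _ in structure.allowed})
    if DEATH in states:
        raise ValueError("sojourn time is undefined for the absorbing Death state")

    if z is not None:
        enc, zterms = z.encode()
        zvals = np.array([enc[zterms.index(t)] if t in zterms else 0.0
                          for t in fit.terms])
    else:
        zvals = np.zeros(len(fit.terms))

    rows = []
    for state in states:
        out_pairs = [p for p in structure.allowed if p[0] == state]
        if not out_pairs:
            continue
        rates = []
        for pair in out_pairs:
            eta = fit.params.baseline_log_intensity[pair] + sum(
                v * fit.params.coefficients.get((pair, t), 0.0)
                for v, t in zip(zvals, fit.terms)
            )
            rates.append(np.exp(eta))
        rates = np.array(rates)
        total = rates.sum()
        mean = 1.0 / total

        se = ci_low = ci_high = np.nan
        if fit.covariance is not None:
            # gradient of s = log(total exit rate) in theta
            g = np.zeros(len(fit.theta))
            for r, pair in zip(rates, out_pairs):
                share = r / total
                g[_theta_index(fit, pair)] += share
                for t, v in zip(fit.terms, zvals):
                    g[_theta_index(fit, pair, t)] += share * v
            var_s = float(g @ fit.covariance @ g)
            se_s = np.sqrt(max(var_s, 0.0))
            se = mean * se_s
            with np.errstate(over="ignore"):  # near-flat direction: the
                ci_low = mean * np.exp(-Z95 * se_s)   # upper bound is inf
                ci_high = mean * np.exp(Z95 * se_s)
        rows.append({
            "state": state,
            "label": STATE_LABELS[state],
            "mean_days": mean,
            "se": se,
            "ci_low": ci_low,
            "ci_high": ci_high,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class LRTestResult:
    chisq: float
    df: int
    p_value: float


def likelihood_ratio_test(null_fit: FitResult, full_fit: FitResult) -> LRTestResult:
    """Likelihood-ratio test of a nested null model against the full model."""
    df = full_fit.n_params - null_fit.n_params
    if df <= 0:
        raise ValueError("full model must have more parameters than the null")
    chisq = 2.0 * (full_fit.loglik - null_fit.loglik)
    if chisq < -1e-6:
        raise ValueError(
            "full-model log-likelihood below the null's: optimization failed"
        )
    chisq = max(chisq, 0.0)
    return LRTestResult(chisq=chisq, df=df,
                        p_value=float(stats.chi2.sf(chisq, df)))
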