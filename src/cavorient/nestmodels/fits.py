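"""Model fitting and reporting for the harmonic success models.

Fixed-effects-only fits are delegated to statsmodels GLM; random-intercept
fits use the package's Gauss-Hermite marginal-likelihood fitter. Estimates
are reported both on the link scale and as exponentiated ratios (incidence
rate ratios for Poisson, odds ratios for binomial) with Wald 95% intervals
formed on the link scale and exponentiated.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats, special

from cavorient.errors import (
    ConvergenceError,
    EmptyInputError,
    ModelSpecError,
    ValueRangeError,
)
from cavorient.nestmodels.design import ModelSpec, design_column_names, spec_design
from cavorient.nestmodels.glmm import fit_glmm
from cavorient.records import NestRecord

log = logging.getLogger(__name__)

#: Latent (level-1) residual variance of the logistic distribution.
LOGIT_LATENT_VARIANCE = math.pi**2 / 3.0

#: Below this cluster variance the mixed model is declared singular.
SINGULARITY_TOL = 1e-6


@dataclass(frozen=True)
class HarmonicFit:
    """A fitted harmonic success model with link- and ratio-scale estimates."""

    spec: ModelSpec
    coefficients: pd.DataFrame  # index term; estimate, se, ci_low, ci_high, p_value
    ratio_estimates: pd.DataFrame  # index term; ratio, ci_low, ci_high
    tau00: float
    sigma2_latent: float | None
    icc: float | None
    loglik: float
    n_obs: int
    singular: bool
    cov_beta: np.ndarray = field(repr=False)
    pseudo_r2: tuple[float, float] | None = None

    @property
    def n_params(self) -> int:
        extra = 0 if self.singular or not self.spec.random_intercept else 1
        return len(self.coefficients) + extra

    @property
    def beta(self) -> np.ndarray:
        return self.coefficients["estimate"].to_numpy()


def _response_arrays(records: list[NestRecord], response: str) -> tuple[np.ndarray, np.ndarray | None, list[NestRecord]]:
    """(successes-or-counts, trials-or-None, rows actually used)."""
    if response == "fledglings":
        y = np.array([r.fledglings for r in records], dtype=float)
        return y, None, list(records)
    if response == "hatch":
        used = [r for r in records if r.eggs >= 1]
        y = np.array([r.hatchlings for r in used], dtype=float)
        m = np.array([r.eggs for r in used], dtype=float)
    elif response == "fledge":
        used = [r for r in records if r.hatchlings >= 1]
        y = np.array([r.fledglings for r in used], dtype=float)
        m = np.array([r.hatchlings for r in used], dtype=float)
    else:
        raise ModelSpecError(f"unknown response {response!r}")
    dropped = len(records) - len(used)
    if dropped:
        log.info("%s model: excluded %d rows with zero denominator", response, dropped)
    return y, m, used


def _wald_tables(
    beta: np.ndarray, se: np.ndarray, names: list[str], conf: float = 0.95
) -> tuple[pd.DataFrame, pd.DataFrame]:
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    lo, hi = beta - zcrit * se, beta + zcrit * se
    with np.errstate(divide="ignore"):
        zval = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    p = 2.0 * stats.norm.sf(np.abs(zval))
    coef = pd.DataFrame(
        {"estimate": beta, "se": se, "ci_low": lo, "ci_high": hi, "p_value": p}, index=names
    )
    ratios = pd.DataFrame(
        {"ratio": np.exp(beta), "ci_low": np.exp(lo), "ci_high": np.exp(hi)}, index=names
    )
    return coef, ratios


def _fit_glm(X: np.ndarray, y: np.ndarray, trials: np.ndarray | None, family: str):
    if family == "poisson_count":
        model = sm.GLM(y, X, family=sm.families.Poisson())
    else:
        endog = np.column_stack([y, trials - y])
        model = sm.GLM(endog, X, family=sm.families.Binomial())
    try:
        return model.fit(maxiter=200, tol=1e-10)
    except Exception as exc:  # perfect separation and friends
        raise ConvergenceError(f"GLM fit failed: {exc}") from exc


def _assemble(
    spec: ModelSpec,
    beta: np.ndarray,
    se: np.ndarray,
    cov_beta: np.ndarray,
    loglik: float,
    n_obs: int,
    tau00: float,
    singular: bool,
) -> HarmonicFit:
    names = design_column_names(spec)
    coef, ratios = _wald_tables(beta, se, names)
    if spec.family == "binomial_rate":
        s2 = LOGIT_LATENT_VARIANCE
        icc = tau00 / (tau00 + s2)
    else:
        s2, icc = None, None
    return HarmonicFit(
        spec=spec,
        coefficients=coef,
        ratio_estimates=ratios,
        tau00=float(tau00),
        sigma2_latent=s2,
        icc=icc,
        loglik=float(loglik),
        n_obs=int(n_obs),
        singular=singular,
        cov_beta=cov_beta,
    )


def _fit_harmonic(records: list[NestRecord], spec: ModelSpec) -> HarmonicFit:
    if not records:
        raise EmptyInputError("no nest records supplied")
    y, trials, used = _response_arrays(records, spec.response)
    if y.size == 0:
        raise EmptyInputError(f"no usable rows for response {spec.response!r}")
    direction = [r.direction_deg for r in used]
    adults = [r.adults for r in used]
    X = spec_design(spec, direction, adults)
    if y.size <= X.shape[1]:
        raise ValueRangeError(
            f"n_obs={y.size} must exceed the {X.shape[1]} parameters of the model"
        )
    if trials is not None:
        if np.all(y == trials) or np.all(y == 0):
            raise ConvergenceError(
                f"{spec.response} response is all successes or all failures (complete separation)"
            )

    glm = _fit_glm(X, y, trials, spec.family)
    if not spec.random_intercept:
        return _assemble(
            spec, np.asarray(glm.params), np.asarray(glm.bse),
            np.asarray(glm.cov_params()), float(glm.llf), y.size, 0.0, False,
        )

    groups = np.array([r.cluster_id for r in used])
    fam = "poisson" if spec.family == "poisson_count" else "binomial"
    mixed = fit_glmm(X, y, groups, fam, trials=trials, start_beta=np.asarray(glm.params))
    if mixed.tau00 < SINGULARITY_TOL:
        # variance at (numerically) zero: report the fixed-effects-only refit
        return _assemble(
            spec, np.asarray(glm.params), np.asarray(glm.bse),
            np.asarray(glm.cov_params()), float(glm.llf), y.size, 0.0, True,
        )
    return _assemble(
        spec, mixed.beta, mixed.se_beta, mixed.cov_beta, mixed.loglik, y.size,
        mixed.tau00, False,
    )


def fit_fecundity(records: list[NestRecord], spec: ModelSpec) -> HarmonicFit:
    """Poisson (log link) model of total fledglings per nest.

    With ``spec.random_intercept`` the cluster variance is estimated by
    marginal ML; an estimate below tolerance triggers a fixed-effects-only
    refit flagged ``singular=True``.
    """
    if spec.family != "poisson_count":
        raise ModelSpecError("fit_fecundity requires family='poisson_count'")
    for r in records:
        if r.fledglings < 0 or int(r.fledglings) != r.fledglings:
            raise ValueRangeError(f"cluster {r.cluster_id!r}: non-integer or negative fledglings")
    return _fit_harmonic(records, spec)


def fit_rate_glmm(records: list[NestRecord], spec: ModelSpec) -> HarmonicFit:
    """Binomial-logit model of hatch or fledge rate with a cluster random intercept.

    Rows with a zero denominator are excluded (logged). Reports ``tau00``
    and the ICC against the logistic latent residual variance pi^2/3.
    """
    if spec.family != "binomial_rate":
        raise ModelSpecError("fit_rate_glmm requires family='binomial_rate'")
    if spec.response not in ("hatch", "fledge"):
        raise ModelSpecError("rate models need response 'hatch' or 'fledge'")
    return _fit_harmonic(records, spec)


def fit_null(records: list[NestRecord], family: str, response: str, random_intercept: bool = True) -> HarmonicFit:
    """Intercept(+random)-only reference fit on the same rows."""
    spec = ModelSpec(
        family=family, response=response, cycles=frozenset(),
        include_adults=False, interactions=frozenset(), random_intercept=random_intercept,
    )
    return _fit_harmonic(records, spec)


def pseudo_r2(fit: HarmonicFit, null_fit: HarmonicFit) -> tuple[float, float]:
    """Cox & Snell and Nagelkerke pseudo-R-squared from two nested fits."""
    if fit.n_obs != null_fit.n_obs:
        raise ValueRangeError("fits compare different numbers of observations")
    ll1, ll0, n = fit.loglik, null_fit.loglik, fit.n_obs
    if ll1 < ll0 - 1e-8:
        raise ValueRangeError(
            f"full-model loglik {ll1:.6f} below null loglik {ll0:.6f}; models are not nested"
        )
    cox_snell = 1.0 - math.exp(min(2.0 * (ll0 - ll1) / n, 0.0))
    denom = 1.0 - math.exp(2.0 * ll0 / n)
    nagelkerke = cox_snell / denom if denom > 0 else float("nan")
    return cox_snell, nagelkerke


def predict_success(
    fit: HarmonicFit,
    direction_grid: np.ndarray,
    adults_levels: list[int],
    conf: float = 0.95,
) -> pd.DataFrame:
    """Response-scale predictions with delta-method CIs on a direction grid.

    One curve per adults level; random effects enter at their mean (zero),
    matching the usual fixed-effects prediction curve.
    """
    grid = np.asarray(direction_grid, dtype=float)
    if grid.size == 0:
        raise EmptyInputError("empty direction grid")
    zcrit = stats.norm.ppf(0.5 + conf / 2.0)
    beta = fit.beta
    rows = []
    for a in adults_levels:
        X = spec_design(fit.spec, grid, np.full(grid.shape, a))
        eta = X @ beta
        se_eta = np.sqrt(np.clip(np.einsum("ij,jk,ik->i", X, fit.cov_beta, X), 0.0, None))
        if fit.spec.family == "poisson_count":
            mu = np.exp(eta)
            dmu = mu
        else:
            mu = special.expit(eta)
            dmu = mu * (1.0 - mu)
        se_mu = dmu * se_eta
        rows.append(
            pd.DataFrame(
                {
                    "direction_deg": grid,
                    "adults": a,
                    "predicted": mu,
                    "ci_low": mu - zcrit * se_mu,
                    "ci_high": mu + zcrit * se_mu,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def refit_without_random_intercept(records: list[NestRecord], fit: HarmonicFit) -> HarmonicFit:
    """Fixed-effects-only refit of the same specification (diagnostic helper)."""
    return _fit_harmonic(records, replace(fit.spec, random_intercept=False))
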