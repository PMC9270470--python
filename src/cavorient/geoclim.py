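"""Population-level gradient analyses.

Mean cavity directions across populations are regressed on latitude and on
climate principal components; a permutation partial Mantel test asks
whether climate distances explain direction distances once latitude is
controlled; and a sunset-azimuth helper quantifies how much of the
latitudinal gradient plain solar geometry could account for.

The linear treatment of mean direction is only valid when all population
means fall inside one contiguous arc narrower than 180 degrees; a wider
spread raises :class:`~cavorient.errors.WraparoundError` rather than
silently producing nonsense.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from cavorient.errors import (
    ConsistencyError,
    InsufficientDataError,
    ValueRangeError,
    WraparoundError,
)


@dataclass(frozen=True)
class SiteSummary:
    """Per-population circular summary plus coordinates."""

    site: str
    latitude_deg: float
    longitude_deg: float
    mean_dir_deg: float
    r: float
    n: int | None = None


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    se_slope: float
    t_statistic: float
    df: int
    p_value: float
    r_squared: float


@dataclass(frozen=True)
class PCAResult:
    loadings: pd.DataFrame  # variables x components
    scores: pd.DataFrame  # sites x components
    variance_proportion: np.ndarray
    dropped_variables: tuple[str, ...] = ()


@dataclass(frozen=True)
class MantelResult:
    partial_r: float
    p_value: float
    n_perm: int
    seed: int | None
    perm_r: np.ndarray = field(repr=False, default=None)


def arc_span_deg(angles_deg: Sequence[float]) -> float:
    """Width of the smallest contiguous arc containing all angles."""
    a = np.sort(np.asarray(angles_deg, dtype=float) % 360.0)
    if a.size <= 1:
        return 0.0
    gaps = np.diff(np.concatenate([a, [a[0] + 360.0]]))
    return float(360.0 - gaps.max())


def _check_linearizable(mean_dirs: Sequence[float]) -> None:
    span = arc_span_deg(mean_dirs)
    if span >= 180.0:
        raise WraparoundError(
            f"mean directions span a {span:.1f} degree arc (>= 180); the linear "
            f"treatment is invalid — re-center angles before regressing"
        )


def _ols_simple(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    X = sm.add_constant(x)
    fit = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        se_slope=float(fit.bse[1]),
        t_statistic=float(fit.tvalues[1]),
        df=int(fit.df_resid),
        p_value=float(fit.pvalues[1]),
        r_squared=float(fit.rsquared),
    )


def latitude_regression(summaries: Sequence[SiteSummary]) -> RegressionResult:
    """OLS of population mean direction (degrees) on latitude, t test on the slope."""
    if len(summaries) < 3:
        raise InsufficientDataError(f"latitude regression needs >= 3 sites, got {len(summaries)}")
    dirs = [s.mean_dir_deg for s in summaries]
    _check_linearizable(dirs)
    x = np.array([s.latitude_deg for s in summaries], dtype=float)
    return _ols_simple(x, np.asarray(dirs, dtype=float))


def climate_pca(climate_table: pd.DataFrame) -> PCAResult:
    """PCA of the standardized (z-scored) climate table.

    Implemented as the eigendecomposition of the sample correlation matrix.
    Component signs are fixed so the largest-magnitude loading on each
    component is positive. Zero-variance variables are dropped (their
    standardization is undefined).
    """
    if climate_table.shape[0] < 3:
        raise InsufficientDataError("climate PCA needs >= 3 sites")
    if climate_table.isna().any().any():
        raise ConsistencyError("climate table contains missing values")
    sd = climate_table.std(axis=0, ddof=1)
    dropped = tuple(sd.index[sd == 0.0])
    table = climate_table.drop(columns=list(dropped))
    if table.shape[1] == 0:
        raise ConsistencyError("all climate variables have zero variance")
    z = (table - table.mean(axis=0)) / table.std(axis=0, ddof=1)
    corr = np.cov(z.to_numpy(), rowvar=False, ddof=1)
    corr = np.atleast_2d(corr)
    eigval, eigvec = np.linalg.eigh(corr)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = np.clip(eigval[order], 0.0, None), eigvec[:, order]
    # deterministic sign: largest |loading| positive per component
    for j in range(eigvec.shape[1]):
        k = int(np.argmax(np.abs(eigvec[:, j])))
        if eigvec[k, j] < 0:
            eigvec[:, j] *= -1.0
    comp_names = [f"PC{i + 1}" for i in range(eigvec.shape[1])]
    loadings = pd.DataFrame(eigvec, index=table.columns, columns=comp_names)
    scores = pd.DataFrame(z.to_numpy() @ eigvec, index=table.index, columns=comp_names)
    return PCAResult(
        loadings=loadings,
        scores=scores,
        variance_proportion=eigval / eigval.sum(),
        dropped_variables=dropped,
    )


def pc_regression(summaries: Sequence[SiteSummary], pca: PCAResult, component: str = "PC1") -> RegressionResult:
    """OLS of mean direction on one principal-component score."""
    if len(summaries) < 3:
        raise InsufficientDataError("PC regression needs >= 3 sites")
    dirs = [s.mean_dir_deg for s in summaries]
    _check_linearizable(dirs)
    try:
        x = pca.scores.loc[[s.site for s in summaries], component].to_numpy(dtype=float)
    except KeyError as exc:
        raise ConsistencyError(f"PCA scores missing a site or component: {exc}") from exc
    return _ols_simple(x, np.asarray(dirs, dtype=float))


# ---------------------------------------------------------------------------
# Partial Mantel test
# ---------------------------------------------------------------------------

def direction_distance_matrix(summaries: Sequence[SiteSummary]) -> np.ndarray:
    """Pairwise absolute differences in mean direction (plain, not circular)."""
    d = np.asarray([s.mean_dir_deg for s in summaries], dtype=float)
    _check_linearizable(d)
    return np.abs(d[:, None] - d[None, :])


def latitude_distance_matrix(summaries: Sequence[SiteSummary]) -> np.ndarray:
    lat = np.asarray([s.latitude_deg for s in summaries], dtype=float)
    return np.abs(lat[:, None] - lat[None, :])


def climate_distance_matrix(climate_table: pd.DataFrame, site_order: Sequence[str]) -> np.ndarray:
    """Euclidean distances on the standardized climate variables."""
    table = climate_table.loc[list(site_order)]
    sd = table.std(axis=0, ddof=1)
    table = table.loc[:, sd > 0]
    z = ((table - table.mean(axis=0)) / table.std(axis=0, ddof=1)).to_numpy()
    diff = z[:, None, :] - z[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def _check_distance_matrix(m: np.ndarray, name: str, n: int) -> None:
    if m.shape != (n, n):
        raise ValueRangeError(f"{name}: expected a {n}x{n} matrix, got {m.shape}")
    if not np.allclose(m, m.T):
        raise ConsistencyError(f"{name}: matrix is not symmetric")
    if not np.allclose(np.diag(m), 0.0):
        raise ConsistencyError(f"{name}: diagonal is not zero")


def _partial_corr(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    rxy = np.corrcoef(x, y)[0, 1]
    rxz = np.corrcoef(x, z)[0, 1]
    ryz = np.corrcoef(y, z)[0, 1]
    denom = (1.0 - rxz**2) * (1.0 - ryz**2)
    if denom <= 1e-15:
        raise ConsistencyError(
            "covariate distances are perfectly collinear with another matrix; "
            "the partial correlation is undefined"
        )
    return float((rxy - rxz * ryz) / math.sqrt(denom))


def partial_mantel(
    d_response: np.ndarray,
    d_predictor: np.ndarray,
    d_covariate: np.ndarray,
    n_perm: int = 1000,
    seed: int | None = None,
    permute: str = "response",
    exhaustive: bool = False,
) -> MantelResult:
    """Permutation partial Mantel test (two-tailed).

    The statistic is the Pearson partial correlation of the vectorized upper
    triangles of the response and predictor distance matrices, controlling
    for the covariate matrix. Significance comes from jointly permuting the
    rows and columns of the response matrix (``permute="response"``, the
    default) or of the residual matrix of response on covariate
    (``permute="residual"``). ``exhaustive=True`` enumerates all n!
    permutations instead of sampling (small n only).
    """
    dr = np.asarray(d_response, dtype=float)
    n = dr.shape[0]
    if n < 4:
        raise InsufficientDataError("partial Mantel needs matrices of dimension >= 4")
    dp = np.asarray(d_predictor, dtype=float)
    dc = np.asarray(d_covariate, dtype=float)
    for m, name in ((dr, "response"), (dp, "predictor"), (dc, "covariate")):
        _check_distance_matrix(m, name, n)
    if permute not in ("response", "residual"):
        raise ValueError(f"permute must be 'response' or 'residual', got {permute!r}")

    iu = np.triu_indices(n, k=1)
    x, y, z = dr[iu], dp[iu], dc[iu]
    r_obs = _partial_corr(x, y, z)

    if permute == "residual":
        beta = np.polyfit(z, x, 1)
        resid = x - np.polyval(beta, z)
        perm_source = np.zeros_like(dr)
        perm_source[iu] = resid
        perm_source = perm_source + perm_source.T
    else:
        perm_source = dr

    if exhaustive:
        from itertools import permutations

        perms = [np.array(p) for p in permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]

    perm_r = np.empty(len(perms))
    for i, p in enumerate(perms):
        xp = perm_source[np.ix_(p, p)][iu]
        perm_r[i] = _partial_corr(xp, y, z)

    if exhaustive:
        # the identity permutation is part of the enumeration
        p_value = float(np.count_nonzero(np.abs(perm_r) >= abs(r_obs) - 1e-12) / len(perms))
        n_used = len(perms)
    else:
        b = int(np.count_nonzero(np.abs(perm_r) >= abs(r_obs) - 1e-12))
        p_value = (1 + b) / (n_perm + 1)
        n_used = n_perm
    return MantelResult(partial_r=r_obs, p_value=float(p_value), n_perm=n_used, seed=seed, perm_r=perm_r)


# ---------------------------------------------------------------------------
# Sunset azimuth
# ---------------------------------------------------------------------------

def solar_declination_deg(day_of_year: float) -> float:
    """Sinusoidal approximation of solar declination (degrees)."""
    return 23.44 * math.sin(2.0 * math.pi * (day_of_year - 80.0) / 365.25)


def sunset_azimuth(latitude_deg: float, day_of_year: float) -> float:
    """Azimuth of sunset (degrees clockwise from north) at a given latitude and date.

    ``A = 360 - arccos(sin(declination) / cos(latitude))``; at an equinox
    this is exactly 270 (due west). Latitudes inside the polar circles, or
    dates without a sunset, raise a range error.
    """
    if not abs(latitude_deg) < 66.5:
        raise ValueRangeError(f"latitude {latitude_deg} is in the polar regime (|lat| >= 66.5)")
    delta = math.radians(solar_declination_deg(day_of_year))
    ratio = math.sin(delta) / math.cos(math.radians(latitude_deg))
    if abs(ratio) > 1.0:
        raise ValueRangeError("no sunset at this latitude/date (polar day or night)")
    return 360.0 - math.degrees(math.acos(ratio))


def sunset_gradient_contrast(
    summaries: Sequence[SiteSummary], day_of_year: float = 172.0
) -> dict[str, float]:
    """Compare the fitted orientation-vs-latitude slope with the sunset-azimuth slope.

    Returns both per-degree-latitude gradients and their ratio; the sunset
    gradient is evaluated as the secant slope of the sunset azimuth across
    the observed latitude range at the given date.
    """
    reg = latitude_regression(summaries)
    lats = [s.latitude_deg for s in summaries]
    lo, hi = min(lats), max(lats)
    if hi - lo <= 0:
        raise InsufficientDataError("sites span zero latitude range")
    sunset_slope = (sunset_azimuth(hi, day_of_year) - sunset_azimuth(lo, day_of_year)) / (hi - lo)
    return {
        "orientation_slope_deg_per_lat": reg.slope,
        "sunset_slope_deg_per_lat": sunset_slope,
        "ratio": abs(reg.slope) / abs(sunset_slope) if sunset_slope != 0 else math.inf,
    }
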