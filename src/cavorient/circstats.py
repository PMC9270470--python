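"""Circular descriptive statistics by vector addition.

Every bearing is a unit vector; the mean direction is the direction of the
vector sum and the mean resultant length ``r`` is its norm divided by the
sample size (0 = uniform spread, 1 = perfect concentration).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from cavorient.errors import EmptyInputError, InsufficientDataError

#: Below this resultant length the mean direction is reported as undefined.
R_UNDEFINED_TOL = 1e-12


@dataclass(frozen=True)
class CircularSummary:
    """Descriptive circular statistics for one group of bearings."""

    n: int
    mean_dir_deg: float | None  # None when r is (numerically) zero
    r: float
    rayleigh_z: float | None = None
    rayleigh_p: float | None = None
    ci_low_deg: float | None = None
    ci_high_deg: float | None = None


def _unit_vectors(angles_deg: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    theta = np.deg2rad(angles_deg)
    return np.cos(theta), np.sin(theta)


def circ_mean(angles_deg: Sequence[float]) -> tuple[float | None, float]:
    """Mean direction (degrees in [0, 360), or None) and mean resultant length r.

    Raises
    ------
    EmptyInputError
        If no angles are supplied.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise EmptyInputError("circ_mean requires at least one angle")
    c, s = _unit_vectors(a)
    cbar, sbar = c.mean(), s.mean()
    r = float(np.hypot(cbar, sbar))
    if r < R_UNDEFINED_TOL:
        return None, 0.0
    mean = float(np.rad2deg(np.arctan2(sbar, cbar))) % 360.0
    if mean >= 360.0:  # -eps % 360 can round up to exactly 360
        mean = 0.0
    return mean, min(r, 1.0)


def resultant_length(angles_deg: np.ndarray) -> float:
    """Mean resultant length only (vectorization-friendly fast path)."""
    c, s = _unit_vectors(np.asarray(angles_deg, dtype=float))
    return float(np.hypot(c.mean(), s.mean()))


def rayleigh_test(angles_deg: Sequence[float]) -> tuple[float, float]:
    """Rayleigh test of circular uniformity against a unimodal alternative.

    Returns ``(z, p)`` with ``z = n * r**2`` and the second-order series
    approximation

    ``p = exp(-z) * [1 + (2z - z^2)/(4n) - (24z - 132z^2 + 76z^3 - 9z^4)/(288 n^2)]``

    clamped to [0, 1].
    """
    a = np.asarray(angles_deg, dtype=float)
    n = a.size
    if n < 3:
        raise InsufficientDataError(f"Rayleigh test needs n >= 3, got {n}")
    if n < 10:
        warnings.warn(f"Rayleigh test with n={n} < 10 has limited power", stacklevel=2)
    r = resultant_length(a)
    z = n * r * r
    p = np.exp(-z) * (
        1.0
        + (2.0 * z - z * z) / (4.0 * n)
        - (24.0 * z - 132.0 * z**2 + 76.0 * z**3 - 9.0 * z**4) / (288.0 * n * n)
    )
    return float(z), float(min(max(p, 0.0), 1.0))


def _wrap_deviation(deg: np.ndarray) -> np.ndarray:
    """Wrap angular differences into (-180, 180]."""
    return -((-np.asarray(deg) + 180.0) % 360.0 - 180.0)


def bootstrap_mean_ci(
    angles_deg: Sequence[float],
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the mean direction.

    The percentile interval is formed on the angular deviations of the
    bootstrap means from the observed mean (wrapped into (-180, 180]) to
    handle wraparound, then mapped back to bearings. Replicates whose
    resample is perfectly balanced (r = 0, undefined mean) are redrawn.
    """
    a = np.asarray(angles_deg, dtype=float)
    if a.size < 10:
        raise InsufficientDataError(f"bootstrap CI needs n >= 10, got {a.size}")
    if n_boot < 200:
        raise InsufficientDataError(f"bootstrap CI needs n_boot >= 200, got {n_boot}")
    mean_obs, r_obs = circ_mean(a)
    if mean_obs is None:
        raise InsufficientDataError("observed mean direction undefined (r = 0)")
    if rng is None:
        rng = np.random.default_rng(seed)

    theta = np.deg2rad(a)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    idx = rng.integers(0, a.size, size=(n_boot, a.size))
    cbar = cos_t[idx].mean(axis=1)
    sbar = sin_t[idx].mean(axis=1)
    r_boot = np.hypot(cbar, sbar)
    bad = r_boot < R_UNDEFINED_TOL
    n_redrawn = 0
    while bad.any():  # degenerate resamples redrawn; vanishingly rare in practice
        n_redrawn += int(bad.sum())
        idx = rng.integers(0, a.size, size=(int(bad.sum()), a.size))
        cbar[bad] = cos_t[idx].mean(axis=1)
        sbar[bad] = sin_t[idx].mean(axis=1)
        r_boot = np.hypot(cbar, sbar)
        bad = r_boot < R_UNDEFINED_TOL
    if n_redrawn:
        warnings.warn(f"{n_redrawn} degenerate bootstrap replicates redrawn", stacklevel=2)

    means = np.rad2deg(np.arctan2(sbar, cbar)) % 360.0
    dev = _wrap_deviation(means - mean_obs)
    alpha = 1.0 - conf
    lo, hi = np.quantile(dev, [alpha / 2.0, 1.0 - alpha / 2.0])
    return float((mean_obs + lo) % 360.0), float((mean_obs + hi) % 360.0)


def summarize(
    angles_deg: Sequence[float],
    *,
    ci: bool = False,
    n_boot: int = 1000,
    conf: float = 0.95,
    seed: int | None = None,
) -> CircularSummary:
    """Full circular summary: mean, r, Rayleigh test, optional bootstrap CI."""
    a = np.asarray(angles_deg, dtype=float)
    mean, r = circ_mean(a)
    z = p = None
    if a.size >= 3:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z, p = rayleigh_test(a)
    lo = hi = None
    if ci and a.size >= 10 and mean is not None:
        lo, hi = bootstrap_mean_ci(a, n_boot=n_boot, conf=conf, seed=seed)
    return CircularSummary(
        n=int(a.size), mean_dir_deg=mean, r=r, rayleigh_z=z, rayleigh_p=p,
        ci_low_deg=lo, ci_high_deg=hi,
    )
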