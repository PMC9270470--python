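"""Resampling null model for stage-wise directional clustering.

The question: is a focal subset of excavations (completed cavities, cavity
starts, or nests) more or less directionally clustered than a random subset
of a reference pool of the same size? The null distribution of the mean
resultant length ``r`` is built by repeatedly resampling, with replacement,
``n_subset`` orientations from the pool.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from cavorient.circstats import circ_mean
from cavorient.errors import EmptyInputError
from cavorient.records import CavityRecord

log = logging.getLogger(__name__)

#: Floating-point slack when counting null draws tied with the observed r.
_TIE_TOL = 1e-12


@dataclass(frozen=True)
class NullTestResult:
    """Outcome of one subset-vs-pool clustering test."""

    test_name: str
    observed_r: float
    null_r: np.ndarray = field(repr=False)
    n_subset: int
    n_pool: int
    n_iter: int
    tail: str  # "greater" | "less"
    p: float
    seed: int | None

    @property
    def null_mean_r(self) -> float:
        return float(self.null_r.mean())

    def to_row(self) -> dict:
        return {
            "test_name": self.test_name,
            "n_subset": self.n_subset,
            "n_pool": self.n_pool,
            "observed_r": self.observed_r,
            "null_mean_r": self.null_mean_r,
            "p": self.p,
            "tail": self.tail,
            "n_iter": self.n_iter,
            "seed": self.seed,
        }


def clustering_null_test(
    subset_deg: Sequence[float],
    pool_deg: Sequence[float],
    n_iter: int = 1000,
    tail: str = "greater",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    test_name: str = "subset_vs_pool",
) -> NullTestResult:
    """Test whether the subset is more ("greater") or less ("less") clustered than the pool.

    Each iteration draws ``len(subset)`` angles from the pool with
    replacement and records the resultant length. The one-tailed p-value is
    ``(1 + b) / (n_iter + 1)`` where ``b`` counts null values at least as
    extreme as the observed r (ties count as extreme).
    """
    subset = np.asarray(subset_deg, dtype=float)
    pool = np.asarray(pool_deg, dtype=float)
    if subset.size == 0 or pool.size == 0:
        raise EmptyInputError("clustering_null_test needs a nonempty subset and pool")
    if tail not in ("greater", "less"):
        raise ValueError(f"tail must be 'greater' or 'less', got {tail!r}")
    if n_iter < 100:
        warnings.warn(f"n_iter={n_iter} < 100 gives a coarse p-value", stacklevel=2)
    if subset.size > pool.size:
        log.info(
            "subset (n=%d) larger than pool (n=%d); resampling with replacement proceeds",
            subset.size, pool.size,
        )

    _, r_obs = circ_mean(subset)
    if rng is None:
        rng = np.random.default_rng(seed)

    theta = np.deg2rad(pool)
    cos_p, sin_p = np.cos(theta), np.sin(theta)
    idx = rng.integers(0, pool.size, size=(n_iter, subset.size))
    null_r = np.hypot(cos_p[idx].mean(axis=1), sin_p[idx].mean(axis=1))

    if tail == "greater":
        b = int(np.count_nonzero(null_r >= r_obs - _TIE_TOL))
    else:
        b = int(np.count_nonzero(null_r <= r_obs + _TIE_TOL))
    p = (1 + b) / (n_iter + 1)
    return NullTestResult(
        test_name=test_name,
        observed_r=r_obs,
        null_r=null_r,
        n_subset=int(subset.size),
        n_pool=int(pool.size),
        n_iter=n_iter,
        tail=tail,
        p=float(p),
        seed=seed,
    )


STAGEWISE_TESTS = (
    # (name, focal selector, pool selector, tail)
    ("complete_vs_all", "complete", "all", "greater"),
    ("start_vs_all", "start", "all", "less"),
    ("nest_vs_complete", "nest", "complete", "greater"),
)


def stage_angles(cavities: Iterable[CavityRecord], which: str, include_nests_in_pool: bool = True) -> np.ndarray:
    if which == "all":
        recs = [c for c in cavities if include_nests_in_pool or not c.is_nest]
    elif which == "complete":
        recs = [c for c in cavities if c.stage == "complete" and (include_nests_in_pool or not c.is_nest)]
    elif which == "start":
        recs = [c for c in cavities if c.stage == "start"]
    elif which == "nest":
        recs = [c for c in cavities if c.is_nest]
    else:
        raise ValueError(f"unknown selector {which!r}")
    return np.array([c.orientation_deg for c in recs], dtype=float)


def stagewise_tests(
    cavities: Sequence[CavityRecord],
    n_iter: int = 1000,
    seed: int | None = None,
    include_nests_in_pool: bool = True,
) -> list[NullTestResult]:
    """Run the three stage-wise clustering tests for one site's cavities.

    Tests: completed vs all (tail=greater), starts vs all (tail=less),
    nests vs completed (tail=greater). Tests whose focal subset or pool is
    empty are skipped with a logged notice. ``include_nests_in_pool=False``
    excludes nest cavities from the reference pool of the nest test.
    """
    rng = np.random.default_rng(seed)
    results: list[NullTestResult] = []
    for name, focal_sel, pool_sel, tail in STAGEWISE_TESTS:
        exclude_self = name == "nest_vs_complete" and not include_nests_in_pool
        focal = stage_angles(cavities, focal_sel)
        pool = stage_angles(cavities, pool_sel, include_nests_in_pool=not exclude_self)
        if focal.size == 0 or pool.size == 0:
            log.info("skipping %s: focal n=%d, pool n=%d", name, focal.size, pool.size)
            continue
        results.append(
            clustering_null_test(
                focal, pool, n_iter=n_iter, tail=tail, rng=rng, seed=seed, test_name=name
            )
        )
    return results
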