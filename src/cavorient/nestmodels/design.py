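"""Harmonic (sine/cosine) design matrices for periodic direction effects.

Direction enters the linear predictor as paired ``sin(k*theta)`` and
``cos(k*theta)`` terms so that the fitted effect respects the circular
topology of bearings. Column order is deterministic:

    intercept, adults, sin(1t), cos(1t), ..., adults:sin(1t), adults:cos(1t), ...

with cycles sorted ascending and interaction columns after all main effects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from cavorient.errors import ModelSpecError

VALID_CYCLES = frozenset({1, 2, 3, 4})


@dataclass(frozen=True)
class ModelSpec:
    """Specification of one harmonic success model."""

    family: str  # "poisson_count" | "binomial_rate"
    response: str  # "fledglings" | "hatch" | "fledge"
    cycles: frozenset[int] = frozenset({1, 2, 3, 4})
    include_adults: bool = True
    interactions: frozenset[int] = frozenset()
    random_intercept: bool = True

    def __post_init__(self) -> None:
        object.__setattr__(self, "cycles", frozenset(self.cycles))
        object.__setattr__(self, "interactions", frozenset(self.interactions))
        if self.family not in ("poisson_count", "binomial_rate"):
            raise ModelSpecError(f"unknown family {self.family!r}")
        if self.response not in ("fledglings", "hatch", "fledge"):
            raise ModelSpecError(f"unknown response {self.response!r}")
        if not self.cycles <= VALID_CYCLES:
            raise ModelSpecError(f"cycles must be a subset of {{1,2,3,4}}, got {set(self.cycles)}")
        if self.interactions and not self.cycles:
            raise ModelSpecError("interactions requested with no direction cycles in the model")
        if not self.interactions <= self.cycles:
            raise ModelSpecError(
                f"interaction cycles {set(self.interactions - self.cycles)} lack their main effects"
            )
        if self.interactions and not self.include_adults:
            raise ModelSpecError("adults-by-direction interactions require the adults main effect")


def design_column_names(spec: ModelSpec) -> list[str]:
    names = ["intercept"]
    if spec.include_adults:
        names.append("adults")
    for k in sorted(spec.cycles):
        names += [f"sin({k}t)", f"cos({k}t)"]
    for k in sorted(spec.interactions):
        names += [f"adults:sin({k}t)", f"adults:cos({k}t)"]
    return names


def build_harmonic_design(
    direction_deg: Sequence[float],
    cycles: Sequence[int] | frozenset[int],
    adults: Sequence[int] | None = None,
    interactions: Sequence[int] | frozenset[int] = (),
) -> np.ndarray:
    """Build the design matrix (including intercept) for given directions.

    ``adults=None`` omits the group-size main effect (and forbids
    interactions). Returns an ``(n, p)`` float array whose columns follow
    :func:`design_column_names`.
    """
    cycles = frozenset(int(k) for k in cycles)
    interactions = frozenset(int(k) for k in interactions)
    if not cycles <= VALID_CYCLES:
        raise ModelSpecError(f"cycles must be a subset of {{1,2,3,4}}, got {set(cycles)}")
    if interactions and not cycles:
        raise ModelSpecError("interactions requested with no direction cycles")
    if not interactions <= cycles:
        raise ModelSpecError("every interaction cycle needs its main-effect cycle present")
    if interactions and adults is None:
        raise ModelSpecError("interactions require the adults covariate")

    theta = np.deg2rad(np.asarray(direction_deg, dtype=float))
    cols: list[np.ndarray] = [np.ones_like(theta)]
    if adults is not None:
        a = np.asarray(adults, dtype=float)
        if a.shape != theta.shape:
            raise ModelSpecError("adults and direction lengths differ")
        cols.append(a)
    trig: dict[int, tuple[np.ndarray, np.ndarray]] = {
        k: (np.sin(k * theta), np.cos(k * theta)) for k in sorted(cycles)
    }
    for k in sorted(cycles):
        cols += list(trig[k])
    for k in sorted(interactions):
        cols += [a * trig[k][0], a * trig[k][1]]
    return np.column_stack(cols)


def spec_design(spec: ModelSpec, direction_deg: Sequence[float], adults: Sequence[int]) -> np.ndarray:
    """Design matrix for a full :class:`ModelSpec`."""
    return build_harmonic_design(
        direction_deg,
        spec.cycles,
        adults=np.asarray(adults) if spec.include_adults else None,
        interactions=spec.interactions,
    )
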