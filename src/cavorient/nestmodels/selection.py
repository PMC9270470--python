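"""Top-down model selection for the harmonic success models.

Selection starts from the full model — sine/cosine pairs for cycles 1-4,
the adults main effect, all adults-by-cycle interactions, and a cluster
random intercept — and repeatedly drops the least-supported term block.
Blocks are sin/cos pairs (jointly, 2 df); an interaction block must leave
before its main-effect block; the adults main effect can only leave once no
interactions remain. The default criterion is a likelihood-ratio test at
alpha = 0.05 on ML fits; ``criterion="aic"`` drops the block whose removal
most improves AIC instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

from scipy import stats

from cavorient.errors import ConvergenceError, InsufficientDataError
from cavorient.nestmodels.design import ModelSpec
from cavorient.nestmodels.fits import HarmonicFit, fit_fecundity, fit_rate_glmm
from cavorient.records import NestRecord

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class SelectionStep:
    model: str
    candidate: str
    loglik: float
    criterion_value: float  # LRT p-value, or AIC delta
    decision: str  # "drop" | "keep" | "start"


@dataclass(frozen=True)
class SelectionTrace:
    steps: list[SelectionStep]

    def to_rows(self) -> list[dict]:
        return [vars(s) for s in self.steps]


def _describe(spec: ModelSpec) -> str:
    parts = []
    if spec.include_adults:
        parts.append("adults")
    parts += [f"cyc{k}" for k in sorted(spec.cycles)]
    parts += [f"adults:cyc{k}" for k in sorted(spec.interactions)]
    return "+".join(parts) if parts else "intercept-only"


def _fit(records: list[NestRecord], spec: ModelSpec) -> HarmonicFit:
    if spec.family == "poisson_count":
        return fit_fecundity(records, spec)
    return fit_rate_glmm(records, spec)


def _candidates(spec: ModelSpec) -> list[tuple[str, ModelSpec, int]]:
    """Droppable blocks: (label, reduced spec, df)."""
    out: list[tuple[str, ModelSpec, int]] = []
    for k in sorted(spec.interactions):
        out.append(
            (f"adults:cyc{k}", replace(spec, interactions=spec.interactions - {k}), 2)
        )
    for k in sorted(spec.cycles - spec.interactions):
        out.append((f"cyc{k}", replace(spec, cycles=spec.cycles - {k}), 2))
    if spec.include_adults and not spec.interactions:
        out.append(("adults", replace(spec, include_adults=False), 1))
    return out


def select_model(
    records: list[NestRecord],
    family: str,
    response: str,
    seed: int | None = None,
    alpha: float = 0.05,
    criterion: str = "lrt",
    random_intercept: bool = True,
) -> tuple[HarmonicFit, SelectionTrace]:
    """Top-down term selection; returns the final fit and the full trace.

    ``seed`` is accepted for interface uniformity with the stochastic
    subcommands; the fits themselves are deterministic.
    """
    if criterion not in ("lrt", "aic"):
        raise ValueError(f"criterion must be 'lrt' or 'aic', got {criterion!r}")
    clusters = {r.cluster_id for r in records}
    if len(records) < 50 or len(clusters) < 2:
        raise InsufficientDataError(
            f"model selection needs >= 50 records over >= 2 clusters, got "
            f"{len(records)} records / {len(clusters)} clusters"
        )

    full = ModelSpec(
        family=family,
        response=response,
        cycles=frozenset({1, 2, 3, 4}),
        include_adults=True,
        interactions=frozenset({1, 2, 3, 4}),
        random_intercept=random_intercept,
    )
    try:
        current_fit = _fit(records, full)
        current = full
    except ConvergenceError:
        log.warning("full model failed to converge; restarting from cycles {1, 2}")
        current = replace(full, cycles=frozenset({1, 2}), interactions=frozenset({1, 2}))
        current_fit = _fit(records, current)

    steps = [SelectionStep(_describe(current), "", current_fit.loglik, float("nan"), "start")]

    while True:
        cands = _candidates(current)
        if not cands:
            break
        best: tuple[float, str, ModelSpec, HarmonicFit] | None = None
        for label, reduced_spec, df in cands:
            try:
                reduced_fit = _fit(records, reduced_spec)
            except ConvergenceError:
                log.info("candidate drop %s failed to converge; kept", label)
                continue
            if criterion == "lrt":
                lr = max(2.0 * (current_fit.loglik - reduced_fit.loglik), 0.0)
                score = float(stats.chi2.sf(lr, df))
                better = score > alpha  # non-significant block: droppable
            else:
                aic_cur = 2 * current_fit.n_params - 2 * current_fit.loglik
                aic_red = 2 * reduced_fit.n_params - 2 * reduced_fit.loglik
                score = aic_red - aic_cur
                better = score < 0.0
            if better and (best is None or _prefer(criterion, score, best[0])):
                best = (score, label, reduced_spec, reduced_fit)
        if best is None:
            for label, _, df in cands:
                steps.append(SelectionStep(_describe(current), label, current_fit.loglik, float("nan"), "keep"))
            break
        score, label, current, current_fit = best
        steps.append(SelectionStep(_describe(current), label, current_fit.loglik, score, "drop"))

    return current_fit, SelectionTrace(steps=steps)


def _prefer(criterion: str, new: float, old: float) -> bool:
    return new > old if criterion == "lrt" else new < old
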