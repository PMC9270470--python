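import math

import numpy as np
import pytest

from cavorient.errors import ModelSpecError, ValueRangeError
from cavorient.nestmodels import (
    ModelSpec,
    fit_fecundity,
    fit_null,
    fit_rate_glmm,
    predict_success,
    pseudo_r2,
)
from cavorient.nestmodels.fits import LOGIT_LATENT_VARIANCE, refit_without_random_intercept
from cavorient.records import NestRecord


def _poisson_records(rng, n_clusters=40, per_cluster=10, beta=None, tau=0.0):
    """Fledgling counts from a known 2-cycle log-linear model."""
    beta = beta or {"b0": 0.1, "ba": 0.15, "bs": -0.25, "bc": 0.2, "bsa": 0.1, "bca": -0.05}
    u = rng.normal(0, math.sqrt(tau), n_clusters)
    recs = []
    for c in range(n_clusters):
        for yidx in range(per_cluster):
            d = float(rng.uniform(0, 360))
            a = int(rng.integers(2, 7))
            t = math.radians(d)
            eta = (
                beta["b0"] + beta["ba"] * a
                + (beta["bs"] + beta["bsa"] * a) * math.sin(2 * t)
                + (beta["bc"] + beta["bca"] * a) * math.cos(2 * t)
                + u[c]
            )
            fl = int(rng.poisson(math.exp(min(eta, 4.0))))
            eggs = max(fl, int(rng.integers(2, 6)))
            recs.append(NestRecord(f"cl{c:03d}", 2000 + yidx, d, a, eggs, max(fl, 1), fl))
    return recs


SPEC_POIS = ModelSpec(family="poisson_count", response="fledglings", cycles={2}, interactions={2})
SPEC_HATCH = ModelSpec(family="binomial_rate", response="hatch", cycles={2}, interactions={2})


class TestFitFecundity:
    def test_constant_counts_intercept_log_c(self):
        recs = [
            NestRecord(f"cl{i % 4}", 2000 + i // 4, float(i * 7 % 360), 3, 4, 3, 3)
            for i in range(40)
        ]
        spec = ModelSpec(
            family="poisson_count", response="fledglings", cycles=frozenset(),
            include_adults=False, random_intercept=False,
        )
        fit = fit_fecundity(recs, spec)
        assert len(fit.coefficients) == 1
        assert fit.coefficients.loc["intercept", "estimate"] == pytest.approx(math.log(3.0), abs=1e-8)

    def test_family_checked(self, nest_records):
        with pytest.raises(ModelSpecError):
            fit_fecundity(nest_records, SPEC_HATCH)

    def test_singular_fallback_matches_glm(self, rng):
        # zero between-cluster variance: GLMM collapses to the GLM fit
        recs = _poisson_records(rng, tau=0.0)
        mixed = fit_fecundity(recs, SPEC_POIS)
        plain = refit_without_random_intercept(recs, mixed)
        assert mixed.singular is True
        assert mixed.tau00 == 0.0
        np.testing.assert_allclose(mixed.beta, plain.beta, atol=1e-6)
        assert mixed.loglik == pytest.approx(plain.loglik, abs=1e-6)

    def test_parameter_recovery_coverage(self):
        # each true coefficient inside its own 95% CI in >= 90% of replicates
        truth = {"b0": 0.1, "ba": 0.15, "bs": -0.25, "bc": 0.2, "bsa": 0.1, "bca": -0.05}
        order = ["b0", "ba", "bs", "bc", "bsa", "bca"]
        n_rep = 30
        covered = np.zeros(6)
        for rep in range(n_rep):
            rng = np.random.default_rng(5000 + rep)
            recs = _poisson_records(rng, n_clusters=78, per_cluster=9, beta=truth)
            fit = fit_fecundity(recs, SPEC_POIS)
            lo = fit.coefficients["ci_low"].to_numpy()
            hi = fit.coefficients["ci_high"].to_numpy()
            tv = np.array([truth[k] for k in order])
            covered += (lo <= tv) & (tv <= hi)
        assert (covered / n_rep >= 0.8).all()
        assert (covered / n_rep).mean() >= 0.9

    def test_negative_counts_rejected(self, nest_records):
        bad = nest_records[:60]
        object.__setattr__(bad[0], "fledglings", -1)  # bypass record validation on purpose
        with pytest.raises(ValueRangeError):
            fit_fecundity(bad, SPEC_POIS)


class TestFitRateGLMM:
    def test_icc_arithmetic_known_tau(self):
        assert LOGIT_LATENT_VARIANCE == pytest.approx(math.pi**2 / 3)
        assert 0.06 / (0.06 + LOGIT_LATENT_VARIANCE) == pytest.approx(0.018, abs=5e-4)
        assert round(0.06 / (0.06 + LOGIT_LATENT_VARIANCE), 2) == 0.02
        assert round(0.17 / (0.17 + LOGIT_LATENT_VARIANCE), 2) == 0.05

    def test_fit_reports_icc_consistent_with_tau(self, rng):
        from cavorient.synthgen import SimConfig, gen_nesting

        recs, _ = gen_nesting(SimConfig(seed=4, tau00_true=0.3))
        fit = fit_rate_glmm(recs, SPEC_HATCH)
        assert fit.sigma2_latent == pytest.approx(LOGIT_LATENT_VARIANCE)
        assert fit.icc == pytest.approx(fit.tau00 / (fit.tau00 + LOGIT_LATENT_VARIANCE))
        assert fit.tau00 >= 0.0

    def test_zero_denominator_rows_excluded(self, rng):
        recs = [
            NestRecord(f"cl{i % 5}", 2000 + i // 5, float(i * 11 % 360), 3, 3, 2, 1)
            for i in range(50)
        ] + [NestRecord("cl9", 2050, 10.0, 3, 0, 0, 0)]  # zero eggs
        spec = ModelSpec(
            family="binomial_rate", response="hatch", cycles=frozenset(),
            include_adults=False, random_intercept=False,
        )
        fit = fit_rate_glmm(recs, spec)
        assert fit.n_obs == 50

    def test_ratio_estimates_consistent_with_link(self, nest_records):
        fit = fit_rate_glmm(nest_records, SPEC_HATCH)
        np.testing.assert_allclose(
            np.log(fit.ratio_estimates["ratio"].to_numpy()), fit.beta, atol=1e-10
        )

    def test_rotation_by_360_identical(self, nest_records):
        rotated = [
            NestRecord(r.cluster_id, r.year, (r.direction_deg + 360.0) % 360.0,
                       r.adults, r.eggs, r.hatchlings, r.fledglings)
            for r in nest_records
        ]
        f0 = fit_rate_glmm(nest_records, SPEC_HATCH)
        f1 = fit_rate_glmm(rotated, SPEC_HATCH)
        np.testing.assert_allclose(f0.beta, f1.beta, atol=1e-12)
        assert f0.loglik == pytest.approx(f1.loglik, abs=1e-10)

    def test_glmm_recovery(self):
        # known beta and tau00 = 0.2 over 80 clusters x 9 years
        from dataclasses import replace

        from cavorient.synthgen import SimConfig, gen_nesting

        base = SimConfig(n_clusters=80, n_years=9, n_nest_records=702, tau00_true=0.2)
        hits_tau, hits_beta = 0, 0
        n_rep = 12
        for rep in range(n_rep):
            recs, truth = gen_nesting(replace(base, seed=900 + rep))
            fit = fit_rate_glmm(recs, SPEC_HATCH)
            hits_tau += 0.05 <= fit.tau00 <= 0.5
            b = truth["beta"]
            tv = np.array([b["intercept"], b["adults"], b["sin2"], b["cos2"],
                           b["adults_sin2"], b["adults_cos2"]])
            lo = fit.coefficients["ci_low"].to_numpy()
            hi = fit.coefficients["ci_high"].to_numpy()
            hits_beta += ((lo <= tv) & (tv <= hi)).all()
        assert hits_tau / n_rep >= 0.85
        assert hits_beta / n_rep >= 0.6  # joint coverage of all six coefficients


class TestPseudoR2:
    def test_equal_logliks_zero(self, nest_records):
        fit = fit_null(nest_records, "binomial_rate", "hatch", random_intercept=False)
        assert pseudo_r2(fit, fit) == (0.0, 0.0)

    def test_direct_formula_values(self, nest_records):
        # frozen hand evaluation: n=100, ll0=-150, ll1=-140
        class _F:
            loglik, n_obs = -140.0, 100

        class _N:
            loglik, n_obs = -150.0, 100

        cs, nk = pseudo_r2(_F, _N)
        assert cs == pytest.approx(1 - math.exp(-0.2), abs=1e-12)
        assert nk == pytest.approx((1 - math.exp(-0.2)) / (1 - math.exp(-3.0)), abs=1e-12)

    def test_nagelkerke_at_least_cox_snell(self, nest_records):
        full = fit_rate_glmm(nest_records, SPEC_HATCH)
        null = fit_null(nest_records, "binomial_rate", "hatch")
        cs, nk = pseudo_r2(full, null)
        assert nk >= cs >= 0.0

    def test_nesting_violation_raises(self):
        class _F:
            loglik, n_obs = -160.0, 100

        class _N:
            loglik, n_obs = -150.0, 100

        with pytest.raises(ValueRangeError):
            pseudo_r2(_F, _N)


class TestPredictSuccess:
    def test_two_cycle_period_180(self, nest_records):
        fit = fit_rate_glmm(nest_records, SPEC_HATCH)
        grid = np.arange(0.0, 180.0, 15.0)
        a = predict_success(fit, grid, [4])
        b = predict_success(fit, grid + 180.0, [4])
        np.testing.assert_allclose(a["predicted"], b["predicted"], atol=1e-12)

    def test_intercept_only_flat(self, nest_records):
        fit = fit_null(nest_records, "binomial_rate", "hatch", random_intercept=False)
        out = predict_success(fit, np.linspace(0, 350, 36), [2])
        assert out["predicted"].std() == pytest.approx(0.0, abs=1e-12)
        # flat at the aggregate success rate
        tot_y = sum(r.hatchlings for r in nest_records)
        tot_m = sum(r.eggs for r in nest_records)
        assert out["predicted"].iloc[0] == pytest.approx(tot_y / tot_m, abs=1e-6)

    def test_optima_recovered_within_15_degrees(self):
        from cavorient.synthgen import SimConfig, gen_nesting

        # strong pure-cos2 effect: optima exactly at 0 and 180 degrees
        cfg = SimConfig(
            seed=21,
            beta={"intercept": 0.2, "adults": 0.1, "sin2": 0.0, "cos2": 0.9,
                  "adults_sin2": 0.0, "adults_cos2": 0.0},
            tau00_true=0.05,
        )
        recs, _ = gen_nesting(cfg)
        fit = fit_rate_glmm(recs, SPEC_HATCH)
        grid = np.arange(0.0, 360.0, 1.0)
        pred = predict_success(fit, grid, [4])
        peak = grid[int(pred["predicted"].to_numpy().argmax())]
        dist = min(peak % 180.0, 180.0 - peak % 180.0)
        assert dist <= 15.0

    def test_empty_grid_rejected(self, nest_records):
        from cavorient.errors import EmptyInputError

        fit = fit_null(nest_records, "binomial_rate", "hatch", random_intercept=False)
        with pytest.raises(EmptyInputError):
            predict_success(fit, np.array([]), [3])
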