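"""Laplace evidence against closed-form and quadrature oracles; baselines."""

import math

import numpy as np
import pytest

from bcisa.delay import DELAYS_MS, Exp2ParticipantData
from bcisa.evidence import (
    LaplaceEvidence,
    PriorSpec,
    bernoulli_loglik,
    bias_model_loglik,
    compare_models,
    forced_fusion_loglik,
    forced_separation_loglik,
    kl_goodness_of_fit,
    laplace_evidence,
    uniform_model_loglik,
)
from bcisa.tactile import MOVEMENT_TRIAL_TYPES, Exp1ParticipantData


def gaussian_gaussian_log_evidence(y, sigma, prior_mean, prior_sd):
    """Closed-form log evidence of the conjugate normal-normal model."""
    y = np.asarray(y, dtype=float)
    n = y.size
    ybar = y.mean()
    s2 = sigma**2
    post_var = n * prior_sd**2 + s2
    return (
        -0.5 * n * math.log(2 * math.pi * s2)
        + 0.5 * math.log(s2 / post_var)
        - np.sum((y - ybar) ** 2) / (2 * s2)
        - n * (ybar - prior_mean) ** 2 / (2 * post_var)
    )


class TestLaplaceEvidence:
    def test_zero_dim_model_is_bare_loglik(self):
        ev = laplace_evidence(lambda x: -7.25, np.array([]))
        assert ev.lap == -7.25
        assert ev.dim == 0

    def test_component_identity(self):
        """lap is exactly the stated combination of its components."""
        ev = LaplaceEvidence(
            log_lik_at_opt=-3.0, log_prior_at_opt=-1.5, dim=2,
            log_det_hessian=0.7,
        )
        expected = -3.0 - 1.5 + math.log(2 * math.pi) - 0.35
        assert ev.lap == pytest.approx(expected, abs=1e-12)

    def test_matches_conjugate_gaussian_closed_form(self):
        """Gaussian likelihood + Gaussian prior: Laplace is exact."""
        rng = np.random.default_rng(42)
        sigma, prior = 2.0, PriorSpec(sd=1.5, mean=0.3)
        y = rng.normal(1.0, sigma, size=60)

        def log_lik(theta):
            t = float(np.atleast_1d(theta)[0])
            return float(
                -0.5 * np.sum(((y - t) / sigma) ** 2)
                - y.size * math.log(sigma * math.sqrt(2 * math.pi))
            )

        ev = laplace_evidence(log_lik, np.array([0.0]), prior)
        closed = gaussian_gaussian_log_evidence(y, sigma, prior.mean, prior.sd)
        assert ev.lap == pytest.approx(closed, abs=1e-6)

    def test_matches_quadrature_on_bernoulli_rate_model(self):
        """Logit-rate Bernoulli model, n=50, k=30: LAP within 0.05 nats of a
        1e5-point quadrature over the logit."""
        n, k = 50, 30
        prior = PriorSpec(sd=1.0)

        def log_lik(theta):
            t = float(np.atleast_1d(theta)[0])
            return k * t - n * math.log1p(math.exp(t))

        grid = np.linspace(-10, 10, 100_001)
        log_integrand = (
            k * grid - n * np.log1p(np.exp(grid))
            - 0.5 * grid**2 - 0.5 * math.log(2 * math.pi)
        )
        m = log_integrand.max()
        quadrature = m + math.log(
            np.trapezoid(np.exp(log_integrand - m), grid)
        )
        ev = laplace_evidence(log_lik, np.array([0.2]), prior)
        assert abs(ev.lap - quadrature) < 0.05

    @pytest.mark.parametrize("n,k,sd", [(50, 10, 1.0), (200, 120, 2.0)])
    def test_quadrature_agreement_across_models(self, n, k, sd):
        """The 0.1-nat quadrature bound holds across sample sizes and priors."""
        prior = PriorSpec(sd=sd)

        def log_lik(theta):
            t = float(np.atleast_1d(theta)[0])
            return k * t - n * math.log1p(math.exp(t))

        grid = np.linspace(-12, 12, 100_001)
        log_integrand = (
            k * grid - n * np.log1p(np.exp(grid))
            - 0.5 * (grid / sd) ** 2 - math.log(sd) - 0.5 * math.log(2 * math.pi)
        )
        m = log_integrand.max()
        quadrature = m + math.log(np.trapezoid(np.exp(log_integrand - m), grid))
        ev = laplace_evidence(log_lik, np.array([0.0]), prior)
        assert abs(ev.lap - quadrature) < 0.1

    def test_irreparable_curvature_raises_named_error(self):
        """Curvature too negative for the bounded jitter repair raises with
        the offending eigendirections named."""

        def log_lik(x):
            x = np.atleast_1d(x)
            return -0.5 * x[0] ** 2 + 5.0 * x[1] ** 2

        with pytest.raises(np.linalg.LinAlgError, match="flat"):
            laplace_evidence(
                log_lik, np.array([0.0, 0.0]), PriorSpec(sd=1e3), polish=False
            )

    def test_pd_repair_flagged_on_boundary_like_curvature(self):
        """A tiny negative eigenvalue is jitter-repaired, not rejected."""

        def log_lik(x):
            x = np.atleast_1d(x)
            return -0.5 * x[0] ** 2 + 5e-7 * x[1] ** 2

        ev = laplace_evidence(
            log_lik, np.array([0.0, 0.0]), PriorSpec(sd=1e3), polish=False
        )
        assert ev.pd_repair_applied


class TestCompareModels:
    def test_identical_laps_give_unit_ratio(self):
        laps = {"a": np.array([1.0, -2.0, 3.0]), "b": np.array([1.0, -2.0, 3.0])}
        res = compare_models(laps, "a", "b")
        assert np.all(res.delta_lap == 0.0)
        assert res.group_ratio == 1.0

    def test_direct_arithmetic(self):
        laps = {"a": np.array([2.0, -1.0, 3.0]), "b": np.zeros(3)}
        res = compare_models(laps, "a", "b")
        assert res.group_sum == 4.0
        assert res.group_ratio == pytest.approx(math.exp(4.0))

    def test_antisymmetry(self):
        rng = np.random.default_rng(1)
        laps = {"a": rng.normal(size=10), "b": rng.normal(size=10)}
        ab = compare_models(laps, "a", "b")
        ba = compare_models(laps, "b", "a")
        assert ab.group_sum == -ba.group_sum

    def test_group_ratio_reproduces_published_magnitude(self):
        """32 participants at mean ΔLAP 1.20 give a ~5e16 group ratio."""
        laps = {"causal": np.full(32, 1.20), "bias": np.zeros(32)}
        res = compare_models(laps, "causal", "bias")
        assert res.group_ratio == pytest.approx(math.exp(38.4))
        # the printed 4.9e16 lies within the rounding band of the mean
        lo = math.exp(32 * 1.195)
        hi = math.exp(32 * 1.205)
        assert lo < 4.9e16 < hi
        assert lo < res.group_ratio < hi

    def test_mismatched_participants_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            compare_models({"a": np.zeros(3), "b": np.zeros(4)}, "a", "b")


class TestKLGoodnessOfFit:
    def test_zero_at_equality(self):
        assert kl_goodness_of_fit([0.5], [0.5]) == 0.0

    def test_printed_example(self):
        assert kl_goodness_of_fit([0.9], [0.5]) == pytest.approx(0.3680642, abs=1e-7)

    def test_degenerate_cells_guarded(self):
        assert kl_goodness_of_fit([0.0], [0.0]) == pytest.approx(0.0, abs=1e-12)
        assert kl_goodness_of_fit([1.0], [1.0]) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative_on_grid(self):
        grid = np.linspace(0, 1, 21)
        for p in grid:
            for q in grid:
                assert kl_goodness_of_fit([p], [q]) >= -1e-12


def _exp1_data(rates, n=100):
    return Exp1ParticipantData(
        {tt: (n, int(round(r * n))) for tt, r in zip(MOVEMENT_TRIAL_TYPES, rates)}
    )


class TestBaselineModels:
    def test_bias_model_closed_form(self):
        data = _exp1_data([0.4, 0.4, 0.4, 0.4], n=25)  # 40/100 overall
        ll, dim = bias_model_loglik(data)
        assert dim == 1
        assert ll == pytest.approx(100 * (0.4 * math.log(0.4) + 0.6 * math.log(0.6)))

    def test_bias_model_boundary_rate_is_finite(self):
        data = _exp1_data([1.0, 1.0, 1.0, 1.0], n=10)
        ll, _ = bias_model_loglik(data)
        assert math.isfinite(ll)

    def test_bias_rate_depends_only_on_totals(self):
        a = _exp1_data([0.2, 0.4, 0.6, 0.8], n=50)
        b = _exp1_data([0.8, 0.6, 0.4, 0.2], n=50)
        assert bias_model_loglik(a)[0] == pytest.approx(bias_model_loglik(b)[0])

    def test_uniform_model_closed_form(self):
        ll, dim = uniform_model_loglik([(3, 1)])
        assert dim == 0
        assert ll == pytest.approx(math.log(1 / 3) + 2 * math.log(2 / 3))

    def test_uniform_model_empty_data(self):
        ll, _ = uniform_model_loglik([])
        assert ll == 0.0

    def test_uniform_loglik_linear_in_trial_count(self):
        ll1, _ = uniform_model_loglik([(10, 4)])
        ll2, _ = uniform_model_loglik([(20, 8)])
        assert ll2 == pytest.approx(2 * ll1)

    def test_forced_structures_are_delay_insensitive_and_opposed(self):
        counts = {("active", d): (30, 10 + i) for i, d in enumerate(DELAYS_MS)}
        data = Exp2ParticipantData(counts)
        fus_ll, fus_dim = forced_fusion_loglik(data, "active")
        sep_ll, sep_dim = forced_separation_loglik(data, "active")
        assert fus_dim == sep_dim == 0
        k_tot = sum(k for _, k in counts.values())
        n_tot = sum(n for n, _ in counts.values())
        # fusion never predicts a detection: every detection costs log(clip)
        assert fus_ll == pytest.approx(
            k_tot * math.log(1e-12) + (n_tot - k_tot) * math.log(1 - 1e-12)
        )
        assert sep_ll == pytest.approx(
            (n_tot - k_tot) * math.log(1e-12) + k_tot * math.log(1 - 1e-12)
        )


def test_bernoulli_loglik_matches_direct_sum():
    cells = [(10, 3), (20, 11)]
    rates = [0.3, 0.6]
    direct = (3 * math.log(0.3) + 7 * math.log(0.7)
              + 11 * math.log(0.6) + 9 * math.log(0.4))
    assert bernoulli_loglik(rates, cells) == pytest.approx(direct, abs=1e-12)
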