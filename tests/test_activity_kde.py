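import math

import numpy as np
import pytest
from scipy import optimize, special, stats

from dielact.activity_kde import (
    ActivityDensity,
    activity_level,
    bootstrap_level,
    circular_integral,
    fit_circular_kde,
    select_bandwidth,
)
from dielact.solar_time import TWO_PI


def closed_form_level(kappa):
    """For a von Mises(kappa) density, 1/(2*pi*f_max) = I0(k) exp(-k)."""
    return special.i0e(kappa)


def test_closed_form_level_formula():
    assert closed_form_level(2.0) == pytest.approx(0.3085, abs=5e-4)


class TestFitCircularKde:
    def test_uniform_limit(self, rng):
        x = rng.uniform(0, TWO_PI, 10_000)
        dens = fit_circular_kde(x)
        assert np.abs(dens.values - 1.0 / TWO_PI).max() < 0.02

    def test_von_mises_pointwise_oracle(self, rng):
        x = rng.vonmises(math.pi, 2.0, 5_000) % TWO_PI
        dens = fit_circular_kde(x)
        truth = stats.vonmises.pdf(dens.grid, kappa=2.0, loc=math.pi)
        assert np.abs(dens.values - truth).max() < 0.02

    def test_antipodal_points_symmetric_bimodal(self):
        dens = fit_circular_kde([0.5, 0.5 + math.pi], bandwidth=50.0)
        peaks = dens.values
        # Two equal peaks half a circle apart.
        i = int(np.argmax(peaks))
        j = (i + len(peaks) // 2) % len(peaks)
        assert peaks[i] == pytest.approx(peaks[j], rel=1e-6)

    def test_normalization_property(self, rng):
        for kappa in (0.5, 2.0, 8.0):
            x = rng.vonmises(1.0, kappa, 400) % TWO_PI
            dens = fit_circular_kde(x)
            assert abs(dens.integral - 1.0) < 1e-3

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_circular_kde([1.0])
        with pytest.raises(ValueError):
            fit_circular_kde([2.0, 2.0, 2.0])


class TestSelectBandwidth:
    def test_plugin_formula_oracle(self, rng):
        # Independent oracle: ML kappa by direct likelihood maximization,
        # then the plug-in expression evaluated verbatim. All trig-moment
        # orders estimate the same kappa for unimodal von Mises data, so
        # at this n the moment-maximizing selector agrees with the ML
        # plug-in.
        x = rng.vonmises(math.pi, 2.0, 2_000) % TWO_PI

        def negll(k):
            return -np.sum(stats.vonmises.logpdf(x, kappa=k, loc=math.pi))

        k_ml = optimize.minimize_scalar(negll, bounds=(0.01, 50), method="bounded").x
        n = len(x)
        expected = (3 * n * k_ml**2 * special.iv(2, 2 * k_ml)
                    / (4 * math.sqrt(math.pi) * special.iv(0, k_ml) ** 2)) ** 0.4
        assert select_bandwidth(x) == pytest.approx(expected, rel=0.2)

    def test_monotone_in_n(self, rng):
        x = rng.vonmises(0.0, 3.0, 400) % TWO_PI
        doubled = np.concatenate([x, x])  # identical moments, larger n
        assert select_bandwidth(doubled) > select_bandwidth(x)

    def test_deterministic(self, rng):
        x = rng.vonmises(0.0, 2.0, 300) % TWO_PI
        assert select_bandwidth(x) == select_bandwidth(x)

    def test_degenerate_sample_rejected(self):
        with pytest.raises(ValueError):
            select_bandwidth(np.full(50, 1.3))


class TestActivityLevel:
    def test_flat_density_level_one(self):
        grid = np.linspace(0, TWO_PI, 512, endpoint=False)
        dens = ActivityDensity(grid, np.full(512, 1 / TWO_PI), 1.0, 100)
        assert activity_level(dens).estimate == pytest.approx(1.0)

    def test_analytic_von_mises_density(self):
        grid = np.linspace(0, TWO_PI, 2048, endpoint=False)
        vals = stats.vonmises.pdf(grid, kappa=2.0, loc=math.pi)
        dens = ActivityDensity(grid, vals, 2.0, 1000)
        assert activity_level(dens).estimate == pytest.approx(
            closed_form_level(2.0), abs=1e-3)

    def test_kde_level_near_closed_form(self, rng):
        x = rng.vonmises(math.pi, 2.0, 5_000) % TWO_PI
        dens = fit_circular_kde(x)
        assert activity_level(dens).estimate == pytest.approx(
            closed_form_level(2.0), abs=0.03)

    def test_rotation_equivariance(self, rng):
        x = rng.vonmises(1.0, 2.0, 2_000) % TWO_PI
        l0 = activity_level(fit_circular_kde(x)).estimate
        l1 = activity_level(fit_circular_kde((x + 1.7) % TWO_PI)).estimate
        assert l1 == pytest.approx(l0, abs=1e-6)

    def test_unnormalized_density_rejected(self):
        grid = np.linspace(0, TWO_PI, 512, endpoint=False)
        dens = ActivityDensity(grid, np.full(512, 0.5), 1.0, 100)
        with pytest.raises(ValueError, match="integral"):
            activity_level(dens)


class TestBootstrapLevel:
    def test_seeded_reproducibility(self, rng):
        x = rng.vonmises(0.0, 2.0, 500) % TWO_PI
        a = bootstrap_level(x, n_boot=100, seed=7)
        b = bootstrap_level(x, n_boot=100, seed=7)
        assert a.se == b.se and a.ci_low == b.ci_low

    def test_uniform_se_small(self, rng):
        x = rng.uniform(0, TWO_PI, 2_000)
        res = bootstrap_level(x, n_boot=200, seed=1)
        assert res.se < 0.05

    def test_replicates_in_unit_interval(self, rng):
        x = rng.vonmises(2.0, 3.0, 400) % TWO_PI
        res = bootstrap_level(x, n_boot=150, seed=2)
        assert np.all((res.replicates > 0) & (res.replicates <= 1))
        assert res.ci_low <= res.estimate <= res.ci_high

    def test_se_decreases_with_n(self, rng):
        small = rng.vonmises(0.0, 2.0, 200) % TWO_PI
        large = rng.vonmises(0.0, 2.0, 2_000) % TWO_PI
        se_small = bootstrap_level(small, n_boot=500, seed=3).se
        se_large = bootstrap_level(large, n_boot=500, seed=3).se
        assert se_large < se_small

    def test_too_few_replicates_rejected(self, rng):
        with pytest.raises(ValueError):
            bootstrap_level(rng.uniform(0, TWO_PI, 100), n_boot=1)


def test_circular_integral_closes_the_circle():
    grid = np.linspace(0, TWO_PI, 256, endpoint=False)
    vals = (1 + np.cos(grid)) / TWO_PI
    assert circular_integral(grid, vals) == pytest.approx(1.0, abs=1e-6)
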