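import math
import warnings

import numpy as np
import pytest

from nwatch.designs import DesignSpec, make_target, site_at
from nwatch.inference import (
    ChainSet,
    InferenceConfig,
    ParamVector,
    PriorSpec,
    cell_likelihood,
    check_success,
    compile_designs,
    gelman_rubin,
    posterior_mode,
    run_mcmc,
    success_count,
    total_log_likelihood,
)
from nwatch.models import decide, ModelParams
from nwatch.ring import BaselineProfileParams, BeadSpec, apply_design, make_baseline


class TestCellLikelihood:
    def test_midpoint_is_half(self):
        assert cell_likelihood(0.0, 1, 0.05) == pytest.approx(0.5)
        assert cell_likelihood(0.0, -1, 0.05) == pytest.approx(0.5)

    def test_one_delta_above_threshold(self):
        assert cell_likelihood(0.05, 1, 0.05) == pytest.approx(1 / (1 + math.exp(-1)))

    def test_penalised_false_positive(self):
        assert cell_likelihood(10.0, -1, 0.05) < 1e-50

    def test_step_function_limit(self):
        """As delta shrinks the sigmoid approaches the exact sign step."""
        f, D = 0.02, 1
        values = [cell_likelihood(f, D, d) for d in (0.05, 0.005, 0.0005)]
        assert values == sorted(values)
        assert values[-1] > 1 - 1e-10
        assert cell_likelihood(-0.02, 1, 0.0005) < 1e-10


def toy_design(n_cells=20):
    baseline = BaselineProfileParams(inducer_sigma=3.0)
    beads = [BeadSpec("inducer_source", n_cells // 2, 3, 1.0, 2.0)]
    target = make_target(
        n_cells, [site_at(n_cells // 2, n_cells, 3)], np.arange(n_cells)
    )
    return DesignSpec(
        name="toy",
        beads=beads,
        target=target,
        expected_sites=[site_at(n_cells // 2, n_cells, 3)],
        n_cells=n_cells,
        baseline=baseline,
    )


class TestTotalLogLikelihood:
    def test_matches_per_cell_oracle_on_toy_ring(self):
        """Cell-by-cell product over the toy design equals the fast path."""
        design = toy_design()
        config = InferenceConfig(seed=0)
        prior = PriorSpec.for_model("B")
        theta = ParamVector(prior, np.array([1.3, 4, 0.7, 0.3, 1.5, 2.0]))
        # oracle: rebuild everything with the plain library calls
        field = apply_design(
            make_baseline(design.baseline, design.n_cells),
            design.scaled_beads(1.5, 2.0),
        )
        params = ModelParams(model_id="B", a_V=10**0.7, a_B=10**0.3, beta=1.3, n=4)
        prof = decide(field, params, form=config.form)
        expected = 0.0
        for i in design.target.evaluation_cells:
            expected += math.log(
                1 / (1 + math.exp(-design.target.D[i] * prof.f[i] / config.delta))
            )
        got = total_log_likelihood(theta, [design], "B", config)
        assert got == pytest.approx(expected, rel=1e-9)

    def test_outside_prior_is_minus_inf(self):
        prior = PriorSpec.for_model("B")
        theta = ParamVector(prior, prior.upper + 1.0)
        assert total_log_likelihood(theta, [toy_design()], "B", InferenceConfig()) == -np.inf

    def test_additive_over_designs(self):
        config = InferenceConfig(seed=0)
        prior = PriorSpec.for_model("B")
        theta = ParamVector(prior, np.array([1.2, 3, 0.5, 0.5, 1.0, 3.0]))
        one = total_log_likelihood(theta, [toy_design()], "B", config)
        two = total_log_likelihood(theta, [toy_design(), toy_design()], "B", config)
        assert two == pytest.approx(2 * one, rel=1e-12)


class TestCheckSuccess:
    def test_empty_expectation_empty_mask(self):
        design = toy_design()
        design = DesignSpec(
            name="null",
            beads=[],
            target=make_target(20, [], np.arange(20)),
            expected_sites=[],
            n_cells=20,
            baseline=BaselineProfileParams(inducer_sigma=3.0),
        )
        prior = PriorSpec.for_model("A", free_beads=False)
        # alpha close to 1: nothing fires
        theta = ParamVector(prior, np.array([0.99, 0.0, 0.0]))
        assert check_success(theta, design, "A", InferenceConfig())

    def test_single_site_hit(self):
        design = toy_design()
        prior = PriorSpec.for_model("B")
        theta = ParamVector(prior, np.array([1.2, 4, 0.7, 0.3, 1.5, 2.0]))
        cd = compile_designs([design])[0]
        f = cd.threshold_distance(theta, "B", "difference")
        expected = f.max() > 0  # fires at the bead if anywhere
        assert check_success(theta, design, "B", InferenceConfig()) == (
            expected and f[10] > 0
        )

    def test_merged_component_across_two_sites_fails(self, groups):
        """A plateau covering both expected sites is one component, not two."""
        aca = next(d for d in groups["microbead"] if d.name == "A-C-A")
        prior = PriorSpec.for_model("A")
        # low threshold, strong inducer: the whole bead row fires as one run
        theta = ParamVector(prior, np.array([0.01, 2.0, -2.0, 8.0, 30.0]))
        cd = compile_designs([aca])[0]
        f = cd.threshold_distance(theta, "A", "difference")
        assert (f[280:320] > 0).all()  # merged plateau
        assert not check_success(theta, aca, "A", InferenceConfig())


class TestSampler:
    def test_same_seed_identical_chains(self):
        design = toy_design()
        prior = PriorSpec.for_model("B")
        config = InferenceConfig(seed=11, min_iterations=200, n_chains=3)
        a = run_mcmc([design], "B", prior, config)
        b = run_mcmc([design], "B", prior, config)
        np.testing.assert_array_equal(a.draws, b.draws)
        np.testing.assert_array_equal(a.logls, b.logls)

    def test_draws_respect_prior_support(self):
        design = toy_design()
        prior = PriorSpec.for_model("B")
        config = InferenceConfig(seed=5, min_iterations=300, n_chains=3)
        chains = run_mcmc([design], "B", prior, config)
        pooled = chains.pooled(burn=False)
        assert np.all(pooled >= prior.lower) and np.all(pooled <= prior.upper)

    def test_one_parameter_posterior_matches_quadrature(self):
        """Smoothed-step posterior on one cell vs numeric normalisation."""
        prior = PriorSpec(names=("alpha",), lower=np.array([0.0]), upper=np.array([1.0]))
        delta = 0.05

        def log_prob(theta):
            a = theta.values[0]
            if not 0 <= a <= 1:
                return -np.inf
            return -np.logaddexp(0.0, -(0.5 - a) / delta)

        config = InferenceConfig(seed=3, min_iterations=4000, n_chains=4)
        chains = run_mcmc([], "A", prior, config, log_prob=log_prob)
        draws = chains.pooled()[:, 0]
        grid = np.linspace(0, 1, 2001)
        dens = np.exp(-np.logaddexp(0.0, -(0.5 - grid) / delta))
        cdf = np.cumsum(dens)
        cdf /= cdf[-1]
        for q in (0.1, 0.25, 0.5, 0.75, 0.9):
            expected = grid[np.searchsorted(cdf, q)]
            assert np.quantile(draws, q) == pytest.approx(expected, abs=0.03)


class TestGelmanRubin:
    def _chainset(self, x):
        prior = PriorSpec(names=("p",), lower=np.array([-1e6]), upper=np.array([1e6]))
        x = np.asarray(x, dtype=float)[:, :, None]
        return ChainSet(
            prior=prior,
            model_id="A",
            draws=x,
            logls=np.zeros(x.shape[:2]),
            config=InferenceConfig(seed=0, burn_frac=0.0),
            accept_rate=np.zeros(x.shape[0]),
        )

    def test_iid_chains_near_one(self):
        rng = np.random.default_rng(0)
        chains = self._chainset(rng.normal(size=(4, 2000)))
        assert gelman_rubin(chains, "p") == pytest.approx(1.0, abs=0.05)

    def test_disjoint_chains_detected(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(2, 500))
        x[1] += 50
        assert gelman_rubin(self._chainset(x), "p") > 5

    def test_degenerate_chains_warn_and_report_one(self):
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            r = gelman_rubin(self._chainset([[0, 0, 0], [1, 1, 1]]), "p")
        assert r == 1.0
        assert any("identical" in str(w.message) for w in caught)


class TestPosteriorMode:
    def _chainset_for(self, values, name="n", lo=1, hi=150):
        prior = PriorSpec(names=(name,), lower=np.array([lo], float), upper=np.array([hi], float))
        x = np.asarray(values, dtype=float)[None, :, None]
        x = np.repeat(x, 2, axis=0)
        return ChainSet(
            prior=prior,
            model_id="B",
            draws=x,
            logls=np.zeros(x.shape[:2]),
            config=InferenceConfig(seed=0, burn_frac=0.0),
            accept_rate=np.zeros(2),
        )

    def test_integer_mode_equals_counting_oracle(self):
        rng = np.random.default_rng(2)
        values = rng.choice([55, 56, 57, 58], p=[0.1, 0.2, 0.55, 0.15], size=3000)
        chains = self._chainset_for(values + rng.uniform(-0.4, 0.4, 3000))
        mode, info = posterior_mode(chains, "n")
        ints = np.round(chains.param_draws("n")).astype(int)
        counts = np.bincount(ints)
        assert mode == int(np.argmax(counts)) == 57

    def test_flat_draws_flagged(self):
        rng = np.random.default_rng(3)
        chains = self._chainset_for(rng.uniform(1, 150, 4000))
        _, info = posterior_mode(chains, "n")
        assert info["flat"]

    def test_continuous_mode_near_peak(self):
        rng = np.random.default_rng(4)
        values = np.clip(rng.normal(0.4, 0.05, 4000), 0, 1)
        chains = self._chainset_for(values, name="alpha", lo=0, hi=1)
        mode, _ = posterior_mode(chains, "alpha")
        assert mode == pytest.approx(0.4, abs=0.05)


def test_shared_bead_regime_smoke(groups):
    """Joint fitting with one bead-parameter set for both models yields
    per-model summaries whose draws respect each sub-prior."""
    from nwatch.inference import model_comparison

    designs = groups["inhibitor_mod"]
    config = InferenceConfig(seed=4, min_iterations=200, n_chains=3)
    sum_A, sum_B = model_comparison(
        designs, config, shared_beads=True, success_subsample=100, de_maxiter=0
    )
    assert sum_A.model_id == "A" and sum_B.model_id == "B"
    assert set(sum_A.prior.names) == {"alpha", "b_V", "b_B", "c", "s"}
    assert set(sum_B.prior.names) == {"beta", "n", "b_V", "b_B", "c", "s"}
    # the shared bead parameters coincide at the per-model best vectors
    assert 0.0 <= sum_A.success_rate <= 1.0
    assert 0.0 <= sum_B.success_rate <= 1.0


def test_prior_spec_validation_and_rounding():
    prior = PriorSpec.for_model("B")
    assert prior.names == ("beta", "n", "b_V", "b_B", "c", "s")
    theta = prior.round_integers(np.array([1.5, 56.7, 0, 0, 1, 1]))
    assert theta[prior.index("n")] == 57
    with pytest.raises(ValueError):
        PriorSpec(names=("a",), lower=np.array([1.0]), upper=np.array([0.0]))


def test_success_count_on_microbead(bead_designs):
    """A hand-picked neighbourhood-model vector solves all five designs."""
    prior = PriorSpec.for_model("B")
    theta = ParamVector(
        prior, np.array([1.1756, 33.0, 0.6385, 1.1286, 7.3326, 15.2097])
    )
    assert success_count(theta, bead_designs, "B", InferenceConfig()) == 5
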