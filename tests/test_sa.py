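"""The SGD-enhanced annealing optimizer: gradient, proposals, MH rule and
full gene fits against brute-force oracles."""

import math

import numpy as np
import pytest

from tanhgrn.dataset import ExpressionDataset
from tanhgrn.sa import (
    SAConfig,
    SAState,
    ScheduleError,
    build_design,
    energy_of,
    fit_gene,
    gradient_of,
    gradient_probability,
    mh_accept,
    propose,
    restart_perturbation,
)


@pytest.fixture()
def toy_design(toy_data):
    ds, params = toy_data
    X, dg, var = build_design(ds, "g2", ["g1", "g3"])
    return X, dg, var


class TestGradient:
    def test_zero_at_perfect_fit(self, toy_data):
        ds, params = toy_data
        X, dg, var = build_design(ds, "g2", ["g1"])
        theta = np.array([params.alpha, params.beta, params.w["g1"]])
        np.testing.assert_allclose(gradient_of(theta, X, dg, var), 0.0, atol=1e-10)

    def test_matches_central_finite_differences(self, toy_design):
        X, dg, var = toy_design
        rng = np.random.default_rng(0)
        h = 1e-6
        for _ in range(10):
            theta = rng.uniform(-1.5, 1.5, 4)
            g = gradient_of(theta, X, dg, var)
            fd = np.array([
                (energy_of(theta + h * e, X, dg, var)
                 - energy_of(theta - h * e, X, dg, var)) / (2 * h)
                for e in np.eye(4)
            ])
            np.testing.assert_allclose(g, fd, rtol=1e-5, atol=1e-7)

    def test_alpha_zero_kills_weight_gradient(self, toy_design):
        X, dg, var = toy_design
        theta = np.array([0.0, 0.3, 0.5, -0.2])
        g = gradient_of(theta, X, dg, var)
        np.testing.assert_allclose(g[1:], 0.0, atol=1e-14)


class TestPropose:
    def test_gradient_probability_endpoints(self):
        assert gradient_probability(100, 100) == pytest.approx(0.5)
        assert gradient_probability(0, 100) == pytest.approx(0.2)

    def test_lambda_zero_gradient_branch_is_identity(self, toy_design):
        X, dg, var = toy_design
        cfg = SAConfig(lam=1e-300)  # lam must be > 0; effectively zero
        theta = np.array([0.5, 0.1, 0.3, -0.4])
        state = SAState(theta=theta, energy=energy_of(theta, X, dg, var), t=50, t_max=100)
        rng = np.random.default_rng(1)
        for _ in range(50):
            new, branch = propose(state, cfg, rng, X, dg, var)
            if branch == "gradient":
                np.testing.assert_allclose(new, theta, atol=1e-290)

    def test_branch_frequencies_match_p_gradient(self, toy_design):
        """At fixed t the random branch is taken with frequency
        P_gradient = 0.2 + 0.3 t/T_max (1e5 draws, within 1%)."""
        X, dg, var = toy_design
        cfg = SAConfig()
        theta = np.array([0.5, 0.1, 0.3, -0.4])
        state = SAState(theta=theta, energy=0.0, t=60, t_max=100)
        rng = np.random.default_rng(2)
        n = 100_000
        n_random = sum(
            propose(state, cfg, rng, X, dg, var)[1] == "random" for _ in range(n)
        )
        assert n_random / n == pytest.approx(0.2 + 0.3 * 0.6, abs=0.01)


class TestMHAccept:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(mh_accept(1.0, 0.5, t, 1.0, rng) for t in (1, 10, 100))

    def test_equal_energies_always_accepted(self):
        rng = np.random.default_rng(0)
        assert all(mh_accept(2.0, 2.0, 5, 0.5, rng) for _ in range(100))

    def test_uphill_frequency_is_boltzmann(self):
        """E gap 1 at kappa*t = 1: acceptance frequency e^-1 over 1e5 trials."""
        rng = np.random.default_rng(3)
        n = 100_000
        acc = sum(mh_accept(1.0, 2.0, 1.0, 1.0, rng) for _ in range(n))
        assert acc / n == pytest.approx(math.exp(-1), abs=0.01)

    def test_zero_temperature_rejected(self):
        with pytest.raises(ScheduleError):
            mh_accept(1.0, 2.0, 0.0, 1.0, np.random.default_rng(0))

    def test_cold_limit_is_strict_descent(self):
        rng = np.random.default_rng(4)
        assert not any(
            mh_accept(1.0, 1.0 + 1e-6, 1e-9, 1.0, rng) for _ in range(10_000)
        )


class TestRestart:
    def test_multipliers_within_bounds(self):
        rng = np.random.default_rng(5)
        theta = np.ones(2000)
        pert = restart_perturbation(theta, rng)
        assert (pert >= 0.75).all() and (pert <= 1.25).all()


class TestFitGene:
    def test_recovers_generating_parameters(self, toy_data):
        """Noise-free single-regulator data from (alpha, beta, w) =
        (1.5, 0.2, 0.8): parameters recovered within 1e-2, E < 1e-6."""
        ds, params = toy_data
        fit = fit_gene(["g1"], ds, "g2", SAConfig(), seed=0)
        assert fit.energy < 1e-6
        th = np.array([fit.params.alpha, fit.params.beta, fit.params.w["g1"]])
        truth = np.array([1.5, 0.2, 0.8])
        # tanh sign symmetry: (a, b, w) and (-a, -b, -w) are the same model
        err = min(np.abs(th - truth).max(), np.abs(-th - truth).max())
        assert err < 1e-2

    def test_matches_grid_search_on_two_parameter_problem(self, toy_data):
        """Fit only (alpha, beta) with w frozen structurally: the annealed
        minimum is within one grid cell of a 401x401 brute-force scan."""
        ds, params = toy_data
        # target: g2, no regulators -> theta = (alpha, beta) only
        X, dg, var = build_design(ds, "g2", [])
        alphas = np.linspace(-2, 2, 401)
        betas = np.linspace(-2, 2, 401)
        A, B = np.meshgrid(alphas, betas, indexing="ij")
        # E = sum (dg - a*tanh(-b))^2 / var, vectorised over the grid
        pred = A * np.tanh(-B)
        E = ((dg[None, None, :] - pred[..., None]) ** 2).sum(axis=2) / var
        i, j = np.unravel_index(E.argmin(), E.shape)
        fit = fit_gene([], ds, "g2", SAConfig(), seed=2)
        cell = alphas[1] - alphas[0]
        assert fit.energy <= E[i, j] + 1e-9 or (
            abs(fit.params.alpha - alphas[i]) <= cell
            and abs(fit.params.beta - betas[j]) <= cell
        )

    def test_trace_is_monotone_nonincreasing(self, toy_data):
        ds, _ = toy_data
        fit = fit_gene(["g1", "g3"], ds, "g2", SAConfig(), seed=7)
        assert (np.diff(fit.trace) <= 1e-15).all()

    def test_same_seed_reproduces_bit_identical(self, toy_data):
        ds, _ = toy_data
        f1 = fit_gene(["g1"], ds, "g2", SAConfig(), seed=11)
        f2 = fit_gene(["g1"], ds, "g2", SAConfig(), seed=11)
        assert f1.energy == f2.energy
        assert f1.params == f2.params

    def test_inactive_weights_stay_structurally_zero(self, toy_data):
        ds, _ = toy_data
        fit = fit_gene(["g1"], ds, "g2", SAConfig(), seed=1)
        assert set(fit.params.w) == {"g1"}
        assert fit.params.w_factor == {}

    def test_gene_fits_are_independent(self, bench_data):
        """Fitting one gene is unaffected by which other genes exist: the
        same design rows give the same fit on a row-subset dataset."""
        sub = ExpressionDataset(
            bench_data.frame.loc[["g1", "g4", "F1"]].copy(), ["F1"]
        )
        f_full = fit_gene(["g1", "F1"], bench_data, "g4", SAConfig(), seed=5)
        f_sub = fit_gene(["g1", "F1"], sub, "g4", SAConfig(), seed=5)
        assert f_full.energy == pytest.approx(f_sub.energy, rel=1e-12)
        assert f_full.params.alpha == pytest.approx(f_sub.params.alpha, rel=1e-12)

    def test_zero_variance_gene_rejected(self):
        ds = ExpressionDataset.from_arrays(
            np.array([[1.0, 1.0, 1.0], [0.1, 0.5, 0.9]]), ["flat", "g2"]
        )
        with pytest.raises(Exception, match="variance"):
            fit_gene(["g2"], ds, "flat", SAConfig(), seed=0)
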