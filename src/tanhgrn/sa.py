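"""SGD-enhanced simulated annealing parameter estimator.

Given a fixed incoming-link set pi_i for one gene, estimate Theta(pi_i) =
(alpha_i, beta_i, active weights) by minimising E = SSE/Var. Proposals mix a
damped steepest-descent step with an annealed random perturbation; moves are
accepted by the Metropolis-Hastings rule; after convergence over several
consecutive temperatures the best state is perturbed multiplicatively
(U(0.75, 1.25) per coordinate) and annealing restarts, until no restart
improves the best energy. A deterministic adaptive-step gradient descent
then polishes the returned optimum.

Structurally absent weights are never part of the parameter vector, so they
stay exactly zero. Gene fits are independent of each other by construction
(the model for gene i reads only observed series), so fitting order never
matters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import _kernels
from .dataset import ExpressionDataset
from .dynamics import GeneParameters, ModelInputError


class ScheduleError(ValueError):
    """Raised for invalid annealing-schedule state (e.g. t <= 0)."""


@dataclass(frozen=True)
class SAConfig:
    """Annealing controls.

    t_max : initial temperature (integer countdown t <- t - 1).
    lam : damping constant of the gradient step.
    kappa : Metropolis-Hastings scale constant (the energy-gap divisor is
        kappa * t). Must be small relative to the SSE/Var energy scale and
        the temperature range, or the hot phase accepts every uphill move
        and the walk escapes to saturated-tanh plateaus it cannot leave.
    sigma0 : base scale of the random proposal; the effective scale is
        sigma0 * t / t_max, shrinking as the system cools.
    eps : convergence tolerance on energy differences.
    n_c : number of consecutive temperature pairs whose energies must agree
        within eps to declare convergence at the current restart.
    n_f : number of consecutive restarts without improvement of the best
        energy before the fit terminates.
    inner_iters : proposals evaluated at each temperature.
    """

    t_max: int = 100
    lam: float = 0.01
    kappa: float = 0.001
    sigma0: float = 0.5
    eps: float = 1e-6
    n_c: int = 5
    n_f: int = 3
    inner_iters: int = 50
    max_cycles: int = 64
    polish_iters: int = 1000

    def __post_init__(self) -> None:
        if self.t_max < self.n_c + 1:
            raise ScheduleError("t_max must be at least n_c + 1")
        if min(self.lam, self.kappa, self.eps) <= 0:
            raise ScheduleError("lam, kappa and eps must be positive")

    def scaled(self, **kw) -> "SAConfig":
        return replace(self, **kw)


#: reduced budget used inside the structure search, where each candidate
#: link set only needs a competitive fit, not final polish
SEARCH_BUDGET = SAConfig(t_max=50, inner_iters=25, n_c=3, n_f=2, max_cycles=6, polish_iters=200)

#: minimal budget for the factor-finding scan, which needs a cost ranking
RANKING_BUDGET = SAConfig(t_max=15, inner_iters=15, n_c=3, n_f=1, max_cycles=3, polish_iters=100)


@dataclass
class SAState:
    """Current annealing state for one gene."""

    theta: np.ndarray
    energy: float
    t: int
    t_max: int
    p: int = 1
    best_theta: np.ndarray | None = None
    best_energy: float = math.inf


@dataclass
class GeneFit:
    """Result of fitting one gene for one structure."""

    gene: str
    regulators: tuple[str, ...]
    params: GeneParameters
    energy: float
    sse: float
    trace: np.ndarray = field(default_factory=lambda: np.empty(0))
    n_restarts: int = 0


# ----------------------------------------------------------------------
# elementary operations (pure Python; the compiled kernel inlines the same
# rules and is validated against these in the tests)
# ----------------------------------------------------------------------

def gradient_probability(t: int, t_max: int) -> float:
    """P_gradient = 0.2 + 0.3 * t / t_max: chance of the *random* branch is
    1 - P_gradient (the uniform draw r must exceed P_gradient to take the
    gradient step)."""
    return 0.2 + 0.3 * t / t_max


def build_design(
    data: ExpressionDataset, gene: str, regulators: Sequence[str]
) -> tuple[np.ndarray, np.ndarray, float]:
    """Design matrix X (T-1 x p), one-step changes dg, and Var(g_i)."""
    if gene not in set(data.ids):
        raise ModelInputError(f"unknown gene {gene!r}")
    known = set(data.ids)
    for rid in regulators:
        if rid not in known:
            raise ModelInputError(f"regulator {rid!r} not in dataset")
    g = data.row(gene)
    dg = g[1:] - g[:-1]
    if regulators:
        X = np.column_stack([data.row(r)[:-1] for r in regulators])
    else:
        X = np.zeros((data.n_times - 1, 0))
    var = float(data.var[gene])
    if var <= 0:
        raise ModelInputError(f"gene {gene!r} has zero variance")
    return X, dg, var


def energy_of(theta: np.ndarray, X: np.ndarray, dg: np.ndarray, var: float) -> float:
    return float(_kernels.energy(X, dg, 1.0 / var, np.asarray(theta, dtype=float)))


def gradient_of(theta: np.ndarray, X: np.ndarray, dg: np.ndarray, var: float) -> np.ndarray:
    """Analytic gradient of E = SSE/Var at theta = [alpha, beta, w...]."""
    g = _kernels.gradient(X, dg, 1.0 / var, np.asarray(theta, dtype=float))
    if not np.isfinite(g).all():
        raise FloatingPointError(f"non-finite gradient at theta={theta!r}")
    return np.asarray(g)


def propose(
    state: SAState,
    cfg: SAConfig,
    rng: np.random.Generator,
    X: np.ndarray,
    dg: np.ndarray,
    var: float,
) -> tuple[np.ndarray, str]:
    """One proposal: damped gradient step or annealed Gaussian perturbation.

    Returns the proposed theta and which branch was taken ("gradient" or
    "random").
    """
    r = rng.random()
    p_gradient = gradient_probability(state.t, state.t_max)
    if r > p_gradient:
        return state.theta - cfg.lam * gradient_of(state.theta, X, dg, var), "gradient"
    sigma = cfg.sigma0 * state.t / state.t_max
    return state.theta + sigma * rng.standard_normal(state.theta.shape[0]), "random"


def mh_accept(
    e_old: float, e_new: float, t: float, kappa: float, rng: np.random.Generator
) -> bool:
    """Metropolis-Hastings acceptance: downhill always, uphill with
    probability exp((E_old - E_new) / (kappa * t))."""
    if t <= 0:
        raise ScheduleError(f"temperature must be positive, got {t}")
    if e_new < e_old:
        return True
    return rng.random() < math.exp((e_old - e_new) / (kappa * t))


def restart_perturbation(
    theta_best: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Multiplicative restart: each coordinate scaled by r_k ~ U(0.75, 1.25)."""
    return theta_best * rng.uniform(0.75, 1.25, theta_best.shape[0])


# ----------------------------------------------------------------------
# full fit
# ----------------------------------------------------------------------

def _theta_to_params(
    theta: np.ndarray, regulators: Sequence[str], factor_ids: set[str]
) -> GeneParameters:
    w, w_factor = {}, {}
    for rid, weight in zip(regulators, theta[2:]):
        (w_factor if rid in factor_ids else w)[rid] = float(weight)
    return GeneParameters(alpha=float(theta[0]), beta=float(theta[1]), w=w, w_factor=w_factor)


def fit_gene(
    regulators: Sequence[str],
    data: ExpressionDataset,
    gene: str,
    cfg: SAConfig | None = None,
    seed: int = 0,
) -> GeneFit:
    """Estimate Theta(pi_i) for one gene given its incoming-link set.

    ``regulators`` may include the gene itself (a self-link) and any factor
    ids. Initialisation draws theta ~ U(-1, 1) per coordinate from ``seed``;
    the same seed reproduces the fit bit for bit.
    """
    cfg = cfg or SAConfig()
    X, dg, var = build_design(data, gene, regulators)
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(-1.0, 1.0, 2 + len(regulators))
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    theta_best, e_best, trace, n_cycles = _kernels.anneal(
        X,
        dg,
        1.0 / var,
        theta0,
        cfg.t_max,
        cfg.inner_iters,
        cfg.lam,
        cfg.kappa,
        cfg.sigma0,
        cfg.eps,
        cfg.n_c,
        cfg.n_f,
        cfg.max_cycles,
        kernel_seed,
    )
    if not np.isfinite(e_best):
        raise FloatingPointError(f"annealing diverged for gene {gene!r}")
    if cfg.polish_iters > 0:
        theta_pol, e_pol = _kernels.polish(
            X, dg, 1.0 / var, theta_best, cfg.lam, cfg.polish_iters
        )
        if e_pol < e_best:
            theta_best, e_best = theta_pol, e_pol
    params = _theta_to_params(theta_best, regulators, set(data.factor_ids))
    return GeneFit(
        gene=gene,
        regulators=tuple(regulators),
        params=params,
        energy=float(e_best),
        sse=float(e_best * var),
        trace=np.asarray(trace),
        n_restarts=int(n_cycles),
    )
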