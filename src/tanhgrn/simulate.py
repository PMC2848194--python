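"""Synthetic benchmark generator.

Datasets are produced by running the tanh rate model forward from fixed
initial values, driven by external factors with sinusoidal profiles, with
optional Gaussian noise whose per-gene variance is Var(g_i)/c for a chosen
signal-to-noise divisor c (c = 10: medium noise, c = 4: high noise). The
packaged reference network has 11 genes, 2 factors, 26 directed links and
59 time points, mimicking the scale and behaviour of sparse cis-regulatory
circuits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset
from .dynamics import GeneParameters


class SimulationError(RuntimeError):
    """Raised when a forward run produces non-finite values."""


@dataclass(frozen=True)
class NoiseSpec:
    """Noise level as a signal-to-noise divisor: sigma_i^2 = Var(g_i)/c."""

    snr_divisor: float

    def __post_init__(self) -> None:
        if self.snr_divisor <= 0:
            raise ValueError("snr divisor c must be positive")

    def sigma(self, var: np.ndarray) -> np.ndarray:
        return np.sqrt(np.asarray(var, dtype=float) / self.snr_divisor)


@dataclass(frozen=True)
class SimulationConfig:
    """Run controls: (network, seed) fully determine the dataset."""

    noise: NoiseSpec | None = None
    replicates: int = 1
    seed: int = 0
    T: int | None = None  # defaults to the network's native length


@dataclass
class GroundTruthNetwork:
    """A fully specified generating network.

    ``params`` holds one :class:`GeneParameters` per gene; regulator weight
    maps define the signed, weighted edge structure. Factors have no
    incoming links by definition. ``factor_series`` holds each factor's
    driving trajectory F_k(1..T).
    """

    gene_ids: list[str]
    factor_ids: list[str]
    params: dict[str, GeneParameters]
    initial_values: dict[str, float]
    factor_series: dict[str, np.ndarray]
    name: str = "network"

    def __post_init__(self) -> None:
        for fid in self.factor_ids:
            for gp in self.params.values():
                if fid in gp.w:
                    raise ValueError(f"factor {fid} used as gene regulator")
        if set(self.params) != set(self.gene_ids):
            raise ValueError("params must cover exactly the gene ids")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_factors(self) -> int:
        return len(self.factor_ids)

    @property
    def T(self) -> int:
        return len(next(iter(self.factor_series.values()))) if self.factor_series else 0

    def edges(self) -> list[tuple[str, str, float, int]]:
        """Signed edge list (regulator, target, weight, sign).

        The sign of the influence of regulator j on target i is
        sign(alpha_i * w_ji) (the weight acts through alpha*tanh).
        """
        out = []
        for gid in self.gene_ids:
            gp = self.params[gid]
            for rid, w in {**gp.w, **gp.w_factor}.items():
                out.append((rid, gid, float(w), int(np.sign(gp.alpha * w)) or 1))
        return sorted(out, key=lambda e: (e[0], e[1]))

    def n_links(self) -> int:
        return len(self.edges())

    def n_candidates(self) -> int:
        """All possible regulator -> gene pairs (self pairs included;
        factors are never targets)."""
        return (self.n_genes + self.n_factors) * self.n_genes


# ----------------------------------------------------------------------

def generate_factor_series(
    T: int, amplitude: float, period: float, phase: float = 0.0
) -> np.ndarray:
    """Sinusoidal factor profile a*sin(2*pi*t/period + phase), t = 0..T-1."""
    if T < 3:
        raise ValueError("need T >= 3")
    if period <= 0:
        raise ValueError("period must be positive")
    t = np.arange(T, dtype=float)
    return amplitude * np.sin(2.0 * math.pi * t / period + phase)


def _forward(
    net: GroundTruthNetwork,
    T: int,
    noise_sigma: np.ndarray | None,
    rng: np.random.Generator | None,
) -> np.ndarray:
    """Recursive forward generation of the n_genes x T matrix."""
    n = net.n_genes
    g = np.empty((n, T))
    g[:, 0] = [net.initial_values[gid] for gid in net.gene_ids]
    gene_index = {gid: i for i, gid in enumerate(net.gene_ids)}
    # precompute per-gene regulator index lists and weights
    plans = []
    for gid in net.gene_ids:
        gp = net.params[gid]
        gidx = [gene_index[r] for r in gp.w]
        gw = np.array([gp.w[r] for r in gp.w], dtype=float)
        fser = (
            np.column_stack([net.factor_series[f] for f in gp.w_factor])
            if gp.w_factor
            else np.zeros((T, 0))
        )
        fw = np.array(list(gp.w_factor.values()), dtype=float)
        plans.append((gp.alpha, gp.beta, np.array(gidx, dtype=int), gw, fser, fw))
    for t in range(T - 1):
        if noise_sigma is not None:
            eps = rng.normal(0.0, 1.0, n) * noise_sigma
        for i, (alpha, beta, gidx, gw, fser, fw) in enumerate(plans):
            u = -beta
            if gidx.size:
                u += g[gidx, t] @ gw
            if fw.size:
                u += fser[t] @ fw
            val = g[i, t] + alpha * math.tanh(u)
            if noise_sigma is not None:
                val += eps[i]
            if not math.isfinite(val):
                raise SimulationError(
                    f"non-finite value for gene {net.gene_ids[i]} at t={t + 2}"
                )
            g[i, t + 1] = val
    return g


def noise_free_trajectories(net: GroundTruthNetwork, T: int | None = None) -> np.ndarray:
    T = T or net.T
    return _forward(net, T, None, None)


def simulate_dataset(
    net: GroundTruthNetwork, cfg: SimulationConfig | None = None
) -> ExpressionDataset:
    """Simulate one expression dataset (genes + factor rows).

    Noise variances are scaled from the *noise-free* trajectory of the same
    network (sigma_i^2 = Var(g_i)/c with Var from a clean pre-pass), so the
    noise level is a property of the network, not of one noisy realisation.
    Noise is added after the tanh increment at each recursion step.
    """
    cfg = cfg or SimulationConfig()
    T = cfg.T or net.T
    if cfg.noise is None:
        g = _forward(net, T, None, None)
    else:
        clean = _forward(net, T, None, None)
        var = clean.var(axis=1, ddof=1)
        rng = np.random.default_rng(cfg.seed)
        g = _forward(net, T, cfg.noise.sigma(var), rng)
    factors = np.vstack([net.factor_series[f][:T] for f in net.factor_ids])
    return ExpressionDataset.from_arrays(
        g, net.gene_ids, net.factor_ids, factors
    )


def simulate_replicates(
    net: GroundTruthNetwork, cfg: SimulationConfig
) -> list[ExpressionDataset]:
    """Independent noisy replicates; replicate r uses child seed r of cfg.seed."""
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.replicates)
    out = []
    for ss in seeds:
        sub = SimulationConfig(
            noise=cfg.noise, replicates=1, seed=int(ss.generate_state(1)[0] % 2**31), T=cfg.T
        )
        out.append(simulate_dataset(net, sub))
    return out


# ----------------------------------------------------------------------

def sample_power_law_indegrees(
    n: int, l_max: int, gamma: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw per-gene in-degrees from P(k) proportional to k^-gamma over 1..l_max."""
    if not 2.0 < gamma < 3.0:
        raise ValueError("gamma must lie in (2, 3)")
    k = np.arange(1, l_max + 1, dtype=float)
    p = k**-gamma
    p /= p.sum()
    return rng.choice(np.arange(1, l_max + 1), size=n, p=p)


def random_sparse_network(
    n: int,
    K: int,
    n_links: int,
    l_max: int,
    power_law: float | None = None,
    seed: int = 0,
    T: int = 59,
) -> GroundTruthNetwork:
    """A random sparse tanh network driven by K sinusoidal factors.

    In-degrees are uniform over 1..l_max (or power-law k^-gamma when
    ``power_law`` is given) and then repaired to sum to ``n_links``.
    Factors have no incoming links.
    """
    if n_links > n * l_max:
        raise ValueError(f"cannot place {n_links} links with n={n}, l_max={l_max}")
    if n_links < 0:
        raise ValueError("n_links must be >= 0")
    rng = np.random.default_rng(seed)
    if n_links == 0:
        degrees = np.zeros(n, dtype=int)
    elif power_law is not None:
        degrees = sample_power_law_indegrees(n, l_max, power_law, rng)
    else:
        degrees = rng.integers(1, l_max + 1, size=n)
    # repair the degree sequence to the requested total
    lo = 0 if n_links < n else 1
    while degrees.sum() != n_links:
        i = int(rng.integers(0, n))
        if degrees.sum() > n_links and degrees[i] > lo:
            degrees[i] -= 1
        elif degrees.sum() < n_links and degrees[i] < l_max:
            degrees[i] += 1

    gene_ids = [f"g{i + 1}" for i in range(n)]
    factor_ids = [f"F{k + 1}" for k in range(K)]
    factor_series = {
        fid: generate_factor_series(
            T,
            amplitude=rng.uniform(0.6, 1.0),
            period=rng.uniform(T / 3, T / 1.5),
            phase=rng.uniform(0, 2 * math.pi),
        )
        for fid in factor_ids
    }
    params: dict[str, GeneParameters] = {}
    for i, gid in enumerate(gene_ids):
        candidates = [g for g in gene_ids if g != gid] + factor_ids
        regs = list(rng.choice(candidates, size=degrees[i], replace=False))
        w, w_factor = {}, {}
        for rid in regs:
            weight = float(rng.uniform(0.6, 1.4) * rng.choice([-1.0, 1.0]))
            (w_factor if rid in factor_ids else w)[rid] = weight
        params[gid] = GeneParameters(
            alpha=float(rng.uniform(0.25, 0.5) * rng.choice([-1.0, 1.0])),
            beta=float(rng.uniform(-0.2, 0.2)),
            w=w,
            w_factor=w_factor,
        )
    initial = {gid: float(rng.uniform(-0.5, 0.5)) for gid in gene_ids}
    return GroundTruthNetwork(
        gene_ids, factor_ids, params, initial, factor_series, name=f"random-{seed}"
    )


# ----------------------------------------------------------------------
# packaged reference network: 11 genes, 2 factors, 26 links, 59 points
# ----------------------------------------------------------------------

def benchmark_network() -> GroundTruthNetwork:
    """The packaged fixed benchmark: 11 genes, 2 sinusoid-driven factors,
    26 directed links (143 candidate pairs, 117 absent), 59 time points.

    Coefficients were hand-tuned so that noise-free trajectories are
    bounded, oscillatory and non-constant; it is an analogue of published
    small-network benchmarks, not a replica of any particular one.
    """
    T = 59
    # each factor mixes a dominant slow tone with a weaker fast one: the
    # gene tier low-passes its inputs, so the fast component never reaches
    # the gene rows with full amplitude — factors stay identifiable as
    # factors (no within-network explanation) and no gene can impersonate
    # a true regulator that carries the fast component
    factor_series = {
        "F1": (
            generate_factor_series(T, amplitude=0.9, period=12.0, phase=0.0)
            + generate_factor_series(T, amplitude=0.45, period=5.0, phase=0.5)
        ),
        "F2": (
            generate_factor_series(T, amplitude=0.8, period=9.0, phase=0.9)
            + generate_factor_series(T, amplitude=0.45, period=5.0, phase=2.6)
        ),
    }
    # 26 links total: 15 gene/factor -> other-gene links + a repressive
    # self-loop on every gene (mean reversion keeps the cascade oscillating
    # around its driven equilibrium instead of drifting). Factor periods
    # are fast relative to T so per-step increments carry a sizeable share
    # of each trajectory's variance (one-step changes are informative);
    # g5 mixes both factor lineages so no single other row can impersonate
    # an upstream gene's self-feedback.
    spec: dict[str, tuple[float, float, dict[str, float], dict[str, float]]] = {
        # gid: (alpha, beta, w (genes incl. self), w_factor)
        "g1": (0.55, 0.0, {"g1": -0.8}, {"F1": 1.8}),
        "g2": (0.50, 0.0, {"g2": -1.2}, {"F2": -1.8}),
        "g3": (0.60, 0.0, {"g3": -1.2}, {"F1": 1.4, "F2": 1.2}),
        "g4": (0.55, 0.0, {"g1": 1.8, "g4": -0.6}, {}),
        "g5": (0.50, 0.0, {"g2": -1.8, "g5": -1.2}, {"F1": 1.2}),
        "g6": (0.60, 0.0, {"g3": 1.6, "g6": -1.2}, {}),
        "g7": (0.55, 0.0, {"g4": 1.8, "g7": -1.5}, {}),
        "g8": (0.50, 0.0, {"g5": -1.6, "g8": -1.2}, {}),
        "g9": (0.65, 0.0, {"g6": 1.8, "g7": -1.8, "g9": -1.5}, {}),
        "g10": (0.55, 0.0, {"g8": 1.6, "g10": -1.2}, {}),
        "g11": (0.60, 0.0, {"g10": 1.8, "g9": 1.8, "g11": -1.5}, {}),
    }
    params = {
        gid: GeneParameters(alpha=a, beta=b, w=w, w_factor=wf)
        for gid, (a, b, w, wf) in spec.items()
    }
    initial = {gid: 0.0 for gid in spec}
    gene_ids = [f"g{i}" for i in range(1, 12)]
    return GroundTruthNetwork(
        gene_ids, ["F1", "F2"], params, initial, factor_series, name="benchmark"
    )
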