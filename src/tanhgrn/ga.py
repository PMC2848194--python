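"""Genetic-algorithm search over partially-connected network structures.

A candidate structure is encoded as an n x l_max bit matrix: each gene's
l_max bits specify its in-degree (the popcount), so the search space has
l_max^n structures when zero in-degree is disallowed. For a given
chromosome, all regulator sets of the encoded in-degree are enumerated per
gene, each is fitted by the annealing optimizer, and the set with the
smallest SSE is retained; the self-link is a separate per-gene toggle that
is fitted both ways and counted in the parameter total but not in the
in-degree. Chromosome fitness is an AIC/BIC score over the per-gene fits,
on the same SSE/Var scale as the estimation cost (Gaussian likelihood with
each gene's sample variance treated as known):

    score = sum_i SSE_i / Var_i + pen * p(pi),
    p(pi) = sum_i (2 + L(pi_i) + self_i),  pen = 2 (AIC) or ln(T') (BIC)

with T' = T - 1 fitted steps entering the BIC penalty; lower is better. Generations evolve by
one-point interior crossover, single-bit mutation biased toward fitter
chromosomes, and elitist selection of the best N/2 parents plus the best
N/2 children. The in-degree alphabet may optionally be restricted to a
power-law distribution P(k) ~ k^-gamma, 2 < gamma < 3.

Because the retained fit per (gene, in-degree) never changes, fits are
memoised: each distinct candidate link set is annealed once per dataset.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np

from .dataset import ExpressionDataset
from .dynamics import GeneParameters
from .sa import RANKING_BUDGET, SAConfig, SEARCH_BUDGET, GeneFit, fit_gene

SSE_FLOOR = 1e-12

class StructureSearchError(ValueError):
    pass


# ----------------------------------------------------------------------
# counting / enumeration
# ----------------------------------------------------------------------

def search_space_size(n: int, l_max: int, allow_zero_indegree: bool = False) -> int:
    """Number of encodable structures: l_max^n in-degree assignments per
    gene (in-degrees 1..l_max), or (l_max+1)^n when zero is allowed."""
    if n < 1 or l_max < 1:
        raise StructureSearchError("need n >= 1 and l_max >= 1")
    base = l_max + 1 if allow_zero_indegree else l_max
    return base**n


def enumerate_link_sets(candidates: list[str], d: int) -> list[tuple[str, ...]]:
    """All C(len(candidates), d) regulator sets of size d (self-links are
    handled as a separate binary option, not enumerated here)."""
    if d < 0 or d > len(candidates):
        raise StructureSearchError(
            f"in-degree {d} infeasible with {len(candidates)} candidates"
        )
    return list(itertools.combinations(candidates, d))


def penalty_coefficient(criterion: str, t_prime: int) -> float:
    if criterion == "aic":
        return 2.0
    if criterion == "bic":
        return math.log(t_prime)
    raise StructureSearchError(f"unknown criterion {criterion!r}")


def gene_score(
    sse: float,
    var: float,
    n_links: int,
    has_self: bool,
    t_prime: int,
    criterion: str,
) -> float:
    """Per-gene contribution to the AIC/BIC fitness (lower is better).

    SSE/Var is -2 log likelihood (up to a constant) for Gaussian one-step
    errors with the gene's sample variance treated as known, so a
    parameter must buy an SSE/Var reduction of 2 (AIC) or ln(T') (BIC)
    to pay for itself. Always positive.
    """
    pen = penalty_coefficient(criterion, t_prime)
    n_params = 2 + n_links + (1 if has_self else 0)
    return max(sse, SSE_FLOOR) / var + pen * n_params


# ----------------------------------------------------------------------
# chromosome operators
# ----------------------------------------------------------------------

@dataclass
class Chromosome:
    """n x l_max bit matrix; row popcount = the gene's in-degree."""

    bits: np.ndarray  # (n, l_max) uint8

    @property
    def n_genes(self) -> int:
        return self.bits.shape[0]

    @property
    def l_max(self) -> int:
        return self.bits.shape[1]

    def in_degrees(self) -> np.ndarray:
        return self.bits.sum(axis=1).astype(int)

    def flat(self) -> np.ndarray:
        return self.bits.reshape(-1)

    def copy(self) -> "Chromosome":
        return Chromosome(self.bits.copy())

    def key(self) -> tuple:
        return tuple(self.in_degrees())


def _bits_for_degree(d: int, l_max: int, rng: np.random.Generator) -> np.ndarray:
    row = np.zeros(l_max, dtype=np.uint8)
    if d:
        row[rng.choice(l_max, size=d, replace=False)] = 1
    return row


def random_chromosome(
    n: int,
    l_max: int,
    rng: np.random.Generator,
    power_law: float | None = None,
    allow_zero_indegree: bool = False,
) -> Chromosome:
    """Random structure; per-gene in-degrees uniform over the alphabet, or
    power-law distributed when gamma is given."""
    if power_law is not None:
        from .simulate import sample_power_law_indegrees

        degrees = sample_power_law_indegrees(n, l_max, power_law, rng)
    else:
        lo = 0 if allow_zero_indegree else 1
        degrees = rng.integers(lo, l_max + 1, size=n)
    bits = np.vstack([_bits_for_degree(int(d), l_max, rng) for d in degrees])
    return Chromosome(bits)


def repair(chrom: Chromosome, rng: np.random.Generator) -> Chromosome:
    """Enforce the in-degree alphabet {1..l_max}: any gene left with zero
    bits after crossover/mutation gets one random bit set."""
    for i in range(chrom.n_genes):
        if chrom.bits[i].sum() == 0:
            chrom.bits[i, rng.integers(0, chrom.l_max)] = 1
    return chrom


def crossover(
    parent1: Chromosome, parent2: Chromosome, rng: np.random.Generator
) -> tuple[Chromosome, Chromosome]:
    """One-point crossover; the cut is uniform over interior bit positions
    (never at the end points), and the children swap suffixes."""
    f1, f2 = parent1.flat(), parent2.flat()
    if f1.size != f2.size:
        raise StructureSearchError("parents must have equal length")
    if f1.size < 3:
        raise StructureSearchError("chromosome too short for interior crossover")
    cut = int(rng.integers(1, f1.size))  # cut before position `cut`, 1..L-1
    c1 = np.concatenate([f1[:cut], f2[cut:]])
    c2 = np.concatenate([f2[:cut], f1[cut:]])
    shape = parent1.bits.shape
    return Chromosome(c1.reshape(shape)), Chromosome(c2.reshape(shape))


def mutation_weights(scores: np.ndarray, delta: float = 1e-9) -> np.ndarray:
    """Selection weights for mutation: literally inversely proportional to
    the score, w_i = 1/score_i normalised (scores are positive on the
    SSE/Var + penalty scale). Lower-score (fitter) chromosomes are *more*
    likely to be refined by mutation; equal scores give uniform selection.
    Falls back to a shifted-inverse if a non-positive score ever appears."""
    s = np.asarray(scores, dtype=float)
    if not np.isfinite(s).all():
        raise StructureSearchError("fitness scores must be finite")
    if (s <= 0).any():
        s = s - s.min() + 1.0
    w = 1.0 / (s + delta)
    return w / w.sum()


def mutate(
    population: list[Chromosome],
    scores: np.ndarray,
    rng: np.random.Generator,
    count: int | None = None,
    power_law: float | None = None,
) -> list[Chromosome]:
    """Create mutant children by toggling one bit of selected chromosomes
    (or, under the power-law restriction, resampling one gene's in-degree
    from k^-gamma)."""
    n_pop = len(population)
    count = count if count is not None else max(1, n_pop // 2)
    weights = mutation_weights(np.asarray(scores))
    picks = rng.choice(n_pop, size=count, p=weights)
    mutants = []
    for idx in picks:
        m = population[idx].copy()
        if power_law is not None:
            from .simulate import sample_power_law_indegrees

            gi = int(rng.integers(0, m.n_genes))
            d = int(sample_power_law_indegrees(1, m.l_max, power_law, rng)[0])
            m.bits[gi] = _bits_for_degree(d, m.l_max, rng)
        else:
            pos = int(rng.integers(0, m.bits.size))
            m.bits.reshape(-1)[pos] ^= 1
        mutants.append(repair(m, rng))
    return mutants


def select_next_generation(
    parents: list[Chromosome],
    parent_scores: np.ndarray,
    children: list[Chromosome],
    child_scores: np.ndarray,
    n: int,
) -> tuple[list[Chromosome], np.ndarray]:
    """Elitist selection: the best n/2 parents and the best n/2 children
    (lower score = fitter); ties broken by fewer total links then index.
    A short child pool is topped up from the remaining parents."""
    if n % 2:
        raise StructureSearchError("population size must be even")

    def order(pool, scores):
        return sorted(
            range(len(pool)),
            key=lambda i: (scores[i], int(pool[i].in_degrees().sum()), i),
        )

    po = order(parents, parent_scores)
    co = order(children, child_scores)
    half = n // 2
    take_children = min(half, len(children))
    take_parents = n - take_children
    sel = [(parents[i], parent_scores[i]) for i in po[:take_parents]]
    sel += [(children[i], child_scores[i]) for i in co[:take_children]]
    chroms = [c for c, _ in sel]
    scores = np.array([s for _, s in sel], dtype=float)
    return chroms, scores


# ----------------------------------------------------------------------
# per-gene fit cache
# ----------------------------------------------------------------------

@dataclass
class GeneDegreeFit:
    """Best fit (smallest SSE) for one gene at one in-degree and self flag."""

    regulators: tuple[str, ...]
    has_self: bool
    params: GeneParameters
    sse: float
    energy: float


class GeneFitCache:
    """Memoised per-(gene, in-degree) best fits over enumerated link sets.

    For gene i and in-degree d, every set of d candidate regulators (all
    other genes plus all factors) is fitted by the annealing optimizer with
    and without the self-link, and the smallest-SSE set per self flag is
    retained. Seeds derive deterministically from the root seed and the
    combination index, so repeated runs are identical.
    """

    def __init__(
        self,
        data: ExpressionDataset,
        factors: list[str],
        sa_cfg: SAConfig | None = None,
        seed: int = 0,
        fit_self: bool = True,
        refine_cfg: SAConfig | None = None,
        top_k: int = 3,
    ):
        self.data = data
        self.factors = list(factors)
        self.genes = [g for g in data.ids if g not in set(factors)]
        self.sa_cfg = sa_cfg or RANKING_BUDGET
        self.seed = seed
        self.fit_self = fit_self
        # two-stage fitting: every set is ranked with the cheap budget,
        # then the top_k per (degree, self flag) are refitted at refine_cfg
        # so the retained SSE is a trustworthy minimum (restart cycles are
        # capped: on noisy data eps-sized improvements never dry up and
        # uncapped restarts triple the run time for no selection benefit)
        self.refine_cfg = refine_cfg if refine_cfg is not None else SAConfig(max_cycles=8)
        self.top_k = max(1, top_k)
        self._cache: dict[tuple[str, int], dict[bool, GeneDegreeFit]] = {}
        self.n_fits = 0

    def candidates(self, gene: str) -> list[str]:
        return [g for g in self.genes if g != gene] + self.factors

    def _fit_seed(self, gene_i: int, d: int, combo_i: int, with_self: bool) -> int:
        ss = np.random.SeedSequence(
            entropy=[self.seed, gene_i, d, combo_i, int(with_self)]
        )
        return int(ss.generate_state(1)[0] % 2**31)

    def best_fits(self, gene: str, d: int) -> dict[bool, GeneDegreeFit]:
        key = (gene, d)
        if key in self._cache:
            return self._cache[key]
        gene_i = self.genes.index(gene)
        cands = self.candidates(gene)
        best: dict[bool, GeneDegreeFit] = {}
        self_options = (False, True) if self.fit_self else (False,)
        combos = enumerate_link_sets(cands, d)
        for with_self in self_options:
            # stage 1: cheap ranking fit of every candidate set
            ranked: list[tuple[float, int]] = []
            for combo_i, combo in enumerate(combos):
                regs = list(combo) + ([gene] if with_self else [])
                fit: GeneFit = fit_gene(
                    regs,
                    self.data,
                    gene,
                    self.sa_cfg,
                    seed=self._fit_seed(gene_i, d, combo_i, with_self),
                )
                self.n_fits += 1
                ranked.append((fit.sse, combo_i))
            ranked.sort()
            # stage 2: refit the leading sets with the full budget and
            # retain the smallest refined SSE
            for rank, (_, combo_i) in enumerate(ranked[: self.top_k]):
                combo = combos[combo_i]
                regs = list(combo) + ([gene] if with_self else [])
                fit = fit_gene(
                    regs,
                    self.data,
                    gene,
                    self.refine_cfg,
                    seed=self._fit_seed(gene_i, d, combo_i, with_self) + 1,
                )
                self.n_fits += 1
                if with_self not in best or fit.sse < best[with_self].sse:
                    best[with_self] = GeneDegreeFit(
                        regulators=tuple(combo),
                        has_self=with_self,
                        params=fit.params,
                        sse=fit.sse,
                        energy=fit.energy,
                    )
        self._cache[key] = best
        return best

    def gene_term(self, gene: str, d: int, t_prime: int, criterion: str) -> tuple[float, GeneDegreeFit]:
        """Best per-gene criterion contribution at in-degree d (the self
        flag is chosen by the criterion, since raw SSE always prefers the
        extra self parameter)."""
        var = float(self.data.var[gene])
        options = self.best_fits(gene, d)
        scored = [
            (gene_score(f.sse, var, d, f.has_self, t_prime, criterion), f)
            for f in options.values()
        ]
        scored.sort(key=lambda sf: (sf[0], sf[1].has_self))
        return scored[0]


# ----------------------------------------------------------------------
# full search
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class GAConfig:
    """Structure-search controls (population size N must be even)."""

    N: int = 50
    l_max: int = 4
    criterion: str = "aic"
    power_law: float | None = None
    max_generations: int = 200
    convergence_window: int = 20
    tol: float = 1e-6
    allow_zero_indegree: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.N % 2 or self.N < 2:
            raise StructureSearchError("population size N must be even and >= 2")
        if self.l_max < 1:
            raise StructureSearchError("l_max must be >= 1")
        if self.power_law is not None and not 2.0 < self.power_law < 3.0:
            raise StructureSearchError("power-law gamma must lie in (2, 3)")
        penalty_coefficient(self.criterion, 2)  # validates the name


@dataclass
class StructureFit:
    """A fitted network structure: per-gene link sets and parameters."""

    genes: list[str]
    factors: list[str]
    regulators: dict[str, tuple[str, ...]]  # excludes the self-link
    has_self: dict[str, bool]
    params: dict[str, GeneParameters]
    sse: dict[str, float]
    fitness: float
    criterion: str
    trace: list[float] = field(default_factory=list)
    converged: bool = True
    n_fits: int = 0

    def n_links(self, gene: str) -> int:
        return len(self.regulators[gene])

    def edges(self) -> list[tuple[str, str, float, int]]:
        """Predicted signed edge list, self-links included."""
        out = []
        for gid in self.genes:
            gp = self.params[gid]
            for rid, w in {**gp.w, **gp.w_factor}.items():
                out.append((rid, gid, float(w), int(np.sign(gp.alpha * w)) or 1))
        return sorted(out, key=lambda e: (e[0], e[1]))


def _chromosome_fitness(
    chrom: Chromosome,
    cache: GeneFitCache,
    t_prime: int,
    criterion: str,
    memo: dict,
) -> float:
    key = chrom.key()
    if key in memo:
        return memo[key]
    total = 0.0
    for gene, d in zip(cache.genes, chrom.in_degrees()):
        term, _ = cache.gene_term(gene, int(d), t_prime, criterion)
        total += term
    memo[key] = total
    return total


def structure_from_chromosome(
    chrom: Chromosome, cache: GeneFitCache, t_prime: int, criterion: str
) -> StructureFit:
    regulators, has_self, params, sse = {}, {}, {}, {}
    total = 0.0
    for gene, d in zip(cache.genes, chrom.in_degrees()):
        term, fit = cache.gene_term(gene, int(d), t_prime, criterion)
        total += term
        regulators[gene] = fit.regulators
        has_self[gene] = fit.has_self
        params[gene] = fit.params
        sse[gene] = fit.sse
    return StructureFit(
        genes=list(cache.genes),
        factors=list(cache.factors),
        regulators=regulators,
        has_self=has_self,
        params=params,
        sse=sse,
        fitness=total,
        criterion=criterion,
        n_fits=cache.n_fits,
    )


def run_ga(
    data: ExpressionDataset,
    factors: list[str] | None = None,
    cfg: GAConfig | None = None,
    sa_cfg: SAConfig | None = None,
) -> StructureFit:
    """Evolve network structures and return the best-scoring one.

    ``factors`` defaults to the dataset's designated factor rows. The run
    converges when the best score changes by less than ``tol`` over
    ``convergence_window`` consecutive generations.
    """
    cfg = cfg or GAConfig()
    factors = list(factors if factors is not None else data.factor_ids)
    cache = GeneFitCache(data, factors, sa_cfg, seed=cfg.seed)
    n = len(cache.genes)
    if n < 1:
        raise StructureSearchError("no gene rows to fit")
    t_prime = data.n_times - 1
    rng = np.random.default_rng(np.random.SeedSequence(entropy=[cfg.seed, 0x6A]))
    memo: dict = {}

    pop = [
        random_chromosome(n, cfg.l_max, rng, cfg.power_law, cfg.allow_zero_indegree)
        for _ in range(cfg.N)
    ]
    scores = np.array(
        [_chromosome_fitness(c, cache, t_prime, cfg.criterion, memo) for c in pop]
    )
    best_trace = [float(scores.min())]
    converged = False

    for _gen in range(cfg.max_generations):
        children: list[Chromosome] = []
        if pop[0].flat().size >= 3:
            perm = rng.permutation(cfg.N)
            for i in range(0, cfg.N - 1, 2):
                c1, c2 = crossover(pop[perm[i]], pop[perm[i + 1]], rng)
                if not cfg.allow_zero_indegree:
                    repair(c1, rng), repair(c2, rng)
                children.extend([c1, c2])
        children.extend(
            mutate(pop, scores, rng, count=max(1, cfg.N // 2), power_law=cfg.power_law)
        )
        child_scores = np.array(
            [_chromosome_fitness(c, cache, t_prime, cfg.criterion, memo) for c in children]
        )
        pop, scores = select_next_generation(pop, scores, children, child_scores, cfg.N)
        best_trace.append(float(scores.min()))
        w = cfg.convergence_window
        if len(best_trace) > w and abs(best_trace[-1 - w] - best_trace[-1]) < cfg.tol:
            converged = True
            break

    best_idx = min(
        range(len(pop)),
        key=lambda i: (scores[i], int(pop[i].in_degrees().sum()), i),
    )
    fit = structure_from_chromosome(pop[best_idx], cache, t_prime, cfg.criterion)
    fit.trace = best_trace
    fit.converged = converged
    fit.n_fits = cache.n_fits
    return fit
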